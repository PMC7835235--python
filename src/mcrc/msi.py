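"""MSI-prone sequence counting and enrichment tests.

Genes preferentially mutated in microsatellite-instable (MSI) tumors are
identified in two steps: (1) genes associated with the high-TMB cluster by a
Fisher exact test corrected with a TMB-weighted permutation test (high-burden
samples are more likely to carry any mutation by chance); (2) for each such
gene, a one-sided sign test of its MSI-sample mutation frequency against the
frequencies of control genes carrying a comparable number (within +/-10%) of
MSI-prone coding sequences (exonic repeats plus mononucleotide stretches of
length 6-13).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import fisher_2x2, hochberg_adjust


def find_mono_stretches(
    seq: str, min_len: int = 6, max_len: int = 13
) -> list[tuple[int, int, str]]:
    """Maximal mononucleotide runs with min_len <= length <= max_len.

    Returns (offset, length, base) per qualifying run. Longer runs are NOT
    counted here (they are assumed covered by the repeat annotation input);
    non-ACGT characters break runs. Case-insensitive.
    """
    s = seq.upper()
    out = []
    i, n = 0, len(s)
    while i < n:
        b = s[i]
        j = i + 1
        while j < n and s[j] == b:
            j += 1
        if b in "ACGT" and min_len <= j - i <= max_len:
            out.append((i, j - i, b))
        i = j
    return out


def count_mono_stretches(
    sequence: str | list[str], min_len: int = 6, max_len: int = 13
) -> int:
    """Count qualifying mononucleotide stretches; a list is counted per exon
    (runs never span exon junctions)."""
    exons = [sequence] if isinstance(sequence, str) else list(sequence)
    return sum(len(find_mono_stretches(e, min_len, max_len)) for e in exons)


def count_msi_prone(
    sequences: dict[str, str | list[str]],
    repeats: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene MSI-prone profile: annotated repeats + mononucleotide stretches."""
    repeats = repeats or {}
    rows = []
    genes = sorted(set(sequences) | set(repeats))
    for gene in genes:
        seq = sequences.get(gene)
        n_stretch = count_mono_stretches(seq) if seq is not None else np.nan
        n_rep = int(repeats.get(gene, 0))
        rows.append(
            {
                "gene_id": gene,
                "n_repeats": n_rep,
                "n_mono_stretches": n_stretch,
                "msi_prone_total": n_rep + (0 if np.isnan(n_stretch) else int(n_stretch)),
                "sequence_missing": seq is None,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class EnrichmentResult:
    gene_id: str
    observed_freq: float
    n_controls: int
    n_effective: int
    n_below: int
    p_sign: float
    testable: bool
    note: str = ""


def sign_test_p(k: int, n_eff: int) -> float:
    """One-sided sign test: P(Bin(n_eff, 1/2) >= k).

    Exact integer arithmetic up to n_eff = 64 (the tail is a dyadic
    rational), scipy's survival function beyond.
    """
    if n_eff == 0:
        return 1.0
    if n_eff <= 64:
        import math

        tail = sum(math.comb(n_eff, j) for j in range(max(k, 0), n_eff + 1))
        return tail / 2**n_eff
    return float(sps.binom.sf(k - 1, n_eff, 0.5))


def matched_control_test(
    gene: str,
    mutation_matrix: pd.DataFrame,  # samples x genes boolean flags
    msi_samples: list[str],
    profiles: pd.DataFrame,  # from count_msi_prone
    tolerance: float = 0.10,
) -> EnrichmentResult:
    """One-sided sign test of a gene's MSI mutation frequency against
    stretch-count-matched control genes.

    Controls are all other genes whose msi_prone_total lies within
    +/- tolerance of the gene's; ties with the observed frequency are
    excluded from the effective trials.
    """
    if not msi_samples:
        raise ValueError("need at least one MSI sample")
    total = profiles.loc[gene, "msi_prone_total"]
    lo, hi = total * (1 - tolerance), total * (1 + tolerance)
    pool = profiles[
        (profiles.msi_prone_total >= lo)
        & (profiles.msi_prone_total <= hi)
        & (profiles.index != gene)
    ].index
    pool = [g for g in pool if g in mutation_matrix.columns]
    msi_flags = mutation_matrix.loc[msi_samples]
    observed = float(msi_flags[gene].mean())
    if not pool:
        return EnrichmentResult(
            gene, observed, 0, 0, 0, np.nan, testable=False,
            note="no reliable control distribution",
        )
    control_freqs = msi_flags[pool].mean(axis=0).to_numpy()
    below = int((control_freqs < observed).sum())
    ties = int((control_freqs == observed).sum())
    n_eff = len(pool) - ties
    p = sign_test_p(below, n_eff)
    return EnrichmentResult(gene, observed, len(pool), n_eff, below, p, testable=True)


def _weighted_sample_counts(
    weights: np.ndarray, m: int, in_cluster: np.ndarray, n_perm: int, rng
) -> np.ndarray:
    """For n_perm draws of m samples without replacement with probability
    proportional to ``weights``, count how many fall in the cluster.

    Uses the Gumbel top-k trick: the indices of the m largest
    log(w) + Gumbel noise are a weighted sample without replacement.
    """
    n = len(weights)
    logw = np.log(weights)
    gumbel = rng.gumbel(size=(n_perm, n))
    keys = logw[None, :] + gumbel
    top = np.argpartition(keys, n - m, axis=1)[:, n - m :]
    return in_cluster[top].sum(axis=1)


def high_tmb_gene_test(
    mutation_matrix: pd.DataFrame,  # samples x genes boolean
    cluster_flags: pd.Series,  # boolean, True = high-TMB cluster member
    tmb: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cluster-association test per gene with TMB-weighted permutation control.

    Per gene: two-sided Fisher exact on mutated x cluster membership, Hochberg
    adjusted across genes; the permutation null redraws the gene's mutated
    samples without replacement with probability proportional to sample TMB
    and recounts the cluster overlap, p_perm = (1 + #{>= observed}) /
    (n_perm + 1). A gene is reported when both the adjusted Fisher p and
    p_perm fall below ``alpha``.
    """
    samples = list(mutation_matrix.index)
    cl = cluster_flags.reindex(samples).to_numpy(dtype=bool)
    w = tmb.reindex(samples).to_numpy(dtype=float)
    if cl.sum() < 2 or (~cl).sum() < 2:
        raise ValueError("need at least 2 samples in each cluster group")
    if (w <= 0).any():
        w = np.maximum(w, w[w > 0].min() / 10 if (w > 0).any() else 1e-6)
    rng = np.random.default_rng(seed)
    rows = []
    for gene in mutation_matrix.columns:
        mut = mutation_matrix[gene].to_numpy(dtype=bool)
        m = int(mut.sum())
        a = int((mut & cl).sum())
        fisher = fisher_2x2(a, m - a, int(cl.sum()) - a, int((~cl).sum()) - (m - a))
        if m == 0:
            p_perm = 1.0
        else:
            perm_counts = _weighted_sample_counts(w, m, cl.astype(int), n_perm, rng)
            p_perm = (1 + int((perm_counts >= a).sum())) / (n_perm + 1)
        rows.append(
            {
                "gene_id": gene,
                "n_mutated": m,
                "n_mutated_in_cluster": a,
                "p_fisher": fisher.p_two_sided,
                "p_perm": p_perm,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    df["p_fisher_adjusted"] = hochberg_adjust(df.p_fisher.to_numpy())
    df["reported"] = (df.p_fisher_adjusted < alpha) & (df.p_perm < alpha)
    return df
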