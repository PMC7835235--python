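"""Context counting, reference-signature refitting, dominant-signature selection,
TMB, and exposure-based hierarchical clustering.

Refitting solves, per sample, the non-negative least-squares problem
min ||R e - c||_2 s.t. e >= 0 over the reference profile matrix R and the
sample's channel counts c; relative contributions are e / sum(e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls

from . import channels
from .io import FormatError, MutationCatalog, SignatureMatrix


@dataclass
class ContextCounts:
    """samples x channels non-negative integer matrix (96 SBS or 78 DBS)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.shape[1] == 96:
            expected = list(channels.SBS96_LABELS)
        elif self.df.shape[1] == 78:
            expected = list(channels.DBS78_LABELS)
        else:
            raise FormatError(f"expected 96 or 78 channels, got {self.df.shape[1]}")
        self.df = self.df[expected].astype(np.int64)
        if (self.df.to_numpy() < 0).any():
            raise FormatError("negative channel counts")


@dataclass
class ExposureResult:
    """Refitting output: relative and absolute exposures plus diagnostics."""

    relative: pd.DataFrame  # samples x signatures, rows sum to 1 (or all-zero)
    absolute: pd.DataFrame  # estimated mutation counts per signature
    reconstruction_cosine: pd.Series
    zero_samples: list[str] = field(default_factory=list)


def count_contexts(
    catalog: MutationCatalog,
    context_source: str | dict[str, str] = "stored",
) -> tuple[ContextCounts, ContextCounts, pd.DataFrame]:
    """Tabulate SBS96 and DBS78 channel counts per sample.

    SNVs need a trinucleotide context: either stored on the record
    (``context_source="stored"``) or looked up in chromosome sequences passed
    as a dict. Doublet channels come from length-2 MNVs; longer MNVs and
    indels are excluded and returned in the residual report.
    """
    v = catalog.variants
    samples = catalog.samples
    sbs = pd.DataFrame(
        0, index=samples, columns=list(channels.SBS96_LABELS), dtype=np.int64
    )
    dbs = pd.DataFrame(
        0, index=samples, columns=list(channels.DBS78_LABELS), dtype=np.int64
    )
    residuals = []

    snvs = v[v.vclass == "SNV"]
    missing = []
    labels = []
    label_samples = []
    for row in snvs.itertuples():
        if isinstance(context_source, dict):
            seq = context_source.get(row.chrom)
            if seq is None or not (2 <= row.pos <= len(seq) - 1):
                missing.append(f"{row.sample_id}:{row.chrom}:{row.pos}")
                continue
            ctx = seq[row.pos - 2 : row.pos + 1].upper()
        else:
            ctx = row.context
        if not isinstance(ctx, str) or len(ctx) != 3:
            missing.append(f"{row.sample_id}:{row.chrom}:{row.pos}")
            continue
        labels.append(channels.sbs_channel(row.ref, row.alt, ctx))
        label_samples.append(row.sample_id)
    if missing:
        raise FormatError(
            f"{len(missing)} SNVs lack a trinucleotide context, e.g. {missing[:5]}"
        )
    if labels:
        tab = pd.crosstab(pd.Series(label_samples), pd.Series(labels))
        sbs = sbs.add(
            tab.reindex(index=samples, columns=sbs.columns, fill_value=0), fill_value=0
        ).astype(np.int64)

    mnvs = v[v.vclass == "MNV"]
    dlabels, dsamples = [], []
    for row in mnvs.itertuples():
        if len(row.ref) != 2:
            residuals.append((row.sample_id, row.chrom, row.pos, "MNV length > 2"))
            continue
        try:
            dlabels.append(channels.dbs_channel(row.ref, row.alt))
        except ValueError as exc:
            residuals.append((row.sample_id, row.chrom, row.pos, str(exc)))
            continue
        dsamples.append(row.sample_id)
    if dlabels:
        tab = pd.crosstab(pd.Series(dsamples), pd.Series(dlabels))
        dbs = dbs.add(
            tab.reindex(index=samples, columns=dbs.columns, fill_value=0), fill_value=0
        ).astype(np.int64)

    residual_df = pd.DataFrame(
        residuals, columns=["sample_id", "chrom", "pos", "reason"]
    )
    return ContextCounts(sbs), ContextCounts(dbs), residual_df


def refit_exposures(counts: ContextCounts, reference: SignatureMatrix) -> ExposureResult:
    """Non-negative least-squares refit of reference signatures per sample."""
    if list(counts.df.columns) != reference.channels:
        raise FormatError("channel labels of counts and reference do not match")
    R = reference.values.to_numpy()
    sigs = reference.signatures
    rel_rows, abs_rows, cosines, zero = [], [], [], []
    for sample, row in counts.df.iterrows():
        c = row.to_numpy(dtype=float)
        total = c.sum()
        if total == 0:
            rel_rows.append(np.zeros(len(sigs)))
            abs_rows.append(np.zeros(len(sigs)))
            cosines.append(np.nan)
            zero.append(sample)
            continue
        e, _ = nnls(R, c)
        recon = R @ e
        denom = np.linalg.norm(recon) * np.linalg.norm(c)
        cosines.append(float(recon @ c / denom) if denom > 0 else np.nan)
        s = e.sum()
        rel_rows.append(e / s if s > 0 else np.zeros(len(sigs)))
        abs_rows.append(e)
    idx = counts.df.index
    return ExposureResult(
        relative=pd.DataFrame(rel_rows, index=idx, columns=sigs),
        absolute=pd.DataFrame(abs_rows, index=idx, columns=sigs),
        reconstruction_cosine=pd.Series(cosines, index=idx, name="cosine"),
        zero_samples=zero,
    )


def select_dominant(
    exposures: pd.DataFrame,
    min_contribution: float = 0.10,
    min_samples: int = 10,
) -> list[str]:
    """Signatures with relative contribution >= min_contribution in >= min_samples samples.

    Both thresholds are inclusive ("at least 10% in minimally 10 cases").
    All-zero rows (zero-mutation samples) are excluded before counting.
    """
    nonzero = exposures[exposures.sum(axis=1) > 0]
    hits = (nonzero >= min_contribution).sum(axis=0)
    return [s for s in exposures.columns if hits.get(s, 0) >= min_samples]


def clustering_signature_set(
    exposures: pd.DataFrame,
    dominant: list[str],
    extra: list[str] | None = None,
    single_sample_threshold: float = 0.25,
) -> list[str]:
    """Dominant signatures, plus externally curated extras, plus any signature
    exceeding ``single_sample_threshold`` (strict) in at least one sample."""
    extra = extra or []
    unknown = [s for s in extra if s not in exposures.columns]
    if unknown:
        raise FormatError(f"unknown extra signatures: {unknown}")
    singles = [
        s
        for s in exposures.columns
        if (exposures[s] > single_sample_threshold).any()
    ]
    seen: dict[str, None] = {}
    for s in list(dominant) + list(extra) + singles:
        seen.setdefault(s)
    return list(seen)


def _safe_correlation_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance with a deterministic rule for
    zero-variance rows: equal constant rows are at distance 0, anything else
    at distance 1."""
    n = x.shape[0]
    sd = x.std(axis=1)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                d = 0.0 if np.array_equal(x[i], x[j]) else 1.0
            else:
                r = np.corrcoef(x[i], x[j])[0, 1]
                d = 1.0 - r
            out.append(d)
    return np.array(out)


def cluster_samples(
    exposures: pd.DataFrame,
    signatures: list[str],
    k: int = 6,
    distance: str = "correlation",
    linkage: str = "average",
) -> tuple[pd.Series, list[str], np.ndarray]:
    """Hierarchical clustering of samples on median-centered contributions.

    Each signature's contributions are median-centered across samples before
    the distance computation; the tree is cut into (at most) k flat clusters.
    Returns (labels, dendrogram leaf order, linkage matrix). Deterministic
    given inputs; sample order only permutes labels.
    """
    missing = [s for s in signatures if s not in exposures.columns]
    if missing:
        raise FormatError(f"signatures not in exposure matrix: {missing}")
    data = exposures.loc[exposures.sum(axis=1) > 0, signatures]
    if k > len(data):
        raise FormatError(f"k={k} exceeds the {len(data)} clusterable samples")
    centered = data - data.median(axis=0)
    x = centered.to_numpy()
    if distance == "correlation":
        dist = _safe_correlation_distance(x)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        dist = pdist(x, metric="euclidean")
    else:
        raise FormatError(f"unknown distance {distance!r}")
    Z = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = [data.index[i] for i in hierarchy.leaves_list(Z)]
    return pd.Series(labels, index=data.index, name="cluster"), order, Z


def compute_tmb(
    catalog: MutationCatalog, genome_mb: float, high_cutoff: float = 10.0
) -> pd.DataFrame:
    """Tumor mutational burden: (SNV + MNV + InDel) per Mb, with a strict
    high-TMB flag at > high_cutoff. SVs are excluded."""
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    counts = (
        catalog.variants.groupby("sample_id").size().reindex(catalog.samples, fill_value=0)
    )
    tmb = counts / genome_mb
    return pd.DataFrame(
        {"n_mutations": counts, "tmb": tmb, "high_tmb": tmb > high_cutoff}
    )
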