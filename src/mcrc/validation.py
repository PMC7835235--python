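"""Property-suite experiments over the synthetic cohorts.

Each function runs a self-contained simulation experiment (planted-truth
recovery, null calibration, or oracle agreement) and returns summary numbers.
They back both the acceptance test suite and scripts/acceptance.py; problem
sizes are chosen so each suite runs in minutes on one CPU.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import kataegis as kat
from . import msi as msi_mod
from . import noncoding as nc
from . import response as resp
from . import signatures as sig
from . import synthetic as syn
from .io import MutationCatalog
from .synthetic import child_seed


# ---------------------------------------------------------------------------
# signature refitting
# ---------------------------------------------------------------------------

def nnls_recovery_min_cosine(
    seed: int = 0, n_mixtures: int = 20, n_signatures: int = 5,
    n_mutations: int = 10_000,
) -> float:
    """Minimum cosine between planted and refit relative contributions on
    noise-free mixtures of reference signatures."""
    ref = syn.synthetic_signature_reference(n_signatures, seed=child_seed(seed, "ref"))
    rng = np.random.default_rng(child_seed(seed, "mix"))
    R = ref.values.to_numpy()
    rows, truths = [], []
    for i in range(n_mixtures):
        k = int(rng.integers(1, n_signatures + 1))
        active = rng.choice(n_signatures, size=k, replace=False)
        e = np.zeros(n_signatures)
        e[active] = rng.dirichlet(np.ones(k))
        counts = np.round(R @ e * n_mutations).astype(int)
        rows.append(counts)
        truths.append(e)
    counts_df = pd.DataFrame(
        rows, index=[f"M{i}" for i in range(n_mixtures)], columns=ref.channels
    )
    result = sig.refit_exposures(sig.ContextCounts(counts_df), ref)
    cosines = []
    for i, e in enumerate(truths):
        est = result.relative.iloc[i].to_numpy()
        cosines.append(
            float(est @ e / (np.linalg.norm(est) * np.linalg.norm(e)))
        )
    return min(cosines)


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

def _injection_genome(seed: int) -> syn.GenomeModel:
    return syn.build_genome(
        n_chrom=1, chrom_length=50_000_000, n_coding=2, n_noncoding=2,
        n_nonannotated=20, seed=seed,
    )


def kataegis_injection_sensitivity(
    seed: int = 0, n_seeds: int = 100, n_snvs: int = 6, imd_bp: float = 500.0,
    background_per_mb: float = 1.0,
) -> float:
    """Fraction of injected foci recovered at a 1 SNV/Mb background."""
    genome = _injection_genome(child_seed(seed, "genome"))
    ref = syn.synthetic_signature_reference(3, seed=child_seed(seed, "ref"))
    hits = 0
    for i in range(n_seeds):
        expo = syn.random_exposures(["S0"], ref.signatures, seed=child_seed(seed, f"e{i}"))
        truth = syn.SimulationTruth(exposures=expo)
        catalog = syn.simulate_catalog(
            genome, truth, ref, mean_tmb=background_per_mb / 0.9,
            seed=child_seed(seed, f"c{i}"), sv_rate=0,
        )
        catalog, focus = syn.inject_kataegis(
            catalog, genome, "S0", "chr1", n_snvs, imd_bp,
            seed=child_seed(seed, f"k{i}"),
        )
        table, _ = kat.detect_kataegis(catalog)
        hits += int(
            any(
                row.start <= focus["end"] and row.end >= focus["start"]
                for row in table.itertuples()
            )
        )
    return hits / n_seeds


def kataegis_null_fpr(
    seed: int = 0, n_seeds: int = 100, n_snvs: int = 1000,
    chrom_length: int = 100_000_000,
) -> float:
    """Fraction of null seeds (uniform SNVs) with any kataegis call."""
    false_pos = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(child_seed(seed, f"null{i}"))
        pos = np.sort(rng.integers(1, chrom_length, n_snvs))
        variants = pd.DataFrame(
            {
                "sample_id": "S0",
                "chrom": "chr1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "vclass": "SNV",
                "context": "ACA",
            }
        )
        table, _ = kat.detect_kataegis(MutationCatalog(variants=variants, samples=["S0"]))
        false_pos += int(len(table) > 0)
    return false_pos / n_seeds


def _brute_force_segment(y: np.ndarray, gamma: float) -> float:
    """Optimal segmentation objective by exhaustive enumeration (n <= 12)."""
    n = len(y)
    best = np.inf
    for mask in range(2 ** (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        obj = gamma * (len(bounds) - 1)
        for a, b in zip(bounds, bounds[1:]):
            seg = y[a:b]
            obj += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, obj)
    return best


def pcf_oracle_agreement(seed: int = 0, n_series: int = 40) -> float:
    """Fraction of short random series where the DP objective equals the
    exhaustive-enumeration optimum."""
    rng = np.random.default_rng(child_seed(seed, "pcf"))
    agree = 0
    for _ in range(n_series):
        n = int(rng.integers(2, 13))
        y = rng.normal(size=n)
        gamma = float(rng.uniform(0.05, 3.0))
        spans = kat.segment_piecewise_constant(y, gamma)
        obj = gamma * len(spans) + sum(
            float(((y[a:b] - y[a:b].mean()) ** 2).sum()) for a, b in spans
        )
        agree += int(abs(obj - _brute_force_segment(y, gamma)) < 1e-9)
    return agree / n_series


# ---------------------------------------------------------------------------
# noncoding scan
# ---------------------------------------------------------------------------

def _cohort(genome, ref, n_samples: int, mean_tmb: float, seed: int):
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expo = syn.random_exposures(samples, ref.signatures, seed=child_seed(seed, "e"))
    truth = syn.SimulationTruth(exposures=expo)
    return syn.simulate_catalog(
        genome, truth, ref, mean_tmb=mean_tmb, seed=child_seed(seed, "c"), sv_rate=0
    )


def noncoding_planted_detection(
    seed: int = 0, n_seeds: int = 100, n_samples: int = 200,
    mean_tmb: float = 7.0, multiplier: float = 10.0,
) -> float:
    """Fraction of seeds where a planted 10x noncoding driver reaches
    adjusted p < 0.05."""
    genome = syn.build_genome(seed=child_seed(seed, "genome"))
    ref = syn.synthetic_signature_reference(3, seed=child_seed(seed, "ref"))
    detected = 0
    for i in range(n_seeds):
        catalog = _cohort(genome, ref, n_samples, mean_tmb, child_seed(seed, f"s{i}"))
        catalog, _ = syn.plant_noncoding_driver(
            catalog, genome, "nc000", multiplier, 0.10, seed=child_seed(seed, f"p{i}")
        )
        results, _ = nc.scan_noncoding(catalog, genome)
        row = results[results.gene_id == "nc000"]
        detected += int(len(row) > 0 and float(row.p_adjusted.iloc[0]) < 0.05)
    return detected / n_seeds


def noncoding_null_typeI(
    seed: int = 0, n_cohorts: int = 200, n_samples: int = 200,
    mean_tmb: float = 7.0, alpha: float = 0.05,
) -> tuple[float, float, int]:
    """Fraction of tested genes with p_raw < alpha under the no-driver null.

    Returns (mean per-cohort fraction, its Monte-Carlo standard error across
    cohorts, total genes tested). The published procedure is anticonservative
    here because the gene's own rate estimate is the shared test center.
    """
    genome = syn.build_genome(seed=child_seed(seed, "genome"))
    ref = syn.synthetic_signature_reference(3, seed=child_seed(seed, "ref"))
    fractions = []
    n_tested = 0
    for i in range(n_cohorts):
        catalog = _cohort(genome, ref, n_samples, mean_tmb, child_seed(seed, f"n{i}"))
        results, _ = nc.scan_noncoding(catalog, genome)
        if len(results):
            fractions.append(float((results.p_raw < alpha).mean()))
            n_tested += len(results)
    fr = np.array(fractions)
    se = fr.std(ddof=1) / math.sqrt(len(fr)) if len(fr) > 1 else np.nan
    return float(fr.mean()), float(se), n_tested


# ---------------------------------------------------------------------------
# MSI enrichment
# ---------------------------------------------------------------------------

def sign_test_max_abs_error(max_n: int = 30) -> float:
    """Max |implementation - exact closed form| of the sign-test p over all
    (n_eff <= max_n, k) pairs, with the closed form computed in exact
    rational arithmetic."""
    worst = 0.0
    for n in range(1, max_n + 1):
        denom = Fraction(2) ** n
        for k in range(0, n + 1):
            exact = sum(Fraction(math.comb(n, j)) for j in range(k, n + 1)) / denom
            worst = max(worst, abs(msi_mod.sign_test_p(k, n) - float(exact)))
    return worst


def permutation_vs_hypergeometric(
    seed: int = 0, n_samples: int = 120, cluster_size: int = 20,
    m_mutated: int = 15, n_perm: int = 10_000,
) -> tuple[float, float]:
    """With equal TMB weights the permutation p must match the hypergeometric
    tail. Returns (max abs deviation over observed overlaps, max 3 MC SE)."""
    rng = np.random.default_rng(child_seed(seed, "perm"))
    cluster = pd.Series(
        np.arange(n_samples) < cluster_size, index=[f"S{i}" for i in range(n_samples)]
    )
    tmb = pd.Series(5.0, index=cluster.index)
    worst, worst_se = 0.0, 0.0
    for a_obs in (2, 4, 6):
        mutated = np.zeros(n_samples, dtype=bool)
        mutated[:a_obs] = True  # a_obs inside the cluster
        mutated[cluster_size : cluster_size + (m_mutated - a_obs)] = True
        flags = pd.DataFrame({"gene": mutated}, index=cluster.index)
        res = msi_mod.high_tmb_gene_test(
            flags, cluster, tmb, n_perm=n_perm, seed=child_seed(seed, f"g{a_obs}")
        )
        p_perm = float(res.loc["gene", "p_perm"])
        p_hyper = float(
            sps.hypergeom.sf(a_obs - 1, n_samples, cluster_size, m_mutated)
        )
        se = math.sqrt(p_hyper * (1 - p_hyper) / n_perm)
        worst = max(worst, abs(p_perm - p_hyper))
        worst_se = max(worst_se, 3 * se)
    return worst, worst_se


# ---------------------------------------------------------------------------
# proportional odds
# ---------------------------------------------------------------------------

def po_recovery_rate(
    seed: int = 0, n_seeds: int = 100, n: int = 2000, beta: float = 1.0,
    thresholds: tuple[float, float] = (-1.0, 1.0), tol: float = 0.15,
) -> float:
    """Fraction of seeds with |beta_hat - beta| < tol for a single standard
    normal feature at sample size n."""
    from scipy.special import expit

    ok = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(child_seed(seed, f"po{i}"))
        x = rng.normal(size=n)
        eta = beta * x
        u = rng.random(n)
        y = np.where(
            u < expit(thresholds[0] - eta), 0,
            np.where(u < expit(thresholds[1] - eta), 1, 2),
        )
        fit = resp.OrdinalResponseModel(y, pd.DataFrame({"x": x})).fit()
        ok += int(abs(float(fit.beta["x"]) - beta) < tol)
    return ok / n_seeds


def lasso_unpenalized_max_diff(seed: int = 0, n: int = 400, p: int = 5) -> float:
    """Max |coefficient difference| between the lam=0 proximal-gradient fit
    and the Newton maximum-likelihood fit."""
    from scipy.special import expit

    rng = np.random.default_rng(child_seed(seed, "lasso"))
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.0, 0.3, 0.0])
    eta = X @ beta
    u = rng.random(n)
    y = np.where(u < expit(-0.8 - eta), 0, np.where(u < expit(1.0 - eta), 1, 2))
    frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    model = resp.OrdinalResponseModel(y, frame)
    newton = model.fit()
    pen = model.fit_regularized(lam=0.0, tol=1e-13, maxiter=300_000)
    return float(
        max(
            np.max(np.abs(pen.beta - newton.beta.to_numpy())),
            np.max(np.abs(pen.theta - newton.theta)),
        )
    )


def enumerate_jonckheere_pvalue(groups: list[np.ndarray]) -> float:
    """Exhaustive two-sided Jonckheere-Terpstra p for small groups (oracle)."""
    from mcrc.stats import jonckheere_statistic

    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    obs = jonckheere_statistic(groups)
    mean = sum(
        sizes[i] * sizes[j]
        for i in range(len(sizes))
        for j in range(i + 1, len(sizes))
    ) / 2
    n = len(pooled)
    idx = list(range(n))
    hits = total = 0
    for comb1 in itertools.combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in comb1]
        for comb2 in itertools.combinations(rest1, sizes[1]):
            comb3 = [i for i in rest1 if i not in comb2]
            gs = [pooled[list(comb1)], pooled[list(comb2)], pooled[comb3]]
            t = jonckheere_statistic(gs)
            total += 1
            hits += int(abs(t - mean) >= abs(obs - mean) - 1e-12)
    return hits / total
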