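"""Cohort contingency and group-comparison statistics.

Two-sided Fisher exact tests (point-probability rule), Hochberg step-up
multiple-testing adjustment, Mann-Whitney / Kruskal-Wallis group comparisons
with Dunn post hoc, trend tests (Cochran-Armitage for binary outcomes,
permutation Jonckheere-Terpstra for continuous ones), and SV-derived
per-sample deletion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_two_sided: float
    zero_margin: bool = False


def fisher_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test of the 2x2 table [[a, b], [c, d]].

    Two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose point probability does not exceed the observed
    one (standard exact definition). A zero margin yields p = 1, flagged.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    table = ((int(a), int(b)), (int(c), int(d)))
    if min(a + b, c + d, a + c, b + d) == 0:
        odds = np.nan
        return ContingencyResult(table, odds, 1.0, zero_margin=True)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(table, float(odds), float(p))


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p values.

    For sorted p(1) <= ... <= p(m): adjusted(i) = min over j >= i of
    (m - j + 1) * p(j), capped at 1, returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-d array of p values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p values (used for Dunn post hoc)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def mann_whitney(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null for combined n <= exact_max_n
    without ties, otherwise normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if has_ties and len(np.unique(pooled)) == 1:
        return float("nan"), 1.0  # identical values everywhere
    method = "exact" if (len(pooled) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks after Kruskal-Wallis, with
    Benjamini-Hochberg adjustment across pairs (tie-corrected variance)."""
    k = len(groups)
    labels = labels or [f"g{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(k)]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(
                (n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * sps.norm.sf(abs(z))
            rows.append((labels[i], labels[j], z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    df["p_adjusted"] = benjamini_hochberg(df.p_raw.to_numpy())
    return df


def compare_groups(
    groups: list, labels: list[str] | None = None
) -> dict:
    """Mann-Whitney U for two groups, Kruskal-Wallis + Dunn for more."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if len(arrays) == 2:
        stat, p = mann_whitney(arrays[0], arrays[1])
        return {"method": "MWU", "statistic": stat, "p": p}
    pooled = np.concatenate(arrays)
    if len(np.unique(pooled)) == 1:
        return {"method": "KWH+Dunn", "statistic": 0.0, "p": 1.0,
                "dunn": dunn_posthoc(arrays, labels)}
    stat, p = sps.kruskal(*arrays)
    return {
        "method": "KWH+Dunn",
        "statistic": float(stat),
        "p": float(p),
        "dunn": dunn_posthoc(arrays, labels),
    }


def cochran_armitage(categories, outcome) -> tuple[float, float]:
    """Cochran-Armitage trend test (equally spaced scores, two-sided)."""
    cats = np.asarray(categories)
    y = np.asarray(outcome, dtype=float)
    levels = np.unique(cats)
    if len(levels) < 2:
        raise ValueError("need >= 2 ordered categories")
    scores = {lev: i for i, lev in enumerate(levels)}
    s = np.array([scores[c] for c in cats], dtype=float)
    n = len(y)
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    t = float(np.sum(s * (y - pbar)))
    var = pbar * (1 - pbar) * (np.sum(s**2) - np.sum(s) ** 2 / n)
    if var <= 0:
        return 0.0, 1.0
    z = t / np.sqrt(var)
    return float(z), float(2 * sps.norm.sf(abs(z)))


def jonckheere_statistic(groups: list[np.ndarray]) -> float:
    """Jonckheere-Terpstra statistic: sum over ordered group pairs of
    Mann-Whitney counts (ties weigh 1/2)."""
    total = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = groups[i][:, None]
            b = groups[j][None, :]
            total += (a < b).sum() + 0.5 * (a == b).sum()
    return float(total)


def jonckheere_terpstra(
    categories, outcome, n_perm: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Two-sided permutation Jonckheere-Terpstra trend test for a continuous
    outcome across ordered categories."""
    cats = np.asarray(categories)
    y = np.asarray(outcome, dtype=float)
    levels = np.unique(cats)
    if len(levels) < 2:
        raise ValueError("need >= 2 ordered categories")
    sizes = [int((cats == lev).sum()) for lev in levels]
    groups = [y[cats == lev] for lev in levels]
    obs = jonckheere_statistic(groups)
    # permutation null, centered at the exact mean sum(ni*nj)/2
    mean = sum(
        sizes[i] * sizes[j] for i in range(len(sizes)) for j in range(i + 1, len(sizes))
    ) / 2
    rng = np.random.default_rng(seed)
    idx = np.cumsum([0] + sizes)
    hits = 0
    yy = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yy)
        perm_groups = [yy[idx[i] : idx[i + 1]] for i in range(len(sizes))]
        t = jonckheere_statistic(perm_groups)
        if abs(t - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return obs, (1 + hits) / (n_perm + 1)


def trend_test(
    categories, outcome, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Trend across ordered categories: Cochran-Armitage when the outcome is
    binary, permutation Jonckheere-Terpstra when continuous."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)).issubset({0.0, 1.0}):
        stat, p = cochran_armitage(categories, y)
        return {"method": "cochran-armitage", "statistic": stat, "p": p}
    stat, p = jonckheere_terpstra(categories, y, n_perm=n_perm, seed=seed)
    return {"method": "jonckheere-terpstra", "statistic": stat, "p": p}


def count_size_deletions(
    svs: pd.DataFrame,
    min_bp: int = 10_000,
    max_bp: int = 1_000_000,
    cfs_regions: pd.DataFrame | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample count of DEL records with min_bp <= size <= max_bp (inclusive).

    With a table of common-fragile-site intervals (chrom/start/end, 0-based
    half-open) also counts the subset intersecting any such interval.
    """
    dels = svs[
        (svs.svtype == "DEL") & (svs["size"] >= min_bp) & (svs["size"] <= max_bp)
    ]
    if samples is None:
        samples = sorted(set(svs.sample_id))
    counts = dels.groupby("sample_id").size().reindex(samples, fill_value=0)
    out = pd.DataFrame({"n_del_10kb_1mb": counts})
    if cfs_regions is not None:
        def in_cfs(row) -> bool:
            cand = cfs_regions[cfs_regions.chrom == row.chrom]
            # SV span 1-based inclusive -> 0-based half-open [start-1, end)
            return bool(
                ((cand.start < row.end) & (cand.end > row.start - 1)).any()
            )

        flags = dels.apply(in_cfs, axis=1) if len(dels) else pd.Series(dtype=bool)
        cfs_counts = (
            dels[flags].groupby("sample_id").size().reindex(samples, fill_value=0)
            if len(dels)
            else pd.Series(0, index=samples)
        )
        out["n_del_cfs"] = cfs_counts
    return out
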