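"""Noncoding driver scan against gene-local background mutation rates.

Per noncoding gene, the cohort-wide mutation rate (total SNV+MNV+indel events
divided by region size) is compared to the rates of nonannotated regions
(> 1 kb) within a 2 Mb window around the gene, using a one-sided one-sample
Wilcoxon signed-rank test of the baseline rates against the gene's rate as
hypothesized center (alternative: baselines below the gene). Only recurrent
genes (mutated in at least 5% of the cohort) are tested; p values are Hochberg
step-up adjusted across tested genes.

Caveat: the gene's rate is itself an estimate shared by every baseline
difference, which makes the test anticonservative when per-gene counts are
small; see the methods documentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .io import MutationCatalog, RegionSet
from .stats import hochberg_adjust
from .synthetic import GenomeModel


def region_mutation_rates(
    catalog: MutationCatalog, regions: RegionSet, n_samples: int | None = None
) -> pd.DataFrame:
    """Cohort-wide mutation count, rate (events/bp) and mutated-sample count per region.

    A mutation belongs to a region iff its (1-based) position converted to
    0-based falls in the half-open [start, end). SVs are ignored.
    """
    if n_samples is None:
        n_samples = len(catalog.samples)
    v = catalog.variants
    out = []
    for chrom, grp in regions.df.groupby("chrom", sort=False):
        muts = v[v.chrom == chrom]
        pos0 = muts.pos.to_numpy() - 1  # 0-based
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        samp = muts.sample_id.to_numpy()[order]
        lo = np.searchsorted(pos0, grp.start.to_numpy(), side="left")
        hi = np.searchsorted(pos0, grp.end.to_numpy(), side="left")
        for (row, a, b) in zip(grp.itertuples(), lo, hi):
            n_mut = int(b - a)
            n_mut_samples = int(len(np.unique(samp[a:b])))
            out.append(
                {
                    "region_id": row.region_id,
                    "region_class": row.region_class,
                    "chrom": row.chrom,
                    "size": int(row.end - row.start),
                    "n_mutations": n_mut,
                    "rate": n_mut / (row.end - row.start),
                    "n_mutated_samples": n_mut_samples,
                    "frac_mutated_samples": n_mut_samples / n_samples
                    if n_samples
                    else np.nan,
                }
            )
    df = pd.DataFrame(
        out,
        columns=[
            "region_id",
            "region_class",
            "chrom",
            "size",
            "n_mutations",
            "rate",
            "n_mutated_samples",
            "frac_mutated_samples",
        ],
    )
    return df.set_index("region_id")


def local_baseline(
    genome: GenomeModel,
    gene: pd.Series,
    window_bp: int = 2_000_000,
    min_region_bp: int = 1_000,
) -> pd.DataFrame:
    """Nonannotated regions (> min_region_bp, strict) intersecting the window
    [gene.start - window/2, gene.end + window/2) on the gene's chromosome.

    The window is truncated at the chromosome start but regions are not
    clipped to it (intersection suffices).
    """
    half = window_bp // 2
    w_start = max(0, int(gene.start) - half)
    w_end = min(int(genome.chromosomes[gene.chrom]), int(gene.end) + half)
    bg = genome.regions.subset("nonannotated")
    hit = bg[
        (bg.chrom == gene.chrom)
        & (bg["size"] > min_region_bp)
        & (bg.start < w_end)
        & (bg.end > w_start)
    ]
    return hit.reset_index(drop=True)


def baseline_vs_gene_test(baseline_rates: np.ndarray, gene_rate: float) -> float:
    """One-sided signed-rank p for 'baselines sit below the gene's rate'.

    Differences equal to zero are dropped; exact null for <= 25 untied
    differences, otherwise normal approximation with continuity correction.
    """
    d = np.asarray(baseline_rates, dtype=float) - gene_rate
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    untied = len(np.unique(np.abs(d))) == len(d)
    method = "exact" if (len(d) <= 25 and untied) else "approx"
    res = wilcoxon(d, alternative="less", method=method, correction=True)
    return float(res.pvalue)


def scan_noncoding(
    catalog: MutationCatalog,
    genome: GenomeModel,
    recurrence_min: float = 0.05,
    window_bp: int = 2_000_000,
    min_region_bp: int = 1_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan all noncoding genes for locally enriched mutation rates.

    Returns (results table for tested genes with Hochberg-adjusted p values,
    report of genes excluded by the recurrence filter or for lacking baseline
    regions).
    """
    n_samples = len(catalog.samples)
    rates = region_mutation_rates(catalog, genome.regions, n_samples)
    nc = genome.regions.subset("noncoding")
    tested, excluded = [], []
    for gene in nc.itertuples():
        rec = rates.loc[gene.region_id]
        if rec.frac_mutated_samples < recurrence_min:
            excluded.append((gene.region_id, "below recurrence threshold"))
            continue
        bl = local_baseline(genome, pd.Series(gene._asdict()), window_bp, min_region_bp)
        if not len(bl):
            excluded.append((gene.region_id, "insufficient baseline"))
            continue
        bl_rates = rates.loc[bl.region_id, "rate"].to_numpy()
        p = baseline_vs_gene_test(bl_rates, rec.rate)
        tested.append(
            {
                "gene_id": gene.region_id,
                "chrom": gene.chrom,
                "size": int(gene.end - gene.start),
                "gene_rate": rec.rate,
                "n_mutations": int(rec.n_mutations),
                "n_mutated_samples": int(rec.n_mutated_samples),
                "pct_mutated_samples": 100 * rec.frac_mutated_samples,
                "n_baseline_regions": len(bl),
                "median_baseline_rate": float(np.median(bl_rates)),
                "p_raw": p,
            }
        )
    results = pd.DataFrame(
        tested,
        columns=[
            "gene_id",
            "chrom",
            "size",
            "gene_rate",
            "n_mutations",
            "n_mutated_samples",
            "pct_mutated_samples",
            "n_baseline_regions",
            "median_baseline_rate",
            "p_raw",
        ],
    )
    if len(results):
        results["p_adjusted"] = hochberg_adjust(results.p_raw.to_numpy())
    else:
        results["p_adjusted"] = pd.Series(dtype=float)
    report = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return results.sort_values("p_adjusted").reset_index(drop=True), report
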