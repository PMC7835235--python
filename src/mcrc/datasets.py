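"""Published cohort-comparison contingency inputs.

Printed mutation-frequency tables comparing a 429-patient metastatic CRC WGS
cohort against primary CRC (TCGA-DFCI, n=1949 targeted/exome; ICGC, n=866 for
noncoding genes) and against an independent metastatic cohort profiled by
targeted sequencing (Yaeger et al., n=321). These counts are inputs for the
cohort contingency statistics (two-sided Fisher exact tests with Hochberg
step-up correction); the package recomputes the tests from the counts.
"""

from __future__ import annotations

import pandas as pd

N_MCRC = 429
N_TCGA = 1949
N_ICGC = 866
N_YAEGER = 321

# driver genes: mutated-sample counts in mCRC (of 429) and primary CRC
# (TCGA-DFCI, of 1949) with the published two-sided Fisher p values
_DRIVER_ROWS = [
    # gene, n_mcrc, n_primary, printed_fisher_p
    ("TP53", 317, 1123, 2.04e-10),
    ("ZFP36L2", 42, 97, 3.61e-04),
    ("KRAS", 203, 744, 5.88e-04),
    ("APC", 336, 1372, 8.86e-04),
    ("PIK3CA", 68, 445, 0.001),
    ("B2M", 8, 91, 0.007),
    ("SMAD4", 74, 243, 0.010),
    ("ATM", 33, 227, 0.017),
    ("FBXW7", 51, 301, 0.061),
    ("AMER1", 37, 209, 0.220),
    ("ARID1A", 39, 201, 0.480),
    ("BCL9", 28, 107, 0.419),
    ("BCL9L", 27, 133, 0.750),
    ("BRAF", 56, 273, 0.644),
    ("ELF3", 7, 51, 0.299),
    ("LMTK3", 15, 56, 0.530),
    ("NRAS", 26, 125, 0.913),
    ("PTEN", 17, 123, 0.069),
    ("RNF43", 28, 162, 0.239),
    ("SMAD3", 11, 72, 0.309),
    ("SOX9", 41, 177, 0.782),
    ("TCF7L2", 50, 177, 0.103),
    ("TGIF1", 18, 62, 0.300),
]

# noncoding genes with ICGC primary-CRC comparison (one gene of the published
# fifteen lacks ICGC annotation and is absent here)
_NONCODING_ROWS = [
    ("AL731533.2", 6, 0, 1.29e-03),
    ("AL513548.1", 14, 3, 3.84e-05),
    ("AL365361.1", 17, 0, 5.62e-09),
    ("AC018521.5", 16, 1, 2.06e-07),
    ("DBIL5P2", 18, 1, 2.39e-08),
    ("LINC02035", 23, 0, 6.15e-12),
    ("LINC01180", 13, 1, 5.00e-06),
    ("AC005618.1", 18, 1, 2.39e-08),
    ("MALAT1", 30, 19, 4.19e-05),
    ("AC007066.2", 11, 2, 1.86e-04),
    ("LINC00672", 14, 2, 9.70e-06),
    ("PIPSL", 14, 34, 0.640),
    ("PTENP1", 15, 22, 0.376),
    ("AC093627.4", 18, 2, 1.66e-07),
]

# genes shared with the Yaeger targeted panel (mutated counts of 321)
_YAEGER_ROWS = [
    ("TP53", 317, 246, 0.395),
    ("KRAS", 203, 127, 0.037),
    ("APC", 336, 241, 0.335),
    ("PIK3CA", 68, 49, 0.840),
    ("FBXW7", 51, 25, 0.068),
    ("AMER1", 37, 11, 0.004),
    ("BRAF", 56, 38, 0.657),
]


def driver_gene_table() -> pd.DataFrame:
    """mCRC vs primary CRC (TCGA-DFCI) driver-gene mutation counts."""
    df = pd.DataFrame(
        _DRIVER_ROWS, columns=["gene", "n_mcrc", "n_primary", "printed_p"]
    )
    df["n_total_mcrc"] = N_MCRC
    df["n_total_primary"] = N_TCGA
    return df.set_index("gene")


def noncoding_gene_table() -> pd.DataFrame:
    """mCRC vs primary CRC (ICGC) noncoding-gene mutation counts."""
    df = pd.DataFrame(
        _NONCODING_ROWS, columns=["gene", "n_mcrc", "n_primary", "printed_p"]
    )
    df["n_total_mcrc"] = N_MCRC
    df["n_total_primary"] = N_ICGC
    return df.set_index("gene")


def yaeger_table() -> pd.DataFrame:
    """mCRC WGS cohort vs Yaeger targeted-sequencing cohort counts."""
    df = pd.DataFrame(
        _YAEGER_ROWS, columns=["gene", "n_mcrc", "n_yaeger", "printed_p"]
    )
    df["n_total_mcrc"] = N_MCRC
    df["n_total_yaeger"] = N_YAEGER
    return df.set_index("gene")


def cohort_comparison(table: pd.DataFrame, other_count_col: str,
                      other_total_col: str) -> pd.DataFrame:
    """Recompute two-sided Fisher p and Hochberg-adjusted p from the counts."""
    from .stats import fisher_2x2, hochberg_adjust

    ps = []
    for gene, row in table.iterrows():
        res = fisher_2x2(
            int(row.n_mcrc),
            int(row.n_total_mcrc - row.n_mcrc),
            int(row[other_count_col]),
            int(row[other_total_col] - row[other_count_col]),
        )
        ps.append(res.p_two_sided)
    out = table.copy()
    out["fisher_p"] = ps
    out["fisher_p_adjusted"] = hochberg_adjust(out["fisher_p"].to_numpy())
    out["printed_p_adjusted"] = hochberg_adjust(out["printed_p"].to_numpy())
    return out
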