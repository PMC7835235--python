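"""Mononucleotide-stretch counting, sign tests, and the TMB-corrected
permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mcrc import msi


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAAAA", 1),          # length 6: boundary, counted
        ("AAAAA", 0),           # length 5: below
        ("A" * 13, 1),          # length 13: boundary, counted
        ("A" * 14, 0),          # length 14: left to the repeat annotation
        ("AAAAAACCCCCCCGTTTTTT", 3),  # A6, C7, T6 (manual run-length scan)
        ("AAAAAANAAAAAA", 2),   # N breaks runs
        ("", 0),
    ],
)
def test_mono_stretch_counting(seq, expected):
    assert msi.count_mono_stretches(seq) == expected


def test_stretch_counting_case_insensitive():
    assert msi.count_mono_stretches("aaaaaa") == msi.count_mono_stretches("AAAAAA")


def test_stretches_do_not_span_exon_junctions():
    exons = ["AAAA", "AATT"]  # concatenation would create an A6 run
    assert msi.count_mono_stretches(exons) == 0
    assert msi.count_mono_stretches("".join(exons)) == 1
    assert msi.count_mono_stretches(exons[::-1]) == msi.count_mono_stretches(exons)


def test_msi_prone_profile_totals():
    profiles = msi.count_msi_prone(
        {"g1": "AAAAAACC", "g2": "ACGT"}, {"g1": 3, "g3": 2}
    )
    assert profiles.loc["g1", "msi_prone_total"] == 4
    assert profiles.loc["g2", "msi_prone_total"] == 0
    assert profiles.loc["g3", "sequence_missing"]


def test_sign_test_closed_form_for_all_small_n():
    from mcrc.validation import sign_test_max_abs_error

    assert sign_test_max_abs_error(max_n=30) == 0.0


def _profiles(totals):
    return pd.DataFrame(
        {"msi_prone_total": totals,
         "n_repeats": 0, "n_mono_stretches": totals, "sequence_missing": False},
        index=[f"g{i}" for i in range(len(totals))],
    )


def _flags(matrix, genes, samples):
    return pd.DataFrame(matrix, index=samples, columns=genes, dtype=bool)


def test_matched_control_sign_test_all_below():
    samples = [f"M{i}" for i in range(4)]
    genes = [f"g{i}" for i in range(17)]
    matrix = np.zeros((4, 17), dtype=bool)
    matrix[:, 0] = True  # target gene mutated in every MSI sample
    res = msi.matched_control_test(
        "g0", _flags(matrix, genes, samples), samples, _profiles([10] * 17)
    )
    assert res.n_controls == 16 and res.n_below == 16
    assert res.p_sign == pytest.approx(0.5**16)


def test_matched_control_symmetric_controls_not_significant():
    samples = [f"M{i}" for i in range(4)]
    genes = [f"g{i}" for i in range(11)]
    matrix = np.zeros((4, 11), dtype=bool)
    matrix[:2, 0] = True            # observed freq 0.5
    matrix[:1, 1:6] = True          # five controls at 0.25 (below)
    matrix[:3, 6:11] = True         # five controls at 0.75 (above)
    res = msi.matched_control_test(
        "g0", _flags(matrix, genes, samples), samples, _profiles([10] * 11)
    )
    assert res.n_effective == 10 and res.n_below == 5
    assert res.p_sign > 0.35


def test_matched_control_tolerance_window_and_untestable_flag():
    samples = ["M0"]
    genes = ["g0", "g1", "g2", "g3"]
    matrix = np.zeros((1, 4), dtype=bool)
    profiles = _profiles([100, 110, 90, 150])  # +/-10% of 100 -> g1, g2 only
    res = msi.matched_control_test("g0", _flags(matrix, genes, samples), samples, profiles)
    assert res.n_controls == 2
    lonely = _profiles([100, 300, 400, 500])
    res = msi.matched_control_test("g0", _flags(matrix, genes, samples), samples, lonely)
    assert not res.testable and "control distribution" in res.note


def _cluster_setup(n=60, cluster=12):
    samples = [f"S{i}" for i in range(n)]
    flags = pd.Series(np.arange(n) < cluster, index=samples)
    tmb = pd.Series(5.0, index=samples)
    return samples, flags, tmb


def test_unmutated_gene_has_permutation_p_one():
    samples, cluster, tmb = _cluster_setup()
    flags = _flags(np.zeros((60, 1), dtype=bool), ["g"], samples)
    res = msi.high_tmb_gene_test(flags, cluster, tmb, n_perm=200, seed=0)
    assert res.loc["g", "p_perm"] == 1.0
    assert not res.loc["g", "reported"]


def test_permutation_p_has_add_one_floor():
    samples, cluster, tmb = _cluster_setup()
    matrix = np.zeros((60, 1), dtype=bool)
    matrix[:10, 0] = True  # all mutations inside the cluster
    res = msi.high_tmb_gene_test(_flags(matrix, ["g"], samples), cluster, tmb,
                                 n_perm=500, seed=0)
    assert res.loc["g", "p_perm"] >= 1 / 501


def test_equal_weights_permutation_matches_hypergeometric():
    from mcrc.validation import permutation_vs_hypergeometric

    deviation, three_se = permutation_vs_hypergeometric(seed=5, n_perm=4000)
    assert deviation <= three_se


def test_confounding_free_enrichment_detected():
    samples, cluster, tmb = _cluster_setup(n=100, cluster=10)
    matrix = np.zeros((100, 1), dtype=bool)
    matrix[:10, 0] = True  # mutated exactly in the cluster, TMB equal everywhere
    res = msi.high_tmb_gene_test(_flags(matrix, ["g"], samples), cluster, tmb,
                                 n_perm=2000, seed=1)
    assert res.loc["g", "p_perm"] < 0.01
    assert res.loc["g", "p_fisher"] < 1e-6


def test_tmb_weighting_corrects_burden_confounding():
    # mutations track TMB, not the cluster: Fisher alarms, permutation does not
    rng = np.random.default_rng(2)
    n = 200
    samples = [f"S{i}" for i in range(n)]
    tmb = pd.Series(np.where(np.arange(n) < 30, 60.0, 3.0), index=samples)
    cluster = pd.Series(np.arange(n) < 30, index=samples)  # = high-TMB samples
    p = (tmb / tmb.sum()).to_numpy()
    fisher_ps, perm_ps = [], []
    for g in range(20):
        mutated = rng.choice(n, size=12, replace=False, p=p)
        matrix = np.zeros((n, 1), dtype=bool)
        matrix[mutated, 0] = True
        res = msi.high_tmb_gene_test(_flags(matrix, ["g"], samples), cluster, tmb,
                                     n_perm=1000, seed=g)
        fisher_ps.append(res.loc["g", "p_fisher"])
        perm_ps.append(res.loc["g", "p_perm"])
    assert np.median(fisher_ps) < 0.01      # burden confounding fools Fisher
    assert np.mean(np.array(perm_ps) < 0.05) <= 0.2  # permutation absorbs it


def test_degenerate_cluster_groups_error():
    samples, _, tmb = _cluster_setup()
    bad = pd.Series([True] * 59 + [False], index=samples)
    flags = _flags(np.zeros((60, 1), dtype=bool), ["g"], samples)
    with pytest.raises(ValueError, match="each cluster group"):
        msi.high_tmb_gene_test(flags, bad, tmb, n_perm=100, seed=0)
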