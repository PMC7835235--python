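"""Channel counting, NNLS refitting, dominant selection, clustering, TMB."""

import numpy as np
import pandas as pd
import pytest

from mcrc import channels, signatures as sig
from mcrc.io import FormatError, SignatureMatrix

from conftest import make_catalog


def test_single_snv_counted_in_its_channel():
    catalog = make_catalog([("S0", "chr1", 100, "C", "A", "SNV", "ACA")])
    sbs, dbs, _ = sig.count_contexts(catalog)
    assert sbs.df.loc["S0", "A[C>A]A"] == 1
    assert sbs.df.loc["S0"].sum() == 1
    assert dbs.df.loc["S0"].sum() == 0


@pytest.mark.parametrize(
    "ref,alt,ctx,expected",
    [
        # all six purine-centered substitutions, hand reverse-complemented
        ("G", "T", "TGT", "A[C>A]A"),
        ("G", "C", "TGT", "A[C>G]A"),
        ("G", "A", "TGT", "A[C>T]A"),
        ("A", "T", "CAG", "C[T>A]G"),
        ("A", "G", "CAG", "C[T>C]G"),
        ("A", "C", "CAG", "C[T>G]G"),
    ],
)
def test_purine_centered_snvs_collapse_to_pyrimidine_strand(ref, alt, ctx, expected):
    catalog = make_catalog([("S0", "chr1", 50, ref, alt, "SNV", ctx)])
    sbs, _, _ = sig.count_contexts(catalog)
    assert sbs.df.loc["S0", expected] == 1


def test_purine_context_reverse_complements_flanks():
    # G>T with 5'T and 3'T: TGT -> revcomp ACA handled above; asymmetric check
    catalog = make_catalog([("S0", "chr1", 50, "G", "T", "SNV", "AGC")])
    sbs, _, _ = sig.count_contexts(catalog)
    assert sbs.df.loc["S0", "G[C>A]T"] == 1  # revcomp(AGC) = GCT


def test_empty_catalog_gives_zero_matrices():
    catalog = make_catalog([], samples=["S0", "S1"])
    sbs, dbs, residuals = sig.count_contexts(catalog)
    assert sbs.df.to_numpy().sum() == 0
    assert dbs.df.to_numpy().sum() == 0
    assert len(residuals) == 0


def test_doublet_counting_collapses_and_reports_residuals():
    catalog = make_catalog(
        [
            ("S0", "chr1", 10, "AT", "CA", "MNV"),
            ("S0", "chr1", 20, "CA", "TG", "MNV"),   # CA not canonical -> TG>CA
            ("S0", "chr1", 30, "ACG", "TGA", "MNV"),  # length 3: residual
            ("S0", "chr1", 40, "A", "AT", "INS"),     # indel ignored
        ]
    )
    _, dbs, residuals = sig.count_contexts(catalog)
    assert dbs.df.loc["S0", "AT>CA"] == 1
    assert dbs.df.loc["S0", "TG>CA"] == 1
    assert dbs.df.loc["S0"].sum() == 2
    assert list(residuals.reason) == ["MNV length > 2"]


def test_missing_context_raises_with_offenders():
    catalog = make_catalog([("S0", "chr1", 100, "C", "A", "SNV")])
    with pytest.raises(FormatError, match="S0:chr1:100"):
        sig.count_contexts(catalog)


def test_context_lookup_from_chromosome_sequence():
    seq = "AACAG"  # pos 3 (1-based) is C with context ACA
    catalog = make_catalog([("S0", "chr1", 3, "C", "T", "SNV")])
    sbs, _, _ = sig.count_contexts(catalog, context_source={"chr1": seq})
    assert sbs.df.loc["S0", "A[C>T]A"] == 1


def _orthogonal_reference():
    vals = np.zeros((96, 2))
    vals[:10, 0] = 0.1
    vals[10:30, 1] = 0.05
    df = pd.DataFrame(vals, index=list(channels.SBS96_LABELS), columns=["A", "B"])
    return SignatureMatrix(df)


def test_refit_recovers_pure_signature(reference3):
    R = reference3.values.to_numpy()
    counts = np.round(R[:, 0] * 100_000).astype(int)
    df = pd.DataFrame([counts], index=["S0"], columns=reference3.channels)
    result = sig.refit_exposures(sig.ContextCounts(df), reference3)
    assert result.relative.loc["S0", reference3.signatures[0]] > 0.999
    assert result.reconstruction_cosine["S0"] > 0.999


def test_refit_orthogonal_mixture_is_exact():
    ref = _orthogonal_reference()
    counts = 60 * ref.values["A"].to_numpy() + 40 * ref.values["B"].to_numpy()
    df = pd.DataFrame(
        [np.round(counts * 100).astype(int)], index=["S0"], columns=ref.channels
    )
    result = sig.refit_exposures(sig.ContextCounts(df), ref)
    assert abs(result.relative.loc["S0", "A"] - 0.60) < 1e-6
    assert abs(result.relative.loc["S0", "B"] - 0.40) < 1e-6


def test_refit_zero_sample_flagged_not_error(reference3):
    df = pd.DataFrame(
        np.zeros((1, 96), dtype=int), index=["S0"], columns=reference3.channels
    )
    result = sig.refit_exposures(sig.ContextCounts(df), reference3)
    assert result.zero_samples == ["S0"]
    assert (result.relative.loc["S0"] == 0).all()


def test_refit_residual_never_exceeds_count_norm(reference3):
    rng = np.random.default_rng(0)
    R = reference3.values.to_numpy()
    for _ in range(5):
        c = rng.poisson(rng.uniform(0, 50, 96))
        df = pd.DataFrame([c], index=["S0"], columns=reference3.channels)
        res = sig.refit_exposures(sig.ContextCounts(df), reference3)
        e = res.absolute.loc["S0"].to_numpy()
        assert np.linalg.norm(R @ e - c) <= np.linalg.norm(c) + 1e-9


def test_refit_rejects_channel_mismatch(reference3):
    df = pd.DataFrame(np.zeros((1, 78), dtype=int), index=["S0"],
                      columns=list(channels.DBS78_LABELS))
    with pytest.raises(FormatError, match="channel"):
        sig.refit_exposures(sig.ContextCounts(df), reference3)


def _exposures(rows, sigs=("A", "B")):
    return pd.DataFrame(rows, columns=list(sigs))


def test_dominant_selection_thresholds_are_inclusive():
    expo = _exposures([[0.10, 0.90]] * 10 + [[0.0, 1.0]] * 5)
    assert sig.select_dominant(expo) == ["A", "B"]
    expo = _exposures([[0.09, 0.91]] * 400)
    assert sig.select_dominant(expo) == ["B"]
    expo = _exposures([[0.10, 0.90]] * 9)
    assert sig.select_dominant(expo) == []
    assert sig.select_dominant(_exposures(np.zeros((5, 2)))) == []


def test_dominant_selection_is_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    expo = pd.DataFrame(rng.dirichlet(np.ones(4), size=40), columns=list("ABCD"))
    base = set(sig.select_dominant(expo, 0.10, 10))
    assert set(sig.select_dominant(expo, 0.15, 10)) <= base
    assert set(sig.select_dominant(expo, 0.10, 15)) <= base


def test_clustering_set_union_rules():
    expo = _exposures([[0.26, 0.74]] + [[0.0, 1.0]] * 9)
    assert sig.clustering_signature_set(expo, ["B"], []) == ["B", "A"]
    expo = _exposures([[0.25, 0.75]] * 10)  # strict > 0.25
    assert sig.clustering_signature_set(expo, ["B"], []) == ["B"]
    assert sig.clustering_signature_set(expo, ["B"], ["B"]) == ["B"]  # dedup
    with pytest.raises(FormatError, match="unknown"):
        sig.clustering_signature_set(expo, ["B"], ["Z"])


def _two_archetype_exposures(n_per=50, seed=0):
    rng = np.random.default_rng(seed)
    a = np.column_stack([rng.uniform(0.7, 0.9, n_per), rng.uniform(0.0, 0.1, n_per)])
    b = np.column_stack([rng.uniform(0.0, 0.1, n_per), rng.uniform(0.7, 0.9, n_per)])
    x = np.vstack([a, b])
    x = np.column_stack([x, 1 - x.sum(axis=1)])
    return pd.DataFrame(x, columns=["A", "B", "C"],
                        index=[f"S{i}" for i in range(2 * n_per)])


def test_clustering_recovers_planted_archetypes():
    from sklearn.metrics import adjusted_rand_score

    expo = _two_archetype_exposures()
    labels, order, _ = sig.cluster_samples(expo, ["A", "B", "C"], k=2)
    truth = [0] * 50 + [1] * 50
    assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
    assert set(order) == set(expo.index)


def test_clustering_median_centering_definition():
    expo = _two_archetype_exposures(seed=1)
    centered = expo - expo.median(axis=0)
    assert np.allclose(centered.median(axis=0), 0)


def test_clustering_invariant_to_sample_order():
    from sklearn.metrics import adjusted_rand_score

    expo = _two_archetype_exposures(seed=2)
    labels1, _, _ = sig.cluster_samples(expo, ["A", "B", "C"], k=2)
    perm = expo.sample(frac=1.0, random_state=4)
    labels2, _, _ = sig.cluster_samples(perm, ["A", "B", "C"], k=2)
    joined = pd.concat([labels1.rename("a"), labels2.rename("b")], axis=1)
    assert adjusted_rand_score(joined.a, joined.b) == 1.0


def test_clustering_identical_rows_degenerate_but_deterministic():
    expo = pd.DataFrame(
        np.tile([0.5, 0.3, 0.2], (6, 1)), columns=["A", "B", "C"],
        index=[f"S{i}" for i in range(6)],
    )
    labels1, _, _ = sig.cluster_samples(expo, ["A", "B", "C"], k=3)
    labels2, _, _ = sig.cluster_samples(expo, ["A", "B", "C"], k=3)
    assert (labels1 == labels2).all()
    with pytest.raises(FormatError, match="k="):
        sig.cluster_samples(expo, ["A", "B", "C"], k=7)


def _bulk_catalog(n_variants):
    variants = pd.DataFrame(
        {
            "sample_id": "S0",
            "chrom": "chr1",
            "pos": np.arange(1, n_variants + 1) * 3,
            "ref": "C",
            "alt": "T",
            "vclass": "SNV",
            "context": "ACA",
        }
    )
    return make_catalog([], samples=["S0"]).add_variants(variants)


def test_tmb_definition_and_strict_high_flag():
    empty = make_catalog([], samples=["S0"])
    tmb = sig.compute_tmb(empty, 2859.0)
    assert tmb.loc["S0", "tmb"] == 0 and not tmb.loc["S0", "high_tmb"]
    at_cut = sig.compute_tmb(_bulk_catalog(28_590), 2859.0)
    assert at_cut.loc["S0", "tmb"] == pytest.approx(10.0)
    assert not at_cut.loc["S0", "high_tmb"]  # strictly greater than 10
    above = sig.compute_tmb(_bulk_catalog(28_591), 2859.0)
    assert above.loc["S0", "high_tmb"]


def test_tmb_excludes_svs(small_catalog, small_genome):
    with_sv = sig.compute_tmb(small_catalog, small_genome.total_mb)
    no_sv_catalog = make_catalog([], samples=small_catalog.samples).add_variants(
        small_catalog.variants
    )
    without_sv = sig.compute_tmb(no_sv_catalog, small_genome.total_mb)
    pd.testing.assert_series_equal(with_sv["tmb"], without_sv["tmb"])
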