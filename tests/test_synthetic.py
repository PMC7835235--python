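"""Synthetic-cohort generator: determinism, planted truth, and invariants."""

import io as stdio

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mcrc import signatures as sig
from mcrc import synthetic as syn
from mcrc.io import write_variants_tsv
from mcrc.synthetic import SimulationError


def test_build_genome_deterministic_under_seed():
    a = syn.build_genome(n_chrom=1, chrom_length=10_000_000, n_coding=10,
                         n_noncoding=5, n_nonannotated=60, seed=7)
    b = syn.build_genome(n_chrom=1, chrom_length=10_000_000, n_coding=10,
                         n_noncoding=5, n_nonannotated=60, seed=7)
    pd.testing.assert_frame_equal(a.regions.df, b.regions.df)
    assert a.sequences == b.sequences


def test_build_genome_infeasible_packing_errors():
    with pytest.raises(SimulationError, match="packing"):
        syn.build_genome(n_chrom=1, chrom_length=1_000_000, n_coding=0,
                         n_noncoding=5, n_nonannotated=400, seed=0)
    with pytest.raises(SimulationError, match="nonannotated regions per"):
        syn.build_genome(n_noncoding=10, n_nonannotated=5, seed=0)


def test_genome_regions_nonoverlapping_pairwise_oracle(small_genome):
    df = small_genome.regions.df
    for chrom, grp in df.groupby("chrom"):
        rows = grp[["start", "end"]].to_numpy()
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i], rows[j]
                assert a[1] <= b[0] or b[1] <= a[0], (chrom, a, b)


def test_noncoding_genes_have_local_baselines(small_genome):
    from mcrc.noncoding import local_baseline

    for gene in small_genome.regions.subset("noncoding").itertuples():
        bl = local_baseline(small_genome, pd.Series(gene._asdict()))
        assert len(bl) >= 3
        assert (bl["size"] > 1000).all()


def test_simulated_channels_match_planted_signature(reference3):
    genome = syn.build_genome(n_chrom=1, chrom_length=30_000_000, n_coding=2,
                              n_noncoding=2, n_nonannotated=20, seed=3)
    expo = pd.DataFrame(
        [[1.0, 0.0, 0.0]], index=["S0"], columns=reference3.signatures
    )
    truth = syn.SimulationTruth(exposures=expo)
    catalog = syn.simulate_catalog(
        genome, truth, reference3, mean_tmb=50_000 / 0.9 / genome.total_mb, seed=4,
        sv_rate=0,
    )
    sbs, _, _ = sig.count_contexts(catalog)
    freq = sbs.df.loc["S0"].to_numpy(dtype=float)
    assert freq.sum() >= 10_000
    freq = freq / freq.sum()
    target = reference3.values.iloc[:, 0].to_numpy()
    cosine = freq @ target / (np.linalg.norm(freq) * np.linalg.norm(target))
    assert cosine >= 0.995


def test_zero_tmb_gives_empty_catalog(small_genome, reference3):
    expo = syn.random_exposures(["S0"], reference3.signatures, seed=0)
    truth = syn.SimulationTruth(exposures=expo)
    catalog = syn.simulate_catalog(small_genome, truth, reference3, mean_tmb=0.0,
                                   seed=0, sv_rate=0)
    assert len(catalog.variants) == 0


def test_catalog_byte_identical_under_fixed_seed(small_genome, reference3):
    expo = syn.random_exposures(["S0", "S1"], reference3.signatures, seed=5)
    truth = syn.SimulationTruth(exposures=expo)
    outputs = []
    for _ in range(2):
        catalog = syn.simulate_catalog(small_genome, truth, reference3,
                                       mean_tmb=3.0, seed=11)
        buf = stdio.StringIO()
        write_variants_tsv(catalog, buf)
        outputs.append(buf.getvalue())
    assert outputs[0] == outputs[1]


def test_exposure_signature_mismatch_errors(small_genome, reference3):
    expo = pd.DataFrame([[1.0]], index=["S0"], columns=["OTHER"])
    truth = syn.SimulationTruth(exposures=expo)
    with pytest.raises(SimulationError, match="signatures"):
        syn.simulate_catalog(small_genome, truth, reference3, seed=0)


def test_kataegis_injection_span_and_count(small_genome, small_catalog):
    before = small_catalog.n_variants("S0")
    catalog, focus = syn.inject_kataegis(
        small_catalog, small_genome, "S0", "chr1", 6, 500, seed=9
    )
    assert catalog.n_variants("S0") == before + 6
    span = focus["end"] - focus["start"]
    assert 5 * 500 * 0.8 <= span <= 5 * 500 * 1.2


def test_kataegis_injection_precondition():
    with pytest.raises(SimulationError, match="at least 2"):
        syn.inject_kataegis(None, None, "S0", "chr1", 1, 500)


def test_planted_driver_multiplier_one_adds_nothing(small_genome, small_catalog):
    catalog, entry = syn.plant_noncoding_driver(
        small_catalog, small_genome, "nc000", 1.0, 0.5, seed=0
    )
    assert entry["n_added"] == 0
    assert len(catalog.variants) == len(small_catalog.variants)


def test_planted_driver_matches_poisson_expectation(small_genome, small_catalog):
    from mcrc.io import RegionSet
    from mcrc.noncoding import local_baseline, region_mutation_rates

    gene = small_genome.regions.by_id("nc000")
    bl = local_baseline(small_genome, gene)
    rates = region_mutation_rates(small_catalog, RegionSet(bl), 8)
    pooled = rates.n_mutations.sum() / rates["size"].sum()
    expected = 9 * pooled * (gene.end - gene.start)
    added = []
    for s in range(30):
        _, entry = syn.plant_noncoding_driver(
            small_catalog, small_genome, "nc000", 10.0, 0.5, seed=s
        )
        added.append(entry["n_added"])
    mean_added = np.mean(added)
    # Poisson mean estimate from 30 draws: allow 4 standard errors
    se = np.sqrt(expected / 30)
    assert abs(mean_added - expected) < 4 * se + 1e-9


def test_planted_driver_unknown_gene_errors(small_genome, small_catalog):
    with pytest.raises(KeyError):
        syn.plant_noncoding_driver(small_catalog, small_genome, "nope", 2.0, 0.1)


def test_msi_injection_lands_inside_stretches(small_genome, small_catalog):
    from mcrc.msi import find_mono_stretches

    coding = small_genome.regions.subset("coding").set_index("region_id")
    targets = [g for g in sorted(small_genome.sequences)
               if find_mono_stretches(small_genome.sequences[g])][:3]
    catalog = syn.inject_msi(
        small_catalog, small_genome, ["S0", "S1"], 5000.0, seed=1,
        target_genes=targets,
    )
    new = catalog.variants.iloc[len(small_catalog.variants):]
    new = pd.concat([catalog.variants, small_catalog.variants]).drop_duplicates(keep=False)
    assert len(new) > 0
    for row in new.itertuples():
        gene = next(
            g for g in targets
            if coding.loc[g].chrom == row.chrom
            and coding.loc[g].start < row.pos <= coding.loc[g].end
        )
        off = row.pos - 1 - coding.loc[gene].start
        assert any(
            o <= off < o + length
            for o, length, _ in find_mono_stretches(small_genome.sequences[gene])
        )
        assert row.vclass in ("INS", "DEL")


def test_msi_injection_multiplier_one_is_neutral(small_genome, small_catalog):
    catalog = syn.inject_msi(small_catalog, small_genome, ["S0"], 1.0, seed=0)
    assert len(catalog.variants) == len(small_catalog.variants)


def test_msi_injection_requires_sequences(small_catalog, small_genome):
    bare = syn.GenomeModel(small_genome.chromosomes, small_genome.regions, None)
    with pytest.raises(SimulationError, match="sequences"):
        syn.inject_msi(small_catalog, bare, ["S0"], 10.0)


def test_response_null_frequencies_match_cutpoints():
    n = 10_000
    features = pd.DataFrame({"x": np.zeros(n)})
    y = syn.simulate_response(features, {"x": 0.0}, (-0.5, 1.5), seed=3)
    freq = y.value_counts(normalize=True)
    expected = {
        "PD": expit(-0.5),
        "SD": expit(1.5) - expit(-0.5),
        "PR": 1 - expit(1.5),
    }
    for level, p in expected.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq[level] - p) < 4 * se


def test_response_extreme_cutpoint_removes_pd():
    features = pd.DataFrame({"x": np.zeros(500)})
    y = syn.simulate_response(features, {"x": 0.0}, (-30.0, 1.0), seed=0)
    assert (y != "PD").all()


def test_response_deterministic_and_validates():
    features = pd.DataFrame({"x": [0.0, 1.0]})
    a = syn.simulate_response(features, {"x": 1.0}, (-1, 1), seed=5)
    b = syn.simulate_response(features, {"x": 1.0}, (-1, 1), seed=5)
    assert (a == b).all()
    with pytest.raises(SimulationError):
        syn.simulate_response(features, {"x": np.inf}, (-1, 1), seed=0)
    with pytest.raises(SimulationError):
        syn.simulate_response(features, {"x": 0.0}, (1, -1), seed=0)


def test_injections_preserve_region_disjointness(small_genome, small_catalog):
    catalog, _ = syn.inject_kataegis(
        small_catalog, small_genome, "S0", "chr1", 6, 400, seed=2
    )
    small_genome.validate()  # class disjointness unchanged by injections
    catalog.validate()
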