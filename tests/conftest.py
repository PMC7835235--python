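import numpy as np
import pandas as pd
import pytest

from mcrc import synthetic as syn
from mcrc.io import MutationCatalog


@pytest.fixture(scope="session")
def reference3():
    return syn.synthetic_signature_reference(3, seed=0)


@pytest.fixture(scope="session")
def small_genome():
    return syn.build_genome(
        n_chrom=2, chrom_length=10_000_000, n_coding=10, n_noncoding=5,
        n_nonannotated=60, seed=7,
    )


@pytest.fixture(scope="session")
def small_catalog(small_genome, reference3):
    samples = [f"S{i}" for i in range(8)]
    expo = syn.random_exposures(samples, reference3.signatures, seed=1)
    truth = syn.SimulationTruth(exposures=expo)
    return syn.simulate_catalog(
        small_genome, truth, reference3, mean_tmb=5.0, seed=2
    )


def make_catalog(rows, samples=None, svs=None):
    """Build a catalog from (sample, chrom, pos, ref, alt, vclass[, context]) tuples."""
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "vclass", "context"]
    recs = [tuple(r) + (None,) * (7 - len(r)) for r in rows]
    variants = pd.DataFrame(recs, columns=cols)
    kwargs = {"variants": variants}
    if samples is not None:
        kwargs["samples"] = samples
    if svs is not None:
        kwargs["svs"] = svs
    return MutationCatalog(**kwargs)


@pytest.fixture
def snv_catalog_builder():
    def build(positions, sample="S0", chrom="chr1", context="ACA"):
        rows = [(sample, chrom, int(p), "C", "T", "SNV", context) for p in positions]
        variants = pd.DataFrame(
            rows,
            columns=["sample_id", "chrom", "pos", "ref", "alt", "vclass", "context"],
        )
        return MutationCatalog(variants=variants, samples=[sample])

    return build
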