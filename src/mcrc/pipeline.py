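"""End-to-end orchestration: simulate -> signatures -> kataegis ->
noncoding-scan -> msi-scan -> stats -> response, from one validated
configuration, with a machine-readable run manifest (seeds, thresholds,
output checksums)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io, kataegis as kat, msi as msi_mod, noncoding, response as resp
from . import signatures as sig
from . import stats as st
from . import synthetic as syn

STAGES = (
    "simulate",
    "signatures",
    "kataegis",
    "noncoding_scan",
    "msi_scan",
    "stats",
    "response",
)


class SimulateBlock(BaseModel):
    n_samples: int = 50
    n_chrom: int = 2
    chrom_length: int = 40_000_000
    n_coding: int = 30
    n_noncoding: int = 15
    n_nonannotated: int = 200
    mean_tmb: float = 7.0
    n_signatures: int = 5
    msi_fraction: float = 0.03
    # per-stretch-site slippage in MMR-deficient tumors runs 3-4 orders of
    # magnitude above the ~5e-7/bp background indel rate
    msi_indel_multiplier: float = 3000.0
    n_msi_target_genes: int = 5
    kataegis_fraction: float = 0.24
    kataegis_n_snvs: int = 8
    kataegis_imd_bp: float = 500.0
    planted_noncoding_gene: str | None = "nc000"
    planted_rate_multiplier: float = 10.0
    planted_affected_fraction: float = 0.10
    treated_fraction: float = 0.66
    response_coefficients: dict[str, float] = Field(
        default_factory=lambda: {"prior_treatment": 0.6, "tmb": 0.05}
    )
    response_thresholds: tuple[float, float] = (-0.5, 1.5)


class Thresholds(BaseModel):
    """All cohort-analysis cutoffs, defaulting to the published values."""

    dominant_min_contribution: float = 0.10
    dominant_min_samples: int = 10
    clustering_single_sample_threshold: float = 0.25
    clustering_k: int = 6
    kataegis_min_snvs: int = 5
    kataegis_max_mean_imd: float = 2000.0
    kataegis_gamma: float = 1.0  # calibrated on the synthetic suites
    noncoding_recurrence_min: float = 0.05
    noncoding_window_bp: int = 2_000_000
    noncoding_min_region_bp: int = 1_000
    tmb_high_cutoff: float = 10.0
    deletion_min_bp: int = 10_000
    deletion_max_bp: int = 1_000_000
    msi_control_tolerance: float = 0.10
    msi_n_perm: int = 10_000
    screen_alpha: float = 0.05
    screen_min_events: int = 5


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: str = "mcrc_run"
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    variants_path: str | None = None  # external inputs instead of simulation
    svs_path: str | None = None
    meta_path: str | None = None

    @model_validator(mode="after")
    def _check_stages(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a manifest dict (also written to manifest.json in the output
    directory) recording seeds, thresholds, and output checksums. A stage
    failure raises StageError; earlier outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    seeds = {s: syn.child_seed(config.seed, s) for s in STAGES}
    outputs: dict[str, Path] = {}
    state: dict = {}

    def save(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index)
        outputs[name] = path

    enabled = [s for s in STAGES if s in config.stages]
    for stage in enabled:
        try:
            if stage == "simulate":
                _stage_simulate(config, seeds[stage], out, state, save)
            elif stage == "signatures":
                _stage_signatures(config, state, save)
            elif stage == "kataegis":
                _stage_kataegis(th, state, save)
            elif stage == "noncoding_scan":
                _stage_noncoding(th, state, save)
            elif stage == "msi_scan":
                _stage_msi(th, seeds[stage], state, save)
            elif stage == "stats":
                _stage_stats(th, seeds[stage], state, save)
            elif stage == "response":
                _stage_response(th, seeds[stage], state, save)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(stage, exc) from exc

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seeds": seeds,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _require(state: dict, key: str, stage: str) -> object:
    if key not in state:
        raise StageError(stage, RuntimeError(f"missing dependency: {key}"))
    return state[key]


def _stage_simulate(config: PipelineConfig, seed: int, out: Path, state: dict, save) -> None:
    sb = config.simulate
    if config.variants_path:
        state["catalog"] = io.read_variants(config.variants_path, "tsv")
        if config.svs_path:
            state["catalog"].svs = io.read_svs(config.svs_path)
        state["meta"] = io.read_sample_meta(config.meta_path) if config.meta_path else None
        state["genome"] = None
        return
    genome = syn.build_genome(
        n_chrom=sb.n_chrom,
        chrom_length=sb.chrom_length,
        n_coding=sb.n_coding,
        n_noncoding=sb.n_noncoding,
        n_nonannotated=sb.n_nonannotated,
        seed=syn.child_seed(seed, "genome"),
    )
    reference = syn.synthetic_signature_reference(
        sb.n_signatures, seed=syn.child_seed(seed, "reference")
    )
    samples = [f"S{i:03d}" for i in range(sb.n_samples)]
    exposures = syn.random_exposures(
        samples, reference.signatures, seed=syn.child_seed(seed, "exposures")
    )
    truth = syn.SimulationTruth(exposures=exposures)
    truth.child_seeds = {"master": config.seed, "simulate": seed}
    rng = np.random.default_rng(syn.child_seed(seed, "assignments"))

    n_msi = max(1, int(round(sb.msi_fraction * sb.n_samples)))
    truth.msi_samples = sorted(rng.choice(samples, size=n_msi, replace=False))
    tmb = pd.Series(sb.mean_tmb, index=samples)
    tmb[truth.msi_samples] = sb.mean_tmb * 6  # hypermutated MSI burden

    catalog = syn.simulate_catalog(
        genome, truth, reference, mean_tmb=sb.mean_tmb,
        seed=syn.child_seed(seed, "catalog"), tmb_per_sample=tmb,
    )

    n_kat = int(round(sb.kataegis_fraction * sb.n_samples))
    kat_samples = rng.choice(samples, size=n_kat, replace=False)
    for i, s in enumerate(kat_samples):
        chrom = list(genome.chromosomes)[i % len(genome.chromosomes)]
        catalog, focus = syn.inject_kataegis(
            catalog, genome, s, chrom, sb.kataegis_n_snvs, sb.kataegis_imd_bp,
            seed=syn.child_seed(seed, f"kataegis{i}"),
        )
        truth.kataegis_foci.append(focus)

    if sb.planted_noncoding_gene:
        catalog, entry = syn.plant_noncoding_driver(
            catalog, genome, sb.planted_noncoding_gene,
            sb.planted_rate_multiplier, sb.planted_affected_fraction,
            seed=syn.child_seed(seed, "driver"),
        )
        truth.planted_noncoding[entry["gene_id"]] = entry["rate_multiplier"]

    target_genes = sorted(genome.sequences)[: sb.n_msi_target_genes]
    catalog = syn.inject_msi(
        catalog, genome, truth.msi_samples, sb.msi_indel_multiplier,
        seed=syn.child_seed(seed, "msi"), target_genes=target_genes,
    )
    state["msi_target_genes"] = target_genes

    meta = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    meta["msi_status"] = np.where(pd.Index(samples).isin(truth.msi_samples), "MSI", "MSS")
    treated = rng.random(sb.n_samples) < sb.treated_fraction
    meta["prior_treatment_group"] = np.where(treated, "PLAT/PYR + targeted", "naive")
    meta["purity"] = rng.uniform(0.2, 0.9, sb.n_samples).round(3)

    tmb_obs = sig.compute_tmb(catalog, genome.total_mb)["tmb"]
    features = pd.DataFrame(
        {
            "prior_treatment": treated.astype(float),
            "tmb": tmb_obs.to_numpy(),
        },
        index=samples,
    )
    truth.response_coefficients = dict(sb.response_coefficients)
    meta["response"] = syn.simulate_response(
        features, sb.response_coefficients, sb.response_thresholds,
        seed=syn.child_seed(seed, "response"),
    ).astype(str)

    state.update(genome=genome, catalog=catalog, truth=truth, reference=reference,
                 meta=meta)
    io.write_variants_tsv(catalog, out / "variants.tsv")
    outputs_path = out / "variants.tsv"
    io.write_svs_tsv(catalog.svs, out / "svs.tsv")
    io.write_sample_meta(meta, out / "meta.tsv")
    io.write_exon_fasta(genome.sequences, out / "exons.fa")
    io.write_regions_bed(genome.regions, out / "regions.bed")
    truth.to_json(out / "truth.json")
    save("meta", meta)
    state["variants_path"] = outputs_path


def _stage_signatures(config: PipelineConfig, state: dict, save) -> None:
    catalog = _require(state, "catalog", "signatures")
    reference = state.get("reference")
    genome = state.get("genome")
    sbs, dbs, residuals = sig.count_contexts(catalog)
    if reference is None:
        reference = syn.synthetic_signature_reference(5, seed=0)
    refit = sig.refit_exposures(sbs, reference)
    th = config.thresholds
    dominant = sig.select_dominant(
        refit.relative, th.dominant_min_contribution, th.dominant_min_samples
    )
    cluster_set = sig.clustering_signature_set(
        refit.relative, dominant, [],
        single_sample_threshold=th.clustering_single_sample_threshold,
    )
    k = min(th.clustering_k, max(2, len(refit.relative) - 1))
    labels, order, _ = sig.cluster_samples(refit.relative, cluster_set or list(refit.relative.columns), k=k)
    genome_mb = genome.total_mb if genome is not None else 2859.0
    tmb = sig.compute_tmb(catalog, genome_mb, config.thresholds.tmb_high_cutoff)
    state.update(exposures=refit.relative, dominant=dominant, clusters=labels, tmb=tmb)
    save("exposures", refit.relative)
    save("clusters", labels.to_frame())
    save("tmb", tmb)


def _stage_kataegis(th: Thresholds, state: dict, save) -> None:
    catalog = _require(state, "catalog", "kataegis")
    table, counts = kat.detect_kataegis(
        catalog, gamma=th.kataegis_gamma, min_snvs=th.kataegis_min_snvs,
        max_mean_imd=th.kataegis_max_mean_imd,
    )
    state["kataegis_counts"] = counts
    save("kataegis", table, index=False)
    save("kataegis_counts", counts.to_frame())


def _stage_noncoding(th: Thresholds, state: dict, save) -> None:
    catalog = _require(state, "catalog", "noncoding_scan")
    genome = _require(state, "genome", "noncoding_scan")
    results, report = noncoding.scan_noncoding(
        catalog, genome, recurrence_min=th.noncoding_recurrence_min,
        window_bp=th.noncoding_window_bp, min_region_bp=th.noncoding_min_region_bp,
    )
    state["noncoding_results"] = results
    save("noncoding", results, index=False)


def _stage_msi(th: Thresholds, seed: int, state: dict, save) -> None:
    catalog = _require(state, "catalog", "msi_scan")
    genome = _require(state, "genome", "msi_scan")
    meta = _require(state, "meta", "msi_scan")
    tmb = _require(state, "tmb", "msi_scan")
    profiles = msi_mod.count_msi_prone(genome.sequences)
    coding = genome.regions.subset("coding")
    flags = _mutation_flags(catalog, coding)
    cluster = tmb["high_tmb"]
    gene_tests = msi_mod.high_tmb_gene_test(
        flags, cluster, tmb["tmb"], n_perm=th.msi_n_perm, seed=seed
    )
    msi_samples = meta.index[meta.msi_status == "MSI"].tolist()
    sign_rows = []
    for gene in gene_tests.index[gene_tests.reported]:
        res = msi_mod.matched_control_test(
            gene, flags, msi_samples, profiles, tolerance=th.msi_control_tolerance
        )
        sign_rows.append(res.__dict__)
    sign_df = pd.DataFrame(
        sign_rows,
        columns=["gene_id", "observed_freq", "n_controls", "n_effective",
                 "n_below", "p_sign", "testable", "note"],
    )
    state["msi_gene_tests"] = gene_tests
    save("msi_cluster_genes", gene_tests)
    save("msi_sign_tests", sign_df, index=False)


def _mutation_flags(catalog, regions_df: pd.DataFrame) -> pd.DataFrame:
    v = catalog.variants
    flags = pd.DataFrame(False, index=catalog.samples, columns=regions_df.region_id)
    for row in regions_df.itertuples():
        hit = v[(v.chrom == row.chrom) & (v.pos - 1 >= row.start) & (v.pos - 1 < row.end)]
        for s in hit.sample_id.unique():
            flags.loc[s, row.region_id] = True
    return flags


def _stage_stats(th: Thresholds, seed: int, state: dict, save) -> None:
    catalog = _require(state, "catalog", "stats")
    meta = _require(state, "meta", "stats")
    tmb = _require(state, "tmb", "stats")
    rows = []
    treated = meta.prior_treatment_group != "naive"
    if treated.any() and (~treated).any():
        mwu = st.compare_groups(
            [tmb.loc[treated[treated].index, "tmb"], tmb.loc[treated[~treated].index, "tmb"]]
        )
        rows.append({"test": "tmb_by_prior_treatment", "method": mwu["method"],
                     "statistic": mwu["statistic"], "p": mwu["p"]})
    if "kataegis_counts" in state:
        kc = state["kataegis_counts"].reindex(tmb.index, fill_value=0)
        tmb_class = pd.cut(tmb["tmb"], bins=[-np.inf, 5, 10, np.inf],
                           labels=["low", "mid", "high"])
        tt = st.trend_test(tmb_class.astype(str), (kc > 0).astype(float),
                           seed=seed)
        rows.append({"test": "kataegis_vs_tmb_class_trend", "method": tt["method"],
                     "statistic": tt["statistic"], "p": tt["p"]})
    dels = st.count_size_deletions(
        catalog.svs, th.deletion_min_bp, th.deletion_max_bp, samples=catalog.samples
    )
    state["deletion_counts"] = dels
    save("stats", pd.DataFrame(rows), index=False)
    save("deletion_counts", dels)


def _stage_response(th: Thresholds, seed: int, state: dict, save) -> None:
    meta = _require(state, "meta", "response")
    exposures = _require(state, "exposures", "response")
    tmb = _require(state, "tmb", "response")
    features = pd.DataFrame(index=meta.index)
    features["prior_treatment"] = (meta.prior_treatment_group != "naive").astype(float)
    features["tmb"] = tmb["tmb"]
    if "kataegis_counts" in state:
        features["n_kataegis"] = state["kataegis_counts"].reindex(meta.index, fill_value=0)
    if "deletion_counts" in state:
        features["n_del_10kb_1mb"] = state["deletion_counts"].reindex(meta.index)[
            "n_del_10kb_1mb"
        ]
    for s in exposures.columns:
        features[f"sig_{s}"] = exposures[s].reindex(meta.index).fillna(0.0)
    y = pd.Categorical(meta.response, categories=["PD", "SD", "PR"], ordered=True)
    screen = resp.univariate_screen(
        pd.Series(y, index=meta.index), features,
        alpha=th.screen_alpha, min_events=th.screen_min_events,
    )
    out_rows = screen.table
    selected = screen.selected
    lasso_coefs = pd.Series(dtype=float)
    if len(selected) >= 2:
        fit = resp.ordinal_lasso(
            pd.Series(y, index=meta.index), features[selected], seed=seed
        )
        lasso_coefs = fit.nonzero()
    table = out_rows.set_index("feature")
    table["selected"] = table.index.isin(selected)
    table["lasso_coef"] = lasso_coefs.reindex(table.index)
    save("response", table)
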