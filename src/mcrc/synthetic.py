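"""Synthetic-cohort generator with planted ground truth.

Every downstream stage (signature refitting, kataegis calling, noncoding-driver
scan, MSI enrichment, ordinal response models) is testable against cohorts
generated here: per-sample mutation burdens with signature-mixture channel
distributions, injected hypermutation foci, planted noncoding drivers with
locally elevated rates, MSI samples with excess 1-bp indels inside
mononucleotide stretches, SV size distributions with a deletion mode near
128 kb, and ordinal response drawn from a proportional-odds model.

The generator emulates the *statistical* structure of a metastatic-CRC WGS
cohort, not real genomes: chromosomes are sequence-free coordinate spaces
(trinucleotide context is stored per variant), and only coding genes carry
exon sequences. All operations are deterministic under a fixed seed and
return/extend a SimulationTruth object recording what was planted.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels, msi
from .io import (
    FormatError,
    MutationCatalog,
    RegionSet,
    SignatureMatrix,
)

_PYR_REF = []
_PYR_ALT = []
_PYR_CTX = []
for _lab in channels.SBS96_LABELS:
    _r, _a, _c = channels.parse_sbs_label(_lab)
    _PYR_REF.append(_r)
    _PYR_ALT.append(_a)
    _PYR_CTX.append(_c)
_PYR_REF = np.array(_PYR_REF)
_PYR_ALT = np.array(_PYR_ALT)
_PYR_CTX = np.array(_PYR_CTX)

_DBS_REF = np.array([lab.split(">")[0] for lab in channels.DBS78_LABELS])
_DBS_ALT = np.array([lab.split(">")[1] for lab in channels.DBS78_LABELS])


class SimulationError(RuntimeError):
    pass


@dataclass
class GenomeModel:
    """Chromosome lengths plus disjoint labeled region sets."""

    chromosomes: dict[str, int]
    regions: RegionSet
    sequences: dict[str, str] | None = None

    @property
    def total_bp(self) -> int:
        return int(sum(self.chromosomes.values()))

    @property
    def total_mb(self) -> float:
        return self.total_bp / 1e6

    def validate(self) -> None:
        df = self.regions.df
        for row in df.itertuples():
            if row.chrom not in self.chromosomes:
                raise SimulationError(f"region {row.region_id} on unknown {row.chrom}")
            if row.end > self.chromosomes[row.chrom]:
                raise SimulationError(f"region {row.region_id} beyond chromosome end")
        # class disjointness across ALL classes
        for chrom, grp in df.groupby("chrom"):
            g = grp.sort_values("start")
            prev_end = -1
            for row in g.itertuples():
                if row.start < prev_end:
                    raise SimulationError(f"overlapping regions on {chrom}")
                prev_end = max(prev_end, row.end)


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator."""

    exposures: pd.DataFrame  # samples x signatures, rows sum to 1
    kataegis_foci: list[dict] = field(default_factory=list)
    planted_noncoding: dict[str, float] = field(default_factory=dict)
    msi_samples: list[str] = field(default_factory=list)
    response_coefficients: dict[str, float] = field(default_factory=dict)
    child_seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.exposures.to_numpy()
        if (vals < 0).any():
            raise SimulationError("negative exposure weights")
        if len(vals) and not np.allclose(vals.sum(axis=1), 1.0, atol=1e-8):
            raise SimulationError("exposure rows must sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "exposures": {
                s: dict(row.round(10))
                for s, row in self.exposures.iterrows()
            },
            "kataegis_foci": self.kataegis_foci,
            "planted_noncoding": self.planted_noncoding,
            "msi_samples": self.msi_samples,
            "response_coefficients": self.response_coefficients,
            "child_seeds": self.child_seeds,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out, kept below 2**31."""
    h = int(seed)
    for ch in stage:
        h = (h * 1000003 + ord(ch)) % (2**63 - 1)
    return h % (2**31 - 1)


def synthetic_signature_reference(
    n_signatures: int = 5, seed: int = 0, kind: str = "sbs", sparsity: float = 0.15
) -> SignatureMatrix:
    """A synthetic stand-in for a reference signature matrix.

    Profiles are sparse Dirichlet draws over the 96 (or 78) channels, named
    SYN1..SYNk. Purely synthetic: used where a curated reference catalog is
    not shipped with the package.
    """
    labels = channels.SBS96_LABELS if kind == "sbs" else channels.DBS78_LABELS
    rng = np.random.default_rng(seed)
    n_ch = len(labels)
    cols = {}
    for j in range(n_signatures):
        weights = rng.dirichlet(np.full(n_ch, sparsity))
        cols[f"SYN{j + 1}"] = weights
    df = pd.DataFrame(cols, index=list(labels))
    return SignatureMatrix(df)


def random_exposures(
    samples: list[str], signatures: list[str], seed: int = 0, concentration: float = 0.8
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(len(signatures), concentration), size=len(samples))
    return pd.DataFrame(w, index=samples, columns=signatures)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _try_place(
    occupied: list[tuple[int, int]], size: int, lo: int, hi: int, rng, attempts: int = 400
) -> tuple[int, int]:
    """Place a [start, start+size) interval inside [lo, hi) avoiding overlap."""
    hi = hi - size
    if hi <= lo:
        raise SimulationError("placement window smaller than region size")
    starts = [s for s, _ in occupied]
    for _ in range(attempts):
        start = int(rng.integers(lo, hi))
        end = start + size
        i = bisect.bisect_right(starts, start)
        if i and occupied[i - 1][1] > start:
            continue
        if i < len(occupied) and occupied[i][0] < end:
            continue
        occupied.insert(i, (start, end))
        starts.insert(i, start)
        return start, end
    raise SimulationError("could not place region without overlap (packing too dense)")


def build_genome(
    n_chrom: int = 2,
    chrom_length: int = 40_000_000,
    n_coding: int = 30,
    n_noncoding: int = 15,
    n_nonannotated: int = 200,
    seed: int = 0,
    noncoding_size: tuple[int, int] = (3_000, 9_000),
    nonannotated_size: tuple[int, int] = (2_000, 30_000),
    coding_length: int = 1_500,
    max_planted_stretches: int = 12,
    min_local_baselines: int = 10,
) -> GenomeModel:
    """Construct a synthetic annotated genome.

    Noncoding gene sizes default to the 3-9 kb range typical of recurrently
    mutated lncRNAs; every noncoding gene is guaranteed at least
    ``min_local_baselines`` (>= 3) nonannotated regions (> 1 kb) within
    +/- 1 Mb, emulating the density of intergenic sequence around real genes
    and keeping the local-baseline rate test well-posed (an exact signed-rank
    test over b baselines cannot fall below 2**-b). Coding genes carry random
    exon sequences with a variable number of planted mononucleotide stretches
    (lengths 6-13) to give the MSI-prone counter a realistic spread.
    """
    min_local_baselines = max(3, min_local_baselines)
    if n_nonannotated < min_local_baselines * n_noncoding:
        raise SimulationError(
            "infeasible packing: need >= "
            f"{min_local_baselines} nonannotated regions per noncoding gene"
        )
    requested = (
        n_coding * coding_length
        + n_noncoding * noncoding_size[1]
        + n_nonannotated * nonannotated_size[1]
    )
    if requested > n_chrom * chrom_length:
        raise SimulationError(
            f"infeasible packing: requested ~{requested} bp of regions on "
            f"{n_chrom * chrom_length} bp of genome"
        )
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": int(chrom_length) for i in range(n_chrom)}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows: list[tuple[str, int, int, str, str]] = []

    # noncoding genes, each with 3 guaranteed nearby nonannotated baselines
    n_bg_placed = 0
    for i in range(n_noncoding):
        chrom = f"chr{i % n_chrom + 1}"
        size = int(rng.integers(noncoding_size[0], noncoding_size[1] + 1))
        lo = min(1_000_000, chrom_length // 4)
        start, end = _try_place(
            occupied[chrom], size, lo, chrom_length - lo, rng
        )
        rows.append((chrom, start, end, "noncoding", f"nc{i:03d}"))
        for _ in range(min_local_baselines):
            bsize = int(rng.integers(nonannotated_size[0], nonannotated_size[1] + 1))
            wlo = max(0, start - 900_000)
            whi = min(chrom_length, end + 900_000)
            bs, be = _try_place(occupied[chrom], bsize, wlo, whi, rng)
            rows.append((chrom, bs, be, "nonannotated", f"bg{n_bg_placed:03d}"))
            n_bg_placed += 1

    for i in range(n_bg_placed, n_nonannotated):
        chrom = f"chr{int(rng.integers(n_chrom)) + 1}"
        bsize = int(rng.integers(nonannotated_size[0], nonannotated_size[1] + 1))
        bs, be = _try_place(occupied[chrom], bsize, 0, chrom_length, rng)
        rows.append((chrom, bs, be, "nonannotated", f"bg{i:03d}"))

    sequences: dict[str, str] = {}
    for i in range(n_coding):
        chrom = f"chr{int(rng.integers(n_chrom)) + 1}"
        start, end = _try_place(occupied[chrom], coding_length, 0, chrom_length, rng)
        gene_id = f"gene{i:03d}"
        rows.append((chrom, start, end, "coding", gene_id))
        seq = rng.choice(list(channels.BASES), size=coding_length)
        n_stretch = int(rng.integers(0, max_planted_stretches + 1))
        for _ in range(n_stretch):
            run_len = int(rng.integers(6, 14))
            base = channels.BASES[int(rng.integers(4))]
            off = int(rng.integers(0, coding_length - run_len))
            seq[off : off + run_len] = base
        sequences[gene_id] = "".join(seq)

    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region_class", "region_id"]
    )
    genome = GenomeModel(chroms, RegionSet(df), sequences)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# mutation catalog simulation
# ---------------------------------------------------------------------------

def _uniform_positions(genome: GenomeModel, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    names = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in names], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    offsets = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, offsets, side="right") - 1
    pos = offsets - cum[idx] + 1  # 1-based
    return np.array(names, dtype=object)[idx], pos.astype(np.int64)


def simulate_catalog(
    genome: GenomeModel,
    truth: SimulationTruth,
    reference: SignatureMatrix,
    mean_tmb: float = 7.0,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.90, 0.02, 0.08),
    tmb_per_sample: pd.Series | None = None,
    dbs_reference: SignatureMatrix | None = None,
    dbs_exposures: pd.DataFrame | None = None,
    sv_rate: float = 40.0,
    sv_type_probs: tuple[float, float, float, float] = (0.45, 0.30, 0.15, 0.10),
) -> MutationCatalog:
    """Draw a mutation catalog for the samples in ``truth.exposures``.

    Per-sample small-variant count is Poisson(tmb_sample x genome Mb), split
    into SNV / doublet-MNV / 1-bp-indel by ``fractions`` (defaults 0.90 / 0.02
    / 0.08, mirroring the cohort composition). SNV channels are multinomial
    draws from the sample's signature mixture; the drawn channel's reference
    trinucleotide is stored with the variant (on a random strand, so the
    pyrimidine collapse is exercised downstream). Deletion SV sizes have a
    log10 mode at 5.1 (~128 kb).
    """
    if list(truth.exposures.columns) != reference.signatures:
        raise SimulationError(
            "exposure columns do not match reference signatures: "
            f"{list(truth.exposures.columns)} vs {reference.signatures}"
        )
    rng = np.random.default_rng(seed)
    ref_vals = reference.values.to_numpy()  # 96 x S
    samples = list(truth.exposures.index)
    tmb = (
        tmb_per_sample.reindex(samples)
        if tmb_per_sample is not None
        else pd.Series(mean_tmb, index=samples)
    )

    frames = []
    sv_frames = []
    sv_names = np.array(["DEL", "DUP", "INV", "TRA"], dtype=object)
    # (log10-size mean, sd) per SV type; deletions peak at ~128 kb
    sv_size_params = {"DEL": (5.107, 0.35), "DUP": (4.42, 0.30), "INV": (7.15, 0.35)}

    for sample in samples:
        n_small = rng.poisson(max(tmb[sample], 0.0) * genome.total_mb)
        n_snv, n_mnv, n_indel = rng.multinomial(n_small, fractions)

        if n_snv:
            probs = ref_vals @ truth.exposures.loc[sample].to_numpy()
            probs = probs / probs.sum()
            ch_counts = rng.multinomial(n_snv, probs)
            ch_idx = np.repeat(np.arange(96), ch_counts)
            rng.shuffle(ch_idx)
            chrom, pos = _uniform_positions(genome, n_snv, rng)
            ref = _PYR_REF[ch_idx].copy()
            alt = _PYR_ALT[ch_idx].copy()
            ctx = _PYR_CTX[ch_idx].copy()
            flip = rng.random(n_snv) < 0.5
            for k in np.nonzero(flip)[0]:
                ref[k] = channels.COMPLEMENT[ref[k]]
                alt[k] = channels.COMPLEMENT[alt[k]]
                ctx[k] = channels.revcomp(ctx[k])
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "vclass": "SNV",
                        "context": ctx,
                    }
                )
            )

        if n_mnv:
            if dbs_reference is not None and dbs_exposures is not None:
                dprobs = dbs_reference.values.to_numpy() @ dbs_exposures.loc[
                    sample
                ].to_numpy()
                dprobs = dprobs / dprobs.sum()
            else:
                dprobs = np.full(78, 1 / 78)
            d_idx = rng.choice(78, size=n_mnv, p=dprobs)
            chrom, pos = _uniform_positions(genome, n_mnv, rng)
            ref = _DBS_REF[d_idx].copy()
            alt = _DBS_ALT[d_idx].copy()
            flip = rng.random(n_mnv) < 0.5
            for k in np.nonzero(flip)[0]:
                ref[k] = channels.revcomp(ref[k])
                alt[k] = channels.revcomp(alt[k])
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "vclass": "MNV",
                        "context": ref,
                    }
                )
            )

        if n_indel:
            chrom, pos = _uniform_positions(genome, n_indel, rng)
            is_ins = rng.random(n_indel) < 0.5
            b1 = rng.choice(list(channels.BASES), size=n_indel)
            b2 = rng.choice(list(channels.BASES), size=n_indel)
            ref = np.where(is_ins, b1, np.char.add(b1.astype(str), b2.astype(str)))
            alt = np.where(is_ins, np.char.add(b1.astype(str), b2.astype(str)), b1)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "vclass": np.where(is_ins, "INS", "DEL"),
                        "context": None,
                    }
                )
            )

        n_sv = rng.poisson(sv_rate)
        if n_sv:
            types = sv_names[rng.choice(4, size=n_sv, p=list(sv_type_probs))]
            chrom, start = _uniform_positions(genome, n_sv, rng)
            sizes = np.ones(n_sv, dtype=np.int64)
            for t, (mu, sd) in sv_size_params.items():
                mask = types == t
                if mask.any():
                    sizes[mask] = np.clip(
                        10 ** rng.normal(mu, sd, size=int(mask.sum())), 50, 3e7
                    ).astype(np.int64)
            end = start + np.where(types == "TRA", 0, sizes - 1)
            for k, c in enumerate(chrom):  # clip at chromosome end
                end[k] = min(end[k], genome.chromosomes[c])
            sv_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "svtype": types,
                    }
                )
            )

    variants = (
        pd.concat(frames, ignore_index=True) if frames else None
    )
    svs = pd.concat(sv_frames, ignore_index=True) if sv_frames else None
    kwargs = {"samples": samples}
    if variants is not None:
        kwargs["variants"] = variants
    if svs is not None:
        svs["size"] = np.where(svs.svtype == "TRA", np.nan, svs.end - svs.start + 1)
        kwargs["svs"] = svs
    return MutationCatalog(**kwargs)


def inject_kataegis(
    catalog: MutationCatalog,
    genome: GenomeModel,
    sample: str,
    chrom: str,
    n_snvs: int,
    imd_bp: float,
    seed: int = 0,
    start: int | None = None,
) -> tuple[MutationCatalog, dict]:
    """Insert a clustered hypermutation focus of ``n_snvs`` SNVs.

    Successive gaps are ``imd_bp`` jittered +/- 20%. Returns the extended
    catalog and the truth entry for the focus.
    """
    if n_snvs < 2:
        raise SimulationError("a kataegis focus needs at least 2 SNVs")
    rng = np.random.default_rng(seed)
    length = genome.chromosomes[chrom]
    gaps = np.maximum(1, np.round(imd_bp * rng.uniform(0.8, 1.2, n_snvs - 1))).astype(
        np.int64
    )
    span = int(gaps.sum())
    if start is None:
        if span + 2 >= length:
            raise SimulationError("focus does not fit on chromosome")
        start = int(rng.integers(1, length - span))
    positions = start + np.concatenate([[0], np.cumsum(gaps)])
    if positions[-1] > length:
        raise SimulationError("focus overlaps chromosome end")
    ch_idx = rng.integers(0, 96, size=n_snvs)
    new = pd.DataFrame(
        {
            "sample_id": sample,
            "chrom": chrom,
            "pos": positions,
            "ref": _PYR_REF[ch_idx],
            "alt": _PYR_ALT[ch_idx],
            "vclass": "SNV",
            "context": _PYR_CTX[ch_idx],
        }
    )
    focus = {
        "sample": sample,
        "chrom": chrom,
        "start": int(positions[0]),
        "end": int(positions[-1]),
        "n_snvs": int(n_snvs),
    }
    return catalog.add_variants(new), focus


def plant_noncoding_driver(
    catalog: MutationCatalog,
    genome: GenomeModel,
    gene_id: str,
    rate_multiplier: float,
    affected_fraction: float,
    seed: int = 0,
) -> tuple[MutationCatalog, dict]:
    """Raise a noncoding gene's cohort mutation rate to a multiple of its local baseline.

    Adds Poisson((multiplier - 1) x local_rate x gene_size) SNVs, spread over a
    random ``affected_fraction`` of samples, so the gene's expected cohort-wide
    rate becomes ~ rate_multiplier x the rate of nearby nonannotated regions.
    """
    from .noncoding import local_baseline, region_mutation_rates

    if rate_multiplier < 1:
        raise SimulationError("rate_multiplier must be >= 1")
    gene = genome.regions.by_id(gene_id)
    if gene.region_class != "noncoding":
        raise SimulationError(f"{gene_id} is not a noncoding gene")
    rng = np.random.default_rng(seed)
    baselines = local_baseline(genome, gene)
    rates = region_mutation_rates(catalog, RegionSet(baselines), len(catalog.samples))
    pooled = rates.n_mutations.sum() / rates["size"].sum()
    gene_size = gene.end - gene.start
    n_add = rng.poisson((rate_multiplier - 1.0) * pooled * gene_size)
    entry = {
        "gene_id": gene_id,
        "rate_multiplier": float(rate_multiplier),
        "affected_fraction": float(affected_fraction),
        "n_added": int(n_add),
    }
    if n_add == 0:
        return catalog, entry
    n_affected = max(1, int(round(affected_fraction * len(catalog.samples))))
    affected = rng.choice(catalog.samples, size=n_affected, replace=False)
    ch_idx = rng.integers(0, 96, size=n_add)
    new = pd.DataFrame(
        {
            "sample_id": rng.choice(affected, size=n_add),
            "chrom": gene.chrom,
            "pos": rng.integers(gene.start + 1, gene.end + 1, size=n_add),
            "ref": _PYR_REF[ch_idx],
            "alt": _PYR_ALT[ch_idx],
            "vclass": "SNV",
            "context": _PYR_CTX[ch_idx],
        }
    )
    return catalog.add_variants(new), entry


def inject_msi(
    catalog: MutationCatalog,
    genome: GenomeModel,
    msi_samples: list[str],
    indel_multiplier: float,
    seed: int = 0,
    target_genes: list[str] | None = None,
) -> MutationCatalog:
    """Add 1-bp indels inside mononucleotide stretches of coding genes for MSI samples.

    The added count per (sample, gene) is Poisson((multiplier - 1) x baseline
    indel rate per bp x the gene's total stretch bp), so genes with more
    stretches accumulate more events. ``target_genes`` restricts the planting
    to a chosen gene set (default: all exon-bearing genes).
    """
    if not genome.sequences:
        raise SimulationError("genome carries no exon sequences")
    rng = np.random.default_rng(seed)
    base_rate = max(
        (catalog.variants.vclass.isin(["INS", "DEL"])).sum()
        / max(len(catalog.samples), 1)
        / genome.total_bp,
        1e-10,
    )
    genes = target_genes if target_genes is not None else sorted(genome.sequences)
    coding = genome.regions.subset("coding").set_index("region_id")
    frames = []
    for gene in genes:
        seq = genome.sequences.get(gene)
        if seq is None:
            raise SimulationError(f"no sequence for gene {gene}")
        stretches = msi.find_mono_stretches(seq)
        if not stretches:
            continue
        stretch_bp = sum(length for _, length, _ in stretches)
        weights = np.array([length for _, length, _ in stretches], dtype=float)
        weights /= weights.sum()
        gstart = int(coding.loc[gene].start)
        lam = (indel_multiplier - 1.0) * base_rate * stretch_bp
        for sample in msi_samples:
            n_add = rng.poisson(lam)
            if not n_add:
                continue
            which = rng.choice(len(stretches), size=n_add, p=weights)
            rows = []
            for w in which:
                off, length, base = stretches[w]
                inside = int(rng.integers(0, length - 1))
                pos = gstart + off + inside + 1  # 1-based
                if rng.random() < 0.5:
                    rows.append((sample, coding.loc[gene].chrom, pos, base + base, base, "DEL"))
                else:
                    rows.append((sample, coding.loc[gene].chrom, pos, base, base + base, "INS"))
            frames.append(
                pd.DataFrame(
                    rows,
                    columns=["sample_id", "chrom", "pos", "ref", "alt", "vclass"],
                )
            )
    if not frames:
        return catalog
    new = pd.concat(frames, ignore_index=True)
    new["context"] = None
    return catalog.add_variants(new)


def simulate_response(
    features: pd.DataFrame,
    coefficients: dict[str, float] | pd.Series,
    thresholds: tuple[float, float],
    seed: int = 0,
) -> pd.Series:
    """Draw ordinal best-overall-response labels from a proportional-odds model.

    P(Y <= k | x) = logistic(theta_k - x.beta) with PD < SD < PR coded 0 < 1 < 2.
    """
    from scipy.special import expit

    beta = pd.Series(coefficients, dtype=float)
    if not np.isfinite(beta).all():
        raise SimulationError("non-finite response coefficients")
    t1, t2 = thresholds
    if not t1 < t2:
        raise SimulationError("thresholds must satisfy theta1 < theta2")
    missing = set(beta.index) - set(features.columns)
    if missing:
        raise SimulationError(f"coefficients for unknown features: {sorted(missing)}")
    eta = features[beta.index].to_numpy() @ beta.to_numpy()
    rng = np.random.default_rng(seed)
    u = rng.random(len(features))
    p1 = expit(t1 - eta)
    p2 = expit(t2 - eta)
    codes = np.where(u < p1, 0, np.where(u < p2, 1, 2))
    labels = np.array(["PD", "SD", "PR"], dtype=object)[codes]
    return pd.Series(
        pd.Categorical(labels, categories=["PD", "SD", "PR"], ordered=True),
        index=features.index,
        name="response",
    )
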