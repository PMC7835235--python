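"""Core domain containers and file readers/writers.

Coordinate conventions: variant positions are 1-based (VCF convention);
regions are 0-based half-open (BED convention); all interval arithmetic in the
package is half-open. Alleles are stored as given in the input; strand
collapsing happens only in channel counting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import channels

VCLASSES = ("SNV", "MNV", "INS", "DEL")
SVTYPES = ("DEL", "DUP", "INV", "TRA")
REGION_CLASSES = ("coding", "noncoding", "nonannotated")
RESPONSE_LEVELS = ("PD", "SD", "PR")  # ordered: progressive < stable < partial

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "vclass", "context"]
SV_COLUMNS = ["sample_id", "chrom", "start", "end", "svtype", "size"]


class FormatError(ValueError):
    """Raised for malformed input files or records."""


def classify_variant(ref: str, alt: str) -> str:
    """Classify an allele pair into SNV/MNV/INS/DEL by the length rule."""
    if not ref or not alt:
        raise FormatError(f"empty allele in {ref!r}>{alt!r}")
    for allele in (ref, alt):
        if any(b not in channels.BASES for b in allele):
            raise FormatError(f"non-ACGT allele {allele!r}")
    if len(ref) == len(alt):
        if ref == alt:
            raise FormatError(f"ref equals alt: {ref!r}")
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: str
    context: str | None = None


@dataclass(frozen=True)
class SVRecord:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    svtype: str

    @property
    def size(self) -> float:
        if self.svtype == "TRA":
            return float("nan")
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """A table of labeled genomic intervals (0-based half-open)."""

    df: pd.DataFrame  # chrom, start, end, region_class, region_id, size

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if len(df):
            bad = df[(df.start < 0) | (df.start >= df.end)]
            if len(bad):
                raise FormatError(
                    f"invalid region intervals (need 0 <= start < end): "
                    f"{bad.region_id.tolist()[:5]}"
                )
            if df.region_id.duplicated().any():
                dups = df.region_id[df.region_id.duplicated()].tolist()
                raise FormatError(f"duplicate region ids: {dups[:5]}")
        df["size"] = df.end - df.start
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, region_class: str) -> pd.DataFrame:
        return self.df[self.df.region_class == region_class]

    def by_id(self, region_id: str) -> pd.Series:
        rows = self.df[self.df.region_id == region_id]
        if not len(rows):
            raise KeyError(f"unknown region id {region_id!r}")
        return rows.iloc[0]

    def overlap_report(self) -> pd.DataFrame:
        """Pairs of same-class overlapping regions (interval sweep)."""
        hits = []
        for (_, _), grp in self.df.groupby(["region_class", "chrom"], sort=True):
            g = grp.sort_values("start")
            ids = g.region_id.to_numpy()
            starts = g.start.to_numpy()
            ends = g.end.to_numpy()
            open_end = -1
            open_id = None
            for rid, s, e in zip(ids, starts, ends):
                if s < open_end:
                    hits.append((open_id, rid))
                if e > open_end:
                    open_end, open_id = e, rid
        return pd.DataFrame(hits, columns=["region_a", "region_b"])

    @staticmethod
    def concat(sets: Iterable["RegionSet"]) -> "RegionSet":
        return RegionSet(pd.concat([s.df for s in sets], ignore_index=True))


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "vclass": pd.Series(dtype=str),
            "context": pd.Series(dtype=object),
        }
    )


def _empty_svs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "svtype": pd.Series(dtype=str),
            "size": pd.Series(dtype=float),
        }
    )


@dataclass
class MutationCatalog:
    """Per-sample somatic small variants plus structural variants."""

    variants: pd.DataFrame = field(default_factory=_empty_variants)
    svs: pd.DataFrame = field(default_factory=_empty_svs)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.variants.copy()
        if "context" not in v.columns:
            v["context"] = None
        v = v[VARIANT_COLUMNS]
        v = v.sort_values(["sample_id", "chrom", "pos"], kind="mergesort")
        self.variants = v.reset_index(drop=True)
        s = self.svs.copy()
        if "size" not in s.columns:
            s["size"] = np.where(
                s.svtype == "TRA", np.nan, s.end - s.start + 1
            )
        self.svs = s[SV_COLUMNS].reset_index(drop=True)
        if not self.samples:
            self.samples = sorted(
                set(self.variants.sample_id) | set(self.svs.sample_id)
            )
        known = set(self.samples)
        for df, what in ((self.variants, "variant"), (self.svs, "SV")):
            unknown = set(df.sample_id) - known
            if unknown:
                raise FormatError(f"{what} records for unknown samples: {sorted(unknown)[:5]}")

    def validate(self) -> None:
        v = self.variants
        if len(v):
            if (v.pos < 1).any():
                raise FormatError("variant positions must be >= 1")
            for row in v.itertuples():
                expected = classify_variant(row.ref, row.alt)
                if expected != row.vclass:
                    raise FormatError(
                        f"vclass {row.vclass} inconsistent with alleles "
                        f"{row.ref}>{row.alt} at {row.chrom}:{row.pos}"
                    )
        s = self.svs
        non_tra = s[s.svtype != "TRA"]
        if len(non_tra) and (non_tra.start > non_tra.end).any():
            raise FormatError("SV start > end")

    def n_variants(self, sample_id: str | None = None) -> int:
        if sample_id is None:
            return len(self.variants)
        return int((self.variants.sample_id == sample_id).sum())

    def sample_variants(self, sample_id: str) -> pd.DataFrame:
        return self.variants[self.variants.sample_id == sample_id]

    def add_variants(self, new: pd.DataFrame) -> "MutationCatalog":
        merged = pd.concat([self.variants, new], ignore_index=True)
        samples = sorted(set(self.samples) | set(new.sample_id))
        return MutationCatalog(merged, self.svs, samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationCatalog):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.variants.fillna("").equals(other.variants.fillna(""))
            and self.svs.fillna(0).equals(other.svs.fillna(0))
        )


@dataclass
class SignatureMatrix:
    """Reference signature profiles: channels x signatures, columns sum to 1."""

    values: pd.DataFrame  # index = channel labels, columns = signature names

    def __post_init__(self) -> None:
        vals = self.values
        n = len(vals)
        if n == 96:
            canonical = list(channels.SBS96_LABELS)
        elif n == 78:
            canonical = list(channels.DBS78_LABELS)
        else:
            raise FormatError(f"expected 96 or 78 channels, got {n}")
        missing = set(canonical) - set(vals.index)
        if missing:
            raise FormatError(f"missing channels: {sorted(missing)[:5]}")
        vals = vals.loc[canonical]
        if (vals.to_numpy() < 0).any():
            raise FormatError("negative signature entries")
        sums = vals.sum(axis=0)
        off = (sums - 1.0).abs()
        if (off > 1e-3).any():
            bad = sums[off > 1e-3]
            raise FormatError(f"signature columns do not sum to 1: {dict(bad.round(4))}")
        self.values = vals / sums

    @property
    def channels(self) -> list[str]:
        return list(self.values.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.values.columns)


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    sample_id: str | None = None,
) -> MutationCatalog:
    """Read small variants from a VCF or a tab-separated variant table.

    The tsv dialect has columns sample_id/chrom/pos/ref/alt (context optional).
    For VCF, records are assigned to the declared ``sample_id`` if given,
    otherwise to every genotype sample carrying the alternate allele.
    Multi-allelic rows are split into one record per ALT.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path, sample_id)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _read_variants_tsv(path: Path) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"variant table missing columns {sorted(missing)}")
    if "context" not in df.columns:
        df["context"] = None
    else:
        df["context"] = df["context"].where(df["context"].notna(), None)
    vclasses = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            if row.pos < 1:
                raise FormatError("position must be >= 1")
            vclasses.append(classify_variant(str(row.ref), str(row.alt)))
        except (FormatError, TypeError) as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    df["vclass"] = vclasses
    return MutationCatalog(variants=df)


def _read_variants_vcf(path: Path, declared_sample: str | None) -> MutationCatalog:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if declared_sample is None and not vcf_samples:
            raise FormatError(
                f"{path}: VCF has no genotype columns; pass a sample_id"
            )
        for rec in vcf:
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                try:
                    vclass = classify_variant(rec.ref, alt)
                except FormatError as exc:
                    raise FormatError(f"{path} at {rec.chrom}:{rec.pos}: {exc}") from exc
                if declared_sample is not None:
                    carriers = [declared_sample]
                else:
                    carriers = [
                        s
                        for s in vcf_samples
                        if alt_idx in (rec.samples[s].get("GT") or ())
                    ]
                for carrier in carriers:
                    records.append(
                        (carrier, rec.chrom, rec.pos, rec.ref, alt, vclass, None)
                    )
    df = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    if not len(df):
        df = _empty_variants()
    samples = [declared_sample] if declared_sample else None
    return MutationCatalog(variants=df, samples=samples or [])


def write_variants_tsv(catalog: MutationCatalog, path: str | Path) -> None:
    out = catalog.variants.copy()
    out.to_csv(path, sep="\t", index=False)


def read_svs(path: str | Path) -> pd.DataFrame:
    """Read a structural-variant table (sample/chrom/start/end/svtype)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    required = {"sample_id", "chrom", "start", "end", "svtype"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"SV table missing columns {sorted(missing)}")
    bad_type = set(df.svtype) - set(SVTYPES)
    if bad_type:
        raise FormatError(f"unknown SV types {sorted(bad_type)}")
    non_tra = df[df.svtype != "TRA"]
    if len(non_tra) and (non_tra.start > non_tra.end).any():
        raise FormatError("SV start > end")
    df["size"] = np.where(df.svtype == "TRA", np.nan, df.end - df.start + 1)
    return df


def write_svs_tsv(svs: pd.DataFrame, path: str | Path) -> None:
    svs.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, region_class: str) -> RegionSet:
    """Read a BED file (3+ columns, 0-based half-open) into a RegionSet."""
    if region_class not in REGION_CLASSES:
        raise FormatError(f"unknown region class {region_class!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            region_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, region_class, region_id))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region_class", "region_id"]
    )
    if not len(df):
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "region_class", "region_id"]
        ).astype({"start": np.int64, "end": np.int64})
    return RegionSet(df)


def write_regions_bed(regions: RegionSet, path: str | Path) -> None:
    regions.df[["chrom", "start", "end", "region_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_signature_reference(path: str | Path) -> SignatureMatrix:
    """Read a reference signature TSV (first column channel labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] not in (96, 78):
        raise FormatError(
            f"signature table must have 96 or 78 channel rows, got {df.shape[0]}"
        )
    return SignatureMatrix(df)


def write_signature_reference(sig: SignatureMatrix, path: str | Path) -> None:
    sig.values.to_csv(path, sep="\t", index_label="channel")


def read_exon_sequences(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read per-gene exon sequences from FASTA.

    Returns (gene_id -> uppercased sequence, gene_id -> count of non-ACGT
    characters). Duplicate gene ids raise.
    """
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    oddities: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        if gene in sequences:
            raise FormatError(f"duplicate gene id {gene!r} in {path}")
        seq = str(rec.seq).upper()
        n_odd = sum(1 for b in seq if b not in channels.BASES)
        sequences[gene] = seq
        if n_odd:
            oddities[gene] = n_odd
    return sequences, oddities


def write_exon_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in sequences.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (msi_status, prior_treatment_group, response, purity)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata table needs a sample_id column")
    df = df.set_index("sample_id")
    if "msi_status" in df.columns:
        bad = set(df.msi_status.dropna()) - {"MSI", "MSS"}
        if bad:
            raise FormatError(f"unknown MSI status values {sorted(bad)}")
    if "response" in df.columns:
        bad = set(df.response.dropna()) - set(RESPONSE_LEVELS)
        if bad:
            raise FormatError(f"unknown response levels {sorted(bad)}")
        df["response"] = pd.Categorical(
            df["response"], categories=RESPONSE_LEVELS, ordered=True
        )
    if "purity" in df.columns:
        p = df.purity.dropna()
        if ((p < 0) | (p > 1)).any():
            raise FormatError("purity outside [0, 1]")
    return df


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")
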