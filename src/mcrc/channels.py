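"""Mutation channel conventions for signature analysis.

Single-base substitutions are tabulated over the 96 trinucleotide-context
channels (6 pyrimidine-centered substitution classes x 16 flanking-base
contexts); doublet substitutions over the 78 collapsed dinucleotide channels.
Both follow the COSMIC v3 conventions: substitutions observed on the purine
strand are reverse-complemented onto the pyrimidine strand, and doublet
ref/alt pairs are collapsed onto a fixed canonical reference-doublet set.
"""

from __future__ import annotations

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# Canonical reference doublets of the 78-channel doublet catalog. The four
# palindromic doublets (AT, CG, GC, TA) are their own reverse complement and
# have their alternate alleles collapsed pairwise.
DBS_CANONICAL_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _sbs96_labels() -> tuple[str, ...]:
    labels = []
    for sub in PYRIMIDINE_SUBS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


def _dbs78_labels() -> tuple[str, ...]:
    labels = []
    for ref in DBS_CANONICAL_REFS:
        alts = [
            a + b
            for a in BASES
            for b in BASES
            if a != ref[0] and b != ref[1]
        ]
        if revcomp(ref) == ref:
            # collapse alt with its reverse complement, keep the smaller
            alts = sorted({min(alt, revcomp(alt)) for alt in alts})
        labels.extend(f"{ref}>{alt}" for alt in alts)
    return tuple(labels)


SBS96_LABELS: tuple[str, ...] = _sbs96_labels()
DBS78_LABELS: tuple[str, ...] = _dbs78_labels()

assert len(SBS96_LABELS) == 96
assert len(DBS78_LABELS) == 78

_SBS_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}
_DBS_INDEX = {lab: i for i, lab in enumerate(DBS78_LABELS)}


def sbs_channel(ref: str, alt: str, context: str) -> str:
    """Return the 96-channel label of an SNV given its reference trinucleotide.

    ``context`` is the reference-strand trinucleotide centered on the mutated
    base; purine-centered substitutions are reverse-complemented.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if any(b not in BASES for b in context):
        raise ValueError(f"non-ACGT context {context!r}")
    if ref in "AG":
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def dbs_channel(ref: str, alt: str) -> str:
    """Return the 78-channel label of a doublet substitution.

    Requires both positions to change (a length-2 MNV with one unchanged base
    is not a doublet event and raises ValueError).
    """
    if len(ref) != 2 or len(alt) != 2:
        raise ValueError("doublet channels require 2-base ref and alt")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise ValueError(f"{ref}>{alt} is not a doublet substitution")
    if ref not in DBS_CANONICAL_REFS:
        ref, alt = revcomp(ref), revcomp(alt)
    if revcomp(ref) == ref:
        alt = min(alt, revcomp(alt))
    return f"{ref}>{alt}"


def sbs_index(label: str) -> int:
    return _SBS_INDEX[label]


def dbs_index(label: str) -> int:
    return _DBS_INDEX[label]


def parse_sbs_label(label: str) -> tuple[str, str, str]:
    """Decompose ``X[R>A]Y`` into (ref, alt, context trinucleotide)."""
    five, rest = label[0], label[2:5]
    ref, alt = rest.split(">")
    three = label[-1]
    return ref, alt, five + ref + three
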