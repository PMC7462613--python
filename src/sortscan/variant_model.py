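"""Core domain types: references, variant keys, and barcode-map construction.

Variant identity is carried by :class:`VariantKey` using 1-based residue
coordinates (codon ``i`` occupies ``coding_sequence[3*(i-1):3*i]``).
Barcode-to-variant maps are built by collapsing reads that share a barcode
into a consensus sequence and calling a single codon change against the
reference; anything else (indels, multi-codon changes, ambiguous consensus,
wild-type-identical sequences) is rejected with an explicit reason.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "MutClass",
    "RejectionReason",
    "ProteinReference",
    "VariantKey",
    "BarcodeRecord",
    "BarcodeMapSummary",
    "call_variant",
    "collapse_barcode_reads",
    "build_barcode_map",
]

STOP = "*"
_DNA = set("ACGT")
_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


class MutClass(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"


class RejectionReason(str, Enum):
    INDEL = "rejected_indel"
    MULTI_AA = "rejected_multi_aa"
    AMBIGUOUS = "rejected_ambiguous"
    WT_IDENTICAL = "rejected_wt_identical"


@dataclass(frozen=True)
class ProteinReference:
    """A coding reference with a designated mutagenized residue interval."""

    name: str
    coding_sequence: str
    mutagenized_range: tuple[int, int] = (2, 163)
    protein_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.coding_sequence.upper()
        object.__setattr__(self, "coding_sequence", seq)
        if len(seq) == 0 or len(seq) % 3 != 0:
            raise ValueError(
                f"coding sequence length {len(seq)} is not a positive multiple of 3"
            )
        if not set(seq) <= _DNA:
            raise ValueError("reference contains non-ACGT characters")
        protein = str(Seq(seq).translate())
        if protein.endswith(STOP):
            protein = protein[:-1]
        if STOP in protein:
            raise ValueError("reference translation contains an internal stop")
        object.__setattr__(self, "protein_sequence", protein)
        lo, hi = self.mutagenized_range
        if not (1 <= lo <= hi <= len(protein)):
            raise ValueError(
                f"mutagenized_range {self.mutagenized_range} outside [1, {len(protein)}]"
            )

    def __len__(self) -> int:
        return len(self.protein_sequence)

    def codon(self, position: int) -> str:
        """Reference codon at 1-based residue ``position``."""
        if not 1 <= position <= len(self.protein_sequence) + 1:
            raise IndexError(f"position {position} out of range")
        return self.coding_sequence[3 * (position - 1) : 3 * position]

    def wt_aa(self, position: int) -> str:
        return self.protein_sequence[position - 1]


@dataclass(frozen=True, order=True)
class VariantKey:
    position: int
    wt_aa: str
    alt_aa: str
    alt_codon: str | None = None
    mut_class: MutClass = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if self.alt_aa == STOP:
            cls = MutClass.NONSENSE
        elif self.alt_aa == self.wt_aa:
            cls = MutClass.SYNONYMOUS
        else:
            cls = MutClass.MISSENSE
        object.__setattr__(self, "mut_class", cls)

    @property
    def token(self) -> str:
        """Compact representation, e.g. ``R98W``, ``W5*``, ``L27L``."""
        return f"{self.wt_aa}{self.position}{self.alt_aa}"

    @classmethod
    def from_token(cls, token: str, alt_codon: str | None = None) -> "VariantKey":
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise ValueError(f"unparseable variant token: {token!r}")
        wt, pos, alt = m.groups()
        return cls(position=int(pos), wt_aa=wt, alt_aa=alt, alt_codon=alt_codon)


@dataclass(frozen=True)
class BarcodeRecord:
    barcode: str
    variant: VariantKey | None
    n_supporting_reads: int
    status: str  # "accepted" or a RejectionReason value

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def call_variant(
    observed: str, reference: ProteinReference
) -> VariantKey | RejectionReason:
    """Call a single-codon variant from a frame-registered coding sequence.

    Returns a :class:`VariantKey` when exactly one codon differs from the
    reference and encodes at most one amino-acid change; otherwise returns
    the applicable :class:`RejectionReason`. Length differences are treated
    as indels; non-ACGT characters in a differing codon make the call
    ambiguous rather than raising.
    """
    observed = observed.upper()
    ref_seq = reference.coding_sequence
    if len(observed) != len(ref_seq):
        return RejectionReason.INDEL
    if observed == ref_seq:
        return RejectionReason.WT_IDENTICAL

    changed = [
        i
        for i in range(len(ref_seq) // 3)
        if observed[3 * i : 3 * i + 3] != ref_seq[3 * i : 3 * i + 3]
    ]
    if len(changed) > 1:
        return RejectionReason.MULTI_AA

    (idx,) = changed
    position = idx + 1
    codon = observed[3 * idx : 3 * idx + 3]
    if not set(codon) <= _DNA:
        return RejectionReason.AMBIGUOUS
    lo, hi = reference.mutagenized_range
    if not lo <= position <= hi:
        # off-target edit outside the mutagenized window: not a library member
        return RejectionReason.AMBIGUOUS
    alt_aa = str(Seq(codon).translate())
    return VariantKey(
        position=position,
        wt_aa=reference.wt_aa(position),
        alt_aa=alt_aa,
        alt_codon=codon,
    )


def collapse_barcode_reads(
    barcode: str,
    reads: Sequence[str],
    reference: ProteinReference,
    min_reads: int = 1,
) -> BarcodeRecord:
    """Collapse reads sharing one barcode to a consensus and call its variant.

    Per-base majority vote; a tie at any base rejects the barcode as
    ambiguous (reproducibility over yield). Fewer than ``min_reads`` reads,
    or reads of unequal length, also reject as ambiguous.
    """
    if not reads:
        raise ValueError("collapse_barcode_reads requires at least one read")
    n = len(reads)
    if len({len(r) for r in reads}) != 1:
        return BarcodeRecord(barcode, None, n, RejectionReason.AMBIGUOUS.value)
    if n < min_reads:
        return BarcodeRecord(barcode, None, n, RejectionReason.AMBIGUOUS.value)

    consensus_chars = []
    for column in zip(*(r.upper() for r in reads)):
        counts = Counter(column).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            return BarcodeRecord(barcode, None, n, RejectionReason.AMBIGUOUS.value)
        consensus_chars.append(counts[0][0])
    consensus = "".join(consensus_chars)

    result = call_variant(consensus, reference)
    if isinstance(result, RejectionReason):
        return BarcodeRecord(barcode, None, n, result.value)
    return BarcodeRecord(barcode, result, n, "accepted")


@dataclass
class BarcodeMapSummary:
    n_input: int = 0
    n_accepted: int = 0
    by_status: dict = field(default_factory=dict)
    by_mut_class: dict = field(default_factory=dict)
    n_conflicting_barcodes: int = 0
    conflicting_barcodes: list = field(default_factory=list)


def build_barcode_map(
    records: Iterable[BarcodeRecord],
) -> tuple[dict[str, VariantKey], BarcodeMapSummary]:
    """Retain accepted records as a barcode->variant map with summary counts.

    A barcode appearing more than once with conflicting variant calls is
    dropped entirely and logged in the summary. Output iteration order is
    lexicographic by barcode.
    """
    records = list(records)
    summary = BarcodeMapSummary(n_input=len(records))
    status_counter: Counter = Counter()
    class_counter: Counter = Counter()

    candidates: dict[str, VariantKey] = {}
    conflicted: set[str] = set()
    for rec in records:
        status_counter[rec.status] += 1
        if not rec.accepted:
            continue
        assert rec.variant is not None
        if rec.barcode in candidates:
            if candidates[rec.barcode] != rec.variant:
                conflicted.add(rec.barcode)
            continue
        candidates[rec.barcode] = rec.variant

    mapping = {
        bc: candidates[bc] for bc in sorted(candidates) if bc not in conflicted
    }
    for variant in mapping.values():
        class_counter[variant.mut_class.value] += 1

    summary.n_accepted = len(mapping)
    summary.by_status = dict(status_counter)
    summary.by_mut_class = dict(class_counter)
    summary.n_conflicting_barcodes = len(conflicted)
    summary.conflicting_barcodes = sorted(conflicted)
    return mapping, summary
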