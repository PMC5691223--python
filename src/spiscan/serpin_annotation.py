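"""Serpin reactive-center-loop (RCL) annotation and P1 specificity.

The serpin hinge (P17-P9) anchors the metastable RCL; the scissile bond
lies between P1 and P1' near the C terminus.  The identity of P1
determines which serine-protease class a serpin inhibits: Arg/Lys point
to trypsin-like proteases, Phe/Tyr/Leu/Ile to chymotrypsin-like
proteases, and Ala/Val to elastase-like enzymes.

RCL localization maps the annotated hinge start and P1 column of a
reference inhibitory serpin onto the query through a deterministic
global pairwise alignment (BLOSUM62, gap open 10 / extend 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, FormatError, ProteinRecord, read_fasta

#: consensus residue classes of the hinge, positions P17..P9
HINGE_CONSENSUS = (
    "ED",      # P17
    "EDGST",   # P16
    "G",       # P15
    "TS",      # P14
    "EKRQ",    # P13
    "AG",      # P12
    "AGS",     # P11
    "AGST",    # P10
    "AGSTV",   # P9
)

#: P1 -> target protease class rules
P1_SPECIFICITY = {
    "R": "trypsin",
    "K": "trypsin",
    "F": "chymotrypsin",
    "Y": "chymotrypsin",
    "L": "chymotrypsin",
    "I": "chymotrypsin",
    "A": "elastase",
    "V": "elastase",
}

#: hinge score at or above which a serpin is called inhibitory
INHIBITORY_HINGE_THRESHOLD = 0.667

#: minimum fraction of reference RCL columns aligned to positively
#: scoring query residues for the RCL to count as mappable
RCL_MIN_COVERAGE = 0.5


class RCLUnmappableError(ValueError):
    """The query cannot support an RCL annotation ("RCL unmappable")."""


@dataclass(frozen=True)
class SerpinReference:
    """A reference serpin with annotated hinge start and P1 position."""

    record: ProteinRecord
    hinge_start: int  # 1-based position of P17
    p1_position: int  # 1-based position of P1

    def __post_init__(self) -> None:
        n = len(self.record.sequence)
        if not 1 <= self.hinge_start <= n or not 1 <= self.p1_position <= n:
            raise FormatError("reference annotations outside sequence bounds")
        if self.p1_position != self.hinge_start + 16:
            raise FormatError("reference P1 must sit 16 residues after the hinge start")


@dataclass(frozen=True)
class SerpinAnnotation:
    """RCL annotation of one serpin domain (spans 1-based inclusive)."""

    label: str
    hinge_span: tuple[int, int] | None
    rcl_span: tuple[int, int] | None
    p1_position: int | None
    p1_residue: str | None
    p1prime_residue: str | None
    hinge_score: float
    specificity: frozenset[str]

    @property
    def inhibitory(self) -> bool:
        return self.hinge_score >= INHIBITORY_HINGE_THRESHOLD


def load_packaged_reference() -> SerpinReference:
    """The packaged synthetic reference serpin with annotated hinge/P1."""
    data = resources.files("spiscan.data")
    with resources.as_file(data / "synthetic_serpin_reference.fasta") as p:
        record = read_fasta(p)[0]
    with resources.as_file(data / "synthetic_serpin_reference.yaml") as p:
        meta = yaml.safe_load(Path(p).read_text())
    return SerpinReference(
        record=record,
        hinge_start=int(meta["hinge_start"]),
        p1_position=int(meta["p1_position"]),
    )


def classify_specificity(p1_residue: str) -> frozenset[str]:
    """Protease classes inhibited given a P1 residue; empty when unknown."""
    if len(p1_residue) != 1 or p1_residue.upper() not in AMINO_ACIDS | {"X"}:
        raise ValueError(f"not an amino-acid residue: {p1_residue!r}")
    cls = P1_SPECIFICITY.get(p1_residue.upper())
    return frozenset([cls]) if cls else frozenset()


def hinge_consensus_score(hinge_seq: str) -> float:
    """Fraction of the 9 hinge positions matching the consensus classes."""
    if len(hinge_seq) != 9:
        raise ValueError(f"hinge must be 9 residues (P17-P9), got {len(hinge_seq)}")
    hinge_seq = hinge_seq.upper()
    return sum(
        1 for aa, allowed in zip(hinge_seq, HINGE_CONSENSUS) if aa in allowed
    ) / 9.0


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def locate_rcl(
    serpin_seq: str, reference: SerpinReference
) -> tuple[tuple[int, int] | None, tuple[int, int] | None, int | None]:
    """Map the reference hinge/RCL/P1 onto a query serpin.

    Returns (hinge_span, rcl_span, p1_position), all 1-based inclusive;
    a field is None ("unresolved") when its reference column aligns to a
    query gap.  Raises RCLUnmappableError when fewer than half of the
    reference RCL columns align to positively scoring query residues —
    the profile of degenerate serpins missing the definitive hinge
    residues.
    """
    serpin_seq = serpin_seq.upper()
    if len(serpin_seq) < 200:
        raise ValueError("serpin sequence shorter than 200 residues")
    aligner = _make_aligner()
    aln = aligner.align(reference.record.sequence, serpin_seq)[0]
    ref_to_query = _column_map(aln)

    matrix = aligner.substitution_matrix
    ref_seq = reference.record.sequence
    rcl_cols = range(reference.hinge_start, reference.p1_position + 2)  # P17..P1'
    supported = 0
    total = 0
    for ref_pos in rcl_cols:
        if ref_pos > len(ref_seq):
            continue
        total += 1
        q = ref_to_query.get(ref_pos)
        if q is None:
            continue
        try:
            score = matrix[ref_seq[ref_pos - 1], serpin_seq[q - 1]]
        except (KeyError, IndexError):
            score = -1
        if score > 0:
            supported += 1
    if total == 0 or supported / total < RCL_MIN_COVERAGE:
        raise RCLUnmappableError(
            f"RCL unmappable: {supported}/{total} reference RCL columns supported"
        )

    hinge_q = ref_to_query.get(reference.hinge_start)
    p1_q = ref_to_query.get(reference.p1_position)
    hinge_span = (hinge_q, hinge_q + 8) if hinge_q is not None else None
    p1_position = p1_q
    rcl_span = None
    if hinge_q is not None and p1_q is not None:
        rcl_span = (hinge_q, min(p1_q + 1, len(serpin_seq)))  # P17..P1'
    return hinge_span, rcl_span, p1_position


def _column_map(alignment) -> dict[int, int]:
    """1-based reference position -> 1-based query position (gaps omitted)."""
    mapping: dict[int, int] = {}
    ref_blocks, query_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, query_blocks):
        for k in range(r1 - r0):
            mapping[int(r0) + k + 1] = int(q0) + k + 1
    return mapping


def annotate_serpin(
    label: str, serpin_seq: str, reference: SerpinReference
) -> SerpinAnnotation:
    """Full RCL annotation of one serpin domain sequence."""
    hinge_span, rcl_span, p1_position = locate_rcl(serpin_seq, reference)
    serpin_seq = serpin_seq.upper()
    hinge_score = 0.0
    if hinge_span is not None and hinge_span[1] <= len(serpin_seq):
        hinge_score = hinge_consensus_score(
            serpin_seq[hinge_span[0] - 1 : hinge_span[1]]
        )
    p1_residue = p1prime = None
    specificity: frozenset[str] = frozenset()
    if p1_position is not None:
        p1_residue = serpin_seq[p1_position - 1]
        if p1_position < len(serpin_seq):
            p1prime = serpin_seq[p1_position]
        specificity = classify_specificity(p1_residue)
    return SerpinAnnotation(
        label=label,
        hinge_span=hinge_span,
        rcl_span=rcl_span,
        p1_position=p1_position,
        p1_residue=p1_residue,
        p1prime_residue=p1prime,
        hinge_score=hinge_score,
        specificity=specificity,
    )
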