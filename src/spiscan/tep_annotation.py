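"""Thioester-containing protein (TEP) feature annotation.

Alpha-2-macroglobulins (A2Ms) and insect TEPs (iTEPs) share a
diagnostic thioester motif (GCGEQ, replaced by DCGEQ in divergent
members) with a catalytic His roughly 100 residues downstream.  A2Ms
additionally carry an FPETW-containing bait region cleaved by the
target protease, and some show an excess-cysteine C-terminal extension.
The motif-level rule cascade here classifies a sequence as A2M, iTEP or
atypical; users with reference TEP sets can refine the call by clade
placement through the phylogenetics module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io_formats import ProteinRecord

THIOESTER_RE = re.compile(r"[GD]CGEQ")
CANONICAL_THIOESTER = "GCGEQ"
BAIT_MOTIF = "FPETW"

#: catalytic His search window, residues downstream of the motif start
HIS_WINDOW = (80, 120)
HIS_EXPECTED_OFFSET = 100

#: C-terminal tail length and Cys-fraction threshold for the cys-rich flag
DEFAULT_TAIL_LEN = 150
CYS_RICH_THRESHOLD = 0.06


@dataclass(frozen=True)
class TEPAnnotation:
    """Motif-level feature profile of one TEP candidate."""

    gene_id: str
    thioester: tuple[int, str] | None
    catalytic_his: int | None
    bait_fpetw: int | None
    cterm_cys_fraction: float
    signal_peptide: bool
    tep_class: str  # A2M | iTEP | atypical | not_tep

    @property
    def canonical_thioester(self) -> bool:
        return self.thioester is not None and self.thioester[1] == CANONICAL_THIOESTER

    @property
    def cys_rich_tail(self) -> bool:
        return self.cterm_cys_fraction >= CYS_RICH_THRESHOLD


def find_thioester_motif(seq: str) -> tuple[int, str] | None:
    """First [GD]CGEQ match (1-based position, motif), canonical first.

    When both GCGEQ and DCGEQ occur, the leftmost canonical GCGEQ wins.
    """
    seq = seq.upper()
    matches = [(m.start() + 1, m.group(0)) for m in THIOESTER_RE.finditer(seq)]
    if not matches:
        return None
    canonical = [m for m in matches if m[1] == CANONICAL_THIOESTER]
    return canonical[0] if canonical else matches[0]


def check_catalytic_his(seq: str, thioester_pos: int) -> int | None:
    """Position of the catalytic His ~100 residues past the thioester.

    Searches [pos+80, pos+120] and returns the His closest to pos+100
    (ties to the smaller position); None when absent or the window falls
    beyond the sequence.
    """
    seq = seq.upper()
    if not 1 <= thioester_pos <= len(seq):
        raise ValueError(f"thioester position {thioester_pos} outside sequence")
    lo = thioester_pos + HIS_WINDOW[0]
    hi = min(thioester_pos + HIS_WINDOW[1], len(seq))
    target = thioester_pos + HIS_EXPECTED_OFFSET
    candidates = [p for p in range(lo, hi + 1) if p <= len(seq) and seq[p - 1] == "H"]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (abs(p - target), p))


def find_bait_region(seq: str) -> int | None:
    """First exact FPETW match (1-based position) or None."""
    idx = seq.upper().find(BAIT_MOTIF)
    return idx + 1 if idx >= 0 else None


def cterm_cys_fraction(seq: str, tail_len: int = DEFAULT_TAIL_LEN) -> float:
    """Fraction of Cys in the last ``tail_len`` residues (whole sequence
    when shorter)."""
    seq = seq.upper()
    tail = seq[-tail_len:] if len(seq) > tail_len else seq
    if not tail:
        raise ValueError("empty sequence")
    return tail.count("C") / len(tail)


def classify_tep(
    thioester: tuple[int, str] | None,
    catalytic_his: int | None,
    bait_fpetw: int | None,
) -> str:
    """Rule cascade: features -> {A2M, iTEP, atypical, not_tep}.

    No thioester -> not_tep; canonical GCGEQ + His + bait -> A2M;
    canonical GCGEQ + His, no bait -> iTEP; variant motif or missing
    His -> atypical.
    """
    if thioester is None:
        return "not_tep"
    canonical = thioester[1] == CANONICAL_THIOESTER
    if canonical and catalytic_his is not None:
        return "A2M" if bait_fpetw is not None else "iTEP"
    return "atypical"


def annotate_tep(protein: ProteinRecord, tail_len: int = DEFAULT_TAIL_LEN) -> TEPAnnotation:
    """Full motif-level TEP annotation of one protein."""
    from .properties_and_reporting import signal_peptide_heuristic

    seq = protein.sequence
    thioester = find_thioester_motif(seq)
    his = check_catalytic_his(seq, thioester[0]) if thioester else None
    bait = find_bait_region(seq)
    return TEPAnnotation(
        gene_id=protein.id,
        thioester=thioester,
        catalytic_his=his,
        bait_fpetw=bait,
        cterm_cys_fraction=cterm_cys_fraction(seq, tail_len),
        signal_peptide=signal_peptide_heuristic(seq),
        tep_class=classify_tep(thioester, his, bait),
    )
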