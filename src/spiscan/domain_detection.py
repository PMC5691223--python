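"""Detection of SPI domains on raw protein sequences.

Canonical-inhibitor families (Kazal, Kunitz/BPTI, Pacifastin, WAP, TIL)
are recognized by their conserved cysteine frameworks: an ordered run of
6, 6, 6, 8 or 10 cysteines whose successive spacings fall inside
family-specific windows.  Serpin domains are recognized by the conserved
small-residue hinge motif at the N-terminal end of the reactive center
loop; alpha-2-macroglobulin (A2M/TEP) candidates by overall length plus
the thioester motif.

The spacing windows are generous pattern-style envelopes chosen by this
package (calibration against real proteomes is a user task); the
synthetic-data generator samples inside the same windows, so detection
tests measure the scanner, not window mis-specification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .io_formats import ProteinRecord

#: number of framework cysteines per canonical family
FRAMEWORK_SIZE = {
    "Kazal": 6,
    "Kunitz_BPTI": 6,
    "Pacifastin": 6,
    "WAP": 8,
    "TIL": 10,
}

#: default inter-cysteine spacing windows, (min_gap, max_gap) residues
#: strictly between successive framework cysteines
DEFAULT_SPACING: dict[str, tuple[tuple[int, int], ...]] = {
    "Kazal": ((1, 12), (4, 12), (1, 14), (4, 16), (6, 30)),
    "Kunitz_BPTI": ((6, 10), (12, 18), (5, 9), (10, 16), (2, 6)),
    "Pacifastin": ((7, 12), (4, 8), (2, 6), (6, 10), (3, 7)),
    "WAP": ((4, 10), (4, 8), (4, 8), (4, 10), (4, 8), (2, 6), (2, 6)),
    "TIL": ((4, 10), (4, 10), (3, 8), (3, 10), (4, 12), (3, 8), (3, 10), (2, 8), (3, 10)),
}

#: residues of flanking context included on each side of a framework hit
DOMAIN_FLANK = 3

#: serpin hinge (P17-P9) motif used for detection
HINGE_REGEX = re.compile(r"[ED].{0,2}G[TS][EKRQ][AG][AGS][AGST][AGSTV]")

#: minimum body length N-terminal of the hinge for a serpin call; a
#: typical mature serpin is 300-400 residues with the hinge in the
#: C-terminal third, so a genuine hinge needs ~200 residues before it
SERPIN_MIN_BODY = 200
SERPIN_WINDOW = (300, 500)
#: minimum separation between hinge motifs of tandem serpin domains
SERPIN_MIN_SEPARATION = 250
#: residues kept C-terminal of the hinge when delimiting a serpin hit
SERPIN_TAIL = 50

#: minimum length for an A2M/TEP candidate
MIN_TEP_LENGTH = 1000


class DetectionError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """One detected SPI domain on a protein (1-based inclusive span)."""

    family: str
    start: int
    end: int
    cys_positions: tuple[int, ...] = ()
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DetectionError(f"bad span {self.start}..{self.end}")
        if list(self.cys_positions) != sorted(set(self.cys_positions)):
            raise DetectionError("cysteine positions must be strictly increasing")


@dataclass(frozen=True)
class SpacingTable:
    """Per-family inter-cysteine spacing windows; configurable."""

    windows: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPACING)
    )

    def __post_init__(self) -> None:
        for family, wins in self.windows.items():
            if family not in FRAMEWORK_SIZE:
                raise DetectionError(f"unknown canonical family {family!r}")
            if len(wins) != FRAMEWORK_SIZE[family] - 1:
                raise DetectionError(
                    f"{family}: need {FRAMEWORK_SIZE[family] - 1} windows, got {len(wins)}"
                )
            for lo, hi in wins:
                if lo < 0 or lo > hi:
                    raise DetectionError(f"{family}: bad window ({lo},{hi})")

    def for_family(self, family: str) -> tuple[tuple[int, int], ...]:
        try:
            return self.windows[family]
        except KeyError:
            raise DetectionError(f"unknown canonical family {family!r}") from None


def _extend_framework(
    cys: list[int], start_idx: int, windows: tuple[tuple[int, int], ...]
) -> list[int] | None:
    """Depth-first completion of a framework starting at cys[start_idx].

    Candidate next cysteines are tried in increasing-gap order, so the
    first complete match is the leftmost-compact one.
    """

    def recurse(chain: list[int], widx: int) -> list[int] | None:
        if widx == len(windows):
            return chain
        lo, hi = windows[widx]
        last = chain[-1]
        candidates = [p for p in cys if last + 1 + lo <= p <= last + 1 + hi]
        for cand in candidates:  # cys sorted => increasing gap order
            result = recurse(chain + [cand], widx + 1)
            if result is not None:
                return result
        return None

    return recurse([cys[start_idx]], 0)


def _window_score(gaps: list[int], windows: tuple[tuple[int, int], ...]) -> float:
    """Centrality of the observed gaps inside their windows, in [0,1]."""
    total = 0.0
    for gap, (lo, hi) in zip(gaps, windows):
        if hi == lo:
            total += 1.0
        else:
            mid = (lo + hi) / 2.0
            half = (hi - lo) / 2.0
            total += max(0.0, 1.0 - abs(gap - mid) / half)
    return total / len(gaps)


def scan_cysteine_framework(
    protein: ProteinRecord, family: str, spacing: SpacingTable | None = None
) -> list[DomainHit]:
    """Find non-overlapping cysteine-framework matches of one family.

    Matching is greedy left to right: from each unconsumed cysteine a
    framework completion is attempted (smaller gaps preferred); on
    success the hit is emitted and scanning resumes after it.  Spans are
    padded by ``DOMAIN_FLANK`` residues, clipped to the sequence.
    """
    spacing = spacing or SpacingTable()
    windows = spacing.for_family(family)
    seq = protein.sequence
    cys = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    hits: list[DomainHit] = []
    i = 0
    while i < len(cys):
        chain = _extend_framework(cys, i, windows)
        if chain is None:
            i += 1
            continue
        gaps = [b - a - 1 for a, b in zip(chain, chain[1:])]
        start = max(1, chain[0] - DOMAIN_FLANK)
        end = min(len(seq), chain[-1] + DOMAIN_FLANK)
        hits.append(
            DomainHit(
                family=family,
                start=start,
                end=end,
                cys_positions=tuple(chain),
                score=_window_score(gaps, windows),
            )
        )
        # resume after the last framework cysteine of this hit
        i = next(k for k, p in enumerate(cys) if p == chain[-1]) + 1
    return hits


def detect_serpin_domain(protein: ProteinRecord) -> list[DomainHit]:
    """Detect serpin domains via the P17-P9 hinge consensus motif.

    A motif occurrence counts as a serpin domain when at least
    ``SERPIN_MIN_BODY`` residues precede it (since the previous accepted
    hit), putting the hinge in the C-terminal third of a plausible
    serpin-length window.  Tandem twin-domain serpins yield one hit per
    motif, at least ``SERPIN_MIN_SEPARATION`` residues apart.
    """
    seq = protein.sequence
    hits: list[DomainHit] = []
    prev_end = 0  # 0-based offset of the end of the previous accepted domain
    prev_motif_start = None
    for m in HINGE_REGEX.finditer(seq):
        motif_start = m.start() + 1  # 1-based
        if motif_start - 1 - prev_end < SERPIN_MIN_BODY:
            continue
        if prev_motif_start is not None and motif_start - prev_motif_start < SERPIN_MIN_SEPARATION:
            continue
        start = max(prev_end + 1, motif_start - (SERPIN_WINDOW[1] - SERPIN_TAIL))
        end = min(len(seq), m.end() + SERPIN_TAIL)
        score = _hinge_match_score(m.group(0))
        hits.append(DomainHit(family="serpin", start=start, end=end, score=score))
        prev_end = end
        prev_motif_start = motif_start
    return hits


def _hinge_match_score(motif: str) -> float:
    """Count of consensus-preferred residues in a matched hinge motif."""
    preferred = set("EDGTSAKRQV")
    return float(sum(1 for aa in motif if aa in preferred))


def detect_a2m_like(protein: ProteinRecord, min_tep_length: int = MIN_TEP_LENGTH) -> list[DomainHit]:
    """One whole-protein A2M hit when long enough and thioester-positive."""
    from .tep_annotation import find_thioester_motif

    if len(protein.sequence) < min_tep_length:
        return []
    if find_thioester_motif(protein.sequence) is None:
        return []
    return [DomainHit(family="A2M", start=1, end=len(protein.sequence))]


def classify_gene(hits: list[DomainHit], gene_id: str = ""):
    """Roll hits on one protein up to a gene-level category.

    Precedence: any A2M hit makes the gene A2M (with a warning flag if
    serpin hits coexist); otherwise any serpin hit makes it serpin;
    otherwise any canonical-family hit makes it canonical; otherwise the
    category is "none".  Permutation-invariant in the hit list.
    """
    from .canonical_annotation import SPIGeneAnnotation

    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.family))
    families = {h.family for h in ordered}
    flags: list[str] = []
    if "A2M" in families:
        category = "A2M"
        if "serpin" in families:
            flags.append("serpin_and_a2m_hits")
    elif "serpin" in families:
        category = "serpin"
    elif families & set(FRAMEWORK_SIZE):
        category = "canonical"
    else:
        category = "none"
    return SPIGeneAnnotation(
        gene_id=gene_id,
        category=category,
        hits=tuple(ordered),
        p1_calls=(),
        specificity_set=frozenset(),
        flags=tuple(flags),
    )


def resolve_canonical_overlaps(hits: list[DomainHit]) -> list[DomainHit]:
    """Drop cross-family canonical hits nested in a better framework.

    The per-family scanners may call overlapping frameworks of
    different families on the same residues — e.g. the 6-cysteine Kazal
    envelope frequently nests inside a genuine 10-cysteine TIL
    framework.  Such a nested call is an artifact of envelope overlap:
    the larger framework (more cysteines), then the higher-scoring one,
    wins; the rest are discarded.
    """
    canonical = [h for h in hits if h.family in FRAMEWORK_SIZE]
    other = [h for h in hits if h.family not in FRAMEWORK_SIZE]
    ranked = sorted(
        canonical, key=lambda h: (-len(h.cys_positions), -h.score, h.start, h.family)
    )
    accepted: list[DomainHit] = []
    for hit in ranked:
        if any(hit.start <= a.end and a.start <= hit.end for a in accepted):
            continue
        accepted.append(hit)
    return sorted(accepted + other, key=lambda h: (h.start, h.end, h.family))


def detect_all(
    protein: ProteinRecord,
    spacing: SpacingTable | None = None,
    min_tep_length: int = MIN_TEP_LENGTH,
) -> list[DomainHit]:
    """Run every family detector on one protein.

    Overlapping canonical hits of different families are resolved by
    ``resolve_canonical_overlaps``.  A2M precedence over coexisting
    serpin/canonical hits is applied by classify_gene's category rule,
    not here; callers that only want the hit list get everything.
    """
    hits: list[DomainHit] = []
    hits.extend(detect_a2m_like(protein, min_tep_length=min_tep_length))
    hits.extend(detect_serpin_domain(protein))
    for family in FRAMEWORK_SIZE:
        hits.extend(scan_cysteine_framework(protein, family, spacing))
    return resolve_canonical_overlaps(hits)
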