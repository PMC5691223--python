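"""Canonical-inhibitor annotation: disulfide connectivity, P1 calls,
and aggregation of per-domain specificities.

Each canonical family stabilizes its binding loop with a fixed disulfide
connectivity among the framework cysteines: three bonds in Kazal (1-5,
2-4, 3-6), Kunitz (1-6, 2-4, 3-5) and Pacifastin (1-4, 2-6, 3-5), four
in WAP (1-6, 2-7, 3-5, 4-8) and five in TIL (1-7, 2-6, 3-5, 4-10, 8-9).
As in serpins, the P1 residue of the exposed binding loop determines
which protease class a canonical domain inhibits.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_detection import FRAMEWORK_SIZE, DomainHit
from .io_formats import ProteinRecord
from .serpin_annotation import classify_specificity

#: framework-index disulfide connectivity per canonical family (1-based
#: indices into the ordered framework cysteines)
DISULFIDE_MAP: dict[str, tuple[tuple[int, int], ...]] = {
    "Kazal": ((1, 5), (2, 4), (3, 6)),
    "Kunitz_BPTI": ((1, 6), (2, 4), (3, 5)),
    "Pacifastin": ((1, 4), (2, 6), (3, 5)),
    "WAP": ((1, 6), (2, 7), (3, 5), (4, 8)),
    "TIL": ((1, 7), (2, 6), (3, 5), (4, 10), (8, 9)),
}

#: P1 call rule per family: (anchor framework-cysteine index, residue offset).
#: The binding loop sits at a fixed offset from an anchor cysteine; these
#: defaults are this package's deterministic rule (alignment-based
#: assignment on real data is a calibration task) and the synthetic
#: generator plants P1 at the same offsets.
P1_ANCHOR: dict[str, tuple[int, int]] = {
    "Kazal": (2, 2),
    "Kunitz_BPTI": (1, 2),
    "Pacifastin": (4, 1),
    "TIL": (5, 2),
    "WAP": (2, 2),
}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class SPIGeneAnnotation:
    """Per-gene roll-up of SPI domain annotation."""

    gene_id: str
    category: str  # serpin | canonical | A2M | none
    hits: tuple[DomainHit, ...]
    p1_calls: tuple  # per canonical domain: (position, residue) or None
    specificity_set: frozenset[str]
    flags: tuple[str, ...] = ()
    mixed_type: bool = False
    accessory: tuple = ()

    @property
    def families(self) -> frozenset[str]:
        return frozenset(h.family for h in self.hits)

    def domain_count(self, family: str) -> int:
        return sum(1 for h in self.hits if h.family == family)


def assign_disulfide_pairs(hit: DomainHit) -> list[tuple[int, int]]:
    """Map a family's framework connectivity onto actual residue positions.

    Returns 3 pairs for Kazal/Kunitz/Pacifastin, 4 for WAP and 5 for TIL.
    """
    if hit.family not in DISULFIDE_MAP:
        raise AnnotationError(f"no disulfide map for family {hit.family!r}")
    expected = FRAMEWORK_SIZE[hit.family]
    if len(hit.cys_positions) != expected:
        raise AnnotationError(
            f"incomplete framework: {hit.family} expects {expected} cysteines, "
            f"found {len(hit.cys_positions)}"
        )
    cys = hit.cys_positions
    return [(cys[a - 1], cys[b - 1]) for a, b in DISULFIDE_MAP[hit.family]]


def call_domain_p1(hit: DomainHit, protein: ProteinRecord) -> tuple[int, str] | None:
    """P1 residue of a canonical domain, or None when unassignable.

    The P1 position is ``anchor cysteine + offset`` per the family rule;
    an offset that leaves the sequence yields None ("unassigned").
    """
    if hit.family not in P1_ANCHOR:
        raise AnnotationError(f"no P1 rule for family {hit.family!r}")
    anchor_idx, offset = P1_ANCHOR[hit.family]
    if len(hit.cys_positions) < anchor_idx:
        return None
    pos = hit.cys_positions[anchor_idx - 1] + offset
    if not 1 <= pos <= len(protein.sequence):
        return None
    return pos, protein.residue(pos)


def aggregate_specificities(p1_calls) -> frozenset[str]:
    """Union of P1-rule specificities over a gene's domains.

    Multi-domain inhibitors carry a variety of P1 residues and can
    therefore inhibit several protease classes at once.  Monotone:
    adding a domain never removes a specificity.
    """
    spec: set[str] = set()
    for call in p1_calls:
        if call is None:
            continue
        residue = call[1] if isinstance(call, tuple) else call
        spec |= classify_specificity(residue)
    return frozenset(spec)


def flag_mixed_type(
    hits: list[DomainHit], accessory: list[tuple[str, tuple[int, int]]] | None = None
) -> tuple[bool, list[tuple[str, tuple[int, int]]], list[str]]:
    """Flag genes mixing SPI domains with non-inhibitor accessory domains.

    ``accessory`` entries are externally supplied (name, (start, end))
    records; they are not detected here.  Returns (mixed, accessory,
    warnings); overlap between accessory and SPI spans is a warning, not
    an error.
    """
    accessory = accessory or []
    warnings: list[str] = []
    mixed = bool(hits) and bool(accessory)
    for name, (a_start, a_end) in accessory:
        for h in hits:
            if a_start <= h.end and h.start <= a_end:
                warnings.append(f"accessory {name} overlaps {h.family} domain")
    return mixed, accessory, warnings


def annotate_canonical_gene(
    gene_id: str,
    protein: ProteinRecord,
    hits: list[DomainHit],
    accessory: list[tuple[str, tuple[int, int]]] | None = None,
) -> SPIGeneAnnotation:
    """Full canonical roll-up for one gene: P1 calls, specificities, flags."""
    canonical_hits = [h for h in hits if h.family in FRAMEWORK_SIZE]
    p1_calls = tuple(call_domain_p1(h, protein) for h in canonical_hits)
    spec = aggregate_specificities(p1_calls)
    mixed, acc, warnings = flag_mixed_type(canonical_hits, accessory)
    return SPIGeneAnnotation(
        gene_id=gene_id,
        category="canonical" if canonical_hits else "none",
        hits=tuple(sorted(canonical_hits, key=lambda h: h.start)),
        p1_calls=p1_calls,
        specificity_set=spec,
        flags=tuple(warnings),
        mixed_type=mixed,
        accessory=tuple(acc),
    )
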