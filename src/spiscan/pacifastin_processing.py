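"""Pacifastin precursor processing at dibasic cleavage sites.

Pacifastin inhibitors are translated as precursors — a signal peptide
followed by several Pacifastin-like domains — and are post-
translationally split into smaller inhibitor peptides at dibasic sites
(RR, RK or KK; KR is not a recognized site here).  Cleavage is modeled
C-terminal of the basic pair, with no residues removed, so product
lengths always sum to the precursor length; a site falling inside a
domain span is suppressed so that no domain is ever bisected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .domain_detection import DomainHit
from .io_formats import ProteinRecord

DIBASIC_MOTIFS = ("RR", "RK", "KK")
_DIBASIC_RE = re.compile(r"(?=(RR|RK|KK))")


@dataclass(frozen=True)
class DibasicSite:
    """A dibasic pair at 1-based positions (position, position+1)."""

    position: int
    motif: str

    def __post_init__(self) -> None:
        if self.motif not in DIBASIC_MOTIFS:
            raise ValueError(f"not a dibasic motif: {self.motif!r}")


@dataclass(frozen=True)
class CleavageProduct:
    """One putative peptide released from a precursor (span 1-based incl.)."""

    parent_id: str
    span: tuple[int, int]
    domains: tuple[DomainHit, ...]

    @property
    def domainless(self) -> bool:
        return not self.domains

    def __len__(self) -> int:
        return self.span[1] - self.span[0] + 1


def find_dibasic_sites(seq: str) -> list[DibasicSite]:
    """All (possibly overlapping) RR/RK/KK occurrences, left to right."""
    seq = seq.upper()
    return [
        DibasicSite(position=m.start() + 1, motif=m.group(1))
        for m in _DIBASIC_RE.finditer(seq)
    ]


def split_precursor(
    protein: ProteinRecord,
    sites: list[DibasicSite],
    domain_hits: list[DomainHit],
) -> list[CleavageProduct]:
    """Split a precursor at usable dibasic sites into tiling products.

    A site is usable when both residues of the pair lie at least one
    residue outside every domain span.  Overlapping usable sites are
    resolved greedily leftmost.  Cleavage occurs C-terminal of the pair;
    each product carries the domains it fully contains, and products
    without any domain are flagged "domainless".
    """
    n = len(protein.sequence)
    for h in domain_hits:
        if h.end > n:
            raise ValueError(
                f"domain hit {h.family} {h.start}..{h.end} outside {protein.id} (len {n})"
            )

    def usable(site: DibasicSite) -> bool:
        lo, hi = site.position, site.position + 1
        for h in domain_hits:
            # suppress any pair within one residue of a domain span
            if hi >= h.start - 1 and lo <= h.end + 1:
                return False
        return True

    cut_points: list[int] = []  # cleave after this 1-based position
    last_cut_pair_end = 0
    for site in sites:
        if not usable(site):
            continue
        if site.position <= last_cut_pair_end:  # overlapping pair already used
            continue
        pair_end = site.position + 1
        if pair_end >= n:  # a cut at the very C terminus releases nothing
            continue
        cut_points.append(pair_end)
        last_cut_pair_end = pair_end

    bounds = [0] + cut_points + [n]
    products: list[CleavageProduct] = []
    for a, b in zip(bounds, bounds[1:]):
        span = (a + 1, b)
        contained = tuple(
            h for h in domain_hits if span[0] <= h.start and h.end <= span[1]
        )
        products.append(
            CleavageProduct(parent_id=protein.id, span=span, domains=contained)
        )
    return products
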