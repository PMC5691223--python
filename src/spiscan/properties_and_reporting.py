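"""Physicochemical properties, inventory summaries and the pipeline.

Molecular weights are average-isotopic sums of residue masses plus one
water; isoelectric points solve Henderson-Hasselbalch net charge = 0 by
bisection with a fixed, documented pKa set.  The signal-peptide check
is an explicitly labelled heuristic (N-terminal hydrophobic core with a
basic n-region), not a trained predictor, and can simply be ignored by
callers that have external predictions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .canonical_annotation import SPIGeneAnnotation, annotate_canonical_gene
from .domain_detection import (
    FRAMEWORK_SIZE,
    MIN_TEP_LENGTH,
    SpacingTable,
    classify_gene,
    detect_all,
)
from .io_formats import (
    GeneInventoryRow,
    ProteinRecord,
    read_fasta,
    write_annotation_tsv,
)

#: average isotopic residue masses (Da)
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01524
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: side-chain and terminal pKa values (Bjellqvist/Expasy-style set)
PKA_POSITIVE = {"n_term": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE = {"c_term": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

#: Kyte-Doolittle hydropathy
KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_MEAN_KD = sum(KD_HYDROPATHY.values()) / len(KD_HYDROPATHY)

SIGNAL_SEARCH_REGION = 30
SIGNAL_STRETCH_LEN = 8
SIGNAL_HYDROPATHY_MIN = 1.6
SIGNAL_EARLY_START = 6


@dataclass(frozen=True)
class ProteinProperties:
    gene_id: str
    mw_da: float
    pi: float
    has_signal_peptide: bool


@dataclass(frozen=True)
class InventorySummary:
    """Pure counting roll-up of a gene inventory."""

    total_genes: int
    category_counts: dict[str, int]
    family_gene_counts: dict[str, int]
    distinct_domain_types: int
    canonical_family_count: int


def molecular_weight(seq: str) -> float:
    """Average-isotopic molecular weight in Da; X uses the mean residue mass."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in seq:
        if aa == "X":
            total += _MEAN_RESIDUE_MASS
        else:
            try:
                total += RESIDUE_MASS[aa]
            except KeyError:
                raise ValueError(f"unknown residue {aa!r}") from None
    return total


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    seq = seq.upper()
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["c_term"] - ph))
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-6) -> float:
    """pH of zero net charge, by bisection over [0, 14]."""
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 6)


def signal_peptide_heuristic(seq: str) -> bool:
    """Heuristic secretion-signal check on the N terminus.

    True iff the first 30 residues contain a hydrophobic stretch of >= 8
    residues with mean Kyte-Doolittle hydropathy > 1.6, preceded by a
    basic residue (K/R) or starting within the first 6 positions.
    Sequences shorter than 15 residues are never called positive.
    """
    seq = seq.upper()
    if len(seq) < 15:
        return False
    limit = min(SIGNAL_SEARCH_REGION, len(seq))
    for s0 in range(0, limit - SIGNAL_STRETCH_LEN + 1):
        window = seq[s0 : s0 + SIGNAL_STRETCH_LEN]
        mean_kd = sum(KD_HYDROPATHY.get(aa, _MEAN_KD) for aa in window) / len(window)
        if mean_kd <= SIGNAL_HYDROPATHY_MIN:
            continue
        if s0 + 1 <= SIGNAL_EARLY_START or any(aa in "KR" for aa in seq[:s0]):
            return True
    return False


def count_summary(rows: list[GeneInventoryRow]) -> InventorySummary:
    """Counting roll-up of an inventory; a dual-family gene counts once
    in the total and once per family in the family counts."""
    genes: dict[str, str] = {}
    family_genes: dict[str, set[str]] = {}
    for row in rows:
        genes.setdefault(row.gene_id, row.category)
        family_genes.setdefault(row.family, set()).add(row.gene_id)
    category_counts: dict[str, int] = {}
    for category in genes.values():
        category_counts[category] = category_counts.get(category, 0) + 1
    family_gene_counts = {fam: len(ids) for fam, ids in sorted(family_genes.items())}
    canonical_families = {
        fam for fam in family_genes if fam in FRAMEWORK_SIZE
    }
    return InventorySummary(
        total_genes=len(genes),
        category_counts=category_counts,
        family_gene_counts=family_gene_counts,
        distinct_domain_types=len(family_genes),
        canonical_family_count=len(canonical_families),
    )


def annotate_proteome(
    records: list[ProteinRecord],
    spacing: SpacingTable | None = None,
    min_tep_length: int = MIN_TEP_LENGTH,
) -> list[SPIGeneAnnotation]:
    """Detect and roll up SPI domains for every protein."""
    annotations: list[SPIGeneAnnotation] = []
    for record in records:
        hits = detect_all(record, spacing=spacing, min_tep_length=min_tep_length)
        rollup = classify_gene(hits, gene_id=record.id)
        if rollup.category == "canonical":
            ann = annotate_canonical_gene(record.id, record, list(rollup.hits))
        else:
            ann = rollup
        annotations.append(ann)
    return annotations


def run_pipeline(
    fasta_path: str | Path,
    out_annotation: str | Path | None = None,
    out_summary: str | Path | None = None,
    config: dict | None = None,
) -> tuple[list[SPIGeneAnnotation], dict]:
    """End-to-end annotation of a protein FASTA.

    Deterministic given input and config; the summary carries the
    package version, a config hash, and per-stage counts.
    """
    config = config or {}
    spacing = SpacingTable(config["spacing"]) if "spacing" in config else None
    min_tep = int(config.get("min_tep_length", MIN_TEP_LENGTH))
    records = read_fasta(fasta_path)
    annotations = annotate_proteome(records, spacing=spacing, min_tep_length=min_tep)

    categories: dict[str, int] = {}
    families: dict[str, int] = {}
    for ann in annotations:
        categories[ann.category] = categories.get(ann.category, 0) + 1
        for fam in ann.families:
            families[fam] = families.get(fam, 0) + 1
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    summary = {
        "spiscan_version": __version__,
        "config_hash": config_hash,
        "n_proteins": len(records),
        "categories": dict(sorted(categories.items())),
        "families": dict(sorted(families.items())),
        "n_domain_hits": sum(len(a.hits) for a in annotations),
    }
    if out_annotation is not None:
        write_annotation_tsv(annotations, out_annotation)
    if out_summary is not None:
        Path(out_summary).write_text(json.dumps(summary, indent=2) + "\n")
    return annotations, summary
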