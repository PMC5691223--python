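"""Readers and writers for the external formats the pipeline touches.

Covers protein FASTA (unaligned and aligned), the packaged SPI gene
inventory table, tab-separated annotation output, and newick trees with
bootstrap supports as internal-node labels.  All residue coordinates in
this package are 1-based and inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in sequences; X marks an unknown residue
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}

SPI_FAMILIES = ("serpin", "Kazal", "Pacifastin", "TIL", "Kunitz_BPTI", "WAP", "A2M")
CANONICAL_FAMILIES = ("Kazal", "Pacifastin", "TIL", "Kunitz_BPTI", "WAP")

#: gene-level category implied by each domain family
CATEGORY_BY_FAMILY = {
    "serpin": "serpin",
    "A2M": "A2M",
    **{fam: "canonical" for fam in CANONICAL_FAMILIES},
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence; residues are indexed 1-based."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-amino-acid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside 1..{len(self.sequence)}")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class GeneInventoryRow:
    """One (gene, family) entry of the SPI gene inventory.

    A gene appears in more than one row only when it carries domains of
    more than one family (e.g. a Kunitz/WAP mosaic gene).
    """

    gene_id: str
    family: str
    domain_count: int
    category: str

    def __post_init__(self) -> None:
        if self.family not in SPI_FAMILIES:
            raise FormatError(f"unknown SPI family {self.family!r}")
        if self.domain_count < 1:
            raise FormatError(
                f"{self.gene_id}: domain_count must be positive, got {self.domain_count}"
            )
        expected = CATEGORY_BY_FAMILY[self.family]
        if self.category != expected:
            raise FormatError(
                f"{self.gene_id}: family {self.family} implies category "
                f"{expected!r}, row says {self.category!r}"
            )


@dataclass(frozen=True)
class AlignedBlock:
    """A multiple alignment: equal-length gapped protein sequences."""

    records: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least two sequences")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)


# AlignedBlock rows bypass the ProteinRecord gap check by carrying '-' in
# an extended alphabet; construct them through read_aligned_fasta.


@dataclass(frozen=True)
class _GappedRecord(ProteinRecord):
    def __post_init__(self) -> None:  # allow '-' columns
        if not self.id:
            raise FormatError("protein record requires a non-empty id")
        bad = set(self.sequence) - SEQUENCE_ALPHABET - {"-"}
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-alignment characters: {sorted(bad)}"
            )


def _normalize_sequence(raw: str, record_id: str, allow_gaps: bool) -> str:
    seq = str(raw).upper().replace("*", "")
    if not allow_gaps and "-" in seq:
        raise FormatError(f"record {record_id!r} contains gap characters")
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read unaligned protein FASTA.

    Sequences are uppercased and '*' stop characters stripped; record
    order is preserved.  Duplicate ids and gap characters are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id, allow_gaps=False)
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_aligned_fasta(path: str | Path) -> AlignedBlock:
    """Read a pre-aligned protein FASTA block ('-' gaps allowed)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id, allow_gaps=True)
        records.append(_GappedRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return AlignedBlock(records=tuple(records))


def make_aligned_block(items: Iterable[tuple[str, str]]) -> AlignedBlock:
    """Build an AlignedBlock from (id, gapped-sequence) pairs."""
    return AlignedBlock(
        records=tuple(_GappedRecord(id=i, sequence=s.upper()) for i, s in items)
    )


def read_inventory(path: str | Path) -> list[GeneInventoryRow]:
    """Read a gene inventory TSV (columns gene_id, family, domain_count, category)."""
    rows: list[GeneInventoryRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "family", "domain_count", "category"]
        if header != expected:
            raise FormatError(f"inventory header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            gene_id, family, count_str, category = parts
            try:
                count = int(count_str)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: bad domain_count {count_str!r}"
                ) from exc
            rows.append(
                GeneInventoryRow(
                    gene_id=gene_id, family=family, domain_count=count, category=category
                )
            )
    return rows


def load_packaged_inventory() -> list[GeneInventoryRow]:
    """The packaged *Pteromalus puparum* SPI gene inventory (57 genes, 58 rows)."""
    ref = resources.files("spiscan.data") / "pp_spi_inventory.tsv"
    with resources.as_file(ref) as path:
        return read_inventory(path)


_ANNOTATION_COLUMNS = [
    "gene_id",
    "category",
    "families",
    "domain_spans",
    "p1_calls",
    "specificity",
    "flags",
]


def write_annotation_tsv(annotations: Sequence, path: str | Path) -> None:
    """Write per-gene SPI annotations as a TSV, one row per gene.

    Rows are ordered by gene_id for determinism; all coordinates are
    1-based inclusive (stated in the file header).
    """
    lines = ["# coordinates are 1-based inclusive", "\t".join(_ANNOTATION_COLUMNS)]
    for ann in sorted(annotations, key=lambda a: a.gene_id):
        families = ",".join(sorted(ann.families))
        spans = ",".join(f"{h.family}:{h.start}-{h.end}" for h in ann.hits)
        p1 = ",".join(
            "unassigned" if call is None else f"{call[1]}@{call[0]}"
            for call in ann.p1_calls
        )
        spec = ",".join(sorted(ann.specificity_set))
        flags = ";".join(ann.flags)
        lines.append(
            "\t".join([ann.gene_id, ann.category, families, spans, p1, spec, flags])
        )
    Path(path).write_text("\n".join(lines) + "\n")


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize a tree as newick.

    Branch lengths are written to 6 decimals; bootstrap supports, when
    present as integer internal-node labels, are preserved.  Taxon labels
    containing newick metacharacters are quoted.
    """
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    ).strip()
    Path(path).write_text(text + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree, interpreting internal node labels as supports."""
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
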