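"""Ground-truthed synthetic inputs for every pipeline stage.

The study's genome, transcriptomes and qPCR tables are not publicly
deposited, so tests run against generated stand-ins whose structure
mirrors the real inputs: proteomes with planted SPI domains in
family-correct cysteine frameworks (single-domain, tandem repeats up to
11 copies, a mixed Kunitz/WAP mosaic), serpins with planted hinge/P1,
Pacifastin precursors with dibasic linkers, TEP-like sequences with
thioester/His/bait grammars, FPKM matrices with planted venom-specific
genes, and Ct tables with planted fold changes.

Every generator is deterministic given its seed.  Planted domains are
sampled strictly inside the detection spacing windows and
rejection-sampled so that no *other* family's envelope matches them,
and decoys are rejection-sampled to contain no detectable SPI signal at
all; recovery tests therefore measure the scanner, not window
mis-specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canonical_annotation import P1_ANCHOR
from .domain_detection import (
    DEFAULT_SPACING,
    FRAMEWORK_SIZE,
    SpacingTable,
    detect_all,
    detect_serpin_domain,
    scan_cysteine_framework,
)
from .io_formats import ProteinRecord

_AA_NO_C = "ADEFGHIKLMNPQRSTVWY"
_AA_ALL = "ACDEFGHIKLMNPQRSTVWY"

#: hinge (P17-P9) planted into synthetic serpins; scores 1.0 on the consensus
PLANTED_HINGE = "EEGTEAAAA"
#: signal-peptide-like N-terminus satisfying the package's heuristic
SIGNAL_PREFIX = "MKLLLLLLLLLA"

#: minimum linker between planted domains; exceeds every spacing-window
#: maximum so no framework chain can span two domains
MIN_LINKER = 32


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class ProteomeConfig:
    """Study-shaped defaults: 60 canonical domains over 5 families in
    single/tandem/mosaic architectures, 6 serpin genes (one twin-domain),
    3 TEP genes and 200 low-cysteine decoys."""

    n_decoys: int = 200
    decoy_length: tuple[int, int] = (150, 500)
    cys_freq: float = 0.02
    canonical_architectures: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "Kazal": (1, 1, 3, 8, 11),
            "Pacifastin": (1, 2, 7),
            "TIL": (1, 1, 1, 1, 1),
            "Kunitz_BPTI": (1, 3, 9),
            "WAP": (1, 1, 2, 1),
        }
    )
    mixed_architectures: tuple[tuple[tuple[str, int], ...], ...] = (
        (("Kunitz_BPTI", 2), ("WAP", 1)),
    )
    n_serpins: int = 5
    n_twin_serpins: int = 1
    tep_classes: tuple[str, ...] = ("A2M", "iTEP", "atypical")
    p1_choices: str = "RKFYLIAVGS"


def _background(rng: np.random.Generator, length: int, alphabet: str = _AA_NO_C) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _decoy_sequence(rng: np.random.Generator, length: int, cys_freq: float) -> str:
    out = []
    for _ in range(length):
        if rng.random() < cys_freq:
            out.append("C")
        else:
            out.append(_AA_NO_C[rng.integers(len(_AA_NO_C))])
    return "".join(out)


def _sample_domain(
    rng: np.random.Generator, family: str, p1_residue: str, max_attempts: int = 2000
) -> tuple[str, tuple[int, ...], int]:
    """One planted domain: (sequence, cys offsets 1-based, P1 offset).

    Gaps are sampled inside the family's spacing windows and rejected
    until the cysteine run matches no *same-size* rival family pattern
    (checked with the scanner itself).  Smaller frameworks nested in a
    larger one are unavoidable envelope overlap and are handled by
    detection-time overlap resolution instead.
    """
    windows = DEFAULT_SPACING[family]
    anchor_idx, p1_offset = P1_ANCHOR[family]
    size = FRAMEWORK_SIZE[family]
    other_families = [
        f for f in FRAMEWORK_SIZE if f != family and FRAMEWORK_SIZE[f] == size
    ]
    for _ in range(max_attempts):
        gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in windows]
        cys_offsets = [1]
        for g in gaps:
            cys_offsets.append(cys_offsets[-1] + g + 1)
        length = cys_offsets[-1]
        seq = list(_background(rng, length))
        for pos in cys_offsets:
            seq[pos - 1] = "C"
        p1_pos = cys_offsets[anchor_idx - 1] + p1_offset
        seq[p1_pos - 1] = p1_residue
        domain = "".join(seq)
        # embed in neutral context so flank padding cannot alias families
        probe = ProteinRecord(id="probe", sequence="A" * MIN_LINKER + domain + "A" * MIN_LINKER)
        if any(scan_cysteine_framework(probe, f2) for f2 in other_families):
            continue
        return domain, tuple(cys_offsets), p1_pos
    raise GeneratorError(f"could not sample a cross-family-clean {family} domain")


def _build_canonical_gene(
    rng: np.random.Generator,
    gene_id: str,
    segments: tuple[tuple[str, int], ...],
    p1_choices: str,
) -> tuple[str, list[dict]]:
    """Assemble flank + domains + linkers; returns (sequence, truth rows)."""
    parts: list[str] = [_background(rng, int(rng.integers(MIN_LINKER, MIN_LINKER + 14)))]
    offset = len(parts[0])
    truth: list[dict] = []
    first = True
    for family, count in segments:
        for _ in range(count):
            if not first:
                linker = _background(rng, int(rng.integers(MIN_LINKER, MIN_LINKER + 14)))
                parts.append(linker)
                offset += len(linker)
            first = False
            p1_residue = p1_choices[rng.integers(len(p1_choices))]
            domain, cys_offsets, p1_off = _sample_domain(rng, family, p1_residue)
            truth.append(
                {
                    "gene_id": gene_id,
                    "family": family,
                    "category": "canonical",
                    "start": offset + 1,
                    "end": offset + len(domain),
                    "cys_positions": ";".join(str(offset + c) for c in cys_offsets),
                    "p1_position": offset + p1_off,
                    "p1_residue": p1_residue,
                }
            )
            parts.append(domain)
            offset += len(domain)
    parts.append(_background(rng, int(rng.integers(MIN_LINKER, MIN_LINKER + 14))))
    return "".join(parts), truth


#: seed of the deterministic serpin domain template all synthetic
#: serpins (and the packaged reference) derive from
_SERPIN_TEMPLATE_SEED = 20170
#: per-site substitution probability of synthetic serpins vs the template
SERPIN_DIVERGENCE = 0.3
_serpin_template_cache: str | None = None


def _serpin_template() -> str:
    """387-residue serpin domain: hinge at 280-288, P1 'R' at 296."""
    global _serpin_template_cache
    if _serpin_template_cache is None:
        rng = np.random.default_rng(_SERPIN_TEMPLATE_SEED)
        body = _background(rng, 279)
        rcl = PLANTED_HINGE + _background(rng, 7) + "R" + "S"
        tail = _background(rng, 90)
        _serpin_template_cache = body + rcl + tail
    return _serpin_template_cache


def _build_serpin_gene(
    rng: np.random.Generator, gene_id: str, n_domains: int, p1_choices: str
) -> tuple[str, list[dict]]:
    """Serpin gene: diverged copy of the template, hinge kept intact.

    Each domain is the template with substitutions at rate
    ``SERPIN_DIVERGENCE`` outside the hinge and P1' positions (no
    indels), emulating homologous serpins around a conserved reactive
    center loop.
    """
    rule_residues = "".join(c for c in p1_choices if c in "RKFYLIAV") or "RKFYLIAV"
    template = _serpin_template()
    hinge_region = set(range(279, 288))  # 0-based hinge P17..P9
    p1prime_idx = 296
    truth: list[dict] = []
    parts: list[str] = []
    offset = 0
    for d in range(n_domains):
        domain = list(template)
        for i in range(len(domain)):
            if i in hinge_region or i == p1prime_idx:
                continue
            if rng.random() < SERPIN_DIVERGENCE:
                domain[i] = _AA_NO_C[rng.integers(len(_AA_NO_C))]
        p1_residue = rule_residues[rng.integers(len(rule_residues))]
        domain[295] = p1_residue  # 0-based P1
        motif_start = offset + 280
        truth.append(
            {
                "gene_id": gene_id,
                "family": "serpin",
                "category": "serpin",
                "start": offset + 1,
                "end": offset + len(domain),
                "cys_positions": "",
                "p1_position": motif_start + 16,
                "p1_residue": p1_residue,
            }
        )
        parts.append("".join(domain))
        offset += len(domain)
    return "".join(parts), truth


def _scrub(seq: list[str], lo: int, hi: int, residues: str, rng: np.random.Generator) -> None:
    """Replace unwanted residues in seq[lo:hi] (0-based, exclusive)."""
    for i in range(max(lo, 0), min(hi, len(seq))):
        if seq[i] in residues:
            seq[i] = "Q"


def _build_tep_gene(
    rng: np.random.Generator, gene_id: str, tep_class: str, length: int = 1400
) -> tuple[str, list[dict]]:
    """TEP gene with the class's feature grammar planted.

    A2M: GCGEQ + catalytic His + FPETW bait + cysteine-rich tail;
    iTEP: GCGEQ + His, no bait; atypical: DCGEQ with the His site
    substituted.
    """
    if tep_class not in ("A2M", "iTEP", "atypical"):
        raise GeneratorError(f"unknown TEP class {tep_class!r}")
    if length < 1000:
        raise GeneratorError("TEP sequences must be at least 1000 residues")
    seq = list(SIGNAL_PREFIX + _background(rng, length - len(SIGNAL_PREFIX)))
    motif_pos = 300  # 1-based start of the thioester motif
    motif = "GCGEQ" if tep_class in ("A2M", "iTEP") else "DCGEQ"
    seq[motif_pos - 1 : motif_pos + 4] = list(motif)
    # control the His window [motif+80, motif+120] exactly
    _scrub(seq, motif_pos + 79, motif_pos + 120, "H", rng)
    his_site = motif_pos + 100 - 1
    seq[his_site] = "H" if tep_class in ("A2M", "iTEP") else "D"
    bait_pos = 700
    if tep_class == "A2M":
        seq[bait_pos - 1 : bait_pos + 4] = list("FPETW")
        # cysteine-rich C-terminal extension: three CCC clusters whose
        # spacing (0 within, ~47 between) fits no canonical framework
        tail_start = length - 150
        for cluster in (10, 60, 110):
            for k in range(3):
                seq[tail_start + cluster + k] = "C"
    else:
        # make sure no accidental bait motif exists
        text = "".join(seq)
        while "FPETW" in text:
            seq[text.index("FPETW")] = "Q"
            text = "".join(seq)
    truth = [
        {
            "gene_id": gene_id,
            "family": "A2M",
            "category": "A2M",
            "start": 1,
            "end": length,
            "cys_positions": "",
            "p1_position": None,
            "p1_residue": None,
            "tep_class": tep_class,
        }
    ]
    return "".join(seq), truth


def _gene_detection_matches_truth(seq: str, gene_id: str, truth_rows: list[dict]) -> bool:
    """Final gene-level check: detection reproduces exactly the plants."""
    record = ProteinRecord(id=gene_id, sequence=seq)
    hits = detect_all(record)
    expected_canonical = {
        (row["family"], row["cys_positions"])
        for row in truth_rows
        if row["family"] in FRAMEWORK_SIZE
    }
    got_canonical = {
        (h.family, ";".join(str(p) for p in h.cys_positions))
        for h in hits
        if h.family in FRAMEWORK_SIZE
    }
    if expected_canonical != got_canonical:
        return False
    n_serpin_expected = sum(1 for row in truth_rows if row["family"] == "serpin")
    serpin_hits = [h for h in hits if h.family == "serpin"]
    if len(serpin_hits) != n_serpin_expected:
        return False
    for row in truth_rows:
        if row["family"] == "serpin":
            motif_start = row["p1_position"] - 16
            if not any(h.start <= motif_start <= h.end for h in serpin_hits):
                return False
    n_a2m_expected = sum(1 for row in truth_rows if row["family"] == "A2M")
    if sum(1 for h in hits if h.family == "A2M") != n_a2m_expected:
        return False
    if n_a2m_expected == 0 and any(h.family == "A2M" for h in hits):
        return False
    return True


def _build_until_clean(builder, rng, gene_id, *args, max_attempts: int = 50):
    for _ in range(max_attempts):
        seq, truth = builder(rng, gene_id, *args)
        if _gene_detection_matches_truth(seq, gene_id, truth):
            return seq, truth
    raise GeneratorError(f"could not build a detection-clean gene {gene_id}")


def generate_proteome(
    seed: int, config: ProteomeConfig | None = None
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Synthetic proteome with planted SPI genes and clean decoys.

    Returns (records, truth) where truth has one row per planted domain
    (gene_id, family, category, span, cysteine positions, planted P1)
    plus one category row per decoy.
    """
    cfg = config or ProteomeConfig()
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []

    for s in range(cfg.n_serpins):
        gene_id = f"SERPIN{s + 1}"
        seq, truth = _build_until_clean(_build_serpin_gene, rng, gene_id, 1, cfg.p1_choices)
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        truth_rows.extend(truth)
    for s in range(cfg.n_twin_serpins):
        gene_id = f"SERPINTWIN{s + 1}"
        seq, truth = _build_until_clean(_build_serpin_gene, rng, gene_id, 2, cfg.p1_choices)
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        truth_rows.extend(truth)

    for family, architectures in cfg.canonical_architectures.items():
        for g, n_domains in enumerate(architectures):
            gene_id = f"{family.upper()}{g + 1}"
            seq, truth = _build_until_clean(
                _build_canonical_gene, rng, gene_id, ((family, n_domains),), cfg.p1_choices
            )
            records.append(ProteinRecord(id=gene_id, sequence=seq))
            truth_rows.extend(truth)
    for g, segments in enumerate(cfg.mixed_architectures):
        gene_id = f"MIXED{g + 1}"
        seq, truth = _build_until_clean(
            _build_canonical_gene, rng, gene_id, tuple(segments), cfg.p1_choices
        )
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        truth_rows.extend(truth)

    for t, tep_class in enumerate(cfg.tep_classes):
        gene_id = f"TEP{t + 1}"
        seq, truth = _build_until_clean(_build_tep_gene, rng, gene_id, tep_class)
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        truth_rows.extend(truth)

    for d in range(cfg.n_decoys):
        gene_id = f"DECOY{d + 1}"
        length = int(rng.integers(cfg.decoy_length[0], cfg.decoy_length[1] + 1))
        for _ in range(200):
            seq = _decoy_sequence(rng, length, cfg.cys_freq)
            if not detect_all(ProteinRecord(id=gene_id, sequence=seq)):
                break
        else:
            raise GeneratorError(f"could not build a hit-free decoy {gene_id}")
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        truth_rows.append(
            {
                "gene_id": gene_id,
                "family": "",
                "category": "none",
                "start": None,
                "end": None,
                "cys_positions": "",
                "p1_position": None,
                "p1_residue": None,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth


def evaluate_detection(
    records: list[ProteinRecord], truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-family precision/recall of detection against generator truth.

    Canonical hits match on exact (gene, family, framework cysteines);
    serpin hits match a planted hinge they cover; A2M hits match per
    gene.  Returns a table with columns family, tp, fp, fn, precision,
    recall.
    """
    hits_by_gene = {r.id: detect_all(r) for r in records}
    families = list(FRAMEWORK_SIZE) + ["serpin", "A2M"]
    rows = []
    for family in families:
        tp = fp = fn = 0
        for record in records:
            gene_truth = truth[
                (truth["gene_id"] == record.id) & (truth["family"] == family)
            ]
            hits = [h for h in hits_by_gene[record.id] if h.family == family]
            if family in FRAMEWORK_SIZE:
                expected = set(gene_truth["cys_positions"])
                got = {";".join(str(p) for p in h.cys_positions) for h in hits}
                tp += len(expected & got)
                fp += len(got - expected)
                fn += len(expected - got)
            elif family == "serpin":
                motifs = [int(p) - 16 for p in gene_truth["p1_position"].dropna()]
                unmatched_hits = list(hits)
                for motif in motifs:
                    covering = [h for h in unmatched_hits if h.start <= motif <= h.end]
                    if covering:
                        unmatched_hits.remove(covering[0])
                        tp += 1
                    else:
                        fn += 1
                fp += len(unmatched_hits)
            else:  # A2M: per-gene presence
                expected_n = len(gene_truth)
                got_n = len(hits)
                tp += min(expected_n, got_n)
                fp += max(0, got_n - expected_n)
                fn += max(0, expected_n - got_n)
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / (tp + fn) if (tp + fn) else 1.0
        rows.append(
            {"family": family, "tp": tp, "fp": fp, "fn": fn,
             "precision": precision, "recall": recall}
        )
    return pd.DataFrame(rows)


def generate_pacifastin_precursors(
    seed: int, domain_counts: tuple[int, ...] = (1, 2, 3, 5)
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Pacifastin precursors: signal + k domains joined by dibasic linkers.

    Each linker carries exactly one RR/RK/KK site, so a k-domain
    precursor splits into exactly k products, one intact domain each.
    Truth lists expected product spans.
    """
    rng = np.random.default_rng(seed)
    linker_alphabet = "ADEFGHILMNPQSTVWY"  # no C (frameworks) and no R/K (sites)
    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    for g, k in enumerate(domain_counts):
        if k < 1:
            raise GeneratorError("domain count must be >= 1")
        gene_id = f"PACIPRE{g + 1}"
        parts = [SIGNAL_PREFIX + _background(rng, 20, linker_alphabet)]
        offset = len(parts[0])
        cuts: list[int] = []
        domain_spans: list[tuple[int, int]] = []
        for d in range(k):
            if d > 0:
                # half-linkers exceed every spacing-window maximum so no
                # framework chain can span two domains
                half = MIN_LINKER // 2 + 1
                motif = ("RR", "RK", "KK")[rng.integers(3)]
                linker = (
                    _background(rng, half, linker_alphabet)
                    + motif
                    + _background(rng, half, linker_alphabet)
                )
                cuts.append(offset + half + 2)  # after the dibasic pair
                parts.append(linker)
                offset += len(linker)
            domain, cys_offsets, _ = _sample_domain(rng, "Pacifastin", "R")
            domain_spans.append((offset + 1, offset + len(domain)))
            parts.append(domain)
            offset += len(domain)
        parts.append(_background(rng, 20, linker_alphabet))
        offset += 20
        seq = "".join(parts)
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        bounds = [0] + cuts + [len(seq)]
        for p, (a, b) in enumerate(zip(bounds, bounds[1:])):
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "product_index": p + 1,
                    "product_start": a + 1,
                    "product_end": b,
                    "n_domains": 1,
                    "domain_start": domain_spans[p][0],
                    "domain_end": domain_spans[p][1],
                }
            )
    return records, pd.DataFrame(truth_rows)


def generate_tep_sequences(
    seed: int, classes: tuple[str, ...] = ("A2M", "iTEP", "atypical")
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """One TEP-like sequence per requested class, with class truth."""
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for t, tep_class in enumerate(classes):
        gene_id = f"TEP{t + 1}"
        seq, truth = _build_until_clean(_build_tep_gene, rng, gene_id, tep_class)
        records.append(ProteinRecord(id=gene_id, sequence=seq))
        rows.append({"gene_id": gene_id, "tep_class": tep_class})
    return records, pd.DataFrame(rows)


EXPRESSION_SAMPLES = (
    "embryo", "larva", "pupa_female", "pupa_male", "adult_female",
    "adult_male", "ovary", "venom_gland", "carcass",
)


def generate_expression(
    seed: int,
    n_genes: int = 100,
    n_venom: int = 8,
    n_near_miss_per_gate: int = 3,
    n_pseudogenes: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix with planted venom-specific genes and near-misses.

    Venom-specific genes clear every gate with margin (FPKM_VG >= 20,
    >= 4x enrichment); near-miss genes sit just outside one gate;
    pseudogenes never exceed 1 FPKM; background genes have venom-gland
    values tied to carcass so the enrichment gate always fails.  Under
    the binomial stand-in test an abundant, enriched gene is always
    significant, so the "p-gate" near-miss necessarily fails the ratio
    gate too; truth records the failed gates per gene.
    """
    rng = np.random.default_rng(seed)
    roles: list[tuple[str, str]] = []
    for i in range(n_venom):
        roles.append((f"VENOM{i + 1}", "venom_specific"))
    for gate in ("vg", "ratio", "p"):
        for i in range(n_near_miss_per_gate):
            roles.append((f"NEARMISS_{gate.upper()}{i + 1}", f"near_miss_{gate}"))
    for i in range(n_pseudogenes):
        roles.append((f"PSEUDO{i + 1}", "pseudogene"))
    n_background = n_genes - len(roles)
    if n_background < 0:
        raise GeneratorError("n_genes too small for the planted classes")
    for i in range(n_background):
        roles.append((f"BG{i + 1}", "background"))

    data: dict[str, dict[str, float]] = {}
    truth_rows = []
    for gene, role in roles:
        base = float(10.0 ** rng.normal(1.5, 1.0))
        values = {
            s: float(base * 10.0 ** rng.normal(0.0, 0.15)) for s in EXPRESSION_SAMPLES
        }
        if role == "venom_specific":
            car = float(rng.uniform(0.5, 5.0))
            vg = max(20.0, car * float(rng.uniform(4.0, 40.0)))
            gates_failed = ""
        elif role == "near_miss_vg":
            car = float(rng.uniform(0.1, 0.5))
            vg = float(rng.uniform(8.0, 9.8))
            gates_failed = "vg"
        elif role == "near_miss_ratio":
            car = float(rng.uniform(150.0, 180.0))
            vg = car * float(rng.uniform(1.6, 1.9))
            gates_failed = "ratio"
        elif role == "near_miss_p":
            vg = float(rng.uniform(11.0, 13.0))
            car = vg * float(rng.uniform(0.85, 0.95))
            gates_failed = "p;ratio"
        elif role == "pseudogene":
            values = {s: float(rng.uniform(0.0, 0.8)) for s in EXPRESSION_SAMPLES}
            vg = values["venom_gland"]
            car = values["carcass"]
            gates_failed = "p;ratio;vg"
        else:  # background: enrichment gate always fails
            car = values["carcass"]
            vg = car * float(rng.uniform(0.3, 1.6))
            gates_failed = "ratio"
        values["venom_gland"] = vg
        values["carcass"] = car
        data[gene] = values
        truth_rows.append(
            {
                "gene_id": gene,
                "role": role,
                "passes": role == "venom_specific",
                "gates_failed": gates_failed,
            }
        )
    mat = pd.DataFrame.from_dict(data, orient="index")[list(EXPRESSION_SAMPLES)]
    mat.index.name = "gene_id"
    return mat, pd.DataFrame(truth_rows)


CT_SAMPLES = ("gut", "fat_body", "ovary", "venom_gland", "carcass")
REFERENCE_GENE = "Pp18S"


def generate_ct(
    seed: int,
    n_genes: int = 8,
    samples: tuple[str, ...] = CT_SAMPLES,
    calibrator: str = "carcass",
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    fold_log2_range: tuple[float, float] = (-3.0, 3.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table with planted fold changes.

    Ct_target = base - log2(fold) + N(0, sd) per replicate; the
    reference gene is flat across samples up to the same noise.  The
    calibrator sample's true fold is 1.  Truth holds the planted fold
    per (gene, sample).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for s in samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "gene": REFERENCE_GENE,
                    "sample": s,
                    "replicate": rep,
                    "ct": float(15.0 + rng.normal(0.0, noise_sd)),
                }
            )
    for g in range(n_genes):
        gene = f"GENE{g + 1}"
        base = float(rng.uniform(20.0, 28.0))
        for s in samples:
            fold = (
                1.0
                if s == calibrator
                else float(2.0 ** rng.uniform(*fold_log2_range))
            )
            truth_rows.append({"gene": gene, "sample": s, "true_fold": fold})
            for rep in range(1, n_replicates + 1):
                ct = base - np.log2(fold) + rng.normal(0.0, noise_sd)
                rows.append(
                    {"gene": gene, "sample": s, "replicate": rep, "ct": float(ct)}
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def build_reference_serpin() -> tuple[ProteinRecord, int, int]:
    """Deterministic synthetic reference serpin for RCL mapping.

    Returns (record, hinge_start, p1_position): the undiverged serpin
    template itself.  The packaged fixture in ``spiscan/data`` was
    frozen from this builder.
    """
    seq = _serpin_template()
    if not _gene_detection_matches_truth(
        seq,
        "SYNREF_SERPIN",
        [{"family": "serpin", "p1_position": 296, "cys_positions": ""}],
    ):
        raise GeneratorError("serpin template failed its own detection check")
    return (
        ProteinRecord(
            id="SYNREF_SERPIN",
            sequence=seq,
            description="synthetic reference serpin (generated fixture)",
        ),
        280,
        296,
    )


def generate_two_cluster_alignment(
    seed: int,
    n_per_cluster: int = 2,
    n_columns: int = 200,
    divergence: float = 0.5,
) -> "AlignedBlock":
    """Alignment with two internally identical, well-separated clusters.

    Every bootstrap resample preserves the central split, so its
    support is 100%.
    """
    from .io_formats import make_aligned_block

    rng = np.random.default_rng(seed)
    base_a = _background(rng, n_columns, _AA_ALL)
    base_b = list(base_a)
    n_mut = int(round(divergence * n_columns))
    for c in rng.choice(n_columns, size=n_mut, replace=False):
        choices = [aa for aa in _AA_ALL if aa != base_a[c]]
        base_b[c] = choices[rng.integers(len(choices))]
    base_b = "".join(base_b)
    items = [(f"A{i + 1}", base_a) for i in range(n_per_cluster)]
    items += [(f"B{i + 1}", base_b) for i in range(n_per_cluster)]
    return make_aligned_block(items)


def random_additive_matrix(
    seed: int, n_taxa: int = 6, length_range: tuple[float, float] = (0.1, 1.0)
):
    """Random unrooted binary tree and its exact path-length matrix.

    Returns (tree, DistanceMatrix); NJ on the matrix must recover the
    tree's topology.
    """
    import dendropy

    from .phylogenetics import DistanceMatrix, tree_path_lengths

    if n_taxa < 4:
        raise GeneratorError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        node.edge.length = float(rng.uniform(*length_range))
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(*length_range))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    center = dendropy.Node()
    for node in nodes:
        center.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    dm = tree_path_lengths(tree)
    return tree, dm
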