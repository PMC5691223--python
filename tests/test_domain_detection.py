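import numpy as np
import pytest

from spiscan.domain_detection import (
    DEFAULT_SPACING,
    FRAMEWORK_SIZE,
    DetectionError,
    SpacingTable,
    classify_gene,
    detect_a2m_like,
    detect_serpin_domain,
    scan_cysteine_framework,
)
from spiscan.io_formats import ProteinRecord
from spiscan.synthetic_data import generate_proteome


def _plant(family: str, gaps, lead=50, trail=50) -> tuple[str, list[int]]:
    """Sequence with one framework planted after `lead` A residues."""
    positions = [lead + 1]
    for g in gaps:
        positions.append(positions[-1] + g + 1)
    length = positions[-1] + trail
    seq = ["A"] * length
    for p in positions:
        seq[p - 1] = "C"
    return "".join(seq), positions


class TestFrameworkScan:
    def test_planted_kazal_recovered(self):
        seq, cys = _plant("Kazal", [3, 6, 5, 8, 10])
        hits = scan_cysteine_framework(ProteinRecord(id="p", sequence=seq), "Kazal")
        assert len(hits) == 1
        assert list(hits[0].cys_positions) == cys
        assert hits[0].start == cys[0] - 3 and hits[0].end == cys[-1] + 3

    def test_no_cysteines_no_hits(self):
        record = ProteinRecord(id="p", sequence="A" * 200)
        assert scan_cysteine_framework(record, "Kazal") == []

    def test_tandem_domains_nonoverlapping_in_order(self):
        seq1, cys1 = _plant("Kazal", [3, 6, 5, 8, 10], lead=40, trail=40)
        seq2, cys2 = _plant("Kazal", [2, 7, 4, 9, 12], lead=0, trail=40)
        seq = seq1 + seq2
        hits = scan_cysteine_framework(ProteinRecord(id="p", sequence=seq), "Kazal")
        assert len(hits) == 2
        assert hits[0].end < hits[1].start
        assert list(hits[1].cys_positions) == [c + len(seq1) for c in cys2]

    @pytest.mark.parametrize("family", sorted(FRAMEWORK_SIZE))
    def test_framework_size_respected(self, family):
        gaps = [lo for lo, hi in DEFAULT_SPACING[family]]
        seq, cys = _plant(family, gaps)
        hits = scan_cysteine_framework(ProteinRecord(id="p", sequence=seq), family)
        assert len(hits) == 1
        assert len(hits[0].cys_positions) == FRAMEWORK_SIZE[family]

    def test_gap_outside_window_not_matched(self):
        # final Kazal gap window is (6, 30); a gap of 31 must not match
        seq, _ = _plant("Kazal", [3, 6, 5, 8, 31])
        assert scan_cysteine_framework(ProteinRecord(id="p", sequence=seq), "Kazal") == []

    def test_unknown_family_is_error(self):
        record = ProteinRecord(id="p", sequence="ACCA")
        with pytest.raises(DetectionError, match="unknown"):
            scan_cysteine_framework(record, "Serpina")

    def test_bad_spacing_table_rejected(self):
        with pytest.raises(DetectionError):
            SpacingTable({"Kazal": ((1, 2),)})


class TestSerpinDetection:
    def test_planted_hinge_detected(self):
        seq = "A" * 280 + "EEGTEAAAA" + "A" * 100
        hits = detect_serpin_domain(ProteinRecord(id="p", sequence=seq))
        assert len(hits) == 1
        assert hits[0].start <= 281 <= hits[0].end

    def test_twin_domains_give_two_hits(self):
        domain = "A" * 279 + "EEGTEAAAA" + "A" * 99
        hits = detect_serpin_domain(ProteinRecord(id="p", sequence=domain * 2))
        assert len(hits) == 2

    def test_poly_a_has_no_hits(self):
        assert detect_serpin_domain(ProteinRecord(id="p", sequence="A" * 400)) == []

    def test_hinge_without_nterminal_body_rejected(self):
        seq = "A" * 50 + "EEGTEAAAA" + "A" * 300
        assert detect_serpin_domain(ProteinRecord(id="p", sequence=seq)) == []


class TestA2MDetection:
    def test_long_protein_with_thioester_hit(self):
        seq = "A" * 500 + "GCGEQ" + "A" * 900
        hits = detect_a2m_like(ProteinRecord(id="p", sequence=seq))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, len(seq))

    def test_short_protein_gated_out(self):
        seq = "A" * 100 + "GCGEQ" + "A" * 195
        assert detect_a2m_like(ProteinRecord(id="p", sequence=seq)) == []

    def test_long_protein_without_motif(self):
        assert detect_a2m_like(ProteinRecord(id="p", sequence="A" * 1400)) == []


class TestClassifyGene:
    def test_serpin_category(self):
        seq = "A" * 280 + "EEGTEAAAA" + "A" * 100
        hits = detect_serpin_domain(ProteinRecord(id="p", sequence=seq))
        assert classify_gene(hits).category == "serpin"

    def test_multidomain_canonical_counts(self):
        seq1, _ = _plant("Kazal", [3, 6, 5, 8, 10], lead=40, trail=40)
        hits = scan_cysteine_framework(
            ProteinRecord(id="p", sequence=seq1 * 11), "Kazal"
        )
        ann = classify_gene(hits)
        assert ann.category == "canonical"
        assert ann.domain_count("Kazal") == 11

    def test_empty_hits_category_none(self):
        assert classify_gene([]).category == "none"

    def test_permutation_invariant(self, proteome):
        records, _ = proteome
        rng = np.random.default_rng(0)
        from spiscan.domain_detection import detect_all

        for record in records[:20]:
            hits = detect_all(record)
            if len(hits) < 2:
                continue
            shuffled = list(hits)
            rng.shuffle(shuffled)
            a = classify_gene(hits, gene_id=record.id)
            b = classify_gene(shuffled, gene_id=record.id)
            assert a == b


def test_hits_stay_in_bounds_and_never_overlap_within_family(proteome):
    records, _ = proteome
    from spiscan.domain_detection import detect_all

    for record in records:
        by_family = {}
        for h in detect_all(record):
            assert 1 <= h.start <= h.end <= len(record.sequence)
            by_family.setdefault(h.family, []).append(h)
        for hits in by_family.values():
            hits.sort(key=lambda h: h.start)
            for a, b in zip(hits, hits[1:]):
                assert a.end < b.start
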