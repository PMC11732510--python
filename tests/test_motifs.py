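import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicscan.io import ProteinRecord
from mimicscan.motifs import (
    FootprintMotif,
    MotifMatch,
    build_motifs,
    dedup_ligands,
    enumerate_cores,
    parse_pattern,
    scan_motifs,
    truncate_window,
)
from oracles import brute_motif_scan

MOG = "MEVGWYRSPFSRVVHLYRNGK"
P3 = "TTLSFYRPPFLRVRRPFYIIF"
SCRAMBLED = "KGNRYLHVVRSFPSRYWGVEM"


class TestBuildMotifs:
    def test_five_motifs_with_full_pattern_first(self, motif_set):
        assert len(motif_set) == 5
        assert motif_set[0].pattern_string == "YR..F.RV."

    def test_each_variant_relaxes_exactly_one_tcr_contact(self, motif_set):
        full = motif_set[0].required
        for variant in motif_set[1:]:
            dropped = set(full) - set(variant.required)
            assert len(dropped) == 1 and dropped != {0}
            assert all(variant.required[k] == full[k] for k in variant.required)

    def test_relaxing_the_f_contact(self, motif_set):
        by_pattern = {m.pattern_string: m for m in motif_set}
        assert by_pattern["YR....RV."].required == {0: "Y", 1: "R", 6: "R", 7: "V"}

    def test_anchor_never_relaxed(self, motif_set):
        assert all(m.required[0] == "Y" for m in motif_set)

    def test_missing_anchor_rejected(self, epitope):
        from mimicscan.analog import EpitopeQuery

        bad = EpitopeQuery("no_anchor", MOG, {6: "R", 9: "F"}, 6)
        # anchor exists here, but a motif without offset 0 must be rejected
        with pytest.raises(ValueError):
            FootprintMotif("x", {1: "R"})
        assert build_motifs(bad)  # anchor at 6 rebases to offset 0: fine

    def test_literal_pattern_parsing(self):
        m = parse_pattern("[YR..F.RV.]")
        assert m.required == {0: "Y", 1: "R", 4: "F", 6: "R", 7: "V"}
        with pytest.raises(ValueError):
            parse_pattern("YR..F.R.")  # 8 positions


class TestScanMotifs:
    def test_mog_matches_full_motif_at_5(self, motif_set):
        matches = scan_motifs(MOG, motif_set)
        full = [m for m in matches if m.motif_id == "YR..F.RV."]
        assert len(full) == 1
        assert full[0].start == 5 and full[0].matched_9mer == "YRSPFSRVV"

    def test_p3_matches_full_motif_at_5(self, motif_set):
        full = [m for m in scan_motifs(P3, motif_set) if m.motif_id == "YR..F.RV."]
        assert len(full) == 1
        assert full[0].start == 5 and full[0].matched_9mer == "YRPPFLRVR"

    def test_scrambled_peptide_matches_nothing(self, motif_set):
        assert scan_motifs(SCRAMBLED, motif_set) == []

    def test_full_motif_site_matches_all_five(self, motif_set):
        matches = scan_motifs(MOG, motif_set)
        assert {m.motif_id for m in matches if m.start == 5} == {
            m.motif_id for m in motif_set
        }

    def test_x_never_satisfies_required_position(self, motif_set):
        seq = MOG[:5] + "X" + MOG[6:]  # anchor Y -> X
        assert scan_motifs(seq, motif_set) == []

    def test_empty_sequence(self, motif_set):
        assert scan_motifs("", motif_set) == []

    def test_overlapping_matches_all_reported(self, motif_set):
        seq = "YRAAFARVYRAAFARVA"  # second full site overlaps first frame end
        got = {(m.start, m.motif_id) for m in scan_motifs(seq, motif_set)}
        assert got == brute_motif_scan(seq, motif_set)

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", max_size=60))
    def test_engine_equals_brute_force_oracle(self, motif_set, seq):
        got = {(m.start, m.motif_id) for m in scan_motifs(seq, motif_set)}
        assert got == brute_motif_scan(seq, motif_set)


def _match(start, motif_id="YR..F.RV.", seq_id="p"):
    return MotifMatch(seq_id, motif_id, start, "")


class TestTruncateWindow:
    def test_embedded_epitope_reproduces_its_own_window(self, motif_set):
        parent = ProteinRecord("p", "AAAAA" + MOG + "AAAAA", "g")
        w = truncate_window(parent, _match(10))
        assert w.sequence == MOG and w.anchor_index == 5
        assert w.parent_start == 5

    def test_left_clamp(self):
        parent = ProteinRecord("p", "AG" + "YRAAFARVA" + "C" * 30, "g")
        w = truncate_window(parent, _match(2))
        assert w.parent_start == 0 and w.anchor_index == 2
        assert len(w.sequence) == 21

    def test_exact_21mer_parent_is_identity(self):
        parent = ProteinRecord("p", MOG, "g")
        w = truncate_window(parent, _match(5))
        assert w.sequence == MOG and w.anchor_index == 5

    def test_right_clip_shortens_window(self):
        parent = ProteinRecord("p", "AAAAA" + "YRAAFARVA", "g")  # len 14
        w = truncate_window(parent, _match(5))
        assert w.sequence == parent.sequence and len(w) == 14

    def test_rescan_finds_motif_at_anchor_index(self, motif_set):
        parent = ProteinRecord("p", "GGGGGGG" + "YRAAFARVA" + "GGGGG", "g")
        w = truncate_window(parent, _match(7))
        rescans = scan_motifs(w.sequence, motif_set)
        assert any(m.start == w.anchor_index for m in rescans)

    def test_match_outside_parent_rejected(self):
        parent = ProteinRecord("p", MOG, "g")
        with pytest.raises(ValueError):
            truncate_window(parent, _match(15))


def _window(seq, parent="p", start=0, motif="YR..F.RV.", genome="g"):
    from mimicscan.motifs import LigandWindow

    return LigandWindow(seq, parent, start, motif, 5, genome)


class TestDedupLigands:
    def test_identical_windows_collapse_with_sources(self):
        reps = dedup_ligands([
            _window(MOG, parent="a", genome="g1"),
            _window(MOG, parent="b", genome="g2"),
        ])
        assert len(reps) == 1
        assert reps[0].multiplicity == 2
        assert {s[3] for s in reps[0].sources} == {"g1", "g2"}

    def test_single_residue_difference_kept_separate(self):
        reps = dedup_ligands([_window(MOG), _window(MOG[:-1] + "A")])
        assert len(reps) == 2

    def test_count_equals_distinct_strings(self):
        rng = random.Random(0)
        pool = ["".join(rng.choices("ACDEFG", k=21)) for _ in range(40)]
        windows = [_window(rng.choice(pool)) for _ in range(500)]
        reps = dedup_ligands(windows)
        assert len(reps) == len({w.sequence for w in windows})
        assert sum(r.multiplicity for r in reps) == 500

    def test_idempotent(self):
        windows = [_window(MOG), _window(MOG), _window(P3)]
        once = dedup_ligands(windows)
        twice = dedup_ligands(once)
        assert [(w.sequence, w.multiplicity) for w in once] == [
            (w.sequence, w.multiplicity) for w in twice
        ]

    def test_first_encountered_is_representative(self):
        reps = dedup_ligands([
            _window(MOG, parent="first"), _window(MOG, parent="second"),
        ])
        assert reps[0].parent_id == "first"


class TestEnumerateCores:
    def test_21mer_yields_11_candidates(self):
        lig = _window("ABCDEFGHIKLMNPQRSTVWY")
        lig.ligand_id = "lig_0"
        cands = enumerate_cores(lig)
        assert len(cands) == 11
        assert cands[0].window11 == "ABCDEFGHIKL"
        assert cands[0].core9 == "BCDEFGHIK"

    @pytest.mark.parametrize("L", range(11, 31))
    def test_count_formula_L_minus_10(self, L):
        seq = ("ACDEFGHIKLMNPQRSTVWY" * 2)[:L]
        lig = _window(seq)
        assert len(enumerate_cores(lig)) == L - 10

    def test_11mer_yields_itself(self):
        lig = _window("ACDEFGHIKLM")
        cands = enumerate_cores(lig)
        assert len(cands) == 1 and cands[0].window11 == "ACDEFGHIKLM"

    def test_10mer_yields_nothing(self):
        assert enumerate_cores(_window("ACDEFGHIKL")) == []

    def test_windows_are_verbatim_substrings(self):
        lig = _window(MOG)
        for c in enumerate_cores(lig):
            assert MOG[c.start_in_ligand:c.start_in_ligand + 11] == c.window11

    def test_duplicate_11mers_within_ligand_collapse(self):
        lig = _window("A" * 21)
        assert len(enumerate_cores(lig)) == 1

    def test_x_windows_excluded(self):
        lig = _window("ACDEFXHIKLMNPQRSTVWYA")
        cands = enumerate_cores(lig)
        assert all("X" not in c.window11 for c in cands)
        assert len(cands) < 11
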