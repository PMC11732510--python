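import numpy as np
import pandas as pd
import pytest

from mimicscan.io import TaxonAssignment
from mimicscan.motifs import CoreCandidate, LigandWindow, MotifMatch
from mimicscan.profiling import (
    group_logos_by_start,
    phylum_profile,
    position_frequency_matrix,
    prioritize,
)
from mimicscan.triage import BinderCall

FULL = "YR..F.RV."


def _tax(genome, phylum, species=""):
    lineage = f"d__Bacteria;p__{phylum}"
    if species:
        lineage += f";c__;o__;f__;g__;s__{species}"
    return TaxonAssignment.from_lineage(genome, lineage)


def _match(genome, motif=FULL):
    return MotifMatch("seq", motif, 0, "YRAAFARVA", genome_id=genome)


class TestPhylumProfile:
    def test_rate_is_analogs_per_genome(self):
        taxonomy = [_tax(f"g{i}", "A") for i in range(4)]
        # a 4-genome phylum pools into Others under the default min of 10
        prof = phylum_profile([_match("g0"), _match("g1")], taxonomy)
        row = prof[prof.phylum == "Others"].iloc[0]
        assert row.analog_count == 2 and row.genome_count == 4
        assert row.rate == pytest.approx(0.5)

    def test_named_phylum_keeps_its_own_row(self):
        taxonomy = [_tax(f"g{i}", "Big") for i in range(12)]
        prof = phylum_profile([_match("g3")], taxonomy)
        assert list(prof.phylum) == ["Big"]
        assert prof.iloc[0].genome_count == 12

    def test_nine_genome_phylum_folds_into_others(self):
        taxonomy = [_tax(f"g{i}", "Small") for i in range(9)]
        prof = phylum_profile([_match("g0")], taxonomy)
        assert "Small" not in set(prof.phylum)
        assert set(prof.phylum) == {"Others"}

    def test_unclassified_contig_counts_in_others(self):
        taxonomy = [_tax(f"g{i}", "Big") for i in range(12)]
        taxonomy.append(TaxonAssignment.from_lineage("contig1", "d__Bacteria"))
        prof = phylum_profile([_match("contig1")], taxonomy)
        assert set(prof.phylum) == {"Others"}

    def test_genome_missing_from_table_goes_to_others(self):
        taxonomy = [_tax(f"g{i}", "Big") for i in range(12)]
        prof = phylum_profile([_match("unknown_genome")], taxonomy)
        assert set(prof.phylum) == {"Others"}

    def test_counts_conserved_under_pooling(self):
        rng = np.random.default_rng(1)
        taxonomy = (
            [_tax(f"a{i}", "Alpha") for i in range(15)]
            + [_tax(f"b{i}", "Beta") for i in range(11)]
            + [_tax(f"c{i}", "Gamma") for i in range(3)]
        )
        genomes = [t.genome_id for t in taxonomy]
        motifs_ids = [FULL, "Y...F.RV.", "YR....RV."]
        matches = [
            _match(genomes[rng.integers(len(genomes))],
                   motifs_ids[rng.integers(3)])
            for _ in range(200)
        ]
        prof = phylum_profile(matches, taxonomy)
        assert prof.analog_count.sum() == 200
        genome_sum = prof.groupby("phylum").genome_count.first().sum()
        assert genome_sum == 15 + 11 + 3
        # rate * genome_count reconstructs the analog count
        recon = (prof.rate * prof.genome_count).round(9)
        assert (recon == prof.analog_count).all()


def _cand(window11, cid="c", lig="lig_0"):
    return CoreCandidate(cid, window11, window11[1:10], lig, 0)


class TestPositionFrequencyMatrix:
    def test_two_copies_give_one_hot_columns(self):
        pfm = position_frequency_matrix(
            [_cand("AYRSPFSRVVA", "c1"), _cand("AYRSPFSRVVA", "c2")]
        )
        assert pfm["loc_0"]["A"] == 1.0
        assert (pfm.max(axis=0) == 1.0).all()

    def test_hand_counted_split(self):
        pfm = position_frequency_matrix(
            [_cand("AYRSPFSRVVA"), _cand("GYRSPFSRVVG")]
        )
        core = "YRSPFSRVV"
        for j, aa in enumerate(core, start=1):
            assert pfm[f"loc_{j}"][aa] == 1.0
        assert pfm["loc_0"]["A"] == pytest.approx(0.5)
        assert pfm["loc_0"]["G"] == pytest.approx(0.5)
        assert pfm["loc_10"]["A"] == pytest.approx(0.5)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        cands = [
            _cand("".join(rng.choice(aas, 11)), f"c{i}") for i in range(50)
        ]
        pfm = position_frequency_matrix(cands)
        assert np.allclose(pfm.sum(axis=0), 1.0, atol=1e-9)
        assert pfm.attrs["n_sequences"] == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])


class TestGroupLogos:
    def test_groups_keyed_by_first_core_residue(self):
        groups = group_logos_by_start(
            [_cand("AYRSPFSRVVA", "c1"), _cand("ALRSPFSRVVA", "c2")]
        )
        assert set(groups) == {"Y", "L"}

    def test_single_group_when_all_share_start(self):
        groups = group_logos_by_start(
            [_cand("AYRSPFSRVVA", "c1"), _cand("GYRAPFSRVVG", "c2")]
        )
        assert set(groups) == {"Y"}
        assert groups["Y"].attrs["n_sequences"] == 2

    def test_partition_and_weighted_mean_reconstructs_global(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        cands = [
            _cand("".join(rng.choice(aas, 11)), f"c{i}") for i in range(80)
        ]
        groups = group_logos_by_start(cands)
        sizes = sum(g.attrs["n_sequences"] for g in groups.values())
        assert sizes == len(cands)
        global_pfm = position_frequency_matrix(cands)
        weighted = sum(
            g * g.attrs["n_sequences"] for g in groups.values()
        ) / len(cands)
        assert np.allclose(weighted.values, global_pfm.values, atol=1e-12)


def _ligand(seq, lid, motif=FULL, genome="g0", sources=None):
    w = LigandWindow(seq, "p", 0, motif, 5, genome)
    w.ligand_id = lid
    w.sources = sources or [("p", 0, motif, genome)]
    return w


class TestPrioritize:
    P3 = "TTLSFYRPPFLRVRRPFYIIF"

    def _setup(self):
        taxonomy = [
            _tax("g0", "Verrucomicrobiota", "Akkermansia muciniphila"),
            _tax("g1", "Bacillota", "Bacillota sp0001"),
        ]
        ligands = [
            _ligand(self.P3, "lig_0", FULL, "g0"),
            _ligand("A" * 21, "lig_1", "Y...F.RV.", "g1"),
        ]
        calls = [BinderCall("lig_0:05", True, 95, 3)]
        cands = [CoreCandidate("lig_0:05", self.P3[5:16], self.P3[6:15],
                               "lig_0", 5)]
        return ligands, calls, cands, taxonomy

    def test_p3_like_ligand_satisfies_criteria(self):
        ligands, calls, cands, taxonomy = self._setup()
        df = prioritize(
            ligands, calls, cands, taxonomy,
            cohort_ids={self.P3},
            flagged_species={"Akkermansia muciniphila"},
        )
        top = df.iloc[0]
        assert top.ligand_id == "lig_0"
        assert bool(top.has_canonical_motif) and bool(top.species_flagged)
        assert bool(top.in_metagenome_cohort)
        # the binder core RPPFLRVRR starts with R, not F/L
        assert not top.noncanonical_start
        assert top.n_criteria == 3

    def test_relaxed_motif_not_canonical(self):
        ligands, calls, cands, taxonomy = self._setup()
        df = prioritize(ligands, calls, cands, taxonomy)
        row = df[df.ligand_id == "lig_1"].iloc[0]
        assert not row.has_canonical_motif

    def test_noncanonical_start_from_binder_core(self):
        taxonomy = [_tax("g0", "Bacillota")]
        seq = "AAAAA" + "LRAAFARVA" + "AAAAAAA"
        lig = _ligand(seq, "lig_0", FULL, "g0")
        cand = CoreCandidate("lig_0:04", seq[4:15], seq[5:14], "lig_0", 4)
        call = BinderCall("lig_0:04", True, 95, 3)
        df = prioritize([lig], [call], [cand], taxonomy)
        assert bool(df.iloc[0].noncanonical_start)  # core starts with L

    def test_empty_flag_sets_leave_criteria_false(self):
        ligands, calls, cands, taxonomy = self._setup()
        df = prioritize(ligands, calls, cands, taxonomy)
        assert not df.in_metagenome_cohort.any()
        assert not df.species_flagged.any()

    def test_sorted_by_criteria_then_id(self):
        ligands, calls, cands, taxonomy = self._setup()
        df = prioritize(
            ligands, calls, cands, taxonomy, cohort_ids={self.P3},
            flagged_species={"Akkermansia muciniphila"},
        )
        assert list(df.n_criteria) == sorted(df.n_criteria, reverse=True)

    def test_deterministic(self):
        ligands, calls, cands, taxonomy = self._setup()
        a = prioritize(ligands, calls, cands, taxonomy, cohort_ids={self.P3})
        b = prioritize(ligands, calls, cands, taxonomy, cohort_ids={self.P3})
        pd.testing.assert_frame_equal(a, b)
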