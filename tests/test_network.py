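"""Network construction, reduction, and synthesis-column tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chondroflux as cf
from chondroflux.network import NetworkParseError, RESIDUE_PRECURSORS

from .oracles import tally_precursors


class TestParsing:
    def test_simple_equation_column(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "metabolite_id\tname\trole\tmeasurable\tetc_member\n"
            "A\ta\texternal\t0\t0\nB\tb\tinternal\t1\t0\n")
        (tmp_path / "r.tsv").write_text(
            "reaction_id\tpathway\treversible\tequation\nR1\tG\t0\tA -> B\n")
        net = cf.parse_network(tmp_path / "r.tsv", tmp_path / "m.tsv")
        assert net.S.tolist() == [[-1.0], [1.0]]
        assert net.reactions[0].reversible is False

    def test_stoichiometric_coefficients_parsed(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "metabolite_id\tname\trole\tmeasurable\tetc_member\n"
            "NADH\t-\tinternal\t1\t0\nO2\t-\texternal\t0\t0\nNAD\t-\tinternal\t1\t0\n")
        (tmp_path / "r.tsv").write_text(
            "reaction_id\tpathway\treversible\tequation\n"
            "R1\tETC\t0\t2 NADH + O2 -> 2 NAD\n")
        net = cf.parse_network(tmp_path / "r.tsv", tmp_path / "m.tsv")
        assert net.S[:, 0].tolist() == [-2.0, -1.0, 2.0]

    def test_unknown_metabolite_names_line(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "metabolite_id\tname\trole\tmeasurable\tetc_member\nA\ta\tinternal\t1\t0\n")
        (tmp_path / "r.tsv").write_text(
            "reaction_id\tpathway\treversible\tequation\nR1\tG\t0\tA -> ZZZ\n")
        with pytest.raises(NetworkParseError, match="ZZZ"):
            cf.parse_network(tmp_path / "r.tsv", tmp_path / "m.tsv")

    def test_duplicate_reaction_id_rejected(self, toy_chain):
        with pytest.raises(ValueError, match="duplicate"):
            cf.StoichiometricNetwork(toy_chain.metabolites,
                                     [toy_chain.reactions[0], toy_chain.reactions[0]])

    def test_roundtrip_parse_write_parse(self, full_net, tmp_path):
        cf.write_network(full_net, tmp_path / "r.tsv", tmp_path / "m.tsv")
        again = cf.parse_network(tmp_path / "r.tsv", tmp_path / "m.tsv")
        assert again.metabolite_ids == full_net.metabolite_ids
        assert again.reaction_ids == full_net.reaction_ids
        np.testing.assert_array_equal(again.S, full_net.S)
        assert [r.reversible for r in again.reactions] == \
               [r.reversible for r in full_net.reactions]


class TestPackagedNetwork:
    def test_full_dimensions(self, full_net):
        assert full_net.S.shape == (52, 38)

    def test_pathway_groups_present(self, full_net):
        assert {r.pathway for r in full_net.reactions} == \
               {"G", "PYP", "TCA", "PPP", "ETC", "AP", "LDH", "GDH"}

    def test_etc_reactions_touch_etc_carriers(self, full_net):
        carriers = {m.id for m in full_net.metabolites if m.etc_member}
        for r in full_net.reactions:
            if r.pathway == "ETC":
                assert carriers & set(r.stoichiometry)

    def test_internal_columns_have_both_signs(self, full_net):
        # mass cannot appear from nothing inside a pathway
        for r in full_net.reactions:
            coeffs = list(r.stoichiometry.values())
            assert min(coeffs) < 0 and max(coeffs) > 0

    def test_matrix_matches_reaction_lists(self, full_net):
        S = full_net.S
        row = {m: i for i, m in enumerate(full_net.metabolite_ids)}
        for j, r in enumerate(full_net.reactions):
            col = dict(zip(full_net.metabolite_ids, S[:, j]))
            for met, coef in r.stoichiometry.items():
                assert col[met] == coef
            assert sum(v != 0 for v in S[:, j]) == len(r.stoichiometry)


class TestReduction:
    def test_paper_shaped_reduction(self, reduced_net):
        S = reduced_net.S
        assert S.shape == (48, 39)
        assert np.linalg.matrix_rank(S) == 39

    def test_unmeasured_internal_rows_kept_and_flagged(self, full_net):
        red = cf.reduce_to_measured(full_net, cf.packaged_measured_ids())
        flags = {m.id: m.constrained_zero for m in red.metabolites}
        assert flags["BPG"] and flags["6PGL"]
        assert all(flags[m.id] for m in red.metabolites if m.etc_member)
        assert not any(m.id in ("GLC", "O2", "CO2", "NH3") for m in red.metabolites)

    def test_etc_rows_lowest_weight_flag(self, full_net):
        red = cf.reduce_to_measured(full_net, cf.packaged_measured_ids())
        for m in red.metabolites:
            assert m.lowest_weight == m.etc_member

    def test_all_measured_changes_only_flags(self, toy_chain):
        red = cf.reduce_to_measured(toy_chain, {"A", "B", "C"})
        assert red.metabolite_ids == toy_chain.metabolite_ids
        assert red.reaction_ids == toy_chain.reaction_ids
        np.testing.assert_array_equal(red.S, toy_chain.S)

    def test_unmeasured_internal_middle_metabolite(self, toy_chain):
        red = cf.reduce_to_measured(toy_chain, {"A", "C"})
        assert red.metabolite("B").constrained_zero
        assert len(red.reactions) == 2

    def test_reduction_monotone(self, full_net):
        red = cf.reduce_to_measured(full_net, {"PYR", "3PG"})
        assert len(red.metabolites) <= len(full_net.metabolites)
        assert len(red.reactions) == len(full_net.reactions)

    def test_errors(self, full_net):
        with pytest.raises(ValueError, match="empty"):
            cf.reduce_to_measured(full_net, set())
        with pytest.raises(ValueError, match="absent"):
            cf.reduce_to_measured(full_net, {"NOT_A_MET"})


class TestSynthesis:
    def test_tri_alanine_maps_to_pyruvate(self):
        syn = cf.synthesis_from_sequence("AAA", "tri-ala")
        assert syn.coefficients == {"PYR": 1.0}

    def test_ser_gly_maps_to_3pg(self):
        assert cf.synthesis_from_sequence("SG", "sg").coefficients == {"3PG": 1.0}

    def test_random_sequence_matches_independent_tally(self):
        rng = np.random.default_rng(42)
        residues = list(RESIDUE_PRECURSORS)
        seq = "".join(rng.choice(residues, size=60))
        syn = cf.synthesis_from_sequence(seq, "random")
        expected = tally_precursors(seq)
        assert set(syn.coefficients) == set(expected)
        for k in expected:
            assert syn.coefficients[k] == pytest.approx(expected[k], abs=1e-12)

    def test_fraction_normalization_sums_to_one(self):
        syn = cf.synthesis_from_sequence("ACDEFGHIKLMNPQRSTVWY", "all20")
        assert sum(syn.coefficients.values()) == pytest.approx(1.0, abs=1e-12)
        assert syn.skipped_residues == 4  # F, Y, W, H

    @given(st.text(alphabet=list(RESIDUE_PRECURSORS), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seq):
        try:
            a = cf.synthesis_from_sequence(seq, "x")
        except ValueError:
            return  # all-aromatic sequences have no precursor content
        b = cf.synthesis_from_sequence(seq[::-1], "x")
        assert a.coefficients == pytest.approx(b.coefficients)

    def test_additive_over_concatenation_before_normalization(self):
        a = cf.synthesis_from_sequence("AAS", "a", normalization="per-molecule")
        b = cf.synthesis_from_sequence("DDE", "b", normalization="per-molecule")
        ab = cf.synthesis_from_sequence("AASDDE", "ab", normalization="per-molecule")
        merged = {}
        for d in (a.coefficients, b.coefficients):
            for k, v in d.items():
                merged[k] = merged.get(k, 0) + v
        assert ab.coefficients == pytest.approx(merged)

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            cf.synthesis_from_sequence("AAZ", "bad")
        with pytest.raises(ValueError, match="empty"):
            cf.synthesis_from_sequence("", "empty")

    def test_lipid_reaction(self):
        lip = cf.lipid_synthesis_reaction()
        assert lip.coefficients == {"ACCOA": 1.0}
        assert lip.product_name == "lipid"
        assert not set(lip.coefficients) & {"3PG", "PYR", "AKG", "OAA"}

    def test_add_synthesis_column(self, full_net):
        syn = cf.SynthesisReaction("x", {"PYR": 0.5, "AKG": 0.5})
        net2 = cf.add_synthesis_reaction(full_net, syn)
        assert len(net2.reactions) == len(full_net.reactions) + 1
        col = net2.S[:, -1]
        idx = {m: i for i, m in enumerate(net2.metabolite_ids)}
        assert col[idx["PYR"]] == -0.5 and col[idx["AKG"]] == -0.5
        assert np.count_nonzero(col) == 2
        assert net2.reactions[-1].pathway == "SYN"
        assert not net2.reactions[-1].reversible

    def test_add_synthesis_missing_precursor(self, toy_chain):
        syn = cf.SynthesisReaction("x", {"PYR": 1.0})
        with pytest.raises(ValueError, match="measured"):
            cf.add_synthesis_reaction(toy_chain, syn)
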