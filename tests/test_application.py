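"""Substrate composition analysis and protease screening."""

import numpy as np
import pytest

import pepqsar as pq
from pepqsar.application import DipeptideCandidate


@pytest.fixture(scope="module")
def dwgp():
    return pq.load_dwgp_composition()


@pytest.fixture(scope="module")
def hydrophobic():
    return pq.ResidueClassSet("hydrophobic", pq.HYDROPHOBIC_RESIDUES)


@pytest.fixture(scope="module")
def aromatic():
    return pq.ResidueClassSet("aromatic", pq.AROMATIC_RESIDUES)


class TestClassFraction:
    def test_wheat_germ_hydrophobic_content(self, dwgp, hydrophobic):
        # component rows sum to 42.83 under printed rounding (reported 42.84)
        assert pq.class_fraction(dwgp, hydrophobic) == pytest.approx(
            42.84, abs=0.02)

    def test_wheat_germ_aromatic_content(self, dwgp, aromatic):
        assert pq.class_fraction(dwgp, aromatic) == pytest.approx(
            8.89, abs=0.02)

    def test_empty_intersection_is_zero(self, dwgp):
        # N and Q exist only inside combined entries, which are excluded
        nq = pq.ResidueClassSet("amide", frozenset("NQ"))
        assert pq.class_fraction(dwgp, nq) == 0.0

    def test_additive_over_disjoint_classes(self, dwgp):
        a = pq.ResidueClassSet("a", frozenset("AVL"))
        b = pq.ResidueClassSet("b", frozenset("IPF"))
        ab = pq.ResidueClassSet("ab", frozenset("AVLIPF"))
        assert pq.class_fraction(dwgp, a) + pq.class_fraction(dwgp, b) == \
            pytest.approx(pq.class_fraction(dwgp, ab))


class TestCompositionFromSequence:
    def test_poly_alanine_is_pure(self):
        comp = pq.composition_from_sequence("AAAA")
        assert comp.content == {"A": pytest.approx(100.0)}

    def test_two_residue_fractions_proportional_to_masses(self):
        comp = pq.composition_from_sequence("AV")
        assert sum(comp.content.values()) == pytest.approx(100.0)
        # V's residue mass exceeds A's, so its fraction is larger
        assert comp.content["V"] > comp.content["A"]

    def test_fractions_sum_to_100(self):
        comp = pq.composition_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 3)
        assert sum(comp.content.values()) == pytest.approx(100.0, abs=1e-9)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            pq.composition_from_sequence("AXZ")


class TestProteaseSpecs:
    def test_builtin_fixtures(self):
        specs = {s.name: s for s in pq.builtin_protease_specs()}
        assert len(specs) == 4
        assert "L" in specs["Alcalase"].c_terminal_preference
        assert specs["Neutrase"].c_terminal_preference == frozenset("YWF")
        for s in specs.values():
            assert s.c_terminal_preference <= set(pq.STANDARD_AMINO_ACIDS)

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            pq.ProteaseSpec("bad", frozenset("XZ"))


class TestCandidates:
    def test_neutrase_on_gavw(self):
        spec = pq.ProteaseSpec("Neutrase", frozenset("YWF"))
        cands = pq.candidate_dipeptides("GAVW", spec)
        assert [c.sequence for c in cands] == ["VW"]

    def test_alcalase_on_gavw(self):
        spec = next(s for s in pq.builtin_protease_specs()
                    if s.name == "Alcalase")
        assert [c.sequence for c in pq.candidate_dipeptides("GAVW", spec)] \
            == ["AV", "VW"]

    def test_no_match_gives_empty_list(self):
        spec = pq.ProteaseSpec("x", frozenset("K"))
        assert pq.candidate_dipeptides("GAVW", spec) == []

    def test_duplicates_retained_with_positions(self):
        spec = pq.ProteaseSpec("x", frozenset("W"))
        cands = pq.candidate_dipeptides("GWGW", spec)
        assert [(c.sequence, c.position) for c in cands] == \
            [("GW", 1), ("GW", 3)]

    def test_candidates_are_substrings_and_bounded(self):
        seq = "GAVWMILYPKRE"
        spec = next(s for s in pq.builtin_protease_specs()
                    if s.name == "Proteinase K")
        cands = pq.candidate_dipeptides(seq, spec)
        assert len(cands) <= len(seq) - 1
        for c in cands:
            assert seq[c.position - 1:c.position + 1] == c.sequence
            assert c.sequence[1] in spec.c_terminal_preference


class TestRanking:
    def test_w_preferring_spec_outranks_g_preferring(self, trained_model):
        # Trp-rich C-termini are the high-activity motif the model learned
        seq = "GAIWGVWGLWAGAG"
        spec_w = pq.ProteaseSpec("prefers-W", frozenset("W"))
        spec_g = pq.ProteaseSpec("prefers-G", frozenset("G"))
        ranking = pq.rank_proteases(seq, [spec_w, spec_g], trained_model)
        assert ranking.digests[0].name == "prefers-W"

    def test_order_of_specs_does_not_matter(self, trained_model):
        seq = "GAIWGVWGLWAGAG"
        specs = pq.builtin_protease_specs()
        a = pq.rank_proteases(seq, specs, trained_model)
        b = pq.rank_proteases(seq, specs[::-1], trained_model)
        assert [d.name for d in a.digests] == [d.name for d in b.digests]

    def test_identical_specs_identical_summaries(self, trained_model):
        seq = "GAVWML"
        s1 = pq.ProteaseSpec("a", frozenset("WL"))
        s2 = pq.ProteaseSpec("b", frozenset("WL"))
        ranking = pq.rank_proteases(seq, [s1, s2], trained_model)
        means = [d.mean_activity for d in ranking.digests]
        assert means[0] == pytest.approx(means[1])

    def test_empty_candidate_protease_excluded_but_reported(
            self, trained_model):
        spec_none = pq.ProteaseSpec("never", frozenset("K"))
        spec_w = pq.ProteaseSpec("w", frozenset("W"))
        ranking = pq.rank_proteases("GAVW", [spec_none, spec_w],
                                    trained_model)
        assert [d.name for d in ranking.digests] == ["w"]
        assert ranking.excluded == ["never"]

    def test_candidate_constraint_holds_in_ranking(self, trained_model):
        ranking = pq.rank_proteases("GAVWMILY",
                                    pq.builtin_protease_specs(),
                                    trained_model)
        for d in ranking.digests:
            spec = next(s for s in pq.builtin_protease_specs()
                        if s.name == d.name)
            for c in d.candidates:
                assert c.sequence[1] in spec.c_terminal_preference
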