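"""Motif-template parsing, scanning, P-position mapping and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdzcoupling import sequence_motif as sm

TABLE = sm.ResidueClassTable()


class TestParseTemplate:
    def test_short_hydrophilic_class_resolves_to_ser_thr(self):
        tpl = sm.parse_template("W-Φs-D-X-P", TABLE)
        assert len(tpl) == 5
        assert tpl.positions[1] == frozenset("ST")
        assert tpl.positions[3] == sm.AMINO_ACIDS

    def test_alternation_token(self):
        tpl = sm.parse_template("X-Y-G-W-Φa-D/G", TABLE)
        assert tpl.positions[-1] == frozenset("DG")
        assert tpl.positions[4] == frozenset("AVLIM")

    @pytest.mark.parametrize("bad", ["", "W--D", "W-Zz-D"])
    def test_bad_specs_raise(self, bad):
        with pytest.raises(ValueError):
            sm.parse_template(bad, TABLE)

    def test_error_names_unknown_token(self):
        with pytest.raises(ValueError, match="Zz"):
            sm.parse_template("W-Zz-D", TABLE)


def brute_force_scan(seq, templates, min_score, max_strict, s_cons=0.5):
    """Independent window-by-window enumeration oracle."""
    hits = []
    for t_order, tpl in enumerate(templates):
        L = len(tpl)
        for s0 in range(len(seq.residues) - L + 1):
            window = seq.residues[s0:s0 + L]
            scores = []
            for r, allowed in zip(window, tpl.positions):
                if r in allowed:
                    scores.append(1.0)
                elif r != "X" and any(r in g and allowed & g
                                      for g in sm.CONSERVATIVE_GROUPS):
                    scores.append(s_cons)
                else:
                    scores.append(0.0)
            score = sum(scores) / L
            strict = scores.count(0.0)
            if score >= min_score and strict <= max_strict:
                hits.append((-score, s0 + seq.numbering_offset, t_order,
                             tpl.name, window, strict))
    hits.sort(key=lambda h: h[:3])
    return hits


class TestScan:
    def test_wgef_internal_peptide_is_the_only_hit(self):
        """The WGEF internal peptide region yields exactly one hit, from the
        W-Φs-D-X-P template over its WQDIP window, at default thresholds."""
        seq = sm.ProteinSequence("xWGEF", "MKAV" + "GSTFSLWQDIP" + "LREK",
                                 numbering_offset=398)
        hits = sm.scan(seq)
        assert len(hits) == 1
        h = hits[0]
        assert (h.template, h.matched) == ("W-Φs-D-X-P", "WQDIP")
        # hit lies inside the 11-mer at 402-412
        assert 402 <= h.start and h.end <= 412
        assert h.score == pytest.approx(0.8)
        assert h.n_strict_mismatches == 1

    def test_sequence_shorter_than_template_gives_empty_list(self):
        seq = sm.ProteinSequence("s", "AAAA")
        assert sm.scan(seq, [sm.parse_template("W-Φs-D-X-P", TABLE)]) == []

    def test_random_sequence_matches_brute_force(self, rng):
        residues = "".join(rng.choice(sorted(sm.AMINO_ACIDS), size=60))
        seq = sm.ProteinSequence("r", residues)
        templates = sm.default_templates(TABLE)
        got = sm.scan(seq, templates, min_score=0.5, max_strict_mismatches=2)
        want = brute_force_scan(seq, templates, 0.5, 2)
        assert [(h.score, h.start, h.template, h.matched, h.n_strict_mismatches)
                for h in got] == \
               [(-s, st_, name, w, k) for s, st_, _, name, w, k in want]

    def test_single_strict_mismatch_costs_one_over_length(self):
        tpl = sm.parse_template("W-S-D-I-P", TABLE)
        perfect = sm.scan(sm.ProteinSequence("p", "WSDIP"), [tpl], 0.0, 5)[0]
        mutated = sm.scan(sm.ProteinSequence("m", "WSDIH"), [tpl], 0.0, 5)[0]
        assert perfect.score == 1.0
        assert perfect.score - mutated.score == pytest.approx(1 / 5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet=sorted(sm.AMINO_ACIDS) + ["X"], min_size=1, max_size=100),
           st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=0, max_value=6))
    def test_scanner_equals_brute_force_enumeration(self, residues, min_score, max_strict):
        seq = sm.ProteinSequence("h", residues)
        templates = sm.default_templates(TABLE)
        got = sm.scan(seq, templates, min_score, max_strict)
        want = brute_force_scan(seq, templates, min_score, max_strict)
        assert len(got) == len(want)
        for h, (neg_s, start, _, name, window, strict) in zip(got, want):
            assert (h.score, h.start, h.template, h.matched, h.n_strict_mismatches) \
                == (-neg_s, start, name, window, strict)


class TestPdzPositions:
    def test_wgef_peptide_assignment(self):
        pmap = sm.assign_pdz_positions("GSTFSLWQDIP")
        pep = "GSTFSLWQDIP"
        expected = {"D": 0, "I": 1, "P": 2, "Q": -1, "W": -2, "L": -3, "S": -4, "F": -5}
        for aa, p in expected.items():
            assert pmap.residue_at(pep, p) == aa

    def test_n3_peptide_anchor_and_tryptophan(self):
        pmap = sm.assign_pdz_positions("EIVLWSDIP")
        assert pmap[7] == 0 and "EIVLWSDIP"[7 - 1] == "D"
        assert pmap.residue_at("EIVLWSDIP", -2) == "W"

    def test_no_aspartate_raises(self):
        with pytest.raises(ValueError, match="no aspartate"):
            sm.assign_pdz_positions("AAAA")

    def test_multiple_aspartates_need_explicit_anchor(self):
        with pytest.raises(ValueError, match="ambiguous"):
            sm.assign_pdz_positions("ADAD")
        pmap = sm.assign_pdz_positions("ADAD", anchor_index=4)
        assert pmap[4] == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=30), st.integers(min_value=0, max_value=29))
    def test_bijection_onto_consecutive_range(self, length, pos):
        pos = pos % length
        peptide = "A" * pos + "D" + "A" * (length - pos - 1)
        pmap = sm.assign_pdz_positions(peptide)
        assert sorted(pmap.keys()) == list(range(1, length + 1))
        ps = sorted(pmap.values())
        assert ps == list(range(ps[0], ps[0] + length))
        assert 0 in ps


class TestConservationProfile:
    def test_identical_sequences_are_fully_conserved(self):
        seqs = [sm.ProteinSequence(f"s{i}", "GSTFSLWQDIP") for i in range(5)]
        assert np.all(sm.conservation_profile(seqs) == 1.0)

    def test_single_divergent_column(self):
        seqs = [sm.ProteinSequence("a", "GSTF"), sm.ProteinSequence("b", "GSAF")]
        prof = sm.conservation_profile(seqs)
        assert list(prof) == [1.0, 1.0, 0.5, 1.0]

    def test_random_alignment_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        aas = sorted(sm.AMINO_ACIDS)
        rows = ["".join(rng.choice(aas, size=12)) for _ in range(6)]
        seqs = [sm.ProteinSequence(str(i), r) for i, r in enumerate(rows)]
        prof = sm.conservation_profile(seqs)
        for c in range(12):
            col = [r[c] for r in rows]
            assert prof[c] == pytest.approx(max(col.count(a) for a in set(col)) / 6)

    def test_gaps_excluded_from_both_counts(self):
        seqs = [sm.ProteinSequence("a", "A-"), sm.ProteinSequence("b", "A-"),
                sm.ProteinSequence("c", "GA")]
        prof = sm.conservation_profile(seqs)
        assert prof[0] == pytest.approx(2 / 3)
        assert prof[1] == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        seqs = [sm.ProteinSequence(str(i), "".join(rng.choice(list("ACDG"), size=8)))
                for i in range(5)]
        ref = sm.conservation_profile(seqs)
        perm = [seqs[i] for i in rng.permutation(5)]
        assert np.array_equal(ref, sm.conservation_profile(perm))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            sm.conservation_profile([sm.ProteinSequence("a", "AA"),
                                     sm.ProteinSequence("b", "AAA")])
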