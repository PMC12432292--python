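import numpy as np
import pytest

import cladediag as cd
from cladediag.errors import BoundsError
from oracles import brute_enumerate


def _aln(rows: dict[str, str]) -> cd.Alignment:
    return cd.Alignment([cd.AlignedSequence(i, s) for i, s in rows.items()])


class TestConservationProfile:
    def test_hand_counted_columns(self):
        # col0: {A,A,A,A}; col2: {A,A,C,-} with the gap internal
        aln = _aln(
            {
                "s1": "AGAG",
                "s2": "AGAG",
                "s3": "AGCG",
                "s4": "AG-G",
            }
        )
        prof = cd.conservation_profile(aln)
        assert prof.gap_fraction[0] == 0.0
        assert prof.majority_frequency[0] == 1.0
        assert prof.gap_fraction[2] == pytest.approx(0.25)
        assert prof.majority_frequency[2] == pytest.approx(2 / 3)

    def test_leading_gap_columns_are_uncovered(self):
        aln = _aln({"s1": "--ACGT", "s2": "--ACGT"})
        prof = cd.conservation_profile(aln)
        assert prof.covered_count[0] == 0
        assert prof.gap_fraction[0] == 1.0
        assert prof.majority_frequency[0] == 0.0


class TestWindowIsConserved:
    def _profile(self, majority):
        n = len(majority)
        return cd.ConservationProfile(
            gap_fraction=np.zeros(n),
            majority_frequency=np.array(majority, dtype=float),
            covered_count=np.full(n, 4),
        )

    def test_fully_conserved_window(self):
        prof = self._profile([1.0] * 10)
        assert cd.window_is_conserved(prof, 0, 10, cd.ScreenParams())

    @pytest.mark.parametrize("n_conserved, expected", [(7, False), (8, True)])
    def test_threshold_is_inclusive(self, n_conserved, expected):
        maj = [1.0] * n_conserved + [0.5] * (10 - n_conserved)
        prof = self._profile(maj)
        assert cd.window_is_conserved(prof, 0, 10, cd.ScreenParams()) is expected

    def test_out_of_bounds_window(self):
        prof = self._profile([1.0] * 10)
        with pytest.raises(BoundsError):
            cd.window_is_conserved(prof, 5, 10, cd.ScreenParams())


class TestCladeConsensus:
    def test_within_clade_variation_becomes_degenerate_code(self):
        # one member has T where the other has C -> Y
        aln = _aln({"s1": "AACGG", "s2": "AATGG", "o1": "AAAGG", "o2": "AAAGG"})
        part = cd.CladePartition({"s1": "X", "s2": "X"})
        cons, support = cd.clade_consensus(aln, part, "X", 0, 5)
        assert cons == "AAYGG"
        assert support == 2

    def test_internal_gap_rejects_window(self):
        aln = _aln({"s1": "AAC-G", "s2": "AACGG", "o1": "AAAGG"})
        part = cd.CladePartition({"s1": "X", "s2": "X"})
        assert cd.clade_consensus(aln, part, "X", 0, 5) is None

    def test_member_missing_the_window_is_excluded_not_failed(self):
        aln = _aln({"s1": "ACGTACGT", "s2": "ACGTACGT", "s3": "----ACGT"})
        part = cd.CladePartition({"s1": "X", "s2": "X", "s3": "X"})
        cons, support = cd.clade_consensus(aln, part, "X", 0, 4)
        assert (cons, support) == ("ACGT", 2)

    def test_unknown_clade(self):
        aln = _aln({"s1": "ACGT", "s2": "ACGT"})
        part = cd.CladePartition({"s1": "X", "s2": "X"})
        with pytest.raises(KeyError):
            cd.clade_consensus(aln, part, "nope", 0, 4)


class TestOutcladeOccurrence:
    def test_brute_counted_fraction(self):
        # consensus AYG: exactly one of four outsiders matches
        aln = _aln(
            {
                "m1": "ACGTT",
                "m2": "ATGTT",
                "o1": "ACGTT",  # matches A,Y,G
                "o2": "AAGTT",  # A not in Y
                "o3": "A-GTT",  # gap never matches
                "o4": "TCGTT",  # T not in A
            }
        )
        part = cd.CladePartition({"m1": "X", "m2": "X"})
        cons, _ = cd.clade_consensus(aln, part, "X", 0, 3)
        assert cons == "AYG"
        frac, evaluated = cd.outclade_occurrence(aln, part, "X", 0, cons)
        assert evaluated == 4
        assert frac == pytest.approx(0.25)

    def test_exact_threshold_fraction_fails_strict_rule(self):
        # 1 match among 10 evaluated = 0.10 is NOT < 0.10
        rows = {"m1": "AAAA", "m2": "AAAA"}
        rows["o1"] = "AAAA"  # the single match
        for k in range(2, 11):
            rows[f"o{k}"] = "TTTT"
        aln = _aln(rows)
        part = cd.CladePartition({"m1": "X", "m2": "X"})
        frac, evaluated = cd.outclade_occurrence(aln, part, "X", 0, "AAAA")
        assert (frac, evaluated) == (0.1, 10)
        assert not frac < cd.ScreenParams().outclade_max

    def test_adding_matching_outsider_never_decreases_fraction(self):
        rows = {"m1": "ACGTACGTAC", "m2": "ACGTACGTAC", "o1": "TTTTACGTAC"}
        aln = _aln(rows)
        part = cd.CladePartition({"m1": "X", "m2": "X"})
        frac1, _ = cd.outclade_occurrence(aln, part, "X", 4, "ACGTAC")
        rows["o2"] = "ACGTACGTAC"
        frac2, _ = cd.outclade_occurrence(_aln(rows), part, "X", 4, "ACGTAC")
        assert frac2 >= frac1


class TestEnumerateCandidates:
    def test_matches_brute_force_on_toy(self, toy_alignment):
        aln, part, rows = toy_alignment
        clade_of = dict(part.assignments)
        for clade in ("CladeA", "CladeB"):
            got = {
                (c.start, c.length, c.consensus, c.in_clade_support,
                 c.outclade_fraction, c.outclade_evaluated)
                for c in cd.enumerate_candidates(aln, part, clade)
            }
            want = set(brute_enumerate(rows, clade_of, clade))
            assert got == want, clade

    def test_identical_clades_yield_nothing(self):
        row = "ACGTACGTGCTAGCATCGATCGATTACGATTACGGT"
        aln = _aln({f"s{i}": row for i in range(6)})
        part = cd.CladePartition(
            {f"s{i}": ("X" if i < 3 else "Y") for i in range(6)}
        )
        assert cd.enumerate_candidates(aln, part, "X") == []

    def test_clade_specific_insert_passes_gap_never_matches(self):
        # outsiders are gapped across the insert block: fraction 0
        core = "ACGTACGTGCTAGCATCGAT"
        ins = "GGATCCGGAATT"
        rows = {
            "m1": core + ins + core,
            "m2": core + ins + core,
            "o1": core + "-" * 12 + core,
            "o2": core + "-" * 12 + core,
        }
        aln = _aln(rows)
        part = cd.CladePartition({"m1": "X", "m2": "X"})
        cands = cd.enumerate_candidates(
            aln, part, "X", cd.ScreenParams(min_len=10, max_len=12)
        )
        spanning = [c for c in cands if c.start <= 21 <= c.start + c.length - 1]
        assert spanning
        assert all(c.outclade_fraction == 0.0 for c in spanning)

    def test_repeated_pattern_fails_uniqueness(self):
        # the clade block occurs twice in the members' ungapped sequences;
        # outsiders differ from it at only two columns, so the windows stay
        # conserved and diagnostic — uniqueness is the deciding filter
        block = "GGATCCGGAATT"
        outs_block = "GGAACCGGTATT"  # offsets 3 and 8 differ
        filler = "ACGTACGTGCTAGCATCGAT"
        rows = {
            "m1": filler + block + filler + block + filler,
            "m2": filler + block + filler + block + filler,
            "o1": filler + outs_block + filler + outs_block + filler,
            "o2": filler + outs_block + filler + outs_block + filler,
        }
        aln = _aln(rows)
        part = cd.CladePartition({"m1": "X", "m2": "X"})
        cands = cd.enumerate_candidates(
            aln, part, "X", cd.ScreenParams(min_len=12, max_len=12)
        )
        starts = {c.start for c in cands}
        assert 21 not in starts and 53 not in starts


class TestSelection:
    def _cand(self, start, length, frac, clade="X"):
        return cd.MotifCandidate(
            clade=clade, start=start, length=length, consensus="A" * length,
            in_clade_support=3, degenerate_positions=0,
            outclade_fraction=frac, outclade_evaluated=10,
        )

    def test_disjoint_candidates_both_selected(self):
        rep = cd.select_nonoverlapping([self._cand(1, 10, 0.0), self._cand(20, 10, 0.0)])
        assert [(m.start, m.length) for m in rep.motifs] == [(1, 10), (20, 10)]

    def test_longer_candidate_wins_on_overlap(self):
        rep = cd.select_nonoverlapping(
            [self._cand(10, 12, 0.0), self._cand(21, 15, 0.0)]
        )
        assert [(m.start, m.length) for m in rep.motifs] == [(21, 15)]

    def test_full_tie_breaks_by_start(self):
        rep = cd.select_nonoverlapping(
            [self._cand(103, 12, 0.0), self._cand(100, 12, 0.0)]
        )
        assert [m.start for m in rep.motifs] == [100]

    def test_lower_outclade_fraction_wins_first(self):
        rep = cd.select_nonoverlapping(
            [self._cand(10, 20, 0.05), self._cand(15, 10, 0.0)]
        )
        assert [m.start for m in rep.motifs] == [15]

    def test_selected_motifs_are_disjoint(self, default_reports):
        for rep in default_reports.values():
            spans = sorted((m.start0, m.start0 + m.length) for m in rep.motifs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestScreenAllClades:
    def test_order_permutation_leaves_reports_unchanged(self, toy_alignment):
        aln, part, rows = toy_alignment
        shuffled = cd.Alignment(
            [cd.AlignedSequence(i, rows[i]) for i in reversed(list(rows))]
        )
        r1 = cd.screen_all_clades(aln, part)
        r2 = cd.screen_all_clades(shuffled, part)
        for clade in r1:
            assert [
                (m.start, m.length, m.consensus) for m in r1[clade].motifs
            ] == [(m.start, m.length, m.consensus) for m in r2[clade].motifs]

    def test_singleton_clade_warns_and_reports_empty(self):
        aln = _aln({"s1": "ACGTACGTACGT", "s2": "ACGTACGTACGT", "s3": "ACGTACGTACGT"})
        part = cd.CladePartition({"s1": "X", "s2": "X", "s3": "solo"})
        with pytest.warns(UserWarning, match="solo"):
            reports = cd.screen_all_clades(aln, part)
        assert reports["solo"].motifs == []

    def test_consensus_soundness_on_default_dataset(self, default_ds, default_reports):
        aln, part, _ = default_ds
        from cladediag.iupac import CODE_TO_BASES
        for clade, rep in default_reports.items():
            members = part.members(clade)
            for m in rep.motifs:
                for sid in members:
                    if not aln.covers(sid, m.start0, m.length):
                        continue
                    window = aln[sid].residues[m.start0 : m.start0 + m.length]
                    assert all(
                        CODE_TO_BASES[r] <= CODE_TO_BASES[c]
                        for r, c in zip(window, m.consensus)
                    )
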