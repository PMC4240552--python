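"""Alignment, profile construction, calibration and threshold behavior."""

import math

import numpy as np
import pytest

from orthomerge.align import build_msa
from orthomerge.meta import select_assignments
from orthomerge.model import MetaParams, ProteinRef, ProteinSequence, ValidationError
from orthomerge.profile import (
    AA_INDEX,
    Calibration,
    ProfileHit,
    assign_unassigned,
    build_profile,
    calibrate_profile,
    encode_sequence,
    fit_gumbel_moments,
    score_sequence,
)

from oracles import sw_score_oracle


def seq(name, residues):
    return ProteinSequence(ProteinRef("S", name), residues)


class TestBuildMsa:
    def test_identical_sequences_no_gaps(self):
        msa = build_msa([seq("a", "ACDEF"), seq("b", "ACDEF"), seq("c", "ACDEF")])
        assert msa.column_count == 5
        assert all("-" not in aligned for _r, aligned in msa.rows)

    def test_single_deletion_gap(self):
        msa = build_msa([seq("a", "ACDE"), seq("b", "ACE")])
        assert msa.column_count == 4
        by_name = {r.protein: aligned for r, aligned in msa.rows}
        assert by_name["a"] == "ACDE"
        assert by_name["b"].count("-") == 1
        assert by_name["b"].replace("-", "") == "ACE"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(list(aas), size=40))
        seqs = []
        for k in range(5):
            s = list(base)
            for pos in rng.choice(40, size=4, replace=False):
                s[pos] = aas[int(rng.integers(20))]
            seqs.append(seq(f"s{k}", "".join(s)))
        reference = build_msa(seqs)
        for _rep in range(10):
            order = [seqs[i] for i in rng.permutation(len(seqs))]
            assert build_msa(order).rows == reference.rows

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            build_msa([seq("a", "ACDEF")])

    def test_rows_reproduce_inputs(self):
        seqs = [seq("a", "MKVLA"), seq("b", "MKLA"), seq("c", "MKVLAG")]
        msa = build_msa(seqs)
        by_ref = {s.ref: s.residues for s in seqs}
        for ref, aligned in msa.rows:
            assert aligned.replace("-", "") == by_ref[ref]


class TestBuildProfile:
    def test_pure_column_score_is_log_odds(self):
        msa = build_msa([seq(c, "AAAA") for c in "wxyz"])
        uniform = np.full(20, 0.05)
        profile = build_profile(msa, background=uniform, pseudocount=0.0)
        a_col = AA_INDEX["A"]
        assert profile.match_scores.shape == (4, 21)
        assert profile.match_scores[0, a_col] == pytest.approx(
            math.log2(1 / 0.05), abs=1e-9
        )

    def test_majority_gap_column_excluded(self):
        from orthomerge.align import Msa

        rows = [
            (ProteinRef("S", "a"), "A-CD"),
            (ProteinRef("S", "b"), "A-CD"),
            (ProteinRef("S", "c"), "AEC-"),
            (ProteinRef("S", "d"), "A-CD"),
        ]
        profile = build_profile(Msa(rows, 4))
        # column 2 has 3/4 gaps -> dropped; the rest stay (<= 50% gaps)
        assert profile.length == 3

    def test_bad_background_rejected(self):
        msa = build_msa([seq("a", "ACDE"), seq("b", "ACDE")])
        with pytest.raises(ValidationError):
            build_profile(msa, background=np.full(20, 0.1))


class TestCalibration:
    def test_moment_fit_recovers_known_gumbel(self):
        rng = np.random.default_rng(123)
        true_mu, true_lam = 10.0, 0.3
        draws = rng.gumbel(loc=true_mu, scale=1.0 / true_lam, size=5000)
        mu, lam = fit_gumbel_moments(draws)
        assert mu == pytest.approx(true_mu, rel=0.05)
        assert lam == pytest.approx(true_lam, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            fit_gumbel_moments(np.full(100, 3.0))

    def test_evalue_limits(self):
        msa = build_msa([seq("a", "ACDEFGHIKL"), seq("b", "ACDEFGHIKL")])
        profile = build_profile(msa)
        profile.calibration = Calibration(mu=5.0, lam=0.4, database_size=250)
        assert profile.evalue(1e9) == pytest.approx(0.0, abs=1e-12)
        assert profile.evalue(-1e9) == pytest.approx(250.0)

    def test_same_seed_identical_calibration(self):
        msa = build_msa([seq("a", "MKVLAGTWE" * 3), seq("b", "MKVLAGSWE" * 3)])
        profile = build_profile(msa)
        pool = [seq(f"d{k}", "LVKAMGETW" * 3) for k in range(5)]
        c1 = calibrate_profile(profile, pool, 60, np.random.default_rng(9), 100)
        c2 = calibrate_profile(profile, pool, 60, np.random.default_rng(9), 100)
        assert c1.calibration == c2.calibration

    def test_min_decoys_enforced(self):
        msa = build_msa([seq("a", "ACDEF"), seq("b", "ACDEF")])
        profile = build_profile(msa)
        with pytest.raises(ValidationError):
            calibrate_profile(profile, [seq("d", "ACDEF")], 10,
                              np.random.default_rng(0))


class TestScoreSequence:
    def _calibrated_profile(self, seqs, rng_seed=0):
        msa = build_msa(seqs)
        profile = build_profile(msa)
        profile.calibration = Calibration(mu=3.0, lam=0.5, database_size=100)
        return profile

    def test_self_hit_full_coverage(self):
        members = [seq(c, "MKVLAGTWENPQRSHIYCDF") for c in "abcd"]
        profile = self._calibrated_profile(members)
        hit = score_sequence(profile, seq("q", "MKVLAGTWENPQRSHIYCDF"))
        assert hit.seq_coverage == pytest.approx(1.0)
        assert hit.profile_coverage == pytest.approx(1.0)
        assert hit.raw_score > 0

    def test_uncalibrated_profile_rejected(self):
        msa = build_msa([seq("a", "ACDEF"), seq("b", "ACDEF")])
        profile = build_profile(msa)
        with pytest.raises(ValidationError, match="not calibrated"):
            score_sequence(profile, seq("q", "ACDEF"))

    def test_no_positive_cell_floors_at_zero(self):
        members = [seq(c, "WWWWWWWWWW") for c in "ab"]
        profile = self._calibrated_profile(members)
        hit = score_sequence(profile, seq("q", "PPPPP"))
        assert hit.raw_score == 0.0
        assert hit.seq_coverage == 0.0
        assert hit.profile_coverage == 0.0

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(77)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _case in range(100):
            L = int(rng.integers(3, 31))
            M = int(rng.integers(3, 31))
            scores = np.round(rng.normal(0, 2.0, size=(L, 21)), 3)
            scores[:, 20] = 0.0
            residues = "".join(aas[int(i)] for i in rng.integers(0, 20, size=M))
            profile_scores = scores
            encoded = encode_sequence(residues)
            from orthomerge.profile import _sw_affine

            got, *_ = _sw_affine(profile_scores, encoded, 5.5, 0.5)
            expected = sw_score_oracle(profile_scores, list(encoded), 5.5, 0.5)
            assert got == pytest.approx(expected, abs=1e-9)


class TestAssignment:
    def _hit(self, protein, group, evalue, cov):
        return ProfileHit(
            protein=ProteinRef("S", protein), group_id=group,
            raw_score=50.0, evalue=evalue,
            seq_coverage=cov, profile_coverage=cov,
        )

    def test_passing_hit_assigned(self):
        params = MetaParams()
        got = select_assignments([self._hit("p", "G1", 1e-12, 0.5)], params)
        assert got == {ProteinRef("S", "p"): "G1"}

    def test_evalue_above_threshold_rejected(self):
        params = MetaParams()
        assert select_assignments([self._hit("p", "G1", 1e-8, 0.9)], params) == {}

    def test_evalue_threshold_is_strict(self):
        params = MetaParams()
        assert select_assignments([self._hit("p", "G1", 1e-10, 0.9)], params) == {}

    def test_coverage_threshold_is_inclusive(self):
        params = MetaParams()
        got = select_assignments([self._hit("p", "G1", 1e-12, 0.40)], params)
        assert got == {ProteinRef("S", "p"): "G1"}
        assert select_assignments(
            [self._hit("p", "G1", 1e-12, 0.39)], params
        ) == {}

    def test_min_of_both_coverages_enforced(self):
        params = MetaParams()
        hit = ProfileHit(
            protein=ProteinRef("S", "p"), group_id="G1", raw_score=50.0,
            evalue=1e-12, seq_coverage=0.9, profile_coverage=0.3,
        )
        assert select_assignments([hit], params) == {}

    def test_equal_evalue_higher_coverage_wins(self):
        params = MetaParams()
        got = select_assignments(
            [self._hit("p", "G1", 1e-15, 0.6), self._hit("p", "G2", 1e-15, 0.9)],
            params,
        )
        assert got == {ProteinRef("S", "p"): "G2"}

    def test_lower_evalue_wins(self):
        params = MetaParams()
        got = select_assignments(
            [self._hit("p", "G1", 1e-15, 0.5), self._hit("p", "G2", 1e-20, 0.45)],
            params,
        )
        assert got == {ProteinRef("S", "p"): "G2"}

    def test_at_most_one_group_per_protein(self):
        params = MetaParams()
        hits = [self._hit("p", f"G{k}", 1e-15, 0.5) for k in range(5)]
        got = select_assignments(hits, params)
        assert list(got) == [ProteinRef("S", "p")]
        assert got[ProteinRef("S", "p")] == "G0"  # id tie-break

    def test_assign_unassigned_end_to_end(self):
        members = [seq(c, "MKVLAGTWENPQRSHIYCDF" * 3) for c in "abcd"]
        msa = build_msa(members)
        profile = build_profile(msa, group_id="G1")
        rng = np.random.default_rng(5)
        decoys = [
            seq(f"d{k}", "".join(
                np.random.default_rng(k).choice(
                    list("ACDEFGHIKLMNPQRSTVWY"), size=60)))
            for k in range(6)
        ]
        profile = calibrate_profile(profile, decoys, 60, rng, len(decoys) + 1)
        related = seq("rel", "MKVLAGTWENPQRSHIYCDF" * 3)
        got = assign_unassigned([profile], decoys + [related], MetaParams())
        assert got == {related.ref: "G1"}
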