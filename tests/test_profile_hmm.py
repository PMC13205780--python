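"""Profile HMM construction, scoring and E-value calibration."""

import numpy as np
import pytest

from cmcpminer.msa import AA, Alignment
from cmcpminer.profile_hmm import (
    ProfileHMM,
    build_profile,
    calibrate,
    evalue,
    forward_score,
    forward_scores,
    viterbi,
)
from oracles import enumerate_forward, enumerate_viterbi, random_toy_hmm

UNIFORM_BG = np.full(20, 0.05)


class TestBuildProfile:
    def test_laplace_pseudocount_hand_arithmetic(self):
        # 3 identical rows "ACD"; weight 20 with uniform background is a
        # +1 Laplace prior: P(A | col 1) = (3 + 1) / (3 + 20) = 4/23
        aln = Alignment("f", ["a", "b", "c"], ["ACD"] * 3)
        hmm = build_profile(aln, pseudocount_weight=20.0, background=UNIFORM_BG)
        assert hmm.L == 3
        assert hmm.match_p[0, AA.index("A")] == pytest.approx(4 / 23)
        assert hmm.match_p[0, AA.index("C")] == pytest.approx(1 / 23)

    def test_majority_gap_column_becomes_insert(self):
        rows = ["A-D", "A-D", "AC-", "ACD", "A-D"]  # col 2: 60% gaps
        aln = Alignment("f", list("abcde"), rows)
        hmm = build_profile(aln)
        assert hmm.L == 2
        assert hmm.match_columns == [0, 2]

    def test_all_gappy_alignment_rejected(self):
        rows = ["A--", "-C-", "--D"]  # every column 2/3 gaps
        aln = Alignment("f", list("abc"), rows)
        with pytest.raises(ValueError, match="consensus"):
            build_profile(aln)

    def test_distributions_normalised(self, coherent_hmm):
        hmm = coherent_hmm
        assert np.allclose(hmm.match_p.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(hmm.t_mm + hmm.t_mi + hmm.t_md, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_im + hmm.t_ii, 1.0, atol=1e-9)
        assert np.allclose(hmm.t_dm + hmm.t_dd, 1.0, atol=1e-9)
        assert hmm.t_bm + hmm.t_bd == pytest.approx(1.0)

    def test_serialisation_round_trip(self, coherent_hmm, tmp_path):
        hmm = calibrate(coherent_hmm, decoy_length=50, n_decoys=200, seed=1)
        path = tmp_path / "model.json"
        hmm.save(path)
        back = ProfileHMM.load(path)
        assert back.L == hmm.L
        assert np.allclose(back.match_p, hmm.match_p)
        assert np.allclose(back.t_mm, hmm.t_mm)
        assert back.calibration.lam == pytest.approx(hmm.calibration.lam)
        assert back.calibration.xi == pytest.approx(hmm.calibration.xi)
        # normalisation preserved through the round trip
        assert np.allclose(back.match_p.sum(axis=1), 1.0, atol=1e-9)


class TestScoring:
    def test_forward_matches_path_enumeration(self, rng):
        for _ in range(25):
            hmm = random_toy_hmm(rng, int(rng.integers(1, 4)))
            seq = "".join(rng.choice(list(AA), int(rng.integers(1, 6))))
            assert forward_score(hmm, seq) == pytest.approx(
                enumerate_forward(hmm, seq), abs=1e-9)

    def test_viterbi_matches_max_path_enumeration(self, rng):
        for _ in range(25):
            hmm = random_toy_hmm(rng, int(rng.integers(1, 4)))
            seq = "".join(rng.choice(list(AA), int(rng.integers(1, 6))))
            _, score = viterbi(hmm, seq)
            assert score == pytest.approx(enumerate_viterbi(hmm, seq), abs=1e-9)

    def test_forward_dominates_viterbi(self, rng, coherent_hmm):
        for _ in range(5):
            seq = "".join(rng.choice(list(AA), 30))
            assert forward_score(coherent_hmm, seq) >= viterbi(coherent_hmm, seq)[1]

    def test_consensus_beats_shuffles(self, rng, coherent_hmm):
        cons = coherent_hmm.consensus()
        s_cons = forward_score(coherent_hmm, cons)
        letters = list(cons)
        for _ in range(100):
            rng.shuffle(letters)
            assert s_cons > forward_score(coherent_hmm, "".join(letters))

    def test_viterbi_consensus_is_all_match(self, coherent_hmm):
        path, _ = viterbi(coherent_hmm, coherent_hmm.consensus())
        core = [st for st in path if st[0] in "MID"]
        assert all(st[0] == "M" for st in core)
        assert [st[1] for st in core] == list(range(1, coherent_hmm.L + 1))

    def test_path_emission_bookkeeping(self, rng, coherent_hmm):
        for _ in range(5):
            seq = "".join(rng.choice(list(AA), int(rng.integers(5, 60))))
            path, _ = viterbi(coherent_hmm, seq)
            emitting = sum(1 for st in path if st[0] in "MI")
            flanks = sum(1 for st in path if st[0] in "NC") - 2
            assert emitting + flanks == len(seq)

    def test_unknown_residue_scores_as_background(self, coherent_hmm):
        # X emits at background => consensus with one X scores lower but runs
        cons = coherent_hmm.consensus()
        seq = "X" + cons[1:]
        assert forward_score(coherent_hmm, seq) < forward_score(coherent_hmm, cons)

    def test_empty_sequence_rejected(self, coherent_hmm):
        with pytest.raises(ValueError):
            forward_scores(coherent_hmm, [""])


class TestCalibration:
    def test_gumbel_tail_probability_at_mu(self, coherent_hmm):
        hmm = calibrate(coherent_hmm, decoy_length=50, n_decoys=500, seed=2,
                        n_eff=1)
        cal = hmm.calibration
        assert cal.mu < cal.tau  # the Gumbel piece covers mu
        assert cal.tail_probability(cal.mu) == pytest.approx(
            1 - np.exp(-1), abs=1e-12)

    def test_evalue_linear_in_search_space(self, coherent_hmm):
        hmm = calibrate(coherent_hmm, decoy_length=50, n_decoys=500, seed=2,
                        n_eff=100)
        s = hmm.calibration.mu + 3.0
        assert evalue(hmm, s, n_eff=200) == pytest.approx(2 * evalue(hmm, s, n_eff=100))

    def test_evalue_monotone_decreasing(self, coherent_hmm):
        hmm = calibrate(coherent_hmm, decoy_length=50, n_decoys=500, seed=2,
                        n_eff=1000)
        scores = np.linspace(hmm.calibration.mu - 10,
                             hmm.calibration.tau + 40, 300)
        evs = [evalue(hmm, float(s)) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_degenerate_scores_raise(self):
        # uniform emissions equal to a uniform background: every decoy
        # scores identically, so no extreme-value fit is possible
        L = 3
        hmm = ProfileHMM(
            family="flat",
            match_p=np.full((L, 20), 0.05), insert_p=UNIFORM_BG.copy(),
            background=UNIFORM_BG.copy(),
            t_mm=np.full(L - 1, 0.8), t_mi=np.full(L - 1, 0.1),
            t_md=np.full(L - 1, 0.1), t_im=np.full(L - 1, 0.5),
            t_ii=np.full(L - 1, 0.5), t_dm=np.full(L - 1, 0.5),
            t_dd=np.full(L - 1, 0.5), t_bm=0.9, t_bd=0.1,
        )
        with pytest.raises(ValueError, match="degenerate"):
            calibrate(hmm, decoy_length=10, n_decoys=200, seed=0)

    def test_uncalibrated_evalue_rejected(self, coherent_family):
        from cmcpminer.msa import progressive_align
        hmm = build_profile(progressive_align(coherent_family.members))
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(hmm, 10.0)
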