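import itertools

import numpy as np
import pytest

from phasestates.evaluation import (games_howell, match_states, matched_correlation,
                                    welch_anova)
from phasestates.hmm_inference import StateTimeCourse
from phasestates.markov_states import StateSequence


def _seq_from_labels(labels, K):
    labels = np.asarray(labels, dtype=np.int64)
    occ = []
    start = 0
    for t in range(1, labels.size + 1):
        if t == labels.size or labels[t] != labels[t - 1]:
            occ.append((int(labels[start]), start, t))
            start = t
    return StateSequence(labels=labels, n_states=K, occurrences=occ)


def _stc(path, K, offset=0):
    path = np.asarray(path, dtype=np.int64)
    post = np.zeros((K, path.size))
    post[path, np.arange(path.size)] = 1.0
    return StateTimeCourse(path=path, posteriors=post, offset=offset)


class TestMatchStates:
    def test_recovers_known_permutation(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 500)
        truth = _seq_from_labels(labels, 4)
        mapping = np.array([2, 3, 1, 0])
        inferred = _stc(mapping[labels], 4)
        perm = match_states(inferred, truth)
        # inferred state mapping[k] should match back to truth state k
        assert np.array_equal(perm[mapping], np.arange(4))

    def test_munkres_equals_brute_force(self):
        """Hungarian cost equals the exhaustive minimum over 5! relabelings."""
        rng = np.random.default_rng(1)
        K, T = 5, 400
        t_lab = rng.integers(0, K, T)
        i_lab = rng.integers(0, K, T)
        truth = _seq_from_labels(t_lab, K)
        inferred = _stc(i_lab, K)
        perm = match_states(inferred, truth)
        def cost_of(p):
            ti = np.zeros((K, T)); ti[t_lab, np.arange(T)] = 1
            ii = np.zeros((K, T)); ii[i_lab, np.arange(T)] = 1
            tot = 0.0
            for m in range(K):
                a, b = ti[p[m]], ii[m]
                tot -= np.corrcoef(a, b)[0, 1]
            return tot
        best = min(cost_of(p) for p in itertools.permutations(range(K)))
        assert abs(cost_of(perm) - best) < 1e-12

    def test_state_count_mismatch_rejected(self):
        truth = _seq_from_labels([0, 1, 0, 1], 2)
        with pytest.raises(ValueError):
            match_states(_stc([0, 1, 2, 0], 3), truth)


class TestMatchedCorrelation:
    def test_identical_sequences_perfect(self):
        labels = np.random.default_rng(2).integers(0, 3, 300)
        truth = _seq_from_labels(labels, 3)
        inferred = _stc(labels, 3)
        res = matched_correlation(inferred, truth, match_states(inferred, truth))
        assert res.mean_r == pytest.approx(1.0)

    def test_independent_sequences_near_zero(self):
        rng = np.random.default_rng(3)
        T = 10_000
        truth = _seq_from_labels(rng.integers(0, 3, T), 3)
        inferred = _stc(rng.integers(0, 3, T), 3)
        res = matched_correlation(inferred, truth, match_states(inferred, truth))
        assert abs(res.mean_r) < 3 / np.sqrt(T) + 0.02

    def test_flipped_binary_labels_recovered_by_matching(self):
        labels = np.random.default_rng(4).integers(0, 2, 400)
        truth = _seq_from_labels(labels, 2)
        inferred = _stc(1 - labels, 2)
        perm = match_states(inferred, truth)
        res = matched_correlation(inferred, truth, perm)
        assert res.mean_r == pytest.approx(1.0)

    def test_unvisited_state_scores_zero(self):
        truth = _seq_from_labels([0, 0, 1, 1, 2, 2], 3)
        inferred = _stc([0, 0, 1, 1, 1, 1], 3)  # state 2 never decoded
        perm = match_states(inferred, truth)
        res = matched_correlation(inferred, truth, perm)
        assert np.any(res.per_state_r == 0.0)

    def test_posterior_scoring_flag(self):
        labels = np.random.default_rng(11).integers(0, 3, 200)
        truth = _seq_from_labels(labels, 3)
        inferred = _stc(labels, 3)  # posteriors are one-hot == indicators
        perm = match_states(inferred, truth)
        hard = matched_correlation(inferred, truth, perm)
        soft = matched_correlation(inferred, truth, perm, use_posteriors=True)
        assert soft.mean_r == pytest.approx(hard.mean_r)

    def test_embedded_offset_crops_truth(self):
        labels = np.arange(10) % 2
        truth = _seq_from_labels(labels, 2)
        inferred = _stc(labels[1:9], 2, offset=1)
        res = matched_correlation(inferred, truth, match_states(inferred, truth))
        assert res.mean_r == pytest.approx(1.0)


class TestWelchAnova:
    def test_equal_variance_limit_matches_classical(self):
        """With exactly equal group variances and sizes, Welch's F equals
        the classical one-way F up to Welch's finite-sample denominator
        1 + 2(k-2)/(k^2-1)*Lambda (which -> 1 as n grows); the identity
        holds to 1e-10."""
        from scipy.stats import f_oneway
        rng = np.random.default_rng(5)
        base = rng.standard_normal(12)
        groups = [base + shift for shift in (0.0, 0.5, 1.3)]
        F, df1, df2, p = welch_anova(groups)
        F_classic = f_oneway(*groups).statistic
        k, n = 3, 12
        lam = sum((1 - 1 / k) ** 2 / (n - 1) for _ in range(k))
        corr = 1 + 2 * (k - 2) / (k**2 - 1) * lam
        assert F * corr == pytest.approx(F_classic, abs=1e-10)
        assert df1 == 2

    def test_manual_formula_oracle(self):
        """Hand-computed Welch statistic for a fixed 3-group fixture."""
        groups = [np.array([1.0, 2.0, 3.0, 4.0]),
                  np.array([2.0, 4.0, 6.0]),
                  np.array([5.0, 5.5, 6.5, 7.0, 8.0])]
        w = [g.size / g.var(ddof=1) for g in groups]
        mw = sum(wi * g.mean() for wi, g in zip(w, groups)) / sum(w)
        k = 3
        num = sum(wi * (g.mean() - mw) ** 2 for wi, g in zip(w, groups)) / (k - 1)
        lam = sum((1 - wi / sum(w)) ** 2 / (g.size - 1) for wi, g in zip(w, groups))
        den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
        F_manual = num / den
        df2_manual = (k**2 - 1) / (3 * lam)
        F, df1, df2, p = welch_anova(groups)
        assert F == pytest.approx(F_manual, rel=1e-10)
        assert df2 == pytest.approx(df2_manual, rel=1e-10)

    def test_eighteen_groups_df1(self):
        rng = np.random.default_rng(6)
        groups = [rng.standard_normal(5) + i * 0.1 for i in range(18)]
        _, df1, _, _ = welch_anova(groups)
        assert df1 == 17

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([np.array([1.0, 1.0]), np.array([1.0, 2.0])])


class TestGamesHowell:
    def test_identical_groups_ci_straddles_zero(self):
        rng = np.random.default_rng(7)
        g = rng.standard_normal(10)
        table = games_howell([g, g.copy() + rng.standard_normal(10) * 1e-6,
                              rng.standard_normal(10)])
        row = table.iloc[0]
        assert abs(row.mean_diff) < 1e-5
        assert row.ci_lower < 0 < row.ci_upper

    def test_ci_symmetric_about_difference(self):
        rng = np.random.default_rng(8)
        table = games_howell([rng.standard_normal(8) + i for i in range(4)])
        for _, row in table.iterrows():
            assert (row.ci_upper - row.mean_diff) == pytest.approx(
                row.mean_diff - row.ci_lower, abs=1e-10)

    def test_p_values_match_pingouin(self):
        """Independent-implementation oracle: p-values agree with
        pingouin's Games-Howell on a random 3-group fixture."""
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(9)
        groups = [rng.standard_normal(9) * s + m
                  for s, m in ((1.0, 0.0), (2.0, 1.0), (0.5, 1.5))]
        table = games_howell(groups)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
        })
        ref = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for (_, mine), (_, theirs) in zip(table.iterrows(), ref.iterrows()):
            assert mine.p == pytest.approx(theirs.pval, abs=1e-6)
            assert mine.se == pytest.approx(theirs.se, rel=1e-9)
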