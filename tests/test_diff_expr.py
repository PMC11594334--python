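"""CPM, TMM factors, BH adjustment, thresholds, and the exact NB test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cernaforge.diff_expr import (
    DEResult,
    DEThresholds,
    apply_thresholds,
    bh_adjust,
    cpm,
    de_test,
    exact_nb_test,
    tmm_factors,
)
from conftest import make_matrix


class TestCpm:
    def test_definition(self):
        counts = np.zeros((3, 2), dtype=int)
        counts[0] = [10, 100]
        counts[1] = [0, 0]
        counts[2] = [999_990, 1_999_900]
        m = make_matrix(counts)
        out = cpm(m)
        assert out.iloc[0, 0] == pytest.approx(10.0)   # 10 in 1e6
        assert out.iloc[0, 1] == pytest.approx(50.0)   # 100 in 2e6
        assert (out.iloc[1] == 0).all()                # all-zero feature

    def test_log2_prior(self):
        m = make_matrix(np.array([[0, 0], [1_000_000, 2_000_000]]))
        out = cpm(m, log2=True)
        assert out.iloc[0, 0] == pytest.approx(np.log2(0.5))

    def test_zero_library_rejected(self):
        m = make_matrix(np.array([[0, 5], [0, 5]]))
        with pytest.raises(ValueError, match="library size"):
            cpm(m)


class TestTmm:
    def test_identical_libraries(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, 200)
        m = make_matrix(np.stack([col, col], axis=1))
        assert np.allclose(tmm_factors(m).values, 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, 200) + 1
        m = make_matrix(np.stack([col, 2 * col], axis=1))
        assert np.allclose(tmm_factors(m).values, 1.0)

    def test_partial_inflation_recovered(self):
        """20% of features 4-fold inflated in sample B.

        All unchanged features share M = log2(1/1.6); the inflated 20% fall in
        the trimmed upper M tail, so B's factor is 2^M = 0.625 before the
        geometric-mean rescaling. Expected pair: (sqrt(1.6), sqrt(1.6)*0.625).
        """
        base = np.full(200, 100)
        b = base.copy()
        b[:40] = 400
        m = make_matrix(np.stack([base, b], axis=1))
        f = tmm_factors(m).values
        expected = np.array([np.sqrt(1.6), np.sqrt(1.6) * (1 / 1.6)])
        assert np.allclose(f, expected, rtol=0.05)

    def test_geometric_mean_is_one(self, six_sample_matrix):
        f = tmm_factors(six_sample_matrix).values
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_all_zero_sample_rejected(self):
        counts = np.ones((5, 2), dtype=int)
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(make_matrix(counts))


class TestBH:
    def test_hand_computed_examples(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])
        # step-up on (0.01, 0.02, 0.03, 0.04): every q collapses to 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_bruteforce_stepup(self, p):
        # direct transcription of q_(i) = min_{j>=i}(p_(j) * m / j)
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        expected = [0.0] * m
        for pos, i in enumerate(order):
            expected[i] = min(
                min(p[order[k]] * m / (k + 1) for k in range(pos, m)), 1.0
            )
        assert bh_adjust(p) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestExactNbTest:
    def test_balanced_split_not_significant(self):
        assert exact_nb_test(100, 3, 100, 3, 0.1) > 0.5

    def test_extreme_split_significant(self):
        assert exact_nb_test(800, 3, 100, 3, 0.05) < 0.01

    def test_zero_total(self):
        assert exact_nb_test(0, 3, 0, 3, 0.1) == 1.0

    def test_symmetry(self):
        assert exact_nb_test(300, 3, 80, 3, 0.1) == pytest.approx(
            exact_nb_test(80, 3, 300, 3, 0.1)
        )


class TestDeTest:
    def test_identical_counts_no_signal(self):
        m = make_matrix(np.full((3, 6), 50))
        for method in ("nb_exact", "welch_logcpm"):
            for r in de_test(m, method=method):
                assert r.log2_fc == pytest.approx(0.0)

    def test_requires_two_replicates_per_group(self):
        counts = np.ones((3, 2), dtype=int) * 5
        m = make_matrix(counts)  # c1 control, c2 control -> no treated
        m.groups.update({"c2": "treated"})
        with pytest.raises(ValueError, match="2 replicates"):
            de_test(m)

    def test_planted_eightfold_detected(self):
        """8-fold change at mean ~100, dispersion 0.05, 3v3: high power."""
        rng = np.random.default_rng(7)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            mean = np.full((50, 6), 100.0)
            mean[0, 3:] *= 8  # planted feature among null features
            r = 1 / 0.05
            counts = rng.negative_binomial(r, r / (r + mean))
            m = make_matrix(counts)
            res = de_test(m, method="nb_exact")
            if res[0].p_value < 0.05:
                detected += 1
        assert detected / n_rep >= 0.95

    def test_direction_matches_sign(self, six_sample_matrix):
        for r in de_test(six_sample_matrix, method="welch_logcpm"):
            assert (r.direction == "up") == (r.log2_fc >= 0)

    def test_fdr_jointly_adjusted(self, six_sample_matrix):
        res = de_test(six_sample_matrix, method="welch_logcpm")
        p = [r.p_value for r in res]
        fdr = [r.fdr for r in res]
        assert fdr == pytest.approx(list(bh_adjust(p)))
        assert all(q >= pv - 1e-12 for pv, q in zip(p, fdr))


class TestThresholds:
    @staticmethod
    def _res(p=0.01, fdr=0.01, lfc=2.0):
        return [DEResult("f", lfc, p, fdr, 10.0, "up" if lfc >= 0 else "down")]

    def test_circ_preset_rules(self):
        circ = DEThresholds.circrna()
        assert apply_thresholds(self._res(p=0.04, lfc=np.log2(2.5)), circ) == {"f"}
        # FC exactly 2 fails the strict inequality
        assert apply_thresholds(self._res(p=0.04, lfc=1.0), circ) == set()
        assert apply_thresholds(self._res(p=0.05, lfc=2.0), circ) == set()

    def test_mrna_preset_rules(self):
        mrna = DEThresholds.mrna()
        assert apply_thresholds(self._res(fdr=0.06, lfc=np.log2(3)), mrna) == set()
        assert apply_thresholds(self._res(fdr=0.04, lfc=np.log2(3)), mrna) == {"f"}

    def test_downregulation_counts(self):
        circ = DEThresholds.circrna()
        assert apply_thresholds(self._res(p=0.01, lfc=-2.0), circ) == {"f"}

    def test_loosening_is_monotone(self):
        rng = np.random.default_rng(9)
        results = [
            DEResult(f"f{i}", float(rng.normal(0, 2)), float(rng.uniform()),
                     float(rng.uniform()), 10.0, "up")
            for i in range(100)
        ]
        tight = DEThresholds(max_p=0.05, max_fdr=0.1, min_linear_fc=2.0)
        loose = DEThresholds(max_p=0.20, max_fdr=0.5, min_linear_fc=1.2)
        assert apply_thresholds(results, tight) <= apply_thresholds(results, loose)

    def test_fc_must_exceed_one(self):
        with pytest.raises(ValueError):
            DEThresholds(max_p=0.05, max_fdr=None, min_linear_fc=1.0)
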