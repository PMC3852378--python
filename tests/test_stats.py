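import numpy as np
import pytest
from scipy import stats as sps

from fitr.stats import (
    DegenerateFocalError,
    DegenerateInputError,
    NoReferenceError,
    ZeroDenominatorError,
    empirical_p,
    filter_reference_loci,
    fit_increments,
    fit_test,
    fit_test_batch,
    fitr_component,
    fitr_increments,
    fitr_null,
    fitr_statistic,
    fitr_test,
    fitr_test_batch,
)
from fitr.wf import TrajectorySet


def make_traj(freqs, times=None):
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    if times is None:
        times = np.arange(freqs.shape[1])
    return TrajectorySet(times=np.asarray(times), freqs=freqs)


class TestFitIncrements:
    def test_constant_series_gives_zero_increments(self):
        assert np.all(fit_increments([0.5, 0.5, 0.5], [0, 1, 2]) == 0.0)

    @pytest.mark.parametrize(
        "x,t,expected",
        [
            ([0.5, 1.0], [0, 1], [0.7071067811865476]),
            ([0.5, 0.6, 0.7], [0, 1, 2], [0.14142135623730953, 0.1443375672974065]),
            ([0.5, 0.6], [0, 4], [0.05 * np.sqrt(2)]),
        ],
    )
    def test_direct_arithmetic(self, x, t, expected):
        assert fit_increments(x, t) == pytest.approx(expected, rel=1e-12)

    def test_boundary_frequency_names_offending_time(self):
        with pytest.raises(DegenerateInputError, match="time 5"):
            fit_increments([0.5, 1.0, 0.9], [0, 5, 10])


class TestFitTest:
    def test_symmetric_increments_give_zero_statistic(self):
        # construct x so that Y_2 = -Y_1 exactly
        x0, x1 = 0.5, 0.62
        y1 = (x1 - x0) / np.sqrt(2 * x0 * (1 - x0))
        x2 = x1 - y1 * np.sqrt(2 * x1 * (1 - x1))
        res = fit_test([x0, x1, x2], [0, 1, 2])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_agrees_with_generic_one_sample_t_test(self, rng):
        for _ in range(20):
            x = np.clip(0.5 + np.cumsum(rng.normal(0, 0.03, 6)), 0.05, 0.95)
            x = np.concatenate([[0.5], x])
            t = np.arange(0, 14, 2)
            res = fit_test(x, t)
            oracle = sps.ttest_1samp(fit_increments(x, t), 0.0)
            assert res.statistic == pytest.approx(oracle.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_needs_two_increments(self):
        with pytest.raises(ValueError):
            fit_test([0.4, 0.5], [0, 1])

    def test_identical_increments_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_test([0.5, 0.5, 0.5], [0, 1, 2])

    def test_batch_matches_scalar_path(self, rng):
        x = np.clip(
            0.5 + np.cumsum(rng.normal(0, 0.02, size=(50, 5)), axis=1), 0.05, 0.95
        )
        x = np.hstack([np.full((50, 1), 0.5), x])
        t = np.arange(6)
        stat, p, degen = fit_test_batch(x, t)
        assert not degen.any()
        for i in range(0, 50, 7):
            res = fit_test(x[i], t)
            assert stat[i] == pytest.approx(res.statistic, rel=1e-12)
            assert p[i] == pytest.approx(res.p_value, rel=1e-12)


class TestIncrementsAndFiltering:
    def test_constant_frequencies_all_valid_zero_increments(self):
        inc = fitr_increments(make_traj([[0.5, 0.5], [0.3, 0.3]]))
        assert np.all(inc.d == 0.0)
        assert inc.valid.all()

    def test_single_step_standardization(self):
        inc = fitr_increments(make_traj([0.5, 0.75]))
        assert inc.d[0, 0] == pytest.approx(0.5)

    def test_fixed_reference_is_flagged_not_dropped(self):
        inc = fitr_increments(make_traj([[0.5, 0.6, 0.7], [0.4, 0.0, 0.0]]))
        assert inc.valid[0] and not inc.valid[1]
        assert inc.d.shape == (2, 2)

    def test_focal_fixation_before_last_interval_raises(self):
        with pytest.raises(DegenerateFocalError):
            fitr_increments(make_traj([[0.5, 1.0, 1.0], [0.4, 0.5, 0.6]]))

    def test_filter_keeps_clean_references(self):
        inc = fitr_increments(make_traj([[0.5, 0.6], [0.4, 0.5], [0.2, 0.3]]))
        out = filter_reference_loci(inc)
        assert out.R == 2 and out.removed == ()

    def test_filter_removes_references_that_hit_boundaries(self):
        inc = fitr_increments(
            make_traj(
                [[0.5, 0.6, 0.7], [0.4, 0.0, 0.0], [0.2, 0.3, 1.0], [0.4, 0.5, 0.6]]
            )
        )
        out = filter_reference_loci(inc)
        # a reference that reaches a boundary at any sampled time is removed,
        # including locus 2, which only fixes at the final time
        assert out.removed == (1, 2)
        assert out.R == 1 and tuple(out.locus_index) == (0, 3)

    def test_all_references_fixed_is_an_error(self):
        inc = fitr_increments(make_traj([[0.5, 0.6], [1.0, 1.0]]))
        with pytest.raises(NoReferenceError):
            filter_reference_loci(inc)


class TestFitrStatistic:
    def test_component_trivial_cases(self):
        assert fitr_component(0.0, [0.1, 0.2]) == 0.0
        assert fitr_component(0.3, [0.3]) == pytest.approx(1.0)

    def test_component_arithmetic(self):
        assert fitr_component(0.3, [0.1, -0.2, 0.2]) == pytest.approx(
            np.sqrt(3.0), rel=1e-12
        )

    def test_component_zero_denominator(self):
        with pytest.raises(ZeroDenominatorError):
            fitr_component(0.2, [0.0, 0.0])

    def test_statistic_zero_when_focal_flat(self):
        inc = fitr_increments(make_traj([[0.5, 0.5, 0.5], [0.3, 0.4, 0.5]]))
        assert fitr_statistic(inc) == 0.0

    def test_single_interval_equals_component(self):
        inc = fitr_increments(make_traj([[0.5, 0.6], [0.3, 0.4], [0.5, 0.45]]))
        assert fitr_statistic(inc) == pytest.approx(
            fitr_component(inc.d[0, 0], inc.d[1:, 0])
        )

    def test_summed_and_pooled_forms_agree(self, rng):
        # per-interval t-sum vs the equivalent single-expression form
        for _ in range(25):
            L, R = rng.integers(1, 7), rng.integers(1, 12)
            d = rng.normal(size=(R + 1, L))
            inc_like = type("I", (), {"d": d, "L": L, "R": R})
            lhs = fitr_statistic(inc_like)
            rhs = np.sum(
                d[0] / np.sqrt((L / R) * np.sum(d[1:] ** 2, axis=0))
            )
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_per_interval_scale_invariance(self, rng):
        # multiplying every locus at one interval by c leaves |t^(i)| unchanged:
        # the per-interval drift scale (hence N_i and dt_i) cancels
        d = rng.normal(size=(6, 4))
        base = [fitr_component(d[0, i], d[1:, i]) for i in range(4)]
        for c in (2.0, -3.0, 1e-3):
            scaled = d.copy()
            scaled[:, 2] *= c
            comps = [fitr_component(scaled[0, i], scaled[1:, i]) for i in range(4)]
            assert abs(comps[2]) == pytest.approx(abs(base[2]), rel=1e-12)
            assert comps[:2] == pytest.approx(base[:2])


class TestFitrNull:
    def test_single_interval_null_is_student_t(self, rng):
        draws = fitr_null(1, 8, M=100_000, rng=rng)
        assert sps.kstest(draws, sps.t(8).cdf).pvalue > 0.01

    def test_null_moments(self, rng):
        draws = fitr_null(4, 10, M=100_000, rng=rng)
        assert draws.mean() == pytest.approx(0.0, abs=3 * np.sqrt(1.25 / 1e5))
        assert draws.var() == pytest.approx(10 / 8, abs=0.03)

    def test_seeded_null_is_cached_and_reproducible(self):
        a = fitr_null(3, 5, M=2000, seed=11)
        b = fitr_null(3, 5, M=2000, seed=11)
        assert a is b
        c = fitr_null(3, 5, M=2000, seed=12)
        assert not np.array_equal(a, c)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            fitr_null(0, 5)


class TestFitrTest:
    def test_single_interval_uses_analytic_student_t(self, rng):
        traj = make_traj(np.vstack([[0.5, 0.7], rng.uniform(0.3, 0.7, (5, 2))]))
        res = fitr_test(traj)
        expect = 2 * sps.t.sf(abs(res.statistic), 5)
        assert res.p_value == pytest.approx(expect, rel=1e-12)
        assert res.null == (1, 5, "analytic")

    def test_empirical_p_uses_add_one_estimator(self, rng):
        null = rng.standard_t(5, size=999)
        assert empirical_p(np.inf, null) == pytest.approx(1 / 1000)
        assert empirical_p(0.0, null) == 1.0

    def test_reference_removal_reported(self, rng):
        freqs = np.vstack(
            [[0.5, 0.6, 0.7], rng.uniform(0.3, 0.7, (3, 3)), [[0.4, 0.0, 0.0]]]
        )
        res = fitr_test(make_traj(freqs), M=2000, rng=rng)
        assert res.R_used == 3
        assert res.removed_loci == (4,)
        assert 0 < res.p_value <= 1

    def test_flat_references_zero_denominator(self):
        with pytest.raises(ZeroDenominatorError):
            fitr_test(make_traj([[0.5, 0.6], [0.3, 0.3]]))

    def test_no_reference_locus_is_an_error(self):
        with pytest.raises(NoReferenceError):
            fitr_test(make_traj([0.5, 0.6]))

    def test_batch_matches_scalar_path(self, rng):
        freqs = np.clip(
            0.5 + np.cumsum(rng.normal(0, 0.03, size=(30, 6, 4)), axis=2), 0.05, 0.95
        )
        freqs[:, :, 0] = 0.5
        stat, p, r_used, degen = fitr_test_batch(freqs, M=50_000,
                                                 null_rng=np.random.default_rng(5))
        assert not degen.any()
        assert np.all(r_used == 5)
        for i in range(0, 30, 5):
            res = fitr_test(make_traj(freqs[i]), M=50_000,
                            rng=np.random.default_rng(9))
            assert stat[i] == pytest.approx(res.statistic, rel=1e-10)
            # same statistic, independent nulls: p agrees to Monte-Carlo error
            assert p[i] == pytest.approx(res.p_value, abs=0.01)
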