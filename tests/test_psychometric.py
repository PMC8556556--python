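"""Crowding-function fitting: recovery, shared slopes, criterion readouts."""

import math

import numpy as np
import pytest

import crowdkit as ck
from crowdkit.geometry import CriterionSpec, UNFLANKED
from tests.conftest import logistic_cells


class TestSingleFit:
    def test_noiseless_generative_identity(self):
        cells = logistic_cells(mu=0.0, beta=3.0, guess=0.04, asymptote=1.0, n=100000)
        res = ck.CrowdingFunctionModel(cells, asymptote=1.0, seed=0).fit(bootstrap=False)
        assert res.mu == pytest.approx(0.0, abs=1e-3)
        assert res.beta == pytest.approx(3.0, abs=1e-3)

    def test_cumulative_gaussian_form_recovers_its_own_data(self):
        import scipy.special as sp

        xs = np.linspace(-0.8, 0.8, 7)
        task = ck.TaskSpec(4)
        cells = [
            ck.StimulusCell(5.0, 0.5, 10.0**x, task,
                            int(round((0.25 + 0.75 * sp.ndtr(2.0 * (x - 0.1))) * 100000)), 100000)
            for x in xs
        ]
        res = ck.CrowdingFunctionModel(cells, form="cumulative_gaussian", asymptote=1.0, seed=0).fit(
            bootstrap=False
        )
        assert res.mu == pytest.approx(0.1, abs=1e-3)
        assert res.beta == pytest.approx(2.0, abs=5e-3)

    def test_unflanked_cells_anchor_the_asymptote(self):
        cells = logistic_cells(mu=0.0, beta=3.0, guess=0.25, asymptote=0.9, n=100000)
        cells.append(ck.StimulusCell(5.0, 0.5, UNFLANKED, ck.TaskSpec(4), 90000, 100000))
        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        assert res.asymptote == pytest.approx(0.9, abs=5e-3)

    def test_mle_invariant_to_cell_order(self):
        cells = logistic_cells(seed=7)
        res_fwd = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        res_rev = ck.CrowdingFunctionModel(cells[::-1], seed=0).fit(bootstrap=False)
        assert res_fwd.mu == pytest.approx(res_rev.mu, abs=1e-6)
        assert res_fwd.beta == pytest.approx(res_rev.beta, abs=1e-5)

    def test_fit_deterministic_given_seed(self):
        cells = logistic_cells(seed=3)
        a = ck.CrowdingFunctionModel(cells, seed=11).fit(n_boot=25)
        b = ck.CrowdingFunctionModel(cells, seed=11).fit(n_boot=25)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.boot, b.boot)

    def test_predictions_monotone_in_spacing(self):
        cells = logistic_cells(seed=5)
        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        grid = np.logspace(-1.2, 1.2, 80)
        preds = res.predict(grid)
        assert np.all(np.diff(preds) >= -1e-12)
        assert np.all(preds >= res.guess - 1e-12)
        assert np.all(preds <= res.asymptote + 1e-12)

    def test_all_ceiling_data_flagged_unconstrained(self):
        task = ck.TaskSpec(4)
        cells = [ck.StimulusCell(5.0, 0.5, s, task, 99, 100) for s in (0.5, 1.0, 2.0, 4.0)]
        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        assert "unconstrained" in res.flags

    def test_too_few_distinct_spacings_rejected(self):
        task = ck.TaskSpec(4)
        cells = [ck.StimulusCell(5.0, 0.5, s, task, 50, 100) for s in (1.0, 2.0)]
        with pytest.raises(ValueError):
            ck.CrowdingFunctionModel(cells)

    def test_mixed_tasks_rejected(self):
        cells = logistic_cells()
        cells[0] = ck.StimulusCell(5.0, 0.5, cells[0].spacing, ck.TaskSpec(10), 50, 100)
        with pytest.raises(ValueError):
            ck.CrowdingFunctionModel(cells)

    def test_summary_mentions_parameters(self):
        res = ck.CrowdingFunctionModel(logistic_cells(seed=1), seed=0).fit(n_boot=25)
        text = res.summary()
        assert "beta" in text and "asymptote" in text


class TestCriticalSpacingReadout:
    def test_half_amplitude_criterion_reads_off_mu(self):
        # absolute 0.52 is the half-amplitude point of a g=0.04, A=1 logistic,
        # which sits at mu by construction (here 10^0 = 1 degree)
        cells = logistic_cells(mu=0.0, beta=3.0, guess=0.04, asymptote=1.0, n=100000)
        res = ck.CrowdingFunctionModel(cells, asymptote=1.0, seed=0).fit(bootstrap=False)
        est = res.critical_spacing(CriterionSpec("absolute", 0.52), alpha=None)
        assert est.value == pytest.approx(1.0, rel=1e-3)

    def test_closed_form_inversion_matches_bisection(self):
        cells = logistic_cells(mu=0.1, beta=4.0, guess=0.25, asymptote=0.97, n=100000)
        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        crit = CriterionSpec("proportion_of_asymptote", 0.7)
        est = res.critical_spacing(crit, alpha=None)
        # independent oracle: bisection on the fitted prediction function
        level = ck.criterion_level(crit, res.guess, res.asymptote)
        lo, hi = 1e-4, 1e4
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if res.predict(mid)[0] < level:
                lo = mid
            else:
                hi = mid
        assert est.value == pytest.approx(math.sqrt(lo * hi), rel=1e-6)

    def test_level_above_asymptote_unattainable(self):
        cells = logistic_cells(mu=0.0, beta=3.0, guess=0.25, asymptote=0.7, n=100000)
        cells.append(ck.StimulusCell(5.0, 0.5, UNFLANKED, ck.TaskSpec(4), 70000, 100000))
        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        est = res.critical_spacing(CriterionSpec("absolute", 0.8), alpha=None)
        assert not est.attainable
        assert math.isnan(est.value)

    def test_monotone_in_proportion_of_asymptote_level(self):
        res = ck.CrowdingFunctionModel(logistic_cells(seed=9), seed=0).fit(bootstrap=False)
        values = [
            res.critical_spacing(CriterionSpec("proportion_of_asymptote", q), alpha=None).value
            for q in (0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_invariant_to_nominal_vs_absolute_expression(self):
        # rescaling all spacings by a constant (deg -> nominal units) shifts mu
        # by the log of the constant and leaves critical spacing consistent
        cells = logistic_cells(seed=21)
        size = 0.5
        scaled = [
            ck.StimulusCell(c.eccentricity, c.letter_size, c.spacing / size, c.task, c.n_correct, c.n_trials)
            for c in cells
        ]
        crit = CriterionSpec("proportion_of_asymptote", 0.6)
        cs_abs = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False).critical_spacing(crit, alpha=None)
        cs_nom = ck.CrowdingFunctionModel(scaled, seed=0).fit(bootstrap=False).critical_spacing(crit, alpha=None)
        assert cs_nom.value * size == pytest.approx(cs_abs.value, rel=1e-3)


class TestSharedSlope:
    def test_two_identical_groups_pool_to_single_fit(self):
        g = logistic_cells(seed=5)
        single = ck.CrowdingFunctionModel(g, seed=0).fit(bootstrap=False)
        dup = ck.SharedSlopeModel([g, g], seed=0).fit()
        assert dup.beta_shared == pytest.approx(single.beta, abs=1e-3)

    def test_shift_recovery_and_ordering(self):
        mus = (-0.3, -0.1, 0.1, 0.3)
        groups = [logistic_cells(mu=m, seed=100 + i) for i, m in enumerate(mus)]
        res = ck.SharedSlopeModel(groups, asymptote=1.0, seed=0).fit(n_boot=99)
        fitted = [g["mu"] for g in res.per_group]
        assert fitted == sorted(fitted)
        lo, hi = res.conf_int_beta()
        assert lo <= 3.0 <= hi

    def test_grossly_different_slopes_inflate_deviance(self):
        alike = [logistic_cells(beta=3.0, seed=s) for s in (0, 1)]
        unlike = [logistic_cells(beta=1.0, seed=2), logistic_cells(beta=6.0, seed=3)]
        d_alike = ck.SharedSlopeModel(alike, seed=0).fit().deviance_vs_free_slopes
        d_unlike = ck.SharedSlopeModel(unlike, seed=0).fit().deviance_vs_free_slopes
        assert d_unlike > d_alike + 5.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            ck.SharedSlopeModel([logistic_cells()])


class TestBootstrapCalibration:
    def test_location_intervals_achieve_nominal_coverage(self):
        """95% parametric-bootstrap intervals on mu cover the generating value
        90-98% of the time across 200 binomial datasets at 100 trials/point."""
        import scipy.special as sp

        task = ck.TaskSpec(4)
        xs = np.linspace(-0.8, 0.8, 7)
        covered = 0
        for s in range(200):
            rng = np.random.default_rng(5000 + s)
            cells = [
                ck.StimulusCell(5.0, 0.5, 10.0**x, task,
                                int(rng.binomial(100, 0.25 + 0.75 * sp.expit(3.0 * x))), 100)
                for x in xs
            ]
            res = ck.CrowdingFunctionModel(cells, asymptote=1.0, seed=s).fit(n_boot=199)
            lo, hi = res.conf_int()["mu"]
            covered += lo <= 0.0 <= hi
        assert 180 <= covered <= 196


class TestZScoreNormalization:
    def test_equal_slope_different_asymptote_curves_collapse(self):
        # one underlying slope, asymptotes 0.95 vs 0.75: z-transformed curves
        # should agree pointwise up to binomial noise
        a = logistic_cells(mu=0.0, beta=3.0, guess=0.25, asymptote=0.95, n=100000)
        b = logistic_cells(mu=0.0, beta=3.0, guess=0.25, asymptote=0.75, n=100000)
        fit_a = ck.CrowdingFunctionModel(a, seed=0).fit(bootstrap=False)
        fit_b = ck.CrowdingFunctionModel(b, seed=0).fit(bootstrap=False)
        za = dict(ck.zscore_normalize(a, fit_a))
        zb = dict(ck.zscore_normalize(b, fit_b))
        # compare shapes after removing each curve's own asymptote z offset
        xs = sorted(za)
        da = np.diff([za[x] for x in xs])
        db = np.diff([zb[x] for x in xs])
        assert np.allclose(da > 0, db > 0)

    def test_boundary_proportions_clamped(self):
        task = ck.TaskSpec(4)
        cells = [
            ck.StimulusCell(5.0, 0.5, 0.6, task, 25, 100),  # exactly at chance
            ck.StimulusCell(5.0, 0.5, 1.2, task, 60, 100),
            ck.StimulusCell(5.0, 0.5, 2.4, task, 100, 100),  # perfect
        ]
        from scipy.special import ndtri

        res = ck.CrowdingFunctionModel(cells, seed=0).fit(bootstrap=False)
        pairs = ck.zscore_normalize(cells, res, eps=1e-3)
        zs = [z for _, z in pairs]
        assert min(zs) == pytest.approx(float(ndtri(1e-3)))
        assert max(zs) <= float(ndtri(1 - 1e-3)) + 1e-9
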