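"""Synthetic observer: determinism, convergence, staircases, fixtures."""

import math

import numpy as np
import pytest

import crowdkit as ck
from crowdkit.geometry import UNFLANKED
from crowdkit.observer import (
    ExperimentDesign,
    StaircaseRule,
    bouma_landscape_family,
    generate_bouma1970_like,
    generate_meta_dataset,
    run_staircase,
    simulate_trials,
)


def spacing_design(task, seed=0, n=100):
    return ExperimentDesign(
        paradigm="constant_stimuli_spacing", task=task, n_trials=n, seed=seed,
        letter_size=0.5, spacings=(0.6, 0.9, 1.4, 2.1, 3.2, UNFLANKED),
    )


class TestConstantStimuli:
    def test_same_seed_identical_tables(self, landscape_params, task4):
        a = simulate_trials(landscape_params, spacing_design(task4, seed=42))
        b = simulate_trials(landscape_params, spacing_design(task4, seed=42))
        assert a == b

    def test_different_seeds_differ(self, landscape_params, task4):
        a = simulate_trials(landscape_params, spacing_design(task4, seed=1))
        b = simulate_trials(landscape_params, spacing_design(task4, seed=2))
        assert any(x.n_correct != y.n_correct for x, y in zip(a, b))

    def test_adding_cells_preserves_existing_substreams(self, landscape_params, task4):
        short = spacing_design(task4, seed=9)
        longer = ExperimentDesign(
            paradigm="constant_stimuli_spacing", task=task4, n_trials=100, seed=9,
            letter_size=0.5, spacings=short.spacings + (6.4,),
        )
        a = simulate_trials(landscape_params, short)
        b = simulate_trials(landscape_params, longer)
        assert a == b[: len(a)]

    def test_large_n_converges_to_landscape_probability(self, landscape_params, task4):
        design = ExperimentDesign(
            paradigm="constant_stimuli_spacing", task=task4, n_trials=10000, seed=0,
            letter_size=0.02, spacings=(0.5,),  # tiny letters: p at guess rate
        )
        [cell] = simulate_trials(landscape_params, design)
        p = 0.25
        se = math.sqrt(p * (1 - p) / 10000)
        assert abs(cell.proportion_correct - p) < 3 * se

    def test_nominal_size_design_covaries_spacing(self, landscape_params, task4):
        design = ExperimentDesign(
            paradigm="constant_stimuli_size_at_nominal", task=task4, n_trials=50,
            seed=0, nominal_multiple=2.0, sizes=(0.2, 0.4, 0.8),
        )
        cells = simulate_trials(landscape_params, design)
        for c in cells:
            assert c.spacing == pytest.approx(2.0 * c.letter_size)

    def test_overlap_and_zero_trial_designs_rejected(self, task4):
        with pytest.raises(ValueError):
            ExperimentDesign(paradigm="constant_stimuli_spacing", task=task4,
                             n_trials=100, seed=0, letter_size=0.5, spacings=(0.3,))
        with pytest.raises(ValueError):
            ExperimentDesign(paradigm="constant_stimuli_spacing", task=task4,
                             n_trials=0, seed=0, letter_size=0.5, spacings=(0.6,))


class TestStaircase:
    def test_deterministic_step_observer_converges_to_step_location(self):
        step_at = 0.5  # log10 size of the 0 -> 1 performance step

        def observer(size, spacing):
            return 1.0 if math.log10(size) >= step_at else 0.0

        run = run_staircase(observer, 2.0, StaircaseRule(), seed=0, start_log_size=1.0)
        assert run.converged
        assert abs(run.threshold_log_size - step_at) <= StaircaseRule().step

    def test_zero_step_size_rejected(self):
        with pytest.raises(ValueError):
            StaircaseRule(step=0.0)

    def test_three_down_one_up_targets_79_percent(self):
        assert StaircaseRule().target_pcorrect == pytest.approx(0.7937, abs=1e-4)

    def test_trial_record_aggregates_for_refitting(self, landscape_params, task4):
        run = run_staircase(landscape_params, 2.0, seed=5)
        cells = run.to_cells(landscape_params, task4)
        assert sum(c.n_trials for c in cells) == run.n_trials
        assert all(c.spacing == pytest.approx(2.0 * c.letter_size) for c in cells)

    def test_nonconvergence_flagged(self, landscape_params):
        rule = StaircaseRule(max_trials=5)
        run = run_staircase(landscape_params, 2.0, rule, seed=0)
        assert not run.converged


class TestBoumaFixture:
    def test_reproducible_and_shaped_like_the_classic_design(self):
        fam = bouma_landscape_family(eccs=(3.0, 5.0))
        a = generate_bouma1970_like(fam, seed=7)
        b = generate_bouma1970_like(fam, seed=7)
        assert a == b
        eccs = sorted({c.eccentricity for c in a})
        assert eccs == [3.0, 5.0]
        per_ecc = [c for c in a if c.eccentricity == 3.0]
        assert len(per_ecc) == 7  # six slot multiples + unflanked
        assert all(c.n_trials == 100 for c in per_ecc)
        assert all(c.task.n_alternatives == 25 for c in per_ecc)
        assert all(c.letter_size == 0.23 for c in per_ecc)

    def test_asymptotes_decline_with_eccentricity(self):
        fam = bouma_landscape_family(eccs=(3.0, 7.0))
        cells = generate_bouma1970_like(fam, seed=0, n_per_point=2000)
        unf = {c.eccentricity: c.proportion_correct for c in cells if c.is_unflanked}
        assert unf[7.0] < unf[3.0]

    def test_calibrated_hinges_encode_the_generating_rule(self):
        crit = ck.CriterionSpec("proportion_of_asymptote", 0.9)
        fam = bouma_landscape_family(eccs=(3.0, 5.0), bouma_fraction=0.4, criterion=crit)
        from crowdkit.landscape import FlankedAcuityLandscape

        for ecc, params in fam.items():
            cs = FlankedAcuityLandscape(params).critical_spacing_at_size(0.23, crit)
            assert cs.value == pytest.approx(0.4 * ecc, rel=1e-6)


class TestMetaFixture:
    def test_zero_noise_points_exactly_on_line(self):
        pts = generate_meta_dataset(true_slope=-0.16, true_intercept=0.3, noise_sd=0.0)
        for p in pts:
            assert p.bouma_fraction == pytest.approx(0.3 - 0.16 * math.log10(p.duration), abs=1e-12)

    def test_seeds_change_tables(self):
        a = generate_meta_dataset(seed=0)
        b = generate_meta_dataset(seed=1)
        assert any(x.bouma_fraction != y.bouma_fraction for x, y in zip(a, b))

    def test_planted_offset_raises_only_the_prefix(self):
        base = generate_meta_dataset(noise_sd=0.0)
        planted = generate_meta_dataset(noise_sd=0.0, planted_prefix_offset=0.2, n_prefix=2)
        diffs = [p.bouma_fraction - b.bouma_fraction for p, b in zip(planted, base)]
        assert diffs[0] == pytest.approx(0.2) and diffs[1] == pytest.approx(0.2)
        assert all(d == pytest.approx(0.0, abs=1e-12) for d in diffs[2:])
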