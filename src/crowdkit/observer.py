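"""Synthetic observer: simulate crowding experiments from a landscape.

Every generator is a pure function of its parameters and a seed. Trials
are independent Bernoulli draws with success probability given by the
landscape's predicted proportion correct; per-cell random substreams
are derived deterministically from the run seed and the cell index, so
adding cells to a design never perturbs existing cells.

Supported designs mirror the classic paradigms: constant stimuli over
flanker spacing at fixed size (Bouma-style crowding functions, 100
trials per point, 25-alternative letter identification), constant
stimuli over size at fixed nominal spacing (flanked acuity), an
adaptive size staircase along the fixed-nominal-spacing diagonal
(3-down-1-up by default, converging near 79.4% correct), and a
study-level (duration, Bouma fraction) meta-analysis table generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .geometry import UNFLANKED, CriterionSpec, TaskSpec, center_to_center, slots_to_edge_gap
from .landscape import FlankedAcuityLandscape, HingeSpec, LandscapeParams
from .meta import MetaPoint
from .psychometric import StimulusCell

__all__ = [
    "ExperimentDesign",
    "StaircaseRule",
    "StaircaseRun",
    "simulate_trials",
    "run_staircase",
    "generate_bouma1970_like",
    "bouma_landscape_family",
    "generate_meta_dataset",
]


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic substream for cell ``index`` of a run seeded with ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


@dataclass(frozen=True)
class ExperimentDesign:
    """A constant-stimuli design evaluated against a landscape.

    paradigms
    ---------
    constant_stimuli_spacing
        one ``letter_size``, a list of center-to-center ``spacings``
        (math.inf allowed for unflanked cells).
    constant_stimuli_size_at_nominal
        one ``nominal_multiple``, a list of ``sizes``; the absolute
        spacing co-varies as m x size.
    """

    paradigm: Literal["constant_stimuli_spacing", "constant_stimuli_size_at_nominal"]
    task: TaskSpec
    n_trials: int
    seed: int
    letter_size: float | None = None
    spacings: tuple[float, ...] = ()
    nominal_multiple: float | None = None
    sizes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.paradigm == "constant_stimuli_spacing":
            if self.letter_size is None or self.letter_size <= 0:
                raise ValueError("constant_stimuli_spacing needs a positive letter_size")
            if len(self.spacings) == 0:
                raise ValueError("constant_stimuli_spacing needs spacings")
            for s in self.spacings:
                if not math.isinf(s) and s < self.letter_size:
                    raise ValueError(f"spacing {s} overlaps letter size {self.letter_size}")
        elif self.paradigm == "constant_stimuli_size_at_nominal":
            if self.nominal_multiple is None or self.nominal_multiple < 1:
                raise ValueError("constant_stimuli_size_at_nominal needs nominal_multiple >= 1")
            if len(self.sizes) == 0:
                raise ValueError("constant_stimuli_size_at_nominal needs sizes")
        else:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")

    def cells_geometry(self) -> list[tuple[float, float]]:
        """(letter_size, spacing) per cell, in design order."""
        if self.paradigm == "constant_stimuli_spacing":
            assert self.letter_size is not None
            return [(self.letter_size, s) for s in self.spacings]
        assert self.nominal_multiple is not None
        return [(s, self.nominal_multiple * s) for s in self.sizes]


def simulate_trials(params: LandscapeParams, design: ExperimentDesign) -> list[StimulusCell]:
    """Simulate binomial counts for each cell of a constant-stimuli design."""
    scape = FlankedAcuityLandscape(params)
    cells = []
    for i, (size, spacing) in enumerate(design.cells_geometry()):
        p = scape.predict_pcorrect(size, spacing)  # raises on overlap geometry
        rng = _cell_rng(design.seed, i)
        k = int(rng.binomial(design.n_trials, p))
        cells.append(
            StimulusCell(
                eccentricity=params.eccentricity,
                letter_size=size,
                spacing=spacing,
                task=design.task,
                n_correct=k,
                n_trials=design.n_trials,
            )
        )
    return cells


# --- adaptive staircase -------------------------------------------------------


@dataclass(frozen=True)
class StaircaseRule:
    """Up/down rule on log10 letter size.

    3-down-1-up converges near 79.4% correct, matching the 79% size-
    threshold criterion of flanked-acuity studies; the convergence level
    is 0.5 ** (1 / n_down).
    """

    n_down: int = 3
    n_up: int = 1
    step: float = 0.05  # log10 size units
    n_reversals: int = 16
    n_average: int = 6
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step size must be positive")
        if self.n_down < 1 or self.n_up < 1:
            raise ValueError("n_down and n_up must be >= 1")
        if self.n_average > self.n_reversals:
            raise ValueError("cannot average more reversals than are collected")

    @property
    def target_pcorrect(self) -> float:
        return 0.5 ** (1.0 / self.n_down)


@dataclass
class StaircaseRun:
    """Trial record and threshold estimate from one staircase."""

    log_sizes: np.ndarray
    responses: np.ndarray  # 1 correct, 0 incorrect
    reversal_log_sizes: np.ndarray
    threshold_log_size: float
    converged: bool
    rule: StaircaseRule
    nominal_multiple: float

    @property
    def threshold_size(self) -> float:
        return 10.0**self.threshold_log_size

    @property
    def n_trials(self) -> int:
        return len(self.log_sizes)

    def to_cells(self, params: LandscapeParams, task: TaskSpec) -> list[StimulusCell]:
        """Aggregate the trial record to StimulusCell counts for re-fitting."""
        out = []
        for ls in np.unique(np.round(self.log_sizes, 10)):
            mask = np.isclose(self.log_sizes, ls)
            size = 10.0**ls
            out.append(StimulusCell(
                eccentricity=params.eccentricity, letter_size=size,
                spacing=self.nominal_multiple * size, task=task,
                n_correct=int(self.responses[mask].sum()), n_trials=int(mask.sum()),
            ))
        return out


def run_staircase(
    params: LandscapeParams | Callable[[float, float], float],
    nominal_multiple: float,
    rule: StaircaseRule = StaircaseRule(),
    seed: int = 0,
    start_log_size: float | None = None,
) -> StaircaseRun:
    """Adaptive size staircase along the fixed-nominal-spacing diagonal.

    ``params`` may be a :class:`LandscapeParams` or any callable
    (size, spacing) -> p; the latter admits deterministic test
    observers. The threshold is the mean of the last ``rule.n_average``
    reversal log sizes; non-convergence within ``rule.max_trials`` is
    flagged via ``converged``.
    """
    if callable(params) and not isinstance(params, LandscapeParams):
        prob = params
        if start_log_size is None:
            raise ValueError("start_log_size required with a callable observer")
        start = start_log_size
    else:
        scape = FlankedAcuityLandscape(params)
        prob = scape.predict_pcorrect
        # start well above threshold so the first reversals bracket it
        start = start_log_size if start_log_size is not None else scape.mu_inf + 1.0
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    log_size = float(start)
    consecutive_correct = 0
    consecutive_wrong = 0
    last_direction = 0  # -1 down, +1 up
    log_sizes: list[float] = []
    responses: list[int] = []
    reversals: list[float] = []
    while len(reversals) < rule.n_reversals and len(log_sizes) < rule.max_trials:
        size = 10.0**log_size
        p = prob(size, nominal_multiple * size)
        correct = int(rng.random() < p)
        log_sizes.append(log_size)
        responses.append(correct)
        move = 0
        if correct:
            consecutive_correct += 1
            consecutive_wrong = 0
            if consecutive_correct >= rule.n_down:
                move = -1
                consecutive_correct = 0
        else:
            consecutive_wrong += 1
            consecutive_correct = 0
            if consecutive_wrong >= rule.n_up:
                move = +1
                consecutive_wrong = 0
        if move != 0:
            if last_direction != 0 and move != last_direction:
                reversals.append(log_size)
            last_direction = move
            log_size += move * rule.step
    converged = len(reversals) >= rule.n_reversals
    tail = reversals[-rule.n_average:] if reversals else [log_size]
    return StaircaseRun(
        log_sizes=np.array(log_sizes),
        responses=np.array(responses),
        reversal_log_sizes=np.array(reversals),
        threshold_log_size=float(np.mean(tail)),
        converged=converged,
        rule=rule,
        nominal_multiple=nominal_multiple,
    )


# --- Bouma-1970-style fixture -------------------------------------------------


def bouma_landscape_family(
    eccs: Sequence[float] = (1.0, 3.0, 5.0, 7.0),
    bouma_fraction: float = 0.4,
    letter_size: float = 0.23,
    criterion: CriterionSpec = CriterionSpec("proportion_of_asymptote", 0.9),
    beta_shared: float = 6.0,
    guess: float = 1.0 / 25.0,
    asymptote: float = 0.99,
    crowded_slope: float = -0.8,
    acuity_foveal: float = 0.05,
    acuity_e2: float = 1.5,
) -> dict[float, LandscapeParams]:
    """A family of landscapes encoding a constant generating Bouma fraction.

    Peripheral acuity declines as S0(ecc) = acuity_foveal * (1 + ecc /
    acuity_e2), so a fixed letter size yields declining asymptotes with
    eccentricity, as in Bouma's constant-size design. The hinge of each
    landscape is calibrated by bisection so that the analytic
    horizontal-slice critical spacing at ``letter_size`` under
    ``criterion`` equals ``bouma_fraction * ecc`` — the generating rule
    that end-to-end analyses should recover.
    """
    out: dict[float, LandscapeParams] = {}
    for ecc in eccs:
        target = bouma_fraction * ecc
        s0 = acuity_foveal * (1.0 + ecc / acuity_e2)

        def cs_at(hinge_loc: float) -> float:
            params = LandscapeParams(
                eccentricity=ecc, unflanked_threshold_size=s0, beta_shared=beta_shared,
                guess=guess, asymptote=asymptote,
                hinge=HingeSpec(hinge_location=hinge_loc, crowded_slope=crowded_slope),
            )
            est = FlankedAcuityLandscape(params).critical_spacing_at_size(letter_size, criterion)
            if est.measurable:
                return est.value
            # ceiling (hinge too low: no crowding at this size) sorts below any
            # target, floor (criterion unreachable) above
            return -math.inf if est.status == "ceiling" else math.inf

        lo, hi = math.log10(1.05), 4.0
        if not (cs_at(lo) < target < cs_at(hi)):
            raise ValueError(
                f"cannot calibrate hinge for ecc {ecc}: target spacing {target:.3g} deg "
                "outside the reachable range"
            )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if cs_at(mid) < target:
                lo = mid
            else:
                hi = mid
        out[ecc] = LandscapeParams(
            eccentricity=ecc, unflanked_threshold_size=s0, beta_shared=beta_shared,
            guess=guess, asymptote=asymptote,
            hinge=HingeSpec(hinge_location=0.5 * (lo + hi), crowded_slope=crowded_slope),
        )
    return out


def generate_bouma1970_like(
    params_per_ecc: dict[float, LandscapeParams],
    slot_deg: float = 0.29,
    letter_size: float = 0.23,
    slot_multiples: Sequence[float] = (0, 2, 5, 8, 11, 15),
    n_per_point: int = 100,
    task: TaskSpec = TaskSpec(25),
    include_unflanked: bool = True,
    seed: int = 0,
) -> list[StimulusCell]:
    """A constant-size, constant-stimuli letter-identification table.

    Per eccentricity: one fixed letter size, spacings at multiples of
    empty letter slots (edge gap = multiple x slot width, converted to
    center-to-center) plus an unflanked point, 100 trials per point,
    25-alternative identification — Bouma's design. Asymptotes decline
    with eccentricity when the landscape family encodes acuity decline.
    """
    cells: list[StimulusCell] = []
    index = 0
    for ecc in sorted(params_per_ecc):
        params = params_per_ecc[ecc]
        scape = FlankedAcuityLandscape(params)
        spacings = [center_to_center(slots_to_edge_gap(m, slot_deg), letter_size) for m in slot_multiples]
        if include_unflanked:
            spacings.append(UNFLANKED)
        for spacing in spacings:
            p = scape.predict_pcorrect(letter_size, spacing)
            rng = _cell_rng(seed, index)
            k = int(rng.binomial(n_per_point, p))
            cells.append(StimulusCell(
                eccentricity=ecc, letter_size=letter_size, spacing=spacing,
                task=task, n_correct=k, n_trials=n_per_point,
            ))
            index += 1
    return cells


# --- meta-analysis fixture ----------------------------------------------------


def generate_meta_dataset(
    true_slope: float = -0.16,
    true_intercept: float = 0.30,
    durations: Sequence[float] = (0.013, 0.027, 0.047, 0.058, 0.15, 0.2, 0.25, 0.36, 0.5, 1.0),
    noise_sd: float = 0.02,
    planted_prefix_offset: float = 0.0,
    n_prefix: int = 1,
    n_flankers: str = "4",
    seed: int = 0,
) -> list[MetaPoint]:
    """Semilog-linear Bouma fractions b = intercept + slope * log10(t) + noise.

    ``planted_prefix_offset`` raises the ``n_prefix`` shortest-duration
    points, emulating the elevation seen at the very shortest exposures,
    which the iterative prefix-exclusion rule should detect and remove.
    """
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be positive")
    pts = []
    order = sorted(range(len(durations)), key=lambda i: durations[i])
    prefix = set(order[:n_prefix]) if planted_prefix_offset else set()
    for i, t in enumerate(durations):
        rng = _cell_rng(seed, i)
        b = true_intercept + true_slope * math.log10(t) + rng.normal(0.0, noise_sd)
        if i in prefix:
            b += planted_prefix_offset
        pts.append(MetaPoint(
            study=f"synthetic-{i:02d}", duration=float(t),
            bouma_fraction=max(b, 1e-3), n_flankers=n_flankers,
        ))
    return pts
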