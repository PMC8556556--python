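"""The flanked-acuity landscape: performance over the size x spacing plane.

The model composes two ingredients:

1.  A base psychometric function over log10 letter size with one shared
    slope ``beta`` across all conditions:

        p(size, spacing) = g + (A - g) * F(beta * (log10 size - mu(spacing, size)))

2.  A hinged ("clipped") line giving the location ``mu`` of that
    function as a function of flanker separation on a transformed
    abscissa t: below the hinge (close flankers) the location rises
    with slope ``crowded_slope`` (default -0.8) as t decreases; at and
    beyond the hinge the flankers are outside the crowding zone, the
    branch is flat, and ``mu`` equals the unflanked location exactly.

The default hinge abscissa is log10 *nominal* spacing, t = log10
(spacing / size); with crowded slope -1 this yields exactly right-angle
iso-performance contours (the classic flanked-acuity form), and -0.8
slightly slants the crowded edge. Log10 absolute center-to-center
spacing is available as the alternative named transform "log_c2c".

Horizontal slices of the landscape are ordinary crowding functions
(fixed size, varying spacing); diagonal slices at fixed nominal spacing
are flanked-acuity psychometric functions, the path a size staircase
travels. Both paradigms sample one surface, which is what makes their
critical-spacing estimates mutually predictable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import expit, logit, ndtr, ndtri

from .geometry import (
    UNFLANKED,
    CriterionSpec,
    CriterionUnattainableError,
    criterion_level,
)

__all__ = [
    "HingeSpec",
    "LandscapeParams",
    "FlankedAcuityLandscape",
    "SpacingSizeOverlapError",
    "CriticalSpacingAtSize",
    "predict_pcorrect",
    "threshold_size",
    "iso_performance_contour",
    "critical_spacing_at_size",
    "valid_size_window",
]

_LINKS = {
    "logistic": (expit, lambda q: float(logit(q))),
    "cumulative_gaussian": (ndtr, lambda q: float(ndtri(q))),
}

#: Named hinge-abscissa strategies: (size, spacing) -> transformed x.
HINGE_TRANSFORMS: dict[str, Callable[[float, float], float]] = {
    "log_nominal": lambda size, spacing: math.log10(spacing / size),
    "log_c2c": lambda size, spacing: math.log10(spacing),
}


class SpacingSizeOverlapError(ValueError):
    """Center-to-center spacing smaller than the letter size: flankers overlap the target."""


@dataclass(frozen=True)
class HingeSpec:
    """Hinged-line location function of the landscape.

    ``hinge_location`` lives on the transformed abscissa: for the
    default "log_nominal" transform it is log10 of the critical nominal
    spacing; for "log_c2c" it is log10 of the critical center-to-center
    spacing in degrees. The flat branch has slope 0 by definition, and
    continuity at the hinge is enforced by construction (the crowded
    branch is anchored at the unflanked location).
    """

    hinge_location: float
    crowded_slope: float = -0.8
    transform: str = "log_nominal"

    def __post_init__(self) -> None:
        if self.crowded_slope >= 0:
            raise ValueError("crowded_slope must be negative")
        if self.transform not in HINGE_TRANSFORMS:
            raise ValueError(f"unknown hinge transform {self.transform!r}; known: {sorted(HINGE_TRANSFORMS)}")

    def location_shift(self, size: float, spacing: float) -> float:
        """Upward shift of mu (log10 size units) relative to unflanked, >= 0."""
        if math.isinf(spacing):
            return 0.0
        t = HINGE_TRANSFORMS[self.transform](size, spacing)
        if t >= self.hinge_location:
            return 0.0
        return self.crowded_slope * (t - self.hinge_location)


@dataclass(frozen=True)
class LandscapeParams:
    """Parameters of a flanked-acuity landscape at one eccentricity.

    ``unflanked_threshold_size`` is the isolated-letter size identified
    at ``reference_level`` (default 75% correct, the most common
    acuity convention; some studies use 79%).
    """

    eccentricity: float
    unflanked_threshold_size: float
    beta_shared: float
    guess: float
    hinge: HingeSpec
    asymptote: float = 0.99
    reference_level: float = 0.75
    form: str = "logistic"

    def __post_init__(self) -> None:
        if self.unflanked_threshold_size <= 0:
            raise ValueError("unflanked_threshold_size must be positive")
        if self.beta_shared <= 0:
            raise ValueError("beta_shared must be positive")
        if not 0.0 < self.guess < self.asymptote <= 1.0:
            raise ValueError("need 0 < guess < asymptote <= 1")
        if not self.guess < self.reference_level < self.asymptote:
            raise ValueError("reference_level must lie strictly between guess and asymptote")
        if self.form not in _LINKS:
            raise ValueError(f"unknown form {self.form!r}")


@dataclass(frozen=True)
class CriticalSpacingAtSize:
    """Horizontal-slice critical spacing, or why it cannot be measured."""

    value: float  # degrees; nan when unmeasurable
    status: str  # "ok" | "floor" | "ceiling"
    raw_level: float | None = None

    @property
    def measurable(self) -> bool:
        return self.status == "ok"


class FlankedAcuityLandscape:
    """Evaluate, slice, and invert a flanked-acuity performance landscape."""

    def __init__(self, params: LandscapeParams) -> None:
        self.params = params
        p = params
        F, Finv = _LINKS[p.form]
        self._F, self._Finv = F, Finv
        q_ref = (p.reference_level - p.guess) / (p.asymptote - p.guess)
        # anchor: unflanked letters of the threshold size are identified at the
        # reference level, which pins the unflanked location mu_inf
        self.mu_inf = math.log10(p.unflanked_threshold_size) - Finv(q_ref) / p.beta_shared

    # --- forward model --------------------------------------------------------

    def location(self, size: float, spacing: float) -> float:
        """Location mu (log10 size units) of the base function for this geometry."""
        return self.mu_inf + self.params.hinge.location_shift(size, spacing)

    def predict_pcorrect(self, letter_size: float, spacing: float) -> float:
        """Expected proportion correct for a flanked letter of a given geometry.

        ``spacing`` is center-to-center degrees (UNFLANKED for isolated
        targets) and must be at least the letter size: physically
        overlapping flankers are outside the model's domain.
        """
        p = self.params
        if letter_size <= 0:
            raise ValueError("letter_size must be positive")
        if not math.isinf(spacing):
            if spacing <= 0:
                raise ValueError("spacing must be positive")
            if spacing < letter_size:
                raise SpacingSizeOverlapError(
                    f"spacing {spacing:g} < letter size {letter_size:g}: flankers overlap the target"
                )
        mu = self.location(letter_size, spacing)
        return p.guess + (p.asymptote - p.guess) * float(self._F(p.beta_shared * (math.log10(letter_size) - mu)))

    # --- slices and inversions ------------------------------------------------

    def slice_asymptote(self, letter_size: float) -> float:
        """Asymptotic (wide-spacing/unflanked) performance of a horizontal slice."""
        return self.predict_pcorrect(letter_size, UNFLANKED)

    def threshold_size(self, nominal_multiple: float, level: float, rtol: float = 1e-6) -> float:
        """Size along the fixed-nominal-spacing diagonal where performance hits ``level``.

        This is the quantity a flanked-acuity staircase estimates. For
        nominal multiples beyond the crowding zone it equals the
        unflanked threshold size at the same level.
        """
        p = self.params
        if nominal_multiple < 1:
            raise ValueError("nominal_multiple must be >= 1 (non-overlapping flankers)")
        if not p.guess < level < p.asymptote:
            raise CriterionUnattainableError(
                f"level {level} outside attainable range ({p.guess}, {p.asymptote})"
            )
        # performance along the diagonal is monotone increasing in size
        lo, hi = self.mu_inf - 8.0, self.mu_inf + 8.0
        f = lambda logS: self.predict_pcorrect(10**logS, nominal_multiple * 10**logS) - level
        flo, fhi = f(lo), f(hi)
        if flo > 0 or fhi < 0:  # pragma: no cover - bracket is generous
            raise RuntimeError("failed to bracket the threshold size")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < rtol * max(1.0, abs(mid)):
                break
        return 10 ** (0.5 * (lo + hi))

    def _required_shift(self, letter_size: float, level: float) -> float:
        """Location shift Delta >= 0 at which a slice of this size crosses ``level``.

        Negative return means the level exceeds the slice asymptote
        (never reached at any spacing)."""
        p = self.params
        q = (level - p.guess) / (p.asymptote - p.guess)
        if not 0.0 < q < 1.0:
            return -math.inf if q >= 1.0 else math.inf
        mu_req = math.log10(letter_size) - self._Finv(q) / p.beta_shared
        return mu_req - self.mu_inf

    def _spacing_for_shift(self, letter_size: float, delta: float) -> float:
        """Invert the hinged line: spacing whose location shift equals ``delta`` > 0."""
        h = self.params.hinge
        t = h.hinge_location + delta / h.crowded_slope
        if h.transform == "log_nominal":
            return letter_size * 10**t
        return 10**t

    def critical_spacing_at_size(
        self, letter_size: float, criterion: CriterionSpec
    ) -> CriticalSpacingAtSize:
        """Analyze a horizontal slice exactly like a measured crowding function.

        Flags ``floor`` when the criterion level is unattainable at this
        size (letters too small: the slice never reaches it) and
        ``ceiling`` when performance already exceeds the level at the
        minimum non-overlapping spacing (letters too large: no crowding
        measurable).
        """
        p = self.params
        A_size = self.slice_asymptote(letter_size)
        try:
            level = criterion_level(criterion, p.guess, A_size)
        except CriterionUnattainableError:
            return CriticalSpacingAtSize(value=float("nan"), status="floor")
        delta = self._required_shift(letter_size, level)
        if delta <= 0.0:
            # level at or above the slice asymptote is unreachable at finite spacing
            return CriticalSpacingAtSize(value=float("nan"), status="floor", raw_level=level)
        spacing = self._spacing_for_shift(letter_size, delta)
        if spacing < letter_size:
            return CriticalSpacingAtSize(value=float("nan"), status="ceiling", raw_level=level)
        return CriticalSpacingAtSize(value=spacing, status="ok", raw_level=level)

    def iso_performance_contour(
        self, level: float, size_grid: Sequence[float]
    ) -> list[tuple[float, float]]:
        """(size, spacing) pairs where predicted performance equals ``level``.

        Spacing is nan where the level is unattainable at that size
        (below the contour's reach) and where performance exceeds the
        level everywhere in the non-overlap domain (above it).
        """
        p = self.params
        if not p.guess < level < p.asymptote:
            raise ValueError("contour level must lie strictly between guess and asymptote")
        out: list[tuple[float, float]] = []
        for size in size_grid:
            delta = self._required_shift(size, level)
            if not np.isfinite(delta) or delta <= 0.0:
                out.append((size, float("nan")))
                continue
            spacing = self._spacing_for_shift(size, delta)
            out.append((size, spacing if spacing >= size else float("nan")))
        return out

    def valid_size_window(
        self,
        criterion: CriterionSpec,
        size_range: tuple[float, float] | None = None,
        n_scan: int = 256,
        bits: int = 60,
    ) -> tuple[float, float] | None:
        """Size window over which the slice critical spacing is measurable.

        Boundaries (floor -> measurable and measurable -> ceiling
        transitions) are located by bisection on log size. Returns None
        when no size in the scanned range yields a finite critical
        spacing.
        """
        S0 = self.params.unflanked_threshold_size
        if size_range is None:
            size_range = (S0 * 1e-3, S0 * 1e3)
        logs = np.linspace(math.log10(size_range[0]), math.log10(size_range[1]), n_scan)
        status = [self.critical_spacing_at_size(10**ls, criterion).status for ls in logs]
        ok_idx = [i for i, s in enumerate(status) if s == "ok"]
        if not ok_idx:
            return None

        def bisect(lo: float, hi: float, want_ok_high: bool) -> float:
            # invariant: exactly one of (lo, hi) has status "ok"
            for _ in range(bits):
                mid = 0.5 * (lo + hi)
                ok = self.critical_spacing_at_size(10**mid, criterion).status == "ok"
                if ok == want_ok_high:
                    hi = mid
                else:
                    lo = mid
            return 0.5 * (lo + hi)

        i0, i1 = ok_idx[0], ok_idx[-1]
        if i0 == 0:
            lo_edge = logs[0]
        else:
            lo_edge = bisect(logs[i0 - 1], logs[i0], want_ok_high=True)
        if i1 == n_scan - 1:
            hi_edge = logs[-1]
        else:
            hi_edge = bisect(logs[i1], logs[i1 + 1], want_ok_high=False)
        return (10**lo_edge, 10**hi_edge)

    # --- export / plotting ----------------------------------------------------

    def to_grid(self, sizes: Sequence[float], spacings: Sequence[float]):
        """Long-format DataFrame (size, spacing, p) over the non-overlap domain."""
        import pandas as pd

        rows = []
        for s in sizes:
            for sp in spacings:
                if sp < s:
                    continue
                rows.append({"letter_size_deg": s, "spacing_deg": sp,
                             "p_correct": self.predict_pcorrect(s, sp)})
        return pd.DataFrame(rows)

    def plot(self, ax=None, n_size: int = 120, n_spacing: int = 120, levels: Sequence[float] = (0.4, 0.6, 0.8)):
        """Quick-look heat map with iso-performance contours."""
        import matplotlib.pyplot as plt

        p = self.params
        if ax is None:
            _, ax = plt.subplots()
        S0 = p.unflanked_threshold_size
        sizes = np.logspace(math.log10(S0 / 8), math.log10(S0 * 8), n_size)
        spacings = np.logspace(math.log10(S0 / 8), math.log10(S0 * 60), n_spacing)
        grid = np.full((n_size, n_spacing), np.nan)
        for i, s in enumerate(sizes):
            for j, sp in enumerate(spacings):
                if sp >= s:
                    grid[i, j] = self.predict_pcorrect(s, sp)
        mesh = ax.pcolormesh(spacings, sizes, grid, shading="auto", cmap="inferno",
                             vmin=p.guess, vmax=1.0)
        for lv in levels:
            pts = self.iso_performance_contour(lv, sizes)
            xs = [sp for _, sp in pts]
            ax.plot(xs, sizes, lw=1.5, label=f"p = {lv:g}")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("center-to-center spacing (deg)")
        ax.set_ylabel("letter size (deg)")
        ax.legend(loc="lower right", fontsize="small")
        plt.colorbar(mesh, ax=ax, label="proportion correct")
        return ax


# --- functional wrappers ------------------------------------------------------


def predict_pcorrect(letter_size: float, spacing: float, params: LandscapeParams) -> float:
    return FlankedAcuityLandscape(params).predict_pcorrect(letter_size, spacing)


def threshold_size(nominal_multiple: float, level: float, params: LandscapeParams) -> float:
    return FlankedAcuityLandscape(params).threshold_size(nominal_multiple, level)


def iso_performance_contour(level: float, params: LandscapeParams, size_grid: Sequence[float]):
    return FlankedAcuityLandscape(params).iso_performance_contour(level, size_grid)


def critical_spacing_at_size(letter_size: float, criterion: CriterionSpec, params: LandscapeParams):
    return FlankedAcuityLandscape(params).critical_spacing_at_size(letter_size, criterion)


def valid_size_window(criterion: CriterionSpec, params: LandscapeParams, **kwargs):
    return FlankedAcuityLandscape(params).valid_size_window(criterion, **kwargs)
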