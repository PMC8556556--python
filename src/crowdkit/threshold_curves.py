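"""Critical spacing from threshold-versus-spacing curves.

When the dependent variable is a threshold (contrast to identify a
letter of fixed size, or flanked acuity size) measured at several
flanker spacings, the standard estimator is a two-line ("clipped line")
fit in log-log coordinates: a sloped crowded branch at close spacings
joined continuously to a flat branch at wide spacings, with the hinge
abscissa taken as the critical spacing. The hinge is profiled over a
candidate grid and polished; identifying the intersection this way is
akin to a highly conservative (near-asymptote) criterion on proportion
-correct curves.

Two cruder estimators are provided for comparison: the spacing at which
thresholds reach a fixed multiple of the unflanked baseline (doubling),
and the spacing at which thresholds first diverge from the baseline by
k baseline standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import UNFLANKED

__all__ = [
    "ThresholdPoint",
    "ClippedLineModel",
    "HingedLineFit",
    "fit_clipped_line",
    "critical_spacing_from_thresholds",
]


@dataclass(frozen=True)
class ThresholdPoint:
    """One threshold measurement at one flanker spacing.

    ``spacing`` is center-to-center degrees (``math.inf`` marks the
    unflanked baseline); ``threshold`` is a positive contrast proportion
    or size in degrees; ``se`` an optional standard error.
    """

    spacing: float
    threshold: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive (math.inf for unflanked)")
        if self.se is not None and self.se <= 0:
            raise ValueError("se must be positive when given")

    @property
    def is_unflanked(self) -> bool:
        return math.isinf(self.spacing)


@dataclass
class HingedLineFit:
    """Continuous two-line fit in log10 threshold vs log10 spacing."""

    x_hinge: float  # log10 spacing
    left_slope: float
    right_slope: float
    right_level: float  # log10 threshold of the flat (or right) branch at the hinge
    rss: float
    reduced_chi_square: float
    n_points: int
    weighted: bool
    flags: list[str]

    @property
    def critical_spacing(self) -> float:
        """Hinge abscissa in degrees."""
        return 10.0**self.x_hinge

    def predict_log10(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        left = self.right_level + self.left_slope * (x - self.x_hinge)
        right = self.right_level + self.right_slope * (x - self.x_hinge)
        return np.where(x < self.x_hinge, left, right)

    def summary(self) -> str:
        lines = [
            "Clipped-line threshold fit",
            "=" * 50,
            f"critical spacing (hinge): {self.critical_spacing:.4f} deg "
            f"(log10 {self.x_hinge:.4f})",
            f"crowded-branch slope: {self.left_slope:.4f}",
            f"flat-branch slope: {self.right_slope:.4f}",
            f"RSS: {self.rss:.5g}   reduced chi-square: {self.reduced_chi_square:.4g}",
            f"n points: {self.n_points}   weighted: {self.weighted}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class ClippedLineModel:
    """Least-squares hinged-line model of a threshold-vs-spacing curve.

    Unflanked baseline points are anchored to the flat branch. Weighting
    by 1/se^2 engages when every point carries a standard error (or
    force with ``weighted=True``/``False``); whether published two-line
    fits weighted by SE varies, so both behaviors are exposed.
    """

    def __init__(
        self,
        points: Sequence[ThresholdPoint],
        constrain_flat: bool = True,
        weighted: bool | str = "auto",
        n_grid: int = 50,
    ) -> None:
        points = list(points)
        finite = [p for p in points if not p.is_unflanked]
        if len({round(math.log10(p.spacing), 12) for p in finite}) != len(finite):
            raise ValueError("spacings must be distinct within a curve")
        n_params = 3 if constrain_flat else 4
        if len(points) < max(4, n_params + 1):
            raise ValueError(f"need at least {max(4, n_params + 1)} points for a clipped-line fit")
        if len(finite) < 3:
            raise ValueError("need at least 3 finite-spacing points")
        self.points = points
        self.constrain_flat = constrain_flat
        self.n_grid = n_grid
        if weighted == "auto":
            self.weighted = all(p.se is not None for p in points)
        else:
            self.weighted = bool(weighted)
            if self.weighted and not all(p.se is not None for p in points):
                raise ValueError("weighted fit requested but some points lack se")

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "ClippedLineModel":
        pts = [
            ThresholdPoint(
                spacing=float(r.spacing_deg),
                threshold=float(r.threshold),
                se=(float(r.se) if hasattr(r, "se") and np.isfinite(getattr(r, "se")) else None),
            )
            for r in df.itertuples()
        ]
        return cls(pts, **kwargs)

    def _arrays(self):
        finite = [p for p in self.points if not p.is_unflanked]
        unf = [p for p in self.points if p.is_unflanked]
        x = np.array([math.log10(p.spacing) for p in finite])
        y = np.array([math.log10(p.threshold) for p in finite])
        if self.weighted:
            # log-space SE via the delta method: se(log10 y) ~ se / (y ln 10)
            w = np.array([1.0 / (p.se / (p.threshold * math.log(10))) ** 2 for p in finite])
        else:
            w = np.ones_like(x)
        y_unf = np.array([math.log10(p.threshold) for p in unf])
        if self.weighted and unf:
            w_unf = np.array([1.0 / (p.se / (p.threshold * math.log(10))) ** 2 for p in unf])
        else:
            w_unf = np.ones_like(y_unf)
        return x, y, w, y_unf, w_unf

    def _rss_at(self, xh: float):
        """Profiled weighted RSS with the hinge fixed at ``xh``; returns (rss, params)."""
        x, y, w, y_unf, w_unf = self._arrays()
        left = x < xh
        # design: y = b + a * min(x - xh, 0) (+ c * max(x - xh, 0) if right slope free)
        cols = [np.ones_like(x), np.minimum(x - xh, 0.0)]
        if not self.constrain_flat:
            cols.append(np.maximum(x - xh, 0.0))
        X = np.column_stack(cols)
        # unflanked points: flat-branch observations (x - xh contributions vanish
        # for the constrained fit; for a free right slope they sit at the hinge)
        if len(y_unf):
            Xu = np.zeros((len(y_unf), X.shape[1]))
            Xu[:, 0] = 1.0
            X = np.vstack([X, Xu])
            yy = np.concatenate([y, y_unf])
            ww = np.concatenate([w, w_unf])
        else:
            yy, ww = y, w
        sw = np.sqrt(ww)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], yy * sw, rcond=None)
        resid = yy - X @ coef
        rss = float(np.sum(ww * resid**2))
        b = float(coef[0])
        a = float(coef[1])
        c = 0.0 if self.constrain_flat else float(coef[2])
        return rss, (a, c, b)

    def fit(self) -> HingedLineFit:
        x, y, w, y_unf, w_unf = self._arrays()
        xs = np.sort(x)
        flags: list[str] = []
        # candidate hinges between the 2nd and penultimate abscissae keep the
        # crowded and flat regimes populated and avoid degenerate boundary hinges
        lo, hi = xs[1], xs[-2]
        if lo >= hi:
            lo, hi = xs[0], xs[-1]
        grid = np.linspace(lo, hi, self.n_grid)
        rss_grid = np.array([self._rss_at(g)[0] for g in grid])
        # ties in profile RSS break toward the larger hinge (conservative CS)
        best_i = int(np.flatnonzero(rss_grid <= rss_grid.min() + 1e-12)[-1])
        bl = grid[max(best_i - 1, 0)]
        bh = grid[min(best_i + 1, len(grid) - 1)]
        if bh > bl:
            res = minimize_scalar(lambda g: self._rss_at(g)[0], bounds=(bl, bh), method="bounded",
                                  options={"xatol": 1e-10})
            xh = float(res.x)
            if self._rss_at(xh)[0] > rss_grid[best_i] + 1e-12:
                xh = float(grid[best_i])
        else:
            xh = float(grid[best_i])
        rss, (a, c, b) = self._rss_at(xh)
        if a >= -1e-6:
            # thresholds never rise toward close spacings: no crowding detected
            flags.append("no_crowding_detected")
            xh = float(xs[0])
            rss, (a, c, b) = self._rss_at(xh)
        n = len(self.points)
        n_par = 3 if self.constrain_flat else 4
        dof = n - n_par
        red_chi2 = rss / dof if dof > 0 else float("nan")
        if not xs[0] <= xh <= xs[-1]:
            flags.append("hinge_extrapolated")
        return HingedLineFit(
            x_hinge=xh, left_slope=a, right_slope=c, right_level=b, rss=rss,
            reduced_chi_square=red_chi2, n_points=n, weighted=self.weighted, flags=flags,
        )


def fit_clipped_line(
    points: Sequence[ThresholdPoint], constrain_flat: bool = True, **kwargs
) -> HingedLineFit:
    """Functional wrapper around :class:`ClippedLineModel`."""
    return ClippedLineModel(points, constrain_flat=constrain_flat, **kwargs).fit()


def _baseline(points: Sequence[ThresholdPoint]) -> tuple[float, float | None]:
    unf = [p for p in points if p.is_unflanked]
    if unf:
        base = float(np.mean([p.threshold for p in unf]))
        ses = [p.se for p in unf if p.se is not None]
        se = float(np.mean(ses)) if len(ses) == len(unf) else None
        return base, se
    raise ValueError("baseline missing: supply an unflanked (infinite-spacing) point")


def critical_spacing_from_thresholds(
    points: Sequence[ThresholdPoint],
    method: Literal["clipped_line", "doubling", "divergence"] = "clipped_line",
    factor: float = 2.0,
    k_se: float = 2.0,
    **fit_kwargs,
) -> float:
    """Critical spacing in degrees from a threshold-vs-spacing curve.

    methods
    -------
    clipped_line
        hinge abscissa of the two-line fit (default).
    doubling
        spacing at which thresholds reach ``factor`` x the unflanked
        baseline, interpolated on log-log axes; nan when thresholds
        never get there.
    divergence
        spacing at which thresholds exceed baseline + ``k_se`` baseline
        standard errors, interpolated on log axes (requires a baseline SE).
    """
    if method == "clipped_line":
        return fit_clipped_line(points, **fit_kwargs).critical_spacing
    base, base_se = _baseline(points)
    if method == "doubling":
        target = math.log10(factor * base)
    elif method == "divergence":
        if base_se is None:
            raise ValueError("divergence method needs a standard error on the baseline")
        target = math.log10(base + k_se * base_se)
    else:
        raise ValueError(f"unknown method {method!r}")
    finite = sorted((p for p in points if not p.is_unflanked), key=lambda p: p.spacing)
    x = np.array([math.log10(p.spacing) for p in finite])
    y = np.array([math.log10(p.threshold) for p in finite])
    above = y >= target
    if not above.any():
        return float("nan")
    # walk down from wide spacings: the boundary is the last crossing of the
    # (threshold-decreasing-with-spacing) curve through the target level
    idx = int(np.max(np.flatnonzero(above)))
    if idx == len(x) - 1:
        return float(10 ** x[-1])  # still elevated at the widest spacing measured
    x0, x1 = x[idx], x[idx + 1]
    y0, y1 = y[idx], y[idx + 1]
    if y0 == y1:
        return float(10**x0)
    return float(10 ** (x0 + (target - y0) * (x1 - x0) / (y1 - y0)))
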