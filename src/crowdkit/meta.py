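"""Meta-regression of the Bouma fraction against stimulus duration.

Across studies, the ratio of critical spacing to eccentricity falls
roughly linearly with log10 stimulus duration, except at the very
shortest durations where it turns back down. The trend is fitted by
(optionally SE-weighted) least squares of the Bouma fraction (semilog)
or its log10 (log-log) on log10 duration, with an iterative exclusion
rule: candidate fits drop 0, 1, 2, ... of the shortest-duration levels
and the fit with the lowest reduced chi-square wins. Exclusion is
restricted to a duration-sorted prefix so the procedure can never
cherry-pick interior points.

Flanker-configuration comparisons fit four-flanker and two-radial-
flanker data jointly (radial flankers show winner-takes-all behavior)
while two-tangential-flanker data are reported separately and never
pooled (radial-tangential anisotropy).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "MetaPoint",
    "DurationTrendModel",
    "DurationTrendResult",
    "fit_duration_trend",
    "compare_flanker_configs",
    "aggregate_by_study",
]

FLANKER_CONFIGS = ("4", "2_radial", "2_tangential")


@dataclass(frozen=True)
class MetaPoint:
    """One study/condition's (duration, Bouma fraction) measurement."""

    study: str
    duration: float  # seconds
    bouma_fraction: float
    se: float | None = None
    n_flankers: str = "4"  # "4" | "2_radial" | "2_tangential"
    visual_field: str = ""
    excluded_a_priori: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.bouma_fraction <= 0:
            raise ValueError("bouma_fraction must be positive")
        if self.n_flankers not in FLANKER_CONFIGS:
            raise ValueError(f"n_flankers must be one of {FLANKER_CONFIGS}")


def aggregate_by_study(points: Sequence[MetaPoint]) -> list[MetaPoint]:
    """Average multiple eccentricities/conditions to one point per
    (study, duration, flanker configuration)."""
    groups: dict[tuple[str, float, str], list[MetaPoint]] = {}
    for p in points:
        groups.setdefault((p.study, p.duration, p.n_flankers), []).append(p)
    out = []
    for (study, dur, nf), grp in groups.items():
        if len(grp) == 1:
            out.append(grp[0])
            continue
        b = float(np.mean([p.bouma_fraction for p in grp]))
        ses = [p.se for p in grp if p.se is not None]
        se = float(np.sqrt(np.sum(np.square(ses))) / len(grp)) if len(ses) == len(grp) else None
        out.append(MetaPoint(study=study, duration=dur, bouma_fraction=b, se=se,
                             n_flankers=nf, visual_field=grp[0].visual_field,
                             excluded_a_priori=any(p.excluded_a_priori for p in grp)))
    return out


@dataclass
class DurationTrendResult:
    """Fitted duration trend with its exclusion bookkeeping."""

    slope: float
    intercept: float
    slope_se: float
    excluded_durations: list[float]  # contiguous prefix of sorted durations
    reduced_chi_square: float
    axes: str
    n_used: int
    n_excluded_a_priori: int
    flags: list[str] = field(default_factory=list)

    def predict(self, duration) -> np.ndarray:
        """Predicted Bouma fraction at duration(s) in seconds."""
        logt = np.log10(np.asarray(duration, dtype=float))
        y = self.intercept + self.slope * logt
        return 10**y if self.axes == "loglog" else y

    def summary(self) -> str:
        lines = [
            "Bouma-fraction vs duration trend",
            "=" * 50,
            f"axes: {self.axes}   n points used: {self.n_used}",
            f"slope: {self.slope:.4f} +/- {self.slope_se:.4f} per log10 s",
            f"intercept (at 1 s): {self.intercept:.4f}",
            f"reduced chi-square: {self.reduced_chi_square:.4g}",
            f"excluded shortest durations: {self.excluded_durations or 'none'}",
            f"a-priori exclusions: {self.n_excluded_a_priori}",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)


class DurationTrendModel:
    """Least-squares trend of Bouma fraction on log10 duration.

    Parameters
    ----------
    points : sequence of MetaPoint
        A-priori-excluded points (outlier studies) are dropped before
        anything else.
    axes : {"semilog", "loglog"}
        Regress b (semilog) or log10 b (loglog) on log10 t.
    exclusion : {"none", "iterative_prefix"}
        The reduced-chi-square prefix-exclusion search.
    collapse : bool
        Average to one point per (study, duration, configuration) first.
    """

    def __init__(
        self,
        points: Sequence[MetaPoint],
        axes: Literal["semilog", "loglog"] = "semilog",
        exclusion: Literal["none", "iterative_prefix"] = "iterative_prefix",
        weighted: bool | str = "auto",
        collapse: bool = True,
    ) -> None:
        if axes not in ("semilog", "loglog"):
            raise ValueError("axes must be 'semilog' or 'loglog'")
        if exclusion not in ("none", "iterative_prefix"):
            raise ValueError("exclusion must be 'none' or 'iterative_prefix'")
        pts = [p for p in points if not p.excluded_a_priori]
        self.n_excluded_a_priori = len(points) - len(pts)
        if collapse:
            pts = aggregate_by_study(pts)
        min_pts = 3 if exclusion == "iterative_prefix" else 2
        if len(pts) < min_pts:
            raise ValueError(f"need >= {min_pts} points after a-priori exclusion")
        self.points = sorted(pts, key=lambda p: p.duration)
        self.axes = axes
        self.exclusion = exclusion
        if weighted == "auto":
            self.weighted = all(p.se is not None for p in self.points)
        else:
            self.weighted = bool(weighted)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "DurationTrendModel":
        pts = []
        for r in df.itertuples():
            se = getattr(r, "se", None)
            se = float(se) if se is not None and np.isfinite(se) else None
            pts.append(MetaPoint(
                study=str(r.study), duration=float(r.duration_s),
                bouma_fraction=float(r.bouma_fraction), se=se,
                n_flankers=str(getattr(r, "n_flankers", "4")),
                visual_field=str(getattr(r, "visual_field", "")),
                excluded_a_priori=bool(getattr(r, "a_priori_exclude", False)),
            ))
        return cls(pts, **kwargs)

    def _xyw(self, pts: Sequence[MetaPoint]):
        x = np.log10([p.duration for p in pts])
        b = np.array([p.bouma_fraction for p in pts])
        if self.axes == "semilog":
            y = b
            se = np.array([p.se if p.se is not None else np.nan for p in pts])
        else:
            y = np.log10(b)
            se = np.array([
                (p.se / (p.bouma_fraction * math.log(10))) if p.se is not None else np.nan
                for p in pts
            ])
        return x, y, se

    def _ols(self, pts: Sequence[MetaPoint]):
        x, y, se = self._xyw(pts)
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            # an exact two-point line has zero residual dof; its SEs are nan
            warnings.simplefilter("ignore", RuntimeWarning)
            if self.weighted:
                res = sm.WLS(y, X, weights=1.0 / se**2).fit()
            else:
                res = sm.OLS(y, X).fit()
            res.bse
        resid = y - res.predict(X)
        dof = len(pts) - 2
        if dof <= 0:
            chi2 = float("nan")
        elif self.weighted:
            chi2 = float(np.sum((resid / se) ** 2) / dof)
        else:
            chi2 = float(np.sum(resid**2) / dof)
        return res, chi2, resid

    def fit(self) -> DurationTrendResult:
        flags: list[str] = []
        res_all, chi2_all, resid_all = self._ols(self.points)
        if len(self.points) == 2:
            flags.append("exact_fit_two_points")
        best = (res_all, chi2_all, [], len(self.points))
        if self.exclusion == "iterative_prefix" and len(self.points) > 3:
            if self.weighted:
                score_scale = 1.0
            else:
                # fixed normalizer from the no-exclusion fit so the unweighted
                # score is comparable across candidate exclusions; a ~zero MSE
                # (numerically exact line) must not amplify rounding noise
                mse_all = float(np.sum(resid_all**2) / (len(self.points) - 2))
                score_scale = mse_all if mse_all > 1e-16 else 1.0
            durations = sorted({p.duration for p in self.points})
            best_score = chi2_all / score_scale if np.isfinite(chi2_all) else math.inf
            for k in range(1, len(durations)):
                keep = [p for p in self.points if p.duration > durations[k - 1]]
                if len(keep) < 3:
                    break
                res_k, chi2_k, _ = self._ols(keep)
                score = chi2_k / score_scale
                if score < best_score - 1e-12:  # strict improvement: noise-free data excludes nothing
                    best_score = score
                    best = (res_k, chi2_k, durations[:k], len(keep))
        res, chi2, excluded, n_used = best
        return DurationTrendResult(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            excluded_durations=list(excluded),
            reduced_chi_square=chi2,
            axes=self.axes,
            n_used=n_used,
            n_excluded_a_priori=self.n_excluded_a_priori,
            flags=flags,
        )


def fit_duration_trend(
    points: Sequence[MetaPoint],
    axes: Literal["semilog", "loglog"] = "semilog",
    exclusion: Literal["none", "iterative_prefix"] = "iterative_prefix",
    **kwargs,
) -> DurationTrendResult:
    """Functional wrapper around :class:`DurationTrendModel`."""
    return DurationTrendModel(points, axes=axes, exclusion=exclusion, **kwargs).fit()


def compare_flanker_configs(
    points: Sequence[MetaPoint], axes: Literal["semilog", "loglog"] = "semilog", **kwargs
) -> dict[str, DurationTrendResult]:
    """Per-configuration and pooled duration trends.

    Returns fits keyed by configuration plus "pooled" (four-flanker +
    two-radial). Tangential points are fitted separately and never
    pooled. Groups with fewer than three points are skipped with a
    warning.
    """
    out: dict[str, DurationTrendResult] = {}
    for cfg in FLANKER_CONFIGS:
        grp = [p for p in points if p.n_flankers == cfg and not p.excluded_a_priori]
        if not grp:
            continue
        if len(grp) < 3:
            warnings.warn(f"flanker configuration {cfg!r} has < 3 points; skipped")
            continue
        out[cfg] = fit_duration_trend(grp, axes=axes, exclusion="none", **kwargs)
    pooled = [p for p in points if p.n_flankers in ("4", "2_radial") and not p.excluded_a_priori]
    if len(pooled) >= 3:
        out["pooled"] = fit_duration_trend(pooled, axes=axes, exclusion="none", **kwargs)
    return out
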