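"""Binomial-likelihood fitting of crowding functions.

A crowding function maps log10 center-to-center flanker spacing (or log
letter size, in the flanked-acuity paradigm) to proportion correct.
Both supported sigmoid forms share the parameterization

    p(x) = g + (A - g) * F(beta * (x - mu)),   x = log10 abscissa,

with F the logistic or the standard normal CDF, guess rate g fixed by
the task, asymptote A free (<= 1) or fixed, location mu, and slope beta
per log10 unit (beta > 0: performance improves with spacing). Unflanked
cells enter the likelihood at the asymptote, the spacing -> infinity
limit.

The default estimator is maximum likelihood with jittered restarts and
a parametric bootstrap for uncertainty; MCMC with flat priors (emcee)
is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr, ndtri

from .geometry import (
    UNFLANKED,
    CriterionSpec,
    CriterionUnattainableError,
    TaskSpec,
    correct_for_guessing,
    criterion_level,
)

__all__ = [
    "StimulusCell",
    "CrowdingFunctionModel",
    "CrowdingFunctionResult",
    "SharedSlopeModel",
    "SharedSlopeResult",
    "CriticalSpacingEstimate",
    "fit_crowding_function",
    "fit_shared_slope",
    "critical_spacing",
    "zscore_normalize",
]

Form = Literal["logistic", "cumulative_gaussian"]

_LINKS: dict[str, tuple[Callable, Callable]] = {
    "logistic": (expit, lambda q: logit(q)),
    "cumulative_gaussian": (ndtr, ndtri),
}


@dataclass(frozen=True)
class StimulusCell:
    """One experimental condition: geometry, task, and response counts.

    ``spacing`` is center-to-center degrees; ``math.inf`` marks an
    unflanked cell. In the flanked-acuity paradigm ``letter_size``
    varies across cells and ``spacing`` co-varies with it.
    """

    eccentricity: float
    letter_size: float
    spacing: float
    task: TaskSpec
    n_correct: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.n_correct <= self.n_trials:
            raise ValueError(f"need 0 <= n_correct <= n_trials, got {self.n_correct}/{self.n_trials}")
        if self.letter_size <= 0:
            raise ValueError("letter_size must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive (use math.inf for unflanked)")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be nonnegative")

    @property
    def is_unflanked(self) -> bool:
        return math.isinf(self.spacing)

    @property
    def proportion_correct(self) -> float:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class CriticalSpacingEstimate:
    """Critical spacing read off a fitted function under one criterion."""

    value: float  # degrees; nan when unattainable
    status: str  # "ok" | "unattainable"
    criterion: CriterionSpec
    raw_level: float | None = None
    conf_int: tuple[float, float] | None = None

    @property
    def attainable(self) -> bool:
        return self.status == "ok"


def _prepare(cells: Sequence[StimulusCell]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([math.log10(c.spacing) if not c.is_unflanked else np.inf for c in cells])
    k = np.array([c.n_correct for c in cells], dtype=float)
    n = np.array([c.n_trials for c in cells], dtype=float)
    unflanked = np.isinf(x)
    return x, k, n, unflanked


class CrowdingFunctionModel:
    """Model for a single crowding function fitted to StimulusCell counts.

    Parameters
    ----------
    cells : sequence of StimulusCell
        All cells must share the task and eccentricity; at least three
        distinct finite spacings are required.
    form : {"logistic", "cumulative_gaussian"}
    asymptote : "free" or float
        Free (bounded above by 1) or fixed upper asymptote.
    abscissa : {"spacing", "size"}
        Which stimulus dimension is the x-axis (log10 of it); "size"
        serves the flanked-acuity paradigm.
    seed : int
        Seeds optimizer jitter and the parametric bootstrap.
    """

    def __init__(
        self,
        cells: Sequence[StimulusCell],
        form: Form = "logistic",
        asymptote: float | str = "free",
        abscissa: str = "spacing",
        seed: int = 0,
    ) -> None:
        cells = list(cells)
        if not cells:
            raise ValueError("no cells supplied")
        if form not in _LINKS:
            raise ValueError(f"unknown form {form!r}")
        if abscissa not in ("spacing", "size"):
            raise ValueError("abscissa must be 'spacing' or 'size'")
        tasks = {c.task for c in cells}
        if len(tasks) != 1:
            raise ValueError("all cells must share one TaskSpec")
        eccs = {c.eccentricity for c in cells}
        if len(eccs) != 1:
            raise ValueError("all cells must share one eccentricity")
        self.cells = cells
        self.form = form
        self.abscissa = abscissa
        self.task = cells[0].task
        self.eccentricity = cells[0].eccentricity
        self.seed = int(seed)
        if abscissa == "spacing":
            self._x, self._k, self._n, self._unflanked = _prepare(cells)
        else:
            self._x = np.array([math.log10(c.letter_size) for c in cells])
            self._k = np.array([c.n_correct for c in cells], dtype=float)
            self._n = np.array([c.n_trials for c in cells], dtype=float)
            self._unflanked = np.isinf(self._x)
        finite = self._x[~self._unflanked]
        if len(np.unique(np.round(finite, 12))) < 3:
            raise ValueError("need >= 3 distinct finite abscissa values to constrain a sigmoid")
        self.guess = self.task.guess_rate
        if asymptote == "free":
            self._fixed_asymptote = None
        else:
            a = float(asymptote)
            if not self.guess < a <= 1.0:
                raise ValueError("fixed asymptote must lie in (guess, 1]")
            self._fixed_asymptote = a
        lo, hi = finite.min(), finite.max()
        self._bounds_mu = (lo - 3.0, hi + 3.0)
        self._bounds_beta = (0.05, 50.0)
        self._bounds_A = (self.guess + 1e-4, 1.0)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "CrowdingFunctionModel":
        """Build from a tidy frame with columns eccentricity_deg, letter_size_deg,
        spacing_deg (inf for unflanked), n_alternatives, n_correct, n_trials."""
        cells = [
            StimulusCell(
                eccentricity=float(r.eccentricity_deg),
                letter_size=float(r.letter_size_deg),
                spacing=float(r.spacing_deg),
                task=TaskSpec(int(r.n_alternatives)),
                n_correct=int(r.n_correct),
                n_trials=int(r.n_trials),
            )
            for r in df.itertuples()
        ]
        return cls(cells, **kwargs)

    # --- likelihood machinery -------------------------------------------------

    def _predict_p(self, theta: np.ndarray, x: np.ndarray, unflanked: np.ndarray) -> np.ndarray:
        mu, beta = theta[0], theta[1]
        A = self._fixed_asymptote if self._fixed_asymptote is not None else theta[2]
        F = _LINKS[self.form][0]
        p = np.empty_like(x)
        fin = ~unflanked
        p[fin] = self.guess + (A - self.guess) * F(beta * (x[fin] - mu))
        p[unflanked] = A
        return p

    def _nll(self, theta: np.ndarray, k: np.ndarray | None = None) -> float:
        if k is None:
            k = self._k
        p = self._predict_p(theta, self._x, self._unflanked)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -float(np.sum(k * np.log(p) + (self._n - k) * np.log1p(-p)))

    def _theta_bounds(self) -> list[tuple[float, float]]:
        b = [self._bounds_mu, self._bounds_beta]
        if self._fixed_asymptote is None:
            b.append(self._bounds_A)
        return b

    def _start(self) -> np.ndarray:
        phat = self._k / self._n
        fin = ~self._unflanked
        A0 = float(np.clip(phat.max(), self.guess + 0.2, 1.0 - 1e-3))
        mid = (self.guess + A0) / 2.0
        order = np.argsort(self._x[fin])
        xs, ps = self._x[fin][order], phat[fin][order]
        idx = int(np.argmin(np.abs(ps - mid)))
        mu0 = float(xs[idx])
        theta = [mu0, 3.0]
        if self._fixed_asymptote is None:
            theta.append(A0)
        return np.array(theta)

    def _fit_once(self, start: np.ndarray, k: np.ndarray | None = None) -> tuple[np.ndarray, float]:
        res = minimize(
            self._nll,
            start,
            args=(k,),
            method="L-BFGS-B",
            bounds=self._theta_bounds(),
        )
        return res.x, float(res.fun)

    def _fit_mle(self, n_restarts: int, rng: np.random.Generator, k: np.ndarray | None = None,
                 extra_starts: Iterable[np.ndarray] = ()) -> tuple[np.ndarray, float]:
        base = self._start()
        starts = [base] + list(extra_starts)
        scales = np.array([0.4, 1.0] + ([0.1] if self._fixed_asymptote is None else []))
        for _ in range(max(0, n_restarts - len(starts))):
            jitter = rng.normal(0.0, 1.0, size=len(base)) * scales
            cand = base + jitter
            lo = np.array([b[0] for b in self._theta_bounds()])
            hi = np.array([b[1] for b in self._theta_bounds()])
            starts.append(np.clip(cand, lo, hi))
        best: tuple[np.ndarray, float] | None = None
        for s in starts:
            theta, nll = self._fit_once(s, k)
            if best is None or nll < best[1] - 1e-9:
                best = (theta, nll)
            elif abs(nll - best[1]) <= 1e-9 and theta[1] < best[0][1]:
                # tie on likelihood: prefer the shallower slope
                best = (theta, nll)
        assert best is not None
        return best

    # --- public fitting API ---------------------------------------------------

    def fit(
        self,
        n_restarts: int = 5,
        n_boot: int = 199,
        bootstrap: bool = True,
    ) -> "CrowdingFunctionResult":
        """Maximize the binomial likelihood; parametric bootstrap for uncertainty.

        Deterministic for a given model seed. Bootstrap refits start at
        the MLE (single start), which keeps 199 resamples fast.
        """
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        theta, nll = self._fit_mle(n_restarts, rng)
        boot = None
        if bootstrap and n_boot > 0:
            p_hat = np.clip(self._predict_p(theta, self._x, self._unflanked), 1e-9, 1 - 1e-9)
            boot = np.empty((n_boot, len(theta)))
            for b in range(n_boot):
                k_star = rng.binomial(self._n.astype(int), p_hat).astype(float)
                boot[b], _ = self._fit_once(theta, k_star)
        return CrowdingFunctionResult(model=self, theta=theta, loglike=-nll, boot=boot, method="mle+bootstrap")

    def fit_mcmc(self, n_walkers: int = 16, n_steps: int = 1500, n_burn: int = 500) -> "CrowdingFunctionResult":
        """Posterior sampling with flat priors over the box bounds (emcee)."""
        import emcee

        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        theta0, nll0 = self._fit_mle(5, rng)
        bounds = self._theta_bounds()

        def logpost(theta: np.ndarray) -> float:
            for v, (lo, hi) in zip(theta, bounds):
                if not lo <= v <= hi:
                    return -np.inf
            return -self._nll(theta)

        ndim = len(theta0)
        p0 = theta0 + 1e-3 * rng.standard_normal((n_walkers, ndim))
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        sampler = emcee.EnsembleSampler(n_walkers, ndim, logpost)
        sampler.run_mcmc(p0, n_steps, progress=False, rstate0=None)
        chain = sampler.get_chain(discard=n_burn, flat=True)
        theta = np.median(chain, axis=0)
        return CrowdingFunctionResult(
            model=self, theta=theta, loglike=-self._nll(theta), boot=chain, method="mcmc-flat-priors"
        )


@dataclass
class CrowdingFunctionResult:
    """Fitted crowding function: parameters, uncertainty, and readouts."""

    model: CrowdingFunctionModel
    theta: np.ndarray
    loglike: float
    boot: np.ndarray | None
    method: str

    @property
    def mu(self) -> float:
        return float(self.theta[0])

    @property
    def beta(self) -> float:
        return float(self.theta[1])

    @property
    def guess(self) -> float:
        return self.model.guess

    @property
    def asymptote(self) -> float:
        if self.model._fixed_asymptote is not None:
            return self.model._fixed_asymptote
        return float(self.theta[2])

    @property
    def form(self) -> str:
        return self.model.form

    @property
    def flags(self) -> list[str]:
        """Data-quality flags; 'unconstrained' mirrors dropping conditions whose
        functions are not constrained by the data (all-ceiling/all-floor)."""
        out = []
        eps = 1e-6
        if abs(self.beta - self.model._bounds_beta[0]) < 1e-3 or abs(self.beta - self.model._bounds_beta[1]) < 1e-3:
            out.append("unconstrained")
        lo, hi = self.model._bounds_mu
        if self.mu < lo + eps or self.mu > hi - eps:
            out.append("unconstrained")
        fin = ~self.model._unflanked
        xf = self.model._x[fin]
        if self.mu < xf.min() - 1.0 or self.mu > xf.max() + 1.0:
            out.append("unconstrained")
        phat = self.model._k / self.model._n
        amp = self.asymptote - self.guess
        if np.all(phat[fin] >= self.guess + 0.9 * amp) or np.all(phat[fin] <= self.guess + 0.1 * amp):
            out.append("unconstrained")
        return sorted(set(out))

    def predict(self, spacing) -> np.ndarray:
        """Predicted proportion correct at center-to-center spacing (degrees)."""
        spacing = np.atleast_1d(np.asarray(spacing, dtype=float))
        x = np.where(np.isinf(spacing), np.inf, np.log10(spacing))
        return self.model._predict_p(self.theta, x, np.isinf(x))

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Percentile intervals from the bootstrap/posterior draws."""
        if self.boot is None:
            raise ValueError("no bootstrap/posterior draws; fit with bootstrap=True")
        qs = np.quantile(self.boot, [alpha / 2, 1 - alpha / 2], axis=0)
        names = ["mu", "beta"] + ([] if self.model._fixed_asymptote is not None else ["asymptote"])
        return {nm: (float(qs[0, i]), float(qs[1, i])) for i, nm in enumerate(names)}

    def critical_spacing(self, criterion: CriterionSpec, alpha: float | None = 0.05) -> CriticalSpacingEstimate:
        return critical_spacing(self, criterion, alpha=alpha)

    def zscore_normalize(self, eps: float = 1e-3) -> list[tuple[float, float]]:
        return zscore_normalize(self.model.cells, self, eps=eps)

    def summary(self) -> str:
        lines = [
            "Crowding function fit",
            "=" * 60,
            f"form: {self.form}   method: {self.method}   abscissa: log10 {self.model.abscissa}",
            f"task: {self.model.task.n_alternatives}-AFC (guess {self.guess:.4f})   "
            f"eccentricity: {self.model.eccentricity:g} deg",
            f"n cells: {len(self.model.cells)}   log-likelihood: {self.loglike:.3f}",
            "-" * 60,
            f"{'param':<12}{'estimate':>12}{'95% CI':>26}",
        ]
        cis = self.conf_int() if self.boot is not None else {}
        rows = [("mu (log10)", self.mu, cis.get("mu")), ("beta", self.beta, cis.get("beta")),
                ("asymptote", self.asymptote, cis.get("asymptote"))]
        for name, est, ci in rows:
            ci_s = f"[{ci[0]:.4f}, {ci[1]:.4f}]" if ci else "(fixed)" if name == "asymptote" and self.model._fixed_asymptote is not None else ""
            lines.append(f"{name:<12}{est:>12.4f}{ci_s:>26}")
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Quick-look plot of data and fitted curve on a log abscissa."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fin = ~self.model._unflanked
        x = self.model._x
        phat = self.model._k / self.model._n
        ax.semilogx(10 ** x[fin], phat[fin], "o", label="data")
        grid = np.logspace(x[fin].min() - 0.2, x[fin].max() + 0.2, n_grid)
        ax.semilogx(grid, self.predict(grid), "-", label="fit")
        if self.model._unflanked.any():
            ax.axhline(self.asymptote, ls=":", color="gray", label="asymptote")
        ax.set_xlabel(f"{self.model.abscissa} (deg)")
        ax.set_ylabel("proportion correct")
        ax.legend()
        return ax


# --- shared-slope joint fitting ----------------------------------------------


class SharedSlopeModel:
    """Joint fit of several crowding functions with one common slope.

    Parallel psychometric functions on a log abscissa — one beta, a
    location mu_j (and optionally an asymptote A_j) per condition — are
    the minimal-assumption model behind the flanked-acuity landscape.
    """

    def __init__(
        self,
        groups: Sequence[Sequence[StimulusCell]],
        form: Form = "logistic",
        asymptote: float | str = "free",
        abscissa: str = "spacing",
        seed: int = 0,
    ) -> None:
        if len(groups) < 2:
            raise ValueError("need >= 2 groups for a shared-slope fit")
        self.submodels = [
            CrowdingFunctionModel(g, form=form, asymptote=asymptote, abscissa=abscissa, seed=seed + 1 + i)
            for i, g in enumerate(groups)
        ]
        self.form = form
        self.seed = int(seed)
        self._free_A = self.submodels[0]._fixed_asymptote is None

    def _unpack(self, theta: np.ndarray) -> list[np.ndarray]:
        k = len(self.submodels)
        beta = theta[0]
        mus = theta[1 : 1 + k]
        out = []
        for j, sm in enumerate(self.submodels):
            if self._free_A:
                out.append(np.array([mus[j], beta, theta[1 + k + j]]))
            else:
                out.append(np.array([mus[j], beta]))
        return out

    def _nll(self, theta: np.ndarray) -> float:
        return sum(sm._nll(th) for sm, th in zip(self.submodels, self._unpack(theta)))

    def _bounds(self) -> list[tuple[float, float]]:
        b = [self.submodels[0]._bounds_beta]
        b += [sm._bounds_mu for sm in self.submodels]
        if self._free_A:
            b += [sm._bounds_A for sm in self.submodels]
        return b

    def fit(self, n_restarts: int = 5, n_boot: int = 0) -> "SharedSlopeResult":
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        # free-slope single fits double as starts and as the deviance reference
        singles = [sm.fit(n_restarts=3, bootstrap=False) for sm in self.submodels]
        ll_free = sum(s.loglike for s in singles)
        start = [float(np.median([s.beta for s in singles]))]
        start += [s.mu for s in singles]
        if self._free_A:
            start += [s.asymptote for s in singles]
        start = np.array(start)

        def run(s0: np.ndarray) -> tuple[np.ndarray, float]:
            res = minimize(self._nll, s0, method="L-BFGS-B", bounds=self._bounds())
            return res.x, float(res.fun)

        best = run(start)
        for _ in range(max(0, n_restarts - 1)):
            jit = start.copy()
            jit[0] = max(0.06, jit[0] * math.exp(rng.normal(0, 0.3)))
            jit[1 : 1 + len(self.submodels)] += rng.normal(0, 0.15, len(self.submodels))
            cand = run(np.clip(jit, [b[0] for b in self._bounds()], [b[1] for b in self._bounds()]))
            if cand[1] < best[1] - 1e-9:
                best = cand
        theta, nll = best
        boot = None
        if n_boot > 0:
            boot = np.empty((n_boot, len(theta)))
            thetas = self._unpack(theta)
            p_hats = [
                np.clip(sm._predict_p(th, sm._x, sm._unflanked), 1e-9, 1 - 1e-9)
                for sm, th in zip(self.submodels, thetas)
            ]
            originals = [sm._k for sm in self.submodels]
            for b in range(n_boot):
                for sm, ph in zip(self.submodels, p_hats):
                    sm._k = rng.binomial(sm._n.astype(int), ph).astype(float)
                boot[b], _ = run(theta)
            for sm, k0 in zip(self.submodels, originals):
                sm._k = k0
        deviance = 2.0 * (ll_free - (-nll))
        return SharedSlopeResult(
            model=self, theta=theta, loglike=-nll, deviance_vs_free_slopes=deviance,
            df_deviance=len(self.submodels) - 1, boot=boot, singles=singles,
        )


@dataclass
class SharedSlopeResult:
    """Joint shared-slope fit across conditions."""

    model: SharedSlopeModel
    theta: np.ndarray
    loglike: float
    deviance_vs_free_slopes: float
    df_deviance: int
    boot: np.ndarray | None
    singles: list[CrowdingFunctionResult]

    @property
    def beta_shared(self) -> float:
        return float(self.theta[0])

    @property
    def per_group(self) -> list[dict[str, float]]:
        out = []
        for sm, th in zip(self.model.submodels, self.model._unpack(self.theta)):
            A = sm._fixed_asymptote if sm._fixed_asymptote is not None else float(th[2])
            out.append({"mu": float(th[0]), "asymptote": A, "guess": sm.guess})
        return out

    def group_result(self, j: int) -> CrowdingFunctionResult:
        """Per-group result object carrying the shared slope (for readouts)."""
        sm = self.model.submodels[j]
        th = self.model._unpack(self.theta)[j]
        return CrowdingFunctionResult(model=sm, theta=th, loglike=-sm._nll(th), boot=None, method="shared-slope")

    def conf_int_beta(self, alpha: float = 0.05) -> tuple[float, float]:
        if self.boot is None:
            raise ValueError("fit with n_boot > 0 for an interval on beta")
        lo, hi = np.quantile(self.boot[:, 0], [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            "Shared-slope crowding fit",
            "=" * 60,
            f"form: {self.model.form}   groups: {len(self.model.submodels)}",
            f"shared beta: {self.beta_shared:.4f}",
            f"log-likelihood: {self.loglike:.3f}   deviance vs free slopes: "
            f"{self.deviance_vs_free_slopes:.3f} (df {self.df_deviance})",
            "-" * 60,
            f"{'group':<8}{'mu':>10}{'asymptote':>12}",
        ]
        for j, g in enumerate(self.per_group):
            lines.append(f"{j:<8}{g['mu']:>10.4f}{g['asymptote']:>12.4f}")
        return "\n".join(lines)


# --- readouts -----------------------------------------------------------------


def fit_crowding_function(cells: Sequence[StimulusCell], form: Form = "logistic", **options) -> CrowdingFunctionResult:
    """Functional wrapper: build a :class:`CrowdingFunctionModel` and fit it."""
    fit_kw = {k: options.pop(k) for k in ("n_restarts", "n_boot", "bootstrap") if k in options}
    return CrowdingFunctionModel(cells, form=form, **options).fit(**fit_kw)


def fit_shared_slope(groups: Sequence[Sequence[StimulusCell]], form: Form = "logistic", **options) -> SharedSlopeResult:
    """Functional wrapper: joint shared-slope fit across groups."""
    fit_kw = {k: options.pop(k) for k in ("n_restarts", "n_boot") if k in options}
    return SharedSlopeModel(groups, form=form, **options).fit(**fit_kw)


def critical_spacing(
    fit: CrowdingFunctionResult, criterion: CriterionSpec, alpha: float | None = 0.05
) -> CriticalSpacingEstimate:
    """Invert a fitted sigmoid at a criterion level; closed form, in degrees.

    Returns an estimate with status "unattainable" when the raw level
    exceeds the fitted asymptote (the curve never gets there), which is
    how too-small letters manifest in fixed-criterion analyses.
    """
    g, A = fit.guess, fit.asymptote
    try:
        level = criterion_level(criterion, g, A)
    except CriterionUnattainableError:
        if criterion.family == "absolute" and criterion.level >= A:
            return CriticalSpacingEstimate(value=float("nan"), status="unattainable", criterion=criterion)
        raise
    if level <= g:
        raise ValueError("criterion level at or below the guess rate is invalid")
    if level >= A:
        return CriticalSpacingEstimate(value=float("nan"), status="unattainable", criterion=criterion, raw_level=level)

    def invert(mu: float, beta: float, A_: float) -> float:
        q = (level - g) / (A_ - g)
        if not 0.0 < q < 1.0:
            return float("nan")
        Finv = _LINKS[fit.form][1]
        return 10.0 ** (mu + float(Finv(q)) / beta)

    value = invert(fit.mu, fit.beta, A)
    ci = None
    if alpha is not None and fit.boot is not None:
        draws = []
        for row in fit.boot:
            A_b = fit.model._fixed_asymptote if fit.model._fixed_asymptote is not None else row[2]
            try:
                lv = criterion_level(criterion, g, A_b)
            except CriterionUnattainableError:
                continue
            q = (lv - g) / (A_b - g)
            if 0 < q < 1:
                Finv = _LINKS[fit.form][1]
                draws.append(10.0 ** (row[0] + float(Finv(q)) / row[1]))
        if len(draws) >= 10:
            lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
            ci = (float(lo), float(hi))
    return CriticalSpacingEstimate(value=value, status="ok", criterion=criterion, raw_level=level, conf_int=ci)


def zscore_normalize(
    cells: Sequence[StimulusCell], fit: CrowdingFunctionResult, eps: float = 1e-3
) -> list[tuple[float, float]]:
    """Express observed proportions as probit z of the guessing-corrected scale.

    Curves measured at different sizes (hence different asymptotes)
    collapse onto a common template in these coordinates. Corrected
    proportions are clamped to [eps, 1 - eps] before the probit.
    """
    if not fit.asymptote > fit.guess:
        raise ValueError("fit asymptote must exceed the guess rate")
    out = []
    for c in cells:
        if c.is_unflanked:
            continue
        corrected = (c.proportion_correct - fit.guess) / (1.0 - fit.guess)
        corrected = min(max(corrected, eps), 1.0 - eps)
        out.append((math.log10(c.spacing), float(ndtri(corrected))))
    return out
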