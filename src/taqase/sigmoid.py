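"""Four-parameter logistic fitting of qPCR amplification curves.

Raw per-cycle fluorescence from one well and one channel is modelled as

    F(t) = y0 + a / (1 + exp(-(t - b) / c))

with baseline ``y0``, plateau amplitude ``a`` above baseline, inflection
cycle ``b`` and slope scale ``c``.  A two-step refinement refits the curve
after truncating plateau-phase cycles identified by the first fit, which
reduces the parameter bias introduced by a variable-length plateau (late
plateau drift pulls ``b`` and ``a`` away from the kinetic phase that
actually carries the information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CHANNELS",
    "FluorescenceCurve",
    "SigmoidFit",
    "NoAmplificationError",
    "logistic4",
    "initial_guess",
    "fit_sigmoid_single",
    "fit_sigmoid_two_step",
    "FourParamLogistic",
]

CHANNELS = ("FAM", "VIC")

# internal seed for multi-start jitter; fixed so refits are reproducible
_MULTISTART_SEED = 192837


class NoAmplificationError(ValueError):
    """Raised when a curve carries no amplification signal above noise."""


@dataclass(frozen=True)
class FluorescenceCurve:
    """Per-cycle raw fluorescence for one well and one dye channel."""

    well_id: str
    channel: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=int)
        fluor = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluor)
        channel = str(self.channel).upper()
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        object.__setattr__(self, "channel", channel)
        if cycles.ndim != 1 or fluor.ndim != 1 or len(cycles) != len(fluor):
            raise ValueError("cycles and fluorescence must be 1-D and equal length")
        if len(cycles) < 8:
            raise ValueError("need at least 8 cycles to identify 4 parameters")
        if not np.all(np.diff(cycles) == 1):
            raise ValueError("cycles must be strictly increasing consecutive integers")
        if not np.all(np.isfinite(fluor)):
            raise ValueError("fluorescence values must be finite")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class SigmoidFit:
    """Fitted four-parameter logistic with fit diagnostics."""

    y0: float
    a: float
    b: float
    c: float
    rss: float
    converged: bool
    truncation_cycle: int | None = None
    step2_fell_back: bool = False

    def params(self) -> tuple[float, float, float, float]:
        return (self.y0, self.a, self.b, self.c)

    def predict(self, cycles: Sequence[float]) -> np.ndarray:
        return logistic4(np.asarray(cycles, dtype=float), self.y0, self.a, self.b, self.c)


def logistic4(t: np.ndarray, y0: float, a: float, b: float, c: float) -> np.ndarray:
    """Evaluate the 4-parameter logistic at cycles ``t``."""
    return y0 + a / (1.0 + np.exp(-(np.asarray(t, dtype=float) - b) / c))


def _robust_noise_sd(fluor: np.ndarray) -> float:
    # sigma of iid read noise from successive differences; insensitive to the
    # smooth sigmoid trend, which contributes little to the median difference
    diffs = np.abs(np.diff(fluor))
    if len(diffs) == 0:
        return 0.0
    return 1.4826 * float(np.median(diffs)) / math.sqrt(2.0)


def initial_guess(curve: FluorescenceCurve) -> tuple[float, float, float, float]:
    """Heuristic (y0, a, b, c) seeds for the optimizer.

    Raises :class:`NoAmplificationError` when the signal range is
    indistinguishable from read noise (flat or noise-only channel, e.g. the
    dye for an allele absent from the reaction).
    """
    fluor = curve.fluorescence
    cycles = curve.cycles.astype(float)
    fmin, fmax = float(np.min(fluor)), float(np.max(fluor))
    frange = fmax - fmin
    noise_floor = max(10.0 * _robust_noise_sd(fluor), 1e-12 * max(1.0, abs(fmax)))
    if frange < noise_floor:
        raise NoAmplificationError(
            f"well {curve.well_id} channel {curve.channel}: "
            f"signal range {frange:.3g} below noise floor {noise_floor:.3g}"
        )
    y0 = fmin
    a = frange
    diffs = np.diff(fluor)
    dmax = float(np.max(diffs))
    # ties (e.g. a linear ramp) resolve to the median tied cycle
    tied = np.flatnonzero(diffs >= dmax - 1e-9 * max(abs(dmax), 1.0))
    b = float(np.median(cycles[tied + 1]))
    mid = (fluor - fmin) / frange
    rising = cycles[(mid >= 0.25) & (mid <= 0.75)]
    if len(rising) >= 2:
        # logistic rises 25%->75% over 2*ln(3)*c cycles
        c = (float(rising.max()) - float(rising.min())) / (2.0 * math.log(3.0))
    else:
        c = 1.0
    return (y0, a, b, max(c, 0.5))


def _default_bounds(fluor: np.ndarray, n_cycles: int) -> tuple[np.ndarray, np.ndarray]:
    fmin, fmax = float(np.min(fluor)), float(np.max(fluor))
    frange = max(fmax - fmin, 1e-12)
    lower = np.array([fmin - frange, 1e-9 * frange, 0.0, 0.05])
    upper = np.array([fmax, 10.0 * frange, 2.0 * n_cycles, float(n_cycles)])
    return lower, upper


def _residual_and_jac(t: np.ndarray, f: np.ndarray):
    def residual(p: np.ndarray) -> np.ndarray:
        y0, a, b, c = p
        s = 1.0 / (1.0 + np.exp(-(t - b) / c))
        return y0 + a * s - f

    def jac(p: np.ndarray) -> np.ndarray:
        y0, a, b, c = p
        s = 1.0 / (1.0 + np.exp(-(t - b) / c))
        w = s * (1.0 - s)
        J = np.empty((len(t), 4))
        J[:, 0] = 1.0
        J[:, 1] = s
        J[:, 2] = -a * w / c
        J[:, 3] = -a * w * (t - b) / (c * c)
        return J

    return residual, jac


def _fit_arrays(
    t: np.ndarray,
    f: np.ndarray,
    seeds: tuple[float, float, float, float],
    tol: float,
    max_iter: int,
    n_cycles_bound: int,
    multi_start: int = 5,
) -> tuple[np.ndarray, float, bool]:
    lower, upper = _default_bounds(f, n_cycles_bound)
    residual, jac = _residual_and_jac(t, f)

    def attempt(p0: np.ndarray):
        p0 = np.clip(p0, lower + 1e-12, upper - 1e-12)
        try:
            return least_squares(
                residual,
                p0,
                jac=jac,
                bounds=(lower, upper),
                method="trf",
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=max_iter,
            )
        except Exception:
            return None

    res = attempt(np.asarray(seeds, dtype=float))
    best = res
    if res is None or res.status <= 0 or not np.isfinite(res.cost):
        rng = np.random.default_rng(_MULTISTART_SEED)
        for _ in range(multi_start):
            jitter = 1.0 + rng.uniform(-0.3, 0.3, size=4)
            res = attempt(np.asarray(seeds, dtype=float) * jitter)
            if res is None:
                continue
            if best is None or (np.isfinite(res.cost) and res.cost < best.cost):
                best = res
            if res.status > 0 and np.isfinite(res.cost):
                break
    if best is None:
        return np.asarray(seeds, dtype=float), float("inf"), False
    converged = best.status > 0 and bool(np.all(np.isfinite(best.x)))
    rss = float(2.0 * best.cost)
    return best.x, rss, converged


def fit_sigmoid_single(
    curve: FluorescenceCurve,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> SigmoidFit:
    """Nonlinear least-squares fit of the 4-parameter logistic to all cycles."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    seeds = initial_guess(curve)
    t = curve.cycles.astype(float)
    params, rss, converged = _fit_arrays(
        t, curve.fluorescence, seeds, tol, max_iter, curve.n_cycles
    )
    y0, a, b, c = (float(v) for v in params)
    return SigmoidFit(y0=y0, a=a, b=b, c=c, rss=rss, converged=converged)


def default_plateau_rule(fit: SigmoidFit, n_cycles: int) -> int:
    """Last cycle to keep for the refit: ceil(b + 3c), clamped to [b+2, n]."""
    raw = min(max(fit.b + 3.0 * fit.c, fit.b + 2.0), float(n_cycles))
    return min(int(math.ceil(raw)), n_cycles)


def fit_sigmoid_two_step(
    curve: FluorescenceCurve,
    tol: float = 1e-10,
    max_iter: int = 2000,
    plateau_rule: Callable[[SigmoidFit, int], int] | None = None,
) -> SigmoidFit:
    """Two-step fit: full-curve fit, then refit on cycles up to the plateau onset.

    The truncation point defaults to ``ceil(b + 3c)`` from the step-1 fit,
    i.e. roughly where 95% of the plateau is reached.  If truncation would
    remove fewer than 2 cycles (or leave too few points), the step-1 fit is
    returned unchanged.  A non-converging refit falls back to step 1 with
    ``step2_fell_back`` set.
    """
    rule = plateau_rule or default_plateau_rule
    step1 = fit_sigmoid_single(curve, tol=tol, max_iter=max_iter)
    if not step1.converged:
        return step1
    last_cycle = int(curve.cycles[-1])
    trunc = rule(step1, last_cycle)
    keep = curve.cycles <= trunc
    n_keep = int(np.count_nonzero(keep))
    if curve.n_cycles - n_keep < 2 or n_keep < 8:
        return step1
    t = curve.cycles[keep].astype(float)
    f = curve.fluorescence[keep]
    params, rss, converged = _fit_arrays(
        t, f, step1.params(), tol, max_iter, curve.n_cycles
    )
    if not converged:
        return SigmoidFit(
            y0=step1.y0, a=step1.a, b=step1.b, c=step1.c, rss=step1.rss,
            converged=True, truncation_cycle=trunc, step2_fell_back=True,
        )
    y0, a, b, c = (float(v) for v in params)
    return SigmoidFit(y0=y0, a=a, b=b, c=c, rss=rss, converged=True,
                      truncation_cycle=trunc)


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the 4-parameter logistic amplification model.

    Parameters
    ----------
    two_step : bool, default True
        Apply the plateau-truncating refit after the full-curve fit.
    tol : float, default 1e-10
        Optimizer convergence tolerance (xtol/ftol/gtol).
    max_iter : int, default 2000
        Maximum residual evaluations per optimizer run.
    plateau_rule : callable or None
        ``(SigmoidFit, n_cycles) -> last cycle kept``; None uses ceil(b+3c).

    Attributes
    ----------
    y0_, a_, b_, c_ : float
        Fitted baseline, amplitude, inflection cycle and slope scale.
    rss_ : float
        Residual sum of squares of the returned fit.
    converged_ : bool
    truncation_cycle_ : int or None
    fit_result_ : SigmoidFit
    """

    def __init__(self, two_step: bool = True, tol: float = 1e-10,
                 max_iter: int = 2000, plateau_rule=None):
        self.two_step = two_step
        self.tol = tol
        self.max_iter = max_iter
        self.plateau_rule = plateau_rule

    def fit(self, X, y):
        cycles = np.asarray(X).reshape(-1)
        fluor = np.asarray(y, dtype=float).reshape(-1)
        curve = FluorescenceCurve("estimator", "FAM", cycles, fluor)
        if self.two_step:
            result = fit_sigmoid_two_step(
                curve, tol=self.tol, max_iter=self.max_iter,
                plateau_rule=self.plateau_rule,
            )
        else:
            result = fit_sigmoid_single(curve, tol=self.tol, max_iter=self.max_iter)
        self.fit_result_ = result
        self.y0_, self.a_, self.b_, self.c_ = result.params()
        self.rss_ = result.rss
        self.converged_ = result.converged
        self.truncation_cycle_ = result.truncation_cycle
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return logistic4(t, self.y0_, self.a_, self.b_, self.c_)
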