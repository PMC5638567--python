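"""Standard-curve calibration of k' against predefined plasmid mixtures.

Thirteen plasmid standards mix the two alleles at known P. mexicana-derived
fractions x in {1.0, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1,
0.05, 0.0}.  The replicate-averaged k' of each mixture is regressed on x by
ordinary least squares (k' = intercept + slope * x); unknown samples are
then inverted through the line, x_hat = (k' - intercept) / slope, and
clamped to [0, 1].  Pure-plasmid standards (x = 0 and x = 1) behave
aberrantly in the assay and are excluded from the regression by default
while still contributing to precision summaries (CV, Intra-CV).

A bundled reference dataset (``load_reference_standards``) carries the
published replicate-averaged k' and CV values for the 13 standards of the
original ar-alpha assay, one series each for the cDNA and gDNA runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "AlleleFrequencyEstimate",
    "coefficient_of_variation",
    "intra_cv",
    "build_standard_curve",
    "estimate_frequency",
    "StandardCurveCalibrator",
    "load_reference_standards",
    "reference_standard_points",
]

_PURE_TOL = 1e-12


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Percent CV: 100 * sample sd (n-1) / mean.  Needs >= 2 values, nonzero mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / mean


@dataclass
class StandardPoint:
    """One plasmid mixture: known allele fraction with replicate k' values.

    Either ``k_values`` (raw replicates) or precomputed summary values
    (``k_mean``/``cv_percent``, e.g. from a published table) are supplied.
    """

    x_true: float
    k_values: tuple[float, ...] = ()
    k_mean: float | None = None
    cv_percent: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_true <= 1.0:
            raise ValueError(f"x_true must lie in [0, 1], got {self.x_true}")
        self.k_values = tuple(float(v) for v in self.k_values)
        if self.k_values:
            mean = float(np.mean(self.k_values))
            if self.k_mean is None:
                self.k_mean = mean
            if self.cv_percent is None and len(self.k_values) >= 2:
                self.cv_percent = coefficient_of_variation(self.k_values)
        if self.k_mean is None:
            raise ValueError("StandardPoint needs k_values or an explicit k_mean")

    @property
    def is_pure(self) -> bool:
        return self.x_true <= _PURE_TOL or self.x_true >= 1.0 - _PURE_TOL


@dataclass
class StandardCurve:
    """OLS calibration line k' = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded_pure: bool
    assay: str = "cDNA"

    def predict_k(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def invert(self, k: float) -> float:
        """Raw (unclamped) allele-fraction estimate for a k' value."""
        if self.slope == 0:
            raise ValueError("non-informative calibration: zero slope")
        return (k - self.intercept) / self.slope


@dataclass
class AlleleFrequencyEstimate:
    sample_id: str
    tissue: str
    k_values: tuple[float, ...]
    x_hat: float
    clamped: bool
    x_hat_replicates: tuple[float, ...] = ()
    x_replicate_sd: float | None = None

    @property
    def k_mean(self) -> float:
        return float(np.mean(self.k_values))


def intra_cv(points: Iterable[StandardPoint]) -> float:
    """Unweighted mean CV (%) over all standards, pure mixtures included."""
    cvs = [p.cv_percent for p in points if p.cv_percent is not None]
    if not cvs:
        raise ValueError("no standard points with a defined CV")
    return float(np.mean(cvs))


def build_standard_curve(points: Sequence[StandardPoint],
                         exclude_pure: bool = True,
                         assay: str = "cDNA") -> StandardCurve:
    """OLS of replicate-averaged k' on the known mixture fraction x."""
    included = [p for p in points if not (exclude_pure and p.is_pure)]
    if len(included) < 3:
        raise ValueError("underdetermined calibration: need >= 3 included points")
    x = np.array([p.x_true for p in included])
    k = np.array([p.k_mean for p in included])
    if np.all(x == x[0]):
        raise ValueError("all standards share one mixture fraction; cannot calibrate")
    res = stats.linregress(x, k)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_points=len(included),
        excluded_pure=exclude_pure,
        assay=assay,
    )


def estimate_frequency(k_values: Sequence[float], curve: StandardCurve,
                       sample_id: str = "", tissue: str = "") -> AlleleFrequencyEstimate:
    """Invert replicate k' values through the standard curve.

    The replicate mean k' is inverted (average-then-invert); per-replicate
    inversions are retained so downstream dispersion can be reported.
    """
    ks = tuple(float(v) for v in k_values)
    if not ks:
        raise ValueError("need at least one k' value")
    raw = curve.invert(float(np.mean(ks)))
    clamped = not 0.0 <= raw <= 1.0
    x_hat = float(np.clip(raw, 0.0, 1.0))
    reps = tuple(float(np.clip(curve.invert(k), 0.0, 1.0)) for k in ks)
    rep_sd = float(np.std(reps, ddof=1)) if len(reps) >= 2 else None
    return AlleleFrequencyEstimate(
        sample_id=sample_id, tissue=tissue, k_values=ks,
        x_hat=x_hat, clamped=clamped,
        x_hat_replicates=reps, x_replicate_sd=rep_sd,
    )


class StandardCurveCalibrator(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper around the standard-curve regression.

    ``fit(X, y)`` takes known mixture fractions ``X`` (n,) or (n, 1) and
    replicate-averaged k' values ``y``; ``predict`` maps fractions to k',
    and :meth:`estimate_frequency` inverts k' values to clamped allele
    fractions.

    Attributes
    ----------
    slope_, intercept_, r_squared_ : float
    curve_ : StandardCurve
    """

    def __init__(self, exclude_pure: bool = True, assay: str = "cDNA"):
        self.exclude_pure = exclude_pure
        self.assay = assay

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(k):
            raise ValueError("X and y must have equal length")
        points = [StandardPoint(x_true=xi, k_mean=ki) for xi, ki in zip(x, k)]
        self.curve_ = build_standard_curve(points, exclude_pure=self.exclude_pure,
                                           assay=self.assay)
        self.slope_ = self.curve_.slope
        self.intercept_ = self.curve_.intercept
        self.r_squared_ = self.curve_.r_squared
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.curve_.predict_k(x)

    def estimate_frequency(self, k):
        """Clamped allele-fraction estimates for k' values (array-like)."""
        ks = np.asarray(k, dtype=float).reshape(-1)
        return np.array([
            estimate_frequency([ki], self.curve_).x_hat for ki in ks
        ])


def load_reference_standards() -> pd.DataFrame:
    """Published 13-standard calibration summaries for the ar-alpha assay.

    Columns: assay (cDNA|gDNA), x_true_percent, k_mean, cv_percent.
    """
    with resources.files("taqase.data").joinpath("reference_standards.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_standard_points(assay: str = "cDNA") -> list[StandardPoint]:
    """The bundled reference series for one assay as StandardPoint objects."""
    df = load_reference_standards()
    sub = df[df["assay"] == assay]
    if sub.empty:
        raise ValueError(f"unknown assay {assay!r}; expected cDNA or gDNA")
    return [
        StandardPoint(x_true=row.x_true_percent / 100.0,
                      k_mean=row.k_mean, cv_percent=row.cv_percent)
        for row in sub.itertuples()
    ]
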