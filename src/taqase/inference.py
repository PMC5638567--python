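"""Tissue-level ASE inference.

Per-tissue allele-frequency estimates (one value per biological sample,
technical replicates already collapsed upstream) are summarised and tested
for deviation from balanced 1:1 expression with a two-sided one-sample
t-test against 0.5.  Differences between tissues are assessed with a
one-way fixed-effects ANOVA followed by Tukey HSD pairwise comparisons
(family-wise adjusted p-values); Bonferroni-adjusted pairwise t-tests are
available as an alternative post hoc.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .calibration import AlleleFrequencyEstimate

__all__ = ["TissueSummary", "AnovaResult", "tissue_summary", "anova_across_tissues"]


@dataclass
class TissueSummary:
    tissue: str
    n_samples: int
    mean_x: float
    sd_x: float
    t_vs_half: float | None
    p_vs_half: float | None
    significant_vs_half: bool
    alpha: float = 0.05
    degenerate: bool = False


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    posthoc: list[tuple[tuple[str, str], float]] = field(default_factory=list)


def tissue_summary(estimates: Sequence[AlleleFrequencyEstimate], tissue: str,
                   alpha: float = 0.05) -> TissueSummary:
    """Summarise one tissue and test its mean allele fraction against 0.5."""
    xs = np.array([e.x_hat for e in estimates if e.tissue == tissue], dtype=float)
    n = len(xs)
    if n == 0:
        raise ValueError(f"no estimates for tissue {tissue!r}")
    if n < 2:
        return TissueSummary(tissue=tissue, n_samples=n, mean_x=float(xs[0]),
                             sd_x=0.0, t_vs_half=None, p_vs_half=None,
                             significant_vs_half=False, alpha=alpha, degenerate=True)
    mean = float(np.mean(xs))
    sd = float(np.std(xs, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        sd = 0.0
        if abs(mean - 0.5) <= 1e-12:
            return TissueSummary(tissue, n, mean, sd, 0.0, 1.0, False, alpha, True)
        t = math.copysign(math.inf, mean - 0.5)
        return TissueSummary(tissue, n, mean, sd, t, 0.0, True, alpha, True)
    t, p = stats.ttest_1samp(xs, 0.5)
    return TissueSummary(tissue=tissue, n_samples=n, mean_x=mean, sd_x=sd,
                         t_vs_half=float(t), p_vs_half=float(p),
                         significant_vs_half=bool(p < alpha), alpha=alpha)


def anova_across_tissues(groups: Mapping[str, Sequence[float]],
                         posthoc: str = "tukey",
                         alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA on per-sample allele fractions, with pairwise post hoc.

    ``posthoc`` is ``"tukey"`` (Tukey HSD, default) or ``"bonferroni"``
    (pairwise two-sample t-tests with Bonferroni correction).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    n_total = sum(len(a) for a in arrays)
    df_between = len(names) - 1
    df_within = n_total - len(names)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    pairs = list(itertools.combinations(names, 2))

    if np.all(values == values[0]):
        return AnovaResult(f_stat=0.0, df_between=df_between, df_within=df_within,
                           p_value=1.0, posthoc=[(p, 1.0) for p in pairs])

    f_stat, p_value = stats.f_oneway(*arrays)
    if posthoc == "tukey":
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        uniq = list(res.groupsunique)
        tukey_pairs = list(itertools.combinations(uniq, 2))
        pvals = dict(zip(tukey_pairs, np.atleast_1d(res.pvalues)))
        ph = [((a, b), float(pvals[tuple(sorted((a, b)))])) for a, b in pairs]
    elif posthoc == "bonferroni":
        m = len(pairs)
        ph = []
        for a, b in pairs:
            _, p = stats.ttest_ind(np.asarray(groups[a], float),
                                   np.asarray(groups[b], float))
            ph.append(((a, b), float(min(1.0, p * m))))
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return AnovaResult(f_stat=float(f_stat), df_between=df_between,
                       df_within=df_within, p_value=float(p_value), posthoc=ph)
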