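"""The transformed fluorescence ratio k' for dual-probe allele quantification.

A TaqMan reaction interrogating one heterozygous site carries two dyes: FAM
reports one allele (here the P. latipinna-derived allele) and VIC the other
(P. mexicana-derived).  After both channels are fitted with the 4-parameter
logistic, the conditional fluorescence ratio R' combines the plateau-height
ratio with a correction for which channel reached its maximum amplification
speed first:

    b_fam < b_vic:  R' = 0.5 * (a_fam/a_vic) * (1 + exp(-(b_fam - b_vic)/c_vic))
    b_fam > b_vic:  R' = 2   * (a_fam/a_vic) / (1 + exp(-(b_vic - b_fam)/c_fam))

Both branches coincide at b_fam == b_vic, where R' = a_fam/a_vic.  The
transformed ratio k' = R'/(R' + 1) maps R' from (0, inf) onto (0, 1) with
k'(1) = 0.5; it is the statistic calibrated against known allele mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .sigmoid import FluorescenceCurve, SigmoidFit, fit_sigmoid_two_step

__all__ = [
    "Branch",
    "KPrimeResult",
    "compute_r_prime",
    "compute_k_prime",
    "k_prime_for_reaction",
]

# two inflection cycles closer than this are treated as simultaneous
TIE_TOLERANCE = 1e-9


class Branch(str, Enum):
    EQ1 = "EQ1"  # FAM reached maximum speed first (b_fam < b_vic)
    EQ2 = "EQ2"  # VIC reached maximum speed first (b_fam > b_vic)
    TIE = "TIE"  # simultaneous inflection; both formulas coincide


@dataclass
class KPrimeResult:
    r_prime: float
    k_prime: float
    branch: Branch
    fam_fit: SigmoidFit
    vic_fit: SigmoidFit


def compute_r_prime(fam_fit: SigmoidFit, vic_fit: SigmoidFit,
                    tie_tol: float = TIE_TOLERANCE) -> tuple[float, Branch]:
    """Conditional fluorescence ratio R' from a pair of channel fits."""
    if not (fam_fit.converged and vic_fit.converged):
        raise ValueError("unfit curve: both channel fits must have converged")
    if vic_fit.a <= 0:
        raise ValueError("degenerate VIC channel: non-positive plateau amplitude")
    if fam_fit.c <= 0 or vic_fit.c <= 0:
        raise ValueError("slope scales must be positive")
    ratio = fam_fit.a / vic_fit.a
    db = fam_fit.b - vic_fit.b
    if abs(db) <= tie_tol:
        return ratio, Branch.TIE
    if db < 0:
        r = 0.5 * ratio * (1.0 + math.exp(-db / vic_fit.c))
        return r, Branch.EQ1
    r = 2.0 * ratio / (1.0 + math.exp(db / fam_fit.c))
    return r, Branch.EQ2


def compute_k_prime(r_prime: float) -> float:
    """Map R' in (0, inf) to k' = R'/(R'+1) in (0, 1)."""
    if not math.isfinite(r_prime) or r_prime <= 0:
        raise ValueError(f"r_prime must be finite and positive, got {r_prime!r}")
    return r_prime / (r_prime + 1.0)


def k_prime_for_reaction(fam_curve: FluorescenceCurve,
                         vic_curve: FluorescenceCurve,
                         **fit_kwargs) -> KPrimeResult:
    """Fit both channels of one reaction (two-step) and compute R' and k'.

    ``fit_kwargs`` are forwarded to :func:`fit_sigmoid_two_step`.
    """
    if fam_curve.channel != "FAM" or vic_curve.channel != "VIC":
        raise ValueError(
            f"expected (FAM, VIC) curves, got ({fam_curve.channel}, {vic_curve.channel})"
        )
    if fam_curve.well_id != vic_curve.well_id:
        raise ValueError(
            f"channel curves from different wells: {fam_curve.well_id!r} vs {vic_curve.well_id!r}"
        )
    fam_fit = fit_sigmoid_two_step(fam_curve, **fit_kwargs)
    vic_fit = fit_sigmoid_two_step(vic_curve, **fit_kwargs)
    r, branch = compute_r_prime(fam_fit, vic_fit)
    k = compute_k_prime(r)
    return KPrimeResult(r_prime=r, k_prime=k, branch=branch,
                        fam_fit=fam_fit, vic_fit=vic_fit)
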