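"""Cis-trans exchange kinetics from 2D EXSY buildup curves.

For a two-state exchange between the trans and cis conformers of a
pThr-Pro bond, the cross-peak-to-diagonal intensity ratio grows with the
mixing time as

    I_ct/I_tt = k_tc [1 - exp(-k_EX t_mix)] / (k_ct + k_tc exp(-k_EX t_mix))

with k_EX = k_tc + k_ct.  Convention: k_tc is the trans->cis rate and
k_ct the cis->trans rate, so the long-time plateau k_tc/k_ct equals the
equilibrium cis/trans population ratio.  The model neglects differential
longitudinal relaxation between the conformers, which cancels from the
ratio only when the two R1 values are equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .errors import FitError, UnderdeterminedError, ValidationError
from .io import ExsyCurve

_KEX_STARTS = (0.1, 1.0, 10.0, 100.0)
_PC_STARTS = (0.05, 0.1, 0.2)

#: exchange rates (s^-1) detectable by the EXSY experiment
DETECTABILITY_WINDOW = (0.1, 100.0)


@dataclass(frozen=True)
class ConformerPopulations:
    """Equilibrium trans/cis fractions of the prolyl bond."""

    p_trans: float
    p_cis: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_trans <= 1.0 and 0.0 <= self.p_cis <= 1.0):
            raise ValidationError("populations must lie in [0, 1]")
        if abs(self.p_trans + self.p_cis - 1.0) > 1e-12:
            raise ValidationError("populations must sum to 1")


@dataclass(frozen=True)
class ExsyFitResult:
    """Fitted exchange rate constants (s^-1)."""

    k_tc: float
    k_ct: float
    se_k_tc: float
    se_k_ct: float
    se_k_EX: float
    rss: float
    converged: bool
    n_starts_agreeing: int = 0
    diagnosis: Optional[str] = None

    @property
    def k_EX(self) -> float:
        return self.k_tc + self.k_ct

    def to_dict(self) -> dict:
        return {
            "k_tc_per_s": self.k_tc,
            "k_ct_per_s": self.k_ct,
            "k_EX_per_s": self.k_EX,
            "se_k_tc_per_s": self.se_k_tc,
            "se_k_ct_per_s": self.se_k_ct,
            "se_k_EX_per_s": self.se_k_EX,
            "rss": self.rss,
            "converged": self.converged,
            "n_starts_agreeing": self.n_starts_agreeing,
            "diagnosis": self.diagnosis,
            "in_detectability_window": detectability_window(self.k_EX)
            if self.k_tc > 0
            else None,
        }


def exsy_ratio(k_tc, k_ct, t_mix):
    """Cross-peak/diagonal ratio I_ct/I_tt at mixing time t_mix (s).

    Vectorized in ``t_mix``; strictly increasing in t_mix and bounded
    above by k_tc/k_ct.
    """
    if not (k_tc > 0 and k_ct > 0):
        raise ValidationError(f"rates must be > 0, got k_tc={k_tc}, k_ct={k_ct}")
    t = np.asarray(t_mix, dtype=float)
    if np.any(t < 0):
        raise ValidationError("t_mix must be >= 0")
    e = np.exp(-(k_tc + k_ct) * t)
    out = k_tc * (1.0 - e) / (k_ct + k_tc * e)
    return out if t.ndim else float(out)


def conformer_populations(I_tt: float, I_cc: float) -> ConformerPopulations:
    """Trans/cis populations from resolved diagonal-peak intensities."""
    if I_tt < 0 or I_cc < 0:
        raise ValidationError("intensities must be >= 0")
    total = I_tt + I_cc
    if total == 0:
        raise ValidationError("both diagonal intensities are zero: populations undefined")
    p_t = I_tt / total
    return ConformerPopulations(p_trans=p_t, p_cis=1.0 - p_t)


def detectability_window(k_EX: float) -> bool:
    """True when the exchange rate falls in the EXSY-detectable range.

    Both boundaries (0.1 and 100 s^-1) are inclusive.
    """
    if not k_EX > 0:
        raise ValidationError(f"k_EX must be > 0, got {k_EX}")
    lo, hi = DETECTABILITY_WINDOW
    return lo <= k_EX <= hi


def fit_exsy(curve: ExsyCurve) -> ExsyFitResult:
    """Fit (k_tc, k_ct) to a ratio buildup curve by least squares.

    Multi-start over k_EX decades crossed with plausible cis fractions;
    rates are optimized on a log scale to enforce positivity.  An all-zero
    curve is diagnosed as 'no exchange' rather than raising.
    """
    t = np.asarray(curve.mixing_times, dtype=float)
    y = np.asarray(curve.ratio_ct, dtype=float)
    if len(curve) < 3:
        raise UnderdeterminedError(f"need >= 3 mixing times, got {len(curve)}")
    if np.all(y == 0):
        return ExsyFitResult(
            k_tc=math.nan, k_ct=math.nan,
            se_k_tc=math.nan, se_k_ct=math.nan, se_k_EX=math.nan,
            rss=0.0, converged=False, diagnosis="no exchange detected (all ratios zero)",
        )

    def resid(p):
        return exsy_ratio(math.exp(p[0]), math.exp(p[1]), t) - y

    results = []
    for kex in _KEX_STARTS:
        for pc in _PC_STARTS:
            x0 = np.array([math.log(kex * pc), math.log(kex * (1.0 - pc))])
            try:
                res = optimize.least_squares(
                    resid, x0, method="trf", gtol=1e-12, xtol=1e-14, ftol=1e-14,
                    max_nfev=5000,
                )
            except Exception:
                continue
            results.append(res)
    if not results:
        raise FitError("EXSY fit failed to converge from every start")
    results.sort(key=lambda r: float(np.sum(r.fun**2)))
    best = results[0]
    k_tc, k_ct = math.exp(best.x[0]), math.exp(best.x[1])
    k_ex = k_tc + k_ct
    agree = sum(
        1
        for r in results
        if abs(math.exp(r.x[0]) + math.exp(r.x[1]) - k_ex) <= 0.01 * k_ex
    )
    rss = float(np.sum(best.fun**2))
    if not (np.any(t[t > 0] < 1.0 / k_ex) and np.any(t >= 3.0 / k_ex)):
        warnings.warn(
            "mixing-time schedule poorly brackets 1/k_EX; rates may be "
            "weakly identifiable"
        )
    dof = len(curve) - 2
    if dof > 0 and best.jac is not None:
        s2 = rss / dof
        try:
            cov_log = s2 * np.linalg.inv(best.jac.T @ best.jac)
            se_tc = k_tc * math.sqrt(max(cov_log[0, 0], 0.0))
            se_ct = k_ct * math.sqrt(max(cov_log[1, 1], 0.0))
            cov_tc_ct = k_tc * k_ct * cov_log[0, 1]
            se_ex = math.sqrt(max(se_tc**2 + se_ct**2 + 2.0 * cov_tc_ct, 0.0))
        except np.linalg.LinAlgError:
            se_tc = se_ct = se_ex = math.nan
    else:
        se_tc = se_ct = se_ex = math.nan
    return ExsyFitResult(
        k_tc=k_tc, k_ct=k_ct,
        se_k_tc=se_tc, se_k_ct=se_ct, se_k_EX=se_ex,
        rss=rss, converged=bool(best.success), n_starts_agreeing=agree,
    )
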