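"""Closed-form binding-response models with ligand depletion.

Two equilibria are covered:

* single site, P + L <-> PL, where the bound fraction follows the
  quadratic ("tight-binding") isotherm in total concentrations; and
* two independent sites on one receptor (here the WW and PPIase domains
  of Pin1 engaging a phosphopeptide), where the free-ligand concentration
  [L] is the physical root of a cubic mass balance, evaluated with the
  trigonometric (Viete) solution.

Free ligand is always solved exactly — the free ~ total approximation is
never used, because the experiments run at protein concentrations
comparable to the dissociation constants.

A brute-force bisection solver of the same mass balance is provided as an
independent oracle for testing the closed form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize

from .errors import NumericError, ValidationError
from .io import Domain

logger = logging.getLogger(__name__)

#: tolerance for clamping the arccos argument onto [-1, 1]
_ACOS_GUARD = 1e-9


@dataclass(frozen=True)
class SingleSiteParams:
    """Single-site isotherm parameters: Kd (uM) and saturation response (ppm)."""

    Kd: float
    Amax: float

    def __post_init__(self) -> None:
        if not self.Kd > 0:
            raise ValidationError(f"Kd must be > 0, got {self.Kd}")
        if not math.isfinite(self.Amax):
            raise ValidationError(f"Amax must be finite, got {self.Amax}")


@dataclass(frozen=True)
class TwoSiteParams:
    """Two-independent-site parameters.

    ``amplitudes`` maps ``(residue_id, dimension)`` to the saturation shift
    change A (ppm) of that residue's curve; each residue reports on the
    site of its own domain.
    """

    Kd_W: float
    Kd_I: float
    amplitudes: Mapping[tuple[int, str], float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.Kd_W > 0 and self.Kd_I > 0):
            raise ValidationError(
                f"both Kd must be > 0, got Kd_W={self.Kd_W}, Kd_I={self.Kd_I}"
            )
        if self.amplitudes is None:
            object.__setattr__(self, "amplitudes", {})


def bound_fraction_single(P0, L0, Kd):
    """Fraction of protein bound, quadratic isotherm in totals. Vectorized in L0."""
    P0 = float(P0)
    if P0 <= 0:
        raise ValidationError(f"P0 must be > 0, got {P0}")
    L0 = np.asarray(L0, dtype=float)
    if np.any(L0 < 0):
        raise ValidationError("L0 must be >= 0")
    if not Kd > 0:
        raise ValidationError(f"Kd must be > 0, got {Kd}")
    s = P0 + L0 + Kd
    disc = s * s - 4.0 * P0 * L0
    frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P0)
    return frac if frac.ndim else float(frac)


def single_site_response(P0, L0, Kd, Amax):
    """Observed shift change Δ (ppm) for the 1:1 binding isotherm."""
    return Amax * bound_fraction_single(P0, L0, Kd)


def _free_ligand_viete_scalar(P0: float, L0: float, Kd_W: float, Kd_I: float) -> float:
    if L0 == 0.0:
        return 0.0
    a = Kd_W + Kd_I + 2.0 * P0 - L0
    b = Kd_W * Kd_I + (Kd_I + Kd_W) * P0 - (Kd_W + Kd_I) * L0
    c = -Kd_W * Kd_I * L0
    disc = a * a - 3.0 * b
    if disc <= 0.0:
        # unreachable for physical positive inputs; fall back to bisection
        logger.warning(
            "degenerate cubic discriminant (a^2-3b=%g); falling back to bisection", disc
        )
        return free_ligand_oracle(P0, L0, Kd_W, Kd_I)
    arg = (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * disc**1.5)
    if arg > 1.0 or arg < -1.0:
        if abs(arg) - 1.0 > _ACOS_GUARD:
            raise NumericError(
                f"arccos argument {arg} outside [-1, 1] beyond tolerance; "
                "check input magnitudes"
            )
        arg = max(-1.0, min(1.0, arg))
    theta = math.acos(arg)
    L = -a / 3.0 + (2.0 / 3.0) * math.sqrt(disc) * math.cos(theta / 3.0)
    L = min(max(L, 0.0), L0)  # guard round-off outside the physical interval
    return _polish_root(P0, L0, Kd_W, Kd_I, L)


def _polish_root(P0: float, L0: float, Kd_W: float, Kd_I: float, L: float) -> float:
    """Safeguarded Newton refinement of the mass-balance root.

    The trigonometric root loses precision when [L] is many orders of
    magnitude below the coefficient scale (cos-term cancellation); a few
    Newton steps on the monotone mass-balance residual restore machine
    accuracy while keeping the closed form as the seed.
    """
    lo, hi = 0.0, L0
    for _ in range(100):
        g = L + P0 * L / (Kd_W + L) + P0 * L / (Kd_I + L) - L0
        if g > 0:
            hi = L
        else:
            lo = L
        dg = 1.0 + P0 * Kd_W / (Kd_W + L) ** 2 + P0 * Kd_I / (Kd_I + L) ** 2
        step = g / dg
        L_new = L - step
        if not lo < L_new < hi:
            L_new = 0.5 * (lo + hi)  # bisect when Newton leaves the bracket
        if abs(L_new - L) <= 1e-15 * max(L_new, 1e-300):
            return L_new
        L = L_new
    return L


def free_ligand_two_site(P0, L0, Kd_W, Kd_I):
    """Exact free-ligand concentration [L] for two independent sites.

    Solves the ternary mass balance
    ``L0 = [L] + P0*[L]/(Kd_W+[L]) + P0*[L]/(Kd_I+[L])``
    through the trigonometric solution of the underlying cubic.
    Vectorized in L0.
    """
    P0 = float(P0)
    if P0 < 0:
        raise ValidationError(f"P0 must be >= 0, got {P0}")
    if not (Kd_W > 0 and Kd_I > 0):
        raise ValidationError(f"both Kd must be > 0, got {Kd_W}, {Kd_I}")
    L0_arr = np.asarray(L0, dtype=float)
    if np.any(L0_arr < 0):
        raise ValidationError("L0 must be >= 0")
    out = np.array(
        [_free_ligand_viete_scalar(P0, float(l), Kd_W, Kd_I) for l in np.atleast_1d(L0_arr)]
    )
    return out if L0_arr.ndim else float(out[0])


def free_ligand_oracle(
    P0: float,
    L0: float,
    Kd_W: float,
    Kd_I: float,
    xtol: float = 1e-10,
    rtol: float = 1e-9,
) -> float:
    """Bisection solution of the same mass balance (independent verification).

    Converges to ``xtol`` absolute by default; pass a smaller ``xtol`` with a
    tight ``rtol`` to certify tiny roots relatively.
    """
    P0, L0 = float(P0), float(L0)
    if P0 < 0 or L0 < 0 or Kd_W <= 0 or Kd_I <= 0:
        raise ValidationError("inputs must satisfy P0,L0 >= 0 and Kd > 0")
    if L0 == 0.0:
        return 0.0

    def balance(L: float) -> float:
        return L + P0 * L / (Kd_W + L) + P0 * L / (Kd_I + L) - L0

    return float(optimize.bisect(balance, 0.0, L0, xtol=xtol, rtol=rtol, maxiter=400))


def two_site_response(P0, L0, params: TwoSiteParams, domain: Domain, A: float):
    """Shift change Δ (ppm) of one residue curve under the two-site model.

    ``A`` is the curve's saturation amplitude; the residue's domain selects
    which site's occupancy drives it.  Vectorized in L0.
    """
    domain = Domain(domain)
    if domain == Domain.LINKER:
        raise ValidationError("no site model exists for linker residues")
    L = free_ligand_two_site(P0, L0, params.Kd_W, params.Kd_I)
    Kd = params.Kd_W if domain == Domain.WW else params.Kd_I
    return A * L / (Kd + L)
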