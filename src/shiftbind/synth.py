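"""Synthetic titration and EXSY data with recorded ground truth.

The generator emulates the design of the NMR binding experiments the
package analyses: ~100 uM protein observed over 8-12 titration points, a
handful of responsive residues per domain with saturation amplitudes of a
few tenths of a ppm, fast-exchange averaging (observed shift moves
linearly with site occupancy), and Gaussian ppm noise at the level of
peak-position uncertainty.  EXSY buildup curves follow the two-state
exchange ratio model on the experimental mixing-time schedules, with
multiplicative noise.

Randomness is split into independent per-purpose, per-residue streams
derived from the recorded seed, so adding a residue or changing the noise
seed never perturbs other draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .exsy import exsy_ratio
from .io import Domain, ExsyCurve, ResidueMeta, ResidueShift, TitrationDataset
from .models import bound_fraction_single, free_ligand_two_site

#: 15N noise is drawn with sd sigma/0.152 so combined-CSP noise is isotropic
from .csp import N_SCALE

#: EXSY mixing-time schedules (s) used in the catalysis experiments
MIXING_TIMES_P640A = (0.020, 0.035, 0.050, 0.075, 0.100, 0.140, 0.200, 0.280, 0.400, 0.500)
MIXING_TIMES_SP2 = (0.010, 0.025, 0.030, 0.040, 0.070, 0.100, 0.150, 0.200, 0.300, 0.400, 0.500)

_AMP_RANGE_PPM = 0.3
_APO_H_RANGE = (6.5, 10.5)
_APO_N_RANGE = (102.0, 133.0)

# streams within the per-dataset RNG family
_STREAM_APO = 0
_STREAM_AMP = 1
_STREAM_NOISE = 2
_STREAM_EXSY = 3


@dataclass
class GroundTruth:
    """Parameter record emitted alongside every synthetic dataset."""

    scenario: str
    model: str  # single_site | two_site_independent | exsy
    seed: int
    P0: float = 100.0
    L0_schedule: tuple[float, ...] = ()
    Kd: Optional[float] = None
    Kd_W: Optional[float] = None
    Kd_I: Optional[float] = None
    amplitudes: dict[int, tuple[float, float]] = field(default_factory=dict)
    domains: dict[int, Domain] = field(default_factory=dict)
    apo_shifts: dict[int, tuple[float, float]] = field(default_factory=dict)
    noise_sigma_ppm: float = 0.0
    k_tc: Optional[float] = None
    k_ct: Optional[float] = None
    mixing_times: tuple[float, ...] = ()
    exsy_noise_frac: float = 0.0

    def __post_init__(self) -> None:
        for kd in (self.Kd, self.Kd_W, self.Kd_I):
            if kd is not None and kd <= 0:
                raise ValidationError(f"Kd must be > 0, got {kd}")
        for k in (self.k_tc, self.k_ct):
            if k is not None and k <= 0:
                raise ValidationError(f"rate must be > 0, got {k}")
        if self.noise_sigma_ppm < 0 or self.exsy_noise_frac < 0:
            raise ValidationError("noise levels must be >= 0")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["domains"] = {str(k): v.value for k, v in self.domains.items()}
        d["amplitudes"] = {str(k): list(v) for k, v in self.amplitudes.items()}
        d["apo_shifts"] = {str(k): list(v) for k, v in self.apo_shifts.items()}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _titration_schedule(P0: float, kd_scale: float, n_points: int = 10) -> tuple[float, ...]:
    """0 plus increasing totals reaching >= 80% site saturation."""
    l_max = 5.0 * kd_scale + 2.0 * P0
    frac = np.array([0.04, 0.09, 0.16, 0.25, 0.36, 0.49, 0.64, 0.81, 1.0])[: n_points - 1]
    return (0.0, *(float(l_max * f) for f in frac))


def _draw_residue(rng_family: int, seed: int, rid: int, low: float, high: float, n: int = 1):
    rng = np.random.default_rng([seed, rng_family, rid])
    return rng.uniform(low, high, size=n)


def make_truth(scenario: str, seed: int, noise_sigma_ppm: Optional[float] = None) -> GroundTruth:
    """Deterministic ground truth for a named study scenario.

    Scenarios:

    * ``single_site`` — one common site, Kd 154 uM, 12 responsive residues.
    * ``pHMbII_two_site`` — independent WW/PPIase sites with Kd_W 257 uM
      and Kd_I 75 uM (the affinities measured for the phosphorylated
      hydrophobic motif of PKC beta-II), 10 residues per domain.
    * ``no_binding`` — flat curves, all amplitudes zero.
    * ``exsy_p640a`` — catalyzed isomerization with k_EX 29.6 s^-1 split
      91:9 between the conformers, on the P640A mixing-time schedule.
    """
    if noise_sigma_ppm is None:
        noise_sigma_ppm = 0.005
    if scenario == "exsy_p640a":
        k_ex, p_cis = 29.6, 0.09
        return GroundTruth(
            scenario=scenario, model="exsy", seed=seed,
            k_tc=k_ex * p_cis, k_ct=k_ex * (1.0 - p_cis),
            mixing_times=MIXING_TIMES_P640A, exsy_noise_frac=0.0,
        )
    if scenario == "single_site":
        kd, n_res = 154.0, 12
        residues = list(range(1, n_res + 1))
        domains = {
            rid: (Domain.WW if i < n_res // 2 else Domain.PPIASE)
            for i, rid in enumerate(residues)
        }
        truth = GroundTruth(
            scenario=scenario, model="single_site", seed=seed,
            Kd=kd, L0_schedule=_titration_schedule(100.0, kd),
            noise_sigma_ppm=noise_sigma_ppm, domains=domains,
        )
    elif scenario == "pHMbII_two_site":
        kd_w, kd_i = 257.0, 75.0
        residues = list(range(1, 21))
        domains = {rid: (Domain.WW if rid <= 10 else Domain.PPIASE) for rid in residues}
        truth = GroundTruth(
            scenario=scenario, model="two_site_independent", seed=seed,
            Kd_W=kd_w, Kd_I=kd_i,
            L0_schedule=_titration_schedule(100.0, max(kd_w, kd_i), n_points=10),
            noise_sigma_ppm=noise_sigma_ppm, domains=domains,
        )
    elif scenario == "no_binding":
        residues = list(range(1, 13))
        domains = {rid: (Domain.WW if rid <= 6 else Domain.PPIASE) for rid in residues}
        truth = GroundTruth(
            scenario=scenario, model="single_site", seed=seed,
            Kd=154.0, L0_schedule=_titration_schedule(100.0, 154.0),
            noise_sigma_ppm=noise_sigma_ppm, domains=domains,
        )
        truth.amplitudes = {rid: (0.0, 0.0) for rid in residues}
        truth.apo_shifts = _draw_apo(truth)
        return truth
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")
    truth.amplitudes = {
        rid: tuple(_draw_residue(_STREAM_AMP, seed, rid, -_AMP_RANGE_PPM, _AMP_RANGE_PPM, 2))
        for rid in truth.domains
    }
    truth.apo_shifts = _draw_apo(truth)
    return truth


def _draw_apo(truth: GroundTruth) -> dict[int, tuple[float, float]]:
    out = {}
    for rid in truth.domains:
        h = _draw_residue(_STREAM_APO, truth.seed, rid, *_APO_H_RANGE)[0]
        n = _draw_residue(_STREAM_APO, truth.seed, 10_000 + rid, *_APO_N_RANGE)[0]
        out[rid] = (float(h), float(n))
    return out


def _occupancy(truth: GroundTruth, rid: int) -> np.ndarray:
    L0 = np.asarray(truth.L0_schedule, dtype=float)
    if truth.model == "single_site":
        return np.asarray(bound_fraction_single(truth.P0, L0, truth.Kd))
    L = np.asarray(free_ligand_two_site(truth.P0, L0, truth.Kd_W, truth.Kd_I))
    kd = truth.Kd_W if truth.domains[rid] == Domain.WW else truth.Kd_I
    return L / (kd + L)


def simulate_titration(truth: GroundTruth, seed: Optional[int] = None) -> TitrationDataset:
    """Forward-simulate a titration dataset from a ground truth.

    ``seed`` overrides the noise stream only: re-simulating the same truth
    with a different seed redraws noise while the design (apo positions,
    amplitudes, schedule) stays fixed.
    """
    if not truth.L0_schedule:
        raise ValidationError("ground truth has an empty ligand schedule")
    noise_seed = truth.seed if seed is None else seed
    shifts: dict[tuple[int, int], ResidueShift] = {}
    meta: dict[int, ResidueMeta] = {}
    for rid in sorted(truth.domains):
        occ = _occupancy(truth, rid)
        apo_h, apo_n = truth.apo_shifts[rid]
        a_h, a_n = truth.amplitudes[rid]
        rng = np.random.default_rng([noise_seed, _STREAM_NOISE, rid])
        noise = rng.normal(0.0, 1.0, size=(len(occ), 2)) * truth.noise_sigma_ppm
        for k, f in enumerate(occ):
            h = apo_h + a_h * f + noise[k, 0]
            n = apo_n + a_n * f + noise[k, 1] / N_SCALE
            shifts[(rid, k)] = ResidueShift(rid, "X", float(h), float(n))
        meta[rid] = ResidueMeta(
            residue_id=rid, domain=truth.domains[rid], fast_exchange=True, resolved=True
        )
    return TitrationDataset(
        protein_conc_P0=truth.P0,
        ligand_concs_L0=truth.L0_schedule,
        shifts=shifts,
        meta=meta,
        label=f"synthetic::{truth.scenario}::seed{truth.seed}",
    )


def simulate_exsy(truth: GroundTruth, seed: Optional[int] = None) -> ExsyCurve:
    """Forward-simulate an EXSY ratio buildup from a kinetic ground truth."""
    if truth.k_tc is None or truth.k_ct is None:
        raise ValidationError("ground truth carries no exchange rates")
    if not truth.mixing_times:
        raise ValidationError("ground truth has an empty mixing-time schedule")
    t = np.asarray(truth.mixing_times, dtype=float)
    clean = np.asarray(exsy_ratio(truth.k_tc, truth.k_ct, t))
    noise_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([noise_seed, _STREAM_EXSY])
    noisy = clean * (1.0 + truth.exsy_noise_frac * rng.normal(size=clean.size))
    noisy = np.maximum(noisy, 0.0)
    return ExsyCurve(mixing_times=tuple(t), ratio_ct=tuple(float(v) for v in noisy))
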