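"""Chemical-shift-perturbation (CSP) profiles and residue selection.

The combined amide CSP collapses the two spectral dimensions into one
displacement, Δ = sqrt(Δδ_H² + (0.152·Δδ_N)²), with the conventional
0.152 scaling compressing the ¹⁵N axis onto the ¹H ppm scale.  Residues
feeding the binding-curve analysis are those whose Δ strictly exceeds the
profile mean and whose peaks are both resolved and in fast exchange.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .io import Domain, ResidueMeta, ResidueShift, TitrationDataset

#: ¹⁵N-to-¹H scaling used in the combined CSP (dimensionless).
N_SCALE = 0.152


def compute_csp(apo: ResidueShift, bound: ResidueShift, n_scale: float = N_SCALE) -> float:
    """Combined CSP Δ (ppm) between two states of the same residue."""
    if apo.residue_id != bound.residue_id:
        raise ValidationError(
            f"residue identity mismatch: {apo.residue_id} vs {bound.residue_id}"
        )
    ddh = bound.delta_H - apo.delta_H
    ddn = bound.delta_N - apo.delta_N
    return math.hypot(ddh, n_scale * ddn)


@dataclass(frozen=True)
class CspProfile:
    """Per-residue Δ at one titration point vs. the apo reference.

    ``mean_delta`` is the mean Δ over resolved residues only: unresolved
    (overlapped) peaks carry untrustworthy displacements and must not
    shape the selection threshold.
    """

    conc_index: int
    values: Mapping[int, float]
    mean_delta: float


def csp_profile(
    ds: TitrationDataset, conc_index: int, n_scale: float = N_SCALE
) -> CspProfile:
    """Δ for every residue observed at both the apo point and ``conc_index``."""
    if not 1 <= conc_index < ds.n_points:
        raise IndexError(
            f"conc_index {conc_index} out of range [1, {ds.n_points - 1}]"
        )
    values: dict[int, float] = {}
    for rid in ds.residues:
        apo = ds.shift_at(rid, 0)
        bound = ds.shift_at(rid, conc_index)
        if apo is None or bound is None:
            continue  # missing at either point: excluded from profile and mean
        values[rid] = compute_csp(apo, bound, n_scale=n_scale)
    resolved = [v for rid, v in values.items() if ds.meta[rid].resolved]
    if resolved:
        mean = float(np.mean(resolved))
    else:
        warnings.warn("no resolved residues in CSP profile; mean is undefined")
        mean = math.nan
    return CspProfile(conc_index=conc_index, values=values, mean_delta=mean)


def select_responsive_residues(
    profile: CspProfile, meta: Mapping[int, ResidueMeta]
) -> set[int]:
    """Residues with Δ strictly above the mean, fast-exchange, and resolved."""
    if not profile.values:
        warnings.warn("empty CSP profile: no residues to select")
        return set()
    return {
        rid
        for rid, delta in profile.values.items()
        if delta > profile.mean_delta
        and meta[rid].fast_exchange
        and meta[rid].resolved
    }


@dataclass(frozen=True)
class CorrelationSummary:
    """Agreement of bound-state shift patterns between two complexes."""

    domain: Domain
    n_points: int
    pearson_r: float
    rmsd: float
    identity_line_max_dev: float

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "domain": self.domain.value,
                    "n_points": self.n_points,
                    "pearson_r": self.pearson_r,
                    "rmsd_ppm": self.rmsd,
                    "identity_line_max_dev_ppm": self.identity_line_max_dev,
                },
                indent=2,
                sort_keys=True,
            )
        )


def shift_correlation(
    state_a: Mapping[int, ResidueShift],
    state_b: Mapping[int, ResidueShift],
    domain_filter: Domain,
    meta: Mapping[int, ResidueMeta],
    n_scale: float = N_SCALE,
) -> CorrelationSummary:
    """Correlate two bound-state shift patterns within one domain.

    The coordinates compared are the union of per-residue ¹H shifts and
    scaled (0.152·) ¹⁵N shifts of residues common to both states, resolved,
    and belonging to ``domain_filter``.
    """
    domain_filter = Domain(domain_filter)
    common = sorted(
        rid
        for rid in set(state_a) & set(state_b)
        if rid in meta and meta[rid].domain == domain_filter and meta[rid].resolved
    )
    if len(common) < 2:
        raise InsufficientDataError(
            f"need >= 2 common resolved residues in {domain_filter.value}, got {len(common)}"
        )
    a = np.array(
        [state_a[r].delta_H for r in common] + [n_scale * state_a[r].delta_N for r in common]
    )
    b = np.array(
        [state_b[r].delta_H for r in common] + [n_scale * state_b[r].delta_N for r in common]
    )
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        r = 1.0 if np.allclose(a - b, (a - b)[0]) else math.nan
    else:
        r = float(stats.pearsonr(a, b).statistic)
    dev = a - b
    return CorrelationSummary(
        domain=domain_filter,
        n_points=len(common),
        pearson_r=r,
        rmsd=float(np.sqrt(np.mean(dev**2))),
        identity_line_max_dev=float(np.max(np.abs(dev))),
    )


def export_csp_profile(profile: CspProfile, selected: set[int], path) -> None:
    """CSV export: residue_id, delta_ppm, selected."""
    lines = ["residue_id,delta_ppm,selected"]
    for rid in sorted(profile.values):
        lines.append(f"{rid},{profile.values[rid]!r},{rid in selected}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
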