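"""Global nonlinear least-squares fitting of binding curves.

Many per-residue curves are fitted simultaneously with the dissociation
constants shared across curves and one saturation amplitude local to each
curve.  Kd parameters are optimized on a log10 scale (positivity, better
conditioning); amplitudes are linear in the model and are profiled out at
every objective evaluation (variable projection), so the nonlinear search
runs over one (single-site) or two (two-site) parameters only.  A
multi-start protocol over decades of Kd guards against local minima.

Single-site fits operate on combined-CSP curves; two-site fits operate on
per-dimension (1H and 15N) shift-change curves routed to the WW- or
PPIase-site occupancy by each residue's domain label.
"""

from __future__ import annotations

import itertools
import math
from types import SimpleNamespace
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .csp import N_SCALE, compute_csp
from .errors import (
    FitError,
    IdentifiabilityWarning,
    UnderdeterminedError,
    ValidationError,
)
from .io import Domain, TitrationDataset
from .models import TwoSiteParams, bound_fraction_single, free_ligand_two_site

_GTOL = 1e-10
_MAX_NFEV = 5000
_SINGLE_STARTS_LOG10 = (-1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
_AGREE_RTOL = 0.01

SINGLE_SITE = "single_site"
TWO_SITE = "two_site_independent"


@dataclass
class BindingFitResult:
    """Outcome of a global binding-curve fit."""

    model: str
    global_params: dict[str, float]
    global_se: dict[str, float]
    local_amplitudes: dict[str, float]
    local_se: dict[str, float]
    rss: float
    n_curves: int
    n_points: int
    converged: bool
    n_starts_agreeing: int
    unidentifiable: tuple[str, ...] = ()
    ci: Optional[dict[str, tuple[float, float]]] = None
    uncertainty_method: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "global_params_uM": self.global_params,
            "global_se_uM": self.global_se,
            "local_amplitudes_ppm": self.local_amplitudes,
            "local_se_ppm": self.local_se,
            "rss_ppm2": self.rss,
            "n_curves": self.n_curves,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_starts_agreeing": self.n_starts_agreeing,
            "unidentifiable": list(self.unidentifiable),
        }
        if self.ci is not None:
            d["ci95_uM"] = {k: list(v) for k, v in self.ci.items()}
            d["uncertainty_method"] = self.uncertainty_method
        return d


@dataclass
class _CurveSet:
    """Dense observation matrix: one row per curve, one column per non-apo point."""

    P0: float
    L0: np.ndarray          # (K-1,) non-apo total ligand concentrations
    Y: np.ndarray           # (n_curves, K-1); NaN marks a missing peak
    curve_ids: list[str]
    domains: list[Optional[Domain]]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.Y)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def _build_single_curves(ds: TitrationDataset, selection: Iterable[int]) -> _CurveSet:
    sel = sorted(set(selection))
    if not sel:
        raise ValidationError("empty residue selection")
    K = ds.n_points
    rows, ids = [], []
    for rid in sel:
        apo = ds.shift_at(rid, 0)
        if apo is None:
            warnings.warn(f"residue {rid} lacks an apo peak; curve dropped")
            continue
        row = np.full(K - 1, np.nan)
        for k in range(1, K):
            bound = ds.shift_at(rid, k)
            if bound is not None:
                row[k - 1] = compute_csp(apo, bound)
        rows.append(row)
        ids.append(str(rid))
    if not rows:
        raise ValidationError("no usable curves in selection")
    return _CurveSet(
        P0=ds.protein_conc_P0,
        L0=np.asarray(ds.ligand_concs_L0[1:], dtype=float),
        Y=np.vstack(rows),
        curve_ids=ids,
        domains=[None] * len(ids),
    )


def _build_two_site_curves(
    ds: TitrationDataset, selection: Iterable[int], dimensions: Sequence[str] = ("H", "N")
) -> _CurveSet:
    sel = sorted(set(selection))
    if not sel:
        raise ValidationError("empty residue selection")
    K = ds.n_points
    rows, ids, doms = [], [], []
    for rid in sel:
        dom = ds.meta[rid].domain
        if dom == Domain.LINKER:
            warnings.warn(f"residue {rid} is in the linker; no site model, curve dropped")
            continue
        apo = ds.shift_at(rid, 0)
        if apo is None:
            warnings.warn(f"residue {rid} lacks an apo peak; curves dropped")
            continue
        for dim in dimensions:
            attr = "delta_H" if dim == "H" else "delta_N"
            # 15N curves are placed on the 1H ppm scale (x 0.152) so that all
            # residuals share one unit and the unweighted global objective is
            # homoscedastic; each curve still enters the fit individually.
            scale = 1.0 if dim == "H" else N_SCALE
            row = np.full(K - 1, np.nan)
            for k in range(1, K):
                bound = ds.shift_at(rid, k)
                if bound is not None:
                    row[k - 1] = scale * (getattr(bound, attr) - getattr(apo, attr))
            rows.append(row)
            ids.append(f"{rid}:{dim}")
            doms.append(dom)
    if not rows:
        raise ValidationError("no usable curves in selection")
    return _CurveSet(
        P0=ds.protein_conc_P0,
        L0=np.asarray(ds.ligand_concs_L0[1:], dtype=float),
        Y=np.vstack(rows),
        curve_ids=ids,
        domains=doms,
    )


def _occupancy_matrix(cs: _CurveSet, model: str, params: np.ndarray) -> np.ndarray:
    """Per-curve occupancy rows at each titration point for given log10-Kd params."""
    if model == SINGLE_SITE:
        occ = bound_fraction_single(cs.P0, cs.L0, 10.0 ** params[0])
        return np.tile(occ, (len(cs.curve_ids), 1))
    kd_w, kd_i = 10.0 ** params[0], 10.0 ** params[1]
    L = np.asarray(free_ligand_two_site(cs.P0, cs.L0, kd_w, kd_i))
    f_w, f_i = L / (kd_w + L), L / (kd_i + L)
    return np.vstack([f_w if d == Domain.WW else f_i for d in cs.domains])


def _profiled_amplitudes(occ: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares amplitude per curve given occupancies (missing-aware)."""
    mask = ~np.isnan(Y)
    Y0 = np.where(mask, Y, 0.0)
    num = np.sum(occ * Y0 * mask, axis=1)
    den = np.sum(occ * occ * mask, axis=1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def _varpro_residuals(cs: _CurveSet, model: str, params: np.ndarray) -> np.ndarray:
    occ = _occupancy_matrix(cs, model, params)
    A = _profiled_amplitudes(occ, cs.Y)
    R = cs.Y - A[:, None] * occ
    return R[cs.mask]


def _numeric_jacobian(fun, theta: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    f0 = fun(theta)
    J = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        h = rel_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (fun(tp) - fun(tm)) / (2.0 * h)
    return J


def _full_residuals(cs: _CurveSet, model: str, theta: np.ndarray, n_global: int) -> np.ndarray:
    occ = _occupancy_matrix(cs, model, theta[:n_global])
    A = theta[n_global:]
    R = cs.Y - A[:, None] * occ
    return R[cs.mask]


def _asymptotic_cov(cs: _CurveSet, model: str, theta: np.ndarray, n_global: int, rss: float):
    n_obs, p = cs.n_obs, theta.size
    dof = n_obs - p
    if dof <= 0:
        return None
    J = _numeric_jacobian(lambda t: _full_residuals(cs, model, t, n_global), theta)
    JTJ = J.T @ J
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def _run_starts(cs: _CurveSet, model: str, starts: Sequence[np.ndarray]):
    results = []
    for x0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: _varpro_residuals(cs, model, p),
                x0,
                method="trf",
                gtol=_GTOL,
                xtol=1e-14,
                ftol=1e-14,
                max_nfev=_MAX_NFEV,
            )
        except Exception:  # a start may diverge into numeric trouble; others remain
            continue
        results.append(res)
    if not results:
        raise FitError("optimizer failed to converge from every starting point")
    results.sort(key=lambda r: float(np.sum(r.fun**2)))
    return results


def _check_determined(cs: _CurveSet, n_global: int) -> None:
    n_params = n_global + len(cs.curve_ids)
    if cs.n_obs <= n_params:
        raise UnderdeterminedError(
            f"{cs.n_obs} observations for {n_params} parameters"
        )
    if np.nanmax(np.abs(cs.Y)) < 1e-12:
        raise UnderdeterminedError("flat curves: no binding response to fit")


def _package_result(
    cs: _CurveSet,
    model: str,
    param_names: Sequence[str],
    results,
    unidentifiable: tuple[str, ...] = (),
) -> BindingFitResult:
    best = results[0]
    params = best.x
    occ = _occupancy_matrix(cs, model, params)
    A = _profiled_amplitudes(occ, cs.Y)
    rss = float(np.sum(best.fun**2))
    kds = [float(10.0**v) for v in params]
    agree = sum(
        1
        for r in results
        if all(
            abs(10.0 ** r.x[i] - kds[i]) <= _AGREE_RTOL * kds[i]
            for i in range(len(kds))
        )
    )
    theta = np.concatenate([params, A])
    cov = _asymptotic_cov(cs, model, theta, len(params), rss)
    n_g = len(params)
    if cov is not None:
        se_log = np.sqrt(np.maximum(np.diag(cov)[:n_g], 0.0))
        se_kd = [math.log(10.0) * kds[i] * se_log[i] for i in range(n_g)]
        se_A = np.sqrt(np.maximum(np.diag(cov)[n_g:], 0.0))
    else:
        se_kd = [math.nan] * n_g
        se_A = np.full(len(A), math.nan)
    return BindingFitResult(
        model=model,
        global_params=dict(zip(param_names, kds)),
        global_se=dict(zip(param_names, se_kd)),
        local_amplitudes=dict(zip(cs.curve_ids, A.tolist())),
        local_se=dict(zip(cs.curve_ids, se_A.tolist())),
        rss=rss,
        n_curves=len(cs.curve_ids),
        n_points=cs.n_obs,
        converged=bool(best.success),
        n_starts_agreeing=agree,
        unidentifiable=unidentifiable,
    )


def fit_single_site(
    ds: TitrationDataset,
    selection: Iterable[int],
    starts_log10: Sequence[float] = _SINGLE_STARTS_LOG10,
) -> BindingFitResult:
    """Globally fit combined-CSP curves with one shared Kd.

    Each selected residue contributes one curve of combined CSP vs. total
    ligand; the fit shares Kd across curves and assigns each its own
    saturation amplitude.
    """
    if ds.n_points < 3:
        raise UnderdeterminedError("need >= 3 titration points")
    cs = _build_single_curves(ds, selection)
    _check_determined(cs, n_global=1)
    results = _run_starts(cs, SINGLE_SITE, [np.array([lg]) for lg in starts_log10])
    return _package_result(cs, SINGLE_SITE, ("Kd",), results)


def fit_two_site(
    ds: TitrationDataset,
    selection: Iterable[int],
    dimensions: Sequence[str] = ("H", "N"),
    starts_log10: Sequence[float] = _SINGLE_STARTS_LOG10,
) -> BindingFitResult:
    """Globally fit per-dimension curves with shared (Kd_W, Kd_I).

    Curves from WW-domain residues follow the WW-site occupancy, PPIase
    curves the PPIase-site occupancy, with the exact free-ligand
    concentration shared between them.  When the selection covers only one
    domain the other site's Kd is unconstrained: it is flagged
    unidentifiable and held at its starting value rather than silently
    fitted.
    """
    if ds.n_points < 3:
        raise UnderdeterminedError("need >= 3 titration points")
    cs = _build_two_site_curves(ds, selection, dimensions)
    present = {d for d in cs.domains}
    missing = {Domain.WW, Domain.PPIASE} - present
    if missing:
        names = {Domain.WW: "Kd_W", Domain.PPIASE: "Kd_I"}
        flagged = tuple(sorted(names[d] for d in missing))
        warnings.warn(
            f"selection covers only one domain; {', '.join(flagged)} unidentifiable",
            IdentifiabilityWarning,
        )
        _check_determined(cs, n_global=1)
        fixed_lg = 2.0  # 100 uM placeholder, reported as unidentifiable
        free_idx = 0 if Domain.WW in present else 1

        def embed(p):
            full = np.array([fixed_lg, fixed_lg])
            full[free_idx] = p[0]
            return full

        results = []
        for lg in starts_log10:
            try:
                res = optimize.least_squares(
                    lambda p: _varpro_residuals(cs, TWO_SITE, embed(p)),
                    np.array([lg]),
                    method="trf",
                    gtol=_GTOL,
                    xtol=1e-14,
                    ftol=1e-14,
                    max_nfev=_MAX_NFEV,
                )
            except Exception:
                continue
            results.append(
                SimpleNamespace(x=embed(res.x), fun=res.fun, success=res.success)
            )
        if not results:
            raise FitError("optimizer failed to converge from every starting point")
        results.sort(key=lambda r: float(np.sum(r.fun**2)))
        return _package_result(cs, TWO_SITE, ("Kd_W", "Kd_I"), results, unidentifiable=flagged)

    _check_determined(cs, n_global=2)
    starts = [np.array(p) for p in itertools.product(starts_log10, starts_log10)]
    results = _run_starts(cs, TWO_SITE, starts)
    fit = _package_result(cs, TWO_SITE, ("Kd_W", "Kd_I"), results)
    kw, ki = fit.global_params["Kd_W"], fit.global_params["Kd_I"]
    if abs(kw - ki) <= 0.1 * max(kw, ki):
        warnings.warn(
            "fitted Kd_W and Kd_I are within 10%; the two sites are weakly "
            "distinguishable from these curves",
            IdentifiabilityWarning,
        )
    return fit


def _curves_for(fit: BindingFitResult, ds: TitrationDataset, selection: Iterable[int]) -> _CurveSet:
    if fit.model == SINGLE_SITE:
        return _build_single_curves(ds, selection)
    return _build_two_site_curves(ds, selection)


def residual_table(
    fit: BindingFitResult, ds: TitrationDataset, selection: Iterable[int]
) -> pd.DataFrame:
    """Per-observation table of observed, predicted, and residual values."""
    cs = _curves_for(fit, ds, selection)
    params = np.array([math.log10(v) for v in fit.global_params.values()])
    occ = _occupancy_matrix(cs, fit.model, params)
    A = np.array([fit.local_amplitudes[c] for c in cs.curve_ids])
    pred = A[:, None] * occ
    rows = []
    for i, cid in enumerate(cs.curve_ids):
        for k, l0 in enumerate(cs.L0):
            if np.isnan(cs.Y[i, k]):
                continue
            rows.append(
                {
                    "curve_id": cid,
                    "L0_uM": float(l0),
                    "observed_ppm": float(cs.Y[i, k]),
                    "predicted_ppm": float(pred[i, k]),
                    "residual_ppm": float(cs.Y[i, k] - pred[i, k]),
                }
            )
    return pd.DataFrame(rows)


def estimate_uncertainty(
    fit: BindingFitResult,
    ds: TitrationDataset,
    selection: Iterable[int],
    method: str = "asymptotic",
    n_boot: int = 200,
    seed: int = 0,
) -> BindingFitResult:
    """Augment a converged fit with standard errors and 95% intervals.

    ``asymptotic`` uses the Jacobian of the full parameter vector at the
    optimum; ``bootstrap`` resamples whole curves (the independent sampling
    units) with a fixed seed and refits, reporting t-based intervals on the
    log-Kd scale.  A singular Jacobian degrades asymptotic to bootstrap
    (with a warning).
    """
    if not fit.converged:
        raise FitError("uncertainty requires a converged fit")
    cs = _curves_for(fit, ds, selection)
    names = list(fit.global_params)
    params = np.array([math.log10(v) for v in fit.global_params.values()])
    if method == "asymptotic":
        A = np.array([fit.local_amplitudes[c] for c in cs.curve_ids])
        theta = np.concatenate([params, A])
        cov = _asymptotic_cov(cs, fit.model, theta, len(params), fit.rss)
        if cov is None:
            warnings.warn("singular Jacobian; falling back to bootstrap")
            return estimate_uncertainty(fit, ds, selection, "bootstrap", n_boot, seed)
        se_log = np.sqrt(np.maximum(np.diag(cov)[: len(params)], 0.0))
        ci = {}
        se = {}
        for i, name in enumerate(names):
            kd = fit.global_params[name]
            se[name] = math.log(10.0) * kd * se_log[i]
            ci[name] = (10.0 ** (params[i] - 1.96 * se_log[i]), 10.0 ** (params[i] + 1.96 * se_log[i]))
        return replace(fit, global_se=se, ci=ci, uncertainty_method="asymptotic")
    if method != "bootstrap":
        raise ValidationError(f"unknown uncertainty method {method!r}")
    rng = np.random.default_rng(seed)
    n_curves = len(cs.curve_ids)
    # case resampling at the curve level, stratified by domain: every point of
    # a curve shares the same noisy apo anchor, so within-curve errors are
    # correlated and residual-level resampling understates the Kd uncertainty
    strata = {}
    for i, d in enumerate(cs.domains):
        strata.setdefault(d, []).append(i)
    draws_log = {n: [] for n in names}
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(members, size=len(members), replace=True) for members in strata.values()]
        )
        cs_b = _CurveSet(
            cs.P0, cs.L0, cs.Y[idx], [str(i) for i in range(len(idx))],
            [cs.domains[i] for i in idx],
        )
        try:
            res_b = _run_starts(cs_b, fit.model, [params])
        except FitError:
            continue
        for i, n in enumerate(names):
            draws_log[n].append(float(res_b[0].x[i]))
    # interval: estimate +/- t_{n_curves-1} * bootstrap SE on the log10 scale
    # (t rather than normal: few curve-level sampling units)
    tcrit = float(stats.t.ppf(0.975, max(n_curves - 1, 1)))
    ci, se = {}, {}
    for i, n in enumerate(names):
        v = draws_log[n]
        if len(v) > 1:
            se_log = float(np.std(v, ddof=1))
            ci[n] = (10.0 ** (params[i] - tcrit * se_log), 10.0 ** (params[i] + tcrit * se_log))
            se[n] = math.log(10.0) * fit.global_params[n] * se_log
        else:
            ci[n] = (math.nan, math.nan)
            se[n] = math.nan
    return replace(fit, global_se=se, ci=ci, uncertainty_method="bootstrap")
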