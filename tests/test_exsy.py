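"""EXSY ratio model vs. a two-state exchange ODE oracle, and rate fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from shiftbind import (
    ExsyCurve,
    GroundTruth,
    UnderdeterminedError,
    ValidationError,
    conformer_populations,
    detectability_window,
    exsy_ratio,
    fit_exsy,
    read_exsy_table,
    simulate_exsy,
)
from shiftbind.synth import MIXING_TIMES_P640A

rates = st.floats(0.1, 100.0, allow_nan=False)


def ode_ratio(k_tc: float, k_ct: float, t: float) -> float:
    """Independent oracle: integrate the two-state magnetization exchange.

    Diagonal tt follows magnetization prepared on trans (equilibrium
    weight p_trans); cross-peak ct follows magnetization prepared on cis
    (weight p_cis) and detected on trans.
    """
    if t == 0:
        return 0.0
    k_ex = k_tc + k_ct
    p_t, p_c = k_ct / k_ex, k_tc / k_ex

    def rhs(_, m):
        mt, mc = m
        return [-k_tc * mt + k_ct * mc, k_tc * mt - k_ct * mc]

    opts = dict(rtol=1e-12, atol=1e-14, dense_output=False)
    from_trans = solve_ivp(rhs, (0, t), [p_t, 0.0], **opts)
    from_cis = solve_ivp(rhs, (0, t), [0.0, p_c], **opts)
    i_tt = from_trans.y[0, -1]
    i_ct = from_cis.y[0, -1]
    return i_ct / i_tt


class TestRatioModel:
    def test_zero_mixing_time(self):
        assert exsy_ratio(2.0, 20.0, 0.0) == 0.0

    def test_long_time_plateau(self):
        assert exsy_ratio(2.0, 20.0, 1e6) == pytest.approx(0.1, rel=1e-12)

    def test_against_ode_oracle_example(self):
        got = exsy_ratio(2.0, 20.0, 0.1)
        assert got == pytest.approx(ode_ratio(2.0, 20.0, 0.1), rel=1e-8)
        assert got == pytest.approx(0.0879452, abs=1e-6)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(k_tc=rates, k_ct=rates, t=st.floats(0.001, 2.0))
    def test_against_ode_oracle_property(self, k_tc, k_ct, t):
        assert exsy_ratio(k_tc, k_ct, t) == pytest.approx(
            ode_ratio(k_tc, k_ct, t), rel=1e-8, abs=1e-12
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(k_tc=rates, k_ct=rates, t=st.floats(1e-4, 5.0), step=st.floats(1.01, 4.0))
    def test_increasing_and_bounded(self, k_tc, k_ct, t, step):
        from hypothesis import assume

        # strict monotonicity is only observable before exp(-k_EX t) underflows
        assume((k_tc + k_ct) * t * step < 25.0)
        r1, r2 = exsy_ratio(k_tc, k_ct, t), exsy_ratio(k_tc, k_ct, t * step)
        assert r2 > r1
        assert r2 < k_tc / k_ct

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(k_tc=rates, k_ct=rates)
    def test_plateau_equals_population_ratio(self, k_tc, k_ct):
        """Detailed balance p_t*k_tc = p_c*k_ct makes the plateau p_c/p_t."""
        k_ex = k_tc + k_ct
        p_t, p_c = k_ct / k_ex, k_tc / k_ex
        assert exsy_ratio(k_tc, k_ct, 1e7) == pytest.approx(p_c / p_t, rel=1e-9)


class TestFit:
    def test_noiseless_recovery_on_experimental_schedule(self):
        k_tc, k_ct = 3.0, 27.0
        curve = ExsyCurve(
            mixing_times=MIXING_TIMES_P640A,
            ratio_ct=tuple(float(exsy_ratio(k_tc, k_ct, t)) for t in MIXING_TIMES_P640A),
        )
        fit = fit_exsy(curve)
        assert fit.converged
        assert fit.k_EX == pytest.approx(30.0, rel=1e-6)
        assert fit.k_tc == pytest.approx(k_tc, rel=1e-6)
        assert fit.k_ct == pytest.approx(k_ct, rel=1e-6)

    def test_two_points_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            fit_exsy(ExsyCurve(mixing_times=(0.1, 0.2), ratio_ct=(0.01, 0.02)))

    def test_noisy_recovery(self):
        truth = GroundTruth(
            scenario="custom", model="exsy", seed=7,
            k_tc=2.664, k_ct=26.936,
            mixing_times=MIXING_TIMES_P640A, exsy_noise_frac=0.05,
        )
        fit = fit_exsy(simulate_exsy(truth))
        assert fit.k_EX == pytest.approx(29.6, rel=0.10)

    def test_all_zero_ratios_diagnosed(self):
        curve = ExsyCurve(mixing_times=(0.1, 0.2, 0.3), ratio_ct=(0.0, 0.0, 0.0))
        fit = fit_exsy(curve)
        assert not fit.converged
        assert "no exchange" in fit.diagnosis

    def test_scale_invariance_of_intensity_input(self, tmp_path):
        t = MIXING_TIMES_P640A[:5]
        itt = [100.0, 95.0, 90.0, 85.0, 80.0]
        ict = [1.0, 2.0, 3.0, 4.0, 5.0]
        for scale, name in [(1.0, "a.csv"), (7.3, "b.csv")]:
            rows = ["t_mix,I_tt,I_ct"] + [
                f"{tm},{scale * a},{scale * b}" for tm, a, b in zip(t, itt, ict)
            ]
            (tmp_path / name).write_text("\n".join(rows))
        a = read_exsy_table(tmp_path / "a.csv")
        b = read_exsy_table(tmp_path / "b.csv")
        assert a.ratio_ct == pytest.approx(b.ratio_ct, rel=1e-12)


class TestPopulations:
    def test_resolved_diagonals(self):
        pops = conformer_populations(91.0, 9.0)
        assert pops.p_trans == pytest.approx(0.91)
        assert pops.p_cis == pytest.approx(0.09)

    def test_pure_trans(self):
        pops = conformer_populations(50.0, 0.0)
        assert (pops.p_trans, pops.p_cis) == (1.0, 0.0)

    def test_symmetric(self):
        pops = conformer_populations(5.0, 5.0)
        assert pops.p_trans == pops.p_cis == 0.5

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            conformer_populations(0.0, 0.0)


class TestDetectabilityWindow:
    @pytest.mark.parametrize(
        "k_ex,expected",
        [(29.6, True), (0.05, False), (100.0, True), (0.1, True), (150.0, False)],
    )
    def test_window(self, k_ex, expected):
        assert detectability_window(k_ex) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            detectability_window(0.0)
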