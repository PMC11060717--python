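"""Equilibrium isotherms: closed forms vs. independent mass-balance oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from shiftbind import (
    Domain,
    TwoSiteParams,
    ValidationError,
    bound_fraction_single,
    free_ligand_oracle,
    free_ligand_two_site,
    single_site_response,
    two_site_response,
)

conc = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)
kd = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestSingleSite:
    def test_no_ligand(self):
        assert single_site_response(100.0, 0.0, 50.0, 1.0) == 0.0

    def test_tight_binding_limit(self):
        # Kd -> 0: all ligand bound, response = L0/P0 of saturation
        assert single_site_response(100.0, 50.0, 1e-9, 1.0) == pytest.approx(0.5, abs=1e-9)

    def test_against_mass_balance_oracle(self):
        got = single_site_response(100.0, 100.0, 100.0, 1.0)
        # independent numeric solve of L + P0*L/(Kd+L) = L0, then bound protein
        def balance(L):
            return L + 100.0 * L / (100.0 + L) - 100.0

        L = optimize.brentq(balance, 0.0, 100.0, xtol=1e-14)
        assert got == pytest.approx(L / (100.0 + L), rel=1e-10)
        assert got == pytest.approx(0.3819660112501051, rel=1e-12)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValidationError):
            single_site_response(0.0, 10.0, 10.0, 1.0)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(P0=conc, L0=conc, Kd=kd, Amax=st.floats(0.01, 10))
    def test_response_bounded(self, P0, L0, Kd, Amax):
        r = single_site_response(P0, L0, Kd, Amax)
        assert -1e-12 <= r / Amax <= 1.0 + 1e-12


class TestFreeLigand:
    def test_no_ligand(self):
        assert free_ligand_two_site(100.0, 0.0, 10.0, 10.0) == 0.0

    def test_no_binding_limit(self):
        L = free_ligand_two_site(100.0, 50.0, 1e9, 1e9)
        assert L == pytest.approx(50.0, rel=1e-4)

    def test_symmetric_case_analytic(self):
        # Kd_W = Kd_I = 100, P0 = 100, L0 = 200: mass balance gives [L] = 100
        assert free_ligand_two_site(100.0, 200.0, 100.0, 100.0) == pytest.approx(100.0, rel=1e-10)
        assert free_ligand_oracle(100.0, 200.0, 100.0, 100.0) == pytest.approx(100.0, abs=1e-8)

    def test_symmetric_case_reduces_to_quadratic(self):
        # equal Kds: L + 2*P0*L/(K+L) = L0 has a closed quadratic solution
        for P0, L0, K in [(100.0, 37.0, 55.0), (90.0, 400.0, 12.0), (100.0, 5.0, 1000.0)]:
            q = K + 2 * P0 - L0
            L_quad = (-q + math.sqrt(q * q + 4 * K * L0)) / 2.0
            assert free_ligand_two_site(P0, L0, K, K) == pytest.approx(L_quad, rel=1e-9)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(P0=conc, L0=conc, Kd_W=kd, Kd_I=kd)
    def test_closed_form_matches_bisection(self, P0, L0, Kd_W, Kd_I):
        closed = free_ligand_two_site(P0, L0, Kd_W, Kd_I)
        oracle = free_ligand_oracle(P0, L0, Kd_W, Kd_I)
        assert closed == pytest.approx(oracle, rel=1e-8, abs=1e-8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(P0=conc, L0=conc, Kd_W=kd, Kd_I=kd)
    def test_mass_conservation(self, P0, L0, Kd_W, Kd_I):
        L = free_ligand_two_site(P0, L0, Kd_W, Kd_I)
        total = L + P0 * L / (Kd_W + L) + P0 * L / (Kd_I + L)
        assert total == pytest.approx(L0, rel=1e-8)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(P0=conc, Kd_W=kd, Kd_I=kd, L0=st.floats(1e-2, 1e5), step=st.floats(1.01, 3))
    def test_monotone_in_total_ligand(self, P0, Kd_W, Kd_I, L0, step):
        L1 = free_ligand_two_site(P0, L0, Kd_W, Kd_I)
        L2 = free_ligand_two_site(P0, L0 * step, Kd_W, Kd_I)
        assert L2 > L1
        # site occupancies inherit strict monotonicity
        assert L2 / (Kd_W + L2) > L1 / (Kd_W + L1)
        assert L2 / (Kd_I + L2) > L1 / (Kd_I + L1)


class TestTwoSiteResponse:
    def test_saturation_limit(self):
        p = TwoSiteParams(Kd_W=257.0, Kd_I=75.0)
        r = two_site_response(100.0, 1e9, p, Domain.WW, A=0.25)
        assert r == pytest.approx(0.25, rel=1e-6)

    def test_half_saturation_at_kd(self):
        # construct L0 so that [L] = Kd_W exactly, via the mass balance
        p = TwoSiteParams(Kd_W=50.0, Kd_I=200.0, amplitudes={})
        L = 50.0
        L0 = L + 100.0 * L / (p.Kd_W + L) + 100.0 * L / (p.Kd_I + L)
        r = two_site_response(100.0, L0, p, Domain.WW, A=1.0)
        assert r == pytest.approx(0.5, rel=1e-9)

    def test_composed_symmetric_example(self):
        p = TwoSiteParams(Kd_W=100.0, Kd_I=100.0)
        r = two_site_response(100.0, 200.0, p, Domain.WW, A=1.0)
        assert r == pytest.approx(0.5, rel=1e-9)

    def test_linker_rejected(self):
        p = TwoSiteParams(Kd_W=100.0, Kd_I=100.0)
        with pytest.raises(ValidationError):
            two_site_response(100.0, 10.0, p, Domain.LINKER, A=1.0)

    def test_reduces_to_single_site_when_other_site_vanishes(self):
        """Kd_I -> infinity: a WW curve follows the 1:1 isotherm with Kd_W."""
        Kd_W, P0, A = 80.0, 100.0, 1.0
        p = TwoSiteParams(Kd_W=Kd_W, Kd_I=1e9 * Kd_W)
        for L0 in (10.0, 100.0, 400.0, 2000.0):
            two = two_site_response(P0, L0, p, Domain.WW, A=A)
            one = single_site_response(P0, L0, Kd_W, A)
            assert two == pytest.approx(one, rel=1e-4)
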