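"""Combined-CSP computation, residue selection, and shift correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shiftbind import (
    CspProfile,
    Domain,
    InsufficientDataError,
    ResidueMeta,
    ResidueShift,
    ValidationError,
    compute_csp,
    csp_profile,
    select_responsive_residues,
    shift_correlation,
    simulate_titration,
)
from shiftbind.models import bound_fraction_single

finite = st.floats(-5, 5, allow_nan=False, allow_infinity=False)


def _pair(ddh, ddn):
    apo = ResidueShift(1, "A", 8.0, 120.0)
    return apo, ResidueShift(1, "A", 8.0 + ddh, 120.0 + ddn)


class TestCompute:
    @pytest.mark.parametrize(
        "ddh,ddn,expected",
        [
            (0.0, 0.0, 0.0),
            (0.0, 1.0, 0.152),
            # high-precision evaluation: sqrt(0.1^2 + (0.152*1.0)^2)
            (0.1, 1.0, 0.18194504664870632),
        ],
    )
    def test_examples(self, ddh, ddn, expected):
        apo, bound = _pair(ddh, ddn)
        assert compute_csp(apo, bound) == pytest.approx(expected, abs=1e-12)

    def test_residue_mismatch(self):
        with pytest.raises(ValidationError):
            compute_csp(ResidueShift(1, "A", 8, 120), ResidueShift(2, "A", 8, 120))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(ddh=finite, ddn=finite)
    def test_symmetric_in_state_order(self, ddh, ddn):
        apo, bound = _pair(ddh, ddn)
        assert compute_csp(apo, bound) == pytest.approx(compute_csp(bound, apo), abs=0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(ddh=finite, ddn=finite, extra=st.floats(0, 3))
    def test_monotone_in_each_displacement(self, ddh, ddn, extra):
        base = compute_csp(*_pair(ddh, ddn))
        grow_h = compute_csp(*_pair(math.copysign(abs(ddh) + extra, ddh or 1), ddn))
        grow_n = compute_csp(*_pair(ddh, math.copysign(abs(ddn) + extra, ddn or 1)))
        assert grow_h >= base - 1e-15
        assert grow_n >= base - 1e-15


class TestProfile:
    def test_identity_profile_is_zero(self, single_truth):
        import dataclasses

        flat = dataclasses.replace(single_truth)
        flat.amplitudes = {rid: (0.0, 0.0) for rid in flat.amplitudes}
        ds = simulate_titration(flat)
        prof = csp_profile(ds, ds.n_points - 1)
        assert all(v == 0.0 for v in prof.values.values())
        assert prof.mean_delta == 0.0

    def test_noiseless_profile_reproduces_truth(self, single_truth, single_ds):
        """Generator identity: Delta equals |combined amplitude| x occupancy."""
        k = single_ds.n_points - 1
        occ = bound_fraction_single(
            single_truth.P0, single_truth.L0_schedule[k], single_truth.Kd
        )
        prof = csp_profile(single_ds, k)
        for rid, (ah, an) in single_truth.amplitudes.items():
            expected = occ * math.hypot(ah, 0.152 * an)
            assert prof.values[rid] == pytest.approx(expected, abs=1e-12)

    def test_missing_residue_excluded(self, single_ds):
        import copy

        ds = copy.deepcopy(single_ds)
        k = ds.n_points - 1
        del ds.shifts[(1, k)]
        prof = csp_profile(ds, k)
        assert 1 not in prof.values

    def test_conc_index_out_of_range(self, single_ds):
        with pytest.raises(IndexError):
            csp_profile(single_ds, single_ds.n_points)


class TestSelection:
    @staticmethod
    def _meta(rids, resolved=None):
        resolved = resolved or {}
        return {
            r: ResidueMeta(r, Domain.WW, True, resolved.get(r, True)) for r in rids
        }

    def test_strictly_above_mean(self):
        prof = CspProfile(1, {1: 0.1, 2: 0.2, 3: 0.3}, mean_delta=0.2)
        assert select_responsive_residues(prof, self._meta([1, 2, 3])) == {3}

    def test_all_equal_selects_none(self):
        prof = CspProfile(1, {1: 0.2, 2: 0.2}, mean_delta=0.2)
        assert select_responsive_residues(prof, self._meta([1, 2])) == set()

    def test_unresolved_residue_gated_out(self):
        prof = CspProfile(1, {1: 0.5, 2: 0.01}, mean_delta=0.255)
        meta = self._meta([1, 2], resolved={1: False})
        assert select_responsive_residues(prof, meta) == set()

    def test_empty_profile_warns(self):
        with pytest.warns(UserWarning):
            out = select_responsive_residues(CspProfile(1, {}, math.nan), {})
        assert out == set()

    def test_order_invariance(self):
        vals = {1: 0.11, 2: 0.29, 3: 0.31, 4: 0.05}
        meta = self._meta([1, 2, 3, 4])
        a = select_responsive_residues(CspProfile(1, vals, 0.19), meta)
        rev = dict(reversed(list(vals.items())))
        b = select_responsive_residues(CspProfile(1, rev, 0.19), meta)
        assert a == b


class TestCorrelation:
    @staticmethod
    def _states(n=5, offset=0.0, rng=None):
        meta, a, b = {}, {}, {}
        for rid in range(1, n + 1):
            meta[rid] = ResidueMeta(rid, Domain.WW, True, True)
            h, nn = 8.0 + 0.1 * rid, 118.0 + rid
            a[rid] = ResidueShift(rid, "A", h, nn)
            if rng is None:
                b[rid] = ResidueShift(rid, "A", h + offset, nn + offset / 0.152)
            else:
                b[rid] = ResidueShift(rid, "A", rng.uniform(7, 10), rng.uniform(105, 130))
        return a, b, meta

    def test_identical_states(self):
        a, _, meta = self._states()
        out = shift_correlation(a, a, Domain.WW, meta)
        assert out.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert out.rmsd == 0.0

    def test_constant_offset(self):
        c = 0.37
        a, b, meta = self._states(offset=c)
        out = shift_correlation(a, b, Domain.WW, meta)
        assert out.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert out.rmsd == pytest.approx(c, abs=1e-12)
        assert out.identity_line_max_dev == pytest.approx(c, abs=1e-12)

    def test_rmsd_matches_brute_force(self):
        rng = np.random.default_rng(0)
        a, b, meta = self._states(n=200, rng=rng)
        out = shift_correlation(a, b, Domain.WW, meta)
        sq = []
        for rid in a:
            sq.append((a[rid].delta_H - b[rid].delta_H) ** 2)
            sq.append((0.152 * (a[rid].delta_N - b[rid].delta_N)) ** 2)
        assert out.rmsd == pytest.approx(math.sqrt(sum(sq) / len(sq)), abs=1e-12)
        assert out.n_points == 200

    def test_insufficient_common_residues(self):
        a, b, meta = self._states(n=1)
        with pytest.raises(InsufficientDataError):
            shift_correlation(a, b, Domain.WW, meta)
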