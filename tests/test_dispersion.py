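"""Forward-model tests: coefficient laws, geometry, plume, puffs, merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plumetrack.dispersion import (
    DispersionState,
    Puff,
    Receptor,
    SourceTerm,
    WindSeries,
    advect_puff,
    decay_factor,
    emit_puffs,
    multi_puff_concentration,
    plume_concentration,
    plume_field,
    puff_concentration,
    puff_train_field,
    sigma_plume,
    sigma_puff,
    to_plume_frame,
)

state_strategy = st.builds(
    DispersionState,
    a1=st.floats(0.1, 0.5), b1=st.floats(0.8, 1.0),
    a2=st.floats(0.9, 1.1), b2=st.floats(0.4, 0.6),
)


class TestSigmaLaws:
    @pytest.mark.parametrize("coefs,x,expected", [
        ((0.4, 0.9, 1.0, 0.5), 1.0, (0.4, 1.0)),          # x=1 forces sigma=a
        ((0.4, 0.9, 1.0, 0.5), 100.0, (None, 10.0)),      # sqrt(100)
        # high-precision value of 0.3 * exp(0.9 * ln 1000)
        ((0.3, 0.9, 1.0, 0.5), 1000.0, (150.356170088181685, None)),
    ])
    def test_plume_power_law(self, coefs, x, expected):
        state = DispersionState(*coefs)
        sy, sz = sigma_plume(state, x)
        if expected[0] is not None:
            assert sy == pytest.approx(expected[0], rel=1e-13)
        if expected[1] is not None:
            assert sz == pytest.approx(expected[1], rel=1e-13)

    def test_puff_power_law(self):
        state = DispersionState(0.2, 1.0, 0.9, 0.4)
        sx, sy, sz = sigma_puff(state, 50.0)
        assert sx == sy == pytest.approx(10.0)               # linear case
        # high-precision value of 0.9 * exp(0.4 * ln 200)
        _, _, sz200 = sigma_puff(state, 200.0)
        assert sz200 == pytest.approx(7.49297886661685826, rel=1e-13)
        sx1, sy1, sz1 = sigma_puff(state, 1.0)
        assert (sx1, sz1) == (0.2, 0.9)                      # d=1 forces sigma=a

    @pytest.mark.parametrize("func,bad", [(sigma_plume, 0.0), (sigma_plume, -5.0),
                                          (sigma_puff, 0.0), (sigma_puff, -1.0)])
    def test_nonpositive_distance_rejected(self, midstate, func, bad):
        with pytest.raises(ValueError):
            func(midstate, bad)

    @given(state=state_strategy)
    @settings(max_examples=50, deadline=None)
    def test_sigma_strictly_increasing(self, state):
        x = np.array([10.0, 100.0, 1000.0, 10000.0])
        sy, sz = sigma_plume(state, x)
        assert np.all(np.diff(sy) > 0) and np.all(np.diff(sz) > 0)


class TestDecay:
    def test_inert_and_closed_form(self):
        assert decay_factor(12345.0, 0.0) == 1.0
        assert decay_factor(0.0, 1e-3) == 1.0
        assert decay_factor(1.0 / 1e-3, 1e-3) == pytest.approx(math.exp(-1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_factor(-1.0, 0.0)


class TestPlumeFrame:
    def test_receptor_exactly_downwind(self, source):
        # wind from 210 deg -> axis toward 30 deg
        ax = math.radians(30.0)
        r = Receptor(x=source.x + 2000 * math.sin(ax),
                     y=source.y + 2000 * math.cos(ax))
        xd, yc = to_plume_frame(source, 210.0, r)
        assert xd == pytest.approx(2000.0)
        assert yc == pytest.approx(0.0, abs=1e-9)

    def test_receptor_at_source(self, source):
        assert to_plume_frame(source, 210.0, Receptor(x=source.x, y=source.y)) \
            == pytest.approx((0.0, 0.0))

    def test_nne_receptor_is_downwind_of_210_wind(self, source):
        # high concentrations NNE of the source under a 210-deg wind
        xd, _ = to_plume_frame(source, 210.0, Receptor(x=1000.0, y=1700.0))
        assert xd > 0


class TestPlume:
    def test_zero_release_is_zero_everywhere(self, midstate):
        src = SourceTerm.constant(0.0, height=50.0)
        r = Receptor(x=500.0, y=900.0)
        assert plume_concentration(src, 210.0, 1.85, midstate, r) == 0.0

    def test_ground_source_centerline_closed_form(self, midstate):
        src = SourceTerm.constant(1.0e-3, height=0.0)
        ax = math.radians(30.0)
        x = 1000.0
        r = Receptor(x=x * math.sin(ax), y=x * math.cos(ax), z=0.0)
        sy, sz = sigma_plume(midstate, x)
        # reflection doubles the half-space value: q / (pi v sy sz)
        expected = 1.0e-3 / (math.pi * 1.85 * sy * sz)
        assert plume_concentration(src, 210.0, 1.85, midstate, r) \
            == pytest.approx(expected, rel=1e-12)

    def test_elevated_centerline_high_precision(self, source, midstate):
        # q exp(-H^2/2 sz^2) / (pi v sy sz) at x=2000 m; frozen from an
        # independent 50-digit evaluation of the closed form.
        ax = math.radians(30.0)
        r = Receptor(x=2000 * math.sin(ax), y=2000 * math.cos(ax), z=0.0)
        c = plume_concentration(source, 210.0, 1.85, midstate, r)
        assert c == pytest.approx(1.101834502900832595821571e-8, rel=1e-12)

    def test_upwind_is_zero(self, source, midstate):
        r = Receptor(x=-1000.0, y=-1700.0)
        assert plume_concentration(source, 210.0, 1.85, midstate, r) == 0.0

    def test_nonpositive_wind_rejected(self, source, midstate):
        with pytest.raises(ValueError):
            plume_concentration(source, 210.0, 0.0, midstate, Receptor(x=1, y=1))

    @given(y=st.floats(1.0, 5000.0), x=st.floats(100.0, 10000.0),
           state=state_strategy)
    @settings(max_examples=50, deadline=None)
    def test_crosswind_symmetry(self, y, x, state):
        # exact mirror symmetry about the plume axis (wind from the south,
        # axis = +y, so +-x offsets are crosswind)
        src = SourceTerm.constant(4.65e-3, height=83.8)
        c_plus = plume_concentration(src, 180.0, 1.85, state, Receptor(x=y, y=x))
        c_minus = plume_concentration(src, 180.0, 1.85, state, Receptor(x=-y, y=x))
        assert c_plus == c_minus

    def test_ground_reflection_doubles(self, source, midstate):
        ax = math.radians(30.0)
        x = 3000.0
        r = Receptor(x=x * math.sin(ax), y=x * math.cos(ax), z=0.0)
        c = plume_concentration(source, 210.0, 1.85, midstate, r)
        sy, sz = sigma_plume(midstate, x)
        single = (4.65e-3 / (2 * math.pi * 1.85 * sy * sz)
                  * math.exp(-83.8 ** 2 / (2 * sz ** 2)))
        assert c == pytest.approx(2.0 * single, rel=1e-12)

    def test_centerline_vanishes_far_downwind(self, source, midstate):
        ax = math.radians(30.0)
        vals = [plume_concentration(source, 210.0, 1.85, midstate,
                                    Receptor(x=x * math.sin(ax), y=x * math.cos(ax)))
                for x in (1e4, 1e5, 1e6, 1e7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # sy*sz grows like x^(b1+b2) = x^1.4, so c falls ~3 decades over 1e4..1e7
        assert vals[-1] < 1e-4 * vals[0]

    def test_vectorised_field_matches_scalar(self, source, midstate):
        recs = [Receptor(x=500.0, y=1000.0), Receptor(x=-300.0, y=2000.0),
                Receptor(x=2500.0, y=4000.0, z=10.0)]
        arr = np.array([[r.x, r.y, r.z] for r in recs])
        field = plume_field(source, 210.0, 1.85, midstate.as_array()[None, :], arr)
        scalar = [plume_concentration(source, 210.0, 1.85, midstate, r) for r in recs]
        np.testing.assert_allclose(field[0], scalar, rtol=1e-13)


class TestPuffs:
    def test_advection_constant_wind(self, wind):
        p = Puff(xs=0, ys=0, zs=83.8, q=1.0, tstart=100.0)
        pa = advect_puff(p, wind, 700.0)
        assert pa.d == pytest.approx(1.85 * 600.0)
        assert pa.zc == 83.8
        pa0 = advect_puff(p, wind, 100.0)
        assert (pa0.xc, pa0.yc, pa0.d) == (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            advect_puff(p, wind, 50.0)

    def test_advection_two_step_wind(self):
        wind = WindSeries(samples=((0.0, 1.0, 270.0), (100.0, 3.0, 270.0)))
        p = Puff(xs=0, ys=0, zs=0, q=1.0, tstart=0.0)
        pa = advect_puff(p, wind, 150.0)
        assert pa.d == pytest.approx(1.0 * 100 + 3.0 * 50)
        assert pa.xc == pytest.approx(pa.d)  # wind from west -> moves east
        assert pa.yc == pytest.approx(0.0, abs=1e-9)

    def test_zero_mass_and_birth_are_zero(self, wind, midstate):
        r = Receptor(x=100.0, y=100.0)
        p0 = Puff(xs=0, ys=0, zs=10, q=0.0, tstart=0.0)
        assert puff_concentration(p0, wind, midstate, r, 600.0) == 0.0
        p = Puff(xs=0, ys=0, zs=10, q=1.0, tstart=0.0)
        assert puff_concentration(p, wind, midstate, r, 0.0) == 0.0

    def test_center_value_with_reflection(self, wind, midstate):
        p = Puff(xs=0, ys=0, zs=83.8, q=0.0465, tstart=0.0)
        t = 600.0
        pa = advect_puff(p, wind, t)
        sx, sy, sz = (float(v) for v in
                      __import__("plumetrack.dispersion", fromlist=["sigma_puff"])
                      .sigma_puff(midstate, pa.d))
        c = puff_concentration(p, wind, midstate,
                               Receptor(x=pa.xc, y=pa.yc, z=pa.zc), t)
        expected = (p.q / ((2 * math.pi) ** 1.5 * sx * sy * sz)
                    * (1.0 + math.exp(-2.0 * pa.zc ** 2 / sz ** 2)))
        assert c == pytest.approx(expected, rel=1e-12)

    def test_far_receptor_negligible(self, wind, midstate):
        p = Puff(xs=0, ys=0, zs=83.8, q=0.0465, tstart=0.0)
        t = 600.0
        pa = advect_puff(p, wind, t)
        from plumetrack.dispersion import sigma_puff
        sx, _, _ = sigma_puff(midstate, pa.d)
        center = puff_concentration(p, wind, midstate,
                                    Receptor(x=pa.xc, y=pa.yc, z=pa.zc), t)
        far = puff_concentration(p, wind, midstate,
                                 Receptor(x=pa.xc + 9 * sx, y=pa.yc, z=pa.zc), t)
        assert far < 1e-12 * center

    def test_mass_conservation_quadrature(self, wind, midstate):
        # Gauss-Legendre product quadrature of the reflected kernel over the
        # half-space z >= 0 recovers the released mass q * D(t).
        from plumetrack.dispersion import sigma_puff
        p = Puff(xs=0, ys=0, zs=83.8, q=0.0465, tstart=0.0)
        t = 600.0
        pa = advect_puff(p, wind, t)
        sx, sy, sz = sigma_puff(midstate, pa.d)
        n = 40
        xg, wg = np.polynomial.legendre.leggauss(n)

        def axis(a, b):
            return 0.5 * (b - a) * xg + 0.5 * (a + b), 0.5 * (b - a) * wg

        X, WX = axis(pa.xc - 8 * sx, pa.xc + 8 * sx)
        Y, WY = axis(pa.yc - 8 * sy, pa.yc + 8 * sy)
        Z, WZ = axis(0.0, pa.zc + 10 * sz)
        total = sum(
            wx * wy * wz * puff_concentration(p, wind, midstate,
                                              Receptor(x=x, y=y, z=z), t)
            for x, wx in zip(X, WX) for y, wy in zip(Y, WY)
            for z, wz in zip(Z, WZ))
        assert total == pytest.approx(p.q, rel=1e-6)


class TestEmission:
    def test_constant_rate_counts_and_mass(self, source):
        puffs = emit_puffs(source, 10.0, (0.0, 3600.0))
        assert len(puffs) == 360
        total = sum(p.q for p in puffs)
        assert total == pytest.approx(16.74)  # 4.65 g/s x 3600 s = 16.74 kg

    def test_zero_rate_and_empty_window(self):
        src = SourceTerm.constant(0.0)
        assert all(p.q == 0.0 for p in emit_puffs(src, 10.0, (0.0, 100.0)))
        assert emit_puffs(src, 10.0, (100.0, 100.0)) == []

    def test_bad_dt_rejected(self, source):
        with pytest.raises(ValueError):
            emit_puffs(source, 0.0, (0.0, 100.0))


class TestMultiPuff:
    def test_single_puff_equals_puff(self, wind, midstate):
        p = Puff(xs=0, ys=0, zs=83.8, q=0.0465, tstart=0.0)
        r = Receptor(x=500.0, y=900.0)
        assert multi_puff_concentration([p], wind, midstate, r, 600.0) \
            == puff_concentration(p, wind, midstate, r, 600.0)

    def test_linearity_in_mass(self, source, wind, midstate):
        puffs = emit_puffs(source, 60.0, (0.0, 1800.0))
        doubled = [Puff(xs=p.xs, ys=p.ys, zs=p.zs, q=2 * p.q, tstart=p.tstart)
                   for p in puffs]
        r = Receptor(x=800.0, y=1400.0)
        c1 = multi_puff_concentration(puffs, wind, midstate, r, 1800.0)
        c2 = multi_puff_concentration(doubled, wind, midstate, r, 1800.0)
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_puff_train_converges_to_plume(self, source, wind, midstate):
        # established plume: receptor at 2 km downwind, release running 4 h
        ax = math.radians(30.0)
        rec = np.array([[2000 * math.sin(ax), 2000 * math.cos(ax), 0.0]])
        t = 4 * 3600.0
        train = puff_train_field(source, wind, 10.0,
                                 midstate.as_array()[None, :], rec, t)[0, 0]
        plume = plume_concentration(
            source, 210.0, 1.85, midstate,
            Receptor(x=rec[0, 0], y=rec[0, 1], z=0.0))
        assert train == pytest.approx(plume, rel=0.10)

    def test_train_field_matches_scalar_sum(self, source, wind, midstate):
        t = 1800.0
        puffs = emit_puffs(source, 60.0, (0.0, t))
        r = Receptor(x=800.0, y=1400.0)
        scalar = multi_puff_concentration(puffs, wind, midstate, r, t)
        vec = puff_train_field(source, wind, 60.0, midstate.as_array()[None, :],
                               np.array([[r.x, r.y, r.z]]), t)[0, 0]
        assert vec == pytest.approx(scalar, rel=1e-12)


class TestValidation:
    def test_source_invariants(self):
        with pytest.raises(ValueError):
            SourceTerm(height=-1.0)
        with pytest.raises(ValueError):
            SourceTerm(rate_series=((0.0, -1.0),))
        with pytest.raises(ValueError):
            SourceTerm(rate_series=((10.0, 1.0), (5.0, 1.0)))

    def test_wind_invariants(self):
        with pytest.raises(ValueError):
            WindSeries(samples=((0.0, 0.0, 210.0),))
        with pytest.raises(ValueError):
            WindSeries(samples=((0.0, 1.0, 400.0),))
        with pytest.raises(ValueError):
            WindSeries(samples=((0.0, 1.0, 210.0), (0.0, 1.0, 210.0)))

    def test_state_range_enforcement(self):
        with pytest.raises(ValueError):
            DispersionState(0.05, 0.9, 1.0, 0.5)
        with pytest.raises(ValueError):
            Receptor(x=0, y=0, z=-1.0)
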