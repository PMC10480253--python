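"""Reliability metrics: ORR, loop area / NLA, PW, reference omnipole, MD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omnicliq import (
    CliqueConfig,
    LoopTrajectory,
    PlanarWaveParams,
    UnipolarRecording,
    clique_bipoles,
    enumerate_cliques,
    estimate_omnipole,
    generate_planar_wave,
    loop_area,
    make_grid,
    morphology_distortion,
    nla,
    orr,
    project_omnipole,
    pulse_width,
    reference_omnipole,
    segment_activations,
)
from omnicliq.estimation import OmnipoleEstimate

from conftest import synthetic_bipole_pair


def make_estimate(o, r=None, fs=1000.0):
    o = np.asarray(o, dtype=float)
    r = np.zeros_like(o) if r is None else np.asarray(r, dtype=float)
    return OmnipoleEstimate(o_hat=o, residual=r, theta_o=0.0, direction_deg=0.0,
                           ratio_at_optimum=np.inf, capped=False, fs=fs)


def shoelace(points):
    """Independent oracle: net signed polygon area by the cross-product sum."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def star_polygon(rng, n):
    """Random simple polygon, star-shaped with the origin interior (every
    angular gap < pi) — the anatomy of an electric-field loop, and the
    shape class on which the swept-area and enclosed-area readings agree."""
    n = max(int(n), 8)
    gaps = rng.uniform(0.2, 1.8, size=n)
    phi = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    r = rng.uniform(0.1, 2.0, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


class TestOrr:
    def test_direct_quotient(self):
        o = np.array([0.0, 2.0, -1.0])
        r = np.array([0.5, -0.2, 0.1])
        val, capped = orr(make_estimate(o, r))
        assert val == pytest.approx(4.0) and not capped

    def test_zero_residual_capped(self):
        val, capped = orr(make_estimate(np.array([0.0, 1.0, 0.0])))
        assert capped and val > 1e6

    def test_maximal_at_estimated_angle(self, noiseless_rec, first_clique, first_window):
        pair = clique_bipoles(noiseless_rec, first_clique, CliqueConfig.X)
        w = first_window.slice
        best = estimate_omnipole(pair, window=w)
        best_orr, _ = orr(best, window=w)
        for theta_deg in range(-180, 180, 5):
            other = project_omnipole(pair, np.deg2rad(theta_deg))
            val, _ = orr(other, window=w)
            assert best_orr >= val - 1e-9


class TestLoopArea:
    def test_unit_square(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert loop_area(LoopTrajectory(sq)) == pytest.approx(1.0)

    def test_collinear_through_origin_is_zero(self):
        x = np.linspace(-3, 3, 50)
        traj = LoopTrajectory(np.column_stack([x, 0.7 * x]))
        assert loop_area(traj) < 1e-12  # zero up to fp rounding of the products

    def test_ellipse_closed_form(self):
        phi = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        pts = np.column_stack([np.cos(phi), 0.5 * np.sin(phi)])
        assert loop_area(LoopTrajectory(pts)) == pytest.approx(np.pi * 0.5, abs=1e-4)

    def test_degenerate_too_few_points(self):
        assert loop_area(LoopTrajectory(np.array([[0.0, 0.0], [1.0, 1.0]]))) == 0.0

    def test_matches_shoelace_oracle_on_star_polygons(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pts = star_polygon(rng, rng.integers(3, 40))
            ours = loop_area(LoopTrajectory(pts))
            assert ours == pytest.approx(shoelace(pts), rel=1e-9)

    def test_matches_shapely_on_star_polygons(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Polygon

        rng = np.random.default_rng(5)
        for _ in range(25):
            pts = star_polygon(rng, 20)
            assert loop_area(LoopTrajectory(pts)) == pytest.approx(
                Polygon(pts).area, rel=1e-9
            )


class TestNla:
    def test_proportional_bipoles_exactly_zero(self):
        x = np.linspace(-2, 2, 80)
        pair = synthetic_bipole_pair(x, 0.3 * x)
        est = make_estimate(np.abs(x))  # peak 2.0
        assert nla(pair, est) < 1e-12  # zero up to fp rounding

    def test_quadrature_circle_is_pi(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        P = 3.0
        pair = synthetic_bipole_pair(P * np.cos(t), P * np.sin(t))
        est = make_estimate(P * np.cos(t))
        assert nla(pair, est) == pytest.approx(np.pi, rel=1e-4)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_invariant_to_joint_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        bx = np.convolve(rng.normal(size=100), np.hanning(10), mode="same")
        by = np.convolve(rng.normal(size=100), np.hanning(10), mode="same")
        est = make_estimate(np.abs(bx) + 0.1)
        est2 = make_estimate(scale * (np.abs(bx) + 0.1))
        a = nla(synthetic_bipole_pair(bx, by), est)
        b = nla(synthetic_bipole_pair(scale * bx, scale * by), est2)
        assert b == pytest.approx(a, rel=1e-9)

    def test_spacing_trend_cross_clique(self):
        # noiseless planar wave: NLA grows with interelectrode distance
        g = make_grid(6, 6, 1.0)
        p = PlanarWaveParams(psi_w_deg=30.0, noise_sd=0.0, n_beats=1)
        rec = generate_planar_wave(g, p)
        w = segment_activations(rec)[0].slice
        vals = []
        for k in (1, 4):
            pair = clique_bipoles(rec, enumerate_cliques(g, k)[0], CliqueConfig.X)
            est = estimate_omnipole(pair, window=w)
            vals.append(nla(pair, est, window=w))
        assert vals[0] < vals[1]


class TestPulseWidth:
    def test_triangular_pulse_half_width(self):
        # symmetric triangle, base 10 ms at 1 kHz: FWHM is half the base
        o = np.concatenate([np.zeros(20), np.linspace(0, 1, 6)[1:],
                            np.linspace(1, 0, 6)[1:], np.zeros(20)])
        assert pulse_width(make_estimate(o)) == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("sigma_ms", [2.0, 4.0])
    def test_gaussian_fwhm_closed_form(self, sigma_ms):
        t = np.arange(400) - 200.0  # 1 kHz -> ms
        o = np.exp(-0.5 * (t / sigma_ms) ** 2)
        expect = 2 * sigma_ms * np.sqrt(2 * np.log(2))
        assert pulse_width(make_estimate(o)) == pytest.approx(expect, abs=1.0)

    def test_invariant_to_scale_and_shift(self):
        t = np.arange(300) - 120.0
        o = np.exp(-0.5 * (t / 3.0) ** 2)
        base = pulse_width(make_estimate(o))
        assert pulse_width(make_estimate(7.5 * o)) == pytest.approx(base, abs=1e-9)
        assert pulse_width(make_estimate(np.roll(o, 40))) == pytest.approx(base, abs=1e-9)

    def test_delayed_sum_widens_pulse(self):
        t = np.arange(300) - 150.0
        o = np.exp(-0.5 * (t / 3.0) ** 2)
        both = o + np.roll(o, 4)
        assert pulse_width(make_estimate(both)) > pulse_width(make_estimate(o))

    def test_negative_signal_undefined(self):
        assert np.isnan(pulse_width(make_estimate(-np.ones(10))))


class TestReferenceOmnipole:
    def grid_rec(self, data, fs=1000.0):
        g = make_grid(2, 2, 1.0)
        return g, UnipolarRecording(grid=g, fs=fs, data=np.asarray(data, dtype=float))

    def test_identical_channels_give_single_derivative(self):
        t = np.arange(200) / 1000.0 * 1000.0
        u = np.exp(-0.5 * ((t - 100) / 5.0) ** 2)
        g, rec = self.grid_rec(np.tile(u, (4, 1)))
        ref = reference_omnipole(rec, enumerate_cliques(g, 1)[0])
        np.testing.assert_allclose(ref.o_ref, -np.gradient(u, 1.0), atol=1e-12)
        assert not ref.alignment_failed
        assert list(ref.lags) == [0, 0, 0, 0]

    def test_delayed_copies_recover_common_shape(self):
        t = np.arange(300.0)
        u = np.exp(-0.5 * ((t - 150) / 5.0) ** 2)
        delays = [0, 3, 5, 8]
        g, rec = self.grid_rec([np.roll(u, d) for d in delays])
        ref = reference_omnipole(rec, enumerate_cliques(g, 1)[0])
        expect = -np.gradient(u, 1.0)
        core = slice(20, 280)  # edge samples affected by shifting
        np.testing.assert_allclose(ref.o_ref[core], expect[core], atol=1e-6)
        assert list(ref.lags) == delays

    def test_averaging_halves_independent_noise(self):
        # sd of the averaged derivative is ~sigma/2 of a single channel
        rng = np.random.default_rng(123)
        t = np.arange(400.0)
        u = 100 * np.exp(-0.5 * ((t - 200) / 5.0) ** 2)
        sds_single, sds_avg = [], []
        for _ in range(30):
            chans = [u + rng.normal(0, 10.0, size=len(t)) for _ in range(4)]
            g, rec = self.grid_rec(chans)
            ref = reference_omnipole(rec, enumerate_cliques(g, 1)[0])
            quiet = slice(0, 100)  # pre-activation noise floor
            sds_single.append(ref.per_electrode[0][quiet].std())
            sds_avg.append(ref.o_ref[quiet].std())
        ratio = np.mean(sds_single) / np.mean(sds_avg)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_excessive_lag_flagged(self):
        t = np.arange(100.0)
        u = np.exp(-0.5 * ((t - 30) / 3.0) ** 2)
        g, rec = self.grid_rec([u, u, u, np.roll(u, 40)])
        ref = reference_omnipole(rec, enumerate_cliques(g, 1)[0], max_lag=10)
        assert ref.alignment_failed


class TestMorphologyDistortion:
    def ref_of(self, o, fs=1000.0):
        from omnicliq.metrics import ReferenceOmnipole

        return ReferenceOmnipole(o_ref=np.asarray(o, dtype=float),
                                 per_electrode=np.tile(o, (4, 1)),
                                 lags=np.zeros(4, dtype=int), fs=fs)

    def gaussian(self, n=200, mu=100.0, sig=5.0):
        t = np.arange(float(n))
        return np.exp(-0.5 * ((t - mu) / sig) ** 2)

    def test_identical_and_rescaled_are_zero(self):
        o = self.gaussian()
        assert morphology_distortion(make_estimate(o), self.ref_of(o)) == 0.0
        # rescaling cancels in normalisation up to fp rounding
        assert morphology_distortion(make_estimate(3 * o), self.ref_of(o)) < 1e-12

    def test_known_shift_without_alignment(self):
        o = self.gaussian()
        shifted = np.roll(o, 10)
        expect = np.sqrt(np.mean((o - shifted) ** 2))
        got = morphology_distortion(make_estimate(o), self.ref_of(shifted), align="none")
        assert got == pytest.approx(expect, rel=1e-9)

    def test_peak_alignment_removes_pure_shift(self):
        o = self.gaussian()
        got = morphology_distortion(make_estimate(o), self.ref_of(np.roll(o, 10)))
        assert got == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        a = self.gaussian(sig=5.0)
        b = self.gaussian(mu=110.0, sig=8.0) + 0.1 * self.gaussian(mu=60.0, sig=4.0)
        ab = morphology_distortion(make_estimate(a), self.ref_of(b))
        ba = morphology_distortion(make_estimate(b), self.ref_of(a))
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_zero_signal_undefined(self):
        o = self.gaussian()
        assert np.isnan(morphology_distortion(make_estimate(np.zeros_like(o)), self.ref_of(o)))
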