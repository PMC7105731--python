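"""Instability-metric tests: phase mapping closed forms, singularity and
filament detection against analytic ground truth, DF and APD summaries."""

import numpy as np
import pytest

from arrhythmech.tissue_sim import TissueGrid, VoltageMovie
from arrhythmech.instability_metrics import (
    PhaseParams, FilamentParams, InsufficientActivityError,
    mean_reentry_apd, dominant_frequency_map, compute_phase,
    phase_difference, detect_ps, ps_record, detect_filaments,
    filament_record, case_metrics,
)
from arrhythmech.synthetic_data import (
    SpiralSpec, gen_spiral_movie, gen_scroll_movie, gen_plane_wave_movie,
)


def _movie_from_traces(trace, ny=2, nx=2):
    """Tiny movie with the same V_m trace at every node."""
    nt = len(trace)
    frames = np.tile(np.asarray(trace, float)[:, None, None, None],
                     (1, 1, ny, nx))
    grid = TissueGrid(nx=nx, ny=ny, h=0.5, d_x=0.0, d_y=0.0, d_z=0.0)
    return VoltageMovie(grid, np.arange(nt) * 10.0, frames)


def _beat(apd, peak=40.0, rest=-86.0, cycle=600, dt=10.0):
    """One beat: sharp upstroke, linear repolarization over ~apd ms."""
    t = np.arange(0.0, cycle, dt)
    v = np.full_like(t, rest)
    up = 30.0
    seg = (t >= up) & (t <= up + apd / 0.9)
    v[seg] = peak - (peak - rest) * (t[seg] - up) / (apd / 0.9)
    return v


class TestMeanReentryApd:
    def test_identical_beats(self):
        v = np.concatenate([_beat(250.0)] * 4)
        apd, n = mean_reentry_apd(_movie_from_traces(v))
        assert n == 4
        assert apd == pytest.approx(250.0, abs=12.0)   # 10 ms sampling

    def test_mean_of_mixed_beats(self):
        """Beats engineered to APD 100/120/140 average to 120."""
        v = np.concatenate([_beat(a) for a in (100.0, 120.0, 140.0)])
        apd, n = mean_reentry_apd(_movie_from_traces(v))
        assert n == 3
        assert apd == pytest.approx(120.0, abs=12.0)

    def test_insufficient_activity(self):
        v = np.full(100, -86.0)
        with pytest.raises(InsufficientActivityError):
            mean_reentry_apd(_movie_from_traces(v))

    def test_spiral_probe_fine_scan_oracle(self, spiral_movie):
        """Probe APDs equal a brute-force sample-by-sample scan using the
        same conventions (onset at the steepest rise, 90% level on the
        falling limb), to within the 10 ms frame quantum."""
        movie, _ = spiral_movie
        apd, n = mean_reentry_apd(movie)
        v = movie.node_trace(*movie.center_index())
        t = movie.times
        ups = np.flatnonzero((v[:-1] < -40) & (v[1:] >= -40)) + 1
        vals = []
        for i, iu in enumerate(ups):
            nxt = ups[i + 1] if i + 1 < len(ups) else len(v)
            lo = ups[i - 1] if i > 0 else 0
            v_rest = v[lo:iu + 1].min()
            # onset: the depolarized side of the steepest inter-sample rise
            w0 = max(iu - 1, lo)
            w1 = min(iu + 1, len(v) - 1)
            on = w0 + int(np.argmax(np.diff(v[w0:w1 + 1]))) + 1
            seg = v[on:nxt]
            v90 = v_rest + 0.1 * (seg.max() - v_rest)
            pk = int(np.argmax(seg))
            rel = np.flatnonzero(seg[pk:] <= v90)
            if len(rel):
                vals.append(t[on + pk + rel[0]] - t[on])
        assert n == len(ups)
        assert apd == pytest.approx(np.mean(vals), abs=11.0)


class TestDominantFrequency:
    def test_uniform_sine(self):
        t = np.arange(0.0, 10_000.0, 10.0)
        v = -26 + 60 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        _, mdf, nexc = dominant_frequency_map(_movie_from_traces(v))
        assert mdf == pytest.approx(5.0, abs=0.01)
        assert nexc == 0

    def test_higher_power_wins(self):
        t = np.arange(0.0, 10_000.0, 10.0)
        v = (np.sin(2 * np.pi * 3.0 * t / 1000.0)
             + 2.0 * np.sin(2 * np.pi * 7.0 * t / 1000.0)) * 30 - 26
        _, mdf, _ = dominant_frequency_map(_movie_from_traces(v))
        assert mdf == pytest.approx(7.0, abs=0.01)

    def test_constant_nodes_excluded(self):
        t = np.arange(0.0, 4000.0, 10.0)
        frames = np.full((len(t), 1, 2, 2), -85.0)
        frames[:, 0, 0, 0] = -26 + 60 * np.sin(2 * np.pi * 4 * t / 1000.0)
        grid = TissueGrid(nx=2, ny=2, h=0.5, d_x=0, d_y=0, d_z=0)
        dfm, mdf, nexc = dominant_frequency_map(
            VoltageMovie(grid, t, frames))
        assert nexc == 3
        assert mdf == pytest.approx(4.0, abs=0.01)
        assert np.isnan(dfm[0, 1, 1])

    def test_spiral_cycle_count_oracle(self, spiral_movie):
        """Mean DF within one bin of 1/T, cross-checked by counting probe
        upstrokes."""
        movie, _ = spiral_movie
        _, mdf, _ = dominant_frequency_map(movie)
        assert mdf == pytest.approx(5.0, abs=0.02)
        v = movie.node_trace(0, 5, 5)
        cycles = np.sum((v[:-1] < -26) & (v[1:] >= -26))
        assert mdf == pytest.approx(cycles / (movie.duration / 1000.0),
                                    rel=0.1)

    def test_short_movie_rejected(self):
        v = np.zeros(50)
        with pytest.raises(ValueError):
            dominant_frequency_map(_movie_from_traces(v))


class TestPhase:
    def test_quadrature_closed_form(self):
        """V(t) = origin + A sin(2 pi t / T), tau = T/4:
        theta(0) = atan2(A, 0) = pi/2."""
        t = np.arange(0.0, 400.0, 10.0)
        v = -26.0 + 60.0 * np.sin(2 * np.pi * t / 40.0)
        movie = _movie_from_traces(v)
        phase = compute_phase(movie, origin=-26.0)
        assert phase.theta[0, 0, 0, 0] == pytest.approx(np.pi / 2)

    def test_constant_offset_degenerate(self):
        """V identically origin + A: theta = atan2(A, A) = pi/4."""
        movie = _movie_from_traces(np.full(30, -26.0 + 60.0))
        phase = compute_phase(movie, origin=-26.0)
        assert np.allclose(phase.theta, np.pi / 4)

    def test_range_half_open(self, spiral_movie):
        movie, _ = spiral_movie
        th = compute_phase(movie).theta
        assert th.min() >= -np.pi and th.max() < np.pi

    def test_tau_must_align_with_frames(self, spiral_movie):
        movie, _ = spiral_movie
        with pytest.raises(ValueError):
            compute_phase(movie, PhaseParams(tau=15.0))

    def test_spiral_phase_matches_generator(self, spiral_movie):
        """Detected phase circularly correlates > 0.99 with the analytic
        phase of the generator, up to a constant offset."""
        movie, tracks = spiral_movie
        spec = SpiralSpec(period=200.0)
        # quadrature delay (tau = T/4): the embedding is then the exact
        # analytic phase, not a distorted monotone image of it
        phase = compute_phase(movie, PhaseParams(tau=50.0))
        k = 10
        x = np.arange(spec.nx) * spec.h
        X, Y = np.meshgrid(x, x)
        x0, y0, chi = tracks[k][0]
        truth = (chi * np.arctan2(Y - y0, X - x0)
                 - 2 * np.pi * movie.times[k] / spec.period)
        d = phase.theta[k, 0] - truth
        # circular correlation: resultant length of the phase difference
        r = np.abs(np.mean(np.exp(1j * d)))
        assert r > 0.99


class TestPhaseDifference:
    def test_wrap_cases(self):
        assert phase_difference(np.pi / 2, -np.pi / 2) == pytest.approx(-np.pi)
        assert phase_difference(0.1, 0.3) == pytest.approx(-0.2)
        assert phase_difference(-3.0, 3.0) == pytest.approx(
            -6.0 + 2 * np.pi)

    def test_matches_modular_oracle_on_grid(self):
        """Exhaustive grid: the three-case rule equals the modular wrap
        ((d + pi) mod 2 pi) - pi everywhere."""
        th = np.linspace(-np.pi, np.pi, 101, endpoint=False)
        a, b = np.meshgrid(th, th)
        got = phase_difference(a, b)
        oracle = np.mod(a - b + np.pi, 2 * np.pi) - np.pi
        np.testing.assert_allclose(got, oracle, atol=1e-12)
        assert got.min() >= -np.pi and got.max() < np.pi

    def test_antisymmetry_off_boundary(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        d1, d2 = phase_difference(a, b), phase_difference(b, a)
        off = np.abs(np.abs(d1) - np.pi) > 1e-9
        np.testing.assert_allclose(d1[off], -d2[off], atol=1e-12)


def _winding_oracle(theta_frame, cy, cx, radius, n_samples=720):
    """Brute-force winding number: integrate wrapped phase differences
    along a dense discrete loop around (cy, cx)."""
    ang = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    iy = np.clip(np.round(cy + radius * np.sin(ang)).astype(int), 0,
                 theta_frame.shape[0] - 1)
    ix = np.clip(np.round(cx + radius * np.cos(ang)).astype(int), 0,
                 theta_frame.shape[1] - 1)
    vals = theta_frame[iy, ix]
    total = np.sum(phase_difference(np.roll(vals, -1), vals))
    return total / (2 * np.pi)


class TestDetectPs:
    def test_point_vortex_both_chiralities(self):
        x = np.arange(40)
        X, Y = np.meshgrid(x, x)
        th = np.arctan2(Y - 19.7, X - 20.2)
        th[th >= np.pi] = -np.pi
        from arrhythmech.instability_metrics import PhaseField
        for sign in (+1, -1):
            field = PhaseField(np.array([0.0]), (sign * th)[None, None])
            pts = detect_ps(field, 0)
            assert len(pts) == 1
            fy, fx, q = pts[0]
            assert q == pytest.approx(sign * 2 * np.pi)
            assert abs(fy - 19.7) <= 1.0 and abs(fx - 20.2) <= 1.0

    def test_uniform_phase_no_ps(self):
        from arrhythmech.instability_metrics import PhaseField
        field = PhaseField(np.array([0.0]), np.full((1, 1, 30, 30), 0.7))
        assert detect_ps(field, 0) == []

    def test_two_vortices_match_winding_oracle(self):
        spec = SpiralSpec(cores=[(8.0, 12.5, +1), (17.0, 12.5, -1)])
        movie, tracks = gen_spiral_movie(spec, 600.0)
        phase = compute_phase(movie)
        pts = detect_ps(phase, 4)
        assert len(pts) == 2
        assert sum(p[2] for p in pts) == pytest.approx(0.0, abs=1e-9)
        for (fy, fx, q) in pts:
            w = _winding_oracle(phase.theta[4, 0], fy, fx, radius=4.0)
            assert w == pytest.approx(q / (2 * np.pi), abs=0.1)

    def test_net_charge_zero_for_vortex_pair(self):
        spec = SpiralSpec(cores=[(9.0, 9.0, +1), (16.0, 16.0, -1)])
        movie, _ = gen_spiral_movie(spec, 500.0)
        rec = ps_record(compute_phase(movie))
        for pts in rec.points:
            assert sum(p[3] for p in pts) == pytest.approx(0.0, abs=1e-9)


class TestFilaments:
    def test_uniform_scroll_single_component(self):
        movie, _ = gen_scroll_movie(SpiralSpec(period=200.0), nz=6)
        mask, ne, nc = detect_filaments(movie, 3,
                                        FilamentParams(v_iso=-40.0))
        assert nc == 1
        assert mask.any(axis=(1, 2)).all()      # spans every layer pair

    def test_resting_tissue_no_filaments(self):
        grid = TissueGrid(nx=10, ny=10, nz=4, h=0.5, d_x=0, d_y=0, d_z=0)
        frames = np.full((5, 4, 10, 10), -86.0)
        movie = VoltageMovie(grid, np.arange(5) * 10.0, frames)
        _, ne, nc = detect_filaments(movie, 0, FilamentParams(v_iso=-40.0))
        assert ne == 0 and nc == 0

    def test_elements_at_least_components(self):
        movie, _ = gen_scroll_movie(
            SpiralSpec(period=200.0,
                       cores=[(8.0, 8.0, +1), (17.0, 17.0, -1)]), nz=5)
        rec = filament_record(movie, FilamentParams(v_iso=-40.0))
        assert np.all(rec.element_counts >= rec.component_counts)

    def test_element_count_linear_in_layers(self):
        counts = {}
        for nz in (6, 11):
            movie, _ = gen_scroll_movie(SpiralSpec(period=200.0), nz=nz)
            rec = filament_record(movie, FilamentParams(v_iso=-40.0))
            counts[nz] = rec.mean_elements
        # elements live on layer pairs: count scales with nz - 1
        assert counts[11] / counts[6] == pytest.approx(10.0 / 5.0, rel=0.1)

    def test_filament_columns_near_surface_ps(self):
        """Filament-bearing (x, y) columns coincide with per-slice PS
        locations within one voxel."""
        movie, _ = gen_scroll_movie(SpiralSpec(period=200.0), nz=6)
        mask, _, _ = detect_filaments(movie, 3, FilamentParams(v_iso=-40.0))
        cols = np.argwhere(mask.any(axis=0))
        phase = compute_phase(movie)
        ps = detect_ps(phase, 3, iz=0)
        assert len(ps) == 1 and len(cols) > 0
        fy, fx, _ = ps[0]
        dist = np.abs(cols - np.array([fy, fx])).max(axis=1)
        assert dist.min() <= 1.5

    def test_2d_movie_rejected(self, spiral_movie):
        movie, _ = spiral_movie
        with pytest.raises(ValueError, match="detect_ps"):
            detect_filaments(movie, 0)

    def test_v_iso_estimated_from_surface_ps_is_clamped(self):
        movie, _ = gen_scroll_movie(SpiralSpec(period=200.0), nz=4)
        from arrhythmech.instability_metrics import _estimate_v_iso
        phase = compute_phase(movie)
        v_iso = _estimate_v_iso(movie, phase, 2, FilamentParams())
        assert -75.0 <= v_iso <= -10.0


class TestCaseMetrics:
    def test_plane_wave_has_no_singularities(self):
        movie = gen_plane_wave_movie(40.0, duration=2500.0)
        out = case_metrics(movie)
        assert out["ps_count"] == 0.0
        assert out["filament_count"] == 0.0

    def test_single_spiral_ps_near_one(self, spiral_movie):
        movie, _ = spiral_movie
        out = case_metrics(movie)
        assert 0.9 <= out["ps_count"] <= 1.1

    def test_schema(self, spiral_movie):
        movie, _ = spiral_movie
        out = case_metrics(movie)
        for key in ("apd_ms", "df_hz", "ps_count", "filament_count",
                    "sv_ml", "amptens_kpa"):
            assert key in out
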