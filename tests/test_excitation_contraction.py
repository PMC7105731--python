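"""Excitation–contraction tests: cross-bridge chain, tension summary
statistics, activation, circulation conservation and stroke volume."""

import numpy as np
import pytest

from arrhythmech.excitation_contraction import (
    CrossBridgeParams, CirculationParams, CirculationState, TensionField,
    run_crossbridge, amp_tens, activation_from_tension, step_circulation,
    run_circulation, stroke_volume,
)


def _ca_transients(duration=3000.0, period=1000.0, peak=1e-3):
    """Clipped-sine calcium transients (mM) at 10 ms cadence."""
    t = np.arange(0.0, duration, 10.0)
    ca = 1e-4 + peak * np.clip(np.sin(2 * np.pi * t / period) ** 9, 0, None)
    return t, ca


class TestCrossBridge:
    def test_zero_calcium_gives_zero_tension(self):
        t = np.arange(0.0, 500.0, 10.0)
        field = run_crossbridge(t, np.zeros((len(t), 3)))
        assert np.all(field.tension == 0.0)

    def test_negative_calcium_rejected(self):
        t = np.arange(0.0, 100.0, 10.0)
        with pytest.raises(ValueError, match="nonnegative"):
            run_crossbridge(t, np.full((len(t), 1), -1e-4))

    def test_saturating_calcium_plateau(self):
        """Constant saturating calcium: tension approaches a constant;
        SD after the transient < 1% of the plateau."""
        t = np.arange(0.0, 8000.0, 10.0)
        field = run_crossbridge(t, np.full((len(t), 1), 2e-3))
        tail = field.tension[len(t) // 2:, 0]
        assert tail[-1] > 0
        assert tail.std() < 0.01 * tail[-1]

    def test_occupancies_sum_to_one(self):
        """N + P + PreR + PostR = 1 at every recorded step (1e-10)."""
        t, ca = _ca_transients()
        _, states = run_crossbridge(t, ca, return_states=True)
        sums = states.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)
        assert np.all(states >= -1e-12)

    def test_periodic_drive_dual_step_oracle(self):
        """1 Hz calcium gives 1 Hz tension; a 10x finer integration step
        reproduces the same waveform."""
        t, ca = _ca_transients(4000.0)
        coarse = run_crossbridge(t, ca, CrossBridgeParams(dt=0.1))
        fine = run_crossbridge(t, ca, CrossBridgeParams(dt=0.01))
        scale = fine.tension.max()
        assert scale > 1.0
        np.testing.assert_allclose(coarse.tension, fine.tension,
                                   atol=0.02 * scale)
        # periodicity: last two cycles match
        cyc = 100   # frames per 1000 ms
        last, prev = coarse.tension[-cyc:, 0], coarse.tension[-2*cyc:-cyc, 0]
        np.testing.assert_allclose(last, prev, atol=0.02 * scale)

    def test_monotone_calcium_coupling(self):
        """Scaling calcium transients up by 20% never decreases ampTens."""
        t, ca = _ca_transients()
        base = amp_tens(run_crossbridge(t, ca))
        up = amp_tens(run_crossbridge(t, 1e-4 + 1.2 * (ca - 1e-4)))
        assert up >= base


class TestAmpTens:
    def test_constant_field_zero(self):
        t = np.arange(0.0, 200.0, 10.0)
        field = TensionField(t, np.full((len(t), 5), 3.3))
        assert amp_tens(field) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_closed_form(self):
        """T(t) = 2 + sin(wt) sampled over whole periods: population SD
        is exactly sqrt(1/2) at every node."""
        t = np.arange(0.0, 1600.0, 10.0)      # two 800 ms periods
        w = 2 * np.pi / 800.0
        field = TensionField(t, np.tile(2 + np.sin(w * t), (4, 1)).T)
        assert amp_tens(field) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_random_field_two_pass_oracle(self, rng):
        x = np.abs(rng.normal(size=(50, 7)))
        field = TensionField(np.arange(50) * 10.0, x)
        # brute force: explicit two-pass population SD per node
        expected = np.mean([np.sqrt(np.mean((x[:, j] - x[:, j].mean()) ** 2))
                            for j in range(7)])
        assert amp_tens(field) == pytest.approx(expected, abs=1e-12)

    def test_single_frame_rejected(self):
        field = TensionField(np.array([0.0]), np.ones((1, 3)))
        with pytest.raises(ValueError):
            amp_tens(field)


class TestActivation:
    def test_constant_maps_to_zero(self):
        t = np.arange(0.0, 100.0, 10.0)
        field = TensionField(t, np.full((len(t), 3), 7.0))
        assert np.all(activation_from_tension(field) == 0.0)

    def test_alternating_full_range(self):
        t = np.arange(0.0, 100.0, 10.0)
        tension = np.tile((np.arange(len(t)) % 2) * 30.0, (2, 1)).T
        y = activation_from_tension(TensionField(t, tension))
        np.testing.assert_allclose(np.unique(y), [0.0, 1.0])

    def test_spiral_driven_spectral_match(self):
        """y_v of a spiral-driven tension field peaks at the tissue's mean
        dominant frequency (within one bin)."""
        from arrhythmech.synthetic_data import SpiralSpec, gen_spiral_movie
        from arrhythmech.instability_metrics import dominant_frequency_map
        from arrhythmech.pipeline import calcium_from_voltage
        movie, _ = gen_spiral_movie(
            SpiralSpec(nx=30, ny=30, period=250.0), 3000.0)
        _, mean_df, _ = dominant_frequency_map(movie)
        ca = calcium_from_voltage(movie.frames)
        field = run_crossbridge(movie.times, ca)
        y = activation_from_tension(field) - 0.5
        n_fft = 2 ** 14
        freqs = np.fft.rfftfreq(n_fft, d=0.01)
        power = np.abs(np.fft.rfft(y - y.mean(), n=n_fft)) ** 2
        band = (freqs >= 0.5) & (freqs <= 30)
        peak = freqs[band][np.argmax(power[band])]
        assert peak == pytest.approx(mean_df, abs=0.35)


class TestCirculation:
    def test_rest_volume_gives_zero_pressure(self):
        p = CirculationParams()
        y = 0.3
        v_rest_lv = (1 - y) * (p.v_rest_lv_d - p.v_rest_lv_s) + p.v_rest_lv_s
        v_rest_rv = (1 - y) * (p.v_rest_rv_d - p.v_rest_rv_s) + p.v_rest_rv_s
        s = CirculationState(v_lv=v_rest_lv, v_rv=v_rest_rv)
        out = step_circulation(s, p, y, 0.5)
        assert out.p_lv == pytest.approx(0.0, abs=1e-12)
        assert out.p_rv == pytest.approx(0.0, abs=1e-12)

    def test_compliance_endpoints(self):
        """y = 0 -> C = C_min exactly; y = 1 -> C = C_max exactly
        (pressure slope in volume is 1/C)."""
        p = CirculationParams()
        for y, c in [(0.0, p.c_min_lv), (1.0, p.c_max_lv)]:
            s1 = step_circulation(CirculationState(v_lv=150.0), p, y, 0.5)
            s2 = step_circulation(CirculationState(v_lv=160.0), p, y, 0.5)
            slope = (s2.p_lv - s1.p_lv) / 10.0
            assert slope == pytest.approx(1.0 / c, rel=1e-12)

    def test_closed_loop_volume_conservation(self):
        """Total blood volume constant to 1e-6 relative over 20 s."""
        t = np.arange(0.0, 20_000.0, 10.0)
        y = 0.5 * (1 + np.sin(2 * np.pi * t / 1000.0))
        res = run_circulation(t, y)
        v0 = res["total_volume"][0]
        assert np.max(np.abs(res["total_volume"] - v0)) / v0 < 1e-6

    def test_dt_guard(self):
        with pytest.raises(ValueError):
            step_circulation(CirculationState(), CirculationParams(), 0.5,
                             dt=2.0)

    def test_literal_rest_vector_variant_differs(self):
        base = CirculationParams()
        lit = CirculationParams(literal_rest_vector=True)
        s = CirculationState()
        a = step_circulation(s, base, 0.8, 0.5)
        b = step_circulation(s, lit, 0.8, 0.5)
        assert a.p_lv == pytest.approx(b.p_lv)     # LV unchanged
        assert a.p_rv != b.p_rv                    # RV offset differs

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CirculationParams(c_min_lv=2.0, c_max_lv=1.0)
        with pytest.raises(ValueError):
            CirculationParams(r_sa=-1.0)

    def test_faster_activation_lowers_sv(self):
        """Directional property: a 3-point ladder of faster, more
        fragmented activation produces non-increasing stroke volume."""
        svs = []
        for period in (1000.0, 400.0, 160.0):
            t = np.arange(0.0, 8000.0, 10.0)
            y = 0.5 * (1 + np.sin(2 * np.pi * t / period))
            res = run_circulation(t, y)
            svs.append(stroke_volume(t, res["v_lv"],
                                     res["aortic_flow"]).value)
        assert svs[0] > svs[-1]
        assert np.all(np.diff(svs) <= 1e-9), svs


class TestStrokeVolume:
    def test_sinusoid_extrema(self):
        """V = 85 + 35 cos(2 pi t / 800): EDV 120, ESV 50, SV 70."""
        t = np.arange(0.0, 3200.0, 10.0)
        v = 85 + 35 * np.cos(2 * np.pi * t / 800.0)
        res = stroke_volume(t, v)
        assert res.value == pytest.approx(70.0, abs=0.1)
        assert not res.no_ejection

    def test_constant_volume_flags_no_ejection(self):
        t = np.arange(0.0, 1000.0, 10.0)
        res = stroke_volume(t, np.full(len(t), 120.0))
        assert res.value == 0.0 and res.no_ejection

    def test_meaningful_period_excludes_valveless_cycles(self):
        """Cycles with no aortic flow on the falling limb do not count."""
        t = np.arange(0.0, 3200.0, 10.0)
        v = 85 + 35 * np.cos(2 * np.pi * t / 800.0)
        res = stroke_volume(t, v, aortic_flow=np.zeros(len(t)))
        assert res.no_ejection and res.value == 0.0

    def test_noisy_trace_matches_extremum_scan(self, rng):
        """Multi-cycle trace: matches a brute-force neighbor-comparison
        extremum scan when every swing is far above the prominence
        threshold."""
        t = np.arange(0.0, 6000.0, 10.0)
        v = 100 + 30 * np.sin(2 * np.pi * t / 700.0) \
            + 5 * np.sin(2 * np.pi * t / 6000.0)
        res = stroke_volume(t, v)
        # oracle: local max followed by next local min, neighbor test
        up = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
        dn = np.flatnonzero((v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:])) + 1
        pairs = [(v[i], v[dn[dn > i][0]]) for i in up if np.any(dn > i)]
        expected = np.mean([a - b for a, b in pairs])
        assert res.value == pytest.approx(expected, rel=1e-9)
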