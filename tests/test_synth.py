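import numpy as np
import pytest

from loomkit.geometry import LoomingStimulus, WingSpec, angular_subtense
from loomkit.glides import detect_glides
from loomkit.kinematics import frame_speeds
from loomkit.spikes import RateSeries, threshold_crossings
from loomkit.synth import (
    EtaModelParams,
    SimulationConfig,
    effective_gating,
    eta_peak_rate,
    eta_peak_time,
    eta_rate,
    inject_glides,
    sample_spike_train,
    sample_wingbeats,
    scenario_battery,
    synth_track,
)

from conftest import DISC_LOVS, disc_for_lov


class TestEtaModel:
    def test_zero_scale_is_silent(self):
        params = EtaModelParams(scale_C=0.0)
        stim = disc_for_lov(10.0)
        t = np.linspace(0.01, 0.5, 50)
        np.testing.assert_allclose(eta_rate(params, stim, t), 0.0)

    def test_peak_time_closed_form_alpha5(self):
        # alpha=5, l/|v|=10 ms, delta=0 -> peak 50 ms before collision
        params = EtaModelParams(alpha=5.0, delta_ms=0.0)
        stim = disc_for_lov(10.0)
        assert eta_peak_time(params, stim) == pytest.approx(0.050)
        t = np.linspace(0.001, 0.3, 300000)
        r = eta_rate(params, stim, t)
        assert t[np.argmax(r)] == pytest.approx(0.050, abs=5e-4)

    def test_subtense_at_peak_independent_of_lov(self):
        params = EtaModelParams()
        for lov in (40.0, 10.0, 4.0):
            stim = disc_for_lov(lov)
            t_star_stim = eta_peak_time(params, stim) + params.delta_ms / 1000.0
            theta = angular_subtense(stim.half_size_l, stim.speed_v * t_star_stim)
            assert theta == pytest.approx(
                np.degrees(2 * np.arctan(1 / params.alpha)), rel=1e-9
            )

    def test_zero_outside_motion(self):
        params = EtaModelParams(delta_ms=0.0)
        stim = disc_for_lov(10.0)
        t_start = stim.start_distance / stim.speed_v
        assert eta_rate(params, stim, t_start + 1.0) == 0.0
        t_end = stim.end_distance / stim.speed_v
        assert eta_rate(params, stim, t_end / 2.0) == 0.0

    def test_wing_attenuation_reduces_late_rate_only(self):
        stim = disc_for_lov(10.0)
        winged = LoomingStimulus(
            half_size_l=stim.half_size_l,
            speed_v=stim.speed_v,
            wing=WingSpec(),
        )
        plain = EtaModelParams()
        damped = EtaModelParams(wing_attenuation=0.7)
        t_start = stim.start_distance / stim.speed_v
        t_end = stim.end_distance / stim.speed_v
        quarter = t_end + 0.25 * (t_start - t_end)
        delta_s = plain.delta_ms / 1000.0
        late = quarter - delta_s - 0.01
        early = quarter - delta_s + 0.05
        assert eta_rate(damped, winged, late) == pytest.approx(
            0.7 * eta_rate(plain, winged, late), rel=1e-9
        )
        assert eta_rate(damped, winged, early) == pytest.approx(
            eta_rate(plain, winged, early), rel=1e-9
        )

    def test_wing_attenuation_delays_threshold_crossing(self):
        stim = LoomingStimulus(half_size_l=0.04, speed_v=10.0, wing=WingSpec())
        t = np.linspace(0.4, -0.02, 4000)  # toward and past collision
        for atten in (0.9, 0.7, 0.5):
            plain = EtaModelParams(scale_C=300.0)
            damped = EtaModelParams(scale_C=300.0, wing_attenuation=atten)
            r0 = eta_rate(plain, stim, t)
            r1 = eta_rate(damped, stim, t)
            s0 = RateSeries(t=-t * 1000.0, rate=r0)
            s1 = RateSeries(t=-t * 1000.0, rate=r1)
            c0, _ = threshold_crossings(s0, 150.0)
            c1, _ = threshold_crossings(s1, 150.0)
            assert c0 is not None and c1 is not None
            assert c1 > c0  # attenuated profile crosses strictly later

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            EtaModelParams(alpha=0.0)
        with pytest.raises(ValueError):
            EtaModelParams(wing_attenuation=1.5)
        with pytest.raises(ValueError):
            EtaModelParams(delta_ms=-1.0)


class TestSampleSpikeTrain:
    def test_zero_rate_empty(self):
        tr = sample_spike_train(lambda t: np.zeros_like(t), (0.0, 1.0), 0)
        assert len(tr) == 0

    def test_constant_rate_poisson_count(self):
        counts = [
            len(sample_spike_train(lambda t: np.full_like(t, 100.0), (0.0, 1.0), s))
            for s in range(1000)
        ]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 100.0) < 3 * se + 1e-9

    def test_seed_determinism(self):
        f = lambda t: np.full_like(t, 80.0)  # noqa: E731
        a = sample_spike_train(f, (-1.0, 0.0), 7)
        b = sample_spike_train(f, (-1.0, 0.0), 7)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        c = sample_spike_train(f, (-1.0, 0.0), 8)
        assert len(a) != len(c) or not np.array_equal(a.spike_times, c.spike_times)

    def test_unbounded_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spike_train(lambda t: np.full_like(t, np.inf), (-1.0, 1.0), 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_spike_train(lambda t: -np.ones_like(t), (0.0, 1.0), 0)


class TestSampleWingbeats:
    def test_zero_jitter_exact_lattice(self):
        wb = sample_wingbeats(50.0, 0.0, (0.0, 500.0), 0)
        np.testing.assert_allclose(wb.event_times, 50.0 * np.arange(1, 11))

    def test_phase_shifts_lattice(self):
        wb = sample_wingbeats(50.0, 0.0, (0.0, 500.0), 0, phase_ms=20.0)
        np.testing.assert_allclose(wb.event_times, 20.0 + 50.0 * np.arange(1, 10))

    def test_interval_mean_near_period(self):
        means = []
        for seed in range(50):
            wb = sample_wingbeats(50.0, 3.0, (0.0, 5000.0), seed)
            means.append(float(np.mean(np.diff(wb.event_times))))
        assert np.mean(means) == pytest.approx(50.0, abs=0.5)

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError):
            sample_wingbeats(50.0, 20.0, (0.0, 500.0), 0)

    def test_determinism(self):
        a = sample_wingbeats(50.0, 2.0, (0.0, 1000.0), 3)
        b = sample_wingbeats(50.0, 2.0, (0.0, 1000.0), 3)
        np.testing.assert_array_equal(a.event_times, b.event_times)


class TestInjectGlides:
    @staticmethod
    def _rate(t_ms):
        t = np.asarray(t_ms, dtype=float)
        return np.where(t > -300.0, 250.0, 0.0)

    def test_subthreshold_rate_unchanged(self):
        wb = sample_wingbeats(50.0, 0.0, (-1000.0, 100.0), 0)
        out = inject_glides(wb, self._rate, threshold_hz=300.0, seed=0)
        np.testing.assert_array_equal(out.event_times, wb.event_times)

    def test_gating_zero_unchanged_for_all_seeds(self):
        wb = sample_wingbeats(50.0, 0.0, (-1000.0, 100.0), 0)
        for seed in range(20):
            out = inject_glides(
                wb, self._rate, gating_probability=0.0, seed=seed
            )
            np.testing.assert_array_equal(out.event_times, wb.event_times)

    def test_gating_one_creates_detectable_gap(self):
        wb = sample_wingbeats(50.0, 0.0, (-1000.0, 100.0), 0)
        out = inject_glides(wb, self._rate, gating_probability=1.0, seed=0)
        intervals = np.diff(out.event_times)
        assert intervals.max() > 1.25 * 50.0
        assert len(detect_glides(out)) == 1


class TestSynthTrack:
    def test_zero_noise_exact_speed(self):
        seg = synth_track(10.0, 30.0, 25.0, 0.008, 0.0, 20, 0)
        np.testing.assert_allclose(frame_speeds(seg), 10.0, rtol=1e-9)

    def test_heading_invariance(self):
        a = synth_track(7.0, 0.0, 25.0, 0.008, 0.0, 15, 0)
        b = synth_track(7.0, 123.0, 25.0, 0.008, 0.0, 15, 0)
        np.testing.assert_allclose(frame_speeds(a), frame_speeds(b), rtol=1e-9)

    def test_determinism(self):
        a = synth_track(7.0, 10.0, 25.0, 0.008, 0.5, 15, 11)
        b = synth_track(7.0, 10.0, 25.0, 0.008, 0.5, 15, 11)
        np.testing.assert_array_equal(a.x_px, b.x_px)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            synth_track(0.0, 0.0, 25.0, 0.008, 0.5, 15, 0)
        with pytest.raises(ValueError):
            synth_track(1.0, 0.0, 25.0, 0.008, 0.5, 1, 0)


@pytest.fixture(scope="module")
def small_config():
    stims = tuple(disc_for_lov(l) for l in (10.0, 5.3, 2.7))
    return SimulationConfig(
        stimuli=stims, n_individuals=2, n_presentations=2, rng_seed=5
    )


class TestScenarioBattery:
    def test_product_counts(self, small_config):
        battery = scenario_battery(small_config)
        assert len(battery.spike_trains) == 3 * 2 * 2
        assert len(battery.wingbeat_trains) == 3 * 2 * 2
        assert len(battery.presentation_order) == 3 * 2 * 2

    def test_master_seed_reproducibility(self, small_config):
        a = scenario_battery(small_config)
        b = scenario_battery(small_config)
        for ta, tb in zip(a.spike_trains, b.spike_trains):
            np.testing.assert_array_equal(ta.spike_times, tb.spike_times)
        for wa, wb_ in zip(a.wingbeat_trains, b.wingbeat_trains):
            np.testing.assert_array_equal(wa.event_times, wb_.event_times)
        assert a.presentation_order == b.presentation_order

    def test_different_seeds_differ(self, small_config):
        import dataclasses

        a = scenario_battery(small_config)
        b = scenario_battery(dataclasses.replace(small_config, rng_seed=6))
        assert any(
            len(x) != len(y) or not np.array_equal(x.spike_times, y.spike_times)
            for x, y in zip(a.spike_trains, b.spike_trains)
        )

    def test_presentation_order_is_a_permutation(self, small_config):
        battery = scenario_battery(small_config)
        for ind in ("ind00", "ind01"):
            recs = [r for r in battery.presentation_order if r["individual_id"] == ind]
            assert sorted(r["rank"] for r in recs) == list(range(6))
            assert len({(r["stim_id"], r["presentation"]) for r in recs}) == 6

    def test_effective_gating_monotone_in_lov(self, disc_stimuli):
        config = SimulationConfig(
            stimuli=tuple(disc_stimuli), eta=EtaModelParams(scale_C=300.0)
        )
        gates = [effective_gating(config, s) for s in disc_stimuli]
        assert all(a <= b + 1e-12 for a, b in zip(gates, gates[1:]))


class TestSimulationConfigValidation:
    def test_bad_values(self, disc_stimuli):
        with pytest.raises(ValueError):
            SimulationConfig(stimuli=())
        with pytest.raises(ValueError):
            SimulationConfig(stimuli=tuple(disc_stimuli), n_individuals=0)
        with pytest.raises(ValueError):
            SimulationConfig(stimuli=tuple(disc_stimuli), gating_probability=1.5)
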