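import json

import numpy as np
import pytest

from calmod import synthgen
from calmod.errors import InvalidConfigError
from calmod.synthgen import EventStats, SimConfig

ALL_STATES = ("Still", "StillWhisking", "Locomotion")


def flat_model(rate=0.0, amp=0.5, dur=2.0):
    return {
        comp: {state: EventStats(rate, amp, dur) for state in ALL_STATES}
        for comp in ("AS", "AP", "Gp", "AE", "Neuron")
    }


class TestConfig:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"duration_s": 0.0},
            {"sampling_rate": -1.0},
            {"alpha_true": 1.5},
            {"mean_loc_bout_s": -2.0},
            {"event_model": flat_model(rate=-1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(InvalidConfigError):
            SimConfig(**overrides).validate()

    def test_presets_validate(self):
        synthgen.wildtype_config().validate()
        synthgen.knockout_config().validate()


class TestBehaviorGeneration:
    def test_no_locomotion_probability_gives_single_still_schedule(self):
        cfg = synthgen.wildtype_config(seed=1, loc_bout_prob=0.0, whisk_rate_per_min=0.0)
        beh, schedule = synthgen.generate_behavior(cfg)
        assert (beh.speed < 1.0).all()
        assert schedule.intervals == ((0.0, 300.0, "Still"),)

    def test_zero_whisk_rate_gives_no_whisk_bouts(self):
        cfg = synthgen.wildtype_config(seed=2, whisk_rate_per_min=0.0)
        _, schedule = synthgen.generate_behavior(cfg)
        assert schedule.total_time("StillWhisking") == 0.0
        # without locomotion the energy trace never crosses the threshold
        from calmod import behavior as bh

        cfg = synthgen.wildtype_config(seed=2, whisk_rate_per_min=0.0, loc_bout_prob=0.0)
        beh, schedule2 = synthgen.generate_behavior(cfg)
        assert bh.detect_whisking(beh, [(0.0, beh.duration)]) == []

    def test_determinism_byte_identical(self):
        cfg = synthgen.wildtype_config(seed=9)
        b1, s1 = synthgen.generate_behavior(cfg)
        b2, s2 = synthgen.generate_behavior(cfg)
        assert np.array_equal(b1.speed, b2.speed)
        assert np.array_equal(b1.whisk_energy, b2.whisk_energy)
        assert s1.intervals == s2.intervals

    def test_speed_respects_schedule(self):
        cfg = synthgen.wildtype_config(seed=4)
        beh, schedule = synthgen.generate_behavior(cfg)
        labels = schedule.sample_labels(beh.n_samples)
        assert (beh.speed[labels == "Locomotion"] > 1.0).all()
        assert (beh.speed[labels != "Locomotion"] < 1.0).all()


class TestFluorescenceGeneration:
    def test_silent_config_constant_at_baseline(self):
        cfg = synthgen.wildtype_config(
            seed=1, event_model=flat_model(0.0), noise_sd=0.0,
            bleach_slope=0.0, corr_level=0.0, neuropil_fluct_sd=0.0,
        )
        beh, schedule = synthgen.generate_behavior(cfg, np.random.default_rng(1))
        traces, truth = synthgen.generate_fluorescence(cfg, schedule, np.random.default_rng(1))
        for t in traces:
            if t.compartment == "Neuron":
                assert np.allclose(t.F - cfg.alpha_true * t.F_np, cfg.f0_level, atol=1.0)
            else:
                assert np.allclose(t.F, cfg.f0_level)
        assert all(len(v) == 0 for v in truth.events.values())

    def test_determinism_full_session(self):
        cfg = synthgen.knockout_config(seed=5, n_mice=1, sessions_per_mouse=1)
        s1 = synthgen.generate_session(cfg)
        s2 = synthgen.generate_session(cfg)
        for t1, t2 in zip(s1.traces, s2.traces):
            assert np.array_equal(t1.F, t2.F)
        # NaN-aware comparison (undefined indices serialize identically)
        assert json.dumps(s1.ground_truth.to_dict()) == json.dumps(
            s2.ground_truth.to_dict()
        )

    def test_event_rate_calibration(self):
        """Empirical true event counts match configured rates within 3 SE."""
        rate = 2.0   # events/min in every state: expected count = rate*duration
        cfg = synthgen.wildtype_config(
            duration_s=120.0, event_model=flat_model(rate=rate, amp=0.5, dur=1.0),
        )
        counts = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            beh, schedule = synthgen.generate_behavior(
                synthgen.wildtype_config(seed=seed, duration_s=120.0), rng
            )
            _, truth = synthgen.generate_fluorescence(cfg, schedule, rng)
            counts.append(len(truth.events["sim-AS0"]))
        expected = rate * 2.0    # 2-minute sessions
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_state_switched_rates(self):
        """Per-state event counts follow the per-state configured rates."""
        model = flat_model(0.0)
        for comp in model:
            model[comp] = {
                "Still": EventStats(0.5, 0.5, 1.0),
                "StillWhisking": EventStats(0.5, 0.5, 1.0),
                "Locomotion": EventStats(6.0, 0.5, 1.0),
            }
        still_counts, loc_counts = [], []
        still_t, loc_t = 0.0, 0.0
        for seed in range(50):
            cfg = synthgen.wildtype_config(seed=seed, event_model=model)
            rng = np.random.default_rng(seed)
            beh, schedule = synthgen.generate_behavior(cfg, rng)
            _, truth = synthgen.generate_fluorescence(cfg, schedule, rng)
            labels = {lab: 0 for lab in ALL_STATES}
            for ev in truth.events["sim-Gp0"]:
                labels[schedule.label_at(ev.onset_s)] += 1
            still_counts.append(labels["Still"])
            loc_counts.append(labels["Locomotion"])
            still_t += schedule.total_time("Still") / 60.0
            loc_t += schedule.total_time("Locomotion") / 60.0
        for total, t, rate in [(sum(still_counts), still_t, 0.5),
                               (sum(loc_counts), loc_t, 6.0)]:
            se = np.sqrt(rate * t)
            assert abs(total - rate * t) < 3 * se

    def test_analytic_modulation_identity(self):
        _, truth = _small_truth()
        for roi, means in truth.state_mean_dff.items():
            m_loc, m_s = means["Locomotion"], means["Still"]
            if m_loc + m_s > 0:
                expected = (m_loc - m_s) / (m_loc + m_s)
                assert truth.locmi_true[roi] == expected
            m_w = means["StillWhisking"]
            if m_w + m_s > 0:
                assert truth.whiskmi_true[roi] == (m_w - m_s) / (m_w + m_s)

    def test_all_true_events_inside_session(self):
        _, truth = _small_truth()
        for evs in truth.events.values():
            for ev in evs:
                assert 0.0 <= ev.onset_s < truth.schedule.duration

    def test_alpha_zero_decouples_neuron_from_neuropil(self):
        cfg = synthgen.wildtype_config(
            seed=8, duration_s=600.0, alpha_true=0.0,
            event_model=flat_model(0.0), bleach_slope=0.0,
        )
        rng = np.random.default_rng(8)
        beh, schedule = synthgen.generate_behavior(cfg, rng)
        traces, _ = synthgen.generate_fluorescence(cfg, schedule, rng)
        neuron = next(t for t in traces if t.compartment == "Neuron")
        r = np.corrcoef(neuron.F, neuron.F_np)[0, 1]
        assert abs(r) < 3 / np.sqrt(neuron.n_samples)

    def test_alpha_mixing_recoverable(self):
        """With alpha_true = 0.7, subtracting 0.7*F_np recovers the intrinsic
        baseline while subtracting nothing leaves the neuropil signal in."""
        from calmod import fluor

        cfg = synthgen.wildtype_config(
            seed=9, event_model=flat_model(0.0), noise_sd=0.5, bleach_slope=0.0
        )
        rng = np.random.default_rng(9)
        beh, schedule = synthgen.generate_behavior(cfg, rng)
        traces, _ = synthgen.generate_fluorescence(cfg, schedule, rng)
        neuron = next(t for t in traces if t.compartment == "Neuron")
        corrected = fluor.subtract_neuropil(neuron, alpha=0.7)
        resid = corrected.F - cfg.f0_level
        assert np.std(resid) < 1.0   # fluctuation of the neuropil removed
        raw_resid = neuron.F - cfg.f0_level - 0.7 * cfg.neuropil_level
        assert np.std(raw_resid) > np.std(resid)


def _small_truth():
    cfg = synthgen.wildtype_config(seed=6, duration_s=120.0)
    rng = np.random.default_rng(6)
    beh, schedule = synthgen.generate_behavior(cfg, rng)
    return synthgen.generate_fluorescence(cfg, schedule, rng)


class TestCohort:
    def test_cohort_shape_and_determinism(self):
        cfg = synthgen.knockout_config(seed=3, n_mice=2, sessions_per_mouse=2)
        c1 = synthgen.generate_cohort(cfg)
        c2 = synthgen.generate_cohort(cfg)
        assert len(c1) == 4
        assert {s.mouse_id for s in c1} == {"knockout-m0", "knockout-m1"}
        for a, b in zip(c1, c2):
            assert a.session_id == b.session_id
            assert np.array_equal(a.behavior.speed, b.behavior.speed)
            assert np.array_equal(a.traces[0].F, b.traces[0].F)
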