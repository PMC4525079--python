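"""Generator behavior: degenerate configs, determinism, calibration."""

import dataclasses

import numpy as np
import pytest

from activetouch import kinematics as kin
from activetouch.config import GeneratorConfig
from activetouch.synth import (
    generate_session,
    generate_spikes,
    generate_whisker_trace,
    plan_bouts,
)


def _trial(cfg, i):
    trace = generate_whisker_trace(cfg, i)
    phase = kin.decompose_whisking(trace)
    touches = kin.extract_touch_features(trace)
    return trace, phase, touches


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(trial_duration=-5)
    with pytest.raises(ValueError):
        GeneratorConfig(touch_spike_prob_first=1.2, count_model="binomial")
    with pytest.raises(ValueError):
        GeneratorConfig(touch_latency=-1.0)
    # poisson model admits per-touch means above 1
    GeneratorConfig(touch_spike_prob_first=1.5, count_model="poisson")


def test_no_touch_config_gives_flat_kappa():
    cfg = GeneratorConfig(touches_per_trial_mean=0, seed=2)
    trace = generate_whisker_trace(cfg, 0)
    assert len(trace.touch_intervals) == 0
    assert np.all(trace.kappa == trace.kappa[0])


def test_zero_amplitude_gives_constant_theta():
    cfg = GeneratorConfig(whisk_p2p_amp=0, touches_per_trial_mean=0, seed=2)
    trace = generate_whisker_trace(cfg, 0)
    assert np.allclose(trace.theta, cfg.setpoint)
    phase = kin.decompose_whisking(trace)
    assert len(kin.whisking_cycles(phase)) == 0


def test_deterministic_sessions():
    cfg = GeneratorConfig(n_trials=5, seed=42)
    a = generate_session(cfg)
    b = generate_session(GeneratorConfig(n_trials=5, seed=42))
    for ta, tb in zip(a.traces, b.traces):
        assert np.array_equal(ta.theta, tb.theta)
        assert np.array_equal(ta.touch_intervals, tb.touch_intervals)
    for sa, sb in zip(a.spikes, b.spikes):
        assert np.array_equal(sa.spike_times, sb.spike_times)
    assert np.array_equal(
        a.ground_truth.spike_times, b.ground_truth.spike_times
    )


def test_empty_session():
    s = generate_session(GeneratorConfig(n_trials=0, seed=1))
    assert s.n_trials == 0
    assert len(s.ground_truth.spike_times) == 0


def test_deterministic_spiking_one_spike_per_touch():
    """p=1, no jitter, no background: exactly one spike at onset+latency."""
    cfg = GeneratorConfig(
        baseline_rate=0.0,
        phase_A=0.0,
        phase_B=0.0,
        touch_spike_prob_first=1.0,
        touch_spike_prob_later=1.0,
        touch_jitter=0.0,
        seed=5,
    )
    trace, phase, touches = _trial(cfg, 0)
    train, gt = generate_spikes(trace, touches, phase, cfg)
    assert len(train.spike_times) == len(touches)
    expected = np.sort([tc.onset + cfg.touch_latency for tc in touches])
    assert np.allclose(train.spike_times, expected)
    assert set(gt["labels"]) <= {"touch"}


def test_baseline_only_is_poisson():
    """No touch/phase drive: counts match Poisson moments."""
    cfg = GeneratorConfig(
        baseline_rate=5.0,
        phase_A=0.0,
        phase_B=0.0,
        touch_spike_prob_first=0.0,
        touch_spike_prob_later=0.0,
        refractory=0.0,
        n_trials=100,
        seed=6,
    )
    counts = []
    for i in range(cfg.n_trials):
        trace, phase, touches = _trial(cfg, i)
        train, _ = generate_spikes(trace, touches, phase, cfg)
        counts.append(len(train.spike_times))
    counts = np.asarray(counts)
    expected = cfg.baseline_rate * cfg.trial_duration / 1000.0
    se = np.sqrt(expected / len(counts))
    assert abs(counts.mean() - expected) < 4 * se
    ff = counts.var() / counts.mean()
    assert abs(ff - 1.0) < 0.3


def test_binomial_touch_moments():
    """p=0.7 over ~500 touches: mean ~0.7, variance ~0.21 (binomial)."""
    cfg = GeneratorConfig(
        baseline_rate=0.0,
        phase_A=0.0,
        phase_B=0.0,
        touch_spike_prob_first=0.7,
        touch_spike_prob_later=0.7,
        n_trials=220,
        seed=8,
    )
    per_touch = []
    for i in range(cfg.n_trials):
        trace, phase, touches = _trial(cfg, i)
        train, _ = generate_spikes(trace, touches, phase, cfg)
        for tc in touches:
            # fixed 40 ms window: shorter than the >= 65 ms gap between
            # candidate touch onsets, so windows never collect a
            # neighboring touch's spike
            per_touch.append(
                int(
                    np.sum(
                        (train.spike_times >= tc.onset)
                        & (train.spike_times < tc.onset + 40.0)
                    )
                )
            )
    per_touch = np.asarray(per_touch)
    assert len(per_touch) >= 400
    assert set(np.unique(per_touch)) <= {0, 1}  # binomial mode: 0/1 counts
    p_se = np.sqrt(0.21 / len(per_touch))
    assert abs(per_touch.mean() - 0.7) < 4 * p_se
    assert abs(per_touch.var() - 0.21) < 0.04


def test_labels_partition_all_spikes(small_analyzed):
    gt = small_analyzed.session.ground_truth
    assert set(gt.labels) <= {"touch", "phase", "baseline"}
    n_kept = sum(
        len(st.spike_times) for st in small_analyzed.session.spikes
    )
    assert n_kept == int((~gt.deleted).sum())


def test_behavioral_calibration():
    """200 trials reproduce the target whisking and touch statistics."""
    cfg = GeneratorConfig(n_trials=200, seed=77)
    freqs, n_touches, bout_durs, bout_amps = [], [], [], []
    for i in range(cfg.n_trials):
        for b in plan_bouts(cfg, i):
            bout_durs.append(b["full_duration"])
            bout_amps.append(b["p2p"])
        trace = generate_whisker_trace(cfg, i)
        n_touches.append(len(trace.touch_intervals))
        phase = kin.decompose_whisking(trace)
        p2p = kin._cycle_p2p(phase)
        sel = (p2p > kin.WHISKING_P2P_DEG) & phase.cycle_monotonic
        d = phase.cycles[sel, 1] - phase.cycles[sel, 0]
        freqs.extend(1000.0 / d)
    assert abs(np.mean(freqs) - 15.4) / 15.4 < 0.10
    assert abs(np.mean(n_touches) - 2.33) / 2.33 < 0.15
    # bootstrap 95% intervals of the generated summary statistics cover
    # the calibration targets
    rng = np.random.default_rng(3)
    for sample, target in ((bout_durs, 261.0), (bout_amps, 15.7)):
        sample = np.asarray(sample)
        boots = rng.choice(sample, (500, len(sample))).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        assert lo <= target <= hi


def test_default_summary_in_published_ranges(default_analyzed):
    """Default-session per-neuron summary falls in the reported L4 ranges."""
    import activetouch.spike_metrics as sm

    a = default_analyzed
    rates = sm.epoch_rates(a.session.spikes, a.epochs, a.touches)
    spt = rates["spikes_per_touch"]
    firsts = np.array([tc.is_first for tc in a.touches])
    assert 0.08 <= spt[firsts].mean() <= 5.77
    assert 4 <= a.latency <= 18
    fit = sm.phase_tuning(a.session.spikes, a.phases, a.epochs)
    assert 0.0 <= fit.modulation_depth <= 1.0


def test_refractory_enforced():
    cfg = GeneratorConfig(baseline_rate=40.0, refractory=2.3, seed=9)
    trace, phase, touches = _trial(cfg, 0)
    train, gt = generate_spikes(trace, touches, phase, cfg)
    assert np.all(np.diff(train.spike_times) > cfg.refractory)
    assert gt["deleted"].sum() > 0  # deletions are logged


def test_config_roundtrip(tmp_path):
    from activetouch.config import load_config

    cfg = GeneratorConfig(n_trials=3, seed=4)
    p = tmp_path / "cfg.json"
    import json

    p.write_text(json.dumps(cfg.to_dict()))
    cfg2 = load_config(p)
    assert dataclasses.asdict(cfg2) == dataclasses.asdict(cfg)
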