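"""Synthetic active-touch sessions with known ground truth.

Generates whisker traces, touch events, and single-unit spike trains from a
parameterized model of pole localization behavior: whisking occurs in bouts
(gamma-distributed durations, raised-cosine amplitude envelopes), touches
occur at protraction peaks while the pole is in reach (thinned to the target
touch count), and spikes arise from three labeled processes:

* touch-evoked: per touch, a binomial (0/1) or Poisson count at latency
  ``touch_latency`` plus a half-normal delay (scale ``touch_jitter``), so the
  configured latency is the onset of the response, not its center;
* phase-coupled: an inhomogeneous Poisson process with rate
  ``A [1 + cos(phi - phase_pref)] + B`` during whisking epochs;
* baseline: a homogeneous Poisson process throughout the trial.

Spikes closer than the absolute refractory period to the previous kept
spike are deleted (forward deletion, matching the refractory-Poisson null
used in the variability analysis). Every generated spike keeps its process
label so parameter-recovery analyses can join on spike identity.
"""

from __future__ import annotations

import numpy as np

from .config import GeneratorConfig
from .types import GroundTruth, Session, SpikeTrain, WhiskerTrace

__all__ = [
    "plan_bouts",
    "generate_whisker_trace",
    "generate_spikes",
    "generate_session",
]

_TRACE_STREAM = 0
_SPIKE_STREAM = 1


def _rng(config: GeneratorConfig, trial_index: int, stream: int):
    return np.random.default_rng(
        [int(config.seed) % (2**31), int(trial_index), stream]
    )


def plan_bouts(config: GeneratorConfig, trial_index: int) -> list:
    """Deterministic whisking-bout schedule for one trial.

    Returns a list of dicts with keys start, end (ms), p2p (deg), freq
    (Hz), phi0 (rad). Alternates gamma-distributed rest and bout periods
    until the trial is covered.
    """
    rng = _rng(config, trial_index, _TRACE_STREAM)
    T = config.trial_duration
    bouts = []
    # gamma shapes: 4 for bouts (skewed, positive), 2 for rests
    t = rng.gamma(2.0, config.rest_duration_mean / 2.0)
    while t < T:
        dur = rng.gamma(4.0, config.bout_duration_mean / 4.0)
        p2p = (
            rng.gamma(9.0, config.whisk_p2p_amp / 9.0)
            if config.whisk_p2p_amp > 0
            else 0.0
        )
        freq = max(6.5, rng.normal(config.whisk_freq, 1.0))
        bouts.append(
            {
                "start": t,
                "full_duration": dur,  # before truncation at the trial end
                "end": min(t + dur, T),
                "p2p": p2p,
                "freq": freq,
                "phi0": rng.uniform(0, 2 * np.pi),
            }
        )
        t += dur + rng.gamma(2.0, config.rest_duration_mean / 2.0)
    return bouts


def _bout_waveform(t_ms, bout):
    """Oscillation of one bout on the time grid (deg), raised-cosine ramps."""
    start, end = bout["start"], bout["end"]
    dur = end - start
    ramp = min(50.0, dur / 2.0)
    local = t_ms - start
    active = (local >= 0) & (local < dur)
    env = np.zeros_like(t_ms)
    x = local[active]
    e = np.ones_like(x)
    e = np.where(x < ramp, 0.5 * (1 - np.cos(np.pi * x / ramp)), e)
    tail = dur - x
    e = np.where(tail < ramp, 0.5 * (1 - np.cos(np.pi * tail / ramp)), e)
    env[active] = e
    carrier = np.cos(
        2 * np.pi * bout["freq"] * (t_ms - start) / 1000.0 + bout["phi0"]
    )
    return env * (bout["p2p"] / 2.0) * carrier


def _protraction_peaks(bout):
    """Times (ms) of carrier maxima within the bout."""
    f = bout["freq"] / 1000.0  # cycles per ms
    period = 1.0 / f
    # carrier max where 2*pi*f*(t-start) + phi0 = 2*pi*k
    first = bout["start"] + ((-bout["phi0"] / (2 * np.pi)) % 1.0) * period
    peaks = np.arange(first, bout["end"], period)
    return peaks[peaks >= bout["start"]]


def _dkappa_profile(n, onset_i, offset_i, peak):
    """Linear 10 ms rise, plateau to offset, exponential release (tau 5 ms)."""
    prof = np.zeros(n)
    rise_end = min(onset_i + 10, offset_i)
    if rise_end > onset_i:
        prof[onset_i:rise_end] = peak * np.linspace(
            1.0 / (rise_end - onset_i), 1.0, rise_end - onset_i
        )
    prof[rise_end:offset_i] = peak
    tail = np.arange(offset_i, min(offset_i + 15, n))
    prof[tail] = peak * np.exp(-(tail - offset_i) / 5.0)
    return prof


def generate_whisker_trace(
    config: GeneratorConfig, trial_index: int
) -> WhiskerTrace:
    """Generate theta(t), kappa(t), touches, and licks for one trial."""
    config.validate()
    rng = _rng(config, trial_index, _TRACE_STREAM + 2)
    n = int(round(config.trial_duration))
    t = np.arange(n, dtype=float)
    theta = np.full(n, config.setpoint, dtype=float)
    bouts = plan_bouts(config, trial_index)
    for bout in bouts:
        theta += _bout_waveform(t, bout)

    # candidate touch onsets: protraction peaks while the pole is in reach
    s0, s1 = config.sample_epoch
    candidates = []
    for bout in bouts:
        peaks = _protraction_peaks(bout)
        peaks = peaks[(peaks >= s0) & (peaks < s1)]
        candidates.extend(np.round(peaks))
    candidates = np.unique(candidates)

    touches = []
    if len(candidates) and config.touches_per_trial_mean > 0:
        k = config.touch_rate_dispersion
        vigor = rng.gamma(k, 1.0 / k) if np.isfinite(k) and k > 0 else 1.0
        p_accept = min(
            1.0, vigor * config.touches_per_trial_mean / len(candidates)
        )
        accepted = candidates[rng.random(len(candidates)) < p_accept]
        last_off = -np.inf
        for onset in accepted:
            if onset <= last_off:
                continue  # overlapping contact: keep the earlier touch
            dur = max(5.0, rng.gamma(3.0, config.touch_duration_mean / 3.0))
            offset = min(onset + np.round(dur), n - 1)
            if offset <= onset:
                continue
            touches.append((onset, offset))
            last_off = offset

    kappa = np.zeros(n)
    for onset, offset in touches:
        peak = abs(rng.normal(config.kappa_peak_mean, config.kappa_peak_sd))
        kappa += _dkappa_profile(n, int(onset), int(offset), peak)

    lick_times = np.empty(0)
    if touches and rng.random() < config.lick_prob:
        rt = max(
            50.0, rng.normal(config.reaction_time_mean, config.reaction_time_sd)
        )
        first = touches[0][0] + np.round(rt)
        lick_times = first + np.array([0.0, 120.0, 260.0])
        lick_times = lick_times[lick_times < n]

    return WhiskerTrace(
        trial_id=trial_index,
        t=t,
        theta=theta,
        kappa=kappa,
        lick_times=lick_times,
        pole_in_reach=(float(s0), float(s1)),
        touch_intervals=np.array(touches, dtype=float).reshape(-1, 2),
    )


def _feature_prob(p0, touch, effects):
    """Per-touch spike probability after the log-linear feature link."""
    g = effects
    p = p0 * g.order_gain ** (touch.order - 1)
    if g.velocity_gain != 0.0 and np.isfinite(touch.pretouch_velocity):
        z = (touch.pretouch_velocity - g.velocity_ref[0]) / g.velocity_ref[1]
        p *= np.exp(g.velocity_gain * z)
    if g.dkappa_gain != 0.0:
        z = (touch.max_dkappa - g.dkappa_ref[0]) / g.dkappa_ref[1]
        p *= np.exp(g.dkappa_gain * z)
    return float(np.clip(p, 0.0, 1.0))


def generate_spikes(trace, touches, phase, config):
    """Draw one trial's spike train plus ground-truth labels.

    Parameters
    ----------
    trace : WhiskerTrace
    touches : list of TouchEvent for this trial (features drive the
        log-linear probability link when feature gains are nonzero)
    phase : PhaseSeries from ``kinematics.decompose_whisking(trace)``;
        the phase-coupled process reads its phase and whisking cycles
    config : GeneratorConfig

    Returns
    -------
    (SpikeTrain, dict) where the dict holds per-spike arrays
    ``times``, ``labels``, ``deleted`` and per-touch ``touch_probs``.
    """
    config.validate()
    if config.touch_latency < 0:
        raise ValueError("negative latency")
    rng = _rng(config, trace.trial_id, _SPIKE_STREAM)
    n = len(trace.t)
    times, labels = [], []

    # (i) touch-evoked spikes
    touch_probs = np.empty(len(touches))
    for k, touch in enumerate(touches):
        p0 = (
            config.touch_spike_prob_first
            if touch.is_first
            else config.touch_spike_prob_later
        )
        p = _feature_prob(p0, touch, config.feature_effects)
        touch_probs[k] = p
        if config.count_model == "binomial":
            count = int(rng.random() < p)
        else:
            count = int(rng.poisson(p))
        if count:
            delay = np.abs(rng.normal(0.0, config.touch_jitter, count))
            ts = touch.onset + config.touch_latency + delay
            times.extend(ts)
            labels.extend(["touch"] * count)

    # (ii) phase-coupled spikes during whisking cycles
    from .kinematics import whisking_cycles_mask

    mask = whisking_cycles_mask(phase)
    if mask.any() and (config.phase_A > 0 or config.phase_B > 0):
        rate = (
            config.phase_A * (1 + np.cos(phase.phi - config.phase_pref))
            + config.phase_B
        ) / 1000.0  # spk per ms
        counts = rng.poisson(np.where(mask, rate, 0.0))
        idx = np.nonzero(counts)[0]
        for i in idx:
            ts = trace.t[i] + rng.random(counts[i])
            times.extend(ts)
            labels.extend(["phase"] * counts[i])

    # (iii) homogeneous baseline throughout the trial
    if config.baseline_rate > 0:
        n_base = rng.poisson(config.baseline_rate * n / 1000.0)
        ts = rng.uniform(0, n, n_base)
        times.extend(ts)
        labels.extend(["baseline"] * n_base)

    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels, dtype=object)
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]

    # forward refractory deletion: keep the earlier spike
    deleted = np.zeros(len(times), dtype=bool)
    last = -np.inf
    for i, ts in enumerate(times):
        if ts - last <= config.refractory or ts <= last:
            deleted[i] = True
        else:
            last = ts
    train = SpikeTrain(trace.trial_id, times[~deleted])
    gt = {
        "times": times,
        "labels": labels,
        "deleted": deleted,
        "touch_probs": touch_probs,
    }
    return train, gt


def generate_session(
    config: GeneratorConfig, session_id: str = "synthetic"
) -> Session:
    """Generate a full multi-trial session with ground truth.

    Identical configs (including seed) give identical sessions.
    """
    from .kinematics import decompose_whisking, extract_touch_features

    config.validate()
    traces, spikes = [], []
    gt_times, gt_trials, gt_labels, gt_deleted, gt_probs = [], [], [], [], []
    for trial in range(config.n_trials):
        trace = generate_whisker_trace(config, trial)
        phase = decompose_whisking(trace)
        touches = extract_touch_features(trace)
        train, gt = generate_spikes(trace, touches, phase, config)
        traces.append(trace)
        spikes.append(train)
        gt_times.append(gt["times"])
        gt_trials.append(np.full(len(gt["times"]), trial))
        gt_labels.append(gt["labels"])
        gt_deleted.append(gt["deleted"])
        gt_probs.append(gt["touch_probs"])

    def _cat(parts, dtype=float):
        return (
            np.concatenate(parts)
            if parts
            else np.empty(0, dtype=dtype)
        )

    ground_truth = GroundTruth(
        trial_ids=_cat(gt_trials),
        spike_times=_cat(gt_times),
        labels=_cat(gt_labels, object),
        deleted=_cat(gt_deleted, bool),
        phase_pref=config.phase_pref,
        modulation_depth=config.true_modulation_depth,
        p_first=config.touch_spike_prob_first,
        p_later=config.touch_spike_prob_later,
        touch_probs=_cat(gt_probs),
    )
    return Session(
        session_id=session_id,
        traces=traces,
        spikes=spikes,
        meta={"config": config.to_dict()},
        ground_truth=ground_truth,
    )
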