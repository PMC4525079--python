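"""Whisker kinematics: phase decomposition, epochs, touch features.

The azimuthal angle theta is bandpassed at 6-60 Hz (4th-order Butterworth,
zero-phase) and decomposed with the Hilbert transform into instantaneous
phase and envelope. Phase is 0 at maximum protraction and +/-pi at maximum
retraction; whisk cycles are delimited at the -pi wrap.

Epoch rules (all thresholds exact, intervals half-open on the ms grid):

* whisking: whisk cycles whose bandpassed peak-to-peak amplitude exceeds
  2.5 deg;
* non-whisking: contiguous stretches of at least 100 ms with envelope
  below 1.25 deg and no touch or lick;
* exploration: whisking plus touch epochs within the pole-in-reach
  (sample) period, with prolonged touches (> 100 ms) removed;
* cycles during licking or within 70 ms after a touch, or with
  non-monotonic phase, are excluded from phase analyses.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from . import intervals as iv
from .types import EpochSet, PhaseSeries, TouchEvent, WhiskerTrace

__all__ = [
    "decompose_whisking",
    "whisking_cycles_mask",
    "segment_epochs",
    "extract_touch_features",
    "reaction_time",
]

BAND_HZ = (6.0, 60.0)
WHISKING_P2P_DEG = 2.5
NONWHISKING_ENV_DEG = 1.25
NONWHISKING_MIN_MS = 100.0
POSTTOUCH_EXCLUDE_MS = 70.0
PROLONGED_TOUCH_MS = 100.0
MIN_TRACE_MS = 170


def decompose_whisking(trace: WhiskerTrace) -> PhaseSeries:
    """Bandpass theta and extract phase, envelope, and whisk cycles."""
    theta = trace.theta
    if len(theta) < MIN_TRACE_MS:
        raise ValueError(
            f"trace too short for 6-60 Hz filtering ({len(theta)} ms, "
            f"need >= {MIN_TRACE_MS})"
        )
    if np.all(np.isnan(theta)):
        raise ValueError("theta is all NaN")
    b, a = butter(4, BAND_HZ, btype="bandpass", fs=1000.0)
    theta_band = filtfilt(b, a, theta)
    analytic = hilbert(theta_band)
    phi = np.angle(analytic)  # 0 at maximum protraction of the band signal
    amplitude = np.abs(analytic)

    # cycle boundaries at the -pi wrap (phase jumps from ~+pi to ~-pi)
    wraps = np.nonzero(np.diff(phi) < -np.pi)[0] + 1
    cycles, monotonic = [], []
    for s, e in zip(wraps[:-1], wraps[1:]):
        cycles.append((trace.t[s], trace.t[e]))
        monotonic.append(bool(np.all(np.diff(phi[s:e]) > -1e-9)))
    return PhaseSeries(
        trial_id=trace.trial_id,
        t=trace.t,
        theta_band=theta_band,
        phi=phi,
        amplitude=amplitude,
        cycles=np.array(cycles, dtype=float).reshape(-1, 2),
        cycle_monotonic=np.array(monotonic, dtype=bool),
    )


def _cycle_p2p(phase: PhaseSeries) -> np.ndarray:
    """Peak-to-peak bandpassed amplitude of each whisk cycle (deg)."""
    t0 = phase.t[0]
    p2p = np.empty(len(phase.cycles))
    for k, (s, e) in enumerate(phase.cycles):
        seg = phase.theta_band[int(s - t0): int(e - t0)]
        p2p[k] = seg.max() - seg.min() if len(seg) else 0.0
    return p2p


def whisking_cycles(phase: PhaseSeries) -> np.ndarray:
    """Cycles passing the 2.5 deg peak-to-peak whisking threshold."""
    if len(phase.cycles) == 0:
        return np.empty((0, 2))
    return phase.cycles[_cycle_p2p(phase) > WHISKING_P2P_DEG]


def whisking_cycles_mask(phase: PhaseSeries) -> np.ndarray:
    """Boolean 1 ms mask of samples inside whisking cycles."""
    return iv.contains(whisking_cycles(phase), phase.t)


def segment_epochs(trace: WhiskerTrace, phase: PhaseSeries) -> EpochSet:
    """Segment the trial into whisking / non-whisking / exploration epochs."""
    p2p = _cycle_p2p(phase) if len(phase.cycles) else np.empty(0)
    is_whisking_cycle = p2p > WHISKING_P2P_DEG
    # epoch classes are mutually exclusive: touch takes priority
    whisk = iv.subtract(
        iv.union(phase.cycles[is_whisking_cycle]), trace.touch_intervals
    )

    # non-whisking: quiet, >= 100 ms, no touch or lick, outside whisking
    # cycles (long bout-edge cycles can dip below the envelope threshold)
    quiet = phase.amplitude < NONWHISKING_ENV_DEG
    quiet &= ~iv.contains(trace.touch_intervals, trace.t)
    quiet &= ~iv.contains(phase.cycles[is_whisking_cycle], trace.t)
    for lick in trace.lick_times:
        j = int(lick - trace.t[0])
        if 0 <= j < len(quiet):
            quiet[j] = False
    non_whisking = []
    edges = np.flatnonzero(np.diff(np.r_[0, quiet.view(np.int8), 0]))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= NONWHISKING_MIN_MS:
            non_whisking.append((trace.t[0] + s, trace.t[0] + e))

    touch = trace.touch_intervals
    short_touch = (
        touch[(touch[:, 1] - touch[:, 0]) <= PROLONGED_TOUCH_MS]
        if len(touch)
        else touch
    )
    exploration = iv.intersect(
        iv.union(whisk, short_touch), [trace.pole_in_reach]
    )

    # cycles valid for phase analyses
    valid = []
    post_touch = (
        np.column_stack([touch[:, 0], touch[:, 1] + POSTTOUCH_EXCLUDE_MS])
        if len(touch)
        else np.empty((0, 2))
    )
    for k, (s, e) in enumerate(phase.cycles):
        if not is_whisking_cycle[k]:
            continue
        if not phase.cycle_monotonic[k]:
            continue
        if np.any((trace.lick_times >= s) & (trace.lick_times < e)):
            continue
        if len(post_touch) and iv.total_duration(
            iv.intersect([(s, e)], post_touch)
        ) > 0:
            continue
        valid.append((s, e))
    return EpochSet(
        whisking=whisk,
        non_whisking=non_whisking,
        touch=touch,
        exploration=exploration,
        phase_valid_cycles=valid,
    )


PRETOUCH_VELOCITY_MS = 5
DKAPPA_WINDOW_MS = 20
KAPPA_BASELINE_MS = 20


def extract_touch_features(trace: WhiskerTrace) -> list:
    """Per-touch order, inter-contact interval, velocity, and max dkappa.

    Pretouch velocity is the least-squares slope of theta over the 5 ms
    ending at onset (NaN when the trial starts mid-window). max_dkappa is
    the maximum |kappa - baseline| within 20 ms of onset, with baseline
    the median kappa over the 20 ms preceding onset.
    """
    t0 = int(trace.t[0])
    events = []
    prev_offset = None
    for k, (onset, offset) in enumerate(trace.touch_intervals):
        i = int(onset) - t0
        lo = i - PRETOUCH_VELOCITY_MS
        if lo >= 0:
            x = np.arange(PRETOUCH_VELOCITY_MS, dtype=float)
            y = trace.theta[lo:i]
            velocity = float(np.polyfit(x, y, 1)[0])
        else:
            velocity = float("nan")
        base_lo = max(0, i - KAPPA_BASELINE_MS)
        baseline = (
            float(np.median(trace.kappa[base_lo:i])) if i > base_lo else 0.0
        )
        win = trace.kappa[i: i + DKAPPA_WINDOW_MS]
        max_dk = float(np.max(np.abs(win - baseline))) if len(win) else 0.0
        ici = float("inf") if prev_offset is None else float(onset - prev_offset)
        events.append(
            TouchEvent(
                trial_id=trace.trial_id,
                onset=float(onset),
                offset=float(offset),
                order=k + 1,
                pretouch_velocity=velocity,
                max_dkappa=max_dk,
                ici=ici,
                is_first=(k == 0),
            )
        )
        prev_offset = offset
    return events


def reaction_time(trace: WhiskerTrace):
    """First lick time minus first touch onset (ms).

    Returns None when the trial has no lick or no touch. A lick preceding
    the first touch yields a negative value (left to the caller to filter).
    """
    if len(trace.lick_times) == 0 or len(trace.touch_intervals) == 0:
        return None
    return float(trace.lick_times.min() - trace.touch_intervals[0, 0])
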