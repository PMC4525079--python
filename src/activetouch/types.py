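"""Core data containers for whisker behavior and spike trains.

Conventions: time in milliseconds on a 1 kHz grid; intervals half-open
``[start, end)``; angles in degrees (azimuthal whisker angle theta),
curvature kappa in 1/mm (inverse radius of the osculating circle);
whisking phase phi in radians in [-pi, pi) with 0 at maximum protraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import as_intervals


@dataclass
class WhiskerTrace:
    """Per-trial 1 kHz kinematic time series with behavioral annotations.

    Attributes
    ----------
    trial_id : int
    t : ndarray, ms, strictly increasing with uniform 1 ms spacing
    theta : ndarray, azimuthal whisker angle in degrees
    kappa : ndarray, whisker curvature in 1/mm
    lick_times : ndarray, ms
    pole_in_reach : (start, end) ms, half-open; the sample epoch
    touch_intervals : (n, 2) ndarray of half-open touch periods, ms
    """

    trial_id: int
    t: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pole_in_reach: tuple = (0.0, 0.0)
    touch_intervals: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        self.touch_intervals = as_intervals(self.touch_intervals)
        if len(self.t) != len(self.theta) or len(self.t) != len(self.kappa):
            raise ValueError("t, theta, kappa must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0):
                raise ValueError("time grid must have uniform 1 ms spacing")
        if len(self.touch_intervals) > 1:
            if np.any(
                self.touch_intervals[1:, 0] < self.touch_intervals[:-1, 1]
            ):
                raise ValueError("touch intervals overlap")

    @property
    def duration(self) -> float:
        return float(len(self.t))


@dataclass
class PhaseSeries:
    """Bandpassed whisker angle with instantaneous phase and envelope.

    ``cycles`` are whisk cycles delimited at the -pi phase wrap (retraction
    extreme); ``cycle_monotonic`` flags cycles whose unwrapped phase is
    non-decreasing throughout.
    """

    trial_id: int
    t: np.ndarray
    theta_band: np.ndarray
    phi: np.ndarray
    amplitude: np.ndarray
    cycles: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    cycle_monotonic: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=bool)
    )

    def __post_init__(self):
        self.cycles = as_intervals(self.cycles)
        self.cycle_monotonic = np.asarray(self.cycle_monotonic, dtype=bool)


@dataclass
class EpochSet:
    """Behavioral epoch segmentation for one trial.

    whisking: whisk cycles with peak-to-peak amplitude > 2.5 deg.
    non_whisking: >= 100 ms stretches with envelope < 1.25 deg, no touch
        or lick.
    touch: the trace's touch intervals.
    exploration: (whisking union touch) restricted to the sample epoch,
        with prolonged touches (> 100 ms) removed.
    phase_valid_cycles: whisking cycles usable for phase analyses (no lick
        within the cycle, not within 70 ms after a touch, monotonic phase).
    """

    whisking: np.ndarray
    non_whisking: np.ndarray
    touch: np.ndarray
    exploration: np.ndarray
    phase_valid_cycles: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )

    def __post_init__(self):
        for name in (
            "whisking",
            "non_whisking",
            "touch",
            "exploration",
            "phase_valid_cycles",
        ):
            setattr(self, name, as_intervals(getattr(self, name)))


@dataclass
class TouchEvent:
    """One whisker-pole contact with derived stimulus features."""

    trial_id: int
    onset: float
    offset: float
    order: int  # 1-based within trial
    pretouch_velocity: float  # deg/ms; NaN when undefined
    max_dkappa: float  # max |kappa - baseline| in [onset, onset+20) ms
    ici: float  # ms since previous touch offset; inf for first
    is_first: bool

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class SpikeTrain:
    """Sorted spike times for one neuron in one trial (ms)."""

    trial_id: int
    spike_times: np.ndarray

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class GroundTruth:
    """Generative labels and parameters stored beside a synthetic session.

    ``labels`` maps every generated spike (trial_id, spike_time_ms) to its
    source process: 'touch', 'phase', or 'baseline'. Spikes removed by the
    refractory rule are retained with deleted=True so labels partition all
    generated spikes. The stored modulation depth is the effective depth of
    the whisking-epoch rate, A/(A+B+r0): the homogeneous baseline process
    runs throughout the trial and contributes a uniform component that any
    tuning fit necessarily absorbs.
    """

    trial_ids: np.ndarray
    spike_times: np.ndarray
    labels: np.ndarray  # 'touch' | 'phase' | 'baseline'
    deleted: np.ndarray  # refractory deletions
    phase_pref: float
    modulation_depth: float
    p_first: float
    p_later: float
    touch_probs: np.ndarray  # per generated touch, after feature effects

    def touch_fraction(self, mask=None) -> float:
        """Fraction of (kept) spikes that are touch-evoked."""
        keep = ~self.deleted
        if mask is not None:
            keep = keep & mask
        if keep.sum() == 0:
            return float("nan")
        return float(np.mean(self.labels[keep] == "touch"))


@dataclass
class Session:
    """One synthetic or loaded recording session: one neuron, many trials."""

    session_id: str
    traces: list  # list[WhiskerTrace]
    spikes: list  # list[SpikeTrain], parallel to traces
    meta: dict = field(default_factory=dict)
    ground_truth: GroundTruth | None = None

    def __post_init__(self):
        if len(self.traces) != len(self.spikes):
            raise ValueError("one spike train per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.traces)
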