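"""Attribution of exploration-epoch spikes to touch onset and whisking phase.

Each spike during active exploration is indexed by the time elapsed since
the closest preceding touch onset. The cumulative curve y_ton(t_i) (spikes
within t_i of an onset, windows expanding 1 ms at a time from the cell's
response latency) rises steeply for touch-coupled cells and then levels
off. The cutoff t_on is the first window size at which the curve's slope
drops below chance, where chance is the 95th percentile of the slopes of
1000 surrogate curves built by redistributing the spike times uniformly
over the exploration epochs. Cumulative curves (empirical and surrogate)
are smoothed with a degree-11 polynomial before differentiation. The
touch-coupled fraction is y_ton(t_on) divided by the total number of
exploration spikes. Spikes not attributed to touch are then indexed by the
time to the preferred whisking phase of their own whisk cycle (windows
truncated at cycle margins) and the same chance rule yields the
touch-or-phase fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv

__all__ = [
    "AttributionCurves",
    "AttributionResult",
    "touch_coupled_fraction",
    "phase_coupled_fraction",
]

POLY_DEGREE = 11
DEFAULT_N_SHUFFLE = 1000
TOUCH_GRID_MS = 100
PHASE_GRID_MS = 50


@dataclass
class AttributionCurves:
    """Cumulative attribution curve with its shuffle chance band."""

    t_grid: np.ndarray  # window sizes, ms
    y: np.ndarray  # cumulative spike counts at each window size
    emp_slope: np.ndarray  # smoothed empirical slope
    chance_slope: np.ndarray  # 95th percentile smoothed surrogate slope
    surrogate_y95: np.ndarray  # 95th percentile of raw surrogate curves
    cutoff: float  # t_on (or t_w), ms
    cutoff_index: int
    n_spikes: int  # total exploration spikes


@dataclass
class AttributionResult:
    frac_touch: float
    frac_touch_or_phase: float
    frac_phase_only: float
    occupancy_touch: float
    occupancy_total: float
    t_on: float
    t_w: float | None = None
    chance_frac_touch: float = float("nan")
    n_exploration_spikes: int = 0
    touch_windows: list = field(default_factory=list)


def _smoothed_slopes(x_scaled, Y):
    """Degree-11 polynomial fit of each column of Y, then its derivative.

    The fit domain is scaled to [-1, 1] for numerical stability; slopes are
    returned in scaled units, identical for empirical and surrogate curves
    so the comparison is unaffected.
    """
    deg = min(POLY_DEGREE, len(x_scaled) - 1)
    coef = np.polyfit(x_scaled, Y, deg)  # (deg+1, K), highest power first
    powers = np.arange(deg, 0, -1)
    dcoef = coef[:-1] * powers[:, None]
    V = np.vander(x_scaled, deg)
    return V @ dcoef  # (n_points, K)


def _cumulative_counts(dts, latency, width, n_rows):
    """Row-wise cumulative histograms of dt values on a 1 ms grid.

    dts: (n_rows, m) times since the reference event; counts spikes with
    latency <= dt < latency + i for i = 1..width.
    """
    rel = dts - latency
    valid = (rel >= 0) & (rel < width)
    rows = np.broadcast_to(
        np.arange(n_rows)[:, None], dts.shape
    )[valid]
    bins = rel[valid].astype(int)
    counts = np.bincount(rows * width + bins, minlength=n_rows * width)
    return np.cumsum(counts.reshape(n_rows, width), axis=1)


def _dt_since_onset(times, onsets):
    """Time since the closest preceding touch onset (inf if none)."""
    times = np.asarray(times, dtype=float)
    if len(onsets) == 0:
        return np.full(times.shape, np.inf)
    idx = np.searchsorted(onsets, times.ravel(), side="right") - 1
    dt = np.full(times.size, np.inf)
    ok = idx >= 0
    dt[ok] = times.ravel()[ok] - onsets[idx[ok]]
    return dt.reshape(times.shape)


def _find_cutoff(t_grid, emp_slope, chance_slope):
    below = emp_slope < chance_slope
    idx = int(np.argmax(below)) if below.any() else len(t_grid) - 1
    return float(t_grid[idx]), idx


def touch_coupled_fraction(
    spikes,
    touches,
    latency,
    epochs,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int = 0,
    max_window: float = TOUCH_GRID_MS,
):
    """Estimate the touch-coupled spike fraction for one cell.

    Parameters
    ----------
    spikes, epochs : per-trial lists of SpikeTrain and EpochSet
    touches : list of TouchEvent across trials
    latency : ms, the cell's response onset latency (windows open there)
    n_shuffle : surrogate repetitions for the chance band
    seed : seed of the shuffle generator

    Returns
    -------
    (AttributionCurves, AttributionResult) — the result's phase fields are
    filled by :func:`phase_coupled_fraction`.
    """
    rng = np.random.default_rng(seed)
    width = int(max_window)
    t_grid = latency + 1.0 + np.arange(width)

    onsets_by_trial = {}
    for tc in touches:
        onsets_by_trial.setdefault(tc.trial_id, []).append(tc.onset)
    onsets_by_trial = {
        k: np.sort(v) for k, v in onsets_by_trial.items()
    }

    emp = np.zeros((1, width), dtype=np.int64)
    sur = np.zeros((n_shuffle, width), dtype=np.int64)
    n_expl = 0
    expl_duration = 0.0
    for st, ep in zip(spikes, epochs):
        expl = ep.exploration
        expl_duration += iv.total_duration(expl)
        sp = st.spike_times[iv.contains(expl, st.spike_times)]
        if len(sp) == 0:
            continue
        n_expl += len(sp)
        onsets = onsets_by_trial.get(st.trial_id, np.empty(0))
        emp += _cumulative_counts(
            _dt_since_onset(sp[None, :], onsets), latency, width, 1
        )
        shuf = np.sort(
            _sample_in_intervals(expl, (n_shuffle, len(sp)), rng), axis=1
        )
        sur += _cumulative_counts(
            _dt_since_onset(shuf, onsets), latency, width, n_shuffle
        )

    if n_expl == 0:
        curves = AttributionCurves(
            t_grid, emp[0], np.zeros(width), np.zeros(width),
            np.zeros(width), float("nan"), 0, 0,
        )
        result = AttributionResult(
            float("nan"), float("nan"), float("nan"), 0.0, 0.0,
            float("nan"), n_exploration_spikes=0,
        )
        return curves, result

    if len(touches) == 0:
        curves = AttributionCurves(
            t_grid, emp[0], np.zeros(width), np.zeros(width),
            np.zeros(width), latency, 0, n_expl,
        )
        result = AttributionResult(
            0.0, 0.0, 0.0, 0.0, 0.0, latency,
            n_exploration_spikes=n_expl,
            touch_windows=[np.empty((0, 2)) for _ in spikes],
        )
        return curves, result

    x = np.linspace(-1.0, 1.0, width)
    emp_slope = _smoothed_slopes(x, emp.T.astype(float))[:, 0]
    chance_slope = np.percentile(
        _smoothed_slopes(x, sur.T.astype(float)), 95, axis=1
    )
    t_on, idx = _find_cutoff(t_grid, emp_slope, chance_slope)
    y95 = np.percentile(sur, 95, axis=0)

    frac_touch = emp[0, idx] / n_expl
    windows = []
    occ = 0.0
    for st, ep in zip(spikes, epochs):
        onsets = onsets_by_trial.get(st.trial_id, np.empty(0))
        if len(onsets) == 0:
            windows.append(np.empty((0, 2)))
            continue
        w = np.column_stack([onsets + latency, onsets + t_on])
        w = iv.intersect(w, ep.exploration)
        windows.append(w)
        occ += iv.total_duration(w)
    occupancy = occ / expl_duration if expl_duration > 0 else float("nan")

    curves = AttributionCurves(
        t_grid, emp[0], emp_slope, chance_slope, y95, t_on, idx, n_expl
    )
    result = AttributionResult(
        frac_touch=float(frac_touch),
        frac_touch_or_phase=float(frac_touch),
        frac_phase_only=0.0,
        occupancy_touch=float(occupancy),
        occupancy_total=float(occupancy),
        t_on=t_on,
        chance_frac_touch=float(y95[idx] / n_expl),
        n_exploration_spikes=n_expl,
        touch_windows=windows,
    )
    return curves, result


def _sample_in_intervals(intervals, shape, rng):
    iv_u = iv.union(intervals)
    lengths = iv_u[:, 1] - iv_u[:, 0]
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    u = rng.random(shape) * edges[-1]
    k = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(iv_u) - 1)
    return iv_u[k, 0] + (u - edges[k])


def _preferred_phase_events(phase, cycles, phase_pref):
    """Per-cycle time of closest approach to the preferred phase."""
    t0 = phase.t[0]
    events = []
    for s, e in cycles:
        sl = slice(int(s - t0), int(e - t0))
        seg = np.cos(phase.phi[sl] - phase_pref)
        if len(seg) == 0:
            continue
        events.append((s + float(np.argmax(seg)), s, e))
    return events


def _dt_to_phase_event(times, events):
    """|time - preferred-phase event| within the spike's own cycle."""
    times = np.asarray(times, dtype=float)
    dt = np.full(times.shape, np.inf)
    for c, s, e in events:
        in_cyc = (times >= s) & (times < e)
        dt[in_cyc] = np.abs(times[in_cyc] - c)
    return dt


def phase_coupled_fraction(
    curves,
    result,
    spikes,
    phases,
    epochs,
    phase_pref: float,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    seed: int = 1,
    max_window: float = PHASE_GRID_MS,
) -> AttributionResult:
    """Attribute residual (non-touch) spikes to the preferred whisking phase.

    Residual spikes are those exploration spikes outside the touch windows
    found by :func:`touch_coupled_fraction`. Each is indexed by its distance
    to the preferred-phase time of its own whisk cycle (cycles with
    non-monotonic phase included; windows truncated at cycle margins). The
    cutoff t_w uses the same smoothed-surrogate 95th-percentile slope rule,
    with surrogates drawn uniformly over exploration minus touch windows.
    """
    rng = np.random.default_rng(seed)
    n_expl = result.n_exploration_spikes
    if n_expl == 0 or not np.isfinite(result.t_on):
        return result

    from .kinematics import whisking_cycles

    width = int(max_window)
    t_grid = 1.0 + np.arange(width)
    emp = np.zeros((1, width), dtype=np.int64)
    sur = np.zeros((n_shuffle, width), dtype=np.int64)
    any_cycles = False
    win_time = 0.0
    for st, ph, ep, w in zip(spikes, phases, epochs, result.touch_windows):
        cycles = whisking_cycles(ph)
        support = iv.subtract(ep.exploration, w)
        sp = st.spike_times[iv.contains(ep.exploration, st.spike_times)]
        sp = sp[~iv.contains(w, sp)]
        if len(cycles) == 0 or iv.total_duration(support) == 0:
            continue
        any_cycles = True
        events = _preferred_phase_events(ph, cycles, phase_pref)
        if len(sp):
            emp += _cumulative_counts(
                _dt_to_phase_event(sp[None, :], events), 0.0, width, 1
            )
            shuf = _sample_in_intervals(support, (n_shuffle, len(sp)), rng)
            sur += _cumulative_counts(
                _dt_to_phase_event(shuf, events), 0.0, width, n_shuffle
            )

    if not any_cycles or emp.sum() == 0:
        return result

    x = np.linspace(-1.0, 1.0, width)
    emp_slope = _smoothed_slopes(x, emp.T.astype(float))[:, 0]
    chance_slope = np.percentile(
        _smoothed_slopes(x, sur.T.astype(float)), 95, axis=1
    )
    t_w, idx = _find_cutoff(t_grid, emp_slope, chance_slope)

    # occupancy of the phase windows (truncated at cycle margins),
    # outside the touch windows
    for st, ph, ep, w in zip(spikes, phases, epochs, result.touch_windows):
        cycles = whisking_cycles(ph)
        if len(cycles) == 0:
            continue
        events = _preferred_phase_events(ph, cycles, phase_pref)
        pw = [
            (max(c - t_w, s), min(c + t_w, e)) for c, s, e in events
        ]
        pw = iv.subtract(iv.intersect(pw, ep.exploration), w)
        win_time += iv.total_duration(pw)

    touch_spikes = curves.y[curves.cutoff_index]
    frac_both = (touch_spikes + emp[0, idx]) / n_expl
    expl_duration = sum(iv.total_duration(ep.exploration) for ep in epochs)
    result.t_w = t_w
    result.frac_touch_or_phase = float(min(frac_both, 1.0))
    result.frac_phase_only = float(
        result.frac_touch_or_phase - result.frac_touch
    )
    result.occupancy_total = float(
        result.occupancy_touch
        + (win_time / expl_duration if expl_duration > 0 else 0.0)
    )
    return result
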