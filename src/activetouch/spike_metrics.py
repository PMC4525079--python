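"""Single-neuron spike metrics: touch-aligned histograms, onset latency,
phase tuning, and epoch firing rates.

The phase-tuning model is ``rate(phi) = A [1 + cos(phi - phi_pref)] + B``
with A, B >= 0, fitted by nonlinear least squares on a 12-bin
occupancy-normalized phase histogram; the modulation depth is A/(A+B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import intervals as iv
from .types import EpochSet, PhaseSeries, SpikeTrain

__all__ = [
    "PSTH",
    "PhaseTuningFit",
    "touch_aligned_psth",
    "onset_latency",
    "phase_tuning",
    "epoch_rates",
]


@dataclass
class PSTH:
    """Event-aligned spike rate histogram.

    ``rate[k]`` is spikes/s in bin ``[edges[k], edges[k+1])`` ms relative
    to the alignment event; ``counts`` holds the raw summed spike counts so
    that sum(counts) == rate . bin_width . n_events (mass conservation).
    """

    alignment: str
    bin_width: float
    edges: np.ndarray
    rate: np.ndarray
    counts: np.ndarray
    n_events: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def touch_aligned_psth(
    spikes,
    touches,
    alignment: str = "all_touch",
    bin_width: float = 1.0,
    window=(-50.0, 50.0),
) -> PSTH:
    """Peri-contact time histogram aligned to touch onsets.

    Parameters
    ----------
    spikes : list of SpikeTrain (one per trial)
    touches : list of TouchEvent across trials
    alignment : 'all_touch', 'first_touch', or 'later_touch'
    bin_width : ms
    window : (pre, post) ms relative to onset
    """
    if alignment == "first_touch":
        touches = [tc for tc in touches if tc.is_first]
    elif alignment == "later_touch":
        touches = [tc for tc in touches if not tc.is_first]
    elif alignment != "all_touch":
        raise ValueError(f"unknown alignment {alignment!r}")
    if len(touches) == 0:
        raise ValueError("no alignment events")
    by_trial = {st.trial_id: st.spike_times for st in spikes}
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    for tc in touches:
        ts = by_trial.get(tc.trial_id)
        if ts is None or len(ts) == 0:
            continue
        rel = ts - tc.onset
        rel = rel[(rel >= window[0]) & (rel < window[1])]
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(touches) * bin_width / 1000.0)
    return PSTH(
        alignment=alignment,
        bin_width=bin_width,
        edges=edges,
        rate=rate,
        counts=counts,
        n_events=len(touches),
    )


LATENCY_SEARCH_MS = 50.0


def onset_latency(psth: PSTH):
    """Response onset: first post-onset bin exceeding baseline + 2 s.d.

    Baseline is the -50 to 0 ms pre-onset stretch of the PSTH. The onset
    bin must strictly exceed mean + 2 s.d. and the rise must be sustained:
    at least 2 spikes in the onset bin and at least 1 in the following
    bin. (With sparse baselines the 2-s.d. threshold can fall below a
    single spike count, so an unsustained stray spike is not a response
    onset.) Silent-baseline cells (mean and s.d. both 0) trigger on their
    first spike. Returns the bin start in ms, or None when never exceeded
    (latency cannot be determined for unresponsive cells).
    """
    if psth.bin_width != 1.0:
        raise ValueError("onset latency requires 1 ms bins")
    if psth.edges[0] > -50.0 or psth.edges[-1] < LATENCY_SEARCH_MS:
        raise ValueError("PSTH must span at least [-50, +50] ms")
    pre = (psth.edges[:-1] >= -50.0) & (psth.edges[:-1] < 0.0)
    mu, sd = psth.rate[pre].mean(), psth.rate[pre].std()
    post = np.nonzero(
        (psth.edges[:-1] >= 0.0) & (psth.edges[:-1] < LATENCY_SEARCH_MS)
    )[0]
    silent = mu == 0 and sd == 0
    for k in post:
        if psth.rate[k] <= mu + 2 * sd:
            continue
        if silent:
            if psth.counts[k] >= 1:
                return float(psth.edges[k])
            continue
        sustained = k + 1 >= len(psth.counts) or psth.counts[k + 1] >= 1
        if psth.counts[k] >= 2 and sustained:
            return float(psth.edges[k])
    return None


@dataclass
class PhaseTuningFit:
    """Cosine fit A[1+cos(phi - phase_pref)] + B to the phase histogram."""

    A: float
    B: float
    phase_pref: float
    modulation_depth: float
    bin_centers: np.ndarray
    rates: np.ndarray  # spikes/s, occupancy-normalized
    occupancy_s: np.ndarray  # seconds spent per phase bin
    n_spikes: int

    def predict(self, phi) -> np.ndarray:
        return self.A * (1 + np.cos(np.asarray(phi) - self.phase_pref)) + self.B


N_PHASE_BINS = 12


def _spike_phases(spikes, phases, cycles_per_trial):
    """Map spikes inside valid cycles to phase by linear interpolation."""
    out = []
    for st, ph, cycles in zip(spikes, phases, cycles_per_trial):
        if len(cycles) == 0 or len(st.spike_times) == 0:
            continue
        t0 = ph.t[0]
        for s, e in cycles:
            in_cyc = st.spike_times[
                (st.spike_times >= s) & (st.spike_times < e)
            ]
            if len(in_cyc) == 0:
                continue
            sl = slice(int(s - t0), int(e - t0))
            # phase is monotone within a valid cycle: direct interpolation
            out.extend(np.interp(in_cyc, ph.t[sl], ph.phi[sl]))
    return np.asarray(out)


def _fit_cosine(centers, rates, weights=None):
    """Constrained least squares with a 12-start grid over phase_pref."""
    ok = np.isfinite(rates)
    c, y = centers[ok], rates[ok]
    w = np.ones_like(y) if weights is None else weights[ok]

    def resid(x):
        A, B, p = x
        return np.sqrt(w) * (A * (1 + np.cos(c - p)) + B - y)

    a0 = max((y.max() - y.min()) / 2.0, 1e-6)
    b0 = max(y.min(), 0.0)
    best = None
    for p0 in np.linspace(-np.pi, np.pi, N_PHASE_BINS, endpoint=False):
        res = least_squares(
            resid,
            x0=[a0, b0, p0],
            bounds=([0, 0, -2 * np.pi], [np.inf, np.inf, 2 * np.pi]),
        )
        if best is None or res.cost < best.cost:
            best = res
    A, B, p = best.x
    p = float(np.angle(np.exp(1j * p)))
    return float(A), float(B), p


def phase_tuning(spikes, phases, epochs) -> PhaseTuningFit:
    """Occupancy-normalized 12-bin phase histogram with cosine fit.

    Parameters
    ----------
    spikes, phases, epochs : per-trial lists of SpikeTrain, PhaseSeries,
        EpochSet. Only phase-valid whisking cycles contribute (monotonic
        phase, no lick, not within 70 ms after touch).
    """
    if isinstance(spikes, SpikeTrain):
        spikes, phases, epochs = [spikes], [phases], [epochs]
    cycles = [ep.phase_valid_cycles for ep in epochs]
    edges = np.linspace(-np.pi, np.pi, N_PHASE_BINS + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    occupancy = np.zeros(N_PHASE_BINS)
    for ph, cyc in zip(phases, cycles):
        if len(cyc) == 0:
            continue
        mask = iv.contains(cyc, ph.t)
        occupancy += np.histogram(ph.phi[mask], bins=edges)[0] / 1000.0
    if occupancy.sum() == 0:
        raise ValueError("no valid whisking time for phase tuning")

    spike_phi = _spike_phases(spikes, phases, cycles)
    counts = np.histogram(spike_phi, bins=edges)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occupancy > 0, counts / occupancy, np.nan)

    if counts.sum() == 0:
        return PhaseTuningFit(
            0.0, 0.0, float("nan"), float("nan"), centers, rates,
            occupancy, 0,
        )
    # occupancy weights: bin rate variance scales as 1/occupancy
    A, B, pref = _fit_cosine(centers, rates, weights=occupancy)
    depth = A / (A + B) if A + B > 0 else float("nan")
    return PhaseTuningFit(
        A, B, pref, depth, centers, rates, occupancy, int(counts.sum())
    )


def epoch_rates(spikes, epochs, touches=None, latency=8.0, window=30.0):
    """Whisking / non-whisking rates, minimum ISI, per-touch counts.

    Rates are spike counts within the epoch class divided by the summed
    epoch duration. ``spikes_per_touch`` counts spikes in
    ``[onset + latency, onset + latency + window)`` per touch (the
    cell-specific attribution window is a better choice when available).
    Returns a dict; undefined quantities are NaN.
    """
    if isinstance(spikes, SpikeTrain):
        spikes, epochs = [spikes], [epochs]
    out = {}
    for name in ("whisking", "non_whisking"):
        dur = sum(iv.total_duration(getattr(ep, name)) for ep in epochs)
        cnt = sum(
            int(iv.contains(getattr(ep, name), st.spike_times).sum())
            for st, ep in zip(spikes, epochs)
        )
        out[f"{name}_rate"] = cnt / (dur / 1000.0) if dur > 0 else float("nan")
    isis = [np.diff(st.spike_times) for st in spikes if len(st.spike_times) > 1]
    out["min_isi"] = (
        float(min(i.min() for i in isis)) if isis else float("nan")
    )
    if touches is not None:
        by_trial = {st.trial_id: st.spike_times for st in spikes}
        counts = []
        for tc in touches:
            ts = by_trial.get(tc.trial_id, np.empty(0))
            lo = tc.onset + latency
            counts.append(int(np.sum((ts >= lo) & (ts < lo + window))))
        out["spikes_per_touch"] = np.asarray(counts)
    return out
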