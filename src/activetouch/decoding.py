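"""Resampling-based population decoding of touch and whisking phase.

Simulated populations are assembled by sampling neurons with replacement
from a recorded (or synthetic) pool and resampling each neuron's
touch-aligned responses with replacement, under the assumption of
independent neural responses. Three read-outs:

* touch presence: at each time point a one-dimensional threshold on the
  pooled causally-integrated count (w = 10 ms), trained on half the data
  (maximizing balanced accuracy) and evaluated on the held-out half;
* time since touch: a multinomial naive Bayes classifier (add-one
  smoothing) over per-neuron integrated counts, one class per time bin,
  scored by RMS time error with bootstrap bounds;
* whisking phase: a Poisson naive Bayes two-class discriminator on
  120-bin phase tuning curves with preferred phases uniformized by random
  circular shifts; performance is the smallest phase difference reaching
  76% correct (the d' = 1 criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.naive_bayes import MultinomialNB

from . import intervals as iv

__all__ = [
    "DecoderResult",
    "build_touch_responses",
    "build_nontouch_responses",
    "decode_touch_presence",
    "decode_touch_time",
    "decode_phase",
    "dprime_to_pc",
    "pc_to_dprime",
]

RESPONSE_WINDOW = (-30.0, 50.0)
INTEGRATION_MS = 10.0
N_RESAMPLE = 1000
NONTOUCH_BUFFER_MS = 100.0
N_PHASE_BINS = 120
PC_CRITERION = 0.76


def dprime_to_pc(d_prime: float) -> float:
    """Two-alternative proportion correct for sensitivity d'.

    Equal-variance Gaussian model: Phi(d'/sqrt(2)); d' = 1 gives 0.76.
    """
    if d_prime < 0:
        raise ValueError("d_prime must be non-negative")
    return float(norm.cdf(d_prime / np.sqrt(2.0)))


def pc_to_dprime(pc: float) -> float:
    """Inverse of :func:`dprime_to_pc`."""
    if not 0.5 <= pc < 1.0:
        raise ValueError("pc must be in [0.5, 1)")
    return float(np.sqrt(2.0) * norm.ppf(pc))


@dataclass
class DecoderResult:
    task: str  # 'presence' | 'time' | 'phase'
    n_grid: np.ndarray
    performance: np.ndarray  # median over runs
    lo: np.ndarray
    hi: np.ndarray
    details: dict = field(default_factory=dict)


def _causal_counts(spike_times, origin, t_grid, window=INTEGRATION_MS):
    """Counts in (origin + t - window, origin + t] for each t in t_grid."""
    hi = np.searchsorted(spike_times, origin + t_grid, side="right")
    lo = np.searchsorted(spike_times, origin + t_grid - window, side="right")
    return hi - lo


def build_touch_responses(
    spikes, touches, window=RESPONSE_WINDOW, w=INTEGRATION_MS
):
    """Per-touch causally integrated count segments for one neuron.

    Touches followed by a second touch within 50 ms post-onset are
    excluded. Returns (counts, t_grid) with counts of shape
    (n_touches_kept, len(t_grid)), t_grid = window[0]..window[1] in 1 ms
    steps.
    """
    by_trial = {st.trial_id: st.spike_times for st in spikes}
    onsets_by_trial = {}
    for tc in touches:
        onsets_by_trial.setdefault(tc.trial_id, []).append(tc.onset)
    t_grid = np.arange(window[0], window[1] + 1.0)
    rows = []
    for tc in touches:
        others = [
            o
            for o in onsets_by_trial[tc.trial_id]
            if tc.onset < o <= tc.onset + 50.0
        ]
        if others:
            continue
        ts = by_trial.get(tc.trial_id, np.empty(0))
        rows.append(_causal_counts(ts, tc.onset, t_grid, w))
    counts = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(t_grid)), dtype=int)
    )
    return counts, t_grid


def build_nontouch_responses(
    spikes,
    epochs,
    touches,
    n_samples: int,
    seed: int = 0,
    w=INTEGRATION_MS,
    buffer_ms=NONTOUCH_BUFFER_MS,
):
    """Integrated counts at random times in exploration away from touches.

    Sampling support is exploration minus a ``buffer_ms`` margin around
    every touch. Returns an array of ``n_samples`` counts.
    """
    rng = np.random.default_rng(seed)
    supports, trains = [], []
    for st, ep in zip(spikes, epochs):
        tiv = [
            (tc.onset - buffer_ms, tc.offset + buffer_ms)
            for tc in touches
            if tc.trial_id == st.trial_id
        ]
        sup = iv.subtract(ep.exploration, tiv)
        if iv.total_duration(sup) > 0:
            supports.append(sup)
            trains.append(st.spike_times)
    if not supports:
        raise ValueError("no touch-free exploration time to sample")
    durs = np.array([iv.total_duration(s) for s in supports])
    pick = rng.choice(len(supports), size=n_samples, p=durs / durs.sum())
    out = np.empty(n_samples, dtype=int)
    for i, k in enumerate(pick):
        t = iv.sample_uniform(supports[k], 1, rng)[0]
        out[i] = _causal_counts(trains[k], t, np.array([0.0]), w)[0]
    return out


def _resample(rows, n, rng):
    return rows[rng.integers(0, len(rows), n)]


def decode_touch_presence(
    touch_counts_by_neuron,
    nontouch_counts_by_neuron,
    n_grid,
    t_grid=None,
    n_draws: int = N_RESAMPLE,
    n_runs: int = 10,
    seed: int = 0,
) -> DecoderResult:
    """Touch detection by thresholding the pooled integrated count.

    Parameters
    ----------
    touch_counts_by_neuron : list of (n_touches_i, T) arrays (or
        (n_touches_i,) arrays for a single time point)
    nontouch_counts_by_neuron : list of (n_i,) count arrays
    n_grid : population sizes; neurons are sampled with replacement, so
        sizes beyond the pool are valid
    n_draws : resampled events per neuron and class
    n_runs : repetitions over random neuron/event draws (95% bounds)

    Balanced accuracy on the held-out half, maximized over time points,
    is the reported performance.
    """
    rng = np.random.default_rng(seed)
    pool = [np.atleast_2d(c.T).T for c in touch_counts_by_neuron]
    T = pool[0].shape[1]
    n_grid = np.asarray(n_grid, dtype=int)
    perf = np.empty((n_runs, len(n_grid)))
    for r in range(n_runs):
        for a, n in enumerate(n_grid):
            members = rng.integers(0, len(pool), n)
            pooled_touch = np.zeros((n_draws, T))
            pooled_non = np.zeros(n_draws)
            for i in members:
                pooled_touch += _resample(pool[i], n_draws, rng)
                pooled_non += _resample(
                    nontouch_counts_by_neuron[i], n_draws, rng
                )
            half = n_draws // 2
            best = 0.0
            for tj in range(T):
                xt, xn = pooled_touch[:, tj], pooled_non
                thr_grid = np.unique(
                    np.concatenate([xt[:half], xn[:half]])
                )
                acc_tr = [
                    0.5 * ((xt[:half] >= th).mean() + (xn[:half] < th).mean())
                    for th in thr_grid
                ]
                th = thr_grid[int(np.argmax(acc_tr))]
                acc = 0.5 * (
                    (xt[half:] >= th).mean() + (xn[half:] < th).mean()
                )
                best = max(best, acc)
            perf[r, a] = best
    return DecoderResult(
        task="presence",
        n_grid=n_grid,
        performance=np.median(perf, axis=0),
        lo=np.percentile(perf, 2.5, axis=0),
        hi=np.percentile(perf, 97.5, axis=0),
        details={"runs": perf},
    )


def decode_touch_time(
    touch_counts_by_neuron,
    t_grid,
    n_neurons: int = 200,
    class_window=(0.0, 50.0),
    n_train: int = 40,
    n_test: int = 20,
    n_runs: int = 100,
    seed: int = 0,
) -> DecoderResult:
    """Multinomial naive Bayes decoding of time elapsed since touch onset.

    Classes are the 1 ms time points in ``class_window``; features are the
    per-neuron 10 ms causally integrated counts. RMS time error per class
    and overall, with bootstrap bounds over ``n_runs`` runs.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid)
    cls_idx = np.nonzero(
        (t_grid >= class_window[0]) & (t_grid <= class_window[1])
    )[0]
    classes = t_grid[cls_idx]
    C = len(classes)
    rms_runs = np.empty(n_runs)
    rms_by_class = np.zeros((n_runs, C))
    for r in range(n_runs):
        members = rng.integers(
            0, len(touch_counts_by_neuron), n_neurons
        )
        mats = [touch_counts_by_neuron[i] for i in members]

        def draw(n_per_class):
            X = np.empty((C * n_per_class, n_neurons), dtype=int)
            y = np.repeat(np.arange(C), n_per_class)
            for ci, tc_i in enumerate(cls_idx):
                for k in range(n_per_class):
                    row = C * 0 + ci * n_per_class + k
                    for ni, m in enumerate(mats):
                        j = rng.integers(0, len(m))
                        X[row, ni] = m[j, tc_i]
            return X, y

        Xtr, ytr = draw(n_train)
        Xte, yte = draw(n_test)
        clf = MultinomialNB(alpha=1.0)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        err = classes[pred] - classes[yte]
        rms_runs[r] = np.sqrt(np.mean(err**2))
        for ci in range(C):
            sel = yte == ci
            rms_by_class[r, ci] = np.sqrt(np.mean(err[sel] ** 2))
    return DecoderResult(
        task="time",
        n_grid=np.array([n_neurons]),
        performance=np.array([np.median(rms_runs)]),
        lo=np.array([np.percentile(rms_runs, 2.5)]),
        hi=np.array([np.percentile(rms_runs, 97.5)]),
        details={
            "classes": classes,
            "rms_by_class": np.median(rms_by_class, axis=0),
            "runs": rms_runs,
        },
    )


def uniform_guess_rms(classes) -> float:
    """RMS error of guessing uniformly at random on the class grid."""
    c = np.asarray(classes, dtype=float)
    d = c[:, None] - c[None, :]
    return float(np.sqrt(np.mean(d**2)))


def decode_phase(
    tuning_rates,
    n_grid,
    cycle_ms: float = 65.0,
    window_ms: float = INTEGRATION_MS,
    delta_bins=None,
    n_trials: int = 400,
    n_runs: int = 20,
    seed: int = 0,
    criterion: float = PC_CRITERION,
) -> DecoderResult:
    """Smallest discriminable phase difference at the 76%-correct criterion.

    Parameters
    ----------
    tuning_rates : (n_pool, 120) array of spikes/s per phase bin for the
        neuron pool (occupancy-normalized tuning curves)
    n_grid : population sizes
    cycle_ms, window_ms : whisk-cycle period and integration window; the
        expected count per neuron at phase phi is rate(phi) * window.
    delta_bins : candidate phase differences in 3-degree bins
        (default 1..60, i.e. 3..180 degrees)

    For each run, neurons are drawn with replacement and circularly
    shifted so preferred phases are uniform; two-class Poisson naive Bayes
    discrimination between phi and phi + delta is simulated at ``n_trials``
    trials per delta; the performance is the smallest delta reaching the
    criterion, in degrees (inf when never reached).
    """
    rng = np.random.default_rng(seed)
    rates = np.asarray(tuning_rates, dtype=float)
    n_bins = rates.shape[1]
    if delta_bins is None:
        delta_bins = np.arange(1, n_bins // 2 + 1)
    bin_deg = 360.0 / n_bins
    n_grid = np.asarray(n_grid, dtype=int)
    res = np.full((n_runs, len(n_grid)), np.inf)
    for r in range(n_runs):
        for a, n in enumerate(n_grid):
            members = rng.integers(0, len(rates), n)
            shifts = rng.integers(0, n_bins, n)
            lam = np.stack(
                [np.roll(rates[m], s) for m, s in zip(members, shifts)]
            )  # (n, n_bins) spikes/s
            lam = lam * window_ms / 1000.0 + 1e-12
            loglam = np.log(lam)
            for d in delta_bins:
                b0 = rng.integers(0, n_bins, n_trials)
                b1 = (b0 + d) % n_bins
                correct = 0
                for cls, (ba, bb) in enumerate(((b0, b1), (b1, b0))):
                    x = rng.poisson(lam[:, ba])  # (n, n_trials)
                    ll_a = (x * loglam[:, ba]).sum(0) - lam[:, ba].sum(0)
                    ll_b = (x * loglam[:, bb]).sum(0) - lam[:, bb].sum(0)
                    win = ll_a > ll_b
                    tie = ll_a == ll_b
                    correct += win.sum() + 0.5 * tie.sum()
                acc = correct / (2.0 * n_trials)
                if acc >= criterion:
                    res[r, a] = d * bin_deg
                    break
    with np.errstate(invalid="ignore"):
        return DecoderResult(
            task="phase",
            n_grid=n_grid,
            performance=np.median(res, axis=0),
            lo=np.percentile(res, 2.5, axis=0),
            hi=np.percentile(res, 97.5, axis=0),
            details={"runs": res, "bin_deg": bin_deg},
        )
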