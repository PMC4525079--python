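"""Spike-count variability: Fano factors, binomial minimum, touch grouping,
sliding-window analysis, and refractory-Poisson nulls.

The Fano factor (FF) is the variance of the spike count divided by its
mean over a counting window; FF = 1 for a Poisson process. Because counts
are integers while means are continuous, the smallest achievable FF at
mean mu is not zero: it is attained by a distribution supported on the two
integers bracketing mu, giving (mu-k)(k+1-mu)/mu with k = floor(mu), which
reduces to 1 - mu for mu < 1 (binomial limit).

To isolate intrinsic variability from stimulus variability, touches with
inter-contact interval > 250 ms are grouped by similarity of z-scored
pretouch velocity and maximum curvature change using OPTICS density
ordering: the window of N consecutive ordered points minimizing the sum of
pairwise distances forms a group, is removed, and the procedure repeats
until five groups exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import OPTICS

from .spike_metrics import PSTH

__all__ = [
    "fano_factor",
    "min_fano",
    "select_touches",
    "TouchGrouping",
    "group_touches",
    "FanoCurve",
    "sliding_fano",
    "refractory_poisson_null",
    "ff_conditions",
]

ICI_MIN_MS = 250.0
DEFAULT_WINDOW_MS = 10.0
DEFAULT_OFFSETS = np.arange(0.0, 21.0)
N_BOOT = 1000


def fano_factor(counts, ddof: int = 0) -> float:
    """Variance / mean of spike counts (population variance by default).

    Returns NaN when the mean is zero (FF undefined).
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("need at least 2 counts")
    mu = counts.mean()
    if mu == 0:
        return float("nan")
    return float(counts.var(ddof=ddof) / mu)


def min_fano(mean: float) -> float:
    """Smallest FF attainable by integer counts with the given mean.

    (mu - k)(k + 1 - mu)/mu with k = floor(mu): 1 - mu for mu < 1, zero at
    integer means. NaN at mean 0 (FF undefined there).
    """
    mu = float(mean)
    if mu < 0:
        raise ValueError("mean must be non-negative")
    if mu == 0:
        return float("nan")
    k = np.floor(mu)
    return float((mu - k) * (k + 1 - mu) / mu)


def select_touches(touches) -> list:
    """Touches with inter-contact interval strictly greater than 250 ms.

    First touches (infinite ICI) pass.
    """
    return [tc for tc in touches if tc.ici > ICI_MIN_MS]


@dataclass
class TouchGrouping:
    """Output of the density-based touch grouping."""

    groups: list  # list of integer index arrays into the input touch list
    features: np.ndarray  # z-scored (velocity, max_dkappa) used
    group_sds: np.ndarray  # within-group feature s.d. (per group, averaged
    # over the two features)


def _zscore_features(touches) -> np.ndarray:
    v = np.array([tc.pretouch_velocity for tc in touches])
    k = np.array([tc.max_dkappa for tc in touches])
    feats = np.column_stack([v, k])
    mu = np.nanmean(feats, axis=0)
    sd = np.nanstd(feats, axis=0)
    sd[sd == 0] = 1.0
    return (feats - mu) / sd


def _best_window(D: np.ndarray, ordering: np.ndarray, N: int) -> np.ndarray:
    """Consecutive ordered window minimizing the sum of pairwise distances."""
    best_score = np.inf
    best = ordering[:N]
    for s in range(len(ordering) - N + 1):
        idx = ordering[s: s + N]
        score = D[np.ix_(idx, idx)].sum()
        if score < best_score:
            best_score = score
            best = idx
    return best


def group_touches(
    touches,
    n_groups: int = 5,
    min_size: int = 20,
    group_frac: float = 0.2,
    min_samples: int = 10,
) -> TouchGrouping:
    """Group touches by stimulus-feature similarity (OPTICS ordering).

    Iteratively: run OPTICS on the remaining touches' z-scored features,
    scan all windows of N consecutive points in the reachability ordering
    (N = max(min_size, group_frac of remaining)), keep the window with the
    smallest sum of pairwise Euclidean distances as the next group, remove
    it, and repeat until ``n_groups`` groups exist. Touches with undefined
    velocity are excluded up front.
    """
    valid = np.array(
        [
            i
            for i, tc in enumerate(touches)
            if np.isfinite(tc.pretouch_velocity)
        ],
        dtype=int,
    )
    if len(valid) < n_groups * min_size:
        raise ValueError(
            f"need at least {n_groups * min_size} touches with defined "
            f"features, got {len(valid)}"
        )
    feats_all = _zscore_features([touches[i] for i in valid])
    remaining = np.arange(len(valid))
    groups = []
    for _ in range(n_groups):
        pts = feats_all[remaining]
        N = max(min_size, int(round(group_frac * len(remaining))))
        N = min(N, len(remaining))
        if len(remaining) > max(min_samples, N):
            optics = OPTICS(min_samples=min_samples, max_eps=np.inf)
            optics.fit(pts)
            ordering = optics.ordering_
        else:
            ordering = np.arange(len(remaining))
        diff = pts[:, None, :] - pts[None, :, :]
        D = np.sqrt((diff**2).sum(-1))
        local = _best_window(D, np.asarray(ordering), N)
        groups.append(valid[remaining[local]])
        remaining = np.delete(remaining, local)
    sds = np.array(
        [
            feats_all[np.searchsorted(valid, g)].std(axis=0).mean()
            for g in groups
        ]
    )
    return TouchGrouping(groups=groups, features=feats_all, group_sds=sds)


@dataclass
class FanoCurve:
    """FF versus window offset from touch onset."""

    window: float
    offsets: np.ndarray
    ff: np.ndarray
    mean_count: np.ndarray
    binomial_min: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_events: int = 0
    groups: list = field(default_factory=list)  # per-group curves, if any

    @property
    def min_ff(self) -> float:
        """Minimum FF over offsets (NaN offsets skipped)."""
        ok = np.isfinite(self.ff)
        return float(self.ff[ok].min()) if ok.any() else float("nan")


def touch_counts(spikes, touches, window: float, offsets) -> np.ndarray:
    """counts[j, o] = spikes in [onset_j + offset_o, + window)."""
    by_trial = {st.trial_id: st.spike_times for st in spikes}
    offsets = np.asarray(offsets, dtype=float)
    counts = np.zeros((len(touches), len(offsets)), dtype=int)
    for j, tc in enumerate(touches):
        ts = by_trial.get(tc.trial_id, np.empty(0))
        starts = tc.onset + offsets
        counts[j] = np.searchsorted(ts, starts + window) - np.searchsorted(
            ts, starts
        )
    return counts


def _fano_curve_from_counts(
    counts, window, offsets, n_boot=N_BOOT, seed=0
) -> FanoCurve:
    rng = np.random.default_rng(seed)
    n, m = counts.shape
    mean = counts.mean(axis=0)
    var = counts.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(mean > 0, var / mean, np.nan)
    bmin = np.array([min_fano(mu) if mu > 0 else np.nan for mu in mean])
    lo = np.full(m, np.nan)
    hi = np.full(m, np.nan)
    if n >= 2 and n_boot:
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = counts[idx]  # (n_boot, n, m)
        bmean = boot.mean(axis=1)
        bvar = boot.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bff = np.where(bmean > 0, bvar / bmean, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(bff, 2.5, axis=0)
            hi = np.nanpercentile(bff, 97.5, axis=0)
    return FanoCurve(
        window=window,
        offsets=np.asarray(offsets, float),
        ff=ff,
        mean_count=mean,
        binomial_min=bmin,
        ci_low=lo,
        ci_high=hi,
        n_events=n,
    )


def sliding_fano(
    spikes,
    touches,
    grouping: TouchGrouping | None = None,
    window: float = DEFAULT_WINDOW_MS,
    offsets=DEFAULT_OFFSETS,
    n_boot: int = N_BOOT,
    seed: int = 0,
) -> FanoCurve:
    """FF in sliding windows after touch onset.

    Without ``grouping``, one curve over all touches. With it, per-group
    curves are attached to ``result.groups`` and the top-level curve
    reports, per offset, the mean FF across groups (the per-group minimum
    and the cross-group minimum are available from the attached curves).
    """
    counts = touch_counts(spikes, touches, window, offsets)
    if grouping is None:
        return _fano_curve_from_counts(counts, window, offsets, n_boot, seed)
    curves = []
    for k, idx in enumerate(grouping.groups):
        if len(idx) == 0:
            continue
        curves.append(
            _fano_curve_from_counts(
                counts[idx], window, offsets, n_boot, seed + k + 1
            )
        )
    stacked = np.vstack([c.ff for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ff = np.nanmean(stacked, axis=0)
    top = _fano_curve_from_counts(counts, window, offsets, 0, seed)
    top.ff = mean_ff
    top.groups = curves
    return top


def refractory_poisson_null(
    psth: PSTH,
    refractory: float,
    n_events: int,
    seed: int = 0,
    window: float = DEFAULT_WINDOW_MS,
    offsets=DEFAULT_OFFSETS,
    n_boot: int = 0,
) -> FanoCurve:
    """Sliding FF of a rate-matched Poisson process with refractory period.

    Draws ``n_events`` event-aligned spike trains from the PSTH rate
    profile (inhomogeneous Poisson on the PSTH bins) and deletes spikes
    within the absolute refractory period of the previous kept spike
    (forward deletion), then computes the same sliding FanoCurve.
    """
    rng = np.random.default_rng(seed)
    rate_per_bin = psth.rate * psth.bin_width / 1000.0  # expected per bin
    offsets = np.asarray(offsets, dtype=float)
    counts = np.zeros((n_events, len(offsets)), dtype=int)
    starts = offsets
    for j in range(n_events):
        k = rng.poisson(rate_per_bin)
        idx = np.nonzero(k)[0]
        ts = np.concatenate(
            [
                psth.edges[i] + rng.random(k[i]) * psth.bin_width
                for i in idx
            ]
        ) if len(idx) else np.empty(0)
        ts.sort()
        if refractory > 0 and len(ts) > 1:
            keep = np.ones(len(ts), dtype=bool)
            last = -np.inf
            for i, t in enumerate(ts):
                if t - last <= refractory:
                    keep[i] = False
                else:
                    last = t
            ts = ts[keep]
        counts[j] = np.searchsorted(ts, starts + window) - np.searchsorted(
            ts, starts
        )
    return _fano_curve_from_counts(counts, window, offsets, n_boot, seed)


def ff_conditions(
    spikes,
    traces,
    touches,
    latency: float = 6.0,
    window_broad: float = 38.0,
    seed: int = 0,
    grouping: TouchGrouping | None = None,
):
    """FF under five alignment conditions of decreasing behavioral blur.

    1. counts over the whole pole-in-reach (sample) period per trial;
    2. counts in random 38 ms windows inside the sample period, matched in
       number to the trial's touches;
    3. counts in 38 ms windows starting ``latency`` (6 ms) after each
       touch onset;
    4. minimum FF over a 10 ms window slid 0-20 ms after touch onset,
       ICI-filtered touches;
    5. as 4, but touches divided into five similar-stimulus groups; the
       per-cell value is the mean over groups of the per-group minimum.

    Returns a dict with ``ff`` and ``mean_count`` arrays of length 5
    (NaN where undefined) plus the per-condition details.
    """
    rng = np.random.default_rng(seed)
    by_trial = {st.trial_id: st.spike_times for st in spikes}

    sample_counts = []
    random_counts = []
    touches_per_trial = {}
    for tc in touches:
        touches_per_trial[tc.trial_id] = touches_per_trial.get(
            tc.trial_id, 0
        ) + 1
    for tr in traces:
        ts = by_trial.get(tr.trial_id, np.empty(0))
        s0, s1 = tr.pole_in_reach
        sample_counts.append(int(np.sum((ts >= s0) & (ts < s1))))
        n_win = touches_per_trial.get(tr.trial_id, 0)
        if n_win and s1 - window_broad > s0:
            starts = rng.uniform(s0, s1 - window_broad, n_win)
            for st_ in starts:
                random_counts.append(
                    int(np.sum((ts >= st_) & (ts < st_ + window_broad)))
                )
    c3 = touch_counts(spikes, touches, window_broad, [latency])[:, 0]

    filtered = select_touches(touches)
    curve4 = (
        sliding_fano(spikes, filtered, n_boot=0)
        if len(filtered) >= 2
        else None
    )
    ff5 = float("nan")
    mean5 = float("nan")
    curve5 = None
    if grouping is None and len(filtered) >= 100:
        grouping = group_touches(filtered)
    if grouping is not None:
        curve5 = sliding_fano(spikes, filtered, grouping, n_boot=0)
        per_group_min = [g.min_ff for g in curve5.groups]
        ff5 = float(np.nanmean(per_group_min))
        mins = [
            g.mean_count[np.nanargmin(g.ff)]
            for g in curve5.groups
            if np.isfinite(g.ff).any()
        ]
        mean5 = float(np.mean(mins)) if mins else float("nan")

    def _safe_ff(c):
        c = np.asarray(c)
        return (
            fano_factor(c) if len(c) >= 2 and c.mean() > 0 else float("nan")
        )

    ff4 = curve4.min_ff if curve4 is not None else float("nan")
    mean4 = (
        float(curve4.mean_count[np.nanargmin(curve4.ff)])
        if curve4 is not None and np.isfinite(curve4.ff).any()
        else float("nan")
    )
    ff = np.array(
        [
            _safe_ff(sample_counts),
            _safe_ff(random_counts),
            _safe_ff(c3),
            ff4,
            ff5,
        ]
    )
    mean_count = np.array(
        [
            np.mean(sample_counts) if sample_counts else np.nan,
            np.mean(random_counts) if random_counts else np.nan,
            c3.mean() if len(c3) else np.nan,
            mean4,
            mean5,
        ]
    )
    return {
        "ff": ff,
        "mean_count": mean_count,
        "curve_sliding": curve4,
        "curve_grouped": curve5,
        "grouping": grouping,
    }
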