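"""Modulation of per-touch spike counts by touch properties.

Touches are sorted by a stimulus feature (touch order, pretouch velocity,
or maximum curvature change), split into equal-occupancy bins, and the
mean spikes/touch per bin is summarized by the modulation index
(max bin - min bin) / (max bin + min bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningCurve",
    "touch_feature_values",
    "bin_touch_responses",
    "modulation_index",
    "tuning_correlations",
]

FEATURES = ("order", "velocity", "max_curvature")


@dataclass
class TuningCurve:
    feature: str
    bin_means: np.ndarray  # mean spikes/touch per equal-occupancy bin
    ci_low: np.ndarray  # bootstrap 95% CI per bin
    ci_high: np.ndarray
    bin_counts: np.ndarray  # touches per bin (differ by at most 1)
    feature_edges: np.ndarray  # feature value at each bin boundary
    modulation_index: float


def touch_feature_values(touches, feature: str) -> np.ndarray:
    if feature == "order":
        return np.array([tc.order for tc in touches], dtype=float)
    if feature == "velocity":
        return np.array([tc.pretouch_velocity for tc in touches])
    if feature == "max_curvature":
        return np.array([tc.max_dkappa for tc in touches])
    raise ValueError(f"unknown feature {feature!r}; one of {FEATURES}")


def bin_touch_responses(
    counts,
    touches,
    feature: str,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> TuningCurve:
    """Equal-occupancy feature bins of per-touch spike counts.

    ``counts[j]`` is the spike count of touch ``touches[j]`` in the cell's
    touch-coupled window. Touches with undefined feature values (NaN) are
    dropped; ties in the feature are broken by touch chronology (stable
    sort). Bootstrap CIs use ``n_boot`` within-bin resamples.
    """
    counts = np.asarray(counts, dtype=float)
    values = touch_feature_values(touches, feature)
    ok = np.isfinite(values)
    counts, values = counts[ok], values[ok]
    if len(values) < n_bins:
        raise ValueError(
            f"need at least {n_bins} touches with defined {feature!r}, "
            f"got {len(values)}"
        )
    order = np.argsort(values, kind="stable")
    chunks = np.array_split(order, n_bins)
    rng = np.random.default_rng(seed)
    means = np.empty(n_bins)
    lo = np.empty(n_bins)
    hi = np.empty(n_bins)
    sizes = np.empty(n_bins, dtype=int)
    edges = [values[order[0]]]
    for k, idx in enumerate(chunks):
        c = counts[idx]
        means[k] = c.mean()
        sizes[k] = len(c)
        boots = rng.choice(c, size=(n_boot, len(c)), replace=True).mean(axis=1)
        lo[k], hi[k] = np.percentile(boots, [2.5, 97.5])
        edges.append(values[idx[-1]])
    return TuningCurve(
        feature=feature,
        bin_means=means,
        ci_low=lo,
        ci_high=hi,
        bin_counts=sizes,
        feature_edges=np.asarray(edges),
        modulation_index=modulation_index(means),
    )


def modulation_index(bin_means) -> float:
    """(max bin - min bin) / (max bin + min bin); NaN for all-zero curves."""
    m = np.asarray(
        bin_means.bin_means if isinstance(bin_means, TuningCurve) else bin_means,
        dtype=float,
    )
    hi, lo = m.max(), m.min()
    if hi + lo == 0:
        return float("nan")
    return float((hi - lo) / (hi + lo))


def tuning_correlations(indices_by_feature: dict):
    """Pairwise Pearson correlations of per-cell modulation indices.

    ``indices_by_feature`` maps feature name -> array of one index per
    cell (same cell order in every array, >= 3 cells). Returns a nested
    dict ``corr[f1][f2]``; correlations with a constant vector are NaN.
    """
    feats = list(indices_by_feature)
    arrays = {f: np.asarray(indices_by_feature[f], float) for f in feats}
    n = {len(a) for a in arrays.values()}
    if len(n) != 1:
        raise ValueError("feature index arrays must have equal length")
    if n.pop() < 3:
        raise ValueError("need at least 3 cells")
    out = {f: {} for f in feats}
    for f1 in feats:
        for f2 in feats:
            a, b = arrays[f1], arrays[f2]
            if a.std() == 0 or b.std() == 0:
                out[f1][f2] = float("nan")
            else:
                out[f1][f2] = float(np.corrcoef(a, b)[0, 1])
    return out
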