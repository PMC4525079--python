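"""Configuration for the synthetic-session generator.

The defaults are calibrated to the printed behavioral and neural statistics
of layer-4 recordings in the principal (C2) barrel during pole
localization: whisking bouts of mean duration 261 ms, peak-to-peak
amplitude 15.7 deg at 15.4 Hz, 2.33 touches per trial, ~0.7 spikes per
touch under a binomial (0-or-1 spike) count model with 8 ms onset latency,
cosine phase tuning with effective modulation depth 0.5, and low baseline
rates (~0.2 spk/s).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["GeneratorConfig", "FeatureEffects", "load_config"]


@dataclass
class FeatureEffects:
    """Log-linear gains linking touch features to per-touch spike probability.

    p_touch = clip(p0 * order_gain**(order-1)
                      * exp(velocity_gain * z_v + dkappa_gain * z_k), 0, 1)

    where z_v, z_k are pretouch velocity and max curvature change
    standardized against the generator's own reference scales. All gains
    default to neutral (no feature modulation): the per-touch probability is
    then constant, which is the calibration the printed per-touch means pin
    down. Nonzero gains are an opt-in for feature-tuning studies.
    """

    velocity_gain: float = 0.0
    dkappa_gain: float = 0.0
    order_gain: float = 1.0  # multiplicative per touch order step

    # reference scales used to standardize features inside the generator
    velocity_ref: tuple = (0.15, 0.08)  # (mean, sd) deg/ms
    dkappa_ref: tuple = (0.004, 0.0015)  # (mean, sd) 1/mm


@dataclass
class GeneratorConfig:
    """Parameters of the generative model for one synthetic session."""

    n_trials: int = 160
    trial_duration: float = 5000.0  # ms
    sample_epoch: tuple = (1000.0, 3400.0)  # pole-in-reach, ms
    whisk_freq: float = 15.4  # Hz
    whisk_p2p_amp: float = 15.7  # deg, mean bout peak-to-peak amplitude
    bout_duration_mean: float = 261.0  # ms
    rest_duration_mean: float = 112.0  # ms between bouts (~0.7 whisking duty)
    setpoint: float = 10.0  # deg, slow component of theta
    touches_per_trial_mean: float = 2.33
    # gamma shape of the per-trial touch-rate multiplier: trial-to-trial
    # variability in exploration vigor (touch counts are then negative-
    # binomial-like, Var = mu + mu^2/shape); np.inf disables
    touch_rate_dispersion: float = 2.0
    touch_duration_mean: float = 30.0  # ms
    kappa_peak_mean: float = 0.004  # 1/mm
    kappa_peak_sd: float = 0.0015
    baseline_rate: float = 0.15  # spk/s, homogeneous throughout the trial
    touch_spike_prob_first: float = 0.7
    touch_spike_prob_later: float = 0.7
    touch_latency: float = 8.0  # ms to response onset
    touch_jitter: float = 2.0  # ms, half-normal scale of the evoked delay
    phase_A: float = 0.15  # spk/s, modulated part of whisking rate
    phase_B: float = 0.0  # spk/s, unmodulated part of whisking rate
    phase_pref: float = 0.0  # rad, 0 = maximum protraction
    refractory: float = 2.3  # ms, absolute; forward deletion
    count_model: str = "binomial"  # or "poisson"
    feature_effects: FeatureEffects = field(default_factory=FeatureEffects)
    lick_prob: float = 0.8  # per trial with touches
    reaction_time_mean: float = 367.0  # ms
    reaction_time_sd: float = 234.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.feature_effects, dict):
            self.feature_effects = FeatureEffects(**self.feature_effects)
        self.validate()

    def validate(self):
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        s0, s1 = self.sample_epoch
        if not (0 <= s0 < s1 <= self.trial_duration):
            raise ValueError("sample_epoch must lie within the trial")
        for name in (
            "whisk_freq",
            "whisk_p2p_amp",
            "bout_duration_mean",
            "rest_duration_mean",
            "touches_per_trial_mean",
            "baseline_rate",
            "phase_A",
            "phase_B",
            "refractory",
            "touch_jitter",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.touch_latency < 0:
            raise ValueError("touch_latency must be non-negative")
        for name in ("touch_spike_prob_first", "touch_spike_prob_later"):
            p = getattr(self, name)
            if p < 0:
                raise ValueError(f"{name} must be non-negative")
            if self.count_model == "binomial" and p > 1:
                raise ValueError(f"{name} > 1 invalid under binomial model")
        if self.count_model not in ("binomial", "poisson"):
            raise ValueError("count_model must be 'binomial' or 'poisson'")

    @property
    def true_modulation_depth(self) -> float:
        """Effective depth of the whisking-epoch rate, A/(A+B+r0)."""
        denom = self.phase_A + self.phase_B + self.baseline_rate
        return self.phase_A / denom if denom > 0 else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("sample_epoch", "reaction_time"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        fe = d.get("feature_effects")
        if isinstance(fe, dict):
            for key in ("velocity_ref", "dkappa_ref"):
                if key in fe and isinstance(fe[key], list):
                    fe[key] = tuple(fe[key])
        return cls(**d)


def load_config(path) -> GeneratorConfig:
    """Read a GeneratorConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return GeneratorConfig.from_dict(data or {})
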