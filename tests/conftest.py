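"""Shared fixtures: synthetic sessions and their derived kinematics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from activetouch import intervals as iv
from activetouch import kinematics as kin
from activetouch import spike_metrics as sm
from activetouch.config import GeneratorConfig
from activetouch.synth import generate_session


@dataclass
class Analyzed:
    """A session bundled with its derived per-trial analyses."""

    session: object
    phases: list
    epochs: list
    touches: list
    psth: object
    latency: float | None

    def gt_exploration_fraction(self) -> float:
        """Ground-truth touch-evoked fraction among exploration spikes."""
        gt = self.session.ground_truth
        n = n_touch = 0
        for tr, ep in zip(self.session.traces, self.epochs):
            m = (gt.trial_ids == tr.trial_id) & (~gt.deleted)
            ts, lab = gt.spike_times[m], gt.labels[m]
            inside = iv.contains(ep.exploration, ts)
            n += inside.sum()
            n_touch += (lab[inside] == "touch").sum()
        return n_touch / n if n else float("nan")


def analyze(session) -> Analyzed:
    phases = [kin.decompose_whisking(tr) for tr in session.traces]
    epochs = [
        kin.segment_epochs(tr, ph)
        for tr, ph in zip(session.traces, phases)
    ]
    touches = [
        tc
        for tr in session.traces
        for tc in kin.extract_touch_features(tr)
    ]
    psth = sm.touch_aligned_psth(session.spikes, touches)
    latency = sm.onset_latency(psth)
    return Analyzed(session, phases, epochs, touches, psth, latency)


@pytest.fixture(scope="session")
def default_session():
    """One full-size session under the default generative conditions."""
    return generate_session(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def default_analyzed(default_session):
    return analyze(default_session)


@pytest.fixture(scope="session")
def small_analyzed():
    """A 40-trial session for cheaper integration tests."""
    return analyze(generate_session(GeneratorConfig(n_trials=40, seed=7)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
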