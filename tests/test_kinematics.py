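"""Phase decomposition, epoch rules, touch features, reaction time."""

import numpy as np
import pytest

from activetouch import kinematics as kin
from activetouch.types import EpochSet, PhaseSeries, WhiskerTrace


def _trace(theta, **kw):
    n = len(theta)
    kw.setdefault("kappa", np.zeros(n))
    return WhiskerTrace(
        trial_id=0, t=np.arange(n, dtype=float), theta=np.asarray(theta), **kw
    )


def test_pure_tone_phase_and_envelope():
    """15 Hz tone: 2pi phase advance per ~66.7 ms, envelope ~10 deg."""
    t = np.arange(2000)
    trace = _trace(10.0 * np.sin(2 * np.pi * 15 * t / 1000.0))
    ph = kin.decompose_whisking(trace)
    interior = slice(300, 1700)
    assert np.all(np.abs(ph.amplitude[interior] - 10.0) / 10.0 < 0.05)
    durs = ph.cycles[:, 1] - ph.cycles[:, 0]
    core = durs[(ph.cycles[:, 0] > 300) & (ph.cycles[:, 1] < 1700)]
    assert np.all(np.abs(core - 1000.0 / 15.0) <= 2.0)


def test_constant_theta_no_whisking():
    trace = _trace(np.full(1000, 7.0))
    ph = kin.decompose_whisking(trace)
    assert np.max(ph.amplitude) < 1e-6
    assert len(kin.whisking_cycles(ph)) == 0


def test_short_or_nan_trace_rejected():
    with pytest.raises(ValueError):
        kin.decompose_whisking(_trace(np.zeros(100)))
    with pytest.raises(ValueError):
        kin.decompose_whisking(_trace(np.full(1000, np.nan)))


def test_cycle_boundaries_match_peakfinding_oracle():
    """Cycle edges within +-2 ms of retraction minima on a clean bout."""
    t = np.arange(3000, dtype=float)
    f, phi0 = 14.0, 0.3
    carrier = np.cos(2 * np.pi * f * t / 1000.0 + phi0)
    gate = ((t > 500) & (t < 1400)) | ((t > 1800) & (t < 2600))
    trace = _trace(5.0 * gate * carrier + 10.0)
    ph = kin.decompose_whisking(trace)
    # oracle: retraction minima of the noiseless carrier
    minima = []
    for k in range(200):
        tm = 1000.0 * ((2 * k + 1) * np.pi - phi0) / (2 * np.pi * f)
        if gate[int(tm)] if tm < 3000 else False:
            minima.append(tm)
    minima = np.asarray(minima)
    wc = kin.whisking_cycles(ph)
    interior = wc[
        (wc[:, 0] > 600) & (wc[:, 1] < 1300)
        | (wc[:, 0] > 1900) & (wc[:, 1] < 2500)
    ]
    for edge in interior[:, 0]:
        assert np.min(np.abs(minima - edge)) <= 2.0


def test_filter_roundtrip_on_bandlimited_signal():
    """Re-filtering a mid-band signal changes it by < 1% RMS."""
    t = np.arange(4000)
    x = 4 * np.sin(2 * np.pi * 18 * t / 1000) + 2 * np.sin(
        2 * np.pi * 31 * t / 1000 + 1.0
    )
    ph = kin.decompose_whisking(_trace(x))
    core = slice(500, 3500)
    err = np.sqrt(np.mean((ph.theta_band[core] - x[core]) ** 2))
    assert err / np.sqrt(np.mean(x[core] ** 2)) < 0.01


def test_phase_envelope_consistency():
    t = np.arange(2000)
    x = 6 * np.sin(2 * np.pi * 12 * t / 1000)
    ph = kin.decompose_whisking(_trace(x))
    recon = ph.amplitude * np.cos(ph.phi)
    core = slice(200, 1800)
    assert np.allclose(recon[core], ph.theta_band[core], atol=1e-9)


def _phase_series(amplitude, cycles=(), monotonic=None):
    n = len(amplitude)
    cycles = np.asarray(cycles, dtype=float).reshape(-1, 2)
    if monotonic is None:
        monotonic = np.ones(len(cycles), dtype=bool)
    return PhaseSeries(
        trial_id=0,
        t=np.arange(n, dtype=float),
        theta_band=np.asarray(amplitude, float),
        phi=np.zeros(n),
        amplitude=np.asarray(amplitude, float),
        cycles=cycles,
        cycle_monotonic=monotonic,
    )


def test_non_whisking_minimum_duration_rule():
    """A quiet stretch needs >= 100 ms to count as non-whisking."""
    for quiet_len, expect in ((200, 1), (90, 0), (100, 1)):
        amp = np.full(1000, 5.0)
        amp[300: 300 + quiet_len] = 0.5
        trace = _trace(np.zeros(1000))
        ep = kin.segment_epochs(trace, _phase_series(amp))
        inside = [
            (s, e) for s, e in ep.non_whisking if s >= 300 and e <= 300 + quiet_len
        ]
        assert len(inside) == expect, quiet_len


def test_non_whisking_excludes_touch_and_lick():
    amp = np.full(400, 0.5)
    trace = _trace(
        np.zeros(400),
        touch_intervals=[(150, 160)],
        lick_times=np.array([320.0]),
    )
    ep = kin.segment_epochs(trace, _phase_series(amp))
    # touch at 150 and lick at 320 split the quiet time; only [0,150) and
    # [161?,320) segments over 100 ms survive
    for s, e in ep.non_whisking:
        assert e - s >= 100
        assert not (s <= 150 < e)
        assert not (s <= 320 < e)


def test_whisking_epoch_from_bout():
    """A 300 ms bout at 5 deg peak-to-peak yields one whisking epoch."""
    t = np.arange(1500, dtype=float)
    gate = (t > 600) & (t < 900)
    trace = _trace(2.5 * gate * np.cos(2 * np.pi * 15 * t / 1000) + 10)
    ph = kin.decompose_whisking(trace)
    ep = kin.segment_epochs(trace, ph)
    from activetouch import intervals as iv

    covered = iv.total_duration(iv.intersect(ep.whisking, [(560, 940)]))
    assert covered >= 150  # most of the bout's full cycles
    # and nothing far outside the bout
    outside = iv.total_duration(
        iv.subtract(ep.whisking, [(450, 1000)])
    )
    assert outside == 0.0


def test_exploration_excludes_prolonged_touches():
    amp = np.full(2000, 5.0)
    cycles = [(i, i + 50) for i in range(0, 2000, 50)]
    phase = _phase_series(amp, cycles)
    phase.theta_band = 5 * np.cos(2 * np.pi * 20 * np.arange(2000) / 1000)
    trace = _trace(
        np.zeros(2000),
        touch_intervals=[(500, 550), (1000, 1150)],  # second is prolonged
        pole_in_reach=(0.0, 2000.0),
    )
    ep = kin.segment_epochs(trace, phase)
    from activetouch import intervals as iv

    assert iv.contains(ep.exploration, [520.0])[0]
    # prolonged touch (150 ms) removed from exploration unless whisking
    # covers it; whisking excludes touch time by construction
    assert not iv.contains(ep.whisking, [1100.0])[0]


def test_pretouch_velocity_linear_ramp():
    theta = np.arange(300, dtype=float)  # 1 deg/ms everywhere
    trace = _trace(theta, touch_intervals=[(100.0, 140.0)])
    (tc,) = kin.extract_touch_features(trace)
    assert tc.pretouch_velocity == pytest.approx(1.0)
    assert tc.ici == np.inf and tc.is_first


def test_touch_at_trial_start_flagged():
    trace = _trace(np.zeros(300), touch_intervals=[(2.0, 30.0)])
    (tc,) = kin.extract_touch_features(trace)
    assert np.isnan(tc.pretouch_velocity)


def test_ici_and_dkappa_construction():
    kappa = np.zeros(600)
    kappa[412] = 0.004  # peak at onset+12
    trace = _trace(
        np.zeros(600),
        kappa=kappa,
        touch_intervals=[(100.0, 150.0), (400.0, 430.0)],
    )
    t1, t2 = kin.extract_touch_features(trace)
    assert t2.ici == pytest.approx(250.0)
    assert t2.max_dkappa == pytest.approx(0.004)
    assert t2.order == 2 and not t2.is_first


@pytest.mark.parametrize(
    "licks,touches,expected",
    [
        ([867.0], [(500.0, 530.0)], 367.0),
        ([], [(500.0, 530.0)], None),
        ([867.0], [], None),
        ([400.0], [(500.0, 530.0)], -100.0),
    ],
)
def test_reaction_time(licks, touches, expected):
    trace = _trace(
        np.zeros(1000),
        lick_times=np.asarray(licks),
        touch_intervals=touches,
    )
    rt = kin.reaction_time(trace)
    if expected is None:
        assert rt is None
    else:
        assert rt == pytest.approx(expected)


def test_epoch_partition_disjoint(small_analyzed):
    """No millisecond is both whisking and non-whisking."""
    from activetouch import intervals as iv

    for ep in small_analyzed.epochs:
        overlap = iv.intersect(ep.whisking, ep.non_whisking)
        assert iv.total_duration(overlap) == 0.0
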