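"""Session persistence (CSV tables + JSON manifest) and the pipeline driver.

A session directory holds:

* ``manifest.json`` — session id, schema version, per-trial metadata;
* ``whisker.csv`` — trial_id, time_ms, theta_deg, kappa;
* ``events.csv`` — trial_id, type (touch_on | touch_off | lick | pole_in |
  pole_out), time_ms;
* ``spikes.csv`` — trial_id, spike_time_ms;
* ``ground_truth.csv`` (optional) — per-spike generative labels.

Times are stored in ms with microsecond precision; all intervals are
half-open.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Session, SpikeTrain, WhiskerTrace

log = logging.getLogger("activetouch")

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.3f"


def write_session(session: Session, path) -> Path:
    """Write a session directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "session_id": session.session_id,
        "schema_version": SCHEMA_VERSION,
        "trials": [
            {
                "trial_id": int(tr.trial_id),
                "duration_ms": tr.duration,
                "pole_in_reach": list(tr.pole_in_reach),
            }
            for tr in session.traces
        ],
        "meta": session.meta,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    wrows = []
    erows = []
    for tr in session.traces:
        wrows.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "time_ms": tr.t,
                    "theta_deg": tr.theta,
                    "kappa": tr.kappa,
                }
            )
        )
        erows.append((tr.trial_id, "pole_in", tr.pole_in_reach[0]))
        erows.append((tr.trial_id, "pole_out", tr.pole_in_reach[1]))
        for on, off in tr.touch_intervals:
            erows.append((tr.trial_id, "touch_on", on))
            erows.append((tr.trial_id, "touch_off", off))
        for lk in tr.lick_times:
            erows.append((tr.trial_id, "lick", lk))
    pd.concat(wrows).to_csv(
        path / "whisker.csv", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(erows, columns=["trial_id", "type", "time_ms"]).to_csv(
        path / "events.csv", index=False, float_format=_FLOAT_FMT
    )
    srows = [
        pd.DataFrame(
            {"trial_id": st.trial_id, "spike_time_ms": st.spike_times}
        )
        for st in session.spikes
    ]
    pd.concat(srows or [pd.DataFrame(columns=["trial_id", "spike_time_ms"])]
              ).to_csv(path / "spikes.csv", index=False,
                       float_format=_FLOAT_FMT)
    if session.ground_truth is not None:
        gt = session.ground_truth
        pd.DataFrame(
            {
                "trial_id": gt.trial_ids.astype(int),
                "spike_time_ms": gt.spike_times,
                "label": gt.labels,
                "deleted": gt.deleted.astype(int),
            }
        ).to_csv(
            path / "ground_truth.csv", index=False, float_format=_FLOAT_FMT
        )
        (path / "ground_truth.json").write_text(
            json.dumps(
                {
                    "phase_pref": gt.phase_pref,
                    "modulation_depth": gt.modulation_depth,
                    "p_first": gt.p_first,
                    "p_later": gt.p_later,
                }
            )
        )
    return path


class SchemaError(ValueError):
    pass


def _require_columns(df, cols, fname):
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{fname}: missing columns {sorted(missing)}")


def read_session(path) -> Session:
    """Load and validate a session directory."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise SchemaError(f"missing manifest: {mpath}")
    for fname in ("whisker.csv", "events.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise SchemaError(f"missing table: {path / fname}")
    manifest = json.loads(mpath.read_text())
    whisker = pd.read_csv(path / "whisker.csv")
    events = pd.read_csv(path / "events.csv")
    spikes = pd.read_csv(path / "spikes.csv")
    _require_columns(
        whisker, ["trial_id", "time_ms", "theta_deg", "kappa"], "whisker.csv"
    )
    _require_columns(events, ["trial_id", "type", "time_ms"], "events.csv")
    _require_columns(spikes, ["trial_id", "spike_time_ms"], "spikes.csv")

    trial_meta = {t["trial_id"]: t for t in manifest["trials"]}
    traces, trains = [], []
    bad_rows = []
    for trial_id, meta in trial_meta.items():
        w = whisker[whisker.trial_id == trial_id]
        if len(w) == 0:
            raise SchemaError(f"trial {trial_id} absent from whisker.csv")
        ev = events[events.trial_id == trial_id]
        touches_on = np.sort(ev[ev.type == "touch_on"].time_ms.to_numpy())
        touches_off = np.sort(ev[ev.type == "touch_off"].time_ms.to_numpy())
        if len(touches_on) != len(touches_off):
            raise SchemaError(
                f"trial {trial_id}: unmatched touch_on/touch_off events"
            )
        licks = ev[ev.type == "lick"].time_ms.to_numpy()
        pole_in = ev[ev.type == "pole_in"].time_ms
        pole_out = ev[ev.type == "pole_out"].time_ms
        pole = (
            float(pole_in.iloc[0]) if len(pole_in) else 0.0,
            float(pole_out.iloc[0]) if len(pole_out) else float(len(w)),
        )
        traces.append(
            WhiskerTrace(
                trial_id=trial_id,
                t=w.time_ms.to_numpy(),
                theta=w.theta_deg.to_numpy(),
                kappa=w.kappa.to_numpy(),
                lick_times=licks,
                pole_in_reach=pole,
                touch_intervals=np.column_stack([touches_on, touches_off])
                if len(touches_on)
                else np.empty((0, 2)),
            )
        )
        sp = spikes[spikes.trial_id == trial_id].spike_time_ms.to_numpy()
        if np.any(np.diff(sp) < 0):
            warnings.warn(
                f"trial {trial_id}: spikes unsorted, sorting", stacklevel=2
            )
            sp = np.sort(sp)
        out_of_bounds = np.nonzero(
            (sp < 0) | (sp > meta["duration_ms"])
        )[0]
        if len(out_of_bounds):
            rows = spikes.index[spikes.trial_id == trial_id][out_of_bounds]
            bad_rows.extend(rows.tolist())
        trains.append(SpikeTrain(trial_id=trial_id, spike_times=sp))
    if bad_rows:
        raise SchemaError(
            f"spikes.csv: spike times outside trial bounds at rows {bad_rows}"
        )
    return Session(
        session_id=manifest["session_id"],
        traces=traces,
        spikes=trains,
        meta=manifest.get("meta", {}),
    )


DEFAULT_PIPELINE = {
    "n_shuffle": 1000,
    "decoding": True,
    "decoding_n_grid": [1, 2, 4, 8, 16],
    "phase_n_grid": [10, 100],
    "fano_window": 10.0,
    "fano_offsets": [0.0, 20.0, 1.0],  # start, stop, step
    "seed": 0,
}


def run_pipeline(session: Session, config: dict | None = None, outdir=None):
    """Run every analysis stage on one session; return the summary dict.

    Stages: kinematics -> spike metrics -> attribution -> touch tuning ->
    Fano analysis -> decoding. Stage CSVs plus ``summary.json`` are
    written to ``outdir`` when given. Reruns with identical inputs and
    seed are bit-identical.
    """
    from . import attribution as attr
    from . import decoding as dec
    from . import fano as fano_mod
    from . import kinematics as kin
    from . import spike_metrics as sm
    from . import touch_tuning as tt

    cfg = dict(DEFAULT_PIPELINE)
    cfg.update(config or {})
    seed = int(cfg["seed"])
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("kinematics: %d trials", session.n_trials)
    phases = [kin.decompose_whisking(tr) for tr in session.traces]
    epochs = [
        kin.segment_epochs(tr, ph)
        for tr, ph in zip(session.traces, phases)
    ]
    touches = [
        tc for tr in session.traces for tc in kin.extract_touch_features(tr)
    ]

    summary = {"session_id": session.session_id, "seed": seed}
    psth = sm.touch_aligned_psth(session.spikes, touches)
    latency = sm.onset_latency(psth)
    summary["latency_ms"] = latency
    try:
        fit = sm.phase_tuning(session.spikes, phases, epochs)
        summary["modulation_depth"] = _r(fit.modulation_depth)
        summary["phase_pref"] = _r(fit.phase_pref)
    except ValueError:
        fit = None
        summary["modulation_depth"] = None
        summary["phase_pref"] = None
    rates = sm.epoch_rates(
        session.spikes, epochs, touches,
        latency=latency if latency is not None else 8.0,
    )
    summary["whisking_rate"] = _r(rates["whisking_rate"])
    summary["non_whisking_rate"] = _r(rates["non_whisking_rate"])
    summary["min_isi_ms"] = _r(rates["min_isi"])
    per_touch = rates.get("spikes_per_touch", np.empty(0))
    firsts = np.array([tc.is_first for tc in touches], dtype=bool)
    if len(per_touch):
        summary["spikes_per_first_touch"] = _r(per_touch[firsts].mean())
        summary["spikes_per_later_touch"] = _r(
            per_touch[~firsts].mean() if (~firsts).any() else float("nan")
        )

    log.info("attribution: n_shuffle=%d", cfg["n_shuffle"])
    lat = latency if latency is not None else 8.0
    curves, result = attr.touch_coupled_fraction(
        session.spikes, touches, lat, epochs,
        n_shuffle=int(cfg["n_shuffle"]), seed=seed,
    )
    if fit is not None and np.isfinite(fit.phase_pref):
        result = attr.phase_coupled_fraction(
            curves, result, session.spikes, phases, epochs,
            fit.phase_pref, n_shuffle=int(cfg["n_shuffle"]), seed=seed + 1,
        )
    summary["frac_touch"] = _r(result.frac_touch)
    summary["frac_touch_or_phase"] = _r(result.frac_touch_or_phase)
    summary["occupancy_touch"] = _r(result.occupancy_touch)
    summary["t_on_ms"] = _r(result.t_on)

    tuning_rows = []
    if len(per_touch) >= 10:
        for feature in tt.FEATURES:
            try:
                curve = tt.bin_touch_responses(
                    per_touch, touches, feature, seed=seed
                )
            except ValueError:
                continue
            summary[f"modulation_index_{feature}"] = _r(
                curve.modulation_index
            )
            for b in range(len(curve.bin_means)):
                tuning_rows.append(
                    {
                        "feature": feature,
                        "bin": b,
                        "mean_spikes_per_touch": curve.bin_means[b],
                        "ci_low": curve.ci_low[b],
                        "ci_high": curve.ci_high[b],
                        "n_touches": curve.bin_counts[b],
                    }
                )

    log.info("fano analysis")
    off = cfg["fano_offsets"]
    offsets = np.arange(off[0], off[1] + off[2] / 2, off[2])
    conds = fano_mod.ff_conditions(
        session.spikes, session.traces, touches, seed=seed
    )
    summary["ff_conditions"] = [_r(v) for v in conds["ff"]]
    summary["ff_mean_counts"] = [_r(v) for v in conds["mean_count"]]
    curve = fano_mod.sliding_fano(
        session.spikes, fano_mod.select_touches(touches),
        window=float(cfg["fano_window"]), offsets=offsets, seed=seed,
    )
    summary["min_ff"] = _r(curve.min_ff)

    if cfg["decoding"]:
        log.info("decoding")
        tc_counts, t_grid = dec.build_touch_responses(session.spikes, touches)
        if len(tc_counts) >= 4:
            non = dec.build_nontouch_responses(
                session.spikes, epochs, touches, 500, seed=seed
            )
            pres = dec.decode_touch_presence(
                [tc_counts], [non], cfg["decoding_n_grid"],
                n_draws=200, n_runs=5, seed=seed,
            )
            summary["presence_performance"] = [
                _r(v) for v in pres.performance
            ]
            time_res = dec.decode_touch_time(
                [tc_counts], t_grid, n_neurons=20, n_runs=10, seed=seed
            )
            summary["time_rms_ms"] = _r(time_res.performance[0])
        if fit is not None and np.isfinite(fit.modulation_depth):
            centers = np.linspace(-np.pi, np.pi, 120, endpoint=False) + (
                np.pi / 120
            )
            rates_120 = fit.predict(centers)[None, :]
            ph = dec.decode_phase(
                rates_120, cfg["phase_n_grid"], n_runs=5, seed=seed
            )
            summary["phase_resolution_deg"] = [
                _r(v) if np.isfinite(v) else None for v in ph.performance
            ]

    if outdir is not None:
        pd.DataFrame(
            {
                "t_ms": psth.edges[:-1],
                "rate_hz": psth.rate,
                "counts": psth.counts,
            }
        ).to_csv(outdir / "psth.csv", index=False)
        pd.DataFrame(
            {
                "window_ms": curves.t_grid,
                "y_ton": curves.y,
                "emp_slope": curves.emp_slope,
                "chance_slope": curves.chance_slope,
            }
        ).to_csv(outdir / "attribution_curve.csv", index=False)
        if tuning_rows:
            pd.DataFrame(tuning_rows).to_csv(
                outdir / "touch_tuning.csv", index=False
            )
        pd.DataFrame(
            {
                "offset_ms": curve.offsets,
                "ff": curve.ff,
                "mean_count": curve.mean_count,
                "binomial_min": curve.binomial_min,
                "ci_low": curve.ci_low,
                "ci_high": curve.ci_high,
            }
        ).to_csv(outdir / "fano_curve.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True)
        )
    return summary


def _r(x, nd: int = 6):
    """Round for stable JSON output; None for NaN."""
    if x is None:
        return None
    x = float(x)
    if not np.isfinite(x):
        return None
    return round(x, nd)
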