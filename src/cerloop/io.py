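"""Plain-text interchange formats.

Spike CSV: ``unit_id,trial_id,t_ms`` where ``trial_id`` is a trial index
or the string ``baseline:<k>`` for the k-th inter-trial baseline epoch.
Eyelid CSV: ``t_ms,position_mm`` (one file per trial) or wide per-session
tables.  Weight snapshots: ``synapse_id,pre_idx,post_idx,weight``.
Correlograms: ``lag_ms,count,norm_count,z``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_spike_csv(path, spike_times: dict, baseline_epochs: dict | None = None):
    """``spike_times``: unit_id -> list of per-trial time arrays."""
    rows = []
    for unit, trials in spike_times.items():
        for k, times in enumerate(trials):
            for t in np.asarray(times, dtype=float):
                rows.append((unit, str(k), t))
    for unit, epochs in (baseline_epochs or {}).items():
        for k, times in enumerate(epochs):
            for t in np.asarray(times, dtype=float):
                rows.append((unit, f"baseline:{k}", t))
    pd.DataFrame(rows, columns=["unit_id", "trial_id", "t_ms"]).to_csv(
        path, index=False)


def read_spike_csv(path):
    """Returns (trials, baselines): unit_id -> list of sorted time arrays."""
    df = pd.read_csv(path, dtype={"trial_id": str})
    trials: dict = {}
    baselines: dict = {}
    for unit, sub in df.groupby("unit_id"):
        is_base = sub["trial_id"].str.startswith("baseline:")
        tr = sub[~is_base]
        keys = sorted(tr["trial_id"].unique(), key=lambda x: int(x))
        trials[unit] = [np.sort(tr[tr.trial_id == k]["t_ms"].to_numpy())
                        for k in keys]
        ba = sub[is_base]
        bkeys = sorted(ba["trial_id"].unique(),
                       key=lambda x: int(x.split(":")[1]))
        baselines[unit] = [np.sort(ba[ba.trial_id == k]["t_ms"].to_numpy())
                           for k in bkeys]
    return trials, baselines


def write_eyelid_csv(path, trace_mm: np.ndarray):
    pd.DataFrame({"t_ms": np.arange(len(trace_mm)),
                  "position_mm": trace_mm}).to_csv(path, index=False)


def read_eyelid_csv(path) -> np.ndarray:
    return pd.read_csv(path)["position_mm"].to_numpy()


def write_weights_csv(path, weights: np.ndarray, pre_idx=None, post_idx=None):
    n = len(weights)
    pd.DataFrame({
        "synapse_id": np.arange(n),
        "pre_idx": pre_idx if pre_idx is not None else np.arange(n),
        "post_idx": post_idx if post_idx is not None else np.zeros(n, dtype=int),
        "weight": weights,
    }).to_csv(path, index=False)


def write_correlogram_csv(path, result):
    pd.DataFrame({"lag_ms": result.lags, "count": result.counts,
                  "norm_count": result.norm_counts, "z": result.z}).to_csv(
        path, index=False)


def write_manifest(path, config, extra: dict | None = None):
    from . import __version__
    d = {"config": json.loads(config.to_json()), "version": __version__}
    d.update(extra or {})
    Path(path).write_text(json.dumps(d, indent=2))


def write_cr_table(path, measures):
    """CR table: trial, is_cr, amplitude_mm, onset_ms, criterion_ms."""
    rows = [(i, m.is_cr, m.amplitude, m.onset_latency, m.criterion_latency)
            for i, m in enumerate(measures)]
    pd.DataFrame(rows, columns=["trial", "is_cr", "amplitude_mm", "onset_ms",
                                "criterion_ms"]).to_csv(path, index=False)
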