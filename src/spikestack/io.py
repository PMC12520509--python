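"""Plain-text persistence for spike ensembles and decoding results.

Ensembles are stored as a directory of UTF-8 delimited tables:

  spikes.csv            trial_id, neuron_id, time_ms   (window-relative,
                        half-open [0, window_ms))
  presample_spikes.csv  same schema, pre-stimulus windows (optional)
  trials.csv            trial_id, event_type, one binary column per category
  neurons.csv           neuron_id, region
  meta.yaml             window length, seed/provenance, ground truth

Reading validates the schema and rejects malformed rows with their
line numbers; ``read_ensemble(write_ensemble(x)) == x`` up to float
round-trip (times are written at full precision, so equality is exact).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .simulate import Bump, SpikeEnsemble

__all__ = ["write_ensemble", "read_ensemble", "write_results"]


def _spikes_frame(spikes) -> pd.DataFrame:
    rows = []
    for t, trial in enumerate(spikes):
        for n, times in enumerate(trial):
            for time in times:
                rows.append((t, n, float(time)))
    return pd.DataFrame(rows, columns=["trial_id", "neuron_id", "time_ms"])


def write_ensemble(ensemble: SpikeEnsemble, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    _spikes_frame(ensemble.spikes).to_csv(
        os.path.join(directory, "spikes.csv"), index=False
    )
    if ensemble.presample_spikes is not None:
        _spikes_frame(ensemble.presample_spikes).to_csv(
            os.path.join(directory, "presample_spikes.csv"), index=False
        )
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(ensemble.n_trials),
            "event_type": ensemble.event_type,
            **{
                name: ensemble.labels[:, c]
                for c, name in enumerate(ensemble.category_names)
            },
        }
    )
    trials.to_csv(os.path.join(directory, "trials.csv"), index=False)
    pd.DataFrame(
        {
            "neuron_id": np.arange(ensemble.n_neurons),
            "region": list(ensemble.regions),
        }
    ).to_csv(os.path.join(directory, "neurons.csv"), index=False)
    meta = {
        "window_ms": float(ensemble.window_ms),
        "event_type": ensemble.event_type,
        "category_names": list(ensemble.category_names),
        "provenance": {k: _plain(v) for k, v in ensemble.provenance.items()},
        "ground_truth": [
            {
                "neuron": int(n),
                "category": int(c),
                "bumps": [
                    [float(b.onset_ms), float(b.duration_ms), float(b.gain_hz)]
                    for b in bumps
                ],
            }
            for (n, c), bumps in sorted(ensemble.ground_truth.items())
        ],
    }
    with open(os.path.join(directory, "meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _read_spikes(
    path: str, n_trials: int, n_neurons: int, window_ms: float
) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["trial_id", "neuron_id", "time_ms"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    spikes = [
        [np.empty(0) for _ in range(n_neurons)] for _ in range(n_trials)
    ]
    bad_trial = ~df["trial_id"].between(0, n_trials - 1)
    bad_neuron = ~df["neuron_id"].between(0, n_neurons - 1)
    bad_time = ~((df["time_ms"] >= 0) & (df["time_ms"] < window_ms))
    for name, bad in [
        ("trial_id", bad_trial),
        ("neuron_id", bad_neuron),
        ("time_ms", bad_time),
    ]:
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}, line {line}: invalid {name} "
                f"{df.loc[bad.idxmax(), name]!r}"
            )
    for (t, n), sub in df.groupby(["trial_id", "neuron_id"], sort=True):
        spikes[int(t)][int(n)] = np.sort(sub["time_ms"].to_numpy(dtype=float))
    return spikes


def read_ensemble(directory: str) -> SpikeEnsemble:
    with open(os.path.join(directory, "meta.yaml")) as fh:
        meta = yaml.safe_load(fh)
    window_ms = float(meta["window_ms"])
    category_names = tuple(meta["category_names"])
    trials = pd.read_csv(os.path.join(directory, "trials.csv"))
    if trials["trial_id"].duplicated().any():
        dup = trials.loc[trials["trial_id"].duplicated(), "trial_id"].iloc[0]
        raise ValueError(f"trials.csv: duplicate trial_id {dup}")
    if not (trials["trial_id"].to_numpy() == np.arange(len(trials))).all():
        raise ValueError("trials.csv: trial_id must be contiguous from 0")
    neurons = pd.read_csv(os.path.join(directory, "neurons.csv"))
    if neurons["neuron_id"].duplicated().any():
        raise ValueError("neurons.csv: duplicate neuron_id")
    missing = [c for c in category_names if c not in trials.columns]
    if missing:
        raise ValueError(f"trials.csv: missing category columns {missing}")
    labels = trials[list(category_names)].to_numpy(dtype=np.int8)
    n_trials, n_neurons = len(trials), len(neurons)
    spikes = _read_spikes(
        os.path.join(directory, "spikes.csv"), n_trials, n_neurons, window_ms
    )
    pre_path = os.path.join(directory, "presample_spikes.csv")
    presample = (
        _read_spikes(pre_path, n_trials, n_neurons, window_ms)
        if os.path.exists(pre_path)
        else None
    )
    ground_truth = {}
    for entry in meta.get("ground_truth", []):
        ground_truth[(entry["neuron"], entry["category"])] = tuple(
            Bump(*b) for b in entry["bumps"]
        )
    return SpikeEnsemble(
        window_ms=window_ms,
        category_names=category_names,
        regions=tuple(neurons["region"]),
        labels=labels,
        spikes=spikes,
        presample_spikes=presample,
        event_type=str(meta.get("event_type", "SampleResponse")),
        ground_truth=ground_truth,
        provenance=dict(meta.get("provenance", {})),
    )


def write_results(bundle: dict, directory: str) -> None:
    """Write a pipeline result bundle (metrics table, predictions,
    optional sparseness / importance tables) as delimited text."""
    os.makedirs(directory, exist_ok=True)
    result = bundle["result"]
    result.metrics_table().to_csv(
        os.path.join(directory, "metrics.csv"), index=False
    )
    preds = pd.DataFrame(
        {
            "trial_id": np.arange(len(result.categories[0].y_true)),
            **{
                f"{c.category}_true": c.y_true for c in result.categories
            },
            **{
                f"{c.category}_prob": c.oof_prob for c in result.categories
            },
        }
    )
    preds.to_csv(os.path.join(directory, "predictions.csv"), index=False)
    for key in ("sparseness", "resolution_profile", "importance"):
        obj = bundle.get(key)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(os.path.join(directory, f"{key}.csv"), index=False)
    with open(os.path.join(directory, "run.yaml"), "w") as fh:
        yaml.safe_dump(bundle.get("run_info", {}), fh, sort_keys=False)
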