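"""On-disk formats: long-format trial CSVs, dictionary CSV + JSON sidecars.

Trials are written one row per (trial, time point) with columns
trial_id, class_label, t, sensor_1 ... sensor_s.  Dictionaries and
coefficient matrices are plain CSV matrices with a JSON metadata sidecar
(method, hyperparameters, group structure) so any run can be reloaded
without the fitting code.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import FactorizationResult, SynergyDictionary
from .groups import build_joint_groups
from .preprocessing import KinematicDataset, TrialRecording, devectorize


def write_trials_csv(dataset: KinematicDataset, path: str | Path) -> None:
    """Write a vectorized dataset back out as long-format trial rows."""
    rows = []
    for i in range(dataset.n):
        series = devectorize(dataset.X[i], dataset.s, dataset.length)
        for t in range(dataset.length):
            row = {"trial_id": i, "class_label": dataset.labels[i], "t": t}
            row.update({f"sensor_{j + 1}": series[t, j] for j in range(dataset.s)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> list[TrialRecording]:
    """Read long-format trial rows into TrialRecording objects."""
    df = pd.read_csv(path)
    sensor_cols = sorted(
        (c for c in df.columns if c.startswith("sensor_")),
        key=lambda c: int(c.split("_")[1]),
    )
    trials = []
    for trial_id, sub in df.groupby("trial_id", sort=True):
        sub = sub.sort_values("t")
        trials.append(TrialRecording(
            trial_id=int(trial_id),
            class_label=str(sub["class_label"].iloc[0]),
            angles=sub[sensor_cols].to_numpy(dtype=float),
        ))
    return trials


def write_factorization(result: FactorizationResult, out_dir: str | Path,
                        stem: str = "factorization") -> None:
    """Dictionary and coefficients as CSV matrices plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / f"{stem}_V.csv", result.dictionary.V, delimiter=",")
    np.savetxt(out_dir / f"{stem}_U.csv", result.U, delimiter=",")
    gs = result.dictionary.group_structure
    meta = {
        "method": result.dictionary.method,
        "r": result.dictionary.r,
        "lambda": result.lambda_,
        "eta": result.eta,
        "seed": result.seed,
        "converged": bool(result.converged),
        "objective_trace": [float(v) for v in result.objective_trace],
        "group_structure": None if gs is None else {"s": gs.s, "length": gs.length},
        "mean": None if result.dictionary.mean is None
        else [float(v) for v in result.dictionary.mean],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))


def read_factorization(out_dir: str | Path,
                       stem: str = "factorization") -> FactorizationResult:
    """Inverse of :func:`write_factorization`."""
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.json").read_text())
    V = np.loadtxt(out_dir / f"{stem}_V.csv", delimiter=",", ndmin=2)
    U = np.loadtxt(out_dir / f"{stem}_U.csv", delimiter=",", ndmin=2)
    gs_meta = meta["group_structure"]
    gs = None if gs_meta is None else build_joint_groups(gs_meta["s"], gs_meta["length"])
    dictionary = SynergyDictionary(
        V=V, r=meta["r"], group_structure=gs, method=meta["method"],
        mean=None if meta["mean"] is None else np.asarray(meta["mean"], float),
    )
    return FactorizationResult(
        dictionary=dictionary, U=U, lambda_=meta["lambda"], eta=meta["eta"],
        objective_trace=np.asarray(meta["objective_trace"], float),
        converged=meta["converged"], seed=meta["seed"],
    )


def write_raster_csv(results, path: str | Path) -> None:
    """Rasters as tidy (class, level, neuron, bin, spike) rows."""
    rows = []
    for res in results:
        for level, spikes in (("command", res.command_spikes),
                              ("synergy", res.synergy_spikes)):
            neuron, bin_ = np.nonzero(spikes)
            for nn, bb in zip(neuron, bin_):
                rows.append({"class_index": res.class_index, "level": level,
                             "neuron": int(nn), "bin": int(bb), "spike": 1})
    pd.DataFrame(rows, columns=["class_index", "level", "neuron", "bin",
                                "spike"]).to_csv(path, index=False)
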