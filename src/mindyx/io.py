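"""Reading and writing the package's file formats.

Model archives are HDF5 containers with datasets Ws, W1, W2, alpha, D, B and
scalar attributes (b, n, k, TR, format version). Runs travel as TSV
(parcels as rows, volumes as columns, a header row of volume indices) or
HDF5; events as BIDS-like TSV (onset, duration, trial_type); framewise
displacement as single-column TSV; attractor sets as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .attractors import AttractorSet, Equilibrium, LimitCycle
from .model import MindyXParams
from .preprocess import BoldRun

__all__ = [
    "save_model", "load_model",
    "save_run_tsv", "load_run_tsv",
    "load_events_tsv", "load_fd_tsv",
    "attractors_to_json", "attractors_from_json",
    "save_attractors", "load_attractors",
]

FORMAT_VERSION = "mindyx-model-1"


def save_model(path, params: MindyXParams) -> None:
    with h5py.File(path, "w") as f:
        for name in ("Ws", "W1", "W2", "alpha", "D", "B"):
            # track_times=False keeps archives byte-identical across reruns
            f.create_dataset(name, data=getattr(params, name),
                             track_times=False)
        f.attrs["b"] = params.b
        f.attrs["n"] = params.n
        f.attrs["k"] = params.k
        if params.tr is not None:
            f.attrs["TR"] = params.tr
        f.attrs["format"] = FORMAT_VERSION


def load_model(path) -> MindyXParams:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != FORMAT_VERSION:
            raise ValueError(f"not a {FORMAT_VERSION} archive: {path}")
        return MindyXParams(
            Ws=f["Ws"][()], W1=f["W1"][()], W2=f["W2"][()],
            alpha=f["alpha"][()], D=f["D"][()], B=f["B"][()],
            b=float(f.attrs["b"]),
            tr=float(f.attrs["TR"]) if "TR" in f.attrs else None,
        )


def save_run_tsv(path, run: BoldRun) -> None:
    """Run as TSV: one parcel per row, volumes as columns; condition labels
    in a companion ``<path>.labels.tsv`` when present."""
    df = pd.DataFrame(run.data, columns=np.arange(run.n_volumes))
    df.to_csv(path, sep="\t", index=False)
    if run.condition is not None:
        pd.DataFrame({"condition": run.condition}).to_csv(
            str(path) + ".labels.tsv", sep="\t", index=False)


def load_run_tsv(path, tr: float, run_id: str = "", modality: str = "rest",
                 kind: str = "bold") -> BoldRun:
    data = pd.read_csv(path, sep="\t").to_numpy(dtype=np.float64)
    labels_path = Path(str(path) + ".labels.tsv")
    condition = None
    if labels_path.exists():
        condition = pd.read_csv(labels_path, sep="\t")["condition"].to_numpy(object)
    return BoldRun(data=data, tr=tr, condition=condition,
                   run_id=run_id or Path(path).stem, modality=modality, kind=kind)


def load_events_tsv(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(ev.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    return ev


def load_fd_tsv(path) -> np.ndarray:
    """Single headerless column: one framewise-displacement value (mm) per
    volume."""
    return pd.read_csv(path, sep="\t", header=None).iloc[:, 0].to_numpy(
        dtype=np.float64)


def attractors_to_json(attrs: AttractorSet) -> str:
    obj = {
        "input": None if attrs.input is None else np.asarray(attrs.input).tolist(),
        "topology": attrs.topology,
        "unclassified_flag": bool(attrs.unclassified_flag),
        "equilibria": [
            {"x_star": e.x_star.tolist(), "basin_count": int(e.basin_count)}
            for e in attrs.equilibria
        ],
        "cycles": [
            {"orbit": c.orbit.tolist(), "period": int(c.period),
             "basin_count": int(c.basin_count)}
            for c in attrs.cycles
        ],
    }
    return json.dumps(obj, indent=1)


def attractors_from_json(text: str) -> AttractorSet:
    obj = json.loads(text)
    return AttractorSet(
        equilibria=[Equilibrium(np.asarray(e["x_star"]), int(e["basin_count"]))
                    for e in obj["equilibria"]],
        cycles=[LimitCycle(np.asarray(c["orbit"]), int(c["period"]),
                           int(c["basin_count"])) for c in obj["cycles"]],
        input=None if obj["input"] is None else np.asarray(obj["input"]),
        topology=obj["topology"],
        unclassified_flag=obj["unclassified_flag"],
    )


def save_attractors(path, attrs: AttractorSet) -> None:
    Path(path).write_text(attractors_to_json(attrs))


def load_attractors(path) -> AttractorSet:
    return attractors_from_json(Path(path).read_text())
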