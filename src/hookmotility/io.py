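"""Plain-text and TIFF interchange for every pipeline object.

Trajectories travel as CSV (cell_id, t_s, x_um, y_um) with ground truth in
sidecar CSVs; image stacks as multi-page TIFF with a YAML metadata sidecar
(pixel_size_um, frame_interval_s, modality); models, fits and summaries as
JSON; configs as flat YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .optics import ImageStack
from .rtmodel import CorrelationCurve
from .tracking import TumbleModel
from .tracks import CellTruth, TrackSet, Trajectory

__all__ = [
    "write_trackset", "read_trackset",
    "write_image_stack", "read_image_stack",
    "write_tumble_model", "read_tumble_model",
    "write_curve", "read_curve",
    "write_json", "read_json",
    "load_config", "save_config",
]


def write_trackset(tracks: TrackSet, path) -> None:
    """Write trajectories and, when present, ground-truth sidecars.

    ``path`` is the trajectory CSV; sidecars are derived from it:
    ``<stem>.truth.csv`` (per-cell ψ, speed), ``<stem>.tumbles.csv``
    (tumble event times) and ``<stem>.truth_xy.csv`` (unwrapped positions).
    """
    path = Path(path)
    rows = []
    for traj in tracks:
        rows.append(pd.DataFrame({"cell_id": traj.cell_id, "t_s": traj.times,
                                  "x_um": traj.x, "y_um": traj.y}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if tracks.ground_truth:
        stem = path.with_suffix("")
        params = pd.DataFrame(
            [{"cell_id": cid, "psi_rad_s": ct.psi, "speed_um_s": ct.speed}
             for cid, ct in sorted(tracks.ground_truth.items())])
        params.to_csv(stem.with_suffix(".truth.csv"), index=False)
        ev = [{"cell_id": cid, "t_s": t}
              for cid, ct in sorted(tracks.ground_truth.items())
              for t in np.asarray(ct.tumble_times).ravel()]
        pd.DataFrame(ev, columns=["cell_id", "t_s"]).to_csv(
            stem.with_suffix(".tumbles.csv"), index=False)
        xy = []
        for traj in tracks:
            ct = tracks.ground_truth.get(traj.cell_id)
            if ct is not None and ct.x_true is not None:
                xy.append(pd.DataFrame({"cell_id": traj.cell_id, "t_s": traj.times,
                                        "x_um": ct.x_true, "y_um": ct.y_true}))
        if xy:
            pd.concat(xy, ignore_index=True).to_csv(
                stem.with_suffix(".truth_xy.csv"), index=False)


def read_trackset(path) -> TrackSet:
    """Read a trajectory CSV (plus sidecars if present) back into a TrackSet."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"cell_id", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    trajs = [Trajectory(g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                        g["y_um"].to_numpy(), cell_id=int(cid))
             for cid, g in df.groupby("cell_id", sort=True)]
    stem = path.with_suffix("")
    truth = None
    tpath = stem.with_suffix(".truth.csv")
    if tpath.exists():
        truth = {}
        params = pd.read_csv(tpath)
        for _, row in params.iterrows():
            truth[int(row["cell_id"])] = CellTruth(psi=float(row["psi_rad_s"]),
                                                   speed=float(row["speed_um_s"]))
        epath = stem.with_suffix(".tumbles.csv")
        if epath.exists():
            ev = pd.read_csv(epath)
            for cid, g in ev.groupby("cell_id"):
                if int(cid) in truth:
                    truth[int(cid)].tumble_times = g["t_s"].to_numpy()
        xpath = stem.with_suffix(".truth_xy.csv")
        if xpath.exists():
            xy = pd.read_csv(xpath)
            for cid, g in xy.groupby("cell_id"):
                if int(cid) in truth:
                    truth[int(cid)].x_true = g["x_um"].to_numpy()
                    truth[int(cid)].y_true = g["y_um"].to_numpy()
    return TrackSet(trajs, ground_truth=truth)


def write_image_stack(stack: ImageStack, path) -> None:
    """Multi-page TIFF plus a YAML metadata sidecar ``<stem>.meta.yaml``."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    meta = {"pixel_size_um": float(stack.pixel_size),
            "frame_interval_s": float(stack.frame_interval),
            "modality": stack.modality}
    path.with_suffix("").with_suffix(".meta.yaml").write_text(
        yaml.safe_dump(meta), encoding="utf-8")


def read_image_stack(path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta_path = path.with_suffix("").with_suffix(".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
    return ImageStack(frames=frames, pixel_size=meta["pixel_size_um"],
                      frame_interval=meta["frame_interval_s"],
                      modality=meta.get("modality", "phase"))


def write_tumble_model(model: TumbleModel, path) -> None:
    obj = {"transition_matrix": model.transition_matrix.tolist(),
           "means": model.means.tolist(),
           "covariances": model.covariances.tolist(),
           "initial_probs": model.initial_probs.tolist()}
    Path(path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


def read_tumble_model(path) -> TumbleModel:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    return TumbleModel(transition_matrix=np.array(obj["transition_matrix"]),
                       means=np.array(obj["means"]),
                       covariances=np.array(obj["covariances"]),
                       initial_probs=np.array(obj["initial_probs"]))


def write_curve(curve: CorrelationCurve, path) -> None:
    pd.DataFrame({"lag_s": curve.lags, "value": curve.values,
                  "n_pairs": curve.n_pairs}).to_csv(path, index=False)


def read_curve(path, kind: str = "acf") -> CorrelationCurve:
    df = pd.read_csv(path)
    return CorrelationCurve(lags=df["lag_s"].to_numpy(),
                            values=df["value"].to_numpy(),
                            n_pairs=df["n_pairs"].to_numpy(), kind=kind)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder),
                          encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def load_config(path) -> dict:
    """Flat key-value YAML config; a ``seed`` key is required."""
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("config must declare a seed")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
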