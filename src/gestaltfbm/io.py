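"""File I/O helpers: session CSVs, MUA HDF5 containers, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from gestaltfbm.ephys_preproc import MUADataset, SiteRecording

__all__ = [
    "save_session_csv", "load_session_csv",
    "save_mua_h5", "load_mua_h5",
    "save_json", "load_json", "load_yaml", "save_yaml",
    "save_stimulus_png",
]


def save_session_csv(session: pd.DataFrame, path) -> None:
    session.to_csv(path, index=False)


def load_session_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict("records")
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def load_json(path):
    return json.loads(Path(path).read_text())


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def save_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def save_mua_h5(dataset: MUADataset, path) -> None:
    """Write an MUADataset to an HDF5 container (one group per site)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=dataset.time_ms)
        f.attrs["sample_rate"] = dataset.sample_rate
        f.attrs["state"] = json.dumps(dataset.state)
        f.attrs["meta"] = json.dumps(dataset.meta, default=str)
        f.attrs["ground_truth"] = json.dumps(dataset.ground_truth,
                                             default=str)
        grp_all = f.create_group("sites")
        for site in dataset.sites:
            g = grp_all.create_group(site.site_id)
            g.create_dataset("data", data=site.data)
            g.attrs["monkey"] = site.monkey
            g.attrs["area"] = site.area
            g.attrs["array_id"] = site.array_id
            g.attrs["meta"] = json.dumps(site.meta, default=str)
            g.attrs["trials"] = site.trials.to_json(orient="split")


def load_mua_h5(path) -> MUADataset:
    with h5py.File(path, "r") as f:
        sites = []
        for sid, g in f["sites"].items():
            sites.append(SiteRecording(
                site_id=sid, data=g["data"][()],
                trials=pd.read_json(__import__("io").StringIO(
                    g.attrs["trials"]), orient="split"),
                monkey=g.attrs["monkey"], area=g.attrs["area"],
                array_id=g.attrs["array_id"],
                meta=json.loads(g.attrs["meta"])))
        return MUADataset(
            sites=sites, time_ms=f["time_ms"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            state=json.loads(f.attrs["state"]),
            ground_truth=json.loads(f.attrs["ground_truth"]),
            meta=json.loads(f.attrs["meta"]))


def save_stimulus_png(stim, path) -> None:
    """8-bit PNG of a stimulus with a JSON luminance-calibration sidecar."""
    import matplotlib.image as mpimg

    path = Path(path)
    mpimg.imsave(path, stim.image, cmap="gray", vmin=0.0,
                 vmax=stim.geometry.max_luminance)
    sidecar = {
        "max_luminance_cd_m2": stim.geometry.max_luminance,
        "pixels_per_degree": stim.geometry.pixels_per_degree,
        "center_deg": list(stim.center_deg),
        "cue": stim.spec.cue,
        "seed": stim.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    np.save(path.with_suffix(".labels.npy"), stim.labels)
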