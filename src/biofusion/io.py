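"""Persistence: recordings (HDF5 / CSV+JSON / EDF), window and image sets.

The HDF5 container mirrors the session structure::

    /trials/<t>/reps/<r>/samples   (5, N) float32, mV
        attrs: speed_label, weight_label, start_marker, end_marker
    root attrs: subject_id, sampling_rate, channel_names

The CSV alternative is a directory of ``trial_<t>/rep_<r>/samples.csv``
(one column per channel) with a ``metadata.json`` sidecar per repetition.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .imaging import ImageDataset, LAYOUTS
from .preprocess import WindowSet
from .session import CHANNEL_NAMES, Recording, Repetition, Trial

_REP_KEYS = ("speed_label", "weight_label", "start_marker", "end_marker")


class SchemaError(KeyError):
    """A required metadata key is missing from a stored recording."""


def _require(mapping, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing metadata key '{key}' in {where}")
    return mapping[key]


# -- recordings: HDF5 ------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to one HDF5 container."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["channel_names"] = list(rec.channel_names)
        for ti, t in enumerate(rec.trials):
            for ri, r in enumerate(t.reps):
                d = f.create_dataset(f"trials/{ti}/reps/{ri}/samples",
                                     data=r.samples.astype(np.float32))
                d.attrs["speed_label"] = t.speed_label
                d.attrs["weight_label"] = float(t.weight_label)
                d.attrs["start_marker"] = int(r.start_marker)
                d.attrs["end_marker"] = int(r.end_marker)
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (or CSV dir)."""
    path = Path(path)
    if path.is_dir():
        return read_recording_csv(path)
    with h5py.File(path, "r") as f:
        subject = str(_require(f.attrs, "subject_id", "root"))
        fs = float(_require(f.attrs, "sampling_rate", "root"))
        trials = []
        for ti in sorted(f["trials"], key=int):
            g = f[f"trials/{ti}/reps"]
            reps, speed, weight = [], None, None
            for ri in sorted(g, key=int):
                d = g[f"{ri}/samples"]
                where = f"trial {ti} rep {ri}"
                speed = str(_require(d.attrs, "speed_label", where))
                weight = float(_require(d.attrs, "weight_label", where))
                reps.append(Repetition(
                    d[()],
                    int(_require(d.attrs, "start_marker", where)),
                    int(_require(d.attrs, "end_marker", where)),
                ))
            trials.append(Trial(speed, weight, reps))
    return Recording(subject, fs, trials)


# -- recordings: CSV + JSON sidecars ---------------------------------------

def write_recording_csv(rec: Recording, root: str | Path) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "session.json").write_text(json.dumps({
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "channel_names": list(rec.channel_names),
    }, indent=2))
    for ti, t in enumerate(rec.trials):
        for ri, r in enumerate(t.reps):
            d = root / f"trial_{ti:02d}" / f"rep_{ri:02d}"
            d.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(r.samples.T, columns=list(rec.channel_names)
                         ).to_csv(d / "samples.csv", index=False)
            (d / "metadata.json").write_text(json.dumps({
                "speed_label": t.speed_label,
                "weight_label": float(t.weight_label),
                "start_marker": int(r.start_marker),
                "end_marker": int(r.end_marker),
            }, indent=2))
    return root


def read_recording_csv(root: str | Path) -> Recording:
    root = Path(root)
    session = json.loads((root / "session.json").read_text())
    subject = str(_require(session, "subject_id", "session.json"))
    fs = float(_require(session, "sampling_rate", "session.json"))
    trials = []
    for tdir in sorted(root.glob("trial_*")):
        reps, speed, weight = [], None, None
        for rdir in sorted(tdir.glob("rep_*")):
            meta = json.loads((rdir / "metadata.json").read_text())
            where = f"{tdir.name}/{rdir.name}/metadata.json"
            speed = str(_require(meta, "speed_label", where))
            weight = float(_require(meta, "weight_label", where))
            samples = pd.read_csv(rdir / "samples.csv").to_numpy().T
            reps.append(Repetition(
                samples.astype(np.float32),
                int(_require(meta, "start_marker", where)),
                int(_require(meta, "end_marker", where)),
            ))
        trials.append(Trial(speed, weight, reps))
    return Recording(subject, fs, trials)


# -- recordings: EDF import ------------------------------------------------

def read_recording_edf(path: str | Path, speed_label: str = "slow",
                       weight_label: float = 0.0,
                       markers: tuple[int, int] | None = None,
                       channel_map: dict[str, str] | None = None) -> Recording:
    """Import a 5-channel EDF file as a single-trial recording.

    Channel labels are mapped by (case-insensitive substring) name to the
    canonical [C3, C4, Cz, biceps, triceps] order, or explicitly via
    ``channel_map`` (EDF label -> canonical name).  Trial metadata is not
    part of EDF, so speed/weight/markers are supplied by the caller
    (markers default to the full span).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e3  # MNE returns volts; sessions are in mV
    names = raw.ch_names
    if channel_map is None:
        channel_map = {}
        for label in names:
            for canon in CHANNEL_NAMES:
                if canon.lower() in label.lower():
                    channel_map[label] = canon
                    break
    rows = {}
    for label, canon in channel_map.items():
        rows[canon] = data[names.index(label)]
    missing = [c for c in CHANNEL_NAMES if c not in rows]
    if missing:
        raise SchemaError(f"EDF channels could not be mapped to {missing}")
    samples = np.stack([rows[c] for c in CHANNEL_NAMES]).astype(np.float32)
    n = samples.shape[1]
    start, end = markers or (0, n)
    rep = Repetition(samples, start, end)
    return Recording(Path(path).stem, float(raw.info["sfreq"]),
                     [Trial(speed_label, float(weight_label), [rep])])


# -- window sets -----------------------------------------------------------

def save_windows(ws: WindowSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = ws.subject_id
        f.attrs["sampling_rate"] = ws.sampling_rate
        f.attrs["class_weights"] = list(ws.class_weights)
        f.create_dataset("windows", data=ws.samples)
        f.create_dataset("labels", data=ws.weight_class)
        f.create_dataset("meta/weight_label", data=ws.weight_label)
        f.create_dataset("meta/speed_label",
                         data=np.array(ws.speed_label, dtype="S"))
        f.create_dataset("meta/trial_index", data=ws.trial_index)
        f.create_dataset("meta/rep_index", data=ws.rep_index)
        f.create_dataset("meta/window_index", data=ws.window_index)
    return path


def load_windows(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as f:
        return WindowSet(
            subject_id=str(f.attrs["subject_id"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            samples=f["windows"][()],
            weight_class=f["labels"][()],
            weight_label=f["meta/weight_label"][()],
            speed_label=f["meta/speed_label"][()].astype(str).astype(object),
            trial_index=f["meta/trial_index"][()],
            rep_index=f["meta/rep_index"][()],
            window_index=f["meta/window_index"][()],
            class_weights=tuple(f.attrs["class_weights"]),
        )


def windows_meta_table(ws: WindowSet) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": ws.subject_id,
        "weight_class": ws.weight_class,
        "weight_label": ws.weight_label,
        "speed_label": ws.speed_label.astype(str),
        "trial_index": ws.trial_index,
        "rep_index": ws.rep_index,
        "window_index": ws.window_index,
    })


# -- image datasets --------------------------------------------------------

def save_images(ds: ImageDataset, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout"] = ds.layout
        f.attrs["subject_id"] = ds.subject_id
        f.attrs["row_order"] = list(ds.row_order)
        f.attrs["n_classes"] = ds.n_classes
        f.create_dataset("images", data=ds.images.astype(np.float32))
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("meta/weight_label", data=ds.weight_label)
        f.create_dataset("meta/speed_label",
                         data=np.array(ds.speed_label, dtype="S"))
        f.create_dataset("meta/trial_index", data=ds.trial_index)
        f.create_dataset("meta/rep_index", data=ds.rep_index)
    return path


def load_images(path: str | Path) -> ImageDataset:
    with h5py.File(path, "r") as f:
        layout = str(f.attrs["layout"])
        if layout not in LAYOUTS:
            raise SchemaError(f"unknown layout '{layout}' in {path}")
        return ImageDataset(
            layout=layout,
            subject_id=str(f.attrs["subject_id"]),
            images=f["images"][()],
            labels=f["labels"][()],
            weight_label=f["meta/weight_label"][()],
            speed_label=f["meta/speed_label"][()].astype(str).astype(object),
            rep_index=f["meta/rep_index"][()],
            trial_index=f["meta/trial_index"][()],
            row_order=tuple(f.attrs["row_order"]),
            n_classes=int(f.attrs["n_classes"]),
        )


def export_png(ds: ImageDataset, out_dir: str | Path,
               indices: list[int] | None = None) -> list[Path]:
    """Write selected images as 8-bit PNGs (value x 255) for inspection."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in indices or range(min(len(ds), 10)):
        img = ds.images[i]
        if img.ndim == 3:  # depth-stacked: tile channels side by side
            img = np.concatenate([img[..., c] for c in range(img.shape[-1])],
                                 axis=1)
        arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
        p = out / f"{ds.layout}_{i:05d}.png"
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths
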