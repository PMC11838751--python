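"""Readers and writers for the pipeline's on-disk formats.

Recordings travel as HDF5 (dataset ``signals`` in uV with ``fs`` and channel
attributes) or 16-column delimited text, each with a JSON sidecar carrying
layout/ground-truth pointers and provenance (config hash, package version).
Tables are CSV, movies and float maps multi-page TIFF, meshes legacy-VTK
ASCII (see :mod:`shellmea.spheremap`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .activation import LATTable, OrderConfusion
from .sigproc import MultichannelRecording
from .synth import FrameStack

__all__ = [
    "save_recording_h5", "load_recording_h5",
    "save_recording_text", "load_recording_text",
    "write_sidecar", "provenance",
    "save_lat_table", "load_lat_table",
    "save_confusion", "save_stack_tiff", "load_stack_tiff",
    "save_float_tiff", "load_float_tiff",
]


def provenance(config: dict | None = None) -> dict:
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    return {"tool": "shellmea", "version": __version__,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


def write_sidecar(path, config: dict | None = None, **extra) -> None:
    doc = {"provenance": provenance(config)}
    if config is not None:
        doc["config"] = config
    doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)


# -- recordings --------------------------------------------------------------

def save_recording_h5(path, rec: MultichannelRecording) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signals", data=rec.signals)
        d.attrs["fs"] = rec.fs
        d.attrs["units"] = "uV"
        d.attrs["t0"] = rec.t0
        d.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]


def load_recording_h5(path) -> MultichannelRecording:
    with h5py.File(path, "r") as f:
        d = f["signals"]
        ids = tuple(c.decode() if isinstance(c, bytes) else str(c)
                    for c in d.attrs["channel_ids"])
        return MultichannelRecording(d[...], float(d.attrs["fs"]), ids,
                                     float(d.attrs.get("t0", 0.0)))


def save_recording_text(path, rec: MultichannelRecording) -> None:
    """Delimited text: one column per channel, header row of channel ids."""
    header = "\t".join(str(c) for c in rec.channel_ids)
    np.savetxt(path, rec.signals.T, delimiter="\t", header=header,
               comments="", fmt="%.6g")


def load_recording_text(path, fs: float, t0: float = 0.0
                        ) -> MultichannelRecording:
    with open(path) as fh:
        ids = tuple(fh.readline().strip().split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return MultichannelRecording(np.atleast_2d(data).T, fs, ids, t0)


# -- tables ------------------------------------------------------------------

def save_lat_table(path, table: LATTable) -> None:
    table.to_frame().to_csv(path)


def load_lat_table(path) -> LATTable:
    df = pd.read_csv(path, index_col=0)
    return LATTable(tuple(df.index), df.to_numpy())


def save_confusion(path, conf: OrderConfusion) -> None:
    df = conf.to_frame()
    df.attrs["accuracy"] = conf.accuracy
    df.to_csv(path)


# -- images ------------------------------------------------------------------

def save_stack_tiff(path, stack: FrameStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     metadata={"frame_rate": stack.frame_rate,
                               "pixel_size_um": stack.pixel_size})


def load_stack_tiff(path, frame_rate: float | None = None,
                    pixel_size: float | None = None) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    fr = frame_rate if frame_rate is not None else float(
        meta.get("frame_rate", 60.0))
    px = pixel_size if pixel_size is not None else float(
        meta.get("pixel_size_um", 1.0))
    return FrameStack(frames, fr, px)


def save_float_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def load_float_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
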