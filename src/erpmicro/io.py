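"""On-disk formats: delimited matrices, CSV tables, JSON manifests, EDF.

ERP matrices are written as tab-delimited text (channels x samples) with a
JSON sidecar carrying fs, window and trial counts; inverse kernels go to a
binary array container (.npz) with a JSON header.  A manifest records every
file a pipeline run writes, together with shapes and the seeds consumed, so
a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, Erp
from .errors import FormatError
from .montage import Montage, read_sfp, write_sfp  # noqa: F401  (re-export)


def write_matrix(path, data: np.ndarray) -> None:
    np.savetxt(path, np.asarray(data), delimiter="\t", fmt="%.12g")


def read_matrix(path) -> np.ndarray:
    try:
        return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_erp(path_base, erp: Erp) -> list[str]:
    """Write one ERP as <base>.tsv plus <base>.json sidecar."""
    base = Path(path_base)
    write_matrix(base.with_suffix(".tsv"), erp.data)
    meta = {
        "fs": erp.fs, "window_ms": list(erp.window), "n_trials": erp.n_trials,
        "condition": erp.condition, "subject": erp.subject,
        "shape": list(erp.data.shape),
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return [str(base.with_suffix(".tsv")), str(base.with_suffix(".json"))]


def read_erp(path_base) -> Erp:
    base = Path(path_base)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = read_matrix(base.with_suffix(".tsv"))
    if list(data.shape) != meta["shape"]:
        raise FormatError(f"{base}: matrix shape {data.shape} != manifest {meta['shape']}")
    return Erp(data, meta["fs"], tuple(meta["window_ms"]), meta["n_trials"],
               meta["condition"], meta["subject"])


def write_kernel(path, kernel: np.ndarray, **header) -> None:
    """Binary array container with a JSON header (shape, model parameters)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), kernel=kernel)
    header = {"shape": list(kernel.shape), **header}
    path.with_suffix(".hdr.json").write_text(json.dumps(header, indent=1))


def read_kernel(path):
    path = Path(path)
    kernel = np.load(path.with_suffix(".npz"))["kernel"]
    header = json.loads(path.with_suffix(".hdr.json").read_text())
    if list(kernel.shape) != header["shape"]:
        raise FormatError(f"{path}: kernel shape mismatch with header")
    return kernel, header


def read_edf(path, montage: Montage | None = None) -> ContinuousRecording:
    """Load a continuous EDF recording (channels x samples, uV)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> uV
    if montage is not None and data.shape[0] != montage.n_channels:
        raise FormatError(
            f"EDF has {data.shape[0]} channels, montage expects {montage.n_channels}"
        )
    events = []
    for onset, _dur, desc in zip(raw.annotations.onset, raw.annotations.duration,
                                 raw.annotations.description):
        events.append((int(round(onset * raw.info["sfreq"])), str(desc)))
    return ContinuousRecording(data, float(raw.info["sfreq"]), montage, events)


class Manifest:
    """Run log: files written, array shapes, seeds, package versions."""

    def __init__(self, out_dir, seed: int | None = None):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        import numpy, pandas, scipy  # noqa: PLC0415

        self.record: dict = {
            "seed": seed,
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
            },
            "files": [],
            "stages": {},
        }

    def add(self, *paths) -> None:
        for p in paths:
            self.record["files"].append(str(Path(p).relative_to(self.out_dir)))

    def note(self, stage: str, **info) -> None:
        self.record["stages"].setdefault(stage, {}).update(info)

    def write_csv(self, name: str, frame: pd.DataFrame) -> Path:
        path = self.out_dir / name
        frame.to_csv(path, index=False)
        self.add(path)
        return path

    def save(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.record, indent=1, default=str))
        return path
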