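"""Plain-text serialization of datasets, ground truth and results.

The internal on-disk format for a dataset is a directory holding
``spectra.tsv`` (pixel_x, pixel_y, label, mz, intensity — one row per peak)
plus a ``meta.json`` sidecar with raster metadata and the processing log.
When ground truth is available it is written alongside as
``ground_truth.tsv`` and ``layout.json``.  All floats are written with
enough digits to round-trip, so regenerating with the same seed produces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import IMSDataset, Spectrum
from .synthetic import GroundTruth, TissueLayout

__all__ = ["write_dataset", "read_dataset", "write_ground_truth", "read_layout"]

_FLOAT_FMT = "%.12g"


def write_dataset(path: "str | Path", dataset: IMSDataset,
                  ground_truth: Optional[GroundTruth] = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for sp in dataset.spectra:
        for mz, inten in zip(sp.mz, sp.intensity):
            rows.append((sp.x, sp.y, sp.label, mz, inten))
    frame = pd.DataFrame(rows, columns=["pixel_x", "pixel_y", "label", "mz", "intensity"])
    frame.to_csv(path / "spectra.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    meta = {
        "width": dataset.width,
        "height": dataset.height,
        "pixel_spacing_um": dataset.pixel_spacing,
        "mass_range": list(dataset.mass_range),
        "processing_log": dataset.processing_log,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    if ground_truth is not None:
        write_ground_truth(path, ground_truth)
    return path


def write_ground_truth(path: "str | Path", gt: GroundTruth) -> None:
    path = Path(path)
    rows = []
    for i in range(gt.pixels.shape[0]):
        for s, name in enumerate(gt.species_names):
            for a, adduct in enumerate(gt.adducts):
                rows.append(
                    (
                        int(gt.pixels[i, 0]),
                        int(gt.pixels[i, 1]),
                        str(gt.labels[i]),
                        name,
                        adduct,
                        gt.intensities[i, s, a],
                    )
                )
    frame = pd.DataFrame(
        rows, columns=["pixel_x", "pixel_y", "label", "species", "adduct", "intensity"]
    )
    frame.to_csv(path / "ground_truth.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    layout = gt.layout

    def grid_to_lists(arr: np.ndarray) -> list:
        out = np.where(np.isnan(arr), None, np.round(arr.astype(float), 10))
        return [[None if v is None else float(v) for v in row] for row in out.tolist()]

    payload = {
        "grid": gt.layout.grid.astype(int).tolist(),
        "pixel_spacing_um": layout.pixel_spacing,
        "crypt_axis": grid_to_lists(layout.crypt_axis),
        "mucosa_axis": grid_to_lists(layout.mucosa_axis),
        "crypt_centers": [int(c) for c in layout.crypt_centers],
    }
    (path / "layout.json").write_text(json.dumps(payload, sort_keys=True))


def read_layout(path: "str | Path") -> TissueLayout:
    payload = json.loads((Path(path) / "layout.json").read_text())

    def lists_to_grid(rows: list) -> np.ndarray:
        return np.array(
            [[np.nan if v is None else float(v) for v in row] for row in rows]
        )

    return TissueLayout(
        grid=np.array(payload["grid"], dtype=np.int8),
        pixel_spacing=float(payload["pixel_spacing_um"]),
        crypt_axis=lists_to_grid(payload["crypt_axis"]),
        mucosa_axis=lists_to_grid(payload["mucosa_axis"]),
        crypt_centers=list(payload["crypt_centers"]),
    )


def read_dataset(path: "str | Path") -> IMSDataset:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    frame = pd.read_csv(path / "spectra.tsv", sep="\t")
    frame["label"] = frame["label"].fillna("")
    spectra = []
    for (x, y, label), grp in frame.groupby(["pixel_x", "pixel_y", "label"], sort=True):
        spectra.append(
            Spectrum(int(x), int(y), grp["mz"].to_numpy(), grp["intensity"].to_numpy(), str(label))
        )
    return IMSDataset(
        spectra,
        width=int(meta["width"]),
        height=int(meta["height"]),
        pixel_spacing=float(meta["pixel_spacing_um"]),
        mass_range=tuple(meta["mass_range"]),
        processing_log=list(meta["processing_log"]),
    )
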