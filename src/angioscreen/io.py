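"""TIFF and CSV readers/writers.

Images travel as single-channel TIFF (16-bit for intensities, 8-bit for the
{0,1,2} mask); tables as CSV. Network ground truth is a branch/junction CSV
pair plus a label-grid TIFF, so a synthetic chip round-trips losslessly.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .synth.network import Branch, NetworkTruth
from .types import ChipGeometry, ChipImage, VesselMask


def write_image(path, image: ChipImage) -> None:
    arr = np.round(np.asarray(image.data)).astype(
        np.uint16 if image.bit_depth > 8 else np.uint8
    )
    tifffile.imwrite(str(path), arr)


def read_image(
    path,
    geometry: Optional[ChipGeometry] = None,
    pixel_size_um: Optional[float] = None,
) -> ChipImage:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return ChipImage(
        data=arr.astype(np.float64),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        geometry=geometry,
    )


def write_mask(path, mask: VesselMask) -> None:
    tifffile.imwrite(str(path), mask.labels.astype(np.uint8))


def read_mask(path) -> VesselMask:
    return VesselMask(tifffile.imread(str(path)))


def write_truth(directory, stem: str, truth: NetworkTruth, labels: np.ndarray) -> None:
    """Sidecar ground truth: branches.csv, junctions.csv, labels TIFF."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, b in enumerate(truth.branches):
        for j, (r, c) in enumerate(b.points):
            rows.append({"branch": i, "vertex": j, "row": r, "col": c,
                         "width": b.width, "kind": b.kind})
    pd.DataFrame(rows).to_csv(d / f"{stem}_branches.csv", index=False)
    pd.DataFrame(truth.junctions, columns=["row", "col"]).to_csv(
        d / f"{stem}_junctions.csv", index=False
    )
    tifffile.imwrite(str(d / f"{stem}_labels.tif"), labels.astype(np.uint8))


def read_truth(directory, stem: str) -> tuple[NetworkTruth, np.ndarray]:
    d = Path(directory)
    btab = pd.read_csv(d / f"{stem}_branches.csv")
    branches = []
    for _, grp in btab.groupby("branch", sort=True):
        grp = grp.sort_values("vertex")
        branches.append(Branch(
            points=grp[["row", "col"]].to_numpy(dtype=float),
            width=float(grp["width"].iloc[0]),
            kind=str(grp["kind"].iloc[0]),
        ))
    junctions = pd.read_csv(d / f"{stem}_junctions.csv").to_numpy(dtype=float)
    labels = tifffile.imread(str(d / f"{stem}_labels.tif"))
    truth = NetworkTruth(
        branches=branches,
        junctions=junctions.reshape(-1, 2),
        total_length=float(sum(b.arc_length for b in branches)),
        thick_area=int((labels == 2).sum()),
        thin_area=int((labels == 1).sum()),
    )
    return truth, labels
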