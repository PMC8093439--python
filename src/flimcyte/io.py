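"""Standard-format I/O: HDF5 TCSPC stacks, TIFF images/masks/labels, CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .decay import IRF
from .synthetic import GroundTruth, TCSPCStack

__all__ = [
    "write_stack_h5",
    "read_stack_h5",
    "write_intensity_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_label_tiff",
    "read_label_tiff",
    "write_ground_truth",
    "read_ground_truth",
]


def write_stack_h5(path, stack: TCSPCStack, irf: IRF) -> None:
    """Write a TCSPC stack and its IRF to HDF5.

    Layout: ``/data`` [C, Y, X, T] uint16, ``/irf`` float, attrs
    ``channels``, ``period_ns``, ``n_bins``.
    """
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=stack.data.astype(np.uint16), compression="gzip")
        f.create_dataset("irf", data=irf.histogram)
        d.attrs["channels"] = list(stack.channels)
        d.attrs["period_ns"] = stack.period
        d.attrs["n_bins"] = stack.n_time_bins


def read_stack_h5(path) -> tuple:
    """Read ``(TCSPCStack, IRF)`` back from HDF5."""
    with h5py.File(path, "r") as f:
        d = f["data"]
        channels = tuple(
            c.decode() if isinstance(c, bytes) else str(c) for c in d.attrs["channels"]
        )
        period = float(d.attrs["period_ns"])
        stack = TCSPCStack(data=d[()], channels=channels, period=period)
        irf = IRF(histogram=f["irf"][()], bin_width=period / stack.n_time_bins)
    return stack, irf


def write_intensity_tiff(path, stack: TCSPCStack) -> None:
    """Time-integrated intensity projections, one float32 page per channel."""
    pages = np.stack([stack.intensity(c).astype(np.float32) for c in stack.channels])
    tifffile.imwrite(path, pages, photometric="minisblack", metadata={"axes": "CYX"})


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_ground_truth(directory, gt: GroundTruth) -> tuple:
    """Write ground truth as a label TIFF plus a per-cell CSV; returns paths."""
    directory = Path(directory)
    tif = directory / "ground_truth_labels.tif"
    csv = directory / "ground_truth_cells.csv"
    write_label_tiff(tif, gt.label_image)
    gt.per_cell.to_csv(csv, index=False)
    return tif, csv


def read_ground_truth(directory) -> GroundTruth:
    import pandas as pd

    directory = Path(directory)
    labels = read_label_tiff(directory / "ground_truth_labels.tif")
    per_cell = pd.read_csv(directory / "ground_truth_cells.csv")
    return GroundTruth(label_image=labels, per_cell=per_cell)
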