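"""Single-cell feature extraction from label images and parameter planes.

Each segmented cell is summarized by the unweighted mean, over its defined
pixels, of: the per-pixel optical redox ratio (NAD(P)H intensity / FAD
intensity), the fitted lifetime parameters of both metabolic channels, and
the raw channel intensities. Per-cell redox ratio is the mean of per-pixel
ratios (matching pixel-wise averaging within cell masks), not the ratio of
mean intensities; the latter is available via ``ratio_of_means=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import LabelImage

__all__ = [
    "CELL_COLUMNS",
    "redox_ratio_image",
    "extract_cell_features",
    "match_to_ground_truth",
    "attach_ground_truth",
]

CELL_COLUMNS = [
    "cell_id",
    "condition",
    "redox_ratio",
    "nadh_taum",
    "nadh_tau1",
    "nadh_tau2",
    "nadh_alpha1",
    "fad_taum",
    "fad_tau1",
    "fad_tau2",
    "fad_alpha1",
    "nadh_intensity",
    "fad_intensity",
    "area",
    "phenotype",
]

# feature column -> plane key expected in the `planes` dict
_PLANE_FEATURES = {
    "redox_ratio": "redox_ratio",
    "nadh_taum": "nadh_taum",
    "nadh_tau1": "nadh_tau1",
    "nadh_tau2": "nadh_tau2",
    "nadh_alpha1": "nadh_alpha1",
    "fad_taum": "fad_taum",
    "fad_tau1": "fad_tau1",
    "fad_tau2": "fad_tau2",
    "fad_alpha1": "fad_alpha1",
    "nadh_intensity": "nadh_intensity",
    "fad_intensity": "fad_intensity",
}


def redox_ratio_image(
    nadh_intensity: np.ndarray, fad_intensity: np.ndarray
) -> np.ndarray:
    """Per-pixel optical redox ratio NAD(P)H / FAD.

    Pixels with zero FAD intensity are undefined (NaN), never an error.
    """
    nadh = np.asarray(nadh_intensity, dtype=float)
    fad = np.asarray(fad_intensity, dtype=float)
    if nadh.shape != fad.shape:
        raise ValueError("intensity planes must be co-registered (same shape)")
    out = np.full(nadh.shape, np.nan)
    np.divide(nadh, fad, out=out, where=fad != 0)
    return out


def extract_cell_features(
    labels: LabelImage | np.ndarray,
    planes: dict,
    condition: str | None = None,
) -> pd.DataFrame:
    """One row of averaged features per labeled cell.

    ``planes`` maps feature names (see ``CELL_COLUMNS``) to co-registered
    float images; NaN pixels are excluded per feature, and a cell whose
    pixels are all undefined for a feature carries NaN there.
    """
    lab = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
    for name, img in planes.items():
        if img.shape != lab.shape:
            raise ValueError(f"plane {name!r} shape {img.shape} != labels {lab.shape}")

    rows = []
    for cell_id in np.unique(lab[lab > 0]):
        sel = lab == cell_id
        row = {"cell_id": int(cell_id), "condition": condition, "area": int(sel.sum()),
               "phenotype": None}
        for feature, key in _PLANE_FEATURES.items():
            if key not in planes:
                row[feature] = np.nan
                continue
            vals = planes[key][sel]
            vals = vals[np.isfinite(vals)]
            row[feature] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def extract_cell_features_ratio_of_means(
    labels: LabelImage | np.ndarray,
    nadh_intensity: np.ndarray,
    fad_intensity: np.ndarray,
) -> pd.DataFrame:
    """Alternative redox-ratio convention: ratio of per-cell mean intensities."""
    lab = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
    rows = []
    for cell_id in np.unique(lab[lab > 0]):
        sel = lab == cell_id
        fad_mean = float(fad_intensity[sel].mean())
        rr = float(nadh_intensity[sel].mean()) / fad_mean if fad_mean != 0 else np.nan
        rows.append({"cell_id": int(cell_id), "redox_ratio": rr})
    return pd.DataFrame(rows, columns=["cell_id", "redox_ratio"])


def match_to_ground_truth(
    labels: LabelImage | np.ndarray, true_labels: np.ndarray
) -> dict:
    """Map each segmented label to the ground-truth cell with maximal
    pixel overlap (ties broken toward the smaller true id); labels with no
    overlap map to 0."""
    lab = labels.labels if isinstance(labels, LabelImage) else np.asarray(labels)
    if lab.shape != true_labels.shape:
        raise ValueError("label images must share the same grid")
    mapping = {}
    for cell_id in np.unique(lab[lab > 0]):
        overlap = true_labels[(lab == cell_id) & (true_labels > 0)]
        if overlap.size == 0:
            mapping[int(cell_id)] = 0
            continue
        ids, counts = np.unique(overlap, return_counts=True)
        mapping[int(cell_id)] = int(ids[np.argmax(counts)])
    return mapping


def attach_ground_truth(
    cells: pd.DataFrame,
    labels: LabelImage | np.ndarray,
    ground_truth,
) -> pd.DataFrame:
    """Join ground-truth provenance (true RR, phenotype, ...) onto a cell
    table by maximal footprint overlap; unmatched cells get NaN/None."""
    mapping = match_to_ground_truth(labels, ground_truth.label_image)
    gt = ground_truth.per_cell.set_index("cell_id")
    out = cells.copy()
    matched = out["cell_id"].map(mapping).fillna(0).astype(int)
    out["true_cell_id"] = matched
    for col in gt.columns:
        if col in ("centroid_x", "centroid_y", "radius"):
            continue
        target = col if col.startswith("true_") else f"true_{col}"
        out[target] = [gt.at[m, col] if m in gt.index else np.nan for m in matched]
    # phenotype comes from ground truth when available
    out["phenotype"] = out["true_phenotype"].where(matched > 0, None)
    return out
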