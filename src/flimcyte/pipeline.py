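"""End-to-end orchestration: simulate -> analyze -> compare -> report.

Each stage reads/writes standard formats (HDF5 stacks, TIFF images, CSV
tables, YAML configs), logs its thresholds and surviving counts, and is
deterministic for a fixed config and seed. The resolved configuration is
written beside every run's outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .features import (
    attach_ground_truth,
    extract_cell_features,
    redox_ratio_image,
)
from .fitting import (
    DEFAULT_PHOTON_THRESHOLD,
    estimate_mcherry_lifetime,
    fit_channel,
)
from .segmentation import (
    build_fad_mask,
    geodesic_reconstruct,
    label_cells,
    threshold_mcherry,
)
from .stats import (
    cv_heatmap,
    mann_whitney,
    phenotype_proportions,
    summarize_population,
)
from .synthetic import ScenePreset, make_preset, render_scene

__all__ = [
    "RunConfig",
    "analyze_stack",
    "run_simulate",
    "run_analyze",
    "run_compare",
    "run_report",
]

logger = logging.getLogger("flimcyte")

#: Variables compared between conditions and summarized per population.
ANALYSIS_VARIABLES = [
    "redox_ratio",
    "nadh_taum",
    "fad_taum",
    "nadh_tau1",
    "nadh_tau2",
    "nadh_alpha1",
    "fad_tau1",
    "fad_tau2",
    "fad_alpha1",
]


@dataclass
class RunConfig:
    """Resolved options for one pipeline run; YAML round-trips losslessly."""

    out_dir: str = "."
    preset: str | None = None  # condition name or path to a preset YAML
    seed: int = 0
    n_cells: int | None = None
    field_size: tuple | None = None
    stack_path: str | None = None
    kernel: int = 3
    photon_threshold: float = DEFAULT_PHOTON_THRESHOLD
    lifetime_window: tuple = (1.3, 1.5)
    mask_method: str = "otsu"
    min_area: int = 20
    fit_scope: str = "cells"  # "cells": bi-exp fits restricted to segmented footprints
    keep_intermediates: bool = True
    log_level: str = "INFO"

    def resolve_preset(self) -> ScenePreset:
        if self.preset is None:
            raise ValueError("config has no preset")
        if Path(self.preset).suffix in (".yml", ".yaml") and Path(self.preset).exists():
            preset = ScenePreset.from_yaml(self.preset)
        else:
            preset = make_preset(self.preset)
        overrides = {"seed": self.seed}
        if self.n_cells is not None:
            overrides["n_cells"] = self.n_cells
        if self.field_size is not None:
            overrides["field_size"] = tuple(self.field_size)
        return preset.replace(**overrides)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("field_size", "lifetime_window"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("field_size", "lifetime_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _prepare(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out / "run_config.yaml")
    return out


def run_simulate(config: RunConfig) -> dict:
    """Render a synthetic scene to disk; returns a dict of output paths."""
    out = _prepare(config)
    preset = config.resolve_preset()
    logger.info(
        "simulate: condition=%s field=%s n_cells=%d seed=%d",
        preset.condition_name, preset.field_size, preset.n_cells, preset.seed,
    )
    stack, gt, irf = render_scene(preset)
    paths = {
        "stack": out / "stack.h5",
        "intensity": out / "intensity.tif",
        "preset": out / "preset.yaml",
    }
    fio.write_stack_h5(paths["stack"], stack, irf)
    fio.write_intensity_tiff(paths["intensity"], stack)
    preset.to_yaml(paths["preset"])
    gt_tif, gt_csv = fio.write_ground_truth(out, gt)
    paths.update({"ground_truth_labels": gt_tif, "ground_truth_cells": gt_csv})
    logger.info("simulate: wrote %d cells to %s", gt.n_cells, out)
    return {k: str(v) for k, v in paths.items()}


def analyze_stack(
    stack,
    irf,
    config: RunConfig | None = None,
    ground_truth=None,
    condition: str | None = None,
) -> tuple:
    """In-memory fit -> segment -> feature-extraction for one scene.

    Returns ``(cells, artifacts)`` where ``cells`` is the single-cell
    feature table and ``artifacts`` holds the intermediate marker/mask/
    reconstruction/label images. Ground-truth provenance (true RR,
    phenotype) is joined when ``ground_truth`` is given.
    """
    if config is None:
        config = RunConfig()
    mch_tau = estimate_mcherry_lifetime(
        stack, irf, kernel=config.kernel, photon_threshold=config.photon_threshold
    )
    low, high = config.lifetime_window
    marker = threshold_mcherry(mch_tau, low, high)
    fad_intensity = stack.intensity("FAD").astype(float)
    mask = build_fad_mask(fad_intensity, method=config.mask_method)
    reconstructed = geodesic_reconstruct(marker, mask)
    labels = label_cells(reconstructed, min_area=config.min_area)
    logger.info(
        "analyze: marker=%d px, mask=%d px, reconstructed=%d px, %d cells >= %d px",
        marker.sum(), mask.sum(), reconstructed.sum(), labels.n_labels, config.min_area,
    )

    fit_mask = labels.labels > 0 if config.fit_scope == "cells" else None
    lifetime_planes = {}
    for channel, prefix in (("NADH", "nadh"), ("FAD", "fad")):
        img = fit_channel(
            stack, channel, irf, kernel=config.kernel,
            photon_threshold=config.photon_threshold, mask=fit_mask,
        )
        for par, key in (("tau_m", "taum"), ("tau1", "tau1"), ("tau2", "tau2"), ("alpha1", "alpha1")):
            lifetime_planes[f"{prefix}_{key}"] = img[par]
        logger.info("analyze: %s fitted %d px", channel, int(img.fit_mask.sum()))

    nadh_intensity = stack.intensity("NADH").astype(float)
    planes = {
        "redox_ratio": redox_ratio_image(nadh_intensity, fad_intensity),
        "nadh_intensity": nadh_intensity,
        "fad_intensity": fad_intensity,
        **lifetime_planes,
    }
    cells = extract_cell_features(labels, planes, condition=condition)
    if ground_truth is not None:
        cells = attach_ground_truth(cells, labels, ground_truth)
        if condition is not None:
            cells["condition"] = condition
    artifacts = {
        "mcherry_lifetime": mch_tau,
        "marker": marker,
        "fad_mask": mask,
        "reconstructed": reconstructed,
        "labels": labels,
    }
    return cells, artifacts


def run_analyze(config: RunConfig) -> dict:
    """Fit -> segment -> extract features for one stored scene.

    Reads ``config.stack_path`` (HDF5); joins ground-truth provenance when
    ground-truth files sit beside the stack. Writes ``cells.csv`` plus
    intermediate masks/label images when requested.
    """
    out = _prepare(config)
    if config.stack_path is None:
        raise ValueError("run_analyze requires config.stack_path")
    stack, irf = fio.read_stack_h5(config.stack_path)
    logger.info("analyze: stack %s channels=%s", stack.data.shape, stack.channels)

    stack_dir = Path(config.stack_path).parent
    gt = None
    if (stack_dir / "ground_truth_labels.tif").exists():
        gt = fio.read_ground_truth(stack_dir)
    condition = None
    preset_yaml = stack_dir / "preset.yaml"
    if preset_yaml.exists():
        condition = ScenePreset.from_yaml(preset_yaml).condition_name

    cells, artifacts = analyze_stack(stack, irf, config, ground_truth=gt, condition=condition)
    marker, mask = artifacts["marker"], artifacts["fad_mask"]
    reconstructed, labels = artifacts["reconstructed"], artifacts["labels"]

    paths = {"cells": out / "cells.csv"}
    cells.to_csv(paths["cells"], index=False)
    if config.keep_intermediates:
        fio.write_mask_tiff(out / "marker.tif", marker)
        fio.write_mask_tiff(out / "fad_mask.tif", mask)
        fio.write_mask_tiff(out / "reconstructed.tif", reconstructed)
        fio.write_label_tiff(out / "labels.tif", labels.labels)
        paths.update(
            marker=out / "marker.tif", fad_mask=out / "fad_mask.tif",
            reconstructed=out / "reconstructed.tif", labels=out / "labels.tif",
        )
    if len(cells) == 0:
        logger.warning("analyze: no cells segmented; downstream stats will be skipped")
    logger.info("analyze: %d cells -> %s", len(cells), paths["cells"])
    return {k: str(v) for k, v in paths.items()}


def run_compare(cells_a, cells_b, out_dir) -> dict:
    """Between-condition statistics from two cell tables (paths or frames).

    Writes summaries.csv, tests.csv, cv_heatmap.csv and — when phenotype
    and FOV columns are present — proportions.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for c in (cells_a, cells_b):
        df = pd.read_csv(c) if not isinstance(c, pd.DataFrame) else c.copy()
        if len(df) == 0:
            raise ValueError("cannot compare: one cell table is empty")
        frames.append(df)
    a, b = frames
    cond_a = a["condition"].iloc[0] if "condition" in a else "A"
    cond_b = b["condition"].iloc[0] if "condition" in b else "B"

    summaries, tests = [], []
    for var in ANALYSIS_VARIABLES:
        if var not in a or var not in b:
            continue
        sa = summarize_population(a, var, condition=cond_a)
        sb = summarize_population(b, var, condition=cond_b)
        summaries.extend([sa, sb])
        tests.append(mann_whitney(a[var], b[var], variable=var))

    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    tests_df = pd.DataFrame([dataclasses.asdict(t) for t in tests])
    heat = cv_heatmap(summaries)
    paths = {
        "summaries": out / "summaries.csv",
        "tests": out / "tests.csv",
        "cv_heatmap": out / "cv_heatmap.csv",
    }
    summary_df.to_csv(paths["summaries"], index=False)
    tests_df.to_csv(paths["tests"], index=False)
    heat.to_csv(paths["cv_heatmap"])

    both = pd.concat(
        [a.assign(condition=cond_a), b.assign(condition=cond_b)], ignore_index=True
    )
    if "phenotype" in both and "fov" in both and both["phenotype"].notna().any():
        props = phenotype_proportions(both.dropna(subset=["phenotype"]))
        props_df = pd.DataFrame([dataclasses.asdict(p) for p in props])
        paths["proportions"] = out / "proportions.csv"
        props_df.to_csv(paths["proportions"], index=False)
    logger.info("compare: %s vs %s -> %s", cond_a, cond_b, out)
    return {k: str(v) for k, v in paths.items()}


def run_report(compare_dir, out_dir=None) -> dict:
    """Render summary figures (CV heatmap, redox-ratio means) from a compare run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    compare_dir = Path(compare_dir)
    out = Path(out_dir) if out_dir else compare_dir
    out.mkdir(parents=True, exist_ok=True)
    heat = pd.read_csv(compare_dir / "cv_heatmap.csv", index_col=0)
    summaries = pd.read_csv(compare_dir / "summaries.csv")

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(heat.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(heat.shape[1]), heat.columns)
    ax.set_yticks(range(heat.shape[0]), heat.index)
    fig.colorbar(im, ax=ax, label="%CV")
    ax.set_title("Coefficient of variation")
    fig.tight_layout()
    heat_png = out / "cv_heatmap.png"
    fig.savefig(heat_png, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    rr = summaries[summaries["variable"] == "redox_ratio"]
    ax.bar(rr["condition"], rr["mean"], yerr=rr["ci95_half_width"], capsize=4)
    ax.set_ylabel("optical redox ratio (mean ± 95% CI)")
    fig.tight_layout()
    rr_png = out / "redox_ratio_summary.png"
    fig.savefig(rr_png, dpi=150)
    plt.close(fig)
    return {"cv_heatmap_png": str(heat_png), "redox_ratio_png": str(rr_png)}
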