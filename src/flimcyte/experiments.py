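"""Study-scale recovery experiments: many scenes -> pooled cell tables.

These helpers run the full simulate -> fit -> segment -> feature pipeline
over enough fields of view to reach a target cell count, or survey
phenotype composition across simulated fields, pooling results the way
cells are pooled across fields and animals in an in vivo study.
Desk-scale defaults (50 cells per 128x128 field) keep a multi-hundred-cell
experiment at minutes of CPU; the population statistics are set by the
condition presets, not by the field size.
"""

from __future__ import annotations

import math

import pandas as pd

from .pipeline import RunConfig, analyze_stack
from .synthetic import make_preset, place_cells, render_scene

__all__ = ["recover_condition", "phenotype_survey"]


def recover_condition(
    condition: str,
    total_cells: int,
    cells_per_scene: int = 50,
    field_size: tuple = (128, 128),
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline over enough scenes to generate ``total_cells``.

    Scene ``i`` uses seed ``seed + i``. Returns the pooled single-cell
    feature table with ground-truth provenance and an ``fov`` column.
    """
    n_scenes = math.ceil(total_cells / cells_per_scene)
    frames = []
    for i in range(n_scenes):
        n = min(cells_per_scene, total_cells - i * cells_per_scene)
        preset = make_preset(
            condition, n_cells=n, field_size=field_size, seed=seed + i
        )
        stack, gt, irf = render_scene(preset)
        cells, _ = analyze_stack(
            stack, irf, config, ground_truth=gt, condition=condition
        )
        cells["fov"] = i + 1
        frames.append(cells)
    return pd.concat(frames, ignore_index=True)


def phenotype_survey(
    condition: str,
    n_fov: int,
    cells_per_fov: int = 35,
    field_size: tuple = (256, 256),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw phenotype-labeled cell populations for ``n_fov`` fields of view.

    Only the placement/labeling stage runs (no imaging); returns one row
    per cell with ``condition``, ``fov`` and ``phenotype`` columns, ready
    for :func:`flimcyte.stats.phenotype_proportions`.
    """
    frames = []
    for i in range(n_fov):
        preset = make_preset(
            condition, n_cells=cells_per_fov, field_size=field_size, seed=seed + i
        )
        gt = place_cells(preset)
        frames.append(
            pd.DataFrame(
                {
                    "condition": condition,
                    "fov": i + 1,
                    "phenotype": gt.per_cell["phenotype"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
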