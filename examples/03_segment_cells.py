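"""Segment mCherry+ cells by marker-controlled geodesic reconstruction.

The marker is the mCherry lifetime image thresholded on the reporter's
1.3-1.5 ns window; the mask is the Otsu-binarized FAD intensity image.
Reconstruction by dilation keeps exactly the mask components touching the
marker; per-cell Dice against the generator's true footprints measures
segmentation agreement (1.0 = pixel-perfect).
"""

import numpy as np

import flimcyte as fc
from flimcyte.features import match_to_ground_truth

preset = fc.make_preset("dermis", n_cells=10, field_size=(128, 128), seed=3)
stack, gt, irf = fc.render_scene(preset)

cells, artifacts = fc.analyze_stack(stack, irf, ground_truth=gt)
labels = artifacts["labels"]

print(f"true cells: {gt.n_cells}, segmented: {labels.n_labels}")
mapping = match_to_ground_truth(labels, gt.label_image)
dices = [
    fc.dice_coefficient(labels.labels == seg, gt.label_image == true)
    for seg, true in mapping.items() if true > 0
]
print(f"mean per-cell Dice vs ground truth: {np.mean(dices):.3f}")

matched = cells[cells["true_cell_id"] > 0]
err = (matched["redox_ratio"] - matched["true_rr"]).abs() / matched["true_rr"]
print(f"per-cell redox-ratio recovery: median relative error {err.median():.4f}")
print(cells[["cell_id", "area", "redox_ratio", "nadh_taum", "fad_taum", "phenotype"]]
      .head().to_string(index=False))
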