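"""Compare tumor and dermal macrophage populations end to end.

Runs the full pipeline over a few small fields per condition, then
computes the between-condition Mann-Whitney test on single-cell redox
ratio, %CV heterogeneity per variable, and phenotype proportions across
fields of view. (Small cell counts here keep the example fast; the
recovered statistics scatter more than at study scale.)
"""

import pandas as pd

import flimcyte as fc
from flimcyte.experiments import phenotype_survey, recover_condition

tumor = recover_condition("tumor", total_cells=60, cells_per_scene=30, seed=5)
dermis = recover_condition("dermis", total_cells=60, cells_per_scene=30, seed=6)

res = fc.mann_whitney(tumor["redox_ratio"], dermis["redox_ratio"], "redox_ratio")
print(f"Mann-Whitney redox ratio: U={res.u_statistic:.0f}, p={res.p_value:.2e} "
      f"({res.method}, n={res.n1} vs {res.n2})")

summaries = []
for var in ("redox_ratio", "nadh_taum", "fad_taum"):
    for name, cells in (("tumor", tumor), ("dermis", dermis)):
        summaries.append(fc.summarize_population(cells, var, condition=name))
heat = fc.cv_heatmap(summaries)
print("\n%CV heatmap (heterogeneity per variable and condition):")
print(heat.round(1).to_string())

proportions = fc.phenotype_proportions(
    pd.concat(
        [phenotype_survey("tumor", n_fov=8, seed=70),
         phenotype_survey("dermis", n_fov=8, seed=80)],
        ignore_index=True,
    )
)
print("\nphenotype composition of mCherry+ cells (mean % across FOVs ± SEM):")
for p in proportions:
    print(f"  {p.condition:7s} CD206+ {p.frac_cd206_pos:5.1f}±{p.sem_cd206_pos:.1f}  "
          f"CD86+ {p.frac_cd86_pos:5.1f}±{p.sem_cd86_pos:.1f}")
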