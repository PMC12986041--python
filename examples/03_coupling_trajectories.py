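"""Stage-stratified hub coupling: correlation tables, the DDR2-COL11A1
trajectory, hub summaries and the receptor divergence ratio."""

import pandas as pd

from ddrcoupling import (
    coupling_trajectory,
    default_spec,
    divergence_ratio,
    generate_dataset,
    hub_coupling_summary,
    hub_targets,
    stage_correlation_table,
)
from ddrcoupling.panel import STAGES

X, ann = generate_dataset(default_spec(seed=2, batch_effects=False))
records = pd.concat(
    [stage_correlation_table(X, ann, s) for s in STAGES], ignore_index=True
)
print(f"{len(records)} correlation records ({len(records) // 3} pairs per stage)")

traj = coupling_trajectory(records, ("DDR2", "COL11A1"))
print("DDR2-COL11A1 R2 by stage:",
      {k: round(v, 3) for k, v in traj.r_squared_by_stage.items()})
print("overall delta R2:", round(traj.delta_r2["normal->carcinoma"], 3),
      "| kinetic class:", traj.kinetic_class)

ddr2 = hub_coupling_summary(records, "DDR2", hub_targets("DDR2"))
ddr1 = hub_coupling_summary(records, "DDR1", hub_targets("DDR1"))
print("DDR2 mean R2 by stage:",
      {k: round(v, 3) for k, v in ddr2.mean_r2_by_stage.items()},
      f"(overall fold {ddr2.overall_fold:.2f})")
print("DDR2/DDR1 divergence in carcinoma:",
      round(divergence_ratio(ddr2, ddr1, "carcinoma"), 1))
# The pair's coupling rises from a near-zero baseline to R2 ~ 0.55
# ("de novo" class) and the DDR2 hub mean strengthens ~2.6-fold while
# DDR1 stays weak -- the planted study conditions recovered from data.
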