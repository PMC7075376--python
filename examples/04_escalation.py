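"""Simulate prescription escalation from 15 to 23 Gy against skin limits.

The engine is linear in the prescription, so every dose metric rescales with
Dp; the table reports the skin doses per prescription level and whether all
single-fraction organ-at-risk limits still pass.
"""

import gridfire as gf
from gridfire.evaluate import RTOGLimits, escalate

# metrics of a planned case (see 03_plan_and_metrics.py); entered here
# directly so the example runs in seconds
base = gf.PlanMetrics(
    prescription_gy=15.0, mean_gtv_dose_gy=12.73, pvdr=2.37,
    skin_dmax_gy=4.32, skin_d5cc_gy=3.90, skin_d10cc_gy=3.65,
    d2cm_percent=68.5, oar_max_gy={"CORD": 1.22},
    total_mu=3024.0, beam_on_time_min=7.56,
)

table, feasible = escalate(base, RTOGLimits())
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nmaximum feasible prescription: {feasible} Gy "
      "(skin limit 26 Gy Dmax / 23 Gy D10cc, single fraction)")
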