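"""Calibrate the decomposition cell-mean table, simulate the litterbag
experiment, and test for home-field advantage (HFA).

Prints the per-species ADH statistic (additional decomposition at home,
in mass-loss percentage points) with its replicate-draw t-test: ADH > 0
means the litter decomposes faster in its home forest than away.
"""

from litterlab import calibrate_cell_means, generate_litterbags, hfa_analysis
from litterlab.hfa import hfa_results_to_frame
from litterlab.synthetic import LitterSimConfig

table = calibrate_cell_means()
print(f"calibration residual norm: {table.residual_norm:.2e}")
print("cell-mean mass loss (%), natural drought, 24 months:")
print(table.slice("ND", 24).round(1), end="\n\n")

records = generate_litterbags(LitterSimConfig(cell_means=table), seed=42)
print(f"simulated {len(records)} litterbags "
      "(36 modalities x 2 dates x 7 replicates)\n")

results = hfa_analysis(records, n_draws=12, seed=42)
frame = hfa_results_to_frame(results)
print(frame.round(2).to_string(index=False))
print("\nADH > 0 with p < 0.05 indicates a home-field advantage; the "
      "P. halepensis ND/24-month entry should sit near the calibrated "
      "+18.5 points, the Q. pubescens one near -10 (a disadvantage).")
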