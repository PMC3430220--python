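"""Correct systematically biased DFT BDEs with the exact-design RBF network.

Generates a synthetic table whose DFT-like BDE estimate carries a smooth
systematic error of ~4.5 kcal/mol mean magnitude, scans the RBF spread
over 0.2..3.0, and corrects at the best spread.  Training rows are
interpolated exactly (deviations ~1e-13), so quality is judged on the 12
held-out molecules.
"""

import numpy as np

from sofmrbf import SyntheticSpec, generate, mad, run_correction, spread_scan

FEATURES = ("dH_homo", "Q_Y", "Q_N", "N_X", "mu", "alpha", "E_HOMO", "E_LUMO")

table, truth = generate(SyntheticSpec(seed=1))
raw = table.descriptor_matrix(["dH_homo"])[:, 0] - table.expt_bde
test = ~table.train_mask
print(f"raw DFT error: MAD {mad(raw):.2f} kcal/mol (test rows: {mad(raw[test]):.2f})")

scan = spread_scan(table, FEATURES)
print(f"spread scan 0.2..3.0: best spread = {scan.best_spread}")

result = run_correction(table, FEATURES, scan.best_spread)
print(f"corrected: train MAD {result.mad('train'):.1e} (exact interpolation), "
      f"test MAD {result.mad('test'):.2f} kcal/mol")
print(f"error reduction on held-out molecules: "
      f"{mad(raw[test]) / result.mad('test'):.1f}x")
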