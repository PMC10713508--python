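#!/usr/bin/env python
"""Method validation on known ground truth: solver-vs-oracle agreement for
the graphical lasso, edge-recovery of the EBIC-glasso estimator as sample
size grows, a reduced-scale type-I-error check of the permutation network
comparison test, and planar-configuration recovery by ordinal MDS.

This is the desk-scale counterpart of scripts/acceptance.py (which runs the
full calibration); the comparison-test check here uses fewer repeats so the
whole script stays in the minutes range.

Writes results/validation.json.
"""

import json
from pathlib import Path

from shsnet import studies

OUT = Path("results")
OUT.mkdir(exist_ok=True)

out = {}

out["glasso_oracle_max_abs_deviation"] = studies.glasso_oracle_deviation()
print(f"glasso vs numeric optimiser: max |Δθ| = {out['glasso_oracle_max_abs_deviation']:.2e}")

out["recovery_by_n"] = studies.recovery_study(seed=1)
for n, vals in out["recovery_by_n"].items():
    print(f"recovery at n={n}: sensitivity {vals['sensitivity']:.2f}, "
          f"specificity {vals['specificity']:.2f}")

out["nct_type_one_error_reduced"] = studies.nct_type_one_error(
    seed=1, repeats=40, n_perm=100
)
print(f"NCT type-I error ({out['nct_type_one_error_reduced']['repeats']} repeats): "
      f"{out['nct_type_one_error_reduced']['rate']:.3f} (nominal 0.05)")

out["mds_planar_recovery"] = studies.mds_recovery(seed=1)
print(f"MDS planar recovery: stress {out['mds_planar_recovery']['stress']:.2e}, "
      f"Procrustes {out['mds_planar_recovery']['procrustes']:.2e}")

(OUT / "validation.json").write_text(json.dumps(out, indent=2))
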