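"""Find traps whose phenotype deviates from their genotype's majority.

Builds a phenotype scatter (maturation time vs pre-swap brightness)
with 5% of traps planted far from the main cluster — the signature of
a mis-decoded trap — and recovers them with DBSCAN.
"""

import numpy as np
import pandas as pd

from poolscreen.outliers import OutlierParams, detect_outliers

rng = np.random.default_rng(5)
rows = []
for trap in range(60):
    deviating = trap >= 57  # 3 of 60 traps planted off-cluster
    tau, fluor = (200.0, 400.0) if deviating else (60.0, 100.0)
    for lin in range(3):
        rows.append({
            "trap_id": trap, "lineage_id": f"t{trap}l{lin}",
            "tau_m": tau + rng.normal(0, 2.0),
            "pre_chl_fluorescence": fluor + rng.normal(0, 4.0),
        })
points = pd.DataFrame(rows)

res = detect_outliers(points, OutlierParams(eps=0.5, min_pts=5))
print(f"major-cluster traps: {res.n_major}, deviating: {res.n_deviating}, "
      f"excluded: {res.n_excluded}")
print(f"deviating fraction: {res.deviating_fraction:.3f} (planted: {3/60:.3f})")
print("deviating traps hold cells whose phenotype disagrees with their decoded")
print("genotype - candidate decoding errors or rare biological outliers.")
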