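#!/usr/bin/env python
"""Clinical correlations: GSCORR vs HAMA/HAMD within each patient group.

The score replaces the measure as the mixed-model response, with the target's
GSCORR as focal predictor and the same covariates and site random structure.
Prints the associations at the generative link ROIs.
"""

import pandas as pd

from _common import RESULTS, RUN_DIR, demo_config

config = demo_config()
clinical = pd.read_csv(RUN_DIR / "results" / "clinical_all.tsv", sep="\t")

link_hama = f"roi_{config.sim.clinical_link_rois[0]}"
link_hamd = f"roi_{config.sim.clinical_link_rois[1]}"
for score, target in (("HAMA", link_hama), ("HAMD", link_hamd)):
    rows = clinical[(clinical["measure"] == f"GSCORR~{score}")
                    & (clinical["target_id"] == target)]
    for _, r in rows.iterrows():
        print(f"{score} ~ GSCORR[{target}] in {r['contrast']:12s}: "
              f"t={r['t']:+.2f} p={r['p']:.4f} q={r['q']:.4f} "
              f"{'*' if r['significant'] else ''}")

sig = clinical[clinical["significant"]]
print(f"\n{len(sig)} significant clinical associations overall "
      f"(tables in {RESULTS}/clinical_all.tsv)")
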