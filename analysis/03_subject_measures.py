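#!/usr/bin/env python
"""Subject-level measures: GSCORR, SFI, GMV, ALFF, fALFF.

Nuisance-regresses every included subject's BOLD, extracts the gray-matter
global signal, and computes all five measure tables at whole-brain, network
and regional levels.  Tables are copied to results/measures/.
"""

import shutil

import pandas as pd

from _common import RESULTS, RUN_DIR, demo_config
from gstopo.pipeline import stage_features

tables = stage_features(demo_config(), RUN_DIR)
out = RESULTS / "measures"
out.mkdir(parents=True, exist_ok=True)
for measure in tables:
    shutil.copy(RUN_DIR / "measures" / f"{measure}.tsv", out / f"{measure}.tsv")
shutil.copy(RUN_DIR / "analysis_manifest.tsv", RESULTS / "analysis_manifest.tsv")

manifest = pd.read_csv(RUN_DIR / "analysis_manifest.tsv", sep="\t")
gscorr = tables["GSCORR"].values.join(manifest.set_index("subject_id")["diagnosis"])
print("whole-brain GSCORR (Fisher z) by group:")
print(gscorr.groupby("diagnosis")["whole_brain"].agg(["mean", "std"]).round(3))
net_cols = [c for c in tables["GSCORR"].values.columns if c.startswith("net_")]
print("network GSCORR means:")
print(gscorr.groupby("diagnosis")[net_cols].mean().round(3))
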