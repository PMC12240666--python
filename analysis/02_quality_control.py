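#!/usr/bin/env python
"""Quality control: FD, coverage, ReHo similarity, exclusion cascade.

Applies the seven-criterion cascade and the HAMA>14 stratification; writes
results/qc_report.tsv and prints the exclusion tally and final group sizes.
"""

import shutil

from _common import RESULTS, RUN_DIR, demo_config
from gstopo.pipeline import stage_qc

report = stage_qc(demo_config(), RUN_DIR)
RESULTS.mkdir(exist_ok=True)
shutil.copy(RUN_DIR / "qc_report.tsv", RESULTS / "qc_report.tsv")

n = len(report)
print(f"{int(report['included'].sum())}/{n} subjects included")
excluded = report[~report["included"]]
if len(excluded):
    print("exclusions by criterion:", excluded["failed_criteria"].value_counts().to_dict())
print("final groups:", report[report["included"]]["diagnosis"].value_counts().to_dict())
print("mean FD range: %.3f-%.3f mm; ReHo similarity range: %.2f-%.2f"
      % (report["mean_fd"].min(), report["mean_fd"].max(),
         report["reho_corr"].min(), report["reho_corr"].max()))
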