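"""Shared configuration for the analysis drivers.

The demo study: a four-site cohort with three groups (HC, non-anxious MDD,
anxious MDD), planted anxiety-specific coupling decreases in ROIs 1, 2, 11, 12
(CON/SEN territory), a GMV-mediated SFI effect across the SEN network, and
HAMA/HAMD linked to the couplings of ROIs 8 and 9.  The planted effects are
deliberately large (coupling shift -0.2, clinical slope 40 points per z-unit):
with only 20 subjects per group the demo illustrates the machinery end to end,
not the power of the full-scale design (the calibration studies in
scripts/acceptance.py use the d = 0.8 / n = 60-per-group conditions).  Image
data live under scratch/ (regenerated on demand); tables land under results/.
"""

from pathlib import Path

from gstopo.pipeline import RunConfig
from gstopo.synthetic import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "demo_run"
RESULTS = ROOT / "results"

SEED = 7


def demo_config() -> RunConfig:
    sim = SimulationConfig(n_sites=4, subjects_per_site_per_group=5,
                           grid_shape=(16, 16, 12), n_rois=20, n_timepoints=150,
                           seed=SEED, effect_rois=(1, 2, 11, 12), effect_size=-0.2,
                           clinical_link_rois=(8, 9), clinical_link_beta=40.0)
    return RunConfig(sim=sim, seed=SEED)
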