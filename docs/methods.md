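# Methods

This note documents the models, parameters and numerical choices behind
`gstopo`, and what its synthetic validation does and does not establish.

## The measures

**Global signal (GS).** Unweighted mean time series over gray-matter voxels
of the nuisance-regressed BOLD.  No global-signal regression is applied
anywhere in the pipeline: the GS is the object of study, not a nuisance.

**GSCORR.** For each ROI, the ROI mean series (mean over member voxels,
"ROI-mean-first") is correlated with the GS and Fisher-transformed,
`z = atanh(r)`.  `|r|` is clipped at `1 − 1e−7` before the transform so `z`
stays finite; clips are logged.  GSCORR is computed on nuisance-regressed,
*unfiltered* series — only the amplitude measures are band-limited — with an
optional 0.01–0.1 Hz band-pass behind a config flag for sensitivity analysis.

**ALFF / fALFF.** Per voxel, the one-sided FFT amplitude spectrum
`a_k = |X_k|/n`.  ALFF is the mean of `a_k` over `0.01 ≤ f_k ≤ 0.1` Hz
(inclusive bounds, DC excluded); fALFF divides the band amplitude sum by the
sum over all positive frequencies up to Nyquist.  Maps are Z-standardized
(in-mask mean 0, SD 1) and then smoothed (6 mm FWHM default), in that order.
The whole-brain scalar uses the *raw* map's in-mask mean: the Z map's mean is
0 by construction and would be a degenerate group-contrast response; network
and regional values are parcel means of the smoothed Z map.

**GMV and SFI.** Per-ROI GMV is the *mean* over parcel voxels (a `sum` mode
exists) so the interaction statistic `SFI_r = z_r × GMV_r` is not confounded
by parcel size.  Total GMV (the model covariate) is the sum over the brain
mask.  Whole-brain GSCORR/SFI/GMV scalars are unweighted ROI means.

**ReHo (QC only).** Kendall's coefficient of concordance over each voxel's
27-neighborhood (19/7 configurable) with midrank tie correction; edge voxels
use in-mask neighbors only, isolated voxels get W = 1 and are flagged.  The
similarity screen correlates each subject's map with the *leave-one-out*
group mean, avoiding self-correlation inflation.

**Framewise displacement.** Power's formulation: sum of absolute backward
differences of the six rigid-body parameters, rotations scaled by a 50 mm
radius.  The QC report records the variant, since consortium pipelines vary.

## Quality control

The exclusion cascade applies, in order: (1) missing sex/age/education,
(2) age outside 18–65, (3) a visual-inspection failure flag (an *input*
column — image-quality judgment is not computed), (4) mean FD > 0.2 mm or
coverage < 90% of the group mask, (5) ReHo similarity < 0.6 (a fixed floor by
default; an adaptive mean − 2 SD mode recomputes it on the candidate pool),
(6) missing HAMA, and finally (7) sites left with fewer than 10 subjects.
Included MDD subjects are stratified by HAMA: > 14 anxious, ≤ 14 non-anxious.
The cascade is idempotent and monotone in its thresholds (property-tested).

## The mixed model

Each analysis target is tested with

    y ~ 1 + Diagnosis + Age + Sex + Education + Motion + totalGMV
        + (1|Site) + (Diagnosis|Site)

The package fits this with its own profiled-REML solver specialized to the
two-variance-component structure (site random intercept, independent site
random slope on the focal covariate).  Writing the marginal covariance as
`σ²(I + τ_u Z_u Z_u' + τ_v Z_v Z_v')`, `σ²` and the fixed effects are
profiled out and the restricted likelihood minimized over `(log τ_u, log
τ_v)` by Nelder–Mead; all per-site quantities reduce to small cross-product
matrices via the Woodbury identity, so one fit costs milliseconds and the
large calibration simulations stay tractable.  Fits agree with R `lme4`
(`(1|site) + (0+dc|site)`) to ~1e-5 relative on shared data, which the test
suite checks with frozen reference values.

Design choices:

* **Independent intercept and slope variances.**  The textbook
  `(1|Site) + (Diagnosis|Site)` with a free 2×2 covariance is
  overparameterized as written; the independent form is the standard
  identifiable reduction.  The slope column is **centered**, which makes the
  random structure invariant to the choice of reference group (contrast
  antisymmetry is then exact, and is property-tested).
* **Wald t with df = n − p_fixed**, two-sided.  Satterthwaite approximations
  are out of scope; with the simulated site counts (3–5) this df choice is
  mildly liberal for between-site effects but accurate for the within-site
  diagnosis contrast, and the null calibration below confirms it.
* **Degradation ladder.**  Full model → random intercept only → OLS with
  site fixed effects; a single site goes directly to OLS (where the t equals
  the classical OLS/partial-correlation t, an acceptance check).  The rung
  used is recorded in every result row.
* **Indicator coding.**  The binary Diagnosis indicator codes the
  second-named group of a contrast as 1 and is recorded in a `coding` column;
  a decrease in the first-named group therefore appears with positive sign.
* Rows with any missing covariate are dropped per model and counted.

**FDR.**  Benjamini–Hochberg within each (measure, contrast) family — or
(score, group) for the clinical models.  The default family pools the
whole-brain, network and regional p-values (1 + 6 + R tests); a `per-level`
mode corrects each level separately.  Both behaviors exist because either
reading of a multi-level correction scheme is defensible; neither is asserted
as uniquely correct.

**Clinical correlations.**  HAMA/HAMD replace the measure as response within
each patient group, with the target's GSCORR as focal fixed effect and the
same covariates; the site random structure is retained, with the by-site
slope now on the (centered) predictor.

## The synthetic cohort generator

The generator is the package's ground-truth instrument, not a fixture.  Every
gray-matter voxel of ROI r follows

    x_v(t) = c_r · g(t) + l_r(t) + leakage + ε_v(t)

with `g(t)` a unit-variance Gaussian process band-limited to 0.01–0.1 Hz
(FFT-domain mask — the simplest stationary band-limited process, chosen so the
ALFF/fALFF band logic is analytically checkable), `l_r(t)` a *local*
band-limited signal shared by the ROI's member voxels, WM/CSF signal leakage
and motion-coupled nuisance, and white voxel noise (SD 4 by default, ~40–50
voxels per parcel at desk scale).  The local signal is what gives the phantom
a regional-homogeneity topography — high concordance inside parcels, low
across boundaries — that is stable across subjects; without it, ReHo maps are
sampling-noise-dominated and the 0.6 similarity floor misclassifies clean
subjects.  Amplitude-based alternatives cannot work here because Kendall's W
is rank-based and therefore scale-invariant.

The subject's coupling vector is

    c = base + effect·1[group, planted ROIs] + u_site + v_site·1[MDD]
             + covariate effects + subject deviation,

where `coupling_sd` (0.1) is the **total** per-ROI between-subject SD — so a
planted shift of `0.8 × coupling_sd` is a standardized effect of exactly
d = 0.8 — of which `subject_global_sd` (0.03) is the component shared across
ROIs.  Site intercepts have SD 0.05; the site-by-diagnosis slope SD defaults
to 0.01, kept small relative to subject variability because harmonized
consortium protocols show modest site-by-diagnosis heterogeneity and because,
with a handful of sites, a large random slope makes any fixed-effect contrast
degenerate.  Covariate confounds (age −0.001/yr, sex 0.01, education
0.002/yr, motion 0.1/mm on the coupling) exercise the adjustment path.

GMV is piecewise constant per ROI at `gmv_base 0.5 ± 0.05` with planted group
shifts (default −0.08 across the SEN network for the anxious group, the
GMV-mediated SFI effect).  The measure-level generator's total-GMV covariate
adds an unparcellated GM remainder (mean 60, SD 3): at desk scale the parcels
would otherwise hold an unrealistically large share of total gray matter,
making the planted GMV effect collinear with diagnosis — a phantom scaling
artifact, not a property of the method.  The image-level pipeline computes
total GMV from the map itself, so desk-scale image runs retain a mild version
of this collinearity.

HAMA/HAMD are linear in the coupling of designated link ROIs (default 18
score points per z-unit) plus Gaussian noise (SD 4), rounded and truncated to
scale ranges — anxious into (14, 56], non-anxious into [0, 14] — so the
HAMA stratification recovers the generative groups exactly and the
correlation analyses have a recoverable slope.  Motion is a bounded
random-walk (reflected at ±1 mm / ±0.02 rad) calibrated to mean FD ≈ 0.1 mm.
Sex is Bernoulli(0.5), education truncated normal (12 ± 3, clipped 6–22),
age uniform 18–64.

Parcellations are grown by multi-source BFS (geodesic Voronoi) from seeds
drawn uniformly in the GM mask of a concentric ellipsoid head phantom
(CSF core, WM shell, GM rind), so parcels are contiguous by construction and
exhaustively tile the GM mask; ROIs are assigned to the six networks in
contiguous id blocks.  All randomness fans out from a single seed through
counter-based substreams, so any subject can be regenerated independently of
order, and whole runs are byte-reproducible (tested).

Two generators share this model: the image-level one renders full NIfTI
cohorts and exercises every pipeline stage; the measure-level one draws the
per-subject per-ROI coupling (as observed GSCORR z) and GMV tables directly,
which is what simulation studies needing hundreds of cohorts require.  The
measure-level route contains no GSCORR estimation noise; its subject-level
variation is entirely the model's own.

## Validation studies and their scope

The test suite includes, at fixed seeds and reduced dimensions chosen to keep
a full run in minutes on one CPU:

* **Oracle equivalence** of GSCORR, ALFF/fALFF, ReHo and the aggregations
  against independent brute-force implementations (1e-10 to 1e-12).
* **Null calibration**: 500 null cohorts (10 ROIs, 3 sites, 15 per cell); the
  family-wise false-discovery proportion stays within Monte-Carlo error of
  the nominal 0.05.
* **Effect recovery**: d = 0.8 planted in 5 of 40 ROIs, n = 60/group over 4
  sites, 100 replicates, in a recovery design where the planted shift is the
  only group-linked signal (no site-by-diagnosis heterogeneity, though the
  full random-slope model is still fitted): sensitivity ≈ 0.83, false flags
  ≈ 0.003, SEN-network SFI detection ≈ 0.99.  With site-slope heterogeneity
  at the generator default the sensitivity drops to ≈ 0.78: with only four
  sites, the REML slope-variance estimate is noisy and its SE cost is real.
  Users fitting `(Diagnosis|Site)` with few sites should expect this.
* **Clinical recovery**: the generative HAMA link is recovered with ≥ 95%
  power at n = 150; permuted scores reject at the nominal rate.
* **Determinism**: two complete runs from one seed are byte-identical.

What passing these does **not** show: the phantom has no hemodynamic
response, physiological noise, scanner drift, registration error or real
anatomy; its noise is temporally white; GSCORR's sampling distribution under
band-limited signals is narrower than for real autocorrelated BOLD.  Results
on real consortium data depend on preprocessing choices (FD variant, ReHo
neighborhood, group-mean construction) that the source literature does not
pin down; these are all configurable and recorded in outputs.

## Degenerate inputs and numerical conventions

Readers reject malformed input rather than coercing (duplicate subjects,
non-numeric cells, 3D files where 4D is required, missing values stay
missing).  Constant series yield ALFF = 0 with fALFF flagged 0; zero-variance
ROIs, masks and responses raise errors naming the culprit.  Exactly collinear
nuisance columns are dropped and logged (constant motion, for instance,
collapses the Friston-24 set).  Smoothing uses reflective boundaries with
σ = FWHM / (2√(2 ln 2)).  Friston-24 lag terms are zero-padded at t = 1.
FDR q-values are capped at 1 and ties share a q.  TSV outputs use `%.17g`
and round-trip float64 exactly (readers use round-trip parsing).
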