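"""Seeded synthetic multi-site cohorts with known ground-truth effects.

The generative model mirrors the constructs the pipeline measures.  A latent
band-limited global signal g(t) drives every gray-matter voxel with an
ROI-specific coupling c_r; diagnostic group shifts, site random intercepts and
slopes, and covariate confounds act additively on the coupling; gray-matter
volume is piecewise constant per ROI with its own planted group effects; and
clinical scores (HAMA/HAMD) are linear in the coupling of designated ROIs.

Two generators share this model:

* the image-level generator (:func:`generate_subject`, :func:`generate_cohort`)
  renders full 4D NIfTI BOLD series, tissue masks, motion traces and GMV maps,
  exercising the whole pipeline end to end;
* the measure-level generator (:func:`generate_measure_cohort`) draws the
  per-subject per-ROI coupling (on the Fisher-z scale) and GMV tables directly,
  which is what large statistical calibration simulations need.

Everything is reproducible bit-for-bit from (config, seed): cohort-level draws
(base coupling topography, site effects) and per-subject draws use disjoint,
counter-based random substreams, so regenerating one subject never depends on
generation order.
"""

from __future__ import annotations

import dataclasses
import json
from collections import deque
from pathlib import Path

import numpy as np
import pandas as pd

from gstopo.io import (
    NETWORKS,
    BoldImage,
    Parcellation,
    RoiMeasureTable,
    write_manifest,
    write_nifti,
)

GROUPS = ("HC", "MDD_nonanx", "MDD_anx")

# Substream tags for counter-based seeding (all < 2**31).
_STREAM_COHORT = 11
_STREAM_SUBJECT = 23
_STREAM_PARCELLATION = 37

# Clinical scale ranges.
HAMA_MAX = 56
HAMD_MAX = 52
HAMA_CUTOFF = 14


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-site cohort.

    Group structure is three cells per site (HC, non-anxious MDD, anxious
    MDD).  Couplings live on the Fisher-z correlation scale; ``effect_size``
    is the additive coupling shift of the affected group in ``effect_rois``
    (a standardized effect of d = |effect_size| / coupling_sd).
    """

    n_sites: int = 4
    subjects_per_site_per_group: int = 10
    grid_shape: tuple[int, int, int] = (20, 20, 16)
    n_rois: int = 40
    n_timepoints: int = 200
    n_discard: int = 5
    tr_seconds: float = 2.0
    gs_band: tuple[float, float] = (0.01, 0.1)

    # Coupling topography (Fisher-z scale).  coupling_sd is the TOTAL
    # between-subject sd of a single ROI's coupling (so a planted shift of
    # 0.8 * coupling_sd is a standardized effect of exactly d = 0.8);
    # subject_global_sd is the part of it shared across all ROIs.
    coupling_base: float = 0.3
    coupling_roi_sd: float = 0.08   # cohort-level ROI-to-ROI spread
    coupling_sd: float = 0.1
    subject_global_sd: float = 0.03

    # Planted group effects.
    effect_rois: tuple[int, ...] = (1, 2, 3, 22, 23)
    effect_size: float = -0.08
    effect_group: str = "MDD_anx"
    gmv_effect_rois: tuple[int, ...] | None = None  # default: all SEN ROIs
    gmv_effect_size: float = -0.08

    # Gray-matter volume (arbitrary concentration units).  The total-GMV
    # covariate adds an unparcellated GM remainder so the parcels hold a
    # realistically small share of total gray matter.
    gmv_base: float = 0.5
    gmv_roi_sd: float = 0.05
    gmv_sd: float = 0.05
    gm_remainder_mean: float = 60.0
    gm_remainder_sd: float = 3.0

    # Site random effects on coupling.  The slope scale is kept small relative
    # to subject-level variability: harmonized consortium protocols show
    # modest site-by-diagnosis heterogeneity, and with a handful of sites a
    # large random slope makes any fixed-effect contrast degenerate.
    site_intercept_sd: float = 0.05
    site_slope_sd: float = 0.01

    # Image-level nuisance structure.  Besides the global signal, every ROI
    # carries a local band-limited signal shared by its member voxels
    # (local_signal_sd): this is what gives the phantom a regional-homogeneity
    # topography — high concordance inside parcels, low across boundaries —
    # that is stable across subjects, as in real data.
    noise_sd: float = 3.0
    local_signal_sd: float = 1.0
    wm_leak: float = 0.2            # WM signal leakage into GM voxels
    csf_leak: float = 0.2
    motion_leak: float = 0.05

    # Covariate confounding on coupling (age in years, sex 0/1, education in
    # years, motion as mean FD in mm), applied as coef * centered covariate.
    covariate_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"age": -0.001, "sex": 0.01, "education": 0.002, "motion": 0.1}
    )

    # Clinical score generation: the first link ROI drives HAMA, the second
    # (or the first again) drives HAMD, in score points per coupling-z unit.
    clinical_link_rois: tuple[int, ...] = (15, 16)
    clinical_link_beta: float = 18.0
    hama_noise_sd: float = 4.0
    hamd_noise_sd: float = 4.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "subjects_per_site_per_group", "n_rois", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive counts, got {self.grid_shape}")
        if self.n_rois > int(np.prod(self.grid_shape)):
            raise ValueError("n_rois exceeds the number of voxels in the grid")
        nyquist = 0.5 / self.tr_seconds
        lo, hi = self.gs_band
        if not (0 < lo < hi <= nyquist):
            raise ValueError(f"gs_band {self.gs_band} must lie within (0, Nyquist={nyquist}]")
        bad = [r for r in self.effect_rois if not 1 <= r <= self.n_rois]
        if bad:
            raise ValueError(f"effect_rois outside 1..{self.n_rois}: {bad}")
        bad = [r for r in self.clinical_link_rois if not 1 <= r <= self.n_rois]
        if bad:
            raise ValueError(f"clinical_link_rois outside 1..{self.n_rois}: {bad}")
        for name in ("coupling_sd", "site_intercept_sd", "site_slope_sd", "noise_sd",
                     "gmv_sd", "subject_global_sd", "hama_noise_sd", "hamd_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_group not in GROUPS:
            raise ValueError(f"effect_group must be one of {GROUPS}")
        if self.gmv_effect_rois is None:
            self.gmv_effect_rois = tuple(
                r for r, net in network_assignment(self.n_rois).items() if net == "SEN"
            )
        bad = [r for r in self.gmv_effect_rois if not 1 <= r <= self.n_rois]
        if bad:
            raise ValueError(f"gmv_effect_rois outside 1..{self.n_rois}: {bad}")

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        for key in ("grid_shape", "gs_band", "effect_rois", "gmv_effect_rois",
                    "clinical_link_rois"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class SubjectGroundTruth:
    """Planted per-subject truth, reproducible from (config, site, group, index)."""

    subject_id: str
    group: str
    true_coupling: np.ndarray
    true_gmv: np.ndarray
    site_intercept: float
    site_slope: float
    hama: int
    hamd: int
    gs_trace: np.ndarray | None = None


def network_assignment(n_rois: int) -> dict[int, str]:
    """Deterministic ROI -> network map: contiguous id blocks over six networks."""
    if n_rois < len(NETWORKS):
        raise ValueError(f"need at least {len(NETWORKS)} ROIs to cover all networks")
    chunks = np.array_split(np.arange(1, n_rois + 1), len(NETWORKS))
    return {int(r): net for net, chunk in zip(NETWORKS, chunks) for r in chunk}


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


# ---------------------------------------------------------------------------
# Geometry: tissue masks and parcellation
# ---------------------------------------------------------------------------

def tissue_masks(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Concentric synthetic head: CSF core, WM shell, GM rind, air outside.

    The 'brain' is an axis-aligned ellipsoid of semi-axes 0.45 * grid size;
    within it, normalized radius < 0.25 is CSF (ventricle stand-in), 0.25-0.55
    is WM, and the remainder is GM.
    """
    shape = config.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    idx = np.indices(shape).astype(float)
    rho = np.sqrt(sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3)))
    brain = rho <= 1.0
    csf = rho < 0.25
    wm = (rho >= 0.25) & (rho < 0.55)
    gm = brain & ~csf & ~wm
    return {"gm": gm, "wm": wm, "csf": csf, "brain": brain}


_NEIGH6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _grow_parcels(mask: np.ndarray, seeds: list[tuple[int, int, int]]) -> np.ndarray:
    """Multi-source BFS (geodesic Voronoi) within mask: contiguous by construction."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    queue: deque = deque()
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        queue.append(s)
    shape = mask.shape
    while queue:
        x, y, z = queue.popleft()
        lab = labels[x, y, z]
        for dx, dy, dz in _NEIGH6:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if mask[nx, ny, nz] and labels[nx, ny, nz] == 0:
                    labels[nx, ny, nz] = lab
                    queue.append((nx, ny, nz))
    return labels


def generate_parcellation(config: SimulationConfig) -> Parcellation:
    """Partition the synthetic GM mask into ``n_rois`` contiguous parcels.

    Seed voxels are drawn uniformly without replacement from the GM mask and
    parcels grown by multi-source breadth-first search, so every parcel is a
    non-empty contiguous cluster and their union is exactly the GM mask.
    """
    gm = tissue_masks(config)["gm"]
    coords = np.argwhere(gm)
    if len(coords) < config.n_rois:
        raise ValueError(
            f"grid {config.grid_shape} has only {len(coords)} GM voxels; "
            f"cannot host {config.n_rois} parcels"
        )
    rng = _rng(config.seed, _STREAM_PARCELLATION)
    pick = rng.choice(len(coords), size=config.n_rois, replace=False)
    seeds = [tuple(coords[i]) for i in pick]
    labels = _grow_parcels(gm, seeds)
    if (labels[gm] == 0).any():  # GM mask is connected by construction
        raise RuntimeError("parcel growth left unlabeled GM voxels")
    return Parcellation(labels=labels, network_of=network_assignment(config.n_rois))


# ---------------------------------------------------------------------------
# Cohort-level and subject-level draws
# ---------------------------------------------------------------------------

def cohort_params(config: SimulationConfig) -> dict:
    """Cohort-level draws shared by all subjects (deterministic from config.seed)."""
    rng = _rng(config.seed, _STREAM_COHORT)
    base_coupling = config.coupling_base + config.coupling_roi_sd * rng.standard_normal(config.n_rois)
    base_gmv = config.gmv_base + config.gmv_roi_sd * rng.standard_normal(config.n_rois)
    base_gmv = np.clip(base_gmv, 0.05, None)
    site_intercepts = config.site_intercept_sd * rng.standard_normal(config.n_sites)
    site_slopes = config.site_slope_sd * rng.standard_normal(config.n_sites)
    return {
        "base_coupling": base_coupling,
        "base_gmv": base_gmv,
        "site_intercepts": site_intercepts,
        "site_slopes": site_slopes,
    }


def _subject_id(site: int, group: str, index: int) -> str:
    return f"s{site:02d}_{group}_{index:03d}"


def _draw_demographics(rng: np.random.Generator) -> dict:
    age = int(rng.integers(18, 65))
    sex = int(rng.integers(0, 2))
    education = float(np.clip(np.round(rng.normal(12.0, 3.0)), 6, 22))
    return {"age": age, "sex": sex, "education": education}


def _draw_motion(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Bounded random walk: 3 translations (mm), 3 rotations (rad)."""
    t = config.n_timepoints
    step_sd = np.array([0.02, 0.02, 0.02, 4e-4, 4e-4, 4e-4])
    bound = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
    steps = rng.normal(0.0, step_sd, size=(t, 6))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    # reflect at +/- bound (triangle-wave fold of the unbounded walk)
    walk = bound - np.abs((walk + bound) % (4 * bound) - 2 * bound)
    return walk


def _mean_fd(motion: np.ndarray, radius: float = 50.0) -> float:
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    return float(np.concatenate([[0.0], fd]).mean())


def _subject_coupling(config: SimulationConfig, params: dict, group: str, site: int,
                      demo: dict, mean_fd: float, rng: np.random.Generator) -> np.ndarray:
    c = params["base_coupling"].copy()
    if group == config.effect_group:
        c[np.asarray(config.effect_rois) - 1] += config.effect_size
    is_mdd = float(group != "HC")
    c += params["site_intercepts"][site] + params["site_slopes"][site] * is_mdd
    ce = config.covariate_effects
    c += (
        ce.get("age", 0.0) * (demo["age"] - 40.0)
        + ce.get("sex", 0.0) * demo["sex"]
        + ce.get("education", 0.0) * (demo["education"] - 12.0)
        + ce.get("motion", 0.0) * (mean_fd - 0.1)
    )
    if config.subject_global_sd > config.coupling_sd:
        raise ValueError("subject_global_sd cannot exceed the total coupling_sd")
    roi_sd = np.sqrt(config.coupling_sd**2 - config.subject_global_sd**2)
    c += config.subject_global_sd * rng.standard_normal()
    c += roi_sd * rng.standard_normal(config.n_rois)
    return c


def _subject_gmv(config: SimulationConfig, params: dict, group: str,
                 rng: np.random.Generator) -> np.ndarray:
    g = params["base_gmv"].copy()
    if group == config.effect_group:
        g[np.asarray(config.gmv_effect_rois) - 1] += config.gmv_effect_size
    g += config.gmv_sd * rng.standard_normal(config.n_rois)
    return np.clip(g, 0.0, None)


def _clinical_scores(config: SimulationConfig, group: str, coupling: np.ndarray,
                     params: dict, rng: np.random.Generator) -> tuple[int, int]:
    """HAMA/HAMD linear in the coupling of the designated link ROIs.

    Anxious MDD scores are truncated into (14, 56], non-anxious into [0, 14],
    so the HAMA-based stratification recovers the generative groups exactly.
    """
    links = config.clinical_link_rois
    hama_dev = coupling[links[0] - 1] - params["base_coupling"][links[0] - 1]
    hamd_roi = links[1] if len(links) > 1 else links[0]
    hamd_dev = coupling[hamd_roi - 1] - params["base_coupling"][hamd_roi - 1]
    beta = config.clinical_link_beta
    if group == "HC":
        hama = int(np.clip(np.round(rng.normal(3.0, 2.0)), 0, 10))
        hamd = int(np.clip(np.round(rng.normal(2.0, 2.0)), 0, 7))
    elif group == "MDD_nonanx":
        hama = int(np.clip(np.round(8.0 + beta * hama_dev + rng.normal(0, config.hama_noise_sd)),
                           0, HAMA_CUTOFF))
        hamd = int(np.clip(np.round(17.0 + beta * hamd_dev + rng.normal(0, config.hamd_noise_sd)),
                           0, HAMD_MAX))
    elif group == "MDD_anx":
        hama = int(np.clip(np.round(24.0 + beta * hama_dev + rng.normal(0, config.hama_noise_sd)),
                           HAMA_CUTOFF + 1, HAMA_MAX))
        hamd = int(np.clip(np.round(22.0 + beta * hamd_dev + rng.normal(0, config.hamd_noise_sd)),
                           0, HAMD_MAX))
    else:
        raise ValueError(f"unknown group {group!r}")
    return hama, hamd


def _band_limited_signal(n: int, tr: float, band: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian process with power confined to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec[~keep] = 0.0
    g = np.fft.irfft(spec, n=n)
    sd = g.std()
    if sd > 0:
        g = g / sd
    return g


def generate_subject(config: SimulationConfig, site: int, group: str, index: int,
                     parcellation: Parcellation | None = None):
    """Render one synthetic subject: BOLD, tissue masks, motion, GMV, truth.

    Every gray-matter voxel of ROI r follows ``c_r * g(t)`` plus WM/CSF signal
    leakage, motion-coupled nuisance and white noise; the GMV map is constant
    within each ROI at the subject's true value.

    Returns ``(BoldImage, masks, motion, gmv_map, SubjectGroundTruth)`` where
    ``masks`` is a dict with keys gm/wm/csf/brain.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if not 0 <= site < config.n_sites:
        raise ValueError(f"site index {site} outside 0..{config.n_sites - 1}")
    if parcellation is None:
        parcellation = generate_parcellation(config)
    params = cohort_params(config)
    masks = tissue_masks(config)
    g_idx = GROUPS.index(group)
    rng = _rng(config.seed, _STREAM_SUBJECT, site, g_idx, index)

    demo = _draw_demographics(rng)
    motion = _draw_motion(config, rng)
    fd = _mean_fd(motion)
    coupling = _subject_coupling(config, params, group, site, demo, fd, rng)
    gmv = _subject_gmv(config, params, group, rng)
    hama, hamd = _clinical_scores(config, group, coupling, params, rng)

    t_total = config.n_timepoints + config.n_discard
    tr = config.tr_seconds
    g_full = _band_limited_signal(t_total, tr, config.gs_band, rng)
    wm_sig = _band_limited_signal(t_total, tr, (0.005, 0.15), rng)
    csf_sig = _band_limited_signal(t_total, tr, (0.005, 0.2), rng)
    # motion nuisance regressor: summed translations, padded to the full series
    mo_sig = np.zeros(t_total)
    mo_sig[config.n_discard:] = motion[:, :3].sum(axis=1)

    shape = config.grid_shape
    data = np.zeros(shape + (t_total,), dtype=np.float64)
    labels = parcellation.labels
    for r in parcellation.roi_ids:
        vox = labels == r
        series = coupling[r - 1] * g_full
        if config.local_signal_sd > 0:
            series = series + config.local_signal_sd * _band_limited_signal(
                t_total, tr, config.gs_band, rng)
        data[vox] = series
    gm = masks["gm"]
    data[gm] += config.wm_leak * 0.5 * wm_sig + config.csf_leak * 0.5 * csf_sig
    data[gm] += config.motion_leak * mo_sig
    data[masks["wm"]] = wm_sig + config.motion_leak * mo_sig
    data[masks["csf"]] = csf_sig + config.motion_leak * mo_sig
    if config.noise_sd > 0:
        data[masks["brain"]] += config.noise_sd * rng.standard_normal(
            (int(masks["brain"].sum()), t_total))

    bold = BoldImage(data=data, tr_seconds=tr, affine=np.eye(4), n_discarded=0)
    gmv_map = np.zeros(shape)
    for r in parcellation.roi_ids:
        gmv_map[labels == r] = gmv[r - 1]

    truth = SubjectGroundTruth(
        subject_id=_subject_id(site, group, index),
        group=group,
        true_coupling=coupling,
        true_gmv=gmv,
        site_intercept=float(params["site_intercepts"][site]),
        site_slope=float(params["site_slopes"][site]),
        hama=hama,
        hamd=hamd,
        gs_trace=g_full[config.n_discard:],
    )
    truth.demographics = demo  # type: ignore[attr-defined]
    truth.mean_fd = fd  # type: ignore[attr-defined]
    truth.duration_months = _duration_months(group, rng)  # type: ignore[attr-defined]
    return bold, masks, motion, gmv_map, truth


def _duration_months(group: str, rng: np.random.Generator) -> float | None:
    if group == "HC":
        return None
    mu = 3.2 if group == "MDD_anx" else 2.8
    return float(np.round(np.exp(rng.normal(mu, 0.5)), 1))


def generate_cohort(config: SimulationConfig, out_dir: str | Path,
                    overwrite: bool = False) -> pd.DataFrame:
    """Write a full synthetic cohort to ``out_dir`` and return its manifest.

    Layout: shared ``parcellation.nii.gz``/``networks.tsv``/tissue masks, one
    BOLD + motion + GMV file per subject under ``subjects/``, the manifest as
    ``manifest.tsv`` (diagnosis pre-stratification: HC/MDD), the planted truth
    as ``ground_truth.tsv`` and the config as ``config.json``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    (out / "subjects").mkdir(parents=True, exist_ok=True)

    parc = generate_parcellation(config)
    masks = tissue_masks(config)
    parc.to_files(out / "parcellation.nii.gz", out / "networks.tsv")
    for name in ("gm", "wm", "csf"):
        write_nifti(masks[name].astype(np.uint8), out / f"{name}_mask.nii.gz", dtype=np.uint8)
    config.to_json(out / "config.json")

    rows = []
    truth_rows = []
    for site in range(config.n_sites):
        for group in GROUPS:
            for index in range(config.subjects_per_site_per_group):
                bold, _, motion, gmv_map, truth = generate_subject(
                    config, site, group, index, parcellation=parc
                )
                sid = truth.subject_id
                bold_path = out / "subjects" / f"{sid}_bold.nii.gz"
                motion_path = out / "subjects" / f"{sid}_motion.txt"
                gmv_path = out / "subjects" / f"{sid}_gmv.nii.gz"
                write_nifti(bold.data, bold_path, tr_seconds=config.tr_seconds)
                np.savetxt(motion_path, motion, fmt="%.8f")
                write_nifti(gmv_map, gmv_path)
                demo = truth.demographics
                rows.append({
                    "subject_id": sid,
                    "site_id": f"site{site:02d}",
                    "diagnosis": "HC" if group == "HC" else "MDD",
                    "age": demo["age"],
                    "sex": demo["sex"],
                    "education": demo["education"],
                    "hama": truth.hama,
                    "hamd": truth.hamd,
                    "duration_months": truth.duration_months,
                    "visual_qc_fail": 0,
                    "tr_seconds": config.tr_seconds,
                    "n_discard": config.n_discard,
                    "bold_path": str(bold_path.relative_to(out)),
                    "gm_mask_path": "gm_mask.nii.gz",
                    "wm_mask_path": "wm_mask.nii.gz",
                    "csf_mask_path": "csf_mask.nii.gz",
                    "motion_path": str(motion_path.relative_to(out)),
                    "gmv_path": str(gmv_path.relative_to(out)),
                })
                truth_rows.append({
                    "subject_id": sid,
                    "true_group": group,
                    "site_intercept": truth.site_intercept,
                    "site_slope": truth.site_slope,
                    "mean_fd": truth.mean_fd,
                    **{f"coupling_roi_{r}": truth.true_coupling[r - 1] for r in parc.roi_ids},
                    **{f"gmv_roi_{r}": truth.true_gmv[r - 1] for r in parc.roi_ids},
                })
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.tsv")
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False,
                                    float_format="%.17g")
    return manifest


# ---------------------------------------------------------------------------
# Measure-level cohorts (for statistical calibration at scale)
# ---------------------------------------------------------------------------

def generate_measure_cohort(config: SimulationConfig):
    """Draw per-subject per-ROI measure tables directly from the generative model.

    Skips image rendering: the subject's coupling vector is taken as the
    observed GSCORR (Fisher z), GMV as the observed per-ROI gray-matter volume,
    and SFI as their product — exactly the quantities the feature stage would
    estimate, without estimation noise beyond the model's own subject-level
    variation.  Used for simulation studies (type-I calibration, power) where
    thousands of cohorts are needed.

    Returns ``(manifest, measures)`` where manifest rows carry post-
    stratification diagnosis labels plus covariates, and ``measures`` maps
    GSCORR/GMV/SFI to :class:`RoiMeasureTable`.
    """
    params = cohort_params(config)
    net_of = network_assignment(config.n_rois)
    rows = []
    z_rows = []
    gmv_rows = []
    for site in range(config.n_sites):
        for group in GROUPS:
            for index in range(config.subjects_per_site_per_group):
                g_idx = GROUPS.index(group)
                rng = _rng(config.seed, _STREAM_SUBJECT, site, g_idx, index)
                demo = _draw_demographics(rng)
                motion = _draw_motion(config, rng)
                fd = _mean_fd(motion)
                coupling = _subject_coupling(config, params, group, site, demo, fd, rng)
                gmv = _subject_gmv(config, params, group, rng)
                hama, hamd = _clinical_scores(config, group, coupling, params, rng)
                remainder = config.gm_remainder_mean + config.gm_remainder_sd * rng.standard_normal()
                sid = _subject_id(site, group, index)
                rows.append({
                    "subject_id": sid,
                    "site_id": f"site{site:02d}",
                    "diagnosis": group,
                    "age": demo["age"],
                    "sex": demo["sex"],
                    "education": demo["education"],
                    "hama": hama,
                    "hamd": hamd,
                    "mean_fd": fd,
                    "total_gmv": float(gmv.sum() + remainder),
                })
                z_rows.append(coupling)
                gmv_rows.append(gmv)
    manifest = pd.DataFrame(rows)
    z = np.asarray(z_rows)
    gmv = np.asarray(gmv_rows)
    measures = {
        "GSCORR": _roi_table("GSCORR", z, manifest["subject_id"], net_of),
        "GMV": _roi_table("GMV", gmv, manifest["subject_id"], net_of),
        "SFI": _roi_table("SFI", z * gmv, manifest["subject_id"], net_of),
    }
    return manifest, measures


def _roi_table(measure: str, values: np.ndarray, subject_ids, net_of: dict[int, str]) -> RoiMeasureTable:
    """Assemble a measure table with whole-brain and network aggregates."""
    n_rois = values.shape[1]
    cols = {"whole_brain": values.mean(axis=1)}
    for net in NETWORKS:
        members = [r - 1 for r, n in net_of.items() if n == net]
        cols[f"net_{net}"] = values[:, members].mean(axis=1)
    for r in range(1, n_rois + 1):
        cols[f"roi_{r}"] = values[:, r - 1]
    df = pd.DataFrame(cols, index=pd.Index(subject_ids, name="subject_id"))
    return RoiMeasureTable(measure=measure, values=df)
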