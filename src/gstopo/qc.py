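"""Subject-level quality control and anxious/non-anxious stratification.

Implements the seven-step exclusion cascade used for multi-site resting-state
cohorts: (1) missing sex/age/education, (2) age outside 18-65, (3) poor image
quality or bad normalization (an input flag — visual inspection is not
computable), (4) excessive motion (mean FD > 0.2 mm) or inadequate brain
coverage (< 90% of the group mask), (5) ReHo spatial correlation with the
group mean below 0.6, (6) missing HAMA, (7) sites left with fewer than 10
subjects.  Included MDD subjects are then stratified by HAMA: > 14 anxious,
<= 14 non-anxious.

FD is Power's formulation (sum of absolute backward differences, rotations
converted to arc length on a 50 mm sphere).  ReHo is Kendall's coefficient of
concordance over a voxel's time series and its in-mask neighbors, with midrank
tie correction; the group-mean ReHo map for the similarity check is
leave-one-out by default to avoid self-correlation inflation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy import ndimage

from gstopo.io import BoldImage

#: Exclusion criterion codes, in cascade order.
CRITERIA = {
    1: "missing sex/age/education",
    2: "age outside 18-65",
    3: "poor imaging quality / bad normalization (visual flag)",
    4: "excessive motion or inadequate coverage",
    5: "ReHo spatial correlation below threshold",
    6: "missing HAMA",
    7: "site below minimum subject count",
}


@dataclasses.dataclass
class QcThresholds:
    """Exclusion thresholds; defaults follow the stated cascade."""

    age_min: float = 18.0
    age_max: float = 65.0
    fd_max: float = 0.2            # mm, mean framewise displacement
    coverage_min: float = 0.90     # fraction of the group mask
    reho_corr_min: float = 0.6     # fixed floor (adaptive mean-2SD optional)
    reho_adaptive: bool = False    # recompute threshold as pool mean - 2SD
    site_min_n: int = 10
    hama_cutoff: float = 14.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage_min <= 1:
            raise ValueError(f"coverage_min must be in (0, 1], got {self.coverage_min}")
        for name in ("age_min", "age_max", "fd_max", "reho_corr_min", "hama_cutoff"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def compute_fd(motion: np.ndarray, rotation_radius: float = 50.0) -> tuple[np.ndarray, float]:
    """Power-style framewise displacement from T x 6 rigid-body parameters.

    FD_t = sum_i |d trans_i| + radius * sum_j |d rot_j| for t >= 2, FD_1 = 0.
    Columns are 3 translations in mm then 3 rotations in radians.  Returns the
    per-frame trace and its mean over all frames.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate([[0.0], d[:, :3].sum(axis=1) + rotation_radius * d[:, 3:].sum(axis=1)])
    return fd, float(fd.mean())


def coverage_fraction(subject_mask: np.ndarray, group_mask: np.ndarray) -> float:
    """Fraction of the group mask covered by the subject's brain mask."""
    group_mask = np.asarray(group_mask, bool)
    n_group = int(group_mask.sum())
    if n_group == 0:
        raise ValueError("group mask is empty")
    return float(np.logical_and(subject_mask, group_mask).sum() / n_group)


_NEIGHBORHOODS = {
    7: np.array([[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
                 [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
                 [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool),
    19: ndimage.generate_binary_structure(3, 2),
    27: np.ones((3, 3, 3), dtype=bool),
}


def compute_reho(bold: BoldImage, mask: np.ndarray, neighborhood: int = 27) -> np.ndarray:
    """Voxelwise Kendall's coefficient of concordance (W) over local neighborhoods.

    For each in-mask voxel, W is computed across the time series of the voxel
    and its in-mask neighbors (K series, n timepoints):

        W = 12 * S / (K^2 (n^3 - n) - K * T_corr),

    with S the sum of squared deviations of per-timepoint rank sums from their
    mean and T_corr the midrank tie correction sum((t^3 - t)) over tied groups
    of every series.  Edge voxels use available in-mask neighbors only; an
    isolated voxel gets W = 1 by convention.  Out-of-mask voxels are 0.
    """
    if neighborhood not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n = bold.n_timepoints
    if n < 3:
        raise ValueError("need at least 3 timepoints for ReHo")
    data = bold.data
    # per-voxel temporal ranks (midranks for ties)
    ranks = np.zeros_like(data)
    ranks[mask] = rankdata(data[mask], axis=-1)
    ranks[~mask] = 0.0
    # per-voxel tie correction term sum(t^3 - t) over tied groups
    tie = np.zeros(data.shape[:3])
    in_idx = np.argwhere(mask)
    sorted_in = np.sort(data[mask], axis=-1)
    changes = np.diff(sorted_in, axis=-1) != 0
    # run lengths of ties: for each voxel, group sizes of equal values
    tie_vals = np.zeros(len(in_idx))
    for i in range(len(in_idx)):
        # boundaries of tied runs
        t_sizes = np.diff(np.concatenate([[0], np.flatnonzero(changes[i]) + 1, [n]]))
        t_sizes = t_sizes[t_sizes > 1]
        if t_sizes.size:
            tie_vals[i] = float(np.sum(t_sizes**3 - t_sizes))
    tie[mask] = tie_vals

    kern = _NEIGHBORHOODS[neighborhood].astype(float)
    maskf = mask.astype(float)
    k_map = ndimage.convolve(maskf, kern, mode="constant", cval=0.0)
    tie_sum = ndimage.convolve(tie * maskf, kern, mode="constant", cval=0.0)
    # rank sums per timepoint over the neighborhood
    rank_sum = np.stack(
        [ndimage.convolve(ranks[..., t] * maskf, kern, mode="constant", cval=0.0)
         for t in range(n)],
        axis=-1,
    )
    mean_rank = rank_sum.mean(axis=-1, keepdims=True)
    s = ((rank_sum - mean_rank) ** 2).sum(axis=-1)
    k = np.round(k_map)
    denom = k**2 * (n**3 - n) - k * tie_sum
    w = np.zeros(data.shape[:3])
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(12.0 * s, denom, out=w, where=denom > 0)
    # all-constant neighborhood (denom == 0) or isolated voxel: W = 1 by convention
    w[mask & (denom <= 0)] = 1.0
    w[mask & (k == 1)] = 1.0
    w[~mask] = 0.0
    return np.clip(w, 0.0, 1.0)


def reho_similarity(subject_reho: np.ndarray, group_mean_reho: np.ndarray,
                    mask: np.ndarray, subject_id: str = "?") -> float:
    """Pearson correlation between a subject's ReHo map and the group mean."""
    mask = np.asarray(mask, bool)
    a = np.asarray(subject_reho, float)[mask]
    b = np.asarray(group_mean_reho, float)[mask]
    if a.size < 3:
        raise ValueError("need at least 3 in-mask voxels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError(f"zero-variance ReHo map for subject {subject_id}")
    return float(np.corrcoef(a, b)[0, 1])


def group_mean_reho(reho_maps: dict[str, np.ndarray], leave_out: str | None = None) -> np.ndarray:
    """Mean ReHo map across subjects, optionally leaving one subject out."""
    keys = [k for k in reho_maps if k != leave_out]
    if not keys:
        raise ValueError("no maps left after leave-one-out")
    return np.mean([reho_maps[k] for k in keys], axis=0)


def apply_exclusions(manifest: pd.DataFrame, metrics: pd.DataFrame,
                     thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Run the exclusion cascade and HAMA stratification; return the QC report.

    ``metrics`` is indexed (or keyed) by subject_id with optional columns
    ``mean_fd``, ``coverage``, ``reho_corr``; a metric absent for a subject
    simply cannot trigger its criterion.  Criterion 3 reads the manifest's
    ``visual_qc_fail`` flag.  Criteria 1-6 are applied in order, then the
    site minimum is enforced on the survivors (criterion 7).  Included MDD
    subjects are split by HAMA into MDD_anx (> cutoff) and MDD_nonanx.

    The report has one row per subject: all computed metrics, the ordered
    failed-criterion codes (comma-separated), inclusion status, and the final
    diagnosis label.
    """
    thr = thresholds or QcThresholds()
    if metrics is not None and len(metrics) and "subject_id" in metrics.columns:
        metrics = metrics.set_index("subject_id")

    if thr.reho_adaptive and metrics is not None and "reho_corr" in getattr(metrics, "columns", []):
        pool = metrics["reho_corr"].dropna()
        reho_floor = float(pool.mean() - 2 * pool.std(ddof=1)) if len(pool) > 2 else thr.reho_corr_min
    else:
        reho_floor = thr.reho_corr_min

    rows = []
    for _, sub in manifest.iterrows():
        sid = sub["subject_id"]
        failed: list[int] = []
        met = metrics.loc[sid] if metrics is not None and sid in getattr(metrics, "index", []) else None

        def metric(name):
            if met is None or name not in met.index:
                return None
            v = met[name]
            return None if pd.isna(v) else float(v)

        if any(pd.isna(sub.get(c)) or sub.get(c) == "" for c in ("sex", "age", "education")):
            failed.append(1)
        age = sub.get("age")
        if not pd.isna(age) and not (thr.age_min <= float(age) <= thr.age_max):
            failed.append(2)
        if int(sub.get("visual_qc_fail", 0) or 0):
            failed.append(3)
        fd = metric("mean_fd")
        cov = metric("coverage")
        if (fd is not None and fd > thr.fd_max) or (cov is not None and cov < thr.coverage_min):
            failed.append(4)
        rs = metric("reho_corr")
        if rs is not None and rs < reho_floor:
            failed.append(5)
        if pd.isna(sub.get("hama")):
            failed.append(6)
        rows.append({
            "subject_id": sid,
            "site_id": sub["site_id"],
            "diagnosis_in": sub["diagnosis"],
            "mean_fd": fd,
            "coverage": cov,
            "reho_corr": rs,
            "failed_criteria": failed,
        })
    report = pd.DataFrame(rows)

    survivors = report["failed_criteria"].map(len) == 0
    # criterion 7: sites with fewer than site_min_n survivors lose all subjects
    counts = report.loc[survivors, "site_id"].value_counts()
    small_sites = set(counts[counts < thr.site_min_n].index)
    for i in report.index[survivors]:
        if report.at[i, "site_id"] in small_sites:
            report.at[i, "failed_criteria"].append(7)

    report["included"] = report["failed_criteria"].map(len) == 0
    hama = pd.to_numeric(manifest.set_index("subject_id")["hama"], errors="coerce")

    def final_label(row):
        if not row["included"]:
            return ""
        diag = row["diagnosis_in"]
        if diag == "HC":
            return "HC"
        if diag in ("MDD_anx", "MDD_nonanx"):  # already stratified upstream
            return diag
        h = hama.get(row["subject_id"])
        return "MDD_anx" if h > thr.hama_cutoff else "MDD_nonanx"

    report["diagnosis"] = report.apply(final_label, axis=1)
    report["failed_criteria"] = report["failed_criteria"].map(
        lambda codes: ",".join(str(c) for c in codes)
    )
    report["fd_variant"] = "power_radius50mm"
    return report
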