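"""Subject-level measures: nuisance regression, ALFF/fALFF, GS, GSCORR, SFI.

The global signal (GS) is the unweighted mean time series over gray-matter
voxels of the nuisance-regressed BOLD.  GSCORR is the Pearson correlation of
each ROI's mean series with the GS, Fisher r-to-z transformed; SFI is the
per-ROI product of GSCORR (z) and mean gray-matter volume.  ALFF is the mean
amplitude (square root of power) over 0.01-0.1 Hz of the voxel spectrum;
fALFF normalizes by the amplitude summed over all positive frequencies.

GSCORR is computed on nuisance-regressed, unfiltered series (band-limiting
applies only to ALFF/fALFF); optional band-pass is available for sensitivity
analysis.  No global-signal regression is performed anywhere: the GS is the
object of study.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from gstopo.io import NETWORKS, BoldImage, Parcellation

logger = logging.getLogger(__name__)

#: |r| is clipped here before atanh so Fisher z stays finite.
R_CLIP = 1.0 - 1e-7

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass
class NuisanceDesign:
    """T x k regressor matrix: Friston-24 motion set, WM/CSF means, intercept, trend.

    The Friston-24 set is {p_t, p_t^2, p_{t-1}, p_{t-1}^2} for the six
    rigid-body parameters (lag-1 terms zero-padded at t=1).  Exactly collinear
    columns are dropped (and logged) to keep the design full rank.
    """

    matrix: np.ndarray
    names: list[str]
    dropped: list[str]


def build_nuisance_design(motion: np.ndarray, wm_series: np.ndarray,
                          csf_series: np.ndarray, linear_trend: bool = True) -> NuisanceDesign:
    motion = np.asarray(motion, float)
    t = motion.shape[0]
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got {motion.shape}")
    if len(wm_series) != t or len(csf_series) != t:
        raise ValueError("WM/CSF series length must match motion rows")
    lag = np.vstack([np.zeros(6), motion[:-1]])
    cols = [motion, motion**2, lag, lag**2]
    names = (
        [f"mo{i}" for i in range(6)] + [f"mo{i}_sq" for i in range(6)]
        + [f"mo{i}_lag" for i in range(6)] + [f"mo{i}_lag_sq" for i in range(6)]
    )
    x = np.column_stack(cols + [wm_series, csf_series, np.ones(t)])
    names += ["wm", "csf", "intercept"]
    if linear_trend:
        x = np.column_stack([x, np.linspace(-1, 1, t)])
        names.append("trend")

    keep, dropped = _drop_collinear(x, names)
    if dropped:
        logger.warning("dropped exactly-collinear nuisance columns: %s", dropped)
    return NuisanceDesign(matrix=x[:, keep], names=[names[i] for i in keep], dropped=dropped)


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[list[int], list[str]]:
    """Greedy rank-preserving column selection via incremental QR."""
    keep: list[int] = []
    dropped: list[str] = []
    basis = np.zeros((x.shape[0], 0))
    for j in range(x.shape[1]):
        col = x[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > 1e-10 * max(1.0, np.linalg.norm(col)):
            basis = np.column_stack([basis, resid / norm])
            keep.append(j)
        else:
            dropped.append(names[j])
    return keep, dropped


def regress_nuisance(bold: BoldImage, motion: np.ndarray, wm_mask: np.ndarray,
                     csf_mask: np.ndarray, linear_trend: bool = True) -> BoldImage:
    """Residualize every voxel against the nuisance design (least squares)."""
    for name, m in (("WM", wm_mask), ("CSF", csf_mask)):
        if not np.asarray(m, bool).any():
            raise ValueError(f"{name} mask is empty")
    t = bold.n_timepoints
    if motion.shape[0] != t:
        raise ValueError(f"motion has {motion.shape[0]} rows, BOLD has {t} retained volumes")
    wm_series = bold.data[np.asarray(wm_mask, bool)].mean(axis=0)
    csf_series = bold.data[np.asarray(csf_mask, bool)].mean(axis=0)
    design = build_nuisance_design(motion, wm_series, csf_series, linear_trend=linear_trend)
    x = design.matrix
    if t <= x.shape[1]:
        raise ValueError(
            f"series too short ({t} volumes) for {x.shape[1]} nuisance regressors; "
            "acquire a longer series or reduce the design"
        )
    flat = bold.data.reshape(-1, t).T  # T x V
    beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
    resid = (flat - x @ beta).T.reshape(bold.data.shape)
    return BoldImage(data=resid, tr_seconds=bold.tr_seconds, affine=bold.affine,
                     n_discarded=bold.n_discarded)


@dataclasses.dataclass
class AmplitudeMaps:
    """Voxelwise ALFF and fALFF with Z-standardized, smoothed variants."""

    alff: np.ndarray
    falff: np.ndarray
    alff_z: np.ndarray | None = None
    falff_z: np.ndarray | None = None
    band: tuple[float, float] = (0.01, 0.1)
    n_flagged: int = 0  # voxels with no non-DC power (fALFF set to 0)


def compute_alff_falff(bold: BoldImage, mask: np.ndarray,
                       band: tuple[float, float] = (0.01, 0.1)) -> AmplitudeMaps:
    """ALFF/fALFF from the one-sided FFT amplitude spectrum.

    Amplitudes a_k = |X_k| / n at positive frequencies; ALFF is the mean of
    a_k with 0.01 <= f_k <= 0.1 Hz (inclusive, DC excluded), fALFF the ratio
    of the band amplitude sum to the sum over all positive frequencies up to
    Nyquist.  Voxels with zero non-DC power get fALFF = 0 and are counted in
    ``n_flagged``.
    """
    mask = np.asarray(mask, bool)
    n = bold.n_timepoints
    freqs = np.fft.rfftfreq(n, d=bold.tr_seconds)
    nyquist = 0.5 / bold.tr_seconds
    if band[1] > nyquist + 1e-12:
        raise ValueError(f"band upper edge {band[1]} Hz exceeds Nyquist {nyquist} Hz")
    in_band = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not in_band.any():
        raise ValueError(
            f"no frequency bins in [{band[0]}, {band[1]}] Hz at resolution "
            f"{freqs[1]:.6f} Hz (T={n}, TR={bold.tr_seconds}s)"
        )
    series = bold.data[mask]  # V x T
    amp = np.abs(np.fft.rfft(series, axis=-1)) / n
    band_amp = amp[:, in_band]
    pos = freqs > 0
    alff_v = band_amp.mean(axis=-1)
    total = amp[:, pos].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        falff_v = np.where(total > 0, band_amp.sum(axis=-1) / np.where(total > 0, total, 1.0), 0.0)
    n_flagged = int((total <= 0).sum())
    if n_flagged:
        logger.warning("%d voxel(s) with no non-DC power; fALFF set to 0", n_flagged)
    alff = np.zeros(bold.grid_shape)
    falff = np.zeros(bold.grid_shape)
    alff[mask] = alff_v
    falff[mask] = falff_v
    return AmplitudeMaps(alff=alff, falff=falff, band=tuple(band), n_flagged=n_flagged)


def z_standardize(map_3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the in-mask mean and divide by the in-mask SD; zero outside."""
    mask = np.asarray(mask, bool)
    vals = np.asarray(map_3d, float)[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("in-mask standard deviation is zero; cannot Z-standardize")
    out = np.zeros_like(np.asarray(map_3d, float))
    out[mask] = (vals - vals.mean()) / sd
    return out


def smooth_map(map_3d: np.ndarray, fwhm_mm: float, voxel_size_mm: float | tuple = 1.0) -> np.ndarray:
    """Separable Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Reflective boundary handling; ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    vox = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    if (vox <= 0).any():
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm == 0:
        return np.asarray(map_3d, float).copy()
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / vox
    return ndimage.gaussian_filter(np.asarray(map_3d, float), sigma=sigma_vox, mode="reflect")


def extract_gs(bold: BoldImage, gm_mask: np.ndarray) -> np.ndarray:
    """Global signal: unweighted mean over gray-matter voxels at each timepoint."""
    gm_mask = np.asarray(gm_mask, bool)
    if not gm_mask.any():
        raise ValueError("gray-matter mask is empty")
    return bold.data[gm_mask].mean(axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance series in correlation")
    return float(xc @ yc / (nx * ny))


def compute_gscorr(bold: BoldImage, gs: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Per-ROI Fisher-z GSCORR: correlate each ROI mean series with the GS.

    |r| is clipped at 1 - 1e-7 before atanh (clips are logged), so z is always
    finite.  Raises on empty or zero-variance ROI series.
    """
    if parc.labels.shape != bold.grid_shape:
        raise ValueError("parcellation grid does not match BOLD grid")
    z = np.empty(parc.n_rois)
    n_clipped = 0
    for i, roi in enumerate(parc.roi_ids):
        vox = parc.labels == roi
        if not vox.any():
            raise ValueError(f"ROI {roi} has no voxels")
        series = bold.data[vox].mean(axis=0)
        if series.std() == 0:
            raise ValueError(f"ROI {roi} has a zero-variance mean series")
        r = _pearson(series, gs)
        if abs(r) > R_CLIP:
            n_clipped += 1
            r = np.sign(r) * R_CLIP
        z[i] = np.arctanh(r)
    if n_clipped:
        logger.warning("clipped |r| to %.7f for %d ROI(s) before Fisher z", R_CLIP, n_clipped)
    return z


def roi_gmv(gmv_map: np.ndarray, parc: Parcellation, agg: str = "mean") -> tuple[np.ndarray, float]:
    """Per-ROI gray-matter volume plus the total-GMV covariate.

    ``agg`` is 'mean' (default: SFI not confounded by parcel size) or 'sum'.
    Total GMV is the sum over the parcellation's brain mask either way.
    """
    gmv_map = np.asarray(gmv_map, float)
    if gmv_map.shape != parc.labels.shape:
        raise ValueError("GMV map grid does not match parcellation grid")
    if (gmv_map[parc.brain_mask] < 0).any():
        raise ValueError("GMV map contains negative values")
    if agg not in ("mean", "sum"):
        raise ValueError("agg must be 'mean' or 'sum'")
    out = np.empty(parc.n_rois)
    for i, roi in enumerate(parc.roi_ids):
        vals = gmv_map[parc.labels == roi]
        out[i] = vals.sum() if agg == "sum" else vals.mean()
    total = float(gmv_map[parc.brain_mask].sum())
    return out, total


def compute_sfi(gscorr_z: np.ndarray, gmv_roi: np.ndarray) -> np.ndarray:
    """Structural-functional interaction: elementwise product z_r * GMV_r."""
    gscorr_z = np.asarray(gscorr_z, float)
    gmv_roi = np.asarray(gmv_roi, float)
    if gscorr_z.shape != gmv_roi.shape:
        raise ValueError(f"length mismatch: {gscorr_z.shape} vs {gmv_roi.shape}")
    return gscorr_z * gmv_roi


def aggregate_levels(roi_values: np.ndarray, parc: Parcellation) -> dict[str, float]:
    """Whole-brain and per-network aggregates of a per-ROI vector.

    Network value = unweighted mean over member ROIs; whole-brain value =
    unweighted mean over all ROIs.  Returns a dict keyed ``whole_brain``,
    ``net_<NETWORK>``.
    """
    roi_values = np.asarray(roi_values, float)
    if roi_values.shape != (parc.n_rois,):
        raise ValueError(f"expected {parc.n_rois} ROI values, got {roi_values.shape}")
    out = {"whole_brain": float(roi_values.mean())}
    ids = parc.roi_ids
    declared = set(parc.network_of.values())
    for net in NETWORKS:
        if net not in declared:
            continue
        members = [i for i, roi in enumerate(ids) if parc.network_of[roi] == net]
        if not members:
            raise ValueError(f"network {net} has no ROIs")
        out[f"net_{net}"] = float(roi_values[members].mean())
    return out


def bandpass(bold: BoldImage, band: tuple[float, float]) -> BoldImage:
    """FFT-domain band-pass (optional GSCORR sensitivity analysis)."""
    n = bold.n_timepoints
    freqs = np.fft.rfftfreq(n, d=bold.tr_seconds)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    return BoldImage(data=np.fft.irfft(spec, n=n, axis=-1), tr_seconds=bold.tr_seconds,
                     affine=bold.affine, n_discarded=bold.n_discarded)
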