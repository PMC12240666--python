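"""Readers/writers for on-disk artifacts and the shared in-memory data model.

All tabular artifacts are TSV; images are NIfTI-1 (optionally gzipped); motion
parameters are 6-column whitespace-delimited text with one row per retained
volume.  Readers validate and reject malformed input rather than silently
coercing it, and missing values stay missing (empty TSV fields), never sentinel
numbers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: The six functional networks of the 160-ROI functional parcellation:
#: cingulo-opercular, fronto-parietal, default-mode, sensorimotor, occipital
#: and cerebellar.
NETWORKS: tuple[str, ...] = ("CON", "FPN", "DMN", "SEN", "ON", "CEN")

#: Measures handled by the pipeline.
MEASURES: tuple[str, ...] = ("GSCORR", "SFI", "GMV", "ALFF", "fALFF")

#: Required manifest columns (path columns are optional for table-only work).
MANIFEST_REQUIRED = ("subject_id", "site_id", "diagnosis", "age", "sex", "education")

MANIFEST_NUMERIC = ("age", "education", "hama", "hamd", "duration_months", "mean_fd", "total_gmv")

DIAGNOSES = ("HC", "MDD", "MDD_nonanx", "MDD_anx")


@dataclasses.dataclass
class BoldImage:
    """A 4D BOLD series: voxel grid x time, with repetition time metadata.

    ``data`` has shape (x, y, z, t) with ``t >= 2``; ``n_discarded`` records how
    many leading volumes were already removed at load.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError(f"BOLD series needs >= 2 timepoints, got {self.data.shape[3]}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite voxels")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


@dataclasses.dataclass
class Parcellation:
    """Labeled ROI volume plus ROI -> network lookup.

    ``labels`` is a 3D integer volume with 0 = background and ROI ids
    1..R; ``network_of`` maps every ROI id to one of the six networks.
    """

    labels: np.ndarray
    network_of: dict[int, str]
    roi_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation labels must be a 3D volume")
        present = set(np.unique(self.labels)) - {0}
        ids = set(self.network_of)
        if present - ids:
            raise ValueError(f"labels contain ROI ids without a network: {sorted(present - ids)}")
        if ids - present:
            raise ValueError(f"network map names ROI ids absent from labels: {sorted(ids - present)}")
        bad = {r: n for r, n in self.network_of.items() if n not in NETWORKS}
        if bad:
            raise ValueError(f"unknown network names: {bad}")
        if self.roi_names is None:
            self.roi_names = {r: f"roi_{r:03d}" for r in sorted(ids)}

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.network_of)

    @property
    def n_rois(self) -> int:
        return len(self.network_of)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def rois_in_network(self, network: str) -> list[int]:
        return [r for r in self.roi_ids if self.network_of[r] == network]

    def to_files(self, labels_path: str | Path, networks_path: str | Path,
                 affine: np.ndarray | None = None) -> None:
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(labels_path))
        rows = [
            {"roi_id": r, "roi_name": self.roi_names[r], "network": self.network_of[r]}
            for r in self.roi_ids
        ]
        pd.DataFrame(rows).to_csv(networks_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, labels_path: str | Path, networks_path: str | Path) -> "Parcellation":
        labels = np.asanyarray(nib.load(str(labels_path)).dataobj).astype(int)
        tab = pd.read_csv(networks_path, sep="\t")
        for col in ("roi_id", "network"):
            if col not in tab.columns:
                raise ValueError(f"network table {networks_path} lacks column {col!r}")
        names = None
        if "roi_name" in tab.columns:
            names = dict(zip(tab["roi_id"].astype(int), tab["roi_name"].astype(str)))
        return cls(
            labels=labels,
            network_of=dict(zip(tab["roi_id"].astype(int), tab["network"].astype(str))),
            roi_names=names,
        )


@dataclasses.dataclass
class RoiMeasureTable:
    """Per-subject values of one measure at whole-brain, network and ROI level.

    ``values`` is indexed by subject_id with columns ``whole_brain``,
    ``net_<NETWORK>`` for each of the six networks, and ``roi_<id>`` for each
    ROI, in that order.
    """

    measure: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")

    @property
    def roi_columns(self) -> list[str]:
        return [c for c in self.values.columns if c.startswith("roi_")]

    @property
    def target_columns(self) -> list[str]:
        """All analysis targets in whole-brain, network, regional order."""
        nets = [c for c in self.values.columns if c.startswith("net_")]
        return ["whole_brain"] + nets + self.roi_columns

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index=True, index_label="subject_id",
                           float_format="%.17g")

    @classmethod
    def from_tsv(cls, measure: str, path: str | Path) -> "RoiMeasureTable":
        values = pd.read_csv(path, sep="\t", index_col="subject_id",
                             float_precision="round_trip")
        return cls(measure=measure, values=values)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest TSV.

    Returns typed rows; empty cells in numeric columns become NaN (missing is
    representable, never imputed).  Rejects missing required columns, duplicate
    subject ids and unparseable numerics.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required column(s): {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"manifest {path} has duplicate subject_id(s): {sorted(set(dupes))}")
    for col in MANIFEST_NUMERIC:
        if col not in df.columns:
            continue
        raw = df[col].str.strip()
        blank = raw == ""
        try:
            vals = pd.to_numeric(raw.where(~blank, None))
        except (ValueError, TypeError) as err:
            raise ValueError(f"manifest {path} column {col!r} is not numeric: {err}") from None
        df[col] = vals
    bad_diag = sorted(set(df["diagnosis"]) - set(DIAGNOSES))
    if bad_diag:
        raise ValueError(f"manifest {path} has unknown diagnosis value(s): {bad_diag}")
    neg = [c for c in ("age", "education") if (df[c].dropna() < 0).any()]
    if neg:
        raise ValueError(f"manifest {path} has negative values in {neg}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    """Write a manifest TSV; missing values become empty fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_bold(path: str | Path, n_discard: int = 0,
              tr_override: float | None = None) -> BoldImage:
    """Load a 4D NIfTI, dropping the first ``n_discard`` volumes.

    The repetition time is taken from the NIfTI header unless ``tr_override``
    is given (e.g. from the manifest).
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {img.ndim}D")
    t_total = img.shape[3]
    if t_total - n_discard < 2:
        raise ValueError(
            f"{path}: {t_total} volumes with n_discard={n_discard} leaves fewer than 2"
        )
    data = np.asanyarray(img.dataobj).astype(np.float64)[..., n_discard:]
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: BOLD contains NaN/Inf voxels")
    tr = float(tr_override) if tr_override is not None else float(img.header.get_zooms()[3])
    return BoldImage(data=data, tr_seconds=tr, affine=img.affine, n_discarded=int(n_discard))


def read_mask(path: str | Path) -> np.ndarray:
    """Load a 3D mask volume as boolean (any nonzero voxel is in-mask)."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {img.ndim}D")
    return np.asanyarray(img.dataobj) > 0


def read_map(path: str | Path) -> np.ndarray:
    """Load a 3D scalar map (e.g. gray-matter volume) as float64."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {img.ndim}D")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: map contains non-finite values")
    return data


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column rigid-body motion parameter file (one row per volume).

    Columns are 3 translations (mm) then 3 rotations (radians).
    """
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: motion file must have 6 columns, got {arr.shape[1]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: motion parameters contain non-finite values")
    return arr


RESULT_COLUMNS = [
    "measure", "contrast", "target_id", "level", "estimate", "t", "p", "q",
    "significant", "n_used", "convergence",
]


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a contrast/correlation result table to TSV at full precision."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"result table lacks column(s) {missing}")
    try:
        results[RESULT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as err:
        raise OSError(f"failed writing results to {path}: {err}") from err


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"result table {path} lacks column(s) {missing}")
    if len(df):
        df["significant"] = df["significant"].astype(bool)
    return df


def write_nifti(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None,
                tr_seconds: float | None = None, dtype=np.float32) -> None:
    """Save an array as NIfTI-1, recording TR in the header for 4D images."""
    aff = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), aff)
    if tr_seconds is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
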