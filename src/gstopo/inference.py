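"""Group contrasts and clinical correlations with multi-level FDR correction.

Every analysis target (whole-brain scalar, six network means, R regional
values) of every measure is tested with the site-aware mixed model

    y ~ 1 + Diagnosis + Age + Sex + Education + Motion + totalGMV
        + (1|Site) + (Diagnosis|Site)

fit by REML (see :mod:`gstopo.lme`), giving a Wald t and p for the Diagnosis
fixed effect.  Clinical correlation models replace the response with the HAMA
or HAMD total score and the focal fixed effect with the target's GSCORR.

FDR families: each (measure, contrast) — or (score, group) for correlations —
forms one Benjamini-Hochberg family.  In the default 'pooled' mode the family
pools the whole-brain, network and regional p-values (1 + 6 + R tests); the
'per-level' mode corrects each level separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from gstopo.io import RESULT_COLUMNS, RoiMeasureTable
from gstopo.lme import SiteLme

logger = logging.getLogger(__name__)

#: Pairwise diagnosis contrasts, as (first, second); the indicator codes the
#: second-named group as 1 (recorded per row in the ``coding`` metadata).
CONTRASTS = (
    ("MDD_anx", "HC"),
    ("MDD_nonanx", "HC"),
    ("MDD_anx", "MDD_nonanx"),
)

COVARIATES = ("age", "sex", "education", "mean_fd", "total_gmv")


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; ties share one q; flags
    are q < alpha.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if not np.all(np.isfinite(p)) or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q < alpha


def _target_level(target_id: str) -> str:
    if target_id == "whole_brain":
        return "whole_brain"
    return "network" if target_id.startswith("net_") else "regional"


def _analysis_frame(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COVARIATES + ("subject_id", "site_id", "diagnosis")
               if c not in manifest.columns]
    if missing:
        raise ValueError(f"analysis manifest lacks column(s): {missing}")
    return manifest.set_index("subject_id")


def _apply_fdr(rows: list[dict], fdr_family: str, alpha: float) -> None:
    """Attach q and significance in place, per the configured family mode."""
    df = pd.DataFrame(rows)
    if fdr_family == "pooled":
        fams = [np.arange(len(rows))]
    elif fdr_family == "per-level":
        fams = [np.flatnonzero(df["level"] == lev) for lev in df["level"].unique()]
    else:
        raise ValueError("fdr_family must be 'pooled' or 'per-level'")
    for idx in fams:
        q, flags = fdr_correct(df.loc[idx, "p"].to_numpy(), alpha=alpha)
        for i, qi, fi in zip(idx, q, flags):
            rows[i]["q"] = float(qi)
            rows[i]["significant"] = bool(fi)


def run_group_contrasts(measures: dict[str, RoiMeasureTable], manifest: pd.DataFrame,
                        fdr_family: str = "pooled", alpha: float = 0.05,
                        contrasts=CONTRASTS) -> pd.DataFrame:
    """All pairwise diagnosis contrasts for every measure and target.

    For each (measure, contrast) family: one mixed-model fit per target with
    the diagnosis indicator as focal fixed effect, then BH correction within
    the family.  Rows with any missing covariate or score are dropped per
    model (counts logged).
    """
    man = _analysis_frame(manifest)
    all_rows: list[dict] = []
    for measure_name, table in measures.items():
        for first, second in contrasts:
            sub = man[man["diagnosis"].isin([first, second])]
            sub = sub.join(table.values, how="inner")
            n_before = len(sub)
            needed = list(COVARIATES)
            sub = sub.dropna(subset=needed)
            if n_before - len(sub):
                logger.info("%s %s-vs-%s: dropped %d row(s) with missing covariates",
                            measure_name, first, second, n_before - len(sub))
            for grp in (first, second):
                if (sub["diagnosis"] == grp).sum() < 2:
                    raise ValueError(
                        f"contrast {first}-vs-{second}: fewer than 2 subjects in {grp}")
            indicator = (sub["diagnosis"] == second).to_numpy(float)
            X = np.column_stack([np.ones(len(sub)), indicator,
                                 *(sub[c].to_numpy(float) for c in COVARIATES)])
            solver = SiteLme(X, sub["site_id"].to_numpy(), slope=indicator)
            rows = []
            for target in table.target_columns:
                fit = solver.fit(sub[target].to_numpy(float), focal_index=1)
                rows.append({
                    "measure": measure_name,
                    "contrast": f"{first}_vs_{second}",
                    "target_id": target,
                    "level": _target_level(target),
                    "estimate": fit.estimate,
                    "t": fit.t,
                    "p": fit.p,
                    "n_used": fit.n,
                    "convergence": fit.convergence,
                    "coding": f"{second}=1",
                })
            _warn_nonconverged(rows, f"{measure_name} {first}_vs_{second}")
            _apply_fdr(rows, fdr_family, alpha)
            all_rows.extend(rows)
    return pd.DataFrame(all_rows)[RESULT_COLUMNS + ["coding"]]


def _warn_nonconverged(rows: list[dict], family: str) -> None:
    bad = [r["target_id"] for r in rows if "not_converged" in r["convergence"]
           or r["convergence"].startswith("ols")]
    if bad:
        logger.warning("family %s: %d fit(s) degraded or not converged: %s",
                       family, len(bad), bad[:5])


def run_clinical_correlations(gscorr: RoiMeasureTable, manifest: pd.DataFrame,
                              fdr_family: str = "pooled", alpha: float = 0.05,
                              groups=("MDD_anx", "MDD_nonanx"),
                              scores=("hama", "hamd")) -> pd.DataFrame:
    """Per-group association of each GSCORR target with HAMA/HAMD.

    The score is the response, the target's GSCORR the focal fixed effect,
    with the usual covariates and the same site random structure (intercept
    plus by-site slope on the predictor).  One BH family per (score, group).
    """
    man = _analysis_frame(manifest)
    all_rows: list[dict] = []
    for group in groups:
        for score in scores:
            sub = man[man["diagnosis"] == group]
            if score not in sub.columns:
                raise ValueError(f"manifest lacks clinical score column {score!r}")
            sub = sub.join(gscorr.values, how="inner")
            sub = sub.dropna(subset=[score, *COVARIATES])
            y = sub[score].to_numpy(float)
            if len(sub) < 3:
                raise ValueError(f"too few {group} subjects with {score} present")
            if y.std() == 0:
                raise ValueError(f"{score} is constant within {group}")
            rows = []
            for target in gscorr.target_columns:
                pred = sub[target].to_numpy(float)
                X = np.column_stack([np.ones(len(sub)), pred,
                                     *(sub[c].to_numpy(float) for c in COVARIATES)])
                fit = SiteLme(X, sub["site_id"].to_numpy(), slope=pred).fit(y, focal_index=1)
                rows.append({
                    "measure": f"GSCORR~{score.upper()}",
                    "contrast": group,
                    "target_id": target,
                    "level": _target_level(target),
                    "estimate": fit.estimate,
                    "t": fit.t,
                    "p": fit.p,
                    "n_used": fit.n,
                    "convergence": fit.convergence,
                    "coding": "slope",
                })
            _warn_nonconverged(rows, f"{score}~GSCORR {group}")
            _apply_fdr(rows, fdr_family, alpha)
            all_rows.extend(rows)
    return pd.DataFrame(all_rows)[RESULT_COLUMNS + ["coding"]]
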