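"""Cohort orchestration: imaging -> biomarker table -> harmonization ->
survival and cutpoint analyses.

Per subject the chain is: tensor fit -> scalar maps -> ROI
categorization against the tumor labels -> ALPS per hemisphere ->
free-water fit -> mean FW over the contralateral NAWM mask.  Cohort
level: eligibility filtering (bilateral tumors, midline shift > 5 mm,
necrosis-overlap ROIs), ComBat harmonization across sites, ANOVA/Tukey
over ROI categories, median-split log-rank, univariate and multivariate
Cox models, a cutpoint scan on the discovery cohort and fixed-threshold
validation plus joint ALPS x FW stratification on the validation
cohort.  Per-subject failures are quarantined and logged, never fatal;
every stage writes into a run manifest for reproducibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from glymph import io
from glymph.alps import AlpsRoiSet, TumorSegmentation, alps_index, categorize_roi
from glymph.cutpoint import apply_threshold, scan_cutpoints, stratify_joint
from glymph.diffusion import DiffusionVolume, fit_tensor, tensor_metrics
from glymph.freewater import fit_bitensor, init_fw, mean_fw
from glymph.harmonize import combat_apply, combat_fit
from glymph.stats import (
    ConvergenceError,
    SurvivalData,
    anova_tukey,
    cox_fit,
    dichotomize_median,
    logrank,
)

logger = logging.getLogger("glymph")

__all__ = [
    "RunConfig",
    "filter_cohort",
    "process_subject",
    "run_subject",
    "run_cohort",
    "CATEGORY_COLUMN",
]

#: ipsilateral ROI category -> cohort column holding that hemisphere's ALPS
CATEGORY_COLUMN = {
    "iNAWM": "alps_inawm",
    "flair_tumor": "alps_flair",
    "enhancing_tumor": "alps_enh",
    "excluded_necrosis": "alps_necrosis",
}

MIDLINE_SHIFT_LIMIT_MM = 5.0  # strict inequality: > 5 mm excludes

BIOMARKERS = ("alps_cnawm", "alps_inawm", "fw_cnawm")
BASE_COVARIATES = ("age", "sex", "enh_vol_ml")
WM_COVARIATES = ("fa_proj", "fa_assoc", "md_proj", "md_assoc")


@dataclass
class RunConfig:
    """Paths and knobs for a cohort run.

    ``subjects`` is a manifest: one dict per subject with keys
    subject_id, site, tumor_side, dwi, bval, bvec, seg, rois (JSON
    sidecar path), cnawm_mask.  Survival and demographics come from
    ``clinical_csv`` (joined on subject_id).
    """

    out_dir: str
    subjects: list[dict] = field(default_factory=list)
    clinical_csv: str | None = None
    discovery_site: str | None = None
    validation_site: str | None = None
    harmonize: bool = True
    alps_step: float = 0.01
    fw_step: float = 0.001
    min_group_frac: float = 0.1
    fw_reg_weight: float = 0.5
    fw_max_iter: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


# ---------------------------------------------------------------------------
# table-level eligibility filtering
# ---------------------------------------------------------------------------


def filter_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility filters and survival-column exclusions.

    Drops subjects with bilateral tumors or midline shift strictly
    greater than 5 mm; moves ipsilateral ALPS values whose ROIs overlap
    tumor out of the survival column (``alps_inawm``) into the
    per-category columns.  Returns (filtered table, exclusion counts).
    """
    df = records.copy()
    counts = {"bilateral": 0, "midline_shift": 0, "necrosis_overlap_roi": 0}

    if "bilateral" in df.columns:
        drop = df["bilateral"].fillna(False).astype(bool)
        counts["bilateral"] = int(drop.sum())
        df = df[~drop]
    else:
        warnings.warn("no 'bilateral' column; keeping all subjects", stacklevel=2)
    if "midline_shift_mm" in df.columns:
        drop = df["midline_shift_mm"] > MIDLINE_SHIFT_LIMIT_MM
        drop = drop.fillna(False)
        counts["midline_shift"] = int(drop.sum())
        df = df[~drop]
    else:
        warnings.warn(
            "no 'midline_shift_mm' column; keeping all subjects", stacklevel=2
        )

    # tumor-overlap hemispheres leave the survival column
    if "roi_category_ipsi" in df.columns and "alps_inawm" in df.columns:
        for cat, col in CATEGORY_COLUMN.items():
            if cat == "iNAWM":
                continue
            m = df["roi_category_ipsi"] == cat
            if m.any():
                if col not in df.columns:
                    df[col] = np.nan
                df.loc[m, col] = df.loc[m, col].where(
                    df.loc[m, col].notna(), df.loc[m, "alps_inawm"]
                )
                df.loc[m, "alps_inawm"] = np.nan
                if cat == "excluded_necrosis":
                    counts["necrosis_overlap_roi"] = int(m.sum())
    if df.empty:
        raise ValueError("cohort empty after eligibility filtering")
    for reason, k in counts.items():
        if k:
            logger.info("excluded %d subjects/values: %s", k, reason)
    return df.reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# subject-level processing
# ---------------------------------------------------------------------------


def process_subject(
    subject_id: str,
    site: str,
    dwi: DiffusionVolume,
    rois: AlpsRoiSet,
    seg: TumorSegmentation,
    tumor_side: str,
    cnawm_mask: np.ndarray,
    fw_reg_weight: float = 0.5,
    fw_max_iter: int = 30,
) -> dict:
    """One subject end to end, on in-memory objects.

    Returns a flat record dict; the ipsilateral ALPS lands in the column
    named for its ROI category (see :data:`CATEGORY_COLUMN`).
    """
    tf = fit_tensor(dwi)
    maps = tensor_metrics(tf)
    rois = categorize_roi(rois, seg, tumor_side)
    contra = "left" if tumor_side == "right" else "right"

    rec: dict = {
        "subject_id": subject_id,
        "site": site,
        "tumor_side": tumor_side,
        "enh_vol_ml": seg.enhancing_volume_ml,
        "alps_inawm": np.nan,
        "alps_flair": np.nan,
        "alps_enh": np.nan,
        "alps_necrosis": np.nan,
    }

    m_contra = alps_index(maps, rois, contra)
    rec["alps_cnawm"] = m_contra.alps if m_contra.valid else np.nan
    rec["roi_category_contra"] = m_contra.category
    rec["fa_proj"] = m_contra.fa_proj
    rec["fa_assoc"] = m_contra.fa_assoc
    rec["md_proj"] = m_contra.md_proj
    rec["md_assoc"] = m_contra.md_assoc

    m_ipsi = alps_index(maps, rois, tumor_side)
    rec["roi_category_ipsi"] = m_ipsi.category
    col = CATEGORY_COLUMN[m_ipsi.category]
    rec[col] = m_ipsi.alps if m_ipsi.valid else np.nan

    try:
        # the FW biomarker is the cNAWM mean, so fit only there
        fw_dwi = DiffusionVolume(
            signal=dwi.signal,
            scheme=dwi.scheme,
            voxel_size=dwi.voxel_size,
            brain_mask=cnawm_mask,
        )
        f0 = init_fw(fw_dwi)
        fit = fit_bitensor(
            fw_dwi, f0, reg_weight=fw_reg_weight, max_iter=fw_max_iter
        )
        rec["fw_cnawm"] = mean_fw(fit, cnawm_mask).mean_fw
    except ValueError as exc:
        warnings.warn(f"{subject_id}: free-water fit failed ({exc})", stacklevel=2)
        rec["fw_cnawm"] = np.nan
    return rec


def run_subject(cfg: RunConfig, subject: dict) -> dict:
    """File-based wrapper around :func:`process_subject`."""
    scheme = io.load_bval_bvec(subject["bval"], subject["bvec"])
    signal, voxel_size = io.load_nifti(subject["dwi"])
    dwi = DiffusionVolume(
        signal=signal, scheme=scheme, voxel_size=tuple(voxel_size)
    )
    seg_data, seg_vox = io.load_nifti(subject["seg"])
    sidecar = io.load_json(subject["rois"])
    legend = {int(k): v for k, v in sidecar["tumor_legend"].items()}
    seg = TumorSegmentation(
        labels=seg_data.astype(int), legend=legend, voxel_size=float(seg_vox[0])
    )
    masks = {}
    for key in ("proj_left", "assoc_left", "proj_right", "assoc_right"):
        data, _ = io.load_nifti(sidecar["masks"][key])
        masks[key] = data > 0.5
    rois = AlpsRoiSet(voxel_size=float(seg_vox[0]), **masks)
    cnawm, _ = io.load_nifti(subject["cnawm_mask"])
    return process_subject(
        subject_id=subject["subject_id"],
        site=subject["site"],
        dwi=dwi,
        rois=rois,
        seg=seg,
        tumor_side=subject["tumor_side"],
        cnawm_mask=cnawm > 0.5,
        fw_reg_weight=cfg.fw_reg_weight,
        fw_max_iter=cfg.fw_max_iter,
    )


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------


def _survival_ready(df: pd.DataFrame) -> None:
    missing = {"os_days", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"missing survival columns: {sorted(missing)}")


def _anova_by_category(df: pd.DataFrame) -> dict | None:
    cols = {
        "cNAWM": "alps_cnawm",
        "iNAWM": "alps_inawm",
        "flair_tumor": "alps_flair",
        "enhancing_tumor": "alps_enh",
    }
    values, groups = [], []
    for cat, col in cols.items():
        if col in df.columns:
            v = df[col].dropna().to_numpy(float)
            if v.size >= 2:
                values.append(v)
                groups.append(np.full(v.size, cat))
    if len(values) < 2:
        return None
    vals = np.concatenate(values)
    grps = np.concatenate(groups)
    out = anova_tukey(vals, grps)
    out["pairwise"] = {f"{a} vs {b}": p for (a, b), p in out["pairwise"].items()}
    out["group_means"] = {
        cat: float(df[col].mean())
        for cat, col in cols.items()
        if col in df.columns and df[col].notna().sum() >= 2
    }
    return out


def _median_split_logrank(df: pd.DataFrame, metric: str) -> dict | None:
    sub = df[[metric, "os_days", "event"]].dropna()
    if len(sub) < 4 or sub["event"].sum() == 0:
        return None
    try:
        groups = dichotomize_median(sub[metric].to_numpy(float))
        res = logrank(
            SurvivalData(
                time=sub["os_days"].to_numpy(float),
                event=sub["event"].to_numpy(int),
                group=groups,
            )
        )
    except (ValueError, ConvergenceError) as exc:
        return {"error": str(exc)}
    return {
        "chi2": res.chi2,
        "p": res.p,
        "hr_high_vs_low": res.hr,
        "ci95": list(res.ci95),
        "n_per_group": {str(k): v for k, v in res.n_per_group.items()},
    }


def _cox_block(df: pd.DataFrame, biomarker: str, covars: tuple[str, ...]) -> dict:
    cols = [biomarker, *[c for c in covars if c in df.columns]]
    sub = df[cols + ["os_days", "event"]].dropna()
    if len(sub) < len(cols) + 2 or sub["event"].sum() < len(cols) + 1:
        return {"error": "insufficient data"}
    try:
        res = cox_fit(
            sub["os_days"].to_numpy(float),
            sub["event"].to_numpy(int),
            sub[cols],
        )
    except (ValueError, ConvergenceError) as exc:
        return {"error": str(exc)}
    row = res[biomarker]
    return {
        "n": res.n,
        "n_events": res.n_events,
        "beta": float(row["beta"]),
        "z": float(row["z"]),
        "p": float(row["p"]),
        "hr": float(row["hr"]),
        "ci95": [float(row["ci_lo"]), float(row["ci_hi"])],
        "covariates": cols[1:],
    }


def survival_report(df: pd.DataFrame) -> dict:
    """Median-split log-rank plus uni/multivariate Cox per biomarker."""
    _survival_ready(df)
    report: dict = {}
    for metric in BIOMARKERS:
        if metric not in df.columns:
            continue
        block = {
            "median_split_logrank": _median_split_logrank(df, metric),
            "cox_univariate": _cox_block(df, metric, ()),
            "cox_multivariate": _cox_block(df, metric, BASE_COVARIATES),
        }
        if metric.startswith("alps"):
            block["cox_multivariate_wm"] = _cox_block(
                df, metric, BASE_COVARIATES + WM_COVARIATES
            )
        report[metric] = block
    return report


def _scan_plots(scan, out_dir: Path, tag: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    adm = scan.admissible
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(adm["threshold"], adm["p"], "k-")
    axes[0].axhline(0.05, color="r", ls=":")
    axes[0].set_xlabel(scan.metric)
    axes[0].set_ylabel("log-rank p")
    axes[0].set_yscale("log")
    axes[1].plot(adm["threshold"], adm["hr"], "k-")
    axes[1].plot(adm["threshold"], adm["ci_lo"], "k--", lw=0.8)
    axes[1].plot(adm["threshold"], adm["ci_hi"], "k--", lw=0.8)
    axes[1].axhline(1.0, color="r", ls=":")
    axes[1].set_xlabel(scan.metric)
    axes[1].set_ylabel("HR (high vs low)")
    fig.tight_layout()
    fig.savefig(out_dir / f"scan_{tag}.png", dpi=110)
    plt.close(fig)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_cohort(cfg: RunConfig) -> dict:
    """Full cohort run; returns the results dict (also written as JSON).

    Deterministic given the config seed: reprocessing the same inputs
    yields byte-identical CSV outputs.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "n_subjects_in": len(cfg.subjects),
        "parameters": {
            "alps_step": cfg.alps_step,
            "fw_step": cfg.fw_step,
            "min_group_frac": cfg.min_group_frac,
            "fw_reg_weight": cfg.fw_reg_weight,
            "harmonize": cfg.harmonize,
        },
        "failures": [],
    }

    records = []
    for subject in cfg.subjects:
        try:
            records.append(run_subject(cfg, subject))
        except (ValueError, OSError, KeyError) as exc:
            logger.warning("subject %s failed: %s", subject.get("subject_id"), exc)
            manifest["failures"].append(
                {"subject_id": subject.get("subject_id"), "error": str(exc)}
            )
    if not records:
        raise ValueError("no subject produced a usable record")
    imaging = pd.DataFrame.from_records(records)

    if cfg.clinical_csv:
        clinical = pd.read_csv(cfg.clinical_csv)
        drop = [c for c in clinical.columns if c in imaging.columns and c != "subject_id"]
        cohort = imaging.merge(
            clinical.drop(columns=drop), on="subject_id", how="left"
        )
    else:
        cohort = imaging
    _survival_ready(cohort)
    _write_csv(cohort, out_dir / "cohort.csv")

    filtered, exclusions = filter_cohort(cohort)
    manifest["exclusions"] = exclusions
    manifest["n_subjects_analyzed"] = len(filtered)
    _write_csv(filtered, out_dir / "cohort_filtered.csv")

    sites = sorted(filtered["site"].astype(str).unique())
    harmonized = filtered
    if cfg.harmonize and len(sites) >= 2:
        features = [
            c
            for c in ("alps_cnawm", "alps_inawm", "fw_cnawm", *WM_COVARIATES)
            if c in filtered.columns
        ]
        complete = filtered.dropna(subset=features)
        try:
            model = combat_fit(complete, features)
            harmonized = combat_apply(model, filtered)
            io.save_json(out_dir / "combat_model.json", model.to_dict())
            manifest["combat"] = {"features": features, "n_fit": len(complete)}
        except ValueError as exc:
            logger.warning("harmonization skipped: %s", exc)
            manifest["combat"] = {"error": str(exc)}
    _write_csv(harmonized, out_dir / "cohort_harmonized.csv")

    results: dict = {"anova_roi_categories": _anova_by_category(harmonized)}

    disc = (
        harmonized[harmonized["site"] == cfg.discovery_site]
        if cfg.discovery_site
        else harmonized
    )
    valid = (
        harmonized[harmonized["site"] == cfg.validation_site]
        if cfg.validation_site
        else None
    )
    results["survival_discovery"] = survival_report(disc)
    if valid is not None and len(valid):
        results["survival_validation"] = survival_report(valid)

    results["cutpoints"] = {}
    thresholds: dict[str, float] = {}
    for metric, step in (("alps_cnawm", cfg.alps_step), ("fw_cnawm", cfg.fw_step)):
        if metric not in disc.columns:
            continue
        try:
            scan = scan_cutpoints(
                disc, metric, step=step, min_group_frac=cfg.min_group_frac
            )
        except ValueError as exc:
            results["cutpoints"][metric] = {"error": str(exc)}
            continue
        _write_csv(
            scan.table, out_dir / f"scan_{metric}.csv"
        )
        _scan_plots(scan, out_dir, metric)
        thresholds[metric] = scan.optimal_threshold
        adm = scan.admissible
        best = adm.loc[adm["threshold"] == scan.optimal_threshold].iloc[0]
        results["cutpoints"][metric] = {
            "optimal_threshold": scan.optimal_threshold,
            "p_at_optimum": float(best["p"]),
            "hr_at_optimum": float(best["hr"]),
            "n_low": int(best["n_low"]),
            "n_high": int(best["n_high"]),
            "n_thresholds": int(len(scan.table)),
            "significant_range": [
                float(adm.loc[adm["significant"], "threshold"].min()),
                float(adm.loc[adm["significant"], "threshold"].max()),
            ]
            if adm["significant"].any()
            else None,
        }

    if valid is not None and len(valid):
        results["validation"] = {}
        for metric in ("alps_cnawm", "fw_cnawm"):
            if metric not in thresholds:
                continue
            try:
                applied = apply_threshold(valid, metric, thresholds[metric])
                results["validation"][metric] = {
                    "threshold": applied.threshold,
                    "p": applied.logrank.p,
                    "hr_high_vs_low": applied.logrank.hr,
                    "median_months_high": applied.km_high.median_months,
                    "median_months_low": applied.km_low.median_months,
                    "n_high": applied.n_high,
                    "n_low": applied.n_low,
                }
            except ValueError as exc:
                results["validation"][metric] = {"error": str(exc)}
        if {"alps_cnawm", "fw_cnawm"} <= set(thresholds):
            try:
                strata = stratify_joint(
                    valid, thresholds["alps_cnawm"], thresholds["fw_cnawm"]
                )
                results["validation"]["joint_strata"] = {
                    "counts": strata.counts,
                    "pairwise": {
                        f"{a} vs {b}": {"chi2": r.chi2, "p": r.p, "hr": r.hr}
                        for (a, b), r in strata.pairwise.items()
                    },
                }
            except ValueError as exc:
                results["validation"]["joint_strata"] = {"error": str(exc)}

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return v if np.isfinite(v) else None
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    results = _clean(results)
    io.save_json(out_dir / "results.json", results)
    io.save_json(out_dir / "manifest.json", _clean(manifest))
    return results
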