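"""Survival threshold discovery, external validation and joint strata.

The discovery procedure scans candidate cutoffs over a biomarker's
observed range on a fixed step grid (0.01 for ALPS, 0.001 for FW),
dichotomizes the cohort at each threshold (value > threshold = "high"),
runs a log-rank test with the accompanying hazard ratio, and selects
the optimum as the threshold with the lowest p-value, ties broken by
the largest |log HR|, then by the lowest threshold.  A selected
threshold is then applied unchanged to an independent cohort
(no re-optimization), and the two biomarker thresholds jointly
stratify subjects into favorable (high ALPS / low FW), adverse
(low ALPS / high FW) and discordant (the two mixed patterns) groups.

No multiplicity correction is applied across the scan — minimum-p
selection inflates the type-I error, which is a documented and tested
property of the procedure, not a defect to fix here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glymph.stats import (
    ConvergenceError,
    KmCurve,
    LogrankResult,
    SurvivalData,
    km_estimate,
    logrank,
    logrank_chi2,
)

__all__ = [
    "CutpointScan",
    "ThresholdResult",
    "JointStrata",
    "scan_cutpoints",
    "select_optimal",
    "apply_threshold",
    "stratify_joint",
]


@dataclass
class CutpointScan:
    """Per-threshold log-rank results over a fixed step grid."""

    metric: str
    step: float
    min_group_frac: float
    table: pd.DataFrame  # threshold, p, hr, ci_lo, ci_hi, n_low, n_high,
    #                      significant, admissible
    optimal_threshold: float
    selection_rule: str = (
        "lowest p; ties by largest |log HR|; ties by lowest threshold"
    )

    @property
    def admissible(self) -> pd.DataFrame:
        return self.table[self.table["admissible"]]


@dataclass
class ThresholdResult:
    """Fixed-threshold dichotomization of one cohort."""

    metric: str
    threshold: float
    groups: np.ndarray  # "high" / "low" per subject
    logrank: LogrankResult
    km_high: KmCurve
    km_low: KmCurve
    n_high: int
    n_low: int


@dataclass
class JointStrata:
    """Three-group ALPS x FW stratification."""

    alps_threshold: float
    fw_threshold: float
    strata: np.ndarray  # "favorable" / "discordant" / "adverse" per subject
    counts: dict[str, int]
    pairwise: dict[tuple[str, str], LogrankResult] = field(default_factory=dict)


def _grid(values: np.ndarray, step: float) -> np.ndarray:
    """Thresholds ceil(min/step)*step .. floor(max/step)*step inclusive."""
    k0 = int(np.ceil(values.min() / step - 1e-9))
    k1 = int(np.floor(values.max() / step + 1e-9))
    decimals = max(0, int(np.ceil(-np.log10(step)))) + 2
    return np.round(np.arange(k0, k1 + 1) * step, decimals)


def scan_cutpoints(
    table: pd.DataFrame,
    metric: str,
    step: float,
    min_group_frac: float = 0.1,
    time_col: str = "os_days",
    event_col: str = "event",
) -> CutpointScan:
    """Log-rank p / HR at every step-grid threshold of ``metric``.

    Thresholds whose smaller group falls below ``min_group_frac`` of the
    cohort are recorded but marked inadmissible.  Raises if fewer than
    two thresholds are admissible.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not 0.0 <= min_group_frac < 0.5:
        raise ValueError("min_group_frac must lie in [0, 0.5)")
    sub = table[[metric, time_col, event_col]].dropna()
    values = sub[metric].to_numpy(float)
    time = sub[time_col].to_numpy(float)
    event = sub[event_col].to_numpy(int)
    n = len(sub)
    if n < 4:
        raise ValueError("too few subjects with metric and survival data")

    rows = []
    for thr in _grid(values, step):
        high = values > thr
        n_high, n_low = int(high.sum()), int((~high).sum())
        admissible = (
            min(n_high, n_low) >= max(1, int(np.ceil(min_group_frac * n)))
            and event.sum() > 0
        )
        p = hr = ci_lo = ci_hi = np.nan
        if admissible:
            _, p = logrank_chi2(time, event, high)
            try:
                res = logrank(
                    SurvivalData(
                        time=time,
                        event=event,
                        group=np.where(high, "high", "low"),
                    )
                )
                hr, (ci_lo, ci_hi) = res.hr, res.ci95
            except (ConvergenceError, ValueError):
                pass
        rows.append(
            {
                "threshold": float(thr),
                "p": p,
                "hr": hr,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
                "n_low": n_low,
                "n_high": n_high,
                "significant": bool(admissible and p < 0.05),
                "admissible": bool(admissible),
            }
        )
    scan_table = pd.DataFrame(rows)
    if int(scan_table["admissible"].sum()) < 2:
        raise ValueError(
            "fewer than 2 admissible thresholds "
            f"(n={n}, min_group_frac={min_group_frac})"
        )
    scan = CutpointScan(
        metric=metric,
        step=float(step),
        min_group_frac=float(min_group_frac),
        table=scan_table,
        optimal_threshold=np.nan,
    )
    scan.optimal_threshold = select_optimal(scan)
    return scan


def select_optimal(scan: CutpointScan) -> float:
    """Lowest p; ties by largest |log HR|; remaining ties by lowest
    threshold.  NaN hazard ratios lose every |log HR| tiebreak."""
    adm = scan.admissible
    if adm.empty:
        raise ValueError("scan has no admissible thresholds")
    p = adm["p"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.abs(np.log(adm["hr"].to_numpy(float)))
    mag = np.where(np.isfinite(mag), mag, -np.inf)
    thr = adm["threshold"].to_numpy(float)
    order = np.lexsort((thr, -mag, p))  # last key most significant
    return float(thr[order[0]])


def apply_threshold(
    table: pd.DataFrame,
    metric: str,
    threshold: float,
    high_is_favorable: bool = True,
    time_col: str = "os_days",
    event_col: str = "event",
) -> ThresholdResult:
    """Dichotomize at a fixed (externally derived) threshold and test.

    Warns if the threshold lies outside the observed metric range; an
    empty resulting group is an error.  No re-optimization happens here.
    """
    sub = table[[metric, time_col, event_col]].dropna()
    values = sub[metric].to_numpy(float)
    time = sub[time_col].to_numpy(float)
    event = sub[event_col].to_numpy(int)
    if not values.min() <= threshold <= values.max():
        warnings.warn(
            f"threshold {threshold} outside observed {metric} range "
            f"[{values.min():.4g}, {values.max():.4g}]",
            stacklevel=2,
        )
    high = values > threshold
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"threshold {threshold} leaves an empty group "
            f"(n_high={n_high}, n_low={n_low})"
        )
    groups = np.where(high, "high", "low")
    lr = logrank(SurvivalData(time=time, event=event, group=groups))
    km_high = km_estimate(SurvivalData(time=time[high], event=event[high]))
    km_low = km_estimate(SurvivalData(time=time[~high], event=event[~high]))
    del high_is_favorable  # recorded by callers; direction fixed: > = high
    return ThresholdResult(
        metric=metric,
        threshold=float(threshold),
        groups=groups,
        logrank=lr,
        km_high=km_high,
        km_low=km_low,
        n_high=n_high,
        n_low=n_low,
    )


def stratify_joint(
    table: pd.DataFrame,
    alps_threshold: float,
    fw_threshold: float,
    alps_col: str = "alps_cnawm",
    fw_col: str = "fw_cnawm",
    time_col: str = "os_days",
    event_col: str = "event",
) -> JointStrata:
    """Three-group stratification by joint ALPS / FW status.

    favorable = ALPS > threshold and FW <= threshold; adverse = ALPS <=
    threshold and FW > threshold; discordant pools the two mixed
    patterns.  Pairwise log-rank tests compare all three strata; an
    empty stratum is an error.
    """
    sub = table[[alps_col, fw_col, time_col, event_col]].dropna()
    alps = sub[alps_col].to_numpy(float)
    fw = sub[fw_col].to_numpy(float)
    time = sub[time_col].to_numpy(float)
    event = sub[event_col].to_numpy(int)

    high_alps = alps > alps_threshold
    low_fw = fw <= fw_threshold
    strata = np.where(
        high_alps & low_fw,
        "favorable",
        np.where(~high_alps & ~low_fw, "adverse", "discordant"),
    )
    counts = {k: int((strata == k).sum()) for k in ("favorable", "discordant", "adverse")}
    empty = [k for k, v in counts.items() if v == 0]
    if empty:
        raise ValueError(f"empty strata {empty}; sizes {counts}")

    pairwise: dict[tuple[str, str], LogrankResult] = {}
    for a, b in (
        ("favorable", "discordant"),
        ("favorable", "adverse"),
        ("discordant", "adverse"),
    ):
        m = (strata == a) | (strata == b)
        try:
            pairwise[(a, b)] = logrank(
                SurvivalData(time=time[m], event=event[m], group=strata[m])
            )
        except ValueError:
            pairwise[(a, b)] = LogrankResult(chi2=np.nan, p=np.nan)
    return JointStrata(
        alps_threshold=float(alps_threshold),
        fw_threshold=float(fw_threshold),
        strata=strata,
        counts=counts,
        pairwise=pairwise,
    )
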