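"""Cutpoint scanning, optimum selection, validation, joint strata."""

import numpy as np
import pandas as pd
import pytest

from glymph.cutpoint import (
    CutpointScan,
    _grid,
    apply_threshold,
    scan_cutpoints,
    select_optimal,
    stratify_joint,
)


def survival_table(n=200, beta=0.5, seed=0, metric="alps_cnawm"):
    rng = np.random.default_rng(seed)
    v = rng.normal(1.4, 0.15, n)
    t = rng.exponential(500 * np.exp(beta * (v - 1.4) / 0.15))
    c = rng.uniform(0, 1500, n)
    return pd.DataFrame(
        {metric: v, "os_days": np.minimum(t, c), "event": (t <= c).astype(int)}
    )


def changepoint_table(n=300, thr=1.40, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.normal(1.40, 0.15, n)
    lam = np.where(v <= thr, 2.0, 1.0) / 600.0
    t = rng.exponential(1.0 / lam)
    c = rng.uniform(0, 1500, n)
    return pd.DataFrame(
        {"alps_cnawm": v, "os_days": np.minimum(t, c), "event": (t <= c).astype(int)}
    )


class TestGrid:
    def test_range_one_to_two_step_001_gives_101(self):
        assert len(_grid(np.array([1.0, 2.0]), 0.01)) == 101

    def test_grid_endpoints_inside_range(self, rng):
        v = rng.normal(1.4, 0.15, 100)
        g = _grid(v, 0.01)
        assert g[0] >= v.min() - 1e-9
        assert g[-1] <= v.max() + 1e-9
        assert np.allclose(np.diff(g), 0.01)


class TestScan:
    def test_group_sizes_partition_cohort(self):
        df = survival_table(150, seed=1)
        scan = scan_cutpoints(df, "alps_cnawm", step=0.01, min_group_frac=0.1)
        assert (scan.table["n_low"] + scan.table["n_high"] == 150).all()

    def test_dichotomization_matches_apply_threshold(self):
        # boundary consistency: same strict > convention everywhere
        df = survival_table(120, seed=2)
        scan = scan_cutpoints(df, "alps_cnawm", step=0.01, min_group_frac=0.1)
        row = scan.admissible.iloc[len(scan.admissible) // 2]
        res = apply_threshold(df, "alps_cnawm", row["threshold"])
        assert res.n_high == row["n_high"]
        assert res.n_low == row["n_low"]

    def test_deterministic(self):
        df = survival_table(100, seed=3)
        a = scan_cutpoints(df, "alps_cnawm", step=0.01)
        b = scan_cutpoints(df, "alps_cnawm", step=0.01)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.optimal_threshold == b.optimal_threshold

    def test_min_group_frac_filters(self):
        df = survival_table(100, seed=4)
        scan = scan_cutpoints(df, "alps_cnawm", step=0.01, min_group_frac=0.25)
        adm = scan.admissible
        assert (adm[["n_low", "n_high"]].min(axis=1) >= 25).all()

    def test_too_few_admissible_rejected(self):
        df = survival_table(10, seed=5)
        with pytest.raises(ValueError, match="admissible"):
            scan_cutpoints(df, "alps_cnawm", step=0.5, min_group_frac=0.45)

    def test_bad_parameters_rejected(self):
        df = survival_table(50, seed=6)
        with pytest.raises(ValueError):
            scan_cutpoints(df, "alps_cnawm", step=0.0)
        with pytest.raises(ValueError):
            scan_cutpoints(df, "alps_cnawm", step=0.01, min_group_frac=0.6)

    def test_min_p_selection_inflates_type_one_error(self):
        # under the null the scan's *selected* threshold is "significant"
        # far more often than 5% — the documented cost of min-p selection
        hits = 0
        reps = 120
        for s in range(reps):
            rng = np.random.default_rng(3000 + s)
            df = pd.DataFrame(
                {
                    "alps_cnawm": rng.normal(1.4, 0.15, 120),
                    "os_days": rng.exponential(500.0, 120),
                    "event": np.ones(120, int),
                }
            )
            scan = scan_cutpoints(df, "alps_cnawm", step=0.02, min_group_frac=0.1)
            adm = scan.admissible
            best_p = adm.loc[
                adm["threshold"] == scan.optimal_threshold, "p"
            ].iloc[0]
            hits += best_p < 0.05
        assert hits / reps > 0.10  # well above the nominal 5%

    def test_changepoint_recovered(self):
        # quick 20-rep version of the recovery study (full one in acceptance)
        hits = sum(
            abs(
                scan_cutpoints(
                    changepoint_table(300, seed=s), "alps_cnawm", 0.01
                ).optimal_threshold
                - 1.40
            )
            <= 0.05
            for s in range(20)
        )
        assert hits >= 14


class TestSelectOptimal:
    def _scan(self, rows):
        table = pd.DataFrame(rows)
        table["significant"] = table["p"] < 0.05
        table["admissible"] = True
        for c in ("ci_lo", "ci_hi", "n_low", "n_high"):
            table[c] = 1
        return CutpointScan(
            metric="m", step=0.01, min_group_frac=0.0, table=table,
            optimal_threshold=np.nan,
        )

    def test_unique_minimum_p(self):
        scan = self._scan(
            [
                {"threshold": 1.0, "p": 0.2, "hr": 0.9},
                {"threshold": 1.1, "p": 0.01, "hr": 0.8},
                {"threshold": 1.2, "p": 0.5, "hr": 0.7},
            ]
        )
        assert select_optimal(scan) == 1.1

    def test_p_tie_broken_by_larger_log_hr_magnitude(self):
        scan = self._scan(
            [
                {"threshold": 1.0, "p": 0.01, "hr": 0.8},
                {"threshold": 1.1, "p": 0.01, "hr": 0.6},
            ]
        )
        assert select_optimal(scan) == 1.1  # |log 0.6| > |log 0.8|

    def test_remaining_tie_broken_by_lowest_threshold(self):
        scan = self._scan(
            [
                {"threshold": 1.3, "p": 0.01, "hr": 2.0},
                {"threshold": 1.1, "p": 0.01, "hr": 0.5},  # same |log HR|
            ]
        )
        assert select_optimal(scan) == 1.1

    def test_matches_brute_force_rule_on_random_scans(self, rng):
        for _ in range(25):
            k = rng.integers(3, 12)
            rows = [
                {
                    "threshold": round(1.0 + 0.01 * i, 4),
                    "p": float(rng.choice([0.01, 0.02, 0.05])),
                    "hr": float(rng.uniform(0.3, 3.0)),
                }
                for i in range(k)
            ]
            scan = self._scan(rows)
            best = min(
                rows,
                key=lambda r: (r["p"], -abs(np.log(r["hr"])), r["threshold"]),
            )
            assert select_optimal(scan) == best["threshold"]


class TestApplyThreshold:
    def test_threshold_below_min_errors_empty_group(self):
        df = survival_table(50, seed=7)
        with pytest.warns(UserWarning, match="outside"):
            with pytest.raises(ValueError, match="empty"):
                apply_threshold(df, "alps_cnawm", 0.0)

    def test_group_sizes_equal_brute_force(self):
        df = survival_table(80, seed=8)
        thr = 1.42
        res = apply_threshold(df, "alps_cnawm", thr)
        assert res.n_high == int((df["alps_cnawm"] > thr).sum())
        assert res.n_low == int((df["alps_cnawm"] <= thr).sum())

    def test_reports_km_medians(self):
        df = survival_table(120, beta=0.8, seed=9)
        res = apply_threshold(df, "alps_cnawm", 1.40)
        assert res.km_high.median_months > 0
        assert res.km_low.median_months > 0


class TestStratifyJoint:
    def _joint_table(self, n=200, seed=10):
        rng = np.random.default_rng(seed)
        alps = rng.normal(1.4, 0.15, n)
        fw = rng.normal(0.21, 0.06, n)
        lam = np.exp(-1.0 * (alps - 1.4) / 0.15 + 1.0 * (fw - 0.21) / 0.06) / 500.0
        t = rng.exponential(1.0 / lam)
        return pd.DataFrame(
            {
                "alps_cnawm": alps,
                "fw_cnawm": fw,
                "os_days": t,
                "event": np.ones(n, int),
            }
        )

    def test_counts_equal_brute_force_and_partition(self):
        df = self._joint_table()
        js = stratify_joint(df, 1.40, 0.21)
        fav = ((df.alps_cnawm > 1.40) & (df.fw_cnawm <= 0.21)).sum()
        adv = ((df.alps_cnawm <= 1.40) & (df.fw_cnawm > 0.21)).sum()
        assert js.counts["favorable"] == fav
        assert js.counts["adverse"] == adv
        assert sum(js.counts.values()) == len(df)

    def test_three_pairwise_tests_reported(self):
        js = stratify_joint(self._joint_table(), 1.40, 0.21)
        assert set(js.pairwise) == {
            ("favorable", "discordant"),
            ("favorable", "adverse"),
            ("discordant", "adverse"),
        }

    def test_planted_hazard_ordering(self):
        # favorable vs adverse separates more sharply than vs discordant
        js = stratify_joint(self._joint_table(400, seed=11), 1.40, 0.21)
        assert (
            js.pairwise[("favorable", "adverse")].p
            < js.pairwise[("favorable", "discordant")].p
        )

    def test_empty_stratum_rejected(self):
        df = self._joint_table(50)
        with pytest.raises(ValueError, match="empty"):
            stratify_joint(df, df.alps_cnawm.max() + 1, 0.21)
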