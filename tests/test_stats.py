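import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mpioquant.stats import (
    PearsonResult,
    TestResult,
    apply_exclusions,
    compare_cells,
    fdr_adjust,
    pearson_correlation,
    required_sample_size,
    treatment_effect,
    two_sample_t_power,
    validate_group_table,
)


def bh_bruteforce(pvals):
    """Independent step-up oracle straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(pvals[i] * m / rank, running_min)
        running_min = val
        adjusted[i] = val
    return adjusted


def make_table(rng, agents=("targeted", "control"), days=(1,), rois=("core",), n=5, shift=None):
    rows = []
    for agent in agents:
        for day in days:
            for roi in rois:
                for s in range(n):
                    mu = 0.0
                    if shift and (agent, day, roi) == shift[0]:
                        mu = shift[1]
                    rows.append(
                        dict(
                            subject=f"{agent}{day}s{s}",
                            agent=agent,
                            day=day,
                            roi=roi,
                            eq1=0.0,
                            eq3=rng.normal(mu, 1.0),
                            lesion_volume_mm3=rng.uniform(5, 20),
                            hemispheric_lesion_fraction=rng.uniform(5, 25),
                        )
                    )
    return pd.DataFrame(rows)


class TestFDR:
    def test_hand_computed_stepup(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037]) == pytest.approx([0.037])

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_adjust([0.5, 1.2])

    def test_empty(self):
        assert fdr_adjust([]) == []

    def test_adjusted_ge_raw(self, rng):
        p = rng.uniform(size=50)
        q = fdr_adjust(p)
        assert np.all(np.asarray(q) >= p - 1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        pvals=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=40
        )
    )
    def test_matches_bruteforce_oracle(self, pvals):
        assert fdr_adjust(pvals) == pytest.approx(bh_bruteforce(pvals))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        ours = fdr_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)


class TestPearson:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2 * v + 1 for v in x]
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_reported_study_values(self):
        # r printed to two decimals as 0.73 at n = 5 corresponds to
        # p ~ 0.17 and 95% CI ~ (-0.44, 0.98)
        candidates = np.arange(0.725, 0.735, 0.0005)
        ok = False
        for r_true in candidates:
            x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
            # construct y with exact sample correlation r_true
            y0 = np.array([0.1, -0.4, 0.2, -0.3, 0.4])
            y0 = y0 - y0.mean()
            xc = x - x.mean()
            y0 = y0 - (y0 @ xc) / (xc @ xc) * xc  # orthogonalise
            y = r_true * xc / np.linalg.norm(xc) + np.sqrt(1 - r_true**2) * y0 / np.linalg.norm(y0)
            res = pearson_correlation(x, y)
            assert res.r == pytest.approx(r_true, abs=1e-9)
            if (
                abs(res.p_value - 0.17) <= 0.01
                and abs(res.ci_low - (-0.44)) <= 0.02
                and abs(res.ci_high - 0.98) <= 0.01
            ):
                ok = True
        assert ok

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_null_p_uniform_at_n5(self, rng):
        pvals = []
        for _ in range(2000):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            pvals.append(pearson_correlation(x, y).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        ours = pearson_correlation(x, y)
        theirs = sps.pearsonr(x, y)
        assert ours.r == pytest.approx(theirs.statistic)
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-6)


class TestSampleSize:
    def test_simulation_oracle_d2(self, rng):
        # independent Monte-Carlo power oracle: smallest n whose simulated
        # power reaches 0.8 (d = 40/20 = 2, alpha 0.05, two-sided)
        def sim_power(n, alpha, reps=4000):
            a = rng.normal(0.0, 1.0, (reps, n))
            b = rng.normal(2.0, 1.0, (reps, n))
            p = sps.ttest_ind(a, b, axis=1).pvalue
            return (p < alpha).mean()

        n_oracle = next(n for n in range(2, 20) if sim_power(n, 0.05) >= 0.8)
        assert required_sample_size(40.0, 20.0) == n_oracle
        n_oracle_bonf = next(n for n in range(2, 20) if sim_power(n, 0.05 / 3) >= 0.8)
        assert required_sample_size(40.0, 20.0, n_pairwise=3) == n_oracle_bonf

    def test_consistent_with_study_range(self):
        # the study used five to seven per group for a 40-45% reduction at
        # 20% SD; unadjusted and Bonferroni-adjusted bounds bracket that
        n_lo = required_sample_size(45.0, 20.0)
        n_hi = required_sample_size(40.0, 20.0, n_pairwise=3)
        assert n_lo >= 5
        assert n_hi <= 7

    def test_power_floor_gives_minimum_n(self):
        assert required_sample_size(40.0, 20.0, power=0.0) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            required_sample_size(0.0, 20.0)

    def test_monotone_in_reduction(self):
        ns = [required_sample_size(red, 20.0) for red in (10.0, 20.0, 40.0, 80.0)]
        assert ns == sorted(ns, reverse=True)

    def test_monotone_in_n_pairwise(self):
        ns = [required_sample_size(40.0, 20.0, n_pairwise=k) for k in (1, 2, 3, 6)]
        assert ns == sorted(ns)

    def test_power_function_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for n, d in [(5, 2.0), (8, 1.0), (12, 0.8)]:
            theirs = TTestIndPower().power(effect_size=d, nobs1=n, alpha=0.05)
            assert two_sample_t_power(n, d, 0.05) == pytest.approx(theirs, abs=1e-6)


class TestCompareCells:
    def test_identical_groups_degenerate(self, rng):
        table = make_table(rng, n=4)
        # force identical data in both groups
        vals = rng.normal(size=4)
        table.loc[table["agent"] == "targeted", "eq3"] = vals
        table.loc[table["agent"] == "control", "eq3"] = vals
        res = compare_cells(table, model="welch")
        assert len(res) == 1
        assert res[0].estimate == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_small_cells_skipped(self, rng):
        table = make_table(rng, n=1)
        assert compare_cells(table, model="welch") == []

    def test_adjusted_ge_raw_and_populated(self, rng):
        table = make_table(rng, days=(1, 2, 3), rois=("core", "borderzone"), n=4)
        res = compare_cells(table, model="welch")
        assert len(res) == 6
        for r in res:
            assert r.p_adjusted is not None
            assert r.p_adjusted >= r.p_value - 1e-12

    def test_mixed_and_welch_agree_in_sign(self, rng):
        table = make_table(
            rng,
            days=(1, 2),
            rois=("core", "borderzone"),
            n=5,
            shift=(("targeted", 2, "core"), 5.0),
        )
        mixed = compare_cells(table, model="mixed")
        welch = compare_cells(table, model="welch")
        for m, w in zip(mixed, welch):
            assert m.contrast == w.contrast
            assert np.sign(m.estimate) == np.sign(w.estimate)
            assert m.estimate == pytest.approx(w.estimate, abs=1e-6)

    def test_seeded_shift_detected_in_right_cell(self, rng):
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            table = make_table(
                r,
                days=(1, 2),
                rois=("core", "borderzone"),
                n=6,
                shift=(("targeted", 2, "core"), 4.0),
            )
            res = compare_cells(table, model="welch")
            by_name = {x.contrast: x for x in res}
            target = [v for k, v in by_name.items() if "core" in k and "day=2" in k][0]
            others = [v for k, v in by_name.items() if v is not target]
            if target.p_adjusted < 0.05 and all(o.p_adjusted > 0.05 for o in others):
                hits += 1
        assert hits >= 18

    def test_type_one_error_calibration(self):
        rejections = 0
        reps = 300
        for rep in range(reps):
            r = np.random.default_rng(10_000 + rep)
            table = make_table(r, n=6)
            res = compare_cells(table, model="welch")
            rejections += res[0].p_value < 0.05
        rate = rejections / reps
        assert 0.02 <= rate <= 0.08  # ~3 MC standard errors around 0.05

    def test_invalid_model_rejected(self, rng):
        with pytest.raises(ValueError, match="model"):
            compare_cells(make_table(rng), model="anova")


class TestTreatmentEffect:
    def _longitudinal_table(self, rng, shift_by_agent):
        rows = []
        for agent, shift in shift_by_agent.items():
            for s in range(6):
                base = rng.uniform(10, 25)
                for day, val in ((1, base), (3, base + rng.normal(shift, 2.0))):
                    rows.append(
                        dict(
                            subject=f"{agent}{s}",
                            agent=agent,
                            day=day,
                            roi="core",
                            hemispheric_lesion_fraction=val,
                        )
                    )
        return pd.DataFrame(rows)

    def test_degenerate_equal_groups(self):
        rows = []
        for agent in ("saline", "control", "targeted"):
            for s in range(3):
                rows.append(dict(subject=f"{agent}{s}", agent=agent, day=1, roi="core",
                                 hemispheric_lesion_fraction=20.0))
                rows.append(dict(subject=f"{agent}{s}", agent=agent, day=3, roi="core",
                                 hemispheric_lesion_fraction=18.0))
        res = treatment_effect(pd.DataFrame(rows))
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_shifted_group_detected(self, rng):
        table = self._longitudinal_table(
            rng, {"saline": 0.0, "control": 0.0, "targeted": -10.0}
        )
        res = treatment_effect(table)
        assert res.p_value < 0.05
        assert res.n_per_group == {"saline": 6, "control": 6, "targeted": 6}

    def test_null_high_p_typical(self, rng):
        pvals = []
        for rep in range(100):
            r = np.random.default_rng(rep)
            table = self._longitudinal_table(r, {"a": 0.0, "b": 0.0, "c": 0.0})
            pvals.append(treatment_effect(table).p_value)
        # p should be roughly uniform; crude calibration check on the rate
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert rate <= 0.12

    def test_missing_days_rejected(self, rng):
        table = self._longitudinal_table(rng, {"a": 0.0, "b": 0.0})
        with pytest.raises(ValueError, match="day"):
            treatment_effect(table, day_from=1, day_to=21)


class TestTableHygiene:
    def test_validate_missing_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_group_table(pd.DataFrame({"subject": ["a"]}))

    def test_validate_duplicates(self, rng):
        table = make_table(rng, n=2)
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            validate_group_table(dup)

    def test_apply_exclusions(self, rng):
        table = make_table(rng, n=3)
        kept, excluded = apply_exclusions(
            table,
            {
                "no lesion on T2 map": lambda row: row["lesion_volume_mm3"] < 8.0,
            },
        )
        assert len(kept) + len(excluded) == len(table)
        if len(excluded):
            assert set(excluded["exclusion_reason"]) == {"no lesion on T2 map"}
            assert excluded["lesion_volume_mm3"].max() < 8.0
        assert kept["lesion_volume_mm3"].min() >= 8.0

    def test_testresult_validation(self):
        with pytest.raises(ValueError, match="p value"):
            TestResult("x", 0.0, 1.5)
        with pytest.raises(ValueError, match="adjusted"):
            TestResult("x", 0.0, 0.5, p_adjusted=0.2)
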