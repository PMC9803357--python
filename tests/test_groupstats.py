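"""Mixed ANOVA, t-tests, effect sizes: hand-computed oracles and calibration."""

import numpy as np
import pandas as pd
import pytest

from stoprace.groupstats import (
    independent_t,
    mixed_anova_2x3,
    paired_t,
    samplewise_tests,
)


def _long_table(values):
    """values: dict (group, subject) -> [a, b, c] across 3 trial types."""
    rows = []
    for (g, s), vals in values.items():
        for cond, v in zip(("successful_stop", "failed_stop", "go"), vals):
            rows.append({"group": g, "subject": f"{g}{s}",
                         "trial_type": cond, "normalized_rate": float(v)})
    return pd.DataFrame(rows)


# 2 groups x 4 subjects x 3 conditions, small integers.
FIXTURE = {
    ("lesion", 0): [4, 3, 2], ("lesion", 1): [5, 4, 2],
    ("lesion", 2): [6, 5, 4], ("lesion", 3): [5, 4, 3],
    ("comp", 0): [2, 2, 2], ("comp", 1): [3, 2, 1],
    ("comp", 2): [4, 3, 3], ("comp", 3): [3, 3, 2],
}


def _hand_anova(values):
    """Textbook mixed-design sums-of-squares decomposition."""
    data = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    groups = sorted({g for g, _ in data})
    n_per = len({s for g, s in data if g == groups[0]})
    k = 3
    all_vals = np.array([v for v in data.values()])  # (subjects, k)
    grand = all_vals.mean()
    # Between-subjects partition.
    subj_means = all_vals.mean(axis=1)
    group_of = np.array([g for g, _ in sorted(data)])
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    group_means = {g: all_vals[[i for i, key in enumerate(sorted(data))
                                if key[0] == g]].mean() for g in groups}
    ss_group = n_per * k * sum((group_means[g] - grand) ** 2 for g in groups)
    ss_subj_within = ss_between_subj - ss_group
    # Within-subjects partition.
    cond_means = all_vals.mean(axis=0)
    ss_cond = len(data) * ((cond_means - grand) ** 2).sum()
    cell = {g: all_vals[[i for i, key in enumerate(sorted(data))
                         if key[0] == g]].mean(axis=0) for g in groups}
    ss_cells = n_per * sum(
        ((cell[g] - grand) ** 2).sum() for g in groups)
    ss_inter = ss_cells - ss_cond - ss_group
    ss_total = ((all_vals - grand) ** 2).sum()
    ss_error_within = ss_total - ss_between_subj - ss_cond - ss_inter
    df_group, df_sw = len(groups) - 1, len(data) - len(groups)
    df_cond = k - 1
    df_int = df_group * df_cond
    df_err = df_sw * df_cond
    out = {}
    out["group"] = (ss_group / df_group) / (ss_subj_within / df_sw), \
        df_group, df_sw, ss_group / (ss_group + ss_subj_within)
    out["trial_type"] = (ss_cond / df_cond) / (ss_error_within / df_err), \
        df_cond, df_err, ss_cond / (ss_cond + ss_error_within)
    out["interaction"] = (ss_inter / df_int) / (ss_error_within / df_err), \
        df_int, df_err, ss_inter / (ss_inter + ss_error_within)
    checks = {"ss_total": ss_total,
              "ss_parts": ss_group + ss_subj_within + ss_cond + ss_inter
              + ss_error_within}
    return out, checks


class TestMixedAnova:
    def test_matches_hand_computed_decomposition(self):
        results = {r.effect: r for r in mixed_anova_2x3(_long_table(FIXTURE))}
        expected, checks = _hand_anova(FIXTURE)
        # Conservation of total sums of squares in the oracle itself.
        assert checks["ss_total"] == pytest.approx(checks["ss_parts"])
        for effect, (f, df1, df2, np2) in expected.items():
            r = results[effect]
            assert r.F == pytest.approx(f, rel=1e-10), effect
            assert (r.df1, r.df2) == (df1, df2), effect
            assert r.partial_eta_sq == pytest.approx(np2, rel=1e-10), effect

    def test_eta_squared_f_identity(self):
        for r in mixed_anova_2x3(_long_table(FIXTURE)):
            recon = (r.partial_eta_sq / (1 - r.partial_eta_sq)) \
                * (r.df2 / r.df1)
            assert recon == pytest.approx(r.F, rel=1e-9)

    def test_constant_data_gives_zero_f(self):
        flat = {k: [3, 3, 3] for k in FIXTURE}
        for r in mixed_anova_2x3(_long_table(flat)):
            assert r.F == pytest.approx(0.0, abs=1e-10) or np.isnan(r.F)

    def test_missing_cell_rejected(self):
        df = _long_table(FIXTURE).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova_2x3(df)

    def test_degrees_of_freedom_match_study_design(self):
        """16 subjects per group, 3 conditions: df = (2, 60) and (1, 30)."""
        rng = np.random.default_rng(0)
        values = {(g, s): rng.normal(size=3)
                  for g in ("a", "b") for s in range(16)}
        results = {r.effect: r for r in mixed_anova_2x3(_long_table(values))}
        assert (results["trial_type"].df1, results["trial_type"].df2) == (2, 60)
        assert (results["interaction"].df1, results["interaction"].df2) == (2, 60)
        assert (results["group"].df1, results["group"].df2) == (1, 30)


class TestTTests:
    def test_paired_hand_computed(self):
        # diffs = [1, 2, 3, 2]: mean 2, sd sqrt(2/3); t = 2/(sd/2).
        a = np.array([5.0, 7.0, 9.0, 8.0])
        b = np.array([4.0, 5.0, 6.0, 6.0])
        r = paired_t(a, b)
        sd = np.sqrt(2.0 / 3.0)
        assert r.t == pytest.approx(2.0 / (sd / 2.0))
        assert r.cohens_d == pytest.approx(2.0 / sd)
        assert r.df == 3

    def test_independent_hand_computed(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 6.0, 8.0])
        r = independent_t(a, b)
        pooled = np.sqrt((2 * 1.0 + 2 * 4.0) / 4.0)
        assert r.cohens_d == pytest.approx((2.0 - 6.0) / pooled)
        assert r.df == 4
        from scipy import stats as sps
        assert r.t == pytest.approx(sps.ttest_ind(a, b).statistic)

    def test_zero_variance_flagged(self):
        r = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.flagged and np.isnan(r.t)

    def test_d_calibration_shifted_normals(self):
        """Shift of 1 SD at n=16: average d near 1 across replicates."""
        rng = np.random.default_rng(1)
        ds = []
        for _ in range(200):
            a = rng.normal(1.0, 1.0, 16)
            b = rng.normal(0.0, 1.0, 16)
            ds.append(independent_t(a, b).cohens_d)
        assert np.mean(ds) == pytest.approx(1.0, abs=0.1)


class TestSamplewise:
    def test_identical_inputs_empty_mask(self):
        x = np.random.default_rng(2).normal(size=(10, 50))
        p, mask = samplewise_tests(x, x.copy(), paired=True)
        assert not mask.any()

    def test_null_type_one_rate(self):
        """Independent null samples: ~5% of time points flagged on average."""
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(40):
            a = rng.normal(size=(16, 60))
            b = rng.normal(size=(16, 60))
            _, mask = samplewise_tests(a, b, paired=True)
            fracs.append(mask.mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_detects_injected_window(self):
        """A 1.5-SD difference over a contiguous window is flagged there."""
        rng = np.random.default_rng(4)
        a = rng.normal(size=(16, 100))
        b = rng.normal(size=(16, 100))
        a[:, 40:60] += 1.5
        _, mask = samplewise_tests(a, b, paired=True)
        assert mask[40:60].mean() > 0.8
        assert mask[:30].mean() < 0.2

    def test_misaligned_axes_rejected(self):
        with pytest.raises(ValueError):
            samplewise_tests(np.zeros((4, 10)), np.zeros((4, 12)))
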