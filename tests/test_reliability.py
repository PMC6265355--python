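import numpy as np
import pandas as pd
import pytest

from pkquant.core import StudyTable
from pkquant.reliability import (absvar_pct, icc_oneway, icc_oneway_many,
                                 md_pct_from, median_summary, sem_from,
                                 summarize_trt, validity_matrix)


class TestICC:
    def test_hand_anova_value(self):
        # one-way ANOVA by hand: MSB = 2.11167, MSW = 0.0100
        icc = icc_oneway([(1.0, 1.1), (2.0, 1.9), (3.0, 3.2)])
        assert icc == pytest.approx(0.990573, abs=1e-6)

    def test_matches_pingouin_icc1(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        pairs = rng.normal(0, 1, (8, 2)) + rng.normal(0, 1, (8, 1))
        df = pd.DataFrame({
            "s": np.repeat(np.arange(8), 2),
            "r": np.tile([1, 2], 8),
            "y": pairs.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]) \
            if (ref["Type"] == "ICC(1,1)").any() else \
            float(ref.loc[ref["Type"] == "ICC1", "ICC"].iloc[0])
        assert icc_oneway(pairs) == pytest.approx(ref_icc, abs=1e-9)

    def test_perfect_retest_gives_one(self):
        assert icc_oneway([(1.0, 1.0), (2.0, 2.0)]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_oneway([(1.0, 1.0), (1.0, 1.0)])

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(0, 1, (6, 50))
        x2 = rng.normal(0, 1, (6, 50))
        many = icc_oneway_many(x1, x2, axis=0)
        for j in range(50):
            assert many[j] == pytest.approx(
                icc_oneway(np.column_stack([x1[:, j], x2[:, j]])), abs=1e-12)


class TestAbsVar:
    def test_identical_pairs_zero(self):
        assert absvar_pct([(2.0, 2.0), (3.0, 3.0)]) == 0.0

    def test_single_pair_arithmetic(self):
        assert absvar_pct([(1.0, 1.2)]) == pytest.approx(100 * 0.2 / 1.1,
                                                         abs=1e-9)

    def test_zero_mean_pair_excluded(self):
        v = absvar_pct([(-1.0, 1.0), (1.0, 1.2)])
        assert v == pytest.approx(100 * 0.2 / 1.1, abs=1e-9)
        with pytest.raises(ValueError):
            absvar_pct([(-1.0, 1.0)])


class TestSemMd:
    def test_table_cell_arithmetic(self):
        # published V_T frontal-cortex row: SD 0.16, ICC 0.73 -> SEM 0.083
        sem = sem_from(0.16, 0.73)
        assert sem == pytest.approx(0.0831, abs=1e-4)
        assert round(sem, 2) == 0.08
        md = md_pct_from(sem, 0.72)
        assert md == pytest.approx(32.0, abs=0.5)

    def test_perfect_reliability(self):
        assert sem_from(0.2, 1.0) == 0.0
        assert md_pct_from(0.0, 1.0) == 0.0

    def test_negative_icc_gives_sem_above_sd(self):
        # cerebellum BP_ND: SD 0.31, ICC -0.31 -> SEM larger than SD
        sem = sem_from(0.31, -0.31)
        assert sem > 0.31
        assert sem == pytest.approx(0.355, abs=0.01)

    def test_icc_above_one_rejected(self):
        with pytest.raises(ValueError):
            sem_from(0.1, 1.2)


def _toy_study():
    rows = []
    rng = np.random.default_rng(0)
    for outcome, scale in [("V_T", 1.0), ("SUV", 10.0)]:
        for region in ("GM", "FC"):
            for s in range(5):
                subj_effect = rng.normal(0, 0.3)
                for session in (1, 2):
                    rows.append({
                        "subject_id": f"S{s}", "session": session,
                        "region": region, "outcome": outcome,
                        "value": scale * (1 + subj_effect +
                                          rng.normal(0, 0.1)),
                        "injected_dose_MBq": 300.0, "body_weight_kg": 75.0})
    return StudyTable(pd.DataFrame(rows))


class TestSummaries:
    def test_summary_identities_and_pooled_moments(self):
        study = _toy_study()
        metrics = summarize_trt(study)
        t = metrics.table
        assert set(t["outcome"]) == {"V_T", "SUV"}
        row = t[(t.outcome == "V_T") & (t.region == "GM")].iloc[0]
        pooled = study.data.query(
            "outcome == 'V_T' and region == 'GM'")["value"]
        assert row["mean"] == pytest.approx(pooled.mean())
        assert row["sd"] == pytest.approx(pooled.std(ddof=1))
        assert row["sem"] == pytest.approx(
            row["sd"] * np.sqrt(1 - row["icc"]))

    def test_incomplete_subject_dropped(self):
        study = _toy_study()
        df = study.data.drop(study.data.index[0])  # S0 session 1 of V_T/GM
        metrics = summarize_trt(StudyTable(df))
        row = metrics.table[(metrics.table.outcome == "V_T") &
                            (metrics.table.region == "GM")].iloc[0]
        assert row["n"] == 4

    def test_median_summary_single_region(self):
        study = _toy_study()
        metrics = summarize_trt(study)
        v = median_summary(metrics, "icc", "V_T", regions=["GM"])
        row = metrics.table[(metrics.table.outcome == "V_T") &
                            (metrics.table.region == "GM")].iloc[0]
        assert v == row["icc"]

    def test_estimator_calibration_against_anova_oracle(self):
        """Replicate-mean ICC agrees with the F-statistic oracle and shows
        the small-sample negative bias."""
        from scipy.stats import f_oneway
        rng = np.random.default_rng(2)
        true_icc = 0.5
        n, reps = 6, 400
        subj = rng.normal(0, np.sqrt(true_icc), (n, reps))
        x1 = subj + rng.normal(0, np.sqrt(1 - true_icc), (n, reps))
        x2 = subj + rng.normal(0, np.sqrt(1 - true_icc), (n, reps))
        mine = icc_oneway_many(x1, x2)
        F = f_oneway(*[np.stack([x1[i], x2[i]]) for i in range(n)],
                     axis=0).statistic
        oracle = (F - 1) / (F + 1)
        np.testing.assert_allclose(mine, oracle, atol=1e-12)
        assert abs(mine.mean() - oracle.mean()) < 0.05
        assert mine.mean() < true_icc  # negative small-sample bias


class TestValidity:
    def test_self_and_affine_correlation(self):
        study = _toy_study()
        df = study.data
        twice = df[df.outcome == "V_T"].copy()
        twice["outcome"] = "V_T_affine"
        twice["value"] = 2 * twice["value"] + 1
        study2 = StudyTable(pd.concat([df, twice], ignore_index=True))
        vm = validity_matrix(study2, ["V_T", "V_T_affine", "SUV"])
        assert vm.r.loc["V_T", "V_T"] == 1.0
        assert vm.r.loc["V_T", "V_T_affine"] == pytest.approx(1.0)
        assert vm.r2.loc["V_T", "V_T_affine"] == pytest.approx(1.0)
        assert (vm.r - vm.r.T).abs().max().max() < 1e-12

    def test_independent_outcomes_near_zero(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(30):
            for session in (1, 2):
                rows.append({"subject_id": f"S{s}", "session": session,
                             "region": "GM", "outcome": "A",
                             "value": rng.normal(), "injected_dose_MBq": 300,
                             "body_weight_kg": 75})
                rows.append({"subject_id": f"S{s}", "session": session,
                             "region": "GM", "outcome": "B",
                             "value": rng.normal(), "injected_dose_MBq": 300,
                             "body_weight_kg": 75})
        vm = validity_matrix(StudyTable(pd.DataFrame(rows)), ["A", "B"])
        assert vm.r2.loc["A", "B"] < 0.15
        assert vm.n.loc["A", "B"] == 60

    def test_too_few_points_rejected(self):
        df = _toy_study().data
        sub = StudyTable(df[(df.subject_id == "S0") & (df.region == "GM")])
        with pytest.raises(ValueError, match="fewer than 3"):
            validity_matrix(sub, ["V_T", "SUV"])
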