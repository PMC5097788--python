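"""Subgroup frames, summary computation, simulation, and CSV round trips."""

import itertools
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from htebayes import (CovariateSpec, EstimabilityError, FormatError,
                      InvalidSpecError, SubjectTable, SubgroupSummary,
                      ValidationError, build_subgroup_frame,
                      compute_subgroup_summaries, cox_fit, read_summary_table,
                      simulate_subject_data, simulate_summary_data,
                      write_summary_table)


class TestBuildSubgroupFrame:
    def test_three_covariates_yield_twelve_subgroups(self, trial_frame):
        assert trial_frame.n_subgroups == 12
        assert len(set(trial_frame.subgroups)) == 12

    def test_single_covariate(self):
        frame = build_subgroup_frame([CovariateSpec("c", ["A", "B"])])
        assert frame.subgroups == (("A",), ("B",))

    @given(st.lists(st.integers(min_value=2, max_value=4), min_size=1, max_size=4))
    @settings(max_examples=30, deadline=None)
    def test_size_matches_brute_force_cross_product(self, ks):
        covs = [CovariateSpec(f"c{i}", [f"l{i}_{j}" for j in range(k)])
                for i, k in enumerate(ks)]
        frame = build_subgroup_frame(covs)
        brute = list(itertools.product(*(c.levels for c in covs)))
        assert frame.n_subgroups == len(brute)
        assert list(frame.subgroups) == brute  # lexicographic, declaration order

    def test_rejects_degenerate_specs(self):
        with pytest.raises(InvalidSpecError):
            build_subgroup_frame([CovariateSpec("solo", ["only"])])
        with pytest.raises(InvalidSpecError):
            build_subgroup_frame([CovariateSpec("a", ["x", "y"]),
                                  CovariateSpec("a", ["u", "v"])])
        with pytest.raises(InvalidSpecError):
            build_subgroup_frame([])
        with pytest.raises(InvalidSpecError):
            CovariateSpec("dup", ["x", "x"])


def _subject_table(rows, kind, covs):
    return SubjectTable(pd.DataFrame(rows), outcome_kind=kind, covariates=covs)


class TestComputeSummaries:
    covs = (CovariateSpec("grp", ["A", "B"]),)

    def _frame(self):
        return build_subgroup_frame(self.covs)

    def test_continuous_two_sample_formulas(self):
        rows = [{"grp": "A", "treatment": 1, "outcome": v} for v in (1.0, 3.0)]
        rows += [{"grp": "A", "treatment": 0, "outcome": v} for v in (0.0, 2.0)]
        rows += [{"grp": "B", "treatment": 1, "outcome": v} for v in (5.0, 6.0)]
        rows += [{"grp": "B", "treatment": 0, "outcome": v} for v in (5.0, 6.0)]
        data = _subject_table(rows, "continuous", self.covs)
        s = compute_subgroup_summaries(data, self._frame())
        # textbook pooled two-sample arithmetic: sp^2 = 2, se = sqrt(2*(1/2+1/2))
        assert s.theta_hat[0] == pytest.approx(1.0)
        assert s.se[0] == pytest.approx(np.sqrt(2.0))
        assert s.theta_hat[1] == pytest.approx(0.0)
        assert s.effect_scale == "mean_diff"
        assert list(s.n_trt) == [2, 2] and list(s.n_ctl) == [2, 2]

    def test_binary_symmetric_table(self):
        rows = []
        for grp in ("A", "B"):
            for arm in (0, 1):
                rows += [{"grp": grp, "treatment": arm, "outcome": 1}] * 10
                rows += [{"grp": grp, "treatment": arm, "outcome": 0}] * 10
        data = _subject_table(rows, "binary", self.covs)
        s = compute_subgroup_summaries(data, self._frame())
        assert s.theta_hat == pytest.approx([0.0, 0.0])
        assert s.se == pytest.approx(np.sqrt(4 / 10))

    def test_binary_zero_cell_raises_without_correction(self):
        rows = [{"grp": "A", "treatment": 1, "outcome": 1}] * 5
        rows += [{"grp": "A", "treatment": 0, "outcome": o} for o in (0, 1, 0, 1)]
        rows += [{"grp": "B", "treatment": a, "outcome": o}
                 for a in (0, 1) for o in (0, 1)]
        data = _subject_table(rows, "binary", self.covs)
        with pytest.raises(EstimabilityError, match="A.*zero cell"):
            compute_subgroup_summaries(data, self._frame())

    def test_survival_matches_cox_core(self):
        rng = np.random.default_rng(11)
        rows = []
        for grp in ("A", "B"):
            for arm in (0, 1):
                for t in rng.exponential(1.0, size=8):
                    rows.append({"grp": grp, "treatment": arm,
                                 "time": float(t), "event": 1})
        data = _subject_table(rows, "survival", self.covs)
        s = compute_subgroup_summaries(data, self._frame())
        sub = data.table[data.table["grp"] == "A"]
        fit = cox_fit(sub["time"], sub["event"], sub["treatment"].astype(float))
        assert s.theta_hat[0] == pytest.approx(fit.coefficients[0])
        assert s.se[0] == pytest.approx(fit.se[0])
        assert s.effect_scale == "log_hr"

    def test_empty_arm_names_subgroup(self):
        rows = [{"grp": "A", "treatment": 1, "outcome": v} for v in (1.0, 2.0)]
        rows += [{"grp": "B", "treatment": a, "outcome": float(a + o)}
                 for a in (0, 1) for o in (0, 2)]
        data = _subject_table(rows, "continuous", self.covs)
        with pytest.raises(EstimabilityError, match="A"):
            compute_subgroup_summaries(data, self._frame())

    def test_missing_covariate_rows_dropped_with_log(self, caplog):
        rows = [{"grp": g, "treatment": a, "outcome": float(o)}
                for g in ("A", "B") for a in (0, 1) for o in (0, 1, 3)]
        rows.append({"grp": None, "treatment": 1, "outcome": 9.0})
        data = _subject_table(rows, "continuous", self.covs)
        with caplog.at_level(logging.WARNING, logger="htebayes.subgroup_data"):
            s = compute_subgroup_summaries(data, self._frame())
        assert "1 subject" in caplog.text
        assert s.n_trt.sum() + s.n_ctl.sum() == 12  # dropped row excluded


class TestSimulateSummaryData:
    def test_zero_omega_gives_degenerate_truth(self, trial_frame):
        se = np.full(12, 0.2)
        truth, _ = simulate_summary_data(-0.3, 0.0, se, trial_frame, seed=5)
        assert truth == pytest.approx(np.full(12, -0.3))

    def test_deterministic_under_seed(self, trial_frame):
        se = np.linspace(0.1, 0.4, 12)
        a = simulate_summary_data(-0.3, 0.2, se, trial_frame, seed=42)
        b = simulate_summary_data(-0.3, 0.2, se, trial_frame, seed=42)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].theta_hat, b[1].theta_hat)

    def test_large_sample_moments(self):
        G = 5000
        frame = build_subgroup_frame(
            [CovariateSpec("c", [f"l{i}" for i in range(G)])])
        se = np.full(G, 0.01)
        _, data = simulate_summary_data(0.0, 1.0, se, frame, seed=9)
        sd_marginal = np.sqrt(1.0 + 0.0001)
        assert abs(data.theta_hat.mean()) < 3 * sd_marginal / np.sqrt(G)
        assert data.theta_hat.std(ddof=1) == pytest.approx(sd_marginal, rel=0.05)

    def test_length_mismatch_rejected(self, trial_frame):
        with pytest.raises(InvalidSpecError):
            simulate_summary_data(0.0, 0.1, np.ones(5), trial_frame, seed=1)


class TestSimulateSubjectData:
    def test_no_censoring_means_all_events(self, two_by_two_frame):
        data = simulate_subject_data(two_by_two_frame, np.zeros(4), "survival",
                                     n_per_arm=20, seed=3, censoring_rate=0.0)
        assert (data.table["event"] == 1).all()
        assert (data.table["time"] > 0).all()

    def test_minimal_continuous_table(self, two_by_two_frame):
        data = simulate_subject_data(two_by_two_frame, np.zeros(4),
                                     "continuous", n_per_arm=1, seed=3)
        assert data.n_subjects == 2 * two_by_two_frame.n_subgroups

    def test_censoring_rate_realized(self, two_by_two_frame):
        data = simulate_subject_data(two_by_two_frame, np.zeros(4), "survival",
                                     n_per_arm=500, seed=3, censoring_rate=0.3)
        assert (data.table["event"] == 0).mean() == pytest.approx(0.3, abs=0.03)

    @pytest.mark.parametrize("kind", ["continuous", "binary", "survival"])
    def test_null_pipeline_recovers_zero_effects(self, two_by_two_frame, kind):
        data = simulate_subject_data(two_by_two_frame, np.zeros(4), kind,
                                     n_per_arm=800, seed=17)
        s = compute_subgroup_summaries(data, two_by_two_frame)
        within = np.abs(s.theta_hat) <= 4 * s.se
        assert within.mean() >= 0.95

    def test_effect_recovery_at_large_n(self, two_by_two_frame):
        effects = np.array([-0.5, -0.2, 0.0, 0.4])
        data = simulate_subject_data(two_by_two_frame, effects, "continuous",
                                     n_per_arm=10_000, seed=23)
        s = compute_subgroup_summaries(data, two_by_two_frame)
        assert np.all(np.abs(s.theta_hat - effects) <= 3 * s.se)

    def test_invalid_censoring_rate(self, two_by_two_frame):
        with pytest.raises(InvalidSpecError):
            simulate_subject_data(two_by_two_frame, np.zeros(4), "survival",
                                  n_per_arm=5, seed=1, censoring_rate=1.0)


class TestSummaryTableIO:
    def test_round_trip_bit_identical(self, trial_frame, tmp_path):
        se = np.linspace(0.1, 0.4, 12)
        _, data = simulate_summary_data(-0.3, 0.2, se, trial_frame, seed=8)
        path = tmp_path / "subgroups.csv"
        write_summary_table(data, path)
        back = read_summary_table(path, covariates=list(trial_frame.covariates))
        assert np.array_equal(back.theta_hat, data.theta_hat)
        assert np.array_equal(back.se, data.se)
        assert back.frame.subgroups == trial_frame.subgroups

    def test_covariates_inferred_from_columns(self, trial_frame, tmp_path):
        se = np.full(12, 0.2)
        _, data = simulate_summary_data(0.1, 0.1, se, trial_frame, seed=2)
        path = tmp_path / "subgroups.csv"
        write_summary_table(data, path)
        back = read_summary_table(path)
        assert back.frame.covariate_names == trial_frame.covariate_names
        assert back.frame.n_subgroups == 12

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("grp,theta_hat\nA,0.1\nB,0.2\n")
        with pytest.raises(FormatError, match="se"):
            read_summary_table(path)

    def test_nonpositive_se_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("grp,theta_hat,se\nA,0.1,0.2\nB,0.2,0.0\n")
        with pytest.raises(ValidationError, match="1"):
            read_summary_table(path)


def test_summary_validation_rejects_bad_se(trial_frame):
    with pytest.raises(ValidationError):
        SubgroupSummary(trial_frame, np.zeros(12), np.zeros(12))
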