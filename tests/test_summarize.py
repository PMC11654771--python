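import math

import numpy as np
import pandas as pd
import pytest

from webergrasp import (
    EmptyCellError,
    ESTIMATE_PARAMS,
    InvalidParameterError,
    STANDARD_SIZES,
    TwoStageParams,
    drop_initial_repetitions,
    estimate_implementation_noise,
    exclude_outlier_subjects,
    exclude_outlier_trials,
    fit_slopes,
    generate_experiment,
    predicted_sd,
    summarize_subjects,
)
from webergrasp.simulate import ExperimentDesign, TRIAL_COLUMNS


def make_table(responses, subject=1, condition="c", block=1, size=35.0):
    n = len(responses)
    return pd.DataFrame(
        {
            "subject": subject,
            "group": "g",
            "condition": condition,
            "block": block,
            "size_mm": size,
            "repetition": np.arange(1, n + 1),
            "response_mm": responses,
        }
    )[TRIAL_COLUMNS]


def stack(*tables):
    return pd.concat(tables, ignore_index=True)


class TestTrialExclusion:
    def test_gross_outlier_removed(self):
        # 19 x 10.0 and one 30.0: deviation 19 > 2.5 * 4.472
        table = make_table([10.0] * 19 + [30.0])
        filtered, report = exclude_outlier_trials(table, z=2.5)
        assert len(filtered) == 19
        assert (filtered.response_mm == 10.0).all()
        assert report["n_removed"] == 1
        assert report["removed_cells"][0]["n_removed"] == 1

    def test_identical_cell_untouched(self):
        table = make_table([10.0] * 20)
        filtered, report = exclude_outlier_trials(table, z=2.5)
        assert len(filtered) == 20 and report["n_removed"] == 0

    def test_infinite_threshold_is_identity(self):
        table = make_table(list(np.linspace(5, 50, 20)))
        filtered, _ = exclude_outlier_trials(table, z=math.inf)
        assert filtered.equals(table)

    def test_small_cell_passed_through_and_flagged(self):
        table = make_table([1.0, 100.0])
        filtered, report = exclude_outlier_trials(table, z=2.5)
        assert len(filtered) == 2
        assert report["flagged_cells"][0]["reason"] == "n<3"

    def test_cells_are_independent(self):
        clean = make_table([10.0] * 20, size=21.0)
        dirty = make_table([10.0] * 19 + [30.0], size=42.0)
        filtered, _ = exclude_outlier_trials(stack(clean, dirty))
        assert len(filtered) == 39


class TestDropInitialRepetitions:
    def test_twenty_to_eighteen(self):
        table = make_table(np.arange(20.0))
        out = drop_initial_repetitions(table, 2)
        assert len(out) == 18 and out.repetition.min() == 3

    def test_zero_is_identity(self):
        table = make_table(np.arange(20.0))
        assert drop_initial_repetitions(table, 0).equals(table)

    def test_three_block_count(self):
        # 3 blocks x 4 sizes x 20 reps = 240 trials; dropping 2 per
        # block x size removes 3*4*2 = 24
        blocks = []
        for b in range(1, 4):
            for s in (21.0, 28.0, 35.0, 42.0):
                blocks.append(make_table(np.arange(20.0), block=b, size=s))
        table = stack(*blocks)
        assert len(table) == 240
        assert len(drop_initial_repetitions(table, 2)) == 216

    def test_dropping_all_reps_rejected(self):
        with pytest.raises(EmptyCellError):
            drop_initial_repetitions(make_table([1.0, 2.0]), 2)


class TestSummaries:
    def test_mean_and_sd(self):
        summary = summarize_subjects(make_table([10.0, 12.0]))
        row = summary.iloc[0]
        assert row.mean_response == 11.0
        assert row.sd_response == pytest.approx(math.sqrt(2), rel=1e-12)
        assert row.n_trials == 2

    def test_three_value_cell(self):
        row = summarize_subjects(make_table([39.5, 42.5, 45.5])).iloc[0]
        assert row.mean_response == 42.5 and row.sd_response == pytest.approx(3.0)

    def test_identical_values_have_zero_sd(self):
        assert summarize_subjects(make_table([7.0] * 5)).iloc[0].sd_response == 0.0

    def test_singleton_cell_flagged(self):
        row = summarize_subjects(make_table([7.0])).iloc[0]
        assert not row.sd_defined and np.isnan(row.sd_response)


def summary_frame(sizes, means, sds, subject=1, condition="c"):
    return pd.DataFrame(
        {
            "subject": subject,
            "condition": condition,
            "size_mm": sizes,
            "mean_response": means,
            "sd_response": sds,
            "n_trials": 20,
        }
    )


class TestFitSlopes:
    SIZES = [21.0, 28.0, 35.0, 42.0]

    def test_exact_linear_sd(self):
        out = fit_slopes(summary_frame(self.SIZES, [30, 37, 44, 51], [2.1, 2.8, 3.5, 4.2]))
        assert out.iloc[0].weber_fraction == pytest.approx(0.1, rel=1e-10)
        assert out.iloc[0].intercept_sd == pytest.approx(0.0, abs=1e-10)
        assert out.iloc[0].k_resp == pytest.approx(1.0, rel=1e-10)

    def test_constant_sd_gives_zero_weber(self):
        out = fit_slopes(summary_frame(self.SIZES, [30, 37, 44, 51], [2.0] * 4))
        assert out.iloc[0].weber_fraction == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_estimation_condition(self):
        """OLS slope of sqrt((0.06 s)^2 + 4) over the four sizes ~ 0.0406."""
        sizes = np.array(self.SIZES)
        sds = predicted_sd(sizes, ESTIMATE_PARAMS)
        # independent oracle: textbook OLS slope formula
        expected = float(
            np.sum((sizes - sizes.mean()) * (sds - sds.mean()))
            / np.sum((sizes - sizes.mean()) ** 2)
        )
        assert expected == pytest.approx(0.0406, abs=5e-4)
        out = fit_slopes(summary_frame(self.SIZES, sds + 10, sds))
        assert out.iloc[0].weber_fraction == pytest.approx(expected, rel=1e-10)

    def test_single_size_rejected(self):
        from webergrasp import UndefinedSlopeError

        with pytest.raises(UndefinedSlopeError):
            fit_slopes(summary_frame([35.0, 35.0], [30, 31], [2, 2]))

    def test_noise_free_pipeline_recovers_parameters(self):
        params = TwoStageParams(k=0.7, overshoot=18.0, sigma_impl=0.0, weber_v=0.0)
        design = ExperimentDesign(
            sizes=STANDARD_SIZES, conditions={"c": params}, reps_per_size=5, n_subjects=3
        )
        table = generate_experiment(design, seed=0)
        out = fit_slopes(summarize_subjects(table))
        assert np.allclose(out.k_resp, 0.7)
        assert np.allclose(out.intercept_resp, 18.0)
        assert np.allclose(out.weber_fraction, 0.0)


class TestSubjectExclusion:
    def cohort_summary(self, n=20):
        frames = []
        for subj in range(1, n + 1):
            frames.append(
                summary_frame(
                    [21.0, 42.0], [32.0 + subj * 0.01, 47.0], [2.0 + subj * 0.01, 3.0],
                    subject=subj,
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_displaced_subject_removed(self):
        summary = self.cohort_summary()
        sd_across = summary[summary.size_mm == 42.0].mean_response.std(ddof=1)
        assert sd_across == 0.0  # constructed: all identical in that cell
        summary.loc[
            (summary.subject == 7) & (summary.size_mm == 42.0), "mean_response"
        ] += 10 * summary[summary.size_mm == 21.0].mean_response.std(ddof=1)
        filtered, report = exclude_outlier_subjects(summary, z=2.5)
        excluded = [e["subject"] for e in report["excluded_subjects"]]
        assert excluded == [7]
        assert 7 not in filtered.subject.values

    def test_identical_subjects_all_kept(self):
        frames = [summary_frame([21.0, 42.0], [30, 47], [2, 3], subject=s) for s in range(1, 6)]
        filtered, report = exclude_outlier_subjects(pd.concat(frames, ignore_index=True))
        assert report["excluded_subjects"] == [] and filtered.subject.nunique() == 5

    def test_infinite_threshold_keeps_all(self):
        filtered, report = exclude_outlier_subjects(self.cohort_summary(), z=math.inf)
        assert report["excluded_subjects"] == []

    def test_requires_three_subjects(self):
        frames = [summary_frame([21.0, 42.0], [30, 47], [2, 3], subject=s) for s in (1, 2)]
        with pytest.raises(InvalidParameterError):
            exclude_outlier_subjects(pd.concat(frames, ignore_index=True))


class TestImplementationNoiseRecovery:
    def test_exact_on_closed_form(self):
        sizes = np.array([21.0, 28.0, 35.0, 42.0])
        sds = predicted_sd(sizes, ESTIMATE_PARAMS)
        est = estimate_implementation_noise(sizes, sds, k=1.0, weber_v=0.06)
        assert est == pytest.approx(2.0, rel=1e-12)
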