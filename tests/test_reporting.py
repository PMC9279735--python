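"""Cohort statistics, course processing and the CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from adaptrt.cli import main as cli_main
from adaptrt.reporting import (
    load_cohort_table,
    process_course,
    records_from_json,
    report_to_json,
    summarize,
    two_sample_t,
)


class TestSummarize:
    def test_matches_brute_force_on_cohort_fixtures(self):
        for table, col in (
            ("ptv_coverage", "delta_v95"),
            ("parotid_dmean", "delta_dmean"),
        ):
            vals = load_cohort_table(table)[col].to_numpy(float)
            s = summarize(vals)
            assert s["n"] == len(vals)
            assert s["mean"] == pytest.approx(vals.mean(), abs=1e-12)
            assert s["median"] == pytest.approx(np.median(vals), abs=1e-12)
            assert s["min"] == vals.min() and s["max"] == vals.max()
            from scipy import stats

            half = stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(
                len(vals)
            )
            assert s["ci95_half_width"] == pytest.approx(half, abs=1e-12)

    def test_single_record_has_undefined_ci(self):
        s = summarize([2.5])
        assert s["mean"] == s["median"] == 2.5
        assert np.isnan(s["ci95_half_width"])

    def test_empty_selection_is_empty_summary(self):
        assert summarize([]) == {"n": 0}


class TestTwoSampleT:
    def test_identical_groups_give_t0_p1(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_shifted_groups_are_significant(self):
        res = two_sample_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res["p"] < 0.001

    def test_matches_pooled_variance_hand_formula(self):
        a, b = np.array([2.0, 2.2]), np.array([2.1, 2.1])
        res = two_sample_t(a, b)
        sp2 = ((a.var(ddof=1)) * 1 + (b.var(ddof=1)) * 1) / 2
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert res["t"] == pytest.approx(t_hand, abs=1e-9)

    def test_too_small_groups_are_hard_error(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestProcessCourse:
    def test_zero_drift_truth_fields_are_an_exact_fixed_point(
        self, plan_bundle, zero_course
    ):
        img, plan, dose = plan_bundle
        report = process_course(
            img, plan, dose, zero_course["dailies"],
            dvfs=zero_course["truth_dvfs"],
        )
        assert report.violations == []
        assert not report.qa_flagged
        for rec in report.records:
            assert rec.final == pytest.approx(rec.initial, abs=1e-9)
        for fr in report.fractions:
            for key, v in fr.dp_sum.items():
                assert v == pytest.approx(fr.dp_day[key], abs=1e-9)

    def test_engineered_crossing_detected_from_truth_fields(
        self, drift_plan_bundle, drift_course
    ):
        img, plan, dose = drift_plan_bundle
        report = process_course(
            img, plan, dose, drift_course["dailies"],
            dvfs=drift_course["truth_dvfs"],
        )
        truth_traj = drift_course["truth_dmean_sum"]
        truth_fx = int(np.argmax(truth_traj > 20.0)) + 1
        ev = next(
            v for v in report.violations
            if v.structure == "parotid_L" and v.level == "warning"
        )
        assert ev.crossing_fraction == truth_fx

    def test_failed_fraction_is_recorded_and_processing_continues(
        self, plan_bundle, zero_course
    ):
        img, plan, dose = plan_bundle
        dvfs = list(zero_course["truth_dvfs"])
        dvfs[1] = "not a dvf"  # breaks fraction 2 only
        report = process_course(
            img, plan, dose, zero_course["dailies"], dvfs=dvfs
        )
        assert report.fractions[1].failed
        assert not report.fractions[0].failed
        assert all(not fr.failed for fr in report.fractions[2:])
        assert report.records  # end-of-course records still produced

    def test_report_json_round_trip(self, tmp_path, plan_bundle, zero_course):
        img, plan, dose = plan_bundle
        report = process_course(
            img, plan, dose, zero_course["dailies"][:2],
            dvfs=zero_course["truth_dvfs"][:2],
        )
        p = tmp_path / "report.json"
        report_to_json(report, p)
        records = records_from_json(p)
        assert len(records) == len(report.records)
        for a, b in zip(records, report.records):
            assert a == b


class TestRegistrationPipeline:
    """Course runs driven by actual registration (session-scoped fixtures)."""

    def test_zero_drift_course_is_a_fixed_point(self, zero_course_report):
        report = zero_course_report
        assert not report.qa_flagged
        assert report.violations == []
        for rec in report.records:
            if rec.metric in ("V95", "hotspot"):
                assert rec.final == pytest.approx(rec.initial, abs=0.5)
            else:
                assert rec.final == pytest.approx(rec.initial, abs=0.2)

    def test_drift_course_dmean_trend_tracks_truth_within_2pct(
        self, drift_course, drift_course_report
    ):
        traj = [
            fr.dp_sum["parotid_L:Dmean"] for fr in drift_course_report.fractions
        ]
        truth = drift_course["truth_dmean_sum"]
        rel = np.abs(np.array(traj) - truth) / truth
        assert rel.max() < 0.02

    def test_drift_course_crossing_detected_within_one_fraction(
        self, drift_course, drift_course_report
    ):
        truth_traj = drift_course["truth_dmean_sum"]
        truth_fx = int(np.argmax(truth_traj > 20.0)) + 1
        ev = next(
            v for v in drift_course_report.violations
            if v.structure == "parotid_L" and v.level == "warning"
        )
        assert abs(ev.crossing_fraction - truth_fx) <= 1

    def test_predictions_appear_from_fraction_five(self, drift_course_report):
        for fr in drift_course_report.fractions:
            if fr.fraction < 5:
                assert fr.predictions == {}
            else:
                assert any(len(v) == 4 for v in fr.predictions.values())


class TestCLI:
    def test_phantom_report_predict_verbs(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "course"
        res = runner.invoke(
            cli_main,
            ["phantom", "--out", str(out), "--seed", "3", "--fractions", "2",
             "--config", str(_tiny_cfg(tmp_path))],
        )
        assert res.exit_code == 0, res.output
        assert (out / "plan" / "plan.json").exists()
        assert (out / "fraction_002.nrrd").exists()

        res = runner.invoke(cli_main, ["report", "--table", "parotid_dmean"])
        assert res.exit_code == 0
        stats = json.loads(res.output)
        assert stats["n"] == 17

        trend = tmp_path / "trend.csv"
        trend.write_text(
            "dp_sum\n" + "\n".join(str(19 + 0.3 * f) for f in range(1, 9))
        )
        res = runner.invoke(cli_main, ["predict", "--trend", str(trend)])
        assert res.exit_code == 0
        assert "21.7000" in res.output

    def test_predict_refuses_short_series(self, tmp_path):
        trend = tmp_path / "trend.csv"
        trend.write_text("dp_sum\n1\n2\n3\n")
        res = runner_result = CliRunner().invoke(
            cli_main, ["predict", "--trend", str(trend)]
        )
        assert res.exit_code != 0
        assert "refused" in res.output


def _tiny_cfg(tmp_path):
    import yaml

    p = tmp_path / "cfg.yaml"
    p.write_text(
        yaml.safe_dump(
            {
                "phantom": {
                    "shape": [32, 48, 48],
                    "spacing": [3.0, 3.5, 3.5],
                    "body_semiaxes": [42.0, 75.0, 80.0],
                },
                "course": {"noise_sigma": 2.0},
            }
        )
    )
    return p
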