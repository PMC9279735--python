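"""Course processing, per-fraction reports and cohort-level statistics.

``process_course`` runs the full per-fraction chain — registration, dose
mapping, DVH metrics, endpoint evaluation, trend forecasting and DIR QA —
and emits a machine-readable report per fraction plus an end-of-course
cohort record per monitored endpoint.  ``summarize`` and ``two_sample_t``
reproduce the aggregate statistics used at cohort level (mean / median /
range, Student-t CI95, pooled-variance two-tailed t-test).

Reference cohort tables (per-structure initial/final values, deltas and
crossing fractions for flagged PTVs and parotids) ship with the package as
CSV and load through :func:`load_cohort_table`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_mapping, dvh, endpoints, forecast, qa
from .geometry import DoseGrid, ImageVolume, resample_to_grid
from .registration import RegistrationParams, register
from .rt_io import PlanContext

log = logging.getLogger(__name__)

COHORT_TABLES = {
    "ptv_coverage": "ptv_coverage_cohort.csv",
    "parotid_dmean": "parotid_dmean_cohort.csv",
}


def load_cohort_table(name: str) -> pd.DataFrame:
    """Load a packaged cohort table (``ptv_coverage`` or ``parotid_dmean``)."""
    try:
        fname = COHORT_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown cohort table {name!r}; have {list(COHORT_TABLES)}")
    with resources.files("adaptrt").joinpath("data", fname).open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Cohort records and summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    """One monitored endpoint's course outcome (a row of a cohort table)."""

    study: str
    structure: str
    metric: str
    initial: float                       # planned value
    final: float                         # EOT DP_sum value
    warning_level: float                 # DE_0
    adaptation_level: float
    crossing_fraction_warning: int | None = None
    crossing_fraction_adaptation: int | None = None
    violated_at_eot: bool = False

    @property
    def delta(self) -> float:
        return self.final - self.initial


def summarize(values) -> dict:
    """n / mean / median / min / max / CI95 half-width of a value list.

    The CI95 uses Student-t with n−1 df; with n < 2 it is reported as NaN.
    An empty selection returns an empty summary rather than an error.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"n": 0}
    out = {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
    if arr.size >= 2:
        out["sd"] = float(arr.std(ddof=1))
        out["ci95_half_width"] = float(
            stats.t.ppf(0.975, arr.size - 1) * out["sd"] / np.sqrt(arr.size)
        )
    else:
        out["sd"] = float("nan")
        out["ci95_half_width"] = float("nan")
    return out


def two_sample_t(group_a, group_b, pooled: bool = True) -> dict:
    """Two-tailed two-sample t-test (pooled variance by default)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return {"t": float(t), "p": float(p)}


# ---------------------------------------------------------------------------
# Course processing
# ---------------------------------------------------------------------------

@dataclass
class FractionRecord:
    """Machine-readable processing report for one fraction."""

    fraction: int
    dp_day: dict = field(default_factory=dict)    # (structure, metric) key -> value
    dp_sum: dict = field(default_factory=dict)
    predictions: dict = field(default_factory=dict)  # 4-ahead pDP_sum per endpoint
    qa_flags: dict = field(default_factory=dict)     # structure -> flag list
    out_of_grid: dict = field(default_factory=dict)
    failed: bool = False
    error: str | None = None


@dataclass
class CourseReport:
    fractions: list[FractionRecord]
    records: list[CohortRecord]
    violations: list[endpoints.ViolationEvent]
    qa_flagged: bool = False


def _endpoint_key(spec: endpoints.EndpointSpec) -> str:
    return f"{spec.structure}:{spec.metric}"


def _metric_from_samples(samples: np.ndarray, spec, voxel_volume: float, scope: str):
    return dvh.extract_metric(
        samples, spec.metric if spec.metric != "hotspot" else "hotspot",
        reference=spec.reference, voxel_volume=voxel_volume, scope=scope,
        structure=spec.structure,
    ).value


def process_course(
    plan_image: ImageVolume,
    plan: PlanContext,
    plan_dose: DoseGrid,
    daily_volumes: list[ImageVolume],
    endpoint_config: dict | None = None,
    reg_params: RegistrationParams | None = None,
    dvfs: list | None = None,
    study: str = "phantom",
    qa_thresholds: dict | None = None,
) -> CourseReport:
    """Run the full decision-support chain over a course of daily volumes.

    ``dvfs`` may supply precomputed deformation fields (e.g. phantom ground
    truth or cached registrations); otherwise each fraction is registered.
    A fraction that fails hard is marked failed in its report and processing
    continues with the next fraction.
    """
    monitored = {s.name for s in plan.structures if s.role in ("target", "oar")}
    plan_samples = {
        name: plan_dose.voxels[plan.structure(name).mask] for name in monitored
    }
    plan_metrics = {
        name: {"Dmean": float(v.mean()), "Dmax": float(v.max())}
        for name, v in plan_samples.items()
    }
    specs = endpoints.build_endpoint_set(plan, plan_metrics, endpoint_config)
    vv = plan_dose.voxel_volume_cc
    plan_dp = {
        _endpoint_key(s): _metric_from_samples(plan_samples[s.structure], s, vv, "plan")
        for s in specs
    }

    per_struct_samples: dict[str, list] = {s.structure: [] for s in specs}
    trajectories: dict[str, list[float]] = {_endpoint_key(s): [] for s in specs}
    fraction_reports: list[FractionRecord] = []
    qa_flagged = False

    for f, daily in enumerate(daily_volumes, start=1):
        rec = FractionRecord(fraction=f)
        n_before = {name: len(v) for name, v in per_struct_samples.items()}
        traj_before = {key: len(v) for key, v in trajectories.items()}
        try:
            if dvfs is not None:
                dvf = dvfs[f - 1]
            else:
                dvf = register(plan_image, daily, reg_params)
            daily_on_plan = resample_to_grid(
                daily, plan_image, outside=float(daily.voxels.min())
            )
            realigned = qa.warp_image(
                daily_on_plan, dvf, background=float(daily_on_plan.voxels.min())
            )
            struct_names = {s.structure for s in specs}
            for name in struct_names:
                structure = plan.structure(name)
                samples = dose_mapping.daily_dose(plan_dose, dvf, structure)
                per_struct_samples[name].append(samples)
                rec.out_of_grid[name] = samples.out_of_grid
                qres = qa.structure_qa(
                    plan_image, daily_on_plan, dvf, structure,
                    thresholds=qa_thresholds, realigned=realigned,
                )
                if qres.flags:
                    rec.qa_flags[name] = list(qres.flags)
                    qa_flagged = True
            for spec in specs:
                key = _endpoint_key(spec)
                acc = dose_mapping.accumulate(
                    per_struct_samples[spec.structure], plan.total_fractions
                )
                rec.dp_day[key] = _metric_from_samples(acc.day, spec, vv, "day")
                dp_sum = _metric_from_samples(acc.cumulative, spec, vv, "sum")
                rec.dp_sum[key] = dp_sum
                trajectories[key].append(dp_sum)
                ts = forecast.fit_predict(
                    np.array(trajectories[key]), structure=spec.structure,
                    metric=spec.metric,
                    percent_metric=spec.metric in ("V95", "hotspot"),
                )
                if ts.predictions is not None:
                    rec.predictions[key] = [float(v) for v in ts.predictions]
        except Exception as exc:  # keep processing the remaining fractions
            log.error("fraction %d failed: %s", f, exc)
            rec.failed = True
            rec.error = str(exc)
            for name, n in n_before.items():  # drop this fraction's partial state
                del per_struct_samples[name][n:]
            for key, n in traj_before.items():
                del trajectories[key][n:]
        fraction_reports.append(rec)

    violations: list[endpoints.ViolationEvent] = []
    records: list[CohortRecord] = []
    dpf = plan.dose_per_fraction
    for spec in specs:
        key = _endpoint_key(spec)
        traj = np.array(trajectories[key])
        if traj.size == 0:
            continue
        events = endpoints.detect_crossings(traj, spec, dose_per_fraction=dpf)
        violations.extend(events)
        fx_w = next(
            (e.crossing_fraction for e in events if e.level == "warning"), None
        )
        fx_a = next(
            (e.crossing_fraction for e in events if e.level == "adaptation"), None
        )
        records.append(
            CohortRecord(
                study=study,
                structure=spec.structure,
                metric=spec.metric,
                initial=plan_dp[key],
                final=float(traj[-1]),
                warning_level=spec.warning_level,
                adaptation_level=spec.adaptation_level,
                crossing_fraction_warning=fx_w,
                crossing_fraction_adaptation=fx_a,
                violated_at_eot=spec.violates(float(traj[-1]), "warning"),
            )
        )
    return CourseReport(
        fractions=fraction_reports, records=records, violations=violations,
        qa_flagged=qa_flagged,
    )


# ---------------------------------------------------------------------------
# Report serialization (JSON round-trip)
# ---------------------------------------------------------------------------

def report_to_json(report: CourseReport, path: str | Path) -> None:
    payload = {
        "fractions": [asdict(r) for r in report.fractions],
        "records": [asdict(r) for r in report.records],
        "violations": [asdict(v) for v in report.violations],
        "qa_flagged": report.qa_flagged,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def records_from_json(path: str | Path) -> list[CohortRecord]:
    payload = json.loads(Path(path).read_text())
    return [CohortRecord(**r) for r in payload["records"]]
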