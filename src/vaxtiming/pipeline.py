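"""End-to-end pipeline: validate -> classify -> tabulate -> delays -> risks.

One call runs every analysis stage on a cohort and writes all tables as
delimited text under an output directory, together with a manifest of
content digests so reruns can be checked for byte-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import delays as _delays
from . import risks as _risks
from . import tables as _tables
from .cohort import CohortTables, attendance_profile, attending_set, load_cohort
from .schedule import ScheduleSpec, load_schedule, zambia_epi_schedule

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("vaxtiming")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    ``schedule`` is a built-in name ("zambia-epi") or a YAML schedule
    file; every printed-output convention (window-3 end, compression
    thresholds, rounding) is a named option defaulting to the
    table-compatibility values.
    """

    roster: str
    visits: str
    doses: str
    out_dir: str
    schedule: str = "zambia-epi"
    window3_end: int = 127
    compression_thresholds: tuple[int, ...] = (28, 25, 20)
    n_scheduled_visits: int = 6
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "compression_thresholds" in data:
            data["compression_thresholds"] = tuple(data["compression_thresholds"])
        return cls(**data)

    def resolve_schedule(self) -> ScheduleSpec:
        if self.schedule in ("zambia-epi", "zambia-epi-6-10-14"):
            return zambia_epi_schedule(window3_end=self.window3_end)
        return load_schedule(self.schedule)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, cohort: CohortTables | None = None) -> dict:
    """Run every stage; returns a report with row counts and an output manifest."""
    schedule = config.resolve_schedule()
    if cohort is None:
        cohort = load_cohort(config.roster, config.visits, config.doses)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    attendance = attending_set(cohort)
    n_attending = int(attendance["attended_any"].sum())
    n_excluded = len(attendance) - n_attending
    log.info("enrolled=%d attending=%d excluded_never_attending=%d",
             len(attendance), n_attending, n_excluded)

    classifications = _classify.classify_cohort(schedule, cohort)

    artifacts: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = path

    write("attendance_profile", attendance_profile(cohort, max_age=schedule.last_window_end + 3))
    write("end_of_study", _classify.end_of_study_doses(classifications, schedule.n_doses))
    write("window_table", _tables.window_table(schedule, classifications))
    cum = _tables.cumulative_table(schedule, classifications)
    write("cumulative_per_range", cum.per_range.reset_index(names="dose"))
    write("cumulative_by_window_end", cum.cumulative.reset_index(names="dose"))
    write("doses_per_window", cum.doses_per_window.rename("doses").rename_axis("range").reset_index())
    write("compression_summary",
          _tables.compression_summary(classifications, config.compression_thresholds))
    hist = _tables.timing_histograms(schedule, classifications)
    for name, df in hist.items():
        write(f"hist_{name}", df)

    curve_frames, quantile_frames = [], []
    for dose in range(1, schedule.n_doses + 1):
        for assumption in ("standard", "worst-case"):
            curve = _delays.km_curve(cohort, dose, assumption, schedule, attendance)
            curve_frames.append(curve.as_frame()[1:])  # drop the -inf anchor row
            quantile_frames.append(_delays.delay_quantiles(curve, schedule).as_frame())
    write("delay_curves", pd.concat(curve_frames, ignore_index=True))
    write("delay_quantiles", pd.concat(quantile_frames, ignore_index=True))

    write("risk_screen", _risks.covariate_screen(cohort, classifications))
    write("demographics", _risks.demographics_table(cohort, config.n_scheduled_visits))
    write("unvaccinated_attending",
          _classify.attending_unvaccinated_fraction(schedule, cohort, classifications))

    if config.make_plots:
        from . import plots

        plots.plot_attendance_profile(
            attendance_profile(cohort, schedule.last_window_end + 3), schedule, out / "attendance.png")
        plots.plot_weekly_timing(hist["weekly"], out / "weekly_timing.png")
        if len(hist["spacing"]):
            plots.plot_spacing_histogram(hist["spacing"], schedule.min_interval, out / "spacing.png")

    manifest = {name: {"path": str(p), "sha256": _digest(p)} for name, p in sorted(artifacts.items())}
    report = {
        "n_enrolled": len(attendance),
        "n_attending": n_attending,
        "n_excluded_never_attending": n_excluded,
        "n_dose_events": len(cohort.doses),
        "schedule": schedule.name,
        "manifest": manifest,
    }
    (out / "manifest.json").write_text(json.dumps(report, indent=2))
    return report
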