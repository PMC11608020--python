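"""End-to-end study orchestration: weather I/O, averaging, calibration runs.

Weather files are comma-delimited with a required header
``date,tmax,tmin,tmean,rhmax,rhmin,rhmean,rs,u2`` (ISO-8601 dates, decimal
point, no thousands separators).  Rows violating the record invariants are
dropped with a logged reason and count rather than aborting the run.

Monthly aggregation uses equal-weight day means within each month; the
seasonal average is, by default, the equal-weight mean of the monthly
means ("monthly" convention).  A day-weighted alternative (plain mean of
all daily values) is also available; the two differ because months have
unequal lengths.
"""

from __future__ import annotations

import calendar
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import metrics as met_mod
from . import models as mdl
from .calibration import CalibrationResult, calibrate_all_models, coefficients_table
from .meteorology import DailyWeatherRecord, StationMeta
from .metrics import MetricSet, evaluate, metrics_table
from .models import ET0Series, MASS_TRANSFER_MODELS

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ["date", "tmax", "tmin", "tmean", "rhmax", "rhmin",
                   "rhmean", "rs", "u2"]


# ---------------------------------------------------------------------------
# Weather file I/O
# ---------------------------------------------------------------------------


def load_weather(path) -> list[DailyWeatherRecord]:
    """Read and validate a weather CSV; invalid rows are dropped and logged."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[DailyWeatherRecord] = []
    dropped = 0
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header on line 1
        try:
            date = datetime.date.fromisoformat(str(row["date"]).strip()[:10])
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: unparseable date "
                             f"{row['date']!r}") from exc
        try:
            records.append(DailyWeatherRecord(
                date=date,
                **{c: float(row[c]) for c in WEATHER_COLUMNS[1:]},
            ))
        except (TypeError, ValueError) as exc:
            dropped += 1
            logger.warning("%s:%d: dropped row (%s)", path, line_no, exc)
    if dropped:
        logger.warning("%s: dropped %d invalid row(s), kept %d", path,
                       dropped, len(records))
    if not records:
        raise ValueError(f"{path}: no valid rows after filtering")
    return records


def save_weather(records: Sequence[DailyWeatherRecord], path) -> None:
    """Write records to the weather CSV schema read by :func:`load_weather`."""
    frame = pd.DataFrame(
        [{"date": r.date.isoformat(),
          **{c: getattr(r, c) for c in WEATHER_COLUMNS[1:]}}
         for r in records]
    )
    frame.to_csv(path, index=False)


def load_et0_series(path, method: str, variant: str = "original") -> ET0Series:
    """Read a two-column (date,value) CSV into an :class:`ET0Series`."""
    frame = pd.read_csv(path)
    if not {"date", "value"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns 'date' and 'value'")
    dates = tuple(datetime.date.fromisoformat(str(d)[:10]) for d in frame["date"])
    return ET0Series(dates=dates, values=frame["value"].to_numpy(dtype=float),
                     method=method, variant=variant)


def save_et0_series(series: ET0Series, path) -> None:
    pd.DataFrame({
        "date": [d.isoformat() for d in series.dates],
        "value": series.values,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Averaging
# ---------------------------------------------------------------------------


def multi_year_average(records: Sequence[DailyWeatherRecord],
                       season: "SeasonWindow | None" = None
                       ) -> list[DailyWeatherRecord]:
    """Per-calendar-day mean of each field across years.

    The averaged season is dated in the final year present in the input.
    With a ``season`` window, every day of the window must be covered by
    at least one year.
    """
    if not records:
        raise ValueError("no records to average")
    by_day: dict[tuple[int, int], list[DailyWeatherRecord]] = {}
    for rec in records:
        by_day.setdefault((rec.date.month, rec.date.day), []).append(rec)
    year = max(rec.date.year for rec in records)
    if season is not None:
        for month, day in season.iter_days(year):
            if (month, day) not in by_day:
                raise ValueError(
                    f"season day {month:02d}-{day:02d} missing in all years"
                )
    out = []
    for (month, day) in sorted(by_day):
        group = by_day[(month, day)]
        means = {c: float(np.mean([getattr(r, c) for r in group]))
                 for c in WEATHER_COLUMNS[1:]}
        out.append(DailyWeatherRecord(date=datetime.date(year, month, day),
                                      **means))
    return out


@dataclass(frozen=True)
class SeasonWindow:
    """A within-year window of calendar days (inclusive)."""

    start_month: int = 4
    start_day: int = 1
    end_month: int = 10
    end_day: int = 31

    def contains(self, date: datetime.date) -> bool:
        return (
            (self.start_month, self.start_day)
            <= (date.month, date.day)
            <= (self.end_month, self.end_day)
        )

    def iter_days(self, year: int) -> Iterable[tuple[int, int]]:
        d = datetime.date(year, self.start_month, self.start_day)
        end = datetime.date(year, self.end_month, self.end_day)
        while d <= end:
            yield d.month, d.day
            d += datetime.timedelta(days=1)


def monthly_means(series: ET0Series) -> pd.Series:
    """Equal-weight mean of daily values within each calendar month."""
    s = series.to_pandas()
    grouped = s.groupby(s.index.month).mean()
    grouped.index = [calendar.month_abbr[m] for m in grouped.index]
    return grouped


def seasonal_mean(series: ET0Series, convention: str = "monthly") -> float:
    """Season average: equal-weight mean of monthly means, or day-weighted."""
    if convention == "monthly":
        return float(monthly_means(series).mean())
    if convention == "daily":
        return float(series.values.mean())
    raise ValueError(f"unknown seasonal-mean convention {convention!r}")


def mean_of_monthly_values(values: Sequence[float]) -> float:
    """Equal-weight mean of already-aggregated monthly values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no monthly values")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# Study configuration and report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Full-study configuration."""

    station: StationMeta = StationMeta(latitude=38.4667, elevation=1669.0)
    train_years: tuple[int, ...] = tuple(range(2012, 2021))
    test_years: tuple[int, ...] = (2021, 2022)
    season: SeasonWindow = SeasonWindow()
    models: tuple[str, ...] = MASS_TRANSFER_MODELS
    soil_heat_flux: float = 0.0
    seasonal_mean_convention: str = "monthly"
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.train_years) & set(self.test_years):
            raise ValueError("training and validation years must be disjoint")
        for m in self.models:
            mdl.get_model_spec(m)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "station" in raw:
            kwargs["station"] = StationMeta(**raw["station"])
        if "season" in raw:
            kwargs["season"] = SeasonWindow(**raw["season"])
        for key in ("train_years", "test_years", "models"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("soil_heat_flux", "seasonal_mean_convention", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class Report:
    """All tables and series produced by :func:`run_study`."""

    calibration: list[CalibrationResult]
    monthly_original: pd.DataFrame
    monthly_modified: pd.DataFrame
    training_metrics: dict[str, dict[str, MetricSet]]  # variant -> model -> m
    validation_metrics: dict[str, dict[str, dict[str, MetricSet]]]
    # variant -> year/"avg" -> model -> MetricSet
    series: dict[str, ET0Series] = field(default_factory=dict)


def _records_for_years(records: Sequence[DailyWeatherRecord],
                       years: Sequence[int],
                       season: SeasonWindow) -> list[DailyWeatherRecord]:
    return [r for r in records
            if r.date.year in years and season.contains(r.date)]


def _metric_frame_mean(per_year: Mapping[str, Mapping[str, MetricSet]]
                       ) -> dict[str, MetricSet]:
    """Arithmetic mean of per-year metrics for each model (the 'Avg' column)."""
    models = sorted(next(iter(per_year.values())).keys())
    out = {}
    for model_id in models:
        vals = {}
        for stat in ("mae", "mape", "rmse", "nse", "r2"):
            vals[stat] = float(np.mean(
                [getattr(per_year[y][model_id], stat) for y in per_year]
            ))
        out[model_id] = MetricSet(
            **vals,
            mape_class=met_mod.classify_mape(vals["mape"]),
            nse_class=met_mod.classify_nse(vals["nse"]),
            acceptable_mae=vals["mae"] < met_mod.MAE_ACCEPTABLE_LIMIT,
            acceptable_rmse=vals["rmse"] < met_mod.RMSE_ACCEPTABLE_LIMIT,
            acceptable_nse=vals["nse"] > met_mod.NSE_ACCEPTABLE_LIMIT,
        )
    return out


def run_study(config: RunConfig,
              weather: Sequence[DailyWeatherRecord]) -> Report:
    """Calibrate on the averaged training season, validate on held-out years."""
    train = _records_for_years(weather, config.train_years, config.season)
    if not train:
        raise ValueError("no weather records in the training period")
    avg_season = multi_year_average(train, season=None)

    reference = mdl.reference_series(avg_season, config.station,
                                     config.soil_heat_flux)
    originals = {m: mdl.model_series(avg_season, m) for m in config.models}
    calib = calibrate_all_models(reference, originals, models=config.models)
    coef = {r.model_id: (r.a, r.b) for r in calib}
    modified = {m: mdl.calibrated_series(originals[m], *coef[m])
                for m in config.models}

    series: dict[str, ET0Series] = {"train/reference": reference}
    for m in config.models:
        series[f"train/original/{m}"] = originals[m]
        series[f"train/modified/{m}"] = modified[m]

    # monthly tables (training representation)
    def _monthly_table(per_model: Mapping[str, ET0Series]) -> pd.DataFrame:
        cols = {"fao56pm": monthly_means(reference)}
        cols.update({m: monthly_means(per_model[m]) for m in config.models})
        table = pd.DataFrame(cols)
        table.loc["Avg"] = [
            seasonal_mean(reference if c == "fao56pm" else per_model[c],
                          config.seasonal_mean_convention)
            for c in table.columns
        ]
        return table

    monthly_original = _monthly_table(originals)
    monthly_modified = _monthly_table(modified)

    training_metrics = {
        "original": {m: evaluate(reference, originals[m])
                     for m in config.models},
        "modified": {m: evaluate(reference, modified[m])
                     for m in config.models},
    }

    # validation on each held-out year, then the across-year average
    validation_metrics: dict[str, dict[str, dict[str, MetricSet]]] = {
        "original": {}, "modified": {},
    }
    for year in config.test_years:
        recs = _records_for_years(weather, [year], config.season)
        if not recs:
            raise ValueError(f"no weather records for validation year {year}")
        ref_y = mdl.reference_series(recs, config.station,
                                     config.soil_heat_flux)
        series[f"{year}/reference"] = ref_y
        orig_y = {m: mdl.model_series(recs, m) for m in config.models}
        mod_y = {m: mdl.calibrated_series(orig_y[m], *coef[m])
                 for m in config.models}
        validation_metrics["original"][str(year)] = {
            m: evaluate(ref_y, orig_y[m]) for m in config.models}
        validation_metrics["modified"][str(year)] = {
            m: evaluate(ref_y, mod_y[m]) for m in config.models}
        for m in config.models:
            series[f"{year}/original/{m}"] = orig_y[m]
            series[f"{year}/modified/{m}"] = mod_y[m]
    if config.test_years:
        for variant in ("original", "modified"):
            validation_metrics[variant]["avg"] = _metric_frame_mean(
                validation_metrics[variant])

    return Report(
        calibration=calib,
        monthly_original=monthly_original,
        monthly_modified=monthly_modified,
        training_metrics=training_metrics,
        validation_metrics=validation_metrics,
        series=series,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_report(report: Report, out_dir, formats: Sequence[str] = ("csv", "txt")
                  ) -> list[Path]:
    """Write the report tables; deterministic output for identical reports.

    ``csv`` tables carry full precision; the ``txt`` summary rounds to two
    decimals for human reading.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(frame: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        frame.to_csv(p, float_format="%.10g")
        written.append(p)

    if "csv" in formats:
        _write_csv(coefficients_table(report.calibration), "calibration.csv")
        _write_csv(report.monthly_original, "monthly_means_original.csv")
        _write_csv(report.monthly_modified, "monthly_means_modified.csv")
        for variant, per_model in report.training_metrics.items():
            _write_csv(metrics_table(per_model),
                       f"metrics_training_{variant}.csv")
        for variant, per_year in report.validation_metrics.items():
            for year, per_model in sorted(per_year.items()):
                _write_csv(metrics_table(per_model),
                           f"metrics_validation_{variant}_{year}.csv")
        for key in sorted(report.series):
            safe = key.replace("/", "_")
            p = out_dir / f"series_{safe}.csv"
            save_et0_series(report.series[key], p)
            written.append(p)

    if "txt" in formats:
        p = out_dir / "summary.txt"
        with open(p, "w") as fh:
            fh.write("Calibration coefficients\n")
            fh.write(coefficients_table(report.calibration)
                     .round(4).to_string())
            fh.write("\n\nMonthly means, original equations (mm/day)\n")
            fh.write(report.monthly_original.round(2).to_string())
            fh.write("\n\nMonthly means, modified equations (mm/day)\n")
            fh.write(report.monthly_modified.round(2).to_string())
            for variant, per_model in report.training_metrics.items():
                fh.write(f"\n\nTraining metrics ({variant})\n")
                fh.write(metrics_table(per_model).round(2).to_string())
            for variant, per_year in report.validation_metrics.items():
                for year, per_model in sorted(per_year.items()):
                    fh.write(f"\n\nValidation metrics ({variant}, {year})\n")
                    fh.write(metrics_table(per_model).round(2).to_string())
            fh.write("\n")
        written.append(p)
    return written
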