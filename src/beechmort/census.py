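"""Census-table domain model for permanent-plot tree mortality data.

The study design this package targets is a network of 20 x 20 m permanent
plots, each divided into a 4 x 4 grid of 5 x 5 m subplots.  Every stem with
diameter at breast height (D, measured 135 cm above ground) of at least
3 cm (30 mm) is tagged and followed through repeated censuses; censuses are
separated by multi-year intervals that need not be equal.

This module holds the record types (:class:`TreeRecord`, :class:`CensusPeriod`,
:class:`PlotLayout`), tab-delimited census-table I/O, the small/large
size-class split at 20 cm, and stand-level basal-area summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STATUS_ALIVE",
    "STATUS_DEAD",
    "STATUS_ABSENT",
    "TAG_THRESHOLD_MM",
    "SIZE_CLASS_THRESHOLD_MM",
    "PLOT_AREA_HA",
    "SchemaError",
    "ValidationError",
    "TreeRecord",
    "CensusPeriod",
    "PlotLayout",
    "read_census",
    "write_census",
    "read_periods",
    "write_periods",
    "validate_records",
    "split_size_classes",
    "stand_basal_area",
    "StandBasalArea",
    "tree_basal_area_m2",
]

STATUS_ALIVE = "alive"
STATUS_DEAD = "dead"
STATUS_ABSENT = "absent"
VALID_STATUSES = frozenset({STATUS_ALIVE, STATUS_DEAD, STATUS_ABSENT})

#: Tagging threshold: stems below 30 mm D are not part of the census.
TAG_THRESHOLD_MM = 30.0
#: Small/large split: small is 30 <= D < 200 mm, large is D >= 200 mm.
SIZE_CLASS_THRESHOLD_MM = 200.0
#: Area of one 20 x 20 m plot in hectares.
PLOT_AREA_HA = 0.04
#: Side of the subplot grid (4 x 4 subplots of 5 x 5 m).
SUBPLOT_GRID = 4


class SchemaError(ValueError):
    """A census table is missing required columns or has malformed keys."""


class ValidationError(ValueError):
    """Census records violate a biological or structural invariant.

    Carries the offending tree ids in :attr:`tree_ids`.
    """

    def __init__(self, message: str, tree_ids: Sequence[str] = ()):
        super().__init__(message)
        self.tree_ids = tuple(tree_ids)


@dataclass(frozen=True)
class CensusPeriod:
    """A remeasurement interval between two censuses.

    ``t_years`` is the interval length in years; the three field periods of
    the target design are 9, 10 and 11 years, and a pooled 30-year period is
    used for the overall size-mortality curve.  Arbitrary positive lengths
    are accepted for synthetic scenarios.
    """

    label: str
    start_census: str
    end_census: str
    t_years: float

    def __post_init__(self) -> None:
        if self.t_years <= 0:
            raise ValueError(f"period {self.label!r}: t_years must be > 0")


@dataclass(frozen=True)
class PlotLayout:
    """Geometry of one permanent plot: a 4 x 4 grid of 5 x 5 m subplots."""

    plot_id: str
    plot_side_m: float = 20.0
    subplot_side_m: float = 5.0
    subplot_grid: int = SUBPLOT_GRID


@dataclass
class TreeRecord:
    """One tagged stem with subplot-resolved location and per-census state.

    ``diameter_mm`` and ``status`` are keyed by census label; the insertion
    order of ``status`` defines census chronology for validation purposes.
    A census absent from ``status`` is treated as ``absent``.
    """

    tree_id: str
    plot_id: str
    subplot_row: int
    subplot_col: int
    diameter_mm: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def status_at(self, census: str) -> str:
        return self.status.get(census, STATUS_ABSENT)

    def diameter_at(self, census: str) -> float:
        return self.diameter_mm.get(census, math.nan)

    def is_alive(self, census: str) -> bool:
        return self.status_at(census) == STATUS_ALIVE

    def validate(self) -> None:
        """Check structural and biological invariants for this record."""
        if not (0 <= self.subplot_row < SUBPLOT_GRID):
            raise ValidationError(
                f"tree {self.tree_id}: subplot_row {self.subplot_row} outside 0-3",
                [self.tree_id],
            )
        if not (0 <= self.subplot_col < SUBPLOT_GRID):
            raise ValidationError(
                f"tree {self.tree_id}: subplot_col {self.subplot_col} outside 0-3",
                [self.tree_id],
            )
        seen_dead = False
        seen_alive = False
        for census, status in self.status.items():
            if status not in VALID_STATUSES:
                raise ValidationError(
                    f"tree {self.tree_id}: unknown status {status!r} at census {census}",
                    [self.tree_id],
                )
            if status == STATUS_ALIVE:
                if seen_dead:
                    raise ValidationError(
                        f"tree {self.tree_id}: resurrection (dead then alive) at census {census}",
                        [self.tree_id],
                    )
                d = self.diameter_at(census)
                if not seen_alive:
                    if not (d >= TAG_THRESHOLD_MM):
                        raise ValidationError(
                            f"tree {self.tree_id}: first living diameter {d} mm "
                            f"below the {TAG_THRESHOLD_MM:.0f} mm tagging threshold",
                            [self.tree_id],
                        )
                    seen_alive = True
                elif not (math.isnan(d) or d > 0):
                    raise ValidationError(
                        f"tree {self.tree_id}: non-positive diameter {d} mm at census {census}",
                        [self.tree_id],
                    )
            elif status == STATUS_DEAD:
                seen_dead = True


def validate_records(records: Iterable[TreeRecord]) -> None:
    """Validate a collection, reporting every offending tree id at once."""
    bad: list[str] = []
    messages: list[str] = []
    seen_ids: set[str] = set()
    for rec in records:
        if rec.tree_id in seen_ids:
            bad.append(rec.tree_id)
            messages.append(f"duplicate tree_id {rec.tree_id}")
            continue
        seen_ids.add(rec.tree_id)
        try:
            rec.validate()
        except ValidationError as err:
            bad.extend(err.tree_ids)
            messages.append(str(err))
    if bad:
        raise ValidationError(
            "invalid census records: " + "; ".join(messages[:20]), bad
        )


# ---------------------------------------------------------------------------
# Census table I/O
#
# TSV layout: tree_id, plot_id, subplot_row, subplot_col, then one pair of
# wide columns per census: D_<census> (mm, blank if not measured) and
# status_<census> (alive/dead/absent).  Census chronology follows column
# order.  Period definitions travel separately as YAML/JSON.
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ("tree_id", "plot_id", "subplot_row", "subplot_col")


def _census_keys_from_columns(columns: Sequence[str]) -> list[str]:
    keys: list[str] = []
    for col in columns:
        if col.startswith("status_"):
            keys.append(col[len("status_"):])
    return keys


def read_census(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    periods_path: str | Path | None = None,
    validate: bool = True,
) -> tuple[list[TreeRecord], list[CensusPeriod]]:
    """Read a tab-delimited census table (and optional period definitions).

    ``schema`` optionally maps canonical column names (``tree_id`` etc.) to
    the names actually present in the file.  Returns the validated records
    and the period list (empty when ``periods_path`` is not given).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, float_precision="round_trip")
    if schema:
        frame = frame.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in _BASE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    census_keys = _census_keys_from_columns(list(frame.columns))
    if not census_keys:
        raise SchemaError(f"{path.name}: no status_<census> columns found")
    for key in census_keys:
        if f"D_{key}" not in frame.columns:
            raise SchemaError(f"{path.name}: status_{key} present but D_{key} missing")

    records: list[TreeRecord] = []
    for row in frame.itertuples(index=False):
        row_d = row._asdict()
        diameter: dict[str, float] = {}
        status: dict[str, str] = {}
        for key in census_keys:
            st = row_d[f"status_{key}"]
            st = STATUS_ABSENT if (isinstance(st, float) and math.isnan(st)) else str(st)
            status[key] = st
            d = row_d[f"D_{key}"]
            if d is not None and not (isinstance(d, float) and math.isnan(d)):
                diameter[key] = float(d)
        records.append(
            TreeRecord(
                tree_id=str(row_d["tree_id"]),
                plot_id=str(row_d["plot_id"]),
                subplot_row=int(row_d["subplot_row"]),
                subplot_col=int(row_d["subplot_col"]),
                diameter_mm=diameter,
                status=status,
            )
        )
    if validate:
        validate_records(records)
    periods = read_periods(periods_path) if periods_path is not None else []
    return records, periods


def census_keys(records: Sequence[TreeRecord]) -> list[str]:
    """Union of census labels across records, in first-seen order."""
    keys: dict[str, None] = {}
    for rec in records:
        for key in rec.status:
            keys.setdefault(key)
    return list(keys)


def write_census(records: Sequence[TreeRecord], path: str | Path) -> None:
    """Write records to the wide TSV layout read by :func:`read_census`."""
    keys = census_keys(records)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "tree_id": rec.tree_id,
            "plot_id": rec.plot_id,
            "subplot_row": rec.subplot_row,
            "subplot_col": rec.subplot_col,
        }
        for key in keys:
            d = rec.diameter_at(key)
            row[f"D_{key}"] = "" if math.isnan(d) else repr(d)
            row[f"status_{key}"] = rec.status_at(key)
        rows.append(row)
    columns = list(_BASE_COLUMNS) + [c for key in keys for c in (f"D_{key}", f"status_{key}")]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_periods(path: str | Path) -> list[CensusPeriod]:
    """Read period definitions from YAML or JSON (a list of mappings)."""
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)  # JSON is a YAML subset
    if not isinstance(raw, list):
        raise SchemaError("period file must contain a list of period mappings")
    periods = []
    for entry in raw:
        try:
            periods.append(
                CensusPeriod(
                    label=str(entry["label"]),
                    start_census=str(entry["start"]),
                    end_census=str(entry["end"]),
                    t_years=float(entry["t_years"]),
                )
            )
        except KeyError as err:
            raise SchemaError(f"period entry missing key {err}") from err
    return periods


def write_periods(periods: Sequence[CensusPeriod], path: str | Path) -> None:
    payload = [
        {
            "label": p.label,
            "start": p.start_census,
            "end": p.end_census,
            "t_years": p.t_years,
        }
        for p in periods
    ]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# Size classes and stand summaries
# ---------------------------------------------------------------------------


def split_size_classes(
    records: Sequence[TreeRecord],
    census: str,
    threshold_mm: float = SIZE_CLASS_THRESHOLD_MM,
) -> tuple[list[TreeRecord], list[TreeRecord]]:
    """Partition live trees into small (D < threshold) and large (D >= threshold).

    All records must be alive at ``census`` with diameter at or above the
    30 mm tagging threshold; the split is exhaustive and disjoint.
    """
    small: list[TreeRecord] = []
    large: list[TreeRecord] = []
    bad: list[str] = []
    for rec in records:
        if not rec.is_alive(census):
            bad.append(rec.tree_id)
            continue
        d = rec.diameter_at(census)
        if not (d >= TAG_THRESHOLD_MM):
            bad.append(rec.tree_id)
            continue
        (large if d >= threshold_mm else small).append(rec)
    if bad:
        raise ValidationError(
            f"{len(bad)} record(s) not alive at census {census!r} or below "
            f"the {TAG_THRESHOLD_MM:.0f} mm threshold",
            bad,
        )
    return small, large


def tree_basal_area_m2(diameter_mm: float | np.ndarray) -> float | np.ndarray:
    """Cross-sectional stem area pi*(D/2)^2, with D in mm, in m^2."""
    return np.pi * (np.asarray(diameter_mm, dtype=float) / 2000.0) ** 2


@dataclass(frozen=True)
class StandBasalArea:
    """Per-plot basal area (m^2 ha^-1) with across-plot mean and SEM."""

    per_plot: dict[str, float]
    mean: float
    sem: float
    n_plots: int


def stand_basal_area(
    records: Sequence[TreeRecord],
    census: str,
    plot_area_ha: float = PLOT_AREA_HA,
) -> StandBasalArea:
    """Per-plot basal area of live stems at ``census``, in m^2 ha^-1.

    Every plot_id present among the records counts as a plot, so plots where
    all stems have died contribute a basal area of zero.  The SEM is
    SD/sqrt(n_plots) with the sample (ddof=1) standard deviation; with a
    single plot the SEM is NaN.
    """
    if plot_area_ha <= 0:
        raise ValueError("plot_area_ha must be > 0")
    per_plot: dict[str, float] = {}
    for rec in records:
        per_plot.setdefault(rec.plot_id, 0.0)
        if rec.is_alive(census):
            d = rec.diameter_at(census)
            if not math.isnan(d):
                per_plot[rec.plot_id] += float(tree_basal_area_m2(d)) / plot_area_ha
    if not per_plot:
        raise ValueError("no plots in input: basal area undefined")
    values = np.array(list(per_plot.values()), dtype=float)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else math.nan
    return StandBasalArea(per_plot=per_plot, mean=mean, sem=sem, n_plots=len(values))
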