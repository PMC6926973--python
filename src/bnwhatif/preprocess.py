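"""Survey preprocessing: BMI categorization, row filtering, attribute merges.

Mirrors the cleaning a categorical adolescent-health survey needs before
network learning: BMI computed as weight / height² and categorized against
age- and sex-specific growth-chart percentile cutoffs (5th / 85th / 95th),
rows with missing values or invalid smartphone-usage answers dropped, and
groups of ordinal items combined into single coarser attributes.

The packaged growth chart covers ages 12–18 for boys and girls; category
intervals are closed on the left, i.e. BMI in [p85, p95) is overweight and
BMI >= p95 is obese.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidAnthropometryError,
    InvalidDurationError,
    MergeTypeError,
    OutOfChartError,
)

#: Tokens treated as missing values in raw survey files.
MISSING_MARKERS = frozenset({"", "NA", "-9"})

#: Token a corrupted smartphone-usage cell carries for a never-user.
NON_USER_TOKEN = "Non_user"
#: Token for a "don't know" answer on smartphone usage.
DONT_KNOW_TOKEN = "Dont_know"

#: Ordered BMI categories, lightest to heaviest.
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

_SEXES = ("boy", "girl")
_AGES = tuple(range(12, 19))


@dataclass(frozen=True)
class GrowthChartTable:
    """(age, sex) -> (p5, p85, p95) BMI percentile cutoffs in kg/m²."""

    entries: dict[tuple[int, str], tuple[float, float, float]]

    def __post_init__(self) -> None:
        expected = {(a, s) for a in _AGES for s in _SEXES}
        if set(self.entries) != expected:
            raise ValueError(
                "growth chart must cover exactly ages 12-18 for boy and girl"
            )
        for key, (p5, p85, p95) in self.entries.items():
            if not p5 < p85 < p95:
                raise ValueError(f"cutoffs not increasing at {key}: {(p5, p85, p95)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthChartTable":
        entries = {
            (int(row.age), str(row.sex)): (float(row.p5), float(row.p85), float(row.p95))
            for row in frame.itertuples()
        }
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "GrowthChartTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def load_default(cls) -> "GrowthChartTable":
        """The packaged 2007 growth chart for Korean children and adolescents."""
        ref = resources.files("bnwhatif.data") / "growth_chart_2007.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


@dataclass(frozen=True)
class SmartphoneRules:
    """Which column flags smartphone usage and which answers drop a row."""

    column: str
    nonuser_tokens: frozenset[str] = frozenset({NON_USER_TOKEN})
    dontknow_tokens: frozenset[str] = frozenset({DONT_KNOW_TOKEN})


@dataclass(frozen=True)
class FilterReport:
    """Reconciled row counts for one filtering pass."""

    rows_in: int
    rows_dropped_missing: int
    rows_dropped_nonuser: int
    rows_dropped_dontknow: int
    rows_out: int

    def __post_init__(self) -> None:
        drops = (
            self.rows_dropped_missing
            + self.rows_dropped_nonuser
            + self.rows_dropped_dontknow
        )
        if min(
            self.rows_in,
            self.rows_dropped_missing,
            self.rows_dropped_nonuser,
            self.rows_dropped_dontknow,
            self.rows_out,
        ) < 0 or self.rows_out != self.rows_in - drops:
            raise ValueError("filter report counts do not reconcile")


@dataclass(frozen=True)
class MergeSpec:
    """Combine ordinal source columns into one quantile-binned attribute."""

    new_name: str
    source_columns: tuple[str, ...]
    combine: str = "ordinal_sum"
    bins: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_columns", tuple(self.source_columns))
        if not self.source_columns:
            raise ValueError("merge needs at least one source column")
        if self.combine not in ("ordinal_sum", "mean"):
            raise ValueError(f"unknown combine rule {self.combine!r}")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


# ---------------------------------------------------------------------------
# BMI
# ---------------------------------------------------------------------------

def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by the square of height (m)."""
    if np.any(np.asarray(weight_kg) <= 0) or np.any(np.asarray(height_m) <= 0):
        raise InvalidAnthropometryError(
            f"weight and height must be positive, got ({weight_kg}, {height_m})"
        )
    return weight_kg / height_m**2


def lookup_cutoff(
    chart: GrowthChartTable, age: int, sex: str, percentile: int
) -> float:
    """The chart's 5th/85th/95th percentile BMI cutoff for (age, sex)."""
    if percentile not in (5, 85, 95):
        raise ValueError(f"percentile must be 5, 85 or 95, got {percentile}")
    key = (int(age), str(sex))
    if key not in chart.entries:
        raise OutOfChartError(
            f"(age={age}, sex={sex!r}) outside the chart (ages 12-18, boy/girl)"
        )
    p5, p85, p95 = chart.entries[key]
    return {5: p5, 85: p85, 95: p95}[percentile]


def classify_bmi(
    bmi: float, age: int, sex: str, chart: GrowthChartTable | None = None
) -> str:
    """BMI category against the growth chart; intervals closed on the left."""
    chart = chart or GrowthChartTable.load_default()
    key = (int(age), str(sex))
    if key not in chart.entries:
        raise OutOfChartError(
            f"(age={age}, sex={sex!r}) outside the chart (ages 12-18, boy/girl)"
        )
    p5, p85, p95 = chart.entries[key]
    if bmi < p5:
        return "underweight"
    if bmi < p85:
        return "normal"
    if bmi < p95:
        return "overweight"
    return "obese"


# ---------------------------------------------------------------------------
# row filtering
# ---------------------------------------------------------------------------

def filter_rows(
    data: pd.DataFrame,
    missing_markers: Iterable[str] = MISSING_MARKERS,
    smartphone_rules: SmartphoneRules | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows with missing cells, smartphone never-users and "don't know"s.

    Rows are counted once, in that precedence order.  Returns the surviving
    rows (index reset) and a reconciled :class:`FilterReport`.
    """
    markers = set(str(m) for m in missing_markers)
    rows_in = len(data)
    as_str = data.astype(str)
    missing = data.isna().any(axis=1) | as_str.isin(markers).any(axis=1)

    nonuser = pd.Series(False, index=data.index)
    dontknow = pd.Series(False, index=data.index)
    if smartphone_rules is not None and smartphone_rules.column in data.columns:
        col = as_str[smartphone_rules.column]
        nonuser = col.isin(set(smartphone_rules.nonuser_tokens)) & ~missing
        dontknow = (
            col.isin(set(smartphone_rules.dontknow_tokens)) & ~missing & ~nonuser
        )
    keep = ~(missing | nonuser | dontknow)
    report = FilterReport(
        rows_in=rows_in,
        rows_dropped_missing=int(missing.sum()),
        rows_dropped_nonuser=int(nonuser.sum()),
        rows_dropped_dontknow=int(dontknow.sum()),
        rows_out=int(keep.sum()),
    )
    return data.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# attribute merging
# ---------------------------------------------------------------------------

def merge_attributes(
    data: pd.DataFrame, specs: Sequence[MergeSpec]
) -> pd.DataFrame:
    """Combine ordinal columns (sum or mean) and quantile-bin the result.

    Bin edges are interpolated quantiles of the combined value; output
    categories are labelled ``q1`` (lowest) through ``q<bins>``.  Row count
    and order are preserved; source columns are dropped.
    """
    out = data.copy()
    for spec in specs:
        cols = []
        for name in spec.source_columns:
            if name not in out.columns:
                raise MergeTypeError(f"merge source column {name!r} not in data")
            col = out[name]
            if not pd.api.types.is_numeric_dtype(col):
                try:
                    col = pd.to_numeric(col)
                except (TypeError, ValueError):
                    raise MergeTypeError(
                        f"merge source column {name!r} is not ordinal-coded"
                    ) from None
            cols.append(col.to_numpy(dtype=float))
        stacked = np.column_stack(cols)
        combined = (
            stacked.sum(axis=1) if spec.combine == "ordinal_sum" else stacked.mean(axis=1)
        )
        edges = np.unique(np.quantile(combined, np.linspace(0, 1, spec.bins + 1)))
        if len(edges) < 2:  # constant column: single category
            labels = pd.Series(["q1"] * len(out), index=out.index)
        else:
            labels = pd.cut(
                combined,
                bins=edges,
                include_lowest=True,
                labels=[f"q{i + 1}" for i in range(len(edges) - 1)],
            ).astype(str)
        out = out.drop(columns=list(spec.source_columns))
        out[spec.new_name] = np.asarray(labels, dtype=object)
    return out


def combine_weekday_weekend(weekday_minutes, weekend_minutes):
    """Weekly-average minutes per day: (5·weekday + 2·weekend) / 7."""
    wd = np.asarray(weekday_minutes, dtype=float)
    we = np.asarray(weekend_minutes, dtype=float)
    if np.any(wd < 0) or np.any(we < 0):
        raise InvalidDurationError("minute counts must be non-negative")
    result = (5.0 * wd + 2.0 * we) / 7.0
    if result.ndim == 0:
        return float(result)
    return result


# ---------------------------------------------------------------------------
# survey I/O
# ---------------------------------------------------------------------------

def read_survey_csv(path) -> pd.DataFrame:
    """Read a categorical survey CSV keeping all cells as strings.

    Empty cells survive as empty strings so missing-marker filtering sees
    them; nothing is coerced to NaN.
    """
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_survey_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_arff(path) -> pd.DataFrame:
    """Read a nominal-attribute ARFF file into a string DataFrame."""
    from scipy.io import arff

    raw, _meta = arff.loadarff(path)
    frame = pd.DataFrame(raw)
    for col in frame.columns:
        if frame[col].dtype == object:
            frame[col] = frame[col].str.decode("utf-8")
    return frame.astype(str)
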