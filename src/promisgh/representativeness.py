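"""Check a sample's sociodemographic margins against census margins.

A sample is accepted as representative when, for every checked variable
(age band, gender, education level, region, ethnicity), every category's
sample percentage deviates from the census percentage by less than a
criterion — 2.5 percentage points by default.  Deviations are absolute
differences of percentages; the criterion comparison is strict (<).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from promisgh.instrument import ResponseRecord

DEFAULT_CRITERION = 2.5

#: Age banding used for the representativeness check (coarser than the
#: reference-table bands).  18-39 and 40-65 include both endpoints; >65
#: excludes 65.
CHECK_AGE_BANDS: tuple[tuple[int, Optional[int], str], ...] = (
    (18, 39, "18-39"),
    (40, 65, "40-65"),
    (66, None, ">65"),
)


class MarginError(ValueError):
    pass


def check_age_band(age: int) -> str:
    for lo, hi, label in CHECK_AGE_BANDS:
        if age >= lo and (hi is None or age <= hi):
            return label
    raise MarginError(f"age {age} below the adult range")


@dataclass(frozen=True)
class MarginSpec:
    """Census percentages for one variable's categories."""

    variable: str
    categories: tuple[str, ...]
    census_pct: tuple[float, ...]
    unknown_categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.census_pct):
            raise MarginError(
                f"{self.variable}: {len(self.categories)} categories but "
                f"{len(self.census_pct)} percentages"
            )
        if any(p < 0 for p in self.census_pct):
            raise MarginError(f"{self.variable}: negative census percentage")
        # printed margins can sum slightly off 100 (e.g. 34+44+23 = 101)
        total = sum(self.census_pct)
        if not 99.0 <= total <= 101.0:
            raise MarginError(
                f"{self.variable}: census percentages sum to {total:.2f}"
            )


@dataclass(frozen=True)
class RepresentativenessReport:
    """Per-category deviations and the overall pass/fail verdict."""

    table: pd.DataFrame  # variable, category, sample_pct, census_pct, deviation
    max_deviation: float
    max_category: str
    criterion: float

    @property
    def passed(self) -> bool:
        return self.max_deviation < self.criterion


def margin_deviations(
    sample_pct: Mapping[str, float], spec: MarginSpec
) -> pd.DataFrame:
    """Deviation rows for one variable given sample category percentages.

    Every census category is enumerated even when absent from the sample
    (its deviation is then the full census percentage).  Sample categories
    outside the spec must be declared unknown; unknown buckets are reported
    with a NaN deviation and excluded from the maximum.
    """
    known = set(spec.categories) | set(spec.unknown_categories)
    extra = set(sample_pct) - known
    if extra:
        raise MarginError(
            f"{spec.variable}: sample categories {sorted(extra)} not in the "
            f"margin spec and no unknown bucket declared for them"
        )
    rows = []
    for cat, census in zip(spec.categories, spec.census_pct):
        sample = float(sample_pct.get(cat, 0.0))
        rows.append(
            {
                "variable": spec.variable,
                "category": cat,
                "sample_pct": sample,
                "census_pct": census,
                "deviation": abs(sample - census),
            }
        )
    for cat in spec.unknown_categories:
        rows.append(
            {
                "variable": spec.variable,
                "category": cat,
                "sample_pct": float(sample_pct.get(cat, 0.0)),
                "census_pct": np.nan,
                "deviation": np.nan,
            }
        )
    return pd.DataFrame(rows)


def sample_margins(
    records: Sequence[ResponseRecord], variable: str
) -> dict[str, float]:
    """Observed category percentages of one demographic variable."""
    getter: Callable[[ResponseRecord], Optional[str]]
    if variable == "age_band":
        getter = lambda r: check_age_band(r.age)
    elif variable in ("gender", "education", "region", "ethnicity"):
        getter = lambda r: getattr(r, variable)
    else:
        raise MarginError(f"margin variable {variable!r} absent from records")
    values = [getter(r) for r in records]
    values = [v if v is not None else "unknown" for v in values]
    n = len(values)
    if n == 0:
        raise MarginError("empty record collection")
    out: dict[str, float] = {}
    for v in values:
        out[v] = out.get(v, 0.0) + 100.0 / n
    return out


def margin_deviation_report(
    records: Sequence[ResponseRecord],
    margins: Sequence[MarginSpec],
    criterion: float = DEFAULT_CRITERION,
) -> RepresentativenessReport:
    """Compare a sample's margins to census margins, variable by variable."""
    tables = [
        margin_deviations(sample_margins(records, spec.variable), spec)
        for spec in margins
    ]
    return _assemble_report(pd.concat(tables, ignore_index=True), criterion)


def margin_deviation_report_from_percentages(
    sample: Mapping[str, Mapping[str, float]],
    margins: Sequence[MarginSpec],
    criterion: float = DEFAULT_CRITERION,
) -> RepresentativenessReport:
    """Same check, starting from already-tabulated sample percentages."""
    tables = []
    for spec in margins:
        if spec.variable not in sample:
            raise MarginError(f"margin variable {spec.variable!r} absent")
        tables.append(margin_deviations(sample[spec.variable], spec))
    return _assemble_report(pd.concat(tables, ignore_index=True), criterion)


def _assemble_report(
    table: pd.DataFrame, criterion: float
) -> RepresentativenessReport:
    valid = table.dropna(subset=["deviation"])
    imax = valid["deviation"].idxmax()
    return RepresentativenessReport(
        table=table,
        max_deviation=float(valid.loc[imax, "deviation"]),
        max_category=f"{valid.loc[imax, 'variable']}:{valid.loc[imax, 'category']}",
        criterion=criterion,
    )


def load_margins(path: str | Path) -> tuple[list[MarginSpec], dict[str, dict[str, float]]]:
    """Read a margins CSV: columns variable, category, census_pct, sample_pct.

    An empty census cell declares an unknown bucket (excluded from
    deviations).  Returns the margin specs plus any sample percentages
    present in the file.
    """
    df = pd.read_csv(path, comment="#")
    specs: list[MarginSpec] = []
    sample: dict[str, dict[str, float]] = {}
    for variable, grp in df.groupby("variable", sort=False):
        known = grp[grp["census_pct"].notna()]
        unknown = grp[grp["census_pct"].isna()]
        specs.append(
            MarginSpec(
                variable=str(variable),
                categories=tuple(known["category"]),
                census_pct=tuple(float(x) for x in known["census_pct"]),
                unknown_categories=tuple(unknown["category"]),
            )
        )
        if "sample_pct" in grp and grp["sample_pct"].notna().any():
            sample[str(variable)] = {
                str(c): float(p)
                for c, p in zip(grp["category"], grp["sample_pct"])
                if pd.notna(p)
            }
    return specs, sample


def load_default_margins() -> tuple[list[MarginSpec], dict[str, dict[str, float]]]:
    """The shipped 2016 Dutch census margins (and published panel margins)."""
    with resources.as_file(
        resources.files("promisgh.data").joinpath("census_margins_2016.csv")
    ) as path:
        return load_margins(path)
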