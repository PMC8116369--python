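"""Descriptive surfaces: item distributions, subgroup reference tables,
comparisons to a fixed reference mean, and long-vs-short subscale gaps.

Reference (normative) values summarize T-scores for a general population
and its subgroups — here: total, gender, and six age bands (18-34, 35-44,
45-54, 55-64, 65-74, 75+).  Statistics are unweighted: the sample is
constructed to be representative, so no post-stratification is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from promisgh.formatting import round_half_up
from promisgh.instrument import InstrumentSpec, ResponseRecord, recode_response

SUBSCALES = ("GMH", "GMH-2a", "GPH", "GPH-2a")

#: Age bands used for reference tables (closed integer ranges; the last is
#: open-ended).  Distinct from the representativeness-check banding.
REFERENCE_AGE_BANDS: tuple[tuple[int, Optional[int], str], ...] = (
    (18, 34, "18-34"),
    (35, 44, "35-44"),
    (45, 54, "45-54"),
    (55, 64, "55-64"),
    (65, 74, "65-74"),
    (75, None, "75+"),
)

SUBGROUP_ORDER = ("total", "male", "female") + tuple(
    label for *_, label in REFERENCE_AGE_BANDS
)


class PopRefError(ValueError):
    pass


def reference_age_band(age: int) -> str:
    for lo, hi, label in REFERENCE_AGE_BANDS:
        if age >= lo and (hi is None or age <= hi):
            return label
    raise PopRefError(f"age {age} below the adult range")


# ---------------------------------------------------------------------------
# Item distributions (response-category percentages, mean, SD)
# ---------------------------------------------------------------------------


def item_distribution_table(
    records: Sequence[ResponseRecord], spec: InstrumentSpec
) -> pd.DataFrame:
    """Per-item distribution of responses over displayed categories.

    Display convention: 5-category items are shown on the scored 1-5 scale
    (i.e. after reverse coding, so a higher displayed code is better
    health); the 11-point pain item is shown on its raw 0-10 scale, worst
    first.  Mean and SD are of the displayed codes over non-missing
    responses.
    """
    if not records:
        raise PopRefError("empty record collection")
    rows = []
    for item_id in spec.item_order:
        item = spec.items[item_id]
        if len(item.raw_scale) > 5:
            display_values = tuple(sorted(item.raw_scale, reverse=True))
            codes = [
                r.raw_responses[item_id]
                for r in records
                if r.raw_responses.get(item_id) is not None
            ]
        else:
            display_values = (1, 2, 3, 4, 5)
            codes = [
                recode_response(item, r.raw_responses[item_id])
                for r in records
                if r.raw_responses.get(item_id) is not None
            ]
        codes_arr = np.asarray(codes, dtype=float)
        n = codes_arr.size
        pcts = tuple(
            100.0 * float(np.sum(codes_arr == v)) / n if n else np.nan
            for v in display_values
        )
        rows.append(
            {
                "item_id": item_id,
                "display_values": display_values,
                "percentages": pcts,
                "n": n,
                "mean": float(codes_arr.mean()) if n else np.nan,
                "sd": float(codes_arr.std()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("item_id")


def mean_from_distribution(
    percentages: Sequence[float], values: Sequence[float]
) -> float:
    """Weighted mean of category values from percentage weights.

    Reported to 1 decimal, rounded half-up — the printing convention of
    distribution tables.  Percentages must be non-negative and sum to 100
    within printed-rounding slack (0.5).
    """
    p = np.asarray(percentages, dtype=float)
    v = np.asarray(values, dtype=float)
    if p.shape != v.shape:
        raise PopRefError(
            f"{p.size} percentages but {v.size} category values"
        )
    if np.any(p < 0):
        raise PopRefError("negative percentage")
    if abs(p.sum() - 100.0) > 0.5:
        raise PopRefError(f"percentages sum to {p.sum():.2f}, not 100")
    return round_half_up(float(p @ v) / 100.0, 1)


def sd_from_distribution(
    percentages: Sequence[float], values: Sequence[float]
) -> float:
    """Population SD of category values from percentage weights (1 dp)."""
    p = np.asarray(percentages, dtype=float) / 100.0
    v = np.asarray(values, dtype=float)
    p = p / p.sum()
    mean = float(p @ v)
    return round_half_up(float(np.sqrt(p @ (v - mean) ** 2)), 1)


# ---------------------------------------------------------------------------
# Subgroup reference tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceTable:
    """Per-subgroup n / mean T / SD for each subscale.

    ``data`` is long form with columns ``subgroup, subscale, n, mean_t,
    sd_t``; gender rows and age-band rows each partition the total row
    (respondents with unknown gender land in an extra ``unknown`` row that
    is reported but excluded from partition checks).
    """

    data: pd.DataFrame

    def row(self, subgroup: str, subscale: str) -> pd.Series:
        m = self.data[
            (self.data["subgroup"] == subgroup) & (self.data["subscale"] == subscale)
        ]
        if m.empty:
            raise PopRefError(f"no row for {subgroup!r} x {subscale!r}")
        return m.iloc[0]

    def means(self, subscale: str) -> pd.Series:
        sub = self.data[self.data["subscale"] == subscale]
        return sub.set_index("subgroup")["mean_t"]

    def wide(self, decimals: int = 1) -> pd.DataFrame:
        """Render as subgroup rows x (n, per-subscale mean (SD)) columns."""
        out = {}
        sub0 = self.data[self.data["subscale"] == self.data["subscale"].iloc[0]]
        out["n"] = sub0.set_index("subgroup")["n"]
        for subscale in self.data["subscale"].unique():
            sub = self.data[self.data["subscale"] == subscale].set_index("subgroup")
            out[subscale] = sub.apply(
                lambda r: f"{round_half_up(r['mean_t'], decimals):.{decimals}f} "
                f"({round_half_up(r['sd_t'], decimals):.{decimals}f})"
                if r["n"] > 0
                else "-",
                axis=1,
            )
        order = [g for g in SUBGROUP_ORDER if g in set(sub0["subgroup"])]
        extra = [g for g in sub0["subgroup"] if g not in SUBGROUP_ORDER]
        return pd.DataFrame(out).loc[order + extra]

    def partition_check(self) -> bool:
        """Gender n's and age-band n's must each sum to the total n."""
        sub = self.data[self.data["subscale"] == self.data["subscale"].iloc[0]]
        n = sub.set_index("subgroup")["n"]
        total = n.get("total", 0)
        genders = [g for g in ("male", "female") if g in n.index]
        ages = [a for *_, a in REFERENCE_AGE_BANDS if a in n.index]
        unknown = n.get("unknown", 0)
        return (
            n[genders].sum() + unknown == total and n[ages].sum() == total
        )


def subgroup_reference_table(
    tscores: pd.DataFrame, records: Sequence[ResponseRecord]
) -> ReferenceTable:
    """Build the reference table from per-respondent T-scores.

    ``tscores`` is wide: indexed by respondent id, one column per subscale.
    Rows: total, male, female, the six age bands (plus ``unknown`` if any
    respondent lacks a gender).  Means and SDs are unweighted; an empty
    subgroup yields n = 0 and NaN statistics.
    """
    rec_by_id = {r.respondent_id: r for r in records}
    missing = [rid for rid in tscores.index if rid not in rec_by_id]
    if missing:
        raise PopRefError(f"scored respondents absent from records: {missing[:5]}")
    demo = pd.DataFrame(
        {
            "gender": [rec_by_id[rid].gender for rid in tscores.index],
            "age_band": [reference_age_band(rec_by_id[rid].age) for rid in tscores.index],
        },
        index=tscores.index,
    )
    groups: list[tuple[str, pd.Index]] = [("total", tscores.index)]
    for g in ("male", "female"):
        groups.append((g, demo.index[demo["gender"] == g]))
    unknown_idx = demo.index[~demo["gender"].isin(["male", "female"])]
    if len(unknown_idx):
        groups.append(("unknown", unknown_idx))
    for *_, label in REFERENCE_AGE_BANDS:
        groups.append((label, demo.index[demo["age_band"] == label]))

    rows = []
    for label, idx in groups:
        for subscale in tscores.columns:
            vals = tscores.loc[idx, subscale].dropna()
            rows.append(
                {
                    "subgroup": label,
                    "subscale": subscale,
                    "n": int(len(idx)),
                    "mean_t": float(vals.mean()) if len(vals) else np.nan,
                    "sd_t": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "flagged_empty": len(vals) == 0,
                }
            )
    return ReferenceTable(data=pd.DataFrame(rows))


@dataclass(frozen=True)
class ComparisonResult:
    """A subgroup mean against a fixed reference constant."""

    subgroup: str
    subscale: str
    sample_mean: float
    reference_mean: float
    difference: float
    ci_low: float
    ci_high: float


def compare_to_reference(
    mean: float,
    sd: float,
    n: int,
    reference_mean: float,
    subgroup: str = "total",
    subscale: str = "",
) -> ComparisonResult:
    """Difference of a sample mean T from a fixed reference mean.

    The 95% CI is one-sample normal (difference +/- 1.96 sd / sqrt(n));
    the reference mean is treated as a known constant.
    """
    if n < 2:
        raise PopRefError("need n >= 2 for a comparison")
    if sd <= 0:
        raise PopRefError("need sd > 0")
    diff = mean - reference_mean
    half = 1.96 * sd / np.sqrt(n)
    return ComparisonResult(
        subgroup=subgroup,
        subscale=subscale,
        sample_mean=mean,
        reference_mean=reference_mean,
        difference=diff,
        ci_low=diff - half,
        ci_high=diff + half,
    )


def subscale_gap_table(
    table: ReferenceTable, pair: tuple[str, str], rounded_input: bool = True
) -> pd.DataFrame:
    """Absolute per-subgroup gap between a long subscale and its short form.

    With ``rounded_input`` the means are first rounded to 1 decimal (so a
    printed table reproduces its published gaps exactly); otherwise the
    unrounded means are compared.  Returns one row per subgroup with the
    gap; the maximum sits in ``.attrs['max_gap']`` / ``.attrs['argmax']``.
    """
    long_id, short_id = pair
    for sid in pair:
        if not (table.data["subscale"] == sid).any():
            raise PopRefError(f"subscale {sid!r} missing from table")
    long_means = table.means(long_id)
    short_means = table.means(short_id)
    if rounded_input:
        long_means = long_means.map(lambda x: round_half_up(x, 1))
        short_means = short_means.map(lambda x: round_half_up(x, 1))
    gaps = (long_means - short_means).abs().rename("gap")
    out = gaps.reset_index()
    valid = gaps.dropna()
    out.attrs["max_gap"] = float(valid.max()) if len(valid) else np.nan
    out.attrs["argmax"] = str(valid.idxmax()) if len(valid) else ""
    return out


# ---------------------------------------------------------------------------
# Shipped published tables
# ---------------------------------------------------------------------------


def load_printed_distributions() -> pd.DataFrame:
    """The published Dutch item-distribution table (percentages, mean, SD)."""
    with resources.as_file(
        resources.files("promisgh.data").joinpath("item_distributions_printed.csv")
    ) as path:
        df = pd.read_csv(path, comment="#")
    df["display_values"] = df["display_values"].map(
        lambda s: tuple(int(x) for x in s.split("|"))
    )
    df["percentages"] = df["percentages"].map(
        lambda s: tuple(float(x) for x in s.split("|"))
    )
    return df.set_index("item_id")


def load_printed_reference_table() -> ReferenceTable:
    """The published Dutch reference values as a :class:`ReferenceTable`."""
    df = _load_reference_csv()
    col_map = {
        "GMH": ("gmh_mean", "gmh_sd"),
        "GMH-2a": ("gmh2a_mean", "gmh2a_sd"),
        "GPH": ("gph_mean", "gph_sd"),
        "GPH-2a": ("gph2a_mean", "gph2a_sd"),
    }
    rows = []
    for _, r in df.iterrows():
        for subscale, (mcol, scol) in col_map.items():
            rows.append(
                {
                    "subgroup": r["subgroup"],
                    "subscale": subscale,
                    "n": int(r["nl_n"]),
                    "mean_t": float(r[mcol]),
                    "sd_t": float(r[scol]),
                    "flagged_empty": False,
                }
            )
    return ReferenceTable(data=pd.DataFrame(rows))


def load_us_reference() -> pd.DataFrame:
    """US reference constants (n, mean, SD per subgroup for GMH/GPH)."""
    df = _load_reference_csv()
    return df.set_index("subgroup")[
        ["us_gmh_n", "us_gmh_mean", "us_gmh_sd", "us_gph_n", "us_gph_mean", "us_gph_sd"]
    ]


def _load_reference_csv() -> pd.DataFrame:
    with resources.as_file(
        resources.files("promisgh.data").joinpath("reference_values_printed.csv")
    ) as path:
        return pd.read_csv(path, comment="#")
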