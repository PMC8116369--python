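"""End-to-end scoring and reporting pipeline.

Chains the modules: read/validate responses -> recode -> score every
subscale -> subgroup reference table -> anchor-based thresholds ->
representativeness report, and writes a deterministic bundle of CSV
tables plus a run log.  All content is computed before anything is
written, so a failing run leaves no partial bundle behind.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from promisgh import __version__
from promisgh.formatting import round_half_up
from promisgh.grm import (
    ItemParameters,
    QuadratureGrid,
    default_grid,
    load_default_parameters,
    load_item_parameters,
    score_population,
    summed_score_table,
)
from promisgh.instrument import (
    InstrumentSpec,
    ResponseRecord,
    load_default_instrument,
    recode_response,
    subscale_responses,
)
from promisgh.io import read_responses
from promisgh.popref import (
    SUBSCALES,
    ReferenceTable,
    item_distribution_table,
    subgroup_reference_table,
)
from promisgh.representativeness import (
    DEFAULT_CRITERION,
    load_default_margins,
    load_margins,
    margin_deviation_report,
)
from promisgh.thresholds import derive_bands


class PipelineError(ValueError):
    pass


def response_matrix(
    records: Sequence[ResponseRecord], spec: InstrumentSpec, subscale_id: str
) -> np.ndarray:
    """(n, J) matrix of scored categories for one subscale; 0 = missing."""
    rows = []
    for r in records:
        scored = subscale_responses(r, spec, subscale_id)
        rows.append([0 if s is None else s for s in scored])
    return np.asarray(rows, dtype=int)


def score_records(
    records: Sequence[ResponseRecord],
    spec: Optional[InstrumentSpec] = None,
    params: Optional[Mapping[str, ItemParameters]] = None,
    grid: Optional[QuadratureGrid] = None,
    method: str = "pattern",
    subscales: Sequence[str] = SUBSCALES,
) -> pd.DataFrame:
    """Score every subscale for every respondent.

    Returns a frame indexed by respondent id with, per subscale, columns
    ``<id>`` (T-score), ``<id>_se`` and ``<id>_n_items``.  The ``pattern``
    method is response-pattern EAP and handles missing items; the
    ``sum-table`` method converts raw sums through the Lord-Wingersky
    conversion table and is only valid when all subscale items are
    complete.
    """
    spec = spec or load_default_instrument()
    params = params or load_default_parameters()
    grid = grid or default_grid()
    if method not in ("pattern", "sum-table"):
        raise PipelineError(f"unknown scoring method {method!r}")
    out: dict[str, np.ndarray] = {}
    for subscale_id in subscales:
        item_ids = spec.subscale_items(subscale_id)
        items = [params[i] for i in item_ids]
        matrix = response_matrix(records, spec, subscale_id)
        if method == "pattern":
            theta, se, n_items = score_population(matrix, items, grid)
            t = 50.0 + 10.0 * theta
            se_t = 10.0 * se
        else:
            if np.any(matrix == 0):
                n_bad = int((matrix == 0).any(axis=1).sum())
                raise PipelineError(
                    f"sum-table scoring requires complete responses; "
                    f"{n_bad} respondent(s) miss {subscale_id} items"
                )
            table = summed_score_table(items, grid, subscale_id=subscale_id)
            sums = matrix.sum(axis=1)
            looked = np.array([table.lookup(int(s)) for s in sums])
            t, se_t = looked[:, 0], looked[:, 1]
            n_items = np.full(len(records), len(items))
        out[subscale_id] = t
        out[f"{subscale_id}_se"] = se_t
        out[f"{subscale_id}_n_items"] = n_items
    return pd.DataFrame(out, index=pd.Index([r.respondent_id for r in records], name="respondent_id"))


def anchor_codes(
    records: Sequence[ResponseRecord], spec: Optional[InstrumentSpec] = None
) -> pd.Series:
    """Scored anchor-item categories (1..5; NaN when missing)."""
    spec = spec or load_default_instrument()
    item = spec.items[spec.anchor_item]
    vals = [
        np.nan if r.raw_responses.get(spec.anchor_item) is None
        else recode_response(item, r.raw_responses[spec.anchor_item])
        for r in records
    ]
    return pd.Series(vals, index=[r.respondent_id for r in records], name="anchor")


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and policies for a full pipeline run."""

    responses_path: str
    out_dir: str
    params_path: Optional[str] = None
    margins_path: Optional[str] = None
    scoring_method: str = "pattern"
    criterion: float = DEFAULT_CRITERION
    threshold_subscales: tuple[str, ...] = ("GMH", "GPH")

    def digest(self) -> str:
        # analytic settings only: where the bundle lands must not change it
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns the in-memory bundle: scores frame, reference table, threshold
    bands, representativeness report and the log lines.
    """
    spec = load_default_instrument()
    params = (
        load_item_parameters(config.params_path)
        if config.params_path
        else load_default_parameters()
    )
    if config.margins_path:
        margins, _ = load_margins(config.margins_path)
    else:
        margins, _ = load_default_margins()

    records = read_responses(config.responses_path, spec)
    log = [
        f"promisgh {__version__}",
        f"config digest {config.digest()}",
        f"records read: {len(records)}",
        f"scoring method: {config.scoring_method}",
    ]

    scores = score_records(records, spec, params, method=config.scoring_method)
    n_flagged = int((scores[[f"{s}_n_items" for s in SUBSCALES]] == 0).any(axis=1).sum())
    if n_flagged:
        log.append(f"warning: {n_flagged} respondent(s) with zero answered subscale items")

    tmat = scores[list(SUBSCALES)]
    ref_table = subgroup_reference_table(tmat, records)
    dist_table = item_distribution_table(records, spec)

    anchors = anchor_codes(records, spec)
    bands = {}
    for subscale_id in config.threshold_subscales:
        mask = anchors.notna()
        b, cuts, summary = derive_bands(
            tmat.loc[mask.values, subscale_id].to_numpy(),
            anchors[mask].astype(int).to_numpy(),
            subscale_id=subscale_id,
        )
        bands[subscale_id] = b
        for w in cuts.warnings:
            log.append(f"warning: {subscale_id}: {w}")
        for cat in summary.empty_categories:
            log.append(f"warning: {subscale_id}: empty anchor category {cat!r}")

    rep = margin_deviation_report(records, margins, criterion=config.criterion)
    log.append(
        f"representativeness: max deviation {rep.max_deviation:.2f} "
        f"({rep.max_category}); criterion {rep.criterion}; "
        f"{'PASS' if rep.passed else 'FAIL'}"
    )

    conv_tables = {
        s: summed_score_table([params[i] for i in spec.subscale_items(s)], subscale_id=s)
        for s in SUBSCALES
    }

    _write_bundle(
        Path(config.out_dir),
        scores,
        ref_table,
        dist_table,
        bands,
        rep,
        conv_tables,
        log,
    )
    return {
        "records": records,
        "scores": scores,
        "reference_table": ref_table,
        "distribution_table": dist_table,
        "bands": bands,
        "representativeness": rep,
        "log": log,
    }


def _write_bundle(
    out_dir: Path,
    scores: pd.DataFrame,
    ref_table: ReferenceTable,
    dist_table: pd.DataFrame,
    bands: Mapping[str, object],
    rep,
    conv_tables: Mapping[str, object],
    log: list[str],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    reported = scores.copy()
    for s in SUBSCALES:
        reported[s] = reported[s].map(lambda x: round_half_up(x, 1))
        reported[f"{s}_se"] = reported[f"{s}_se"].map(lambda x: round_half_up(x, 1))
    reported.to_csv(out_dir / "scores.csv")
    ref_table.data.to_csv(out_dir / "reference_table.csv", index=False)
    ref_table.wide().to_csv(out_dir / "reference_table_wide.csv")
    flat = dist_table.copy()
    flat["display_values"] = flat["display_values"].map(lambda v: "|".join(map(str, v)))
    flat["percentages"] = flat["percentages"].map(
        lambda v: "|".join(f"{round_half_up(x, 1):.1f}" for x in v)
    )
    flat.to_csv(out_dir / "item_distributions.csv")
    rows = []
    for subscale_id, b in bands.items():
        for label, rng_str in b.band_ranges():
            rows.append({"subscale": subscale_id, "band": label, "range": rng_str})
    pd.DataFrame(rows).to_csv(out_dir / "thresholds.csv", index=False)
    rep.table.to_csv(out_dir / "representativeness.csv", index=False)
    for s, table in conv_tables.items():
        table.to_dataframe().to_csv(out_dir / f"conversion_{s}.csv", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    summary = {
        "n_records": int(len(scores)),
        "max_deviation": rep.max_deviation,
        "representative": bool(rep.passed),
        "thresholds": {s: list(b.thresholds) for s, b in bands.items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
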