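"""The PROMIS Global Health instrument: items, recoding and subscales.

The 10-item instrument measures global mental health (GMH subscale:
Global02, Global04, Global05, Global10) and global physical health (GPH
subscale: Global03, Global06, Global07, Global08), plus two 2-item short
forms (GMH-2a: Global04/Global05; GPH-2a: Global03/Global06).  Global01
(general self-rated health) and Global09 stand alone; Global01 doubles as
the anchor item for interpretability thresholds.

Items are stored in the raw direction of administration.  Two items run in
the reverse direction (more fatigue / more frequent emotional problems =
higher raw code) and are reverse coded when scoring; the pain item is
administered on a 0-10 numerical scale and banded onto the 1-5 scored
scale.  After recoding, a higher scored category always means better
health.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

ITEM_IDS = tuple(f"Global{i:02d}" for i in range(1, 11))
SUBSCALE_IDS = ("GMH", "GMH-2a", "GPH", "GPH-2a")


class InstrumentError(ValueError):
    """Raised for responses or definitions that violate the instrument."""


@dataclass(frozen=True)
class ItemDefinition:
    """One item's raw response scale and its map onto scored categories 1-5.

    ``recode_map`` is total over ``raw_scale`` and monotone: non-increasing
    in the raw code for reverse-direction items, non-decreasing otherwise.
    """

    item_id: str
    raw_scale: tuple[int, ...]
    reverse_coded: bool = False
    recode_map: Mapping[int, int] = field(default_factory=dict)
    content: str = ""

    def __post_init__(self) -> None:
        if self.item_id not in ITEM_IDS:
            raise InstrumentError(f"unknown item id {self.item_id!r}")
        if not self.recode_map:
            n = len(self.raw_scale)
            if self.reverse_coded:
                mapping = {r: n + min(self.raw_scale) - r for r in self.raw_scale}
            else:
                mapping = {r: r for r in self.raw_scale}
            object.__setattr__(self, "recode_map", mapping)
        missing = set(self.raw_scale) - set(self.recode_map)
        if missing:
            raise InstrumentError(
                f"{self.item_id}: recode_map misses raw values {sorted(missing)}"
            )
        scored = [self.recode_map[r] for r in self.raw_scale]
        if not set(scored) <= set(range(1, 6)):
            raise InstrumentError(f"{self.item_id}: scored categories outside 1..5")
        if len(self.raw_scale) >= 5 and set(scored) != set(range(1, 6)):
            raise InstrumentError(f"{self.item_id}: recode_map not onto 1..5")
        steps = [b - a for a, b in zip(scored, scored[1:])]
        if self.reverse_coded:
            if any(s > 0 for s in steps):
                raise InstrumentError(f"{self.item_id}: reverse recode not monotone")
        elif any(s < 0 for s in steps):
            raise InstrumentError(f"{self.item_id}: recode not monotone")

    @property
    def n_scored_categories(self) -> int:
        return len(set(self.recode_map.values()))


@dataclass(frozen=True)
class InstrumentSpec:
    """The full instrument: ordered items, subscale membership, anchor."""

    items: Mapping[str, ItemDefinition]
    subscales: Mapping[str, tuple[str, ...]]
    anchor_item: str
    standalone_items: tuple[str, ...]
    item_order: tuple[str, ...] = ITEM_IDS
    version: str = "1.2"

    def __post_init__(self) -> None:
        if set(self.items) != set(self.item_order):
            raise InstrumentError("items do not match the declared item order")
        for sid in SUBSCALE_IDS:
            if sid not in self.subscales:
                raise InstrumentError(f"missing subscale {sid!r}")
        gmh, gph = set(self.subscales["GMH"]), set(self.subscales["GPH"])
        if not set(self.subscales["GMH-2a"]) <= gmh:
            raise InstrumentError("GMH-2a is not a subset of GMH")
        if not set(self.subscales["GPH-2a"]) <= gph:
            raise InstrumentError("GPH-2a is not a subset of GPH")
        if gmh & gph:
            raise InstrumentError("GMH and GPH share items")
        scale_members = gmh | gph
        for sid in self.standalone_items:
            if sid in scale_members:
                raise InstrumentError(f"standalone item {sid} belongs to a subscale")

    def subscale_items(self, subscale_id: str) -> tuple[str, ...]:
        """Member item ids of ``subscale_id`` in fixed instrument order."""
        if subscale_id not in self.subscales:
            raise InstrumentError(
                f"unknown subscale {subscale_id!r}; expected one of {SUBSCALE_IDS}"
            )
        members = set(self.subscales[subscale_id])
        return tuple(i for i in self.item_order if i in members)


@dataclass(frozen=True)
class ResponseRecord:
    """A respondent: demographics plus raw item responses (None = missing)."""

    respondent_id: str
    age: int
    gender: Optional[str]
    education: Optional[str]
    region: Optional[str]
    ethnicity: Optional[str]
    raw_responses: Mapping[str, Optional[int]]

    def __post_init__(self) -> None:
        if self.age < 18:
            raise InstrumentError(
                f"respondent {self.respondent_id}: age {self.age} below 18"
            )

    def validate_against(self, spec: InstrumentSpec) -> None:
        for item_id, raw in self.raw_responses.items():
            if item_id not in spec.items:
                raise InstrumentError(
                    f"respondent {self.respondent_id}: unknown item {item_id!r}"
                )
            if raw is not None and raw not in spec.items[item_id].raw_scale:
                raise InstrumentError(
                    f"respondent {self.respondent_id}: value {raw} outside "
                    f"{item_id}'s scale {list(spec.items[item_id].raw_scale)}"
                )


def recode_response(item: ItemDefinition, raw: int) -> int:
    """Map a raw response code onto the scored 1-5 scale.

    After recoding, a higher scored category always means better health;
    reverse-direction items are flipped here and nowhere else.
    """
    if raw not in item.recode_map:
        raise InstrumentError(
            f"{item.item_id}: raw value {raw!r} outside scale "
            f"{list(item.raw_scale)}"
        )
    return item.recode_map[raw]


def subscale_responses(
    record: ResponseRecord, spec: InstrumentSpec, subscale_id: str
) -> tuple[Optional[int], ...]:
    """Recoded responses for exactly the subscale's member items.

    Entries follow the fixed instrument order; a missing raw response stays
    missing (``None``).  The returned length always equals the subscale's
    item count.
    """
    out: list[Optional[int]] = []
    for item_id in spec.subscale_items(subscale_id):
        raw = record.raw_responses.get(item_id)
        out.append(None if raw is None else recode_response(spec.items[item_id], raw))
    return tuple(out)


def load_instrument(path: str | Path) -> InstrumentSpec:
    """Read an instrument definition from a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return _instrument_from_config(cfg)


def load_default_instrument() -> InstrumentSpec:
    """The shipped PROMIS-GH v1.2 definition."""
    text = (
        resources.files("promisgh.data").joinpath("instrument_v1_2.yaml").read_text()
    )
    return _instrument_from_config(yaml.safe_load(text))


def _instrument_from_config(cfg: Mapping) -> InstrumentSpec:
    items = {}
    for item_id, entry in cfg["items"].items():
        recode = entry.get("recode_map") or {}
        items[item_id] = ItemDefinition(
            item_id=item_id,
            raw_scale=tuple(entry["raw_scale"]),
            reverse_coded=bool(entry.get("reverse_coded", False)),
            recode_map={int(k): int(v) for k, v in recode.items()},
            content=str(entry.get("content", "")),
        )
    return InstrumentSpec(
        items=items,
        subscales={k: tuple(v) for k, v in cfg["subscales"].items()},
        anchor_item=cfg["anchor_item"],
        standalone_items=tuple(cfg["standalone_items"]),
        item_order=tuple(cfg.get("item_order", ITEM_IDS)),
        version=str(cfg.get("version", "")),
    )
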