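"""Seeded synthetic populations with the structure the analysis assumes.

The generator emulates a general-population web panel answering the
PROMIS-GH: each respondent belongs to a gender x age-band stratum, carries
a bivariate-normal pair of latent traits (global mental health, global
physical health) whose means depend on the stratum, and answers each item
by sampling from its graded-response-model category probabilities at the
respondent's trait value.  The two standalone items load on a standardized
composite of both traits, which couples the anchor item to overall health.
Raw (un-recoded) response codes are written, reverse-direction items in
their administration direction, so generated data exercises the same
recoding path as real data.

All draws come from one seeded generator in a fixed order
(strata -> demographics -> latents -> items -> missingness masks), so a
seed fully determines the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from promisgh.grm import ItemParameters, category_probabilities, load_default_parameters
from promisgh.instrument import (
    InstrumentSpec,
    ResponseRecord,
    load_default_instrument,
)
from promisgh.popref import REFERENCE_AGE_BANDS


class SyntheticConfigError(ValueError):
    pass


#: Default stratum margins: the panel's gender split and the reference-table
#: age-band counts (fractions of n = 4370).
DEFAULT_GENDER_PROPS = {"male": 0.47, "female": 0.53}
DEFAULT_AGE_PROPS = {
    "18-34": 891 / 4370,
    "35-44": 753 / 4370,
    "45-54": 646 / 4370,
    "55-64": 918 / 4370,
    "65-74": 893 / 4370,
    "75+": 269 / 4370,
}

#: Published subgroup mean T-scores mapped onto the latent metric
#: ((T - 50) / 10); stratum means are built additively from these margins.
_GMH_T = {
    "total": 44.7,
    "male": 45.5,
    "female": 44.1,
    "18-34": 45.6,
    "35-44": 43.8,
    "45-54": 43.6,
    "55-64": 43.6,
    "65-74": 45.9,
    "75+": 47.3,
}
_GPH_T = {
    "total": 45.2,
    "male": 46.1,
    "female": 44.5,
    "18-34": 47.8,
    "35-44": 45.2,
    "45-54": 44.6,
    "55-64": 43.4,
    "65-74": 45.1,
    "75+": 44.9,
}

#: Other demographics are drawn independently from the panel margins.
DEFAULT_DEMOGRAPHIC_MARGINS: dict[str, dict[str, float]] = {
    "education": {"low": 0.29, "middle": 0.41, "high": 0.30},
    "region": {"north": 0.10, "east": 0.21, "south": 0.21, "west": 0.48},
    "ethnicity": {
        "native": 0.78,
        "western_immigrant": 0.12,
        "non_western_immigrant": 0.10,
    },
}

_AGE_RANGES = {label: (lo, hi if hi is not None else 93) for lo, hi, label in REFERENCE_AGE_BANDS}

#: Fraction of a band's respondents drawn from its lower half.  The 35-44
#: band is skewed young so that the population satisfies both banding
#: schemes at once: the reference-table band sizes and the coarser census
#: margins (about a third of adults aged 18-39).  The 65-74 band is skewed
#: young as well, emulating declining internet-panel coverage with age.
DEFAULT_AGE_YOUNG_FRACTION = {"35-44": 0.73, "65-74": 0.65}


def _default_strata() -> dict[tuple[str, str], dict]:
    """Gender x age-band cells: product proportions, additive latent means."""
    strata = {}
    for g, pg in DEFAULT_GENDER_PROPS.items():
        for a, pa in DEFAULT_AGE_PROPS.items():
            mu_gmh = (
                _GMH_T["total"] + (_GMH_T[g] - _GMH_T["total"]) + (_GMH_T[a] - _GMH_T["total"]) - 50.0
            ) / 10.0
            mu_gph = (
                _GPH_T["total"] + (_GPH_T[g] - _GPH_T["total"]) + (_GPH_T[a] - _GPH_T["total"]) - 50.0
            ) / 10.0
            strata[(g, a)] = {
                "proportion": pg * pa,
                "mu_gmh": mu_gmh,
                "mu_gph": mu_gph,
                "sd_gmh": 1.0,
                "sd_gph": 1.0,
            }
    return strata


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that determines a synthetic population.

    ``strata`` maps (gender, age-band) to a dict with ``proportion``,
    ``mu_gmh``, ``mu_gph``, ``sd_gmh``, ``sd_gph``.  ``anchor_weight`` is
    the mental-health weight w of the composite trait w*theta_GMH +
    (1-w)*theta_GPH driving the two standalone items (standardized to unit
    variance before use).  ``missingness`` is a per-item
    missing-completely-at-random rate; the default is 0 everywhere because
    the emulated survey did not allow skipping items.
    """

    n: int = 4370
    seed: int = 0
    strata: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=_default_strata
    )
    latent_correlation: float = 0.6
    anchor_weight: float = 0.5
    item_parameters: Optional[Mapping[str, ItemParameters]] = None
    missingness: Mapping[str, float] = field(default_factory=dict)
    demographic_margins: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_DEMOGRAPHIC_MARGINS
    )
    age_young_fraction: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_AGE_YOUNG_FRACTION
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SyntheticConfigError("n must be positive")
        props = [s["proportion"] for s in self.strata.values()]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise SyntheticConfigError("stratum proportions must sum to 1")
        if any(s["sd_gmh"] <= 0 or s["sd_gph"] <= 0 for s in self.strata.values()):
            raise SyntheticConfigError("stratum SDs must be positive")
        if not -1.0 < self.latent_correlation < 1.0:
            raise SyntheticConfigError("latent correlation must be in (-1, 1)")
        if not 0.0 <= self.anchor_weight <= 1.0:
            raise SyntheticConfigError("anchor weight must be in [0, 1]")
        if any(not 0.0 <= r < 1.0 for r in self.missingness.values()):
            raise SyntheticConfigError("missingness rates must be in [0, 1)")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _draw_category(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of 1-based categories; probs is (n, K), u is (n,)."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    return 1 + (u[:, None] > cum).sum(axis=1)


def generate_population(
    config: Optional[SyntheticConfig] = None,
    spec: Optional[InstrumentSpec] = None,
) -> tuple[list[ResponseRecord], pd.DataFrame]:
    """Draw a synthetic population; returns (records, truth table).

    The truth table holds each respondent's stratum and true latent traits
    for recovery tests; real analyses never see it.
    """
    config = config or SyntheticConfig()
    spec = spec or load_default_instrument()
    params = dict(config.item_parameters or load_default_parameters())
    for item_id in spec.item_order:
        if item_id not in params:
            raise SyntheticConfigError(f"no item parameters for {item_id}")
    rng = np.random.default_rng(config.seed)
    n = config.n

    # 1. strata
    keys = list(config.strata.keys())
    props = np.array([config.strata[k]["proportion"] for k in keys], dtype=float)
    props = props / props.sum()
    stratum_idx = rng.choice(len(keys), size=n, p=props)
    genders = np.array([keys[i][0] for i in stratum_idx])
    bands = np.array([keys[i][1] for i in stratum_idx])
    ages = np.empty(n, dtype=int)
    for label, (lo, hi) in _AGE_RANGES.items():
        sel = bands == label
        if not sel.any():
            continue
        m = int(sel.sum())
        frac = config.age_young_fraction.get(label)
        if frac is None:
            ages[sel] = rng.integers(lo, hi + 1, size=m)
        else:
            mid = (lo + hi) // 2
            young = rng.random(m) < frac
            drawn = np.where(
                young,
                rng.integers(lo, mid + 1, size=m),
                rng.integers(mid + 1, hi + 1, size=m),
            )
            ages[sel] = drawn

    # 2. other demographics, independent of strata
    demo: dict[str, np.ndarray] = {}
    for var, margins in config.demographic_margins.items():
        cats = list(margins.keys())
        p = np.array([margins[c] for c in cats], dtype=float)
        demo[var] = np.array(cats)[rng.choice(len(cats), size=n, p=p / p.sum())]

    # 3. latent traits: bivariate normal per stratum
    rho = config.latent_correlation
    z = rng.standard_normal((n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    mu_g = np.array([config.strata[keys[i]]["mu_gmh"] for i in stratum_idx])
    mu_p = np.array([config.strata[keys[i]]["mu_gph"] for i in stratum_idx])
    sd_g = np.array([config.strata[keys[i]]["sd_gmh"] for i in stratum_idx])
    sd_p = np.array([config.strata[keys[i]]["sd_gph"] for i in stratum_idx])
    theta_gmh = mu_g + sd_g * z[:, 0]
    theta_gph = mu_p + sd_p * z[:, 1]

    w = config.anchor_weight
    comp_scale = np.sqrt(w**2 + (1 - w) ** 2 + 2 * w * (1 - w) * rho)
    theta_comp = (w * theta_gmh + (1 - w) * theta_gph) / comp_scale

    gmh_items = set(spec.subscales["GMH"])
    gph_items = set(spec.subscales["GPH"])

    # 4. item responses, instrument order; scored category then raw code
    raw_by_item: dict[str, np.ndarray] = {}
    for item_id in spec.item_order:
        if item_id in gmh_items:
            trait = theta_gmh
        elif item_id in gph_items:
            trait = theta_gph
        else:
            trait = theta_comp
        probs = category_probabilities(params[item_id], trait)
        scored = _draw_category(probs, rng.random(n))
        item = spec.items[item_id]
        # invert the recode map; a non-injective map (the banded pain item)
        # gets a uniform draw among the raw codes of the scored band
        inverse: dict[int, list[int]] = {}
        for r in item.raw_scale:
            inverse.setdefault(item.recode_map[r], []).append(r)
        raw = np.empty(n, dtype=int)
        for cat, raws in inverse.items():
            sel = scored == cat
            if not sel.any():
                continue
            if len(raws) == 1:
                raw[sel] = raws[0]
            else:
                raw[sel] = rng.choice(raws, size=int(sel.sum()))
        raw_by_item[item_id] = raw

    # 5. missingness masks
    masks: dict[str, np.ndarray] = {}
    for item_id in spec.item_order:
        rate = float(config.missingness.get(item_id, 0.0))
        masks[item_id] = rng.random(n) < rate if rate > 0 else np.zeros(n, dtype=bool)

    width = len(str(n))
    records = []
    for i in range(n):
        responses = {
            item_id: (None if masks[item_id][i] else int(raw_by_item[item_id][i]))
            for item_id in spec.item_order
        }
        records.append(
            ResponseRecord(
                respondent_id=f"R{i + 1:0{width}d}",
                age=int(ages[i]),
                gender=str(genders[i]),
                education=str(demo["education"][i]),
                region=str(demo["region"][i]),
                ethnicity=str(demo["ethnicity"][i]),
                raw_responses=responses,
            )
        )
    truth = pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in records],
            "theta_gmh": theta_gmh,
            "theta_gph": theta_gph,
            "gender": genders,
            "age_band": bands,
        }
    )
    return records, truth


def implied_category_frequencies(
    items: Sequence[ItemParameters],
    trait_mean: float = 0.0,
    trait_sd: float = 1.0,
    n_quad: int = 61,
) -> pd.DataFrame:
    """Expected per-category percentages under a normal trait distribution.

    Gauss-Hermite integration of the GRM category probabilities over
    theta ~ N(mean, sd^2); the closed-form counterpart of simulating a very
    large population, used to validate the generator.
    """
    x, w = np.polynomial.hermite_e.hermegauss(n_quad)
    nodes = trait_mean + trait_sd * x
    weights = w / w.sum()
    rows = []
    for item in items:
        probs = category_probabilities(item, nodes)  # (Q, K)
        freq = 100.0 * (weights @ probs)
        rows.append({"item_id": item.item_id, **{f"cat{k + 1}": freq[k] for k in range(len(freq))}})
    return pd.DataFrame(rows).set_index("item_id")
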