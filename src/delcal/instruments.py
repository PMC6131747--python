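"""Instrument definitions, response validation, scoring, and anchor maps.

An *instrument* is an ordered set of rated items, each with a number of
ordered response categories and a dichotomization cut. The unit of analysis
is the assessment: one (person, day) pair rated on one instrument. Items
carry a ``domain`` label describing the delirium sign or symptom they rate;
domains are the join key used to pair anchor items across instruments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Item",
    "InstrumentSpec",
    "ResponseTable",
    "AnchorMap",
    "AnchorMaps",
    "ConfigurationError",
    "ValidationError",
    "DEFAULT_MISSING_CODES",
    "CONCEPT_MAP",
    "concept",
    "load_instrument_spec",
    "load_bundled_specs",
    "recode_missing",
    "sum_score",
    "dichotomize",
    "build_anchor_maps",
    "shared_items",
]


class ConfigurationError(ValueError):
    """An instrument or anchor configuration is internally inconsistent."""


class ValidationError(ValueError):
    """Response data violate the instrument's category structure."""


#: Raw codes treated as missing when recoding response tables.
DEFAULT_MISSING_CODES = frozenset({"", "NA", "uncertain", "refused", "dont_know"})

#: Domains collapsed to a single shared concept. Psychomotor disturbance is
#: rated as separate agitation/retardation items on the DRS-R-98 and CAM-S
#: but as a single activity item on the MDAS; at the concept level all three
#: describe the same symptom family.
CONCEPT_MAP = {
    "psychomotor_agitation": "psychomotor",
    "psychomotor_retardation": "psychomotor",
    "psychomotor_activity": "psychomotor",
}


def concept(domain: str) -> str:
    """Collapse a fine-grained domain label to its shared concept."""
    return CONCEPT_MAP.get(domain, domain)


@dataclass(frozen=True)
class Item:
    item_id: str
    domain: str
    n_categories: int
    dichotomization_cut: int = 1

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ConfigurationError(
                f"item {self.item_id!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )
        if not 1 <= self.dichotomization_cut <= self.n_categories - 1:
            raise ConfigurationError(
                f"item {self.item_id!r}: dichotomization cut "
                f"{self.dichotomization_cut} outside [1, {self.n_categories - 1}]"
            )


@dataclass(frozen=True)
class InstrumentSpec:
    """An instrument's items and derived score range.

    ``max_score`` is always computed as sum(n_categories - 1) over items,
    never trusted from a file.
    """

    name: str
    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"{self.name}: duplicate item ids")
        if not self.items:
            raise ConfigurationError(f"{self.name}: no items")

    @property
    def max_score(self) -> int:
        return sum(it.n_categories - 1 for it in self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def domains(self) -> list[str]:
        return [it.domain for it in self.items]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"{self.name}: no item {item_id!r}")

    def items_for_domain(self, domain: str) -> list[Item]:
        return [it for it in self.items if it.domain == domain]

    def dichotomized(self) -> "InstrumentSpec":
        """The binary (2-category) version of this instrument."""
        return InstrumentSpec(
            name=self.name,
            items=tuple(
                Item(it.item_id, it.domain, 2, 1) for it in self.items
            ),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [
                {
                    "id": it.item_id,
                    "domain": it.domain,
                    "categories": it.n_categories,
                    "cut": it.dichotomization_cut,
                }
                for it in self.items
            ],
        }


def _spec_from_dict(raw: Mapping, source: str) -> InstrumentSpec:
    for key in ("name", "items"):
        if key not in raw:
            raise ConfigurationError(f"{source}: missing field {key!r}")
    items = []
    for i, entry in enumerate(raw["items"]):
        for key in ("id", "domain", "categories"):
            if key not in entry:
                raise ConfigurationError(
                    f"{source}: item {i} missing field {key!r}"
                )
        items.append(
            Item(
                item_id=str(entry["id"]),
                domain=str(entry["domain"]),
                n_categories=int(entry["categories"]),
                dichotomization_cut=int(entry.get("cut", 1)),
            )
        )
    return InstrumentSpec(name=str(raw["name"]), items=tuple(items))


def load_instrument_spec(path: str | Path) -> InstrumentSpec:
    """Load and validate an instrument definition from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return _spec_from_dict(raw, str(path))


_BUNDLED = {
    "DRS-R-98": "drs_r98.yaml",
    "MDAS": "mdas.yaml",
    "CAM-S-long": "cams_long.yaml",
    "CAM-S-short": "cams_short.yaml",
}


def load_bundled_specs(names: Sequence[str] | None = None) -> dict[str, InstrumentSpec]:
    """Load the bundled DRS-R-98 / MDAS / CAM-S instrument definitions."""
    names = list(names) if names is not None else list(_BUNDLED)
    out: dict[str, InstrumentSpec] = {}
    for name in names:
        fname = _BUNDLED[name]
        ref = resources.files("delcal.configs").joinpath(fname)
        raw = yaml.safe_load(ref.read_text())
        out[name] = _spec_from_dict(raw, fname)
    return out


@dataclass
class ResponseTable:
    """Person-day x item integer ratings for one instrument.

    ``data`` is a wide DataFrame with columns ``person_id``, ``day`` and one
    float column per item; missing ratings are NaN.
    """

    instrument: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("person_id", "day"):
            if col not in self.data.columns:
                raise ValidationError(f"response table missing column {col!r}")
        dup = self.data.duplicated(subset=["person_id", "day"])
        if dup.any():
            raise ValidationError(
                f"{self.instrument}: duplicate (person_id, day) assessments: "
                f"{self.data.loc[dup, ['person_id', 'day']].values.tolist()[:5]}"
            )

    @property
    def item_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("person_id", "day")]

    @property
    def n_assessments(self) -> int:
        return len(self.data)

    def validate(self, spec: InstrumentSpec) -> "ResponseTable":
        """Check every non-missing rating against the spec's category ranges."""
        missing_cols = set(spec.item_ids) - set(self.data.columns)
        if missing_cols:
            raise ValidationError(
                f"{self.instrument}: missing item columns {sorted(missing_cols)}"
            )
        for it in spec.items:
            vals = self.data[it.item_id]
            ok = vals.isna() | (
                (vals >= 0) & (vals <= it.n_categories - 1) & (vals % 1 == 0)
            )
            if not ok.all():
                bad = self.data.loc[~ok, ["person_id", "day", it.item_id]]
                raise ValidationError(
                    f"{self.instrument}: out-of-range ratings for item "
                    f"{it.item_id!r}:\n{bad.head().to_string(index=False)}"
                )
        return self

    def responses(self, item_ids: Sequence[str]) -> np.ndarray:
        """Integer response matrix (n_assessments, n_items); -1 marks missing."""
        arr = self.data[list(item_ids)].to_numpy(dtype=float)
        out = np.where(np.isnan(arr), -1, arr).astype(np.int64)
        return out


def recode_missing(
    raw: pd.DataFrame,
    spec: InstrumentSpec,
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
) -> ResponseTable:
    """Turn a raw wide table with string/integer codes into a ResponseTable.

    Codes listed in ``missing_codes`` (matched case-insensitively after
    stripping whitespace) become NaN; every remaining code must parse to a
    valid category integer for its item.
    """
    codes = {str(c).strip().lower() for c in missing_codes}
    out = raw[["person_id", "day"]].copy()
    for it in spec.items:
        if it.item_id not in raw.columns:
            raise ValidationError(f"raw table missing item column {it.item_id!r}")
        col = raw[it.item_id]

        def _recode(v, item=it):
            if pd.isna(v):
                return np.nan
            s = str(v).strip()
            if s.lower() in codes:
                return np.nan
            try:
                x = float(s)
            except ValueError:
                raise ValidationError(
                    f"item {item.item_id!r}: unrecognized code {v!r}"
                ) from None
            return x

        out[it.item_id] = col.map(_recode).astype(float)
    table = ResponseTable(instrument=spec.name, data=out)
    return table.validate(spec)


def sum_score(
    table: ResponseTable, spec: InstrumentSpec, prorate: bool = False
) -> pd.Series:
    """Per-assessment total score.

    By default the total is missing whenever any item is missing (severity is
    never silently understated). With ``prorate=True`` an assessment with at
    least one observed item gets round(mean observed item score x n_items).
    """
    table.validate(spec)
    vals = table.data[spec.item_ids]
    total = vals.sum(axis=1, min_count=len(spec.items))
    if prorate:
        prorated = (vals.mean(axis=1) * len(spec.items)).round()
        total = total.fillna(prorated)
    total.index = pd.MultiIndex.from_frame(table.data[["person_id", "day"]])
    return total.rename(f"{spec.name}_total")


def dichotomize(table: ResponseTable, spec: InstrumentSpec) -> ResponseTable:
    """Collapse each item to 0/1 at its dichotomization cut.

    Ratings below the cut become 0, ratings at or above it become 1; missing
    stays missing. Idempotent on its own output (a binary item has cut 1).
    """
    table.validate(spec)
    out = table.data[["person_id", "day"]].copy()
    for it in spec.items:
        vals = table.data[it.item_id]
        out[it.item_id] = np.where(
            vals.isna(), np.nan, (vals >= it.dichotomization_cut).astype(float)
        )
    return ResponseTable(instrument=table.instrument, data=out)


@dataclass(frozen=True)
class AnchorMap:
    """Item pairs (reference_item_id, target_item_id) matched on domain."""

    reference: str
    target: str
    pairs: tuple[tuple[str, str], ...]
    domains: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.pairs)


#: Anchor domains used to place each instrument on the DRS-R-98 metric.
#: The MDAS list deliberately excludes attention and psychomotor activity;
#: the CAM-S list splits psychomotor agitation and retardation.
DEFAULT_ANCHOR_DOMAINS: dict[str, tuple[str, ...]] = {
    "MDAS": (
        "disorganized_thinking",
        "orientation",
        "perceptual_disturbance",
        "sleep_wake",
        "delusions",
        "memory",
    ),
    "CAM-S-long": (
        "attention",
        "disorganized_thinking",
        "orientation",
        "perceptual_disturbance",
        "psychomotor_agitation",
        "sleep_wake",
        "psychomotor_retardation",
    ),
}


@dataclass(frozen=True)
class AnchorMaps:
    """Pairwise anchor maps onto one reference plus the shared concept set."""

    reference: str
    pairwise: Mapping[str, AnchorMap]
    shared_concepts: tuple[str, ...]
    shared_items: Mapping[str, tuple[str, ...]] = field(default_factory=dict)


def _single_item_for_domain(spec: InstrumentSpec, domain: str) -> Item:
    matches = spec.items_for_domain(domain)
    if not matches:
        raise ConfigurationError(
            f"anchor domain {domain!r} absent from instrument {spec.name!r}"
        )
    return matches[0]


def shared_items(
    spec: InstrumentSpec, shared_concepts: Sequence[str]
) -> tuple[str, ...]:
    """One designated item per shared concept (the first listed in the spec).

    Where an instrument rates a concept with more than one item (psychomotor
    agitation/retardation on the DRS-R-98 and CAM-S), only the first enters
    the shared-item calibration; the others are calibrated with the
    instrument's remaining items.
    """
    out = []
    for c in shared_concepts:
        matches = [it for it in spec.items if concept(it.domain) == c]
        if not matches:
            raise ConfigurationError(
                f"shared concept {c!r} absent from instrument {spec.name!r}"
            )
        out.append(matches[0].item_id)
    return tuple(out)


def build_anchor_maps(
    specs: Mapping[str, InstrumentSpec],
    reference: str = "DRS-R-98",
    anchor_domains: Mapping[str, Sequence[str]] | None = None,
) -> AnchorMaps:
    """Construct pairwise anchor maps onto the reference instrument.

    ``anchor_domains`` maps each non-reference instrument name to the ordered
    domain list of its anchors; it defaults to the bundled MDAS (6 domains)
    and CAM-S (7 domains) lists. The three-way shared set is computed at the
    concept level over all instruments passed in.
    """
    if reference not in specs:
        raise ConfigurationError(f"reference instrument {reference!r} not given")
    ref_spec = specs[reference]
    if anchor_domains is None:
        anchor_domains = {
            name: DEFAULT_ANCHOR_DOMAINS[name]
            for name in specs
            if name != reference and name in DEFAULT_ANCHOR_DOMAINS
        }
    pairwise: dict[str, AnchorMap] = {}
    for name, domains in anchor_domains.items():
        target_spec = specs[name]
        pairs = []
        for d in domains:
            ref_item = _single_item_for_domain(ref_spec, d)
            tgt_item = _single_item_for_domain(target_spec, d)
            pairs.append((ref_item.item_id, tgt_item.item_id))
        pairwise[name] = AnchorMap(
            reference=reference,
            target=name,
            pairs=tuple(pairs),
            domains=tuple(domains),
        )
    concept_sets = [
        {concept(d) for d in spec.domains} for spec in specs.values()
    ]
    shared = set.intersection(*concept_sets) if concept_sets else set()
    # keep the reference instrument's item order
    ordered = tuple(
        c
        for c in dict.fromkeys(concept(d) for d in ref_spec.domains)
        if c in shared
    )
    shared_by_instrument = {
        name: shared_items(spec, ordered) for name, spec in specs.items()
    }
    return AnchorMaps(
        reference=reference,
        pairwise=pairwise,
        shared_concepts=ordered,
        shared_items=shared_by_instrument,
    )
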