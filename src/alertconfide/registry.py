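"""The twelve-criterion confidence registry and tier weighting schemes.

A structural alert is assessed against twelve named criteria, each assigned
one of three confidence levels (high / moderate / low, numerically 3 / 2 / 1)
or marked not-applicable.  Criteria belong to one of three importance tiers —
essential, desirable, optional — carrying default weights of 10, 5 and 2.
The default registry ships as a packaged YAML document so that users can copy
and adapt it; :func:`load_registry` reads the same dialect from any path.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping

import yaml

from .errors import RegistryError
from .validation import ValidationReport

SCHEME_VERSION = 1

_NA_ALIASES = frozenset({"na", "n/a", "not_applicable", "not applicable"})


class ConfidenceLevel(enum.Enum):
    """Assessed confidence in one criterion.

    HIGH, MODERATE and LOW map to the numeric scores 3, 2 and 1 used by the
    confidence-score arithmetic.  NOT_APPLICABLE carries no numeric score:
    asking for one raises ``ValueError``, and scoring code must exclude such
    criteria instead.
    """

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    NOT_APPLICABLE = "na"

    @property
    def numeric_score(self) -> int:
        if self is ConfidenceLevel.NOT_APPLICABLE:
            raise ValueError("NOT_APPLICABLE carries no numeric score")
        return {"high": 3, "moderate": 2, "low": 1}[self.value]

    @property
    def applicable(self) -> bool:
        return self is not ConfidenceLevel.NOT_APPLICABLE

    @classmethod
    def parse(cls, token: str | "ConfidenceLevel") -> "ConfidenceLevel":
        if isinstance(token, cls):
            return token
        norm = str(token).strip().lower()
        if norm in _NA_ALIASES:
            return cls.NOT_APPLICABLE
        try:
            return cls(norm)
        except ValueError:
            raise ValueError(
                f"unknown confidence level {token!r}; "
                "expected high, moderate, low or na"
            ) from None


class Tier(enum.Enum):
    """Importance tier of a criterion, with its default weight."""

    ESSENTIAL = ("essential", 10)
    DESIRABLE = ("desirable", 5)
    OPTIONAL = ("optional", 2)

    def __init__(self, token: str, default_weight: int):
        self.token = token
        self.default_weight = default_weight

    @classmethod
    def parse(cls, token: str | "Tier") -> "Tier":
        if isinstance(token, cls):
            return token
        for tier in cls:
            if tier.token == str(token).strip().lower():
                return tier
        raise ValueError(f"unknown tier {token!r}")


@dataclass(frozen=True)
class Criterion:
    """One assessable property of a structural alert."""

    id: str
    name: str
    tier: Tier
    definition: str
    level_descriptors: Mapping[ConfidenceLevel, str]
    display_rank: int

    def __post_init__(self):
        object.__setattr__(
            self, "level_descriptors", MappingProxyType(dict(self.level_descriptors))
        )
        missing = {
            ConfidenceLevel.HIGH,
            ConfidenceLevel.MODERATE,
            ConfidenceLevel.LOW,
        } - set(self.level_descriptors)
        if missing:
            raise RegistryError(
                f"criterion {self.id!r} lacks descriptors for "
                f"{sorted(l.value for l in missing)}"
            )


@dataclass(frozen=True)
class WeightingScheme:
    """Positive per-criterion weights used by the weighted confidence score."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "weights", MappingProxyType(dict(self.weights)))

    def weight(self, criterion_id: str) -> float:
        return self.weights[criterion_id]

    def scaled(self, factor: float, name: str | None = None) -> "WeightingScheme":
        return WeightingScheme(
            name or f"{self.name}*{factor:g}",
            {cid: w * factor for cid, w in self.weights.items()},
        )


def _criterion_from_mapping(entry: Mapping, source: str) -> Criterion:
    try:
        descriptors = {
            ConfidenceLevel.parse(level): text
            for level, text in entry["levels"].items()
        }
        return Criterion(
            id=entry["id"],
            name=entry["name"],
            tier=Tier.parse(entry["tier"]),
            definition=str(entry.get("definition", "")).strip(),
            level_descriptors=descriptors,
            display_rank=int(entry["display_rank"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryError(f"malformed criterion entry in {source}: {exc}") from exc


def _validate_registry(criteria: tuple[Criterion, ...], source: str) -> None:
    ids = [c.id for c in criteria]
    if len(set(ids)) != len(ids):
        raise RegistryError(f"duplicate criterion ids in {source}")
    ranks = sorted(c.display_rank for c in criteria)
    if ranks != list(range(1, len(criteria) + 1)):
        raise RegistryError(f"display_rank is not a permutation of 1..n in {source}")
    # tiers must form contiguous, ordered blocks in display order
    order = [c.tier for c in sorted(criteria, key=lambda c: c.display_rank)]
    tier_rank = {Tier.ESSENTIAL: 0, Tier.DESIRABLE: 1, Tier.OPTIONAL: 2}
    if [tier_rank[t] for t in order] != sorted(tier_rank[t] for t in order):
        raise RegistryError(f"display order mixes tiers in {source}")


def load_registry(path: str | Path) -> tuple[Criterion, ...]:
    """Load a criterion registry from a YAML or JSON document."""
    path = Path(path)
    try:
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        criteria = tuple(
            _criterion_from_mapping(entry, str(path)) for entry in doc["criteria"]
        )
    except RegistryError:
        raise
    except Exception as exc:
        raise RegistryError(f"cannot load registry from {path}: {exc}") from exc
    _validate_registry(criteria, str(path))
    return criteria


def load_default_registry() -> tuple[Criterion, ...]:
    """Load the packaged twelve-criterion registry.

    Returns the criteria sorted by display rank: the five essential criteria
    first, then the three desirable, then the four optional ones.
    """
    ref = resources.files("alertconfide.data").joinpath("criteria.yaml")
    try:
        doc = yaml.safe_load(ref.read_text())
        criteria = tuple(
            _criterion_from_mapping(entry, "criteria.yaml") for entry in doc["criteria"]
        )
    except RegistryError:
        raise
    except Exception as exc:
        raise RegistryError(f"packaged registry criteria.yaml is corrupted: {exc}") from exc
    _validate_registry(criteria, "criteria.yaml")
    if len(criteria) != 12:
        raise RegistryError(
            f"packaged registry must define 12 criteria, found {len(criteria)}"
        )
    return tuple(sorted(criteria, key=lambda c: c.display_rank))


def default_weighting_scheme(
    registry: Iterable[Criterion] | None = None,
) -> WeightingScheme:
    """Tier-default weights: essential 10, desirable 5, optional 2."""
    criteria = tuple(registry) if registry is not None else load_default_registry()
    return WeightingScheme(
        "default", {c.id: float(c.tier.default_weight) for c in criteria}
    )


def validate_weighting_scheme(
    scheme: WeightingScheme, registry: Iterable[Criterion]
) -> ValidationReport:
    """Check a weighting scheme against a registry.

    Findings: ``missing_criterion`` for registry ids absent from the scheme,
    ``unknown_id`` for scheme ids absent from the registry, and
    ``non_positive_weight`` for weights that are not strictly positive.
    An empty report means the scheme is usable with that registry.
    """
    report = ValidationReport(subject=f"weighting scheme {scheme.name!r}")
    registry_ids = {c.id for c in registry}
    for cid in sorted(registry_ids - set(scheme.weights)):
        report.add("missing_criterion", cid, "no weight defined for this criterion")
    for cid in sorted(set(scheme.weights) - registry_ids):
        report.add("unknown_id", cid, "weight defined for an id not in the registry")
    for cid, w in scheme.weights.items():
        if not (w > 0):
            report.add("non_positive_weight", cid, f"weight must be > 0, got {w!r}")
    return report


def registry_to_dict(criteria: Iterable[Criterion]) -> dict:
    """Serialise a registry to the packaged YAML/JSON dialect."""
    return {
        "scheme_version": SCHEME_VERSION,
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "tier": c.tier.token,
                "display_rank": c.display_rank,
                "definition": c.definition,
                "levels": {
                    level.value: text for level, text in sorted(
                        c.level_descriptors.items(), key=lambda kv: -kv[0].numeric_score
                    )
                },
            }
            for c in sorted(criteria, key=lambda c: c.display_rank)
        ],
    }
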