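"""Use-case requirement profiles and gap analysis.

Five application scenarios for structural alerts ship with the package, each
defining the ideal minimum confidence level per criterion:

* ``hazard_identification`` — direct toxicity prediction supporting risk
  assessment,
* ``mechanism_analogue_identification`` — analogue selection for
  mechanistically justified read-across,
* ``category_identification`` — assignment to chemical class-based
  categories,
* ``classification_labelling`` — predictions feeding regulatory
  classification and labelling,
* ``screening_prioritisation`` — screening or prioritisation of inventories.

Some requirement cells admit two adjacent levels (written ``high/moderate``
in the packaged file).  By default the *lower* of the two is treated as the
acceptable minimum (the permissive reading); ``strict=True`` requires the
higher one instead.

A gap exists when the assessed numeric level of a criterion falls strictly
below the required minimum.  A criterion assessed as not-applicable cannot be
compared numerically: when the requirement demands moderate or better it is
reported as a gap of kind ``not_assessable``, and is otherwise accepted.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ProfileError, RegistryError, UnknownUseCaseError
from .registry import ConfidenceLevel, Criterion, load_default_registry
from .scoring import ConfidenceProfile, validate_profile


class GapKind(enum.Enum):
    BELOW_MINIMUM = "below_minimum"
    NOT_ASSESSABLE = "not_assessable"


class Verdict(enum.Enum):
    MEETS_ALL = "MEETS_ALL"
    GAPS_FOUND = "GAPS_FOUND"


@dataclass(frozen=True)
class UseCaseRequirement:
    """Ideal minimum confidence levels for one application scenario."""

    use_case_id: str
    name: str
    minima: Mapping[str, tuple[ConfidenceLevel, ...]]

    def __post_init__(self):
        object.__setattr__(self, "minima", MappingProxyType(dict(self.minima)))

    def minimum_level(self, criterion_id: str, strict: bool = False) -> ConfidenceLevel:
        """The minimum acceptable level for a criterion.

        For a single-level cell this is that level.  For a two-level cell the
        permissive reading (default) returns the lower level; the strict
        reading returns the higher.
        """
        admitted = self.minima[criterion_id]
        key = max if strict else min
        return key(admitted, key=lambda lv: lv.numeric_score)


@dataclass(frozen=True)
class Gap:
    criterion_id: str
    required: ConfidenceLevel
    observed: ConfidenceLevel
    kind: GapKind


@dataclass(frozen=True)
class GapReport:
    """Result of checking one alert's profile against one use case."""

    alert_id: str
    use_case_id: str
    gaps: tuple[Gap, ...]
    strict: bool

    @property
    def verdict(self) -> Verdict:
        return Verdict.MEETS_ALL if not self.gaps else Verdict.GAPS_FOUND

    def to_dict(self) -> dict:
        return {
            "alert_id": self.alert_id,
            "use_case_id": self.use_case_id,
            "strict": self.strict,
            "verdict": self.verdict.value,
            "gaps": [
                {
                    "criterion_id": g.criterion_id,
                    "required": g.required.value,
                    "observed": g.observed.value,
                    "kind": g.kind.value,
                }
                for g in self.gaps
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_markdown(self) -> str:
        lines = [
            f"## Gap report: `{self.alert_id}` vs `{self.use_case_id}`",
            "",
            f"Verdict: **{self.verdict.value}** "
            f"({'strict' if self.strict else 'permissive'} reading of two-level minima)",
            "",
        ]
        if self.gaps:
            lines += [
                "| criterion | required minimum | observed | kind |",
                "| --- | --- | --- | --- |",
            ]
            lines += [
                f"| {g.criterion_id} | {g.required.value} | {g.observed.value} | {g.kind.value} |"
                for g in self.gaps
            ]
        else:
            lines.append("No gaps: the profile meets every required minimum.")
        return "\n".join(lines) + "\n"


def _use_case_from_mapping(entry: Mapping, source: str) -> UseCaseRequirement:
    try:
        minima = {
            cid: tuple(ConfidenceLevel.parse(lv) for lv in levels)
            for cid, levels in entry["minima"].items()
        }
        return UseCaseRequirement(
            use_case_id=entry["id"], name=entry["name"], minima=minima
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryError(f"malformed use case entry in {source}: {exc}") from exc


def load_use_cases(path: str | Path | None = None) -> tuple[UseCaseRequirement, ...]:
    """Load the packaged five use cases, or a user file in the same dialect."""
    if path is None:
        ref = resources.files("alertconfide.data").joinpath("use_cases.yaml")
        source, text = "use_cases.yaml", ref.read_text()
    else:
        path = Path(path)
        source, text = str(path), path.read_text()
    try:
        doc = json.loads(text) if source.endswith(".json") else yaml.safe_load(text)
        use_cases = tuple(
            _use_case_from_mapping(entry, source) for entry in doc["use_cases"]
        )
    except RegistryError:
        raise
    except Exception as exc:
        raise RegistryError(f"cannot load use cases from {source}: {exc}") from exc
    registry_ids = {c.id for c in load_default_registry()}
    for uc in use_cases:
        missing = registry_ids - set(uc.minima)
        if missing and path is None:
            raise RegistryError(
                f"packaged use case {uc.use_case_id!r} lacks minima for {sorted(missing)}"
            )
    return use_cases


def get_use_case(use_case_id: str) -> UseCaseRequirement:
    for uc in load_use_cases():
        if uc.use_case_id == use_case_id:
            return uc
    known = ", ".join(uc.use_case_id for uc in load_use_cases())
    raise UnknownUseCaseError(f"unknown use case {use_case_id!r}; packaged: {known}")


def gap_analysis(
    profile: ConfidenceProfile,
    requirement: UseCaseRequirement | str,
    registry: Sequence[Criterion] | None = None,
    strict: bool = False,
) -> GapReport:
    """List the criteria where a profile falls short of a use case's minima."""
    if isinstance(requirement, str):
        requirement = get_use_case(requirement)
    registry = registry if registry is not None else load_default_registry()
    validate_profile(profile, registry).raise_if_invalid(ProfileError)
    levels = profile.levels()
    gaps = []
    for criterion in registry:
        required = requirement.minimum_level(criterion.id, strict=strict)
        observed = levels[criterion.id]
        if not observed.applicable:
            if required.numeric_score >= ConfidenceLevel.MODERATE.numeric_score:
                gaps.append(Gap(criterion.id, required, observed, GapKind.NOT_ASSESSABLE))
        elif observed.numeric_score < required.numeric_score:
            gaps.append(Gap(criterion.id, required, observed, GapKind.BELOW_MINIMUM))
    return GapReport(
        alert_id=profile.alert_id,
        use_case_id=requirement.use_case_id,
        gaps=tuple(gaps),
        strict=strict,
    )


@dataclass(frozen=True)
class FitnessMatrix:
    """Meets/gap flags for every criterion across all packaged use cases."""

    alert_id: str
    table: pd.DataFrame  # index: criterion ids (display order); columns: use cases
    verdicts: Mapping[str, Verdict]

    def __post_init__(self):
        object.__setattr__(self, "verdicts", MappingProxyType(dict(self.verdicts)))


def fitness_matrix(
    profile: ConfidenceProfile,
    registry: Sequence[Criterion] | None = None,
    strict: bool = False,
) -> FitnessMatrix:
    """Summarise gap analyses of one profile against all five use cases.

    Cell values: ``"meets"``, ``"below_minimum"`` or ``"not_assessable"``.
    """
    registry = registry if registry is not None else load_default_registry()
    use_cases = load_use_cases()
    columns = {}
    verdicts = {}
    for uc in use_cases:
        report = gap_analysis(profile, uc, registry, strict=strict)
        flags = {g.criterion_id: g.kind.value for g in report.gaps}
        columns[uc.use_case_id] = [flags.get(c.id, "meets") for c in registry]
        verdicts[uc.use_case_id] = report.verdict
    table = pd.DataFrame(columns, index=[c.id for c in registry])
    table.index.name = "criterion_id"
    return FitnessMatrix(alert_id=profile.alert_id, table=table, verdicts=verdicts)
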