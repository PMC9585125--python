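"""Confidence profiles and the mean / weighted confidence scores.

A confidence profile records, for one structural alert, the assessed level of
every criterion in the registry.  Two summaries are computed over the
applicable (non-NA) criteria:

* the **mean confidence score** — the unweighted arithmetic mean of the
  numeric levels, and
* the **weighted confidence score** — the weight-averaged numeric level,

      WCS = sum_i(w_i * s_i) / sum_i(w_i)

  where ``s_i`` in {3, 2, 1} is the numeric level of criterion ``i`` and
  ``w_i`` its (strictly positive) weight.  Both scores live on the scale from
  3 (greatest confidence) to 1 (lowest confidence).

Criteria marked NOT_APPLICABLE are excluded from both numerator and
denominator; a profile in which every criterion is not-applicable has no
score and raises :class:`~alertconfide.errors.NoApplicableCriteriaError`.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, NoApplicableCriteriaError, ProfileError
from .registry import (
    ConfidenceLevel,
    Criterion,
    WeightingScheme,
    load_default_registry,
)
from .validation import ValidationReport


@dataclass(frozen=True)
class CriterionAssessment:
    """Assessed confidence level for one criterion, with its justification."""

    criterion_id: str
    level: ConfidenceLevel
    justification: str = ""
    evidence_refs: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "level", ConfidenceLevel.parse(self.level))
        object.__setattr__(self, "evidence_refs", tuple(self.evidence_refs))


@dataclass(frozen=True)
class ConfidenceProfile:
    """A complete per-criterion confidence assessment of one alert."""

    alert_id: str
    assessments: tuple[CriterionAssessment, ...]
    assessor: str = ""
    date: str = ""

    def __post_init__(self):
        object.__setattr__(self, "assessments", tuple(self.assessments))

    def levels(self) -> dict[str, ConfidenceLevel]:
        return {a.criterion_id: a.level for a in self.assessments}

    def level_of(self, criterion_id: str) -> ConfidenceLevel:
        for a in self.assessments:
            if a.criterion_id == criterion_id:
                return a.level
        raise KeyError(criterion_id)

    def with_level(self, criterion_id: str, level: ConfidenceLevel) -> "ConfidenceProfile":
        """Copy of this profile with one criterion re-assessed."""
        level = ConfidenceLevel.parse(level)
        if criterion_id not in self.levels():
            raise KeyError(criterion_id)
        return ConfidenceProfile(
            alert_id=self.alert_id,
            assessments=tuple(
                CriterionAssessment(a.criterion_id, level, a.justification, a.evidence_refs)
                if a.criterion_id == criterion_id
                else a
                for a in self.assessments
            ),
            assessor=self.assessor,
            date=self.date,
        )


@dataclass(frozen=True)
class CriterionContribution:
    criterion_id: str
    numeric_score: int
    weight: float
    contribution: float


@dataclass(frozen=True)
class ScoreResult:
    """Mean and weighted confidence scores with the per-criterion breakdown."""

    alert_id: str
    mean_score: float
    weighted_score: float
    n_applicable: int
    per_criterion: tuple[CriterionContribution, ...]
    weight_total: float
    scheme_name: str


def uniform_profile(
    level: ConfidenceLevel | str,
    alert_id: str = "alert",
    registry: Sequence[Criterion] | None = None,
) -> ConfidenceProfile:
    """Profile assigning the same level to every registry criterion."""
    registry = registry if registry is not None else load_default_registry()
    level = ConfidenceLevel.parse(level)
    return ConfidenceProfile(
        alert_id=alert_id,
        assessments=tuple(CriterionAssessment(c.id, level) for c in registry),
    )


def profile_from_levels(
    alert_id: str,
    levels: Mapping[str, ConfidenceLevel | str],
    assessor: str = "",
    date: str = "",
) -> ConfidenceProfile:
    return ConfidenceProfile(
        alert_id=alert_id,
        assessments=tuple(
            CriterionAssessment(cid, ConfidenceLevel.parse(level))
            for cid, level in levels.items()
        ),
        assessor=assessor,
        date=date,
    )


def validate_profile(
    profile: ConfidenceProfile, registry: Sequence[Criterion] | None = None
) -> ValidationReport:
    """Completeness check: every registry criterion assessed exactly once.

    Findings: ``missing_criterion``, ``duplicate_criterion``, ``unknown_id``.
    """
    registry = registry if registry is not None else load_default_registry()
    report = ValidationReport(subject=f"profile {profile.alert_id!r}")
    seen: dict[str, int] = {}
    for a in profile.assessments:
        seen[a.criterion_id] = seen.get(a.criterion_id, 0) + 1
    registry_ids = {c.id for c in registry}
    for cid in (c.id for c in registry):
        if cid not in seen:
            report.add("missing_criterion", cid, "criterion not assessed")
    for cid, count in seen.items():
        if cid not in registry_ids:
            report.add("unknown_id", cid, "assessment for an id not in the registry")
        elif count > 1:
            report.add("duplicate_criterion", cid, f"assessed {count} times")
    return report


def _applicable(profile: ConfidenceProfile) -> list[CriterionAssessment]:
    applicable = [a for a in profile.assessments if a.level.applicable]
    if not applicable:
        raise NoApplicableCriteriaError(
            f"profile {profile.alert_id!r}: every criterion is NOT_APPLICABLE, "
            "no confidence score can be computed"
        )
    return applicable


def mean_confidence_score(
    profile: ConfidenceProfile, registry: Sequence[Criterion] | None = None
) -> float:
    """Unweighted mean of numeric levels over the applicable criteria."""
    validate_profile(profile, registry).raise_if_invalid(ProfileError)
    applicable = _applicable(profile)
    return min(max(sum(a.level.numeric_score for a in applicable) / len(applicable), 1.0), 3.0)


def weighted_confidence_score(
    profile: ConfidenceProfile,
    scheme: WeightingScheme | None = None,
    registry: Sequence[Criterion] | None = None,
) -> ScoreResult:
    """Weighted confidence score of a complete profile under a weighting scheme.

    Not-applicable criteria drop out of both numerator and denominator, so the
    result always stays on the 1–3 scale.  The default scheme weights
    essential criteria 10, desirable 5 and optional 2.
    """
    registry = registry if registry is not None else load_default_registry()
    if scheme is None:
        from .registry import default_weighting_scheme

        scheme = default_weighting_scheme(registry)
    validate_profile(profile, registry).raise_if_invalid(ProfileError)
    applicable = _applicable(profile)
    contributions = []
    for a in applicable:
        if a.criterion_id not in scheme.weights:
            raise ConfigurationError(
                f"scheme {scheme.name!r} has no weight for applicable "
                f"criterion {a.criterion_id!r}"
            )
        w = float(scheme.weights[a.criterion_id])
        if not (w > 0):
            raise ConfigurationError(
                f"scheme {scheme.name!r}: weight for {a.criterion_id!r} "
                f"must be > 0, got {w!r}"
            )
        s = a.level.numeric_score
        contributions.append(CriterionContribution(a.criterion_id, s, w, w * s))
    weight_total = sum(c.weight for c in contributions)
    # scores are convex combinations of values in [1,3]; clamp away the
    # occasional 1-ulp float overshoot so the bound holds exactly
    weighted = min(max(sum(c.contribution for c in contributions) / weight_total, 1.0), 3.0)
    mean = min(max(sum(c.numeric_score for c in contributions) / len(contributions), 1.0), 3.0)
    return ScoreResult(
        alert_id=profile.alert_id,
        mean_score=mean,
        weighted_score=weighted,
        n_applicable=len(contributions),
        per_criterion=tuple(contributions),
        weight_total=weight_total,
        scheme_name=scheme.name,
    )


def compare_profiles(
    profiles: Sequence[ConfidenceProfile],
    scheme: WeightingScheme | None = None,
    registry: Sequence[Criterion] | None = None,
) -> pd.DataFrame:
    """Benchmark several alerts: one row per profile, best confidence first.

    Sorted by weighted score descending, ties broken by mean score then
    alert_id.  Invalid profiles abort with an aggregated error naming each
    offender.
    """
    if not profiles:
        raise ProfileError("compare_profiles requires at least one profile")
    registry = registry if registry is not None else load_default_registry()
    bad = []
    for p in profiles:
        rep = validate_profile(p, registry)
        if not rep.ok:
            bad.append(f"{p.alert_id}: {'; '.join(str(f) for f in rep.findings)}")
    if bad:
        raise ProfileError("invalid profiles: " + " | ".join(bad))
    rows = []
    for p in profiles:
        result = weighted_confidence_score(p, scheme, registry)
        row = {
            "alert_id": p.alert_id,
            "weighted_score": result.weighted_score,
            "mean_score": result.mean_score,
            "n_applicable": result.n_applicable,
        }
        levels = p.levels()
        for c in registry:
            row[c.id] = levels[c.id].value
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["weighted_score", "mean_score", "alert_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Profile serialisation.
#
# CSV dialect: optional leading "# key: value" metadata lines (alert_id,
# assessor, date), then a header row `criterion_id,level,justification`.
# Levels are case-insensitive high/moderate/low/na.  YAML/JSON documents carry
# the same content under explicit keys.  Both round-trip losslessly.
# ---------------------------------------------------------------------------

_META_KEYS = ("alert_id", "assessor", "date")


def profile_to_csv(profile: ConfidenceProfile) -> str:
    buf = io.StringIO()
    for key in _META_KEYS:
        value = getattr(profile, key)
        if value:
            buf.write(f"# {key}: {value}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["criterion_id", "level", "justification"])
    for a in profile.assessments:
        writer.writerow([a.criterion_id, a.level.value, a.justification])
    return buf.getvalue()


def profile_from_csv(text: str, default_alert_id: str = "alert") -> ConfidenceProfile:
    meta = {"alert_id": default_alert_id, "assessor": "", "date": ""}
    data_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            key, _, value = body.partition(":")
            if key.strip() in _META_KEYS:
                meta[key.strip()] = value.strip()
        elif stripped:
            data_lines.append(line)
    reader = csv.DictReader(data_lines)
    if reader.fieldnames is None or "criterion_id" not in reader.fieldnames:
        raise ProfileError("profile CSV must have a criterion_id,level[,justification] header")
    assessments = []
    for row in reader:
        assessments.append(
            CriterionAssessment(
                criterion_id=row["criterion_id"].strip(),
                level=ConfidenceLevel.parse(row["level"]),
                justification=(row.get("justification") or "").strip(),
            )
        )
    return ConfidenceProfile(
        alert_id=meta["alert_id"],
        assessments=tuple(assessments),
        assessor=meta["assessor"],
        date=meta["date"],
    )


def profile_to_dict(profile: ConfidenceProfile) -> dict:
    return {
        "alert_id": profile.alert_id,
        "assessor": profile.assessor,
        "date": profile.date,
        "assessments": [
            {
                "criterion_id": a.criterion_id,
                "level": a.level.value,
                "justification": a.justification,
                "evidence_refs": list(a.evidence_refs),
            }
            for a in profile.assessments
        ],
    }


def profile_from_dict(doc: Mapping) -> ConfidenceProfile:
    return ConfidenceProfile(
        alert_id=doc["alert_id"],
        assessments=tuple(
            CriterionAssessment(
                criterion_id=entry["criterion_id"],
                level=ConfidenceLevel.parse(entry["level"]),
                justification=entry.get("justification", ""),
                evidence_refs=tuple(entry.get("evidence_refs", ())),
            )
            for entry in doc["assessments"]
        ),
        assessor=doc.get("assessor", ""),
        date=doc.get("date", ""),
    )


def read_profile(path: str | Path) -> ConfidenceProfile:
    """Read a profile from .csv, .yaml/.yml or .json by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".csv":
        return profile_from_csv(text, default_alert_id=path.stem)
    if path.suffix in (".yaml", ".yml"):
        return profile_from_dict(yaml.safe_load(text))
    if path.suffix == ".json":
        return profile_from_dict(json.loads(text))
    raise ProfileError(f"unsupported profile format: {path.suffix!r}")


def write_profile(profile: ConfidenceProfile, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        path.write_text(profile_to_csv(profile))
    elif path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(profile_to_dict(profile), sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(profile_to_dict(profile), indent=2) + "\n")
    else:
        raise ProfileError(f"unsupported profile format: {path.suffix!r}")
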