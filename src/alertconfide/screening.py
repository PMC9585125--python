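"""Objective alert statistics: inventory coverage and classification performance.

A structural alert is a set of SMARTS substructure patterns; a molecule is a
hit iff at least one pattern matches.  Screening a labelled inventory yields a
2x2 contingency table (hit/no-hit vs active/inactive) from which two families
of statistics are derived:

* **Cooper statistics** — sensitivity, specificity, predictive values,
  accuracy and error rates.  Because most alerts flag the *presence* of
  toxicity, the absence of an alert is not a negative prediction; in
  ``positive_alert`` mode the true-negative-dependent statistics are omitted
  entirely and only sensitivity and the positive predictive value are
  reported.
* **Fisher enrichment** — the one-sided exact probability (hypergeometric
  tail) that at least the observed number of actives falls among the hits,
  i.e. the standard over-representation test used for chemotype enrichment.

Coverage — the fraction of the inventory the alert matches — uses every
parseable molecule, labelled or not; performance statistics use only the
labelled subset.  Unparseable records are quarantined and reported, never
silently dropped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from scipy.stats import hypergeom

from .errors import (
    ConfigurationError,
    EmptyInventoryError,
    PatternError,
    UndefinedStatisticError,
)
from .registry import ConfidenceLevel

RDLogger.DisableLog("rdApp.*")  # RDKit parse noise goes to quarantine, not stderr

ACTIVITY_VALUES = ("active", "inactive", "unknown")


class DerivationMethod(enum.Enum):
    """How an alert was derived (metadata only; not used in computation)."""

    EXPERT_TOX_DATA = "expert_tox_data"
    EXPERT_MECHANISTIC = "expert_mechanistic"
    DATA_DRIVEN = "data_driven"
    CHEMOTYPE_ENRICHMENT = "chemotype_enrichment"
    HYBRID = "hybrid"


@dataclass(frozen=True)
class StructuralAlert:
    """A substructure alert: SMARTS patterns plus toxicological metadata."""

    alert_id: str
    name: str
    patterns: tuple[str, ...]
    endpoint: str = ""
    species: tuple[str, ...] = ()
    metabolic_activation: str = "unknown"  # required | not_required | unknown
    mechanism: str = ""
    derivation_method: DerivationMethod | None = None
    references: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "patterns", tuple(self.patterns))
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "references", tuple(self.references))
        if not self.patterns:
            raise PatternError(f"alert {self.alert_id!r} defines no patterns")
        if self.metabolic_activation not in ("required", "not_required", "unknown"):
            raise ValueError(
                f"metabolic_activation must be required/not_required/unknown, "
                f"got {self.metabolic_activation!r}"
            )

    def compiled_patterns(self) -> list[Chem.Mol]:
        compiled = []
        for pattern in self.patterns:
            query = Chem.MolFromSmarts(pattern)
            if query is None:
                raise PatternError(
                    f"alert {self.alert_id!r}: SMARTS pattern {pattern!r} does not parse"
                )
            compiled.append(query)
        return compiled


@dataclass(frozen=True)
class InventoryRecord:
    """One inventory entry: an identifier, a SMILES and an optional label."""

    molecule_id: str
    structure: str
    activity: str = "unknown"

    def __post_init__(self):
        if self.activity not in ACTIVITY_VALUES:
            raise ValueError(
                f"activity must be one of {ACTIVITY_VALUES}, got {self.activity!r}"
            )


@dataclass(frozen=True)
class MoleculeHit:
    molecule_id: str
    hit: bool
    pattern_index: int | None  # 1-based index of the first matching pattern


@dataclass(frozen=True)
class Contingency:
    """2x2 counts of hit/no-hit vs active/inactive on the labelled subset."""

    tp: int  # hit and active
    fp: int  # hit and inactive
    fn: int  # no hit and active
    tn: int  # no hit and inactive

    @property
    def n_labelled(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> list[list[int]]:
        return [[self.tp, self.fp], [self.fn, self.tn]]


@dataclass(frozen=True)
class ScreeningResult:
    """Per-molecule hit flags and the contingency counts of one screen."""

    alert_id: str
    n_total: int
    n_hits: int
    per_molecule: tuple[MoleculeHit, ...]
    contingency: Contingency
    n_unlabelled: int
    quarantined: tuple[str, ...] = ()  # molecule_ids whose SMILES failed to parse

    def __post_init__(self):
        c = self.contingency
        if c.n_labelled + self.n_unlabelled != self.n_total:
            raise ValueError("contingency cells plus unlabelled must sum to n_total")


class CooperMode(enum.Enum):
    STANDARD = "standard"
    POSITIVE_ALERT = "positive_alert"


@dataclass(frozen=True)
class CooperStatistics:
    """Classification performance of an alert on the labelled subset.

    In ``positive_alert`` mode every statistic that depends on true negatives
    is ``None`` — absent by construction, not zero.
    """

    mode: CooperMode
    sensitivity: float
    positive_predictive_value: float
    specificity: float | None = None
    negative_predictive_value: float | None = None
    accuracy: float | None = None
    false_positive_rate: float | None = None
    false_negative_rate: float | None = None

    def to_dict(self) -> dict:
        out = {"mode": self.mode.value}
        for name in (
            "sensitivity",
            "positive_predictive_value",
            "specificity",
            "negative_predictive_value",
            "accuracy",
            "false_positive_rate",
            "false_negative_rate",
        ):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided exact over-representation test of actives among hits."""

    p_value: float
    odds_ratio: float  # (TP*TN)/(FP*FN); inf when FP*FN = 0 and TP*TN > 0
    counts: Contingency
    degenerate: bool = False  # margins give the test no power (no hits/actives)


def match_alert(
    alert: StructuralAlert, inventory: Sequence[InventoryRecord]
) -> ScreeningResult:
    """Screen an inventory against an alert.

    A molecule is a hit iff any pattern matches; the recorded pattern index is
    the 1-based position of the first matching pattern.  Molecules whose
    SMILES do not parse are quarantined; an inventory with no parseable
    molecule is an error.
    """
    queries = alert.compiled_patterns()
    per_molecule = []
    quarantined = []
    tp = fp = fn = tn = n_unlabelled = 0
    for record in inventory:
        mol = Chem.MolFromSmiles(record.structure)
        if mol is None:
            quarantined.append(record.molecule_id)
            continue
        hit, index = False, None
        for i, query in enumerate(queries, start=1):
            if mol.HasSubstructMatch(query):
                hit, index = True, i
                break
        per_molecule.append(MoleculeHit(record.molecule_id, hit, index))
        if record.activity == "active":
            tp, fn = (tp + 1, fn) if hit else (tp, fn + 1)
        elif record.activity == "inactive":
            fp, tn = (fp + 1, tn) if hit else (fp, tn + 1)
        else:
            n_unlabelled += 1
    if not per_molecule:
        raise EmptyInventoryError(
            f"alert {alert.alert_id!r}: no parseable molecules in inventory "
            f"({len(quarantined)} quarantined)"
        )
    return ScreeningResult(
        alert_id=alert.alert_id,
        n_total=len(per_molecule),
        n_hits=sum(1 for m in per_molecule if m.hit),
        per_molecule=tuple(per_molecule),
        contingency=Contingency(tp, fp, fn, tn),
        n_unlabelled=n_unlabelled,
        quarantined=tuple(quarantined),
    )


def coverage(result: ScreeningResult) -> float:
    """Fraction of the (parseable) inventory matched by the alert."""
    if result.n_total == 0:
        raise EmptyInventoryError("coverage is undefined on an empty inventory")
    return result.n_hits / result.n_total


def _contingency(result: ScreeningResult | Contingency) -> Contingency:
    return result.contingency if isinstance(result, ScreeningResult) else result


def cooper_statistics(
    result: ScreeningResult | Contingency,
    mode: CooperMode | str = CooperMode.STANDARD,
) -> CooperStatistics:
    """Cooper classification statistics from a screening contingency table.

    ``standard`` mode reports all seven statistics and requires every
    denominator to be non-zero.  ``positive_alert`` mode — appropriate for
    alerts that flag presence of toxicity, where a non-hit is not a negative
    prediction — reports only sensitivity and the positive predictive value.
    """
    mode = CooperMode(mode) if not isinstance(mode, CooperMode) else mode
    c = _contingency(result)
    if c.n_labelled == 0:
        raise UndefinedStatisticError(
            "no labelled molecules: Cooper statistics are undefined"
        )
    if c.tp + c.fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: no active molecules (TP+FN=0)")
    if c.tp + c.fp == 0:
        raise UndefinedStatisticError("PPV undefined: the alert produced no hits (TP+FP=0)")
    sensitivity = c.tp / (c.tp + c.fn)
    ppv = c.tp / (c.tp + c.fp)
    if mode is CooperMode.POSITIVE_ALERT:
        return CooperStatistics(
            mode=mode, sensitivity=sensitivity, positive_predictive_value=ppv
        )
    if c.tn + c.fp == 0:
        raise UndefinedStatisticError(
            "specificity undefined: no inactive molecules (TN+FP=0)"
        )
    if c.tn + c.fn == 0:
        raise UndefinedStatisticError("NPV undefined: the alert missed nothing (TN+FN=0)")
    specificity = c.tn / (c.tn + c.fp)
    return CooperStatistics(
        mode=mode,
        sensitivity=sensitivity,
        positive_predictive_value=ppv,
        specificity=specificity,
        negative_predictive_value=c.tn / (c.tn + c.fn),
        accuracy=(c.tp + c.tn) / c.n_labelled,
        false_positive_rate=1.0 - specificity,
        false_negative_rate=1.0 - sensitivity,
    )


def fisher_enrichment(result: ScreeningResult | Contingency) -> EnrichmentResult:
    """Exact one-sided test that actives are over-represented among hits.

    The p-value is the upper hypergeometric tail P(X >= TP) for X drawn with
    population n_labelled, successes = actives, draws = hits.  Degenerate
    margins (no hits, or no actives) make the test powerless: the p-value is
    1.0 and the result is flagged degenerate.
    """
    c = _contingency(result)
    if c.n_labelled == 0:
        raise UndefinedStatisticError("no labelled molecules: enrichment is undefined")
    hits = c.tp + c.fp
    actives = c.tp + c.fn
    if c.fp * c.fn == 0:
        odds_ratio = math.inf if c.tp * c.tn > 0 else math.nan
    else:
        odds_ratio = (c.tp * c.tn) / (c.fp * c.fn)
    if hits == 0 or actives == 0:
        return EnrichmentResult(
            p_value=1.0, odds_ratio=odds_ratio, counts=c, degenerate=True
        )
    p = float(hypergeom.sf(c.tp - 1, c.n_labelled, actives, hits))
    return EnrichmentResult(
        p_value=min(p, 1.0), odds_ratio=odds_ratio, counts=c, degenerate=False
    )


@dataclass(frozen=True)
class ObjectiveThresholds:
    """Cut-offs mapping coverage and performance onto suggested levels.

    These numeric defaults are this package's own calibration of the
    qualitative semantics (a specific, low-coverage alert inspires high
    confidence; an undiscriminating alert inspires none); they are advisory
    and must accompany any report that uses the suggestions.

    coverage <= coverage_high_max        -> HIGH
    coverage <= coverage_moderate_max    -> MODERATE, else LOW
    performance: LOW when the alert shows no enrichment over the labelled
    prevalence (PPV <= prevalence), HIGH when both sensitivity and PPV reach
    performance_high_min, MODERATE otherwise.
    """

    coverage_high_max: float = 0.05
    coverage_moderate_max: float = 0.20
    performance_high_min: float = 0.90

    def validate(self) -> None:
        if not (0 < self.coverage_high_max < self.coverage_moderate_max < 1):
            raise ConfigurationError(
                "coverage thresholds must satisfy 0 < high_max < moderate_max < 1"
            )
        if not (0.5 <= self.performance_high_min <= 1):
            raise ConfigurationError("performance_high_min must be in [0.5, 1]")


def suggest_objective_levels(
    result: ScreeningResult,
    thresholds: ObjectiveThresholds | None = None,
) -> dict[str, ConfidenceLevel]:
    """Advisory confidence-level suggestions for the two objective criteria.

    Returns ``{"coverage": level, "performance": level}``.  The mapping is a
    suggestion to seed a human assessment, not a verdict: the thresholds are
    package defaults, and the assessor remains responsible for the final
    profile.
    """
    thresholds = thresholds or ObjectiveThresholds()
    thresholds.validate()
    cov = coverage(result)
    if cov <= thresholds.coverage_high_max:
        coverage_level = ConfidenceLevel.HIGH
    elif cov <= thresholds.coverage_moderate_max:
        coverage_level = ConfidenceLevel.MODERATE
    else:
        coverage_level = ConfidenceLevel.LOW
    stats = cooper_statistics(result, CooperMode.POSITIVE_ALERT)
    c = _contingency(result)
    prevalence = (c.tp + c.fn) / c.n_labelled
    if stats.positive_predictive_value <= prevalence:
        performance_level = ConfidenceLevel.LOW  # no better than random labelling
    elif (
        stats.sensitivity >= thresholds.performance_high_min
        and stats.positive_predictive_value >= thresholds.performance_high_min
    ):
        performance_level = ConfidenceLevel.HIGH
    else:
        performance_level = ConfidenceLevel.MODERATE
    return {"coverage": coverage_level, "performance": performance_level}


# ---------------------------------------------------------------------------
# File I/O: inventories (CSV / SDF) and alert collections (YAML / JSON).
# ---------------------------------------------------------------------------


def load_inventory_csv(
    path: str | Path,
    quarantine_path: str | Path | None = None,
) -> tuple[list[InventoryRecord], list[tuple[int, str, str]]]:
    """Read an inventory CSV (``molecule_id,smiles[,activity]``).

    Rows whose SMILES do not parse are quarantined and returned as
    ``(line_number, molecule_id, smiles)`` tuples (and appended to
    *quarantine_path* if given); they are never silently dropped.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"molecule_id", "smiles"}
    if not required.issubset(frame.columns):
        raise EmptyInventoryError(
            f"inventory {path} must have columns molecule_id,smiles[,activity]"
        )
    records, quarantined = [], []
    for i, row in frame.iterrows():
        line_no = i + 2  # header is line 1
        smiles = row["smiles"].strip()
        if Chem.MolFromSmiles(smiles) is None:
            quarantined.append((line_no, row["molecule_id"], smiles))
            continue
        activity = (row.get("activity") or "unknown").strip().lower() or "unknown"
        records.append(InventoryRecord(row["molecule_id"], smiles, activity))
    if quarantine_path is not None and quarantined:
        lines = [f"{ln}\t{mid}\t{smi}\n" for ln, mid, smi in quarantined]
        Path(quarantine_path).write_text("".join(lines))
    return records, quarantined


def load_inventory_sdf(path: str | Path, activity_tag: str = "activity") -> tuple[
    list[InventoryRecord], list[tuple[int, str, str]]
]:
    """Read an inventory from an SDF file; activity from a property tag."""
    records, quarantined = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            quarantined.append((i, f"sdf_record_{i}", ""))
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_record_{i}"
        activity = (
            mol.GetProp(activity_tag).strip().lower()
            if mol.HasProp(activity_tag)
            else "unknown"
        ) or "unknown"
        records.append(InventoryRecord(mol_id, Chem.MolToSmiles(mol), activity))
    return records, quarantined


def write_inventory_csv(records: Iterable[InventoryRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "molecule_id": r.molecule_id,
                "smiles": r.structure,
                "activity": "" if r.activity == "unknown" else r.activity,
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


def alert_from_dict(doc: Mapping) -> StructuralAlert:
    method = doc.get("derivation_method")
    return StructuralAlert(
        alert_id=doc["alert_id"],
        name=doc.get("name", doc["alert_id"]),
        patterns=tuple(doc["patterns"]),
        endpoint=doc.get("endpoint", ""),
        species=tuple(doc.get("species", ())),
        metabolic_activation=doc.get("metabolic_activation", "unknown"),
        mechanism=doc.get("mechanism", ""),
        derivation_method=DerivationMethod(method) if method else None,
        references=tuple(doc.get("references", ())),
    )


def load_alerts(path: str | Path) -> list[StructuralAlert]:
    """Read an alert collection from a YAML or JSON document."""
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    entries = doc["alerts"] if isinstance(doc, Mapping) else doc
    alerts = [alert_from_dict(entry) for entry in entries]
    seen = set()
    for alert in alerts:
        if alert.alert_id in seen:
            raise PatternError(f"duplicate alert_id {alert.alert_id!r} in {path}")
        seen.add(alert.alert_id)
    return alerts


def screening_summary(
    result: ScreeningResult,
    mode: CooperMode | str = CooperMode.POSITIVE_ALERT,
    thresholds: ObjectiveThresholds | None = None,
) -> dict:
    """JSON-ready summary: counts, coverage, Cooper statistics, enrichment."""
    thresholds = thresholds or ObjectiveThresholds()
    c = result.contingency
    summary: dict = {
        "alert_id": result.alert_id,
        "n_total": result.n_total,
        "n_hits": result.n_hits,
        "n_quarantined": len(result.quarantined),
        "n_unlabelled": result.n_unlabelled,
        "coverage": coverage(result),
        "contingency": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
    }
    try:
        summary["cooper_statistics"] = cooper_statistics(result, mode).to_dict()
        enrichment = fisher_enrichment(result)
        summary["fisher_enrichment"] = {
            "p_value": enrichment.p_value,
            "odds_ratio": enrichment.odds_ratio,
            "degenerate": enrichment.degenerate,
        }
        suggestions = suggest_objective_levels(result, thresholds)
        summary["suggested_levels"] = {
            "note": "advisory suggestions from package-default thresholds",
            "thresholds": {
                "coverage_high_max": thresholds.coverage_high_max,
                "coverage_moderate_max": thresholds.coverage_moderate_max,
                "performance_high_min": thresholds.performance_high_min,
            },
            "coverage": suggestions["coverage"].value,
            "performance": suggestions["performance"].value,
        }
    except UndefinedStatisticError as exc:
        summary["performance_note"] = str(exc)
    return summary
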