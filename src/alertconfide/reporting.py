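"""Radar-style confidence profiles and deterministic evaluation reports.

The radar series lists the twelve criteria in display order — essential at
the top, then desirable, then optional — each with its numeric score (3/2/1)
or an explicit NA marker.  Not-applicable axes are rendered as gaps, never as
zero, so they cannot read as "worse than low".  Reports render to Markdown or
JSON; identical inputs always produce identical bytes (any timestamp lives in
an optional metadata field supplied by the caller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import AlertConfideError, ProfileError
from .registry import ConfidenceLevel, Criterion, Tier, load_default_registry
from .scoring import ConfidenceProfile, ScoreResult, validate_profile
from .usecases import GapReport

SOFTWARE_VERSION = "0.1.0"


@dataclass(frozen=True)
class RadarSeries:
    """Axis data for one alert's confidence radar."""

    alert_id: str
    axes: tuple[tuple[str, int | None], ...]  # (display name, score or None=NA)
    tier_boundaries: tuple[int, int]  # index of first desirable, first optional axis


def radar_series(
    profile: ConfidenceProfile, registry: Sequence[Criterion] | None = None
) -> RadarSeries:
    """Order a profile's scores along the registry's display ranking."""
    registry = registry if registry is not None else load_default_registry()
    validate_profile(profile, registry).raise_if_invalid(ProfileError)
    levels = profile.levels()
    ordered = sorted(registry, key=lambda c: c.display_rank)
    axes = tuple(
        (
            c.name,
            levels[c.id].numeric_score if levels[c.id].applicable else None,
        )
        for c in ordered
    )
    tiers = [c.tier for c in ordered]
    return RadarSeries(
        alert_id=profile.alert_id,
        axes=axes,
        tier_boundaries=(tiers.index(Tier.DESIRABLE), tiers.index(Tier.OPTIONAL)),
    )


def plot_radar(
    series: RadarSeries | Sequence[RadarSeries],
    path: str | Path,
) -> None:
    """Render one or more radar series to SVG or PNG (by file extension).

    Tier blocks are distinguished by axis-label colour; NA axes are gaps in
    the polygon (the line is broken, no vertex is drawn at zero).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series_list = [series] if isinstance(series, RadarSeries) else list(series)
    if not series_list:
        raise AlertConfideError("plot_radar needs at least one series")
    n = len(series_list[0].axes)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    for s in series_list:
        scores = np.array(
            [score if score is not None else np.nan for _, score in s.axes],
            dtype=float,
        )
        closed_angles = np.concatenate([angles, angles[:1]])
        closed_scores = np.concatenate([scores, scores[:1]])
        ax.plot(closed_angles, closed_scores, marker="o", label=s.alert_id)
    boundary_desirable, boundary_optional = series_list[0].tier_boundaries
    tier_colors = ["#1f4e9c"] * boundary_desirable
    tier_colors += ["#1d7a36"] * (boundary_optional - boundary_desirable)
    tier_colors += ["#a03030"] * (n - boundary_optional)
    ax.set_xticks(angles)
    ax.set_xticklabels([name for name, _ in series_list[0].axes], fontsize=8)
    for label, color in zip(ax.get_xticklabels(), tier_colors):
        label.set_color(color)
    ax.set_ylim(0, 3)
    ax.set_yticks([1, 2, 3])
    ax.set_yticklabels(["1 (low)", "2 (moderate)", "3 (high)"], fontsize=8)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


@dataclass(frozen=True)
class EvaluationReport:
    """Everything known about one alert's evaluation, ready to render.

    Every numeric value in a rendered report is recomputable from the
    embedded profile, weighting scheme name and thresholds (provenance).
    """

    profile: ConfidenceProfile
    score: ScoreResult
    alert_metadata: Mapping[str, object] = field(default_factory=dict)
    screening_summary: Mapping[str, object] | None = None
    gap_reports: tuple[GapReport, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        from .scoring import profile_to_dict

        doc: dict = {
            "alert_metadata": dict(self.alert_metadata),
            "profile": profile_to_dict(self.profile),
            "scores": {
                "mean_score": round(self.score.mean_score, 4),
                "weighted_score": round(self.score.weighted_score, 4),
                "n_applicable": self.score.n_applicable,
                "weight_total": self.score.weight_total,
                "scheme": self.score.scheme_name,
                "per_criterion": [
                    {
                        "criterion_id": c.criterion_id,
                        "numeric_score": c.numeric_score,
                        "weight": c.weight,
                        "contribution": c.contribution,
                    }
                    for c in self.score.per_criterion
                ],
            },
            "provenance": {
                "software_version": SOFTWARE_VERSION,
                "registry_version": 1,
                **dict(self.provenance),
            },
        }
        if self.screening_summary is not None:
            doc["screening"] = dict(self.screening_summary)
        if self.gap_reports:
            doc["gap_reports"] = [g.to_dict() for g in self.gap_reports]
        return doc


def render_report(report: EvaluationReport, format: str = "json") -> str:
    """Render an evaluation report to a deterministic JSON or Markdown string."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format in ("markdown", "md"):
        return _render_markdown(report)
    raise AlertConfideError(f"unknown report format {format!r}; use json or markdown")


def _render_markdown(report: EvaluationReport) -> str:
    registry = load_default_registry()
    names = {c.id: c.name for c in registry}
    levels = report.profile.levels()
    weights = {c.criterion_id: c.weight for c in report.score.per_criterion}
    lines = [
        f"# Confidence evaluation: {report.profile.alert_id}",
        "",
        f"- Weighted confidence score: **{report.score.weighted_score:.4f}** "
        f"(scheme: {report.score.scheme_name})",
        f"- Mean confidence score: **{report.score.mean_score:.4f}**",
        f"- Applicable criteria: {report.score.n_applicable} / {len(registry)}",
        "",
        "| # | criterion | level | weight |",
        "| --- | --- | --- | --- |",
    ]
    for c in sorted(registry, key=lambda c: c.display_rank):
        level = levels[c.id]
        weight = weights.get(c.id, "—")
        lines.append(
            f"| {c.display_rank} | {names[c.id]} | {level.value} | {weight} |"
        )
    if report.screening_summary:
        lines += ["", "## Screening", ""]
        summary = report.screening_summary
        lines.append(f"- Inventory size: {summary.get('n_total')}")
        lines.append(f"- Hits: {summary.get('n_hits')} (coverage {summary.get('coverage'):.4f})")
        suggested = summary.get("suggested_levels")
        if suggested:
            thresholds = suggested.get("thresholds", {})
            lines.append(
                "- Suggested levels (advisory; thresholds "
                f"{json.dumps(thresholds, sort_keys=True)}): "
                f"coverage={suggested['coverage']}, performance={suggested['performance']}"
            )
    for gap_report in report.gap_reports:
        lines += ["", gap_report.to_markdown().rstrip()]
    lines += [
        "",
        f"_Generated by alertconfide {SOFTWARE_VERSION}; "
        f"registry scheme_version 1._",
        "",
    ]
    return "\n".join(lines)
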