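"""Report-based validation shared by the registry and profile layers.

Validators in this package do not raise on bad input; they return a
:class:`ValidationReport` listing every finding, so callers can show all
problems at once.  Operations that *require* valid input call
``report.raise_if_invalid()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlertConfideError


@dataclass(frozen=True)
class Finding:
    kind: str           # e.g. "missing_criterion", "unknown_id", "non_positive_weight"
    subject: str        # the criterion id or other token the finding is about
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    subject: str
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, kind: str, subject: str, message: str) -> None:
        self.findings.append(Finding(kind, subject, message))

    def by_kind(self, kind: str) -> list[Finding]:
        return [f for f in self.findings if f.kind == kind]

    def raise_if_invalid(self, exc_type: type[AlertConfideError] = AlertConfideError) -> None:
        if not self.ok:
            detail = "; ".join(str(f) for f in self.findings)
            raise exc_type(f"{self.subject}: {detail}")
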