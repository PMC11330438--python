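"""Validation reports shared by the metadata model and the form engine.

Problems found while validating metadata or submissions are never raised as
exceptions; they accumulate in a :class:`ValidationReport`. ``entries`` are
errors (``ok`` is true iff there are none); ``warnings`` are advisory and do
not block persistence (e.g. values supplied to hidden widgets, which are
stripped before storage).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ReportEntry:
    variable_id: str | None
    code: str
    message: str


@dataclass
class ValidationReport:
    entries: list[ReportEntry] = field(default_factory=list)
    warnings: list[ReportEntry] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.entries

    def add(self, variable_id: str | None, code: str, message: str) -> None:
        self.entries.append(ReportEntry(variable_id, code, message))

    def warn(self, variable_id: str | None, code: str, message: str) -> None:
        self.warnings.append(ReportEntry(variable_id, code, message))

    def extend(self, other: "ValidationReport") -> None:
        self.entries.extend(other.entries)
        self.warnings.extend(other.warnings)

    def codes(self) -> set[str]:
        return {e.code for e in self.entries}

    def __repr__(self) -> str:  # compact, test-failure friendly
        if self.ok and not self.warnings:
            return "ValidationReport(ok)"
        parts = [f"{e.code}({e.variable_id}): {e.message}" for e in self.entries]
        parts += [f"warn {e.code}({e.variable_id})" for e in self.warnings]
        return "ValidationReport[" + "; ".join(parts) + "]"
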