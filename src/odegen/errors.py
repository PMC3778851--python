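"""Exception hierarchy and diagnostics shared by all compiler stages.

Every error type carries the name of the stage that raised it so front ends
can print line-oriented ``SEVERITY: module: message`` diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass


class OdegenError(Exception):
    """Base class for all expected errors raised by this package."""

    module: str = "odegen"

    def diagnostic(self) -> str:
        return f"ERROR: {self.module}: {self}"


class ParseError(OdegenError):
    """Malformed XML or a document outside the supported dialect."""

    module = "model_ir"

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UnsupportedConstructError(ParseError):
    """A MathML (or dialect) element outside the supported subset."""


class ModelError(OdegenError):
    module = "model_ir"


class EvaluationError(OdegenError):
    """Unbound variable or arithmetic/domain failure during evaluation."""

    module = "model_ir"


class SchemeError(OdegenError):
    module = "scheme"


class MapError(OdegenError):
    module = "mapping"


class ExpansionError(OdegenError):
    module = "expander"


class CodegenError(OdegenError):
    module = "codegen"


class SimulationError(OdegenError):
    module = "runtime"


class FixtureError(OdegenError):
    module = "fixtures"


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding. ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    module: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper()}: {self.module}: {self.message}"


def errors_only(diags: list[Diagnostic]) -> list[Diagnostic]:
    return [d for d in diags if d.severity == "error"]
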