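"""Stage 2: emit runnable single-cell simulation source from a flat program.

Two targets are supported:

* ``python`` — a self-contained script using only the standard library;
  runs in IEEE double or in an N-significant-digit decimal context.
* ``c``      — C99 using only the C standard library, double precision.

Every emitted program assigns its inputs, executes the flat program's
assignments in order inside a fixed-step time loop, and writes ``t`` plus
the state variables as CSV to standard output every ``stride`` steps.
Constants and initial values are baked into the source as literals, so
emission is a pure function of (program, options): identical inputs yield
byte-identical source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping

from .errors import CodegenError
from .expander import FlatProgram, check_well_formed, count_steps
from .model_ir import expr_to_c, expr_to_python, expr_to_str

STEP_BEGIN = "begin time-evolution assignments"
STEP_END = "end time-evolution assignments"


@dataclass(frozen=True)
class CodegenOptions:
    target: str = "python"  # "python" | "c"
    precision: int | str = "double"  # "double" or significant decimal digits
    t_start: str = "0"
    t_end: str = "1"
    delta: str = "0.01"
    stride: int = 1
    initial_values: Mapping[str, str] = field(default_factory=dict)
    constant_values: Mapping[str, str] = field(default_factory=dict)
    columns: tuple[str, ...] | None = None  # output order; default diffvar order

    def validate(self) -> None:
        if self.target not in ("python", "c"):
            raise CodegenError(f"unknown target {self.target!r}")
        if Decimal(self.delta) <= 0:
            raise CodegenError("delta must be positive")
        if Decimal(self.t_end) <= Decimal(self.t_start):
            raise CodegenError("t_end must be greater than t_start")
        if self.stride < 1:
            raise CodegenError("stride must be >= 1")
        if self.precision != "double":
            if int(self.precision) < 1:
                raise CodegenError("decimal precision must be >= 1")
            if self.target == "c":
                raise CodegenError(
                    "the C target is double-precision only; use the python "
                    "target for decimal arithmetic"
                )


def _check_bindings(p: FlatProgram, opts: CodegenOptions) -> tuple[list[str], int]:
    bad = check_well_formed(p)
    if bad:
        raise CodegenError(f"program is not well formed: {bad[0].message}")
    if not p.diffvars:
        raise CodegenError("program has no state variables; nothing to simulate")
    missing = [v for v in p.diffvars if v not in opts.initial_values]
    missing += [c for c in p.constants if c not in opts.constant_values]
    if missing:
        raise CodegenError(f"unbound constant/initial value(s): {missing}")
    cols = list(opts.columns) if opts.columns is not None else list(p.diffvars)
    unknown = [c for c in cols if c not in p.diffvars]
    if unknown:
        raise CodegenError(f"unknown output column(s): {unknown}")
    span = Decimal(opts.t_end) - Decimal(opts.t_start)
    nsteps = int((span / Decimal(opts.delta)).to_integral_value())
    return cols, nsteps


def emit_source(p: FlatProgram, opts: CodegenOptions) -> str:
    """Emit a complete simulation program for ``p``."""
    opts.validate()
    cols, nsteps = _check_bindings(p, opts)
    if opts.target == "python":
        return _emit_python(p, opts, cols, nsteps)
    return _emit_c(p, opts, cols, nsteps)


def _emit_python(p: FlatProgram, opts: CodegenOptions, cols, nsteps) -> str:
    decimal_mode = opts.precision != "double"
    L: list[str] = ["#!/usr/bin/env python3"]
    if decimal_mode:
        L += [
            "from decimal import Decimal, getcontext",
            f"getcontext().prec = {int(opts.precision)}",
        ]
        lit = lambda v: f"Decimal({str(v)!r})"
    else:
        L += ["import math"]
        lit = lambda v: repr(float(v))
    L.append("")
    for c in p.constants:
        L.append(f"{c} = {lit(opts.constant_values[c])}")
    L.append(f"{p.delta_name} = {lit(opts.delta)}")
    L.append(f"_t0 = {lit(opts.t_start)}")
    L.append(f"_nsteps = {nsteps}")
    L.append(f"_stride = {opts.stride}")
    for v in p.diffvars:
        L.append(f"{v} = {lit(opts.initial_values[v])}")
    L.append("")
    fmt = ",".join(["{}"] * (len(cols) + 1))
    emit_row = "print(" + repr(fmt) + f".format(_t, {', '.join(cols)}))"
    L.append(f"print({('t,' + ','.join(cols))!r})")
    L.append("_t = _t0")
    L.append(emit_row)
    L.append("for _i in range(_nsteps):")
    L.append(f"    {p.time_name} = _t0 + _i * {p.delta_name}")
    for v in p.diffvars:
        L.append(f"    {p.input_of[v]} = {v}")
    L.append(f"    # {STEP_BEGIN}")
    for a in p.assignments:
        L.append(f"    {a.lhs} = {expr_to_python(a.rhs, decimal_mode)}")
    L.append(f"    # {STEP_END}")
    for v in p.diffvars:
        L.append(f"    {v} = {p.output_of[v]}")
    L.append(f"    _t = _t0 + (_i + 1) * {p.delta_name}")
    L.append("    if (_i + 1) % _stride == 0:")
    L.append("        " + emit_row)
    L.append("")
    return "\n".join(L)


def _emit_c(p: FlatProgram, opts: CodegenOptions, cols, nsteps) -> str:
    L: list[str] = [
        "#include <stdio.h>",
        "#include <math.h>",
        "",
        "int main(void) {",
    ]
    for c in p.constants:
        L.append(f"    const double {c} = {float(opts.constant_values[c])!r};")
    L.append(f"    const double {p.delta_name} = {float(opts.delta)!r};")
    L.append(f"    const double _t0 = {float(opts.t_start)!r};")
    L.append(f"    const long _nsteps = {nsteps}L;")
    L.append(f"    const long _stride = {opts.stride}L;")
    for v in p.diffvars:
        L.append(f"    double {v} = {float(opts.initial_values[v])!r};")
    header = "t," + ",".join(cols)
    row_fmt = ",".join(["%.17g"] * (len(cols) + 1))
    row_args = ", ".join(cols)
    L.append(f'    printf("{header}\\n");')
    L.append(f'    printf("{row_fmt}\\n", _t0, {row_args});')
    L.append("    for (long _i = 0; _i < _nsteps; _i++) {")
    L.append(f"        double {p.time_name} = _t0 + _i * {p.delta_name};")
    for v in p.diffvars:
        L.append(f"        double {p.input_of[v]} = {v};")
    L.append(f"        /* {STEP_BEGIN} */")
    for a in p.assignments:
        L.append(f"        double {a.lhs} = {expr_to_c(a.rhs)};")
    L.append(f"        /* {STEP_END} */")
    for v in p.diffvars:
        L.append(f"        {v} = {p.output_of[v]};")
    L.append("        if ((_i + 1) % _stride == 0) {")
    L.append(
        f'            printf("{row_fmt}\\n", _t0 + (_i + 1) * {p.delta_name}, {row_args});'
    )
    L.append("        }")
    L.append("    }")
    L.append("    return 0;")
    L.append("}")
    L.append("")
    return "\n".join(L)


def count_emitted_assignments(source: str) -> int:
    """Number of flat-program assignment statements in an emitted loop body."""
    counting = False
    n = 0
    for line in source.splitlines():
        if STEP_BEGIN in line:
            counting = True
            continue
        if STEP_END in line:
            break
        if counting and "=" in line:
            n += 1
    return n


def emit_equation_listing(p: FlatProgram) -> str:
    """Numbered human-readable listing of the flat program, one line per
    assignment (the auditable stage-1 output)."""
    width = len(str(len(p.assignments)))
    lines = [
        f"{i:>{width}}: {a.lhs} = {expr_to_str(a.rhs)}"
        for i, a in enumerate(p.assignments, start=1)
    ]
    return "\n".join(lines)


__all__ = [
    "CodegenOptions",
    "emit_source",
    "emit_equation_listing",
    "count_emitted_assignments",
    "count_steps",
    "STEP_BEGIN",
    "STEP_END",
]
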