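"""Reference execution of flat programs and the time-step accuracy study.

The interpreter executes a flat program's assignment list repeatedly,
feeding each step's output bindings back as the next step's inputs.
Arithmetic runs either in IEEE double precision or in a decimal context of N
significant digits (the high-precision mode used for accuracy studies, so
truncation error can be separated from round-off).  For speed the assignment
list is compiled once into a Python step loop; the semantics are exactly the
per-assignment evaluation order of the program.

The accuracy study reruns one model under several schemes and time steps,
measures the root-mean-square error of each run against a high-accuracy
reference trajectory, and fits each scheme's empirical convergence order as
the least-squares slope of log10(RMSE) against log10(delta).  Entries whose
RMSE sits at the round-off floor of the arithmetic context are flagged and
excluded from the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import (
    Decimal,
    DivisionByZero,
    InvalidOperation,
    Overflow,
    localcontext,
)
from typing import Mapping, Sequence

import numpy as np

from .errors import SimulationError
from .expander import FlatProgram, check_well_formed, expand
from .mapping import RelMap
from .model_ir import CellModel, expr_to_python
from .scheme import TecScheme, builtin_scheme

Precision = int | str  # number of significant decimal digits, or "double"

_DOUBLE_DIGITS = 16  # significant decimal digits carried by IEEE double


# ---------------------------------------------------------------------------
# Interpreter
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    t_start: Decimal
    delta: Decimal
    stride: int
    times: list[Decimal]  # sampled time grid (exact decimals)
    series: dict[str, list]  # diffvar -> sampled values (Decimal or float)
    precision: Precision
    diverged_at: int | None = None  # global step index of first non-finite step

    @property
    def diverged(self) -> bool:
        return self.diverged_at is not None


def _compile_runner(p: FlatProgram, decimal_mode: bool):
    """Build the per-step loop for ``p`` as a compiled Python function."""
    names = p.diffvars
    lines = [
        "def _runner(nsteps, stride, t0, dt, state, consts, record):",
    ]
    for c in p.constants:
        lines.append(f"    {c} = consts[{c!r}]")
    unpack = ", ".join(names) + ("," if len(names) == 1 else "")
    lines.append(f"    ({unpack}) = state")
    lines.append(f"    {p.delta_name} = dt")
    lines.append("    for _i in range(nsteps):")
    lines.append(f"        {p.time_name} = t0 + _i * dt")
    lines.append("        try:")
    for v in names:
        lines.append(f"            {p.input_of[v]} = {v}")
    for a in p.assignments:
        lines.append(f"            {a.lhs} = {expr_to_python(a.rhs, decimal_mode)}")
    for v in names:
        lines.append(f"            {v} = {p.output_of[v]}")
    lines.append("        except (ArithmeticError, ValueError):")
    lines.append("            return _i")
    if decimal_mode:
        finite = " and ".join(f"{v}.is_finite()" for v in names)
    else:
        finite = " and ".join(f"math.isfinite({v})" for v in names)
    lines.append(f"        if not ({finite}):")
    lines.append("            return _i")
    lines.append("        if (_i + 1) % stride == 0:")
    lines.append(f"            record(_i + 1, ({unpack}))")
    lines.append("    return None")
    src = "\n".join(lines)
    glb = {"math": math, "Decimal": Decimal}
    exec(compile(src, f"<flatprogram:{'+'.join(names)}>", "exec"), glb)
    return glb["_runner"]


def interpret(
    p: FlatProgram,
    init: Mapping[str, Decimal | float | int | str],
    consts: Mapping[str, Decimal | float | int | str],
    t_start,
    t_end,
    delta,
    precision: Precision = "double",
    sample_stride: int = 1,
) -> SimulationResult:
    """Run ``p`` from ``t_start`` to ``t_end`` with time step ``delta``.

    ``init`` binds every state variable, ``consts`` every constant.  Values
    are sampled every ``sample_stride`` steps (the initial state is always
    sample 0).  A non-finite state or an arithmetic trap stops the run and
    sets the divergence flag to the offending step index.
    """
    bad = [d.message for d in check_well_formed(p)]
    if bad:
        raise SimulationError(f"program is not well formed: {bad[0]}")
    missing = [v for v in p.diffvars if v not in init]
    if missing:
        raise SimulationError(f"unbound initial value(s): {missing}")
    missing = [c for c in p.constants if c not in consts]
    if missing:
        raise SimulationError(f"unbound constant(s): {missing}")

    t0 = Decimal(str(t_start))
    dt = Decimal(str(delta))
    if dt <= 0:
        raise SimulationError("delta must be positive")
    span = Decimal(str(t_end)) - t0
    nsteps = int((span / dt).to_integral_value())
    if nsteps < 0:
        raise SimulationError("t_end must be >= t_start")

    decimal_mode = precision != "double"
    if decimal_mode:
        digits = int(precision)
        if digits < 1:
            raise SimulationError("precision must be >= 1 significant digit")
        conv = lambda v: Decimal(str(v))
    else:
        conv = lambda v: float(v)

    state = tuple(conv(init[v]) for v in p.diffvars)
    cvals = {c: conv(consts[c]) for c in p.constants}

    times: list[Decimal] = [t0]
    columns: list[tuple] = [state]

    def record(step_index: int, values):
        times.append(t0 + step_index * dt)
        columns.append(values if isinstance(values, tuple) else (values,))

    runner = _compile_runner(p, decimal_mode)
    if decimal_mode:
        with localcontext() as ctx:
            ctx.prec = digits
            ctx.traps[InvalidOperation] = True
            ctx.traps[DivisionByZero] = True
            ctx.traps[Overflow] = True
            diverged_at = runner(
                nsteps, sample_stride, t0, dt, state, cvals, record
            )
    else:
        diverged_at = runner(
            nsteps, sample_stride, float(t0), float(dt), state, cvals, record
        )

    series = {
        v: [row[i] for row in columns] for i, v in enumerate(p.diffvars)
    }
    return SimulationResult(
        t_start=t0,
        delta=dt,
        stride=sample_stride,
        times=times,
        series=series,
        precision=precision,
        diverged_at=diverged_at,
    )


# ---------------------------------------------------------------------------
# RMSE and convergence order
# ---------------------------------------------------------------------------


def rmse(
    candidate: SimulationResult,
    reference: SimulationResult,
    variables: Sequence[str] | None = None,
) -> float:
    """Root-mean-square deviation over shared sample times and variables.

    The candidate's sample times must all occur in the reference grid.
    Differences are taken in exact decimal arithmetic before squaring so
    that deviations far below double-precision spacing remain measurable.
    """
    if variables is None:
        variables = list(candidate.series)
    ref_index = {t: i for i, t in enumerate(reference.times)}
    shared = [(j, ref_index[t]) for j, t in enumerate(candidate.times) if t in ref_index]
    if not shared:
        raise SimulationError("no shared sample times between candidate and reference")
    total = 0.0
    count = 0
    for var in variables:
        cs, rs = candidate.series[var], reference.series[var]
        for j, i in shared:
            d = float(Decimal(str(cs[j])) - Decimal(str(rs[i])))
            total += d * d
            count += 1
    return math.sqrt(total / count)


def estimate_order(entries: Sequence[tuple]) -> float:
    """Least-squares slope of log10(RMSE) against log10(delta)."""
    usable = [(float(d), float(r)) for d, r in entries if float(r) > 0.0]
    if len(usable) < 2:
        raise SimulationError(
            f"need at least 2 entries with positive RMSE, got {len(usable)}"
        )
    logd = np.log10([d for d, _ in usable])
    logr = np.log10([r for _, r in usable])
    slope = np.polyfit(logd, logr, 1)[0]
    return float(slope)


@dataclass
class StudyEntry:
    scheme: str
    delta: Decimal
    rmse: float | None
    flag: str = ""  # "", "floor" or "divergent"


@dataclass
class AccuracyReport:
    reference_scheme: str
    reference_delta: Decimal
    precision: Precision
    entries: list[StudyEntry]
    orders: dict[str, float | None]
    floor: float

    def to_csv(self) -> str:
        lines = ["scheme,delta,rmse,flag"]
        for e in self.entries:
            r = "" if e.rmse is None else repr(e.rmse)
            lines.append(f"{e.scheme},{e.delta},{r},{e.flag}")
        return "\n".join(lines) + "\n"

    def to_json_summary(self) -> dict:
        return {
            "reference": {
                "scheme": self.reference_scheme,
                "delta": str(self.reference_delta),
                "precision": str(self.precision),
            },
            "floor": self.floor,
            "orders": {k: v for k, v in self.orders.items()},
        }

    def plot(self, path: str) -> None:
        """Write a log-log RMSE vs time-step plot (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for scheme in dict.fromkeys(e.scheme for e in self.entries):
            pts = [
                (float(e.delta), e.rmse)
                for e in self.entries
                if e.scheme == scheme and e.rmse is not None and e.rmse > 0
            ]
            if pts:
                ax.loglog(*zip(*pts), marker="o", label=scheme)
        ax.set_xlabel("time step")
        ax.set_ylabel("RMSE")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _scheme_of(s: str | TecScheme) -> TecScheme:
    return builtin_scheme(s) if isinstance(s, str) else s


def convergence_study(
    m: CellModel,
    rmap: RelMap,
    schemes: Sequence[str | TecScheme],
    deltas: Sequence,
    ref: tuple,
    horizon,
    precision: Precision = 32,
    init: Mapping | None = None,
    consts: Mapping | None = None,
    t_start=0,
) -> AccuracyReport:
    """Run the scheme/time-step accuracy experiment on one model.

    One reference run (``ref = (scheme, delta_ref)``), then one candidate run
    per (scheme, delta); trajectories are sampled at multiples of the largest
    candidate delta and compared by RMSE over all state variables.  Entries
    below the round-off floor of the context — ten units in the last carried
    digit, scaled by the reference trajectory's RMS magnitude — are flagged
    ``floor``; divergent runs are flagged ``divergent``; both are excluded
    from the per-scheme order fit.
    """
    deltas = [Decimal(str(d)) for d in deltas]
    if not deltas and not schemes:
        return AccuracyReport(
            str(ref[0]), Decimal(str(ref[1])), precision, [], {}, 0.0
        )
    ref_scheme_in, ref_delta = ref
    ref_delta = Decimal(str(ref_delta))
    d_max = max(deltas) if deltas else None
    if d_max is not None and ref_delta >= min(deltas):
        raise SimulationError("reference delta must be below every candidate delta")

    inits = dict(init) if init is not None else {}
    cvals = dict(consts) if consts is not None else {}
    declared = m.initial_values()
    for v in rmap.diffvars:
        inits.setdefault(v, declared.get(v))
        if inits[v] is None:
            raise SimulationError(f"no initial value for state variable {v!r}")
    for c in rmap.constvars:
        cvals.setdefault(c, declared.get(c))
        if cvals[c] is None:
            raise SimulationError(f"no value for constant {c!r}")

    horizon = Decimal(str(horizon))
    if d_max is not None and (horizon / d_max) != (horizon / d_max).to_integral_value():
        raise SimulationError("horizon must be an integer multiple of max(deltas)")

    def run(scheme, delta) -> SimulationResult:
        program = expand(m, _scheme_of(scheme), rmap)
        stride_delta = d_max if d_max is not None else delta
        stride = int((stride_delta / delta).to_integral_value())
        return interpret(
            program, inits, cvals, t_start, Decimal(str(t_start)) + horizon,
            delta, precision, sample_stride=stride,
        )

    reference = run(ref_scheme_in, ref_delta)
    if reference.diverged:
        raise SimulationError(
            f"reference run diverged at step {reference.diverged_at}"
        )
    ref_scale = math.sqrt(
        sum(
            float(v) ** 2
            for series in reference.series.values()
            for v in series
        )
        / max(1, sum(len(s) for s in reference.series.values()))
    )
    digits = _DOUBLE_DIGITS if precision == "double" else int(precision)
    floor = 10.0 * (10.0 ** -digits) * ref_scale

    entries: list[StudyEntry] = []
    for scheme in schemes:
        name = scheme if isinstance(scheme, str) else scheme.name
        for delta in deltas:
            result = run(scheme, delta)
            if result.diverged:
                entries.append(StudyEntry(name, delta, None, "divergent"))
                continue
            err = rmse(result, reference)
            flag = "floor" if err < floor else ""
            entries.append(StudyEntry(name, delta, err, flag))

    orders: dict[str, float | None] = {}
    for scheme in schemes:
        name = scheme if isinstance(scheme, str) else scheme.name
        pts = [
            (e.delta, e.rmse)
            for e in entries
            if e.scheme == name and e.flag == "" and e.rmse is not None and e.rmse > 0
        ]
        orders[name] = estimate_order(pts) if len(pts) >= 2 else None

    return AccuracyReport(
        reference_scheme=ref_scheme_in if isinstance(ref_scheme_in, str) else ref_scheme_in.name,
        reference_delta=ref_delta,
        precision=precision,
        entries=entries,
        orders=orders,
        floor=floor,
    )
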