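"""Stage 1: weave model equations into a scheme, producing a flat program.

Expansion walks the scheme's statements in order and scalarizes each one
over the model:

* input/output bindings and stage updates emit one assignment per state
  variable, with scheme symbols replaced by model names plus stage suffixes;
* the time binding and time updates emit one assignment for the time scalar;
* arithvar evaluations emit one assignment per algebraic model equation
  (topologically ordered), with the model right-hand side unfolded and every
  state/algebraic/time reference given the current stage suffix;
* derivative evaluations likewise unfold the differential equations.

The result is an ordered single-assignment scalar program advancing the
state from ``t`` to ``t + delta``.  Nothing is simplified, folded or
eliminated: the assignment count is the program's execution-step count and
the right-hand sides are the model's formulas verbatim.

Scalar naming is deterministic: ``<name>_<stage>`` for stage copies,
``kappa<i>_<name>`` for derivative scalars, ``<name>_in`` / ``<name>_out``
for the bindings, ``delta`` for the time step.  Constants are never
suffixed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import Diagnostic, ExpansionError
from .mapping import RelMap, validate_mapping
from .model_ir import (
    CellModel,
    Equation,
    MathExpr,
    Num,
    Var,
    expr_equal,
    expr_to_str,
    free_variables,
    substitute,
)
from .scheme import TecScheme, validate_scheme

DELTA_NAME = "delta"


@dataclass(frozen=True)
class ScalarAssignment:
    lhs: str
    rhs: MathExpr
    provenance: str = ""  # "<statement kind>[:<model lhs>]"

    def __str__(self) -> str:
        return f"{self.lhs} = {expr_to_str(self.rhs)}"


@dataclass
class FlatProgram:
    """Ordered single-assignment equation set for one time step."""

    diffvars: list[str]  # model state names, declaration order
    time_name: str  # model time-variable name (also the time input scalar)
    constants: list[str]  # free constant names, never suffixed
    assignments: list[ScalarAssignment]
    input_of: dict[str, str]  # diffvar -> input scalar (x -> x_in)
    output_of: dict[str, str]  # diffvar -> output scalar (x -> x_out)
    delta_name: str = DELTA_NAME

    @property
    def inputs(self) -> list[str]:
        return (
            [self.input_of[v] for v in self.diffvars]
            + [self.time_name, self.delta_name]
            + list(self.constants)
        )

    @property
    def outputs(self) -> list[str]:
        return [self.output_of[v] for v in self.diffvars]


def classify_equations(
    m: CellModel, rmap: RelMap
) -> tuple[list[Equation], list[Equation]]:
    """Split equations into (differential f, algebraic g).

    ``f`` is ordered by the map's diffvar order so derivative components stay
    aligned with the state components; ``g`` keeps document order.
    """
    by_var = {eq.lhs.var: eq for eq in m.diff_equations}
    f = [by_var[v] for v in rmap.diffvars if v in by_var]
    g = list(m.algebraic_equations)
    return f, g


def order_arith(g: list[Equation]) -> list[Equation]:
    """Topologically order algebraic equations by their mutual dependencies.

    Stable: equations with no unresolved dependencies keep document order.
    A dependency cycle means the model needs a simultaneous (DAE) solve,
    which explicit schemes cannot express.
    """
    names = [eq.lhs.name for eq in g]
    name_set = set(names)
    deps = {
        eq.lhs.name: free_variables(eq.rhs) & name_set for eq in g
    }
    ordered: list[Equation] = []
    placed: set[str] = set()
    pending = list(g)
    while pending:
        progressed = False
        for eq in list(pending):
            if deps[eq.lhs.name] <= placed:
                ordered.append(eq)
                placed.add(eq.lhs.name)
                pending.remove(eq)
                progressed = True
        if not progressed:
            cycle = sorted(eq.lhs.name for eq in pending)
            raise ExpansionError(
                f"algebraic equations form a dependency cycle {cycle}: "
                "simultaneous (DAE) systems are not supported"
            )
    return ordered


def expand(m: CellModel, s: TecScheme, rmap: RelMap) -> FlatProgram:
    """Apply the replacement algorithm; refuses to run on an invalid triple."""
    scheme_errors = [d for d in validate_scheme(s) if d.severity == "error"]
    if scheme_errors:
        raise ExpansionError(f"invalid scheme: {scheme_errors[0].message}")
    map_errors = [d for d in validate_mapping(rmap, m, s) if d.severity == "error"]
    if map_errors:
        raise ExpansionError(f"invalid mapping: {map_errors[0].message}")
    if m.nx == 0:
        raise ExpansionError("model has no differential equations; nothing to expand")

    diffvars = rmap.diffvars
    t = rmap.timevar or m.time_variable
    f, g_raw = classify_equations(m, rmap)
    g = order_arith(g_raw)
    constants = [n for n in rmap.constvars]

    def stage_name(var: str, i: int) -> str:
        return f"{var}_{i}"

    def kappa_name(i: int, var: str) -> str:
        return f"kappa{i}_{var}"

    def in_name(var: str) -> str:
        return f"{var}_in"

    def out_name(var: str) -> str:
        return f"{var}_out"

    # stage-i substitution for unfolded model right-hand sides
    def model_subst(i: int) -> dict[str, MathExpr]:
        sub: dict[str, MathExpr] = {}
        for v in diffvars:
            sub[v] = Var(stage_name(v, i))
        for eq in g:
            sub[eq.lhs.name] = Var(stage_name(eq.lhs.name, i))
        if t is not None:
            sub[t] = Var(stage_name(t, i))
        return sub  # constants map to themselves

    # scheme-symbol substitution for one state variable's formulas
    def scheme_subst(v: str) -> dict[str, MathExpr]:
        sub: dict[str, MathExpr] = {DELTA_NAME: Var(DELTA_NAME)}
        for i in range(0, s.n_stages + 1):
            sub[f"xi_{i}"] = Var(stage_name(v, i))
            if t is not None:
                sub[f"tau_{i}"] = Var(stage_name(t, i))
            if i >= 1:
                sub[f"kappa_{i}"] = Var(kappa_name(i, v))
        return sub

    def time_subst() -> dict[str, MathExpr]:
        sub: dict[str, MathExpr] = {DELTA_NAME: Var(DELTA_NAME)}
        for i in range(0, s.n_stages + 1):
            sub[f"tau_{i}"] = Var(stage_name(t, i))
        return sub

    assignments: list[ScalarAssignment] = []
    for st in s.statements:
        if st.kind == "input-binding":
            for v in diffvars:
                assignments.append(
                    ScalarAssignment(stage_name(v, 0), Var(in_name(v)), "input-binding")
                )
        elif st.kind == "time-binding":
            if t is not None:
                assignments.append(
                    ScalarAssignment(stage_name(t, 0), Var(t), "time-binding")
                )
        elif st.kind == "arith-eval":
            sub = model_subst(st.stage)
            for eq in g:
                assignments.append(
                    ScalarAssignment(
                        stage_name(eq.lhs.name, st.stage),
                        substitute(eq.rhs, sub),
                        f"arith-eval:{eq.lhs.name}",
                    )
                )
        elif st.kind == "deriv-eval":
            sub = model_subst(st.stage - 1)
            for eq in f:
                assignments.append(
                    ScalarAssignment(
                        kappa_name(st.stage, eq.lhs.var),
                        substitute(eq.rhs, sub),
                        f"deriv-eval:d{eq.lhs.var}/d{eq.lhs.bvar}",
                    )
                )
        elif st.kind == "stage-update":
            i = int(st.target.rsplit("_", 1)[1])
            for v in diffvars:
                assignments.append(
                    ScalarAssignment(
                        stage_name(v, i),
                        substitute(st.expr, scheme_subst(v)),
                        f"stage-update:{v}",
                    )
                )
        elif st.kind == "time-update":
            if t is not None:
                i = int(st.target.rsplit("_", 1)[1])
                assignments.append(
                    ScalarAssignment(
                        stage_name(t, i),
                        substitute(st.expr, time_subst()),
                        "time-update",
                    )
                )
        elif st.kind == "output-binding":
            for v in diffvars:
                rhs = (
                    Var(stage_name(v, s.n_stages))
                    if st.expr is None
                    else substitute(st.expr, scheme_subst(v))
                )
                assignments.append(
                    ScalarAssignment(out_name(v), rhs, f"output-binding:{v}")
                )

    # generated scalar names must not collide with bare names (constants, time,
    # delta) that stay unsuffixed in the program
    bare = set(constants) | {DELTA_NAME} | ({t} if t is not None else set())
    clash = bare & {a.lhs for a in assignments}
    if clash:
        raise ExpansionError(
            f"model variable name(s) {sorted(clash)} collide with generated "
            "scalar names; rename the variable(s)"
        )

    program = FlatProgram(
        diffvars=list(diffvars),
        time_name=t,
        constants=constants,
        assignments=assignments,
        input_of={v: in_name(v) for v in diffvars},
        output_of={v: out_name(v) for v in diffvars},
    )
    bad = check_well_formed(program)
    if bad:  # internal invariant: expansion output is always well formed
        raise ExpansionError(f"internal error, malformed expansion: {bad[0].message}")
    return program


def count_steps(p: FlatProgram) -> int:
    """Execution-step count: the number of scalar assignments."""
    return len(p.assignments)


def check_well_formed(p: FlatProgram) -> list[Diagnostic]:
    """Single-assignment and definition-before-use, in one linear scan."""
    diags: list[Diagnostic] = []
    defined = set(p.inputs)
    for a in p.assignments:
        for name in sorted(free_variables(a.rhs)):
            if name not in defined:
                diags.append(
                    Diagnostic(
                        "error", "expander", f"{name!r} used before definition in {a.lhs!r}"
                    )
                )
        if a.lhs in defined:
            diags.append(
                Diagnostic("error", "expander", f"duplicate assignment to {a.lhs!r}")
            )
        defined.add(a.lhs)
    for out in p.outputs:
        if out not in defined:
            diags.append(Diagnostic("error", "expander", f"output {out!r} never assigned"))
    return diags


def alpha_equivalent(
    p: FlatProgram,
    expected: list[tuple[str, MathExpr]],
    fixed_names: set[str] | None = None,
) -> bool:
    """Assignment-by-assignment equality up to bijective renaming of scalars.

    ``expected`` is an ordered list of (lhs, rhs) pairs.  Names in
    ``fixed_names`` (constants) must match verbatim; every other name is
    mapped bijectively on first encounter, left-hand sides pairing up
    positionally.
    """
    fixed = fixed_names if fixed_names is not None else set(p.constants)
    if len(p.assignments) != len(expected):
        return False
    fwd: dict[str, str] = {}
    bwd: dict[str, str] = {}

    def bind(a: str, b: str) -> bool:
        if a in fixed or b in fixed:
            return a == b
        if a in fwd:
            return fwd[a] == b
        if b in bwd:
            return False
        fwd[a], bwd[b] = b, a
        return True

    def eq_expr(x: MathExpr, y: MathExpr) -> bool:
        if type(x) is not type(y):
            return False
        if isinstance(x, Var):
            return bind(x.name, y.name)
        if isinstance(x, Num):
            return expr_equal(x, y)
        from .model_ir import BinOp, Call, Cmp, Piecewise

        cx, cy = x.children(), y.children()
        if isinstance(x, (BinOp, Cmp)) and x.op != y.op:
            return False
        if isinstance(x, Call) and x.func != y.func:
            return False
        if isinstance(x, Piecewise) and (
            len(x.pieces) != len(y.pieces)
            or (x.otherwise is None) != (y.otherwise is None)
        ):
            return False
        if len(cx) != len(cy):
            return False
        return all(eq_expr(a, b) for a, b in zip(cx, cy))

    for (a, (lhs_b, rhs_b)) in zip(p.assignments, expected):
        if not bind(a.lhs, lhs_b):
            return False
        if not eq_expr(a.rhs, rhs_b):
            return False
    return True
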