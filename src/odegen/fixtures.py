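"""Self-contained input documents: the FitzHugh-Nagumo triple, the builtin
scheme files, and reproducible random synthetic models for property tests.

The FitzHugh-Nagumo (FHN) model is the canonical two-variable excitable-cell
model:

    r     = x^3
    dx/dt = x - r/3.0 - y + a
    dy/dt = b*(x + c - d*y)

with membrane-like variable ``x``, recovery variable ``y``, the removable
algebraic variable ``r`` and constants ``a`` (applied current), ``b``, ``c``,
``d``.  Parameter defaults follow the classical FitzHugh parameterization
mapped onto this form (b=0.08, c=0.7, d=0.8, a=0.5, x(0)=-1.2, y(0)=-0.6);
they give a bounded excitable trajectory for every builtin scheme at time
steps of 0.1 and below.

Random models emulate the shape of biological ODE models at small scale:
damped state equations with mild polynomial/rational couplings, an acyclic
algebraic layer, and constants.  They do not emulate stiffness, units, or
multi-component structure.  Each generated model ships with ground-truth
roles and direct numeric evaluators of its ``f`` and ``g`` vectors computed
from the generator's own term lists, independent of the expression trees —
the oracle for expansion/interpretation tests.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

from .errors import FixtureError
from .model_ir import (
    BinOp,
    CellModel,
    Deriv,
    Equation,
    MathExpr,
    Num,
    Var,
    Variable,
    serialize_cellml,
)
from .mapping import RelMap, serialize_relml
from .scheme import BUILTIN_SCHEME_XML

# ---------------------------------------------------------------------------
# FitzHugh-Nagumo fixture
# ---------------------------------------------------------------------------

FHN_CONSTANTS = {"a": "0.5", "b": "0.08", "c": "0.7", "d": "0.8"}
FHN_INITIAL = {"x": "-1.2", "y": "-0.6"}


def fhn_model() -> CellModel:
    """The FHN model as an in-memory :class:`CellModel`."""
    x, y, r, a, b, c, d = (Var(n) for n in "xyrabcd")
    eq_r = Equation(r, BinOp("pow", x, Num("3")))
    eq_x = Equation(
        Deriv("x", "time"),
        BinOp(
            "add",
            BinOp("sub", BinOp("sub", x, BinOp("div", r, Num("3.0"))), y),
            a,
        ),
    )
    eq_y = Equation(
        Deriv("y", "time"),
        BinOp("mul", b, BinOp("sub", BinOp("add", x, c), BinOp("mul", d, y))),
    )
    variables = [
        Variable("x", FHN_INITIAL["x"], "dimensionless"),
        Variable("y", FHN_INITIAL["y"], "dimensionless"),
        Variable("r", None, "dimensionless"),
        Variable("a", FHN_CONSTANTS["a"], "dimensionless"),
        Variable("b", FHN_CONSTANTS["b"], "dimensionless"),
        Variable("c", FHN_CONSTANTS["c"], "dimensionless"),
        Variable("d", FHN_CONSTANTS["d"], "dimensionless"),
        Variable("time", None, "dimensionless"),
    ]
    return CellModel("fhn", variables, [eq_r, eq_x, eq_y], "time")


def fhn_cellml() -> str:
    """The FHN model as a CellML-style document."""
    return serialize_cellml(fhn_model())


def fhn_relml() -> str:
    """Role map for the FHN model: x, y states; r removable; a-d constants."""
    roles = {
        "x": "diffvar",
        "y": "diffvar",
        "dx/dtime": "derivativevar",
        "dy/dtime": "derivativevar",
        "r": "arithvar",
        "a": "constvar",
        "b": "constvar",
        "c": "constvar",
        "d": "constvar",
        "time": "timevar",
    }
    return serialize_relml(RelMap("fhn.cellml", "modified_euler.tecml.xml", roles))


def scheme_tecml(name: str) -> str:
    """The pinned TecML document for a builtin scheme."""
    try:
        return BUILTIN_SCHEME_XML[name]
    except KeyError:
        raise FixtureError(
            f"unknown scheme {name!r}; available: {', '.join(sorted(BUILTIN_SCHEME_XML))}"
        ) from None


# direct float evaluators of the FHN f and g vectors (hand arithmetic, not
# expression trees) — oracle for expansion and interpretation tests
def fhn_eval_g(state: dict, t: float) -> dict:
    return {"r": state["x"] ** 3}


def fhn_eval_f(state: dict, aux: dict, t: float) -> dict:
    a, b, c, d = (float(FHN_CONSTANTS[k]) for k in "abcd")
    return {
        "x": state["x"] - aux["r"] / 3.0 - state["y"] + a,
        "y": b * (state["x"] + c - d * state["y"]),
    }


# ---------------------------------------------------------------------------
# Random synthetic models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    seed: int
    nx: int = 2  # state variables
    ny: int = 1  # algebraic variables
    nz: int = 2  # constants
    depth: int = 2  # bound on terms per right-hand side
    name_prefix: str = ""  # prepended to every variable name


# one additive term of a right-hand side; ``kind`` selects the shape:
#   const: coef | lin: coef*v | prod: coef*v1*v2 | sq: coef*v^2
#   sat:   coef*v1/(1 + v2^2)   (denominator can never vanish)
#   exp:   coef*exp(0.2*v)
@dataclass(frozen=True)
class _Term:
    kind: str
    coef: str
    vars: tuple[str, ...] = ()


def _term_expr(t: _Term) -> MathExpr:
    c = Num(t.coef)
    if t.kind == "const":
        return c
    if t.kind == "lin":
        return BinOp("mul", c, Var(t.vars[0]))
    if t.kind == "prod":
        return BinOp("mul", c, BinOp("mul", Var(t.vars[0]), Var(t.vars[1])))
    if t.kind == "sq":
        return BinOp("mul", c, BinOp("pow", Var(t.vars[0]), Num("2")))
    if t.kind == "sat":
        denom = BinOp("add", Num("1"), BinOp("pow", Var(t.vars[1]), Num("2")))
        return BinOp("div", BinOp("mul", c, Var(t.vars[0])), denom)
    if t.kind == "exp":
        from .model_ir import Call

        return BinOp("mul", c, Call("exp", (BinOp("mul", Num("0.2"), Var(t.vars[0])),)))
    raise FixtureError(f"unknown term kind {t.kind!r}")


def _term_value(t: _Term, env: dict) -> float:
    c = float(t.coef)
    if t.kind == "const":
        return c
    if t.kind == "lin":
        return c * env[t.vars[0]]
    if t.kind == "prod":
        return c * env[t.vars[0]] * env[t.vars[1]]
    if t.kind == "sq":
        return c * env[t.vars[0]] ** 2
    if t.kind == "sat":
        return c * env[t.vars[0]] / (1.0 + env[t.vars[1]] ** 2)
    if t.kind == "exp":
        return c * math.exp(0.2 * env[t.vars[0]])
    raise FixtureError(f"unknown term kind {t.kind!r}")


def _sum_expr(terms: list[_Term]) -> MathExpr:
    expr = _term_expr(terms[0])
    for t in terms[1:]:
        expr = BinOp("add", expr, _term_expr(t))
    return expr


@dataclass
class GroundTruth:
    roles: dict[str, str]
    diffvars: list[str]
    arithvars: list[str]  # dependency (topological) order
    constants: dict[str, str]
    initial: dict[str, str]
    time_name: str
    eval_g: Callable[[dict, float], dict]
    eval_f: Callable[[dict, dict, float], dict]


def random_model(spec: ModelSpec) -> tuple[str, str, GroundTruth]:
    """Generate a reproducible (CellML text, RelML text, ground truth) triple.

    State equations carry a unit damping term ``-1.0*<state>`` plus mildly
    scaled couplings, so trajectories stay bounded at moderate time steps.
    The algebraic layer is a DAG by construction (each algebraic variable
    references only earlier ones), but the document order of the algebraic
    equations is shuffled so consumers must topologically sort them.
    """
    if spec.nx < 1:
        raise FixtureError("need at least one state variable")
    if spec.depth < 1:
        raise FixtureError("expression depth bound must be >= 1 for a model with equations")
    rng = random.Random(spec.seed)
    pre = spec.name_prefix
    t_name = f"{pre}time"
    states = [f"{pre}s{i + 1}" for i in range(spec.nx)]
    ariths = [f"{pre}w{i + 1}" for i in range(spec.ny)]
    consts = [f"{pre}c{i + 1}" for i in range(spec.nz)]

    def coef() -> str:
        return f"{rng.uniform(-0.5, 0.5):.2f}"

    def pick_term(pool: list[str], kinds: tuple[str, ...]) -> _Term:
        kind = rng.choice(kinds)
        if kind == "const":
            return _Term("const", coef())
        if kind in ("lin", "sq", "exp"):
            return _Term(kind, coef(), (rng.choice(pool),))
        return _Term(kind, coef(), (rng.choice(pool), rng.choice(pool)))

    deep_kinds = ("lin", "prod", "sq", "sat", "const", "exp")
    kinds = ("lin", "const") if spec.depth == 1 else deep_kinds

    # algebraic layer: w_i references states, constants, time, and w_j (j < i)
    g_terms: dict[str, list[_Term]] = {}
    for i, w in enumerate(ariths):
        pool = states + consts + [t_name] + ariths[:i]
        n_terms = rng.randint(1, spec.depth)
        g_terms[w] = [pick_term(pool, kinds) for _ in range(n_terms)]

    # state equations: damping plus scaled couplings over everything
    f_terms: dict[str, list[_Term]] = {}
    for s in states:
        pool = states + ariths + consts + [t_name]
        n_extra = rng.randint(0, spec.depth - 1)
        f_terms[s] = [_Term("lin", "-1.0", (s,))] + [
            pick_term(pool, kinds) for _ in range(n_extra)
        ]

    const_values = {c: f"{rng.uniform(-1.0, 1.0):.2f}" for c in consts}
    initial = {s: f"{rng.uniform(-1.0, 1.0):.2f}" for s in states}

    variables = (
        [Variable(s, initial[s], "dimensionless") for s in states]
        + [Variable(w, None, "dimensionless") for w in ariths]
        + [Variable(c, const_values[c], "dimensionless") for c in consts]
        + [Variable(t_name, None, "dimensionless")]
    )
    g_equations = [Equation(Var(w), _sum_expr(g_terms[w])) for w in ariths]
    rng.shuffle(g_equations)
    f_equations = [
        Equation(Deriv(s, t_name), _sum_expr(f_terms[s])) for s in states
    ]
    model = CellModel(
        f"synthetic_{spec.seed}", variables, g_equations + f_equations, t_name
    )

    roles: dict[str, str] = {}
    for s in states:
        roles[s] = "diffvar"
        roles[f"d{s}/d{t_name}"] = "derivativevar"
    for w in ariths:
        roles[w] = "arithvar"
    for c in consts:
        roles[c] = "constvar"
    roles[t_name] = "timevar"
    rmap = RelMap(f"{model.name}.cellml", None, roles)

    cvals = {c: float(v) for c, v in const_values.items()}

    def eval_g(state: dict, t: float) -> dict:
        env = dict(state)
        env.update(cvals)
        env[t_name] = t
        out: dict[str, float] = {}
        for w in ariths:  # generator order is the dependency order
            val = sum(_term_value(term, env) for term in g_terms[w])
            env[w] = out[w] = val
        return out

    def eval_f(state: dict, aux: dict, t: float) -> dict:
        env = dict(state)
        env.update(aux)
        env.update(cvals)
        env[t_name] = t
        return {
            s: sum(_term_value(term, env) for term in f_terms[s]) for s in states
        }

    gt = GroundTruth(
        roles=roles,
        diffvars=list(states),
        arithvars=list(ariths),
        constants=dict(const_values),
        initial=dict(initial),
        time_name=t_name,
        eval_g=eval_g,
        eval_f=eval_f,
    )
    return serialize_cellml(model), serialize_relml(rmap), gt


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------


def write_all(outdir: str | Path) -> list[Path]:
    """Write every fixture document to ``outdir``; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in [
        ("fhn.cellml", fhn_cellml()),
        ("fhn.relml.xml", fhn_relml()),
        *[(f"{n}.tecml.xml", xml) for n, xml in sorted(BUILTIN_SCHEME_XML.items())],
    ]:
        path = out / name
        path.write_text(text)
        written.append(path)
    return written
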