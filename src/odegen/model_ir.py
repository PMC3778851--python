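"""Cell-model intermediate representation.

A cell model is a flat collection of variables and single-assignment
equations: differential equations ``d<v>/d<t> = f_i(x, y, t, z)`` over the
state vector ``x`` and algebraic ("temporal") equations ``y_i = g_i(x, y, t,
z)`` that exist only to keep the model readable.  Equations are carried as
:class:`MathExpr` trees parsed from MathML content markup; numeric literals
are kept as exact decimal strings until evaluation so that high-precision
decimal arithmetic never sees a binary-float artifact.

The parser accepts CellML 1.0/1.1-style documents: any number of
``<component>`` elements, each with ``<variable>`` declarations and ``<math>``
blocks, plus ``<connection>`` maps that unify variables across components.
Units are recorded as free text and never interpreted.  Unsupported elements
(units definitions, reactions, metadata) are skipped with a warning.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from decimal import (
    Decimal,
    DivisionByZero,
    InvalidOperation,
    Overflow,
    localcontext,
)
from typing import Iterator, Mapping

from .errors import (
    Diagnostic,
    EvaluationError,
    ModelError,
    ParseError,
    UnsupportedConstructError,
)

# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

BINARY_OPS = ("add", "sub", "mul", "div", "pow")
FUNCTIONS = ("exp", "ln", "log", "root")
RELATIONS = ("eq", "neq", "lt", "leq", "gt", "geq")


class MathExpr:
    """Base class for expression-tree nodes.  All nodes are immutable."""

    __slots__ = ()

    def children(self) -> tuple["MathExpr", ...]:
        return ()


@dataclass(frozen=True)
class Num(MathExpr):
    """Numeric literal, stored as its exact decimal source string."""

    value: str

    def __post_init__(self):
        try:
            Decimal(self.value)
        except InvalidOperation as exc:  # pragma: no cover - guarded upstream
            raise ValueError(f"not a decimal literal: {self.value!r}") from exc


@dataclass(frozen=True)
class Var(MathExpr):
    """Reference to a declared model variable."""

    name: str


@dataclass(frozen=True)
class Deriv(MathExpr):
    """Derivative reference d<var>/d<bvar>; legal only as an equation lhs."""

    var: str
    bvar: str


@dataclass(frozen=True)
class Neg(MathExpr):
    operand: MathExpr

    def children(self):
        return (self.operand,)


@dataclass(frozen=True)
class BinOp(MathExpr):
    op: str  # one of BINARY_OPS
    left: MathExpr
    right: MathExpr

    def children(self):
        return (self.left, self.right)


@dataclass(frozen=True)
class Call(MathExpr):
    """Elementary function application.

    ``log`` may carry (base, arg); ``root`` may carry (degree, arg); with a
    single argument the defaults are base 10 and degree 2.
    """

    func: str  # one of FUNCTIONS
    args: tuple[MathExpr, ...]

    def children(self):
        return self.args


@dataclass(frozen=True)
class Cmp(MathExpr):
    """Relational node; appears only inside piecewise conditions."""

    op: str  # one of RELATIONS
    left: MathExpr
    right: MathExpr

    def children(self):
        return (self.left, self.right)


@dataclass(frozen=True)
class Piecewise(MathExpr):
    pieces: tuple[tuple[MathExpr, MathExpr], ...]  # (condition, value) pairs
    otherwise: MathExpr | None = None

    def children(self):
        out: list[MathExpr] = []
        for cond, val in self.pieces:
            out.extend((cond, val))
        if self.otherwise is not None:
            out.append(self.otherwise)
        return tuple(out)


def walk(e: MathExpr) -> Iterator[MathExpr]:
    """Pre-order traversal."""
    yield e
    for c in e.children():
        yield from walk(c)


def free_variables(e: MathExpr) -> set[str]:
    """Exactly the variable names referenced anywhere in ``e``."""
    return {n.name for n in walk(e) if isinstance(n, Var)}


def substitute(e: MathExpr, mapping: Mapping[str, MathExpr]) -> MathExpr:
    """Replace every ``Var(name)`` with ``mapping[name]`` where present."""
    if isinstance(e, Var):
        return mapping.get(e.name, e)
    if isinstance(e, (Num, Deriv)):
        return e
    if isinstance(e, Neg):
        return Neg(substitute(e.operand, mapping))
    if isinstance(e, BinOp):
        return BinOp(e.op, substitute(e.left, mapping), substitute(e.right, mapping))
    if isinstance(e, Call):
        return Call(e.func, tuple(substitute(a, mapping) for a in e.args))
    if isinstance(e, Cmp):
        return Cmp(e.op, substitute(e.left, mapping), substitute(e.right, mapping))
    if isinstance(e, Piecewise):
        return Piecewise(
            tuple(
                (substitute(c, mapping), substitute(v, mapping))
                for c, v in e.pieces
            ),
            None if e.otherwise is None else substitute(e.otherwise, mapping),
        )
    raise TypeError(f"unknown node {e!r}")


def expr_equal(a: MathExpr, b: MathExpr) -> bool:
    """Structural equality with numeric literals compared by decimal value."""
    if isinstance(a, Num) and isinstance(b, Num):
        return Decimal(a.value) == Decimal(b.value)
    if type(a) is not type(b):
        return False
    if isinstance(a, Var):
        return a.name == b.name
    if isinstance(a, Deriv):
        return (a.var, a.bvar) == (b.var, b.bvar)
    if isinstance(a, (BinOp, Cmp)) and a.op != b.op:
        return False
    if isinstance(a, Call) and a.func != b.func:
        return False
    ca, cb = a.children(), b.children()
    if isinstance(a, Piecewise):
        if len(a.pieces) != len(b.pieces) or (a.otherwise is None) != (
            b.otherwise is None
        ):
            return False
    if len(ca) != len(cb):
        return False
    return all(expr_equal(x, y) for x, y in zip(ca, cb))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate_expr(
    e: MathExpr,
    bindings: Mapping[str, Decimal | int | float | str],
    precision: int = 28,
) -> Decimal:
    """Evaluate ``e`` in a decimal context of ``precision`` significant digits.

    All free variables must be bound.  Division by zero and log/root domain
    violations raise :class:`EvaluationError`; the result is never a silent
    NaN.
    """
    if precision < 1:
        raise EvaluationError("precision must be >= 1")
    coerced = {k: _as_decimal(v) for k, v in bindings.items()}
    with localcontext() as ctx:
        ctx.prec = precision
        ctx.traps[InvalidOperation] = True
        ctx.traps[DivisionByZero] = True
        ctx.traps[Overflow] = True
        try:
            return _eval(e, coerced)
        except (InvalidOperation, DivisionByZero, Overflow, ValueError) as exc:
            raise EvaluationError(f"arithmetic/domain error: {exc}") from exc


def _as_decimal(v) -> Decimal:
    if isinstance(v, Decimal):
        return v
    if isinstance(v, float):
        # repr round-trips the double; Decimal(float) would print noise digits
        return Decimal(repr(v))
    return Decimal(v)


def _eval(e: MathExpr, b: Mapping[str, Decimal]) -> Decimal:
    if isinstance(e, Num):
        return +Decimal(e.value)  # unary plus applies the context rounding
    if isinstance(e, Var):
        try:
            return +b[e.name]
        except KeyError:
            raise EvaluationError(f"unbound variable {e.name!r}") from None
    if isinstance(e, Neg):
        return -_eval(e.operand, b)
    if isinstance(e, BinOp):
        x, y = _eval(e.left, b), _eval(e.right, b)
        if e.op == "add":
            return x + y
        if e.op == "sub":
            return x - y
        if e.op == "mul":
            return x * y
        if e.op == "div":
            return x / y
        if e.op == "pow":
            return x ** y
    if isinstance(e, Call):
        return _eval_call(e, b)
    if isinstance(e, Piecewise):
        for cond, val in e.pieces:
            if _eval_cond(cond, b):
                return _eval(val, b)
        if e.otherwise is None:
            raise EvaluationError("piecewise: no branch matched and no otherwise")
        return _eval(e.otherwise, b)
    if isinstance(e, Cmp):
        raise EvaluationError("relational expression outside a piecewise condition")
    if isinstance(e, Deriv):
        raise EvaluationError("derivative reference cannot be evaluated")
    raise TypeError(f"unknown node {e!r}")


def _eval_call(e: Call, b: Mapping[str, Decimal]) -> Decimal:
    args = [_eval(a, b) for a in e.args]
    if e.func == "exp":
        return args[0].exp()
    if e.func == "ln":
        if args[0] <= 0:
            raise EvaluationError(f"ln of non-positive value {args[0]}")
        return args[0].ln()
    if e.func == "log":
        base, x = (args[0], args[1]) if len(args) == 2 else (Decimal(10), args[0])
        if x <= 0 or base <= 0 or base == 1:
            raise EvaluationError(f"log domain violation (base={base}, x={x})")
        return x.ln() / base.ln()
    if e.func == "root":
        deg, x = (args[0], args[1]) if len(args) == 2 else (Decimal(2), args[0])
        if deg == 2:
            if x < 0:
                raise EvaluationError(f"square root of negative value {x}")
            return x.sqrt()
        if x < 0:
            raise EvaluationError(f"root of negative value {x}")
        if x == 0:
            return Decimal(0)
        return (x.ln() / deg).exp()
    raise EvaluationError(f"unknown function {e.func!r}")


def _eval_cond(e: MathExpr, b: Mapping[str, Decimal]) -> bool:
    if not isinstance(e, Cmp):
        raise EvaluationError("piecewise condition must be a relation")
    x, y = _eval(e.left, b), _eval(e.right, b)
    return {
        "eq": x == y,
        "neq": x != y,
        "lt": x < y,
        "leq": x <= y,
        "gt": x > y,
        "geq": x >= y,
    }[e.op]


# ---------------------------------------------------------------------------
# MathML content markup <-> MathExpr
# ---------------------------------------------------------------------------

MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_OP_TAGS = {
    "plus": "add",
    "minus": "sub",
    "times": "mul",
    "divide": "div",
    "power": "pow",
}
_REL_TAGS = {"eq": "eq", "neq": "neq", "lt": "lt", "leq": "leq", "gt": "gt", "geq": "geq"}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_mathml_expr(node: ET.Element) -> MathExpr:
    """Parse one MathML content-markup element into a :class:`MathExpr`.

    Supported subset: apply with plus/minus/times/divide/power, the relations
    eq/neq/lt/leq/gt/geq, exp/ln/log (with logbase)/root (with degree),
    piecewise/piece/otherwise, ci, cn, and diff with a bvar.  Anything else is
    an :class:`UnsupportedConstructError` — downstream stages must never see
    an unknown node.
    """
    tag = _local(node.tag)
    if tag == "math":
        kids = list(node)
        if len(kids) != 1:
            raise ParseError(f"<math> must contain exactly one expression, got {len(kids)}")
        return parse_mathml_expr(kids[0])
    if tag == "ci":
        name = (node.text or "").strip()
        if not name:
            raise ParseError("<ci> with empty name")
        return Var(name)
    if tag == "cn":
        text = (node.text or "").strip()
        if node.get("type") == "e-notation":
            kids = list(node)
            if len(kids) == 1 and _local(kids[0].tag) == "sep":
                text = text + "E" + (kids[0].tail or "").strip()
        try:
            Decimal(text)
        except InvalidOperation:
            raise ParseError(f"<cn> with non-decimal content {text!r}") from None
        return Num(text)
    if tag == "piecewise":
        pieces: list[tuple[MathExpr, MathExpr]] = []
        otherwise = None
        for child in node:
            ctag = _local(child.tag)
            if ctag == "piece":
                parts = list(child)
                if len(parts) != 2:
                    raise ParseError("<piece> needs value and condition")
                val, cond = parse_mathml_expr(parts[0]), parse_mathml_expr(parts[1])
                pieces.append((cond, val))
            elif ctag == "otherwise":
                parts = list(child)
                if len(parts) != 1:
                    raise ParseError("<otherwise> needs one child")
                otherwise = parse_mathml_expr(parts[0])
            else:
                raise UnsupportedConstructError(f"unsupported element <{ctag}> in piecewise")
        return Piecewise(tuple(pieces), otherwise)
    if tag == "apply":
        return _parse_apply(node)
    raise UnsupportedConstructError(f"unsupported MathML element <{tag}>")


def _parse_apply(node: ET.Element) -> MathExpr:
    kids = list(node)
    if not kids:
        raise ParseError("empty <apply>")
    head = _local(kids[0].tag)
    args = kids[1:]

    if head in _OP_TAGS:
        op = _OP_TAGS[head]
        if head == "minus" and len(args) == 1:
            return Neg(parse_mathml_expr(args[0]))
        if head in ("plus", "times"):
            if len(args) < 2:
                raise ParseError(f"<{head}> needs at least two operands")
            expr = parse_mathml_expr(args[0])
            for a in args[1:]:  # n-ary folds left-associatively
                expr = BinOp(op, expr, parse_mathml_expr(a))
            return expr
        if len(args) != 2:
            raise ParseError(f"<{head}> needs exactly two operands")
        return BinOp(op, parse_mathml_expr(args[0]), parse_mathml_expr(args[1]))

    if head in _REL_TAGS:
        if len(args) != 2:
            raise ParseError(f"<{head}> needs exactly two operands")
        return Cmp(_REL_TAGS[head], parse_mathml_expr(args[0]), parse_mathml_expr(args[1]))

    if head in ("exp", "ln"):
        if len(args) != 1:
            raise ParseError(f"<{head}> needs one argument")
        return Call(head, (parse_mathml_expr(args[0]),))
    if head == "log":
        base = None
        rest = []
        for a in args:
            if _local(a.tag) == "logbase":
                base = parse_mathml_expr(list(a)[0])
            else:
                rest.append(a)
        if len(rest) != 1:
            raise ParseError("<log> needs one argument")
        arg = parse_mathml_expr(rest[0])
        return Call("log", (base, arg) if base is not None else (arg,))
    if head == "root":
        degree = None
        rest = []
        for a in args:
            if _local(a.tag) == "degree":
                degree = parse_mathml_expr(list(a)[0])
            else:
                rest.append(a)
        if len(rest) != 1:
            raise ParseError("<root> needs one argument")
        arg = parse_mathml_expr(rest[0])
        return Call("root", (degree, arg) if degree is not None else (arg,))

    if head == "diff":
        bvar = None
        rest = []
        for a in args:
            if _local(a.tag) == "bvar":
                inner = [c for c in a if _local(c.tag) == "ci"]
                if len(inner) != 1:
                    raise ParseError("<bvar> must contain one <ci>")
                bvar = (inner[0].text or "").strip()
            else:
                rest.append(a)
        if bvar is None or len(rest) != 1 or _local(rest[0].tag) != "ci":
            raise ParseError("<diff> needs a <bvar> and one <ci>")
        return Deriv((rest[0].text or "").strip(), bvar)

    raise UnsupportedConstructError(f"unsupported MathML operator <{head}>")


def serialize_mathml_expr(e: MathExpr) -> ET.Element:
    """Inverse of :func:`parse_mathml_expr` (namespace-free element tree)."""
    if isinstance(e, Num):
        el = ET.Element("cn")
        el.text = e.value
        return el
    if isinstance(e, Var):
        el = ET.Element("ci")
        el.text = e.name
        return el
    if isinstance(e, Deriv):
        el = ET.Element("apply")
        ET.SubElement(el, "diff")
        bv = ET.SubElement(el, "bvar")
        ci = ET.SubElement(bv, "ci")
        ci.text = e.bvar
        ci2 = ET.SubElement(el, "ci")
        ci2.text = e.var
        return el
    if isinstance(e, Neg):
        el = ET.Element("apply")
        ET.SubElement(el, "minus")
        el.append(serialize_mathml_expr(e.operand))
        return el
    if isinstance(e, (BinOp, Cmp)):
        rev = {v: k for k, v in (_OP_TAGS if isinstance(e, BinOp) else _REL_TAGS).items()}
        el = ET.Element("apply")
        ET.SubElement(el, rev[e.op])
        el.append(serialize_mathml_expr(e.left))
        el.append(serialize_mathml_expr(e.right))
        return el
    if isinstance(e, Call):
        el = ET.Element("apply")
        ET.SubElement(el, e.func)
        args = e.args
        if e.func == "log" and len(args) == 2:
            lb = ET.SubElement(el, "logbase")
            lb.append(serialize_mathml_expr(args[0]))
            args = args[1:]
        elif e.func == "root" and len(args) == 2:
            dg = ET.SubElement(el, "degree")
            dg.append(serialize_mathml_expr(args[0]))
            args = args[1:]
        for a in args:
            el.append(serialize_mathml_expr(a))
        return el
    if isinstance(e, Piecewise):
        el = ET.Element("piecewise")
        for cond, val in e.pieces:
            pc = ET.SubElement(el, "piece")
            pc.append(serialize_mathml_expr(val))
            pc.append(serialize_mathml_expr(cond))
        if e.otherwise is not None:
            ow = ET.SubElement(el, "otherwise")
            ow.append(serialize_mathml_expr(e.otherwise))
        return el
    raise TypeError(f"unknown node {e!r}")


# ---------------------------------------------------------------------------
# Pretty printing and target-language rendering
# ---------------------------------------------------------------------------

_PREC = {"add": 1, "sub": 1, "mul": 2, "div": 2, "pow": 3}
_SYM = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "^"}
_CMPSYM = {"eq": "==", "neq": "!=", "lt": "<", "leq": "<=", "gt": ">", "geq": ">="}


def expr_to_str(e: MathExpr, parent_prec: int = 0) -> str:
    """Human-readable infix rendering with minimal parentheses."""
    if isinstance(e, Num):
        return e.value
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Deriv):
        return f"d{e.var}/d{e.bvar}"
    if isinstance(e, Neg):
        inner = expr_to_str(e.operand, 4)
        return f"-{inner}"
    if isinstance(e, BinOp):
        prec = _PREC[e.op]
        left = expr_to_str(e.left, prec)
        # right operand of - / ^ needs a higher binding level
        right = expr_to_str(e.right, prec + (0 if e.op in ("add", "mul") else 1))
        s = f"{left} {_SYM[e.op]} {right}"
        return f"({s})" if prec < parent_prec else s
    if isinstance(e, Cmp):
        return f"{expr_to_str(e.left, 1)} {_CMPSYM[e.op]} {expr_to_str(e.right, 1)}"
    if isinstance(e, Call):
        return f"{e.func}({', '.join(expr_to_str(a) for a in e.args)})"
    if isinstance(e, Piecewise):
        parts = [f"{expr_to_str(v)} if {expr_to_str(c)}" for c, v in e.pieces]
        if e.otherwise is not None:
            parts.append(f"{expr_to_str(e.otherwise)} otherwise")
        return "piecewise(" + "; ".join(parts) + ")"
    raise TypeError(f"unknown node {e!r}")


def expr_to_python(e: MathExpr, decimal_mode: bool) -> str:
    """Render as a Python expression.

    ``decimal_mode`` renders literals as ``Decimal('...')`` and elementary
    functions as Decimal methods; otherwise float literals and ``math.*``.
    """
    if isinstance(e, Num):
        if decimal_mode:
            return f"Decimal({e.value!r})"
        return repr(float(e.value))
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Neg):
        return f"(-{expr_to_python(e.operand, decimal_mode)})"
    if isinstance(e, BinOp):
        l = expr_to_python(e.left, decimal_mode)
        r = expr_to_python(e.right, decimal_mode)
        op = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "**"}[e.op]
        return f"({l} {op} {r})"
    if isinstance(e, Cmp):
        l = expr_to_python(e.left, decimal_mode)
        r = expr_to_python(e.right, decimal_mode)
        return f"({l} {_CMPSYM[e.op]} {r})"
    if isinstance(e, Call):
        args = [expr_to_python(a, decimal_mode) for a in e.args]
        if decimal_mode:
            if e.func == "exp":
                return f"({args[0]}).exp()"
            if e.func == "ln":
                return f"({args[0]}).ln()"
            if e.func == "log":
                if len(args) == 2:
                    return f"(({args[1]}).ln() / ({args[0]}).ln())"
                return f"({args[0]}).log10()"
            if e.func == "root":
                if len(args) == 2:
                    return f"(({args[1]}) ** (Decimal(1) / ({args[0]})))"
                return f"({args[0]}).sqrt()"
        else:
            if e.func == "exp":
                return f"math.exp({args[0]})"
            if e.func == "ln":
                return f"math.log({args[0]})"
            if e.func == "log":
                if len(args) == 2:
                    return f"(math.log({args[1]}) / math.log({args[0]}))"
                return f"math.log10({args[0]})"
            if e.func == "root":
                if len(args) == 2:
                    return f"(({args[1]}) ** (1.0 / ({args[0]})))"
                return f"math.sqrt({args[0]})"
    if isinstance(e, Piecewise):
        out = None
        if e.otherwise is not None:
            out = expr_to_python(e.otherwise, decimal_mode)
        else:
            out = "_no_branch()"
        for cond, val in reversed(e.pieces):
            c = expr_to_python(cond, decimal_mode)
            v = expr_to_python(val, decimal_mode)
            out = f"({v} if {c} else {out})"
        return out
    raise TypeError(f"cannot render {e!r}")


def expr_to_c(e: MathExpr) -> str:
    """Render as a C99 double-precision expression."""
    if isinstance(e, Num):
        return repr(float(e.value))
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Neg):
        return f"(-{expr_to_c(e.operand)})"
    if isinstance(e, BinOp):
        l, r = expr_to_c(e.left), expr_to_c(e.right)
        if e.op == "pow":
            return f"pow({l}, {r})"
        op = {"add": "+", "sub": "-", "mul": "*", "div": "/"}[e.op]
        return f"({l} {op} {r})"
    if isinstance(e, Cmp):
        return f"({expr_to_c(e.left)} {_CMPSYM[e.op]} {expr_to_c(e.right)})"
    if isinstance(e, Call):
        args = [expr_to_c(a) for a in e.args]
        if e.func == "exp":
            return f"exp({args[0]})"
        if e.func == "ln":
            return f"log({args[0]})"
        if e.func == "log":
            if len(args) == 2:
                return f"(log({args[1]}) / log({args[0]}))"
            return f"log10({args[0]})"
        if e.func == "root":
            if len(args) == 2:
                return f"pow({args[1]}, 1.0 / ({args[0]}))"
            return f"sqrt({args[0]})"
    if isinstance(e, Piecewise):
        out = expr_to_c(e.otherwise) if e.otherwise is not None else "(0.0/0.0)"
        for cond, val in reversed(e.pieces):
            out = f"({expr_to_c(cond)} ? {expr_to_c(val)} : {out})"
        return out
    raise TypeError(f"cannot render {e!r}")


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variable:
    name: str
    initial_value: str | None = None  # decimal string
    units: str | None = None  # recorded, never checked


@dataclass(frozen=True)
class Equation:
    """Single-assignment equation: lhs is a Var or Deriv, rhs a MathExpr."""

    lhs: MathExpr
    rhs: MathExpr

    @property
    def is_differential(self) -> bool:
        return isinstance(self.lhs, Deriv)


@dataclass
class CellModel:
    name: str
    variables: list[Variable]
    equations: list[Equation]
    time_variable: str | None = None
    warnings: list[Diagnostic] = field(default_factory=list, compare=False)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def diff_equations(self) -> list[Equation]:
        return [e for e in self.equations if e.is_differential]

    @property
    def algebraic_equations(self) -> list[Equation]:
        return [e for e in self.equations if not e.is_differential]

    @property
    def nx(self) -> int:
        return len(self.diff_equations)

    @property
    def ny(self) -> int:
        return len(self.algebraic_equations)

    @property
    def is_simulable(self) -> bool:
        return self.nx >= 1

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def initial_values(self) -> dict[str, str]:
        return {
            v.name: v.initial_value
            for v in self.variables
            if v.initial_value is not None
        }


# ---------------------------------------------------------------------------
# CellML-style parsing
# ---------------------------------------------------------------------------

_SKIPPED_ELEMENTS = {
    "units",
    "reaction",
    "RDF",
    "documentation",
    "import",
    "group",
}


def parse_cellml(document: str) -> CellModel:
    """Parse a CellML 1.0/1.1-style document into a flat :class:`CellModel`.

    Components are flattened into one namespace: variables connected by
    ``<connection>`` maps are unified under one name; unconnected variables
    whose names collide across components are qualified as
    ``<component>_<name>``.  Every equation must have a single-term lhs (a
    bare ``<ci>`` or a ``<diff>`` application).
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed XML: {exc.msg if hasattr(exc, 'msg') else exc}", line=line) from exc

    if _local(root.tag) != "model":
        raise ParseError(f"root element must be <model>, got <{_local(root.tag)}>")
    model_name = root.get("name", "unnamed")
    warnings: list[Diagnostic] = []

    components: dict[str, list[ET.Element]] = {}
    connections: list[ET.Element] = []
    for child in root:
        tag = _local(child.tag)
        if tag == "component":
            cname = child.get("name", f"component{len(components)}")
            components[cname] = list(child)
        elif tag == "connection":
            connections.append(child)
        elif tag in _SKIPPED_ELEMENTS:
            warnings.append(
                Diagnostic("warning", "model_ir", f"skipped unsupported element <{tag}>")
            )
        else:
            warnings.append(
                Diagnostic("warning", "model_ir", f"skipped unknown element <{tag}>")
            )

    # collect raw variables per component
    raw_vars: dict[tuple[str, str], Variable] = {}
    maths: list[tuple[str, ET.Element]] = []
    for cname, children in components.items():
        for el in children:
            tag = _local(el.tag)
            if tag == "variable":
                vname = el.get("name")
                if not vname:
                    raise ParseError(f"<variable> without name in component {cname!r}")
                if (cname, vname) in raw_vars:
                    raise ModelError(
                        f"duplicate variable {vname!r} in component {cname!r}"
                    )
                raw_vars[(cname, vname)] = Variable(
                    vname, el.get("initial_value"), el.get("units")
                )
            elif tag == "math":
                maths.append((cname, el))
            elif tag in _SKIPPED_ELEMENTS:
                warnings.append(
                    Diagnostic(
                        "warning", "model_ir", f"skipped unsupported element <{tag}>"
                    )
                )
            else:
                warnings.append(
                    Diagnostic("warning", "model_ir", f"skipped unknown element <{tag}>")
                )

    flat_name, variables = _flatten_components(raw_vars, connections)

    equations: list[Equation] = []
    for cname, math_el in maths:
        rename = {
            local: flat
            for (comp, local), flat in flat_name.items()
            if comp == cname
        }
        for eq_el in math_el:
            if _local(eq_el.tag) != "apply":
                raise ParseError(
                    f"<math> children must be <apply> equations, got <{_local(eq_el.tag)}>"
                )
            expr = parse_mathml_expr(eq_el)
            if not (isinstance(expr, Cmp) and expr.op == "eq"):
                raise ModelError("top-level equation must be an <eq> application")
            lhs, rhs = expr.left, expr.right
            if not isinstance(lhs, (Var, Deriv)):
                raise ModelError(
                    "equation left-hand side must be a single variable or "
                    f"derivative reference, got: {expr_to_str(lhs)}"
                )
            lhs = _rename_node(lhs, rename)
            rhs = substitute(rhs, {k: Var(v) for k, v in rename.items()})
            equations.append(Equation(lhs, rhs))

    time_var = _detect_time_variable(equations)
    model = CellModel(model_name, variables, equations, time_var, warnings)
    diags = [d for d in validate_model(model) if d.severity == "error"]
    if diags:
        raise ModelError("; ".join(d.message for d in diags))
    return model


def _rename_node(lhs: MathExpr, rename: Mapping[str, str]) -> MathExpr:
    if isinstance(lhs, Var):
        return Var(rename.get(lhs.name, lhs.name))
    assert isinstance(lhs, Deriv)
    return Deriv(rename.get(lhs.var, lhs.var), rename.get(lhs.bvar, lhs.bvar))


def _flatten_components(
    raw_vars: dict[tuple[str, str], Variable],
    connections: list[ET.Element],
) -> tuple[dict[tuple[str, str], str], list[Variable]]:
    """Unify connected variables and qualify colliding names."""
    parent: dict[tuple[str, str], tuple[str, str]] = {k: k for k in raw_vars}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for conn in connections:
        comps = None
        for el in conn:
            tag = _local(el.tag)
            if tag == "map_components":
                comps = (el.get("component_1"), el.get("component_2"))
            elif tag == "map_variables":
                if comps is None:
                    raise ParseError("<map_variables> before <map_components>")
                a = (comps[0], el.get("variable_1"))
                b = (comps[1], el.get("variable_2"))
                if a not in raw_vars or b not in raw_vars:
                    raise ModelError(
                        f"connection references undeclared variable: {a} / {b}"
                    )
                union(a, b)

    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for k in raw_vars:
        groups.setdefault(find(k), []).append(k)

    # choose a flat name per group; qualify on collision
    name_count: dict[str, int] = {}
    for rep in groups:
        name_count[rep[1]] = name_count.get(rep[1], 0) + 1

    flat_name: dict[tuple[str, str], str] = {}
    variables: list[Variable] = []
    for rep, members in groups.items():
        base = rep[1]
        flat = base if name_count[base] == 1 else f"{rep[0]}_{base}"
        init = None
        units = None
        for m in members:
            v = raw_vars[m]
            if v.initial_value is not None:
                if init is not None and Decimal(init) != Decimal(v.initial_value):
                    raise ModelError(
                        f"conflicting initial values for connected variable {flat!r}"
                    )
                init = v.initial_value
            units = units or v.units
        for m in members:
            flat_name[m] = flat
        variables.append(Variable(flat, init, units))
    variables.sort(key=lambda v: min(i for i, k in enumerate(raw_vars) if flat_name[k] == v.name))
    return flat_name, variables


def _detect_time_variable(equations: list[Equation]) -> str | None:
    bvars = {e.lhs.bvar for e in equations if isinstance(e.lhs, Deriv)}
    if len(bvars) > 1:
        raise ModelError(
            f"multiple independent variables in derivatives: {sorted(bvars)} "
            "(only a single bound variable is supported)"
        )
    return next(iter(bvars), None)


def validate_model(m: CellModel) -> list[Diagnostic]:
    """Check every CellModel invariant; an empty list means the model is valid."""
    diags: list[Diagnostic] = []
    declared = set(m.variable_names)
    seen_names = set()
    for v in m.variables:
        if v.name in seen_names:
            diags.append(Diagnostic("error", "model_ir", f"duplicate variable {v.name!r}"))
        seen_names.add(v.name)

    seen_lhs: set[str] = set()
    for eq in m.equations:
        if isinstance(eq.lhs, Var):
            key = eq.lhs.name
            if eq.lhs.name not in declared:
                diags.append(
                    Diagnostic("error", "model_ir", f"equation assigns undeclared variable {eq.lhs.name!r}")
                )
        elif isinstance(eq.lhs, Deriv):
            key = f"d{eq.lhs.var}/d{eq.lhs.bvar}"
            if eq.lhs.var not in declared:
                diags.append(
                    Diagnostic("error", "model_ir", f"derivative of undeclared variable {eq.lhs.var!r}")
                )
            if m.time_variable is not None and eq.lhs.bvar != m.time_variable:
                diags.append(
                    Diagnostic("error", "model_ir",
                               f"derivative bound variable {eq.lhs.bvar!r} is not the time variable {m.time_variable!r}")
                )
            if eq.lhs.bvar not in declared:
                diags.append(
                    Diagnostic("error", "model_ir", f"undeclared bound variable {eq.lhs.bvar!r}")
                )
        else:
            diags.append(
                Diagnostic("error", "model_ir",
                           f"equation left-hand side must be a single term, got: {expr_to_str(eq.lhs)}")
            )
            continue
        if key in seen_lhs:
            diags.append(Diagnostic("error", "model_ir", f"duplicate equation for {key}"))
        seen_lhs.add(key)

        for node in walk(eq.rhs):
            if isinstance(node, Deriv):
                diags.append(
                    Diagnostic("error", "model_ir",
                               "derivative reference in right-hand side is not supported")
                )
        for name in sorted(free_variables(eq.rhs)):
            if name not in declared:
                diags.append(
                    Diagnostic("error", "model_ir", f"reference to undeclared variable {name!r}")
                )

    if not m.is_simulable:
        diags.append(
            Diagnostic("warning", "model_ir", "model has no differential equations; not simulable")
        )
    return diags


# ---------------------------------------------------------------------------
# Canonical re-serialization (round-trip support)
# ---------------------------------------------------------------------------

CELLML_NS = "http://www.cellml.org/cellml/1.0#"


def serialize_cellml(m: CellModel) -> str:
    """Render the flattened model back to a single-component document."""
    root = ET.Element("model", {"name": m.name, "xmlns": CELLML_NS})
    comp = ET.SubElement(root, "component", {"name": "main"})
    for v in m.variables:
        attrs = {"name": v.name}
        if v.initial_value is not None:
            attrs["initial_value"] = v.initial_value
        if v.units is not None:
            attrs["units"] = v.units
        ET.SubElement(comp, "variable", attrs)
    if m.equations:
        math = ET.SubElement(comp, "math", {"xmlns": MATHML_NS})
        for eq in m.equations:
            apply_el = ET.SubElement(math, "apply")
            ET.SubElement(apply_el, "eq")
            apply_el.append(serialize_mathml_expr(eq.lhs))
            apply_el.append(serialize_mathml_expr(eq.rhs))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def models_structurally_equal(a: CellModel, b: CellModel) -> bool:
    """Identity up to whitespace and numeric-literal normalization."""
    if a.name != b.name or a.time_variable != b.time_variable:
        return False
    if len(a.variables) != len(b.variables) or len(a.equations) != len(b.equations):
        return False
    for va, vb in zip(a.variables, b.variables):
        if va.name != vb.name or va.units != vb.units:
            return False
        ia, ib = va.initial_value, vb.initial_value
        if (ia is None) != (ib is None):
            return False
        if ia is not None and Decimal(ia) != Decimal(ib):
            return False
    return all(
        expr_equal(ea.lhs, eb.lhs) and expr_equal(ea.rhs, eb.rhs)
        for ea, eb in zip(a.equations, b.equations)
    )
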