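"""Explicit ODE-solving-scheme descriptions (TecML dialect).

A scheme is a typed, ordered list of statements that advance the state
vector of a model from ``t`` to ``t + delta``:

* ``input-binding``   — xi_0 = current state (one scalar per state variable)
* ``time-binding``    — tau_0 = t
* ``arith-eval``      — iota_i = Gamma(xi_i, iota_i, tau_i, zeta): one scalar
  per algebraic model equation, unfolded at expansion time
* ``deriv-eval``      — kappa_{i+1} = Phi(xi_i, iota_i, tau_i, zeta): one
  scalar per differential model equation, unfolded at expansion time
* ``stage-update``    — xi_i = sigma_i(Xi, pi, delta), an explicit formula
* ``time-update``     — tau_i = T_i(t, delta), an explicit formula
* ``output-binding``  — state at t+delta = xi_{N} (or an explicit combine
  formula, as in classical RK4)

Scheme formulas are MathML content markup over the symbol names ``xi_<i>``,
``kappa_<i>``, ``tau_<i>`` and ``delta``.  Only explicit schemes are
representable: every statement may reference only symbols produced by an
earlier statement, so implicit and adaptive methods are rejected at
validation.

The four builtin schemes (forward Euler, modified Euler / Heun, midpoint
RK2, classical RK4) are pinned XML documents.  Their statement layouts fix
the execution-step counting convention: Euler carries its time update as a
separate statement, modified Euler keeps the final combine and the output
bindings as separate statements, and RK4 folds the final combine into the
output bindings.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .errors import Diagnostic, ParseError, SchemeError
from .model_ir import (
    MathExpr,
    free_variables,
    parse_mathml_expr,
    serialize_mathml_expr,
    _local,
)

ROLES = ("diffvar", "derivativevar", "arithvar", "constvar", "timevar", "deltatimevar")

STATEMENT_KINDS = (
    "input-binding",
    "time-binding",
    "arith-eval",
    "deriv-eval",
    "stage-update",
    "time-update",
    "output-binding",
)

_ROLE_OF_BASE = {
    "xi": "diffvar",
    "kappa": "derivativevar",
    "iota": "arithvar",
    "tau": "timevar",
    "delta": "deltatimevar",
    "zeta": "constvar",
}

_SYMBOL_RE = re.compile(r"^(xi|kappa|iota|tau)_(\d+)$|^delta$")


@dataclass(frozen=True)
class SchemeSymbol:
    """A stage-indexed scheme symbol, e.g. xi_1 or kappa_2."""

    base: str  # xi | kappa | iota | tau | delta | zeta
    stage: int | None = None

    @property
    def role(self) -> str:
        return _ROLE_OF_BASE[self.base]

    @property
    def name(self) -> str:
        return self.base if self.stage is None else f"{self.base}_{self.stage}"


def parse_symbol(name: str) -> SchemeSymbol:
    m = _SYMBOL_RE.match(name)
    if not m:
        raise SchemeError(f"not a scheme symbol: {name!r}")
    if name == "delta":
        return SchemeSymbol("delta")
    return SchemeSymbol(m.group(1), int(m.group(2)))


@dataclass(frozen=True)
class SchemeStatement:
    kind: str
    stage: int | None = None  # arith-eval: stage i; deriv-eval: kappa index i+1
    target: str | None = None  # stage-update / time-update: "xi_i" or "tau_i"
    expr: MathExpr | None = None  # stage/time updates and optional output combine


@dataclass
class TecScheme:
    name: str
    n_stages: int  # N_xi: highest stage index of the state vector
    statements: list[SchemeStatement]

    @property
    def uses_arithvars(self) -> bool:
        return any(s.kind == "arith-eval" for s in self.statements)


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------


def parse_tecml(document: str) -> TecScheme:
    """Parse a TecML document; statement order is document order."""
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed XML: {exc}", line=line) from exc
    if _local(root.tag) != "tecml":
        raise SchemeError(f"root element must be <tecml>, got <{_local(root.tag)}>")
    name = root.get("name", "unnamed")
    try:
        n_stages = int(root.get("stages", ""))
    except ValueError:
        raise SchemeError("<tecml> needs an integer 'stages' attribute") from None

    statements: list[SchemeStatement] = []
    for child in root:
        tag = _local(child.tag)
        if tag == "symbols":
            for sym in child:
                role = sym.get("role")
                if role not in ROLES:
                    raise SchemeError(f"unknown symbol role {role!r}")
                base = sym.get("base")
                if base not in _ROLE_OF_BASE or _ROLE_OF_BASE[base] != role:
                    raise SchemeError(
                        f"symbol base {base!r} does not match role {role!r}"
                    )
            continue
        if tag != "step":
            raise SchemeError(f"unexpected element <{tag}> in <tecml>")
        kind = child.get("kind")
        if kind not in STATEMENT_KINDS:
            raise SchemeError(f"unknown statement kind {kind!r}")
        stage = child.get("stage")
        stage_i = int(stage) if stage is not None else None
        target = child.get("target")
        expr = None
        math_children = [c for c in child if _local(c.tag) == "math"]
        if math_children:
            expr = parse_mathml_expr(math_children[0])
        statements.append(SchemeStatement(kind, stage_i, target, expr))

    s = TecScheme(name, n_stages, statements)
    diags = [d for d in validate_scheme(s) if d.severity == "error"]
    if diags:
        raise SchemeError("; ".join(d.message for d in diags))
    return s


def serialize_tecml(s: TecScheme) -> str:
    root = ET.Element("tecml", {"name": s.name, "stages": str(s.n_stages)})
    symbols = ET.SubElement(root, "symbols")
    for base, role in _ROLE_OF_BASE.items():
        ET.SubElement(symbols, "symbol", {"base": base, "role": role})
    for st in s.statements:
        attrs = {"kind": st.kind}
        if st.stage is not None:
            attrs["stage"] = str(st.stage)
        if st.target is not None:
            attrs["target"] = st.target
        step = ET.SubElement(root, "step", attrs)
        if st.expr is not None:
            math = ET.SubElement(step, "math")
            math.append(serialize_mathml_expr(st.expr))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_scheme(s: TecScheme) -> list[Diagnostic]:
    """Empty diagnostics iff all scheme invariants hold.

    Checked: exactly one input binding and one output binding; every symbol
    referenced by a formula was produced by an earlier statement
    (definition-before-use, which also rejects implicit methods); stage
    indices within bounds; arith/deriv evaluations precede the statements
    that consume them.
    """
    d: list[Diagnostic] = []

    def err(msg: str):
        d.append(Diagnostic("error", "scheme", msg))

    inputs = [st for st in s.statements if st.kind == "input-binding"]
    outputs = [st for st in s.statements if st.kind == "output-binding"]
    if len(inputs) != 1:
        err(f"expected exactly one input-binding, found {len(inputs)}")
    if len(outputs) != 1:
        err(f"expected exactly one output-binding, found {len(outputs)}")
    if outputs and s.statements and s.statements[-1].kind != "output-binding":
        err("output-binding must be the final statement")

    has_arith = s.uses_arithvars
    defined: set[str] = {"delta"}

    for idx, st in enumerate(s.statements):
        where = f"statement {idx + 1} ({st.kind})"
        if st.kind == "input-binding":
            defined.add("xi_0")
        elif st.kind == "time-binding":
            defined.add("tau_0")
        elif st.kind == "arith-eval":
            if st.stage is None or not (0 <= st.stage <= s.n_stages):
                err(f"{where}: arith-eval needs a stage in [0, {s.n_stages}]")
                continue
            if f"xi_{st.stage}" not in defined:
                err(f"{where}: evaluates at stage {st.stage} before xi_{st.stage} is defined")
            defined.add(f"iota_{st.stage}")
        elif st.kind == "deriv-eval":
            if st.stage is None or not (1 <= st.stage <= s.n_stages):
                err(f"{where}: deriv-eval needs a kappa index in [1, {s.n_stages}]")
                continue
            at = st.stage - 1  # kappa_{i+1} is evaluated at stage i
            if f"xi_{at}" not in defined:
                err(f"{where}: kappa_{st.stage} uses xi_{at} before it is defined")
            if has_arith and f"iota_{at}" not in defined:
                err(f"{where}: kappa_{st.stage} uses iota_{at} before it is defined")
            defined.add(f"kappa_{st.stage}")
        elif st.kind in ("stage-update", "time-update"):
            base = "xi" if st.kind == "stage-update" else "tau"
            if st.target is None:
                err(f"{where}: missing target")
                continue
            try:
                tsym = parse_symbol(st.target)
            except SchemeError:
                err(f"{where}: bad target {st.target!r}")
                continue
            if tsym.base != base or tsym.stage is None or not (
                1 <= tsym.stage <= s.n_stages
            ):
                err(f"{where}: target {st.target!r} invalid for {st.kind}")
                continue
            if st.expr is None:
                err(f"{where}: missing formula")
                continue
            _check_refs(st.expr, defined, where, err)
            defined.add(st.target)
        elif st.kind == "output-binding":
            if st.expr is not None:
                _check_refs(st.expr, defined, where, err)
            elif f"xi_{s.n_stages}" not in defined:
                err(f"{where}: xi_{s.n_stages} is not defined at the output binding")
    return d


def _check_refs(expr: MathExpr, defined: set[str], where: str, err) -> None:
    for name in sorted(free_variables(expr)):
        try:
            parse_symbol(name)
        except SchemeError:
            err(f"{where}: unknown symbol {name!r} in formula")
            continue
        if name not in defined:
            err(f"{where}: use of {name} before definition")


# ---------------------------------------------------------------------------
# Builtin schemes (pinned documents)
# ---------------------------------------------------------------------------


def _math(expr_xml: str) -> str:
    return f"<math>{expr_xml}</math>"


def _ci(n: str) -> str:
    return f"<ci>{n}</ci>"


def _times(*xs: str) -> str:
    return "<apply><times/>" + "".join(xs) + "</apply>"


def _plus(*xs: str) -> str:
    return "<apply><plus/>" + "".join(xs) + "</apply>"


def _div(a: str, b: str) -> str:
    return f"<apply><divide/>{a}{b}</apply>"


_SYMBOLS_XML = (
    "<symbols>"
    '<symbol base="xi" role="diffvar"/>'
    '<symbol base="kappa" role="derivativevar"/>'
    '<symbol base="iota" role="arithvar"/>'
    '<symbol base="tau" role="timevar"/>'
    '<symbol base="delta" role="deltatimevar"/>'
    '<symbol base="zeta" role="constvar"/>'
    "</symbols>"
)

_EULER_XML = (
    '<tecml name="euler" stages="1">'
    + _SYMBOLS_XML
    + '<step kind="input-binding"/>'
    + '<step kind="time-binding"/>'
    + '<step kind="arith-eval" stage="0"/>'
    + '<step kind="deriv-eval" stage="1"/>'
    + '<step kind="stage-update" target="xi_1">'
    + _math(_plus(_ci("xi_0"), _times(_ci("kappa_1"), _ci("delta"))))
    + "</step>"
    + '<step kind="time-update" target="tau_1">'
    + _math(_plus(_ci("tau_0"), _ci("delta")))
    + "</step>"
    + '<step kind="output-binding"/>'
    + "</tecml>"
)

_MODIFIED_EULER_XML = (
    '<tecml name="modified_euler" stages="2">'
    + _SYMBOLS_XML
    + '<step kind="input-binding"/>'
    + '<step kind="time-binding"/>'
    + '<step kind="arith-eval" stage="0"/>'
    + '<step kind="deriv-eval" stage="1"/>'
    + '<step kind="stage-update" target="xi_1">'
    + _math(_plus(_ci("xi_0"), _times(_ci("kappa_1"), _ci("delta"))))
    + "</step>"
    + '<step kind="time-update" target="tau_1">'
    + _math(_plus(_ci("tau_0"), _ci("delta")))
    + "</step>"
    + '<step kind="arith-eval" stage="1"/>'
    + '<step kind="deriv-eval" stage="2"/>'
    + '<step kind="stage-update" target="xi_2">'
    + _math(
        _plus(
            _ci("xi_0"),
            _times(
                _times("<cn>0.5</cn>", _plus(_ci("kappa_1"), _ci("kappa_2"))),
                _ci("delta"),
            ),
        )
    )
    + "</step>"
    + '<step kind="output-binding"/>'
    + "</tecml>"
)

_RK2_XML = (
    '<tecml name="rk2" stages="2">'
    + _SYMBOLS_XML
    + '<step kind="input-binding"/>'
    + '<step kind="time-binding"/>'
    + '<step kind="arith-eval" stage="0"/>'
    + '<step kind="deriv-eval" stage="1"/>'
    + '<step kind="stage-update" target="xi_1">'
    + _math(
        _plus(
            _ci("xi_0"),
            _times(_times("<cn>0.5</cn>", _ci("kappa_1")), _ci("delta")),
        )
    )
    + "</step>"
    + '<step kind="time-update" target="tau_1">'
    + _math(_plus(_ci("tau_0"), _times("<cn>0.5</cn>", _ci("delta"))))
    + "</step>"
    + '<step kind="arith-eval" stage="1"/>'
    + '<step kind="deriv-eval" stage="2"/>'
    + '<step kind="output-binding">'
    + _math(_plus(_ci("xi_0"), _times(_ci("kappa_2"), _ci("delta"))))
    + "</step>"
    + "</tecml>"
)


def _rk4_xml() -> str:
    half = lambda k: _math(
        _plus(_ci("xi_0"), _times(_times("<cn>0.5</cn>", _ci(k)), _ci("delta")))
    )
    half_t = _math(_plus(_ci("tau_0"), _times("<cn>0.5</cn>", _ci("delta"))))
    full_t = _math(_plus(_ci("tau_0"), _ci("delta")))
    combine = _math(
        _plus(
            _ci("xi_0"),
            _div(
                _times(
                    _plus(
                        _ci("kappa_1"),
                        _times("<cn>2</cn>", _ci("kappa_2")),
                        _times("<cn>2</cn>", _ci("kappa_3")),
                        _ci("kappa_4"),
                    ),
                    _ci("delta"),
                ),
                "<cn>6</cn>",
            ),
        )
    )
    return (
        '<tecml name="rk4" stages="4">'
        + _SYMBOLS_XML
        + '<step kind="input-binding"/>'
        + '<step kind="time-binding"/>'
        + '<step kind="arith-eval" stage="0"/>'
        + '<step kind="deriv-eval" stage="1"/>'
        + '<step kind="stage-update" target="xi_1">' + half("kappa_1") + "</step>"
        + '<step kind="time-update" target="tau_1">' + half_t + "</step>"
        + '<step kind="arith-eval" stage="1"/>'
        + '<step kind="deriv-eval" stage="2"/>'
        + '<step kind="stage-update" target="xi_2">' + half("kappa_2") + "</step>"
        + '<step kind="time-update" target="tau_2">' + half_t + "</step>"
        + '<step kind="arith-eval" stage="2"/>'
        + '<step kind="deriv-eval" stage="3"/>'
        + '<step kind="stage-update" target="xi_3">'
        + _math(_plus(_ci("xi_0"), _times(_ci("kappa_3"), _ci("delta"))))
        + "</step>"
        + '<step kind="time-update" target="tau_3">' + full_t + "</step>"
        + '<step kind="arith-eval" stage="3"/>'
        + '<step kind="deriv-eval" stage="4"/>'
        + '<step kind="output-binding">' + combine + "</step>"
        + "</tecml>"
    )


BUILTIN_SCHEME_XML: dict[str, str] = {
    "euler": _EULER_XML,
    "modified_euler": _MODIFIED_EULER_XML,
    "rk2": _RK2_XML,
    "rk4": _rk4_xml(),
}


def builtin_scheme(name: str) -> TecScheme:
    """Return one of the pinned schemes: euler, modified_euler, rk2, rk4."""
    try:
        xml = BUILTIN_SCHEME_XML[name]
    except KeyError:
        raise SchemeError(
            f"unknown scheme {name!r}; available: {', '.join(sorted(BUILTIN_SCHEME_XML))}"
        ) from None
    return parse_tecml(xml)
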