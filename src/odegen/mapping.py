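"""Variable-role maps (RelML dialect) binding model variables to scheme roles.

A role map assigns each model variable one of the six scheme roles:
state variables (``diffvar``) and their paired derivatives
(``derivativevar``, named ``d<var>/d<time>``), removable algebraic variables
(``arithvar``), constants (``constvar``), the time variable (``timevar``)
and the time step (``deltatimevar``).  Equation classes are always derived
from the shape of the equation's left-hand side — a derivative lhs is a
differential equation, anything else is algebraic — and a map that
contradicts that classification is an error, never a silent override.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .errors import Diagnostic, MapError, ParseError
from .model_ir import CellModel, Deriv, _local
from .scheme import ROLES, TecScheme


@dataclass
class RelMap:
    model_ref: str | None
    scheme_ref: str | None
    roles: dict[str, str]  # ordered: variable or derivative name -> role

    @property
    def diffvars(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "diffvar"]

    @property
    def arithvars(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "arithvar"]

    @property
    def constvars(self) -> list[str]:
        return [n for n, r in self.roles.items() if r == "constvar"]

    @property
    def timevar(self) -> str | None:
        for n, r in self.roles.items():
            if r == "timevar":
                return n
        return None

    def derivative_pairs(self) -> dict[str, str]:
        """derivativevar entry name -> its diffvar, via d<name>/d<t> naming."""
        out = {}
        for n, r in self.roles.items():
            if r == "derivativevar" and n.startswith("d") and "/d" in n:
                out[n] = n[1:].rsplit("/d", 1)[0]
        return out


def parse_relml(document: str) -> RelMap:
    """Parse a RelML document; entries keep document order."""
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed XML: {exc}", line=line) from exc
    if _local(root.tag) != "relml":
        raise MapError(f"root element must be <relml>, got <{_local(root.tag)}>")

    model_ref = scheme_ref = None
    roles: dict[str, str] = {}
    for child in root:
        tag = _local(child.tag)
        if tag == "model":
            model_ref = child.get("href")
        elif tag == "scheme":
            scheme_ref = child.get("href")
        elif tag == "var":
            name = child.get("name")
            role = child.get("type")
            if not name:
                raise MapError("<var> without a name")
            if role not in ROLES:
                raise MapError(f"unknown role token {role!r} for variable {name!r}")
            if name in roles:
                raise MapError(f"duplicate entry for variable {name!r}")
            roles[name] = role
        else:
            raise MapError(f"unexpected element <{tag}> in <relml>")
    return RelMap(model_ref, scheme_ref, roles)


def serialize_relml(m: RelMap) -> str:
    root = ET.Element("relml")
    if m.model_ref is not None:
        ET.SubElement(root, "model", {"href": m.model_ref})
    if m.scheme_ref is not None:
        ET.SubElement(root, "scheme", {"href": m.scheme_ref})
    for name, role in m.roles.items():
        ET.SubElement(root, "var", {"name": name, "type": role})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def infer_roles(m: CellModel) -> RelMap:
    """Derive the role map directly from the model structure.

    Derivative-lhs variables become diffvars (with a paired derivativevar
    entry), algebraic-lhs variables become arithvars, the bound variable of
    the derivatives becomes the timevar, and everything else is a constant.
    """
    diff_lhs = []
    for eq in m.diff_equations:
        assert isinstance(eq.lhs, Deriv)
        diff_lhs.append(eq.lhs)
    diff_names = [d.var for d in diff_lhs]
    alg_names = [eq.lhs.name for eq in m.algebraic_equations]
    both = set(diff_names) & set(alg_names)
    if both:
        raise MapError(
            f"variable(s) defined by both a differential and an algebraic "
            f"equation: {sorted(both)}"
        )

    roles: dict[str, str] = {}
    for d in diff_lhs:
        roles[d.var] = "diffvar"
        roles[f"d{d.var}/d{d.bvar}"] = "derivativevar"
    for n in alg_names:
        roles[n] = "arithvar"
    if m.time_variable is not None:
        roles[m.time_variable] = "timevar"
    for v in m.variables:
        if v.name not in roles:
            roles[v.name] = "constvar"
    return RelMap(f"{m.name}.cellml", None, roles)


def validate_mapping(
    rmap: RelMap, m: CellModel, s: TecScheme
) -> list[Diagnostic]:
    """Empty diagnostics iff the (model, scheme, map) triple is coherent.

    The state/derivative role sets must be in bijection and of size Nx, every
    model variable must be mapped exactly once, there must be exactly one
    time variable, and every role the scheme relies on must be satisfiable
    from the model.
    """
    d: list[Diagnostic] = []

    def err(msg):
        d.append(Diagnostic("error", "mapping", msg))

    def warn(msg):
        d.append(Diagnostic("warning", "mapping", msg))

    declared = set(m.variable_names)
    deriv_entries = {n for n, r in rmap.roles.items() if r == "derivativevar"}
    pairs = rmap.derivative_pairs()

    for name, role in rmap.roles.items():
        if role == "derivativevar":
            if name not in pairs:
                err(f"derivativevar entry {name!r} is not of the form d<var>/d<t>")
            elif pairs[name] not in declared:
                err(f"derivativevar {name!r} pairs with unknown variable {pairs[name]!r}")
        elif name not in declared:
            err(f"map references variable {name!r} absent from the model")

    unmapped = declared - {n for n in rmap.roles if n not in deriv_entries}
    for name in sorted(unmapped):
        err(f"model variable {name!r} is not mapped to any role")

    timevars = [n for n, r in rmap.roles.items() if r == "timevar"]
    if len(timevars) != 1:
        err(f"expected exactly one timevar, found {len(timevars)}")
    elif m.time_variable is not None and timevars[0] != m.time_variable:
        err(
            f"timevar {timevars[0]!r} differs from the model's bound variable "
            f"{m.time_variable!r}"
        )

    # diffvar <-> derivativevar bijection, aligned with the model's equations
    diffvars = set(rmap.diffvars)
    paired = set(pairs.values())
    if diffvars != paired:
        err(
            f"diffvar and derivativevar sets are not in bijection: "
            f"diffvars={sorted(diffvars)}, paired={sorted(paired)}"
        )
    model_diff = {eq.lhs.var for eq in m.diff_equations}
    if diffvars != model_diff:
        err(
            f"diffvar set {sorted(diffvars)} does not match the model's "
            f"derivative equations {sorted(model_diff)}"
        )
    model_alg = {eq.lhs.name for eq in m.algebraic_equations}
    map_arith = set(rmap.arithvars)
    if map_arith != model_alg:
        err(
            f"arithvar set {sorted(map_arith)} does not match the model's "
            f"algebraic equations {sorted(model_alg)}"
        )
    for n in sorted(model_diff):
        role = rmap.roles.get(n)
        if role is not None and role != "diffvar":
            err(f"variable {n!r} has a derivative equation but is mapped as {role}")

    if model_alg and not s.uses_arithvars:
        err(
            f"model has algebraic (arithvar) equations but scheme {s.name!r} "
            "never evaluates arithvars"
        )
    if m.nx == 0:
        warn("no diffvars: model is not simulable")
    return d
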