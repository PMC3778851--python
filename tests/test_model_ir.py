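"""Model parsing, expression trees, evaluation and validation."""

from __future__ import annotations

from decimal import Decimal

import mpmath
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odegen import (
    BinOp,
    Call,
    Cmp,
    Deriv,
    Equation,
    Num,
    Piecewise,
    Var,
    evaluate_expr,
    expr_equal,
    free_variables,
    parse_cellml,
    parse_mathml_expr,
    serialize_cellml,
    validate_model,
)
from odegen.errors import (
    EvaluationError,
    ModelError,
    ParseError,
    UnsupportedConstructError,
)
from odegen.fixtures import ModelSpec, fhn_cellml, random_model
from odegen.model_ir import (
    models_structurally_equal,
    parse_mathml_expr as _pm,
    serialize_mathml_expr,
)

import xml.etree.ElementTree as ET


def mathml(fragment: str) -> ET.Element:
    return ET.fromstring(fragment)


class TestMathMLParsing:
    def test_sum_of_differences(self):
        # x - r/3.0 - y + a : four variable leaves in a sub/add tree
        frag = (
            "<apply><plus/>"
            "<apply><minus/>"
            "<apply><minus/><ci>x</ci>"
            "<apply><divide/><ci>r</ci><cn>3.0</cn></apply></apply>"
            "<ci>y</ci></apply>"
            "<ci>a</ci></apply>"
        )
        e = parse_mathml_expr(mathml(frag))
        assert free_variables(e) == {"x", "r", "y", "a"}
        assert isinstance(e, BinOp) and e.op == "add"
        assert isinstance(e.left, BinOp) and e.left.op == "sub"

    def test_number_literal(self):
        assert parse_mathml_expr(mathml("<cn>0</cn>")) == Num("0")

    def test_e_notation(self):
        e = parse_mathml_expr(mathml('<cn type="e-notation">1<sep/>-5</cn>'))
        assert Decimal(e.value) == Decimal("1e-5")

    def test_unary_minus_is_negation(self):
        from odegen import Neg

        e = parse_mathml_expr(mathml("<apply><minus/><ci>x</ci></apply>"))
        assert e == Neg(Var("x"))

    def test_nary_plus_folds_left(self):
        e = parse_mathml_expr(
            mathml("<apply><plus/><ci>u</ci><ci>v</ci><ci>w</ci></apply>")
        )
        assert e == BinOp("add", BinOp("add", Var("u"), Var("v")), Var("w"))

    def test_unsupported_element_is_hard_error(self):
        with pytest.raises(UnsupportedConstructError, match="csymbol"):
            parse_mathml_expr(mathml("<apply><csymbol/><ci>x</ci></apply>"))

    def test_piecewise_with_relations(self):
        frag = (
            "<piecewise>"
            "<piece><ci>u</ci><apply><lt/><ci>u</ci><cn>0</cn></apply></piece>"
            "<otherwise><ci>v</ci></otherwise>"
            "</piecewise>"
        )
        e = parse_mathml_expr(mathml(frag))
        assert isinstance(e, Piecewise)
        assert free_variables(e) == {"u", "v"}

    def test_diff_with_bvar(self):
        e = parse_mathml_expr(
            mathml(
                "<apply><diff/><bvar><ci>time</ci></bvar><ci>x</ci></apply>"
            )
        )
        assert e == Deriv("x", "time")


# strategy for random well-formed expression trees
_names = st.sampled_from(["u", "v", "w"])
_leaf = st.one_of(
    _names.map(Var),
    st.integers(-9, 9).map(lambda n: Num(str(n))),
    st.decimals(
        min_value=-10, max_value=10, places=3, allow_nan=False, allow_infinity=False
    ).map(lambda d: Num(str(d))),
)


def _tree(children):
    return st.one_of(
        st.tuples(st.sampled_from(["add", "sub", "mul"]), children, children).map(
            lambda t: BinOp(*t)
        ),
        # scaled argument keeps exp's condition number (=|arg|) small even
        # when nested, so a fixed ulp tolerance stays meaningful
        children.map(lambda c: Call("exp", (BinOp("mul", Num("0.1"), c),))),
        st.tuples(children, children, children).map(
            lambda t: Piecewise(((Cmp("lt", t[0], Num("0")), t[1]),), t[2])
        ),
    )


_exprs = st.recursive(_leaf, _tree, max_leaves=8)


class TestExpressionProperties:
    @settings(max_examples=80, derandomize=True)
    @given(_exprs)
    def test_mathml_round_trip_is_identity(self, e):
        again = _pm(serialize_mathml_expr(e))
        assert expr_equal(e, again)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(_exprs, st.decimals(-2, 2, places=2), st.decimals(-2, 2, places=2),
           st.decimals(-2, 2, places=2))
    def test_evaluation_agrees_with_mpmath(self, e, u, v, w):
        """Tree evaluation matches an independent arbitrary-precision walker
        to a couple of units in the last place of the working context."""
        digits = 20
        bind = {"u": Decimal(u), "v": Decimal(v), "w": Decimal(w)}
        try:
            ours = evaluate_expr(e, bind, precision=digits)
        except EvaluationError:
            return  # domain/overflow cases are out of scope here
        with mpmath.workdps(digits + 10):
            theirs = _mp_eval(e, {k: mpmath.mpf(str(x)) for k, x in bind.items()})
            gap = abs(mpmath.mpf(str(ours)) - theirs)
            tol = 10 * mpmath.mpf(10) ** (-digits + 1) * max(1, abs(theirs))
            assert gap <= tol


def _mp_eval(e, b):
    if isinstance(e, Num):
        return mpmath.mpf(e.value)
    if isinstance(e, Var):
        return b[e.name]
    if isinstance(e, BinOp):
        x, y = _mp_eval(e.left, b), _mp_eval(e.right, b)
        if e.op == "add":
            return x + y
        if e.op == "sub":
            return x - y
        if e.op == "mul":
            return x * y
        if e.op == "div":
            return x / y
        return x**y
    if isinstance(e, Call):
        (a,) = e.args
        return {"exp": mpmath.exp}[e.func](_mp_eval(a, b))
    if isinstance(e, Piecewise):
        for cond, val in e.pieces:
            x, y = _mp_eval(cond.left, b), _mp_eval(cond.right, b)
            if {"lt": x < y, "leq": x <= y, "gt": x > y, "geq": x >= y,
                "eq": x == y, "neq": x != y}[cond.op]:
                return _mp_eval(val, b)
        return _mp_eval(e.otherwise, b)
    raise TypeError(e)


class TestEvaluation:
    def test_cube(self):
        e = BinOp("pow", Var("x"), Num("3"))
        assert evaluate_expr(e, {"x": 2}) == Decimal(8)

    def test_fhn_rhs_by_hand(self):
        # x - x^3/3.0 - y + a at x=1, y=0, a=0 -> 2/3 in the context digits
        e = BinOp(
            "add",
            BinOp(
                "sub",
                BinOp("sub", Var("x"), BinOp("div", Var("r"), Num("3.0"))),
                Var("y"),
            ),
            Var("a"),
        )
        got = evaluate_expr(e, {"x": 1, "r": 1, "y": 0, "a": 0}, precision=7)
        assert got == Decimal("0.6666667")

    def test_unbound_variable(self):
        with pytest.raises(EvaluationError, match="unbound"):
            evaluate_expr(Var("q"), {})

    def test_division_by_zero_is_loud(self):
        with pytest.raises(EvaluationError):
            evaluate_expr(BinOp("div", Num("1"), Var("x")), {"x": 0})

    def test_log_domain_violation(self):
        with pytest.raises(EvaluationError):
            evaluate_expr(Call("ln", (Num("-1"),)), {})


class TestFreeVariables:
    def test_fhn_recovery_equation(self):
        # b*(x + c - d*y)
        e = BinOp(
            "mul",
            Var("b"),
            BinOp("sub", BinOp("add", Var("x"), Var("c")), BinOp("mul", Var("d"), Var("y"))),
        )
        assert free_variables(e) == {"x", "y", "b", "c", "d"}

    def test_literal_has_none(self):
        assert free_variables(Num("3.5")) == set()

    def test_nested_piecewise(self):
        inner = Piecewise(((Cmp("lt", Var("u"), Num("0")), Var("v")),), Var("u"))
        outer = Piecewise(((Cmp("gt", Var("v"), Num("1")), inner),), Var("v"))
        assert free_variables(outer) == {"u", "v"}


class TestCellMLParsing:
    def test_fhn_fixture(self, fhn):
        assert set(fhn.variable_names) == {"x", "y", "r", "a", "b", "c", "d", "time"}
        assert fhn.nx == 2 and fhn.ny == 1
        assert fhn.time_variable == "time"
        assert fhn.initial_values()["x"] == "-1.2"

    def test_constant_only_model_is_valid_but_not_simulable(self):
        doc = (
            '<model name="k"><component name="main">'
            '<variable name="c" initial_value="1"/>'
            "</component></model>"
        )
        m = parse_cellml(doc)
        assert m.nx == 0 and m.ny == 0
        assert not m.is_simulable
        diags = validate_model(m)
        assert any(d.severity == "warning" for d in diags)
        assert not [d for d in diags if d.severity == "error"]

    def test_malformed_xml_reports_line(self):
        with pytest.raises(ParseError, match="line"):
            parse_cellml("<model name='x'>\n<component>\n</model>")

    def test_multi_term_lhs_rejected(self):
        doc = (
            '<model name="bad"><component name="main">'
            '<variable name="u"/><variable name="v"/><variable name="w"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><plus/><ci>u</ci><ci>v</ci></apply><ci>w</ci></apply>"
            "</math></component></model>"
        )
        with pytest.raises(ModelError, match="single"):
            parse_cellml(doc)

    def test_duplicate_lhs_rejected(self):
        doc = (
            '<model name="dup"><component name="main">'
            '<variable name="r"/><variable name="x"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><ci>r</ci><ci>x</ci></apply>"
            "<apply><eq/><ci>r</ci><apply><power/><ci>x</ci><cn>3</cn></apply></apply>"
            "</math></component></model>"
        )
        with pytest.raises(ModelError, match="duplicate"):
            parse_cellml(doc)

    def test_undeclared_variable_rejected(self):
        doc = (
            '<model name="und"><component name="main">'
            '<variable name="r"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><ci>r</ci><ci>ghost</ci></apply>"
            "</math></component></model>"
        )
        with pytest.raises(ModelError, match="ghost"):
            parse_cellml(doc)

    def test_two_bvars_rejected(self):
        doc = (
            '<model name="pde"><component name="main">'
            '<variable name="x"/><variable name="t"/><variable name="s"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply><cn>1</cn></apply>"
            "<apply><eq/><apply><diff/><bvar><ci>s</ci></bvar><ci>x</ci></apply><cn>1</cn></apply>"
            "</math></component></model>"
        )
        with pytest.raises(ModelError, match="independent"):
            parse_cellml(doc)

    def test_components_flatten_through_connections(self):
        doc = (
            '<model name="two">'
            '<component name="gate">'
            '<variable name="x" initial_value="1"/><variable name="t"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply>"
            "<apply><minus/><ci>x</ci></apply></apply>"
            "</math></component>"
            '<component name="env"><variable name="t"/><variable name="x"/></component>'
            "<connection><map_components component_1='gate' component_2='env'/>"
            "<map_variables variable_1='t' variable_2='t'/>"
            "<map_variables variable_1='x' variable_2='x'/></connection>"
            "<units name='ms'/>"
            "</model>"
        )
        m = parse_cellml(doc)
        assert sorted(m.variable_names) == ["t", "x"]
        assert m.nx == 1
        assert any("units" in d.message for d in m.warnings)

    def test_serialize_parse_round_trip_fhn(self, fhn):
        again = parse_cellml(serialize_cellml(fhn))
        assert models_structurally_equal(fhn, again)

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_serialize_parse_round_trip_random(self, seed):
        text, _, _ = random_model(ModelSpec(seed=seed, nx=3, ny=2, nz=2, depth=3))
        m = parse_cellml(text)
        again = parse_cellml(serialize_cellml(m))
        assert models_structurally_equal(m, again)


class TestValidateModel:
    def test_fhn_clean(self, fhn):
        assert not [d for d in validate_model(fhn) if d.severity == "error"]

    def test_duplicate_algebraic_lhs(self, fhn):
        m = parse_cellml(fhn_cellml())
        m.equations.append(Equation(Var("r"), Num("0")))
        assert any("duplicate" in d.message for d in validate_model(m))

    def test_multi_term_lhs_diagnosed(self, fhn):
        m = parse_cellml(fhn_cellml())
        m.equations.append(Equation(BinOp("add", Var("a"), Var("b")), Num("0")))
        assert any("single term" in d.message for d in validate_model(m))
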