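"""Expansion: the golden FHN weave, step counts, ordering, well-formedness,
and the semantic cross-check against direct numeric stepping."""

from __future__ import annotations

import pytest

from conftest import SCHEME_NAMES, direct_step, golden_modified_euler_fhn, relative_gap

from odegen import (
    BinOp,
    Equation,
    Num,
    Var,
    alpha_equivalent,
    builtin_scheme,
    check_well_formed,
    classify_equations,
    count_steps,
    expand,
    infer_roles,
    interpret,
    order_arith,
    parse_cellml,
    parse_relml,
)
from odegen.errors import ExpansionError
from odegen.expander import FlatProgram, ScalarAssignment
from odegen.fixtures import ModelSpec, random_model
from odegen.model_ir import free_variables


class TestClassifyAndOrder:
    def test_fhn_classification(self, fhn, fhn_map):
        f, g = classify_equations(fhn, fhn_map)
        assert [eq.lhs.var for eq in f] == ["x", "y"]
        assert [eq.lhs.name for eq in g] == ["r"]

    def test_no_algebraic_equations(self):
        m = parse_cellml(
            '<model name="p"><component name="main">'
            '<variable name="x" initial_value="0"/><variable name="t"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply><cn>1</cn></apply>"
            "</math></component></model>"
        )
        f, g = classify_equations(m, infer_roles(m))
        assert len(f) == 1 and g == []

    def test_order_arith_reorders_dependency(self):
        u = Equation(Var("u"), BinOp("add", Var("v"), Num("1")))
        v = Equation(Var("v"), BinOp("pow", Var("x"), Num("2")))
        assert [e.lhs.name for e in order_arith([u, v])] == ["v", "u"]

    def test_order_arith_stable_for_independent(self):
        a = Equation(Var("p"), Num("1"))
        b = Equation(Var("q"), Num("2"))
        assert [e.lhs.name for e in order_arith([a, b])] == ["p", "q"]

    def test_cycle_is_dae_error(self):
        u = Equation(Var("u"), Var("v"))
        v = Equation(Var("v"), Var("u"))
        with pytest.raises(ExpansionError, match="DAE"):
            order_arith([u, v])


class TestGoldenExpansion:
    def test_fhn_modified_euler_matches_published_equations(self, fhn, fhn_map):
        """The expansion must be alpha-equivalent, assignment by assignment
        and in order, to the published 16-equation FHN weave."""
        p = expand(fhn, builtin_scheme("modified_euler"), fhn_map)
        expected, fixed = golden_modified_euler_fhn()
        assert alpha_equivalent(p, expected, fixed)

    def test_order_mismatch_is_detected(self, fhn, fhn_map):
        p = expand(fhn, builtin_scheme("modified_euler"), fhn_map)
        expected, fixed = golden_modified_euler_fhn()
        swapped = expected[:4] + [expected[5], expected[4]] + expected[6:]
        assert not alpha_equivalent(p, swapped, fixed)

    def test_constant_rename_is_not_alpha_equivalent(self, fhn, fhn_map):
        p = expand(fhn, builtin_scheme("modified_euler"), fhn_map)
        expected, fixed = golden_modified_euler_fhn()
        renamed = [
            (lhs, _rename_var(rhs, "a", "applied")) for lhs, rhs in expected
        ]
        assert not alpha_equivalent(p, renamed, fixed | {"applied"})


def _rename_var(e, old, new):
    from odegen.model_ir import substitute

    return substitute(e, {old: Var(new)})


class TestStepCounts:
    @pytest.mark.parametrize("name,steps", [
        ("euler", 11), ("modified_euler", 16), ("rk4", 26),
    ])
    def test_fhn_table(self, fhn, fhn_map, name, steps):
        p = expand(fhn, builtin_scheme(name), fhn_map)
        assert count_steps(p) == steps

    def test_invariant_under_model_renaming(self):
        for name in SCHEME_NAMES:
            counts = set()
            for prefix in ("", "cell_"):
                spec = ModelSpec(seed=5, nx=2, ny=2, nz=1, depth=2, name_prefix=prefix)
                cellml, relml, _ = random_model(spec)
                p = expand(
                    parse_cellml(cellml), builtin_scheme(name), parse_relml(relml)
                )
                counts.add(count_steps(p))
            assert len(counts) == 1


class TestSingleVariableEuler:
    def test_hand_expansion(self):
        """dx/dt = z under forward Euler: six assignments, matching the
        one-stage restriction of the scheme done by hand."""
        m = parse_cellml(
            '<model name="drift"><component name="main">'
            '<variable name="x" initial_value="0"/><variable name="z" initial_value="1"/>'
            '<variable name="t"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply><ci>z</ci></apply>"
            "</math></component></model>"
        )
        p = expand(m, builtin_scheme("euler"), infer_roles(m))
        got = [(a.lhs, a.rhs) for a in p.assignments]
        assert got == [
            ("x_0", Var("x_in")),
            ("t_0", Var("t")),
            ("kappa1_x", Var("z")),
            ("x_1", BinOp("add", Var("x_0"), BinOp("mul", Var("kappa1_x"), Var("delta")))),
            ("t_1", BinOp("add", Var("t_0"), Var("delta"))),
            ("x_out", Var("x_1")),
        ]


class TestStructure:
    def test_rk4_kappa_references_matching_stage_arithvars(self, fhn, fhn_map):
        p = expand(fhn, builtin_scheme("rk4"), fhn_map)
        for a in p.assignments:
            if a.lhs.startswith("kappa"):
                stage = int(a.lhs[5]) - 1
                r_refs = {n for n in free_variables(a.rhs) if n.startswith("r_")}
                assert r_refs <= {f"r_{stage}"}
                if a.lhs.endswith("_x"):  # the x equation does use r
                    assert r_refs == {f"r_{stage}"}

    def test_expand_refuses_invalid_triple(self, fhn, fhn_map):
        from odegen.mapping import RelMap

        roles = {k: v for k, v in fhn_map.roles.items() if k != "r"}
        with pytest.raises(ExpansionError, match="invalid mapping"):
            expand(fhn, builtin_scheme("euler"), RelMap(None, None, roles))

    def test_bare_name_collision_is_detected(self):
        # a constant literally named like a generated stage scalar
        m = parse_cellml(
            '<model name="clash"><component name="main">'
            '<variable name="x" initial_value="0"/>'
            '<variable name="x_1" initial_value="2"/>'
            '<variable name="t"/>'
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><eq/><apply><diff/><bvar><ci>t</ci></bvar><ci>x</ci></apply><ci>x_1</ci></apply>"
            "</math></component></model>"
        )
        with pytest.raises(ExpansionError, match="collide"):
            expand(m, builtin_scheme("euler"), infer_roles(m))


class TestWellFormed:
    def test_expansion_is_always_clean(self, fhn, fhn_map, schemes):
        for s in schemes.values():
            assert check_well_formed(expand(fhn, s, fhn_map)) == []

    def test_use_before_definition(self):
        p = FlatProgram(
            diffvars=["x"], time_name="t", constants=[],
            assignments=[
                ScalarAssignment("x_0", Var("x_1")),
                ScalarAssignment("x_1", Var("x_in")),
                ScalarAssignment("x_out", Var("x_1")),
            ],
            input_of={"x": "x_in"}, output_of={"x": "x_out"},
        )
        diags = check_well_formed(p)
        assert any("x_1" in d.message and "before" in d.message for d in diags)

    def test_duplicate_assignment(self):
        p = FlatProgram(
            diffvars=["x"], time_name="t", constants=[],
            assignments=[
                ScalarAssignment("r_0", Num("1")),
                ScalarAssignment("r_0", Num("2")),
                ScalarAssignment("x_out", Var("x_in")),
            ],
            input_of={"x": "x_in"}, output_of={"x": "x_out"},
        )
        assert any("duplicate" in d.message for d in check_well_formed(p))


class TestSemanticOracle:
    """One interpreted step of the expansion equals a direct, non-symbolic
    implementation of the same scheme on the generator's ground truth."""

    @pytest.mark.parametrize("seed", [0, 3, 11, 29, 41, 57])
    @pytest.mark.parametrize("scheme_name", SCHEME_NAMES)
    def test_one_step_matches_direct_stepper(self, seed, scheme_name):
        spec = ModelSpec(seed=seed, nx=1 + seed % 4, ny=seed % 3, nz=1 + seed % 2, depth=3)
        cellml, relml, gt = random_model(spec)
        m = parse_cellml(cellml)
        p = expand(m, builtin_scheme(scheme_name), parse_relml(relml))
        assert check_well_formed(p) == []

        init = {v: float(gt.initial[v]) for v in gt.diffvars}
        dt = 0.01
        res = interpret(p, gt.initial, gt.constants, 0, dt, dt, precision="double")
        want = direct_step(scheme_name, init, 0.0, dt, gt.eval_f, gt.eval_g)
        for v in gt.diffvars:
            assert relative_gap(res.series[v][-1], want[v]) <= 1e-12
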