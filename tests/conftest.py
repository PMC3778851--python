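"""Shared fixtures and independent numeric oracles.

The oracles here implement the builtin schemes directly as numeric stepping
loops (no symbolic expansion, no flat programs), so tests can cross-check
the expander+interpreter route against a hand-coded route.
"""

from __future__ import annotations

import pytest

from odegen import (
    builtin_scheme,
    fhn_cellml,
    fhn_relml,
    parse_cellml,
    parse_relml,
)
from odegen.fixtures import fhn_eval_f, fhn_eval_g

SCHEME_NAMES = ("euler", "modified_euler", "rk2", "rk4")


@pytest.fixture(scope="session")
def fhn():
    return parse_cellml(fhn_cellml())


@pytest.fixture(scope="session")
def fhn_map():
    return parse_relml(fhn_relml())


@pytest.fixture(scope="session")
def schemes():
    return {name: builtin_scheme(name) for name in SCHEME_NAMES}


# ---------------------------------------------------------------------------
# Direct (non-symbolic) scheme steppers
# ---------------------------------------------------------------------------


def direct_step(scheme_name, state, t, dt, eval_f, eval_g):
    """Advance ``state`` one step with a hand-coded explicit scheme.

    ``eval_g(state, t) -> aux`` and ``eval_f(state, aux, t) -> derivs`` are
    plain numeric callables; everything here is float arithmetic on dicts.
    """

    def deriv(s, tt):
        return eval_f(s, eval_g(s, tt), tt)

    if scheme_name == "euler":
        k1 = deriv(state, t)
        return {v: state[v] + k1[v] * dt for v in state}
    if scheme_name == "modified_euler":
        k1 = deriv(state, t)
        s1 = {v: state[v] + k1[v] * dt for v in state}
        k2 = deriv(s1, t + dt)
        return {v: state[v] + 0.5 * (k1[v] + k2[v]) * dt for v in state}
    if scheme_name == "rk2":
        k1 = deriv(state, t)
        s1 = {v: state[v] + 0.5 * k1[v] * dt for v in state}
        k2 = deriv(s1, t + 0.5 * dt)
        return {v: state[v] + k2[v] * dt for v in state}
    if scheme_name == "rk4":
        k1 = deriv(state, t)
        s1 = {v: state[v] + 0.5 * k1[v] * dt for v in state}
        k2 = deriv(s1, t + 0.5 * dt)
        s2 = {v: state[v] + 0.5 * k2[v] * dt for v in state}
        k3 = deriv(s2, t + 0.5 * dt)
        s3 = {v: state[v] + k3[v] * dt for v in state}
        k4 = deriv(s3, t + dt)
        return {
            v: state[v] + (k1[v] + 2 * k2[v] + 2 * k3[v] + k4[v]) * dt / 6
            for v in state
        }
    raise ValueError(scheme_name)


@pytest.fixture(scope="session")
def fhn_oracle():
    """Direct FHN stepper: (scheme, state, t, dt) -> next state."""

    def step(scheme_name, state, t, dt):
        return direct_step(scheme_name, state, t, dt, fhn_eval_f, fhn_eval_g)

    return step


def relative_gap(a: float, b: float) -> float:
    scale = max(abs(a), abs(b), 1.0)
    return abs(a - b) / scale


# ---------------------------------------------------------------------------
# Golden expansion: FHN woven with the modified Euler scheme
# ---------------------------------------------------------------------------


def golden_modified_euler_fhn():
    """The published 16-equation FHN/modified-Euler expansion.

    Written with its own scalar names (x0, kappa1_x, xt, ...) so comparing
    against the expander output genuinely exercises alpha-equivalence.
    Returns (assignments, fixed_names).
    """
    from odegen import BinOp, Num, Var

    def v(n):
        return Var(n)

    def fx(x, r, y):  # x - r/3.0 - y + a
        return BinOp(
            "add",
            BinOp("sub", BinOp("sub", v(x), BinOp("div", v(r), Num("3.0"))), v(y)),
            v("a"),
        )

    def fy(x, y):  # b*(x + c - d*y)
        return BinOp(
            "mul",
            v("b"),
            BinOp("sub", BinOp("add", v(x), v("c")), BinOp("mul", v("d"), v(y))),
        )

    def euler_update(base, kappa):  # base + kappa*dt
        return BinOp("add", v(base), BinOp("mul", v(kappa), v("dt")))

    def combine(base, k1, k2):  # base + 0.5*(k1 + k2)*dt
        return BinOp(
            "add",
            v(base),
            BinOp(
                "mul",
                BinOp("mul", Num("0.5"), BinOp("add", v(k1), v(k2))),
                v("dt"),
            ),
        )

    assignments = [
        ("x0", v("xt")),
        ("y0", v("yt")),
        ("t0", v("t")),
        ("r0", BinOp("pow", v("x0"), Num("3"))),
        ("kappa1_x", fx("x0", "r0", "y0")),
        ("kappa1_y", fy("x0", "y0")),
        ("x1", euler_update("x0", "kappa1_x")),
        ("y1", euler_update("y0", "kappa1_y")),
        ("t1", BinOp("add", v("t0"), v("dt"))),
        ("r1", BinOp("pow", v("x1"), Num("3"))),
        ("kappa2_x", fx("x1", "r1", "y1")),
        ("kappa2_y", fy("x1", "y1")),
        ("x2", combine("x0", "kappa1_x", "kappa2_x")),
        ("y2", combine("y0", "kappa1_y", "kappa2_y")),
        ("xtd", v("x2")),
        ("ytd", v("y2")),
    ]
    return assignments, {"a", "b", "c", "d"}
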