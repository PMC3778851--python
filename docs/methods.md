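# Methods

## The compilation model

`odegen` treats a simulation as the composition of three declarative
inputs: a **cell model** (variables, initial values, and equations carried
as MathML content markup in a CellML 1.0/1.1-style XML dialect), an
**explicit ODE solving scheme** (a TecML document: typed, stage-indexed
symbols plus an ordered statement list), and a **role map** (a RelML
document assigning every model variable one of six roles: `diffvar`,
`derivativevar`, `arithvar`, `constvar`, `timevar`, `deltatimevar`).
Equation classes are always derived from the equation's left-hand side — a
derivative lhs is a differential equation, a plain variable lhs is an
algebraic one — and a role map that contradicts this is rejected rather
than silently overridden.  Role maps can also be inferred mechanically from
the model (`infer_roles`), since the lhs shapes determine everything.

Stage 1 (expansion) walks the scheme statements in document order and
scalarizes each one over the model: bindings and stage/time updates emit
one assignment per state variable with scheme symbols replaced by model
names plus stage suffixes; `arith-eval` and `deriv-eval` statements unfold
the model's `g` and `f` right-hand sides with every state/algebraic/time
reference given the current stage suffix.  Constants and the time step are
never suffixed.  The output is a **flat program**: an ordered,
single-assignment scalar equation set whose well-formedness
(definition-before-use, single assignment) is checked in one linear scan
after every expansion.

Stage 2 (code generation) renders the flat program into a self-contained
simulation source: assignments in order inside a fixed-step time loop,
CSV output of time plus the state variables every `stride` steps.

## Deliberate non-optimizations

No algebraic simplification, constant folding, common-subexpression
elimination or dead-code elimination is ever applied.  This is a design
point, not an omission: the assignment count of the flat program is the
tool's "execution step" metric and must be stable under renaming and
re-emission, and the emitted right-hand sides must remain recognizably the
model's own formulas so a reviewer can audit the generated arithmetic
line by line.

## Step-counting conventions

The builtin schemes pin a particular statement layout, and with it the
execution-step count of an expansion (inputs + per-stage algebraic and
derivative evaluations + stage/time updates + outputs).  For a model with
Nx states and Ny algebraic equations:

| scheme          | layout                                                         | FHN (Nx=2, Ny=1) |
|-----------------|----------------------------------------------------------------|------------------|
| euler           | Nx+1 bindings, Ny+Nx evals, Nx+1 updates, Nx outputs           | 11               |
| modified_euler  | adds a second eval round, the combine, separate outputs        | 16               |
| rk2 (midpoint)  | like modified_euler but the combine is folded into the outputs | 14               |
| rk4             | 4 eval rounds, 3 intermediate x/t update rounds, folded combine| 26               |

Two conventions are data, not code, and live in the pinned TecML documents:
forward Euler carries its (otherwise unused) time update `t1 = t0 + δ` as a
real statement, and modified Euler keeps the final combine `ξ2 = ξ0 +
½(κ1+κ2)δ` and the output bindings as separate statements while RK4 writes
its combine directly into the output bindings.  These choices make the
per-scheme counts mutually consistent with the worked modified-Euler
expansion (which itself counts both the combine and the outputs among its
16 equations); no single convention documented elsewhere fixes them, so
they are flagged here as this package's pinned interpretation.

## Numerical execution

The interpreter executes the assignment list with output bindings fed back
as next-step inputs.  Two arithmetic modes exist:

* **double** — IEEE 754 binary64; non-finite states set a divergence flag
  with the offending step index.
* **decimal:N** — an N-significant-digit decimal context (default 32 for
  studies).  Numeric literals are kept as exact decimal strings from the
  XML all the way to evaluation, so the high-precision mode never inherits
  binary-float artifacts.  Arithmetic traps (overflow, invalid, division
  by zero) are converted into the divergence flag.

For speed the assignment list is compiled once into a Python step loop;
semantics are exactly the per-assignment evaluation order, and the tests
cross-check this route against (a) hand-coded direct implementations of
each scheme and (b) the independently emitted standalone sources.
Time is never accumulated: step *i* runs at `t0 + i·δ` computed afresh,
which in decimal mode is exact.

Closed-form limits serve as exact oracles: on dx/dt = λx one step of each
scheme must reproduce its stability polynomial (1+z for Euler, 1+z+z²/2
for the two-stage schemes, Σ_{k≤4} z^k/k! for RK4, z = λδ) to the last
digit of the decimal context, and n Euler steps on dx/dt = −x equal
(1−δ)ⁿ with no drift tolerance at all (with δ = 0.1 and n = 20 every
intermediate product fits in 32 digits, so no rounding ever occurs).

## The accuracy study

`convergence_study` runs one reference trajectory (by default RK4 at a δ
one decade below the smallest candidate) and one candidate per (scheme, δ),
all in the same arithmetic context (default decimal:32).  Trajectories are
sampled at multiples of the largest candidate δ; the error of a candidate
is the root-mean-square deviation over all shared sample times and all
state variables, with differences taken in exact decimal before squaring
so deviations far below double spacing stay measurable.  The fitted order
is the least-squares slope of log₁₀RMSE against log₁₀δ.

Entries are excluded from the fit when flagged:

* **floor** — RMSE below ten units in the last carried digit scaled by the
  reference trajectory's RMS magnitude (`10 · 10^−digits · scale`): the
  truncation error has dropped under round-off and the point no longer
  carries order information.  This formalizes the plateau a high-order
  scheme reaches when the arithmetic context saturates.
* **divergent** — the run produced a non-finite state (e.g. forward Euler
  outside its stability region).

Defaults for the FHN study are candidates δ ∈ {10⁻¹, 10⁻², 10⁻³, 10⁻⁴},
reference RK4 at 10⁻⁵, horizon 20 time units, decimal:32 — sizes chosen so
the whole study completes in well under a minute on one core while leaving
every candidate's truncation error orders of magnitude above the decimal
floor.  Wider grids are plain configuration.  Measured on these defaults
the fitted orders come out ≈ 1.00 / 2.01 / 4.02 for Euler / modified Euler
/ RK4, with the RMSE ranking Euler > modified Euler > RK4 at every step
size (these numbers are recomputed by `tests/test_acceptance.py`, not
stored).

## Parameters that matter

| parameter | where | default | meaning |
|---|---|---|---|
| `delta` (δ) | interpret / codegen / study | 0.01 (CLI) | integration step, model time units |
| `precision` | interpret / codegen / study | double (runs), 32 digits (study) | arithmetic context |
| `horizon` | study | 20 | compared trajectory length, model time units |
| `stride` | run / codegen | 1 | sampling interval in steps |
| FHN a,b,c,d | fixtures | 0.5, 0.08, 0.7, 0.8 | classical FitzHugh parameterization; a is the applied current |
| FHN x(0),y(0) | fixtures | −1.2, −0.6 | classical resting start |

The FHN parameter values are a documented choice of this package (the
classical parameterization mapped onto the r = x³ form); every structural
result (step counts, alpha-equivalence, orders) is independent of them,
and the bundled values give a bounded orbit for all schemes at δ ≤ 0.1.

## The synthetic model generator

`fixtures.random_model` emulates the *shape* of biological ODE models at
small scale: Nx damped state equations (a fixed `−1.0·xᵢ` term plus up to
`depth−1` mildly scaled couplings), an acyclic layer of Ny algebraic
equations whose document order is shuffled (so consumers must topologically
sort), Nz constants, and expressions drawn from linear, product, square,
saturating-rational (`c·u/(1+v²)`, denominator bounded away from zero by
construction) and small-argument exponential terms.  Each generated model
ships ground-truth roles and direct numeric evaluators of `f` and `g`
computed from the generator's term lists rather than its expression trees,
so oracle tests do not share code with the path under test.  The generator
does **not** emulate stiffness, unit structure, multi-component models or
realistic ionic-current magnitudes; green property tests therefore say the
compiler is faithful to the mathematics it is given, not that any
particular physiological model is well approximated at a given δ.

## Design choices where the design was open

* **Dialects.** The concrete TecML and RelML XML dialects are defined by
  this package (root `tecml`/`relml` elements, `step` statements with
  embedded MathML formulas over `xi_i`/`kappa_i`/`tau_i`/`delta`, `var`
  role entries with derivative pairing via `d<name>/d<time>` naming).
* **Scalar naming.** `<name>_<stage>` for stage copies, `kappa<i>_<name>`
  for derivative scalars, `<name>_in`/`<name>_out` for bindings; chosen so
  emitted code is deterministic and byte-stable.  A model variable whose
  own name collides with a generated scalar is rejected with an explicit
  error rather than silently renamed.
* **Targets.** Python script and C99; the decimal mode lives in the Python
  target and the interpreter (C stays double-only).  GPU/accelerator
  emission and multi-cell spatial coupling are out of scope.
* **Explicit schemes only.** Validation rejects any statement that reads a
  symbol not produced earlier, which excludes implicit and adaptive
  methods by construction; an algebraic dependency cycle in the model is
  reported as an unsupported simultaneous (DAE) system.
* **Tie-breaks.** Document order everywhere (equations, map entries,
  independent algebraic equations after the topological sort); expansion
  has no randomness and no hash-order dependence.

## Known limitations

* CellML units are recorded as text and never checked or converted;
  CellML 2.0, reactions, imports and RDF metadata are not supported.
* Equations must have a single-term left-hand side; systems requiring a
  simultaneous solve (DAEs, implicit methods) are rejected at validation.
* One independent variable: several distinct derivative bound variables
  are an error.
* The RMSE of a study depends on the chosen horizon, sampling grid and
  variable set; only convergence orders and scheme rankings are
  grid-robust, and absolute error values should not be compared across
  differently configured studies.
* The interpreter and the emitted Python share the expression-rendering
  helper; their agreement is therefore necessary but not sufficient for
  correctness, which is why the test suite also checks both against
  hand-coded direct scheme implementations and exact closed forms.
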