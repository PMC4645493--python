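# Methods

## Models

**Two-gene cross-regulation** (state `(m1, m2, p1, p2)`, dimensionless
concentration and time units). Gene 1 is transcribed at rate
`λ1·H⁺(p2; θ2, n2)`, gene 2 at `λ2·H⁻(p1; θ1, n1)`, where
`H⁺(p; θ, n) = pⁿ/(pⁿ+θⁿ)` and `H⁻ = 1 − H⁺` are Hill activation/inhibition
functions; mRNAs are translated at rates `κ_i m_i` and all species degrade
linearly (`γ_i`, `μ_i`). Defaults: `n = 3`, `λ1 = 1.15`, `λ2 = 2.35`,
`γ = κ = μ = 1`, `θ = 0.21` — an operating point at which the unique
positive steady state `(0.475099, 0.186810, 0.475099, 0.186810)` is an
unstable spiral (eigenvalues `−2.049997 ± 1.049997i`,
`0.049997 ± 1.049997i`) surrounded by a limit cycle.

**PER circadian oscillator** (state `(M, P0, P1, P2, PN)`, µM and hours).
Cytosolic *per* mRNA `M` is transcribed under Hill-type repression by
nuclear protein `PN` (`v_s K_I⁴/(K_I⁴ + P_N⁴)`) and degraded by Michaelis–
Menten kinetics; protein is synthesized at `k_s M`, reversibly
phosphorylated through `P0 → P1 → P2` (four Michaelis–Menten fluxes
`V_i x/(K_i + x)`), degraded from `P2`, and exchanged with the nucleus
(`k1`, `k2`). Defaults are the standard circadian set (`v_s = 0.76` µM/h,
…, `V4 = 2.5` µM/h); steady state
`(1.851476, 1.049558, 0.672924, 0.570982, 0.834512)` with eigenvalues
`{−4.266573, −1.834793, 0.032824 ± 0.297276i, −0.829294}` and a ~23.7 h
cycle.

The Jacobians are hand-derived analytic forms; `g = J·f` is expanded over
each Jacobian's sparsity pattern for speed in the integrator's inner loop.
Both are validated against central finite differences, and `g` against
`jac @ f`, at seeded random states in `[0.05, 2]^d` — the closed forms never
rest on transcription alone. A general builder assembles arbitrary N-gene
transcription/translation networks from user-supplied regulation functions
and their partials; the two-gene model is reproduced as an instance of it in
the tests.

## The integrators

The family shares one four-stage explicit tableau: `c = (0, 1/4, 2/3, 1)`,
`A` strictly lower triangular with rows `(1/32)`, `(−2/81, 20/81)`,
`(5/4, −6/5, 9/20)`, prototype weights
`b = (3/40, 64/225, 27/200, 1/180)`, `η = β = 1`. The row-sum identity
`A e = c²/2` and the `b`-side quadrature identities are asserted in exact
rational arithmetic at construction, which pins the `A` entries uniquely:
given the third row and `b`, the order conditions `b·Ac = 1/120` and
`b·Ac² = 1/360` plus the row sum determine `(a41, a42, a43)` exactly.

Fitted weights:

* **Method a** — for `|ν| ≥ 0.05`, the six unknowns `(η, β, b1..b4)` solve
  the four trigonometric conditions (defect operator annihilating
  `exp(±iωt)`, `t exp(±iωt)`) plus `b·e = 1/2`, `b·c = 1/6`. The 6×6 system
  is assembled and solved in 80-bit extended precision (a small pivoted LU;
  LAPACK does not accept that dtype) because the solution emerges from
  `(η − cos ν)/ν²`-type cancellations that cost ~`ε/ν⁴` in double precision;
  the two branches then agree to ≥ 10 significant digits at the switch
  point. Below 0.05 the tabulated Taylor series is used. Residuals of all
  six equations at the returned weights are < 1e−12 whenever the solve is
  used. A condition-number cutoff (1e12) falls back to the series, flagged
  in the `source` field.
* **Methods b and c** — evaluated from their tabulated truncated series
  (exact rationals, even powers of ν through ν⁸ for the `b_i`, ν¹⁰ for η
  and β). Documented validity radius `|ν| ≤ 1.5`: the coefficients decay
  fast enough that the truncation tail is ≲ 1e−12 there; beyond it a
  warning is issued and the value still returned. Deriving these two
  methods' full trigonometric fitting systems is not attempted: their
  reference sets make the fitting system overdetermined (the polynomial
  members force `η = 1` exactly, yet the tabulated series have
  `η = 1 + O(ν⁸)`), so the series are taken as the methods' definition.
  Consequently their defect residuals on polynomial reference members do
  not vanish to machine precision but to the `η − 1 ~ 3e−9`-at-`ν = 0.5`
  scale; the tests bound rather than zero them.

A ν-independent check: method c's coefficient series equals method a's with
`ν → 2ν` coefficientwise (their reference sets differ by `ω → 2ω`), which
the test suite asserts exactly — a strong guard on the tabulated rationals
of both.

**Order verification.** Truncated power series over `fractions.Fraction`
(unknown-beyond-truncation semantics: arithmetic propagates the valid order
as the minimum of the operands') form each condition
`b(ν)·φ = 1/γ + O(ν^p)` symbolically; the required leading coefficients are
compared as exact rationals. The reduced ten-condition list is the default
(valid under `A e = c²/2`, asserted separately); the five conditions that
assumption subsumes can be checked too (`full_list=True`) and also pass.
Conditions whose required power exceeds a series' truncation are reported
"not checkable", never silently passed.

**Stepping.** Fixed step only: `n = round((t_end − t0)/h)` must hit the end
point within `1e−9·h` (no partial final step; all benchmark step sizes
divide their intervals exactly). `ν = ωh` is computed once per run and the
weights solved once — the fitting frequency is constant along the
trajectory. Evaluation counts are exact by construction: 1 `f` + 4 `g` per
TDRK step; the order-six Runge–Kutta baseline (Butcher's seven-stage 1964
tableau, order verified numerically in the tests) costs 7 `f`. State
positivity is *not* enforced (coarse steps may transiently undershoot);
only finiteness is checked, and a failure reports the offending stage and
time. The production loop is an unrolled four-stage path bound to plain
floats; it is bit-identical to the generic checked stepper (asserted in
tests), and a fitted method at ω = 0 is bit-identical to the prototype.

## Analysis conventions

**Steady states.** Damped Newton with the analytic Jacobian: full step,
halved up to 30 times when `‖f‖_∞` fails to decrease or when, starting from
a strictly positive iterate, the step would leave the positive orthant (the
physical domain; without this safeguard one in ~10 random starts wanders to
negative concentrations and stalls). Tolerance 1e−12 on `‖f‖_∞`.

**Limit-cycle frequency = 2π/period.** Fine prototype integration
(two-gene: h = 0.005, burn-in 200, window 200; PER: h = 0.01, burn-in 300,
window 300 — windows long enough for ≥ 13 cycles after the transient has
decayed below measurement resolution), strict local maxima of the protein
readout refined by three-point quadratic interpolation, period = mean
peak-to-peak interval. The standard deviation of the intervals is reported;
a run is flagged unreliable above 1e−3 of the mean. Fewer than three maxima
raises "no sustained oscillation detected". *Caveat:* the measured cycle
frequencies are 0.977999 (two-gene) and 0.265530 (PER). The value this
package computes for the two-gene model differs by 1.2% from the benchmark
value in circulation (0.989478); the measurement here is converged to ~1e−7
in h and window and agrees with an independent adaptive integrator, and no
transient window reproduces the larger value (the transient frequency is
lower still). Neither model's cycle frequency equals the linearized
rotation rate at the steady state (1.049997 / 0.297276) — the spiral slows
as the orbit grows.

**Global error (GE).** Deviation of one designated component (Protein 1 for
the two-gene model, nuclear PER for the circadian model) from a reference
solution, *at the final time* `t = 100` by default — the convention under
which the published benchmark tables for these models are reproduced to all
printed digits; a max-over-grid norm is available (`norm="max"`). The
reference is the prototype itself at `h_ref = min(h/256, 1/1024)`, compared
only at the coarse grid's time points: being sixth-order, its error sits
8+ orders below the coarse error, and being self-generated it keeps the
pipeline dependency-free. Sweeps and tables share a single reference
trajectory per (model, interval).

**Empirical order** is the least-squares slope of `log₂ GE` vs `log₂ h`
over `h ∈ {1/4, 1/8, 1/16, 1/32}`, measured in the max norm: at the finest
steps the endpoint error reaches the double-precision accumulation floor
(~1e−14) and would bias the fit, while the max-over-grid error remains
truncation-dominated. Measured slopes: 5.95 (two-gene), 6.36 (PER). The
ladder shares one reference at the finest implied step (1/8192), strictly
finer than each per-h default.

**Best fitting frequency.** GE(ω) evaluated on a grid from 0 to
`min(π/h, 4)` at resolution 0.001 (matching the 3-decimal convention for
reported best frequencies); ties resolve to the smallest ω, failed grid
points are excluded with a warning. GE(ω) near the optimum is a sharp
V-shaped notch — the endpoint error changes sign — so minima are
well-localized but the error *at* a slightly-off ω can be orders of
magnitude above the notch bottom. For the PER model at h = 1/2, method a's
notch sits at ω\* = 1.982 (GE\* = 7.2e−10), 0.011 above the benchmark value
in circulation (1.971); the location was cross-checked against an
independent adaptive-integrator reference (the signed endpoint error
crosses zero between 1.981 and 1.982). The six other benchmark best-ω
values checked (methods b and c at h = 1/2, method a at other steps on both
models) are all recovered to within ±0.002.

## Problem sizes

The shipped tests and the acceptance script use the benchmark intervals
`[0, 100]` with step ladders down to 1/32 (references to 1/8192 —
~8·10⁵ reference steps per model), frequency runs to t = 400/600 at
h = 0.005/0.01, and full-resolution ω sweeps at h ∈ {1/2, 1/4}; the whole
suite completes in a few minutes on one core.

## Known limitations

* Explicit, fixed-step only: no adaptive control, dense output, or stiff
  (implicit) variants; step sizes must divide the interval.
* The fitting frequency is a single global scalar per run; no per-step or
  per-component fitting, and no stage-level (A-matrix) fitting.
* Methods b and c exist only through their truncated series; outside
  `|ν| ≤ 1.5` their accuracy degrades gracefully but is not certified.
* Models are deterministic ODEs: no delay terms, no stochastic (Gillespie)
  simulation, no parameter inference.
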