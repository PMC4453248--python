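# Methods

## Model

A population of `N` individuals sits on a directed graph with edge-weight
matrix `W`; `w_ij` is the probability that `i`'s offspring replaces `j`
when `i` reproduces, so every row sums to 1.  All built-in families have
`w_ii = 0` (no self-replacement); generic matrices with self-loops are
accepted and flagged.  Updating is birth–death: one individual reproduces
per step, chosen with probability proportional to fitness (`r` for the
mutant type, 1 for residents), and the offspring replaces a neighbour
drawn by edge weight.  A state is a binary occupancy vector; the chain
absorbs at extinction (all 0) and fixation (all 1), and `x_v` denotes the
probability of absorbing at fixation from state `v`.

State indexing: bit `k − 1` of the integer state index corresponds to
vertex `k`, so a lone mutant at vertex `k` is state `2^(k−1)` and the
labels `x_1, x_2, x_4, x_8, …` mean single-mutant starts at vertices
1, 2, 3, 4, ….

## Master-equation solver

For each interior state the one-step balance equation is assembled with
`a(v) = v·W` (mutant reproductive weight into each vertex) and
`b(v) = v'·W`.  The two boundary values are hard substitutions — moved to
the right-hand side, never solved for — leaving a dense `2^N − 2` system.

* **Float backend**: LAPACK LU via `numpy.linalg.solve`; for systems of
  dimension ≤ 256 a condition estimate is computed and anything above
  `1e12` is rejected as numerically singular rather than returned.
* **Rational backend**: Gauss–Jordan elimination on `fractions.Fraction`
  entries.  Family constructors build `W` exactly (floats are converted
  to their exact binary rationals), so results are exact for rational
  parameters and fitness.

The default full-state-space cap is `N = 12`; beyond it the solver
refuses and points at the lumped solver.

**Reducible graphs.**  If some interior state has zero total transition
rate (two mutually unreachable components, for example), the system is
singular and the solver raises an error naming the trapped states.  At
*quarantine endpoints* — e.g. the (s, n) partial bipartite graph at
`p = 1, q = 0`, where one block stops receiving any reproductive weight —
the strict absorption probability jumps discontinuously (most starts can
then never reach fixation), while the scientifically meaningful quantity
is the limit of the solution along the parameter, which exists because
the solution is a rational function of the weights.  Fitness-crossing
searches therefore evaluate such endpoints by Richardson extrapolation,
`2 f(1 − ε) − f(1 − 2ε)` with `ε = 1e−5`, carrying an `O(ε²) ≈ 1e−10`
continuation error; condition numbers at that offset stay near `1e7`,
well inside float accuracy.  When a bisection residual falls below
`1e−12` the sign is recomputed with the rational backend (at exact
rational offsets in the continued case) before being trusted.

## Lumped solver for circular flows

Vertices within a level of a uniform-weight dual circular flow are
exchangeable, so states lump to level occupancies `(m_0, …, m_k)`,
reducing `2^N − 2` unknowns to `Π(n_i + 1) − 2`.  The lumped transition
weights are derived directly from the construction: level `s` gains a
mutant with weight `r (n_s − m_s)[m_{s+1} p + m_{s−1}(1 − p)]/n_s` and
loses one with weight `m_s[(n_{s+1} − m_{s+1}) p + (n_{s−1} − m_{s−1})
(1 − p)]/n_s` (indices mod `k + 1`).  The lumping is validated against
the full `2^N` solver on several profiles to `1e−10`; the
multiplicity-weighted average `ρ = Σ n_i x_i / N` agrees between the two
routes.  Per-level (tuned) weights break the within-level derivation
above only in that the same lumping argument would need per-level `p_i`
bookkeeping; the package keeps the lumped solver restricted to uniform
weights and sends tuned flows through the full solver, which at the
relevant sizes (N ≤ 8) is cheap.

## Spectra

The Laplacian is `Δ = Φ^{1/2}(I − W)Φ^{−1/2}` with `Φ = diag(φ)`,
`φ·W = φ`, `Σφ = 1`.  Two consequences the code exploits:

* `Δ` is a similarity transform of `I − W`, so eigenvalues are always
  reported from `I − W` — available even when a reducible graph has no
  unique `φ` (the matrix `Δ` itself then stays undefined and the report
  says why).  The count of near-zero eigenvalues (tolerance `1e−10`)
  equals the number of components.
* If the chain is reversible (`φ_i w_ij = φ_j w_ji`), `Δ` is symmetric
  and the antisymmetric part `Δ_A = (Δ − Δᵀ)/2` vanishes identically.
  Partial bipartite graphs are reversible for every `(p, q)`, so their
  `Δ_A` polynomial is `λ^N`; directional bias is a cycle/flow phenomenon.
  For biased cycles `φ` is uniform, `Δ = I − W`, and `Δ_A` is circulant
  with eigenvalues `(1 − 2p) i sin(2πj/N)` — all imaginary, all carrying
  the bias factor `1 − 2p`, vanishing at the balanced point `p = 1/2`.
  A `k+1`-level flow inherits exactly the `k+1`-cycle's `Δ_A` spectrum
  padded with zeros, and its `Δ` characteristic polynomial is
  `(λ−1)^(N−k−1)` times the `k+1`-cycle polynomial.

The cycle characteristic polynomial is generated from the coefficient
recurrence `C^N_j = C^(N−1)_j + C^(N−2)_(j−1)` with `C^N_0 = 1`,
`C^N_1 = N` and the convention `C^M_j = 0` for `2j > M`, plus an endpoint
term (`p^N + (1−p)^N` for odd `N`; a squared half-power correction split
by `N mod 4` for even `N`).  Single-link polynomials factor into lumped
roots `s/(s−1)` and `n/(n−1)` and a quartic obtained exactly from the
4×4 equitable-partition quotient of `W`; the quartic always divides by
`λ`, leaving the zero eigenvalue and a cubic.  All polynomial algebra is
exact (sympy rationals); every closed form is asserted to vanish at the
numeric eigenvalues to `1e−8` across parameter grids in the tests.
Complex eigenvalues are reported as complex and sorted by real part then
imaginary part; tests compare spectra as multisets with rounded keys
because near-degenerate pairs make strict complex ordering unstable.

## Structure metrics

* **Conductance** `C(S) = N/(|S||V∖S|) Σ_{i∈S, j∉S} w_ij`, exact in
  rationals.  The global minimum is found by exhaustive subset scan,
  capped at `N = 20`.
* **Communicability** `V = e^W` by scaling-and-squaring, or the literal
  order-6 Taylor series; for row-stochastic `W` the entrywise truncation
  remainder is below `e − Σ_{k≤6} 1/k! ≈ 2.3e−4`, and the tests assert
  `3e−4` agreement between the modes.  For partial bipartite graphs the
  exponential is evaluated in closed form from the equitable-partition
  decomposition (`W` has eigenvalues `1`, `p+q−1`, `−p/(s−1)` and
  `−q/(n−1)`); the resulting entry formulas and trace are verified
  against `expm` to `1e−12`.  The trace minimiser coincides exactly with
  the eigenvalue-equality point `(p, q) = (s−1, n−1)/(n+s−1)`.
* **Hitting times** via the Kemeny–Snell fundamental matrix
  `Z = [I − (W − A)]^{−1}` (every row of `A` is `φ`) and
  `M = (I − Z + J Z*) D`.  `D` is the diagonal of reciprocal stationary
  probabilities — fixed by requiring agreement with an independent
  first-step-analysis linear solve, which the tests enforce to `1e−9` on
  every family.  Diagonal entries of `M` are expected return times
  `1/φ_j`.  Closed-form hitting expressions for the two-component
  families were derived by exact symbolic first-step analysis and are
  shipped only in that oracle-verified form; entries whose defining
  transitions lose all probability at parameter endpoints are reported
  as `+inf`.  One structural constant worth noting: from a non-linking
  vertex of an internally complete `n`-component, the linker is reached
  in `n − 1` expected steps regardless of the cross-coupling (excursions
  out of the component can only pass through the target), so the (3,4)
  single-link value is exactly 3.
* **Stationary-point search**: multi-start quasi-Newton root-finding on
  the central-difference gradient (`h = 1e−5`), accepting points with
  gradient norm below `1e−10`, deduplicated and classified by the
  central-difference Hessian's eigenvalues.  On the (3,4) single-link
  average-centrality surface this finds a single interior saddle at
  `(0.5542, 0.3734)` (order-6 series; the exact-expm surface moves it by
  under `1e−3`).
* **Cycle tipping points** by golden-section search (tolerance `1e−6`)
  on the one-step hitting time.  Direction naming: "ccw" is the
  increasing-index step, which the package's weight convention executes
  with probability `1 − p`; its N=5 argmax is 0.68806 and the mirrored
  direction peaks at exactly one minus that.

## Temperature tuning

The inverse problem — choose per-level flow weights realising a target
temperature profile `t` — is the cyclic linear system
`n_{i+1} p_{i+1} − n_{i−1} p_{i−1} = t_i n_i − n_{i−1}`, solved by exact
rational RREF.  Necessary condition: `Σ t_i n_i = N` (total incoming
weight equals total outgoing weight).  With an odd number of levels the
recurrence couples all weights: rank `k`, a one-parameter affine family.
With an even number it splits into two alternating chains whose
consistency conditions appear as zero rows with nonzero right-hand
sides; violations raise a structural-infeasibility error.  RREF pivots
left-to-right, so the free parameters are the highest-index weight of
each chain.  Feasibility intervals come from intersecting the `[0, 1]`
box constraints; endpoints are exact Fractions, empty intersections
raise with the violated bound named.  Degenerate profiles (repeated
sizes producing `0 = 0` rows) enlarge the family automatically through
the rank computation.  A family member tuned to `t ≡ 1` is verified
doubly stochastic, hence fixes at the Moran probability; tuning to any
non-flat profile does *not* determine fixation — members of one family
differ in `ρ` by far more than solver error, which is exactly why
temperature alone is a weak summary of a graph's selective effect.

## Synthetic fixtures

`fixture_graph` emulates arbitrary influence structures for property
tests: row-stochastic matrices from integer-valued random rows (exact
normalisation), and doubly stochastic matrices as convex combinations of
`2N` random derangement permutations with exact rational coefficients —
a Birkhoff-style construction guaranteeing both marginals exactly and a
zero diagonal.  These fixtures exercise the solvers on dense, asymmetric,
irregular weights; they do not emulate sparse contact networks, degree
heterogeneity at scale, or `N` beyond 10, so the passing isothermal and
oracle suites certify correctness of the machinery at desk scale, not
behaviour on large empirical networks.

## Numerical constants

| constant | value | where |
|---|---|---|
| row-sum tolerance (float input) | 1e−12 | graph validation |
| condition limit, float solve | 1e12 | master solver |
| zero-eigenvalue tolerance | 1e−10 | spectra |
| closed-form polynomial residual | 1e−8 | spectra tests |
| bisection tolerance (default / crossings) | 1e−7 / 1e−5 | crossing finders |
| golden-section tolerance | 1e−6 | tipping points |
| continuation offset ε | 1e−5 | endpoint crossings |
| rational-sign guard | 1e−12 | endpoint crossings |
| FD step / gradient acceptance | 1e−5 / 1e−10 | stationary points |
| exhaustive-conductance cap | N = 20 | metrics |
| full-state-space cap | N = 12 | master solver |

## Limitations

The full solver is exponential in `N` by design (exact answers, small
graphs); the rational backend grows expensive beyond `N ≈ 7`.  Hitting
times and stationary distributions require irreducibility; endpoint
divergences are reported, not smoothed.  Only birth–death updating is
implemented — death–birth and voter dynamics reweight the master
equations and are out of scope — and time-to-fixation distributions are
not computed.
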