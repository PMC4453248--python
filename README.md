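# graphfix

Exact birth–death fixation probabilities and structural metrics on small
weighted digraphs.

## The problem

A structured population of `N` individuals is modelled as a directed graph:
vertex `i` influences vertex `j` with probability `w_ij`, and every row of
the edge-weight matrix `W` sums to 1.  Under **birth–death updating** an
individual is chosen to reproduce with probability proportional to fitness
(a mutant type has fitness `r`, residents 1) and its offspring replaces a
neighbour drawn according to the edge weights.  Starting from a set of
mutant vertices `v`, the quantity of interest is the **fixation
probability** `x_v` — the chance that the mutant type eventually occupies
every vertex.  The same machinery describes the spread of a rumour, an
infection or an innovation through a polarized or layered population.

The fixation probabilities of all `2^N` initial states satisfy a linear
master system: with `a(v) = v·W`, `b(v) = v'·W` (`v'` the complement),

```
[ r a(v)·v' + b(v)·v ] x_v  =  Σ_i r a_i(v) v'_i x_{v+e_i}  +  Σ_i b_i(v) v_i x_{v-e_i},
x_extinction = 0,   x_fixation = 1,
```

which `graphfix` assembles and solves densely — in floats or in exact
rational arithmetic — for any row-stochastic `W` with `N ≤ 12`.  The
reference value is the Moran probability of the complete graph,
`ρ_M = (1 − 1/r)/(1 − 1/r^N)`; a graph *amplifies* or *suppresses*
selection according to whether its single-mutant fixation probability
exceeds or falls short of `ρ_M`.  By the isothermal theorem the two agree
exactly iff `W` is doubly stochastic.

Four parametric graph families are built in:

* **biased cycles** `C(N, p)` — probability `p` one way round, `1 − p` the
  other (always doubly stochastic);
* **dual circular flows** — a ring of vertex levels `(n_0, …, n_k)` with
  edges only between adjacent levels; `p = 1` is the funnel, `p = 0` the
  cascade, and per-level weights can be *tuned* to match a prescribed
  vertex-temperature profile;
* **partial bipartite graphs** — two internally complete blocks with
  cross-coupling `(1 − p)/n`, `(1 − q)/s`;
* **single-link graphs** — two complete components joined through a single
  pair of directed edges.

Alongside fixation the package computes the structure measures that track
it: the directed-graph Laplacian `Δ = Φ^{1/2}(I − W)Φ^{−1/2}` and its
spectrum (with closed-form characteristic polynomials per family, each
cross-checked against the numeric eigensolver), subset conductances
(Cheeger constants), communicability `e^W` (exact and the sixth-order
series), and expected hitting times via the Kemeny–Snell fundamental
matrix (validated against an independent first-step-analysis solver).

## Worked example

Fixation on the (3,4) partial bipartite graph with `p = 1/5`, `q = 1/2`
at fitness `r = 2`, in exact rational arithmetic:

```python
from fractions import Fraction
from graphfix import partial_bipartite, solve_fixation, moran_probability

g = partial_bipartite(3, 4, Fraction(1, 5), Fraction(1, 2))
sol = solve_fixation(g, 2, backend="rational")
print(float(sol.single_vertex[1]))   # 0.5342355116151006  (mutant in the 3-block)
print(float(sol.single_vertex[4]))   # 0.4813489457667547  (mutant in the 4-block)
print(float(sol.rho))                # 0.5040146168446172  (average)
print(float(moran_probability(7, 2)))  # 0.5039370078740157
```

A lone mutant fixes more easily from the small block than from the large
one here, and on average this graph is a very slight amplifier at `r = 2`.
The two single-mutant curves coincide exactly on the conductance-balance
line `q = (1 + 3p)/4`; at `(p, q) = (1/3, 1/2)` all three nonzero
Laplacian eigenvalues merge and the communicability trace is minimal.

Tuning a (1,2,3) flow to the flat temperature profile forces the unique
weights `(p_0, p_1, p_2) = (1, 0, 2/3)`, whose graph is doubly stochastic
and fixes at exactly the Moran value:

```python
from graphfix import isothermal_tuning, solve_fixation

sol = isothermal_tuning((1, 2, 3))
print(sol.weights())                       # (Fraction(1, 1), Fraction(0, 1), Fraction(2, 3))
fix = solve_fixation(sol.graph(), 2, backend="rational")
print(fix.rho)                             # 32/63  == moran_probability(6, 2)
```

The same operations are available from the command line:

```
graphfix build --family cycle --n-vertices 5 --p 7/10 --out c5.json
graphfix fixation --graph c5.json --r 2 --backend rational
graphfix tune --sizes 1,2,3 --t 1,1,1
graphfix crossing --family flow --sizes 1,2,3 --p 1 --target moran --bracket 1.01,20
```

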