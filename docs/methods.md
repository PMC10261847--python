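# Methods

## The model

Three boundedly rational populations interact repeatedly over the allocation
of scarce medical supplies during a public health emergency:

* a **GNPO** (government-owned nonprofit organization, e.g. a Red Cross
  branch) that either *allocates on demand* (probability `x`) or not;
* a **hospital** that either *accepts* the allocation plan (probability `y`)
  or *refuses and fights*;
* a **government** that supervises *strictly* (probability `z`) or *loosely*.

Twenty-one non-negative parameters in a common abstract payoff unit (the
model names no currency) populate the 8-cell payoff table: penalties `K1,
K2, P1, P2`, reputation losses `V1 < V2`, the GNPO's opportunistic gain `A`,
compensations `W1 < W2`, the reward `B`, coordination costs `H1, H2`,
social benefits `R1, R2`, effort and supervision costs `H3, H4 > H5`, the
accountability loss `T > H4`, and the hospital's fighting degree
`alpha ∈ [0, 1]`, which scales every fighting-related payoff.

Strategy shares evolve by **replicator dynamics**: each share grows in
proportion to the gap between its pure-strategy expected payoff and the
population average, which factors as

```
dx/dt = x(1-x) [ alpha(V2-V1)(1-y) + z K2 - A ]
dy/dt = y(1-y) [ z((B + alpha P2)(1-x) + x alpha(P1 - P2)) + x alpha(W2-W1) + alpha(H2 - W2) ]
dz/dt = z(1-z) [ ... affine in x, y, xy ... ]
```

Five parameters (`D, E, R1, H1, H3`) appear in payoffs but cancel from all
three brackets; the field is bit-identical under their perturbation (tested).
The unit cube is forward invariant and its corners are rest points.

## Stability

Only strict Nash equilibria — the eight cube corners — can be evolutionarily
stable in an asymmetric game, so classification is restricted to corners.
There the Jacobian is diagonal; its eigenvalues have exact affine closed
forms, used as primary output with a numeric eigendecomposition of the
analytic Jacobian as cross-check (agreement ≲ 1e-14 relative). The Lyapunov
indirect method assigns the class: all real parts below `-eps` → ESS; any
above `+eps` → unstable; otherwise **critical**, reported as such and never
guessed (`eps = 1e-9` by default). Interior rest points are located
numerically from a small lattice of starts and reported unclassified.

Two inequality sets govern the empirically interesting regime: condition 1
(`alpha(W2-H2) < 0` and `H5-H4-B+K2+R2 < 0`) stabilises E3 = (0,1,0)
(not-on-demand, accept, loose), and condition 2 (`A < K2`, `H4-H5-R2 < 0`,
`alpha(W1-P1-H2) < 0`) stabilises E8 = (1,1,1) (on-demand, accept, strict).
The calibrated baseline (`K1=80, K2=60, V1=100, V2=150, A=25, H1=80, D=300,
E=200, alpha=0.6, W1=80, W2=100, B=80, P1=160, P2=80, H2=110, R1=170,
H3=160, H4=100, H5=50, R2=60, T=150`) satisfies both, giving exactly two
ESS with eigenvalues (−6, −25, −10) at E3 and (−35, −10, −114) at E8.

Note one discrepancy with the commonly printed sign pattern for E1: its
second eigenvalue `alpha(H2 - W2)` is *positive* (+6) whenever condition 1
holds; E1 is unstable either way, and this package always reports computed
signs.

## Preference volumes

Each player's indifference surface (`y*(z)`, `x*(z)`, `y**(x)`) splits the
cube; the volume on the attracting side of a pure strategy is read as the
probability of evolving toward it. `V_G1` (GNPO → on-demand) has the closed
form `(A-K2)(A-K2+2αV1-2αV2) / (2αK2(V2-V1))`, reproduced by quadrature of
its defining integral to ≲1e-9 (the integrand is affine, so the midpoint
rule is exact up to roundoff).

The surfaces are rational in one coordinate and can exit the cube or blow up
inside it (at the baseline `x*(z)` has a pole at z = 0.375, so the raw
hospital-volume integral diverges). The **geometric volumes therefore clip
the surface into [0, 1] pointwise** before a 1-D midpoint quadrature
(default 2001 cells; the integrand depends on a single coordinate, so the
other two axes integrate to 1). Singular cells contribute the clip-range
midpoint; they have measure zero in the limit and the reported volumes are
grid-stable to <1e-3 under refinement. Both the as-printed and the clipped
GNPO values are reported (0.9236 vs 119/144 ≈ 0.8264 at the baseline);
which of the two the original construction intended is not decidable, so
neither is suppressed.

**Monotonicity.** The sign table differentiates the clipped probability
volumes by central differences (relative step 2e-3, grid 20001), with an
"indeterminate" verdict when the difference is within 10× the quadrature
self-convergence error, and separately reports the uniform pointwise sign of
the unclipped surface's partial derivative. The two conventions can
genuinely disagree: clipping freezes the surface at the cube boundary while
moving the pole re-partitions the cube. At the baseline the clipped
on-demand volume rises in `alpha` and `K2` and falls in `A` (even though the
unclipped antiderivative *falls* in `alpha`); the clipped strict-supervision
volume rises in `K2`, `T`, `P2` and falls in `B`; the clipped
refuse-and-fight volume falls in `P1` but *rises* in `B` and `P2`, whereas
its unclipped surface falls pointwise in `B` and `P2` and rises in `P1`. No
single convention makes all ten claimed signs hold; the package reports both
computed facts per row.

## Numerics

* **Integration:** `scipy.integrate.solve_ivp` RK45, `rtol 1e-8`,
  `atol 1e-10`, horizon 50 time units, early stop when the field norm drops
  below `1e-8`. The right-hand side evaluates on states clipped to the cube,
  so boundary overshoot (a local-error artifact, observed ≲2e-6 at default
  tolerances and shrinking with them) does not feed back; output states are
  clipped. Terminal states are invariant to 1e-6 under tolerance halving.
* **Default start** (0.5, 0.5, 0.5) — a symmetric-ignorance prior, since the
  original sensitivity figures state no initial condition — plus an optional
  3³ interior lattice for basin exploration.
* **Strict inequalities** in validation are checked with zero tolerance;
  `allow_ties=True` admits boundary ties (needed because the printed
  accountability grid includes `T = H4 = 100`, where the dynamics remain
  well defined).
* **Scenario generation:** independent uniform draws on ±50% intervals
  around the baseline (`alpha` clipped to [0,1]), rejection-sampled against
  the model inequalities and, optionally, the condition sets; seeded and
  bit-reproducible, with a 1e-4 acceptance-rate floor before erroring.

## Sensitivity sweeps

The nine preset sweeps use the printed grids verbatim (`alpha` 0.1–0.9 step
0.1; `H2` 80–140; `H4` 70–130; `H5` 30–70; `T` 100–200; `K1`, `B` 40–120;
`P1` 120–200; `A` 10–40). Runs are deterministic; outputs (per-sweep CSV +
JSON summary) are byte-stable across reruns. Because the original figures'
initial state and horizon are unstated, sweep results here are read as
convergence/ordering statements at the default start, not as pointwise curve
reproductions. Two caveats the sweeps themselves expose:

* `H5 = 40` is exactly degenerate (`H4 - H5 - R2 = 0`): E8 becomes critical,
  the whole `x = y = 1` edge is a line of rest points, and the trajectory
  settles at (1, 1, ≈0.884) — a rest point but not an ESS. All other 50
  preset runs terminate at ESS corners.
* At the default start, the transient probability of on-demand allocation is
  weakly *decreasing* in `H2` and the time-averaged strict-supervision share
  *decreasing* in `alpha`; published narrative for those figures claims the
  opposite directions, which could not be reproduced from the printed
  equations at any start probed. These orderings are therefore reported, not
  asserted.
* The direction reversal along the `A` grid is emitted as an exploratory
  diagnostic (detected flip value per start), never asserted: it is
  start-state dependent.

## What the synthetic scenarios do and do not show

Random scenarios exercise the *algebraic* machinery (field identities,
Jacobians, classification, volume identities) across the whole admissible
parameter region. They say nothing about which parameter magnitudes are
realistic for an actual emergency — the baseline encodes that judgement —
and independence of draws is itself a modelling idealisation the underlying
theory states explicitly.

## Problem sizes

Default suite sizes: 100 random scenarios (60 condition-enforced), 1000
field-comparison pairs, 100 finite-difference states, 800 corner
eigendecompositions, 51 sweep integrations, 2001-cell volume grids
(20001 for derivative estimation). These are the package's reference sizes
for reproducible reports; all scale linearly via function arguments.
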