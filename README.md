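# supplygame

Tripartite evolutionary game of emergency medical-supply allocation.

During a public health emergency, donated medical supplies flow through a
government-owned nonprofit organization (GNPO, e.g. a Red Cross branch) to
hospitals, under government supervision. The three parties have conflicting
interests and act under bounded rationality: the GNPO chooses to *allocate
on demand* (probability `x`) or not, the hospital *accepts* the plan
(probability `y`) or *refuses and fights*, and the government supervises
*strictly* (probability `z`) or *loosely*. `supplygame` implements the full
evolutionary-game analysis of this system for researchers in emergency
management and game-theoretic policy modelling:

* the 8-profile payoff table over 21 payoff parameters and expected payoffs
  under mixed strategies (`payoff`);
* the replicator dynamics `du/dt = u(1-u)·bracket(u)`, threshold surfaces
  `y*(z)`, `x*(z)`, `y**(x)`, and adaptive trajectory integration
  (`dynamics`);
* enumeration of the eight pure-strategy equilibria, exact closed-form
  Jacobian eigenvalues at each corner, and Lyapunov (indirect method)
  classification into ESS / unstable / critical (`stability`);
* strategy-preference volumes of the phase diagram with their monotonicity
  sign table (`volumes`);
* the nine parameter-sensitivity sweeps with CSV/JSON reporting
  (`experiments`), plus a seeded random scenario generator under the model's
  inequality constraints (`params`).

## Worked example

```python
import supplygame as sg

p = sg.baseline()                      # calibrated emergency scenario
for r in sg.classify_equilibria(p):
    print(f"{r.label} {tuple(int(v) for v in r.point)}  "
          f"eigenvalues {r.eigenvalues}  ->  {r.classification}")

traj = sg.integrate(p)                 # replicator run from (0.5, 0.5, 0.5)
print("terminal:", tuple(round(float(v), 6) for v in traj.terminal),
      "converged:", traj.converged)

rep = sg.volume_report(p)
print(f"V_G1 closed form: {rep.v_g1_closed:.5f}  clipped: {rep.v_g1_clipped:.5f}")
print(f"V_Q1: {rep.v_q1:.5f}  V_N1: {rep.v_n1:.5f}")
```

prints

```
E1 (0, 0, 0)  eigenvalues (5.0, 6.0, 348.0)  ->  unstable
E2 (1, 0, 0)  eigenvalues (18.0, -5.0, 336.0)  ->  unstable
E3 (0, 1, 0)  eigenvalues (-6.0, -25.0, -10.0)  ->  ESS
E4 (0, 0, 1)  eigenvalues (65.0, 134.0, -348.0)  ->  unstable
E5 (1, 1, 0)  eigenvalues (25.0, -18.0, 10.0)  ->  unstable
E6 (1, 0, 1)  eigenvalues (114.0, -65.0, -336.0)  ->  unstable
E7 (0, 1, 1)  eigenvalues (35.0, -134.0, 10.0)  ->  unstable
E8 (1, 1, 1)  eigenvalues (-35.0, -10.0, -114.0)  ->  ESS
terminal: (1.0, 1.0, 1.0) converged: True
V_G1 closed form: 0.92361  clipped: 0.82639
V_Q1: 0.62519  V_N1: 0.99291
```

Reading: at the baseline the system is **bistable**. Evolution ends either at
(not-on-demand, accept, loose supervision) or at (on-demand, accept, strict
supervision); from the symmetric start it reaches the second, the socially
preferred outcome. The eigenvalues are the exact affine closed forms
evaluated at the baseline — all negative exactly at the two ESS. `V_G1` is
the probability mass of the strategy cube pulled toward on-demand
allocation (both the as-printed and the clipped geometric convention are
reported; they differ because the threshold surface exits the cube — see
`docs/methods.md`).

The same analyses are available from the shell:

```sh
supplygame --out out stability        # per-corner report, stability.json
supplygame --out out sweep alpha      # one preset sensitivity sweep
supplygame --seed 1 --out out scenarios --n 20 --enforce both
```

## Layout

```
src/supplygame/   params, payoff, dynamics, stability, volumes, experiments, cli
tests/            unit + property tests; test_acceptance.py holds the
                  end-to-end checks of the headline results
docs/methods.md   model, conventions, numerics, known degeneracies
```
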