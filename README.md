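# rpsmeta

Metapopulation rock-paper-scissors dynamics on networks: a simulator and
analysis library for cyclic three-species competition coupled by
random-walk migration between habitat patches.

## The problem

Three species in cyclic dominance — rock (R) beats scissors (S), S beats
paper (P), P beats R — coexist through replacement reactions

    R + S → R + R   (victory rate a)
    S + P → S + S   (victory rate b)
    P + R → P + P   (victory rate c)

In a single well-mixed habitat the densities obey

    dρ_R/dt = a ρ_R ρ_S − c ρ_P ρ_R        (and cyclically for S, P),

which oscillates forever around the equilibrium
(ρ_R, ρ_S, ρ_P)ₑ = (b, c, a)/(a+b+c): coexistence is only *neutrally*
stable, so any perturbation shifts the orbit permanently.

This package implements the metapopulation extension: the population is
split over the nodes of an undirected graph, and each individual leaves
its node at unit rate for a uniformly random neighbor, giving the
degree-weighted migration term

    dρ_{α,i}/dt = Σ_{j∈N_i} ( ρ_{α,j}/k_j − ρ_{α,i}/k_i ) + [reactions in node i],

where k_i is the degree of node i.  The interior equilibrium factorizes
into a degree-proportional node share times the single-habitat species
split:

    ρ_{α,i,e} = (k_i / Σ_j k_j) · ρ_{α,e}.

The dichotomy the library makes measurable: when the graph is
**homogeneous** (all degrees equal) the equilibrium is neutrally stable
and every node oscillates in synchrony, at one third of the single-habitat
frequency for the three-node complete graph; when the graph is
**heterogeneous** (a hub exists) the equilibrium is a stable focus — the
oscillations damp out and all three species coexist at fixed,
node-dependent densities.  Network heterogeneity stabilizes biodiversity.

Intended users: anyone studying cyclic competition, replicator dynamics
on networks, or metapopulation models who wants closed-form equilibria,
Jacobian stability classification, and quantitative oscillation
observables (frequency, phase lag, damping, synchronization) from one
consistent toolkit.

## Worked example

Equilibrium and stability of the heterogeneous three-node path (node 1
is the hub; migration between nodes 2 and 3 must pass through it), at
unit victory rates:

```sh
$ rpsmeta equilibrium --graph path --n 3
graph: 3 nodes, 2 links (heterogeneous)
equilibrium densities rho[species, node] (nodes 1-based):
  R:  0.16666667  0.08333333  0.08333333
  S:  0.16666667  0.08333333  0.08333333
  P:  0.16666667  0.08333333  0.08333333
node totals: 0.50000000  0.25000000  0.25000000
closed-form vs numeric max gap: 0.000e+00
classification: stable_focus
```

Each species settles at 1/6 in the hub and 1/12 in the leaves — the hub
(degree 2 of the 4 total degree) holds half the population — and the
Jacobian spectrum classifies the equilibrium as a stable focus: the
densities spiral into coexistence instead of cycling forever.

The same from Python, including a trajectory and its observables:

```python
import numpy as np
from rpsmeta import (Rates, MetaState, path_graph, integrate,
                     classify_stability, SeriesWindow, damping_rate)

g = path_graph(3)
rates = Rates(1.0, 1.0, 1.0)
init = np.full((3, 3), 0.1); init[0, 2] = 0.2   # rock in node 3 doubled
tr = integrate(MetaState(init), g, rates, t_end=3000.0, n_points=6001)

print(tr.final_state.rho[:, 0])   # [0.16666013 0.16666015 0.16667972] -> 1/6
report = classify_stability(g, rates)
print(report.classification)      # stable_focus
rate = damping_rate(SeriesWindow(tr.times, tr.series("R", 1)), 1/6)
print(rate)                       # -0.0026051... (envelope decay per unit time)
print(report.eigenvalues.real.max(initial=-np.inf,
      where=np.abs(report.eigenvalues) > 1e-9))  # -0.0026076 (matches)
```

The measured envelope decay rate of the rock oscillation agrees with the
real part of the leading Jacobian eigenvalue to 0.1% — the damping is
exactly the linear relaxation of the stable focus.

Ready-made scenarios (`rpsmeta presets`) cover the canonical runs:
the homogeneous triangle (`fig2a`), the single-habitat baseline
(`fig2b`), the heterogeneous path (`fig4`), and both again with rock's
victory rate lowered to a = 0.8 (`fig5`, `fig6`).  For example
`rpsmeta simulate --preset fig4 --outdir out` writes the trajectory CSV,
stability JSON, observables JSON and a run log.

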