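# Methods

## Model

The state is the density table ρ_{α,i} of species α ∈ {R, S, P} in node
i of a connected, undirected, unweighted habitat graph; densities are
fractions of the single global population, Σ_{α,i} ρ_{α,i} = 1.  Two
processes act:

**Reactions** (within a node, mass-action): R converts S at rate a, S
converts P at rate b, P converts R at rate c, giving for node i

    dρ_{R,i}/dt |_react = a ρ_{R,i} ρ_{S,i} − c ρ_{P,i} ρ_{R,i}

and cyclic analogues.  The three components cancel, so each node's total
is untouched by the reactions.

**Random-walk migration** (along links, rate unity): each individual
leaves its node at unit rate toward a uniformly random neighbor, so node
j exports ρ_j/k_j along each of its k_j links:

    dρ_{α,i}/dt |_mig = Σ_{j∈N_i} ( ρ_{α,j}/k_j − ρ_{α,i}/k_i )
                      = (M ρ_α)_i,   M = A diag(1/k) − I.

M's columns sum to zero, so migration conserves each species exactly.
The full right-hand side is the sum of the two terms.

Assumptions: infinite local populations (deterministic mean-field; no
demographic noise), complete mixing within a node, identical unit
migration rate for all species, static topology.

## Equilibria and stability

Migration is stationary iff ρ_i/k_i is constant across nodes
(degree-proportional node shares k_i/Σk — the stationary distribution of
the random walk); the reactions are stationary in a node iff the species
split is (b, c, a)/(a+b+c).  Because the reaction term is homogeneous of
degree 2 and the migration term linear, both vanish simultaneously at
the product

    ρ_{α,i,e} = (k_i / Σ_j k_j) · (b, c, a)_α /(a+b+c),

which is the interior coexistence equilibrium used throughout.  An
independent numeric cross-check solves rhs = 0 with one (linearly
dependent) component replaced by the normalization constraint, via a
hybrid Newton method with the analytic Jacobian; closed form and root
agree to < 1e-10 on every tested graph/rate combination.

The 3N×3N Jacobian is assembled analytically: M on each species block
diagonal plus a per-node 3×3 reaction block; finite differences of the
right-hand side serve as a test oracle only (relative agreement < 1e-6).

Classification discounts exactly **one** structural zero eigenvalue
(global conservation).  Any further near-zero eigenvalues are *not*
discounted — on homogeneous graphs the leading pair is purely imaginary
and is precisely what makes the label `neutrally_stable`.  Labels, with
m = max Re over non-discounted eigenvalues and tol = 1e-7 (an order
above the finite-difference verification error):

- `unstable`: m > tol
- `neutrally_stable`: |m| ≤ tol and a leading eigenvalue is nonreal
- `stable_focus`: m < −tol with nonreal eigenvalues present
- `stable_node`: m < −tol, all eigenvalues real
- `indeterminate`: anything else

Boundary (single-species) equilibria exist and are exact roots; the
classifier targets only the interior equilibrium, but boundary points
can be analyzed by composing `solve_equilibrium_numeric` with
`jacobian`.

## Integration

Adaptive 8th-order Runge-Kutta (scipy's DOP853) with rel_tol 1e-10,
abs_tol 1e-12, sampled on a uniform grid.  These tolerances keep the
conserved quantity of the well-mixed system,
V = b ln ρ_R + c ln ρ_S + a ln ρ_P (dV/dt = 0 identically under the
reaction term), below 1e-6 drift over the longest preset run, and global
normalization below 10·rel_tol.  Densities in (−abs_tol, 0) are clipped
to zero; anything lower aborts with an error, signalling an accuracy
problem rather than silently clamping the dynamics.  The state vector is
species-major — (R,1..N), (S,1..N), (P,1..N) — so trajectories serialize
deterministically.

Default horizon t_end = 500 with 5001 samples resolves ≥ 7 oscillation
periods after the transient cut (the slowest preset oscillation has
period ≈ 33).  The damped presets (`fig4`, `fig6`) run to t_end = 3000:
their leading eigenvalue real part is ≈ −0.0026 (e-folding ≈ 385 time
units), so ≈ 3000 units bring every density within 1e-4 of its
equilibrium value.

## Observables

- **Dominant frequency**: Hann-windowed FFT of the mean-removed series,
  largest non-DC peak, parabolically refined on log power.  A peak below
  10× the spectral median (or a numerically constant series) is flagged
  non-oscillatory.  Hann windowing plus parabolic refinement matters
  because the analysis windows hold only ~7 periods, where a bare peak
  bin would bias the frequency-ratio measurement by several percent.
- **Phase difference**: instantaneous phases from the analytic signal
  (Hilbert transform), circular mean of φ₁ − φ₂ with 10% trimmed at
  each end against edge effects; requires both series oscillatory at
  dominant frequencies within 2%.  Convention: the result in [0, 2π) is
  the phase by which the *second* series lags the first, so a quarter-
  period delay of s2 yields π/2.  The rock–scissors gap on the
  homogeneous attractor measures 2.0962 rad.  This is not an estimation
  artifact: for a = b = c the cyclic relabeling R→S→P→R maps the system
  onto itself while V is permutation-symmetric, so the attractor orbit
  satisfies ρ_S(t) = ρ_R(t + T/3) exactly and the gap is exactly
  2π/3 ≈ 2.0944 — a useful consistency check on the phase machinery.
- **Damping rate**: least-squares slope of log |extremum − equilibrium|
  against extremum time over the successive envelope extrema (≥ 4
  required).  On the heterogeneous path it reproduces the leading
  Jacobian eigenvalue's real part to ~0.1%.
- **Attractor label**: `fixed_point` when every component's final-
  quarter standard deviation is below a tolerance; otherwise
  `limit_cycle_or_center` when amplitudes over the post-transient half
  of the run are steady (half-to-half ratio within [0.95, 1.05]); else
  `undetermined`.  The steadiness comparison excludes the first half of
  the run because the approach to the synchronized orbit otherwise
  inflates the first-window amplitude.
- Transient discard: frequency/phase/mean analyses use the last 50% of
  the run; damping uses the full series (the transient *is* the decay
  being measured).

## Experiment presets

The presets are the canonical study conditions: near-uniform initial
densities ρ_{α,i}(0) = 0.1 with rock in node 3 doubled to 0.2 (a
normalized, asymmetric perturbation), unit victory rates, on the
homogeneous triangle (`fig2a`), the heterogeneous 3-node path with node
1 central (`fig4`), and the single habitat started at (0.4, 0.2, 0.4)
(`fig2b`); `fig5`/`fig6` repeat the triangle/path with a = 0.8, b = c =
1.  Runs are deterministic; no seeds exist anywhere in the dynamics.

## Design choices

- Graphs are connected, undirected, unweighted only; migration on a
  disconnected graph has component-dependent stationary states, so such
  inputs are rejected rather than supported.
- External node labels (files, CLI, reports) are 1-based; internal
  arrays 0-based.  `path_graph(3)` puts the center at node 1, matching
  the labeling convention of the heterogeneous three-node scenario.
- The single-habitat system is a dedicated reaction-only code path
  (`integrate_single_habitat`), since the Graph type requires N ≥ 2.
- The phase-lag direction ("R leads S" vs "S leads R") is reported under
  the stated lag convention; consumers needing only the magnitude should
  fold the result via min(θ, 2π − θ).

## Limitations

- Mean-field and deterministic: no finite-population extinction, which
  is the phenomenon that makes neutral cycling fragile in reality; the
  package quantifies the linear mechanism (heterogeneity ⇒ negative real
  parts) rather than stochastic persistence times.
- Neutral stability on homogeneous graphs is measured numerically
  (|Re λ| below tolerance), not proven.
- Phase/frequency estimators assume clean, uniformly sampled,
  near-periodic ODE output; they are not noise-robust.
- Directed, weighted, or time-varying topologies and species-dependent
  migration rates are out of scope.
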