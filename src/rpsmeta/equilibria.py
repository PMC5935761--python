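"""Equilibria and linear stability of the reaction-migration system.

The interior coexistence equilibrium factorizes: random-walk migration is
stationary exactly when every node holds a degree-proportional share
``k_i / sum_j k_j`` of the population, and the reactions are stationary
within a node exactly when the species split in the ratios of the
single-habitat equilibrium

    (rho_R, rho_S, rho_P)_e = (b, c, a) / (a + b + c).

Their product,

    rho_{alpha,i,e} = (k_i / sum_j k_j) * rho_{alpha,e},

zeroes both terms simultaneously and is the unique interior equilibrium
up to the conserved total.  A damped Newton root-finder on the full
right-hand side serves as an independent numeric cross-check.

Linearizing at the equilibrium yields a 3N x 3N Jacobian whose spectrum
decides the headline dichotomy: on homogeneous graphs (all degrees
equal) the leading non-conserved eigenvalues are purely imaginary and
the coexistence oscillation is neutrally stable; on heterogeneous graphs
they acquire strictly negative real parts and the equilibrium is a
stable focus, i.e. degree heterogeneity damps the oscillation and
stabilizes coexistence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dynamics import MetaState, Rates, migration_matrix, rhs
from .graphs import Graph

__all__ = [
    "StabilityReport",
    "single_node_equilibrium",
    "network_equilibrium",
    "solve_equilibrium_numeric",
    "reaction_jacobian",
    "jacobian",
    "classify_spectrum",
    "classify_stability",
]


def single_node_equilibrium(rates: Rates) -> np.ndarray:
    """Interior equilibrium (rho_R, rho_S, rho_P) of the well-mixed system.

    Setting the reaction term to zero with all densities positive forces
    a rho_S = c rho_P, b rho_P = a rho_R, hence the triple
    (b, c, a)/(a+b+c); at unit rates each species holds 1/3.
    """
    a, b, c = rates.as_tuple()
    return np.array([b, c, a]) / (a + b + c)


def network_equilibrium(g: Graph, rates: Rates) -> MetaState:
    """Interior coexistence equilibrium of the full system.

    rho_{alpha,i} = (k_i / sum_j k_j) * single-habitat equilibrium of
    species alpha.  Node totals are exactly degree-proportional, so hubs
    hold more of every species; the species split inside every node is
    the same.
    """
    share = g.degrees / g.degrees.sum()
    eq = single_node_equilibrium(rates)
    return MetaState(np.outer(eq, share))


def solve_equilibrium_numeric(
    g: Graph,
    rates: Rates,
    initial_guess: MetaState,
    tol: float = 1e-13,
) -> MetaState:
    """Root of the right-hand side under the constraint Sigma rho = 1.

    Independent of the closed form: a hybrid Newton solve of the system
    with one (linearly dependent) component replaced by the
    normalization constraint.  Raises if the residual of the full
    right-hand side at the root exceeds 1e-12.
    """
    initial_guess.validate(atol=1e-9)
    n = g.n_nodes

    def fun(x):
        f = rhs(0.0, MetaState.from_flat(x, n), g, rates).ravel()
        out = f.copy()
        out[-1] = x.sum() - 1.0  # rhs components sum to 0, so dropping one is exact
        return out

    def jac_fun(x):
        j = jacobian(MetaState.from_flat(x, n), g, rates)
        j = j.copy()
        j[-1, :] = 1.0
        return j

    sol = optimize.root(fun, initial_guess.to_flat(), jac=jac_fun, method="hybr", tol=tol)
    x = sol.x
    resid = float(np.linalg.norm(rhs(0.0, MetaState.from_flat(x, n), g, rates)))
    if not sol.success or resid > 1e-12:
        raise RuntimeError(f"equilibrium solve did not converge: residual {resid:g} ({sol.message})")
    return MetaState.from_flat(x, n)


def reaction_jacobian(node_state, rates: Rates) -> np.ndarray:
    """3x3 Jacobian of the within-habitat reaction term at one density triple."""
    r, s, p = (float(x) for x in node_state)
    a, b, c = rates.as_tuple()
    return np.array(
        [
            [a * s - c * p, a * r, -c * r],
            [-a * s, b * p - a * r, b * s],
            [c * p, -b * p, c * r - b * s],
        ]
    )


def jacobian(state: MetaState, g: Graph, rates: Rates) -> np.ndarray:
    """Analytic 3N x 3N Jacobian of the right-hand side (species-major).

    Migration contributes the graph operator M = A diag(1/k) - I on each
    species block diagonal; the reactions contribute a 3x3 block per
    node coupling the species locally.
    """
    if state.n_nodes != g.n_nodes:
        raise ValueError("state / graph size mismatch")
    n = g.n_nodes
    j = np.zeros((3 * n, 3 * n))
    m = migration_matrix(g)
    for s in range(3):
        j[s * n : (s + 1) * n, s * n : (s + 1) * n] += m
    for i in range(n):
        block = reaction_jacobian(state.rho[:, i], rates)
        for u in range(3):
            for v in range(3):
                j[u * n + i, v * n + i] += block[u, v]
    return j


@dataclass(frozen=True)
class StabilityReport:
    """Equilibrium, Jacobian spectrum, and the stability label.

    ``n_conserved_modes`` eigenvalues (the global-conservation zero) are
    treated as structural and excluded from the classification; any
    further near-zero eigenvalues are *not* discounted — on homogeneous
    graphs they are exactly what makes the oscillation neutral.
    """

    equilibrium: MetaState
    eigenvalues: np.ndarray
    n_conserved_modes: int
    classification: str
    tol: float

    def to_dict(self) -> dict:
        return {
            "equilibrium": [float(x) for x in self.equilibrium.to_flat()],
            "n_nodes": self.equilibrium.n_nodes,
            "eigenvalues": [[float(e.real), float(e.imag)] for e in self.eigenvalues],
            "n_conserved_modes": self.n_conserved_modes,
            "classification": self.classification,
            "tol": self.tol,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def classify_spectrum(eigenvalues: np.ndarray, tol: float = 1e-7) -> tuple[str, int]:
    """Label a Jacobian spectrum; returns (label, n_discounted).

    Exactly one structural zero (global density conservation) is
    removed: the eigenvalue of smallest magnitude, required to be below
    ``tol``.  The rest decide the label by the real part of the leading
    (largest real part) eigenvalues:

    - ``unstable``         max Re > tol
    - ``neutrally_stable`` |max Re| <= tol and a leading eigenvalue is nonreal
    - ``stable_focus``     max Re < -tol and nonreal eigenvalues exist
    - ``stable_node``      max Re < -tol and the spectrum is real
    - ``indeterminate``    anything else
    """
    eig = np.asarray(eigenvalues, dtype=complex)
    i0 = int(np.argmin(np.abs(eig)))
    if abs(eig[i0]) > tol:
        return "indeterminate", 0
    rest = np.delete(eig, i0)
    if rest.size == 0:
        return "indeterminate", 1
    max_re = float(rest.real.max())
    if max_re > tol:
        return "unstable", 1
    if abs(max_re) <= tol:
        leading = rest[rest.real >= max_re - tol]
        if (np.abs(leading.imag) > tol).any():
            return "neutrally_stable", 1
        return "indeterminate", 1
    if (np.abs(rest.imag) > tol).any():
        return "stable_focus", 1
    return "stable_node", 1


def classify_stability(g: Graph, rates: Rates, tol: float = 1e-7) -> StabilityReport:
    """Linear stability of the interior coexistence equilibrium.

    Homogeneous graphs give ``neutrally_stable`` (pure oscillation with
    initial-condition-dependent amplitude); heterogeneous graphs give
    ``stable_focus`` (damped oscillation into coexistence).
    """
    eq = network_equilibrium(g, rates)
    eig = np.linalg.eigvals(jacobian(eq, g, rates))
    eig = eig[np.lexsort((-np.abs(eig.imag), -eig.real))]
    label, n_disc = classify_spectrum(eig, tol)
    return StabilityReport(eq, eig, n_disc, label, tol)
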