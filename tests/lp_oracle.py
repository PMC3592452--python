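"""Independent brute-force oracle for tiny FBA problems.

Maximizes c.v over {v : S v = 0, lb <= v <= ub} by enumerating candidate
vertices of the polytope: with r = rank(S), every vertex has at least
n - r coordinates pinned to a box bound, so trying all such pinnings and
solving the equality system for the rest visits every vertex.  The optimum
of a bounded LP is attained at a vertex, hence the enumeration maximum
equals the LP optimum.  No code from the solver under test is used.
"""

from __future__ import annotations

import itertools

import numpy as np


def max_biomass_bruteforce(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, c: np.ndarray, tol: float = 1e-9
) -> float:
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if m else 0
    n_pin = n - r
    best = 0.0  # v = 0 is always feasible
    if n_pin == 0:
        return best
    for free_idx in itertools.combinations(range(n), r):
        pin_idx = [j for j in range(n) if j not in free_idx]
        for sides in itertools.product((0, 1), repeat=len(pin_idx)):
            v = np.zeros(n)
            for j, s in zip(pin_idx, sides):
                v[j] = lb[j] if s == 0 else ub[j]
            if r:
                A = S[:, list(free_idx)]
                b = -S[:, pin_idx] @ v[pin_idx]
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[list(free_idx)] = sol
                if np.max(np.abs(S @ v)) > 1e-7:
                    continue  # pinning inconsistent with mass balance
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                best = max(best, float(c @ v))
    return best


def effective_bounds(model, media_uptakes: dict[str, float]):
    """Replicate the media convention independently: exchange lower bounds
    are -uptake for listed compounds, 0 otherwise."""
    lb, ub = [], []
    for rxn in model.reactions:
        lo, hi = rxn.lower_bound, rxn.upper_bound
        if rxn.is_exchange and len(rxn.stoichiometry) == 1:
            met = rxn.stoichiometry[0][0]
            lo = -media_uptakes.get(met, 0.0)
        lb.append(lo)
        ub.append(hi)
    return np.array(lb), np.array(ub)


def model_matrices(model):
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    c = np.zeros(len(model.reactions))
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry:
            S[met_index[met], j] = coeff
        if rxn.is_biomass:
            c[j] = 1.0
    return S, c
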