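"""Independent LP oracles used only by the test suite.

Two routes, both independent of the package's GLPK/optlang solve path:

* :func:`linprog_max` — scipy's HiGHS interior/simplex implementation;
* :func:`vertex_enum_max` — exhaustive vertex enumeration: fixed variables
  are eliminated, the equality system S v = b is reduced to an affine
  parameterisation v = p + N t over the polytope's free dimensions, every
  choice of d active bounds is solved, and the objective is maximised over
  the feasible candidates.  Exact up to linear algebra round-off, and
  tractable because the generated cores keep d small.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog

from pyroflux.model import stoichiometric_matrix

FIX_TOL = 1e-12


def _arrays(model, objective):
    S, _, rxns = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    c = np.zeros(len(rxns))
    c[rxns.index(objective)] = 1.0
    return S, lb, ub, c, rxns


def linprog_max(model, objective: str) -> float:
    """LP maximum via scipy HiGHS; raises if not optimal."""
    S, lb, ub, c, _ = _arrays(model, objective)
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        raise RuntimeError(f"HiGHS oracle failed: {res.message}")
    return float(-res.fun)


def vertex_enum_max(model, objective: str, max_dim: int = 6,
                    tol: float = 1e-7) -> float:
    """Exhaustive maximum of ``objective`` over all polytope vertices."""
    S, lb, ub, c, _ = _arrays(model, objective)

    fixed = ub - lb <= FIX_TOL
    free = ~fixed
    b = -S[:, fixed] @ lb[fixed] if fixed.any() else np.zeros(S.shape[0])
    Sf, lbf, ubf, cf = S[:, free], lb[free], ub[free], c[free]
    base = float(c[fixed] @ lb[fixed]) if fixed.any() else 0.0

    # particular solution and null space of S_free v = b
    p, residual, *_ = np.linalg.lstsq(Sf, b, rcond=None)
    if np.max(np.abs(Sf @ p - b)) > 1e-8:
        raise RuntimeError("equality system inconsistent (infeasible fixings)")
    N = null_space(Sf)
    d = N.shape[1]
    if d > max_dim:
        raise RuntimeError(f"polytope dimension {d} exceeds max_dim={max_dim}")
    if d == 0:
        if np.any(p < lbf - tol) or np.any(p > ubf + tol):
            raise RuntimeError("unique solution violates bounds (infeasible)")
        return base + float(cf @ p)

    n_free = len(lbf)
    best = -np.inf
    signs = np.array(list(product((0, 1), repeat=d)))  # 0 -> lb, 1 -> ub
    for rows in combinations(range(n_free), d):
        A = N[list(rows), :]  # d x d
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        # rhs: each sign pattern picks lb or ub for the active rows
        targets = np.where(signs.T, ubf[list(rows)][:, None],
                           lbf[list(rows)][:, None]) - p[list(rows)][:, None]
        T = np.linalg.solve(A, targets)  # d x 2^d candidate t's
        V = p[:, None] + N @ T  # n_free x 2^d candidate vertices
        ok = (V >= lbf[:, None] - tol).all(axis=0) & \
             (V <= ubf[:, None] + tol).all(axis=0)
        if ok.any():
            vals = cf @ V[:, ok]
            best = max(best, float(vals.max()))
    if not np.isfinite(best):
        raise RuntimeError("no feasible vertex found (infeasible model?)")
    return base + best
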