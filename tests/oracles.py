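"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different route than the library:
exhaustive lag search for alignment, active-set NNLS for the constrained
library fit, polytope vertex enumeration for FBA, restricted-LP enumeration
over activation patterns for GIMME, and combinatorial enumeration for the
hypergeometric tail.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog, nnls


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def exhaustive_circular_lag(y: np.ndarray, ref: np.ndarray, max_shift: int) -> int:
    """Arg-max lag of dot(ref, roll(y, lag)); ties -> smallest |lag|, then negative."""
    best_lag, best_score = None, None
    for lag in sorted(range(-max_shift, max_shift + 1), key=lambda l: (abs(l), l)):
        score = float(np.dot(ref, np.roll(y, lag)))
        if best_score is None or score > best_score + 1e-12 * max(1.0, abs(best_score)):
            best_lag, best_score = lag, score
    return best_lag


def edge_fill_shift(y: np.ndarray, lag: int) -> np.ndarray:
    out = np.empty_like(y)
    n = y.size
    if lag == 0:
        return y.copy()
    if lag > 0:
        out[lag:] = y[: n - lag]
        out[:lag] = y[0]
    else:
        out[: n + lag] = y[-lag:]
        out[n + lag:] = y[-1]
    return out


def exhaustive_segment_lag(seg: np.ndarray, target: np.ndarray, max_shift: int) -> int:
    best_lag, best_score = None, None
    for lag in sorted(range(-max_shift, max_shift + 1), key=lambda l: (abs(l), l)):
        score = float(np.dot(target, edge_fill_shift(seg, lag)))
        if best_score is None or score > best_score + 1e-12 * max(1.0, abs(best_score)):
            best_lag, best_score = lag, score
    return best_lag


# ---------------------------------------------------------------------------
# non-negative least squares
# ---------------------------------------------------------------------------

def nnls_oracle(matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Active-set NNLS solution of min ||matrix^T c - y|| s.t. c >= 0."""
    c, _ = nnls(matrix.T, y)
    return c


# ---------------------------------------------------------------------------
# FBA by vertex enumeration
# ---------------------------------------------------------------------------

def fba_vertex_oracle(model) -> float:
    """Maximum objective flux over all vertices of {S v = 0, lb <= v <= ub}.

    A vertex pins n - rank(S) additional bound constraints; enumerate all
    choices of bound subsets and lb/ub patterns, solve the square system,
    keep feasible solutions.
    """
    S, lb, ub = model.S, model.lb, model.ub
    n = len(model.reactions)
    obj = model.reaction_index(model.objective_reaction)
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = -np.inf
    for combo in itertools.combinations(range(n), d):
        for pattern in itertools.product((0, 1), repeat=d):
            rows = np.zeros((d, n))
            rhs = np.zeros(d)
            for r, (j, side) in enumerate(zip(combo, pattern)):
                rows[r, j] = 1.0
                rhs[r] = lb[j] if side == 0 else ub[j]
            A = np.vstack([S, rows])
            b = np.concatenate([np.zeros(S.shape[0]), rhs])
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            best = max(best, v[obj])
    return float(best)


# ---------------------------------------------------------------------------
# GIMME by activation-pattern enumeration
# ---------------------------------------------------------------------------

def _min_penalty_lp(model, weights, allowed_zero, z_target):
    """Min sum w_j |v_j| with reactions in allowed_zero fixed to 0."""
    n = len(model.reactions)
    lb = model.lb.copy()
    ub = model.ub.copy()
    for j in allowed_zero:
        lb[j] = 0.0
        ub[j] = 0.0
    if np.any(lb > ub):
        return None
    bounds = []
    for lo, hi in zip(lb, ub):
        bounds.append((max(lo, 0.0), max(hi, 0.0)))
    for lo, hi in zip(lb, ub):
        bounds.append((max(-hi, 0.0), max(-lo, 0.0)))
    A_eq = np.hstack([model.S, -model.S])
    cost = np.concatenate([weights, weights])
    obj = model.reaction_index(model.objective_reaction)
    a_ub = np.zeros(2 * n)
    a_ub[obj] = -1.0
    a_ub[n + obj] = 1.0
    res = linprog(
        cost, A_ub=a_ub[None, :], b_ub=[-z_target], A_eq=A_eq,
        b_eq=np.zeros(model.S.shape[0]), bounds=bounds, method="highs",
    )
    return float(res.fun) if res.status == 0 else None


def gimme_bruteforce(model, rxn_expr, expr_cutoff, objective_fraction) -> float:
    """Minimum inconsistency over all activation patterns of penalized reactions."""
    n = len(model.reactions)
    weights = np.zeros(n)
    penalized = []
    for j, rid in enumerate(model.reactions):
        expr = rxn_expr.get(rid)
        if expr is not None and expr < expr_cutoff:
            weights[j] = expr_cutoff - expr
            penalized.append(j)
    zstar = fba_vertex_oracle(model)
    z_target = objective_fraction * zstar
    best = None
    for r in range(len(penalized) + 1):
        for active in itertools.combinations(penalized, r):
            zeroed = [j for j in penalized if j not in active]
            score = _min_penalty_lp(model, weights, zeroed, z_target)
            if score is not None and (best is None or score < best):
                best = score
    return best


# ---------------------------------------------------------------------------
# hypergeometric tail by enumeration
# ---------------------------------------------------------------------------

def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(overlap >= k) when drawing n of N items, K of which are marked."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(max(k, 0), min(K, n) + 1)
    )
    return hits / total
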