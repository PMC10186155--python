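"""Brute-force reference solver for small activation problems.

Enumerates every binary activation pattern over the y-bearing reactions and
checks each with a plain LP feasibility solve under the bounds the pattern
implies (y = 1: flux in [eps, ub]; y = 0: flux in [0, min(ub, eps)]).  This
is exponential in the number of activation variables and is intended only
for fixtures with at most ~10 such variables, where it provides an
independent check of the mixed-integer implementation: it shares the
condition data but none of the big-M indicator encoding or integer search.

Fixture manifests are produced with this oracle so that tests of the main
solver are non-circular.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from .optimize import ConditionConstrainedProblem

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}

MAX_ENUMERATION = 14  # 2^14 LPs is the practical ceiling


def _lp_for_pattern(problem: ConditionConstrainedProblem, pattern, c=None):
    """LP under the flux bounds implied by a 0/1 activation pattern."""
    lb = problem.lb.copy()
    ub = problem.ub.copy()
    ridx = {r: i for i, r in enumerate(problem.reaction_ids)}
    eps = problem.epsilon
    for yj, rid in enumerate(problem.y_reactions):
        vj = ridx[rid]
        if pattern[yj]:
            if ub[vj] < eps:  # activation impossible under this bound
                return None
            lb[vj] = max(lb[vj], eps)
        else:
            ub[vj] = min(ub[vj], eps)
    n = problem.n_reactions
    res = linprog(
        np.zeros(n) if c is None else c,
        A_eq=problem.N,
        b_eq=np.zeros(problem.N.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    return res if res.status == 0 else None


def _patterns(problem: ConditionConstrainedProblem):
    k = problem.n_binaries
    if k > MAX_ENUMERATION:
        raise ValueError(
            f"{k} activation variables exceed the enumeration ceiling "
            f"({MAX_ENUMERATION}); the oracle is for small fixtures only"
        )
    for pattern in itertools.product((0, 1), repeat=k):
        if any(pattern[a] + pattern[b] > 1 for a, b in problem.pairs):
            continue
        yield pattern


def brute_force_z(problem: ConditionConstrainedProblem) -> int:
    """Maximum signed activation count by exhaustive enumeration.

    Honors the one-direction-per-pair rule and, in penalized mode, the
    negative weight on reactions with inactive GPR state.  Raises
    ``ValueError`` if no activation pattern is feasible (the condition's
    physiology is infeasible).
    """
    best = None
    for pattern in _patterns(problem):
        if _lp_for_pattern(problem, pattern) is None:
            continue
        score = int(np.dot(problem.y_sign, pattern)) if problem.n_binaries else 0
        if best is None or score > best:
            best = score
    if best is None:
        raise ValueError("no feasible activation pattern: problem infeasible")
    return best


def brute_force_q(problem: ConditionConstrainedProblem, z: int) -> float:
    """Minimum total flux over all feasible patterns with signed count z."""
    best = None
    c = np.ones(problem.n_reactions)
    for pattern in _patterns(problem):
        score = int(np.dot(problem.y_sign, pattern)) if problem.n_binaries else 0
        if score != z:
            continue
        res = _lp_for_pattern(problem, pattern, c=c)
        if res is None:
            continue
        if best is None or res.fun < best:
            best = float(res.fun)
    if best is None:
        raise ValueError(f"no feasible activation pattern with count {z}")
    return best


def brute_force_gpr(node, abundances) -> float:
    """Exhaustive evaluator for GPR trees, independent of the recursive one.

    Flattens the tree into the full list of leaf->root paths and computes
    the max/min semantics by explicit enumeration of OR-choices: for every
    way of resolving each OR node to one child, the value is the minimum
    over the remaining AND-joined leaves; the result is the maximum over
    all resolutions.
    """
    from .gpr import Leaf, Op

    def resolutions(n):
        if isinstance(n, Leaf):
            yield [n.gene]
            return
        if n.kind == "or":
            for child in n.children:
                yield from resolutions(child)
        else:  # and: cartesian product of child resolutions, concatenated
            pools = [list(resolutions(c)) for c in n.children]
            for combo in itertools.product(*pools):
                merged = []
                for part in combo:
                    merged.extend(part)
                yield merged

    best = None
    for genes in resolutions(node):
        val = min(float(abundances.get(g, 0.0)) for g in genes)
        if best is None or val > best:
            best = val
    return best
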