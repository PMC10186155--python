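"""Two-step MILP flux estimation, the penalized variant, pFBA and FVA.

The method integrates a proteomics profile into an irreversible metabolic
model and estimates fluxes in two steps:

Step 1 (MILP) maximizes the number of reactions that carry flux and have an
active GPR state (the set Ra), subject to steady state ``N v = 0``, bounds
``0 <= v_i <= vmax_i``, the growth constraint on the biomass reaction, and
per-reaction indicator constraints that tie a binary y_j to the flux::

    eps * y_j <= v_j <= y_j * vmax_j + eps * (1 - y_j),   j in Ra

so y_j = 1 forces at least the activation flux eps through j and y_j = 0
caps j at eps (the formulation deliberately permits residual flux up to eps
when y_j = 0).  For a split reversible pair, at most one direction may be
activated: ``y_fwd + y_bwd <= 1``.

Step 2 (MILP) minimizes the total flux over all reactions while fixing the
number of activated reactions to the step-1 optimum z — the parsimony
principle restricted to the maximal-activation face.

The penalized variant maximizes ``sum_{Ra} y_j - sum_{Ri} y_j``, adding
indicator variables for reactions with inactive GPR state (Ri) so that
activating a reaction with no proteomic support costs one unit.

pFBA drops all integer structure: it minimizes total flux subject to the
same physiological constraints.  FVA computes per-reaction flux ranges with
the optima (z and q, or q' for pFBA) held fixed.

All programs are solved with HiGHS through ``scipy.optimize.milp`` /
``linprog``.  Mixed-integer solutions are polished by re-solving the LP with
the binaries fixed at their rounded values, which yields vertex-exact flux
vectors and clean indicator semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .gpr import ConditionProfile, GPRActivity
from .model_io import DEFAULT_VMAX, IrreversibleModel, net_fluxes, stoichiometric_matrix

#: absolute slack on the fixed total-flux equality in FVA
Q_SLACK = 1e-6

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "error"}


class InfeasibleProblemError(RuntimeError):
    """The constraint set admits no flux distribution."""


class SolverError(RuntimeError):
    """The backend terminated without an optimal certificate."""


def uptake_direction(irr: IrreversibleModel, original_exchange_id: str) -> str | None:
    """Split-model reaction importing the boundary metabolite, if any.

    For an exchange reaction the uptake direction is the one whose single
    stoichiometric coefficient is positive (it produces the metabolite
    inside the system boundary).
    """
    fwd, bwd = irr.split_map[original_exchange_id]
    for rid in (fwd, bwd):
        if rid is None:
            continue
        (coef,) = irr.reactions[rid].stoichiometry.values()
        if coef > 0:
            return rid
    return None


@dataclass
class ConditionConstrainedProblem:
    """An irreversible model with one condition's constraints applied.

    Holds the variable order, the effective bounds (biomass and carbon
    source constraints folded in), the activation-variable bookkeeping and
    the sparse steady-state matrix.  ``epsilon`` is the activation
    threshold flux in mmol/gDW/h.
    """

    irr: IrreversibleModel
    profile: ConditionProfile
    activity: GPRActivity
    epsilon: float = 1e-4
    biomass_mode: str = "equality"  # or "band"
    objective_mode: str = "standard"  # or "penalized"
    reaction_ids: list[str] = field(default_factory=list)
    lb: np.ndarray | None = None
    ub: np.ndarray | None = None
    y_reactions: list[str] = field(default_factory=list)
    y_sign: np.ndarray | None = None  # +1 for Ra members, -1 for Ri (penalized)
    pairs: list[tuple[int, int]] = field(default_factory=list)  # indices into y_reactions
    N: sparse.csr_matrix | None = None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_binaries(self) -> int:
        return len(self.y_reactions)

    def index_of(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)


def build_problem(
    irr: IrreversibleModel,
    profile: ConditionProfile,
    activity: GPRActivity,
    *,
    epsilon: float = 1e-4,
    biomass_mode: str = "equality",
    biomass_band: tuple[float, float] = (0.95, 1.05),
    objective_mode: str = "standard",
    default_vmax: float = DEFAULT_VMAX,
    zero_other_carbon: bool = True,
) -> ConditionConstrainedProblem:
    """Apply one condition's physiological constraints to the split model.

    The designated carbon-source exchange may take up at most the profile's
    uptake bound; every other carbon exchange has its uptake direction
    closed.  The biomass reaction is fixed to mu (equality mode, default)
    or confined to ``[0.95 mu, 1.05 mu]`` (band mode).  Infeasibility of mu
    under the uptake bound surfaces later as solver status, not here.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if epsilon >= default_vmax:
        raise ValueError("epsilon must be below the default flux upper bound")
    if biomass_mode not in ("equality", "band"):
        raise ValueError(f"unknown biomass mode {biomass_mode!r}")
    if objective_mode not in ("standard", "penalized"):
        raise ValueError(f"unknown objective mode {objective_mode!r}")
    if profile.carbon_exchange_id not in irr.split_map:
        raise KeyError(
            f"carbon exchange {profile.carbon_exchange_id!r} not in model"
        )

    rids = list(irr.reactions)
    ridx = {r: i for i, r in enumerate(rids)}
    lb = np.zeros(len(rids))
    ub = np.empty(len(rids))
    for i, rid in enumerate(rids):
        u = irr.reactions[rid].upper_bound
        ub[i] = default_vmax if not np.isfinite(u) else u

    # carbon-source constraints: find the original exchange ids with carbon
    carbon_split_ids = set(irr.carbon_exchange_ids())
    carbon_originals = {
        orig
        for orig, (fwd, bwd) in irr.split_map.items()
        if fwd in carbon_split_ids or (bwd is not None and bwd in carbon_split_ids)
    }
    designated = profile.carbon_exchange_id
    for orig in carbon_originals:
        up = uptake_direction(irr, orig)
        if up is None:
            continue
        if orig == designated:
            ub[ridx[up]] = profile.uptake_bound
        elif zero_other_carbon:
            ub[ridx[up]] = 0.0
    if designated in carbon_originals:
        pass
    else:
        # designated source may lack a carbon formula; still open its uptake
        up = uptake_direction(irr, designated)
        if up is not None:
            ub[ridx[up]] = profile.uptake_bound

    bio = irr.biomass_reaction_id
    if biomass_mode == "equality":
        lb[ridx[bio]] = profile.mu
        ub[ridx[bio]] = profile.mu
    else:
        lo, hi = biomass_band
        lb[ridx[bio]] = lo * profile.mu
        ub[ridx[bio]] = hi * profile.mu

    y_reactions = list(activity.ra)
    y_sign = [1.0] * len(y_reactions)
    if objective_mode == "penalized":
        y_reactions += list(activity.ri)
        y_sign += [-1.0] * len(activity.ri)
    yidx = {r: i for i, r in enumerate(y_reactions)}

    pairs: list[tuple[int, int]] = []
    for orig, (fwd, bwd) in irr.split_map.items():
        if bwd is not None and fwd in yidx and bwd in yidx:
            pairs.append((yidx[fwd], yidx[bwd]))

    N, _, _ = stoichiometric_matrix(irr, rids)
    return ConditionConstrainedProblem(
        irr=irr,
        profile=profile,
        activity=activity,
        epsilon=epsilon,
        biomass_mode=biomass_mode,
        objective_mode=objective_mode,
        reaction_ids=rids,
        lb=lb,
        ub=ub,
        y_reactions=y_reactions,
        y_sign=np.asarray(y_sign),
        pairs=pairs,
        N=N,
    )


@dataclass
class NidleSolution:
    """Result of the two-step solve for one condition."""

    condition_id: str
    fluxes: dict[str, float]
    y: dict[str, int]
    z: int
    q: float
    objective_mode: str
    status: str
    epsilon: float = 1e-4

    def net_fluxes(self, irr: IrreversibleModel) -> dict[str, float]:
        return net_fluxes(irr, self.fluxes)


@dataclass
class PfbaSolution:
    """Minimum-total-flux distribution for one condition."""

    condition_id: str
    fluxes: dict[str, float]
    q_prime: float
    status: str

    def net_fluxes(self, irr: IrreversibleModel) -> dict[str, float]:
        return net_fluxes(irr, self.fluxes)


@dataclass
class FVAResult:
    """Per-reaction flux ranges at fixed optima."""

    mode: str  # "nidle" or "pfba"
    minimum: dict[str, float]
    maximum: dict[str, float]
    fixed: dict[str, float]
    status: str = "optimal"

    @property
    def variability(self) -> dict[str, float]:
        return {r: self.maximum[r] - self.minimum[r] for r in self.minimum}


def _milp_constraints(
    problem: ConditionConstrainedProblem,
    *,
    fix_activation: int | None = None,
    fix_total_flux: float | None = None,
) -> list[LinearConstraint]:
    """Assemble the shared constraint blocks of the MILPs.

    Variables are ordered [v_1..v_n, y_1..y_k].  Blocks: steady state,
    indicator lower/upper rows for every y-bearing reaction, the
    one-direction-per-pair rows, and optionally the fixed-optimum rows
    (activation count exact; total flux within ``Q_SLACK``).
    """
    n, k = problem.n_reactions, problem.n_binaries
    eps = problem.epsilon
    ridx = {r: i for i, r in enumerate(problem.reaction_ids)}
    cons = []

    Nfull = sparse.hstack([problem.N, sparse.csr_matrix((problem.N.shape[0], k))])
    cons.append(LinearConstraint(Nfull, 0.0, 0.0))

    if k:
        rows, cols, vals = [], [], []
        lo, hi = [], []
        r = 0
        for yj, rid in enumerate(problem.y_reactions):
            vj = ridx[rid]
            ubj = problem.ub[vj]
            # eps * y - v <= 0   (y=1 forces v >= eps)
            rows += [r, r]
            cols += [vj, n + yj]
            vals += [-1.0, eps]
            lo.append(-np.inf)
            hi.append(0.0)
            r += 1
            # v - (ub - eps) * y <= eps   (y=0 caps v at eps)
            rows += [r, r]
            cols += [vj, n + yj]
            vals += [1.0, -(ubj - eps)]
            lo.append(-np.inf)
            hi.append(eps)
            r += 1
        for yf, yb in problem.pairs:
            rows += [r, r]
            cols += [n + yf, n + yb]
            vals += [1.0, 1.0]
            lo.append(-np.inf)
            hi.append(1.0)
            r += 1
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n + k))
        cons.append(LinearConstraint(A, lo, hi))

    if fix_activation is not None:
        row = np.concatenate([np.zeros(n), problem.y_sign])
        cons.append(LinearConstraint(row[None, :], fix_activation, fix_activation))
    if fix_total_flux is not None:
        row = np.concatenate([np.ones(n), np.zeros(k)])
        cons.append(
            LinearConstraint(row[None, :], fix_total_flux - Q_SLACK, fix_total_flux + Q_SLACK)
        )
    return cons


def _variable_bounds(problem: ConditionConstrainedProblem) -> Bounds:
    n, k = problem.n_reactions, problem.n_binaries
    lb = np.concatenate([problem.lb, np.zeros(k)])
    ub = np.concatenate([problem.ub, np.ones(k)])
    return Bounds(lb, ub)


def _solve_milp(problem, c, constraints) -> tuple[np.ndarray | None, float | None, str]:
    n, k = problem.n_reactions, problem.n_binaries
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=_variable_bounds(problem),
        options={"mip_rel_gap": 0.0},
    )
    status = _STATUS.get(res.status, "error")
    if res.status != 0:
        return None, None, status
    return res.x, float(res.fun), status


def _polish_fluxes(
    problem: ConditionConstrainedProblem,
    y: np.ndarray,
    c_v: np.ndarray,
    *,
    fix_total_flux: float | None = None,
) -> tuple[np.ndarray, float] | None:
    """Re-solve the LP with binaries fixed, for vertex-exact fluxes.

    y = 1 implies v in [eps, ub]; y = 0 implies v in [0, min(ub, eps)].
    Returns None when the fixed-binary LP is (numerically) infeasible.
    """
    lb = problem.lb.copy()
    ub = problem.ub.copy()
    ridx = {r: i for i, r in enumerate(problem.reaction_ids)}
    eps = problem.epsilon
    for yj, rid in enumerate(problem.y_reactions):
        vj = ridx[rid]
        if y[yj] >= 0.5:
            lb[vj] = max(lb[vj], eps)
        else:
            ub[vj] = min(ub[vj], eps)
    A_eq, b_eq = problem.N, np.zeros(problem.N.shape[0])
    A_ub = b_ub = None
    if fix_total_flux is not None:
        ones = np.ones((1, problem.n_reactions))
        A_ub = np.vstack([ones, -ones])
        b_ub = np.array([fix_total_flux + Q_SLACK, -(fix_total_flux - Q_SLACK)])
    res = linprog(
        c_v,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status != 0:
        return None
    return res.x, float(res.fun)


def nidle_step1(problem: ConditionConstrainedProblem) -> int:
    """Maximum number of Ra reactions that can carry activating flux.

    Returns the optimal activation count z (penalized mode: the signed
    count over Ra minus Ri).  Raises ``InfeasibleProblemError`` when the
    physiological constraints admit no flux distribution.
    """
    n, k = problem.n_reactions, problem.n_binaries
    c = np.concatenate([np.zeros(n), -problem.y_sign])  # maximize signed sum
    x, fun, status = _solve_milp(problem, c, _milp_constraints(problem))
    if status == "infeasible":
        raise InfeasibleProblemError(
            f"condition {problem.profile.condition_id!r}: constraints infeasible"
        )
    if x is None:
        raise SolverError(f"step-1 solve ended with status {status!r}")
    return int(round(-fun))


def nidle_penalized_step1(problem: ConditionConstrainedProblem) -> int:
    """Step-1 optimum of the penalized objective (Ra count minus Ri count).

    The problem must have been built with ``objective_mode='penalized'`` so
    that Ri reactions carry indicator variables too.
    """
    if problem.objective_mode != "penalized":
        raise ValueError("problem was not built with objective_mode='penalized'")
    return nidle_step1(problem)


def nidle_step2(problem: ConditionConstrainedProblem, z: int) -> NidleSolution:
    """Minimum-total-flux solution at the fixed activation optimum z."""
    n, k = problem.n_reactions, problem.n_binaries
    c = np.concatenate([np.ones(n), np.zeros(k)])
    cons = _milp_constraints(problem, fix_activation=z)
    x, fun, status = _solve_milp(problem, c, cons)
    if x is None:
        return NidleSolution(
            condition_id=problem.profile.condition_id,
            fluxes={},
            y={},
            z=z,
            q=float("nan"),
            objective_mode=problem.objective_mode,
            status=status,
            epsilon=problem.epsilon,
        )
    yvec = (x[n:] >= 0.5).astype(int)
    polished = _polish_fluxes(problem, yvec, np.ones(n))
    if polished is not None:
        v, q = polished
    else:  # fall back to the MILP incumbent
        v, q = x[:n], float(fun)
    return NidleSolution(
        condition_id=problem.profile.condition_id,
        fluxes={r: float(v[i]) for i, r in enumerate(problem.reaction_ids)},
        y={r: int(yvec[j]) for j, r in enumerate(problem.y_reactions)},
        z=z,
        q=float(q),
        objective_mode=problem.objective_mode,
        status=status,
        epsilon=problem.epsilon,
    )


def solve_nidle(problem: ConditionConstrainedProblem) -> NidleSolution:
    """Run both steps; infeasibility is reported as a status, not raised."""
    try:
        z = nidle_step1(problem)
    except InfeasibleProblemError:
        return NidleSolution(
            condition_id=problem.profile.condition_id,
            fluxes={},
            y={},
            z=0,
            q=float("nan"),
            objective_mode=problem.objective_mode,
            status="infeasible",
            epsilon=problem.epsilon,
        )
    return nidle_step2(problem, z)


def pfba(problem: ConditionConstrainedProblem) -> PfbaSolution:
    """Parsimonious FBA: minimize total flux under the same physiology.

    No integer variables; the indicator constraints play no role.
    """
    n = problem.n_reactions
    res = linprog(
        np.ones(n),
        A_eq=problem.N,
        b_eq=np.zeros(problem.N.shape[0]),
        bounds=np.column_stack([problem.lb, problem.ub]),
        method="highs",
        options=_LP_OPTIONS,
    )
    if res.status != 0:
        return PfbaSolution(
            condition_id=problem.profile.condition_id,
            fluxes={},
            q_prime=float("nan"),
            status=_STATUS.get(res.status, "error"),
        )
    return PfbaSolution(
        condition_id=problem.profile.condition_id,
        fluxes={r: float(res.x[i]) for i, r in enumerate(problem.reaction_ids)},
        q_prime=float(res.fun),
        status="optimal",
    )


def fva(
    problem: ConditionConstrainedProblem,
    fixed: Mapping[str, float],
    targets: Iterable[str] | None = None,
    mode: str = "nidle",
) -> FVAResult:
    """Flux ranges per reaction with the generating optima held fixed.

    ``fixed`` supplies ``{"z": ..., "q": ...}`` for the mixed-integer mode
    (activation count exact, total flux within ``Q_SLACK``) or
    ``{"q_prime": ...}`` for the pFBA mode (pure LP).  ``targets`` defaults
    to every reaction in Ra.
    """
    if mode not in ("nidle", "pfba"):
        raise ValueError(f"unknown FVA mode {mode!r}")
    targets = list(targets) if targets is not None else list(problem.activity.ra)
    ridx = {r: i for i, r in enumerate(problem.reaction_ids)}
    for t in targets:
        if t not in ridx:
            raise KeyError(f"FVA target {t!r} not in model")
    n, k = problem.n_reactions, problem.n_binaries
    minimum: dict[str, float] = {}
    maximum: dict[str, float] = {}

    if mode == "nidle":
        z = int(fixed["z"])
        q = float(fixed["q"])
        cons = _milp_constraints(problem, fix_activation=z, fix_total_flux=q)
        for t in targets:
            c = np.zeros(n + k)
            c[ridx[t]] = 1.0
            xmin, fmin, smin = _solve_milp(problem, c, cons)
            xmax, fmax, smax = _solve_milp(problem, -c, cons)
            if xmin is None or xmax is None:
                raise SolverError(
                    f"FVA for {t!r} infeasible at fixed optima "
                    f"(statuses {smin!r}/{smax!r}); the fixed z/q may be stale"
                )
            minimum[t] = float(fmin)
            maximum[t] = float(-fmax)
        return FVAResult(mode=mode, minimum=minimum, maximum=maximum, fixed={"z": z, "q": q})

    q_prime = float(fixed.get("q_prime", fixed.get("q")))
    ones = np.ones((1, n))
    A_ub = np.vstack([ones, -ones])
    b_ub = np.array([q_prime + Q_SLACK, -(q_prime - Q_SLACK)])
    bounds = np.column_stack([problem.lb, problem.ub])
    for t in targets:
        c = np.zeros(n)
        c[ridx[t]] = 1.0
        vals = []
        for sign in (1.0, -1.0):
            res = linprog(
                sign * c,
                A_ub=A_ub,
                b_ub=b_ub,
                A_eq=problem.N,
                b_eq=np.zeros(problem.N.shape[0]),
                bounds=bounds,
                method="highs",
                options=_LP_OPTIONS,
            )
            if res.status != 0:
                raise SolverError(f"pFBA-FVA for {t!r} failed: status {res.status}")
            vals.append(sign * float(res.fun))
        minimum[t], maximum[t] = vals[0], vals[1]
    return FVAResult(mode=mode, minimum=minimum, maximum=maximum, fixed={"q_prime": q_prime})
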