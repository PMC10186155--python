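"""Per-condition pipeline orchestration and cross-method comparison reports.

``run_condition`` executes the full estimation chain for one condition —
split, classify, solve (mixed-integer or pFBA), net fluxes, activity,
idle-enzyme statistics, kapp — and returns an in-memory bundle.
``compare_report`` joins two or more method bundles over shared conditions
into summary statistics: idle percentages, active/Ra ratios, kapp
cardinality (min/max/mean/median/sample std across conditions), kvivomax
cardinality and pairwise log-Pearson correlations of shared net fluxes and
shared kvivomax values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .estimate import (
    ACTIVITY_THRESHOLD,
    IdleReport,
    KappRecord,
    KvivomaxRecord,
    active_reactions,
    compute_kapp,
    compute_kvivomax,
    idle_enzymes,
    log_pearson,
)
from .gpr import ConditionProfile, classify_reactions
from .model_io import MetabolicModel, split_reversible
from .optimize import build_problem, pfba, solve_nidle


@dataclass
class ConditionResult:
    """Everything computed for one condition under one method."""

    condition_id: str
    method: str
    status: str
    net_fluxes: dict[str, float]
    idle: IdleReport | None
    kapp: list[KappRecord]
    z: int | None = None
    q: float | None = None
    q_prime: float | None = None
    active_count: int = 0
    active_with_gpr: int = 0
    active_no_gpr: int = 0


@dataclass
class MethodBundle:
    """All conditions of one estimation method, plus kvivomax."""

    method: str
    conditions: dict[str, ConditionResult] = field(default_factory=dict)

    def kvivomax(self) -> list[KvivomaxRecord]:
        records: list[KappRecord] = []
        for res in self.conditions.values():
            records.extend(res.kapp)
        return compute_kvivomax(records)


def run_condition(
    model: MetabolicModel,
    profile: ConditionProfile,
    method: str = "nidle",
    *,
    epsilon: float = 1e-4,
    biomass_mode: str = "equality",
    threshold: float = ACTIVITY_THRESHOLD,
) -> ConditionResult:
    """Run one method on one condition and collect all derived statistics.

    ``method`` is ``"nidle"``, ``"nidle-penalized"`` or ``"pfba"``.
    Infeasible conditions yield a result with status ``"infeasible"`` and
    empty fluxes rather than an exception.
    """
    if method not in ("nidle", "nidle-penalized", "pfba"):
        raise ValueError(f"unknown method {method!r}")
    irr = split_reversible(model)
    activity = classify_reactions(irr, profile)
    objective_mode = "penalized" if method == "nidle-penalized" else "standard"
    problem = build_problem(
        irr,
        profile,
        activity,
        epsilon=epsilon,
        biomass_mode=biomass_mode,
        objective_mode=objective_mode,
    )
    z = q = q_prime = None
    if method == "pfba":
        sol = pfba(problem)
        q_prime = sol.q_prime
    else:
        sol = solve_nidle(problem)
        z, q = sol.z, sol.q
    if sol.status != "optimal":
        return ConditionResult(
            condition_id=profile.condition_id,
            method=method,
            status=sol.status,
            net_fluxes={},
            idle=None,
            kapp=[],
            z=z,
            q=q,
            q_prime=q_prime,
        )
    net = sol.net_fluxes(irr)
    active = active_reactions(net, threshold)
    idle = idle_enzymes(irr, activity, active, profile)
    kapp = compute_kapp(net, irr, activity, profile, threshold)
    ra_orig = {
        orig
        for orig, (fwd, _) in irr.split_map.items()
        if activity.state.get(fwd) == "active"
    }
    gpr_orig = {
        orig
        for orig, (fwd, _) in irr.split_map.items()
        if activity.state.get(fwd) != "no-gpr"
    }
    return ConditionResult(
        condition_id=profile.condition_id,
        method=method,
        status=sol.status,
        net_fluxes=net,
        idle=idle,
        kapp=kapp,
        z=z,
        q=q,
        q_prime=q_prime,
        active_count=len(active),
        active_with_gpr=len(active & gpr_orig),
        active_no_gpr=len(active - gpr_orig),
    )


def _cardinality_stats(counts: Sequence[int]) -> dict:
    arr = np.asarray(counts, dtype=float)
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        # sample standard deviation (n-1 denominator)
        "std": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "n_conditions": len(arr),
    }


def compare_report(bundles: Sequence[MethodBundle]) -> dict:
    """Join method bundles over shared conditions into one report.

    Raises when the bundles share no condition ids.  The report is a pure
    function of its inputs: identical bundles give identical output.
    """
    if len(bundles) < 2:
        raise ValueError("need at least two method bundles to compare")
    shared_conditions = set.intersection(
        *(set(b.conditions) for b in bundles)
    )
    if not shared_conditions:
        raise ValueError("method bundles share no condition ids")
    shared_conditions = sorted(shared_conditions)

    report: dict = {"conditions": shared_conditions, "methods": {}, "pairwise": {}}
    kvivo_by_method: dict[str, dict[str, float]] = {}
    for bundle in bundles:
        per_cond = {}
        kapp_counts = []
        for cid in shared_conditions:
            res = bundle.conditions[cid]
            kapp_counts.append(len(res.kapp))
            per_cond[cid] = {
                "status": res.status,
                "idle_percentage": res.idle.idle_percentage if res.idle else None,
                "active_ra_ratio": res.idle.active_ra_ratio if res.idle else None,
                "active_reactions": res.active_count,
                "active_with_gpr": res.active_with_gpr,
                "active_no_gpr": res.active_no_gpr,
                "z": res.z,
                "q": res.q,
                "q_prime": res.q_prime,
                "n_kapp": len(res.kapp),
            }
        kvivo = bundle.kvivomax()
        kvivo_by_method[bundle.method] = {r.reaction_id: r.kvivomax for r in kvivo}
        report["methods"][bundle.method] = {
            "per_condition": per_cond,
            "kapp_cardinality": _cardinality_stats(kapp_counts),
            "kvivomax_cardinality": len(kvivo),
        }

    for i, b1 in enumerate(bundles):
        for b2 in bundles[i + 1 :]:
            key = f"{b1.method}|{b2.method}"
            entry: dict = {}
            # correlation of shared net fluxes, pooled over conditions
            flux_r = []
            for cid in shared_conditions:
                f1 = b1.conditions[cid].net_fluxes
                f2 = b2.conditions[cid].net_fluxes
                try:
                    r, n, dropped = log_pearson(f1, f2)
                    flux_r.append({"condition": cid, "r": r, "n": n, "dropped": dropped})
                except ValueError:
                    flux_r.append({"condition": cid, "r": None, "n": 0, "dropped": 0})
            entry["net_flux_log_pearson"] = flux_r
            k1, k2 = kvivo_by_method[b1.method], kvivo_by_method[b2.method]
            try:
                r, n, dropped = log_pearson(k1, k2)
                entry["kvivomax_log_pearson"] = {"r": r, "n": n, "dropped": dropped}
            except ValueError:
                entry["kvivomax_log_pearson"] = {"r": None, "n": 0, "dropped": 0}
            report["pairwise"][key] = entry
    return report


def write_report(path, report: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
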