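"""Apparent catalytic rates, maximal in vivo rates and idle-enzyme reports.

Given a steady-state flux distribution v(C) and a proteomics profile E(C)
for condition C, the apparent catalytic rate of a reaction catalyzed by a
unique homomeric enzyme is ``kapp(C) = v(C) / E(C)``; with fluxes in
mmol/gDW/h and abundances in mmol/gDW this is 1/h, divided by 3600 for 1/s.
The maximal in vivo catalytic rate kvivomax is the maximum of kapp(C) over
conditions (or strains); when biological replicates exist the per-replicate
maxima are averaged.  kvivomax is a lower bound on the in vitro turnover
number kcat since the saturation factor is at most 1.

A reaction counts as active if its net flux exceeds 1e-10 mmol/gDW/h
(strictly); 1e-5 serves as the alternate threshold for robustness runs.
An expressed enzyme is *idle* when none of its active-GPR reactions is
active under the estimated fluxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gpr import ConditionProfile, GPRActivity
from .model_io import IrreversibleModel

logger = logging.getLogger(__name__)

#: default activity threshold in mmol/gDW/h (strict inequality)
ACTIVITY_THRESHOLD = 1e-10
#: alternate threshold for robustness analyses
ROBUSTNESS_THRESHOLD = 1e-5

SECONDS_PER_HOUR = 3600.0


@dataclass
class KappRecord:
    """One apparent catalytic rate: reaction x condition (x replicate)."""

    reaction_id: str
    gene_id: str
    condition_id: str
    replicate_id: str
    net_flux: float  # mmol/gDW/h
    abundance: float  # mmol/gDW
    kapp: float  # 1/s

    def __post_init__(self) -> None:
        if not math.isfinite(self.kapp) or self.kapp < 0:
            raise ValueError(f"kapp must be finite and nonnegative, got {self.kapp}")


@dataclass
class KvivomaxRecord:
    """Across-condition maximum of kapp for one reaction/enzyme."""

    reaction_id: str
    gene_id: str
    kvivomax: float  # 1/s
    argmax_condition: str  # per replicate, ';'-joined when replicated
    n_conditions: int
    replicate_values: dict[str, float]


@dataclass
class IdleReport:
    """Expressed-but-flux-free enzyme statistics for one condition."""

    condition_id: str
    expressed_enzymes: int
    idle_enzymes: int
    active_reactions: int
    ra_reactions: int
    idle_abundance_fraction: float

    @property
    def idle_percentage(self) -> float:
        if self.expressed_enzymes == 0:
            return 0.0
        return 100.0 * self.idle_enzymes / self.expressed_enzymes

    @property
    def active_ra_ratio(self) -> float:
        if self.ra_reactions == 0:
            return 0.0
        return self.active_reactions / self.ra_reactions


def active_reactions(
    net_flux: Mapping[str, float], threshold: float = ACTIVITY_THRESHOLD
) -> set[str]:
    """Reactions whose net flux magnitude strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("activity threshold must be positive")
    return {r for r, v in net_flux.items() if abs(v) > threshold}


def _gene_reaction_map(
    irr: IrreversibleModel, activity: GPRActivity
) -> dict[str, set[str]]:
    """Map each gene to the original reactions whose rules mention it."""
    out: dict[str, set[str]] = {}
    for orig, (fwd, _) in irr.split_map.items():
        rule = activity.rules.get(fwd)
        if rule is None or rule.is_empty:
            continue
        for g in rule.genes():
            out.setdefault(g, set()).add(orig)
    return out


def idle_enzymes(
    irr: IrreversibleModel,
    activity: GPRActivity,
    active: set[str],
    profile: ConditionProfile,
) -> IdleReport:
    """Count expressed enzymes none of whose Ra reactions carries flux.

    ``active`` must hold original (net) reaction ids from the same
    condition as ``activity``.  The abundance-weighted idle fraction sums
    idle-enzyme abundance over total expressed abundance.
    """
    gene_rxns = _gene_reaction_map(irr, activity)
    # active-GPR state per original reaction (both split directions agree)
    ra_orig = {
        orig
        for orig, (fwd, _) in irr.split_map.items()
        if activity.state.get(fwd) == "active"
    }
    expressed = {
        g for g, a in profile.abundances.items() if a > 0 and g in gene_rxns
    }
    idle = {
        g
        for g in expressed
        if not any(r in active for r in gene_rxns[g] & ra_orig)
    }
    total_abund = sum(profile.abundances[g] for g in expressed)
    idle_abund = sum(profile.abundances[g] for g in idle)
    return IdleReport(
        condition_id=profile.condition_id,
        expressed_enzymes=len(expressed),
        idle_enzymes=len(idle),
        active_reactions=len(active & ra_orig),
        ra_reactions=len(ra_orig),
        idle_abundance_fraction=(idle_abund / total_abund) if total_abund > 0 else 0.0,
    )


def compute_kapp(
    net_flux: Mapping[str, float],
    irr: IrreversibleModel,
    activity: GPRActivity,
    profile: ConditionProfile,
    threshold: float = ACTIVITY_THRESHOLD,
) -> list[KappRecord]:
    """Apparent catalytic rates for single-gene (homomeric) reactions.

    One record per original reaction whose rule is a single gene, whose net
    flux magnitude strictly exceeds the threshold, and whose gene has a
    measured positive abundance.  Reactions carrying flux without a
    measured abundance are skipped (logged), never a division error.
    """
    records: list[KappRecord] = []
    for orig, (fwd, _) in irr.split_map.items():
        rule = activity.rules.get(fwd)
        if rule is None or rule.is_empty or not rule.is_single_gene:
            continue
        v = net_flux.get(orig)
        if v is None or abs(v) <= threshold:
            continue
        (gene,) = rule.genes()
        abundance = profile.abundances.get(gene, 0.0)
        if abundance <= 0:
            logger.debug(
                "reaction %s carries flux %.3g but gene %s has no measured "
                "abundance; skipped",
                orig,
                v,
                gene,
            )
            continue
        kapp = abs(v) / abundance / SECONDS_PER_HOUR
        records.append(
            KappRecord(
                reaction_id=orig,
                gene_id=gene,
                condition_id=profile.condition_id,
                replicate_id=profile.replicate_id,
                net_flux=float(v),
                abundance=float(abundance),
                kapp=float(kapp),
            )
        )
    return records


def compute_kvivomax(records: Iterable[KappRecord]) -> list[KvivomaxRecord]:
    """Across-condition maxima of kapp, replicate-averaged when replicated.

    Per reaction: within each replicate take the maximum kapp across
    conditions (recording the argmax condition), then average the
    per-replicate maxima.  Reactions with no records are absent from the
    output, never reported as zero.
    """
    by_rxn: dict[str, list[KappRecord]] = {}
    for rec in records:
        by_rxn.setdefault(rec.reaction_id, []).append(rec)
    out: list[KvivomaxRecord] = []
    for rxn, recs in sorted(by_rxn.items()):
        by_rep: dict[str, list[KappRecord]] = {}
        for rec in recs:
            by_rep.setdefault(rec.replicate_id, []).append(rec)
        rep_values: dict[str, float] = {}
        argmaxes: list[str] = []
        n_conditions = 0
        for rep, rrecs in sorted(by_rep.items()):
            best = max(rrecs, key=lambda r: r.kapp)
            rep_values[rep] = best.kapp
            argmaxes.append(best.condition_id)
            n_conditions = max(n_conditions, len({r.condition_id for r in rrecs}))
        out.append(
            KvivomaxRecord(
                reaction_id=rxn,
                gene_id=recs[0].gene_id,
                kvivomax=float(np.mean(list(rep_values.values()))),
                argmax_condition=";".join(argmaxes),
                n_conditions=n_conditions,
                replicate_values=rep_values,
            )
        )
    return out


def log_pearson(
    x: Mapping[str, float], y: Mapping[str, float]
) -> tuple[float, int, int]:
    """Pearson correlation of log10-transformed paired positive values.

    Pairs are formed on shared keys; pairs with a nonpositive member are
    dropped and counted.  Returns (r, n_pairs, n_dropped).  Fewer than 3
    usable pairs is an error: the correlation would be meaningless.
    """
    shared = sorted(set(x) & set(y))
    if not shared:
        raise ValueError("no shared ids between the two value maps")
    pairs = [(x[k], y[k]) for k in shared]
    usable = [(a, b) for a, b in pairs if a > 0 and b > 0]
    dropped = len(pairs) - len(usable)
    if dropped:
        logger.debug("log_pearson: dropped %d nonpositive pairs", dropped)
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} strictly positive pairs; need at least 3"
        )
    xa = np.log10([a for a, _ in usable])
    ya = np.log10([b for _, b in usable])
    if np.allclose(xa, xa[0]) or np.allclose(ya, ya[0]):
        raise ValueError("zero variance after log transform; correlation undefined")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return r, len(usable), dropped


def interval_coverage(
    net_flux: Mapping[str, float],
    intervals: Mapping[str, tuple[float, float]],
) -> float:
    """Fraction of shared reactions whose flux lies in the closed interval.

    Used to compare estimated fluxes against externally supplied confidence
    intervals (e.g. from 13C flux analysis).
    """
    for r, (lo, hi) in intervals.items():
        if lo > hi:
            raise ValueError(f"interval for {r!r} is inverted: [{lo}, {hi}]")
    shared = set(net_flux) & set(intervals)
    if not shared:
        raise ValueError("no shared reaction ids between fluxes and intervals")
    covered = sum(
        1 for r in shared if intervals[r][0] <= net_flux[r] <= intervals[r][1]
    )
    return covered / len(shared)


def write_kapp_table(path, records: Sequence[KappRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "reaction_id\tgene_id\tcondition_id\treplicate_id\t"
            "net_flux\tabundance\tkapp_per_s\n"
        )
        for r in records:
            fh.write(
                f"{r.reaction_id}\t{r.gene_id}\t{r.condition_id}\t{r.replicate_id}\t"
                f"{r.net_flux:.12g}\t{r.abundance:.12g}\t{r.kapp:.12g}\n"
            )


def write_kvivomax_table(path, records: Sequence[KvivomaxRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "reaction_id\tgene_id\tkvivomax_per_s\targmax_condition\tn_conditions\n"
        )
        for r in records:
            fh.write(
                f"{r.reaction_id}\t{r.gene_id}\t{r.kvivomax:.12g}\t"
                f"{r.argmax_condition}\t{r.n_conditions}\n"
            )
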