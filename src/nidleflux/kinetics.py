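"""Michaelis–Menten-like flux reconstruction from kvivomax and metabolomics.

A reaction's flux is modelled as

    v = kmax * E * P / (1 + P),     P = prod_j (s_j / K_j)^(m_j)

where kmax is the maximal in vivo catalytic rate (1/s), E the enzyme
abundance (mmol/gDW), s_j the concentration of the j-th substrate, K_j its
Michaelis constant (same concentration units as s_j) and m_j its
stoichiometric exponent.  The saturation term P/(1+P) is shared across
substrates (one common product in numerator and denominator, no
substrate-specific denominators).  The result is converted from 1/s to a
flux in mmol/gDW/h by the factor 3600; it is bounded by 3600 * kmax * E.

Reconstructed fluxes are compared against solver fluxes by Pearson
correlation of log10 values, the package's standard qualitative-agreement
measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .estimate import SECONDS_PER_HOUR, log_pearson
from .gpr import ConditionProfile


@dataclass(frozen=True)
class SubstrateTerm:
    substrate_id: str
    km: float  # Michaelis constant, concentration units matching s
    m: int = 1  # stoichiometric exponent

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError(f"K must be positive for {self.substrate_id!r}")
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError(f"m must be a positive integer for {self.substrate_id!r}")


@dataclass
class ReactionKinetics:
    """Kinetic parameters of one reaction: substrates with K and m."""

    reaction_id: str
    substrates: tuple[SubstrateTerm, ...]


@dataclass
class KineticSpec:
    """Kinetic parameters for a set of reactions plus a units declaration.

    Concentration units must match between K values and the concentration
    table; the declared unit string is compared verbatim and nothing is
    converted silently.
    """

    reactions: dict[str, ReactionKinetics]
    concentration_units: str = "mM"

    @classmethod
    def from_tsv(cls, path: str | Path, concentration_units: str = "mM") -> "KineticSpec":
        """Read a kinetics TSV: reaction_id, substrate_id, K, m."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        rxns: dict[str, list[SubstrateTerm]] = {}
        for row in df.itertuples(index=False):
            rxns.setdefault(str(row.reaction_id), []).append(
                SubstrateTerm(str(row.substrate_id), float(row.K), int(row.m))
            )
        return cls(
            reactions={
                r: ReactionKinetics(r, tuple(terms)) for r, terms in rxns.items()
            },
            concentration_units=concentration_units,
        )


def load_concentrations(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a concentrations TSV: condition_id, substrate_id, concentration."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"condition_id": str})
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.condition_id), {})[str(row.substrate_id)] = float(
            row.concentration
        )
    return out


def saturation(kin: ReactionKinetics, concentrations: Mapping[str, float]) -> float:
    """The shared saturation factor P/(1+P) with P = prod (s/K)^m."""
    P = 1.0
    for term in kin.substrates:
        if term.substrate_id not in concentrations:
            raise KeyError(
                f"no concentration for substrate {term.substrate_id!r} "
                f"of reaction {kin.reaction_id!r}"
            )
        s = concentrations[term.substrate_id]
        if s < 0:
            raise ValueError(f"negative concentration for {term.substrate_id!r}")
        P *= (s / term.km) ** term.m
    return P / (1.0 + P)


def mm_flux(
    kmax: float,
    abundance: float,
    kin: ReactionKinetics,
    concentrations: Mapping[str, float],
) -> float:
    """Predicted flux in mmol/gDW/h under saturation kinetics.

    ``kmax`` in 1/s, ``abundance`` in mmol/gDW.  The value lies in
    ``[0, 3600 * kmax * abundance]``; any substrate at concentration 0
    gives 0, full saturation approaches the ceiling.
    """
    if kmax < 0 or abundance < 0:
        raise ValueError("kmax and abundance must be nonnegative")
    return kmax * SECONDS_PER_HOUR * abundance * saturation(kin, concentrations)


def predict_fluxes(
    kvivomax: Mapping[str, float],
    gene_of: Mapping[str, str],
    profile: ConditionProfile,
    spec: KineticSpec,
    concentrations: Mapping[str, float],
) -> dict[str, float]:
    """Reconstruct fluxes for every reaction with kmax, kinetics and E.

    Reactions missing from any of the three tables, or whose enzyme has no
    measured positive abundance in the profile, are omitted.
    """
    out: dict[str, float] = {}
    for rxn, kmax in kvivomax.items():
        kin = spec.reactions.get(rxn)
        gene = gene_of.get(rxn)
        if kin is None or gene is None:
            continue
        abundance = profile.abundances.get(gene, 0.0)
        if abundance <= 0:
            continue
        out[rxn] = mm_flux(kmax, abundance, kin, concentrations)
    return out


def validate_against_solution(
    kvivomax: Mapping[str, float],
    gene_of: Mapping[str, str],
    profile: ConditionProfile,
    spec: KineticSpec,
    concentrations: Mapping[str, float],
    solver_net_flux: Mapping[str, float],
) -> tuple[float, int]:
    """log-Pearson agreement between kinetic and solver flux estimates.

    Returns (r, n_pairs) over the reactions shared between the kinetic
    reconstruction and the solver's net fluxes.
    """
    predicted = predict_fluxes(kvivomax, gene_of, profile, spec, concentrations)
    if not set(predicted) & set(solver_net_flux):
        raise ValueError("no shared reactions between predictions and solver fluxes")
    r, n, _ = log_pearson(predicted, dict(solver_net_flux))
    return r, n
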