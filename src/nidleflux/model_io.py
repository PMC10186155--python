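"""Metabolic model containers, file I/O, and reversible-reaction splitting.

Models are held in lightweight containers rather than full COBRA objects:
the optimization layer needs only stoichiometry, bounds and GPR strings.
SBML (Level 3 + FBC) and COBRA-JSON files are read and written through
COBRApy so the standard dialects are honoured.

Splitting convention: a reversible reaction ``R`` (lower bound < 0) becomes
a forward reaction ``R__fwd`` with the original stoichiometry and bounds
``[0, ub]`` and a backward reaction ``R__bwd`` with negated stoichiometry
and bounds ``[0, -lb]``.  Irreversible reactions keep their original id.
The net flux of the original reaction is ``v_fwd - v_bwd``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

DEFAULT_VMAX = 1000.0
FWD_SUFFIX = "__fwd"
BWD_SUFFIX = "__bwd"

# a carbon atom in a Hill-style formula: C not followed by a lowercase letter
_CARBON_RE = re.compile(r"C(?![a-z])")


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


class ModelParseError(ValueError):
    """Raised when a model file cannot be read under the named standard."""


@dataclass
class Metabolite:
    id: str
    formula: str | None = None
    compartment: str | None = None

    def has_carbon(self) -> bool:
        """True if the chemical formula contains at least one carbon atom."""
        if not self.formula:
            return False
        return bool(_CARBON_RE.search(self.formula))


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions import/export exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic model.

    Houses the stoichiometric matrix N implicitly via per-reaction
    stoichiometry maps, the default flux bounds, GPR rule strings and the
    biomass pseudo-reaction whose flux equals the growth rate mu.
    """

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_reaction_id: str
    id: str = "model"
    carbon_exchange_override: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} "
                    f"> upper bound {rxn.upper_bound}"
                )
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r}: empty stoichiometry")
            for met_id, coef in rxn.stoichiometry.items():
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )
                if coef == 0:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r}: zero stoichiometric coefficient "
                        f"for {met_id!r}"
                    )
        if self.biomass_reaction_id not in self.reactions:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def carbon_exchange_ids(self) -> list[str]:
        """Exchange reactions whose boundary metabolite contains carbon.

        Detection parses the metabolite's chemical formula; when formulas
        are absent a user-supplied override set (``carbon_exchange_override``)
        is consulted instead.
        """
        if self.carbon_exchange_override is not None:
            return [r for r in self.exchange_ids if r in self.carbon_exchange_override]
        out = []
        for rid in self.exchange_ids:
            (met_id,) = self.reactions[rid].stoichiometry.keys()
            if self.metabolites[met_id].has_carbon():
                out.append(rid)
        return out


@dataclass
class IrreversibleModel(MetabolicModel):
    """Model with all reactions irreversible (lower bounds 0).

    ``split_map`` maps every original reaction id to its (forward id,
    backward id or None) pair; the backward reaction's stoichiometry is the
    negation of the forward's.
    """

    split_map: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def validate(self) -> None:
        super().validate()
        for rxn in self.reactions.values():
            if rxn.lower_bound != 0:
                raise ModelValidationError(
                    f"irreversible model reaction {rxn.id!r} has nonzero "
                    f"lower bound {rxn.lower_bound}"
                )
        for orig, (fwd, bwd) in self.split_map.items():
            if fwd not in self.reactions:
                raise ModelValidationError(f"split_map forward id {fwd!r} missing")
            if bwd is not None:
                if bwd not in self.reactions:
                    raise ModelValidationError(f"split_map backward id {bwd!r} missing")
                fs = self.reactions[fwd].stoichiometry
                bs = self.reactions[bwd].stoichiometry
                if set(fs) != set(bs) or any(
                    not math.isclose(bs[m], -c) for m, c in fs.items()
                ):
                    raise ModelValidationError(
                        f"split pair {orig!r}: backward stoichiometry is not "
                        "the negation of the forward"
                    )

    def pair_of(self, original_id: str) -> tuple[str, str | None]:
        return self.split_map[original_id]


def _from_cobra(cmodel, biomass_reaction_id: str | None = None) -> MetabolicModel:
    import cobra

    mets = {
        m.id: Metabolite(m.id, m.formula or None, m.compartment or None)
        for m in cmodel.metabolites
    }
    rxns: dict[str, Reaction] = {}
    for r in cmodel.reactions:
        rxns[r.id] = Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
            name=r.name or "",
        )
    if biomass_reaction_id is None:
        # the objective reaction is the biomass pseudo-reaction by convention
        obj = [r.id for r in cmodel.reactions if r.objective_coefficient]
        if len(obj) != 1:
            raise ModelParseError(
                "cannot infer biomass reaction: model objective does not name "
                "exactly one reaction; pass biomass_reaction_id explicitly"
            )
        biomass_reaction_id = obj[0]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_reaction_id,
        id=cmodel.id or "model",
    )


def load_model(
    path: str | Path,
    format: str | None = None,
    biomass_reaction_id: str | None = None,
) -> MetabolicModel:
    """Read a metabolic model from SBML or COBRA-JSON.

    Parameters
    ----------
    path:
        Model file.  ``format`` may be ``"sbml"`` or ``"cobra-json"``;
        when omitted it is inferred from the file extension.
    biomass_reaction_id:
        Override for the biomass reaction; by default the model's objective
        reaction is used.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    try:
        if format == "cobra-json":
            cmodel = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            cmodel = cobra.io.read_sbml_model(str(path))
        else:
            raise ValueError(f"unknown model format {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # cobra raises assorted exception types
        raise ModelParseError(f"cannot parse {path} as {format}: {exc}") from exc
    return _from_cobra(cmodel, biomass_reaction_id)


def to_cobra(model: MetabolicModel):
    """Convert to a COBRApy model (used for writing standard formats)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites.values():
        cm = cobra.Metabolite(m.id, formula=m.formula, compartment=m.compartment or "c")
        cmets[m.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cmodel.add_reactions([cr])
        cr.add_metabolites({cmets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    cmodel.objective = model.biomass_reaction_id
    return cmodel


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML or COBRA-JSON (inferred from extension)."""
    import cobra.io

    path = Path(path)
    if format is None:
        format = "cobra-json" if path.suffix.lower() == ".json" else "sbml"
    cmodel = to_cobra(model)
    if format == "cobra-json":
        cobra.io.save_json_model(cmodel, str(path))
    elif format == "sbml":
        cobra.io.write_sbml_model(cmodel, str(path))
    else:
        raise ValueError(f"unknown model format {format!r}")


def split_reversible(model: MetabolicModel) -> IrreversibleModel:
    """Split every reversible reaction into forward and backward parts.

    A reaction with lower bound < 0 becomes a forward copy (bounds
    ``[0, max(ub, 0)]``) and a backward copy with negated stoichiometry
    (bounds ``[0, -lb]``); both inherit the GPR rule.  Backward-only
    reactions (ub <= 0) are split the same way, leaving the forward
    direction with upper bound 0 so id bookkeeping stays uniform.
    """
    rxns: dict[str, Reaction] = {}
    split_map: dict[str, tuple[str, str | None]] = {}
    for r in model.reactions.values():
        if r.lower_bound < 0:
            fwd_id = r.id + FWD_SUFFIX
            bwd_id = r.id + BWD_SUFFIX
            rxns[fwd_id] = Reaction(
                id=fwd_id,
                stoichiometry=dict(r.stoichiometry),
                lower_bound=0.0,
                upper_bound=max(r.upper_bound, 0.0),
                gpr=r.gpr,
                name=r.name,
            )
            rxns[bwd_id] = Reaction(
                id=bwd_id,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=-r.lower_bound,
                gpr=r.gpr,
                name=r.name,
            )
            split_map[r.id] = (fwd_id, bwd_id)
        else:
            rxns[r.id] = Reaction(
                id=r.id,
                stoichiometry=dict(r.stoichiometry),
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gpr=r.gpr,
                name=r.name,
            )
            split_map[r.id] = (r.id, None)
    return IrreversibleModel(
        metabolites=dict(model.metabolites),
        reactions=rxns,
        biomass_reaction_id=split_map[model.biomass_reaction_id][0],
        id=model.id,
        carbon_exchange_override=model.carbon_exchange_override,
        split_map=split_map,
    )


def net_fluxes(irr: IrreversibleModel, v: Mapping[str, float]) -> dict[str, float]:
    """Map a flux vector on the split model back to net fluxes.

    Net flux of a split pair is ``v_fwd - v_bwd``; unsplit reactions pass
    through unchanged.
    """
    out: dict[str, float] = {}
    for orig, (fwd, bwd) in irr.split_map.items():
        if fwd not in v:
            raise KeyError(f"flux vector missing reaction {fwd!r}")
        if bwd is None:
            out[orig] = float(v[fwd])
        else:
            if bwd not in v:
                raise KeyError(f"flux vector missing reaction {bwd!r}")
            out[orig] = float(v[fwd]) - float(v[bwd])
    return out


def write_fluxes(path: str | Path, fluxes: Mapping[str, float]) -> None:
    """Write a flux vector as TSV (reaction_id, flux)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid, flux in fluxes.items():
            fh.write(f"{rid}\t{flux:.12g}\n")


def write_split_map(path: str | Path, irr: IrreversibleModel) -> None:
    """Write the split map as TSV (original_id, forward_id, backward_id)."""
    with open(path, "w") as fh:
        fh.write("original_id\tforward_id\tbackward_id\n")
        for orig, (fwd, bwd) in irr.split_map.items():
            fh.write(f"{orig}\t{fwd}\t{bwd or ''}\n")


def stoichiometric_matrix(model: MetabolicModel, reaction_order: Iterable[str] | None = None):
    """Sparse stoichiometric matrix N (metabolites x reactions)."""
    from scipy.sparse import lil_matrix

    rids = list(reaction_order) if reaction_order is not None else list(model.reactions)
    mids = list(model.metabolites)
    midx = {m: i for i, m in enumerate(mids)}
    N = lil_matrix((len(mids), len(rids)))
    for j, rid in enumerate(rids):
        for m, c in model.reactions[rid].stoichiometry.items():
            N[midx[m], j] = c
    return N.tocsr(), mids, rids
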