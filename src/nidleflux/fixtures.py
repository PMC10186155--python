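"""Deterministic toy models with matching synthetic proteomics.

Small metabolic networks exercising every structural motif the estimator
has to handle: parallel single-gene (isozyme-like) reactions, OR/AND GPR
rules, reversible reactions that split into direction pairs, unmeasured
genes (Ri membership) and complexes with missing subunits.  All fixtures
are synthetic: they emulate the *shape* of a genome-scale model plus
condition metadata (carbon source, uptake bound, growth rate, abundances)
at toy scale, not the scale or biochemistry of a real reconstruction.

Canonical fixtures:

* T1 — glucose-like uptake, two parallel single-gene reactions A->B, biomass.
* T2 — T1 plus a reversible single-gene reaction A<->B.
* T3 — T1 with one gene unmeasured (its reaction lands in Ri).
* T4 — single-gene reaction in parallel with an AND-complex missing a subunit.

Expected optima in the manifests are computed with the brute-force
enumeration oracle (``nidleflux.oracle``), never with the main solver, so
tests against the manifests are non-circular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gpr import ConditionProfile, classify_reactions
from .model_io import MetabolicModel, Metabolite, Reaction, split_reversible
from .optimize import build_problem

GLC_FORMULA = "C6H12O6"


@dataclass
class FixtureSpec:
    """Parameters of a generated toy instance.

    The motif counts shape the network between the carbon source and the
    biomass precursor; ``mu`` (1/h) and ``uptake_bound`` (mmol/gDW/h) are
    the condition's physiology; ``seed`` fixes the instance byte-for-byte.
    """

    chain_length: int = 0
    isozyme_pairs: int = 1
    complex_reactions: int = 0
    reversible_reactions: int = 0
    mu: float = 5.0
    uptake_bound: float = 10.0
    abundance: float = 1e-3  # mmol/gDW for every measured gene
    unmeasured_genes: frozenset[str] = frozenset()
    condition_id: str = "c1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chain_length", "isozyme_pairs", "complex_reactions", "reversible_reactions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mu <= 0 or self.uptake_bound <= 0:
            raise ValueError("mu and uptake_bound must be positive")
        if self.mu > self.uptake_bound:
            raise ValueError(
                f"mu {self.mu} unreachable under uptake bound {self.uptake_bound}: "
                "the fixture would be infeasible"
            )


def make_toy_model(spec: FixtureSpec) -> tuple[MetabolicModel, ConditionProfile]:
    """Build a feasible toy model and its condition profile.

    Layout: carbon uptake EX_A -> A, an optional single-gene linear chain
    A -> ... -> H, a parallel section H -> P holding the isozyme pairs,
    complexes and reversible reactions, and a biomass reaction consuming P.
    Every stoichiometric coefficient is 1, so biomass flux mu is reachable
    iff mu <= uptake_bound (validated at construction).
    """
    mets = {"A": Metabolite("A", GLC_FORMULA)}
    rxns: dict[str, Reaction] = {
        "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0)
    }
    genes: list[str] = []

    def new_gene() -> str:
        g = f"g{len(genes) + 1}"
        genes.append(g)
        return g

    head = "A"
    for i in range(spec.chain_length):
        nxt = f"M{i + 1}"
        mets[nxt] = Metabolite(nxt, "C3H6O3")
        g = new_gene()
        rxns[f"C{i + 1}"] = Reaction(f"C{i + 1}", {head: -1.0, nxt: 1.0}, 0.0, 1000.0, gpr=g)
        head = nxt

    mets["P"] = Metabolite("P", "C3H4O3")
    n_parallel = 0
    for i in range(spec.isozyme_pairs):
        for _ in range(2):
            n_parallel += 1
            g = new_gene()
            rid = f"R{n_parallel}"
            rxns[rid] = Reaction(rid, {head: -1.0, "P": 1.0}, 0.0, 1000.0, gpr=g)
    for i in range(spec.complex_reactions):
        n_parallel += 1
        g1, g2 = new_gene(), new_gene()
        rid = f"R{n_parallel}"
        rxns[rid] = Reaction(
            rid, {head: -1.0, "P": 1.0}, 0.0, 1000.0, gpr=f"{g1} and {g2}"
        )
    for i in range(spec.reversible_reactions):
        n_parallel += 1
        g = new_gene()
        rid = f"R{n_parallel}"
        rxns[rid] = Reaction(rid, {head: -1.0, "P": 1.0}, -1000.0, 1000.0, gpr=g)
    if n_parallel == 0:
        rxns["LNK"] = Reaction("LNK", {head: -1.0, "P": 1.0}, 0.0, 1000.0)

    rxns["BIOMASS"] = Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0)
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        id=f"toy_seed{spec.seed}",
    )
    profile = ConditionProfile(
        condition_id=spec.condition_id,
        abundances={
            g: spec.abundance for g in genes if g not in spec.unmeasured_genes
        },
        mu=spec.mu,
        carbon_exchange_id="EX_A",
        uptake_bound=spec.uptake_bound,
    )
    return model, profile


def _manifest(model: MetabolicModel, profile: ConditionProfile, **extra) -> dict:
    """Expected optima computed with the brute-force oracle."""
    from . import oracle

    irr = split_reversible(model)
    activity = classify_reactions(irr, profile)
    problem = build_problem(irr, profile, activity)
    z = oracle.brute_force_z(problem)
    q = oracle.brute_force_q(problem, z)
    man = {
        "model_id": model.id,
        "condition_id": profile.condition_id,
        "mu": profile.mu,
        "uptake_bound": profile.uptake_bound,
        "expected_z": z,
        "expected_q": q,
        "n_ra": len(activity.ra),
        "n_ri": len(activity.ri),
    }
    man.update(extra)
    return man


def t1() -> tuple[MetabolicModel, ConditionProfile, dict]:
    """Two parallel single-gene reactions, both genes measured (z = 2)."""
    spec = FixtureSpec(isozyme_pairs=1, mu=5.0, uptake_bound=10.0)
    model, profile = make_toy_model(spec)
    model.id = "T1"
    return model, profile, _manifest(model, profile, name="T1")


def t2() -> tuple[MetabolicModel, ConditionProfile, dict]:
    """T1 plus a reversible single-gene reaction (one y-pair after split)."""
    spec = FixtureSpec(isozyme_pairs=1, reversible_reactions=1, mu=5.0, uptake_bound=10.0)
    model, profile = make_toy_model(spec)
    model.id = "T2"
    return model, profile, _manifest(model, profile, name="T2")


def t3() -> tuple[MetabolicModel, ConditionProfile, dict]:
    """T1 with the second isozyme gene unmeasured: its reaction is in Ri."""
    spec = FixtureSpec(isozyme_pairs=1, mu=5.0, uptake_bound=10.0, unmeasured_genes=frozenset({"g2"}))
    model, profile = make_toy_model(spec)
    model.id = "T3"
    return model, profile, _manifest(model, profile, name="T3")


def t4() -> tuple[MetabolicModel, ConditionProfile, dict]:
    """Single-gene reaction in parallel with a complex missing a subunit."""
    spec = FixtureSpec(
        isozyme_pairs=0,
        complex_reactions=1,
        mu=5.0,
        uptake_bound=10.0,
        unmeasured_genes=frozenset({"g2"}),
    )
    model, profile = make_toy_model(spec)
    # add a measured single-gene bypass so the condition is informative
    model.reactions["RS"] = Reaction("RS", {"A": -1.0, "P": 1.0}, 0.0, 1000.0, gpr="g3")
    model.validate()
    model.id = "T4"
    profile.abundances["g3"] = spec.abundance
    return model, profile, _manifest(model, profile, name="T4")


CANONICAL = {"T1": t1, "T2": t2, "T3": t3, "T4": t4}


def plant_kcat_scenario(
    v_star: float,
    e_star: float,
    mu: float | None = None,
    condition_id: str = "c1",
    replicate_id: str = "",
) -> tuple[MetabolicModel, ConditionProfile, dict]:
    """Fixture where one single-gene reaction must carry a known flux.

    A linear chain EX_A -> A -> (R_KAPP, gene gk, abundance ``e_star``)
    -> P -> biomass with biomass fixed to ``v_star`` forces exactly
    ``v_star`` through R_KAPP in every feasible flux distribution, so the
    apparent catalytic rate is ``v_star / e_star / 3600`` by construction.
    """
    if v_star <= 0 or e_star <= 0:
        raise ValueError("v_star and e_star must be positive")
    mu = v_star if mu is None else mu
    mets = {
        "A": Metabolite("A", GLC_FORMULA),
        "P": Metabolite("P", "C3H4O3"),
    }
    rxns = {
        "EX_A": Reaction("EX_A", {"A": 1.0}, 0.0, 1000.0),
        "R_KAPP": Reaction("R_KAPP", {"A": -1.0, "P": 1.0}, 0.0, 1000.0, gpr="gk"),
        "BIOMASS": Reaction("BIOMASS", {"P": -1.0}, 0.0, 1000.0),
    }
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, biomass_reaction_id="BIOMASS", id="planted"
    )
    profile = ConditionProfile(
        condition_id=condition_id,
        replicate_id=replicate_id,
        abundances={"gk": e_star},
        mu=mu,
        carbon_exchange_id="EX_A",
        uptake_bound=2.0 * v_star,
    )
    manifest = {
        "name": "planted_kcat",
        "reaction_id": "R_KAPP",
        "gene_id": "gk",
        "v_star": v_star,
        "e_star": e_star,
        "expected_kapp_per_s": v_star / e_star / 3600.0,
    }
    return model, profile, manifest


def random_fixture(
    seed: int, max_binaries: int = 10
) -> tuple[MetabolicModel, ConditionProfile]:
    """Randomized toy instance for property tests and oracle comparisons.

    Samples the motif counts, the measured-gene subset, lognormal
    abundances and the physiology; the number of activation variables
    after splitting is kept at or below ``max_binaries`` so brute-force
    enumeration stays cheap.  The skeleton path guarantees feasibility.
    """
    rng = np.random.default_rng(seed)
    while True:
        spec = FixtureSpec(
            chain_length=int(rng.integers(0, 3)),
            isozyme_pairs=int(rng.integers(0, 3)),
            complex_reactions=int(rng.integers(0, 2)),
            reversible_reactions=int(rng.integers(0, 2)),
            mu=float(rng.uniform(0.5, 5.0)),
            uptake_bound=float(rng.uniform(5.0, 20.0)),
            seed=seed,
        )
        model, profile = make_toy_model(spec)
        # drop a random subset of genes from the measured set
        genes = sorted(profile.abundances)
        measured = {
            g: float(rng.lognormal(mean=-7.0, sigma=1.0))
            for g in genes
            if rng.random() < 0.75
        }
        profile.abundances = measured
        # occasionally mix in an OR rule over a fresh gene
        for rid, rxn in model.reactions.items():
            if rxn.gpr and "and" not in rxn.gpr and rng.random() < 0.2:
                extra = f"gx_{rid}"
                rxn.gpr = f"{rxn.gpr} or {extra}"
                if rng.random() < 0.5:
                    profile.abundances[extra] = float(rng.lognormal(-7.0, 1.0))
        # a second, closed carbon source exercises the other-carbon rule
        if rng.random() < 0.5:
            model.metabolites["A2"] = Metabolite("A2", "C2H4O2")
            model.reactions["EX_A2"] = Reaction("EX_A2", {"A2": 1.0}, 0.0, 1000.0)
            model.reactions["RU2"] = Reaction(
                "RU2", {"A2": -1.0, "P": 1.0}, 0.0, 1000.0
            )
            model.validate()
        irr = split_reversible(model)
        activity = classify_reactions(irr, profile)
        if len(activity.ra) <= max_binaries:
            return model, profile


def write_fixture(
    directory: str | Path,
    model: MetabolicModel,
    profile: ConditionProfile,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Emit a fixture as COBRA-JSON + proteomics/metadata TSV + manifest.

    Output is deterministic (sorted JSON) so identical inputs yield
    byte-identical files.
    """
    import cobra.io

    from .model_io import to_cobra

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = model.id
    paths = {}
    model_path = directory / f"{name}.json"
    cobra.io.save_json_model(to_cobra(model), str(model_path), sort=True)
    paths["model"] = model_path

    prot_path = directory / f"{name}_proteomics.tsv"
    with open(prot_path, "w") as fh:
        fh.write("condition_id\treplicate_id\tgene_id\tabundance_mmol_per_gDW\n")
        for g in sorted(profile.abundances):
            fh.write(
                f"{profile.condition_id}\t{profile.replicate_id}\t{g}\t"
                f"{profile.abundances[g]:.12g}\n"
            )
    paths["proteomics"] = prot_path

    meta_path = directory / f"{name}_metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write(
            "condition_id\treplicate_id\tmu_per_h\tcarbon_exchange_id\t"
            "uptake_mmol_per_gDW_h\n"
        )
        fh.write(
            f"{profile.condition_id}\t{profile.replicate_id}\t{profile.mu:.12g}\t"
            f"{profile.carbon_exchange_id}\t{profile.uptake_bound:.12g}\n"
        )
    paths["metadata"] = meta_path

    if manifest is not None:
        man_path = directory / f"{name}_manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = man_path
    return paths


def write_canonical_fixtures(directory: str | Path) -> dict[str, dict[str, Path]]:
    """Write T1–T4 with oracle-derived manifests into a directory."""
    out = {}
    for name, builder in CANONICAL.items():
        model, profile, manifest = builder()
        out[name] = write_fixture(directory, model, profile, manifest)
    return out
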