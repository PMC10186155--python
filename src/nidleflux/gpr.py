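"""Gene–protein-reaction (GPR) rules and their proteomics-based evaluation.

A GPR rule is a boolean expression over gene ids where OR joins isoenzymes
and AND joins the subunits of a protein complex.  Against a quantitative
proteomics profile the rule evaluates to an *effective abundance*: OR takes
the maximum over children, AND the minimum — an isoenzyme set is as abundant
as its most abundant member, a complex is limited by its scarcest subunit.
Genes without a measurement evaluate to 0, so a complex with an unmeasured
subunit is inactive while an isoenzyme set survives through its measured
members.  No abundance threshold is applied: any nonzero measured abundance
makes a rule active.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .model_io import IrreversibleModel


class GPRParseError(ValueError):
    """Malformed GPR string; message carries the offending position."""


@dataclass(frozen=True)
class Leaf:
    gene: str


@dataclass(frozen=True)
class Op:
    kind: str  # "and" | "or"
    children: tuple


@dataclass(frozen=True)
class GPRRule:
    """Parsed GPR expression tree; ``root`` is None for an empty rule."""

    root: Leaf | Op | None
    source: str = ""

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if isinstance(node, Leaf):
                out.add(node.gene)
            elif isinstance(node, Op):
                for c in node.children:
                    walk(c)

        walk(self.root)
        return frozenset(out)

    @property
    def is_single_gene(self) -> bool:
        """True iff the rule reduces to a single distinct gene.

        Degenerate rules like ``gA and gA`` normalize to single-gene before
        the homomeric filter is applied.
        """
        return self.root is not None and len(self.genes()) == 1


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> GPRRule:
    """Parse a GPR string into an expression tree.

    Grammar (operators case-insensitive, AND binds tighter than OR)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := gene | "(" expr ")"

    Empty or whitespace-only strings yield the empty rule.
    """
    tokens = _tokenize(rule)
    if not tokens:
        return GPRRule(None, rule)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def err(msg: str):
        pos = tokens[idx][1] if idx < len(tokens) else len(rule)
        raise GPRParseError(f"{msg} at position {pos} in {rule!r}")

    def parse_factor():
        nonlocal idx
        tok = peek()
        if tok is None:
            err("unexpected end of rule")
        if tok == "(":
            idx += 1
            node = parse_expr()
            if peek() != ")":
                err("expected ')'")
            idx += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            err(f"unexpected {tok!r}")
        idx += 1
        return Leaf(tok)

    def parse_term():
        nonlocal idx
        children = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            idx += 1
            children.append(parse_factor())
        return children[0] if len(children) == 1 else Op("and", tuple(children))

    def parse_expr():
        nonlocal idx
        children = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            idx += 1
            children.append(parse_term())
        return children[0] if len(children) == 1 else Op("or", tuple(children))

    root = parse_expr()
    if idx < len(tokens):
        err(f"unexpected token {peek()!r}")
    return GPRRule(root, rule)


def evaluate_gpr(rule: GPRRule, abundances: Mapping[str, float]) -> float | None:
    """Effective enzyme abundance of a rule under a proteomics profile.

    OR nodes take the maximum of their children (isoenzymes), AND nodes the
    minimum (complex subunits).  Unmeasured genes count as 0.  The empty
    rule evaluates to None (no enzyme associated).
    """
    if rule.is_empty:
        return None

    def ev(node) -> float:
        if isinstance(node, Leaf):
            return float(abundances.get(node.gene, 0.0))
        vals = [ev(c) for c in node.children]
        return max(vals) if node.kind == "or" else min(vals)

    return ev(rule.root)


@dataclass
class ConditionProfile:
    """One experimental condition: proteomics plus physiology.

    Abundances are in mmol/gDW (see ``load_proteomics`` for unit
    conversion), the growth rate mu in 1/h, and the uptake bound in
    mmol/gDW/h for the designated carbon-source exchange reaction.
    """

    condition_id: str
    abundances: dict[str, float]
    mu: float
    carbon_exchange_id: str
    uptake_bound: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"growth rate must be positive, got {self.mu}")
        if self.uptake_bound <= 0:
            raise ValueError(f"uptake bound must be positive, got {self.uptake_bound}")
        for g, a in self.abundances.items():
            if a < 0:
                raise ValueError(f"negative abundance for gene {g!r}: {a}")


@dataclass
class GPRActivity:
    """Per-reaction GPR classification under one condition.

    ``state`` is ``active`` (nonzero effective abundance, the set Ra),
    ``inactive`` (nonempty rule evaluating to 0, the set Ri) or ``no-gpr``.
    Both directions of a split reversible pair share state and abundance.
    """

    state: dict[str, str]
    abundance: dict[str, float | None]
    single_gene: dict[str, bool]
    rules: dict[str, GPRRule] = field(default_factory=dict)

    @property
    def ra(self) -> list[str]:
        return [r for r, s in self.state.items() if s == "active"]

    @property
    def ri(self) -> list[str]:
        return [r for r, s in self.state.items() if s == "inactive"]

    @property
    def no_gpr(self) -> list[str]:
        return [r for r, s in self.state.items() if s == "no-gpr"]


def classify_reactions(irr: IrreversibleModel, profile: ConditionProfile) -> GPRActivity:
    """Classify each reaction of the split model into Ra / Ri / no-GPR.

    Abundance exactly 0 in the data counts as unmeasured: Ra is defined by
    strictly nonzero effective abundance.
    """
    state: dict[str, str] = {}
    abundance: dict[str, float | None] = {}
    single: dict[str, bool] = {}
    rules: dict[str, GPRRule] = {}
    cache: dict[str, tuple[GPRRule, float | None]] = {}
    for rxn in irr.reactions.values():
        if rxn.gpr in cache:
            rule, eff = cache[rxn.gpr]
        else:
            rule = parse_gpr(rxn.gpr)
            eff = evaluate_gpr(rule, profile.abundances)
            cache[rxn.gpr] = (rule, eff)
        rules[rxn.id] = rule
        if rule.is_empty:
            state[rxn.id] = "no-gpr"
            abundance[rxn.id] = None
            single[rxn.id] = False
        else:
            active = eff is not None and eff > 0
            state[rxn.id] = "active" if active else "inactive"
            abundance[rxn.id] = eff if active else None
            single[rxn.id] = rule.is_single_gene
    return GPRActivity(state=state, abundance=abundance, single_gene=single, rules=rules)


_UNIT_FACTORS = {
    "mmol/gDW": 1.0,
    "umol/gDW": 1e-3,
    "nmol/gDW": 1e-6,
    "pmol/gDW": 1e-9,
}


def load_proteomics(path: str | Path, units: str = "mmol/gDW") -> dict[tuple[str, str], dict[str, float]]:
    """Read a proteomics TSV into per-(condition, replicate) abundance maps.

    Expected columns: ``condition_id``, ``replicate_id``, ``gene_id``,
    ``abundance_mmol_per_gDW`` (or ``abundance`` with ``units`` declaring
    the scale; values are converted to mmol/gDW, never silently).
    """
    import pandas as pd

    if units not in _UNIT_FACTORS:
        raise ValueError(f"unknown abundance units {units!r}; one of {sorted(_UNIT_FACTORS)}")
    df = pd.read_csv(path, sep="\t", dtype={"condition_id": str, "replicate_id": str})
    col = "abundance_mmol_per_gDW" if "abundance_mmol_per_gDW" in df.columns else "abundance"
    factor = _UNIT_FACTORS[units]
    out: dict[tuple[str, str], dict[str, float]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.condition_id), _replicate(row))
        out.setdefault(key, {})[str(row.gene_id)] = float(getattr(row, col)) * factor
    return out


def _replicate(row) -> str:
    """Replicate label; absent or blank fields normalize to ''."""
    rep = getattr(row, "replicate_id", "")
    if rep is None or (isinstance(rep, float) and rep != rep):  # NaN from pandas
        return ""
    return str(rep)


def load_metadata(path: str | Path) -> dict[tuple[str, str], dict]:
    """Read per-condition metadata TSV.

    Expected columns: ``condition_id``, ``replicate_id``, ``mu_per_h``,
    ``carbon_exchange_id``, ``uptake_mmol_per_gDW_h``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"condition_id": str, "replicate_id": str})
    out: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (str(row.condition_id), _replicate(row))
        out[key] = {
            "mu": float(row.mu_per_h),
            "carbon_exchange_id": str(row.carbon_exchange_id),
            "uptake_bound": float(row.uptake_mmol_per_gDW_h),
        }
    return out


def build_profiles(
    proteomics: dict[tuple[str, str], dict[str, float]],
    metadata: dict[tuple[str, str], dict],
) -> list[ConditionProfile]:
    """Join proteomics and metadata tables into ConditionProfiles."""
    profiles = []
    for key, abunds in proteomics.items():
        if key not in metadata:
            raise KeyError(f"no metadata for condition/replicate {key}")
        meta = metadata[key]
        profiles.append(
            ConditionProfile(
                condition_id=key[0],
                replicate_id=key[1],
                abundances=abunds,
                mu=meta["mu"],
                carbon_exchange_id=meta["carbon_exchange_id"],
                uptake_bound=meta["uptake_bound"],
            )
        )
    return profiles
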