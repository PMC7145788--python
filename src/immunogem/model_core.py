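"""Stoichiometric model data structures, GPR evaluation and network views.

The in-memory model is deliberately lightweight: metabolites, reactions with
signed stoichiometry, flux bounds, gene-protein-reaction (GPR) boolean rules
and a free-text subsystem per reaction.  The stoichiometric matrix S
(metabolites x reactions) is reconstructed on demand.  Compartments follow
the bracket convention used throughout the reports: [c] cytosol, [g] Golgi,
[r] endoplasmic reticulum, [l] lysosome, [m] mitochondrion, [e] extracellular.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_COMPARTMENTS = frozenset({"c", "g", "r", "l", "m", "e"})

#: Highly connected cofactors excluded from reporter-metabolite neighborhoods
#: by default; they link most of the network and destroy signal locality.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {"h2o", "h", "atp", "adp", "amp", "pi", "ppi", "nad", "nadh",
     "nadp", "nadph", "coa", "co2", "o2"}
)


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|\band\b|\bor\b|[^\s()]+")

#: Sentinel returned by :func:`evaluate_gpr` when a rule carries no usable
#: gene evidence (empty rule, or all genes missing from the expression data).
NO_EVIDENCE = None


@dataclass(frozen=True)
class GPR:
    """Boolean AND/OR tree over gene identifiers.

    ``op`` is ``"gene"`` (leaf, ``children`` holds the gene id), ``"and"``
    or ``"or"`` (``children`` holds sub-trees).  The empty rule is
    represented by ``GPR.empty()``.
    """

    op: str
    children: tuple

    @staticmethod
    def empty() -> "GPR":
        return GPR("empty", ())

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset({self.children[0]})
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.children[0]
        joiner = " and " if self.op == "and" else " or "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or") and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)


def parse_gpr(rule: str | None) -> GPR:
    """Parse a boolean gene rule such as ``"(g1 and g2) or g3"``.

    AND binds tighter than OR.  Case-insensitive keywords; anything else is
    a gene identifier.  Empty/whitespace input yields the empty rule.
    """
    if rule is None or not rule.strip():
        return GPR.empty()
    tokens = _TOKEN_RE.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPR:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPR("or", tuple(terms))

    def parse_and() -> GPR:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GPR("and", tuple(terms))

    def parse_atom() -> GPR:
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return node
        if tok == ")":
            raise ValueError(f"unexpected ')' in GPR rule: {rule!r}")
        take()
        return GPR("gene", (tok,))

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR rule: {rule!r}")
    return node


def evaluate_gpr(
    gpr: GPR | str | None,
    gene_values: Mapping[str, float],
    and_rule: Callable[[Sequence[float]], float] = min,
    or_rule: Callable[[Sequence[float]], float] = max,
) -> float | None:
    """Map gene expression onto a reaction through its GPR rule.

    AND nodes are combined with ``and_rule`` (default ``min``: the limiting
    subunit of a complex), OR nodes with ``or_rule`` (default ``max``: the
    most expressed isoenzyme).  Genes absent from ``gene_values`` contribute
    no evidence: they are dropped from their node rather than treated as
    zero (absence of a probe is not absence of expression).  A rule whose
    genes are all missing -- or the empty rule -- evaluates to
    :data:`NO_EVIDENCE`.
    """
    if gpr is None or isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    if gpr.is_empty:
        return NO_EVIDENCE
    if gpr.op == "gene":
        return gene_values.get(gpr.children[0], NO_EVIDENCE)
    vals = [evaluate_gpr(c, gene_values, and_rule, or_rule) for c in gpr.children]
    vals = [v for v in vals if v is not NO_EVIDENCE]
    if not vals:
        return NO_EVIDENCE
    return and_rule(vals) if gpr.op == "and" else or_rule(vals)


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self):
        if self.compartment not in VALID_COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )

    @property
    def tagged(self) -> str:
        """Report-style name with bracketed compartment, e.g. ``GlcCer[c]``."""
        base = self.name or self.id
        return f"{base}[{self.compartment}]"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]  # metabolite id -> signed coefficient
    lb: float = 0.0
    ub: float = 1000.0
    gpr: GPR = field(default_factory=GPR.empty)
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def genes(self) -> frozenset[str]:
        return self.gpr.genes()


def make_reaction(
    id: str,
    stoich: Mapping[str, float],
    lb: float = 0.0,
    ub: float = 1000.0,
    gpr: str | GPR = "",
    subsystem: str = "",
    name: str = "",
) -> Reaction:
    """Convenience constructor accepting the GPR as a rule string."""
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    return Reaction(id=id, stoich=dict(stoich), lb=lb, ub=ub, gpr=gpr,
                    subsystem=subsystem, name=name)


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    def metabolite(self, mid: str) -> Metabolite:
        index = getattr(self, "_met_by_id", None)
        if index is None:
            index = {m.id: m for m in self.metabolites}
            object.__setattr__(self, "_met_by_id", index)
        try:
            return index[mid]
        except KeyError:
            raise KeyError(f"unknown metabolite id {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ModelValidationError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        declared = set(mids)
        for r in self.reactions:
            missing = set(r.stoich) - declared
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites {sorted(missing)}"
                )

    # -- matrix view -----------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with rows ordered as ``metabolites``, columns as ``reactions``."""
        midx = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoich.items():
                S[midx[mid], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([r.lb for r in self.reactions]),
                np.array([r.ub for r in self.reactions]))

    def reactions_by_metabolite(self) -> dict[str, list[Reaction]]:
        """Participation index (cached); treat the model as immutable."""
        cached = getattr(self, "_rxn_index", None)
        if cached is None:
            cached = {}
            for r in self.reactions:
                for mid in r.stoich:
                    cached.setdefault(mid, []).append(r)
            object.__setattr__(self, "_rxn_index", cached)
        return cached

    # -- structural queries ---------------------------------------------
    def exchange_reactions(self) -> list[Reaction]:
        """Reactions with single-metabolite stoichiometry on an extracellular species."""
        comp = {m.id: m.compartment for m in self.metabolites}
        return [r for r in self.reactions
                if len(r.stoich) == 1 and comp[next(iter(r.stoich))] == "e"]

    def boundary_reactions(self) -> list[Reaction]:
        """All single-metabolite reactions (exchanges, demands, sinks)."""
        return [r for r in self.reactions if len(r.stoich) == 1]


# ---------------------------------------------------------------------------
# Reversibility splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitModel:
    """An irreversible model plus the bookkeeping to map fluxes back."""

    model: MetabolicModel
    #: split reaction id -> (original id, +1 forward / -1 backward)
    origin: Mapping[str, tuple[str, int]]

    def merge_fluxes(self, v_split: Mapping[str, float]) -> dict[str, float]:
        """Net flux per original reaction: forward minus backward."""
        net: dict[str, float] = {}
        for rid, flux in v_split.items():
            orig, sign = self.origin[rid]
            net[orig] = net.get(orig, 0.0) + sign * flux
        return net


def split_reversible(model: MetabolicModel) -> SplitModel:
    """Replace every reversible reaction by an irreversible forward/backward pair.

    The backward member mirrors the stoichiometry; all lower bounds end up at
    zero.  Already-irreversible models come back unchanged (identity mapping).
    """
    reactions: list[Reaction] = []
    origin: dict[str, tuple[str, int]] = {}
    for r in model.reactions:
        if not r.reversible:
            reactions.append(r)
            origin[r.id] = (r.id, +1)
            continue
        fwd = replace(r, id=f"{r.id}__fwd", lb=0.0, ub=r.ub)
        bwd = replace(
            r,
            id=f"{r.id}__bwd",
            stoich={m: -c for m, c in r.stoich.items()},
            lb=0.0,
            ub=-r.lb,
        )
        reactions.extend([fwd, bwd])
        origin[fwd.id] = (r.id, +1)
        origin[bwd.id] = (r.id, -1)
    split = MetabolicModel(id=model.id, metabolites=list(model.metabolites),
                           reactions=reactions)
    return SplitModel(model=split, origin=origin)


# ---------------------------------------------------------------------------
# Reporter neighborhoods
# ---------------------------------------------------------------------------

def _currency_base(metabolite: Metabolite) -> str:
    base = (metabolite.name or metabolite.id).lower()
    # strip a trailing compartment suffix such as "_c" from the id form
    base = re.sub(r"_[cgrlme]$", "", base)
    return base

def metabolite_gene_neighborhood(
    model: MetabolicModel,
    metabolite_id: str,
    currency_metabolites: Iterable[str] = DEFAULT_CURRENCY_METABOLITES,
) -> frozenset[str]:
    """Genes of every reaction in which the metabolite participates.

    Currency metabolites (by lower-cased base name or id) return the empty
    set: their neighborhoods span the whole network and carry no local
    signal.  Unknown ids raise ``KeyError``.
    """
    met = model.metabolite(metabolite_id)
    currency = {c.lower() for c in currency_metabolites}
    if _currency_base(met) in currency or met.id.lower() in currency:
        return frozenset()
    genes: set[str] = set()
    for r in model.reactions_by_metabolite().get(metabolite_id, []):
        genes |= r.genes
    return frozenset(genes)
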