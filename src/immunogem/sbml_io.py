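"""SBML (Level 3 + FBC v2) round-trip for :class:`~immunogem.model_core.MetabolicModel`.

Reading and writing are delegated to cobrapy's SBML layer, which handles FBC
bounds and gene-product associations.  Subsystems are persisted explicitly
as SBML groups (cobrapy reads groups but does not write the ``subsystem``
attribute on its own).  Unknown SBML packages are ignored with a warning,
which is cobrapy's behaviour as well.
"""

from __future__ import annotations

import logging
from pathlib import Path

import cobra
import pandas as pd

from .model_core import (
    GPR,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)

logger = logging.getLogger(__name__)

# our models carry no FBA objective inside the SBML (objectives are chosen
# per analysis); cobra logs that as an error, which is just noise here
logging.getLogger("cobra.io.sbml").setLevel(logging.CRITICAL)


class SBMLParseError(ValueError):
    """Raised when an SBML file cannot be parsed into a valid model."""


def to_cobra(model: MetabolicModel) -> cobra.Model:
    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name or m.id,
                                compartment=m.compartment,
                                formula=m.formula)
        mets[m.id] = cmet
    # add metabolites first, in declared order, so the SBML species list
    # (and hence the re-read model) preserves ordering
    cm.add_metabolites(list(mets.values()))
    reactions = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name or r.id)
        reactions.append(cr)
    cm.add_reactions(reactions)
    for cr, r in zip(reactions, model.reactions):
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoich.items()})
        cr.bounds = (r.lb, r.ub)
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
        # subsystem goes into the notes body: per-reaction, hence with a
        # deterministic serialisation (SBML groups via cobrapy are backed by
        # an unordered set and do not round-trip byte-stably)
        if r.subsystem:
            cr.notes["SUBSYSTEM"] = r.subsystem
    return cm


def from_cobra(cm: cobra.Model) -> MetabolicModel:
    subsystem_of: dict[str, str] = {
        cr.id: str(cr.notes["SUBSYSTEM"])
        for cr in cm.reactions if "SUBSYSTEM" in (cr.notes or {})
    }
    metabolites = [
        Metabolite(id=m.id, name=m.name or m.id, compartment=m.compartment,
                   formula=m.formula or None)
        for m in cm.metabolites
    ]
    reactions = []
    for cr in cm.reactions:
        gpr = parse_gpr(cr.gene_reaction_rule) if cr.gene_reaction_rule else GPR.empty()
        reactions.append(Reaction(
            id=cr.id,
            stoich={m.id: coef for m, coef in cr.metabolites.items()},
            lb=cr.lower_bound,
            ub=cr.upper_bound,
            gpr=gpr,
            subsystem=subsystem_of.get(cr.id, cr.subsystem or ""),
            name=cr.name or cr.id,
        ))
    return MetabolicModel(id=cm.id or "model", metabolites=metabolites,
                          reactions=reactions)


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML L3/FBC file into a :class:`MetabolicModel`.

    Malformed XML raises :class:`SBMLParseError` naming the underlying
    problem; structural violations (e.g. a reaction citing an undeclared
    species) surface as :class:`ModelValidationError`.
    """
    path = Path(path)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except ModelValidationError:
        raise
    except Exception as exc:  # libsbml/cobra raise a mix of types
        raise SBMLParseError(f"cannot parse SBML file {path}: {exc}") from exc
    return from_cobra(cm)


def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    path = Path(path)
    cobra.io.write_sbml_model(to_cobra(model), str(path))
    return path


def reaction_table(model: MetabolicModel) -> pd.DataFrame:
    """Flat per-reaction table (TSV-exportable)."""
    rows = []
    for r in model.reactions:
        eq = " + ".join(f"{-c:g} {m}" for m, c in sorted(r.stoich.items()) if c < 0)
        eq += " --> " if not r.reversible else " <=> "
        eq += " + ".join(f"{c:g} {m}" for m, c in sorted(r.stoich.items()) if c > 0)
        rows.append({
            "reaction": r.id,
            "equation": eq,
            "lb": r.lb,
            "ub": r.ub,
            "gpr": r.gpr.to_string(),
            "subsystem": r.subsystem,
        })
    return pd.DataFrame(rows)


def metabolite_table(model: MetabolicModel) -> pd.DataFrame:
    return pd.DataFrame(
        [{"metabolite": m.id, "name": m.name, "compartment": m.compartment,
          "tagged": m.tagged} for m in model.metabolites]
    )
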