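"""Flux balance analysis on (context) models and per-subsystem summaries.

FBA solves max/min c·v subject to S·v = 0 and lb ≤ v ≤ ub with scipy's
HiGHS LP solver at tight tolerances.  Because an FBA optimum is generally a
face rather than a point, the reported flux vector is the parsimonious one:
total absolute flux is minimised at the fixed optimal objective, which makes
subsystem summaries reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import MetabolicModel

logger = logging.getLogger(__name__)

_LP_OPTS = {"presolve": True,
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10}


@dataclass
class FluxState:
    objective_id: str
    objective_value: float
    status: str                        # optimal | infeasible | unbounded
    fluxes: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def fba(model: MetabolicModel, objective_reaction: str, sense: str = "max",
        parsimonious: bool = True) -> FluxState:
    """Flux balance analysis for one objective reaction.

    With ``parsimonious`` (default), a second LP minimises Σ|v| at the
    fixed optimum so the returned vertex is unique in total flux.
    """
    rids = model.reaction_ids
    if objective_reaction not in rids:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n_m, n_r = S.shape
    j_obj = rids.index(objective_reaction)

    c = np.zeros(n_r)
    c[j_obj] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(n_m), bounds=list(zip(lb, ub)),
                  method="highs", options=_LP_OPTS)
    if res.status == 2:
        return FluxState(objective_reaction, float("nan"), "infeasible")
    if res.status == 3:
        return FluxState(objective_reaction, float("inf"), "unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    opt = float(res.x[j_obj])
    v = res.x

    if parsimonious:
        # min Σ|v| with v = v+ - v-, at the fixed optimum
        A_eq = np.hstack([S, -S])
        A_eq = np.vstack([A_eq, np.zeros(2 * n_r)])
        A_eq[-1, j_obj] = 1.0
        A_eq[-1, n_r + j_obj] = -1.0
        b_eq = np.concatenate([np.zeros(n_m), [opt]])
        bounds = ([(max(l, 0), max(u, 0)) for l, u in zip(lb, ub)]
                  + [(max(-u, 0), max(-l, 0)) for l, u in zip(lb, ub)])
        res2 = linprog(np.ones(2 * n_r), A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                       method="highs", options=_LP_OPTS)
        if res2.status == 0:
            v = res2.x[:n_r] - res2.x[n_r:]
        else:
            logger.warning("parsimonious step failed (%s); reporting raw vertex",
                           res2.message)
    return FluxState(objective_reaction, opt, "optimal",
                     fluxes=dict(zip(rids, v)))


def mass_balance_residual(model: MetabolicModel, state: FluxState) -> float:
    """‖S·v‖∞ of an optimal flux state (should be ≤ 1e-9)."""
    S = model.stoichiometric_matrix()
    v = np.array([state.fluxes[r] for r in model.reaction_ids])
    return float(np.abs(S @ v).max())


def with_demand(model: MetabolicModel, template: MetabolicModel,
                objective: str) -> MetabolicModel | None:
    """Re-add a demand objective pruned during extraction.

    Demand reactions carry no gene evidence, so extraction may drop them on
    weight ties even when the producing pathway is kept; the objective is
    then addable back as a single-metabolite drain.  Returns ``None`` when
    the template itself lacks the reaction or the model lacks its
    metabolite.
    """
    if objective in model.reaction_ids:
        return model
    if objective not in template.reaction_ids:
        return None
    dm = template.reaction(objective)
    if any(mid not in model.metabolite_ids for mid in dm.stoich):
        return None
    return MetabolicModel(id=model.id, metabolites=list(model.metabolites),
                          reactions=list(model.reactions) + [dm])


def optimize_glycoceramide_production(
    context_models: dict[str, MetabolicModel],
    objectives: tuple[str, str] = ("DM_glccer_c", "DM_digalcer_g"),
    reference_group: str = "CTRL",
    template: MetabolicModel | None = None,
) -> pd.DataFrame:
    """FBA optima of the two glycoceramide objectives per group model.

    An objective reaction pruned from a context model is re-added as a
    demand (from ``template``) before optimising, with the pruning noted in
    the ``pruned`` flag; if it cannot be re-added it is recorded as 0.  The
    table also carries each group's ratio to the reference group.
    """
    rows = []
    for group, model in context_models.items():
        for obj in objectives:
            pruned = obj not in model.reaction_ids
            target = (with_demand(model, template, obj)
                      if template is not None else (None if pruned else model))
            if target is not None:
                state = fba(target, obj, "max")
                value = state.objective_value if state.optimal else 0.0
            else:
                value = 0.0
            rows.append({"group": group, "objective": obj,
                         "optimum": value, "pruned": pruned})
    df = pd.DataFrame(rows)
    ref = df[df["group"] == reference_group].set_index("objective")["optimum"]

    def ratio(row):
        r = ref.get(row["objective"], np.nan)
        if r == 0:
            return np.inf if row["optimum"] > 0 else 1.0
        return row["optimum"] / r

    df["ratio_vs_" + reference_group] = df.apply(ratio, axis=1)
    return df


def subsystem_flux_deltas(flux_a: FluxState, flux_b: FluxState,
                          model: MetabolicModel) -> pd.DataFrame:
    """Per-subsystem total |flux| comparison between two optimal states.

    Reactions present in both flux vectors (intersection) are grouped by
    the model's subsystem labels; absolute and relative changes of
    Σ|v| are reported, largest absolute change first.
    """
    shared = sorted(set(flux_a.fluxes) & set(flux_b.fluxes))
    subsys = {r.id: (r.subsystem or "(none)") for r in model.reactions}
    totals_a: dict[str, float] = {}
    totals_b: dict[str, float] = {}
    for rid in shared:
        ss = subsys.get(rid, "(none)")
        totals_a[ss] = totals_a.get(ss, 0.0) + abs(flux_a.fluxes[rid])
        totals_b[ss] = totals_b.get(ss, 0.0) + abs(flux_b.fluxes[rid])
    rows = []
    for ss in sorted(set(totals_a) | set(totals_b)):
        a = totals_a.get(ss, 0.0)
        b = totals_b.get(ss, 0.0)
        rel = (b - a) / a if a > 0 else (np.inf if b > 0 else 0.0)
        rows.append({"subsystem": ss, "total_abs_flux_a": a,
                     "total_abs_flux_b": b, "delta": b - a, "relative": rel})
    return (pd.DataFrame(rows)
            .sort_values("delta", key=lambda s: s.abs(), ascending=False,
                         kind="mergesort")
            .reset_index(drop=True))


def flux_table(states: dict[str, FluxState], model: MetabolicModel) -> pd.DataFrame:
    subsys = {r.id: r.subsystem for r in model.reactions}
    rids = sorted({rid for s in states.values() for rid in s.fluxes})
    data = {"reaction": rids, "subsystem": [subsys.get(r, "") for r in rids]}
    for name, s in states.items():
        data[name] = [s.fluxes.get(r, np.nan) for r in rids]
    return pd.DataFrame(data)
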