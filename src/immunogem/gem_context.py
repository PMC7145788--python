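"""Context-specific model extraction: reaction scoring, metabolite evidence,
exchange constraints, and the INIT-style MILP.

The extraction solves

    max  Σ_i w_i·y_i + κ·Σ_j x_j
    s.t. S·v = b
         ε·y_i ≤ v_i ≤ M·y_i                (y_i binary: reaction kept)
         ε·x_j ≤ b_j ≤ b_max·x_j            (x_j binary: evidenced metabolite
                                             net-produced; b_j = 0 otherwise)

on a reversibility-split network, so every kept reaction must be able to
carry at least ε flux simultaneously with the rest of the kept set, and
each evidenced metabolite that the network can net-produce earns the κ
bonus.  Reaction weights come from expression mapped through GPR rules:
w_i = log2(e_i / τ), clipped, with τ an expression threshold (default the
median gene signal).  The MILP runs on scipy's HiGHS solver and is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, milp

from .model_core import MetabolicModel, SplitModel, evaluate_gpr

logger = logging.getLogger(__name__)

NO_EVIDENCE = "no evidence"


@dataclass(frozen=True)
class ReactionScore:
    reaction: str
    expression_level: float | str  # linear-scale e_i, or "no evidence"
    weight: float


@dataclass(frozen=True)
class MetaboliteEvidence:
    metabolite: str
    present: bool


class ExtractionError(RuntimeError):
    """MILP infeasibility or solver failure, with a cause hint."""


@dataclass
class ContextModel:
    """Result of an INIT extraction."""

    included: list[str]            # split-reaction ids with y = 1
    y: dict                        # reaction id -> 0/1
    b: dict                        # evidenced metabolite -> accumulation
    objective: float
    status: str
    model: MetabolicModel          # the extracted (pruned) split model
    flux_witness: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scoring and evidence
# ---------------------------------------------------------------------------

def score_reactions(model: MetabolicModel, gene_expression: pd.Series,
                    tau: float | None = None, w_max: float = 5.0,
                    and_rule=min, or_rule=max) -> list[ReactionScore]:
    """Expression-derived inclusion weight per reaction.

    ``gene_expression`` holds linear-scale per-gene signal (e.g. group
    means).  Each reaction's level e_i comes from its GPR (AND -> min,
    OR -> max by default); the weight is log2(e_i / τ) clipped to
    [−w_max, +w_max].  τ defaults to the median of the gene signal.
    Reactions without usable gene evidence get weight 0.
    """
    if tau is None:
        tau = float(np.median(gene_expression.to_numpy(dtype=float)))
    if tau <= 0:
        raise ValueError("expression threshold tau must be positive")
    values = gene_expression.to_dict()
    scores = []
    for r in model.reactions:
        e = evaluate_gpr(r.gpr, values, and_rule=and_rule, or_rule=or_rule)
        if e is None:
            scores.append(ReactionScore(r.id, NO_EVIDENCE, 0.0))
        else:
            w = float(np.clip(np.log2(max(e, 1e-300) / tau), -w_max, w_max))
            scores.append(ReactionScore(r.id, float(e), w))
    return scores


def metabolite_evidence_from_metabolomics(
    model: MetabolicModel, detected_features, mapping: dict[str, list[str]],
) -> list[MetaboliteEvidence]:
    """Presence calls for model metabolites from detected feature names.

    A feature mapping to several candidate metabolites (e.g. hexosylceramide
    -> glucosyl- or galactosylceramide) marks all of them present, with a
    logged warning.  Unmapped features are logged and skipped.
    """
    model_ids = set(model.metabolite_ids)
    present: set[str] = set()
    for feat in detected_features:
        targets = mapping.get(feat)
        if not targets:
            logger.info("feature %r has no model mapping; skipped", feat)
            continue
        valid = [t for t in targets if t in model_ids]
        if len(valid) > 1:
            logger.warning("feature %r maps ambiguously to %s; all marked present",
                           feat, valid)
        present.update(valid)
    return [MetaboliteEvidence(mid, mid in present)
            for mid in model.metabolite_ids]


def exchange_bounds_from_metabolomics(
    model: MetabolicModel, evidence: list[MetaboliteEvidence],
    media_whitelist=(), default_uptake: float = 10.0,
) -> MetabolicModel:
    """Close all uptakes except for evidenced or whitelisted metabolites.

    Exchange reactions (single extracellular metabolite) keep free
    secretion; uptake (lb = −default_uptake) is permitted only when the
    exchanged metabolite -- or its intracellular namesake -- is evidenced
    or whitelisted.  Applying the overlay twice is a no-op.
    """
    from dataclasses import replace

    present = {e.metabolite for e in evidence if e.present}
    media = set(media_whitelist)
    name_of = {m.id: (m.name or m.id) for m in model.metabolites}
    present_names = {name_of[mid] for mid in present if mid in name_of}

    exchange_ids = {r.id for r in model.exchange_reactions()}
    new_reactions = []
    for r in model.reactions:
        if r.id in exchange_ids:
            mid = next(iter(r.stoich))
            name = name_of[mid]
            allowed = (mid in present or mid in media or name in media
                       or name in present_names)
            lb = -default_uptake if allowed else 0.0
            new_reactions.append(replace(r, lb=lb))
        else:
            new_reactions.append(r)
    return MetabolicModel(id=model.id, metabolites=list(model.metabolites),
                          reactions=new_reactions)


# ---------------------------------------------------------------------------
# INIT MILP
# ---------------------------------------------------------------------------

def init_extract(split: SplitModel, scores: list[ReactionScore],
                 evidence: list[MetaboliteEvidence] | None = None,
                 eps: float = 1e-3, big_m: float = 1000.0,
                 kappa: float = 20.0, b_max: float = 100.0,
                 mip_rel_gap: float = 1e-6,
                 verify: bool = True) -> ContextModel:
    """Extract a context-specific subnetwork by the INIT MILP.

    ``split`` must be a reversibility-split model (all lb = 0);
    ``scores`` must cover every reaction of the split model (forward and
    backward twins of a reversible reaction inherit the original's score
    when scored on the unsplit model).  Returns the kept reaction set; when
    ``verify`` is on, each kept reaction is re-checked to carry ≥ eps flux
    in the extracted model.
    """
    model = split.model
    rids = model.reaction_ids
    n_r = len(rids)
    lb, ub = model.bounds_arrays()
    if (lb < 0).any():
        raise ValueError("init_extract requires a reversibility-split model")

    score_by_id = {s.reaction: s for s in scores}
    w = np.zeros(n_r)
    for j, rid in enumerate(rids):
        s = score_by_id.get(rid)
        if s is None:
            orig, _ = split.origin[rid]
            s = score_by_id.get(orig)
        if s is None:
            raise ValueError(f"no score for reaction {rid!r}")
        w[j] = s.weight

    evid_ids = [e.metabolite for e in (evidence or []) if e.present]
    mids = model.metabolite_ids
    midx = {m: i for i, m in enumerate(mids)}
    for mid in evid_ids:
        if mid not in midx:
            raise ValueError(f"evidenced metabolite {mid!r} not in model")
    n_m, n_e = len(mids), len(evid_ids)

    S = sp.csr_matrix(model.stoichiometric_matrix())
    # variables: v (n_r), y (n_r), b (n_e), x (n_e)
    n_var = n_r + n_r + n_e + n_e
    iv = np.arange(n_r)
    iy = n_r + np.arange(n_r)
    ib = 2 * n_r + np.arange(n_e)
    ix = 2 * n_r + n_e + np.arange(n_e)

    cons = []
    # S v - b = 0 (b only on evidenced metabolite rows)
    B = sp.lil_matrix((n_m, n_var))
    B[:, :n_r] = S
    for col, mid in enumerate(evid_ids):
        B[midx[mid], ib[col]] = -1.0
    cons.append(LinearConstraint(B.tocsr(), np.zeros(n_m), np.zeros(n_m)))
    # eps*y <= v <= M*y
    D1 = sp.lil_matrix((n_r, n_var))  # v - M y <= 0
    D2 = sp.lil_matrix((n_r, n_var))  # v - eps y >= 0
    for j in range(n_r):
        D1[j, iv[j]] = 1.0
        D1[j, iy[j]] = -min(big_m, ub[j]) if ub[j] > 0 else -big_m
        D2[j, iv[j]] = 1.0
        D2[j, iy[j]] = -eps
    cons.append(LinearConstraint(D1.tocsr(), -np.inf, np.zeros(n_r)))
    cons.append(LinearConstraint(D2.tocsr(), np.zeros(n_r), np.inf))
    # eps*x <= b <= b_max*x
    if n_e:
        E1 = sp.lil_matrix((n_e, n_var))
        E2 = sp.lil_matrix((n_e, n_var))
        for j in range(n_e):
            E1[j, ib[j]] = 1.0
            E1[j, ix[j]] = -b_max
            E2[j, ib[j]] = 1.0
            E2[j, ix[j]] = -eps
        cons.append(LinearConstraint(E1.tocsr(), -np.inf, np.zeros(n_e)))
        cons.append(LinearConstraint(E2.tocsr(), np.zeros(n_e), np.inf))

    c = np.zeros(n_var)
    c[iy] = -w          # maximize -> minimize negated
    c[ix] = -kappa
    integrality = np.zeros(n_var)
    integrality[iy] = 1
    integrality[ix] = 1
    var_lb = np.zeros(n_var)
    var_ub = np.concatenate([np.minimum(ub, big_m), np.ones(n_r),
                             np.full(n_e, b_max), np.ones(n_e)])

    import warnings as _warnings

    from scipy.optimize import Bounds

    # tight integrality/feasibility tolerances: with big-M coupling, the
    # default 1e-6 integrality tolerance lets y ~ 1e-6 pass as "zero" while
    # M*y still covers eps of flux
    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Unrecognized options")
        res = milp(c=c, constraints=cons, integrality=integrality,
                   bounds=Bounds(var_lb, var_ub),
                   options={"mip_rel_gap": mip_rel_gap,
                            "mip_feasibility_tolerance": 1e-9,
                            "primal_feasibility_tolerance": 1e-9})
    if res.status != 0 or res.x is None:
        hint = "no open uptakes?" if not any(
            r.lb < 0 or (len(r.stoich) == 1) for r in model.reactions) else res.message
        raise ExtractionError(f"INIT MILP failed (status {res.status}): {hint}")

    y = {rid: int(res.x[iy[j]] > 0.5) for j, rid in enumerate(rids)}
    included = [rid for rid in rids if y[rid] == 1]
    b = {mid: float(res.x[ib[j]]) for j, mid in enumerate(evid_ids)}
    flux = {rid: float(res.x[iv[j]]) for j, rid in enumerate(rids)}

    kept = [r for r in model.reactions if y[r.id] == 1]
    extracted = MetabolicModel(id=f"{model.id}__context",
                               metabolites=list(model.metabolites),
                               reactions=kept)
    ctx = ContextModel(included=included, y=y, b=b,
                       objective=float(-res.fun), status="optimal",
                       model=extracted, flux_witness=flux)
    if verify and included:
        bad = _verify_included(extracted, evid_ids, b_max, eps)
        if bad:
            raise ExtractionError(
                f"extracted model not self-consistent; blocked reactions: {bad[:5]}")
    return ctx


def _verify_included(extracted: MetabolicModel, evid_ids, b_max, eps) -> list[str]:
    """Feasibility re-solve: each kept reaction must reach ≥ eps flux."""
    S = extracted.stoichiometric_matrix()
    lb, ub = extracted.bounds_arrays()
    mids = extracted.metabolite_ids
    n_m, n_r = S.shape
    # allow accumulation of evidenced metabolites, as in the MILP
    cols = []
    for mid in evid_ids:
        e = np.zeros(n_m)
        e[mids.index(mid)] = -1.0
        cols.append(e)
    A = np.hstack([S] + [c[:, None] for c in cols]) if cols else S
    lo = np.concatenate([np.maximum(lb, 0), np.zeros(len(cols))])
    hi = np.concatenate([ub, np.full(len(cols), b_max)])
    bad = []
    for j, rid in enumerate(extracted.reaction_ids):
        c = np.zeros(A.shape[1])
        c[j] = -1.0
        res = linprog(c, A_eq=A, b_eq=np.zeros(n_m),
                      bounds=list(zip(lo, hi)), method="highs")
        if res.status != 0 or -res.fun < eps - 1e-9:
            bad.append(rid)
    return bad


def score_table(scores: list[ReactionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"reaction": s.reaction, "expression": s.expression_level,
          "weight": s.weight} for s in scores]
    )
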