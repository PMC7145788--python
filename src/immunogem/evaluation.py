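"""Validation experiments: solver-vs-oracle agreement, statistical
calibration, planted-signal recovery, and end-to-end direction checks.

Each function runs one self-contained experiment from scratch under a seed
and returns plain numbers.  The brute-force routines here (subset
enumeration with LP feasibility, hypergeometric tail enumeration) are
deliberately independent of the production code paths they validate.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import differential as diff
from . import synthetic_data as syn
from .gem_context import ReactionScore, init_extract
from .model_core import (
    MetabolicModel,
    Metabolite,
    make_reaction,
    split_reversible,
)
from .pathway_ora import PathwaySet, hypergeom_ora
from .pipeline import RunConfig, run_pipeline
from .reporter_mets import GeneStat, gene_zscores, reporter_scores


# ---------------------------------------------------------------------------
# brute-force references
# ---------------------------------------------------------------------------

def _subset_feasible(S, ub, cols, eps):
    if not cols:
        return True
    Ssub = S[:, cols]
    touched = np.abs(Ssub).sum(axis=1) > 0
    if np.any(touched & ~((Ssub > 0).any(axis=1) & (Ssub < 0).any(axis=1))):
        return False
    res = linprog(np.zeros(len(cols)), A_eq=Ssub, b_eq=np.zeros(S.shape[0]),
                  bounds=[(eps, ub[j]) for j in cols], method="highs")
    return res.status == 0


def best_subnetwork_bruteforce(model: MetabolicModel, weights: dict,
                               eps: float = 1e-3) -> float:
    """Maximum total weight over all feasible subnetworks, by enumeration."""
    S = model.stoichiometric_matrix()
    _, ub = model.bounds_arrays()
    n = len(model.reactions)
    w = np.array([weights[r.id] for r in model.reactions])
    best = 0.0
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            gain = w[list(subset)].sum()
            if gain <= best:
                continue
            if _subset_feasible(S, ub, list(subset), eps):
                best = gain
    return best


def hypergeom_tail_enumeration(N, K, n, k) -> float:
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def milp_oracle_agreement(n_networks: int = 25, seed: int = 0):
    """INIT MILP vs exhaustive enumeration on random small networks.

    Returns (fraction of networks with matching optimum, max |difference|).
    """
    rng = np.random.default_rng(seed)
    agree, worst = 0, 0.0
    for trial in range(n_networks):
        n_rxn = int(rng.integers(6, 13))
        model = syn.random_network(n_reactions=n_rxn,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        weights = {r.id: float(rng.uniform(-5, 5)) for r in model.reactions}
        scores = [ReactionScore(r.id, 1.0, weights[r.id])
                  for r in model.reactions]
        ctx = init_extract(split_reversible(model), scores)
        oracle = best_subnetwork_bruteforce(model, weights)
        delta = abs(ctx.objective - oracle)
        worst = max(worst, delta)
        agree += delta <= 1e-9
    return agree / n_networks, worst


def reporter_recovery_rate(n_replicates: int = 50, seed: int = 0,
                           n_null_genes: int = 200,
                           p_planted: float = 0.001) -> float:
    """Fraction of replicates in which GlcCer, GalCer and LacCer all rank in
    the top-5 up-reporters when their synthase genes are planted
    up-regulated among null genes."""
    model = syn.build_toy_sphingolipid_model()
    planted = ("UGCG", "UGT8", "B4GALT5")
    hits = 0
    rng = np.random.default_rng(seed)
    for rep in range(n_replicates):
        stats = [GeneStat(g, p_planted, +1) for g in planted]
        others = sorted(set(model.genes) - set(planted))
        names = others + [f"NULL{i}" for i in range(n_null_genes - len(others))]
        stats += [GeneStat(g, float(rng.uniform(0, 1)), int(rng.choice([-1, 1])))
                  for g in names]
        z = gene_zscores(stats, mode="up")
        results = reporter_scores(model, z, n_background=10000,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  mode="up")
        top5 = {r.metabolite.split("[")[0] for r in results[:5]}
        hits += {"GlcCer", "GalCer", "LacCer"} <= top5
    return hits / n_replicates


def _null_reporter_network(n_metabolites: int, genes_per_reaction: int,
                           n_genes: int, rng) -> MetabolicModel:
    """A long conversion chain whose reactions carry random GPRs."""
    mets = [Metabolite(f"m{i}", f"m{i}", "c") for i in range(n_metabolites)]
    rxns = []
    for i in range(n_metabolites - 1):
        picked = rng.choice(n_genes, size=genes_per_reaction, replace=False)
        rule = " or ".join(f"g{j}" for j in picked)
        rxns.append(make_reaction(f"r{i}", {f"m{i}": -1, f"m{i + 1}": 1},
                                  ub=100, gpr=rule))
    return MetabolicModel(id="nullnet", metabolites=mets, reactions=rxns)


def reporter_null_fpr(n_metabolites: int = 2000, seed: int = 0) -> float:
    """Reporter false-positive rate under uniform gene p-values."""
    rng = np.random.default_rng(seed)
    n_genes = 1000
    model = _null_reporter_network(n_metabolites, 2, n_genes, rng)
    stats = [GeneStat(f"g{j}", float(rng.uniform(0, 1)), 1)
             for j in range(n_genes)]
    z = gene_zscores(stats, mode="combined")
    results = reporter_scores(model, z, n_background=10000, seed=seed + 1)
    ps = np.array([r.p for r in results])
    return float((ps < 0.05).mean())


def ora_exactness(max_universe: int = 25) -> float:
    """Max |ORA p − enumeration| over all instances with N <= max_universe."""
    worst = 0.0
    for N in range(5, max_universe + 1, 5):
        universe = [f"m{i}" for i in range(N)]
        for K in (2, N // 3, N // 2):
            for n in (2, N // 3, N // 2):
                for k in range(0, min(K, n) + 1):
                    pw = PathwaySet(name="pw", members=frozenset(universe[:K]))
                    hits = universe[:k] + universe[K:K + (n - k)]
                    (res,) = hypergeom_ora(hits, [pw], universe)
                    oracle = hypergeom_tail_enumeration(N, K, n, k)
                    worst = max(worst, abs(res.p - oracle))
    return worst


def type1_error(n_features: int = 2000, seed: int = 0) -> float:
    """Fraction of null features with p < 0.05 in a PT1D-vs-CTRL contrast on
    effect-free synthetic data (cohort-sized groups)."""
    features = pd.DataFrame({
        "feature": [f"null_{i}" for i in range(n_features)],
        "class": "null", "kind": "lipid"})
    design = syn.CohortDesign(seed=seed, missingness_rate=0.0)
    values, smeta, *_ = syn.simulate_metabolomics(
        design, effects=[], seed=seed, features=features)
    res = diff.two_sample_contrast(diff.log2_normalize(values), smeta,
                                   "PT1D", "CTRL", age_bin=24)
    return float((res.table["p"] < 0.05).mean())


def log2fc_bias(n_per_group: int = 30, n_replicates: int = 200,
                effect: float = -0.8, sd: float = 0.5, seed: int = 0) -> float:
    """Mean (estimate − truth) of the log2 fold-change estimator."""
    features = pd.DataFrame({
        "feature": [f"f{i}" for i in range(n_replicates)],
        "class": "x", "kind": "lipid"})
    effects = [syn.PlantedEffect(f, "PT1D", None, effect)
               for f in features["feature"]]
    design = syn.CohortDesign(
        group_sizes={"CTRL": n_per_group, "P1Ab": 2, "PT1D": n_per_group},
        missingness_rate=0.0, seed=seed)
    values, smeta, *_ = syn.simulate_metabolomics(
        design, effects=effects, noise_sd=sd, subject_sd=0.0,
        seed=seed, features=features)
    res = diff.two_sample_contrast(diff.log2_normalize(values), smeta,
                                   "PT1D", "CTRL", age_bin=24)
    return float((res.table["log2fc"] - effect).mean())


def vip_identity_max_deviation(n_fits: int = 10, seed: int = 0) -> float:
    """Max |ΣVIP² − p| over random sparse PLS-DA fits."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fits):
        n, p = int(rng.integers(20, 80)), int(rng.integers(10, 60))
        X = pd.DataFrame(rng.normal(0, 1, (n, p)))
        y = np.array([0, 1] * (n // 2) + [0] * (n % 2))
        model = diff.plsda_fit(X, y, n_components=2,
                               keep_per_component=min(20, p))
        vip = diff.vip_scores(model)
        worst = max(worst, abs(float((vip ** 2).sum()) - p))
    return worst


def null_cv_auc(n: int = 200, p: int = 30, seed: int = 0) -> float:
    """Cross-validated AUC with labels independent of the data."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(0, 1, (n, p)))
    y = rng.integers(0, 2, n)
    return diff.cv_auc(X, y, repeats=10, seed=seed)


def fba_reference_checks() -> dict:
    """Chain bottleneck, closed-model zero, and the mass-balance residual."""
    from dataclasses import replace

    from .flux_analysis import fba, mass_balance_residual

    mets = [Metabolite("a", "A", "c"), Metabolite("b", "B", "c")]
    chain = MetabolicModel(id="chain", metabolites=mets, reactions=[
        make_reaction("up_a", {"a": 1}, ub=10),
        make_reaction("conv", {"a": -1, "b": 1}, ub=1000),
        make_reaction("sink_b", {"b": -1}, ub=1000),
    ])
    chain_state = fba(chain, "sink_b")

    toy = syn.build_toy_sphingolipid_model()
    closed = MetabolicModel(
        id="closed", metabolites=toy.metabolites,
        reactions=[replace(r, lb=0.0, ub=0.0) if r.id.startswith("EX_") else r
                   for r in toy.reactions])
    toy_state = fba(toy, "DM_glccer_c")
    return {
        "chain_optimum": chain_state.objective_value,
        "closed_optimum": fba(closed, "DM_glccer_c").objective_value,
        "toy_glccer_optimum": toy_state.objective_value,
        "mass_balance_residual": max(
            mass_balance_residual(chain, chain_state),
            mass_balance_residual(toy, toy_state)),
    }


def end_to_end_run_matches(rundir: Path) -> dict:
    """Direction checks for one finished pipeline run."""
    flux = pd.read_csv(rundir / "glycoceramide_flux.tsv", sep="\t")
    glc = flux[flux["objective"] == "DM_glccer_c"].set_index("group")["optimum"]
    t36 = pd.read_csv(rundir / "contrast_PT1D_vs_P1Ab_36m.tsv",
                      sep="\t", index_col=0)
    hex_ok = all(t36.loc[f, "p"] < 0.05 and t36.loc[f, "log2fc"] > 0
                 for f in syn.HEXCER_FEATURES)
    cer_rows = [pd.read_csv(rundir / f"contrast_PT1D_vs_CTRL_{a}m.tsv",
                            sep="\t", index_col=0).loc[syn.CERAMIDE_FEATURE]
                for a in (12, 24, 36)]
    cer_ok = (all(r["log2fc"] < 0 for r in cer_rows)
              and any(r["p"] < 0.05 for r in cer_rows))
    rep = pd.read_csv(rundir / "reporters_PT1D_vs_P1Ab_up.tsv", sep="\t")
    top5 = {m.split("[")[0] for m in rep["metabolite"].head(5)}
    return {
        "ceramide_down": cer_ok,
        "hexcer_up_36m": hex_ok,
        "flux_pt1d_gt_ctrl": bool(glc["PT1D"] > glc["CTRL"]),
        "reporters_recovered": {"GlcCer", "GalCer", "LacCer"} <= top5,
        "pt1d_glccer_flux": float(glc["PT1D"]),
        "ctrl_glccer_flux": float(glc["CTRL"]),
    }


def end_to_end_match_rate(n_runs: int = 20, seed: int = 0,
                          workdir: str | Path = "scratch/e2e") -> dict:
    """Fraction of seeded pipeline runs reproducing the full direction
    pattern (ceramide down, hexosylceramides up at 36 months, progressor
    glucosylceramide flux above control)."""
    workdir = Path(workdir)
    hits = 0
    flux_ratio_runs = []
    for i in range(n_runs):
        run_seed = (seed * 1009 + i) % (2**31 - 1)
        rundir = run_pipeline(RunConfig(outdir=str(workdir / f"run{i}"),
                                        seed=run_seed))
        checks = end_to_end_run_matches(rundir)
        hits += (checks["ceramide_down"] and checks["hexcer_up_36m"]
                 and checks["flux_pt1d_gt_ctrl"])
        flux_ratio_runs.append((checks["pt1d_glccer_flux"],
                                checks["ctrl_glccer_flux"]))
    return {"match_rate": hits / n_runs, "flux_pairs": flux_ratio_runs}


def determinism_check(seed: int = 0, workdir: str | Path = "scratch/det") -> bool:
    """Two identical config+seed runs produce bit-identical manifests."""
    workdir = Path(workdir)
    d = run_pipeline(RunConfig(outdir=str(workdir), seed=seed))
    first = (d / "manifest.json").read_bytes()
    d = run_pipeline(RunConfig(outdir=str(workdir), seed=seed))
    return (d / "manifest.json").read_bytes() == first
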