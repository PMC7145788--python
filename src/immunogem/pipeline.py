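"""End-to-end analysis pipeline: synthetic data (or files) through QC,
contrasts, pathway enrichment, reaction scoring, context extraction,
reporter metabolites and flux comparison.

Every stage is a pure function of the validated :class:`RunConfig` and the
preceding stages' in-memory results; outputs are written as TSV/SBML plus a
JSON manifest with SHA-256 hashes, so a rerun with the same config and seed
is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import flux_analysis as fa
from . import gem_context as gc
from . import pathway_ora as ora
from . import reporter_mets as rm
from . import synthetic_data as syn
from .model_core import split_reversible
from .sbml_io import read_sbml, write_sbml

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "contrast", "ora", "score", "extract",
          "reporters", "flux")

GROUP_PAIRS = (("P1Ab", "CTRL"), ("PT1D", "CTRL"), ("PT1D", "P1Ab"))

#: nutrients whose uptake stays open regardless of metabolite evidence
DEFAULT_MEDIA = ("glucose", "galactose", "serine", "palmitate", "PC")


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold and seed lives here."""

    outdir: str = "run"
    synthetic: bool = True
    seed: int = 0
    # input paths, used when synthetic is false
    metabolomics: str | None = None
    sample_meta: str | None = None
    feature_meta: str | None = None
    expression: str | None = None
    expression_meta: str | None = None
    model: str | None = None
    pathways_gmt: str | None = None
    pathway_edges: str | None = None
    feature_mapping: str | None = None
    # cohort / generator parameters
    group_sizes: dict = field(default_factory=lambda: {"CTRL": 10, "P1Ab": 27, "PT1D": 34})
    ages: tuple = (12, 24, 36)
    missingness_rate: float = 0.15
    # selection thresholds
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    vip_threshold: float = 1.0
    rc_threshold: float = 0.05
    auc_threshold: float = 0.65
    rho_threshold: float = 0.70
    # GEM parameters
    tau: float | None = None
    w_max: float = 5.0
    kappa: float = 20.0
    eps: float = 1e-3
    big_m: float = 1000.0
    b_max: float = 100.0
    default_uptake: float = 10.0
    # reporter parameters
    n_background: int = 10000
    # PLS-DA parameters
    n_components: int = 2
    keep_per_component: int = 20
    cv_repeats: int = 3

    @property
    def thresholds(self) -> dict:
        return {"p": self.p_threshold, "fdr": self.fdr_threshold,
                "vip": self.vip_threshold, "rc": self.rc_threshold,
                "auc": self.auc_threshold, "rho": self.rho_threshold}


PAPER_DEFAULTS = {"p_threshold": 0.05, "fdr_threshold": 0.05,
                  "vip_threshold": 1.0, "rc_threshold": 0.05,
                  "auc_threshold": 0.65, "rho_threshold": 0.70}


def validate_config(config: RunConfig) -> tuple[list[str], list[str]]:
    """Range/path checks.  Returns (errors, warnings); empty errors = ok."""
    errors, warns = [], []
    for name in ("p_threshold", "fdr_threshold"):
        v = getattr(config, name)
        if not (0 < v < 1):
            errors.append(f"{name} must be in (0,1), got {v}")
    for name in ("vip_threshold", "rc_threshold", "kappa", "eps", "big_m",
                 "b_max", "default_uptake", "w_max"):
        v = getattr(config, name)
        if v is not None and v < 0:
            errors.append(f"{name} must be non-negative, got {v}")
    if not (0 <= config.auc_threshold <= 1):
        errors.append(f"auc_threshold must be in [0,1], got {config.auc_threshold}")
    if not (0 <= config.rho_threshold <= 1):
        errors.append(f"rho_threshold must be in [0,1], got {config.rho_threshold}")
    if not (0 <= config.missingness_rate < 0.5):
        errors.append(f"missingness_rate must be in [0,0.5), got {config.missingness_rate}")
    if not config.synthetic:
        for name in ("metabolomics", "sample_meta", "expression",
                     "expression_meta", "model"):
            path = getattr(config, name)
            if path is None:
                errors.append(f"synthetic=false requires input path {name!r}")
            elif not Path(path).exists():
                errors.append(f"input path {name!r} does not exist: {path}")
    for name, default in PAPER_DEFAULTS.items():
        if not errors and getattr(config, name) != default:
            warns.append(f"{name}={getattr(config, name)} differs from the "
                         f"study default {default}")
    return errors, warns


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def evidence_features_for_group(group: str,
                                contrasts: dict[str, diff.ContrastResult],
                                fdr_threshold: float = 0.05
                                ) -> dict[str, set]:
    """Features elevated in ``group`` in any pairwise contrast, with support.

    A feature counts when it is significant at the given FDR and its fold
    change points toward the group.  Returns feature -> set of age bins at
    which it was supported.  The FDR gate (rather than the raw-p selection
    used for reporting) keeps spurious single-test hits from flooding the
    evidence call.
    """
    out: dict[str, set] = {}
    for res in contrasts.values():
        a, rest = res.name.split("_vs_")
        parts = rest.split("_")
        b = parts[0]
        age = parts[1] if len(parts) > 1 else ""
        t = res.table
        sig = t["q"] < fdr_threshold
        if group == a:
            feats = t.index[sig & (t["log2fc"] > 0)]
        elif group == b:
            feats = t.index[sig & (t["log2fc"] < 0)]
        else:
            continue
        for f in feats:
            out.setdefault(f, set()).add(age)
    return out


def corroborated_evidence(model, support: dict[str, set],
                          mapping: dict[str, list[str]]) -> list:
    """Metabolite presence calls requiring corroboration.

    A metabolite is marked present only when backed by at least two
    distinct supporting features, or by one feature supported at two or
    more ages.  A single feature significant in a single comparison is not
    enough: at FDR 0.05 the discovery lists contain ~5% false features,
    and one such hit would otherwise open a whole pathway branch through
    the evidence bonus of the extraction MILP.
    """
    feats_of: dict[str, set] = {}
    ages_of: dict[str, set] = {}
    for feat, ages in support.items():
        for mid in mapping.get(feat, []):
            feats_of.setdefault(mid, set()).add(feat)
            ages_of.setdefault(mid, set()).update(ages)
    present = {mid for mid in feats_of
               if len(feats_of[mid]) >= 2 or len(ages_of[mid]) >= 2}
    return [gc.MetaboliteEvidence(mid, mid in present)
            for mid in model.metabolite_ids]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, upto: str | None = None) -> Path:
    """Run all stages (or through ``upto``) and return the run directory."""
    errors, warns = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    for w in warns:
        logger.warning("config: %s", w)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stages": []}
    last = upto or STAGES[-1]
    if last not in STAGES:
        raise ValueError(f"unknown stage {last!r}")
    n_stages = STAGES.index(last) + 1

    def record(stage: str, params: dict, outputs: dict[str, Path]):
        manifest["stages"].append({
            "stage": stage,
            "parameters": params,
            "outputs": {k: {"path": str(p.relative_to(outdir)),
                            "sha256": _sha256(p)} for k, p in outputs.items()},
        })

    # ---- stage 1: simulate / ingest -----------------------------------
    datadir = outdir / "data"
    if config.synthetic:
        design = syn.CohortDesign(group_sizes=dict(config.group_sizes),
                                  ages=tuple(config.ages),
                                  missingness_rate=config.missingness_rate,
                                  seed=config.seed)
        paths = syn.write_cohort(datadir, design=design, seed=config.seed)
    else:
        paths = {k: Path(getattr(config, k)) for k in
                 ("metabolomics", "sample_meta", "feature_meta", "expression",
                  "expression_meta", "model", "pathways_gmt", "pathway_edges",
                  "feature_mapping")
                 if getattr(config, k)}
    values = pd.read_csv(paths["metabolomics"], sep="\t", index_col=0)
    sample_meta = pd.read_csv(paths["sample_meta"], sep="\t", index_col=0)
    feature_meta = pd.read_csv(paths["feature_meta"], sep="\t", index_col=0)
    expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    expression_meta = pd.read_csv(paths["expression_meta"], sep="\t", index_col=0)
    model = read_sbml(paths["model"])
    gmt = ora.read_gmt(paths["pathways_gmt"]) if "pathways_gmt" in paths else {}
    edges = (ora.read_pathway_edges(paths["pathway_edges"])
             if "pathway_edges" in paths else {})
    if "feature_mapping" in paths:
        mdf = pd.read_csv(paths["feature_mapping"], sep="\t")
        mapping: dict[str, list[str]] = {}
        for _, row in mdf.iterrows():
            mapping.setdefault(row["feature"], []).append(row["metabolite"])
    else:
        mapping = {}
    record("simulate", {"synthetic": config.synthetic, "seed": config.seed},
           {k: Path(p) for k, p in paths.items() if Path(p).is_relative_to(outdir)})
    if n_stages == 1:
        return _finish(outdir, manifest)

    # ---- stage 2: qc ---------------------------------------------------
    log2 = diff.log2_normalize(values)
    bins = diff.assign_age_bins(sample_meta, target_ages=config.ages)
    outliers = diff.pca_outlier_check(log2)
    ev = diff.variance_explained(log2, sample_meta)
    qc_out = {
        "age_bins": _write(bins.rename("bin").to_frame(), outdir / "age_bins.tsv"),
        "explained_variation": _write(ev, outdir / "explained_variation.tsv"),
        "ev_summary": _write(diff.ev_summary(ev).rename("median_ev_pct").to_frame(),
                             outdir / "ev_summary.tsv"),
        "pca_outliers": _write(pd.DataFrame({"sample": outliers}),
                               outdir / "pca_outliers.tsv", index=False),
    }
    record("qc", {"n_outliers": len(outliers)}, qc_out)
    if n_stages == 2:
        return _finish(outdir, manifest)

    # ---- stage 3: contrasts -------------------------------------------
    contrasts: dict[str, diff.ContrastResult] = {}
    contrast_out = {}
    for a, b in GROUP_PAIRS:
        for age in config.ages:
            res = diff.full_contrast(
                log2, sample_meta, a, b, age_bin=age, bins=bins,
                thresholds=config.thresholds,
                n_components=config.n_components,
                keep_per_component=config.keep_per_component,
                cv_repeats=config.cv_repeats, seed=config.seed)
            contrasts[res.name] = res
            contrast_out[res.name] = _write(res.table, outdir / f"contrast_{res.name}.tsv")
    paired = {}
    for group in ("P1Ab", "PT1D"):
        pres = diff.paired_seroconversion_contrast(log2, sample_meta, group)
        paired[pres.name] = pres
        contrast_out[pres.name] = _write(pres.table, outdir / f"contrast_{pres.name}.tsv")
    anova_rows = [{"age": age, **dict(zip(("F", "p"),
                   diff.group_totals_anova(log2, sample_meta, age, bins=bins)))}
                  for age in config.ages]
    contrast_out["totals_anova"] = _write(pd.DataFrame(anova_rows),
                                          outdir / "totals_anova.tsv", index=False)
    record("contrast", {"pairs": [f"{a}_vs_{b}" for a, b in GROUP_PAIRS],
                        "ages": list(config.ages)}, contrast_out)
    if n_stages == 3:
        return _finish(outdir, manifest)

    # ---- stage 4: pathway over-representation -------------------------
    pathways = ora.build_pathway_sets(gmt, edges)
    universe = list(values.columns)
    ora_out = {}
    for name, res in contrasts.items():
        hits = list(res.table.index[res.table["selected_uni"]])
        results = ora.hypergeom_ora(hits, pathways, universe,
                                    fdr_threshold=config.fdr_threshold)
        ora_out[name] = _write(ora.ora_table(results),
                               outdir / f"ora_{name}.tsv", index=False)
    record("ora", {"n_pathways": len(pathways)}, ora_out)
    if n_stages == 4:
        return _finish(outdir, manifest)

    # ---- stage 5: reaction scoring + DEG ------------------------------
    groups = sorted(expression_meta["group"].unique())
    group_means = {g: expression.loc[:, expression_meta.index[expression_meta["group"] == g]].mean(axis=1)
                   for g in groups}
    tau = config.tau
    if tau is None:
        tau = float(np.median(np.concatenate([m.to_numpy() for m in group_means.values()])))
    scores = {g: gc.score_reactions(model, group_means[g], tau=tau,
                                    w_max=config.w_max) for g in groups}
    score_out = {g: _write(gc.score_table(s), outdir / f"reaction_scores_{g}.tsv",
                           index=False) for g, s in scores.items()}
    log2expr = diff.log2_normalize(expression.T)
    degs = {}
    for a, b in GROUP_PAIRS:
        res = diff.two_sample_contrast(log2expr, expression_meta, a, b)
        degs[f"{a}_vs_{b}"] = res.table
        score_out[f"deg_{a}_vs_{b}"] = _write(res.table, outdir / f"deg_{a}_vs_{b}.tsv")
    record("score", {"tau": tau, "w_max": config.w_max}, score_out)
    if n_stages == 5:
        return _finish(outdir, manifest)

    # ---- stage 6: context extraction ----------------------------------
    context_models = {}
    extract_out = {}
    inclusion_rows = []
    for g in groups:
        support = evidence_features_for_group(g, contrasts,
                                              config.fdr_threshold)
        evidence = corroborated_evidence(model, support, mapping)
        constrained = gc.exchange_bounds_from_metabolomics(
            model, evidence, media_whitelist=DEFAULT_MEDIA,
            default_uptake=config.default_uptake)
        split = split_reversible(constrained)
        ctx = gc.init_extract(split, scores[g], evidence, eps=config.eps,
                              big_m=config.big_m, kappa=config.kappa,
                              b_max=config.b_max)
        context_models[g] = ctx.model
        sbml_path = outdir / f"context_{g}.xml"
        write_sbml(ctx.model, sbml_path)
        extract_out[f"model_{g}"] = sbml_path
        for rid in split.model.reaction_ids:
            inclusion_rows.append({"group": g, "reaction": rid,
                                   "included": ctx.y[rid]})
    extract_out["inclusion"] = _write(pd.DataFrame(inclusion_rows),
                                      outdir / "inclusion.tsv", index=False)
    record("extract", {"kappa": config.kappa, "eps": config.eps,
                       "b_max": config.b_max}, extract_out)
    if n_stages == 6:
        return _finish(outdir, manifest)

    # ---- stage 7: reporter metabolites --------------------------------
    reporter_out = {}
    for key in ("PT1D_vs_P1Ab", "PT1D_vs_CTRL"):
        for mode in ("up", "down"):
            results = rm.reporters_from_deg(model, degs[key], mode=mode,
                                            n_background=config.n_background,
                                            seed=config.seed)
            reporter_out[f"{key}_{mode}"] = _write(
                rm.reporter_table(results),
                outdir / f"reporters_{key}_{mode}.tsv", index=False)
    record("reporters", {"n_background": config.n_background}, reporter_out)
    if n_stages == 7:
        return _finish(outdir, manifest)

    # ---- stage 8: flux comparison -------------------------------------
    flux_df = fa.optimize_glycoceramide_production(context_models, template=model)
    flux_out = {"glycoceramide_flux": _write(flux_df, outdir / "glycoceramide_flux.tsv",
                                             index=False)}
    states = {}
    for g, cm in context_models.items():
        aug = fa.with_demand(cm, model, syn.GLCCER_DEMAND)
        if aug is not None:
            states[g] = fa.fba(aug, syn.GLCCER_DEMAND, "max")
    if "PT1D" in states and "CTRL" in states:
        # split template carries subsystem labels for every split-space id
        label_model = split_reversible(model).model
        deltas = fa.subsystem_flux_deltas(states["CTRL"], states["PT1D"],
                                          label_model)
        flux_out["subsystem_deltas"] = _write(deltas, outdir / "subsystem_deltas.tsv",
                                              index=False)
    if states:
        flux_out["fluxes"] = _write(fa.flux_table(states, model),
                                    outdir / "fluxes.tsv", index=False)
    record("flux", {"objectives": ["DM_glccer_c", "DM_digalcer_g"]}, flux_out)
    return _finish(outdir, manifest)


def _finish(outdir: Path, manifest: dict) -> Path:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
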