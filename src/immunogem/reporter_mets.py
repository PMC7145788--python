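"""Reporter-metabolite analysis.

Aggregates gene-level differential-expression significance onto the
metabolites of a stoichiometric network: each metabolite's score is the
normalised sum of the inverse-normal-transformed p-values of the genes in
its reaction neighborhood, corrected against a Monte-Carlo background of
equally sized random gene sets.  High-scoring ("reporter") metabolites mark
hot spots of transcriptional change in the network.  Directional variants
use one-sided p-values so up- and down-regulated reporters are scored
separately; compartment-specific metabolites are scored separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .model_core import DEFAULT_CURRENCY_METABOLITES, MetabolicModel, metabolite_gene_neighborhood

logger = logging.getLogger(__name__)

P_FLOOR = 1e-15  # keeps the normal quantile finite


@dataclass(frozen=True)
class GeneStat:
    gene: str
    p: float
    direction: int  # sign of log2FC

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ValueError(f"gene {self.gene}: p must lie in (0, 1], got {self.p}")


@dataclass
class ReporterResult:
    metabolite: str       # compartment-tagged, e.g. GlcCer[c]
    metabolite_id: str
    k: int
    z_raw: float
    z_corrected: float
    p: float
    fdr: float
    mode: str


def gene_zscores(gene_stats: list[GeneStat], mode: str = "combined") -> pd.Series:
    """Inverse-normal gene scores Z = Φ⁻¹(1 − p).

    ``combined`` uses the two-sided p directly.  Directional modes convert
    to a one-sided p in the requested direction first (p/2 on the matching
    side, 1 − p/2 on the other), so genes moving against the direction get
    negative Z.
    """
    if mode not in ("combined", "up", "down"):
        raise ValueError(f"unknown mode {mode!r}")
    z = {}
    for g in gene_stats:
        p = max(g.p, P_FLOOR)
        if p > 1:
            raise ValueError(f"gene {g.gene}: p > 1")
        if mode == "combined":
            p_eff = p
        else:
            towards = (g.direction >= 0) if mode == "up" else (g.direction <= 0)
            p_eff = p / 2 if towards else 1 - p / 2
        p_eff = min(max(p_eff, P_FLOOR), 1 - P_FLOOR)
        z[g.gene] = float(stats.norm.isf(p_eff))
    return pd.Series(z)


def reporter_scores(model: MetabolicModel, gene_z: pd.Series,
                    n_background: int = 10000, seed: int = 0,
                    mode: str = "combined",
                    currency_metabolites=DEFAULT_CURRENCY_METABOLITES
                    ) -> list[ReporterResult]:
    """Score every network metabolite as a reporter of transcriptional change.

    For a metabolite with neighborhood genes G (|G| = k, restricted to
    scored genes), z_raw = Σ_{g∈G} Z_g / √k.  The background mean and sd of
    the same statistic over ``n_background`` random size-k draws (with
    replacement) from the scored-gene pool give
    z_corrected = (z_raw − μ_k) / σ_k and p = 1 − Φ(z_corrected); BH FDR is
    applied across metabolites.  Metabolites with empty neighborhoods are
    skipped and logged.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    pool = gene_z.to_numpy(dtype=float)
    if pool.size == 0:
        raise ValueError("no scored genes")
    scored = set(gene_z.index)

    per_met: list[tuple[str, str, list[str]]] = []
    for m in model.metabolites:
        genes = metabolite_gene_neighborhood(model, m.id, currency_metabolites)
        genes = sorted(g for g in genes if g in scored)
        if not genes:
            logger.debug("metabolite %s has no scored neighborhood genes; skipped", m.id)
            continue
        per_met.append((m.id, m.tagged, genes))

    # Monte-Carlo background per distinct neighborhood size
    sizes = sorted({len(genes) for _, _, genes in per_met})
    background: dict[int, tuple[float, float]] = {}
    for k in sizes:
        draws = rng.choice(pool, size=(n_background, k), replace=True)
        agg = draws.sum(axis=1) / np.sqrt(k)
        background[k] = (float(agg.mean()), float(agg.std(ddof=1)))

    results = []
    for mid, tagged, genes in per_met:
        k = len(genes)
        z_raw = float(gene_z[genes].sum() / np.sqrt(k))
        mu, sd = background[k]
        if sd == 0:
            z_corr = 0.0
        else:
            z_corr = (z_raw - mu) / sd
        p = float(stats.norm.sf(z_corr))
        results.append(ReporterResult(metabolite=tagged, metabolite_id=mid,
                                      k=k, z_raw=z_raw, z_corrected=z_corr,
                                      p=p, fdr=np.nan, mode=mode))
    if results:
        q = bh_fdr([r.p for r in results])
        for r, qv in zip(results, q):
            r.fdr = float(qv)
    results.sort(key=lambda r: (-r.z_corrected, r.metabolite))
    return results


def reporters_from_deg(model: MetabolicModel, deg: pd.DataFrame,
                       mode: str = "up", n_background: int = 10000,
                       seed: int = 0) -> list[ReporterResult]:
    """Reporter metabolites straight from a DEG table (gene, log2fc, p)."""
    gene_stats = [GeneStat(g, max(float(row["p"]), P_FLOOR),
                           int(np.sign(row["log2fc"])))
                  for g, row in deg.iterrows()]
    gz = gene_zscores(gene_stats, mode=mode)
    return reporter_scores(model, gz, n_background=n_background,
                           seed=seed, mode=mode)


def reporter_table(results: list[ReporterResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"metabolite": r.metabolite, "metabolite_id": r.metabolite_id,
          "k": r.k, "z_raw": r.z_raw, "z_corrected": r.z_corrected,
          "p": r.p, "fdr": r.fdr, "mode": r.mode} for r in results]
    )
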