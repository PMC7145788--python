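"""Synthetic study materials: toy sphingolipid network and simulated cohort omics.

This module generates, with planted ground truth, everything the analysis
pipeline consumes:

* a small flux-consistent genome-scale model of human sphingolipid
  metabolism (de novo ceramide synthesis in the ER, sphingomyelin cycling
  through the Golgi and lysosome, glyco­ceramide branches, the
  sphingosine-1-phosphate exit route), with one distinct gene per enzyme;
* a longitudinal PBMC metabolomics cohort — three clinical groups (CTRL,
  autoantibody-positive non-progressors P1Ab, progressors PT1D) sampled at
  12/24/36 months of age — with named planted effects: a long-chain
  ceramide persistently decreased in progressors, two hexosylceramides
  increased in progressors at 36 months, and a broad early decrease of
  lipids in seroconverters;
* a gene-expression matrix over the network's genes (plus decoys) with the
  glycoceramide-synthesis program up-regulated in progressors;
* toy pathway definitions (GMT sets plus intra-pathway adjacency) and a
  feature-to-model-metabolite mapping table.

All generators are bit-reproducible under a fixed seed, and every planted
effect is returned in a registry so downstream stages can be scored for
recovery without re-reading generator code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, Metabolite, make_reaction

GROUPS = ("CTRL", "P1Ab", "PT1D")

# enzyme gene symbols of the toy network (one per catalytic step)
GENE_SPT = "SPTLC1"      # serine palmitoyltransferase
GENE_KSR = "KDSR"        # 3-ketodihydrosphingosine reductase
GENE_CERS = "CERS2"      # ceramide synthase
GENE_DES = "DEGS1"       # dihydroceramide desaturase
GENE_SMS = "SGMS1"       # sphingomyelin synthase
GENE_SMASE = "SMPD1"     # sphingomyelinase
GENE_GCS = "UGCG"        # glucosylceramide synthase
GENE_GCDASE = "GBA1"     # glucosylceramidase
GENE_GALCS = "UGT8"      # galactosylceramide synthase
GENE_GALCDASE = "GALC"   # galactosylceramidase
GENE_LACCERS = "B4GALT5" # lactosylceramide synthase
GENE_DIGALCERS = "A4GALT"  # digalactosylceramide synthase
GENE_CDASE = "ASAH1"     # ceramidase
GENE_SK = "SPHK1"        # sphingosine kinase
GENE_S1PL = "SGPL1"      # sphingosine-1-phosphate lyase
GENE_CK = "CERK"         # ceramide kinase
GENE_C1PP = "PLPP1"      # ceramide-1-phosphate phosphatase

#: genes whose PT1D up-regulation is planted by default: the glycoceramide
#: synthesis program (glucosyl-, galactosyl-, lactosyl- and
#: digalactosylceramide synthases)
GLYCO_SYNTHASE_GENES = (GENE_GCS, GENE_GALCS, GENE_LACCERS, GENE_DIGALCERS)

#: the whole glycoceramide branch (synthases plus the catabolic
#: glycosidases); at baseline the branch sits just below the median gene
#: signal, so reaction scoring marks it absent outside PT1D
GLYCO_BRANCH_GENES = GLYCO_SYNTHASE_GENES + (GENE_GCDASE, GENE_GALCDASE)

GLCCER_DEMAND = "DM_glccer_c"
DIGALCER_DEMAND = "DM_digalcer_g"


class GenerationError(RuntimeError):
    """Raised when a requested synthetic configuration is infeasible."""


# ---------------------------------------------------------------------------
# Toy sphingolipid network
# ---------------------------------------------------------------------------

def build_toy_sphingolipid_model(uptake_bound: float = 10.0,
                                 max_flux: float = 1000.0) -> MetabolicModel:
    """Build the toy sphingolipid metabolic network.

    Unit stoichiometries throughout; compartments c/g/r/l/e; exchange
    reactions allow uptake of serine, palmitate, glucose, galactose and a
    phosphatidylcholine head-group donor up to ``uptake_bound``.  Demand
    reactions drain sphingomyelin, the glycoceramides and the
    sphingosine-1-phosphate breakdown products, so the model is
    flux-consistent by construction.
    """
    if uptake_bound <= 0 or max_flux <= 0:
        raise GenerationError("uptake_bound and max_flux must be positive")

    M = Metabolite
    mets = [
        # extracellular
        M("ser_e", "serine", "e"), M("palm_e", "palmitate", "e"),
        M("glc_e", "glucose", "e"), M("gal_e", "galactose", "e"),
        M("pc_e", "PC", "e"),
        # cytosol
        M("ser_c", "serine", "c"), M("palm_c", "palmitate", "c"),
        M("glc_c", "glucose", "c"), M("gal_c", "galactose", "c"),
        M("pc_c", "PC", "c"), M("cer_c", "Cer", "c"),
        M("glccer_c", "GlcCer", "c"), M("sph_c", "sphingosine", "c"),
        M("s1p_c", "S1P", "c"), M("c1p_c", "C1P", "c"),
        # endoplasmic reticulum
        M("ser_r", "serine", "r"), M("palm_r", "palmitate", "r"),
        M("kdhsph_r", "3-ketodihydrosphingosine", "r"),
        M("sphga_r", "sphinganine", "r"), M("dhcer_r", "dihydroceramide", "r"),
        M("cer_r", "Cer", "r"), M("gal_r", "galactose", "r"),
        M("galcer_r", "GalCer", "r"), M("s1p_r", "S1P", "r"),
        M("hexdec_r", "hexadecenal", "r"), M("etnp_r", "ethanolamine-phosphate", "r"),
        # Golgi
        M("cer_g", "Cer", "g"), M("pc_g", "PC", "g"), M("sm_g", "SM", "g"),
        M("dag_g", "DAG", "g"), M("glccer_g", "GlcCer", "g"),
        M("laccer_g", "LacCer", "g"), M("gal_g", "galactose", "g"),
        M("galcer_g", "GalCer", "g"), M("digalcer_g", "DigalCer", "g"),
        # lysosome
        M("sm_l", "SM", "l"), M("cer_l", "Cer", "l"),
        M("galcer_l", "GalCer", "l"), M("sph_l", "sphingosine", "l"),
    ]

    R = make_reaction
    U, F = uptake_bound, max_flux
    EXCH, TRANS = "Exchange", "Transport"
    DENOVO = "De novo ceramide synthesis"
    SMM = "Sphingomyelin metabolism"
    GLYCO = "Glycosphingolipid metabolism"
    SPH = "Sphingosine metabolism"
    DEMAND = "Demand"

    rxns = [
        # exchanges (reversible: uptake up to U, free secretion)
        R("EX_ser_e", {"ser_e": -1}, lb=-U, ub=F, subsystem=EXCH),
        R("EX_palm_e", {"palm_e": -1}, lb=-U, ub=F, subsystem=EXCH),
        R("EX_glc_e", {"glc_e": -1}, lb=-U, ub=F, subsystem=EXCH),
        R("EX_gal_e", {"gal_e": -1}, lb=-U, ub=F, subsystem=EXCH),
        R("EX_pc_e", {"pc_e": -1}, lb=-U, ub=F, subsystem=EXCH),
        # plasma-membrane uptake
        R("SERt", {"ser_e": -1, "ser_c": 1}, ub=F, subsystem=TRANS),
        R("PALMt", {"palm_e": -1, "palm_c": 1}, ub=F, subsystem=TRANS),
        R("GLCt", {"glc_e": -1, "glc_c": 1}, ub=F, subsystem=TRANS),
        R("GALt", {"gal_e": -1, "gal_c": 1}, ub=F, subsystem=TRANS),
        R("PCt", {"pc_e": -1, "pc_c": 1}, ub=F, subsystem=TRANS),
        # cytosol <-> ER
        R("SERtr", {"ser_c": -1, "ser_r": 1}, ub=F, subsystem=TRANS),
        R("PALMtr", {"palm_c": -1, "palm_r": 1}, ub=F, subsystem=TRANS),
        R("GALtr", {"gal_c": -1, "gal_r": 1}, ub=F, subsystem=TRANS),
        R("CERtrc", {"cer_r": -1, "cer_c": 1}, lb=-F, ub=F, subsystem=TRANS),
        R("S1Ptr", {"s1p_c": -1, "s1p_r": 1}, ub=F, subsystem=TRANS),
        # cytosol -> Golgi
        R("CERtcg", {"cer_c": -1, "cer_g": 1}, ub=F, gpr="CERT1", subsystem=TRANS),
        R("PCtcg", {"pc_c": -1, "pc_g": 1}, ub=F, subsystem=TRANS),
        R("GLCCERtcg", {"glccer_c": -1, "glccer_g": 1}, ub=F, subsystem=TRANS),
        R("GALtcg", {"gal_c": -1, "gal_g": 1}, ub=F, subsystem=TRANS),
        # ER -> Golgi / lysosome, Golgi -> lysosome, lysosome -> cytosol
        R("GALCERtrg", {"galcer_r": -1, "galcer_g": 1}, ub=F, subsystem=TRANS),
        R("GALCERtrl", {"galcer_r": -1, "galcer_l": 1}, ub=F, subsystem=TRANS),
        R("SMtgl", {"sm_g": -1, "sm_l": 1}, ub=F, subsystem=TRANS),
        R("CERtlc", {"cer_l": -1, "cer_c": 1}, ub=F, subsystem=TRANS),
        R("SPHtlc", {"sph_l": -1, "sph_c": 1}, ub=F, subsystem=TRANS),
        # de novo synthesis (ER)
        R("SPT", {"ser_r": -1, "palm_r": -1, "kdhsph_r": 1}, ub=F,
          gpr=GENE_SPT, subsystem=DENOVO, name="serine palmitoyltransferase"),
        R("KSR", {"kdhsph_r": -1, "sphga_r": 1}, ub=F,
          gpr=GENE_KSR, subsystem=DENOVO, name="3-ketodihydrosphingosine reductase"),
        R("CERS", {"sphga_r": -1, "palm_r": -1, "dhcer_r": 1}, ub=F,
          gpr=GENE_CERS, subsystem=DENOVO, name="ceramide synthase"),
        R("DES", {"dhcer_r": -1, "cer_r": 1}, ub=F,
          gpr=GENE_DES, subsystem=DENOVO, name="dihydroceramide desaturase"),
        # sphingomyelin cycle
        R("SMS", {"cer_g": -1, "pc_g": -1, "sm_g": 1, "dag_g": 1}, ub=F,
          gpr=GENE_SMS, subsystem=SMM, name="sphingomyelin synthase"),
        R("SMASE", {"sm_l": -1, "cer_l": 1}, ub=F,
          gpr=GENE_SMASE, subsystem=SMM, name="sphingomyelinase"),
        # glycosphingolipid branches
        R("GCS", {"cer_c": -1, "glc_c": -1, "glccer_c": 1}, ub=F,
          gpr=GENE_GCS, subsystem=GLYCO, name="glucosylceramide synthase"),
        R("GCDASE", {"glccer_c": -1, "cer_c": 1}, ub=F,
          gpr=GENE_GCDASE, subsystem=GLYCO, name="glucosylceramidase"),
        R("GALCS", {"cer_r": -1, "gal_r": -1, "galcer_r": 1}, ub=F,
          gpr=GENE_GALCS, subsystem=GLYCO, name="galactosylceramide synthase"),
        R("GALCDASE", {"galcer_l": -1, "cer_l": 1}, ub=F,
          gpr=GENE_GALCDASE, subsystem=GLYCO, name="galactosylceramidase"),
        R("LACCERS", {"glccer_g": -1, "gal_g": -1, "laccer_g": 1}, ub=F,
          gpr=GENE_LACCERS, subsystem=GLYCO, name="lactosylceramide synthase"),
        R("DIGALCERS", {"galcer_g": -1, "gal_g": -1, "digalcer_g": 1}, ub=F,
          gpr=GENE_DIGALCERS, subsystem=GLYCO, name="digalactosylceramide synthase"),
        # sphingosine exit route and C1P cycle
        R("CDASE", {"cer_l": -1, "sph_l": 1}, ub=F,
          gpr=GENE_CDASE, subsystem=SPH, name="ceramidase"),
        R("SK", {"sph_c": -1, "s1p_c": 1}, ub=F,
          gpr=GENE_SK, subsystem=SPH, name="sphingosine kinase"),
        R("S1PL", {"s1p_r": -1, "hexdec_r": 1, "etnp_r": 1}, ub=F,
          gpr=GENE_S1PL, subsystem=SPH, name="sphingosine-1-phosphate lyase"),
        R("CK", {"cer_c": -1, "c1p_c": 1}, ub=F,
          gpr=GENE_CK, subsystem=SPH, name="ceramide kinase"),
        R("C1PP", {"c1p_c": -1, "cer_c": 1}, ub=F,
          gpr=GENE_C1PP, subsystem=SPH, name="ceramide-1-phosphate phosphatase"),
        # demands; the ceramide sink stands for the many consumers of
        # cytosolic ceramide outside this pathway's scope -- without it,
        # any profitable de novo chain would be forced to drain through a
        # glycoceramide branch regardless of that branch's own evidence
        R("DM_cer_c", {"cer_c": -1}, ub=F, subsystem=DEMAND,
          name="ceramide utilization sink"),
        R("DM_sm_g", {"sm_g": -1}, ub=F, subsystem=DEMAND),
        R(GLCCER_DEMAND, {"glccer_c": -1}, ub=F, subsystem=DEMAND,
          name="glucosylceramide production"),
        R("DM_laccer_g", {"laccer_g": -1}, ub=F, subsystem=DEMAND),
        R("DM_galcer_r", {"galcer_r": -1}, ub=F, subsystem=DEMAND),
        R(DIGALCER_DEMAND, {"digalcer_g": -1}, ub=F, subsystem=DEMAND,
          name="digalactosylceramide production"),
        R("DM_hexdec_r", {"hexdec_r": -1}, ub=F, subsystem=DEMAND),
        R("DM_etnp_r", {"etnp_r": -1}, ub=F, subsystem=DEMAND),
        R("DM_dag_g", {"dag_g": -1}, ub=F, subsystem=DEMAND),
    ]
    return MetabolicModel(id="toy_sphingolipid", metabolites=mets, reactions=rxns)


def random_network(n_reactions: int = 10, seed: int = 0,
                   max_flux: float = 100.0) -> MetabolicModel:
    """Small random irreversible network for solver validation.

    A linear backbone (uptake -> chain of conversions -> sink) guarantees at
    least one feasible route; extra random conversion/boundary reactions are
    added up to ``n_reactions``.  All bounds are [0, max_flux].
    """
    if n_reactions < 3:
        raise GenerationError("need at least uptake, conversion and sink")
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, max(3, n_reactions - 1)))
    mets = [Metabolite(f"m{i}", f"m{i}", "c") for i in range(n_mets)]
    R = make_reaction
    rxns = [R("up0", {"m0": 1}, ub=max_flux)]
    for i in range(n_mets - 1):
        rxns.append(R(f"conv{i}", {f"m{i}": -1, f"m{i + 1}": 1}, ub=max_flux))
    rxns.append(R(f"sink{n_mets - 1}", {f"m{n_mets - 1}": -1}, ub=max_flux))
    k = 0
    while len(rxns) < n_reactions:
        kind = rng.random()
        if kind < 0.25:
            i = int(rng.integers(0, n_mets))
            rxns.append(R(f"up{len(rxns)}_{k}", {f"m{i}": 1}, ub=max_flux))
        elif kind < 0.5:
            i = int(rng.integers(0, n_mets))
            rxns.append(R(f"sink{len(rxns)}_{k}", {f"m{i}": -1}, ub=max_flux))
        else:
            i, j = rng.choice(n_mets, size=2, replace=False)
            rxns.append(R(f"x{len(rxns)}_{k}",
                          {f"m{i}": -1.0, f"m{j}": 1.0}, ub=max_flux))
        k += 1
    return MetabolicModel(id=f"random_{seed}", metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Cohort design and planted effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal three-group design mirroring the study cohort.

    Group sizes default to 10 controls, 27 seroconverted non-progressors and
    34 progressors, each scheduled for sampling at 12, 24 and 36 months of
    age.  Seroconversion ages are drawn so that the P1Ab median is near 24
    months and the PT1D median near 14 months.  ``missingness_rate`` drops
    subject-by-age samples at random (longitudinal dropout).
    """

    group_sizes: dict = field(default_factory=lambda: {"CTRL": 10, "P1Ab": 27, "PT1D": 34})
    ages: tuple = (12, 24, 36)
    missingness_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")
        if list(self.ages) != sorted(set(self.ages)):
            raise ValueError("ages must be strictly increasing")
        if not (0 <= self.missingness_rate < 0.5):
            raise ValueError("missingness_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class PlantedEffect:
    """One planted group-by-age shift on a named feature (log2 units)."""

    feature: str
    group: str
    age: int | None  # None: applies at every age
    log2_effect: float

    @property
    def direction(self) -> str:
        return "up" if self.log2_effect > 0 else ("down" if self.log2_effect < 0 else "null")


def subject_table(design: CohortDesign) -> pd.DataFrame:
    """Per-subject metadata: id, group, sex, seroconversion age (months).

    Seroconversion ages: P1Ab ~ lognormal with median 24 months, PT1D ~
    lognormal with median 14 months (controls never seroconvert).
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for group in GROUPS:
        for i in range(design.group_sizes[group]):
            if group == "P1Ab":
                sc = float(np.round(24.0 * np.exp(rng.normal(0, 0.5)), 1))
            elif group == "PT1D":
                sc = float(np.round(14.0 * np.exp(rng.normal(0, 0.35)), 1))
            else:
                sc = np.nan
            rows.append({
                "subject": f"{group}_{i + 1:02d}",
                "group": group,
                "sex": "F" if rng.random() < 0.5 else "M",
                "seroconversion_age": sc,
            })
    return pd.DataFrame(rows)


def _sample_grid(design: CohortDesign, subjects: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Subject x age sampling grid with dropout and small visit-age jitter."""
    rows = []
    for _, subj in subjects.iterrows():
        for age in design.ages:
            if rng.random() < design.missingness_rate:
                continue
            observed_age = age + float(np.round(rng.uniform(-2.0, 2.0), 1))
            rows.append({
                "sample": f"{subj.subject}_m{age}",
                "subject": subj.subject,
                "group": subj.group,
                "sex": subj.sex,
                "age_months": observed_age,
                "nominal_age": age,
                "seroconversion_age": subj.seroconversion_age,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature catalogue
# ---------------------------------------------------------------------------

_LIPID_CLASSES = {
    "TG": 40, "PC": 30, "LPC": 10, "PE": 12, "PI": 8,
    "SM": 15, "CE": 10, "Cer": 12, "HexCer": 6, "LacCer": 7,
}
_POLAR_CLASSES = {
    "amino acid": 25, "carboxylic acid": 15, "sugar derivative": 12,
    "fatty acid": 10, "hydroxy acid": 8,
}
_NAMED_AMINO_ACIDS = [
    "alanine", "glutamic acid", "serine", "aspartic acid", "phenylalanine",
    "proline", "threonine", "cystine", "lysine", "valine", "leucine",
    "isoleucine", "glycine", "tyrosine", "tryptophan",
]
_NAMED_FATTY_ACIDS = ["palmitic acid", "stearic acid", "myristic acid"]

CERAMIDE_FEATURE = "Cer(d18:1/24:0)"
HEXCER_FEATURES = ("HexCer(d18:1/16:0)", "HexCer(d18:1/22:0)")


def feature_catalogue() -> pd.DataFrame:
    """~150 lipid and ~70 polar features with class labels.

    Includes the named species the analysis tracks: Cer(d18:1/24:0), six
    glycoceramides, sphingomyelins, and the amino/fatty acids reported in
    the cohort.
    """
    rows = []

    def add(name, cls, kind):
        rows.append({"feature": name, "class": cls, "kind": kind})

    add(CERAMIDE_FEATURE, "Cer", "lipid")
    add("Cer(d18:1/22:0)", "Cer", "lipid")
    for f in HEXCER_FEATURES:
        add(f, "HexCer", "lipid")
    add("HexCer(d18:1/24:0)", "HexCer", "lipid")
    for tail in ("12:0", "14:0", "16:0"):
        add(f"LacCer(d18:1/{tail})", "LacCer", "lipid")
    named_counts: dict[str, int] = {}
    for r in rows:
        named_counts[r["class"]] = named_counts.get(r["class"], 0) + 1
    for cls, n in _LIPID_CLASSES.items():
        for i in range(n - named_counts.get(cls, 0)):
            carbons = (40 if cls == "TG" else 30) + 2 * (i // 4)
            add(f"{cls}({carbons}:{i % 4})", cls, "lipid")
    for aa in _NAMED_AMINO_ACIDS:
        add(aa, "amino acid", "polar")
    for fa in _NAMED_FATTY_ACIDS:
        add(fa, "fatty acid", "polar")
    named_counts = {}
    for r in rows:
        if r["kind"] == "polar":
            named_counts[r["class"]] = named_counts.get(r["class"], 0) + 1
    for cls, n in _POLAR_CLASSES.items():
        short = cls.split()[0]
        for i in range(n - named_counts.get(cls, 0)):
            add(f"{short}_{i + 1:02d}", cls, "polar")
    return pd.DataFrame(rows)


def default_metabolomics_effects(features: pd.DataFrame,
                                 seed: int = 0) -> list[PlantedEffect]:
    """The study-pattern planted effects.

    * Cer(d18:1/24:0) down (-0.8 log2) in PT1D at every age, and
      Cer(d18:1/22:0) down at 36 months;
    * HexCer(d18:1/16:0) and HexCer(d18:1/22:0) up (+0.8) in PT1D at 36 months;
    * a broad early decrease: 50% of the non-glycoceramide features down
      (-0.4) in both P1Ab and PT1D at 12 months (chosen reproducibly from
      ``seed``).  Glycoceramide classes are left out of the early decrease:
      the cohort's early drop concerns triacylglycerols, phospholipids,
      ceramides and polar metabolites, while hexosyl-/lactosylceramides
      only diverge late.
    """
    effects = [PlantedEffect(CERAMIDE_FEATURE, "PT1D", None, -0.8),
               PlantedEffect("Cer(d18:1/22:0)", "PT1D", 36, -0.8)]
    effects += [PlantedEffect(f, "PT1D", 36, +0.8) for f in HEXCER_FEATURES]
    rng = np.random.default_rng(seed + 104729)
    protected = {CERAMIDE_FEATURE, "Cer(d18:1/22:0)", *HEXCER_FEATURES}
    glyco = set(features.loc[features["class"].isin(["HexCer", "LacCer"]), "feature"])
    pool = [f for f in features["feature"] if f not in protected | glyco]
    early = rng.choice(pool, size=len(pool) // 2, replace=False)
    for f in sorted(early):
        effects.append(PlantedEffect(f, "P1Ab", 12, -0.4))
        effects.append(PlantedEffect(f, "PT1D", 12, -0.4))
    return effects


# ---------------------------------------------------------------------------
# Metabolomics simulator
# ---------------------------------------------------------------------------

def simulate_metabolomics(
    design: CohortDesign,
    effects: list[PlantedEffect] | None = None,
    noise_sd: float = 0.5,
    subject_sd: float = 0.3,
    seed: int = 0,
    features: pd.DataFrame | None = None,
):
    """Simulate the samples-by-features intensity table.

    Per feature f, subject s, age a (log2 scale)::

        y = baseline_f + ageslope_f * (a - 24)/12 + u_{s,f} + effect + noise

    with baseline ~ U(10, 20), a mild age trend ~ N(0, 0.1), subject
    intercepts u ~ N(0, subject_sd) drawn independently per subject-feature
    pair, planted effects from the registry, and residual noise
    N(0, noise_sd).  Intensities are exponentiated back to the raw scale,
    so every value is positive.  Returns ``(values, sample_meta,
    feature_meta, registry)``.
    """
    if features is None:
        features = feature_catalogue()
    if effects is None:
        effects = default_metabolomics_effects(features, seed=seed)
    unknown = {e.feature for e in effects} - set(features["feature"])
    if unknown:
        raise ValueError(f"planted effects name unknown features: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    subjects = subject_table(design)
    samples = _sample_grid(design, subjects, rng)
    n_s, n_f = len(samples), len(features)

    baseline = rng.uniform(10, 20, size=n_f)
    ageslope = rng.normal(0, 0.1, size=n_f)
    # per subject x feature random intercepts
    subj_ids = subjects["subject"].tolist()
    u = rng.normal(0, subject_sd, size=(len(subj_ids), n_f))
    u_of = {s: u[i] for i, s in enumerate(subj_ids)}

    log2 = np.tile(baseline, (n_s, 1))
    age_centered = ((samples["nominal_age"].to_numpy() - 24) / 12)[:, None]
    log2 = log2 + age_centered * ageslope[None, :]
    log2 += np.vstack([u_of[s] for s in samples["subject"]])

    fidx = {f: j for j, f in enumerate(features["feature"])}
    group_arr = samples["group"].to_numpy()
    age_arr = samples["nominal_age"].to_numpy()
    for e in effects:
        mask = group_arr == e.group
        if e.age is not None:
            mask = mask & (age_arr == e.age)
        log2[mask, fidx[e.feature]] += e.log2_effect

    log2 += rng.normal(0, noise_sd, size=(n_s, n_f))

    values = pd.DataFrame(np.exp2(log2), index=samples["sample"],
                          columns=features["feature"])
    sample_meta = samples.set_index("sample")
    feature_meta = features.set_index("feature")
    return values, sample_meta, feature_meta, list(effects)


# ---------------------------------------------------------------------------
# Expression simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionDesign:
    """Cross-sectional expression cohort (one sample per subject)."""

    group_sizes: dict = field(default_factory=lambda: {"CTRL": 15, "P1Ab": 15, "PT1D": 51})
    n_decoy_genes: int = 180
    log2_sd: float = 0.5


def default_expression_effects() -> list[PlantedEffect]:
    """Doubling of the glycoceramide-synthase program in progressors."""
    return [PlantedEffect(g, "PT1D", None, 1.0) for g in GLYCO_SYNTHASE_GENES]


def simulate_expression(
    model: MetabolicModel,
    design: ExpressionDesign | None = None,
    effects: list[PlantedEffect] | None = None,
    seed: int = 0,
):
    """Simulate the genes-by-samples expression matrix for the toy network.

    Baseline per gene: log2 mean ~ U(3, 10) for decoys and most network
    genes.  The glycoceramide-branch genes (synthases and glycosidases) are
    pinned 0.5 log2 units below the gene-population median: at baseline the
    branch reads as absent to reaction scoring, and the planted PT1D
    doubling of the synthases (+1 log2) lifts exactly the synthesis arm
    above threshold -- the recoverable ground truth for context
    extraction.  (Both arms must start low: a highly expressed glycosidase
    would pay for its negative-weight synthase partner through their futile
    cycle and re-open the branch in every group.)
    Returns ``(values genes x samples, sample_meta, registry)``.
    """
    if design is None:
        design = ExpressionDesign()
    if effects is None:
        effects = default_expression_effects()

    genes = sorted(model.genes) + [f"GENE{i:04d}" for i in range(design.n_decoy_genes)]
    unknown = {e.feature for e in effects} - set(genes)
    if unknown:
        raise ValueError(f"planted expression effects name unknown genes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    base = rng.uniform(3, 10, size=len(genes))
    median = float(np.median(base))
    gidx = {g: i for i, g in enumerate(genes)}
    for g in GLYCO_BRANCH_GENES:
        if g in gidx:
            base[gidx[g]] = median - 0.5

    rows = []
    for group in GROUPS:
        for i in range(design.group_sizes[group]):
            rows.append({"sample": f"expr_{group}_{i + 1:02d}", "group": group})
    sample_meta = pd.DataFrame(rows).set_index("sample")

    log2 = np.tile(base[:, None], (1, len(sample_meta)))
    group_arr = sample_meta["group"].to_numpy()
    for e in effects:
        mask = group_arr == e.group
        log2[gidx[e.feature], mask] += e.log2_effect
    log2 = log2 + rng.normal(0, design.log2_sd, size=log2.shape)

    values = pd.DataFrame(np.exp2(log2), index=pd.Index(genes, name="gene"),
                          columns=sample_meta.index)
    return values, sample_meta, list(effects)


# ---------------------------------------------------------------------------
# Pathway fixtures and feature -> metabolite mapping
# ---------------------------------------------------------------------------

def build_toy_pathways(features: pd.DataFrame):
    """Pathway sets over measured features, each with an internal adjacency.

    Sets are defined by feature class; the graph within a pathway is a hub
    topology (first member connected to the rest plus a chain), giving the
    impact score a non-trivial centrality profile.  Returns
    ``{name: (members, edges)}``.
    """
    by_class: dict[str, list[str]] = {}
    for _, row in features.iterrows():
        by_class.setdefault(row["class"], []).append(row["feature"])
    composition = {
        "Sphingolipid metabolism": ["Cer", "SM", "HexCer", "LacCer"],
        "Glycerophospholipid metabolism": ["PC", "LPC", "PE", "PI"],
        "Triacylglycerol metabolism": ["TG", "CE"],
        "Alanine, aspartate and glutamate metabolism": ["amino acid"],
        "Central carbon metabolism": ["carboxylic acid", "sugar derivative"],
        "Fatty acid biosynthesis": ["fatty acid", "hydroxy acid"],
    }
    pathways = {}
    for name, classes in composition.items():
        members = [f for c in classes for f in by_class.get(c, [])]
        edges = [(members[0], m) for m in members[1:]]
        edges += list(zip(members[1:], members[2:]))
        pathways[name] = (members, edges)
    return pathways


_CLASS_TO_METABOLITES = {
    "Cer": ["cer_c"],
    "HexCer": ["glccer_c", "galcer_r"],  # hexosyl- is glucosyl- or galactosyl-
    "LacCer": ["laccer_g"],
    "SM": ["sm_g"],
}
_NAME_TO_METABOLITES = {
    "serine": ["ser_c"],
    "palmitic acid": ["palm_c"],
}


def feature_metabolite_mapping(features: pd.DataFrame | None = None) -> dict[str, list[str]]:
    """Map measured feature names onto toy-model metabolite ids.

    Sphingolipid classes map by class label; hexosylceramides are ambiguous
    (glucosyl- or galactosyl-) and map to both candidates, per the stated
    policy of marking every candidate present.
    """
    if features is None:
        features = feature_catalogue()
    mapping: dict[str, list[str]] = {}
    for _, row in features.iterrows():
        if row["feature"] in _NAME_TO_METABOLITES:
            mapping[row["feature"]] = list(_NAME_TO_METABOLITES[row["feature"]])
        elif row["class"] in _CLASS_TO_METABOLITES:
            mapping[row["feature"]] = list(_CLASS_TO_METABOLITES[row["class"]])
    return mapping


# ---------------------------------------------------------------------------
# File export (consumed unchanged by the pipeline CLI)
# ---------------------------------------------------------------------------

def write_cohort(outdir: str | Path, design: CohortDesign | None = None,
                 seed: int = 0) -> dict[str, Path]:
    """Generate and write the full synthetic study to ``outdir``.

    Writes metabolomics TSV + sample metadata, expression TSV + metadata,
    the toy model as SBML, pathway GMT + edge lists, the feature mapping
    and the planted-effect registry (JSON).  Returns the path map.
    """
    from .sbml_io import write_sbml  # deferred: keeps import light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = CohortDesign(seed=seed)

    model = build_toy_sphingolipid_model()
    values, smeta, fmeta, met_effects = simulate_metabolomics(design, seed=seed)
    expr, expr_meta, expr_effects = simulate_expression(model, seed=seed + 1)
    pathways = build_toy_pathways(fmeta.reset_index())

    paths = {
        "metabolomics": outdir / "metabolomics.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "feature_meta": outdir / "feature_meta.tsv",
        "expression": outdir / "expression.tsv",
        "expression_meta": outdir / "expression_meta.tsv",
        "model": outdir / "toy_sphingolipid.xml",
        "pathways_gmt": outdir / "pathways.gmt",
        "pathway_edges": outdir / "pathway_edges.tsv",
        "feature_mapping": outdir / "feature_mapping.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    values.to_csv(paths["metabolomics"], sep="\t")
    smeta.to_csv(paths["sample_meta"], sep="\t")
    fmeta.to_csv(paths["feature_meta"], sep="\t")
    expr.to_csv(paths["expression"], sep="\t")
    expr_meta.to_csv(paths["expression_meta"], sep="\t")
    write_sbml(model, paths["model"])

    with open(paths["pathways_gmt"], "w") as fh:
        for name, (members, _) in pathways.items():
            fh.write("\t".join([name, "synthetic"] + members) + "\n")
    edge_rows = [{"pathway": name, "source": a, "target": b}
                 for name, (_, edges) in pathways.items() for a, b in edges]
    pd.DataFrame(edge_rows).to_csv(paths["pathway_edges"], sep="\t", index=False)

    map_rows = [{"feature": f, "metabolite": m}
                for f, mets in feature_metabolite_mapping().items() for m in mets]
    pd.DataFrame(map_rows).to_csv(paths["feature_mapping"], sep="\t", index=False)

    registry = {
        "metabolomics": [e.__dict__ for e in met_effects],
        "expression": [e.__dict__ for e in expr_effects],
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(registry, fh, indent=1, default=float)
    return paths
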