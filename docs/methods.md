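# Methods

This note documents the models, the statistical procedures, the synthetic
study design and the numerical choices behind `immunogem`, in the order
the pipeline runs them.

## Study design emulated by the generator

The simulated cohort mirrors a longitudinal at-risk birth cohort: three
groups of children — 10 autoantibody-negative controls (CTRL), 27
seroconverted non-progressors (P1Ab) and 34 progressors to type 1 diabetes
(PT1D) — each scheduled for PBMC sampling at 12, 24 and 36 months of age.
Seroconversion ages are drawn lognormally with medians near 24 months
(P1Ab) and 14 months (PT1D), so "before vs after seroconversion" paired
contrasts are possible at the cohort's group sizes.  Longitudinal dropout
removes each subject×age sample independently with probability 0.15 — a
realistic attrition level that still leaves every group×age cell analysable
(the real cohort's higher missingness is concentrated in cells the paired
analyses do not need).

### Metabolomics

220 features (150 lipid-like across TG/PC/LPC/PE/PI/SM/CE/Cer/HexCer/LacCer
classes, 70 polar-like including named amino and fatty acids) are simulated
on the log2 scale and exponentiated, guaranteeing positive raw intensities:

    y_{s,f,a} = baseline_f + ageslope_f·(a−24)/12 + u_{s,f} + effect + ε

with baseline ~ U(10, 20), age slopes ~ N(0, 0.1), subject random
intercepts u ~ N(0, 0.3), residual ε ~ N(0, 0.5).  The planted effects are
the study pattern itself:

* `Cer(d18:1/24:0)` −0.8 log2 in PT1D at every age, `Cer(d18:1/22:0)`
  −0.8 at 36 months;
* `HexCer(d18:1/16:0)` and `HexCer(d18:1/22:0)` +0.8 in PT1D at 36 months;
* a broad early decrease (−0.4 at 12 months in both P1Ab and PT1D) on half
  of the non-glycoceramide features — the early drop concerns
  triacylglycerols, phospholipids, ceramides and polar metabolites, while
  the glycoceramide classes only diverge late.

The intercept/residual sds (0.3/0.5 log2) make a planted |log2FC| = 0.8
detectable at these group sizes without being trivial.  Subject intercepts
are drawn independently per subject×feature pair; real metabolomes carry
shared subject-level variation across features, which this generator omits
so that feature columns are exchangeable and calibration statements
(fraction of null features with p < 0.05) concentrate tightly.  Passing
null-calibration tests here therefore does not certify behaviour under
strong inter-feature correlation.

### Toy sphingolipid network

`build_toy_sphingolipid_model` returns a 50-reaction, 39-metabolite model
over compartments c/g/r/l/e: de novo ceramide synthesis in the ER
(SPT → KSR → CerS → DES), the sphingomyelin cycle through Golgi (SMS) and
lysosome (SMase), the glycoceramide branches (GCS/GCDase in the cytosol,
GalCS in the ER, LacCerS and digalactosylceramide synthase in the Golgi,
GalCDase in the lysosome), the sphingosine exit route (CDase → SK → S1P
lyase) and the ceramide-1-phosphate cycle (CK/C1PP).  Each enzyme carries
one distinct gene; exchanges allow uptake of serine, palmitate, glucose,
galactose and a PC head-group donor (bound 10); demand reactions drain
sphingomyelin, every glycoceramide, the S1P breakdown products, DAG — and
cytosolic ceramide itself.  The ceramide sink stands for the many ceramide
consumers outside the modelled pathway; without it any profitable de novo
chain would be forced to drain through a glycoceramide branch regardless of
that branch's own evidence.  Stoichiometries are unit coefficients; the
sugar moieties released by the glycosidases are omitted (backbone species
are tracked, leaving groups are not), and mass balance is maintained for
every internal metabolite.  Every reaction can carry flux
(FVA-style check in the test suite); maximum glucosylceramide production is
palmitate-limited at uptake/2 = 5 flux units because ceramide consumes two
palmitate equivalents (SPT and CerS).

Nutrient transporters deliberately carry no gene rules: in this small
network a transporter gene's expression weight would topologically force
its sole downstream consumer (e.g. glucose → GCS) into every extracted
model, an artefact a genome-scale network would dilute.

### Expression

Gene baselines (log2 means) are U(3, 10) for ~180 decoy genes and most
network genes.  The glycoceramide branch — the four synthases UGCG, UGT8,
B4GALT5, A4GALT and the glycosidases GBA1, GALC — is pinned 0.5 log2 units
below the gene-population median, and the synthases are doubled (+1 log2)
in PT1D.  This is the planted ground truth for context extraction: at
baseline the whole branch reads as absent to reaction scoring, and the
PT1D doubling lifts exactly the synthesis arm above threshold.  Both arms
must start low — a highly expressed glycosidase would pay for its
negative-weight synthase partner through their futile cycle and re-open
the branch in every group.  Doubling all four synthases (not just UGCG)
reflects the coordinated up-regulation the reporter analysis is meant to
recover across glucosyl-, galactosyl- and lactosylceramide species.

## Differential statistics

Intensities are log2(x+1)-transformed (offset 1 keeps zeros finite).
Samples are assigned to the nearest target age within ±6 months; per
subject and bin the closest sample is kept (earlier on ties).  Homogeneity
is screened by PCA scores on the first two components against the
Hotelling T² limit k(n−1)/(n−k)·F_{k,n−k}(0.95); with 95% confidence a few
samples per ~200 are expected outside the ellipse and this is not treated
as failure.  Explained variation uses sequential (type I) sums of squares
of age, sex, group and their pairwise interactions, as percent of each
feature's total sum of squares.

Contrasts use Welch's t by default (a Student option exists); the fold
change is first-named group minus second.  Degenerate features (zero
variance in both groups) report p = 1 with a flag rather than NaN.  BH FDR
is computed within each contrast×age family with the exact operation order
of the standard reference implementations, so q-values agree bit for bit.

Sparse PLS-DA is NIPALS PLS1 against the centred 0/1 class indicator on
column-standardised data.  Per component, the weight vector keeps the
`keep_per_component` (default 20) largest-|w| features via soft
thresholding at the (k+1)-th magnitude, then is renormalised; defaults are
2 components.  The reported RC is each feature's coefficient in the final
linear predictor B = W(PᵀW)⁻¹q.  VIP_j = √(p·Σ_a SSY_a w_{ja}² / Σ_a SSY_a)
with unit-norm weight columns, which makes Σ_j VIP_j² = p an exact
identity.  AUC is stratified 5-fold cross-validation (3 repeats inside the
pipeline, 10 in standalone use), with folds stratified on first-appearance
class codes so the estimate is invariant to label renaming.  The combined
selection rule flags "multi+uni" when AUC ≥ 0.65, |RC| > 0.05, VIP > 1 and
p < 0.05 all hold, and "uni-only" on p < 0.05 alone; all thresholds are
configuration.

## Pathway over-representation and impact

ORA is the one-sided hypergeometric upper tail with the universe defined
as all measured features mapped to the pathway database (standard ORA
practice), pathway sets intersected with the universe before testing, and
BH FDR across pathways.  The pathway impact score weights hit metabolites
by relative betweenness centrality within the pathway's own graph
(PIS = Σ_hits C_B / Σ_members C_B, 0 when no member carries centrality,
undefined — reported as null — when the pathway has no graph).  The
synthetic pathway graphs use a hub-plus-chain topology so centrality is
non-uniform.

## Context-specific extraction

Reaction expression e_i comes from the GPR tree with AND → min
(limiting subunit) and OR → max (strongest isoenzyme); genes missing from
the data contribute no evidence rather than zero.  Weights are
w_i = log2(e_i/τ) clipped to ±5, with τ the median gene signal — sign-
symmetric around the evidence threshold and bounded; reactions without
gene evidence get weight 0.  Metabolite evidence enters the MILP through
accumulation variables b_j ∈ [0, 100] (ε·x_j ≤ b_j ≤ b_max·x_j) with bonus
κ = 20 per evidenced metabolite the network can net-produce, so evidenced
production outranks single low-weight reactions.  ε = 10⁻³ and M = 1000;
the MILP runs single-threaded on HiGHS at relative gap 10⁻⁶ with
integrality and primal feasibility tolerances of 10⁻⁹ — the default 10⁻⁶
integrality tolerance would let y ≈ 10⁻⁶ count as integer zero while
M·y still grants ε of flux, a real leak observed during development.
Every kept reaction is re-verified post hoc to sustain ≥ ε flux in the
extracted model.

In the pipeline, metabolite evidence per clinical group is derived from
the differential stage: a metabolite counts as present for a group when
features mapped to it are elevated in that group (BH q < 0.05, fold change
toward the group) with corroboration — at least two distinct supporting
features, or one feature supported at two or more ages.  The raw-p gate
used for reporting would let single false discoveries open whole pathway
branches through the κ bonus; the exact presence/absence scoring of the
original analysis is not published, so this corroborated call is this
package's own reconstruction.  Exchange bounds follow the evidence:
uptake (lb = −10) only for evidenced or media-whitelisted nutrients
(glucose, galactose, serine, palmitate, PC donor), secretion always open.

On a 50-reaction network, a group whose expression supports no profitable
chain and whose evidence set is empty legitimately extracts a (near-)empty
model — "no active flux route demanded by the data".  Group comparisons
remain well-defined (pruned objectives score 0).

## Reporter metabolites

Gene Z-scores are Φ⁻¹(1−p) with p floored at 10⁻¹⁵; directional modes
convert the two-sided p to one-sided first (p/2 toward the direction,
1−p/2 against), so up- and down-reporters are scored separately, per
compartment.  A metabolite with k scored neighborhood genes (currency
metabolites — water, protons, ATP/ADP, NAD(P)(H), CoA, etc. — excluded via
a configurable list) gets z_raw = ΣZ/√k, corrected by the mean and sd of
the same statistic over 10 000 random size-k draws (with replacement) from
the scored-gene pool; p = 1−Φ(z_corrected), BH across metabolites.  The
background pool is all scored genes, so adding planted signal genes shifts
the pool's moments slightly — rankings are stable but z values are exactly
invariant to extra non-network genes only under a null pool.

## Flux analysis

FBA is max/min c·v s.t. S·v = 0, lb ≤ v ≤ ub on HiGHS with 10⁻¹⁰
feasibility tolerances; basic solutions give mass-balance residuals at
machine precision (the acceptance bound is 10⁻⁹).  Because optima are
generally degenerate, the reported vector is parsimonious: Σ|v| is
minimised at the fixed optimum (split-variable LP), which zeroes futile
cycles (e.g. CK/C1PP) and makes subsystem summaries reproducible.  A
demand objective pruned during extraction is re-added as a
single-metabolite drain before optimising (the pruning is informative and
flagged, not an error); subsystem summaries compare Σ|v| per subsystem on
the intersection of reaction sets.

## Pipeline, determinism, validation sizes

The eight stages (simulate → qc → contrast → ora → score → extract →
reporters → flux) are pure functions of a validated YAML/dataclass config;
outputs are TSV/SBML plus a manifest with SHA-256 hashes.  All randomness
(generators, CV folds, reporter backgrounds) derives from the config seed;
SBML is serialised with per-reaction subsystem notes specifically because
the alternative (SBML groups) does not serialise in a stable order.  Two
runs with the same config are bit-identical, manifests included.

The validation experiments use these problem sizes, chosen to make the
checks statistically meaningful at desk scale: 25 random networks of 6–12
reactions for MILP-vs-enumeration equivalence (exhaustive subsets with LP
feasibility); 50 replicates of the 3-synthase planted reporter recovery
among 200 null genes; a 2000-metabolite chain network for reporter null
calibration; every hypergeometric instance with universe ≤ 25; 2000 null
features at cohort group sizes for type-I error; 200 replicate features at
n = 30/group for fold-change bias; 20 seeded end-to-end pipeline runs for
the direction-match rate.  An end-to-end run takes a few seconds on one
CPU.

## Known limitations

* The toy network's branch fates hinge on single genes; genome-scale
  models average over isoenzymes and parallel routes, so extraction there
  is less all-or-nothing.
* About 5% of seeded end-to-end runs plant a hexosylceramide signal that
  clears p < 0.05 but not the within-contrast q < 0.05 evidence gate; no
  group then produces glucosylceramide (a flux tie at zero, not a false
  positive in controls).
* No batch effects, chromatographic artefacts or censoring at a detection
  limit are simulated (documented extension points), and no imputation or
  loess smoothing is implemented (out of scope).
* Differential expression uses plain Welch t + BH; moderated (shrinkage)
  statistics would behave differently at very small group sizes.
* The INIT weight formula, κ, ε and the presence-call corroboration rule
  are this package's own declared choices where the original analysis
  parameters are not published; all are configurable.
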