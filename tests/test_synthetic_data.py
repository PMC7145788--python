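import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunogem import synthetic_data as syn
from immunogem.differential import bh_fdr, log2_normalize, two_sample_contrast
from immunogem.flux_analysis import fba


class TestToyModel:
    def test_size_and_connectivity(self, toy_model):
        assert 35 <= len(toy_model.reactions) <= 60
        named = {"SPT", "KSR", "CERS", "DES", "SMS", "SMASE", "GCS", "GCDASE",
                 "GALCS", "GALCDASE", "LACCERS", "DIGALCERS", "CDASE", "SK",
                 "S1PL", "CK", "C1PP"}
        assert named <= set(toy_model.reaction_ids)
        # one distinct single-gene GPR per enzyme
        genes = [toy_model.reaction(r).gpr.genes() for r in named]
        assert all(len(g) == 1 for g in genes)
        assert len(set(frozenset(g) for g in genes)) == len(named)
        assert {m.compartment for m in toy_model.metabolites} == {"c", "g", "r", "l", "e"}

    def test_glccer_demand_positive(self, toy_model):
        state = fba(toy_model, "DM_glccer_c")
        assert state.optimal and state.objective_value > 0

    def test_every_reaction_carries_flux(self, toy_model):
        """Flux-consistency: FVA-style per-reaction maximisation."""
        blocked = [r.id for r in toy_model.reactions
                   if abs(fba(toy_model, r.id, "max", parsimonious=False).objective_value) < 1e-6
                   and abs(fba(toy_model, r.id, "min", parsimonious=False).objective_value) < 1e-6]
        assert blocked == []

    def test_mass_balance_structure(self, toy_model):
        """Internal metabolites have producers and consumers (or a boundary)."""
        S = toy_model.stoichiometric_matrix()
        boundary_mets = {next(iter(r.stoich)) for r in toy_model.boundary_reactions()}
        for i, m in enumerate(toy_model.metabolites):
            if m.id in boundary_mets:
                continue
            assert (S[i] > 0).any() and (S[i] < 0).any(), m.id

    def test_no_glucose_no_glucosylceramide(self, toy_model):
        from dataclasses import replace
        rxns = [replace(r, lb=0.0, ub=0.0) if r.id == "EX_glc_e" else r
                for r in toy_model.reactions]
        closed = syn.MetabolicModel(id="noglc", metabolites=toy_model.metabolites,
                                    reactions=rxns)
        assert fba(closed, "DM_glccer_c").objective_value == pytest.approx(0, abs=1e-9)

    def test_bad_config_raises(self):
        with pytest.raises(syn.GenerationError):
            syn.build_toy_sphingolipid_model(uptake_bound=-1)


class TestRandomNetwork:
    def test_backbone_feasible_and_sized(self):
        for seed in range(5):
            m = syn.random_network(n_reactions=9, seed=seed)
            assert len(m.reactions) == 9
            assert fba(m, m.reaction_ids[0], parsimonious=False).optimal


class TestCohortDesign:
    def test_invariants(self):
        with pytest.raises(ValueError):
            syn.CohortDesign(group_sizes={"CTRL": 1, "P1Ab": 5, "PT1D": 5})
        with pytest.raises(ValueError):
            syn.CohortDesign(ages=(24, 12))
        with pytest.raises(ValueError):
            syn.CohortDesign(missingness_rate=0.7)

    def test_seroconversion_age_medians(self):
        """P1Ab median near 24 months, PT1D near 14, as in the cohort."""
        design = syn.CohortDesign(group_sizes={"CTRL": 10, "P1Ab": 200, "PT1D": 200},
                                  seed=3)
        subjects = syn.subject_table(design)
        med = subjects.groupby("group")["seroconversion_age"].median()
        assert med["P1Ab"] == pytest.approx(24, rel=0.25)
        assert med["PT1D"] == pytest.approx(14, rel=0.25)
        assert subjects.loc[subjects.group == "CTRL", "seroconversion_age"].isna().all()


class TestMetabolomicsSimulator:
    def test_shapes_and_positivity(self, small_cohort):
        values, smeta, fmeta, registry = small_cohort
        assert (values.to_numpy() > 0).all()
        assert len(values) == len(smeta)
        assert values.shape[1] == len(fmeta) == 220
        assert (fmeta["kind"] == "lipid").sum() == 150
        assert (fmeta["kind"] == "polar").sum() == 70

    def test_determinism_and_seed_sensitivity(self):
        design = syn.CohortDesign(seed=5)
        v1, *_ = syn.simulate_metabolomics(design, seed=5)
        v2, *_ = syn.simulate_metabolomics(design, seed=5)
        v3, *_ = syn.simulate_metabolomics(design, seed=6)
        pd.testing.assert_frame_equal(v1, v2)
        assert not v1.equals(v3)

    def test_zero_missingness_gives_complete_grid(self):
        design = syn.CohortDesign(missingness_rate=0.0, seed=1)
        values, smeta, *_ = syn.simulate_metabolomics(design, seed=1)
        n_subj = sum(design.group_sizes.values())
        assert len(values) == n_subj * len(design.ages)

    def test_registry_describes_planted_truth(self, small_cohort):
        *_, registry = small_cohort
        by_feat = {}
        for e in registry:
            by_feat.setdefault(e.feature, []).append(e)
        cer = by_feat[syn.CERAMIDE_FEATURE]
        assert all(e.log2_effect < 0 and e.group == "PT1D" for e in cer)
        for f in syn.HEXCER_FEATURES:
            (e,) = by_feat[f]
            assert e.age == 36 and e.log2_effect > 0 and e.direction == "up"

    def test_planted_ceramide_recovered_across_seeds(self):
        """The down-planted ceramide shows a negative fold change in PT1D vs
        CTRL at 36 months in nearly every replicate."""
        hits = 0
        n = 50
        for seed in range(n):
            design = syn.CohortDesign(seed=seed)
            values, smeta, *_ = syn.simulate_metabolomics(design, seed=seed)
            res = two_sample_contrast(log2_normalize(values), smeta,
                                      "PT1D", "CTRL", age_bin=36)
            hits += res.table.loc[syn.CERAMIDE_FEATURE, "log2fc"] < 0
        assert hits >= int(0.95 * n)

    def test_unknown_effect_feature_rejected(self):
        design = syn.CohortDesign(seed=0)
        with pytest.raises(ValueError):
            syn.simulate_metabolomics(
                design, effects=[syn.PlantedEffect("no-such-feature", "PT1D", 12, 1.0)])


class TestExpressionSimulator:
    def test_determinism(self, toy_model):
        e1, *_ = syn.simulate_expression(toy_model, seed=2)
        e2, *_ = syn.simulate_expression(toy_model, seed=2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_covers_model_genes(self, toy_model):
        expr, meta, registry = syn.simulate_expression(toy_model, seed=0)
        assert set(toy_model.genes) <= set(expr.index)
        assert set(meta["group"]) == {"CTRL", "P1Ab", "PT1D"}

    def test_null_pvalues_uniform(self, toy_model):
        """With no planted effects two-group gene p-values are U(0,1)."""
        design = syn.ExpressionDesign(group_sizes={"CTRL": 25, "P1Ab": 2, "PT1D": 25},
                                      n_decoy_genes=400)
        expr, meta, _ = syn.simulate_expression(toy_model, design=design,
                                                effects=[], seed=9)
        log2 = np.log2(expr.T)
        a = log2.loc[meta.index[meta.group == "PT1D"]].to_numpy()
        b = log2.loc[meta.index[meta.group == "CTRL"]].to_numpy()
        _, p = stats.ttest_ind(a, b, axis=0)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_synthase_detected_across_seeds(self, toy_model):
        """x2 up-regulation at n=25/group is found at FDR < 0.05 in >= 90%
        of replicates."""
        design = syn.ExpressionDesign(group_sizes={"CTRL": 25, "P1Ab": 2, "PT1D": 25})
        effects = [syn.PlantedEffect(syn.GENE_GCS, "PT1D", None, 1.0)]
        hits, n = 0, 50
        for seed in range(n):
            expr, meta, _ = syn.simulate_expression(toy_model, design=design,
                                                    effects=effects, seed=seed)
            log2 = np.log2(expr.T)
            a = log2.loc[meta.index[meta.group == "PT1D"]].to_numpy()
            b = log2.loc[meta.index[meta.group == "CTRL"]].to_numpy()
            _, p = stats.ttest_ind(a, b, axis=0)
            q = bh_fdr(p)
            hits += q[list(expr.index).index(syn.GENE_GCS)] < 0.05
        assert hits >= int(0.9 * n)

    def test_unknown_gene_rejected(self, toy_model):
        with pytest.raises(ValueError):
            syn.simulate_expression(
                toy_model, effects=[syn.PlantedEffect("NOGENE", "PT1D", None, 1.0)])


def test_write_cohort_produces_consumable_files(tmp_path):
    paths = syn.write_cohort(tmp_path / "cohort", seed=3)
    for p in paths.values():
        assert p.exists() and p.stat().st_size > 0
    gmt = (tmp_path / "cohort" / "pathways.gmt").read_text().splitlines()
    assert any(line.startswith("Sphingolipid metabolism\t") for line in gmt)
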