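import numpy as np
import pandas as pd
import pytest

from immunogem import synthetic_data as syn
from immunogem.gem_context import (
    ExtractionError,
    MetaboliteEvidence,
    ReactionScore,
    exchange_bounds_from_metabolomics,
    init_extract,
    metabolite_evidence_from_metabolomics,
    score_reactions,
)
from immunogem.model_core import (
    MetabolicModel,
    Metabolite,
    make_reaction,
    split_reversible,
)
from oracles import best_subnetwork_bruteforce


def chain_model():
    """Aex -> A -> B -> Bex, all irreversible."""
    mets = [Metabolite("a", "A", "c"), Metabolite("b", "B", "c")]
    rxns = [
        make_reaction("up_a", {"a": 1}, ub=100),
        make_reaction("conv", {"a": -1, "b": 1}, ub=100),
        make_reaction("sink_b", {"b": -1}, ub=100),
    ]
    return MetabolicModel(id="chain", metabolites=mets, reactions=rxns)


def scores_for(model, weights):
    return [ReactionScore(r.id, 1.0, weights.get(r.id, 0.0))
            for r in model.reactions]


class TestScoreReactions:
    def _model(self):
        mets = [Metabolite("a", "A", "c")]
        rxns = [make_reaction("r1", {"a": 1}, gpr="g1"),
                make_reaction("r2", {"a": -1}, gpr="g2"),
                make_reaction("r3", {"a": -1})]
        return MetabolicModel(id="m", metabolites=mets, reactions=rxns)

    def test_weight_formula(self):
        m = self._model()
        expr = pd.Series({"g1": 8.0, "g2": 32.0})
        scores = {s.reaction: s for s in score_reactions(m, expr, tau=8.0)}
        assert scores["r1"].weight == pytest.approx(0.0)   # e = tau
        assert scores["r2"].weight == pytest.approx(2.0)   # e = 4*tau
        assert scores["r3"].weight == 0.0                  # no evidence
        assert scores["r3"].expression_level == "no evidence"

    def test_clipping(self):
        m = self._model()
        expr = pd.Series({"g1": 8.0 / 1e6, "g2": 8.0 * 1e6})
        scores = {s.reaction: s for s in score_reactions(m, expr, tau=8.0,
                                                         w_max=5.0)}
        assert scores["r1"].weight == -5.0
        assert scores["r2"].weight == 5.0

    def test_default_tau_is_median(self):
        m = self._model()
        expr = pd.Series({"g1": 2.0, "g2": 8.0, "gX": 4.0})
        scores = {s.reaction: s for s in score_reactions(m, expr)}
        assert scores["r1"].weight == pytest.approx(-1.0)  # log2(2/4)
        assert scores["r2"].weight == pytest.approx(1.0)


class TestMetaboliteEvidence:
    def test_direct_mapping(self, toy_model):
        ev = metabolite_evidence_from_metabolomics(
            toy_model, {"HexCer(d18:1/16:0)"},
            {"HexCer(d18:1/16:0)": ["glccer_c"]})
        present = {e.metabolite for e in ev if e.present}
        assert present == {"glccer_c"}

    def test_empty_detection(self, toy_model):
        ev = metabolite_evidence_from_metabolomics(toy_model, [], {})
        assert not any(e.present for e in ev)
        assert len(ev) == len(toy_model.metabolites)

    def test_ambiguous_mapping_marks_all(self, toy_model, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="immunogem.gem_context"):
            ev = metabolite_evidence_from_metabolomics(
                toy_model, {"HexCer(d18:1/16:0)"},
                {"HexCer(d18:1/16:0)": ["glccer_c", "galcer_r"]})
        present = {e.metabolite for e in ev if e.present}
        assert present == {"glccer_c", "galcer_r"}
        assert any("ambiguous" in r.message for r in caplog.records)


class TestExchangeBounds:
    def test_evidenced_metabolite_opens_uptake(self, toy_model):
        ev = [MetaboliteEvidence("glc_c", True)]
        out = exchange_bounds_from_metabolomics(toy_model, ev,
                                                default_uptake=7.0)
        assert out.reaction("EX_glc_e").lb == -7.0

    def test_unevidenced_uptake_closed_secretion_open(self, toy_model):
        out = exchange_bounds_from_metabolomics(toy_model, [],
                                                default_uptake=7.0)
        for rid in ("EX_ser_e", "EX_palm_e", "EX_glc_e", "EX_gal_e", "EX_pc_e"):
            assert out.reaction(rid).lb == 0.0
            assert out.reaction(rid).ub > 0

    def test_media_whitelist(self, toy_model):
        out = exchange_bounds_from_metabolomics(
            toy_model, [], media_whitelist=("glucose",), default_uptake=3.0)
        assert out.reaction("EX_glc_e").lb == -3.0
        assert out.reaction("EX_gal_e").lb == 0.0

    def test_idempotent(self, toy_model):
        ev = [MetaboliteEvidence("glc_c", True)]
        once = exchange_bounds_from_metabolomics(toy_model, ev)
        twice = exchange_bounds_from_metabolomics(once, ev)
        assert [(r.lb, r.ub) for r in once.reactions] == \
               [(r.lb, r.ub) for r in twice.reactions]


class TestInitExtract:
    def test_all_positive_weights_includes_everything(self, toy_model):
        split = split_reversible(toy_model)
        scores = scores_for(toy_model, {r.id: 1.0 for r in toy_model.reactions})
        ctx = init_extract(split, scores)
        assert set(ctx.included) == set(split.model.reaction_ids)

    def test_unprofitable_chain_yields_empty_model(self):
        """up(+1) -> conv(-3) -> sink(+1): the connector is forced, the total
        is negative, so the optimum is the empty network; verified against
        all 2^3 subsets."""
        m = chain_model()
        weights = {"up_a": 1.0, "conv": -3.0, "sink_b": 1.0}
        split = split_reversible(m)
        ctx = init_extract(split, scores_for(m, weights))
        assert ctx.included == []
        best, best_set = best_subnetwork_bruteforce(m, weights)
        assert best == 0.0 and best_set == set()
        assert ctx.objective == pytest.approx(best, abs=1e-9)

    def test_profitable_chain_included_whole(self):
        m = chain_model()
        weights = {"up_a": 1.0, "conv": -1.0, "sink_b": 1.5}
        split = split_reversible(m)
        ctx = init_extract(split, scores_for(m, weights))
        assert set(ctx.included) == {"up_a", "conv", "sink_b"}
        best, _ = best_subnetwork_bruteforce(m, weights)
        assert ctx.objective == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_enumeration_on_random_networks(self, trial):
        """MILP optimum equals exhaustive subset enumeration with LP
        feasibility checking on random networks."""
        rng = np.random.default_rng(1000 + trial)
        n_rxn = int(rng.integers(6, 11))
        m = syn.random_network(n_reactions=n_rxn, seed=trial)
        weights = {r.id: float(rng.uniform(-5, 5)) for r in m.reactions}
        split = split_reversible(m)
        ctx = init_extract(split, scores_for(m, weights))
        best, _ = best_subnetwork_bruteforce(m, weights)
        assert ctx.objective == pytest.approx(best, abs=1e-9)

    def test_evidence_bonus_pulls_pathway_in(self, toy_model):
        """GlcCer evidence plus kappa overrides mildly negative weights along
        its production route."""
        weights = {r.id: -0.5 for r in toy_model.reactions}
        ev = [MetaboliteEvidence("glccer_c", True)]
        constrained = exchange_bounds_from_metabolomics(
            toy_model, [], media_whitelist=("glucose", "serine", "palmitate"))
        split = split_reversible(constrained)
        ctx = init_extract(split, scores_for(toy_model, weights), ev, kappa=20.0)
        assert "GCS" in ctx.included
        assert ctx.b["glccer_c"] >= 1e-3 - 1e-9

    def test_group_specific_extraction_pattern(self, toy_model):
        """Positive synthase weight + glycoceramide evidence keeps GCS in the
        progressor model; negative weight without evidence prunes it from the
        control model."""
        base = {r.id: 0.0 for r in toy_model.reactions}
        constrained = exchange_bounds_from_metabolomics(
            toy_model, [MetaboliteEvidence("cer_c", True)],
            media_whitelist=("glucose", "serine", "palmitate"))
        split = split_reversible(constrained)

        pt1d = dict(base, GCS=0.5)
        ctx_pt1d = init_extract(split, scores_for(toy_model, pt1d),
                                [MetaboliteEvidence("glccer_c", True),
                                 MetaboliteEvidence("cer_c", True)])
        assert "GCS" in ctx_pt1d.included

        ctrl = dict(base, GCS=-0.5)
        ctx_ctrl = init_extract(split, scores_for(toy_model, ctrl),
                                [MetaboliteEvidence("cer_c", True)])
        assert "GCS" not in ctx_ctrl.included

    def test_monotone_in_weights(self):
        """Raising one reaction's weight never drops it from the optimum once
        included."""
        m = chain_model()
        split = split_reversible(m)
        included_before = False
        for w_conv in (-3.0, -1.5, -0.5, 0.5):
            weights = {"up_a": 1.0, "conv": w_conv, "sink_b": 1.0}
            ctx = init_extract(split, scores_for(m, weights))
            now = "conv" in ctx.included
            assert now or not included_before
            included_before = included_before or now

    def test_included_reactions_carry_flux(self, toy_model):
        rng = np.random.default_rng(5)
        weights = {r.id: float(rng.uniform(-2, 2)) for r in toy_model.reactions}
        split = split_reversible(toy_model)
        ctx = init_extract(split, scores_for(toy_model, weights))
        # the post-hoc verification inside init_extract already enforces this;
        # double-check through the returned witness
        for rid in ctx.included:
            assert ctx.flux_witness[rid] >= 1e-3 - 1e-6

    def test_requires_split_model(self, toy_model):
        scores = scores_for(toy_model, {})
        with pytest.raises(ValueError, match="split"):
            init_extract(
                type("S", (), {"model": toy_model,
                               "origin": {r.id: (r.id, 1) for r in toy_model.reactions}})(),
                scores)
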