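"""Dead-end detection, candidate pooling, penalties and the gap-fill MILP."""

import statistics

import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from ecforge import fixtures as fx
from ecforge.ensemble import ScoredAnnotation
from ecforge.gapfill import (
    GapFillCandidate,
    GapFillInfeasibleError,
    GapFillProblem,
    augment_model,
    build_candidate_pool,
    compute_penalties,
    find_dead_end_metabolites,
    solve_gapfill_milp,
)
from ecforge.model import MetabolicModel, Reaction
from ecforge.reaction_db import ReactionDatabase
from tests.conftest import enumerate_min_penalty, lp_max_objective


class TestDeadEnds:
    def test_produced_never_consumed(self):
        m = MetabolicModel()
        m.add_reaction(Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0}))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                reversible=True))
        assert find_dead_end_metabolites(m) == {"B"}

    def test_reversible_producer_plus_consumer_is_fine(self):
        m = MetabolicModel()
        m.add_reaction(Reaction(id="R1", stoichiometry={"A": -1.0, "B": 1.0},
                                reversible=True))
        m.add_reaction(Reaction(id="R2", stoichiometry={"B": -1.0, "C": 1.0}))
        m.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                reversible=True))
        m.add_reaction(Reaction(id="EX_C", stoichiometry={"C": -1.0}))
        assert find_dead_end_metabolites(m) == set()

    def test_consumed_only_metabolite_is_dead_end(self):
        m = MetabolicModel()
        m.add_reaction(Reaction(id="R", stoichiometry={"A": -1.0, "B": 1.0}))
        m.add_reaction(Reaction(id="EX_B", stoichiometry={"B": -1.0}))
        assert find_dead_end_metabolites(m) == {"A"}


class TestCandidatePool:
    def setup_pool(self):
        db = ReactionDatabase()
        db.add(Reaction(id="Rlow", stoichiometry={"A": -1.0, "B": 1.0},
                        ec_links=frozenset({"1.1.1.1", "2.2.2.2"})))
        db.add(Reaction(id="Rhigh", stoichiometry={"B": -1.0, "C": 1.0},
                        ec_links=frozenset({"3.3.3.3"})))
        db.add(Reaction(id="Rnone", stoichiometry={"C": -1.0, "D": 1.0}))
        model = MetabolicModel()
        model.add_reaction(Reaction(id="base", stoichiometry={"Z": -1.0, "A": 1.0}))
        scored = [
            ScoredAnnotation("p1", "1.1.1.1", 0.2, False, "classifier"),
            ScoredAnnotation("p2", "1.1.1.1", 0.1, False, "classifier"),
            ScoredAnnotation("p1", "2.2.2.2", 0.4, False, "classifier"),
            ScoredAnnotation("p3", "3.3.3.3", 0.6, True, "classifier"),
        ]
        return db, model, scored

    def test_highest_low_conf_score_per_reaction(self):
        db, model, scored = self.setup_pool()
        pool = build_candidate_pool(db, scored, model,
                                    synthesize_deadend_exchanges=False)
        by_id = {c.reaction.id: c for c in pool}
        assert by_id["Rlow"].kind == "low_conf_ec"
        assert by_id["Rlow"].raw_score == pytest.approx(0.4)

    def test_high_confidence_reaction_not_a_candidate(self):
        db, model, scored = self.setup_pool()
        pool = build_candidate_pool(db, scored, model,
                                    synthesize_deadend_exchanges=False)
        assert "Rhigh" not in {c.reaction.id for c in pool}

    def test_no_conf_reactions_included_by_default(self):
        db, model, scored = self.setup_pool()
        pool = build_candidate_pool(db, scored, model,
                                    synthesize_deadend_exchanges=False)
        by_id = {c.reaction.id: c for c in pool}
        assert by_id["Rnone"].kind == "no_conf"
        restricted = build_candidate_pool(
            db, scored, model, include_no_conf=False,
            synthesize_deadend_exchanges=False,
        )
        assert "Rnone" not in {c.reaction.id for c in restricted}

    def test_deadend_exchanges_synthesized(self):
        db, model, scored = self.setup_pool()
        pool = build_candidate_pool(db, scored, model)
        exch = {c.reaction.id: c for c in pool if c.kind == "deadend_exchange"}
        # Z is consumed-only in the combined network -> supply-capable exchange
        assert "EX_Z" in exch
        assert exch["EX_Z"].reaction.lower_bound < 0

    def test_base_model_reactions_excluded(self):
        db, model, scored = self.setup_pool()
        db.add(Reaction(id="base", stoichiometry={"Z": -1.0, "A": 1.0}))
        pool = build_candidate_pool(db, scored, model,
                                    synthesize_deadend_exchanges=False)
        assert "base" not in {c.reaction.id for c in pool}


class TestPenalties:
    def make(self, scores):
        return [
            GapFillCandidate(
                reaction=Reaction(id=f"r{i}", stoichiometry={"A": -1.0, "B": 1.0}),
                kind="low_conf_ec", raw_score=s,
            )
            for i, s in enumerate(scores)
        ]

    def test_hand_worked_example(self):
        out = compute_penalties(self.make([0.1, 0.2, 0.4]))
        assert [c.scaled_score for c in out] == pytest.approx([0.5, 1.0, 2.0])
        assert [c.penalty for c in out] == pytest.approx([2 / 3, 1 / 2, 1 / 3])

    def test_median_score_gets_penalty_half(self):
        out = compute_penalties(self.make([0.15, 0.3, 0.45]))
        mid = next(c for c in out if c.raw_score == 0.3)
        assert mid.scaled_score == pytest.approx(1.0)
        assert mid.penalty == pytest.approx(0.5)

    def test_unscored_and_deadend_defaults(self):
        cands = [
            GapFillCandidate(
                reaction=Reaction(id="u", stoichiometry={"A": 1.0}), kind="no_conf"
            ),
            GapFillCandidate(
                reaction=Reaction(id="EX_d", stoichiometry={"D": -1.0}),
                kind="deadend_exchange",
            ),
        ]
        out = compute_penalties(cands, default_penalty=1.0, deadend_penalty=10.0)
        assert out[0].penalty == 1.0
        assert out[1].penalty == 10.0

    @seed(11)
    @given(st.lists(st.floats(0.0002, 0.5), min_size=1, max_size=25))
    @settings(max_examples=300, deadline=None)
    def test_median_of_scaled_scores_is_one(self, scores):
        out = compute_penalties(self.make(scores))
        assert statistics.median(c.scaled_score for c in out) == pytest.approx(1.0)

    @seed(12)
    @given(
        st.lists(st.integers(2, 5000), min_size=2, max_size=15, unique=True).map(
            lambda ints: [v / 10000 for v in ints]  # distinct scores in (0.0001, 0.5]
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_penalty_strictly_decreasing_in_score(self, scores):
        out = compute_penalties(self.make(scores))
        ranked = sorted(out, key=lambda c: c.raw_score)
        for a, b in zip(ranked, ranked[1:]):
            assert a.penalty > b.penalty


class TestMILP:
    def test_already_feasible_selects_nothing(self, chain3):
        cands = compute_penalties(
            build_candidate_pool(chain3.db, [], chain3.model)
        )
        res = solve_gapfill_milp(GapFillProblem(model=chain3.model,
                                                candidates=cands, beta=0.1))
        assert res.selected == () and res.objective_value == 0.0

    def test_cheaper_of_two_single_reaction_fixes_wins(self):
        # base: EX_A -> (gap) -> biomass(B); two candidate bridges
        model = MetabolicModel()
        model.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                    reversible=True, lower_bound=-1.0))
        model.add_reaction(Reaction(id="biomass", stoichiometry={"B": -1.0}))
        model.set_objective("biomass")
        mk = lambda rid: Reaction(id=rid, stoichiometry={"A": -1.0, "B": 1.0})
        cands = [
            GapFillCandidate(reaction=mk("fix_cheap"), kind="no_conf", penalty=0.4),
            GapFillCandidate(reaction=mk("fix_dear"), kind="no_conf", penalty=0.9),
        ]
        res = solve_gapfill_milp(GapFillProblem(model=model, candidates=cands,
                                                beta=0.1))
        assert res.selected == ("fix_cheap",)
        assert res.objective_value == pytest.approx(0.4)
        assert res.biomass_flux >= 0.1

    def test_infeasible_reports_unreachable_precursors(self):
        model = MetabolicModel()
        model.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                    reversible=True, lower_bound=-1.0))
        model.add_reaction(Reaction(id="biomass", stoichiometry={"Zfar": -1.0}))
        model.set_objective("biomass")
        cands = [
            GapFillCandidate(
                reaction=Reaction(id="useless", stoichiometry={"A": -1.0, "B": 1.0}),
                kind="no_conf", penalty=1.0,
            )
        ]
        with pytest.raises(GapFillInfeasibleError) as exc:
            solve_gapfill_milp(GapFillProblem(model=model, candidates=cands,
                                              beta=0.1))
        assert "Zfar" in exc.value.unreachable

    def test_matches_enumeration_on_random_gapped_networks(self):
        for s in range(6):
            net = fx.synth_network("gapped", size=4, seed=300 + s)
            cands = compute_penalties(
                build_candidate_pool(net.db, net.scored_annotations, net.model)
            )
            assert len(cands) <= 12
            res = solve_gapfill_milp(
                GapFillProblem(model=net.model, candidates=cands, beta=0.1)
            )
            oracle = enumerate_min_penalty(net.model, cands, 0.1)
            assert oracle is not None
            assert res.objective_value == pytest.approx(oracle[0], abs=1e-9)

    def test_raising_deadend_penalty_never_adds_exchanges(self):
        # the base route needs cofactor C (a dead-end: nothing makes it), the
        # candidate bypass does not; cheap dead-end exchanges win at penalty 1
        # and lose to the bypass at penalty 10
        model = MetabolicModel()
        model.add_reaction(Reaction(id="EX_A", stoichiometry={"A": -1.0},
                                    reversible=True, lower_bound=-1.0))
        model.add_reaction(
            Reaction(id="R1", stoichiometry={"A": -1.0, "C": -1.0, "B": 1.0})
        )
        model.add_reaction(Reaction(id="biomass", stoichiometry={"B": -1.0}))
        model.set_objective("biomass")
        db = ReactionDatabase()
        db.add(Reaction(id="bypass", stoichiometry={"A": -1.0, "B": 1.0}))
        counts = {}
        for pen in (1.0, 10.0):
            cands = compute_penalties(
                build_candidate_pool(db, [], model),
                default_penalty=2.0, deadend_penalty=pen,
            )
            res = solve_gapfill_milp(
                GapFillProblem(model=model, candidates=cands, beta=0.1)
            )
            counts[pen] = sum(r.startswith("EX_") for r in res.selected)
        assert counts[1.0] == 1 and counts[10.0] == 0
        assert counts[10.0] <= counts[1.0]

    def test_solution_minimality(self):
        """Dropping any selected flux-carrying reaction breaks the beta floor."""
        net = fx.synth_network("gapped", size=5, seed=77)
        cands = compute_penalties(
            build_candidate_pool(net.db, net.scored_annotations, net.model)
        )
        res = solve_gapfill_milp(
            GapFillProblem(model=net.model, candidates=cands, beta=0.1)
        )
        by_id = {c.reaction.id: c for c in cands}
        carrying = [r for r in res.selected if abs(res.fluxes[r]) > 1e-9]
        assert carrying
        for rid in carrying:
            m = net.model.copy()
            for other in res.selected:
                if other != rid:
                    m.add_reaction(by_id[other].reaction)
            assert lp_max_objective(m) < 0.1 - 1e-9


class TestAugment:
    def test_adds_with_provenance_and_penalty(self, chain3):
        net = fx.synth_network("gapped", size=4, seed=42)
        cands = compute_penalties(
            build_candidate_pool(net.db, net.scored_annotations, net.model)
        )
        res = solve_gapfill_milp(
            GapFillProblem(model=net.model, candidates=cands, beta=0.1)
        )
        aug = augment_model(net.model, res, cands)
        assert len(aug.reactions) == len(net.model.reactions) + len(res.selected)
        for rid in res.selected:
            assert aug.provenance[rid] == "gapfill"
            assert aug.gapfill_penalties[rid] > 0
        assert lp_max_objective(aug) >= 0.1 - 1e-9

    def test_empty_result_leaves_model_unchanged(self, chain3):
        cands = compute_penalties(build_candidate_pool(chain3.db, [], chain3.model))
        res = solve_gapfill_milp(
            GapFillProblem(model=chain3.model, candidates=cands, beta=0.1)
        )
        aug = augment_model(chain3.model, res, cands)
        assert set(aug.reactions) == set(chain3.model.reactions)
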