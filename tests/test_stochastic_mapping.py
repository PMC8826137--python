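"""Biogeographic stochastic mapping: sampling, counting, conservation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import biogeodec as bg


@pytest.fixture(scope="module")
def fitted_small():
    cfg = bg.SimConfig(n_tips=10, birth=0.5, death=0.0, crown_age=10, n_areas=3,
                       d=0.1, e=0.04, root_range="A")
    tree, geog, _ = bg.simulate_dataset(cfg, seed=42)
    engine = bg.DecLikelihood(tree, geog, "DEC")
    return tree, geog, engine


class TestSampler:
    def test_zero_rates_give_zero_anagenetic_events(self):
        tree = bg.Chronogram.from_newick("((t1:1,t2:1):1,t3:2);")
        geog = bg.GeographyTable(["A", "B"], {"t1": 1, "t2": 1, "t3": 1})
        engine = bg.DecLikelihood(tree, geog, "DEC")
        for h in bg.sample_histories(engine, 0.0, 0.0, 20, seed=1):
            assert h.anagenetic == []

    def test_same_seed_same_event_log(self, fitted_small):
        tree, _, engine = fitted_small
        h1 = bg.sample_histories(engine, 0.1, 0.04, 3, seed=7)
        h2 = bg.sample_histories(engine, 0.1, 0.04, 3, seed=7)
        for a, b in zip(h1, h2):
            assert a.to_event_log(tree).equals(b.to_event_log(tree))

    def test_tip_states_always_match_observations(self, fitted_small):
        tree, geog, engine = fitted_small
        for h in bg.sample_histories(engine, 0.15, 0.05, 50, seed=3):
            for t in range(tree.n_tips):
                st = int(engine.space.states[h.node_state[t]])
                assert st == geog.presence[tree.labels[t]]

    def test_trajectories_consistent_with_node_events(self, fitted_small):
        tree, _, engine = fitted_small
        (h,) = bg.sample_histories(engine, 0.15, 0.05, 1, seed=11)
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            segs = h.trajectory(v, float(tree.ages[p]), float(tree.ages[v]))
            assert segs[0][2] == h.start_state[v]
            assert segs[-1][2] == h.node_state[v]
            for (hi, lo, _), (hi2, lo2, _) in zip(segs[:-1], segs[1:]):
                assert lo == hi2
            for _, age, _, _, _ in h.events_on(v):
                assert tree.ages[v] <= age <= tree.ages[p]

    def test_node_frequencies_match_marginals_loosely(self, fitted_small):
        # a coarse (N=2000) version of the joint-vs-marginal consistency check
        tree, _, engine = fitted_small
        d, e = 0.1, 0.04
        anc = bg.ancestral_marginals(engine, d, e)
        N = 2000
        mapper = bg.StochasticMapper(engine, d, e, seed=5)
        freq = np.zeros((tree.n_nodes, engine.space.n_states))
        for _ in range(N):
            h = mapper.sample()
            freq[np.arange(tree.n_nodes), h.node_state] += 1
        freq /= N
        se = np.sqrt(anc.probs * (1 - anc.probs) / N)
        assert np.all(np.abs(freq - anc.probs) <= 4 * se + 1e-9)

    def test_single_branch_event_count_matches_analytic_expectation(self):
        # two-area instance: expected number of real jumps on an
        # endpoint-conditioned path, against direct quadrature of
        # E[N] = sum_{i!=j} q_ij \int P_ai(s) P_jb(t-s) ds / P_ab(t)
        tree = bg.Chronogram.from_newick("(t1:4,t2:4);")
        geog = bg.GeographyTable(["A", "B"], {"t1": 1, "t2": 2})
        engine = bg.DecLikelihood(tree, geog, "DEC")
        d, e, t = 0.3, 0.2, 4.0
        mapper = bg.StochasticMapper(engine, d, e, seed=17)
        Q = mapper.Qs[0]
        a, b = engine.space.index[1], engine.space.index[3]  # {A} -> {A,B}
        Pab = expm(Q * t)[a, b]

        expect = 0.0
        for i in range(Q.shape[0]):
            for j in range(Q.shape[0]):
                if i == j or Q[i, j] == 0:
                    continue
                val, _ = quad(
                    lambda s, i=i, j=j: expm(Q * s)[a, i] * expm(Q * (t - s))[j, b],
                    0, t, limit=200,
                )
                expect += Q[i, j] * val
        expect /= Pab

        N = 4000
        counts = [
            len(mapper._sample_segment(0, t, a, b, Pab, age_old=t)) for _ in range(N)
        ]
        mc, se = np.mean(counts), np.std(counts) / np.sqrt(N)
        assert mc == pytest.approx(expect, abs=4 * se)

    def test_conditioned_engine_refused(self, fitted_small):
        tree, geog, _ = fitted_small
        engine = bg.DecLikelihood(tree, geog, "DEC", condition_survival=True)
        with pytest.raises(ValueError):
            bg.StochasticMapper(engine, 0.1, 0.04)


class TestCounting:
    def _expansion_history(self, space, codes, events):
        h = bg.BioHistory(space=space, area_codes=codes,
                          node_state=np.zeros(1, dtype=int),
                          start_state=np.zeros(1, dtype=int))
        h.anagenetic = events
        return h

    def test_single_source_expansion(self):
        space = bg.build_state_space(3)
        # {A} -> {A,B} at age 1.0
        h = self._expansion_history(
            space, ["A", "B", "C"],
            [(0, 1.0, "expansion", space.index[0b001], space.index[0b011])],
        )
        c = bg.classify_and_count(h, np.array([0.0, 2.0]))
        assert c.d_pair[0, 0, 1] == 1.0
        assert c.dt[0, 1] == 1.0 and c.df[0, 0] == 1.0
        assert c.d_pair.sum() == 1.0

    def test_multi_source_expansion_splits_fractionally(self):
        space = bg.build_state_space(3)
        # {A,C} -> {A,B,C}
        h = self._expansion_history(
            space, ["A", "B", "C"],
            [(0, 1.0, "expansion", space.index[0b101], space.index[0b111])],
        )
        c = bg.classify_and_count(h, np.array([0.0, 2.0]))
        assert c.dt[0, 1] == pytest.approx(1.0)
        assert c.d_pair[0, 0, 1] == pytest.approx(0.5)
        assert c.d_pair[0, 2, 1] == pytest.approx(0.5)
        full = bg.classify_and_count(h, np.array([0.0, 2.0]), source_attribution="full")
        assert full.d_pair[0, 0, 1] == pytest.approx(1.0)

    def test_vicariance_counts_no_dispersal_but_counts_speciation(self):
        space = bg.build_state_space(2)
        h = bg.BioHistory(space=space, area_codes=["A", "B"],
                          node_state=np.zeros(1, dtype=int),
                          start_state=np.zeros(1, dtype=int))
        h.cladogenetic = [
            (0, 1.0, "vicariance", space.index[0b11], space.index[0b01], space.index[0b10])
        ]
        c = bg.classify_and_count(h, np.array([0.0, 2.0]))
        assert c.d_pair.sum() == 0.0
        assert c.speciation[0].tolist() == [1.0, 1.0]  # both areas retained by a daughter
        both = bg.classify_and_count(h, np.array([0.0, 2.0]), speciation_rule="both")
        assert both.speciation.sum() == 0.0

    def test_contractions_tallied_separately(self):
        space = bg.build_state_space(2)
        h = self._expansion_history(
            space, ["A", "B"],
            [(0, 0.5, "contraction", space.index[0b11], space.index[0b10])],
        )
        c = bg.classify_and_count(h, np.array([0.0, 2.0]))
        assert c.contraction[0, 0] == 1.0
        assert c.d_pair.sum() == 0.0

    def test_conservation_on_sampled_histories(self, fitted_small):
        tree, _, engine = fitted_small
        edges = np.arange(0.0, 11.0, 1.0)
        for h in bg.sample_histories(engine, 0.12, 0.05, 30, seed=9):
            c = bg.classify_and_count(h, edges)
            assert np.allclose(c.df.sum(axis=1), c.dt.sum(axis=1), atol=1e-9)


class TestFlows:
    def test_all_zero_histories_average_zero(self):
        space = bg.build_state_space(2)
        hs = [
            bg.BioHistory(space=space, area_codes=["A", "B"],
                          node_state=np.zeros(1, dtype=int),
                          start_state=np.zeros(1, dtype=int))
            for _ in range(4)
        ]
        counts = [bg.classify_and_count(h, np.array([0.0, 1.0])) for h in hs]
        flows = bg.summarize_flows(counts, ["A", "B"])
        assert np.all(flows.pair_mean == 0.0)

    def test_favored_corridor_dominates_average_flow(self):
        # one strongly favored corridor (A->B multiplier 10x the rest)
        mult = np.full((3, 3), 0.1)
        np.fill_diagonal(mult, 1.0)
        mult[0, 1] = 1.0
        epochs = bg.EpochModel(np.array([np.inf, 0.0]), mult[None])
        cfg = bg.SimConfig(n_tips=40, birth=0.5, death=0.0, crown_age=10, n_areas=3,
                           d=0.12, e=0.05, epochs=epochs, root_range="A")
        tree, geog, _ = bg.simulate_dataset(cfg, seed=8)
        engine = bg.DecLikelihood(tree, geog, "DEC", epochs)
        hs = bg.sample_histories(engine, 0.12, 0.05, 40, seed=2)
        edges = np.arange(0.0, 11.0, 1.0)
        counts = [bg.classify_and_count(h, edges) for h in hs]
        flows = bg.summarize_flows(counts, geog.areas)
        off = flows.pair_mean.copy()
        np.fill_diagonal(off, -1.0)
        assert np.unravel_index(np.argmax(off), off.shape) == (0, 1)
        roles = flows.role_table()
        assert roles.loc[roles.area == "A", "top_destination"].item() == "B"
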