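"""State space, rate matrices, cladogenesis, pruning likelihood, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biogeodec as bg
from biogeodec.range_evolution import SlicePropagator, build_clado_table

from oracles import all_ranges, brute_force, naive_rate_matrix


def _mask(space, areas_str, codes="ABCDEF"):
    return space.index[sum(1 << codes.index(ch) for ch in areas_str)]


class TestStateSpace:
    @pytest.mark.parametrize(
        "n_areas, max_size, expected",
        [(3, 3, 7), (6, 6, 63), (3, 2, 6), (1, 1, 1), (6, 2, 21)],
    )
    def test_nonempty_state_counts(self, n_areas, max_size, expected):
        space = bg.build_state_space(n_areas, max_size)
        assert space.n_nonempty == expected

    def test_deterministic_ordering(self):
        space = bg.build_state_space(3)
        labels = [space.label(i, "ABC") for i in range(space.n_states)]
        assert labels == ["-", "A", "B", "C", "AB", "AC", "BC", "ABC"]

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            bg.build_state_space(0)
        with pytest.raises(ValueError):
            bg.build_state_space(3, 4)


class TestRateMatrix:
    def test_expansion_and_contraction_rates(self):
        space = bg.build_state_space(3)
        Q = bg.build_rate_matrix(space, d=0.1, e=0.02, multipliers=np.ones((3, 3)))
        assert Q[_mask(space, "A"), _mask(space, "AB")] == pytest.approx(0.1)
        assert Q[_mask(space, "AB"), _mask(space, "A")] == pytest.approx(0.02)
        # single-area ranges contract into the absorbing null range
        assert Q[_mask(space, "A"), 0] == pytest.approx(0.02)
        assert np.all(Q[0] == 0.0)

    def test_multiplier_scales_expansion(self, neotropical):
        space = bg.build_state_space(6)
        Q = bg.build_rate_matrix(space, d=0.3, e=0.0, multipliers=neotropical.multipliers[0])
        assert Q[_mask(space, "B"), _mask(space, "BE")] == pytest.approx(0.3 * 0.7)

    def test_multi_source_expansion_sums_multipliers(self, neotropical):
        space = bg.build_state_space(6)
        m = neotropical.multipliers[1]  # young slice
        Q = bg.build_rate_matrix(space, d=1.0, e=0.0, multipliers=m)
        expect = m[0, 2] + m[1, 2]  # A->C plus B->C
        assert Q[_mask(space, "AB"), _mask(space, "ABC")] == pytest.approx(expect)

    @settings(max_examples=25, deadline=None)
    @given(
        d=st.floats(0, 2), e=st.floats(0, 2),
        seed=st.integers(0, 10_000), n_areas=st.integers(1, 4),
    )
    def test_rows_sum_to_zero(self, d, e, seed, n_areas):
        mult = np.random.default_rng(seed).uniform(0, 3, (n_areas, n_areas))
        space = bg.build_state_space(n_areas)
        Q = bg.build_rate_matrix(space, d, e, mult)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_agrees_with_naive_construction(self):
        rng = np.random.default_rng(3)
        mult = rng.uniform(0, 2, (3, 3))
        space = bg.build_state_space(3, 2)
        Q = bg.build_rate_matrix(space, 0.17, 0.06, mult)
        Q_naive = naive_rate_matrix(all_ranges(3, 2), 0.17, 0.06, mult)
        assert np.allclose(Q, Q_naive, atol=1e-12)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        space = bg.build_state_space(2)
        Q = bg.build_rate_matrix(space, 0.3, 0.1, np.ones((2, 2)))
        assert np.allclose(bg.transition_probabilities(Q, 0.0), np.eye(len(space)))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bg.transition_probabilities(np.zeros((2, 2)), -1.0)

    @pytest.mark.parametrize("d,t", [(0.05, 1.0), (0.2, 3.0), (1.0, 0.25)])
    def test_pure_expansion_closed_form(self, d, t):
        # 2 areas, e=0: {A} -> {A,B} is a one-way two-state chain
        space = bg.build_state_space(2)
        Q = bg.build_rate_matrix(space, d, 0.0, np.ones((2, 2)))
        P = bg.transition_probabilities(Q, t)
        assert P[_mask(space, "A"), _mask(space, "AB")] == pytest.approx(
            1 - np.exp(-d * t), abs=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(d=st.floats(0, 1), e=st.floats(0, 1), t=st.floats(0, 50), seed=st.integers(0, 99))
    def test_rows_are_stochastic(self, d, e, t, seed):
        mult = np.random.default_rng(seed).uniform(0, 2, (3, 3))
        Q = bg.build_rate_matrix(bg.build_state_space(3), d, e, mult)
        P = bg.transition_probabilities(Q, t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= 0)

    def test_propagator_matches_expm(self):
        rng = np.random.default_rng(11)
        Q = bg.build_rate_matrix(bg.build_state_space(3), 0.2, 0.07, rng.uniform(0, 1, (3, 3)))
        prop = SlicePropagator(Q)
        v = rng.uniform(0, 1, Q.shape[0])
        for t in (0.1, 2.0, 7.5):
            P = bg.transition_probabilities(Q, t)
            assert np.allclose(prop.apply(v, t), P @ v, atol=1e-9)
            assert np.allclose(prop.apply_transpose(v, t), P.T @ v, atol=1e-9)


class TestCladogenesis:
    def test_dec_single_area_copies(self):
        space = bg.build_state_space(2)
        events = bg.cladogenesis_events(0b01, "DEC", space)
        assert events == [(0b01, 0b01, 1.0, "sympatry-copy")]

    def test_dec_two_area_enumeration(self):
        space = bg.build_state_space(2)
        events = bg.cladogenesis_events(0b11, "DEC", space)
        assert len(events) == 6
        assert all(w == pytest.approx(1 / 6) for _, _, w, _ in events)
        kinds = sorted(k for _, _, _, k in events)
        assert kinds == ["subset-sympatry"] * 4 + ["vicariance"] * 2

    def test_divalike_is_vicariance_only(self):
        space = bg.build_state_space(3)
        events = bg.cladogenesis_events(0b111, "DIVALIKE", space)
        assert len(events) == 6  # 2^3 - 2 ordered bipartitions
        for l, r, w, kind in events:
            assert l & r == 0 and l | r == 0b111
            assert kind == "vicariance"
            assert w == pytest.approx(1 / 6)

    def test_bayarealike_copies_any_size(self):
        space = bg.build_state_space(2)
        assert bg.cladogenesis_events(0b11, "BAYAREALIKE", space) == [
            (0b11, 0b11, 1.0, "sympatry-copy")
        ]

    def test_empty_ancestor_rejected(self):
        with pytest.raises(ValueError):
            bg.cladogenesis_events(0, "DEC", bg.build_state_space(2))

    @pytest.mark.parametrize("family", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    @pytest.mark.parametrize("n_areas", [2, 3, 4])
    def test_weights_sum_to_one_for_every_ancestor(self, family, n_areas):
        space = bg.build_state_space(n_areas)
        table = build_clado_table(space, family)
        for g in range(1, space.n_states):
            weights = table.weight[table.anc == g]
            assert weights.sum() == pytest.approx(1.0)

    def test_founder_events_reweight(self):
        space = bg.build_state_space(3)
        events = bg.cladogenesis_events(0b001, "DEC", space, founder_weight=0.5)
        # 1 copy event (rel 1) + 4 founder events (rel 0.5 each)
        assert len(events) == 5
        total = sum(w for _, _, w, _ in events)
        assert total == pytest.approx(1.0)
        copy = [w for l, r, w, k in events if k == "sympatry-copy"][0]
        assert copy == pytest.approx(1 / 3)


class TestTreeLikelihood:
    def test_two_identical_tips_hand_value(self):
        tree = bg.Chronogram.from_newick("(t1:1,t2:1);")
        geog = bg.GeographyTable(["A", "B"], {"t1": 1, "t2": 1})
        lnl = bg.tree_log_likelihood(tree, geog, 0.0, 0.0)
        assert lnl == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_impossible_data_reported_as_minus_inf(self):
        # with no anagenetic change and copy-only cladogenesis, two tips in
        # different areas cannot be produced
        tree = bg.Chronogram.from_newick("(t1:1,t2:1);")
        geog = bg.GeographyTable(["A", "B"], {"t1": 1, "t2": 2})
        assert bg.tree_log_likelihood(tree, geog, 0.0, 0.0, "BAYAREALIKE") == -np.inf

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        nt = int(rng.integers(2, 5))
        family = ["DEC", "DIVALIKE", "BAYAREALIKE"][trial % 3]
        cfg = bg.SimConfig(n_tips=nt, birth=0.5, death=0.0, crown_age=8, n_areas=3,
                           d=0.15, e=0.05, root_range="AB")
        tree, geog, _ = bg.simulate_dataset(cfg, seed=trial)
        mults = np.stack([rng.uniform(0.05, 1.5, (3, 3)) for _ in range(2)])
        epochs = bg.EpochModel(np.array([np.inf, 4.0, 0.0]), mults)
        d, e = float(rng.uniform(0.01, 0.4)), float(rng.uniform(0.0, 0.25))
        lnl = bg.tree_log_likelihood(tree, geog, d, e, family, epochs)
        lik, _ = brute_force(tree, geog, d, e, family, epochs)
        assert lnl == pytest.approx(np.log(lik), abs=1e-9)

    def test_invariant_to_tip_order_in_geography(self, small_dataset):
        _, tree, geog, _ = small_dataset
        shuffled = bg.GeographyTable(
            list(geog.areas), dict(reversed(list(geog.presence.items())))
        )
        a = bg.tree_log_likelihood(tree, geog, 0.07, 0.03)
        b = bg.tree_log_likelihood(tree, shuffled, 0.07, 0.03)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariant_to_daughter_orientation(self, small_dataset):
        _, tree, geog, _ = small_dataset
        flipped = bg.Chronogram(
            tree.parent.copy(), tree.ages.copy(), tree.labels,
            {v: (r, l) for v, (l, r) in tree.children.items()},
        )
        a = bg.tree_log_likelihood(tree, geog, 0.07, 0.03)
        b = bg.tree_log_likelihood(flipped, geog, 0.07, 0.03)
        assert a == pytest.approx(b, abs=1e-12)

    def test_epoch_split_equals_unsplit_when_neutral(self, small_dataset):
        _, tree, geog, _ = small_dataset
        one_slice = bg.tree_log_likelihood(tree, geog, 0.1, 0.02)
        two_slices = bg.tree_log_likelihood(
            tree, geog, 0.1, 0.02,
            epochs=bg.EpochModel(np.array([np.inf, 4.0, 0.0]), np.ones((2, 3, 3))),
        )
        assert one_slice == pytest.approx(two_slices, abs=1e-10)

    def test_zero_rates_leave_partials_unchanged(self, small_dataset):
        _, tree, geog, _ = small_dataset
        engine = bg.DecLikelihood(tree, geog, "DEC")
        props = engine.propagators(0.0, 0.0)
        v = np.zeros(engine.space.n_states)
        v[3] = 1.0
        out = engine.propagate_branch(v, 0, props)
        assert np.allclose(out, v, atol=1e-12)


class TestFitting:
    def test_optimum_beats_fixed_start(self, small_dataset):
        _, tree, geog, _ = small_dataset
        fit = bg.fit_ml(tree, geog, "DEC")
        start_lnl = bg.tree_log_likelihood(tree, geog, 0.01, 0.01)
        assert fit.lnL >= start_lnl
        assert fit.n_params == 2

    def test_uniform_single_area_data_drives_rates_to_lower_bound(self):
        tree = bg.Chronogram.from_newick("((t1:1,t2:1):1,(t3:1.5,t4:1.5):0.5);")
        geog = bg.GeographyTable(["A", "B"], {f"t{i}": 1 for i in range(1, 5)})
        fit = bg.fit_ml(tree, geog, "DEC")
        assert fit.d < 1e-6 and fit.e < 1e-6

    def test_fit_is_deterministic(self, small_dataset):
        _, tree, geog, _ = small_dataset
        f1 = bg.fit_ml(tree, geog, "DEC")
        f2 = bg.fit_ml(tree, geog, "DEC")
        assert (f1.d, f1.e, f1.lnL) == (f2.d, f2.e, f2.lnL)


class TestModelSelection:
    def test_aic_aicc_formulas(self):
        fit = bg.FitResult("DEC", True, lnL=-383.72, n_params=2, d=0.16, e=0.0)
        (out,) = bg.model_selection([fit], n_obs=134)
        assert out.aic == pytest.approx(2 * 2 - 2 * (-383.72), abs=1e-12)
        assert out.aicc == pytest.approx(out.aic + 12 / 131, abs=1e-12)

    def test_identical_fits_share_weight(self):
        fits = [
            bg.FitResult("DEC", False, lnL=-100.0, n_params=2, d=0.1, e=0.1)
            for _ in range(2)
        ]
        out = bg.model_selection(fits, n_obs=50)
        assert [f.aic_weight for f in out] == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_and_best_has_zero_delta(self):
        rng = np.random.default_rng(0)
        fits = [
            bg.FitResult("DEC", False, lnL=float(-rng.uniform(50, 500)), n_params=2,
                         d=0.1, e=0.1)
            for _ in range(6)
        ]
        out = bg.model_selection(fits, n_obs=40)
        assert sum(f.aic_weight for f in out) == pytest.approx(1.0)
        assert min(f.delta_aic for f in out) == 0.0
        assert sum(f.aicc_weight for f in out) == pytest.approx(1.0)

    def test_aicc_undefined_for_tiny_samples(self):
        fit = bg.FitResult("DEC", False, lnL=-10.0, n_params=2, d=0.1, e=0.1)
        (out,) = bg.model_selection([fit], n_obs=3)
        assert np.isnan(out.aicc)
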