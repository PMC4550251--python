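"""Stochastic engine: payoffs, single steps, enumeration oracle, fixation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import asymgames as ag
from conftest import ALL_RULES


class TestPayoffAndFitness:
    def test_defector_among_defectors_zero(self, graph30, donation30):
        state = ag.PopulationState(np.ones(30, dtype=int), 2)
        assert ag.total_payoff(state, donation30, graph30, 0) == 0.0

    def test_cooperator_payoff_sums_neighbor_benefits(self, k4):
        tr = ag.ExplicitTraits(benefit=[0, 2, 3, 4], cost=[1.0, 0, 0, 0]).sample(
            4, np.random.default_rng(0)
        )
        fld = ag.donation_field(tr, k4)
        state = ag.PopulationState(np.zeros(4, dtype=int), 2)
        # (2-1) + (3-1) + (4-1)
        assert ag.total_payoff(state, fld, k4, 0) == pytest.approx(6.0)

    def test_fitness_values(self):
        assert ag.fitness(123.0, 0.0) == 1.0
        assert ag.fitness(0.0, 7.0) == 1.0
        assert ag.fitness(5.0, 0.01) == pytest.approx(np.exp(0.05))

    def test_fitness_monotone(self):
        assert ag.fitness(2.0, 0.3) > ag.fitness(1.0, 0.3) > 0


class TestStateStatistics:
    def test_frequencies_and_pairs(self, graph30, mixed_state30):
        p = mixed_state30.frequencies()
        assert p.sum() == pytest.approx(1.0)
        prs = mixed_state30.pair_frequencies(graph30)
        assert prs.sum() == pytest.approx(1.0)
        assert np.allclose(prs, prs.T, atol=1e-15)  # undirected symmetry
        q = mixed_state30.conditional_frequencies(graph30)
        assert np.allclose(q.sum(axis=1), 1.0)
        assert np.allclose(p[:, None] * q, prs, atol=1e-15)


class TestStep:
    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    def test_monomorphic_absorbing(self, graph30, donation30, rule):
        state = ag.PopulationState(np.zeros(30, dtype=int), 2)
        rng = np.random.default_rng(0)
        out = ag.step(state, rule, donation30, graph30, 0.5, rng)
        assert np.array_equal(out.strategies, state.strategies)

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    def test_at_most_one_change_and_conservation(self, graph30, donation30, rule,
                                                 mixed_state30):
        rng = np.random.default_rng(1)
        state = mixed_state30
        for _ in range(50):
            new = ag.step(state, rule, donation30, graph30, 0.1, rng)
            assert (new.strategies != state.strategies).sum() <= 1
            assert new.frequencies().sum() == pytest.approx(1.0)
            state = new

    def test_genotype_immutable_under_cultural(self, graph30, donation30):
        g0 = np.arange(30) % 2 + 1
        state = ag.PopulationState(np.arange(30) % 2, 2, genotype=g0)
        rng = np.random.default_rng(2)
        for rule in (ag.IMITATION, ag.PAIRWISE_COMPARISON):
            out = state
            for _ in range(40):
                out = ag.step(out, rule, donation30, graph30, 0.2, rng)
            assert np.array_equal(out.genotype, g0)

    def test_genotype_copied_under_genetic(self, graph30, donation30):
        g0 = np.arange(30) % 3 + 1
        state = ag.PopulationState(np.arange(30) % 2, 2, genotype=g0)
        rng = np.random.default_rng(3)
        for rule in (ag.DEATH_BIRTH, ag.BIRTH_DEATH):
            prev = state
            for _ in range(40):
                new = ag.step(prev, rule, donation30, graph30, 0.2, rng)
                # genotype counts change by at most one per elementary update
                diff = np.abs(
                    np.bincount(new.genotype, minlength=4)
                    - np.bincount(prev.genotype, minlength=4)
                )
                assert diff.sum() <= 2 and diff.max() <= 1
                prev = new

    def test_db_transition_distribution_matches_enumeration(self):
        """Empirical DB one-step outcomes vs exhaustive enumeration (8 vertices)."""
        g = ag.random_regular_graph(8, 3, seed=4)
        tr = ag.assign_traits(g, ag.GaussianTraits(3.0, 0.5, 0.5, 0.1), seed=5)
        fld = ag.donation_field(tr, g)
        s0 = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        state = ag.PopulationState(s0, 2)
        beta = 0.05
        tensor = fld.payoff_tensor(g)
        pi = np.array([ag.total_payoff(state, fld, g, i) for i in range(8)])
        # exact P(state'): uniform death x fitness-proportional replacement
        probs: dict[tuple, float] = {}
        for i in range(8):
            w = np.exp(beta * pi[g.neighbors[i]])
            w /= w.sum()
            for l in range(3):
                new = s0.copy()
                new[i] = s0[g.neighbors[i, l]]
                key = tuple(new)
                probs[key] = probs.get(key, 0.0) + (1 / 8) * w[l]
        n_draws = 20_000
        rng = np.random.default_rng(6)
        counts: dict[tuple, int] = {}
        for _ in range(n_draws):
            out = ag.step(state, ag.DEATH_BIRTH, fld, g, beta, rng)
            key = tuple(out.strategies)
            counts[key] = counts.get(key, 0) + 1
        assert set(counts) <= set(probs)
        for key, p in probs.items():
            se = np.sqrt(p * (1 - p) * n_draws)
            assert abs(counts.get(key, 0) - p * n_draws) < 4 * se + 1


class TestExactStepExpectation:
    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    def test_neutral_martingale(self, graph30, donation30, rule):
        rng = np.random.default_rng(7)
        for _ in range(10):
            s = rng.integers(0, 2, 30)
            e = ag.exact_step_expectation(
                ag.PopulationState(s, 2), rule, donation30, graph30, 0.0
            )
            assert np.max(np.abs(e)) < 1e-12

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    def test_frequency_conservation(self, graph30, donation30, rule, mixed_state30):
        e = ag.exact_step_expectation(mixed_state30, rule, donation30, graph30, 0.3)
        assert abs(e.sum()) < 1e-14

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    def test_linear_in_beta_for_small_beta(self, graph30, donation30, rule, mixed_state30):
        e1 = ag.exact_step_expectation(mixed_state30, rule, donation30, graph30, 1e-4)[0]
        e2 = ag.exact_step_expectation(mixed_state30, rule, donation30, graph30, 2e-4)[0]
        assert e2 / e1 == pytest.approx(2.0, rel=1e-3)

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.name)
    @pytest.mark.parametrize("beta", [0.0, 0.01, 0.5])
    def test_monte_carlo_matches_enumeration(self, graph30, donation30, mixed_state30,
                                             rule, beta):
        exact = ag.exact_step_expectation(mixed_state30, rule, donation30, graph30, beta)[0]
        mean, se = ag.sample_step_deltas(
            mixed_state30, rule, donation30, graph30, beta, 100_000, seed=42
        )
        assert abs(mean - exact) <= 3 * max(se, 1e-12)

    def test_single_defector_imitation_negative(self, graph30):
        tr = ag.assign_traits(graph30, ag.ConstantTraits(3.0, 1.0), seed=0)
        fld = ag.donation_field(tr, graph30)
        s = np.zeros(30, dtype=int)
        s[4] = 1
        state = ag.PopulationState(s, 2)
        assert ag.exact_step_expectation(state, ag.IMITATION, fld, graph30, 0.01)[0] < 0
        assert ag.exact_step_expectation(state, ag.IMITATION, fld, graph30, 0.0)[0] == \
            pytest.approx(0.0, abs=1e-15)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    rule_idx=st.integers(0, 3),
    k=st.sampled_from([3, 4]),
)
def test_neutral_martingale_property(seed, rule_idx, k):
    """E[dp] = 0 at beta = 0 for every rule on random graphs and states."""
    rng = np.random.default_rng(seed)
    g = ag.random_regular_graph(16, k, seed=seed % 50)
    tr = ag.VertexTraits(benefit=rng.normal(3, 1, 16), cost=rng.normal(0.5, 0.4, 16))
    fld = ag.donation_field(tr, g)
    s = rng.integers(0, 2, 16)
    e = ag.exact_step_expectation(
        ag.PopulationState(s, 2), ALL_RULES[rule_idx], fld, g, 0.0
    )
    assert np.max(np.abs(e)) < 1e-12


class TestIncrementalPayoffs:
    def test_kernel_payoffs_consistent_after_many_updates(self, graph30, donation30):
        """Incremental payoff caching agrees with a full recompute."""
        from asymgames import _kernels

        tensor = donation30.payoff_tensor(graph30)
        s = (np.arange(30) % 2).astype(np.int64)
        pi = _kernels.recompute_payoffs(s, graph30.neighbors, tensor)
        counts = np.bincount(s, minlength=2)
        np.random.seed(0)
        for t in range(5000):
            _kernels.elementary_update(
                0, s, pi, graph30.neighbors, graph30.neighbor_pos, tensor, 0.3, counts
            )
            if t % 500 == 0:
                fresh = _kernels.recompute_payoffs(s, graph30.neighbors, tensor)
                assert np.max(np.abs(pi - fresh)) < 1e-9
        fresh = _kernels.recompute_payoffs(s, graph30.neighbors, tensor)
        assert np.max(np.abs(pi - fresh)) < 1e-9


class TestRunToFixation:
    def test_initial_monomorphic(self, graph30, donation30):
        state = ag.PopulationState(np.zeros(30, dtype=int), 2)
        res = ag.run_to_fixation(state, ag.DEATH_BIRTH, donation30, graph30, 0.1, rng=1)
        assert res.absorbed == 0 and res.n_updates == 0 and res.status == "fixated"

    def test_max_updates_reported_not_raised(self, graph30, donation30, mixed_state30):
        res = ag.run_to_fixation(
            mixed_state30, ag.DEATH_BIRTH, donation30, graph30, 0.0, rng=2, max_updates=5
        )
        assert res.status == "max_updates" and res.absorbed is None

    def test_trajectory_recording(self, graph30, donation30, mixed_state30):
        res = ag.run_to_fixation(
            mixed_state30, ag.DEATH_BIRTH, donation30, graph30, 0.0, rng=3,
            record_trajectory=True,
        )
        assert res.trajectory is not None
        assert res.trajectory[0] == pytest.approx(0.5)
        assert res.trajectory[-1] in (0.0, 1.0)

    def test_strong_selection_birth_death_favors_defection(self):
        g = ag.random_regular_graph(30, 3, seed=9)
        tr = ag.assign_traits(g, ag.ConstantTraits(3.0, 1.0), seed=0)
        fld = ag.donation_field(tr, g)
        rng = np.random.default_rng(10)
        wins_d = 0
        for _ in range(40):
            s = (rng.random(30) < 0.5).astype(int)
            if s.min() == s.max():
                continue
            res = ag.run_to_fixation(ag.PopulationState(s, 2), ag.BIRTH_DEATH, fld, g,
                                     beta=2.0, rng=rng)
            wins_d += res.absorbed == 1
        assert wins_d >= 35


@pytest.fixture(scope="module")
def small_profile():
    g = ag.random_regular_graph(20, 3, seed=12)
    tr = ag.assign_traits(g, ag.ConstantTraits(3.0, 1.0), seed=1)
    fld = ag.donation_field(tr, g)
    return ag.delta_profile(fld, g, ag.DEATH_BIRTH, 0.0,
                            min_samples_per_bin=200, rng=13, cycle_budget=20_000)


class TestDeltaProfile:
    def test_boundaries_identically_zero(self, small_profile):
        assert small_profile.mean_delta[0] == 0.0
        assert small_profile.mean_delta[-1] == 0.0

    def test_neutral_interior_within_three_se(self, small_profile):
        inner = slice(1, -1)
        ok = np.abs(small_profile.mean_delta[inner]) <= \
            3 * small_profile.stderr[inner] + 1e-15
        assert ok.mean() > 0.9  # 3-sigma bound, allow rare excursions

    def test_counts_reached(self, small_profile):
        assert small_profile.status == "ok"
        assert small_profile.count[1:-1].min() >= 200

    def test_determinism(self):
        g = ag.random_regular_graph(20, 3, seed=12)
        tr = ag.assign_traits(g, ag.ConstantTraits(3.0, 1.0), seed=1)
        fld = ag.donation_field(tr, g)
        kwargs = dict(min_samples_per_bin=50, rng=77, cycle_budget=5_000)
        a = ag.delta_profile(fld, g, ag.PAIRWISE_COMPARISON, 0.1, **kwargs)
        b = ag.delta_profile(fld, g, ag.PAIRWISE_COMPARISON, 0.1, **kwargs)
        assert np.array_equal(a.mean_delta, b.mean_delta)
        assert np.array_equal(a.count, b.count)

    def test_partial_status_on_tiny_budget(self, graph30, donation30):
        prof = ag.delta_profile(donation30, graph30, ag.DEATH_BIRTH, 0.01,
                                min_samples_per_bin=10_000, rng=5, cycle_budget=10)
        assert prof.status == "partial"

    def test_tsv_round_trip(self, tmp_path, small_profile):
        p = tmp_path / "profile.tsv"
        small_profile.write_tsv(p)
        back = ag.DeltaProfile.read_tsv(p)
        assert np.array_equal(back.mean_delta, small_profile.mean_delta)
        assert np.array_equal(back.count, small_profile.count)
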