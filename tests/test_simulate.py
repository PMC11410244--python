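"""Stochastic serial-passage core: growth, sampling, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import graphpassage as gp
from graphpassage.deterministic import growth_map
from graphpassage.simulate import (
    PopulationParams,
    PopulationState,
    PostGrowthState,
    _sample_arrays,
    make_initial_state,
    run_ensemble,
    run_trajectory,
    sample_bottleneck,
)

SEED = 0


class TestParams:
    def test_st_resolved_from_s_and_t(self):
        p = PopulationParams(B=100, s=0.2, t=math.log(100))
        assert p.st == pytest.approx(0.2 * math.log(100))

    def test_s_resolved_from_st(self):
        p = PopulationParams(B=100, st=0.01)
        assert p.s == pytest.approx(0.01 / math.log(100))

    def test_inconsistent_s_t_st_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PopulationParams(B=100, st=0.5, s=0.2, t=1.0)

    def test_selection_parameter_required(self):
        with pytest.raises(ValueError, match="st"):
            PopulationParams(B=100)


class TestGrow:
    def test_absorbing_fractions_are_fixed_points(self):
        params = PopulationParams(B=100, st=0.3)
        state = PopulationState(M=[0, 100], W=[100, 0])
        post = gp.grow(state, params)
        xp = post.Mp / post.Np
        assert xp[0] == 0.0 and xp[1] == 1.0

    def test_growth_map_value(self):
        # x = 1e-3 under st = 0.2 ln(100): enrichment to ~2.508e-3
        st_ = 0.2 * math.log(100)
        assert growth_map(1e-3, st_) == pytest.approx(2.508094e-3, rel=1e-6)

    def test_growth_map_doubling(self):
        assert growth_map(0.5, math.log(2)) == pytest.approx(2 / 3)

    def test_fraction_depends_only_on_product_st(self):
        state = PopulationState(M=[17], W=[83])
        for s, t in [(0.1, 3.0), (0.3, 1.0), (0.03, 10.0)]:
            post = gp.grow(state, PopulationParams(B=100, s=s, t=t))
            assert post.Mp[0] / post.Np[0] == pytest.approx(growth_map(0.17, 0.3))

    def test_per_type_exponential_sizes(self):
        params = PopulationParams(B=100, s=0.2, t=math.log(100))
        post = gp.grow(PopulationState(M=[10], W=[90]), params)
        assert post.Wp[0] == pytest.approx(9000)
        assert post.Mp[0] == pytest.approx(10 * 100**1.2)

    @given(
        x=st.floats(1e-6, 1 - 1e-6),
        st1=st.floats(-1.0, 1.0),
        dx=st.floats(1e-6, 0.1),
        dst=st.floats(1e-6, 0.5),
    )
    def test_growth_map_strictly_increasing_in_x_and_st(self, x, st1, dx, dst):
        x2 = min(x + dx, 1 - 1e-9)
        assert growth_map(x2, st1) > growth_map(x, st1)
        assert growth_map(x, st1 + dst) > growth_map(x, st1)


class TestSampleBottleneck:
    def test_leaf_receives_m_O_B_mutants_on_average(self):
        # all-mutant center after growth: E[leaf mutants] = m_O * B = 50
        g = gp.build_star(5, 0.05, 1 / 10, "receive_B")
        params = PopulationParams(B=100, st=0.01)
        post = gp.grow(PopulationState(M=[100, 0, 0, 0, 0], W=[0, 100, 100, 100, 100]), params)
        R = 4000
        Mp = np.tile(post.Mp, (R, 1))
        Wp = np.tile(post.Wp, (R, 1))
        newM, _ = _sample_arrays(Mp, Wp, g, 100, np.random.default_rng(SEED))
        se = newM[:, 1].std(ddof=1) / math.sqrt(R)
        assert newM[:, 1].mean() == pytest.approx(50, abs=3 * se)

    def test_fully_mutant_population_stays_fully_mutant(self):
        g = gp.build_clique(3, 0.1)
        params = PopulationParams(B=50, st=0.1)
        post = gp.grow(PopulationState(M=[50, 50, 50], W=[0, 0, 0]), params)
        new = sample_bottleneck(post, g, params, np.random.default_rng(SEED))
        assert np.all(new.W == 0)
        assert new.M.sum() > 0

    def test_empty_source_sends_nothing(self):
        g = gp.build_clique(2, 0.5)
        params = PopulationParams(B=10, st=0.0)
        post = PostGrowthState(Mp=np.array([0.0, 0.0]), Wp=np.array([0.0, 1000.0]))
        new = sample_bottleneck(post, g, params, np.random.default_rng(SEED))
        assert new.M.sum() == 0

    def test_oversized_sampling_probability_rejected(self):
        # post-growth deme far smaller than m * B: p = m B / N' > 1
        g = gp.build_clique(2, 0.5)
        params = PopulationParams(B=1000, st=0.0)
        post = PostGrowthState(Mp=np.array([10.0, 10.0]), Wp=np.array([10.0, 10.0]))
        with pytest.raises(ValueError, match="exceeds 1"):
            sample_bottleneck(post, g, params, np.random.default_rng(SEED))

    def test_conservation_in_expectation_receive_B(self):
        # every deme's mean bottleneck size equals B under receive_B
        g = gp.build_star(5, 0.05, 1 / 10, "receive_B")
        params = PopulationParams(B=100, st=0.01)
        post = gp.grow(PopulationState(M=[100, 0, 0, 0, 0], W=[0, 100, 100, 100, 100]), params)
        R = 10_000
        Mp = np.tile(post.Mp, (R, 1))
        Wp = np.tile(post.Wp, (R, 1))
        newM, newW = _sample_arrays(Mp, Wp, g, 100, np.random.default_rng(SEED))
        tot = newM + newW
        se = tot.std(axis=0, ddof=1) / math.sqrt(R)
        assert np.all(np.abs(tot.mean(axis=0) - 100) < 3 * se)

    def test_conservation_in_expectation_contribute_B(self):
        # mean deme size equals B times the migration-matrix column sum
        g = gp.build_star(4, 0.09, 3.0, "contribute_B")
        params = PopulationParams(B=100, st=0.0)
        post = gp.grow(PopulationState(M=[0, 100, 0, 0], W=[100, 0, 100, 100]), params)
        R = 10_000
        Mp = np.tile(post.Mp, (R, 1))
        Wp = np.tile(post.Wp, (R, 1))
        newM, newW = _sample_arrays(Mp, Wp, g, 100, np.random.default_rng(SEED))
        tot = newM + newW
        expected = 100 * g.column_sums()
        se = tot.std(axis=0, ddof=1) / math.sqrt(R)
        assert np.all(np.abs(tot.mean(axis=0) - expected) < 3 * se)


class TestInitialState:
    def test_center_placement(self):
        g = gp.build_star(5, 0.05, 1 / 10)
        s = make_initial_state(g, PopulationParams(B=100, st=0.01), "center")
        assert s.M.tolist() == [100, 0, 0, 0, 0]
        assert s.W.tolist() == [0, 100, 100, 100, 100]

    def test_partial_count_in_well_mixed(self):
        g = gp.build_well_mixed(500)
        s = make_initial_state(g, PopulationParams(B=500, st=0.01), "count:100")
        assert s.M.tolist() == [100] and s.W.tolist() == [400]

    def test_count_in_chosen_deme_at_large_B(self):
        g = gp.build_clique(4, 0.01)
        s = make_initial_state(g, PopulationParams(B=1e7, st=0.5), "count:10000:0")
        assert s.M.tolist() == [10**4, 0, 0, 0]
        assert s.W.tolist() == [10**7 - 10**4, 10**7, 10**7, 10**7]

    def test_count_exceeding_B_rejected(self):
        g = gp.build_well_mixed(100)
        with pytest.raises(ValueError, match="exceeds"):
            make_initial_state(g, PopulationParams(B=100, st=0.01), "count:101")

    def test_center_on_non_star_rejected(self):
        g = gp.build_clique(4, 0.1)
        with pytest.raises(ValueError, match="star"):
            make_initial_state(g, PopulationParams(B=100, st=0.01), "center")


class TestTrajectories:
    def test_all_wild_type_is_extinct_at_step_zero(self):
        g = gp.build_clique(3, 0.1)
        params = PopulationParams(B=50, st=0.1)
        init = PopulationState(M=[0, 0, 0], W=[50, 50, 50])
        traj = run_trajectory(init, g, params, np.random.default_rng(SEED))
        assert traj.outcome == "extinct" and traj.absorption_step == 0
        assert traj.fractions.tolist() == [0.0]

    def test_all_mutant_is_fixed_at_step_zero(self):
        g = gp.build_clique(3, 0.1)
        params = PopulationParams(B=50, st=0.1)
        init = PopulationState(M=[50, 50, 50], W=[0, 0, 0])
        traj = run_trajectory(init, g, params, np.random.default_rng(SEED))
        assert traj.outcome == "fixed" and traj.absorption_step == 0

    def test_empty_population_rejected(self):
        g = gp.build_clique(2, 0.1)
        params = PopulationParams(B=10, st=0.0)
        with pytest.raises(ValueError, match="at least one"):
            run_trajectory(PopulationState(M=[0, 0], W=[0, 0]), g, params, np.random.default_rng(0))

    def test_star_center_trajectory_absorbs_and_starts_at_fifth(self):
        g = gp.build_star(5, 0.05, 1 / 10)
        params = PopulationParams(B=100, st=0.01, max_steps=10**5)
        init = make_initial_state(g, params, "center")
        traj = run_trajectory(init, g, params, np.random.default_rng(SEED))
        assert traj.fractions[0] == pytest.approx(0.2)  # 100 of 500
        assert traj.outcome in ("fixed", "extinct")
        assert traj.fractions[-1] in (0.0, 1.0)
        assert np.all((traj.fractions >= 0) & (traj.fractions <= 1))

    def test_unresolved_is_a_value_not_an_error(self):
        g = gp.build_clique(2, 0.1)
        params = PopulationParams(B=100, st=0.0, max_steps=2)
        res = run_ensemble(g, params, "deme:0", 50, rng=SEED)
        assert res.n_unresolved > 0
        assert np.all(res.absorption_steps[res.outcomes == 2] == -1)

    def test_neutral_fixation_probability_on_circulation(self):
        # st = 0 on a circulation: fixation probability = initial fraction
        g = gp.build_clique(2, 0.1)
        params = PopulationParams(B=50, st=0.0)
        res = run_ensemble(g, params, "deme:0", 20_000, rng=SEED, record_fractions=False)
        rho = res.n_fixed / res.reps
        assert rho == pytest.approx(0.5, abs=3 * math.sqrt(0.25 / res.reps))

    def test_same_seed_same_results(self):
        g = gp.build_star(5, 0.05, 1 / 10)
        params = PopulationParams(B=100, st=0.01)
        a = run_ensemble(g, params, "uniform", 300, rng=SEED)
        b = run_ensemble(g, params, "uniform", 300, rng=SEED)
        assert np.array_equal(a.outcomes, b.outcomes)
        assert np.array_equal(a.absorption_steps, b.absorption_steps)
        assert np.array_equal(a.fractions, b.fractions)
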