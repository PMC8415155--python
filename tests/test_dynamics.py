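import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from culturesim.config import SimulationConfig
from culturesim.dynamics import (
    StepReport,
    choose_culture_to_learn,
    choose_parent,
    learning_step,
    local_type_frequencies,
    mortality_step,
    mutate_preference,
    parent_weight,
    replacement_step,
    run_simulation,
    step,
)
from culturesim.state import (
    CONFORMITY,
    EMPTY_CULTURE,
    NOVELTY,
    Juvenile,
    initialize_population,
)

from conftest import make_state


class TestMortality:
    def test_zero_death_prob_changes_nothing(self, rng):
        cfg = SimulationConfig(grid_side=6, death_prob=0.0)
        state = initialize_population(cfg, rng)
        after, n = mortality_step(state, cfg, rng)
        assert n == 0
        assert after.equals(state)

    def test_certain_death_empties_the_lattice(self, rng):
        cfg = SimulationConfig(grid_side=6, death_prob=1.0)
        state = initialize_population(cfg, rng)
        after, n = mortality_step(state, cfg, rng)
        assert n == 36
        assert after.n_alive == 0
        assert (after.culture == EMPTY_CULTURE).all()

    def test_death_fraction_matches_binomial_rate(self):
        # binomial oracle: mean fraction over seeds within 3 sigma of p
        p = 0.2
        cfg = SimulationConfig(grid_side=128, death_prob=p)
        n_seeds, n_ind = 200, 128**2
        fracs = []
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            state = initialize_population(cfg, r)
            _, deaths = mortality_step(state, cfg, r)
            fracs.append(deaths / n_ind)
        sigma = np.sqrt(p * (1 - p) / (n_ind * n_seeds))
        assert abs(np.mean(fracs) - p) < 3 * sigma


class TestParentWeight:
    @pytest.mark.parametrize(
        "freq,inp,mode,expected",
        [
            (0.4, 0.4, "ceiling", 1.0),
            (1.0, 0.0, "ceiling", 0.0),
            (0.25, 0.75, "ceiling", 1.0),  # at or below the ideal: no penalty
            (0.75, 0.25, "ceiling", 0.5),
            (0.4, 0.4, "distance", 1.0),
            (1.0, 0.0, "distance", 0.0),
            (0.25, 0.75, "distance", 0.5),
        ],
    )
    def test_weight_arithmetic(self, freq, inp, mode, expected):
        assert parent_weight(freq, inp, mode) == pytest.approx(expected)

    @pytest.mark.parametrize("freq,inp", [(0.0, 0.5), (1.2, 0.5), (0.5, -0.1), (0.5, 1.5)])
    def test_domain_errors(self, freq, inp):
        with pytest.raises(ValueError):
            parent_weight(freq, inp)

    @given(
        freq=st.floats(min_value=0.01, max_value=1.0),
        inp=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_weight_bounds_and_ceiling_semantics(self, freq, inp):
        w = parent_weight(freq, inp, "ceiling")
        assert 0.0 <= w <= 1.0
        assert (w == 1.0) == (freq <= inp)
        wd = parent_weight(freq, inp, "distance")
        assert 0.0 <= wd <= 1.0
        assert (wd == 1.0) == (freq == inp)
        # the ceiling form never penalizes harder than the symmetric form
        assert w >= wd


class TestLocalFrequencies:
    def test_uniform_neighborhood(self):
        state = make_state([[3, 3, 3], [3, -1, 3], [3, 3, 3]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4)
        assert local_type_frequencies(state, (1, 1), cfg) == {3: 1.0}

    def test_even_split(self):
        state = make_state([[7, 7, 7], [7, -1, 8], [8, 8, 8]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4)
        freqs = local_type_frequencies(state, (1, 1), cfg)
        assert freqs == {7: 0.5, 8: 0.5}
        assert abs(sum(freqs.values()) - 1.0) < 1e-12

    def test_dead_neighbors_are_ignored(self):
        state = make_state([[5, -1, -1], [5, -1, -1], [6, -1, -1]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4)
        freqs = local_type_frequencies(state, (1, 1), cfg)
        assert freqs == {5: pytest.approx(2 / 3), 6: pytest.approx(1 / 3)}

    def test_empty_neighborhood_signals_empty_dict(self):
        state = make_state([[-1, -1, -1], [-1, -1, -1], [-1, -1, -1]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4)
        assert local_type_frequencies(state, (1, 1), cfg) == {}


class TestChooseParent:
    def test_single_candidate_is_certain(self, rng):
        state = make_state([[5, -1, -1], [-1, -1, -1], [-1, -1, -1]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4)
        for _ in range(20):
            assert choose_parent(state, (1, 1), cfg, rng) == (0, 0)

    def test_occupied_site_rejected(self, rng):
        state = make_state([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        with pytest.raises(ValueError):
            choose_parent(state, (1, 1), SimulationConfig(grid_side=3, n_initial_cultures=4), rng)

    def test_no_candidates_returns_none(self, rng):
        state = make_state([[-1, -1, -1], [-1, -1, -1], [-1, -1, -1]])
        assert choose_parent(state, (1, 1), SimulationConfig(grid_side=3, n_initial_cultures=4), rng) is None

    def test_uniform_fallback_when_all_weights_vanish(self, rng):
        # all neighbors one type (f=1) at inp=0: every weight is 0 in both modes
        state = make_state([[4, 4, 4], [4, -1, 4], [4, 4, 4]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4, ideal_neighbor_proportion=0.0)
        n_draws, k = 10_000, 8
        counts = {}
        for _ in range(n_draws):
            site = choose_parent(state, (1, 1), cfg, rng)
            counts[site] = counts.get(site, 0) + 1
        sigma = np.sqrt((1 / k) * (1 - 1 / k) * n_draws)
        for c in counts.values():
            assert abs(c - n_draws / k) < 3 * sigma
        assert len(counts) == k

    @pytest.mark.parametrize("mode", ["ceiling", "distance"])
    def test_weighted_sampling_distribution(self, rng, mode):
        # neighbors {A x6, B x2}, inp=0.25: w(A)=0.5, w(B)=1.0 in both modes,
        # so P(parent is type B) = 2*1.0 / (6*0.5 + 2*1.0) = 0.4
        state = make_state([[0, 0, 0], [0, -1, 0], [0, 1, 1]])
        cfg = SimulationConfig(
            grid_side=3, n_initial_cultures=4,
            ideal_neighbor_proportion=0.25, selection_mode=mode
        )
        n_draws = 10_000
        hits = 0
        for _ in range(n_draws):
            r, c = choose_parent(state, (1, 1), cfg, rng)
            hits += state.culture[r, c] == 1
        p = 0.4
        assert abs(hits / n_draws - p) < 3 * np.sqrt(p * (1 - p) / n_draws)


class TestMutatePreference:
    def test_zero_rate_is_identity(self, rng):
        cfg = SimulationConfig(preference_mutation_prob=0.0)
        assert all(
            mutate_preference(CONFORMITY, cfg, rng) == CONFORMITY for _ in range(100)
        )

    def test_certain_mutation_is_uniform_redraw(self, rng):
        cfg = SimulationConfig(preference_mutation_prob=1.0)
        n = 10_000
        flips = sum(mutate_preference(CONFORMITY, cfg, rng) == NOVELTY for _ in range(n))
        assert abs(flips / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestChooseCultureToLearn:
    def test_strict_bias_directions(self, rng):
        freqs = {10: 5 / 8, 11: 2 / 8, 12: 1 / 8}
        cfg = SimulationConfig(bias_mode="strict")
        assert choose_culture_to_learn(freqs, CONFORMITY, cfg, rng) == 10
        assert choose_culture_to_learn(freqs, NOVELTY, cfg, rng) == 12

    @pytest.mark.parametrize("pref", [CONFORMITY, NOVELTY])
    def test_tie_broken_uniformly(self, rng, pref):
        freqs = {0: 0.5, 1: 0.5}
        cfg = SimulationConfig(bias_mode="strict")
        n = 10_000
        ones = sum(choose_culture_to_learn(freqs, pref, cfg, rng) == 1 for _ in range(n))
        assert abs(ones / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_weighted_conformity_distribution(self, rng):
        # P(A) = 0.75^2 / (0.75^2 + 0.25^2) = 0.9
        freqs = {0: 0.75, 1: 0.25}
        cfg = SimulationConfig(bias_mode="weighted")
        n = 10_000
        a = sum(choose_culture_to_learn(freqs, CONFORMITY, cfg, rng) == 0 for _ in range(n))
        assert abs(a / n - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_weighted_novelty_single_type_fallback(self, rng):
        # sole type has 1 - f = 0: weights vanish, uniform fallback returns it
        cfg = SimulationConfig(bias_mode="weighted")
        assert choose_culture_to_learn({7: 1.0}, NOVELTY, cfg, rng) == 7

    def test_empty_frequencies_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_culture_to_learn({}, CONFORMITY, SimulationConfig(), rng)


class TestReplacement:
    def test_full_lattice_produces_no_juveniles(self, rng):
        cfg = SimulationConfig(grid_side=4)
        state = initialize_population(cfg, rng)
        after, juveniles = replacement_step(state, cfg, rng)
        assert juveniles == []
        assert after.equals(state)

    def test_single_vacancy_inherits_preference(self, rng):
        state = make_state([[1, 1, 1], [1, -1, 1], [1, 1, 1]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4, preference_mutation_prob=0.0)
        after, juveniles = replacement_step(state, cfg, rng)
        assert juveniles == [Juvenile((1, 1), CONFORMITY)]
        assert after.alive[1, 1]
        assert after.culture[1, 1] == EMPTY_CULTURE  # unlearned until learning phase

    def test_dead_lattice_stays_dead(self, rng):
        state = make_state([[-1] * 4] * 4)
        cfg = SimulationConfig(grid_side=4)
        after, juveniles = replacement_step(state, cfg, rng)
        assert juveniles == []
        assert after.n_alive == 0


class TestLearning:
    def test_certain_invention_mints_distinct_types(self, rng):
        state = make_state([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4, invention_prob=1.0)
        juveniles = [Juvenile((0, 0), CONFORMITY), Juvenile((2, 2), NOVELTY)]
        state.culture[0, 0] = EMPTY_CULTURE
        state.culture[2, 2] = EMPTY_CULTURE
        after, n_inv = learning_step(state, juveniles, cfg, rng)
        assert n_inv == 2
        assert after.next_culture_id == state.next_culture_id + 2
        assert {int(after.culture[0, 0]), int(after.culture[2, 2])} == {
            state.next_culture_id,
            state.next_culture_id + 1,
        }

    def test_single_available_type_is_learned(self, rng):
        state = make_state([[7, 7, 7], [7, -1, 7], [7, 7, 7]])
        state.alive[1, 1] = True  # juvenile placed, culture sentinel
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4, invention_prob=0.0)
        after, n_inv = learning_step(state, [Juvenile((1, 1), CONFORMITY)], cfg, rng)
        assert n_inv == 0
        assert after.culture[1, 1] == 7

    def test_isolated_juvenile_invents(self, rng):
        state = make_state([[-1, -1, -1], [-1, -1, -1], [-1, -1, -1]])
        state.alive[1, 1] = True
        state.next_culture_id = 16
        cfg = SimulationConfig(grid_side=3, n_initial_cultures=4, invention_prob=0.0)
        after, n_inv = learning_step(state, [Juvenile((1, 1), NOVELTY)], cfg, rng)
        assert n_inv == 1
        assert after.culture[1, 1] == 16

    def test_same_step_juveniles_are_not_tutors(self, rng):
        # two adjacent juveniles: each must survey only the adults
        state = make_state([[5, 5, 5, 5]] * 4)
        for site in ((1, 1), (1, 2)):
            state.culture[site] = EMPTY_CULTURE
        juveniles = [Juvenile((1, 1), NOVELTY), Juvenile((1, 2), NOVELTY)]
        cfg = SimulationConfig(grid_side=4, invention_prob=0.0)
        after, _ = learning_step(state, juveniles, cfg, rng)
        assert after.culture[1, 1] == 5 and after.culture[1, 2] == 5


class TestStep:
    def test_no_mortality_is_a_no_op_besides_time(self, rng):
        cfg = SimulationConfig(grid_side=5, death_prob=0.0)
        state = initialize_population(cfg, rng)
        after, report = step(state, cfg, rng)
        assert report == StepReport(0, 0, 0, 0, 0)
        assert after.timestep == 1
        assert np.array_equal(after.culture, state.culture)

    def test_same_seed_same_trajectory(self):
        cfg = SimulationConfig(grid_side=8, n_timesteps=0, seed=5)
        s1 = initialize_population(cfg, np.random.default_rng(5))
        s2 = initialize_population(cfg, np.random.default_rng(5))
        r1, r2 = np.random.default_rng(99), np.random.default_rng(99)
        for _ in range(10):
            s1, _ = step(s1, cfg, r1)
            s2, _ = step(s2, cfg, r2)
            assert s1.equals(s2)

    def test_step_invariants(self):
        cfg = SimulationConfig(grid_side=10, seed=2, ideal_neighbor_proportion=0.3)
        rng = np.random.default_rng(2)
        state = initialize_population(cfg, rng)
        for _ in range(15):
            before = state
            state, report = step(state, cfg, rng)
            # no living site carries the sentinel after a full step
            assert (state.culture[state.alive] != EMPTY_CULTURE).all()
            # counter moves exactly with inventions
            assert state.next_culture_id == before.next_culture_id + report.n_inventions
            assert report.n_births <= (10 * 10 - before.n_alive) + report.n_deaths
            assert report.n_inventions <= report.n_births
            state.validate()

    def test_surviving_adults_keep_their_preferences(self):
        # preference composition changes only through replacement: adults who
        # survive mortality carry their preference through the whole step
        cfg = SimulationConfig(grid_side=10, seed=7)
        rng = np.random.default_rng(7)
        state = initialize_population(cfg, rng)
        for _ in range(10):
            before_pref = state.preference.copy()
            state, _ = mortality_step(state, cfg, rng)
            survivors = state.alive.copy()
            state, juveniles = replacement_step(state, cfg, rng)
            state, _ = learning_step(state, juveniles, cfg, rng)
            state.timestep += 1
            assert np.array_equal(
                state.preference[survivors], before_pref[survivors]
            )

    def test_frozen_culture_with_single_type_and_no_invention(self):
        cfg = SimulationConfig(
            grid_side=8, n_initial_cultures=1, invention_prob=0.0, seed=3
        )
        rng = np.random.default_rng(3)
        state = initialize_population(cfg, rng)
        for _ in range(20):
            state, _ = step(state, cfg, rng)
            assert set(np.unique(state.culture)) <= {EMPTY_CULTURE, 0}

    @given(
        side=st.integers(min_value=3, max_value=7),
        inp=st.floats(min_value=0.0, max_value=1.0),
        death=st.floats(min_value=0.0, max_value=1.0),
        bias=st.sampled_from(["strict", "weighted"]),
        sel=st.sampled_from(["ceiling", "distance"]),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_step_invariants_hold_across_parameter_space(
        self, side, inp, death, bias, sel, seed
    ):
        cfg = SimulationConfig(
            grid_side=side,
            n_initial_cultures=9,
            death_prob=death,
            ideal_neighbor_proportion=inp,
            bias_mode=bias,
            selection_mode=sel,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        state = initialize_population(cfg, rng)
        for _ in range(3):
            prev_counter = state.next_culture_id
            state, report = step(state, cfg, rng)
            assert (state.culture[state.alive] != EMPTY_CULTURE).all()
            assert state.next_culture_id >= prev_counter
            state.validate()


class TestRunSimulation:
    def test_zero_timesteps_gives_single_record(self):
        traj = run_simulation(SimulationConfig(grid_side=8, n_timesteps=0, seed=1))
        assert len(traj.records) == 1
        assert traj.records[0].timestep == 0

    def test_records_bracket_the_run(self):
        traj = run_simulation(
            SimulationConfig(grid_side=8, n_timesteps=25, record_every=10, seed=1)
        )
        times = [r.timestep for r in traj.records]
        assert times == [0, 10, 20, 25]
        assert traj.final_state.timestep == 25

    def test_novelty_selected_for_at_low_ideal_proportion(self):
        # scaled-down check of the rare-types-favored regime
        cfg = SimulationConfig(
            grid_side=32, n_timesteps=400, ideal_neighbor_proportion=0.10,
            record_every=100,
        )
        finals = [
            run_simulation(cfg.replace(seed=s), keep_final_state=False)
            .final_record.novelty_fraction
            for s in range(3)
        ]
        assert np.mean(finals) > 0.5
        assert all(f > cfg.initial_novelty_fraction for f in finals)

    def test_preference_drift_is_neutral_with_homogeneous_culture(self):
        # with one culture type and no invention every parent weight is equal,
        # so preference transmission is a martingale: mean change ~ 0
        cfg = SimulationConfig(
            grid_side=32, n_timesteps=300, n_initial_cultures=1,
            invention_prob=0.0, record_every=300,
        )
        deltas = []
        for s in range(12):
            traj = run_simulation(cfg.replace(seed=s), keep_final_state=False)
            deltas.append(
                traj.records[-1].novelty_fraction - traj.records[0].novelty_fraction
            )
        sem = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * sem + 1e-12
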