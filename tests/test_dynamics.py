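"""Unit tests for the individual state-transition rules."""

import math
import random

import pytest

from msabm.dynamics import (
    PulseEvent,
    activate_by_virus,
    attempt_duplication,
    count_tregs_in_radius,
    decrement_life_and_reap,
    introduce_agents,
    move_agent,
    pulse_events,
    recover_myelin,
    teff_attack,
    teff_duplication_probability,
    treg_suppress,
)
from msabm.params import Params
from msabm.world import CellState, Species, World


def make_world(seed=0, **kwargs) -> World:
    return World(Params(**kwargs), seed)


class TestPulseEvents:
    def test_zero_probability_always_empty(self):
        params = Params(pulse_prob=0.0, virus_pulse_prob=0.0)
        rng = random.Random(0)
        assert all(pulse_events(s, params, rng) == [] for s in range(2000))

    def test_per_day_trials_only_on_day_steps(self):
        params = Params(pulse_prob=1.0, pulse_mode="per_day")
        rng = random.Random(0)
        for s in range(50):
            events = pulse_events(s, params, rng)
            if s % params.steps_per_day == 0:
                assert len(events) == 3  # one certain success per species
            else:
                assert events == []

    def test_per_day_rate_is_about_100_per_year(self):
        # 5 simulated years: 1825 daily Bernoulli trials at p = 100/365
        params = Params(pulse_mode="per_day")
        rng = random.Random(1)
        years = 5
        teff_pulses = sum(
            any(e.species is Species.TEFF for e in pulse_events(s, params, rng))
            for s in range(years * params.steps_per_year)
        )
        # E = 100/yr, binomial SE over 5 years ~ 19
        assert teff_pulses / years == pytest.approx(100, abs=12)

    def test_per_step_rate_is_about_1000_per_year(self):
        # the literal every-step reading: 3650 trials/yr at p = 100/365
        params = Params(pulse_mode="per_step")
        rng = random.Random(1)
        virus_pulses = sum(
            any(e.species is Species.VIRUS for e in pulse_events(s, params, rng))
            for s in range(params.steps_per_year)
        )
        assert virus_pulses == pytest.approx(1000, abs=90)

    def test_virus_override_silences_only_virus(self):
        params = Params(pulse_prob=1.0, virus_pulse_prob=0.0, pulse_mode="per_step")
        rng = random.Random(0)
        species = {e.species for e in pulse_events(0, params, rng)}
        assert species == {Species.TEFF, Species.TREG}

    def test_introduced_t_cells_are_resting_with_valid_life(self):
        w = make_world()
        born = introduce_agents(
            w, [PulseEvent(Species.TEFF, 5), PulseEvent(Species.VIRUS, 2)]
        )
        assert len(born) == 7
        for a in born:
            assert 1 <= a.life <= 2 * w.params.hlife
            if a.species is Species.VIRUS:
                assert a.state is None
            else:
                assert a.state is CellState.RESTING


class TestMovement:
    def test_moves_to_von_neumann_neighbor(self):
        w = make_world()
        a = w.spawn(Species.TEFF, CellState.RESTING, (5, 5), 10)
        for _ in range(50):
            old = a.pos
            new = move_agent(w, a)
            assert new in {
                ((old[0] - 1) % 51, old[1]),
                ((old[0] + 1) % 51, old[1]),
                (old[0], (old[1] - 1) % 51),
                (old[0], (old[1] + 1) % 51),
            }
            assert a in w.occupancy_at(new)

    def test_choice_is_uniform(self):
        # tally destination of single moves from a fixed start
        w = make_world(seed=3)
        a = w.spawn(Species.TREG, CellState.RESTING, (10, 10), 10)
        tally = {}
        for _ in range(10 ** 4):
            w.relocate(a, (10, 10))
            dest = move_agent(w, a)
            tally[dest] = tally.get(dest, 0) + 1
        freqs = [c / 10 ** 4 for c in tally.values()]
        assert len(tally) == 4
        assert all(abs(f - 0.25) < 0.02 for f in freqs)


class TestActivation:
    def test_no_virus_no_activation(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.RESTING, (5, 5), 10)
        assert activate_by_virus(w, t) is False
        assert t.state is CellState.RESTING

    def test_virus_in_radius_consumed_and_cell_activates(self):
        w = make_world()
        t = w.spawn(Species.TREG, CellState.RESTING, (5, 5), 10)
        v = w.spawn(Species.VIRUS, None, (5, 7), 10)  # distance 2 <= 3
        assert activate_by_virus(w, t) is True
        assert t.state is CellState.ACTIVE
        assert not v.alive
        assert w.population_counts()["virus"] == 0

    def test_virus_beyond_radius_ignored(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.RESTING, (0, 0), 10)
        w.spawn(Species.VIRUS, None, (0, 4), 10)  # distance 4 > 3
        assert activate_by_virus(w, t) is False
        assert t.state is CellState.RESTING

    def test_nearest_virus_is_taken(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.RESTING, (10, 10), 10)
        near = w.spawn(Species.VIRUS, None, (10, 11), 10)
        far = w.spawn(Species.VIRUS, None, (10, 13), 10)
        assert activate_by_virus(w, t)
        assert not near.alive and far.alive

    def test_contract_rejects_active_cell(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 10)
        with pytest.raises(ValueError):
            activate_by_virus(w, t)

    def test_activation_conserves_population_classes(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.RESTING, (5, 5), 10)
        w.spawn(Species.VIRUS, None, (5, 6), 10)
        before = w.population_counts()
        activate_by_virus(w, t)
        after = w.population_counts()
        assert after["virus"] - before["virus"] == -1
        assert after["teff_active"] - before["teff_active"] == 1
        assert after["teff_resting"] - before["teff_resting"] == -1


class TestTeffAttack:
    def test_attack_removes_eat_mye(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.ACTIVE, (2, 2), 10)
        assert teff_attack(w, t) is True
        assert w.myelin[2, 2] == 95.0

    def test_bare_patch_blocks_attack_and_duplication(self):
        w = make_world()
        w.myelin[2, 2] = 0.0
        t = w.spawn(Species.TEFF, CellState.ACTIVE, (2, 2), 10)
        assert teff_attack(w, t) is False
        assert w.myelin[2, 2] == 0.0

    def test_attack_clamps_at_zero_but_still_eligible(self):
        w = make_world()
        w.myelin[2, 2] = 3.0
        t = w.spawn(Species.TEFF, CellState.ACTIVE, (2, 2), 10)
        assert teff_attack(w, t) is True
        assert w.myelin[2, 2] == 0.0

    def test_contract_rejects_resting_teff(self):
        w = make_world()
        t = w.spawn(Species.TEFF, CellState.RESTING, (2, 2), 10)
        with pytest.raises(ValueError):
            teff_attack(w, t)


class TestDuplicationProbability:
    def test_full_myelin_no_tregs_gives_eff_dup(self):
        p = Params()
        assert teff_duplication_probability(100.0, p, 0) == pytest.approx(0.1)

    def test_zero_myelin_gives_zero(self):
        p = Params()
        assert teff_duplication_probability(0.0, p, 50) == 0.0

    def test_half_myelin_and_saturating_tregs(self):
        p = Params(mean_Tregs=10.0)
        # 0.1 * (50/100)^2 * 10/(10+10) = 0.0125
        assert teff_duplication_probability(50.0, p, 10) == pytest.approx(0.0125)

    def test_formula_on_a_grid_of_points(self):
        p = Params(mean_Tregs=10.0)
        for myelin in range(0, 101, 10):
            for treg in range(0, 50, 5):
                expected = (
                    0.1 * (myelin / 100.0) ** 2 * (10.0 / (treg + 10.0))
                )
                got = teff_duplication_probability(float(myelin), p, treg)
                assert got == pytest.approx(expected)
                assert 0.0 <= got <= p.eff_dup

    def test_monotonicity(self):
        p = Params()
        probs_m = [teff_duplication_probability(m, p, 5) for m in range(0, 101, 5)]
        assert probs_m == sorted(probs_m)
        probs_t = [teff_duplication_probability(80.0, p, t) for t in range(0, 40)]
        assert probs_t == sorted(probs_t, reverse=True)

    def test_rejects_myelin_out_of_range(self):
        with pytest.raises(ValueError):
            teff_duplication_probability(101.0, Params(), 0)


class TestCountTregs:
    def test_empty_world(self):
        w = make_world()
        assert count_tregs_in_radius(w, (5, 5), 3.0) == 0

    def test_active_treg_at_exact_radius_counts(self):
        w = make_world()
        w.spawn(Species.TREG, CellState.ACTIVE, (5, 8), 10)  # distance 3
        assert count_tregs_in_radius(w, (5, 5), 3.0) == 1

    def test_resting_treg_does_not_count(self):
        w = make_world()
        w.spawn(Species.TREG, CellState.RESTING, (5, 6), 10)
        assert count_tregs_in_radius(w, (5, 5), 3.0) == 0

    def test_other_species_do_not_count(self):
        w = make_world()
        w.spawn(Species.TEFF, CellState.ACTIVE, (5, 6), 10)
        w.spawn(Species.VIRUS, None, (5, 5), 10)
        assert count_tregs_in_radius(w, (5, 5), 3.0) == 0

    def test_counts_across_torus_seam(self):
        w = make_world()
        w.spawn(Species.TREG, CellState.ACTIVE, (0, 50), 10)  # distance 1 from (0,0)
        assert count_tregs_in_radius(w, (0, 0), 3.0) == 1


class TestAttemptDuplication:
    def test_zero_probability_never_duplicates(self):
        w = make_world()
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 50)
        assert all(attempt_duplication(w, a, 0.0) is None for _ in range(100))
        assert a.life == 50

    def test_certain_duplication_on_uncrowded_patch(self):
        w = make_world()
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 50)
        child = attempt_duplication(w, a, 1.0)
        assert child is not None
        assert child.state is CellState.ACTIVE
        assert child.species is Species.TEFF
        assert child.pos in {(4, 5), (6, 5), (5, 4), (5, 6)}
        assert a.life == 25  # parent pays half its life
        assert 1 <= child.life <= 2 * w.params.hlife

    def test_life_halving_floors_at_one(self):
        w = make_world()
        a = w.spawn(Species.TREG, CellState.ACTIVE, (5, 5), 1)
        child = attempt_duplication(w, a, 1.0)
        assert child is not None
        assert a.life == 1

    def test_crowded_patch_relocates_and_retries_once(self):
        w = make_world(seed=1)
        # saturate the whole neighborhood so the retry must also fail
        for i in range(51):
            for j in range(51):
                if abs(i - 5) <= 2 and abs(j - 5) <= 2:
                    for _ in range(3):
                        w.spawn(Species.VIRUS, None, (i, j), 10)
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 50)
        child = attempt_duplication(w, a, 1.0)
        assert child is None
        assert a.life == 50  # no duplication, no life cost
        assert a.pos != (5, 5)  # but the parent did relocate

    def test_retry_can_succeed_on_free_neighbor(self):
        w = make_world(seed=2)
        for _ in range(3):
            w.spawn(Species.VIRUS, None, (5, 5), 10)
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 50)
        # neighbors are empty, so after relocation the retry succeeds
        child = attempt_duplication(w, a, 1.0)
        assert child is not None

    def test_rejects_invalid_probability(self):
        w = make_world()
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 50)
        with pytest.raises(ValueError):
            attempt_duplication(w, a, 1.5)

    def test_bernoulli_frequency_matches_probability(self):
        # Monte-Carlo check of the success frequency at fixed conditions
        w = make_world(seed=9)
        a = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 10 ** 9)
        prob, n = 0.3, 10 ** 4
        successes = 0
        for _ in range(n):
            child = attempt_duplication(w, a, prob)
            if child is not None:
                successes += 1
                w.remove(child)
            w.relocate(a, (5, 5))
        se = math.sqrt(prob * (1 - prob) / n)
        assert successes / n == pytest.approx(prob, abs=3 * se)


class TestTregSuppress:
    def test_no_prey_no_action(self):
        w = make_world()
        tr = w.spawn(Species.TREG, CellState.ACTIVE, (5, 5), 10)
        w.spawn(Species.TEFF, CellState.RESTING, (5, 6), 10)  # resting: not prey
        assert treg_suppress(w, tr) is False
        assert tr.pos == (5, 5)

    def test_suppression_removes_teff_and_moves_treg(self):
        w = make_world()
        tr = w.spawn(Species.TREG, CellState.ACTIVE, (5, 5), 10)
        te = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 7), 10)
        assert treg_suppress(w, tr) is True
        assert not te.alive
        assert tr.pos == (5, 7)
        assert w.population_counts()["teff_active"] == 0

    def test_prey_beyond_radius_is_safe(self):
        w = make_world()
        tr = w.spawn(Species.TREG, CellState.ACTIVE, (0, 0), 10)
        w.spawn(Species.TEFF, CellState.ACTIVE, (0, 4), 10)  # distance 4 > 3
        assert treg_suppress(w, tr) is False

    def test_equidistant_ties_broken_uniformly(self):
        hits = {"left": 0, "right": 0}
        rng_seeds = range(2000)
        for seed in rng_seeds:
            w = make_world(seed=seed)
            tr = w.spawn(Species.TREG, CellState.ACTIVE, (10, 10), 10)
            left = w.spawn(Species.TEFF, CellState.ACTIVE, (10, 8), 10)
            right = w.spawn(Species.TEFF, CellState.ACTIVE, (10, 12), 10)
            treg_suppress(w, tr)
            hits["left" if not left.alive else "right"] += 1
        frac = hits["left"] / len(rng_seeds)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_contract_rejects_non_treg(self):
        w = make_world()
        te = w.spawn(Species.TEFF, CellState.ACTIVE, (5, 5), 10)
        with pytest.raises(ValueError):
            treg_suppress(w, te)


class TestRecoverMyelin:
    def test_pristine_world_recovers_nothing(self):
        w = make_world()
        assert recover_myelin(w) == 0.0

    def test_partial_damage_recovers_by_rate(self):
        w = make_world(rec_mye=1.0)
        w.myelin[3, 3] = 95.0
        assert recover_myelin(w) == 1.0
        assert w.myelin[3, 3] == 96.0

    def test_recovery_clamps_at_init_mye(self):
        w = make_world(rec_mye=10.0)
        w.myelin[3, 3] = 95.0
        recover_myelin(w)
        assert w.myelin[3, 3] == 100.0

    def test_bare_patch_never_recovers(self):
        w = make_world()
        w.myelin[3, 3] = 0.0
        for _ in range(100):
            recover_myelin(w)
        assert w.myelin[3, 3] == 0.0


class TestDeath:
    def test_life_one_agent_dies_this_step(self):
        w = make_world()
        w.spawn(Species.VIRUS, None, (5, 5), 1)
        assert decrement_life_and_reap(w) == 1
        assert w.population_counts()["virus"] == 0

    def test_agent_survives_exactly_life_steps(self):
        w = make_world()
        w.spawn(Species.TEFF, CellState.RESTING, (5, 5), 120)
        for k in range(119):
            assert decrement_life_and_reap(w) == 0
        assert decrement_life_and_reap(w) == 1

    def test_empty_world(self):
        w = make_world()
        assert decrement_life_and_reap(w) == 0
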