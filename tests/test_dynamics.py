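"""Birth-death turnover and the three social-inheritance mechanisms."""

import numpy as np
import pytest

from avoidnet import (
    ModelParams,
    SignedNetwork,
    add_offspring,
    birth_death_step,
    classify_candidate,
    count_ties,
    init_random_network,
    make_fixture,
    run_simulation,
    signed_triad_census,
    tie_probabilities,
)
from conftest import random_signed_matrix


def make_net(n, seed=0, p=0.2):
    return init_random_network(n, p, p, np.random.default_rng(seed))


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pn": 1.5},
            {"pa": -0.1},
            {"pr": 0.6},  # stay-null probability 1-2*pr would go negative
            {"n": 1},
            {"timesteps": -1},
            {"variant": "three_step"},
            {"classification_rule": "majority"},
            {"p_assoc_init": 0.7, "p_avoid_init": 0.7},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    @pytest.mark.parametrize("relation", [1, -1, 0])
    @pytest.mark.parametrize("pn,pa,pr", [(0.3, 0.8, 0.01), (1.0, 0.0, 0.5), (0.5, 0.5, 0.0)])
    def test_rule_table_probabilities_sum_to_one(self, relation, pn, pa, pr):
        probs = tie_probabilities(relation, ModelParams(pn=pn, pa=pa, pr=pr))
        assert sum(probs) == pytest.approx(1.0)
        assert all(p >= 0 for p in probs)


class TestBirthDeathStep:
    def test_population_size_and_invariants_preserved(self, rng):
        params = ModelParams(n=20, variant="two_step")
        net = make_net(20)
        for _ in range(50):
            birth_death_step(net, params, rng)
            net.validate()
            assert net.n == 20

    def test_mother_and_offspring_always_associate(self, rng):
        for variant in ("one_step", "two_step", "random_associates"):
            params = ModelParams(n=15, variant=variant)
            net = make_net(15, seed=3)
            for _ in range(30):
                ev = birth_death_step(net, params, rng)
                assert net.matrix[ev.slot, ev.mother_slot] == 1

    def test_no_tie_to_dead_individual_and_fresh_id(self, rng):
        params = ModelParams(n=10)
        net = make_net(10, seed=1)
        seen_ids = set(net.ids)
        for _ in range(40):
            ev = birth_death_step(net, params, rng)
            assert ev.newborn_id not in seen_ids  # ids never reused
            seen_ids.add(ev.newborn_id)
            assert ev.dead_id not in net.ids
            assert ev.mother_id != ev.dead_id

    def test_all_inheritance_off_leaves_only_maternal_tie(self, rng):
        params = ModelParams(n=12, pn=0, pa=0, pr=0)
        net = make_net(12, seed=5)
        for _ in range(20):
            ev = birth_death_step(net, params, rng)
            row = net.matrix[ev.slot]
            assert row[ev.mother_slot] == 1
            assert np.count_nonzero(row) == 1

    def test_too_small_population_cannot_step(self, rng):
        net = SignedNetwork(np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            birth_death_step(net, ModelParams(n=2), rng)


class TestOneStepInheritance:
    def test_perfect_fidelity_clones_mother(self, rng):
        params = ModelParams(n=20, pn=1.0, pa=1.0, pr=0.0)
        net = make_net(20, seed=7)
        for _ in range(50):
            ev = birth_death_step(net, params, rng)
            others = [k for k in range(20) if k not in (ev.slot, ev.mother_slot)]
            assert np.array_equal(
                net.matrix[ev.slot, others], net.matrix[ev.mother_slot, others]
            )

    def test_strangers_split_evenly_when_pr_is_half(self):
        # pr = 0.5 leaves zero stay-null probability for mother's strangers
        params = ModelParams(n=40, pn=0, pa=0, pr=0.5)
        net = SignedNetwork(np.zeros((40, 40), dtype=np.int8))  # everyone a stranger
        rng = np.random.default_rng(11)
        plus = minus = zero = 0
        for _ in range(60):
            ev = birth_death_step(net, params, rng)
            row = np.delete(net.matrix[ev.slot], [ev.slot, ev.mother_slot])
            plus += int((row == 1).sum())
            minus += int((row == -1).sum())
            zero += int((row == 0).sum())
            net = SignedNetwork(np.zeros((40, 40), dtype=np.int8))
        total = plus + minus
        assert zero == 0
        assert abs(plus / total - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_maternal_inheritance_enforces_structural_balance(self, rng):
        # starting from a balanced two-faction network, cloning with loss
        # (pr = 0) can never create an unstable (++- or ---) triad
        net = make_fixture("balanced_factions")
        params = ModelParams(n=8, pn=0.7, pa=0.7, pr=0.0)
        for _ in range(60):
            birth_death_step(net, params, rng)
            census = signed_triad_census(net)
            assert census.ppm == 0 and census.mmm == 0


class TestCandidateClassification:
    @pytest.mark.parametrize(
        "ties,expected",
        [
            ({(5, 1): 1, (5, 2): 1, (5, 3): -1}, "potential_associate"),  # p=2 q=1
            ({(5, 1): 1, (5, 2): -1}, "potential_avoidance"),  # p=q=1
            ({}, "neutral"),  # p=q=0
        ],
    )
    def test_count_rule(self, ties, expected):
        m = np.zeros((6, 6), dtype=np.int8)
        for (i, j), s in ties.items():
            m[i, j] = m[j, i] = s
        net = SignedNetwork(m)
        assert classify_candidate(net, [1, 2, 3], 5, rule="count") == expected

    def test_fraction_rule_leaves_a_gap_class(self):
        # one positive tie out of four associates: neither >50% positive
        # nor >=50% negative -> no tie under the fraction rule
        m = np.zeros((6, 6), dtype=np.int8)
        m[5, 1] = m[1, 5] = 1
        net = SignedNetwork(m)
        assert classify_candidate(net, [1, 2, 3, 4], 5, rule="fraction") == "none"
        assert classify_candidate(net, [1, 2, 3, 4], 5, rule="count") == "potential_associate"


class TestTwoStepInheritance:
    def test_no_inheritance_leaves_only_maternal_tie(self, rng):
        params = ModelParams(n=15, pn=0, pa=0, pr=0, variant="two_step")
        net = make_net(15, seed=9)
        ev = birth_death_step(net, params, rng)
        assert np.count_nonzero(net.matrix[ev.slot]) == 1

    def test_two_step_gains_more_ties_than_one_step(self):
        # matched parameters and seeds; horizontal inheritance adds ties
        totals = {}
        for variant in ("one_step", "two_step"):
            params = ModelParams(n=50, timesteps=150, pn=0.5, pa=0.5, pr=0.01, variant=variant)
            counts = []
            for rep in range(10):
                trace = run_simulation(params, 100 + rep, record="final")
                final = trace.metrics.iloc[-1]
                counts.append(final["n_associations"] + final["n_avoidances"])
            totals[variant] = np.mean(counts)
        assert totals["two_step"] >= totals["one_step"]

    def test_step_two_adopts_associates_of_associates(self):
        # deterministic corner: pn=1, pa=1, pr=0 adopts every classified candidate
        net = make_fixture("two_step_worked_example")
        params = ModelParams(n=9, pn=1.0, pa=1.0, pr=0.0, variant="two_step")
        grown, slot = add_offspring(net, 0, params, np.random.default_rng(0))
        row = grown.matrix[slot]
        assert row[7] == 1            # associate of both maternal associates
        assert row[5] == -1 and row[6] == -1  # avoided by a maternal associate
        assert row[3] == -1 and row[4] == -1  # mother's avoidances, step 1
        assert row[8] == 0            # neutral, pr = 0


class TestRandomAssociatesVariant:
    def test_zero_pa_gives_no_avoidances(self):
        params = ModelParams(n=20, pa=0.0, variant="random_associates", timesteps=50)
        trace = run_simulation(params, 21, record="final")
        assert trace.metrics.iloc[-1]["n_avoidances"] == 0

    def test_zero_draw_probability_leaves_only_maternal_tie(self, rng):
        params = ModelParams(n=15, variant="random_associates", random_assoc_prob=0.0, pa=0.8)
        net = make_net(15, seed=2)
        ev = birth_death_step(net, params, rng)
        assert np.count_nonzero(net.matrix[ev.slot]) == 1


class TestMonotonicity:
    def test_avoidance_count_nondecreasing_in_pa(self):
        means = []
        for pa in (0.0, 0.8):
            vals = [
                run_simulation(
                    ModelParams(n=50, timesteps=200, pa=pa, pn=0.5, pr=0.01), 300 + r,
                    record="final",
                ).metrics.iloc[-1]["n_avoidances"]
                for r in range(20)
            ]
            means.append(np.mean(vals))
        assert means[1] >= means[0]

    def test_associate_count_increasing_in_pn(self):
        means = []
        for pn in (0.3, 0.8):
            vals = [
                run_simulation(
                    ModelParams(n=50, timesteps=200, pa=0.4, pn=pn, pr=0.01), 400 + r,
                    record="final",
                ).metrics.iloc[-1]["n_associations"]
                for r in range(20)
            ]
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestRunSimulation:
    def test_identical_seed_gives_bit_identical_traces(self):
        params = ModelParams(n=30, timesteps=80, variant="two_step")
        a = run_simulation(params, 42, record="all")
        b = run_simulation(params, 42, record="all")
        assert a.metrics.equals(b.metrics)
        assert np.array_equal(a.final.matrix, b.final.matrix)
        assert np.array_equal(a.final.ids, b.final.ids)

    def test_trace_length_is_timesteps_plus_initial(self):
        trace = run_simulation(ModelParams(n=10, timesteps=25), 1, record="all")
        assert len(trace) == 26
        assert trace.metrics["step"].iloc[0] == 0

    def test_zero_timesteps_records_initial_state_only(self):
        trace = run_simulation(ModelParams(n=10, timesteps=0), 1)
        assert len(trace) == 1
        assert trace.final.n == 10

    def test_user_supplied_initial_network(self):
        init = make_fixture("balanced_factions")
        trace = run_simulation(ModelParams(n=8, timesteps=5), 1, initial=init)
        assert trace.final.n == 8
        with pytest.raises(ValueError, match="initial network"):
            run_simulation(ModelParams(n=9, timesteps=5), 1, initial=init)
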