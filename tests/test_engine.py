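"""The Gillespie event loop: root sampling, event draws, branch simulation."""

import numpy as np
import pytest

from shiftscape import (
    Alphabet,
    ExplicitRegime,
    FitnessVector,
    InitSource,
    InstanceSettings,
    LandscapeRule,
    MutationMatrix,
    NoChangeRegime,
    PeriodicRegime,
    ScheduledEvent,
    StationaryDistribution,
    StochasticRegime,
    build_rate_system,
    draw_next_event,
    run_simulation,
    sample_root_sequence,
    transition_probability_oracle,
)
from shiftscape.engine import LandscapeContext, SequenceState, simulate_branch


def flat_ctx(dna):
    return LandscapeContext(
        FitnessVector(np.zeros(4), dna), MutationMatrix.uniform(dna), "normalized"
    )


def no_change(dna, length=1):
    return InstanceSettings(dna, length, LandscapeRule(InitSource.flat()), NoChangeRegime())


class TestRootSequence:
    def test_frequencies_match_stationary_distribution(self, dna, rng):
        pi = StationaryDistribution(np.full(4, 0.25), dna)
        state = sample_root_sequence(pi, 100_000, rng)
        freqs = np.bincount(state.alleles, minlength=4) / state.alleles.size
        se = np.sqrt(0.25 * 0.75 / state.alleles.size)
        assert np.all(np.abs(freqs - 0.25) < 4 * se)

    def test_degenerate_distribution(self, two_letter, rng):
        pi = StationaryDistribution(np.array([1.0, 0.0]), two_letter)
        state = sample_root_sequence(pi, 1000, rng)
        assert np.all(state.alleles == 0)

    def test_user_root_used_verbatim(self, dna, rng):
        pi = StationaryDistribution(np.full(4, 0.25), dna)
        state = sample_root_sequence(pi, 4, rng, user_sequence="ACGT")
        assert dna.decode(state.alleles) == "ACGT"

    def test_user_root_validated(self, dna, rng):
        pi = StationaryDistribution(np.full(4, 0.25), dna)
        with pytest.raises(ValueError, match="length"):
            sample_root_sequence(pi, 5, rng, user_sequence="ACGT")
        with pytest.raises(KeyError, match="'X'"):
            sample_root_sequence(pi, 4, rng, user_sequence="ACGX")


class TestDrawNextEvent:
    def test_flat_waiting_time_and_uniform_target(self, dna, rng):
        Q, _ = build_rate_system(FitnessVector(np.zeros(4), dna), MutationMatrix.uniform(dna))
        waits, targets = [], []
        for _ in range(20_000):
            ev = draw_next_event(SequenceState(np.array([0])), Q, 0.0, np.inf, 50.0, rng)
            if ev is not None:
                waits.append(ev.time)
                targets.append(ev.to_allele)
        waits = np.array(waits)
        assert abs(waits.mean() - 1.0) < 4 / np.sqrt(waits.size)  # Exponential(1)
        freqs = np.bincount(targets, minlength=4)[1:] / len(targets)
        se = np.sqrt((1 / 3) * (2 / 3) / len(targets))
        assert np.all(np.abs(freqs - 1 / 3) < 4 * se)

    def test_position_chosen_proportional_to_exit_rate(self, two_letter, rng):
        # exit rates differ by a factor e^F = 3 between the two alleles, so
        # with sequence [slow, fast] the second position carries 3/4 of the rate
        F = FitnessVector(np.array([0.0, np.log(3.0)]), two_letter)
        Q, _ = build_rate_system(F, MutationMatrix.uniform(two_letter), "raw")
        assert Q.exit_rates[0] / Q.exit_rates[1] == pytest.approx(3.0)
        hits = 0
        n = 8000
        for _ in range(n):
            ev = draw_next_event(SequenceState(np.array([1, 0])), Q, 0.0, np.inf, np.inf, rng)
            hits += ev.position == 1
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 4 * se

    def test_overshoot_returns_deterministic_change(self, dna, rng):
        Q, _ = build_rate_system(FitnessVector(np.zeros(4), dna), MutationMatrix.uniform(dna))
        ev = draw_next_event(SequenceState(np.array([0])), Q, 0.0, 1e-9, 5.0, rng)
        assert ev.kind == "deterministic_change" and ev.time == pytest.approx(1e-9)

    def test_branch_end_returns_nothing(self, dna, rng):
        Q, _ = build_rate_system(FitnessVector(np.zeros(4), dna), MutationMatrix.uniform(dna))
        assert draw_next_event(SequenceState(np.array([0])), Q, 0.0, np.inf, 1e-9, rng) is None

    def test_zero_length_sequence_changes_are_poisson(self, dna):
        # landscape changes alone at rate 10 over total length L are Poisson(10 L)
        lam, L, n = 10.0, 1.5, 800
        counts = []
        settings = InstanceSettings(
            dna,
            0,
            LandscapeRule(InitSource.lognormal(0, 0.5), "permute"),
            StochasticRegime(lam),
            record_changes=False,
        )
        ctx = flat_ctx(dna)
        for i in range(n):
            rng = np.random.default_rng([17, i])
            log = []
            counter = [0]
            simulate_branch(
                SequenceState(np.empty(0, dtype=np.intp)),
                ctx,
                L,
                settings,
                rng,
                change_counter=counter,
            )
            counts.append(counter[0])
        counts = np.array(counts, dtype=float)
        se = np.sqrt(lam * L / n)
        assert abs(counts.mean() - lam * L) < 4 * se


class TestSimulateBranch:
    def test_zero_length_branch_is_a_no_op(self, dna, rng):
        settings = no_change(dna, length=5)
        start = SequenceState(np.array([0, 1, 2, 3, 0]))
        end, _ = simulate_branch(start, flat_ctx(dna), 0.0, settings, rng)
        assert np.array_equal(end.alleles, start.alleles)

    def test_flat_landscape_change_probability_matches_closed_form(self, dna):
        # P(end != start) over t=1 under flat normalized Q is (3/4)(1 - e^{-4/3})
        settings = no_change(dna)
        ctx = flat_ctx(dna)
        rng = np.random.default_rng(23)
        n, diff = 20_000, 0
        for _ in range(n):
            end, _ = simulate_branch(SequenceState(np.array([0])), ctx, 1.0, settings, rng)
            diff += end.alleles[0] != 0
        p = 0.75 * (1 - np.exp(-4 / 3))
        assert abs(diff / n - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_event_times_strictly_increase_and_stay_on_branch(self, dna):
        settings = InstanceSettings(
            dna,
            20,
            LandscapeRule(InitSource.lognormal(0, 0.5), "permute"),
            StochasticRegime(2.0),
        )
        ctx = LandscapeContext(
            FitnessVector(np.array([0.2, 0.4, 0.9, 1.4]), dna),
            MutationMatrix.uniform(dna),
            "normalized",
        )
        events = []
        simulate_branch(
            SequenceState(np.zeros(20, dtype=np.intp)),
            ctx,
            3.0,
            settings,
            np.random.default_rng(4),
            events_out=events,
        )
        times = [ev.time for ev in events]
        assert len(times) > 5
        assert all(b > a for a, b in zip(times, times[1:]))
        assert times[-1] <= 3.0

    def test_explicit_change_applied_and_new_landscape_governs(self, dna, rng):
        # after an explicit switch to a strongly peaked landscape, a long
        # branch tail drives the allele to the favoured state
        peak = FitnessVector(np.array([8.0, 0.0, 0.0, 0.0]), dna)
        settings = InstanceSettings(
            dna, 1, LandscapeRule(InitSource.flat()), ExplicitRegime([ScheduledEvent("A", 0.1, peak)])
        )
        log = []
        end, ctx = simulate_branch(
            SequenceState(np.array([2])),
            flat_ctx(dna),
            30.0,
            settings,
            rng,
            det_events=[ScheduledEvent("A", 0.1, peak)],
            change_log=log,
            branch_name="A",
        )
        assert len(log) == 1 and log[0].offset == pytest.approx(0.1)
        assert end.alleles[0] == 0
        assert ctx.landscape_id == 1


class TestRunSimulation:
    def test_every_node_gets_a_sequence_of_configured_length(self, simple_tree, dna, rng):
        settings = no_change(dna, length=7)
        res = run_simulation(simple_tree, settings, rng)
        assert set(res.node_sequences) == {"A", "B", "C", "D", "E", "F", "G"}
        assert all(len(s) == 7 for s in res.node_sequences.values())

    def test_same_seed_reproduces_bit_identically(self, simple_tree, dna):
        settings = InstanceSettings(
            dna,
            10,
            LandscapeRule(InitSource.lognormal(0, 0.5), "resample"),
            StochasticRegime(1.0),
        )
        r1 = run_simulation(simple_tree, settings, np.random.default_rng(99))
        r2 = run_simulation(simple_tree, settings, np.random.default_rng(99))
        assert r1.node_sequences == r2.node_sequences
        assert [(c.branch, c.global_time) for c in r1.change_log] == [
            (c.branch, c.global_time) for c in r2.change_log
        ]

    def test_change_log_is_time_ordered_with_consistent_coordinates(self, simple_tree, dna):
        settings = InstanceSettings(
            dna,
            1,
            LandscapeRule(InitSource.lognormal(0, 0.5), "permute"),
            StochasticRegime(3.0),
        )
        res = run_simulation(simple_tree, settings, np.random.default_rng(12))
        times = [c.global_time for c in res.change_log]
        assert times == sorted(times)
        for c in res.change_log:
            node = simple_tree.node_index[c.branch]
            parent_time = simple_tree.global_time[node.parent.name]
            assert c.global_time == pytest.approx(parent_time + c.offset)
            assert 0 <= c.offset <= node.branch_length

    def test_convergence_to_new_stationary_distribution(self, dna):
        # landscape change followed by a long branch: allele frequencies at the
        # leaf match the new landscape's stationary distribution
        from shiftscape import make_single_branch_tree, stationary_distribution

        new_F = FitnessVector(np.array([2.0, 0.0, 0.0, 0.0]), dna)
        pi_new = stationary_distribution(new_F, MutationMatrix.uniform(dna))
        settings = InstanceSettings(
            dna,
            3000,
            LandscapeRule(InitSource.flat()),
            ExplicitRegime([ScheduledEvent("A", 1.0, new_F)]),
        )
        tree = make_single_branch_tree(13.0)
        res = run_simulation(tree, settings, np.random.default_rng(6))
        seq = res.node_sequences["A"]
        for sym, p in zip("ACGT", pi_new.probs):
            se = np.sqrt(p * (1 - p) / len(seq))
            assert abs(seq.count(sym) / len(seq) - p) < 4 * se

    def test_increase_current_requires_single_position(self, dna):
        rule = LandscapeRule(InitSource.lognormal(0, 0.5), "increase_current", delta=0.5)
        with pytest.raises(ValueError, match="one position"):
            InstanceSettings(dna, 10, rule, PeriodicRegime(1.0))

    def test_increase_current_incompatible_with_shared_ticks(self, dna):
        rule = LandscapeRule(InitSource.lognormal(0, 0.5), "increase_current", delta=0.5)
        with pytest.raises(ValueError, match="shared"):
            InstanceSettings(dna, 1, rule, PeriodicRegime(1.0, "shared"))

    def test_timing_without_rule_rejected(self, dna):
        with pytest.raises(ValueError, match="change_rule"):
            InstanceSettings(dna, 1, LandscapeRule(InitSource.flat()), StochasticRegime(1.0))


class TestOracleAgreement:
    def test_transition_frequencies_match_matrix_exponential(self, dna):
        # fixed non-flat landscape, branch t=0.8: empirical transition
        # frequencies from one start allele vs expm(Qt), modest n
        F = FitnessVector(np.array([0.0, 0.5, 1.0, 1.5]), dna)
        ctx = LandscapeContext(F, MutationMatrix.uniform(dna), "normalized")
        P = transition_probability_oracle(ctx.Q, 0.8)
        settings = no_change(dna)
        rng = np.random.default_rng(31)
        n = 12_000
        ends = np.empty(n, dtype=int)
        for k in range(n):
            end, _ = simulate_branch(SequenceState(np.array([2])), ctx, 0.8, settings, rng)
            ends[k] = end.alleles[0]
        freqs = np.bincount(ends, minlength=4) / n
        for j in range(4):
            se = np.sqrt(P[2, j] * (1 - P[2, j]) / n)
            assert abs(freqs[j] - P[2, j]) < 4 * se
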