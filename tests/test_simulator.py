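import math

import numpy as np
import pytest

from weighted_voter.errors import ParameterError
from weighted_voter.graphs import InteractionGraph, make_graph
from weighted_voter.noisy import GammaDist, PointMass
from weighted_voter.simulator import (
    SimOptions,
    Simulation,
    init_state,
    replicate_seed,
    run,
    run_many,
)
from weighted_voter.theory import (
    NoiseFreeModel,
    birth_death_chain,
    fixation_prob,
)

SPECS = [PointMass(1.0), PointMass(0.8)]  # lam = 1.25


def three_se(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestInitState:
    def test_point_mass_rates_exact(self, rng):
        g = make_graph("complete:n=6")
        st = init_state(g, [0, 0, 0, 1, 1, 1], SPECS, rng=rng)
        assert np.all(st.qualities[:3] == 1.0)
        assert np.all(st.qualities[3:] == 0.8)
        assert st.rates[3] == pytest.approx(1.25)

    def test_size_biased_init_mean(self):
        # gamma(2, mean 0.9) size-biased has mean E[T^2]/E[T] = 1.35
        rng = np.random.default_rng(5)
        g = make_graph("excycle:n=10000,d=2")
        st = init_state(
            g, [0] * 10000, [GammaDist.from_mean(2, 0.9)], "size_biased", rng
        )
        assert st.qualities.mean() == pytest.approx(1.35, abs=0.05)

    def test_consensus_detected_at_init(self):
        g = make_graph("complete:n=5")
        res = run(g, [0] * 5, SPECS, rng=np.random.default_rng(0))
        assert (res.winner, res.consensus_time, res.n_updates) == (0, 0.0, 0)

    def test_missing_spec_rejected(self, rng):
        g = make_graph("complete:n=3")
        with pytest.raises(ParameterError):
            init_state(g, [0, 1, 2], SPECS, rng=rng)

    def test_per_option_init_modes(self):
        rng = np.random.default_rng(9)
        g = make_graph("complete:n=4")
        st = init_state(
            g, [0, 1, 1, 1], [PointMass(1.0), GammaDist.from_mean(2, 0.9)],
            ("fresh", "size_biased"), rng,
        )
        assert st.qualities[0] == 1.0


class TestStepRunEquivalence:
    @pytest.mark.parametrize(
        "options",
        [
            SimOptions(),
            SimOptions(lag_mean=0.5),
            SimOptions(dynamic=True),
            SimOptions(init_mode="size_biased"),
        ],
    )
    def test_bit_identical_trajectories(self, options):
        g = (
            make_graph("rr:n=12,d=4", np.random.default_rng(3))
            if options.dynamic
            else make_graph("complete:n=12")
        )
        specs = [GammaDist.from_mean(2, 1.0), GammaDist.from_mean(2, 0.8)]
        asg = [0] * 4 + [1] * 8
        for seed in (0, 1, 2):
            sim = Simulation(g, asg, specs, options=options, rng=seed)
            r1 = sim.run()
            r2 = run(g, asg, specs, options, np.random.default_rng(seed))
            assert (r1.winner, r1.n_updates) == (r2.winner, r2.n_updates)
            assert r1.consensus_time == r2.consensus_time

    def test_zero_lag_is_the_base_model(self):
        g = make_graph("complete:n=8")
        asg = [0] * 4 + [1] * 4
        r1 = run(g, asg, SPECS, SimOptions(lag_mean=0.0), np.random.default_rng(11))
        r2 = run(g, asg, SPECS, None, np.random.default_rng(11))
        assert (r1.winner, r1.consensus_time, r1.n_updates) == (
            r2.winner,
            r2.consensus_time,
            r2.n_updates,
        )


class TestTwoAgents:
    def test_single_event_reaches_consensus(self):
        g = make_graph("complete:n=2")
        for seed in range(20):
            res = run(g, [0, 1], SPECS, rng=np.random.default_rng(seed))
            assert res.n_updates == 1

    def test_winner_frequency_matches_race_odds(self):
        # the faster (worse-option) clock fires first w.p. lam/(1+lam),
        # which equals the fixation formula at N=2
        g = make_graph("complete:n=2")
        s = run_many(g, [0, 1], SPECS, reps=3000, base_seed=21, keep_results=False)
        p = 1.25 / 2.25
        assert abs(s.fixation_freq[0] - p) <= three_se(p, 3000) + 0.01


class TestAgainstBirthDeathChain:
    def test_jump_odds_and_sojourn_times(self):
        # on the complete graph the better-option count is a birth-death
        # chain: state-independent up-odds lam/(1+lam) and residence means
        # (N-1)/((1+lam) j (N-j))
        n, lam = 4, 1.5
        g = make_graph(f"complete:n={n}")
        specs = [PointMass(1.0), PointMass(1.0 / lam)]
        chain = birth_death_chain(n, lam)
        rng_seed = 0
        ups = downs = 0
        sojourns = {j: [] for j in range(1, n)}
        for seed in range(400):
            sim = Simulation(g, [0, 0, 1, 1], specs, rng=seed)
            j = 2
            entered = 0.0
            while sim.state.consensus_winner() is None:
                ev = sim.step()
                if ev.new_opinion != ev.old_opinion:
                    sojourns[j].append(ev.time - entered)
                    entered = ev.time
                    if ev.new_opinion == 0:
                        ups += 1
                        j += 1
                    else:
                        downs += 1
                        j -= 1
        total = ups + downs
        p_up = lam / (1 + lam)
        assert abs(ups / total - p_up) <= three_se(p_up, total)
        for j in range(1, n):
            samples = np.array(sojourns[j])
            want = chain.residence_mean[j - 1]
            sem = samples.std() / math.sqrt(samples.size)
            assert abs(samples.mean() - want) <= 4 * sem

    def test_fixation_matches_closed_form_on_complete(self):
        n, k = 16, 4
        g = make_graph(f"complete:n={n}")
        s = run_many(
            g, [0] * k + [1] * (n - k), SPECS, reps=4000, base_seed=8,
            keep_results=False,
        )
        p = fixation_prob(NoiseFreeModel(n, 1.25, k))
        assert abs(s.fixation_freq[0] - p) <= three_se(p, 4000) + 0.005

    def test_fixation_is_topology_free_on_regular_graphs(self):
        g = make_graph("rr:n=16,d=4", np.random.default_rng(14))
        s = run_many(
            g, [0] * 4 + [1] * 12, SPECS, reps=4000, base_seed=9, keep_results=False
        )
        p = fixation_prob(NoiseFreeModel(16, 1.25, 4))
        assert abs(s.fixation_freq[0] - p) <= three_se(p, 4000) + 0.005


class TestLags:
    def test_lag_rescales_fixation_odds_and_slows_consensus(self):
        # a measurement lag L extends every signalling cycle by Exp(L), so
        # the per-jump odds become (L+q_A):(L+q_B) and fixation tracks the
        # gambler's-ruin value at that effective ratio, while the mean
        # consensus time grows strictly with L
        n, k, reps = 30, 15, 1200
        g = make_graph(f"complete:n={n}")
        asg = [0] * k + [1] * (n - k)
        base = run_many(g, asg, SPECS, reps=reps, base_seed=31, keep_results=True)
        t_base = np.array([r.consensus_time for r in base.results])
        prev_mean, prev_sem = t_base.mean(), t_base.std() / math.sqrt(reps)
        for lag in (1.0, 5.0):
            s = run_many(
                g, asg, SPECS, reps=reps, base_seed=31,
                options=SimOptions(lag_mean=lag), keep_results=True,
            )
            lam_eff = (lag + 1.0) / (lag + 0.8)
            pred = fixation_prob(NoiseFreeModel(n, lam_eff, k))
            assert abs(s.fixation_freq[0] - pred) <= 4 * math.sqrt(
                pred * (1 - pred) / reps
            ) + 0.01
            t = np.array([r.consensus_time for r in s.results])
            sem = t.std() / math.sqrt(reps)
            assert t.mean() - prev_mean > 3 * math.sqrt(sem**2 + prev_sem**2)
            prev_mean, prev_sem = t.mean(), sem


class TestDynamicNetworks:
    def test_dynamic_rewiring_keeps_regularity_and_fixation(self):
        rng = np.random.default_rng(17)
        g = make_graph("rr:n=20,d=4", rng)
        asg = [0] * 5 + [1] * 15
        sim = Simulation(g, asg, SPECS, options=SimOptions(dynamic=True), rng=2)
        sim.run()
        final = sim.current_graph()
        assert np.all(final.degrees() == 4)
        s = run_many(
            g, asg, SPECS, reps=2000, base_seed=12,
            options=SimOptions(dynamic=True), keep_results=False,
        )
        p = fixation_prob(NoiseFreeModel(20, 1.25, 5))
        assert abs(s.fixation_freq[0] - p) <= three_se(p, 2000) + 0.01


class TestBestOfN:
    def test_equal_qualities_win_in_proportion(self):
        # classical voter model: each option wins with its initial share
        g = make_graph("complete:n=12")
        specs = [PointMass(1.0)] * 3
        asg = [0] * 4 + [1] * 4 + [2] * 4
        s = run_many(g, asg, specs, reps=1500, base_seed=4, keep_results=False)
        assert s.fixation_freq.sum() == pytest.approx(1.0)
        for o in range(3):
            assert abs(s.fixation_freq[o] - 1 / 3) <= three_se(1 / 3, 1500) + 0.01

    def test_best_option_favoured(self):
        g = make_graph("complete:n=20")
        specs = [PointMass(1.0), PointMass(0.8), PointMass(0.5)]
        asg = [0] * 5 + [1] * 5 + [2] * 10
        s = run_many(g, asg, specs, reps=800, base_seed=6, keep_results=False)
        assert s.fixation_freq[0] > s.fixation_freq[2]


class TestRunMany:
    def test_reproducible_from_base_seed(self):
        g = make_graph("complete:n=10")
        asg = [0] * 5 + [1] * 5
        s1 = run_many(g, asg, SPECS, reps=50, base_seed=13)
        s2 = run_many(g, asg, SPECS, reps=50, base_seed=13)
        assert [r.winner for r in s1.results] == [r.winner for r in s2.results]
        assert [r.consensus_time for r in s1.results] == [
            r.consensus_time for r in s2.results
        ]

    def test_replicate_seeds_are_distinct(self):
        seeds = {replicate_seed(42, rep) for rep in range(1000)}
        assert len(seeds) == 1000

    def test_single_rep_degenerates_to_run(self):
        g = make_graph("complete:n=6")
        asg = [0, 0, 0, 1, 1, 1]
        s = run_many(g, asg, SPECS, reps=1, base_seed=5)
        r = run(g, asg, SPECS, rng=np.random.default_rng(replicate_seed(5, 0)))
        assert s.results[0].consensus_time == r.consensus_time
        assert s.mean_time == r.consensus_time

    def test_quartiles_bracket_mean_time(self):
        g = make_graph("complete:n=10")
        s = run_many(g, [0] * 5 + [1] * 5, SPECS, reps=400, base_seed=19)
        assert s.time_q1 <= np.median(
            [r.consensus_time for r in s.results]
        ) <= s.time_q3


class TestIrregularCorners:
    def test_isolated_agent_only_remeasures(self):
        g = InteractionGraph.from_edges(3, [(0, 1)])
        res = run(
            g, [0, 1, 0], SPECS,
            SimOptions(max_events=20000), np.random.default_rng(3),
        )
        # the isolated agent never changes opinion: consensus happens only
        # if the connected pair lands on its opinion; otherwise we cap out
        assert res.winner in (0, None)

    def test_event_cap_reported_not_raised(self):
        g = make_graph("complete:n=30")
        res = run(
            g, [0] * 15 + [1] * 15, [PointMass(1.0), PointMass(1.0)],
            SimOptions(max_events=50), np.random.default_rng(0),
        )
        assert res.capped and res.winner is None and res.n_updates == 50
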