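import numpy as np
import pytest

from rrtd import (
    Task,
    TaskGraph,
    betweenness_score,
    pairwise_correlation,
    sample_probe_tasks,
    select_filler_task,
    shortest_path_lengths,
    simulate_agent,
    standardize_scores,
    generate_choice_fixture,
)
from rrtd.decomposition import SubgoalScores
from rrtd.experiment import Trial, TrialSchedule, make_schedule, sample_long_task
from rrtd.graph import eligible_for_experiment
from rrtd.heuristics import occupancy_score

from conftest import random_connected_graph


class TestSelectFillerTask:
    def test_avoids_most_visited_state(self, k3):
        rng = np.random.default_rng(0)
        visits = {0: 10, 1: 2, 2: 3}
        for _ in range(30):
            t = select_filler_task(k3, visits, rng)
            assert 0 not in (t.start, t.goal)

    def test_all_tied_skips_exclusion_step(self, k3):
        rng = np.random.default_rng(1)
        visits = {0: 4, 1: 4, 2: 4}
        tasks = {select_filler_task(k3, visits, rng) for _ in range(100)}
        # exclusion step skipped: all six directed edge tasks remain
        assert len(tasks) == 6

    def test_greatest_visit_sum_wins(self):
        # after excluding the most-visited state d, edges (a,b) and (b,c)
        # remain with visit sums 5 and 7; the sum-7 edge must always win
        g = TaskGraph("abcd", [(0, 1), (1, 2), (2, 3)])
        visits = {0: 2, 1: 3, 2: 4, 3: 10}
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = select_filler_task(g, visits, rng)
            assert {t.start, t.goal} == {1, 2}

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            select_filler_task(TaskGraph("a", []), {0: 0}, np.random.default_rng(0))


class TestSampleProbeTasks:
    def test_all_distances_at_least_three(self):
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        rng = np.random.default_rng(3)
        tasks = sample_probe_tasks(p8, 10, rng)
        d = shortest_path_lengths(p8)
        assert len(set(tasks)) == 10
        assert all(d[t.start, t.goal] >= 3 for t in tasks)

    def test_ineligible_graph_rejected(self):
        k8 = TaskGraph(range(8), [(i, j) for i in range(8) for j in range(i + 1, 8)])
        with pytest.raises(ValueError):
            sample_probe_tasks(k8, 10, np.random.default_rng(0))

    def test_same_seed_same_tasks(self):
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        a = sample_probe_tasks(p8, 10, np.random.default_rng(42))
        b = sample_probe_tasks(p8, 10, np.random.default_rng(42))
        assert a == b


class TestSchedule:
    def test_alternation_and_probe_reuse(self):
        rng = np.random.default_rng(4)
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        sched = make_schedule(p8, rng)
        kinds = [t.kind for t in sched]
        nav = [k for k in kinds if k in ("long", "filler")]
        assert nav == ["long", "filler"] * 30
        implicit = [t.task for t in sched if t.kind == "probe_implicit"]
        explicit = [t.task for t in sched if t.kind == "probe_explicit"]
        assert sorted(map(repr, implicit)) == sorted(map(repr, explicit))
        d = shortest_path_lengths(p8)
        assert all(d[t.start, t.goal] >= 3 for t in implicit)
        longs = [t.task for t in sched if t.kind == "long"]
        assert all(d[t.start, t.goal] >= 2 for t in longs)


class TestSimulateAgent:
    def test_optimal_agent_on_unique_shortest_path(self, p3):
        sched = TrialSchedule([Trial("long", Task(0, 2))])
        trajectories, visits = simulate_agent(p3, sched, np.random.default_rng(0))
        assert trajectories == [[0, 1, 2]]
        assert visits == {0: 1, 1: 1, 2: 1}

    def test_zero_epsilon_equals_optimal(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        g = random_connected_graph(8, np.random.default_rng(6))
        sched = TrialSchedule([Trial("long", sample_long_task(g, np.random.default_rng(7)))] * 5)
        a, _ = simulate_agent(g, sched, rng1, epsilon=0.0)
        b, _ = simulate_agent(g, sched, rng2)
        assert a == b

    def test_noise_lengthens_paths_on_average(self):
        rng = np.random.default_rng(8)
        excess = 0
        for _ in range(10):
            g = random_connected_graph(8, rng)
            t = sample_long_task(g, rng)
            d = shortest_path_lengths(g)[t.start, t.goal]
            sched = TrialSchedule([Trial("long", t)] * 5)
            trajs, _ = simulate_agent(g, sched, rng, epsilon=0.2)
            excess += sum(len(tr) - 1 - d for tr in trajs)
        assert excess > 0

    def test_filler_trials_resolved_adaptively(self, k3):
        sched = TrialSchedule([Trial("long", Task(0, 2)), Trial("filler", None)])
        trajectories, visits = simulate_agent(k3, sched, np.random.default_rng(9))
        assert len(trajectories) == 2
        assert len(trajectories[1]) == 2  # one-action task


class TestChoiceFixture:
    def _scores(self, graph, rng):
        raw = SubgoalScores("m", graph, dict(enumerate(rng.standard_normal(graph.n_states))))
        return standardize_scores(raw)

    def test_candidate_rules_hold_on_every_row(self):
        rng = np.random.default_rng(10)
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        rows = generate_choice_fixture(p8, self._scores(p8, rng), beta=1.0, rng=rng)
        assert {r.probe_type for r in rows} == {"implicit", "explicit", "teleport"}
        for r in rows:
            if r.probe_type == "implicit":
                assert r.task.start not in r.candidates
                assert r.task.goal not in r.candidates
            elif r.probe_type == "explicit":
                assert r.task.start not in r.candidates
                assert r.task.goal in r.candidates
            else:
                assert len(r.candidates) == 8

    def test_high_beta_concentrates_on_modal_candidate(self):
        rng = np.random.default_rng(11)
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        # well-separated scores: concentration holds once beta * gap is large
        sc = standardize_scores(
            SubgoalScores("m", p8, {s: float(s) for s in range(8)})
        )
        hits = total = 0
        for _ in range(20):
            rows = generate_choice_fixture(p8, sc, beta=10.0, rng=rng)
            for r in rows:
                total += 1
                best = max(r.candidates, key=lambda c: r.scores[c])
                hits += r.chosen == best
        assert hits / total >= 0.95

    def test_zero_beta_choice_frequencies_uniform(self):
        rng = np.random.default_rng(12)
        p8 = TaskGraph(range(8), [(i, i + 1) for i in range(7)])
        sc = self._scores(p8, rng)
        counts = np.zeros(8)
        n_rounds = 150
        for _ in range(n_rounds):
            rows = generate_choice_fixture(p8, sc, beta=0.0, rng=rng)
            for r in rows:
                if r.probe_type == "teleport":
                    counts[r.chosen] += 1
        p = counts / counts.sum()
        assert abs(p - 1 / 8).max() < 4 * np.sqrt((1 / 8) * (7 / 8) / n_rounds)


class TestFillerDissociation:
    def test_adaptive_fillers_decorrelate_visits_from_betweenness(self):
        """Interleaving adaptive one-step trials weakens the confound between
        state visit counts and betweenness relative to long trials only."""
        rng = np.random.default_rng(13)
        deltas = []
        n_graphs = 0
        while n_graphs < 20:
            g = random_connected_graph(8, rng)
            if not eligible_for_experiment(g):
                continue
            n_graphs += 1
            btw = betweenness_score(g)
            long_only = TrialSchedule(
                [Trial("long", sample_long_task(g, rng)) for _ in range(30)]
            )
            mixed = TrialSchedule(
                [t for pair in zip(long_only.trials, [Trial("filler", None)] * 30)
                 for t in pair]
            )
            rs = []
            for sched in (long_only, mixed):
                _, visits = simulate_agent(g, sched, rng)
                occ = occupancy_score(
                    [[s] * c for s, c in visits.items() if c], g
                )
                rs.append(pairwise_correlation(occ, btw))
            deltas.append(rs[0] - rs[1])
        assert np.mean(deltas) > 0
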