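"""Cutoff pruning, resource accounting, the toy annealer, and the exhaustive oracle."""

import numpy as np
import pytest

from fixbbgcn.packing import PackingProblem
from fixbbgcn.pruning import (
    apply_cutoff,
    exhaustive_pack,
    prune_problem,
    solution_space_factor,
    sweep,
    toy_pack,
)
from fixbbgcn.synthetic import (
    bin_occupancy,
    build_protein_graph,
    make_packing_problem,
    sample_backbone,
)


def uniform_problem(rng, n_positions=4, n_rotamers=3, chain=True, distinct_bins=True):
    """A packing problem built directly from tables (no graph), chain topology."""
    bins, embeds, one_body = [], [], []
    for i in range(n_positions):
        if distinct_bins:
            b = np.arange(n_rotamers)
        else:
            b = rng.integers(0, 54, size=n_rotamers)
        bins.append(b)
        v = rng.normal(size=(n_rotamers, 4))
        embeds.append(v / np.linalg.norm(v, axis=1, keepdims=True))
        one_body.append(rng.normal(size=n_rotamers))
    pairs = [(i, i + 1) for i in range(n_positions - 1)] if chain else []
    two_body = {}
    for i, j in pairs:
        m = rng.normal(size=(n_rotamers, n_rotamers))
        two_body[(i, j)] = m
        two_body[(j, i)] = m.T
    return PackingProblem(bins, embeds, one_body, two_body, pairs)


class TestApplyCutoff:
    def test_control_cutoff_keeps_all_bins(self, rng):
        scores = rng.uniform(size=54)
        assert apply_cutoff(scores, -1.0).sum() == 54

    def test_cutoff_above_one_removes_everything(self, rng):
        scores = rng.uniform(size=54)
        assert apply_cutoff(scores, 1.01).sum() == 0

    def test_exact_survivor_set(self):
        scores = np.linspace(0.0, 1.0, 54)
        expected = (scores >= 0.3).sum()
        mask = apply_cutoff(scores, 0.3)
        assert mask.sum() == expected
        assert np.array_equal(np.flatnonzero(mask), np.flatnonzero(scores >= 0.3))

    def test_monotone_in_cutoff(self, rng):
        scores = rng.uniform(size=54)
        prev = apply_cutoff(scores, -1.0)
        for c in np.linspace(0, 1, 11):
            cur = apply_cutoff(scores, c)
            assert np.all(cur <= prev)  # survivors shrink as cutoff rises
            prev = cur


class TestPruneProblem:
    def test_identity_pruning(self, rng):
        prob = uniform_problem(rng)
        ones = [np.ones(54, dtype=np.int8)] * prob.n_positions
        pruned, report = prune_problem(prob, ones)
        assert report.retention == 1.0
        assert report.log10_solution_space_factor == 0.0
        assert pruned.total_rotamers == prob.total_rotamers
        state = np.zeros(prob.n_positions, dtype=int)
        assert pruned.energy(state) == prob.energy(state)

    def test_forty_percent_reduction_accounting(self, rng):
        # keeping 6 of 10 rotamers everywhere: 40% fewer qubits, 64% fewer pair entries
        prob = uniform_problem(rng, n_positions=5, n_rotamers=10)
        mask = np.zeros(54, dtype=np.int8)
        mask[:6] = 1
        _, report = prune_problem(prob, [mask] * 5)
        assert report.logical_qubits_before == 50
        assert report.logical_qubits_after == 30
        assert report.retention == pytest.approx(0.6)
        assert report.pair_energy_entries_after / report.pair_energy_entries_before \
            == pytest.approx(0.36)

    def test_energy_preserved_for_surviving_assignments(self, rng):
        prob = uniform_problem(rng, n_positions=4, n_rotamers=4)
        mask = np.zeros(54, dtype=np.int8)
        mask[1:3] = 1  # keep rotamers with bins 1 and 2
        pruned, report = prune_problem(prob, [mask] * 4)
        # enumerate all pruned assignments; energies must match the originals exactly
        keep = [np.flatnonzero(mask[prob.bins[i]]) for i in range(4)]
        import itertools

        for pruned_state in itertools.product(*[range(len(k)) for k in keep]):
            original_state = [keep[i][pruned_state[i]] for i in range(4)]
            assert pruned.energy(pruned_state) == prob.energy(original_state)

    def test_emptied_position_keeps_best_one_body_rotamer(self, rng):
        prob = uniform_problem(rng, n_positions=3, n_rotamers=3)
        empty = np.zeros(54, dtype=np.int8)
        pruned, report = prune_problem(prob, [empty] * 3)
        assert all(pruned.n_rotamers(i) == 1 for i in range(3))
        for i in range(3):
            assert pruned.one_body[i][0] == prob.one_body[i].min()

    def test_pruned_optimum_never_beats_original(self, rng):
        for trial in range(5):
            local = np.random.default_rng(trial)
            prob = uniform_problem(local, n_positions=4, n_rotamers=3)
            mask = local.integers(0, 2, size=54).astype(np.int8)
            pruned, _ = prune_problem(prob, [mask] * 4)
            _, e_orig = exhaustive_pack(prob)
            _, e_pruned = exhaustive_pack(pruned)
            assert e_pruned >= e_orig - 1e-12

    def test_empty_problem_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prune_problem(PackingProblem([], [], [], {}, []), [])


class TestSolutionSpaceFactor:
    def test_published_small_case(self):
        factor, log10f = solution_space_factor(0.6, 10)
        assert factor == pytest.approx(0.006, abs=5e-4)
        assert 1.0 / factor == pytest.approx(165.0, rel=0.01)

    def test_published_large_case_via_log(self):
        _, log10f = solution_space_factor(0.6, 827)
        reciprocal = 10 ** (-log10f)
        assert reciprocal == pytest.approx(2.9e183, rel=0.05)

    def test_full_retention_is_identity(self):
        factor, log10f = solution_space_factor(1.0, 12)
        assert factor == 1.0 and log10f == 0.0

    def test_log_additivity(self):
        _, l_a = solution_space_factor(0.37, 11)
        _, l_b = solution_space_factor(0.37, 29)
        _, l_ab = solution_space_factor(0.37, 40)
        assert l_ab == pytest.approx(l_a + l_b, abs=1e-12)


class TestExhaustivePack:
    def test_single_position_is_one_body_argmin(self, rng):
        prob = uniform_problem(rng, n_positions=1, n_rotamers=5, chain=False)
        state, energy = exhaustive_pack(prob)
        assert state[0] == np.argmin(prob.one_body[0])
        assert energy == prob.one_body[0].min()

    def test_two_position_hand_calculation(self):
        one = [np.array([0.0, 1.0]), np.array([0.5, 0.0])]
        m = np.array([[2.0, -1.0], [0.0, 0.5]])
        prob = PackingProblem(
            bins=[np.array([0, 1])] * 2,
            embeddings=[np.eye(2)] * 2,
            one_body=one,
            two_body={(0, 1): m, (1, 0): m.T},
            interacting_pairs=[(0, 1)],
        )
        # energies: (0,0)=2.5, (0,1)=-1.0, (1,0)=1.5, (1,1)=1.5
        state, energy = exhaustive_pack(prob)
        assert tuple(state) == (0, 1)
        assert energy == pytest.approx(-1.0)

    def test_rotamer_relabeling_consistency(self, rng):
        prob = uniform_problem(rng, n_positions=3, n_rotamers=3)
        state, energy = exhaustive_pack(prob)
        # reverse rotamer order at position 0
        flip = PackingProblem(
            bins=[prob.bins[0][::-1]] + prob.bins[1:],
            embeddings=[prob.embeddings[0][::-1]] + prob.embeddings[1:],
            one_body=[prob.one_body[0][::-1]] + prob.one_body[1:],
            two_body={
                k: (m[::-1] if k[0] == 0 else (m[:, ::-1] if k[1] == 0 else m))
                for k, m in prob.two_body.items()
            },
            interacting_pairs=prob.interacting_pairs,
        )
        state2, energy2 = exhaustive_pack(flip)
        assert energy2 == pytest.approx(energy)
        assert state2[0] == 2 - state[0]

    def test_capacity_guard(self, rng):
        prob = uniform_problem(rng, n_positions=10, n_rotamers=5, chain=True,
                               distinct_bins=False)
        # 5^10 ~ 9.8e6 states exceeds the enumeration guard
        with pytest.raises(ValueError, match="too large"):
            exhaustive_pack(prob)


class TestToyPack:
    def test_single_position_finds_one_body_minimum(self, rng):
        prob = uniform_problem(rng, n_positions=1, n_rotamers=6, chain=False)
        for seed in range(10):
            state, energy = toy_pack(prob, (3.0, 0.05, 50), seed=seed)
            assert energy == pytest.approx(prob.one_body[0].min())

    def test_flat_landscape_gives_zero_energy(self, rng):
        prob = uniform_problem(rng, n_positions=3, n_rotamers=3)
        for i in range(3):
            prob.one_body[i][:] = 0.0
        for k in prob.two_body:
            prob.two_body[k][:] = 0.0
        _, energy = toy_pack(prob, seed=1)
        assert energy == 0.0

    def test_matches_exhaustive_on_small_instances(self):
        # 10 seeded 4-position / 3-rotamer instances; a long, slowly cooled
        # schedule so the end state is the 81-state global optimum
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            prob = uniform_problem(rng, n_positions=4, n_rotamers=3)
            _, e_opt = exhaustive_pack(prob)
            _, e_sa = toy_pack(prob, (3.0, 0.02, 3000), seed=seed)
            if e_sa <= e_opt + 1e-9:
                hits += 1
        assert hits >= 9

    def test_deterministic_per_seed(self, rng):
        prob = uniform_problem(rng)
        a = toy_pack(prob, seed=7)
        b = toy_pack(prob, seed=7)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_trajectory_records_every_sweep(self, rng):
        prob = uniform_problem(rng)
        _, _, traj = toy_pack(prob, (3.0, 0.3, 25), seed=0, record=True)
        assert traj.states.shape == (25, prob.n_positions)
        assert traj.temperatures[0] == pytest.approx(3.0)
        assert traj.temperatures[-1] == pytest.approx(0.3)
        assert np.all(np.diff(traj.temperatures) < 0)


@pytest.fixture(scope="module")
def problem_and_scores():
    coords = sample_backbone(12, seed=21)
    g = build_protein_graph(coords, seed=21)
    prob = make_packing_problem(g, 6, seed=21)
    _, _, traj = toy_pack(prob, (6.0, 0.15, 300), seed=21, record=True)
    scores = np.stack([bin_occupancy(traj, prob, i) for i in range(12)])
    return prob, scores


class TestSweep:
    def test_control_row_leads_with_full_retention(self, problem_and_scores):
        prob, scores = problem_and_scores
        table = sweep(prob, scores, [0.01, -1.0, 0.1], repeats=3, seed=0,
                      schedule=(3.0, 0.1, 100))
        assert table.iloc[0]["cutoff"] == -1.0
        assert table.iloc[0]["retention"] == 1.0
        assert table.iloc[0]["rotamers"] == prob.total_rotamers

    def test_retention_non_increasing_in_cutoff(self, problem_and_scores):
        prob, scores = problem_and_scores
        table = sweep(prob, scores, [-1.0, 0.001, 0.01, 0.05, 0.2], repeats=2,
                      seed=0, schedule=(3.0, 0.1, 80))
        by_cutoff = table.sort_values("cutoff")
        assert (np.diff(by_cutoff["retention"].values) <= 1e-12).all()

    def test_moderate_pruning_keeps_energy_near_control(self, problem_and_scores):
        # with oracle occupancy scores, some cutoff at retention <= 0.7 stays
        # within one standard deviation of the control energy
        prob, scores = problem_and_scores
        table = sweep(prob, scores, [-1.0, 0.01, 0.1, 0.2, 0.3], repeats=5,
                      seed=3, schedule=(3.0, 0.05, 300))
        control = table.iloc[0]
        ok = table[
            (table["retention"] <= 0.7)
            & (table["mean_energy"] <= control["mean_energy"] + control["sd_energy"])
        ]
        assert len(ok) > 0
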