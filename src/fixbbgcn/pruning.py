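"""Cutoff pruning, the toy annealer, the exhaustive oracle, and resource accounting.

The classifier emits 54 per-bin scores in (0, 1) for a position; a rotamer
survives when its bin's score clears the cutoff. Pruning shrinks three
resources at once:

* **logical qubits** — the one-hot quantum-annealer mapping spends one qubit
  per rotamer, so qubit count falls linearly with retention;
* **pair-energy memory** — the classical pre-computation stores an energy for
  every rotamer pair of every interacting position pair, so memory falls
  quadratically;
* **solution space** — with ``N`` positions, uniform retention ``r`` rescales
  the ``D^N`` solution space by ``r^N``, exponentially.

The toy simulated annealer mirrors the Metropolis single-rotamer-substitution
scheme of classical packers at desk scale, and the exhaustive enumerator
provides the exact optimum on tiny instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .graphs import N_BINS
from .packing import PackingProblem, Trajectory

__all__ = [
    "PruningReport",
    "apply_cutoff",
    "prune_problem",
    "solution_space_factor",
    "toy_pack",
    "exhaustive_pack",
    "sweep",
]

DEFAULT_SCHEDULE = (3.0, 0.3, 200)  #: (T_start, T_end, n_sweeps) in energy units


@dataclass
class PruningReport:
    """Per-position survivors plus classical and quantum resource accounting."""

    masks: List[np.ndarray]                  # per position: surviving-bin mask [54]
    surviving_counts: np.ndarray             # per position D'_i
    counts_before: np.ndarray                # per position D_i
    total_before: int
    total_after: int
    retention: float
    logical_qubits_before: int               # one qubit per rotamer
    logical_qubits_after: int
    info_qubits_before: float                # information-theoretic sum(log2 D_i)
    info_qubits_after: float
    pair_energy_entries_before: int          # stored two-body entries (memory proxy)
    pair_energy_entries_after: int
    log10_solution_space_factor: float       # sum(log10(D'_i / D_i)) <= 0


def apply_cutoff(scores, cutoff: float) -> np.ndarray:
    """Per-bin survival mask: bin b survives iff ``scores[b] >= cutoff``.

    Scores are sigmoid outputs in [0, 1], so the control cutoff of -1.0
    keeps every bin.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (N_BINS,):
        raise ValueError(f"scores must have shape ({N_BINS},)")
    return (scores >= cutoff).astype(np.int8)


def _pair_entries(counts: np.ndarray, pairs) -> int:
    return int(sum(counts[i] * counts[j] for i, j in pairs))


def prune_problem(
    problem: PackingProblem, masks: Sequence[np.ndarray]
) -> Tuple[PackingProblem, PruningReport]:
    """Remove rotamers whose bin is masked out, slicing all tables consistently.

    A position whose mask would eliminate every rotamer retains its single
    best one-body rotamer, so the pruned problem always stays packable.
    Energies of surviving assignments are preserved exactly.
    """
    n = problem.n_positions
    if n == 0:
        raise ValueError("empty problem")
    if len(masks) != n:
        raise ValueError(f"need one mask per position ({n}), got {len(masks)}")
    keep: List[np.ndarray] = []
    for i in range(n):
        mask = np.asarray(masks[i])
        sel = np.flatnonzero(mask[problem.bins[i]])
        if sel.size == 0:
            sel = np.array([int(np.argmin(problem.one_body[i]))])
        keep.append(sel)

    new_two = {}
    for (i, j), m in problem.two_body.items():
        new_two[(i, j)] = m[np.ix_(keep[i], keep[j])]
    pruned = PackingProblem(
        bins=[problem.bins[i][keep[i]] for i in range(n)],
        embeddings=[np.asarray(problem.embeddings[i])[keep[i]] for i in range(n)],
        one_body=[problem.one_body[i][keep[i]] for i in range(n)],
        two_body=new_two,
        interacting_pairs=list(problem.interacting_pairs),
    )

    before = problem.rotamer_counts
    after = pruned.rotamer_counts
    report = PruningReport(
        masks=[np.asarray(m, dtype=np.int8) for m in masks],
        surviving_counts=after,
        counts_before=before,
        total_before=int(before.sum()),
        total_after=int(after.sum()),
        retention=float(after.sum() / before.sum()),
        logical_qubits_before=int(before.sum()),
        logical_qubits_after=int(after.sum()),
        info_qubits_before=float(np.log2(before).sum()),
        info_qubits_after=float(np.log2(after).sum()),
        pair_energy_entries_before=_pair_entries(before, problem.interacting_pairs),
        pair_energy_entries_after=_pair_entries(after, problem.interacting_pairs),
        log10_solution_space_factor=float(np.log10(after / before).sum()),
    )
    return pruned, report


def solution_space_factor(retention: float, n_positions: int) -> Tuple[float, float]:
    """Rescaling of the D^N solution space under uniform retention.

    Returns ``(retention ** n_positions, n_positions * log10(retention))``;
    the factor is computed in log space so the log form stays exact even when
    the direct power underflows.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    if n_positions <= 0:
        raise ValueError("n_positions must be positive")
    log10_factor = n_positions * math.log10(retention)
    return 10.0 ** log10_factor, log10_factor


def _temperatures(schedule) -> np.ndarray:
    t_start, t_end, n_sweeps = schedule
    if n_sweeps < 1:
        raise ValueError("schedule needs at least one sweep")
    if t_start <= 0 or t_end <= 0:
        raise ValueError("temperatures must be positive")
    if n_sweeps == 1:
        return np.array([float(t_end)])
    frac = np.arange(n_sweeps) / (n_sweeps - 1)
    return t_start * (t_end / t_start) ** frac


def toy_pack(
    problem: PackingProblem,
    schedule=DEFAULT_SCHEDULE,
    seed: int = 0,
    record: bool = False,
):
    """Simulated annealing by Metropolis single-rotamer substitutions.

    Each sweep visits every position once, proposes a uniform random
    alternative rotamer, and accepts with probability ``min(1, exp(-dE/T))``;
    temperature decays geometrically from ``T_start`` to ``T_end`` across the
    sweeps. Returns ``(assignment, energy)`` or, with ``record``,
    ``(assignment, energy, Trajectory)`` where the trajectory logs the
    temperature and representative rotamers after every sweep.
    """
    n = problem.n_positions
    if n == 0 or any(problem.n_rotamers(i) < 1 for i in range(n)):
        raise ValueError("every position needs at least one rotamer")
    rng = np.random.default_rng(seed)
    counts = problem.rotamer_counts
    state = np.array([rng.integers(c) for c in counts])
    adj = problem.neighbors()
    temps = _temperatures(schedule)
    rec_states = []

    for T in temps:
        for i in range(n):
            d = counts[i]
            if d < 2:
                continue
            alt = int(rng.integers(d - 1))
            if alt >= state[i]:
                alt += 1
            delta = float(problem.one_body[i][alt] - problem.one_body[i][state[i]])
            for j in adj[i]:
                delta += problem.pair_energy(i, alt, j, state[j])
                delta -= problem.pair_energy(i, int(state[i]), j, int(state[j]))
            if delta <= 0 or rng.random() < math.exp(-delta / T):
                state[i] = alt
        if record:
            rec_states.append(state.copy())

    energy = problem.energy(state)
    if record:
        return state, energy, Trajectory(temps, np.array(rec_states))
    return state, energy


def exhaustive_pack(problem: PackingProblem) -> Tuple[np.ndarray, float]:
    """Exact global optimum by full enumeration (lexicographic tie-break).

    Guarded at 10^6 states; raises beyond that.
    """
    counts = problem.rotamer_counts
    n_states = int(np.prod(counts, dtype=np.float64))
    if np.prod(counts, dtype=np.float64) > 1e6:
        raise ValueError(f"state space too large for enumeration ({n_states})")
    best = None
    best_e = math.inf
    for assignment in itertools.product(*[range(c) for c in counts]):
        e = problem.energy(assignment)
        if e < best_e:
            best_e = e
            best = assignment
    return np.asarray(best), best_e


def sweep(
    problem: PackingProblem,
    scores: np.ndarray,
    cutoffs: Sequence[float],
    repeats: int = 10,
    seed: int = 0,
    schedule=DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Cutoff sweep: prune at each cutoff, re-pack repeatedly, track energy and resources.

    ``scores`` holds one 54-long per-bin score vector per position (model
    predictions or oracle occupancies). The -1.0 control, when present, is
    run first; rows are sorted by retention, descending, so the control leads
    the table. Each (cutoff, repeat) pair gets its own derived seed.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (problem.n_positions, N_BINS):
        raise ValueError(
            f"scores must have shape ({problem.n_positions}, {N_BINS}), got {scores.shape}"
        )
    cutoffs = list(cutoffs)
    cutoffs.sort(key=lambda c: (c != -1.0, c))  # control first, then ascending
    children = np.random.SeedSequence(seed).spawn(len(cutoffs) * repeats)
    rows = []
    for ci, cutoff in enumerate(cutoffs):
        masks = [apply_cutoff(scores[i], cutoff) for i in range(problem.n_positions)]
        pruned, report = prune_problem(problem, masks)
        energies = []
        for rep in range(repeats):
            run_seed = children[ci * repeats + rep]
            _, e = toy_pack(pruned, schedule, seed=run_seed)
            energies.append(e)
        energies = np.asarray(energies)
        rows.append(
            {
                "cutoff": cutoff,
                "retention": report.retention,
                "rotamers": report.total_after,
                "logical_qubits": report.logical_qubits_after,
                "info_qubits": report.info_qubits_after,
                "pair_entries": report.pair_energy_entries_after,
                "log10_space_factor": report.log10_solution_space_factor,
                "mean_energy": float(energies.mean()),
                "sd_energy": float(energies.std(ddof=1)) if repeats > 1 else 0.0,
                "repeats": repeats,
                "seed": seed,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("retention", ascending=False, kind="stable").reset_index(drop=True)
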