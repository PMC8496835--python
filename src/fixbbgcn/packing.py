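"""Side-chain packing problems as one- and two-body energy tables.

A :class:`PackingProblem` is the classical pre-computation of a rotamer
optimization problem: every sequence position carries a list of candidate
rotamers (each tagged with its rotamer bin and an embedding vector), a
one-body energy per rotamer, and, for every interacting position pair, a
matrix of two-body energies over rotamer pairs. Total energy of an
assignment (one rotamer per position) is the sum of the selected one-body
energies plus the two-body energies over interacting pairs.

Two-body tables are stored for both ordered directions of each pair; the
energy sum uses the canonical ``i < j`` orientation. The two directions
need not be transposes of each other when the generating features are
direction dependent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = ["PackingProblem", "Trajectory"]


@dataclass
class PackingProblem:
    bins: List[np.ndarray]                       # per position: [D_i] rotamer-bin indices
    embeddings: List[np.ndarray]                 # per position: [D_i, k] unit rows
    one_body: List[np.ndarray]                   # per position: [D_i]
    two_body: Dict[Tuple[int, int], np.ndarray]  # ordered (i, j) -> [D_i, D_j]
    interacting_pairs: List[Tuple[int, int]] = field(default_factory=list)  # i < j

    def __post_init__(self):
        self.bins = [np.asarray(b, dtype=np.int64) for b in self.bins]
        self.one_body = [np.asarray(e, dtype=np.float64) for e in self.one_body]
        for i, j in self.interacting_pairs:
            for key in [(i, j), (j, i)]:
                if key not in self.two_body:
                    raise ValueError(f"missing two-body table for pair {key}")
            m = self.two_body[(i, j)]
            if m.shape != (self.n_rotamers(i), self.n_rotamers(j)):
                raise ValueError(
                    f"two_body[{(i, j)}] shape {m.shape} does not match rotamer counts"
                )

    @property
    def n_positions(self) -> int:
        return len(self.bins)

    def n_rotamers(self, i: int) -> int:
        return len(self.bins[i])

    @property
    def rotamer_counts(self) -> np.ndarray:
        return np.array([len(b) for b in self.bins])

    @property
    def total_rotamers(self) -> int:
        return int(self.rotamer_counts.sum())

    def neighbors(self) -> List[List[int]]:
        adj: List[List[int]] = [[] for _ in range(self.n_positions)]
        for i, j in self.interacting_pairs:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def pair_energy(self, i: int, r_i: int, j: int, r_j: int) -> float:
        """Two-body energy of (rotamer r_i at i, rotamer r_j at j), canonical orientation."""
        if i < j:
            return float(self.two_body[(i, j)][r_i, r_j])
        return float(self.two_body[(j, i)][r_j, r_i])

    def energy(self, assignment) -> float:
        """Total energy of one rotamer per position."""
        a = np.asarray(assignment, dtype=np.int64)
        if a.shape != (self.n_positions,):
            raise ValueError("assignment must name one rotamer per position")
        e = sum(float(self.one_body[i][a[i]]) for i in range(self.n_positions))
        for i, j in self.interacting_pairs:
            e += float(self.two_body[(i, j)][a[i], a[j]])
        return e

    def to_json(self, path) -> None:
        payload = {
            "n_positions": self.n_positions,
            "bins": [b.tolist() for b in self.bins],
            "embeddings": [np.asarray(v).tolist() for v in self.embeddings],
            "one_body": [e.tolist() for e in self.one_body],
            "interacting_pairs": [list(p) for p in self.interacting_pairs],
            "two_body": {
                f"{i},{j}": np.asarray(m).tolist() for (i, j), m in self.two_body.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PackingProblem":
        with open(path) as fh:
            payload = json.load(fh)
        two_body = {}
        for key, m in payload["two_body"].items():
            i, j = (int(v) for v in key.split(","))
            two_body[(i, j)] = np.asarray(m, dtype=np.float64)
        return cls(
            bins=[np.asarray(b) for b in payload["bins"]],
            embeddings=[np.asarray(v, dtype=np.float64) for v in payload["embeddings"]],
            one_body=[np.asarray(e) for e in payload["one_body"]],
            two_body=two_body,
            interacting_pairs=[tuple(p) for p in payload["interacting_pairs"]],
        )


@dataclass
class Trajectory:
    """Per-sweep record of an annealing run: temperature and representative rotamers."""

    temperatures: np.ndarray       # [n_recorded]
    states: np.ndarray             # [n_recorded, n_positions]

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.int64)
        if (self.temperatures <= 0).any():
            raise ValueError("temperatures must be positive")
        if self.states.shape[0] != self.temperatures.shape[0]:
            raise ValueError("states and temperatures must align per recorded step")
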