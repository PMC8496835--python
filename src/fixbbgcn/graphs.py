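"""Attributed residue-interaction graphs.

A graph here is the input object of the rotamer-bin classifier: one node per
sequence position, an undirected (symmetric) edge set connecting positions
that are close in space, and *directional* attribute vectors — ``edge_attrs[i, j]``
may differ from ``edge_attrs[j, i]`` even though the edge set itself is
symmetric, because most geometric pair features (frames, offsets) are
direction dependent.

The on-disk archive is JSON lines ("xegraph" format): a header record with
the attribute dimensions followed by one record per graph listing node
attributes and explicit directed edge rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

N_BINS = 54  #: number of rotamer-bin outputs (see synthetic.RotamerBinSpec)
DEFAULT_MAX_NODES = 30

__all__ = [
    "AttributedGraph",
    "GraphDataset",
    "GraphFormatError",
    "validate_graph",
    "permute_graph",
    "extract_focus_subgraph",
    "write_graphs",
    "read_graphs",
    "N_BINS",
    "DEFAULT_MAX_NODES",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph archives."""


@dataclass
class AttributedGraph:
    """A node-attributed graph with a symmetric edge set and asymmetric edge attributes.

    Parameters
    ----------
    node_attrs : (n, F) float array
    adjacency : (n, n) binary array, symmetric, zero diagonal
    edge_attrs : (n, n, S) float array, zero wherever ``adjacency`` is zero
    focus : optional node index of the residue position the classifier targets
    labels : optional 54-long 0/1 vector of occupied rotamer bins
    """

    node_attrs: np.ndarray
    adjacency: np.ndarray
    edge_attrs: np.ndarray
    focus: Optional[int] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self):
        self.node_attrs = np.asarray(self.node_attrs, dtype=np.float64)
        self.adjacency = np.asarray(self.adjacency)
        self.edge_attrs = np.asarray(self.edge_attrs, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def n_nodes(self) -> int:
        return self.node_attrs.shape[0]

    @property
    def n_node_attrs(self) -> int:
        return self.node_attrs.shape[1]

    @property
    def n_edge_attrs(self) -> int:
        return self.edge_attrs.shape[2]

    def copy(self) -> "AttributedGraph":
        return AttributedGraph(
            self.node_attrs.copy(),
            self.adjacency.copy(),
            self.edge_attrs.copy(),
            self.focus,
            None if self.labels is None else self.labels.copy(),
        )

    def equals(self, other: "AttributedGraph") -> bool:
        if self.focus != other.focus:
            return False
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        return (
            np.array_equal(self.node_attrs, other.node_attrs)
            and np.array_equal(self.adjacency, other.adjacency)
            and np.array_equal(self.edge_attrs, other.edge_attrs)
        )


@dataclass
class GraphDataset:
    """An ordered collection of graphs sharing attribute dimensions."""

    graphs: list = field(default_factory=list)
    n_node_attrs: int = 46
    n_edge_attrs: int = 28
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[AttributedGraph]:
        return iter(self.graphs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return GraphDataset(self.graphs[i], self.n_node_attrs, self.n_edge_attrs, dict(self.metadata))
        return self.graphs[i]

    @property
    def labeled(self) -> bool:
        return len(self.graphs) > 0 and all(g.labels is not None for g in self.graphs)

    def label_matrix(self) -> np.ndarray:
        return np.stack([g.labels for g in self.graphs]).astype(np.float64)


def validate_graph(g: AttributedGraph) -> list:
    """Return a list of human-readable invariant violations (empty when valid).

    Shape mismatches between members raise immediately; invariant violations
    (asymmetric adjacency, nonzero diagonal, nonzero attributes on absent
    edges, out-of-range focus) are collected with offending indices.
    """
    n = g.node_attrs.shape[0]
    if g.adjacency.shape != (n, n):
        raise ValueError(
            f"adjacency shape {g.adjacency.shape} inconsistent with {n} nodes"
        )
    if g.edge_attrs.shape[:2] != (n, n):
        raise ValueError(
            f"edge_attrs leading shape {g.edge_attrs.shape[:2]} inconsistent with {n} nodes"
        )
    report = []
    A = np.asarray(g.adjacency)
    bad = np.argwhere((A != 0) & (A != 1))
    for i, j in bad[:10]:
        report.append(f"adjacency[{i},{j}] is not binary")
    asym = np.argwhere(A != A.T)
    for i, j in asym:
        if i < j:
            report.append(f"adjacency not symmetric at ({i},{j})")
    diag = np.flatnonzero(np.diag(A))
    for i in diag:
        report.append(f"self-edge at node {i}")
    off = np.argwhere((A == 0) & (np.abs(g.edge_attrs).sum(axis=2) != 0))
    for i, j in off:
        report.append(f"nonzero edge_attrs[{i},{j}] on absent edge")
    if g.focus is not None and not (0 <= g.focus < n):
        report.append(f"focus {g.focus} out of range for {n} nodes")
    if g.labels is not None and g.labels.shape != (N_BINS,):
        report.append(f"labels shape {g.labels.shape} != ({N_BINS},)")
    return report


def permute_graph(g: AttributedGraph, perm: Sequence[int]) -> AttributedGraph:
    """Relabel node ``i`` as ``perm[i]`` consistently across every field.

    ``new.edge_attrs[perm[i], perm[j]] == g.edge_attrs[i, j]`` for all pairs;
    applying the inverse permutation restores the input exactly.
    """
    perm = np.asarray(perm)
    n = g.n_nodes
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("perm must be a bijection on 0..n_nodes-1")
    inv = np.argsort(perm)  # inv[new] = old
    X = g.node_attrs[inv]
    A = g.adjacency[np.ix_(inv, inv)]
    E = g.edge_attrs[np.ix_(inv, inv)]
    focus = None if g.focus is None else int(perm[g.focus])
    labels = None if g.labels is None else g.labels.copy()
    return AttributedGraph(X, A, E, focus, labels)


def extract_focus_subgraph(
    g_full: AttributedGraph,
    focus: int,
    max_nodes: int,
    positions: np.ndarray,
) -> AttributedGraph:
    """Crop to the focus node plus its nearest neighbors in space.

    Keeps ``focus`` and the ``max_nodes - 1`` nearest other nodes by Euclidean
    distance from ``positions`` (ties broken by lower node index), copies the
    induced edges and attributes, and remaps the focus index. Selected nodes
    keep their relative original order.
    """
    if max_nodes < 1:
        raise ValueError("max_nodes must be >= 1")
    n = g_full.n_nodes
    if not 0 <= focus < n:
        raise ValueError(f"focus {focus} out of range")
    positions = np.asarray(positions, dtype=np.float64)
    d = np.linalg.norm(positions - positions[focus], axis=1)
    others = [i for i in range(n) if i != focus]
    others.sort(key=lambda i: (d[i], i))
    chosen = sorted([focus] + others[: max_nodes - 1])
    idx = np.asarray(chosen)
    sub = AttributedGraph(
        g_full.node_attrs[idx],
        g_full.adjacency[np.ix_(idx, idx)],
        g_full.edge_attrs[np.ix_(idx, idx)],
        focus=chosen.index(focus),
        labels=None if g_full.labels is None else g_full.labels.copy(),
    )
    return sub


def _graph_record(g: AttributedGraph) -> dict:
    edges = []
    A = np.asarray(g.adjacency)
    for i, j in np.argwhere(A == 1):
        edges.append([int(i), int(j)] + [float(v) for v in g.edge_attrs[i, j]])
    return {
        "n": int(g.n_nodes),
        "F": int(g.n_node_attrs),
        "S": int(g.n_edge_attrs),
        "focus": None if g.focus is None else int(g.focus),
        "labels": None if g.labels is None else [int(v) for v in g.labels],
        "X": [[float(v) for v in row] for row in g.node_attrs],
        "edges": edges,
    }


def write_graphs(path, ds: GraphDataset) -> None:
    """Write a dataset in the xegraph JSON-lines archive format."""
    header = {
        "format": "xegraph",
        "version": 1,
        "F": int(ds.n_node_attrs),
        "S": int(ds.n_edge_attrs),
    }
    if ds.metadata:
        header["metadata"] = ds.metadata
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for g in ds.graphs:
            fh.write(json.dumps(_graph_record(g)) + "\n")


def read_graphs(path) -> GraphDataset:
    """Read an xegraph archive, validating dimensions record by record."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GraphFormatError("empty archive: missing header line")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise GraphFormatError(f"malformed header: {exc}") from exc
    if not isinstance(header, dict) or header.get("format") != "xegraph":
        raise GraphFormatError("header does not declare format 'xegraph'")
    if header.get("version") != 1:
        raise GraphFormatError(f"unsupported archive version {header.get('version')!r}")
    F, S = int(header["F"]), int(header["S"])
    graphs = []
    for rec_no, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise GraphFormatError(f"record {rec_no}: malformed JSON: {exc}") from exc
        if rec.get("F") != F or rec.get("S") != S:
            raise GraphFormatError(
                f"record {rec_no}: dims (F={rec.get('F')}, S={rec.get('S')}) "
                f"disagree with header (F={F}, S={S})"
            )
        n = int(rec["n"])
        X = np.asarray(rec["X"], dtype=np.float64)
        if X.shape != (n, F):
            raise GraphFormatError(f"record {rec_no}: X shape {X.shape} != ({n}, {F})")
        A = np.zeros((n, n), dtype=np.int8)
        E = np.zeros((n, n, S), dtype=np.float64)
        for row in rec["edges"]:
            if len(row) != 2 + S:
                raise GraphFormatError(
                    f"record {rec_no}: edge row carries {len(row) - 2} attribute "
                    f"values, expected {S}"
                )
            i, j = int(row[0]), int(row[1])
            if not (0 <= i < n and 0 <= j < n):
                raise GraphFormatError(f"record {rec_no}: edge index ({i},{j}) out of range")
            A[i, j] = 1
            E[i, j] = row[2:]
        labels = rec.get("labels")
        g = AttributedGraph(
            X, A, E,
            focus=rec.get("focus"),
            labels=None if labels is None else np.asarray(labels, dtype=np.int8),
        )
        problems = validate_graph(g)
        if problems:
            raise GraphFormatError(f"record {rec_no}: {problems[0]}")
        graphs.append(g)
    return GraphDataset(graphs, F, S, header.get("metadata", {}))
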