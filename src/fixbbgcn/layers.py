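"""Message-passing layers for symmetric directed graphs with asymmetric edge attributes.

Three layer kinds are provided as explicit parameter records plus pure
forward functions:

* **XENet** — the edge-aware convolution at the core of this package. For
  every ordered node pair ``(i, j)`` on an edge it builds a *feature stack*

      s_ij = phi_s(x_i || x_j || e_ij || e_ji)

  from both endpoints and both directional edge attributes, aggregates the
  stacks separately along the outgoing and incoming directions with scalar
  sigmoid self-attention gates,

      s_i_out = sum_j a_out(s_ij) * s_ij
      s_i_in  = sum_j a_in(s_ij)  * s_ji

  updates nodes with ``x'_i = phi_n(x_i || s_i_out || s_i_in)`` and,
  optionally, edges with ``e'_ij = phi_e(s_ij)``. The MLPs use PReLU
  activations with per-channel slopes; ``phi_s`` always has depth 2.

* **CrystalConv** — gated residual aggregation over incoming messages:
  ``x'_i = x_i + sum_j sigmoid(z_ij W_f + b_f) * softplus(z_ij W_s + b_s)``
  with ``z_ij = x_i || x_j || e_ji``. Requires equal input/output node width.

* **ECC** — edge-conditioned convolution: a filter-generating network maps
  each incoming edge attribute to a full weight matrix,
  ``x'_i = mean_j Theta(e_ji) x_j + bias``.

All forwards accept batched inputs ``[B, N, ...]`` internally; the public
functions take a single graph's ``(X, A, E)`` arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _autodiff as ad

__all__ = [
    "AffinePReLU",
    "XENetParams",
    "CrystalParams",
    "ECCParams",
    "init_params",
    "count_params",
    "xenet_forward",
    "crystal_forward",
    "ecc_forward",
    "save_params",
    "load_params",
]


@dataclass
class AffinePReLU:
    """One dense layer ``y = act(x W + b)``; ``slope`` present for PReLU, None for linear."""

    W: np.ndarray
    b: np.ndarray
    slope: Optional[np.ndarray] = None

    def arrays(self):
        out = {"W": self.W, "b": self.b}
        if self.slope is not None:
            out["slope"] = self.slope
        return out


@dataclass
class XENetParams:
    stack_mlp: List[AffinePReLU]      # phi_s, depth 2, widths S_h
    gate_out: AffinePReLU             # a_out: S_h -> 1, sigmoid
    gate_in: AffinePReLU              # a_in:  S_h -> 1, sigmoid
    node_mlp: List[AffinePReLU]       # phi_n: (F_in + 2 S_h) -> F_out
    edge_mlp: List[AffinePReLU]       # phi_e: S_h -> S_out
    include_edge_output: bool = True
    gate_arg_swapped: bool = False    # gate s_ji by a_in(s_ji) instead of a_in(s_ij)

    kind = "xenet"


@dataclass
class CrystalParams:
    filter_map: AffinePReLU           # (2F + S) -> F, sigmoid gate
    core_map: AffinePReLU             # (2F + S) -> F, softplus core

    kind = "crystal"


@dataclass
class ECCParams:
    fgn_hidden: AffinePReLU           # S -> S_h, ReLU
    fgn_out: AffinePReLU              # S_h -> F_in * F_out, linear
    bias: np.ndarray                  # [F_out]
    f_in: int = 0
    f_out: int = 0

    kind = "ecc"


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


def _affine(rng, n_in, n_out, prelu: bool) -> AffinePReLU:
    return AffinePReLU(
        W=_uniform(rng, n_in, (n_in, n_out)),
        b=np.zeros(n_out),
        slope=np.full(n_out, 0.25) if prelu else None,
    )


def init_params(
    kind: str,
    F_in: int,
    S_in: int,
    F_out: int,
    S_out: int,
    S_h: int,
    seed: int,
    *,
    node_mlp_depth: int = 1,
    edge_mlp_depth: int = 1,
    include_edge_output: bool = True,
    gate_arg_swapped: bool = False,
):
    """Seeded initialization of one layer's parameter record.

    Weights are fan-in-scaled uniform (limit ``sqrt(6 / fan_in)``), biases
    zero, PReLU slopes 0.25.
    """
    for name, w in [("F_in", F_in), ("S_in", S_in), ("F_out", F_out),
                    ("S_out", S_out), ("S_h", S_h)]:
        if w < 1:
            raise ValueError(f"{name} must be positive, got {w}")
    rng = np.random.default_rng(seed)
    if kind == "xenet":
        stack = [
            _affine(rng, 2 * F_in + 2 * S_in, S_h, prelu=True),
            _affine(rng, S_h, S_h, prelu=True),
        ]
        gate_out = _affine(rng, S_h, 1, prelu=False)
        gate_in = _affine(rng, S_h, 1, prelu=False)
        node_widths = [F_in + 2 * S_h] + [F_out] * node_mlp_depth
        node = [_affine(rng, node_widths[i], node_widths[i + 1], prelu=True)
                for i in range(node_mlp_depth)]
        edge_widths = [S_h] + [S_out] * edge_mlp_depth
        edge = [_affine(rng, edge_widths[i], edge_widths[i + 1], prelu=True)
                for i in range(edge_mlp_depth)]
        return XENetParams(stack, gate_out, gate_in, node, edge,
                           include_edge_output, gate_arg_swapped)
    if kind == "crystal":
        if F_in != F_out:
            raise ValueError(
                f"CrystalConv is a residual update and needs F_in == F_out "
                f"(got {F_in} != {F_out})"
            )
        z = 2 * F_in + S_in
        return CrystalParams(_affine(rng, z, F_in, prelu=False),
                             _affine(rng, z, F_in, prelu=False))
    if kind == "ecc":
        return ECCParams(
            fgn_hidden=_affine(rng, S_in, S_h, prelu=False),
            fgn_out=_affine(rng, S_h, F_in * F_out, prelu=False),
            bias=np.zeros(F_out),
            f_in=F_in,
            f_out=F_out,
        )
    raise ValueError(f"unknown layer kind {kind!r}")


def _count_affine(layer: AffinePReLU) -> int:
    n = layer.W.size + layer.b.size
    if layer.slope is not None:
        n += layer.slope.size
    return n


def count_params(p) -> int:
    """Count every learnable scalar in a layer record (weights, biases, PReLU slopes).

    For XENet, the edge MLP is omitted when ``include_edge_output`` is False —
    matching the convention of not tallying parameters that only build a final,
    unused edge tensor.
    """
    if isinstance(p, XENetParams):
        n = sum(_count_affine(l) for l in p.stack_mlp)
        n += _count_affine(p.gate_out) + _count_affine(p.gate_in)
        n += sum(_count_affine(l) for l in p.node_mlp)
        if p.include_edge_output:
            n += sum(_count_affine(l) for l in p.edge_mlp)
        return n
    if isinstance(p, CrystalParams):
        return _count_affine(p.filter_map) + _count_affine(p.core_map)
    if isinstance(p, ECCParams):
        return _count_affine(p.fgn_hidden) + _count_affine(p.fgn_out) + p.bias.size
    raise TypeError(f"not a layer parameter record: {type(p)!r}")


# ---------------------------------------------------------------------------
# autodiff forwards (batched [B, N, ...]); used by the model builder and by
# the public single-graph wrappers below.
# ---------------------------------------------------------------------------

def _apply_affine(t, layer, lift):
    W, b = lift(layer.W), lift(layer.b)
    out = ad.add(ad.einsum("...i,io->...o", t, W), b)
    if layer.slope is not None:
        out = ad.prelu(out, lift(layer.slope))
    return out


def _apply_mlp(t, layers, lift):
    for layer in layers:
        t = _apply_affine(t, layer, lift)
    return t


def _pair_grid(X, n):
    """Broadcast node attrs to ordered-pair grids Xi [B,N,N,F] and Xj."""
    B, N, F = X.shape
    ones_row = ad.constant(np.ones((1, 1, N, 1)))
    ones_col = ad.constant(np.ones((1, N, 1, 1)))
    Xi = ad.mul(ad.reshape(X, (B, N, 1, F)), ones_row)
    Xj = ad.mul(ad.reshape(X, (B, 1, N, F)), ones_col)
    return Xi, Xj


def xenet_forward_ad(X, A: np.ndarray, E, p: XENetParams, lift=ad.constant):
    """XENet forward on autodiff tensors. ``A`` is a plain [B,N,N] 0/1 array."""
    B, N, _ = X.shape
    Amask = ad.constant(A[..., None].astype(np.float64))
    Xi, Xj = _pair_grid(X, N)
    E_T = ad.transpose(E, (0, 2, 1, 3))
    stack_in = ad.concat([Xi, Xj, E, E_T], axis=-1)
    S = _apply_mlp(stack_in, p.stack_mlp, lift)          # s_ij  [B,N,N,S_h]
    S_T = ad.transpose(S, (0, 2, 1, 3))                  # s_ji

    g_out = ad.sigmoid(_apply_affine(S, p.gate_out, lift))           # a_out(s_ij)
    gin_arg = S_T if p.gate_arg_swapped else S
    g_in = ad.sigmoid(_apply_affine(gin_arg, p.gate_in, lift))       # a_in(s_ij)

    s_out = ad.reduce_sum(ad.mul(ad.mul(g_out, S), Amask), axis=2)
    s_in = ad.reduce_sum(ad.mul(ad.mul(g_in, S_T), Amask), axis=2)

    X_new = _apply_mlp(ad.concat([X, s_out, s_in], axis=-1), p.node_mlp, lift)
    E_new = None
    if p.include_edge_output:
        E_new = ad.mul(_apply_mlp(S, p.edge_mlp, lift), Amask)
    return X_new, E_new


def crystal_forward_ad(X, A: np.ndarray, E, p: CrystalParams, lift=ad.constant):
    B, N, _ = X.shape
    Amask = ad.constant(A[..., None].astype(np.float64))
    Xi, Xj = _pair_grid(X, N)
    E_T = ad.transpose(E, (0, 2, 1, 3))                  # e_ji at [i, j]
    Z = ad.concat([Xi, Xj, E_T], axis=-1)
    gate = ad.sigmoid(_apply_affine(Z, p.filter_map, lift))
    core = ad.softplus(_apply_affine(Z, p.core_map, lift))
    msg = ad.mul(ad.mul(gate, core), Amask)
    return ad.add(X, ad.reduce_sum(msg, axis=2))


def ecc_forward_ad(X, A: np.ndarray, E, p: ECCParams, lift=ad.constant):
    B, N, _ = X.shape
    E_T = ad.transpose(E, (0, 2, 1, 3))                  # e_ji at [i, j]
    h = ad.relu(_apply_affine(E_T, p.fgn_hidden, lift))
    theta = ad.reshape(_apply_affine(h, p.fgn_out, lift),
                       (B, N, N, p.f_in, p.f_out))
    Amask = ad.constant(A[:, :, :, None, None].astype(np.float64))
    theta = ad.mul(theta, Amask)
    msg = ad.einsum("bjf,bijfo->bio", X, theta)
    deg = A.sum(axis=2).astype(np.float64)               # [B, N]
    scale = ad.constant((1.0 / np.maximum(deg, 1.0))[..., None])
    return ad.add(ad.mul(msg, scale), lift(p.bias))


# ---------------------------------------------------------------------------
# public single-graph numpy wrappers
# ---------------------------------------------------------------------------

def _check_inputs(X, A, E, f_expect=None, s_expect=None):
    X = np.asarray(X, dtype=np.float64)
    A = np.asarray(A)
    E = np.asarray(E, dtype=np.float64)
    n = X.shape[0]
    if A.shape != (n, n) or E.shape[:2] != (n, n):
        raise ValueError("X, A, E shapes are inconsistent")
    if np.isnan(X).any() or np.isnan(E).any():
        raise FloatingPointError("NaN in layer inputs")
    if ((A == 0) & (np.abs(E).sum(axis=2) != 0)).any():
        raise ValueError("edge_attrs nonzero on an absent edge")
    if f_expect is not None and X.shape[1] != f_expect:
        raise ValueError(f"node width {X.shape[1]} does not match layer ({f_expect})")
    if s_expect is not None and E.shape[2] != s_expect:
        raise ValueError(f"edge width {E.shape[2]} does not match layer ({s_expect})")
    return X, A, E


def xenet_forward(X, A, E, p: XENetParams) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Apply one XENet layer to a single graph.

    Returns ``(X', E')``; ``E'`` is None when the record omits the edge output.
    The zero pattern of ``E'`` matches ``A`` exactly, and nodes with empty
    neighborhoods receive zero vectors for both directional aggregates.
    """
    X, A, E = _check_inputs(X, A, E)
    two_fs = p.stack_mlp[0].W.shape[0]
    if 2 * X.shape[1] + 2 * E.shape[2] != two_fs:
        raise ValueError(
            f"stack MLP expects 2F+2S = {two_fs}, got F={X.shape[1]}, S={E.shape[2]}"
        )
    Xn, En = xenet_forward_ad(
        ad.constant(X[None]), A[None], ad.constant(E[None]), p
    )
    return Xn.value[0], (None if En is None else En.value[0])


def crystal_forward(X, A, E, p: CrystalParams) -> np.ndarray:
    X, A, E = _check_inputs(X, A, E)
    if 2 * X.shape[1] + E.shape[2] != p.filter_map.W.shape[0]:
        raise ValueError("CrystalConv widths do not match inputs")
    out = crystal_forward_ad(ad.constant(X[None]), A[None], ad.constant(E[None]), p)
    return out.value[0]


def ecc_forward(X, A, E, p: ECCParams) -> np.ndarray:
    X, A, E = _check_inputs(X, A, E, f_expect=p.f_in)
    if E.shape[2] != p.fgn_hidden.W.shape[0]:
        raise ValueError("ECC FGN input width does not match edge attributes")
    out = ecc_forward_ad(ad.constant(X[None]), A[None], ad.constant(E[None]), p)
    return out.value[0]


# ---------------------------------------------------------------------------
# named-array serialization
# ---------------------------------------------------------------------------

def _record_arrays(p) -> Tuple[dict, dict]:
    """Flatten a parameter record into (manifest, name->array)."""
    arrays = {}
    if isinstance(p, XENetParams):
        manifest = {
            "kind": "xenet",
            "stack_depth": len(p.stack_mlp),
            "node_depth": len(p.node_mlp),
            "edge_depth": len(p.edge_mlp),
            "include_edge_output": p.include_edge_output,
            "gate_arg_swapped": p.gate_arg_swapped,
        }
        groups = (
            [(f"stack{i}", l) for i, l in enumerate(p.stack_mlp)]
            + [("gate_out", p.gate_out), ("gate_in", p.gate_in)]
            + [(f"node{i}", l) for i, l in enumerate(p.node_mlp)]
            + [(f"edge{i}", l) for i, l in enumerate(p.edge_mlp)]
        )
        for prefix, layer in groups:
            for name, arr in layer.arrays().items():
                arrays[f"{prefix}.{name}"] = arr
    elif isinstance(p, CrystalParams):
        manifest = {"kind": "crystal"}
        for prefix, layer in [("filter", p.filter_map), ("core", p.core_map)]:
            for name, arr in layer.arrays().items():
                arrays[f"{prefix}.{name}"] = arr
    elif isinstance(p, ECCParams):
        manifest = {"kind": "ecc", "f_in": p.f_in, "f_out": p.f_out}
        for prefix, layer in [("fgn_hidden", p.fgn_hidden), ("fgn_out", p.fgn_out)]:
            for name, arr in layer.arrays().items():
                arrays[f"{prefix}.{name}"] = arr
        arrays["bias"] = p.bias
    else:
        raise TypeError(f"not a layer parameter record: {type(p)!r}")
    return manifest, arrays


def save_params(path, p) -> None:
    """Serialize a parameter record as a JSON named-array archive."""
    manifest, arrays = _record_arrays(p)
    payload = {
        "manifest": manifest,
        "arrays": {
            name: {"shape": list(arr.shape), "values": arr.ravel().tolist()}
            for name, arr in arrays.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _read_affine(arrays, prefix) -> AffinePReLU:
    slope = arrays.get(f"{prefix}.slope")
    return AffinePReLU(arrays[f"{prefix}.W"], arrays[f"{prefix}.b"], slope)


def load_params(path):
    with open(path) as fh:
        payload = json.load(fh)
    manifest = payload["manifest"]
    arrays = {
        name: np.asarray(spec["values"], dtype=np.float64).reshape(spec["shape"])
        for name, spec in payload["arrays"].items()
    }
    kind = manifest["kind"]
    if kind == "xenet":
        return XENetParams(
            stack_mlp=[_read_affine(arrays, f"stack{i}") for i in range(manifest["stack_depth"])],
            gate_out=_read_affine(arrays, "gate_out"),
            gate_in=_read_affine(arrays, "gate_in"),
            node_mlp=[_read_affine(arrays, f"node{i}") for i in range(manifest["node_depth"])],
            edge_mlp=[_read_affine(arrays, f"edge{i}") for i in range(manifest["edge_depth"])],
            include_edge_output=manifest["include_edge_output"],
            gate_arg_swapped=manifest["gate_arg_swapped"],
        )
    if kind == "crystal":
        return CrystalParams(_read_affine(arrays, "filter"), _read_affine(arrays, "core"))
    if kind == "ecc":
        return ECCParams(
            _read_affine(arrays, "fgn_hidden"),
            _read_affine(arrays, "fgn_out"),
            arrays["bias"],
            manifest["f_in"],
            manifest["f_out"],
        )
    raise ValueError(f"unknown layer kind {kind!r}")
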