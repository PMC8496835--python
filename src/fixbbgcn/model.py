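"""FixbbGCN: a single-node multi-label classifier over residue-interaction graphs.

The network predicts, for one focus position of a packing problem, which of
the 54 rotamer bins the annealer will actually visit. Architecture:

    X --dense(F_h, ReLU)--\\
    E --dense(S_h, ReLU)---+--> n message-passing layers (XENet / CrystalConv / ECC)
                           |        (the last XENet layer omits its edge output)
    X_in ------------------+--> concat(conv output, raw input X)   # skip vs over-smoothing
                           +--> crop to the focus node
                           +--> dense(100, ReLU) --> dense(54, sigmoid)

Training follows the harness the use case calls for: Adam at 0.001 on mean
binary crossentropy, the learning rate divided by 10 when validation loss
plateaus for 2 consecutive epochs (min_delta 0.001), early stop after a
5-epoch plateau, best-validation weights restored.

The surface is modelling-object style: build a :class:`FixbbGCN` from a
config, call :meth:`~FixbbGCN.fit` to get a :class:`FitResults` carrying the
history and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import _autodiff as ad
from .graphs import AttributedGraph, GraphDataset, N_BINS
from .layers import (
    AffinePReLU,
    XENetParams,
    CrystalParams,
    ECCParams,
    init_params,
    count_params,
    xenet_forward_ad,
    crystal_forward_ad,
    ecc_forward_ad,
    _affine,
    _apply_affine,
    _record_arrays,
)

__all__ = [
    "FixbbGCNConfig",
    "TrainConfig",
    "FixbbGCN",
    "FitResults",
    "build_model",
    "train",
    "evaluate",
    "predict",
    "binary_crossentropy",
    "micro_auc",
    "PRESETS",
]

#: published sizing presets: (conv_kind, F_h, S_h)
PRESETS = {
    "ecc": ("ecc", 49, 32),
    "crystal_s": ("crystal", 49, 32),
    "crystal_p": ("crystal", 125, 64),
    "xenet_s": ("xenet", 49, 32),
    "xenet_p": ("xenet", 128, 64),
}


@dataclass
class FixbbGCNConfig:
    conv_kind: str = "xenet"
    n_conv_layers: int = 3
    F_h: int = 32
    S_h: int = 16
    head_width: int = 100
    n_outputs: int = N_BINS
    max_nodes: int = 30
    F_in: int = 46
    S_in: int = 28

    def __post_init__(self):
        if self.conv_kind not in ("xenet", "crystal", "ecc"):
            raise ValueError(f"unknown conv kind {self.conv_kind!r}")
        if self.n_conv_layers < 1:
            raise ValueError("the architecture requires at least one message-passing layer")
        for name in ("F_h", "S_h", "head_width", "n_outputs", "max_nodes", "F_in", "S_in"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def preset(cls, name: str, n_conv_layers: int = 3, **kw) -> "FixbbGCNConfig":
        kind, fh, sh = PRESETS[name]
        return cls(conv_kind=kind, n_conv_layers=n_conv_layers, F_h=fh, S_h=sh, **kw)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    lr_drop_factor: float = 10.0
    plateau_patience: int = 2
    plateau_min_delta: float = 0.001
    stop_patience: int = 5
    batch_size: int = 64
    max_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.plateau_patience < 1 or self.stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.lr_drop_factor <= 1:
            raise ValueError("lr_drop_factor must exceed 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def binary_crossentropy(labels: np.ndarray, probs: np.ndarray, clip: float = 1e-7) -> float:
    """Mean BCE over all (sample, output) pairs, with probability clipping."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.clip(np.asarray(probs, dtype=np.float64), clip, 1.0 - clip)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def micro_auc(labels: np.ndarray, probs: np.ndarray) -> float:
    """Micro-averaged ROC AUC over the flattened (label, score) pool."""
    y = np.asarray(labels).ravel()
    p = np.asarray(probs, dtype=np.float64).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: all labels identical across the pool")
    return float(roc_auc_score(y, p))


def _pad_batch(graphs: List[AttributedGraph], cfg: FixbbGCNConfig):
    """Pad a list of graphs into dense [B, N, ...] arrays with node masks.

    Pads to the largest graph in the batch (never beyond ``cfg.max_nodes``);
    padded rows are masked out of every aggregation, so the result is
    independent of the padding width.
    """
    B = len(graphs)
    N = min(cfg.max_nodes, max(g.n_nodes for g in graphs))
    X = np.zeros((B, N, cfg.F_in))
    A = np.zeros((B, N, N), dtype=np.int8)
    E = np.zeros((B, N, N, cfg.S_in))
    mask = np.zeros((B, N))
    focus = np.zeros(B, dtype=np.int64)
    for b, g in enumerate(graphs):
        n = g.n_nodes
        if n > N:
            raise ValueError(f"graph with {n} nodes exceeds max_nodes={N}")
        if g.focus is None:
            raise ValueError("every graph needs a focus node for single-node prediction")
        if g.n_node_attrs != cfg.F_in or g.n_edge_attrs != cfg.S_in:
            raise ValueError("graph attribute dims do not match the model config")
        X[b, :n] = g.node_attrs
        A[b, :n, :n] = g.adjacency
        E[b, :n, :n] = g.edge_attrs
        mask[b, :n] = 1.0
        focus[b] = g.focus
    return X, A, E, mask, focus


class _Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(self, arrays, lr: float):
        self.arrays = arrays
        self.lr = lr
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class FixbbGCN:
    """The assembled trainable network (see module docstring for the layout)."""

    def __init__(self, config: FixbbGCNConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        cfg = config
        self.pre_x = _affine(rng, cfg.F_in, cfg.F_h, prelu=False)
        self.pre_e = _affine(rng, cfg.S_in, cfg.S_h, prelu=False)
        self.convs = []
        for layer in range(cfg.n_conv_layers):
            child = int(rng.integers(0, 2**31))
            if cfg.conv_kind == "xenet":
                last = layer == cfg.n_conv_layers - 1
                p = init_params(
                    "xenet", cfg.F_h, cfg.S_h, cfg.F_h, cfg.S_h, cfg.S_h, child,
                    include_edge_output=not last,
                )
                if last:
                    p.edge_mlp = []   # truly omit the unused final edge head
            else:
                p = init_params(cfg.conv_kind, cfg.F_h, cfg.S_h, cfg.F_h, cfg.S_h,
                                cfg.S_h, child)
            self.convs.append(p)
        self.head = _affine(rng, cfg.F_h + cfg.F_in, cfg.head_width, prelu=False)
        self.out = _affine(rng, cfg.head_width, cfg.n_outputs, prelu=False)

    # -- parameter bookkeeping ------------------------------------------------

    def _records(self):
        recs = [("pre_x", self.pre_x), ("pre_e", self.pre_e)]
        recs += [(f"conv{i}", p) for i, p in enumerate(self.convs)]
        recs += [("head", self.head), ("out", self.out)]
        return recs

    def parameter_arrays(self):
        """Ordered (name, array) pairs of every trainable scalar array."""
        out = []
        for name, rec in self._records():
            if isinstance(rec, AffinePReLU):
                for k, arr in rec.arrays().items():
                    out.append((f"{name}.{k}", arr))
            else:
                _, arrays = _record_arrays(rec)
                for k, arr in arrays.items():
                    out.append((f"{name}.{k}", arr))
        return out

    @property
    def n_params(self) -> int:
        return int(sum(arr.size for _, arr in self.parameter_arrays()))

    def conv_param_counts(self) -> List[int]:
        return [count_params(p) for p in self.convs]

    # -- forward --------------------------------------------------------------

    def _forward(self, X, A, E, mask, focus, lift):
        cfg = self.config
        Xt = ad.constant(X)
        Et = ad.constant(E)
        mask3 = ad.constant(mask[..., None])
        Amask = ad.constant(A[..., None].astype(np.float64))
        Xh = ad.mul(ad.relu(_apply_affine(Xt, self.pre_x, lift)), mask3)
        Eh = ad.mul(ad.relu(_apply_affine(Et, self.pre_e, lift)), Amask)
        for p in self.convs:
            if isinstance(p, XENetParams):
                Xh, Enew = xenet_forward_ad(Xh, A, Eh, p, lift)
                if Enew is not None:
                    Eh = Enew
            elif isinstance(p, CrystalParams):
                Xh = crystal_forward_ad(Xh, A, Eh, p, lift)
            elif isinstance(p, ECCParams):
                Xh = ecc_forward_ad(Xh, A, Eh, p, lift)
            Xh = ad.mul(Xh, mask3)
        skip = ad.concat([Xh, Xt], axis=-1)
        focus_row = ad.gather_rows(skip, focus)
        hidden = ad.relu(_apply_affine(focus_row, self.head, lift))
        return _apply_affine(hidden, self.out, lift)   # logits [B, 54]

    def _predict_arrays(self, X, A, E, mask, focus) -> np.ndarray:
        logits = self._forward(X, A, E, mask, focus, ad.constant)
        return 1.0 / (1.0 + np.exp(-logits.value))

    def predict(self, g: AttributedGraph) -> np.ndarray:
        """54 sigmoid scores in (0, 1) for the graph's focus node."""
        if g.focus is None:
            raise ValueError("graph has no focus node")
        X, A, E, mask, focus = _pad_batch([g], self.config)
        return self._predict_arrays(X, A, E, mask, focus)[0]

    def predict_batch(self, ds, batch_size: int = 128) -> np.ndarray:
        graphs = list(ds)
        out = np.zeros((len(graphs), self.config.n_outputs))
        for start in range(0, len(graphs), batch_size):
            chunk = graphs[start : start + batch_size]
            out[start : start + len(chunk)] = self._predict_arrays(
                *_pad_batch(chunk, self.config)
            )
        return out

    # -- training -------------------------------------------------------------

    def evaluate(self, ds: GraphDataset) -> Tuple[float, float]:
        """(mean binary crossentropy, micro-averaged ROC AUC) on a labeled dataset."""
        if not ds.labeled:
            raise ValueError("dataset is unlabeled")
        probs = self.predict_batch(ds)
        y = ds.label_matrix()
        return binary_crossentropy(y, probs), micro_auc(y, probs)

    def fit(self, train_ds: GraphDataset, val_ds: GraphDataset,
            tc: Optional[TrainConfig] = None, callback=None) -> "FitResults":
        """Train with Adam + plateau LR drops + early stopping; restores best weights.

        ``callback(epoch, row)`` — when given — is invoked after each epoch with
        the history row and may return True to stop training early.
        """
        tc = tc or TrainConfig()
        for name, ds in [("train", train_ds), ("val", val_ds)]:
            if not ds.labeled:
                raise ValueError(f"{name} dataset is unlabeled")
        rng = np.random.default_rng(tc.seed)
        arrays = [arr for _, arr in self.parameter_arrays()]
        opt = _Adam(arrays, tc.learning_rate)
        graphs = list(train_ds)
        y_train = train_ds.label_matrix()

        history = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        lr_best, lr_wait = np.inf, 0
        stop_best, stop_wait = np.inf, 0

        for epoch in range(tc.max_epochs):
            order = rng.permutation(len(graphs))
            train_losses, train_sizes = [], []
            for start in range(0, len(order), tc.batch_size):
                idx = order[start : start + tc.batch_size]
                batch = [graphs[i] for i in idx]
                X, A, E, mask, focus = _pad_batch(batch, self.config)
                cache = {}

                def lift(arr, _cache=cache):
                    t = _cache.get(id(arr))
                    if t is None:
                        t = ad.parameter(arr)
                        _cache[id(arr)] = t
                    return t

                logits = self._forward(X, A, E, mask, focus, lift)
                loss = ad.bce_with_logits(logits, y_train[idx])
                ad.backward(loss)
                grads = [
                    cache[id(arr)].grad if id(arr) in cache else None
                    for arr in arrays
                ]
                opt.step(grads)
                train_losses.append(float(loss.value))
                train_sizes.append(len(idx))

            train_bce = float(np.average(train_losses, weights=train_sizes))
            val_bce, val_auc = self.evaluate(val_ds)
            row = {
                "epoch": epoch,
                "lr": opt.lr,
                "train_bce": train_bce,
                "val_bce": val_bce,
                "val_auc": val_auc,
            }
            history.append(row)

            if val_bce < best_val:
                best_val = val_bce
                best_epoch = epoch
                best_state = [arr.copy() for arr in arrays]

            # independent plateau monitors for LR drop and early stop
            if lr_best - val_bce > tc.plateau_min_delta:
                lr_best, lr_wait = val_bce, 0
            else:
                lr_wait += 1
                if lr_wait >= tc.plateau_patience:
                    opt.lr /= tc.lr_drop_factor
                    lr_wait = 0
            if stop_best - val_bce > tc.plateau_min_delta:
                stop_best, stop_wait = val_bce, 0
            else:
                stop_wait += 1

            if callback is not None and callback(epoch, row):
                break
            if stop_wait >= tc.stop_patience:
                break

        if best_state is not None:
            for arr, best in zip(arrays, best_state):
                arr[...] = best
        return FitResults(
            model=self,
            history=pd.DataFrame(
                history, columns=["epoch", "lr", "train_bce", "val_bce", "val_auc"]
            ),
            best_epoch=best_epoch,
            best_val_bce=float(best_val) if best_epoch >= 0 else np.nan,
            train_config=tc,
        )

    # -- persistence ----------------------------------------------------------

    def save(self, path, extra_manifest: Optional[dict] = None) -> None:
        """Checkpoint: JSON manifest (config, seed) plus named arrays."""
        arrays = dict(self.parameter_arrays())
        payload = {
            "manifest": {
                "config": asdict(self.config),
                "seed": self.seed,
                **(extra_manifest or {}),
            },
            "arrays": {
                name: {"shape": list(a.shape), "values": a.ravel().tolist()}
                for name, a in arrays.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FixbbGCN":
        with open(path) as fh:
            payload = json.load(fh)
        manifest = payload["manifest"]
        model = cls(FixbbGCNConfig(**manifest["config"]), seed=manifest["seed"])
        stored = {
            name: np.asarray(spec["values"], dtype=np.float64).reshape(spec["shape"])
            for name, spec in payload["arrays"].items()
        }
        for name, arr in model.parameter_arrays():
            arr[...] = stored[name]
        return model


@dataclass
class FitResults:
    """Outcome of one training run: best model, history, and diagnostics."""

    model: FixbbGCN
    history: pd.DataFrame
    best_epoch: int
    best_val_bce: float
    train_config: TrainConfig

    def evaluate(self, ds: GraphDataset) -> Tuple[float, float]:
        return self.model.evaluate(ds)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "FixbbGCN fit results",
            "====================",
            f"conv kind        : {cfg.conv_kind}",
            f"conv layers      : {cfg.n_conv_layers}",
            f"F_h / S_h        : {cfg.F_h} / {cfg.S_h}",
            f"trainable params : {self.model.n_params}",
            f"epochs run       : {len(self.history)}",
            f"best epoch       : {self.best_epoch}",
            f"best val BCE     : {self.best_val_bce:.4f}",
        ]
        if len(self.history):
            lines.append(f"final val AUC    : {self.history['val_auc'].iloc[-1]:.4f}")
            lines.append(
                f"best val AUC     : {self.history['val_auc'].max():.4f}"
            )
        return "\n".join(lines)


# -- functional aliases over the modelling objects ---------------------------

def build_model(cfg: FixbbGCNConfig, seed: int = 0) -> FixbbGCN:
    return FixbbGCN(cfg, seed)


def train(model: FixbbGCN, train_ds, val_ds, tc: TrainConfig, callback=None) -> FitResults:
    return model.fit(train_ds, val_ds, tc, callback=callback)


def evaluate(model: FixbbGCN, ds) -> Tuple[float, float]:
    return model.evaluate(ds)


def predict(model: FixbbGCN, g: AttributedGraph) -> np.ndarray:
    return model.predict(g)
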