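"""Feedforward network for genomic prediction on Cholesky-constructed inputs.

The input matrix concatenates three blocks built from the record layout:
environment indicators ``ZE``, genotype indicators post-multiplied by the
transpose of the upper-triangular Cholesky factor of the genomic
relationship matrix (``ZG* = ZG Q'`` with ``G = Q'Q``), and the G x E block
``ZGE* = ZGE (I_e (x) Q')``.  Because ``ZG* ZG*' = ZG G ZG'``, the network
sees inputs whose linear kernel reproduces the genomic relationship, while
remaining free to learn non-additive structure.

The network itself is a dense ReLU feedforward regressor (3 hidden layers of
50 units by default) trained by Adam on mean squared error with inverted
dropout on the hidden layers; one output unit per trait.  Training is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class DLDesign:
    """Indicator blocks for records: environments, genotypes, and G x E.

    Environment and line levels are sorted lexically; the G x E column index
    is environment-major: ``env_index * n_lines + line_index``.
    """

    ZE: np.ndarray
    ZG: np.ndarray
    ZGE: np.ndarray
    env_levels: list[str]
    line_levels: list[str]
    record_lines: list[str]
    record_envs: list[str]


@dataclass
class DLInputs:
    X: np.ndarray
    Q: np.ndarray  # upper-triangular, G = Q'Q
    block_slices: dict


@dataclass
class MLPConfig:
    hidden_layers: int = 3
    units_per_layer: int = 50
    dropout_rate: float = 0.2
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None: full batch below 1024 records
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainedMLP:
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    y_mean: np.ndarray
    y_sd: np.ndarray
    loss_trace: np.ndarray
    config: MLPConfig
    n_inputs: int


def build_design_matrices(records: pd.DataFrame) -> DLDesign:
    """Build ZE / ZG / ZGE indicator blocks from line and environment labels.

    ``records`` needs one row per observation with ``line`` and
    ``environment`` columns (trait values are handled separately as targets).
    """
    for col in ("line", "environment"):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    lines = records["line"].astype(str).tolist()
    envs = records["environment"].astype(str).tolist()
    line_levels = sorted(set(lines))
    env_levels = sorted(set(envs))
    g, e, n = len(line_levels), len(env_levels), len(records)
    li = {l: i for i, l in enumerate(line_levels)}
    ei = {v: i for i, v in enumerate(env_levels)}
    ZE = np.zeros((n, e))
    ZG = np.zeros((n, g))
    ZGE = np.zeros((n, g * e))
    for r, (l, v) in enumerate(zip(lines, envs)):
        ZE[r, ei[v]] = 1.0
        ZG[r, li[l]] = 1.0
        ZGE[r, ei[v] * g + li[l]] = 1.0
    return DLDesign(
        ZE=ZE,
        ZG=ZG,
        ZGE=ZGE,
        env_levels=env_levels,
        line_levels=line_levels,
        record_lines=lines,
        record_envs=envs,
    )


def build_dl_inputs(design: DLDesign, grm) -> DLInputs:
    """Assemble X = [ZE, ZG Q', ZGE (I_e (x) Q')] from the relationship matrix.

    ``grm`` is a :class:`~maizegp.panel.KinshipMatrix` (or a raw array
    aligned to ``design.line_levels``); it is jittered once if needed before
    the Cholesky factorization.
    """
    G = grm.align(design.line_levels) if hasattr(grm, "align") else np.asarray(grm, dtype=float)
    g = len(design.line_levels)
    if G.shape != (g, g):
        raise ValueError("relationship matrix does not match line levels")
    G = (G + G.T) / 2.0
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        G = G + 1e-8 * np.mean(np.diag(G)) * np.eye(g)
        L = np.linalg.cholesky(G)  # raises again on genuine failure
    Q = L.T  # upper triangular, G = Q'Q
    ZGs = design.ZG @ Q.T
    e = len(design.env_levels)
    ZGEs = design.ZGE @ np.kron(np.eye(e), Q.T)
    X = np.hstack([design.ZE, ZGs, ZGEs])
    slices = {
        "ZE": slice(0, e),
        "ZG": slice(e, e + g),
        "ZGE": slice(e + g, e + g + g * e),
    }
    return DLInputs(X=X, Q=Q, block_slices=slices)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def train_mlp(X: np.ndarray, Y: np.ndarray, config: MLPConfig | None = None) -> TrainedMLP:
    """Train the dense ReLU network by Adam on standardized targets.

    Targets are z-scored per column on the training data and predictions are
    de-standardized at :func:`predict_mlp` time.  Dropout (inverted scaling)
    is active only during training.  A NaN loss aborts with the epoch index.
    """
    config = config or MLPConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    n, p = X.shape
    t = Y.shape[1]
    y_mean = Y.mean(axis=0)
    y_sd = Y.std(axis=0)
    y_sd = np.where(y_sd < 1e-12, 1.0, y_sd)
    Ys = (Y - y_mean) / y_sd

    rng = np.random.default_rng(config.seed)
    sizes = [p] + [config.units_per_layer] * config.hidden_layers + [t]
    W = [
        rng.standard_normal((sizes[i], sizes[i + 1])) * np.sqrt(2.0 / sizes[i])
        for i in range(len(sizes) - 1)
    ]
    b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    mW = [np.zeros_like(w) for w in W]
    vW = [np.zeros_like(w) for w in W]
    mb = [np.zeros_like(x) for x in b]
    vb = [np.zeros_like(x) for x in b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    batch = config.batch_size or (n if n < 1024 else 256)

    losses = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            a = X[idx]
            acts, masks = [a], []
            for layer in range(len(W) - 1):
                h = _relu(acts[-1] @ W[layer] + b[layer])
                if config.dropout_rate > 0:
                    mask = (rng.random(h.shape) >= config.dropout_rate) / (
                        1.0 - config.dropout_rate
                    )
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
                acts.append(h)
            out = acts[-1] @ W[-1] + b[-1]
            err = out - Ys[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"NaN loss at epoch {epoch}")
            epoch_loss += loss
            n_batches += 1
            # backward pass
            grad = 2.0 * err / err.size
            gW = [None] * len(W)
            gb = [None] * len(W)
            delta = grad
            for layer in range(len(W) - 1, -1, -1):
                gW[layer] = acts[layer].T @ delta
                gb[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = delta @ W[layer].T
                    if masks[layer - 1] is not None:
                        delta = delta * masks[layer - 1]
                    delta = delta * (acts[layer] > 0)
            step += 1
            c1 = 1.0 - beta1**step
            c2 = 1.0 - beta2**step
            for layer in range(len(W)):
                mW[layer] = beta1 * mW[layer] + (1 - beta1) * gW[layer]
                vW[layer] = beta2 * vW[layer] + (1 - beta2) * gW[layer] ** 2
                W[layer] -= lr * (mW[layer] / c1) / (np.sqrt(vW[layer] / c2) + eps)
                mb[layer] = beta1 * mb[layer] + (1 - beta1) * gb[layer]
                vb[layer] = beta2 * vb[layer] + (1 - beta2) * gb[layer] ** 2
                b[layer] -= lr * (mb[layer] / c1) / (np.sqrt(vb[layer] / c2) + eps)
        losses.append(epoch_loss / n_batches)

    return TrainedMLP(
        weights=W,
        biases=b,
        y_mean=y_mean,
        y_sd=y_sd,
        loss_trace=np.asarray(losses),
        config=config,
        n_inputs=p,
    )


def predict_mlp(model: TrainedMLP, X_new: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off), de-standardized outputs."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_inputs:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_inputs}"
        )
    a = X_new
    for layer in range(len(model.weights) - 1):
        a = _relu(a @ model.weights[layer] + model.biases[layer])
    out = a @ model.weights[-1] + model.biases[-1]
    return out * model.y_sd + model.y_mean
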