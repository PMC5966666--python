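"""Restricted Boltzmann machine trained by one-step contrastive divergence.

The RBM is a bipartite energy-based model over a visible vector ``v``
(here the unit-interval clinical features, treated as activation
probabilities) and a binary hidden vector ``h``:

    E(v, h) = -a'v - b'h - v'Wh

with visible bias ``a``, hidden bias ``b`` and weights ``W`` (one entry
per visible-hidden pair).  Conditional activations factorize over units:

    P(h_j = 1 | v) = sigmoid(sum_i v_i W_ij + b_j)
    P(v_i = 1 | h) = sigmoid(sum_j W_ij h_j + a_i)

CD-1 training replaces the intractable model expectation in the
log-likelihood gradient with statistics after a single Gibbs
reconstruction: hidden probabilities are computed from the data, a
binary hidden sample drives one reconstruction of the visible layer,
and the hidden probabilities of the reconstruction close the negative
phase.  The reconstruction error -- the mean absolute difference
between the data and its one-step mean-field reconstruction -- doubles
as the training diagnostic and, in the stacked model, as the
depth-growth statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import expit


@dataclass
class RBMParams:
    """One RBM layer's parameters: weights plus visible/hidden biases."""

    w: np.ndarray  # (n_visible, n_hidden)
    a: np.ndarray  # visible bias, (n_visible,)
    b: np.ndarray  # hidden bias, (n_hidden,)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.w.ndim != 2:
            raise ValueError("w must be a matrix")
        if self.a.shape != (self.w.shape[0],) or self.b.shape != (self.w.shape[1],):
            raise ValueError(
                f"inconsistent shapes: w{self.w.shape}, a{self.a.shape}, "
                f"b{self.b.shape}"
            )
        if not (np.isfinite(self.w).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.w.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """CD-1 training hyperparameters.

    Defaults follow the reference protocol for small clinical tables:
    learning rate 1, at most 10 epochs per RBM, mini-batches of 100.
    A batch size larger than the data simply yields one full batch;
    remainder batches are kept.
    """

    learning_rate: float = 1.0
    max_epochs: int = 10
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, max_epochs, batch_size must be positive")


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    return expit(x)


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Energy of a joint state: E(v,h) = -a'v - b'h - v'Wh."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValueError("state dimensions do not match the RBM")
    return float(-params.a @ v - params.b @ h - v @ params.w @ h)


def hidden_probs(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) for each hidden unit; v may be a vector or a matrix."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValueError(
            f"visible dimension {v.shape[-1]} != {params.n_visible}"
        )
    return sigmoid(v @ params.w + params.b)


def visible_probs(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) for each visible unit; h may be a vector or a matrix."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError(
            f"hidden dimension {h.shape[-1]} != {params.n_hidden}"
        )
    return sigmoid(h @ params.w.T + params.a)


def init_params(
    n_visible: int, n_hidden: int, rng: np.random.Generator, scale: float = 0.1
) -> RBMParams:
    """Small zero-mean Gaussian weights, zero biases.

    The 0.1 scale matters under the short fixed epoch budget: much
    smaller initializations leave CD-1 stuck near the symmetric saddle
    (hidden units at ~0.5) for most of the budget, so the layer learns
    almost nothing and stacked activations degenerate toward constants.
    """
    w = rng.normal(0.0, scale, size=(n_visible, n_hidden))
    return RBMParams(w=w, a=np.zeros(n_visible), b=np.zeros(n_hidden))


def reconstruction_error(params: RBMParams, data: np.ndarray) -> float:
    """Mean absolute one-step mean-field reconstruction error.

    Each row x is pushed to hidden probabilities and back to visible
    probabilities p; the error is sum |p_ij - x_ij| / (n * m), a mean
    absolute deviation in [0, 1] for unit-interval data.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("reconstruction_error needs non-empty data")
    p = visible_probs(hidden_probs(data, params), params)
    return float(np.mean(np.abs(p - data)))


def cd1_step(
    params: RBMParams,
    batch: np.ndarray,
    learning_rate: float,
    rng: np.random.Generator,
) -> tuple[RBMParams, float]:
    """One CD-1 parameter update on a mini-batch.

    Positive phase uses hidden probabilities h1 = P(h|v1); the Gibbs step
    samples binary hidden states from h1 to reconstruct v1' and re-maps
    to h1'.  Updates (averaged over the batch, scaled by the learning
    rate):

        dW = v1'h1 - v1''h1',  da = mean(v1 - v1'),  db = mean(h1 - h1')

    Returns the updated parameters and the batch mean absolute
    reconstruction error |v1' - v1|.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.min() < 0.0 or batch.max() > 1.0:
        raise ValueError("visible values must lie in [0, 1]")
    n = batch.shape[0]
    h1 = hidden_probs(batch, params)
    h_sample = (rng.random(h1.shape) < h1).astype(float)
    v_recon = visible_probs(h_sample, params)
    h_recon = hidden_probs(v_recon, params)

    dw = (batch.T @ h1 - v_recon.T @ h_recon) / n
    da = np.mean(batch - v_recon, axis=0)
    db = np.mean(h1 - h_recon, axis=0)
    updated = RBMParams(
        w=params.w + learning_rate * dw,
        a=params.a + learning_rate * da,
        b=params.b + learning_rate * db,
    )
    return updated, float(np.mean(np.abs(v_recon - batch)))


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    config: TrainConfig,
    epoch_callback: Callable[[int, RBMParams, float], None] | None = None,
) -> tuple[RBMParams, float]:
    """Train one RBM by shuffled mini-batch CD-1.

    Runs exactly ``config.max_epochs`` epochs and returns the epoch
    snapshot with the lowest full-data reconstruction error, together
    with that error ("train until the reconstruction error is least"
    within the fixed epoch budget).  Fully deterministic given
    ``config.seed``.

    ``epoch_callback(epoch, params, r_error)`` is invoked after every
    epoch, e.g. to record training diagnostics.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("train_rbm needs non-empty data")
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError("visible values must lie in [0, 1]")
    n = data.shape[0]
    rng = np.random.default_rng(config.seed)
    params = init_params(data.shape[1], n_hidden, rng)

    best_params = params.copy()
    best_error = reconstruction_error(params, data)
    batch_size = min(config.batch_size, n)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = data[order[start:start + batch_size]]
            params, _ = cd1_step(params, batch, config.learning_rate, rng)
        err = reconstruction_error(params, data)
        if epoch_callback is not None:
            epoch_callback(epoch, params, err)
        if err < best_error:
            best_error = err
            best_params = params.copy()
    return best_params, best_error


def params_to_dict(params: RBMParams) -> dict:
    return {
        "n_visible": params.n_visible,
        "n_hidden": params.n_hidden,
        "w": params.w.tolist(),
        "a": params.a.tolist(),
        "b": params.b.tolist(),
    }


def params_from_dict(doc: dict) -> RBMParams:
    p = RBMParams(
        w=np.array(doc["w"], dtype=float),
        a=np.array(doc["a"], dtype=float),
        b=np.array(doc["b"], dtype=float),
    )
    if p.n_visible != doc["n_visible"] or p.n_hidden != doc["n_hidden"]:
        raise ValueError("dimension header does not match stored arrays")
    return p


def save_params(params: RBMParams, path: str) -> None:
    """Write one layer to a flat JSON file (dimension header + arrays)."""
    with open(path, "w") as fh:
        json.dump(params_to_dict(params), fh)


def load_params(path: str) -> RBMParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))
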