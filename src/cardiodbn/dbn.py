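"""Deep belief network with reconstruction-error depth selection.

The network is a greedy stack of RBMs topped by a single logistic
output unit.  Construction has two phases:

1.  *Unsupervised growth.*  The first RBM is trained on the encoded
    features; each further candidate RBM is trained on the mean-field
    hidden activations of the layer below.  Hidden-layer widths are
    searched over the square-root heuristic

        N = ceil(sqrt(m * n)) + k,   k in [1, 5]

    (m = layer input dimension, n = output dimension 1), keeping the
    candidate with the smallest reconstruction error.  Growth stops
    autonomously when the improvement in reconstruction error between
    consecutive layers falls below a threshold epsilon (default 0.03):
    the candidate layer that fails the test is discarded and the depth
    is frozen.  A hard cap bounds the depth regardless.

2.  *Supervised fine-tuning.*  The pretrained weights initialize a
    feed-forward sigmoid network; full backpropagation of the
    cross-entropy loss through the logistic head and every layer
    adjusts all weights jointly.

Depth is counted in feature layers including the visible input, so a
stack of 3 RBMs over 13 inputs with widths 7-6-4 is a depth-4 network
written "13-7-6-4".
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .rbm import (
    RBMParams,
    TrainConfig,
    hidden_probs,
    params_from_dict,
    params_to_dict,
    reconstruction_error,
    sigmoid,
    train_rbm,
)

STOP_EPSILON = "epsilon-rule"
STOP_CAP = "max-depth-cap"


@dataclass
class GrowthConfig:
    """Configuration of depth growth, width search and fine-tuning.

    epsilon:
        Stopping threshold on the between-layer improvement in
        reconstruction error; values outside the validated [0.01, 0.05]
        band trigger a warning, not an error.
    max_depth_cap:
        Hard upper bound on depth (feature layers including the visible
        input), so at most ``max_depth_cap - 1`` RBMs.
    unit_offset_range:
        Inclusive integer interval of the offset k in the width
        heuristic ceil(sqrt(m*n)) + k.
    keep_stopping_layer:
        If True, the candidate layer whose improvement fell below
        epsilon is retained instead of discarded (the alternative
        reading of the stopping rule); default False.
    finetune_val_fraction:
        Fraction of the training rows held out during fine-tuning for
        early stopping on validation cross-entropy; 0 disables early
        stopping and trains on everything for the full epoch budget.
    early_stop_interval:
        Epoch interval at which the validation loss is evaluated and
        the best snapshot updated.
    """

    epsilon: float = 0.03
    max_depth_cap: int = 8
    unit_offset_range: tuple[int, int] = (1, 5)
    rbm_config: TrainConfig = field(default_factory=TrainConfig)
    head_epochs: int = 1000
    head_learning_rate: float = 2.0
    finetune_val_fraction: float = 0.15
    early_stop_interval: int = 20
    keep_stopping_layer: bool = False
    n_output: int = 1

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.01 <= self.epsilon <= 0.05:
            warnings.warn(
                f"epsilon={self.epsilon} is outside the validated band "
                "[0.01, 0.05]", stacklevel=2,
            )
        if self.max_depth_cap < 2:
            raise ValueError("max_depth_cap must allow at least one RBM layer")
        lo, hi = self.unit_offset_range
        if lo > hi:
            raise ValueError("unit_offset_range must be a nonempty interval")


@dataclass
class DepthTrace:
    """Record of the growth process: per-kept-layer reconstruction
    errors and widths, the width-search errors per candidate, the
    rejected layer's error (if growth stopped on the epsilon rule), and
    the stop reason."""

    r_errors: list[float]
    hidden_units: list[int]
    epsilon: float
    stop_reason: str
    candidate_errors: list[dict[int, float]] = field(default_factory=list)
    rejected_error: float | None = None

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.r_errors):
            raise ValueError("reconstruction errors must be nonnegative")


@dataclass
class DBNModel:
    """Ordered RBM stack plus a single logistic output unit."""

    layers: list[RBMParams]
    head_w: np.ndarray
    head_b: float
    trace: DepthTrace | None = None

    def __post_init__(self) -> None:
        for lower, upper in zip(self.layers, self.layers[1:]):
            if lower.n_hidden != upper.n_visible:
                raise ValueError("layer dimensions do not chain")
        self.head_w = np.asarray(self.head_w, dtype=float)
        if self.layers and self.head_w.shape != (self.layers[-1].n_hidden,):
            raise ValueError("head width does not match the top layer")

    @property
    def depth(self) -> int:
        """Feature layers including the visible input: len(layers) + 1."""
        return len(self.layers) + 1

    @property
    def architecture(self) -> str:
        """Width string such as '13-7-6-4'."""
        widths = [self.layers[0].n_visible] + [p.n_hidden for p in self.layers]
        return "-".join(str(w) for w in widths)


def candidate_hidden_units(
    m: int, n: int = 1, offset_range: tuple[int, int] = (1, 5)
) -> list[int]:
    """Candidate hidden-unit counts ceil(sqrt(m*n)) + k, k in the range.

    With 13 inputs and a single output this yields the 5..9 search
    window used for the first hidden layer.
    """
    if m < 1 or n < 1:
        raise ValueError("dimensions must be >= 1")
    base = math.ceil(math.sqrt(m * n))
    lo, hi = offset_range
    return [base + k for k in range(lo, hi + 1)]


def select_hidden_units(
    layer_input: np.ndarray,
    candidates: list[int],
    rbm_config: TrainConfig,
) -> tuple[int, dict[int, float], RBMParams]:
    """Train one RBM per candidate width and keep the best.

    Every candidate is trained with the same seed so the comparison
    differs only in width.  The winner is the smallest reconstruction
    error, ties broken toward the smaller width.  Returns the chosen
    width, the per-candidate error table, and the winning trained RBM.
    """
    if not candidates:
        raise ValueError("need at least one candidate width")
    errors: dict[int, float] = {}
    trained: dict[int, RBMParams] = {}
    for n_hidden in candidates:
        params, err = train_rbm(layer_input, n_hidden, rbm_config)
        errors[n_hidden] = err
        trained[n_hidden] = params
    best = min(sorted(errors), key=lambda c: errors[c])
    return best, errors, trained[best]


def layers_to_keep(
    r_errors: list[float], epsilon: float, keep_stopping_layer: bool = False
) -> int:
    """Apply the depth-stopping rule to a reconstruction-error trace.

    ``r_errors[t]`` is the reconstruction error of the (t+1)-th RBM on
    its own input.  The first layer is always kept; layer t+1 is kept
    while r_errors[t-1] - r_errors[t] > epsilon.  The first layer that
    fails the test is discarded (or, with ``keep_stopping_layer``,
    retained) and growth stops.  Returns the number of RBM layers kept.
    """
    if not r_errors:
        return 0
    kept = 1
    for prev, cur in zip(r_errors, r_errors[1:]):
        if prev - cur > epsilon:
            kept += 1
        else:
            if keep_stopping_layer:
                kept += 1
            break
    return kept


def _layer_seed(base_seed: int, layer_index: int) -> int:
    """Stable per-layer RBM seed, independent of epsilon and depth cap."""
    return int(
        np.random.SeedSequence([base_seed, layer_index]).generate_state(1)[0]
        % (2 ** 31)
    )


def grow_pretrain(
    X: np.ndarray,
    config: GrowthConfig,
    forced_layers: int | None = None,
) -> tuple[DBNModel, DepthTrace]:
    """Greedy layer-wise pretraining with autonomous depth selection.

    The first RBM is trained on ``X``; each subsequent candidate on the
    mean-field hidden activations of the previous layer (probabilities,
    not samples, so stacking is deterministic given the seed).  Width is
    searched per layer with :func:`candidate_hidden_units` against an
    output dimension of ``config.n_output``.  Growth stops by the
    epsilon rule or at the depth cap; ``forced_layers`` disables the
    epsilon rule and grows exactly that many RBMs (for depth sweeps).

    Returns the unsupervised model (logistic head initialized to zero)
    and the growth trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("grow_pretrain needs non-empty data")

    if forced_layers is not None:
        if forced_layers < 1:
            raise ValueError("forced_layers must be >= 1")
        max_layers = forced_layers
    else:
        max_layers = config.max_depth_cap - 1

    layers: list[RBMParams] = []
    r_errors: list[float] = []
    widths: list[int] = []
    cand_tables: list[dict[int, float]] = []
    rejected: float | None = None
    stop_reason = STOP_CAP

    current = X
    for t in range(max_layers):
        cands = candidate_hidden_units(
            current.shape[1], config.n_output, config.unit_offset_range
        )
        layer_cfg = replace(
            config.rbm_config, seed=_layer_seed(config.rbm_config.seed, t)
        )
        best_n, table, best_params = select_hidden_units(current, cands, layer_cfg)
        err = table[best_n]
        improved = t == 0 or (r_errors[-1] - err > config.epsilon)
        if forced_layers is not None or improved or config.keep_stopping_layer:
            layers.append(best_params)
            r_errors.append(err)
            widths.append(best_n)
            cand_tables.append(table)
            current = hidden_probs(current, best_params)
            if forced_layers is None and not improved:
                stop_reason = STOP_EPSILON  # kept under keep_stopping_layer
                break
        else:
            stop_reason = STOP_EPSILON
            rejected = err
            break

    trace = DepthTrace(
        r_errors=r_errors,
        hidden_units=widths,
        epsilon=config.epsilon,
        stop_reason=stop_reason if forced_layers is None else STOP_CAP,
        candidate_errors=cand_tables,
        rejected_error=rejected,
    )
    model = DBNModel(
        layers=layers,
        head_w=np.zeros(layers[-1].n_hidden),
        head_b=0.0,
        trace=trace,
    )
    return model, trace


def _forward(model: DBNModel, X: np.ndarray) -> list[np.ndarray]:
    """Mean-field activations per layer; activations[0] is the input."""
    activations = [X]
    for p in model.layers:
        activations.append(sigmoid(activations[-1] @ p.w + p.b))
    return activations


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Disease probability per row: deterministic mean-field forward pass
    through all layers and the logistic head."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layers[0].n_visible:
        raise ValueError(
            f"feature dimension {X.shape[1]} != {model.layers[0].n_visible}"
        )
    top = _forward(model, X)[-1]
    return sigmoid(top @ model.head_w + model.head_b)


def predict_label(
    model: DBNModel, X: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Binary prediction: 1 iff the predicted probability >= threshold."""
    return (predict_proba(model, X) >= threshold).astype(int)


def _cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def finetune(
    model: DBNModel,
    X: np.ndarray,
    y: np.ndarray,
    config: GrowthConfig,
    loss_callback=None,
) -> DBNModel:
    """Supervised backpropagation fine-tuning of the whole stack.

    The pretrained weights are the initialization; full-batch gradient
    descent on the mean cross-entropy updates the logistic head and
    every layer's weights and hidden biases for up to
    ``config.head_epochs`` epochs at rate ``config.head_learning_rate``.
    When ``config.finetune_val_fraction`` > 0, that fraction of the rows
    is held out and the snapshot with the lowest validation
    cross-entropy (checked every ``config.early_stop_interval`` epochs)
    is returned, which guards against overfitting the small training
    tables; the holdout is seeded from the RBM seed, so fine-tuning is
    deterministic.  Topology is never changed.  Visible biases play no
    role in the feed-forward pass and are left untouched.

    ``loss_callback(epoch, train_ce)`` receives the pre-update training
    cross-entropy each epoch.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError(f"{X.shape[0]} rows but {y.size} labels")
    n = X.shape[0]

    n_val = int(round(config.finetune_val_fraction * n))
    if n_val > 0 and n - n_val >= 2:
        rng = np.random.default_rng(config.rbm_config.seed)
        order = rng.permutation(n)
        X_val, y_val = X[order[:n_val]], y[order[:n_val]]
        X_fit, y_fit = X[order[n_val:]], y[order[n_val:]]
    else:
        X_val = y_val = None
        X_fit, y_fit = X, y

    layers = [p.copy() for p in model.layers]
    head_w = model.head_w.copy()
    head_b = float(model.head_b)
    lr = config.head_learning_rate
    n_fit = X_fit.shape[0]

    best: tuple[list[RBMParams], np.ndarray, float] | None = None
    best_val = np.inf
    for epoch in range(config.head_epochs):
        tuned = DBNModel(layers=layers, head_w=head_w, head_b=head_b)
        acts = _forward(tuned, X_fit)
        top = acts[-1]
        p = sigmoid(top @ head_w + head_b)
        if loss_callback is not None:
            loss_callback(epoch, _cross_entropy(p, y_fit))

        # d(mean CE)/d(logit) = (p - y)/n; backpropagate through the stack.
        delta = (p - y_fit) / n_fit
        grad_head_w = acts[-1].T @ delta
        grad_head_b = float(delta.sum())
        delta_h = np.outer(delta, head_w) * top * (1 - top)
        for t in range(len(layers) - 1, -1, -1):
            grad_w = acts[t].T @ delta_h
            grad_b = delta_h.sum(axis=0)
            if t > 0:
                a = acts[t]
                delta_h = (delta_h @ layers[t].w.T) * a * (1 - a)
            layers[t] = RBMParams(
                w=layers[t].w - lr * grad_w,
                a=layers[t].a,
                b=layers[t].b - lr * grad_b,
            )
        head_w = head_w - lr * grad_head_w
        head_b = head_b - lr * grad_head_b

        if X_val is not None and (epoch + 1) % config.early_stop_interval == 0:
            candidate = DBNModel(layers=layers, head_w=head_w, head_b=head_b)
            val_ce = _cross_entropy(predict_proba(candidate, X_val), y_val)
            if val_ce < best_val:
                best_val = val_ce
                best = ([l.copy() for l in layers], head_w.copy(), head_b)

    if best is not None:
        layers, head_w, head_b = best
    return DBNModel(layers=layers, head_w=head_w, head_b=head_b,
                    trace=model.trace)


def model_to_dict(model: DBNModel) -> dict:
    doc: dict = {
        "architecture": model.architecture,
        "depth": model.depth,
        "layers": [params_to_dict(p) for p in model.layers],
        "head_w": model.head_w.tolist(),
        "head_b": model.head_b,
    }
    if model.trace is not None:
        doc["trace"] = {
            "r_errors": model.trace.r_errors,
            "hidden_units": model.trace.hidden_units,
            "epsilon": model.trace.epsilon,
            "stop_reason": model.trace.stop_reason,
            "candidate_errors": [
                {str(k): v for k, v in tbl.items()}
                for tbl in model.trace.candidate_errors
            ],
            "rejected_error": model.trace.rejected_error,
        }
    return doc


def model_from_dict(doc: dict) -> DBNModel:
    trace = None
    if "trace" in doc:
        t = doc["trace"]
        trace = DepthTrace(
            r_errors=list(t["r_errors"]),
            hidden_units=list(t["hidden_units"]),
            epsilon=t["epsilon"],
            stop_reason=t["stop_reason"],
            candidate_errors=[
                {int(k): v for k, v in tbl.items()}
                for tbl in t.get("candidate_errors", [])
            ],
            rejected_error=t.get("rejected_error"),
        )
    return DBNModel(
        layers=[params_from_dict(d) for d in doc["layers"]],
        head_w=np.array(doc["head_w"], dtype=float),
        head_b=float(doc["head_b"]),
        trace=trace,
    )


def save_model(model: DBNModel, path: str) -> None:
    """Serialize the full stack, head and growth trace to one JSON file."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str) -> DBNModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
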