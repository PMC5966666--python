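"""Exact enumeration oracles for tiny RBMs.

For an RBM with at most ~20 total units the Boltzmann distribution can
be tabulated exactly: the partition function is a sum over all binary
(v, h) pairs, and every marginal, conditional and log-likelihood
gradient follows from the normalized table.  These routines exist to
cross-check the analytic conditionals and the CD-1 update direction in
tests; they are exponential in the unit count and guarded accordingly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .rbm import RBMParams, hidden_probs

#: Enumeration is refused above this many total units (2^20 states).
MAX_ENUM_UNITS = 20


def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, one per row, in counting order."""
    if n < 1:
        raise ValueError("need at least one unit")
    bits = np.arange(2 ** n)[:, None] >> np.arange(n - 1, -1, -1) & 1
    return bits.astype(float)


def _check_size(params: RBMParams) -> None:
    if params.n_visible + params.n_hidden > MAX_ENUM_UNITS:
        raise ValueError(
            f"enumeration limited to {MAX_ENUM_UNITS} total units, "
            f"got {params.n_visible + params.n_hidden}"
        )


def _neg_energy_table(params: RBMParams) -> np.ndarray:
    """-E(v, h) for every state pair; shape (2^n_visible, 2^n_hidden)."""
    V = enumerate_states(params.n_visible)
    H = enumerate_states(params.n_hidden)
    return (V @ params.a)[:, None] + (H @ params.b)[None, :] + V @ params.w @ H.T


def exact_log_partition(params: RBMParams) -> float:
    """log Z = log sum_{v,h} exp(-E(v,h)), by full enumeration."""
    _check_size(params)
    return float(logsumexp(_neg_energy_table(params)))


def exact_joint(params: RBMParams) -> np.ndarray:
    """Normalized joint P(v, h) as a (2^n_visible, 2^n_hidden) table."""
    _check_size(params)
    table = _neg_energy_table(params)
    return np.exp(table - logsumexp(table))


def exact_hidden_conditional(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) obtained from the enumerated joint, not the
    analytic sigmoid form -- the independent route for conditional-
    independence checks."""
    _check_size(params)
    H = enumerate_states(params.n_hidden)
    neg_e = (params.a @ v) + H @ params.b + (v @ params.w) @ H.T
    p_h = np.exp(neg_e - logsumexp(neg_e))
    return p_h @ H


def exact_visible_conditional(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h) from the enumerated joint."""
    _check_size(params)
    V = enumerate_states(params.n_visible)
    neg_e = V @ params.a + (params.b @ h) + V @ (params.w @ h)
    p_v = np.exp(neg_e - logsumexp(neg_e))
    return p_v @ V


def exact_loglik(params: RBMParams, data: np.ndarray) -> float:
    """Mean log-likelihood of binary data rows under the enumerated model."""
    _check_size(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    H = enumerate_states(params.n_hidden)
    log_z = exact_log_partition(params)
    neg_e = (data @ params.a)[:, None] + (H @ params.b)[None, :] \
        + data @ params.w @ H.T
    return float(np.mean(logsumexp(neg_e, axis=1) - log_z))


def exact_loglik_gradient(
    params: RBMParams, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the mean log-likelihood w.r.t. (a, b, w).

    Data phase: visible statistics are the data themselves, hidden
    statistics the analytic conditional means given each data row.
    Model phase: expectations under the fully enumerated joint.
    Returns (grad_a, grad_b, grad_w).
    """
    _check_size(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]

    h_mean = hidden_probs(data, params)
    data_v = data.mean(axis=0)
    data_h = h_mean.mean(axis=0)
    data_vh = data.T @ h_mean / n

    V = enumerate_states(params.n_visible)
    H = enumerate_states(params.n_hidden)
    joint = exact_joint(params)
    model_v = joint.sum(axis=1) @ V
    model_h = joint.sum(axis=0) @ H
    model_vh = V.T @ joint @ H

    return data_v - model_v, data_h - model_h, data_vh - model_vh
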