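"""Outcome likelihoods: Bernoulli ties and multinomial allocations.

Both are written against *score* (linear predictor) arrays:

* Bernoulli: each directed cell (i, j) is an independent Bernoulli with
  success probability ``sigmoid(eta_ij)``.
* Multinomial: each focal's budget of B indistinguishable coins is dropped
  over the categories {self} U {alters} with probabilities
  ``softmax(eta_i)``; the log-pmf includes the multinomial coefficient, so
  probabilities over all possible allocations sum to one.

The softmax is shift-invariant per focal: adding any constant to all of a
focal's scores leaves the likelihood unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp


def log_sigmoid(eta: np.ndarray) -> np.ndarray:
    """Numerically stable log(sigmoid(eta))."""
    return -np.logaddexp(0.0, -np.asarray(eta, dtype=float))


def loglik_bernoulli(y: np.ndarray, eta: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sum of Bernoulli log-probabilities over (masked) cells.

    ``y`` and ``eta`` are broadcast-compatible arrays; ``mask`` selects the
    cells that are real dyads (self cells excluded).
    """
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    ll = y * log_sigmoid(eta) + (1.0 - y) * log_sigmoid(-eta)
    if mask is not None:
        ll = np.where(mask, ll, 0.0)
    return float(ll.sum())


def log_softmax(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    return eta - logsumexp(eta, axis=axis, keepdims=True)


def softmax(eta: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.exp(log_softmax(eta, axis=axis))


def loglik_multinomial(counts: np.ndarray, eta: np.ndarray) -> float:
    """Multinomial log-pmf of integer counts with softmax(eta) cell
    probabilities.

    1-D inputs are a single allocation record; 2-D inputs are stacked
    per-focal records (rows). Counts in each row must sum to that row's
    budget by construction; the budget is taken from the counts.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    if counts.shape != eta.shape:
        raise ValueError(f"counts shape {counts.shape} != eta shape {eta.shape}")
    budgets = counts.sum(axis=1)
    log_p = log_softmax(eta, axis=1)
    coef = gammaln(budgets + 1.0) - gammaln(counts + 1.0).sum(axis=1)
    return float((coef + (counts * log_p).sum(axis=1)).sum())
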