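"""Sampling-based Shapley attribution against a single background row.

For a model score function f and a background b (here the training-data
median), the Shapley value of feature j at sample x is the average, over
orderings of the features, of the score change when feature j flips from its
background value to its sample value given the features before it have
already flipped. Sampling orderings uniformly gives an unbiased estimate,
and — because each ordering's contributions telescope — the estimated
attributions sum exactly to ``f(x) - f(b)`` for every sample (the
local-accuracy property holds by construction, not just in expectation).
"""

from __future__ import annotations

import numpy as np

__all__ = ["shapley_values", "score_function"]


def score_function(model):
    """Best available scalar MCI-class score for a fitted classifier."""
    if hasattr(model, "predict_proba"):
        return lambda X: model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), float)
    return lambda X: np.asarray(model.predict(X), float)


def shapley_values(
    f,
    X: np.ndarray,
    background: np.ndarray,
    rng: np.random.Generator,
    n_permutations: int = 32,
) -> np.ndarray:
    """Estimate per-sample, per-feature Shapley attributions.

    Parameters
    ----------
    f
        Vectorized score function mapping an (n, d) array to n scores.
    X
        Samples to explain, shape (n, d).
    background
        Reference row, shape (d,).
    rng
        Randomness source for the permutations.
    n_permutations
        Orderings sampled; the estimator variance shrinks as 1/sqrt of this.

    Returns
    -------
    (n, d) attribution array whose rows sum to ``f(X) - f(background)``.
    """
    X = np.asarray(X, float)
    n, d = X.shape
    phi = np.zeros((n, d))
    base = np.tile(np.asarray(background, float), (n, 1))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        z = base.copy()
        prev = f(z)
        for j in order:
            z[:, j] = X[:, j]
            cur = f(z)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations
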