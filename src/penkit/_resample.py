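"""Class-imbalance resampling for the classification stage.

Implements the usual menu of under- and oversamplers on top of
``sklearn.neighbors``: random undersampling, NearMiss-1, edited nearest
neighbours, SMOTE, Borderline-SMOTE, SVM-SMOTE and ADASYN. Every sampler is
a pure function ``(X, y, rng) -> (X_res, y_res)`` operating on dense float
arrays with binary labels; the minority class is whichever label is rarer.
Degenerate inputs (already balanced, or too few minority samples to build a
neighbourhood) fall back to returning the data unchanged or to plain SMOTE,
whichever is closer to the sampler's intent.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

__all__ = ["SAMPLERS", "resample"]


def _split(X: np.ndarray, y: np.ndarray):
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("resampling expects binary labels")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = classes[1], classes[0]
    return minority, majority


def _none(X, y, rng):
    return X, y


def _random_under(X, y, rng):
    mino, majo = _split(X, y)
    idx_min = np.flatnonzero(y == mino)
    idx_maj = np.flatnonzero(y == majo)
    keep = rng.choice(idx_maj, size=len(idx_min), replace=False)
    idx = np.sort(np.r_[idx_min, keep])
    return X[idx], y[idx]


def _near_miss(X, y, rng):
    """NearMiss-1: keep majority samples closest (on average) to their
    k nearest minority neighbours."""
    mino, majo = _split(X, y)
    Xmin = X[y == mino]
    idx_maj = np.flatnonzero(y == majo)
    k = min(3, len(Xmin))
    nn = NearestNeighbors(n_neighbors=k).fit(Xmin)
    d, _ = nn.kneighbors(X[idx_maj])
    order = np.argsort(d.mean(axis=1), kind="stable")
    keep = idx_maj[order[: np.count_nonzero(y == mino)]]
    idx = np.sort(np.r_[np.flatnonzero(y == mino), keep])
    return X[idx], y[idx]


def _edited_nn(X, y, rng):
    """Edited nearest neighbours: drop majority samples whose 3-NN vote
    disagrees with their label."""
    mino, majo = _split(X, y)
    k = min(3, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    votes = y[idx[:, 1:]]  # exclude self
    keep_mask = np.ones(len(X), dtype=bool)
    maj_rows = np.flatnonzero(y == majo)
    agree = (votes[maj_rows] == majo).mean(axis=1) >= 0.5
    keep_mask[maj_rows[~agree]] = False
    if keep_mask.sum() < 2 or len(np.unique(y[keep_mask])) < 2:
        return X, y
    return X[keep_mask], y[keep_mask]


def _interpolate(Xmin, seeds, n_needed, rng, k=5):
    """SMOTE-style interpolation between seed rows and minority neighbours."""
    k = min(k, len(Xmin) - 1)
    if k < 1 or n_needed <= 0 or len(seeds) == 0:
        return np.empty((0, Xmin.shape[1]))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, nbrs = nn.kneighbors(seeds)
    new = np.empty((n_needed, Xmin.shape[1]))
    seed_idx = rng.integers(0, len(seeds), size=n_needed)
    for i, si in enumerate(seed_idx):
        j = nbrs[si, rng.integers(1, k + 1)]
        u = rng.random()
        new[i] = seeds[si] + u * (Xmin[j] - seeds[si])
    return new


def _smote(X, y, rng, seeds=None):
    mino, majo = _split(X, y)
    Xmin = X[y == mino]
    n_needed = np.count_nonzero(y == majo) - len(Xmin)
    if n_needed <= 0 or len(Xmin) < 2:
        return X, y
    new = _interpolate(Xmin, Xmin if seeds is None else seeds, n_needed, rng)
    if len(new) == 0:
        return X, y
    return np.vstack([X, new]), np.r_[y, np.full(len(new), mino, dtype=y.dtype)]


def _borderline_smote(X, y, rng):
    """Oversample only 'danger' minority samples: more than half (but not
    all) of their m nearest neighbours belong to the majority class."""
    mino, majo = _split(X, y)
    Xmin = X[y == mino]
    if len(Xmin) < 2:
        return X, y
    m = min(5, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=m + 1).fit(X)
    _, idx = nn.kneighbors(Xmin)
    maj_frac = (y[idx[:, 1:]] == majo).mean(axis=1)
    danger = (maj_frac > 0.5) & (maj_frac < 1.0)
    seeds = Xmin[danger]
    if len(seeds) == 0:
        return _smote(X, y, rng)
    return _smote(X, y, rng, seeds=seeds)


def _svm_smote(X, y, rng):
    """Oversample from the minority support vectors of an RBF SVC."""
    mino, majo = _split(X, y)
    Xmin = X[y == mino]
    if len(Xmin) < 2:
        return X, y
    svc = SVC(kernel="rbf", C=1.0, gamma="scale").fit(X, y)
    sv = svc.support_[y[svc.support_] == mino]
    seeds = X[sv]
    if len(seeds) == 0:
        return _smote(X, y, rng)
    return _smote(X, y, rng, seeds=seeds)


def _adasyn(X, y, rng):
    """Density-adaptive SMOTE: synthesis effort proportional to the local
    majority fraction around each minority sample."""
    mino, majo = _split(X, y)
    Xmin = X[y == mino]
    n_needed = np.count_nonzero(y == majo) - len(Xmin)
    if n_needed <= 0 or len(Xmin) < 2:
        return X, y
    k = min(5, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(Xmin)
    r = (y[idx[:, 1:]] == majo).mean(axis=1)
    if r.sum() == 0:
        return _smote(X, y, rng)
    weights = r / r.sum()
    counts = rng.multinomial(n_needed, weights)
    kk = min(5, len(Xmin) - 1)
    nn_min = NearestNeighbors(n_neighbors=kk + 1).fit(Xmin)
    _, nbrs = nn_min.kneighbors(Xmin)
    rows = []
    for i, c in enumerate(counts):
        for _ in range(c):
            j = nbrs[i, rng.integers(1, kk + 1)]
            u = rng.random()
            rows.append(Xmin[i] + u * (Xmin[j] - Xmin[i]))
    if not rows:
        return X, y
    new = np.vstack(rows)
    return np.vstack([X, new]), np.r_[y, np.full(len(new), mino, dtype=y.dtype)]


SAMPLERS = {
    "none": _none,
    "random_under": _random_under,
    "near_miss": _near_miss,
    "edited_nn": _edited_nn,
    "smote": _smote,
    "borderline_smote": _borderline_smote,
    "svm_smote": _svm_smote,
    "adasyn": _adasyn,
}


def resample(name: str, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Apply the named sampler; unknown names raise KeyError."""
    return SAMPLERS[name](np.asarray(X, float), np.asarray(y), rng)
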