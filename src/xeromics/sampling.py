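"""Class-balancing and data-cleaning samplers for imbalanced cohorts.

Implements the ten sampling options of the multivariate workflow: random
oversampling (ROS), SMOTE, ADASYN, one-sided selection (OSS), Tomek-link
removal (TL), Wilson's edited nearest neighbours (ENN), the neighbourhood
cleaning rule (NCL), the SMOTE+ENN and SMOTE+TL combinations, and the
identity ("none").  All samplers operate on a numeric feature matrix and a
binary label vector and return a resampled (X, y) pair; all randomness is
drawn from a caller-supplied generator.

Definitions follow the original literature: Tomek links are mutual
cross-class nearest-neighbour pairs; ENN removes majority points
misclassified by their 3 nearest neighbours; OSS applies Tomek-link removal
after 1-NN condensing; NCL extends ENN by also cleaning the majority
neighbourhoods of misclassified minority points.  Oversamplers synthesize
minority points on segments towards k = 5 minority neighbours (ADASYN
allocates them proportionally to the local majority density).  When the
minority class is smaller than the neighbour count, k is reduced with a
warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SAMPLERS", "apply_sampler"]

#: The sampler vocabulary of the multivariate workflow.
SAMPLERS: tuple[str, ...] = (
    "ROS",
    "SMOTE",
    "ADASYN",
    "OSS",
    "TL",
    "ENN",
    "NCL",
    "SMOTE+ENN",
    "SMOTE+TL",
    "none",
)


def _validate(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or y.ndim != 1 or len(X) != len(y):
        raise ValueError("X must be (n, d) and y (n,) with matching n")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("samplers require exactly two classes present")
    # on a tie the positive class is treated as the minority
    minority = classes[np.lexsort((classes, counts))[0]] if counts[0] != counts[1] else classes.max()
    majority = classes[classes != minority][0]
    return X, y, int(minority), int(majority)


def _safe_k(k: int, available: int, what: str) -> int:
    if available < 1:
        raise ValueError(f"{what}: no neighbours available")
    if k > available:
        warnings.warn(f"{what}: reducing k from {k} to {available} (small minority class)")
        return available
    return k


# ---------------------------------------------------------------------------
# oversamplers


def _ros(X, y, minority, majority, rng):
    n_needed = (y == majority).sum() - (y == minority).sum()
    if n_needed <= 0:
        return X, y
    idx = np.flatnonzero(y == minority)
    picks = rng.choice(idx, size=n_needed, replace=True)
    return np.vstack([X, X[picks]]), np.concatenate([y, y[picks]])


def _smote_points(X_min, n_new, k, rng):
    """Synthesize n_new points on segments from minority points to their
    k nearest minority neighbours."""
    if len(X_min) < 2:
        warnings.warn("SMOTE: minority class has a single point; duplicating it")
        return np.repeat(X_min, n_new, axis=0)
    k = _safe_k(k, len(X_min) - 1, "SMOTE")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, len(X_min), size=n_new)
    partner = neigh[base, rng.integers(0, k, size=n_new)]
    gap = rng.uniform(0, 1, size=(n_new, 1))
    return X_min[base] + gap * (X_min[partner] - X_min[base])


def _smote(X, y, minority, majority, rng, k: int = 5):
    n_new = (y == majority).sum() - (y == minority).sum()
    if n_new <= 0:
        return X, y
    X_min = X[y == minority]
    new = _smote_points(X_min, n_new, k, rng)
    return np.vstack([X, new]), np.concatenate([y, np.full(n_new, minority)])


def _adasyn(X, y, minority, majority, rng, k: int = 5):
    n_new = (y == majority).sum() - (y == minority).sum()
    if n_new <= 0:
        return X, y
    X_min = X[y == minority]
    kk = _safe_k(k, len(X) - 1, "ADASYN")
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(X)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    r = (y[neigh] == majority).mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)  # no borderline points: fall back to uniform allocation
    r = r / r.sum()
    counts = np.floor(r * n_new).astype(int)
    short = n_new - counts.sum()
    if short > 0:  # distribute the rounding remainder by weight
        extra = rng.choice(len(r), size=short, p=r)
        np.add.at(counts, extra, 1)
    if len(X_min) < 2:
        warnings.warn("ADASYN: minority class has a single point; duplicating it")
        new = np.repeat(X_min, n_new, axis=0)
    else:
        km = _safe_k(k, len(X_min) - 1, "ADASYN")
        nn_min = NearestNeighbors(n_neighbors=km + 1).fit(X_min)
        neigh_min = nn_min.kneighbors(X_min, return_distance=False)[:, 1:]
        pieces = []
        for i, c in enumerate(counts):
            if c == 0:
                continue
            partner = neigh_min[i, rng.integers(0, km, size=c)]
            gap = rng.uniform(0, 1, size=(c, 1))
            pieces.append(X_min[i] + gap * (X_min[partner] - X_min[i]))
        new = np.vstack(pieces) if pieces else np.empty((0, X.shape[1]))
    return np.vstack([X, new]), np.concatenate([y, np.full(len(new), minority)])


# ---------------------------------------------------------------------------
# cleaning / undersamplers


def tomek_links(X, y) -> np.ndarray:
    """Indices of points participating in a Tomek link.

    A Tomek link is a pair of opposite-class points that are each other's
    nearest neighbour.  Returns an (m, 2) index array, one row per link.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    first = nn.kneighbors(X, return_distance=False)[:, 1]
    links = []
    for i, j in enumerate(first):
        if i < j and first[j] == i and y[i] != y[j]:
            links.append((i, j))
    return np.asarray(links, dtype=int).reshape(-1, 2)


def _tl(X, y, minority, majority, rng):
    links = tomek_links(X, y)
    drop = {int(i) if y[i] == majority else int(j) for i, j in links}
    keep = np.array([i for i in range(len(y)) if i not in drop])
    return X[keep], y[keep]


def _enn_drop_set(X, y, minority, majority, k: int = 3) -> set[int]:
    """Majority points misclassified by the majority vote of their k NN."""
    if len(X) <= k:
        return set()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
    drop = set()
    for i in np.flatnonzero(y == majority):
        if (y[neigh[i]] == majority).sum() <= k / 2:
            drop.add(int(i))
    return drop


def _enn(X, y, minority, majority, rng, k: int = 3):
    drop = _enn_drop_set(X, y, minority, majority, k)
    keep = np.array([i for i in range(len(y)) if i not in drop])
    return X[keep], y[keep]


def _ncl(X, y, minority, majority, rng, k: int = 3):
    drop = _enn_drop_set(X, y, minority, majority, k)
    if len(X) > k:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        neigh = nn.kneighbors(X, return_distance=False)[:, 1:]
        for i in np.flatnonzero(y == minority):
            votes = y[neigh[i]]
            if (votes == minority).sum() <= k / 2:
                # minority point misclassified: clean its majority neighbours
                drop.update(int(j) for j in neigh[i] if y[j] == majority)
    keep = np.array([i for i in range(len(y)) if i not in drop])
    return X[keep], y[keep]


def _oss(X, y, minority, majority, rng):
    """One-sided selection: 1-NN condensing, then Tomek-link removal."""
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    seed = rng.choice(maj_idx)
    store = list(min_idx) + [int(seed)]
    for i in maj_idx:
        if i == seed:
            continue
        nn = NearestNeighbors(n_neighbors=1).fit(X[store])
        j = nn.kneighbors(X[i : i + 1], return_distance=False)[0, 0]
        if y[store[j]] != y[i]:  # misclassified by 1-NN on the store: keep it
            store.append(int(i))
    store = np.sort(np.asarray(store))
    Xs, ys = X[store], y[store]
    return _tl(Xs, ys, minority, majority, rng)


# ---------------------------------------------------------------------------

_DISPATCH = {
    "ROS": _ros,
    "SMOTE": _smote,
    "ADASYN": _adasyn,
    "OSS": _oss,
    "TL": _tl,
    "ENN": _enn,
    "NCL": _ncl,
}


def apply_sampler(name: str, X, y, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Apply a named sampling algorithm; combinations compose left-to-right."""
    if name not in SAMPLERS:
        raise ValueError(f"unknown sampler {name!r}; choose one of {SAMPLERS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if name == "none":
        return X, y
    rng = np.random.default_rng(rng)
    for part in name.split("+"):
        X, y, minority, majority = _validate(X, y)
        X, y = _DISPATCH[part](X, y, minority, majority, rng)
    return X, y
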