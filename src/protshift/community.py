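"""Community-level statistics: beta-diversity and per-feature dynamics.

Bray-Curtis dissimilarity BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i) compares
two abundance profiles; classical scaling (PCoA) embeds the dissimilarity
matrix; PERMANOVA tests group structure in it by permuting labels. Per-feature
dynamics over the intervention are summarised by the subject-wise log ratio
log(T12/T0) and by Cliff's delta, the nonparametric effect size
delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

__all__ = [
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
    "cliffs_delta",
    "log_fold_change",
    "default_pseudocount",
]


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if u.sum() == 0 and v.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero samples")
    return float(braycurtis(u, v))


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray-Curtis matrix from a features x samples table."""
    X = table.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample(s) present; Bray-Curtis undefined")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.columns, columns=table.columns)


def pcoa(dist: pd.DataFrame, n_axes: int | None = None):
    """Principal-coordinate analysis (classical scaling) of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and returns
    ``(coordinates, eigenvalues)`` with axes ordered by decreasing eigenvalue.
    Coordinates are only produced for positive eigenvalues; negative
    eigenvalues (non-Euclidean input) are reported but their axes dropped,
    with a warning when ``n_axes`` exceeds the positive rank.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    rank = int(pos.sum())
    if n_axes is None:
        n_axes = rank
    if n_axes > rank:
        import warnings

        warnings.warn(f"requested {n_axes} axes but positive rank is {rank}; truncating")
        n_axes = rank
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    coords = pd.DataFrame(coords, index=index,
                          columns=[f"PCo{i+1}" for i in range(n_axes)])
    return coords, evals


def permanova(dist: pd.DataFrame, labels: pd.Series, n_perm: int = 999,
              seed: int = 0) -> dict:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_between / (g-1)) / (SS_within / (n-g)) with sums of squared
    distances computed from the distance matrix; the p-value is
    (1 + #{permuted F >= observed}) / (1 + n_perm) under random relabelling,
    and R^2 = SS_between / SS_total.
    """
    D2 = np.asarray(dist, dtype=float) ** 2
    labels = pd.Series(labels)
    if isinstance(dist, pd.DataFrame):
        labels = labels.reindex(dist.index)
    y = labels.to_numpy()
    groups, counts = np.unique(y, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    n = len(y)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n

    def ss_within(perm_y: np.ndarray) -> float:
        s = 0.0
        for g, c in zip(groups, counts):
            idx = np.flatnonzero(perm_y == g)
            s += D2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / c
        return s

    g = len(groups)

    def pseudo_f(perm_y: np.ndarray) -> float:
        sw = ss_within(perm_y)
        sb = ss_total - sw
        return (sb / (g - 1)) / (sw / (n - g))

    f_obs = pseudo_f(y)
    rng = np.random.default_rng(seed)
    exceed = sum(pseudo_f(rng.permutation(y)) >= f_obs for _ in range(n_perm))
    sw_obs = ss_within(y)
    return {
        "pseudo_F": f_obs,
        "R2": (ss_total - sw_obs) / ss_total,
        "p": (1 + exceed) / (1 + n_perm),
        "n_perm": n_perm,
    }


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size; ties contribute zero (strict inequalities)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float(((diff > 0).sum() - (diff < 0).sum()) / diff.size)


def default_pseudocount(table: pd.DataFrame) -> float:
    """Half the smallest nonzero abundance in the table (0 if none)."""
    vals = table.to_numpy()
    nz = vals[vals > 0]
    return float(nz.min() / 2) if nz.size else 0.0


def log_fold_change(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    pseudocount: float | None = None,
    base: float | None = None,
) -> pd.DataFrame:
    """Subject-wise log((T12 + eps) / (T0 + eps)) per feature.

    ``pairs`` has columns ``t0`` and ``t12`` holding sample ids, indexed by
    subject. The pseudocount defaults to half the smallest nonzero abundance
    (see :func:`default_pseudocount`); ``base=None`` means natural log.
    """
    if (table.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    eps = default_pseudocount(table) if pseudocount is None else pseudocount
    t0 = table[pairs["t0"]].to_numpy(dtype=float)
    t12 = table[pairs["t12"]].to_numpy(dtype=float)
    lfc = np.log(t12 + eps) - np.log(t0 + eps)
    if base is not None:
        lfc = lfc / np.log(base)
    return pd.DataFrame(lfc, index=table.index, columns=pairs.index)
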