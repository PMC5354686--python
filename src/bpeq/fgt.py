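"""Fibroglandular-tissue segmentation by fuzzy c-means on intensities.

Clustering runs on the 1D intensity sample of all voxels inside one
breast mask (3D, whole-breast — not per slice — for statistical
stability). The number of clusters is selected automatically by a cluster
validity index (Xie–Beni by default), and on a fat-suppressed pre-contrast
image FGT is the highest-intensity cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume
from .breast import BreastMasks


class NoFgtSeparableError(ValueError):
    """Clustering found no intensity cluster separable as FGT."""


@dataclass
class FuzzyPartition:
    """Converged FCM state over a 1D intensity sample.

    ``memberships`` has one row per sample and one column per cluster
    (rows sum to 1); ``centroids`` are sorted ascending.
    """

    k: int
    m: float
    memberships: np.ndarray
    centroids: np.ndarray
    objective: float
    n_iter: int
    objective_history: np.ndarray

    def hard_labels(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)


def _fcm_once(x: np.ndarray, centroids: np.ndarray, m: float, tol: float, max_iter: int):
    exp = 2.0 / (m - 1.0)
    history = []
    u = None
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - centroids[None, :]) ** 2
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        # samples exactly at a centroid get full membership there
        at_c = np.isinf(inv)
        singular = at_c.any(axis=1)
        inv[singular] = at_c[singular]
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u**m
        centroids = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        d2 = (x[:, None] - centroids[None, :]) ** 2
        obj = float((um * d2).sum())
        history.append(obj)
        if it > 1 and abs(history[-2] - obj) < tol:
            break
    return u, centroids, history


def fcm(
    intensities: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 0,
) -> FuzzyPartition:
    """Fuzzy c-means on a 1D sample with deterministic quantile initialisation.

    Alternates the standard membership update
    u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1)) and the weighted-centroid update
    until the objective changes by less than ``tol``. ``n_restarts`` extra
    seeded random initialisations keep the best (lowest) objective.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if m <= 1:
        raise ValueError(f"fuzziness exponent m must be > 1, got {m}")
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct intensities for k={k} clusters")

    inits = [np.quantile(x, (2 * np.arange(k) + 1) / (2 * k))]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        lo, hi = x.min(), x.max()
        inits += [np.sort(rng.uniform(lo, hi, size=k)) for _ in range(n_restarts)]

    best = None
    for c0 in inits:
        u, c, history = _fcm_once(x, np.asarray(c0, dtype=float), m, tol, max_iter)
        if best is None or history[-1] < best[2][-1]:
            best = (u, c, history)
    u, c, history = best
    order = np.argsort(c)
    return FuzzyPartition(
        k=k,
        m=m,
        memberships=u[:, order],
        centroids=c[order],
        objective=history[-1],
        n_iter=len(history),
        objective_history=np.asarray(history),
    )


def xie_beni(partition: FuzzyPartition, x: np.ndarray) -> float:
    """Xie–Beni validity index: compactness / separation (lower is better)."""
    x = np.asarray(x, dtype=float).ravel()
    c = partition.centroids
    d2 = (x[:, None] - c[None, :]) ** 2
    compact = float((partition.memberships**partition.m * d2).sum())
    sep = np.min((c[:, None] - c[None, :])[np.triu_indices(partition.k, 1)] ** 2)
    return compact / (x.size * sep)


def partition_coefficient(partition: FuzzyPartition, x: np.ndarray) -> float:
    """Bezdek partition coefficient (higher is better); returned negated
    so every index is minimised."""
    return -float((partition.memberships**2).sum() / partition.memberships.shape[0])


_VALIDITY_INDICES = {"xie-beni": xie_beni, "partition-coefficient": partition_coefficient}


def select_cluster_number(
    intensities: np.ndarray,
    k_range: tuple[int, int] = (2, 5),
    validity_index: str = "xie-beni",
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> tuple[int, dict[int, FuzzyPartition]]:
    """Pick k in ``k_range`` minimising the validity index (ties → smaller k).

    Candidate k values exceeding the number of distinct intensities are
    skipped (they cannot be fitted); a singleton range is returned without
    evaluating the index.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    if not (2 <= lo <= hi <= 8):
        raise ValueError(f"k_range must lie within [2, 8], got {k_range}")
    if validity_index not in _VALIDITY_INDICES:
        raise ValueError(f"unknown validity index {validity_index!r}")
    x = np.asarray(intensities, dtype=float).ravel()
    n_distinct = np.unique(x).size
    candidates = [k for k in range(lo, hi + 1) if k <= n_distinct]
    if not candidates:
        raise ValueError(f"only {n_distinct} distinct intensities; no feasible k in {k_range}")
    partitions = {
        k: fcm(x, k, m=m, tol=tol, max_iter=max_iter, seed=seed) for k in candidates
    }
    if len(candidates) == 1:
        return candidates[0], partitions
    index_fn = _VALIDITY_INDICES[validity_index]
    scores = {k: index_fn(partitions[k], x) for k in candidates}
    best_k = min(candidates, key=lambda k: (scores[k], k))
    return best_k, partitions


def segment_fgt(
    volume: Volume,
    masks: BreastMasks,
    k_range: tuple[int, int] = (2, 5),
    validity_index: str = "xie-beni",
    m: float = 2.0,
    top_clusters: int = 1,
    min_separation: float = 4.0,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """FGT mask per breast: voxels whose largest membership is in the
    top-intensity cluster(s).

    Guards against the all-fat breast: if the overall centroid spread is
    below ``min_separation`` robust noise units (1.4826 x MAD of the
    in-mask intensities), no cluster is separable as FGT and
    :class:`NoFgtSeparableError` is raised rather than returning fat.
    """
    out: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        mask = getattr(masks, side)
        n = int(mask.sum())
        if n < 100:
            raise ValueError(f"{side} breast mask has {n} voxels; need >= 100 for clustering")
        x = np.asarray(volume.data, dtype=float)[mask]
        sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
        k, partitions = select_cluster_number(
            x, k_range=k_range, validity_index=validity_index, m=m, seed=seed
        )
        part = partitions[k]
        spread = part.centroids[-1] - part.centroids[0]
        if sigma > 0 and spread < min_separation * sigma:
            raise NoFgtSeparableError(
                f"{side} breast: centroid spread {spread:.2f} < "
                f"{min_separation} x noise ({sigma:.2f}); no FGT cluster separable"
            )
        labels = part.hard_labels()
        is_fgt = labels >= k - top_clusters
        fgt_mask = np.zeros(volume.shape, dtype=bool)
        fgt_mask[mask] = is_fgt
        out[side] = fgt_mask
    return out
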