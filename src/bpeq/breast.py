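"""Whole-breast segmentation by dynamic-programming boundary delineation.

Each axial slice is treated as a 2D image in which the skin line and the
chest wall are both single-valued curves: one row coordinate per column
(prone position, anterior at row 0). Both curves are extracted as globally
minimum-cost paths through an edge-cost grid under a per-step smoothness
bound, seeded on the central slice and propagated outward inside a band
around the neighbouring slice's curve — boundaries vary slowly across
adjacent slices, and the band makes that continuity explicit.

The cost is one minus the rescaled Gaussian-smoothed intensity gradient
along the anterior–posterior axis, optionally restricted to one edge
polarity: the skin is a dark-to-bright (air to tissue) transition, the
chest wall bright-to-dark (fat to thorax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume


class DegenerateSliceError(ValueError):
    """A slice has no intensity edge to delineate."""


class InfeasibleBandError(ValueError):
    """The band constraint admits no path under the smoothness bound."""


@dataclass
class BoundaryPath:
    """Open curve on one slice: one row index per column, plus its cost."""

    slice_index: int
    rows: np.ndarray  # (n_cols,) int
    cost: float
    kind: str = "boundary"  # "skin" | "chest" | "boundary"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        if not np.isfinite(self.cost):
            raise ValueError("path cost must be finite")

    def to_dict(self) -> dict:
        return {
            "slice": int(self.slice_index),
            "kind": self.kind,
            "rows": self.rows.tolist(),
            "cost": float(self.cost),
        }


@dataclass
class BreastMasks:
    """Left/right whole-breast masks plus the per-slice boundary curves."""

    left: np.ndarray
    right: np.ndarray
    skin_paths: list[BoundaryPath]
    chest_paths: list[BoundaryPath]

    def __post_init__(self) -> None:
        if (self.left & self.right).any():
            raise ValueError("left and right breast masks must be disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.left | self.right

    def skin_rows(self) -> np.ndarray:
        """(cols, slices) array of skin rows."""
        return np.stack([p.rows for p in self.skin_paths], axis=1)

    def chest_rows(self) -> np.ndarray:
        return np.stack([p.rows for p in self.chest_paths], axis=1)


def boundary_cost(
    slice_image: np.ndarray,
    sigma: float = 1.0,
    direction: str = "both",
) -> np.ndarray:
    """Edge cost grid in [0, 1]; low cost marks strong row-direction edges.

    ``direction`` selects the edge polarity along increasing row index:
    "increasing" keeps dark→bright edges (skin on a prone axial slice),
    "decreasing" bright→dark (chest wall), "both" the gradient magnitude.
    Raises :class:`DegenerateSliceError` for constant slices.
    """
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 8:
        raise ValueError(f"slice must be 2D with >= 8 rows and columns, got {img.shape}")
    grad = ndimage.gaussian_filter1d(img, sigma=sigma, axis=0, order=1)
    if direction == "both":
        edge = np.abs(grad)
    elif direction == "increasing":
        edge = np.clip(grad, 0.0, None)
    elif direction == "decreasing":
        edge = np.clip(-grad, 0.0, None)
    else:
        raise ValueError(f"direction must be both/increasing/decreasing, got {direction!r}")
    peak = edge.max()
    if peak <= 0:
        raise DegenerateSliceError("constant slice: no intensity edge to delineate")
    return 1.0 - edge / peak


def dp_min_path(
    cost: np.ndarray,
    smoothness: int = 2,
    band: tuple[np.ndarray, int] | None = None,
    prefer: str = "low",
) -> BoundaryPath:
    """Globally minimum-cost left-to-right path, one row per column.

    Consecutive rows may differ by at most ``smoothness``; ``band`` as
    ``(prior_rows, width)`` restricts column c to rows within ``width`` of
    ``prior_rows[c]``. Among equal-cost optima, the ``prefer`` = "low"
    (anterior) or "high" (posterior) row is taken, resolved column by
    column from the left — this makes the output deterministic.

    The returned cost is the exact sum of traversed cell costs, accumulated
    right-to-left.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2:
        raise ValueError("cost grid must be 2D")
    if smoothness < 1:
        raise ValueError("smoothness bound must be >= 1")
    if prefer not in ("low", "high"):
        raise ValueError("prefer must be 'low' or 'high'")
    n_rows, n_cols = cost.shape

    allowed = np.ones_like(cost, dtype=bool)
    if band is not None:
        prior, width = band
        prior = np.asarray(prior, dtype=int)
        if prior.shape != (n_cols,) or width < 0:
            raise ValueError("band must be (rows-per-column, nonnegative width)")
        rr = np.arange(n_rows)[:, None]
        allowed = np.abs(rr - prior[None, :]) <= width
        if not allowed.any(axis=0).all():
            raise InfeasibleBandError("band admits no rows in some column")

    INF = np.inf
    # suffix cost-to-go, filled right to left
    D = np.where(allowed[:, -1], cost[:, -1], INF)
    suffix = np.empty_like(cost)
    suffix[:, -1] = D
    size = 2 * smoothness + 1
    for c in range(n_cols - 2, -1, -1):
        reach = ndimage.minimum_filter1d(suffix[:, c + 1], size=size, mode="constant", cval=INF)
        D = np.where(allowed[:, c], cost[:, c] + reach, INF)
        suffix[:, c] = D
    if not np.isfinite(suffix[:, 0]).any():
        raise InfeasibleBandError("band is disconnected under the smoothness bound")

    def _pick(values: np.ndarray, lo: int, hi: int) -> int:
        window = values[lo:hi]
        best = window.min()
        ties = np.flatnonzero(window == best)
        return lo + (ties[0] if prefer == "low" else ties[-1])

    rows = np.empty(n_cols, dtype=int)
    rows[0] = _pick(suffix[:, 0], 0, n_rows)
    for c in range(1, n_cols):
        lo = max(0, rows[c - 1] - smoothness)
        hi = min(n_rows, rows[c - 1] + smoothness + 1)
        rows[c] = _pick(suffix[:, c], lo, hi)
    if not np.isfinite(suffix[rows[0], 0]):
        raise InfeasibleBandError("no feasible path")
    return BoundaryPath(slice_index=-1, rows=rows, cost=float(suffix[rows[0], 0]))


def _column_profiles(data: np.ndarray, sigma: float) -> np.ndarray:
    """Row-smoothed intensities, (rows, cols, slices)."""
    return ndimage.gaussian_filter1d(data, sigma=max(sigma, 0.5), axis=0)


def _initial_curves(data: np.ndarray, s: int, sigma: float):
    """Threshold-based first-tissue and last-bright-tissue rows on slice s.

    Self-calibrated thresholds: air level from the anterior rows, fat level
    from just behind the first tissue crossing, thoracic level from the
    posterior rows. Returns (skin_init, chest_init) per column.
    """
    sl = _column_profiles(data[:, :, s], sigma)
    n_rows, n_cols = sl.shape
    air_ref = float(np.median(sl[:3, :]))
    post_ref = float(np.median(sl[-4:, :]))
    body = sl > (air_ref + sl.max()) / 4.0
    if not body.any(axis=0).all():
        raise DegenerateSliceError(f"no detectable anterior edge on slice {s}")
    skin_init = body.argmax(axis=0)
    # fat reference: rows just posterior of the skin crossing
    samples = []
    for c in range(0, n_cols, max(1, n_cols // 32)):
        r0 = skin_init[c] + 1
        samples.append(sl[r0 : r0 + 3, c])
    fat_ref = float(np.median(np.concatenate(samples)))
    t_bright = (fat_ref + post_ref) / 2.0
    bright = sl > t_bright
    if not bright.any(axis=0).all():
        raise DegenerateSliceError(f"no bright tissue band on slice {s}")
    chest_init = n_rows - 1 - bright[::-1].argmax(axis=0) + 1
    chest_init = np.clip(chest_init, 1, n_rows - 1)
    skin_init = ndimage.median_filter(skin_init, size=7, mode="nearest")
    chest_init = ndimage.median_filter(chest_init, size=7, mode="nearest")
    return skin_init, chest_init


def _delineate_slice(
    data: np.ndarray,
    s: int,
    sigma: float,
    smoothness: int,
    skin_band: tuple[np.ndarray, int],
    chest_band: tuple[np.ndarray, int],
) -> tuple[BoundaryPath, BoundaryPath]:
    sl = data[:, :, s]
    skin = dp_min_path(
        boundary_cost(sl, sigma=sigma, direction="increasing"),
        smoothness=smoothness,
        band=skin_band,
        prefer="low",
    )
    chest = dp_min_path(
        boundary_cost(sl, sigma=sigma, direction="decreasing"),
        smoothness=smoothness,
        band=chest_band,
        prefer="high",
    )
    skin.slice_index = chest.slice_index = s
    skin.kind, chest.kind = "skin", "chest"
    return skin, chest


def voi_crop(volume: Volume, fraction: float = 1.0) -> tuple[Volume, tuple[int, int]]:
    """Fixed-fraction in-plane crop centred on the intensity centroid.

    Returns the cropped volume and the (row, col) offset of its origin in
    the input grid. ``fraction`` = 1 is the identity.
    """
    if not 0.2 < fraction <= 1.0:
        raise ValueError("crop fraction must be in (0.2, 1]")
    if fraction == 1.0:
        return volume, (0, 0)
    data = volume.data
    w = data - data.min()
    total = w.sum()
    rows, cols, _ = data.shape
    r_c = float((w.sum(axis=(1, 2)) * np.arange(rows)).sum() / total)
    c_c = float((w.sum(axis=(0, 2)) * np.arange(cols)).sum() / total)
    hr, hc = int(round(fraction * rows / 2)), int(round(fraction * cols / 2))
    r0 = int(np.clip(round(r_c) - hr, 0, rows - 2 * hr))
    c0 = int(np.clip(round(c_c) - hc, 0, cols - 2 * hc))
    cropped = Volume(data[r0 : r0 + 2 * hr, c0 : c0 + 2 * hc, :], volume.spacing, volume.phase)
    return cropped, (r0, c0)


def segment_whole_breast(
    volume: Volume,
    smoothness: int = 2,
    band_width: int = 3,
    sigma: float = 1.0,
    init_band_width: int = 4,
    crop_fraction: float = 1.0,
) -> BreastMasks:
    """Delineate skin line and chest wall on every slice; split at the midline.

    The central slice is delineated first inside a band around
    threshold-derived initial curves; each further slice is constrained to
    ``band_width`` voxels around its already-segmented neighbour. The
    breast region on a slice is the set of voxels strictly between the two
    curves; left and right masks split at the midline column (columns run
    subject-right to subject-left).
    """
    vol, (r_off, c_off) = voi_crop(volume, crop_fraction)
    data = np.asarray(vol.data, dtype=float)
    n_rows, n_cols, n_slices = data.shape
    s_mid = n_slices // 2

    skin_init, chest_init = _initial_curves(data, s_mid, sigma)
    skin_paths: dict[int, BoundaryPath] = {}
    chest_paths: dict[int, BoundaryPath] = {}
    skin_paths[s_mid], chest_paths[s_mid] = _delineate_slice(
        data,
        s_mid,
        sigma,
        smoothness,
        (skin_init, init_band_width),
        (chest_init, init_band_width),
    )
    for direction in (-1, 1):
        s = s_mid + direction
        while 0 <= s < n_slices:
            prev_skin = skin_paths[s - direction].rows
            prev_chest = chest_paths[s - direction].rows
            skin_paths[s], chest_paths[s] = _delineate_slice(
                data,
                s,
                sigma,
                smoothness,
                (prev_skin, band_width),
                (prev_chest, band_width),
            )
            s += direction

    skin_rows = np.stack([skin_paths[s].rows for s in range(n_slices)], axis=1)
    chest_rows = np.stack([chest_paths[s].rows for s in range(n_slices)], axis=1)
    r = np.arange(n_rows)[:, None, None]
    between = (r > skin_rows[None, :, :]) & (r < chest_rows[None, :, :])

    # map back onto the uncropped grid
    full = np.zeros(volume.shape, dtype=bool)
    full[r_off : r_off + n_rows, c_off : c_off + n_cols, :] = between
    cmid = volume.shape[1] // 2
    left = full.copy()
    left[:, :cmid, :] = False
    right = full.copy()
    right[:, cmid:, :] = False

    def _shift(paths: dict[int, BoundaryPath]) -> list[BoundaryPath]:
        out = []
        for s in range(n_slices):
            p = paths[s]
            rows_full = np.full(volume.shape[1], p.rows[0] + r_off)
            rows_full[c_off : c_off + n_cols] = p.rows + r_off
            out.append(BoundaryPath(s, rows_full, p.cost, p.kind))
        return out

    return BreastMasks(
        left=left, right=right, skin_paths=_shift(skin_paths), chest_paths=_shift(chest_paths)
    )
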