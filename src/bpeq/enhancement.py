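"""Enhanced-FGT segmentation on pre/post subtraction images.

Enhancement is isolated by subtracting the pre-contrast volume from a
post-contrast phase, estimating the subtraction-noise level robustly on a
non-enhancing reference region, and keeping FGT voxels whose subtraction
value exceeds z times that noise level (z = 3 by default, i.e. a one-sided
normal tail of ~0.00135 under the pure-noise null).
"""

from __future__ import annotations

import numpy as np

from .breast import BreastMasks
from .volume import SubtractionVolume, Volume


def subtract(post: Volume, pre: Volume) -> SubtractionVolume:
    """Voxel-wise post − pre difference; grids and spacings must match."""
    if post.shape != pre.shape:
        raise ValueError(f"grid mismatch: post {post.shape} vs pre {pre.shape}")
    if post.spacing != pre.spacing:
        raise ValueError(f"spacing mismatch: post {post.spacing} vs pre {pre.spacing}")
    if post.phase not in ("early", "mid", "late"):
        raise ValueError(f"post volume needs a post-contrast phase label, got {post.phase!r}")
    return SubtractionVolume(
        data=np.asarray(post.data, dtype=float) - np.asarray(pre.data, dtype=float),
        spacing=post.spacing,
        phase=post.phase,
        provenance=(str(post.phase), str(pre.phase)),
    )


def estimate_noise(sub: SubtractionVolume, reference_mask: np.ndarray) -> float:
    """Robust noise scale of the subtraction in a non-enhancing region.

    Median absolute deviation scaled by 1.4826 (consistent for a normal),
    so a few enhancing outliers in the reference barely move the estimate.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    n = int(reference_mask.sum())
    if n < 50:
        raise ValueError(f"reference region has {n} voxels; need >= 50")
    values = sub.data[reference_mask]
    return float(1.4826 * np.median(np.abs(values - np.median(values))))


def air_reference_mask(masks: BreastMasks, margin: int = 3) -> np.ndarray:
    """Default noise-reference region: air anterior of the skin line.

    Keeps ``margin`` voxels clear of the skin to avoid edge blur.
    """
    skin = masks.skin_rows()  # (cols, slices)
    n_rows = masks.left.shape[0]
    r = np.arange(n_rows)[:, None, None]
    return r < (skin[None, :, :] - margin)


def threshold_enhanced(
    sub: SubtractionVolume,
    fgt_mask: np.ndarray,
    sigma: float,
    z: float = 3.0,
) -> np.ndarray:
    """Enhanced-FGT mask: FGT voxels with subtraction value > z·sigma."""
    if z <= 0:
        raise ValueError(f"multiplier z must be > 0, got {z}")
    if sigma < 0:
        raise ValueError(f"noise level must be >= 0, got {sigma}")
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    if not fgt_mask.any():
        raise ValueError("FGT mask is empty")
    return fgt_mask & (sub.data > z * sigma)
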