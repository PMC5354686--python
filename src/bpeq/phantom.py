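"""Synthetic bilateral-breast DCE-MRI phantom with known ground truth.

The phantom emulates a prone-position, axial, fat-suppressed T1 acquisition:
air anterior of a smooth skin line, two breast lobes of fat containing
blobby fibroglandular tissue (FGT), a smooth chest-wall boundary behind
which lies darker thoracic tissue. Post-contrast phases (early/mid/late at
2/4/6 minutes) add a signal uplift to a prescribed, phase-nested fraction of
FGT voxels, so the true background parenchymal enhancement rate
(BPER = enhanced FGT voxels / FGT voxels x 100) is known exactly. Additive
i.i.d. Gaussian noise models acquisition noise (magnitude-image Rician noise
is deliberately not modelled; see docs/methods.md).

Intensity ordering on the pre-contrast image is fixed by construction:
air < thorax < fat < FGT, which is the labelling convention the FGT
segmenter relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import PHASES, Volume

#: minimum grid extent able to hold two breast lobes
_MIN_EXTENT = 32


def _as_pair(x) -> tuple[float, float]:
    """Broadcast a scalar to a (left, right) pair."""
    if np.isscalar(x):
        return float(x), float(x)
    pair = tuple(float(v) for v in x)
    if len(pair) != 2:
        raise ValueError(f"expected scalar or (left, right) pair, got {x!r}")
    return pair  # type: ignore[return-value]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``fgt_fraction`` is the FGT share of each breast's volume;
    ``enhancement_fractions`` maps each post-contrast phase to the enhanced
    share of FGT voxels per breast and must be non-decreasing over
    (early, mid, late) — enhancement accumulates with time after injection.
    Intensities are arbitrary scanner units; defaults put 5% noise at
    sigma_noise=5 relative to fat.
    """

    shape: tuple[int, int, int] = (128, 128, 48)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    fgt_fraction: float | tuple[float, float] = 0.30
    enhancement_fractions: dict[str, float | tuple[float, float]] = field(
        default_factory=lambda: {"early": 0.25, "mid": 0.40, "late": 0.50}
    )
    intensity_air: float = 5.0
    intensity_thorax: float = 40.0
    intensity_fat: float = 100.0
    intensity_fgt: float = 180.0
    uplift: dict[str, float] = field(
        default_factory=lambda: {"early": 80.0, "mid": 110.0, "late": 140.0}
    )
    sigma_noise: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < _MIN_EXTENT for n in self.shape):
            raise ValueError(
                f"grid {self.shape} too small: every axis needs >= {_MIN_EXTENT} voxels "
                "to contain two breasts"
            )
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        for side_frac in _as_pair(self.fgt_fraction):
            if not 0 <= side_frac < 1:
                raise ValueError(f"fgt_fraction must be in [0, 1), got {self.fgt_fraction}")
        if set(self.enhancement_fractions) != set(PHASES):
            raise ValueError(f"enhancement_fractions must have keys {PHASES}")
        for side in (0, 1):
            fracs = [_as_pair(self.enhancement_fractions[p])[side] for p in PHASES]
            if any(not 0 <= f <= 1 for f in fracs):
                raise ValueError(f"enhancement fractions must lie in [0, 1], got {fracs}")
            if any(b < a for a, b in zip(fracs, fracs[1:])):
                raise ValueError(
                    f"enhancement fractions must be non-decreasing over {PHASES}, got {fracs}"
                )
        for name in ("intensity_air", "intensity_thorax", "intensity_fat", "intensity_fgt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(u < 0 for u in self.uplift.values()):
            raise ValueError("uplift values must be >= 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")


@dataclass
class GroundTruth:
    """Masks, boundary rows and exact per-breast BPER emitted with a phantom.

    ``skin_rows`` / ``chest_rows`` give, per (column, slice), the first
    tissue row resp. the first thoracic row, i.e. breast tissue occupies
    rows ``skin_rows <= r < chest_rows``.
    """

    breast: dict[str, np.ndarray]
    fgt: dict[str, np.ndarray]
    enhanced: dict[str, dict[str, np.ndarray]]  # phase -> side -> mask
    skin_rows: np.ndarray  # (cols, slices) int
    chest_rows: np.ndarray  # (cols, slices) int
    true_bper: dict[str, dict[str, float]]  # phase -> side -> %

    def summary(self) -> dict:
        """JSON-serialisable summary (counts and true BPER)."""
        return {
            "fgt_voxels": {s: int(m.sum()) for s, m in self.fgt.items()},
            "breast_voxels": {s: int(m.sum()) for s, m in self.breast.items()},
            "enhanced_voxels": {
                p: {s: int(m.sum()) for s, m in side.items()}
                for p, side in self.enhanced.items()
            },
            "true_bper": self.true_bper,
        }


def _smooth_field(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Gaussian-correlated random field used to carve blobby regions."""
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)


def _geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Skin and chest-wall row per (column, slice) plus per-breast lobe windows."""
    rows, cols, slices = spec.shape
    c = np.arange(cols)
    s = np.arange(slices)
    cmid = (cols - 1) / 2.0

    # chest wall: anteriorly convex low-order polynomial, plus a smooth,
    # bounded slice-to-slice wobble (|step| <= ~1 voxel keeps the cross-slice
    # continuity assumption of the breast segmenter satisfiable)
    x = (c - cmid) / cmid  # [-1, 1]
    base = 0.52 * rows + 0.05 * rows * x**2
    phase0, phase1 = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.5 * np.sin(2 * np.pi * s / slices + phase0) + 0.8 * np.sin(
        4 * np.pi * s / slices + phase1
    )
    chest = np.rint(base[:, None] + wobble[None, :]).astype(int)
    chest = np.clip(chest, 8, rows - 4)

    # breast lobes: two smooth bumps anterior of the chest wall, tapering
    # over slices but present on every slice; a thin subcutaneous layer
    # spans the full width so a skin line exists between the breasts too
    # lobe height/width chosen so the skin slope stays below 2 rows/column,
    # inside the delineator's default per-step smoothness bound
    amp = 0.26 * rows
    taper = np.sqrt(np.clip(1.0 - ((s - (slices - 1) / 2) / ((slices - 1) / 2 * 1.15)) ** 2, 0, 1))
    taper = 0.45 + 0.55 * taper  # in [0.45, 1]
    centers = (0.27 * (cols - 1), 0.73 * (cols - 1))
    width = 0.215 * cols
    bump = np.zeros((cols, slices))
    for cc in centers:
        u = (c[:, None] - cc) / width
        bump += np.clip(1.0 - u**2, 0, None) ** 1.2
    bump = amp * bump * taper[None, :]
    layer = 3  # subcutaneous tissue thickness, voxels
    skin = np.rint(chest - bump - layer).astype(int)
    skin = np.clip(skin, 2, chest - layer)
    return skin, chest, centers, width


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, dict[str, Volume], GroundTruth]:
    """Build the pre-contrast volume, the three post-contrast volumes and truth.

    Deterministic for equal specs (the seed lives in the spec). Enhanced
    masks are nested across phases because enhancement fractions are
    non-decreasing and voxels are recruited along a fixed smooth-field
    ranking.
    """
    rows, cols, slices = spec.shape
    rng = np.random.default_rng(spec.seed)
    skin, chest, centers, width = _geometry(spec, rng)

    r = np.arange(rows)[:, None, None]
    skin_b = skin[None, :, :]
    chest_b = chest[None, :, :]
    tissue = (r >= skin_b) & (r < chest_b)
    thorax = r >= chest_b

    cmid = cols // 2
    col_idx = np.zeros((1, cols, 1), dtype=int)
    col_idx[0, :, 0] = np.arange(cols)
    # columns run subject-right -> subject-left, so the left breast is the
    # high-column half
    breast = {
        "right": tissue & (col_idx < cmid),
        "left": tissue & (col_idx >= cmid),
    }

    # FGT: top-ranked voxels of a smooth random field inside each lobe core
    # (kept clear of skin and chest wall so boundary voxels stay fat)
    field3 = _smooth_field(rng, spec.shape, sigma=(4, 4, 2))
    enh_field = _smooth_field(rng, spec.shape, sigma=(3, 3, 1.5))
    fgt: dict[str, np.ndarray] = {}
    enhanced: dict[str, dict[str, np.ndarray]] = {p: {} for p in PHASES}
    fgt_pair = _as_pair(spec.fgt_fraction)
    for side, center in zip(("right", "left"), centers):
        frac = dict(zip(("left", "right"), fgt_pair))[side]
        # stand-off from skin and chest wall: the strong FGT-fat edges must
        # not fall inside the boundary delineator's search band, mirroring
        # real anatomy (subcutaneous and retromammary fat layers)
        top_margin = max(3, round(0.052 * rows))
        bottom_margin = max(4, round(0.083 * rows))
        lobe_core = (
            breast[side]
            & (r >= skin_b + top_margin)
            & (r < chest_b - bottom_margin)
            & (np.abs(col_idx - center) < 0.9 * width)
        )
        n_target = int(round(frac * breast[side].sum()))
        core_idx = np.flatnonzero(lobe_core)
        if n_target > core_idx.size:
            raise ValueError(
                f"fgt_fraction {frac} needs {n_target} voxels but the {side} lobe core "
                f"has only {core_idx.size}"
            )
        order = core_idx[np.argsort(field3.flat[core_idx])[::-1]]
        mask = np.zeros(spec.shape, dtype=bool)
        mask.flat[order[:n_target]] = True
        fgt[side] = mask

        fgt_idx = np.flatnonzero(mask)
        enh_order = fgt_idx[np.argsort(enh_field.flat[fgt_idx])[::-1]]
        for p in PHASES:
            f = dict(zip(("left", "right"), _as_pair(spec.enhancement_fractions[p])))[side]
            n_enh = int(round(f * fgt_idx.size))
            emask = np.zeros(spec.shape, dtype=bool)
            emask.flat[enh_order[:n_enh]] = True
            enhanced[p][side] = emask

    pre = np.full(spec.shape, spec.intensity_air, dtype=float)
    pre[thorax] = spec.intensity_thorax
    pre[tissue] = spec.intensity_fat
    all_fgt = fgt["left"] | fgt["right"]
    pre[all_fgt] = spec.intensity_fgt

    vols: dict[str, Volume] = {}
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    pre_noisy = pre + spec.sigma_noise * noise_rng.standard_normal(spec.shape)
    for p in PHASES:
        post = pre.copy()
        emask = enhanced[p]["left"] | enhanced[p]["right"]
        post[emask] += spec.uplift[p]
        post += spec.sigma_noise * noise_rng.standard_normal(spec.shape)
        vols[p] = Volume(post, spec.spacing, phase=p)

    true_bper = {
        p: {
            side: 100.0 * enhanced[p][side].sum() / fgt[side].sum()
            if fgt[side].sum()
            else float("nan")
            for side in ("left", "right")
        }
        for p in PHASES
    }
    truth = GroundTruth(
        breast=breast,
        fgt=fgt,
        enhanced=enhanced,
        skin_rows=skin,
        chest_rows=chest,
        true_bper=true_bper,
    )
    return Volume(pre_noisy, spec.spacing, phase="pre"), vols, truth


# ---------------------------------------------------------------------------
# cohort simulator


#: truncated-normal (mean, sd) of subject-level BPER (%) per
#: (menopause, group, phase); medians ordered cancer > benign > control,
#: premenopausal > postmenopausal, and increasing with phase, mirroring the
#: study population. Overridable per call; treated as configuration.
DEFAULT_COHORT_MODEL: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "premenopausal": {
        "control": {"early": (25, 20), "mid": (32, 20), "late": (38, 20)},
        "benign": {"early": (32, 20), "mid": (40, 20), "late": (46, 20)},
        "cancer": {"early": (39, 20), "mid": (46, 20), "late": (52, 20)},
    },
    "postmenopausal": {
        "control": {"early": (8, 12), "mid": (12, 12), "late": (16, 12)},
        "benign": {"early": (12, 12), "mid": (17, 12), "late": (22, 12)},
        "cancer": {"early": (17, 12), "mid": (22, 12), "late": (27, 12)},
    },
}

GROUPS = ("cancer", "benign", "control")


def simulate_cohort(
    n_per_group: int,
    seed: int,
    model: dict | None = None,
    premenopausal_fraction: float = 47 / 101,
) -> pd.DataFrame:
    """Simulate per-subject BPER for the three study groups.

    Returns one row per subject with columns ``subject, group, menopause,
    bper_early, bper_mid, bper_late``; values are truncated-normal draws on
    [0, 100]. Menopausal status is assigned deterministically so every group
    has the same premenopausal count (matched design).
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    model = DEFAULT_COHORT_MODEL if model is None else model
    for meno in model.values():
        for group in meno.values():
            for loc, scale in group.values():
                if scale <= 0:
                    raise ValueError("cohort model scales must be > 0")
    rng = np.random.default_rng(seed)
    n_pre = int(round(premenopausal_fraction * n_per_group))
    frames = []
    for group in GROUPS:
        meno = np.where(np.arange(n_per_group) < n_pre, "premenopausal", "postmenopausal")
        frame = pd.DataFrame(
            {
                "subject": [f"{group}-{i:03d}" for i in range(n_per_group)],
                "group": group,
                "menopause": meno,
            }
        )
        for phase in PHASES:
            values = np.empty(n_per_group)
            for m, n in (("premenopausal", n_pre), ("postmenopausal", n_per_group - n_pre)):
                loc, scale = model[m][group][phase]
                a, b = (0 - loc) / scale, (100 - loc) / scale
                draw = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
                values[meno == m] = draw
            frame[f"bper_{phase}"] = values
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
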