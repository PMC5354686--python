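"""The BPER statistic and the subject-level measurement-target rules.

BPER (background parenchymal enhancement rate) is the volume ratio of
enhanced fibroglandular tissue to total fibroglandular tissue,

    BPER = Ve / Vt x 100%

computed per breast and per post-contrast phase. At the subject level the
measurement target is the mean of the two breasts for controls and the
contralateral (lesion-free) breast for cancer and benign-lesion subjects,
so the lesion itself never contaminates the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GROUPS = ("cancer", "benign", "control")
SIDES = ("left", "right")


class BperUndefinedError(ZeroDivisionError):
    """Vt = 0: BPER is undefined for an empty FGT mask."""


@dataclass(frozen=True)
class BperResult:
    """Per-breast, per-phase volumes and BPER."""

    subject: str
    side: str
    phase: str
    vt_voxels: int
    ve_voxels: int
    vt_mm3: float
    ve_mm3: float
    bper: float  # percent


@dataclass(frozen=True)
class SubjectRecord:
    """Subject metadata with the study's consistency rules enforced."""

    subject: str
    group: str
    menopause: str  # "premenopausal" | "postmenopausal"
    lesion_side: str | None = None
    menstrual_week: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.menopause not in ("premenopausal", "postmenopausal"):
            raise ValueError(f"bad menopausal status {self.menopause!r}")
        if self.group == "control":
            if self.lesion_side is not None:
                raise ValueError("controls have no lesion side")
        else:
            if self.lesion_side not in SIDES:
                raise ValueError(f"{self.group} subject requires a lesion side in {SIDES}")
        if self.menopause == "premenopausal":
            if self.menstrual_week not in (1, 2, 3, 4):
                raise ValueError("premenopausal subjects require menstrual week 1-4")
        elif self.menstrual_week is not None:
            raise ValueError("postmenopausal subjects have no menstrual week")


def compute_bper(
    fgt_mask: np.ndarray,
    enhanced_mask: np.ndarray,
    spacing: tuple[float, float, float],
    subject: str = "",
    side: str = "",
    phase: str = "",
) -> BperResult:
    """Ve, Vt and BPER from nested masks on one grid.

    The ratio is taken on voxel counts (identical grids), spacing only
    converts counts to mm^3 for reporting.
    """
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    enhanced_mask = np.asarray(enhanced_mask, dtype=bool)
    if fgt_mask.shape != enhanced_mask.shape:
        raise ValueError("masks must share a grid")
    if (enhanced_mask & ~fgt_mask).any():
        raise ValueError("enhanced mask must be a subset of the FGT mask")
    vt = int(fgt_mask.sum())
    ve = int(enhanced_mask.sum())
    if vt == 0:
        raise BperUndefinedError("Vt = 0, BPER undefined")
    voxel = float(np.prod(spacing))
    return BperResult(
        subject=subject,
        side=side,
        phase=phase,
        vt_voxels=vt,
        ve_voxels=ve,
        vt_mm3=vt * voxel,
        ve_mm3=ve * voxel,
        bper=100.0 * ve / vt,
    )


def subject_bper(
    left: "BperResult | float | None",
    right: "BperResult | float | None",
    group: str,
    lesion_side: str | None = None,
) -> float:
    """Subject-level BPER under the measurement-target rules.

    Controls: mean of the two breasts (both required). Cancer/benign:
    the breast contralateral to the lesion (that breast required; the
    ipsilateral value is ignored entirely).
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")

    def _value(x, side):
        if x is None:
            raise ValueError(f"missing {side}-breast BPER")
        return float(x.bper) if isinstance(x, BperResult) else float(x)

    if group == "control":
        return 0.5 * (_value(left, "left") + _value(right, "right"))
    if lesion_side not in SIDES:
        raise ValueError(f"{group} subject requires lesion_side in {SIDES}")
    contralateral = "right" if lesion_side == "left" else "left"
    return _value(left if contralateral == "left" else right, contralateral)
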