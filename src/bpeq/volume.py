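"""Volumetric image container and NIfTI round-trip IO.

Axis convention (documented, callers must reorient to it):

* axis 0 — rows, anterior → posterior (subject prone, chest wall at high
  row index);
* axis 1 — columns, subject-right → subject-left;
* axis 2 — slices, inferior → superior.

Voxel spacing is in millimetres per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: DCE phase labels in acquisition order and their nominal post-injection times.
PHASES: tuple[str, ...] = ("early", "mid", "late")
PHASE_MINUTES: dict[str, float] = {"early": 2.0, "mid": 4.0, "late": 6.0}


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and an optional DCE phase label."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume requires a 3D array, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.phase is not None and self.phase not in ("pre",) + PHASES:
            raise ValueError(f"phase must be one of pre/{'/'.join(PHASES)}, got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray, phase: str | None = None) -> "Volume":
        """New volume on the same grid, optionally relabelled."""
        return Volume(data, self.spacing, phase if phase is not None else self.phase)


def read_volume(path: str | Path, phase: str | None = None) -> Volume:
    """Read a NIfTI volume, keeping voxel spacing from the header.

    Raises on non-3D images. A header with zero spacing on any axis is
    repaired to 1 mm with a warning: BPER is a ratio of voxel counts, so
    spacing only affects reported absolute volumes.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        warnings.warn(
            f"{path}: missing/zero voxel spacing {zooms}; assuming 1 mm. "
            "BPER is unaffected; absolute volumes (mm^3) will be wrong.",
            stacklevel=2,
        )
        zooms = tuple(z if z > 0 else 1.0 for z in zooms)
    return Volume(data, zooms, phase=phase)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume (or integer mask) as NIfTI with spacing in the affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


@dataclass
class SubtractionVolume:
    """Voxel-wise post − pre difference image for one post-contrast phase."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    phase: str
    provenance: tuple[str, str] = field(default=("post", "pre"))

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def minutes(self) -> float:
        return PHASE_MINUTES[self.phase]
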