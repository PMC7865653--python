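"""Core containers shared across the pipeline.

A lesion is represented by a gray-level volume, an aligned binary mask and
the physical voxel spacing; a patient carries one such volume per lesion and
contrast phase, for one reader's segmentation.  Feature values travel as a
tidy pandas DataFrame (patient_id, reader, feature_name, family, value) or a
wide patients x features matrix — helpers for both live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "LesionVolume",
    "DiscretizedLesion",
    "PatientRecord",
    "tidy_to_wide",
    "wide_to_tidy",
    "DegenerateLesionError",
]


class DegenerateLesionError(ValueError):
    """Raised when a lesion is too small/degenerate for a feature family."""


@dataclass
class LesionVolume:
    """One lesion's 3D gray-level array plus mask, for a single phase.

    Parameters
    ----------
    image : float ndarray, shape (nx, ny, nz)
        Gray-level volume (cropped to a bounding box around the lesion).
    mask : bool ndarray, same shape
        Voxels belonging to the lesion.
    spacing : tuple of 3 floats
        Physical voxel edge lengths in mm, ordered as the array axes.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.image.ndim != 3:
            raise ValueError("expected a 3D volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def values(self) -> np.ndarray:
        """In-mask intensities as a flat array."""
        return self.image[self.mask]


@dataclass
class DiscretizedLesion:
    """Gray levels quantized to 1..n_levels inside the mask.

    Out-of-mask voxels hold 0, a sentinel excluded from every texture matrix.
    ``provenance`` records how the levels were produced (resampling scale,
    wavelet weight, quantization scheme, degenerate-intensity flag).
    """

    levels: np.ndarray  # int array, 0 outside mask, 1..n_levels inside
    n_levels: int
    mask: np.ndarray
    spacing: float  # isotropic voxel edge, mm
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in 1..n_levels")
        if np.any(self.levels[~self.mask] != 0):
            raise ValueError("out-of-mask voxels must carry the 0 sentinel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PatientRecord:
    """All lesion volumes for one patient, as segmented by one reader.

    ``lesions`` maps (lesion_id, phase) -> LesionVolume.  ``label`` is the
    binary endpoint (1 = RAS mutant, 0 = wild type).
    """

    patient_id: str
    label: int
    reader: int
    lesions: dict[tuple[int, int], LesionVolume] = field(default_factory=dict)

    @property
    def lesion_ids(self) -> list[int]:
        return sorted({lid for lid, _ in self.lesions})

    @property
    def phases(self) -> list[int]:
        return sorted({ph for _, ph in self.lesions})

    def max_equivalent_diameter_mm(self) -> float:
        """Largest lesion's sphere-equivalent diameter (first phase masks)."""
        best = 0.0
        ph0 = min(self.phases)
        for lid in self.lesion_ids:
            vol = self.lesions[(lid, ph0)]
            v_mm3 = vol.n_voxels * vol.voxel_volume
            d = 2.0 * (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
            best = max(best, d)
        return best


def wide_to_tidy(wide: pd.DataFrame, reader: int, families: dict[str, str]) -> pd.DataFrame:
    """Melt a patients x features matrix into the tidy on-disk schema."""
    tidy = wide.reset_index(names="patient_id").melt(
        id_vars="patient_id", var_name="feature_name", value_name="value"
    )
    tidy["reader"] = reader
    tidy["family"] = tidy["feature_name"].map(families)
    return tidy[["patient_id", "reader", "feature_name", "family", "value"]]


def tidy_to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy schema back to a patients x features matrix."""
    return tidy.pivot_table(
        index="patient_id", columns="feature_name", values="value", aggfunc="first"
    ).rename_axis(columns=None)
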