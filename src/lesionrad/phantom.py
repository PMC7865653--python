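"""Synthetic multi-lesion, multi-phase, dual-reader patient cohorts.

The generator emulates the statistical structure a CE-MRI radiomics study
of liver metastases assumes, without any MR physics: each patient carries
1..k ellipsoid-like lesions with smoothly deformed boundaries, a per-phase
gray-level field inside each lesion drawn from a spatially correlated
Gaussian random field, and a binary class label (RAS mutant vs wild type).
The two classes differ only in the correlation length of the intensity
field — i.e. in gray-level co-occurrence structure — scaled by
``texture_effect``; shape parameters are drawn from identical distributions
for both classes, so morphology carries no class signal by construction.
A second reader is simulated by a random smooth dilation/erosion of each
lesion boundary.

Cohorts are reproducible: a single global seed spawns one independent
substream per patient, so enlarging the cohort never reshuffles existing
patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import LesionVolume, PatientRecord

__all__ = ["PhantomConfig", "generate_cohort", "write_cohort", "read_cohort"]

# study-conditions defaults: 76 patients, 41/76 mutant, 1-15 lesions with
# single-nodule probability 0.579, diameters 18-54 mm, nine contrast phases
@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the synthetic cohort.

    texture_effect is a dimensionless separation parameter: 0 makes the two
    classes exchangeable; the default is calibrated so that per-class means
    of GLCM-contrast-type features separate by at least two pooled SDs.
    reader_perturbation is the boundary displacement scale of the second
    reader's masks, in voxels.
    """

    n_patients: int = 76
    mutant_fraction: float = 41.0 / 76.0
    lesions_per_patient: tuple[int, int] = (1, 15)
    single_lesion_prob: float = 0.579
    diameter_mm: tuple[float, float] = (18.0, 54.0)
    voxel_spacing_mm: tuple[float, float, float] = (1.2, 1.2, 3.0)
    n_phases: int = 9
    texture_effect: float = 1.0
    reader_perturbation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must lie in [0, 1]")
        for name in ("lesions_per_patient", "diameter_mm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min exceeds max")
        if self.lesions_per_patient[0] < 1:
            raise ValueError("at least one lesion per patient")
        if self.n_phases < 1:
            raise ValueError("need at least one phase")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing components must be positive")
        if self.diameter_mm[0] < 3.0 * max(self.voxel_spacing_mm):
            raise ValueError(
                "minimum diameter under 3 voxels along the coarsest axis: "
                "texture matrices would be undefined"
            )
        if self.texture_effect < 0:
            raise ValueError("texture_effect must be >= 0")
        if self.reader_perturbation < 0:
            raise ValueError("reader_perturbation must be >= 0")


# correlated-field base parameters (voxel units / arbitrary intensity units)
_BASE_CORR_LEN = 0.7      # correlation length of the in-lesion field, voxels
_CORR_LEN_GAIN = 0.35     # relative lengthening per unit texture_effect (wild type)
_FIELD_SD = 25.0          # in-lesion texture amplitude
_BOUNDARY_AMP = 0.06      # smooth boundary deformation, fraction of radius
_PHASE_BASE = 110.0       # mean enhancement level
_PHASE_SWING = 35.0       # enhancement modulation across phases


def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _lesion_mask(rng: np.random.Generator, diameter_mm: float,
                 spacing: np.ndarray) -> np.ndarray:
    """Ellipsoid-like mask with smooth random boundary deformation."""
    ratios = np.exp(rng.normal(0.0, 0.15, size=3))
    ratios /= ratios.prod() ** (1.0 / 3.0)  # keep the equivalent diameter
    semi = 0.5 * diameter_mm * ratios
    shape = np.ceil(2.0 * semi / spacing).astype(int) + 6
    grids = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    xx, yy, zz = np.meshgrid(*grids, indexing="ij")
    e = np.sqrt((xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2)
    pert = _smooth_unit_field(rng, tuple(shape), sigma=2.0)
    pert -= pert.mean()
    mask = e <= 1.0 + _BOUNDARY_AMP * pert
    # keep the equivalent diameter within the configured bracket
    v_mm3 = mask.sum() * spacing.prod()
    d_eq = 2.0 * (3.0 * v_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    if not (0.9 * diameter_mm <= d_eq <= 1.1 * diameter_mm):
        mask = e <= 1.0
    return mask


def _reader2_mask(rng: np.random.Generator, mask: np.ndarray,
                  scale_vox: float) -> np.ndarray:
    """Smooth random dilation/erosion of the boundary at ``scale_vox``."""
    if scale_vox == 0:
        return mask.copy()
    signed = ndimage.distance_transform_edt(mask) - ndimage.distance_transform_edt(
        ~mask
    )
    u = _smooth_unit_field(rng, mask.shape, sigma=3.0)
    out = (signed + scale_vox * u) > 0
    return out if out.any() else mask.copy()


def _draw_n_lesions(rng: np.random.Generator, cfg: PhantomConfig) -> int:
    """Lesion count: the minimum with probability single_lesion_prob, else a
    truncated-geometric draw over (min, max] so multi-lesion patients carry
    a few lesions typically and many only rarely."""
    lo, hi = cfg.lesions_per_patient
    if lo == hi:
        return lo
    if rng.random() < cfg.single_lesion_prob:
        return lo
    support = np.arange(lo + 1, hi + 1)
    weights = 0.4 ** (support - (lo + 1))
    return int(rng.choice(support, p=weights / weights.sum()))


def generate_cohort(config: PhantomConfig) -> list[PatientRecord]:
    """Generate the synthetic cohort; two PatientRecords (readers) per patient.

    Returns a flat list ordered by patient then reader; both readers share
    the same images and differ only in their masks.
    """
    spacing = np.asarray(config.voxel_spacing_mm, dtype=float)
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records: list[PatientRecord] = []
    for p_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        label = int(rng.random() < config.mutant_fraction)
        n_lesions = _draw_n_lesions(rng, config)
        # wild-type lesions get a longer correlation length (smoother field,
        # lower co-occurrence contrast); mutants keep the base length
        corr_len = _BASE_CORR_LEN * (
            1.0 + _CORR_LEN_GAIN * config.texture_effect * (1 - label)
        )
        rec1 = PatientRecord(patient_id=f"P{p_idx:03d}", label=label, reader=1)
        rec2 = PatientRecord(patient_id=f"P{p_idx:03d}", label=label, reader=2)
        for lid in range(n_lesions):
            dmin, dmax = config.diameter_mm
            pad = min(1.0, 0.25 * (dmax - dmin))
            diameter = rng.uniform(dmin + pad, dmax - pad)
            mask = _lesion_mask(rng, diameter, spacing)
            mask2 = _reader2_mask(rng, mask, config.reader_perturbation)
            for ph in range(config.n_phases):
                base = _PHASE_BASE + _PHASE_SWING * np.sin(
                    np.pi * (ph + 1) / (config.n_phases + 1)
                ) + rng.normal(0.0, 4.0)
                texture = _smooth_unit_field(rng, mask.shape, corr_len) * _FIELD_SD
                background = 55.0 + rng.normal(0.0, 5.0, size=mask.shape)
                image = np.where(mask, base + texture, background)
                vol = LesionVolume(image=image, mask=mask, spacing=tuple(spacing))
                rec1.lesions[(lid, ph)] = vol
                rec2.lesions[(lid, ph)] = LesionVolume(
                    image=image.copy(), mask=mask2, spacing=tuple(spacing)
                )
        records.append(rec1)
        records.append(rec2)
    return records


# ---------------------------------------------------------------------------
# on-disk round trip: NIfTI volumes + manifest CSV
# ---------------------------------------------------------------------------

def write_cohort(records: list[PatientRecord], outdir: str | Path) -> Path:
    """Write one NIfTI per (patient, lesion, phase, reader) plus a manifest.

    The manifest CSV columns are patient_id, label, lesion_id, phase,
    reader, image_path, mask_path; the affine encodes the voxel spacing.
    Returns the manifest path.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for (lid, ph), vol in sorted(rec.lesions.items()):
            stem = f"{rec.patient_id}_les{lid}_ph{ph}_r{rec.reader}"
            affine = np.diag([*vol.spacing, 1.0])
            img_path = outdir / f"{stem}_img.nii"
            msk_path = outdir / f"{stem}_msk.nii"
            nib.save(nib.Nifti1Image(vol.image.astype(np.float32), affine), img_path)
            nib.save(
                nib.Nifti1Image(vol.mask.astype(np.uint8), affine), msk_path
            )
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    label=rec.label,
                    lesion_id=lid,
                    phase=ph,
                    reader=rec.reader,
                    image_path=img_path.name,
                    mask_path=msk_path.name,
                )
            )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[PatientRecord]:
    """Load a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records: dict[tuple[str, int], PatientRecord] = {}
    for row in df.itertuples():
        key = (row.patient_id, int(row.reader))
        if key not in records:
            records[key] = PatientRecord(
                patient_id=row.patient_id, label=int(row.label), reader=int(row.reader)
            )
        img = nib.load(base / row.image_path)
        msk = nib.load(base / row.mask_path)
        spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
        records[key].lesions[(int(row.lesion_id), int(row.phase))] = LesionVolume(
            image=np.asarray(img.dataobj, dtype=float),
            mask=np.asarray(msk.dataobj) > 0,
            spacing=spacing,
        )
    return [records[k] for k in sorted(records)]
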