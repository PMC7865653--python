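"""Cohort-level feature extraction.

Runs preprocessing + texture + morphology on every lesion volume of every
patient and aggregates to one row per patient by the nested-median rule
(median over phases within each lesion, then median over lesions).
Morphology depends only on the mask, which is constant across phases for a
given lesion and reader, so it is computed once per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .morphology import MORPHOLOGY_FEATURES, morphology_features
from .preprocess import prepare_lesion
from .texture import FEATURE_FAMILIES, aggregate_patient, all_texture_features
from .types import DegenerateLesionError, PatientRecord

__all__ = ["ExtractionConfig", "extract_patient", "extract_cohort", "family_map"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Preprocessing and feature settings applied to every lesion."""

    target_mm: float | None = None  # None: finest native spacing
    wavelet_weight: float = 1.0
    quantize_scheme: Literal["fixed-bin-number", "equal-probability"] = "fixed-bin-number"
    n_levels: int = 32
    entropy_log_base: float | None = None  # natural log
    surface_method: Literal["mesh", "faces"] = "mesh"
    include_morphology: bool = True


def extract_patient(record: PatientRecord, config: ExtractionConfig = ExtractionConfig()) -> pd.Series:
    """One patient's aggregated feature vector (63 features by default)."""
    rows = []
    morph_cache: dict[int, dict[str, float]] = {}
    for (lid, ph), vol in sorted(record.lesions.items()):
        disc = prepare_lesion(
            vol,
            target_mm=config.target_mm,
            wavelet_weight=config.wavelet_weight,
            scheme=config.quantize_scheme,
            n_levels=config.n_levels,
        )
        feats = all_texture_features(vol, disc, config.entropy_log_base)
        if config.include_morphology:
            if lid not in morph_cache:
                morph_cache[lid] = morphology_features(
                    vol.mask, vol.spacing, surface_method=config.surface_method
                )
            feats.update(morph_cache[lid])
        feats["lesion_id"] = lid
        feats["phase"] = ph
        rows.append(feats)
    if not rows:
        raise DegenerateLesionError(f"patient {record.patient_id} has no lesions")
    df = pd.DataFrame(rows)
    agg = aggregate_patient(df)
    agg.name = record.patient_id
    return agg


def extract_cohort(
    records: list[PatientRecord],
    config: ExtractionConfig = ExtractionConfig(),
    reader: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Patients x features matrix and the aligned label vector.

    ``reader`` restricts extraction to one reader's segmentations; with
    ``None`` all records are used (caller must then disambiguate ids).
    """
    rows, labels = [], {}
    for rec in records:
        if reader is not None and rec.reader != reader:
            continue
        rows.append(extract_patient(rec, config))
        labels[rec.patient_id] = rec.label
    wide = pd.DataFrame(rows)
    y = pd.Series(labels, name="label").loc[wide.index]
    return wide, y


def family_map() -> dict[str, str]:
    """feature name -> family, across texture and morphology."""
    fam = dict(FEATURE_FAMILIES)
    fam.update({name: "morphology" for name in MORPHOLOGY_FEATURES})
    return fam
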