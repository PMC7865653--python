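"""3D texture matrices and the 48-feature texture set.

Matrices follow the merged-direction 3D convention of the classical
radiomics toolboxes: co-occurrences and runs are accumulated over the 13
unique distance-1 directions of the 3D neighborhood (each counted with its
opposite), zones use 26-connectivity, and the neighborhood gray-tone
difference uses the 26-neighborhood with incomplete neighborhoods at the
mask edge falling back to the neighbors that exist.

The feature set is 48 scalars: 9 first-order statistics on the continuous
in-mask intensities plus 39 matrix features (8 GLCM, 13 GLRLM, 13 GLSZM,
5 NGTDM).  Features undefined on degenerate lesions (e.g. correlation of a
constant lesion) propagate as NaN, never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import DegenerateLesionError, DiscretizedLesion, LesionVolume

__all__ = [
    "DIRECTIONS_3D",
    "TextureMatrices",
    "build_matrices",
    "first_order",
    "texture_features",
    "all_texture_features",
    "aggregate_patient",
    "FEATURE_FAMILIES",
]

# The 13 unique direction vectors of the 26-neighborhood (one per +/- pair),
# ordered with the first nonzero component positive.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass
class TextureMatrices:
    """Texture matrices for one discretized lesion.

    glcm : (Ng, Ng) symmetric co-occurrence probabilities, summing to 1,
        merged over the 13 directions at distance 1.
    glrlm : (Ng, Rmax) run counts by gray level and run length, merged over
        the 13 directions.
    glszm : (Ng, Zmax) zone counts by gray level and zone size
        (26-connected zones).
    ngtdm_s : (Ng,) per-level sums of absolute differences from the
        neighborhood mean; ngtdm_n : (Ng,) per-level voxel counts entering
        those sums.
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_s: np.ndarray
    ngtdm_n: np.ndarray
    n_levels: int
    n_voxels: int
    n_directions: int = len(DIRECTIONS_3D)
    provenance: dict = field(default_factory=dict)


def _glcm(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in directions:
        sl_a = tuple(
            slice(max(c, 0), s + min(c, 0)) for c, s in zip(d, levels.shape)
        )
        sl_b = tuple(
            slice(max(-c, 0), s + min(-c, 0)) for c, s in zip(d, levels.shape)
        )
        a = levels[sl_b].ravel()
        b = levels[sl_a].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        pair = (a[ok] - 1) * ng + (b[ok] - 1)
        counts += np.bincount(pair, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T  # count each offset with its opposite
    total = counts.sum()
    if total == 0:
        raise DegenerateLesionError("no valid voxel pairs: lesion too small for GLCM")
    return counts / total


def _runs_one_direction(levels: np.ndarray, d: tuple[int, int, int]):
    """Gray level and length of every run along direction ``d``.

    Lines of the volume parallel to ``d`` are linearized by a lexicographic
    sort on (line identity, position along line) and run-length encoded in
    one vectorized pass; the 0 sentinel (out-of-mask) breaks runs and its
    own runs are discarded.
    """
    arr = levels
    for ax, c in enumerate(d):
        if c < 0:
            arr = np.flip(arr, axis=ax)
    step = tuple(abs(c) for c in d)
    idx = np.indices(arr.shape).reshape(3, -1)
    moving = [ax for ax in range(3) if step[ax] == 1]
    fixed = [ax for ax in range(3) if step[ax] == 0]
    t = idx[moving[0]]
    keys = [idx[ax] for ax in fixed] + [idx[ax] - t for ax in moving[1:]]
    order = np.lexsort(tuple([t] + keys))
    flat = arr.reshape(-1)[order]
    newline = np.zeros(flat.size, dtype=bool)
    newline[0] = True
    if keys:
        kmat = np.stack(keys)[:, order]
        newline[1:] = np.any(kmat[:, 1:] != kmat[:, :-1], axis=0)
    breaks = newline.copy()
    breaks[1:] |= flat[1:] != flat[:-1]
    starts = np.flatnonzero(breaks)
    lengths = np.diff(np.append(starts, flat.size))
    vals = flat[starts]
    keep = vals > 0
    return vals[keep], lengths[keep]


def _glrlm(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    max_len = max(levels.shape) + 1
    counts = np.zeros((ng, max_len), dtype=np.int64)
    for d in directions:
        vals, lens = _runs_one_direction(levels, d)
        np.add.at(counts, (vals - 1, lens - 1), 1)
    used = np.flatnonzero(counts.sum(axis=0))
    rmax = used.max() + 1 if used.size else 1
    return counts[:, :rmax]


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    zmax = 1
    for lvl in range(1, ng + 1):
        blob = levels == lvl
        if not blob.any():
            continue
        lab, nlab = ndimage.label(blob, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append((lvl, sizes))
        zmax = max(zmax, int(sizes.max()))
    counts = np.zeros((ng, zmax), dtype=np.int64)
    for lvl, sizes in sizes_by_level:
        np.add.at(counts, (lvl - 1, sizes - 1), 1)
    return counts


def _ngtdm(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    mask = levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nbr_count = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    nbr_sum = ndimage.convolve(levels.astype(float) * mask, kernel, mode="constant")
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    valid = mask & (nbr_count > 0.5)
    mean_nbr = np.zeros_like(nbr_sum)
    mean_nbr[valid] = nbr_sum[valid] / nbr_count[valid]
    diffs = np.abs(levels[valid] - mean_nbr[valid])
    lv = levels[valid] - 1
    np.add.at(s, lv, diffs)
    np.add.at(n, lv, 1)
    return s, n


def build_matrices(
    lesion: DiscretizedLesion,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D,
) -> TextureMatrices:
    """Compute GLCM, GLRLM, GLSZM and NGTDM for a discretized lesion.

    ``directions`` defaults to the full 13-direction 3D set; a restricted
    set (e.g. the two in-plane axes) is mainly useful for hand-checkable
    constructions.
    """
    if not lesion.mask.any():
        raise DegenerateLesionError("empty mask")
    if lesion.n_voxels < 2:
        raise DegenerateLesionError("single-voxel lesion: co-occurrences undefined")
    ng = lesion.n_levels
    glcm = _glcm(lesion.levels, ng, directions)
    glrlm = _glrlm(lesion.levels, ng, directions)
    glszm = _glszm(lesion.levels, ng)
    s, n = _ngtdm(lesion.levels, ng)
    return TextureMatrices(
        glcm=glcm,
        glrlm=glrlm,
        glszm=glszm,
        ngtdm_s=s,
        ngtdm_n=n,
        n_levels=ng,
        n_voxels=lesion.n_voxels,
        n_directions=len(directions),
        provenance=dict(lesion.provenance),
    )


# ---------------------------------------------------------------------------
# first-order statistics (continuous, pre-quantization intensities)
# ---------------------------------------------------------------------------

def first_order(lesion: LesionVolume) -> dict[str, float]:
    """Nine first-order statistics over the in-mask intensities.

    Conventions: mode is the most frequent exact value (smallest on ties, as
    in the common numeric packages; mainly meaningful on integer-valued
    data); MAD is the median absolute deviation from the median; IQR uses
    linearly interpolated quantiles; kurtosis is the plain fourth
    standardized moment (3 for a normal); skewness/kurtosis of a constant
    lesion are undefined and reported as NaN.
    """
    if not lesion.mask.any():
        raise DegenerateLesionError("empty mask")
    x = lesion.values()
    med = float(np.median(x))
    constant = x.max() == x.min()
    return {
        "fo_mean": float(np.mean(x)),
        "fo_mode": float(stats.mode(x, keepdims=False).mode),
        "fo_median": med,
        "fo_std": float(np.std(x)),
        "fo_mad": float(np.median(np.abs(x - med))),
        "fo_range": float(x.max() - x.min()),
        "fo_kurtosis": float("nan") if constant else float(stats.kurtosis(x, fisher=False)),
        "fo_skewness": float("nan") if constant else float(stats.skew(x)),
        "fo_iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }


# ---------------------------------------------------------------------------
# matrix features
# ---------------------------------------------------------------------------

def _glcm_features(p: np.ndarray, log_base: float | None) -> dict[str, float]:
    ng = p.shape[0]
    i, j = np.indices((ng, ng)) + 1
    mu = float((p * i).sum())  # symmetric: row mean == column mean
    var = float((p * (i - mu) ** 2).sum())
    nz = p[p > 0]
    logs = np.log(nz) if log_base is None else np.log(nz) / math.log(log_base)
    # Haralick sum average over the diagonal-sum marginal
    k = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(i + j) == kk].sum() for kk in k])
    corr = float("nan")
    if var > 0:
        corr = float((p * (i - mu) * (j - mu)).sum() / var)
    return {
        "glcm_energy": float((p**2).sum()),
        "glcm_contrast": float((p * (i - j) ** 2).sum()),
        "glcm_correlation": corr,
        "glcm_homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "glcm_variance": var,
        "glcm_sum_average": float((k * p_sum).sum()),
        "glcm_entropy": float(-(nz * logs).sum()),
        "glcm_dissimilarity": float((p * np.abs(i - j)).sum()),
    }


def _rl_features(counts: np.ndarray, n_voxels: int, n_dirs: int,
                 prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone feature algebra.

    ``counts[i-1, j-1]`` holds runs (zones) of gray level i and length
    (size) j.  ``prefix`` is 'glrlm' or 'glszm' and picks the field names.
    """
    nr = counts.sum()
    if nr == 0:
        raise DegenerateLesionError("empty run/zone matrix")
    ng, jmax = counts.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, jmax + 1)[None, :].astype(float)
    p = counts / nr
    gl_marg = counts.sum(axis=1).astype(float)  # per gray level
    len_marg = counts.sum(axis=0).astype(float)  # per run length / zone size
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    if prefix == "glrlm":
        names = dict(se="sre", le="lre", ln="rln", pct="rp", sv="rlv")
        denom_pct = n_voxels * n_dirs
    else:
        names = dict(se="sze", le="lze", ln="zsn", pct="zp", sv="zsv")
        denom_pct = n_voxels
    return {
        f"{prefix}_{names['se']}": float((counts / j**2).sum() / nr),
        f"{prefix}_{names['le']}": float((counts * j**2).sum() / nr),
        f"{prefix}_gln": float((gl_marg**2).sum() / nr),
        f"{prefix}_{names['ln']}": float((len_marg**2).sum() / nr),
        f"{prefix}_{names['pct']}": float(nr / denom_pct),
        f"{prefix}_lgre" if prefix == "glrlm" else f"{prefix}_lgze": float(
            (counts / i**2).sum() / nr
        ),
        f"{prefix}_hgre" if prefix == "glrlm" else f"{prefix}_hgze": float(
            (counts * i**2).sum() / nr
        ),
        f"{prefix}_srlge" if prefix == "glrlm" else f"{prefix}_szlge": float(
            (counts / (i**2 * j**2)).sum() / nr
        ),
        f"{prefix}_srhge" if prefix == "glrlm" else f"{prefix}_szhge": float(
            (counts * i**2 / j**2).sum() / nr
        ),
        f"{prefix}_lrlge" if prefix == "glrlm" else f"{prefix}_lzlge": float(
            (counts * j**2 / i**2).sum() / nr
        ),
        f"{prefix}_lrhge" if prefix == "glrlm" else f"{prefix}_lzhge": float(
            (counts * i**2 * j**2).sum() / nr
        ),
        f"{prefix}_glv": float((p * (i - mu_i) ** 2).sum()),
        f"{prefix}_{names['sv']}": float((p * (j - mu_j) ** 2).sum()),
    }


def _ngtdm_features(s: np.ndarray, n: np.ndarray) -> dict[str, float]:
    nvn = n.sum()
    if nvn == 0:
        raise DegenerateLesionError("empty NGTDM")
    p = n / nvn
    levels = np.arange(1, len(s) + 1, dtype=float)
    active = p > 0
    i_act = levels[active]
    p_act = p[active]
    s_act = s[active]
    ngp = int(active.sum())
    dot_ps = float((p_act * s_act).sum())
    coarseness = float("nan") if dot_ps == 0 else 1.0 / dot_ps
    if ngp < 2:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    else:
        di = i_act[:, None] - i_act[None, :]
        pp = p_act[:, None] * p_act[None, :]
        contrast = float(
            (pp * di**2).sum() / (ngp * (ngp - 1)) * (s_act.sum() / nvn)
        )
        denom_busy = float(
            np.abs(i_act[:, None] * p_act[:, None] - i_act[None, :] * p_act[None, :]).sum()
        )
        busyness = 0.0 if denom_busy == 0 else dot_ps / denom_busy
        ps = p_act * s_act
        psum = p_act[:, None] + p_act[None, :]
        complexity = float(
            (np.abs(di) * (ps[:, None] + ps[None, :]) / psum).sum() / nvn
        )
        s_total = float(s_act.sum())
        strength = 0.0 if s_total == 0 else float((psum * di**2).sum() / s_total)
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def texture_features(
    matrices: TextureMatrices, entropy_log_base: float | None = None
) -> dict[str, float]:
    """The 39 matrix-derived texture features.

    ``entropy_log_base=None`` uses the natural logarithm for GLCM entropy
    (the historical toolbox convention); pass 2 for bits.
    """
    out: dict[str, float] = {}
    out.update(_glcm_features(matrices.glcm, entropy_log_base))
    out.update(
        _rl_features(matrices.glrlm, matrices.n_voxels, matrices.n_directions, "glrlm")
    )
    out.update(_rl_features(matrices.glszm, matrices.n_voxels, 1, "glszm"))
    out.update(_ngtdm_features(matrices.ngtdm_s, matrices.ngtdm_n))
    return out


def all_texture_features(
    raw: LesionVolume,
    discretized: DiscretizedLesion,
    entropy_log_base: float | None = None,
) -> dict[str, float]:
    """All 48 texture features: first-order on ``raw`` + matrix features."""
    out = first_order(raw)
    out.update(texture_features(build_matrices(discretized), entropy_log_base))
    return out


def aggregate_patient(
    per_lesion_phase: pd.DataFrame,
    lesion_col: str = "lesion_id",
    phase_col: str = "phase",
) -> pd.Series:
    """Patient-level feature vector: median over phases, then over lesions.

    ``per_lesion_phase`` has one row per (lesion, phase) and one column per
    feature (plus the two id columns).  A single lesion/phase passes through
    unchanged.
    """
    feature_cols = [c for c in per_lesion_phase.columns if c not in (lesion_col, phase_col)]
    per_lesion = per_lesion_phase.groupby(lesion_col)[feature_cols].median()
    return per_lesion.median()


def _family_of(name: str) -> str:
    return {
        "fo": "first_order",
        "glcm": "glcm",
        "glrlm": "glrlm",
        "glszm": "glszm",
        "ngtdm": "ngtdm",
    }[name.split("_", 1)[0]]


def feature_families(names: Iterable[str]) -> dict[str, str]:
    """Map texture feature names to their family label."""
    return {n: _family_of(n) for n in names}


FEATURE_FAMILIES = feature_families(
    [
        *[f"fo_{s}" for s in ("mean", "mode", "median", "std", "mad", "range",
                              "kurtosis", "skewness", "iqr")],
        *[f"glcm_{s}" for s in ("energy", "contrast", "correlation", "homogeneity",
                                 "variance", "sum_average", "entropy", "dissimilarity")],
        *[f"glrlm_{s}" for s in ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre",
                                  "srlge", "srhge", "lrlge", "lrhge", "glv", "rlv")],
        *[f"glszm_{s}" for s in ("sze", "lze", "gln", "zsn", "zp", "lgze", "hgze",
                                  "szlge", "szhge", "lzlge", "lzhge", "glv", "zsv")],
        *[f"ngtdm_{s}" for s in ("coarseness", "contrast", "busyness", "complexity",
                                  "strength")],
    ]
)
assert len(FEATURE_FAMILIES) == 48
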