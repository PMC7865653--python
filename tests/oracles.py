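"""Independent brute-force reference implementations for the test suite.

Everything here is written as plain double/triple loops over voxels and
matrix entries, deliberately sharing no code path with the package: these
are the oracles the vectorized implementations are checked against.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, x, y, z):
    return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]


def glcm_brute(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    """Co-occurrence probabilities by voxel-pair enumeration (both senses)."""
    counts = np.zeros((ng, ng))
    sh = levels.shape
    for x in range(sh[0]):
        for y in range(sh[1]):
            for z in range(sh[2]):
                i = levels[x, y, z]
                if i == 0:
                    continue
                for d in directions:
                    for sign in (1, -1):
                        nx, ny, nz = x + sign * d[0], y + sign * d[1], z + sign * d[2]
                        if not _in(sh, nx, ny, nz):
                            continue
                        j = levels[nx, ny, nz]
                        if j == 0:
                            continue
                        counts[i - 1, j - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glrlm_brute(levels: np.ndarray, ng: int, directions) -> np.ndarray:
    """Run counts by walking every maximal run from its start voxel."""
    sh = levels.shape
    runs = []
    for d in directions:
        for x in range(sh[0]):
            for y in range(sh[1]):
                for z in range(sh[2]):
                    lvl = levels[x, y, z]
                    if lvl == 0:
                        continue
                    px, py, pz = x - d[0], y - d[1], z - d[2]
                    if _in(sh, px, py, pz) and levels[px, py, pz] == lvl:
                        continue  # not a run start
                    length = 1
                    nx, ny, nz = x + d[0], y + d[1], z + d[2]
                    while _in(sh, nx, ny, nz) and levels[nx, ny, nz] == lvl:
                        length += 1
                        nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
                    runs.append((lvl, length))
    rmax = max(l for _, l in runs)
    out = np.zeros((ng, rmax), dtype=np.int64)
    for lvl, length in runs:
        out[lvl - 1, length - 1] += 1
    return out


def glszm_brute(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts by flood fill with 26-connectivity."""
    sh = levels.shape
    seen = np.zeros(sh, dtype=bool)
    zones = []
    for x in range(sh[0]):
        for y in range(sh[1]):
            for z in range(sh[2]):
                lvl = levels[x, y, z]
                if lvl == 0 or seen[x, y, z]:
                    continue
                size = 0
                q = deque([(x, y, z)])
                seen[x, y, z] = True
                while q:
                    cx, cy, cz = q.popleft()
                    size += 1
                    for dx, dy, dz in ALL_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            _in(sh, nx, ny, nz)
                            and not seen[nx, ny, nz]
                            and levels[nx, ny, nz] == lvl
                        ):
                            seen[nx, ny, nz] = True
                            q.append((nx, ny, nz))
                zones.append((lvl, size))
    zmax = max(s for _, s in zones)
    out = np.zeros((ng, zmax), dtype=np.int64)
    for lvl, size in zones:
        out[lvl - 1, size - 1] += 1
    return out


def ngtdm_brute(levels: np.ndarray, ng: int):
    """Per-level difference sums and counts by explicit neighbor averaging."""
    sh = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng, dtype=np.int64)
    for x in range(sh[0]):
        for y in range(sh[1]):
            for z in range(sh[2]):
                lvl = levels[x, y, z]
                if lvl == 0:
                    continue
                nbrs = []
                for dx, dy, dz in ALL_26:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if _in(sh, nx, ny, nz) and levels[nx, ny, nz] > 0:
                        nbrs.append(levels[nx, ny, nz])
                if not nbrs:
                    continue
                s[lvl - 1] += abs(lvl - sum(nbrs) / len(nbrs))
                n[lvl - 1] += 1
    return s, n


# ---------------------------------------------------------------------------
# feature formulas as naive loops
# ---------------------------------------------------------------------------

def glcm_features_brute(p: np.ndarray) -> dict:
    ng = p.shape[0]
    mu = sum(p[i, j] * (i + 1) for i in range(ng) for j in range(ng))
    var = sum(p[i, j] * (i + 1 - mu) ** 2 for i in range(ng) for j in range(ng))
    out = {
        "glcm_energy": sum(p[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "glcm_contrast": sum(
            p[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
        ),
        "glcm_homogeneity": sum(
            p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        ),
        "glcm_variance": var,
        "glcm_entropy": -sum(
            p[i, j] * math.log(p[i, j])
            for i in range(ng)
            for j in range(ng)
            if p[i, j] > 0
        ),
        "glcm_dissimilarity": sum(
            p[i, j] * abs(i - j) for i in range(ng) for j in range(ng)
        ),
        "glcm_sum_average": sum(
            (i + j + 2) * p[i, j] for i in range(ng) for j in range(ng)
        ),
    }
    if var > 0:
        out["glcm_correlation"] = (
            sum(
                p[i, j] * (i + 1 - mu) * (j + 1 - mu)
                for i in range(ng)
                for j in range(ng)
            )
            / var
        )
    return out


def rl_features_brute(counts: np.ndarray, n_voxels: int, n_dirs: int, prefix: str) -> dict:
    ng, jm = counts.shape
    nr = counts.sum()
    p = counts / nr

    def tot(f):
        return sum(
            counts[i, j] * f(i + 1, j + 1) for i in range(ng) for j in range(jm)
        ) / nr

    mu_i = sum(p[i, j] * (i + 1) for i in range(ng) for j in range(jm))
    mu_j = sum(p[i, j] * (j + 1) for i in range(ng) for j in range(jm))
    gl = [counts[i, :].sum() for i in range(ng)]
    ln = [counts[:, j].sum() for j in range(jm)]
    if prefix == "glrlm":
        k = dict(se="sre", le="lre", ln="rln", pct="rp", sv="rlv",
                 lg="lgre", hg="hgre", slg="srlge", shg="srhge",
                 llg="lrlge", lhg="lrhge")
        denom = n_voxels * n_dirs
    else:
        k = dict(se="sze", le="lze", ln="zsn", pct="zp", sv="zsv",
                 lg="lgze", hg="hgze", slg="szlge", shg="szhge",
                 llg="lzlge", lhg="lzhge")
        denom = n_voxels
    return {
        f"{prefix}_{k['se']}": tot(lambda i, j: 1 / j**2),
        f"{prefix}_{k['le']}": tot(lambda i, j: j**2),
        f"{prefix}_gln": sum(g**2 for g in gl) / nr,
        f"{prefix}_{k['ln']}": sum(l**2 for l in ln) / nr,
        f"{prefix}_{k['pct']}": nr / denom,
        f"{prefix}_{k['lg']}": tot(lambda i, j: 1 / i**2),
        f"{prefix}_{k['hg']}": tot(lambda i, j: i**2),
        f"{prefix}_{k['slg']}": tot(lambda i, j: 1 / (i**2 * j**2)),
        f"{prefix}_{k['shg']}": tot(lambda i, j: i**2 / j**2),
        f"{prefix}_{k['llg']}": tot(lambda i, j: j**2 / i**2),
        f"{prefix}_{k['lhg']}": tot(lambda i, j: i**2 * j**2),
        f"{prefix}_glv": tot(lambda i, j: (i - mu_i) ** 2),
        f"{prefix}_{k['sv']}": tot(lambda i, j: (j - mu_j) ** 2),
    }


def ngtdm_features_brute(s: np.ndarray, n: np.ndarray) -> dict:
    nvn = n.sum()
    ng = len(s)
    p = n / nvn
    act = [i for i in range(ng) if p[i] > 0]
    dot = sum(p[i] * s[i] for i in act)
    out = {"ngtdm_coarseness": (1.0 / dot) if dot > 0 else float("nan")}
    if len(act) < 2:
        out.update(
            ngtdm_contrast=0.0, ngtdm_busyness=0.0,
            ngtdm_complexity=0.0, ngtdm_strength=0.0,
        )
        return out
    ngp = len(act)
    out["ngtdm_contrast"] = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in act for j in act)
        / (ngp * (ngp - 1))
        * (sum(s[i] for i in act) / nvn)
    )
    denom_busy = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in act for j in act
    )
    out["ngtdm_busyness"] = dot / denom_busy if denom_busy else 0.0
    out["ngtdm_complexity"] = (
        sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in act
            for j in act
        )
        / nvn
    )
    stot = sum(s[i] for i in act)
    out["ngtdm_strength"] = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in act for j in act) / stot
        if stot
        else 0.0
    )
    return out


def wilcoxon_exact_brute(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    n_a = len(a)
    # midranks
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    def u_of(idx):
        return sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2.0
    center = n_a * len(b) / 2.0
    dev = abs(u_of(range(n_a)) - center)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_of(comb) - center) >= dev - 1e-12:
            hits += 1
    return hits / total


def youden_brute(values, labels):
    """Best (J, specificity) threshold scan, positives called at >= t."""
    best = None
    for t in sorted(set(values)):
        tp = sum(1 for v, y in zip(values, labels) if y == 1 and v >= t)
        fn = sum(1 for v, y in zip(values, labels) if y == 1 and v < t)
        tn = sum(1 for v, y in zip(values, labels) if y == 0 and v < t)
        fp = sum(1 for v, y in zip(values, labels) if y == 0 and v >= t)
        sen = tp / (tp + fn)
        spec = tn / (tn + fp)
        if best is None or (sen + spec - 1, spec) > best[:2]:
            best = (sen + spec - 1, spec, t)
    return best
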