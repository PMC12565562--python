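"""Brute-force reference implementations of the texture matrices/features.

Everything here is written as direct enumeration (python loops, BFS) with
no shared code with the package, so it can serve as an independent oracle
for the vectorized implementations on small grids.
"""

from __future__ import annotations

import math
from collections import Counter, deque

import numpy as np


def glcm_counts(levels, mask, n_levels, directions):
    counts = np.zeros((n_levels, n_levels), dtype=float)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in directions:
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]):
                        continue
                    if not mask[u, v, w]:
                        continue
                    i, j = levels[x, y, z] - 1, levels[u, v, w] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts


def glcm_features(levels, mask, n_levels, directions):
    counts = glcm_counts(levels, mask, n_levels, directions)
    p = counts / counts.sum()
    homog = energy = contrast = entropy = dissim = 0.0
    mu = sig = 0.0
    pi = p.sum(axis=1)
    for i in range(n_levels):
        mu += (i + 1) * pi[i]
    for i in range(n_levels):
        sig += (i + 1 - mu) ** 2 * pi[i]
    sig = math.sqrt(sig)
    corr = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            if p[i, j] == 0:
                continue
            homog += p[i, j] / (1 + abs(i - j))
            energy += p[i, j] ** 2
            contrast += (i - j) ** 2 * p[i, j]
            entropy -= p[i, j] * math.log2(p[i, j])
            dissim += abs(i - j) * p[i, j]
            if sig > 0:
                corr += (i + 1 - mu) * (j + 1 - mu) * p[i, j] / (sig * sig)
    return {
        "GLCM_Homogeneity": homog,
        "GLCM_Energy": energy,
        "GLCM_Contrast": contrast,
        "GLCM_Correlation": corr,
        "GLCM_Entropy": entropy,
        "GLCM_Dissimilarity": dissim,
    }


def enumerate_runs(levels, mask, direction):
    """All maximal in-mask equal-level runs along one direction, as (level, length)."""
    shape = levels.shape
    dx, dy, dz = direction

    def inside(x, y, z):
        return 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]

    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                px, py, pz = x - dx, y - dy, z - dz
                if (
                    inside(px, py, pz)
                    and mask[px, py, pz]
                    and levels[px, py, pz] == levels[x, y, z]
                ):
                    continue  # not a run start
                length = 1
                cx, cy, cz = x + dx, y + dy, z + dz
                while (
                    inside(cx, cy, cz)
                    and mask[cx, cy, cz]
                    and levels[cx, cy, cz] == levels[x, y, z]
                ):
                    length += 1
                    cx, cy, cz = cx + dx, cy + dy, cz + dz
                runs.append((int(levels[x, y, z]), length))
    return runs


def glrlm_counts(levels, mask, n_levels, directions):
    max_len = max(levels.shape)
    counts = np.zeros((n_levels, max_len), dtype=float)
    for d in directions:
        for lev, length in enumerate_runs(levels, mask, d):
            counts[lev - 1, length - 1] += 1
    return counts


def rl_features(counts, n_voxels, n_directions):
    nr = counts.sum()
    feats = Counter()
    for i0 in range(counts.shape[0]):
        for j0 in range(counts.shape[1]):
            r = counts[i0, j0]
            if r == 0:
                continue
            i, j = i0 + 1, j0 + 1
            feats["SRE"] += r / j**2
            feats["LRE"] += r * j**2
            feats["LGRE"] += r / i**2
            feats["HGRE"] += r * i**2
            feats["SRLGE"] += r / (i**2 * j**2)
            feats["SRHGE"] += r * i**2 / j**2
            feats["LRLGE"] += r * j**2 / i**2
            feats["LRHGE"] += r * i**2 * j**2
    out = {f"GLRLM_{k}": v / nr for k, v in feats.items()}
    out["GLRLM_GLNU"] = sum(row.sum() ** 2 for row in counts) / nr
    out["GLRLM_RLNU"] = sum(counts[:, j].sum() ** 2 for j in range(counts.shape[1])) / nr
    out["GLRLM_RP"] = nr / (n_directions * n_voxels)
    for name in ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE"):
        out.setdefault(f"GLRLM_{name}", 0.0)
    return out


def enumerate_zones(levels, mask):
    """26-connected equal-level in-mask components via BFS, as (level, size)."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or seen[x, y, z]:
                    continue
                lev = levels[x, y, z]
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in offsets:
                        u, v, w = cx + dx, cy + dy, cz + dz
                        if not (
                            0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]
                        ):
                            continue
                        if seen[u, v, w] or not mask[u, v, w] or levels[u, v, w] != lev:
                            continue
                        seen[u, v, w] = True
                        queue.append((u, v, w))
                zones.append((int(lev), size))
    return zones


def glzlm_counts(levels, mask, n_levels):
    nv = int(mask.sum())
    counts = np.zeros((n_levels, nv), dtype=float)
    for lev, size in enumerate_zones(levels, mask):
        counts[lev - 1, size - 1] += 1
    return counts


def zone_features(counts, n_voxels):
    nz = counts.sum()
    feats = Counter()
    for i0 in range(counts.shape[0]):
        for s0 in range(counts.shape[1]):
            zc = counts[i0, s0]
            if zc == 0:
                continue
            i, s = i0 + 1, s0 + 1
            feats["SZE"] += zc / s**2
            feats["LZE"] += zc * s**2
            feats["LGZE"] += zc / i**2
            feats["HGZE"] += zc * i**2
            feats["SZLGE"] += zc / (i**2 * s**2)
            feats["SZHGE"] += zc * i**2 / s**2
            feats["LZLGE"] += zc * s**2 / i**2
            feats["LZHGE"] += zc * i**2 * s**2
    out = {f"GLZLM_{k}": v / nz for k, v in feats.items()}
    out["GLZLM_GLNU"] = sum(row.sum() ** 2 for row in counts) / nz
    out["GLZLM_ZLNU"] = sum(counts[:, s].sum() ** 2 for s in range(counts.shape[1])) / nz
    out["GLZLM_ZP"] = nz / n_voxels
    for name in ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE"):
        out.setdefault(f"GLZLM_{name}", 0.0)
    return out


def ngldm_features(levels, mask, n_levels, eps=1e-12):
    shape = levels.shape
    s = np.zeros(n_levels)
    cnt = np.zeros(n_levels)
    n = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if (
                                0 <= u < shape[0]
                                and 0 <= v < shape[1]
                                and 0 <= w < shape[2]
                                and mask[u, v, w]
                            ):
                                nbrs.append(levels[u, v, w])
                if not nbrs:
                    continue
                n += 1
                lev = levels[x, y, z]
                s[lev - 1] += abs(lev - sum(nbrs) / len(nbrs))
                cnt[lev - 1] += 1
    p = cnt / n
    occ = [i for i in range(n_levels) if p[i] > 0]
    ng = len(occ)
    coarseness = 1.0 / (eps + float((p * s).sum()))
    contrast = 0.0
    if ng > 1:
        acc = 0.0
        for i in occ:
            for j in occ:
                if i != j:
                    acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (ng * (ng - 1)) * (s.sum() / n)
    denom = 0.0
    for i in occ:
        for j in occ:
            denom += abs((i + 1) * p[i] - (j + 1) * p[j])
    busyness = float((p * s).sum()) / denom if denom > 0 else 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }
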