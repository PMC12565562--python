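"""3D texture features from a discretized tumor VOI.

Implements the 37-feature panel extracted per sequence: 6 intensity
histogram features, 6 gray-level co-occurrence matrix (GLCM) features, 11
gray-level run-length matrix (GLRLM) features, 3 neighborhood gray-level
difference (NGLDM) features and 11 gray-level zone-length matrix (GLZLM)
features, plus the raw in-VOI minimum/maximum intensity as extra
first-order statistics.

Conventions (fixed for determinism):

* 3D analysis uses the 13 unique unit-offset directions (the 26-neighborhood
  modulo sign). GLCM and GLRLM are *summed* over directions, not averaged.
* Runs and co-occurring pairs never cross out-of-mask voxels: the mask
  breaks adjacency.
* Zones are maximal 26-connected equal-level components (which degrades to
  8-connectivity for single-slice VOIs).
* Degenerate inputs stay total: a constant VOI has skewness = kurtosis = 0,
  GLCM correlation is 0 when either marginal variance vanishes, and NGLDM
  coarseness uses a 1e-12 regularizer.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

from .discretize import DiscretizationSpec, discretize_voi
from .errors import DegenerateVoiError, EmptyMaskError
from .volume_io import Voi, extract_voi

NGLDM_EPS = 1e-12

#: the 13 unique 3D unit offsets (26 neighbors modulo sign), lexicographically
#: canonical: the first non-zero component is positive.
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and next(c for c in d if c != 0) > 0
)
assert len(DIRECTIONS_3D) == 13

HISTOGRAM_FEATURES = (
    "HISTO_Skewness",
    "HISTO_Kurtosis",
    "HISTO_Entropy_log10",
    "HISTO_Entropy_log2",
    "HISTO_Energy",
    "HISTO_AUC_CSH",
)
GLCM_FEATURES = (
    "GLCM_Homogeneity",
    "GLCM_Energy",
    "GLCM_Contrast",
    "GLCM_Correlation",
    "GLCM_Entropy",
    "GLCM_Dissimilarity",
)
GLRLM_FEATURES = (
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRLGE",
    "GLRLM_SRHGE",
    "GLRLM_LRLGE",
    "GLRLM_LRHGE",
    "GLRLM_GLNU",
    "GLRLM_RLNU",
    "GLRLM_RP",
)
NGLDM_FEATURES = (
    "NGLDM_Coarseness",
    "NGLDM_Contrast",
    "NGLDM_Busyness",
)
GLZLM_FEATURES = (
    "GLZLM_SZE",
    "GLZLM_LZE",
    "GLZLM_LGZE",
    "GLZLM_HGZE",
    "GLZLM_SZLGE",
    "GLZLM_SZHGE",
    "GLZLM_LZLGE",
    "GLZLM_LZHGE",
    "GLZLM_GLNU",
    "GLZLM_ZLNU",
    "GLZLM_ZP",
)
ALL_FEATURES = (
    HISTOGRAM_FEATURES
    + GLCM_FEATURES
    + GLRLM_FEATURES
    + NGLDM_FEATURES
    + GLZLM_FEATURES
)
assert len(ALL_FEATURES) == 37
#: raw-intensity extras reported alongside the 37-feature panel
EXTRA_FEATURES = ("RIM_min", "RIM_max")

FAMILIES = {
    "histogram": HISTOGRAM_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "ngldm": NGLDM_FEATURES,
    "glzlm": GLZLM_FEATURES,
}


# ---------------------------------------------------------------------------
# array shifting helper

def _neighbor(a: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """out[v] = a[v + d] where v + d is in bounds, else ``fill``."""
    out = np.full_like(a, fill)
    dst = []
    src = []
    for k, dk in enumerate(d):
        n = a.shape[k]
        dst.append(slice(max(0, -dk), n - max(0, dk)))
        src.append(slice(max(0, dk), n + min(0, dk)))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _check_voi(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels = np.asarray(levels)
    mask = np.asarray(mask, dtype=bool)
    if levels.shape != mask.shape:
        raise ValueError(f"levels shape {levels.shape} != mask shape {mask.shape}")
    if levels.ndim != 3:
        raise ValueError("texture matrices require a 3D subgrid")
    if not mask.any():
        raise EmptyMaskError("empty VOI")
    return levels.astype(np.int64), mask


# ---------------------------------------------------------------------------
# histogram

def histogram_features(levels) -> dict[str, float]:
    """First-order statistics of the discretized gray-level distribution.

    Skewness/kurtosis are the third/fourth standardized population moments
    (kurtosis of a normal ~ 3); both are 0 for a constant VOI by convention.
    AUC_CSH is the area under the cumulative (normalized) gray-level-volume
    curve ``t -> fraction of voxels with normalized level >= t``, which
    equals the mean normalized level exactly; a constant VOI scores 1.
    """
    x = np.asarray(levels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty level list")
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    if var > 0:
        skew = ((x - mu) ** 3).mean() / var**1.5
        kurt = ((x - mu) ** 4).mean() / var**2
    else:
        skew = 0.0
        kurt = 0.0
    _, counts = np.unique(x, return_counts=True)
    p = counts / x.size
    ent2 = float(-(p * np.log2(p)).sum())
    ent10 = float(-(p * np.log10(p)).sum())
    energy = float((p**2).sum())
    lo, hi = x.min(), x.max()
    auc_csh = float(((x - lo) / (hi - lo)).mean()) if hi > lo else 1.0
    return {
        "HISTO_Skewness": float(skew),
        "HISTO_Kurtosis": float(kurt),
        "HISTO_Entropy_log10": ent10,
        "HISTO_Entropy_log2": ent2,
        "HISTO_Energy": energy,
        "HISTO_AUC_CSH": auc_csh,
    }


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels, mask, n_levels: int, directions=DIRECTIONS_3D) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix summed over directions.

    Only pairs with both voxels in-mask are counted; each unordered pair
    contributes to both (i, j) and (j, i).
    """
    levels, mask = _check_voi(levels, mask)
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for d in directions:
        nb_mask = _neighbor(mask, d, False)
        valid = mask & nb_mask
        if not valid.any():
            continue
        i = levels[valid] - 1
        j = _neighbor(levels, d, 0)[valid] - 1
        np.add.at(counts, (i, j), 1.0)
        np.add.at(counts, (j, i), 1.0)
    total = counts.sum()
    if total == 0:
        raise DegenerateVoiError("VOI has no in-mask voxel pair along any direction")
    return counts / total


def glcm_features(levels, mask, n_levels: int, directions=DIRECTIONS_3D) -> dict[str, float]:
    p = glcm_matrix(levels, mask, n_levels, directions)
    idx = np.arange(1, n_levels + 1, dtype=np.float64)
    ii = idx[:, None]
    jj = idx[None, :]
    pi = p.sum(axis=1)
    mu_i = float((idx * pi).sum())
    sigma_i = float(np.sqrt(((idx - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    if sigma_i > 0:
        corr = float((((ii - mu_i) * (jj - mu_i) * p).sum()) / (sigma_i * sigma_i))
    else:
        corr = 0.0
    nz = p[p > 0]
    return {
        "GLCM_Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "GLCM_Energy": float((p**2).sum()),
        "GLCM_Contrast": float(((ii - jj) ** 2 * p).sum()),
        "GLCM_Correlation": corr,
        "GLCM_Entropy": float(-(nz * np.log2(nz)).sum()),
        "GLCM_Dissimilarity": float((np.abs(ii - jj) * p).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels, mask, n_levels: int, directions=DIRECTIONS_3D) -> np.ndarray:
    """Run-length counts r(i, j) summed over directions.

    A run is a maximal collinear in-mask sequence of equal gray level; the
    mask breaks adjacency. Returns an ``(n_levels, max_run_length)`` integer
    array. Conservation: ``sum_j j * r(i, j) = n_directions * Nv``.
    """
    levels, mask = _check_voi(levels, mask)
    max_len = max(levels.shape)
    counts = np.zeros((n_levels, max_len), dtype=np.int64)
    for d in directions:
        nb_mask = _neighbor(mask, d, False)
        same = mask & nb_mask & (levels == _neighbor(levels, d, 0))
        back = tuple(-c for c in d)
        cont_prev = _neighbor(same, back, False)
        starts = mask & ~cont_prev
        # run length by fixpoint: R[v] = 1 + same[v] * R[v + d]
        run = mask.astype(np.int64)
        while True:
            nxt = mask * (1 + same * _neighbor(run, d, 0))
            if np.array_equal(nxt, run):
                break
            run = nxt
        np.add.at(counts, (levels[starts] - 1, run[starts] - 1), 1)
    return counts


def glrlm_features(
    matrix: np.ndarray, n_voxels: int, n_directions: int = 13
) -> dict[str, float]:
    """The 11 run-length features from a (direction-summed) GLRLM.

    ``RP = Nr / (n_directions * Nv)`` so run percentage stays in (0, 1]
    under direction summation.
    """
    r = np.asarray(matrix, dtype=np.float64)
    nr = r.sum()
    if nr == 0:
        raise DegenerateVoiError("empty run-length matrix")
    i = np.arange(1, r.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r.shape[1] + 1, dtype=np.float64)[None, :]
    ri = r.sum(axis=1)
    rj = r.sum(axis=0)
    return {
        "GLRLM_SRE": float((r / j**2).sum() / nr),
        "GLRLM_LRE": float((r * j**2).sum() / nr),
        "GLRLM_LGRE": float((r / i**2).sum() / nr),
        "GLRLM_HGRE": float((r * i**2).sum() / nr),
        "GLRLM_SRLGE": float((r / (i**2 * j**2)).sum() / nr),
        "GLRLM_SRHGE": float((r * i**2 / j**2).sum() / nr),
        "GLRLM_LRLGE": float((r * j**2 / i**2).sum() / nr),
        "GLRLM_LRHGE": float((r * i**2 * j**2).sum() / nr),
        "GLRLM_GLNU": float((ri**2).sum() / nr),
        "GLRLM_RLNU": float((rj**2).sum() / nr),
        "GLRLM_RP": float(nr / (n_directions * n_voxels)),
    }


# ---------------------------------------------------------------------------
# GLZLM

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def glzlm_matrix(levels, mask, n_levels: int) -> np.ndarray:
    """Zone counts z(i, s): 26-connected equal-level in-mask components.

    Returns an ``(n_levels, Nv)`` integer array (zone size is 1-based on
    axis 1). Conservation: ``sum_s s * z(i, s) = Nv``.
    """
    levels, mask = _check_voi(levels, mask)
    nv = int(mask.sum())
    counts = np.zeros((n_levels, nv), dtype=np.int64)
    for lev in np.unique(levels[mask]):
        component = mask & (levels == lev)
        labeled, n_zones = ndimage.label(component, structure=_STRUCTURE_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            counts[lev - 1, s - 1] += 1
    return counts


def glzlm_features(matrix: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 zone features; same weights as GLRLM with run length -> zone size."""
    z = np.asarray(matrix, dtype=np.float64)
    nz = z.sum()
    if nz == 0:
        raise DegenerateVoiError("empty zone matrix")
    i = np.arange(1, z.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, z.shape[1] + 1, dtype=np.float64)[None, :]
    zi = z.sum(axis=1)
    zs = z.sum(axis=0)
    return {
        "GLZLM_SZE": float((z / s**2).sum() / nz),
        "GLZLM_LZE": float((z * s**2).sum() / nz),
        "GLZLM_LGZE": float((z / i**2).sum() / nz),
        "GLZLM_HGZE": float((z * i**2).sum() / nz),
        "GLZLM_SZLGE": float((z / (i**2 * s**2)).sum() / nz),
        "GLZLM_SZHGE": float((z * i**2 / s**2).sum() / nz),
        "GLZLM_LZLGE": float((z * s**2 / i**2).sum() / nz),
        "GLZLM_LZHGE": float((z * i**2 * s**2).sum() / nz),
        "GLZLM_GLNU": float((zi**2).sum() / nz),
        "GLZLM_ZLNU": float((zs**2).sum() / nz),
        "GLZLM_ZP": float(nz / n_voxels),
    }


# ---------------------------------------------------------------------------
# NGLDM

def ngldm_features(levels, mask, n_levels: int) -> dict[str, float]:
    """Coarseness, contrast and busyness from voxel-vs-neighborhood
    gray-level differences.

    For each in-mask voxel the neighborhood mean is the average level over
    its in-mask 26-neighbors; voxels without any in-mask neighbor are
    excluded. With occurrence probabilities ``p_i`` and summed absolute
    differences ``s_i`` over contributing voxels:

    * coarseness = 1 / (eps + sum_i p_i s_i)
    * contrast   = [sum_{i != j} p_i p_j (i - j)^2 / (Ng (Ng - 1))] * [sum_i s_i / n]
    * busyness   = sum_i p_i s_i / sum_{i, j occurring} |i p_i - j p_j|
      (0 when the denominator vanishes, e.g. a constant VOI)
    """
    levels, mask = _check_voi(levels, mask)
    kernel = np.ones((3, 3, 3), dtype=np.int64)
    kernel[1, 1, 1] = 0
    m = mask.astype(np.int64)
    nbr_count = ndimage.convolve(m, kernel, mode="constant", cval=0)
    nbr_sum = ndimage.convolve(levels * m, kernel, mode="constant", cval=0)
    contributing = mask & (nbr_count > 0)
    n = int(contributing.sum())
    if n == 0:
        raise DegenerateVoiError("no VOI voxel has an in-mask neighbor")
    lev = levels[contributing].astype(np.float64)
    diff = np.abs(lev - nbr_sum[contributing] / nbr_count[contributing])
    s = np.zeros(n_levels, dtype=np.float64)
    cnt = np.zeros(n_levels, dtype=np.float64)
    np.add.at(s, levels[contributing] - 1, diff)
    np.add.at(cnt, levels[contributing] - 1, 1.0)
    p = cnt / n
    occ = p > 0
    ng = int(occ.sum())
    idx = np.arange(1, n_levels + 1, dtype=np.float64)
    coarseness = float(1.0 / (NGLDM_EPS + (p * s).sum()))
    if ng > 1:
        pij = np.outer(p[occ], p[occ])
        dij = (idx[occ][:, None] - idx[occ][None, :]) ** 2
        contrast = float((pij * dij).sum() / (ng * (ng - 1)) * (s.sum() / n))
    else:
        contrast = 0.0
    ip = idx[occ] * p[occ]
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())
    busyness = float((p * s).sum() / denom) if denom > 0 else 0.0
    return {
        "NGLDM_Coarseness": coarseness,
        "NGLDM_Contrast": contrast,
        "NGLDM_Busyness": busyness,
    }


# ---------------------------------------------------------------------------
# per-patient extraction

def compute_features(
    voi: Voi,
    spec: DiscretizationSpec,
    families=None,
    directions=DIRECTIONS_3D,
) -> dict[str, float]:
    """All requested feature families for one sequence's VOI.

    ``families`` is an iterable drawn from ``FAMILIES`` keys (default all
    five plus the raw-intensity extras).
    """
    if families is None:
        families = tuple(FAMILIES)
    levels_flat = discretize_voi(voi.values, spec)
    sub_levels = np.zeros(voi.submask.shape, dtype=np.int64)
    sub_levels[voi.submask] = discretize_voi(voi.subgrid[voi.submask], spec)
    nv = int(voi.submask.sum())
    out: dict[str, float] = {}
    if "histogram" in families:
        out.update(histogram_features(levels_flat))
    if "glcm" in families:
        out.update(glcm_features(sub_levels, voi.submask, spec.n_levels, directions))
    if "glrlm" in families:
        rlm = glrlm_matrix(sub_levels, voi.submask, spec.n_levels, directions)
        out.update(glrlm_features(rlm, nv, n_directions=len(directions)))
    if "ngldm" in families:
        out.update(ngldm_features(sub_levels, voi.submask, spec.n_levels))
    if "glzlm" in families:
        zm = glzlm_matrix(sub_levels, voi.submask, spec.n_levels)
        out.update(glzlm_features(zm, nv))
    out["RIM_min"] = float(voi.values.min())
    out["RIM_max"] = float(voi.values.max())
    return out


def extract_features(patient, specs: dict[str, DiscretizationSpec], families=None):
    """Per-sequence feature dicts for one patient record.

    Returns ``{sequence_tag: {feature_name: value}}``; deterministic given
    the inputs and invariant to voxel storage order.
    """
    out = {}
    for tag, volume in patient.volumes.items():
        voi = extract_voi(volume, patient.mask)
        out[tag] = compute_features(voi, specs[tag], families=families)
    return out
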