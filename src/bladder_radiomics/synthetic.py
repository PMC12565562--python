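"""Synthetic mpMRI tumor cohorts with a tunable texture effect.

No patient images are distributed with this package, so every downstream
stage is exercised on simulated cohorts that emulate the study conditions:
1.5 T bladder tumor VOIs spanning 2-6 axial slices, one volume per sequence
(T2, DWI, ADC) with the nominal per-sequence intensity ranges, and a
class-dependent texture mechanism.

Mechanism. Each sequence is a correlated Gaussian random field (smoothed
white noise, correlation length ``corr_len_*`` voxels) min-max scaled into
the sequence's nominal range, plus additive noise. Every patient carries a
small, patient-varying fraction of coherent low-intensity *streaks*
(hypointense strands, elongated in T2, short in ADC) emulating focal
necrosis/fibrosis; muscle-invasive (MIBC) patients additionally receive a
gamma-distributed excess streak fraction scaled by ``effect_size``. The
baseline fraction makes the classes overlap (AUCs stay below 1 at moderate
effects, as in real cohorts) while the excess raises the low-gray-level
run/zone emphasis features (LGRE/SRLGE/LRLGE and zone analogues) with
effect size. DWI streaks never depend on the label, giving the screening
stage a true-negative feature family. With ``effect_size = 0`` generation
ignores the label entirely, so the two classes are exchangeable by
construction.

Reproducibility: each patient consumes an RNG stream seeded by
``(seed, patient_index)``, so cohorts are reproducible independent of
generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateMaskError
from .discretize import DEFAULT_RANGES
from .volume_io import Volume3D, VoiMask, write_mask, write_volume

#: streak length ranges (voxels): long runs in T2, short in ADC
STREAK_LENGTH = {"T2": (6, 10), "DWI": (3, 5), "ADC": (1, 2)}
#: every patient's baseline dark-streak fraction is uniform on this interval
BASELINE_STREAK_FRACTION = (0.0, 0.04)
#: normalized intensity of baseline dark streaks (moderately low levels)
BASELINE_STREAK_LEVEL = (0.08, 0.20)
#: MIBC excess streak fraction: effect_size * Gamma(shape, scale)
EXCESS_STREAK_GAMMA = (2.0, 0.04)
#: class-independent bright-speckle fraction (nuisance heterogeneity axis)
SPECKLE_FRACTION = (0.0, 0.12)
#: in-plane streak directions (dx, dy)
_STREAK_DIRS = ((1, 0), (0, 1), (1, 1), (1, -1))

GRID_SHAPE = (28, 28, 9)
VOXEL_SPACING = (1.0, 1.0, 4.0)

_MASK_RETRIES = 25


@dataclass(frozen=True)
class SyntheticParams:
    """Cohort-generation parameters.

    ``effect_size`` controls class separation (0 = null: labels carry no
    signal) by scaling the MIBC excess streak fraction. ``low_shift_mibc``
    is the fractional intensity down-shift of streak voxels.
    """

    n_patients: int = 40
    prevalence: float = 0.525
    effect_size: float = 1.0
    corr_len_nmibc: float = 1.2
    corr_len_mibc: float = 1.2
    low_shift_mibc: float = 0.8
    noise_sd: float = 0.02
    slices_min: int = 2
    slices_max: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.slices_min < 2:
            raise ValueError("slices_min must be >= 2")
        if self.slices_max > 6:
            raise ValueError("slices_max must be <= 6")
        if self.slices_min > self.slices_max:
            raise ValueError("slices_min must not exceed slices_max")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        return cls(**d)


@dataclass
class PatientRecord:
    """One synthetic patient: label, per-sequence volumes and a shared mask."""

    patient_id: str
    label: int
    volumes: dict[str, Volume3D]
    mask: VoiMask

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        for tag, vol in self.volumes.items():
            if vol.grid.shape != self.mask.grid.shape:
                raise ValueError(f"{tag} volume shape mismatch with mask")


def _make_mask(rng: np.random.Generator, params: SyntheticParams) -> np.ndarray:
    """Ellipsoidal blob perturbed by smoothed noise, on consecutive axial slices."""
    nx, ny, nz = GRID_SHAPE
    n_slices = int(rng.integers(params.slices_min, params.slices_max + 1))
    z0 = int(rng.integers(1, nz - n_slices))
    cx = nx / 2 + rng.uniform(-2, 2)
    cy = ny / 2 + rng.uniform(-2, 2)
    cz = z0 + (n_slices - 1) / 2
    rx = rng.uniform(4.5, 8.0)
    ry = rng.uniform(4.5, 8.0)
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    # per-slice radius taper keeps every slice in the band populated
    taper = np.sqrt(np.clip(1.0 - ((z - cz) / (n_slices / 2 + 0.4)) ** 2, 0.25, 1.0))
    pert = ndimage.gaussian_filter(rng.standard_normal(GRID_SHAPE), sigma=2.0) * 0.35
    implicit = ((x - cx) / (rx * taper)) ** 2 + ((y - cy) / (ry * taper)) ** 2
    mask = (implicit <= 1.0 + pert) & (z >= z0) & (z < z0 + n_slices)
    if mask.sum() < 8:
        return np.zeros(GRID_SHAPE, dtype=bool)
    # keep the largest connected component so the VOI is a single blob
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        mask = labeled == (int(np.argmax(sizes)) + 1)
    occupied = np.flatnonzero(mask.any(axis=(0, 1)))
    if (
        mask.sum() < 8
        or len(occupied) < params.slices_min
        or len(occupied) > params.slices_max
    ):
        return np.zeros(GRID_SHAPE, dtype=bool)
    return mask


def _streak_voxels(
    rng: np.random.Generator,
    mask: np.ndarray,
    target: int,
    length_range: tuple[int, int],
) -> list[np.ndarray]:
    """Sample elongated in-plane streaks of in-mask voxels, ~``target`` total."""
    coords = np.argwhere(mask)
    streaks: list[np.ndarray] = []
    marked = 0
    for _ in range(8 * target + 16):
        if marked >= target:
            break
        seed_voxel = coords[rng.integers(len(coords))]
        dx, dy = _STREAK_DIRS[rng.integers(len(_STREAK_DIRS))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        vox = []
        vx, vy, vz = (int(c) for c in seed_voxel)
        for _step in range(length):
            if not (0 <= vx < mask.shape[0] and 0 <= vy < mask.shape[1]):
                break
            if not mask[vx, vy, vz]:
                break
            vox.append((vx, vy, vz))
            vx += dx
            vy += dy
        if vox:
            streaks.append(np.array(vox))
            marked += len(vox)
    return streaks


def generate_patient(
    params: SyntheticParams, label: int, rng: np.random.Generator, patient_id: str = "P0"
) -> PatientRecord:
    """Generate one patient's mask and T2/DWI/ADC volumes.

    The tumor mask is a connected blob spanning ``slices_min..slices_max``
    axial slices; masks with fewer than 8 voxels trigger regeneration up to
    a bounded retry count, then a seed-reporting failure.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    mask = None
    for _ in range(_MASK_RETRIES):
        candidate = _make_mask(rng, params)
        if candidate.any():
            mask = candidate
            break
    if mask is None:
        raise DegenerateMaskError(
            f"could not generate a usable mask for patient {patient_id} "
            f"(seed {params.seed}) after {_MASK_RETRIES} attempts"
        )
    effect = min(params.effect_size, 1.0)
    volumes: dict[str, Volume3D] = {}
    for tag, (lo, hi) in DEFAULT_RANGES.items():
        if tag == "DWI" or label == 0:
            corr_len = params.corr_len_nmibc
        else:
            corr_len = params.corr_len_nmibc + effect * (
                params.corr_len_mibc - params.corr_len_nmibc
            )
        field_raw = ndimage.gaussian_filter(
            rng.standard_normal(GRID_SHAPE), sigma=corr_len
        )
        fmin, fmax = field_raw[mask].min(), field_raw[mask].max()
        norm = (field_raw - fmin) / (fmax - fmin) if fmax > fmin else np.full_like(field_raw, 0.5)
        intensity = lo + norm * (hi - lo)
        intensity += rng.standard_normal(GRID_SHAPE) * params.noise_sd * (hi - lo)
        # bright speckles: isolated high-intensity voxels in every patient,
        # fraction varying per patient independently of the class — a
        # nuisance heterogeneity axis that loads on contrast/busyness-type
        # features but not on the 1/i^2-weighted low-gray-level family
        n_speckle = int(round(rng.uniform(*SPECKLE_FRACTION) * mask.sum()))
        if n_speckle > 0:
            coords = np.argwhere(mask)
            pick = coords[rng.choice(len(coords), size=n_speckle, replace=False)]
            intensity[tuple(pick.T)] = lo + rng.uniform(0.9, 1.0, n_speckle) * (hi - lo)
        # dark streaks: every patient carries a few moderately dark streaks;
        # MIBC patients additionally get *deep* dark streaks (down-shifted
        # by low_shift_mibc) whose 1/i^2 weight dominates the low-gray
        # family. Draws happen unconditionally so the RNG stream stays
        # aligned across labels and the classes are exchangeable at
        # effect_size = 0.
        base_frac = rng.uniform(*BASELINE_STREAK_FRACTION)
        shape, scale = EXCESS_STREAK_GAMMA
        excess_frac = min(params.effect_size * rng.gamma(shape, scale), 0.4)
        plans = [(base_frac, BASELINE_STREAK_LEVEL)]
        if label == 1 and tag != "DWI" and excess_frac > 0:
            deep_hi = (1.0 - params.low_shift_mibc) * 0.1
            plans.append((excess_frac, (0.0, deep_hi)))
        for frac, level_range in plans:
            target = int(round(frac * mask.sum()))
            if target == 0:
                continue
            for streak in _streak_voxels(rng, mask, target, STREAK_LENGTH[tag]):
                # coherent per-streak value so streaks form equal-level runs
                base = rng.uniform(*level_range)
                jitter = rng.standard_normal(len(streak)) * 0.001
                vals = lo + np.clip(base + jitter, 0.0, 1.0) * (hi - lo)
                intensity[tuple(streak.T)] = vals
        np.clip(intensity, lo, hi, out=intensity)
        volumes[tag] = Volume3D(grid=intensity, spacing=VOXEL_SPACING, sequence_tag=tag)
    return PatientRecord(
        patient_id=patient_id, label=int(label), volumes=volumes, mask=VoiMask(mask.copy())
    )


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_cohort(params: SyntheticParams) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a full cohort plus its cohort table.

    The MIBC count is ``round(prevalence * n_patients)``; label order is
    shuffled deterministically from the seed; the whole cohort is
    reproducible from ``params`` alone.
    """
    n = params.n_patients
    n_pos = int(round(params.prevalence * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1 << 20]))
    shuffle_rng.shuffle(labels)
    records = []
    for idx, label in enumerate(labels):
        pid = f"P{idx + 1:04d}"
        rng = _patient_rng(params.seed, idx)
        records.append(generate_patient(params, int(label), rng, patient_id=pid))
    table = pd.DataFrame(
        {"patient_id": [r.patient_id for r in records], "label": [r.label for r in records]}
    )
    return records, table


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(
    records: list[PatientRecord],
    out_dir,
    params: SyntheticParams | None = None,
) -> dict:
    """Write NIfTI volumes/masks, the cohort CSV and a JSON manifest.

    Uncompressed ``.nii`` is used so output bytes are deterministic and the
    manifest's content hashes allow regeneration checks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for rec in records:
        for tag, vol in rec.volumes.items():
            name = f"{rec.patient_id}_{tag}.nii"
            try:
                write_volume(vol, out / name)
            except OSError as exc:
                raise OSError(f"failed writing volume {out / name}: {exc}") from exc
            files[name] = _sha256(out / name)
        mname = f"{rec.patient_id}_mask.nii"
        try:
            write_mask(rec.mask, out / mname, spacing=VOXEL_SPACING)
        except OSError as exc:
            raise OSError(f"failed writing mask {out / mname}: {exc}") from exc
        files[mname] = _sha256(out / mname)
    table = pd.DataFrame(
        {"patient_id": [r.patient_id for r in records], "label": [r.label for r in records]}
    )
    table_path = out / "cohort.csv"
    table.to_csv(table_path, index=False)
    files["cohort.csv"] = _sha256(table_path)
    manifest = {
        "n_patients": len(records),
        "params": params.to_dict() if params is not None else None,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
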