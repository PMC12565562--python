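"""Fixed-bin (absolute-resampling) intensity discretization.

Raw MR intensities are mapped to integer gray levels ``1..n_levels`` using
population-fixed per-sequence bounds rather than per-lesion extrema, the
recommended practice for MRI texture analysis. The default bounds are the
published per-sequence measurements (T2 175-3152, DWI 50-5300, ADC 20-2550)
with 128 gray levels for every sequence; the same spec must be applied
identically to training and validation data, which the pipeline enforces by
serializing the spec inside the locked descriptor.

Level mapping: ``level = floor((I - min) / (max - min) * n_levels) + 1``
after clamping ``I`` to ``[min, max]``, with ``I = max`` joining the top
bin. Levels are 1-based so that low-gray-level weights ``1/i**2`` are
always defined; out-of-range intensities saturate instead of erroring.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

#: published per-sequence absolute-resampling bounds (min, max)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "T2": (175.0, 3152.0),
    "DWI": (50.0, 5300.0),
    "ADC": (20.0, 2550.0),
}

DEFAULT_N_LEVELS = 128


@dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin discretization parameters for one sequence."""

    min_intensity: float
    max_intensity: float
    n_levels: int = DEFAULT_N_LEVELS
    sequence_tag: str = "T2"

    def __post_init__(self) -> None:
        if not self.max_intensity > self.min_intensity:
            raise ValueError(
                f"max_intensity ({self.max_intensity}) must exceed "
                f"min_intensity ({self.min_intensity})"
            )
        if self.n_levels < 2:
            raise ValueError(f"n_levels must be >= 2, got {self.n_levels}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationSpec":
        return cls(**d)


def default_spec(sequence_tag: str, n_levels: int = DEFAULT_N_LEVELS) -> DiscretizationSpec:
    """The published fixed-bin spec for a sequence tag."""
    lo, hi = DEFAULT_RANGES[sequence_tag]
    return DiscretizationSpec(lo, hi, n_levels=n_levels, sequence_tag=sequence_tag)


def default_specs(n_levels: int = DEFAULT_N_LEVELS) -> dict[str, DiscretizationSpec]:
    return {tag: default_spec(tag, n_levels) for tag in DEFAULT_RANGES}


def discretize_voi(intensities, spec: DiscretizationSpec) -> np.ndarray:
    """Map raw intensities to integer gray levels in ``1..spec.n_levels``.

    Accepts any array shape; the output matches it. Empty input or
    non-finite intensities raise.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot discretize an empty intensity list")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensity encountered during discretization")
    lo, hi, g = spec.min_intensity, spec.max_intensity, spec.n_levels
    x = np.clip(x, lo, hi)
    levels = np.floor((x - lo) / (hi - lo) * g).astype(np.int64) + 1
    # I = max would land in an unreachable (g+1)-th bin; fold it into the top one
    return np.minimum(levels, g)
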