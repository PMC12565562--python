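"""The locked two-feature AND descriptor.

A patient is called muscle-invasive iff *both* component feature values
exceed their training-derived cut-offs (strict inequality, per stored
orientation). The published descriptor pairs GLRLM-LRLGE from T2 with
GLRLM-SRLGE from ADC at cut-offs 3731.71 and 3785.45; derivation from a
fresh training cohort picks the top-AUC significant feature from each of T2
and ADC (one per sequence — cross-sequence complementarity avoids
same-sequence redundancy).

The spec is serialized as JSON with a content hash over its decision-
relevant fields; loading verifies the hash, so any post-hoc tampering with
a locked descriptor fails hard instead of silently re-tuning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError, MissingFeatureError, ScreeningError

#: published locked cut-offs
DEFAULT_COMPONENTS = (
    ("T2", "GLRLM_LRLGE", 3731.71, ">"),
    ("ADC", "GLRLM_SRLGE", 3785.45, ">"),
)


@dataclass(frozen=True)
class DescriptorComponent:
    sequence: str
    feature: str
    cutoff: float
    orientation: str = ">"

    def __post_init__(self) -> None:
        if self.orientation not in (">", "<"):
            raise ValueError(f"orientation must be '>' or '<', got {self.orientation!r}")

    def is_positive(self, value: float) -> bool:
        if self.orientation == ">":
            return value > self.cutoff
        return value < self.cutoff

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "feature": self.feature,
            "cutoff": self.cutoff,
            "orientation": self.orientation,
        }


@dataclass(frozen=True)
class DescriptorSpec:
    """Two (sequence, feature, cutoff, orientation) components + AND rule."""

    components: tuple[DescriptorComponent, DescriptorComponent]
    rule: str = "AND"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.components) != 2:
            raise ValueError("descriptor must have exactly two components")
        keys = {(c.sequence, c.feature) for c in self.components}
        if len(keys) != 2:
            raise ValueError("descriptor components must be distinct")
        if len({c.sequence for c in self.components}) != 2:
            raise ValueError("descriptor components must come from distinct sequences")
        if self.rule != "AND":
            raise ValueError("only the AND decision rule is supported")

    def content_hash(self) -> str:
        payload = {
            "components": [c.to_dict() for c in self.components],
            "rule": self.rule,
            "discretization": self.provenance.get("discretization"),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_dict(self) -> dict:
        return {
            "components": [c.to_dict() for c in self.components],
            "rule": self.rule,
            "provenance": self.provenance,
            "sha256": self.content_hash(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSpec":
        spec = cls(
            components=tuple(DescriptorComponent(**c) for c in d["components"]),
            rule=d.get("rule", "AND"),
            provenance=d.get("provenance", {}),
        )
        stored = d.get("sha256")
        if stored is not None and stored != spec.content_hash():
            raise IntegrityError(
                "descriptor hash mismatch: artifact was modified after locking"
            )
        return spec

    @classmethod
    def load(cls, path) -> "DescriptorSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_descriptor() -> DescriptorSpec:
    """The published locked descriptor (T2-LRLGE and ADC-SRLGE, AND rule)."""
    return DescriptorSpec(
        components=tuple(DescriptorComponent(*c) for c in DEFAULT_COMPONENTS),
        provenance={"source": "published training cohort"},
    )


@dataclass
class DescriptorEvaluation:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auc: float
    auc_method: str = "binary-rule (Se+Sp)/2"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "auc_method": self.auc_method,
        }


def derive_descriptor(
    screen_results: pd.DataFrame,
    sequences: tuple[str, str] = ("T2", "ADC"),
    exclude_features: tuple[str, ...] = ("RIM_min", "RIM_max"),
) -> DescriptorSpec:
    """Lock a two-feature descriptor from a screening table.

    Takes the top-AUC *significant* feature from each required sequence
    (ties broken by higher Youden J, then feature name order). Raw-intensity
    extras are excluded by default: the descriptor is a texture signature.
    Fails explicitly if a required sequence has no significant feature.
    """
    components = []
    for seq in sequences:
        cand = screen_results[
            (screen_results["sequence"] == seq)
            & screen_results["significant"]
            & ~screen_results["feature"].isin(exclude_features)
        ]
        if cand.empty:
            raise ScreeningError(
                f"no significant feature available in sequence {seq}; "
                f"cannot derive a descriptor"
            )
        cand = cand.sort_values(
            by=["auc", "youden_j", "feature"], ascending=[False, False, True]
        )
        row = cand.iloc[0]
        components.append(
            DescriptorComponent(
                sequence=seq,
                feature=str(row["feature"]),
                cutoff=float(row["cutoff"]),
                orientation=str(row["orientation"]),
            )
        )
    return DescriptorSpec(components=tuple(components))


def apply_descriptor(spec: DescriptorSpec, feature_table: pd.DataFrame) -> pd.Series:
    """Predicted label (1 = invasive) per patient under the AND rule.

    ``feature_table`` is the tidy per-patient x sequence table. A missing
    component value is a per-patient error naming the missing key.
    """
    wide = feature_table.set_index(["patient_id", "sequence"])
    preds = {}
    for pid in feature_table["patient_id"].unique():
        verdict = True
        for comp in spec.components:
            key = (pid, comp.sequence)
            if key not in wide.index or comp.feature not in wide.columns:
                raise MissingFeatureError(
                    f"patient {pid}: missing feature "
                    f"({comp.sequence}, {comp.feature})"
                )
            value = wide.loc[key, comp.feature]
            if pd.isna(value):
                raise MissingFeatureError(
                    f"patient {pid}: missing feature "
                    f"({comp.sequence}, {comp.feature})"
                )
            verdict = verdict and comp.is_positive(float(value))
        preds[pid] = int(verdict)
    return pd.Series(preds, name="prediction").sort_index()


def evaluate_descriptor(predictions, labels) -> DescriptorEvaluation:
    """Confusion counts, Se, Sp and the binary-rule AUC (Se + Sp) / 2.

    The AND rule yields a single operating point, so its ROC has one
    interior vertex and the trapezoidal AUC reduces to (Se + Sp)/2; the
    evaluation labels the method explicitly.
    """
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels must align")
    if not (np.any(lab == 1) and np.any(lab == 0)):
        raise ValueError("labels must contain both classes")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    return DescriptorEvaluation(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=se, specificity=sp, auc=(se + sp) / 2.0,
    )
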