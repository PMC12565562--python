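"""End-to-end study orchestration: simulate -> extract -> train -> validate.

Reproduces the two-cohort locked-descriptor design: features are screened
exclusively on the training cohort, a two-feature descriptor is locked
(serialized with a content hash and the discretization it assumes), and
validation applies it unchanged — the validation stage carries no tuning
parameters, and a hash mismatch aborts instead of silently re-tuning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import texture
from .auc_stats import AucInference, infer_auc
from .descriptor import (
    DescriptorSpec,
    apply_descriptor,
    derive_descriptor,
    evaluate_descriptor,
    DescriptorEvaluation,
)
from .discretize import DiscretizationSpec, default_specs
from .errors import ConfigError
from .screening import screen_cohort
from .synthetic import PatientRecord, SyntheticParams, generate_cohort
from .volume_io import read_mask, read_volume, SEQUENCE_TAGS

logger = logging.getLogger("bladder_radiomics")


@dataclass
class CohortSource:
    """Either synthetic-generation parameters or a directory of NIfTI data."""

    synthetic: SyntheticParams | None = None
    data_dir: Path | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ConfigError("a cohort source needs exactly one of: synthetic, data_dir")

    def key(self) -> str:
        if self.synthetic is not None:
            return f"synthetic:{self.synthetic.seed}"
        return f"dir:{Path(self.data_dir).resolve()}"


@dataclass
class StudyConfig:
    training: CohortSource
    validation: CohortSource
    alpha: float = 0.05
    n_levels: int = 128
    discretization: dict[str, DiscretizationSpec] = field(default_factory=default_specs)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 0.5 and self.alpha != 0:
            raise ConfigError(f"alpha must be in (0, 0.5] or 0, got {self.alpha}")
        if self.training.key() == self.validation.key():
            raise ConfigError(
                "training and validation must reference disjoint data "
                f"(both resolve to {self.training.key()})"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        required = {"training", "validation"}
        missing = required - set(d)
        if missing:
            raise ConfigError(f"config missing required sections: {sorted(missing)}")
        unknown = set(d) - required - {"alpha", "n_levels", "discretization"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def source(section: dict) -> CohortSource:
            if not isinstance(section, dict):
                raise ConfigError("cohort sections must be mappings")
            if "synthetic" in section:
                try:
                    return CohortSource(synthetic=SyntheticParams.from_dict(section["synthetic"]))
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"bad synthetic parameters: {exc}") from exc
            if "data_dir" in section:
                return CohortSource(data_dir=Path(section["data_dir"]))
            raise ConfigError("cohort section needs 'synthetic' or 'data_dir'")

        n_levels = int(d.get("n_levels", 128))
        disc = d.get("discretization")
        if disc is None:
            specs = default_specs(n_levels)
        else:
            specs = {
                tag: DiscretizationSpec(
                    min_intensity=float(v["min"]),
                    max_intensity=float(v["max"]),
                    n_levels=int(v.get("n_levels", n_levels)),
                    sequence_tag=tag,
                )
                for tag, v in disc.items()
            }
        return cls(
            training=source(d["training"]),
            validation=source(d["validation"]),
            alpha=float(d.get("alpha", 0.05)),
            n_levels=n_levels,
            discretization=specs,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(d)


@dataclass
class TrainingResult:
    screen_table: pd.DataFrame
    descriptor: DescriptorSpec
    evaluation: DescriptorEvaluation
    inference: AucInference
    feature_table: pd.DataFrame
    cohort_table: pd.DataFrame


@dataclass
class ValidationResult:
    evaluation: DescriptorEvaluation
    inference: AucInference
    feature_table: pd.DataFrame
    cohort_table: pd.DataFrame
    descriptor_hash: str

    def report(self) -> dict:
        """The validation metric set: Se, Sp, AUC +- SE, 95% CI."""
        return {
            "sensitivity": self.evaluation.sensitivity,
            "specificity": self.evaluation.specificity,
            "auc": self.inference.auc,
            "auc_method": self.evaluation.auc_method,
            "se": self.inference.se,
            "ci_low": self.inference.ci_low,
            "ci_high": self.inference.ci_high,
            "power": self.inference.power,
            "descriptor_sha256": self.descriptor_hash,
        }


def load_cohort(data_dir) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Read a cohort written by :func:`synthetic.write_cohort` (or shaped
    like one: per-patient ``<id>_<seq>.nii[.gz]`` + ``<id>_mask.nii[.gz]``
    and a ``cohort.csv`` with patient_id,label)."""
    data_dir = Path(data_dir)
    table = pd.read_csv(data_dir / "cohort.csv")
    records = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])

        def find(stem: str) -> Path:
            for ext in (".nii", ".nii.gz"):
                p = data_dir / f"{stem}{ext}"
                if p.exists():
                    return p
            raise FileNotFoundError(f"missing file {data_dir / stem}.nii[.gz]")

        volumes = {tag: read_volume(find(f"{pid}_{tag}"), tag) for tag in SEQUENCE_TAGS}
        mask = read_mask(find(f"{pid}_mask"))
        records.append(
            PatientRecord(patient_id=pid, label=int(row["label"]), volumes=volumes, mask=mask)
        )
    return records, table


def materialize_cohort(source: CohortSource) -> tuple[list[PatientRecord], pd.DataFrame]:
    if source.synthetic is not None:
        return generate_cohort(source.synthetic)
    return load_cohort(source.data_dir)


def extract_cohort_features(
    records: list[PatientRecord],
    specs: dict[str, DiscretizationSpec],
    families=None,
) -> pd.DataFrame:
    """Tidy feature table: one row per patient x sequence, one column per feature."""
    rows = []
    for rec in records:
        per_seq = texture.extract_features(rec, specs, families=families)
        for tag, feats in per_seq.items():
            rows.append({"patient_id": rec.patient_id, "sequence": tag, **feats})
    return pd.DataFrame(rows)


def _cohort_hash(table: pd.DataFrame, source: CohortSource) -> str:
    payload = table.to_csv(index=False) + source.key()
    if source.synthetic is not None:
        payload += json.dumps(source.synthetic.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_training(config: StudyConfig) -> TrainingResult:
    """Screen the training cohort, lock the descriptor, evaluate in-sample."""
    logger.info("training: materializing cohort")
    records, table = materialize_cohort(config.training)
    logger.info("training: extracting features for %d patients", len(records))
    features = extract_cohort_features(records, config.discretization)
    labels = table.set_index("patient_id")["label"]
    logger.info("training: screening %d feature columns", features.shape[1] - 2)
    screen = screen_cohort(features, labels, alpha=config.alpha)
    spec = derive_descriptor(screen)
    spec = DescriptorSpec(
        components=spec.components,
        rule=spec.rule,
        provenance={
            "training_manifest_sha256": _cohort_hash(table, config.training),
            "discretization": {
                tag: s.to_dict() for tag, s in sorted(config.discretization.items())
            },
            "alpha": config.alpha,
        },
    )
    logger.info("training: locked descriptor %s", spec.content_hash()[:12])
    preds = apply_descriptor(spec, features)
    aligned = labels.loc[preds.index]
    evaluation = evaluate_descriptor(preds.to_numpy(), aligned.to_numpy())
    inference = infer_auc(
        evaluation.auc, int((aligned == 1).sum()), int((aligned == 0).sum())
    )
    return TrainingResult(screen, spec, evaluation, inference, features, table)


def run_validation(config: StudyConfig, descriptor: DescriptorSpec) -> ValidationResult:
    """Apply a locked descriptor unchanged to the validation cohort."""
    records, table = materialize_cohort(config.validation)
    features = extract_cohort_features(records, config.discretization)
    labels = table.set_index("patient_id")["label"]
    preds = apply_descriptor(descriptor, features)
    aligned = labels.loc[preds.index]
    evaluation = evaluate_descriptor(preds.to_numpy(), aligned.to_numpy())
    inference = infer_auc(
        evaluation.auc, int((aligned == 1).sum()), int((aligned == 0).sum())
    )
    digest = descriptor.content_hash()
    logger.info("validation: applied locked descriptor %s", digest[:12])
    return ValidationResult(evaluation, inference, features, table, digest)


def run_study(config: StudyConfig) -> tuple[TrainingResult, ValidationResult]:
    """Full two-cohort study; deterministic given the config's seeds."""
    training = run_training(config)
    # round-trip through serialization so the hash check is always exercised
    locked = DescriptorSpec.from_dict(training.descriptor.to_dict())
    validation = run_validation(config, locked)
    return training, validation
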