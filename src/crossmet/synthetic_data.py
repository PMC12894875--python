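"""Synthetic paired-platform cohorts with known latent structure.

Each compound class owns a latent factor; features on both platforms load
on their class factor so that the expected correlation between a target
feature and a same-class input feature equals ``cross_platform_loading``.
Outcomes are linear in the class factors on the standardised-beta scale,
with age and sex effects, making clustering, imputation, model selection
and association concordance all testable end to end without any download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PlatformMatrix

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missing_and_outliers",
    "write_cohort",
]

_AGE_BETA = 0.2
_SEX_BETA = 0.1


@dataclass
class CohortConfig:
    n_samples: int = 500
    n_classes: int = 5
    # scalar = same count for every class; sequence = one count per class
    n_input_per_class: int | tuple[int, ...] = 20
    n_target_per_class: int | tuple[int, ...] = 10
    latent_dim: int = 1
    # scalar = same loading for every class; sequence = one loading per class
    cross_platform_loading: float | tuple[float, ...] = 0.8
    noise_sd: float = 0.3
    missing_frac: float = 0.0
    outlier_frac: float = 0.0
    outlier_multiplier: float = 10.0
    # feature ids forced to an elevated missing fraction (exercises the QC filter)
    elevated_missing: dict[str, float] = field(default_factory=dict)
    # outcome name -> per-class standardised effect sizes (length n_classes)
    outcome_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    # fraction of target features given an annotation shared with an input feature
    annotated_frac: float = 0.5
    class_names: tuple[str, ...] | None = None
    age_range: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def per_class_counts(self, which: str) -> list[int]:
        raw = self.n_input_per_class if which == "input" else self.n_target_per_class
        counts = [int(raw)] * self.n_classes if np.isscalar(raw) else [int(c) for c in raw]
        if len(counts) != self.n_classes:
            raise ValueError(f"need {self.n_classes} per-class {which} counts, got {len(counts)}")
        return counts

    def per_class_loadings(self) -> list[float]:
        raw = self.cross_platform_loading
        lams = [float(raw)] * self.n_classes if np.isscalar(raw) else [float(v) for v in raw]
        if len(lams) != self.n_classes:
            raise ValueError(f"need {self.n_classes} per-class loadings, got {len(lams)}")
        return lams

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_classes < 1:
            raise ValueError("n_samples and n_classes must be >= 1")
        for which in ("input", "target"):
            if min(self.per_class_counts(which)) < 1:
                raise ValueError("per-class feature counts must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        for name in ("missing_frac", "outlier_frac", "annotated_frac"):
            frac = getattr(self, name)
            if not 0.0 <= frac < 1.0 and not (name == "annotated_frac" and frac == 1.0):
                raise ValueError(f"{name}={frac} outside valid range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for lam in self.per_class_loadings():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"cross_platform_loading={lam} outside [0, 1]")
            if lam * np.sqrt(1.0 + self.noise_sd**2) > 1.0 + 1e-12:
                raise ValueError(
                    "cross_platform_loading too large for noise_sd: need "
                    "loading * sqrt(1 + noise_sd^2) <= 1"
                )
        for outcome, effects in self.outcome_effects.items():
            if len(effects) != self.n_classes:
                raise ValueError(f"outcome {outcome!r} needs {self.n_classes} effects")
            if sum(e**2 for e in effects) + _AGE_BETA**2 + _SEX_BETA**2 >= 1.0:
                raise ValueError(f"outcome {outcome!r} effects leave no room for noise")

    def class_name(self, c: int) -> str:
        if self.class_names is not None:
            return self.class_names[c]
        return f"class_{c}"


@dataclass
class SyntheticCohort:
    input_matrix: PlatformMatrix
    target_matrix: PlatformMatrix
    feature_metadata: pd.DataFrame  # feature_id, platform, compound_class, annotation
    phenotypes: pd.DataFrame  # sample_id index; age, sex, outcome columns
    true_factors: np.ndarray  # samples x (n_classes * latent_dim); tests only
    config: CohortConfig
    planted_outliers: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.input_matrix.sample_ids != self.target_matrix.sample_ids:
            raise ValueError("platform matrices must share sample ordering")
        ids = self.feature_metadata["feature_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate feature ids in metadata")


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a paired-platform cohort from the shared-factor model.

    Input feature i of class c:  ``x_i = u_i . z_c + noise_sd * eps``;
    target feature t of class c: ``y_t = lam * (1 + noise_sd^2) * v_t . z_c
    + s * eta`` with ``s`` chosen so both platforms have equal variance,
    giving corr(x_i, y_t) = lam * (u_i . v_t)  (= lam for latent_dim 1).
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, q = config.n_samples, config.latent_dim
    lams = config.per_class_loadings()
    sd = config.noise_sd
    var_total = 1.0 + sd**2

    sample_ids = [f"S{i:05d}" for i in range(n)]
    factors = rng.standard_normal((n, config.n_classes, q))

    def _directions(count: int) -> np.ndarray:
        if q == 1:
            return np.ones((count, 1))
        u = rng.standard_normal((count, q))
        return u / np.linalg.norm(u, axis=1, keepdims=True)

    input_counts = config.per_class_counts("input")
    target_counts = config.per_class_counts("target")
    input_cols, target_cols = [], []
    input_ids, target_ids = [], []
    meta_rows = []
    for c in range(config.n_classes):
        cname = config.class_name(c)
        n_in, n_tg = input_counts[c], target_counts[c]
        target_signal = lams[c] * var_total
        target_noise_sd = float(np.sqrt(max(0.0, var_total - target_signal**2)))
        u_in = _directions(n_in)
        u_tg = _directions(n_tg)
        z = factors[:, c, :]
        x = z @ u_in.T + sd * rng.standard_normal((n, n_in))
        y = target_signal * (z @ u_tg.T) + target_noise_sd * rng.standard_normal((n, n_tg))
        input_cols.append(x)
        target_cols.append(y)
        n_annot = int(round(config.annotated_frac * n_tg))
        for i in range(n_in):
            fid = f"IN_c{c}_f{i}"
            input_ids.append(fid)
            annotation = f"anno_c{c}_{i}" if i < n_annot else f"in_only_c{c}_{i}"
            meta_rows.append((fid, "input", cname, annotation))
        for t in range(n_tg):
            fid = f"TG_c{c}_f{t}"
            target_ids.append(fid)
            # the first n_annot targets share an annotation with an input feature
            annotation = f"anno_c{c}_{t}" if t < n_annot else f"unique_c{c}_{t}"
            meta_rows.append((fid, "target", cname, annotation))

    input_values = np.concatenate(input_cols, axis=1)
    target_values = np.concatenate(target_cols, axis=1)

    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_std = (age - age.mean()) / age.std()
    sex_std = (sex - 0.5) * 2.0  # unit variance in expectation
    pheno = {"age": age, "sex": sex}
    for outcome, effects in config.outcome_effects.items():
        signal = factors[:, :, 0] @ np.asarray(effects, dtype=float)
        resid_var = 1.0 - sum(e**2 for e in effects) - _AGE_BETA**2 - _SEX_BETA**2
        raw = signal + _AGE_BETA * age_std + _SEX_BETA * sex_std
        raw = raw + np.sqrt(resid_var) * rng.standard_normal(n)
        pheno[outcome] = (raw - raw.mean()) / raw.std()

    metadata = pd.DataFrame(
        meta_rows, columns=["feature_id", "platform", "compound_class", "annotation"]
    )
    cohort = SyntheticCohort(
        input_matrix=PlatformMatrix(
            input_values, np.ones_like(input_values, bool), sample_ids, input_ids, "input"
        ),
        target_matrix=PlatformMatrix(
            target_values, np.ones_like(target_values, bool), sample_ids, target_ids, "target"
        ),
        feature_metadata=metadata,
        phenotypes=pd.DataFrame(pheno, index=pd.Index(sample_ids, name="sample_id")),
        true_factors=factors.reshape(n, -1),
        config=config,
    )
    return cohort


def _mask_matrix(matrix: PlatformMatrix, config: CohortConfig, rng) -> PlatformMatrix:
    values = matrix.values.copy()
    mask = matrix.observed_mask.copy()
    n = matrix.n_samples
    for j, fid in enumerate(matrix.feature_ids):
        frac = config.elevated_missing.get(fid, config.missing_frac)
        if frac <= 0.0:
            continue
        k = int(round(frac * n))
        rows = rng.choice(n, size=k, replace=False)
        mask[rows, j] = False
        values[rows, j] = np.nan
    return PlatformMatrix(values, mask, matrix.sample_ids, matrix.feature_ids, matrix.platform)


def inject_missing_and_outliers(cohort: SyntheticCohort, config: CohortConfig) -> SyntheticCohort:
    """Apply MCAR missingness per feature and inflate a fraction of samples
    into outliers; the observed mask is updated consistently."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    input_matrix = _mask_matrix(cohort.input_matrix, config, rng)
    target_matrix = _mask_matrix(cohort.target_matrix, config, rng)

    planted: set[str] = set()
    if config.outlier_frac > 0.0:
        n = input_matrix.n_samples
        k = int(round(config.outlier_frac * n))
        rows = rng.choice(n, size=k, replace=False)
        planted = {input_matrix.sample_ids[i] for i in rows}
        for m in (input_matrix, target_matrix):
            m.values[rows, :] *= config.outlier_multiplier

    return SyntheticCohort(
        input_matrix=input_matrix,
        target_matrix=target_matrix,
        feature_metadata=cohort.feature_metadata,
        phenotypes=cohort.phenotypes,
        true_factors=cohort.true_factors,
        config=config,
        planted_outliers=planted,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write matrices, metadata and phenotypes as CSV plus a JSON sidecar
    recording the generating configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.input_matrix.write_csv(out / "input_matrix.csv")
    cohort.target_matrix.write_csv(out / "target_matrix.csv")
    cohort.feature_metadata.to_csv(out / "feature_metadata.csv", index=False)
    cohort.phenotypes.to_csv(out / "phenotypes.csv")
    cfg = dataclasses.asdict(cohort.config)
    cfg["class_names"] = list(cfg["class_names"]) if cfg["class_names"] else None
    cfg["outcome_effects"] = {k: list(v) for k, v in cfg["outcome_effects"].items()}
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=list)
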