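"""Feature filtering, outlier-sample removal, sample splitting and scaling.

The quality-control path mirrors common metabolomics practice: features that
are invariant or have more than 25% missing values are dropped, outlying
samples are flagged with the local outlier factor at default settings, and
matrices are affinely mapped into [-1, 1] using statistics estimated on the
training samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

__all__ = [
    "PlatformMatrix",
    "SampleSplit",
    "ScalerParams",
    "FilterReport",
    "filter_features",
    "detect_outlier_samples",
    "split_samples",
    "fit_scaler",
    "transform",
    "inverse_transform",
]


@dataclass
class PlatformMatrix:
    """Samples x features numeric matrix with an explicit observed mask.

    ``values`` holds NaN wherever ``observed_mask`` is False; observed
    entries are finite.
    """

    values: np.ndarray
    observed_mask: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    platform: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        if self.values.shape != self.observed_mask.shape:
            raise ValueError("values and observed_mask shapes differ")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("matrix shape inconsistent with id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if np.isnan(self.values[self.observed_mask]).any():
            raise ValueError("NaN at an observed entry")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, platform: str = "unknown") -> "PlatformMatrix":
        values = frame.to_numpy(dtype=np.float64)
        return cls(
            values=values,
            observed_mask=~np.isnan(values),
            sample_ids=[str(s) for s in frame.index],
            feature_ids=[str(f) for f in frame.columns],
            platform=platform,
        )

    def to_dataframe(self) -> pd.DataFrame:
        values = self.values.copy()
        values[~self.observed_mask] = np.nan
        return pd.DataFrame(values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def read_csv(cls, path, platform: str = "unknown") -> "PlatformMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls.from_dataframe(frame, platform=platform)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="sample_id")

    def select_samples(self, sample_ids: list[str]) -> "PlatformMatrix":
        index = [self.sample_ids.index(s) for s in sample_ids]
        return PlatformMatrix(
            values=self.values[index],
            observed_mask=self.observed_mask[index],
            sample_ids=list(sample_ids),
            feature_ids=self.feature_ids,
            platform=self.platform,
        )

    def select_features(self, feature_ids: list[str]) -> "PlatformMatrix":
        index = [self.feature_ids.index(f) for f in feature_ids]
        return PlatformMatrix(
            values=self.values[:, index],
            observed_mask=self.observed_mask[:, index],
            sample_ids=self.sample_ids,
            feature_ids=list(feature_ids),
            platform=self.platform,
        )


@dataclass
class SampleSplit:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        groups = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("split sets are not pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


@dataclass
class ScalerParams:
    """Per-feature affine map into [-1, 1] with clipping outside the range."""

    feature_ids: list[str]
    center: np.ndarray
    half_range: np.ndarray
    fitted_on: set[str] = field(default_factory=set)
    mode: str = "minmax"
    clip_bounds: tuple[float, float] = (-1.0, 1.0)


@dataclass
class FilterReport:
    removed: list[tuple[str, str]]  # (feature_id, reason)

    @property
    def removed_ids(self) -> list[str]:
        return [fid for fid, _ in self.removed]


def filter_features(
    matrix: PlatformMatrix, max_missing_frac: float = 0.25
) -> tuple[PlatformMatrix, FilterReport]:
    """Drop invariant features and features missing in more than
    ``max_missing_frac`` of samples (strict inequality)."""
    removed: list[tuple[str, str]] = []
    keep: list[str] = []
    for j, fid in enumerate(matrix.feature_ids):
        observed = matrix.observed_mask[:, j]
        missing_frac = 1.0 - observed.mean()
        if missing_frac > max_missing_frac:
            removed.append((fid, f"missing_frac={missing_frac:.3f}>{max_missing_frac}"))
            continue
        col = matrix.values[observed, j]
        if col.size == 0 or np.nanvar(col) == 0.0:
            removed.append((fid, "invariant"))
            continue
        keep.append(fid)
    if not keep:
        raise ValueError("all features removed by filtering")
    return matrix.select_features(keep), FilterReport(removed)


def detect_outlier_samples(matrix: PlatformMatrix, n_neighbors: int = 20) -> set[str]:
    """Flag samples with local outlier factor above the default threshold.

    Residual missing values are mean-completed per feature for the distance
    computation only.
    """
    if matrix.n_samples <= n_neighbors:
        raise ValueError(
            f"need more than n_neighbors={n_neighbors} samples, got {matrix.n_samples}"
        )
    x = matrix.values.copy()
    col_means = np.nanmean(np.where(matrix.observed_mask, x, np.nan), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    missing = ~matrix.observed_mask
    x[missing] = np.broadcast_to(col_means, x.shape)[missing]
    if np.allclose(x, x[0]):
        return set()
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    flags = lof.fit_predict(x)
    return {sid for sid, flag in zip(matrix.sample_ids, flags) if flag == -1}


def split_samples(
    sample_ids: list[str],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SampleSplit:
    """Randomly partition samples into train/val/test.

    Sizes follow floor-then-largest-remainder rounding, so the three sets
    always partition the input exactly.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(sample_ids)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainders = [r - s for r, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [sample_ids[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return SampleSplit(train, val, test, tuple(fractions), seed)


def fit_scaler(matrix: PlatformMatrix, train_ids: list[str], mode: str = "minmax") -> ScalerParams:
    """Fit per-feature scaling statistics on the training rows only.

    ``minmax`` maps the training min/max onto [-1, 1]; ``zscore-clipped``
    standardises by training mean/SD (values beyond one SD are clipped by
    :func:`transform`).
    """
    if mode not in ("minmax", "zscore-clipped"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    train = matrix.select_samples(train_ids)
    vals = np.where(train.observed_mask, train.values, np.nan)
    if mode == "minmax":
        lo = np.nanmin(vals, axis=0)
        hi = np.nanmax(vals, axis=0)
        center = (lo + hi) / 2.0
        half_range = (hi - lo) / 2.0
    else:
        center = np.nanmean(vals, axis=0)
        half_range = np.nanstd(vals, axis=0, ddof=1)
    if np.any(half_range <= 0.0) or np.any(~np.isfinite(half_range)):
        bad = [f for f, h in zip(matrix.feature_ids, half_range) if not h > 0.0]
        raise ValueError(f"zero half-range features (should have been filtered): {bad}")
    return ScalerParams(
        feature_ids=list(matrix.feature_ids),
        center=center,
        half_range=half_range,
        fitted_on=set(train_ids),
        mode=mode,
    )


def transform(matrix: PlatformMatrix, params: ScalerParams) -> PlatformMatrix:
    """Scale into [clip_bounds] using training statistics; out-of-range
    values (e.g. test rows beyond the training range) are clipped."""
    if list(matrix.feature_ids) != list(params.feature_ids):
        raise ValueError("feature ids do not match the fitted scaler")
    lo, hi = params.clip_bounds
    scaled = (matrix.values - params.center) / params.half_range
    scaled = np.clip(scaled, lo, hi)
    scaled[~matrix.observed_mask] = np.nan
    return PlatformMatrix(
        values=scaled,
        observed_mask=matrix.observed_mask.copy(),
        sample_ids=matrix.sample_ids,
        feature_ids=matrix.feature_ids,
        platform=matrix.platform,
    )


def inverse_transform(matrix: PlatformMatrix, params: ScalerParams) -> PlatformMatrix:
    if list(matrix.feature_ids) != list(params.feature_ids):
        raise ValueError("feature ids do not match the fitted scaler")
    raw = matrix.values * params.half_range + params.center
    raw[~matrix.observed_mask] = np.nan
    return PlatformMatrix(
        values=raw,
        observed_mask=matrix.observed_mask.copy(),
        sample_ids=matrix.sample_ids,
        feature_ids=matrix.feature_ids,
        platform=matrix.platform,
    )
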