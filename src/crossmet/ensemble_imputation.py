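"""Per-cluster + global model ensemble with greedy per-metabolite selection.

One autoencoder is trained per feature cluster (on that cluster's input and
target features only) plus one on the full panel; for every target
metabolite the candidate with the best validation imputation performance is
chosen greedily.  Repeated stochastic imputation cycles quantify
uncertainty: the first cycle gives a baseline R^2 per metabolite and the
variance of R^2 over the remaining cycles is the uncertainty measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_clustering import ClusterAssignment
from .iwae_core import IWAEConfig, TrainedIWAE, grid_search, impute, train
from .preprocess import PlatformMatrix, ScalerParams

__all__ = [
    "EnsembleModel",
    "SelectionTable",
    "ImputationEvaluation",
    "stack_platforms",
    "train_ensemble",
    "validation_metrics",
    "greedy_select",
    "impute_dataset",
    "evaluate_imputation",
    "select_well_imputed",
]

ALL_MODEL = "all"


def stack_platforms(input_matrix: PlatformMatrix, target_matrix: PlatformMatrix) -> PlatformMatrix:
    """Column-concatenate the two platforms over shared, ordered samples."""
    if input_matrix.sample_ids != target_matrix.sample_ids:
        raise ValueError("platform matrices must share sample ordering")
    return PlatformMatrix(
        values=np.hstack([input_matrix.values, target_matrix.values]),
        observed_mask=np.hstack([input_matrix.observed_mask, target_matrix.observed_mask]),
        sample_ids=input_matrix.sample_ids,
        feature_ids=input_matrix.feature_ids + target_matrix.feature_ids,
        platform="stacked",
    )


@dataclass
class EnsembleModel:
    models: dict[str, TrainedIWAE]  # keys: "cluster_<label>" and "all"
    cluster_assignment: ClusterAssignment
    scaler: ScalerParams
    feature_ids: list[str]
    target_ids: list[str]

    def __post_init__(self):
        if ALL_MODEL not in self.models:
            raise ValueError("ensemble must contain the 'all' model")
        covered = set()
        for key, trained in self.models.items():
            if key == ALL_MODEL:
                continue
            covered.update(trained.feature_ids)
        uncovered = [t for t in self.target_ids if t not in covered]
        if uncovered:
            warnings.warn(f"{len(uncovered)} target features covered only by the 'all' model")

    def candidates(self, metabolite: str) -> list[str]:
        """Model keys covering a target metabolite: its cluster's model (if
        trained) and the global model."""
        keys = [
            key
            for key, trained in self.models.items()
            if key != ALL_MODEL and metabolite in trained.feature_ids
        ]
        return keys + [ALL_MODEL]


@dataclass
class SelectionTable:
    table: pd.DataFrame  # index metabolite; chosen_model, metric_<key>..., margin, note
    metric: str = "r2"
    higher_is_better: bool = True

    @property
    def chosen(self) -> pd.Series:
        return self.table["chosen_model"]


@dataclass
class ImputationEvaluation:
    per_metabolite: pd.DataFrame  # index metabolite; baseline_r2, mean_r2, r2_variance
    per_sample_spearman: pd.Series
    n_cycles: int
    excluded: list[str] = field(default_factory=list)  # constant-truth columns


# --------------------------------------------------------------------- train
def _subset(
    x: np.ndarray, obs: np.ndarray, feature_ids: list[str], members: list[str]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    index = [feature_ids.index(f) for f in members]
    return x[:, index], obs[:, index], index


def train_ensemble(
    x_train: np.ndarray,
    obs_train: np.ndarray,
    x_val: np.ndarray,
    obs_val: np.ndarray,
    feature_ids: list[str],
    target_ids: list[str],
    clusters: ClusterAssignment,
    config: IWAEConfig,
    grid: list[IWAEConfig] | None = None,
    scaler: ScalerParams | None = None,
) -> EnsembleModel:
    """Train one model per cluster plus the global model.

    When ``grid`` is given each model is tuned independently by
    coarse-to-fine search; otherwise ``config`` is used as-is (cluster
    models get per-cluster seeds derived from it).
    """
    target_set = set(target_ids)
    models: dict[str, TrainedIWAE] = {}

    def _fit(members: list[str], key: str, seed_offset: int) -> TrainedIWAE | None:
        targets = [f for f in members if f in target_set]
        if not targets:
            warnings.warn(f"cluster {key} has no target-platform members; model skipped")
            return None
        xs, os_, _ = _subset(x_train, obs_train, feature_ids, members)
        xv, ov, _ = _subset(x_val, obs_val, feature_ids, members)
        tidx = np.array([members.index(t) for t in targets])
        cfg = IWAEConfig(**{**config.__dict__, "seed": config.seed + seed_offset})
        if grid:
            local = [IWAEConfig(**{**g.__dict__, "seed": g.seed + seed_offset}) for g in grid]
            cfg, _board = grid_search(xs, os_, xv, ov, members, tidx, local)
        return train(xs, os_, xv, ov, members, tidx, cfg)

    for offset, label in enumerate(sorted(set(int(l) for l in clusters.labels))):
        members = [f for f in clusters.members(label) if f in feature_ids]
        fitted = _fit(members, f"cluster_{label}", offset + 1)
        if fitted is not None:
            models[f"cluster_{label}"] = fitted
    fitted_all = _fit(list(feature_ids), ALL_MODEL, 0)
    if fitted_all is None:
        raise ValueError("no target-platform features in the panel")
    models[ALL_MODEL] = fitted_all
    return EnsembleModel(models, clusters, scaler, list(feature_ids), list(target_ids))


# ----------------------------------------------------------------- selection
def _per_feature_r2(imputed: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per column over masked entries."""
    out = np.full(truth.shape[1], np.nan)
    for j in range(truth.shape[1]):
        rows = mask[:, j]
        if rows.sum() < 3:
            continue
        a, b = imputed[rows, j], truth[rows, j]
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            continue
        out[j] = float(np.corrcoef(a, b)[0, 1] ** 2)
    return out


def validation_metrics(
    ensemble: EnsembleModel,
    x_val: np.ndarray,
    obs_val: np.ndarray,
    metric: str = "r2",
    L: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-metabolite validation performance of every covering model,
    computed by masking all target columns and imputing them back."""
    records: dict[str, dict[str, float]] = {t: {} for t in ensemble.target_ids}
    for key, trained in ensemble.models.items():
        members = trained.feature_ids
        xs, os_, _ = _subset(x_val, obs_val, ensemble.feature_ids, members)
        vis = os_.copy()
        vis[:, trained.target_idx] = False
        imputed = impute(trained, np.where(vis, xs, 0.0), vis, L=L, rng=np.random.default_rng(seed))
        targets = [members[i] for i in trained.target_idx]
        truth = xs[:, trained.target_idx]
        score_mask = os_[:, trained.target_idx]
        if metric == "r2":
            vals = _per_feature_r2(imputed[:, trained.target_idx], truth, score_mask)
        elif metric in ("mae", "mse"):
            diff = np.where(score_mask, imputed[:, trained.target_idx] - truth, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = (
                    np.nanmean(np.abs(diff), axis=0)
                    if metric == "mae"
                    else np.nanmean(diff**2, axis=0)
                )
        else:
            raise ValueError(f"unknown selection metric {metric!r}")
        for t, v in zip(targets, vals):
            if t in records:
                records[t][key] = float(v)
    frame = pd.DataFrame.from_dict(records, orient="index")
    frame.index.name = "metabolite"
    return frame


def greedy_select(
    metrics: pd.DataFrame, higher_is_better: bool = True, prefer: str | None = None
) -> SelectionTable:
    """Pick the best model per metabolite; exact ties prefer the
    cluster-specific (non-global) candidate."""
    rows = []
    for metabolite, row in metrics.iterrows():
        finite = row.dropna()
        finite = finite[np.isfinite(finite.values.astype(float))]
        if finite.empty:
            rows.append(
                {"metabolite": metabolite, "chosen_model": None, "margin": np.nan,
                 "note": "no finite metric; excluded"}
            )
            continue
        best = finite.max() if higher_is_better else finite.min()
        tied = [k for k, v in finite.items() if abs(v - best) < 1e-12]
        note = ""
        if len(tied) > 1:
            cluster_tied = [k for k in tied if k != ALL_MODEL]
            choice = (prefer if prefer in tied else None) or (
                cluster_tied[0] if cluster_tied else tied[0]
            )
            note = f"tie among {sorted(tied)}; preferred cluster model"
        else:
            choice = tied[0]
        others = finite.drop(choice)
        margin = float(
            (best - others.max()) if higher_is_better and not others.empty
            else (others.min() - best) if not others.empty
            else np.nan
        )
        rows.append(
            {"metabolite": metabolite, "chosen_model": choice, "margin": margin, "note": note}
        )
    table = pd.DataFrame(rows).set_index("metabolite")
    table = table.join(metrics.add_prefix("metric_"))
    return SelectionTable(table, higher_is_better=higher_is_better)


# ---------------------------------------------------------------- imputation
def impute_dataset(
    ensemble: EnsembleModel,
    selection: SelectionTable,
    x: np.ndarray,
    observed_mask: np.ndarray,
    n_cycles: int = 51,
    seed: int = 0,
    inverse_scale: bool = True,
    sample_ids: list[str] | None = None,
    L: int | None = None,
    sample_noise: bool = False,
) -> list[pd.DataFrame]:
    """Run ``n_cycles`` stochastic imputation cycles of the selected models.

    Target columns are force-masked before anything reaches a model, so
    observed target entries (evaluation mode) can never leak into the
    imputation inputs.  Returns one samples x selected-metabolites frame
    per cycle, in original units when a scaler is attached.
    """
    rng = np.random.default_rng(seed)
    feature_ids = ensemble.feature_ids
    target_cols = [feature_ids.index(t) for t in ensemble.target_ids]
    vis = np.asarray(observed_mask, bool).copy()
    vis[:, target_cols] = False
    x_masked = np.where(vis, x, 0.0)

    chosen = selection.chosen.dropna()
    by_model: dict[str, list[str]] = {}
    for metabolite, key in chosen.items():
        if key not in ensemble.models:
            raise ValueError(f"selected model {key!r} not in ensemble")
        by_model.setdefault(key, []).append(metabolite)

    cycles: list[pd.DataFrame] = []
    columns = list(chosen.index)
    for _cycle in range(n_cycles):
        out = pd.DataFrame(index=sample_ids or range(x.shape[0]), columns=columns, dtype=float)
        for key, metabolites in by_model.items():
            trained = ensemble.models[key]
            members = trained.feature_ids
            missing_inputs = [f for f in members if f not in feature_ids]
            if missing_inputs:
                raise ValueError(f"model {key} misses input features {missing_inputs}")
            xs, vs, _ = _subset(x_masked, vis, feature_ids, members)
            imputed = impute(trained, xs, vs, L=L, rng=rng, sample_noise=sample_noise)
            for metabolite in metabolites:
                out[metabolite] = imputed[:, members.index(metabolite)]
        if inverse_scale and ensemble.scaler is not None:
            sc = ensemble.scaler
            pos = [sc.feature_ids.index(m) for m in columns]
            out = out * sc.half_range[pos] + sc.center[pos]
        cycles.append(out)
    return cycles


# ---------------------------------------------------------------- evaluation
def _r2(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "squared-pearson":
        return float(np.corrcoef(a, b)[0, 1] ** 2)
    if method == "ss":  # 1 - SS_res / SS_tot, may be negative
        ss_tot = float(np.sum((b - b.mean()) ** 2))
        return float(1.0 - np.sum((a - b) ** 2) / ss_tot)
    raise ValueError(f"unknown r2 method {method!r}")


def evaluate_imputation(
    cycles: list[pd.DataFrame], truth: pd.DataFrame, r2_method: str = "squared-pearson"
) -> ImputationEvaluation:
    """Baseline R^2 from cycle 1; mean and variance of R^2 over cycles
    2..n; per-sample Spearman rho of the cycle-mean profile vs truth."""
    if not cycles:
        raise ValueError("no imputation cycles given")
    for frame in cycles:
        if list(frame.columns) != list(cycles[0].columns) or frame.shape != cycles[0].shape:
            raise ValueError("imputation cycles disagree in shape or columns")
    metabolites = [m for m in cycles[0].columns if m in truth.columns]
    if not metabolites:
        raise ValueError("truth shares no metabolites with the imputed cycles")
    truth = truth.loc[cycles[0].index, metabolites]

    excluded = [m for m in metabolites if truth[m].std() == 0.0]
    kept = [m for m in metabolites if m not in excluded]
    rows = []
    for m in kept:
        t = truth[m].to_numpy()
        baseline = _r2(cycles[0][m].to_numpy(), t, r2_method)
        if len(cycles) > 1:
            r2s = np.array([_r2(c[m].to_numpy(), t, r2_method) for c in cycles[1:]])
            mean_r2, r2_var = float(r2s.mean()), float(r2s.var(ddof=1)) if len(r2s) > 1 else 0.0
        else:
            mean_r2, r2_var = np.nan, np.nan
        rows.append(
            {"metabolite": m, "baseline_r2": baseline, "mean_r2": mean_r2, "r2_variance": r2_var}
        )
    per_metabolite = pd.DataFrame(rows).set_index("metabolite")

    profile_cycles = cycles[1:] if len(cycles) > 1 else cycles
    mean_imputed = sum(c[kept] for c in profile_cycles) / len(profile_cycles)
    rhos = {}
    for sid in truth.index:
        a = mean_imputed.loc[sid].to_numpy(dtype=float)
        b = truth.loc[sid, kept].to_numpy(dtype=float)
        rhos[sid] = float(stats.spearmanr(a, b).statistic) if len(kept) > 2 else np.nan
    return ImputationEvaluation(
        per_metabolite=per_metabolite,
        per_sample_spearman=pd.Series(rhos, name="spearman_rho"),
        n_cycles=len(cycles),
        excluded=excluded,
    )


def select_well_imputed(
    evaluation: ImputationEvaluation,
    feature_metadata: pd.DataFrame | None = None,
    r2_min: float = 0.55,
    var_max: float = 0.025,
) -> tuple[set[str], pd.DataFrame | None, set[str]]:
    """Metabolites with baseline R^2 >= r2_min and R^2 variance <= var_max.

    Returns (selected set, per-superclass summary, selected metabolites
    with no same-annotation input feature)."""
    pm = evaluation.per_metabolite
    mask = (pm["baseline_r2"] >= r2_min) & (pm["r2_variance"] <= var_max)
    selected = set(pm.index[mask])
    if feature_metadata is None:
        return selected, None, set()
    meta = feature_metadata.set_index("feature_id")
    input_annotations = set(
        feature_metadata.loc[feature_metadata["platform"] == "input", "annotation"]
    )
    unique = {
        m for m in selected
        if m in meta.index and meta.loc[m, "annotation"] not in input_annotations
    }
    known = [m for m in pm.index if m in meta.index]
    summary = (
        pm.loc[known]
        .join(meta.loc[known, ["compound_class"]])
        .groupby("compound_class")["baseline_r2"]
        .agg(mean_r2="mean", sd_r2="std", n="count")
        .reset_index()
    )
    return selected, summary, unique
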