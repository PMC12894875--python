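import numpy as np
import pandas as pd
import pytest

from crossmet import synthetic_data as sd
from crossmet.ensemble_imputation import (
    ALL_MODEL,
    ImputationEvaluation,
    evaluate_imputation,
    greedy_select,
    impute_dataset,
    select_well_imputed,
    stack_platforms,
    train_ensemble,
    validation_metrics,
)
from crossmet.feature_clustering import ClusterAssignment
from crossmet.iwae_core import IWAEConfig

from conftest import SMALL_IWAE, prepare_cohort


# ------------------------------------------------------------------ ensemble
def test_ensemble_has_one_model_per_cluster_plus_all(pipeline_run):
    models = pipeline_run.ensemble.models
    assert set(models) == {"cluster_0", "cluster_1", "cluster_2", ALL_MODEL}
    for metabolite in pipeline_run.ensemble.target_ids:
        keys = pipeline_run.ensemble.candidates(metabolite)
        assert ALL_MODEL in keys and len(keys) == 2


def test_degenerate_single_cluster_equals_all_model():
    config = sd.CohortConfig(n_samples=120, n_classes=1, n_input_per_class=6,
                             n_target_per_class=3, seed=1)
    data = prepare_cohort(sd.generate_cohort(config), seed=0)
    clusters = ClusterAssignment(
        data.feature_ids, np.zeros((len(data.feature_ids), 2)),
        np.zeros(len(data.feature_ids), int), k=1, cluster_names={0: "all-in-one"},
    )
    iwae = IWAEConfig(seed=0, **{**SMALL_IWAE, "max_epochs": 5})
    ensemble = train_ensemble(
        data.train.values, data.train.observed_mask,
        data.val.values, data.val.observed_mask,
        data.feature_ids, data.target_ids, clusters, iwae,
    )
    assert ensemble.models["cluster_0"].feature_ids == ensemble.models[ALL_MODEL].feature_ids


def test_cluster_without_targets_skipped_with_warning():
    config = sd.CohortConfig(n_samples=120, n_classes=2, n_input_per_class=6,
                             n_target_per_class=3, seed=2)
    data = prepare_cohort(sd.generate_cohort(config), seed=0)
    labels = np.array(
        [2 if f.startswith("IN_c0") else (0 if "c0" in f else 1) for f in data.feature_ids]
    )
    clusters = ClusterAssignment(
        data.feature_ids, np.zeros((len(labels), 2)), labels, k=3,
        cluster_names={0: "a", 1: "b", 2: "inputs-only"},
    )
    iwae = IWAEConfig(seed=0, **{**SMALL_IWAE, "max_epochs": 3})
    with pytest.warns(UserWarning, match="no target-platform members"):
        ensemble = train_ensemble(
            data.train.values, data.train.observed_mask,
            data.val.values, data.val.observed_mask,
            data.feature_ids, data.target_ids, clusters, iwae,
        )
    assert "cluster_2" not in ensemble.models


def test_cluster_model_no_worse_than_all_on_own_targets(pipeline_run):
    # class-c targets depend only on class-c inputs; the information-restricted
    # cluster model should match or beat the global model on them on average
    metrics = pipeline_run.metrics
    for label in (0, 1):
        members = pipeline_run.clusters.members(label)
        targets = [m for m in members if m in metrics.index]
        sub = metrics.loc[targets]
        assert sub[f"cluster_{label}"].mean() >= sub[ALL_MODEL].mean() - 0.02


# ---------------------------------------------------------------- selection
def test_greedy_select_prefers_higher_r2():
    metrics = pd.DataFrame({"cluster_0": [0.6], ALL_MODEL: [0.4]}, index=["m1"])
    table = greedy_select(metrics)
    assert table.chosen["m1"] == "cluster_0"


def test_greedy_select_tie_prefers_cluster_model():
    metrics = pd.DataFrame({ALL_MODEL: [0.5], "cluster_1": [0.5]}, index=["m1"])
    table = greedy_select(metrics)
    assert table.chosen["m1"] == "cluster_1"
    assert "tie" in table.table.loc["m1", "note"]


def test_greedy_select_excludes_all_nan_metabolite():
    metrics = pd.DataFrame(
        {"cluster_0": [np.nan, 0.3], ALL_MODEL: [np.nan, 0.2]}, index=["bad", "ok"]
    )
    table = greedy_select(metrics)
    assert table.chosen["bad"] is None
    assert "excluded" in table.table.loc["bad", "note"]
    assert table.chosen["ok"] == "cluster_0"


def test_greedy_select_lower_is_better_mode():
    metrics = pd.DataFrame({"cluster_0": [0.2], ALL_MODEL: [0.1]}, index=["m1"])
    table = greedy_select(metrics, higher_is_better=False)
    assert table.chosen["m1"] == ALL_MODEL


def test_greedy_dominance_exact(pipeline_run):
    # the selected model is >= every candidate on the selection metric
    metrics = pipeline_run.metrics
    for metabolite, key in pipeline_run.selection.chosen.items():
        row = metrics.loc[metabolite].dropna()
        assert metrics.loc[metabolite, key] >= row.max() - 1e-12


# --------------------------------------------------------------- imputation
def test_single_cycle_deterministic(pipeline_run):
    run = pipeline_run
    kwargs = dict(
        ensemble=run.ensemble, selection=run.selection,
        x=run.data.test.values, observed_mask=run.data.test.observed_mask,
        n_cycles=1, seed=99, sample_ids=run.data.test.sample_ids,
    )
    a = impute_dataset(**kwargs)[0]
    b = impute_dataset(**kwargs)[0]
    pd.testing.assert_frame_equal(a, b)


def test_observed_target_entries_cannot_leak(pipeline_run):
    run = pipeline_run
    x = run.data.test.values.copy()
    target_cols = [run.data.feature_ids.index(t) for t in run.data.target_ids]
    rng = np.random.default_rng(0)
    x[:, target_cols] = rng.permutation(x[:, target_cols], axis=0)  # scramble truth
    scrambled = impute_dataset(
        run.ensemble, run.selection, x, run.data.test.observed_mask,
        n_cycles=1, seed=5, sample_ids=run.data.test.sample_ids,
    )[0]
    original = impute_dataset(
        run.ensemble, run.selection, run.data.test.values, run.data.test.observed_mask,
        n_cycles=1, seed=5, sample_ids=run.data.test.sample_ids,
    )[0]
    pd.testing.assert_frame_equal(scrambled, original)


def test_default_cycle_count_matches_contract():
    import inspect

    assert inspect.signature(impute_dataset).parameters["n_cycles"].default == 51


def test_imputed_values_in_original_units(pipeline_run):
    run = pipeline_run
    sc = run.ensemble.scaler
    cols = list(run.selection.chosen.index)
    pos = [sc.feature_ids.index(c) for c in cols]
    lo = sc.center[pos] - sc.half_range[pos]
    hi = sc.center[pos] + sc.half_range[pos]
    values = run.cycles[0][cols].to_numpy()
    assert (values >= lo - 1e-9).all() and (values <= hi + 1e-9).all()


# --------------------------------------------------------------- evaluation
def _toy_cycles(n_cycles=5, n=30, d=4, seed=0):
    rng = np.random.default_rng(seed)
    truth = pd.DataFrame(rng.standard_normal((n, d)),
                         columns=[f"m{j}" for j in range(d)])
    cycles = [truth + 0.1 * rng.standard_normal((n, d)) for _ in range(n_cycles)]
    return cycles, truth


def test_perfect_imputation_identities():
    _, truth = _toy_cycles()
    cycles = [truth.copy() for _ in range(5)]
    ev = evaluate_imputation(cycles, truth)
    assert np.allclose(ev.per_metabolite["baseline_r2"], 1.0)
    assert np.allclose(ev.per_metabolite["mean_r2"], 1.0)
    assert np.allclose(ev.per_metabolite["r2_variance"], 0.0)
    assert np.allclose(ev.per_sample_spearman, 1.0)


def test_pure_noise_r2_matches_null_expectation():
    # E[r^2] under independence = 1/(n-1)
    n = 200
    rng = np.random.default_rng(1)
    truth = pd.DataFrame(rng.standard_normal((n, 400)),
                         columns=[f"m{j}" for j in range(400)])
    noise = pd.DataFrame(rng.standard_normal((n, 400)), columns=truth.columns)
    ev = evaluate_imputation([noise], truth)
    mean_r2 = ev.per_metabolite["baseline_r2"].mean()
    assert abs(mean_r2 - 1.0 / (n - 1)) < 0.002


def test_constant_truth_column_excluded():
    cycles, truth = _toy_cycles()
    truth["m0"] = 3.0
    ev = evaluate_imputation(cycles, truth)
    assert ev.excluded == ["m0"]
    assert "m0" not in ev.per_metabolite.index


def test_cycle_exchangeability(pipeline_run):
    run = pipeline_run
    rng = np.random.default_rng(2)
    shuffled = [run.cycles[0]] + [run.cycles[1:][i] for i in rng.permutation(10)]
    ev = evaluate_imputation(shuffled, run.truth_raw)
    base = run.evaluation.per_metabolite
    np.testing.assert_allclose(ev.per_metabolite["mean_r2"], base["mean_r2"], atol=1e-12)
    np.testing.assert_allclose(ev.per_metabolite["r2_variance"], base["r2_variance"], atol=1e-12)


def test_uncertainty_inversely_related_to_performance():
    # weakly imputed metabolites must owe their weakness to uninformative
    # inputs (few input features per class) for cycle-to-cycle instability to
    # rise as performance falls; single-draw cycles expose that instability
    from scipy.stats import spearmanr

    from crossmet.iwae_core import IWAEConfig

    config = sd.CohortConfig(
        n_samples=450, n_classes=3, n_input_per_class=(12, 4, 1),
        n_target_per_class=5, cross_platform_loading=(0.85, 0.7, 0.85),
        noise_sd=0.6, seed=17,
    )
    cohort = sd.generate_cohort(config)
    data = prepare_cohort(cohort, seed=5)
    classes = cohort.feature_metadata.set_index("feature_id")["compound_class"]
    class_names = [config.class_name(c) for c in range(3)]
    labels = np.array([class_names.index(classes[f]) for f in data.feature_ids])
    clusters = ClusterAssignment(
        data.feature_ids, np.column_stack([labels, labels]).astype(float),
        labels, 3, dict(enumerate(class_names)),
    )
    iwae = IWAEConfig(seed=3, **{
        **SMALL_IWAE, "max_epochs": 120, "patience": 15, "latent_dim": 6,
        "encoder_widths": (48,), "decoder_widths": (48,),
    })
    ensemble = train_ensemble(
        data.train.values, data.train.observed_mask,
        data.val.values, data.val.observed_mask,
        data.feature_ids, data.target_ids, clusters, iwae, scaler=data.scaler,
    )
    metrics = validation_metrics(ensemble, data.val.values, data.val.observed_mask, seed=2)
    selection = greedy_select(metrics)
    cycles = impute_dataset(
        ensemble, selection, data.test.values, data.test.observed_mask,
        n_cycles=21, seed=11, sample_ids=data.test.sample_ids, L=1,
    )
    truth = (
        data.stacked.select_samples(data.test.sample_ids)
        .to_dataframe()[list(selection.chosen.index)]
    )
    pm = evaluate_imputation(cycles, truth).per_metabolite
    rho = spearmanr(pm["mean_r2"], pm["r2_variance"]).statistic
    assert rho < 0


def test_per_class_r2_ranking_matches_planted_loadings(pipeline_run):
    run = pipeline_run
    classes = run.cohort.feature_metadata.set_index("feature_id")["compound_class"]
    pm = run.evaluation.per_metabolite
    means = pm.join(classes).groupby("compound_class")["mean_r2"].mean()
    by_lam = [means[run.config.class_name(c)] for c in range(3)]
    assert by_lam[0] > by_lam[1] > by_lam[2]  # lambda^2 ranking 0.81 > 0.49 > 0.09


# ----------------------------------------------------------- well-imputed set
def eval_from_frame(frame):
    return ImputationEvaluation(frame, pd.Series(dtype=float), n_cycles=11)


def test_threshold_rule_application():
    frame = pd.DataFrame(
        {"baseline_r2": [0.60, 0.60, 0.50], "mean_r2": [0.6, 0.6, 0.5],
         "r2_variance": [0.01, 0.03, 0.01]},
        index=["keep", "too-uncertain", "too-weak"],
    )
    selected, _, _ = select_well_imputed(eval_from_frame(frame))
    assert selected == {"keep"}


def test_default_thresholds():
    import inspect

    sig = inspect.signature(select_well_imputed)
    assert sig.parameters["r2_min"].default == 0.55
    assert sig.parameters["var_max"].default == 0.025


def test_selection_set_monotonicity(pipeline_run):
    ev = pipeline_run.evaluation
    base, _, _ = select_well_imputed(ev, r2_min=0.3, var_max=0.05)
    stricter_r2, _, _ = select_well_imputed(ev, r2_min=0.5, var_max=0.05)
    stricter_var, _, _ = select_well_imputed(ev, r2_min=0.3, var_max=0.01)
    assert stricter_r2 <= base
    assert stricter_var <= base


def test_superclass_summary_and_unique_targets(pipeline_run):
    run = pipeline_run
    selected, summary, unique = select_well_imputed(
        run.evaluation, run.cohort.feature_metadata, r2_min=0.3, var_max=0.1
    )
    assert set(summary["compound_class"]) <= {
        run.config.class_name(c) for c in range(3)
    }
    meta = run.cohort.feature_metadata.set_index("feature_id")
    for m in unique:
        assert meta.loc[m, "annotation"].startswith("unique")
    # annotated targets share annotations with input features -> not unique
    assert all(not meta.loc[m, "annotation"].startswith("anno") for m in unique)
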