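"""Shared fixtures: small synthetic cohorts and pre-trained models reused
across the suite to keep runtime inside the CI budget."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from crossmet import synthetic_data as sd
from crossmet.ensemble_imputation import stack_platforms
from crossmet.iwae_core import IWAEConfig, train
from crossmet.preprocess import fit_scaler, split_samples, transform


def prepare_cohort(cohort: sd.SyntheticCohort, seed: int = 0) -> SimpleNamespace:
    """Stack platforms, split, fit the scaler on train rows, scale all."""
    stacked = stack_platforms(cohort.input_matrix, cohort.target_matrix)
    split = split_samples(stacked.sample_ids, seed=seed)
    scaler = fit_scaler(stacked, split.train_ids)
    scaled = transform(stacked, scaler)
    target_ids = cohort.target_matrix.feature_ids
    return SimpleNamespace(
        cohort=cohort,
        stacked=stacked,
        split=split,
        scaler=scaler,
        scaled=scaled,
        train=scaled.select_samples(split.train_ids),
        val=scaled.select_samples(split.val_ids),
        test=scaled.select_samples(split.test_ids),
        feature_ids=stacked.feature_ids,
        target_ids=target_ids,
        target_idx=np.array([stacked.feature_ids.index(f) for f in target_ids]),
    )


SMALL_IWAE = dict(
    latent_dim=4,
    encoder_widths=(32,),
    decoder_widths=(32,),
    K=5,
    L=30,
    value_mask_rate=0.3,
    target_mask_rate=0.5,
    learning_rate=3e-3,
    batch_size=64,
    max_epochs=150,
    patience=15,
)


@pytest.fixture(scope="session")
def noisy_linear_data():
    """Two-class shared-factor cohort with moderate noise, scaled + split."""
    config = sd.CohortConfig(
        n_samples=400, n_classes=2, n_input_per_class=8, n_target_per_class=4,
        cross_platform_loading=0.9, noise_sd=0.2, seed=1,
    )
    return prepare_cohort(sd.generate_cohort(config), seed=0)


@pytest.fixture(scope="session")
def noisefree_linear_data():
    """Noise-free cohort: targets are exact linear functions of inputs."""
    config = sd.CohortConfig(
        n_samples=400, n_classes=2, n_input_per_class=8, n_target_per_class=4,
        cross_platform_loading=1.0, noise_sd=0.0, seed=1,
    )
    return prepare_cohort(sd.generate_cohort(config), seed=0)


@pytest.fixture(scope="session")
def pipeline_run():
    """Full ensemble pipeline on a 3-class cohort with per-class loadings
    (0.9, 0.7, 0.3): train per-cluster + global models, select greedily,
    run imputation cycles on the test split and evaluate."""
    import pandas as pd

    from crossmet.ensemble_imputation import (
        evaluate_imputation,
        greedy_select,
        impute_dataset,
        train_ensemble,
        validation_metrics,
    )
    from crossmet.feature_clustering import ClusterAssignment

    lams = (0.9, 0.7, 0.3)
    config = sd.CohortConfig(
        n_samples=450, n_classes=3, n_input_per_class=10, n_target_per_class=5,
        cross_platform_loading=lams, noise_sd=0.3, annotated_frac=0.6, seed=17,
        outcome_effects={"BMI": (0.25, 0.2, 0.15), "CRP": (0.1, 0.2, 0.05)},
    )
    cohort = sd.generate_cohort(config)
    data = prepare_cohort(cohort, seed=5)
    classes = cohort.feature_metadata.set_index("feature_id")["compound_class"]
    class_names = [config.class_name(c) for c in range(3)]
    labels = np.array([class_names.index(classes[f]) for f in data.feature_ids])
    clusters = ClusterAssignment(
        feature_ids=data.feature_ids,
        coords=np.column_stack([labels, labels]).astype(float),
        labels=labels,
        k=3,
        cluster_names=dict(enumerate(class_names)),
    )
    iwae = IWAEConfig(seed=3, **{
        **SMALL_IWAE, "max_epochs": 150, "patience": 20, "latent_dim": 6,
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
        n_cycles=11, seed=11, sample_ids=data.test.sample_ids,
    )
    truth_scaled = data.test.to_dataframe()[list(selection.chosen.index)]
    truth_raw = (
        data.stacked.select_samples(data.test.sample_ids)
        .to_dataframe()[list(selection.chosen.index)]
    )
    evaluation = evaluate_imputation(cycles, truth_raw)
    return SimpleNamespace(
        lams=lams, config=config, cohort=cohort, data=data, clusters=clusters,
        ensemble=ensemble, metrics=metrics, selection=selection, cycles=cycles,
        truth_raw=truth_raw, truth_scaled=truth_scaled, evaluation=evaluation,
    )


@pytest.fixture(scope="session")
def trained_small_model(noisy_linear_data):
    data = noisy_linear_data
    config = IWAEConfig(seed=0, **SMALL_IWAE)
    return train(
        data.train.values, data.train.observed_mask,
        data.val.values, data.val.observed_mask,
        data.feature_ids, data.target_idx, config,
    )
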