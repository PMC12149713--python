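"""End-to-end orchestration of the habitat-imaging pipeline on a cohort.

Chains all stages on a (synthetic or loaded) patient cohort:

1. voxelwise IVIM fitting of every patient's tumor;
2. pooled K-means habitat clustering fit on training-set voxels and applied
   to every patient;
3. habitat feature extraction (volumes, volume ratios, first-order
   statistics of the selected channels);
4. staged feature selection on the training rows only;
5. training of the requested model variant and scoring of the held-out
   test set;
6. ROC evaluation of the test scores.

Test-set information never enters clustering, normalization or selection:
those are fit on training patients and applied frozen to the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, features, habitats, ivim, models, phantom, selection

__all__ = ["PipelineResult", "fit_cohort_maps", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    cluster_model: habitats.HabitatClusterModel
    feature_table: pd.DataFrame
    selection_report: selection.SelectionReport
    fitted_model: models.FittedModel
    scores_train: np.ndarray
    scores_test: np.ndarray
    roc_train: evaluation.ROCResult
    roc_test: evaluation.ROCResult
    manifest: pd.DataFrame
    extras: dict = field(default_factory=dict)


def fit_cohort_maps(phantoms, config: ivim.FitConfig | None = None):
    """IVIM maps for every phantom of a cohort."""
    return [ivim.fit_volume(ph.signal, ph.mask, ph.bscheme, config)
            for ph in phantoms]


def run_pipeline(phantoms, manifest: pd.DataFrame, *, channels=("f", "D"),
                 K: int = 3, variant: str = "Habitats", classifier: str = "logistic",
                 covariates: pd.DataFrame | None = None, rfe_target: int | None = 6,
                 seed: int = 0, fit_config: ivim.FitConfig | None = None,
                 maps_list=None) -> PipelineResult:
    """Run the full pipeline on a cohort of phantoms with a manifest.

    ``manifest`` must carry patient_id, outcome and split columns aligned
    with ``phantoms``.  Precomputed IVIM maps may be passed via
    ``maps_list`` to avoid refitting.  ``covariates`` supplies the CF/IHC
    blocks for combined variants.
    """
    manifest = manifest.reset_index(drop=True)
    if maps_list is None:
        maps_list = fit_cohort_maps(phantoms, fit_config)
    train_idx = manifest.index[manifest["split"] == "train"].to_numpy()
    test_idx = manifest.index[manifest["split"] == "test"].to_numpy()
    pids = manifest["patient_id"].to_numpy()

    # pooled clustering on training voxels only
    voxels = habitats.pool_voxels([maps_list[i] for i in train_idx], channels,
                                  patient_ids=[pids[i] for i in train_idx])
    cluster_model = habitats.fit_clusters(voxels, K=K, seed=seed)

    cases = []
    for i, ph in enumerate(phantoms):
        labels = habitats.assign_labels(maps_list[i], ph.mask, cluster_model)
        cases.append({"patient_id": pids[i], "maps": maps_list[i],
                      "labels": labels, "outcome": int(manifest["outcome"][i]),
                      "split": manifest["split"][i]})
    needed = set(variant.split("+"))
    table = features.build_feature_table(
        cases, K=K, channels=channels,
        voxel_volume=phantoms[0].voxel_volume,
        include_whole="WH" in needed)

    y = table["outcome"].to_numpy()
    feat_cols = features.feature_columns(table)
    train_mask = (table["split"] == "train").to_numpy()
    whole_cols = [c for c in feat_cols if "whole" in c]
    habitat_cols = [c for c in feat_cols if "whole" not in c]

    blocks, report, norm = {}, None, None
    for block_name, cols in (("Habitats", habitat_cols), ("WH", whole_cols)):
        if block_name not in needed or not cols:
            continue
        rep, nrm = selection.run_selection(
            table.loc[train_mask, cols], y[train_mask],
            rfe_target=rfe_target, seed=seed)
        X_all = table[cols].fillna(table.loc[train_mask, cols].median())
        blocks[block_name] = nrm.transform(X_all)[rep.selected]
        if report is None:  # primary radiomic block's report is surfaced
            report, norm = rep, nrm
    if covariates is not None:
        cov = covariates.set_index(table.index)
        blocks["CF"] = cov[[c for c in models.CF_FEATURES if c in cov.columns]]
        blocks["IHC"] = cov[[c for c in models.IHC_FEATURES if c in cov.columns]]
    X_model = models.assemble_variant(variant, blocks)

    spec = models.ModelSpec(variant=variant, classifier=classifier, seed=seed)
    fitted = models.train_classifier(X_model[train_mask], y[train_mask], spec)
    s_train = models.predict_scores(fitted, X_model[train_mask])
    s_test = models.predict_scores(fitted, X_model[~train_mask])
    roc_train = evaluation.roc_auc(s_train, y[train_mask])
    roc_test = evaluation.roc_auc(s_test, y[~train_mask])
    return PipelineResult(cluster_model=cluster_model, feature_table=table,
                          selection_report=report, fitted_model=fitted,
                          scores_train=s_train, scores_test=s_test,
                          roc_train=roc_train, roc_test=roc_test,
                          manifest=manifest)
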