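"""End-to-end orchestration of the two-stage clustering pipeline.

Given a cohort of normalized envelopes with a typically-developed (TD)
reference group, runs: feature extraction -> TD-referenced norm-distance
standardization (patients only) -> per-feature PSO/K-means labelling ->
PCA + Ward hierarchical clustering with a dendrogram-gap cut -> cluster
characterization.  This is the programmatic surface behind the CLI and
the recovery simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import features, stage1, stage2
from .synthetic import SyntheticCohort

TD_LABEL = "TD"


@dataclass
class PipelineResult:
    """Everything the two-stage run produces, in execution order."""

    feature_matrix: pd.DataFrame
    td_reference: features.TDReference
    nd: features.NormalizedFeatureMatrix
    label_matrix: stage1.LabelMatrix
    reduction: stage2.PcaReduction
    tree: stage2.MergeTree
    assignment: stage2.ClusterAssignment
    report: pd.DataFrame
    patient_ids: list


def run_two_stage(envelopes: pd.DataFrame, clinical: pd.DataFrame | None = None,
                  td_group: str = TD_LABEL, seed: int = 0,
                  pso: stage1.PsoConfig | None = None,
                  var_threshold: float = stage2.VAR_THRESHOLD,
                  linkage_method: str = "ward", k_max: int = 10) -> PipelineResult:
    """Run the full two-stage clustering on a wide envelope cohort frame.

    Rows with ``group_true == td_group`` form the TD reference and are
    excluded from clustering; all remaining rows are treated as patients.
    """
    fm = features.extract_feature_matrix(envelopes)
    is_td = (envelopes["group_true"] == td_group).to_numpy()
    if is_td.sum() < 2:
        raise ValueError("need at least 2 TD subjects for the reference")
    td_ref = features.build_td_reference(fm[is_td])
    patients = fm[~is_td]
    nd = features.normalize_features(patients, td_ref)
    cfg = pso if pso is not None else stage1.PsoConfig(seed=seed)
    lm = stage1.build_label_matrix(nd, cfg)
    red = stage2.reduce_dimensions(lm.labels, var_threshold=var_threshold)
    tree = stage2.hierarchical_cluster(red.scores, method=linkage_method)
    assignment = stage2.cut_dendrogram(tree, k_max=k_max)
    patient_envelopes = envelopes.loc[~is_td].reset_index(drop=True)
    patient_clinical = None
    if clinical is not None:
        patient_clinical = clinical.loc[
            clinical["group_true"] != td_group].reset_index(drop=True)
    report = stage2.characterize_clusters(assignment, patient_envelopes,
                                          patient_clinical)
    return PipelineResult(feature_matrix=fm, td_reference=td_ref, nd=nd,
                          label_matrix=lm, reduction=red, tree=tree,
                          assignment=assignment, report=report,
                          patient_ids=list(patients.index))


def run_on_cohort(cohort: SyntheticCohort, **kwargs) -> PipelineResult:
    """Convenience wrapper for synthetic cohorts."""
    return run_two_stage(cohort.envelopes, cohort.clinical, **kwargs)
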