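"""Responder sub-clustering from pre/post-treatment change scores.

Patients of the pathological-gait cluster with paired gait-laboratory
examinations (E1 pre-, E2 post-treatment) are stratified by the first
principal component of the *change matrix* dE = parameters@E2 -
parameters@E1 over seven frontal-plane outcome parameters (trunk and
pelvic obliquity RoM, peak hip abduction angle and moment in mid-stance,
and the mean/min/max EMG summaries).  Because the columns mix degrees,
Nm/kg and percent-of-mean units they are standardized before the PCA
(disable with ``scale=False`` for sensitivity checks).  The PC1 sign is
oriented so that a *decrease* in trunk-obliquity RoM — the hallmark of an
improved Duchenne pattern — contributes positively; subjects with a
positive score form SUB_1 (responders), negative scores SUB_2, and exact
zeros are left unassigned.

Group comparisons use the Kruskal-Wallis rank test (for two groups,
equivalent to a rank-sum test), computed here with tie correction and a
chi-square reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, MissingExamError
from .synthetic import CLIN_COLUMNS, EMG_COLUMNS, OUTCOME_PARAMS

logger = logging.getLogger(__name__)

DELTA_COLUMNS = OUTCOME_PARAMS + EMG_COLUMNS

DISTAL_SURGERIES = ["baumann", "strayer", "bony_foot", "tibialis_posterior_lengthening"]
PROXIMAL_SURGERIES = ["femoral_derotation", "rectus_transfer", "hamstring_lengthening"]


@dataclass
class ChangeMatrix:
    """Subjects x parameters matrix of E2 - E1 differences."""

    delta: pd.DataFrame


@dataclass
class SubclusterResult:
    """PC1 scores, SUB labels and the sign-orientation record."""

    pc1_scores: pd.Series
    labels: pd.Series            # SUB_1 | SUB_2 | unassigned
    loadings: pd.Series
    flipped: bool
    dropped_columns: list[str] = field(default_factory=list)


def build_change_matrix(e1: pd.DataFrame, e2: pd.DataFrame,
                        columns: list[str] | None = None) -> ChangeMatrix:
    """Columnwise E2 - E1 differences, subjects aligned by id."""
    if columns is None:
        columns = DELTA_COLUMNS
    a = e1.set_index("subject_id")
    b = e2.set_index("subject_id")
    unpaired = sorted(set(a.index).symmetric_difference(b.index))
    if unpaired:
        raise MissingExamError(f"subjects without both examinations: {unpaired}")
    if a.index.has_duplicates or b.index.has_duplicates:
        raise MissingExamError("duplicate examination records for some subject")
    delta = b.loc[a.index, columns].astype(float) - a[columns].astype(float)
    if not np.all(np.isfinite(delta.to_numpy())):
        raise ValueError("change matrix contains non-finite entries")
    return ChangeMatrix(delta=delta)


def pca_subcluster(change: ChangeMatrix, scale: bool = True) -> SubclusterResult:
    """Split subjects by the sign of the oriented first PC score of dE."""
    delta = change.delta
    if len(delta) < 3:
        raise ValueError("sub-clustering needs at least 3 subjects")
    X = delta.to_numpy(dtype=float)
    if np.allclose(X, 0.0):
        raise DegenerateInputError("change matrix is identically zero")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(delta.columns, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance change columns: %s", dropped)
    cols = [c for c, k in zip(delta.columns, keep) if k]
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    if scale:
        Xc = Xc / sd[keep]
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Xc)[:, 0]
    loadings = pca.components_[0]
    flipped = False
    trunk = cols.index("rom_trunk_obl") if "rom_trunk_obl" in cols else None
    if trunk is not None and loadings[trunk] > 0:
        scores, loadings, flipped = -scores, -loadings, True
    labels = np.where(scores > 0, "SUB_1", np.where(scores < 0, "SUB_2", "unassigned"))
    if (labels == "unassigned").any():
        logger.warning("%d subject(s) with exactly zero PC1 score left unassigned",
                       (labels == "unassigned").sum())
    return SubclusterResult(
        pc1_scores=pd.Series(scores, index=delta.index, name="pc1_score"),
        labels=pd.Series(labels, index=delta.index, name="subcluster"),
        loadings=pd.Series(loadings, index=cols, name="pc1_loading"),
        flipped=flipped,
        dropped_columns=dropped,
    )


def kruskal_wallis(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kruskal-Wallis H with tie correction, chi-square p (1 df).

    All-identical pooled values give (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    n = len(pooled)
    if np.all(pooled == pooled[0]):
        logger.warning("all values identical; Kruskal-Wallis p set to 1")
        return 0.0, 1.0
    ranks = rankdata(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (ranks[idx].mean() - (n + 1) / 2.0) ** 2
        for g, idx in ((a, slice(0, len(a))), (b, slice(len(a), n)))
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    h /= tie
    return float(h), float(chi2.sf(h, df=1))


def compare_within_and_between(sub: SubclusterResult, e1: pd.DataFrame,
                               e2: pd.DataFrame, alpha: float = 0.05
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Statistical characterization of the sub-clusters.

    Returns ``(within, between)``: *within* compares E1 vs E2 per group
    for the four kinematic/kinetic parameters (mean (SD) at each
    examination plus the Kruskal-Wallis p); *between* compares SUB_1 vs
    SUB_2 at E1 for the three swing-window EMG summaries and the four
    clinical-exam scalars.  Groups with fewer than two members yield NA
    test results.
    """
    a1 = e1.set_index("subject_id")
    a2 = e2.set_index("subject_id")
    within_rows = []
    for grp in ("SUB_1", "SUB_2"):
        ids = sub.labels.index[sub.labels == grp]
        for param in OUTCOME_PARAMS:
            x1 = a1.loc[ids, param].to_numpy(dtype=float)
            x2 = a2.loc[ids, param].to_numpy(dtype=float)
            row = {"group": grp, "parameter": param, "n": len(ids),
                   "e1_mean": x1.mean() if len(ids) else np.nan,
                   "e1_sd": x1.std(ddof=1) if len(ids) > 1 else np.nan,
                   "e2_mean": x2.mean() if len(ids) else np.nan,
                   "e2_sd": x2.std(ddof=1) if len(ids) > 1 else np.nan}
            if len(ids) >= 2:
                h, p = kruskal_wallis(x1, x2)
                row.update(h=h, p=p, significant=p <= alpha)
            else:
                row.update(h=np.nan, p=np.nan, significant=False)
            within_rows.append(row)
    between_rows = []
    ids1 = sub.labels.index[sub.labels == "SUB_1"]
    ids2 = sub.labels.index[sub.labels == "SUB_2"]
    for param in EMG_COLUMNS + [c for c in CLIN_COLUMNS if c in a1.columns]:
        x1 = a1.loc[ids1, param].to_numpy(dtype=float)
        x2 = a1.loc[ids2, param].to_numpy(dtype=float)
        row = {"parameter": param,
               "sub1_mean": x1.mean() if len(ids1) else np.nan,
               "sub1_sd": x1.std(ddof=1) if len(ids1) > 1 else np.nan,
               "sub2_mean": x2.mean() if len(ids2) else np.nan,
               "sub2_sd": x2.std(ddof=1) if len(ids2) > 1 else np.nan}
        if len(ids1) >= 2 and len(ids2) >= 2:
            h, p = kruskal_wallis(x1, x2)
            row.update(h=h, p=p, significant=p <= alpha)
        else:
            row.update(h=np.nan, p=np.nan, significant=False)
        between_rows.append(row)
    return pd.DataFrame(within_rows), pd.DataFrame(between_rows)


def tabulate_surgeries(surgery_records: pd.DataFrame,
                       sub_labels: pd.Series) -> pd.DataFrame:
    """Descriptive surgery counts per sub-cluster (no inference).

    ``surgery_records`` needs columns subject_id and surgery_type; types
    outside the known distal/proximal lists are counted under "other"
    with a warning.  Rows: one per sub-cluster plus a Total row.
    """
    known = set(DISTAL_SURGERIES + PROXIMAL_SURGERIES)
    rows = []
    groups = [g for g in ("SUB_1", "SUB_2") if (sub_labels == g).any()]
    for grp in groups + ["Total"]:
        if grp == "Total":
            ids = set(sub_labels.index)
        else:
            ids = set(sub_labels.index[sub_labels == grp])
        rec = surgery_records[surgery_records["subject_id"].isin(ids)]
        counts = rec["surgery_type"].value_counts()
        unknown = [t for t in counts.index if t not in known]
        if unknown and grp != "Total":
            logger.warning("unknown surgery types counted as 'other': %s", unknown)
        row = {"group": grp, "n_patients": len(ids),
               "no_surgery": len(ids - set(rec["subject_id"]))}
        for t in DISTAL_SURGERIES + PROXIMAL_SURGERIES:
            row[t] = int(counts.get(t, 0))
        row["other"] = int(sum(counts[t] for t in unknown))
        row["total_distal"] = int(sum(counts.get(t, 0) for t in DISTAL_SURGERIES))
        row["total_proximal"] = int(sum(counts.get(t, 0) for t in PROXIMAL_SURGERIES))
        rows.append(row)
    return pd.DataFrame(rows)


def responder_heuristic(emg_mean_swing: float, rom_hip_abd_90: float,
                        emg_threshold: float = 70.0,
                        rom_threshold: float = 30.0) -> str:
    """Heuristic pre-treatment flag for likely trunk-movement improvement.

    A plain decision rule, not a validated classifier: restricted passive
    hip abduction (< rom_threshold degrees at 90 degrees hip flexion)
    suggests a structural limitation; adequate RoM with swing-window GM
    activity above emg_threshold percent-of-mean suggests a likely
    responder; adequate RoM with low activity suggests a motor-control
    limitation with limited expected improvement.
    """
    if rom_hip_abd_90 < rom_threshold:
        return "structural_limitation"
    if emg_mean_swing > emg_threshold:
        return "likely_responder"
    return "motor_control_limitation"
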