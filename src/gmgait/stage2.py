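"""Stage-2 clustering: PCA reduction, Ward tree, dendrogram cut, report.

The stage-1 ordinal label matrix is mean-centered (no per-column
rescaling: the labels already share a common small-integer scale) and
projected onto the smallest set of leading principal components whose
cumulative explained variance exceeds the retention threshold (default
96 %).  Agglomerative clustering with Ward linkage on the component
scores yields the merge tree; the final cluster count is the cut with the
largest *relative* gap between consecutive merge heights — a
deterministic analog of reading the dendrogram by eye — searched over
2..k_max clusters.  The per-cluster report mirrors the cohort
characterization tables: subphase envelope means and hip clinical-exam
scalars as mean (SD) per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .core import envelope_values
from .errors import DegenerateInputError
from .features import SUBPHASES, phase_windows
from .synthetic import CLIN_COLUMNS

VAR_THRESHOLD = 0.96


@dataclass
class PcaReduction:
    """Retained principal-component scores of the label matrix."""

    scores: np.ndarray       # subjects x m
    loadings: np.ndarray     # features x m, orthonormal columns
    explained: np.ndarray    # all components' variance fractions
    cum_explained: float     # for the retained set
    n_retained: int


@dataclass
class MergeTree:
    """Agglomerative merge list in scipy linkage format."""

    merges: np.ndarray
    linkage_method: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class ClusterAssignment:
    """Final flat clustering from a dendrogram cut."""

    labels: np.ndarray       # per-subject cluster id, 0..k-1
    k: int
    cut_height: float


def reduce_dimensions(label_matrix: pd.DataFrame | np.ndarray,
                      var_threshold: float = VAR_THRESHOLD) -> PcaReduction:
    """Retain the fewest leading PCs explaining more than ``var_threshold``.

    Columns are mean-centered but not rescaled.  Raises
    :class:`DegenerateInputError` when all rows are identical (no
    variance to decompose).
    """
    X = np.asarray(label_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 columns")
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all rows identical; nothing to decompose")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    explained = pca.explained_variance_ratio_
    cum = np.cumsum(explained)
    m = int(np.searchsorted(cum, var_threshold, side="right")) + 1
    m = min(m, len(explained))
    return PcaReduction(scores=scores[:, :m], loadings=pca.components_[:m].T,
                        explained=explained, cum_explained=float(cum[m - 1]),
                        n_retained=m)


def hierarchical_cluster(scores: np.ndarray, method: str = "ward") -> MergeTree:
    """Agglomerative clustering of PC scores with Euclidean distance."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    return MergeTree(merges=linkage(scores, method=method), linkage_method=method)


def cut_dendrogram(tree: MergeTree, k_max: int = 10) -> ClusterAssignment:
    """Cut at the largest relative gap between consecutive merge heights.

    For each candidate count c in 2..k_max the gap is
    (h[n-c] - h[n-c-1]) / h[n-c-1] over the ascending merge heights; the
    first maximum (smallest c) wins, and all-equal gaps fall back to
    c = 2.  Labels are renumbered 0..k-1 by decreasing cluster size
    (ties by first subject occurrence) for subject-order stability.
    """
    h = np.sort(tree.heights)
    n = len(h) + 1
    best_c, best_gap = 2, -np.inf
    for c in range(2, min(k_max, n) + 1):
        low = h[n - c - 1] if n - c - 1 >= 0 else 0.0
        high = h[n - c]
        if low <= 0:
            gap = np.inf if high > 0 else 0.0
        else:
            gap = (high - low) / low
        if gap > best_gap:
            best_c, best_gap = c, gap
    raw = fcluster(tree.merges, t=best_c, criterion="maxclust")
    low_h = h[n - best_c - 1] if n - best_c - 1 >= 0 else 0.0
    cut_height = float((low_h + h[n - best_c]) / 2.0)
    # canonical renumbering: by size desc, then by first occurrence
    ids, first = np.unique(raw, return_index=True)
    sizes = np.array([(raw == i).sum() for i in ids])
    order = np.lexsort((first, -sizes))
    remap = {int(ids[o]): new for new, o in enumerate(order)}
    labels = np.array([remap[int(r)] for r in raw])
    return ClusterAssignment(labels=labels, k=len(ids), cut_height=cut_height)


def characterize_clusters(assignment: ClusterAssignment, envelopes: pd.DataFrame,
                          clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cluster cohort characterization (the published-table analog).

    One row per cluster: n, then mean and SD of the envelope average in
    each of the seven Perry subphases, then mean and SD of the four hip
    clinical-exam scalars when available.
    """
    if len(assignment.labels) != len(envelopes):
        raise ValueError("assignment does not cover all subjects")
    values = envelope_values(envelopes)
    fo = envelopes["foot_off_pct"].to_numpy(dtype=float)
    sub_means = np.empty((len(envelopes), len(SUBPHASES)))
    for fo_val in np.unique(fo):
        rows = np.nonzero(fo == fo_val)[0]
        wins = {ph.name: ph.sample_indices() for ph in phase_windows(fo_val)}
        for c, name in enumerate(SUBPHASES):
            sub_means[rows, c] = values[np.ix_(rows, wins[name])].mean(axis=1)
    rows_out = []
    for cl in range(assignment.k):
        mask = assignment.labels == cl
        row: dict[str, float] = {"cluster": cl, "n": int(mask.sum())}
        for c, name in enumerate(SUBPHASES):
            row[f"{name}_mean"] = sub_means[mask, c].mean()
            row[f"{name}_sd"] = sub_means[mask, c].std(ddof=1) if mask.sum() > 1 else 0.0
        if clinical is not None:
            clin = clinical.reset_index(drop=True)
            for col in CLIN_COLUMNS:
                vals = clin.loc[mask, col].to_numpy(dtype=float)
                row[f"{col}_mean"] = vals.mean()
                row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        rows_out.append(row)
    return pd.DataFrame(rows_out)
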