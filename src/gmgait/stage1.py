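"""Stage-1 clustering: PSO-seeded 1-D K-means per feature column.

Each of the 60 norm-distance feature columns is clustered independently.
A particle swarm (each particle encoding a candidate set of k centroids,
fitness = within-cluster sum of squares) provides the global-search
initialization; Lloyd's algorithm then refines the winning centroid set.
The cluster count k is selected per column by minimizing the
Davies-Bouldin index over a small k range (ties towards the smaller k),
and labels are re-encoded ordinally by ascending centroid so that a
larger label always means "further from the typically-developed mean".
The resulting subjects x features matrix of ordinal labels is the input
to the stage-2 hierarchical clustering.

Per-column random streams are seeded as ``master_seed + column_index`` so
results are invariant to subject order and reproducible column by column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import NormalizedFeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyperparameters (constriction-style defaults)."""

    swarm_size: int = 30
    iterations: int = 100
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    k_min: int = 2
    k_max: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2 or self.iterations < 1:
            raise ValueError("swarm_size >= 2 and iterations >= 1 required")
        if not 0.0 < self.inertia < 1.0:
            raise ValueError("inertia must lie in (0, 1)")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ColumnClustering:
    """Result of clustering one 1-D feature column."""

    k: int
    centroids: np.ndarray          # strictly increasing
    labels: np.ndarray             # ordinal, 0..k-1 by ascending centroid
    db_index: float
    wcss: float


@dataclass
class LabelMatrix:
    """Subjects x features ordinal label matrix plus per-column metadata."""

    labels: pd.DataFrame
    per_column: dict[str, ColumnClustering] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)


def _wcss(column: np.ndarray, centroids: np.ndarray) -> float:
    d = (column[:, None] - centroids[None, :]) ** 2
    return float(d.min(axis=1).sum())


def pso_search(column: np.ndarray, k: int, config: PsoConfig,
               rng: np.random.Generator,
               return_swarm: bool = False) -> np.ndarray:
    """Global-best centroid set after a fixed-iteration particle swarm.

    Positions are k-vectors of candidate centroids initialized at data
    points; velocities are clamped to the column's data range and
    positions clipped to it.  Returns the best particle's centroids; with
    ``return_swarm`` also the personal-best positions ordered by fitness,
    which make good multi-start seeds for the Lloyd refinement.
    """
    n = len(column)
    if k > n:
        raise ValueError(f"k={k} exceeds column length {n}")
    lo, hi = float(column.min()), float(column.max())
    span = max(hi - lo, 1e-12)
    # all swarm state is built from the sorted column so the search only
    # sees the value multiset, keeping results subject-order invariant
    xs = np.sort(column)
    pos = np.empty((config.swarm_size, k))
    for p in range(config.swarm_size):
        pos[p] = xs[rng.choice(n, size=k, replace=False)]
    vel = rng.uniform(-0.1, 0.1, size=pos.shape) * span

    # WCSS against sorted centroids via prefix sums: nearest-centroid
    # boundaries are the centroid midpoints, so each cluster is a
    # contiguous segment of the sorted column
    cum1 = np.concatenate([[0.0], np.cumsum(xs)])
    cum2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def fitness(P: np.ndarray) -> np.ndarray:
        S = P.shape[0]
        C = np.sort(P, axis=1)
        bounds = (C[:, 1:] + C[:, :-1]) / 2.0
        idx = np.searchsorted(xs, bounds.ravel()).reshape(S, k - 1) if k > 1 \
            else np.empty((S, 0), dtype=int)
        edges = np.concatenate(
            [np.zeros((S, 1), int), idx, np.full((S, 1), n)], axis=1)
        cnt = np.diff(edges, axis=1)
        seg1 = cum1[edges[:, 1:]] - cum1[edges[:, :-1]]
        seg2 = cum2[edges[:, 1:]] - cum2[edges[:, :-1]]
        return (seg2 - 2.0 * C * seg1 + cnt * C ** 2).sum(axis=1)

    fit = fitness(pos)
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    for _ in range(config.iterations):
        r1 = rng.random(pos.shape)
        r2 = rng.random(pos.shape)
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest[None, :] - pos))
        np.clip(vel, -span, span, out=vel)
        pos = np.clip(pos + vel, lo, hi)
        fit = fitness(pos)
        improved = fit < pbest_fit
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    if return_swarm:
        order = np.argsort(pbest_fit, kind="stable")
        return np.sort(gbest), np.sort(pbest[order], axis=1)
    return np.sort(gbest)


def kmeans_refine(column: np.ndarray, init_centroids: np.ndarray,
                  max_iter: int = 300) -> ColumnClustering:
    """Lloyd refinement at fixed k from given (distinct) initial centroids.

    An emptied cluster is re-seeded at the point farthest from its
    current centroid.  WCSS is non-increasing across iterations.
    """
    centroids = np.array(init_centroids, dtype=float)
    k = len(centroids)
    labels = None
    for _it in range(max_iter):
        d = (column[:, None] - centroids[None, :]) ** 2
        new_labels = d.argmin(axis=1)
        for j in range(k):
            members = column[new_labels == j]
            if len(members):
                centroids[j] = members.mean()
            else:
                far = int(d.min(axis=1).argmax())
                centroids[j] = column[far]
                new_labels[far] = j
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
    order = np.argsort(centroids, kind="stable")
    centroids = centroids[order]
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    return ColumnClustering(k=k, centroids=centroids, labels=labels,
                            db_index=np.nan, wcss=_wcss(column, centroids))


def davies_bouldin(column: np.ndarray, labels: np.ndarray,
                   centroids: np.ndarray) -> float:
    """Davies-Bouldin index for a 1-D partition.

    DB = (1/k) sum_i max_{j != i} (s_i + s_j) / d_ij with s_i the mean
    absolute distance of cluster i's members to its centroid and d_ij the
    centroid separation.  Coincident centroids give +inf (worst).
    """
    k = len(centroids)
    if k < 2:
        raise ValueError("Davies-Bouldin undefined for k < 2")
    s = np.empty(k)
    for j in range(k):
        members = column[labels == j]
        if len(members) == 0:
            raise ValueError(f"cluster {j} is empty")
        s[j] = np.abs(members - centroids[j]).mean()
    d = np.abs(centroids[:, None] - centroids[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s[:, None] + s[None, :]) / d
    np.fill_diagonal(ratio, -np.inf)
    worst = ratio.max(axis=1)
    if np.any(np.isnan(worst)):  # coincident centroids with zero scatter
        return float("inf")
    return float(worst.mean())


def cluster_feature_column(column: np.ndarray, config: PsoConfig) -> ColumnClustering | None:
    """PSO + Lloyd at each k in the configured range; keep the minimum-DB k.

    Ties break towards the smaller k.  If the column has fewer than two
    distinct values it cannot be partitioned and ``None`` is returned
    (the column is flagged upstream).
    """
    column = np.asarray(column, dtype=float)
    rng = np.random.default_rng(config.seed)
    n_distinct = len(np.unique(column))
    if n_distinct < 2:
        return None
    best: ColumnClustering | None = None
    for k in range(config.k_min, config.k_max + 1):
        k_eff = min(k, n_distinct)
        if k_eff < k:
            logger.warning("k=%d reduced to %d distinct values", k, k_eff)
        if k_eff < 2:
            continue
        gbest, swarm = pso_search(column, k_eff, config, rng, return_swarm=True)
        # multi-start Lloyd: the swarm's best candidates plus a few fresh
        # data-point seeds guard against the swarm having collapsed into
        # a single local basin
        xs_distinct = np.unique(column)
        n_extra = 20 if len(column) <= 20 else 10
        extras = [xs_distinct[rng.choice(len(xs_distinct), size=k_eff, replace=False)]
                  for _ in range(n_extra)]
        res = kmeans_refine(column, gbest)
        for cand in list(swarm[:5]) + extras:
            alt = kmeans_refine(column, np.sort(cand))
            if alt.wcss < res.wcss - 1e-12:
                res = alt
        occupied = len(np.unique(res.labels))
        if occupied < 2:
            continue
        res.db_index = davies_bouldin(column, res.labels, res.centroids)
        if best is None or res.db_index < best.db_index:
            best = res
    return best


def build_label_matrix(nd: NormalizedFeatureMatrix, config: PsoConfig) -> LabelMatrix:
    """Cluster every feature column and assemble the ordinal label matrix.

    Column j uses seed ``config.seed + j`` so the outcome is independent
    of subject order; unclusterable columns are excluded and recorded in
    ``flagged``.
    """
    cols, meta, flagged = {}, {}, []
    for j, name in enumerate(nd.nd.columns):
        col_cfg = PsoConfig(**{**config.__dict__, "seed": config.seed + j})
        res = cluster_feature_column(nd.nd[name].to_numpy(), col_cfg)
        if res is None:
            flagged.append(name)
            logger.warning("feature %s flagged: no valid partition", name)
            continue
        cols[name] = res.labels
        meta[name] = res
    labels = pd.DataFrame(cols, index=nd.nd.index)
    return LabelMatrix(labels=labels, per_column=meta, flagged=flagged)
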