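"""Region-1 link selection by clustering in scaled attribute space.

High-similarity (near-global) alignments occupy one limit of the scaled
attribute space ("Region 1": l_a close to 1, large s_a, f_id at or above
0.3) and weak short alignments the other ("Region 2"), joined by a
continuous transition band.  The steps implemented here:

1. rotate the 4-D attribute vectors onto their principal axes (all four
   components kept — the rotation helps k-means, dropping dimensions would
   discard attribute information);
2. k-means with many random restarts for each candidate cluster count,
   scored by the Calinski-Harabasz (CH) coefficient; the cluster count q is
   chosen at the elbow of the CH curve;
3. coarse-grain the q clusters into two groups by 2-means on their mean
   attribute vectors; the group with the larger mean s_a is Region 1, and
   any cluster whose mean s_a reaches the floor (0.30) is forced into
   Region 1 regardless of the grouping;
4. exclude links whose l_a is an outlier of the Region-1 l_a distribution
   under the medcouple-adjusted fences, and sort the survivors by ascending
   distance d.

Also provided: the coarse-grained attribute "pathway" (cluster means at
about 100 points per cluster, ordered by mean s_a) used to visualize the
Region 2 -> transition -> Region 1 trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score

from .robust_stats import adjusted_fences

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "ClusterModel",
    "Region1Selection",
    "NoRegion1Error",
    "pca_project",
    "select_num_clusters",
    "coarse_grain_regions",
    "filter_la_outliers",
    "coarse_grain_pathway",
]

ATTRIBUTE_COLUMNS = ("l_a", "f_id", "f_m", "s_a")

MEAN_SA_FLOOR = 0.30


class NoRegion1Error(ValueError):
    """No attribute cluster qualifies as Region 1."""


@dataclass
class ClusterModel:
    """Fitted attribute-space clustering with region assignment."""

    n_clusters: int
    assignment: np.ndarray  # link index -> cluster id
    means: pd.DataFrame  # cluster id -> mean scaled attribute vector
    ch_curve: dict[int, float]
    pca_rotation: np.ndarray
    region1_clusters: set[int] = field(default_factory=set)


@dataclass
class Region1Selection:
    """d-sorted Region-1 links with the l_a outliers set aside."""

    links: pd.DataFrame
    excluded_outliers: pd.DataFrame


def _attribute_matrix(links: pd.DataFrame) -> np.ndarray:
    return links.loc[:, list(ATTRIBUTE_COLUMNS)].to_numpy(dtype=float)


def pca_project(links: pd.DataFrame) -> tuple[np.ndarray, PCA]:
    """Mean-center the 4-D vectors and rotate onto all four principal axes.

    No dimension is dropped; the top-2 projection (columns 0 and 1) is the
    plotting view.
    """
    x = _attribute_matrix(links)
    if x.shape[0] < 2:
        raise ValueError("PCA projection needs at least 2 links")
    pca = PCA(n_components=4)
    projected = pca.fit_transform(x)
    return projected, pca


def _elbow(ch_curve: dict[int, float]) -> int:
    """Elbow of the CH curve: sharpest slope drop, else the CH argmax.

    The knee strength at an interior candidate k is
    2 CH(k) - CH(k-1) - CH(k+1) (the negated discrete second difference).
    A genuine knee bends out of a rise, so only candidates with
    CH(k) > CH(k-1) qualify; on a flat or decreasing curve (single-cluster
    data) no candidate does and the CH argmax wins.  Ties break toward
    smaller k.
    """
    ks = sorted(ch_curve)
    if len(ks) == 1:
        return ks[0]
    best_k, best_strength = None, 0.0
    for prev_k, k, next_k in zip(ks, ks[1:], ks[2:]):
        if ch_curve[k] <= ch_curve[prev_k]:
            continue
        strength = 2.0 * ch_curve[k] - ch_curve[prev_k] - ch_curve[next_k]
        if strength > best_strength:
            best_k, best_strength = k, strength
    if best_k is None:
        return min(ks, key=lambda k: (-ch_curve[k], k))
    return best_k


def select_num_clusters(
    projected: np.ndarray,
    k_max: int = 10,
    k_max_extended: int = 15,
    replicas: int = 100,
    random_state: int | None = 0,
) -> tuple[int, dict[int, float], dict[int, KMeans]]:
    """Choose the cluster count q by the CH elbow over replicated k-means.

    Each candidate k is fitted best-of-``replicas`` random initializations.
    The CH coefficient is undefined for a single cluster, so candidates run
    from k = 2 (the curve the elbow is read from starts there).  When the
    elbow lands on 8 or 9 the candidate range is extended to
    ``k_max_extended`` and re-read.  Candidates with more clusters than
    points are skipped with a warning.
    """
    n = projected.shape[0]
    ch_curve: dict[int, float] = {}
    models: dict[int, KMeans] = {}

    def _fit_range(lo: int, hi: int) -> None:
        for k in range(lo, hi + 1):
            if k in ch_curve:
                continue
            if k > n - 1:
                import warnings

                warnings.warn(f"skipping k={k}: only {n} points", stacklevel=3)
                continue
            km = KMeans(n_clusters=k, n_init=replicas, random_state=random_state)
            labels = km.fit_predict(projected)
            if len(np.unique(labels)) < 2:
                continue
            ch_curve[k] = float(calinski_harabasz_score(projected, labels))
            models[k] = km

    _fit_range(2, k_max)
    if not ch_curve:
        raise ValueError("no candidate cluster count could be evaluated")
    q = _elbow(ch_curve)
    if q in (8, 9) and k_max < k_max_extended:
        _fit_range(k_max + 1, k_max_extended)
        q = _elbow(ch_curve)
    return q, ch_curve, models


def fit_attribute_clusters(
    links: pd.DataFrame,
    k_max: int = 10,
    k_max_extended: int = 15,
    replicas: int = 100,
    random_state: int | None = 0,
) -> ClusterModel:
    """PCA-rotate, select q, and assign every link to an attribute cluster."""
    projected, pca = pca_project(links)
    q, ch_curve, models = select_num_clusters(
        projected,
        k_max=k_max,
        k_max_extended=k_max_extended,
        replicas=replicas,
        random_state=random_state,
    )
    labels = models[q].predict(projected)
    x = _attribute_matrix(links)
    means = (
        pd.DataFrame(x, columns=list(ATTRIBUTE_COLUMNS))
        .groupby(labels)
        .mean()
        .rename_axis("cluster")
    )
    return ClusterModel(
        n_clusters=q,
        assignment=labels,
        means=means,
        ch_curve=ch_curve,
        pca_rotation=pca.components_,
    )


def coarse_grain_regions(
    model: ClusterModel,
    mean_sa_floor: float = MEAN_SA_FLOOR,
    random_state: int | None = 0,
) -> set[int]:
    """Assign attribute clusters to Region 1.

    The q cluster-mean vectors are 2-means clustered; the group with the
    larger mean s_a is Region 1.  Additionally any cluster whose mean s_a
    reaches ``mean_sa_floor`` is forced into Region 1 (correcting clusters
    dragged toward the transition band).  Raises :class:`NoRegion1Error` if
    nothing qualifies.
    """
    means = model.means
    if len(means) == 1:
        only = int(means.index[0])
        if means["s_a"].iloc[0] >= mean_sa_floor:
            model.region1_clusters = {only}
            return model.region1_clusters
        raise NoRegion1Error("single attribute cluster with mean s_a below the floor")
    if float(means["s_a"].max()) < mean_sa_floor:
        raise NoRegion1Error(
            "every attribute cluster has mean s_a below the floor; no Region 1"
        )
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
    groups = km.fit_predict(means.to_numpy(dtype=float))
    sa_by_group = {g: means["s_a"].to_numpy()[groups == g].mean() for g in (0, 1)}
    high_group = max(sa_by_group, key=sa_by_group.get)
    region1 = {int(c) for c, g in zip(means.index, groups) if g == high_group}
    region1 |= {int(c) for c in means.index[means["s_a"] >= mean_sa_floor]}
    if not region1:
        raise NoRegion1Error("no attribute cluster assigned to Region 1")
    model.region1_clusters = region1
    return region1


def filter_la_outliers(region1_links: pd.DataFrame) -> Region1Selection:
    """Drop Region-1 links whose l_a falls outside the adjusted fences.

    Survivors are returned sorted by ascending d (stable, so ties keep the
    lexicographic pair order of the input table).  An empty survivor set is
    allowed but warned about.
    """
    if len(region1_links) < 4:
        raise ValueError("l_a outlier filtering needs at least 4 links")
    fences = adjusted_fences(region1_links["l_a"].to_numpy(dtype=float))
    outlier_mask = fences.is_outlier(region1_links["l_a"].to_numpy(dtype=float))
    kept = region1_links.loc[~outlier_mask]
    excluded = region1_links.loc[outlier_mask]
    if len(kept) == 0:
        import warnings

        warnings.warn("every Region-1 link was an l_a outlier", stacklevel=2)
    kept = kept.sort_values("d", kind="stable").reset_index(drop=True)
    return Region1Selection(links=kept, excluded_outliers=excluded.reset_index(drop=True))


def select_region1(
    links: pd.DataFrame,
    k_max: int = 10,
    k_max_extended: int = 15,
    replicas: int = 100,
    mean_sa_floor: float = MEAN_SA_FLOOR,
    random_state: int | None = 0,
) -> tuple[Region1Selection, ClusterModel]:
    """Full Region-1 pipeline: cluster, coarse-grain, filter l_a outliers."""
    model = fit_attribute_clusters(
        links,
        k_max=k_max,
        k_max_extended=k_max_extended,
        replicas=replicas,
        random_state=random_state,
    )
    region1 = coarse_grain_regions(model, mean_sa_floor=mean_sa_floor, random_state=random_state)
    mask = np.isin(model.assignment, list(region1))
    selection = filter_la_outliers(links.loc[mask])
    return selection, model


def coarse_grain_pathway(
    links: pd.DataFrame,
    points_per_cluster: int = 100,
    random_state: int | None = 0,
) -> pd.DataFrame:
    """Cluster-mean pathway through attribute space, ordered by mean s_a.

    k-means with k = round(n / points_per_cluster) (at least 1); the cluster
    mean vectors are returned sorted by ascending mean s_a, tracing the
    Region 2 -> transition -> Region 1 trajectory.
    """
    x = _attribute_matrix(links)
    n = x.shape[0]
    k = max(1, round(n / points_per_cluster))
    if k == 1:
        means = pd.DataFrame([x.mean(axis=0)], columns=list(ATTRIBUTE_COLUMNS))
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        labels = km.fit_predict(x)
        means = (
            pd.DataFrame(x, columns=list(ATTRIBUTE_COLUMNS)).groupby(labels).mean()
        )
    return means.sort_values("s_a", kind="stable").reset_index(drop=True)
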