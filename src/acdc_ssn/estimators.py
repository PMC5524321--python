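"""Scikit-learn style estimators wiring the pipeline stages together.

:class:`ACDCCommunityDetector` is a clusterer over a scaled-link table: fit
runs attribute clustering -> Region-1 selection -> l_a outlier filtering ->
partition-density maximization over d-sorted links -> (s_f, Z_0) refinement,
and exposes the node partition as fitted attributes.

:class:`GridSearchCutoff` is the supervised cutoff-vector baseline: fit(X, y)
scans the cutoff grid against ground-truth families and records the optimal
cutoff hypersurface and its quality.  It is a benchmark harness, not a
predictor — without ground truth there is nothing to maximize.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from . import attribute_clustering, gridsearch
from .alignment_io import NetworkTable
from .attribute_scaling import ensure_distance, scale_network
from .evaluation import GroundTruth
from .partition_density import optimize_over_d
from .refinement import default_sf_grid, default_z0_grid, refine

__all__ = ["ACDCCommunityDetector", "GridSearchCutoff"]


def _as_link_table(X) -> pd.DataFrame:
    if isinstance(X, NetworkTable):
        X = scale_network(X)
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "X must be a scaled-link DataFrame (node_a, node_b, l_a, f_id, f_m, "
            "s_a[, d]) or a NetworkTable"
        )
    required = {"node_a", "node_b", "l_a", "f_id", "f_m", "s_a"}
    missing = required - set(X.columns)
    if missing:
        raise ValueError(f"link table lacks column(s): {sorted(missing)}")
    if len(X) < 8:
        raise ValueError(f"need at least 8 links to run the pipeline, got {len(X)}")
    return ensure_distance(X)


class ACDCCommunityDetector(ClusterMixin, BaseEstimator):
    """Unsupervised community detection on a sequence similarity network.

    Parameters
    ----------
    mean_sa_floor : float, default 0.30
        Minimum cluster-mean scaled score forcing an attribute cluster into
        Region 1 regardless of the 2-means coarse-graining.
    kmeans_replicas : int, default 100
        Random k-means restarts per candidate cluster count.
    ch_k_max, ch_k_max_extended : int, defaults 10 and 15
        Candidate cluster-count range for the Calinski-Harabasz elbow; the
        range is extended when the elbow lands on 8 or 9.
    points_per_cluster : int, default 100
        Coarse-graining size for the diagnostic attribute pathway.
    sf_grid, z0_grid : array-like or None
        Refinement grid; defaults to s_f = 1.01..1.10 (step 0.01) and
        Z_0 = 1.100..1.110 (step 0.001).
    min_final_zm : float, default 1.0
        Admissibility bound on the final Z_m of a refinement grid point.
    random_state : int, default 0
        Seeds every stochastic stage (k-means restarts); fits are
        deterministic for a fixed value.

    Attributes
    ----------
    nodes_ : list — node ids in deterministic (sorted) order.
    labels_ : ndarray — community id per node, aligned with ``nodes_``.
    community_of_ : dict — node id -> community id.
    n_communities_ : int.
    cluster_model_ : fitted attribute-space clustering (q, CH curve, means).
    region1_ : Region1Selection — d-sorted links fed to the optimizer.
    density_profile_ : DensityProfile — D after each distinct d.
    refinement_ : RefinementResult — per-grid-point refinement log.
    """

    def __init__(
        self,
        *,
        mean_sa_floor: float = 0.30,
        kmeans_replicas: int = 100,
        ch_k_max: int = 10,
        ch_k_max_extended: int = 15,
        points_per_cluster: int = 100,
        sf_grid=None,
        z0_grid=None,
        min_final_zm: float = 1.0,
        random_state: int = 0,
    ):
        self.mean_sa_floor = mean_sa_floor
        self.kmeans_replicas = kmeans_replicas
        self.ch_k_max = ch_k_max
        self.ch_k_max_extended = ch_k_max_extended
        self.points_per_cluster = points_per_cluster
        self.sf_grid = sf_grid
        self.z0_grid = z0_grid
        self.min_final_zm = min_final_zm
        self.random_state = random_state

    def fit(self, X, y=None):
        """Detect communities on a scaled-link table (or NetworkTable)."""
        links = _as_link_table(X)
        nodes = sorted(set(links["node_a"]) | set(links["node_b"]), key=str)
        selection, model = attribute_clustering.select_region1(
            links,
            k_max=self.ch_k_max,
            k_max_extended=self.ch_k_max_extended,
            replicas=self.kmeans_replicas,
            mean_sa_floor=self.mean_sa_floor,
            random_state=self.random_state,
        )
        if len(selection.links) == 0:
            raise ValueError("Region-1 selection is empty; nothing to optimize")
        partition, retained, profile = optimize_over_d(selection.links, nodes)
        sf = default_sf_grid() if self.sf_grid is None else np.asarray(self.sf_grid, float)
        z0 = default_z0_grid() if self.z0_grid is None else np.asarray(self.z0_grid, float)
        refinement = refine(
            partition, retained, links, sf_values=sf, z0_values=z0,
            min_final_zm=self.min_final_zm,
        )
        final = refinement.partition.relabeled()
        self.links_ = links
        self.nodes_ = nodes
        self.cluster_model_ = model
        self.region1_ = selection
        self.optimized_partition_ = partition
        self.retained_ = refinement.state.retained
        self.density_profile_ = profile
        self.refinement_ = refinement
        self.partition_ = final
        self.community_of_ = dict(final.community_of)
        self.labels_ = np.asarray([final.community_of[v] for v in nodes])
        self.n_communities_ = final.n_communities
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def pathway_(self) -> pd.DataFrame:
        """Diagnostic coarse-grained attribute pathway of the fitted table."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "links_")
        return attribute_clustering.coarse_grain_pathway(
            self.links_,
            points_per_cluster=self.points_per_cluster,
            random_state=self.random_state,
        )

    def score(self, X=None, y=None) -> float:
        """Partition density of the fitted community structure."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "partition_")
        return self.partition_.density()


class GridSearchCutoff(BaseEstimator):
    """Exhaustive cutoff-vector search maximizing F against ground truth.

    Parameters
    ----------
    step : float, default 0.01
        Grid spacing; 0.01 is the reference, 0.05 the coarse desk mode.
    shortlist_factor : float, default 0.9
        3-D cutoffs with Q >= factor * Q_max,3 enter the fourth-dimension
        scan (and the same factor gates the final kept set).

    Attributes
    ----------
    q_max3_, q_max4_ : float — best F over the 3-D and extended scans.
    best_cutoffs_ : list[CutoffVector] — all Q-maximal cutoff vectors.
    ranges_ : dict — per-component (min, max) over the Q-maximal vectors.
    result_ : GridSResult — full scan outcome.
    """

    def __init__(self, *, step: float = 0.01, shortlist_factor: float = 0.9):
        self.step = step
        self.shortlist_factor = shortlist_factor

    def fit(self, X, y):
        links = _as_link_table(X)
        truth = self._as_truth(y)
        nodes = set(links["node_a"]) | set(links["node_b"])
        unlabeled = nodes - set(truth.family_of)
        if unlabeled:
            raise ValueError(f"ground truth misses node(s): {sorted(map(str, unlabeled))[:5]}")
        result = gridsearch.run_grids(
            links, truth, step=self.step, shortlist_factor=self.shortlist_factor
        )
        self.result_ = result
        self.q_max3_ = result.q_max3
        self.q_max4_ = result.q_max4
        self.best_cutoffs_ = result.best_cutoffs
        self.ranges_ = result.ranges
        return self

    @staticmethod
    def _as_truth(y) -> GroundTruth:
        if isinstance(y, GroundTruth):
            return y
        if isinstance(y, pd.Series):
            return GroundTruth.from_mapping(y.to_dict())
        if isinstance(y, Mapping):
            return GroundTruth.from_mapping(y)
        raise TypeError("y must be a GroundTruth, a mapping node->family, or a Series")
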