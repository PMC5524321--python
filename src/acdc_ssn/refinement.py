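"""Community refinement: Type-1 and Type-2 error correction by merging.

The similarity measure Z between nodes is the link distance d (small d =
high similarity).  For a partition into M communities, the M x M matrices

    Z_max(i, i) = largest d over the links currently retained inside
                  community i (0 for link-less communities),
    Z_min(i, j) = smallest d over ALL links joining i and j in the full
                  attribute table (absent pairs are treated as infinite),

drive two correction passes:

* Type 1 — a community pair whose closest inter-community link is no
  farther than the widest intra-community link
  (Z_min(i,j) <= max[Z_max(i,i), Z_max(j,j)]) violates the consensus
  community definition; the pair is merged and every inter-community link
  with d up to that bound is added.  Merges repeat, most-similar pair
  first, rebuilding the matrices after each, until no pair violates the
  ordering.

* Type 2 — a true family split into parts shows up as a left outlier of
  the inter-community Z_min distribution.  Starting from the largest
  intra-community distance Z_m, each sweep scales Z_m by s_f > 1, takes the
  lower adjusted-fence Z_L of the off-diagonal Z_min values, and merges
  every pair with Z_min <= min{Z_L, Z_m, Z_0} (Z_0 is a hard ceiling),
  re-evaluating Z_m from the merged structure; sweeps stop when nothing
  merges or Z_m reaches Z_0.

The (s_f, Z_0) plane is scanned on a small grid; grid points whose final
Z_m fails to exceed 1 are inadmissible (the sweep never reached the
inter-community distance scale), and among admissible points the partition
with maximal partition density is the final community structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition_density import Partition, partition_density
from .robust_stats import adjusted_fences

__all__ = [
    "RefinementState",
    "RefinementResult",
    "build_Z",
    "merge_type1",
    "merge_type2",
    "refine",
    "default_sf_grid",
    "default_z0_grid",
]


def default_sf_grid() -> np.ndarray:
    """Scale factors 1.01..1.10 in steps of 0.01."""
    return np.round(np.arange(1.01, 1.10 + 1e-9, 0.01), 10)


def default_z0_grid() -> np.ndarray:
    """Merge ceilings 1.100..1.110 in steps of 0.001."""
    return np.round(np.arange(1.100, 1.110 + 1e-9, 0.001), 10)


@dataclass
class RefinementState:
    """A community structure plus the retained/full link tables."""

    node_to_cid: dict
    retained: pd.DataFrame  # links currently inside communities
    full: pd.DataFrame  # complete scaled-link table
    z_m: float = float("nan")

    def copy(self) -> "RefinementState":
        return RefinementState(
            node_to_cid=dict(self.node_to_cid),
            retained=self.retained.copy(),
            full=self.full,
            z_m=self.z_m,
        )

    @property
    def n_communities(self) -> int:
        return len(set(self.node_to_cid.values()))

    def to_partition(self) -> Partition:
        ca = self.retained["node_a"].map(self.node_to_cid)
        cb = self.retained["node_b"].map(self.node_to_cid)
        if (ca != cb).any():
            raise AssertionError("retained table contains inter-community links")
        m_by = ca.value_counts().to_dict()
        return Partition.from_assignment(self.node_to_cid, n_links_by_community=m_by)

    def density(self) -> float:
        return partition_density(self.to_partition())


def build_Z(state: RefinementState) -> tuple[dict[int, float], dict[tuple[int, int], float], float]:
    """Z_max per community, Z_min per community pair, and the overall Z_m.

    Z_max comes from the retained links, Z_min from the complete table;
    community pairs with no connecting link are simply absent from Z_min.
    """
    cids = set(state.node_to_cid.values())
    z_max = {cid: 0.0 for cid in cids}
    if len(state.retained):
        ca = state.retained["node_a"].map(state.node_to_cid).to_numpy()
        d = state.retained["d"].to_numpy(dtype=float)
        for cid, dmax in pd.Series(d).groupby(ca).max().items():
            z_max[int(cid)] = float(dmax)
    z_min: dict[tuple[int, int], float] = {}
    if len(state.full):
        ca = state.full["node_a"].map(state.node_to_cid).to_numpy()
        cb = state.full["node_b"].map(state.node_to_cid).to_numpy()
        d = state.full["d"].to_numpy(dtype=float)
        inter = ca != cb
        if inter.any():
            lo = np.minimum(ca[inter], cb[inter])
            hi = np.maximum(ca[inter], cb[inter])
            frame = pd.DataFrame({"lo": lo, "hi": hi, "d": d[inter]})
            for (i, j), dmin in frame.groupby(["lo", "hi"])["d"].min().items():
                z_min[(int(i), int(j))] = float(dmin)
    z_m = max(z_max.values()) if z_max else 0.0
    return z_max, z_min, z_m


def _merge_pair(state: RefinementState, ci: int, cj: int, link_ceiling: float) -> None:
    """Merge community cj into ci, adding inter-community links with d <= ceiling."""
    ca = state.full["node_a"].map(state.node_to_cid).to_numpy()
    cb = state.full["node_b"].map(state.node_to_cid).to_numpy()
    d = state.full["d"].to_numpy(dtype=float)
    between = (((ca == ci) & (cb == cj)) | ((ca == cj) & (cb == ci))) & (d <= link_ceiling)
    added = state.full.loc[between]
    for node, cid in state.node_to_cid.items():
        if cid == cj:
            state.node_to_cid[node] = ci
    if len(added):
        state.retained = pd.concat([state.retained, added], ignore_index=True)


def merge_type1(state: RefinementState) -> RefinementState:
    """Merge community pairs violating the intra > inter distance ordering.

    On exit every remaining pair satisfies
    Z_min(i, j) > max[Z_max(i, i), Z_max(j, j)].  Merges are applied in
    ascending Z_min order, one at a time, rebuilding the matrices after
    each so cascades are deterministic.
    """
    state = state.copy()
    while True:
        z_max, z_min, z_m = build_Z(state)
        violations = [
            (dmin, i, j)
            for (i, j), dmin in z_min.items()
            if dmin <= max(z_max[i], z_max[j])
        ]
        if not violations:
            state.z_m = z_m
            return state
        dmin, i, j = min(violations)
        _merge_pair(state, i, j, max(z_max[i], z_max[j]))


def merge_type2(state: RefinementState, s_f: float, z_0: float) -> RefinementState:
    """Left-outlier driven merge sweeps for split communities.

    Expects a Type-1-clean state.  Each sweep scales the running Z_m by
    s_f, computes the left-outlier threshold Z_L of the off-diagonal Z_min
    values (with fewer than 4 community pairs the criterion degrades to
    min{Z_m, Z_0}), and merges every pair with Z_min <= min{Z_L, Z_m, Z_0},
    most-similar first, adding the qualifying links.  Sweeps end when no
    pair merged or when Z_m reaches the ceiling Z_0; the final Z_m is
    recorded on the returned state.
    """
    if s_f <= 1.0:
        raise ValueError(f"scale factor s_f must exceed 1, got {s_f}")
    state = state.copy()
    _, _, z_m = build_Z(state)
    state.z_m = z_m
    while True:
        state.z_m = s_f * state.z_m
        z_max, z_min, _ = build_Z(state)
        offdiag = np.array(sorted(z_min.values()), dtype=float)
        if offdiag.size >= 4:
            z_l = adjusted_fences(offdiag).lower
            threshold = min(z_l, state.z_m, z_0)
        else:
            threshold = min(state.z_m, z_0)
        merged_any = False
        while True:
            _, z_min, _ = build_Z(state)
            candidates = [(dmin, i, j) for (i, j), dmin in z_min.items() if dmin <= threshold]
            if not candidates:
                break
            _, i, j = min(candidates)
            _merge_pair(state, i, j, threshold)
            merged_any = True
        if not merged_any:
            return state
        _, _, z_m_new = build_Z(state)  # re-evaluate Z_m from the merged structure
        state.z_m = z_m_new
        if state.z_m >= z_0:
            return state


@dataclass
class RefinementResult:
    """Final refined partition plus the per-grid-point log."""

    partition: Partition
    state: RefinementState
    log: pd.DataFrame  # s_f, z_0, final_z_m, n_communities, D, admissible
    selected: tuple[float, float] | None  # (s_f, z_0) or None if fallback
    type1_state: RefinementState = field(repr=False, default=None)


def refine(
    partition: Partition,
    retained: pd.DataFrame,
    full: pd.DataFrame,
    sf_values: np.ndarray | None = None,
    z0_values: np.ndarray | None = None,
    min_final_zm: float = 1.0,
) -> RefinementResult:
    """Grid-scanned Type-1 + Type-2 refinement, selected by partition density.

    The Type-1 pass does not depend on (s_f, Z_0) and is run once; every
    grid point then runs the Type-2 sweeps from that common state.  Grid
    points whose final Z_m fails to exceed ``min_final_zm`` are
    inadmissible; among admissible points the maximal-density partition is
    returned (first in grid order on ties).  With no admissible point the
    Type-1-refined partition is returned with a warning.
    """
    sf_values = default_sf_grid() if sf_values is None else np.asarray(sf_values, dtype=float)
    z0_values = default_z0_grid() if z0_values is None else np.asarray(z0_values, dtype=float)
    start = RefinementState(
        node_to_cid={node: int(cid) for node, cid in partition.community_of.items()},
        retained=retained.reset_index(drop=True),
        full=full.reset_index(drop=True),
    )
    type1 = merge_type1(start)
    rows = []
    best: tuple[float, RefinementState, tuple[float, float]] | None = None
    for s_f, z_0 in itertools.product(sf_values, z0_values):
        result = merge_type2(type1, float(s_f), float(z_0))
        density = result.density()
        admissible = result.z_m > min_final_zm
        rows.append(
            (float(s_f), float(z_0), float(result.z_m), result.n_communities, density, admissible)
        )
        if admissible and (best is None or density > best[0] + 1e-15):
            best = (density, result, (float(s_f), float(z_0)))
    log = pd.DataFrame(
        rows, columns=["s_f", "z_0", "final_z_m", "n_communities", "D", "admissible"]
    )
    if best is None:
        warnings.warn(
            "no admissible (s_f, Z_0) grid point (final Z_m never exceeded "
            f"{min_final_zm}); returning the Type-1-refined partition",
            stacklevel=2,
        )
        return RefinementResult(
            partition=type1.to_partition(),
            state=type1,
            log=log,
            selected=None,
            type1_state=type1,
        )
    _, state, grid_point = best
    return RefinementResult(
        partition=state.to_partition(),
        state=state,
        log=log,
        selected=grid_point,
        type1_state=type1,
    )
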