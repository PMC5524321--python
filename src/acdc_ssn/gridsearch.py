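"""GridS: brute-force cutoff-vector search against ground-truth families.

A cutoff attribute vector A_c = (l_a_c, f_id_c, f_m_c, s_a_c) retains the
links with l_a >= l_a_c, f_id >= f_id_c, f_m <= f_m_c and s_a >= s_a_c; the
connected components of the retained links (plus singletons) are the
communities, scored by the F-measure Q against the ground truth.

The full 4-D scan is pruned the way the reference protocol does: each of
the four 3-D subspaces (the free dimension held at its no-op cutoff) is
scanned on a regular grid, the cutoffs reaching at least 0.9 of the 3-D
maximum Q_max,3 are shortlisted, and a 1-D scan of the free dimension over
each shortlisted cutoff yields Q_max,4 and the per-component ranges of the
Q-maximal vectors.

Implementation notes: along each axis only cutoff values that change the
retained-link set are evaluated (grid values are grouped by the rank they
cut at), and Q is memoized on the retained-set bitmask, so identical link
sets are never scored twice.  Neither shortcut changes any reported Q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import GroundTruth, f_measure
from .partition_density import components

__all__ = [
    "CutoffVector",
    "GridSResult",
    "apply_cutoff",
    "scan_3d",
    "extend_4th",
    "run_grids",
]

AXES = ("l_a", "f_id", "f_m", "s_a")
#: no-op cutoff per axis: retains every link
NOOP = {"l_a": 0.0, "f_id": 0.0, "f_m": 1.0, "s_a": 0.0}
#: the four 3-D subspaces scanned before the fourth-dimension extension
SUBSPACES = (
    ("l_a", "f_id", "f_m"),
    ("l_a", "f_id", "s_a"),
    ("l_a", "f_m", "s_a"),
    ("s_a", "f_id", "f_m"),
)


@dataclass(frozen=True)
class CutoffVector:
    """A cutoff attribute vector with its quality Q (F-measure)."""

    l_a_c: float
    f_id_c: float
    f_m_c: float
    s_a_c: float
    q: float

    @property
    def vector(self) -> tuple[float, float, float, float]:
        return (self.l_a_c, self.f_id_c, self.f_m_c, self.s_a_c)


def cutoff_mask(links: pd.DataFrame, cutoff) -> np.ndarray:
    """Boolean survivor mask of a cutoff vector over a scaled-link table."""
    if isinstance(cutoff, CutoffVector):
        l_a_c, f_id_c, f_m_c, s_a_c = cutoff.vector
    else:
        l_a_c, f_id_c, f_m_c, s_a_c = cutoff
    return (
        (links["l_a"].to_numpy() >= l_a_c)
        & (links["f_id"].to_numpy() >= f_id_c)
        & (links["f_m"].to_numpy() <= f_m_c)
        & (links["s_a"].to_numpy() >= s_a_c)
    )


def apply_cutoff(links: pd.DataFrame, cutoff, all_nodes):
    """Partition induced by a cutoff vector: components plus singletons."""
    mask = cutoff_mask(links, cutoff)
    return components(links.loc[mask], all_nodes)


class _QualityCache:
    """Memoized Q evaluation keyed on the packed retained-set bitmask."""

    def __init__(self, links: pd.DataFrame, truth: GroundTruth):
        self.links = links
        self.truth = truth
        self.nodes = sorted(truth.family_of, key=str)
        self.ua = links["node_a"].to_numpy()
        self.ub = links["node_b"].to_numpy()
        self.cache: dict[bytes, float] = {}
        self.n_eval = 0

    def q(self, mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        part = components(zip(self.ua[mask], self.ub[mask]), self.nodes)
        value = f_measure(part, self.truth).f
        self.cache[key] = value
        self.n_eval += 1
        return value


def _grid(step: float) -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def _axis_groups(values: np.ndarray, axis: str, grid: np.ndarray, base: np.ndarray | None = None):
    """Group grid cutoffs along one axis by the survivor set they induce.

    Returns a list of (representative_cutoff, grid_values, mask).  For
    >=-type axes the survivor set changes only when the cutoff crosses a
    data value (for the <=-type axis f_m symmetrically), so cutoffs are
    grouped by the insertion rank they cut at — restricted to the ``base``
    survivor subset when given, which collapses the group count as the
    subset shrinks.  Masks within a group are identical by construction.
    """
    subset = values if base is None else values[base]
    order = np.sort(subset)
    if axis == "f_m":
        ranks = np.searchsorted(order, grid, side="right")
    else:
        ranks = np.searchsorted(order, grid, side="left")
    groups = []
    for rank in np.unique(ranks):
        members = grid[ranks == rank]
        rep = float(members[0])
        axis_mask = values <= rep if axis == "f_m" else values >= rep
        mask = axis_mask if base is None else (base & axis_mask)
        groups.append((rep, members, mask))
    return groups


@dataclass
class GridSResult:
    """Outcome of the 3-D scan plus fourth-dimension extension."""

    q_max3: float
    q_max4: float
    best_cutoffs: list[CutoffVector]
    ranges: dict[str, tuple[float, float]]
    table: pd.DataFrame  # one row per evaluated (deduplicated) cutoff
    n_distinct_linksets: int

    def range_report(self) -> str:
        parts = []
        for axis in AXES:
            lo, hi = self.ranges[axis]
            parts.append(f"{lo:.2f}" if lo == hi else f"{lo:.2f}-{hi:.2f}")
        return "(" + ", ".join(parts) + ")"


def scan_3d(
    links: pd.DataFrame,
    truth: GroundTruth,
    step: float = 0.01,
    shortlist_factor: float = 0.9,
):
    """Scan the four 3-D cutoff subspaces; shortlist near-optimal cutoffs.

    Returns (q_max3, shortlist, cache) where each shortlist entry is a dict
    with the free axis, the three fixed-axis grid-value groups, the
    combined retained mask and its Q.  Every grid point with
    Q >= shortlist_factor * Q_max,3 is represented (grouped by identical
    retained sets).
    """
    cache = _QualityCache(links, truth)
    grid = _grid(step)
    evaluated = []  # (free_axis, axes, reps, members, packed_mask, q)
    axis_values = {a: links[a].to_numpy(dtype=float) for a in AXES}
    q_max3 = -np.inf
    for axes in SUBSPACES:
        (free_axis,) = set(AXES) - set(axes)
        for rep0, mem0, m0 in _axis_groups(axis_values[axes[0]], axes[0], grid):
            for rep1, mem1, m01 in _axis_groups(axis_values[axes[1]], axes[1], grid, base=m0):
                for rep2, mem2, mask in _axis_groups(
                    axis_values[axes[2]], axes[2], grid, base=m01
                ):
                    q = cache.q(mask)
                    q_max3 = max(q_max3, q)
                    if q >= shortlist_factor * q_max3:
                        evaluated.append(
                            (
                                free_axis,
                                axes,
                                (rep0, rep1, rep2),
                                (mem0, mem1, mem2),
                                np.packbits(mask).tobytes(),
                                q,
                            )
                        )
            # drop entries that can no longer reach the shortlist
            evaluated = [e for e in evaluated if e[5] >= shortlist_factor * q_max3]
    n_links = len(links)
    shortlist = [
        {
            "free_axis": free_axis,
            "axes": axes,
            "reps": reps,
            "members": members,
            "mask": np.unpackbits(
                np.frombuffer(packed, dtype=np.uint8), count=n_links
            ).astype(bool),
            "q": q,
        }
        for free_axis, axes, reps, members, packed, q in evaluated
        if q >= shortlist_factor * q_max3
    ]
    return float(q_max3), shortlist, cache


def extend_4th(
    links: pd.DataFrame,
    truth: GroundTruth,
    shortlist: list[dict],
    q_max3: float,
    cache: _QualityCache | None = None,
    step: float = 0.01,
    keep_factor: float = 0.9,
) -> GridSResult:
    """1-D scan of each shortlisted cutoff's free dimension.

    Keeps vectors with Q >= keep_factor * Q_max,3, reports Q_max,4, the
    Q-maximal cutoff vectors and the per-component min-max ranges over all
    Q-maximal grid vectors.
    """
    if cache is None:
        cache = _QualityCache(links, truth)
    grid = _grid(step)
    axis_values = {a: links[a].to_numpy(dtype=float) for a in AXES}
    q_max4 = -np.inf
    kept = []  # (axes+free layout, reps by axis, members by axis, q)
    for entry in shortlist:
        free_axis = entry["free_axis"]
        for rep_f, mem_f, mask in _axis_groups(
            axis_values[free_axis], free_axis, grid, base=entry["mask"]
        ):
            q = cache.q(mask)
            if q < keep_factor * q_max3:
                continue
            reps = dict(zip(entry["axes"], entry["reps"]))
            reps[free_axis] = rep_f
            members = dict(zip(entry["axes"], entry["members"]))
            members[free_axis] = mem_f
            kept.append((reps, members, q))
            q_max4 = max(q_max4, q)
    rows = [
        {**{f"{a}_c": reps[a] for a in AXES}, "q": q}
        for reps, members, q in kept
    ]
    table = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
    maximal = [(reps, members) for reps, members, q in kept if q >= q_max4 - 1e-12]
    ranges = {}
    for axis in AXES:
        lo = min(float(np.min(members[axis])) for _, members in maximal)
        hi = max(float(np.max(members[axis])) for _, members in maximal)
        ranges[axis] = (lo, hi)
    best_cutoffs = sorted(
        {
            CutoffVector(
                l_a_c=reps["l_a"], f_id_c=reps["f_id"], f_m_c=reps["f_m"],
                s_a_c=reps["s_a"], q=float(q_max4),
            )
            for reps, _ in maximal
        },
        key=lambda c: c.vector,
    )
    return GridSResult(
        q_max3=float(q_max3),
        q_max4=float(q_max4),
        best_cutoffs=best_cutoffs,
        ranges=ranges,
        table=table,
        n_distinct_linksets=len(cache.cache),
    )


def run_grids(
    links: pd.DataFrame,
    truth: GroundTruth,
    step: float = 0.01,
    shortlist_factor: float = 0.9,
) -> GridSResult:
    """Complete GridS protocol: 3-D subspace scans then the 4th-dimension scan."""
    q_max3, shortlist, cache = scan_3d(links, truth, step=step, shortlist_factor=shortlist_factor)
    return extend_4th(
        links, truth, shortlist, q_max3, cache=cache, step=step, keep_factor=shortlist_factor
    )
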