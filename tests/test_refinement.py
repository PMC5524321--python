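"""Type-1 / Type-2 community refinement over the (s_f, Z_0) grid."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from acdc_ssn.evaluation import f_measure
from acdc_ssn.partition_density import Partition, components
from acdc_ssn.refinement import (
    RefinementState,
    build_Z,
    merge_type1,
    merge_type2,
    refine,
)


def _table(edges_with_d):
    df = pd.DataFrame(edges_with_d, columns=["node_a", "node_b", "d"])
    for col in ("l_a", "f_id", "f_m", "s_a"):
        df[col] = 0.5
    return df


def _state(node_to_cid, retained, full):
    return RefinementState(
        node_to_cid=dict(node_to_cid), retained=_table(retained), full=_table(full)
    )


def _two_cliques(d_intra_1=0.5, d_intra_2=0.6, d_bridge=1.4):
    """Two triangles joined by one bridge link."""
    c1, c2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
    intra = [(u, v, d_intra_1) for u, v in itertools.combinations(c1, 2)]
    intra += [(u, v, d_intra_2) for u, v in itertools.combinations(c2, 2)]
    bridge = [("a1", "b1", d_bridge)]
    node_to_cid = {**{v: 0 for v in c1}, **{v: 1 for v in c2}}
    return node_to_cid, intra, intra + bridge


class TestBuildZ:
    def test_bridge_distance_is_the_pair_minimum(self):
        node_to_cid, retained, full = _two_cliques(d_bridge=1.4)
        z_max, z_min, z_m = build_Z(_state(node_to_cid, retained, full))
        assert z_min[(0, 1)] == 1.4
        assert z_max == {0: 0.5, 1: 0.6}
        assert z_m == 0.6

    def test_singleton_community_has_zero_zmax(self):
        state = _state({"a": 0, "b": 1}, [], [("a", "b", 0.9)])
        z_max, z_min, z_m = build_Z(state)
        assert z_max == {0: 0.0, 1: 0.0}
        assert z_min == {(0, 1): 0.9}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(17)
        nodes = [f"v{i}" for i in range(12)]
        node_to_cid = {v: int(rng.integers(0, 4)) for v in nodes}
        full = [
            (u, v, float(np.round(rng.uniform(0.1, 2.0), 3)))
            for u, v in itertools.combinations(nodes, 2)
        ]
        retained = [
            (u, v, d) for u, v, d in full if node_to_cid[u] == node_to_cid[v] and d < 1.0
        ]
        z_max, z_min, z_m = build_Z(_state(node_to_cid, retained, full))
        for i in set(node_to_cid.values()):
            expect = max(
                (d for u, v, d in retained if node_to_cid[u] == i), default=0.0
            )
            assert z_max[i] == expect
        for (i, j), got in z_min.items():
            expect = min(
                d
                for u, v, d in full
                if {node_to_cid[u], node_to_cid[v]} == {i, j}
            )
            assert got == expect
        assert z_m == max(z_max.values())


class TestMergeType1:
    def test_bridge_below_intra_max_triggers_merge(self):
        """Intra max 1.2, bridge at 1.1 -> merged, bridge links <= 1.2 added."""
        node_to_cid, retained, full = _two_cliques(
            d_intra_1=1.2, d_intra_2=0.6, d_bridge=1.1
        )
        out = merge_type1(_state(node_to_cid, retained, full))
        assert out.n_communities == 1
        assert len(out.retained) == len(retained) + 1  # the bridge came along

    def test_well_separated_communities_unchanged(self):
        node_to_cid, retained, full = _two_cliques(d_bridge=1.5)
        out = merge_type1(_state(node_to_cid, retained, full))
        assert out.n_communities == 2
        assert len(out.retained) == len(retained)

    def test_postcondition_ordering_holds_exactly(self, fitted_detector):
        state = fitted_detector.refinement_.type1_state
        z_max, z_min, _ = build_Z(state)
        for (i, j), dmin in z_min.items():
            assert dmin > max(z_max[i], z_max[j])


class TestMergeType2:
    def test_left_outlier_pair_is_merged(self):
        """Split pair at Z_min=0.4 against background ~1.5 is repaired."""
        rng = np.random.default_rng(3)
        halves = (["a1", "a2", "a3"], ["b1", "b2", "b3"])
        others = [[f"c{k}{i}" for i in range(3)] for k in range(4)]
        groups = [halves[0], halves[1], *others]
        node_to_cid = {v: cid for cid, grp in enumerate(groups) for v in grp}
        # intra distances reach ~0.385 so one s_f=1.10 sweep spans the 0.4 gap
        retained = [
            (u, v, float(rng.uniform(0.25, 0.385)))
            for grp in groups
            for u, v in itertools.combinations(grp, 2)
        ]
        full = list(retained)
        for g1, g2 in itertools.combinations(range(len(groups)), 2):
            base = 0.4 if {g1, g2} == {0, 1} else float(rng.uniform(1.45, 1.55))
            for u, v in itertools.product(groups[g1], groups[g2]):
                full.append((u, v, base + float(rng.uniform(0.0, 0.05))))
        state = merge_type1(_state(node_to_cid, retained, full))
        assert state.n_communities == 6
        out = merge_type2(state, s_f=1.10, z_0=1.105)
        assert out.n_communities == 5
        assert out.node_to_cid["a1"] == out.node_to_cid["b1"]

    def test_z0_below_every_zmin_blocks_merging(self):
        node_to_cid, retained, full = _two_cliques(d_bridge=1.2)
        state = _state(node_to_cid, retained, full)
        out = merge_type2(state, s_f=1.10, z_0=0.1)
        assert out.n_communities == 2

    def test_sf_irrelevant_when_no_outliers(self, fitted_detector):
        """On a clean network both extreme scale factors leave it unchanged."""
        state = fitted_detector.refinement_.type1_state
        out_lo = merge_type2(state, s_f=1.01, z_0=1.105)
        out_hi = merge_type2(state, s_f=1.10, z_0=1.105)
        assert out_lo.node_to_cid == out_hi.node_to_cid == state.node_to_cid

    def test_invalid_scale_factor_rejected(self):
        node_to_cid, retained, full = _two_cliques()
        with pytest.raises(ValueError):
            merge_type2(_state(node_to_cid, retained, full), s_f=0.99, z_0=1.1)


class TestRefine:
    def test_noop_fixture_returns_input_partition(self):
        node_to_cid, retained, full = _two_cliques(d_bridge=1.5)
        part = Partition.from_assignment(
            node_to_cid, links=[(u, v) for u, v, _ in retained]
        )
        with pytest.warns(UserWarning, match="no admissible"):
            result = refine(part, _table(retained), _table(full))
        assert result.partition.community_of == part.community_of
        assert result.selected is None

    def test_split_family_is_repaired(self, fitted_split_detector, split_ssn):
        """Planted split: 4 communities pre-refinement, 3 after, F = 1."""
        det = fitted_split_detector
        assert det.optimized_partition_.n_communities == 4
        assert det.n_communities_ == 3
        assert f_measure(det.community_of_, split_ssn.truth).f == 1.0
        assert det.refinement_.selected is not None

    def test_inadmissible_grid_points_never_selected(self, fitted_split_detector):
        log = fitted_split_detector.refinement_.log
        selected = fitted_split_detector.refinement_.selected
        row = log[(log["s_f"] == selected[0]) & (log["z_0"] == selected[1])]
        assert bool(row["admissible"].iloc[0])
        assert row["final_z_m"].iloc[0] > 1.0
        # the selected density is maximal among admissible points
        admissible = log[log["admissible"]]
        assert row["D"].iloc[0] == pytest.approx(admissible["D"].max())

    def test_refinement_conserves_nodes_and_reduces_communities(
        self, fitted_split_detector
    ):
        det = fitted_split_detector
        pre = det.optimized_partition_
        post = det.partition_
        assert set(post.community_of) == set(pre.community_of)
        assert post.n_communities <= pre.n_communities
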