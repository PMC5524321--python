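"""Comparing predicted partitions with ground-truth families (F-measure).

With N sequences, ground-truth family i of size n_i, predicted community j
of size m_j and overlap O_ij, per-pair precision and recall are defined
(following the source convention; the harmonic mean is symmetric in them) as

    P_ij = O_ij / n_i        R_ij = O_ij / m_j

and the size-weighted F-measure is

    F = (1 / N) * sum_i n_i * max_j [ 2 / (1/R_ij + 1/P_ij) ]
      = (1 / N) * sum_i n_i * max_j [ 2 O_ij / (n_i + m_j) ].

F = 1 exactly when the two set partitions coincide; a partition into all
singletons against one family of n nodes gives the small-but-nonzero floor
2 / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .partition_density import Partition

__all__ = [
    "GroundTruth",
    "EvaluationResult",
    "read_labels",
    "f_measure",
    "count_communities",
]

Node = Hashable


@dataclass(frozen=True)
class GroundTruth:
    """Node -> family label mapping."""

    family_of: dict[Node, str]

    @property
    def n_families(self) -> int:
        return len(set(self.family_of.values()))

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for fam in self.family_of.values():
            sizes[fam] = sizes.get(fam, 0) + 1
        return sizes

    @classmethod
    def from_mapping(cls, mapping: Mapping[Node, object]) -> "GroundTruth":
        return cls(family_of={k: str(v) for k, v in mapping.items()})


def read_labels(path: str | Path) -> GroundTruth:
    """Read two-column tab-separated (seq_id, family_label) ground truth."""
    family_of: dict[Node, str] = {}
    with Path(path).open("rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"labels file line {lineno}: expected 2 columns")
            if parts[0] in family_of:
                raise ValueError(f"labels file line {lineno}: duplicate node {parts[0]}")
            family_of[parts[0]] = parts[1]
    return GroundTruth(family_of=family_of)


@dataclass
class EvaluationResult:
    """F-measure plus per-family best-match bookkeeping."""

    f: float
    n_pred_communities: int
    n_truth_communities: int
    best_matches: pd.DataFrame  # family, n_i, community, m_j, overlap, term

    def summary(self) -> str:
        return (
            f"F = {self.f:.4f}  (#pred communities = {self.n_pred_communities}, "
            f"#truth families = {self.n_truth_communities})"
        )


def _as_mapping(pred: Partition | Mapping[Node, object]) -> Mapping[Node, object]:
    if isinstance(pred, Partition):
        return pred.community_of
    return pred


def f_measure(pred: Partition | Mapping[Node, object], truth: GroundTruth) -> EvaluationResult:
    """Size-weighted F-measure of a predicted partition against families.

    The predicted partition and the ground truth must cover exactly the same
    node set; pairs with zero overlap contribute 0 to the per-family max.
    """
    pred_of = _as_mapping(pred)
    pred_nodes = set(pred_of)
    truth_nodes = set(truth.family_of)
    if pred_nodes != truth_nodes:
        only_pred = sorted(map(str, pred_nodes - truth_nodes))[:5]
        only_truth = sorted(map(str, truth_nodes - pred_nodes))[:5]
        raise ValueError(
            "prediction and ground truth cover different node sets "
            f"(only in prediction: {only_pred}, only in truth: {only_truth})"
        )
    nodes = sorted(pred_nodes, key=str)
    fam_labels = pd.Index(sorted({truth.family_of[v] for v in nodes}))
    com_labels = pd.Index(sorted({pred_of[v] for v in nodes}, key=str))
    fam_idx = fam_labels.get_indexer([truth.family_of[v] for v in nodes])
    com_idx = com_labels.get_indexer([pred_of[v] for v in nodes])
    overlap = np.zeros((len(fam_labels), len(com_labels)), dtype=np.int64)
    np.add.at(overlap, (fam_idx, com_idx), 1)
    n_i = overlap.sum(axis=1)  # family sizes
    m_j = overlap.sum(axis=0)  # community sizes
    # harmonic mean of P_ij and R_ij collapses to 2 O / (n_i + m_j); O = 0 -> 0
    hm = 2.0 * overlap / (n_i[:, None] + m_j[None, :])
    best_j = hm.argmax(axis=1)
    best_term = hm[np.arange(len(fam_labels)), best_j]
    f = float((n_i * best_term).sum() / n_i.sum())
    best = pd.DataFrame(
        {
            "family": fam_labels,
            "n_i": n_i,
            "community": com_labels[best_j],
            "m_j": m_j[best_j],
            "overlap": overlap[np.arange(len(fam_labels)), best_j],
            "term": best_term,
        }
    )
    return EvaluationResult(
        f=f,
        n_pred_communities=len(com_labels),
        n_truth_communities=len(fam_labels),
        best_matches=best,
    )


def count_communities(pred: Partition | Mapping[Node, object], include_singletons: bool = True) -> int:
    """Number of predicted communities (singletons included by default)."""
    pred_of = _as_mapping(pred)
    sizes: dict[object, int] = {}
    for cid in pred_of.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    if include_singletons:
        return len(sizes)
    return sum(1 for n in sizes.values() if n > 1)
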