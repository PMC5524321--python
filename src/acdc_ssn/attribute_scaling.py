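"""Scaled link-attribute vectors and the distance from the perfect alignment.

Each retained pair alignment between sequences A and B is rescaled by the
pair's natural scales: the length of the shorter sequence L_min and the
smaller self-alignment score S_min.  The scaled vector is

    l_a  = L_a / L_min      (scaled alignment length, ~(0, 1], may exceed 1
                             when the alignment contains gaps)
    f_id = N_id / L_a       (fraction of identical residues)
    f_m  = N_m / L_a        (fraction of mismatched residues)
    s_a  = S / S_min        (scaled bit score, ~[0, 1])

A perfect alignment maps to (1, 1, 0, 1); the Euclidean distance d of a
link's vector from that reference point ranges from 0 to about 2 and acts as
a proxy for evolutionary distance between the two sequences.

Components are deliberately not clipped: s_a slightly above 1 and l_a above 1
are legitimate (gapped alignments, composition effects).  Values beyond loose
sanity bounds (s_a > 1.2, l_a > 1.5) trigger a warning naming the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import (
    NetworkTable,
    PairAlignmentRecord,
    ScalingInputError,
    SequenceRecord,
)

__all__ = [
    "PERFECT_VECTOR",
    "SCALED_COLUMNS",
    "ScaledLink",
    "scale_link",
    "scale_network",
    "distance_from_perfect",
    "read_scaled_table",
    "write_scaled_table",
]

PERFECT_VECTOR = (1.0, 1.0, 0.0, 1.0)
SCALED_COLUMNS = ("node_a", "node_b", "l_a", "f_id", "f_m", "s_a", "d")

S_A_SANITY_BOUND = 1.2
L_A_SANITY_BOUND = 1.5


@dataclass(frozen=True)
class ScaledLink:
    """A network edge carrying the scaled attribute vector and distance d."""

    node_a: str
    node_b: str
    l_a: float
    f_id: float
    f_m: float
    s_a: float
    d: float = float("nan")

    def with_distance(self) -> "ScaledLink":
        return ScaledLink(
            self.node_a,
            self.node_b,
            self.l_a,
            self.f_id,
            self.f_m,
            self.s_a,
            distance_from_perfect(self.l_a, self.f_id, self.f_m, self.s_a),
        )

    @property
    def vector(self) -> tuple[float, float, float, float]:
        return (self.l_a, self.f_id, self.f_m, self.s_a)


def distance_from_perfect(l_a, f_id, f_m, s_a):
    """Euclidean distance from the perfect-alignment vector (1, 1, 0, 1).

    Accepts scalars or numpy arrays; d = sqrt((1-l_a)^2 + (1-f_id)^2 +
    f_m^2 + (1-s_a)^2).
    """
    l_a = np.asarray(l_a, dtype=float)
    out = np.sqrt((1.0 - l_a) ** 2 + (1.0 - np.asarray(f_id, dtype=float)) ** 2
                  + np.asarray(f_m, dtype=float) ** 2
                  + (1.0 - np.asarray(s_a, dtype=float)) ** 2)
    return float(out) if out.ndim == 0 else out


def scale_link(
    rec: PairAlignmentRecord,
    seq_a: SequenceRecord,
    seq_b: SequenceRecord,
) -> ScaledLink:
    """Scale one pair alignment by the pair's natural scales.

    L_min is the shorter sequence length; S_min is the smaller of the two
    self-alignment scores (the shorter sequence's self score unless the
    other sequence has the smaller one).
    """
    members = {seq_a.seq_id, seq_b.seq_id}
    if {rec.query_id, rec.subject_id} != members:
        raise ScalingInputError(
            f"record {rec.query_id}/{rec.subject_id} does not join "
            f"{seq_a.seq_id} and {seq_b.seq_id}"
        )
    l_min = min(seq_a.length, seq_b.length)
    s_min = min(seq_a.self_score, seq_b.self_score)
    if l_min <= 0 or s_min <= 0:
        raise ScalingInputError(
            f"pair {rec.pair_key}: non-positive natural scale (L_min={l_min}, S_min={s_min})"
        )
    l_a = rec.aln_length / l_min
    f_id = rec.n_identical / rec.aln_length
    f_m = rec.n_mismatch / rec.aln_length
    s_a = rec.bit_score / s_min
    if s_a > S_A_SANITY_BOUND or l_a > L_A_SANITY_BOUND:
        warnings.warn(
            f"pair {rec.pair_key}: scaled attributes outside sanity bounds "
            f"(l_a={l_a:.3f}, s_a={s_a:.3f})",
            stacklevel=2,
        )
    a, b = rec.pair_key
    return ScaledLink(a, b, l_a, f_id, f_m, s_a).with_distance()


def scale_network(net: NetworkTable) -> pd.DataFrame:
    """Scale every retained pair of a symmetrized network.

    Returns a scaled-link table with columns ``SCALED_COLUMNS`` in
    deterministic lexicographic pair order.
    """
    rows = []
    for key in sorted(net.links):
        rec = net.links[key]
        a, b = key
        try:
            seq_a = net.sequences[a]
            seq_b = net.sequences[b]
        except KeyError as exc:
            raise ScalingInputError(f"pair {key}: unresolved sequence {exc}") from None
        link = scale_link(rec, seq_a, seq_b)
        rows.append((link.node_a, link.node_b, link.l_a, link.f_id, link.f_m, link.s_a, link.d))
    df = pd.DataFrame(rows, columns=list(SCALED_COLUMNS))
    return df


def ensure_distance(links: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a scaled-link table with the ``d`` column present."""
    df = links.copy()
    if "d" not in df.columns or df["d"].isna().any():
        df["d"] = distance_from_perfect(
            df["l_a"].to_numpy(), df["f_id"].to_numpy(), df["f_m"].to_numpy(), df["s_a"].to_numpy()
        )
    return df


def write_scaled_table(
    links: pd.DataFrame, path: str | Path, float_format: str | None = None
) -> Path:
    """Write a scaled-attribute table (tab-separated, with header).

    With the default ``float_format=None`` floats are written with the
    shortest representation that round-trips exactly.
    """
    path = Path(path)
    links.loc[:, list(SCALED_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=float_format
    )
    return path


def read_scaled_table(path: str | Path) -> pd.DataFrame:
    """Read a scaled-attribute table written by :func:`write_scaled_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    missing = set(SCALED_COLUMNS) - {"d"} - set(df.columns)
    if missing:
        raise ValueError(f"scaled table {path} lacks column(s): {sorted(missing)}")
    return ensure_distance(df)

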