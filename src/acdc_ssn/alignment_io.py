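"""Reading, symmetrizing and exporting all-vs-all pair-alignment tables.

Input is the 12-column BLAST tabular dialect (``-outfmt 6``)::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

The raw attributes carried per alignment are the bit score S, the alignment
length L_a, the number of identical residues N_id, the number of mismatched
residues N_m and the number of gap positions N_g, with the identity
L_a = N_id + N_m + N_g.  The tabular dialect stores the percent identity
rather than N_id, so N_id is reconstructed as round(pident * L_a / 100)
(ties to even) and N_g as the remainder L_a - N_id - N_m.

Self alignments (qseqid == sseqid) are not network links: they provide each
sequence's length (the self alignment spans the full sequence) and its
self-alignment score, both of which are the natural scales used downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "BLAST_TAB_COLUMNS",
    "BlastFormatError",
    "MissingSelfAlignmentError",
    "ScalingInputError",
    "PairAlignmentRecord",
    "SequenceRecord",
    "NetworkTable",
    "parse_blast_tabular",
    "resolve_sequences",
    "symmetrize",
    "complete_link_count",
    "export_cytoscape",
    "read_lengths_table",
]

BLAST_TAB_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class BlastFormatError(ValueError):
    """A BLAST tabular row that cannot be parsed or validated."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MissingSelfAlignmentError(KeyError):
    """Sequences that have neither a self-alignment row nor a lengths entry."""

    def __init__(self, seq_ids: Iterable[str]):
        self.seq_ids = sorted(seq_ids)
        super().__init__(
            "no self-alignment row and no lengths-table entry for sequence(s): "
            + ", ".join(self.seq_ids)
        )


class ScalingInputError(ValueError):
    """Raised when a pair cannot be scaled (non-positive natural scales)."""


@dataclass(frozen=True)
class PairAlignmentRecord:
    """One parsed pair alignment with raw attributes.

    ``n_identical`` (N_id) and ``n_gap_positions`` (N_g) are derived from the
    stored percent identity; the invariant N_id + N_m + N_g == L_a holds for
    every valid record.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    n_mismatch: int
    n_gap_open: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    n_identical: int = field(default=-1)
    n_gap_positions: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_identical < 0:
            object.__setattr__(
                self, "n_identical", round(self.percent_identity * self.aln_length / 100.0)
            )
        if self.n_gap_positions < 0:
            object.__setattr__(
                self, "n_gap_positions", self.aln_length - self.n_identical - self.n_mismatch
            )

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id

    @property
    def pair_key(self) -> tuple[str, str]:
        a, b = self.query_id, self.subject_id
        return (a, b) if a <= b else (b, a)

    def validate(self) -> None:
        if self.aln_length < 1:
            raise BlastFormatError(f"alignment length must be >= 1, got {self.aln_length}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise BlastFormatError(f"percent identity out of [0, 100]: {self.percent_identity}")
        if self.bit_score < 0:
            raise BlastFormatError(f"negative bit score: {self.bit_score}")
        if self.n_gap_positions < 0:
            raise BlastFormatError(
                f"record {self.query_id}/{self.subject_id}: N_id + N_m exceeds L_a "
                f"({self.n_identical} + {self.n_mismatch} > {self.aln_length})"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """Per-sequence identity: length L and self-alignment score S_self."""

    seq_id: str
    length: int
    self_score: float

    def validate(self) -> None:
        if self.length < 1:
            raise ScalingInputError(f"sequence {self.seq_id}: length must be >= 1")
        if self.self_score <= 0:
            raise ScalingInputError(f"sequence {self.seq_id}: self score must be > 0")


@dataclass
class NetworkTable:
    """A symmetrized all-vs-all network: sequences plus one record per pair."""

    sequences: dict[str, SequenceRecord]
    links: dict[tuple[str, str], PairAlignmentRecord]

    def link_records(self) -> list[PairAlignmentRecord]:
        return [self.links[k] for k in sorted(self.links)]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_links(self) -> int:
        return len(self.links)


_INT_FIELDS = ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send")


def parse_blast_tabular(
    path: str | Path,
    *,
    allow_comments: bool = True,
    validate: bool = True,
) -> Iterator[PairAlignmentRecord]:
    """Stream :class:`PairAlignmentRecord` from a BLAST tabular file.

    Lines starting with ``#`` are skipped when ``allow_comments`` is true.
    Malformed rows raise :class:`BlastFormatError` naming the line.
    """
    path = Path(path)
    with path.open("rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                if allow_comments:
                    continue
                raise BlastFormatError("comment line not permitted here", lineno)
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastFormatError(
                    f"expected >= 12 tab-separated columns, found {len(fields)}", lineno
                )
            values: dict[str, object] = {"qseqid": fields[0], "sseqid": fields[1]}
            try:
                values["pident"] = float(fields[2])
                for name, raw in zip(_INT_FIELDS, fields[3:10]):
                    values[name] = int(raw)
                values["evalue"] = float(fields[10])
                values["bitscore"] = float(fields[11])
            except ValueError as exc:
                raise BlastFormatError(f"non-numeric field ({exc})", lineno) from None
            rec = PairAlignmentRecord(
                query_id=str(values["qseqid"]),
                subject_id=str(values["sseqid"]),
                percent_identity=float(values["pident"]),  # type: ignore[arg-type]
                aln_length=int(values["length"]),  # type: ignore[arg-type]
                n_mismatch=int(values["mismatch"]),  # type: ignore[arg-type]
                n_gap_open=int(values["gapopen"]),  # type: ignore[arg-type]
                q_start=int(values["qstart"]),  # type: ignore[arg-type]
                q_end=int(values["qend"]),  # type: ignore[arg-type]
                s_start=int(values["sstart"]),  # type: ignore[arg-type]
                s_end=int(values["send"]),  # type: ignore[arg-type]
                e_value=float(values["evalue"]),  # type: ignore[arg-type]
                bit_score=float(values["bitscore"]),  # type: ignore[arg-type]
            )
            if validate:
                try:
                    rec.validate()
                except BlastFormatError as exc:
                    raise BlastFormatError(str(exc), lineno) from None
            yield rec


def read_lengths_table(path: str | Path) -> dict[str, int]:
    """Read the optional two-column (seq_id, length) side table."""
    out: dict[str, int] = {}
    with Path(path).open("rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise BlastFormatError("lengths table needs exactly 2 columns", lineno)
            out[parts[0]] = int(parts[1])
    return out


def resolve_sequences(
    rows: Iterable[PairAlignmentRecord],
    lengths: Mapping[str, int] | None = None,
) -> dict[str, SequenceRecord]:
    """Build :class:`SequenceRecord` for every sequence appearing in ``rows``.

    Each sequence's self score is the bit score of its self-alignment row and
    its length the self row's alignment length; a lengths side table overrides
    the latter.  Sequences with neither source raise
    :class:`MissingSelfAlignmentError`.
    """
    lengths = dict(lengths or {})
    seen: set[str] = set()
    self_rows: dict[str, PairAlignmentRecord] = {}
    for rec in rows:
        seen.add(rec.query_id)
        seen.add(rec.subject_id)
        if rec.is_self:
            prev = self_rows.get(rec.query_id)
            if prev is None or rec.bit_score > prev.bit_score:
                self_rows[rec.query_id] = rec
    missing = {s for s in seen if s not in self_rows and s not in lengths}
    # a lengths entry alone cannot supply the self score
    missing |= {s for s in seen if s not in self_rows}
    if missing:
        raise MissingSelfAlignmentError(missing)
    out: dict[str, SequenceRecord] = {}
    for seq_id in sorted(seen):
        row = self_rows[seq_id]
        length = lengths.get(seq_id, row.aln_length)
        rec = SequenceRecord(seq_id=seq_id, length=length, self_score=row.bit_score)
        rec.validate()
        out[seq_id] = rec
    return out


def symmetrize(
    rows: Iterable[PairAlignmentRecord],
    sequences: Mapping[str, SequenceRecord] | None = None,
) -> NetworkTable:
    """Collapse reciprocal/duplicate alignments to one record per pair.

    For each unordered pair the single highest-bit-score record among all
    (A, B) and (B, A) rows (including multiple HSPs) is retained; self rows
    are routed to sequence resolution, never to links.
    """
    rows = list(rows)
    if sequences is None:
        sequences = resolve_sequences(rows)
    links: dict[tuple[str, str], PairAlignmentRecord] = {}
    for rec in rows:
        if rec.is_self:
            continue
        key = rec.pair_key
        prev = links.get(key)
        if prev is None or rec.bit_score > prev.bit_score:
            links[key] = rec
    return NetworkTable(sequences=dict(sequences), links=links)


def complete_link_count(n_sequences: int) -> int:
    """Number of unordered pairs N(N-1)/2 in a complete all-vs-all network."""
    return n_sequences * (n_sequences - 1) // 2


def export_cytoscape(
    network: NetworkTable,
    links: pd.DataFrame,
    community_of: Mapping[str, object],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write Cytoscape-importable node and edge tables.

    ``links`` is a scaled-link table (columns node_a, node_b, l_a, f_id,
    f_m, s_a, d); ``community_of`` maps every sequence id to its community.
    Returns the (node table, edge table) paths.
    """
    out_prefix = Path(out_prefix)
    missing = [s for s in network.sequences if s not in community_of]
    if missing:
        raise KeyError(f"partition does not cover sequence(s): {', '.join(sorted(missing)[:5])}")
    node_path = out_prefix.parent / (out_prefix.name + "_nodes.tsv")
    edge_path = out_prefix.parent / (out_prefix.name + "_edges.tsv")
    nodes = pd.DataFrame(
        {
            "seq_id": sorted(network.sequences),
            "community_id": [community_of[s] for s in sorted(network.sequences)],
        }
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    cols = ["node_a", "node_b", "l_a", "f_id", "f_m", "s_a", "d"]
    edges = links.loc[:, cols] if len(links) else pd.DataFrame(columns=cols)
    edges = edges.rename(columns={"node_a": "source", "node_b": "target"})
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def all_pairs(seq_ids: Iterable[str]) -> Iterator[tuple[str, str]]:
    """Lexicographically ordered unordered pairs over ``seq_ids``."""
    ordered = sorted(seq_ids)
    return itertools.combinations(ordered, 2)
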