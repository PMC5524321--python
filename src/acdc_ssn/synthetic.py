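"""Planted-family synthetic sequence similarity networks.

The generator emits complete all-vs-all SSNs whose link attributes mimic the
empirical structure of real protein-superfamily alignment data:

* intra-family links live in Region 1 — near-global alignments (l_a close
  to 1), scaled scores in a high band, and an identical fraction that falls
  linearly with s_a toward the ~0.3 floor observed at the Region-1 edge;
* inter-family links live in Region 2 — short weak alignments (small l_a,
  small s_a) with the elevated identical fractions typical of short random
  matches;
* a configurable fraction of intra-family links is drawn from the
  transition band between the two regions.

Outputs come in three invertible forms: the exact planted scaled-attribute
table, a BLAST tabular file (self-alignment rows included) obtained by
inverting the scaling against drawn sequence lengths and self scores, and
the ground-truth family labels.  Parsing and re-scaling the tabular file
recovers the planted vectors within rounding (at most ~1/L_min per
component).

``SplitInjection`` severs one family into two halves for refinement tests:
cross-half pairs become Region-2 links except for a handful of suppressed
"bridge" links whose distance d is planted just above the intra-family
range, so the halves stay disconnected through density maximization and
the bridge d_min is a left outlier of the inter-community distance
distribution — exactly the signature the Type-2 sweep is built to repair.

Distributions are uniform / truncated-normal mixtures: the acceptance
surface is structural (regions, separability), not biological realism.
Self scores are drawn at about 2 bits per residue so the score scaling
inverts well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .attribute_scaling import SCALED_COLUMNS, distance_from_perfect
from .evaluation import GroundTruth

__all__ = [
    "Region1Params",
    "Region2Params",
    "TransitionParams",
    "SplitInjection",
    "GeneratorConfig",
    "SyntheticSSN",
    "generate",
    "generate_region_pathway_sample",
]


@dataclass(frozen=True)
class Region1Params:
    """Intra-family (high similarity) link attribute distributions."""

    l_a: tuple[float, float] = (0.90, 1.00)
    s_a: tuple[float, float] = (0.40, 0.95)
    f_id_intercept: float = 0.30
    f_id_slope: float = 0.68
    f_id_noise: float = 0.015
    f_m_frac: tuple[float, float] = (0.78, 0.92)  # f_m as a fraction of 1 - f_id


@dataclass(frozen=True)
class Region2Params:
    """Inter-family (insignificant similarity) link attribute distributions."""

    l_a: tuple[float, float] = (0.05, 0.30)
    s_a: tuple[float, float] = (0.02, 0.14)
    f_id: tuple[float, float] = (0.18, 0.38)  # elevated identity at small l_a
    f_m_frac: tuple[float, float] = (0.60, 0.90)


@dataclass(frozen=True)
class TransitionParams:
    """The band bridging Regions 1 and 2 (shrinking l_a, falling f_id)."""

    l_a: tuple[float, float] = (0.45, 0.85)
    s_a: tuple[float, float] = (0.16, 0.26)
    f_id: tuple[float, float] = (0.22, 0.32)
    f_m_frac: tuple[float, float] = (0.80, 0.95)


@dataclass(frozen=True)
class SplitInjection:
    """Sever one family into halves joined only by suppressed bridge links."""

    family_index: int = 0
    n_bridges: int = 4
    bridge_d: tuple[float, float] = (0.92, 0.93)
    bridge_s_a: tuple[float, float] = (0.22, 0.27)
    bridge_f_id: tuple[float, float] = (0.68, 0.75)
    bridge_f_m: tuple[float, float] = (0.15, 0.22)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic SSN."""

    family_sizes: tuple[int, ...] = (20, 20, 20)
    seed: int = 0
    region1: Region1Params = field(default_factory=Region1Params)
    region2: Region2Params = field(default_factory=Region2Params)
    transition: TransitionParams = field(default_factory=TransitionParams)
    transition_fraction: float = 0.05
    split_injection: SplitInjection | None = None
    #: one most-diverged homolog pair planted per family (per half for a
    #: split family) at this distance; pins the intra-family distance scale
    anchor_d: tuple[float, float] = (0.875, 0.885)
    sequence_length_range: tuple[int, int] = (150, 400)
    bits_per_residue: tuple[float, float] = (1.9, 2.1)

    def validate(self) -> None:
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError("transition_fraction must lie in [0, 1]")
        if self.region1.s_a[0] <= 0.30:
            raise ValueError("Region-1 s_a support must stay above 0.30")
        if self.region2.s_a[1] >= 0.15:
            raise ValueError("Region-2 s_a support must stay below 0.15")
        if self.split_injection is not None:
            if not 0 <= self.split_injection.family_index < len(self.family_sizes):
                raise ValueError("split_injection.family_index out of range")
            if self.family_sizes[self.split_injection.family_index] < 4:
                raise ValueError("split family needs at least 4 members")

    @property
    def n_sequences(self) -> int:
        return sum(self.family_sizes)


@dataclass
class SyntheticSSN:
    """One generated network with all of its emitted views."""

    config: GeneratorConfig
    sequences: pd.DataFrame  # seq_id, length, self_score, family
    links: pd.DataFrame  # planted scaled-attribute table (SCALED_COLUMNS + region)
    blast: pd.DataFrame  # 12-column BLAST tabular rows incl. self alignments
    truth: GroundTruth

    def write_blast(self, path: str | Path) -> Path:
        path = Path(path)
        self.blast.to_csv(path, sep="\t", index=False, header=False)
        return path

    def write_scaled(self, path: str | Path) -> Path:
        path = Path(path)
        self.links.loc[:, list(SCALED_COLUMNS)].to_csv(path, sep="\t", index=False)
        return path

    def write_labels(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("wt", encoding="utf-8") as fh:
            for seq_id in self.sequences["seq_id"]:
                fh.write(f"{seq_id}\t{self.truth.family_of[seq_id]}\n")
        return path

    def write_lengths(self, path: str | Path) -> Path:
        path = Path(path)
        self.sequences.loc[:, ["seq_id", "length"]].to_csv(
            path, sep="\t", index=False, header=False
        )
        return path


def _u(rng: np.random.Generator, bounds: tuple[float, float], size=None):
    return rng.uniform(bounds[0], bounds[1], size=size)


def _draw_region1(rng: np.random.Generator, p: Region1Params) -> tuple[float, float, float, float]:
    s_a = float(_u(rng, p.s_a))
    f_id = p.f_id_intercept + p.f_id_slope * s_a + rng.normal(0.0, p.f_id_noise)
    f_id = float(np.clip(f_id, p.f_id_intercept, 0.985))
    f_m = float(_u(rng, p.f_m_frac)) * (1.0 - f_id)
    l_a = float(_u(rng, p.l_a))
    return l_a, f_id, f_m, s_a


def _draw_region2(rng: np.random.Generator, p: Region2Params) -> tuple[float, float, float, float]:
    s_a = float(_u(rng, p.s_a))
    f_id = float(_u(rng, p.f_id))
    f_m = float(_u(rng, p.f_m_frac)) * (1.0 - f_id)
    l_a = float(_u(rng, p.l_a))
    return l_a, f_id, f_m, s_a


def _draw_transition(
    rng: np.random.Generator, p: TransitionParams
) -> tuple[float, float, float, float]:
    s_a = float(_u(rng, p.s_a))
    f_id = float(_u(rng, p.f_id))
    f_m = float(_u(rng, p.f_m_frac)) * (1.0 - f_id)
    l_a = float(_u(rng, p.l_a))
    return l_a, f_id, f_m, s_a


def _draw_anchor(
    rng: np.random.Generator, p: Region1Params, anchor_d: tuple[float, float]
) -> tuple[float, float, float, float]:
    """Place a Region-1-edge link at the target anchor distance.

    The anchor sits at the diverged end of the Region-1 band (s_a just above
    the band floor, f_id below the trend line); f_m is solved so the link
    lands exactly at the drawn distance.
    """
    for _ in range(200):
        d = float(_u(rng, anchor_d))
        s_a = p.s_a[0] + float(rng.uniform(0.0, 0.02))
        f_id = float(rng.uniform(0.50, 0.51))
        l_a = float(rng.uniform(0.91, 0.95))
        f_m_sq = d**2 - (1.0 - l_a) ** 2 - (1.0 - f_id) ** 2 - (1.0 - s_a) ** 2
        if f_m_sq <= 0:
            continue
        f_m = float(np.sqrt(f_m_sq))
        if f_id + f_m <= 0.99:
            return l_a, f_id, f_m, s_a
    raise RuntimeError("could not place an anchor link at the target distance")


def _draw_bridge(rng: np.random.Generator, p: SplitInjection) -> tuple[float, float, float, float]:
    """Solve l_a so the bridge link lands exactly at its target distance d."""
    for _ in range(200):
        d = float(_u(rng, p.bridge_d))
        s_a = float(_u(rng, p.bridge_s_a))
        f_id = float(_u(rng, p.bridge_f_id))
        f_m = float(_u(rng, p.bridge_f_m))
        radicand = d**2 - (1.0 - f_id) ** 2 - f_m**2 - (1.0 - s_a) ** 2
        if radicand <= 1e-6:
            continue
        l_a = 1.0 - float(np.sqrt(radicand))
        if 0.05 < l_a < 0.95:
            return l_a, f_id, f_m, s_a
    raise RuntimeError("could not place a bridge link at the target distance")


def generate(config: GeneratorConfig) -> SyntheticSSN:
    """Generate one complete planted-family SSN (deterministic under seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fam_labels = [f"fam{i + 1:02d}" for i in range(len(config.family_sizes))]
    seq_ids: list[str] = []
    family_of: dict[str, str] = {}
    family_members: list[list[str]] = []
    counter = 0
    for label, size in zip(fam_labels, config.family_sizes):
        members = []
        for _ in range(size):
            seq_id = f"seq{counter:04d}"
            counter += 1
            seq_ids.append(seq_id)
            family_of[seq_id] = label
            members.append(seq_id)
        family_members.append(members)

    lengths = rng.integers(
        config.sequence_length_range[0], config.sequence_length_range[1] + 1, size=len(seq_ids)
    )
    bpr = _u(rng, config.bits_per_residue, size=len(seq_ids))
    self_scores = np.round(bpr * lengths, 1)
    sequences = pd.DataFrame(
        {
            "seq_id": seq_ids,
            "length": lengths.astype(int),
            "self_score": self_scores,
            "family": [family_of[s] for s in seq_ids],
        }
    )

    split = config.split_injection
    half_a: set[str] = set()
    bridge_pairs: set[tuple[str, str]] = set()
    if split is not None:
        members = family_members[split.family_index]
        half_a = set(members[: len(members) // 2])
        cross = [
            tuple(sorted((u, v)))
            for u, v in itertools.combinations(members, 2)
            if (u in half_a) != (v in half_a)
        ]
        n_bridges = min(split.n_bridges, len(cross))
        chosen = rng.choice(len(cross), size=n_bridges, replace=False)
        bridge_pairs = {cross[i] for i in chosen}

    rows = []
    anchor_groups: dict[object, list[int]] = {}
    for u, v in itertools.combinations(seq_ids, 2):
        same_family = family_of[u] == family_of[v]
        if same_family and split is not None and family_of[u] == fam_labels[split.family_index]:
            cross_half = (u in half_a) != (v in half_a)
            if cross_half:
                if (u, v) in bridge_pairs:
                    region = "bridge"
                    l_a, f_id, f_m, s_a = _draw_bridge(rng, split)
                else:
                    region = "region2"
                    l_a, f_id, f_m, s_a = _draw_region2(rng, config.region2)
                rows.append((u, v, l_a, f_id, f_m, s_a, region))
                continue
        if same_family:
            if rng.random() < config.transition_fraction:
                region = "transition"
                l_a, f_id, f_m, s_a = _draw_transition(rng, config.transition)
            else:
                region = "region1"
                l_a, f_id, f_m, s_a = _draw_region1(rng, config.region1)
                group: object = family_of[u]
                if split is not None and family_of[u] == fam_labels[split.family_index]:
                    group = (family_of[u], u in half_a)
                anchor_groups.setdefault(group, []).append(len(rows))
        else:
            region = "region2"
            l_a, f_id, f_m, s_a = _draw_region2(rng, config.region2)
        rows.append((u, v, l_a, f_id, f_m, s_a, region))

    # pin the intra-family distance scale: one most-diverged pair per group
    for group in sorted(anchor_groups, key=str):
        indices = anchor_groups[group]
        pick = int(rng.choice(len(indices)))
        u, v, *_ = rows[indices[pick]]
        rows[indices[pick]] = (u, v, *_draw_anchor(rng, config.region1, config.anchor_d), "region1")

    links = pd.DataFrame(rows, columns=["node_a", "node_b", "l_a", "f_id", "f_m", "s_a", "region"])
    links["d"] = distance_from_perfect(
        links["l_a"].to_numpy(), links["f_id"].to_numpy(),
        links["f_m"].to_numpy(), links["s_a"].to_numpy(),
    )
    links = links.loc[:, ["node_a", "node_b", "l_a", "f_id", "f_m", "s_a", "d", "region"]]

    blast = _invert_scaling(rng, sequences, links)
    return SyntheticSSN(
        config=config,
        sequences=sequences,
        links=links,
        blast=blast,
        truth=GroundTruth(family_of=family_of),
    )


def _invert_scaling(
    rng: np.random.Generator, sequences: pd.DataFrame, links: pd.DataFrame
) -> pd.DataFrame:
    """Emit BLAST tabular rows (self rows first) reproducing the scaled table."""
    length_of = dict(zip(sequences["seq_id"], sequences["length"]))
    score_of = dict(zip(sequences["seq_id"], sequences["self_score"]))
    rows = []
    for seq_id in sequences["seq_id"]:
        n = int(length_of[seq_id])
        rows.append(
            (seq_id, seq_id, 100.0, n, 0, 0, 1, n, 1, n, 1e-180, float(score_of[seq_id]))
        )
    for rec in links.itertuples(index=False):
        l_min = min(length_of[rec.node_a], length_of[rec.node_b])
        s_min = min(score_of[rec.node_a], score_of[rec.node_b])
        aln_len = max(1, round(rec.l_a * l_min))
        n_id = round(rec.f_id * aln_len)
        n_m = round(rec.f_m * aln_len)
        tries = 0
        while n_id + n_m > aln_len and tries < 50:
            # resample the mismatch fraction toward its feasible range
            n_m = round(float(rng.uniform(0.0, max(0.0, 1.0 - rec.f_id))) * aln_len)
            tries += 1
        n_m = min(n_m, aln_len - n_id)
        pident = round(100.0 * n_id / aln_len, 2)
        bitscore = round(rec.s_a * s_min, 1)
        gaps = aln_len - n_id - n_m
        evalue = float(
            max(np.exp2(-min(bitscore, 500.0)) * length_of[rec.node_a] * length_of[rec.node_b],
                1e-180)
        )
        rows.append(
            (
                rec.node_a, rec.node_b, pident, aln_len, int(n_m), int(1 if gaps else 0),
                1, aln_len, 1, aln_len, evalue, bitscore,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )


def generate_region_pathway_sample(
    config: GeneratorConfig | None = None,
    n_points: int = 1200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Continuum sample spanning Region 1 -> transition -> Region 2.

    Emits a scaled-attribute table only (synthetic pair ids), suitable for
    the coarse-grained pathway and clustering tests.  With the transition
    band emptied (``transition_fraction == 0``) the sample is bimodal.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    thirds = n_points // 3
    n_trans = 0 if config.transition_fraction == 0 else thirds
    n_r1 = thirds
    n_r2 = n_points - n_r1 - n_trans
    rows = []
    for _ in range(n_r1):
        rows.append(_draw_region1(rng, config.region1) + ("region1",))
    for _ in range(n_trans):
        rows.append(_draw_transition(rng, config.transition) + ("transition",))
    for _ in range(n_r2):
        rows.append(_draw_region2(rng, config.region2) + ("region2",))
    df = pd.DataFrame(rows, columns=["l_a", "f_id", "f_m", "s_a", "region"])
    df.insert(0, "node_b", [f"pB{i:05d}" for i in range(len(df))])
    df.insert(0, "node_a", [f"pA{i:05d}" for i in range(len(df))])
    df["d"] = distance_from_perfect(
        df["l_a"].to_numpy(), df["f_id"].to_numpy(), df["f_m"].to_numpy(), df["s_a"].to_numpy()
    )
    return df.loc[:, ["node_a", "node_b", "l_a", "f_id", "f_m", "s_a", "d", "region"]]
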