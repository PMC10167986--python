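"""Step 3 — chaining ortholog anchors into synteny blocks.

Anchors (ortholog pairs joined to gene positions) are grouped per
chromosome-pair combination and partitioned into blocks by connected
components of the gap-adjacency graph: two anchors are adjacent when they
differ by at most ``max_gap`` gene ranks on both sides.  Components with
at least ``min_anchors`` anchors (default 6, reading "more than five"
strictly) become blocks.  ``max_gap=None`` means no gap constraint, which
reproduces the coarse one-block-per-chromosome-pair rule.

Gaps are measured in gene ranks, not base pairs: the whole method is
gene-order based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .homology import ConservedPair
from .io_formats import GeneRecord

__all__ = ["Anchor", "SyntenyBlock", "build_anchors", "chain_blocks", "block_statistics"]


@dataclass(frozen=True)
class Anchor:
    """One ortholog pair with its rank coordinates on both chromosomes."""

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    chr_a: str
    chr_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class SyntenyBlock:
    """A chained set of anchors between one chromosome of A and one of B."""

    id: str
    species_a: str
    species_b: str
    chr_a: str
    chr_b: str
    anchors: tuple[Anchor, ...]  # sorted by rank_a
    orientation: str  # same | inverted | mixed
    span_a: tuple[int, int]  # inclusive rank interval on chr_a
    span_b: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def build_anchors(
    orthologs: Sequence[ConservedPair], genes: Sequence[GeneRecord]
) -> list[Anchor]:
    """Join ortholog rows to gene positions; one anchor per row.

    The anchor's A side is the lexicographically smaller species (ties on
    species never occur: within-species rows are not valid orthologs).
    Raises ``KeyError`` naming any gene absent from the gene table.
    """
    info: dict[str, GeneRecord] = {g.gene_id: g for g in genes}
    anchors = []
    for row in orthologs:
        for gid in (row.gene_a, row.gene_b):
            if gid not in info:
                raise KeyError(f"ortholog gene {gid!r} missing from gene table")
        ga, gb = info[row.gene_a], info[row.gene_b]
        if ga.species > gb.species:
            ga, gb = gb, ga
        anchors.append(
            Anchor(
                gene_a=ga.gene_id,
                gene_b=gb.gene_id,
                species_a=ga.species,
                species_b=gb.species,
                chr_a=ga.chromosome,
                chr_b=gb.chromosome,
                rank_a=ga.rank,
                rank_b=gb.rank,
            )
        )
    anchors.sort(key=lambda a: (a.chr_a, a.chr_b, a.rank_a, a.rank_b, a.gene_a))
    return anchors


def _components(anchors: list[Anchor], max_gap: int | None) -> list[list[Anchor]]:
    """Connected components of the gap-adjacency graph on one chromosome pair."""
    n = len(anchors)
    if max_gap is None:
        return [list(anchors)]
    order = sorted(range(n), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # sweep over anchors sorted by rank_a; only pairs within the rank_a
    # window can be adjacent
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if anchors[j].rank_a - anchors[i].rank_a > max_gap:
                break
            if abs(anchors[j].rank_b - anchors[i].rank_b) <= max_gap:
                union(i, j)

    groups: dict[int, list[Anchor]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(anchors[i])
    return list(groups.values())


def _orientation(members: Sequence[Anchor]) -> str:
    ra = np.array([a.rank_a for a in members], dtype=float)
    rb = np.array([a.rank_b for a in members], dtype=float)
    if len(members) < 2 or np.all(ra == ra[0]) or np.all(rb == rb[0]):
        return "mixed"
    rho = stats.spearmanr(ra, rb).statistic
    if np.isnan(rho):
        return "mixed"
    if rho >= 0.5:
        return "same"
    if rho <= -0.5:
        return "inverted"
    return "mixed"


def chain_blocks(
    anchors: Sequence[Anchor],
    min_anchors: int = 6,
    max_gap: int | None = 15,
) -> list[SyntenyBlock]:
    """Partition anchors of one species pair into synteny blocks.

    Raises ``ValueError`` if anchors span more than one species pair.
    """
    anchors = list(anchors)
    if not anchors:
        return []
    species_pairs = {(a.species_a, a.species_b) for a in anchors}
    if len(species_pairs) > 1:
        raise ValueError(f"anchors span multiple species pairs: {sorted(species_pairs)}")
    sp_a, sp_b = next(iter(species_pairs))

    by_chrom: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault((a.chr_a, a.chr_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (chr_a, chr_b), group in sorted(by_chrom.items()):
        comps = _components(group, max_gap)
        comps = [c for c in comps if len(c) >= min_anchors]
        comps.sort(key=lambda c: min(a.rank_a for a in c))
        for k, comp in enumerate(comps):
            members = tuple(sorted(comp, key=lambda a: (a.rank_a, a.rank_b, a.gene_a)))
            blocks.append(
                SyntenyBlock(
                    id=f"{sp_a}.{chr_a}|{sp_b}.{chr_b}#{k}",
                    species_a=sp_a,
                    species_b=sp_b,
                    chr_a=chr_a,
                    chr_b=chr_b,
                    anchors=members,
                    orientation=_orientation(members),
                    span_a=(min(a.rank_a for a in members), max(a.rank_a for a in members)),
                    span_b=(min(a.rank_b for a in members), max(a.rank_b for a in members)),
                )
            )
    return blocks


def block_statistics(blocks: Sequence[SyntenyBlock]):
    """Per-block summary table plus block counts per chromosome pair.

    Density is anchors per rank of span on the A side (span measured as
    number of rank positions covered, inclusive).
    """
    import pandas as pd

    rows = []
    for b in blocks:
        span_len_a = b.span_a[1] - b.span_a[0] + 1
        span_len_b = b.span_b[1] - b.span_b[0] + 1
        rows.append(
            {
                "block_id": b.id,
                "species_a": b.species_a,
                "species_b": b.species_b,
                "chr_a": b.chr_a,
                "chr_b": b.chr_b,
                "n_anchors": b.n_anchors,
                "span_a_start": b.span_a[0],
                "span_a_end": b.span_a[1],
                "span_b_start": b.span_b[0],
                "span_b_end": b.span_b[1],
                "orientation": b.orientation,
                "density_a": b.n_anchors / span_len_a,
                "density_b": b.n_anchors / span_len_b,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "species_a",
            "species_b",
            "chr_a",
            "chr_b",
            "n_anchors",
            "span_a_start",
            "span_a_end",
            "span_b_start",
            "span_b_end",
            "orientation",
            "density_a",
            "density_b",
        ],
    )
    return df
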