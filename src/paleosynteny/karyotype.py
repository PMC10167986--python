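"""Step 4 — merging synteny blocks into an ancestral karyotype.

Blocks from all species pairs are merged into conserved ancestral regions
(CARs, i.e. protochromosomes).  The construction is a connected-components
computation over a segment–block graph: nodes are per-species chromosome
segments (overlapping block spans merged per chromosome), edges are the
blocks linking two segments.  Ortholog anchors are simultaneously merged
transitively (union–find over gene co-membership) into protogenes.

Segments — not whole chromosomes — are the graph nodes, so a modern
chromosome produced by a fusion can descend from two different CARs.

After construction, protogenes are ordered within each CAR, conserved
genes beyond one-to-one relationships are back-filled, and protogenes are
classified core (present in all investigated species) versus dispensable
(present in at least two).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .homology import ConservedPair
from .io_formats import GeneRecord
from .synteny import SyntenyBlock

__all__ = [
    "ProtoGene",
    "CAR",
    "AncestralKaryotype",
    "SegmentPair",
    "FractionationLabel",
    "refine_blocks",
    "group_blocks_into_cars",
    "order_protogenes",
    "backfill_conserved_genes",
    "classify_protogenes",
    "classify_fractionation",
]


@dataclass
class ProtoGene:
    """An ancestral gene: a cross-species homology group."""

    pg_id: str
    members: dict[str, list[str]] = field(default_factory=dict)  # species -> gene ids
    backfilled: set[str] = field(default_factory=set)
    status: str | None = None  # core | dispensable
    car_id: str | None = None
    ancestral_rank: int | None = None

    def all_members(self) -> list[str]:
        return [g for members in self.members.values() for g in members]

    def anchor_members(self) -> list[str]:
        """Members supported by Step-2 orthology (excludes back-filled genes)."""
        return [g for g in self.all_members() if g not in self.backfilled]


@dataclass
class CAR:
    """A protochromosome: an ordered group of protogenes."""

    car_id: str
    protogenes: list[str] = field(default_factory=list)  # ordered pg ids
    supporting_blocks: list[str] = field(default_factory=list)
    # species -> list of (chromosome, lo_rank, hi_rank) descending from this CAR
    derived_segments: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


@dataclass
class AncestralKaryotype:
    """The reconstructed ancestor: CARs + protogenes + provenance."""

    cars: list[CAR]
    protogenes: dict[str, ProtoGene]
    species: list[str]
    parameters: dict = field(default_factory=dict)

    def car(self, car_id: str) -> CAR:
        for c in self.cars:
            if c.car_id == car_id:
                return c
        raise KeyError(car_id)

    def audit(self) -> None:
        """Check CAR disjointness and pg uniqueness; raise on violation."""
        seen: set[str] = set()
        for car in self.cars:
            for pg_id in car.protogenes:
                if pg_id in seen:
                    raise AssertionError(f"protogene {pg_id} in more than one CAR")
                seen.add(pg_id)
        for pg in self.protogenes.values():
            if pg.car_id is not None and pg.pg_id not in self.car(pg.car_id).protogenes:
                raise AssertionError(f"protogene {pg.pg_id} not listed by its CAR")


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _merge_spans(
    spans: list[tuple[int, int, str]]
) -> list[tuple[int, int, list[str]]]:
    """Merge strictly overlapping rank intervals; returns (lo, hi, block_ids).

    Touching-but-disjoint intervals stay separate: a fused chromosome must
    be able to carry segments descending from different CARs.
    """
    spans = sorted(spans)
    merged: list[tuple[int, int, list[str]]] = []
    for lo, hi, bid in spans:
        if merged and lo <= merged[-1][1]:
            mlo, mhi, bids = merged[-1]
            merged[-1] = (mlo, max(mhi, hi), bids + [bid])
        else:
            merged.append((lo, hi, [bid]))
    return merged


def _gene_families(blocks: Sequence[SyntenyBlock]) -> tuple[_UnionFind, dict]:
    """Union-find over anchor co-membership plus root -> gene set map."""
    uf = _UnionFind()
    for b in blocks:
        for a in b.anchors:
            uf.union(a.gene_a, a.gene_b)
    fam: dict = {}
    for b in blocks:
        for a in b.anchors:
            for g in (a.gene_a, a.gene_b):
                fam.setdefault(uf.find(g), set()).add(g)
    return uf, fam


def refine_blocks(
    blocks: Sequence[SyntenyBlock],
    genes: Sequence[GeneRecord],
    min_side: int = 3,
    min_witness_votes: int = 2,
    boundary_tolerance: int = 2,
) -> list[SyntenyBlock]:
    """Split blocks that bridge two ancestral chromosomes.

    A rearrangement shared by both species of a pair (a fusion or
    translocation on their common branch) yields one continuous block
    spanning the junction, which would wrongly merge two CARs.  Witness
    species expose such junctions: for each block, each witness labels
    every anchor with the chromosome set its homology family occupies in
    that witness.  A block is cut where a strict majority of informative
    witnesses — and at least ``min_witness_votes`` of them — see a clean
    two-run chromosome switch with at least ``min_side`` labelled anchors
    on each side (votes within ``boundary_tolerance`` anchors are pooled).

    Requiring a single switch leaves events private to the witness alone
    (which produce three or more runs, or no quorum) uncut; spurious cuts
    of genuine blocks are healed downstream because the halves still
    share genes with blocks of other species pairs.
    """
    uf, fam = _gene_families(blocks)
    info = {g.gene_id: g for g in genes}
    pg_chrom: dict = {}
    for root, members in fam.items():
        per_sp: dict[str, set[str]] = {}
        for g in members:
            rec = info.get(g)
            if rec is not None:
                per_sp.setdefault(rec.species, set()).add(rec.chromosome)
        pg_chrom[root] = {sp: tuple(sorted(cs)) for sp, cs in per_sp.items()}

    all_species = sorted({s for b in blocks for s in (b.species_a, b.species_b)})
    out: list[SyntenyBlock] = []
    for b in blocks:
        witnesses = [s for s in all_species if s not in (b.species_a, b.species_b)]
        anchors = list(b.anchors)
        roots = [uf.find(a.gene_a) for a in anchors]
        votes: dict[int, int] = {}
        informative = 0
        for w in witnesses:
            labelled = [
                (i, pg_chrom[r].get(w)) for i, r in enumerate(roots) if pg_chrom[r].get(w)
            ]
            if not labelled:
                continue
            informative += 1
            labels = [lab for _, lab in labelled]
            if len(set(labels)) != 2:
                continue
            switches = [k for k in range(1, len(labels)) if labels[k] != labels[k - 1]]
            if len(switches) != 1:
                continue
            k = switches[0]
            if k < min_side or len(labels) - k < min_side:
                continue
            votes[labelled[k][0]] = votes.get(labelled[k][0], 0) + 1

        cut = None
        if votes:
            pooled: list[tuple[int, int]] = []
            for boundary, v in sorted(votes.items()):
                if pooled and boundary - pooled[-1][0] <= boundary_tolerance:
                    pooled[-1] = (pooled[-1][0], pooled[-1][1] + v)
                else:
                    pooled.append((boundary, v))
            for boundary, v in pooled:
                if v >= min_witness_votes and 2 * v > informative:
                    cut = boundary
                    break
        if cut is None:
            out.append(b)
            continue
        for part_idx, part in enumerate((anchors[:cut], anchors[cut:])):
            members = tuple(part)
            out.append(
                SyntenyBlock(
                    id=f"{b.id}.{part_idx}",
                    species_a=b.species_a,
                    species_b=b.species_b,
                    chr_a=b.chr_a,
                    chr_b=b.chr_b,
                    anchors=members,
                    orientation=b.orientation,
                    span_a=(min(a.rank_a for a in members), max(a.rank_a for a in members)),
                    span_b=(min(a.rank_b for a in members), max(a.rank_b for a in members)),
                )
            )
    return out


def group_blocks_into_cars(
    blocks: Sequence[SyntenyBlock],
    parameters: Mapping | None = None,
) -> AncestralKaryotype:
    """Merge synteny blocks from all species pairs into CARs and protogenes.

    CARs are the connected components of the block graph: two blocks share
    synteny when they have at least one anchor gene in common (a block on
    A-B and a block on A-C covering the same region of A share A's genes).
    Protogenes are the connected components of anchor co-membership over
    the genes of all retained blocks; every block holding a member of a
    protogene lies in the same component, so the protogene's CAR is
    unambiguous.

    Each CAR's derived segments are the per-chromosome rank intervals of
    its own blocks (overlapping intervals merged), so a fused modern
    chromosome descends from every CAR with a block on it.
    """
    # 1. connected components over blocks sharing anchor genes
    graph = nx.Graph()
    graph.add_nodes_from(b.id for b in blocks)
    blocks_of_gene: dict[str, list[str]] = {}
    for b in blocks:
        for a in b.anchors:
            for g in (a.gene_a, a.gene_b):
                blocks_of_gene.setdefault(g, []).append(b.id)
    for bids in blocks_of_gene.values():
        for other in bids[1:]:
            graph.add_edge(bids[0], other)

    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    block_by_id = {b.id: b for b in blocks}
    block_to_car: dict[str, str] = {}
    cars: list[CAR] = []
    for k, comp in enumerate(components, start=1):
        car_id = f"CAR_{k:02d}"
        spans_by_chrom: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        supporting = sorted(comp)
        for bid in supporting:
            block_to_car[bid] = car_id
            b = block_by_id[bid]
            spans_by_chrom.setdefault((b.species_a, b.chr_a), []).append(
                (b.span_a[0], b.span_a[1], bid)
            )
            spans_by_chrom.setdefault((b.species_b, b.chr_b), []).append(
                (b.span_b[0], b.span_b[1], bid)
            )
        segments: dict[str, list[tuple[str, int, int]]] = {}
        for (sp, chrom), spans in sorted(spans_by_chrom.items()):
            for lo, hi, _bids in _merge_spans(spans):
                segments.setdefault(sp, []).append((chrom, lo, hi))
        cars.append(
            CAR(car_id=car_id, supporting_blocks=supporting, derived_segments=segments)
        )

    # 3. protogenes: union-find over anchor co-membership
    uf = _UnionFind()
    gene_species: dict[str, str] = {}
    gene_blocks: dict[str, list[str]] = {}
    for b in blocks:
        for a in b.anchors:
            uf.union(a.gene_a, a.gene_b)
            gene_species[a.gene_a] = a.species_a
            gene_species[a.gene_b] = a.species_b
            gene_blocks.setdefault(a.gene_a, []).append(b.id)
            gene_blocks.setdefault(a.gene_b, []).append(b.id)

    families: dict = {}
    for g in gene_species:
        families.setdefault(uf.find(g), []).append(g)

    protogenes: dict[str, ProtoGene] = {}
    for i, (_, genes) in enumerate(
        sorted(families.items(), key=lambda kv: min(kv[1])), start=1
    ):
        pg = ProtoGene(pg_id=f"PG_{i:06d}")
        for g in sorted(genes):
            pg.members.setdefault(gene_species[g], []).append(g)
        # majority vote over the CARs of the blocks this family's anchors
        # belong to; ties broken by CAR id
        votes: dict[str, int] = {}
        for g in genes:
            for bid in gene_blocks.get(g, []):
                cid = block_to_car[bid]
                votes[cid] = votes.get(cid, 0) + 1
        pg.car_id = min(votes, key=lambda c: (-votes[c], c))
        protogenes[pg.pg_id] = pg

    for pg in protogenes.values():
        next(c for c in cars if c.car_id == pg.car_id).protogenes.append(pg.pg_id)

    species = sorted({sp for b in blocks for sp in (b.species_a, b.species_b)})
    kt = AncestralKaryotype(
        cars=cars,
        protogenes=protogenes,
        species=species,
        parameters=dict(parameters or {}),
    )
    kt.audit()
    return kt


def _normalized_rank(g: GeneRecord, chrom_sizes: Mapping[tuple[str, str], int]) -> float:
    n = chrom_sizes[(g.species, g.chromosome)]
    return g.rank / (n - 1) if n > 1 else 0.5


def order_protogenes(
    car: CAR,
    karyotype: AncestralKaryotype,
    genes: Sequence[GeneRecord],
    reference: str = "median",
) -> None:
    """Assign dense ancestral ranks to the CAR's protogenes in place.

    With a reference species, protogenes present in the reference are
    sorted by (chromosome, rank) of their first reference member; absent
    protogenes are interleaved by the median of their normalized ranks
    across the species bearing them.  ``reference="median"`` orders every
    protogene by that median.  Ties break by pg id.
    """
    info = {g.gene_id: g for g in genes}
    chrom_sizes: dict[tuple[str, str], int] = {}
    for g in genes:
        key = (g.species, g.chromosome)
        chrom_sizes[key] = max(chrom_sizes.get(key, 0), g.rank + 1)

    pgs = [karyotype.protogenes[pid] for pid in car.protogenes]
    if not pgs:
        return

    def median_norm(pg: ProtoGene) -> float:
        vals = [
            _normalized_rank(info[g], chrom_sizes)
            for g in pg.anchor_members()
            if g in info
        ]
        return statistics.median(vals) if vals else 0.5

    if reference == "median":
        keyed = sorted(pgs, key=lambda pg: (median_norm(pg), pg.pg_id))
    else:
        present = [pg for pg in pgs if reference in pg.members]
        if not present:
            raise ValueError(
                f"reference species {reference!r} absent from CAR {car.car_id}"
            )

        def ref_key(pg: ProtoGene):
            recs = [info[g] for g in pg.members[reference] if g in info]
            rec = min(recs, key=lambda r: (r.chromosome, r.rank))
            return (rec.chromosome, rec.rank)

        present.sort(key=lambda pg: (*ref_key(pg), pg.pg_id))
        m = len(present)
        frac = {pg.pg_id: (i / (m - 1) if m > 1 else 0.5) for i, pg in enumerate(present)}
        keyed = sorted(
            pgs,
            key=lambda pg: (
                frac[pg.pg_id] if pg.pg_id in frac else median_norm(pg),
                pg.pg_id,
            ),
        )

    car.protogenes = [pg.pg_id for pg in keyed]
    for i, pg in enumerate(keyed):
        pg.ancestral_rank = i


def backfill_conserved_genes(
    karyotype: AncestralKaryotype,
    step1_pairs: Sequence[ConservedPair],
) -> AncestralKaryotype:
    """Attach Step-1 conserved genes beyond 1:1 relations to protogenes.

    A gene not yet in any protogene attaches to the protogene of its
    best-scoring conserved partner (ties: lexicographic pg id); at most
    one attachment per gene.  CAR structure, protogene count and ordering
    are never modified; attached genes are flagged as back-filled.
    """
    pg_of_gene: dict[str, str] = {}
    for pg in karyotype.protogenes.values():
        for g in pg.all_members():
            pg_of_gene[g] = pg.pg_id

    # candidate attachments: (score, pg_id) per unplaced gene
    best: dict[str, tuple[float, str, str]] = {}  # gene -> (score, pg_id, species)
    for p in step1_pairs:
        for gene, sp, partner in (
            (p.gene_a, p.species_a, p.gene_b),
            (p.gene_b, p.species_b, p.gene_a),
        ):
            if gene in pg_of_gene or partner not in pg_of_gene:
                continue
            cand = (p.score, pg_of_gene[partner], sp)
            cur = best.get(gene)
            # higher score wins; on equal score the smaller pg id wins
            if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best[gene] = cand

    for gene, (_score, pg_id, sp) in sorted(best.items()):
        pg = karyotype.protogenes[pg_id]
        pg.members.setdefault(sp, []).append(gene)
        pg.backfilled.add(gene)
    karyotype.audit()
    return karyotype


def classify_protogenes(
    karyotype: AncestralKaryotype, species: Sequence[str] | None = None
) -> AncestralKaryotype:
    """Set core/dispensable status on every protogene.

    Core: members present for every investigated species.  Dispensable:
    members in at least two.  A protogene with members in fewer than two
    species violates the construction and raises ``ValueError``.
    """
    investigated = list(species) if species is not None else karyotype.species
    for pg in karyotype.protogenes.values():
        n_sp = sum(1 for sp in pg.members if pg.members[sp])
        if n_sp < 2:
            raise ValueError(
                f"protogene {pg.pg_id} has members in {n_sp} species (< 2)"
            )
        pg.status = (
            "core" if all(sp in pg.members and pg.members[sp] for sp in investigated)
            else "dispensable"
        )
    return karyotype


@dataclass(frozen=True)
class SegmentPair:
    """Two descendant segments of one CAR region duplicated by a WGD."""

    segment_a: str
    genes_a: frozenset[str]
    segment_b: str
    genes_b: frozenset[str]


@dataclass(frozen=True)
class FractionationLabel:
    """LF/MF assignment for one duplicated segment pair."""

    lf_segment: str
    mf_segment: str
    lf_retained: int
    mf_retained: int
    tie: bool


def classify_fractionation(
    karyotype: AncestralKaryotype,
    duplicated_segment_pairs: Sequence[SegmentPair],
) -> list[FractionationLabel]:
    """Label each duplicated segment pair LF (least) / MF (most fractionated).

    Retention is counted as the number of the segment's genes that are
    members of any protogene.  The segment retaining more protogene
    members is LF; ties are labelled by lexicographic segment id with the
    tie flag set.
    """
    member_genes = {
        g for pg in karyotype.protogenes.values() for g in pg.all_members()
    }
    labels: list[FractionationLabel] = []
    for pair in duplicated_segment_pairs:
        ra = len(pair.genes_a & member_genes)
        rb = len(pair.genes_b & member_genes)
        if ra > rb or (ra == rb and pair.segment_a <= pair.segment_b):
            lf_seg, mf_seg, lf_n, mf_n = pair.segment_a, pair.segment_b, ra, rb
        else:
            lf_seg, mf_seg, lf_n, mf_n = pair.segment_b, pair.segment_a, rb, ra
        labels.append(
            FractionationLabel(
                lf_segment=lf_seg,
                mf_segment=mf_seg,
                lf_retained=lf_n,
                mf_retained=mf_n,
                tie=(ra == rb),
            )
        )
    return labels
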