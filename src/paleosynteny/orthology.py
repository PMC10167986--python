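"""Step 2 — ortholog assignment: tandem collapse + generalized RBH.

Tandem duplicates (conserved homologs on the same chromosome within a
configurable rank window) are collapsed to one representative per array
before reciprocal-best-hit assignment.  Under whole-genome duplication a
species pair may carry a 1-to-n expectation; the RBH rule generalizes to
"gene ``a`` keeps its top-n partners by score among the genes of the other
species for which ``a`` is the best partner".

Tie-breaking is deterministic throughout: score descending, then
lexicographic gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .homology import ConservedPair
from .io_formats import GeneRecord

__all__ = [
    "MultiplicityMap",
    "TandemArray",
    "TandemReport",
    "collapse_tandem_duplicates",
    "assign_orthologs",
]


@dataclass
class MultiplicityMap:
    """Expected copy ratios per ordered species pair from known WGD history.

    ``ratios[(A, B)] = n`` means each gene of A may retain up to ``n``
    orthologs in B (1-to-n).  Unspecified pairs default to 1 (classical
    1:1 RBH).
    """

    ratios: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, n in self.ratios.items():
            if n < 1:
                raise ValueError(f"multiplicity for {pair} must be >= 1, got {n}")

    def get(self, species_a: str, species_b: str) -> int:
        return self.ratios.get((species_a, species_b), 1)


@dataclass(frozen=True)
class TandemArray:
    species: str
    chromosome: str
    members: tuple[str, ...]  # gene ids, sorted by rank
    representative: str


TandemReport = list


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx

    def groups(self) -> dict:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), []).append(x)
        return out


def collapse_tandem_duplicates(
    pairs: Sequence[ConservedPair],
    genes: Sequence[GeneRecord],
    window: int = 5,
) -> tuple[list[ConservedPair], list[TandemArray]]:
    """Collapse same-chromosome conserved homolog runs to one representative.

    Two genes of the same species belong to one tandem array when they are
    conserved with each other, lie on the same chromosome, and are
    separated by at most ``window`` ranks (transitively closed).  The
    representative is the member with the highest summed score to other
    species (tie: lowest rank, then gene id); every pair involving a
    non-representative is dropped.
    """
    info = {g.gene_id: g for g in genes}
    uf = _UnionFind()
    for p in pairs:
        if p.species_a != p.species_b:
            continue
        ga, gb = info.get(p.gene_a), info.get(p.gene_b)
        if ga is None or gb is None:
            continue
        if ga.chromosome != gb.chromosome:
            continue
        if abs(ga.rank - gb.rank) <= window:
            uf.union(p.gene_a, p.gene_b)

    # summed score to *other* species, the representative-selection key
    outward: dict[str, float] = {}
    for p in pairs:
        if p.species_a == p.species_b:
            continue
        outward[p.gene_a] = outward.get(p.gene_a, 0.0) + p.score
        outward[p.gene_b] = outward.get(p.gene_b, 0.0) + p.score

    dropped: set[str] = set()
    arrays: list[TandemArray] = []
    for members in uf.groups().values():
        if len(members) < 2:
            continue
        rep = min(
            members,
            key=lambda g: (-outward.get(g, 0.0), info[g].rank, g),
        )
        g0 = info[rep]
        arrays.append(
            TandemArray(
                species=g0.species,
                chromosome=g0.chromosome,
                members=tuple(sorted(members, key=lambda g: info[g].rank)),
                representative=rep,
            )
        )
        dropped.update(m for m in members if m != rep)

    kept = [p for p in pairs if p.gene_a not in dropped and p.gene_b not in dropped]
    arrays.sort(key=lambda a: (a.species, a.chromosome, a.members))
    return kept, arrays


def _rank_key(p: ConservedPair, partner: str):
    return (-p.score, partner)


def assign_orthologs(
    pairs: Sequence[ConservedPair],
    mult: MultiplicityMap | None = None,
) -> list[ConservedPair]:
    """Generalized reciprocal-best-hit ortholog assignment.

    Within each species pair (A, B) with expected ratio 1-to-n (``n =
    mult.get(A, B)``), gene ``a`` of A keeps its top-n partners by score
    among the genes ``b`` of B whose single best partner in A is ``a``.
    With n=1 this is classical RBH.  When both directions carry a
    multiplicity > 1 (independent WGDs on both lineages), an edge is kept
    when each end ranks within the other's allowance.

    Within-species pairs are ignored; genes retaining no partner
    (species-specific genes) are simply absent from the output.
    """
    mult = mult or MultiplicityMap()
    by_species_pair: dict[tuple[str, str], list[ConservedPair]] = {}
    for p in pairs:
        if p.species_a == p.species_b:
            continue
        key = tuple(sorted((p.species_a, p.species_b)))
        by_species_pair.setdefault(key, []).append(p)

    out: list[ConservedPair] = []
    for (sp_x, sp_y), plist in sorted(by_species_pair.items()):
        n_xy = mult.get(sp_x, sp_y)  # partners in Y allowed per X gene
        n_yx = mult.get(sp_y, sp_x)
        # edges[(x, y)] keyed with x in sp_x, y in sp_y
        edges: dict[tuple[str, str], ConservedPair] = {}
        for p in plist:
            if p.species_a == sp_x:
                edges[(p.gene_a, p.gene_b)] = p
            else:
                edges[(p.gene_b, p.gene_a)] = p

        partners_of_x: dict[str, list[str]] = {}
        partners_of_y: dict[str, list[str]] = {}
        for x, y in edges:
            partners_of_x.setdefault(x, []).append(y)
            partners_of_y.setdefault(y, []).append(x)

        def top(gene, others, k, side):
            ranked = sorted(
                others,
                key=lambda o: _rank_key(edges[(gene, o) if side == "x" else (o, gene)], o),
            )
            return ranked[:k]

        top_of_x = {x: top(x, ys, n_xy, "x") for x, ys in partners_of_x.items()}
        top_of_y = {y: top(y, xs, n_yx, "y") for y, xs in partners_of_y.items()}

        retained: set[tuple[str, str]] = set()
        if n_yx == 1:
            candidates: dict[str, list[str]] = {}
            for y, xs in top_of_y.items():
                candidates.setdefault(xs[0], []).append(y)
            for x, ys in candidates.items():
                ys.sort(key=lambda y: _rank_key(edges[(x, y)], y))
                retained.update((x, y) for y in ys[:n_xy])
        elif n_xy == 1:
            candidates = {}
            for x, ys in top_of_x.items():
                candidates.setdefault(ys[0], []).append(x)
            for y, xs in candidates.items():
                xs.sort(key=lambda x: _rank_key(edges[(x, y)], x))
                retained.update((x, y) for x in xs[:n_yx])
        else:
            # both sides duplicated: plain mutual top-k
            for (x, y) in edges:
                if y in top_of_x[x] and x in top_of_y[y]:
                    retained.add((x, y))

        out.extend(edges[e] for e in sorted(retained))
    out.sort(key=lambda p: (p.gene_a, p.gene_b))
    return out
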