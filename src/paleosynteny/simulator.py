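"""Ground-truthed genome-evolution simulator.

An ancestral gene order is evolved along a rooted species tree through
inversions, fusions, fissions, translocations, deletions, tandem
duplications and whole-genome duplications with biased fractionation.
The simulator emits exactly the inputs the pipeline consumes — per-species
gene tables and BLAST-like HSP tables with identities decaying along the
tree — together with a :class:`GroundTruth` carrying the ancestor, the
descent map, the event ledger and the set of true ortholog pairs.

Event counts per branch are Poisson(rate x branch length); positions and
targets are uniform.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from .io_formats import GeneRecord, HspRecord, assign_ranks

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "MetricsReport",
    "simulate",
    "truth_metrics",
]

EVENT_TYPES = (
    "inversion",
    "fusion",
    "fission",
    "translocation",
    "deletion",
    "tandem_duplication",
)


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``rates`` maps event type to events per unit branch length.
    ``wgd_events`` lists (branch, kind) where ``branch`` names the child
    node of the edge (a leaf name or an internal node label in the
    newick) and ``kind`` is ``duplication`` or ``triplication``.
    ``fractionation_bias`` is the probability that a post-WGD loss hits
    the designated most-fractionated (MF) subgenome.
    """

    n_ancestral_chromosomes: int = 5
    n_ancestral_genes: int = 500
    species_tree: str = "((A:1.0,B:1.0)AB:1.0,C:2.0)R;"
    rates: dict[str, float] = field(default_factory=dict)
    wgd_events: list[tuple[str, str]] = field(default_factory=list)
    wgd_loss_rate: float = 0.6
    fractionation_bias: float = 0.7
    identity_decay: float = 4.0  # percent identity lost per unit branch length
    noise_sd: float = 1.0
    spurious_pair_rate: float = 0.0  # spurious pairs per true cross-species pair
    multi_hsp: bool = False
    min_gene_length: int = 120
    max_gene_length: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        for ev, r in self.rates.items():
            if ev not in EVENT_TYPES:
                raise ValueError(f"unknown event type {ev!r}")
            if r < 0:
                raise ValueError(f"rate for {ev} must be >= 0")
        if not 0.5 <= self.fractionation_bias <= 1.0:
            raise ValueError("fractionation_bias must lie in [0.5, 1]")
        if self.n_ancestral_genes < self.n_ancestral_chromosomes:
            raise ValueError("need at least one gene per ancestral chromosome")


@dataclass(frozen=True)
class _GeneCopy:
    anc_id: int
    copy_id: int
    subgenome: str = ""  # "" before any WGD, else LF / MF / MF2


Genome = list  # list[list[_GeneCopy]]


@dataclass
class GroundTruth:
    """Everything needed to score a reconstruction of the simulated data."""

    ancestor: list[list[int]]  # ordered ancestral gene ids per chromosome
    descent_map: dict[int, dict[str, list[tuple[str, str]]]]  # anc -> sp -> [(gene, subg)]
    event_ledger: list[dict]
    true_orthologs: set[frozenset]
    gene_to_anc: dict[str, int]
    gene_subgenome: dict[str, str]

    def anc_chromosome(self, anc_id: int) -> int:
        for k, chrom in enumerate(self.ancestor):
            if anc_id in self._chrom_sets[k]:
                return k
        raise KeyError(anc_id)

    @property
    def _chrom_sets(self) -> list[set[int]]:
        if not hasattr(self, "_chrom_sets_cache"):
            object.__setattr__(
                self, "_chrom_sets_cache", [set(c) for c in self.ancestor]
            )
        return self._chrom_sets_cache

    @property
    def anc_position(self) -> dict[int, tuple[int, int]]:
        """Ancestral gene id -> (chromosome index, position on chromosome)."""
        if not hasattr(self, "_anc_pos_cache"):
            pos = {
                a: (k, i)
                for k, chrom in enumerate(self.ancestor)
                for i, a in enumerate(chrom)
            }
            object.__setattr__(self, "_anc_pos_cache", pos)
        return self._anc_pos_cache


@dataclass
class SimulatedDataset:
    genes: list[GeneRecord]  # all species, ranks assigned
    hsps: list[HspRecord]
    gene_lengths: dict[str, int]
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Event operators (each returns a ledger entry; genome mutated in place)
# ---------------------------------------------------------------------------


def _apply_inversion(genome: Genome, rng) -> dict:
    nonempty = [i for i, c in enumerate(genome) if len(c) >= 2]
    if not nonempty:
        return {"skipped": True}
    ci = nonempty[rng.integers(len(nonempty))]
    chrom = genome[ci]
    i, j = sorted(rng.integers(0, len(chrom), size=2))
    chrom[i : j + 1] = chrom[i : j + 1][::-1]
    return {"chromosome": ci, "interval": (int(i), int(j))}


def _apply_fission(genome: Genome, rng) -> dict:
    nonempty = [i for i, c in enumerate(genome) if len(c) >= 2]
    if not nonempty:
        return {"skipped": True}
    ci = nonempty[rng.integers(len(nonempty))]
    chrom = genome[ci]
    cut = int(rng.integers(1, len(chrom)))
    genome[ci] = chrom[:cut]
    genome.append(chrom[cut:])
    return {"chromosome": ci, "cut": cut}


def _apply_fusion(genome: Genome, rng) -> dict:
    if len(genome) < 2:
        return {"skipped": True}
    i, j = rng.choice(len(genome), size=2, replace=False)
    i, j = int(i), int(j)
    genome[i] = genome[i] + genome[j]
    del genome[j]
    return {"chromosomes": (i, j)}


def _apply_translocation(genome: Genome, rng) -> dict:
    if len(genome) < 2:
        return {"skipped": True}
    sources = [i for i, c in enumerate(genome) if len(c) >= 1]
    if len(sources) < 2:
        return {"skipped": True}
    si = sources[rng.integers(len(sources))]
    src = genome[si]
    i, j = sorted(rng.integers(0, len(src), size=2))
    moved = src[i : j + 1]
    genome[si] = src[:i] + src[j + 1 :]
    targets = [k for k in range(len(genome)) if k != si]
    ti = targets[rng.integers(len(targets))]
    pos = int(rng.integers(0, len(genome[ti]) + 1))
    genome[ti] = genome[ti][:pos] + moved + genome[ti][pos:]
    if not genome[si]:
        del genome[si]
    return {"source": si, "interval": (int(i), int(j)), "target": ti, "position": pos}


def _apply_deletion(genome: Genome, rng) -> dict:
    nonempty = [i for i, c in enumerate(genome) if len(c) >= 1]
    if not nonempty:
        return {"skipped": True}
    ci = nonempty[rng.integers(len(nonempty))]
    gi = int(rng.integers(len(genome[ci])))
    lost = genome[ci].pop(gi)
    if not genome[ci]:
        del genome[ci]
    return {"chromosome": ci, "position": gi, "lost_copy": lost.copy_id, "n_deleted": 1}


def _apply_tandem_duplication(genome: Genome, rng, counter: itertools.count) -> dict:
    nonempty = [i for i, c in enumerate(genome) if len(c) >= 1]
    if not nonempty:
        return {"skipped": True}
    ci = nonempty[rng.integers(len(nonempty))]
    gi = int(rng.integers(len(genome[ci])))
    src = genome[ci][gi]
    dup = _GeneCopy(anc_id=src.anc_id, copy_id=next(counter), subgenome=src.subgenome)
    genome[ci].insert(gi + 1, dup)
    return {"chromosome": ci, "position": gi, "copied": src.copy_id, "n_inserted": 1}


def _apply_wgd(
    genome: Genome, kind: str, loss_rate: float, bias: float, rng, counter: itertools.count
) -> dict:
    n_extra_sets = 1 if kind == "duplication" else 2
    original = [list(c) for c in genome]
    n_added = 0
    extra_sets: list[list[list[_GeneCopy]]] = []
    for s in range(n_extra_sets):
        label = "MF" if s == 0 else "MF2"
        new_set = []
        for chrom in original:
            new_chrom = [
                _GeneCopy(anc_id=g.anc_id, copy_id=next(counter), subgenome=label)
                for g in chrom
            ]
            n_added += len(new_chrom)
            new_set.append(new_chrom)
        extra_sets.append(new_set)
    # original copies form the least-fractionated (dominant) subgenome
    for ci, chrom in enumerate(genome):
        genome[ci] = [
            _GeneCopy(anc_id=g.anc_id, copy_id=g.copy_id, subgenome="LF") for g in chrom
        ]
    for new_set in extra_sets:
        genome.extend(new_set)

    # biased fractionation: with probability loss_rate one copy of each
    # duplicated gene is deleted, hitting the MF subgenome with
    # probability `bias`
    n_lost = 0
    by_anc: dict[int, list[tuple[int, int]]] = {}
    for ci, chrom in enumerate(genome):
        for gi, g in enumerate(chrom):
            by_anc.setdefault(g.anc_id, []).append((ci, gi))
    to_delete: set[tuple[int, int]] = set()
    for anc_id in sorted(by_anc):
        positions = by_anc[anc_id]
        if len(positions) < 2:
            continue
        for _ in range(n_extra_sets):
            lf_pos = [p for p in positions if genome[p[0]][p[1]].subgenome == "LF"]
            mf_pos = [p for p in positions if genome[p[0]][p[1]].subgenome != "LF"]
            if not lf_pos or not mf_pos:
                break
            if rng.random() >= loss_rate:
                continue
            pool = mf_pos if rng.random() < bias else lf_pos
            victim = pool[int(rng.integers(len(pool)))]
            to_delete.add(victim)
            positions = [p for p in positions if p != victim]
            n_lost += 1
    for ci in range(len(genome)):
        genome[ci] = [
            g for gi, g in enumerate(genome[ci]) if (ci, gi) not in to_delete
        ]
    genome[:] = [c for c in genome if c]
    return {"kind": kind, "n_inserted": n_added, "n_deleted": n_lost}


# ---------------------------------------------------------------------------
# Main simulation
# ---------------------------------------------------------------------------


def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree


def _node_name(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run one simulation; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    counter = itertools.count()

    # ancestral genome: genes dealt round-robin-free, contiguous slices
    n_chrom = config.n_ancestral_chromosomes
    n_genes = config.n_ancestral_genes
    bounds = np.linspace(0, n_genes, n_chrom + 1).astype(int)
    ancestor_ids = [list(range(bounds[k], bounds[k + 1])) for k in range(n_chrom)]
    root_genome: Genome = [
        [_GeneCopy(anc_id=a, copy_id=next(counter)) for a in chrom]
        for chrom in ancestor_ids
    ]
    gene_length = {
        a: int(rng.integers(config.min_gene_length, config.max_gene_length + 1))
        for a in range(n_genes)
    }

    tree = _parse_tree(config.species_tree)
    wgd_by_branch: dict[str, list[str]] = {}
    for branch, kind in config.wgd_events:
        if kind not in ("duplication", "triplication"):
            raise ValueError(f"unknown WGD kind {kind!r}")
        wgd_by_branch.setdefault(branch, []).append(kind)

    ledger: list[dict] = []
    leaf_genomes: dict[str, Genome] = {}

    def evolve(node, genome: Genome) -> None:
        name = _node_name(node)
        blen = node.edge.length or 0.0
        if node.parent_node is not None:
            for kind in wgd_by_branch.get(name, []):
                entry = _apply_wgd(
                    genome,
                    kind,
                    config.wgd_loss_rate,
                    config.fractionation_bias,
                    rng,
                    counter,
                )
                ledger.append({"branch": name, "event": f"wgd_{kind}", **entry})
            events: list[str] = []
            for ev in EVENT_TYPES:
                rate = config.rates.get(ev, 0.0)
                if rate > 0 and blen > 0:
                    events.extend([ev] * int(rng.poisson(rate * blen)))
            rng.shuffle(events)
            for ev in events:
                if ev == "inversion":
                    entry = _apply_inversion(genome, rng)
                elif ev == "fission":
                    entry = _apply_fission(genome, rng)
                elif ev == "fusion":
                    entry = _apply_fusion(genome, rng)
                elif ev == "translocation":
                    entry = _apply_translocation(genome, rng)
                elif ev == "deletion":
                    entry = _apply_deletion(genome, rng)
                else:
                    entry = _apply_tandem_duplication(genome, rng, counter)
                ledger.append({"branch": name, "event": ev, **entry})
        if node.is_leaf():
            leaf_genomes[name] = genome
        else:
            children = node.child_nodes()
            for i, child in enumerate(children):
                child_genome = genome if i == len(children) - 1 else copy.deepcopy(genome)
                evolve(child, child_genome)

    evolve(tree.seed_node, root_genome)

    # --- emit gene tables -------------------------------------------------
    species = sorted(leaf_genomes)
    genes: list[GeneRecord] = []
    gene_lengths: dict[str, int] = {}
    gene_to_anc: dict[str, int] = {}
    gene_subgenome: dict[str, str] = {}
    descent_map: dict[int, dict[str, list[tuple[str, str]]]] = {}
    copies_by_species: dict[str, list[tuple[str, int]]] = {}

    for sp in species:
        genome = leaf_genomes[sp]
        idx = 0
        for ci, chrom in enumerate(genome):
            chrom_name = f"{sp}_chr{ci + 1}"
            pos = 1
            for g in chrom:
                gid = f"{sp}_g{idx:05d}"
                idx += 1
                length_aa = gene_length[g.anc_id]
                genes.append(
                    GeneRecord(
                        gene_id=gid,
                        species=sp,
                        chromosome=chrom_name,
                        start=pos,
                        end=pos + 3 * length_aa - 1,
                        strand="+",
                    )
                )
                pos += 3 * length_aa + 200
                gene_lengths[gid] = length_aa
                gene_to_anc[gid] = g.anc_id
                gene_subgenome[gid] = g.subgenome
                descent_map.setdefault(g.anc_id, {}).setdefault(sp, []).append(
                    (gid, g.subgenome)
                )
                copies_by_species.setdefault(sp, []).append((gid, g.anc_id))
    genes = assign_ranks(genes)

    # --- pairwise species distances --------------------------------------
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dist: dict[tuple[str, str], float] = {}
    for sa, sb in itertools.combinations(species, 2):
        d = pdm.patristic_distance(taxa[sa], taxa[sb])
        dist[(sa, sb)] = dist[(sb, sa)] = float(d)
    for sp in species:
        dist[(sp, sp)] = 0.0

    # --- HSPs for every true homolog pair ---------------------------------
    hsps: list[HspRecord] = []
    true_orthologs: set[frozenset] = set()

    def emit_pair(ga: str, gb: str, d: float) -> None:
        identity = 100.0 - config.identity_decay * d + rng.normal(0.0, config.noise_sd)
        identity = float(min(100.0, max(20.0, identity)))
        for q, s in ((ga, gb), (gb, ga)):
            qlen = gene_lengths[q]
            score = round(2.0 * qlen * identity / 100.0, 1)
            if config.multi_hsp and qlen >= 90:
                n_parts = int(rng.integers(2, 4))
                cuts = sorted(
                    rng.choice(np.arange(30, qlen - 29), size=n_parts - 1, replace=False)
                )
                pieces = np.diff([0, *cuts, qlen]).astype(int)
            else:
                pieces = np.array([qlen])
            offset = 1
            for plen in pieces:
                plen = int(plen)
                nid = int(round(identity / 100.0 * plen))
                nid = max(0, min(plen, nid))
                hsps.append(
                    HspRecord(
                        query_id=q,
                        subject_id=s,
                        hsp_length=plen,
                        n_identities=nid,
                        query_start=offset,
                        query_end=offset + plen - 1,
                        subject_start=offset,
                        subject_end=offset + plen - 1,
                        score=score / len(pieces),
                    )
                )
                offset += plen

    n_true_cross = 0
    for anc_id in sorted(descent_map):
        per_sp = descent_map[anc_id]
        sps = sorted(per_sp)
        # cross-species homolog pairs
        for sa, sb in itertools.combinations(sps, 2):
            for (ga, _), (gb, _) in itertools.product(per_sp[sa], per_sp[sb]):
                emit_pair(ga, gb, dist[(sa, sb)])
                true_orthologs.add(frozenset((ga, gb)))
                n_true_cross += 1
        # within-species homologs (tandem or WGD copies)
        for sp in sps:
            ids = [g for g, _ in per_sp[sp]]
            for ga, gb in itertools.combinations(ids, 2):
                emit_pair(ga, gb, 0.0)

    # spurious low-identity pairs
    n_spurious = int(rng.poisson(config.spurious_pair_rate * max(1, n_true_cross)))
    all_ids = sorted(gene_lengths)
    for _ in range(n_spurious):
        ga, gb = (all_ids[int(i)] for i in rng.integers(0, len(all_ids), size=2))
        if ga == gb or gene_to_anc[ga] == gene_to_anc[gb]:
            continue
        identity = float(rng.uniform(20, 35))
        for q, s in ((ga, gb), (gb, ga)):
            qlen = gene_lengths[q]
            plen = max(1, int(0.3 * qlen))
            hsps.append(
                HspRecord(
                    query_id=q,
                    subject_id=s,
                    hsp_length=plen,
                    n_identities=int(identity / 100.0 * plen),
                    query_start=1,
                    query_end=plen,
                    subject_start=1,
                    subject_end=plen,
                    score=round(2.0 * plen * identity / 100.0, 1),
                )
            )

    truth = GroundTruth(
        ancestor=ancestor_ids,
        descent_map=descent_map,
        event_ledger=ledger,
        true_orthologs=true_orthologs,
        gene_to_anc=gene_to_anc,
        gene_subgenome=gene_subgenome,
    )
    return SimulatedDataset(
        genes=genes,
        hsps=hsps,
        gene_lengths=gene_lengths,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Scoring a reconstruction against the truth
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    ortholog_precision: float
    ortholog_recall: float
    car_ari: float
    kendall_tau_per_car: dict[str, float]

    @property
    def mean_kendall_tau(self) -> float:
        taus = list(self.kendall_tau_per_car.values())
        return float(np.mean(taus)) if taus else float("nan")


def truth_metrics(
    inferred,
    truth: GroundTruth,
    orthologs: Sequence | None = None,
) -> MetricsReport:
    """Score an inferred karyotype against the simulator's ground truth.

    Ortholog precision/recall are computed from ``orthologs`` (Step-2
    rows) when given, else from cross-species co-membership in protogenes.
    The adjusted Rand index compares, over surviving anchor genes, the
    inferred CAR assignment with the true ancestral-chromosome labels.
    Kendall tau (absolute value: ancestral chromosome orientation is not
    identifiable) compares each CAR's protogene order with the true
    ancestral order.
    """
    from sklearn.metrics import adjusted_rand_score

    # precision / recall
    if orthologs is not None:
        inferred_pairs = {frozenset((p.gene_a, p.gene_b)) for p in orthologs}
    else:
        inferred_pairs = set()
        for pg in inferred.protogenes.values():
            members = pg.anchor_members()
            sp_of = {}
            for sp, ids in pg.members.items():
                for g in ids:
                    sp_of[g] = sp
            for ga, gb in itertools.combinations(members, 2):
                if sp_of[ga] != sp_of[gb]:
                    inferred_pairs.add(frozenset((ga, gb)))
    tp = len(inferred_pairs & truth.true_orthologs)
    precision = tp / len(inferred_pairs) if inferred_pairs else float("nan")
    recall = tp / len(truth.true_orthologs) if truth.true_orthologs else float("nan")

    # ARI over surviving anchor genes
    anc_pos = truth.anc_position
    true_labels: list[int] = []
    car_labels: list[str] = []
    for pg in inferred.protogenes.values():
        if pg.car_id is None:
            continue
        for g in pg.anchor_members():
            anc = truth.gene_to_anc.get(g)
            if anc is None:
                continue
            true_labels.append(anc_pos[anc][0])
            car_labels.append(pg.car_id)
    ari = (
        float(adjusted_rand_score(true_labels, car_labels))
        if true_labels
        else float("nan")
    )

    # per-CAR order recovery
    taus: dict[str, float] = {}
    for car in inferred.cars:
        ranks, true_pos = [], []
        for pg_id in car.protogenes:
            pg = inferred.protogenes[pg_id]
            if pg.ancestral_rank is None:
                continue
            ancs = [truth.gene_to_anc[g] for g in pg.anchor_members() if g in truth.gene_to_anc]
            if not ancs:
                continue
            anc = max(set(ancs), key=ancs.count)
            ranks.append(pg.ancestral_rank)
            true_pos.append(anc_pos[anc][1])
        if len(ranks) >= 2:
            tau = stats.kendalltau(ranks, true_pos).statistic
            taus[car.car_id] = abs(float(tau)) if not np.isnan(tau) else float("nan")
    return MetricsReport(
        ortholog_precision=precision,
        ortholog_recall=recall,
        car_ari=ari,
        kendall_tau_per_car=taus,
    )
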