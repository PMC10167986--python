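"""Step-4 unit, property and oracle tests.

The CAR-construction oracle is an independent breadth-first transitive
closure over "blocks sharing at least one gene".
"""

import itertools

import numpy as np
import pytest

from paleosynteny.homology import ConservedPair
from paleosynteny.io_formats import GeneRecord, assign_ranks
from paleosynteny.karyotype import (
    SegmentPair,
    backfill_conserved_genes,
    classify_fractionation,
    classify_protogenes,
    group_blocks_into_cars,
    order_protogenes,
    refine_blocks,
)
from paleosynteny.synteny import Anchor, SyntenyBlock, build_anchors, chain_blocks
from tests.conftest import run_full_pipeline


def _block(bid, pairs, sp_a="A", sp_b="B", chr_a="c1", chr_b="k1"):
    """pairs: list of (gene_a, rank_a, gene_b, rank_b)."""
    anchors = tuple(
        Anchor(ga, gb, sp_a, sp_b, chr_a, chr_b, ra, rb) for ga, ra, gb, rb in pairs
    )
    return SyntenyBlock(
        id=bid, species_a=sp_a, species_b=sp_b, chr_a=chr_a, chr_b=chr_b,
        anchors=anchors, orientation="same",
        span_a=(min(a.rank_a for a in anchors), max(a.rank_a for a in anchors)),
        span_b=(min(a.rank_b for a in anchors), max(a.rank_b for a in anchors)),
    )


class TestGroupBlocks:
    def test_transitive_linking_across_species_pairs(self):
        ab = _block("ab", [(f"a{i}", i, f"b{i}", i) for i in range(6)])
        bc = _block(
            "bc",
            [(f"b{i}", i, f"c{i}", i) for i in range(6)],
            sp_a="B", sp_b="C", chr_a="k1", chr_b="z2",
        )
        kt = group_blocks_into_cars([ab, bc])
        assert len(kt.cars) == 1
        assert len(kt.protogenes) == 6
        assert all(len(pg.members) == 3 for pg in kt.protogenes.values())

    def test_disjoint_blocks_give_two_cars(self):
        ab1 = _block("x", [(f"a{i}", i, f"b{i}", i) for i in range(6)])
        ab2 = _block(
            "y",
            [(f"p{i}", i, f"q{i}", i) for i in range(6)],
            chr_a="c2", chr_b="k2",
        )
        kt = group_blocks_into_cars([ab1, ab2])
        assert len(kt.cars) == 2

    def test_null_simulation_recovers_chromosome_number(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        assert len(kt.cars) == null_dataset.config.n_ancestral_chromosomes

    def test_fused_chromosome_descends_from_two_cars(self):
        # A's chromosome c1 carries two unrelated regions (ranks 0-5 and
        # 10-15) syntenic to different B chromosomes
        b1 = _block("b1", [(f"a{i}", i, f"b{i}", i) for i in range(6)])
        b2 = _block(
            "b2",
            [(f"a{i+10}", i + 10, f"q{i}", i) for i in range(6)],
            chr_b="k2",
        )
        kt = group_blocks_into_cars([b1, b2])
        assert len(kt.cars) == 2
        cars_on_c1 = {
            car.car_id
            for car in kt.cars
            for chrom, _, _ in car.derived_segments.get("A", [])
            if chrom == "c1"
        }
        assert len(cars_on_c1) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(50)]
        blocks = []
        for k in range(int(rng.integers(2, 8))):
            chosen = rng.choice(genes, size=6, replace=False)
            partners = [f"h{k}_{i}" for i in range(6)]
            blocks.append(
                _block(
                    f"blk{k}",
                    [(g, i, p, i) for i, (g, p) in enumerate(zip(chosen, partners))],
                    chr_a=f"c{k}", chr_b=f"k{k}",
                )
            )
        kt = group_blocks_into_cars(blocks)
        got = {
            car.car_id: frozenset(car.supporting_blocks) for car in kt.cars
        }

        # oracle: BFS closure on shared-gene relation
        def genes_of(b):
            return {a.gene_a for a in b.anchors} | {a.gene_b for a in b.anchors}

        unvisited = {b.id: b for b in blocks}
        comps = []
        while unvisited:
            seed_id = sorted(unvisited)[0]
            frontier = [unvisited.pop(seed_id)]
            comp = {seed_id}
            while frontier:
                cur = frontier.pop()
                for other_id in list(unvisited):
                    if genes_of(unvisited[other_id]) & genes_of(cur):
                        comp.add(other_id)
                        frontier.append(unvisited.pop(other_id))
            comps.append(frozenset(comp))
        assert sorted(got.values(), key=sorted) == sorted(comps, key=sorted)

    def test_audit_passes_after_every_operation(self, null_dataset):
        kt, _, pairs = run_full_pipeline(null_dataset)
        kt.audit()
        backfill_conserved_genes(kt, pairs).audit()
        classify_protogenes(kt).audit()


class TestOrderProtogenes:
    def _karyotype(self):
        blocks = [_block("b", [(f"a{i}", i, f"b{i}", i) for i in range(6)])]
        return group_blocks_into_cars(blocks)

    def _genes(self, ref_ranks):
        recs = []
        for i, r in enumerate(ref_ranks):
            recs.append(GeneRecord("A", "c1", 10 * r + 1, 10 * r + 5, f"a{i}"))
            recs.append(GeneRecord("B", "k1", 10 * i + 1, 10 * i + 5, f"b{i}"))
        return assign_ranks(recs)

    def test_sorted_by_reference_rank(self):
        kt = self._karyotype()
        genes = self._genes([5, 2, 9, 0, 7, 3])
        order_protogenes(kt.cars[0], kt, genes, reference="A")
        ordered_a_genes = [
            kt.protogenes[pid].members["A"][0] for pid in kt.cars[0].protogenes
        ]
        assert ordered_a_genes == ["a3", "a1", "a5", "a0", "a4", "a2"]

    def test_missing_reference_species_raises(self):
        kt = self._karyotype()
        genes = self._genes(range(6))
        with pytest.raises(ValueError, match="C"):
            order_protogenes(kt.cars[0], kt, genes, reference="C")

    def test_median_rank_interleaving(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset, reference="median")
        for car in kt.cars:
            ranks = [kt.protogenes[p].ancestral_rank for p in car.protogenes]
            assert ranks == list(range(len(ranks)))

    def test_null_simulation_order_equals_ancestor(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset, reference="A")
        anc_pos = null_dataset.truth.anc_position
        for car in kt.cars:
            positions = []
            for pid in car.protogenes:
                members = kt.protogenes[pid].anchor_members()
                ancs = {null_dataset.truth.gene_to_anc[g] for g in members}
                assert len(ancs) == 1
                positions.append(anc_pos[ancs.pop()][1])
            assert positions == sorted(positions)


class TestBackfill:
    def test_unique_candidate_attached(self, null_dataset):
        kt, _, pairs = run_full_pipeline(null_dataset)
        member = next(iter(kt.protogenes.values())).all_members()[0]
        extra = ConservedPair(
            gene_a="zz_extra", gene_b=member, species_a="A", species_b="A",
            cip=90.0, calp=90.0, score=500.0,
        )
        before = len(kt.protogenes)
        kt = backfill_conserved_genes(kt, list(pairs) + [extra])
        assert len(kt.protogenes) == before
        owner = [pg for pg in kt.protogenes.values() if "zz_extra" in pg.backfilled]
        assert len(owner) == 1

    def test_best_scoring_pg_wins(self, null_dataset):
        kt, _, pairs = run_full_pipeline(null_dataset)
        pgs = list(kt.protogenes.values())
        m1, m2 = pgs[0].all_members()[0], pgs[1].all_members()[0]
        extras = [
            ConservedPair("zz_x", m1, "A", "A", 90.0, 90.0, score=10.0),
            ConservedPair("zz_x", m2, "A", "A", 90.0, 90.0, score=99.0),
        ]
        kt = backfill_conserved_genes(kt, list(pairs) + extras)
        assert "zz_x" in pgs[1].backfilled
        assert "zz_x" not in pgs[0].backfilled

    def test_counts_audit(self, null_dataset):
        kt, _, pairs = run_full_pipeline(null_dataset)
        n_pg_before = len(kt.protogenes)
        members_before = sum(len(pg.all_members()) for pg in kt.protogenes.values())
        kt = backfill_conserved_genes(kt, pairs)
        assert len(kt.protogenes) == n_pg_before
        assert sum(len(pg.all_members()) for pg in kt.protogenes.values()) >= members_before


class TestClassify:
    def test_core_and_dispensable(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        kt = classify_protogenes(kt, species=["A", "B", "C"])
        assert all(pg.status == "core" for pg in kt.protogenes.values())
        # declaring an absent species makes everything dispensable
        kt = classify_protogenes(kt, species=["A", "B", "C", "D"])
        assert all(pg.status == "dispensable" for pg in kt.protogenes.values())

    def test_statuses_partition_protogenes(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        kt = classify_protogenes(kt)
        n_core = sum(1 for pg in kt.protogenes.values() if pg.status == "core")
        n_disp = sum(1 for pg in kt.protogenes.values() if pg.status == "dispensable")
        assert n_core + n_disp == len(kt.protogenes)

    def test_single_species_pg_rejected(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        pg = next(iter(kt.protogenes.values()))
        pg.members = {"A": pg.members["A"]}
        with pytest.raises(ValueError, match=pg.pg_id):
            classify_protogenes(kt)


class TestFractionation:
    def test_larger_count_is_lf(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        members = sorted(
            {g for pg in kt.protogenes.values() for g in pg.all_members()}
        )
        pair = SegmentPair("segA", frozenset(members[:40]), "segB", frozenset(members[40:65]))
        (label,) = classify_fractionation(kt, [pair])
        assert label.lf_segment == "segA" and label.mf_segment == "segB"
        assert (label.lf_retained, label.mf_retained) == (40, 25)
        assert not label.tie

    def test_tie_flag(self, null_dataset):
        kt, _, _ = run_full_pipeline(null_dataset)
        members = sorted(
            {g for pg in kt.protogenes.values() for g in pg.all_members()}
        )
        pair = SegmentPair("segB", frozenset(members[:30]), "segA", frozenset(members[30:60]))
        (label,) = classify_fractionation(kt, [pair])
        assert label.tie
        assert label.lf_segment == "segA"  # lexicographic on tie


class TestRefineBlocks:
    def _fusion_bridge(self):
        """A and B share a fused chromosome; C and D keep two chromosomes."""
        genes, rows = [], {}
        n = 8  # per ancestral chromosome
        for sp in "ABCD":
            fused = sp in "AB"
            for i in range(2 * n):
                chrom = f"{sp}c1" if fused or i < n else f"{sp}c2"
                genes.append(
                    GeneRecord(sp, chrom, 10 * i + 1, 10 * i + 5, f"{sp.lower()}{i}")
                )
        genes = assign_ranks(genes)
        pairs = []
        for sa, sb in itertools.combinations("ABCD", 2):
            for i in range(2 * n):
                pairs.append(
                    ConservedPair(
                        f"{sa.lower()}{i}", f"{sb.lower()}{i}", sa, sb, 90.0, 90.0, 100.0
                    )
                )
        by_sp = {}
        for p in pairs:
            by_sp.setdefault((p.species_a, p.species_b), []).append(p)
        blocks = []
        for key in sorted(by_sp):
            blocks.extend(chain_blocks(build_anchors(by_sp[key], genes)))
        return genes, blocks

    def test_bridge_block_cut_and_cars_separated(self):
        genes, blocks = self._fusion_bridge()
        kt_raw = group_blocks_into_cars(blocks)
        assert len(kt_raw.cars) == 1  # bridged by the A-B block
        refined = refine_blocks(blocks, genes)
        kt = group_blocks_into_cars(refined)
        assert len(kt.cars) == 2

    def test_no_witness_no_split(self):
        genes, blocks = self._fusion_bridge()
        ab_only = [b for b in blocks if {b.species_a, b.species_b} == {"A", "B"}]
        assert refine_blocks(ab_only, genes) == ab_only
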