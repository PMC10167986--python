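from __future__ import annotations

import pytest

from paleosynteny import homology, karyotype, orthology, synteny
from paleosynteny.io_formats import GeneRecord, assign_ranks
from paleosynteny.orthology import MultiplicityMap
from paleosynteny.simulator import SimulatedDataset, SimulationConfig, simulate


def run_full_pipeline(
    ds: SimulatedDataset,
    mult: MultiplicityMap | None = None,
    reference: str = "median",
    refine: bool = True,
    cip_min: float = 50.0,
    calp_min: float = 50.0,
):
    """Drive the four steps on a simulated dataset; returns (karyotype, orthologs, pairs)."""
    species_of = {g.gene_id: g.species for g in ds.genes}
    summaries = homology.summarize_hsps(ds.hsps, ds.gene_lengths)
    pairs = homology.filter_conserved_pairs(
        summaries, species_of, cip_min=cip_min, calp_min=calp_min
    )
    collapsed, _ = orthology.collapse_tandem_duplicates(pairs, ds.genes)
    orthologs = orthology.assign_orthologs(collapsed, mult)
    by_pair: dict[tuple[str, str], list] = {}
    for p in orthologs:
        by_pair.setdefault(tuple(sorted((p.species_a, p.species_b))), []).append(p)
    blocks = []
    for key in sorted(by_pair):
        anchors = synteny.build_anchors(by_pair[key], ds.genes)
        blocks.extend(synteny.chain_blocks(anchors))
    if refine:
        blocks = karyotype.refine_blocks(blocks, ds.genes)
    kt = karyotype.group_blocks_into_cars(blocks)
    for car in kt.cars:
        karyotype.order_protogenes(car, kt, ds.genes, reference=reference)
    kt = karyotype.backfill_conserved_genes(kt, pairs)
    kt = karyotype.classify_protogenes(kt)
    return kt, orthologs, pairs


@pytest.fixture(scope="session")
def null_dataset() -> SimulatedDataset:
    """Three identical species: no events, no WGD."""
    cfg = SimulationConfig(
        n_ancestral_chromosomes=3, n_ancestral_genes=90, seed=11
    )
    return simulate(cfg)


@pytest.fixture()
def toy_genes() -> list[GeneRecord]:
    recs = []
    for sp in ("A", "B"):
        for chrom in ("1", "2"):
            for i in range(10):
                recs.append(
                    GeneRecord(
                        gene_id=f"{sp}{chrom}_{i}",
                        species=sp,
                        chromosome=chrom,
                        start=100 * i + 1,
                        end=100 * i + 50,
                    )
                )
    return assign_ranks(recs)
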