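# paleosynteny

Ancestral karyotype reconstruction from gene order, as a tested Python
library and CLI, together with a ground-truthed genome-evolution
simulator.

The pipeline implements the classic four-step synteny-based
reconstruction workflow:

1. **Conserved genes** (`paleosynteny.homology`) — per gene pair, BLAST
   HSPs are aggregated into the cumulative identity percentage
   (CIP = 100 x Σ identities / AL, where AL = Σ HSP lengths) and the
   cumulative alignment-length percentage (CALP = 100 x AL / query
   length). Pairs with CIP ≥ 50 and CALP ≥ 50 (inclusive, configurable)
   are retained.
2. **Orthologs** (`paleosynteny.orthology`) — tandem duplicates
   (conserved homologs within a rank window on one chromosome) are
   collapsed to one representative, then a generalized reciprocal-best-hit
   rule extracts one-to-one relationships, or 1-to-n for species pairs
   separated by n-fold whole-genome duplication.
3. **Synteny blocks** (`paleosynteny.synteny`) — ortholog anchors are
   partitioned per chromosome pair into connected components of the
   gap-adjacency graph (both rank gaps ≤ `max_gap`); components with more
   than five anchors (`min_anchors` = 6) become blocks. `max_gap=None`
   reproduces the coarse one-block-per-chromosome-pair rule.
4. **CARs / protochromosomes** (`paleosynteny.karyotype`) — blocks from
   all species pairs are merged into conserved ancestral regions
   (connected components over blocks sharing anchor genes, after
   splitting blocks that bridge two ancestral chromosomes when a majority
   of witness species contradict them). Protogenes (cross-species
   homology groups) are ordered along each CAR, conserved genes beyond
   1:1 relationships are back-filled, and protogenes are classified core
   (all species) vs dispensable (≥ 2 species). Post-WGD segment pairs
   can be labelled LF/MF (least/most fractionated) by retained-gene
   counts.

`paleosynteny.simulator` evolves an ancestral gene order through
inversions, fusions, fissions, translocations, deletions, tandem
duplications and WGD with biased fractionation, and emits exactly the
inputs the pipeline consumes plus the ground truth (descent map, event
ledger, true ortholog set) used by the test oracles.

## CLI

```bash
# simulate a ground-truthed dataset
paleosynteny simulate --seed 1 --n-genes 500 --n-chromosomes 5 \
    --rate inversion 2.0 --rate deletion 1.0 --out-dir sim/

# full pipeline from a flat YAML config (flags override file values)
paleosynteny run --config config.yaml

# or step by step
paleosynteny homology  --hsps sim/hsps.tsv --lengths sim/lengths.tsv \
    --genes sim/genes.tsv --out step1.tsv
paleosynteny orthologs --pairs step1.tsv --genes sim/genes.tsv --out step2.tsv
paleosynteny blocks    --orthologs step2.tsv --genes sim/genes.tsv --out step3.tsv
paleosynteny cars      --orthologs step2.tsv --pairs step1.tsv \
    --genes sim/genes.tsv --out-dir karyotype/
paleosynteny export    --karyotype-dir karyotype/ --genes sim/genes.tsv --out workbook/
paleosynteny validate  --workbook workbook/
```

Example `config.yaml`:

```yaml
genes: sim/genes.tsv          # gene_id, species, chromosome, start, end, strand
hsps: sim/hsps.tsv            # BLAST outfmt-6 + nident column
lengths: sim/lengths.tsv      # gene_id, length (aa)
out_dir: out
cip_min: 50.0
calp_min: 50.0
direction: either             # or "both"
tandem_window: 5
min_anchors: 6
max_gap: 15                   # null = unbounded (chromosome-pair rule)
reference: median             # or a species name
multiplicities: {}            # e.g. "A,B": 2 after a WGD in B
```

`run` writes one tabular file per step, the karyotype tables, the
four-sheet submission workbook (TSV directory + XLSX mirror) and a
manifest with input checksums and per-stage record counts; identical
inputs and config give byte-identical step outputs.

## File formats

* **Gene tables** — TSV with header
  `gene_id species chromosome start end strand` (1-based inclusive
  coordinates), or GFF3 (`gene` features with `ID`; species from a
  `species` attribute or the `--species` argument). Gene ranks are dense
  0-based positions per chromosome after sorting by start.
* **HSP tables** — tab-separated BLAST output, one HSP per row, default
  layout `outfmt "6 std nident"`; self hits are dropped at read time.
* **Submission workbook** — four sheets (CONTACT as key/value rows,
  GENOME, PHYLOGENY mapping modern chromosomes to CARs, HOMOLOGY_GROUP
  with one row per protogene member). The sheet and column names are
  defined by this package (the public template's headers are not
  standardized); canonical on-disk dialect is one TSV per sheet, XLSX is
  a convenience mirror. `validate_workbook` reports unicity violations,
  dangling references and dataset-version conflicts; loading version
  v+1 of a dataset marks version v obsolete.

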