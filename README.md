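# operonkit

Operon prediction for assembled metagenomes and whole genomes, with no
experimental or functional information required.

Metagenomic assemblies yield scaftigs from millions of mostly uncultured
microbes, for which the usual operon-prediction inputs — expression data,
curated pathways, orthology — do not exist. `operonkit` predicts operons
from sequence-derived signals alone:

1. **Proximon clustering.** Adjacent co-directional genes on a scaftig are
   chained while their intergenic distance

   `IGD(G1, G2) = (start(G2) − end(G1)) + 1`

   stays strictly below a permissive threshold (default **< 601 bp**; with
   this formula abutting genes have IGD 2 and overlapping genes IGD ≤ 0).
   The resulting clusters of ≥ 2 proximal, co-directional genes are
   *proximons*: operon candidates with no transcription unit boundary
   (TUB) defined yet.

2. **Promoter-anchored TUB refinement.** Promoter calls over each gene's
   upstream/downstream intergenic flank (trimmed to ≤ 700 bp; flanks
   < 15 bp are tagged `short_ups`/`short_dss` and skipped) delimit
   transcription units inside each proximon: a unit opens at a gene with an
   upstream promoter and closes where a promoter sits in the intergenic
   span before the next gene — one promoter both ends a unit and starts the
   next. A second mode (`promoter_only`) applies the same walk to whole
   co-directional runs, ignoring intergenic distance entirely.

Promoter evidence is pluggable: the tabular output of an external
predictor such as NNPP (`nnpp_file`), a built-in −35/spacer/−10 position
weight matrix scorer (`pwm`, a self-contained surrogate useful for
testing), or planted ground truth from the bundled synthetic-genome
generator (`oracle`).

Predictions can be scored against any reference operon map (e.g. an export
from the DOOR database) two ways: pair-level sensitivity / specificity /
accuracy over adjacent co-directional gene pairs, and a six-way per-operon
configuration taxonomy (perfect match, subset, superset, bridge-1,
bridge-2, novel).

## Worked example

Generate a synthetic dataset with planted operons, predict, and evaluate:

```bash
operonkit simulate --out demo/sim --seed 42 --n-operons 8
operonkit run --gene-tool prodigal \
    --scaftigs demo/sim/scaftigs.fasta --gff demo/sim/genes.gff \
    --promoters demo/sim/promoters.tsv --promoter-backend oracle \
    --out demo/run
```

The run prints its per-stage counts:

```json
{
  "n_genes": 26,
  "n_nonoperonic_genes": 2,
  "n_operonic_genes": 24,
  "n_operons_igd_promoter": 8,
  "n_operons_promoter_only": 8,
  "n_proximon_genes": 24,
  "n_proximons": 8,
  "n_scaftigs": 3
}
```

26 predicted genes on 3 scaftigs collapse into 8 proximons; promoter
evidence confirms all 8 as operons (24 operonic genes), and the 2 planted
decoy genes end up in `nonoperonic_genes.tsv`. `demo/run/operons.tsv`
holds one row per operon and mode:

```text
operon_id   scaftig_id  strand  gene_ids              start  end   upstream_promoter_pos  downstream_promoter_pos  mode
op_scf1_1   scf1        +       scf1_1;scf1_2;scf1_3  1373   3483  1333                   .                        igd_promoter
```

Scoring against the planted truth as reference:

```bash
operonkit eval --predictions demo/run/operons.tsv --reference demo/ref.tsv \
    --gff demo/sim/genes.gff --gene-tool prodigal --out demo/eval
```

```json
{
  "accuracy": 1.0, "fn": 0, "fp": 0,
  "sensitivity": 1.0, "specificity": 1.0,
  "tn": 1, "tp": 16
}
```

All 16 truly co-operonic adjacent gene pairs are recovered and the decoy
pair is correctly left out. Real NNPP output is used the same way: run
NNPP on `demo/run/upstream.fasta`, convert to the four-column promoter TSV
(`scaftig_id  strand  position  score`) and pass it with
`--promoter-backend nnpp_file`.

The `ago` process (`operonkit run --process ago --reads ...`) orchestrates
an external assembler (`idba_ud`) and gene caller before continuing as
above; those tools are invoked, never reimplemented.

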