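# Methods

## Model

`operonkit` treats an operon as a run of two or more co-directional genes
transcribed as one unit, detectable from assembled sequence alone through
two signals: physical proximity and promoter placement.

**Intergenic distance.** For two genes adjacent in genomic order on one
scaftig, `IGD(G1, G2) = (start(G2) − end(G1)) + 1`. This convention is off
by one from the plain gap length: abutting genes score 2, a gap of *g*
bases scores *g* + 1, and overlapping genes score ≤ 0. The clustering
threshold is interpreted on this same scale. Genes are chained while
co-directional and `IGD < max_igd` (default 601, i.e. IGD ≤ 600); chains of
≥ 2 genes are *proximons*. Negative IGDs always pass — gene overlap is
strong co-transcription evidence — and nested genes are chained with their
computed IGD, with no special casing. There is no universal intergenic
distance cutoff across microbes, so the threshold is deliberately
permissive (it must engulf operonic genes across unrelated taxa in a
metagenome) and exposed as a parameter; the promoter step removes the
non-operonic genes it lets through.

**Flanks.** Each gene's upstream and downstream intergenic regions are
computed transcription-relative (upstream of a minus-strand gene lies at
higher genomic coordinates), bounded by the nearest neighbouring gene
regardless of the neighbour's strand, or the scaftig edge. Flanks longer
than 700 bp are trimmed to the 700 bp nearest the gene — promoters sit
near the transcription start, so the distal cut loses the least signal;
the gene-proximal choice is this package's reading where either cut would
satisfy a bare length cap. Flanks shorter than 15 bp are tagged
(`short_ups`/`short_dss`) and excluded from promoter scanning, since
promoter/terminator signatures need at least 15 bp. Abutting or
overlapping neighbours produce raw length 0 and the short tag. Minus-strand
flank sequences are reverse-complemented so they read 5'→3' toward the
gene.

**Boundary walk.** Walking a proximon's genes in transcription order, a
unit opens at a gene with an upstream promoter hit and closes after gene
*i* when a promoter sits in the intergenic span before gene *i* + 1 — that
single promoter simultaneously closes the running unit and opens the next.
Genes encountered while no unit is open, and would-be single-gene units,
are emitted to a non-operonic side table rather than dropped. The walk
treats promoter *presence* as a boundary and absence as continuation; the
alternative (requiring promoter absence for continuation) would make every
multi-gene unit self-contradictory whenever trimming asymmetry duplicates
a hit, and is not used. The final unit in a proximon may close at the
proximon or scaftig edge with no downstream promoter — scaftigs truncate
operons — recorded as an absent boundary, not an error. `promoter_only`
mode runs the identical walk over maximal co-directional runs with no IGD
constraint, so the two modes differ exactly in whether a large intergenic
gap can be bridged by the absence of a promoter.

**Promoter attribution.** A positional call is attributed to a flank by
strict interval containment with matching strand; a call in the shared
span between two co-directional genes counts as the downstream hit of the
earlier gene *and* the upstream hit of the later one. Within one flank the
best score wins; score ties go to the gene-proximal position, then the
smaller coordinate, so attribution is deterministic.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `max_igd` | 601 | bp (exclusive) | proximon chaining threshold on the IGD scale above |
| `flank_cap` | 700 | bp | flank trim length, gene-proximal side kept |
| `flank_min` | 15 | bp | below this a flank is short-tagged and never scanned |
| `min_scaftig_len` | 500 | bp | scaftigs with length ≤ this are removed, inclusive |
| `promoter_threshold` | 0.8 | score in [0,1] | minimum retained call score; external predictors' cutoffs vary, so this is exposed and recorded in the run manifest |

## Promoter backends

`nnpp_file` consumes a four-column TSV (`scaftig_id strand position
score`) converted from an external predictor's output. `pwm` is a
self-contained sigma70-style scorer: 4×6 base-probability matrices for the
−35 (TTGACA) and −10 (TATAAT) boxes with a 15–19 bp spacer, scored as
log2-odds against a uniform background and min-max normalized to [0, 1] so
the model consensus scores exactly 1. It exists so the whole pipeline can
run and be tested with no external tool; output provenance is marked so
PWM calls are never conflated with an external predictor's. `oracle`
replays the synthetic generator's planted promoter positions (score 1.0).
Scanning is gene-oriented: only the strand of the flank's own gene is
considered.

## Synthetic genomes

The generator emulates assembled metagenomic scaftigs at desk scale:
uniform-GC background sequence, transcription units of 2–4 genes (default
size distribution {2: 0.5, 3: 0.3, 4: 0.2}, echoing the predominance of
binary operons in microbial genomes), intra-unit gaps of 20–200 bp
(IGD 21–201, safely below threshold), inter-unit gaps of 700–1500 bp
(IGD ≥ 701, safely above, so planted units are unambiguous), strand
switches between units with probability 0.5, one decoy (non-operonic) gene
per inter-unit slot with probability 0.5 so that specificity is actually
exercised, and a TTGACA–17 bp–TATAAT promoter motif ending 40 bp upstream
of each unit's first gene (also the PWM backend's consensus, giving PWM
tests a positive control). Gap parameters are physical gaps; the planted
IGD is gap + 1.

Defaults (3 scaftigs of 30–50 kb, 12 operons) are sized so the worst-case
layout always fits; infeasible user-supplied combinations raise a
generation error naming the violated constraint. Identical spec + seed
yields byte-identical files.

What the generator does **not** emulate: assembly error and chimeric
scaftigs, operons split across scaftig boundaries, overlapping or nested
genes, promoter-like background motifs at realistic genomic density,
non-uniform GC and codon structure, and read-level artefacts (no reads are
simulated at all). Perfect recovery of planted truth therefore validates
the clustering and boundary logic — not expected accuracy on real
metagenomes, where promoter prediction error dominates.

## Evaluation conventions

The pair-level metrics count adjacent co-directional same-scaftig gene
pairs: positive-in-reference when both genes share a reference operon,
positive-in-prediction likewise. Sensitivity = tp/(tp+fn), specificity =
tn/(tn+fp), accuracy = (tp+tn)/all; an empty denominator yields an
undefined (None) metric, never 0. Published operon-prediction figures use
varying units; numbers from this package are comparable only under this
pair convention.

Configuration labels are decided in a fixed order so each predicted operon
S gets exactly one: *novel* when max over references R of |S∩R|/|S| < 0.5;
*perfect match* when S equals one R; *bridge-1* when S intersects ≥ 2
references; *superset* when S has genes beyond its single matched
reference; *subset* otherwise (S ⊊ R). Superset is keyed on the prediction
carrying extra genes rather than on strict containment so that partial
single-reference overlaps are still labeled. *Bridge-2* (one reference
split across ≥ 2 predictions) is a property of the reference side and is
reported as a separate table, not a per-prediction label. Overlap is
computed on gene IDs, not coordinates, so prediction and reference must
share a gene namespace.

## Numerical and degenerate-input choices

Ambiguous bases score neutrally (log-odds 0) in the PWM. PWM ties across
windows resolve to the smallest offset, then the shortest window. Empty
GFFs, empty promoter files and empty scaftig FASTAs produce empty results
with a warning; duplicate scaftig IDs are fatal because they corrupt the
coordinate space; structurally broken records are dropped and reported
individually. Synthesized gene IDs (`<scaftig>_<ordinal>`) are assigned
after sorting, so parsing is input-order-insensitive. All outputs are
written with fixed column orders, `\n` newlines and stable float
formatting; the run manifest records parameters and input checksums but no
timestamps, so identical runs are byte-identical.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
recovery is measured over 50–100 seeds of the 12-operon default spec
(≥ 600 planted operons), the evaluation study uses one 60-operon /
15-scaftig dataset, and the size-distribution check plants 1000 operons.
These sizes give stable proportions while keeping a full run in seconds.

## Known limitations

Terminators are not modelled; operons never merge across scaftigs; the
`ago` process is orchestration of external binaries only; the PWM backend
is a surrogate, not a trained promoter model; and the pair-level metrics
are undefined (not zero) on universes with no evaluable pairs.
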