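"""Transcription-unit boundary refinement: proximons -> operons.

An operon here is a cluster of two or more co-directional genes delimited
by promoter evidence: a promoter upstream of the first gene opens it, and
a promoter in the intergenic span after gene *i* (equivalently upstream of
gene *i + 1*) both closes the running unit and opens the next — a single
promoter plays the dual role of end-of-operon and start-of-the-next.

Two modes share the same boundary walk:

``igd_promoter``
    walks each proximon (so every internal intergenic distance is already
    below the clustering threshold);
``promoter_only``
    walks maximal co-directional gene runs with no intergenic-distance
    constraint at all.

Genes that never fall inside an emitted operon (no opening promoter,
trailing singletons after a split, singleton runs) are returned as
non-operonic rather than silently dropped.  The last unit in a run may
lack a downstream promoter — metagenomic scaftigs truncate operons — and
that absence is recorded, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import Gene, PromoterCall
from .promoters import PromoterScan
from .proximons import Proximon

log = logging.getLogger(__name__)

MODE_IGD_PROMOTER = "igd_promoter"
MODE_PROMOTER_ONLY = "promoter_only"


@dataclass(frozen=True)
class Operon:
    """A promoter-delimited transcription unit (genes in transcription order)."""

    operon_id: str
    scaftig_id: str
    strand: str
    genes: tuple[Gene, ...]
    start: int
    end: int
    upstream_promoter: PromoterCall
    downstream_promoter: PromoterCall | None
    mode: str

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"operon {self.operon_id}: needs >= 2 genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


class _OperonBuilder:
    def __init__(self, scan: PromoterScan, mode: str, id_prefix: str):
        self.scan = scan
        self.mode = mode
        self.id_prefix = id_prefix
        self.ordinals: dict[str, int] = {}
        self.operons: list[Operon] = []
        self.nonoperonic: list[Gene] = []

    def _require(self, gene: Gene) -> None:
        if not self.scan.covers(gene.gene_id):
            raise RuntimeError(f"promoter scan does not cover gene {gene.gene_id}")

    def _emit(self, genes: list[Gene], closing: PromoterCall | None) -> None:
        if not genes:
            return
        if len(genes) < 2:
            self.nonoperonic.extend(genes)
            return
        scaftig_id = genes[0].scaftig_id
        self.ordinals[scaftig_id] = self.ordinals.get(scaftig_id, 0) + 1
        self.operons.append(Operon(
            operon_id=f"{self.id_prefix}_{scaftig_id}_{self.ordinals[scaftig_id]}",
            scaftig_id=scaftig_id,
            strand=genes[0].strand,
            genes=tuple(genes),
            start=min(g.start for g in genes),
            end=max(g.end for g in genes),
            upstream_promoter=self.scan.best_upstream_call[genes[0].gene_id],
            downstream_promoter=closing,
            mode=self.mode,
        ))

    def walk(self, run: Sequence[Gene]) -> None:
        """Boundary walk over one run of co-directional genes in transcription order."""
        up = self.scan.per_gene_upstream_hit
        down = self.scan.per_gene_downstream_hit
        current: list[Gene] = []
        for g in run:
            self._require(g)
            if current:
                prev = current[-1]
                if down[prev.gene_id] or up[g.gene_id]:
                    closing = self.scan.best_downstream_call.get(prev.gene_id) \
                        or self.scan.best_upstream_call.get(g.gene_id)
                    self._emit(current, closing)
                    current = []
            if current:
                current.append(g)
            elif up[g.gene_id]:
                current = [g]
            else:
                self.nonoperonic.append(g)
        if current:
            last = current[-1]
            closing = self.scan.best_downstream_call.get(last.gene_id) \
                if down[last.gene_id] else None
            self._emit(current, closing)


def _transcription_order(genes: Sequence[Gene], strand: str) -> list[Gene]:
    ordered = list(genes)
    return ordered[::-1] if strand == "-" else ordered


def call_operons_igd_promoter(
    proximons: Sequence[Proximon],
    scan: PromoterScan,
    nonoperonic: list[Gene] | None = None,
    id_prefix: str = "op",
) -> list[Operon]:
    """Define transcription unit boundaries inside each proximon.

    A unit opens at a gene with an upstream promoter hit and closes after
    gene *i* when a promoter sits in the span before gene *i + 1* (or the
    proximon ends).  Runs without an opening promoter, and trailing
    would-be 1-gene units, are reported as non-operonic.
    """
    builder = _OperonBuilder(scan, MODE_IGD_PROMOTER, id_prefix)
    for p in proximons:
        builder.walk(_transcription_order(p.genes, p.strand))
    if nonoperonic is not None:
        nonoperonic.extend(builder.nonoperonic)
    log.info("igd_promoter mode: %d operons (%d genes) from %d proximons",
             len(builder.operons), sum(o.size for o in builder.operons), len(proximons))
    return builder.operons


def codirectional_runs(genes: Sequence[Gene]) -> list[list[Gene]]:
    """Maximal same-scaftig, same-strand runs of sorted genes (any length)."""
    runs: list[list[Gene]] = []
    for g in genes:
        if runs and runs[-1][-1].scaftig_id == g.scaftig_id and runs[-1][-1].strand == g.strand:
            runs[-1].append(g)
        else:
            runs.append([g])
    return runs


def call_operons_promoter_only(
    genes: Sequence[Gene],
    scan: PromoterScan,
    nonoperonic: list[Gene] | None = None,
    id_prefix: str = "op",
) -> list[Operon]:
    """Same boundary walk over maximal co-directional runs, ignoring IGD.

    *genes* must be sorted by (scaftig_id, start).
    """
    builder = _OperonBuilder(scan, MODE_PROMOTER_ONLY, id_prefix)
    for run in codirectional_runs(genes):
        builder.walk(_transcription_order(run, run[0].strand))
    if nonoperonic is not None:
        nonoperonic.extend(builder.nonoperonic)
    log.info("promoter_only mode: %d operons (%d genes)",
             len(builder.operons), sum(o.size for o in builder.operons))
    return builder.operons
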