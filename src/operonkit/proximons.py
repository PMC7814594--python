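"""Proximon calling: intergenic-distance clustering of co-directional genes.

The intergenic distance between two adjacent genes in genomic order is

    IGD(G1, G2) = (start(G2) - end(G1)) + 1

so abutting genes have IGD 2 and overlapping genes have IGD <= 0.  Runs of
consecutive co-directional genes on one scaftig whose successive IGDs stay
strictly below the threshold (default 601 bp, i.e. IGD <= 600) form
*proximons* — proximity/co-directionality clusters with no transcription
unit boundary defined yet.  Singleton runs are discarded: the smallest
proximon is binary.

There is no universal intergenic-distance threshold across microbes; the
601 bp default is deliberately permissive for metagenomes and exposed as a
parameter.  Negative IGDs (overlapping genes) always pass — overlap is
strong co-transcription evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .io_formats import Gene

log = logging.getLogger(__name__)

DEFAULT_MAX_IGD_EXCLUSIVE = 601


@dataclass(frozen=True)
class Proximon:
    """An ordered cluster of >= 2 co-directional, proximal genes."""

    proximon_id: str
    scaftig_id: str
    strand: str
    genes: tuple[Gene, ...]
    igds: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"proximon {self.proximon_id}: needs >= 2 genes")
        if len(self.igds) != len(self.genes) - 1:
            raise ValueError(f"proximon {self.proximon_id}: {len(self.genes)} genes but {len(self.igds)} IGDs")

    @property
    def size(self) -> int:
        return len(self.genes)


def compute_igd(g1: Gene, g2: Gene) -> int:
    """Intergenic distance between genomically ordered genes on one scaftig."""
    if g1.scaftig_id != g2.scaftig_id:
        raise ValueError(f"genes {g1.gene_id} and {g2.gene_id} are on different scaftigs")
    if g1.start > g2.start:
        raise ValueError(f"gene {g1.gene_id} does not precede {g2.gene_id} in genomic order")
    return (g2.start - g1.end) + 1


def _check_sorted(genes: Sequence[Gene]) -> None:
    for a, b in zip(genes, genes[1:]):
        if (a.scaftig_id, a.start) > (b.scaftig_id, b.start):
            raise ValueError("genes must be sorted by (scaftig_id, start)")


def call_proximons(
    genes: Sequence[Gene],
    max_igd_exclusive: int = DEFAULT_MAX_IGD_EXCLUSIVE,
) -> list[Proximon]:
    """Chain sorted genes into proximons.

    Consecutive genes on one scaftig stay in the same chain while the
    strand is unchanged and ``compute_igd < max_igd_exclusive``.  Chains of
    >= 2 genes become proximons with deterministic IDs
    ``prox_<scaftig>_<ordinal>``; singletons are discarded.
    """
    _check_sorted(genes)
    proximons: list[Proximon] = []
    ordinals: dict[str, int] = {}

    def flush(chain: list[Gene]) -> None:
        if len(chain) < 2:
            return
        scaftig_id = chain[0].scaftig_id
        ordinals[scaftig_id] = ordinals.get(scaftig_id, 0) + 1
        igds = tuple(compute_igd(a, b) for a, b in zip(chain, chain[1:]))
        proximons.append(Proximon(
            f"prox_{scaftig_id}_{ordinals[scaftig_id]}",
            scaftig_id, chain[0].strand, tuple(chain), igds,
        ))

    chain: list[Gene] = []
    for g in genes:
        if chain and (
            g.scaftig_id != chain[-1].scaftig_id
            or g.strand != chain[-1].strand
            or compute_igd(chain[-1], g) >= max_igd_exclusive
        ):
            flush(chain)
            chain = []
        chain.append(g)
    flush(chain)

    log.info("called %d proximons covering %d genes", len(proximons), sum(p.size for p in proximons))
    return proximons
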