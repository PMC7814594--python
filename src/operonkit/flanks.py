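"""Upstream/downstream intergenic flank regions of predicted genes.

For every gene the two intergenic slices adjacent to it are computed:
*upstream* is 5' of the gene relative to its transcription direction (so
for a minus-strand gene it lies at higher genomic coordinates) and
*downstream* is 3'.  A flank is bounded by the nearest neighbouring gene
on the scaftig (regardless of that neighbour's strand — the flank is
intergenic space, not strand-partitioned) or by the scaftig edge.

Flanks longer than 700 bp are trimmed to the 700 bp nearest the gene;
promoter signatures cluster near the transcription start, so the distal
cut loses the least signal.  Flanks shorter than 15 bp are tagged
``short_ups``/``short_dss`` and excluded from promoter scanning, as
promoter/terminator signatures only appear on/after 15 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Seq import Seq

from .io_formats import Gene, ParseIssue, ScaftigIndex

log = logging.getLogger(__name__)

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
DEFAULT_FLANK_CAP = 700
DEFAULT_FLANK_MIN = 15


@dataclass
class FlankRegion:
    """One intergenic slice adjacent to a gene (1-based inclusive coords).

    An empty flank (abutting or overlapping neighbour) is represented with
    ``end == start - 1`` anchored at the gene boundary, so its length is 0.
    ``sequence``, when filled, reads 5'->3' relative to the gene's strand.
    """

    gene_id: str
    side: str  # upstream | downstream, transcription-relative
    scaftig_id: str
    gene_strand: str
    start: int
    end: int
    raw_length: int
    status: str = "ok"  # ok | trimmed | short_ups | short_dss
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_left_of_gene(self) -> bool:
        """True when the region lies at lower genomic coordinates than its gene."""
        return (self.side == UPSTREAM) == (self.gene_strand == "+")

    @property
    def scannable(self) -> bool:
        return self.status in ("ok", "trimmed")


def extract_flank_coordinates(
    genes: Sequence[Gene],
    index: ScaftigIndex,
    issues: list[ParseIssue] | None = None,
) -> list[FlankRegion]:
    """Compute raw upstream and downstream flanks for every gene.

    *genes* must be sorted by (scaftig_id, start).  Boundaries come from
    the immediately preceding/following gene in genomic order, or the
    scaftig edge.  Genes extending beyond their scaftig, or on scaftigs
    missing from *index*, have their flanks skipped with a reported issue.
    """
    sink = issues if issues is not None else []
    by_scaftig: dict[str, list[Gene]] = {}
    for g in genes:
        by_scaftig.setdefault(g.scaftig_id, []).append(g)

    regions: list[FlankRegion] = []
    for scaftig_id, group in by_scaftig.items():
        if scaftig_id not in index:
            for g in group:
                sink.append(ParseIssue(scaftig_id, 0, f"gene {g.gene_id}: scaftig not in index; flanks skipped"))
            continue
        scaftig_len = index.length(scaftig_id)
        for i, g in enumerate(group):
            if g.end > scaftig_len:
                sink.append(ParseIssue(
                    scaftig_id, 0,
                    f"gene {g.gene_id} ends at {g.end} beyond scaftig length {scaftig_len}; flanks skipped"))
                continue
            left_bound = group[i - 1].end if i > 0 else 0
            right_bound = group[i + 1].start if i + 1 < len(group) else scaftig_len + 1

            la, lb = left_bound + 1, g.start - 1
            if lb < la:  # abutting or overlapping left neighbour
                la, lb = g.start, g.start - 1
            left_raw = lb - la + 1

            ra, rb = g.end + 1, min(right_bound - 1, scaftig_len)
            if rb < ra:
                ra, rb = g.end + 1, g.end
            right_raw = rb - ra + 1

            if g.strand == "+":
                up = FlankRegion(g.gene_id, UPSTREAM, scaftig_id, "+", la, lb, left_raw)
                down = FlankRegion(g.gene_id, DOWNSTREAM, scaftig_id, "+", ra, rb, right_raw)
            else:
                up = FlankRegion(g.gene_id, UPSTREAM, scaftig_id, "-", ra, rb, right_raw)
                down = FlankRegion(g.gene_id, DOWNSTREAM, scaftig_id, "-", la, lb, left_raw)
            regions.extend((up, down))

    for issue in sink:
        log.warning("%s", issue)
    return regions


def trim_flanks(
    regions: Sequence[FlankRegion],
    cap: int = DEFAULT_FLANK_CAP,
    min_length: int = DEFAULT_FLANK_MIN,
) -> list[FlankRegion]:
    """Apply the length cap and short-flank tagging.

    Regions longer than *cap* keep the *cap* bases nearest the gene and get
    status ``trimmed``; regions with raw length < *min_length* get the
    side-matching short tag (``short_ups``/``short_dss``) and are excluded
    from later promoter scanning; everything in between passes with ``ok``.
    """
    out: list[FlankRegion] = []
    for r in regions:
        r2 = replace(r)
        if r.raw_length < min_length:
            r2.status = "short_ups" if r.side == UPSTREAM else "short_dss"
        elif r.raw_length > cap:
            if r.is_left_of_gene:
                r2.start = r.end - cap + 1
            else:
                r2.end = r.start + cap - 1
            r2.status = "trimmed"
        else:
            r2.status = "ok"
        out.append(r2)
    return out


def extract_flank_sequences(
    regions: Sequence[FlankRegion],
    index: ScaftigIndex,
) -> list[FlankRegion]:
    """Fill flank sequences from the scaftig index.

    Scannable regions get their genomic slice, reverse-complemented for
    minus-strand genes so the sequence reads 5'->3' toward the gene;
    short-tagged regions get an empty sequence.
    """
    if not index.has_sequences:
        raise ValueError("scaftig index was built without sequences; re-index with load_sequences=True")
    out: list[FlankRegion] = []
    for r in regions:
        r2 = replace(r)
        if not r.scannable:
            r2.sequence = ""
        else:
            scaftig_len = index.length(r.scaftig_id)
            if r.start < 1 or r.end > scaftig_len:
                raise RuntimeError(
                    f"flank {r.gene_id}/{r.side} coordinates {r.start}..{r.end} "
                    f"exceed scaftig {r.scaftig_id} length {scaftig_len}")
            seq = index.sequence(r.scaftig_id)[r.start - 1:r.end]  # 1-based inclusive -> half-open
            if r.gene_strand == "-":
                seq = str(Seq(seq).reverse_complement())
            r2.sequence = seq
        out.append(r2)
    return out
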