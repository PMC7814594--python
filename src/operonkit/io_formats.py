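"""Readers and writers for every external format the pipeline touches.

Gene predictions arrive as GFF emitted by Prodigal or MetaGeneMark (two
attribute dialects), assembled scaftigs as multi-record FASTA, promoter
calls as a small positional TSV, and reference operon maps as a two-column
TSV.  All genomic coordinates are 1-based and inclusive at both ends,
matching the GFF convention used by both gene callers; conversion to
Python half-open slices happens only at the point where a sequence is
actually cut.

Malformed *records* (a CDS line with end < start, a promoter row with a
score outside [0, 1], ...) are collected as :class:`ParseIssue` objects and
dropped; malformed *files* (unreadable path, duplicate scaftig IDs) are
fatal.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STRANDS = ("+", "-")
GENE_TOOLS = ("prodigal", "metagenemark")
PROMOTER_SOURCES = ("nnpp_file", "pwm", "oracle")

_PRODIGAL_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_MGM_ID = re.compile(r'gene_id[ =]+"?([^";]+)"?')


@dataclass
class ParseIssue:
    """One dropped input record and why it was dropped."""

    path: str
    line_no: int
    message: str
    line: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}:{self.line_no}: {self.message}"


@dataclass(frozen=True)
class Gene:
    """One predicted coding feature on a scaftig (1-based inclusive coords)."""

    gene_id: str
    scaftig_id: str
    start: int
    end: int
    strand: str
    source_tool: str = "prodigal"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PromoterCall:
    """A predicted promoter/TSS anchor at one scaftig position."""

    scaftig_id: str
    strand: str
    position: int
    score: float
    source: str = "nnpp_file"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"promoter call: bad strand {self.strand!r}")
        if self.position < 1:
            raise ValueError(f"promoter call: position must be >= 1, got {self.position}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"promoter call: score {self.score} outside [0, 1]")
        if self.source not in PROMOTER_SOURCES:
            raise ValueError(f"promoter call: unknown source {self.source!r}")


@dataclass(frozen=True)
class ScaftigRecord:
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("scaftig length does not match its sequence")


class ScaftigIndex:
    """Mapping of scaftig ID to length (and, optionally, sequence)."""

    def __init__(self, entries: Mapping[str, ScaftigRecord]):
        self.entries: dict[str, ScaftigRecord] = dict(entries)

    def __contains__(self, scaftig_id: str) -> bool:
        return scaftig_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return list(self.entries)

    def length(self, scaftig_id: str) -> int:
        return self.entries[scaftig_id].length

    def sequence(self, scaftig_id: str) -> str:
        seq = self.entries[scaftig_id].sequence
        if seq is None:
            raise ValueError(f"scaftig {scaftig_id} was indexed without its sequence")
        return seq

    @property
    def has_sequences(self) -> bool:
        return all(rec.sequence is not None for rec in self.entries.values())


class ReferenceOperonSet:
    """A user-supplied reference operon map (e.g. exported from DOOR).

    Each reference operon is an ordered list of >= 2 gene IDs; a gene may
    belong to at most one reference operon.
    """

    def __init__(self, operons: Mapping[str, Sequence[str]]):
        self.operons: dict[str, tuple[str, ...]] = {}
        self.gene_to_operon: dict[str, str] = {}
        for operon_id, gene_ids in operons.items():
            genes = tuple(gene_ids)
            if len(genes) < 2:
                raise ValueError(f"reference operon {operon_id} has fewer than 2 genes")
            for g in genes:
                if g in self.gene_to_operon:
                    raise ValueError(
                        f"gene {g} appears in reference operons "
                        f"{self.gene_to_operon[g]} and {operon_id}"
                    )
                self.gene_to_operon[g] = operon_id
            self.operons[operon_id] = genes

    def __len__(self) -> int:
        return len(self.operons)


# ---------------------------------------------------------------------------
# gene predictions (GFF)
# ---------------------------------------------------------------------------

def _extract_gene_id(attributes: str, source_tool: str) -> str | None:
    pattern = _PRODIGAL_ID if source_tool == "prodigal" else _MGM_ID
    m = pattern.search(attributes)
    return m.group(1).strip() if m else None


def parse_gene_predictions(
    gff_path: str | Path,
    source_tool: str,
    issues: list[ParseIssue] | None = None,
) -> list[Gene]:
    """Parse CDS features from a Prodigal- or MetaGeneMark-style GFF.

    Returns genes sorted by (scaftig_id, start).  Non-CDS features are
    skipped silently; structurally broken CDS lines are dropped and
    reported through *issues* (and the module logger).  When the dialect's
    ID attribute is absent, a deterministic ``<scaftig>_<ordinal>`` ID is
    synthesized from the gene's rank (by start) on its scaftig, so the
    result is independent of input line order.
    """
    if source_tool not in GENE_TOOLS:
        raise ValueError(f"unknown gene prediction dialect {source_tool!r}; expected one of {GENE_TOOLS}")
    path = Path(gff_path)
    sink = issues if issues is not None else []

    raw: list[tuple[str, int, int, str, str | None, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                sink.append(ParseIssue(str(path), line_no, f"expected >= 8 tab-separated columns, got {len(cols)}", line))
                continue
            if cols[2] != "CDS":
                log.debug("%s:%d: skipping non-CDS feature %r", path, line_no, cols[2])
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                sink.append(ParseIssue(str(path), line_no, f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", line))
                continue
            strand = cols[6]
            if strand not in STRANDS:
                sink.append(ParseIssue(str(path), line_no, f"missing or invalid strand {strand!r}", line))
                continue
            if start < 1 or end < start:
                sink.append(ParseIssue(str(path), line_no, f"invalid coordinates {start}..{end}", line))
                continue
            attributes = cols[8] if len(cols) > 8 else ""
            raw.append((cols[0], start, end, strand, _extract_gene_id(attributes, source_tool), line_no))

    # sort first so synthesized ordinals do not depend on input line order
    raw.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    genes: list[Gene] = []
    seen_ids: set[str] = set()
    per_scaftig: dict[str, int] = {}
    for scaftig_id, start, end, strand, gene_id, line_no in raw:
        ordinal = per_scaftig.get(scaftig_id, 0) + 1
        per_scaftig[scaftig_id] = ordinal
        if gene_id is None:
            gene_id = f"{scaftig_id}_{ordinal}"
        if gene_id in seen_ids:
            sink.append(ParseIssue(str(path), line_no, f"duplicate gene ID {gene_id!r}; record dropped"))
            continue
        seen_ids.add(gene_id)
        genes.append(Gene(gene_id, scaftig_id, start, end, strand, source_tool))

    for issue in sink:
        log.warning("%s", issue)
    return genes


# ---------------------------------------------------------------------------
# scaftigs (FASTA)
# ---------------------------------------------------------------------------

def index_scaftigs(fasta_path: str | Path, load_sequences: bool = True) -> ScaftigIndex:
    """Index a scaftig FASTA by record ID.

    Duplicate IDs are fatal: they would make the gene coordinate space
    ambiguous.  An empty file yields an empty index with a warning.
    """
    entries: dict[str, ScaftigRecord] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in entries:
            raise ValueError(f"duplicate scaftig ID {record.id!r} in {fasta_path}")
        seq = str(record.seq).upper()
        entries[record.id] = ScaftigRecord(len(seq), seq if load_sequences else None)
    if not entries:
        log.warning("no scaftig records found in %s", fasta_path)
    return ScaftigIndex(entries)


def filter_scaftigs(
    index: ScaftigIndex,
    genes: Sequence[Gene],
    min_length: int = 500,
) -> tuple[ScaftigIndex, list[Gene]]:
    """Drop scaftigs with length <= *min_length* and every gene on them.

    The boundary is inclusive: a scaftig of exactly *min_length* bp is
    removed.  Default 500 bp.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = {sid: rec for sid, rec in index.entries.items() if rec.length > min_length}
    kept_genes = [g for g in genes if g.scaftig_id in kept]
    log.info(
        "scaftig filter (<= %d bp): removed %d/%d scaftigs and %d/%d genes",
        min_length, len(index) - len(kept), len(index), len(genes) - len(kept_genes), len(genes),
    )
    return ScaftigIndex(kept), kept_genes


# ---------------------------------------------------------------------------
# promoter calls (NNPP-style TSV)
# ---------------------------------------------------------------------------

def parse_promoter_file(
    path: str | Path,
    issues: list[ParseIssue] | None = None,
    source: str = "nnpp_file",
) -> list[PromoterCall]:
    """Parse a positional promoter TSV: scaftig_id, strand, position, score.

    ``#``-prefixed comment lines and a literal header row are allowed.
    Rows with scores outside [0, 1] or otherwise malformed are dropped and
    reported.
    """
    sink = issues if issues is not None else []
    calls: list[PromoterCall] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "scaftig_id":  # header row
                continue
            if len(cols) < 4:
                sink.append(ParseIssue(str(path), line_no, f"expected 4 columns, got {len(cols)}", line))
                continue
            try:
                call = PromoterCall(cols[0], cols[1], int(cols[2]), float(cols[3]), source)
            except ValueError as exc:
                sink.append(ParseIssue(str(path), line_no, str(exc), line))
                continue
            calls.append(call)
    if not calls:
        log.warning("no promoter calls parsed from %s", path)
    if issues is None:
        for issue in sink:
            log.warning("%s", issue)
    return calls


def write_promoter_file(calls: Iterable[PromoterCall], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["scaftig_id", "strand", "position", "score"])
        for c in calls:
            writer.writerow([c.scaftig_id, c.strand, c.position, f"{c.score:.6g}"])
    return path


# ---------------------------------------------------------------------------
# reference operons (TSV)
# ---------------------------------------------------------------------------

def parse_reference_operons(path: str | Path) -> ReferenceOperonSet:
    """Parse a reference operon TSV: operon_id <tab> gene1;gene2;..."""
    operons: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "operon_id":
                continue
            if len(cols) < 2:
                raise ValueError(f"reference operon row needs 2 columns: {line!r}")
            operons[cols[0]] = [g for g in cols[1].split(";") if g]
    return ReferenceOperonSet(operons)


def write_reference_operons(reference: ReferenceOperonSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["operon_id", "gene_ids"])
        for operon_id, gene_ids in reference.operons.items():
            writer.writerow([operon_id, ";".join(gene_ids)])
    return path


# ---------------------------------------------------------------------------
# result tables (proximons / operons / non-operonic genes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProximonRow:
    proximon_id: str
    scaftig_id: str
    strand: str
    gene_ids: tuple[str, ...]
    igds: tuple[int, ...]


@dataclass(frozen=True)
class OperonRow:
    operon_id: str
    scaftig_id: str
    strand: str
    gene_ids: tuple[str, ...]
    start: int
    end: int
    upstream_promoter_pos: int | None
    downstream_promoter_pos: int | None
    mode: str


def as_proximon_row(p) -> ProximonRow:
    if isinstance(p, ProximonRow):
        return p
    return ProximonRow(
        p.proximon_id, p.scaftig_id, p.strand,
        tuple(g.gene_id for g in p.genes), tuple(p.igds),
    )


def as_operon_row(o) -> OperonRow:
    if isinstance(o, OperonRow):
        return o
    return OperonRow(
        o.operon_id, o.scaftig_id, o.strand,
        tuple(g.gene_id for g in o.genes), o.start, o.end,
        o.upstream_promoter.position if o.upstream_promoter else None,
        o.downstream_promoter.position if o.downstream_promoter else None,
        o.mode,
    )


def _fmt_opt(value: int | None) -> str:
    return "." if value is None else str(value)


def _parse_opt(text: str) -> int | None:
    return None if text == "." else int(text)


def write_tables(
    proximons: Sequence,
    operons: Sequence,
    flank_regions: Sequence,
    out_dir: str | Path,
    index: ScaftigIndex | None = None,
    nonoperonic: Sequence[Gene] | None = None,
) -> dict[str, Path]:
    """Write the pipeline's tab-delimited and FASTA outputs into *out_dir*.

    ``operons.fasta`` (the genomic envelope of each operon, oriented to its
    strand) is only written when *index* carries sequences.  Writing then
    re-reading any table round-trips losslessly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    prox_path = out / "proximons.tsv"
    with open(prox_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["proximon_id", "scaftig_id", "strand", "gene_ids", "igds"])
        for p in map(as_proximon_row, proximons):
            writer.writerow([p.proximon_id, p.scaftig_id, p.strand,
                             ";".join(p.gene_ids), ";".join(map(str, p.igds))])
    paths["proximons"] = prox_path

    op_path = out / "operons.tsv"
    with open(op_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["operon_id", "scaftig_id", "strand", "gene_ids", "start", "end",
                         "upstream_promoter_pos", "downstream_promoter_pos", "mode"])
        for o in map(as_operon_row, operons):
            writer.writerow([o.operon_id, o.scaftig_id, o.strand, ";".join(o.gene_ids),
                             o.start, o.end, _fmt_opt(o.upstream_promoter_pos),
                             _fmt_opt(o.downstream_promoter_pos), o.mode])
    paths["operons"] = op_path

    if nonoperonic is not None:
        nop_path = out / "nonoperonic_genes.tsv"
        with open(nop_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_id", "scaftig_id", "strand"])
            for g in nonoperonic:
                writer.writerow([g.gene_id, g.scaftig_id, g.strand])
        paths["nonoperonic_genes"] = nop_path

    for side in ("upstream", "downstream"):
        fasta_path = out / f"{side}.fasta"
        with open(fasta_path, "w") as fh:
            for r in flank_regions:
                if r.side != side or r.sequence is None:
                    continue
                fh.write(f">{r.gene_id}|{r.side}|{r.scaftig_id}:{r.start}-{r.end}({r.gene_strand})|{r.status}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i:i + 70] + "\n")
        paths[side] = fasta_path

    if index is not None and index.has_sequences:
        ofa_path = out / "operons.fasta"
        with open(ofa_path, "w") as fh:
            for o in map(as_operon_row, operons):
                seq = index.sequence(o.scaftig_id)[o.start - 1:o.end]
                if o.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                fh.write(f">{o.operon_id}|{o.scaftig_id}:{o.start}-{o.end}({o.strand})|{o.mode}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        paths["operons_fasta"] = ofa_path

    return paths


def read_proximon_table(path: str | Path) -> list[ProximonRow]:
    rows: list[ProximonRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[0] != "proximon_id":
            raise ValueError(f"{path} is not a proximon table")
        for cols in reader:
            gene_ids = tuple(g for g in cols[3].split(";") if g)
            igds = tuple(int(x) for x in cols[4].split(";") if x)
            rows.append(ProximonRow(cols[0], cols[1], cols[2], gene_ids, igds))
    return rows


def read_operon_table(path: str | Path) -> list[OperonRow]:
    rows: list[OperonRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[0] != "operon_id":
            raise ValueError(f"{path} is not an operon table")
        for cols in reader:
            rows.append(OperonRow(
                cols[0], cols[1], cols[2], tuple(g for g in cols[3].split(";") if g),
                int(cols[4]), int(cols[5]), _parse_opt(cols[6]), _parse_opt(cols[7]), cols[8],
            ))
    return rows
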