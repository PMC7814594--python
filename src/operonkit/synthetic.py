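"""Synthetic prokaryotic scaftigs with planted operons and promoters.

The generator lays transcription units left-to-right along each scaftig:
every unit is a run of co-directional genes with small intra-unit gaps
(well below the proximon clustering threshold) and a sigma70-style
promoter motif (TTGACA - spacer - TATAAT) planted a fixed offset upstream
of the transcriptionally first gene.  Units — and optional single decoy
genes, which exercise specificity — are separated by gaps above the
clustering threshold so that ground truth is unambiguous.  Alongside the
FASTA and GFF it emits a truth table of planted operons and an oracle
promoter TSV (the planted promoter positions with score 1.0).

Same spec + seed always produces byte-identical files.  Gap parameters are
physical gaps; the recorded intergenic distance of a planted gap *g* is
*g + 1* (adjacent-gene IGD counts both flanking bases' offset, so an
abutting pair already has IGD 2).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import PromoterCall, write_promoter_file

log = logging.getLogger(__name__)


class GenerationError(ValueError):
    """Raised when the requested layout cannot fit the scaftig length range."""


@dataclass
class SyntheticSpec:
    """Layout parameters for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_scaftigs: int = 3
    scaftig_length_range: tuple[int, int] = (30_000, 50_000)
    n_operons: int = 12
    operon_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.2})
    intra_operon_igd_range: tuple[int, int] = (20, 200)   # physical gap; IGD = gap + 1
    inter_unit_gap_range: tuple[int, int] = (700, 1500)   # physical gap, above threshold
    strand_switch_probability: float = 0.5
    decoy_probability: float = 0.5                        # one decoy gene per inter-unit slot
    gene_length_range: tuple[int, int] = (300, 900)
    promoter_minus35: str = "TTGACA"
    promoter_minus10: str = "TATAAT"
    promoter_spacer: int = 17
    promoter_offset: int = 40                             # bp upstream of the first gene
    background_gc: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.operon_size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("operon size probabilities must sum to 1")
        if any(size < 2 for size in self.operon_size_distribution):
            raise ValueError("operon sizes must be >= 2")
        for name in ("scaftig_length_range", "intra_operon_igd_range",
                     "inter_unit_gap_range", "gene_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered: {(lo, hi)}")
        if self.inter_unit_gap_range[0] <= self.promoter_offset + self.motif_length:
            raise ValueError("inter-unit gaps must leave room for the planted promoter motif")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0, 1)")

    @property
    def motif_length(self) -> int:
        return len(self.promoter_minus35) + self.promoter_spacer + len(self.promoter_minus10)


@dataclass(frozen=True)
class TruthOperon:
    operon_id: str
    scaftig_id: str
    strand: str
    gene_ids: tuple[str, ...]  # transcription order
    promoter_position: int


@dataclass
class TruthTable:
    operons: list[TruthOperon]
    nonoperonic_gene_ids: list[str]


@dataclass
class SyntheticDataset:
    fasta_path: Path
    gff_path: Path
    truth_path: Path
    promoter_path: Path
    truth: TruthTable


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class _PlacedGene:
    start: int
    end: int
    strand: str
    gene_id: str = ""


def _layout_scaftig(spec: SyntheticSpec, rng: np.random.Generator, sizes: list[int]):
    """Place units and decoys along one scaftig; returns genes, unit index lists,
    promoter anchor positions, decoy indices, and total content length."""

    def gap(rng):
        return int(rng.integers(spec.inter_unit_gap_range[0], spec.inter_unit_gap_range[1] + 1))

    genes: list[_PlacedGene] = []
    units: list[list[int]] = []
    promoters: list[int] = []
    decoys: list[int] = []
    cursor = 0
    strand = "+" if rng.random() < 0.5 else "-"
    for size in sizes:
        if units and rng.random() < spec.strand_switch_probability:
            strand = "-" if strand == "+" else "+"
        cursor += gap(rng)
        members: list[int] = []
        for j in range(size):
            if j > 0:
                cursor += int(rng.integers(spec.intra_operon_igd_range[0],
                                           spec.intra_operon_igd_range[1] + 1))
            length = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
            genes.append(_PlacedGene(cursor + 1, cursor + length, strand))
            members.append(len(genes) - 1)
            cursor = genes[-1].end
        units.append(members)
        if strand == "+":
            promoters.append(genes[members[0]].start - spec.promoter_offset)
        else:
            promoters.append(genes[members[-1]].end + spec.promoter_offset)
        if rng.random() < spec.decoy_probability:
            cursor += gap(rng)
            length = int(rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1))
            decoy_strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_PlacedGene(cursor + 1, cursor + length, decoy_strand))
            decoys.append(len(genes) - 1)
            cursor = genes[-1].end
    cursor += gap(rng)  # trailing margin (also room for a minus-strand promoter)
    return genes, units, promoters, decoys, cursor


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(alphabet, size=length, p=p)


def generate(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticDataset:
    """Emit FASTA + GFF (prodigal dialect) + truth TSV + oracle promoter TSV.

    Raises :class:`GenerationError` when the planted layout cannot fit the
    requested scaftig length range.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    sizes = list(spec.operon_size_distribution)
    probs = [spec.operon_size_distribution[s] for s in sizes]
    drawn = rng.choice(sizes, size=spec.n_operons, p=probs)
    per_scaftig_sizes: list[list[int]] = [[] for _ in range(spec.n_scaftigs)]
    for i, size in enumerate(drawn):
        per_scaftig_sizes[i % spec.n_scaftigs].append(int(size))

    truth = TruthTable([], [])
    oracle_calls: list[PromoterCall] = []
    fasta_records: list[tuple[str, str]] = []
    gff_lines: list[str] = ["##gff-version 3"]
    unit_counter = 0

    for s in range(spec.n_scaftigs):
        scaftig_id = f"scf{s + 1}"
        genes, units, promoter_pos, decoys, content = _layout_scaftig(spec, rng, per_scaftig_sizes[s])
        lo, hi = spec.scaftig_length_range
        if content > hi:
            raise GenerationError(
                f"{scaftig_id}: planted layout needs {content} bp but "
                f"scaftig_length_range allows at most {hi} bp")
        scaftig_len = int(rng.integers(max(content, lo), hi + 1))

        seq = _background(rng, scaftig_len, spec.background_gc)
        spacer = "".join(rng.choice(list("ACGT"), size=spec.promoter_spacer))
        motif = spec.promoter_minus35 + spacer + spec.promoter_minus10
        for members, pos in zip(units, promoter_pos):
            strand = genes[members[0]].strand
            if strand == "+":
                a, b = pos - len(motif) + 1, pos  # motif ends at the anchor
                planted = motif
            else:
                a, b = pos, pos + len(motif) - 1
                planted = _revcomp(motif)
            seq[a - 1:b] = np.frombuffer(planted.encode(), dtype="S1")

        for k, g in enumerate(genes):
            g.gene_id = f"{scaftig_id}_{k + 1}"
            gff_lines.append("\t".join([
                scaftig_id, "operonkit_synth", "CDS", str(g.start), str(g.end),
                ".", g.strand, "0", f"ID={g.gene_id};",
            ]))
        for members, pos in zip(units, promoter_pos):
            unit_counter += 1
            strand = genes[members[0]].strand
            ordered = members if strand == "+" else members[::-1]
            truth.operons.append(TruthOperon(
                f"tu{unit_counter}", scaftig_id, strand,
                tuple(genes[i].gene_id for i in ordered), pos))
            oracle_calls.append(PromoterCall(scaftig_id, strand, pos, 1.0, "oracle"))
        truth.nonoperonic_gene_ids.extend(genes[i].gene_id for i in decoys)
        fasta_records.append((scaftig_id, seq.tobytes().decode("ascii")))

    fasta_path = out / "scaftigs.fasta"
    with open(fasta_path, "w") as fh:
        for scaftig_id, seq in fasta_records:
            fh.write(f">{scaftig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    gff_path = out / "genes.gff"
    gff_path.write_text("\n".join(gff_lines) + "\n")

    truth_path = write_truth(truth, out / "truth.tsv")
    promoter_path = write_promoter_file(oracle_calls, out / "promoters.tsv")

    log.info("generated %d scaftigs, %d operons, %d decoy genes",
             spec.n_scaftigs, len(truth.operons), len(truth.nonoperonic_gene_ids))
    return SyntheticDataset(fasta_path, gff_path, truth_path, promoter_path, truth)


def write_truth(truth: TruthTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_type", "operon_id", "scaftig_id", "strand",
                         "gene_ids", "promoter_position"])
        for op in truth.operons:
            writer.writerow(["operon", op.operon_id, op.scaftig_id, op.strand,
                             ";".join(op.gene_ids), op.promoter_position])
        for gid in truth.nonoperonic_gene_ids:
            writer.writerow(["nonoperonic_gene", ".", ".", ".", gid, "."])
    return path


def load_truth(path: str | Path) -> TruthTable:
    truth = TruthTable([], [])
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)  # header
        for cols in reader:
            if cols[0] == "operon":
                truth.operons.append(TruthOperon(
                    cols[1], cols[2], cols[3],
                    tuple(g for g in cols[4].split(";") if g), int(cols[5])))
            else:
                truth.nonoperonic_gene_ids.append(cols[4])
    return truth


def truth_reference(truth: TruthTable):
    """The planted operons as a ReferenceOperonSet for evaluation."""
    from .io_formats import ReferenceOperonSet

    return ReferenceOperonSet({op.operon_id: list(op.gene_ids) for op in truth.operons})
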