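"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import itertools
from pathlib import Path

import pytest

from operonkit.io_formats import Gene, PromoterCall, ScaftigIndex, ScaftigRecord
from operonkit.promoters import PromoterScan


def make_gene(gene_id, start, end, strand="+", scaftig="scf1"):
    return Gene(gene_id, scaftig, start, end, strand)


@pytest.fixture
def seq_index():
    """A 2000 bp scaftig with a deterministic repeating sequence."""
    seq = ("ACGT" * 500)
    return ScaftigIndex({"scf1": ScaftigRecord(2000, seq)})


def write_fasta(path: Path, records: dict[str, str], width: int = 70) -> Path:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def write_gff(path: Path, rows, dialect: str = "prodigal") -> Path:
    """rows: iterable of (scaftig, start, end, strand, gene_id-or-None)."""
    lines = ["##gff-version 3"]
    for scaftig, start, end, strand, gene_id in rows:
        if gene_id is None:
            attrs = "."
        elif dialect == "prodigal":
            attrs = f"ID={gene_id};partial=00"
        else:
            attrs = f'gene_id "{gene_id}"'
        lines.append("\t".join([scaftig, "test", "CDS", str(start), str(end), ".", strand, "0", attrs]))
    path.write_text("\n".join(lines) + "\n")
    return path


def scan_from_hits(genes, upstream_hits=(), downstream_hits=(), threshold=0.8):
    """Build a PromoterScan directly from per-gene hit sets (unit-test shim)."""
    up = {g.gene_id: g.gene_id in upstream_hits for g in genes}
    down = {g.gene_id: g.gene_id in downstream_hits for g in genes}
    best_up, best_down = {}, {}
    for g in genes:
        if up[g.gene_id]:
            pos = max(1, g.start - 40) if g.strand == "+" else g.end + 40
            best_up[g.gene_id] = PromoterCall(g.scaftig_id, g.strand, pos, 0.95, "nnpp_file")
        if down[g.gene_id]:
            pos = g.end + 40 if g.strand == "+" else max(1, g.start - 40)
            best_down[g.gene_id] = PromoterCall(g.scaftig_id, g.strand, pos, 0.95, "nnpp_file")
    return PromoterScan("nnpp_file", threshold, list(best_up.values()) + list(best_down.values()),
                        up, down, best_up, best_down)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_proximons(genes, threshold=601):
    """Enumerate maximal co-directional runs and split at IGD >= threshold.

    Written against the proximon definition directly (pairwise link table +
    itertools.groupby segmentation), independently of call_proximons.
    """
    linked = []
    for a, b in zip(genes, genes[1:]):
        ok = (a.scaftig_id == b.scaftig_id and a.strand == b.strand
              and (b.start - a.end) + 1 < threshold)
        linked.append(ok)
    clusters, current = [], [genes[0]] if genes else []
    for gene, link in zip(genes[1:], linked):
        if link:
            current.append(gene)
        else:
            clusters.append(current)
            current = [gene]
    if current:
        clusters.append(current)
    return [tuple(c) for c in clusters if len(c) >= 2]


def mirror_genes(genes, scaftig_lengths):
    """Reverse-complement coordinate transform: flip every gene on its scaftig."""
    out = []
    for g in genes:
        L = scaftig_lengths[g.scaftig_id]
        out.append(Gene(g.gene_id, g.scaftig_id, L - g.end + 1, L - g.start + 1,
                        "-" if g.strand == "+" else "+", g.source_tool))
    return sorted(out, key=lambda g: (g.scaftig_id, g.start))


def mirror_interval(start, end, length):
    return length - end + 1, length - start + 1


def brute_force_classify(pred_gene_ids, reference_operons):
    """Independent re-statement of the configuration taxonomy for one operon.

    reference_operons: dict operon_id -> set of gene ids (disjoint).
    Returns the label string.
    """
    s = set(pred_gene_ids)
    touching = [rid for rid, r in reference_operons.items() if s & set(r)]
    best_overlap = max((len(s & set(reference_operons[rid])) for rid in touching), default=0)
    if best_overlap / len(s) < 0.5:
        return "novel"
    if any(s == set(reference_operons[rid]) for rid in touching):
        return "perfect_match"
    if len(touching) >= 2:
        return "bridge1"
    (rid,) = touching
    if s - set(reference_operons[rid]):
        return "superset"
    return "subset"


def all_hexamers():
    return ("".join(p) for p in itertools.product("ACGT", repeat=6))
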