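"""Promoter calling over flank regions through pluggable backends.

Three backends fill the same per-gene hit maps:

``nnpp_file``
    Positional calls parsed from an external predictor's tabular output
    (NNPP-style) are mapped onto flank regions by strand-matched interval
    containment.
``pwm``
    A built-in sigma70-style scorer: a -35 box / spacer / -10 box position
    weight matrix scanned over each flank's oriented sequence.  This is a
    self-contained testing surrogate, not a reimplementation of any
    external neural-network predictor; output provenance is always marked.
``oracle``
    Planted-truth positional calls from the synthetic genome generator,
    mapped exactly like ``nnpp_file`` but with score 1.0.

A call landing in the shared intergenic span between two co-directional
genes counts simultaneously as the downstream hit of the earlier gene and
the upstream hit of the later one — one promoter can both end a
transcription unit and start the next.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .flanks import FlankRegion
from .io_formats import PromoterCall, parse_promoter_file

log = logging.getLogger(__name__)

BACKENDS = ("nnpp_file", "pwm", "oracle")
DEFAULT_THRESHOLD = 0.8
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PWMModel:
    """A -35/spacer/-10 base-probability model of a bacterial promoter.

    Matrices are 4x6 (rows A, C, G, T; one column per box position) and
    every column sums to 1.  Scores are log2 odds against a uniform
    background, min-max normalized over the model to [0, 1], so the model
    consensus scores exactly 1.
    """

    minus35: np.ndarray
    minus10: np.ndarray
    spacer_range: tuple[int, int] = (15, 19)

    def __post_init__(self) -> None:
        for name, m in (("minus35", self.minus35), ("minus10", self.minus10)):
            if m.shape != (4, 6):
                raise ValueError(f"{name} matrix must be 4x6 (rows A,C,G,T)")
            if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"{name} matrix columns must each sum to 1")
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("spacer_range lower bound exceeds upper bound")

    @classmethod
    def from_consensus(
        cls,
        minus35: str = "TTGACA",
        minus10: str = "TATAAT",
        major: float = 0.85,
        spacer_range: tuple[int, int] = (15, 19),
    ) -> "PWMModel":
        """Build matrices concentrating probability *major* on the consensus base."""

        def matrix(consensus: str) -> np.ndarray:
            m = np.full((4, 6), (1.0 - major) / 3.0)
            for col, base in enumerate(consensus):
                m[_BASE_INDEX[base], col] = major
            return m

        return cls(matrix(minus35), matrix(minus10), spacer_range)

    def box_log_odds(self, seq: str, matrix: np.ndarray) -> float:
        """Log2-odds of one 6-mer under one box matrix (ambiguous bases neutral)."""
        total = 0.0
        for col, base in enumerate(seq):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                continue
            total += math.log2(max(matrix[idx, col], 1e-12) / 0.25)
        return total

    def _bounds(self) -> tuple[float, float]:
        lo = hi = 0.0
        for m in (self.minus35, self.minus10):
            lo += float(np.sum(np.log2(np.maximum(m.min(axis=0), 1e-12) / 0.25)))
            hi += float(np.sum(np.log2(np.maximum(m.max(axis=0), 1e-12) / 0.25)))
        return lo, hi

    def score_window(self, seq: str, offset: int, spacer: int) -> float:
        """Normalized [0, 1] score of the window starting at *offset*."""
        b35 = seq[offset:offset + 6]
        b10 = seq[offset + 6 + spacer:offset + 12 + spacer]
        raw = self.box_log_odds(b35, self.minus35) + self.box_log_odds(b10, self.minus10)
        lo, hi = self._bounds()
        return (raw - lo) / (hi - lo) if hi > lo else 0.0

    def scan_sequence(self, seq: str) -> tuple[float, int, int] | None:
        """Best (score, offset, window_length) over all placements, or None."""
        best: tuple[float, int, int] | None = None
        for spacer in range(self.spacer_range[0], self.spacer_range[1] + 1):
            wlen = 12 + spacer
            for off in range(0, len(seq) - wlen + 1):
                score = self.score_window(seq, off, spacer)
                if best is None or score > best[0] or (score == best[0] and (off, wlen) < (best[1], best[2])):
                    best = (score, off, wlen)
        return best

    def to_text(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, m in (("minus35", self.minus35), ("minus10", self.minus10)):
                fh.write(f"{name}\n")
                for row in range(4):
                    fh.write("\t".join(f"{m[row, col]:.6f}" for col in range(6)) + "\n")
            fh.write(f"spacer\t{self.spacer_range[0]}\t{self.spacer_range[1]}\n")
        return path

    @classmethod
    def from_text(cls, path: str | Path) -> "PWMModel":
        matrices: dict[str, np.ndarray] = {}
        spacer = (15, 19)
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        i = 0
        while i < len(lines):
            token = lines[i].split("\t")[0]
            if token in ("minus35", "minus10"):
                rows = [list(map(float, lines[i + 1 + r].split("\t"))) for r in range(4)]
                raw = np.array(rows)
                matrices[token] = raw / raw.sum(axis=0, keepdims=True)
                i += 5
            elif token == "spacer":
                parts = lines[i].split("\t")
                spacer = (int(parts[1]), int(parts[2]))
                i += 1
            else:
                raise ValueError(f"unrecognized PWM config line: {lines[i]!r}")
        if set(matrices) != {"minus35", "minus10"}:
            raise ValueError("PWM config must define both minus35 and minus10 matrices")
        return cls(matrices["minus35"], matrices["minus10"], spacer)


@dataclass
class PromoterScan:
    """Per-gene promoter evidence over a set of flank regions."""

    backend: str
    threshold: float
    calls: list[PromoterCall]
    per_gene_upstream_hit: dict[str, bool]
    per_gene_downstream_hit: dict[str, bool]
    best_upstream_call: dict[str, PromoterCall] = field(default_factory=dict)
    best_downstream_call: dict[str, PromoterCall] = field(default_factory=dict)

    def covers(self, gene_id: str) -> bool:
        return gene_id in self.per_gene_upstream_hit


def _proximal_distance(region: FlankRegion, position: int) -> int:
    """Distance from a position inside the region to its gene-proximal end."""
    return (region.end - position) if region.is_left_of_gene else (position - region.start)


def _attribute_calls(
    regions: Sequence[FlankRegion],
    calls: Sequence[PromoterCall],
    threshold: float,
    scan: PromoterScan,
) -> None:
    retained = [c for c in calls if c.score >= threshold]
    by_scaftig: dict[tuple[str, str], list[PromoterCall]] = {}
    for c in retained:
        by_scaftig.setdefault((c.scaftig_id, c.strand), []).append(c)
    for r in regions:
        if not r.scannable:
            continue
        candidates = [
            c for c in by_scaftig.get((r.scaftig_id, r.gene_strand), [])
            if r.start <= c.position <= r.end
        ]
        if not candidates:
            continue
        # best score wins; equal scores -> gene-proximal position wins
        best = min(candidates, key=lambda c: (-c.score, _proximal_distance(r, c.position), c.position))
        _record_hit(scan, r, best)
    scan.calls = retained


def _record_hit(scan: PromoterScan, region: FlankRegion, call: PromoterCall) -> None:
    if region.side == "upstream":
        scan.per_gene_upstream_hit[region.gene_id] = True
        scan.best_upstream_call[region.gene_id] = call
    else:
        scan.per_gene_downstream_hit[region.gene_id] = True
        scan.best_downstream_call[region.gene_id] = call


def scan_flanks(
    regions: Sequence[FlankRegion],
    backend: str,
    threshold: float = DEFAULT_THRESHOLD,
    pwm: PWMModel | None = None,
    promoter_file: str | Path | Sequence[PromoterCall] | None = None,
    oracle_truth: str | Path | Sequence[PromoterCall] | None = None,
) -> PromoterScan:
    """Scan flank regions for promoters with the chosen backend.

    Only regions with status ``ok``/``trimmed`` are eligible; short-tagged
    flanks never hit.  Every retained call has score >= *threshold*.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown promoter backend {backend!r}; expected one of {BACKENDS}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")

    scan = PromoterScan(
        backend=backend,
        threshold=threshold,
        calls=[],
        per_gene_upstream_hit={r.gene_id: False for r in regions},
        per_gene_downstream_hit={r.gene_id: False for r in regions},
    )

    if backend in ("nnpp_file", "oracle"):
        source_input = promoter_file if backend == "nnpp_file" else oracle_truth
        if source_input is None:
            raise ValueError(f"backend {backend!r} requires a promoter call file")
        if isinstance(source_input, (str, Path)):
            calls = parse_promoter_file(source_input, source=backend)
        else:
            calls = list(source_input)
        _attribute_calls(regions, calls, threshold, scan)
    else:  # pwm
        if pwm is None:
            raise ValueError("backend 'pwm' requires a PWMModel")
        pwm_calls: list[PromoterCall] = []
        for r in regions:
            if not r.scannable:
                continue
            if r.sequence is None:
                raise ValueError(f"pwm backend needs flank sequences; {r.gene_id}/{r.side} has none")
            best = pwm.scan_sequence(r.sequence)
            if best is None or best[0] < threshold:
                continue
            score, offset, _wlen = best
            # oriented index -> genomic coordinate of the window start
            if r.gene_strand == "+":
                position = r.start + offset
            else:
                position = r.end - offset
            call = PromoterCall(r.scaftig_id, r.gene_strand, position, min(score, 1.0), "pwm")
            pwm_calls.append(call)
            _record_hit(scan, r, call)
        scan.calls = pwm_calls

    n_up = sum(scan.per_gene_upstream_hit.values())
    n_down = sum(scan.per_gene_downstream_hit.values())
    log.info("promoter scan (%s, threshold %.2f): %d upstream hits, %d downstream hits",
             backend, threshold, n_up, n_down)
    return scan
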