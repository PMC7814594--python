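"""Scoring predicted operons against a reference operon map.

Two complementary views:

* **Pair-level confusion counts.**  The evaluation universe is every pair
  of adjacent co-directional genes on one scaftig.  A pair is positive in
  the reference when both genes share a reference operon, and positive in
  the prediction when both share a predicted operon; sensitivity,
  specificity and accuracy follow from the resulting tp/fp/tn/fn.  This
  adjacent-gene-pair convention is the standard in operon-prediction
  benchmarking, and the numbers here are comparable only under it.

* **Per-operon configuration labels.**  Each predicted gene set S is
  classified against the reference operon sets R: ``novel`` when its best
  reference overlap covers < 50% of S; ``perfect_match`` when S equals one
  R; ``bridge1`` when S intersects two or more reference operons;
  ``superset`` when S carries extra genes beyond its single matched
  reference; ``subset`` when S is a proper subset of one R.  The rules are
  tested in that order, so every predicted operon gets exactly one label.
  ``bridge2`` — one reference operon split across several predictions — is
  a property of the reference side and is reported separately.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .io_formats import Gene, ReferenceOperonSet

log = logging.getLogger(__name__)

LABELS = ("perfect_match", "subset", "superset", "bridge1", "bridge2", "novel")


@dataclass(frozen=True)
class ConfigurationLabel:
    label: str
    matched_reference_ids: tuple[str, ...] = ()


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    per_operon_labels: dict[str, ConfigurationLabel] = field(default_factory=dict)
    bridge2_references: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _gene_ids(operon) -> tuple[str, ...]:
    """Gene IDs of an Operon object or an OperonRow read back from disk."""
    if hasattr(operon, "gene_ids"):
        return tuple(operon.gene_ids)
    return tuple(g.gene_id for g in operon.genes)


def adjacent_codirectional_pairs(genes: Sequence[Gene]) -> list[tuple[str, str]]:
    """All (gene_id, gene_id) pairs adjacent in genomic order, same scaftig and strand."""
    pairs: list[tuple[str, str]] = []
    for a, b in zip(genes, genes[1:]):
        if a.scaftig_id == b.scaftig_id and a.strand == b.strand:
            pairs.append((a.gene_id, b.gene_id))
    return pairs


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def evaluate_pairs(
    predicted: Sequence,
    reference: ReferenceOperonSet,
    genes: Sequence[Gene],
) -> EvalReport:
    """Pair-level confusion counts plus per-operon configuration labels.

    *genes* (sorted by scaftig, start) defines the universe of evaluable
    adjacent co-directional pairs.  Metrics with an empty denominator are
    reported as None (undefined), not 0.
    """
    pred_map: dict[str, str] = {}
    for op in predicted:
        oid = op.operon_id
        for gid in _gene_ids(op):
            if gid in pred_map:
                raise ValueError(f"gene {gid} appears in two predicted operons")
            pred_map[gid] = oid

    tp = fp = tn = fn = 0
    pairs = adjacent_codirectional_pairs(genes)
    for a, b in pairs:
        ref_pos = reference.gene_to_operon.get(a) is not None \
            and reference.gene_to_operon.get(a) == reference.gene_to_operon.get(b)
        pred_pos = pred_map.get(a) is not None and pred_map.get(a) == pred_map.get(b)
        if ref_pos and pred_pos:
            tp += 1
        elif ref_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1

    if not pairs:
        log.warning("no evaluable adjacent co-directional gene pairs; metrics undefined")

    report = EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        per_operon_labels=classify_configurations(predicted, reference),
        bridge2_references=reference_splits(predicted, reference),
    )
    return report


def classify_configurations(
    predicted: Sequence,
    reference: ReferenceOperonSet,
) -> dict[str, ConfigurationLabel]:
    """Assign each predicted operon exactly one configuration label."""
    ref_sets = {rid: frozenset(gids) for rid, gids in reference.operons.items()}
    labels: dict[str, ConfigurationLabel] = {}
    for op in predicted:
        s = frozenset(_gene_ids(op))
        overlaps = {rid: len(s & r) for rid, r in ref_sets.items() if s & r}
        matched = tuple(sorted(overlaps))
        if not overlaps or max(overlaps.values()) / len(s) < 0.5:
            labels[op.operon_id] = ConfigurationLabel("novel", matched)
        elif any(s == ref_sets[rid] for rid in overlaps):
            labels[op.operon_id] = ConfigurationLabel("perfect_match", matched)
        elif len(overlaps) >= 2:
            labels[op.operon_id] = ConfigurationLabel("bridge1", matched)
        elif s - ref_sets[matched[0]]:
            labels[op.operon_id] = ConfigurationLabel("superset", matched)
        else:
            labels[op.operon_id] = ConfigurationLabel("subset", matched)
    return labels


def reference_splits(
    predicted: Sequence,
    reference: ReferenceOperonSet,
) -> dict[str, tuple[str, ...]]:
    """bridge-2 report: reference operons whose genes land in >= 2 predictions."""
    hits: dict[str, set[str]] = {}
    for op in predicted:
        s = set(_gene_ids(op))
        for rid, gids in reference.operons.items():
            if s & set(gids):
                hits.setdefault(rid, set()).add(op.operon_id)
    return {rid: tuple(sorted(ops)) for rid, ops in sorted(hits.items()) if len(ops) >= 2}


def _fmt_metric(value: float | None) -> str:
    return "NA" if value is None else f"{value:.6f}"


def write_eval_report(report: EvalReport, out_dir: str | Path) -> dict[str, Path]:
    """Write eval_report.tsv (counts + metrics) and configurations.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report_path = out / "eval_report.tsv"
    with open(report_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["metric", "value"])
        for name in ("tp", "fp", "tn", "fn"):
            writer.writerow([name, getattr(report, name)])
        writer.writerow(["sensitivity", _fmt_metric(report.sensitivity)])
        writer.writerow(["specificity", _fmt_metric(report.specificity)])
        writer.writerow(["accuracy", _fmt_metric(report.accuracy)])

    config_path = out / "configurations.tsv"
    with open(config_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["operon_id", "label", "matched_reference_ids"])
        for operon_id, label in report.per_operon_labels.items():
            writer.writerow([operon_id, label.label, ";".join(label.matched_reference_ids)])
        for rid, preds in report.bridge2_references.items():
            writer.writerow([";".join(preds), "bridge2", rid])

    return {"eval_report": report_path, "configurations": config_path}
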