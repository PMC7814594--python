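"""Promoter backends: file mapping, PWM scoring, oracle truth, thresholds."""

import numpy as np
import pytest

from operonkit.flanks import FlankRegion, extract_flank_coordinates, trim_flanks
from operonkit.io_formats import PromoterCall, ScaftigIndex, ScaftigRecord
from operonkit.promoters import PWMModel, scan_flanks

from conftest import all_hexamers, make_gene


def region(gene_id="gB", side="upstream", start=201, end=900, strand="+",
           status="ok", sequence=None, scaftig="scf1"):
    return FlankRegion(gene_id, side, scaftig, strand, start, end,
                       raw_length=end - start + 1, status=status, sequence=sequence)


class TestFileBackend:
    def test_call_inside_region_hits(self):
        call = PromoterCall("scf1", "+", 250, 0.91)
        scan = scan_flanks([region()], "nnpp_file", promoter_file=[call])
        assert scan.per_gene_upstream_hit["gB"] is True
        assert scan.best_upstream_call["gB"] == call

    @pytest.mark.parametrize("pos,strand,expect", [
        (150, "+", False),   # outside the interval
        (250, "-", False),   # wrong strand
        (201, "+", True),    # inclusive start
        (900, "+", True),    # inclusive end
    ])
    def test_strict_containment_and_strand(self, pos, strand, expect):
        call = PromoterCall("scf1", strand, pos, 0.95)
        scan = scan_flanks([region()], "nnpp_file", promoter_file=[call])
        assert scan.per_gene_upstream_hit["gB"] is expect

    def test_shared_span_counts_for_both_genes(self):
        # one promoter between two co-directional genes: downstream of the
        # first AND upstream of the second
        down_a = region("gA", "downstream", 201, 900)
        up_b = region("gB", "upstream", 201, 900)
        call = PromoterCall("scf1", "+", 500, 0.9)
        scan = scan_flanks([down_a, up_b], "nnpp_file", promoter_file=[call])
        assert scan.per_gene_downstream_hit["gA"] and scan.per_gene_upstream_hit["gB"]

    def test_best_score_wins_then_gene_proximal(self):
        # upstream of a + gene: proximal end is region.end
        calls = [PromoterCall("scf1", "+", 300, 0.85), PromoterCall("scf1", "+", 400, 0.99),
                 PromoterCall("scf1", "+", 600, 0.99)]
        scan = scan_flanks([region()], "nnpp_file", promoter_file=[calls[0], calls[1], calls[2]])
        assert scan.best_upstream_call["gB"].position == 600

    def test_threshold_filters_hits_monotonically(self):
        calls = [PromoterCall("scf1", "+", 250, 0.5), PromoterCall("scf1", "+", 400, 0.9)]
        hits = []
        for threshold in (0.4, 0.6, 0.95):
            scan = scan_flanks([region()], "nnpp_file", threshold=threshold,
                               promoter_file=calls)
            hits.append(sum(scan.per_gene_upstream_hit.values()) + len(scan.calls))
        assert hits == sorted(hits, reverse=True)

    def test_short_regions_never_hit(self):
        short = region(status="short_ups", start=201, end=204)
        call = PromoterCall("scf1", "+", 202, 0.99)
        scan = scan_flanks([short], "nnpp_file", promoter_file=[call])
        assert scan.per_gene_upstream_hit["gB"] is False

    def test_missing_file_is_usage_error(self):
        with pytest.raises(ValueError, match="requires"):
            scan_flanks([region()], "nnpp_file")


class TestOracleBackend:
    def test_truth_positions_mark_their_genes(self):
        up_a = region("gA", "upstream", 100, 400)
        up_b = region("gB", "upstream", 600, 800)
        truth = [PromoterCall("scf1", "+", 360, 1.0, "oracle")]
        scan = scan_flanks([up_a, up_b], "oracle", oracle_truth=truth)
        assert scan.per_gene_upstream_hit == {"gA": True, "gB": False}


class TestPWMBackend:
    CONSENSUS = "TTGACA" + "G" * 17 + "TATAAT"

    def test_consensus_scores_maximum_and_hits(self):
        model = PWMModel.from_consensus()
        seq = "C" * 20 + self.CONSENSUS + "C" * 20
        r = region(sequence=seq, start=201, end=200 + len(seq))
        scan = scan_flanks([r], "pwm", pwm=model)
        assert scan.per_gene_upstream_hit["gB"] is True
        (call,) = scan.calls
        assert call.score == pytest.approx(1.0)
        assert call.source == "pwm"

    def test_background_sequence_scores_below_threshold(self):
        model = PWMModel.from_consensus()
        r = region(sequence="CG" * 60)
        scan = scan_flanks([r], "pwm", pwm=model)
        assert scan.per_gene_upstream_hit["gB"] is False

    def test_consensus_hexamer_beats_all_others_exhaustively(self):
        model = PWMModel.from_consensus()
        best = model.box_log_odds("TATAAT", model.minus10)
        scores = [model.box_log_odds(h, model.minus10) for h in all_hexamers()]
        assert best == pytest.approx(max(scores))
        assert sum(s == best for s in scores) == 1  # the consensus is the unique max

    def test_missing_sequence_is_usage_error(self):
        with pytest.raises(ValueError, match="sequences"):
            scan_flanks([region(sequence=None)], "pwm", pwm=PWMModel.from_consensus())

    def test_model_text_round_trip(self, tmp_path):
        model = PWMModel.from_consensus(major=0.7, spacer_range=(16, 18))
        path = model.to_text(tmp_path / "pwm.txt")
        again = PWMModel.from_text(path)
        assert np.allclose(again.minus35, model.minus35, atol=1e-6)
        assert np.allclose(again.minus10, model.minus10, atol=1e-6)
        assert again.spacer_range == (16, 18)

    def test_column_sums_validated(self):
        bad = np.full((4, 6), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PWMModel(bad, PWMModel.from_consensus().minus10)


def test_backend_name_validated():
    with pytest.raises(ValueError, match="unknown promoter backend"):
        scan_flanks([], "nnpp")


def test_end_to_end_region_mapping_on_real_flanks(seq_index):
    """Positional calls land on the flanks computed from gene coordinates."""
    genes = [make_gene("a", 100, 200), make_gene("b", 901, 1300)]
    regions = trim_flanks(extract_flank_coordinates(genes, seq_index))
    call = PromoterCall("scf1", "+", 860, 0.9)  # in [201, 900], upstream of b
    scan = scan_flanks(regions, "nnpp_file", promoter_file=[call])
    assert scan.per_gene_upstream_hit["b"] is True
    assert scan.per_gene_downstream_hit["a"] is True  # shared intergenic span
    assert scan.per_gene_upstream_hit["a"] is False
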