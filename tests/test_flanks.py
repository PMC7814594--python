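"""Flank geometry: coordinates, trimming, tags, sequences, strand symmetry."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operonkit.flanks import (extract_flank_coordinates, extract_flank_sequences,
                              trim_flanks)
from operonkit.io_formats import Gene, ScaftigIndex, ScaftigRecord

from conftest import make_gene, mirror_genes, mirror_interval


def flanks_of(regions, gene_id):
    up = next(r for r in regions if r.gene_id == gene_id and r.side == "upstream")
    down = next(r for r in regions if r.gene_id == gene_id and r.side == "downstream")
    return up, down


LEN2000 = ScaftigIndex({"scf1": ScaftigRecord(2000)})


class TestExtractCoordinates:
    def test_single_plus_gene(self):
        regions = extract_flank_coordinates([make_gene("g", 500, 900)], LEN2000)
        up, down = flanks_of(regions, "g")
        assert (up.start, up.end, up.raw_length) == (1, 499, 499)
        assert (down.start, down.end, down.raw_length) == (901, 2000, 1100)

    def test_single_minus_gene_mirrors_sides(self):
        regions = extract_flank_coordinates([make_gene("g", 500, 900, "-")], LEN2000)
        up, down = flanks_of(regions, "g")
        assert (up.start, up.end) == (901, 2000)
        assert (down.start, down.end) == (1, 499)

    def test_between_adjacent_genes(self):
        genes = [make_gene("a", 100, 200), make_gene("b", 205, 300)]
        regions = extract_flank_coordinates(genes, LEN2000)
        up_b, _ = flanks_of(regions, "b")
        assert (up_b.start, up_b.end, up_b.raw_length) == (201, 204, 4)

    def test_overlapping_neighbour_gives_zero_length(self):
        genes = [make_gene("a", 100, 250), make_gene("b", 205, 300)]
        regions = extract_flank_coordinates(genes, LEN2000)
        up_b, _ = flanks_of(regions, "b")
        assert up_b.raw_length == 0 and up_b.length == 0

    def test_gene_beyond_scaftig_skipped_with_issue(self):
        issues = []
        regions = extract_flank_coordinates([make_gene("g", 1900, 2100)], LEN2000, issues=issues)
        assert regions == [] and len(issues) == 1


class TestTrim:
    def test_long_upstream_keeps_gene_proximal_700(self):
        # + gene starting at 901: upstream [1, 900] has raw length 900 > 700
        regions = extract_flank_coordinates([make_gene("g", 901, 1200)], LEN2000)
        up = trim_flanks(regions)[0]
        assert up.side == "upstream"
        assert (up.start, up.end, up.status) == (201, 900, "trimmed")

    def test_long_downstream_minus_gene_proximal_cut(self):
        # - gene at 901..1200: downstream is the left region [1, 900]
        regions = extract_flank_coordinates([make_gene("g", 901, 1200, "-")], LEN2000)
        _, down = flanks_of(trim_flanks(regions), "g")
        assert (down.start, down.end, down.status) == (201, 900, "trimmed")

    @pytest.mark.parametrize("raw,expected_status", [(14, "short_ups"), (15, "ok")])
    def test_short_boundary_is_strict(self, raw, expected_status):
        genes = [make_gene("a", 100, 200), make_gene("b", 201 + raw, 400)]
        regions = extract_flank_coordinates(genes, LEN2000)
        up_b, _ = flanks_of(trim_flanks(regions), "b")
        assert up_b.raw_length == raw and up_b.status == expected_status

    def test_short_tag_matches_side(self):
        genes = [make_gene("a", 100, 200, "-"), make_gene("b", 205, 300, "-")]
        regions = trim_flanks(extract_flank_coordinates(genes, LEN2000))
        _, down_b = flanks_of(regions, "b")  # left region, 4 bp, minus strand -> downstream
        assert down_b.status == "short_dss"


class TestSequences:
    def test_plus_strand_direct_slice(self, seq_index):
        regions = trim_flanks(extract_flank_coordinates([make_gene("g", 21, 500)], seq_index))
        up, _ = flanks_of(extract_flank_sequences(regions, seq_index), "g")
        assert up.sequence == "ACGT" * 5  # [1, 20] taken verbatim

    def test_minus_strand_reverse_complement(self, seq_index):
        # upstream of a minus gene ending at 1980 is [1981, 2000]
        regions = trim_flanks(extract_flank_coordinates([make_gene("g", 1501, 1980, "-")], seq_index))
        up, _ = flanks_of(extract_flank_sequences(regions, seq_index), "g")
        assert up.sequence == "ACGT" * 5  # revcomp of the phased ACGT repeat

    def test_short_regions_get_empty_sequence(self, seq_index):
        genes = [make_gene("a", 100, 200), make_gene("b", 205, 300)]
        regions = trim_flanks(extract_flank_coordinates(genes, seq_index))
        filled = extract_flank_sequences(regions, seq_index)
        up_b, _ = flanks_of(filled, "b")
        assert up_b.sequence == ""

    def test_requires_sequences_in_index(self):
        regions = trim_flanks(extract_flank_coordinates([make_gene("g", 500, 900)], LEN2000))
        with pytest.raises(ValueError, match="without sequences"):
            extract_flank_sequences(regions, LEN2000)


@st.composite
def gene_layouts(draw):
    scaftig_len = draw(st.integers(min_value=300, max_value=5000))
    n = draw(st.integers(min_value=1, max_value=8))
    coords = sorted(draw(st.lists(st.integers(1, scaftig_len), min_size=2 * n,
                                  max_size=2 * n, unique=True)))
    genes = []
    for i in range(n):
        start, end = coords[2 * i], coords[2 * i + 1]
        strand = draw(st.sampled_from("+-"))
        genes.append(Gene(f"g{i}", "scf1", start, end, strand))
    return scaftig_len, genes


@settings(max_examples=150, derandomize=True)
@given(gene_layouts())
def test_flank_invariants(layout):
    """Cap, short-tagging, own-gene disjointness and strand-mirror symmetry."""
    scaftig_len, genes = layout
    index = ScaftigIndex({"scf1": ScaftigRecord(scaftig_len)})
    regions = trim_flanks(extract_flank_coordinates(genes, index))
    by_gene = {g.gene_id: g for g in genes}
    for r in regions:
        assert r.length <= 700
        assert (r.status in ("short_ups", "short_dss")) == (r.raw_length < 15)
        if r.status == "trimmed":
            assert r.raw_length > 700 and r.length == 700
        g = by_gene[r.gene_id]
        assert r.end < g.start or r.start > g.end or r.length == 0

    # mirror: reverse-complement the scaftig, flip strands; upstream maps to upstream
    mirrored = mirror_genes(genes, {"scf1": scaftig_len})
    m_regions = trim_flanks(extract_flank_coordinates(mirrored, index))
    fwd = {(r.gene_id, r.side): r for r in regions}
    rev = {(r.gene_id, r.side): r for r in m_regions}
    assert set(fwd) == set(rev)
    for key, r in fwd.items():
        m = rev[key]
        assert m.raw_length == r.raw_length and m.status == r.status
        assert (m.start, m.end) == mirror_interval(r.start, r.end, scaftig_len)
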