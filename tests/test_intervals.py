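"""Interval model, I/O round-trips, consensus calling and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regscreen.intervals import (
    GeneModel,
    GenomicInterval,
    ParseError,
    Peak,
    annotate_features,
    assign_promoters,
    consensus_regions,
    merge_intervals,
    promoter_window,
    read_gene_models,
    read_peaks,
    write_gene_models,
    write_peaks,
)


# ---------------------------------------------------------------------------
# data model


class TestGenomicInterval:
    def test_display_is_one_based_inclusive(self):
        # BED row chr9 5449462 5449962 displays as the printed Region 1 coords
        iv = GenomicInterval("chr9", 5449462, 5449962)
        assert iv.display() == "chr9:5449463-5449962"
        assert iv.width == 500

    def test_region2_coordinates(self):
        iv = GenomicInterval("chr9", 5450249, 5450749)
        assert iv.display() == "chr9:5450250-5450749"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=1),
            dict(chrom="chr1", start=-1, end=5),
            dict(chrom="chr1", start=5, end=5),
            dict(chrom="chr1", start=5, end=3),
            dict(chrom="chr1", start=0, end=1, strand="x"),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_overlap_len(self):
        a = GenomicInterval("chr1", 0, 100)
        assert a.overlap_len(GenomicInterval("chr1", 50, 150)) == 50
        assert a.overlap_len(GenomicInterval("chr1", 100, 150)) == 0
        assert a.overlap_len(GenomicInterval("chr2", 0, 100)) == 0


class TestPeak:
    def test_summit_within_bounds(self):
        iv = GenomicInterval("chr1", 0, 100)
        Peak(interval=iv, summit_offset=99)
        with pytest.raises(ValueError):
            Peak(interval=iv, summit_offset=100)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            Peak(interval=GenomicInterval("chr1", 0, 10), signal=-1)


# ---------------------------------------------------------------------------
# I/O


class TestReadPeaks:
    def test_bed3_paper_coordinates(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr9\t5449462\t5449962\n")
        (peak,) = read_peaks(p, dialect="bed3")
        assert peak.interval.display() == "chr9:5449463-5449962"

    def test_narrowpeak_summit_minus_one_is_absent(self, tmp_path):
        p = tmp_path / "r.narrowPeak"
        p.write_text("chr1\t10\t110\tpk\t0\t.\t7.5\t-1\t-1\t-1\n")
        (peak,) = read_peaks(p, dialect="narrowPeak")
        assert peak.summit_offset is None
        assert peak.signal == 7.5

    def test_narrowpeak_summit_parsed(self, tmp_path):
        p = tmp_path / "r.narrowPeak"
        p.write_text("chr1\t10\t110\tpk\t0\t+\t7.5\t-1\t-1\t42\n")
        (peak,) = read_peaks(p, dialect="narrowPeak")
        assert peak.summit_offset == 42

    def test_end_equals_start_is_parse_error_with_line(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t0\t10\nchr1\t5\t5\n")
        with pytest.raises(ParseError, match=":2:"):
            read_peaks(p, dialect="bed3")

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("track name=x\n# c\nbrowser position chr1\nchr1\t0\t10\n")
        assert len(read_peaks(p, dialect="bed3")) == 1

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "r.narrowPeak"
        p.write_text("chr1\t0\t10\n")
        with pytest.raises(ParseError, match="expected >= 10"):
            read_peaks(p, dialect="narrowPeak")


@pytest.mark.parametrize("dialect", ["bed3", "bed6", "narrowPeak"])
def test_read_write_roundtrip(tmp_path, dialect):
    peaks = [
        Peak(GenomicInterval("chr1", 0, 100, "+"), signal=5.0, summit_offset=10, name="a"),
        Peak(GenomicInterval("chr2", 50, 60, "-"), signal=1.5, summit_offset=None, name="b"),
    ]
    path = tmp_path / "out"
    write_peaks(peaks, path, dialect=dialect)
    back = read_peaks(path, dialect=dialect)
    for orig, rt in zip(peaks, back):
        assert rt.interval.chrom == orig.interval.chrom
        assert rt.interval.start == orig.interval.start
        assert rt.interval.end == orig.interval.end
        if dialect != "bed3":
            assert rt.interval.strand == orig.interval.strand
            assert rt.name == orig.name
            assert rt.signal == orig.signal
        if dialect == "narrowPeak":
            assert rt.summit_offset == orig.summit_offset


def test_gene_model_roundtrip(tmp_path):
    genes = [GeneModel("CD274", "chr9", 5450502, "+"), GeneModel("X", "chr1", 99, "-")]
    path = tmp_path / "genes.bed"
    write_gene_models(genes, path)
    assert read_gene_models(path) == genes


# ---------------------------------------------------------------------------
# consensus calling


def _peaks(*spans, chrom="chr1"):
    return [Peak(GenomicInterval(chrom, s, e)) for s, e in spans]


def brute_force_consensus(peak_sets, min_support, genome_len=20_000, chrom="chr1"):
    """Independent per-base sample-counting oracle (single chromosome)."""
    import math

    n = len(peak_sets)
    k = math.ceil(min_support * n)
    cov = np.zeros(genome_len, dtype=int)
    for ps in peak_sets:
        covered = np.zeros(genome_len, dtype=bool)
        for p in ps:
            covered[p.interval.start : p.interval.end] = True
        cov += covered
    supported = cov >= k
    runs = []
    start = None
    for i, s in enumerate(supported):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, genome_len))
    return [GenomicInterval(chrom, s, e) for s, e in runs]


class TestConsensusRegions:
    def test_single_sample_identity(self):
        ps = _peaks((0, 100), (200, 300), (250, 320))
        out = consensus_regions([ps], min_support=1.0)
        assert [iv for iv, _ in out] == [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 200, 320),
        ]
        assert all(support == 1 for _, support in out)

    def test_three_sample_intersection(self):
        sets = [_peaks((0, 100)), _peaks((50, 150)), _peaks((60, 90))]
        out = consensus_regions(sets, min_support=1.0)
        assert [iv for iv, _ in out] == [GenomicInterval("chr1", 60, 90)]
        assert out[0][1] == 3

    def test_fixed_width_midpoint(self):
        # 30 bp run at [1060, 1090) -> 500 bp window centered at base 1075
        sets = [_peaks((1060, 1090))]
        out = consensus_regions(sets, min_support=1.0, fixed_width=500)
        (iv, support) = out[0]
        assert (iv.start, iv.end) == (1075 - 250, 1075 + 250)
        assert support == 1

    def test_fixed_width_trimmed_at_chromosome_edge(self):
        sets = [_peaks((0, 30))]
        out = consensus_regions(
            sets, min_support=1.0, fixed_width=500, chrom_sizes={"chr1": 400}
        )
        (iv, _) = out[0]
        assert iv.start == 0 and iv.end == 400

    def test_min_support_validation(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                consensus_regions([_peaks((0, 10))], min_support=bad)

    def test_duplicate_peaks_within_sample_do_not_inflate_support(self):
        sets = [_peaks((0, 100), (0, 100), (0, 100)), _peaks((500, 600))]
        assert consensus_regions(sets, min_support=1.0) == []

    def test_permutation_invariance(self, rng):
        sets = [
            _peaks(*[(int(s), int(s) + int(w)) for s, w in
                     zip(rng.integers(0, 5000, 5), rng.integers(10, 500, 5))])
            for _ in range(6)
        ]
        ref = consensus_regions(sets, min_support=0.5)
        perm = [sets[i] for i in rng.permutation(len(sets))]
        assert consensus_regions(perm, min_support=0.5) == ref

    def test_output_sorted_non_overlapping(self, rng):
        sets = [
            _peaks(*[(int(s), int(s) + int(w)) for s, w in
                     zip(rng.integers(0, 8000, 8), rng.integers(10, 800, 8))])
            for _ in range(5)
        ]
        out = [iv for iv, _ in consensus_regions(sets, min_support=0.4)]
        for a, b in zip(out, out[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            assert a.end <= b.start or a.chrom != b.chrom

    @pytest.mark.parametrize("min_support", [0.5, 0.9, 1.0])
    def test_matches_brute_force_oracle(self, min_support):
        rng = np.random.default_rng(int(min_support * 100))
        for _ in range(30):
            n_samples = int(rng.integers(1, 11))
            sets = []
            for _ in range(n_samples):
                k = int(rng.integers(0, 8))
                spans = [
                    (int(s), int(s) + int(w))
                    for s, w in zip(rng.integers(0, 9000, k), rng.integers(1, 1000, k))
                ]
                sets.append(_peaks(*spans))
            got = [iv for iv, _ in consensus_regions(sets, min_support=min_support)]
            expected = brute_force_consensus(sets, min_support)
            assert got == expected


# ---------------------------------------------------------------------------
# promoter assignment and feature classes


class TestAssignPromoters:
    def test_exact_promoter_window_match(self):
        g = GeneModel("A", "chr1", 5000, "+")
        win = promoter_window(g, 2000, 500)
        out = assign_promoters([win], [g], upstream=2000, downstream=500)
        gene, dist = out[win]
        assert gene == "A"
        assert dist == abs(win.midpoint - 5000)

    def test_nearest_tss_wins(self):
        a = GeneModel("A", "chr1", 5000, "+")
        b = GeneModel("B", "chr1", 6000, "+")
        region = GenomicInterval("chr1", 5400, 5600)  # midpoint 5500
        out = assign_promoters([region], [a, b], upstream=2000, downstream=500)
        assert out[region] == ("A", 500)

    def test_distance_tie_breaks_lexicographically(self):
        a = GeneModel("B", "chr1", 5000, "+")
        b = GeneModel("A", "chr1", 6000, "+")
        region = GenomicInterval("chr1", 5450, 5650)  # midpoint 5550
        out = assign_promoters([region], [a, b], upstream=2000, downstream=500)
        # distances: |5550-5000|=550 vs |5550-6000|=450 -> A wins by distance
        assert out[region] == ("A", 450)
        region2 = GenomicInterval("chr1", 5300, 5700)  # midpoint 5500: tie at 500
        out2 = assign_promoters([region2], [a, b], upstream=2000, downstream=500)
        assert out2[region2] == ("A", 500)

    def test_minus_strand_window_extends_rightward(self):
        g = GeneModel("A", "chr1", 10_000, "-")
        win = promoter_window(g, upstream=2000, downstream=500)
        assert win.end == 10_000 + 2000 + 1
        assert win.start == 10_000 - 500 + 1

    def test_unmapped_region_flagged_not_dropped(self):
        g = GeneModel("A", "chr1", 5000, "+")
        far = GenomicInterval("chr1", 100_000, 100_100)
        out = assign_promoters([far], [g])
        assert out[far] is None


class TestAnnotateFeatures:
    def test_promoter_beats_intron(self):
        g = GeneModel("A", "chr1", 5000, "+")
        region = GenomicInterval("chr1", 4900, 5100)
        intron = GenomicInterval("chr1", 4000, 6000)
        classes, counts = annotate_features([region], [g], introns=[intron])
        assert classes[region] == "promoter"

    def test_intergenic(self):
        g = GeneModel("A", "chr1", 5000, "+")
        region = GenomicInterval("chr1", 500_000, 500_100)
        classes, _ = annotate_features([region], [g])
        assert classes[region] == "intergenic"

    def test_counts_partition_input(self, rng):
        g = GeneModel("A", "chr1", 5000, "+")
        exon = GenomicInterval("chr1", 20_000, 21_000)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 50_000, 25)
        ]
        classes, counts = annotate_features(list(set(regions)), [g], exons=[exon])
        assert sum(counts.values()) == len(set(regions))
        assert set(counts) <= {"promoter", "exon", "intron", "intergenic"}


@settings(max_examples=50, deadline=None)
@given(
    spans=st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 500)), min_size=1, max_size=20
    )
)
def test_merge_intervals_covers_same_bases(spans):
    ivs = [GenomicInterval("chr1", s, s + w) for s, w in spans]
    merged = merge_intervals(ivs)
    raster = np.zeros(6000, dtype=bool)
    for iv in ivs:
        raster[iv.start : iv.end] = True
    raster_m = np.zeros(6000, dtype=bool)
    for iv in merged:
        raster_m[iv.start : iv.end] = True
    assert np.array_equal(raster, raster_m)
    for a, b in zip(merged, merged[1:]):
        assert a.end < b.start  # strictly separated after merging
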