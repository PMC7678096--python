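"""BED/bedGraph I/O, track invariants, and rebinning."""

import numpy as np
import pytest

from trackfuse import (
    CoverageTrack,
    ProbabilityTrack,
    TrackParseError,
    TrackValidationError,
    read_coverage_bed,
    write_bed,
    write_bedgraph,
    rebin,
)
from conftest import make_track, make_prob


class TestReadCoverageBed:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\t5\n")
        t = read_coverage_bed(p)
        assert len(t) == 1
        b = t.bins[0]
        assert (b.chrom, b.start, b.end, b.value) == ("chr1", 0, 10, 5.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_coverage_bed(p)) == 0

    def test_three_bins_infers_bin_size(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t10\t1\nchr1\t10\t20\t2\nchr1\t20\t30\t3\n")
        t = read_coverage_bed(p)
        assert t.bin_size == 10
        assert list(t.values) == [1.0, 2.0, 3.0]

    def test_headers_and_comments_skipped(self, tmp_path):
        p = tmp_path / "h.bed"
        p.write_text(
            "track type=bedGraph name=x\nbrowser position chr1\n# comment\n"
            "chr1\t0\t10\t4\n"
        )
        assert len(read_coverage_bed(p)) == 1

    @pytest.mark.parametrize(
        "line,fragment",
        [
            ("chr1\t0\t10", "4 fields"),
            ("chr1\tzero\t10\t5", "integers"),
            ("chr1\t10\t10\t5", "end must exceed start"),
            ("chr1\t0\t10\tnan", "finite"),
            ("chr1\t0\t10\t-3", "non-negative"),
            ("chr1\t0\t10\tfive", "not numeric"),
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line, fragment):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\t1\n" + line + "\n")
        with pytest.raises(TrackParseError, match=r":2:") as exc:
            read_coverage_bed(p)
        assert fragment in str(exc.value)

    def test_overlapping_bins_rejected(self, tmp_path):
        p = tmp_path / "o.bed"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t2\n")
        with pytest.raises(TrackValidationError, match="overlap"):
            read_coverage_bed(p)

    def test_unsorted_input_is_sorted(self, tmp_path, caplog):
        p = tmp_path / "u.bed"
        p.write_text("chr1\t20\t30\t3\nchr1\t0\t10\t1\nchr1\t10\t20\t2\n")
        with caplog.at_level("INFO"):
            t = read_coverage_bed(p)
        assert list(t.values) == [1.0, 2.0, 3.0]
        assert any("sorting" in r.message for r in caplog.records)

    def test_chrom_order_is_first_appearance(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr2\t0\t10\t1\nchr1\t0\t10\t1\n")
        assert read_coverage_bed(p).chrom_order == ["chr2", "chr1"]


class TestWriteBed:
    def test_precision_formatting(self, tmp_path):
        t = make_prob([0.39347])
        out = tmp_path / "o.bed"
        write_bed(t, out, precision=4)
        assert out.read_text() == "chr1\t0\t10\t0.3935\n"

    def test_empty_track_gives_empty_file(self, tmp_path):
        t = CoverageTrack(make_track([]).data, 10, [])
        out = tmp_path / "o.bed"
        write_bed(t, out)
        assert out.read_text() == ""

    @pytest.mark.parametrize("precision", [3, 6])
    def test_roundtrip_within_precision(self, tmp_path, rng, precision):
        t = make_track(rng.uniform(0, 100, size=40))
        out = tmp_path / "rt.bed"
        write_bed(t, out, precision=precision)
        back = read_coverage_bed(out)
        assert back.bin_size == t.bin_size
        np.testing.assert_allclose(back.values, t.values, atol=10 ** -precision / 2 + 1e-12)


class TestWriteBedgraph:
    def test_header_first_line(self, tmp_path):
        out = tmp_path / "o.bg"
        write_bedgraph(make_prob([0.5]), out, track_name="demo")
        assert out.read_text().splitlines()[0] == "track type=bedGraph name=demo"

    def test_runlength_merge(self, tmp_path):
        out = tmp_path / "o.bg"
        write_bedgraph(make_prob([0.5, 0.5, 0.7]), out, merge=True)
        lines = out.read_text().splitlines()[1:]
        assert lines == ["chr1\t0\t20\t0.500000", "chr1\t20\t30\t0.700000"]

    def test_no_merge_keeps_bin_count(self, tmp_path):
        out = tmp_path / "o.bg"
        write_bedgraph(make_prob([0.5, 0.5, 0.7]), out, merge=False)
        assert len(out.read_text().splitlines()) == 4

    def test_merge_does_not_cross_gaps_or_chroms(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 20, 0],
                "end": [10, 30, 10],
                "value": [0.5, 0.5, 0.5],
            }
        )
        out = tmp_path / "o.bg"
        write_bedgraph(ProbabilityTrack(df, 10), out, merge=True)
        assert len(out.read_text().splitlines()) == 4


class TestRebin:
    def test_mean_aggregation(self):
        t = rebin(make_track([2, 4, 6, 8]), 20)
        assert list(t.values) == [3.0, 7.0]
        assert t.bin_size == 20
        assert list(t.data["end"]) == [20, 40]

    def test_identity_bin_size(self):
        t = make_track([1, 2, 3])
        t2 = rebin(t, 10)
        assert list(t2.values) == list(t.values)

    def test_partial_trailing_group(self):
        t = rebin(make_track([2, 4, 6]), 20)
        assert list(t.values) == [3.0, 6.0]
        assert list(t.data["end"]) == [20, 30]  # extent preserved

    def test_weighted_mean_conserved(self, rng):
        vals = rng.uniform(0, 50, size=60)
        t = make_track(vals)
        t2 = rebin(t, 30)
        assert np.isclose(
            (t.values * 10).sum(), (t2.values * 30).sum()
        )

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rebin(make_track([1, 2]), 15)


class TestInvariants:
    def test_probability_track_rejects_out_of_range(self):
        with pytest.raises(TrackValidationError, match="raw coverage"):
            make_prob([0.5, 1.5])

    def test_negative_values_rejected(self):
        with pytest.raises(TrackValidationError):
            make_track([1.0, -1.0])

    def test_genomic_bin_invariants(self):
        from trackfuse import GenomicBin

        with pytest.raises(TrackValidationError):
            GenomicBin("chr1", 10, 10, 1.0)
        with pytest.raises(TrackValidationError):
            GenomicBin("chr1", 0, 10, float("inf"))
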