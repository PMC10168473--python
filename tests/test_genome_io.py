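"""Coordinate model and plain-text format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daric.genome import A, B, UNDEFINED, BinnedGenome, OEMatrix, SignalTrack
from daric.io import (
    CoordinateError,
    ParseError,
    read_compartments,
    read_domains,
    read_gaps,
    read_oe_dump,
    read_track,
    write_domains,
    write_oe_dump,
    write_track,
)
from daric.segmentation import Domain, DomainSegmentation


class TestBinnedGenome:
    def test_bin_counts_ceil_and_short_last_bin(self, genome2):
        # 1,070,000 bp at 50 kb -> 22 bins, the last one 20 kb
        assert genome2.n_bins_chrom("chrA") == 22
        assert genome2.n_bins_chrom("chrB") == 16
        assert genome2.n_bins == 38
        assert genome2.bin_end("chrA", 21) - genome2.bin_start("chrA", 21) == 20_000

    def test_global_index_bijection(self, genome2):
        offsets = genome2.chrom_offsets
        seen = set()
        for chrom in genome2.chrom_names:
            sl = genome2.chrom_slice(chrom)
            assert sl.start == offsets[chrom]
            seen.update(range(sl.start, sl.stop))
        assert seen == set(range(genome2.n_bins))

    def test_gap_mask_length_enforced(self):
        with pytest.raises(ValueError, match="gap_mask"):
            BinnedGenome(("c",), (100_000,), 50_000, gap_mask=np.zeros(5, bool))

    def test_gaps_from_intervals_marks_overlapping_bins(self, genome2):
        g = genome2.with_gaps_from_intervals(
            [("chrA", 60_000, 120_000), ("chrUn", 0, 10_000)]
        )
        sl = g.chrom_slice("chrA")
        assert list(np.flatnonzero(g.gap_mask[sl])) == [1, 2]

    def test_unknown_chromosome_raises_key_error(self, genome2):
        with pytest.raises(KeyError):
            genome2.chrom_slice("chr99")


class TestOEDump:
    def test_three_row_toy_is_mirrored(self, tmp_path):
        g = BinnedGenome(("c",), (100_000,), 50_000)
        p = tmp_path / "oe.txt"
        p.write_text("0 0 1.0\n0 50000 2.0\n50000 50000 1.0\n")
        oe = read_oe_dump(str(p), "c", g)
        assert np.array_equal(oe.values, [[1, 2], [2, 1]])
        assert oe.valid.all()

    def test_empty_file_is_all_invalid(self, tmp_path):
        g = BinnedGenome(("c",), (100_000,), 50_000)
        p = tmp_path / "oe.txt"
        p.write_text("")
        oe = read_oe_dump(str(p), "c", g)
        assert not oe.valid.any()

    def test_nan_entry_invalid_others_kept(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = tmp_path / "oe.txt"
        p.write_text("0 0 1.5\n0 50000 NaN\n50000 100000 0.7\n")
        oe = read_oe_dump(str(p), "c", g)
        assert oe.valid[0, 0] and not oe.valid[0, 1] and oe.valid[1, 2]
        assert oe.values[2, 1] == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "row, err, match",
        [
            ("0 50000\n", ParseError, ":1"),
            ("0 abc 1.0\n", ParseError, ":1"),
            ("0 51000 1.0\n", CoordinateError, "multiple"),
            ("0 950000 1.0\n", CoordinateError, "outside"),
        ],
    )
    def test_malformed_rows(self, tmp_path, row, err, match):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = tmp_path / "oe.txt"
        p.write_text(row)
        with pytest.raises(err, match=match):
            read_oe_dump(str(p), "c", g)

    def test_unknown_chrom_key_error(self, tmp_path, genome2):
        p = tmp_path / "oe.txt"
        p.write_text("")
        with pytest.raises(KeyError):
            read_oe_dump(str(p), "chrZ", genome2)

    def test_gap_rows_invalidated(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000,
                         gap_mask=np.array([False, True, False]))
        p = tmp_path / "oe.txt"
        p.write_text("0 50000 2.0\n0 100000 1.0\n")
        oe = read_oe_dump(str(p), "c", g)
        assert not oe.valid[:, 1].any() and not oe.valid[1, :].any()
        assert oe.valid[0, 2]

    def test_write_read_round_trip_identity_on_valid(self, tmp_path, rng):
        g = BinnedGenome(("c",), (600_000,), 50_000)
        n = 12
        m = rng.uniform(0, 2, (n, n))
        m = (m + m.T) / 2
        valid = rng.random((n, n)) > 0.3
        valid &= valid.T
        oe = OEMatrix("c", np.where(valid, m, 0.0), valid)
        p = tmp_path / "oe.txt"
        write_oe_dump(oe, str(p), g)
        back = read_oe_dump(str(p), "c", g)
        assert np.array_equal(back.valid, valid)
        assert np.allclose(back.values[valid], m[valid], rtol=1e-9)


class TestCompartments:
    def _write(self, tmp_path, lines):
        p = tmp_path / "comp.bedGraph"
        p.write_text("".join(lines))
        return str(p)

    @pytest.mark.parametrize(
        "orientation, expected",
        [("as_is", [A, B, A]), ("flip", [B, A, B])],
    )
    def test_sign_to_label(self, tmp_path, orientation, expected):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = self._write(tmp_path, [
            "c\t0\t50000\t1.2\n", "c\t50000\t100000\t-0.4\n",
            "c\t100000\t150000\t0.1\n",
        ])
        track = read_compartments(p, g, orientation)
        assert list(track.labels) == expected

    def test_zero_value_and_uncovered_are_undefined(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = self._write(tmp_path, ["c\t0\t50000\t0.0\n"])
        track = read_compartments(p, g)
        assert list(track.labels) == [UNDEFINED, UNDEFINED, UNDEFINED]

    def test_overlap_is_format_error(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = self._write(tmp_path, ["c\t0\t100000\t1.0\n", "c\t50000\t150000\t1.0\n"])
        with pytest.raises(ParseError, match="overlap"):
            read_compartments(p, g)

    def test_misaligned_interval_is_coordinate_error(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        p = self._write(tmp_path, ["c\t10000\t60000\t1.0\n"])
        with pytest.raises(CoordinateError, match="aligned"):
            read_compartments(p, g)

    def test_gap_bins_forced_undefined(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000,
                         gap_mask=np.array([False, True, False]))
        p = self._write(tmp_path, ["c\t0\t150000\t1.0\n"])
        track = read_compartments(p, g)
        assert list(track.labels) == [A, UNDEFINED, A]


class TestTrackIO:
    def test_nan_bins_omitted_and_coords_half_open(self, tmp_path):
        g = BinnedGenome(("c",), (150_000,), 50_000)
        t = SignalTrack(g, np.array([1.5, np.nan, -0.2]))
        p = tmp_path / "t.bedGraph"
        write_track(t, str(p))
        lines = p.read_text().strip().split("\n")
        assert lines == ["c\t0\t50000\t1.5", "c\t100000\t150000\t-0.2"]

    def test_all_nan_track_gives_empty_file(self, tmp_path, genome2):
        t = SignalTrack(genome2, np.full(genome2.n_bins, np.nan))
        p = tmp_path / "t.bedGraph"
        write_track(t, str(p))
        assert p.read_text() == ""

    def test_merge_equal_collapses_runs(self, tmp_path):
        g = BinnedGenome(("c",), (200_000,), 50_000)
        t = SignalTrack(g, np.array([2.0, 2.0, 2.0, 1.0]))
        p = tmp_path / "t.bedGraph"
        write_track(t, str(p), merge_equal=True)
        lines = p.read_text().strip().split("\n")
        assert lines == ["c\t0\t150000\t2", "c\t150000\t200000\t1"]

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(
        st.one_of(st.just(float("nan")),
                  st.floats(-50, 50, allow_nan=False).map(lambda x: round(x, 4))),
        min_size=1, max_size=30,
    ))
    def test_round_trip_preserves_finite_values(self, tmp_path_factory, values):
        g = BinnedGenome(("c",), (len(values) * 50_000,), 50_000)
        t = SignalTrack(g, np.array(values))
        p = tmp_path_factory.mktemp("rt") / "t.bedGraph"
        write_track(t, str(p))
        back = read_track(str(p), g)
        finite = np.isfinite(t.values)
        assert np.array_equal(np.isfinite(back.values), finite)
        assert np.allclose(back.values[finite], t.values[finite], rtol=1e-6)

    def test_interval_starts_are_bin_multiples(self, tmp_path, genome2, rng):
        t = SignalTrack(genome2, rng.standard_normal(genome2.n_bins))
        p = tmp_path / "t.bedGraph"
        write_track(t, str(p))
        for line in p.read_text().strip().split("\n"):
            start = int(line.split("\t")[1])
            assert start % genome2.bin_size == 0


class TestDomainIO:
    def test_single_domain_half_open_line(self, tmp_path, genome1):
        seg = DomainSegmentation(genome1, [
            Domain("chr1", 4, 10, "Strong+", mean_residual=1.2, mean_score=3.0,
                   significant=True),
        ])
        p = tmp_path / "d.bed"
        write_domains(seg, str(p))
        fields = p.read_text().strip().split("\t")
        assert fields[:5] == ["chr1", "200000", "500000", "Strong+", "150"]

    def test_empty_segmentation_gives_empty_file(self, tmp_path, genome1):
        p = tmp_path / "d.bed"
        write_domains(DomainSegmentation(genome1, []), str(p))
        assert p.read_text() == ""

    def test_round_trip_preserves_bounds_labels_flags(self, tmp_path, genome2):
        seg = DomainSegmentation(genome2, [
            Domain("chrA", 0, 5, "Weak-", mean_residual=-0.1, mean_score=0.4),
            Domain("chrA", 5, 12, "Strong+", mean_residual=1.4, mean_score=4.2,
                   significant=True),
            Domain("chrB", 2, 16, "Weak+", mean_residual=0.2, mean_score=1.0),
        ])
        p = tmp_path / "d.bed"
        write_domains(seg, str(p))
        back = read_domains(str(p), genome2)
        for orig, rt in zip(seg.domains, back.domains):
            assert (rt.chrom, rt.start_bin, rt.end_bin, rt.state) == (
                orig.chrom, orig.start_bin, orig.end_bin, orig.state)
            assert rt.significant == orig.significant
            assert rt.mean_score == pytest.approx(orig.mean_score, abs=1e-4)


def test_read_gaps_from_bed(tmp_path, genome2):
    p = tmp_path / "gaps.bed"
    p.write_text("chrA\t0\t100000\nchrB\t50000\t100000\n")
    g = read_gaps(str(p), genome2)
    assert g.gap_mask[g.chrom_slice("chrA")][:2].all()
    assert list(np.flatnonzero(g.gap_mask[g.chrom_slice("chrB")])) == [1]
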