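"""Interval semantics: peak cleaning, SNP-in-peak, TSS distance."""

import numpy as np
import pandas as pd
import pytest

from asoc import annotate_tss_distance, clean_peaks, read_bed, snps_in_peaks, write_bed
from asoc.errors import ParseError

from conftest import make_counts, rng_for


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestCleanPeaks:
    def test_one_bp_overlap_dropped(self):
        peaks = bed([("chr1", 100, 600, "p1")])
        blacklist = bed([("chr1", 599, 700, "b1")])
        assert len(clean_peaks(peaks, blacklist)) == 0

    def test_half_open_adjacency_retained(self):
        peaks = bed([("chr1", 100, 600, "p1")])
        blacklist = bed([("chr1", 600, 700, "b1")])
        out = clean_peaks(peaks, blacklist)
        assert list(out["name"]) == ["p1"]

    def test_excluded_and_decoy_chromosomes_dropped(self):
        peaks = bed(
            [
                ("chr1", 0, 10, "a"),
                ("chrX", 0, 10, "b"),
                ("chrM", 0, 10, "c"),
                ("hs37d5", 0, 10, "d"),
            ]
        )
        out = clean_peaks(peaks, None)
        assert list(out["name"]) == ["a"]

    def test_matches_brute_force_oracle(self):
        rng = rng_for("clean_peaks_oracle")
        starts = rng.integers(0, 10_000, size=300)
        peaks = bed([(f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 400)), f"p{i}") for i, s in enumerate(starts)])
        bstarts = rng.integers(0, 10_000, size=100)
        blacklist = bed([(f"chr{rng.integers(1, 4)}", int(s), int(s + rng.integers(1, 200)), f"b{i}") for i, s in enumerate(bstarts)])
        got = set(clean_peaks(peaks, blacklist)["name"])
        want = {
            p.name
            for p in peaks.itertuples(index=False)
            if not any(
                p.chrom == b.chrom and p.start < b.end and b.start < p.end
                for b in blacklist.itertuples(index=False)
            )
        }
        assert got == want

    def test_idempotent_and_sorted(self):
        rng = rng_for("clean_peaks_idem")
        peaks = bed(
            [("chr2", int(s), int(s) + 50, f"p{i}") for i, s in enumerate(rng.integers(0, 5000, 50))]
        )
        blacklist = bed([("chr2", 100, 300, "b")])
        once = clean_peaks(peaks, blacklist)
        twice = clean_peaks(once, blacklist)
        pd.testing.assert_frame_equal(once, twice)
        assert (once["start"].diff().dropna() >= 0).all()


class TestSnpsInPeaks:
    def test_boundary_sweep(self):
        """All 1-based positions 95..205 against peak [100, 200)."""
        peaks = bed([("chr1", 100, 200, "p")])
        snps = make_counts(
            [("chr1", p, f"s{p}", "A", "G", 10, 10, "0/1", True) for p in range(95, 206)]
        )
        inside = set(snps_in_peaks(snps, peaks)["pos"])
        # coordinate-conversion oracle: 1-based p inside iff 100 <= p-1 < 200
        want = {p for p in range(95, 206) if 100 <= p - 1 < 200}
        assert inside == want
        assert 100 not in inside and 101 in inside
        assert 200 in inside and 201 not in inside

    def test_empty_peaks(self):
        snps = make_counts([("chr1", 5, "s", "A", "G", 1, 1, "0/1", True)])
        assert len(snps_in_peaks(snps, bed([]))) == 0

    def test_nested_peak_first_by_sort_order(self):
        peaks = bed([("chr1", 50, 500, "outer"), ("chr1", 100, 200, "inner")])
        snps = make_counts([("chr1", 150, "s", "A", "G", 1, 1, "0/1", True)])
        out = snps_in_peaks(snps, peaks)
        assert list(out["peak_id"]) == ["outer"]

    def test_matches_brute_force_oracle(self):
        rng = rng_for("snps_in_peaks_oracle")
        peaks = bed(
            [
                (f"chr{rng.integers(1, 3)}", int(s), int(s + rng.integers(1, 300)), f"p{i}")
                for i, s in enumerate(rng.integers(0, 20_000, size=200))
            ]
        )
        snps = make_counts(
            [
                (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 20_300)), f"s{i}", "A", "G", 5, 5, "0/1", True)
                for i in range(500)
            ]
        )
        got = set(snps_in_peaks(snps, peaks)["snp_id"])
        want = {
            s.snp_id
            for s in snps.itertuples(index=False)
            if any(
                s.chrom == p.chrom and p.start <= s.pos - 1 < p.end
                for p in peaks.itertuples(index=False)
            )
        }
        assert got == want


class TestTssDistance:
    def _annot(self, dist):
        tss = pd.DataFrame({"chrom": ["chr1"], "tss_pos": [1_000_000], "gene": ["G"], "strand": ["+"]})
        snps = make_counts([("chr1", 1_000_000 + dist, "s", "A", "G", 1, 1, "0/1", True)])
        return annotate_tss_distance(snps, tss).iloc[0]

    @pytest.mark.parametrize(
        "dist,category",
        [
            (4999, "promoter_proximal"),
            (5000, "promoter_proximal"),
            (5001, "intermediate"),
            (50_000, "intermediate"),
            (50_001, "distal"),
            (0, "promoter_proximal"),
        ],
    )
    def test_category_boundaries(self, dist, category):
        row = self._annot(dist)
        assert row["distance_bp"] == dist
        assert row["category"] == category

    def test_unannotated_chromosome(self):
        tss = pd.DataFrame({"chrom": ["chr2"], "tss_pos": [100], "gene": ["G"], "strand": ["+"]})
        snps = make_counts([("chr1", 500, "s", "A", "G", 1, 1, "0/1", True)])
        out = annotate_tss_distance(snps, tss)
        assert out.iloc[0]["category"] == "unannotated"

    def test_nearest_matches_all_pairs_oracle(self):
        rng = rng_for("tss_nearest_oracle")
        tss = pd.DataFrame(
            {
                "chrom": "chr1",
                "tss_pos": rng.integers(1, 1_000_000, size=80),
                "gene": [f"g{i}" for i in range(80)],
                "strand": "+",
            }
        )
        snps = make_counts(
            [("chr1", int(p), f"s{i}", "A", "G", 1, 1, "0/1", True) for i, p in enumerate(rng.integers(1, 1_000_000, size=300))]
        )
        out = annotate_tss_distance(snps, tss)
        for snp, row in zip(snps.itertuples(index=False), out.itertuples(index=False)):
            want = min(abs(int(t) - snp.pos) for t in tss["tss_pos"])
            assert row.distance_bp == want

    def test_categories_partition(self):
        rng = rng_for("tss_partition")
        tss = pd.DataFrame({"chrom": ["chr1"], "tss_pos": [500_000], "gene": ["G"], "strand": ["+"]})
        snps = make_counts(
            [("chr1", int(p), f"s{i}", "A", "G", 1, 1, "0/1", True) for i, p in enumerate(rng.integers(1, 1_000_000, size=400))]
        )
        out = annotate_tss_distance(snps, tss)
        counts = out["category"].value_counts()
        assert counts.sum() == 400
        assert set(counts.index) <= {"promoter_proximal", "intermediate", "distal"}


class TestBedIo:
    def test_round_trip(self, tmp_path):
        df = bed([("chr1", 0, 100, "a"), ("chr2", 50, 80, "b")])
        path = tmp_path / "x.bed"
        write_bed(df, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(back, df)

    def test_malformed_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\t5\n")
        with pytest.raises(ParseError) as exc:
            read_bed(path)
        assert exc.value.line == 2

    def test_invalid_interval(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t100\n")
        with pytest.raises(ParseError):
            read_bed(path)
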