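"""Per-barcode QC metrics, threshold filtering, and Tn5 pileups."""

import numpy as np
import pytest

from trimux.atac_qc import (
    BarcodeQC,
    QCThresholds,
    compute_barcode_qc,
    filter_barcodes,
    footprint_interval,
    fragment_length_histogram,
    tsd_center_pileup,
    tss_footprint_pileup,
)
from trimux.fragments import FragmentRecord
from trimux.intervals import GenomicInterval, IntervalSet, overlaps
from conftest import random_interval_set


def make_qc(**kw):
    defaults = dict(barcode="BC", n_total=2000, n_unique=1500,
                    frac_mito=0.01, frip=0.5, fritss=0.5, frac_dhs=0.8)
    defaults.update(kw)
    return BarcodeQC(**defaults)


class TestComputeBarcodeQC:
    def test_all_fragments_in_peaks(self):
        peaks = IntervalSet([GenomicInterval("chr1", 0, 10_000)])
        frags = [FragmentRecord("chr1", i * 100, i * 100 + 50, "BC1")
                 for i in range(10)]
        qc = compute_barcode_qc(frags, peaks, IntervalSet(), IntervalSet())
        assert qc["BC1"].frip == 1.0
        assert qc["BC1"].fritss == 0.0  # empty TSS set

    def test_mito_fraction_uses_total_fragments(self):
        frags = [
            FragmentRecord("chr1", 0, 100, "BC1", dup_count=3),
            FragmentRecord("chrM", 0, 100, "BC1", dup_count=1),
        ]
        qc = compute_barcode_qc(frags, IntervalSet(), IntervalSet(), IntervalSet())
        assert qc["BC1"].n_total == 4
        assert qc["BC1"].n_unique == 2
        assert qc["BC1"].frac_mito == pytest.approx(0.25)

    def test_matches_brute_force_oracle(self, rng):
        peaks = random_interval_set(rng, 40, max_pos=5000)
        tss = random_interval_set(rng, 30, max_pos=5000)
        dhs = random_interval_set(rng, 30, max_pos=5000)
        frags = [
            FragmentRecord(
                str(rng.choice(["chr1", "chr2", "chrM"])),
                int(s := rng.integers(0, 5000)),
                int(s + rng.integers(20, 300)),
                f"BC{int(rng.integers(0, 8))}",
                int(rng.integers(1, 4)),
            )
            for _ in range(200)
        ]
        qc = compute_barcode_qc(frags, peaks, tss, dhs)
        for bc, q in qc.items():
            mine = [f for f in frags if f.barcode == bc]
            total = sum(f.dup_count for f in mine)
            in_set = lambda f, s: any(
                overlaps(GenomicInterval(f.chrom, f.start, f.end), iv) for iv in s
            )
            assert q.n_total == total
            assert q.n_unique == len(mine)
            assert q.frac_mito == pytest.approx(
                sum(f.dup_count for f in mine if f.chrom == "chrM") / total)
            assert q.frip == pytest.approx(
                sum(in_set(f, peaks) for f in mine) / len(mine))
            assert q.fritss == pytest.approx(
                sum(in_set(f, tss) for f in mine) / len(mine))
            assert q.frac_dhs == pytest.approx(
                sum(in_set(f, dhs) for f in mine) / len(mine))
            assert 0 <= q.frip <= 1 and q.n_unique <= q.n_total


class TestFilterBarcodes:
    def test_exact_threshold_fails_strict_inequality(self):
        qc = {"a": make_qc(n_unique=1000), "b": make_qc(n_unique=1001)}
        passed, failed = filter_barcodes(qc, QCThresholds.from_preset("standard"))
        assert passed == {"b"}
        assert "n_unique" in failed["a"][0]

    def test_marginal_pass(self):
        qc = {"a": make_qc(n_unique=1001, frip=0.21, fritss=0.21, frac_dhs=0.51)}
        passed, _ = filter_barcodes(qc, QCThresholds.from_preset("standard"))
        assert passed == {"a"}

    def test_icicle_frip_boundary(self):
        at = {"a": make_qc(n_unique=600, frip=0.65)}
        above = {"a": make_qc(n_unique=600, frip=0.66)}
        th = QCThresholds.from_preset("icicle")
        assert filter_barcodes(at, th)[0] == set()
        assert filter_barcodes(above, th)[0] == {"a"}

    def test_fail_reasons_list_every_violation(self):
        qc = {"a": make_qc(n_unique=10, frip=0.0, fritss=0.0, frac_dhs=0.0)}
        _, failed = filter_barcodes(qc, QCThresholds.from_preset("standard"))
        assert len(failed["a"]) == 4

    def test_monotone_in_thresholds(self, rng):
        qc = {
            f"b{i}": make_qc(
                barcode=f"b{i}",
                n_unique=int(rng.integers(100, 5000)),
                frip=float(rng.random()),
                fritss=float(rng.random()),
                frac_dhs=float(rng.random()),
            )
            for i in range(50)
        }
        base = filter_barcodes(qc, QCThresholds(1000, 0.2, 0.2, 0.5))[0]
        for th in [QCThresholds(2000, 0.2, 0.2, 0.5),
                   QCThresholds(1000, 0.4, 0.2, 0.5),
                   QCThresholds(1000, 0.2, 0.5, 0.5),
                   QCThresholds(1000, 0.2, 0.2, 0.8)]:
            assert filter_barcodes(qc, th)[0] <= base

    def test_presets(self):
        assert QCThresholds.from_preset("standard") == QCThresholds(1000, 0.2, 0.2, 0.5, "standard")
        assert QCThresholds.from_preset("icicle").min_frip == 0.65
        assert QCThresholds.from_preset("tea_atac").min_unique == 2500


class TestFragmentLengthHistogram:
    def test_length_and_overflow(self):
        frags = [FragmentRecord("chr1", 100, 200, "a"),
                 FragmentRecord("chr1", 0, 5000, "a")]
        h = fragment_length_histogram(frags, max_len=1000)
        assert h.loc[100, "all"] == 1
        assert h.loc[1001, "all"] == 1  # overflow bin
        assert h["all"].sum() == 2

    def test_empty_group_all_zero(self):
        frags = [FragmentRecord("chr1", 0, 80, "a")]
        h = fragment_length_histogram(frags, groups={"a": "g1", "b": "g2"})
        assert h["g2"].sum() == 0 and h["g1"].sum() == 1

    def test_bimodal_mixture_modes(self, rng):
        frags = []
        for i in range(2000):
            L = 80 if i % 2 else 180
            s = int(rng.integers(0, 10_000))
            frags.append(FragmentRecord("chr1", s, s + L, "a"))
        h = fragment_length_histogram(frags)["all"]
        assert h.idxmax() in (80, 180)
        assert h.loc[80] == 1000 and h.loc[180] == 1000


def dense_pileup_oracle(frags, anchors, window, mode, shift_5p=4, shift_3p=-5,
                        flank=10, tsd=9):
    """Per-base accumulation into a dense array, one anchor at a time."""
    counts = np.zeros(2 * window + 1, dtype=int)
    for a in anchors:
        for f in frags:
            if f.chrom != a.chrom:
                continue
            if mode == "fragment_coverage":
                spans = [(f.start, f.end)]
            else:
                spans = []
                for ins in (f.start + shift_5p, f.end - 1 + shift_3p):
                    half = (tsd - 1) // 2 + flank
                    spans.append((ins - half, ins - half + tsd + 2 * flank))
            for s, e in spans:
                for g in range(s, e):
                    off = g - a.start if a.strand != "-" else a.start - g
                    if -window <= off <= window:
                        counts[off + window] += 1
    return counts


class TestFootprintPileup:
    def test_footprint_width_is_29bp(self):
        s, e = footprint_interval(100)
        assert e - s == 29  # 9 bp TSD + 10 bp each side
        assert (s, e) == (86, 115)  # centered on the TSD center

    def test_coverage_mode_conserves_fragment_length(self):
        anchors = IntervalSet([GenomicInterval("chr1", 5000, 5001, "+")])
        frags = [FragmentRecord("chr1", 4900, 5050, "a")]
        prof = tss_footprint_pileup(frags, anchors, window=2000,
                                    mode="fragment_coverage")
        assert prof.counts.sum() == 150

    @pytest.mark.parametrize("mode", ["footprint", "fragment_coverage"])
    def test_matches_dense_oracle(self, rng, mode):
        anchors = IntervalSet([
            GenomicInterval("chr1", int(p), int(p) + 1,
                            str(rng.choice(["+", "-"])))
            for p in rng.integers(2000, 20_000, size=5)
        ])
        frags = [
            FragmentRecord("chr1", int(s := rng.integers(0, 22_000)),
                           int(s + rng.integers(30, 400)), "a")
            for _ in range(100)
        ]
        prof = tss_footprint_pileup(frags, anchors, window=500, mode=mode)
        expected = dense_pileup_oracle(frags, list(anchors), 500, mode)
        assert (prof.counts == expected).all()

    @pytest.mark.parametrize("mode", ["footprint", "fragment_coverage"])
    def test_strand_mirror_reverses_profile(self, rng, mode):
        pos = 10_000
        frags = [
            FragmentRecord("chr1", int(s := rng.integers(9000, 11_000)),
                           int(s + rng.integers(30, 300)), "a")
            for _ in range(50)
        ]
        plus = tss_footprint_pileup(
            frags, IntervalSet([GenomicInterval("chr1", pos, pos + 1, "+")]),
            window=400, mode=mode)
        minus = tss_footprint_pileup(
            frags, IntervalSet([GenomicInterval("chr1", pos, pos + 1, "-")]),
            window=400, mode=mode)
        assert (minus.counts == plus.counts[::-1]).all()

    def test_rejects_nonpositive_window(self):
        with pytest.raises(ValueError):
            tss_footprint_pileup([], IntervalSet(), window=0)


class TestTsdCenterPileup:
    def test_default_shifts(self):
        # fragment (100, 200): centers at 100+4=104 and 199-5=194
        region = IntervalSet([GenomicInterval("chr1", 0, 301, "+")])
        frags = [FragmentRecord("chr1", 100, 200, "a")]
        prof = tsd_center_pileup(frags, region)
        hit_offsets = prof.offsets[prof.counts > 0]
        center = 150  # width 301, center = start + 150
        assert sorted(hit_offsets + center) == [104, 194]

    def test_methods_variant_shifts(self):
        region = IntervalSet([GenomicInterval("chr1", 0, 301, "+")])
        frags = [FragmentRecord("chr1", 100, 200, "a")]
        prof = tsd_center_pileup(frags, region, shift_5p=5, shift_3p=-4)
        assert sorted(prof.offsets[prof.counts > 0] + 150) == [105, 195]

    def test_outside_fragment_contributes_nothing(self):
        region = IntervalSet([GenomicInterval("chr1", 1000, 2001, "+")])
        frags = [FragmentRecord("chr2", 1200, 1400, "a"),
                 FragmentRecord("chr1", 10, 50, "a")]
        prof = tsd_center_pileup(frags, region)
        assert prof.counts.sum() == 0

    def test_mixed_widths_rejected(self):
        regions = IntervalSet([GenomicInterval("chr1", 0, 100),
                               GenomicInterval("chr1", 0, 200)])
        with pytest.raises(ValueError):
            tsd_center_pileup([], regions)

    def test_matches_point_in_interval_oracle(self, rng):
        width = 1001
        regions = IntervalSet([
            GenomicInterval("chr1", int(p), int(p) + width,
                            str(rng.choice(["+", "-"])))
            for p in rng.integers(0, 50_000, size=20)
        ])
        frags = [
            FragmentRecord("chr1", int(s := rng.integers(0, 50_000)),
                           int(s + rng.integers(30, 400)), "a")
            for _ in range(200)
        ]
        prof = tsd_center_pileup(frags, regions)
        half = width // 2
        expected = np.zeros(width, dtype=int)
        for r in regions:
            center = r.start + half
            for f in frags:
                if f.chrom != r.chrom:
                    continue
                for pt in (f.start + 4, f.end - 1 - 5):
                    if r.start <= pt < r.end:
                        off = center - pt if r.strand == "-" else pt - center
                        expected[off + half] += 1
        assert (prof.counts == expected).all()
        # conservation: one tally per in-region TSD center
        n_points = sum(
            1
            for r in regions
            for f in frags
            if f.chrom == r.chrom
            for pt in (f.start + 4, f.end - 1 - 5)
            if r.start <= pt < r.end
        )
        assert prof.counts.sum() == n_points
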