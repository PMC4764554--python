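"""CLIP preprocessing rules, peak filters, TC-anchored profiles and classes."""

import numpy as np
import pytest

from nmdshield import clip
from nmdshield.annotations import GenomeAnnotation, build_transcript, select_exemplars


def rec(seq, rid="r"):
    return (rid, seq, "I" * len(seq))


class TestIclipPreprocessing:
    def test_non_gtt_reads_removed(self):
        out, log = clip.preprocess_iclip([rec("GTTAACGTCAX".replace("X", "A")),
                                          rec("ACGTACGTAAAA", "r2")])
        assert len(out) == 1
        assert log["dropped_no_gtt"] == 1

    def test_duplicates_collapse_to_one(self):
        out, log = clip.preprocess_iclip([rec("GTTACGTACGTA", "a"),
                                          rec("GTTACGTACGTA", "b")])
        assert len(out) == 1
        assert log["dropped_duplicates"] == 1

    def test_trim_removes_first_seven(self):
        out, _ = clip.preprocess_iclip([rec("GTTCCCCAAAT")])
        assert out[0][1] == "AAAT"

    def test_quality_string_trimmed_with_sequence(self):
        out, _ = clip.preprocess_iclip([("r", "GTTCCCCAAAT", "ABCDEFGHIJK")])
        assert out[0][2] == "HIJK"

    def test_conservation_at_every_step(self):
        reads = [rec("GTTAAACCCTTT", "a"), rec("GTTAAACCCTTT", "b"),
                 rec("CCCAAACCCTTT", "c"), rec("GTTCCCC", "d")]  # d too short
        out, log = clip.preprocess_iclip(reads)
        assert log["input"] == log["after_gtt_filter"] + log["dropped_no_gtt"]
        assert log["after_gtt_filter"] == log["after_collapse"] + log["dropped_duplicates"]
        assert log["after_collapse"] == log["after_trim"] + log["dropped_short"]
        assert len(out) == log["after_trim"]


class TestHitsClipPreprocessing:
    def test_duplicate_pair_to_singleton(self):
        out, _ = clip.preprocess_hitsclip([rec("ACGTTTT", "a"), rec("ACGTTTT", "b")])
        assert len(out) == 1

    def test_trim_three(self):
        out, _ = clip.preprocess_hitsclip([rec("ACGTTTT")])
        assert out[0][1] == "TTTT"

    def test_mixed_case_collapsed(self):
        out, log = clip.preprocess_hitsclip([rec("acgttTT", "a"), rec("ACGTTTT", "b")])
        assert len(out) == 1
        assert log["dropped_duplicates"] == 1


class TestPeakWidthFilter:
    def _peak(self, width):
        return clip.ClipPeak("chr1", 1000, 1000 + width, "+")

    def test_strictly_narrower_than_500(self):
        kept = clip.filter_peaks_by_width([self._peak(499), self._peak(500)])
        assert [p.width for p in kept] == [499]

    def test_empty_input(self):
        assert clip.filter_peaks_by_width([]) == []


def toy_annotation():
    """Two single-exon exemplars on opposite strands of one chromosome.

    '+' gene: exon [0, 2000), stop codon ends at 399 (TC origin 400).
    '-' gene: exon [3000, 5000), stop codon ends at 4600 (TC origin 4599).
    """
    plus = build_transcript("Tp", "Gp", "chr1", "+", [(0, 2000)], 399)
    minus = build_transcript("Tm", "Gm", "chr1", "-", [(3000, 5000)], 4600)
    return select_exemplars(GenomeAnnotation(transcripts={"Tp": plus, "Tm": minus}))


class TestAnnotatePeaks:
    def test_center_and_offset_plus_strand(self):
        ann = toy_annotation()
        peak = clip.ClipPeak("chr1", 490, 510, "+")
        assert peak.center == 500
        annos, log = clip.annotate_peak_positions([peak], ann)
        assert annos[0].center_offset == 100
        assert log["assigned"] == 1

    def test_minus_strand_mirror_offset(self):
        ann = toy_annotation()
        peak = clip.ClipPeak("chr1", 4489, 4509, "-")  # center 4499 = origin-100
        annos, _ = clip.annotate_peak_positions([peak], ann)
        assert annos[0].center_offset == 100

    def test_strand_mismatch_unassigned(self):
        ann = toy_annotation()
        annos, log = clip.annotate_peak_positions(
            [clip.ClipPeak("chr1", 490, 510, "-")], ann
        )
        assert not annos and log["unassigned"] == 1

    def test_ambiguous_center_unassigned(self):
        a = build_transcript("Ta", "Ga", "chr1", "+", [(0, 1000)], 99)
        b = build_transcript("Tb", "Gb", "chr1", "+", [(500, 1500)], 599)
        ann = select_exemplars(GenomeAnnotation(transcripts={"Ta": a, "Tb": b}))
        annos, log = clip.annotate_peak_positions(
            [clip.ClipPeak("chr1", 700, 720, "+")], ann
        )
        assert not annos and log["ambiguous"] == 1


class TestDensityProfile:
    def _annos(self, offsets, weights=None):
        ann = toy_annotation()
        t = ann.transcripts["Tp"]
        out = []
        for i, off in enumerate(offsets):
            w = None if weights is None else weights[i]
            p = clip.ClipPeak("chr1", 400 + off - 5, 400 + off + 5, "+", weight=w)
            out.append(clip.PeakAnnotation(p, "Tp", "Gp", off))
        return out

    def test_binned_counting(self):
        prof = clip.tc_density_profile(self._annos([10, 15, 30]), window=(0, 40))
        assert list(prof.values) == [2.0, 1.0]

    def test_empty_annotations_all_zero(self):
        prof = clip.tc_density_profile([], window=(0, 100))
        assert prof.values.sum() == 0

    def test_total_conserved(self):
        annos = self._annos([5, 25, 45, 199])
        prof = clip.tc_density_profile(annos, window=(0, 200))
        assert prof.values.sum() == len(annos)

    def test_reads_mode_uses_weights(self):
        prof = clip.tc_density_profile(
            self._annos([10, 30], weights=[7.0, 2.0]), window=(0, 40),
            weight_mode="reads",
        )
        assert list(prof.values) == [7.0, 2.0]

    def test_translation_invariance(self):
        """Shifting the whole locus leaves the TC-anchored profile unchanged."""
        profiles = []
        for base in (0, 10_000):
            t = build_transcript(
                "T", "G", "chr1", "+", [(base, base + 2000)], base + 399
            )
            ann = select_exemplars(GenomeAnnotation(transcripts={"T": t}))
            peaks = [
                clip.ClipPeak("chr1", base + 400 + off - 5, base + 400 + off + 5, "+")
                for off in (12, 77, 133)
            ]
            annos, _ = clip.annotate_peak_positions(peaks, ann)
            profiles.append(clip.tc_density_profile(annos, window=(0, 200)))
        assert np.array_equal(profiles[0].values, profiles[1].values)

    def test_misaligned_window_rejected(self):
        with pytest.raises(ValueError):
            clip.tc_density_profile([], window=(0, 50), bin_size=20)


class TestIntervalClasses:
    def _dataset(self):
        ann = toy_annotation()  # both 3'UTRs are 1600 nt, > 500
        t = ann.transcripts["Tp"]
        mk = lambda off: clip.PeakAnnotation(
            clip.ClipPeak("chr1", 400 + off - 5, 400 + off + 5, "+"), "Tp", "Gp", off
        )
        return ann, mk

    def test_interval_membership(self):
        ann, mk = self._dataset()
        classes = clip.classify_by_peak_interval([mk(150)], ann)
        assert "Gp" in classes["peak_0_200"]
        assert "Gp" not in classes["peak_200_500"]
        classes = clip.classify_by_peak_interval([mk(350)], ann)
        assert "Gp" in classes["peak_200_500"]

    def test_no_proximal_class(self):
        ann, mk = self._dataset()
        classes = clip.classify_by_peak_interval([mk(150)], ann)
        assert classes["no_tc_proximal_peak"] == {"Gm"}

    def test_short_utr3_excluded(self):
        short = build_transcript("Ts", "Gs", "chr2", "+", [(0, 800)], 399)  # UTR 400
        ann = select_exemplars(GenomeAnnotation(transcripts={"Ts": short}))
        classes = clip.classify_by_peak_interval([], ann)
        assert classes["excluded_short_utr3"] == {"Gs"}
        assert classes["no_tc_proximal_peak"] == set()


class TestNmdSensitivityCdf:
    def test_identical_class_vs_reference(self, rng):
        genes = [f"g{i}" for i in range(40)]
        fc = {g: float(rng.normal()) for g in genes}
        lens = {g: 1000 for g in genes}
        classes = {
            "peak_0_200": set(genes[:20]),
            "no_tc_proximal_peak": set(genes[:20]),  # same genes: D=0
        }
        out = clip.nmd_sensitivity_cdf(classes, fc, lens, band=(0, 2000))
        assert out["peak_0_200"]["ks"].statistic == 0.0
        assert out["peak_0_200"]["ks"].p_value == 1.0

    def test_band_defaults_to_interquartile(self):
        genes = [f"g{i}" for i in range(8)]
        lens = {g: float(v) for g, v in zip(genes, [1, 2, 3, 4, 5, 6, 7, 8])}
        fc = {g: 0.0 for g in genes}
        classes = {"peak_0_200": set(genes), "no_tc_proximal_peak": set(genes)}
        out = clip.nmd_sensitivity_cdf(classes, fc, lens)
        # brute-force percentile oracle on {1..8}: q25=2.75, q75=6.25
        assert out["band"] == pytest.approx((2.75, 6.25))

    def test_small_class_flagged(self, rng):
        genes = [f"g{i}" for i in range(10)]
        fc = {g: float(rng.normal()) for g in genes}
        lens = {g: 1000 for g in genes}
        classes = {"peak_0_200": {"g0"}, "no_tc_proximal_peak": set(genes[1:])}
        out = clip.nmd_sensitivity_cdf(classes, fc, lens, band=(0, 2000))
        assert out["peak_0_200"]["ks"] is None
        assert "flag" in out["peak_0_200"]


class TestBedRoundTrip:
    def test_write_then_read(self, tmp_path, small_dataset):
        peaks = small_dataset["peaks"][:50]
        path = tmp_path / "peaks.bed"
        clip.write_bed6(peaks, path)
        back = clip.read_bed6(path, score_as_weight=True)
        assert [(p.chrom, p.start, p.end, p.strand) for p in back] == [
            (p.chrom, p.start, p.end, p.strand) for p in peaks
        ]
        assert [p.weight for p in back] == [p.weight for p in peaks]
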