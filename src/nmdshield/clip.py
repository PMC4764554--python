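"""CLIP read preprocessing, peak filtering, and TC-anchored positional analysis.

Two preprocessing conventions are supported, matching the two crosslinking
protocols: iCLIP libraries (RT-primer GTT prefix, 7-nt degenerate barcode)
are filtered for the GTT prefix, collapsed on exact sequence, then trimmed
by 7 nt; HITS-CLIP libraries are collapsed and trimmed by 3 nt.  Each step's
read counts are logged so totals are conserved (kept + dropped).

Downstream, called peaks (BED6) narrower than 500 nt are assigned to the
exemplar transcript containing their center, converted to TC-relative
offsets, binned into 20-nt metagene density profiles, and used to classify
genes by peak position for NMD-sensitivity comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import stats
from .annotations import GenomeAnnotation, TranscriptModel, tc_relative_position

logger = logging.getLogger(__name__)

__all__ = [
    "ClipPeak",
    "PeakAnnotation",
    "DensityProfile",
    "preprocess_iclip",
    "preprocess_hitsclip",
    "read_bed6",
    "write_bed6",
    "filter_peaks_by_width",
    "annotate_peak_positions",
    "tc_density_profile",
    "classify_by_peak_interval",
    "nmd_sensitivity_cdf",
]


# ---------------------------------------------------------------------------
# FASTQ preprocessing

def _read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(id, sequence, quality) records from a 4-line FASTQ file."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def _write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _collapse_exact(
    records: list[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    """Keep the first read of each exact (case-normalized) sequence."""
    seen: set[str] = set()
    out = []
    for rid, seq, qual in records:
        s = seq.upper()
        if s in seen:
            continue
        seen.add(s)
        out.append((rid, s, qual))
    return out


def _trim(records: list[tuple[str, str, str]], n: int) -> tuple[list, int]:
    out, dropped = [], 0
    for rid, seq, qual in records:
        if len(seq) <= n:
            dropped += 1
            continue
        out.append((rid, seq[n:], qual[n:]))
    return out, dropped


def preprocess_iclip(
    records: list[tuple[str, str, str]]
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """iCLIP preprocessing: drop reads not starting with the RT-primer GTT,
    collapse exact sequence duplicates, trim the first 7 nt (barcode).

    Returns the surviving (id, seq, qual) records and a step log of counts.
    """
    log = {"input": len(records)}
    gtt = [(r, s, q) for r, s, q in records if s.upper().startswith("GTT")]
    log["after_gtt_filter"] = len(gtt)
    log["dropped_no_gtt"] = log["input"] - len(gtt)
    collapsed = _collapse_exact(gtt)
    log["after_collapse"] = len(collapsed)
    log["dropped_duplicates"] = len(gtt) - len(collapsed)
    trimmed, dropped_short = _trim(collapsed, 7)
    log["after_trim"] = len(trimmed)
    log["dropped_short"] = dropped_short
    return trimmed, log


def preprocess_hitsclip(
    records: list[tuple[str, str, str]]
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """HITS-CLIP preprocessing: collapse exact duplicates, trim 3 nt."""
    log = {"input": len(records)}
    collapsed = _collapse_exact(records)
    log["after_collapse"] = len(collapsed)
    log["dropped_duplicates"] = log["input"] - len(collapsed)
    trimmed, dropped_short = _trim(collapsed, 3)
    log["after_trim"] = len(trimmed)
    log["dropped_short"] = dropped_short
    return trimmed, log


def preprocess_fastq(
    in_path: str | Path, out_path: str | Path, protocol: Literal["iclip", "hitsclip"]
) -> dict[str, int]:
    records = _read_fastq(in_path)
    fn = preprocess_iclip if protocol == "iclip" else preprocess_hitsclip
    out, log = fn(records)
    _write_fastq(out, out_path)
    logger.info("%s preprocessing: %s", protocol, log)
    return log


# ---------------------------------------------------------------------------
# peaks

@dataclass(frozen=True)
class ClipPeak:
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]
    name: str = "."
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty peak [{self.start},{self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """floor((start + end) / 2); for even widths this is the base on
        the chromosomal-right side of the midpoint."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakAnnotation:
    peak: ClipPeak
    transcript_id: str
    gene_id: str
    center_offset: int


@dataclass(frozen=True)
class DensityProfile:
    """TC-anchored metagene density: uniform bins over TC-relative offsets."""

    bin_edges: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if widths.size == 0 or np.ptp(widths) != 0:
            raise ValueError("bin width must be constant")
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")


def read_bed6(path: str | Path, score_as_weight: bool = False) -> list[ClipPeak]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        ClipPeak(
            chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand,
            name=str(r.name),
            weight=float(r.score) if score_as_weight else None,
        )
        for r in df.itertuples()
    ]


def write_bed6(peaks: Iterable[ClipPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = 0 if p.weight is None else p.weight
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score:g}\t{p.strand}\n")


def filter_peaks_by_width(
    peaks: Sequence[ClipPeak], max_width: int = 500
) -> list[ClipPeak]:
    """Keep peaks strictly narrower than ``max_width`` nt."""
    return [p for p in peaks if p.width < max_width]


def annotate_peak_positions(
    peaks: Sequence[ClipPeak],
    ann: GenomeAnnotation,
    mode: Literal["spliced", "genomic"] = "genomic",
) -> tuple[list[PeakAnnotation], dict[str, int]]:
    """Assign each peak to the exemplar transcript whose span contains its
    center on the matching strand, and compute the TC-relative center offset.

    Peaks whose center falls in no exemplar, in more than one exemplar
    (ambiguous), or in an intron (spliced mode) are left unassigned and
    counted in the returned log.
    """
    if not ann.exemplar_of:
        raise ValueError("exemplars not selected")
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in ann.exemplars():
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.span[0], t.span[1], t
        )
    out: list[PeakAnnotation] = []
    log = {"assigned": 0, "unassigned": 0, "ambiguous": 0, "intronic": 0}
    for p in peaks:
        hits = trees.get((p.chrom, p.strand), IntervalTree())[p.center]
        if len(hits) == 0:
            log["unassigned"] += 1
            continue
        if len(hits) > 1:
            log["ambiguous"] += 1
            continue
        t: TranscriptModel = next(iter(hits)).data
        try:
            off = tc_relative_position(t, p.center, mode=mode)
        except ValueError:
            log["intronic"] += 1
            continue
        out.append(PeakAnnotation(p, t.transcript_id, t.gene_id, off))
        log["assigned"] += 1
    return out, log


def tc_density_profile(
    annos: Sequence[PeakAnnotation],
    window: tuple[int, int] = (-200, 600),
    bin_size: int = 20,
    weight_mode: Literal["peaks", "reads"] = "peaks",
    per_transcript_normalize: bool = False,
) -> DensityProfile:
    """Aggregate TC-anchored density of peak centers across all exemplars.

    In ``peaks`` mode each in-window annotation contributes 1; in ``reads``
    mode it contributes its supporting read count.  The optional
    per-transcript normalization divides each annotation's contribution by
    its transcript's total in-window weight before summing.
    """
    a, b = window
    if a % bin_size or b % bin_size:
        raise ValueError("window endpoints must be multiples of the bin size")
    edges = np.arange(a, b + bin_size, bin_size)
    vals = np.zeros(edges.size - 1)
    in_window = [x for x in annos if a <= x.center_offset < b]
    if per_transcript_normalize:
        totals: dict[str, float] = {}
        for x in in_window:
            w = 1.0 if weight_mode == "peaks" or x.peak.weight is None else x.peak.weight
            totals[x.transcript_id] = totals.get(x.transcript_id, 0.0) + w
    for x in in_window:
        w = 1.0 if weight_mode == "peaks" or x.peak.weight is None else x.peak.weight
        if per_transcript_normalize:
            w /= totals[x.transcript_id]
        vals[(x.center_offset - a) // bin_size] += w
    return DensityProfile(bin_edges=edges, values=vals)


def classify_by_peak_interval(
    annos: Sequence[PeakAnnotation],
    ann: GenomeAnnotation,
    intervals: Sequence[tuple[int, int]] = ((0, 200), (200, 500)),
    min_utr3: int = 500,
) -> dict[str, set[str]]:
    """Classify genes by where their peaks center relative to the TC.

    Returns a dict with one (non-exclusive) class per interval, keyed
    ``peak_{a}_{b}``, plus ``no_tc_proximal_peak`` (no peak centered in
    [min(a), max(b))) and ``excluded_short_utr3``.  Genes with 3'UTRs not
    longer than ``min_utr3`` are excluded from the classes to avoid
    length-selection bias.
    """
    lengths = {t.gene_id: t.utr3_length for t in ann.exemplars()}
    eligible = {g for g, L in lengths.items() if L > min_utr3}
    excluded = set(lengths) - eligible
    classes: dict[str, set[str]] = {
        f"peak_{a}_{b}": set() for a, b in intervals
    }
    lo = min(a for a, _ in intervals)
    hi = max(b for _, b in intervals)
    proximal_any: set[str] = set()
    for x in annos:
        if x.gene_id not in eligible:
            continue
        for a, b in intervals:
            if a <= x.center_offset < b:
                classes[f"peak_{a}_{b}"].add(x.gene_id)
        if lo <= x.center_offset < hi:
            proximal_any.add(x.gene_id)
    classes["no_tc_proximal_peak"] = eligible - proximal_any
    classes["excluded_short_utr3"] = excluded
    return classes


def nmd_sensitivity_cdf(
    classes: Mapping[str, set[str]],
    fc_upf1: Mapping[str, float],
    utr3_lengths: Mapping[str, int],
    reference: str = "no_tc_proximal_peak",
    band: tuple[float, float] | None = None,
) -> dict:
    """Compare siUPF1-vs-siNT fold-change ECDFs between gene classes.

    Genes are restricted to an inter-quartile 3'UTR length band (computed
    from the 25th-75th percentiles of the classified genes' lengths unless
    an explicit ``band`` is supplied) to avoid confounding by 3'UTR length.
    Each class is compared to the reference class by a two-tailed K-S test;
    classes with fewer than 3 in-band genes are flagged without a p-value.
    """
    analysis_classes = {
        k: v for k, v in classes.items() if k != "excluded_short_utr3"
    }
    if reference not in analysis_classes:
        raise ValueError(f"reference class {reference!r} missing")
    pool = sorted(set().union(*analysis_classes.values()))
    pool = [g for g in pool if g in fc_upf1 and g in utr3_lengths]
    if band is None:
        lens = np.array([utr3_lengths[g] for g in pool], dtype=float)
        band = (stats.percentile(lens, 0.25), stats.percentile(lens, 0.75))
    lo, hi = band
    in_band = {g for g in pool if lo <= utr3_lengths[g] <= hi}

    def fcs(genes: set[str]) -> np.ndarray:
        return np.sort([fc_upf1[g] for g in sorted(genes & in_band)])

    ref_vals = fcs(analysis_classes[reference])
    out: dict = {"band": (float(lo), float(hi)), "reference": reference}
    for name, genes in analysis_classes.items():
        v = fcs(genes)
        entry: dict = {
            "n": int(v.size),
            "sorted_values": v,
            "ecdf_y": np.arange(1, v.size + 1) / max(v.size, 1),
        }
        if name != reference:
            if v.size < 3 or ref_vals.size < 3:
                entry["ks"] = None
                entry["flag"] = "fewer than 3 in-band genes"
            else:
                entry["ks"] = stats.ks_two_sample(v, ref_vals)
        out[name] = entry
    return out
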