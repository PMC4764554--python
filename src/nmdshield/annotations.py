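"""Transcript models, exemplar selection, and stop-codon-anchored coordinates.

All internal coordinates are 0-based half-open (BED convention); 1-based
dialects are converted on read.  Every positional analysis in the package is
anchored on the termination codon (TC): offset 0 is the first nucleotide 3'
of the stop codon in transcript orientation, positive offsets run into the
3'UTR and negative offsets into the CDS.  Offsets can be measured along the
mature (spliced) transcript or along the chromosome; the spliced mode is the
default for sequence-based analyses, while the genomic mode matches tooling
that operates on chromosomal coordinates (e.g. CLIP peak pipelines).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "GenomeAnnotation",
    "build_transcript",
    "load_annotation",
    "select_exemplars",
    "tc_relative_position",
    "utr3_sequence",
    "write_exemplar_table",
]

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One coding transcript with its TC position and 3'UTR geometry.

    ``cds_end_genomic`` is the genomic coordinate (0-based) of the last base
    of the stop codon in transcript orientation: the highest CDS coordinate
    on '+' transcripts and the lowest on '-' transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    exons: tuple[Interval, ...]
    cds_end_genomic: int
    utr3_intervals: tuple[Interval, ...]
    utr3_length: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.transcript_id}")
            if s < prev_end:
                raise ValueError(f"exons unsorted/overlapping in {self.transcript_id}")
            prev_end = e
        if self.utr3_length != sum(e - s for s, e in self.utr3_intervals):
            raise ValueError("utr3_length inconsistent with utr3_intervals")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class GenomeAnnotation:
    """A collection of coding transcripts, optionally with one exemplar
    transcript (the longest-3'UTR isoform) chosen per gene."""

    transcripts: dict[str, TranscriptModel]
    exemplar_of: dict[str, str] = field(default_factory=dict)
    n_noncoding_skipped: int = 0
    n_bad_cds_skipped: int = 0

    def genes(self) -> list[str]:
        return sorted({t.gene_id for t in self.transcripts.values()})

    def by_gene(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts.values():
            out.setdefault(t.gene_id, []).append(t)
        return out

    def exemplar(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[self.exemplar_of[gene_id]]

    def exemplars(self) -> Iterable[TranscriptModel]:
        for gid in sorted(self.exemplar_of):
            yield self.transcripts[self.exemplar_of[gid]]


def _derive_utr3(
    exons: tuple[Interval, ...], cds_end_genomic: int, strand: str
) -> tuple[Interval, ...]:
    """3'UTR = exonic region strictly 3' of the stop codon's last base."""
    utr: list[Interval] = []
    for s, e in exons:
        if strand == "+":
            lo, hi = max(s, cds_end_genomic + 1), e
        else:
            lo, hi = s, min(e, cds_end_genomic)
        if hi > lo:
            utr.append((lo, hi))
    return tuple(utr)


def build_transcript(
    transcript_id: str,
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Iterable[Interval],
    cds_end_genomic: int,
) -> TranscriptModel:
    """Assemble a TranscriptModel, deriving 3'UTR geometry from the CDS end.

    Raises ValueError if the CDS end does not fall inside an exon.
    """
    ex = tuple(sorted((int(s), int(e)) for s, e in exons))
    if not any(s <= cds_end_genomic < e for s, e in ex):
        raise ValueError(
            f"CDS end {cds_end_genomic} outside exons of {transcript_id}"
        )
    utr = _derive_utr3(ex, cds_end_genomic, strand)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,  # type: ignore[arg-type]
        exons=ex,
        cds_end_genomic=int(cds_end_genomic),
        utr3_intervals=utr,
        utr3_length=sum(e - s for s, e in utr),
    )


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> tuple[dict[str, TranscriptModel], int, int]:
    exons: dict[str, list[Interval]] = {}
    cds: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF record")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            try:
                iv = (int(start) - 1, int(end))  # GTF is 1-based inclusive
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            ad = dict(_GTF_ATTR.findall(attrs))
            tid = ad.get("transcript_id")
            gid = ad.get("gene_id")
            if not tid or not gid:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id")
            meta.setdefault(tid, (gid, chrom, strand))
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:  # CDS or stop_codon both bound the coding span
                cds.setdefault(tid, []).append(iv)
    out: dict[str, TranscriptModel] = {}
    n_noncoding = n_bad = 0
    for tid, (gid, chrom, strand) in meta.items():
        if tid not in cds or tid not in exons:
            n_noncoding += 1
            continue
        spans = cds[tid]
        cds_end = max(e for _s, e in spans) - 1 if strand == "+" else min(
            s for s, _e in spans
        )
        try:
            out[tid] = build_transcript(tid, gid, chrom, strand, exons[tid], cds_end)
        except ValueError as exc:
            logger.warning("skipping %s: %s", tid, exc)
            n_bad += 1
    return out, n_noncoding, n_bad


def _parse_refflat(path: Path) -> tuple[dict[str, TranscriptModel], int, int]:
    """refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    exonCount exonStarts exonEnds (0-based half-open; CDS includes stop)."""
    out: dict[str, TranscriptModel] = {}
    n_noncoding = n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: malformed refFlat record")
            gid, tid, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                cds_start, cds_end_excl = int(fields[6]), int(fields[7])
                starts = [int(x) for x in fields[9].rstrip(",").split(",")]
                ends = [int(x) for x in fields[10].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if cds_start >= cds_end_excl:
                n_noncoding += 1
                continue
            cds_end = cds_end_excl - 1 if strand == "+" else cds_start
            try:
                out[tid] = build_transcript(
                    tid, gid, chrom, strand, zip(starts, ends), cds_end
                )
            except ValueError as exc:
                logger.warning("skipping %s: %s", tid, exc)
                n_bad += 1
    return out, n_noncoding, n_bad


def load_annotation(
    path: str | Path, dialect: Literal["gtf", "refflat"] = "gtf"
) -> GenomeAnnotation:
    """Load coding transcripts from a GTF or refFlat file.

    Non-coding transcripts are excluded and counted; transcripts whose CDS
    end falls outside their exons are skipped with a warning.
    """
    path = Path(path)
    if dialect == "gtf":
        transcripts, n_nc, n_bad = _parse_gtf(path)
    elif dialect == "refflat":
        transcripts, n_nc, n_bad = _parse_refflat(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if n_nc:
        logger.info("%s: excluded %d non-coding transcripts", path, n_nc)
    return GenomeAnnotation(
        transcripts=transcripts, n_noncoding_skipped=n_nc, n_bad_cds_skipped=n_bad
    )


def select_exemplars(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Pick one exemplar transcript per gene: the longest annotated 3'UTR,
    ties broken by lexicographically smallest transcript_id."""
    exemplar_of: dict[str, str] = {}
    for gid, ts in ann.by_gene().items():
        if not ts:
            logger.warning("gene %s has no coding transcript; dropped", gid)
            continue
        best = min(ts, key=lambda t: (-t.utr3_length, t.transcript_id))
        exemplar_of[gid] = best.transcript_id
    ann.exemplar_of = exemplar_of
    return ann


def _spliced_index(t: TranscriptModel, g: int) -> int:
    """Position of genomic base ``g`` along the mature transcript (0 at the
    transcript 5' end).  Raises for intronic or out-of-span coordinates."""
    span = t.span
    if not (span[0] <= g < span[1]):
        raise ValueError(f"{g} outside span of {t.transcript_id}")
    off = 0
    for s, e in t.exons:
        if s <= g < e:
            plus_idx = off + (g - s)
            if t.strand == "+":
                return plus_idx
            total = sum(ee - ss for ss, ee in t.exons)
            return total - 1 - plus_idx
        off += e - s
    raise ValueError(f"{g} is intronic in {t.transcript_id}")


def tc_relative_position(
    t: TranscriptModel, g: int, mode: Literal["spliced", "genomic"] = "spliced"
) -> int:
    """Offset of genomic coordinate ``g`` relative to the termination codon.

    Offset 0 is the first base 3' of the stop codon in transcript
    orientation; positive offsets run downstream into the 3'UTR.  In
    ``spliced`` mode distances are measured along the mature transcript
    (intronic ``g`` raises); in ``genomic`` mode along the chromosome.
    """
    if mode == "genomic":
        span = t.span
        if not (span[0] <= g < span[1]):
            raise ValueError(f"{g} outside span of {t.transcript_id}")
        if t.strand == "+":
            return g - (t.cds_end_genomic + 1)
        return (t.cds_end_genomic - 1) - g
    if mode != "spliced":
        raise ValueError(f"unknown mode {mode!r}")
    return _spliced_index(t, g) - (_spliced_index(t, t.cds_end_genomic) + 1)


def utr3_sequence(t: TranscriptModel, source) -> str:
    """Spliced 3'UTR sequence in transcript orientation, uppercased, U->T.

    ``source`` is a mapping of sequences keyed either by chromosome (genome
    FASTA, e.g. a :class:`pyfaidx.Fasta`) or by transcript id (transcript
    FASTA); genome mode is preferred when both keys resolve.
    """
    keys = source.keys() if hasattr(source, "keys") else source
    if t.chrom in keys:
        pieces = []
        chrom_seq = source[t.chrom]
        for s, e in t.utr3_intervals:
            frag = str(chrom_seq[s:e])
            if len(frag) < e - s:
                raise ValueError(
                    f"{t.chrom} shorter than annotated 3'UTR of {t.transcript_id}"
                )
            pieces.append(frag)
        seq = "".join(pieces)
        if t.strand == "-":
            seq = reverse_complement(seq)
    elif t.transcript_id in keys:
        full = str(source[t.transcript_id])
        if len(full) < t.utr3_length:
            raise ValueError(f"sequence shorter than 3'UTR of {t.transcript_id}")
        seq = full[len(full) - t.utr3_length :] if t.utr3_length else ""
    else:
        raise KeyError(f"no sequence for {t.chrom} or {t.transcript_id}")
    return seq.upper().replace("U", "T")


def write_exemplar_table(ann: GenomeAnnotation, path: str | Path) -> None:
    """TSV of gene_id, transcript_id, utr3_length for the chosen exemplars."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tutr3_length\n")
        for t in ann.exemplars():
            fh.write(f"{t.gene_id}\t{t.transcript_id}\t{t.utr3_length}\n")
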