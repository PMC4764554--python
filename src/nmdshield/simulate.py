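"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator emulates the four-condition knockdown study design on a
synthetic genome: one single-exon coding transcript per gene (so spliced and
genomic TC offsets coincide), 3'UTR lengths drawn log-normally with the
background median at 1308 nt and protected genes' lengths right-shifted by
the 1843/1308 median ratio, negative-binomially dispersed 3'UTR read counts
with planted knockdown/rescue effects, PTBP1 hexamers planted at TC-proximal
offsets in protected genes (background 3'UTRs are rejection-sampled to be
hexamer-free within 400 nt of the TC), CLIP peaks with centers drawn
Normal(+100, 40) nt downstream of the TC on protected genes, and reporter
decay time courses with log-normal multiplicative noise.

Gene labels partition into ``protected`` (down upon PTBP1 knockdown, rescued
by UPF1 co-depletion), ``nmd_target`` (up upon UPF1 knockdown), and
``background``.  A configurable "decoy" subset of non-protected genes
carries hexamers planted at 50-100 nt offsets with no protection effect, so
positional coupling of the motif signal can be probed.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotations import (
    GenomeAnnotation,
    build_transcript,
    reverse_complement,
    select_exemplars,
)
from .clip import ClipPeak, write_bed6
from .expression import CONDITIONS, CountTable
from .motifs import DEFAULT_HEXAMERS

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "simulate_annotation_and_sequences",
    "simulate_counts",
    "simulate_clip_peaks",
    "simulate_decay",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="u1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults encode the emulated regime: 5000 genes, 4% protected with
    2-fold knockdown effects fully rescued in the double knockdown, 10% NMD
    targets with a 2-fold siUPF1 response, NB dispersion 0.05, 3 replicates.
    """

    seed: int = 42
    n_genes: int = 5000
    frac_protected: float = 0.04
    frac_nmd_targets: float = 0.10
    frac_decoy_hexamer: float = 0.05
    effect_ptb: float = 2.0        # protected genes: fold decrease in siPTBP1
    effect_rescue: float = 2.0     # protected genes: fold recovery in double KD
    effect_upf1: float = 2.0       # NMD targets: fold increase upon siUPF1
    nb_dispersion: float = 0.05
    replicates: int = 3
    baseline_log_mean: float = 6.5
    baseline_log_sigma: float = 1.0
    # 3'UTR length regime: median 1308 nt; sigma from the inter-quartile
    # span 484-2251 nt (ln(2251/484) / (2 * 0.6745)); protected shift is
    # ln(1843 / 1308).
    utr3_log_mean: float = math.log(1308.0)
    utr3_log_sigma: float = 1.14
    protected_utr3_log_shift: float = 0.343
    min_utr3: int = 100
    cds_length: int = 300
    spacer: int = 100
    hexamer_offsets: tuple[int, ...] = (10, 30)
    decoy_hexamer_offsets: tuple[int, ...] = (60, 80)
    hexamer_free_window: int = 400
    peak_center_mean: float = 100.0
    peak_center_sd: float = 40.0
    peaks_per_protected_mean: float = 4.0
    background_peak_rate: float = 0.1
    peak_width_range: tuple[int, int] = (30, 120)
    decay_half_lives: tuple[float, ...] = (120.0, 400.0)
    decay_times: tuple[float, ...] = (30.0, 150.0, 270.0, 390.0)
    decay_replicates: int = 3
    noise_sigma_log: float = 0.1

    def __post_init__(self) -> None:
        for name in ("frac_protected", "frac_nmd_targets", "frac_decoy_hexamer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_protected + self.frac_nmd_targets > 1.0:
            raise ValueError("protected and NMD-target fractions exceed 1")
        for name in ("effect_ptb", "effect_rescue", "effect_upf1",
                     "baseline_log_sigma", "utr3_log_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class TruthLabels:
    """Planted ground truth: per-gene labels (a partition), motif offsets,
    CLIP peak centers (TC-relative) and true reporter half-lives."""

    labels: dict[str, str]
    decoy_genes: set[str] = field(default_factory=set)
    motif_offsets: dict[str, tuple[int, ...]] = field(default_factory=dict)
    peak_centers: dict[str, list[int]] = field(default_factory=dict)
    true_half_lives: dict[str, float] = field(default_factory=dict)

    def genes_with(self, label: str) -> set[str]:
        return {g for g, l in self.labels.items() if l == label}


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _hexamer_free_seq(
    rng: np.random.Generator, n: int, pattern: re.Pattern, max_tries: int = 200
) -> str:
    """A random n-mer containing no hexamer from the scan set."""
    for _ in range(max_tries):
        s = _random_seq(rng, n)
        if not pattern.search(s):
            return s
    raise RuntimeError(
        "rejection sampling failed; lower the pyrimidine content or window"
    )


def simulate_annotation_and_sequences(
    cfg: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], TruthLabels]:
    """Build the synthetic genome: annotation (one exemplar transcript per
    gene on alternating strands), chromosome sequence, and truth labels.

    Protected genes' 3'UTR lengths come from a right-shifted log-normal and
    carry planted hexamers at TC-proximal offsets; all other first-400-nt
    3'UTR regions are rejection-sampled hexamer-free; decoy genes then get
    hexamers planted at the 50-100 nt offsets.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    n_prot = int(round(cfg.frac_protected * n))
    n_nmd = int(round(cfg.frac_nmd_targets * n))
    perm = rng.permutation(n)
    prot = {gene_ids[i] for i in perm[:n_prot]}
    nmd = {gene_ids[i] for i in perm[n_prot : n_prot + n_nmd]}
    labels = {
        g: ("protected" if g in prot else "nmd_target" if g in nmd else "background")
        for g in gene_ids
    }
    non_prot = [gene_ids[i] for i in perm[n_prot:]]
    n_decoy = int(round(cfg.frac_decoy_hexamer * n))
    decoys = {
        str(g)
        for g in rng.choice(non_prot, size=min(n_decoy, len(non_prot)), replace=False)
    }

    shift = np.array(
        [cfg.protected_utr3_log_shift if g in prot else 0.0 for g in gene_ids]
    )
    ulens = np.exp(rng.normal(cfg.utr3_log_mean + shift, cfg.utr3_log_sigma))
    ulens = np.maximum(np.round(ulens).astype(int), cfg.min_utr3)

    pattern = re.compile("|".join(DEFAULT_HEXAMERS))
    hexamers = list(DEFAULT_HEXAMERS)
    truth = TruthLabels(labels=labels, decoy_genes=decoys)

    chrom = "chrS"
    pieces: list[str] = []
    cursor = 0
    transcripts = {}
    for i, gid in enumerate(gene_ids):
        ulen = int(ulens[i])
        strand = "+" if i % 2 == 0 else "-"
        cds_seq = "ATG" + _random_seq(rng, cfg.cds_length - 6) + "TAA"
        free = min(cfg.hexamer_free_window, ulen)
        utr = _hexamer_free_seq(rng, free, pattern) + _random_seq(rng, ulen - free)
        offsets: tuple[int, ...] = ()
        if gid in prot:
            offsets = cfg.hexamer_offsets
        elif gid in decoys:
            offsets = cfg.decoy_hexamer_offsets
        if offsets:
            ub = list(utr)
            planted = []
            for j, off in enumerate(offsets):
                if off + 6 <= ulen:
                    ub[off : off + 6] = hexamers[j % len(hexamers)]
                    planted.append(off)
            utr = "".join(ub)
            truth.motif_offsets[gid] = tuple(planted)

        tx_seq = cds_seq + utr
        L = len(tx_seq)
        genomic = tx_seq if strand == "+" else reverse_complement(tx_seq)
        pieces.append(_random_seq(rng, cfg.spacer))
        cursor += cfg.spacer
        start = cursor
        pieces.append(genomic)
        cursor += L
        cds_end = start + cfg.cds_length - 1 if strand == "+" else start + ulen
        tid = f"T{i:05d}.1"
        transcripts[tid] = build_transcript(
            tid, gid, chrom, strand, [(start, start + L)], cds_end
        )

    genome = {chrom: "".join(pieces)}
    ann = select_exemplars(GenomeAnnotation(transcripts=transcripts))
    return ann, genome, truth


def simulate_counts(cfg: SimulationConfig, truth: TruthLabels) -> CountTable:
    """Negative-binomial 3'UTR read counts under the four-condition design.

    Condition multipliers: protected genes are divided by ``effect_ptb`` in
    siPTBP1 and multiplied back by ``effect_rescue`` in the double knockdown
    (defaults restore baseline); NMD targets are multiplied by
    ``effect_upf1`` in siUPF1 and in the double knockdown.  Counts are
    gamma-Poisson with dispersion a (variance m + a*m^2); a=0 is Poisson.
    """
    rng = _rng(cfg, 1)
    genes = sorted(truth.labels)
    n = len(genes)
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, n))

    lab = np.array([truth.labels[g] for g in genes])
    mult = {c: np.ones(n) for c in CONDITIONS}
    is_prot = lab == "protected"
    is_nmd = lab == "nmd_target"
    mult["siPTBP1"][is_prot] = 1.0 / cfg.effect_ptb
    mult["siPTBP1_siUPF1"][is_prot] = cfg.effect_rescue / cfg.effect_ptb
    mult["siUPF1"][is_nmd] = cfg.effect_upf1
    mult["siPTBP1_siUPF1"][is_nmd] *= cfg.effect_upf1

    cols, design_rows = {}, []
    for cond in CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            mean = baseline * mult[cond]
            if cfg.nb_dispersion > 0:
                shape = 1.0 / cfg.nb_dispersion
                lam = rng.gamma(shape, mean * cfg.nb_dispersion)
            else:
                lam = mean
            sample = f"{cond}_{rep}"
            cols[sample] = rng.poisson(lam)
            design_rows.append({"sample": sample, "condition": cond, "replicate": rep})
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountTable(counts=counts, design=design)


def simulate_clip_peaks(
    cfg: SimulationConfig,
    truth: TruthLabels,
    ann: GenomeAnnotation,
    stream: int = 2,
) -> list[ClipPeak]:
    """CLIP peaks: every protected gene gets 1 + Poisson(mean - 1) peaks
    with TC-relative centers drawn Normal(+100, 40) truncated to its 3'UTR;
    background peaks land uniformly on random transcripts.  Widths are
    uniform over ``peak_width_range``; peak weights model supporting reads.

    ``stream`` decouples the random stream so independent peak realizations
    can be drawn over one annotation.
    """
    rng = _rng(cfg, stream)
    peaks: list[ClipPeak] = []
    wlo, whi = cfg.peak_width_range
    exemplars = {t.gene_id: t for t in ann.exemplars()}

    def add_peak(t, g_center: int, weight: float, tag: str) -> None:
        w = int(rng.integers(wlo, whi + 1))
        start = max(0, g_center - w // 2)
        peaks.append(
            ClipPeak(
                chrom=t.chrom, start=start, end=start + w, strand=t.strand,
                name=f"{tag}_{len(peaks)}", weight=weight,
            )
        )

    for gid in sorted(truth.genes_with("protected")):
        t = exemplars[gid]
        k = 1 + rng.poisson(max(cfg.peaks_per_protected_mean - 1.0, 0.0))
        centers = []
        for _ in range(k):
            for _try in range(1000):
                off = rng.normal(cfg.peak_center_mean, cfg.peak_center_sd)
                if 0 <= off < t.utr3_length:
                    break
            off = int(off) if 0 <= off < t.utr3_length else 0
            centers.append(off)
            if t.strand == "+":
                g = t.cds_end_genomic + 1 + off
            else:
                g = t.cds_end_genomic - 1 - off
            add_peak(t, g, float(1 + rng.poisson(15)), "planted")
        truth.peak_centers.setdefault(gid, []).extend(centers)

    n_bg = rng.poisson(cfg.background_peak_rate * cfg.n_genes)
    gids = sorted(exemplars)
    for _ in range(n_bg):
        t = exemplars[gids[int(rng.integers(0, len(gids)))]]
        g = int(rng.integers(t.span[0], t.span[1]))
        add_peak(t, g, float(1 + rng.poisson(5)), "background")
    return peaks


def simulate_decay(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Reporter decay time courses: abundance(t) = 2^(-t / t_half) times
    log-normal noise, sampled at the configured times after transcription
    shutoff.  Returns the long-format table (construct, replicate, time_min,
    exp_band, ctrl_band) and the true half-lives."""
    rng = _rng(cfg, 3)
    rows = []
    truth = {}
    for th in cfg.decay_half_lives:
        construct = f"thalf_{th:g}"
        truth[construct] = float(th)
        for rep in range(1, cfg.decay_replicates + 1):
            for t in cfg.decay_times:
                clean = math.exp(-math.log(2.0) * t / th)
                noise = math.exp(rng.normal(0.0, cfg.noise_sigma_log))
                rows.append(
                    {
                        "construct": construct,
                        "replicate": rep,
                        "time_min": float(t),
                        "exp_band": clean * noise,
                        "ctrl_band": 1.0,
                    }
                )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# dataset writer

def _write_gtf(ann: GenomeAnnotation, cfg: SimulationConfig, path: Path) -> None:
    """GTF in the reader's dialect; CDS features include the stop codon."""
    with open(path, "w") as fh:
        for t in ann.exemplars():
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            if t.strand == "+":
                cs, ce = t.cds_end_genomic - cfg.cds_length + 1, t.cds_end_genomic + 1
            else:
                cs, ce = t.cds_end_genomic, t.cds_end_genomic + cfg.cds_length
            fh.write(f"{t.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t{t.strand}\t.\t{attrs}\n")


def _write_fasta(genome: Mapping[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write the full synthetic dataset (GTF, genome FASTA,
    counts + design TSV, peaks BED, decay TSV, truth TSV, config JSON).
    Returns the map of artifact names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, genome, truth = simulate_annotation_and_sequences(cfg)
    counts = simulate_counts(cfg, truth)
    peaks = simulate_clip_peaks(cfg, truth, ann)
    decay, half_lives = simulate_decay(cfg)
    truth.true_half_lives = half_lives

    paths = {name: str(outdir / fname) for name, fname in [
        ("annotation", "annotation.gtf"), ("genome", "genome.fa"),
        ("counts", "counts.tsv"), ("design", "design.tsv"),
        ("peaks", "peaks.bed"), ("decay", "decay.tsv"),
        ("truth", "truth.tsv"), ("config", "config.json"),
    ]}
    _write_gtf(ann, cfg, Path(paths["annotation"]))
    _write_fasta(genome, Path(paths["genome"]))
    counts.to_tsv(paths["counts"], paths["design"])
    write_bed6(peaks, paths["peaks"])
    decay.to_csv(paths["decay"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tlabel\tdecoy\tmotif_offsets\n")
        for g in sorted(truth.labels):
            offs = ",".join(map(str, truth.motif_offsets.get(g, ())))
            fh.write(f"{g}\t{truth.labels[g]}\t{int(g in truth.decoy_genes)}\t{offs}\n")
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
    return paths
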