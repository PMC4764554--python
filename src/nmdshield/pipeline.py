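"""End-to-end glue: run the full analysis on a dataset directory and produce
the JSON-serializable report the CLI and reproduction script emit."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import clip, expression, kinetics, motifs
from .annotations import GenomeAnnotation, load_annotation, select_exemplars, utr3_sequence
from .expression import CountTable

logger = logging.getLogger(__name__)

__all__ = ["load_dataset_annotation", "classify_dataset", "truth_recovery", "run_report"]


def load_dataset_annotation(path: str | Path, dialect: str = "gtf") -> GenomeAnnotation:
    return select_exemplars(load_annotation(path, dialect=dialect))  # type: ignore[arg-type]


def classify_dataset(
    table: CountTable,
    ann: GenomeAnnotation,
    min_reads: int = 25,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, expression.ProtectionSets]:
    """Normalize, test, and classify the protection sets for one dataset."""
    lengths = {t.gene_id: t.utr3_length for t in ann.exemplars()}
    normalized = expression.normalize_pipeline(table, lengths, min_reads=min_reads)
    diff = expression.differential_anova(normalized, table.design)
    sets = expression.classify_protection_sets(diff, alpha=alpha)
    return diff, sets


def truth_recovery(called: set[str], truth_positive: set[str], universe: set[str]) -> dict:
    """Sensitivity and FDR of a called gene set against planted truth."""
    tp = len(called & truth_positive)
    fp = len(called - truth_positive)
    fn = len((truth_positive & universe) - called)
    return {
        "n_called": len(called),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fdr": fp / (tp + fp) if tp + fp else float("nan"),
    }


def run_report(dataset_dir: str | Path, alpha: float = 0.05, min_reads: int = 25) -> dict:
    """Run classification, motif, CLIP and decay analyses on a simulated (or
    identically laid out) dataset directory; return the summary report."""
    d = Path(dataset_dir)
    ann = load_dataset_annotation(d / "annotation.gtf")
    table = CountTable.from_tsv(d / "counts.tsv", d / "design.tsv")
    diff, sets = classify_dataset(table, ann, min_reads=min_reads, alpha=alpha)

    report: dict = {"n_genes_tested": int(diff.shape[0]), **sets.summary}

    # truth recovery when the directory carries planted labels
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        protected = set(truth.index[truth["label"] == "protected"])
        universe = set(diff.index)
        report["recovery_down"] = truth_recovery(
            set(sets.down_genes), protected, universe
        )
        report["recovery_rescued"] = truth_recovery(
            set(sets.rescued_genes), protected, universe
        )

    # hexamer stratification + rescue correlation over the down set
    genome = Fasta(str(d / "genome.fa"))
    hexset = motifs.HexamerSet()
    strata = {}
    utr_seqs = {}
    for t in ann.exemplars():
        seq = utr3_sequence(t, genome)
        utr_seqs[t.gene_id] = seq
        strata[t.gene_id] = motifs.hexamer_presence(seq, (0, 400), hexset)["present"]
    if len(sets.down_genes) >= 3:
        corr = expression.rescue_correlation(diff, sets.down_genes, strata)
        report["spearman_rho_down"] = corr["overall"].statistic
        for k in ("hexamer_present", "hexamer_absent"):
            report[f"spearman_rho_{k}"] = (
                corr[k].statistic if corr[k].defined else None
            )

    # 3'UTR length CDFs
    lengths = {t.gene_id: t.utr3_length for t in ann.exemplars()}
    expressed = [g for g in diff.index]
    length_sets = {"all_expressed": [lengths[g] for g in expressed]}
    if sets.down_genes:
        length_sets["down"] = [lengths[g] for g in sets.down_genes]
    if sets.rescued_genes:
        length_sets["rescued"] = [lengths[g] for g in sets.rescued_genes]
    cdf = expression.utr_length_cdf(length_sets, reference="all_expressed")
    for name, entry in cdf.items():
        report[f"median_utr3_{name}"] = entry["median"]
        if "ks" in entry:
            report[f"ks_p_utr3_{name}"] = entry["ks"].p_value

    # CLIP positional analysis
    peaks_path = d / "peaks.bed"
    if peaks_path.exists():
        peaks = clip.filter_peaks_by_width(clip.read_bed6(peaks_path, score_as_weight=True))
        annos, assign_log = clip.annotate_peak_positions(peaks, ann, mode="genomic")
        profile = clip.tc_density_profile(annos)
        argmax = int(np.argmax(profile.values))
        report["clip_assignment"] = assign_log
        report["clip_argmax_bin"] = [
            int(profile.bin_edges[argmax]), int(profile.bin_edges[argmax + 1])
        ]
        classes = clip.classify_by_peak_interval(annos, ann)
        fc_upf1 = diff["fc_upf1"].to_dict()
        sens = clip.nmd_sensitivity_cdf(classes, fc_upf1, lengths)
        report["utr3_band"] = list(sens["band"])
        for name in ("peak_0_200", "peak_200_500"):
            ks = sens[name].get("ks")
            report[f"ks_p_fc_upf1_{name}"] = ks.p_value if ks else None

    # decay fits
    decay_path = d / "decay.tsv"
    if decay_path.exists():
        decay = pd.read_csv(decay_path, sep="\t")
        fits = {}
        pts = {}
        for construct, sub in decay.groupby("construct"):
            tcs = [
                kinetics.normalize_timecourse(
                    r["exp_band"].values, r["ctrl_band"].values, r["time_min"].values,
                    construct=construct, replicate=str(rep),
                )
                for rep, r in sub.groupby("replicate")
            ]
            fit = kinetics.fit_exponential_decay(tcs)
            fits[construct] = fit
            pts[construct] = list(
                zip(sub["time_min"], np.log(sub["exp_band"] / sub["ctrl_band"]))
            )
            report[f"t_half_{construct}"] = fit.t_half if fit.resolved else None
        if len(fits) >= 2:
            report["ancova_p_slopes"] = kinetics.compare_slopes_ancova(pts)["p_value"]
    return report
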