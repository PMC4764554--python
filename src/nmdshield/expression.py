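"""Differential expression of 3'UTR-mapped counts across knockdown conditions.

The design is the four-condition knockdown layout siNT / siUPF1 / siPTBP1 /
siPTBP1+siUPF1 with replicates.  Normalization is order-fixed:
RPKM -> upper-quartile scaling -> log2(x + pseudocount).  Per-gene condition
effects are tested by one-way ANOVA across the four conditions; the
"down-regulated" set requires a negative siPTBP1-vs-siNT fold change with
the same sign in every replicate pairing ("reproducibly"), and the
"rescued" subset additionally requires a reproducible positive fold change
of the double knockdown over siPTBP1 alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "CountTable",
    "ProtectionSets",
    "compute_rpkm",
    "upper_quartile_normalize",
    "log2_transform",
    "filter_low_counts",
    "differential_anova",
    "classify_protection_sets",
    "rescue_correlation",
    "utr_length_cdf",
]

CONDITIONS = ("siNT", "siUPF1", "siPTBP1", "siPTBP1_siUPF1")


@dataclass
class CountTable:
    """Gene x sample matrix of 3'UTR-mapped read counts with its design.

    ``counts``: DataFrame (genes x samples, non-negative integers).
    ``design``: DataFrame indexed by sample with columns ``condition`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("count columns and design samples disagree")
        if (self.counts.values < 0).any() or not np.isfinite(
            self.counts.values
        ).all():
            raise ValueError("counts must be finite and non-negative")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def samples_of(self, condition: str) -> list[str]:
        d = self.design[self.design["condition"] == condition]
        return list(d.sort_values("replicate").index)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, design_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(counts=counts, design=design.loc[counts.columns])

    def to_tsv(self, counts_path: str | Path, design_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.design.to_csv(design_path, sep="\t", index_label="sample")


def compute_rpkm(
    table: CountTable,
    lengths: Mapping[str, int],
    libsize: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of 3'UTR per million mapped reads.

    ``libsize`` defaults to the per-sample column sum of 3'UTR-mapped reads;
    an externally supplied total-mapped count may be passed instead.  Genes
    with no annotated length are dropped with a warning.
    """
    counts = table.counts
    have = [g for g in counts.index if g in lengths and lengths[g] > 0]
    missing = len(counts.index) - len(have)
    if missing:
        logger.warning("dropping %d genes lacking a positive 3'UTR length", missing)
    counts = counts.loc[have]
    lens = np.array([lengths[g] for g in have], dtype=float)
    if libsize is None:
        lib = table.counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series({s: float(libsize[s]) for s in counts.columns})
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lens / 1e3, axis=0).div(lib / 1e6, axis=1)


def upper_quartile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample by its 75th percentile of positive values, then
    restore the overall scale with the geometric mean of those percentiles.

    The percentile follows the linear-interpolation convention
    h = (n - 1) * q on the sorted positive values.  Idempotent.
    """
    uq = {}
    for s in m.columns:
        pos = m[s].values[m[s].values > 0]
        if pos.size == 0:
            raise ValueError(f"sample {s} has no positive values")
        uq[s] = stats.percentile(pos, 0.75)
    uq_series = pd.Series(uq)
    scale = float(np.exp(np.mean(np.log(uq_series.values))))
    return m.div(uq_series, axis=1) * scale


def log2_transform(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); the pseudocount keeps zeros finite."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    return np.log2(m + pseudocount)


def filter_low_counts(table: CountTable, min_reads: int = 25) -> CountTable:
    """Remove genes with fewer than ``min_reads`` 3'UTR-mapped reads summed
    across all samples."""
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_reads].index
    if len(keep) == 0:
        logger.warning("all genes fall below the %d-read threshold", min_reads)
    return CountTable(counts=table.counts.loc[keep], design=table.design)


def normalize_pipeline(
    table: CountTable,
    lengths: Mapping[str, int],
    libsize: Mapping[str, float] | None = None,
    min_reads: int = 25,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """The order-fixed pipeline: low-count filter -> RPKM -> upper-quartile
    -> log2.  Returns the normalized log2 table (genes x samples)."""
    filt = filter_low_counts(table, min_reads=min_reads)
    rpkm = compute_rpkm(filt, lengths, libsize=libsize)
    return log2_transform(upper_quartile_normalize(rpkm), pseudocount=pseudocount)


_CONTRASTS = {
    "ptb": ("siPTBP1", "siNT"),
    "rescue": ("siPTBP1_siUPF1", "siPTBP1"),
    "upf1": ("siUPF1", "siNT"),
}


def differential_anova(normalized: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-gene one-way ANOVA across the four conditions plus contrast fold
    changes and per-replicate fold-change sign tallies.

    Returns a DataFrame indexed by gene with columns ``F``, ``p_anova``,
    ``fc_ptb``, ``fc_rescue``, ``fc_upf1``, and for each contrast the number
    of replicate pairings with negative (``*_pairs_neg``) and positive
    (``*_pairs_pos``) differences, plus ``n_pairs``.  Replicates are paired
    by replicate index.
    """
    cols = {c: [s for s in normalized.columns if design.loc[s, "condition"] == c]
            for c in CONDITIONS}
    for c, ss in cols.items():
        if len(ss) < 2:
            raise ValueError(f"condition {c} needs >= 2 replicates for the F test")
        cols[c] = sorted(ss, key=lambda s: design.loc[s, "replicate"])
    mats = {c: normalized[ss].values for c, ss in cols.items()}
    n_pairs = min(len(ss) for ss in cols.values())

    n_genes = normalized.shape[0]
    out = {
        "F": np.empty(n_genes),
        "p_anova": np.empty(n_genes),
    }
    means = {c: mats[c].mean(axis=1) for c in CONDITIONS}
    for name, (a, b) in _CONTRASTS.items():
        out[f"fc_{name}"] = means[a] - means[b]
        diffs = mats[a][:, :n_pairs] - mats[b][:, :n_pairs]
        out[f"{name}_pairs_neg"] = (diffs < 0).sum(axis=1)
        out[f"{name}_pairs_pos"] = (diffs > 0).sum(axis=1)

    # vectorized one-way ANOVA (degenerate rows fixed up afterwards)
    groups = [mats[c] for c in CONDITIONS]
    ns = np.array([g.shape[1] for g in groups], dtype=float)
    N = ns.sum()
    k = len(groups)
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    gmeans = np.stack([g.mean(axis=1) for g in groups], axis=1)
    ssb = (ns[None, :] * (gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    dfb, dfw = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    from scipy.stats import f as f_dist

    p = f_dist.sf(F, dfb, dfw)
    zero_w = ssw == 0
    F = np.where(zero_w & (ssb <= 1e-300), 0.0, F)
    p = np.where(zero_w & (ssb <= 1e-300), 1.0, p)
    F = np.where(zero_w & (ssb > 1e-300), np.inf, F)
    p = np.where(zero_w & (ssb > 1e-300), 0.0, p)
    out["F"], out["p_anova"] = F, p

    df = pd.DataFrame(out, index=normalized.index)
    df["n_pairs"] = n_pairs
    return df


@dataclass
class ProtectionSets:
    """The classified gene sets: down-regulated upon PTBP1 depletion, and
    the rescued subset whose abundance recovers upon UPF1 co-depletion."""

    down_genes: frozenset[str]
    rescued_genes: frozenset[str]
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rescued_genes <= self.down_genes:
            raise ValueError("rescued set must be a subset of the down set")


def classify_protection_sets(diff: pd.DataFrame, alpha: float = 0.05) -> ProtectionSets:
    """Build the down-regulated and rescued gene sets.

    down: fc_ptb < 0, ANOVA p < alpha, and a negative siPTBP1-vs-siNT
    difference in every replicate pairing.  rescued (subset of down):
    fc_rescue > 0 with a positive double-vs-siPTBP1 difference in every
    replicate pairing.
    """
    n = diff["n_pairs"]
    down_mask = (
        (diff["fc_ptb"] < 0)
        & (diff["p_anova"] < alpha)
        & (diff["ptb_pairs_neg"] == n)
    )
    rescued_mask = down_mask & (diff["fc_rescue"] > 0) & (diff["rescue_pairs_pos"] == n)
    down = frozenset(diff.index[down_mask])
    rescued = frozenset(diff.index[rescued_mask])
    summary = {
        "n_down": len(down),
        "n_rescued": len(rescued),
        "mean_fc_ptb_down": float(diff.loc[list(down), "fc_ptb"].mean()) if down else np.nan,
        "mean_fc_rescue_down": float(diff.loc[list(down), "fc_rescue"].mean()) if down else np.nan,
        "mean_fc_upf1_down": float(diff.loc[list(down), "fc_upf1"].mean()) if down else np.nan,
        "alpha": alpha,
    }
    return ProtectionSets(down_genes=down, rescued_genes=rescued, summary=summary)


def rescue_correlation(
    diff: pd.DataFrame,
    down: frozenset[str] | set[str],
    strata: Mapping[str, bool] | None = None,
) -> dict:
    """Spearman correlation of the rescue fold change vs the knockdown fold
    change over the down-regulated genes, overall and within hexamer-present
    / hexamer-absent strata, plus the OLS line for plotting.

    Strata with fewer than 3 genes are flagged with an undefined rho.
    """
    genes = sorted(down)
    if len(genes) < 3:
        raise ValueError("need >= 3 down-regulated genes")
    x = diff.loc[genes, "fc_ptb"].values
    y = diff.loc[genes, "fc_rescue"].values
    out: dict = {"overall": stats.spearman_rho(x, y)}
    slope, intercept = np.polyfit(x, y, 1)
    out["ols"] = {"slope": float(slope), "intercept": float(intercept)}
    if strata is not None:
        for name, flag in (("hexamer_present", True), ("hexamer_absent", False)):
            sub = [g for g in genes if strata.get(g, False) == flag]
            if len(sub) < 3:
                out[name] = stats.TestResult(
                    np.nan, np.nan, (len(sub),), "spearman_rho", defined=False
                )
            else:
                out[name] = stats.spearman_rho(
                    diff.loc[sub, "fc_ptb"].values, diff.loc[sub, "fc_rescue"].values
                )
    return out


def utr_length_cdf(
    sets: Mapping[str, Sequence[float]], reference: str
) -> dict:
    """Per-set ECDFs, medians, and two-tailed K-S p-values vs the reference
    set (typically all expressed exemplar genes)."""
    if reference not in sets:
        raise ValueError(f"reference set {reference!r} missing")
    ref = np.sort(np.asarray(sets[reference], dtype=float))
    if ref.size == 0:
        raise ValueError("reference set is empty")
    out: dict = {}
    for name, vals in sets.items():
        v = np.sort(np.asarray(vals, dtype=float))
        if v.size == 0:
            raise ValueError(f"set {name!r} is empty")
        entry = {
            "sorted_values": v,
            "ecdf_y": np.arange(1, v.size + 1) / v.size,
            "median": float(np.median(v)),
            "n": int(v.size),
        }
        if name != reference:
            entry["ks"] = stats.ks_two_sample(v, ref)
        out[name] = entry
    return out
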