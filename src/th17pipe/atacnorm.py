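"""Null-peak ATAC-seq normalization.

Sequencing-depth differences between ATAC libraries are estimated from
"null" peaks: peaks at transcription start sites of genes that are highly
expressed and near-constant across replicates in every condition. Read
sums within those peaks are assumed to track technical depth only, so
their ratio to the across-sample geometric mean gives a per-sample scale
factor. Replicate agreement is then measured as Pearson correlation of
scale-factor-weighted peak RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountTable, GeneModel, Interval, interval_names, rpkm_table

__all__ = [
    "NullPeakConfig",
    "ScaleFactorSet",
    "select_null_peaks",
    "stable_expressed_genes",
    "compute_scale_factors",
    "scaled_replicate_correlation",
    "apply_threshold_filter",
]


@dataclass(frozen=True)
class NullPeakConfig:
    """Selection thresholds for null peaks.

    expr_threshold : RPKM; per-group mean must exceed this in every group.
    var_threshold  : RPKM^2; per-group replicate variance (ddof=1) must be
                     below this in every group.
    tss_window     : bp each side of the TSS; a peak qualifies when it
                     overlaps [TSS - w, TSS + w + 1) by >= 1 bp.
    """

    expr_threshold: float = 5.0
    var_threshold: float = 0.05
    tss_window: int = 500

    def __post_init__(self) -> None:
        if min(self.expr_threshold, self.var_threshold, self.tss_window) <= 0:
            raise ValueError("all NullPeakConfig fields must be strictly positive")


@dataclass
class ScaleFactorSet:
    """Per-sample depth factors whose geometric mean is 1."""

    factors: dict[str, float]
    null_peak_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()), dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValueError("scale factors must be finite and positive")
        if abs(np.exp(np.mean(np.log(vals))) - 1.0) > 1e-9:
            raise ValueError("geometric mean of scale factors must equal 1")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, name="scale_factor")


def stable_expressed_genes(
    expr_by_group: Mapping[str, pd.DataFrame],
    expr_threshold: float = 5.0,
    var_threshold: float = 0.05,
) -> list[str]:
    """Genes expressed and low-variance in EVERY group.

    ``expr_by_group`` maps group label -> genes x replicate-samples RPKM
    frame. A gene qualifies iff mean > expr_threshold and unbiased variance
    (ddof=1) < var_threshold in every group; comparisons are strict.
    """
    if not expr_by_group:
        raise ValueError("at least one expression group required")
    keep: pd.Series | None = None
    for group, frame in expr_by_group.items():
        if frame.shape[1] < 2:
            raise ValueError(
                f"group {group!r} has {frame.shape[1]} replicate(s); "
                "variance needs >= 2"
            )
        ok = (frame.mean(axis=1) > expr_threshold) & (frame.var(axis=1, ddof=1) < var_threshold)
        keep = ok if keep is None else (keep.reindex(ok.index, fill_value=False) & ok)
    assert keep is not None
    return sorted(keep.index[keep].astype(str))


def select_null_peaks(
    peaks: Sequence[Interval],
    genes: Sequence[GeneModel],
    expr_by_group: Mapping[str, pd.DataFrame],
    cfg: NullPeakConfig = NullPeakConfig(),
) -> list[Interval]:
    """Peaks overlapping a TSS window of any stable, expressed gene.

    The window is [TSS - w, TSS + w + 1): w bp each side of the TSS base.
    Output is sorted by (chrom, start, end).
    """
    stable = set(
        stable_expressed_genes(expr_by_group, cfg.expr_threshold, cfg.var_threshold)
    )
    windows: list[tuple[str, int, int]] = []
    for g in genes:
        if g.gene_id in stable:
            windows.append((g.chrom, max(0, g.tss - cfg.tss_window), g.tss + cfg.tss_window + 1))
    selected = []
    for peak in peaks:
        for chrom, ws, we in windows:
            if peak.chrom == chrom and peak.start < we and ws < peak.end:
                selected.append(peak)
                break
    return sorted(selected, key=lambda p: (p.chrom, p.start, p.end))


def compute_scale_factors(null_counts: CountTable) -> ScaleFactorSet:
    """Per-sample null-peak read sums divided by their geometric mean."""
    if len(null_counts.feature_ids) == 0:
        raise ValueError("no null peaks supplied")
    sums = null_counts.counts.sum(axis=0).astype(float)
    if (sums <= 0).any():
        bad = [s for s, v in zip(null_counts.sample_ids, sums) if v <= 0]
        raise ValueError(
            f"zero null-peak read sum for sample(s) {bad}; supply more null "
            "peaks or add a pseudocount upstream"
        )
    geomean = float(np.exp(np.mean(np.log(sums))))
    factors = {s: float(v / geomean) for s, v in zip(null_counts.sample_ids, sums)}
    return ScaleFactorSet(factors, list(null_counts.feature_ids))


def scaled_replicate_correlation(
    counts: CountTable,
    factors: ScaleFactorSet,
    peak_lengths: Mapping[str, int] | Sequence[int],
    divide_by_factor: bool = True,
) -> pd.DataFrame:
    """Pairwise Pearson r of scale-factor-weighted peak RPKM.

    RPKM per peak is divided by the sample's scale factor (deeper samples
    scaled down); ``divide_by_factor=False`` multiplies instead. Samples
    with zero variance yield NaN against all others.
    """
    missing = [s for s in counts.sample_ids if s not in factors.factors]
    if missing:
        raise ValueError(f"no scale factor for sample(s) {missing}")
    values = rpkm_table(counts, peak_lengths)
    fac = np.array([factors[s] for s in counts.sample_ids], dtype=float)
    normalized = values / fac if divide_by_factor else values * fac
    corr = normalized.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    # zero-variance samples: undefined, keep NaN off-diagonal but NaN diagonal too
    sd = normalized.std(axis=0, ddof=0)
    for s in corr.index[sd == 0]:
        corr.loc[s, :] = np.nan
        corr.loc[:, s] = np.nan
    return corr


def apply_threshold_filter(
    table: pd.DataFrame,
    fc_cutoff: float,
    alpha: float,
    restrict_to: set[str] | None = None,
    fc_column: str = "fold_change",
    sig_column: str = "padj",
    ratio: bool = False,
) -> list[str]:
    """Features passing |fold-change| >= fc_cutoff and significance < alpha.

    With ``ratio=True`` the fold-change column is treated as a ratio, and a
    feature passes when fc >= cutoff or fc <= 1/cutoff (symmetric down-
    regulation). ``restrict_to`` intersects the survivors with a gene set,
    e.g. the reliable-expression (L1) universe.
    """
    for col in (fc_column, sig_column):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    fc = table[fc_column].astype(float)
    if ratio:
        if (fc <= 0).any():
            raise ValueError("ratio fold-changes must be positive")
        pass_fc = (fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff)
    else:
        pass_fc = fc.abs() >= fc_cutoff
    keep = pass_fc & (table[sig_column].astype(float) < alpha)
    survivors = [str(f) for f in table.index[keep]]
    if restrict_to is not None:
        survivors = [f for f in survivors if f in restrict_to]
    return survivors
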