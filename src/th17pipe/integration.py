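"""Reliable-gene filtering and target-set integration.

Builds the reliably-expressed gene universe (L1), restricts RNA-IP and
methylation peak annotations to it, quantifies overlaps between the
methyltransferase-bound, methylated and transcription-factor-bound gene
sets, and provides the supporting analyses: GC enrichment of peaks against
a shuffled genomic background, tertile grouping by promoter ChIP signal,
boxplot-style group comparison with rank-sum tests, metagene profiles and
accessibility-expression strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, Interval, SignalTrack, overlap_genes

logger = logging.getLogger(__name__)

__all__ = [
    "L1Config",
    "TargetSets",
    "TertileGrouping",
    "MetageneProfile",
    "define_l1",
    "build_target_sets",
    "overlap_fractions",
    "gc_content",
    "shuffle_intervals",
    "gc_enrichment",
    "tss_signal",
    "tertile_split",
    "rank_sum_test",
    "compare_group_enrichment",
    "peak_enrichment_per_gene",
    "metagene_profile",
    "expression_accessibility_strata",
]


@dataclass(frozen=True)
class L1Config:
    """Thresholds defining the reliably-expressed gene universe."""

    mrna_mean_threshold: float = 1.0
    input_threshold: float = 1.0
    input_sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mrna_mean_threshold <= 0 or self.input_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if len(self.input_sample_ids) < 1:
            raise ValueError("at least one IP-input sample id required")


@dataclass
class TargetSets:
    """Gene-id sets for the three assays over the reliable universe."""

    nsun2: set[str]
    m5c: set[str]
    rorgt: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.nsun2 <= self.universe or not self.m5c <= self.universe:
            raise ValueError("nsun2 and m5c sets must be subsets of the universe")


@dataclass
class TertileGrouping:
    low: list[str]
    mid: list[str]
    high: list[str]
    signal: dict[str, float] = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, list[str]]:
        return {"low": self.low, "mid": self.mid, "high": self.high}


@dataclass
class MetageneProfile:
    """Mean signal in fixed flank bins and scaled gene-body bins."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int
    flank: int
    flank_bin: int

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def define_l1(
    mrna_expr: pd.DataFrame, input_expr: pd.DataFrame, cfg: L1Config
) -> set[str]:
    """Genes with mean mRNA RPKM above threshold AND above-threshold RPKM in
    every IP-input sample. Comparisons are strict; genes missing from either
    table are excluded with a warning."""
    missing_cols = [s for s in cfg.input_sample_ids if s not in input_expr.columns]
    if missing_cols:
        raise ValueError(f"input samples absent from table: {missing_cols}")
    common = mrna_expr.index.intersection(input_expr.index)
    dropped = len(mrna_expr.index.union(input_expr.index)) - len(common)
    if dropped:
        logger.warning("define_l1: %d gene(s) missing from one table, excluded", dropped)
    mrna_ok = mrna_expr.loc[common].mean(axis=1) > cfg.mrna_mean_threshold
    inputs = input_expr.loc[common, list(cfg.input_sample_ids)]
    input_ok = (inputs > cfg.input_threshold).all(axis=1)
    return set(common[mrna_ok & input_ok].astype(str))


def build_target_sets(
    nsun2_peaks: Sequence[Interval],
    m5c_peaks: Sequence[Interval],
    rorgt_targets: set[str] | Sequence[Interval],
    genes: Sequence[GeneModel],
    l1: set[str],
) -> TargetSets:
    """Annotate peaks to gene bodies and keep only hits within the L1 universe.

    The transcription-factor target set is taken as given (a precomputed gene
    list) or annotated from ChIP peaks; it is NOT restricted to L1.
    """
    if not l1:
        raise ValueError("empty L1 universe")
    nsun2 = set(overlap_genes(nsun2_peaks, genes)) & l1
    m5c = set(overlap_genes(m5c_peaks, genes)) & l1
    if isinstance(rorgt_targets, set):
        rorgt = set(rorgt_targets)
    else:
        rorgt = set(overlap_genes(list(rorgt_targets), genes))
    return TargetSets(nsun2=nsun2, m5c=m5c, rorgt=rorgt, universe=set(l1))


def overlap_fractions(sets: TargetSets) -> dict[str, object]:
    """Overlap fractions and Venn region counts for the three target sets.

    Fractions are percentages; an empty denominator yields None.
    """
    a, b, c = sets.nsun2, sets.m5c, sets.rorgt
    both = a & b

    def frac(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    venn = {
        "nsun2_only": len(a - b - c),
        "m5c_only": len(b - a - c),
        "rorgt_only": len(c - a - b),
        "nsun2_m5c_only": len((a & b) - c),
        "nsun2_rorgt_only": len((a & c) - b),
        "m5c_rorgt_only": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    return {
        "pct_nsun2_with_m5c": frac(len(both), len(a)),
        "pct_rorgt_with_nsun2_m5c": frac(len(c & both), len(c)),
        "venn": venn,
    }


# ---------------------------------------------------------------------------
# GC enrichment vs shuffled background
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Fraction of G/C bases (case-insensitive); N and other bases count in
    the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def shuffle_intervals(
    intervals: Sequence[Interval],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[Interval]:
    """Length-preserving random placement on the genome.

    For each interval a chromosome is drawn with probability proportional to
    its length among chromosomes that can hold the interval, then a start is
    drawn uniformly so the placement is fully in bounds. Placed intervals may
    overlap each other (shuffleBed default behaviour).
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    out = []
    for iv in intervals:
        fits = sizes >= iv.length
        if not fits.any():
            raise ValueError(
                f"interval of length {iv.length} exceeds every chromosome length"
            )
        p = np.where(fits, sizes, 0.0)
        p /= p.sum()
        ci = int(rng.choice(len(chroms), p=p))
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - iv.length + 1))
        out.append(Interval(chroms[ci], start, start + iv.length, iv.name))
    return out


def gc_enrichment(
    peaks: Sequence[Interval],
    genome,
    n_shuffles: int,
    seed: int | np.random.Generator,
) -> dict[str, object]:
    """Observed per-peak GC vs a shuffled-background GC distribution.

    ``genome`` is a mapping chrom -> sequence (a ``pyfaidx.Fasta`` works).
    The background repeats length-preserving uniform placement ``n_shuffles``
    times; observed and background distributions are compared with a
    two-sided rank-sum (Mann-Whitney U) test.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_sizes = {str(c): len(genome[c]) for c in _genome_keys(genome)}
    for iv in peaks:
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"peak {iv.chrom}:{iv.start}-{iv.end} outside genome bounds")
    observed = np.array(
        [gc_content(str(genome[iv.chrom][iv.start : iv.end])) for iv in peaks]
    )
    background_list: list[Interval] = []
    for _ in range(n_shuffles):
        background_list.extend(shuffle_intervals(peaks, chrom_sizes, rng))
    background = np.array(
        [gc_content(str(genome[iv.chrom][iv.start : iv.end])) for iv in background_list]
    )
    u, p = rank_sum_test(observed, background)
    return {
        "observed_gc": observed,
        "background_gc": background,
        "background_intervals": background_list,
        "u_statistic": u,
        "p_value": p,
    }


def _genome_keys(genome) -> list[str]:
    keys = getattr(genome, "keys", None)
    if callable(keys):
        return [str(k) for k in keys()]
    return [str(k) for k in genome]


# ---------------------------------------------------------------------------
# Tertiles, rank-sum comparison, metagene
# ---------------------------------------------------------------------------


def tss_signal(
    genes: Sequence[GeneModel],
    track: SignalTrack,
    window: int = 3000,
    scale_factor: float = 1.0,
) -> dict[str, float]:
    """Mean track value over [TSS - w, TSS + w + 1) per gene, divided by an
    optional per-sample scale factor."""
    out = {}
    for g in genes:
        a = max(0, g.tss - window)
        b = g.tss + window + 1
        out[g.gene_id] = track.mean(g.chrom, a, b) / scale_factor
    return out


def tertile_split(genes: set[str] | Sequence[str], signal: Mapping[str, float]) -> TertileGrouping:
    """Split genes into low/mid/high thirds of the signal.

    Sorted ascending by (signal, gene_id) — the id tie-break makes the split
    deterministic. When the count is not divisible by 3 the extra gene(s) go
    to the highest-signal group(s): remainder 1 -> high, remainder 2 -> mid
    and high.
    """
    ids = sorted(set(genes))
    if len(ids) < 3:
        raise ValueError(f"need >= 3 genes to form tertiles, got {len(ids)}")
    missing = [g for g in ids if g not in signal]
    if missing:
        raise ValueError(f"no signal for gene(s): {missing[:5]}")
    order = sorted(ids, key=lambda g: (signal[g], g))
    n = len(order)
    base, rem = divmod(n, 3)
    n_low = base
    n_mid = base + (1 if rem == 2 else 0)
    return TertileGrouping(
        low=order[:n_low],
        mid=order[n_low : n_low + n_mid],
        high=order[n_low + n_mid :],
        signal={g: float(signal[g]) for g in order},
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small untied samples (both n <= 20), otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 20 and len(y) <= 20
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_group_enrichment(
    grouping: TertileGrouping, enrichment: Mapping[str, float]
) -> dict[str, object]:
    """Boxplot statistics per tertile plus pairwise two-sided rank-sum tests.

    Whisker bounds are Q1 - 1.5*IQR and Q3 + 1.5*IQR (values outside are the
    ones a boxplot would hide).
    """
    groups = grouping.groups
    values: dict[str, np.ndarray] = {}
    summaries: dict[str, dict[str, float]] = {}
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        missing = [g for g in ids if g not in enrichment]
        if missing:
            raise ValueError(f"no enrichment for gene(s): {missing[:5]}")
        v = np.array([enrichment[g] for g in ids], dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        summaries[name] = {
            "n": len(v),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(q1 - 1.5 * iqr),
            "whisker_high": float(q3 + 1.5 * iqr),
        }
        values[name] = v
    tests = {}
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = rank_sum_test(values[a], values[b])
            tests[f"{a}_vs_{b}"] = {"u": u, "p_value": p}
    return {"groups": summaries, "tests": tests}


def peak_enrichment_per_gene(
    gene_peaks: Mapping[str, Sequence[str]],
    ip_rpkm: Mapping[str, float],
    input_rpkm: Mapping[str, float],
    epsilon: float = 0.01,
) -> dict[str, float]:
    """Per-gene IP/input enrichment proxy.

    Enrichment per peak is log2((IP RPKM + eps) / (input RPKM + eps));
    a gene's enrichment is the maximum over its peaks. An externally
    computed per-gene column may be used instead of this proxy.
    """
    out: dict[str, float] = {}
    for gene, peak_names in gene_peaks.items():
        vals = [
            np.log2((ip_rpkm[p] + epsilon) / (input_rpkm[p] + epsilon))
            for p in peak_names
            if p in ip_rpkm and p in input_rpkm
        ]
        if vals:
            out[gene] = float(max(vals))
    return out


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int = 3000,
    flank_bin: int = 50,
    body_bins: int = 100,
) -> MetageneProfile:
    """Mean signal from TSS-flank to TTS+flank, strand-oriented.

    Each gene contributes ``flank // flank_bin`` fixed-width bins upstream of
    the TSS, ``body_bins`` equal-fraction bins across the gene body, and the
    same number of fixed bins downstream of the TTS. Minus-strand genes are
    reversed so that upstream always precedes the TSS in transcription
    direction. Genes shorter than ``body_bins`` bp are skipped with a
    warning; the profile is the unweighted mean across genes.
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    n_flank = flank // flank_bin
    up_acc = np.zeros(n_flank)
    body_acc = np.zeros(body_bins)
    down_acc = np.zeros(n_flank)
    used = 0
    for g in genes:
        if g.length < body_bins:
            logger.warning("metagene: gene %s shorter than %d bp, skipped", g.gene_id, body_bins)
            continue
        left_edges = g.start - flank + flank_bin * np.arange(n_flank + 1)
        body_edges = np.rint(g.start + g.length * np.arange(body_bins + 1) / body_bins).astype(int)
        right_edges = g.end + flank_bin * np.arange(n_flank + 1)
        if left_edges[0] < 0:
            logger.warning("metagene: gene %s flank exits chromosome start, skipped", g.gene_id)
            continue
        left = track.binned_means(g.chrom, left_edges)
        body = track.binned_means(g.chrom, body_edges)
        right = track.binned_means(g.chrom, right_edges)
        if g.strand == "-":
            left, right = right[::-1], left[::-1]
            body = body[::-1]
        up_acc += left
        body_acc += body
        down_acc += right
        used += 1
    if used == 0:
        raise ValueError("no usable genes for metagene profile")
    return MetageneProfile(
        upstream=up_acc / used,
        body=body_acc / used,
        downstream=down_acc / used,
        n_genes=used,
        flank=flank,
        flank_bin=flank_bin,
    )


def expression_accessibility_strata(
    mrna_rpkm: Mapping[str, float] | pd.Series,
    atac_tss_rpkm: Mapping[str, float] | pd.Series,
    h3k4me3_signal: Mapping[str, float] | pd.Series | None = None,
    top_n: int = 15000,
) -> pd.DataFrame:
    """Promoter accessibility and H3K4me3 by expression stratum.

    The ``top_n`` most expressed genes are split low/mid/high by mRNA RPKM
    (same tie and remainder rules as the tertile split); the mean promoter
    ATAC RPKM and mean H3K4me3 enrichment are reported per stratum. Genes
    lacking accessibility values are excluded with a warning.
    """
    mrna = pd.Series(dict(mrna_rpkm)) if not isinstance(mrna_rpkm, pd.Series) else mrna_rpkm
    atac = (
        pd.Series(dict(atac_tss_rpkm))
        if not isinstance(atac_tss_rpkm, pd.Series)
        else atac_tss_rpkm
    )
    if top_n > len(mrna):
        raise ValueError(f"top_n={top_n} exceeds gene count {len(mrna)}")
    top = mrna.sort_values(ascending=False, kind="mergesort").iloc[:top_n]
    have_atac = top.index.intersection(atac.index)
    if len(have_atac) < len(top):
        logger.warning(
            "strata: %d selected gene(s) lack accessibility, excluded",
            len(top) - len(have_atac),
        )
    top = top.loc[have_atac]
    grouping = tertile_split(set(top.index.astype(str)), top.to_dict())
    h3k = (
        pd.Series(dict(h3k4me3_signal))
        if h3k4me3_signal is not None and not isinstance(h3k4me3_signal, pd.Series)
        else h3k4me3_signal
    )
    rows = []
    for name, ids in grouping.groups.items():
        row = {
            "stratum": name,
            "n_genes": len(ids),
            "mean_mrna_rpkm": float(np.mean([top[g] for g in ids])),
            "mean_atac_tss_rpkm": float(np.mean([atac[g] for g in ids])),
        }
        if h3k is not None:
            row["mean_h3k4me3"] = float(np.mean([h3k[g] for g in ids if g in h3k.index]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
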