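"""Synthetic inputs with the statistical structure the analyses assume.

Every generator draws from an independent child stream of one global seed,
so adding or re-running one generator never perturbs another and all
outputs are bit-reproducible. The defaults describe a desk-scale genome
(2 chromosomes x 500 kb, 300 genes, 400 peaks, 2 conditions x 2
replicates) with:

* negative-binomial fragment counts carrying planted per-sample depth
  factors and a block of high, near-constant "housekeeping" genes whose
  TSS peaks are recoverable as null peaks;
* RNA-IP / methylation peak sets planted in designated reliable genes, so
  target-set overlap fractions are known exactly;
* a promoter ChIP signal track whose per-gene amplitude drives IP/input
  enrichment through a configurable slope;
* exponential decay time courses with multiplicative lognormal noise;
* multinomial cell-type compositions with planted disease and rescue
  effects expressed directly as per-type log2 fold-changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CountTable,
    GeneModel,
    Interval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gene_models_gtf,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "make_genome",
    "write_genome_fasta",
    "make_genes_and_peaks",
    "simulate_counts",
    "simulate_expression",
    "simulate_decay",
    "simulate_composition",
    "simulate_study",
    "write_study",
]

# Disease multipliers expressed as intended log2 fold-changes (disease vs
# reference); rescue reverses the listed types. Nine types shift during
# colitis; the stromal/epithelial block drops and the inflammatory block
# expands, with one altered type (cd4_t) deliberately NOT rescued.
_DEFAULT_BASELINE = {
    "enterocyte": 0.15,
    "goblet": 0.09,
    "fibroblast": 0.09,
    "endothelial": 0.05,
    "stromal": 0.05,
    "b_cell": 0.13,
    "plasma": 0.10,
    "pro_b": 0.04,
    "neutrophil": 0.05,
    "monocyte": 0.06,
    "cd4_t": 0.08,
    "cd8_t": 0.06,
    "gd_t": 0.03,
    "ilc1": 0.01,
    "ilc2": 0.01,
}
_DEFAULT_DISEASE_LOG2FC = {
    "enterocyte": -1.3,
    "goblet": -1.2,
    "fibroblast": -1.2,
    "ilc2": -1.4,
    "neutrophil": 1.6,
    "monocyte": 1.4,
    "cd4_t": 1.2,
    "gd_t": 1.3,
    "ilc1": 1.4,
}
_DEFAULT_RESCUED = (
    "enterocyte",
    "goblet",
    "fibroblast",
    "ilc2",
    "neutrophil",
    "monocyte",
    "gd_t",
    "ilc1",
)


@dataclass
class SimulationConfig:
    """Parameters for the full synthetic study."""

    seed: int = 0
    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 500_000
    gc_fraction: float = 0.40
    n_genes: int = 300
    n_peaks: int = 400
    # counts
    depth_factors: dict[str, float] = field(
        default_factory=lambda: {"wt_1": 0.5, "wt_2": 1.0, "ko_1": 2.0, "ko_2": 1.0}
    )
    sample_groups: dict[str, str] = field(
        default_factory=lambda: {"wt_1": "wt", "wt_2": "wt", "ko_1": "ko", "ko_2": "ko"}
    )
    nb_dispersion: float = 0.05
    n_stable_genes: int = 220
    base_reads_per_peak: float = 200.0
    # targeting
    n_l1_extra: int = 40          # reliable genes beyond the stable block
    n_nsun2: int = 90
    n_nsun2_with_m5c: int = 73    # 73/90 = 81.1%
    n_m5c_extra: int = 30         # methylated genes not bound
    n_rorgt: int = 53
    n_rorgt_in_overlap: int = 30  # 30/53 = 56.6%
    enrichment_slope: float = 1.0
    enrichment_noise_sd: float = 0.3
    # decay
    decay_half_lives: dict[str, float] = field(
        default_factory=lambda: {"wt": 60.0, "ko": 30.0}
    )
    decay_timepoints: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0)
    decay_replicates: int = 3
    noise_cv: float = 0.05
    # composition
    n_cells_per_group: int = 10_000
    baseline_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE)
    )
    disease_log2fc: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DISEASE_LOG2FC)
    )
    rescued_types: tuple[str, ...] = _DEFAULT_RESCUED

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")
        for name in ("n_chrom", "chrom_length", "n_genes", "n_peaks", "n_cells_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        total = sum(self.baseline_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"baseline frequencies must sum to 1, got {total}")
        if any(v <= 0 for v in self.depth_factors.values()):
            raise ValueError("depth factors must be positive")

    def streams(self) -> dict[str, np.random.Generator]:
        """Independent named RNG streams derived from the global seed."""
        names = ["genome", "annotation", "counts", "enrichment", "decay", "composition"]
        seq = np.random.SeedSequence(self.seed)
        children = seq.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Genome & annotation
# ---------------------------------------------------------------------------


def make_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """I.i.d. bases at the configured GC fraction, one string per chromosome."""
    rng = rng if rng is not None else cfg.streams()["genome"]
    gc = cfg.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome = {}
    for i in range(cfg.n_chrom):
        bases = rng.choice(np.array(list("AGCT")), size=cfg.chrom_length, p=probs)
        genome[f"chr{i + 1}"] = "".join(bases)
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SimulatedAnnotation:
    genes: list[GeneModel]
    atac_peaks: list[Interval]
    nsun2_peaks: list[Interval]
    m5c_peaks: list[Interval]
    stable_genes: list[str]
    l1_genes: list[str]
    nsun2_targets: set[str]
    m5c_targets: set[str]
    rorgt_targets: set[str]


def make_genes_and_peaks(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedAnnotation:
    """Place non-overlapping gene bodies, TSS-spanning ATAC peaks, and
    IP/methylation peaks inside the designated target genes.

    Genes occupy evenly spaced slots (both strands); the first
    ``n_stable_genes`` are the housekeeping block, the next ``n_l1_extra``
    complete the reliable (L1) universe, and the remainder are
    low-expression genes that fail the reliability filter.
    """
    rng = rng if rng is not None else cfg.streams()["annotation"]
    slot = cfg.n_chrom * cfg.chrom_length // cfg.n_genes
    if slot < 1500:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes into {cfg.n_chrom}x{cfg.chrom_length} bp"
        )
    per_chrom = cfg.n_genes // cfg.n_chrom + (cfg.n_genes % cfg.n_chrom > 0)
    genes: list[GeneModel] = []
    for gi in range(cfg.n_genes):
        chrom = f"chr{gi // per_chrom + 1}"
        offset = (gi % per_chrom) * slot
        length = int(rng.integers(800, min(2500, slot - 400)))
        start = offset + int(rng.integers(100, slot - length - 100))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{gi:04d}", chrom, start, start + length, strand))

    ids = [g.gene_id for g in genes]
    stable = ids[: cfg.n_stable_genes]
    l1 = ids[: cfg.n_stable_genes + cfg.n_l1_extra]
    by_id = {g.gene_id: g for g in genes}

    # ATAC peaks: one spanning each stable-gene TSS, the rest at random TSSs
    atac: list[Interval] = []
    for i, gid in enumerate(stable):
        g = by_id[gid]
        half = int(rng.integers(150, 400))
        atac.append(
            Interval(g.chrom, max(0, g.tss - half), g.tss + half, f"atac_peak_{i:04d}")
        )
    extra = cfg.n_peaks - len(atac)
    others = ids[cfg.n_stable_genes :]
    chosen = rng.choice(len(others), size=min(extra, len(others)), replace=False)
    for j, oi in enumerate(sorted(chosen)):
        g = by_id[others[oi]]
        half = int(rng.integers(150, 400))
        atac.append(
            Interval(
                g.chrom,
                max(0, g.tss - half),
                g.tss + half,
                f"atac_peak_{len(stable) + j:04d}",
            )
        )
    # remaining peaks land anywhere on the genome (intergenic background)
    while len(atac) < cfg.n_peaks:
        chrom = f"chr{int(rng.integers(1, cfg.n_chrom + 1))}"
        width = int(rng.integers(300, 800))
        start = int(rng.integers(0, cfg.chrom_length - width))
        atac.append(Interval(chrom, start, start + width, f"atac_peak_{len(atac):04d}"))

    # target sets drawn inside L1 (binding/methylation), plus TF targets
    l1_arr = list(l1)
    perm = rng.permutation(len(l1_arr))
    nsun2_set = [l1_arr[i] for i in perm[: cfg.n_nsun2]]
    with_m5c = nsun2_set[: cfg.n_nsun2_with_m5c]
    non_nsun2 = [l1_arr[i] for i in perm[cfg.n_nsun2 :]]
    m5c_set = with_m5c + non_nsun2[: cfg.n_m5c_extra]
    overlap = with_m5c
    rorgt_in = list(rng.choice(overlap, size=cfg.n_rorgt_in_overlap, replace=False))
    pool = [g for g in ids if g not in set(overlap)]
    rorgt_out = list(
        rng.choice(pool, size=cfg.n_rorgt - cfg.n_rorgt_in_overlap, replace=False)
    )
    rorgt_set = set(rorgt_in + rorgt_out)

    def body_peaks(targets: Sequence[str], prefix: str) -> list[Interval]:
        out = []
        for i, gid in enumerate(targets):
            g = by_id[gid]
            width = int(rng.integers(100, min(400, g.length)))
            start = g.start + int(rng.integers(0, g.length - width + 1))
            out.append(Interval(g.chrom, start, start + width, f"{prefix}_{i:04d}"))
        return out

    return SimulatedAnnotation(
        genes=genes,
        atac_peaks=atac,
        nsun2_peaks=body_peaks(nsun2_set, "nsun2_peak"),
        m5c_peaks=body_peaks(m5c_set, "m5c_peak"),
        stable_genes=stable,
        l1_genes=l1,
        nsun2_targets=set(nsun2_set),
        m5c_targets=set(m5c_set),
        rorgt_targets=rorgt_set,
    )


# ---------------------------------------------------------------------------
# Counts & expression
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson).

    Dispersion 0 degenerates to the rounded means (noise-free planting).
    """
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_counts(
    cfg: SimulationConfig,
    feature_ids: Sequence[str],
    base_means: Sequence[float],
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Feature x sample counts: mean = base mean x planted depth factor,
    negative-binomial dispersion as configured."""
    rng = rng if rng is not None else cfg.streams()["counts"]
    base = np.asarray(base_means, dtype=float)
    if len(base) != len(feature_ids):
        raise ValueError("base_means must align with feature_ids")
    samples = list(cfg.depth_factors)
    counts = np.empty((len(feature_ids), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        counts[:, j] = _nb_draw(rng, base * cfg.depth_factors[s], cfg.nb_dispersion)
    return CountTable(list(feature_ids), samples, counts)


def simulate_expression(
    cfg: SimulationConfig,
    ann: SimulatedAnnotation,
    rng: np.random.Generator | None = None,
) -> dict[str, object]:
    """Per-gene RPKM tables: mRNA per group, IP-input samples, and the
    per-gene promoter ChIP amplitude with linked IP enrichment.

    Stable genes sit near RPKM 20 with tiny replicate scatter (they pass
    the null-peak rule); other reliable genes are drawn between 2 and 50;
    the rest sit near 0.1 and fail every threshold.
    """
    rng = rng if rng is not None else cfg.streams()["enrichment"]
    ids = [g.gene_id for g in ann.genes]
    n = len(ids)
    stable_ix = np.arange(len(ann.stable_genes))
    l1_ix = np.arange(len(ann.l1_genes))
    base = np.full(n, 0.1)
    base[l1_ix] = rng.uniform(3.0, 50.0, size=len(l1_ix))
    base[stable_ix] = 20.0

    groups = sorted(set(cfg.sample_groups.values()))
    mrna = {}
    for grp in groups:
        reps = [s for s, g in cfg.sample_groups.items() if g == grp]
        cols = {}
        for s in reps:
            noise = rng.lognormal(0.0, 0.15, size=n)
            vals = base * noise
            vals[stable_ix] = base[stable_ix] + rng.normal(0.0, 0.1, size=len(stable_ix))
            cols[s] = np.maximum(vals, 0.0)
        mrna[grp] = pd.DataFrame(cols, index=ids)

    input_samples = ["nsun2_input_1", "nsun2_input_2", "m5c_input_1", "m5c_input_2"]
    input_expr = pd.DataFrame(
        {s: base * rng.lognormal(0.0, 0.1, size=n) for s in input_samples}, index=ids
    )

    # promoter ChIP amplitude and the linked per-gene IP enrichment
    chip = rng.lognormal(1.0, 0.8, size=n)
    enrich = {}
    for gid, amp in zip(ids, chip):
        if gid in ann.nsun2_targets or gid in ann.m5c_targets:
            enrich[gid] = float(
                cfg.enrichment_slope * np.log2(1.0 + amp)
                + rng.normal(0.0, cfg.enrichment_noise_sd)
            )
    return {
        "base_rpkm": pd.Series(base, index=ids),
        "mrna_by_group": mrna,
        "input_expr": input_expr,
        "chip_amplitude": pd.Series(chip, index=ids),
        "enrichment": enrich,
    }


def make_chip_track(ann: SimulatedAnnotation, chip_amplitude: pd.Series) -> SignalTrack:
    """Step track holding each gene's promoter ChIP amplitude over its body
    and immediate TSS flank, clipped to the gene's slot so runs never
    overlap."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        rr = []
        prev_end = 0
        for i, g in enumerate(gs):
            nxt = gs[i + 1].start if i + 1 < len(gs) else g.end + 10_000
            a = max(prev_end, g.start - 500)
            b = min(nxt, g.end + 500)
            if b > a:
                rr.append((a, b, float(chip_amplitude[g.gene_id])))
                prev_end = b
        runs[chrom] = rr
    return SignalTrack(runs)


# ---------------------------------------------------------------------------
# Decay & composition
# ---------------------------------------------------------------------------


def simulate_decay(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Time-course table: abundance(t) = 2^(-t / t_half) x lognormal noise.

    One series per condition and replicate; t = 0 rows are pre-normalization
    raw quantities (drawn around 1) so the t0-normalization step is
    exercised downstream.
    """
    rng = rng if rng is not None else cfg.streams()["decay"]
    sigma = np.sqrt(np.log(1.0 + cfg.noise_cv**2))
    rows = []
    for condition, t_half in cfg.decay_half_lives.items():
        if t_half <= 0:
            raise ValueError("half-lives must be positive")
        for rep in range(1, cfg.decay_replicates + 1):
            scale = rng.lognormal(0.0, sigma) if cfg.noise_cv > 0 else 1.0
            for t in cfg.decay_timepoints:
                noise = rng.lognormal(0.0, sigma) if cfg.noise_cv > 0 else 1.0
                value = scale * 2.0 ** (-t / t_half) * noise
                rows.append(
                    {
                        "series_id": f"{condition}_rep{rep}",
                        "condition": condition,
                        "replicate": rep,
                        "time_min": t,
                        "rel_abundance": value,
                    }
                )
    return pd.DataFrame(rows)


def composition_group_frequencies(cfg: SimulationConfig) -> pd.DataFrame:
    """Expected frequencies for reference / disease / treated groups.

    Disease applies the per-type log2 fold-changes and renormalizes; the
    treated group reverses the effect for rescued types and keeps the
    disease level elsewhere.
    """
    types = list(cfg.baseline_frequencies)
    f = np.array([cfg.baseline_frequencies[t] for t in types])
    d = np.array([2.0 ** cfg.disease_log2fc.get(t, 0.0) for t in types])
    disease = f * d
    disease /= disease.sum()
    rescue_mult = np.array(
        [
            2.0 ** (-cfg.disease_log2fc.get(t, 0.0)) if t in cfg.rescued_types else 1.0
            for t in types
        ]
    )
    treated = disease * rescue_mult
    treated /= treated.sum()
    return pd.DataFrame(
        [f, disease, treated],
        index=["reference", "disease", "treated"],
        columns=types,
    )


def simulate_composition(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-cell table (cell_id, cell_type, group, QC and receptor columns)
    from multinomial draws at the planted group frequencies.

    Rescued cell types express the IL-17 receptor Il17ra in roughly half of
    their cells; other types only sporadically.
    """
    rng = rng if rng is not None else cfg.streams()["composition"]
    freqs = composition_group_frequencies(cfg)
    types = list(freqs.columns)
    frames = []
    for group in freqs.index:
        counts = rng.multinomial(cfg.n_cells_per_group, freqs.loc[group].to_numpy())
        n = int(counts.sum())
        cell_type = np.repeat(types, counts)
        receptor_frac = np.repeat(
            [0.5 if t in cfg.rescued_types else 0.02 for t in types], counts
        )
        expressed = rng.random(n) < receptor_frac
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{group}_cell_{i:06d}" for i in range(n)],
                    "cell_type": cell_type,
                    "group": group,
                    "n_genes": rng.integers(300, 6000, size=n),
                    "mito_frac": rng.uniform(0.0, 0.3, size=n),
                    "Il17ra": expressed * rng.lognormal(0.0, 0.5, size=n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: SimulatedAnnotation
    expression: dict[str, object]
    peak_counts: CountTable
    chip_track: SignalTrack
    decay_table: pd.DataFrame
    cell_table: pd.DataFrame
    truth: dict[str, object]


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate every input of the pipeline plus a ``truth`` record of all
    planted parameters."""
    streams = cfg.streams()
    genome = make_genome(cfg, streams["genome"])
    ann = make_genes_and_peaks(cfg, streams["annotation"])
    expr = simulate_expression(cfg, ann, streams["enrichment"])

    # peak count means follow the stable-gene construction: constant base
    # reads for stable TSS peaks, lognormal spread elsewhere
    rng_counts = streams["counts"]
    n_peaks = len(ann.atac_peaks)
    base_reads = np.full(n_peaks, cfg.base_reads_per_peak)
    n_stable = len(ann.stable_genes)
    base_reads[n_stable:] = cfg.base_reads_per_peak * rng_counts.lognormal(
        0.0, 0.5, size=n_peaks - n_stable
    )
    peak_ids = [p.name for p in ann.atac_peaks]
    peak_counts = simulate_counts(cfg, peak_ids, base_reads, rng_counts)

    chip_track = make_chip_track(ann, expr["chip_amplitude"])
    decay_table = simulate_decay(cfg, streams["decay"])
    cell_table = simulate_composition(cfg, streams["composition"])

    overlap = ann.nsun2_targets & ann.m5c_targets
    truth = {
        "seed": cfg.seed,
        "depth_factors": dict(cfg.depth_factors),
        "stable_genes": list(ann.stable_genes),
        "l1_genes": list(ann.l1_genes),
        "nsun2_targets": sorted(ann.nsun2_targets),
        "m5c_targets": sorted(ann.m5c_targets),
        "rorgt_targets": sorted(ann.rorgt_targets),
        "pct_nsun2_with_m5c": 100.0 * len(overlap) / len(ann.nsun2_targets),
        "pct_rorgt_with_nsun2_m5c": 100.0
        * len(ann.rorgt_targets & overlap)
        / len(ann.rorgt_targets),
        "half_lives": dict(cfg.decay_half_lives),
        "group_frequencies": composition_group_frequencies(cfg).to_dict(),
        "altered_types": sorted(cfg.disease_log2fc),
        "rescued_types": sorted(cfg.rescued_types),
        "gc_fraction": cfg.gc_fraction,
    }
    return SimulatedStudy(
        config=cfg,
        genome=genome,
        annotation=ann,
        expression=expr,
        peak_counts=peak_counts,
        chip_track=chip_track,
        decay_table=decay_table,
        cell_table=cell_table,
        truth=truth,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input in its standard text format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = out / "genome.fa"
    write_genome_fasta(study.genome, paths["genome"])
    paths["genes"] = out / "genes.gtf"
    write_gene_models_gtf(study.annotation.genes, paths["genes"])
    for key in ("atac_peaks", "nsun2_peaks", "m5c_peaks"):
        paths[key] = out / f"{key}.bed"
        write_bed(getattr(study.annotation, key), paths[key])
    paths["rorgt_targets"] = out / "rorgt_targets.txt"
    paths["rorgt_targets"].write_text(
        "".join(f"{g}\n" for g in sorted(study.annotation.rorgt_targets))
    )

    paths["peak_counts"] = out / "peak_counts.tsv"
    study.peak_counts.to_frame().to_csv(paths["peak_counts"], sep="\t")
    expr = study.expression
    for grp, frame in expr["mrna_by_group"].items():
        paths[f"mrna_{grp}"] = out / f"mrna_rpkm_{grp}.tsv"
        frame.to_csv(paths[f"mrna_{grp}"], sep="\t")
    paths["input_expr"] = out / "input_rpkm.tsv"
    expr["input_expr"].to_csv(paths["input_expr"], sep="\t")

    paths["chip_track"] = out / "rorgt_signal.bedgraph"
    write_bedgraph(study.chip_track, paths["chip_track"])
    paths["decay"] = out / "decay_timecourse.tsv"
    study.decay_table.to_csv(paths["decay"], sep="\t", index=False)
    paths["cells"] = out / "cells.tsv"
    study.cell_table.to_csv(paths["cells"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
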