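"""Shared genomic domain types, format I/O, interval arithmetic and RPKM.

All coordinates are held 0-based half-open internally. GTF input (1-based,
closed) is converted on read and back on write; BED passes through unchanged.
Overlap semantics everywhere are ``>= 1 bp``, matching ``bedtools intersect``
defaults.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Interval",
    "CountTable",
    "SignalTrack",
    "read_gene_models",
    "write_gene_models_gtf",
    "write_gene_models_bed12",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "read_count_table",
    "read_expression_table",
    "count_in_intervals",
    "rpkm",
    "rpkm_table",
    "overlap_genes",
    "select_top_transcripts",
]


class FormatError(ValueError):
    """A line of a standard-format file failed to parse."""


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware endpoints (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site: last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """A genomic interval (peak), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CountTable:
    """Non-negative feature x sample counts with per-sample library sizes.

    ``library_size`` defaults to the column sums; an externally computed
    total (e.g. uniquely mapped reads per sample) may be supplied instead,
    in which case it must be at least the column sum.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        if self.library_size is None:
            self.library_size = colsum.astype(np.int64)
        else:
            self.library_size = np.asarray(self.library_size, dtype=np.int64)
            if self.library_size.shape != (len(self.sample_ids),):
                raise ValueError("library_size must have one entry per sample")
            if (self.library_size <= 0).any():
                raise ValueError("library sizes must be positive")
            if (self.library_size < colsum).any():
                raise ValueError("library_size below in-feature column sum")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def restrict(self, feature_ids: Sequence[str]) -> "CountTable":
        """Subset to the given features, keeping library sizes."""
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return CountTable(
            list(feature_ids), list(self.sample_ids), self.counts[rows], self.library_size.copy()
        )


class SignalTrack:
    """Per-chromosome run-length signal (bedGraph semantics).

    Runs are sorted and non-overlapping within each chromosome; regions not
    covered by any run have value 0. Mean queries over arbitrary intervals
    are exact (length-weighted), which keeps metagene binning linear in the
    track values.
    """

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, rr in runs.items():
            if len(rr) == 0:
                continue
            arr = np.asarray(sorted(rr), dtype=float)
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"{chrom}: overlapping runs")
            if (ends <= starts).any():
                raise ValueError(f"{chrom}: empty run")
            # cumulative integral of signal up to each run start, for O(log n) queries
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            self._runs[chrom] = (starts.astype(np.int64), ends.astype(np.int64), values)
            self._cum[chrom] = cum

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end)."""
        if end <= start:
            return 0.0
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        cum = self._cum[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        total = cum[hi] - cum[lo]
        # trim partial overlap at both edges
        total -= max(0, start - starts[lo]) * values[lo]
        total -= max(0, ends[hi - 1] - end) * values[hi - 1]
        return float(total)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValueError("empty query interval")
        return self.integral(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal within each [edges[i], edges[i+1]) bin."""
        edges = np.asarray(edges)
        return np.array(
            [self.mean(chrom, int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        )

    def __add__(self, other: "SignalTrack") -> "SignalTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        for chrom in set(self.chroms) | set(other.chroms):
            cuts = sorted(
                set(
                    int(x)
                    for track in (self, other)
                    if chrom in track._runs
                    for arr in track._runs[chrom][:2]
                    for x in arr
                )
            )
            merged = []
            for a, b in zip(cuts[:-1], cuts[1:]):
                v = self.mean(chrom, a, b) + other.mean(chrom, a, b)
                if v != 0.0:
                    merged.append((a, b, v))
            runs[chrom] = merged
        return SignalTrack(runs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a GTF (1-based closed) or BED12/BED6 (0-based) file.

    The dialect is chosen by the ``fmt`` flag (``"gtf"`` or ``"bed"``) or, when
    omitted, by file extension. Coordinates are converted to 0-based half-open;
    duplicate gene ids are rejected.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".gtf", ".gff"):
            fmt = "gtf"
        elif suffix.startswith(".bed"):
            fmt = "bed"
        else:
            raise ValueError(f"cannot infer format from extension {suffix!r}; pass fmt=")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
                    if feature not in ("gene", "transcript"):
                        continue
                    m = _GTF_ATTR_RE.search(attrs)
                    if m is None:
                        raise ValueError("missing gene_id attribute")
                    model = GeneModel(m.group(1), chrom, int(start) - 1, int(end), strand)
                else:
                    if len(fields) < 6:
                        raise ValueError("expected >= 6 BED fields (need name and strand)")
                    chrom, start, end, name, _, strand = fields[:6]
                    model = GeneModel(name, chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if model.gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {model.gene_id!r}")
            seen.add(model.gene_id)
            genes.append(model)
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tth17pipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t1\t{g.length},\t0,\n"
            )


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ intervals; name/score kept when present."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                name = f[3] if len(f) > 3 else None
                score = float(f[4]) if len(f) > 4 and f[4] != "." else None
                out.append(Interval(f[0], int(f[1]), int(f[2]), name, score))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        runs[str(chrom)] = list(
            zip(sub["start"].astype(int), sub["end"].astype(int), sub["value"].astype(float))
        )
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_count_table(path: str | Path, library_size: Mapping[str, int] | None = None) -> CountTable:
    """Read a TSV count table (first column feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ls = None
    if library_size is not None:
        ls = np.array([library_size[s] for s in df.columns])
    return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(), ls)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-gene, per-sample RPKM values (genes x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all() or (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression values must be finite and >= 0")
    return df


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def _intervals_to_pyranges(intervals: Sequence[Interval], names: Sequence[str]) -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in intervals],
                "Start": [iv.start for iv in intervals],
                "End": [iv.end for iv in intervals],
                "Name": list(names),
            }
        )
    )


def interval_names(intervals: Sequence[Interval]) -> list[str]:
    """Stable per-interval identifiers: the name field or a positional fallback."""
    return [
        iv.name if iv.name is not None else f"interval_{i}" for i, iv in enumerate(intervals)
    ]


def count_in_intervals(
    placements: Mapping[str, Sequence[Interval]] | Mapping[str, str | Path],
    intervals: Sequence[Interval],
) -> CountTable:
    """Count read/fragment placements overlapping each interval, per sample.

    ``placements`` maps sample id to either a list of fragment Intervals or a
    BED path. A fragment overlapping k intervals contributes to each of the k;
    overlap of >= 1 bp counts. Library size is the total number of placements
    in the sample.
    """
    names = interval_names(intervals)
    target = _intervals_to_pyranges(intervals, names)
    sample_ids = list(placements)
    counts = np.zeros((len(intervals), len(sample_ids)), dtype=np.int64)
    library = np.zeros(len(sample_ids), dtype=np.int64)
    order = {n: i for i, n in enumerate(names)}
    interval_chroms = {iv.chrom for iv in intervals}
    for j, sample in enumerate(sample_ids):
        frags = placements[sample]
        if isinstance(frags, (str, Path)):
            frags = read_bed(frags)
        library[j] = len(frags)
        missing = {f.chrom for f in frags} - interval_chroms
        if missing:
            logger.warning(
                "sample %s: %d chromosome(s) absent from intervals: %s",
                sample,
                len(missing),
                ", ".join(sorted(missing)),
            )
        if not frags:
            continue
        frag_pr = _intervals_to_pyranges(frags, [str(i) for i in range(len(frags))])
        joined = target.join(frag_pr).df
        if len(joined):
            hits = joined["Name"].map(order).value_counts()
            counts[hits.index.to_numpy(), j] = hits.to_numpy()
    return CountTable(names, sample_ids, counts, np.maximum(library, 1))


def rpkm(count: float, feature_length: int, library_size: int) -> float:
    """Reads per kilobase of feature per million library reads."""
    if feature_length <= 0:
        raise ValueError(f"feature_length must be positive, got {feature_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be positive, got {library_size}")
    return count / (feature_length / 1_000) / (library_size / 1_000_000)


def rpkm_table(table: CountTable, feature_lengths: Mapping[str, int] | Sequence[int]) -> pd.DataFrame:
    """RPKM-normalize a CountTable; returns a genes x samples DataFrame."""
    if isinstance(feature_lengths, Mapping):
        lengths = np.array([feature_lengths[f] for f in table.feature_ids], dtype=float)
    else:
        lengths = np.asarray(feature_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    values = (
        table.counts / (lengths[:, None] / 1_000) / (table.library_size[None, :] / 1_000_000)
    )
    return pd.DataFrame(values, index=table.feature_ids, columns=table.sample_ids)


def overlap_genes(
    peaks: Sequence[Interval], genes: Sequence[GeneModel]
) -> dict[str, list[str]]:
    """Map gene_id -> sorted names of peaks overlapping the gene body by >= 1 bp."""
    if not peaks or not genes:
        return {}
    peak_names = interval_names(peaks)
    peak_pr = _intervals_to_pyranges(peaks, peak_names)
    gene_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [g.chrom for g in genes],
                "Start": [g.start for g in genes],
                "End": [g.end for g in genes],
                "Name": [g.gene_id for g in genes],
            }
        )
    )
    joined = gene_pr.join(peak_pr).df
    out: dict[str, list[str]] = {}
    if len(joined):
        for gene_id, sub in joined.groupby("Name", sort=False):
            out[str(gene_id)] = sorted(sub["Name_b"].astype(str))
    return out


def select_top_transcripts(
    transcript_gene: Mapping[str, str], expression: pd.DataFrame
) -> dict[str, str]:
    """Pick the most abundant transcript per gene.

    ``expression`` is transcripts x samples; abundance is the mean across
    samples, ties broken by transcript id for determinism.
    """
    mean_expr = expression.mean(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for tx, gene in transcript_gene.items():
        if tx not in mean_expr.index:
            continue
        key = (-float(mean_expr[tx]), tx)
        if gene not in best or key < best[gene]:
            best[gene] = key
    return {gene: tx for gene, (_, tx) in best.items()}
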