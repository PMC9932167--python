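"""Cell-type composition analysis for the three-group colitis design.

Cell-type frequencies are computed per group (reference, disease,
treated-disease; experimentally WT+H2O, WT+DSS, cKO+DSS), log2
fold-changes across consecutive arms classify "altered" types
(|log2FC| > 0.6 during disease) and "rescue" types (altered AND shifted
back, by default in the opposite direction, under treatment). A simple
per-cell QC filter and IL-17 receptor expression flags support the same
workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "RescueCall",
    "composition_from_cells",
    "qc_filter_cells",
    "frequencies",
    "composition_log2fc",
    "classify_rescue",
    "receptor_flags",
]


@dataclass
class CompositionTable:
    """Group x cell-type cell counts; groups ordered reference, disease,
    treated-disease."""

    groups: list[str]
    cell_types: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.groups), len(self.cell_types)):
            raise ValueError("counts shape must be n_groups x n_cell_types")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every group must contain at least one cell")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.groups, columns=self.cell_types)


@dataclass(frozen=True)
class RescueCall:
    cell_type: str
    log2fc_disease: float
    log2fc_rescue: float
    altered: bool
    rescued: bool

    def __post_init__(self) -> None:
        if self.rescued and not self.altered:
            raise ValueError("rescued implies altered")


def qc_filter_cells(
    cells: pd.DataFrame,
    min_genes: int = 500,
    max_genes: int = 4500,
    max_mito_frac: float = 0.20,
) -> pd.DataFrame:
    """Keep cells with min_genes <= n_genes <= max_genes (inclusive) and
    mitochondrial fraction strictly below ``max_mito_frac``.

    Expects columns ``n_genes`` and ``mito_frac``; if either is absent the
    filter passes all cells through unchanged.
    """
    if "n_genes" not in cells.columns or "mito_frac" not in cells.columns:
        logger.warning("qc_filter_cells: QC columns absent, no filtering applied")
        return cells
    keep = (
        (cells["n_genes"] >= min_genes)
        & (cells["n_genes"] <= max_genes)
        & (cells["mito_frac"] < max_mito_frac)
    )
    return cells.loc[keep]


def composition_from_cells(
    cells: pd.DataFrame, group_order: Sequence[str]
) -> CompositionTable:
    """Tabulate a per-cell table (columns cell_id, cell_type, group) into
    group x cell-type counts with the given group ordering."""
    missing = set(group_order) - set(cells["group"].unique())
    if missing:
        raise ValueError(f"groups absent from cell table: {sorted(missing)}")
    cell_types = sorted(cells["cell_type"].unique().astype(str))
    counts = np.zeros((len(group_order), len(cell_types)), dtype=np.int64)
    tab = cells.groupby(["group", "cell_type"]).size()
    for i, g in enumerate(group_order):
        for j, ct in enumerate(cell_types):
            counts[i, j] = int(tab.get((g, ct), 0))
    return CompositionTable(list(group_order), cell_types, counts)


def frequencies(table: CompositionTable) -> pd.DataFrame:
    """Per-group cell-type frequencies (rows sum to 1)."""
    totals = table.counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        table.counts / totals, index=table.groups, columns=table.cell_types
    )


def composition_log2fc(
    counts_a: np.ndarray | Sequence[int],
    counts_b: np.ndarray | Sequence[int],
    pseudocount_cells: float = 0.5,
) -> np.ndarray:
    """Per-type log2(freq_b / freq_a) between two groups of raw counts.

    For any type where either group's raw count is zero, the pseudocount is
    added to both counts (and both totals) before the frequencies for that
    type are recomputed, keeping every fold-change finite.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share shape")
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("group totals must be positive")
    out = np.empty(len(a))
    for i in range(len(a)):
        ai, bi = a[i], b[i]
        tai, tbi = ta, tb
        if ai == 0 or bi == 0:
            ai += pseudocount_cells
            bi += pseudocount_cells
            tai += pseudocount_cells
            tbi += pseudocount_cells
        out[i] = np.log2((bi / tbi) / (ai / tai))
    return out


def classify_rescue(
    table: CompositionTable,
    threshold: float = 0.6,
    require_sign_flip: bool = True,
    pseudocount_cells: float = 0.5,
) -> list[RescueCall]:
    """Classify each cell type as altered and/or rescued.

    ``altered``: |log2FC(disease vs reference)| > threshold.
    ``rescued``: altered AND |log2FC(treated vs disease)| > threshold AND
    (when ``require_sign_flip``) the two fold-changes have opposite signs —
    the treatment moves the frequency back toward the reference rather than
    further away.
    """
    if len(table.groups) != 3:
        raise ValueError(
            f"expected exactly 3 groups (reference, disease, treated), got {len(table.groups)}"
        )
    ref, dis, treat = table.counts
    fc_disease = composition_log2fc(ref, dis, pseudocount_cells)
    fc_rescue = composition_log2fc(dis, treat, pseudocount_cells)
    calls = []
    for j, ct in enumerate(table.cell_types):
        altered = bool(abs(fc_disease[j]) > threshold)
        shifted = bool(abs(fc_rescue[j]) > threshold)
        flip = fc_disease[j] * fc_rescue[j] < 0
        rescued = altered and shifted and (flip or not require_sign_flip)
        calls.append(
            RescueCall(
                cell_type=ct,
                log2fc_disease=float(fc_disease[j]),
                log2fc_rescue=float(fc_rescue[j]),
                altered=altered,
                rescued=rescued,
            )
        )
    return calls


def receptor_flags(
    expression: pd.DataFrame,
    cell_types: Mapping[str, str] | pd.Series,
    receptor_genes: Sequence[str],
    min_frac_expressing: float = 0.1,
) -> dict[str, bool]:
    """Flag cell types in which a receptor gene is detectably expressed.

    ``expression`` is cells x genes (non-negative values); a type is flagged
    iff, for at least one receptor gene, the fraction of its cells with
    nonzero expression is >= ``min_frac_expressing``. Absent genes are
    treated as all-zero with a warning.
    """
    ct = pd.Series(dict(cell_types)) if not isinstance(cell_types, pd.Series) else cell_types
    ct = ct.reindex(expression.index)
    if ct.isna().any():
        raise ValueError("every cell needs a cell-type label")
    present = [g for g in receptor_genes if g in expression.columns]
    for g in receptor_genes:
        if g not in expression.columns:
            logger.warning("receptor gene %s absent from expression, treated as zero", g)
    flags: dict[str, bool] = {}
    for cell_type, idx in expression.groupby(ct).groups.items():
        sub = expression.loc[idx, present]
        flagged = False
        if present and len(sub):
            frac = (sub > 0).mean(axis=0)
            flagged = bool((frac >= min_frac_expressing).any())
        flags[str(cell_type)] = flagged
    return flags
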