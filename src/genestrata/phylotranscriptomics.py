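"""Transcriptome age and divergence indices.

For one condition with expression levels e_i over genes i:

    TAI = sum_i ps_i * e_i / sum_i e_i        (ps_i = PAI of gene i)
    TDI = sum_i DI_i * e_i / sum_i e_i        (DI_i = divergence index)

i.e. the expression-weighted mean gene age (resp. divergence) of the
transcriptome.  Expression values are expected to be normalised already and
non-negative; the indices are invariant to rescaling a condition's column.
Genes lacking a PAI/DI annotation are dropped with a warning by default
(strict mode raises instead) — large expression tables routinely contain
unannotated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhyloProfileRow",
    "tai",
    "tdi",
    "profile",
    "write_profile",
]


@dataclass
class ExpressionMatrix:
    """Gene x condition grid of non-negative normalised expression values."""

    data: pd.DataFrame  # index = gene ids, columns = condition labels

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValueError("expression matrix needs at least one condition")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def conditions(self) -> list[str]:
        return self.data.columns.tolist()

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "ExpressionMatrix":
        """Read a tab-delimited matrix: first column gene ids, header row of
        condition labels."""
        frame = pd.read_csv(source, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        return cls(frame)

    def to_tsv(self, target: str | IO[str]) -> None:
        self.data.to_csv(target, sep="\t", index_label="Gene")


@dataclass
class PhyloProfileRow:
    """TAI/TDI of one condition; ``None`` marks an undefined index."""

    condition: str
    tai: float | None
    tdi: float | None
    n_genes_used_tai: int = 0
    n_genes_used_tdi: int = 0


def _weighted_index(
    value_by_gene: Mapping[str, float],
    expr: pd.Series,
    *,
    strict: bool,
    what: str,
) -> tuple[float | None, int]:
    usable = [g for g in expr.index if g in value_by_gene]
    missing = len(expr) - len(usable)
    if missing:
        if strict:
            raise KeyError(
                f"{missing} expressed genes lack a {what} annotation"
            )
        logger.warning("%d expressed genes lack a %s; dropped", missing, what)
    if not usable:
        return None, 0
    weights = expr.loc[usable].to_numpy(dtype=float)
    values = np.array([value_by_gene[g] for g in usable], dtype=float)
    total = weights.sum()
    if total == 0:
        logger.warning("all usable genes have zero expression; %s undefined", what)
        return None, 0
    return float((values * weights).sum() / total), int((weights > 0).sum())


def tai(
    pai_by_gene: Mapping[str, int],
    expr: pd.Series,
    *,
    strict: bool = False,
) -> tuple[float | None, int]:
    """Transcriptome age index of one condition column.

    Returns ``(value, n_used)``; the value is ``None`` when no expressed gene
    carries a PAI or the usable expression sums to zero.
    """
    return _weighted_index(pai_by_gene, expr, strict=strict, what="PAI")


def tdi(
    di_by_gene: Mapping[str, float],
    expr: pd.Series,
    *,
    strict: bool = False,
) -> tuple[float | None, int]:
    """Transcriptome divergence index of one condition column."""
    return _weighted_index(di_by_gene, expr, strict=strict, what="DI")


def profile(
    matrix: ExpressionMatrix,
    pai_by_gene: Mapping[str, int],
    di_by_gene: Mapping[str, float] | None = None,
    *,
    strict: bool = False,
) -> list[PhyloProfileRow]:
    """One TAI/TDI row per condition, in input column order.

    A condition whose indices cannot be computed yields ``None`` cells rather
    than aborting the run.
    """
    di_by_gene = di_by_gene or {}
    rows = []
    for condition in matrix.conditions:
        column = matrix.data[condition]
        t, n_t = tai(pai_by_gene, column, strict=strict)
        d, n_d = (
            tdi(di_by_gene, column, strict=strict) if di_by_gene else (None, 0)
        )
        rows.append(PhyloProfileRow(condition, t, d, n_t, n_d))
    return rows


def write_profile(rows: list[PhyloProfileRow], target: str | IO[str]) -> None:
    """Write the condition profile as TSV with header Data, TAI, TDI;
    undefined cells are rendered "NA"."""

    def fmt(x: float | None) -> str:
        return "NA" if x is None else format(x, ".6g")

    frame = pd.DataFrame(
        {
            "Data": [r.condition for r in rows],
            "TAI": [fmt(r.tai) for r in rows],
            "TDI": [fmt(r.tdi) for r in rows],
        }
    )
    frame.to_csv(target, sep="\t", index=False)
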