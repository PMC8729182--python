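"""MiniMax integration of per-omics pathway p-values.

The MiniMax statistic summarises, for one pathway, p-values obtained from
separate pathway analyses of G omics data types. For order r it is the
minimum, over all r-subsets of the p-values, of each subset's maximum --
which is simply the r-th smallest p-value (the r-th order statistic). A
small MiniMax value therefore flags a pathway that is dysregulated in *at
least r* omics types, which is the multi-omics evidence pattern this
package prioritises. Because only summary p-values are integrated, the
omics datasets need not share samples or even genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsPValueTable",
    "MiniMaxRecord",
    "MiniMaxResult",
    "InsufficientOmicsError",
    "minimax",
    "contributing_omics",
    "run_minimax",
]


class InsufficientOmicsError(ValueError):
    """Raised when a pathway has fewer non-missing p-values than the order r."""


@dataclass
class OmicsPValueTable:
    """Pathways x omics matrix of p-values.

    Parameters
    ----------
    data:
        DataFrame indexed by pathway identifier with one column per omics
        type. Entries are probabilities in [0, 1]; NaN marks a pathway that
        was not testable in that omics dataset.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("need p-values for at least two omics types")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated pathway IDs: {dupes}")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicated omics labels")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            i, j = np.argwhere(bad & ~np.isnan(values))[0]
            raise ValueError(
                f"p-value out of [0, 1] at pathway {self.data.index[i]!r}, "
                f"omics {self.data.columns[j]!r}: {values[i, j]}"
            )

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def omics_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_omics(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class MiniMaxRecord:
    """Integrated result for a single pathway."""

    pathway_id: str
    statistic: float
    contributing: tuple[str, ...]
    p_value: float
    q_value: float = float("nan")
    g_effective: int = 0


@dataclass
class MiniMaxResult:
    """Ordered records plus a log of pathways skipped for missingness."""

    records: list[MiniMaxRecord]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": [rec.pathway_id for rec in self.records],
                "g_effective": [rec.g_effective for rec in self.records],
                "minimax": [rec.statistic for rec in self.records],
                "contributing_omics": [
                    ",".join(rec.contributing) for rec in self.records
                ],
                "p_value": [rec.p_value for rec in self.records],
                "q_value": [rec.q_value for rec in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)


def minimax(pvals, r: int = 2, pathway_id: str | None = None) -> float:
    """r-th order statistic of the non-missing p-values.

    Equivalent to taking, over every r-subset of the p-values, the subset
    maximum, and then the minimum of those maxima.
    """
    v = np.asarray(pvals, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if np.any((v < 0) | (v > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if r < 1:
        raise ValueError(f"order r must be >= 1, got {r}")
    if v.size < r:
        name = f" for pathway {pathway_id!r}" if pathway_id else ""
        raise InsufficientOmicsError(
            f"insufficient omics{name}: {v.size} non-missing p-values, need {r}"
        )
    return float(np.partition(v, r - 1)[r - 1])


def contributing_omics(pvals: pd.Series, r: int = 2) -> tuple[str, ...]:
    """Labels of the r smallest non-missing p-values.

    Ties are broken by input column order (the first-listed label wins), so
    the result is deterministic. Returned in input-column order.
    """
    s = pd.Series(pvals, dtype=float)
    nonmiss = s.dropna()
    if len(nonmiss) < r:
        raise InsufficientOmicsError(
            f"insufficient omics: {len(nonmiss)} non-missing p-values, need {r}"
        )
    # stable sort keeps input order among ties
    order = np.argsort(nonmiss.to_numpy(), kind="stable")[:r]
    chosen = set(nonmiss.index[order])
    return tuple(label for label in s.index if label in chosen)


def run_minimax(table: OmicsPValueTable, r: int = 2, null=None) -> MiniMaxResult:
    """Integrate a p-value table into per-pathway MiniMax records.

    Parameters
    ----------
    table:
        Validated pathways x omics p-value table.
    r:
        Order of the statistic (default 2: dysregulation in at least two
        omics types).
    null:
        Null provider mapping an effective omics count to a Beta null; any
        object with a ``null_for(g_effective)`` method (see
        :mod:`minimaxomics.nulls`). Defaults to the theoretical
        Beta(r, g - r + 1) null.

    Returns
    -------
    MiniMaxResult
        Records sorted by ascending p-value (ties by pathway ID), with
        Benjamini-Hochberg q-values computed across all returned pathways.
        Pathways with fewer than r non-missing p-values are skipped and
        logged, never silently dropped.
    """
    from .nulls import TheoreticalNullProvider, null_pvalue

    if len(table) == 0:
        raise ValueError("empty p-value table")
    if null is None:
        null = TheoreticalNullProvider(r)

    records: list[MiniMaxRecord] = []
    skipped: list[tuple[str, str]] = []
    for pathway_id, row in table.data.iterrows():
        g_eff = int(row.notna().sum())
        if g_eff < r:
            reason = f"{g_eff} non-missing p-values < order {r}"
            skipped.append((str(pathway_id), reason))
            logger.info("skipping pathway %s: %s", pathway_id, reason)
            continue
        stat = minimax(row.to_numpy(), r, pathway_id=str(pathway_id))
        contrib = contributing_omics(row, r)
        pval = null_pvalue(stat, null.null_for(g_eff))
        records.append(
            MiniMaxRecord(
                pathway_id=str(pathway_id),
                statistic=stat,
                contributing=contrib,
                p_value=pval,
                g_effective=g_eff,
            )
        )

    if not records:
        raise ValueError("no pathway had enough non-missing p-values")

    qvals = multipletests([rec.p_value for rec in records], method="fdr_bh")[1]
    for rec, q in zip(records, qvals):
        rec.q_value = float(q)
    records.sort(key=lambda rec: (rec.p_value, rec.pathway_id))
    return MiniMaxResult(records=records, skipped=skipped)
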