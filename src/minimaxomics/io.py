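"""Readers and writers for the plain-text formats the tool exchanges.

GMT gene sets (MSigDB dialect), delimited p-value tables, omics matrices,
phenotype tables, gene spans (BED or 1-based TSV) and the result TSV. All
tables are TSV by default; comma-separated files are accepted where noted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MiniMaxResult, OmicsPValueTable
from .scoring import OmicsMatrix, Phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "RunConfig",
    "read_gmt",
    "read_pvalue_table",
    "write_pvalue_table",
    "read_omics_matrix",
    "read_phenotype",
    "read_gene_spans",
    "read_features",
    "write_results",
]


@dataclass
class PathwayEntry:
    description: str
    genes: tuple[str, ...]


@dataclass
class PathwayCollection:
    """Ordered pathway_id -> (description, gene set) mapping."""

    entries: dict[str, PathwayEntry]
    source: str = ""

    def items(self):
        return [(pid, entry.genes) for pid, entry in self.entries.items()]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.entries

    def __getitem__(self, pathway_id: str) -> PathwayEntry:
        return self.entries[pathway_id]

    def filter_by_size(self, min_size: int = 3, max_size: int = 200) -> "PathwayCollection":
        if min_size > max_size:
            raise ValueError("min_size must not exceed max_size")
        kept = {
            pid: e
            for pid, e in self.entries.items()
            if min_size <= len(e.genes) <= max_size
        }
        return PathwayCollection(entries=kept, source=self.source)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PathwayCollection":
        return cls(
            entries={
                pid: PathwayEntry(description="", genes=tuple(genes))
                for pid, genes in mapping.items()
            }
        )


@dataclass
class RunConfig:
    """Run-level options shared by the CLI subcommands."""

    order: int = 2
    null_mode: str = "theoretical"
    permutations: int = 100
    seed: int = 0
    fdr_level: float = 0.05
    min_pathway_size: int = 3
    max_pathway_size: int = 200
    log_level: str = "INFO"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("FDR level must lie in (0, 1)")
        if self.min_pathway_size > self.max_pathway_size:
            raise ValueError("min pathway size exceeds max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_gmt(path) -> PathwayCollection:
    """Parse a GMT file: ``id<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a line are deduplicated with a warning;
    duplicate pathway IDs or lines with fewer than three fields are errors.
    """
    entries: dict[str, PathwayEntry] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            if pid in entries:
                raise ValueError(f"{path}: line {lineno}: duplicate pathway ID {pid!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d: %d duplicate genes in %s deduplicated",
                    path, lineno, len(genes) - len(unique), pid,
                )
            if not unique:
                raise ValueError(f"{path}: line {lineno}: pathway {pid!r} has no genes")
            entries[pid] = PathwayEntry(description=desc, genes=tuple(unique))
    return PathwayCollection(entries=entries, source=str(path))


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_pvalue_table(path) -> OmicsPValueTable:
    """Read a pathways x omics p-value table (TSV default, CSV accepted).

    First column is the pathway ID; "NA"/empty cells are missing. Values
    outside [0, 1] are reported with their (pathway, omics) coordinates.
    """
    frame = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=["NA", ""], dtype=str
    )
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least two omics columns")
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated pathway IDs: {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric p-value at ({frame.index[i]}, {frame.columns[j]}): "
            f"{frame.iat[i, j]!r}"
        )
    out_of_range = (numeric < 0) | (numeric > 1)
    if out_of_range.to_numpy().any():
        i, j = np.argwhere(out_of_range.to_numpy())[0]
        raise ValueError(
            f"{path}: p-value out of [0, 1] at ({frame.index[i]}, "
            f"{frame.columns[j]}): {numeric.iat[i, j]}"
        )
    return OmicsPValueTable(numeric)


def write_pvalue_table(table: OmicsPValueTable, path) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index_label="pathway_id", na_rep="NA")


def read_omics_matrix(path, omics_label: str | None = None) -> OmicsMatrix:
    """Genes x samples TSV: first column gene IDs, header = sample IDs."""
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    label = omics_label if omics_label is not None else Path(str(path)).stem
    return OmicsMatrix(data=frame.astype(float), omics_label=label)


def read_phenotype(path) -> Phenotype:
    """Two-column TSV (sample_id, outcome) or three-column
    (sample_id, time, event). Binary vs continuous is inferred from the
    number of distinct outcome values."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    if frame.shape[1] == 3:
        sample, time, event = frame.columns
        return Phenotype(
            outcome=pd.Series(frame[time].to_numpy(float), index=frame[sample]),
            kind="survival",
            event=pd.Series(frame[event].to_numpy(float), index=frame[sample]),
        )
    if frame.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 or 3 columns, got {frame.shape[1]}")
    sample, outcome = frame.columns
    values = frame[outcome]
    kind = "binary" if values.nunique() == 2 else "continuous"
    return Phenotype(
        outcome=pd.Series(values.to_numpy(), index=frame[sample]), kind=kind
    )


def read_gene_spans(path) -> pd.DataFrame:
    """Gene spans as a frame with gene_id, chrom, start, end (1-based,
    inclusive). BED input (.bed: chrom, start, end, name; 0-based
    half-open) is converted; otherwise a 4-column TSV
    (gene_id, chrom, start, end) already 1-based inclusive is expected."""
    if str(path).endswith(".bed"):
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"], usecols=range(4),
        )
        return pd.DataFrame(
            {
                "gene_id": bed["gene_id"],
                "chrom": bed["chrom"],
                "start": bed["start"] + 1,  # 0-based half-open -> 1-based inclusive
                "end": bed["end"],
            }
        )
    frame = pd.read_csv(path, sep=_sep_for(path))
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return frame[["gene_id", "chrom", "start", "end"]]


def read_features(path) -> pd.DataFrame:
    """Feature summary statistics: feature_id, chrom, pos, p_value."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    required = {"feature_id", "chrom", "pos", "p_value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return frame[sorted(required, key=["feature_id", "chrom", "pos", "p_value"].index)]


def _sci(x: float) -> str:
    return f"{x:.2E}"


def write_results(result: MiniMaxResult, path) -> None:
    """Result TSV: 3-significant-figure scientific notation for display
    plus full-precision machine-readable columns."""
    frame = result.to_frame()
    frame["minimax_display"] = frame["minimax"].map(_sci)
    frame["p_value_display"] = frame["p_value"].map(_sci)
    cols = [
        "pathway_id", "g_effective", "minimax", "contributing_omics",
        "p_value", "q_value", "minimax_display", "p_value_display",
    ]
    frame[cols].to_csv(path, sep="\t", index=False)
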