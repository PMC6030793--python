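"""Count-matrix containers, FPKM conversion and the coexpression filter.

The pipeline's entry point is a gene-by-sample matrix of raw fragment
counts with per-gene effective lengths and a sample-to-group map over the
four groups of the cross: the maternal parent (BSB), the paternal parent
(YB), the allodiploid hybrid (2nBY) and the allotriploid hybrid (3nBY).
Counts are converted to FPKM (fragments per kilobase of transcript per
million mapped fragments) and genes silent in any group are removed, so
every downstream stage works on the same coexpressed gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical group labels of the cross, maternal parent first
GROUPS = ("BSB", "YB", "2nBY", "3nBY")


@dataclass
class CountMatrix:
    """Raw fragment counts per gene per sample.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, genes as the index, samples as columns.
    lengths : pandas.Series
        Effective transcript length in bp per gene, same index as ``counts``.
    groups : pandas.Series
        Group label per sample, indexed by sample id (column order of
        ``counts``).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs an effective length")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, group: str) -> list[str]:
        """Sample ids belonging to one group."""
        hits = [s for s, g in self.groups.items() if g == group]
        if not hits:
            raise KeyError(f"group {group!r} not present in the matrix")
        return hits

    def subset(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[gene_ids], self.lengths.loc[gene_ids], self.groups
        )

    def to_tsv(self, path) -> None:
        """Write gene_id, length_bp, then one column per sample."""
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, groups: dict[str, str] | None = None) -> "CountMatrix":
        """Read a counts TSV written by :meth:`to_tsv`.

        If ``groups`` is not given, group labels are inferred from sample
        column names of the form ``GROUP_rep`` (e.g. ``BSB_1``).
        """
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        df.index.name = None
        lengths = df.pop("length_bp")
        if groups is None:
            groups = {s: s.rsplit("_", 1)[0] for s in df.columns}
        return cls(df, lengths, pd.Series(groups))


@dataclass
class FpkmMatrix:
    """FPKM expression values on the same axes as the source counts."""

    values: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series = field(repr=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_of(self, group: str) -> list[str]:
        hits = [s for s, g in self.groups.items() if g == group]
        if not hits:
            raise KeyError(f"group {group!r} not present in the matrix")
        return hits

    def group_means(self) -> pd.DataFrame:
        """Gene-by-group matrix of mean FPKM per group."""
        present = pd.unique(self.groups)
        return pd.DataFrame(
            {g: self.values[self.samples_of(g)].mean(axis=1) for g in present}
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def compute_fpkm(counts: CountMatrix) -> FpkmMatrix:
    """Convert raw counts to FPKM.

    FPKM[g, s] = count[g, s] * 1e9 / (length_bp[g] * total_count[s]).

    Raises
    ------
    ValueError
        If any sample has zero total counts (FPKM undefined).
    """
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero total count in sample(s): {list(zero.index)}")
    vals = counts.counts.astype(float) * 1e9
    vals = vals.div(counts.lengths, axis=0).div(totals, axis=1)
    return FpkmMatrix(vals, counts.lengths, counts.groups)


def filter_coexpressed(
    fpkm: FpkmMatrix,
    counts: CountMatrix | None = None,
    per_sample: bool = False,
) -> tuple[FpkmMatrix, CountMatrix | None]:
    """Keep genes expressed in all four groups (the coexpressed set).

    A gene is retained when its group-mean FPKM is > 0 in every group;
    with ``per_sample=True`` the stricter rule requires every single
    library to be nonzero. Returns the filtered FPKM matrix and, if the
    source counts were given, the matching count submatrix.
    """
    for g in GROUPS:
        if g not in set(fpkm.groups):
            raise ValueError(f"group {g!r} missing; all four groups are required")
    if per_sample:
        keep = (fpkm.values > 0).all(axis=1)
    else:
        keep = (fpkm.group_means()[list(GROUPS)] > 0).all(axis=1)
    n_in, n_keep = len(keep), int(keep.sum())
    logger.info("coexpression filter: retained %d / %d genes", n_keep, n_in)
    if n_keep == 0:
        logger.warning("coexpression filter removed every gene")
    kept_ids = fpkm.values.index[keep]
    out_fpkm = FpkmMatrix(fpkm.values.loc[kept_ids], fpkm.lengths.loc[kept_ids], fpkm.groups)
    out_counts = counts.subset(kept_ids) if counts is not None else None
    return out_fpkm, out_counts
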