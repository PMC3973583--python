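"""Core in-memory containers shared by all pipeline stages.

The pipeline passes three kinds of objects between stages: an
:class:`ExpressionMatrix` (positive linear-scale intensities with a
sample->group map), a :class:`GeneCatalog` (gene coordinates on chromosome
arms plus term and domain annotations), and plain :class:`pandas.DataFrame`
tables for stage outputs (DEG table, bin score track, enrichment rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneCatalog"]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of strictly positive linear-scale intensities.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids with one column per sample.
    groups
        Mapping from sample id to group label; must cover every column.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not np.all(self.values.to_numpy() > 0):
            raise ValueError("expression intensities must be strictly positive")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_of(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in matrix column order."""
        out = [s for s in self.values.columns if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def submatrix(self, group: str) -> np.ndarray:
        """Values of one group as a (genes, replicates) array."""
        return self.values[self.samples_of(group)].to_numpy(dtype=float)


@dataclass
class GeneCatalog:
    """Gene coordinates on chromosome arms plus annotation tables.

    Coordinates are 0-based half-open; each gene lives on exactly one arm.
    ``terms`` maps genes to GO-style term ids (one row per gene/term pair);
    ``domains`` maps genes to protein-domain ids where *repeated rows encode
    instance multiplicity* (a gene with two copies of a domain appears twice).
    """

    genes: pd.DataFrame  # columns: gene, arm, start, end
    arm_lengths: dict[str, int]
    terms: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "term"]))
    domains: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["gene", "domain"]))

    def __post_init__(self) -> None:
        req = {"gene", "arm", "start", "end"}
        if not req.issubset(self.genes.columns):
            raise ValueError(f"catalog needs columns {sorted(req)}")
        if self.genes["gene"].duplicated().any():
            dup = self.genes.loc[self.genes["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if (self.genes["start"] >= self.genes["end"]).any():
            bad = self.genes[self.genes["start"] >= self.genes["end"]].iloc[0]
            raise ValueError(f"gene {bad['gene']!r}: start must be < end")
        unknown = set(self.genes["arm"]) - set(self.arm_lengths)
        if unknown:
            raise ValueError(f"genes on unregistered arms: {sorted(unknown)}")
        off = self.genes["end"] > self.genes["arm"].map(self.arm_lengths)
        if off.any():
            bad = self.genes[off].iloc[0]
            raise ValueError(f"gene {bad['gene']!r} extends past the end of arm {bad['arm']}")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene"])

    def midpoints(self) -> pd.DataFrame:
        """Per-gene single coordinate used for bin assignment: (start+end)//2."""
        mid = (self.genes["start"] + self.genes["end"]) // 2
        return pd.DataFrame(
            {"gene": self.genes["gene"], "arm": self.genes["arm"], "midpoint": mid}
        )
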