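"""Shared in-memory containers for diel expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZT_GRID = (1, 7, 13, 19)  # tissue-collection times, hours after dawn
REPLICATES = (1, 2, 3)


def expression_columns(zts=ZT_GRID, reps=REPLICATES) -> pd.MultiIndex:
    return pd.MultiIndex.from_product([list(zts), list(reps)], names=["zt", "replicate"])


@dataclass
class ExpressionTimeCourse:
    """Log2 normalized expression for one accession x treatment.

    ``data`` is gene x (ZT, replicate) with a MultiIndex column grid of
    exactly ZT {1, 7, 13, 19} x replicates {1, 2, 3}; missing replicates are
    NaN and tracked through :attr:`mask`.
    """

    accession: str
    treatment: str
    data: pd.DataFrame
    imputed: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.names != ["zt", "replicate"]:
            raise ValueError("expression columns must be a (zt, replicate) MultiIndex")
        zts = tuple(sorted(set(cols.get_level_values("zt"))))
        if zts != ZT_GRID:
            raise ValueError(f"ZT grid must be exactly {ZT_GRID}, got {zts}")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean gene x (zt, replicate) frame, True where a value is missing."""
        return self.data.isna()

    def replicate_mean(self) -> pd.DataFrame:
        """Gene x ZT frame of replicate means (NaN-aware)."""
        return self.data.T.groupby(level="zt").mean().T[list(ZT_GRID)]

    def n_missing_per_zt(self) -> pd.DataFrame:
        return self.mask.T.groupby(level="zt").sum().T[list(ZT_GRID)]

    def copy(self) -> "ExpressionTimeCourse":
        return ExpressionTimeCourse(
            self.accession,
            self.treatment,
            self.data.copy(),
            None if self.imputed is None else self.imputed.copy(),
        )


def validate_homoeolog_map(hmap: pd.DataFrame) -> pd.DataFrame:
    """Check the gene -> subgenome / ortholog-group map and index it by gene."""
    required = {"gene_id", "subgenome", "ortholog_group"}
    if not required.issubset(hmap.columns):
        raise ValueError(f"homoeolog map needs columns {sorted(required)}")
    if hmap["gene_id"].duplicated().any():
        dups = hmap.loc[hmap["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene ids in homoeolog map, e.g. {dups}")
    bad = set(hmap["subgenome"]) - {"BnA", "BnC"}
    if bad:
        raise ValueError(f"unknown subgenomes {sorted(bad)}; expected BnA/BnC")
    return hmap.set_index("gene_id", drop=False)
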