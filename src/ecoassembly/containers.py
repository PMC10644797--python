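"""In-memory containers for the pipeline: OTU table, sample metadata, tree.

The phylogenetic tree is a :class:`skbio.TreeNode` and distance matrices are
:class:`skbio.stats.distance.DistanceMatrix`; this module only adds the thin
count-table and metadata wrappers plus their validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Soil environmental covariates carried in sample metadata. TDS (total
#: dissolved solids, the salinity proxy), pH, organic matter, macronutrients,
#: mineral nitrogen and four enzyme activities.
ENV_VARIABLES = (
    "TDS",
    "pH",
    "OM",
    "TN",
    "TP",
    "AP",
    "AK",
    "NH4",
    "NO3",
    "ALP",
    "PPO",
    "urease",
    "POD",
)

#: Metadata columns that are not environmental covariates.
METADATA_CORE_COLUMNS = ("site", "n_di_years")


class OTUTable:
    """Non-negative taxa x samples count table with unique identifiers.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are taxa (index = OTU identifiers), columns are samples. Entries
        must be non-negative and finite; every sample (column) must have a
        positive total. Non-integer entries are accepted (tables may be
        normalized upstream), but operations that require integer counts
        (Chao1, Raup-Crick) validate integrality themselves.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise ValueError("OTU table is empty")
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = counts.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("OTU table contains non-finite entries")
        if (values < 0).any():
            raise ValueError("OTU table contains negative entries")
        col_sums = values.sum(axis=0)
        if (col_sums <= 0).any():
            empty = counts.columns[col_sums <= 0].tolist()
            raise ValueError(f"samples with zero total abundance: {empty}")
        self.counts = counts

    # -- basic properties -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def values(self) -> np.ndarray:
        """Counts as a float array, taxa x samples."""
        return self.counts.to_numpy(dtype=float)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def is_integer(self) -> bool:
        v = self.values()
        return bool(np.all(v == np.round(v)))

    def sort(self) -> "OTUTable":
        """Canonical (lexicographic) ordering of both axes."""
        return OTUTable(
            self.counts.sort_index(axis=0).sort_index(axis=1)
        )

    def select_taxa(self, taxa: Iterable[str]) -> "OTUTable":
        taxa = [t for t in self.taxon_ids if t in set(taxa)]
        if not taxa:
            raise ValueError("no taxa left after selection")
        return OTUTable(self.counts.loc[taxa])

    def select_samples(self, samples: Iterable[str]) -> "OTUTable":
        keep = [s for s in self.sample_ids if s in set(samples)]
        if not keep:
            raise ValueError("no samples left after selection")
        return OTUTable(self.counts[keep])

    def __eq__(self, other) -> bool:
        if not isinstance(other, OTUTable):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"OTUTable({self.shape[0]} taxa x {self.shape[1]} samples)"


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and return a normalized copy.

    Expects one row per sample with the sample identifier as the index (or in
    a ``sample_id`` column), a ``site`` column, a positive integer
    ``n_di_years`` column (years under drip irrigation), and any subset of
    :data:`ENV_VARIABLES` as numeric columns.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dups}")
    for col in METADATA_CORE_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    ndi = pd.to_numeric(meta["n_di_years"], errors="raise")
    if not np.all(ndi == np.round(ndi)) or (ndi <= 0).any():
        raise ValueError("n_di_years must be positive integers")
    meta["n_di_years"] = ndi.astype(int)
    meta["site"] = meta["site"].astype(str)
    for col in meta.columns:
        if col in METADATA_CORE_COLUMNS:
            continue
        vals = pd.to_numeric(meta[col], errors="coerce")
        if np.isinf(vals.to_numpy(dtype=float)).any():
            raise ValueError(f"metadata column {col!r} contains infinite values")
        meta[col] = vals
    return meta


@dataclass
class SyntheticDataset:
    """A simulated community dataset: table + tree + metadata + ground truth.

    ``truth`` maps each group identifier (an N_DI level, as string) to the
    assembly regime its communities were generated under.
    """

    table: OTUTable
    tree: object  # skbio.TreeNode
    metadata: pd.DataFrame
    truth: Mapping[str, str] = field(default_factory=dict)
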