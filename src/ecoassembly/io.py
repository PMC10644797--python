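"""Readers/writers for the classic TSV OTU table, metadata and Newick trees,
plus harmonization of the table/tree/metadata triple."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OTUTable, validate_metadata

logger = logging.getLogger(__name__)

Orientation = Literal["taxa_by_samples", "samples_by_taxa"]

#: Float format used for every TSV this package writes; fixed so that
#: identical inputs + seed give byte-identical output files.
FLOAT_FORMAT = "%.10g"


def read_otu_table(path, orientation: Orientation = "taxa_by_samples") -> OTUTable:
    """Read a classic tab-separated OTU table.

    One header row, one leading identifier column (a ``#OTU ID`` header is
    accepted). ``orientation`` states how the *file* is laid out; the returned
    table is always canonical taxa x samples.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]
    if len(set(body)) != len(body):
        dups = sorted({h for h in body if body.count(h) > 1})
        raise ValueError(f"duplicate column headers in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty OTU table: {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entries in OTU table {path}: {exc}") from exc
    if orientation == "samples_by_taxa":
        df = df.T
    elif orientation != "taxa_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index.name = "#OTU ID"
    return OTUTable(df)


def write_otu_table(table: OTUTable, path) -> None:
    """Write the canonical taxa x samples TSV (``#OTU ID`` leading column)."""
    df = table.counts.copy()
    df.index.name = "#OTU ID"
    if table.is_integer():
        df = df.astype(int)
        df.to_csv(path, sep="\t")
    else:
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (TSV, ``sample_id`` column or leading index)."""
    meta = pd.read_csv(path, sep="\t", header=0)
    if meta.shape[0] == 0:
        raise ValueError(f"empty metadata table: {path}")
    if "sample_id" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta = validate_metadata(meta)
    meta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree.

    Tip labels must be unique. Branches without a length are treated as
    length 0 with a logged warning, so downstream patristic distances stay
    finite.
    """
    tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(tips)) != len(tips):
        seen, dups = set(), set()
        for name in tips:
            (dups if name in seen else seen).add(name)
        raise ValueError(f"duplicate tip labels in tree: {sorted(dups)}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branches lacked a length; treated as 0", n_missing)
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def harmonize(
    table: OTUTable, tree: TreeNode, meta: pd.DataFrame
) -> tuple[OTUTable, TreeNode, pd.DataFrame]:
    """Reconcile table, tree and metadata onto their shared taxa and samples.

    Taxa absent from the tree are dropped from the table (count logged); the
    tree is pruned to the table's taxa; samples without metadata are dropped;
    sample and taxon orderings are canonicalized (lexicographic) so all
    downstream pairwise matrices are reproducible. Idempotent.
    """
    meta = validate_metadata(meta)
    tip_names = {t.name for t in tree.tips()}
    shared_taxa = sorted(set(table.taxon_ids) & tip_names)
    if not shared_taxa:
        raise ValueError("no taxa shared between OTU table and tree")
    n_dropped_taxa = len(table.taxon_ids) - len(shared_taxa)
    if n_dropped_taxa:
        logger.warning(
            "%d taxa in the OTU table are absent from the tree and were dropped",
            n_dropped_taxa,
        )
    shared_samples = sorted(set(table.sample_ids) & set(meta.index))
    if not shared_samples:
        raise ValueError("no samples shared between OTU table and metadata")
    n_dropped_samples = len(table.sample_ids) - len(shared_samples)
    if n_dropped_samples:
        logger.warning(
            "%d samples lacked metadata and were dropped", n_dropped_samples
        )

    out_table = OTUTable(table.counts.loc[shared_taxa, shared_samples])
    if len(shared_taxa) < len(tip_names):
        out_tree = tree.shear(shared_taxa)
    else:
        out_tree = tree.copy()
    for node in out_tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    out_meta = meta.loc[shared_samples]
    return out_table, out_tree, out_meta
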