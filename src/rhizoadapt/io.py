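"""Readers and writers for the pipeline's plain-text formats.

Feature tables, metadata, genotype panels, SSR matrices and trait tables are
TSV; trees are newick; stage results are JSON. Every writer produces a file
its paired reader maps back to an identical object.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import skbio

from .datatypes import (
    RANKS,
    DistanceMatrix,
    FeatureTable,
    GenotypePanel,
    PhyloTree,
    SampleMetadata,
    SSRMatrix,
    TaxonomyTable,
    TraitTable,
    ValidationError,
)

PathLike = Union[str, Path]

MISSING_ALLELE = "NA"


def read_feature_table(path: PathLike) -> FeatureTable:
    """Read a samples-as-rows, taxa-as-columns TSV of integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: PathLike) -> None:
    table.data.to_csv(path, sep="\t")


def read_tree(path: PathLike) -> PhyloTree:
    """Read a rooted newick tree; branch lengths are mandatory."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValidationError(f"could not parse newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: PathLike) -> None:
    tree.tree.write(str(path), format="newick")


def read_metadata(path: PathLike) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str))


def write_metadata(meta: SampleMetadata, path: PathLike) -> None:
    meta.data.to_csv(path, sep="\t", index=False)


def read_panel(path: PathLike) -> GenotypePanel:
    return GenotypePanel(pd.read_csv(path, sep="\t"))


def write_panel(panel: GenotypePanel, path: PathLike) -> None:
    panel.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ssr(path: PathLike) -> SSRMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_ALLELE])
    return SSRMatrix(df)


def write_ssr(ssr: SSRMatrix, path: PathLike) -> None:
    ssr.data.to_csv(path, sep="\t", na_rep=MISSING_ALLELE)


def read_traits(path: PathLike) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t"))


def write_traits(traits: TraitTable, path: PathLike) -> None:
    traits.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_taxonomy(path: PathLike) -> TaxonomyTable:
    """Read a taxonomy TSV: taxon_id, rank columns, and a semicolon-joined
    ``flags`` column of functional-group tags."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in df.columns:
        raise ValidationError("taxonomy table missing 'taxon_id' column")
    ranks = df.set_index("taxon_id")[[r for r in RANKS if r in df.columns]]
    flags: dict[str, set] = {}
    if "flags" in df.columns:
        for taxon, cell in zip(df["taxon_id"], df["flags"]):
            for tag in str(cell).split(";"):
                tag = tag.strip()
                if tag:
                    flags.setdefault(tag, set()).add(taxon)
    return TaxonomyTable(ranks=ranks, flags={k: frozenset(v) for k, v in flags.items()})


def write_taxonomy(tax: TaxonomyTable, path: PathLike) -> None:
    df = tax.ranks.copy()
    tag_col = []
    for taxon in df.index:
        tags = sorted(f for f, members in tax.flags.items() if taxon in members)
        tag_col.append(";".join(tags))
    df["flags"] = tag_col
    df.to_csv(path, sep="\t")


def read_distance_matrix(path: PathLike, metric_name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index), df.to_numpy(), metric_name)


def write_distance_matrix(dm: DistanceMatrix, path: PathLike) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")


def write_json(obj, path: PathLike) -> None:
    """Write JSON deterministically (sorted keys, fixed float repr)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
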