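"""Shared data model for the rhizosphere community / nitrogen-adaptation pipeline.

All tabular containers wrap pandas objects and validate their invariants at
construction time: unique identifiers, non-negative integer counts, complete
environmental vectors, declared factor levels. Downstream modules can
therefore assume well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "ValidationError",
    "ENV_VARS",
    "NITROGEN_LEVELS",
    "MICROBE_LEVELS",
    "FeatureTable",
    "TaxonomyTable",
    "PhyloTree",
    "SampleMetadata",
    "GenotypePanel",
    "SSRMatrix",
    "TraitTable",
    "DistanceMatrix",
]


class ValidationError(ValueError):
    """Raised when an input container violates a data-model invariant."""


#: Historic-environment covariates carried by every genotype panel.
ENV_VARS = (
    "soil_nitrogen",
    "soil_phosphorus",
    "cec",
    "ph",
    "mean_annual_temp",
    "precip_spring",
    "precip_summer",
    "precip_fall",
    "mean_annual_precip",
)

NITROGEN_LEVELS = ("low", "high")
MICROBE_LEVELS = ("live", "sterile")

#: Canonical taxonomic ranks (coarse to fine) used by taxonomy tables.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Functional-group tags recognised in taxonomy tables.
KNOWN_FLAGS = ("ammonia_oxidizer", "diazotroph_16s_match", "glomeromycota")


def _check_unique(tokens: Sequence, what: str) -> None:
    seen = pd.Index(tokens)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


class FeatureTable:
    """Samples x taxa table of non-negative integer counts (the ASV table)."""

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data, pd.DataFrame):
            raise ValidationError("FeatureTable requires a pandas DataFrame")
        _check_unique(data.index, "sample ids")
        _check_unique(data.columns, "taxon ids")
        values = data.to_numpy()
        if values.size:
            if not np.issubdtype(np.asarray(values).dtype, np.number):
                raise ValidationError("counts must be numeric")
            arr = np.asarray(values, dtype=float)
            if not np.isfinite(arr).all():
                raise ValidationError("counts must be finite")
            if (arr < 0).any():
                raise ValidationError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
        self.data = data.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def filter_samples(self, keep: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(keep)])

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<FeatureTable {n} samples x {m} taxa>"


@dataclass
class TaxonomyTable:
    """Per-taxon rank labels plus functional-group membership flags.

    ``ranks`` is indexed by taxon id with columns from :data:`RANKS`;
    ``flags`` maps a tag (e.g. ``diazotroph_16s_match``) to the set of
    taxon ids carrying it.
    """

    ranks: pd.DataFrame
    flags: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        _check_unique(self.ranks.index, "taxon ids")
        self.ranks.index = self.ranks.index.astype(str)
        self.ranks.index.name = "taxon_id"
        known = set(self.ranks.index)
        clean = {}
        for flag, taxa in self.flags.items():
            taxa = frozenset(str(t) for t in taxa)
            unknown = taxa - known
            if unknown:
                raise ValidationError(
                    f"flag {flag!r} references unknown taxa: {sorted(unknown)[:5]}"
                )
            clean[flag] = taxa
        self.flags = clean

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.ranks.index)

    def flagged(self, flag: str) -> frozenset:
        if flag not in self.flags:
            raise KeyError(f"flag {flag!r} not defined; have {sorted(self.flags)}")
        return self.flags[flag]


class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths (wraps skbio TreeNode)."""

    def __init__(self, tree: skbio.TreeNode):
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise ValidationError("all leaves must be named")
        _check_unique(names, "leaf names")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise ValidationError(
                    f"branch above {node.name or '<internal>'} has no length; "
                    "branch lengths are required (weighted UniFrac)"
                )
            if node.length < 0:
                raise ValidationError(f"negative branch length at {node.name}")
        if tree.length is None:
            tree.length = 0.0
        self.tree = tree

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=True))

    def __repr__(self) -> str:
        return f"<PhyloTree {len(self.leaf_names)} leaves>"


class SampleMetadata:
    """One row per sample: genotype, glasshouse block, optional treatments."""

    REQUIRED = ("sample_id", "genotype", "block")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        _check_unique(data["sample_id"], "sample ids")
        data = data.copy()
        for col in ("sample_id", "genotype", "block"):
            data[col] = data[col].astype(str)
        if "nitrogen" in data.columns:
            bad = set(data["nitrogen"].dropna().astype(str)) - set(NITROGEN_LEVELS)
            if bad:
                raise ValidationError(
                    f"unknown nitrogen level(s) {sorted(bad)}; allowed: {NITROGEN_LEVELS}"
                )
        if "microbe" in data.columns:
            bad = set(data["microbe"].dropna().astype(str)) - set(MICROBE_LEVELS)
            if bad:
                raise ValidationError(
                    f"unknown microbe level(s) {sorted(bad)}; allowed: {MICROBE_LEVELS}"
                )
        self.data = data.reset_index(drop=True)

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        indexed = self.data.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing[:5]}")
        return indexed.loc[list(sample_ids)].reset_index()

    def __repr__(self) -> str:
        return f"<SampleMetadata {len(self.data)} samples>"


class GenotypePanel:
    """Per-genotype coordinates and historic-environment covariates."""

    def __init__(self, data: pd.DataFrame):
        required = ["genotype", "lon", "lat", "elevation", *ENV_VARS]
        for col in required:
            if col not in data.columns:
                raise ValidationError(f"panel missing required column {col!r}")
        _check_unique(data["genotype"], "genotypes")
        data = data.copy()
        data["genotype"] = data["genotype"].astype(str)
        num = data[["lon", "lat", "elevation", *ENV_VARS]].apply(
            pd.to_numeric, errors="coerce"
        )
        if num.isna().any().any():
            bad = num.columns[num.isna().any()].tolist()
            raise ValidationError(
                f"panel has missing/non-numeric values in {bad}; "
                "complete environment vectors are required"
            )
        data[num.columns] = num
        self.data = data.reset_index(drop=True)

    @property
    def genotypes(self) -> list[str]:
        return list(self.data["genotype"])

    def env_matrix(self, standardize: bool = True) -> pd.DataFrame:
        env = self.data.set_index("genotype")[list(ENV_VARS) + ["elevation"]]
        if standardize:
            env = (env - env.mean()) / env.std(ddof=0)
        return env

    def soil_nitrogen_z(self) -> pd.Series:
        x = self.data.set_index("genotype")["soil_nitrogen"]
        return (x - x.mean()) / x.std(ddof=0)

    def coordinates(self) -> pd.DataFrame:
        return self.data.set_index("genotype")[["lon", "lat"]]

    def __repr__(self) -> str:
        return f"<GenotypePanel {len(self.data)} genotypes>"


class SSRMatrix:
    """Genotype x locus matrix of integer allele codes; missing allowed (pd.NA)."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 2 or data.shape[1] < 1:
            raise ValidationError("SSR matrix needs >= 2 genotypes and >= 1 locus")
        _check_unique(data.index, "genotypes")
        try:
            data = data.astype("Int64")
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"allele codes must be integers: {exc}") from exc
        data.index = data.index.astype(str)
        data.index.name = "genotype"
        self.data = data

    @property
    def genotypes(self) -> list[str]:
        return list(self.data.index)

    def __repr__(self) -> str:
        g, l = self.data.shape
        return f"<SSRMatrix {g} genotypes x {l} loci>"


class TraitTable:
    """Per-plant trait measurements from the crossed nitrogen x microbe experiment."""

    REQUIRED = ("plant_id", "genotype", "block", "nitrogen", "microbe")
    TRAITS = ("height", "biomass", "tillering")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValidationError(f"trait table missing required column {col!r}")
        _check_unique(data["plant_id"], "plant ids")
        data = data.copy()
        for col in ("plant_id", "genotype", "block"):
            data[col] = data[col].astype(str)
        for col, levels in (("nitrogen", NITROGEN_LEVELS), ("microbe", MICROBE_LEVELS)):
            bad = set(data[col].astype(str)) - set(levels)
            if bad:
                raise ValidationError(
                    f"unknown {col} level(s) {sorted(bad)}; allowed: {levels}"
                )
            data[col] = data[col].astype(str)
        for trait in ("height", "biomass"):
            if trait in data.columns:
                vals = pd.to_numeric(data[trait], errors="coerce")
                if ((vals <= 0) & vals.notna()).any():
                    raise ValidationError(f"{trait} values must be positive")
                data[trait] = vals
        if "tillering" in data.columns:
            vals = pd.to_numeric(data["tillering"], errors="coerce")
            if not vals.dropna().isin([0, 1]).all():
                raise ValidationError("tillering must be binary 0/1")
            data["tillering"] = vals.astype("Int64")
        self.data = data.reset_index(drop=True)

    def __repr__(self) -> str:
        return f"<TraitTable {len(self.data)} plants>"


class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a metric label."""

    def __init__(self, ids: Sequence[str], values: np.ndarray, metric_name: str = ""):
        ids = [str(i) for i in ids]
        _check_unique(ids, "sample ids")
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {values.shape} != ({n},{n})")
        if not np.isfinite(values).all():
            raise ValidationError("distances must be finite")
        if (values < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal must be zero")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        self.ids = list(ids)
        self.values = values
        self.metric_name = metric_name

    @classmethod
    def from_skbio(cls, dm: skbio.DistanceMatrix, metric_name: str = "") -> "DistanceMatrix":
        return cls(list(dm.ids), dm.data, metric_name)

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(str(i)) for i in ids]
        return DistanceMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.metric_name,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:
        return f"<DistanceMatrix {len(self.ids)} samples, metric={self.metric_name!r}>"
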