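"""Community descriptors: rarefaction, alpha diversity, dissimilarity matrices,
beta-dispersion, and functional-group subsetting.

Conventions
-----------
* Shannon entropy uses the natural log; Pielou's evenness H / ln(richness) is
  undefined (NaN) for richness < 2.
* Weighted UniFrac defaults to the raw (non-normalized) variant
  sum_b l_b * |A_b - B_b| over branches b, where A_b and B_b are the fractions
  of each sample's reads descending from b; ``normalized=True`` divides by
  sum_b l_b * (A_b + B_b).
* Rarefaction is a single seeded draw without replacement per sample; samples
  below the target depth are dropped and reported.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio.diversity import beta_diversity

from .datatypes import (
    DistanceMatrix,
    FeatureTable,
    PhyloTree,
    TaxonomyTable,
    ValidationError,
)

__all__ = [
    "rarefy",
    "alpha_metrics",
    "bray_curtis",
    "weighted_unifrac",
    "beta_dispersion",
    "DispersionResult",
    "subset_functional_group",
    "aggregate_to_rank",
]


def rarefy(
    table: FeatureTable, depth: int, seed: int, return_dropped: bool = False
):
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (a warning lists them).
    One draw per sample; the draw is a multivariate hypergeometric sample, so
    rarefied counts never exceed the originals.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    sums = table.row_sums()
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) below depth {depth} dropped: {dropped[:10]}",
            stacklevel=2,
        )
    kept = [s for s in table.sample_ids if sums[s] >= depth]
    out = np.empty((len(kept), table.shape[1]), dtype=np.int64)
    counts = table.data
    for i, s in enumerate(kept):
        row = counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    result = FeatureTable(pd.DataFrame(out, index=kept, columns=table.taxon_ids))
    if return_dropped:
        return result, dropped
    return result


def alpha_metrics(table: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (natural log) and Pielou evenness.

    An all-zero sample gets richness 0 with Shannon/Pielou flagged NaN;
    richness 1 gives Shannon 0 and undefined Pielou (division by ln 1).
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    richness = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(totals))
    for i, (row, tot) in enumerate(zip(counts, totals)):
        if tot == 0:
            shannon[i] = np.nan
            continue
        p = row[row > 0] / tot
        shannon[i] = -np.sum(p * np.log(p))
    pielou = np.full(len(totals), np.nan)
    ok = richness >= 2
    pielou[ok] = shannon[ok] / np.log(richness[ok])
    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "richness": richness,
            "shannon": shannon,
            "pielou": pielou,
        }
    )


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); zero-total pairs -> 0."""
    if table.shape[0] < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    counts = table.counts.astype(float)
    zero_rows = counts.sum(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = squareform(pdist(counts, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn(
            "all-zero samples present; their pairwise Bray-Curtis set to 0 "
            "against other all-zero samples",
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(table.sample_ids, d, "braycurtis")


def weighted_unifrac(
    table: FeatureTable, tree: PhyloTree, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac between all sample pairs.

    Every taxon in the table must be a leaf of the tree (extra leaves are
    fine); a missing taxon is an error rather than a silent prune.
    """
    leaf_set = set(tree.leaf_names)
    missing = [t for t in table.taxon_ids if t not in leaf_set]
    if missing:
        raise ValidationError(
            f"{len(missing)} table taxa absent from tree: {missing[:5]}"
        )
    if (table.counts.sum(axis=1) == 0).any():
        raise ValidationError("weighted UniFrac undefined for all-zero samples")
    dm = beta_diversity(
        "weighted_unifrac",
        table.counts,
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree.tree,
        normalized=normalized,
    )
    name = "weighted_unifrac_normalized" if normalized else "weighted_unifrac"
    return DistanceMatrix.from_skbio(dm, name)


@dataclass
class DispersionResult:
    """Distance-to-centroid (beta-dispersion) per sample, by group."""

    distances: pd.DataFrame  # sample_id, group, dist_to_centroid
    group_means: pd.Series
    skipped_groups: list


def beta_dispersion(dm: DistanceMatrix, groups: pd.Series | dict) -> DispersionResult:
    """Distance of each sample to its group centroid in corrected PCoA space.

    The distance matrix is embedded by principal coordinates keeping both the
    real axes (positive eigenvalues) and imaginary axes (negative
    eigenvalues); squared distance to the group centroid is the real-part
    contribution minus the imaginary-part contribution, floored at zero
    (Anderson's correction for semi-metric dissimilarities).
    """
    from .ordination import pcoa

    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.astype(str)
    missing = [s for s in dm.ids if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without group assignment: {missing[:5]}")
    res = pcoa(dm)
    pos, neg = res.coordinates, res.neg_coordinates
    rows = []
    skipped = []
    for grp, members in groups.loc[dm.ids].groupby(groups.loc[dm.ids]):
        idx = [dm.ids.index(s) for s in members.index]
        if len(idx) < 2:
            warnings.warn(f"group {grp!r} has < 2 members; skipped", stacklevel=2)
            skipped.append(grp)
            continue
        cp = pos[idx].mean(axis=0)
        cn = neg[idx].mean(axis=0) if neg.shape[1] else np.zeros(0)
        for s, i in zip(members.index, idx):
            d2 = np.sum((pos[i] - cp) ** 2)
            if neg.shape[1]:
                d2 -= np.sum((neg[i] - cn) ** 2)
            rows.append((s, grp, np.sqrt(max(d2, 0.0))))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "dist_to_centroid"])
    means = df.groupby("group")["dist_to_centroid"].mean()
    return DispersionResult(distances=df, group_means=means, skipped_groups=skipped)


def subset_functional_group(
    table: FeatureTable, taxonomy: TaxonomyTable, flag: str
) -> tuple[FeatureTable, pd.Series]:
    """Extract the flagged taxa and their per-sample relative abundance.

    Relative abundance uses the parent table's totals (before subsetting), so
    it is the flagged group's share of the whole community.
    """
    flagged = taxonomy.flagged(flag)
    cols = [t for t in table.taxon_ids if t in flagged]
    if not cols:
        warnings.warn(f"flag {flag!r} matches no taxa in the table", stacklevel=2)
    sub = FeatureTable(table.data[cols])
    totals = table.row_sums().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = sub.data.sum(axis=1) / totals
    ra = ra.fillna(0.0)
    ra.name = f"relabund_{flag}"
    return sub, ra


def aggregate_to_rank(
    table: FeatureTable, taxonomy: TaxonomyTable, rank: str
) -> FeatureTable:
    """Merge ASV columns sharing a rank label; unlabeled ASVs pool into
    'unclassified'. ``rank='asv'`` is the identity."""
    if rank.lower() in ("asv", "taxon", "taxon_id"):
        return FeatureTable(table.data.copy())
    if rank not in taxonomy.ranks.columns:
        raise KeyError(f"rank {rank!r} not in taxonomy (have {list(taxonomy.ranks.columns)})")
    labels = {}
    for taxon in table.taxon_ids:
        if taxon in taxonomy.ranks.index:
            lab = str(taxonomy.ranks.loc[taxon, rank]).strip()
            labels[taxon] = lab if lab else "unclassified"
        else:
            labels[taxon] = "unclassified"
    grouped = table.data.T.groupby(pd.Series(labels)).sum().T
    return FeatureTable(grouped)
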