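"""Synthetic study generator: genotype panels, SSR markers, phylogenies,
rhizosphere count tables, and the crossed nitrogen x microbe trait experiment.

The generator emulates a common-garden design: ~40 wild grass genotypes
collected across an Anatolian-scale landscape (lon 26-45, lat 36-42), each
grown in replicate across glasshouse blocks, with amplicon count tables per
marker; and a second experiment crossing 10 genotypes with 2 nitrogen x 2
microbe treatments at 10 replicates (400 pots, ~27% germination failure,
~291 surviving plants).

Community counts are Dirichlet-multinomial: per-sample composition logits are
taxon baselines + per-genotype loadings + environmental responses + block
shifts; the Dirichlet concentration is ``dispersion * composition`` and the
read depth is Poisson around the configured mean. Two calibrated gradients
tied to historic soil nitrogen are planted where configured:

* a diazotroph richness gradient implemented by occupancy thinning
  (Bernoulli presence per taxon per genotype), interpolating the expected
  number of occupied-and-detected taxa between the configured endpoints
  (default 25 at the nitrogen-poor extreme to 12 at the nitrogen-rich one);
* an ammonia-oxidizer relative-abundance gradient implemented by fixing the
  flagged group's expected share of the community (default 0.85% to 1.12%).

All generators are deterministic given their seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import skbio
from scipy.stats import betabinom

from .datatypes import (
    ENV_VARS,
    FeatureTable,
    GenotypePanel,
    PhyloTree,
    SampleMetadata,
    SSRMatrix,
    TaxonomyTable,
    TraitTable,
    ValidationError,
)

__all__ = [
    "CommunityEffectSpec",
    "TraitEffectSpec",
    "default_env_corr",
    "gen_panel",
    "gen_ssr",
    "gen_tree",
    "gen_taxonomy",
    "gen_feature_table",
    "select_spanning_subset",
    "gen_experiment2_traits",
    "calibrate_genotype_sd",
    "spec_16s",
    "spec_nifh",
    "null_community_spec",
]


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

#: Bounding box of the emulated native range (decimal degrees).
LON_RANGE = (26.0, 45.0)
LAT_RANGE = (36.0, 42.0)

#: Fraction of environmental variance that is spatially unstructured.
ENV_NUGGET = 0.3


def default_env_corr() -> np.ndarray:
    """Cross-correlation of the 9 historic-environment covariates, built from
    a soil-fertility factor and a climate/precipitation factor (PSD by
    construction)."""
    # loadings: soil_n, soil_p, cec, ph, temp, p_spring, p_summer, p_fall, map
    fert = np.array([0.8, 0.7, 0.6, 0.4, 0.0, 0.1, 0.1, 0.1, 0.1])
    clim = np.array([0.1, 0.0, 0.1, -0.2, -0.5, 0.8, 0.6, 0.7, 0.9])
    C = np.outer(fert, fert) + np.outer(clim, clim)
    resid = 1.0 - np.clip(np.diag(C), 0.0, 0.95)
    C = C + np.diag(resid)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def _haversine_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lo, la = np.radians(lon), np.radians(lat)
    dlo = lo[:, None] - lo[None, :]
    dla = la[:, None] - la[None, :]
    a = np.sin(dla / 2) ** 2 + np.cos(la[:, None]) * np.cos(la[None, :]) * np.sin(dlo / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _spatial_chol(D: np.ndarray, range_km: float) -> np.ndarray:
    n = D.shape[0]
    if range_km <= 0:
        return np.eye(n)
    K = np.exp(-D / range_km) + 1e-8 * np.eye(n)
    return np.linalg.cholesky(K)


#: (offset, scale, lower clip) mapping standardized fields to plausible units.
_ENV_SCALES = {
    "soil_nitrogen": (1.5, 0.6, 0.1),       # g N / kg soil
    "soil_phosphorus": (30.0, 12.0, 1.0),   # mg P / kg
    "cec": (20.0, 6.0, 1.0),                # cmol+ / kg
    "ph": (7.2, 0.5, 4.0),
    "mean_annual_temp": (12.0, 3.0, -10.0),  # deg C
    "precip_spring": (180.0, 60.0, 5.0),    # mm
    "precip_summer": (80.0, 40.0, 2.0),
    "precip_fall": (150.0, 50.0, 5.0),
    "mean_annual_precip": (550.0, 150.0, 50.0),
}


def gen_panel(
    n_genotypes: int = 40,
    spatial_range_km: float = 300.0,
    env_corr: np.ndarray | None = None,
    seed: int = 0,
) -> GenotypePanel:
    """Genotype source locations plus spatially autocorrelated historic
    environments (exponential-kernel Gaussian process + independent nugget,
    then scaled to plausible units)."""
    if n_genotypes < 3:
        raise ValueError("need at least 3 genotypes")
    if env_corr is None:
        env_corr = default_env_corr()
    env_corr = np.asarray(env_corr, float)
    if env_corr.shape != (len(ENV_VARS), len(ENV_VARS)):
        raise ValueError(f"env_corr must be {len(ENV_VARS)}x{len(ENV_VARS)}")
    evals = np.linalg.eigvalsh((env_corr + env_corr.T) / 2)
    if evals.min() < -1e-10:
        raise ValueError("env_corr must be positive semidefinite")

    rng = np.random.default_rng(seed)
    lon = rng.uniform(*LON_RANGE, n_genotypes)
    lat = rng.uniform(*LAT_RANGE, n_genotypes)
    D = _haversine_km(lon, lat)
    L = _spatial_chol(D, spatial_range_km)
    k = len(ENV_VARS)
    spatial = L @ rng.standard_normal((n_genotypes, k))
    nugget = rng.standard_normal((n_genotypes, k))
    raw = np.sqrt(1 - ENV_NUGGET) * spatial + np.sqrt(ENV_NUGGET) * nugget
    Lc = np.linalg.cholesky(env_corr + 1e-10 * np.eye(k))
    fields = raw @ Lc.T
    fields = (fields - fields.mean(axis=0)) / fields.std(axis=0, ddof=0)

    data = {"genotype": [f"G{i+1:03d}" for i in range(n_genotypes)],
            "lon": lon, "lat": lat}
    elev = 800.0 + 300.0 * (L @ rng.standard_normal(n_genotypes)) \
        + 100.0 * rng.standard_normal(n_genotypes)
    data["elevation"] = np.clip(elev, 0.0, None)
    for j, var in enumerate(ENV_VARS):
        off, scale, lo = _ENV_SCALES[var]
        data[var] = np.clip(off + scale * fields[:, j], lo, None)
    return GenotypePanel(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# SSR markers and phylogeny
# ---------------------------------------------------------------------------

def gen_ssr(
    panel: GenotypePanel,
    n_loci: int = 20,
    ibd_strength: float = 1.0,
    seed: int = 0,
    n_alleles: int = 4,
    missing_rate: float = 0.02,
    range_km: float = 300.0,
) -> SSRMatrix:
    """SSR allele matrix with isolation-by-distance: per-locus latent values
    mix a spatial Gaussian process (weight ``ibd_strength``) with independent
    noise, then discretize into allele classes. ibd_strength = 0 gives
    spatially unstructured markers."""
    if n_loci < 1:
        raise ValueError("need at least one locus")
    rng = np.random.default_rng(seed)
    coords = panel.coordinates().to_numpy()
    D = _haversine_km(coords[:, 0], coords[:, 1])
    L = _spatial_chol(D, range_km)
    n = len(panel.genotypes)
    w = ibd_strength / np.sqrt(1.0 + ibd_strength**2)
    alleles = np.empty((n, n_loci), dtype=float)
    for l in range(n_loci):
        latent = w * (L @ rng.standard_normal(n)) \
            + np.sqrt(1 - w**2) * rng.standard_normal(n)
        edges = np.quantile(latent, np.linspace(0, 1, n_alleles + 1)[1:-1])
        alleles[:, l] = np.digitize(latent, edges)
    df = pd.DataFrame(
        alleles.astype(int),
        index=panel.genotypes,
        columns=[f"locus{l+1:02d}" for l in range(n_loci)],
    ).astype("Int64")
    mask = rng.random((n, n_loci)) < missing_rate
    df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return SSRMatrix(df)


def gen_tree(taxon_ids: list[str], seed: int = 0) -> PhyloTree:
    """Random Kingman-coalescent rooted tree over exactly the given taxa.

    Pair-merge times are exponential with rate C(k,2); the root branch uses
    the zero-length convention."""
    ids = [str(t) for t in taxon_ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    nodes = [(skbio.TreeNode(name=t), 0.0) for t in ids]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = nodes[i], nodes[j]
        a.length = t - ha
        b.length = t - hb
        parent = skbio.TreeNode(children=[a, b])
        nodes[j] = (parent, t)
        del nodes[i]
    root = nodes[0][0]
    root.length = 0.0
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Community count tables
# ---------------------------------------------------------------------------

@dataclass
class CommunityEffectSpec:
    """Effect sizes and noise structure for one amplicon group's count table.

    ``richness_gradient`` plants a declining occupied-taxon gradient along
    historic soil nitrogen in the taxa carrying ``richness_flag`` (all taxa
    if the flag is None); ``group_ra_gradient`` pins the expected community
    share of the taxa carrying ``ra_flag``. Effects of zero everywhere give
    exchangeable samples.
    """

    n_taxa: int = 400
    baseline_sd: float = 1.2          # log-abundance spread across taxa
    genotype_sd: float = 0.236        # per-genotype taxon log-loading SD (calibrated)
    env_responders: float = 0.10      # fraction of taxa responding to soil N
    env_beta: float = 0.5             # log-abundance slope per SD of soil N
    block_sd: float = 0.12            # glasshouse block log shift SD
    depth: int = 10000                # mean sequencing depth (Poisson)
    dispersion: float = 200.0         # Dirichlet concentration scale
    richness_gradient: tuple[float, float] | None = None   # (low-N, high-N)
    richness_flag: str | None = "diazotroph_16s_match"
    group_ra_gradient: tuple[float, float] | None = None   # shares in (0,1)
    ra_flag: str = "ammonia_oxidizer"

    def __post_init__(self):
        if not 0 <= self.env_responders <= 1:
            raise ValueError("env_responders must be in [0, 1]")
        if self.depth <= 0 or self.n_taxa < 2:
            raise ValueError("depth and n_taxa must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.group_ra_gradient is not None:
            lo, hi = self.group_ra_gradient
            if not (0 < lo < 1 and 0 < hi < 1):
                raise ValueError("group relative abundances must be in (0, 1)")


def spec_16s() -> CommunityEffectSpec:
    """Default broad bacterial community: 400 taxa, ammonia-oxidizer share
    gradient 0.85% -> 1.12% along historic soil nitrogen."""
    return CommunityEffectSpec(
        n_taxa=400,
        depth=10000,
        group_ra_gradient=(0.0085, 0.0112),
        richness_gradient=None,
    )


def spec_nifh() -> CommunityEffectSpec:
    """Default diazotroph (nifH) community: 40 taxa, occupied richness
    declining 25 -> 12 along historic soil nitrogen."""
    return CommunityEffectSpec(
        n_taxa=40,
        baseline_sd=0.8,
        depth=4000,
        dispersion=300.0,
        richness_gradient=(25.0, 12.0),
        richness_flag=None,   # the whole marker is the functional group
        group_ra_gradient=None,
    )


def null_community_spec(n_taxa: int = 100, depth: int = 2000) -> CommunityEffectSpec:
    """All planted effects zero: samples are exchangeable."""
    return CommunityEffectSpec(
        n_taxa=n_taxa, genotype_sd=0.0, env_responders=0.0, env_beta=0.0,
        block_sd=0.0, depth=depth, richness_gradient=None,
        group_ra_gradient=None,
    )


def gen_taxonomy(
    group: str,
    n_taxa: int,
    seed: int = 0,
    n_ammonia_oxidizers: int = 25,
    n_diazotroph_matches: int = 30,
) -> TaxonomyTable:
    """Fabricated rank labels plus functional-group flags for one marker.

    For a broad 16S-like group, disjoint subsets are flagged as ammonia
    oxidizers and diazotroph matches; for nifH all taxa are diazotrophs and
    for 18S-AMF all are Glomeromycota.
    """
    rng = np.random.default_rng(seed)
    ids = [f"{group}_asv{i+1:04d}" for i in range(n_taxa)]
    n_orders = max(n_taxa // 12, 2)
    n_genera = max(n_taxa // 4, 2)
    ranks = pd.DataFrame(
        {
            "domain": ["Bacteria"] * n_taxa,
            "phylum": [f"phylum{rng.integers(1, 9)}" for _ in ids],
            "class": [f"class{rng.integers(1, 15)}" for _ in ids],
            "order": [f"order{rng.integers(1, n_orders + 1)}" for _ in ids],
            "family": [f"family{rng.integers(1, n_genera + 1)}" for _ in ids],
            "genus": [f"genus{rng.integers(1, n_genera + 1)}" for _ in ids],
        },
        index=pd.Index(ids, name="taxon_id"),
    )
    flags: dict[str, frozenset] = {}
    if group == "16s":
        chosen = rng.choice(n_taxa, size=n_ammonia_oxidizers + n_diazotroph_matches,
                            replace=False)
        flags["ammonia_oxidizer"] = frozenset(ids[i] for i in chosen[:n_ammonia_oxidizers])
        flags["diazotroph_16s_match"] = frozenset(
            ids[i] for i in chosen[n_ammonia_oxidizers:]
        )
    elif group == "nifh":
        flags["diazotroph_16s_match"] = frozenset(ids)
    elif group in ("18s_amf", "its2"):
        flags["glomeromycota"] = frozenset(ids)
    return TaxonomyTable(ranks=ranks, flags=flags)


def _softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _mean_detection(spec: CommunityEffectSpec, expected_richness: float) -> float:
    """Expected probability that an occupied taxon is seen at least once,
    under the Dirichlet-multinomial with roughly even shares."""
    share = 1.0 / max(expected_richness, 1.0)
    a = spec.dispersion * share
    b = max(spec.dispersion - a, 1e-6)
    p0 = float(betabinom.pmf(0, spec.depth, a, b))
    return max(1.0 - p0, 1e-3)


def gen_feature_table(
    panel: GenotypePanel,
    n_replicates: int = 5,
    n_blocks: int = 5,
    spec: CommunityEffectSpec | None = None,
    taxonomy: TaxonomyTable | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, SampleMetadata]:
    """Dirichlet-multinomial count table for one marker over the panel's
    genotypes, replicated across glasshouse blocks (replicate r sits in
    block r, emulating racks as blocks)."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per genotype")
    spec = spec or spec_16s()
    if taxonomy is None:
        taxonomy = gen_taxonomy("16s", spec.n_taxa, seed=seed)
    taxa = taxonomy.taxon_ids
    if len(taxa) != spec.n_taxa:
        raise ValidationError(
            f"taxonomy has {len(taxa)} taxa but spec expects {spec.n_taxa}"
        )
    rng = np.random.default_rng(seed)
    genotypes = panel.genotypes
    n_g, n_t = len(genotypes), len(taxa)
    z = panel.soil_nitrogen_z().to_numpy()
    z01 = (z - z.min()) / (z.max() - z.min()) if np.ptp(z) > 0 else np.zeros(n_g)

    baseline = rng.normal(0.0, spec.baseline_sd, n_t)
    beta = np.zeros(n_t)
    n_resp = int(round(spec.env_responders * n_t))
    if n_resp and spec.env_beta != 0.0:
        resp = rng.choice(n_t, size=n_resp, replace=False)
        beta[resp] = spec.env_beta * rng.choice([-1.0, 1.0], size=n_resp)
    load = rng.normal(0.0, spec.genotype_sd, (n_g, n_t)) if spec.genotype_sd > 0 else np.zeros((n_g, n_t))
    shift = rng.normal(0.0, spec.block_sd, (n_blocks, n_t)) if spec.block_sd > 0 else np.zeros((n_blocks, n_t))

    # occupancy thinning for the richness gradient
    if spec.richness_gradient is not None:
        if spec.richness_flag is None:
            rich_idx = np.arange(n_t)
        else:
            flagged = taxonomy.flagged(spec.richness_flag)
            rich_idx = np.array([i for i, t in enumerate(taxa) if t in flagged])
            if rich_idx.size == 0:
                raise ValidationError(
                    f"richness flag {spec.richness_flag!r} matches no taxa"
                )
        r_lo, r_hi = spec.richness_gradient
        target = r_lo + (r_hi - r_lo) * z01            # per genotype
        det = _mean_detection(spec, (r_lo + r_hi) / 2.0)
        occ_p = np.clip(target / (rich_idx.size * det), 0.0, 1.0)
        present = np.ones((n_g, n_t), dtype=bool)
        present[:, rich_idx] = rng.random((n_g, rich_idx.size)) < occ_p[:, None]
    else:
        present = np.ones((n_g, n_t), dtype=bool)

    # ammonia-oxidizer share gradient
    ao_idx = None
    if spec.group_ra_gradient is not None:
        flagged = taxonomy.flagged(spec.ra_flag)
        ao_idx = np.array([i for i, t in enumerate(taxa) if t in flagged])
        if ao_idx.size == 0:
            raise ValidationError(f"ra flag {spec.ra_flag!r} matches no taxa")
        ra_lo, ra_hi = spec.group_ra_gradient
        ao_target = ra_lo + (ra_hi - ra_lo) * z01

    rows, sample_ids, meta_rows = [], [], []
    for gi, g in enumerate(genotypes):
        for rep in range(n_replicates):
            block = rep % n_blocks
            logits = baseline + load[gi] + beta * z[gi] + shift[block]
            mask = present[gi]
            p = np.zeros(n_t)
            if ao_idx is not None:
                non_ao = np.setdiff1d(np.where(mask)[0], ao_idx)
                ao_on = ao_idx[mask[ao_idx]]
                t_share = ao_target[gi]
                p[non_ao] = _softmax(logits[non_ao]) * (1.0 - t_share)
                if ao_on.size:
                    p[ao_on] = _softmax(logits[ao_on]) * t_share
            else:
                on = np.where(mask)[0]
                p[on] = _softmax(logits[on])
            on = p > 0
            alpha = spec.dispersion * p[on]
            gam = rng.gamma(alpha)
            if gam.sum() == 0:
                gam = np.ones_like(gam)
            comp = np.zeros(n_t)
            comp[on] = gam / gam.sum()
            depth_s = rng.poisson(spec.depth)
            counts = rng.multinomial(depth_s, comp)
            sid = f"{g}_r{rep+1}"
            rows.append(counts)
            sample_ids.append(sid)
            meta_rows.append(dict(sample_id=sid, genotype=g, block=f"B{block+1}"))

    table = FeatureTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa)
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return table, meta


def calibrate_genotype_sd(
    panel: GenotypePanel,
    spec: CommunityEffectSpec,
    target_r2: tuple[float, float] = (0.21, 0.31),
    n_replicates: int = 5,
    n_seeds: int = 5,
    seed: int = 0,
    tol: float = 0.02,
    bounds: tuple[float, float] = (0.05, 2.0),
    max_iter: int = 12,
) -> float:
    """Bisection search for the per-genotype loading SD whose PERMANOVA
    genotype R^2 (Bray-Curtis) hits the middle of ``target_r2``.

    Monte-Carlo estimate over ``n_seeds`` tables per candidate; stops within
    ``tol`` (R^2 points) of the band midpoint.
    """
    from dataclasses import replace
    from .community import bray_curtis
    from .ordination import permanova

    target = (target_r2[0] + target_r2[1]) / 2.0

    def measure(sd: float) -> float:
        vals = []
        for s in range(n_seeds):
            sp = replace(spec, genotype_sd=sd)
            tab, meta = gen_feature_table(
                panel, n_replicates=n_replicates, spec=sp, seed=seed + 1000 * s
            )
            dm = bray_curtis(tab)
            design = meta.for_samples(tab.sample_ids)
            res = permanova(dm, design, ["genotype", "block"], n_perm=99,
                            seed=seed + s)
            vals.append(float(res.loc[res.term == "genotype", "R2"].iloc[0]))
        return float(np.mean(vals))

    lo, hi = bounds
    r_lo, r_hi = measure(lo), measure(hi)
    if not (r_lo < target < r_hi):
        warnings.warn(
            f"target R2 {target:.2f} outside measured range "
            f"[{r_lo:.2f}, {r_hi:.2f}]; returning nearest bound", stacklevel=2
        )
        return lo if abs(r_lo - target) < abs(r_hi - target) else hi
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        r_mid = measure(mid)
        if abs(r_mid - target) <= tol:
            return float(mid)
        if r_mid < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# Experiment 2: crossed nitrogen x microbe trait table
# ---------------------------------------------------------------------------

@dataclass
class TraitEffectSpec:
    """Planted structure of the nitrogen x microbe experiment.

    The expected microbial effect for genotype g in glasshouse nitrogen level
    e is ``me_intercept + me_slope_e * soil_nitrogen_z(g)`` — opposite-signed
    default slopes plant the environment-dependent reaction norms. Random
    intercept and residual SDs are relative to each trait's baseline.
    ``germination_failure`` rows go missing completely at random (400 pots at
    the default rate leave 291 plants in expectation).
    """

    baselines: dict = field(
        default_factory=lambda: {"height": 20.0, "biomass": 0.55}  # cm, g
    )
    nitrogen_effect: float = 0.35       # proportional gain under high N
    me_intercept: float = 0.05
    me_slope_lowN: float = -0.12        # ME slope per SD historic soil N, low-N pots
    me_slope_highN: float = 0.12        # same, high-N pots
    genotype_sd: float = 0.04           # relative random-intercept SDs
    block_sd: float = 0.03
    residual_sd: float = 0.12
    tiller_logit_coefs: dict = field(
        default_factory=lambda: {
            "intercept": -0.3, "nitrogen": 0.8, "microbe": 0.4, "hist_n": 0.2,
        }
    )
    germination_failure: float = 0.2725

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if any(b <= 0 for b in self.baselines.values()):
            raise ValueError("trait baselines must be positive")
        if not 0 <= self.germination_failure < 1:
            raise ValueError("germination_failure must be in [0, 1)")


def select_spanning_subset(panel: GenotypePanel, k: int = 10) -> GenotypePanel:
    """Pick k genotypes evenly spaced along the historic soil-nitrogen
    gradient (guarantees the subset spans the range)."""
    if k < 2 or k > len(panel.genotypes):
        raise ValueError("subset size out of range")
    order = panel.data.sort_values("soil_nitrogen").reset_index(drop=True)
    idx = np.unique(np.round(np.linspace(0, len(order) - 1, k)).astype(int))
    return GenotypePanel(order.iloc[idx].reset_index(drop=True))


def gen_experiment2_traits(
    panel_subset: GenotypePanel,
    spec: TraitEffectSpec | None = None,
    n_replicates: int = 10,
    seed: int = 0,
) -> tuple[TraitTable, dict]:
    """Trait table for the 2 nitrogen x 2 microbe experiment.

    trait = baseline * (1 + nitrogen_effect * 1[high N])
                     * (1 + microbial effect, live pots only)
            + genotype and block random intercepts + Gaussian noise,
    with the microbial effect linear in standardized historic soil nitrogen
    within each glasshouse level. Tillering is Bernoulli on a logistic linear
    predictor. Returns the table and the planted-truth dictionary.
    """
    spec = spec or TraitEffectSpec()
    if len(panel_subset.genotypes) < 2:
        raise ValueError("need at least 2 genotypes")
    if n_replicates < 3:
        raise ValueError("need at least 3 replicates")
    rng = np.random.default_rng(seed)
    genotypes = panel_subset.genotypes
    z = panel_subset.soil_nitrogen_z()
    n_blocks = n_replicates

    g_int = {
        trait: rng.normal(0.0, spec.genotype_sd * base, len(genotypes))
        for trait, base in spec.baselines.items()
    }
    b_int = {
        trait: rng.normal(0.0, spec.block_sd * base, n_blocks)
        for trait, base in spec.baselines.items()
    }

    rows = []
    pid = 0
    for gi, g in enumerate(genotypes):
        zg = float(z[g])
        for nitrogen in ("low", "high"):
            slope = spec.me_slope_lowN if nitrogen == "low" else spec.me_slope_highN
            me = spec.me_intercept + slope * zg
            for microbe in ("live", "sterile"):
                for rep in range(n_replicates):
                    pid += 1
                    block = rep % n_blocks
                    row = dict(
                        plant_id=f"P{pid:04d}", genotype=g, block=f"B{block+1}",
                        nitrogen=nitrogen, microbe=microbe,
                    )
                    for trait, base in spec.baselines.items():
                        mu = base * (1.0 + spec.nitrogen_effect * (nitrogen == "high"))
                        mu *= 1.0 + (me if microbe == "live" else 0.0)
                        val = (
                            mu + g_int[trait][gi] + b_int[trait][block]
                            + rng.normal(0.0, spec.residual_sd * base)
                        )
                        row[trait] = max(val, 0.01 * base)
                    c = spec.tiller_logit_coefs
                    logit = (
                        c["intercept"]
                        + c["nitrogen"] * (nitrogen == "high")
                        + c["microbe"] * (microbe == "live")
                        + c["hist_n"] * zg
                    )
                    row["tillering"] = int(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
                    rows.append(row)
    df = pd.DataFrame(rows)
    surviving = rng.random(len(df)) >= spec.germination_failure
    df = df[surviving].reset_index(drop=True)
    truth = dict(
        spec=asdict(spec),
        n_pots=len(rows),
        n_surviving=int(surviving.sum()),
        genotypes=list(genotypes),
        soil_nitrogen_z={g: float(z[g]) for g in genotypes},
        seed=seed,
    )
    return TraitTable(df), truth
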