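"""End-to-end orchestration: simulate -> rarefy -> metrics -> PERMANOVA ->
conditioned dbRDA with forward selection -> trait mixed models ->
microbial-effect inference.

Every stage writes plain-text outputs (TSV/JSON) into the run directory; the
bundle embeds the seed and package version and is byte-identical across
repeat runs with the same configuration. Stage failures abort with the stage
name and the underlying cause.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, community, io, mefx, mixedmodels, ordination, synthetic
from .config import RunConfig
from .datatypes import FeatureTable, SampleMetadata

__all__ = ["run_pipeline", "simulate_inputs", "StageError"]

log = logging.getLogger("rhizoadapt")

MARKERS = ("16s", "nifh")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _seeds(config: RunConfig) -> dict[str, int]:
    """Deterministic per-stage substreams derived from the run seed."""
    ss = np.random.SeedSequence(config.seed)
    names = [
        "panel", "ssr", "tree_16s", "tree_nifh", "tax_16s", "tax_nifh",
        "feat_16s", "feat_nifh", "traits", "rarefy_16s", "rarefy_nifh",
        "permanova", "selection", "mefx",
    ]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def simulate_inputs(config: RunConfig, out: Path) -> dict:
    """Generate and write all study inputs; returns them in memory too."""
    s = _seeds(config)
    panel = synthetic.gen_panel(
        config.n_genotypes, config.spatial_range_km, seed=s["panel"]
    )
    ssr = synthetic.gen_ssr(
        panel, config.n_loci, config.ibd_strength, seed=s["ssr"],
        range_km=config.spatial_range_km,
    )
    specs = {"16s": synthetic.spec_16s(), "nifh": synthetic.spec_nifh()}
    bundle: dict = {"panel": panel, "ssr": ssr, "specs": specs}
    io.write_panel(panel, out / "panel.tsv")
    io.write_ssr(ssr, out / "ssr.tsv")
    meta = None
    for marker in MARKERS:
        tax = synthetic.gen_taxonomy(marker, specs[marker].n_taxa, seed=s[f"tax_{marker}"])
        tree = synthetic.gen_tree(tax.taxon_ids, seed=s[f"tree_{marker}"])
        table, meta = synthetic.gen_feature_table(
            panel, config.n_replicates, config.n_blocks,
            spec=specs[marker], taxonomy=tax, seed=s[f"feat_{marker}"],
        )
        bundle[f"taxonomy_{marker}"] = tax
        bundle[f"tree_{marker}"] = tree
        bundle[f"features_{marker}"] = table
        io.write_taxonomy(tax, out / f"taxonomy_{marker}.tsv")
        io.write_tree(tree, out / f"tree_{marker}.nwk")
        io.write_feature_table(table, out / f"features_{marker}.tsv")
    bundle["metadata"] = meta
    io.write_metadata(meta, out / "metadata.tsv")

    subset = synthetic.select_spanning_subset(panel, config.n_genotypes_subset)
    traits, truth = synthetic.gen_experiment2_traits(
        subset, n_replicates=config.n_replicates_expt2, seed=s["traits"]
    )
    bundle["panel_subset"] = subset
    bundle["traits"] = traits
    io.write_traits(traits, out / "traits.tsv")
    io.write_json(
        dict(truth=truth, seed=config.seed, version=__version__),
        out / "truth.json",
    )
    return bundle


def _rarefy_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    s = _seeds(config)
    depths = {"16s": config.rarefaction_depth_16s, "nifh": config.rarefaction_depth_nifh}
    for marker in MARKERS:
        table = bundle[f"features_{marker}"]
        rare, dropped = community.rarefy(
            table, depths[marker], seed=s[f"rarefy_{marker}"], return_dropped=True
        )
        log.info("rarefied %s to %d (%d samples dropped)", marker, depths[marker], len(dropped))
        bundle[f"rarefied_{marker}"] = rare
        bundle[f"dropped_{marker}"] = dropped
        io.write_feature_table(rare, out / f"rarefied_{marker}.tsv")


def _metrics_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    meta: SampleMetadata = bundle["metadata"]
    for marker in MARKERS:
        table: FeatureTable = bundle[f"rarefied_{marker}"]
        alpha = community.alpha_metrics(table)
        alpha.to_csv(out / f"alpha_{marker}.tsv", sep="\t", index=False,
                     float_format="%.10g")
        bundle[f"alpha_{marker}"] = alpha
        bc = community.bray_curtis(table)
        bundle[f"dist_braycurtis_{marker}"] = bc
        io.write_distance_matrix(bc, out / f"dist_braycurtis_{marker}.tsv")
        wu = community.weighted_unifrac(
            table, bundle[f"tree_{marker}"], normalized=config.unifrac_normalized
        )
        bundle[f"dist_wunifrac_{marker}"] = wu
        io.write_distance_matrix(wu, out / f"dist_wunifrac_{marker}.tsv")
        groups = meta.for_samples(table.sample_ids).set_index("sample_id")["genotype"]
        disp = community.beta_dispersion(bc, groups)
        disp.distances.to_csv(out / f"dispersion_{marker}.tsv", sep="\t",
                              index=False, float_format="%.10g")
        bundle[f"dispersion_{marker}"] = disp
    # ammonia-oxidizer share of the 16S community
    _, ra = community.subset_functional_group(
        bundle["rarefied_16s"], bundle["taxonomy_16s"], "ammonia_oxidizer"
    )
    ra_df = ra.rename("ao_relabund").rename_axis("sample_id").reset_index()
    ra_df.to_csv(out / "group_ra.tsv", sep="\t", index=False, float_format="%.10g")
    bundle["ao_relabund"] = ra_df


def _permanova_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    s = _seeds(config)
    meta: SampleMetadata = bundle["metadata"]
    frames = []
    for marker in MARKERS:
        for metric in ("braycurtis", "wunifrac"):
            dm = bundle[f"dist_{metric}_{marker}"]
            design = meta.for_samples(dm.ids)
            tab = ordination.permanova(
                dm, design, ["genotype", "block"],
                n_perm=config.n_permutations, seed=s["permanova"],
            )
            tab.insert(0, "marker", marker)
            tab.insert(1, "metric", metric)
            frames.append(tab)
    permanova_tab = pd.concat(frames, ignore_index=True)
    permanova_tab.to_csv(out / "permanova.tsv", sep="\t", index=False,
                         float_format="%.10g")
    bundle["permanova"] = permanova_tab


def _dbrda_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    s = _seeds(config)
    panel = bundle["panel"]
    meta: SampleMetadata = bundle["metadata"]
    env = panel.env_matrix(standardize=True)

    def _basis(dm_src, source):
        basis = ordination.dbmem(dm_src, source=source)
        if config.mem_subset == "broad":
            basis = ordination.select_broad_mems(basis)
        return basis

    conditions = {}
    if "geo" in config.conditions():
        conditions["geo"] = _basis(
            ordination.haversine_distance_matrix(panel), "geographic"
        )
    if "ssr" in config.conditions():
        conditions["ssr"] = _basis(
            ordination.hamming_distance_matrix(bundle["ssr"]), "genetic"
        )

    results = {}
    for marker in MARKERS:
        for metric in ("braycurtis", "wunifrac"):
            dm = bundle[f"dist_{metric}_{marker}"]
            genos = meta.for_samples(dm.ids)["genotype"]
            predictors = ordination.expand_to_samples(env, genos)
            predictors.index = dm.ids
            cond_cols = []
            for name, basis in conditions.items():
                mem = pd.DataFrame(
                    basis.eigenvectors,
                    index=basis.ids,
                    columns=[f"{name}_mem{i+1}" for i in range(basis.eigenvectors.shape[1])],
                )
                cond_cols.append(
                    ordination.expand_to_samples(mem, genos).to_numpy()
                )
            condition = np.hstack(cond_cols) if cond_cols else None
            model = ordination.forward_select(
                dm, predictors, condition=condition, alpha=config.alpha,
                n_perm=config.selection_permutations, seed=s["selection"],
                groups=genos.to_numpy(),
            )
            results[f"{marker}_{metric}"] = model.to_dict()
    io.write_json(dict(seed=config.seed, version=__version__, models=results),
                  out / "dbrda.json")
    bundle["dbrda"] = results


def _env_diversity_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    panel = bundle["panel"]
    meta = bundle["metadata"]
    env = panel.data.set_index("genotype")["soil_nitrogen"]
    results = {}
    # diazotroph richness vs historic soil N
    alpha_nifh = bundle["alpha_nifh"]
    md = meta.for_samples(list(alpha_nifh["sample_id"]))
    fit = mixedmodels.fit_env_diversity_model(
        alpha_nifh, "richness", md, env
    )
    results["diazotroph_richness_vs_soil_n"] = dict(
        slope=fit["slope"], se=fit["se"], p=fit["p"]
    )
    # ammonia-oxidizer relative abundance vs historic soil N
    ra = bundle["ao_relabund"]
    md_16s = meta.for_samples(list(ra["sample_id"]))
    fit = mixedmodels.fit_env_diversity_model(ra, "ao_relabund", md_16s, env)
    results["ao_relabund_vs_soil_n"] = dict(
        slope=fit["slope"], se=fit["se"], p=fit["p"]
    )
    io.write_json(dict(seed=config.seed, version=__version__, models=results),
                  out / "env_diversity.json")
    bundle["env_diversity"] = results


def _traits_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    traits = bundle["traits"]
    subset = bundle["panel_subset"]
    data = traits.data.copy()
    z = subset.soil_nitrogen_z()
    data["hist_n"] = z.loc[data["genotype"]].to_numpy()
    fixed = mixedmodels.full_factorial(["hist_n", "microbe", "nitrogen"])
    bundle["anova"] = {}
    for trait, family in (("height", "gaussian"), ("biomass", "gaussian"),
                          ("tillering", "binomial")):
        spec = mixedmodels.ModelSpec(
            response=trait, fixed=fixed, random=["genotype", "block"],
            family=family,
        )
        fit = mixedmodels.fit_mixed_model(data, spec)
        tab = mixedmodels.anova_table(fit, type="marginal")
        tab.insert(0, "response", trait)
        tab.to_csv(out / f"anova_{trait}.tsv", sep="\t", index=False,
                   float_format="%.10g")
        bundle["anova"][trait] = tab
        if fit.singular:
            log.info("%s model: singular fit (%s); random terms retained",
                     trait, ",".join(fit.singular_terms))


def _mefx_stage(config: RunConfig, bundle: dict, out: Path) -> None:
    s = _seeds(config)
    traits = bundle["traits"]
    subset = bundle["panel_subset"]
    meta = bundle["metadata"]
    hist_n = subset.data.set_index("genotype")["soil_nitrogen"]

    # genotype-level microbiome traits from experiment 1
    alpha_nifh = bundle["alpha_nifh"].merge(
        meta.for_samples(list(bundle["alpha_nifh"]["sample_id"])), on="sample_id"
    )
    nfix_richness = alpha_nifh.groupby("genotype")["richness"].mean()
    ra = bundle["ao_relabund"].merge(
        meta.for_samples(list(bundle["ao_relabund"]["sample_id"])), on="sample_id"
    )
    ao_ra = ra.groupby("genotype")["ao_relabund"].mean()

    results = {}
    rng = np.random.default_rng(s["mefx"])
    for trait in ("height", "biomass"):
        ests = mefx.compute_microbial_effect(traits, trait)
        mefx.attach_uncertainty(
            ests, method="montecarlo" if config.propagation == "montecarlo" else "delta",
            n_draws=config.mc_draws, seed=int(rng.integers(2**31 - 1)),
        )
        est_low = [e for e in ests if e.glasshouse_n == "low"]
        est_high = [e for e in ests if e.glasshouse_n == "high"]
        entry = {
            "estimates": [
                dict(genotype=e.genotype, glasshouse_n=e.glasshouse_n,
                     me=e.me, me_se=e.me_se, usable=e.usable)
                for e in ests
            ]
        }
        for pred_name, pred in (
            ("hist_n", hist_n),
            ("nfix_richness", nfix_richness),
            ("ao_relabund", ao_ra),
        ):
            comp = mefx.slope_difference_test(
                est_low, est_high, pred, n_sim=config.n_simulations,
                seed=int(rng.integers(2**31 - 1)), predictor_name=pred_name,
            )
            entry[pred_name] = comp.to_dict()
        results[trait] = entry
    io.write_json(dict(seed=config.seed, version=__version__, results=results),
                  out / "mefx.json")
    bundle["mefx"] = results


_STAGES = (
    ("simulate", None),  # handled specially
    ("rarefy", _rarefy_stage),
    ("metrics", _metrics_stage),
    ("permanova", _permanova_stage),
    ("dbrda", _dbrda_stage),
    ("env_diversity", _env_diversity_stage),
    ("traits", _traits_stage),
    ("mefx", _mefx_stage),
)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write the result bundle to
    ``config.out_dir``. Deterministic for a fixed seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # echo the configuration without the bundle path itself, so two runs of
    # the same seed into different directories produce identical bundles
    echo = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    io.write_json(
        dict(seed=config.seed, version=__version__, config=echo),
        out / "run_info.json",
    )
    bundle: dict = {}
    for name, fn in _STAGES:
        log.info("stage: %s", name)
        try:
            if name == "simulate":
                bundle.update(simulate_inputs(config, out))
            else:
                fn(config, bundle, out)
        except Exception as exc:
            raise StageError(name, exc) from exc
    return bundle
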