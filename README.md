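# rhizoadapt

Analysis pipeline for two linked questions about wild-grass rhizosphere
microbiomes:

1. **Is microbiome recruitment shaped by the host's historic environment?**
   Given amplicon count tables (16S, nifH, ...) from a common-garden
   experiment with replicated plant genotypes, the pipeline partitions
   community variation among genotype and glasshouse block (PERMANOVA on
   Bray–Curtis and weighted UniFrac distances), then asks how much of the
   *between-genotype* variation traces back to the genotypes' native
   environments (soil nitrogen, phosphorus, CEC, pH, climate) using
   distance-based redundancy analysis (dbRDA) with forward model selection,
   after partialling out spatial and genetic autocorrelation through Moran's
   eigenvector maps (dbMEM) built from geographic and SSR-marker Hamming
   distances.

2. **Do microbes make the plant's nitrogen response adaptive?** From a
   crossed 2 nitrogen × 2 microbe (live vs. sterilized inoculum) glasshouse
   experiment, it computes the per-genotype *microbial effect*

   &nbsp;&nbsp;&nbsp;&nbsp;ME = (Live − Sterile) / Sterile

   for each trait, propagates uncertainty from the cell means (delta method
   or Monte Carlo), regresses ME on each genotype's historic soil nitrogen
   (the reaction norm), and tests whether the reaction-norm slopes differ
   between the low- and high-nitrogen glasshouse environments with a
   parametric bootstrap. A sign flip of the slope between environments is
   the signature of microbe-contingent local adaptation. Genotype-level
   microbiome traits (diazotroph richness, ammonia-oxidizer relative
   abundance) can stand in for historic nitrogen as the predictor.

Because the original sequencing study is not reproducible at desk scale, the
package ships a first-class synthetic-data generator (`rhizoadapt.synthetic`)
that emulates both experiments: ~40 genotypes × 5 replicates with genotype
effects calibrated to explain ~21–31% of community distance variation,
historic-environment effects of ~1–3%, a diazotroph richness gradient
(≈25 → 12 ASVs across the historic soil-N range), an ammonia-oxidizer share
gradient (≈0.85% → 1.12%), and a 10 × 2 × 2 × 10 trait experiment with
environment-dependent microbial-effect slopes and ~27% germination failure
(291 plants surviving in expectation).

## Worked example

```python
from rhizoadapt import synthetic as syn, community as com, ordination as o, mefx

# experiment 1: community structure
panel = syn.gen_panel(n_genotypes=40, seed=1)
tax = syn.gen_taxonomy("16s", 400, seed=1)
table, meta = syn.gen_feature_table(panel, n_replicates=5,
                                    spec=syn.spec_16s(), taxonomy=tax, seed=1)
rare = com.rarefy(table, depth=9000, seed=1)
dm = com.bray_curtis(rare)
print(o.permanova(dm, meta.for_samples(dm.ids), ["genotype", "block"],
                  n_perm=999, seed=1).round(3))

# experiment 2: microbial effect on height and its reaction norms
sub = syn.select_spanning_subset(panel, 10)
traits, truth = syn.gen_experiment2_traits(sub, n_replicates=10, seed=1)
ests = mefx.compute_microbial_effect(traits, "height")
mefx.attach_uncertainty(ests, method="montecarlo", seed=1)
low = [e for e in ests if e.glasshouse_n == "low"]
high = [e for e in ests if e.glasshouse_n == "high"]
x = sub.data.set_index("genotype")["soil_nitrogen"]
comp = mefx.slope_difference_test(low, high, x, n_sim=10000, seed=1)
print(f"slope (low N)  = {comp.slope_low:+.3f}")
print(f"slope (high N) = {comp.slope_high:+.3f}")
print(f"delta = {comp.delta:+.3f}, P = {comp.p_value:.4f}")
```

prints

```
       term   df      SS     R2      F      p
0  genotype   39   7.756  0.274  1.576  0.001
1     block    4   0.860  0.030  1.704  0.001
2  Residual  156  19.688  0.696    NaN    NaN
3     Total  199  28.305  1.000    NaN    NaN
slope (low N)  = -0.097
slope (high N) = +0.134
delta = +0.231, P = 0.0002
```

Plant genotype explains 27.4% of Bray–Curtis variation (P = 0.001); the
microbial effect on height *declines* with historic soil nitrogen in
nitrogen-limited pots but *rises* in fertilized pots, and the bootstrap
rejects equal slopes — genotypes from nitrogen-poor habitats get the largest
microbial boost exactly when nitrogen is scarce.

## Command line

```bash
rhizoadapt run-all --seed 1 --out-dir out/        # full pipeline
rhizoadapt simulate --seed 1 --out-dir out/       # inputs only
rhizoadapt metrics --seed 1 --out-dir out/        # rarefy + diversity + distances
rhizoadapt permanova --seed 1 --out-dir out/ --terms genotype,block
rhizoadapt dbrda --seed 1 --out-dir out/ --alpha 0.05 --condition geo,ssr
rhizoadapt traits --seed 1 --out-dir out/         # mixed models, Table-style ANOVA
rhizoadapt mefx --seed 1 --out-dir out/ --nsim 10000
```

All stages are deterministic given `--seed`; the bundle (TSV/JSON) records
the seed and package version, and a repeated run is byte-identical.

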