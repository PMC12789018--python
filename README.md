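# beegradient

Wild bees in crop fields face two pervasive agricultural stressors: pesticide
use in the focal field and the loss of semi-natural habitat (SNH — forests,
hedgerows, extensive grasslands) in the surrounding landscape.  Quantitative
syntheses of multi-study field data ask how these gradients reshape bee
assemblages — abundance, species richness, functional and phylogenetic
diversity within sites, and the nestedness and turnover of composition
across sites.  `beegradient` is a tested, reusable implementation of that
analysis pipeline for ecologists and ecotoxicologists, together with a
synthetic multi-study generator with planted effects so every stage can be
validated end to end without any external data.

## What it computes

**Pesticide hazard.**  Per site, the hazard quotient over its N applications

```
HQ = Σₙ log( application rateₙ [g a.i./ha] / LD50ₙ [µg/bee] )
```

with the full resolution cascade of real compilations: unbounded ('>')
limit-test LD50s at their bound, contact LD50 as a proxy for missing oral
values, label-default rates, and mean-imputation of type-only records by
pesticide type × production system × study.  Oral, contact and combined
exposure variants are computed and the best-predicting variant selected by
correlation with the community descriptors.  Sites are alternatively
classed by pesticide-use intensity (conventional = high, organic = low).

**Community descriptors.**  Per site (honey bees excluded, abundance per
sample unit, metrics averaged over years and sampling methods): richness and
exact rarefied/extrapolated richness; functional diversity from a
balanced-weight Gower → PCoA functional space (UPGMA dendrogram branch
length, abundance-weighted MPD, Villéger FEve along the minimum spanning
tree, FSpe relative to the pool centroid); phylogenetic diversity and MPD on
a taxonomy tree with Grafen branch lengths.

**Stressor models.**  Random-intercept-and-slope linear mixed models of
within-dataset z-transformed descriptors on z(HQ) (or intensity) and z(SNH),
fitted by ML with likelihood-ratio p-values, an HQ × SNH interaction screen
and VIF diagnostics.

**Beta diversity.**  Site × species matrices ordered by increasing HQ or
decreasing SNH; weighted nestedness WNODF (matching vegan's `nestednodf`
exactly) z-scored against quantitative swap nulls that preserve row sums,
column sums and fill; study-level one-sample t-tests and a paired Wilcoxon
comparison of the two gradients; a shift-by-3 directional Jaccard
decomposition into losing/gaining turnover and nestedness, summarized per
matrix as paired Hedges' g and pooled by DerSimonian–Laird random-effects
meta-analysis (τ², I², H², moderator omnibus test, Cook's distances).

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import warnings
import beegradient as bg

warnings.filterwarnings("ignore")

sim = bg.SimulationConfig(n_studies=8, studies_with_extra_dataset=2,
                          sites_per_dataset=12, species_pool_size=60,
                          species_per_dataset=20, seed=42)
config = bg.PipelineConfig(simulation=sim, n_nulls=199, seed=42)
result = bg.run_pipeline(config)

ab = result["models"]["abundance"]["hq"]
print(f"hazard pathway selected : {result['report']['hazard_pathway']}")
print(f"abundance ~ HQ slope    : {ab['estimates']['zhq']:+.3f} "
      f"(LRT p = {ab['lrt_p']['zhq']:.2e})")
print(f"abundance ~ SNH slope   : {ab['estimates']['zsnh']:+.3f} "
      f"(LRT p = {ab['lrt_p']['zsnh']:.2e})")
nest = result["beta"]["tests"]["hq"]
print(f"WNODF z (HQ gradient)   : mean {nest['mean']:.2f}, "
      f"t = {nest['t']:.2f}, df = {nest['df']}, p = {nest['p']:.4f}")
```

prints

```
hazard pathway selected : oral
abundance ~ HQ slope    : -0.316 (LRT p = 3.27e-06)
abundance ~ SNH slope   : +0.444 (LRT p = 6.80e-08)
WNODF z (HQ gradient)   : mean 1.13, t = 3.23, df = 7, p = 0.0144
```

The generator planted standardized effects of −0.3 (hazard) and +0.3 (SNH)
on abundance; the mixed model recovers them (−0.316, +0.444 at this small
size; at the default 36 datasets the estimates tighten around the truth).
The positive study-level WNODF z (1.13, p = 0.014) is the planted
hazard-ordered species loss: sensitive species drop out first along the
hazard gradient, so high-hazard communities are nested subsets of low-hazard
ones — more nested than the swap null expects.

The same pipeline runs from the shell, on simulated or on your own CSV
tables (`sites.csv`, `applications.csv`, `toxicity.csv`, `communities.csv`,
`traits.csv`; schemas in `docs/methods.md` and the module docstrings):

```sh
beegradient all --config run.yaml --seed 42 --out results/
```

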