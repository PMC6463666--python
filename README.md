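# uavheight

UAV-based plant-height phenotyping for wheat field trials, with the
downstream quantitative genetics that phenotypes of this kind feed: variance
components and broad-sense heritability, QTL interval mapping in a
doubled-haploid (DH) population, and GBLUP genomic prediction.

**Who it is for.** Phenomics and quantitative-genetics researchers who
extract plot-level canopy heights from drone photogrammetry products (a
digital surface model plus digitized field polygons) and want to verify that
those heights are accurate enough to drive genetic analysis — QTL detection
and genomic selection — before trusting them on real trials.

## The method

From a georeferenced digital surface model (DSM) and operator-digitized
bare-ground polygons:

1. **Terrain model.** Each bare-ground polygon contributes three ground
   control points (centroid/median, lowest and highest pixel); a TIN-linear
   interpolation over these points gives the digital terrain model (DTM) —
   no pre-planting flight needed.
2. **Plant height model.** PHM = DSM − DTM, per pixel.
3. **Plot heights.** Inside each margin-trimmed plot polygon, `n` small
   square windows are placed at random; each contributes its maximum PHM
   value (a canopy-top reading). Readings more than 10 cm below the plot's
   best reading cannot be spike tops and are rejected; the plot height is

   H = (U + L) / 2

   where U and L are the highest and lowest accepted canopy-top readings.
4. **Genetics.** On genotype entry means: two-way genotype × environment
   ANOVA with expected-mean-squares variance components and entry-mean
   heritability h² = σ²g / (σ²g + σ²ge/r + σ²ε/re); inclusive composite
   interval mapping (stepwise cofactor selection, then an adjusted-phenotype
   scan on Haldane expected genotypes, LOD threshold 2.5); and
   ridge-regression BLUP (λ by REML) with repeated k-fold cross-validation,
   including a paired marker-exclusion experiment.

Because real trial data of this kind is rarely shareable, the package ships
a first-class synthetic generator (`simulate_field`) that renders DSM/DTM
pairs for a 198-line DH trial (two sites, three replicate blocks, 1.3 m ×
3 m plots, 2.5 cm ground sampling distance) from a simulated genetic
architecture with two major dwarfing loci (on chromosomes 4B and 4D), a
minor locus on 6D and a marker-borne polygenic background — with full ground
truth, so every stage can be tested for recovery of known quantities.

## Worked example

```python
import uavheight as uh

cfg = uh.SimulationConfig(seed=42, n_sites=1, n_lines=60, n_reps=2, n_plot_columns=12)
sim = uh.simulate_field(cfg)

dsm = sim.dsm["site1"]
points = uh.sample_ground_elevations(dsm, sim.layouts["site1"].bare_ground)
dtm, _ = uh.interpolate_dtm(points, dsm)

uav, _ = uh.extract_all(dsm, dtm, sim.layouts["site1"], uh.ExtractionParams(seed=1))
merged = uav.merge(sim.ground_truth.plot_heights, on="plot_id")
rep = uh.regress_validate(merged["value_cm"].to_numpy(), merged["height_cm"].to_numpy())

means = uh.line_means(uav[~uav.genotype_id.isin(("P1", "P2"))])
cof = uh.select_cofactors(sim.genotypes, means)
scan = uh.icim_scan(sim.genotypes, sim.linkage_map, means, cof)
peaks = uh.qtl_peaks(scan)
cv = uh.cross_validate(sim.genotypes, means, k=5, repeats=10, seed=2)
```

printing (via the obvious f-strings):

```
DTM RMSE vs true terrain: 3.8 cm
UAV vs true height: R^2 = 0.978, bias = 7.7 cm (n = 124 plots)
QTL 4B @ 64 cM: LOD 7.8, a = -9.8 cm, PVE 33.4%
QTL 4D @ 67 cM: LOD 6.0, a = -8.2 cm, PVE 22.7%
GBLUP 5-fold CV accuracy: r = 0.57
```

Reading this: the terrain was recovered to under 4 cm; extracted heights
track the true plot heights almost perfectly (R² 0.98) but systematically
underestimate them by ~8 cm, because the DSM undersamples thin spike tips —
the known, correctable bias of this measurement. Both planted major
dwarfing loci are detected near their true positions (60 and 75 cM) with
effects near the planted −10 and −9 cm, and the marker panel predicts
line heights with r ≈ 0.6 at this reduced population size.

The same stages are available as a CLI (`uavheight simulate-field`,
`build-dtm`, `extract-heights`, `validate`, `varcomp`, `qtl-scan`,
`gblup-cv`, `exclusion-exp`, `run-pipeline`); `run-pipeline` executes
everything in order and writes a manifest with content hashes — identical
configuration and seed reproduce identical manifests.

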