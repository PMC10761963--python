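# lvfield

Phylogeny-free inference of dispersal trajectories and the dispersal
centre of a set of related language varieties (or any comparable cohort of
samples) from a binary trait matrix and per-sample geographic coordinates.

## The problem

Where did a language family spread from?  The standard phylogeographic
answer requires a dated phylogenetic tree, which presumes that relatedness
among the samples is tree-like — an assumption horizontal contact
routinely violates.  `lvfield` implements *language velocity field
estimation* (LVF): instead of a tree, it reconstructs, for every sample, a
short segment of its evolutionary trajectory directly from the data, and
reads the dispersal centre off the geometry of those trajectories.

The pipeline, for `n` samples scored on `p` binary traits (1 = cognate
present, 0 = absent), each at a (lon, lat) coordinate:

1. **State frequencies.** Each binary trait of sample *l* becomes the
   frequency `x_l1(0)` of state 1 among the `k` geographically nearest
   samples (including *l*), `k = 10` by default.
2. **Trait dynamics.** Each trait evolves by competition between its two
   states with per-state *prestige* `s_j = e^-λ + (1 - e^-λ) π_j`, where
   `π_j` is the trait's global state-`j` frequency and λ is the rate of a
   Poisson mutation clock (λ = 1).  The frequency follows the logistic law
   `dx/dt = (s1 - s0) x (1 - x)`, whose closed-form backward solution gives
   the state `x(-m)` at `m` time units before the present (m = 1).
3. **Velocity field.** `V_l = [X_l(0) - X_l(-m)] / m` is sample *l*'s
   velocity in trait space; stacking rows gives the field **V**.
4. **Projections.**  **V** is projected onto the two leading principal
   components of the binary matrix (`V_pc = V A₂`), then into geographic
   space through a transition kernel: the softmax (temperature τ) of the
   cosine alignment between `V_pc_l` and the displacement towards each of
   its `s` PC-nearest neighbours weights the unit geographic displacement
   vectors towards those neighbours,
   `V_geo_l = Σ_j (P_lj - 1/s) (C_j - C_l)/‖C_j - C_l‖`.
5. **Smoothing and gridding.**  Vector lengths (never directions) are
   rescaled and locally averaged under a Gaussian kernel, and the field is
   resampled onto a regular lon/lat grid.
6. **Centre inference.**  Each supported grid point is scored by the
   *radiativity* of the surrounding unit vectors — the mean per-axis
   variance `σ_g² = tr[U^T (E_s - 11^T/s) U] / (2(s-1))` of its `s` nearest
   grid vectors.  Vectors around a true source point outward in every
   direction, so the maximising grid point is the dispersal centre; its
   uncertainty comes from leave-one-sample-out jackknifing.

The package also ships the three classical phylogeny-free baselines
(diversity / centroid / minimal distance), the comparison statistics used
to validate the method (Mantel permutation test, quartet delta score,
cosine field similarity, Procrustes consistency), and a seeded simulator
that generates validation cohorts with a known planted centre.

## Worked example

```python
import lvfield as lv

# a synthetic cohort: 20 samples x 306 binary traits evolved on a random
# tree, coordinates random-walked from a planted centre at (0, 0)
ds = lv.simulate_dataset(seed=3)

model = lv.DispersalModel(ds.traits, ds.coords, lv.ModelParams(k=10, lam=1, m=1))
results = model.fit()
print(results.summary())
```

```
Language velocity field estimation
==================================
samples: 20    traits: 306 (of 306 before filtering)
params: k=10 lam=1 m=1 tau=0.05 grid=50x50 sigma_geo=1.988
PC1/PC2 explained variance: 8.189, 6.731
supported grid points: 2310 / 2500
dispersal centre: lon=-1.4488 lat=4.2833 (max radiativity sigma2=0.5135)
```

The planted centre was (0, 0); the estimate lands within a few degrees —
about the per-dataset accuracy to expect from 20 samples whose random walk
itself has a 5° step scale.  `results.jackknife()` attaches leave-one-out
standard deviations, `results.baselines()` returns the three baseline
homeland estimates, and `results.plot_quiver()` draws the gridded field.

The same pipeline runs from the shell:

```bash
lvfield simulate --out sim/ --seed 7
lvfield run --traits sim/traits.csv --coords sim/coords.csv --out fit/
lvfield baselines --traits sim/traits.csv --coords sim/coords.csv --out base/
lvfield evaluate --traits sim/traits.csv --coords sim/coords.csv \
        --tree sim/tree.nwk --out report.json
```

Trait matrices are read from wide CSV/TSV (rows = samples, header =
traits, missing as `?`, `-` or empty) or NEXUS binary character blocks;
coordinates from an `id,lon,lat` CSV; trees from Newick.

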