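# Methods

## Model

`lvfield` treats each binary trait of each sample as the observable state
of a two-state competition process.  For trait *i*, let `x1` denote the
frequency of state 1 in a sample's geographic neighbourhood and `s1`,
`s0` the *prestige* of the two states — the probability that the state
persists across one unit of time.  With transition rates
`q_uv(x_v, s_v) = s_v x_v`, the frequency obeys

    dx1/dt = (s1 - s0) · x1 · (1 - x1),

a logistic law: the more prestigious state expands at a rate proportional
to the current mixture.  Prestige is estimated from a Poisson mutation
clock with rate λ: over one time unit a trait escapes mutation with
probability `e^-λ`, and a mutating lineage adopts state *j* with
probability equal to the trait's global state-*j* frequency `π_j`, giving

    s_j = e^-λ + (1 - e^-λ) π_j .

The closed-form backward solution

    x1(-m) = [1 + (1/x1(0) - 1) · e^{(s1-s0) m}]^{-1}

reconstructs each neighbourhood frequency `m` units before the present
(the fixed points 0 and 1 are preserved exactly).  The per-sample
velocity `V_l = [X_l(0) - X_l(-m)] / m` measures how the sample's trait
profile has been moving; stacked over samples it forms the velocity field
in `p`-dimensional trait space.

The field is made geographic in two linear steps.  First `V` is projected
onto the two leading eigenvectors `A₂` of the covariance of the binary
matrix (`V_pc = V A₂`; centering cancels in the difference, so projecting
the difference equals differencing the projections).  Second, a
transition kernel maps PC velocities to the map: for the `s` PC-nearest
neighbours `j` of sample `l` (self excluded), the cosine alignment
between `V_pc_l` and `PC_j - PC_l` is passed through a softmax with
temperature τ, and

    V_geo_l = Σ_j (P_lj - 1/s) · (C_j - C_l)/‖C_j - C_l‖ .

Subtracting the uniform baseline `1/s` makes an uninformative kernel
produce a zero vector; zero-velocity samples get uniform rows, and
coincident neighbours (in PC space or geography) contribute nothing.

Smoothing touches only vector lengths, because only directions carry
information downstream: each geographic vector is rescaled to the length
of its PC counterpart, lengths are replaced by the Gaussian-kernel
(`K_σ(a,b) = exp(-‖a-b‖²/2σ²)`, weights normalised to sum 1) weighted
mean of all samples' lengths, and the field is resampled onto a regular
`50 × 50` lon/lat grid over the 5%-padded bounding box, each grid vector
the normalised kernel-weighted mean of its nearest samples' vectors.
Grid points farther than a support radius from every sample are excluded.

The dispersal centre maximises the *radiativity* score: with `U` the
unit-normalised vectors of a grid point's `s` nearest supported grid
points,

    σ_g² = tr[ U^T (E_s - 11^T/s) U ] / (2(s-1)) ,

the mean of the two per-axis sample variances.  A field radiating from a
source has directions spread over the full circle (σ² near 1 for an
isotropic source); a translation field has near-identical directions
(σ² near 0, flagged in the log when the maximum is below 0.05).
Uncertainty comes from the classical jackknife: the whole pipeline is
rerun leaving each sample out once, and
`SD = sqrt((n-1)/n · Σ_i (θ̂_i - θ̄)²)` per coordinate.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `k` | 10 | neighbours (incl. self) for the binary → frequency conversion |
| `lam` | 1 | Poisson mutation rate of the prestige estimator |
| `m` | 1 | reconstruction time, in expected-mutation units |
| `tau` | 0.05 | softmax temperature of the transition kernel |
| `s_proj` | min(n−1, 30) | PC-space neighbours of the kernel |
| `s_grid` | auto | min(n, 30) samples for gridding; min(M, 30) grid points for radiativity |
| `sigma_geo` | auto | Gaussian bandwidth, 1/10 of the bounding-box diagonal (degrees) |
| `grid_nx, grid_ny` | 50 × 50 | grid resolution |
| `support_radius` | auto | 2·σ, support mask for grid points |
| `max_missing` | 0.75 | per-trait missing fraction above which the trait is dropped |
| `impute_mode` | mode_value | fill rule for the complete matrix (PCA, prestige) |

`k`, `lam` and `m` are the estimator's scientific parameters and their
defaults are the validated operating point; the centre estimate is
insensitive to τ, σ and the radiativity neighbourhood within wide ranges
(sweeps over τ ∈ {0.05, 0.2, 1} and neighbourhood ∈ {30, 100, 300}
changed the mean centre error by under a degree), so their defaults
simply follow the kernel-projection precedent and the bounding-box scale.

Coordinates are treated as planar lon/lat degrees throughout — all
operations downstream of input validation are Euclidean.  Great-circle
geometry is deliberately not attempted; at continental scales the
directional error is small against the estimator's own noise, and the
equations are defined on the plane.

### Missing data

Traits with more than 75% missing cells are dropped.  The k-NN frequency
estimator handles the remaining gaps exactly, by disregarding missing
cells inside the neighbourhood, so the velocity field does not depend on
how gaps are filled; imputation (mode-value by default; frequency-value
and zero-value available) feeds only the two steps that structurally need
a complete matrix — the PC embedding and the global frequencies π.  This
is why the three imputation modes agree closely (trait-field cosine
≈ 0.95, Procrustes correlation > 0.99 on the standard fixture): routing
imputed values into the frequencies themselves
(`ModelParams.freq_use_imputed=True`) degrades the agreement to ≈ 0.88
and is kept only for comparison.  Neighbourhoods whose every value is
missing (possible at very small `k`) fall back to the imputed value.

## Synthetic validation data

`simulate_dataset` emulates the validation design: 20 samples × 306
binary traits.  A pure-birth tree (birth rate 1) is grown to 20 tips and
rescaled to crown height 1; each trait evolves independently as a
symmetric two-state Markov chain with per-trait rate drawn from
Gamma(shape 1, mean 1) and root state Bernoulli(0.5); coordinates follow
a Brownian walk along the tree (per-axis step SD `5·√branch-length`
degrees) from the planted centre.  `replicate_datasets` draws each
replicate's centre uniformly from ±60° lon × ±40° lat, so a validation
batch emulates many expansions with distinct homelands; with a single
shared truth the unpaired rank-sum comparison of given and inferred
coordinates rejects at its nominal 5% rate per setting and axis even for
an unbiased estimator, whereas with varying truths the two coordinate
sets share the truth backbone and the comparison is conservative and
stable.

Two optional knobs emulate features of real data the vertical design
lacks.  `missing_rate` masks cells at random (the standard test fixture
uses 0.10).  `borrowing_rate` switches on horizontal contact: a fraction
`rate` of samples is paired into fixed non-sister contact dyads, and each
recipient repeatedly copies 10-trait blocks from its partner until about
55% of its inventory is borrowed.  Partial, persistent convergence is the
point: near-total copying just turns a dyad into a perfect cherry (the
distance matrix becomes tree-like again, only for a different tree),
while diffuse one-off borrowing is noise that neither the PC embedding
nor the tree explains.  At 55% coverage the conflicting vertical and
horizontal signals raise the quartet delta score monotonically with the
rate, and at rate 0.3 the given tree's Mantel r² against observed
relatedness falls below the PC embedding's — the qualitative regime
contrast the method is designed around.

What the simulator does not emulate: real cognate matrices are sparse in
a structured way (missingness follows documentation effort, not a coin
flip), trait gain/loss rates are not exchangeable across meaning classes,
geographic expansion is constrained by coastlines and terrain, and
sampling is biased towards well-studied subgroups.  Passing the simulated
validation therefore shows the estimator recovers sources under its own
generative assumptions, not that empirical homeland inferences are
correct.

## Numerical choices

- Present frequencies are clipped to `[1e-12, 1 - 1e-12]` before the
  backward formula; the exact 0/1 fixed points are restored afterwards.
- The logistic ODE is never integrated in production — the closed form is
  its solution; an integrator appears only as a test oracle.
- PCA is centered and unscaled; component signs are fixed by making each
  component's largest-magnitude loading positive (the geographic kernel
  is not sign-invariant, so reproducibility requires a convention).
- k-NN ties (coincident coordinates) break by sample order, argmax ties
  by lowest grid index; both are logged.
- Kernel weights in both smoothing stages are normalised to sum 1, so
  results do not scale with sampling density; directions are unaffected.
- The quartet delta score enumerates all C(n,4) quartets when that count
  is within budget (default 10⁵) and otherwise samples quartets
  uniformly with a seed; equidistant quartets score 0 by convention.
- The Mantel p-value is one-tailed (greater), `(#{r_perm ≥ r_obs}+1)/(N+1)`.
- Stochastic imputation and every resampling loop derive their seeds from
  `ModelParams.seed` (jackknife replicate *i* uses `seed + i + 1`).

## Validation protocol sizes

The acceptance script and test suite run the effectiveness protocol on
100 replicate datasets at the defaults plus the five extreme
single-parameter settings of the validated grids (k ∈ {2,…,18},
λ ∈ {0.1,…,10}, m ∈ {1,…,9}); robustness and imputation consistency use
one standard fixture (20 × 306, 10% missing); the relatedness-structure
contrast averages eight replicates per borrowing rate with 999 Mantel
permutations.  These sizes give stable statistics while keeping a full
validation run around a minute on one CPU.

## Known limitations

- Planar geometry (above); do not feed cohorts spanning the antimeridian.
- With 20-sample cohorts the centre estimate carries several degrees of
  error per dataset; the protocol's claims are distributional.
- The two-component PC projection discards high-dimensional structure;
  on cohorts whose relatedness needs many components the geographic
  kernel weakens (visible as low PC-frame robustness medians compared to
  trait-frame ones).
- Entropy-based diversity, the hull centroid and minimal distance are
  implemented as planar baselines, matching the estimator's geometry,
  not as spherical geodesic methods.
- The dispersal *date* is out of scope; only the centre is inferred.
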