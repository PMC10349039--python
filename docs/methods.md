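# Methods

## The model

`lesionctl` analyzes weighted undirected structural connectomes `A`
(corrected probabilistic-streamline counts over ≤100 labeled gray-matter
regions, half per hemisphere) from people with chronic left-hemisphere
stroke, and asks whether the *network controllability* of language-related
regions carries the association between advanced brain aging and aphasia
severity.

The dynamical model is the standard discrete-time linear system used in
network control theory of the brain:

    x(t+1) = A_norm x(t) + B u(t),     A_norm = A / (1 + sigma_max(A)),

with `B` the indicator column of a driver region.  Dividing by one plus the
largest singular value makes the dynamics stable, so the infinite-horizon
controllability Gramian

    W = sum_{t>=0} A^t B B' A'^t

exists and solves the discrete Lyapunov equation `A W A' − W + B B' = 0`
(solved with `scipy.linalg.solve_discrete_lyapunov`).  Two quantities are
derived per driver region:

* **average controllability** `trace(W)` — the region's capacity to spread
  input energy through the network.  It is bounded below by 1 (the `t = 0`
  term) and equals 1 exactly for a disconnected driver.  For symmetric
  `A_norm` with eigenpairs `(λ_j, v_j)` it equals `Σ_j v_j(k)² / (1 − λ_j²)`,
  which the test suite uses as an independent oracle together with the
  truncated power series.
* **global controllability** — whether the whole network state can be steered
  from *every* single region, classically phrased as strict positivity of the
  smallest eigenvalue of each driver's Gramian.

### Why the global verdict uses the PBH test

Single-driver Gramians are spectacularly ill-conditioned: on a connected
10-node graph the genuine smallest eigenvalue can be below 1e−80 (we verified
this with an 80-digit truncated-series computation), so thresholding the
double-precision eigenvalue cannot distinguish "tiny but positive" from
"exactly zero".  For symmetric dynamics, λ_min(W) > 0 is *exactly* equivalent
to the Popov–Belevitch–Hautus condition: every eigenvalue of `A_norm` simple,
and no eigenvector with a zero component at the driver.  That condition is
numerically well-posed and is what `global_controllability` uses for the
verdict; the raw Lyapunov-based λ_min values are still computed and reported.
Two consequences worth knowing: graphs with nontrivial spectral symmetry
(e.g. unweighted complete graphs, and some unweighted sparse graphs with
exact eigenvector zeros) are correctly reported uncontrollable from any
single node, while generically weighted connected graphs are controllable
from every node.

## Preprocessing (stroke-adapted)

Fixed order, each stage preserving symmetry, nonnegativity and the zero
diagonal:

1. **Symmetrize** directed streamline counts: `w = (count_ij + count_ji)/2`.
2. **Size correction** `w' = 2 w / (vol_i + vol_j)`.  Streamline *distance*
   correction is assumed done by the tracking software and is not reapplied.
3. **Spurious-link threshold**: remove (set to zero) every link strictly
   below the 20th percentile of the *nonzero links internal to the right
   hemisphere* — the hemisphere untouched by left-lateralized lesions.
   Structural zeros are excluded from the percentile population because with
   ~70% sparsity they would drag the 20th percentile to 0 and make the filter
   vacuous; links with only one right-hemisphere endpoint are likewise
   excluded.  Percentile uses linear interpolation between order statistics.
   Note the operation is not idempotent under re-computation (the survivors'
   20th percentile is higher); re-applying the *recorded* threshold value is
   a no-op, and that is the property the tests pin down.
4. **Zero-degree removal**: repeatedly delete the first (lowest-index)
   zero-degree node and re-evaluate, until none remain; the removal ledger
   (label, round) is reported.  Deleting an isolated node never changes other
   degrees, so one-by-one equals batch removal; one-by-one is kept for ledger
   fidelity.  A connectome that would empty entirely is an error.

Regions damaged by the lesion but still connected are retained.

## Statistics

* **Brain-age gap** = predicted brain age − chronological age (years;
  positive = advanced brain aging).
* **Regression** via OLS with standardized betas `b·sd(x)/sd(y)` (binary
  covariates standardized by the same rule), overall F and R².
* **Mediation (single mediator)**: three OLS fits with a shared covariate set
  (chronological age, lesion volume, months post-stroke, education, sex) —
  total `y~x`, a-path `m~x`, direct/b `y~x+m`; indirect = a·b.  Inference on
  a·b by case-resampling bootstrap with the **bias-corrected** percentile
  method (`z0` from the proportion of draws below the point estimate; no
  acceleration constant, matching the common PROCESS model-4 setting);
  significance = the CI excludes zero.  Complete-case analysis with a logged
  exclusion count; degenerate bootstrap draws are dropped and the result is
  flagged if they exceed 1%.  The seed is mandatory and stored.
* **LMG relative importance**: each regressor's average increment to R² over
  all orderings of entry, computed exactly via subset enumeration with
  combinatorial weights (≤10 regressors); shares sum to the full-model R² by
  telescoping.
* **PCA with varimax**: correlation-matrix eigendecomposition, components
  with eigenvalue ≥ 1.0 retained, varimax rotation with Kaiser
  row-normalization (criterion change < 1e−6, ≤100 iterations), KMO from
  anti-image partial correlations and Bartlett's sphericity test
  `χ² = −(n−1−(2p+5)/6)·ln det R`.  A singular correlation matrix yields
  NaN Bartlett statistics, reported as such.
* **Partial correlation**: Pearson correlation of OLS residuals, p from the
  t transform with `df = n − 2 − #controls`; a variable collinear with the
  controls is flagged with a warning and reported as r = 0.

## The synthetic cohort generator

No raw data from the motivating study design are publicly archived, so the
generator emulates its conditions and plants a recoverable causal structure.

* **Base connectome**: Erdős–Rényi edges at density 0.3 over 100 nodes,
  uniform `U(0.5, 1.5) × weight_scale` weights, *homotopic symmetry* (the
  left intra-hemispheric block is mirrored to the right before lesioning, so
  right-hemisphere percentile thresholding is meaningful), homotopic pairs
  sharing region volumes (uniform 2–12 cm³).  `weight_scale = 1e5` so that
  size-corrected weights are O(1) and per-node average controllability spans
  ≈1–20, the range reported for real stroke connectomes.  The mediator region
  (default left posterior superior temporal gyrus) and its homotopic partner
  get a ×2 link boost: the posterior STG is a language-network hub, and hubs
  carry high average controllability.
* **Lesion operator**: left-lateralized damage centered on a random left
  focus region; each link with a left endpoint is deleted with probability
  `severity·exp(−d)` (d = hop distance of the nearer endpoint from the
  focus) and otherwise attenuated by the complementary factor;
  right-hemisphere-internal links are never touched; per-region lesion
  fractions are recorded.  Severity ~ Beta(2, 5), lesion volume
  `2.4 + severity·465` ml (cohort mean ≈ 130 ml).
* **Planted a path**: edges incident to the mediator are multiplied by
  `exp(−κ·max(gap, 0))`.  κ is calibrated by bisection on the preprocessed
  lesion-free base so that one SD of gap (7.46 y) shifts the mediator's
  *computed* average controllability by `a_path·σ_gap` — i.e. `a_path` is the
  per-year slope, keeping the network-level and variable-level generators on
  the same scale.  Only positive gaps attenuate (aging damages, never
  strengthens), so the realized linear slope is somewhat shallower than
  `a_path`; the recovery tests assert sign and significance, not magnitude.
* **Outcome**: `wab = intercept + c'·gap + b·(m − m_ref) + β_lesion·volume +
  covariate terms + N(0, σ_y)`, clipped to the [0, 100] severity-score range
  (clip count logged; ≈0 at defaults).  `m_ref` is the lesion-free base
  connectome's mediator controllability, so the score stays on scale across
  random bases.  `noise_sd_m` is used only by the variable-level generator,
  where the mediator is drawn directly from `m = m_ref + a·gap + ε`; at
  network level the mediator's dispersion *is* the lesion-driven network
  variability.
* **Demographics** follow the study ranges: age U(29, 80), education
  12–20 y, P(male) = 0.60, months post-stroke lognormal clipped to
  [10, 241], gap ~ N(1.95, 7.46).
* **Default effect sizes** are the study-scale values: `c' = −0.71`
  severity points per year (direct), `a = −0.05` controllability units per
  year, `b = −2.0` points per unit, `β_lesion = −0.125` per ml.  At this
  scale the indirect effect lands around 0.1 with a 95% CI that typically
  grazes zero — the borderline regime of the motivating study.

### What the generator does not emulate

Heavy-tailed streamline-count distributions, spatially contiguous lesions,
distance-dependent connection probability, and any real registration/
tractography noise.  Passing tests therefore demonstrate that the *pipeline*
recovers a planted structure under idealized network variability, not that
the effect exists in any particular dataset.

### Power analysis behind the end-to-end recovery test

The end-to-end test asks that the bootstrap CI for a·b exclude zero in ≥80%
of 20 replicate cohorts of n = 93.  At the study-scale defaults the
per-cohort rejection probability is ~50% (the borderline regime), which
would test luck, not machinery.  The test therefore plants
`a = −0.15, b = −4.0, σ_y = 6`: a Sobel-style calculation at n = 93 with the
generator's lesion-driven mediator dispersion (~1–3 units after covariate
adjustment) gives z ≈ 5–8, i.e. per-cohort power ≈ 1.  A 10-cohort pilot
during development confirmed 10/10 significant with all a-path estimates
negative.

## Problem sizes and numerical choices

* Controllability tolerance 1e−12 (PSD checks and PBH eigenvector-component
  floor); eigenvalue-degeneracy gap 1e−9 relative.
* Mediation bootstrap default 5000 draws (the pipeline default); the
  calibration suite uses 500 draws × 100 cohorts of n = 200, and the
  end-to-end suite 1000 draws × 20 cohorts of n = 93 — sizes chosen so the
  whole default test run finishes in a few minutes on one core.
* The pipeline's control stage computes average controllability for the
  configured region set (default: the nine language ROIs plus the three
  candidate mediators); full per-node batches (all 100 single-driver
  Gramians, ~0.7 s per connectome) are available via `batch_controllability`
  and the `global_check` config flag.
* Adjacency symmetry is enforced at 1e−9; file readers silently symmetrize
  asymmetries ≤1e−6 with a logged warning and reject anything larger.
* All generators and the bootstrap take explicit integer seeds; every output
  artifact carries a hash of the full configuration.

## Known limitations

* The size-correction formula `2w/(vol_i + vol_j)` is a documented
  convention; the motivating literature delegates the exact correction to the
  tracking toolchain.
* Whether inter-hemispheric links belong in the threshold's percentile
  population is unsettled; they are excluded here.
* The mediation stage reports all candidate mediators without
  multiple-comparison correction across mediators (flagged in the output).
* Raw (unstandardized) mediation effects are reported; standardization is
  left to the caller.
* The brain-age prediction model itself is out of scope: predicted ages are
  inputs (real) or draws (synthetic).
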