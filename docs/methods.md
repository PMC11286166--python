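# Methods

## The statistic

The unit of inference is the number of **three-point alignments** on a
mapped surface at search parameters (r, θ): unordered triples (p₁, p₂, p₃)
with p₂ the middle point, both link lengths ‖p₁p₂‖, ‖p₂p₃‖ ≤ r (inclusive),
p₁ ≠ p₃, and bearing change |b′ − b| < θ (strict), where b is the bearing
from p₁ to p₂ and b′ from p₂ to p₃. Conventions fixed here:

* **Unordered counting.** A traversal from either end is the same geometric
  feature; reversals are deduplicated. This is the convention under which
  the analytic expectations below carry a θ/360 factor — a directed count
  would be exactly twice as large. The choice is pinned empirically: the
  simulated mean count under CSR matches E_pois (below) with the θ/360
  factor, not 2θ/360.
* **All overlapping triples count.** A chain of L points contributes
  L − 2 triples; the analytic derivation enumerates all consecutive triples,
  so the detector does too.
* **Tie-breaks.** Distance inclusive (≤ r), angle strict (< θ). Coincident
  points cannot form a link (a zero-length link has no bearing).

Detection uses a k-d tree over the pattern; for each candidate middle point
the alignment condition is equivalent to two neighbours subtending an angle
greater than 180° − θ. Output is identical to exhaustive O(n³) enumeration
(tested on random patterns across the parameter ranges). Triples sharing a
consecutive pair are merged into maximal chains; branches yield separate
chains sharing a prefix.

## Null backgrounds and expected chance counts

Two stationary backgrounds are supported.

**CSR** (homogeneous Poisson, intensity λ in m⁻²):
E_pois = θ π² r⁴ λ³ A / 360, with A the window area in m² and θ in degrees.

**Thomas cluster** (Poisson parents at κ m⁻², Poisson(μ) offspring per
parent, isotropic Gaussian dispersal with per-axis SD σ in metres;
intensity λ = κμ):

    K_TC(r) = π r² + (1 − e^{−r²/4σ²}) / κ
    E_TC    = (θ A κ³ μ³ / 360) · K_TC(r)²

Both are instances of E = (θ/360) A λ³ K(r)², i.e. the expected number of
neighbours of a typical middle point is λK(r), the two neighbour counts are
treated as independent, and a uniformly random pair of link directions
satisfies the angle condition with probability θ/180 (ordered; halved for
unordered counting).

**Where the closed form is exact and where it is not.** Under CSR the
factorisation is exact and simulations agree with E_pois to within Monte-
Carlo noise plus a small edge deficit. Under a clustered background the
neighbour count of a typical point is overdispersed, so E[N₁N₃] > E[N₁]E[N₃]
and the closed form *understates* the true expectation. The package also
provides the exact third-order expectation (`expected_thomas_exact`) by the
cluster decomposition of the Thomas triple product density: a CSR term,
closed-form terms for one shared cluster membership, and two numerically
integrated terms (p₁, p₃ sharing a cluster; all three points in one
cluster, the three-Gaussian parent integral). At the reference surface fit
(κ = 18 m⁻², μ = 6, σ = 72.63 mm, r = 15 mm, θ = 30°) the exact expectation
exceeds the closed form by ~32%, and simulated means match the exact value
to within the edge deficit. The ratio falls to ~1 as clustering weakens
(large σ or large κ). The closed form is retained as the headline formula —
it is the quantity the scan pipeline uses — and its bias under strong
clustering is a documented limitation, visible in the validation harness.

**Edge effects.** The formulas assume an unbounded plane; no edge
correction is applied when counting (triples form only among mapped
points). On a finite window the observed count therefore falls short by
roughly `perimeter · r / A` in relative terms per link. Reports and the
validation harness carry this allowance explicitly. A corollary for the
significance scan: on a pure background the *"fewer than predicted"*
direction inflates beyond α once r is comparable to the window scale
(measured ~10–15% at r = 40–50 mm on a 1 × 1 m window), because the
uncorrected expectation overshoots. The *"more"* direction — the one a
positive conga-line finding rests on — is conservative at every r. High-r
"fewer" bands in scan output should be read with this in mind.

## Count distribution and significance

Replicate simulations show the alignment count is Poisson-distributed around
its expectation (verified by chi-square against Poisson(E_pois) under CSR).
The scan therefore evaluates, per radius, the Poisson tails
P(X ≥ x_obs) (direction "more", used when x_obs > E) and P(X ≤ x_obs)
("fewer"), flags rows with the relevant tail below α = 0.05, and reports
maximal contiguous runs of flagged radii with consistent direction as closed
intervals in mm. No multiple-testing correction is applied across the 46
radii by default (a Bonferroni switch exists); the per-radius readout is the
intended interface, and rows are strongly dependent across r anyway.

Model selection happens once per surface — the background is a property of
the surface, not of the search radius — then the scan sweeps r.

## Background fitting

* **CSR:** λ̂ = n/A, the homogeneous Poisson MLE (exact: λ̂A = n).
* **Pair correlation function:** kernel estimator with an Epanechnikov
  kernel of half-width 0.15/√λ̂ (Stoyan-type rule) and translation edge
  correction. The estimator divides by the pair distance d_ij rather than
  the grid value r, which removes most small-r bias — the region that
  carries the cluster signal. The translation weight needs the set
  covariance γ_W(v) = area(W ∩ (W + v)): exact for rectangles, otherwise
  computed once per window by FFT autocorrelation of a rasterised mask
  (512 cells on the long side; relative error < 1% at the displacements
  used) and interpolated bilinearly. Default grid: 128 radii in
  (0, short_side/4].
* **Thomas fit:** minimum contrast, D(κ, σ) = ∫ |ĝ^q − g^q|^p dr with
  q = 1/4, p = 2 over the PCF grid, optimised in (log κ, log σ) by
  Nelder-Mead from 5 starts (σ₀ log-spaced over 5–200 mm, κ₀ moment-matched
  from the PCF excess at the origin); μ̂ = λ̂/κ̂ by intensity matching, never
  a free parameter. The optimisation is box-bounded (κ ∈ [10⁻², 10⁵] m⁻²,
  σ ∈ [grid_lo/4, 2·r_max]): scales outside the fitted range are
  unidentifiable from ĝ, and unbounded parameters would make the fitted
  model unsimulable. A noise-free input curve is inverted to 10⁻⁴ relative.
  Fits on weakly clustered data are flagged (`weak_clustering`) rather than
  silently returned.
* **Goodness of fit (Diggle):** simulate m patterns from the fitted model,
  estimate each PCF with the same grid/bandwidth/edge correction, and rank
  the observed integrated squared discrepancy
  u_i = ∫ (Ŝ_i − S̄₋ᵢ)² dr within the pool (observed included):
  p_d = (1 + #{u_sim ≥ u_obs})/(m + 1) ∈ (0, 1]. Default m = 99 for
  single-surface runs; replicated simulation studies in the tests and the
  acceptance script use m = 19 (the smallest admissible pool), which keeps
  p_d granularity at 1/20 — under the null P(p_d ≤ 0.05) = 1/20, so type-I
  calibration is still measurable. As with any Monte-Carlo GOF test whose
  model parameters are estimated from the tested pattern, the test is mildly
  anti-conservative: measured rejection rates at nominal 5% run about 5–10%
  across replicate studies.
* **Selection:** the model with the larger p_d wins; exact ties go to CSR
  (parsimony) and are flagged. On genuinely clustered surfaces the Thomas
  model wins in ≳95% of replicates. On CSR surfaces selection is close to a
  coin flip — the Thomas model nests CSR (κ large or σ large), so both fits
  describe the data and both p_d values are near-uniform. This is expected
  behaviour for nested candidates under a pure GOF criterion, and harmless
  for the scan: the selected Thomas model is then CSR-like and yields nearly
  the same expectations.

## Preprocessing

**Retrodeformation.** Tectonic strain is estimated from ovate holdfast
discs: R is the mean axis ratio a/b, the stretch azimuth φ the circular
mean (period 180°) of major-axis azimuths. The correction is the
area-preserving pure shear — rotate by −φ, scale (x, y) by (1/√R, √R),
rotate back — applied to points, window and discs together. Area
preservation keeps fitted intensities comparable before and after; the
alternative one-axis rescale would differ only by an isotropic scale.
R = 1 leaves coordinates untouched and the azimuth is flagged undefined.

**Masking.** Eroded patches become window holes; covered points are
dropped, marks filtered in step, and the area (hence λ̂) adjusts. The
boundary convention is closed-exterior/open-holes: a point exactly on the
exterior or on a hole rim counts as inside. Masking is idempotent for a
fixed hole set.

## Synthetic surfaces

The generator emulates the study conditions: Avalonian surface densities
(tens to ~150 specimens m⁻², backgrounds CSR or Thomas with κ ≈ 10–200 m⁻²,
μ ≈ 2–6, σ ≈ 20–120 mm), mapped areas of a few m², and planted chains of
3–6 points. Chains start at a uniform anchor with uniform azimuth; each
link's bearing is the chain azimuth plus Uniform(−jitter, +jitter) (so
consecutive-link bearing changes never exceed 2·jitter, and any θ > 2·jitter
with r ≥ the spacing detects every planted triple by construction); spacing
is fixed or uniform in a band; chains are resampled until wholly inside the
window. Ground truth (anchors, lengths, spacings, azimuths, indices) is
returned alongside the surface.

The Thomas simulator seeds parents on the window dilated by 4σ (truncation
bias < 0.01% of the mean count), keeps offspring falling inside the window,
and discards parents. In the degenerate κ-huge/μ-tiny corner (the CSR limit
a fitted Thomas model can occupy) it switches to an exactly equivalent
scheme that enumerates only parents with at least one offspring
(zero-truncated Poisson counts). All generators are reproducible given
(seed, parameters, window); replicate studies derive per-replicate child
seeds from one root seed, so changing the replicate count does not reshuffle
earlier replicates.

What the generator does **not** emulate: inhomogeneous intensity
(habitat gradients), inter-specimen inhibition at contact scales, taxon
mixtures with different clustering, mapping error in coordinates. Passing
tests on synthetic surfaces therefore demonstrate correctness of the
machinery under the stated models, not robustness to every feature of real
surfaces.

## Validation harness and tolerances

`validate_analytic` compares closed-form expectations with simulation means
per parameter cell: a cell passes when
|E − mean| ≤ 3·SE + (perimeter·r/A)·E. The SE is the sample standard error
with a Poisson floor √(max(mean, E)/n_sims), which keeps the tolerance
meaningful in cells where E is so small that every simulation yields zero
(sample SE = 0). Standard grids: the CSR product grid
r ∈ {10, 12, 15, 20} mm × θ ∈ {20, 25, 30, 45}° × λ ∈ {10, 50, 100, 150} m⁻²
and a Thomas one-at-a-time grid about the controls
(κ = 55 m⁻², μ = 3, σ = 45 mm; κ ∈ {10, 75, 150, 200}, μ ∈ {2, 3, 4, 6},
σ ∈ {20, 45, 75, 120} mm), on a 2 × 2 m window. All CSR cells pass; most
Thomas cells exceed the tolerance in the direction and magnitude predicted
by the exact third-order expectation — the documented closed-form bias, not
a simulator defect (the simulator is validated separately against the exact
integral, the closed-form K-function and the cluster PCF).

Replicate counts in the shipped tests and acceptance script (500 simulations
per validation cell, 100-replicate recovery/selection studies, 200-replicate
calibration runs, 1000–2000-count distribution checks) are the package's
default desk-scale study sizes; all are parameters, and larger runs only
tighten the Monte-Carlo noise around the same conclusions.

## Units and interfaces

Internally everything is SI (metres, m⁻², degrees for angles and bearings).
The CLI and file formats accept the field's working units — r, σ and
spacings in millimetres — and convert once on ingest. Point maps are CSV
(`id,x_m,y_m[,taxon,...,orientation_deg]`), windows GeoJSON Polygons (first
ring exterior, rest holes), discs CSV ellipses, scan output TSV, everything
else JSON with deterministic key order. Every run log records the seed,
configuration and package version needed to replay it.

## Known limitations

* The closed-form clustered expectation E_TC is a second-order
  approximation; under strong clustering it understates chance alignments
  by tens of percent (use `expected_thomas_exact` where the exact value
  matters). A scan that selects a strongly clustered background therefore
  *over-flags* "more than predicted" to the same degree.
* No edge correction in counting (by design, matching the formulas'
  derivation): high-r "fewer" findings on small windows are partly an edge
  artifact.
* κ and μ from the minimum-contrast fit carry ~25–30% median sampling error
  at realistic conditions (they are anti-correlated through μ = λ̂/κ̂); σ is
  better determined (~12%).
* Only stationary CSR and single-Thomas backgrounds are fitted; double
  Thomas and inhomogeneous Poisson processes are out of scope.
* Expected counts are for triples only; chain-length-resolved expectations
  (beyond L − 2 triple bookkeeping) are not provided.
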