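# Methods

This note records the statistical procedures paleodem implements, the
conventions and defaults it fixes, what the synthetic-data generator does
and does not emulate, and the design choices made where the methodology
was genuinely open.

## Calendar conventions

Time is in calendar years BP (before 1950 CE); larger is older. All
intervals — site phases, time slices, snapshot windows — are half-open
`[older, younger)`: the older bound belongs to the interval, the younger
does not. This makes adjacent slices partition time exactly (a phase
ending at a slice's older edge contributes nothing to it) and makes the
textbook aoristic example exact: a 4,000–3,600 phase covers precisely four
100-year slices at weight 0.25. Grids are 1-year and stored oldest-first.

## Calibration

A calibration curve is a table (cal BP, ¹⁴C BP, 1σ); both the ¹⁴C mean
m(θ) and the curve error s(θ) are interpolated linearly onto a cached
1-year grid. Calibrating `cra ± σ_lab` evaluates the Normal density of the
measurement at every grid year with total standard deviation
√(σ_lab² + s(θ)²). Two output conventions:

* **unnormalized** — the raw per-year density values. Summing these avoids
  the spurious narrow peaks that per-date normalization creates where the
  curve steepens, at the cost that a single date's total mass is ≈ 1/m′(θ)
  rather than exactly 1.
* **normalized** — rescaled to unit mass over the date's support.

Support is trimmed where the cumulative mass outside falls below 1e-5 per
side (bounded memory, negligible bias); calibration is invariant to curve
row order and to grid extension beyond the trimmed support. Dates whose
measurement sits more than ~6 combined σ from the curve's ¹⁴C range raise
a range error. Marine-reservoir correction and Bayesian sequence modelling
are out of scope; marine samples are excluded at the filtering stage.

**Back-sampling.** Simulation needs the inverse map: for a calendar year θ
we draw `cra = m(θ) + N(0, s(θ))` and attach a lab error resampled with
replacement from the observed dataset's errors. The literature this
pipeline follows does not pin down the mechanism; this choice mirrors
common SPD model-testing practice and is the one tested here. The
*generator* additionally adds `N(0, σ_lab)` measurement noise when
fabricating observed datasets, since a real lab measurement carries its
own error; the null-model simulator deliberately does not add it twice
(the lab error already enters the calibration width).

## Filtering, binning, SPD

Retained dates have σ_lab ≤ 300 ¹⁴C yr, an anthropogenic origin, no marine
reservoir problem, and a CRA inside the 6,500–2,500 uncal BP collection
window — a window deliberately wider than the 6,000–3,000 cal BP analysis
window so the SPD carries no artificial taper at the window edges.
Exclusions are logged with per-row reasons.

Within each site, CRAs are clustered by complete-linkage agglomeration cut
at 50 ¹⁴C years ("within 50 years of each other", the rcarbon convention);
a bin contributes the arithmetic mean of its members' calibrated
densities. Dates at different sites never share a bin, and stratigraphic
phases within sites are not distinguished (site-only binning). The SPD is
the per-year sum of bin densities, reported on the analysis window;
internally the sum is also kept on a grid padded by `simulation_pad`
(default 500 yr) per side — see the null model below.

## Logistic null-model test

The null is logistic growth `f(τ) = K / (1 + exp(−r (τ − τ_mid)))` with τ
the years elapsed since the older edge (so r > 0 means growth toward the
present). The fit is deterministic least squares (initialized at
K = max SPD, r = 0.004/yr, τ_mid at mid-window; r bounded to [0, 1]; a fit
pinned at the r ≈ 0 boundary — e.g. a constant SPD — is flagged rather
than rejected). The fit uses the padded SPD so the model is constrained
wherever simulated dates will be drawn.

Each of `nsim` (default 1,000) simulations draws the observed number of
bins as calendar years ∝ f over the *padded* window, back-samples,
recalibrates and sums. Padding matters: the observed SPD contains tail
mass from dates older/younger than the analysis window (that is what the
broader collection window is for), and simulations must carry the same
edge mass or the test manufactures spurious edge deviations. The envelope
is the pointwise 2.5th/97.5th percentile; the deviation statistic is
`S = Σ max(0, obs − hi) + max(0, lo − obs)` over the analysis window only;
the global p uses the (k+1)/(n+1) convention with simulated statistics
measured against the pooled envelope (not leave-one-out — tractable and
standard, slightly conservative). Deviation regions are maximal pointwise
exceedance runs, reported in-window. No per-year z-scoring is applied
before envelope construction. With the bundled smooth curve the test's
type-I error over 100 null replicates at nsim = 199 sits inside the
central binomial band around 5% (the acceptance suite recomputes this).

## Mark-permutation test

Bins carry a categorical mark (the rainfall zone, in the reference
application). Under exchangeability, shuffling marks across bins —
group sizes fixed to the observed counts — leaves group SPDs invariant in
distribution. Permutation is at bin level, not date level, so an
oversampled site-phase moves between groups as a unit. Per-group
envelopes, deviation statistics and global p-values follow the null-model
conventions; with more than two marks each group is tested against its own
envelope and the per-group p-values are reported alongside their minimum
(clearly labelled — the combined statistic is not uniquely defined in this
design).

## Settlement proxies

On the 100-year slice grid (30 slices for the default window):

* **raw counts** — phases overlapping a slice, counted at phase level
  (a site occupied in two phases of one slice counts twice; documented
  choice where site-level counting would also be defensible);
* **aoristic weights** — overlap/length per slice; every phase carries
  total weight 1 over its span, so coarse phases are diluted rather than
  repeated;
* **randomized start** — per run, each phase of length ≥ d (default
  d = 100 yr, the assumed mean occupation span) receives an occupation
  `[s, s − d)` with s uniform such that the occupation stays inside the
  phase; shorter phases are occupied throughout. The per-slice mean
  occupancy over `nsim` runs is reported, bounded above by the raw count.
  A fixed-duration occupation is used (the aoristic literature's
  convention for "mean length of occupation"); an exponential-duration
  variant was considered and not adopted to keep the Monte-Carlo
  expectation analytically checkable;
* **summed area** — settlement hectares per slice, raw or aoristically
  weighted; phases without areas are dropped and counted.

## Spatial summaries

Snapshots at 200-year intervals include every phase overlapping the
interval (half-open rule). Urban (contiguous) data are mapped with a
Gaussian KDE of bandwidth 50 km weighted by site area; the kernel and the
5 km cell size (bandwidth/10) are this package's defaults — the method the
pipeline follows states only the bandwidth. The kernel is evaluated
separably and truncated at 4σ per axis (mass loss < 1e-4), on an
equirectangular projection about the data centroid (distance error well
under 1% at the regional extents intended; the projection is pluggable).
The surface is a density per km², so its integral recovers the total
included weight. Bounded survey data are summarized instead as distinct
sites occupied per km² of survey area.

## Cross-proxy comparison

The per-year SPD is averaged within each slice; proxies are min-max scaled
to [0, 1] for display (Pearson's r is affine-invariant, so scaling cannot
change the correlations, and the tests verify this to 1e-12). Matrices are
computed over the full window and over 6,000–4,000 cal BP (30 vs 20
slices); p-values come from the t transform of r with n − 2 df, with no
multiple-testing correction. How a per-year SPD should be aggregated to
century slices is not uniquely defined; slice means are the documented
choice here.

## Synthetic data: what it emulates, what it does not

The generator fabricates a full study from an explicit per-year "true"
population curve (logistic; boom–bust = logistic rise saturating by 4,500
BP, plateau, linear decline from 4,200 BP to 30% of peak by 3,400 BP; or
uniform). Defaults mirror the reference study design: 963 dates from 77
sites, 1,157 survey sites in 2,783 phases over 16 surveys, 132 urban sites
(≥ 10 ha) in 283 phases, two rainfall zones with configurable multipliers
or per-year trajectory factors, and a mixed-resolution period schema whose
coarsest period spans 2,400 years — reproducing the "dated only to a broad
period" degradation that motivates aoristic weighting. Lab errors are
lognormal (median 30 ¹⁴C yr, shape 0.4, clipped to [10, 300]); dates
concentrate on sites with a Zipf-like law (exponent 1.1) so binning has
realistic work; true occupation spans have ~exponential lengths (mean
250 yr) and are then *reported* only at their period's resolution. All
generators are seeded and record their seed.

Passing tests on this generator show the pipeline recovers known truths
under idealized conditions: a smooth strictly-monotone calibration curve
(no reversals or plateaus as sharp as a real curve's), spatially random
sites within zone latitude bands, no taphonomic loss, no research-bias
clustering of dates beyond the Zipf site law, and period schemas that tile
the window exactly. Real data violate all of these to some degree, so the
synthetic results bound what the methods can do, not what any particular
dataset supports. A real IntCal20 `.14c` file is a drop-in replacement for
the bundled curve wherever a curve is accepted.

## Numerical choices and degenerate inputs

* Calibration densities treated as zero beyond |z| = 6 combined σ; tail
  trim at 1e-5 cumulative mass per side.
* Logistic fit: scipy `curve_fit` with the stated deterministic
  initialization; non-convergence raises a fit error with diagnostics.
* Envelope refuses nsim < 20 (a 95% envelope is undefined); identical
  simulations collapse the envelope onto the observation and give p = 1.
* Constant series cannot be min-max scaled (explicit error); empty
  subsets, zero-length phases, unknown survey ids, negative KDE weights
  and non-monotone curves raise typed errors rather than propagating NaNs.
* Scale: problem sizes in the tests are chosen at desk scale (hundreds of
  dates, ≤ 1,000 simulations per test) so the full suite runs in a few
  minutes; the statistical procedures are identical at full scale and all
  defaults remain the reference-study values.

## Known limitations

* The global p of the permutation test is reported per group (plus the
  labelled minimum); a single combined two-group statistic is not defined.
* Taphonomic correction, phase-model chronologies, exponential/uniform
  nulls and curve mixing are out of scope.
* Survey densities count distinct sites; the raw-count proxy counts
  phases. Both are documented above; mixing them across datasets with very
  different phase conventions requires care.
* The equirectangular projection is adequate regionally but not for
  continental extents; supply projected coordinates (or a different
  projection) there.
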