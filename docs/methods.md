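# Methods

This note documents the statistical models implemented in `elevdiv`, the
choices made where conventions genuinely differ between packages and
papers, and what the synthetic-data experiments do and do not demonstrate.

## Data model and conventions

An occurrence record is a per-species capture tally at a site; sites carry
the elevations actually measured, which may deviate from the nominal 100-m
transect grid. Species elevational ranges are computed from those actual
site elevations (min/max, range size = max − min, midpoint = mean of the
extremes), so ranges need not be multiples of the grid spacing.

*Singletons.* A species represented by a single collected individual fixes
one point, not a range; with `exclude_singletons` (the default for range
analyses) such species are removed before range computation. The rule is
"one individual in total", not "one site".

*Bands.* Elevation bands are regular, half-open `[lower, lower + width)`
with the last band closed at its top edge, so the band grid partitions the
domain. The default spec (origin 900 m, width 200 m, 7 bands) covers
900–2300 m; survey records slightly below the origin (e.g. an 880-m
transect) are clamped into band 0 with a logged warning rather than
discarded. Both origin and width are configurable.

*Altitude areas.* Pooled assemblages follow the vegetation-zone breaks
800 / 1300 / 1800 / 2300 m (low / mid / high), half-open on the left with
the top break closed. Which side a boundary record falls on is a
convention, not biology; it is declared here and configurable.

## Hill-number diversity

Empirical Hill numbers use the standard formula with the q → 1 limit
(exponential Shannon entropy). Asymptotic estimators:

- **q = 0**: bias-corrected Chao1, `S + f1²/(2 f2)` when doubletons exist,
  else `S + f1 (f1 − 1)/2`.
- **q = 1**: the Chao–Jost nearly unbiased entropy estimator (the sum of
  reciprocal terms for observed counts plus the singleton correction
  involving `A = 2 f2 / ((n − 1) f1 + 2 f2)`), exponentiated. This is the
  estimator used by the standard rarefaction/extrapolation framework for
  abundance data; a reference implementation of that framework is not
  available in this environment, so the estimator is validated against its
  published closed form, hand-computed values, and a bias-reduction
  experiment on communities with known entropy.
- **q = 2**: the minimum-variance unbiased inverse Simpson,
  `1 / Σ[x_i (x_i − 1) / (n (n − 1))]`, undefined when every species is a
  singleton (raised as an error).

*Rarefaction/extrapolation.* Richness interpolation uses the exact
hypergeometric expectation `S(m) = S − Σ C(n − x_i, m)/C(n, m)` (evaluated
in log space) and is tested against an exhaustive subsample-enumeration
oracle for n ≤ 8. Richness extrapolation uses the Chao1-based closed form
`S + f0 [1 − (1 − f1/(n f0 + f1))^{m−n}]`, flat when there are no
singletons. For q = 1 the interpolated value is the exact expected
subsample exponential entropy (hypergeometric expectation of the species
count spectrum); for q = 2 the closed form
`1/(1/m + ((m − 1)/m) Σ x_i(x_i − 1)/(n(n − 1)))`, which equals the
empirical value at m = n. Extrapolated q = 1 and q = 2 points approach
their asymptotic estimators along the same saturating curve as richness
(rate `f1/(n f0 + f1)`); the anchor at m = n and the asymptote follow the
framework, the transition curve between them is implementation-defined and
pinned by tests. The default size grid runs to 2n, the commonly
recommended reliable extrapolation horizon.

*Coverage.* The reference-size estimator is the standard `f1/f2` formula;
interpolated coverage uses the exact expectation, extrapolated coverage
the geometric decay form. Curves are non-decreasing over the interpolated
regime (tested).

*Bootstrap.* Confidence intervals (default 1000 replicates, 95%,
percentile) resample from the coverage-adjusted estimated community:
observed frequencies shrunk by estimated coverage, plus `ceil(Chao1 − S)`
unseen species sharing the residual probability — so resamples can contain
species absent from the data, as the estimated community implies. A plain
empirical-multinomial scheme is available (`scheme="multinomial"`).
Degenerate resamples (e.g. all-singleton at q = 2) are dropped via
nan-percentiles. The statistic bootstrapped defaults to the asymptotic
estimator; calibration on communities with known exponential entropy shows
near-nominal coverage at moderate sample sizes.

## Rapoport's rule tests

All four tests consume the same representative-species range table.
Stevens' membership rule at band boundaries follows the global half-open
convention (`min < band_upper` and `max ≥ band_lower`, with the last band
closed) — no published description pins this down, so it is declared and
tested, including against a direct-loop reference implementation. Pagel
and mid-point binning partition the species set (each species in exactly
one band); Stevens counts species once per overlapped band.

Band x-coordinates are arithmetic band mid-elevations. Empty bands are
excluded from fits rather than imputed as zero, because a zero mean range
is not an observation. Fits are ordinary least squares; the p-value is the
two-sided t-test on n − 2 df (for the quadratic fit, the overall F-test on
(2, n − 3) df). A fit requires at least three occupied bands (three
species for the cross-species test).

The `supports_rapoport` verdict is *positive* iff the linear slope is
positive and p < α (default α = 0.05, configurable; surveys sometimes
narrate p-values slightly above 0.05 as support, so the default here is
deliberately the stricter conventional threshold and the raw p is always
reported alongside). The mid-point method additionally reports a parabolic
fit and a unimodality flag (negative leading coefficient with the vertex
strictly inside the observed x-range) — on a bounded domain random range
placement alone produces this interior-maximum profile (the mid-domain
effect), which is why a flat or unimodal mid-point profile does not refute
the other tests.

## Barcode delimitation

K2P distances separate transition (P) and transversion (Q) proportions
over pairwise-complete sites; gap/ambiguity handling is pairwise deletion
by default (complete deletion by flag), matching common barcode practice.
Saturation (either log argument ≤ 0) yields an infinite-distance sentinel;
`nj_tree` refuses saturated matrices rather than silently capping, since a
capped distance would distort the whole topology.

Neighbor joining is the standard Q-matrix agglomeration; on additive
matrices it reproduces the generating tree exactly (tested against random
additive trees up to 12 taxa and against an independent NJ implementation).
Negative branch-length estimates are clamped to zero with the usual
compensating transfer to the sibling branch. Bootstrap supports resample
alignment columns; replicates with saturated distances are skipped and
removed from the denominator. A species is monophyletic iff some edge
bipartition isolates exactly its sequences (single-sequence species are
trivially monophyletic and flagged as such in the report).

Alignment is an input: equal-length barcode fragments are treated as
positionally aligned, and no progressive aligner is included — COI barcode
fragments amplified with standard primers are equal-length and indel-free
in practice, and alignment tools are better used upstream.

The barcode simulator evolves sequences under the K2P process itself
(transition/transversion rate ratio κ, default 4), species ancestors
diverging by `inter_d` and conspecific sequences by `intra_d` expected
substitutions/site, so realized K2P distances are consistent estimates of
the simulation parameters (tested at length 10⁴).

## Synthetic communities

The generator emulates a 15-transect, two-replicate light-trap survey over
880–2280 m:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 88 | species pool (observed richness is lower) |
| `domain_m` | (880, 2280) | elevational domain, m |
| `rapoport_beta` | 0 | slope of expected range width on midpoint |
| `range_width_mean_m` / `_sd_m` | 450 / 220 | width draw (truncated at 0), m |
| `abundance_lognormal_mu`/`_sigma` | −1.5 / 1.1 | log-scale abundance params |
| `midpoint_tilt` | 0 | low-elevation skew of midpoint density |
| `abundance_elevation_decay` | 0 | per-m log-linear abundance decline |
| `detection_prob` | 1.0 | thinning of the Poisson site tally |
| `replicate_elevation_jitter_sd_m` | 15 | replicate elevation jitter, m |

Midpoints are uniform on the domain by default; ranges are clipped to the
domain *after* the width draw, which deliberately builds in the mid-domain
artifact the null model is supposed to exhibit. Detection is Poisson per
available site (a species is available iff the site elevation lies in its
true range) — no detection model is dictated by survey practice, so
Poisson is an explicit implementation choice. Observed ranges are
therefore always subsets of true ranges.

The defaults were chosen once to mirror the structure of a real temperate
montane crambid survey: ~73–75 observed species, the dominant species
holding ~11% of all individuals, and a tail of roughly 13–14
single-specimen species. `study_params()` additionally sets a strongly
positive `rapoport_beta` (0.6), a low-elevation midpoint tilt (2.0) and an
abundance decay (1.2 × 10⁻³ per m, about a three-fold decline across the
gradient); with uniform midpoints alone the bounded domain forces a
mid-elevation richness peak, so the tilt and decay are what produce the
survey-like monotone diversity decline. Totals come out near ~500
individuals per simulated survey — the per-species abundance *structure*
(dominance, singleton tail), not the absolute catch, is what the
downstream estimators are sensitive to.

What passing synthetic tests shows: the estimators recover the generating
model's qualitative structure (positive range-width slopes when simulated,
the mid-domain unimodal profile under the null, 100% barcode monophyly
when intraspecific divergence is far below interspecific). What it does
not show: behaviour under phenology, weather, spatial autocorrelation
beyond elevation, detection heterogeneity between species, or taxonomic
error — none of which the generator models.

## Numerical and reproducibility choices

- One integer seed drives everything: the simulator uses per-stage spawned
  generator streams, and each bootstrap derives a stable sub-seed from the
  run seed and the stage name (FNV hash, kept below 2³¹).
- Combinatorial quantities are evaluated with log-gamma arithmetic; no
  factorial overflow at any sample size.
- Problem sizes in the shipped experiments (200 recovery replicates, 40
  barcode runs, 1000-replicate bootstraps) were chosen as the smallest
  sizes at which the Monte-Carlo error is clearly below the effects being
  demonstrated.
- Dataset-level survey statistics (total individuals, per-area diversity
  triples, mean representative range, dominance share) can be recomputed
  by pointing the ingest pipeline at the survey's archived occurrence and
  site tables (`data/dryad/` in the test suite's convention); the archive
  is external and not redistributed here, so the corresponding test fails
  in its absence rather than silently passing.

## Known limitations

- Hill orders are restricted to q ∈ {0, 1, 2}; no continuous q profiles.
- No beta/gamma diversity partitioning.
- The q = 1/q = 2 extrapolation transition curve is implementation-defined
  (see above); interpolated values and asymptotes are exact.
- The NJ implementation is quadratic-memory and intended for barcode-scale
  trees (hundreds of sequences), not phylogenomics.
- Range estimation ignores detection failure at range edges: observed
  ranges are biased low at low abundance, which is precisely why
  single-specimen species are excluded rather than modelled.
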