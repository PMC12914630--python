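# Methods

## Size taxonomy and the double-count rule

EV classes are closed radius intervals: exomere [15, 30] nm, exosome
[25, 75] nm, microvesicle [50, 500] nm, apoptotic body [500, 2500] nm. The
intervals overlap at [25, 30] nm, [50, 75] nm and the point 500 nm, and
classification is deliberately multivalued there: a grid radius inside an
overlap contributes its full count to every containing class when a profile
is binned. Closed intervals are used on both ends, so the five boundary
radii (25, 30, 50, 75, 500 nm) belong to both adjacent classes; this is the
simplest rule that generalizes "one overlap radius is counted twice" to any
grid. Radii below 15 nm or above 2500 nm are retained in an `unclassified`
bucket so the conservation identity

    Σ_class counts + unclassified − raw total
        = Σ_{overlap points} (multiplicity − 1) × count

can always be checked. The cryo-EM census is the one place assignment is
exclusive (composition percentages must sum to ~100): there a vesicle in an
overlap is assigned to the smaller class.

## DLS profiles and normalization

Profiles are treated as point masses on the exported radius grid: no
interval smearing, no inversion of autocorrelation data — the pipeline
starts where the instrument export ends, and the count-rate unit is an
opaque instrument-relative scale. Per-class counts are normalized by

    rate_k = C_k × (V_media/V_collected) × (V_resusp/V_aliquot) × dilution
                 / (cell_seed_density × collection_days)

with chain defaults 2000/500/50/10 µL and 1:50 dilution (factor 1000),
seeding densities 5×10⁵ cells/mL (Petri) or 1×10⁵ cells/mL (neurofluidic),
and collection intervals of 3 days for maturation samples (media exchanged
every three days) or 0.5/1.0 days for 12 h/24 h post-manipulation samples.
The absolute volume factor cancels in every within-study fold change; it is
kept explicit and configurable so the rate unit is auditable.

## Statistical comparison scheme

Group summaries are median, IQR (q75 − q25) and 10th/90th percentiles,
computed by linear interpolation of order statistics (quantile "type 7");
no convention is imposed by the data source, so one is fixed here and used
everywhere.

Two-group comparisons are gated on normality: both groups must pass
Shapiro-Wilk at 0.05 for the unpaired t-test branch, otherwise Mann-Whitney
U is used. The t-test is Welch's (unequal variances) — the safer default
when the variant is unspecified. Groups with n < 3 cannot be tested for
normality and fall to the non-parametric branch. The Mann-Whitney p-value
is the exact two-sided tail when the pooled sample is ≤ 12 and tie-free,
and the tie-corrected normal approximation with continuity correction
otherwise; fully tied inputs return p = 1 by convention (no ordering
information). Kruskal-Wallis (tie-corrected H, chi-square p with k − 1 df)
serves as the omnibus test for three-condition contrasts, with an exact
enumeration mode for small tie-free fixtures; pairwise fold changes under an
omnibus caption are reported from pairwise medians, uncorrected.

Bonferroni correction is applied to the significance level (α/m — e.g.
0.05/5 = 0.01), not by inflating p-values. Fold changes are max/min of the
two medians, rounded half-up to the number of decimals being reported
(2 by default); direction is relative to the first (baseline) group.
Biological replicates and the 7 technical measurements are pooled as
observations by default, matching how group sizes are reported in the
source figures; callers can aggregate per replicate first if they prefer
the conservative unit of analysis.

## Synthetic experiments

The generator emulates what matters statistically about the study design:

- one lognormal radius component per class, with default medians 21, 40,
  160 and 1000 nm (inside each class's non-overlap core) and log-sigmas
  0.12–0.35 — narrow enough that most mass stays in-class, wide enough to
  exercise cross-class leakage;
- component abundances calibrated in closed form: class rates are linear in
  abundances, so a 4×4 matrix built from one noiseless unit-abundance pass
  per component is solved so the noiseless pipeline output equals the
  designed per-class rate medians exactly (no fitting);
- replicate structure n_bio ≥ 3 (typically 3–10) × exactly 7 measurements,
  as in the study;
- noise: independent multiplicative lognormal per grid point with mean 1
  and coefficient of variation `noise_cv` (default 0.3), plus an optional
  per-measurement global lognormal scale factor with **median** 1
  (`meas_scale_cv`, default 0). The mean-1/median-1 choices keep the class-
  rate medians centred on the design targets, which is what the closed-form
  calibration promises. Positive, right-skewed noise matches the heavy-IQR
  box plots DLS count data produce;
- the default grid is 200 log-spaced radii from 15 nm to 5 µm with
  62.443 nm inserted, so every simulated dataset exercises the double-count
  path.

What the generator does *not* emulate: light-scattering physics (intensity
weighting, Mie effects), correlated noise across radii, replicate-level
biological drift, or instrument saturation. Passing tests therefore show
that the pipeline's arithmetic, test selection and error rates behave as
designed under a plausible noise model — not that any biological
conclusion transfers to real cultures.

## Channel transport

Stokes-Einstein `D = k_B T/(6πηr)` with defaults T = 310.15 K and
η = 6.9×10⁻⁴ Pa·s (water at 37 °C; culture media are slightly more viscous
and the value is configurable). Transit times use the 1-D two-reservoir
scaling `t = L²/(2D)` for channel lengths 557–1353 µm at 5 µm height; the
time-resolved arrival fraction uses the semi-infinite 1-D solution
`erfc(L/(2√(Dt)))`, and steady transport Fick's first law `J = D·A·ΔC/L`.
These are deliberately the simplest textbook models — no convection,
entrance effects or 3-D geometry — and are verified by their scaling
properties (D ∝ 1/r, t ∝ L²), not against external reference values.

## miRNA screening

Median-of-ratios size factors: the reference is the per-miRNA geometric
mean across samples over rows with no zeros; each sample's factor is the
median ratio to the reference. The expressed-miRNA rule keeps a feature if
at least 3 samples have a normalized count ≥ 5 (both thresholds inclusive
and configurable). Differential-expression flagging applies
p_adj ≤ 0.05 AND |log2FC| ≥ log2(1.5), two-sided, to externally supplied
statistics; the negative-binomial model that produces them is the province
of dedicated DE packages and is intentionally not reimplemented (the
size-factor implementation is cross-checked against pydeseq2 in the tests).

## Numerical and testing choices

- Rounding of reported folds and census percentages is decimal half-up (not
  banker's), matching how such values are conventionally printed.
- The exact Mann-Whitney p is validated against an exhaustive enumeration
  oracle over all C(n, n_a) labelings for pooled n ≤ 10.
- Problem sizes in the test suite and acceptance script: 500-case oracle
  sweeps, 2000 simulated null pairs (n = 21/group) for the type-I error
  band [0.03, 0.07] at α = 0.05, 20–50 seeds × (10 bio × 7 meas) profiles
  for parameter-recovery checks. These sizes give stable Monte-Carlo
  estimates (binomial SE ≈ 0.005 on the type-I rate) while keeping a full
  run in seconds.
- Degenerate inputs: empty groups, non-positive radii/volumes/densities and
  malformed profile files raise ValueError (with file:line for parse
  errors); a zero median makes a fold change *flagged undefined* rather
  than raising, since downstream tables must be able to carry it.

## Known limitations

- Absolute secretion rates are instrument-relative; only ratios are
  meaningful across studies (no NTA cross-calibration).
- Whether DLS count rates are intensity- or number-weighted is not modelled;
  profiles are treated as opaque relative counts.
- The published per-sample expressed-miRNA totals require the original
  sequencing data and cannot be recomputed here; only the rules are
  implemented and verified on synthetic counts.
- Several published sham-handling fold values are inconsistent with their
  own printed medians; the worked-example table excludes them.
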