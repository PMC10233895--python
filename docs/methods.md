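# Methods

## Scope and data flow

`colonyscreen` quantifies colony-array chemical-genomic screens starting
from per-colony growth time series; image segmentation and pixel
calibration are upstream concerns (inputs are assumed
background-subtracted, and an optional monotone calibration function
converts intensities to cell counts). The stages are:

1. calibrate → smooth → QC each growth curve;
2. estimate each colony's doubling time *D*;
3. fit the control-colony log2(*D*) surface per plate and normalize;
4. exclude slow growers, compute LPIs, call hits (t-test + BH + effect
   gate);
5. compare hit lists (Venn regions, union percentages, hypergeometric
   tails).

All stage tables are TSV with `#` metadata headers, so any stage can be
re-run standalone on the previous stage's file.

## Growth curves and doubling time

Curves are smoothed with a median filter then a moving average (defaults
5 and 5 points, edge-truncated windows so no padding values are
invented). For a pure exponential both filters multiply the series by a
constant, so they do not bias the log-slope; tests check the estimate
moves by < 1% on noise-free data.

QC flags curves with (a) dynamic range max/min below 2 (less than one
doubling observed over the assay), (b) more than 25% decreasing steps,
or (c) fewer than 10 points. These thresholds are this package's own
minimal rules; the observed rejection rate on simulated screens
(~0.3%) is an emergent property of the corruption model, not a target.

Doubling time: least-squares slope of log2(value) on time in every
sliding window (default 7 points ≈ 2.3 h at 20-min sampling), keeping
the maximum slope among windows with r² ≥ 0.95 and strictly positive
values; *D* = 1/slope, in hours. On noise-free exponentials this is
exact to machine precision for any window length, and it is invariant
to rescaling the series (slope of a log). A curve with no qualifying
window raises a no-growth error (batch processing records a flag
instead). The window targets the early exponential phase; because the
logistic curve's log-slope declines as colonies approach capacity, the
max-slope rule automatically selects early windows.

## Spatial normalization

Control colonies sit at every fourth plate position (one parity
sub-grid, 384 of 1536). The control surface is a Gaussian-kernel
local-linear (LOESS-style, degree 1) fit of the control log2(*D*)
values, evaluated at every plate position and clipped to the observed
control value range; QC-failed controls are dropped, never imputed, and
at least 4 usable controls are required. Normalization is strictly per
plate.

Design choice: a local-constant (Nadaraya–Watson) weighted mean was
considered and rejected — at plate edges its effective kernel is
one-sided, which shrinks tilted bias fields toward the interior and
leaves residuals of ~0.02–0.035 log2 units under realistic gradients;
repeated normalization then keeps moving values by more than 0.01.
Local-linear weighting is exact for planar fields everywhere, including
edges; its leading error is curvature bias ≈ ½·bw²·f″. The default
bandwidth of 3 grid units (1.5× the control spacing) keeps that bias
below 0.01 for bias fields smooth on the plate scale while still
averaging ~10–15 controls per position for noise robustness. With these
defaults, an injected gradient-plus-sinusoid bias field of amplitude
0.2 log2 units is removed to within 0.013, and re-normalizing an
already-normalized plate moves values by < 0.007. The clip to the
control range guards against extrapolation overshoot on plates with
many missing controls.

## LPI and calling

The replicate-level LPI is each usable stressor replicate minus the
*mean* of the usable background replicates (plates are unpaired, so no
replicate pairing is meaningful; the background enters via its mean and
the stressor replicates carry the tested variance). Requires ≥ 2
stressor and ≥ 1 background replicates; strains below that are reported
uncalled rather than silently dropped.

Calls: two-sided one-sample *t*-test of the replicate LPIs against 0
(df = n−1), BH step-up within each condition across all tested strains,
reject at q ≤ α = 0.01, plus the strong-effect gate |mean LPI| ≥ 2.5
(≈ 5.6-fold doubling-time change). Resistance is called symmetrically
at LPI ≤ −2.5 (configurable off). Zero-variance replicates are a
degenerate case: nonzero mean → p = 0; zero mean → p = 1. BH per
condition (not pooled across conditions) matches per-condition hit
lists; the t-test and BH computations are delegated to scipy and
statsmodels, with tests checking them against a closed-form df = 2 CDF
and a direct step-up oracle.

Slow growers — strains whose mean background log2(*D*)_norm is ≥ 1.5
(≈ 2.8-fold slower than the local control) — are excluded before
testing; the cutoff value is this package's choice, as only the outcome
of such an exclusion (a few percent of a collection) is externally
constrained. Dubious ORFs or other unwanted strains can be removed via
a user-supplied blacklist file.

## Gene-set overlaps

Overlap percentage uses the union as denominator, rounded to the
nearest integer. Significance is the exact hypergeometric upper tail
P(X ≥ k) via `scipy.stats.hypergeom.sf` (log-space stable); tests
verify it against exact integer enumeration for universes ≤ 12. The
default universe is 4308 (a genome-wide scored collection), always
configurable: overlap p-values are only meaningful relative to a stated
universe, and published values for externally derived gene sets are
often computed against the full pre-exclusion collection — the
acceptance script uses 4595 for exactly that comparison. Fold changes
are 2^LPI at full precision; report formatting truncates (not rounds)
to one decimal.

## Synthetic screens

The generator emulates the screen design the analysis assumes: 32×48
plates, 384 interleaved controls, one plate per condition × replicate
(default one background + one stressor, n = 3), logistic growth
(no lag term — only doubling time is consumed downstream) sampled every
20 min for 72 h from ~1e5 inoculated cells toward a 1e7-cell capacity.
A colony's log2 doubling time is baseline + spatial bias + strain effect
+ noise:

- baseline_D = 2.5 h (a typical wild-type yeast doubling time on rich
  solid medium; the source screen does not state one);
- bias: a fixed smooth surface (linear gradient + one full-period
  cosine along the long axis, peak amplitude 0.2 log2 units), identical
  across plates so control interpolation can capture it;
- effects: additive log2 terms per strain × condition (positive =
  slower = sensitive); controls always 0;
- noise: i.i.d. N(0, 0.05²) log2 units per colony (calibration choice —
  unstated by the source screen — giving realistic within-replicate
  scatter);
- corruption: with probability 0.003 a curve is replaced by
  high-variance lognormal noise around the inoculum, which QC must
  reject.

Everything derives from one `numpy` generator seeded from the config;
identical seeds give bit-identical screens.

What the simulator does *not* emulate: measurement noise within a
curve (noise acts on the colony's rate, not per time point), lag and
saturation-phase phenotypes, pinning-density and neighbor effects,
scanner batch effects, and non-smooth (e.g. edge-row) position effects.
Passing tests therefore demonstrate the pipeline's correctness under
its own stated assumptions — additive smooth bias, exchangeable
replicates — not robustness to every artifact of real plate data.

## Validation experiment sizing

Simulated validation screens use 1000 strains with 50 planted +3.0
log2-unit effects (and, in the pipeline test, 600 strains with 30
planted) — a ~5% hit fraction matching what genome-wide stressor
screens of this kind actually report. The hit fraction matters: BH's
rejection threshold scales with the fraction of true effects, and with
n = 3 replicates the t-test's attainable p is floor-limited
(p ≈ 1/t²), so screens with only ~2% true hits sit on the decision
boundary at α = 0.01 regardless of effect size. At a 5% hit rate the
dual-gate caller recovers planted +3.0 effects with ≥ 95% power, biases
the mean LPI by < 0.02, and makes essentially zero false calls (the
2.5-unit gate alone is ~50 noise SDs from 0). Null screens (no effects)
across 20 seeds show a false-call fraction of 0.

## Known limitations

- The t-test assumes exchangeable replicate LPIs; plate-level random
  effects are not modeled (a mixed model would be the next step for
  real multi-batch data).
- Local-linear surfaces can be noisy on plates where most controls fail
  QC; the minimum-controls check (4) is a floor, not a guarantee of a
  well-conditioned fit.
- The doubling-time estimator reports the fastest well-fit window; for
  strongly diauxic curves this is the first growth phase only.
- Overlap statistics treat gene identifiers as opaque case-insensitive
  strings; no alias or ortholog resolution is attempted.
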