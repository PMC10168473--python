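# Methods

This note documents the models, numerical choices and limitations of
`daric`. All defaults below are also the values used by the validation
suite and `scripts/acceptance.py`.

## Coordinate model

A `BinnedGenome` tiles each chromosome with fixed-width bins (default
50 kb); the last bin may be short. Coordinates are 0-based and
half-open everywhere, including juicer dump input (positions are bin
starts in bp) and BED/bedGraph output. Assembly gap intervals mark
bins as unmappable; gap bins carry NaN in every track and are excluded
from all computation. Bins whose compartment eigenvector value is
exactly 0, or that are not covered by the compartment file, are
`undefined` and excluded as partners from PIS class means (sign is the
classifier, and 0 has no sign).

## PIS

For bin *i*, PIS_i = log2(mean O/E against A bins / mean O/E against
B bins), over valid matrix entries on the same chromosome
(inter-chromosomal contacts are never read). Choices:

- **Diagonal exclusion** (default on): bin *i*'s own O/E entry is ~1
  by construction and only dilutes the contrast; an `exclude_flank`
  option additionally drops ±k near-diagonal entries.
- **min_class_bins = 10**: a chromosome with fewer than 10 A or 10 B
  bins is skipped (all-NaN, logged warning); means over tiny classes
  are unstable.
- **No pseudocount**: a zero or negative class mean yields NaN rather
  than an arbitrary floor, preserving log-ratio semantics.

**Smoothing** is NaN-aware normalized Gaussian convolution
(`gaussian_filter1d` on the zero-filled values and on the finite-mask,
then the ratio), per chromosome, reflecting boundaries, default
σ = 3 bins (150 kb at 50 kb). σ = 3 suppresses bin-level noise without
erasing domain edges; NaN bins stay NaN and contribute no mass.

## MA normalization

M = PIS_ref − PIS_other, A = (PIS_ref + PIS_other)/2. Background bins
are those with signed M between the 15th and 85th percentiles of
finite M values (configurable). The fit is Huber-weighted IRLS
(tuning constant 1.345, ≤ 50 iterations, tolerance 1e-8, via
statsmodels RLM), preceded by an OLS pass: if the OLS residual MAD is
0 (exact linear relation) the OLS line is returned, since the robust
scale estimate would degenerate; zero-variance A returns slope 0 with
the median M as intercept. The fitted line is extrapolated
genome-wide; the normalized track is ref − M_norm with
M_norm = M − (slope·A + intercept), re-expressing the other sample on
the reference scale (a sign flag flips the reconstruction for callers
using the opposite M orientation).

The key assumption is that most of the genome does not change
compartmentalization; planted-shift experiments confirm that
differential bins covering ≲ 15 % of the genome fall outside the
percentile window and retain ≥ 90 % of their effect. Normalization is
not exactly idempotent under noise — the (M, A) refit is an
errors-in-variables problem — but the second pass is bounded well
below the noise scale and is exactly null for noise-free linear
distortions.

## HMM segmentation

Gaussian emissions with diagonal covariance; 1-D observations
(residual PIS) for differential mode, 2-D (mean, sd of PIS across a
panel) for variability mode. Observation sequences are per chromosome
and split at NaN runs; no imputation, and no state path ever crosses
a gap. Supplying several residual tracks pools all sequences into one
EM fit so every comparison shares state definitions.

EM is deterministic given the seed (default 13). Initialization:

- transitions uniform with 0.9 self-transition, uniform start;
- **1-D:** state means at the (k+0.5)/n quantiles of the pooled
  observations, with the two extreme states re-anchored at the
  0.5 %/99.5 % quantiles and a geometric narrow→broad variance ladder
  across interior states. When differential bins are a small fraction
  of the genome, all bulk quantiles sit inside the null peak and EM
  then converges to a local optimum that never separates the extreme
  states; the extreme anchors plus the variance ladder reliably reach
  the basin where the Strong states lock onto the true shifted levels
  and one interior state can stay narrow on the null peak while the
  other covers broad mild drifts.
- **2-D:** k-means centers (seeded, n_init = 10) with per-cluster
  variances; (mean, sd) states have no natural ordering, so
  per-dimension quantile pairing would fabricate meaningless
  mean/variability combinations.

Decoding is Viterbi per sequence; consecutive same-state bins merge
into domains. States are labeled by ascending emission mean:
Strong− / Weak− / Weak+ / Strong+ for 4 states (matching the four
classes of conventional switching analysis, which is why 4 is the
default), Strong± plus Mid_k otherwise; ties break by state index.
Degenerate input (near-zero pooled variance) returns a single
effective state with sticky transitions and a warning instead of
running EM.

Boundary precision caveat: a five-level residual (strong ±, weak ±,
null) cannot be tiled exactly by four Gaussian states, so one state
must widen to cover two levels; on some datasets EM chooses a wide
extreme state and Viterbi then places strong-domain boundaries a few
bins outside the true edge (the decision threshold slides down the
smoothed ramp). Under the validation conditions below the error is
within ±2 bins; across other random genomes strong-bin recovery stays
above 93 % while the worst boundary error occasionally reaches ~6
bins.

## Variability mode

Per-bin mean and sample standard deviation (ddof = 1) of normalized
PIS across ≥ min_samples (default 3) finite values; five states.
Labeling: the two lowest-sd states are conA/conB by mean sign; of the
remaining three, the highest-sd state is `variable`; the other two are
varA/varB by mean sign. A mean-sign tie falls back to mean ordering
with a warning.

## Significance

φ is built from all four sign combinations (±d₁ ± d₂)/2 of the
within-condition replicate differences at every bin where all four
tracks are finite; its length is exactly 4N and its mean exactly 0 by
construction. The null is parameterized as N(0, σ) with σ the sample
sd of φ (the empirical distribution is well approximated by a
Gaussian; an empirical-CDF option was considered and rejected as it
adds discretization noise at the extreme tail where the cap operates).
The one-sided p-value is taken in the direction of the observed ΔPIS
(equivalently the |ΔPIS| upper tail), so under the null ~2 % of bins
exceed score 2. Scores are clipped at exactly 20 (p ≤ 1e-20). No
multiple-testing correction is applied; the domain-level filter —
Strong± state *and* mean score > 2 — is the significance gate, and
Weak domains are never flagged regardless of score. More than two
replicates per condition are accepted with a warning, generalizing the
within-condition contrast to half-mean differences.

Enrichment of features across domain classes is obs/exp with
exp_i = total × density_i (density = fraction of parent elements in
class i), reported as log2 fold, ±20-capped when the expectation is 0.

## Synthetic generator

The generator emulates the plaid structure that PIS reads:
OE[i,j] = exp(s·e_i·e_j)·ε with latent strength e ∈ [−1, 1]
(blocky profile, block lengths 10–40 bins, magnitudes 0.5–1.0), plaid
strength s = 0.8 and mean-one multiplicative lognormal noise
(sd 0.1 by default) applied symmetrically. Replicates redraw the noise
around the same expectation.

Planted differential domains are specified in residual-PIS (log2)
units and converted to latent shifts via the first-order plaid
relation ΔPIS ≈ s·δe·(ē_A − ē_B)/ln 2; placement is direction-aware so
the shifted profile never clips at ±1, and planted domains keep ≥ 10
unshifted bins between them so every planted boundary is unambiguous.
The default differential load is 4 domains per shift level
(±1.5, ±0.3) of 20–45 bins on a 4 × 2000-bin genome — ~7 % of the
genome differential, consistent with the normalization assumption.
The variability panel assigns each 15–35-bin block one of five
classes with latent (mean, across-sample sd) of (±0.85, 0.03) for
conA/conB, (±0.50, 0.18) for varA/varB and (0, 0.65) for `variable`;
across-sample variation is drawn per block (compartment strength
drifts domain-wise, not bin-wise) with 0.02 per-bin texture.

What the generator does **not** emulate: distance-dependent residual
structure, TADs and loops, coverage/mappability artifacts, partial
cell-type heterogeneity, or chromosome-scale eigenvector sign
ambiguity. Passing tests therefore demonstrate correctness of the
statistical machinery on idealized plaid signal, not performance on
every pathology of real Hi-C.

## Validation conditions

The validation experiments (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use: a 200-bin oracle fixture with 5 % gaps,
5 % missing entries and 5 % undefined bins; a 2 × 1000-bin
normalization fixture with a 1.15x + 0.4 distortion and a +1.2 shift
on 10 % of bins; the 4 × 2000-bin differential pair with noise sd 0.1;
the same genome for null calibration with 2 + 2 replicate renders of
identical truth; and a 19-sample, 2 × 600-bin variability panel. These
sizes keep each experiment within seconds on a single CPU while
leaving thousands of bins per measurement.

## CLI

`daric simulate | pis | norm | diff | test | variability | enrich |
run`. Every subcommand writes a resolved-parameter YAML next to its
output, and outputs carry a `# daric v<version> config=<hash>` header;
the hash covers analysis parameters only (not paths), so re-running
the same analysis elsewhere stamps identically. The `run` subcommand
executes pis → norm → residual → diff → test from a single YAML
config; defaults reproduce the canonical operating point (50 kb bins,
σ = 3, 15–85 % window, 4 states, cap 20, threshold 2).
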