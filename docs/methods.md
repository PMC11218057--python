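# Methods

This note documents the models, conventions and numerical choices behind
`aggdoe`, and what the synthetic campaigns do and do not establish about
real cultures.

## Experimental design

Designs are exact D-optimal designs: n runs drawn (with possible
replication) from a candidate grid of coded points, maximizing det(XᵀX) for
the declared model. The default candidate set is the 3-level full factorial
on the coded cube (3⁵ = 243 points for five factors), which includes the
center and therefore supports mid-level settings. The search is coordinate
exchange: from a random n-run subset, each run's each coordinate is cycled
through the grid levels and any det-increasing exchange is kept, iterating
to a fixed point; 20 seeded restarts guard against local optima and ties
break first-found, so results are reproducible bit-for-bit given the seed.
On small instances the search is verified in tests against exhaustive
enumeration of candidate multisets. G-efficiency is 100·p/d_max with
d_max = maxₓ n·xᵀ(XᵀX)⁻¹x over the candidates; an orthogonal saturated
design scores 100%.

Factor concentrations map linearly (optionally log-linearly) onto coded
[−1, +1]. The shipped default ranges are editable placeholders bracketing
the published anchors (HS optimum 0.1 µg/ml, PEG optimum 10 mg/ml, PVA
literature anchor 1 mg/ml); any real campaign should supply its own
`factors.csv`. Center points replicate the all-midpoint condition; batch
assignment deals center points round-robin first so every batch carries a
normalization anchor, then deals the remaining runs in seed-shuffled
round-robin. Blocking beyond this post-hoc label is out of scope.

## Growth kinetics and aggregate stability

The specific growth rate K (1/day) is the slope of ln(mean daily count)
vs day by least squares, using per-day means of the triplicate counts;
doubling time is ln 2 / K, reported as NaN for non-growing cultures rather
than raised. Diameter summaries are per-day arithmetic mean and sample
(n−1) SD, with the slope of mean diameter over days as a growth-shape
response.

The stability statistic treats an aggregate as a sphere of cells with
diameter 10 µm (single-cell volume V_c = 523.6 µm³) at 64% random close
packing. From the day-1 mean diameter: V₁ → N₁ = (V₁/V_c)·0.64 →
N₃ₚ = N₁·e^{K·h} → V₃ₚ = N₃ₚ·V_c/0.64, compared with the observed day-3
volume as (V₃ − V₃ₚ)/V₃. The comparison is made on volumes; diameters are
derived views. Cell counts per aggregate are continuous (no rounding).

The horizon h defaults to 3 days, the published convention, even though the
day-1 → day-3 window spans 2 days. These are mutually inconsistent: on data
generated by pure exponential growth the 3-day exponent over-predicts by a
factor e^K, producing a constant negative offset of 1 − e^K rather than
zero. `GeometryConstants(horizon_days=...)` makes the exponent explicit;
the interval-matched setting (h = day_final − day_initial) is the
internally consistent variant and is the configuration under which the
zero-noise, zero-fusion self-consistency property holds and is tested.
Because the offset is shared by all runs of a campaign, either convention
ranks conditions identically; only the zero point moves
(`analysis/06_stability_sweep.py` quantifies both).

qPCR responses are expressed as 1000/2^ΔCt with ΔCt = Ct_target −
Ct_housekeeping, so higher expression yields larger values.

## Model fitting and quality metrics

Each response is fitted by OLS to the full main + two-factor-interaction
model in coded units (coefficients are directly comparable across factors);
insignificant terms are kept by default, with pruning left to the caller.
The skewed flow responses (OCT4, TRA-1-60) are fitted after the
normalizing transform −log₁₀(y/100 + ε), ε = 10⁻⁶ guarding exact zeros;
the transform direction means "larger is better" becomes "smaller is
better" on the fitted scale, which the optimization criteria must respect.

* **R²** is the corrected coefficient of determination; a constant response
  is defined to have R² = 0.
* **Q²** is 1 − PRESS/SS_tot with PRESS from the hat-matrix identity
  e_i/(1 − h_ii); negative values are reported, not clipped. The shortcut
  is tested against an explicit leave-one-out refit loop.
* **Validity** transforms the lack-of-fit p-value (residual SS partitioned
  into replicate pure error and lack of fit, F-tested) as
  1 + 0.57647·log₁₀(p_lof), capped at 1. The scaling is chosen so the
  conventional 0.25 floor corresponds exactly to p_lof = 0.05, the stated
  significance level. Without replicates it is NaN, not fabricated.
* **Reproducibility** is 1 − pooled within-replicate variance / total
  response variance. Replicate groups are runs with identical coded
  settings — in this campaign shape, the center points.

Between-batch normalization multiplies every response value in a batch by
(grand center mean)/(batch center mean), preserving the grand center mean
and being idempotent. It is applied only to strictly positive responses:
the signed, near-zero aggregate % error is excluded by default because a
near-zero batch center mean makes the ratio explode. Note the correction
itself is estimated from 1–2 center replicates per batch, so it trades a
small batch bias for extra, batch-correlated variance; consequently,
coefficient-recovery and CI-coverage evaluations are performed on raw-scale
fits, where the generative coefficients are the actual estimand and OLS
intervals are calibrated (~95–96% empirical coverage at default noise,
versus ~86% after normalization).

Correlations between responses are Pearson r with two-sided t-test
p-values on complete pairs.

## Desirability optimization

Per-response desirabilities are piecewise linear (exponents default to 1;
the commercial tool's exact shape is undocumented) and combine by weighted
geometric mean, so a fully violated criterion zeroes the overall score.
The setpoint search is 20-start Nelder–Mead in coded space with box
projection, seeded, and never returns less than the best start point;
tests compare it against dense grid search. Cpk is min over finite spec
limits of the distance from the predicted mean in units of 3 prediction
SDs, where the prediction SD at the setpoint includes both residual and
leverage terms (√(σ²(1 + xᵀ(XᵀX)⁻¹x))) to match the "natural tolerance"
reading; for one-sided goals only the unacceptable end of the ramp acts as
a spec limit. Probability of failure has a closed normal-CDF form, with
Monte Carlo as a cross-check. Factor contributions are a documented
reconstruction (the commercial formula is proprietary): the span of the
predicted response as one factor sweeps its range with the others pinned
at the setpoint, normalized to 100% across factors — with interactions the
result legitimately depends on where the partners sit. Setpoint profiles
sweep one factor and carry the prediction-SD band, which widens toward the
design-space edges with leverage.

## Synthetic campaigns

The generator emulates the structure of the assay, not its biology: 19
conditions (16 D-optimal + 3 center) in 2 batches, 4 days, triplicate
counts, ≥30 diameters/day, endpoint flow/qPCR/viability panel.

* Counts: N₀·e^{K(x)·t} with N₀ = 1.1×10⁵ cells/ml and multiplicative
  lognormal noise (CV 10%, a typical flow-counter repeatability); K(x) =
  0.40 + xᵀβ_K per day, centered on the published optimized rate, with
  PA/PVA/PEG main effects and a PA:PEG synergy of a few ×0.01/day.
* Aggregates: an explicit population of 300 aggregates — a representative
  subsample of the reactor, not its full census; counts are generated
  analytically from K, so this size only sets sampling noise on diameter
  statistics. Day-1 diameters are lognormal (mean 80 µm, σ_log 0.2, a
  realistic day-1 hiPSC aggregate spread); per-aggregate cell numbers grow
  at e^K per day; fusion events are Poisson with per-aggregate rate
  λ_f(x) = 0.05·e^{xᵀγ} per day (volumes add, one aggregate fewer per
  event — conservation is tested), with HS, PEG and HS:PEG suppressing and
  DS/PA/PVA promoting fusion; fragmentation splits an aggregate ~in half.
  Measured diameters get 3% lognormal error. The lognormal size law is an
  assumption; only means/SDs of the real distributions are published.
* Endpoints: marker percentages are generated on the logit scale and
  back-transformed (so the neglog fitting path is exercised), qPCR truths
  are linear in expression units and encoded exactly as Ct pairs that the
  1000/2^ΔCt rule decodes, viability is linear with σ = 1.5 points. A
  shared multiplicative batch factor (σ_log = 0.02) applies to endpoint
  assays only, emulating assay-batch effects; culture series are
  batch-free.

What passing tests show: the analysis chain is self-consistent (zero error
on growth-only data), sensitive in the right direction (monotone in fusion
and fragmentation rates), and statistically calibrated (coefficient CI
coverage, R²/validity floors) *under this generative model*. What they do
not show: correctness of the spherical-packing idealization for real
aggregates (cell size varies with density and state), shear- or
nutrient-driven kinetics, or any claim about which real additive
concentrations are optimal.

Coverage and recovery checks use the responses whose truth is linear on
the fitted scale (growth rate, qPCR expressions, viability); marker
percentages are logit-generated but neglog-fitted, so their coefficients
are not exactly identified by construction and would test transform
mismatch rather than CI calibration.

## Problem sizes and determinism

Default stochastic checks use 50 simulated campaigns for the fit-quality
medians, 500 for CI coverage, 20–30 replicates per point for fusion-rate
sweeps, and 10⁵ draws for Monte-Carlo failure probabilities — sizes at
which the checked quantities are stable to well within their asserted
margins. All randomness flows through seeded `numpy` generators;
rerunning any stage with the same seed and inputs is bit-identical
(timestamps aside), and the pipeline manifest records seeds, versions and
input checksums.

## Known limitations

* The aggregate model assumes uniform cell size and packing; both drift
  with aggregate density and differentiation state.
* Validity and factor contributions reconstruct undocumented/proprietary
  conventions; they anchor the published thresholds exactly but may differ
  from the commercial implementations elsewhere on the scale.
* The desirability optimizer treats predictions as independent normals;
  correlated prediction errors across responses are not propagated.
* Batch normalization with very few center replicates is noisy; with one
  center point per batch it cannot separate batch effect from replicate
  noise at all.
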