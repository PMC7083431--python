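# Methods

## The statistical problem

An indirect reference interval treats a routine laboratory population as a
mixture: a healthy majority whose central 95% range is the quantity of
interest, plus a contaminated minority (disease, pre-analytical trouble)
concentrated in the tails. The pipeline estimates the healthy component's
2.5th and 97.5th percentiles by (i) deterministic record cleaning, (ii)
symmetrising the skewed distribution, (iii) stripping the tails by an
iterated robust rule, and (iv) reading off the central band by two routes
that should agree when the transformed core is near-Gaussian.

## Cleaning

Rules apply in a fixed order — optional pregnancy flag, assay detection
limits, missing fields, first-result deduplication — and each record is
counted under the first rule that removes it. Order affects only the
attribution of exclusions, never the retained set. Boundary values exactly
at a detection limit are retained (the limits exclude strictly outside).
"First result" means earliest collection date, with file order breaking
ties; the ordering key is a convention, stated here because upstream
systems rarely document theirs. Ages are truncated to integer years.
Unparseable values/ages/dates and unrecognised sex codes are treated as
missing fields (and counted by that rule) rather than parse errors, because
LIS exports routinely contain them.

## Box-Cox transformation

x(λ) = (x^λ − 1)/λ for λ ≠ 0 and ln x at λ = 0, fitted by maximising the
profile log-likelihood −(n/2)·ln σ̂²(λ) + (λ−1)·Σ ln x with bounded scalar
search on λ ∈ [−3, 3] (tolerance 1e−5). The interval covers every
physiological skew regime (λ=1 none, λ=0 lognormal, λ<0 heavier); both are
configurable. No shift parameter is used: cleaning guarantees values ≥ the
lower detection limit, comfortably positive. The inverse transform
(1 + λy)^(1/λ) is defined only for 1 + λy > 0; a reference limit outside
that domain is reported as not-representable with its transformed-scale
value retained. λ = 1 is special-cased as the exact unit shift x = y + 1,
which is well defined for any y — without this the identity-like case would
spuriously fail on sub-unit data.

Numerical note: the forward transform uses `expm1`, keeping the power
branch accurate through λ → 0. Round-tripping x → y → x is accurate to
~1e−12 relative in the regime analyte data occupy; when |λ·ln x| ≳ 16 the
quantity 1 + λy approaches 0 and float64 cannot carry enough information
for any inverse to recover x — an ill-conditioning of the parametrisation,
not of the implementation.

## Symmetry testing

Coefficient of skewness m₃/m₂^{3/2} and excess kurtosis m₄/m₂² − 3
(normal ⇒ 0), with p-values from the D'Agostino skewness test and the
Anscombe–Glynn kurtosis test (n ≥ 20 required by their large-sample
approximations). The symmetric/skewed verdict keys on the skewness p-value
at a configurable α (default 0.05): skewness is what the transformation can
and should remove; residual kurtosis is reported but not gating.

## Iterative Tukey deletion

Per pass: fit λ on the current sample (re-fitting each pass is the default;
a switch freezes the initial λ), transform, compute P25/P75 by the rank
rule p·(n+1) with linear interpolation, and delete **as one batch** every
value strictly outside [P25 − 1.5·IQR, P75 + 1.5·IQR]. Values exactly on a
fence stay. Batch-per-pass semantics (rather than one-at-a-time) is what
makes two-to-three passes sufficient on cohorts of thousands; the loop
stops at the first pass that deletes nothing (cap 20 passes, warning if
hit; error if the sample shrinks below 20).

**Known bias.** On an already-clean Gaussian sample the fences sit near
±2.70σ and iterate to a fixed point near ±2.67σ, deleting ≈0.4% in each
tail. Because percentiles are taken on the surviving sample, the estimated
2.5th/97.5th percentiles correspond to z ≈ ∓1.90 of the original healthy
distribution instead of ∓1.96: limits land inside the truth by roughly
e^{0.0575·σ_log} − 1 ≈ 3–5% for log-scale spreads of 0.55–0.80, before
sampling noise. This is intrinsic to the deletion rule, affects both RI
routes equally, and is the main accuracy limit of the whole pipeline; tests
of end-to-end recovery must budget for it.

## Partitioning and age trend

Harris–Boyd: z = |m₁ − m₂|/√(s₁²/n₁ + s₂²/n₂) against
z* = 3·√(((n₁+n₂)/2)/120). z* grows with √n̄, so the enormous power of
routine cohorts cannot force a split on a clinically trivial difference;
the anchor z*(120,120) = 3. By default z is computed on the transformed
scale with a single λ fitted to the pooled subgroups (the test presumes
near-normal subgroup distributions; a raw-scale option exists), and z* uses
the pre-deletion subgroup sizes (a post-deletion option exists). The female
age boundary defaults to 50 years — the menopause-linked rise — and is
configurable. Partition verdicts gate the reported grouping; a flag forces
all subgroups. Age trends use Spearman's ρ (average ranks on ties, t
approximation for p with n−2 df); ρ is invariant under Box-Cox since the
transform is strictly increasing. ρ is computed for n ≥ 3 with a warning
below n = 10, where the p approximation is unreliable.

## Reference intervals

Both routes run on the outlier-deleted sample.

*Parametric*: limits mean ± 1.96·SD on the transformed scale. The 90% CI of
each limit uses Var(x̄ ± z·s) ≈ s²·(1/n + z²/(2(n−1))) — the delta-method
variance of a Gaussian quantile estimate — multiplied out at 1.645, then
everything is back-transformed. n < 120 triggers a warning (CI validity).

*Non-parametric*: limits at ranks 0.025·(n+1) and 0.975·(n+1) (interpolated,
clamped to [1, n]); this "weibull" rank convention is used consistently for
quartiles, percentile limits and the deletion fences. The 90% CI of a limit
is the pair of order statistics (r, s), as symmetric as possible around the
point rank, whose distribution-free coverage BinCDF(s−1; n, p) −
BinCDF(r−1; n, p) first reaches 0.90. n < 40 is an error, n < 120 a
warning. Inputs are not rounded before CI computation; an opt-in flag
rounds to integers to emulate whole-unit assay reporting, on which a CI can
legitimately collapse to a single repeated value. Reported tables print 2
decimals.

## Synthetic cohorts

The generator emulates a health-examination ferritin extract. Healthy
strata are lognormal — consistent with the observation that a Box-Cox fit
near λ = 0 symmetrises such data: medians 190 (males), 45 (females < 50),
90 µg/L (females ≥ 50), log-scale spreads 0.55 / 0.80 / 0.70 (geometric SDs
≈ 1.7–2.2, the range routine ferritin data and published interval widths
imply). Ages are uniform on 18–90 (uniformity is adequate for rank
correlation and partition testing; census weighting is out of scope).
Contamination (default 2% of records) replaces a healthy draw by a
deficiency-like value (×0.04) or an overload-like value (×8), half each;
both tails deliberately overlap the healthy distribution so deletion cannot
be perfect. Raw-file artifacts — values outside 1–2000 µg/L (arising
naturally from contamination), 3% injected later-dated repeat visits, 2%
records with sex or age blanked — are written into the file, not cleaned by
the generator; a truth object records planted row identities, the censored
count, and the closed-form healthy percentiles e^{μ ± 1.96σ} per stratum.
Values are reported at 0.01 µg/L resolution. Identical config and seed give
byte-identical CSV output.

What passing tests on these cohorts shows: the pipeline's filtering,
decisions and interval arithmetic behave correctly when the healthy
component really is lognormal and contamination is tail-concentrated. What
it cannot show: robustness to assay drift over years, mixture components
inside the central mass (e.g. subclinical iron deficiency shading into
normal), demographically structured missingness, or non-lognormal healthy
shapes.

## Problem sizes and determinism

Statistical tests in the suite use 200–1000 seeded replicates and samples
of 10³–2×10⁴ — sizes at which every asserted property has comfortable
margin while the whole suite stays fast. All randomness flows through
`numpy.random.default_rng` with explicit seeds; the pipeline itself is
deterministic given its input, so reports are byte-reproducible.

## Known limitations

- The iterated-deletion bias above (~3–5% inward for ferritin-like
  spreads) is not corrected; a correction would require assuming the very
  distribution the non-parametric route avoids.
- One analyte column per run; multi-analyte panels are out of scope.
- Partitioning considers sex and one fixed age boundary, not a search over
  cut-points or proportion-based criteria.
- The parametric CI formula treats the transformed sample as exactly
  Gaussian; on heavy residual kurtosis its coverage is approximate.
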