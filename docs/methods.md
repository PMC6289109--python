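# Methods

## Density model

All analyses rest on a univariate kernel density estimate
`f̂(x) = (1/nh) Σᵢ K((x−Xᵢ)/h)` with a Gaussian kernel by default (a
uniform kernel is available for sensitivity checks).  The estimate is
evaluated *exactly*: per-observation densities are direct kernel sums,
never grid interpolations.  For large samples the sum is organised over
sorted observations in windows of |u| ≤ 12 bandwidths; beyond that a
Gaussian term is below 5·10⁻³² and cannot change a double-precision sum,
so this is an evaluation-order optimisation, not an approximation.

Assumptions: observations are i.i.d. draws from a continuous underlying
distribution, possibly supported on a half-line or interval set by hard
physical limits.  No boundary correction (reflection or renormalisation)
is applied at natural limits: kernel mass that spills past a bound is
simply lost there.  This is deliberate — it reproduces the behaviour that
a mode sitting on a bound keeps a high density *at* the bound, so no
lower outlier boundary and no interior MPR endpoint appear on that side.
The cost is that the density near a bound is biased low by up to a factor
of two within one bandwidth of it; since both the outlier ranking and the
MPR selection compare observations against each other under the same
bias, the orderings near the bound are far less affected than the
absolute density values.

### Bandwidth rules

* IQR rule (default): `h = 0.79 · IQR · n^(−1/5)`.  Robust to skewness
  and heavy tails; the constant comes from replacing σ with IQR/1.34 in
  the normal-reference rule.
* Normal reference: `h = 1.06 · σ · n^(−1/5)` (σ with the n−1
  denominator).
* Degenerate spread: if IQR = 0 (heavily tied data) the IQR rule falls
  back to the normal-reference bandwidth; if σ = 0 as well the sample is
  constant and no density model exists (error).

Quantiles everywhere — the IQR, the density-rank threshold, percent
cuts — use linear interpolation between order statistics (numpy's
default, "type 7").  This convention is stated because the bandwidth and
the outlier threshold both inherit it.

### Adaptive estimators

* **kNN kernel**: `f̂(x) = (1/(n·d_k(x))) Σᵢ K((x−Xᵢ)/d_k(x))` with
  `d_k(x)` the distance to the k-th nearest observation (default k = 2%
  of n).  Where `d_k(x) = 0` (k or more duplicates at x) the smallest
  positive inter-point distance is substituted and a warning logged; a
  fully constant sample is an error.  Note that this estimator is **not a
  probability density**: `d_k(x)` grows like |x| far from the data, so
  the estimate decays like 1/|x| and its integral over the real line
  diverges.  Measured wide-grid integrals on the bundled fixtures run
  1.08–1.57.  It is provided for what it is used for here — a sensitivity
  check on density *rankings*, which only need relative values.
* **Two-step (Abramson) variable kernel**: an IQR-rule pilot estimate at
  the observations; local bandwidths `hᵢ = h·(f̂_pilot(Xᵢ)/g)^(−1/2)`
  with g the geometric mean pilot density (sensitivity exponent 1/2);
  final estimate averages kernels with per-observation bandwidths.  Zero
  pilot densities are floored to the smallest positive pilot value
  (logged) so the geometric mean exists.

### Density curve and grid

Each fitted model carries a 1024-point equally spaced grid over
[min − 3h, max + 3h] (h from the IQR rule), clipped to the natural
limits.  The grid supports boundary extraction and modality
classification only; every reported density is an exact evaluation.
Normalisation is checked on the *unclipped* span, since clipping
legitimately removes spilled kernel mass.

### Variance of the estimate

`var(f̂(x)) ≈ f̂(x) · R(K) / (nh)` with `R(K) = ∫K(t)²dt` (Gaussian:
1/(2√π) ≈ 0.2821).  A variant using the kernel second moment
`∫t²K(t)dt` (Gaussian: 1) as the constant is selectable, as that form
also circulates; the roughness form is the standard asymptotic result
and is the default.  Two density estimates are compared with a two-sided
z-test on `(f̂_a − f̂_b)/√(var_a + var_b)`.

## Density-ranked outliers (PDR)

At level α the density threshold is the α-quantile of the n
per-observation densities; observations with density *strictly below*
the threshold are flagged.  Strict inequality means threshold ties stay
unflagged, so the flagged fraction can never exceed α beyond quantile
rounding (guarantee: flagged fraction ≤ α + 1/n).  The 1% flagged set is
always a subset of the 5% set for the same model.

Outlier boundaries are the crossings of the grid density curve with the
threshold, refined by bisection on the exact evaluator to 10⁻⁶ of the
grid range, and classified lower/upper relative to the global mode.  A
side whose curve endpoint already sits above the threshold has no
boundary (reported as absent, e.g. zero-inflated metrics whose mode is
the bound).  Thresholds above the curve maximum report an "all outlying"
condition.  Density ranking cannot produce a boundary beyond a natural
limit; the "meaningless bound" annotation therefore applies only to the
baselines.

Conditional analysis splits the sample by a category label and runs the
identical pipeline per category (minimum 10 observations per category,
configurable; smaller categories are skipped with a warning).

## Most Probable Range

MPR at fraction p selects the ⌈p·n⌉ observations with the highest point
density (ties at the selection threshold broken by proximity to the
mode) and reports the [min, max] hull — after a unimodality check on the
grid curve, where local maxima with prominence below 1% of the peak are
ignored.  Natural-limit rule: if the density *at* a natural limit
exceeds the selection threshold, the limit itself replaces that
endpoint (the data are "most probable" all the way to the bound).
Multimodal curves raise an error directing callers to the
multi-interval form.

The multi-interval extension partitions the selected observations into
contiguous runs: a run breaks only where an *unselected* observation
lies strictly between consecutive selected ones — an empty gap cannot
break a run.  Each run becomes one closed interval.  For unimodal curves
this reduces exactly to the single-interval result.  Selections at
increasing fractions are nested, so interval unions are nested, and the
complement of the 95% MPR coincides with the 5% outlier set up to
quantile rounding.

MPR is computed by density ranking — the operational definition — rather
than by combinatorial minimisation of total interval length.  On small
unimodal samples the ranked selection tracks the exhaustively shortest
window containing the same count approximately, not exactly: across
seeded 100-point skewed samples the measured length ratio is median
≤ 1.1, worst case ≈ 1.27.  At fixture sizes (n ≈ 4000–10,000) the
multi-interval MPR of the bimodal fixture undercuts every single
contiguous window covering the same count.

## Baseline methods and conventions

* Z score: μ ± z(α)·σ, z from the two-sided normal quantile (1.96 at
  5%, 2.58 at 1%); σ uses the n−1 denominator.
* Tukey's fences: [Q1 − k·IQR, Q3 + k·IQR]; k = 1.0 ≈ 5% and k = 1.5 ≈
  1% on Normal data.
* MAD: median ± m·MAD with the MAD left **unscaled** (no 1.4826
  consistency factor) — the multiplier is a raw count of median absolute
  deviations and is user-set.  In the comparison table the default
  multiplier is z(α)/z(0.75) so the MAD record targets the same nominal
  level as the other methods on Normal data.
* Percent cut: the α/2 and 1−α/2 percentiles; the α→0 limit is the data
  range.
* A bound lying strictly beyond a natural limit is annotated
  `lower_meaningless`/`upper_meaningless` and never clipped.

All baselines are translation- and scale-equivariant by construction;
this is property-tested.

## Synthetic data

The generator produces five seeded shapes chosen to exercise every code
path the archive-metric use case needs: `normal` (reference case),
`skewed_bounded` (lognormal, limit 0 — clash-score-like),
`zero_inflated` (40% point mass exactly on the limit 0 plus an
exponential tail within [0,1] — violation-fraction-like), `multimodal`
(0.6·N(4, 0.7) + 0.4·N(7, 0.5) above a limit of 1 — multiplicity-like,
with comparable peak densities so both modes enter a 50% selection), and
`clustered_tail` (95% lognormal bulk plus a distant compact cluster —
molecular-weight-like).  Bounded shapes respect their limits exactly via
rejection sampling.  One global seed drives per-shape substreams through
numpy's SeedSequence spawning.

What the generator does *not* emulate: discreteness and rounding of real
archive metrics, reporting artefacts (delta-function spikes at favourite
values), inter-metric correlations, and the actual parameter values of
any real archive distribution.  Passing tests therefore demonstrate the
estimators' and selectors' mathematical behaviour on the named shape
families, not agreement with any particular archive snapshot; the
`examples/reproduce_pdb_benchmarks.py` script exists to rerun the
pipeline on real downloaded tables.

## Problem sizes and numerical choices

The test suite fits shared models on 4000-point fixtures and one
50,000-point Normal sample (used for the μ ± 1.96σ and MPR-vs-quartile
consistency checks, at tolerances 0.1 and 0.03).  The acceptance script
uses n = 50,000 for the Normal consistency block and n = 10,000 for the
shape fixtures.  Grid size 1024, padding 3h, bisection tolerance 10⁻⁶ of
the grid range, modality wiggle tolerance 1% of peak height, kNN default
k = 2% of n, conditional-analysis floor 10 observations — all stated
above next to their rationale.

## Known limitations

* No boundary correction means absolute densities within ~one bandwidth
  of a natural limit are biased low; rankings are much less affected but
  boundary abscissae adjacent to a bound inherit some bias.
* The IQR-rule bandwidth oversmooths widely separated multimodal data
  (the IQR spans the modes); mode-splitting behaviour is reliable at
  thousands of observations but not at n ≈ 100.  Use a smaller bandwidth
  or the adaptive estimators to study local structure in small samples.
* The kNN estimator is not normalisable (see above) and is unsuitable
  wherever integrated probabilities are needed.
* MPR by density ranking approximates the shortest-cover optimum; it is
  not a combinatorial minimiser.
* Univariate only; no streaming updates.
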