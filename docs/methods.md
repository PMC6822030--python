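# Methods

## Data model

A *site* is one camera-trap location. Where two cameras are mounted at a
site to photograph both flanks of a passing animal, the pair is a single
proximity detector: the data model has no camera-level records, and survey
effort is counted in site-nights (so a survey table listing cameras
contributes cameras × nights / 2 trap days). Daily effort and detection
records are collapsed to *occasions* of L successive trap nights (default
L = 5): occasion k covers days (k−1)L+1 … kL, the number of occasions is
⌈days/L⌉, a site-occasion is active if at least one of its days was, and
repeated photographs of one individual at one site within one occasion are
a single binary detection. The trailing short occasion is retained with its
true activity rather than dropped, preserving all detections; published
occasion counts that exceed ⌈mean days/5⌉ (possible with per-site start
staggering, which daily tables do not record) are therefore not reproduced
exactly. Coordinates must be planar meters; latitude/longitude input is
rejected rather than converted because all model distances are Euclidean
meters.

## SCR likelihood

Detection is half-normal, p(d) = p₀ exp(−d²/2σ²), and encounters are
independent Bernoulli trials on active site-occasions. Detection
probability does not vary between occasions, so an individual's likelihood
at a candidate center depends on its history only through per-site
detection counts; the implementation exploits this collapse and computes
everything in log space (log-sum-exp over pixels), so the objective is
finite for any valid input.

The number of activity centers in the state-space follows a homogeneous
Poisson point process of intensity D (a Poisson-N rather than binomial-N
formulation; at these sample sizes the two differ negligibly, and the
Poisson form keeps the likelihood smooth and profile-friendly). The
full-session objective is

    −log L = −Σ_i log Σ_g D a P(y_i | s_g) + Σ_g D a p·(s_g) + log n!

Sessions are independent; declared sharing groups use common (p₀, σ) while
each session keeps its own density, and the total objective is the sum.

**State-space.** The rectangle buffering the outermost traps (default
15 km) gridded at a default 1.5 km (pixel area 2.25 km²). No habitat mask
is applied — density is homogeneous over the rectangle. A post-fit check
flags buffers smaller than 2σ̂. Grid axes have ⌈span/resolution⌉ pixels
with the first center half a pixel inside the edge.

**Fitting.** Parameters are unconstrained: logit p₀, log σ, log D. At
fixed detection parameters the density score has the closed-form root
D̂ = n / (a Σ_g p·(s_g)), so densities are concentrated out and the
optimizer (L-BFGS-B, gradient tolerance 10⁻⁶) runs over detection
parameters only; the profile maximum is the joint maximum. Three
deterministic starts are jittered around a method-of-moments initializer
(σ₀ = MMDM/2, p₀ start 0.1); non-convergence is flagged, never silent.
Standard errors come from the inverse finite-difference Hessian of the
*joint* likelihood at the optimum; a singular or indefinite Hessian yields
NaN SEs with a warning. Abundance is expected abundance N̂ = D̂·A(S) with
delta-method SE (N̂ · SE(log D̂)); realized abundance (n plus expected
undetected) is available and coincides with N̂ at the MLE because the
density score is exactly zero there — only its SE differs. Densities are
reported per 100 km², the reporting convention for large carnivores.

**Density surface.** Pixel g receives Σ_i Pr(s_i = g | y_i, θ̂) (posterior
membership of each detected individual, uniform prior over pixels) plus
D̂·a·(1 − p·(s_g)) for the undetected. Because D̂ solves its score
equation exactly, the pixel sum equals N̂ to numerical precision, which the
tests assert at 10⁻⁶ relative tolerance. Surfaces export as ESRI ASCII
grids (plain-text, GIS-readable, in the input CRS) and long-format CSV.

## Nonspatial estimators

Capture frequencies f_c (individuals detected in exactly c of K occasions,
any site counting once) feed two closed-population estimators. **M0**
maximizes N!/(N−n)! p^T (1−p)^(NK−T) over real N ≥ n with p profiled as
T/(NK); SEs use the analytic observed information, which remains defined
when the maximum lands on the N = n boundary (a boundary flag is raised
when the likelihood instead increases without bound, i.e. the data carry
almost no repeat detections). N is reported both continuous and rounded.
The M0 MLE carries a small negative O(1/N) finite-sample bias (~0.4
animals at N = 100, p = 0.3, K = 10), visible in the recovery test, and is
biased low more strongly when detection heterogeneity is present — the
directional effect the comparison with SCR is meant to expose. **Mh**
defaults to Chao's moment lower bound n + f₁²/(2f₂) (bias-corrected
n + f₁(f₁−1)/(2(f₂+1)) when f₂ = 0) with Chao's variance; the first-order
jackknife is available behind a flag because the heterogeneity estimator
used by any particular study is often not identifiable from its report,
so numerical equality with published Mh rows is not guaranteed.

## MMDM and effective trapping area

MMDM averages, over individuals detected at more than one site, the
maximum pairwise distance between their capture sites; single-site
individuals are excluded, and with no eligible individual the MMDM is NaN
(density conversion then refuses). The trapping area is the convex hull of
the trap coordinates — the dominant convention in the camera-trap
literature; a union-of-discs variant is available for sensitivity
analysis. The dilated-hull area uses the exact Minkowski form
A + P·w + πw² (point → πw², collinear segment → 2Lw + πw²), with the
buffer polygon attached for mapping. Density is 100·N̂/ETA(km²) with the
ETA treated as fixed, so SE(D) rescales SE(N̂) only — matching the usual
reporting pattern for these conversions.

## Synthetic generator

The generator emulates the systematic survey design: checkerboard sites at
the centers of alternate 2.7 km cells, all-active occasion masks with
optional per-site-occasion dropout (camera failure), Poisson-N centers
drawn uniformly by pixel and jittered within-pixel (matching the
estimator's discretization without lattice artifacts; a fixed-N mode
exists for recovery tests), Bernoulli half-normal detections, and sex
labels assigned F/M/U with unknown dominating, as in surveys where sex is
identifiable from photographs only occasionally. Default experiment
settings mirror the study conditions: 91 sites (13 × 14 cells), 13
five-night occasions, p₀ = logit⁻¹(−2.34), σ = e⁸·⁸⁰ ≈ 6,634 m, and ~30
expected individuals in the 15-km-buffered state-space (≈ 4,158 km², so a
generating density of ≈ 0.72 per 100 km²). What the generator does *not*
emulate — behavioral responses to traps, transients, sex-specific
movement, habitat selection, misidentification — bounds what passing
tests show: parameter recovery on these data demonstrates correctness of
the estimator under its own assumptions, not robustness to their
violation in field data.

## Numerical choices and limitations

- Detection probabilities are clipped to [10⁻³⁰⁰, 1 − 10⁻¹²] before
  logging; underflowing histories remain finite in log space.
- The brute-force enumeration oracle used in tests shares no code with the
  vectorized likelihood and agrees to 10 significant digits on all small
  shapes.
- The recovery experiment uses 25 replicates in the acceptance script and
  100 in the test suite; replicates with fewer than two detected
  individuals are skipped (none occur at the default settings).
- Wald intervals and delta-method SEs are asymptotic; with 4–30 detected
  individuals per session they are approximations, and published SEs
  computed by other software, other abundance definitions (expected vs
  realized), or other Mh variants need not match.
- Single-pixel or otherwise degenerate state-spaces make (p₀, σ)
  unidentifiable individually (only detection probability at the observed
  distance matters); the fit still converges to the identifiable
  functionals, which is what the degenerate-model test asserts.
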