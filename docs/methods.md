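# Methods

## Problem and model

Two-photon functional microscopy reads out neural activity as local image
intensity. Vignetting — the radial falloff of brightness and contrast from
the image centre to the periphery — therefore does not merely degrade
aesthetics: it injects a center-periphery bias directly into derived
functional measures (per-neuron activity, its day-to-day changes, and the
set of "highly active" cells). Because the artifact varies day by day and
with depth, reference- or multi-image correction is both unavailable and
undesirable (it would couple images whose mutual correlation is the
scientific question), so the correction here operates on each slice alone.

The observed image is modelled as a spatially distorted version of the true
scene,

    I0(x, y) = (I(x, y) - B_T) / C_T * M_C(x, y) + M_B(x, y),

with `M_B` a spatially varying additive background brightness and `M_C` a
spatially varying multiplicative gain (contrast). Inverting gives the full
correction

    I(x, y) = C_T * (I0(x, y) - M_B(x, y)) / M_C(x, y) + B_T,

plus two diagnostic partial corrections: brightness-only
(`I0 - M_B + B_T`) and contrast-only
(`C_T * (I0 - M_B)/M_C + M_B`). `B_T`, `C_T` are free target constants;
the default policy sets them to the mean brightness/contrast over the valid
support points of the stack so all slices share one value range. Both
fields are modelled as axis-aligned 2D Gaussians with a constant offset
(6 parameters). The offset absorbs the camera baseline; rotation is omitted
because optical vignetting is approximately axis-symmetric.

## Patch-based background estimation

Each slice is tiled into non-overlapping 32x32-pixel patches (512x512
slices: 256 patches). In each patch the background is assumed normal and
the foreground (bright somata) a long-tailed excess on the right. Per
patch:

1. **Power-law tail cut.** A Clauset-style scan fits, for each candidate
   onset `x_min`, a maximum-likelihood continuous power law to the tail
   `{v >= x_min}` and picks the candidate minimising the KS distance;
   pixels at or above the chosen onset are discarded. Candidates are
   restricted to `x_min >=` the sample median: a right-tail onset inside
   the lower half of a patch is never meaningful, and without the
   restriction the KS minimum can collapse onto the background bulk when
   the foreground does not form a smoothly decaying tail. The scan caps
   the number of candidates at 200 (evenly spaced over the unique values);
   the approximation error against the exhaustive scan is tested.
2. **Normality-gated trimming.** The tail-cut sample is trimmed
   iteratively, 2.5% of the sample per step, until the Shapiro-Wilk
   statistic reaches 0.98 or a total budget of 50% (2 x 25% per side) is
   spent. Each step removes the 2.5% from the left end, the right end, or
   split over both — whichever raises the statistic most. The greedy side
   choice is essential: contamination is one-sided, and equal-count
   symmetric trimming provably cannot restore normality to a sample whose
   upper flank was censored by the tail cut (a +/-1.2 sigma symmetric
   truncation of a normal has SW ~0.973, below any useful gate).
3. **Selection.** If the raw patch already passes the gate, nothing is
   removed. Otherwise the trim runs both with and without the tail cut and
   the converged result that discards the least data wins — the tail cut
   helps precisely when a genuine foreground tail exists, and can only
   hurt when it does not.
4. **Normal fit.** Local brightness `B` = mean and contrast `C` = standard
   deviation (MLE, ddof 0) of the surviving pixels. A patch is a valid
   support point iff the gate was passed and `C > 0` (the full correction
   divides by the contrast field). Shapiro-Wilk is evaluated on at most
   4000 values (deterministic even subsample) because the test's accuracy
   degrades at very large n.

Patch size matters: 32 gives 256 support points on a 512x512 slice and
pixel samples of 1024, both comfortable; 16x16 patches (n = 256) start
failing the normality gate, while 128x128 leaves only 16 support points —
barely above the fitting minimum — and a visibly coarser field.

## Surface fitting

Valid support points feed a nonlinear least-squares fit (scipy
`curve_fit`, trust-region reflective) of the 6-parameter Gaussian for each
field. Initialisation: offset = min value, amplitude = range, centre =
value-weighted centroid, sigma = half the point-cloud extent. Bounds:
amplitude >= 0, widths in [patch size, 10 x extent], centre within one
extent of the point cloud — vignetting surfaces are wide and near-centred,
and the bounds exclude needle solutions. At least 15 support points
(2.5x the free parameters) are required, otherwise the slice is flagged
uncorrectable. Goodness of fit is reported as R^2 over the support points;
`M_C` evaluations below 1e-3 x `C_T` raise rather than silently amplify
noise.

## Bias evaluation

Slices are divided 4x4 into 16 regions typed center (inner 2x2, C1-C4),
edge (non-corner border, E1-E8) and angle (corners, A1-A4). Per laminar
compartment and measure (activity `X`, absolute change `dX`, relative
change `rdX`), all 120 unordered region pairs are compared with Welch's
unequal-variance t-test — vignetting induces heteroscedasticity by
construction — Bonferroni-corrected by the family of 120. The spread
mismatch of a pair is `delta_STD = |s_a - s_b| / mean(s_a, s_b)` (sample
standard deviations, symmetric and scale-free). Per region-type pair,
`c_p` is the fraction of non-significant pairs (corrected p >= 0.01), and
the normalised statistics `DeltaC = c_p / <c_p>_same` and
`DeltaSTD = mean(delta_STD) / <mean(delta_STD)>_same` use the unweighted
average over the three within-type pairs (C-C, E-E, A-A) as normaliser.
Untestable pairs (a region with < 2 neurons) are flagged and excluded from
the fractions. Highly active ("memory-trace candidate") cells are those
with `rdX` above the layer mean plus three standard deviations; sets from
different processing variants are compared by the asymmetric overlap rate
`|H_i & H_j| / |H_i|`.

## Phantom generator

Real stacks come without ground truth, so validation uses phantoms built
as the exact generative inverse of the full correction: a true scene
(normal background, mean 100, std 8, in arbitrary intensity units) carrying
disk-shaped somata is pushed through
`observed = (true - 100)/8 * M_C + M_B`. Defaults emulate one 512x512
two-photon slice series: brightness field amplitude 60 over offset 20
(corner background ~ half the central level), contrast field amplitude 6
over offset 3, sigma 0.35-0.4 of the slice side, centred; 150
non-overlapping somata of radius 4 px per slice (rejection sampling, 1000
retries, hard-disk profile so the centre-pixel readout is unambiguous; a
Gaussian-bump profile is available). Soma amplitudes are
truncated-exponential on [40, 120] (scale = range/3): dim cells are common
and bright ones rare, which is both realistic for immediate-early-gene
expression and produces the long-tailed patch histograms the background
estimator is designed for. Two imaging days share positions; day-1
amplitudes follow `a1 = rho a0 + sqrt(1 - rho^2) eps` with `eps` redrawn
from the amplitude distribution (default rho 0.6). Laminar compartments
are assigned by slice-index quartile. One seed drives per-slice,
per-day sub-streams with fixed offsets, so regenerating a slice never
perturbs the others.

The phantom emulates vignetting, background noise and focal somata only.
It has no axon/dendrite texture, vessel shadows, motion, or depth-varying
backgrounds, and its background is exactly normal — so passing tests show
the protocol recovers known smooth Gaussian distortions from single
images, not that real tissue backgrounds satisfy the normality model.

## Problem sizes and numerical choices

Validation runs use single 512x512 slices for field-recovery checks
(20 phantoms), two-slice/two-day phantoms with 250 somata per slice for
the bias battery (10 phantoms), and 32x32 patch simulations for the
contamination stress test (up to 30% foreground coverage). The
acceptance script repeats the same computations at slightly smaller seed
counts. Degenerate inputs are contracts, not crashes: constant patches
yield invalid zero-contrast support points, flat value sets raise on
surface fitting (no identifiable Gaussian), `rdX` with zero denominator is
flagged undefined, and an empty highly-active reference set makes the
overlap rate undefined.

## Known limitations

- The tail cut is scale-equivariant but not shift-equivariant (a power law
  has no location parameter); brightness/contrast equivariance under
  shifts is exact only on patches that pass the normality gate untouched.
- The fitted contrast field is systematically smoother than the truth when
  trimming is active (trimmed standard deviations underestimate sigma by a
  patch-dependent factor); the full correction is insensitive to a global
  contrast scale (absorbed by `C_T`), which is why brightness fits score
  R^2 ~ 0.99 and contrast fits lower.
- Per-slice independent fitting means no information sharing across depth;
  noisy slices with few valid patches are flagged rather than borrowed
  for.
- Real-data effect sizes cannot be reproduced (no deposited stacks); all
  quantitative claims are phantom-scale.
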