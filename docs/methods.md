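# Methods

`acidhif` implements the quantitative analyses used to phenotype tumour
cells under combined extracellular acidosis and hypoxia: growth across a pH
gradient, fluorometric fermentation/respiration fluxes, lysosome abundance
and localization from live-cell images, and factorial differential
abundance from label-free proteomics.  Every stage has a seeded synthetic
generator that produces inputs with the statistical structure the stage
assumes, plus the ground truth needed to verify recovery.  This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## pH-survival modelling (`acidhif.survival`)

Growth versus medium pH is modelled as a product of two Hill-type sigmoids
in pH — one activatory (acid-limited) and one inhibitory
(alkaline-limited) interaction, each with a midpoint (a binding constant
expressed on the pH scale) and a Hill coefficient:

    G(pH) = g_max · 1/(1 + 10^(n_up (pk_up − pH))) · 1/(1 + 10^(n_down (pH − pk_down)))

i.e. four shape parameters plus a maximum.  This is the minimal
"independently cooperative activation and inhibition" form; no other
functional detail is assumed.

**Normalization.**  Plates are normalized per biological replicate to the
peak of a monotone piecewise-cubic (PCHIP) interpolant through the
replicate's mean absorbance over pH; PCHIP gives a smooth peak estimate
without overshoot, so 100% is the interpolated maximum growth, and raw
points may sit a whisker above 100% when the peak falls between grid
points.

**Fitting.**  Weighted least squares with multi-start initialization:
midpoint starts at the half-maximum pH of each flank, Hill starts
{1, 2, 4} per flank (9 starts).  Bounds pk ∈ [5.5, 8.5] (the physiological
window), n ∈ (0, 10] (prevents runaway cooperativity).  Converged starts
are ranked by residual sum of squares with ties broken toward the smallest
n_up + n_down.  Strictly increasing mean growth over the grid makes the
falling limb unidentifiable; the fitter then switches to a reduced
(rising-only) model and flags it instead of failing silently.  `fix_gmax`
supports the normalize-first convention (g_max pinned at 100); the default
leaves g_max free, because normalization rescales the *curve peak* — which
is below g_max for any genuinely biphasic parameter set — so pinning
g_max = 100 on normalized data biases the shape parameters.

**Identifiability.**  Parameter-recovery tests sample pH 6.0–8.8 in 0.1
steps (three replicates, 2% growth noise): both flanks must be crossed for
all five parameters to be identified.  The default generator grid
(6.2–7.7, the standard acid-sensitivity assay window) intentionally
truncates the alkaline flank, as the assay does; fits on that window
recover the midpoints but estimate the alkaline Hill coefficient weakly.

## Metabolic flux (`acidhif.flux`, `acidhif.simulate.flux`)

Raw signals from a ratiometric pH probe (HPTS-like) and a collisionally
quenched O₂ probe (RuBPY-like) are inverted through standard calibrations:

    pH  = pKa + log10((R − R_min)/(R_max − R))
    pO₂ = (I₀/I − 1)/K_SV

Cumulative fluxes follow from the medium's physical constants — buffering
capacity β (mol·L⁻¹·pH⁻¹) and O₂ solubility α (mol·L⁻¹·mmHg⁻¹):

    H⁺(t) = β·V·(pH(0) − pH(t))
    O₂(t) = α·V·(pO₂(0) − pO₂(t)) + ∫ k_in (pO₂_atm − pO₂) α V dt

with the integral correcting for first-order atmospheric ingress through
the oil barrier when `oil_ingress_rate` is set.  Calibration constants are
assay configuration with no authoritative defaults; the shipped defaults
(pKa 7.3, ratio bounds 0.2–5, K_SV 0.004 mmHg⁻¹, β 2 mM/pH, α 1.3
µmol·L⁻¹·mmHg⁻¹, V 200 µL) are plausible values for this probe pair and
format and are shared by the forward simulator, so calibrate→simulate
round trips are exact identities.  The profiling medium is CO₂-free, so
buffering is a single constant β with no open-system carbonate term.
Probe readings outside the calibrated range are clipped with a saturation
warning; noise-driven negative cumulative values are retained because
clipping would bias slope estimates.

The lactate coupling statistic regresses end-point lactate on cumulative
H⁺ across wells, through the origin (with the free slope and intercept
reported as diagnostics).  Fermentation-only wells give slope 1; a
volatile (CO₂-derived) acid fraction f lowers the slope to 1 − f.

**Forward model.**  pH and pO₂ evolve under constant fermentative and
respiratory rates (mol/h), with optional low-pH attenuation of
fermentation (a Hill block with parameters (pK, n)) and optional O₂
ingress.  The state is advanced by classical fixed-step RK4 at the
sampling interval; halving the step changes outputs by < 0.1% (verified in
tests).  Respiration shuts off smoothly as pO₂ → 0 via 1 − exp(−pO₂/1 mmHg),
which equals 1 to machine precision at working tensions.  Default rates
(2×10⁻⁸ mol H⁺/h, 1.5×10⁻⁹ mol O₂/h) drop pH by ≈ 0.8 and pO₂ by
≈ 100 mmHg over 17 h — the scale of a confluent, metabolically active well.
Noise is additive on the ratio trace and proportional on the O₂ intensity
trace (sd 0.005 by default).

## Lysosome imaging (`acidhif.lyso`, `acidhif.simulate.images`)

**Segmentation.**  Cell-occupied area is the Gaussian-smoothed (σ = 4 px)
UV-channel background thresholded at an absolute level, holes filled.
Nuclei are segmented by smoothing and thresholding (Otsu by default), then
splitting touching objects with a watershed on the negated Euclidean
distance transform seeded at its local maxima — the "waterfall" reading of
nuclear segmentation; no seeding scheme is canonical, and
distance-transform maxima are the standard choice for convex nuclei.

**Detection.**  Canny edges vote in a circle Hough accumulator over the
lysosome radius window (2–10 px).  Accumulator local maxima above a
sensitivity floor (0.35) become candidates; duplicates within one radius
merge toward the stronger peak.  Two acceptance criteria follow: a
circularity score — the normalized perimeter support of the peak, with
ideal value 1.0 and a configurable tolerance (default 0.4), since a strict
1.0 would reject every noisy particle — and a photometric contrast check
(disk mean must exceed the surrounding annulus by 5% of saturation), which
suppresses phantom circles assembled from edges of several neighbours.
None of these thresholds is authoritative; they were tuned on the
synthetic generator at its default SNR, where detection reaches F1 ≈ 0.99
and mean radius error ≈ 0.6 px.

**Classification.**  Annotated candidates train a posterior
probability-of-lysosome surface over (radius, mean intensity):
Gaussian-KDE class-conditional densities (Scott bandwidth) combined with
training-frequency priors.  A candidate is accepted when its posterior
reaches the threshold, default the 50% probability level.  The surface
serializes to JSON for reuse.

**Statistics.**  Lysosomes per cell is the count of accepted particles
inside the cell mask divided by the nucleus count, per field of view (a
territory-level assignment is deliberately not the default, matching
whole-field normalization); fields with zero nuclei are flagged and
excluded.  Lysosome-to-nucleus distance is the Euclidean distance
transform of the nuclear mask's complement evaluated at particle centers
(0 inside nuclei), summarized as a histogram whose half-maximal-abundance
marker is found on the decreasing flank of the mode with linear
interpolation between bins.  Cathepsin-activity (Magic-Red-style) images
reuse the lysosome radius window and additionally prune particles whose
mean fluorescence is below 15% of the saturating signal.

**Synthetic fields.**  Nuclei are non-overlapping soft disks; puncta are
placed in cytoplasmic annuli at a radial fraction drawn from a Beta
distribution whose mean shifts outward with `peripheral_bias`, so a
peripheral redistribution is a recoverable ground truth.  Puncta are
rendered as super-Gaussian (order-4) disks, I(d) = peak·exp(−(d/r)⁴):
nearly flat-topped with a steep rim whose gradient maximum sits at 0.93·r,
so the truth radius coincides with the edge a gradient-based Hough
detector sees (a plain Gaussian profile would put the strongest gradient
at half the nominal radius and bias every radius estimate by a factor of
two).  Radii are Beta(1.3, 3.5)-distributed over the 2–10 px support
(most lysosomes are a few pixels), decoy artefacts are smaller and dimmer
(peak 0.25 vs 0.65 of saturation), and particles keep ≥ 0.9·(r₁+r₂)
center separation so each truth record is a resolvable object.  The
generator does not emulate optics (no PSF, no 3-D structure, no
photobleaching), so passing tests demonstrate the pipeline's geometry and
statistics, not robustness to microscope-specific artefacts.

## Factorial proteomics (`acidhif.proteomics`, `acidhif.simulate.proteome`)

The design is 2 (pH) × 2 (O₂) × b (batch), default b = 3, on log₂
label-free abundances.

- **Imputation** (minProb): each missing entry is drawn from a narrow
  normal centered at the q = 0.01 quantile of that sample's observed
  values, sd = 1% of the sample sd (the spread is not specified anywhere
  authoritative; 1% keeps draws tightly left-censored).  Observed entries
  are preserved bit-exactly and the imputation mask is returned.
- **ANOVA**: per-protein linear model with sum-coded acidosis, hypoxia,
  interaction and fixed batch blocks; single-df F-tests by
  residual-sum-of-squares comparison, vectorized across proteins;
  Benjamini–Hochberg adjustment per effect across proteins (per-effect
  families, not pooled).  The interaction coefficient is coded to equal
  the difference between the hypoxia effect under acidosis and under
  alkalosis.  The four pairwise condition contrasts (hypoxia within each
  pH, acidosis within each O₂) are t-tests on the same residual variance.
  An optional empirical-Bayes moderation fits a scaled-inverse-χ² prior to
  the residual variances by matching the first two moments of log s² and
  squeezes each variance toward the prior mode, adding the prior degrees
  of freedom — the moderated route reproduces the behaviour of
  moderated-statistics pipelines; plain OLS is the default and the two are
  surfaced separately rather than blended.
- **Correlation screen**: per-protein Pearson (default) or Spearman
  correlation with a designated reference row (the HIF-1α analogue),
  BH-adjusted; zero-variance rows are excluded with a flag.  Note that
  with batch blocks in the design, textbook correlation p-values are
  anti-conservative (within-batch dependence); the screen mirrors the
  standard practice regardless and the caveat is deliberate.
- **Clustering**: proteins passing a q-threshold on the alkaline-hypoxia
  contrast (or on the interaction effect, for the acid-selective-group
  mode) are row-standardized and clustered hierarchically on Euclidean
  distance.  Ward linkage is the default: on standardized profiles it
  yields balanced compact groups, whereas average linkage shaves off
  singleton outliers instead of splitting response archetypes; average and
  complete linkage remain available.
- **Enrichment**: one-sided Fisher's exact test (hypergeometric upper
  tail) of a protein set against a category list over a shared universe.

**Synthetic matrices** plant the response archetypes observed in this
biology — hypoxic induction strongly attenuated by acid (the HIF-1α
pattern), partially attenuated, acid-synergistic, and pH-independent
downregulation — plus a null remainder, per-protein batch offsets, and
left-censored missingness whose probability is logistic in the underlying
abundance (the real censoring process is unobserved; a logistic
detection-limit model is the standard stand-in).

## Ancillary assays (`acidhif.assays`)

ΔΔCt: replicate Cts are averaged before ΔCt (per-replicate mode exposed),
ΔΔCt is taken against the designated control condition, fold-change is
2^−ΔΔCt with spread by the range method over replicates; no
amplification-efficiency correction.  Proteasome activity: (peak
luminescence − background) / SRB growth, with both background conventions
implemented and labelled — proteasome-inhibited (epoxomicin) wells or
cell-free wells — since both appear in practice and neither is canonical;
non-positive activities are flagged, never clipped.

## Problem sizes and reproducibility

All analysis paths are deterministic given inputs and configuration; the
only RNG lives in the generators and the imputation draw, each consuming a
single seeded `numpy` Generator with no global state.  Test and
reproduction problem sizes: 12 fields of view of 256×256 px with ~8 cells
each for imaging; 12 profiling wells of 171 time points for flux; 5 000
proteins for null calibration and 1 000 for power; pH plates of 3
replicates.  These sizes give stable statistics for every property checked
while keeping the full suite fast.

## Known limitations

- The image generator's noise and intensity statistics are chosen for
  testability; no claim is made that detection thresholds transfer to a
  particular microscope without re-tuning on annotated data.
- Probe calibration constants must come from the user's own calibration;
  the defaults are placeholders of realistic magnitude.
- The unmoderated per-protein F-test is exactly calibrated but less
  powerful than moderated pipelines at b = 3; discovery counts on real
  matrices will differ between the two routes, which is why both are
  exposed.
- Hierarchical (repeat-level) ANOVA of per-field statistics is left to
  downstream consumers; the package emits per-field records suitable for
  that aggregation.
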