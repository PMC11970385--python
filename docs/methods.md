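# Methods

`dropev` implements the computational readout of a droplet-confined
digital immunoassay for single extracellular vesicles (EVs). Antibody-
coated, fluorescently color-coded capture beads are incubated with EVs,
labelled with an enzyme (streptavidin-β-galactosidase), and
encapsulated with a fluorogenic substrate (FDG) in monodisperse
picoliter droplets arranged as a packed monolayer. A droplet whose bead
carries at least one target EV fills with green (FITC) fluorescence;
counting green droplets against total beads turns a bulk immunoassay
into a digital one.

## The measurement model

**Bead loading.** Beads enter droplets independently, so the bead count
per droplet is Poisson with mean λ = C·V, where C is the bead
concentration (beads/mL) and V = (π/6)d³ the droplet volume (≈11.4 pL
at d = 27.9 μm). At the working concentration ~90% of droplets are
empty and ~9–10% hold a single bead; multi-bead droplets are rare
(`poisson_loading` reports P(0), P(1), P(≥2)).

**EV occupancy.** EVs are captured onto beads at a deliberate ~10-fold
bead excess (bead:EV = 1:r with r ≈ 0.1), so an occupied bead almost
always carries exactly one EV. The fraction of beads carrying ≥1 EV,
f_occ, converts the primary readout

    f_pos (% EV+ beads) = 100 × positive droplets / total beads

into the percent of EVs positive for the target: %EV⁺ = f_pos / f_occ.
Two occupancy models are provided:

* `ratio` (default): f_occ = r/(1+r). Every EV is captured by some
  bead; beads partition the EV pool. At r = 0.1, f_occ = 1/11 and the
  conversion is exactly ×11, which reproduces the printed worked
  conversions (5.3 → 58.3, 1.2 → 13.2, 4.3 → 47.3).
* `poisson`: EVs per bead ~ Poisson(r), f_occ = 1 − e^(−r) (0.0952 at
  r = 0.1). Also used for the single-EV purity statistic
  P(1 EV | ≥1 EV) = r·e^(−r)/(1 − e^(−r)) ≈ 0.95 at r = 0.1.

The ratio model is the default because it matches the published
conversions exactly; the Poisson alternative is selectable everywhere
an `OccupancySpec` is taken.

**Positive calling.** Per frame, background is the mean FITC intensity
of droplets containing no bead (they hold substrate but no enzyme);
its SD across beadless droplets is the noise estimate σ_bg. A droplet
is positive iff (raw − μ_bg)/σ_bg > 3 (strict) AND it colocalizes with
≥1 bead. Bright droplets without a bead cannot arise from the assay
chemistry and are excluded from numerator and denominator alike.
Exclusion happens after background estimation (beadless droplets define
the background by construction). Frames with no beadless droplet fall
back to a pooled background over the frame set.

**Calibration.** Response (% EV+ beads) vs concentration (EVs/μL from
nanoparticle tracking analysis) is fit by least squares (linear by
default, log-log selectable). LOD and LOQ are the concentrations whose
fitted response equals blank mean + 3 SD and + 10 SD respectively;
dynamic range runs from the LOD to the highest calibrator. With zero
blank SD the two limits collapse and a warning is raised.

**dSTORM fractions.** Downstream of external localization/clustering,
particles arrive as boolean marker tables. The reference marker (e.g. a
CD9/CD63/CD81 "tetraspanin trio" stain) defines the particle universe;
combination percentages partition that universe exactly (counts first,
division last), and conditional colocalization fractions obey
joint = conditional × marginal on the underlying counts.

**Cohort statistics.** Group comparisons use Kruskal–Wallis with
Dunn's pairwise z-tests (tie-corrected pooled variance; unadjusted by
default, Bonferroni/Holm optional). Discrimination uses the rank-based
(Mann–Whitney) AUC with ties counted ½, and a stratified bootstrap
percentile 95% CI (2,000 replicates, seeded). Association uses Spearman
correlation; repeatability is the inter-assay CV, the mean over samples
of per-sample 100·SD/mean. The headline biomarker is the per-subject
ratio of target % EV+ beads to CD81 % EV+ beads, which normalizes for
the number of EVs captured.

## Synthetic data generator

The generator produces 4-channel frames (brightfield, DAPI, Cy5, FITC)
with exact ground truth, emulating:

* field geometry 953 × 1432 μm², droplet diameter 27.9 μm (CV 3%);
* a squeezed hexagonal monolayer. Hard non-overlapping disks of
  27.9 μm cannot reach the observed 2,500–3,500 droplets per field
  (close packing saturates near 2,000), so droplets are placed on a
  jittered hexagonal lattice at 0.85× diameter spacing and rendered as
  dark bodies clipped to their own territory, separated by thin bright
  oil films (~2,800 droplets per default frame). A dart-throwing mode
  with hard-disk spacing is kept for sparse frames with circular
  footprints;
* Poisson bead loading (default λ = 0.104, i.e. 90.1% empty droplets),
  Bernoulli color coding (DAPI vs Cy5), and hard-sphere bead placement
  (3 μm minimum separation) inside droplets;
* Poisson EV capture per bead (default r = 0.1, per-color rates
  available for duplex experiments) and a detection-efficiency
  parameter for the enzymatic readout;
* rendering: bead spots as 2-D Gaussians (σ = 1.5 px), positive
  droplets as uniform FITC fill kept inside the droplet's territory,
  additive Gaussian noise on all fluorescence channels (bead and fill
  amplitudes specified as multiples of the noise SD). Poisson shot
  noise, illumination gradients, and chromatic shifts are not
  simulated — positive calling operates on SNR ratios and is
  insensitive to the noise family at tested levels, but passing tests
  here do not certify robustness to uneven illumination or
  misregistered channels on real microscopes.

A droplet's recorded ground-truth diameter is the nominal sphere
diameter; in packed frames the rendered footprint is clipped by
neighbours, so segmentation-derived equivalent diameters are evaluated
on sparse (dart-mode) frames.

The synthetic cohort generator draws per-subject readouts from
log-normal (default) or gamma distributions parameterized by group
medians and IQRs (solved numerically), patterned on the published
three-group structure (healthy controls, prodromal iRBD, PD; n = 20
each). Target and CD81 readouts are drawn independently within
subject; real within-subject correlation is not modelled.

## Image-analysis choices

* **Segmentation**: global Otsu threshold on brightfield with polarity
  auto-detection (droplets dark on a bright field; the 99.5th
  percentile is taken as the background side), hole filling, removal
  of sub-droplet specks, then distance-transform watershed seeded at
  h-maxima (h = 15% of the distance maximum). The distance transform
  is smoothed (Gaussian, σ = 1 px) before seed extraction to avoid
  plateau-induced overseeding. Border-touching droplets are kept and
  flagged. No size filter is applied by default; the min/max diameter
  window is configuration.
* **Bead detection**: Gaussian smoothing (σ = 1 px), flat-background
  (global median) subtraction, local maxima above an absolute
  threshold with a minimum pairwise separation (default 3 px). The
  default threshold is 5 robust noise SDs (1.4826 × MAD), keeping the
  false-detection rate well below 10⁻³ per droplet on Gaussian
  backgrounds. Beads closer than the PSF merge distance (~2σ) are
  physically unresolvable and count as one detection.
* **Assignment**: a bead belongs to the droplet whose watershed
  footprint contains its peak pixel; beads outside every droplet are
  counted as unassigned, never fatal.

## Problem sizes in the test suite

Validation at full protocol scale (20 fields × ~2,800 droplets,
100 replicates) renders frames at 3.0 μm/px, and detection-performance
checks run at the realistic 0.65 μm/px on 10 frames; both keep the
statistical conditions (droplet density, λ ≈ 0.1, SNR settings) at
their defaults. Monte-Carlo encapsulation uses 10⁶ droplets.

## Known limitations

* The generator's occupancy and rendering models are idealized; they
  verify the pipeline's statistics, not microscope physics.
* The printed conversions that deviate from ×11 by rounding-level
  amounts (e.g. 7.2 → 80.0, 5.0 → 54.8) imply unrounded internal
  numerators in the original analysis; the package converts whatever
  f_pos it is given and makes no attempt to reconstruct those internal
  values.
* Published clinical AUCs, LOD/LOQ concentrations, and the inter-assay
  CV depend on raw cohort/calibration data that are not deposited;
  the corresponding code paths are validated on synthetic data with
  planted effects instead.
* The claim that >99.9% of occupied beads carry a single EV exceeds
  the Poisson prediction at r = 0.1 (95.1%); the package reports the
  model value and treats the stronger figure as an empirical
  microscopy observation.
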