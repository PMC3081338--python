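# Methods

`bcdburst` quantifies the relationship between a morphogen input — the
Bicoid (Bcd) gradient of the early *Drosophila* embryo — and the
transcriptional bursting of its target genes, read out as intron-probe FISH
"dots" marking nascent transcripts at individual gene loci. Because no
imaging data are distributed with the analysis, the package pairs every
stage with a synthetic-embryo generator whose ground truth encodes exactly
the statistical assumptions the analysis makes; correctness is defined by
round-trip recovery of those planted parameters.

## The model

The pipeline consumes one projected 2-D multi-channel 8-bit image per
embryo (nuclear envelope, Bcd immunostain, intron FISH, optionally a
protein channel) at 0.16 µm/pixel and measures, on three scales:

* **Embryonic.** Nuclei are binned along the anterior-posterior (A-P) axis
  by normalized position x/L. Per bin, the dot density is ρ = n/N (n
  nuclear intron dots, N nuclei) — a proxy for burst probability — and the
  bursting noise is η = σ/ρ with σ the sample SD of per-nucleus dot
  counts. The input-output relation is a Hill response
  ρ(B) = ρ_max·B^n_H/(B^n_H + K^n_H) fitted to (mean B_nuc, ρ) bin pairs,
  where B_nuc = ⟨B_pix⟩ is the mean Bcd pixel intensity of a nucleus. The
  expression boundary x_b is where ρ falls to half its plateau value on the
  posterior flank, read from the x/L profile (not from the fit).
* **Nuclear.** Within each bin, nuclei with ≥1 dot (active) are compared
  against dot-free nuclei by mean B_nuc with a pooled two-sample Student's
  t-test; a difference shows that Bcd fluctuations that carry no positional
  information still propagate to transcription.
* **Local.** Pixel-intensity histograms P(B_pix) are compared between
  inactive nuclei, active nuclei, and the thresholded cluster pixels of
  detected dots mapped onto the Bcd channel (modes, two-sample
  Kolmogorov-Smirnov tests, and the dot-site/active density ratio with its
  baseline at 1). Enrichment above 1 at high intensities marks activator
  accumulation at transcription sites.

For an X-linked target, embryos are sexed by the ratio of two-dot to
one-dot nuclei in the expression region (females carry two copies), and
dosage compensation is assessed by comparing ρ and dot intensities between
sexes.

## Spot calling and threshold choice

An intron dot is a connected cluster (8-connectivity by default,
4-connectivity available) of pixels all ≥ an intensity threshold, with
cluster size ≥ a pixel-count threshold (defaults 32 and 4). The intensity
threshold can be chosen automatically: with the size threshold fixed at 4,
the difference in dot density between two expression regions,
Δρ = ρ(x/L 0.3–0.4) − ρ(x/L 0.2–0.3), is scanned as a function of the
threshold; the chosen value is the smallest at which successive changes in
Δρ stay below 0.01 dots/nucleus for 3 consecutive steps of 2 intensity
units — a detected pattern that has stopped depending on the threshold,
while keeping the dot count maximal among plateau members. The scan starts
at T = 14: below the intranuclear-background percolation point every
nucleus reads as a single stable cluster and Δρ is degenerately flat, which
would satisfy any plateau rule vacuously. Three QC error criteria accompany
a choice: dots/nucleus in the non-expression window x/L 0.55–0.65, the
cytoplasmic-to-nuclear dot ratio, and the fraction of nuclei with >2 dots.

Cluster counts are not globally monotone in the threshold (a merged
two-dot cluster can split as the threshold rises); what thresholding
guarantees is nesting of the suprathreshold pixel set, and count
monotonicity holds exactly for isolated spots.

## Synthetic embryos

The generator renders an elliptical embryo on a configurable canvas
(default 2048×512 px for wild-type cohorts; 2048×2048, the acquisition
size, for X-linked cohorts where sexing power needs real-data nucleus
counts). Key defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.16 µm | acquisition convention |
| nucleus diameter | 6.06 ± 0.80 µm | measured nuclear geometry at cycle 14 |
| gradient | B(x) = 120·e^(−(x/L)/0.2) + 2 | smooth exponential; length constant 0.2·L gives the observed dynamic range |
| Hill response | n = 6, K = 16, q_max = 0.85 | steep cooperative response; K places the half-max boundary at x/L ≈ 0.43 |
| nuclear fluctuation | lognormal, CV 0.15 | nucleus-to-nucleus Bcd noise at fixed position |
| Bcd texture | per-pixel gamma multiplier, shape 8 | punctate intranuclear distribution of Bcd |
| dot rendering | Gaussian spot, σ 0.30 µm; peak ~ lognormal(median 120, σ 0.2) | diffraction-scale spot; intensity independent of position and Bcd |
| local enrichment ε | 10 intensity units (Gaussian bump, σ = dot σ) | enrichment exists but its amplitude is unquantified; set to be detectable at realistic pixel counts |
| intranuclear haze | 14 ± 2 between nuclei, pixel SD 3 | dim nuclear background that gives the threshold scan a non-trivial plateau |
| posterior domain | x/L 0.82–0.96, q = 0.3 | Bcd-independent posterior expression |

Each gene copy bursts independently with probability
q(B) = q_max·B^n/(B^n + K^n) evaluated on the pre-quantization nuclear Bcd
input; one dot is rendered per bursting copy, centered uniformly at random
on the nuclear disc. Male X-linked embryos carry one copy; the
dosage-compensation condition doubles their per-copy q_max. For X-linked
cohorts the female q_max is 0.32 so that the *realized* per-copy
probability among scored expression-window nuclei is 0.275 — the value the
published two-dot/one-dot ratio of 0.19 implies — because the Hill decline
and nuclear fluctuations inside the window lower the realized probability
below q_max.

What the generator does **not** emulate: optics beyond a Gaussian spot (no
PSF, no deconvolution), 3-D z-stacks (images are already projected),
mitotic or irregularly shaped nuclei, spatially structured background, and
segmentation-hostile artifacts (touching nuclei occur only via the
watershed-split path). Passing round-trip tests therefore validates the
statistical machinery and its estimators, not robustness to real-world
image degradation.

## Numerical choices

* **Segmentation**: envelope rings are Otsu-thresholded, filled
  (`scipy.ndimage.binary_fill_holes`), labeled, size-gated to 3–10 µm
  equivalent diameter, and split by a distance-transform watershed when a
  component exceeds a single-nucleus area. Nucleus = filled component
  including the envelope, so recovered diameters match the drawn rings.
  Border-touching components are excluded (configurable).
* **A-P frame**: major axis of the embryo mask by PCA; anterior is the end
  with the higher mean Bcd unless fixed by configuration; x/L by
  orthogonal projection of the nucleus centroid, 0-based pixel centers.
* **Boundary estimator**: the profile is smoothed with a 3-bin running
  mean; ρ_max is the mean over the plateau (bins ≥ 75% of the smoothed
  maximum) rather than the single maximal bin, whose upward noise bias
  would inflate the half-max level and drag the crossing anterior by about
  a bin; the crossing is linearly interpolated.
* **Hill fit**: `scipy.optimize.curve_fit` with bounds n_H ∈ [0.05, 50],
  K within 10× the observed B_nuc range, initialized at n_H = 4 and the
  half-max bin; data whose response decreases with B are rejected with an
  orientation error. Fits use anterior-window bins only (default x/L
  0.1–0.6) so the Bcd-independent posterior domain cannot corrupt ρ(B).
* **Bootstrap**: percentile CIs from resampling nuclei within a bin with
  replacement; deterministic given a seed; replicates with ρ = 0
  contribute no η.
* **t-tests**: pooled-variance two-sample, two-tailed (Welch via flag);
  applied per bin without multiplicity correction by default
  (Benjamini-Hochberg optional off the shelf via `scipy`/`statsmodels` if
  needed downstream).
* **Histograms/K-S**: integer 0–255 support; modes break ties toward the
  lowest intensity with a flag; K-S tests run on the raw pixel samples.
  Dot-site pixels are clipped to the owning nucleus mask — a cluster
  touching the nuclear boundary would otherwise contribute cytoplasmic
  pixels that belong to neither nuclear population. Because dot-site
  pixels are clustered by nucleus, null K-S p-values have a slightly heavy
  extreme tail; enrichment conclusions rest on p ≪ 0.01 together with the
  ratio-curve shape.
* **Degenerate inputs**: blank envelope → segmentation error; no plateau →
  error carrying the scan table; zero-width or flat profiles → boundary
  error; empty QC windows report NaN, never zero; duplicate dot
  coordinates are excluded from pair distances with a warning.

## Problem sizes

Wild-type cohorts use 14 embryos at 2048×512 px (≈270 nuclei each) — the
cohort size of the original measurements at a canvas that keeps a full
pipeline pass to a few seconds per embryo. X-linked cohorts use 8 female +
4 male embryos at 2048×2048 px (≈1200 nuclei each). Monte-Carlo geometry
checks use 10⁵ dot pairs. One detection threshold is chosen on the first
embryo of a cohort and reused, mirroring a single acquisition setting
across embryos.

## Known limitations

* Segmentation quality is only demonstrated on generator-style envelope
  rings; real membrane stains will need parameter adjustment
  (`ring_threshold`, size gates) and possibly a different splitting
  strategy.
* The Hill coefficient recovered from noisy per-embryo fits is mildly
  biased downward (bin noise flattens the apparent response); cohort means
  recover the generating value within the fit spread, which is itself
  large at realistic bin occupancies.
* η compares counts to a protein readout rendered with independent additive
  noise; real protein data share acquisition noise structure with the Bcd
  channel, which the generator does not model.
* Two dots closer than roughly a cluster diameter merge into one detected
  dot (~5% of two-dot nuclei at defaults); this slightly depresses two-dot
  ratios and ρ in high-expression regions, and truncates the short end of
  the measured pair-distance distribution (raising its mean by ~10-15%
  relative to the uniform-disc law), exactly as finite optical resolution
  does in the real measurement.
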