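# bcdburst

Multiscale analysis of morphogen-dependent transcriptional bursting from
multi-channel FISH images of early *Drosophila* embryos.

At nuclear cycle 14, transcription of Bicoid (Bcd) target genes such as
*hunchback* and the X-linked *orthodentical* is stochastic: each gene copy
either carries a nascent-transcript "intron dot" or it does not. `bcdburst`
implements the image analysis that links the Bcd gradient input to this
bursting output on three scales:

* **embryonic** — the dot density ρ = n/N per A-P bin, its Hill response
  ρ(B) = ρ_max·B^n_H/(B^n_H + K^n_H) to the nuclear Bcd level
  B_nuc = ⟨B_pix⟩, the half-max expression boundary x_b, and the bursting
  noise η = σ/ρ with bootstrap error bars;
* **nuclear** — active-vs-inactive comparisons of B_nuc within bins
  (pooled Student's t-tests);
* **local** — P(B_pix) pixel histograms of inactive nuclei, active nuclei
  and detected dot sites, with K-S tests and the dot-site/active density
  ratio (baseline 1) that reveals Bcd enrichment at transcription sites;

plus intron-dot calling by a joint intensity/size threshold (defaults
32/4) with automatic plateau-based threshold selection and three QC error
criteria, within-nucleus dot geometry (radial distribution, pair
distances), and sex classification / dosage-compensation analysis for
X-linked targets from the two-dot/one-dot nucleus ratio.

Because the original confocal data are not distributed, the package
includes a first-class synthetic-embryo generator with ground truth
(`bcdburst.synth`) encoding every statistical assumption of the analysis
— exponential gradient, Hill-dependent per-copy bursting, uniform dot
placement on the nuclear disc, position-independent dot intensities,
1-vs-2 gene copies by sex — so the whole pipeline is testable end to end.
See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
from bcdburst import EmbryoSpec, generate_embryo
from bcdburst.pipeline import process_embryo

image, truth = generate_embryo(EmbryoSpec(seed=3))   # 2048x512 px embryo
res = process_embryo(image, truth=truth)             # auto threshold
print("nuclei:", len(res.nuclei), " dots:", len(res.dots))
print("chosen threshold:", res.thresholds)
print("boundary x_b: %.3f  (generated: %.3f)" % (res.boundary,
                                                 truth.spec.true_boundary))
print("Hill n_H: %.2f" % res.hill.n_hill)
print("QC:", res.qc)
```

prints

```
nuclei: 273  dots: 196
chosen threshold: DotThresholds(t_intensity=26.0, t_size=4)
boundary x_b: 0.418  (generated: 0.430)
Hill n_H: 5.30
QC: QCReport(nonexpression_dots_per_nucleus=0.027, cytoplasm_to_nuclear_ratio=0.0, frac_nuclei_gt2=0.0)
```

The embryo's 273 nuclei are segmented from the envelope channel; the
intensity threshold is chosen where the Δρ scan plateaus; 196 nascent-
transcript dots are detected and assigned to nuclei; the half-max boundary
of the dot-density profile lands within half a bin of the generating value,
the fitted Hill coefficient is noisy per embryo (cohorts of 14 recover the
generating value within the fit spread), and all three detection-error
criteria are near zero.

A full cohort run with CSV/JSON outputs and a manifest:

```bash
bcdburst run-all --seed 0 --out runs/demo     # 14 embryos, all stages
```

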