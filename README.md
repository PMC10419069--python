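# dabquant

Quantification of DAB-immunostained brain histology and nonparametric
cohort comparison, with a synthetic ground-truth generator that makes the
whole pipeline testable end to end.

The package is aimed at preclinical neuropathology studies that compare a
treated against a control cohort of mice on region-of-interest (ROI)
readouts of brightfield immunohistochemistry — for example phospho-tau
(AT8), microglial (Iba1) and astrocytic (GFAP) staining of coronal
sections, outlined per hemisphere over the hippocampus, amygdala, piriform
cortex and somatosensory cortex.

## What it computes

All quantification operates on the DAB optical-density (OD) channel,
obtained per pixel as OD = −log₁₀((I+1)/(I₀+1)) and separated from
hematoxylin by Ruifrok–Johnston colour deconvolution.  Four readouts:

1. **Superpixel H-score** (phospho-tau burden).  Each ROI is partitioned
   into ~10 µm SLIC superpixels (grid-seeded clustering in joint
   space–intensity, so superpixels hug staining contrasts).  Each
   superpixel's mean OD is classified against thresholds held constant
   across the experiment into negative / weak / moderate / strong, and

       H = (SP_W·100 + SP_M·200 + SP_H·300) / SP_T ∈ [0, 300],

   with SP_W, SP_M, SP_H the weak/moderate/strong superpixel counts and
   SP_T the total.  Per-class fractions are also reported, so shifts in the
   signal-intensity distribution (e.g. negative → moderate) can be compared
   between groups.
2. **Pixel-classifier stain load** (microglia).  A random forest over a
   per-pixel feature stack (raw OD, Gaussian-smoothed OD, local SD),
   trained from positive/negative polygon annotations, yields a stain mask;
   load = 100 · stained area / ROI area.
3. **Soma density** (microglia).  A seven-step morphology chain — 8-bit
   conversion, local contrast normalization, auto-threshold, closing,
   erosion, despeckle, 8-connected particle counting with an inclusive
   8 µm² cut-off — counts compact somata, normalized per mm² of ROI.
4. **Phansalkar stain load** (astrocytes).  Local adaptive threshold
   t = μ(1 + p·e^(−qμ) + k(σ/r − 1)) on normalized stain intensity, suited
   to faint finely branched objects; again reported as percent stained area.

Statistics mirror standard practice for such cohorts: paired Wilcoxon
signed-rank tests check left/right hemisphere differences, hemispheres are
then averaged per mouse, and treated vs control groups are compared per
region with two-sided Mann–Whitney tests (exact by complete enumeration at
small n), with results normalized to the control-group mean = 100%, an
optional Grubbs outlier screen, and star labels
(\* p<0.05, \*\* p<0.01, \*\*\* p<0.005, \*\*\*\* p<0.0005).

Because real slide scans are rarely shareable, `dabquant.synthetic`
generates DAB-like brightfield tiles (diffuse patches in four intensity
strata, tangle-like blobs, ramified microglia-like and star-shaped
astrocyte-like cells) with exact ground truth, plus whole cohorts with
programmed per-region effect multipliers and log-normal between-mouse
variability — every stage of the pipeline is validated against this ground
truth.

## Worked example

A synthetic study with a +48% H-score effect programmed only in the
piriform cortex (10 treated vs 6 control mice, between-mouse CV 25%):

```python
import dabquant as dq
from dabquant.synthetic import CohortSpec, GroupSpec

config = dq.StudyConfig(
    seed=3,
    cohort=CohortSpec(
        groups=(
            GroupSpec("sonicated", 10, {"piriform_cortex": 1.48}, arm="sonicated"),
            GroupSpec("control", 6, 1.0, arm="non_sonicated"),
        ),
        between_mouse_cv=0.25,
        within_mouse_cv=0.10,
        seed=3,
    ),
    render=False,
)
report = dq.run_study(config)
for c in report.comparisons:
    print(f"{c['region']:22s} {c['percent_change']:+7.1f}%  "
          f"U={c['U']:4.0f}  p={c['p']:.4f}  {c['stars']}")
```

prints

```
amygdala                 +11.5%  U=  37  p=0.4923  ns
hippocampus               +5.4%  U=  30  p=1.0000  ns
piriform_cortex          +61.2%  U=  52  p=0.0160  *
somatosensory_cortex      +6.9%  U=  32  p=0.8749  ns
```

The programmed effect is recovered where it was planted (+61% observed for
a +48% programmed multiplier under 25% biological noise, exact Mann–Whitney
p = 0.016) and the unaffected regions stay non-significant.  With
`render=True` the same study renders every scene to a brightfield image and
re-quantifies it through the full imaging pipeline (colour deconvolution →
SLIC → classification → H-score) instead of using generator ground truth.

The `dabquant` command exposes the same machinery from a shell:
`simulate`, `hscore`, `load`, `soma`, `gfap`, `stats`, `run`, `validate`
(see `dabquant --help`).

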