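# acidhif

Quantitative pipeline for phenotyping cells under combined extracellular
acidosis and hypoxia — the chemical signature of poorly perfused solid
tumours.  Tumour cells acidify their medium by fermentation and deplete
oxygen by respiration; the interplay between low pHe and low pO₂ reshapes
growth, metabolism, HIF signalling and lysosomal degradation.  `acidhif`
implements the analyses needed to measure those responses:

- **`acidhif.survival`** — growth across a pH gradient, normalized per
  replicate and fitted to a biphasic Hill-type curve
  `G(pH) = g_max · [1 + 10^(n_up(pk_up−pH))]⁻¹ · [1 + 10^(n_down(pH−pk_down))]⁻¹`
  (an activatory and an inhibitory interaction, each with a binding
  constant and a Hill coefficient).
- **`acidhif.flux`** — plate-reader metabolic profiling: ratiometric pH
  probe and Stern–Volmer O₂ probe calibration, cumulative acid production
  `H⁺(t) = β·V·ΔpH` and O₂ consumption `O₂(t) = α·V·ΔpO₂` (+ oil-barrier
  ingress correction), and the lactate-vs-H⁺ coupling slope.
- **`acidhif.lyso`** — live-cell lysosome quantification: cell
  demarcation, watershed nuclear segmentation, circular-Hough puncta
  detection in the 2–10 px radius window, a trained radius–intensity
  posterior classifier (50% probability acceptance), lysosomes per cell,
  sizes, and nucleus-distance histograms via the Euclidean distance
  transform; cathepsin-activity counts with 15%-of-saturation pruning.
- **`acidhif.proteomics`** — factorial label-free proteomics: minProb
  left-censored imputation, per-protein two-way ANOVA (pH × O₂ with batch
  correction) with BH FDR, pairwise condition contrasts, a correlation
  screen against a reference protein (e.g. HIF-1α), hypoxia-response
  clustering, and Fisher-exact enrichment.
- **`acidhif.assays`** — ΔΔCt qPCR fold-changes and normalized proteasome
  activity.
- **`acidhif.simulate`** — seeded generators for every input class
  (punctate two-channel images, probe traces, growth plates, abundance
  matrices) with recoverable ground truth.

## Worked example

Simulate twelve fermentation-only profiling wells, invert the probe
calibration, and relate end-point lactate to cumulative H⁺:

```python
import numpy as np
from acidhif.simulate import FluxSimSpec, make_flux_timecourse
from acidhif.flux import calibrate_timecourse, lactate_slope

cum_h, lactate = [], []
for i in range(12):
    rate = 2e-8 * (0.5 + 1.5 * i / 11)          # mol H+/h, 0.5-2x reference
    spec = FluxSimSpec(fermentative_rate=rate, co2_acid_fraction=0.0, seed=1000 + i)
    raw, truth = make_flux_timecourse(spec)      # noisy probe traces + truth
    flux = calibrate_timecourse(raw, spec.calibration())
    for t in (8.0, 17.0):                        # end-point sampling times
        idx = int(np.argmin(np.abs(flux.time - t)))
        cum_h.append(flux.cumulative_acid[idx])
        lactate.append(truth.lactate_at(t))
res = lactate_slope(np.array(cum_h), np.array(lactate))
print(f"slope_through_origin={res.slope_through_origin:.4f} r={res.pearson_r:.4f} n={res.n}")
```

```
slope_through_origin=0.9998 r=0.9998 n=24
```

A slope of 1 means every mole of acid detected by the pH probe is matched
by a mole of end-point lactate — the assay reads fermentative rate.  With
a volatile (CO₂-derived) acid fraction f the slope falls to 1 − f.

Fitting a simulated growth plate (truth: pk_up 6.6, n_up 2, pk_down 7.9,
n_down 3):

```python
from acidhif.simulate import SurvivalSimSpec, make_survival_plate
from acidhif.survival import normalize_growth, fit_biphasic_hill

plate, _ = make_survival_plate(SurvivalSimSpec(seed=0))
fit = fit_biphasic_hill(normalize_growth(plate))
p = fit.params
print(f"pk_up={p.pk_up:.3f} n_up={p.n_up:.2f} pk_down={p.pk_down:.3f} n_down={p.n_down:.2f}")
```

```
pk_up=6.592 n_up=2.04 pk_down=7.938 n_down=2.63
```

The midpoints recover sharply; the alkaline-flank Hill coefficient is
weakly identified on the default 6.2–7.7 assay window, which only clips
the falling limb (see `docs/methods.md`).

A command-line surface wraps the same functions, e.g.:

```sh
acidhif simulate plate --out sim --seed 3
acidhif fit-survival --in sim/plate.csv --out fit
acidhif simulate proteome --out prot --seed 5
acidhif proteome anova --matrix prot/abundance.tsv --design prot/design.csv --out res
```

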