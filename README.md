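# shgscatter

Wavelength-dependent second-harmonic-generation (SHG) microscopy and
optical-scattering analysis of tissue extracellular matrix, with a
multi-metric discriminant classifier — built for researchers quantifying
collagen remodeling (e.g. in ovarian cancer stroma) from two-channel
depth-resolved SHG image stacks and collimated-transmission measurements.

## What it computes

SHG in collagen is coherent, so imperfect phasematching splits the created
signal into forward and backward lobes. The intrinsic creation ratio
F_SHG/B_SHG encodes fibril size and packing relative to the SHG
wavelength λ_SHG, but the ratio *measured* at the microscope's two
detectors is further shaped by scattering of the SHG photons on their way
out of the section. The package decouples these with a Monte Carlo photon
transport model (MCML-style weighted random walk: exponential free paths,
Henyey–Greenstein phase function with measured anisotropy g, Fresnel
boundaries, NA-bounded detector acceptance):

- **F_SHG/B_SHG** — best χ² fit of the measured F/B-vs-depth curve
  against a library of forward simulations over candidate ratios;
- **relative SHG conversion efficiency** — least-squares scale between
  the measured forward attenuation curve and a per-unit-efficiency
  simulation reusing the fitted ratio;
- **μs, μs′ = μs(1 − g)** — Beer–Lambert inversion of collimated
  transmission (valid when μa ≪ μs) and the reduced scattering
  coefficient;
- **shape factor m** — exponent of the scattering power law
  μs′(λ) ∝ λ^(2m−4), fit in log–log space over 390–535 nm; larger m
  means larger / more ordered sub-micron structure;
- **pairwise tissue classification** — canonical discriminant (≤3
  canonical variables, nearest-centroid, leave-one-out), ROC/AUC via
  logistic regression, ANOVA + Fisher-LSD group tests.

A synthetic-data module generates every input the pipeline consumes
(image stacks, transmission spectra, feature cohorts) from known ground
truth, with five presets emulating normal ovarian stroma, benign, low- and
high-grade serous, and endometrioid tumor ECM.

## Worked example

Generate a small synthetic cohort (three normal, three high-grade serous
samples) and run the full pipeline:

```python
from pathlib import Path
from shgscatter import builtin_presets
from shgscatter.synthetic_data import write_sample
from shgscatter.workbench import PipelineConfig, run_pipeline

root = Path("demo")
dirs = []
for i, name in enumerate(("normal", "HGS")):
    for rep in range(3):
        d = root / f"{name}_{rep}"
        write_sample(builtin_presets()[name], d, seed=10 * i + rep,
                     image_shape=(16, 16), n_photons=8000)
        man = (d / "manifest.yaml").read_text()
        (d / "manifest.yaml").write_text(
            man.replace(f"sample_id: {name}", f"sample_id: {name}_{rep}"))
        dirs.append(str(d))

bundle = run_pipeline(PipelineConfig(
    sample_dirs=dirs, output_dir=str(root / "out"),
    seed=1, n_photons=4000, cv="loo"))
print(bundle["metrics"][["sample_id", "tissue_label", "m_shape",
                         "mus_prime_390", "fb_988", "eff_988",
                         "accepted_988"]].round(3).to_string(index=False))
print(bundle["pairwise_accuracy"].frame.to_string())
```

prints

```
sample_id tissue_label  m_shape  mus_prime_390  fb_988  eff_988  accepted_988
    HGS_0          HGS    1.185         29.796   2.278   44.839          True
    HGS_1          HGS    1.183         30.013   2.278   43.642          True
    HGS_2          HGS    1.180         29.824   2.278   43.736          True
 normal_0       normal    1.338         21.844   4.362   18.349          True
 normal_1       normal    1.325         21.975   4.362   18.153          True
 normal_2       normal    1.285         22.121   4.362   17.735          True

        HGS  normal
HGS     NaN     1.0
normal  1.0     NaN
```

Reading the numbers: the HGS preset scatters more strongly
(μs′(390) ≈ 30 vs 22 cm⁻¹) with a lower shape factor (m ≈ 1.18 vs 1.33 —
less sub-micron order), a lower intrinsic emission directionality
(F_SHG/B_SHG ≈ 2.3 vs 4.4 at 988 nm excitation — small, regularly packed
fibrils favor backward emission through quasi-phasematching), and a
~2.4× higher relative conversion efficiency (denser collagen). The
`accepted` flag is the χ² goodness-of-fit of the Monte Carlo inversion;
identical fb values within a tissue reflect the candidate grid
resolution (~14% steps). Leave-one-out pairwise classification separates
the two types perfectly; one-way ANOVA on the per-sample metrics gives
e.g. p = 1.9×10⁻⁷ (μs′ at 390 nm) and p = 1.2×10⁻³ (m).

The same flow is scriptable from the shell:

```sh
shgscatter synth --out demo --preset normal --preset HGS --wavelength 988
shgscatter scatterfit demo/HGS/transmission.csv --out fit.json
shgscatter extract demo/HGS --out hgs_metrics.csv
```

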