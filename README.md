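# qpidense

Quantitative-phase-imaging (QPI) densitometry of budding yeast under
growth-induced pressure.

Cells proliferating in a confined space push on their surroundings and build
up growth-induced pressure (GIP), and their cytoplasm becomes more crowded.
`qpidense` turns optical-path-difference (OPD) phase images of
*S. cerevisiae* into refractive index (RI) and intracellular dry-mass density
— for free cells on a plate and for cells packed inside an elastic PDMS
microfluidic chamber — and estimates the **nominal intracellular osmotic
pressure Π_c0** by extrapolating the RI-vs-GIP line down to the refractive
index of water. It is written for quantitative microscopists and
biophysicists who want the full analysis chain, plus a forward simulator
that renders scenes with known ground truth so every stage is testable
without microscope data.

## The model

Per pixel, a phase image measures OPD = (n_sample − n_ref)·d. The package
implements the four conversions built on this relation:

| quantity | relation |
|---|---|
| plate-mode cell RI | n_cell = n_media + OPD/d_cell, with d_cell the mask's minor-axis length and OPD the mean of the brightest 5% of in-cell pixels |
| chamber height | d_chamber = \|OPD\|/(n_PDMS − n_media), OLS line d_chamber(P) = h₀ + s·P from hydraulic calibration |
| chamber-mode cell RI | n_cell(P) = n_PDMS + OPD(P)/d_chamber(P), signed OPD (negative below n_PDMS) |
| dry-mass density | ρ = (n_cell − baseline)/α, α = 0.190 ml/g |

GIP is read from the lateral chamber-wall deformation, P = Δw/8.2 μm·MPa⁻¹.
An ordinary-least-squares fit of RI (or, equivalently, density) against GIP —
excluding loosely packed unpressurised chambers and anchored by the
plate-mode population RI at P = 0 — is extrapolated to n_water = 1.332:

    Π_c0 = (a − n_water)/b,   with 95% CI by case-resampling bootstrap
                              (default) or delta method.

Constants (n_media 1.336, n_PDMS 1.405, n_water 1.332, α 0.190 ml/g,
k 8.2 μm/MPa) live in `OpticalConstants`/`RunConfig` and a YAML config, not
in code. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate the study conditions (91 plate cells with RI 1.384 ± 0.004, a
45-chamber pressure series anchored at a true Π_c0 of 1.55 MPa, 10 nm OPD
noise) and run the whole analysis:

```python
from qpidense import RunConfig
from qpidense.pipeline import run_pipeline

report = run_pipeline(RunConfig(seed=1), output_dir="demo")
print(f"plate: n={report['plate']['n_cells']}, "
      f"mean RI {report['plate']['mean_ri']:.4f}, "
      f"mean density {report['plate']['mean_density_mg_ml']:.1f} mg/ml")
print(f"chamber height h0 = {report['height_calibration']['height0_um']:.2f} um")
est = report["nominal_pressure"]
print(f"pi_c0 = {est['pi_c0_mpa']:.3f} MPa, "
      f"95% CI [{est['ci95_mpa'][0]:.3f}, {est['ci95_mpa'][1]:.3f}] ({est['method']})")
```

prints

```
plate: n=91, mean RI 1.3856, mean density 260.9 mg/ml
chamber height h0 = 9.20 um
pi_c0 = 1.570 MPa, 95% CI [1.548, 1.614] (bootstrap)
```

Reading: the segmented population's RI (and its density under the
culture-medium baseline) recovers the generator's 1.384 truth up to the
documented ≲10⁻³ statistic bias; the medium-filled-chamber calibration
recovers the 9.2 μm mold height; and the extrapolation recovers the true
nominal osmotic pressure of 1.55 MPa within its interval. `demo/` then holds
`cells.csv`, `chamber.csv`, `gfp.csv`, `height_calibration.csv` and
`report.json` (with version, seed and config hash).

The same stages are available as shell commands — `qpidense simulate`,
`segment`, `measure`, `calibrate-height`, `chamber-ri`, `fit`, `gfp`,
`report`, `gip` — operating on float-TIFF images and CSV tables;
`read_zenodo_tabs` loads deposited multi-tab Excel workbooks for re-analysis
of published observation tables.

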