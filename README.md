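# kelpcsp

Carbon export, decomposition and **carbon sequestration potential (CSP)**
of Northeast Atlantic *Laminaria* kelp forests.

Kelp forests export large amounts of particulate carbon as eroded lamina
detritus, but how much of it survives long enough to be sequestered
depends on the species. In the southern UK, warm-temperate
*Laminaria ochroleuca* is replacing the cold-temperate
*L. digitata* and *L. hyperborea* as the sea warms. This package
implements the full carbon-flux chain needed to ask what that
compositional change does to the forest's blue-carbon function, for
quantitative ecologists and blue-carbon modellers:

- **Erosion → export**: hole-punch measurements (growth `G = H_F − H_I`,
  lamina loss `E_L = L_I + G − L_F`, dry-mass rate `E_M = E_L·ML_R/Δt`)
  converted to carbon export with tissue carbon fractions, aggregated
  monthly → seasonal → annual with variance-sum errors.
- **Decomposition & biochemistry**: litterbag rates
  `D = (M_0 − M_1)/(M_0·Δt)`, grazing-scar proportions, phloroglucinol
  standard curves, and detrital-age trends (linear phenolics,
  exponential C:N).
- **Respirometry**: blank-corrected light/dark bottle rates
  (`GPP = NPP + R`), photoinhibition-day exclusion, and carbon
  assimilation `CA = NPP·10⁻⁶·12.0107/M_R`.
- **CSP model**: `CSP(t) = N·CE·(1 − t·D)` with Goodman
  product-of-means 95% CIs and delta-method errors on the time to zero.
- **Range projection**: LOESS-smoothed SST trajectories and linear
  density scaling between thermal thresholds
  (`N_C = N·(T_U − T_max)/(T_U − T_max2016)`, analogous for the warm
  species), giving forest CE and CSP through two centuries of warming.
- **Detrital assimilation**: a tanh photosynthesis–irradiance curve and
  exponential light attenuation along a sinking trajectory, accumulated
  as `CA(t) = Σ N·BE·D_CA(k)·h·GPP(k)·P_GPP(k)`.
- **Synthetic data**: generators for every input table, calibrated to
  the study system's reported levels, so the whole pipeline runs and is
  testable without the original field data.

## Worked example

Run the numbered analysis scripts from the repository root (or the
equivalent `kelpcsp run-all --seed 1 --out results/run` console
command):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_carbon_export.py
python analysis/03_decomposition_biochem.py
python analysis/04_respirometry.py
python analysis/05_csp_curves.py
python analysis/06_range_projection.py
python analysis/07_detrital_assimilation.py
```

Selected output from seed 1:

```
decomposition is 41% and 245% faster in the warm species than in
L. digitata and L. hyperborea
ochroleuca: gross production declines, predicted to fail after 33 days
digitata:   CSP reaches zero after  99 +- 15 days
hyperborea: CSP reaches zero after 242 +- 117 days
ochroleuca: CSP reaches zero after  70 +- 9 days
RCP2.6: forest CSP declines 0.03% per year to 2100
RCP6.0: forest CSP declines 0.44% per year to 2100
RCP8.5: forest CSP declines 0.98% per year to 2100
```

Reading this: the warm-temperate species decomposes fastest, so its
exported carbon is remineralized within ~2 months while
*L. hyperborea* detritus persists for most of a year; its detrital
photosynthesis also fails after about a month, compounding the
difference. When warming replaces the cold species with the warm one,
forest carbon *export* stays roughly level but forest *CSP* declines,
fastest under the harshest emission scenario — mitigation (RCP2.6 vs
RCP8.5) retains most of the present sequestration potential.

Per-species tables (export, decomposition, production, CSP curves,
projections, assimilation) are written under `results/`.

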