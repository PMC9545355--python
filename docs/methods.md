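# Methods

This note documents the models, the uncertainty rules, the synthetic
data generator and the numerical choices behind `kelpcsp`.

## Carbon export from lamina erosion

Each tagged plant carries three punched holes (two on the central
digit, one on an outer digit). Hole displacement separates growth from
erosion: `G = H_F − H_I` (holes only move distally; proximal movement
is rejected as a measurement error naming the plant), and
`E_L = L_I + G − L_F ≥ 0`. Per plant, `E_L` is the unweighted mean of
the central-digit and outer-digit means — the sampling design gives no
basis for weighting the two central holes double. Dry mass per unit
length `ML_R` comes from three 5-cm distal segments, **listed
outermost-first**; the outermost segment's own dry:wet ratio `M_R` is
applied to all three (the per-plant ratio is tight, so no pooled ratio
is used). Daily biomass erosion is `E_M = E_L·ML_R/Δt` and carbon
export `CE = E_M·f_C`, where the carbon fraction `f_C` is matched by
nearest date within a 45-day window — tissue carbon is sampled roughly
bimonthly and interpolating would manufacture precision the sampling
does not have.

Aggregation mirrors the field bookkeeping: daily export × actual
calendar days in the record's month (Feb = 28 unless leap), mean ± SE
across plants per month, then seasonal (meteorological seasons:
Mar–May spring, etc.) and annual totals as sums of monthly means with
variance-sum SEs. Missing months raise rather than impute. Plants with
fewer than two surviving punched digits are dropped with a warning.

## Decomposition and biochemistry

Litterbag decomposition is proportional wet-mass loss per day,
`D = (M_0 − M_1)/(M_0·Δt)`, computed on wet mass as measured. Negative
rates (detrital growth, seen in the shallow-forest deployment) are
retained in pooling; only the assimilation model's decay factor
`D_CA = max(0, 1 − tD)` is floored, because a biomass fraction cannot
be negative. Species means pool all bags from both experimental
designs (deep sediment, 40–41 d, ~105 g; forest floor, 13/25/32 d,
~20 g; n = 43 total per species); per-bag identity is carried for
grouping only — random-effect structure is out of scope.

Phenolics are phloroglucinol equivalents from an OLS standard curve
(triplicate plate readings averaged before inversion). The
concentration → %-dry-mass chain exposes the extraction ratio (default
10 % w/v, i.e. 100 mg ml⁻¹ of tissue) and the dilution factor
explicitly, because the assay's dilution chain is protocol-dependent.
Negative back-calculated concentrations clamp to zero with a warning.
Detrital-age trends are OLS fits — linear for phenolics and carbon,
log-linear for C:N so the slope is an exponential rate (day⁻¹).

## Respirometry

Paired light/dark incubations in ~130-ml jars with a shared ~270-ml
blank are read at 0, 10 and 30 min. Rates are computed per window
(0–10, 10–30 min), blank-corrected by volume, normalized by wet mass,
averaged across the two windows and converted to per-hour. Only the
blank's drift matters, not its absolute O₂ level. `GPP = NPP + R`;
carbon assimilation uses fixed photosynthetic and respiratory
quotients of 1 (exposed in config for sensitivity analysis only) and
the species dry:wet ratio. Records from days whose ambient photon flux
reached 971 µmol photons m⁻² s⁻¹ — the level at which in situ
photoinhibition depresses O₂ production in these kelps — are excluded
before averaging, with a logged count.

## The CSP model and its uncertainty

`CSP(t) = N·CE·(1 − tD)`, clamped at zero beyond `t = 1/D`: a carbon
pool cannot be negative, and the decay is linear by construction. Two
uncertainty rules propagate errors everywhere: the variance sum law
for sums of means, and Goodman's exact variance for the product of two
independent means (95 % CI half-width `z·√(SE_A²SE_B² + SE_A²B² +
SE_B²A²)`, `z = 1.959964`). The decay factor carries no error into the
CSP interval — the interval reflects density and export uncertainty
only — while decomposition uncertainty surfaces through the
delta-method SE of the time to zero, `SE(1/D) = SE_D/D²`. Times to
zero are reported as whole days. The cross-species sequestration
horizon defaults to `t = 50` days, the age at which all three species
still hold part of their exported carbon.

## Range projection

Yearly minimum (February), mean and maximum (August) SST are smoothed
with a hand-written tricube-weighted **local quadratic** (span 1)
evaluated at each year. A local linear smoother would bias curvature
and cannot reproduce a quadratic trend exactly, which the degree-2
local fit does by construction; with span 1 the smoother is still
exact on polynomials up to degree 2 while damping noise. Densities
then scale linearly between thermal anchors: cold species with August
SST toward the upper growth limit `T_U`, the warm species with
February SST from the gametophyte-fertility threshold `T_L = 9.53 °C`
(the maximum SST when it first established locally), both anchored at
the 2016 reference year and floored at zero. The warm species is
capped at the total 2016 lower-band density because it cannot tolerate
the emersion stress of the upper zone. Cold species are **not** capped
by default: their density model must scale above the 2016 value in the
cooler past, otherwise the historical forest trajectory cannot decline
— the warm species' arrival would only ever add carbon. A `cap_cold`
option restores a no-re-expansion ceiling for scenario exploration.
`T_U` has no library default; it is a required configuration input
read off the species' thermal-tolerance curve (the generator's truth
configuration uses 19.0 °C). Decline rates are geometric-mean annual
percentage changes over a window.

## Detrital assimilation

The photosynthesis–irradiance curve is `PE(x) = 1.8·tanh(0.006x/1.8)`
and ambient light decays as `PAR_D(x) = e^(−kx+a)` (annual pair
k = 0.15 m⁻¹, a = 5.05, applied from 0 m). The GPP rescaling factor is
reconstructed from its two stated components as

    P_GPP(t) = [1 − PE(PAR_F)/PE(PAR_L)] · PE(PAR_D(depth(t)))/PE(PAR_L)

— the unused excess capacity at the dim field site (PAR_F = 0.54,
PAR_L = 50.4 µmol photons m⁻² s⁻¹) times the proportion of laboratory
production achievable at the current depth. The source's printed
formula is typographically garbled; this reconstruction follows its
prose description and should be treated with corresponding caution.
The depth factor is capped at 1 where ambient light exceeds the
laboratory level: excess production in a brighter milieu is
conservatively assumed unable to photosynthesise. Detritus travels a
straight sloped path from forest edge to sink (default travel time
50 days; sink depth and distance are required inputs with no invented
defaults — the analysis drivers use 30 m and 4 km, a Plymouth-Sound-
scale geometry). Daylight hours default to astronomical day lengths at
latitude 50.36 °N; only the annual attenuation pair is empirically
anchored, so seasonal pairs are configuration inputs.

## Synthetic data generator

The generator emulates the field designs — 10 plants/species/month
with three punched holes, 43 litterbags across both deployments, 42
light/dark incubation pairs, 27 biochemistry samples per species over
ages 0/13/25/32 d, quadrat density surveys in 5 months — with truths
set to the study system's reported levels (decomposition 0.93/0.60/
1.54 % day⁻¹; net assimilation 0.98/0.76 mg C g⁻¹ h⁻¹ with the warm
species declining at 0.03 mg C g⁻¹ h⁻¹ day⁻¹ from 0.60, so net and
gross production fail at 20 and 36 days; phenolics 0.11/1.07(trend)/
0.16 %; common C:N rate 0.005 day⁻¹; water content 85.11/84.40/
87.32 %). SST trajectories are piecewise-linear ramps plus small
Gaussian noise, crossing the fertility threshold in the mid-1940s and
approaching the cold upper limit late-century under the harshest
scenario, ordered RCP2.6 < RCP6.0 < RCP8.5.

Noise families (the sources state none): lognormal with mean 1 for
plant-level export (σ = 0.4) and litterbag mass retention (σ = 0.30) —
positive and right-skewed, as masses are; Gaussian elsewhere —
1 µmol L⁻¹ per O₂ reading (typical optode precision),
0.3 mg C g⁻¹ h⁻¹ sample-level assimilation spread (matching the
reported SE at n = 42), 2.5 % relative analytical spread on C and N
(CHN-analyser replicate precision on homogenized powder), 0.05 % on
phenolics. What the generator does **not** emulate: substratum and
site effects between litterbag experiments (its single per-species
rate understates the real cross-experiment spread), mesh-bag random
effects, seasonal covariance between density and export,
plant-to-plant biochemical variation beyond analytical noise, and any
spatial structure. Passing recovery tests therefore shows the
estimators are unbiased and correctly propagate error under the
assumed structure — not that the field data satisfy that structure.

## Numerical choices and problem sizes

Month lengths use the record's actual calendar year. Ties in the
carbon-fraction match resolve to the earliest nearest date. The LOESS
weight floor (1e-12 within the bandwidth) guards degenerate weight
matrices; `lstsq` handles rank deficiency. CSP curves are evaluated on
whole-day grids to 180 d; projections run 1850–2100 at annual
resolution; assimilation sums run to the 50-day travel time. The test
suite's Monte-Carlo oracle for the product-of-means CI uses 10⁶ draws
(agreement within 1 %). Simulated designs match the field sample
sizes throughout, which keeps the full pipeline run to a few seconds.

## Known limitations

Linear decay overestimates long-term decomposition of the slowest
species (exponential decay fits old detritus better), the projection
treats densities as instantaneous functions of temperature with no
demographic lag, dislodgement and dissolved export are excluded (the
erosion-based export is deliberately conservative), and the
assimilation model ignores hydrodynamics — detritus neither floats nor
strays from the straight sinking path.
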