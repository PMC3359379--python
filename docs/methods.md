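# Methods

## Model

A single leaf layer carries a fixed area-based functional nitrogen budget
`FNA_a = FNC_m * LMA`, where `FNC_m` is plant functional nitrogen per gram
of leaf (total leaf N minus structural N, fixed at 0.001 g N g⁻¹ biomass
when derived). The budget pays for five pools. Three of them produce
photosynthetic capacity through linear nitrogen use efficiencies:

- carboxylation: `Vcmax25 = nue_cb * N_cb`
- electron transport: `Jmax25 = nue_et * N_et`
- light capture: chlorophyll `Chl = chl_per_n * N_lc` sets leaf
  absorptance by Beer's law, `alpha = alpha_max * (1 - exp(-Chl/chl_half))`,
  and the light-driven electron flux is `phi_e * PAR * alpha`.

The other two are sized by demand rules:

- **storage** holds the nitrogen needed to sustain the current growth rate
  for `D_ns` days with zero uptake: whole-plant demand
  `S = max(A_net, 0) / carbon_frac * N_new * D_ns`, of which the leaf
  budget is charged the share `f_s`. New-tissue nitrogen blends leaf and
  non-leaf tissue through the carbon partitioning fraction,
  `N_new = leaf_n * (f_cleaf + (1 - f_cleaf) * nonleaf_n_ratio)`.
- **respiration** holds the mitochondrial enzyme nitrogen whose capacity
  (at 25 °C, Q10 = 2) covers maintenance plus growth respiration at every
  time of day; the leaf budget is charged the share `f_r`. Maintenance
  respiration is proportional to the *total* functional nitrogen
  supported — photosynthetic pools plus the whole storage and respiratory
  pools — so storage is not metabolically free. This coupling also makes
  the likelihood separate `D_ns` (which inflates total storage and hence
  maintenance cost) from `f_s` (which only reweights the budget), leaving
  the two parameters weakly rather than perfectly confounded.

Daily carbon balance: the co-limited net-of-photorespiration rate `A`
holds over the photoperiod; maintenance respiration runs day and night at
the respective temperatures; growth respiration takes the fraction
`growth_resp_frac` of the positive surplus. Net gain
`A_net = (1 - g)(A_gross - R_maint)` feeds the storage demand.

**Optimality / solution.** Co-limitation (equal Rubisco-, electron- and
light-limited rates) makes each photosynthetic pool a closed-form,
strictly increasing function of the common rate `A`; with maintenance
proportional to total functional N, the support pools are a linear fixed
point in `A` with a closed-form solution on each branch of the
net-assimilation clamp. Total demand minus budget is therefore a strictly
increasing scalar function of `A`, bracketed between zero and the
light-capture asymptote `phi_e * PAR * alpha_max * (Ci - G*)/(4Ci + 8G*)`,
and solved by Brent's method (xtol 1e-14; conservation of the budget holds
to ~1e-10 relative). The result coincides with the constrained maximiser
of photosynthesis over the nitrogen simplex, which the test suite verifies
against an independent nested grid search. Degenerate inputs (zero
budget, zero light, Ci at or below the compensation point) return a
flagged all-storage allocation with zero capacities rather than raising,
so calibration likelihoods stay finite. A budget so large that even the
absorptance asymptote cannot exhaust it raises an explicit convergence
error with diagnostics.

## Photosynthesis core

Rates follow the standard C3 forms: gross Rubisco-limited carboxylation
`Wc = Vcmax(T) Ci / (Ci + Kc(1 + O/Ko))` and electron-transport-limited
`Wj = J (Ci - G*) / (4Ci + 8G*)`; for co-limitation both pathways are
compared net of photorespiration (`Ac = Vcmax(T)(Ci - G*)/(Ci + Km)`).
Realised electron transport is the strict minimum of light flux and
`Jmax(T)`; a non-rectangular-hyperbola smoothing is exposed as an option
but off by default because the allocation solver enforces co-limitation
upstream.

Kinetics default to the Collatz C3 convention: `Kc25 = 30 Pa` (Q10 2.1),
`Ko25 = 30 kPa` (Q10 1.2), `G*` from specificity `tau25 = 2600`
(Q10 0.57, i.e. `G*` itself has Q10 1/0.57), `O = 21 kPa`; Vcmax-type
rates use Q10 2.4 with a logistic high-temperature inhibition
(slope 0.3 °C⁻¹, half-point 40 °C), Jmax Q10 2.0, respiration Q10 2.0.
Every response is normalised by its value at 25 °C so scaling at the
reference temperature is exactly the identity; the inhibition term is
normalised likewise (a deliberate, percent-level reformulation of the raw
logistic). `standardize_capacity` converts reported Vcmax25/Jmax25 from a
stated foreign convention into the Collatz convention by equating the
limiting rates at the measurement temperature and a fixed evaluation
point (Ci = 25 Pa); it refuses to run when the reported convention is not
given.

Intercellular CO₂ uses a constant-ratio closure `Ci = ci_ratio * Ca`
(default 0.7) with ppm → Pa at standard pressure 101.325 kPa; relative
humidity is carried as configuration metadata for provenance but does not
enter the default closure (no stomatal model, no leaf energy balance —
leaf temperature equals air temperature).

## Parameter defaults

| parameter | default | units | basis |
|---|---|---|---|
| `nue_cb` | 128 | µmol CO₂ g⁻¹ N s⁻¹ | Rubisco specific activity ~20.5 µmol g⁻¹ s⁻¹, 16 % N |
| `nue_et` | 420 | µmol e⁻ g⁻¹ N s⁻¹ | bioenergetics pool ~¼ of photosynthetic N at Jmax/Vcmax ≈ 1.9 |
| `nue_resp` | 30 | µmol CO₂ g⁻¹ N s⁻¹ | mitochondrial N a few % of leaf N at typical dark respiration |
| `chl_per_n` | 1.8 | mmol Chl g⁻¹ N | ~39 mol N per mol Chl in chlorophyll-protein complexes |
| `chl_half` | 0.11 | mmol m⁻² | Beer-law scale matching hyperbolic absorptance half-saturation |
| `alpha_max` | 0.85 | – | canonical maximal leaf PAR absorptance |
| `phi_e` | 0.22 | e⁻ per absorbed photon | realised operating-point yield (≈ 4 × realised CO₂ quantum yields of 0.05–0.06) |
| `maint_resp_coeff` | 0.5 | µmol CO₂ g⁻¹ N s⁻¹ at 25 °C | leaf dark respiration ~1 µmol m⁻² s⁻¹ per ~2 g functional N |
| `growth_resp_frac` | 0.25 | g C per g C | classical growth-respiration coefficient |
| `nonleaf_n_ratio` | 0.25 | – | non-leaf new tissue at ¼ of leaf N concentration |
| `carbon_frac` | 0.5 | g C g⁻¹ biomass | standard biomass carbon content |
| `f_r` | 0.5 | – | middle of the 0.4–0.6 sensitivity range |
| `structural_n` | 0.001 | g N g⁻¹ biomass | woody-tissue C:N floor |

Absolute predicted capacities scale with the NUE constants; the
acclimation percentages (the quantities the factorial experiment reports)
are robust to moderate rescaling because they compare solutions that share
the same constants. `phi_e` is the one light-chain constant the relative
radiation response is sensitive to: it sets how close the required
absorptance sits to `alpha_max`, hence how steeply light-capture nitrogen
rises when radiation is halved. The sensitivity-analysis environment uses
a 14-hour photoperiod and equal day/night temperature at the stated
growing temperature.

## Calibration

`(D_ns, f_s)` are sampled by single-chain Gaussian random-walk
Metropolis–Hastings under uniform priors (`f_s` ∈ [0, 1], `D_ns` ∈
[0, 365] days — a year of storage as a physical ceiling). The residual
model is homoscedastic Gaussian on standardized Vcmax25 with the variance
profiled at its conditional MLE per evaluation (a fixed sigma can be
supplied instead, under which the log likelihood is exactly additive per
record). Proposal scales adapt multiplicatively toward 30 % acceptance
during the burn-in only (default 20 % of 50 000 iterations) and are frozen
afterwards; a post-adaptation acceptance rate outside [0.05, 0.7] logs a
warning, not an error. Chains are bit-reproducible for a given seed. A
two-seed Gelman–Rubin diagnostic is provided; no further multi-chain
machinery. Only Vcmax is fitted; Jmax observations are held out.

## Synthetic data

The generator sweeps leaf N linearly across a configurable range (default
0.01–0.03 g g⁻¹, 12 points), runs the forward model at known
`(D_ns, f_s)`, and multiplies Vcmax25/Jmax25 by lognormal noise
`exp(N(0, noise_sd²))` (default 5 %) so observations stay positive and
errors are relative. It emulates the calibration's statistical
assumptions exactly — independent multiplicative errors around a
noise-free monotone curve. It does **not** emulate leaf-age or
canopy-position covariance, measurement-temperature scatter, or model
misspecification, so parameter-recovery results certify the sampler and
the identifiability structure, not field performance.

## Numerical choices

- ppm → Pa at 101.325 kPa; µmol CO₂ → g C via 12 × 10⁻⁶ g µmol⁻¹; all
  conversions centralized in `constants.py`.
- Root bracketing on `[0, a_max(1 - 1e-12)]`; Brent xtol 1e-14.
- Profiled residual variance floored at 1e-12 to keep the log likelihood
  finite for perfect fits.
- Degenerate solves are flagged, never raised, inside likelihoods.
- Deterministic row ordering in factorial outputs; percent changes
  reported to one decimal.

## Known limitations

- One leaf layer; no canopy integration, no within-canopy N
  redistribution, and LMA is an input (no prognostic LMA or optimal-LMA
  derivation).
- No stomatal conductance model (fixed Ci/Ca), no C4 pathway, no leaf
  energy balance, no soil nitrogen-uptake costs.
- Storage lumps everything that is not structural, photosynthetic or
  respiratory nitrogen (including defence enzymes), so predicted storage
  fractions can exceed what direct assays would call "storage".
- The published trait table pairs the deciduous column with `f_s = 0.86`,
  `D_ns = 85` while the accompanying text assigns storage durations of
  50/85/4 days to deciduous/evergreen/herbaceous plants — an apparent
  label swap in the source. The packaged fixtures follow the table as
  printed; swap the columns yourself if you prefer the text's reading.
- Complete and instantaneous acclimation is assumed; real plants may take
  seasons to re-balance pools, and may never reach the optimum.
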