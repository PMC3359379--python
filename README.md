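# leafalloc

Mechanistic modelling of leaf nitrogen allocation and photosynthetic
acclimation.

Most terrestrial biosphere models prescribe a fixed relationship between
leaf nitrogen content and photosynthetic capacity (V<sub>c,max</sub>). In
reality that relationship shifts with growing-season temperature, CO₂
concentration and light, because plants re-partition nitrogen among
competing functions. `leafalloc` implements a complete nitrogen-allocation
model for a single leaf layer: the area-based functional nitrogen budget
FNA<sub>a</sub> = FNC<sub>m</sub> · LMA is divided among **storage**,
**respiration**, **light capture**, **electron transport** and
**carboxylation** so that, simultaneously,

1. storage nitrogen equals the demand implied by the daily net
   assimilation rate A<sub>net</sub>, the nitrogen concentration of new
   tissue, and the storage duration D<sub>ns</sub> (leaf share f<sub>s</sub>):
   N<sub>store</sub> = f<sub>s</sub> · A<sub>net</sub> · N<sub>new</sub> · D<sub>ns</sub>;
2. respiratory enzyme nitrogen equals the demand from maintenance plus
   growth respiration at the prevailing temperatures (leaf share f<sub>r</sub>);
3. the Rubisco-limited, electron-transport-limited and
   light-capture-limited carboxylation rates are equal (co-limitation),
   which maximises photosynthesis per unit nitrogen:

   W<sub>c</sub> = V<sub>c,max</sub>(T)·C<sub>i</sub>/(C<sub>i</sub>+K<sub>c</sub>(1+O/K<sub>o</sub>)),  W<sub>j</sub> = J·(C<sub>i</sub>−Γ\*)/(4C<sub>i</sub>+8Γ\*),
   with J the minimum of the chlorophyll-absorbed light flux and
   J<sub>max</sub>(T).

Capacities follow linearly from the pools via nitrogen use efficiencies
(V<sub>c,max25</sub> = nue<sub>cb</sub>·N<sub>cb</sub>, J<sub>max25</sub> =
nue<sub>et</sub>·N<sub>et</sub>, Beer-law absorptance in chlorophyll for
light capture). All kinetics use the Collatz C3 convention with
Q10-style temperature responses, and reported capacities can be
standardized to that convention at 25 °C. The two strategy parameters
(D<sub>ns</sub>, f<sub>s</sub>) are calibrated to observed
V<sub>c,max25</sub>–leaf N data with a random-walk Metropolis–Hastings
sampler under uniform priors.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Solve the allocation for the built-in generic evergreen tree (LMA 85 g m⁻²,
leaf N 0.015 g g⁻¹, f<sub>s</sub> 0.5, D<sub>ns</sub> 50 d) in the control
environment (15 °C, PAR 800 µmol photon m⁻² s⁻¹, 370 ppm):

```bash
leafalloc allocate --config table3_evergreen --out evergreen.csv
```

```
Leaf nitrogen allocation solution
=================================
functional N budget FNA_a :     1.1900 g N m-2
total functional N (plant):     1.9669 g N m-2

pool            g N m-2   fraction
storage           0.7166     0.6022
respiration       0.0603     0.0507
light capture     0.0144     0.0121
electron transp   0.1499     0.1260
carboxylation     0.2487     0.2090

Vcmax25 :    31.83 umol CO2 m-2 s-1
Jmax25  :    62.97 umol e- m-2 s-1
A (day) :     6.11 umol CO2 m-2 s-1 (co-limited, net)
net gain:    2.389 g C m-2 d-1
```

The evergreen strategy (long storage duration) parks 60 % of the budget in
storage; the remaining nitrogen yields a modest V<sub>c,max25</sub> of
32 µmol m⁻² s⁻¹, with the three photosynthetic pools sized so the three
limiting rates coincide at 6.1 µmol CO₂ m⁻² s⁻¹.

Calibration recovers the storage strategy from data. A synthetic set
generated at (D<sub>ns</sub>=50, f<sub>s</sub>=0.5) with 5 % noise and
fitted with 8000 MH iterations prints

```
parameter                              mean (sd)
Proportion of storage N to leaf (f_s)  0.389 (0.158)
Nitrogen storage duration (D_ns, d)    81.3 (34.7)
acceptance rate: 0.305   iterations: 8000   seed: 1
```

with 90 % credible intervals D<sub>ns</sub> ∈ (34, 140) and
f<sub>s</sub> ∈ (0.22, 0.68) covering the truth — the two parameters are
only weakly separable (they act mainly through the product
f<sub>s</sub>·D<sub>ns</sub>), which the wide, strongly correlated
posterior reflects.

Python API (statsmodels-style):

```python
from leafalloc import LeafNitrogenModel, VcmaxCalibration, ChainConfig
from leafalloc.experiments import table3_traits, sensitivity_control_env

sol = LeafNitrogenModel(table3_traits()["evergreen"],
                        sensitivity_control_env()).solve()
print(sol.summary())          # pools, fractions, Vcmax25/Jmax25
result = VcmaxCalibration(obs).fit(ChainConfig(seed=1))
print(result.summary())       # posterior mean (sd) per parameter
```

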