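# reefbudget

Census-based carbonate budgets for coral reefs: from transect-level field
records to site net carbonate production, kriged production surfaces,
potential vertical reef growth, and Bayesian estimates of the live-coral-cover
value below which a reef erodes faster than it builds.

The package is written for reef ecologists and carbonate-budget modellers
working with stratified line-intercept surveys of the kind run on Palau and
Yap (western Pacific): sites stratified by habitat (outer west/east, patch,
inner), six 10 m contour-following benthic transects per site with paired
horizontal rugosity lines, six 30 m x 4 m parrotfish video transects, and six
10 m x 0.6 m echinoid belts.

## The model

Net carbonate production at a site (kg CaCO₃ m⁻² y⁻¹) is

```
net = Cal + sgn·Sed − (parrotfish + urchin + macroboring)
```

with gross calcification from the benthic census,

```
Cal = r · { Σⱼ mⱼ·(xⱼ/100)·dⱼ·gⱼ·10 + 0.018·pca·10 }
```

where `r` is the rugosity index (contour/horizontal tape length), `xⱼ` the
percent planar cover of coral taxon `j`, `mⱼ` a morphological surface
coefficient, `dⱼ` skeletal density (g cm⁻³), `gⱼ` vertical extension
(cm y⁻¹), and `pca` percent coralline-algae cover. Bioerosion is allometric:
parrotfish erode `vol(L)·sp(L)·br(L,brc)·D·365·0.001` per fish (bite volume,
scar proportion and bite rate as functions of fork length `L`), echinoids
erode `c·diam^k·0.365·0.57` per individual (genus-specific `c, k`), and
macroborers erode `plamc·10` for borer cover fraction `plamc`. The sediment
term contributes at most +0.4. Production converts to potential vertical
growth via `v = Cp + Cp·(Cp·α)` (mm y⁻¹), compared against RCP
sea-level-rise rates.

The *inverse problem* — the live coral cover `LCC*` at which expected net
production turns negative per habitat — is estimated with a Bayesian
additive mixed model

```
G = β₀ + f(LCC) + Habitatₕ + a_country + ε
```

with an O'Sullivan penalized cubic spline `f` (five interior knots),
diffuse priors, and a blocked Gibbs sampler; each habitat's expected curve
is solved for its zero crossing per posterior draw, giving a median and 95%
credible interval.

Site production is interpolated spatially by ordinary kriging on a fitted
semivariogram (spherical/exponential/Gaussian, weighted least squares or
Gaussian maximum likelihood), with a directional-semivariogram anisotropy
check.

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
two-island campaign whose ground-truth budgets are known in closed form:

```
$ python analysis/01_simulate_surveys.py --seed 1
simulated 48 sites x 6 transects (seed 1): 1347 parrotfish, 277 urchins
true net production: mean 11.75, range 2.76-25.03 kg CaCO3 m-2 y-1

$ python analysis/02_compute_budgets.py
engine vs closed-form ground truth: max |delta net| = 1.07e-14
48 site budgets: net 11.75 kg CaCO3 m-2 y-1 on average (gross 11.55,
erosion 0.197); 0 sites in net erosion

$ python analysis/03_summarize_habitats.py     # per-habitat means and CIs
$ python analysis/04_krige_surfaces.py         # variograms + kriged maps
$ python analysis/05_fit_threshold_model.py    # LCC* per habitat with 95% CrI
$ python analysis/06_vertical_growth.py
calibrated alpha = -0.01913 (kg m-2 y-1)^-1 from 1 conversion pair(s)
at the peak-site production of 20 kg CaCO3 m-2 y-1: 12.35 mm y-1 potential
vertical growth
  RCP2.6 (5.0 mm y-1): keeps up (margin +4.1 mm y-1; 88% of sites keep up)
  RCP8.5 (9.0 mm y-1): keeps up (margin +0.1 mm y-1; 46% of sites keep up)
```

The `max |delta net| = 1.07e-14` line is the dual-route check: the budget
engine, fed the survey CSVs through the validated ingest path, reproduces
the generator's independent closed-form arithmetic to machine precision.
The 12.35 mm y⁻¹ figure is the vertical-growth conversion evaluated at the
most productive sites' rate of 20 kg CaCO₃ m⁻² y⁻¹, with α calibrated from
the island-wide pair (9.7 kg CaCO₃ m⁻² y⁻¹ ↔ 7.9 mm y⁻¹); it says such
sites could outpace even the RCP 8.5 sea-level-rise projection, while an
average site (margin +0.1 mm y⁻¹ under RCP 8.5) sits at the knife's edge.

Programmatic use mirrors the scripts:

```python
from reefbudget import (generate_survey_dataset, palau_yap_scenario,
                        default_trait_table, budget_table,
                        summarize_by_habitat)

ds, truth = generate_survey_dataset(palau_yap_scenario(seed=1))
budgets = budget_table(ds, default_trait_table())
print(summarize_by_habitat(budgets).round(2))
```

Field data is ingested from five CSV schemas (`benthic.csv`, `fish.csv`,
`urchins.csv`, `sites.csv`, `rugosity.csv`; see `reefbudget.survey`) plus a
taxon-trait table (`traits.csv`). The shipped trait defaults are
literature-typical values for the synthetic community, not laboratory
measurements; supply your own table for real surveys. Archived raw survey
data exported to these schemas under `data/field/` enables the field-data
checks in the test suite.

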