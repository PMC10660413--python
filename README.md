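# scatniche

Scat-based dietary-niche and physiological-stress analysis for a
subordinate large carnivore living along a competition gradient with a
dominant one — the tiger–leopard system of a two-part tiger reserve, where
one side holds nearly all the tigers and the other effectively none, and
where systematic faecal sampling was repeated five years apart. The package
turns per-scat records (identified prey remains, percent inorganic matter
from ashing, faecal glucocorticoid and triiodothyronine metabolite
concentrations) plus NDVI rasters into the study's full analysis chain:

* **Diet composition** — per-group relative frequency of occurrence
  A = i/j·100 (i = scats containing a species, j = total occurrences),
  digestibility-corrected relative biomass D = A·Y / Σ(A·Y)·100 with
  Y = 1.980 + 0.035·X (X = mean prey body weight, kg), and absolute
  frequency of occurrence s_k·100/n by body-size class
  (large ≥ 60 kg, medium 16–60 kg, small < 16 kg).
* **Sampling sufficiency** — sample-based rarefaction of the Shannon index
  H = −Σ p ln p, with a plateau criterion.
* **Classical tests**, implemented from first principles — Pearson χ²,
  two-sided Fisher's exact by hypergeometric enumeration, one-way ANOVA
  with Tukey–Kramer HSD (own studentized-range CDF by Gauss–Legendre
  quadrature), paired t, the extra-sum-of-squares F test for slope
  equality, and simple OLS.
* **Hormone inference** — gamma GLM with log link fitted by IRLS
  (log μ = Xβ; Pearson dispersion; t tests on n−p df), scaled-deviance F
  likelihood-ratio comparison of nested models, and all-pairs group
  contrasts with single-step multivariate-normal adjustment
  (p_adj = P(max|Z| ≥ |z|), Monte Carlo with fixed seed).
* **Habitat productivity** — 3×3 km grids and 2 km scat buffers, mean-NDVI
  zonal statistics on ESRI ASCII rasters (pixel-centre inclusion rule),
  zone-level ANOVA/Tukey and year-to-year paired t tests.
* **Assay QC** — parallelism (logit percent-bound vs log dose slope
  equality), spiked-recovery accuracy and intra/inter-assay CV.
* **Synthetic data** — seeded generators reproducing the study's structure
  (group sizes 86/76/53/89 identified scats of 92/81/60/91 confirmed;
  121 of 324 scats at ≥ 80% inorganic matter; published RFO profiles as
  occurrence probabilities; published coefficient sign patterns), since the
  raw field data are not publicly deposited.

## Worked example

Reproducing one published diet-table cell — the relative biomass of Sambar
(X = 185 kg) in the western-sector 2020 group from that group's printed
RFO column:

```python
from scatniche import PreyReference
from scatniche.diet import GroupDietSummary, compute_biomass, round_half_up
from scatniche.synth import GROUP_RFO_PCT, default_prey_reference

summary = GroupDietSummary("WRTR_2020", n_samples=89)
summary.rfo_pct = dict(GROUP_RFO_PCT["WRTR_2020"])   # printed RFO column (%)
compute_biomass(summary, default_prey_reference())
print(round_half_up(summary.biomass_pct["Sambar"], 2))
print(round_half_up(summary.ackerman_y["Sambar"], 2))
```

prints

```
48.39
8.46
```

i.e. Sambar accounts for 48.39% of consumed biomass in that group, and each
collectable faeces from a Sambar kill represents Y = 1.980 + 0.035·185 ≈
8.46 kg of prey consumed.

The full pipeline runs from a shell on synthetic inputs:

```
scatniche run --out results/ --seed 3
scatniche report --out results/
```

which prints, among other lines,

```
ft3m: Area x Year LRT F(3, 199) = 91.07, p = 0.0000
NDVI 2015: F(2, 279) = 89.78, p = 0.0000
NDVI WRTR 2015 vs 2020: t(134) = 12.90, p = 2.95e-25
```

— the nutritional-hormone model is selected over the null, the three
habitat zones differ in mean NDVI (282 grid cells, hence df (2, 279)), and
the western zone's 135 matched cells improved between years (df 134).
`scatniche show-defaults` prints every configurable threshold and seed.

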