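# litterlab

Statistics for reciprocal litter-transplant decomposition experiments and
untargeted litter metabolomics, built around a Mediterranean-forest rain
exclusion study design: three forests (dominated by *Quercus ilex*,
*Quercus pubescens* and *Pinus halepensis*), each with a natural-drought
(ND) control plot and an amplified-drought (AD) rain-exclusion plot, with
litter of all three species transplanted into every forest x treatment
combination and retrieved after 12 and 24 months.

The package is aimed at ecologists analysing litterbag mass-loss data and
LC-MS litter metabolomes. It provides:

- **Home-field advantage (HFA).** For decomposition measure D(species,
  forest) — mass-loss % here — and species i, j, k with home forests I, J, K:

      HDD_i = (D_iI − D_jI) + (D_iI − D_kI)
      ADD_i = (D_iJ − D_jJ) + (D_iK − D_kK)
      H     = (HDD_i + HDD_j + HDD_k) / (N − 1)
      ADH_i = HDD_i − ADD_i − H

  ADH_i > 0 means species i's litter decomposes faster at home than away
  (HFA); ADH_i < 0 is a home-field disadvantage. Replicate ADH values come
  from repeated one-bag-per-cell draws (12 by default, bags consumed
  without replacement), tested against zero with a one-sample Student t.
- **Factorial mass-loss models.** OLS on the five design factors and their
  interactions, bidirectional stepwise AIC selection with marginality
  enforced, and sequential (Type-I) ANOVA tables reporting %SS per term.
- **LC-MS feature-matrix post-processing.** Blank S/N filter (default 10),
  pooled-QC CV filter (default 0.3), and a co-elution redundancy filter
  (Pearson r ≥ 0.9 within 0.05 min, keep the most intense member), followed
  by ln(x+1)/autoscaling, PCA, PERMANOVA (pseudo-F on Euclidean distances,
  permutation p-value), and PLS-DA VIP ranking.
- **Formula dereplication.** Exhaustive CHO molecular-formula enumeration
  within a ppm window for the common negative/positive-mode adducts
  ([M−H]−, [M+HCOO]−, [M−2H]2−, [M+H]+, [M+Na]+), with RDBE plausibility
  filtering.
- **Calibrated synthetic data.** A cell-mean table solved as an
  equality-constrained least-squares problem so that published summary
  statistics (forest means, the ND−AD gap, per-species ADH) hold exactly,
  plus seeded generators for litterbag datasets, initial-trait samples, and
  feature matrices with planted ground truth.

## Worked example

```python
from litterlab import calibrate_cell_means, generate_litterbags, hfa_analysis
from litterlab.hfa import hfa_results_to_frame
from litterlab.synthetic import LitterSimConfig

table = calibrate_cell_means()            # residual norm ~2.6e-14
records = generate_litterbags(LitterSimConfig(cell_means=table), seed=42)
results = hfa_analysis(records, n_draws=12, seed=42)
print(hfa_results_to_frame(results).round(2))
```

For the natural-drought plots after two years this prints (seed 42):

```
treatment  time_months     species   HDD   ADD     H   ADH  t_value  p_value  n_draws
       ND           24       Qilex  3.13 -8.25 11.05  0.34     0.04     0.97       12
       ND           24  Qpubescens -5.49 -6.99 11.05 -9.54    -7.46     0.00       12
       ND           24 Phalepensis 24.44 -6.85 11.05 20.25    10.05     0.00       12
```

A strongly positive ADH for *P. halepensis* (home-field advantage: pine
needles need their specialised home decomposers), a negative one for
*Q. pubescens* (home-field disadvantage), and none for *Q. ilex*, echoing
the calibrated +18.48, −10.10 and −0.30 under sampling noise. The `examples/` directory holds one short
script per capability (HFA, mass-loss modelling, metabolomics pipeline,
formula annotation); each prints its results with a line of interpretation.

A thin CLI mirrors the library:

```sh
litterlab simulate-litter --seed 1 -o bags.csv
litterlab hfa --input bags.csv --draws 12 --seed 1 -o adh.csv
litterlab metabo filter --matrix features.csv -o filtered.csv
litterlab annotate --mz 615.0987 --adduct "[M-H]-" --ppm 5
```

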