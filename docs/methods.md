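# Methods

## The experimental design being modelled

The package models a reciprocal litter-transplant experiment in three
Mediterranean forests, each dominated by one of *Quercus ilex*,
*Quercus pubescens* or *Pinus halepensis* and each carrying a
natural-drought (ND) control plot and an amplified-drought (AD)
rain-exclusion plot (~30% rainfall reduction). Senescent litter of every
species, collected under both precipitation treatments ("litter type" =
plot of origin), is placed in litterbags (10 g air-dried) in every forest
under both treatments: 3 forests x 3 species x 2 litter types x
2 treatments = 36 modalities, retrieved at 12 and 24 months with 7
replicates — 504 bags. Decomposition per bag is dry-mass loss in percent
of initial mass; remaining mass is its exact complement.

## Home-field advantage (ADH)

With D(s, f) the mean decomposition of species s in forest f within one
(treatment, time) stratum, the home decomposition difference of species i
(home forest I) is HDD_i = (D_iI − D_jI) + (D_iI − D_kI); the away
difference is ADD_i = (D_iJ − D_jJ) + (D_iK − D_kK); the total
H = Σ HDD / (N − 1); and the additional decomposition at home is
ADH_i = HDD_i − ADD_i − H. All four are linear in the D table, hence
translation-invariant, and switching D from mass loss to remaining mass
flips every sign.

**Choice of D.** D is mass-loss % by default (a `d_metric` switch gives
remaining mass). Only with mass loss does "ADH > 0 ⇒ faster decomposition
at home" hold sign-consistently; with remaining mass the inequality
inverts. The reported statistics match published ADH tables only under the
mass-loss reading, which is therefore the default.

**Replicate draws and the t-test.** Replicate ADH values are formed by
assembling a 3 x 3 one-bag-per-cell table repeatedly (12 draws by
default) and recomputing ADH. Within each (species x forest) cell the
bags are randomly permuted once and consumed in order, so no bag is
reused while replicates last; with 2 litter types x 7 replicates = 14
bags per cell and 12 draws, the draws are disjoint and therefore
independent, which makes the one-sample two-sided Student t-test of the
draws against zero exactly calibrated (verified: empirical type-I error
0.05 ± 0.02 under a null with no species-by-forest structure). If more
draws are requested than bags exist, later draws resample with
replacement, a warning is issued, and exactness is lost. The t statistic
carries the sign of the draw mean; no multiplicity correction is applied.

## Calibrated cell-mean table

The litterbag generator is anchored to a 36-cell mean mass-loss table
solved from published summary statistics, all of which are linear
functionals of the cells:

- treatment-pooled forest means at 24 months (44.8 / 40.9 / 39.2% for the
  *Q. ilex* / *P. halepensis* / *Q. pubescens* forests);
- the grand-mean ND−AD mass-loss gap at 24 months (4.0 points, read as an
  absolute percentage-point difference, since every related quantity is
  reported in points);
- per-species ADH at every (treatment, time) stratum;
- treatment- and forest-pooled species means at 12 months (65 / 67 / 62%
  remaining mass, converted to mass loss).

The year-1 ND−AD gap is not published; it defaults to 1.5 points (smaller
than year 2, consistent with a treatment effect that grows with exposure)
and is configurable. Published year-2 species-level remaining-mass means
(58/50/49%) are *not* used: under a balanced design they imply a grand
mean (~48% loss) inconsistent with the year-2 forest means (~41.6%), so
the forest means and ADH values take precedence.

The solver minimises the Euclidean distance to a flat per-date baseline
(the mean of the published date-level marginals) subject to the equality
constraints, via the minimum-norm least-squares correction; the constraint
matrix is built by evaluating each functional on the 36 unit basis tables,
which guarantees the constraints used for solving are the same code paths
used for recomputation. The default system (20 constraints, 36 unknowns,
full row rank) is feasible with residual norm ~1e-14; an infeasible set
returns the least-squares compromise, reports the residual norm, and flags
constraints violated by more than 0.01.

**Litterbag noise.** Per-bag mass loss is Normal(cell mean, SD) truncated
to [0, 100] with SD = 4 percentage points by default — large enough that
single experiments are noisy, small enough that ADH effects of the
calibrated size are detectable at n = 7. The litter-origin (litter type)
effect defaults to 0 points, matching a study in which litter origin had
no detectable effect on decomposition; it is configurable for power
studies.

## Initial litter-quality samples

`generate_trait_samples` emulates the initial-quality campaign: 3 species
x 2 litter types x 5 replicates = 30 samples, with each of 15 traits
(C, N, C/N, P, Ca, K, Mg, Na, phenolics, lignin, cellulose,
hemicellulose, water-soluble compounds, water-holding capacity, specific
leaf area) drawn as Normal(published mean, SE·√5) truncated at zero —
i.e. the replicate-level spread implied by the published standard errors.
These tables feed the two-way (litter type x species) ANOVA.

## Mass-loss models

Design matrices use treatment (reference-level) coding with levels in a
fixed canonical order; interactions are products of margin dummies.
Balanced synthetic designs make the coding immaterial for sums of squares.
ANOVA tables are Type-I (sequential) in the declared term order — main
effects first — so the %SS column telescopes to 100 with the residual;
for balanced data the sequential SS are order-free. F-tests are against
the full-model residual mean square.

AIC uses the Gaussian profile-likelihood convention
n·ln(RSS/n) + 2(k+1), counting the variance parameter; only differences
are meaningful, so absolute AIC values are not comparable across
conventions or datasets. Stepwise selection starts from the full scope
(all main effects and two-way interactions by default), applies the
single best add/drop move per iteration, and enforces marginality (an
interaction is never added before its margins nor kept without them).
AIC retains weak spurious terms with non-vanishing probability by
construction (~16% for a 1-df term); the tests therefore assert that
strong true effects are retained and that anything else retained is
negligible, rather than demanding an exactly minimal model.

## LC-MS feature-matrix pipeline

The pipeline starts at the feature matrix (peak picking, retention-time
alignment and gap filling are out of scope). Filters run in a fixed,
order-dependent sequence, each appending a provenance record:

1. **Blank S/N** (default 10): keep a feature iff
   mean(samples)/mean(blanks) ≥ threshold; a zero blank mean counts as
   infinite S/N. Means over columns are used for robustness at n = 5.
2. **Pooled-QC CV** (default 0.3): keep iff sd(pools)/mean(pools) ≤
   threshold with the sample (n−1) standard deviation; a zero pool mean
   removes the feature.
3. **Co-elution redundancy** (r ≥ 0.9 within 0.05 min): features linked
   by retention-time proximity *and* Pearson correlation across sample
   columns are grouped by transitive closure; only the most intense member
   of each group survives (ties broken by lowest feature id). This
   collapses in-source fragments, adducts and isotopologues of one
   compound.

Downstream statistics use ln(x+1)-transformed, per-feature autoscaled
data (zero-variance features dropped). The log base is immaterial after
autoscaling. PCA is the SVD of the centred matrix (scikit-learn). The
PERMANOVA pseudo-F is computed from squared inter-point distances
(SS_total = Σ_{i<j} d²/n; within-group analogues per group), which for
Euclidean distances coincides with the coordinate-space decomposition to
machine precision; the p-value is (1 + #{permuted F ≥ observed F}) /
(1 + n_perm) with seeded label permutations. Note that permutations can
reproduce the observed partition (probability ~0.8% for two balanced
groups of 5), so even infinitely separated groups have an expected
p-value near 0.009, not 1/(1+n_perm). PLS-DA regresses the 0/1 group
indicator on the features (scikit-learn NIPALS-style PLS, 2 components,
no internal rescaling since the data are already autoscaled); VIP_j =
sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a = q_a²·t_aᵀt_a,
which forces mean(VIP²) = 1 exactly.

## Synthetic feature matrices and their ground truth

The generator emulates one litter species analysed in negative mode: two
groups (ND/AD origin) of 5 biological replicates, 3 extraction blanks,
5 pooled-QC injections, 900 features, m/z uniform in [50, 1200], retention
times in a 20-minute gradient. Intensities are lognormal: per-feature
baselines ~ exp(N(10, 1)) and between-sample biological variability
exp(N(0, 1)) — a CV above 100%, typical of specialized metabolites across
field-grown litter, and deliberately large so that shared group effects
cannot push unrelated discriminating features past the redundancy filter's
correlation threshold. Planted classes are mutually disjoint:

- **discriminating** (10%): a log2 effect uniform in [1, 3] with random
  sign applied to the AD group;
- **blank-contaminated** (5%): realised sample/blank mean ratio drawn in
  [1, 8] (clean features: [50, 500]);
- **irreproducible** (5%): pooled-QC log-SD in [0.7, 1.1] (CV 0.8–1.5)
  versus 0.1 for well-behaved features;
- **redundancy clusters** (20 clusters of 3): members share one noise
  profile scaled by fixed multipliers (1, 0.5, 0.25), i.e. exact
  proportionality (r = 1), co-eluting within ±0.01 min around well
  separated cluster centres. The two non-maximal members per cluster are
  the redundant ground truth.

Because spurious r ≥ 0.9 correlations among unplanted co-eluting pairs
would arise by chance (~0.4 expected per matrix at n = 10 samples), the
generator re-draws the retention time of any unplanted feature that
co-elutes (within 0.06 min) with a feature it correlates with at r ≥ 0.85.
This guard makes the planted clusters the *only* redundant groups, so the
redundancy filter's expected output is exact and seed-independent. Real
data offer no such guarantee — genuinely distinct compounds do co-elute
with correlated intensities — so passing the exact-recovery test
demonstrates correctness of the filter logic, not real-world specificity.
The generator also omits retention-time drift, missing values, censoring
at the detection limit, and isotope envelopes.

## Formula dereplication

Monoisotopic masses: C = 12 exactly, H = 1.0078250319, O = 15.9949146221,
Na = 22.98976928; proton 1.00727646688, electron 0.00054857990. (The
hydrogen atom is ~1.5e-8 u lighter than proton + electron — its binding
energy — so identities between the constants hold only to that level.)
Ion m/z includes the electron mass: [M−H]− = M − proton,
[M+HCOO]− = M + 44.99765 + e, [M−2H]2− = (M − 2·proton)/2,
[M+H]+ = M + proton, [M+Na]+ = M + Na − e. Sodium enters only through the
adduct, never the neutral formula.

Enumeration is an exhaustive vectorised grid over C 1–60, H 0–120
(even H only: an even-electron neutral CHO molecule has integer RDBE),
O 0–40, filtered to RDBE = C − H/2 + 1 ≥ 0 and |ppm| within tolerance
(default 5), ranked by absolute ppm. Published dereplication tables print
ppm errors under an unstated calibration/electron convention, so
agreement is asserted within tolerance bands (≤ 2 ppm for deprotonated
ions, ≤ 5 ppm otherwise) rather than digit-for-digit. Isotope-pattern
scoring and MS/MS interpretation are out of scope.

## Problem sizes and numerical choices

The test suite uses 1000-table oracle sweeps for the ADH identity
(tolerance 1e-12), 1000 simulated experiments for the t-test's type-I
error and 1000 permutation runs (199 permutations each) for the PERMANOVA
null rate (both asserted at 0.05 ± 0.02), and 200 replicate experiments
for treatment-gap recovery (±0.5 points) — sizes chosen so Monte-Carlo
error sits well inside each assertion band while the whole suite stays
fast. Truncated-normal sampling is by rejection (means sit far from the
bounds). Constraint solving uses `numpy.linalg.lstsq` on the deviation
from baseline, which yields the exact minimum-norm solution for
consistent systems. Tie-breaks (equal VIP, equal cluster intensity) are
by lexicographic feature id and are deterministic.
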