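# Methods

## Measurement model

A lesion is characterized by five mean-attenuation values (HU): lesion in
the unenhanced, arterial and delayed phases, and a liver reference per
contrast phase defined as the average of exactly two adjacent-parenchyma
ROI means. The portal venous phase may be present in a series but feeds no
index; the package accepts and ignores it with a log notice. ROI means are
computed over elliptic regions with a deterministic pixel-inclusion rule —
a pixel belongs to the ellipse iff its center (integer coordinates, 0-based)
satisfies `((r−cr)/a)² + ((c−cc)/b)² ≤ 1` — so every mean is exactly
reproducible by exhaustive enumeration, which is how the tests verify it.
Profiles are validated to the plausible HU range [−1000, 3000].

Protocol bookkeeping: per lesion and reader, 3 lesion ROIs + 2×2 liver
ROIs = 7; a 129-lesion cohort therefore yields 903 ROIs per reader.

## Index system

CER, LLC, WO_abs, WO_rel and DPAR are ratios ×100. Each is defined only
where its denominator is strictly positive (UE, LIVART, ART−UE, ART, DEL
respectively); since HU can legitimately be ≤ 0, a failed domain rule marks
that index non-evaluable (NaN) instead of dropping the lesion silently.
Downstream statistics exclude non-evaluable values and report the excluded
count. Reporting precision is one decimal; computation is full precision.

The system is scale-invariant (multiplying all five HU by k > 0 changes
nothing), so inversion back to a profile requires anchoring one value; the
package anchors the unenhanced lesion HU. `WO_abs` is redundant given CER
and WO_rel through `WO_abs = WO_rel·(CER+100)/CER`; reconstruction checks
the supplied triple and warns when the residual exceeds a configurable
0.15 band (one printed-rounding step). One published worked example carries
exactly such a benign residual (printed 1.7 vs implied ≈1.8); it is treated
as rounding, not corrected. Dichotomization at 120 is inclusive (≥ 120 is
"high") everywhere.

## Synthetic cohorts

No per-lesion raw data accompany the study, so the generator is
summary-matched by construction — a stand-in, not a reconstruction.

Continuous quantities are drawn from piecewise-linear quantile functions
pinned to the printed group quartiles, with exponential tails whose scale
matches the adjacent interior density (continuous pdf at the junctions).
For DPAR, the response-associated cut 120 lies strictly between printed
quartiles in both groups (CR+ 116 < 120 < 124; CR− 115 < 120 < 123), so
the exceedance probability at 120 cannot be controlled by the tails; it is
pinned instead by an extra interior quantile knot at (1 − exceedance, 120)
with the printed exceedances 41/64 (CR+) and 21/65 (CR−). Population
quartiles, median and exceedance are then all exact by construction.
Diameter samplers (CR+ 14/19/25.5 mm, CR− 16/23/33 mm) clip their lower
exponential tail at 5 mm; the clip only affects the extreme tail, never
the quartiles.

In `exact_counts` mode (n = 129 only, since the printed joint table is for
129 lesions) the (DPAR ≥ 120) × margins × CR cell counts are reproduced
verbatim — (33, 26 CR), (29, 15), (25, 12), (42, 11) — and each lesion's
continuous DPAR is drawn from its CR group's sampler truncated to the
correct side of 120 (inverse-CDF restricted to the corresponding quantile
band). The single parametric family cannot satisfy the joint table and the
marginal quartiles simultaneously in-sample; the truncation honors the
counts exactly while the untruncated sampler stays marginally
quartile-exact, which is the compromise the calibration over-constraint
forces. Non-CR lesions receive PR/SD/PD in the exact 53:7:5 mix. `sampled`
mode (any n ≥ 8) draws cells multinomially and CR per cell rate.

Full HU profiles are synthesized by inverting the index system at a
Gaussian unenhanced anchor, mean 55 HU and sigma chosen so the population
MAD is 5 HU — the printed unenhanced-phase dispersion and a typical
baseline for HCC on cirrhosis. CER and WO_rel are drawn through a Gaussian
copula (ρ = 0.8) over their quartile-calibrated marginals: wash-in and
wash-out are physiologically coupled (wash-out is the flip side of arterial
hyper-enhancement), and this dependence is what gives the delayed phase its
intermediate dispersion, reproducing the published phase ordering
MAD(ART) > MAD(DEL) > MAD(UE). With independent draws the delayed phase
would disperse more than the arterial one, which real cohorts do not show.
The two per-phase liver ROI means are split symmetrically around the
reference (±N(0, 2 HU)) so their average is preserved exactly.

The generator deliberately does **not** target the patient-data AUC of
0.80: group quartiles do not determine tail behavior, so the calibrated
samplers' own population concordance is ≈0.70, and the empirical AUC of a
synthetic cohort is checked only against that closed-form value and
against chance — calibrating the generator to the published AUC would make
the ROC validation circular. The same caution applies to the printed
diagnostic parameters at DPAR = 120 (0.72/0.67/0.69/0.70), which are
inconsistent with the published counts (41/64 = 0.64) and are therefore
never used as reference values; the count-derived set is.

Phantoms render the reconstructed profile as liver background plus a
lesion ellipse per phase with additive per-phase Gaussian noise; with zero
noise, ROI extraction over the truth geometry recovers the generating
indices exactly. Default lesion/liver ROI semi-axes of 9 px correspond to
≈1.4 cm² at the default 0.75 mm/px in-plane scale, matching the study's
mean traced areas. The second-reader emulator adds independent Gaussian
noise to every HU measurement and flips margin calls with fixed
probability; the calibrated preset (6.5 HU, 12%) puts downstream ICC and
kappa in the ≈0.8 region reported for real readers. These presets are
qualitative bands, not golden values.

All stochastic operations are reproducible from (seed, parameters); the
default generator seed is 20160101.

## Statistical conventions

* Fisher exact, two-sided: sum of hypergeometric tables with probability
  ≤ observed (scipy's convention; verified against direct enumeration).
* OR CI: Woolf log method, z = 1.96, no continuity correction; RR CI: Katz
  log method (statsmodels `Table2x2`). These reproduce the published
  intervals from the published counts, which is why they were frozen.
  A zero cell requires explicitly enabling the documented 0.5 fallback.
* Mann-Whitney: midrank ties; exact when both n ≤ 8 without cross-group
  ties, else normal approximation with tie and continuity corrections.
* Wilcoxon signed-rank: zero differences excluded, midranks; exact null up
  to 12 nonzero differences.
* ROC: empirical curve over all distinct inclusive cuts with ±∞ endpoint
  sentinels; trapezoid AUC (equal to tie-corrected concordance, hence to
  U/(n₊·n₋)); DeLong 95% CI. The CI method is a package decision — it is
  reported but never compared against published values, since the study
  does not name its method.
* Threshold selection: exhaustive scan over distinct cuts for Youden,
  harmonic-mean and corner-distance criteria; ties break toward the higher
  (more specific) cut; the reported threshold is the midpoint of the gap
  below the selected cut. Consensus is the common cut if all three agree,
  else the Youden cut with all three reported.
* Logistic regression: Newton maximum likelihood (≡ IRLS), tol 1e−10,
  max 100 iterations, Wald CIs; complete separation detected per predictor
  and reported by name. The default covariate set is {DPAR ≥ 120, smooth
  margins}; diameter is optional because per-lesion diameters were never
  published, making that coefficient uncheckable.
* ICC is fixed to ICC(2,1) — two-way random effects, absolute agreement,
  single measurement — the standard form for two human readers each
  measuring every lesion once; the study does not name its form, so this
  choice is documented rather than inferred. The "Cronbach coefficient"
  label is ambiguous between Cronbach's alpha and eta-squared; the package
  computes two-rater Cronbach's alpha, `2(1 − (V₁+V₂)/V(x₁+x₂))`, and
  labels it as such.
* Display: percentages and ORs/RRs to one decimal, coefficients to two,
  p-values to four decimals or `<0.0001`.

## Problem sizes

The test suite runs the full pipeline on the 129-lesion exact-counts
cohort, enumeration-oracle sweeps up to 12 observations per group, 200
phantom replicates for the noise model and a 2000-lesion sampled cohort
for multinomial checks. The acceptance script uses 1000 replicates of
n = 64 for the sampler-median estimate. These sizes give stable estimates
for every assertion made while keeping a full run in minutes on one CPU.

## Limitations

Synthetic cohorts match printed summaries, not patient data: passing tests
demonstrate the pipeline's correctness and internal consistency, not
clinical performance. Margins and mRECIST categories are consumed as given
labels. Analysis is per-lesion; multiple lesions per patient are not
clustered. No DICOM ingestion, inter-phase registration, 3-D ROIs or
survival endpoints.
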