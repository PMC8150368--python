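# Methods

This note documents the models, conventions and numerical choices behind
`oenomics`, and what the synthetic study does and does not establish.

## Chemistry layer

**Masses and envelopes.** Element monoisotopic masses and isotope
abundances are pinned to a bundled IUPAC/CODATA table
(`src/oenomics/data/isotopes.tsv`, CHNOPS) so every derived quantity is
bit-stable across environments; formula strings are parsed with pyteomics.
Theoretical isotope envelopes aggregate isotopologues by nominal mass shift
(A, A+1, A+2) via exact convolution of per-element shift distributions.
Fine structure within a cluster is deliberately not modeled: at QToF
resolving power (~20,000 FWHM) the isotopologues within an A+1 cluster are
unresolved, and the negative-mode metabolites of interest are all < 1 kDa.

**Adducts.** Negative mode only: [M−H]⁻ (−1.007276 Da), [M−2H]⁻
(−2.014553 Da; used for flavylium cations such as malvidin 3-O-glucoside,
which lose two protons to give a singly charged anion), and [M+H₂O−H]⁻
(+17.003289 Da). Electron-mass bookkeeping is folded into the proton
constant; the residual error (< 0.1 mDa) is far below the mass accuracy
modeled anywhere in the pipeline.

**Isotopic fit score.** Vendor isotopic-fit statistics (mSigma) are
proprietary, so the package defines a surrogate with the same conventions:
1000 × the RMS deviation between base-peak-normalized relative intensities,
taken over the non-base peaks of the common prefix of the two envelopes
(capped at A+1, A+2). Zero means a perfect match, and the customary
acceptance thresholds (≤ 50 for targets, < 100 for suspects) remain
meaningful for realistic envelope noise: 5 % relative intensity noise on an
A+1 of 0.3 scores ≈ 10–15, while a decoy envelope with A+1 ≈ 0.5–0.9 scores
several hundred. The scale is a declared convention of this package, not a
claim of equivalence to any vendor's statistic.

## Screening

Criteria are strictly conjunctive, and every threshold's strictness is
fixed: mass error and target RT tolerance are strict (<), area, intensity
and peak score are strict (>), the isotopic fit bound is inclusive (≤), and
the suspect RT window is inclusive (≤ 1.8 min). MS/MS qualifier fragments
match within 10 mDa — wider than the 5-mDa precursor tolerance because
broadband-CID fragments are acquired at lower intensity. When several
features qualify for one compound in one sample, the smallest |mass error|
wins, ties broken by |RT error| and then by larger area (the literature is
silent here; this rule is deterministic and auditable).

**QSRR stand-in.** Retention prediction for suspects uses ridge regression
on a single hydrophobicity-like descriptor supplied with each database
entry, trained on the target compounds' experimental retention times. The
applicability domain is the training descriptor range widened by 5 % per
side; out-of-domain compounds (early-eluting organic acids and amino acids
in the default panel) skip the RT window but keep their RT error on record.
This preserves the workflow's RT-window logic without molecular-descriptor
machinery; swapping in a real QSRR model only requires implementing the
same two-method interface (`fit`, `predict`).

**Blank rule.** A compound is treated as blank contamination when its peak
area in any procedural blank reaches 10 % of its median area across class
samples. The cutoff is a package convention (the source workflow does not
state one).

**Internal standard.** The IS (ethyl vanillin, 2 mg/L) is extracted by m/z
(± 5 mDa) and RT (± 0.2 min) match alone, without MS/MS confirmation: it is
spiked at known concentration and identity, and conditioning sample
retention on a stochastic fragment observation would discard whole samples
for no analytical reason.

## Quantification and validation

Calibration is ordinary (unweighted) least squares of the analyte/IS area
ratio on concentration over 7 levels spanning 0.1–20 mg/L; weighting is not
used, matching plain-linear-regression practice for this assay. LOD and LOQ
are 3·noise/slope and 10·noise/slope, so LOQ/LOD = 10/3 identically; the
noise term is a response-scale scalar, estimated in the pipeline as the
residual standard deviation of the solvent calibration fit (ddof = 2).
Concentrations between LOD and LOQ are flagged `traces`, below LOD `<LOD`.
The matrix factor is the ratio of matrix-matched to solvent slopes and
%ME = (MF − 1) × 100; in the generator, matrix-matched responses carry a
per-analyte suppression/enhancement factor drawn once per run from
U[0.7, 1.2], i.e. inside the ±40 % acceptance band.

## Chemometrics

**Scaling.** Column transforms with training-set parameters stored for
test-set application: `center`, `auto` ((x−x̄)/s), `pareto` ((x−x̄)/√s,
ddof = 1) and `range` ((x−min)/(max−min)). Zero-variance columns are dropped
with a warning. The pipeline scales the full sample set once to define the
Kennard–Stone metric (split after scaling), then refits the scaler on the
training rows so that test samples are transformed strictly with training
parameters.

**Kennard–Stone.** Classical max-min selection on Euclidean distances:
the maximally distant pair first, then repeatedly the sample maximizing its
minimum distance to the selected set. Train size is round-half-up
(fraction × n) — 46 samples at 0.8 give 37/9. Rows are ordered by sample
label before selection and ties resolve to the lowest index, making the
selected set invariant under permutation of the input.

**OPLS-DA.** Trygg–Wold orthogonal-signal-correction NIPALS with the class
encoded 0/1 and one predictive component (the natural choice for two
classes). For each orthogonal component: p = Xᵀt/(tᵀt),
w_o ∝ p − (wᵀp)w, t_o = X w_o, and X is deflated by t_o p_oᵀ. Because
w ∝ Xᵀy and w_o ⊥ w, deflation leaves Xᵀy unchanged, so orthogonal scores
are exactly uncorrelated with the response and the n_orthogonal = 0 model
coincides with single-component PLS1 (verified against an independent PLS1
implementation to 1e-8). R²X sums the explained sums of squares of all
extracted components; RMSEE and RMSEP are RMS residuals of the encoded
response on the training and test sets respectively (encoded-response
units).

**VIP and markers.** With one predictive component,
VIPⱼ = √m·|wⱼ|/‖w‖, hence mean(VIP²) = 1 and VIP is proportional to |w₁|
— which is why the VIP/|p₁| ratio is constant down a marker table built
from such a model. Markers are variables with VIP strictly above 1,
class-signed by p₁ (positive p₁ associates with the class encoded 1,
alphabetically second). The V-plot table pairs p₁ with VIP; p(corr)₁ is the
Pearson correlation of t₁ with each (scaled, centered) variable.

**Validation.** Q²Y = 1 − PRESS/TSS from 7-fold cross-validation with
class-stratified round-robin folds after a seeded class-wise shuffle (fold
construction is unstated in the source workflow; this one is deterministic
and keeps both classes in every training fold). The orthogonal-component
count is chosen at the first maximum of Q²Y, adding components only while
Q²Y improves by more than 0.01 — on the clean synthetic study this selects
0 orthogonal components, since the vintage effect is weak relative to the
class separation. The permutation test refits the full model (including
cross-validation) for 20 label permutations. Max-dist prediction assigns
the class whose encoded value is nearest (threshold 0.5); an exact tie goes
to the majority training class. ROC AUC is computed on the continuous
predictions (rank/trapezoidal form, equivalent to the normalized
Mann–Whitney U).

**Univariate screen.** Shapiro (per class) and Levene tests gate a
parametric branch; when assumptions fail — the norm for right-skewed
concentration data — the Wilcoxon–Mann–Whitney test is used. Bonferroni
adjustment multiplies by the number of variables actually tested (constant
variables are reported untestable, not counted).

**Scaling-method ranking.** For each candidate scaling method the full
train/test pipeline is evaluated and the composite score is the mean of
min-max-normalized {Q²Y, external accuracy, 1 − RMSEP} across candidates,
in [0, 1]; a metric with no spread contributes 0.5 to every candidate. The
composite is a package-defined stand-in for proprietary ranking scores; its
absolute value is comparative only and not an externally meaningful number.

## Synthetic study generator

The generator emulates the study design the analysis assumes: 27 + 19
samples of two classes over vintages 2017/2018, 5 pooled-QC injections,
blanks every 10 injections, IS at 2 mg/L, 7-point calibration 0.1–20 mg/L.
Within-class concentrations are log-normal (wine concentration ranges are
right-skewed relative to their means), with per-compound cv in 0.2–0.5
derived from published within-class range/mean ratios; the default is 0.25.
The vintage effect is a multiplicative ±15 % shift shared across compounds
(±30 % and cv 0.5 for the deliberately confounded organic acids and
fermentation/defense glycosides that the pipeline removes before modeling).
Measurement noise: m/z jitter sd 0.5 mDa, RT jitter sd 0.05 min, isotope
intensity noise 5 % relative, injection-level response factor sd 3 %, QC
replicate cv 2 %, calibration response cv 2 %, and per-fragment detection
probability 0.95 (every panel compound carries ≥ 2 qualifier fragments, as
real suspect databases list several qualifier ions per compound).

**Effect sizes and response factors.** The 22 quantified targets carry the
published class-conditional concentration means; the 17 planted markers
(3 targets + 14 suspects) have class-mean ratios of ≈ 2.3–3 with the
published class directions. MS response factors follow
5·10⁴ × (10/mean)^0.9 — ionization efficiency anti-correlated with
abundance class — which compresses IS-normalized areas to ~1.5 orders of
magnitude across the panel. This calibration is chosen so the generated
study reproduces the structure of the published marker table: |p₁| spans
only ~3.5× over compounds whose concentrations span ~100×, and all 17
planted markers sit above the VIP = 1 line. The QSRR descriptors embed a
structural retention residual of ≲ 0.6 min for suspects, consistent with
the reported fractions of suspects predicted within 1 and 2 min.

**Decoys** are uniform in m/z (50–1000) and RT, with A+1 intensities drawn
from U[0.5, 0.9] — inconsistent with any CHNOPS formula — and random or no
fragments; they exercise the false-positive path (an m/z coincidence alone
can never pass the fragment and isotopic-fit criteria). Blanks contain only
decoys.

**Effect multiplier.** `NoiseConfig.effect_multiplier` scales class
separation geometrically (0 → identical class means for type-I-error
checks, 1 → the default study). `NoiseConfig.zero()` is the noiseless
limit, where screening recovers the panel exactly and quantification is
exact — the truth-record round trip.

**What passing does not show.** The generator draws independent compounds
(no correlation structure from shared biosynthetic pathways), uses
well-separated chromatographic peaks (no coelution or peak-shape
artifacts), a one-descriptor retention model, and noise amplitudes typical
of a well-calibrated QToF. Perfect classification on this study therefore
demonstrates the correctness of the pipeline's statistics and rules, not
the discriminability of real wines; on instrument data the same workflow
would face correlated variables, RT drift, and matrix-dependent response.

## Problem sizes and runtime

Default runs were sized for desk-scale reproduction: 46 + 5 + 7 injections
with ~65 features each, a ~50-compound panel, 100-seed calibration and
20-seed classification replications. A full pipeline run takes a few
seconds on one CPU; the complete test suite runs in well under a minute.

## Known limitations

- Positive-mode adducts, multiple charges and fine isotopic structure are
  out of scope.
- In-silico fragmentation and spectral-library retrieval are not
  implemented; identification levels 2a/2b are assigned from caller-supplied
  evidence flags.
- The mSigma surrogate and the scaling-ranking composite are package
  conventions; their absolute scales are not comparable to vendor tools.
- The univariate parametric branch uses Student's t (not Welch); with the
  Levene gate in front, variance inequality routes to the rank test anyway.
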