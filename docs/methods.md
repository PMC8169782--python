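# Methods

## Theoretical lipid database

Species are enumerated at sum-composition level: a class code plus total
acyl carbons C and total double bonds D. Each class carries a backbone
rule giving the elemental composition as
C(C+c₀) H(2C−2D+h₀) N(n₀) O(o₀) P(p₀); the offsets encode the head
group and backbone (e.g. PC: c₀=8, h₀=16, N₁O₈P₁, so PC 34:1 is
C₄₂H₈₂NO₈P, 759.5778 Da). Monoisotopic masses use IUPAC atomic masses;
adduct m/z is (M + δ)/z with electron-mass-corrected deltas. Twelve
classes are covered (PC, LPC, PE, PS, PA, PC-O, PE-O, SM, Cer, TG, CE,
FA), singly charged adducts only.

Composition ranges are a declared convention, not a measurement: even
total carbon counts; diacyl and sphingoid classes C 24–48, TG 30–70,
LPC/FA 12–26, CE 12–24; D capped per class and by D ≤ C/2. The ranges
comfortably cover the species that appear in plasma and uterine-tissue
lipidomes of this kind. Sphingolipids (SM, Cer) are enumerated at total
composition and rendered in d-notation (`SM d34:1`); chain-annotated
names (`SM d18:1/16:0`, `PC 16:0_20:3`, `TG 18:0_18:1_18:1`) are parsed
by summing chains, since chain-level (sn-position) identification is out
of scope.

Queries return all ions within an inclusive ±ppm window (default
10 ppm), ordered by |ppm error| with canonical-name tie-break, and are
implemented as a binary search over the m/z-sorted ion list; a linear
scan is the test oracle.

## Annotation and MS/MS confirmation

MS1 peaks get one candidate annotation per database hit. Confirmation
checks class-diagnostic evidence in an MS/MS spectrum whose precursor
lies within the 3 Da isolation window: phosphocholine fragment 184.0733
(PC/LPC/SM/PC-O), neutral loss 141.0191 (PE/PE-O), cholestadienyl
fragment 369.3516 (CE), water loss (Cer), ammonia loss from [M+NH₄]⁺
(TG), serine loss 87.0320 (PS, negative mode). Fragment tolerance is
absolute (0.01 Da) because the diagnostic ions are low-mass, where a ppm
window would be unreasonably tight. Classes without a bundled rule (PA,
FA) are flagged `no_rule` and left unconfirmed rather than penalized.
Ambiguity resolution is deterministic: confirmed beats unconfirmed, then
smaller |ppm|, then name order. Acquisition logic (DDA top-5 selection,
collision energy, exclusion windows) is not modeled — spectra are
consumed as given, since acquisition does not affect the downstream
statistics.

## Feature table and preprocessing

Features × samples intensity matrix with per-feature (m/z, annotation)
and per-sample (group, matrix, QC flag) metadata; on disk as
`table.csv` + `samples.csv`. The preprocessing order is fixed:

1. half-minimum imputation of zeros/missing (all-zero features dropped),
2. QC-RSD filter: features with relative SD > 0.30 across ≥3 pooled-QC
   injections are dropped (skipped with a warning when QC is absent),
3. total-ion-current normalization of each sample to the median total.

Only features are ever dropped; sample count and order are preserved.
The univariate screen runs on normalized, untransformed intensities
(rank tests are invariant to monotone transforms anyway); OPLS-DA runs
on log₁₀ intensities (variance stabilization before a least-squares
decomposition); the logistic models run on raw-scale intensities, which
is what keeps their coefficients at the 10⁻⁵–10⁻⁶ magnitudes typical of
published panels on ~10⁵-scale signals.

## Synthetic cohorts

The generator draws intensity(f, s) = 10^N(μ_f, σ) · 2^FC(f,g): one
baseline μ_f ~ N(5.0, 0.5) per feature (raw scale ~10⁵), within-group
log-normal noise with natural-scale CV 0.3 (σ = √ln(1+CV²)/ln 10 ≈
0.128 log₁₀ units), and a planted log₂ fold change on marker features in
their affected groups. QC samples are repeated injections of the pooled
sample: expectation equal to the pooled mean log-intensity and a smaller
analytical CV of 0.1. Feature m/z values come from the theoretical
database with Gaussian ppm noise (σ = 2 ppm). A single RNG stream keyed
by the mandatory seed drives everything; no global state.

The default design emulates a three-group plasma study: 15 controls / 35
first-time cases (UF) / 31 recurrent cases (RUF), 267 features, positive
mode m/z 400–1000, 5 QC injections. Eight disease markers carry a fold
change in both case groups and seventeen recurrence markers in the
recurrent group only, with |log₂FC| spaced over [0.6, 1.5] and
alternating signs — moderate, plausible effects chosen as a convention
(the true effect sizes in real cohorts are unknown; only significance is
typically reported). Marker identities are drawn from lipid species
recurrently implicated in this disease context (LPC/PC/SM for disease,
CE/PC/SM/TG for recurrence) so that reports read like a real study.

What the generator does *not* emulate: chromatographic and batch drift,
co-elution and isotopologue interference, missingness that depends on
abundance, heavy-tailed or skewed group differences, correlated lipid
modules. Passing tests therefore demonstrate that the statistical chain
is correct and well-calibrated under its own assumptions, not that any
particular real-data performance (e.g. a published sensitivity) would be
reproduced.

## Mann–Whitney screen

U = #{xᵢ > yⱼ} + ½·#ties. For tie-free designs with both groups ≤ 8 the
two-sided p is exact, from the enumerated null pmf of U (cached per
(n, m)); otherwise a normal approximation with tie-corrected variance
and continuity correction. Fully tied data (zero rank variance) returns
p = 1. The exact/approximate crossover at max(n, m) = 8 keeps the exact
branch ≤ C(16,8) = 12 870 enumerations. The worst-case gap between the
two branches at n = m = 8 is 0.0109 (deterministic sweep over the U
support), attained mid-distribution where it cannot change a 0.05-level
decision. Selection uses raw p < α with no multiplicity adjustment —
the screening convention of this study type — and the BH-adjusted column
is emitted for downstream use.

## OPLS-DA

On centered/UV-scaled X and 0/1-coded centered y, per orthogonal
component: w ∝ Xᵀy (‖w‖=1), t = Xw, p = Xᵀt/(tᵀt),
w_o = p − (wᵀp)w normalized, t_o = Xw_o, p_o = Xᵀt_o/(t_oᵀt_o), deflate
X ← X − t_o p_oᵀ; then one predictive component (w, t, p, q) on the
filtered X. Because w ∝ Xᵀy at every stage, yᵀt_o = ‖Xᵀy‖(wᵀw_o) = 0
exactly: orthogonal scores are uncorrelated with y by construction, and
the test suite asserts this numerically (<10⁻⁸). Sign convention: the
class coded 1 has positive mean predictive score. Default n_ortho = 1;
with n_ortho = 0 the predictive component coincides with the first
NIPALS PLS1 component, which an independently coded oracle verifies.

Q²Y uses stratified k-fold CV (default 7; folds = n gives leave-one-out)
with scaling and the model re-estimated inside each training split:
Q² = 1 − PRESS/SS(y centered). VIP is computed over the predictive
component only, so ΣVIP² = n_features holds exactly and VIP > 1 retains
its "above-average influence" meaning; markers are features with VIP
strictly > 1, sorted descending.

Permutation validation refits the model and its Q²Y under random label
permutations. Note that cross-validated PLS Q² has a systematic negative
bias under the null at p ≈ n (the model fits noise in training that
anticorrelates in held-out folds); at 50 samples × 17 features the null
mean sits near −0.3, matching what independent implementations produce
on iid data. The meaningful validation readout is therefore the
separation between the observed Q²Y and the permutation distribution
(empirical p with the +1 correction), not the absolute null mean.

## Logistic diagnostics

Maximum likelihood by IRLS with a ridge penalty of λ = 10⁻⁸ on the
normal equations — a numerical stabilizer for the quasi-separation that
VIP-preselected panels routinely produce, not regularization; on
well-conditioned data the estimates match the unpenalized MLE to ≤10⁻⁶
(verified against an independent optimizer). Complete separation is
detected (perfect training classification with |η| > 30) and flagged;
the last stable iterate is returned with finite coefficients. Wald SEs,
z, p and 95% CIs come from the penalized information matrix.
Leave-one-out CV refits on n−1 samples and classifies the held-out
sample at P ≥ 0.5 (configurable); sensitivity and specificity recompute
exactly from the stored confusion counts. Prediction uses a numerically
stable logistic for |η| up to ~700.

## Enrichment

Exact upper-tail hypergeometric P(X ≥ k) for k significant members of a
pathway with K background members, n significant and N background lipids
in total; BH adjustment across pathways. The bundled pathway map is a
deliberate stand-in for a curated pathway library: membership by lipid
class (glycerophospholipid = PC/LPC/PE/PS/PA, sphingolipid = SM/Cer,
ether lipid = PC-O/PE-O, glycerolipid = TG) plus linoleic acid
metabolism for names with an explicit 18:2 acyl chain — sum compositions
cannot resolve chains and are excluded, and a d18:2 sphingoid base does
not count. The background is the annotated feature set of the analyzed
table, per standard over-representation practice, not the full
theoretical database.

## Pipeline

Stage order per comparison: Mann–Whitney screen → OPLS-DA on the
significant set → VIP > 1 panel → logistic model + LOOCV → enrichment.
The three default comparisons are control vs UF, control vs RUF, UF vs
RUF. All randomness (CV folds, permutations) derives from the single run
seed; the JSON report (sorted keys, fixed rounding, config hash that
excludes the output path) is byte-identical across repeat runs. A full
default-design run takes a few seconds on one CPU.

## Numerical and design notes

- "Sevenfold leave-one-out" is contradictory as a CV spec; implemented
  as stratified 7-fold with a seed, with folds = n expressing LOO.
- Zero-variance features receive unit scale (they stay at zero after
  centering) rather than being dropped mid-model.
- Ties in marker selection, annotation ambiguity, and database ordering
  are all broken by canonical name order, never by memory order.
- The acceptance checks run the analysis at the default design sizes
  (81 + 5 QC samples × 267 features; 2 000 features for the type-I-error
  check; 100 permutations), which keeps every run in the seconds-to-
  minutes range.

## Known limitations

- Sum-composition annotation cannot distinguish isobaric species or
  chain isomers; ambiguity resolution is a deterministic convention.
- The bundled fragment rules and pathway map are minimal conventions,
  not curated libraries.
- Raw-intensity logistic coefficients are scale-dependent; panels are
  not transferable across platforms without re-fitting.
- Perfect LOOCV on the default synthetic design reflects the planted
  effect sizes; it is an upper bound, not a forecast for real cohorts.
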