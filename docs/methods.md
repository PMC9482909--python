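# Methods

## Mass arithmetic

Atomic masses are IUPAC monoisotopic values hard-coded to ≥ 6 decimals;
proton 1.00727646 Da, electron 0.00054858 Da. Adducts carry their full
ionic mass shift (electron included): m/z = (M + Δ)/|z|. `[M]+` is treated
as an intrinsically charged species — the formula describes the ion's atom
inventory and only the electron mass is subtracted — which is the correct
reading for quaternary ammonium cations such as choline (ignoring the
electron shifts the theoretical m/z by ~5 ppm at m/z 104, outside a 5 ppm
matching window). Shipped adducts: [M+H]+, [M+Na]+, [M+NH4]+, [M]+,
[M−H]−, [M+HCOO]−; |z| > 1 is out of scope.

Theoretical isotope envelopes are per-element nominal-offset distributions
convolved on the unit-mass grid (A, A+1, A+2, …) and base-peak normalized.
The unit-mass aggregation matches what an Orbitrap-resolved envelope
comparison consumes; fine isotopologue structure is deliberately not
modeled.

One known calibration outlier is carried in the test suite: the printed
measured [M−H]⁻ m/z of 3-(3-hydroxyphenyl)propionic acid (165.0547)
deviates ~6.2 ppm from the theoretical value of C9H10O3 (165.05571). It is
asserted to be the sole > 5 ppm worked-example row and is flagged, not
"corrected".

## Spectral matching

Peak pairing is optimal one-to-one assignment within an absolute m/z
tolerance (default 0.01 Da): maximize the number of matches, then minimize
the total |Δm/z|. Exact-tie degeneracies are resolved by a symmetric
intensity-product epsilon so the score is deterministic and symmetric in
its operands. The "dot product" (0–100) is the cosine between
square-root-scaled intensity vectors over the union of peak slots — the
common metabolomics convention; the scheme thresholds (70/50) assume this
0–100 scale. Fragment presence is the percentage of reference peaks
(above a 1% relative-intensity floor) recovered in the query; the same
floor guards the matched-fragment count so "≥ 3 fragments matching" cannot
be satisfied by noise peaks. The normalized library score in [0, 1] is the
dot product / 100 — a documented surrogate for proprietary library match
scores (e.g. MassBank-of-North-America scores computed inside MetFrag); it
preserves the ordering and range the level thresholds assume. Precursor
gating uses 5 ppm, consistent with Orbitrap MS1 accuracy.

## Formula annotation

Candidate formulas for a feature's neutral mass (via the mode's primary
adduct, [M+H]+ or [M−H]−) are enumerated depth-first over element bounds
with mass-window pruning, subject to: integer ring-double-bond equivalents
≥ 0, and 0.1 ≤ H/C ≤ 3.5 when both elements are present (a bare carbon
cluster passes, so a mass of 12.000 still annotates). The search aborts
above 10⁶ explored combinations. Package-wide default bounds cover
C≤40 H≤80 N≤6 O≤12 S≤3 P≤2 Cl≤3 F≤6 for a 60–900 m/z scan range; the
pipeline's run config narrows them to CHNO (C≤30 H≤60 N≤6 O≤12) because
the synthetic compound panel is CHNO — both are plain config keys.

* **isoScore** = 1 − mean absolute deviation of relative abundances over
  the aligned A…A+k peaks (k = shorter pattern), clipped to [0, 1]. The
  score's name circulates without a published formula; this choice is
  bounded, symmetric, and maps identity to 1.
* **annSimForm** = cosine between the query MS/MS and its sub-spectrum of
  peaks explainable as sub-formula fragment ions of the candidate
  (element-wise ≤ candidate counts, ±1 H latitude, electron-mass
  corrected — covering even-electron fragments and candidate-minus-loss
  readings). **annSimComp** additionally caps this by structure-level
  library evidence when present (min with the normalized dot product);
  without library structure evidence the two coincide. These are
  documented surrogates for annotation-similarity columns whose exact
  upstream definitions depend on in-silico fragmentation engines that are
  out of scope.
* Candidates are ranked by isoScore, then |ppm error|, then annSimForm,
  with Hill-string tie-break for determinism; each candidate exposes its
  gap-to-next values, and a single candidate has infinite gaps — which is
  how "0.2 higher than the next candidate" behaves when the search returns
  one formula.

Observed isotope envelopes are not part of the aligned feature-table
schema; they are supplied through an optional sidecar CSV
(feature_id → relative abundances). Features without a sidecar row carry
no isotope evidence and cannot reach the formula-only levels (4a/4b).

## Confidence levels

Three cascades, evaluated best level first; a feature receives the best
level it qualifies for, and level 5 is the total fallback. Range
conventions: "0.7–0.9" is (0.7, 0.9]; "70–100" is [70, 100]; explicit
>/≥ are literal — adjacent bands then partition the score axis without
overlap. In the suspect scheme the fragment rule is a disjunction
("> 3 fragments match" OR "< 3 fragments and all match") and precedes the
annotation-similarity rule. "One candidate only" is read globally: the
candidate count is the number of library candidates when spectral evidence
exists, else the number of enumerated formulas. Level 1
(reference-standard confirmation) has no computational analogue and is
never assigned. The suspect-scheme column is populated only for features
with at least one suspect hit; the non-target schemes are total over all
QC-retained features.

## Statistics

The processing chain mirrors the common web-tool convention: IQR variance
filter (drop fraction by feature-count ladder: 0% < 250, 5% < 500,
10% < 1000, 25% < 2000, else 40%; ties broken by feature id), sum
normalization (each sample rescaled to the mean total — idempotent), Pareto
scaling (centered, divided by √SD; constant features guarded to zero
rows). Fold changes are ratios of group means on the normalized-unscaled
matrix; p-values are two-sided Welch t-tests on the scaled matrix.

PLS-DA is NIPALS PLS1 on −1/+1 centered class labels. With the orthogonal
option (the default), one Trygg–Wold orthogonal-signal component is
removed first and VIP is computed on the predictive component — one
predictive + one orthogonal component is all a two-class problem of this
size supports, and predictive-component VIP was chosen over total-VIP
variants as the more selective reading. VIP_j = √(p · Σ_a w²_ja SSY_a /
Σ_a SSY_a); Σ VIP² = p holds to 1e-8 and is asserted on every fit.

Selection is the strict conjunction p < 0.1 ∧ (FC > 2 ∨ FC < 0.5) ∧
VIP > 1. No multiple-testing correction is applied by default — the
workflow this package operationalizes explicitly reported unadjusted
p-values at n ≈ 10/group — but a Benjamini–Hochberg flag (`stats_fdr`)
is available for reanalysis.

## Overlap and pathways

Overlap reports are exact Venn partitions of 2–4 named InChIKey sets (full
key by default, 14-character connectivity block optionally). Features
without an InChIKey — structure-unknown levels — cannot enter the
comparison; they are counted and reported, never silently dropped.
Pathway over-representation is the hypergeometric upper tail
P(X ≥ hits) per pathway, on case-folded, whitespace-normalized compound
names with duplicates removed; the universe (all annotated names) must be
supplied/derivable explicitly. Pathway-topology impact scores are out of
scope.

## Synthetic cohorts

The generator emulates a two-group cohort (defaults: 10 PD vs 10 Ctrl,
6 pooled QC, 500 features) with:

* log-normal intensity noise, CV 20% (σ = √ln(1+CV²)), per-feature
  baselines log-uniform over one order of magnitude (10^5.5–10^6.5).
  One order is typical of post-QC within-assay dynamic range; it also
  keeps Pareto-scaled class covariance from being dominated by abundance
  rather than effect, which is what the recovery analysis measures.
* multiplicative group effects: 20 spiked features at FC 4, plus a panel
  of 37 designed compounds, nine of which carry the names, formulas,
  adducts and literature-scale effect sizes of known PD-associated
  metabolites (valine, nicotinamide, choline, alanine betaine,
  isonicotinic acid, levodopa, 3-HPPA, cholic and glycocholic acid);
* mass errors N(0, 1 ppm) clipped at ±3 ppm;
* QC intensities affinely rescaled to hit each feature's target RSD
  exactly (10% for well-behaved features; 25 features at a deliberate
  80% to exercise the filter), so the QC-filter outcome is part of the
  ground truth;
* designed MS/MS spectra with equal-intensity peaks, so library cosine
  scores land exactly in the band each compound's evidence archetype
  targets (e.g. sharing k of n equal peaks gives a dot product of
  100·√(k/n)); "noise" peaks sit on half-integer m/z values that no small
  CHNO sub-formula can explain;
* eleven evidence archetypes (≥ 3 compounds each) arranged so every
  confidence level of every scheme is realized, including
  structure-unknown library records (2b/3c), weak-library + formula
  evidence (4a), isotope-only evidence (4b) and bare masses (5).

What the generator does **not** emulate: chromatographic peak shapes,
retention-time drift and RT-based matching, intensity-dependent mass
error, correlated features (adducts/isotopologues of one compound),
batch effects, missing values (absent intensities are zeros), and
realistic MS/MS intensity heterogeneity. Passing tests therefore
demonstrate correctness of the scoring, rule and selection machinery
under controlled conditions — not robustness to those real-data
phenomena.

InChIKeys in generated data are format-valid placeholders derived from
compound names, deliberately not registry keys.

## Problem sizes and determinism

The default end-to-end analysis (500 features, 26 samples) runs in a few
seconds; the recovery analysis repeats it over 10 seeds. All randomness
flows from a single integer seed through `numpy.random.default_rng`;
regenerating a dataset or rerunning the pipeline with the same seed and
config is byte-identical (hash-checked in tests, with file hashes recorded
in each output MANIFEST).

## Known limitations

* The library score surrogate (cosine/100) preserves ordering but is not
  numerically identical to proprietary library scores; thresholds are
  honored as written.
* Suspect matching uses mass + adduct only (suspect lists carry no RT).
* Formula annotation considers the mode's primary adduct when inferring
  the neutral mass; intrinsically charged species therefore receive no
  meaningful formula evidence unless identified spectrally (their levels
  come from library evidence in practice).
* The MS-DIAL-style cascade leaves a strong multi-candidate spectral match
  (dot ≥ 70, ≥ 3 fragments, several candidates) at level 5, which is the
  literal reading of the published rule table.
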