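# Methods

This note documents the models and procedures implemented in `ppbqsar`,
the choices that were genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Endpoint

The fraction unbound fu ∈ (0, 1] is transformed before modelling.

* **logK = log10((1 − fu)/fu)** — a pseudo-equilibrium constant (bound/free
  ratio). Log base 10 is used, the convention for equilibrium constants.
  At fu = 1 the ratio degenerates and the transform returns exactly 2 by
  convention; this value is outside the range of the analytic branch
  (which tends to −∞ as fu → 1), so inverting the transform is only defined
  for outputs ≠ 2. fu = 0 is rejected at curation: logK is undefined there
  and a measured fu of exactly zero is below any assay's quantification
  limit anyway.
* **√fu** — variance-stabilizing for proportions concentrated near 0.

Skewness is the adjusted (bias-corrected) Fisher–Pearson sample γ₁
(`scipy.stats.skew(bias=False)`); the estimator choice matters little at
n = 500 but is fixed for reproducibility.

## Curation

Structures are standardized with RDKit: largest organic fragment, charges
neutralized where a neutral parent exists (quaternary nitrogen keeps its
charge), canonical SMILES output. Rejection reasons: `no_activity`,
`range_value`, `metal` (any element outside H, B, C, N, O, F, Si, P, S,
Cl, Se, Br, I), `inorganic` (no carbon), `ambiguous` (activity outside
(0, 1]), `unparseable`, `duplicate` (canonical-SMILES identity, first
occurrence kept). The metal/inorganic definitions are this package's own,
since no standard exists.

**Ionization at pH 7.4.** Per acidic site the anionic fraction is
f_a = 1/(1 + 10^(pKa − pH)), per basic site the cationic fraction
f_b = 1/(1 + 10^(pH − pKa)); the most ionized site of each kind decides.
Strictly more than 10% ionized flags the class; both flags make a
zwitterion, neither a neutral. The per-site maximum is used rather than a
summed microspecies population — with multiple sites of the same kind the
most ionized one dominates the population in practice, and the per-site
rule needs no microspecies enumeration. Exactly 10% is treated as *not*
more than 10%.

pKa values are taken from the input when provided. Otherwise a small SMARTS
rule table assigns typical literature values (carboxylic acid 4.5, sulfonic
acid −1, phosphonic acid 2, tetrazole 4.9, acyl sulfonamide 4.5, phenol 10,
thiol 10.5; aliphatic amine 10.5, amidine 11.5, imidazole 7.0, pyridine
5.2, aromatic amine 4.6). This is a deterministic, documented fallback, not
a pKa predictor; users with measured or predicted values should supply
them.

For descriptor calculation the neutral parent is the default; the
`use_ionized` option derives the main microspecies at pH 7.4 by
deprotonating strong-acid sites and protonating aliphatic amines (the
rule-table sites whose majority species is charged at 7.4).

## Splitting

The TS/EVS split stratifies on activity: five equal-width bins spanning
[min, max] of the endpoint (equal-count quantile bins behind
`binning="count"`), overall TS size round(0.8·n), apportioned over
non-empty bins by the largest-remainder rule and drawn uniformly at random
within bins. Largest-remainder apportionment keeps every bin within one
compound of the target ratio and makes the overall count exact; empty bins
(possible with skewed endpoints) are skipped. For the correlation-weight
model the TS is further partitioned at random into visible training,
invisible training (ITS) and calibration (CS) portions with default
fractions 108:140:143 (the canonical pattern for a 391-compound TS),
rounded by largest remainder.

## Descriptor models

The descriptor backend is RDKit 2D descriptors (lipophilicity, size,
topology, polarity, charge; ~29 columns, namespaced `rdkit:`). Rows with
any incomputable descriptor are dropped and logged. Prefiltering removes
zero-variance columns, then scans name-sorted column pairs and removes the
later column of any pair with |Pearson r| > 0.95 — keeping the earlier
column makes the result deterministic and row-order invariant.

**Three-step variable selection** (`VSURFSelector`), a random-forest
selection in the spirit of threshold/interpretation/prediction staging:

1. *Thresholding*: the matrix is augmented with 5 row-permuted decoy
   columns; permutation importances are averaged over 5 forests; variables
   whose mean importance does not exceed the mean decoy importance (the
   estimated null level) are dropped.
2. *Interpretation*: survivors are ordered by importance; nested forests on
   each importance-ordered prefix; the prefix with minimum out-of-bag MSE
   is kept.
3. *Prediction*: walking through the interpretation set, a variable is
   retained only if adding it lowers OOB error by more than the standard
   deviation of the step-2 OOB errors (a noise-scaled margin).

Defaults: 500 trees per forest (stability of permutation importances);
tests use 80–100 trees, which is sufficient for the planted-signal
experiments at n = 300. If no variable beats the null level the single
most important one is returned with a warning.

The regression forest uses bootstrap resampling and ⌊√p⌋ candidate
descriptors per split. Metrics: r² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE, and
Q² = 1 − Σ(y−y′)²/Σ(y−ȳ)² with y′ the out-of-fold predictions of a seeded
5-fold partition and ȳ the full-data mean. For constant observations r² is
undefined; the implementation returns nan with a warning while still
returning the RMSE, so callers retain the defined half of the result.

## Optimal SMILES descriptors

Tokenization: bracket atoms `[...]`, two-letter organic-subset elements
(Cl, Br), aromatic lowercase atoms, ring-closure digits and `%nn` labels,
and the bond symbols `=`, `#`, `/`, `\` are tokens; branch parentheses and
explicit single bonds are dropped; `.` acts as a break so pairs/triples
never span disconnected fragments. Attributes: token multiset (Sk),
adjacent pairs (SSk, symmetric key), adjacent triples (SSSk, outer tokens
sorted around the fixed middle), and one HARD key of 11 presence bits
(N, O, S, P, F, Cl, Br, I; double, triple, stereo bond). Pair/triple
symmetry makes attributes invariant to the writing direction of the
string; a single canonicalizer (RDKit) is used for the whole run.

DCW is the weight sum over all attribute occurrences; the endpoint model is
C₀ + C₁·DCW with (C₀, C₁) refit by one-variable least squares after every
proposal. Attributes occurring in fewer than T visible-training compounds
are blocked (weight pinned at 0, excluded from the domain). The target
function is TF = R + R′ − |R − R′| + w·IIC with w = 1.1 (overridable), R/R′
Pearson correlations on the visible/invisible training sets and IIC
computed on the calibration set as r·min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺) over
the signed residual classes (0 if a class is empty). Computing IIC on the
held-aside calibration set follows the index's published usage; computing
it on the training portions would let the optimizer trade correlation for
residual balance on data it is already fitting.

**Optimization.** Seeded hill climbing: per epoch every active attribute is
visited in random order; a uniform step u ∈ [−δ, δ] and its mirror −u are
probed and the better strictly-improving one is accepted. Weights start at
0. Because (C₀, C₁) are refit per proposal and correlations are
scale-invariant, TF is invariant to a global rescaling of the weights; with
a null start δ therefore only sets the scale of the fitted weights, not the
search path, and the accepted-TF trace is non-decreasing by construction.
Defaults: δ = 0.1, T = 1, N = 50 epochs. Degenerate inputs: a constant
endpoint yields C₁ = 0 and constant predictions; zero-variance descriptors
give R = 0 rather than an error.

A note on identifiability: attribute counts of real molecules are heavily
collinear (ring-closure digits track ring counts, aromatic carbons track
benzene fragments, the HARD key tracks element presence), so individual
correlation weights are identified only up to the null space of the count
matrix. Predictions are unaffected; tests that check weight recovery use a
full-rank construction (disconnected single-atom fragments) where the
single-token weights are identifiable.

The applicability domain is attribute coverage: a compound is in domain iff
every one of its attributes (HARD included) was active during training.

## Applicability domains

Seven methods behind one fit/decide interface; coverage is the in-domain
fraction.

* **real_random** — random-forest classifier on TS vs a column-permuted
  mirror copy; in domain iff P(real) ≥ 0.5 (the natural cutoff; with
  uninformative descriptors the classifier sits at chance and everything
  stays in domain).
* **leverage** — h_i from the hat matrix with intercept, threshold
  h\* = 3(p+1)/n (the Williams-plot convention). The TS leverages sum to
  p + 1 (trace identity), used as a self-check.
* **pca_sd / pca_pct** — first two principal components of the autoscaled
  TS; bounds mean ± 3 sd, or the 0.05/0.95 quantiles (a literal
  0.005/0.95 reading is available behind `literal=True`).
* **knn_dist** — in domain iff the distance to the nearest TS compound is
  at most the mean of all pairwise TS distances (threshold overridable).
* **acf** — atom-centred fragments (central heavy atom with aromaticity
  and formal charge, plus the sorted multiset of bond-type/neighbour
  pairs); all test fragments must occur in the TS dictionary. Monotone in
  the TS by construction.
* **fingerprint** — MACCS substructure keys, mean Tanimoto similarity to
  the TS, out of domain below 0.1. MACCS is the open substructure-key
  fingerprint standing in for vendor-specific key sets.

## Outlier-category analysis

Outliers are compounds whose absolute error strictly exceeds the set MAE.
Per category the 2×2 table [[TP, positives−TP], [FP, negatives−FP]] is
tested with the two-sided Fisher exact test (no multiple-testing
correction by default, matching common practice in this analysis; a
Benjamini–Hochberg helper is provided) and summarized by
LR = (TP/FP)·(negatives/positives), which equals 1 when the category's
outlier rate matches the global rate. FP = 0 yields +inf and
positives = 0 yields nan — undefined ratios are signalled, never silently
0. Both enrichment directions are reported. Categories are matched by an
open SMARTS table (quaternary/charged N, aliphatic esters and amides,
tertiary/primary alcohols, CH₂RX, urea derivatives, aromatic hydroxyls,
quaternary and ring-quaternary carbon, β-lactams, sulfides, imidazoles);
the patterns are documented in `category_analysis.CATEGORY_PATTERNS`.

## Synthetic data

The generator emulates the statistical structure of curated human fu
collections: compounds are assembled from a small fragment grammar (alkyl,
branched, aromatic, ether, ester, phenol, sulfide units with ionizable
termini), and fu is the inverse logit of a latent lipophilicity score plus
Gaussian noise (sd 1.2), clipped to (1e-4, 1]. Lipophilic compounds bind
strongly, producing a right-skewed fu distribution with ≳ half the
compounds below fu = 0.1 and γ₁ ≈ 1.6 at n = 500 — the qualitative shape
of real collections. The ionization-class mix (24% acid, 27% base, 38%
neutral, 11% zwitterion) follows the proportions typical of curated drug
collections, and each class's termini carry the matching rule-table pKa
values so the classifier recovers the intended class. Structures are
unique by canonical SMILES and pass curation without rejection.

Ground truth for downstream tests: `plant_coral_signal` builds an endpoint
exactly linear in SMILES-attribute counts (plus optional noise) and also
returns the noiseless values; `simulate_predictions` adds Gaussian error
whose sd is multiplied by a category effect (default ×3 for aliphatic
esters), planting a known high-error category. A single integer seed
drives a hierarchical `SeedSequence`, one child stream per concern, so
runs are bit-reproducible without cross-coupling.

**What passing these tests shows — and does not.** The synthetic space has
a few dozen attribute types and descriptor gradients dominated by a single
latent factor; real medicinal chemistry is vastly more diverse, real fu
has assay-dependent noise far above 0.01, and real category effects are
weaker than ×3. The tests therefore demonstrate correctness of the
machinery (recovery of signals that are present, calibrated statistics,
deterministic pipelines), not expected performance on real data.

## Problem sizes and numerical choices

Tests run the generator at n = 300–500, the Monte-Carlo optimizer at
N = 30–50 epochs, forests at 50–200 trees; these sizes give stable results
for the planted-signal experiments while keeping the suite quick. Fisher
p-values are validated against exhaustive hypergeometric enumeration over
all 2×2 tables with margins ≤ 12. Metric implementations are validated
against independent brute-force summation at 1e-10. Correlation pruning and
selection are deterministic under fixed seeds; all RNG is NumPy
`default_rng`/`SeedSequence` (PCG64), so assignments are reproducible
across platforms.

## Known limitations

* The rule-table pKa fallback covers common ionizable groups only;
  unusual acids/bases default to neutral.
* Protonation edits for the ionized microspecies are limited to
  carboxylic/sulfonic/phosphonic acids and aliphatic amines.
* No tautomer canonicalization or stereochemistry normalization beyond
  RDKit canonical SMILES.
* The Monte-Carlo optimizer is a strict hill climber; it finds good
  correlation-weight solutions for the planted-signal regime but has no
  restart or annealing mechanism for strongly multimodal objectives.
* Functional-group SMARTS are open approximations of vendor functional
  group counts; exact definitions of commercial descriptor packages are
  proprietary and not reproduced.
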