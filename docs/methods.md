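# Methods

This note records the models the package implements, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not establish about real questionnaire data.

## Instruments and data model

Three self-report apathy instruments drive the analyses: AMI (18 items,
a-priori Behavioural/Social/Emotional domains, six items each), AES (18
items) and DAS (24 items). Item→domain keys and reverse-key flags live in
`src/apathynet/data/scale_registry.csv`, shipped as editable plain-text
data because the instruments are published elsewhere and keys may need
correction without a code change. The AMI key follows the published
instrument; the AES and DAS domain assignments follow the instruments'
subscale structure mapped into this package's domain vocabulary (AES
social-content items are labelled Social), and should be checked against
the original publications before substantive use. All responses are
treated as numeric 0–4 (higher = more apathetic after reverse keying);
product-moment correlations are used for factor analysis, Spearman rank
correlations for networks.

Missing-data policy: pairwise deletion for correlation matrices (networks
keep the most data), listwise deletion for EFA/CFA (keeps the likelihood
well-defined).

`apply_reverse_keys` is deliberately non-idempotent: a second application
would silently undo the first, so the transform is recorded on the dataset
and re-application raises.

## Synthetic cohorts

Continuous responses follow the common-factor model y = Λf + ε,
f ~ N(0, Φ), ε ~ N(0, diag(θ)) with θ = 1 − diag(ΛΦΛᵀ), so each
continuous response is standard normal marginally. Ordinal 0–4 responses
cut each item at per-item thresholds; the default is the standard-normal
quintiles (equal 20% category probabilities), which puts simulated item
means mid-scale, where real cohort means sit. Ages are uniform on 16–90
by default, and non-stationary structure is created by *mixing age-band
models at the participant level* (never by interpolating Λ), so every age
window has a well-defined generating model for recovery tests. One seeded
generator per simulation call spawns sub-streams for ages, modes and
responses, so partial reruns reproduce exactly.

What the generator does **not** emulate: acquiescence and other response
styles, item-wording effects, informant/self discrepancies, cohort
differences in marginal severity, and non-normal latent traits.
Consequently, passing recovery tests show the *pipeline* is correct and
well-calibrated under its assumed data-generating process — they do not
show that real questionnaire data satisfy that process.

Discretisation matters for calibration: 0–4 ordinal data generated this
way are not exactly a linear factor model in the population, so exact
distributional checks (the CFA χ² calibration) use continuous draws from
the factor model (`simulate_continuous`), while structure-recovery checks
(networks, EFA patterns) use the ordinal data.

## Exploratory factor analysis

- **Extraction is maximum likelihood** (concentrated likelihood over the
  uniquenesses, Jöreskog's formulation; L-BFGS-B on log-uniquenesses with
  the envelope gradient). A χ²/df model test requires ML; principal-axis
  is available for robustness comparisons. Uniquenesses are floored at
  0.005 (Heywood guard, warned).
- χ² uses the Bartlett-corrected multiplier (n − 1 − (2p+5)/6 − 2k/3);
  Bartlett's sphericity test uses −(n − 1 − (2p+5)/6)·ln|R|. Which exact
  correction a given software package applies varies; these are the
  textbook forms and are stated here so results are comparable.
- Loadings are returned in the canonical orientation (ΛᵀΨ⁻¹Λ diagonal),
  then rotated. Varimax uses Kaiser row-normalisation; promax (default
  power 4) builds the target from the varimax pattern and returns the
  pattern matrix and factor correlation Φ with unit diagonal. Factor
  reflection is fixed so each column's dominant loading is positive.
- Retention is Kaiser's criterion (eigenvalues of R strictly > 1) only;
  parallel analysis is out of scope.
- Singular correlation matrices are ridge-regularised (R + 10⁻⁶I,
  renormalised) before inversion for KMO, with a warning.
- **Factor purity**: λ²(designated)/h², with h² the sum of squared pattern
  loadings. The designated factor defaults to the argmax-|loading| factor,
  with an explicit assignment map available for a-priori designations (the
  choice is left open because "designated" can be fixed either way).
  Zero-communality items are excluded from factor means. The planned
  comparison is a one-sided Welch t of the focal factor versus all
  remaining items pooled (Welch–Satterthwaite df); zero-variance groups
  get a 10⁻¹² variance floor so degenerate inputs yield a finite, huge
  statistic rather than 0/0.
- Recovery tests match factors by greedy |Tucker congruence| assignment
  with sign-flips; the analysis itself never needs a factor order.

## Confirmatory factor analysis

The three-factor AMI model: each retained item loads on exactly one
factor; factor variances 1, loadings, residual variances and the three
factor covariances free; no residual covariances. The default exclusion
set {AMI-2, AMI-6, AMI-8} is configuration (the items are excluded for low
indicator reliability), leaving 15 indicators and df = 120 − 33 = 87.

Estimation minimises the ML discrepancy with analytic gradients
(L-BFGS-B; seeded jittered restarts on non-convergence; residual variances
floored at 0.001 with a Heywood warning). The fit uses the **correlation
matrix**: the model family is closed under diagonal rescaling, so the
minimised discrepancy — and hence χ² — is identical to the covariance fit,
and the solution is already standardised. χ² = n·F_min (multiplier n, the
convention of the SEM software family these indices come from; switchable
to n − 1). The independence baseline on a correlation matrix has
F_B = −ln|R|. RMSEA uses the same n; its 90% CI solves the
noncentral-χ² coverage equations by bracketed root finding (tolerance
10⁻⁶). SRMR averages squared correlation-metric residuals over i ≤ j.
A robust (mean-adjusted) test statistic is not implemented: none of the
package's checks depend on it and the standard indices above are the
reported surface.

## Symptom networks

Edges are |Spearman ρ| (mid-ranks); the signed matrix is retained for
export colouring only. Community detection always runs on the full weight
matrix — the |ρ| ≥ 0.1 threshold exists only for export/visualisation.
Constant items get their edges zeroed with a warning.

**Louvain.** Greedy local moves over a seeded random node order (ties
broken by lowest community id; moving to an empty community is always a
candidate), iterated to convergence, then communities are aggregated into
super-nodes and the move phase repeats until a level makes no move. The
aggregation phase is the default because the local-move-only variant
provably stalls: on small random graphs it cannot merge whole communities,
violating the brute-force oracle bound (observed modal Q 0.066 versus an
exhaustive optimum of 0.107 on an 8-node graph). A `single_level=True`
flag restores the move-only variant; the two agree on every 18-item
planted network in the test battery, so results on AMI-scale networks do
not depend on the choice.

**Stability.** `stable_partition` runs Louvain `n_restarts` times with
sub-seeds derived from one master seed and returns the most frequent
canonical partition (communities renumbered by first appearance in item
order). Frequency ties break by higher modularity, then lexicographic
form. Module summaries report the modal a-priori domain (member count;
ties resolved by the central node's domain), domain purity, and the
central node (highest intra-modular strength; ties go to the first item in
scale order, logged).

## Lifespan scan

The Gaussian kernel (σ = 5) is truncated at the 10-year window (±5 years):
the finite window and the kernel width are reconciled by truncation, and
an untruncated kernel is available behind a flag. The weighted Spearman
correlation is weighted Pearson on mid-ranks computed over in-window
participants — the minimal construction that reduces bit-for-bit to the
unweighted network under uniform weights. The ESS gate uses the Kish
formula (Σw)²/Σw² with floor 30. A domain is "present" at a center iff
some module's modal domain equals it; a module split evenly between two
domains is assigned the central node's domain.

The purity ANOVA uses Type II sums of squares because cohorts contribute
unequal window counts; with empty Group × Domain cells the interaction is
dropped with a warning, and a constant response returns zero F rather
than 0/0.

The assessment-mode sensitivity split re-runs the full network pipeline
per mode (modes below n = 30 skipped), compares modal partitions by
adjusted Rand index, and localises disagreements with a per-item
concordance table after aligning modules by maximal member overlap.

## Pipeline

Per-stage seeds are SHA-256 hashes of (master seed, stage name) reduced
below 2³¹, so adding a stage never perturbs earlier stages' draws.
Every output file is recorded in a manifest with its SHA-256; reruns of
the same config are bit-exact. Config validation (input files exist,
required columns present) happens before any stage runs.

## Problem sizes used in the test battery

Chosen so the full suite runs in minutes on one CPU while leaving all
recovery margins wide: planted-partition recovery uses n = 4000
participants, 3 seeds, 200 restarts; factor recovery n = 5000 on the
60-item battery; CFA calibration 500 replicates at n = 500; lifespan scans
n = 6000 with 100 restarts per window; the brute-force modularity oracle
uses 20 random graphs of at most 8 nodes (exhaustive set-partition
enumeration). The restart default for real analyses remains 1000.

## Known limitations

- Polychoric correlations are not implemented; ordinal 0–4 responses are
  correlated product-moment (factor analyses) or by ranks (networks),
  which attenuates absolute loadings slightly but leaves structure,
  ratios, and partition recovery intact.
- Signed-modularity variants are out of scope; community detection uses
  absolute weights, so a strong negative correlation counts as a strong
  tie.
- No measurement-invariance testing, modification indices, higher-order
  factor models, graphical-lasso networks, or formal between-window
  network-comparison tests.
- The AES/DAS registry domain keys are block-level reconstructions from
  the instruments' published subscale structure, not verbatim reprints.
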