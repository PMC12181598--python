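# Methods

This note documents the models, statistical procedures and design choices
behind `frailmark`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The discovery model

The pipeline assumes the biology of early frailty leaves a signature in
skeletal-muscle gene expression that (a) differs between the sexes and
(b) correlates with timed lower-body function tests — 400-m walk (capped
at 900 s for non-finishers, the cap recorded as the score), 4-m gait, and
five-chair-stand, all in seconds with longer = worse. Analyses are
stratified by sex throughout; no covariate adjustment is applied at the
correlation stage (consistent with a small, age- and BMI-matched design).

### Candidate funnel

Gene sets are read from GMT (term, description, tab-separated members;
duplicates collapsed, malformed lines rejected with their line number).
The knowledge-base filter treats values within a facet as alternatives
(OR) and facets as conjunctive (AND), and requires one *single record* to
satisfy all five facets — population, sample type, validity, conditions,
roles. The single-record convention is a deliberate choice: curated
biomarker databases filter at record level, and allowing criteria to be
co-satisfied across different records of one gene would qualify genes no
single study supports. Category matching is case-insensitive after
whitespace normalization because the vocabularies are hand-curated.
Gene-set term ancestry (ontology graph traversal) is intentionally not
implemented; the GMT is taken as the authoritative term → gene mapping.

### Consensus correlation score

Pearson's r (linear association) and Spearman's ρ (rank association,
average ranks on ties) are computed per gene on the old participants of
one sex against one test's time, with pairwise deletion of missing values
and a minimum of 3 complete pairs. The combined score is
`sign · min(|r|, |ρ|)` when the signs agree and 0 otherwise (also 0 when
either coefficient is exactly 0 or undefined, e.g. constant expression).
The min-rule is the conservative consensus: a gene scores only as high as
its weaker line of evidence. `mean` and `pearson-only` modes are available
via `score_mode` for sensitivity analysis. Ranking is by |score|
descending with deterministic tie-breaks (|r| descending, then gene id);
zero-score genes are excluded from top-k lists rather than padded, since a
zero carries no directional information. Capped 400-m times participate
as-is (the cap is a legitimate worst score, and Spearman is unaffected by
its exact value). Expression is used as provided (normalized values); an
upstream log transform changes Pearson but not Spearman, and is left to
the caller.

### Overlap and direction consistency

Venn regions and unions are exact set algebra. The direction-consistency
statistic takes the union of both sexes' top-k entries, each evaluated at
the test that nominated it, compares combined-score signs between the
sexes, and reports the inconsistent fraction over pairs where both signs
are nonzero (zero/undefined scores are excluded from the denominator and
logged). Counting per (gene, nominating test) pair — rather than once per
gene — is a documented choice; a gene nominated by two tests contributes
twice. Heatmap matrices order rows by average-linkage hierarchical
clustering on Euclidean distance (the linkage/distance choice is recorded
here and in output metadata; rows with missing cells are excluded from
clustering and appended).

### Tertile validation

Tertiles are assigned within sex on one test's times, fastest first, with
a ceil(n/3)-first allocation (n=24 → 8/8/8, n=28 → 10/9/9) and stable
sample-id tie-breaks, so assignment is reproducible under permutation of
input order. Group comparisons are gated by per-group Shapiro–Wilk at
α = 0.05 (the gate threshold is a package default; groups with n < 3,
where the test is undefined, count as normal): all-normal routes to
one-way ANOVA with one-sided Dunnett contrasts of T2 and T3 against T1,
otherwise Kruskal–Wallis with one-sided Mann–Whitney U contrasts. The
omnibus statistic is reported but does **not** gate the contrasts; the
contrasts' own (Dunnett-adjusted or rank-based) p-values carry the
inference, which keeps the per-contrast type-I error interpretable and is
what the calibration tests verify (null rejection ≈ 3–4% at α = 0.05,
slightly conservative because of the Dunnett adjustment). Dunnett
p-values come from the multivariate-t formulation; its internal
quadrature is randomized, so the generator is pinned for run-to-run
reproducibility. The direction of the one-sided alternative is a required
input per marker, defaulting in the demo to the sign of the gene–phenotype
correlation that nominated the marker. Old-vs-young comparisons are
two-sided (t-test or Mann–Whitney U under the same gate); marker–marker
associations are pairwise-complete Pearson correlations.

### Predictive panels

The fittest/weakest split averages each participant's per-test ascending
ranks over the two sex-relevant tests and median-splits the composite
(odd n: the median participant joins the fittest half; composite ties
break by the first test's time, then sample id). The combination rule is a
package convention — documented here because several reasonable rules
exist. Logistic regression is fit by maximum likelihood (statsmodels) on
internally standardized features; if the fit separates (non-convergence or
runaway coefficients, |β| > 15 on the standardized scale), a weak L2
penalty (C = 1000) is applied and the result flagged. ROC/AUC is computed
in-sample — fit and evaluated on the same participants, matching the
small-cohort design this emulates — and every result carries an
`in_sample` flag; no cross-validation is attempted. AUC is the
tie-corrected Mann–Whitney U over n₁n₀ (identical to the trapezoid over
the ROC), and the test against chance is the two-sided normal
approximation to U with tie correction and no continuity correction.
Standardization does not change a single-feature AUC but does affect
multi-feature fits; it is always applied and recorded.

## The synthetic-data generator

The generator emulates the *structure* of a two-sex study of fit and
pre-frail older adults with young reference groups. Defaults: 24 old
females, 28 old males, 13+13 young (ages ~80 ± 3 and ~23 ± 2 years,
BMI ~26 and ~22.4 kg/m²), Fried scores drawn as 0/1/2 with probabilities
0.56/0.30/0.14 (≈44% pre-frail), and per-sex log-normal test-time
marginals moment-matched to means/SDs of 351.7/55.4 and 323.3/40.2 s
(400-m walk), 4.2/1.0 and 3.9/1.1 s (4-m gait), 14.3/4.4 and 13.3/3.7 s
(five-chair-stand) for females/males respectively.

A single latent "slowness" factor per old participant drives all three
log-times with loading √0.6 (pairwise test correlation ≈ 0.6 by default,
configurable; the true cross-test covariance of such cohorts is not
identifiable from published summaries, so this is a free simulation
parameter, not an estimate). Times above the walk cap are truncated to
exactly the cap, reproducing the scoring rule. Planted markers add
`a·z + ε` to one gene within one sex's old participants, where z is the
standardized planted-test time, ε is unit normal and
`a = target_r/√(1 − target_r²)`, so the population correlation equals
`target_r`; all other gene/sample cells are independent noise, which makes
cross-sex leakage and null calibration directly checkable. Serum markers
are log-normal with a per-SD-of-fitness log shift scaled so that adjacent
fitness tertiles differ by the configured number of SDs (the adjacent
tertile means of a standard normal differ by ≈1.09 SD), plus an old-young
shift. The mock knowledge base draws a Poisson number of records per gene
with configurable facet frequencies and saves its own ground truth
(described/qualified gene sets) via a naive per-record loop kept
independent of the vectorized filter. A mock 53-term gene-set collection
covers ~60% of the gene universe; planted genes are force-included in one
term and given one qualifying record so the demo funnel cannot silently
drop the ground truth — a convenience for demonstration, disabled by
leaving `force_qualify` empty.

What the generator does *not* emulate: read-level sequencing noise,
normalization artifacts, batch effects, gene–gene co-expression,
covariate confounding (age/BMI are independent of the latent factor), or
assay-specific serum measurement error. Passing tests therefore show the
*procedures* are correct and calibrated, not that real cohorts contain
recoverable signal of any particular strength.

## Numerical and testing choices

- All randomness flows from one integer seed; per-table generators are
  derived via crc32-hashed stream names so each table is independently
  reproducible, and two runs with the same config+seed are byte-identical
  (no timestamps in reports; fixed float formatting in TSVs).
- Correlation ranking is vectorized (centered matrix products; ranks via
  average-rank transform) and verified against per-gene scipy computation
  to 1e-12; sorting uses explicit deterministic keys.
- Test problem sizes (e.g. 25 seeds × 2020 genes × 24 participants for
  recovery; 500 replicates for statistical calibration; 200 random
  instances for oracle equivalence) were chosen to keep Monte-Carlo error
  comfortably below the asserted margins while the full suite runs in
  about half a minute.
- The heavy-tailed fixture for normality-gate routing uses log-normal data
  with log-SD 1.5, at which Shapiro–Wilk at n=8 per group detects
  non-normality in ≈99% of triplets.
- Degenerate inputs are first-class: constant genes and markers are
  flagged (never silently dropped into statistics), empty cohorts yield
  empty outputs, and strata with < 3 usable participants are skipped and
  listed in the run report.

## Known limitations

- In-sample AUCs are optimistic by construction; with ~26 participants per
  sex a noise panel averages ≈0.59, and the package reports but does not
  correct this (every ROC result is flagged `in_sample`).
- The Dunnett-adjusted one-sided path is mildly conservative per contrast
  (null rejection ≈3–4% at nominal 5%).
- The knowledge-base filter has no notion of record quality or effect
  size; a gene qualifies through any single matching record.
- No multiple-testing control is applied across genes at the correlation
  stage or across markers at validation; the ranking is a screen, not an
  inference.
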