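# Methods notes

This note records the statistical conventions, defaults, and design
choices of `pexvote`, in the spirit of a model-description appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scales and classes

- qPCR expression is analyzed on the −ΔCt scale (Ct_ref − Ct_gene,
  cycle units, monotone increasing in abundance). AUC and threshold
  voting are invariant under strictly monotone transforms, so the
  choice between −ΔCt and 2^−ΔCt cannot change any classification
  output; −ΔCt keeps thresholds in cycle units. A missing marker Ct is
  recorded as absent, never imputed; a missing reference Ct is an
  error naming the patient.
- The positive class for every response ROC is the non-responder
  (best overall response SD, PD, or NE); responders are CR and PR.
- Discovery counts are analyzed as log2 counts-per-million with a +1
  pseudocount. Differential expression uses Welch's t-test per BOR
  grouping (PR vs PD, PR vs SD/PD, PR/SD vs PD) rather than a
  negative-binomial model: only the selection thresholds, not the
  count law, are under test here, and the grouping contrasts are the
  pipeline's own significance machinery elsewhere.

## ROC conventions

- AUC is the tie-corrected Mann–Whitney probability computed from
  midranks. Confidence intervals use DeLong's placement-value variance
  with a normal approximation, clipped to [0, 1].
- Candidate thresholds are midpoints between consecutive distinct
  observed scores, with ∓∞ sentinels. For vote scores on levels k/m
  this makes reported thresholds values like 9/14 ≈ 0.643 (between 4/7
  and 5/7) and 7/12 ≈ 0.583 (between 3/6 and 4/6).
- The operating point minimizes (1−sens)² + (1−spec)²; exact ties are
  broken toward higher specificity (a non-responder-predicting score
  should err toward calling fewer positives).
- A positive call is strictly above the threshold for unfavorable
  markers and strictly below for favorable ones; equality never votes
  and a score exactly at a frozen cut labels the patient score-low.
  One strictness convention is used everywhere (votes, score cuts,
  confusion counts).
- ppv/npv come from confusion counts, or from Bayes' rule when an
  external prevalence is supplied:
  ppv = sens·π / (sens·π + (1−spec)(1−π)), npv analogous.

## Combination search

- Per-marker thresholds are fit once on the full training cohort and
  reused unchanged inside every combination and in any frozen
  application; there is no nested refitting.
- Default enumeration covers subset sizes 2..n (singletons are
  assessed as single rules elsewhere; size_min is configurable to 1).
- Ranking sorts by AUC descending, then fewer markers, then
  lexicographic marker names (genes alphabetical, NLR last) — a
  deterministic total order.
- Patients missing any member marker are excluded from that
  combination (with counts surfaced in results and the run manifest),
  never scored 0.
- The discovery filter takes the union of four criteria (per-grouping
  Welch p < α; |log2 FC| > cutoff; per-gene AUC > cutoff using the
  better orientation; literature allowlist). The rule reducing
  qualifiers to the top k is this package's declared convention —
  criteria count, then best AUC, then smallest p, then gene symbol —
  because a union filter does not by itself pick a unique top-20.

## Survival

- Kaplan–Meier with Greenwood variance; subjects censored at an event
  time count as at risk at that time (censoring ordered after events
  at ties). Two-year OS is the step function evaluated at 24 months.
- The two-group log-rank test uses the Mantel–Haenszel O−E statistic
  with hypergeometric variance, df = 1.
- The Cox model is fit for a single binary covariate by Newton's
  method on the partial likelihood, Efron tie correction by default
  (Breslow selectable for cross-checks), Wald 95% CI. The score
  statistic at β = 0 is exposed; on tie-free data it equals the
  log-rank chi-square, which the tests verify to 1e-8. Monotone
  likelihoods (complete separation in risk sets) are flagged rather
  than reported as converged. The Wald CI convention is a declared
  choice.

## Part-2 statistics

- Pearson correlation with the two-sided t-test on n−2 df; at n = 17 a
  sample r of 0.4785 sits exactly at p = 0.052.
- Fisher's exact test (two-sided, hypergeometric-sum definition) for
  the 2×2 plasma-vs-IHC concordance table.
- Median split: values at or above the median are "high", so odd n
  gives ⌈n/2⌉ high (17 → 9/8).
- Mann–Whitney U is exact for tie-free samples with combined n ≤ 12,
  otherwise a tie-corrected normal approximation; U equals
  n_a·n_b·AUC, an identity the tests check against the ROC module.
- IFN-γ signature scores are the mean over listed genes of
  patient-z-scored log2(TPM+1); genes missing from the matrix are
  dropped with a warning, constant genes contribute 0. The 6- and
  18-gene lists ship as editable config defaults drawn from the ICI
  biomarker literature, not as a claim about any specific cohort's
  exact lists. CPS, IHC calls and immune fractions are consumed as
  data; slide scoring and deconvolution are out of scope.

## Synthetic cohorts: what they emulate, and what not

Defaults are a stated world, chosen once:

- BOR mix CR/PR/SD/PD/NE = 7/12/25/55/5 out of 104.
- Marker −ΔCt is normal per class with shifts of 0.8–1.2 cycles
  (sd 1.5), giving per-marker AUCs ≈ 0.59–0.73; the NLR is lognormal
  with a class shift giving AUC ≈ 0.59 — both matching the
  discrimination range such panels show in practice.
- Survival is exponential per BOR class (CR 0.002, PR 0.004, SD 0.035,
  PD 0.066, NE 0.5 month⁻¹ — anchored to ≈49% OS at 20 months for SD,
  ≈21% at 24 months for PD, rapid death for NE), multiplied by
  exp(0.6 × standardized marker burden) so that score-high patients
  are enriched for early death; censoring is administrative at 36
  months. Exponential-with-frailty is the simplest model consistent
  with the survival ordering being emulated; no survival-time law is
  claimed beyond that.
- Discovery counts are lognormal-Poisson with ≥2-fold library-size
  variation and 6/5/6 PR/SD/PD samples; planted genes shift the PR
  group by a stated log2 fold change. Only the filter's behavior, not
  the count distribution, is under test.
- The part-2 cohort draws plasma and tumor HLA-E from a latent
  bivariate normal (default ρ = 0.7), thresholds a noisy tumor latent
  for the IHC call, elevates the activated-NK fraction in the
  high-tumor-HLA-E half, and omits tumor expression for 3 of 20
  patients. Treatment-naive plasma profiles carry a 4-cycle favorable
  shift (and −0.8 on log-NLR); the shift's defining property is that
  frozen part-1 combinations score these patients low, and its size is
  set so this holds robustly even for small (m = 4) frozen
  combinations whose low score cuts single stray votes could otherwise
  cross.

The generator does not emulate: inter-site batch effects, assay
detection limits / missingness mechanisms, correlated marker panels
(markers are independent given class), non-proportional hazards, or
real count dispersion. A green test therefore establishes that the
analysis machinery behaves correctly under the stated model, not that
the published cohort's numbers are reproduced — patient-level data for
that cohort are not publicly deposited.

## Numerical choices

- Newton iterations stop at |U| < 1e-10 (max 50, step clipped to ±5);
  |β| > 15 is treated as monotone likelihood.
- Degenerate ROC curves (constant scores) report sentinel thresholds
  with ppv/npv absent rather than failing.
- Exact binomial bands, closed-form exponential survival values and
  brute-force enumerations (pair counting, hypergeometric sums,
  permutations, exhaustive subset scans) serve as test oracles,
  independent of the implementation paths they check.

## Known limitations

- The log-rank p-value is asymptotic; at n = 8 it deviates from an
  exact permutation p by 0.03–0.07 on typical fixtures (permutation
  support of 70 points), which the acceptance suite surfaces honestly
  as a failing ±0.02 comparison; correctness of the statistic itself
  is established against an independent implementation to 1e-8.
- Only single-covariate Cox models are provided (no multivariable
  adjustment, proportionality diagnostics, or interval censoring).
- The combination search is exhaustive and intended for panels of
  ~10 markers or fewer (2^n growth).
- No multiple-testing correction is applied at the discovery stage,
  mirroring the screening character of that step.
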