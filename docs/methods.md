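# Methods

This note documents the models, estimators and design choices behind
`combiscreen`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or the acceptance script
does not itself compute.

## 1. Viability and killing effect

Optical densities from a CCK8-style plate are normalized per plate:

    viability(drug, dose) = (mean OD_treated − mean OD_blank)
                            / (mean OD_control − mean OD_blank)

Replicate ODs are averaged per condition **before** the ratio is taken
(ratio-of-means). This is more stable against blank-well noise than
averaging per-replicate ratios; the per-condition SD is propagated through
the linear normalization (SD of treated ODs divided by the control–blank
span). Plates whose mean control OD does not exceed the mean blank OD are
rejected as degenerate.

Raw viability may exceed 1 (growth stimulation) and is recorded as-is next
to a clipped companion column. The killing effect is

    KE = clip(1 − viability, 0, 1),

clipped because the combination index treats killing effects as
probabilities of independent events.

Bead-calibrated live counts follow the standard counting-bead ratio,
`cells = cell_events × beads_added / bead_events`. CIK cytotoxicity is
`((TC − TT)/TC) × 100` on live-tumor-cell percentages; negative values
(apparent stimulation) are returned unchanged rather than clipped, since
they are informative.

## 2. Combination index Q

For one dose pair,

    Q = KE(a+b) / (KEa + KEb − KEa·KEb),

the ratio of the observed combined killing effect to the Bliss
independence expectation (equivalently `1 − (1−KEa)(1−KEb)`; the test suite
checks this algebraic identity on randomized inputs). Classes: antagonism
(Q < 0.85), additive (0.85 ≤ Q ≤ 1.15), synergism (Q > 1.15). The
boundary values are assigned to "additive" because the conventional strict
inequalities attach to the outer classes. Q is undefined when both single
agents are inert (zero denominator); this is raised as an error rather than
returned as NaN.

Q is computed from replicate-mean killing effects, matching the one-Q-per-
dose-pair layout of published combination tables; per-replicate Q values
can be formed from the plate directly when dispersion is of interest (the
test suite does this to verify that the mean of noisy per-replicate Q
values converges to the planted interaction multiplier).

## 3. Differential expression

Counts are normalized to `log2(CPM + 0.5)`, where CPM uses the raw column
total. Adding the pseudocount *after* the CPM transform makes the value
exactly invariant to rescaling a sample's counts, and maps a zero count at
library size 10⁶ to log2(0.5) = −1.

The per-gene test is a two-sided Welch t-test on log2-CPM; logFC is the
difference of group means on that scale. This deliberately replaces a full
negative-binomial framework (edgeR/DESeq2-style dispersion estimation):
the pipeline's purpose is the *filter contract and the downstream overlap*,
not DE methodology, and the Welch test on variance-stabilized values is a
transparent, well-calibrated stand-in at the planted effect sizes the
generator produces. Genes with zero variance in both groups get p = 1 when
the group means are equal and p = 0 otherwise.

Benjamini–Hochberg adjustment is implemented directly (step-up, order
preserved) and is verified in the tests against both a brute-force
implementation of the definition and statsmodels. DEG calling uses strict
inequalities: up = {logFC > 2 and FDR < 0.05}, down = {logFC < −2 and
FDR < 0.05}; logFC exactly 2 is excluded.

## 4. Survival screen

Per gene:

1. **Median dichotomization.** Samples with expression strictly above the
   per-gene median are "high"; ties go to "low". Constant genes are
   skipped and logged. The median is used because published screens of this
   type rarely state the cutpoint; it guarantees balanced groups.
2. **Kaplan–Meier / log-rank.** The product-limit estimator over distinct
   event times; censored-only times shrink the risk set without creating a
   step. The "KM p-value" is the two-group log-rank test,
   `(Σ(O − E))² / ΣV` with the hypergeometric mean and variance at each
   distinct event time, referred to χ²(1).
3. **Cox model.** Univariate Cox fit on the binary high/low indicator
   (default, so the reported HR corresponds to the KM grouping; a
   continuous-covariate fit is available via `cox_covariate="continuous"`).
   Newton–Raphson on the partial likelihood with Efron tie handling,
   gradient tolerance 10⁻⁸, at most 50 iterations, Newton steps damped to
   |step| ≤ 5. Monotone likelihoods (complete separation of the event
   order) are flagged non-converged with |β| capped at 20. SE from the
   observed information; p from the Wald statistic. At β = 0 with Breslow
   ties the score statistic equals the log-rank statistic on untied data —
   the suite asserts this equality to 10⁻⁶ on every simulated cohort, and
   checks full fits against lifelines (which also uses Efron).
4. **Five-year gap.** |S_low(h) − S_high(h)| with h = 1825 days by default
   (configurable time unit); the step-function value at h, with the last
   value carried forward and the result flagged when a curve ends before h.
5. **Pass rule.** log-rank p < 0.001 AND Cox p < 0.001 AND gap > 0.10; all
   thresholds configurable. Passing genes are classed high-risk (HR > 1)
   or low-risk (HR < 1); HR exactly 1 is left unclassed and logged. Genes
   are screened marginally with no cross-gene multiplicity correction,
   mirroring the fixed-α design of the screens this reproduces.

## 5. Direction-matched overlap

Candidate targets = (up-regulated ∩ low-risk) ∪ (down-regulated ∩
high-risk): genes the treatment pushes *against* their prognostic
direction. Gene ids are matched exactly after case normalization; a gene
appearing in both DEG lists is rejected as inconsistent upstream output.
Reports are written with alphabetical gene ordering so identical inputs
give byte-identical files.

## 6. Synthetic-data generators

**Plates.** OD = blank + span·viability + N(0, noise_sd²), span fixed at
1.0 and blank at 0.05 — the simplest model that exercises blank/control
normalization. Single-agent viability follows a Hill curve
`effect(d) = emax·d^h/(ec50^h + d^h)` (0 at dose 0, non-decreasing).

**Combinations.** The true combined killing effect is
`clip(ψ·(KEa + KEb − KEa·KEb), 0, 1)`. ψ multiplies the Bliss expectation,
so noise-free downstream Q recovers ψ exactly wherever no clipping occurs;
ψ = 1 gives Q ≡ 1. Note that ψ also scales the zero-companion-dose rows
(the model applies ψ to the whole Bliss term), so ψ ≠ 1 grids have Q = ψ
even at dose 0 of the companion.

**Counts.** Gene abundances are log-normal (σ = 1), scaled to an expected
library size of 10⁶. Counts are gamma-mixed Poisson, i.e. negative binomial
with variance μ + φμ² (φ = 0.05 by default; 0 gives Poisson). Planted DE
genes multiply the treated-group mean by exactly 2^±lfc (default lfc = 4).
Replicates default to 3 per group — a typical minimal 3'-mRNA-seq design —
and to 5 in the end-to-end pipeline configuration.

**Survival cohorts.** Expression is i.i.d. standard normal per gene,
shifted by +6 onto a non-negative log2(FPKM+1)-like scale (clipped at 0;
the clip is a <10⁻⁸ event). Hazards use the centered values:
`h_i = h₀·exp(Σ_g β_g z_gi)` over the planted genes, with event times
exponential given the hazard, independent exponential censoring (rate 10⁻⁴
per day) and administrative censoring at 3650 days. Defaults: n = 400
patients, 500 genes, h₀ = ln2/1825 per day (five-year median survival),
|β| = ln 3 per unit of standardized expression — a cohort size, event rate
and effect size typical of TCGA-scale prognostic screens. With these
defaults roughly 55–60% of patients experience the event.

**Planting density matters.** All planted genes feed *one* joint
proportional-hazards model, so each additional independent prognostic gene
acts as unobserved frailty for the others and attenuates their marginal
(median-split) hazard ratios. The default end-to-end world therefore plants
8 prognostic genes out of 500 (~1.6%, comparable to the rarity of
p < 0.001 triple-criterion genes in real cohorts): 3 up-regulated +
protective, 3 down-regulated + hazardous (the candidate pattern), and 2
direction-mismatched genes that must never be nominated, plus 24 DE-only
genes. Planting several-fold more would not be more "realistic" unless
gene–gene correlation were modelled too, and it measurably erodes per-gene
marginal effects.

**What a green test does not establish.** The generators draw genes
independently (no co-expression, no pathway structure), use exponential
baseline hazards (constant hazard, exactly proportional groups), Gaussian
plate noise, and a single fixed library-size model. Green recovery tests
therefore establish correctness of the estimators and the filter chain
under the stated model — not robustness to correlated genes, non-PH
hazards, batch effects or count-model misspecification.

## 7. Numerical and design choices

- Seeds: every generator takes an integer seed; multi-stage runs derive
  per-stage seeds from one global seed via a seeded integer draw
  (all seeds < 2³¹).
- Tie-breaks: median ties to "low"; Q thresholds' boundary values to
  "additive"; BH preserves input order.
- Degenerate inputs: control ≤ blank plates, constant genes, both-agents-
  inert dose pairs, zero library sizes and event-free cohorts all raise
  informative errors or logged skips rather than propagating NaN.
- The CLI (`combiscreen`) is a thin click layer over the library; every
  command round-trips through the plain-text formats in `combiscreen.io`
  (tidy CSV plates, TSV matrices and survival tables, one-id-per-line gene
  lists, JSON summaries).

## 8. Known limitations

- No IC50 fitting, plate-effect or edge-effect correction.
- No Chou–Talalay or Loewe synergy models: only the Bliss-ratio index.
- The Welch-on-log2-CPM DE test is a documented simplification; its null
  calibration is verified empirically in the tests, but it is not a
  substitute for NB-based tools on real, small-n RNA-seq data.
- No multivariable Cox, time-varying covariates or interval censoring.
- Five-year survival differences are absolute, not relative.
- Candidate-gene counts from published TCGA-based screens depend on the
  specific data snapshots and are not reproduction targets here.
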