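# Methods

## Discovery arm

### Input harmonization

Each dataset arrives as a log2 expression matrix (probesets or genes ×
samples). Expression indices are assumed already log2-scaled and
normalized upstream; no re-normalization is attempted. When a probe map
is supplied, genes measured by several probesets are represented by the
probeset with the largest sample variance (ddof = 1, missing values
excluded); exact variance ties go to the lexicographically smaller
probeset id so collapse is deterministic. Gene symbols are matched
case-sensitively after whitespace trimming — alias resolution is a data
curation step outside this package. Datasets of one tissue compartment
are then restricted to their common genes (sorted intersection), which
defines both the meta-analysis substrate and the enrichment universe N.
Each dataset must contribute at least two case and two control samples.

### Effect sizes and pooling

The per-dataset effect is the bias-corrected standardized mean
difference d' = d·(1 − 3/(4N − 9)) with sampling variance
1/n₁ + 1/n₂ + d'²/(2N), N = n₁ + n₂ — the classic small-sample-corrected
SMD used in microarray meta-analysis. A gene/dataset cell with fewer
than two non-missing values in either group, or zero pooled variance, is
unusable in that dataset; a gene usable in no dataset is excluded (and
logged). Pooling uses the DerSimonian–Laird moment estimator: Q computed
with fixed-effect weights 1/s², τ² = max(0, (Q − (k−1))/c) with
c = Σw − Σw²/Σw, then μ̂ = Σw*y/Σw* with w* = 1/(s² + τ²),
se = (Σw*)^(−1/2), z = μ̂/se. A single usable effect passes through with
τ² = 0.

### Permutation FDR

The null distribution of z is built by shuffling case/control labels
independently within each dataset (group sizes preserved; one shuffle
per dataset per permutation, shared by all genes) and recomputing the
entire effect-size → DL → z pipeline. The null is pooled across genes
and is two-sided in |z|. For a gene with threshold t = |z_g|:

    q(g) = [ mean_b #{ |z_null_b| ≥ t } ] / #{ |z_obs| ≥ t }

clipped to [0, 1] and made monotone (q(g) = min over thresholds
t' ≤ t of the raw ratio), so q never increases with |z| and tied |z|
receive identical q. The mean (not median) exceedance count is used. No
π₀ estimate is applied, which leaves the estimator slightly conservative
under partial alternatives. B defaults to 1000 and is CLI-settable;
everything is reproducible from a single integer seed.

Under a label-exchangeable null the most extreme observed gene behaves
like one extra draw from the pooled null, so the probability that
anything passes q < 0.05 is ≈ 0.05; with 20 replicates the mean realized
FDP therefore estimates ~0.05 with a standard error near 0.05 — single
seed batches can legitimately land above 0.1.

### Fold change and selection

The per-dataset fold change is 2^(mean_case − mean_control) on the log2
scale; the overall FC is the geometric mean across the datasets where
the gene is usable for effect-size computation (keeping FC and effect on
the same support). Selection requires q < 0.05 and max(FC, 1/FC) > 1.5,
both strict. The FC gate is direction-agnostic because the downstream
enrichment looks for both activated and suppressed miRNAs; a direction
"split" mode runs enrichment separately on up- and down-regulated
subsets.

### Consensus targets and enrichment

Target databases are deduplicated within source first, so repeated rows
inside one database never count as independent support; a (miRNA, gene)
pair is retained iff found in ≥ min_support (default 2 of 3) distinct
sources. Each miRNA's consensus set, intersected with the measured
universe, is tested one-sided for over-representation among significant
genes: p = P(X ≥ k), X ~ Hypergeom(N, m, n) — the upper tail of the
Fisher exact table [k, n−k, m−k, N−n−m+k]. The universe is the measured
gene universe, not the union of database genes. miRNAs with no
in-universe target are skipped and logged. miRNA-level FDR is
Benjamini–Hochberg over the tested miRNAs; candidates (q < 0.05) are
ordered by p with ties broken by miRNA id, and compartment candidate
lists are unioned and deduplicated.

## Validation arm

* **qPCR quantification** — relative expression 2^(−ΔΔCt) with
  ΔΔCt = ΔCt_sample − ΔCt_calibrator. No endogenous reference miRNA is
  assumed (biological normalization is by urine creatinine); by default
  ΔCt is the raw Ct against a plate-calibrator Ct, and a reference-assay
  mode accepts full Ct pairs. Levels are log10(relative/creatinine), in
  log10 copies per mg creatinine; all downstream statistics act on this
  scale.
* **eGFR** — 2009 CKD-EPI creatinine equation, sex-specific κ and α.
  The published race coefficient is off by default (single-site East
  Asian cohort context) and available behind a flag for strict
  replication.
* **Progression** — renal replacement therapy always makes a progressor;
  otherwise any observed eGFR below half of baseline within five years
  does; a follow-up over five years with all observed values within 10%
  of baseline makes a non-progressor; everything between (e.g. 30%
  decline, or short follow-up) is indeterminate and excluded from
  progression analyses. All observed trajectory points inside the window
  are evaluated.
* **Nonparametric statistics** — Spearman rho is the Pearson correlation
  of mid-ranks with a two-sided t approximation (n − 2 df); two-group
  comparisons use Mann–Whitney U (exact enumeration when the pooled
  untied sample is at most 12, otherwise the tie- and continuity-
  corrected normal approximation); more than two groups use
  Kruskal–Wallis with tie correction. Pairwise group tests are reported
  unadjusted, matching the three-group baseline-table convention.
* **ROC AUC** — concordant/tied pair counting (equivalently the
  Mann–Whitney U identity), 95% CI by the Hanley–McNeil variance
  approximation clipped to [0, 1]. The progression outcome is the
  determinate progressor label by default; an event-within-5-years
  indicator is available since the source analyses do not pin this down.
* **Cox regression** — univariate proportional hazards with the Breslow
  tie convention, maximized by Newton–Raphson with step-halving;
  convergence at |score| < 1e-8 or a Newton step below 1e-7·(1 + |β|)
  (at n ≈ 200 the cumulative-sum score carries ~1e-8 of floating noise,
  so a pure score criterion can stall); at most 50 iterations. Constant
  covariates and monotone likelihoods (complete separation, |β| > 30 or
  se > 30) are flagged as non-converged with no estimate. Wald 95% CI
  and two-sided p. The implementation agrees with lifelines to ~1e-6 on
  shared fits and with a dense grid search of the partial likelihood to
  1e-4.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study,
not its biology:

* **Expression** — per gene and dataset a latent effect
  θ_gi ~ N(μ_g, τ²) (μ_g = 0 for non-DE genes, ±μ for implanted genes,
  signs split evenly at random); group means are offset ±θ·σ/2 around a
  gene baseline ~N(8, 1) with noise σ, so the population SMD equals θ
  exactly and parameter-recovery targets are analytic. Defaults mirror
  the study shape: 5 datasets per compartment, 10,000 shared genes, 20
  vs 20 samples. Note that a *label-exchangeable* null requires both
  de_fraction = 0 and τ = 0, since non-DE genes still receive
  θ ~ N(0, τ²).
* **Targets** — ~1,800 miRNAs by default with log-normally dispersed
  target-set sizes (σ_log = 0.8) around 6% of the universe — the pair
  density implied by ~1.1 M pairs over ~1,800 miRNAs and a 10,000-gene
  universe — floored at 1% of the universe (prediction databases list
  hundreds of targets per miRNA). Enriched miRNAs sample DE genes with
  an odds-weight multiplier; each pair gets a primary source and
  replicates into the other sources with the agreement probability, so
  the consensus filter removes a pair with probability
  (1 − agreement)^(sources − 1).
* **Cohort** — three groups (93 IgAN / 11 disease control / 19 normal
  control by default) with group-specific age, eGFR, proteinuria, Oxford
  MEST-C and medication distributions typical of a biopsy cohort; serum
  creatinine is obtained by inverting CKD-EPI so eGFR and creatinine are
  mutually consistent. Assay levels couple negatively to eGFR and
  positively to uPCR; progression event times follow an exponential
  proportional-hazards model whose linear predictor sums per-assay log
  hazard ratios over standardized levels (defaults give the three
  progression-associated markers log-HRs ln 2.13, ln 2.76 and ln 1.31,
  zero elsewhere). eGFR trajectories consistent with each outcome are
  simulated and the progression label is derived by the classification
  rule itself, not assigned. Ct values are constructed to round-trip
  exactly through the ΔΔCt transformation.

What the generator does **not** emulate: probe-level microarray noise,
batch effects, cross-gene correlation, realistic miRNA–mRNA regulatory
topology, informative censoring, or within-patient longitudinal
measurement error. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under its stated model, not
performance on real GEO or cohort data — the original study's headline
counts (884/67 genes, 11 miRNAs, AUC 0.749) depend on external data and
are out of reach by construction.

All generators are pure functions of (parameters, seed): identical calls
produce byte-identical files (fixed float format, seed recorded in file
headers).

## Calibration experiments and problem sizes

`uromir.benchmarks` (driven by `scripts/acceptance.py` and the
acceptance tests) runs:

* oracle agreement — hypergeometric upper tail vs exact integer
  enumeration over all margins N ≤ 60; ROC AUC vs brute-force pair
  counting and Spearman vs an independent mid-rank oracle on 200 random
  instances each; DerSimonian–Laird vs a plain-loop evaluation on ≤5
  studies (all at 1e-10/1e-12 or exact);
* global-null FDR calibration — 20 replicates of 5 datasets × 10 vs 10,
  2,000 genes, B = 200 (scaled from the production default of 1000);
* parameter recovery — 500 implanted genes at μ = 1.0, τ = 0.3 in a
  2,000-gene collection, 5 replicates (the DL moment estimator shows its
  known upward small-k bias: mean τ̂² ≈ 0.12 at τ² = 0.09);
* enrichment recovery — full discovery arm at the study's universe scale
  (10,000 genes, 10% DE as in the 884/~10,000 discovery, B = 100), 200
  miRNAs with 5 implanted at 5× odds, 20 replicates; smaller desk-scale
  universes leave 5×-odds target sets with too little information for
  reliable per-replicate recovery;
* Cox recovery — 200 replicates at n = 200, binary covariate, true
  log-HR 0.7, ~30% censoring, plus a null-covariate bias check;
* determinism — simulate → discover → validate executed twice from one
  configuration and compared byte-for-byte.

Replicate seeds are drawn from one master generator so a single integer
reproduces every experiment. The whole set runs in about a minute on one
CPU.

## Known limitations

* Between-study variance is estimated per gene from at most a handful of
  datasets; τ̂² is noisy and upward-biased at small k, and no
  Knapp–Hartung adjustment is applied (the source analysis used the
  plain Wald z).
* The permutation null is pooled across genes (SAM convention); genes
  with atypical variance structure inherit the pooled calibration.
* Only univariate Cox is provided by design; no multivariate risk
  modeling or external risk-tool scoring.
* The Mann–Whitney exact path is used only for small untied samples;
  tied small samples fall back to the corrected normal approximation.
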