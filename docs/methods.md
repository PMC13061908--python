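# Methods

## The generative model behind the synthetic studies

`rinsemet.synth` draws studies from a log-normal concentration model. For
sample *s* of participant *p*, feature *f*:

```
log x[s,f] = mu_f + b[p,f] + d_s + group effect + time offset
             + sex/age offsets + latent-pair term + eps[s,f]
```

* `mu_f` — baseline log concentration, drawn N(2, 1) per feature unless
  supplied.
* `b[p,f] = sigma_participant * (sqrt(w) g_p + sqrt(1-w) e[p,f])` —
  participant random effect with a shared scalar component: `g_p` is the
  participant's global intensity signature (weight
  `w = participant_shared_frac`, default 0.6) and `e[p,f]` feature-specific
  individuality. Default `sigma_participant = 0.8`.
* `d_s` — per-sample log dilution factor, shared by every feature of the
  sample (default SD 0.5). Ratios of two features cancel it exactly, which
  is the mechanism the whole ratio search exploits.
* `eps` — residual noise, default SD 0.3.
* **Latent pairs** (`latent_pairs`, default one pair): the two planted
  marker features additionally share a per-participant latent with SD 1.2,
  modelling same-pathway covariation. The pair's ratio cancels it; a ratio
  of one pair member against any third feature keeps its variance. Without
  this term, "half-planted" ratios (one marker over a lucky null partner —
  250 such candidates) out-compete the true pair in a large fraction of
  studies.
* **Planted effects**: the default study plants an opposed chronic pair
  (met001 +1.2, met002 −1.2 on the log scale in the high-stress group, so
  the ratio shifts by 2.4) and two acute time-course effects (met003 up
  after both tasks; the sIgA-like protein up after the first task).
  `PlantedEffect.group_time_points` restricts a group effect to chosen
  collection points for transfer experiments.
* **Censoring**: each feature has a fixed LOD placed at the 2 % quantile of
  its marginal distribution; cells below it are flagged and later replaced
  by LOD/5. Detection-decoy features get their LOD at the 75 % quantile so
  they fail the ≥ 50 % detection criterion.
* **Decoys**: configurable fractions of extra metabolite-class features
  violating exactly one inclusion criterion (defaults 10 %/5 %/5 % of the
  metabolite count for recovery/RSD/detection), used to verify the filter
  removes precisely the planted violations.

With the default variance components the participant share of log
concentration variance (ICC) is ≈ 0.65, so participant identity dominates —
the PCA view groups samples by participant, not by stress group, and the
per-group 95 % ellipses contain most samples without separating groups.

One seed drives named sub-streams (mu, participant, dilution, noise,
covariates, decoys, QC, latent) split from a `SeedSequence`, so e.g. adding
decoys never perturbs the core matrix.

**Calibration of the planted effect.** The defaults are a deliberately
strong signal: the planted ratio's population AUC is
Φ(2δ / (σ_r √2)) ≈ 0.98 with σ_r² = 2((1−w)σ_p² + σ_n²). This is set
against the winner's-curse background of the exhaustive search: the best of
8,001 null ratio candidates at n = 16+16 reaches an apparent AUC of ≈ 0.87
on average, so only a planted signal well above that is recoverable as the
top-ranked candidate across most seeds. Passing recovery tests therefore
demonstrates that the search machinery finds a strong planted marker; they
say nothing about the magnitude of real stress effects, which are surely
smaller and would sit inside the winner's-curse band.

**What the generator does not emulate**: correlated metabolite modules
beyond the single latent pair, batch/drift structure, circadian variation,
heavy-tailed or zero-inflated distributions, questionnaire or physiological
channels. Conclusions from synthetic tests transfer to real data only to
the extent that the log-additive model with multiplicative dilution does.

## Statistical stages and their conventions

* **QC filter** — metabolite-class features: recovery ∈ [70, 130]
  (inclusive; "within 100 ± 30 %" read as a closed interval), RSD ≤ 20,
  detected (above LOD) in ≥ 50 % of either group's samples pooled across
  time points (`detection_per_time_point=True` switches to per-point
  evaluation). Steroid- and protein-class features were measured on other
  platforms and bypass all three criteria.
* **Imputation** — censored cells ← min_quantifiable / 5; a feature
  censored everywhere triggers a warning (constant downstream).
* **z-score** — sample SD (ddof = 1); mean/SD stored per feature for exact
  inversion; constant features map to zeros with a warning.
* **Mann–Whitney** — exact enumeration when both n ≤ 8 without ties,
  otherwise the tie-corrected normal approximation with continuity
  correction (the permutation-oracle test bounds the approximation error
  below 0.01 at n = 20). At n = 16+16 the exact type-I rate of the
  p < 0.05 decision is 0.047; censoring ties push it slightly lower.
* **BH adjustment** — applied within each stratum's feature family
  (per time point, and separately for the per-participant-median screen).
* **Friedman** — tie-corrected statistic; an all-tied block returns
  (0, p = 1) rather than NaN.
* **Nemenyi** — |R̄_a − R̄_b| / √(k(k+1)/(6n)) referred to the studentized
  range (k, ∞) after √2 scaling. Checked conservative against the exact
  paired sign-flip permutation oracle in the informative region
  (permutation p ≤ 0.9); very near p = 1 the continuous approximation can
  sit marginally below the discrete permutation value.
* **Interval summary** — per interval, features with BH-adjusted Nemenyi
  q < α across the feature family within that interval; percent change is
  measured between cohort medians relative to the earlier point, and the
  highlighted subset requires |change| ≥ 30 %.

## Threshold models

* **Youden fit** — candidate cutoffs are midpoints between consecutive
  unique scores plus sentinels beyond the range; both orientations are
  searched. Tie-break: maximum J, then maximum specificity, then the
  smaller cutoff, then the high orientation — deterministic, so identical
  inputs give identical models. All-identical scores yield a degenerate
  J = 0 model with a warning.
* **Units** — the participant is the unit of cross-validation and
  resampling everywhere. Single-time-point strata use the participant's
  sample at that point; the pooled "All" stratum summarises each
  participant by the **median of their four per-sample scores** before
  fitting (this keeps accuracy defined over participants and prevents
  within-participant leakage; it differs from pooling all samples as
  independent observations, which would leak).
* **LOOCV** — cutoff and orientation are refit on each fold; held-out AUC
  uses the raw held-out scores under the single orientation of the
  full-data fit (per-fold orientation flips would make a pooled AUC
  incoherent). Since a threshold model's score is the raw feature/ratio
  value, held-out score ordering equals full-data ordering — LOOCV is
  informative for accuracy and F1, not for AUC ranking.
* **Bootstrap** — participants resampled with replacement within each group
  (stratified), LOOCV rerun per replicate with duplicates as distinct
  units (a noted source of slight optimism); percentile 2.5/97.5 CIs over
  the iterations; deterministic given the seed. The DeLong test is
  computed once on the full-data oriented scores, matching the convention
  of one p per reported model.
* **Search** — every feature, or every unordered pair as one canonical
  ratio (numerator/denominator in feature order; the reciprocal is
  redundant under threshold models). Candidates are first screened by
  full-data oriented AUC — an exact screen for held-out-AUC ordering, see
  above — and the `top_k` (default 50) receive the bootstrap-of-LOOCV
  evaluation and are ranked by mean AUC. This two-stage design makes the
  8,001-candidate search run in seconds without changing the ranking the
  full evaluation would produce.
* **Selection** — CI lower bounds strictly greater than the per-stratum
  thresholds (AUC 0.60; 0.65 for Post-WM; 0.50 for All; accuracy and F1
  0.50 everywhere).
* **Transfer** — the fixed full-data (cutoff, orientation) applied
  unchanged to other strata's participant scores.

## Covariate sensitivity

Logistic regression of group on the participant-level marker score with sex
and age group (decades: 20s/30s/40s) as categorical covariates, alongside
the marker-only fit. Wald 95 % CIs on the log-odds scale. With 16 + 16
participants and a strong marker, (quasi-)separation is likely: unstable or
non-converged ML fits fall back to a Jeffreys-prior (Firth-type) penalized
Newton fit and the `separation` flag is surfaced. Zero-information
(constant) columns are dropped and reported with coefficient 0. The raw
ratio is the default score (odds ratios are therefore scale-dependent); a
log transform can be applied by the caller.

## Known limitations

* **Selection-rule null specificity.** The search evaluates candidates
  chosen by apparent performance on the same cohort; LOOCV nested in the
  bootstrap is honest for a fixed candidate but cannot remove that
  selection optimism. Under a global null, the best of 8,001 ratio
  candidates averages apparent AUC ≈ 0.87 and retains cross-validated
  accuracy ≈ 0.79, so the CI-lower-bound rule almost never returns an
  empty set on null data. The acceptance suite keeps a failing test
  documenting this, and `scripts/acceptance.py` reports the measured null
  selection rate and winner's-curse magnitude. Users should treat the
  selected set as a ranked shortlist needing external validation, not as
  a false-discovery-controlled discovery set; restoring null specificity
  would require re-running the search inside every resample.
* Percent-change bases use cohort medians; features with near-zero medians
  give unstable percentages (guarded to NaN at exactly zero).
* The bootstrap percentile CI at 100 iterations has coarse tails; CI lower
  bounds are noisy at the ±0.02 level.

## Problem sizes in the test and acceptance suites

Calibration checks use Monte-Carlo sizes chosen to keep the whole suite in
the minutes range while leaving comfortable statistical margin: 1,000
instances for the AUC/Youden brute-force oracles, 500 seeds for Friedman
calibration, 200 synthetic studies for null screening rates, 50 studies at
n_boot = 25 for planted-marker recovery, and 2¹² exact sign-flip
enumerations for the Nemenyi oracle. The acceptance script uses the same
machinery at 100/25-seed scale.
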