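# Methods

`aromascreen` implements an odor-activity screening pipeline for GC–MS
volatile profiles of cooked fragrant rice: from relative contents
(µg/kg) and compound annotations to odor activity values, key
odor-active compound sets, multivariate structure, a pairwise
discriminating-volatile screen, and ROC marker validation. This note
records the models, conventions and deliberate design choices.

## Data model and censoring

Contents are replicate-level, non-negative, and may be *not detected*
(n.d.). n.d. is treated as censoring at the instrument's detection
capability, but for all downstream arithmetic — replicate means, totals,
OAV, fold change — an n.d. cell is valued 0, matching reporting
conventions in which undetected compounds contribute nothing. An
explicit "absent" flag (all replicates n.d.) is carried alongside so
present/absent contrasts stay distinguishable from small values.
Compound identity keys on a short `compound_id`, not the chemical name,
to tolerate synonym spellings. Files are comma-separated UTF-8 with
"." decimals; the only sentinel tokens are `n.d.` (censored content) and
`-` (absent optional metadata). Contents are stored at full precision;
the three-significant-figure convention applies to reporting only.

The packaged fixture describes 45 volatiles from four cultivars of
cooked medium-milled fragrant Simiao rice (labeled CV1–CV4), of which 29
carry documented odor thresholds in water and 17 carry a GC–O detection
flag. The content fixture holds cultivar-level values serialized as
single replicates; the pipeline detects this and skips replicate-level
statistics explicitly rather than emitting NaNs.

## Chromatographic support

* **Retention index.** For temperature-programmed GC the linear
  (van den Dool–Kratz) index is the standard and is used:
  RI = 100·n + 100·(rt − t_n)/(t_{n+1} − t_n) between the bracketing
  C_n and C_{n+1} alkanes. The index is piecewise linear with
  breakpoints exactly at alkane retention times and is never
  extrapolated outside the ladder — an out-of-range eluter is an error,
  not a guess.
* **Annotation matching** uses |RI_exp − RI_lit| ≤ tol with a default
  tol of 10 index units, which accepts all but one of the fixture's
  annotated rows (2-ethoxy-butane, at a 13-unit gap, is the lone
  outlier on a nonpolar column).
* **Semi-quantification.** content = (peak area / IS area) ×
  m_IS / m_sample, with the spike mass computed volumetrically
  (volume × concentration, no purity correction). The default spike —
  10 µL of 2-methyl-3-heptanone at 8.16 µg/mL into a 4 g sample —
  gives 20.4 µg/kg per unit area ratio. The sample mass is
  configurable because the quantitation basis (flour vs flour+drying
  salt) is a lab convention the software cannot decide.

## Odor activity

OAV_i = C_i / OT_i, computed on cultivar-mean contents against odor
thresholds in water (cooked rice is mostly water). Thresholds are
matrix-specific constants from the metadata table; no temperature or
matrix correction is attempted. Compounds without a documented
threshold have *undefined* OAV — not zero — and are excluded from both
numerator and denominator of every share, because a "total OAV" only
exists over thresholded compounds.

* **Key odor-active compound:** GC-O detected and OAV strictly > 1.0 in
  at least one cultivar.
* **Shared key odorant:** key compound with OAV strictly > 1.0 in every
  cultivar.
* **Share:** Σ OAV over a subset divided by Σ OAV over all defined
  compounds, per cultivar; `share_range` reports the min/max across
  cultivars.

All comparisons with 1.0 are strict; a boundary OAV of exactly 1.0
never qualifies. Both key-compound sets are monotone in content:
enlarging any content never shrinks them.

## Multivariate stack

All methods are implemented directly on numpy linear algebra so every
convention is explicit and outputs are bit-stable.

* **Scaling:** columnwise autoscaling with the sample (n−1) standard
  deviation, consistent with common metabolomics software defaults.
  Constant columns are flagged degenerate and zeroed, not dropped.
* **PCA:** SVD of the scaled matrix; explained-variance ratios are
  relative to total variance; sign fixed by making each loading
  column's largest-magnitude entry positive.
* **HCA:** Ward's minimum-variance agglomeration via the
  Lance–Williams recurrence on squared Euclidean distances; two
  singleton points merge at their Euclidean distance, and heights are
  non-decreasing (Ward is reducible). Merge ties break to the smallest
  cluster indices.
* **k-means:** Lloyd iterations from k-means++ starts, best of 50
  restarts by WCSS; nearest-center ties break to the lowest center
  index; an emptied cluster is re-seeded at the worst-fit point; seeds
  are mandatory inputs, never wall-clock. Compound profiles are
  clustered after standardizing each compound across cultivars
  (default k = 9).
* **OPLS-DA:** two classes coded ±1 and centered; each orthogonal
  round extracts w ∝ X'y, computes the loading residual
  w_o ∝ p − (w'p)w, and deflates X by t_o p_o'; the final predictive
  component is a one-component PLS1 fit of the filtered matrix, so
  n_ortho = 0 reproduces PLS1 exactly. Predictive scores are exactly
  orthogonal to every orthogonal score by construction. Default
  n_ortho = 1 for two-class comparisons.
* **VIP:** computed over the predictive component only — the dominant
  convention for OPLS-DA VIP scores — giving VIP_j = √(p·w_j²) with
  unit-norm weights, so Σ VIP² = p (equivalently mean VIP² = 1) for
  every fitted model. An orthogonal-inclusive variant (orthogonal
  components weighted by modeled X-variance) is available behind
  `include_orthogonal=True` and satisfies the same normalization.
* **Permutation validation:** class labels are permuted with a seeded
  generator and the model refit; p = (1 + #{R2Y_perm strictly
  exceeding R2Y_obs}) / (1 + n_perm). Strict exceedance matters at
  small n: a sampled permutation that reproduces the labeling (or its
  complement) ties the observed R2Y bit-for-bit, and with 3 vs 3
  samples such collisions occur with probability ~0.1 per draw, which
  would floor every p-value near 0.1 if ties counted. Under any
  continuous null the two counting rules coincide. R2Y is the
  permutation statistic; a leave-one-out Q² is not the default because
  3-replicate groups make k-fold schemes degenerate.

## Discriminating-volatile screen

Per pairwise comparison (reference cultivar vs target cultivar), each
compound gets: a two-sample t-test on replicate contents,
Benjamini–Hochberg FDR adjustment *within the comparison* over its
testable compounds, fold change FC = mean_target / mean_reference, and
VIP from the comparison's own two-class OPLS-DA (each volcano belongs
to one comparison). A compound is discriminating when all three strict
thresholds hold: VIP > 1.0, FC > 1.2 or FC < 0.8, q < 0.05.

Numerical conventions:

* The t-test defaults to the **pooled-variance (Student)** form. With
  triplicates, Welch's Satterthwaite correction can halve the degrees
  of freedom; after BH adjustment over ~30 testable compounds a clean
  two-fold effect at 5% replicate CV then misses q < 0.05 in roughly a
  third of runs, whereas the pooled test (df = 4) recovers it in ~98%
  (both rates measured by simulation in the test suite's conditions).
  Welch's variant remains available (`t_test="welch"`) for sensitivity
  checks.
* Both groups constant and equal → t = 0, p = 1. Both constant at
  different values → untestable (degenerate df). A compound absent
  from both groups has no contrast and stays out of the BH pool.
* FC with a zero reference mean and detected target is +∞ — a
  present/absent call that satisfies FC > 1.2; both means zero is
  untestable.
* The volcano display column log2fc uses a pseudocount of half the
  smallest nonzero mean in the comparison so present/absent compounds
  render; classification always uses the raw FC.
* BH-FDR is the textbook step-up, q_(i) = min_{j≥i} p_(j)·m/j capped
  at 1 (cross-checked against statsmodels in the tests).

Venn intersections collect, per compound, the comparisons in which it
discriminates; *discriminating key odor-active compounds* are the
intersection of any-comparison discriminating compounds with the key
odorant set.

**ROC validation** treats a compound's replicate contents as a
diagnostic score for target-vs-rest (the other cultivars' replicates
pooled as the negative class, e.g. 3 vs 9 with triplicates). The curve
is a threshold sweep over distinct scores with joint TP/FP steps at
ties, making the trapezoidal AUC equal the Mann–Whitney U statistic
over n₁·n₂ — an identity the tests verify against exhaustive pair
counting, alongside label-flip antisymmetry and invariance under
strictly increasing score transforms.

## Synthetic replicate generator

The generator emulates what the screen assumes of the unreleased
replicate-level data: triplicate log-normal noise around cultivar-level
means, a detection limit, and plantable fold-change effects.

* **Noise:** log-normal (concentrations are positive and right-skewed),
  parameterized on the arithmetic mean µ and CV so that
  σ²_log = ln(1+cv²), µ_log = ln µ − σ²_log/2 — the generating mean
  equals µ exactly, and cv = 0 degenerates to constant replicates. A
  Gaussian option exists for t-test calibration studies.
* **Defaults:** cv = 0.05 (small enough that FC > 1.2 effects are
  nearly always significant at n = 3), n_replicates = 3, detection
  limit 1.0 µg/kg — just below the smallest fixture contents (≈1.2).
  The replicate CV of real GC–MS contents is a configuration default
  here, not an estimate.
* **Seeding:** one master seed; each (compound, cultivar) cell draws
  from a substream keyed by a stable CRC32 hash, so adding or removing
  a compound never shifts another cell's draws. Identical specs give
  bit-identical matrices.
* With cv = 0 on the fixture means, the generator is the identity on
  means and the full pipeline reproduces every fixture-derived result
  exactly.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: between-compound correlation (shared
precursor pools, co-eluting peaks), between-replicate batch effects,
heteroscedasticity beyond a constant CV, soft detection limits, or
chromatogram-level artifacts. Recovery and false-positive-rate results
are calibration statements about the screen's mathematics under the
stated noise model, not about any instrument.

## Problem sizes and runtime choices

Simulation-based tests run at the conditions above (triplicates, 5%
CV): parameter recovery over 100 seeds, null calibration over 200
seeds, permutation tests at n_perm = 99–199, oracle comparisons on
5–20-point instances. These sizes make the entire suite run in about a
minute on one core while keeping binomial assertion bounds meaningful.
The pipeline itself accepts n_permutations up to whatever the user
funds (the classical choice is 1000).

## Known limitations

* Thresholds vary across literature sources and matrices; OAVs inherit
  that uncertainty wholesale.
* Perceptual mixture interactions (synergy, masking) are out of scope;
  OAV shares are additive by construction.
* Semi-quantification against a single internal standard ignores
  response-factor differences between compounds.
* The screen's VIP is model-dependent: it comes from the pairwise
  OPLS-DA, so compounds can change status if comparisons are pooled
  differently.
* With triplicates, variance estimates are weak; the pooled t-test
  assumption (equal group variances) is what buys back power, and it
  is reasonable at matched concentration scales but not under strong
  heteroscedasticity — use `t_test="welch"` to check sensitivity.
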