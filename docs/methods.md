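# Methods

## Model

A cohort of P microbiome samples over K taxa is modelled as independent
Dirichlet-multinomial (DM) draws. In the (π, θ) parameterization, π is the
vector of expected taxa frequencies and θ ∈ [0, 1) the overdispersion. The
equivalent Dirichlet concentration is α_k = π_k(1−θ)/θ with total
A = (1−θ)/θ, and the log-pmf of a count vector x with N = Σx_k reads is

    log N! − Σ_k log x_k!
    + log Γ(A) − log Γ(N+A) + Σ_k [log Γ(x_k+α_k) − log Γ(α_k)],

evaluated with log-gamma throughout. θ = 0 is the multinomial limit and is
handled as an explicit branch (α is infinite there). Taxa with π_k = 0 are
legal — they arise when groups are aligned on a shared taxon list — and
contribute probability one iff their count is zero.

The variance of a taxon's count at depth N is inflated over multinomial by
the design effect 1 + (N−1)θ, so the variance of a per-sample *frequency* is
bounded below by θ·π_k(1−π_k) no matter how deep the sequencing: reads
cannot substitute for subjects. This single fact drives most of the
package's design-stage behaviour (see Power below).

Sampling is the exact two-stage construction: a Dirichlet(α) draw per
sample, then a multinomial at that sample's read depth (θ = 0 skips the
first stage). It is vectorized over samples and deterministic given a seed;
long simulation loops pass a single `numpy` Generator (or spawned
`SeedSequence` children) so replicates are independent but reproducible.

## Estimation

* **π̂ (moments)** — the read-weighted average of per-sample frequencies,
  i.e. column totals over the grand total. Exactly on the simplex.
* **θ̂ (moments)** — the pooled between/within mean-square ratio
  (Weir–Hill style). Per taxon, with p_ik = X_ik/N_i and pooled p_k:
  S_k = Σ_i N_i(p_ik − p_k)²/(P−1), G_k = Σ_i N_i p_ik(1−p_ik)/(N−P),
  n_c = (N − Σ_i N_i²/N)/(P−1), and
  θ̂ = Σ_k(S_k−G_k) / Σ_k(S_k+(n_c−1)G_k). A negative ratio means the data
  are *under*-dispersed relative to multinomial; it is truncated to 0 (the
  raw value is kept as a diagnostic) because every downstream variance
  formula needs θ ≥ 0.
* **MLE** — numerical maximization of the DM log-likelihood in
  unconstrained coordinates (additive log-ratio of π, logit of θ; both
  clipped at ±30 to keep the map invertible), started from the moment
  estimate and from a uniform start, with a derivative-free pass followed by
  a BFGS polish. Convergence tolerance 1e-8 on the log-likelihood. The
  returned fit is never worse than the moment fit: if the optimizer fails to
  beat it the moment estimate is returned flagged as unconverged. Taxa with
  zero total count are held at frequency 0 rather than being pushed down a
  log barrier. Samples with zero reads are dropped with a warning before any
  estimation.

## Hypothesis tests

**Overdispersion (multinomial vs DM).** T = Σ_i Σ_k (X_ik − N_i π̂_k)² /
(N_i π̂_k), the Pearson homogeneity statistic with π̂ the pooled moment
estimate. With equal reads per sample the null is χ² with (P−1)(K−1) df.
With unequal reads the null is a moment-matched scaled chi-square: given the
null mean μ and variance σ² of T, reject on T/c against χ²_ν with
c = σ²/(2μ), ν = 2μ²/σ². The analytic moments used are μ = (P−1)(K−1) and
σ² = Σ_i Var[T_i | π̂, N_i] − 2(K−1), where Var[T_i | π, N] is the *exact*
variance of a known-π Pearson statistic from multinomial factorial moments;
the subtracted 2(K−1) is the variance absorbed by estimating π̂, chosen so
the approximation collapses onto the classical χ²_{(P−1)(K−1)} null as
reads grow. A parametric-bootstrap alternative (B = 2000 multinomial
datasets at the fitted π̂ and the observed N_i) is available via
`null_moments="bootstrap"` and agrees with the analytic moments on
simulated data; the analytic route is the default because it is
deterministic and fast. Null calibration of the default is verified by
simulation in the test suite (rejection fraction within 3 binomial SEs of
5% at α = 0.05 for 24 samples with reads uniform on 800–1200).

**Generalized Wald tests.** All three frequency-vector tests are quadratic
forms d′ Σ̂⁺ d with Σ̂ the estimated covariance of the difference d and ⁺
the Moore–Penrose pseudo-inverse (singular values below 1e-12 of the
largest are treated as zero). The simplex constraint makes Σ̂ rank K−1, so
the pseudo-inverse—not an ordinary inverse—is the correct tool and the
chi-square df equals the rank.

* *One-sample* (H₀: π = π₀): d = π̂ − π₀ and Σ̂ = C·(diag(π₀) − π₀π₀′) with
  C = Σ_i N_i(1+(N_i−1)θ̂)/N², the DM variance of π̂. Σ̂ is evaluated at π₀
  rather than π̂ because the null distribution is computed under H₀ (the
  choice is invisible to first order; under the null the two coincide).
  df = rank(Σ̂) = K−1 when all π₀_k > 0.
* *Two groups* (H₀: π₁ = π₂): per group m, Σ̂_m = C_m·(diag(π̂) − π̂π̂′)
  around the *pooled* estimate π̂ (read-weighted over both groups), with
  C_m from the group's own reads and θ̂_m — groups may have different
  dispersions. Statistic (π̂₁−π̂₂)′(Σ̂₁+Σ̂₂)⁺(π̂₁−π̂₂), df = K−1.
* *J groups* (H₀: all π_m equal): weights W_m = Σ̂_m⁺, weighted grand mean
  π̄ = (ΣW_m)⁺ ΣW_m π̂_m, statistic Σ_m (π̂_m−π̄)′W_m(π̂_m−π̄),
  df = (J−1)(K−1). For J = 2 this reduces algebraically to the two-group
  statistic, which the tests assert numerically.

Taxa absent from every group in a comparison are removed before inversion
(pseudo-inverting an exactly-zero direction would silently change the df);
K in the df formulas is the post-removal count. Group θ̂_m estimates are
truncated at 0 (multinomial fallback).

**Pairwise follow-up.** After a J-group omnibus rejection, all J(J−1)/2
two-group tests run with Bonferroni adjustment p_adj = min(1, p·#pairs).
When rare-taxa pooling is in play it is recomputed per pair, since the
pooled set depends on which groups are compared. The omnibus-then-pairwise
gate is the default workflow in the CLI but can be forced either way — it
is a convention, not a statistical requirement.

## Rare-taxa pooling and RAD

Chi-square approximations degrade with many near-empty cells, so taxa whose
weighted-average frequency over *all* groups combined falls strictly below a
threshold (default 1%) are summed into a single "Pooled taxa" column
appended last. Strictness at the boundary means an exactly-1% taxon is
retained. Pooling is computed jointly and applied identically to every
group, keeping taxon sets aligned; per-sample read totals are unchanged.
Dropping instead of pooling is available (`drop=True`) but not the default.
A minimum-prevalence criterion (fraction of samples containing the taxon) is
deliberately not part of the rule: frequency only.

Rank abundance distribution (RAD) analysis sorts each sample's counts in
non-increasing order and replaces taxon labels by positional ranks. Ties
keep their original order (stable sort), making the transform deterministic
and idempotent. After ranking, the same DM machinery applies; the tests then
compare community *structure* (richness/evenness) rather than membership,
with a corresponding loss of power when the real difference is in labels.

## Effect size and power

**Effect size.** The modified Cramér's φ is computed on the J×K table of
group frequency vectors with equal group masses:
φ = sqrt([Σ_mk (π_mk − c_k)²/(J c_k)] / min(J−1, K−1)), c_k the unweighted
mean frequency. It is 0 iff all groups share one π, at most 1 (attained by
disjointly supported groups), and depends on the π vectors only — subject
counts and read depths cannot move it. The result is labelled
`variant="cramer_equal_mass"` so a differently-weighted variant could be
added without breaking the interface.

**Power.** Monte-Carlo throughout: for each (subjects/group, reads/sample)
grid point, simulate `n_reps` studies from the stated group parameters, run
the requested test (optionally after RAD ranking and/or pooling), and report
the rejection fraction at level α with its binomial standard error
sqrt(p(1−p)/n_reps). Default n_reps = 1000 keeps the SE at or below ~1.6
points near 50% power. Reads are fixed per grid point (per-sample read
vectors are supported by the sampler for users who want depth variation).
Subject counts are per group, not total. With identical group parameters
the routine estimates the *size* of the test, which is how the calibration
checks are run. Sample-size search doubles the per-group count from 2 until
the power curve crosses the target (default 80% at α = 0.05), then bisects;
each size is evaluated once with a seed derived from the root seed and the
size, so the search is deterministic and monotone up to Monte-Carlo noise.
An unreachable target (e.g. zero effect, where power ≈ α) raises with the
power achieved at the cap.

Qualitative power laws verified by simulation in the test suite: power
increases with subjects and with φ, decreases with θ, and for
taxa-composition tests is approximately flat in reads beyond a few hundred
per sample — deeper sequencing cannot reduce between-subject variance, only
more subjects can.

## Synthetic data: what it does and does not emulate

All test inputs are produced by the package's own DM sampler, at sizes
mimicking oral-microbiome cohorts: K of 3–12 taxa (after pooling), π vectors
with a dominant taxon, θ in 0.005–0.1, 500–50 000 reads per sample, 10–50
subjects per group. Within this world the DM model is *exactly* true, so
the calibration results certify the statistics' internal correctness — they
do not certify that real microbiome counts are DM-distributed. Real data
features not emulated: taxon correlation structure beyond what a single
Dirichlet induces, zero inflation in excess of DM zeros, read-depth
distributions with heavy tails, and classification error upstream of the
count table. Problem sizes in the checked-in suites (1000 replicates for
calibration, 500 for power curves, 200×5000-read tables for recovery) were
chosen to make Monte-Carlo bands tight enough to be meaningful while keeping
the suite quick to run end to end.

## Numerical notes and limitations

* Pseudo-inverse cutoff 1e-12 (relative); df decisions use the same cutoff,
  so statistic and df cannot disagree about the effective dimension.
* Counts within 1e-6 of an integer are accepted and rounded on input
  (export artifacts); anything farther is rejected, as are negative counts,
  with the offending sample/taxon named.
* Identical group inputs give statistic exactly 0 and p = 1.
* The moment-matched overdispersion null is an approximation; for very few
  samples with wildly uneven, shallow depths prefer
  `null_moments="bootstrap"`.
* Standard errors / confidence intervals for (π̂, θ̂) are not provided.
* Tests comparing θ across groups, joint (π, θ) tests, and a DM
  goodness-of-fit test are out of scope, as are closed-form power
  approximations (power here is Monte-Carlo by design) and DM mixture
  modelling.
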