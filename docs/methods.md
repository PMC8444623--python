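# Methods

`memnet` implements a phase-resolved analysis of memory-task functional
connectivity in an amyloid-positive AD cohort versus amyloid-negative
controls, together with a seeded synthetic-cohort generator that carries
the planted structure every downstream test checks against. This note
describes the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic validation does and does not show.

## Analysis model

**Connectivity.** For each subject and memory phase (encoding,
maintenance, retrieval), functional connectivity between nodes *i* and *j*
is the Fisher z-transform of the Pearson correlation of their node time
courses, z_ij = atanh(r_ij), with r clamped to ±(1 − 1e−7) so z stays
finite and the diagonal fixed at 0. Negative weights are zeroed *only* on
the community-detection path; all group comparisons and mean-connectivity
summaries use signed z. Mean within-network connectivity averages z over
unordered node pairs inside a network (diagonal excluded); between-network
connectivity averages over all cross pairs of two disjoint sets.

**Data-driven networks.** The control group's maintenance-phase z-matrices
are averaged, restricted to the 136 nodes of the five cognitive a-priori
networks (limbic, DMN, DAN, VAN, FPN), thresholded at zero, and clustered
by weighted Louvain modularity maximization
(Q = (1/2m) Σ_ij [w_ij − γ k_i k_j / 2m] δ(c_i, c_j), γ = 1 by default).
Louvain is the igraph C multilevel implementation; stochasticity across
runs is injected by randomly permuting node order before each run, and a
single `louvain()` call keeps the best-Q result over 10 permutation
restarts. Because a single greedy run can miss the optimum on small
graphs, the restart count was chosen so that ≥90% of small random
instances reach the exhaustively verified maximum. Robustness to the
remaining stochasticity comes from consensus clustering: 100 runs per
iteration, node-pair agreement matrix, entries below τ = 0.5 zeroed,
agreement re-clustered until all runs coincide (the runs/τ values are the
consensus method's common defaults; the source analysis does not report
its own). Communities are labelled by descending size, so "Network 1" is
always the largest. Isolated nodes become singletons rather than errors.

**Group statistics.** Per-network, per-phase mean connectivity is compared
between groups with a two-sided label-permutation test,
p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (1 + N_perm), default 10,000
permutations. The pooled values are sorted before permuting so the
Monte-Carlo null depends only on the value multiset, which makes the
p-value exactly invariant to swapping group labels at equal group sizes.
Edge-wise inference inside Network 1 follows the network-based statistic:
per edge, an OLS fit of z on (intercept, group, age, sex) gives the group
t (sign convention: positive = controls > AD); edges with |t| above a
primary threshold — by default the |t| of two-sided p = 0.01 at the
design's residual df, with ties included — are segregated by sign and
decomposed into connected components; family-wise p-values come from the
permutation null of the maximal component *edge count*, permuting group
labels while covariates stay attached to subjects (plain label
permutation, not Freedman–Lane, matching the NBS v1.2 behaviour the
analysis emulates). Reduced nodes are the endpoints of significant
controls-greater-than-AD components. Cross-phase comparisons of
reduced-node counts use the Pearson chi-square on the 2×2 table, df = 1,
*without* continuity correction — the convention is pinned by reproducing
the printed p = 0.179 for 16/56 vs 10/56 exactly.

**Sample entropy.** SampEn(m, r) = −ln(A/B), where B counts distinct
pairs of length-m templates within Chebyshev distance r and A the same
for length m + 1; both counts range over the first N − m templates and
exclude self-matches, so A ≤ B are integers. Defaults m = 2 and
r = 0.2 × SD, with the SD pooled over all node time courses of the
subject's phase (the per-node scope is available). 0.2 is the field's
standard tolerance factor; the SD scope is declared, not inferred. When
no (m+1)-pair matches (A = 0) the statistic is infinite; `sample_entropy`
returns the +inf sentinel, and the group comparison caps such values at
the resolution ceiling −ln(2/[(N−m−1)(N−m)]) so permutation tests stay
finite. Node-wise group comparison reuses the permutation mean test at
raw p ≤ 0.05 (no multiplicity correction by default, matching the source
analysis; Benjamini–Hochberg can be applied downstream from the emitted
table).

**Mediation.** The amyloid → connectivity → memory hypothesis is the
linear-Gaussian no-interaction mediation model: M = aT + ΓX + ε and
Y = c′T + bM + Γ′X + ε with T = global cortical SUVR (continuous, not a
dichotomised Aβ status), M = mean Network-1 retrieval connectivity,
Y = memory score, X = age, sex, education in both models. ACME = a·b,
ADE = c′, total = a·b + c′ (additivity holds to machine precision, and
the total equals the treatment coefficient of the reduced model Y ~ T + X
by the Frisch–Waugh identity). All variables are z-scored first, so
effects are standardized. Uncertainty: nonparametric bootstrap over
subjects (default 10,000 draws) with BCa intervals (bias correction from
the bootstrap CDF at the point estimate, acceleration from the jackknife);
a percentile option exists for speed in simulations. Bootstrap p-values
are the doubled tail fraction of draws crossing zero. Resamples with zero
treatment/mediator variance or a singular design are skipped and counted.
The analysis pools both groups, the generator's group structure included.

## Synthetic cohort

The generator emulates the study conditions: 36 AD + 36 controls, 200
cortical nodes carrying the seven canonical network labels, TR = 3 s.
Per-phase volume counts are not reported by the source; the defaults —
encoding 100, maintenance 40 (= 2 min at TR 3 s), retrieval 120 — follow
the task timing and are configurable.

Signals are temporally white multivariate Gaussians with an
equicorrelation block per planted community (default within_r = 0.45,
between_r = 0.05; the separation 0.4 is the regime in which community
recovery is expected to be exact). The planted communities follow the
a-priori labels: community 1 = DMN + limbic (56 nodes), community 2 =
FPN + DAN (50), community 3 = VAN (30), with visual and somatomotor nodes
as excluded communities 4 and 5. In the default regime
0 ≤ between_r ≤ within_r the block covariance is realized exactly by a
factor construction, x_i = √b·g + √(w_c − b)·f_c + √(1 − w_c)·e_i; other
regimes fall back to a Cholesky draw of the (shrinkage-repaired) block
matrix. Shrinkage toward the identity proceeds in convex steps of 0.05
and errors after 19 steps, naming the offending block.

Planted effects, all configurable:

* **Group deficit.** AD subjects' community-1 within-correlation is
  reduced by `ad_within_delta` (default 0.2) in maintenance and retrieval
  only — encoding is null by construction, giving the phase-specific
  pattern the pipeline must recover.
* **Low-entropy nodes.** Five community-1 nodes get AR(1)-recoloured
  *idiosyncratic* noise (φ = 0.9, variance preserved) in AD subjects.
  Recolouring only the idiosyncratic component leaves every planted
  cross-correlation untouched; recolouring the whole signal would scale
  cross-correlations by √(1−φ²) and plant a spurious all-phase FC
  deficit. The resulting lag-1 autocorrelation is (1 − w)·φ ≈ 0.5 —
  enough to depress SampEn clearly at the default phase lengths.
* **Mediation path.** With z-scored SUVR (controls ~ N(1.1, 0.1²), AD ~
  N(1.4, 0.15²), truncated positive — plausible florbetapir scales, free
  generator parameters, not claims), a latent standard-normal connectivity
  propensity ζ = a·z_SUVR + √(1−a²)·η shifts the subject's community-1
  retrieval correlation by `fc_subject_sd`·ζ (default 0.12, a plausible
  between-subject FC spread), and the memory score is
  20 + 4·(c′·z_SUVR + b·ζ + σ_y·ε). The true ACME is a·b on the
  standardized scale. Defaults a = −0.25, b = +0.3, c′ = −0.25 give
  ACME = −0.075, the sign and magnitude regime of the emulated findings.
  Because the analysis measures ζ only through finite-length FC, the
  estimated standardized paths are attenuated by the measurement-noise
  share of the mediator's variance; at the defaults the structural spread
  (≈0.15 in z units) dominates the sampling noise of a 120-volume,
  1540-edge mean (≈0.03–0.05), keeping the attenuation of a·b within a
  few percent — which is why the tight ±0.02 bias check runs on directly
  generated (T, M, Y) triples and the cohort-level check asserts CI
  coverage instead.

Age (N(69, 7²) truncated 50–90), education, and sex (Bernoulli 0.5) are
drawn independently of everything else; the emulated cohort was matched,
so the covariates are pure nuisance dimensions here. Ground truth
(partition, expected within/between z, true ACME, entropy nodes) is
written next to the cohort and never read by analysis code.

**What the synthetic validation does not show.** Real BOLD is temporally
autocorrelated (so effective degrees of freedom are lower than volume
counts), non-Gaussian, subject to motion and physiological structure, and
its community structure is not exactly block-constant. Passing the
recovery and calibration suites therefore demonstrates correctness of the
statistical machinery under its own assumptions, not expected performance
on patient data; the emulated study's headline numbers depend on its
(non-deposited) cohort and are not reproduction targets.

## Preparation conventions

Denoising operates on the full run and only then splits phases (the
conventional order; the source does not state its own): confound
regression (intercept always included; residuals orthogonal to every
regressor; rank-deficient designs rejected with the collinear columns
named), linear detrend, zero-phase 2nd-order Butterworth band-pass
0.008–0.09 Hz applied forward-backward so phase boundaries are not
shifted. Volume indexing is 0-based half-open; event tables in seconds
convert by floor(start/TR), ceil(end/TR). Task-condition regressors are
accepted as pre-computed confound columns; building them would need an
HRF model, which is out of scope. Note that at TR = 3 s the Nyquist
frequency is 0.167 Hz: continuous-time components above it (e.g.
0.25 Hz) alias into low frequencies before any filtering, so the filter's
stopband is only meaningful below Nyquist.

## Numerical and reproducibility choices

* Every stochastic stage draws its seed from the master seed via
  `numpy.random.SeedSequence`; reruns of the pipeline are byte-identical,
  and igraph's global RNG is pinned per Louvain run.
* Suprathreshold ties (|t| equal to the threshold) are included.
* Per-edge GLMs and bootstrap refits are batched (normal equations via
  einsum) so the stated permutation and bootstrap counts run in minutes
  on one CPU; the NBS null typically costs ~1 ms per permutation at
  72 subjects × 1540 edges.
* The pipeline's problem sizes — 36 + 36 subjects, 200 nodes, 100
  consensus runs, 2,000–10,000 permutations, 5,000–10,000 bootstrap
  draws — are the package's default study conditions; recovery tests use
  20 seeded replicate cohorts.
* `config_hash` identifies the analysis configuration; the output
  directory is excluded so reruns into different locations compare equal.

## Known limitations

* No partial-correlation, tangent-space, or dynamic connectivity; no
  multilayer modularity (clustering is on the group-average matrix only).
* Mediation offers no sensitivity analysis for sequential ignorability
  and no treatment×mediator interaction.
* The NBS default threshold (edge-level p = 0.01) is a convention; the
  emulated analysis did not report its primary threshold, so absolute
  component counts are threshold-dependent and not comparable across
  settings.
* SampEn tolerance scope and factor are declared defaults; results are
  sensitive to both, which is why they are explicit configuration.
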