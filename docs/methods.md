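# Methods

This note documents the models, conventions and numerical choices behind
`posturestats`, and what the synthetic-data generator does and does not
emulate.

## Synthetic-study generator

The generator emits the three raw-data modalities the pipeline consumes,
as a pure function of a `SimConfig` and its seed (three independent
substreams, one per modality, so each generator is individually
reproducible).

**COP sway model.** Each 10-s, 20-Hz trial is a discretized stationary
Ornstein–Uhlenbeck process per axis around the stance position's target
center: `x[i] = a·x[i−1] + ε[i]` with `a = exp(−θ·dt)` and innovation SD
`σ·sqrt(1 − a²)`, so `σ` (`cop_noise_sd`) is exactly the stationary
per-axis sway SD and θ (`cop_ou_theta`, default 1 s⁻¹) the mean-reversion
rate. An OU process was chosen because it is the simplest stationary
model with a tunable sway rectangle; no empirical COP spectrum is
claimed. Directional-trial centers sit at participant-specific stability
limits, log-normal around the population extents (defaults 10 cm AP ×
8 cm ML, `limit_sigma` 0.25); sway SD carries a second log-normal
participant multiplier (`sway_sigma` 0.15). These two sigmas were set
from the target between-subject IPS spread (≈ 0.2); `cop_noise_sd` was
then calibrated once, at 0.31 cm, so that the baseline IPS distribution
is centered near the healthy-young-adult scale (mean ≈ 1.7) — the only
physical-units free parameter, since published IPS studies report the
score but not raw sway magnitudes.

**Planted behavioral effect.** The treated arm's sway SD at post-training
sessions is scaled by `10^(−ips_effect/2)`. Both rectangle sides scale
linearly with SD, so the sway area scales by `10^(−ips_effect)` and the
expected IPS rises by `ips_effect` (default +0.09) up to the small
`log10((L+a)/a)` vs `log10(L/a)` curvature. The effect applies at T1 and
T2 alike; the empirical recovery is ≈ 0.084–0.088, i.e. within 0.01 of
the nominal value.

**Code tables.** One Bernoulli draw per participant-document per code,
with per group × time probabilities defaulting to the observed
per-condition report proportions of the emulated study. Draws are
independent across codes; real transcripts have correlated code
presences, which only matters for the omnibus test's dependence caveat
(below).

**ROI time series.** 18 ROIs in four network blocks (SN 7, FPN 4, DMN 4,
SMN 3), 236 volumes per session (240 acquired minus 4 dummy scans).
Signals are multivariate normal with a block correlation matrix
(`fc_base_within` 0.3 inside networks, `fc_base_between` 0.1 across),
AR(1)-smoothed with coefficient 0.3 as a cheap stand-in for the
0.008–0.09 Hz bandpass of denoised BOLD data. The smoothing recursion
`y[t] = φ·y[t−1] + sqrt(1−φ²)·x[t]` preserves the lag-0 covariance
exactly, so the planted structure survives untouched; it does inflate the
sampling variance of 236-volume correlation estimates, as real
autocorrelated BOLD does. The treated arm's T1 covariance is recomposed
with the planted edges' correlations shifted by `planted_delta_r`
(default −0.2 on the two right-supramarginal/anterior-insula edges), and
positive definiteness is verified by eigendecomposition (the error
reports the offending eigenvalue).

**What the generator does not emulate.** Voxel-level fMRI, head motion,
physiological noise, between-subject heterogeneity in coupling strength
(every control subject shares one covariance), non-Gaussian sway,
fatigue/learning drifts, and Japanese-language transcripts (code tables
are generated directly at the binary level). Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
idealized conditions — e.g. planted-edge interaction t values run larger
than field-typical because inter-subject FC variance is purely
sampling-driven — not robustness to real-data artifacts.

## Posturography conventions

- Log base 10 in the IPS (the originating literature's scale, placing
  healthy adults near 1.7).
- Center of sway = per-trial mean COP. The stability-limit rectangle
  takes its AP side from the anterior/posterior trial centers and its ML
  side from the right/left centers.
- Degenerate (constant) trajectories floor the sway rectangle at
  1e−6 cm² with a warning, keeping the log ratio finite.
- Units are cm (AP positive anterior, ML positive right); the sampling
  rate is carried per-trial so other devices load cleanly. No detrending
  or filtering is applied to COP.
- ΔIPS exceedance uses strict inequality against MDC95 = 0.26.

## Split-plot ANOVA

The classical decomposition: group is tested against subjects-within-
groups; time and group × time against the time × subjects-within-groups
residual, with weighted (cell-size) time means so unbalanced group sizes
are handled exactly (verified to 1e−10 against an independent sequential
projection-matrix oracle, and against `pingouin.mixed_anova` for SS, F,
p and Gη²). Gη² = SS_effect / (SS_effect + SS_subjects-within +
SS_within-residual).

Sphericity uses the **pooled within-group covariance** (df = N − g) for
both Mauchly's test and the Greenhouse–Geisser ε — the correct
mixed-design estimate (what R's `car`/`afex` use); `pingouin` estimates
the covariance ignoring group, so its ε/W differ slightly and are not
cross-checked. GG-scaled df and p are always reported for within-stratum
effects; the Mauchly p < .05 flag only selects which p-value is primary.

Simple effects are within-group paired t-tests (not the ANOVA error
term), gated by a significant interaction by default (configurable), with
Shaffer's S1 step-down over the three pairwise contrasts: multipliers
{3, 1, 1} in ascending-p order — after rejecting the smallest p among
three pairwise hypotheses on three means, at most one of the others can
still be true — with a running maximum for monotonicity and capping at 1.

Both paired effect sizes are emitted: dz = mean(diff)/SD(diff) and
d_av = mean(diff)/mean of the two raw SDs. Published IPS change tables
are ambiguous between the two conventions (a CI-implied SD(diff) can
contradict the printed dz), so the package reports both rather than
adjudicating.

## Coding statistics

The omnibus χ² treats the 5 × 4 grid of code-presences as independent
counts (the multi-response convention, N = total presences). This
reproduces the published df = 12 analysis exactly; its caveat — presences
within one participant are dependent — is documented, not "fixed".
Cramér's V = sqrt(χ²/(N·min(r−1, c−1))). Adjusted standardized residuals
follow Haberman; their p-values are two-sided normal with no multiplicity
adjustment. Codebook matching is exact-token / contiguous-phrase,
case-insensitive, on pre-tokenized text; stemming, fuzzy matching and
negation handling are out of scope (negated/uncertain utterances are
excluded upstream in the emulated workflow). The sentence-level summary
is descriptive only.

## Connectome inference

- Fisher z = atanh(r), clipped at atanh(1 − 1e−7) with a warning for
  numerically perfect correlations.
- The group × time interaction on FC with complete T0/T1 pairing is
  computed as the equal-variance two-sample t on ΔFC (algebraically the
  2 × 2 GLM interaction), df = n₁ + n₂ − 2.
- TFCE edge adjacency is the shared-endpoint rule — two edges are
  adjacent iff they share an ROI. This is the single most consequential
  convention in the module; connectivity toolboxes do not document a
  standard choice, so it is config-free but stated here prominently.
- TFCE integrates `extent^0.5 · h² · dh` over 100 equal threshold steps
  from 0 to the max statistic, per tail. The Riemann sum overshoots the
  continuous integral by ~1.5% at 100 steps (an isolated unit edge scores
  0.3384 vs 1/3); monotonicity in any single edge statistic holds exactly
  at a fixed grid, but raising the maximum statistic rescales the grid
  and can perturb other scores at the discretization scale.
- FWE: the null distribution is the max TFCE over all edges and both
  tails under group-label permutation, with the +1 smoothing convention
  p = (1 + #{null ≥ obs})/(1 + n_perm); p-values are therefore bounded
  below by 1/(n_perm+1). Exhaustive enumeration replaces sampling when
  n_perm exceeds the number of distinct relabelings. Default n_perm is
  5000; the pipeline default is 1000 and the calibration test suites use
  200–500, which Monte-Carlo experiments show is sufficient for the
  α = .05 decisions they check.
- Clusters are connected components of FWE-significant edges; the
  cluster TFCE is the max member score (published two-edge clusters print
  a single TFCE without defining the reduction; max is the natural choice
  consistent with the max-statistic null).
- Edge FDR is Benjamini–Hochberg over all 153 edges by default; a
  within-cluster scope is available (`fdr_scope="cluster"`), since
  published post-hoc FDR values do not always state their family.
- ROI centroid coordinates are metadata only; no spatial computation.

## Associations

Spearman correlations (average-rank ties, two-sided t-approximation p)
between ΔFC_cluster / ΔFC_edge / per-session FC and ΔIPS, separately per
group; n < 3 or constant inputs yield an rs/p of NaN. No multiplicity
correction, mirroring the exploratory framing.

## Problem sizes and determinism

Monte-Carlo suites use: FWE calibration 200 replicates × 200 permutations
at n = 24/group; power 50 replicates × 500 permutations at a planted
|Δr| = 0.4; behavioral recovery 100 replicates at the default
n = (25, 23). These sizes give binomial/Monte-Carlo intervals tight
enough for the properties checked while keeping the default suite under
a minute on one CPU. The acceptance script scales the same computations
to ~20 s. All randomness flows through explicit seeds; identical
(config, seed) reproduces bit-identical outputs, including byte-identical
pipeline reports.

## Known limitations

- The generator's homogeneous covariance across control subjects makes
  connectome effect sizes optimistic relative to real cohorts.
- The OU sway model has a single time constant; real COP shows
  multi-scale structure (rambling/trembling) that the IPS largely
  integrates out but velocity-based metrics would not — such metrics are
  deliberately out of scope.
- The split-plot ANOVA requires complete data (no imputation); the
  mixed-effects reformulation that tolerates missingness is out of scope.
- Codebook matching assumes faithful tokenization; token-level
  equivalence with analyses performed in other languages cannot be
  claimed.
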