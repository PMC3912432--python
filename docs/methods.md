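# Methods

This note documents the models, conventions and numerical choices behind
snadlab, the assumptions the synthetic-data generator makes, and what
the test suite does and does not demonstrate about real reactor data.

## Ammonium speciation

Free ammonia (FA, un-ionized NH3) is computed from total ammonium
nitrogen (TAN) by the acid–base equilibrium

    FA = TAN / (1 + 10^-pH / exp(-6344 / (273 + T)))

with concentrations in mg N/L and T in °C; the exponential term is the
van't Hoff temperature dependence of the ammonium ionization constant.
Conventions:

* **Nitrogen molar mass is fixed at 14.0 g/mol** (not 14.0067) so the
  round-number conversions of reactor practice hold exactly
  (3 mM N = 42 mg N/L). All internal concentrations are mg N/L; the
  millimolar scale exists only at the I/O boundary.
* **Default assay temperature is 23 °C.** Room-temperature assays are
  nominally 22 ± 1 °C; 23 °C reproduces the conventional FA figures for
  the high-ammonium conditions (1.9, 2.8, 5.9 mg NH3-N/L), while the
  low-TAN figure of 0.8 mg/L corresponds to 22 °C. Temperature is
  therefore always an explicit argument, never baked into the formula.
* **Free nitrous acid is not modelled.** Nitrite protonation matters in
  acidic nitrite-rich systems, outside this package's near-neutral,
  low-nitrite scope; `free_ammonia` is the template for such a hook.

Unit algebra: specific activity (nmol N mg protein⁻¹ min⁻¹) =
volumetric rate × 1000 / 14 / 60 / protein (mg/mL); TSS-scale activity
= volumetric rate / TSS (g/L). With typical sludge (protein 2.85 mg/mL,
TSS 10 g/L, protein fraction 0.3 g/g) a volumetric 3.83 mg N/L/h is
1.60 nmol N/mg protein/min and 0.383 mg N/gTSS/h. Published gTSS-scale
activity figures sometimes coincide numerically with the volumetric
rate (a factor-of-TSS discrepancy); the package reports both scales
side by side and does not attempt to reconcile them.

## Batch-assay rate estimation

Rates are ordinary least-squares slopes of concentration vs. time,
converted to mg N/L/h. This is deliberate: short assays (3 h, 30-min
sampling) are designed to stay in the initial-rate regime, where
zero-order kinetics holds and Monod parameters are unidentifiable.
Choices:

* Standard errors come from the OLS residual variance; a slope within
  **3 standard errors of zero** is reported as "no detectable activity"
  and refused as a ratio denominator (`UndefinedRatioError`), rather
  than yielding a spurious ratio.
* A constant series has zero total variance, so r² is undefined; it is
  reported as 1.0 when the flat fit is exact and 0.0 otherwise, keeping
  r² in [0, 1].
* Optional lag trimming (drop leading points while r² improves by more
  than 0.02) is **off by default** — there is no principled community
  rule, and the default design assumes linearity from t = 0.
* Stoichiometric ratios are ratios of absolute slopes from the same
  bottle (mg N cancels, so mass ratios are molar ratios), with
  first-order (delta-method) error propagation assuming independent
  numerator and denominator errors.
* pH optima are grid argmaxes. Exact ties report the **lowest pH** of
  the tie (so a 7.8–8.0 plateau reports 7.8), and a maximum at a grid
  endpoint is flagged `boundary` since the profile may be monotone.

## Pathway partitioning

With canonical anammox stoichiometry R = 1.32 mol NO₂⁻ per mol NH₄⁺, an
observed anoxic consumption ratio r ≥ R implies an anammox share of
nitrite consumption of R/r (the remainder is heterotrophic
denitrification and/or DNRA-type anammox side metabolism, which the
ratio alone cannot separate; they form one "other" bucket). r < R
indicates extra ammonium sinks instead; the share is clamped to 1 and
flagged `sub_stoichiometric`. Percentages are additionally reported
rounded to the nearest 5 points with exact halves rounded *down*
(82.5 → 80), i.e. toward the anammox-conservative side; raw fractions
are always carried alongside. R is configurable.

## Inhibition windows and SBR guards

The AOB window (10–150 mg NH3-N/L) and NOB window (0.08–0.82 mg/L) are
treated as FA concentrations directly. Bounds are **closed** (FA exactly
at a bound counts as onset), and the NOB verdict uses the conservative
0.08 lower bound, with FA ≥ 0.82 reported separately as strong
inhibition. The four cycle guards (post-aeration TNN ≤ 8 mg/L; cycle-end
TAN > 0, warning outside 10–40 mg/L; FA ≥ 0.08 mg/L at every point;
post-aeration TNN ≤ 42 mg/L for anammox safety) are evaluated
order-independently over labelled cycle points and require at least one
point for each of `cycle_start`, `post_aeration`, `cycle_end`.

## Diversity

Shannon H uses natural logarithms (nats), the only basis under which an
8-clone 6/1/1 library gives the conventional H = 0.7356. Because small
libraries admit two sensible evenness normalizations, both are
computed: H/ln S (S observed taxa) and H/ln n (n clones). A single
observed class defines both as 0 with an explicit flag.

## Phylogenetics

* **p-distance with pairwise deletion**: a column is dropped for a pair
  iff either sequence has a gap or an ambiguity code there (per pair,
  not per alignment). Zero remaining columns is an error, not a zero.
* **Corrections**: Jukes–Cantor d = −(3/4)ln(1 − 4p/3) for nucleotides
  (domain p < 0.75); Poisson d = −ln(1 − p) for amino acids (p < 1);
  and the **Dayhoff PAM-matrix distance**, obtained by numerically
  inverting the expected proportion of differing residues as a function
  of time under the reversible Dayhoff (1978) rate model with Dayhoff
  equilibrium frequencies. The curve p(d) = 1 − Σ πᵢ[exp(Qd)]ᵢᵢ is
  monotone with asymptote 1 − Σ πᵢ² ≈ 0.940; inversion is by bisection
  to 10⁻⁶ after doubling to bracket. The matrix exponential uses the
  symmetrized eigendecomposition of Q (exact for reversible models;
  verified against a direct matrix-exponential oracle at machine
  precision). p at or beyond a model's asymptote raises a saturation
  error naming the pair.
* **Neighbor joining** follows Saitou–Nei on the Q-criterion with two
  deterministic conventions: ties broken by the lexicographically
  smallest index pair, and negative branch lengths clamped to zero with
  the total clamped deficit stored on the tree and logged. NJ is exact
  on additive matrices (path lengths reproduce the input to 10⁻⁹, which
  the tests verify against an independently constructed random-tree
  oracle).
* **Bootstrap** resamples alignment columns with replacement, rebuilds
  the NJ tree per replicate, and scores each internal edge by the
  percentage of replicates containing the same leaf bipartition
  (bipartitions keyed by the side not containing the reference leaf).
  Replicates whose distances saturate are dropped and counted.
  Supports are stored as raw percentages; rendered Newick can hide
  supports below 50% (display convention only). Everything is
  deterministic for a fixed seed.
* Newick output carries branch lengths to 6 decimals and integer
  support labels; parsing goes through dendropy. Round-trips preserve
  topology, lengths and supports.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

**Assays.** Guild kinetics are zero-order with fixed coupling: AOB turn
1 mol TAN into 1 mol TNN; NOB 1 mol TNN into 1 mol NO3; anammox consume
1 mol TAN + R mol TNN (R = 1.32) yielding y mol NO3-N (y = 0.26,
configurable, 0 to disable) and (1 + R − y) mol N₂-N; nitrate
denitrifiers convert NO3 to TNN; nitrite denitrifiers convert TNN to
N₂. Integration is forward stepping at ≤ 0.1 min with sub-steps that
end exactly where a pool depletes, so the substrate cut-off never
drives a concentration negative and total nitrogen
(TAN + TNN + NO3 + cumulative N₂-N) is conserved to rounding error.
Observations are truth + N(0, σ²) clipped at zero, with σ = 1 mg N/L as
the default measurement noise and the canonical 7-sample/180-min
design; the noiseless truth is retained and seed-independent. An
optional piecewise-linear pH bell can scale rates when generating
pH-profile fixtures; it is a shape device, not a mechanistic pH model.
Denitrifier rates are free parameters of the scenario being simulated.

**Clone libraries** are single multinomial draws of n clones from given
proportions. **Sequence evolution** draws a uniform root sequence and
mutates each site along each branch with the exact Jukes–Cantor
change probability (K−1)/K·(1 − e^(−Kd/(K−1))) for branch length d and
alphabet size K (4 or 20).

**What the generator does not emulate:** diffusion gradients in
granules, oxygen dynamics, pH drift within an assay, Monod saturation,
correlated or heteroscedastic measurement error, PCR/cloning bias in
libraries, and among-site rate variation or indels in sequences.
Passing recovery tests therefore demonstrate that the estimators are
consistent and correctly scaled under the stated noise model — not that
real assays meet those assumptions.

## Problem sizes and determinism

Stochastic checks use fixed seeds throughout (hypothesis runs
derandomized). Recovery tests use 100 replicate assays per scenario at
σ = 1 mg/L and compare medians (5% / ±0.05 windows). Tree-recovery
checks use 4–8-leaf trees with 300–1000-site alignments, and bootstrap
stability compares 500 vs 2000 replicates on a 5-taxon alignment; these
sizes make the whole suite run in seconds while leaving Monte-Carlo
margins far from the assertion thresholds. `scripts/acceptance.py`
derives all replicate seeds from its `--seed` argument.

## Known limitations

* The OLS window is global per fit; no automatic change-point detection
  beyond the optional lag-trim heuristic.
* Partitioning assumes the theoretical stoichiometry is exact and
  attributes all excess nitrite consumption to a single pooled sink.
* Inhibition windows are fixed FA intervals; no temperature or
  adaptation dependence of the thresholds themselves.
* NJ is the only tree method; no ML/Bayesian inference, and no
  alignment construction (alignments are taken as given).
* The Dayhoff distance is the rate-matrix inversion described above;
  other programs' Dayhoff variants (e.g. gamma-distributed rates or
  tabulated approximations) will differ in the third decimal or beyond.
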