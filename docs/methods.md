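# Methods notes

This note records the model, the conventions, and the design decisions
behind `connectopy`, in the spirit of the methods documentation of
packages like statsmodels or msprime: what is computed, under which
assumptions, with which defaults, and what the synthetic calibration
does and does not establish.

## Network construction

A connectome is a symmetric, non-negative, zero-diagonal weight matrix
over an ordered parcellation (72 regions by default: 33 Desikan–Killiany
cortical areas plus thalamus, caudate and lentiform nucleus per
hemisphere; left block first, alphabetical within hemisphere). Directed
streamline counts are normalised by the product of seed and target ROI
volumes (mm³) and symmetrised by the arithmetic mean of the two directed
entries. The mean was chosen over max or sum because it keeps the weight
scale of the directed measurements and is idempotent on already
symmetric input; any of the three would only rescale group contrasts.

**Density thresholding.** For each κ ∈ (0, 1], all n(n−1)/2 node pairs
of the pooled (both groups) median matrix are ranked by descending
weight; the top `round_half_up(κ·n(n−1)/2)` pairs form the mask applied
to every subject. Conventions, each of which matters for exact
reproducibility:

- *Rounding*: half-up (away from zero). This is the unique simple rule
  consistent with all four anchor counts (0.05·2556 = 127.8 → 128,
  0.95·2556 = 2428.2 → 2428, 0.05·630 = 31.5 → 32, 0.95·630 = 598.5 →
  599). Inputs are pre-rounded to 9 decimals so binary-float artefacts
  (0.95·630 = 598.4999…97) land on the intended half.
- *Ranking universe*: all off-diagonal pairs, including structural
  zeros, which rank last. This guarantees the retained count (hence the
  exact edge density κ) even for sparse summaries; retained zero-weight
  pairs carry zero weight and are inert in every measure.
- *Tie-breaking*: stable order by (descending weight, ascending row,
  ascending column), so masks are deterministic and nested across κ.

The interhemispheric 36×36 block is a bipartite set of connections used
only for strength summaries, never for graph measures.

## Graph measures

Edge length is inverse weight, l_e = 1/w_e; zero weights are absent
edges. Shortest paths use Dijkstra from every node (exact); disconnected
pairs contribute 0 to efficiency (the inverse-distance convention), so
ε is defined for fragmented graphs and is 0 for edgeless ones.

**Weighted clustering.** The per-node coefficient uses geometric-mean
triangle intensities after dividing all weights by the global maximum,
which bounds every triangle term by 1. The normalising factor
k_v(k_v−1) admits two readings of k_v: the node *strength* (the formula
as usually printed) or the node *degree* (the convention of the
standard brain-connectivity toolboxes, under which C ≤ 1 and the
unit-weight triangle has C_v = 1). Both are implemented;
`denominator="degree"` is the pipeline default, `"strength"` is
available by flag, and neither is silently "corrected" into the other.
C_v = 0 whenever k_v(k_v−1) ≤ 0.

**Local efficiency** of a node is the global efficiency of the weight
submatrix induced by the node *together with* its neighbours (the
convention that excludes the node is available via
`include_node=False`); nodes with fewer than two neighbours get 0.

**Modularity** is optimised by seeded Louvain community agglomeration
with 10 restarts (best value reported). The optimiser is stochastic;
all nondeterminism is contained by the seed, and on fixtures whose
optimum is known by exhaustive partition enumeration (two disjoint
triangles, Q = 0.5) the restarts reach it.

## Null models and normalisation

ε and C grow with overall connectivity strength, confounding topology
in group comparisons. Each is therefore optionally divided by its mean
over an ensemble (default 150) of randomised reference networks that
preserve size, degree sequence (exactly) and the weight multiset
(exactly), and node strengths approximately. The randomisation is
Maslov–Sneppen double-edge swapping (10 successful swaps per edge,
attempt cap 40×) followed by greedy weight reassignment: weights are
placed in descending order on the free edge whose endpoints have the
largest remaining strength deficit. On 36-node networks this keeps the
source-versus-realisation strength correlation above 0.99. Complete
graphs have a single topology and are left as-is (weights permuted
conceptually, identically in effect). Ensembles are seeded per subject,
κ and measure from a master seed via `numpy.random.SeedSequence`
spawning, so runs are bit-reproducible. Modularity is invariant under a
global strength shift and is never normalised. Degenerate graphs with
zero ensemble-mean measure yield NaN (reported missing).

## Group statistics

**Quartiles.** Within-subject strength distributions per region-set use
the *nonzero* weights (absent edges are not observations of strength);
quantiles are linear-interpolation (type-7), the numpy default.

**t_max family test.** Pooled-variance independent t statistics over
the 9-member family (3 quartiles × 3 region-sets); for each random
relabelling the maximal |t| is recorded; the adjusted p of each member
is the proportion of relabellings (identity included, so p ≥
1/(n_perm)) whose maximum reaches its observed |t|. An `exact=True`
mode enumerates all C(n, n₁) assignments. The t numerator is control
mean minus patient mean throughout the package: positive t means a
patient deficit.

**KS tests** compare "group-averaged within-subject distributions",
constructed as the edge-wise mean matrix per group, vectorised over the
region-set's edge universe. Averaging subject-level quantile functions
would be a defensible alternative; the edge-wise mean was chosen as the
more literal reading of averaging distributions of the same labelled
edges.

**Mixed ANOVA.** The 2×k (between: group, within: region-set) ANOVA is
implemented directly from the textbook sums-of-squares decomposition
for designs balanced in the within factor (unequal group sizes
allowed), exposing every SS stratum so the identity SS_total =
ΣSS_effects + ΣSS_errors is testable to 1e−8. No sphericity correction
is applied (with k = 3 region-sets the within test has 2 numerator df;
users needing Greenhouse–Geisser should treat within-factor p-values as
approximate). partial η² = SS_effect/(SS_effect+SS_error). Hedges' g
uses J = 1 − 3/(4m − 1), m = n₁+n₂−2.

## MTCP

Per κ of the grid (global measures: 0.05 to 0.95 step 0.05; nodal:
0.10 to 0.90 step 0.02), a pooled t is computed; n_perm (default 1000)
random relabellings are evaluated — the *same* relabelling at every κ,
preserving the curve's dependence structure — and t_crit is the 95th
percentile (linear interpolation) of the permutation maxima of |t|.
Significance at the 5% level: observed max |t| > t_crit. The p-value is
(1 + #{perm max ≥ observed max})/(n_perm + 1); in exact mode it is the
plain proportion over all assignments.

The supercritical cluster is the maximal contiguous κ-run containing
the global peak where |t| > t_crit (a single cluster per test, matching
the single-A report format). A is the trapezoidal integral of the
clipped excess max(|t| − t_crit, 0) over the run extended one grid step
to each side; the extension makes a single supercritical point
contribute a positive area, so A > 0 exactly when t_max > t_crit.
κ is the integration variable, so A carries units of t × κ. A_crit is
the mean of the analogously computed areas of the permutations that
exceed t_crit; whether subcritical (zero-area) permutations belong in
that average is ambiguous, so both estimates are reported (`A_crit`
excludes zeros — the default — and `A_crit_with_zeros` includes them).
Densities with degenerate observed variance are dropped with a warning;
all-zero regions are dropped from the nodal screen likewise. The nodal
screen shares one relabelling matrix across regions (each region is
still its own test; sharing only reduces Monte-Carlo noise between
regions).

Reported per test: t_obs(κ), t_crit, t_max, κ_MTCP (peak density),
signed t_MTCP at the peak, A, A_crit, p. Calibration on Gaussian null
curves and on full synthetic null cohorts puts the rejection rate at
≈ 0.05 (see `scripts/acceptance.py`).

## Clinical association

Patients' scores are related to a per-subject measure (canonically the
non-normalised global efficiency of the unthresholded right-hemisphere
network) by Pearson R with t-based p; partial correlation given age by
residualising both variables on age (p with n−3 df); and the Spearman
analogues of both (rank-transform, then the same machinery). Model
comparison fits a line and y = a·exp(b·x) by least squares (the
exponential via Levenberg–Marquardt, initialised from the log-linear
regression plus five seeded ±20% jittered restarts, best RSS kept).
RMSE = √(RSS/(n−p)); AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with
k = p+1 (the residual variance counts as a parameter). Absolute AICc
values are convention-dependent; only differences are meaningful, and
the relative likelihood exp(ΔAICc/2) depends on nothing else — a
property asserted by shifting both values.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis
assumes; defaults are the emulated study conditions and are not meant
to be tuned per run:

| parameter | default | rationale |
|---|---|---|
| nodes per hemisphere / group sizes | 36 / 13+13 | the emulated design |
| template weights | lognormal, σ = 1 (log scale) | standard positive right-skewed model for streamline densities |
| intra/inter mean ratio | 3 | interhemispheric links are markedly weaker; yields the dominant "region" main effect |
| per-edge noise | lognormal, sd 0.4 (log) | between-subject variation of single connections |
| per-subject global scale | lognormal, sd 0.2 (log) | subject-level differences in overall tract visibility; the component a group deficit must beat, so δ = 0.3 corresponds to a median-strength Hedges' g ≈ 1.7 |
| right-hemisphere deficit δ | 0 (null) | multiplicative (1−δ) on patients' right intra-block |
| ROI volumes | lognormal(log 2000 mm³, 0.3) | plausible ROI scale; exercises the volume-normalisation round trip |
| score link | exponential, score = 25·exp(0.7·z) + N(0, 5²), z the within-patient standardised right-hemisphere efficiency | scores span ≈ 9–87 on the 0–100 YGTSS scale without ceiling saturation — saturation would destroy the curvature the link is meant to carry; linear link: 40 + 15·z |

Scores are clipped to [1, 100] and missing for controls. Raw
"streamline counts" are back-constructed as w·vol_s·vol_t so the
cohort enters the pipeline through `build_connectome` like real data.

**What the generator does not emulate:** spatial embedding and
distance-dependent connectivity, tractography biases (gyral bias,
false-positive long-range connections), realistic degree
heterogeneity, age effects on connectivity, and measurement error
correlated across edges. Passing calibration and power tests therefore
shows the *statistical machinery* is correct and calibrated under the
assumed generative structure — not that the pipeline is robust to
tractography artefacts.

## Problem sizes of the shipped calibrations

The test suite and the acceptance script use Monte-Carlo sizes chosen
to make their binomial confidence intervals informative while keeping
runs comfortably interactive: 500 null replicates (200 permutations
each) for the MTCP type-I rate, 100 (tests) / 60 (script) replicates
for power and score-link recovery, 150-realisation null ensembles where
the ensemble size is itself part of the contract, and exhaustive
enumeration wherever the design is small enough (C(8,4) relabellings,
all 203 partitions of six nodes). Release-scale analyses would use
10⁴–10⁶ permutations for the family tests; the permutation counts are
plain function arguments.

## Known limitations

- The Louvain optimiser gives a lower bound on modularity; for n ≳ 10
  the true optimum is unverifiable and only seeded reproducibility and
  fixture optima are guaranteed.
- Strength preservation in the null model is approximate (exact
  preservation of degrees, strengths and the weight multiset
  simultaneously is over-constrained); the contract is correlation
  > 0.9 on 36-node networks, typically > 0.99.
- The mixed ANOVA assumes within-factor balance and two groups.
- MTCP reports a single supercritical cluster (the one containing the
  peak); secondary clusters are visible in `t_obs` but not summarised.
- Exponential fits can diverge for score data consistent with b → ∞;
  divergence raises with diagnostics rather than returning a fit.
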