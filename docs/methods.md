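# Methods

## Model structure

The annual life cycle is a finite-state absorbing Markov chain over four
breeding states in fixed order — pre-breeder (PB), successful breeder (S),
failed breeder (F), non-breeder (NB) — plus death.  The census falls at the
end of the breeding season; a "year" is one projection interval.  Three
stage-specific vital rates parameterize all transitions:

| rate | meaning | unit |
|------|---------|------|
| σ_j | survival from one census to the next | probability / yr |
| β_j | breeding next season, conditional on survival | probability |
| γ_j | raising the chick to fledging, conditional on breeding | probability |

Transitions compose in the order survive → breed → succeed.  A surviving
pre-breeder that does not breed remains a pre-breeder (the PB state is never
re-entered once left); a surviving adult that does not breed becomes a
non-breeder; any surviving breeder lands in S or F by success.  Matrices are
**column-stochastic** (column = from-state) and act on column vectors;
`lifemix.model.STAGES` fixes the canonical index map.  All linear algebra on
the 4×4 transient matrix U uses solves (`np.linalg.solve`), never explicit
inversion.

Unobserved heterogeneity is a *fixed* finite mixture: each individual draws
a group at fledging from the mixing distribution π and keeps it for life.
The packaged parameter set is the three-group southern-fulmar model
(model-averaged rates under ordinary sea-ice conditions, π = 0.14/0.67/0.19);
any other model is supplied as a vital-rates CSV plus a YAML config.  Rates
are validated, never clamped.

## Occupancy and time conventions

The fundamental matrix N = (I − U)⁻¹ counts the *current* census, so its
diagonal is ≥ 1 and, e.g., a pre-breeder facing a constant 0.9 probability
of remaining PB accumulates 1/(1 − 0.9) = 10 expected PB years.
Consequently:

- *longevity* (column sums of N) includes the fledging census — a bird dying
  before its second census has longevity 1;
- *age* at an event is the number of annual steps since fledging;
- *LRO* is the expected occupancy of S (row S of N): one chick per
  successful season.  By the same convention, an individual currently in S
  counts that season's chick even if it never breeds again.

These choices make analytic and simulated moments directly comparable and
match the printed per-group occupancy matrices of the source estimates.

## Conditional first-passage analysis

For an event defined as *entry into a target set T of stages* (recruitment:
T = {S, F}; first success: T = {S}), the chain is modified so that every
transition into T feeds a new absorbing "event" state competing with death:
U′ zeroes the T-rows of U and the event row collects their mass.  With
b_j the probability of event-absorption from stage j (b = e U′-fundamental),
the chain conditioned on the event has transient matrix

    U^c[i, j] = U′[i, j] · b_i / b_j      (stages with b = 0 dropped),

a Bayes reweighting under which absorption into the event is certain (checked
numerically in the tests).  The mean and variance of the time to the event
are then the longevity statistics of U^c.  Starting stages from which the
event is unreachable are reported with probability 0 and an explicit
`no_path` flag — never NaN.

**Inter-breeding intervals.**  `breeding_interval` times the next
*successful* breeding: target {S}, with intermediate failed attempts treated
as transient detours.  Under this convention the per-stage intervals of the
fulmar analysis are reproduced exactly (e.g. 1.4 / 1.9 / 2.6 years from
S / F / NB in group 1); timing the next breeding *attempt* (target {S, F})
yields systematically shorter intervals (1.06 / 1.31 / 2.04) and is available
by passing `target=("S", "F")`.  The target set is always an explicit
argument, so either definition is one call away.

**Adult-lifetime occupancy.**  "Adult life" starts at recruitment, whose
outcome is stochastic; the starting distribution is taken as
(0, γ_PB, 1 − γ_PB, 0) — the success split of the recruitment event itself.
Starting deterministically in S is a nearby alternative that shifts the
shares by at most a couple of percentage points; the recruitment-weighted
start is the package's convention.

## Variance decomposition

For outcome ξ with per-group means m_k and variances v_k,

    within = Σ_k π_k v_k,   between = Σ_k π_k (m_k − Σ_l π_l m_l)²,

an exact identity (total = within + between by construction).  For the
conditional outcome *age at first reproduction*, the group moments are
event-conditional but the weights remain the unconditional fledging π: a
group whose members rarely recruit still enters with its full fledging
weight.  This is the convention under which the published between-group
component follows from the published conditional means;
`condition_weights=True` instead re-normalizes π by the per-group recruitment
probabilities (the group composition *among recruiters*), which is arguably
more natural when the population of interest is recruits — both are exposed,
the fledging-π version is the default.

## Cohort projection

The mixed cohort lives in a group-major s·g vector (stages contiguous within
each group).  The projection matrix Ũ = Kᵀ D K 𝒰 uses the vec-permutation
(commutation) matrix K to shuttle between group-major (for the
block-diagonal stage transitions 𝒰) and stage-major (for the block-diagonal
group transitions D) orderings.  With fixed heterogeneity D = I and Ũ is
exactly block-diagonal — asserted in tests — but arbitrary column-stochastic
D_i are accepted so dynamic-heterogeneity extensions are expressible.
Projection is pure attrition (no recruitment feedback); the default horizon
is 100 years.  Composition output reports both survivor shares and
shares of the initial cohort, since either normalization may be wanted;
time points with an extinct cohort are flagged `defined = False` rather than
propagating NaN silently.

## The simulator

`simulate_individual` realizes one life by drawing, each year in order,
survival, breeding and success Bernoulli variables — distributionally
identical to the chain, but constructed event-by-event so trajectories carry
the full stage sequence.  Design points:

- **Streams.**  One root `SeedSequence` per cohort; each individual consumes
  its own spawned child stream (first draw = group membership).  Identical
  seeds reproduce identical tables byte-for-byte, and enlarging n extends a
  cohort without reshuffling earlier individuals.
- **Cap.**  Lifespans are truncated at 1 000 years and flagged `censored`;
  with the packaged rates the per-individual probability of reaching the cap
  is below 10⁻⁴⁰, so censoring never occurs in practice but is reported
  rather than silent when degenerate rates (σ = 1) are simulated.
- **Summaries.**  `empirical_summaries` applies the same conditioning as the
  analytic side (ages among recruiters only) and attaches standard errors —
  for variances the moment-based large-sample SE using the fourth central
  moment, not the normal-theory shortcut.
- **Capture histories.**  Trajectories are thinned with per-stage detection
  probabilities into a wide, stage-coded table (0 = not seen); the banding
  occasion is always observed.  Default scale mirrors the motivating study
  (1 165 fledglings × 47 occasions).  Detection defaults (0.9 for breeders,
  0.5 for PB and NB) are a generic choice for an intensively monitored
  colony — attendance at the colony makes breeders far more detectable —
  and feed no analytic result.  What the generator does *not* emulate:
  time-varying rates, dynamic heterogeneity, group-specific detection,
  permanent-emigration/death confounding.  Agreement of analytic and
  simulated moments therefore validates the Markov-chain algebra under the
  model's own assumptions; it says nothing about model adequacy for field
  data.

## Numerical choices

- Fundamental-matrix solves require spectral radius ρ(U) < 1 and reciprocal
  condition number ≥ 1e-12; violations raise `SingularChainError` naming the
  group (the all-σ = 1 chain is constructible for unit tests but has no
  absorption, so occupancy statistics refuse to evaluate).
- Column-stochasticity and π-simplex checks use absolute tolerance 1e-12.
- Variance formulas can produce round-off negatives of order −1e-12; values
  in (−1e-9, 0) are clipped to 0, anything more negative is left visible.
- Event-reachability threshold for dropping b = 0 stages is 1e-300 (exact
  structural zeros, not a tuning constant).

## Verification problem sizes

The Monte Carlo oracle suite simulates one mixed cohort of n = 10⁵
individuals (fixed seed 20250921) and checks per-group and pooled means and
variances of longevity, LRO and first-passage outcomes against the analytic
values within 3 standard errors, the pooled variance additionally against
the law-of-total-variance identity, and the simulated survivorship curve
against the matrix projection decade-by-decade.  Deterministic comparisons
against the published per-group matrices use tolerance 0.05, reflecting that
the published inputs are printed to two decimals while the original
computations used unrounded estimates.

## Known limitations

- Heterogeneity is fixed at fledging; dynamic group switching is expressible
  in the projection (D ≠ I) but not in outcomes or simulation.
- No estimation: vital rates and π are inputs, not fitted quantities.  The
  capture-history export exists precisely so that external multistate
  mark–recapture fitting can be exercised against known truth.
- Single absorbing cause (death); cause-of-death decompositions would need
  an extended M.
- No sensitivity/perturbation analysis of outcomes with respect to rates.
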