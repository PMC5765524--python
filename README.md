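# lifemix

Markov chain demography for heterogeneous life histories: how much of the
variation among individual lives is *luck*, and how much is latent *quality*?

`lifemix` implements a stage-classified absorbing Markov chain life-cycle
model with fixed, unobserved heterogeneity represented as a finite mixture of
chains.  It was built around the life history of the southern fulmar
(*Fulmarus glacialoides*), a long-lived Antarctic seabird whose annual cycle
is classified into four breeding states — pre-breeder (PB), successful
breeder (S), failed breeder (F) and non-breeder (NB) — but the machinery
applies to any life cycle expressible in this form.  It is intended for
population ecologists and biodemographers working with multistate
mark–recapture estimates.

## The model

Each heterogeneity group *k* has stage-specific vital rates — survival
σ_j, breeding probability β_j (given survival) and success probability γ_j
(given breeding) — that define a column-stochastic transition matrix
P_k = [[U_k, 0], [M_k, 1]], where U_k moves living individuals among stages
and M_k = 1 − σ absorbs them into death.  A fledgling belongs to group *k*
with probability π_k, fixed for life.  From the fundamental matrix

    N_k = (I − U_k)⁻¹

come all demographic outcomes: life expectancy (column sums of N), occupancy
variances V = (2 N_dg − I)N − N∘N, lifetime reproductive output
(LRO = expected years as a successful breeder, one chick per success), and —
after redirecting transitions into a target stage set to a new absorbing
"event" state and conditioning on the event beating death — ages at first
recruitment/first success and inter-breeding intervals.  A heterogeneous
cohort is projected with the vec-permutation block matrix
Ũ = Kᵀ D K 𝒰, and the inter-individual variance of any outcome ξ splits
exactly by the law of total variance,

    V(ξ) = E_π[V(ξ | group)]  +  V_π[E(ξ | group)],

into individual stochasticity (within-group) and heterogeneity
(between-group) components.

An individual-based Monte Carlo simulator realizes the same model
trajectory-by-trajectory, serving as an independent check on every analytic
result and as a generator of emulated capture–recapture data.

## Worked example

The packaged parameter set is the three-group southern-fulmar model
(π = 0.14, 0.67, 0.19):

```sh
lifemix analyze --out-dir out/
```

prints

```
mixture mean longevity: 15.19 years
mixture mean LRO: 3.74 offspring
mixture mean age at first reproduction: 10.10 years
longevity: 5.9% of variance from heterogeneity
lro: 22.0% of variance from heterogeneity
age_first_reproduction: 3.7% of variance from heterogeneity
report written to out
```

A fledgling from this mixed cohort lives ~15 years and fledges ~3.7 chicks
on average, recruiting around age 10 — yet only 5.9% of the variance in
longevity and 22% of the variance in LRO trace to group membership; the rest
is individual stochasticity, chance playing out on shared rates.  The same
command writes per-group fundamental and variance matrices, occupancy
shares, the first-passage table and the decomposition table as CSV/JSON
under `out/`.

The library surface mirrors the CLI:

```python
import lifemix as lm

m = lm.southern_fulmar()
chain = m.chain("UH-2")
lm.longevity_moments(chain.U).for_stage("PB")   # (13.40, 198.2, 1.0)
lm.first_passage(chain.U, chain.M,
                 lm.FirstPassageSpec(target=("S", "F"))).for_stage("PB")
# -> mean 11.2 years to recruit, conditional on the 0.103 chance of recruiting
```

`lifemix project` exports the 100-year cohort projection (intra-cohort
selection: the short-lived-at-fledging majority group ends up dominating the
survivors), and `lifemix simulate` writes simulated outcome tables and
stage-coded capture histories.

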