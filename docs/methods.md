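# Methods

This note documents the models, conventions and design choices behind
`cricketnets`: what each statistic assumes, what the synthetic generator
does and does not emulate, and the numerical conventions that make results
reproducible.

## Data model and conventions

Time is an integer day index from an arbitrary season origin. An
individual's adult lifespan is `[emergence_day, death_day]`, inclusive;
when death is unobserved in the field this convention stores the last
observation day as `death_day`. Burrow occupancy is pre-aggregated per
(individual, burrow) as a nonnegative duration in arbitrary time units:
every downstream statistic is invariant to the unit because spatial
weights are only ever compared or standardized.

CSV I/O is strict: comma-separated UTF-8 with a required header, `.`
decimal mark, fixed column orders, canonical row sorting on write. The
reader is row-order insensitive; `read ∘ write` is the identity and
writing is byte-stable, so a seed plus a config reproduces files exactly.

## Networks

* **Fighting** (directed): `w(i→j)` counts events where male *i* arrived
  at a burrow and fought resident *j*. Same-day repeats at one burrow are
  distinct events and all count.
* **Mating** (bipartite males × females): counts of matings with a
  successful spermatophore transfer; failed transfers are kept in the
  records but excluded here.
* **Sperm competition** (directed): one-mode projection
  `w(i→j) = Σ_f M[i,f]·1[M[j,f]>0]` — the number of times *i* mated any
  female also mated by *j*. Each spermatophore is one unit of competitive
  investment, so one mating with each of two shared females equals two
  matings with one shared female.
* **Temporal overlap** (symmetric): days both pair members were adult,
  counted inclusively (two crickets alive on the same single day overlap
  by 1, not 0).
* **Spatial overlap** (symmetric): the directed intermediate
  `w(i→j)` sums *i*'s own time at each burrow that *j* also used (the
  partner's use gates which burrows count but does not weight them); the
  two totals are then symmetrized by their geometric mean. The same
  geometric-mean symmetrization is applied to the fighting and
  sperm-competition networks before the dyadic regression. By AM–GM the
  symmetrized weight never exceeds the arithmetic mean, with equality only
  for balanced pairs — unbalanced reciprocal interaction is deliberately
  down-weighted. An alternative projection that weights shared burrows by
  the partner's time is conceivable; the gate-only form mirrors the
  sperm-competition projection's own-investment logic and is the one
  implemented.
* **Isolate filtering**: males who never shared a burrow with another
  male (at any time) are removed before the competitive analyses, once
  per season. The filtered male set is the node universe for all
  male–male matrices and for the mating matrix rows; males with no fights
  or no matings stay in with zero rows.

## Dyadic inference

All matrix permutation tests permute node labels — rows and columns
simultaneously — which preserves the network's dependence structure under
the null. For symmetric matrices the dyad set is the unordered upper
triangle; for directed ones, all ordered off-diagonal pairs (configurable
via `dyad_set`). Predictor standardization uses the population
(divide-by-n) SD over that dyad set; the structural zero diagonal is
excluded everywhere. `degrees_of_freedom = n_dyads − n_predictors − 1`
follows the unordered-dyad convention and is reported so the choice is
auditable.

**MRQAP with Dekker double semipartialling.** The observed fit is plain
OLS with intercept over the dyad vectorization. For each predictor, the
permutation test residualizes it on the remaining predictors, node-permutes
the residual matrix, refits the response on the other predictors plus the
permuted residual, and uses the t-value of the permuted term as the
pivotal statistic (the raw coefficient is available via `statistic="coef"`).
By Frisch–Waugh–Lovell the observed pivotal statistic equals the
full-model t. Coefficients come from the observed fit only; permutations
affect p-values alone. A response-permutation variant (`mrqap_y_permute`)
is kept as a cross-check: with uncorrelated predictors it agrees with the
semipartialled test to Monte-Carlo error, while with a strong effect on a
correlated co-predictor and the coefficient statistic its null
distribution is grossly over-dispersed (rejecting essentially never in our
simulations) — the standard motivation for semipartialling. With the
t statistic the two variants differ little on exchangeable dyads, which is
why the t is the default pivot.

All sampled permutation p-values use the add-one convention
`p = (b+1)/(m+1)`, never zero, bit-reproducible given `(seed, n_perm)`;
default `n_perm = 2000`. Exhaustive enumeration over all `n!` permutations
(identity included) is available for small n and is verified against
independent enumeration oracles in the tests. Tests are two-sided.

**Degree correlation and its null.** The mating network's degree
correlation is the Spearman correlation, over unique positive male–female
edges, of the two endpoint degrees (degree = unique partners; weights
affect only edge existence). The null model multiplies the spatial and
temporal overlap matrices over mixed-sex pairs — nonzero exactly for pairs
that were alive together and shared a burrow at least once — and
subsamples this "possible pairs" set: each possible edge enters a
simulated network independently with probability `E_obs/E_poss`, so the
expected simulated edge count equals the observed count (density matching
in expectation; a fixed-size variant would condition on the count
exactly, Bernoulli sampling is the implemented default). Simulated
networks with an undefined correlation are redrawn (capped at 50·n_sim
draws, count logged). The default p-value is upper-tail with add-one
counting — "more extreme" meaning at least as positively assorted — with
a two-sided option.

**Node statistics.** Degree comparisons between the fighting and
sperm-competition networks use the Wilcoxon signed-rank test on per-male
differences (zeros dropped, average ranks, exact small-sample null without
ties via scipy, normal approximation otherwise); the reported W is the
positive-rank sum (R's `V`). Within-individual correlations use Spearman's
r_s; strength (row sums) is computed on the original directed networks,
and passing a symmetrized matrix to `strength_vector` is a contract error.

## Synthetic generator

The generator emulates a univoltine burrow population over one season in
discrete days — the analyses only consume aggregated durations and event
counts, so no finer time scale is needed.

Burrows form contiguous spatial clusters. Each individual gets a home
cluster, a uniform emergence day over `emergence_spread`, and an adult
lifespan `1 + NegativeBinomial(shape, ·)` with mean `mean_adult_lifespan`
(shape 1 = geometric; larger = tighter), truncated at season end. Males
are near-resident: with probability `moves_per_day` they resample a burrow,
concentrated in the home cluster with probability `cluster_tightness`.
Females are the searching sex: their moves are phonotaxis toward the
burrow of a randomly chosen active male. When a male's move lands on an
occupied burrow he fights the resident with probability
`fight_prob_on_male_encounter`; when a female arrives at the burrow of the
male she followed, they mate with probability `mating_rate_scale`, and the
spermatophore transfers with probability `spermatophore_success_prob`.
Restricting courtship to the followed male on the arrival day is a
deliberate identification choice: it keeps a male pair's shared females
statistically independent of that pair's own co-location, so null
configurations are genuinely null for the MRQAP fighting term (ambient
cohabitation mating couples the two and inflates type-I error
substantially — we measured rejection up to ~0.5 with such variants).

Two planted effects are log-linear propensity multipliers, exactly 1 when
off:

* `beta_fight_sperm` — a searching female who has mated male *j* is drawn
  toward males who fought *j* (target weight `exp(β·min(fights, 3))`), and
  a co-located rival's mating propensity is boosted the same way. Fighting
  pairs thus accrue extra shared females. Documented default **1.5**.
* `assortativity_strength` — individuals carry latent promiscuity ranks
  `u ~ Uniform(0,1)`; female search activity scales as `exp(s(u−½))` and
  target choice is matched on rank (`exp(−(4s(u_f−u_m))²/2)`), so active
  females pair with heavily-visited males. The ranks are uniform rather
  than Gaussian deliberately: with Gaussian scores the matching pool is
  largest at mid-score, which cancels the planted degree assortment.
  Documented default **2.0**.

### Presets

`y2006-like` and `y2013-like` reproduce the observational regimes the
analyses expect: 74/119 males, ~90-day seasons, individuals observed ~12–14
days on average, isolate fractions ≈0.30 (low density) vs ≈0.19 (high
density), ≈90–130 transferred matings. The low-density preset plants both
effects, the high-density one only the fighting coupling (no assortment).

`calibration-null` / `calibration-planted` are the simulation-study
conditions: 119 males, 150 females, *homogeneous phenology* (simultaneous
emergence, tight long lifespans) and lower fight probability. Homogeneity
matters for a substantive reason: the edge-subsample null model represents
spatio-temporal structure only as a binary possibility mask, while in any
phenologically heterogeneous population the probability of a mating edge
grows with the pair's overlap duration. The observed network then shows
positive degree correlation that uniform subsampling cannot reproduce —
with realistic emergence spreads we measured rejection rates near 0.4 at
α = 0.05 under a true null, falling to nominal (≈0.04–0.05) under
homogeneous phenology. The same heterogeneity couples the fighting and
sperm-competition networks beyond what linear space/time covariates
absorb. Calibration claims are therefore made under the homogeneous
presets; this sensitivity of the binary-mask null is a genuine limitation
to keep in mind when interpreting such tests on real data. `demo-small`
is a 32-individual miniature for examples and round-trip tests.

Measured under the calibration presets (500/100 fixed-seed replicates,
recomputed by the test suite and, with user-chosen seeds, by
`scripts/acceptance.py`): type-I error at α = 0.05 within the 99% binomial
envelope for the MRQAP fighting term, the Mantel test (independent noise),
the signed-rank test (independent draws) and the degree-correlation null;
planted-effect recovery (positive and significant at α = 0.05) in ≥ 95% of
replicates for both effects at the documented defaults.

### What the generator does not emulate

Predation, mate guarding, singing effort, nymph behavior, paternity; and
the empirical coupling strength between fighting and sperm competition in
any real population. At the sparse low-density scale (~13 fights per
season) the planted fighting coupling is largely undetectable by MRQAP —
the `y2006-like` demo can show a near-zero fighting coefficient — so
power statements are tied to the calibration presets, where encounter
rates identify the effect. Passing tests show the machinery is correct
and calibrated under the generator's assumptions, not that any particular
field population satisfies them.

## Pipeline and reproducibility

`run_full_analysis` executes: isolate filtering → network construction →
symmetrization/standardization → Mantel covariate checks → MRQAP (sperm
competition ~ fighting + space + time) → degree/strength comparisons →
degree-correlation null, aborting with a stage-labeled error on degenerate
input. One top-level seed is split deterministically into per-stage
streams (recorded in the report's provenance with config, package version
and an input checksum), so identical inputs and config give byte-identical
reports. Multi-year comparisons are two invocations. The analysis defaults
are `n_perm = 2000`, `n_sim = 1000`, upper-tail degree-correlation
counting, unordered dyads; `scripts/acceptance.py` and parts of the test
suite use 99–999 permutations/simulations to keep hundreds of replicates
at desk scale.
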