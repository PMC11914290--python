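# Methods

## Model

A well-mixed population of `z` agents plays the donation game: cooperation
costs the donor `c` and delivers `b` to the recipient (`b > c > 0`), so the
pairwise payoffs are (C,C) → b−c each, (D,C) → b for the defector and −c
for the cooperator, (D,D) → 0. Actions are prescribed by one of four
strategies (AllC, AllD, Disc, pDisc — the discriminators conditioning on the
partner's *perceived* public reputation) and realized through an execution
error channel. After every interaction **both** players are judged as
donors: the emotion definitions refer to joint outcomes (mutual
cooperation, exploitation), the norm is donor-focused, and judging only one
side would leave half the emotion table unused. Both verdicts are formed
from the pre-interaction reputations and applied simultaneously.

A judgement consults, with probability `gamma`, the 8-entry emotion-based
table indexed by (prior reputation, realized action, emotional profile),
and the 4-entry base table otherwise; the nominal verdict is then flipped
with assignment-error probability `chi`. The gamma coin is drawn
independently per judged player per interaction. Judges observe the donor's
emotional *profile* (the full expressed-emotion set), not a single
per-outcome emotion: the 8-entry norm indexes profiles even in outcomes
where the two profiles' instantaneous expressions coincide (anger when
exploited, neutrality on mutual defection). The `Emotion` type and
`express_emotion` are kept for reporting and extensions; an emotion-indexed
norm with ambiguity in those outcomes would be a distinct model and is not
implemented.

### Error semantics

* **epsilon (execution)** — default `flip`: the realized action is the
  opposite of the intended one with probability epsilon, so the
  mutual-defection/neutral pathway stays reachable from cooperative intent.
  The alternative in which only intended cooperation fails is available as
  `execution_error_mode="coop_fails"`.
* **alpha (assessment)** — each player independently misperceives the
  partner's reputation with probability alpha before choosing an action.
* **chi (assignment)** — applied after the gamma coin and after the norm
  lookup: it corrupts the verdict, not the choice of norm.

## Evolutionary dynamics

One generation is `z` Monte Carlo steps, so every agent revises on average
once per generation. Per step, a uniform focal agent either mutates
(probability `mu`; strategy redrawn uniformly from 4 and profile from 2,
possibly unchanged — mutation treats the trait pair as one event) or
undergoes social learning: the focal plays `z` games against uniform random
opponents, a distinct uniform model agent plays `z` games, and the focal
adopts the model's (strategy, profile) jointly with probability
`1/(1+exp(-beta (f_model - f_focal)))`. **Fitness is the average payoff per
game** (`fitness_aggregation="mean"`), keeping `beta = 1` on the scale of a
single game's payoff; the sum is available as a config switch. Reputation
updates during fitness evaluation persist in the public state — the games
are real events, not hypothetical evaluations. Each run starts from
uniformly random strategies, profiles and reputations.

The cooperation index eta counts per *act*: every game contributes two
potential donations, and all games of a generation (focal's and model's)
enter the tally. Eta is the ratio of summed cooperative acts to summed
total acts over post-burn-in generations; run replicates are aggregated
with the sample (n−1) standard deviation.

### Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| b, c | 5, 1 | donation-game benefit and cost (payoff units) |
| z | 50 | population size; also games per fitness evaluation and steps per generation |
| mu | 1/z | mutation probability per step |
| beta | 1 | selection intensity of the Fermi rule |
| epsilon, alpha, chi | 0.002 | error rates (one error per 500 interactions) |
| generations, burn_in | 10000, 1000 | production run control |
| gamma grid | 0–1 in 0.1 steps plus 0.95 | the extra point resolves the cusp between 0.9 and 1 |
| error grid | {10⁻³/z … 10/z} | per-error contour magnitudes |
| runs/point | 300 (contours 100) | production replicate counts |

Scaled runs used by the test suite and `scripts/acceptance.py` are 30
replicates of 2000 generations with burn-in 500 (25% of the run,
comfortably past the transient observed at production scale); these sizes
are the package's choice of a scale at which the qualitative structure is
already separated by many standard errors.

## Implementation and determinism

The inner loops are numba-jitted over integer arrays. The step-level
operations (`evaluate_fitness`, `monte_carlo_step`) and the compiled
per-generation kernel are built from the same jitted primitives and consume
an identical draw sequence from a single `numpy.random.Generator`, so the
two paths are interchangeable and byte-identical under a shared seed (this
is asserted in the tests). Uniform integer draws use `floor(u·n)` on one
float draw so both paths stay on the same stream; the discretisation bias
at n ≤ 50 is ~10⁻¹⁴. Per-run seeds in sweeps derive from
`numpy.random.SeedSequence` over (master seed, experiment tag, norm id,
grid indices, replicate), making sweeps reproducible and identical under
serial or parallel (joblib) execution; CSVs are written with a fixed column
order and `%.12g` floats so repeated sweeps are byte-identical.

The emotion-blind baseline (IS) is represented with its base table lifted
to the 8-entry encoding, so gamma is genuinely inert for it; at gamma = 0
an EBIS run and an IS run with the same seed are draw-for-draw identical.

## Frozen-composition oracle

Because the norms are donor-focused, an agent's reputation is an autonomous
two-state Markov chain once its action distribution is fixed. For AllC/AllD
cells the chain is exact; Disc/pDisc action distributions depend on the
population GOOD fraction, handled in mean field: per-cell chains are
iterated from GOOD fraction 0.5 to a fixed point (tolerance 1e-10). The
mean-field treatment ignores finite-z reputation correlations, so the test
suite asserts 3-standard-error agreement for opponent-independent
compositions and adds a small absolute floor (0.005) for conditional ones.
Two degenerate cases are flagged rather than silently resolved: a reducible
two-state chain raises `ReducibleChainError`, and an error-free
conditional-strategy composition — where every GOOD fraction is a
mean-field fixed point (the stochastic dynamics is then absorbing at all-G
or all-B) — triggers a warning and returns the 0.5-initialised solution.

Frozen comparisons use a dedicated runner that disables mutation and
imitation entirely (each step one random focal plays z games). Running the
ordinary loop with beta = 0 would still imitate with probability 1/2 and
destroy a mixed frozen composition.

## What the simulations show and do not show

The generator *is* the model: there is no external data. Passing tests show
that the implementation reproduces the model's analytic reputation
stationary states and its qualitative evolutionary structure — the
equivalence of the two norms at gamma = 0, the cooperation gain of the
emotion-based norm at high gamma, the collapse at gamma = 1 with AllD
dominance, and neutral-drift symmetry at beta = 0. They say nothing about
real human populations: emotional profiles are binary and truthful by
construction (faking is only implicit in the gamma = 1 analysis),
reputations are public, binary and instantly shared, the population is
well-mixed with a universal fixed gamma, and the donor-focused norm ignores
the recipient's standing (no second-order norms).

## Known limitations

* Mean-field oracle bias of order 1/z for discriminator-heavy compositions.
* No analytic small-mutation (adiabatic) approximation of the full
  mutation–selection dynamics; all evolutionary results are Monte Carlo.
* Parallel sweeps fork one numba-compiled worker per process; with the
  on-disk JIT cache this costs little, but `workers=1` is the default.
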