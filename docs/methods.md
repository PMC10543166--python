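# Methods

## Model

A population of Z players occupies the nodes of an undirected simple
graph.  Each player holds a strategy with two components: an action
(cooperate C / defect D) and a herding trait (H / H̃).  Time advances in
synchronous steps.  Every step:

1. **Payoffs.**  Player *i* plays the 2×2 game with every neighbor and
   accumulates Π_i = Σ_j M[a_i, a_j], with M = [[1, S], [T, 0]] (the R=1,
   P=0 normalization).  Payoffs are recomputed from the current state each
   step; nothing carries over between steps.
2. **Herding costs.**  r_i is the fraction of *i*'s crowd whose *action*
   differs from *i*'s (the trait is a private mentality, not an observable
   behavior, so it does not enter the comparison).  The cost is
   h_i = τ (k_i/⟨k⟩) r_i.  In well-mixed crowd mode the crowd is the whole
   remaining population and the size factor cancels, h_i = τ r_i.
3. **Update.**  Independently per node: with probability μ the strategy is
   redrawn uniformly from the variant's strategy set (the current strategy
   included, so the effective change probability is μ(1−1/|set|));
   otherwise one neighbor *j* is drawn uniformly and its full strategy
   (action and trait) is copied with the Fermi probability
   p = 1/(1+e^{−β(Π′_j−Π′_i)}).  All replacements commit simultaneously.

The three variants differ only in how Π′ is formed in the comparison:
raw payoffs (`pairwise_plain`); both sides discounted by their own costs
for every pair (`pairwise_herding`); or — the asymmetric co-evolutionary
game (`four_strategy`) — both sides discounted if and only if the focal
player carries the herding trait.  The model player's own trait never
affects the pair's evaluation; this focal-perspective asymmetry is what
makes the game a bimatrix game.  With τ=0 all variants coincide with the
plain game.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| S, T | sucker's payoff, temptation | — | exploration ranges [−1,1]×[0,2]; outside values warn |
| τ | social weight of the herding cost | 1.0 | τ=0 disables the mechanism |
| β | selection intensity in the Fermi rule | 5.0 | payoff differences are in accumulated-payoff units |
| μ | per-node mutation probability per step | 0.01 | |
| Z | population size | 70×70 lattice / 5,000 BA at study scale | desk-scale runs use 1,000 |
| m | BA attachment parameter | 2 | gives ⟨k⟩ ≈ 4 matching the 4-regular lattice; m=3 selectable |
| steps | synchronous steps per realization | 3,000 | |
| realizations | independent MC runs | 30 (5 at desk scale) | realization *i* uses seed master_seed+i |
| measure fraction | stationary averaging window | 0.25 | mean over the final ⌈0.25·(steps+1)⌉ records |

The BA generator is seeded with a complete graph on m+1 nodes so every
node has degree ≥ m; a fresh network is drawn per realization for
scale-free runs to avoid anchoring results to one preferential-attachment
draw.  The lattice uses periodic boundaries with von Neumann connectivity —
the only convention making a regular lattice exactly 4-regular.  Initial
conditions are i.i.d. categorical draws (exact-count placement is a config
switch): 25% per strategy in the four-strategy game, 50/50 C/D in the
two-strategy games.

## Numerical choices

* The logistic is evaluated with `scipy.special.expit` and clamped to the
  open interval (0, 1).
* One step consumes exactly four RNG draws in a documented order
  (mutation coins, mutant strategies, neighbor picks, imitation coins), so
  every step, realization and experiment is a pure function of its seeds;
  the unit suite replays steps against a straight-line scalar oracle.
* Degree-0 nodes (possible only via custom edge lists) are inert: payoff
  0, ratio 0, no imitation; a warning is logged rather than raising.
* Well-mixed populations are represented implicitly (no O(Z²) adjacency);
  neighbor draws map a single uniform to one of the Z−1 others.
* Per-strategy mean payoffs recorded in time series are the payoffs as
  seen from each player's own evaluation perspective (discounted for
  herders in the four-strategy game); absent strategies record NaN.

## Scale and what desk-scale runs show

Production-scale experiments (Z=5,000 scale-free or 70×70 lattice, 30
realizations, dense S–T grids) take hours on one CPU.  The bundled tests
and the acceptance script use reduced replicas — Z=1,000, 5 realizations,
coarse 4×5 grids — which finish in minutes and reproduce the stationary
herder fraction (≈ 0.46–0.50 grid-averaged, i.e. "about half the
population herds") and the deterministic limits (harmony → cooperation,
deep prisoner's dilemma → defection).

One caveat is intrinsic to the down-scaling: at the deep stag-hunt corner
(S=−1, T=0) the dynamics is a race between a defection sweep (defectors
never earn below zero) and hub-driven cooperative cascades.  At Z=5,000
the plain game ends in full defection essentially always, as expected;
at Z=1,000 both the plain and the four-strategy games are *bistable*, with
individual realizations fixing on either full defection or full
cooperation.  Herding costs enlarge the cooperative basin (defector hubs
that fail to conform are heavily penalized in herder-focal comparisons)
but do not make the cooperative outcome certain at this size, so
corner-case assertions on small populations carry genuine Monte-Carlo
risk.  Mean-field outcomes in that region should be read from the
production scale.

## Limitations

* The conformity ratio compares actions only; a variant comparing the
  full four-way strategy label is conceivable but makes the herding trait
  itself an observable, which the model treats as private.
* No convergence detection: stationarity is operationalized as the fixed
  step budget plus last-25% averaging.
* The synthetic populations (lattice/BA) capture degree heterogeneity but
  not clustering, communities or degree assortativity of real social
  networks; results on empirical networks should use the edge-list input.
* Payoff noise, weighted edges, time-varying τ, and asynchronous update
  schemes are out of scope.
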