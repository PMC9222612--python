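# Methods

## Model

The population lives on an ordered stack of L undirected simple graphs
(layers) over the same node set {0..N−1}.  Node i of every layer is the
same individual; the L copies form coupling group i.  Games are strictly
within-layer; the only interlayer interaction is the dominance conversion
described below.

Each (layer, node) carries an intrinsic strategy **label** (cooperate C
or defect D).  A synchronous round proceeds in three stages:

1. **Dominance conversion.**  Per coupling group, labels are converted to
   the round's **effective** strategies: under cooperation dominance any
   C label makes the whole group play C; under defection dominance any D
   label makes the whole group play D; natural evolution leaves labels
   unchanged.  Labels are never modified by this stage, and the
   conversion is idempotent.
2. **Payoffs.**  Node x accumulates, over all its neighbours y in its
   layer, the pair payoff of (effective_x, effective_y) from the matrix
   R = 1, S = −r, T = 1 + r, P = 0 (r > 0).  Payoffs reset every round;
   isolated nodes score 0.  There is no degree normalisation: hubs can
   accumulate large payoffs, which is what lets scale-free layers protect
   cooperation.
3. **Imitation.**  Every node x simultaneously picks one uniform-random
   neighbour y in its own layer and, with the Fermi probability
   W = 1/(1 + exp((π_x − π_y)/κ)), sets its next-round label to the
   strategy it observed y *play* this round (y's effective strategy;
   copying y's label instead is a config flag).  Otherwise x keeps its
   current label.  All label changes commit together.

All-C and all-D label states are absorbing under every mode: imitation
can only copy an existing strategy, and dominance conversion of a uniform
population is the identity or maps onto the same uniform state.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| r | — | temptation parameter generating the payoff matrix; the canned experiments use 0.2/0.5/0.8 and the sweep 0.1…0.8 |
| κ | 0.1 | Fermi selection intensity; 0.1 makes a payoff gap of 1 essentially decisive (W ≈ 4.5·10⁻⁵ against it) |
| N | 500 | nodes per layer in every preset |
| BA m | 2 | edges per new node; mean degree 2m(N−m)/N ≈ 4 |
| WS k, p | 4, 0.5 | ring-lattice neighbours and rewiring probability; rewiring conserves the edge count Nk/2 exactly |
| initial fractions | 0.5 (BA), 0.3 (WS) | exactly round(f·N) cooperator labels placed uniformly at random per layer |
| rounds | 1000 | synchronous steps per run |
| replicates | 20 | independent runs with fresh network realisations and initial conditions |
| stationary window | 200 | trailing steps averaged (pooled across replicates) for summaries |

Counting convention: the cooperator fraction counts **labels** by
default; counting effective (played) strategies is the `counting`
config flag.  Under cooperation dominance the effective count bounds the
label count from above, under defection dominance from below — both
orderings are property-tested.

## Randomness and reproducibility

One root seed drives everything.  The chain for (replicate, layer) is a
`numpy` `SeedSequence` keyed by `spawn_key=(replicate, layer)`, which
spawns three independent streams: network construction, initial label
placement, and the per-round imitation draws (one block of neighbour
picks, then one block of Bernoulli coins, node-major).  Two consequences
are tested: identical (config, seed) reproduce trajectories bit for bit,
and a natural-mode multilayer run equals independent single-layer runs
given the same per-layer chains, since the keyed construction makes layer
streams independent of how many layers surround them.

## Numerical conventions

- The Fermi exponent is clamped at ±500 before exponentiation (and
  evaluated via `scipy.special.expit`), so arbitrarily large payoff gaps
  neither overflow nor leave [0, 1].
- Payoff sums use the cached CSR adjacency (payoff of a cooperator with
  n_C cooperating neighbours of degree k is n_C − r(k − n_C); of a
  defector, (1+r)·n_C), verified against per-edge enumeration on random
  graphs up to 20 nodes.
- Neighbour choice indexes the CSR block with floor(u·deg); isolated
  nodes never imitate.
- Trajectories record n_steps + 1 entries; index 0 is the initial state.
  With label counting, entry t reads the labels committed after round t;
  with effective counting it reads the strategies played during round t.
- BA layers use preferential attachment seeded from a star on m+1 nodes
  (the networkx convention); WS layers use the classic one-endpoint
  rewiring dialect.  Edge lists are 0-based "u v" lines; self-loops,
  duplicates and malformed lines are rejected with their line number.

## What the synthetic conditions emulate — and what they do not

The canned presets are stylised social structures: a scale-free layer
(broad degree distribution, hubs) and a small-world layer (narrow degree
distribution, shortcuts), 500 nodes each, with the cooperator-poorer
initial condition on the small-world layer.  Real multiplex populations
have degree correlations between layers, community structure, weighted
and temporal ties — none of which are modelled.  Passing tests therefore
demonstrate properties of the idealised dynamics, not predictions for any
empirical network.

## Behaviour of the dynamics, frankly

The test suite measures the following at full study conditions (20
replicates, 1000 rounds):

- **Natural evolution, BA layers.**  At r = 0.2 cooperation is promoted
  well above the 0.5 initial share in most replicates; at r = 0.8 it
  collapses to essentially zero.  This is classic accumulated-payoff
  network reciprocity: hubs that fix C early are too rich to imitate
  defectors.
- **Natural evolution, WS layer.**  Cooperation dies for every r ≥ 0.2
  tested.  A sparse, weakly clustered small-world graph at κ = 0.1 gives
  cooperators no refuge against S = −r exploitation.
- **Cooperation dominance, BA-BA.**  Strongly promotes cooperation at
  r = 0.2 and 0.5 (stationary means ≈ 0.92 and 0.64); at r = 0.8 the
  20-replicate mean is ≈ 0.34 — the dynamics are bistable there, and
  fixation at all-C happens in only a minority of replicates.
- **Defection dominance, three-layer BA-WS-BA.**  The whole stack is
  driven to all-D within ~50 rounds for every r in 0.1…0.8, under either
  counting convention and either imitation-source convention.  The
  initial density of fully-cooperating groups is only
  0.5 × 0.3 × 0.5 = 7.5%, scattered rather than clustered, and these
  groups are exploited faster than network reciprocity can consolidate
  them; once no group plays C anywhere, payoffs vanish and the residual
  W = 1/2 drift absorbs the labels at the all-D boundary, helped by the
  selection bias accrued during the transient.

The last point is a known limitation: published accounts of closely
related models report interior stationary cooperation (tens of percent)
in the small-world layer under defection dominance, with a
non-monotonic dependence on r.  We could not reproduce that regime under
this model or under the variants we examined (asynchronous random-
sequential updating; imitating labels instead of played strategies;
refusing imitation on payoff ties; payoffs accumulated across rounds;
cross-layer-aligned initial cooperators).  Several of those variants
change the qualitative picture — accumulating payoffs across rounds, for
instance, lets both BA and WS layers retain high cooperation — but none
yields the reported interior levels with a minimum at intermediate r.
The corresponding acceptance tests are therefore expected to fail under
the default conditions; they are retained unmodified as an honest record
of the discrepancy.

## Design choices where the design was open

- **Synchronous rounds.**  The per-round bookkeeping (one effective
  strategy per node per round, fractions recorded per time step) reads
  most naturally as a synchronous map; an asynchronous prototype did not
  change the conclusions above and was not kept.
- **One strategy per node per round.**  Per-neighbour strategies would be
  a different model; the label/effective machinery is node-level
  throughout.
- **What imitation copies.**  Default is the neighbour's effective
  (observable) strategy — what opponents actually experienced; copying
  the intrinsic label is exposed as `imitation_source="label"`.
- **Replication protocol.**  Single runs of these dynamics are highly
  realisation-dependent (bistability on BA layers), so every experiment
  defaults to 20 fresh-network replicates and reports pooled mean ± sd
  over the trailing 200 steps; "stationary" is operationalised as that
  window, not tested for convergence.
- **Problem sizes in the test suite.**  Unit and property tests run on
  graphs of 2–60 nodes where brute-force oracles are exact; the
  acceptance layer runs the full 500-node, 1000-round, 20-replicate
  campaigns, which complete in about a minute each on one core thanks to
  vectorised rounds.
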