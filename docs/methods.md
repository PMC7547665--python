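# Methods

## State and strategy encoding

A joint m-round history is packed into a 2m-bit integer: the upper m bits
are the focal player's own actions (oldest most significant), the lower m
bits the co-player's, with c = 0 and d = 1.  Full cooperation is state 0
for every m.  A deterministic memory-m strategy is then a 4^m-entry
action table, equivalently a 2^2m-bit integer id whose bit *i* (LSB =
state 0) is 1 iff the table defects at state *i*.  The text format
`m=<int> <c/d string in state-index order>` and hex ids round-trip
bit-exactly.  Memory-one strategies given as payoff-conditioned tuples
(p0, pR, pS, pT, pP) map onto action pairs via R=(c,c), S=(c,d), T=(d,c),
P=(d,d) from the focal player's view; p0 is stored but ignored by all
long-run quantities, which are computed from stationary distributions at
e > 0 (or their limits) and are therefore initial-condition-free.

Strategies that are not memory-m for any finite m (Grim Trigger) are
represented as Moore automata with transitions on realized action pairs,
so implementation errors remain representable.  Memory tables convert to
automata (4^m states, started at the full-cooperation history) and are
minimized by Moore partition refinement; minimization is idempotent and
play-equivalence is checked by co-simulation in the tests.

## Joint chains and long-run payoffs

For a strategy pair, the joint chain lives on joint histories (memory
strategies, embedded into the longer memory) or on reachable product
states (automata).  Each player's intended cooperation probability is
convolved with the error rate (q' = q(1−e) + (1−q)e); the four realized
action pairs give the transition mass.  Stationary distributions come
from a dense solve of πM = π with a normalization row; if the system is
singular (reducible chains, which arise at e = 0 with partially
deterministic pairs) the solver falls back to repeated squaring of the
lazy chain (I + M)/2 from the uniform start, i.e. the Cesàro average over
recurrent classes.  Payoff is attributed per transition as the expected
one-shot payoff of the realized pair leaving each state.  Deterministic
pairs at exactly e = 0 are refused with a pointer to the limit analysis.

## The zero-noise limit

Efficiency and distinguishability are limit statements, decided exactly by
the standard zero-noise construction for perturbed Markov chains:

1. recurrent classes of the error-free dynamics are the cycles of the
   deterministic joint map;
2. the cost of a transition is the number of misimplemented actions needed
   to realize it (0 for the deterministic move, 1 per flipped action);
   class-to-class costs are multi-source Dijkstra shortest paths that may
   pass through transient states but not through a third recurrent class;
3. each class gets the weight of the cheapest spanning in-arborescence
   rooted at it over the class digraph (brute force over parent maps for
   up to 7 classes, Edmonds' algorithm via networkx beyond); the limiting
   stationary mass concentrates on the weight-minimizing classes.

A strategy is efficient iff the *unique* minimizing class of self-play is
the full-cooperation fixed point.  Distinguishability applies the same
analysis to the pair (strategy, AllC): with a unique minimizing class the
payoff difference reduces to the dc-count minus cd-count along the cycle
(payoff-free since T > S); in the rare tied case the verdict falls back
to numerical stationary payoffs at e = 1e-5 and 1e-6 with a required gap
of 10e.  The construction is validated in the test suite against a fully
independent batched linear solve: exact efficiency verdicts agree with
the small-e stationary mass (threshold 0.99 at e = 1e-6) on all 65,536
memory-two self-pairs.

Probabilistic strategies (GTFT, ZD) cannot use the graph construction;
efficiency for them is the numerical small-e criterion directly (mass
≥ 0.99 on full cooperation at e = 1e-6).

## Defensibility

The defensibility graph has one node per information state of the focal
player; from each node the focal action is prescribed and the co-player
chooses c or d; edge weights are +1 for (d,c), −1 for (c,d), 0 otherwise.
Any opponent behaviour — of arbitrary memory — induces a walk on this
graph, and long-run payoff differences are cycle averages of the weights,
so the strategy is defensible iff no cycle has negative total weight
(Floyd–Warshall; batched across all 65,536 strategies for the m = 2
scan).  Using weight signs instead of T−S magnitudes makes the verdict
independent of the elementary payoffs.  When the test fails, a
Bellman–Ford pass extracts an explicit negative cycle, and the package
realizes it: a scripted co-player walking the cycle earns a strictly
higher average payoff, which the tests verify.  This exact test requires
a deterministic prescription; for probabilistic strategies such as
extortionate ZD the package offers a sampling certificate (payoffs
against seeded random co-players at e = 0), which is evidence, not proof.

## Recovery paths

From the full-cooperation history, one of Bob's actions is misimplemented
(realized pair (c,d)), and error-free self-play continues until the joint
state returns to full cooperation.  The error round is index 0;
`steps_after_error` counts the rounds after the error up to and including
the first round of the restored all-(c,c) run, so CAPRI's punish-accept
path (c,d), (d,c), (c,c)… counts 2 steps and the TFT-ATFT path
(c,d), (d,d), (d,c), (c,c)… counts 3.  Patterns are tallied as the action
strings from the error round through that first restored round.

## Enumeration

The m = 2 scan classifies all 65,536 ids: defensibility is one batched
Floyd–Warshall (seconds); efficiency rejects ids defecting at full
cooperation, accepts ids whose only recurrent class is the cooperation
fixed point, and runs the full limit analysis on the remainder (~31k
strategies, about a minute).  Distinguishability and recovery tallies are
evaluated on the eight-strategy intersection.  The scan is cached per
process and fully deterministic.  m = 3 enumeration (2^64 ids) is out of
reach by design; `sample_m3` classifies uniform samples (defensibility
first — at its ~3% pass rate the expensive analyses rarely run) and any
explicitly supplied ids.

The canonical TFT-ATFT is *recovered*, not transcribed: the scan yields
four successful memory-two strategies; the canonical member is the one
agreeing with TFT at all four own-history-cc states (all four do), with
smallest id as the residual tie-break.

## Evolutionary simulation

The rare-mutation Moran process keeps the population monomorphic: each
step draws a mutant (from the special set with probability μ, else
uniformly from the 11 × 11 reactive grid), which replaces the resident
with its closed-form fixation probability, evaluated in log-space via
cumulative sums so that no intermediate product can overflow.  Long-run
payoffs are exact stationary chain averages at the configured error rate
in the donation game; they are cached per (strategy pair, payoffs, e).
Reactive strategies are classed as rivals (p_d = 0; the corner (1,0)
counts as a rival), partners (p_c = 1, p_d < p_d* =
min{1−(T−R)/(R−S), (R−P)/(T−P)}; p_d* = 2/3 at b = 3), or other.
Abundance is the time fraction of resident identity per mutation event,
averaged over independent runs; the initial resident is drawn uniformly
from the grid.

Defaults follow the standard abundance experiment: b = 3, N = 50,
e = 1e-3, σ = 10/N, μ = 0.01.  The package's default run length is
scaled to a desk machine: 1e5 mutant introductions and 3 runs (the
reference experiment uses 1e7 and 10); the qualitative outcomes —
partners beat rivals on the plain grid, CAPRI becomes the single most
abundant strategy when present, and CAPRI beats TFT-ATFT head-to-head —
are stable at this size and asserted ordinally in the tests.  When both
special strategies are present each is drawn with probability μ/2 (the
split is a package choice; the reference protocol does not specify it).

### Robustness and the small-error limit

A friendly rival satisfies s_yy ≥ s_xy, s_yy ≥ s_xx and s_yx ≥ s_xy in
the e → 0⁺ limit, which bounds every mutant's fixation probability by the
neutral 1/N for all N and σ.  These are genuinely *limit* statements: at
finite e a never-forgiving mutant (p_d = 0) earns an O(e) payoff edge
over CAPRI by milking its recovery attempts, and at N = 2, e = 1e-3 its
fixation probability exceeds 1/N by ≈ 0.01 — consistent with CAPRI's low
abundance in minimal populations at that error rate.  The robustness
certificate therefore evaluates payoffs by default in the small-error
limit, using one-step Richardson extrapolation from e and 2e (stationary
payoffs are rational in e, so the extrapolation error is O(e²) ≈ 1e-10 at
the default base e = 1e-6); evaluation at the configured finite e is
available and reports the O(e) violations explicitly.

## Numerical choices and limitations

- Stationary solves are dense LU; state spaces are at most 4096 (memory-3
  pairs use 64 joint histories; automaton products stay small).
- The payoff-sampling experiment (random probabilistic memory-three
  co-players) defaults to e = 0: interior cooperation probabilities make
  the chain effectively ergodic, and the reducible-chain fallback covers
  the measure-zero exceptions.  The error rate is configurable.
- Floyd–Warshall path weights are small integers, exact in float32 for
  the batched scan.
- Limit-analysis tie handling: equal arborescence weights are compared
  with a 1e-9 tolerance on what are exact small integers.
- The synthetic ingredients here are the random strategy samples (uniform
  over strategy ids or over the probability hypercube) and the scripted
  exploit sequences; they probe the model's own state space exhaustively
  but say nothing about how human players deviate from these strategy
  classes.
- Strategies with m ≥ 4, n-player games, discounted payoffs, and
  structured populations are out of scope.
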