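# friendlyrivals

Tools for studying *friendly rivals* in the noisy iterated prisoner's
dilemma: deterministic memory-m strategies that are simultaneously

- **partners** — mutual play converges to the cooperative payoff *R*, and a
  deviating co-player earns less than *R*, and
- **rivals** — the player is never outperformed by the co-player, whatever
  strategy (and however long a memory) the co-player has.

The package is aimed at researchers in evolutionary game theory and social
evolution who want to classify repeated-game strategies axiomatically,
reproduce the exhaustive small-memory searches behind the friendly-rival
results, and run the rare-mutation evolutionary simulations in which the
memory-three strategy **CAPRI** dominates.

## The model

Two players repeatedly play a one-shot game with payoffs *T > R > P > S*
and *2R > T + S* (any game with *R > P*, *2R > T + S*, *T > S* is
accepted).  Actions are misimplemented independently with probability
*e*; a deterministic memory-m strategy maps the joint m-round history
(A<sub>t−m</sub>…A<sub>t−1</sub>, B<sub>t−m</sub>…B<sub>t−1</sub>) to c or
d, so there are 2^(2^2m) strategies: 16 at m = 1, 65,536 at m = 2,
~1.8 × 10¹⁹ at m = 3.

A strategy is classified by three axioms:

1. **Efficiency** — self-play reaches mutual cooperation with probability
   one as *e* → 0⁺.  Decided exactly by the zero-noise limit of the
   perturbed self-play Markov chain: recurrent classes of the error-free
   dynamics, minimal error-flip costs between them, and minimum
   spanning-arborescence weights; efficient iff the limiting mass sits
   solely on the full-cooperation class.
2. **Defensibility** — lim<sub>e→0⁺</sub>(π<sub>A</sub> − π<sub>B</sub>) ≥ 0
   against every opponent and every initial condition.  Equivalent to the
   absence of a negative cycle in a graph over the player's 4^m
   information states whose edge weights are the sign of
   (π<sub>A</sub> − π<sub>B</sub>) per realized action pair — a payoff-free
   test.
3. **Distinguishability** — strictly higher limit payoff than an
   unconditional cooperator, which protects a resident population against
   neutral drift toward AllC.

Efficiency ∧ defensibility = *friendly rival*; all three = *successful*.
Exhaustive scans included here reproduce the published memory-two counts:
7,639 efficient, 2,144 defensible, 8 friendly rivals, 4 successful — and
no friendly rival exists at m = 1.

CAPRI is built from its five rules (Cooperate at mutual cooperation,
Accept punishment after one's own error, Punish the co-player's defection
once, Recover from mutual defection, In all other cases defect).  Its
recovery from a single error takes only two rounds — the shortest
possible, and only realizable with m ≥ 3.

The evolution module implements the rare-mutation Moran process with the
Fermi imitation rule f<sub>x→y</sub> = 1/(1 + e^{σ(s_x − s_y)}) and the
closed-form fixation probability

    ρ = 1 / Σ_{i=0}^{N-1} Π_{j=1}^{i} exp(σ[(N−j−1)s_yy + j·s_yx − (N−j)s_xy − (j−1)s_xx])

evaluated in log-space, with long-run payoffs computed exactly from the
pair's stationary chain in the donation game (R = b−1, T = b, S = −1,
P = 0).

## Worked example

```sh
$ friendlyrivals classify --name CAPRI
{
  "strategy_id": 13776510895052946158,
  "m": 3,
  "efficient": true,
  "defensible": true,
  "distinguishable": true,
  "friendly_rival": true,
  "successful": true,
  "recovery_steps": 2,
  "recovery_alice": "cdccc",
  "recovery_bob": "dcccc"
}
```

CAPRI passes all three axioms.  The recovery strings show self-play after
Bob's single erroneous defection (round 0 is the error): Alice punishes
once (d), Bob accepts (c), and mutual cooperation is restored after
2 steps.  TFT, by contrast, classifies as `efficient: false,
defensible: true, distinguishable: false` — a rival, not a partner, since
noise traps TFT self-play into averaging all four payoffs.

The same from Python:

```python
import friendlyrivals as fr

report = fr.enumerate_strategies(2)       # full 65,536-strategy scan
print(report.n_efficient, report.n_defensible,
      report.n_intersection, report.n_successful)
# 7639 2144 8 4

cfg = fr.EvolutionConfig(special=(fr.capri(),), mu=0.01, seed=101)
print(fr.run_moran(cfg).most_abundant())
# CAPRI
```

`fr.canonical_tft_atft()` recovers the memory-two friendly rival TFT-ATFT
from the scan (recovery pattern `cddc` / `ddcc`, 3 steps), and
`fr.sample_payoff_cloud(fr.capri(), 1000, fr.PayoffMatrix(3, 4, 0, 1))`
confirms that CAPRI's long-run payoff is never below a random
probabilistic memory-three co-player's.

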