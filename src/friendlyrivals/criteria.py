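"""The three axioms: efficiency, defensibility, distinguishability.

A strategy is *efficient* if self-play converges to mutual cooperation
with probability one as the implementation-error rate tends to zero;
*defensible* if no co-player — of any memory length — can secure a higher
long-run payoff at zero error from any initial condition; and
*distinguishable* if it earns strictly more than an unconditional
cooperator in the small-error limit.  Efficiency and defensibility
together make a strategy a "friendly rival" (simultaneously a partner and
a rival); all three together make it "successful".

Defensibility reduces to a negative-cycle test on a graph over the focal
player's information states: from each joint state the focal action is
prescribed, the co-player chooses c or d, and the edge weight is the sign
of (focal payoff - co-player payoff) for the realized pair (+1 for dc, -1
for cd, 0 otherwise).  Any co-player behaviour, however long its memory,
induces a walk on this graph, so the absence of negative cycles bounds
lim_{e->0+}(pi_A - pi_B) >= 0 against all opponents; conversely a negative
cycle is a blueprint for an exploiting opponent.  Because only the signs
of the weights matter (given T > S), the verdict is independent of the
elementary payoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .payoffs import PayoffMatrix, build_chain, stationary_payoffs, zero_error_limit
from .strategies import (
    C,
    D,
    DeterministicMemoryStrategy,
    MemoryOneStrategy,
    MooreAutomaton,
    ProbabilisticMemoryStrategy,
    make_named,
    n_states,
    shift_state,
    swap_state,
)

__all__ = [
    "ClassificationResult",
    "RecoveryPath",
    "is_defensible",
    "find_negative_cycle",
    "is_efficient",
    "is_distinguishable",
    "classify",
    "recovery_path",
    "empirical_defensibility",
    "play_scripted",
]

EFFICIENCY_PROB_ERROR = 1e-6
EFFICIENCY_PROB_THRESHOLD = 0.99


# ---------------------------------------------------------------------------
# adversarial graph / defensibility


def _adversarial_graph(s):
    """Nodes, prescribed actions and successors of the defensibility graph.

    Returns ``(n, act, succ)`` where ``succ[u][b]`` is the node reached
    when the co-player plays ``b`` and the focal player follows the
    prescription ``act[u]``.
    """
    if isinstance(s, DeterministicMemoryStrategy):
        n = n_states(s.m)
        act = [int(s.table[u]) for u in range(n)]
        succ = [[shift_state(u, act[u], b, s.m) for b in (C, D)] for u in range(n)]
    elif isinstance(s, MooreAutomaton):
        n = s.n
        act = [int(s.output[u]) for u in range(n)]
        succ = [[s.step(u, act[u], b) for b in (C, D)] for u in range(n)]
    else:
        raise TypeError("defensibility is defined for deterministic strategies")
    return n, act, succ


def _edge_weight(a: int, b: int) -> int:
    if (a, b) == (D, C):
        return 1
    if (a, b) == (C, D):
        return -1
    return 0


def is_defensible(s) -> bool:
    """No cycle of the adversarial state graph favours the co-player.

    Floyd-Warshall on the (at most ``4**m``-node) graph; defensible iff no
    node lies on a negative-weight cycle.
    """
    n, act, succ = _adversarial_graph(s)
    Dm = np.full((n, n), np.inf)
    for u in range(n):
        for b in (C, D):
            w = _edge_weight(act[u], b)
            v = succ[u][b]
            if w < Dm[u, v]:
                Dm[u, v] = w
    for k in range(n):
        Dm = np.minimum(Dm, Dm[:, k, None] + Dm[None, k, :])
    return bool(not (np.diag(Dm) < 0).any())


def find_negative_cycle(s):
    """A negative-weight cycle of the adversarial graph, or ``None``.

    Returns a list of ``(state, co_player_action)`` edges forming the
    cycle; following them from ``cycle[0][0]`` realizes the co-player's
    long-run payoff advantage.
    """
    n, act, succ = _adversarial_graph(s)
    edges = [(u, succ[u][b], _edge_weight(act[u], b), b) for u in range(n) for b in (C, D)]
    dist = [0.0] * n  # virtual source connected to everything: finds any cycle
    pred: list[tuple[int, int] | None] = [None] * n
    marked = None
    for it in range(n + 1):
        updated = False
        for u, v, w, b in edges:
            if dist[u] + w < dist[v] - 1e-12:
                dist[v] = dist[u] + w
                pred[v] = (u, b)
                updated = True
                marked = v
        if not updated:
            return None
    # walk predecessors n steps to land inside the cycle, then extract it
    v = marked
    for _ in range(n):
        v = pred[v][0]
    cycle = []
    u = v
    while True:
        pu, b = pred[u]
        cycle.append((pu, b))
        u = pu
        if u == v:
            break
    cycle.reverse()
    return cycle


def empirical_defensibility(
    s,
    payoffs: PayoffMatrix,
    n_opponents: int = 100,
    seed: int = 0,
    tol: float = 1e-9,
    m_opponent: int = 2,
) -> bool:
    """Monte-Carlo defensibility certificate for probabilistic strategies.

    The exact negative-cycle test needs a deterministic prescription; for
    probabilistic strategies (e.g. extortionate ZD) this samples random
    probabilistic memory-``m_opponent`` co-players and checks that the
    long-run payoff never favours the opponent beyond ``tol`` at e = 0.
    A sampling check, not a proof.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_opponents):
        bob = ProbabilisticMemoryStrategy(m_opponent, rng.random(n_states(m_opponent)))
        res = stationary_payoffs(build_chain(s, bob, 0.0), payoffs)
        if res.pi_B > res.pi_A + tol:
            return False
    return True


# ---------------------------------------------------------------------------
# efficiency and distinguishability


def is_efficient(s) -> bool:
    """Self-play reaches mutual cooperation as ``e -> 0+``.

    Deterministic strategies use the exact zero-noise limit (the limiting
    stationary mass must sit solely on the full-cooperation class);
    probabilistic strategies use the numerical small-e criterion: self-play
    stationary mass on the full-cooperation state above 0.99 at e = 1e-6.
    """
    if isinstance(s, (DeterministicMemoryStrategy, MooreAutomaton)):
        return zero_error_limit(s, s).efficient
    chain = build_chain(s, s, EFFICIENCY_PROB_ERROR)
    res = stationary_payoffs(chain, PayoffMatrix())
    return bool(res.stationary[0] >= EFFICIENCY_PROB_THRESHOLD)


def is_distinguishable(s, verbose: bool = False) -> bool:
    """Strictly higher limit payoff than an unconditional cooperator.

    Exact route: zero-noise limit of the pair (s, AllC); if the limit
    support is a single class, compare cycle-average payoffs (payoff-free:
    the sign is the dc-count minus cd-count on the cycle).  If several
    classes tie, fall back to numerical stationary payoffs at small e and
    require a gap exceeding 10e at both e = 1e-5 and 1e-6.
    """
    allc = make_named("AllC")
    la = zero_error_limit(s, allc)
    if len(la.support) == 1:
        pairs = la.class_pairs[la.support[0]]
        balance = sum(1 if p == (D, C) else -1 if p == (C, D) else 0 for p in pairs)
        return balance > 0
    if verbose:  # pragma: no cover - logging path
        print("distinguishability: tied limit classes, using numerical fallback")
    payoffs = PayoffMatrix()
    for e in (1e-5, 1e-6):
        res = stationary_payoffs(build_chain(s, allc, e), payoffs)
        if not res.pi_A - res.pi_B > 10 * e:
            return False
    return True


# ---------------------------------------------------------------------------
# classification and recovery paths


@dataclass(frozen=True)
class ClassificationResult:
    efficient: bool
    defensible: bool
    distinguishable: bool

    @property
    def friendly_rival(self) -> bool:
        return self.efficient and self.defensible

    @property
    def successful(self) -> bool:
        return self.friendly_rival and self.distinguishable

    def to_dict(self) -> dict:
        return {
            "efficient": self.efficient,
            "defensible": self.defensible,
            "distinguishable": self.distinguishable,
            "friendly_rival": self.friendly_rival,
            "successful": self.successful,
        }


def classify(s) -> ClassificationResult:
    """Evaluate all three axioms for a deterministic strategy (memory table
    or automaton).  Defensibility is checked first (it is the cheapest and
    by far the most selective filter)."""
    defensible = is_defensible(s)
    efficient = is_efficient(s)
    distinguishable = is_distinguishable(s)
    return ClassificationResult(efficient, defensible, distinguishable)


@dataclass(frozen=True)
class RecoveryPath:
    """Self-play actions from the round of a single erroneous defection.

    Index 0 is the error round, always the realized pair (c, d).  If the
    pair returns to permanent mutual cooperation, ``steps_after_error``
    counts the rounds after the error up to and including the first round
    of the restored all-(c, c) run.
    """

    alice_actions: str
    bob_actions: str
    recovered: bool
    steps_after_error: int | None

    @property
    def pattern(self) -> tuple[str, str]:
        """Action strings from the error round through the first restored
        round — the shape tallied across successful strategies."""
        if not self.recovered:
            return (self.alice_actions, self.bob_actions)
        k = self.steps_after_error + 1
        return (self.alice_actions[:k], self.bob_actions[:k])


def recovery_path(s, max_rounds: int = 64) -> RecoveryPath:
    """Error-free self-play after one erroneous defection from mutual
    cooperation.

    Both players use ``s``; from the full-cooperation history Bob's action
    is misimplemented once (realized pair (c, d)), then play continues
    without error until the joint state returns to full cooperation or
    ``max_rounds`` elapses.
    """
    if isinstance(s, DeterministicMemoryStrategy):
        if s.table[0] != C:
            raise ValueError("strategy does not cooperate at mutual cooperation")
        m = s.m
        state = shift_state(0, C, D, m)
        actions = [(C, D)]
        for _ in range(max_rounds):
            if state == 0:
                break
            a = int(s.table[state])
            b = int(s.table[swap_state(state, m)])
            actions.append((a, b))
            state = shift_state(state, a, b, m)
        recovered = state == 0
    elif isinstance(s, MooreAutomaton):
        if s.output[s.initial] != C:
            raise ValueError("strategy does not cooperate at mutual cooperation")
        start = (s.initial, s.initial)
        u, v = s.step(start[0], C, D), s.step(start[1], D, C)
        actions = [(C, D)]
        recovered = False
        for _ in range(max_rounds):
            if (u, v) == start:
                recovered = True
                break
            a, b = int(s.output[u]), int(s.output[v])
            actions.append((a, b))
            u, v = s.step(u, a, b), s.step(v, b, a)
    else:
        raise TypeError("recovery paths are defined for deterministic strategies")

    alice = "".join("cd"[a] for a, _ in actions)
    bob = "".join("cd"[b] for _, b in actions)
    if not recovered:
        return RecoveryPath(alice, bob, False, None)
    last_noncc = 0
    for k in range(1, len(actions)):
        if actions[k] != (C, C):
            last_noncc = k
    return RecoveryPath(alice, bob, True, last_noncc + 1)


def classification_report(s, strategy_id: int | None = None, m: int | None = None) -> dict:
    """JSON-ready report combining the axiom verdicts and recovery path."""
    result = classify(s)
    steps = None
    try:
        path = recovery_path(s)
        steps = path.steps_after_error
    except (ValueError, TypeError):
        path = None
    return {
        "strategy_id": strategy_id,
        "m": m,
        **result.to_dict(),
        "recovery_steps": steps,
        "recovery_alice": path.alice_actions if path else None,
        "recovery_bob": path.bob_actions if path else None,
    }


# ---------------------------------------------------------------------------
# scripted play (witness realization)


def play_scripted(s, bob_actions, payoffs: PayoffMatrix, initial_state: int = 0):
    """Play a deterministic memory strategy against a scripted co-player.

    Alice follows ``s`` from ``initial_state`` (her information state);
    Bob's actions are given verbatim.  Returns average (pi_A, pi_B) over
    the scripted rounds — used to realize the payoff advantage promised by
    a negative defensibility cycle.
    """
    if not isinstance(s, DeterministicMemoryStrategy):
        raise TypeError("scripted play expects a memory-table strategy")
    u_a, u_b = payoffs.payoff_vectors()
    state = initial_state
    tot_a = tot_b = 0.0
    for b in bob_actions:
        b = int(b) if not isinstance(b, str) else "cd".index(b)
        a = int(s.table[state])
        tot_a += u_a[2 * a + b]
        tot_b += u_b[2 * a + b]
        state = shift_state(state, a, b, s.m)
    n = len(bob_actions)
    return tot_a / n, tot_b / n


def realize_negative_cycle(s, payoffs: PayoffMatrix, repeats: int = 50):
    """Construct the exploiting co-player promised by a negative cycle.

    Returns ``(pi_A, pi_B)`` of the focal strategy against a co-player who
    walks the cycle, or ``None`` if the strategy is defensible.
    """
    cycle = find_negative_cycle(s)
    if cycle is None:
        return None
    start = cycle[0][0]
    script = [b for _, b in cycle] * repeats
    return play_scripted(s, script, payoffs, initial_state=start)
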