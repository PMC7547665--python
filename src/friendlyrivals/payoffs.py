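"""Long-run payoffs for strategy pairs under implementation error.

Two deterministic or probabilistic strategies playing the repeated game
with per-action implementation error ``e`` induce a Markov chain on joint
states (joint m-histories for memory strategies, product states for
automata).  This module builds that chain, solves for stationary long-run
payoffs, and — for deterministic pairs — computes the exact ``e -> 0+``
limit by the standard zero-noise construction for perturbed Markov chains:
recurrent classes of the error-free dynamics, minimal error-flip costs
between them, and minimum-arborescence weights that select the classes
carrying the limiting stationary mass.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .strategies import (
    C,
    D,
    DeterministicMemoryStrategy,
    MemoryOneStrategy,
    MooreAutomaton,
    ProbabilisticMemoryStrategy,
    ReactiveStrategy,
    n_states,
    shift_table,
    swap_table,
)

__all__ = [
    "PayoffMatrix",
    "PairDynamics",
    "JointChain",
    "PayoffResult",
    "LimitAnalysis",
    "pair_dynamics",
    "build_chain",
    "stationary_payoffs",
    "zero_error_limit",
    "sample_payoff_cloud",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Elementary payoffs (R, T, S, P) of the one-shot game.

    The defaults describe a prisoner's dilemma (T > R > P > S, 2R > T + S)
    but any game with R > P, 2R > T + S and T > S is accepted — mutual
    cooperation socially optimal, exploiting better than being exploited —
    which also covers snowdrift and stag-hunt orderings.
    """

    R: float = 3.0
    T: float = 5.0
    S: float = 0.0
    P: float = 1.0

    def __post_init__(self):
        if not (self.R > self.P and 2 * self.R > self.T + self.S and self.T > self.S):
            raise ValueError("need R > P, 2R > T + S, and T > S")

    @classmethod
    def donation(cls, b: float) -> "PayoffMatrix":
        """Donation game with benefit ``b`` and unit cost:
        R = b - 1, T = b, S = -1, P = 0."""
        if b <= 1:
            raise ValueError("donation game needs b > 1")
        return cls(R=b - 1.0, T=b, S=-1.0, P=0.0)

    def payoff_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-action-pair payoffs indexed by ``2a + b`` (focal action a)."""
        u_a = np.array([self.R, self.S, self.T, self.P])
        u_b = np.array([self.R, self.T, self.S, self.P])
        return u_a, u_b


# ---------------------------------------------------------------------------
# pair dynamics: a uniform state-space view of any strategy pairing


@dataclass
class PairDynamics:
    """State space shared by a strategy pair.

    ``succ[s, a, b]`` is the successor of state ``s`` when the realized
    actions are ``(a, b)``.  For deterministic pairs ``act_a``/``act_b``
    hold the intended actions; for chains ``coop_a``/``coop_b`` hold
    intended cooperation probabilities.  ``kind`` is "history" (states are
    joint m-histories; full cooperation is state 0) or "product"
    (automaton state pairs reachable from the joint start).
    """

    kind: str
    n: int
    succ: np.ndarray
    coop_a: np.ndarray
    coop_b: np.ndarray
    m: int | None = None
    act_a: np.ndarray | None = None
    act_b: np.ndarray | None = None

    @property
    def deterministic(self) -> bool:
        return self.act_a is not None and self.act_b is not None


def _as_prob_table(s):
    if isinstance(s, DeterministicMemoryStrategy):
        return s
    if isinstance(s, ProbabilisticMemoryStrategy):
        return s
    if isinstance(s, (MemoryOneStrategy, ReactiveStrategy)):
        p = s.to_probabilistic()
        if isinstance(s, MemoryOneStrategy) and s.deterministic:
            return p.to_deterministic()
        return p
    return None


def pair_dynamics(sA, sB) -> PairDynamics:
    """Common state space for a pair of strategies.

    Memory strategies are embedded into the longer of the two memory
    lengths and paired on joint histories; if an automaton is involved both
    sides are converted to automata and paired on reachable product states
    (automata must be deterministic).
    """
    ta, tb = _as_prob_table(sA), _as_prob_table(sB)
    if ta is not None and tb is not None:
        m = max(ta.m, tb.m)
        ta, tb = ta.embed(m), tb.embed(m)
        n = n_states(m)
        swp = swap_table(m)
        qa = ta.cooperation_probs()
        qb = tb.cooperation_probs()[swp]
        dyn = PairDynamics(
            kind="history",
            n=n,
            succ=shift_table(m),
            coop_a=qa,
            coop_b=qb,
            m=m,
        )
        if isinstance(ta, DeterministicMemoryStrategy) and isinstance(tb, DeterministicMemoryStrategy):
            dyn.act_a = ta.table.astype(np.int64)
            dyn.act_b = tb.table.astype(np.int64)[swp]
        return dyn

    # automaton route
    autA = sA if isinstance(sA, MooreAutomaton) else _to_automaton(sA)
    autB = sB if isinstance(sB, MooreAutomaton) else _to_automaton(sB)
    index = {(autA.initial, autB.initial): 0}
    states = [(autA.initial, autB.initial)]
    i = 0
    while i < len(states):
        u, v = states[i]
        for a in (C, D):
            for b in (C, D):
                nxt = (autA.step(u, a, b), autB.step(v, b, a))
                if nxt not in index:
                    index[nxt] = len(states)
                    states.append(nxt)
        i += 1
    n = len(states)
    succ = np.empty((n, 2, 2), dtype=np.int64)
    act_a = np.empty(n, dtype=np.int64)
    act_b = np.empty(n, dtype=np.int64)
    for s, (u, v) in enumerate(states):
        act_a[s] = autA.output[u]
        act_b[s] = autB.output[v]
        for a in (C, D):
            for b in (C, D):
                succ[s, a, b] = index[(autA.step(u, a, b), autB.step(v, b, a))]
    return PairDynamics(
        kind="product",
        n=n,
        succ=succ,
        coop_a=1.0 - act_a.astype(float),
        coop_b=1.0 - act_b.astype(float),
        act_a=act_a,
        act_b=act_b,
    )


def _to_automaton(s):
    t = _as_prob_table(s)
    if isinstance(t, DeterministicMemoryStrategy):
        return t.to_automaton()
    raise TypeError("automaton pairing requires deterministic strategies")


# ---------------------------------------------------------------------------
# chains and stationary payoffs


@dataclass
class JointChain:
    """Row-stochastic transition matrix over the pair's joint states."""

    dyn: PairDynamics
    e: float
    e_b: float
    matrix: np.ndarray
    coop_a: np.ndarray  # effective (error-convolved) cooperation probabilities
    coop_b: np.ndarray

    @property
    def n(self) -> int:
        return self.dyn.n


def build_chain(sA, sB, e: float, payoffs: PayoffMatrix | None = None, e_b: float | None = None) -> JointChain:
    """Joint Markov chain for a strategy pair with implementation error.

    Intended cooperation probabilities come from each strategy's own view
    of the state; each player's realized action then flips independently
    with probability ``e`` (``e_b`` for the second player if given).
    """
    if e_b is None:
        e_b = e
    if not (0.0 <= e <= 0.5 and 0.0 <= e_b <= 0.5):
        raise ValueError("error rates must lie in [0, 1/2]")
    dyn = pair_dynamics(sA, sB)
    qa = dyn.coop_a * (1 - e) + (1 - dyn.coop_a) * e
    qb = dyn.coop_b * (1 - e_b) + (1 - dyn.coop_b) * e_b
    n = dyn.n
    M = np.zeros((n, n))
    rows = np.arange(n)
    for a in (C, D):
        pa = qa if a == C else 1 - qa
        for b in (C, D):
            pb = qb if b == C else 1 - qb
            np.add.at(M, (rows, dyn.succ[:, a, b]), pa * pb)
    return JointChain(dyn, e, e_b, M, qa, qb)


@dataclass
class PayoffResult:
    pi_A: float
    pi_B: float
    stationary: np.ndarray


def _stationary(M: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Dense solve of pi M = pi with a normalization row; falls back to
    repeated squaring of the lazy chain (I + M)/2 from the uniform start
    when the linear system is singular or ill-conditioned (reducible
    chains yield the Cesaro average over recurrent classes in that case).
    """
    n = M.shape[0]
    A = M.T - np.eye(n)
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        pi = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        pi = None
    if pi is not None and pi.min() > -1e-9 and abs(pi.sum() - 1.0) < 1e-6:
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()
    B = 0.5 * (M + np.eye(n))
    for _ in range(60):
        B = B @ B
        B /= B.sum(axis=1, keepdims=True)
    pi = np.full(n, 1.0 / n) @ B
    return pi / pi.sum()


def stationary_payoffs(chain: JointChain, payoffs: PayoffMatrix) -> PayoffResult:
    """Long-run average payoffs from the chain's stationary distribution.

    Payoff is attributed per transition: the expected one-shot payoff of
    the realized action pair leaving each state, averaged under the
    stationary distribution.
    """
    if chain.e == 0.0 and chain.e_b == 0.0 and chain.dyn.deterministic:
        raise ValueError(
            "deterministic pair at e=0 gives a reducible chain; "
            "use zero_error_limit or a positive error rate"
        )
    u_a, u_b = payoffs.payoff_vectors()
    qa, qb = chain.coop_a, chain.coop_b
    r_a = np.zeros(chain.n)
    r_b = np.zeros(chain.n)
    for a in (C, D):
        pa = qa if a == C else 1 - qa
        for b in (C, D):
            pb = qb if b == C else 1 - qb
            r_a += pa * pb * u_a[2 * a + b]
            r_b += pa * pb * u_b[2 * a + b]
    pi = _stationary(chain.matrix)
    return PayoffResult(float(pi @ r_a), float(pi @ r_b), pi)


# ---------------------------------------------------------------------------
# exact e -> 0 limit for deterministic pairs


@dataclass
class LimitAnalysis:
    """Zero-noise limit of a deterministic pair's perturbed chain.

    ``classes`` are the recurrent classes (cycles) of the error-free
    dynamics, ``cost[i, j]`` the minimal number of flipped actions needed
    to travel from class i to class j without crossing a third class, and
    ``W[k]`` the minimum spanning in-arborescence weight rooted at class k.
    The limiting stationary mass concentrates on ``support`` (the argmin
    of W).
    """

    dyn: PairDynamics
    classes: list[list[int]]
    transient: list[int]
    cost: np.ndarray
    W: np.ndarray
    support: list[int]
    class_pairs: list[list[tuple[int, int]]] = field(default_factory=list)

    def class_of_state(self, state: int) -> int | None:
        for k, cls in enumerate(self.classes):
            if state in cls:
                return k
        return None

    def is_full_cooperation(self, k: int) -> bool:
        return all(pair == (C, C) for pair in self.class_pairs[k])

    @property
    def efficient(self) -> bool:
        """True iff the limit mass sits solely on the mutual-cooperation
        class."""
        return len(self.support) == 1 and self.is_full_cooperation(self.support[0])

    def class_payoffs(self, k: int, payoffs: PayoffMatrix) -> tuple[float, float]:
        u_a, u_b = payoffs.payoff_vectors()
        pairs = self.class_pairs[k]
        ia = sum(u_a[2 * a + b] for a, b in pairs) / len(pairs)
        ib = sum(u_b[2 * a + b] for a, b in pairs) / len(pairs)
        return float(ia), float(ib)

    def limit_payoffs(self, payoffs: PayoffMatrix) -> tuple[float, float]:
        if len(self.support) != 1:
            raise ValueError("limit support is not unique; payoffs depend on tie weights")
        return self.class_payoffs(self.support[0], payoffs)


def _recurrent_classes(f: list[int]) -> tuple[list[list[int]], list[int]]:
    """Cycles of a functional graph (= recurrent classes of the error-free
    chain) and the remaining transient states."""
    n = len(f)
    color = [0] * n  # 0 new, 1 on current path, 2 finished
    classes: list[list[int]] = []
    for s0 in range(n):
        if color[s0]:
            continue
        path = []
        s = s0
        while color[s] == 0:
            color[s] = 1
            path.append(s)
            s = f[s]
        if color[s] == 1:  # closed a fresh cycle
            cyc = path[path.index(s):]
            classes.append(cyc)
        for t in path:
            color[t] = 2
    in_class = set(itertools.chain.from_iterable(classes))
    transient = [s for s in range(n) if s not in in_class]
    return classes, transient


def _interclass_costs(f, succ, aA, aB, classes) -> list[list[float]]:
    """Minimal flip-count costs between recurrent classes.

    Multi-source Dijkstra from each class over the full state graph; each
    transition costs the number of actions that must be misimplemented to
    realize it.  Paths may pass through transient states but not through a
    third recurrent class.
    """
    n = len(f)
    K = len(classes)
    class_id = [-1] * n
    for k, cyc in enumerate(classes):
        for s in cyc:
            class_id[s] = k
    cost = [[math.inf] * K for _ in range(K)]
    for i in range(K):
        dist = [math.inf] * n
        heap = []
        for s in classes[i]:
            dist[s] = 0
            heap.append((0, s))
        heapq.heapify(heap)
        while heap:
            d, s = heapq.heappop(heap)
            if d > dist[s]:
                continue
            cid = class_id[s]
            if cid not in (-1, i):
                if d < cost[i][cid]:
                    cost[i][cid] = d
                continue  # record arrival, do not pass through
            a, b = aA[s], aB[s]
            row = succ[s]
            for ra in (0, 1):
                for rb in (0, 1):
                    nd = d + (ra != a) + (rb != b)
                    t = row[ra][rb]
                    if nd < dist[t]:
                        dist[t] = nd
                        heapq.heappush(heap, (nd, t))
    return cost


def _min_arborescence_weight(cost, root: int) -> float:
    """Weight of the cheapest spanning in-arborescence rooted at ``root``:
    every other class gets one outgoing edge and all paths lead to the
    root.  Brute force over parent assignments for up to 7 classes, Edmonds
    via networkx beyond that."""
    K = len(cost)
    if K == 1:
        return 0.0
    others = [i for i in range(K) if i != root]
    if K <= 7:
        best = math.inf
        choices = [[j for j in range(K) if j != i] for i in others]
        for parents in itertools.product(*choices):
            w = 0.0
            for i, p in zip(others, parents):
                w += cost[i][p]
                if w >= best:
                    break
            else:
                pmap = dict(zip(others, parents))
                ok = True
                for i in others:
                    seen = set()
                    j = i
                    while j != root:
                        if j in seen:
                            ok = False
                            break
                        seen.add(j)
                        j = pmap[j]
                    if not ok:
                        break
                if ok and w < best:
                    best = w
        return best
    import networkx as nx

    G = nx.DiGraph()
    G.add_nodes_from(range(K))
    for i in others:
        for j in range(K):
            if j != i and math.isfinite(cost[i][j]):
                # reverse the edge: an out-edge i->j becomes j->i so the
                # in-arborescence toward root becomes an out-arborescence
                G.add_edge(j, i, weight=cost[i][j])
    G.remove_edges_from([(u, root) for u in list(G.predecessors(root))])
    try:
        T = nx.minimum_spanning_arborescence(G, attr="weight")
    except nx.NetworkXException:
        return math.inf
    return float(sum(d["weight"] for _, _, d in T.edges(data=True)))


def _limit_analysis_core(aA, aB, succ):
    """Shared implementation operating on plain lists for speed."""
    n = len(aA)
    f = [succ[s][aA[s]][aB[s]] for s in range(n)]
    classes, transient = _recurrent_classes(f)
    cost = _interclass_costs(f, succ, aA, aB, classes)
    W = [_min_arborescence_weight(cost, k) for k in range(len(classes))]
    wmin = min(W)
    support = [k for k, w in enumerate(W) if w <= wmin + 1e-9]
    return classes, transient, cost, W, support


def zero_error_limit(sA, sB) -> LimitAnalysis:
    """Exact ``e -> 0+`` limit analysis for a deterministic strategy pair."""
    dyn = pair_dynamics(sA, sB)
    if not dyn.deterministic:
        raise ValueError("zero_error_limit requires deterministic strategies; "
                         "use stationary_payoffs at small e instead")
    aA = dyn.act_a.tolist()
    aB = dyn.act_b.tolist()
    succ = dyn.succ.tolist()
    classes, transient, cost, W, support = _limit_analysis_core(aA, aB, succ)
    class_pairs = [[(aA[s], aB[s]) for s in cyc] for cyc in classes]
    return LimitAnalysis(
        dyn=dyn,
        classes=classes,
        transient=transient,
        cost=np.array(cost),
        W=np.array(W),
        support=support,
        class_pairs=class_pairs,
    )


# ---------------------------------------------------------------------------
# payoff sampling against random probabilistic co-players


def sample_payoff_cloud(
    alice,
    n: int,
    payoffs: PayoffMatrix,
    e: float = 0.0,
    seed: int = 0,
    m: int = 3,
) -> np.ndarray:
    """Long-run payoff pairs of ``alice`` against ``n`` co-players drawn
    uniformly from the ``4**m``-dimensional unit hypercube of probabilistic
    memory-m strategies.  Returns an ``(n, 2)`` array of (pi_A, pi_B)."""
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    for i in range(n):
        bob = ProbabilisticMemoryStrategy(m, rng.random(n_states(m)))
        chain = build_chain(alice, bob, e)
        res = stationary_payoffs(chain, payoffs)
        out[i] = (res.pi_A, res.pi_B)
    return out
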