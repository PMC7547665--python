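"""Low-mutation Moran dynamics over a strategy set.

In the rare-mutation regime a well-mixed population of size N is
monomorphic almost all the time: a single mutant either fixes or vanishes
before the next one appears, so evolution reduces to a Markov chain on the
resident strategy.  Fixation probabilities follow the closed form for the
pairwise-comparison (Fermi) process with selection strength sigma,

    rho = 1 / sum_{i=0}^{N-1} prod_{j=1}^{i}
              exp(sigma [ (N-j-1) s_yy + j s_yx - (N-j) s_xy - (j-1) s_xx ])

evaluated in log-space for numerical stability.  Long-run payoffs s_xy are
exact stationary chain averages at the configured error rate, for the
donation game with benefit b (R = b-1, T = b, S = -1, P = 0).

The default mutant set is the 11x11 grid of reactive strategies (pc, pd);
"special" strategies such as CAPRI or TFT-ATFT can be injected with a
small probability per mutation event, mirroring the standard abundance
experiment for partner/rival classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .payoffs import PayoffMatrix, build_chain, stationary_payoffs
from .strategies import ReactiveStrategy, strategy_key

__all__ = [
    "EvolutionConfig",
    "FixationResult",
    "AbundanceReport",
    "reactive_grid",
    "imitation_probability",
    "fixation_probability",
    "fixation_probability_values",
    "long_run_payoffs",
    "limit_long_run_payoffs",
    "classify_reactive",
    "run_moran",
    "robustness_certificate",
    "sweep",
]

logger = logging.getLogger(__name__)

_PAYOFF_CACHE: dict = {}


def reactive_grid(resolution: int = 10) -> list[ReactiveStrategy]:
    """Reactive strategies with pc, pd on the (resolution+1)-point lattice
    {0, 1/res, ..., 1} — the standard 121-strategy mutant set."""
    pts = [k / resolution for k in range(resolution + 1)]
    return [ReactiveStrategy(pc, pd) for pc in pts for pd in pts]


@dataclass
class EvolutionConfig:
    """Parameters of the rare-mutation Moran simulation.

    ``sigma`` defaults to 10/N, keeping the product N*sigma at 10.  ``mu``
    is the probability that a mutation event draws from ``special``
    (uniformly within it) instead of the reactive grid.
    """

    N: int = 50
    b: float = 3.0
    e: float = 1e-3
    sigma: float | None = None
    mu: float = 0.01
    special: tuple = ()
    grid_resolution: int = 10
    grid: tuple | None = None  # explicit mutant set; defaults to the reactive grid
    steps: int = 100_000
    runs: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("population size N must be at least 2")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.sigma is None:
            self.sigma = 10.0 / self.N

    @property
    def payoffs(self) -> PayoffMatrix:
        return PayoffMatrix.donation(self.b)


@dataclass(frozen=True)
class FixationResult:
    rho: float
    s_xx: float
    s_xy: float
    s_yx: float
    s_yy: float


# ---------------------------------------------------------------------------
# payoffs and fixation


def long_run_payoffs(x, y, payoffs: PayoffMatrix, e: float) -> tuple[float, float]:
    """Stationary long-run payoffs (s_xy, s_yx) of x against y, cached."""
    kx, ky = strategy_key(x), strategy_key(y)
    pk = (payoffs.R, payoffs.T, payoffs.S, payoffs.P, e)
    hit = _PAYOFF_CACHE.get((kx, ky, pk))
    if hit is not None:
        return hit
    res = stationary_payoffs(build_chain(x, y, e), payoffs)
    _PAYOFF_CACHE[(kx, ky, pk)] = (res.pi_A, res.pi_B)
    _PAYOFF_CACHE[(ky, kx, pk)] = (res.pi_B, res.pi_A)
    return res.pi_A, res.pi_B


def limit_long_run_payoffs(
    x, y, payoffs: PayoffMatrix, e_base: float = 1e-6
) -> tuple[float, float]:
    """Small-error limit of the long-run payoffs (s_xy, s_yx).

    Stationary payoffs are rational functions of the error rate, so a
    one-step Richardson extrapolation from ``e_base`` and ``2 * e_base``
    removes the O(e) term and estimates the ``e -> 0+`` value with O(e^2)
    error.  This is the scale on which the partner/rival inequalities of a
    friendly rival hold exactly; at any finite e they may be violated by
    O(e) terms (e.g. a never-forgiving mutant milks the focal strategy's
    recovery attempts).
    """
    a1 = long_run_payoffs(x, y, payoffs, e_base)
    a2 = long_run_payoffs(x, y, payoffs, 2 * e_base)
    return tuple(2 * v1 - v2 for v1, v2 in zip(a1, a2))


def imitation_probability(s_x: float, s_y: float, sigma: float) -> float:
    """Fermi rule: probability that a player using X adopts Y instead."""
    return float(1.0 / (1.0 + np.exp(sigma * (s_x - s_y))))


def fixation_probability_values(
    s_xx: float, s_xy: float, s_yx: float, s_yy: float, N: int, sigma: float
) -> float:
    """Closed-form fixation probability of a single X mutant among Y
    residents, evaluated via cumulative log-sums (overflow-free)."""
    if N < 2:
        raise ValueError("N must be at least 2")
    j = np.arange(1, N)
    alpha = sigma * ((N - j - 1) * s_yy + j * s_yx - (N - j) * s_xy - (j - 1) * s_xx)
    cum = np.concatenate(([0.0], np.cumsum(alpha)))
    return float(np.exp(-logsumexp(cum)))


def fixation_probability(x, y, cfg: EvolutionConfig) -> FixationResult:
    """Fixation probability of mutant ``x`` in a resident ``y`` population
    under ``cfg`` (donation payoffs at error rate cfg.e)."""
    payoffs = cfg.payoffs
    s_xy, s_yx = long_run_payoffs(x, y, payoffs, cfg.e)
    s_xx, _ = long_run_payoffs(x, x, payoffs, cfg.e)
    s_yy, _ = long_run_payoffs(y, y, payoffs, cfg.e)
    rho = fixation_probability_values(s_xx, s_xy, s_yx, s_yy, cfg.N, cfg.sigma)
    return FixationResult(rho, s_xx, s_xy, s_yx, s_yy)


# ---------------------------------------------------------------------------
# reactive classification


def partner_pd_threshold(payoffs: PayoffMatrix) -> float:
    """Largest forgiveness p_d* below which a fully-cooperative reactive
    strategy still limits the co-player to at most R."""
    R, T, S, P = payoffs.R, payoffs.T, payoffs.S, payoffs.P
    return min(1 - (T - R) / (R - S), (R - P) / (T - P))


def classify_reactive(s: ReactiveStrategy, payoffs: PayoffMatrix) -> str:
    """Partner / rival / other classification of a reactive strategy.

    Rivals never forgive (pd = 0); partners always reciprocate cooperation
    (pc = 1) and forgive below the threshold p_d*.  The corner (1, 0)
    counts as a rival.
    """
    if s.pd == 0.0:
        return "rival"
    if s.pc == 1.0 and s.pd < partner_pd_threshold(payoffs):
        return "partner"
    return "other"


# ---------------------------------------------------------------------------
# the resident-strategy Markov chain


@dataclass
class AbundanceReport:
    """Long-run resident frequencies from a rare-mutation Moran run."""

    config: EvolutionConfig
    labels: list[str]
    per_strategy: dict[str, float]
    per_class: dict[str, float]

    def most_abundant(self) -> str:
        return max(self.per_strategy, key=self.per_strategy.get)


def _strategy_label(s) -> str:
    if isinstance(s, ReactiveStrategy):
        return f"reactive({s.pc:.1f},{s.pd:.1f})"
    name = getattr(s, "name", None)
    return name or repr(s)


def _rho_matrix(strategies, cfg: EvolutionConfig) -> np.ndarray:
    """rho[i, j]: fixation probability of mutant i in resident j."""
    n = len(strategies)
    payoffs = cfg.payoffs
    s_self = np.array(
        [long_run_payoffs(s, s, payoffs, cfg.e)[0] for s in strategies]
    )
    rho = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                rho[i, j] = 1.0 / cfg.N
                continue
            s_ij, s_ji = long_run_payoffs(strategies[i], strategies[j], payoffs, cfg.e)
            rho[i, j] = fixation_probability_values(
                s_self[i], s_ij, s_ji, s_self[j], cfg.N, cfg.sigma
            )
    return rho


def run_moran(cfg: EvolutionConfig) -> AbundanceReport:
    """Rare-mutation Moran chain over the configured mutant set.

    Each step introduces one mutant (from ``cfg.special`` with probability
    ``cfg.mu``, else uniformly from the reactive grid) into the current
    resident population; the mutant replaces the resident with its
    fixation probability.  Resident identity is accumulated per step and
    averaged over ``cfg.runs`` independent runs.
    """
    grid = list(cfg.grid) if cfg.grid is not None else reactive_grid(cfg.grid_resolution)
    specials = list(cfg.special)
    if not grid and not specials:
        raise ValueError("empty mutant set")
    strategies = grid + specials
    n_grid, n_total = len(grid), len(strategies)
    labels = [_strategy_label(s) for s in strategies]
    logger.info("moran: precomputing %d x %d fixation matrix", n_total, n_total)
    rho = _rho_matrix(strategies, cfg)

    occupancy = np.zeros(n_total)
    for run in range(cfg.runs):
        rng = np.random.default_rng(cfg.seed + 7919 * run)
        resident = int(rng.integers(n_grid))
        u_special = rng.random(cfg.steps)
        grid_draw = rng.integers(0, n_grid, cfg.steps)
        special_draw = (
            rng.integers(0, len(specials), cfg.steps) if specials else np.zeros(cfg.steps, int)
        )
        u_fix = rng.random(cfg.steps)
        use_special = u_special < (cfg.mu if specials else 0.0)
        for t in range(cfg.steps):
            if use_special[t]:
                mutant = n_grid + special_draw[t]
            else:
                mutant = grid_draw[t]
            if u_fix[t] < rho[mutant, resident]:
                resident = mutant
            occupancy[resident] += 1.0
    occupancy /= occupancy.sum()

    per_strategy = dict(zip(labels, occupancy))
    per_class: dict[str, float] = {"partner": 0.0, "rival": 0.0, "other": 0.0}
    payoffs = cfg.payoffs
    for s, frac in zip(grid, occupancy[:n_grid]):
        if isinstance(s, ReactiveStrategy):
            per_class[classify_reactive(s, payoffs)] += float(frac)
        else:
            per_class[_strategy_label(s)] = per_class.get(_strategy_label(s), 0.0) + float(frac)
    for lab, frac in zip(labels[n_grid:], occupancy[n_grid:]):
        per_class[lab] = float(frac)
    return AbundanceReport(cfg, labels, per_strategy, per_class)


def sweep(cfg: EvolutionConfig, vary: str, values) -> list[dict]:
    """Abundance runs varying one environmental parameter at a time.

    ``vary`` is one of ``b`` (benefit-to-cost ratio), ``N`` (population
    size; sigma is re-derived as 10/N), or ``e`` (error rate); all other
    parameters stay at ``cfg``'s values.  Returns one row per cell with
    the per-class abundances.
    """
    if vary not in ("b", "N", "e"):
        raise ValueError("vary must be one of 'b', 'N', 'e'")
    rows = []
    for v in values:
        kwargs = dict(
            N=cfg.N,
            b=cfg.b,
            e=cfg.e,
            sigma=cfg.sigma,
            mu=cfg.mu,
            special=cfg.special,
            grid_resolution=cfg.grid_resolution,
            grid=cfg.grid,
            steps=cfg.steps,
            runs=cfg.runs,
            seed=cfg.seed,
        )
        kwargs[vary] = int(v) if vary == "N" else float(v)
        if vary == "N":
            kwargs["sigma"] = None  # keep N * sigma = 10
        report = run_moran(EvolutionConfig(**kwargs))
        rows.append({vary: kwargs[vary], **report.per_class})
    return rows


# ---------------------------------------------------------------------------
# evolutionary robustness


@dataclass
class RobustnessReport:
    ok: bool
    violations: list[dict]


def robustness_certificate(
    y,
    mutants,
    cfg: EvolutionConfig,
    N_grid=(2, 10, 50),
    tol: float = 1e-6,
    at_limit: bool = True,
) -> RobustnessReport:
    """Check evolutionary robustness of resident ``y`` against ``mutants``.

    Verifies the partner inequalities s_yy >= s_xy and s_yy >= s_xx, the
    rival inequality s_yx >= s_xy (within ``tol``), and rho <= 1/N for
    every mutant and every N in ``N_grid`` with sigma = 10/N.  By default
    payoffs are extrapolated to the ``e -> 0+`` limit, where a friendly
    rival satisfies the inequality chain exactly; with ``at_limit=False``
    payoffs are evaluated at ``cfg.e``, where O(e) violations can appear
    for small populations.  Any violation is reported with the offending
    payoffs.
    """
    payoffs = cfg.payoffs
    if at_limit:
        get = lambda a, b: limit_long_run_payoffs(a, b, payoffs)
    else:
        get = lambda a, b: long_run_payoffs(a, b, payoffs, cfg.e)
    s_yy, _ = get(y, y)
    violations = []
    for x in mutants:
        s_xy, s_yx = get(x, y)
        s_xx, _ = get(x, x)
        for name, lhs, rhs in (
            ("s_yy >= s_xy", s_yy, s_xy),
            ("s_yy >= s_xx", s_yy, s_xx),
            ("s_yx >= s_xy", s_yx, s_xy),
        ):
            if lhs < rhs - tol:
                violations.append(
                    {"mutant": _strategy_label(x), "inequality": name, "lhs": lhs, "rhs": rhs}
                )
        for N in N_grid:
            rho = fixation_probability_values(s_xx, s_xy, s_yx, s_yy, N, 10.0 / N)
            if rho > 1.0 / N + 1e-9:
                violations.append(
                    {
                        "mutant": _strategy_label(x),
                        "inequality": f"rho <= 1/N at N={N}",
                        "lhs": rho,
                        "rhs": 1.0 / N,
                    }
                )
    return RobustnessReport(ok=not violations, violations=violations)
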