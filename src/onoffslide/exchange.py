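"""Flag/Myc histone pool model and the 27-state tagged exchange dynamics.

Cells constitutively express Myc-tagged histone H3 and are induced at t = 0
to additionally express Flag-tagged H3.  The free-histone pool then contains
Myc at a constant level ``M = alpha_M / beta_M`` and Flag rising as
``F(t) = alpha_F / beta_F * (1 - exp(-beta_F (t - t0)))`` after a lag ``t0``.
A newly assembled nucleosome carries a Flag tag with probability
``P+(t) = F(t) / (F(t) + M)``.

To follow tags through any on-off-slide model, each of the 8 promoter
configurations is refined into tagged variants (empty / Flag / Myc per
site), giving 27 extended states.  Assembly splits into a Flag channel
(rate × P+) and a Myc channel (rate × (1 − P+)); disassembly and sliding
move or remove tags at the untagged rates.  Marginalizing over tags
recovers the 8-state dynamics exactly (lumpability).

Observables: ``g(t) = log2(Flag@N-1 / Flag@N-2)`` and
``h(t) = log2(Flag@N-1 / Myc@N-1)``; the measured h series is compared
after centering (subtracting its mean over the time points).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config_space import build_configuration_space
from .dynamics import STATES  # noqa: F401  (documented state order)

__all__ = [
    "PoolParams",
    "EXTENDED_STATES",
    "flag_probability",
    "flag_probability_limit",
    "extended_generator_parts",
    "build_extended_generator",
    "tag_marginal",
    "initial_extended_state",
    "solve_extended",
    "tag_amounts",
    "exchange_observables",
]

_MIN_PER_H = 60.0


@dataclass(frozen=True)
class PoolParams:
    """Histone pool kinetics (rates per minute, lag in minutes)."""

    alpha_flag: float = 50.0   # Flag H3 production rate (1/min)
    alpha_myc: float = 10.0    # Myc H3 production rate (1/min)
    beta_flag: float = 0.01    # Flag H3 degradation rate (1/min)
    beta_myc: float = 0.03     # Myc H3 degradation rate (1/min)
    lag_time_min: float = 15.0

    def __post_init__(self) -> None:
        for name in ("alpha_flag", "alpha_myc", "beta_flag", "beta_myc", "lag_time_min"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"pool parameter {name} must be positive")

    @property
    def lag_time_h(self) -> float:
        return self.lag_time_min / _MIN_PER_H


def flag_probability(t_hours, pool: PoolParams = PoolParams()):
    """Probability P+ that a nucleosome assembled at time ``t_hours`` is Flag-tagged.

    Zero before the lag time, monotone nondecreasing afterwards, approaching
    ``flag_probability_limit(pool)`` as t -> infinity.  Accepts scalars or
    arrays (hours).
    """
    t = np.asarray(t_hours, dtype=float)
    t_min = t * _MIN_PER_H
    myc = pool.alpha_myc / pool.beta_myc
    with np.errstate(over="ignore"):
        flag = (pool.alpha_flag / pool.beta_flag
                * -np.expm1(-pool.beta_flag * (t_min - pool.lag_time_min)))
    flag = np.where(t_min <= pool.lag_time_min, 0.0, flag)
    out = flag / (flag + myc)
    return out if out.ndim else float(out)


def flag_probability_limit(pool: PoolParams = PoolParams()) -> float:
    """Analytic t -> infinity limit of ``flag_probability``."""
    ratio = (pool.alpha_myc * pool.beta_flag) / (pool.alpha_flag * pool.beta_myc)
    return 1.0 / (1.0 + ratio)


# --------------------------------------------------------------------------
# extended (tagged) state space: tag per site in {0: empty, 1: Flag, 2: Myc}

EXTENDED_STATES: tuple[tuple[int, int, int], ...] = tuple(
    itertools.product((0, 1, 2), repeat=3)
)
_EXT_INDEX = {s: i for i, s in enumerate(EXTENDED_STATES)}
N_EXT = len(EXTENDED_STATES)


def _occupancy_of(ext: tuple[int, int, int]) -> tuple[int, int, int]:
    return tuple(int(t != 0) for t in ext)


#: extended state index -> 0-based configuration index (projection map)
_PROJECTION = np.array([
    build_configuration_space().index_of(_occupancy_of(s)) - 1 for s in EXTENDED_STATES
])


def extended_generator_parts(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the tagged generator as ``E(P+) = B + P+ * Delta``.

    ``B`` is the generator with all assembly routed to the Myc channel
    (P+ = 0); ``Delta`` moves assembly probability from the Myc to the Flag
    channel and has zero row sums, so the diagonal of ``E`` is P+-independent.
    """
    space = build_configuration_space()
    B = np.zeros((N_EXT, N_EXT))
    Delta = np.zeros((N_EXT, N_EXT))
    for r in space.reactions:
        rate = Q[r.source - 1, r.target - 1]
        if rate == 0.0:
            continue
        src_occ = space.occupancy(r.source)
        for ext in EXTENDED_STATES:
            if _occupancy_of(ext) != src_occ:
                continue
            e = _EXT_INDEX[ext]
            if r.kind == "assembly":
                k = r.site - 1
                flag_t = list(ext); flag_t[k] = 1
                myc_t = list(ext); myc_t[k] = 2
                fi, mi = _EXT_INDEX[tuple(flag_t)], _EXT_INDEX[tuple(myc_t)]
                B[e, mi] += rate
                Delta[e, fi] += rate
                Delta[e, mi] -= rate
            elif r.kind == "disassembly":
                k = r.site - 1
                tgt = list(ext); tgt[k] = 0
                B[e, _EXT_INDEX[tuple(tgt)]] += rate
            else:  # slide preserves the tag
                a, b = r.slide_from - 1, r.slide_to - 1
                tgt = list(ext); tgt[b] = tgt[a]; tgt[a] = 0
                B[e, _EXT_INDEX[tuple(tgt)]] += rate
    np.fill_diagonal(B, -B.sum(axis=1))
    return B, Delta


def build_extended_generator(Q: np.ndarray, p_plus: float) -> np.ndarray:
    """The 27x27 tagged generator at a fixed Flag incorporation probability."""
    if not (0.0 <= p_plus <= 1.0):
        raise ValueError("p_plus must lie in [0, 1]")
    B, Delta = extended_generator_parts(Q)
    return B + p_plus * Delta


def tag_marginal(q: np.ndarray) -> np.ndarray:
    """Project extended-state probabilities onto the 8 configurations."""
    out = np.zeros(8)
    np.add.at(out, _PROJECTION, q)
    return out


def initial_extended_state(p: np.ndarray) -> np.ndarray:
    """Place a configuration distribution on all-Myc tagged extended states."""
    q0 = np.zeros(N_EXT)
    space = build_configuration_space()
    for cfg in space.configurations:
        tags = tuple(2 * o for o in cfg.occupancy)
        q0[_EXT_INDEX[tags]] = p[cfg.index - 1]
    return q0


def solve_extended(Q: np.ndarray, times_h: Sequence[float],
                   time_scale: float = 1.0,
                   pool: PoolParams = PoolParams(),
                   q0: np.ndarray | None = None,
                   rtol: float = 1e-8, atol: float = 1e-10) -> np.ndarray:
    """Integrate the tagged master equation through the time-dependent pool.

    The default initial condition is the steady state of ``Q`` with every
    nucleosome Myc-tagged; since P+ vanishes before the lag time, starting at
    t = 0 is equivalent to starting at the lag time.  ``Q`` should be the
    generator of the promoter state in which the exchange experiment is done
    (the repressed state for the data modelled here).  Returns an array of
    shape ``(len(times_h), 27)``.
    """
    from .dynamics import steady_state

    times = np.asarray(times_h, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be nonnegative and nondecreasing")
    if q0 is None:
        q0 = initial_extended_state(steady_state(Q))
    B, Delta = extended_generator_parts(Q)
    BT, DT = time_scale * B.T, time_scale * Delta.T

    # scalar fast path of flag_probability, evaluated once per rhs call
    myc = pool.alpha_myc / pool.beta_myc
    af_over_bf = pool.alpha_flag / pool.beta_flag
    bF, t0m = pool.beta_flag, pool.lag_time_min

    def rhs(t, q):
        tm = t * _MIN_PER_H
        if tm <= t0m:
            return BT @ q
        flag = af_over_bf * -math.expm1(-bF * (tm - t0m))
        return (BT + (flag / (flag + myc)) * DT) @ q

    sol = solve_ivp(rhs, (0.0, max(float(times[-1]), 1e-12)), q0,
                    t_eval=times, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"tagged master equation integration failed: {sol.message}")
    traj = sol.y.T
    return traj / traj.sum(axis=1, keepdims=True)


def tag_amounts(q: np.ndarray) -> dict[str, np.ndarray]:
    """Flag and Myc amounts per site from extended-state probabilities.

    ``q`` may be a single 27-vector or a trajectory ``(T, 27)``; returns
    arrays of shape ``(..., 3)`` keyed ``"flag"`` and ``"myc"``.
    """
    q = np.asarray(q)
    flags = np.zeros(q.shape[:-1] + (3,))
    mycs = np.zeros_like(flags)
    for i, s in enumerate(EXTENDED_STATES):
        for k in range(3):
            if s[k] == 1:
                flags[..., k] += q[..., i]
            elif s[k] == 2:
                mycs[..., k] += q[..., i]
    return {"flag": flags, "myc": mycs}


def exchange_observables(q: np.ndarray) -> dict[str, np.ndarray]:
    """The g and h log2-ratio observables from tagged probabilities.

    ``g = log2(Flag@N-1 / Flag@N-2)``, ``h = log2(Flag@N-1 / Myc@N-1)``.
    Zero amounts give -inf/inf observables (e.g. no Flag before the lag
    time); callers decide how to handle those times.
    """
    amounts = tag_amounts(q)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.log2(amounts["flag"][..., 0] / amounts["flag"][..., 1])
        h = np.log2(amounts["flag"][..., 0] / amounts["myc"][..., 0])
    return {"g": g, "h": h}
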