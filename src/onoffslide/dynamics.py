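"""Rate matrices, steady states, accessibilities, fluxes and relaxation.

Matrix convention
-----------------
``Q[i, j]`` (0-based internally) is the rate of the reaction taking
configuration ``i+1`` to configuration ``j+1``; rows sum to zero and the
stationary distribution satisfies ``p^T Q = 0``.  This matches the layout in
which the master equation reads ``dp/dt = Q^T p``.  All relative rates are
dimensionless; multiplying by the model's time scale ``s`` (in 1/h) converts
to physical rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse.csgraph import connected_components

from .config_space import (
    N_CONFIGS,
    RateAssignment,
    build_configuration_space,
)

__all__ = [
    "STATES",
    "ParameterVector",
    "PrefactorVector",
    "ReducibleChainError",
    "build_rate_matrix",
    "steady_state",
    "steady_state_dense",
    "site_accessibility",
    "net_fluxes",
    "site_centric_net_fluxes",
    "relaxation_rate",
    "distribution_dynamics",
    "apply_mutant_prefactors",
    "prefactor_energy_bound",
    "translocation_speed",
]

#: promoter states, in the order used for all (3, ...) arrays
STATES = ("repressed", "weakly_activated", "activated")

RateValue = Union[float, Mapping[str, float]]


@dataclass
class ParameterVector:
    """Relative process rates (per promoter state for regulated slots).

    ``rates`` maps a process id either to a single positive float
    (constitutive) or to a mapping ``{state: rate}`` with all three promoter
    states (regulated).  ``time_scale`` converts relative to physical rates
    and carries units of 1/h.
    """

    rates: dict[str, RateValue]
    time_scale: float = 1.0

    def rate(self, process: str, state: str) -> float:
        v = self.rates[process]
        if isinstance(v, Mapping):
            return float(v[state])
        return float(v)

    def validate(self, bounds: tuple[float, float] = (1e-2, 1e2)) -> None:
        lo, hi = bounds
        for pid, v in self.rates.items():
            vals = v.values() if isinstance(v, Mapping) else (v,)
            for x in vals:
                if not (x > 0):
                    raise ValueError(f"rate of process {pid} must be positive, got {x}")
                if not (lo <= x <= hi):
                    raise ValueError(
                        f"rate of process {pid} = {x} outside bounds [{lo}, {hi}]")
        if not (self.time_scale > 0):
            raise ValueError("time_scale must be positive")

    def copy(self) -> "ParameterVector":
        rates = {p: (dict(v) if isinstance(v, Mapping) else v)
                 for p, v in self.rates.items()}
        return ParameterVector(rates, self.time_scale)


@dataclass(frozen=True)
class PrefactorVector:
    """Sticky-mutant rate prefactors for the four N-3 reaction groups.

    ``a3`` multiplies assembly at N-3, ``d3`` disassembly at N-3, ``s23``
    sliding from N-2 to N-3 and ``s32`` sliding from N-3 to N-2.  Each value
    is bounded to [1/5, 5]; the implied maximal change in apparent N-3
    binding energy is ln(25) ~ 3.2 k_B T.
    """

    a3: float = 1.0
    d3: float = 1.0
    s23: float = 1.0
    s32: float = 1.0

    BOUNDS = (0.2, 5.0)

    def __post_init__(self) -> None:
        lo, hi = self.BOUNDS
        for name in ("a3", "d3", "s23", "s32"):
            v = getattr(self, name)
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"prefactor {name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.a3, self.d3, self.s23, self.s32])


class ReducibleChainError(ValueError):
    """The rate matrix does not have a single closed communicating class."""


def build_rate_matrix(assignment: RateAssignment, params: ParameterVector,
                      state: str) -> np.ndarray:
    """Assemble the 8x8 generator for one promoter state (relative units)."""
    if state not in STATES:
        raise ValueError(f"unknown promoter state {state!r}")
    space = build_configuration_space()
    Q = np.zeros((N_CONFIGS, N_CONFIGS))
    for r in space.reactions:
        pid = assignment.governing[r.index]
        if pid is None:
            continue  # slide reaction not covered by any sliding process
        rate = params.rate(pid, state)
        if not (rate > 0):
            raise ValueError(f"rate of process {pid} must be positive, got {rate}")
        Q[r.source - 1, r.target - 1] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_irreducible(Q: np.ndarray) -> None:
    adj = (Q > 0).astype(int)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        # find the closed class(es) and report what is unreachable from them
        unreachable = [i + 1 for i in range(len(Q)) if labels[i] != labels[0]]
        raise ReducibleChainError(
            "rate matrix is reducible; configurations in separate communicating "
            f"classes: {unreachable}")


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution by state reduction (GTH), subtraction-free.

    The Grassmann–Taksar–Heyman algorithm eliminates states one by one using
    only additions, multiplications and divisions of nonnegative numbers and
    is therefore numerically stable even for stiff rate matrices.
    """
    _check_irreducible(Q)
    n = Q.shape[0]
    A = Q.copy()
    np.fill_diagonal(A, 0.0)
    for k in range(n - 1, 0, -1):
        s = A[k, :k].sum()
        if s <= 0:
            raise ReducibleChainError(f"configuration {k + 1} cannot reach lower states")
        A[:k, :k] += np.outer(A[:k, k], A[k, :k]) / s
    p = np.zeros(n)
    p[0] = 1.0
    for k in range(1, n):
        s = A[k, :k].sum()
        p[k] = p[:k] @ A[:k, k] / s
    p /= p.sum()
    return p


def steady_state_dense(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution via a dense nullspace solve (test oracle)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return p / p.sum()


def site_accessibility(p: np.ndarray) -> np.ndarray:
    """Probability that each of (N-1, N-2, N-3) is nucleosome-free."""
    space = build_configuration_space()
    acc = np.zeros(3)
    for cfg in space.configurations:
        for k in range(3):
            if cfg.occupancy[k] == 0:
                acc[k] += p[cfg.index - 1]
    return acc


def net_fluxes(Q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Net probability fluxes ``J_ij = p_i Q_ij - p_j Q_ji`` (antisymmetric)."""
    F = p[:, None] * Q
    np.fill_diagonal(F, 0.0)
    return F - F.T


@dataclass(frozen=True)
class SiteCentricFluxes:
    """Site-centric aggregation of the configuration net fluxes.

    ``assembly_net`` holds, per site, the summed assembly-minus-disassembly
    net flux (positive = net deposition).  ``slide_21`` is the net slide flux
    of nucleosomes from N-2 to N-1, ``slide_32`` from N-3 to N-2.  At steady
    state each site balances: deposition plus net slide influx is zero.
    All values are probability fluxes per promoter (units of the rates used).
    """

    assembly_net: tuple[float, float, float]
    slide_21: float
    slide_32: float

    def as_array(self) -> np.ndarray:
        return np.array([*self.assembly_net, self.slide_21, self.slide_32])

    def site_balance(self) -> np.ndarray:
        a1, a2, a3 = self.assembly_net
        return np.array([
            a1 + self.slide_21,
            a2 - self.slide_21 + self.slide_32,
            a3 - self.slide_32,
        ])


def site_centric_net_fluxes(J: np.ndarray) -> SiteCentricFluxes:
    """Aggregate configuration net fluxes into the five site-centric numbers."""
    space = build_configuration_space()
    assembly = [0.0, 0.0, 0.0]
    slide_21 = 0.0
    slide_32 = 0.0
    for r in space.reactions:
        j = J[r.source - 1, r.target - 1]
        if r.kind == "assembly":
            assembly[r.site - 1] += j
        elif r.kind == "slide":
            if (r.slide_from, r.slide_to) == (2, 1):
                slide_21 += j
            elif (r.slide_from, r.slide_to) == (3, 2):
                slide_32 += j
    return SiteCentricFluxes(tuple(assembly), slide_21, slide_32)


def relaxation_rate(Q: np.ndarray, time_scale: float = 1.0) -> float:
    """Slowest nonzero relaxation rate of the generator, in physical units.

    Returns ``time_scale * |Re(lambda_2)|`` where ``lambda_2`` is the nonzero
    eigenvalue of ``Q`` with real part closest to zero.  Used as the
    effective chromatin opening rate (activated generator) or closing rate
    (repressed generator): after an instantaneous regulation switch the
    configuration distribution decays toward the new steady state with
    approximately this rate.
    """
    ev = np.linalg.eigvals(Q)
    ev = ev[np.argsort(-ev.real)]
    lam2 = ev[1]
    if abs(lam2.real) < 1e-12:
        warnings.warn("second eigenvalue nearly degenerate with zero; "
                      "relaxation rate ill-determined")
    if abs(lam2.imag) > 1e-10 * max(1.0, abs(lam2.real)):
        warnings.warn(f"slowest relaxation mode is complex ({lam2:.3g}); "
                      "reporting the real part")
    return float(time_scale * abs(lam2.real))


def distribution_dynamics(Q: np.ndarray, p0: np.ndarray,
                          times: Sequence[float],
                          time_scale: float = 1.0) -> np.ndarray:
    """Solve ``dp/dt = time_scale * Q^T p`` at the requested times.

    ``times`` must be nonnegative and nondecreasing; the returned array has
    shape ``(len(times), 8)`` with each row renormalized to unit mass.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros((0, len(p0)))
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be nonnegative and nondecreasing")
    QT = time_scale * Q.T
    sol = solve_ivp(lambda t, p: QT @ p, (0.0, max(float(times[-1]), 1e-12)),
                    np.asarray(p0, dtype=float), t_eval=times,
                    method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"distribution dynamics integration failed: {sol.message}")
    traj = sol.y.T
    return traj / traj.sum(axis=1, keepdims=True)


# reactions touched by the sticky N-3 prefactors, as (source, target) pairs
_KAPPA_GROUPS = {
    "a3": ((4, 1), (5, 3), (6, 2), (8, 7)),   # assembly at N-3
    "d3": ((1, 4), (3, 5), (2, 6), (7, 8)),   # disassembly at N-3
    "s23": ((4, 3), (6, 7)),                  # slide N-2 -> N-3
    "s32": ((3, 4), (7, 6)),                  # slide N-3 -> N-2
}


def apply_mutant_prefactors(Q: np.ndarray, kappa: PrefactorVector) -> np.ndarray:
    """Multiply the N-3-involving rates by the sticky-mutant prefactors.

    Only the twelve reactions in which the N-3 nucleosome participates are
    modified; the diagonal is recomputed.  With all prefactors equal to one
    the matrix is returned unchanged (up to a copy).
    """
    W = Q.copy()
    np.fill_diagonal(W, 0.0)
    for name, pairs in _KAPPA_GROUPS.items():
        f = getattr(kappa, name)
        for (i, j) in pairs:
            W[i - 1, j - 1] *= f
    np.fill_diagonal(W, -W.sum(axis=1))
    return W


def prefactor_energy_bound(bounds: tuple[float, float] = PrefactorVector.BOUNDS) -> float:
    """Maximal |ΔΔE| (in k_B T) representable by a pair of reciprocal-rate
    prefactors within ``bounds``.

    For an equilibrium pair of reverting reactions the rate ratio maps to a
    Boltzmann factor, so prefactors in [1/5, 5] on forward and backward rates
    change the apparent binding energy by at most ``ln(5/(1/5)) = ln 25``.
    """
    lo, hi = bounds
    return float(np.log(hi / lo))


def translocation_speed(rate_per_h: float = 5.0, distance_bp: float = 160.0) -> float:
    """Nucleosome translocation speed (bp/s) implied by a sliding rate.

    A sliding rate of ``rate_per_h`` events per hour over ``distance_bp``
    base pairs, assuming unidirectional constant-speed travel and
    instantaneous remodeler binding, corresponds to this many bp/s — a lower
    bound on the remodeler translocation speed.
    """
    return float(rate_per_h * distance_bp / 3600.0)
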