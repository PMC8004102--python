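"""Stage likelihoods for configuration counts, mutant fold-changes and exchange.

All likelihoods are log10.  Following the modelling convention, additive
constants are dropped in the Gaussian stages (II and III), so a perfect fit
of those data contributes exactly zero; the multinomial stage (I) keeps the
multinomial coefficient, and model quality is reported relative to the
perfect-fit value ``L0`` via the ratios

    R1 = L0 - L_I,   R2 = L0 - (L_I + L_II),   R3 = L0 - (L_I + L_II + L_III).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .config_space import RateAssignment
from .dynamics import (
    STATES,
    ParameterVector,
    PrefactorVector,
    ReducibleChainError,
    apply_mutant_prefactors,
    build_rate_matrix,
    site_accessibility,
    steady_state,
)
from .exchange import PoolParams, exchange_observables, solve_extended

__all__ = [
    "LN10",
    "ConfigCounts",
    "FoldChangeObservations",
    "ExchangeObservations",
    "FitResult",
    "log10lik_config",
    "perfect_fit_loglik",
    "log10lik_foldchange",
    "log10lik_exchange",
]

LN10 = np.log(10.0)

#: accessibility-vector indices of the sites probed in the mutant experiments
_FC_SITES = (1, 2)  # N-2, N-3 (0-based positions in the (N-1, N-2, N-3) vector)
FC_SITE_NAMES = ("N-2", "N-3")


@dataclass(frozen=True)
class ConfigCounts:
    """Observed configuration counts, shape (3 states, 8 configurations).

    Row order follows :data:`onoffslide.dynamics.STATES`.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 8):
            raise ValueError(f"counts must have shape (3, 8), got {c.shape}")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be nonnegative integers")
        if np.any(c.sum(axis=1) <= 0):
            raise ValueError("each promoter state needs a positive total count")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        return self.counts / self.totals[:, None]


@dataclass(frozen=True)
class FoldChangeObservations:
    """Accessibility fold-changes (mutant / wild type) with variances.

    Arrays have shape (2 mutants, 2 sites) with site order (N-2, N-3).
    """

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        m, v = np.asarray(self.mean, float), np.asarray(self.var, float)
        if m.shape != (2, 2) or v.shape != (2, 2):
            raise ValueError("mean and var must have shape (2 mutants, 2 sites)")
        if np.any(m <= 0):
            raise ValueError("fold-change means must be positive")
        if np.any(v <= 0):
            raise ValueError("fold-change variances must be positive")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "var", v)

    @classmethod
    def from_sds(cls, mean, sd) -> "FoldChangeObservations":
        sd = np.asarray(sd, float)
        return cls(np.asarray(mean, float), sd ** 2)


@dataclass(frozen=True)
class ExchangeObservations:
    """Histone-exchange summary data.

    ``g_replicates`` are replicate log2 Flag(N-1)/Flag(N-2) values measured
    at ``g_time_h``; ``h_mean`` are normalized log2 Flag/Myc values at N-1
    at times ``h_times_h`` with an independent per-point standard deviation
    ``h_sd`` *before* mean-centering.  The centered series has the singular
    covariance ``C = h_sd^2 (I - J/4)``; its Moore–Penrose inverse enters
    the degenerate-Gaussian likelihood.
    """

    g_replicates: np.ndarray
    g_time_h: float
    h_mean: np.ndarray
    h_times_h: np.ndarray
    h_sd: float = 0.4
    g_var_override: Optional[float] = None  # replaces the replicate variance if set

    def __post_init__(self) -> None:
        g = np.asarray(self.g_replicates, float)
        h = np.asarray(self.h_mean, float)
        t = np.asarray(self.h_times_h, float)
        if g.size < 2:
            raise ValueError("need at least two g replicates to estimate a variance")
        if h.shape != t.shape:
            raise ValueError("h_mean and h_times_h must have matching shapes")
        if np.any(np.diff(t) <= 0):
            raise ValueError("h measurement times must be strictly increasing")
        if not (self.h_sd > 0) or not (self.g_time_h > 0):
            raise ValueError("h_sd and g_time_h must be positive")
        object.__setattr__(self, "g_replicates", g)
        object.__setattr__(self, "h_mean", h)
        object.__setattr__(self, "h_times_h", t)

    @property
    def g_mean(self) -> float:
        return float(np.mean(self.g_replicates))

    @property
    def g_var(self) -> float:
        if self.g_var_override is not None:
            return float(self.g_var_override)
        v = float(np.var(self.g_replicates, ddof=1))
        if v <= 0:
            raise ValueError("g replicates are identical; supply g_var_override")
        return v

    @property
    def h_tilde(self) -> np.ndarray:
        """Mean-centered measured h values."""
        return self.h_mean - self.h_mean.mean()

    @property
    def covariance(self) -> np.ndarray:
        n = self.h_mean.size
        T = np.eye(n) - np.ones((n, n)) / n
        return self.h_sd ** 2 * T  # T is symmetric idempotent: C = sd^2 T T^T

    @property
    def covariance_pinv(self) -> np.ndarray:
        return np.linalg.pinv(self.covariance, rcond=1e-10)


def _steady_states(assignment: RateAssignment, params: ParameterVector) -> np.ndarray:
    p = np.empty((3, 8))
    for k, state in enumerate(STATES):
        p[k] = steady_state(build_rate_matrix(assignment, params, state))
    return p


def log10lik_config(assignment: RateAssignment, params: ParameterVector,
                    counts: ConfigCounts) -> float:
    """Multinomial log10 likelihood L_I of the configuration counts.

    Sums over the three promoter states the multinomial log-probability of
    the observed counts under the model steady states (multinomial
    coefficient included).  Returns -inf if the model assigns probability
    zero to an observed configuration, or if a state's chain is reducible.
    """
    try:
        p = _steady_states(assignment, params)
    except ReducibleChainError:
        return -np.inf
    return _multinomial_log10(counts.counts, p)


def _multinomial_log10(counts: np.ndarray, p: np.ndarray) -> float:
    total = 0.0
    for n_row, p_row in zip(counts, p):
        if np.any((p_row <= 0) & (n_row > 0)):
            return -np.inf
        n = n_row.sum()
        coeff = gammaln(n + 1) - gammaln(n_row + 1).sum()
        obs = n_row > 0
        total += coeff + (n_row[obs] * np.log(p_row[obs])).sum()
    return float(total / LN10)


def perfect_fit_loglik(counts: ConfigCounts) -> float:
    """L0: the multinomial likelihood at the empirical frequencies."""
    return _multinomial_log10(counts.counts, counts.frequencies())


def log10lik_foldchange(assignment: RateAssignment, params: ParameterVector,
                        kappas: Sequence[PrefactorVector],
                        obs: FoldChangeObservations) -> float:
    """Gaussian log10 likelihood L_II of the sticky-mutant fold-changes.

    The model fold-change at site s is the activated-state accessibility of
    the prefactor-modified matrix over the wild-type one.  Constants are
    dropped, so the maximum attainable value is zero.  ``kappas`` holds one
    prefactor vector per mutant.
    """
    if len(kappas) != obs.mean.shape[0]:
        raise ValueError("need one prefactor vector per mutant")
    try:
        Q_act = build_rate_matrix(assignment, params, "activated")
        acc_wt = site_accessibility(steady_state(Q_act))
    except ReducibleChainError:
        return -np.inf
    if np.any(acc_wt[list(_FC_SITES)] <= 0):
        return -np.inf
    chi2 = 0.0
    for m, kappa in enumerate(kappas):
        try:
            acc_mut = site_accessibility(steady_state(apply_mutant_prefactors(Q_act, kappa)))
        except ReducibleChainError:
            return -np.inf
        for s, site in enumerate(_FC_SITES):
            f = acc_mut[site] / acc_wt[site]
            chi2 += (f - obs.mean[m, s]) ** 2 / obs.var[m, s]
    return float(-chi2 / (2.0 * LN10))


def model_foldchanges(assignment: RateAssignment, params: ParameterVector,
                      kappas: Sequence[PrefactorVector]) -> np.ndarray:
    """Model fold-changes, shape (n mutants, 2 sites), site order (N-2, N-3)."""
    Q_act = build_rate_matrix(assignment, params, "activated")
    acc_wt = site_accessibility(steady_state(Q_act))
    out = np.empty((len(kappas), 2))
    for m, kappa in enumerate(kappas):
        acc_mut = site_accessibility(steady_state(apply_mutant_prefactors(Q_act, kappa)))
        for s, site in enumerate(_FC_SITES):
            out[m, s] = acc_mut[site] / acc_wt[site]
    return out


def log10lik_exchange(assignment: RateAssignment, params: ParameterVector,
                      obs: ExchangeObservations,
                      pool: PoolParams = PoolParams(),
                      lag_shift: bool = False) -> float:
    """L_III: exchange likelihood, sum of the g term and the centered-h term.

    The tagged master equation is solved in the repressed state (where the
    exchange experiments were performed) with the model's time scale.  With
    ``lag_shift`` false (default) model observables are evaluated at the
    nominal measurement times, the lag entering only through the pool's P+;
    with true, times are shifted by the pool lag.
    """
    shift = pool.lag_time_h if lag_shift else 0.0
    times = np.concatenate([[obs.g_time_h + shift], obs.h_times_h + shift])
    unique_times, inverse = np.unique(times, return_inverse=True)
    try:
        traj = solve_extended(build_rate_matrix(assignment, params, "repressed"),
                              unique_times, time_scale=params.time_scale, pool=pool)
    except (RuntimeError, ReducibleChainError):
        return -np.inf
    traj = traj[inverse]
    o = exchange_observables(traj)
    g_model = o["g"][0]
    h_model = o["h"][1:]
    if not np.isfinite(g_model) or not np.all(np.isfinite(h_model)):
        return -np.inf
    l1 = -(g_model - obs.g_mean) ** 2 / (2.0 * obs.g_var)
    resid = (h_model - h_model.mean()) - obs.h_tilde
    l2 = -0.5 * resid @ obs.covariance_pinv @ resid
    return float((l1 + l2) / LN10)


@dataclass
class FitResult:
    """Outcome of a staged maximum-likelihood fit of one model."""

    model: object                       # ModelSpec
    stage: int                          # 1, 2 or 3
    params: ParameterVector
    kappas: Optional[tuple[PrefactorVector, PrefactorVector]] = None
    log10_L0: float = np.nan
    log10_LI: float = np.nan
    log10_LII: float = 0.0
    log10_LIII: float = 0.0
    n_starts: int = 0
    start_spread: float = np.nan        # best-to-worst spread of converged optima
    multiple_optima: bool = False       # distinct maximal likelihood values found
    non_unique_params: bool = False     # same optimum reached at distant parameters
    success: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def R1(self) -> float:
        return self.log10_L0 - self.log10_LI

    @property
    def R2(self) -> float:
        return self.log10_L0 - (self.log10_LI + self.log10_LII)

    @property
    def R3(self) -> float:
        return self.log10_L0 - (self.log10_LI + self.log10_LII + self.log10_LIII)

    @property
    def R(self) -> float:
        """The ratio for this result's stage."""
        return (self.R1, self.R2, self.R3)[self.stage - 1]

    @property
    def time_scale(self) -> float:
        return self.params.time_scale
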