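"""Synthetic data generation from a known ground-truth model.

Every dataset type the staged pipeline consumes can be generated from a
fully specified model, so the whole selection machinery is testable without
any external measurements: multinomial configuration counts per promoter
state, Gaussian-noised accessibility fold-changes for two sticky-N-3
mutants, and Gaussian-noised exchange log-ratios at given times.

The default ground truth (:func:`make_reference_fixture`) uses the model
structure {A regulated; D, D1-4, S2*, S3-4 constitutive} — global assembly
regulated with decreasing rate from repressed to activated, disassembly
from the fully occupied promoter boosted, sliding away from N-2 and from
configuration 3 to 4 enabled — with plausible synthetic rate values, NOT
fitted values from any experiment.  Default per-state sample sizes are in
the hundred-molecule range typical of single-molecule electron-microscopy
configuration counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config_space import ModelSpec, resolve_governance
from .dynamics import (
    STATES,
    ParameterVector,
    PrefactorVector,
    build_rate_matrix,
    steady_state,
)
from .exchange import PoolParams, exchange_observables, solve_extended
from .likelihoods import (
    ConfigCounts,
    ExchangeObservations,
    FoldChangeObservations,
    model_foldchanges,
)

__all__ = [
    "GroundTruth",
    "make_reference_fixture",
    "sample_config_counts",
    "sample_foldchanges",
    "sample_exchange",
]


@dataclass
class GroundTruth:
    """A fully specified generating model plus sampling settings."""

    model: ModelSpec
    params: ParameterVector                      # includes the time scale (1/h)
    kappas: tuple[PrefactorVector, PrefactorVector]
    n_per_state: dict[str, int] = field(
        default_factory=lambda: {s: 150 for s in STATES})
    foldchange_sd: np.ndarray = field(
        default_factory=lambda: np.full((2, 2), 0.08))
    g_time_h: float = 2.0
    n_g_replicates: int = 2
    exchange_times_h: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    exchange_sd: float = 0.4
    pool: PoolParams = PoolParams()
    seed: int = 0

    def __post_init__(self) -> None:
        self.params.validate()
        self.foldchange_sd = np.asarray(self.foldchange_sd, float)
        if self.foldchange_sd.shape != (2, 2) or np.any(self.foldchange_sd <= 0):
            raise ValueError("foldchange_sd must be positive with shape (2, 2)")
        for s in STATES:
            if self.n_per_state.get(s, 0) <= 0:
                raise ValueError(f"sample size for state {s} must be positive")

    def rng(self, seed: Optional[int] = None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)


def make_reference_fixture(seed: int = 0) -> GroundTruth:
    """Ground truth with the best-supported model structure and synthetic rates.

    The regulated global assembly rate decreases from repressed over weakly
    activated to activated, producing a mostly occupied promoter under
    repression and a largely open one upon activation.  The sticky-mutant
    prefactors follow the qualitative pattern expected for a
    nucleosome-stabilizing N-3 sequence: assembly at N-3 and sliding from
    N-3 to N-2 up, disassembly at N-3 and sliding from N-2 to N-3 down.
    """
    model = ModelSpec.make(("A", "D", "D1-4", "S2*", "S3-4"), ("A",))
    params = ParameterVector(
        rates={
            "A": {"repressed": 25.0, "weakly_activated": 4.0, "activated": 1.0},
            "D": 0.4,
            "D1-4": 2.0,
            "S2*": 1.5,
            "S3-4": 2.5,
        },
        time_scale=0.6,
    )
    kappas = (
        PrefactorVector(a3=2.0, d3=0.45, s23=0.5, s32=2.2),
        PrefactorVector(a3=1.6, d3=0.6, s23=0.65, s32=1.8),
    )
    return GroundTruth(model=model, params=params, kappas=kappas, seed=seed)


def sample_config_counts(gt: GroundTruth,
                         rng: Optional[np.random.Generator] = None) -> ConfigCounts:
    """Multinomial configuration counts from the ground-truth steady states."""
    rng = gt.rng() if rng is None else rng
    assignment = resolve_governance(gt.model)
    counts = np.zeros((3, 8), dtype=int)
    for k, state in enumerate(STATES):
        p = steady_state(build_rate_matrix(assignment, gt.params, state))
        counts[k] = rng.multinomial(gt.n_per_state[state], p)
    return ConfigCounts(counts)


def sample_foldchanges(gt: GroundTruth,
                       rng: Optional[np.random.Generator] = None,
                       noise: bool = True) -> FoldChangeObservations:
    """Noisy accessibility fold-changes for the two sticky-N-3 mutants.

    Noise is Gaussian on the fold-change scale (matching the Gaussian
    likelihood used in stage 2), truncated at zero by resampling.
    """
    rng = gt.rng() if rng is None else rng
    assignment = resolve_governance(gt.model)
    f_true = model_foldchanges(assignment, gt.params, gt.kappas)
    f_obs = f_true.copy()
    if noise:
        for idx in np.ndindex(f_true.shape):
            draw = rng.normal(f_true[idx], gt.foldchange_sd[idx])
            while draw <= 0:
                draw = rng.normal(f_true[idx], gt.foldchange_sd[idx])
            f_obs[idx] = draw
    return FoldChangeObservations(f_obs, gt.foldchange_sd ** 2)


def sample_exchange(gt: GroundTruth,
                    rng: Optional[np.random.Generator] = None,
                    noise: bool = True) -> ExchangeObservations:
    """Noisy g replicates and h time series from the tagged dynamics.

    The repressed-state tagged master equation is solved at the ground
    truth's time scale; Gaussian noise with ``gt.exchange_sd`` is added to
    the g replicates and to the h values (before centering, like the real
    normalization pipeline).
    """
    rng = gt.rng() if rng is None else rng
    assignment = resolve_governance(gt.model)
    Q_rep = build_rate_matrix(assignment, gt.params, "repressed")
    times = np.unique(np.concatenate([[gt.g_time_h], gt.exchange_times_h]))
    traj = solve_extended(Q_rep, times, time_scale=gt.params.time_scale,
                          pool=gt.pool)
    obs = exchange_observables(traj)
    g_true = float(obs["g"][np.searchsorted(times, gt.g_time_h)])
    h_true = np.array([obs["h"][np.searchsorted(times, t)]
                       for t in gt.exchange_times_h])
    sd = gt.exchange_sd if noise else 0.0
    g_reps = g_true + sd * rng.standard_normal(gt.n_g_replicates)
    h_obs = h_true + sd * rng.standard_normal(len(h_true))
    return ExchangeObservations(
        g_replicates=g_reps, g_time_h=gt.g_time_h,
        h_mean=h_obs, h_times_h=np.asarray(gt.exchange_times_h, float),
        h_sd=gt.exchange_sd,
        g_var_override=None if noise else gt.exchange_sd ** 2,
    )
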