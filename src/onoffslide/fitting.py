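"""Multi-start maximum-likelihood fitting and the staged selection pipeline.

Fits are performed in log10 parameter space with box bounds using L-BFGS-B
from multiple random starting points.  The global assembly rate of the
activated state is the normalization slot fixed to one (it represents the
overall time-scale degree of freedom, which only the dynamic exchange data
of stage 3 can determine).  Stage 1 fits the configuration counts, stage 2
adds the sticky-mutant fold-changes together with the per-mutant rate
prefactors, and stage 3 adds the histone-exchange data and the physical
time scale.  Models whose likelihood ratio R exceeds the threshold
``rmax`` after a stage are discarded; each stage re-fits the data of all
previous stages, so the staging order does not affect the surviving set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config_space import (
    ModelSpec,
    RateAssignment,
    RedundantModelError,
    resolve_governance,
)
from .dynamics import (
    STATES,
    ParameterVector,
    PrefactorVector,
    build_rate_matrix,
    relaxation_rate,
)
from .exchange import PoolParams
from .likelihoods import (
    ConfigCounts,
    ExchangeObservations,
    FitResult,
    FoldChangeObservations,
    log10lik_config,
    log10lik_exchange,
    log10lik_foldchange,
    perfect_fit_loglik,
)

__all__ = [
    "FitConfig",
    "PipelineResult",
    "fit_stage1",
    "fit_stage2",
    "fit_stage3",
    "run_staged_pipeline",
    "sensitivity_analysis",
    "opening_closing_report",
]

logger = logging.getLogger("onoffslide")

_BIG = 1e10  # objective value standing in for -inf likelihoods


@dataclass(frozen=True)
class FitConfig:
    """Settings shared by all fitting stages."""

    n_starts: int = 100
    rate_bounds: tuple[float, float] = (1e-2, 1e2)
    kappa_bounds: tuple[float, float] = (0.2, 5.0)
    time_scale_bounds: tuple[float, float] = (1e-3, 1e3)  # 1/h
    rmax: float = 6.0
    seed: int = 0
    ftol: float = 1e-9
    maxiter: int = 500
    pool: PoolParams = PoolParams()
    lag_shift: bool = False

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        for b in (self.rate_bounds, self.kappa_bounds, self.time_scale_bounds):
            if not (0 < b[0] < b[1]):
                raise ValueError(f"bounds must be positive and increasing, got {b}")


# --------------------------------------------------------------------------
# parameter packing

@dataclass(frozen=True)
class _Layout:
    """Mapping between the flat log10 optimization vector and model parameters."""

    model: ModelSpec
    rate_slots: tuple[tuple[str, Optional[str]], ...]  # free (process, state|None)
    fixed_slot: tuple[str, Optional[str]]
    n_kappas: int = 0
    fit_time_scale: bool = False

    @property
    def n_params(self) -> int:
        return len(self.rate_slots) + 4 * self.n_kappas + int(self.fit_time_scale)

    def unpack(self, x: np.ndarray, time_scale: float = 1.0):
        rates: dict = {}
        for pid in self.model.processes:
            if pid in self.model.regulated:
                rates[pid] = {}
            else:
                rates[pid] = 1.0
        fp, fs = self.fixed_slot
        if fs is None:
            rates[fp] = 1.0
        else:
            rates[fp][fs] = 1.0
        for (pid, state), v in zip(self.rate_slots, x):
            val = 10.0 ** v
            if state is None:
                rates[pid] = val
            else:
                rates[pid][state] = val
        i = len(self.rate_slots)
        kappas = tuple(
            PrefactorVector(*(10.0 ** x[i + 4 * m: i + 4 * (m + 1)]))
            for m in range(self.n_kappas)
        )
        i += 4 * self.n_kappas
        ts = 10.0 ** x[i] if self.fit_time_scale else time_scale
        return ParameterVector(rates, ts), kappas

    def bounds(self, cfg: FitConfig) -> list[tuple[float, float]]:
        rb = tuple(np.log10(cfg.rate_bounds))
        kb = tuple(np.log10(cfg.kappa_bounds))
        tb = tuple(np.log10(cfg.time_scale_bounds))
        out = [rb] * len(self.rate_slots) + [kb] * (4 * self.n_kappas)
        if self.fit_time_scale:
            out.append(tb)
        return out


def _make_layout(model: ModelSpec, n_kappas: int = 0,
                 fit_time_scale: bool = False) -> _Layout:
    fixed = ("A", "activated") if "A" in model.regulated else ("A", None)
    slots: list[tuple[str, Optional[str]]] = []
    for pid in model.processes:
        if pid in model.regulated:
            for state in STATES:
                if (pid, state) != fixed:
                    slots.append((pid, state))
        elif (pid, None) != fixed:
            slots.append((pid, None))
    return _Layout(model, tuple(slots), fixed, n_kappas, fit_time_scale)


# --------------------------------------------------------------------------
# multi-start driver

def _multistart(objective: Callable[[np.ndarray], float], layout: _Layout,
                cfg: FitConfig, rng: np.random.Generator,
                warm_starts: Sequence[np.ndarray] = ()) -> dict:
    bounds = layout.bounds(cfg)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    n_rate = len(layout.rate_slots)
    starts: list[np.ndarray] = [np.asarray(w, float) for w in warm_starts]
    if not starts:
        starts.append(np.zeros(layout.n_params))
    while len(starts) < cfg.n_starts:
        x0 = np.zeros(layout.n_params)
        x0[:n_rate] = rng.uniform(lo[:n_rate], hi[:n_rate])
        if layout.fit_time_scale:
            x0[-1] = rng.uniform(-1.0, 1.0)  # moderate initial time scales
        # kappa entries start at 1 (log10 = 0) at every start
        starts.append(x0)
    results = []
    for x0 in starts[: cfg.n_starts]:
        res = minimize(objective, np.clip(x0, lo, hi), method="L-BFGS-B",
                       bounds=bounds,
                       options={"ftol": cfg.ftol, "maxiter": cfg.maxiter})
        if np.isfinite(res.fun) and res.fun < _BIG / 2:
            results.append((float(res.fun), res.x))
    if not results:
        return {"success": False, "n_starts": len(starts[: cfg.n_starts])}
    results.sort(key=lambda t: t[0])
    best_f, best_x = results[0]
    values = np.array([f for f, _ in results])
    clusters = np.unique(np.round(values, 2))
    near = [x for f, x in results if f - best_f < 1e-3]
    non_unique = False
    if len(near) > 1:
        spreads = [np.max(np.abs(x - best_x)) for x in near]
        non_unique = max(spreads) > 0.1
    return {
        "success": True,
        "fun": best_f,
        "x": best_x,
        "n_starts": len(starts[: cfg.n_starts]),
        "start_spread": float(values[-1] - values[0]),
        "multiple_optima": len(clusters) > 1,
        "non_unique_params": non_unique,
    }


def _result_from(model: ModelSpec, assignment: RateAssignment, stage: int,
                 layout: _Layout, opt: dict, counts: ConfigCounts,
                 foldchanges: Optional[FoldChangeObservations],
                 exchange: Optional[ExchangeObservations],
                 cfg: FitConfig) -> FitResult:
    L0 = perfect_fit_loglik(counts)
    if not opt.get("success"):
        return FitResult(model=model, stage=stage,
                         params=ParameterVector({p: 1.0 for p in model.processes}),
                         log10_L0=L0, log10_LI=-np.inf, success=False,
                         n_starts=opt.get("n_starts", 0))
    params, kappas = layout.unpack(opt["x"])
    LI = log10lik_config(assignment, params, counts)
    LII = (log10lik_foldchange(assignment, params, kappas, foldchanges)
           if foldchanges is not None and kappas else 0.0)
    LIII = (log10lik_exchange(assignment, params, exchange, pool=cfg.pool,
                              lag_shift=cfg.lag_shift)
            if exchange is not None else 0.0)
    return FitResult(
        model=model, stage=stage, params=params,
        kappas=kappas if kappas else None,
        log10_L0=L0, log10_LI=LI, log10_LII=LII, log10_LIII=LIII,
        n_starts=opt["n_starts"], start_spread=opt["start_spread"],
        multiple_optima=opt["multiple_optima"],
        non_unique_params=opt["non_unique_params"],
        diagnostics={"x_best": opt["x"], "objective": opt["fun"]},
    )


def fit_stage1(model: ModelSpec, counts: ConfigCounts,
               cfg: FitConfig = FitConfig()) -> FitResult:
    """Maximize the configuration likelihood L_I over the relative rates."""
    assignment = resolve_governance(model)
    layout = _make_layout(model)
    rng = np.random.default_rng(cfg.seed)

    def objective(x: np.ndarray) -> float:
        params, _ = layout.unpack(x)
        v = log10lik_config(assignment, params, counts)
        return _BIG if not np.isfinite(v) else -v

    opt = _multistart(objective, layout, cfg, rng)
    return _result_from(model, assignment, 1, layout, opt, counts, None, None, cfg)


def fit_stage2(model: ModelSpec, counts: ConfigCounts,
               foldchanges: FoldChangeObservations,
               cfg: FitConfig = FitConfig(),
               warm: Optional[FitResult] = None) -> FitResult:
    """Jointly maximize L_I + L_II over rates and both mutants' prefactors."""
    assignment = resolve_governance(model)
    layout = _make_layout(model, n_kappas=2)
    rng = np.random.default_rng(cfg.seed + 1)

    def objective(x: np.ndarray) -> float:
        params, kappas = layout.unpack(x)
        v = log10lik_config(assignment, params, counts)
        if np.isfinite(v):
            v += log10lik_foldchange(assignment, params, kappas, foldchanges)
        return _BIG if not np.isfinite(v) else -v

    warm_starts = []
    if warm is not None and warm.success:
        x0 = np.zeros(layout.n_params)
        x0[: len(warm.diagnostics["x_best"])] = warm.diagnostics["x_best"]
        warm_starts.append(x0)
    opt = _multistart(objective, layout, cfg, rng, warm_starts)
    return _result_from(model, assignment, 2, layout, opt, counts, foldchanges,
                        None, cfg)


def fit_stage3(model: ModelSpec, counts: ConfigCounts,
               foldchanges: FoldChangeObservations,
               exchange: ExchangeObservations,
               cfg: FitConfig = FitConfig(),
               warm: Optional[FitResult] = None) -> FitResult:
    """Jointly maximize L_I + L_II + L_III including the physical time scale."""
    assignment = resolve_governance(model)
    layout = _make_layout(model, n_kappas=2, fit_time_scale=True)
    rng = np.random.default_rng(cfg.seed + 2)

    def objective(x: np.ndarray) -> float:
        params, kappas = layout.unpack(x)
        v = log10lik_config(assignment, params, counts)
        if np.isfinite(v):
            v += log10lik_foldchange(assignment, params, kappas, foldchanges)
        if np.isfinite(v):
            v += log10lik_exchange(assignment, params, exchange, pool=cfg.pool,
                                   lag_shift=cfg.lag_shift)
        return _BIG if not np.isfinite(v) else -v

    warm_starts = []
    if warm is not None and warm.success:
        xw = warm.diagnostics["x_best"]
        for ts0 in (-0.5, 0.0, 0.5):
            x0 = np.zeros(layout.n_params)
            x0[: len(xw)] = xw
            x0[-1] = ts0
            warm_starts.append(x0)
    opt = _multistart(objective, layout, cfg, rng, warm_starts)
    return _result_from(model, assignment, 3, layout, opt, counts, foldchanges,
                        exchange, cfg)


# --------------------------------------------------------------------------
# staged pipeline

@dataclass
class PipelineResult:
    """Catalog-level outcome of the staged selection."""

    records: pd.DataFrame                    # one row per model entering stage 1
    survivors: dict[int, list[ModelSpec]]    # stage -> surviving models
    fits: dict[int, dict[int, FitResult]]    # stage -> model index -> fit
    rmax: float = 6.0

    def survivor_counts(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.survivors.items()}


def run_staged_pipeline(models: Sequence[ModelSpec], counts: ConfigCounts,
                        foldchanges: Optional[FoldChangeObservations] = None,
                        exchange: Optional[ExchangeObservations] = None,
                        cfg: FitConfig = FitConfig()) -> PipelineResult:
    """Fit a model catalog stage by stage, filtering at R < rmax each time.

    Stages 2 and 3 run only if their data are supplied.  Each stage re-fits
    the previous stages' data jointly (warm-started from the previous best
    point plus fresh random starts).
    """
    rows = []
    fits: dict[int, dict[int, FitResult]] = {1: {}, 2: {}, 3: {}}
    survivors: dict[int, list[ModelSpec]] = {1: [], 2: [], 3: []}
    stage1: dict[int, FitResult] = {}
    for i, model in enumerate(models):
        try:
            fit = fit_stage1(model, counts, cfg)
        except RedundantModelError:
            continue
        stage1[i] = fit
        fits[1][i] = fit
        if fit.success and fit.R1 < cfg.rmax:
            survivors[1].append(model)
        logger.info("stage 1 model %d/%d %s R1=%.3f", i + 1, len(models),
                    model.label(), fit.R1)
    if foldchanges is not None:
        for i, model in enumerate(models):
            if model not in survivors[1]:
                continue
            fit = fit_stage2(model, counts, foldchanges, cfg, warm=stage1[i])
            fits[2][i] = fit
            if fit.success and fit.R2 < cfg.rmax:
                survivors[2].append(model)
            logger.info("stage 2 model %d %s R2=%.3f", i, model.label(), fit.R2)
    if exchange is not None and foldchanges is not None:
        for i, model in enumerate(models):
            if model not in survivors[2]:
                continue
            fit = fit_stage3(model, counts, foldchanges, exchange, cfg,
                             warm=fits[2][i])
            fits[3][i] = fit
            if fit.success and fit.R3 < cfg.rmax:
                survivors[3].append(model)
            logger.info("stage 3 model %d %s R3=%.3f", i, model.label(), fit.R3)
    for i, model in enumerate(models):
        if i not in fits[1]:
            continue
        row = {
            "model_index": i,
            "processes": ",".join(model.processes),
            "regulated": ",".join(sorted(model.regulated)),
            "param_count": model.param_count,
            "R1": fits[1][i].R1 if i in fits[1] else np.nan,
            "R2": fits[2][i].R2 if i in fits[2] else np.nan,
            "R3": fits[3][i].R3 if i in fits[3] else np.nan,
            "survived_stage1": model in survivors[1],
            "survived_stage2": model in survivors[2],
            "survived_stage3": model in survivors[3],
        }
        if i in fits[3]:
            row["time_scale"] = fits[3][i].time_scale
        rows.append(row)
    return PipelineResult(pd.DataFrame(rows), survivors, fits, cfg.rmax)


# --------------------------------------------------------------------------
# sensitivity analysis

def _numerical_gradient(f, x, h=1e-4):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x); e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _numerical_hessian(f, x, h=5e-3):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


def sensitivity_analysis(objective: Callable[[np.ndarray], float],
                         x_best: np.ndarray,
                         param_names: Sequence[str],
                         drop: float = 0.30,
                         scan_limit: float = 3.0,
                         step0: float = 0.01,
                         growth: float = 1.6) -> pd.DataFrame:
    """Error bars from likelihood scans around a fitted optimum.

    ``objective`` is the *negative* log10 likelihood over log10 parameters;
    the scan walks along each parameter axis, each eigenvector of the
    numerical Hessian and the numerical gradient direction (relevant when
    the optimum sits on a bound), in exponentially growing steps and without
    enforcing bounds, until the likelihood has dropped by ``drop`` (0.30
    log10 units is about a factor of two).  The error bar of a parameter is
    the largest log10 deviation observed at the drop level over all tested
    directions.  Directions that never reach the drop within ``scan_limit``
    mark the involved parameters as sloppy.

    Returns a DataFrame indexed by parameter with columns ``err_minus``,
    ``err_plus`` (log10 units) and ``sloppy``.
    """
    x_best = np.asarray(x_best, float)
    n = len(x_best)
    f0 = objective(x_best)
    directions: list[np.ndarray] = [np.eye(n)[i] for i in range(n)]
    H = _numerical_hessian(objective, x_best)
    _, vecs = np.linalg.eigh(H)
    directions += [vecs[:, i] for i in range(n)]
    grad = _numerical_gradient(objective, x_best)
    if np.linalg.norm(grad) > 1e-8:
        directions.append(grad / np.linalg.norm(grad))
    err_plus = np.zeros(n)
    err_minus = np.zeros(n)
    sloppy = np.zeros(n, dtype=bool)
    for d in directions:
        d = d / np.linalg.norm(d)
        for sign in (+1.0, -1.0):
            t_prev, f_prev = 0.0, f0
            t = step0
            crossed = False
            while t <= scan_limit:
                f_t = objective(x_best + sign * t * d)
                if f_t - f0 >= drop:
                    # linear interpolation between the last two scan points
                    frac = (drop - (f_prev - f0)) / max(f_t - f_prev, 1e-300)
                    t_star = t_prev + frac * (t - t_prev)
                    dev = sign * t_star * d
                    err_plus = np.maximum(err_plus, np.maximum(dev, 0.0))
                    err_minus = np.maximum(err_minus, np.maximum(-dev, 0.0))
                    crossed = True
                    break
                t_prev, f_prev = t, f_t
                t *= growth
            if not crossed:
                big = np.abs(d) >= 0.5 * np.abs(d).max()
                sloppy |= big
                dev = sign * scan_limit * d
                err_plus = np.maximum(err_plus, np.maximum(dev, 0.0))
                err_minus = np.maximum(err_minus, np.maximum(-dev, 0.0))
    return pd.DataFrame({"err_minus": err_minus, "err_plus": err_plus,
                         "sloppy": sloppy},
                        index=pd.Index(param_names, name="parameter"))


def opening_closing_report(assignment: RateAssignment,
                           params: ParameterVector) -> dict[str, float]:
    """Effective chromatin opening and closing rates and their ratio.

    The opening (closing) rate is the slowest nonzero relaxation rate of the
    activated (repressed) generator times the fitted time scale — an upper
    bound on how fast the promoter can switch after an instantaneous
    regulation change.  The ratio is time-scale independent.
    """
    opening = relaxation_rate(build_rate_matrix(assignment, params, "activated"),
                              params.time_scale)
    closing = relaxation_rate(build_rate_matrix(assignment, params, "repressed"),
                              params.time_scale)
    return {"opening_rate": opening, "closing_rate": closing,
            "ratio_closing_over_opening": closing / opening}
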