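"""Readers and writers for the dataset TSV formats, run config and reports.

All files are UTF-8 TSV with '.' decimal separator.  Configuration indices
are 1-based in every user-facing file, matching the configuration numbering
used throughout.

Formats
-------
configuration counts
    columns ``state`` (repressed | weakly_activated | activated),
    ``config_index`` (1..8), ``count``.  Missing (state, config) pairs are
    treated as zero counts with a warning.
fold-changes
    columns ``mutant`` (1 | 2), ``site`` (N-2 | N-3), ``mean``, ``sd``.
exchange observations
    columns ``record`` (g_replicate | h_point), ``value``, ``time_h``,
    ``sd`` (used for h points; g variance comes from the replicates).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import STATES
from .likelihoods import (
    ConfigCounts,
    ExchangeObservations,
    FoldChangeObservations,
)

__all__ = [
    "SchemaError",
    "load_config_counts",
    "write_config_counts",
    "load_foldchanges",
    "write_foldchanges",
    "load_exchange",
    "write_exchange",
    "packaged_foldchanges",
    "packaged_exchange",
    "packaged_counts_synthetic",
    "packaged_data_path",
    "RunConfig",
    "load_run_config",
    "write_reports",
]

logger = logging.getLogger("onoffslide")

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A data file does not conform to its documented schema."""


def _read_tsv(path: PathLike, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_config_counts(path: PathLike) -> ConfigCounts:
    """Read a configuration-count TSV into a validated :class:`ConfigCounts`."""
    df = _read_tsv(path, {"state", "config_index", "count"})
    counts = np.zeros((3, 8), dtype=int)
    seen = set()
    state_row = {s: k for k, s in enumerate(STATES)}
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if row.state not in state_row:
            raise SchemaError(f"{path}:{line}: unknown state {row.state!r}")
        ci = int(row.config_index)
        if not 1 <= ci <= 8:
            raise SchemaError(f"{path}:{line}: config_index {ci} outside 1..8")
        c = float(row.count)
        if c < 0 or c != int(c):
            raise SchemaError(f"{path}:{line}: count must be a nonnegative integer")
        key = (row.state, ci)
        if key in seen:
            raise SchemaError(f"{path}:{line}: duplicate entry for {key}")
        seen.add(key)
        counts[state_row[row.state], ci - 1] = int(c)
    if len(seen) < 24:
        missing = [(s, i) for s in STATES for i in range(1, 9) if (s, i) not in seen]
        warnings.warn(f"{path}: {len(missing)} missing (state, config) pairs "
                      "treated as zero counts")
    return ConfigCounts(counts)


def write_config_counts(counts: ConfigCounts, path: PathLike) -> None:
    rows = [
        {"state": s, "config_index": i + 1, "count": int(counts.counts[k, i])}
        for k, s in enumerate(STATES) for i in range(8)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_SITES = ("N-2", "N-3")


def load_foldchanges(path: PathLike) -> FoldChangeObservations:
    df = _read_tsv(path, {"mutant", "site", "mean", "sd"})
    mean = np.full((2, 2), np.nan)
    sd = np.full((2, 2), np.nan)
    for line, row in enumerate(df.itertuples(index=False), start=2):
        m = int(row.mutant)
        if m not in (1, 2):
            raise SchemaError(f"{path}:{line}: mutant must be 1 or 2")
        if row.site not in _SITES:
            raise SchemaError(f"{path}:{line}: site must be one of {_SITES}")
        if not (float(row.sd) > 0):
            raise SchemaError(f"{path}:{line}: sd must be positive")
        mean[m - 1, _SITES.index(row.site)] = float(row.mean)
        sd[m - 1, _SITES.index(row.site)] = float(row.sd)
    if np.isnan(mean).any():
        raise SchemaError(f"{path}: need all four (mutant, site) fold-changes")
    return FoldChangeObservations.from_sds(mean, sd)


def write_foldchanges(obs: FoldChangeObservations, path: PathLike) -> None:
    rows = []
    for m in range(2):
        for s, site in enumerate(_SITES):
            rows.append({"mutant": m + 1, "site": site,
                         "mean": obs.mean[m, s], "sd": np.sqrt(obs.var[m, s])})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_exchange(path: PathLike) -> ExchangeObservations:
    df = _read_tsv(path, {"record", "value", "time_h"})
    g_vals, g_times = [], []
    h_vals, h_times, h_sds = [], [], []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        if row.record == "g_replicate":
            g_vals.append(float(row.value))
            g_times.append(float(row.time_h))
        elif row.record == "h_point":
            h_vals.append(float(row.value))
            h_times.append(float(row.time_h))
            sd = float(getattr(row, "sd", np.nan))
            if not (sd > 0):
                raise SchemaError(f"{path}:{line}: h_point needs a positive sd")
            h_sds.append(sd)
        else:
            raise SchemaError(f"{path}:{line}: unknown record type {row.record!r}")
    if len(g_vals) < 2:
        raise SchemaError(f"{path}: need at least two g_replicate rows")
    if len(set(g_times)) != 1:
        raise SchemaError(f"{path}: all g replicates must share one time")
    if len(h_vals) < 2:
        raise SchemaError(f"{path}: need at least two h_point rows")
    if len(set(h_sds)) != 1:
        raise SchemaError(f"{path}: h points must share one sd "
                          "(a single independent experimental sd is assumed)")
    order = np.argsort(h_times)
    return ExchangeObservations(
        g_replicates=np.asarray(g_vals), g_time_h=g_times[0],
        h_mean=np.asarray(h_vals)[order], h_times_h=np.asarray(h_times)[order],
        h_sd=h_sds[0],
    )


def write_exchange(obs: ExchangeObservations, path: PathLike) -> None:
    rows = [{"record": "g_replicate", "value": v, "time_h": obs.g_time_h,
             "sd": ""} for v in obs.g_replicates]
    rows += [{"record": "h_point", "value": v, "time_h": t, "sd": obs.h_sd}
             for v, t in zip(obs.h_mean, obs.h_times_h)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def packaged_data_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    ref = importlib.resources.files("onoffslide") / "data" / name
    return Path(str(ref))


def packaged_foldchanges() -> FoldChangeObservations:
    """The published sticky-N-3 restriction-enzyme fold-changes (Table values)."""
    return load_foldchanges(packaged_data_path("foldchanges_sticky_n3.tsv"))


def packaged_exchange() -> ExchangeObservations:
    """The printed histone-exchange summary values.

    The four h measurement times are NOT printed in the modelled summary and
    are assumed values (documented in the file header); replace the file or
    load your own to use transcribed times.
    """
    return load_exchange(packaged_data_path("exchange_flag_myc.tsv"))


def packaged_counts_synthetic() -> ConfigCounts:
    """A synthetic stand-in for single-molecule configuration counts.

    Generated from the package's ground-truth fixture model; it is NOT the
    published single-molecule dataset, which is not redistributed here.
    """
    return load_config_counts(packaged_data_path("config_counts_synthetic.tsv"))


# --------------------------------------------------------------------------
# run configuration and reports

class RunConfig:
    """Structured run configuration for the staged pipeline CLI."""

    DEFAULTS = {
        "max_params": 7,
        "rmax": 6.0,
        "n_starts": 100,
        "seed": 0,
        "rate_bounds": [1e-2, 1e2],
        "kappa_bounds": [0.2, 5.0],
        "time_scale_bounds": [1e-3, 1e3],
        "counts": None,
        "foldchanges": None,
        "exchange": None,
        "subset": None,
        "out_dir": "results",
    }

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(self.DEFAULTS)
        if unknown:
            raise SchemaError(f"unknown run-config keys: {sorted(unknown)}")
        self.values = {**self.DEFAULTS, **kwargs}
        if self.values["max_params"] < 4:
            raise SchemaError("max_params must be >= 4")
        if not (self.values["rmax"] > 0):
            raise SchemaError("rmax must be positive")
        for key in ("counts", "foldchanges", "exchange"):
            p = self.values[key]
            if p is not None and not Path(p).exists():
                raise SchemaError(f"run-config {key} file does not exist: {p}")

    def __getattr__(self, item):
        try:
            return self.values[item]
        except KeyError as exc:
            raise AttributeError(item) from exc

    def fit_config(self):
        from .fitting import FitConfig
        return FitConfig(
            n_starts=self.values["n_starts"],
            rate_bounds=tuple(self.values["rate_bounds"]),
            kappa_bounds=tuple(self.values["kappa_bounds"]),
            time_scale_bounds=tuple(self.values["time_scale_bounds"]),
            rmax=self.values["rmax"],
            seed=self.values["seed"],
        )


def load_run_config(path: PathLike) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: run config must be a mapping")
    return RunConfig(**data)


def _config_hash(cfg) -> str:
    payload = json.dumps(getattr(cfg, "values", repr(cfg)), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_reports(result, out_dir: PathLike, cfg=None) -> dict[str, Path]:
    """Write survivor table, per-model JSON and a run log; deterministic output.

    ``result`` is a :class:`onoffslide.fitting.PipelineResult`.  Returns the
    paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table = out / "model_summary.tsv"
    df = result.records.copy()
    reg_col = []
    for _, row in df.iterrows():
        reg_col.append(row["regulated"])
    df["regulated_processes"] = reg_col
    df.to_csv(table, sep="\t", index=False, float_format="%.6g")
    paths["summary"] = table

    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for stage, fits in sorted(result.fits.items()):
        for idx, fit in sorted(fits.items()):
            rec = {
                "model": fit.model.label(),
                "stage": stage,
                "R1": fit.R1, "R2": fit.R2, "R3": fit.R3,
                "time_scale": fit.time_scale,
                "rates": {p: (dict(v) if isinstance(v, dict) else v)
                          for p, v in fit.params.rates.items()},
                "kappas": [list(k.as_array()) for k in fit.kappas] if fit.kappas else None,
                "multiple_optima": bool(fit.multiple_optima),
                "non_unique_params": bool(fit.non_unique_params),
            }
            p = fits_dir / f"model{idx:06d}_stage{stage}.json"
            p.write_text(json.dumps(rec, indent=2, default=float))
    paths["fits"] = fits_dir

    log = out / "run_log.json"
    log.write_text(json.dumps({
        "survivors": result.survivor_counts(),
        "rmax": result.rmax,
        "config_hash": _config_hash(cfg) if cfg is not None else None,
        "seed": getattr(cfg, "seed", None) if cfg is not None else None,
        "n_models": int(len(result.records)),
    }, indent=2))
    paths["log"] = log
    return paths
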