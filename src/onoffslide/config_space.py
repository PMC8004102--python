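"""Configuration space, process catalog, governance and model enumeration.

The promoter is modelled as three nucleosome sites (N-1, N-2, N-3) whose
joint occupancy defines 8 configurations connected by 32 directed reactions:
12 assemblies, 12 disassemblies and 8 slides (a nucleosome moving to an
adjacent empty site).  A *process* is a group of reactions sharing one rate
parameter.  Processes form a hierarchy — global, site-specific and
configuration-specific — and within a model the most specific process
covering a reaction determines its rate ("overruling").

A *model* is a set of processes (global assembly A and disassembly D are
mandatory) together with a choice of which processes are regulated, i.e.
take a separate rate value in each of the three promoter states.  Regulated
processes contribute three fitted parameters, constitutive processes one.

Configuration encoding (occupancy of (N-1, N-2, N-3); 1 = occupied)::

    1=(1,1,1)  2=(0,1,1)  3=(1,0,1)  4=(1,1,0)
    5=(1,0,0)  6=(0,1,0)  7=(0,0,1)  8=(0,0,0)

This encoding is fixed throughout the package and is asserted in the tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "N_CONFIGS",
    "N_REACTIONS",
    "Configuration",
    "Reaction",
    "Process",
    "ModelSpec",
    "RateAssignment",
    "ConfigurationSpace",
    "RedundantModelError",
    "build_configuration_space",
    "build_process_catalog",
    "resolve_governance",
    "enumerate_models",
    "is_equilibrium",
    "catalog_statistics",
    "models_to_tsv",
    "model_to_json",
]

N_CONFIGS = 8
N_REACTIONS = 32

#: fixed index -> occupancy map; sites ordered (N-1, N-2, N-3)
_OCCUPANCY: dict[int, tuple[int, int, int]] = {
    1: (1, 1, 1), 2: (0, 1, 1), 3: (1, 0, 1), 4: (1, 1, 0),
    5: (1, 0, 0), 6: (0, 1, 0), 7: (0, 0, 1), 8: (0, 0, 0),
}
_INDEX_OF = {occ: i for i, occ in _OCCUPANCY.items()}

#: adjacent site pairs that admit sliding, as 0-based site indices
_SLIDE_PAIRS = ((0, 1), (1, 0), (1, 2), (2, 1))


@dataclass(frozen=True)
class Configuration:
    """One of the 8 promoter occupancy configurations."""

    index: int                       # 1-based, matches the numbering used throughout
    occupancy: tuple[int, int, int]  # (N-1, N-2, N-3), 1 = nucleosome present


@dataclass(frozen=True)
class Reaction:
    """A directed transition between two configurations."""

    index: int           # 0..31, stable internal ordering
    source: int          # 1-based configuration index
    target: int
    kind: str            # "assembly" | "disassembly" | "slide"
    site: Optional[int] = None        # 1-based affected site for assembly/disassembly
    slide_from: Optional[int] = None  # 1-based origin site for slides
    slide_to: Optional[int] = None


@dataclass(frozen=True)
class Process:
    """A named group of reactions sharing one rate parameter."""

    id: str
    level: str            # "global" | "site_specific" | "configuration_specific"
    kind: str             # "assembly" | "disassembly" | "slide"
    reactions: frozenset[int]
    mandatory: bool = False

    @property
    def size(self) -> int:
        return len(self.reactions)


class ConfigurationSpace:
    """The 8 configurations and 32 reactions with fast lookup tables."""

    def __init__(self) -> None:
        self.configurations: tuple[Configuration, ...] = tuple(
            Configuration(i, _OCCUPANCY[i]) for i in range(1, 9)
        )
        reactions: list[Reaction] = []
        for cfg in self.configurations:
            occ = cfg.occupancy
            for k in range(3):
                if occ[k]:
                    tgt = list(occ); tgt[k] = 0
                    reactions.append(Reaction(len(reactions), cfg.index,
                                              _INDEX_OF[tuple(tgt)], "disassembly",
                                              site=k + 1))
                else:
                    tgt = list(occ); tgt[k] = 1
                    reactions.append(Reaction(len(reactions), cfg.index,
                                              _INDEX_OF[tuple(tgt)], "assembly",
                                              site=k + 1))
            for a, b in _SLIDE_PAIRS:
                if occ[a] == 1 and occ[b] == 0:
                    tgt = list(occ); tgt[a] = 0; tgt[b] = 1
                    reactions.append(Reaction(len(reactions), cfg.index,
                                              _INDEX_OF[tuple(tgt)], "slide",
                                              slide_from=a + 1, slide_to=b + 1))
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.reaction_index: dict[tuple[int, int], int] = {
            (r.source, r.target): r.index for r in self.reactions
        }
        #: index of the reverse reaction, or None for one-way pairs (never occurs:
        #: every assembly/disassembly/slide here has a structural reverse)
        self.reverse: tuple[int, ...] = tuple(
            self.reaction_index[(r.target, r.source)] for r in self.reactions
        )

    def occupancy(self, index: int) -> tuple[int, int, int]:
        return _OCCUPANCY[index]

    def index_of(self, occupancy: Sequence[int]) -> int:
        return _INDEX_OF[tuple(occupancy)]


@lru_cache(maxsize=1)
def build_configuration_space() -> ConfigurationSpace:
    """Build (once) the shared configuration space."""
    return ConfigurationSpace()


def _mask(reactions: Iterable[int]) -> frozenset[int]:
    return frozenset(reactions)


@lru_cache(maxsize=1)
def build_process_catalog() -> dict[str, Process]:
    """The 46-process catalog: 2 mandatory global + 44 optional processes.

    Order is the canonical catalog order used for deterministic model sorting:
    A, D, S, A1..A3, D1..D3, S2*, S12, S21, S23, S32, then the 32
    configuration-specific processes in reaction-index order (named e.g.
    ``D1-4`` for the disassembly taking configuration 1 to 4, ``S3-4`` for the
    slide taking 3 to 4).
    """
    space = build_configuration_space()
    rx = space.reactions
    cat: dict[str, Process] = {}

    def add(pid: str, level: str, kind: str, rs: Iterable[int], mandatory: bool = False):
        cat[pid] = Process(pid, level, kind, _mask(rs), mandatory)

    add("A", "global", "assembly", (r.index for r in rx if r.kind == "assembly"), True)
    add("D", "global", "disassembly", (r.index for r in rx if r.kind == "disassembly"), True)
    add("S", "global", "slide", (r.index for r in rx if r.kind == "slide"))
    for k in (1, 2, 3):
        add(f"A{k}", "site_specific", "assembly",
            (r.index for r in rx if r.kind == "assembly" and r.site == k))
        add(f"D{k}", "site_specific", "disassembly",
            (r.index for r in rx if r.kind == "disassembly" and r.site == k))
    add("S2*", "site_specific", "slide",
        (r.index for r in rx if r.kind == "slide" and r.slide_from == 2))
    for frm, to in ((1, 2), (2, 1), (2, 3), (3, 2)):
        add(f"S{frm}{to}", "site_specific", "slide",
            (r.index for r in rx if r.kind == "slide"
             and r.slide_from == frm and r.slide_to == to))
    letter = {"assembly": "A", "disassembly": "D", "slide": "S"}
    for r in rx:
        add(f"{letter[r.kind]}{r.source}-{r.target}", "configuration_specific",
            r.kind, (r.index,))
    return cat


_CATALOG_ORDER: dict[str, int] = {}


def _catalog_order(pid: str) -> int:
    global _CATALOG_ORDER
    if not _CATALOG_ORDER:
        _CATALOG_ORDER = {p: i for i, p in enumerate(build_process_catalog())}
    return _CATALOG_ORDER[pid]


@dataclass(frozen=True)
class ModelSpec:
    """A regulated on-off-slide model: a process set plus regulated flags."""

    processes: tuple[str, ...]      # sorted in catalog order, contains A and D
    regulated: frozenset[str]       # non-empty subset of processes

    def __post_init__(self) -> None:
        if "A" not in self.processes or "D" not in self.processes:
            raise ValueError("every model must contain global assembly A and disassembly D")
        if not self.regulated:
            raise ValueError("at least one process must be regulated")
        if not self.regulated <= set(self.processes):
            raise ValueError("regulated ids must be a subset of the model's processes")
        if len(self.regulated) >= len(self.processes):
            raise ValueError("at least one process must be constitutive")
        ordered = tuple(sorted(self.processes, key=_catalog_order))
        object.__setattr__(self, "processes", ordered)

    @classmethod
    def make(cls, processes: Iterable[str], regulated: Iterable[str]) -> "ModelSpec":
        return cls(tuple(processes), frozenset(regulated))

    @property
    def constitutive(self) -> tuple[str, ...]:
        return tuple(p for p in self.processes if p not in self.regulated)

    @property
    def param_count(self) -> int:
        return 3 * len(self.regulated) + len(self.constitutive)

    def label(self) -> str:
        return ",".join(p + ("*" if p in self.regulated else "") for p in self.processes)

    @property
    def sort_key(self):
        return (self.param_count,
                tuple(_catalog_order(p) for p in self.processes),
                tuple(sorted(_catalog_order(p) for p in self.regulated)))


class RedundantModelError(ValueError):
    """Raised when every reaction of some process is overruled by more specific ones."""


@dataclass(frozen=True)
class RateAssignment:
    """Resolution of a model's governance: reaction -> governing process (or None).

    Slide reactions covered by no sliding process in the model get rate zero
    (``governing`` entry is None).
    """

    model: ModelSpec
    governing: tuple[Optional[str], ...]           # length 32
    slots: Mapping[str, frozenset[int]] = field(hash=False, compare=False, default=None)

    @property
    def signature(self) -> frozenset[tuple[frozenset[int], bool]]:
        """Canonical rate-matrix signature: reaction partition + regulated flags."""
        reg = self.model.regulated
        return frozenset((rs, p in reg) for p, rs in self.slots.items())


def resolve_governance(model: ModelSpec) -> RateAssignment:
    """Map every reaction to its governing process via the overruling rule.

    The most specific process (smallest governed set) covering a reaction
    determines its rate.  Processes at the same hierarchy size never overlap,
    so claiming reactions in ascending size order is exact and insertion-order
    independent.

    Raises
    ------
    RedundantModelError
        if some process ends up governing no reactions at all.
    """
    catalog = build_process_catalog()
    assigned: set[int] = set()
    slots: dict[str, frozenset[int]] = {}
    for pid in sorted(model.processes, key=lambda p: (catalog[p].size, p)):
        take = catalog[pid].reactions - assigned
        if not take:
            raise RedundantModelError(
                f"process {pid} is fully overruled in model {model.label()}")
        slots[pid] = frozenset(take)
        assigned |= take
    governing: list[Optional[str]] = [None] * N_REACTIONS
    for pid, rs in slots.items():
        for r in rs:
            governing[r] = pid
    return RateAssignment(model, tuple(governing), slots)


# --------------------------------------------------------------------------
# enumeration

def _optional_ids() -> list[str]:
    return [p for p, proc in build_process_catalog().items() if not proc.mandatory]


def _raw_candidates(max_params: int):
    """Yield (process tuple, regulated frozenset) before redundancy/dedup filtering."""
    optional = _optional_ids()
    max_extra = max_params - 4  # A, D plus >=1 regulated (3 params) leaves this many
    for n_extra in range(0, max_extra + 1):
        for extras in itertools.combinations(optional, n_extra):
            pset = ("A", "D") + extras
            n = len(pset)
            for n_reg in range(1, n):
                if 3 * n_reg + (n - n_reg) > max_params:
                    break
                for reg in itertools.combinations(pset, n_reg):
                    yield pset, frozenset(reg)


def raw_candidate_count(max_params: int) -> int:
    """Closed-form count of candidates before redundancy and duplicate removal."""
    from math import comb
    n_opt = len(_optional_ids())
    total = 0
    for n_extra in range(0, max(0, max_params - 4) + 1):
        n = 2 + n_extra
        for n_reg in range(1, n):
            if 3 * n_reg + (n - n_reg) <= max_params:
                total += comb(n_opt, n_extra) * comb(n, n_reg)
    return total


def enumerate_models(max_params: int = 7) -> list[ModelSpec]:
    """Enumerate all distinct regulated on-off-slide models within the budget.

    Candidates contain A and D, at least one regulated and one constitutive
    process, and use at most ``max_params`` fitted parameters (3 per regulated
    process, 1 per constitutive; the overall time scale is one of these
    degrees of freedom).  Models with a fully overruled process are redundant
    and dropped.  Among models with identical rate-matrix signature
    (identical reaction partition and regulated flags), those that differ
    only in their *non-global* sliding process composition are duplicates —
    relabelings of the same sliding rate slots — and are collapsed to one
    representative (smallest process set in catalog order).  Signature-equal
    models that differ in assembly/disassembly composition or in the use of
    global sliding remain distinct.

    The returned list is sorted by (param_count, process ids, regulated ids)
    in catalog order, so model indices are stable for this implementation.
    """
    if max_params < 4:
        raise ValueError("max_params must be at least 4 (the two simplest models)")
    catalog = build_process_catalog()
    slide_ids = {p for p, proc in catalog.items()
                 if proc.kind == "slide" and proc.level != "global"}
    # signature -> dedup key -> best representative
    kept: dict[frozenset, dict[tuple, ModelSpec]] = {}
    slots_cache: dict[tuple, Optional[dict]] = {}
    for pset, reg in _raw_candidates(max_params):
        slots = slots_cache.get(pset, False)
        if slots is False:
            try:
                slots = dict(resolve_governance(ModelSpec.make(pset, (pset[0],))).slots)
            except RedundantModelError:
                slots = None
            slots_cache[pset] = slots
        if slots is None:
            continue
        sig = frozenset((rs, p in reg) for p, rs in slots.items())
        key = (frozenset(p for p in pset if p not in slide_ids), "S" in pset)
        model = ModelSpec.make(pset, reg)
        group = kept.setdefault(sig, {})
        prev = group.get(key)
        if prev is None or model.sort_key < prev.sort_key:
            group[key] = model
    models = [m for group in kept.values() for m in group.values()]
    models.sort(key=lambda m: m.sort_key)
    return models


# --------------------------------------------------------------------------
# structural equilibrium detection (Kolmogorov cycle criterion)

@lru_cache(maxsize=64)
def _cycle_basis(slide_pairs: frozenset[tuple[int, int]]) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Cycle basis of the undirected reaction graph (3-cube + given slide edges).

    Each cycle is returned as a tuple of directed (source, target) steps.
    """
    space = build_configuration_space()
    g = nx.Graph()
    g.add_nodes_from(range(1, 9))
    for r in space.reactions:
        if r.kind == "assembly":
            g.add_edge(r.source, r.target)
    for e in slide_pairs:
        g.add_edge(*e)
    basis = []
    for cyc in nx.cycle_basis(g):
        steps = tuple((cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc)))
        basis.append(steps)
    return tuple(basis)


_EQ_CACHE: dict[tuple[str, ...], bool] = {}


def is_equilibrium(model: ModelSpec, n_draws: int = 5, tol: float = 1e-9,
                   seed: int = 12345) -> bool:
    """True iff detailed balance holds for *all* positive parameter values.

    Implements the Kolmogorov cycle criterion with generic random rates: a
    model is an equilibrium model iff (a) every covered slide reaction has a
    covered reverse (no structurally one-way edges) and (b) for generic rate
    draws the log-rate differences around every basis cycle of the reaction
    graph sum to zero.  Regulated flags are irrelevant: the criterion is
    applied to the matrix structure shared by all three promoter states.
    """
    default = (n_draws, tol, seed) == (5, 1e-9, 12345)
    if default and model.processes in _EQ_CACHE:
        # detailed balance is a property of the matrix structure only, so the
        # result is shared by all regulated-flag variants of a process set
        return _EQ_CACHE[model.processes]
    result = _kolmogorov_check(model, n_draws, tol, seed)
    if default:
        _EQ_CACHE[model.processes] = result
    return result


def _kolmogorov_check(model: ModelSpec, n_draws: int, tol: float, seed: int) -> bool:
    space = build_configuration_space()
    assignment = resolve_governance(model)
    gov = assignment.governing
    slide_pairs: set[tuple[int, int]] = set()
    for r in space.reactions:
        if r.kind != "slide":
            continue
        has_fwd = gov[r.index] is not None
        has_rev = gov[space.reverse[r.index]] is not None
        if has_fwd != has_rev:
            return False  # one-way edge with nonzero rate => nonzero net flux
        if has_fwd:
            slide_pairs.add((min(r.source, r.target), max(r.source, r.target)))
    basis = _cycle_basis(frozenset(slide_pairs))
    rindex = space.reaction_index
    rng = np.random.default_rng(seed)
    slot_ids = sorted(assignment.slots)
    for _ in range(n_draws):
        logr = {p: np.log(rng.uniform(0.1, 10.0)) for p in slot_ids}
        for steps in basis:
            s = 0.0
            for (i, j) in steps:
                s += logr[gov[rindex[(i, j)]]] - logr[gov[rindex[(j, i)]]]
            if abs(s) > tol:
                return False
    return True


# --------------------------------------------------------------------------
# catalog statistics and export

def catalog_statistics(models: Sequence[ModelSpec]) -> pd.DataFrame:
    """Per-process occurrence frequencies over a model list.

    Returns a DataFrame indexed by process id with columns ``n_models``,
    ``frequency``, ``n_regulated``, ``n_constitutive``, ``freq_regulated``,
    ``freq_constitutive``.
    """
    if not models:
        raise ValueError("need a nonempty model list")
    catalog = build_process_catalog()
    n_tot = {p: 0 for p in catalog}
    n_reg = {p: 0 for p in catalog}
    for m in models:
        for p in m.processes:
            n_tot[p] += 1
            if p in m.regulated:
                n_reg[p] += 1
    n = len(models)
    df = pd.DataFrame({
        "n_models": pd.Series(n_tot),
        "n_regulated": pd.Series(n_reg),
    })
    df["n_constitutive"] = df["n_models"] - df["n_regulated"]
    df["frequency"] = df["n_models"] / n
    df["freq_regulated"] = df["n_regulated"] / n
    df["freq_constitutive"] = df["n_constitutive"] / n
    df.index.name = "process"
    return df


def models_to_tsv(models: Sequence[ModelSpec], path, equilibrium: bool = False) -> None:
    """Write a model catalog as TSV (one row per model)."""
    rows = []
    for i, m in enumerate(models):
        row = {
            "model_index": i,
            "processes": ",".join(m.processes),
            "regulated": ",".join(sorted(m.regulated, key=_catalog_order)),
            "param_count": m.param_count,
        }
        if equilibrium:
            row["is_equilibrium"] = int(is_equilibrium(m))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def model_to_json(model: ModelSpec) -> str:
    """JSON description of a model including its full governance map."""
    assignment = resolve_governance(model)
    space = build_configuration_space()
    gov = {
        f"{r.source}->{r.target}": assignment.governing[r.index]
        for r in space.reactions
    }
    return json.dumps({
        "processes": list(model.processes),
        "regulated": sorted(model.regulated, key=_catalog_order),
        "param_count": model.param_count,
        "governance": gov,
    }, indent=2)
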