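"""Marxan-style reserve selection by simulated annealing.

The objective minimized over subsets S of planning units is

    O(S) = sum_{i in S} cost_i
         + BLM * exposed_boundary(S)
         + sum_f SPF_f * shortfall_fraction_f(S) * base_penalty_f

where exposed_boundary is the perimeter of the selection (edges of selected
units not shared with another selected unit, including the study-area outer
edge), shortfall_fraction_f = max(0, (target_f - held_f) / target_f), and
base_penalty_f is the cost (including BLM-weighted boundary increments) of
meeting feature f's target greedily from the empty set, fixed at problem
construction. The cost-threshold term is not implemented.

Optimization runs single-unit flip annealing with an adaptive initial
temperature and geometric cooling, followed by iterative improvement to a
local fixed point. Repeated runs give per-unit selection frequencies — the
irreplaceability measure — and units selected in more than a fraction
(default 0.9) of runs form the key protection areas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import PlanningUnitSet


@dataclass
class ReserveProblem:
    costs: np.ndarray                      # (N,)
    amounts: np.ndarray                    # (F, N)
    target_fraction: np.ndarray            # (F,) of total amount
    spf: np.ndarray                        # (F,)
    blm: float
    edges: dict[tuple[int, int], float]    # 0-based index pairs -> length
    outer: np.ndarray                      # (N,) exposed outer edge length
    unit_ids: list[int] | None = None
    feature_names: list[str] | None = None
    locked_in: np.ndarray | None = None    # bool (N,)
    locked_out: np.ndarray | None = None
    targets: np.ndarray = field(init=False)         # absolute amounts
    base_penalty: np.ndarray = field(init=False)    # (F,)

    def __post_init__(self) -> None:
        self.costs = np.asarray(self.costs, float)
        self.amounts = np.atleast_2d(np.asarray(self.amounts, float))
        self.target_fraction = np.asarray(self.target_fraction, float)
        self.spf = np.asarray(self.spf, float)
        n = self.costs.size
        if self.amounts.shape[1] != n:
            raise ValueError("amounts must be (n_features, n_units)")
        if ((self.target_fraction <= 0) | (self.target_fraction > 1)).any():
            raise ValueError("targets must lie in (0, 1]")
        if (self.spf < 0).any() or self.blm < 0:
            raise ValueError("SPF and BLM must be non-negative")
        if self.unit_ids is None:
            self.unit_ids = list(range(1, n + 1))
        if self.locked_in is None:
            self.locked_in = np.zeros(n, bool)
        if self.locked_out is None:
            self.locked_out = np.zeros(n, bool)
        self.outer = np.asarray(self.outer, float)
        # neighbour adjacency lists
        self._nbrs: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for (i, j), l in self.edges.items():
            if i == j:
                continue
            self._nbrs[i].append((j, l))
            self._nbrs[j].append((i, l))
        self.targets = self.target_fraction * self.amounts.sum(axis=1)
        self.base_penalty = self._greedy_base_penalties()
        # per-unit nonzero feature contributions for fast deltas
        self._feats_of = [
            [(f, self.amounts[f, k]) for f in range(self.n_features)
             if self.amounts[f, k] != 0.0]
            for k in range(n)
        ]

    @property
    def n_units(self) -> int:
        return self.costs.size

    @property
    def n_features(self) -> int:
        return self.amounts.shape[0]

    def _boundary_delta(self, sel: np.ndarray, k: int) -> float:
        """Exposed-boundary change of adding k (negate for removing)."""
        db = self.outer[k]
        for j, l in self._nbrs[k]:
            db += -l if sel[j] else l
        return db

    def _greedy_base_penalties(self) -> np.ndarray:
        """Greedy cost of meeting each target from the empty set."""
        base = np.zeros(self.n_features)
        for f in range(self.n_features):
            a = self.amounts[f]
            sel = np.zeros(self.n_units, bool)
            held, total = 0.0, 0.0
            candidates = set(np.flatnonzero(a > 0))
            while held < self.targets[f] - 1e-12 and candidates:
                best_k, best_ratio, best_marg = None, -np.inf, 0.0
                for k in candidates:
                    marg = self.costs[k] + self.blm * self._boundary_delta(sel, k)
                    ratio = a[k] / max(marg, 1e-12)
                    if ratio > best_ratio:
                        best_ratio, best_k, best_marg = ratio, k, marg
                sel[best_k] = True
                total += best_marg
                held += a[best_k]
                candidates.discard(best_k)
            base[f] = total
        return base

    @classmethod
    def from_units(
        cls,
        units: PlanningUnitSet,
        target: float = 0.5,
        spf: float = 16.74,
        blm: float = 2.11,
        include_outer: bool = True,
        features: list[str] | None = None,
    ) -> "ReserveProblem":
        if units.costs is None:
            raise ValueError("unit costs not computed")
        names = features or sorted(units.amounts)
        if not names:
            raise ValueError("no feature amounts on the unit set")
        amounts = np.vstack([units.amounts[n] for n in names])
        id_to_idx = {uid: k for k, uid in enumerate(units.ids)}
        edges = {
            (id_to_idx[a], id_to_idx[b]): l for (a, b), l in units.edges.items()
        }
        outer = units.outer_km if include_outer else np.zeros(len(units))
        nf = len(names)
        return cls(
            costs=units.costs,
            amounts=amounts,
            target_fraction=np.full(nf, target),
            spf=np.full(nf, spf),
            blm=blm,
            edges=edges,
            outer=np.asarray(outer, float),
            unit_ids=list(units.ids),
            feature_names=names,
        )

    @classmethod
    def from_marxan_dir(cls, directory, blm: float = 2.11) -> "ReserveProblem":
        """Build from pu.dat / spec.dat / puvspr.dat / bound.dat.

        spec.dat targets are absolute amounts (standard Marxan semantics);
        they are converted to fractions of each feature's total.
        """
        from .units import read_marxan_dir

        pu, spec, puvspr, bound = read_marxan_dir(directory)
        ids = pu["id"].tolist()
        idx = {uid: k for k, uid in enumerate(ids)}
        n = len(ids)
        sp_ids = spec["id"].tolist()
        f_idx = {sid: f for f, sid in enumerate(sp_ids)}
        amounts = np.zeros((len(sp_ids), n))
        for r in puvspr.itertuples():
            amounts[f_idx[r.species], idx[r.pu]] = r.amount
        totals = amounts.sum(axis=1)
        tf = spec["target"].to_numpy(float) / np.where(totals > 0, totals, 1.0)
        edges, outer = {}, np.zeros(n)
        for r in bound.itertuples():
            if r.id1 == r.id2:
                outer[idx[r.id1]] += r.boundary
            else:
                a, b = sorted((idx[r.id1], idx[r.id2]))
                edges[(a, b)] = r.boundary
        status = pu["status"].to_numpy(int) if "status" in pu else np.zeros(n, int)
        return cls(
            costs=pu["cost"].to_numpy(float),
            amounts=amounts,
            target_fraction=np.clip(tf, 1e-12, 1.0),
            spf=spec["spf"].to_numpy(float),
            blm=blm,
            edges=edges,
            outer=outer,
            unit_ids=ids,
            feature_names=[str(s) for s in
                           (spec["name"] if "name" in spec else sp_ids)],
            locked_in=status == 2,
            locked_out=status == 3,
        )


@dataclass
class Solution:
    selected: np.ndarray           # bool (N,)
    objective: float
    breakdown: dict                # cost, boundary, penalty, blm
    feasible: bool
    unit_ids: list[int]

    @property
    def selected_ids(self) -> list[int]:
        return [uid for uid, s in zip(self.unit_ids, self.selected) if s]


def exposed_boundary(problem: ReserveProblem, sel: np.ndarray) -> float:
    """Perimeter of the selection: outer edges of selected units plus
    shared edges whose other side is unselected."""
    b = float(problem.outer[sel].sum())
    for (i, j), l in problem.edges.items():
        if i == j:
            continue
        if sel[i] != sel[j]:
            b += l
    return b


def objective_value(problem: ReserveProblem, selected) -> tuple[float, dict]:
    """Full (non-incremental) objective evaluation with term breakdown."""
    sel = _as_bool(problem, selected)
    cost = float(problem.costs[sel].sum())
    boundary = exposed_boundary(problem, sel)
    held = problem.amounts[:, sel].sum(axis=1)
    shortfall = np.clip(
        (problem.targets - held) / np.where(problem.targets > 0,
                                            problem.targets, 1.0),
        0.0, None,
    )
    penalty = float((problem.spf * shortfall * problem.base_penalty).sum())
    total = cost + problem.blm * boundary + penalty
    return total, {
        "cost": cost,
        "boundary": boundary,
        "blm": problem.blm,
        "penalty": penalty,
        "held": held,
        "feasible": bool((held >= problem.targets - 1e-9).all()),
    }


def _as_bool(problem: ReserveProblem, selected) -> np.ndarray:
    if isinstance(selected, np.ndarray) and selected.dtype == bool:
        return selected
    sel = np.zeros(problem.n_units, bool)
    idx = {uid: k for k, uid in enumerate(problem.unit_ids)}
    for uid in selected:
        if uid not in idx:
            raise KeyError(f"unknown unit id {uid}")
        sel[idx[uid]] = True
    return sel


class _AnnealState:
    """Incremental objective bookkeeping for single-unit flips."""

    def __init__(self, problem: ReserveProblem, sel: np.ndarray):
        self.p = problem
        self.sel = sel.copy()
        self.cost = float(problem.costs[self.sel].sum())
        self.boundary = exposed_boundary(problem, self.sel)
        self.held = problem.amounts[:, self.sel].sum(axis=1)
        self._spf_base = problem.spf * problem.base_penalty
        self.penalty = self._penalty_from_held(self.held)

    def _penalty_from_held(self, held) -> float:
        t = self.p.targets
        sf = np.clip((t - held) / np.where(t > 0, t, 1.0), 0.0, None)
        return float((self._spf_base * sf).sum())

    @property
    def objective(self) -> float:
        return self.cost + self.p.blm * self.boundary + self.penalty

    def delta(self, k: int) -> float:
        p = self.p
        adding = not self.sel[k]
        db = p._boundary_delta(self.sel, k)
        d = (p.costs[k] + p.blm * db) if adding else -(p.costs[k] + p.blm * db)
        sign = 1.0 if adding else -1.0
        for f, a in p._feats_of[k]:
            t = p.targets[f]
            if t <= 0:
                continue
            old = max(0.0, (t - self.held[f]) / t)
            new = max(0.0, (t - (self.held[f] + sign * a)) / t)
            d += self._spf_base[f] * (new - old)
        return d

    def flip(self, k: int) -> None:
        p = self.p
        adding = not self.sel[k]
        db = p._boundary_delta(self.sel, k)
        sign = 1.0 if adding else -1.0
        self.cost += sign * p.costs[k]
        self.boundary += db if adding else -db
        for f, a in p._feats_of[k]:
            self.held[f] += sign * a
        self.penalty = self._penalty_from_held(self.held)
        self.sel[k] = adding


def _iterative_improvement(state: _AnnealState) -> None:
    """Remove-then-add passes to a local fixed point."""
    n = state.p.n_units
    locked_in, locked_out = state.p.locked_in, state.p.locked_out
    changed = True
    while changed:
        changed = False
        for k in range(n):
            if state.sel[k] and not locked_in[k] and state.delta(k) < -1e-12:
                state.flip(k)
                changed = True
        for k in range(n):
            if not state.sel[k] and not locked_out[k] and state.delta(k) < -1e-12:
                state.flip(k)
                changed = True


def anneal(
    problem: ReserveProblem,
    n_iterations: int = 100_000,
    seed: int = 0,
    t_init: float | None = None,
    t_final_ratio: float = 1e-4,
    init_prob: float = 0.5,
    improve: bool = True,
) -> Solution:
    """One annealing run: flip proposals with Metropolis acceptance under a
    geometric cooling schedule, then iterative improvement."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n = problem.n_units
    sel = rng.random(n) < init_prob
    sel[problem.locked_in] = True
    sel[problem.locked_out] = False
    state = _AnnealState(problem, sel)

    free = np.flatnonzero(~(problem.locked_in | problem.locked_out))
    if free.size == 0:
        total, bd = objective_value(problem, state.sel)
        return Solution(state.sel, total, bd, bd["feasible"], problem.unit_ids)

    if t_init is None:
        probes = rng.choice(free, size=100)
        mags = np.abs([state.delta(int(k)) for k in probes])
        mags = mags[mags > 0]
        t_init = float(np.percentile(mags, 90)) if mags.size else 1.0
    alpha = t_final_ratio ** (1.0 / n_iterations)

    ks = rng.choice(free, size=n_iterations)
    us = rng.random(n_iterations)
    temp = t_init
    for t in range(n_iterations):
        k = int(ks[t])
        d = state.delta(k)
        if d <= 0.0 or (temp > 0 and us[t] < math.exp(-d / temp)):
            state.flip(k)
        temp *= alpha
    if improve:
        _iterative_improvement(state)
    total, bd = objective_value(problem, state.sel)
    return Solution(state.sel.copy(), total, bd, bd["feasible"], problem.unit_ids)


@dataclass
class SelectionFrequency:
    counts: np.ndarray
    n_runs: int
    unit_ids: list[int]

    def __post_init__(self) -> None:
        c = self.counts
        if (c < 0).any() or (c > self.n_runs).any():
            raise ValueError("counts must lie in [0, n_runs]")

    def frequency(self) -> np.ndarray:
        return self.counts / self.n_runs


def repeat_runs(
    problem: ReserveProblem,
    n_runs: int = 1000,
    base_seed: int = 0,
    n_iterations: int = 100_000,
    **anneal_kw,
) -> tuple[SelectionFrequency, Solution]:
    """Independent annealing runs (seeds base_seed + k); returns the
    per-unit selection counts and the best (minimum-objective) solution."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    counts = np.zeros(problem.n_units, int)
    best: Solution | None = None
    for k in range(n_runs):
        sol = anneal(problem, n_iterations=n_iterations,
                     seed=base_seed + k, **anneal_kw)
        counts += sol.selected
        if best is None or sol.objective < best.objective:
            best = sol
    return SelectionFrequency(counts, n_runs, list(problem.unit_ids)), best


def select_key_areas(
    freq: SelectionFrequency,
    threshold_fraction: float = 0.9,
    contiguity: bool = False,
    min_units: int = 2,
    units: PlanningUnitSet | None = None,
    problem: ReserveProblem | None = None,
) -> dict:
    """Units selected in strictly more than threshold_fraction of runs.

    With ``contiguity`` on, only connected components (by shared-edge
    adjacency) of at least ``min_units`` units are retained. Returns ids,
    and — when a unit set is supplied — area and percent of study area.
    """
    cutoff = threshold_fraction * freq.n_runs
    key = [uid for uid, c in zip(freq.unit_ids, freq.counts) if c > cutoff]
    if contiguity and key:
        adj_edges = None
        if units is not None:
            adj_edges = units.edges
        elif problem is not None:
            id_of = problem.unit_ids
            adj_edges = {
                (id_of[i], id_of[j]): l
                for (i, j), l in problem.edges.items() if i != j
            }
        if adj_edges is None:
            raise ValueError("contiguity filter needs units or problem adjacency")
        keyset = set(key)
        nbrs: dict[int, set[int]] = {u: set() for u in key}
        for (a, b), l in adj_edges.items():
            if l > 0 and a in keyset and b in keyset:
                nbrs[a].add(b)
                nbrs[b].add(a)
        seen, kept = set(), []
        for u in key:
            if u in seen:
                continue
            comp, stack_ = [], [u]
            seen.add(u)
            while stack_:
                v = stack_.pop()
                comp.append(v)
                for w in nbrs[v]:
                    if w not in seen:
                        seen.add(w)
                        stack_.append(w)
            if len(comp) >= min_units:
                kept.extend(comp)
        key = sorted(kept)
    if not key:
        warnings.warn("key-area set is empty", stacklevel=2)
    out = {"ids": sorted(key), "n_units": len(key)}
    if units is not None:
        kidx = [units.ids.index(u) for u in key]
        area = float(units.area_km2[kidx].sum()) if kidx else 0.0
        total = float(units.area_km2.sum())
        out["area_km2"] = area
        out["pct_of_study_area"] = 100.0 * area / total if total else 0.0
    return out


def exhaustive_optimum(problem: ReserveProblem) -> tuple[np.ndarray, float]:
    """Exact optimum by subset enumeration (vectorized); n_units <= 20."""
    n = problem.n_units
    if n > 20:
        raise ValueError("exhaustive search limited to 20 units")
    m = 1 << n
    bits = ((np.arange(m)[:, None] >> np.arange(n)) & 1).astype(bool)
    cost = bits @ problem.costs
    boundary = bits @ problem.outer
    for (i, j), l in problem.edges.items():
        if i != j:
            boundary = boundary + l * (bits[:, i] ^ bits[:, j])
    held = bits @ problem.amounts.T  # (m, F)
    t = problem.targets
    sf = np.clip((t - held) / np.where(t > 0, t, 1.0), 0.0, None)
    pen = sf @ (problem.spf * problem.base_penalty)
    obj = cost + problem.blm * boundary + pen
    k = int(np.argmin(obj))
    return bits[k].copy(), float(obj[k])


def synthetic_problem(
    n_units: int,
    n_features: int = 1,
    seed: int = 0,
    blm: float = 2.11,
    spf: float = 16.74,
    target: float = 0.5,
) -> ReserveProblem:
    """Random reserve problem on a rook-adjacency square-ish grid of units
    with unit-length shared edges; used for optimizer studies and tests."""
    rng = np.random.default_rng(seed)
    ncols = int(math.ceil(math.sqrt(n_units)))
    edges: dict[tuple[int, int], float] = {}
    outer = np.zeros(n_units)
    for k in range(n_units):
        r, c = divmod(k, ncols)
        deg = 0
        if c > 0:
            deg += 1
        if c + 1 < ncols and k + 1 < n_units:
            edges[(k, k + 1)] = 1.0
            deg += 1
        if k - ncols >= 0:
            deg += 1
        if k + ncols < n_units:
            edges[(k, k + ncols)] = 1.0
            deg += 1
        outer[k] = 4.0 - deg  # exposed sides of a unit square
    costs = rng.uniform(0.2, 1.2, n_units)
    amounts = rng.uniform(0.0, 1.0, (n_features, n_units))
    return ReserveProblem(
        costs=costs,
        amounts=amounts,
        target_fraction=np.full(n_features, target),
        spf=np.full(n_features, spf),
        blm=blm,
        edges=edges,
        outer=outer,
    )


def sensitivity_sweep(
    problem_factory,
    blm_values=(0.0, 2.11, 20.0),
    spf_values=(1.0, 16.74),
    n_runs: int = 20,
    n_iterations: int = 5000,
    base_seed: int = 0,
):
    """Best objective / boundary / feasibility across a BLM x SPF grid.

    ``problem_factory(blm, spf)`` must return a ReserveProblem. Returns a
    pandas DataFrame; a lightweight stand-in for interactive SPF/BLM
    calibration tools.
    """
    import pandas as pd

    rows = []
    for blm in blm_values:
        for spf in spf_values:
            prob = problem_factory(blm, spf)
            freq, best = repeat_runs(
                prob, n_runs=n_runs, base_seed=base_seed,
                n_iterations=n_iterations,
            )
            rows.append({
                "blm": blm,
                "spf": spf,
                "best_objective": best.objective,
                "boundary": best.breakdown["boundary"],
                "cost": best.breakdown["cost"],
                "feasible": best.feasible,
                "n_selected": int(best.selected.sum()),
            })
    return pd.DataFrame(rows)
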