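"""Marxan-style minimum-set reserve selection over a planning-unit grid.

A planning unit (PU) is a square block of raster cells with a cost, a
per-feature amount (km^2 of suitable habitat inside it), and shared edge
lengths with its lattice neighbors. The objective to minimize is

    total = sum_selected cost
          + blm * boundary_length(selected)
          + sum_features spf * (shortfall_k / target_k) * G_k

where target_k = target_fraction * total amount of feature k, shortfall_k
is the unmet part of the target, and G_k is the cost of meeting target_k
greedily by best amount/cost ratio (a fixed per-feature scale, computed
once). Exterior edges of selected PUs count toward boundary length;
the empty selection has boundary 0 by convention.

Optimization is simulated annealing over single-unit flips (geometric
cooling, initial temperature calibrated to the median |delta| of random
flips) followed by greedy iterative improvement; an ensemble of
independent runs yields the best solution and per-unit selection
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodata import Grid, cell_areas_km2

KM_PER_DEG = 111.19492664455873  # mean-Earth-radius meridian degree


@dataclass
class PlanningUnit:
    id: int
    cost: float
    center: tuple[float, float]  # (lon, lat)
    exterior_edge: float = 0.0   # km of edge not shared with another PU


@dataclass
class PlanningUnitSet:
    units: list[PlanningUnit]
    amounts: dict[int, dict[str, float]]              # unit id -> feature -> amount
    boundaries: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [u.id for u in self.units]
        if len(ids) != len(set(ids)):
            raise ValueError("planning unit ids must be unique")
        for (a, b) in self.boundaries:
            if a >= b:
                raise ValueError("boundary keys must be ordered (a < b) pairs")

    @property
    def ids(self) -> list[int]:
        return [u.id for u in self.units]

    @property
    def features(self) -> list[str]:
        feats: set[str] = set()
        for m in self.amounts.values():
            feats.update(m)
        return sorted(feats)

    def total_amount(self, feature: str) -> float:
        return sum(m.get(feature, 0.0) for m in self.amounts.values())


@dataclass
class ReserveConfig:
    target_fraction: float = 0.30
    spf: float = 100.0
    blm: float = 25000.0
    n_runs: int = 100
    n_proposals: int = 10000
    initial_prob: float = 0.3
    temp_floor_fraction: float = 1e-4  # cooling rate is derived from this
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must be in (0, 1]")
        if self.spf < 0 or self.blm < 0:
            raise ValueError("spf and blm must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ObjectiveComponents:
    cost_term: float
    boundary_term: float
    penalty_term: float

    @property
    def total(self) -> float:
        return self.cost_term + self.boundary_term + self.penalty_term


@dataclass
class ReserveSolution:
    selected: set[int]
    components: ObjectiveComponents
    held: dict[str, float]
    shortfall: dict[str, float]
    selection_frequency: dict[int, int] = field(default_factory=dict)


def build_planning_units(binary: Grid, pu_size_km: float = 25.0,
                         feature: str = "suitable_habitat",
                         cost_mode: str = "area") -> PlanningUnitSet:
    """Overlay a square PU lattice on a binary suitability raster.

    Per-PU amount = summed area (km^2) of suitable cells inside it; cost is
    the PU's land (valid-cell) area, or 1 per PU with ``cost_mode='uniform'``.
    PUs containing no valid cell are dropped. Boundaries are shared edge
    lengths (km) between lattice neighbors; edges facing dropped PUs or the
    outside count as exterior.
    """
    mask = binary.mask
    if not mask.any():
        raise ValueError("raster has no valid cells")
    mid_lat = 0.5 * (binary.y_min + binary.y_max)
    cell_km = binary.cell_size * KM_PER_DEG * max(np.cos(np.radians(mid_lat)), 0.1)
    cells_per_pu = max(1, int(round(pu_size_km / cell_km)))
    if cells_per_pu < 1:
        raise ValueError("pu_size_km must cover at least one cell")
    areas_row = cell_areas_km2(binary)[:, None] * np.ones((1, binary.n_cols))
    suit = (binary.values == 1) * areas_row
    valid_area = mask * areas_row

    n_pu_rows = -(-binary.n_rows // cells_per_pu)
    n_pu_cols = -(-binary.n_cols // cells_per_pu)
    units: list[PlanningUnit] = []
    amounts: dict[int, dict[str, float]] = {}
    pu_at: dict[tuple[int, int], int] = {}
    for pr in range(n_pu_rows):
        for pc in range(n_pu_cols):
            r0, r1 = pr * cells_per_pu, min((pr + 1) * cells_per_pu, binary.n_rows)
            c0, c1 = pc * cells_per_pu, min((pc + 1) * cells_per_pu, binary.n_cols)
            if not mask[r0:r1, c0:c1].any():
                continue
            uid = pr * n_pu_cols + pc
            lon = binary.x_min + (c0 + (c1 - c0) / 2) * binary.cell_size
            lat = binary.y_min + (binary.n_rows - (r0 + (r1 - r0) / 2)) * binary.cell_size
            cost = float(valid_area[r0:r1, c0:c1].sum()) if cost_mode == "area" else 1.0
            units.append(PlanningUnit(id=uid, cost=cost, center=(lon, lat)))
            amounts[uid] = {feature: float(suit[r0:r1, c0:c1].sum())}
            pu_at[(pr, pc)] = uid

    edge_km = cells_per_pu * cell_km
    boundaries: dict[tuple[int, int], float] = {}
    exterior: dict[int, float] = {u.id: 0.0 for u in units}
    for (pr, pc), uid in pu_at.items():
        for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            nb = pu_at.get((pr + dr, pc + dc))
            if nb is None:
                exterior[uid] += edge_km
            elif uid < nb:
                boundaries[(uid, nb)] = edge_km
    for u in units:
        u.exterior_edge = exterior[u.id]
    return PlanningUnitSet(units=units, amounts=amounts, boundaries=boundaries)


def _greedy_cost(pus: PlanningUnitSet, feature: str, target: float) -> float:
    """Cost of meeting `target` by taking best amount/cost units first."""
    rows = [(u.cost, pus.amounts[u.id].get(feature, 0.0)) for u in pus.units]
    rows = [(c, a) for c, a in rows if a > 0]
    rows.sort(key=lambda t: t[0] / t[1])
    got = 0.0
    cost = 0.0
    for c, a in rows:
        if got >= target:
            break
        cost += c
        got += a
    return cost


def _targets_and_scales(pus: PlanningUnitSet,
                        config: ReserveConfig) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for feat in pus.features:
        target = config.target_fraction * pus.total_amount(feat)
        out[feat] = (target, _greedy_cost(pus, feat, target))
    return out


def objective(selected: set[int], pus: PlanningUnitSet, config: ReserveConfig,
              _scales: dict[str, tuple[float, float]] | None = None,
              ) -> ObjectiveComponents:
    """Evaluate the three objective components for a candidate selection."""
    unknown = selected - set(pus.ids)
    if unknown:
        raise KeyError(f"unknown planning unit id(s): {sorted(unknown)}")
    scales = _scales if _scales is not None else _targets_and_scales(pus, config)
    cost_term = sum(u.cost for u in pus.units if u.id in selected)
    boundary = 0.0
    if selected:
        for u in pus.units:
            if u.id in selected:
                boundary += u.exterior_edge
        for (a, b), length in pus.boundaries.items():
            if (a in selected) != (b in selected):
                boundary += length
    penalty = 0.0
    for feat, (target, g_cost) in scales.items():
        if target <= 0:
            continue
        held = sum(pus.amounts[i].get(feat, 0.0) for i in selected)
        shortfall = max(0.0, target - held)
        penalty += config.spf * (shortfall / target) * g_cost
    return ObjectiveComponents(cost_term=cost_term,
                               boundary_term=config.blm * boundary,
                               penalty_term=penalty)


class _AnnealState:
    """Incremental objective bookkeeping for single-unit flips."""

    def __init__(self, pus: PlanningUnitSet, config: ReserveConfig,
                 scales: dict[str, tuple[float, float]], selected: set[int]):
        self.pus = pus
        self.config = config
        self.scales = scales
        self.unit_by_id = {u.id: u for u in pus.units}
        self.neighbors: dict[int, list[tuple[int, float]]] = {i: [] for i in pus.ids}
        for (a, b), length in pus.boundaries.items():
            self.neighbors[a].append((b, length))
            self.neighbors[b].append((a, length))
        self.selected = set(selected)
        self.cost = sum(self.unit_by_id[i].cost for i in self.selected)
        self.held = {f: sum(pus.amounts[i].get(f, 0.0) for i in self.selected)
                     for f in pus.features}
        self.boundary = 0.0
        for i in self.selected:
            self.boundary += self.unit_by_id[i].exterior_edge
        for (a, b), length in pus.boundaries.items():
            if (a in self.selected) != (b in self.selected):
                self.boundary += length

    def _penalty(self, held: dict[str, float]) -> float:
        pen = 0.0
        for f, (target, g_cost) in self.scales.items():
            if target <= 0:
                continue
            short = max(0.0, target - held[f])
            pen += self.config.spf * (short / target) * g_cost
        return pen

    def total(self) -> float:
        return (self.cost + self.config.blm * self.boundary
                + self._penalty(self.held))

    def flip_delta(self, uid: int) -> tuple[float, float, float]:
        """(d_cost, d_boundary, d_penalty) of flipping one unit."""
        u = self.unit_by_id[uid]
        adding = uid not in self.selected
        sgn = 1.0 if adding else -1.0
        d_cost = sgn * u.cost
        d_boundary = sgn * u.exterior_edge
        for nb, length in self.neighbors[uid]:
            if nb in self.selected:
                d_boundary -= sgn * length
            else:
                d_boundary += sgn * length
        pen_old = self._penalty(self.held)
        held_new = dict(self.held)
        for f, a in self.pus.amounts[uid].items():
            held_new[f] = held_new.get(f, 0.0) + sgn * a
        d_pen = self._penalty(held_new) - pen_old
        return d_cost, d_boundary, d_pen

    def apply(self, uid: int) -> None:
        d_cost, d_boundary, _ = self.flip_delta(uid)
        self.cost += d_cost
        self.boundary += d_boundary
        sgn = 1.0 if uid not in self.selected else -1.0
        for f, a in self.pus.amounts[uid].items():
            self.held[f] = self.held.get(f, 0.0) + sgn * a
        if uid in self.selected:
            self.selected.remove(uid)
        else:
            self.selected.add(uid)


def anneal(pus: PlanningUnitSet, config: ReserveConfig, seed: int = 0,
           _scales: dict[str, tuple[float, float]] | None = None) -> ReserveSolution:
    """One simulated-annealing run followed by greedy iterative improvement."""
    if not pus.units:
        raise ValueError("planning unit set is empty")
    rng = np.random.default_rng(seed)
    scales = _scales if _scales is not None else _targets_and_scales(pus, config)
    ids = pus.ids
    init = {i for i in ids if rng.random() < config.initial_prob}
    state = _AnnealState(pus, config, scales, init)

    # initial temperature: median |delta| of random flips
    probes = [abs(sum(state.flip_delta(ids[rng.integers(len(ids))])))
              for _ in range(min(100, 10 * len(ids)))]
    probes_pos = [p for p in probes if p > 0]
    t0 = float(np.median(probes_pos)) if probes_pos else 1.0
    if not np.isfinite(t0) or t0 <= 0:
        t0 = 1.0
    t_floor = t0 * config.temp_floor_fraction
    # geometric decay reaching the floor exactly at the end of the run
    cooling = (config.temp_floor_fraction) ** (1.0 / max(config.n_proposals, 1))
    temp = t0
    for _ in range(config.n_proposals):
        uid = ids[rng.integers(len(ids))]
        delta = sum(state.flip_delta(uid))
        if delta <= 0 or rng.random() < np.exp(-delta / max(temp, t_floor)):
            state.apply(uid)
        temp *= cooling

    # iterative improvement: single flips, then pairwise exchanges (a swap
    # can cross the shortfall-penalty barrier that blocks single flips)
    improved = True
    while improved:
        improved = False
        for uid in ids:
            if sum(state.flip_delta(uid)) < -1e-12:
                state.apply(uid)
                improved = True
        if not improved:
            for a in ids:
                d_a = sum(state.flip_delta(a))
                state.apply(a)
                found = False
                for b in ids:
                    if b == a:
                        continue
                    if d_a + sum(state.flip_delta(b)) < -1e-12:
                        state.apply(b)
                        found = improved = True
                        break
                if not found:
                    state.apply(a)  # revert
                if found:
                    break

    comp = objective(state.selected, pus, config, _scales=scales)
    held = {f: sum(pus.amounts[i].get(f, 0.0) for i in state.selected)
            for f in pus.features}
    short = {f: max(0.0, scales[f][0] - held[f]) for f in pus.features}
    return ReserveSolution(selected=set(state.selected), components=comp,
                           held=held, shortfall=short)


def run_repeats(pus: PlanningUnitSet, config: ReserveConfig) -> ReserveSolution:
    """n_runs independent annealing runs: best solution + selection frequencies.

    Best = lowest total, ties broken by fewer units then lexicographic id
    order of the sorted selection.
    """
    scales = _targets_and_scales(pus, config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31, size=config.n_runs)
    freq: dict[int, int] = {i: 0 for i in pus.ids}
    best: ReserveSolution | None = None
    for s in seeds:
        sol = anneal(pus, config, seed=int(s), _scales=scales)
        for i in sol.selected:
            freq[i] += 1
        if best is None or _solution_key(sol) < _solution_key(best):
            best = sol
    assert best is not None
    best.selection_frequency = freq
    return best


def _solution_key(sol: ReserveSolution) -> tuple:
    return (sol.components.total, len(sol.selected), tuple(sorted(sol.selected)))
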