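"""Event-driven simulation of foraging birds dispersing seeds.

Time runs in continuous minutes per bird. A bird is introduced at a random
cell and repeats: perch (Gamma residence time), possibly eat fruits (ZIP
truncated at availability, species assigned by availability), then either
leave the plot (logistic in edge distance) or fly in a straight line at
constant speed to a destination cell drawn from the movement model. Every
ingested fruit gets an independent Gamma gut-passage-time draw shared by the
seeds of that fruit; a seed is deposited wherever the bird is when its clock
runs out — in the perch cell, at the along-path point of a flight, or beyond
the plot boundary (EXPORTED) on the exit flight.

The ``distance_only`` mode replaces the landscape-responsive destination
choice by resampling observed step lengths with a uniform random bearing,
clipped to the plot; the bird exits when the displaced point falls outside.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import SpeciesTraits, assign_fruit_species
from .landscape import Landscape
from .movement import MovementEngine, Trajectory, TrajectoryStep

__all__ = [
    "SimulationConfig",
    "SeedRecord",
    "CohortResult",
    "simulate_bird",
    "run_cohort",
    "displacement_of",
    "EXPORTED",
]

EXPORTED = -1  # dep_cell sentinel for seeds carried beyond the plot boundary
EXPORT_EPS_M = 1.0  # "just outside" the boundary: 1 m beyond the crossing point


@dataclass
class SimulationConfig:
    """Run protocol. Defaults follow the study design this package emulates:

    5,000 bird sequences per replicate, 30 replicates, the first 5 moves of
    each bird discarded as burn-in, and straight-line flight at 6 m/s.
    """

    n_birds: int = 5000
    n_replicates: int = 30
    burn_in_moves: int = 5
    flight_speed: float = 6.0  # m/s
    seed: int = 0
    mode: str = "full"  # "full" | "distance_only"
    empirical_moves: np.ndarray | None = None  # step lengths (m) for distance_only
    max_moves: int = 100_000  # safety valve

    def __post_init__(self) -> None:
        if self.flight_speed <= 0:
            raise ValueError("flight_speed must be positive")
        if self.burn_in_moves < 0:
            raise ValueError("burn_in_moves must be >= 0")
        if self.mode not in ("full", "distance_only"):
            raise ValueError("mode must be 'full' or 'distance_only'")

    def to_dict(self) -> dict:
        d = {
            "n_birds": self.n_birds,
            "n_replicates": self.n_replicates,
            "burn_in_moves": self.burn_in_moves,
            "flight_speed": self.flight_speed,
            "seed": self.seed,
            "mode": self.mode,
            "max_moves": self.max_moves,
            "n_empirical_moves": None if self.empirical_moves is None else int(len(self.empirical_moves)),
        }
        return d


@dataclass
class SeedRecord:
    """One dispersed seed, from ingestion to deposition (or export)."""

    plant_species: str
    bird_species: str
    origin_cell: int
    dep_cell: int  # EXPORTED (-1) when carried beyond the boundary
    x: float
    y: float
    displacement: float
    ingest_time: float
    dep_time: float
    burn_in: bool

    @property
    def exported(self) -> bool:
        return self.dep_cell == EXPORTED


def displacement_of(
    origin_cell: int, dep_cell: int, dep_xy: tuple[float, float], landscape: Landscape
) -> float:
    """Dispersal distance convention.

    Within the plot: Euclidean distance between the origin and deposition cell
    centroids. Exported: distance from the origin centroid to the boundary
    crossing point, plus 1 m ("just outside the nearest edge").
    """
    ox, oy = landscape.centroids[origin_cell]
    if dep_cell == EXPORTED:
        return math.hypot(dep_xy[0] - ox, dep_xy[1] - oy) + EXPORT_EPS_M
    dx, dy = landscape.centroids[dep_cell]
    return math.hypot(dx - ox, dy - oy)


def _nearest_boundary_point(x: float, y: float, bounds) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = bounds
    cands = [(x - xmin, (xmin, y)), (xmax - x, (xmax, y)),
             (y - ymin, (x, ymin)), (ymax - y, (x, ymax))]
    return min(cands)[1]


def _boundary_crossing(x0, y0, x1, y1, bounds) -> tuple[float, float, float]:
    """First intersection of segment (x0,y0)->(x1,y1) with the plot boundary.

    Returns (t, xc, yc) with t in (0, 1] the fraction of the segment length.
    Assumes (x0,y0) inside and (x1,y1) outside or on the boundary.
    """
    xmin, ymin, xmax, ymax = bounds
    t = 1.0
    dx, dy = x1 - x0, y1 - y0
    for lo, hi, p0, dp in ((xmin, xmax, x0, dx), (ymin, ymax, y0, dy)):
        if dp > 0 and p0 + dp > hi:
            t = min(t, (hi - p0) / dp)
        elif dp < 0 and p0 + dp < lo:
            t = min(t, (lo - p0) / dp)
    return t, x0 + t * dx, y0 + t * dy


class _Gut:
    """Min-heap of seeds in transit, keyed by defecation due time."""

    def __init__(self) -> None:
        self._h: list[tuple[float, int, int, float, bool]] = []
        self._n = 0

    def push(self, due, plant_idx, origin_cell, ingest_time, burn_in):
        heapq.heappush(self._h, (due, plant_idx, origin_cell, ingest_time, burn_in))
        self._n += 1

    def pop_due(self, until: float):
        while self._h and self._h[0][0] <= until:
            yield heapq.heappop(self._h)

    def drain(self):
        while self._h:
            yield heapq.heappop(self._h)

    def __len__(self) -> int:
        return len(self._h)


def simulate_bird(
    traits: SpeciesTraits,
    landscape: Landscape,
    config: SimulationConfig,
    rng: np.random.Generator,
    engine: MovementEngine | None = None,
    record_trajectory: bool = False,
    censor_prob: float = 0.0,
    diet_out: np.ndarray | None = None,
    move_log: list | None = None,
):
    """Simulate one bird from introduction until it leaves the plot.

    Returns (trajectory_or_None, list_of_SeedRecord, n_moves). ``censor_prob``
    ends the *observation* (terminal "lost") at each decision point with that
    probability — used when emulating field tracks. ``diet_out`` accumulates
    fruits eaten per plant species in place; ``move_log`` collects step
    lengths in metres.
    """
    if config.mode == "full" and engine is None:
        engine = MovementEngine(landscape, traits.movement)
    if config.mode == "distance_only" and config.empirical_moves is None:
        raise ValueError("distance_only mode requires an empirical_moves pool")

    n = landscape.n_cells
    plants = landscape.plant_species
    speed = config.flight_speed * 60.0  # m/min
    cur = int(rng.integers(n))
    x, y = landscape.centroids[cur]
    clock = 0.0
    moves = 0
    gut = _Gut()
    records: list[SeedRecord] = []
    steps: list[TrajectoryStep] = [] if record_trajectory else None
    terminal = "lost"

    def deposit_at(seed, dep_cell, px, py):
        due, j, origin, t_in, burn = seed
        records.append(
            SeedRecord(
                plant_species=plants[j],
                bird_species=traits.name,
                origin_cell=origin,
                dep_cell=dep_cell,
                x=px,
                y=py,
                displacement=displacement_of(origin, dep_cell, (px, py), landscape),
                ingest_time=t_in,
                dep_time=due,
                burn_in=burn,
            )
        )

    while moves < config.max_moves:
        # ---- perch & forage
        perch = float(rng.gamma(traits.perch.shape, traits.perch.scale))
        avail = landscape.total_fruits(cur)
        eaten_by: dict[str, int] = {}
        if avail > 0 and rng.random() >= traits.consumption.pi_zero:
            eaten = int(min(rng.poisson(traits.consumption.lam), avail))
            if eaten > 0:
                per_sp = assign_fruit_species(eaten, landscape.fruits[cur], rng)
                burn = moves < config.burn_in_moves
                for j, m in enumerate(per_sp):
                    if m == 0:
                        continue
                    landscape.deplete(cur, j, int(m))
                    eaten_by[plants[j]] = int(m)
                    if diet_out is not None:
                        diet_out[j] += m
                    nseeds = traits.seeds_per_fruit(plants[j])
                    gpts = rng.gamma(traits.gpt_shape, traits.gpt_scale, size=int(m))
                    for g in gpts:
                        for _ in range(nseeds):
                            gut.push(clock + g, j, cur, clock, burn)
        if record_trajectory:
            steps.append(TrajectoryStep(cell_id=cur, perch_min=perch, eaten=eaten_by))

        # ---- deposit seeds that come due while perched
        end = clock + perch
        for seed in gut.pop_due(end):
            deposit_at(seed, cur, x, y)
        clock = end

        # ---- observation censoring (field-track emulation)
        if censor_prob > 0 and rng.random() < censor_prob:
            terminal = "lost"
            break

        # ---- movement decision
        leaving = False
        if config.mode == "full":
            if rng.random() < engine.p_leave_by_cell[cur]:
                ex, ey = _nearest_boundary_point(x, y, landscape.bounds)
                leaving = True
                tx, ty, seg = ex, ey, math.hypot(ex - x, ey - y)
            else:
                k = engine.k_row(cur)
                dest = int(np.searchsorted(np.cumsum(k), rng.random()))
                dest = min(dest, n - 1)
        else:
            d = float(config.empirical_moves[rng.integers(len(config.empirical_moves))])
            theta = rng.uniform(0, 2 * math.pi)
            px, py = x + d * math.cos(theta), y + d * math.sin(theta)
            if not landscape.contains(px, py):
                t, ex, ey = _boundary_crossing(x, y, px, py, landscape.bounds)
                leaving = True
                tx, ty, seg = ex, ey, t * d
            else:
                dest = landscape.cell_of_point(px, py)

        if leaving:
            # fly toward the boundary; seeds due en route drop inside,
            # the rest are carried out and marked EXPORTED at the crossing
            t_cross = seg / speed if speed > 0 else 0.0
            for seed in gut.pop_due(clock + t_cross):
                frac = 0.0 if t_cross == 0 else (seed[0] - clock) / t_cross
                px, py = x + frac * (tx - x), y + frac * (ty - y)
                deposit_at(seed, landscape.cell_of_point(px, py), px, py)
            for seed in gut.drain():
                deposit_at(seed, EXPORTED, tx, ty)
            terminal = "left_plot"
            break

        # ---- fly to the destination cell
        dx_, dy_ = landscape.centroids[dest]
        seg = math.hypot(dx_ - x, dy_ - y)
        t_fly = seg / speed
        for seed in gut.pop_due(clock + t_fly):
            frac = 0.0 if t_fly == 0 else (seed[0] - clock) / t_fly
            px, py = x + frac * (dx_ - x), y + frac * (dy_ - y)
            deposit_at(seed, landscape.cell_of_point(px, py), px, py)
        if move_log is not None:
            move_log.append(seg)
        clock += t_fly
        x, y, cur = dx_, dy_, int(dest)
        moves += 1
    else:
        # safety valve: drop remaining gut contents at the current cell
        for seed in gut.drain():
            deposit_at(seed, cur, x, y)

    traj = Trajectory(traits.name, steps, terminal) if record_trajectory else None
    return traj, records, moves


@dataclass
class CohortResult:
    """Outputs of one multi-replicate simulation run."""

    seed_records: pd.DataFrame  # one row per seed, with a replicate column
    diet: pd.DataFrame  # replicate x bird_species x plant_species fruit tallies
    birds: pd.DataFrame  # replicate x bird_species introduction counts
    move_lengths: pd.DataFrame  # replicate, bird_species, step length (m)
    fruits_eaten_total: int
    fruits_initial_total: int
    fruits_final_total: int
    config: SimulationConfig


def records_to_frame(records, replicate: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "plant_species": [r.plant_species for r in records],
            "bird_species": [r.bird_species for r in records],
            "origin_cell": np.asarray([r.origin_cell for r in records], dtype=np.int64),
            "dep_cell": np.asarray([r.dep_cell for r in records], dtype=np.int64),
            "exported": np.asarray([r.exported for r in records], dtype=bool),
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "displacement_m": [r.displacement for r in records],
            "burn_in": np.asarray([r.burn_in for r in records], dtype=bool),
        }
    )
    if replicate is not None:
        df.insert(0, "replicate", replicate)
    return df


def run_cohort(
    assemblage: list[SpeciesTraits],
    landscape: Landscape,
    config: SimulationConfig,
) -> CohortResult:
    """Run the full protocol: sequential birds, multiple replicates.

    Bird species are drawn by relative abundance. Fruit depletion carries
    across birds within a replicate; the landscape resets between replicates.
    Each replicate uses an independently derived child seed of ``config.seed``.
    """
    if not assemblage:
        raise ValueError("assemblage is empty")
    ab = np.asarray([t.relative_abundance for t in assemblage], dtype=float)
    if abs(ab.sum() - 1.0) > 1e-6:
        raise ValueError("relative abundances must sum to 1")
    ab = ab / ab.sum()

    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.n_replicates)
    engines = None
    if config.mode == "full":
        engines = [MovementEngine(landscape, t.movement) for t in assemblage]

    n_plants = len(landscape.plant_species)
    rec_frames, diet_rows, move_rows, bird_rows = [], [], [], []
    fruits_initial = 0
    eaten_total = 0
    final_total = 0
    for rep, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        landscape.reset_fruits()
        rep_initial = landscape.total_fruits()
        fruits_initial += rep_initial
        diet = np.zeros((len(assemblage), n_plants), dtype=np.int64)
        moves_log: list[list[float]] = [[] for _ in assemblage]
        rep_records = []
        species_idx = rng.choice(len(assemblage), size=config.n_birds, p=ab)
        for si, t in enumerate(assemblage):
            bird_rows.append(
                {"replicate": rep, "bird_species": t.name,
                 "n_birds": int(np.count_nonzero(species_idx == si))}
            )
        for si in species_idx:
            _, recs, _ = simulate_bird(
                assemblage[si],
                landscape,
                config,
                rng,
                engine=None if engines is None else engines[si],
                diet_out=diet[si],
                move_log=moves_log[si],
            )
            rep_records.extend(recs)
        rep_final = landscape.total_fruits()
        final_total += rep_final
        eaten_total += rep_initial - rep_final
        rec_frames.append(records_to_frame(rep_records, replicate=rep))
        for si, t in enumerate(assemblage):
            for j, sp in enumerate(landscape.plant_species):
                diet_rows.append(
                    {"replicate": rep, "bird_species": t.name,
                     "plant_species": sp, "fruits_eaten": int(diet[si, j])}
                )
            if moves_log[si]:
                move_rows.append(
                    pd.DataFrame({"replicate": rep, "bird_species": t.name,
                                  "distance_m": moves_log[si]})
                )
    landscape.reset_fruits()
    return CohortResult(
        seed_records=pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame(),
        diet=pd.DataFrame(diet_rows),
        birds=pd.DataFrame(bird_rows),
        move_lengths=(pd.concat(move_rows, ignore_index=True)
                      if move_rows else pd.DataFrame(columns=["replicate", "bird_species", "distance_m"])),
        fruits_eaten_total=int(eaten_total),
        fruits_initial_total=int(fruits_initial),
        fruits_final_total=int(final_total),
        config=config,
    )
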