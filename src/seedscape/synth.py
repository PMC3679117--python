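"""Synthetic landscapes, assemblages and observation data with known truth.

These generators stand in for the Cantabrian field data: a 400 x 440 m plot of
440 cells (22 rows x 20 cols of 20 m cells) with spatially autocorrelated
forest cover ranging from dense sectors to open ground, and clumped
multi-species fruit crops realized from FAI classes. Observation tracks are
simulated from the full foraging model itself (no parallel implementation)
with an extra per-step "lost" censoring to emulate short field tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .landscape import FruitCrop, Landscape, build_landscape
from .movement import MovementParams, Trajectory, TrajectoryStep
from .simulate import SimulationConfig, simulate_bird

__all__ = [
    "CropSpec",
    "SyntheticLandscapeSpec",
    "generate_cover",
    "generate_crops",
    "generate_landscape",
    "generate_observations",
    "simulate_choice_sequences",
]


@dataclass
class CropSpec:
    """Fruiting-tree layout for one plant species.

    ``clustering`` is the mean number of trees per cluster parent: 0 (or 1)
    places trees completely at random (CSR); larger values produce a
    parent-offspring (Thomas) clustered pattern with Gaussian scatter of sd
    ``cluster_sd_m`` around each parent.
    """

    species: str
    n_trees: int
    clustering: float = 0.0
    cluster_sd_m: float = 30.0
    fai_probs: tuple = (0.05, 0.15, 0.30, 0.30, 0.15, 0.05)


@dataclass
class SyntheticLandscapeSpec:
    rows: int = 22
    cols: int = 20
    cell_size: float = 20.0
    cover_mean: float = 0.45
    cover_sd: float = 0.35
    cover_corr_cells: float = 2.0  # autocorrelation length in cells
    crops: list[CropSpec] = field(default_factory=list)
    fai5_cap: int = 100_000


def generate_cover(spec: SyntheticLandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially autocorrelated cover fractions in [0, 1], one per cell.

    Smoothed Gaussian noise, re-standardized after filtering so the clip to
    [0, 1] produces both saturated (fully covered) and zero-cover cells when
    cover_sd is large.
    """
    if spec.cover_sd == 0:
        return np.full(spec.rows * spec.cols, np.clip(spec.cover_mean, 0, 1))
    z = rng.standard_normal((spec.rows, spec.cols))
    z = gaussian_filter(z, sigma=spec.cover_corr_cells, mode="reflect")
    z = (z - z.mean()) / z.std()
    frac = np.clip(spec.cover_mean + spec.cover_sd * z, 0.0, 1.0)
    return frac.ravel()


def generate_crops(
    spec: SyntheticLandscapeSpec, rng: np.random.Generator
) -> list[FruitCrop]:
    """Place fruiting trees (CSR or Thomas-clustered) and assign FAI classes."""
    xmax = spec.cols * spec.cell_size
    ymax = spec.rows * spec.cell_size
    crops: list[FruitCrop] = []
    tree_id = 0
    for cs in spec.crops:
        if cs.clustering <= 1:
            xs = rng.uniform(0, xmax, cs.n_trees)
            ys = rng.uniform(0, ymax, cs.n_trees)
        else:
            n_parents = max(1, int(round(cs.n_trees / cs.clustering)))
            px = rng.uniform(0, xmax, n_parents)
            py = rng.uniform(0, ymax, n_parents)
            parent = rng.integers(n_parents, size=cs.n_trees)
            xs = px[parent] + rng.normal(0, cs.cluster_sd_m, cs.n_trees)
            ys = py[parent] + rng.normal(0, cs.cluster_sd_m, cs.n_trees)
            # reflect strays back into the plot
            xs = np.abs(xs) % (2 * xmax)
            xs = np.where(xs > xmax, 2 * xmax - xs, xs)
            ys = np.abs(ys) % (2 * ymax)
            ys = np.where(ys > ymax, 2 * ymax - ys, ys)
        fai = rng.choice(6, size=cs.n_trees, p=np.asarray(cs.fai_probs))
        for x, y, f in zip(xs, ys, fai):
            col = min(spec.cols - 1, int(x // spec.cell_size))
            row = min(spec.rows - 1, int(y // spec.cell_size))
            crops.append(
                FruitCrop(tree_id=tree_id, species=cs.species,
                          cell_id=row * spec.cols + col, fai=int(f))
            )
            tree_id += 1
    return crops


def generate_landscape(
    spec: SyntheticLandscapeSpec, rng: np.random.Generator
) -> tuple[Landscape, list[FruitCrop]]:
    """Full synthetic landscape: cover field plus realized fruit crops."""
    cover = generate_cover(spec, rng) * spec.cell_size**2
    crops = generate_crops(spec, rng)
    plant_species = [cs.species for cs in spec.crops]
    ls = build_landscape(
        spec.rows, spec.cols, spec.cell_size, cover, crops,
        plant_species=plant_species, rng=rng, fai5_cap=spec.fai5_cap,
    )
    return ls, crops


def generate_observations(
    landscape: Landscape,
    assemblage,
    n_tracks: int,
    rng: np.random.Generator,
    censor_prob: float = 0.35,
    flight_speed: float = 6.0,
    max_steps: int = 100_000,
) -> list[Trajectory]:
    """Field-like tracks simulated from the full model with random censoring.

    Each track follows one bird until it exits the plot or is "lost" (an
    independent per-step censoring), yielding short tracks like real
    follow-observations. Fruit state is reset after every track so the
    fitted (static-landscape) likelihood matches the generating process.
    """
    ab = np.asarray([t.relative_abundance for t in assemblage], dtype=float)
    ab = ab / ab.sum()
    cfg = SimulationConfig(
        n_birds=1, n_replicates=1, burn_in_moves=0,
        flight_speed=flight_speed, mode="full", max_moves=max_steps,
    )
    from .movement import MovementEngine

    engines = [MovementEngine(landscape, t.movement) for t in assemblage]
    out = []
    for _ in range(n_tracks):
        si = int(rng.choice(len(assemblage), p=ab))
        traj, _, _ = simulate_bird(
            assemblage[si], landscape, cfg, rng,
            engine=engines[si], record_trajectory=True, censor_prob=censor_prob,
        )
        landscape.reset_fruits()
        out.append(traj)
    return out


def simulate_choice_sequences(
    landscape: Landscape,
    params: MovementParams,
    n_events: int,
    rng: np.random.Generator,
    species: str = "sim",
) -> list[Trajectory]:
    """Pure movement-decision data: exactly ``n_events`` decisions.

    Birds start at random cells and make leave/move decisions from the static
    fruit state (no foraging, no depletion); each exit ends a track and a new
    bird starts. Fast path for likelihood-recovery and model-selection
    experiments.
    """
    from .movement import MovementEngine

    engine = MovementEngine(landscape, params)
    K = engine.k_matrix()
    cumK = np.cumsum(K, axis=1)
    p_leave = engine.p_leave_by_cell
    n = landscape.n_cells
    trajectories = []
    cells = [int(rng.integers(n))]
    events = 0
    while events < n_events:
        cur = cells[-1]
        if rng.random() < p_leave[cur]:
            trajectories.append(
                Trajectory(species, [TrajectoryStep(c) for c in cells], "left_plot")
            )
            cells = [int(rng.integers(n))]
        else:
            dest = int(np.searchsorted(cumK[cur], rng.random()))
            cells.append(min(dest, n - 1))
        events += 1
    if len(cells) > 1:
        trajectories.append(
            Trajectory(species, [TrajectoryStep(c) for c in cells], "lost")
        )
    return trajectories
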