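"""Gridded landscape: forest cover and multi-species fruit crops on square cells.

The plot is a rectangle of ``rows x cols`` square cells of side ``cell_size``
metres. The coordinate origin sits at the lower-left corner of the plot, cell
ids are 0-based row-major (id = row * cols + col) and the centroid of the cell
in row r, column c is ((c + 0.5) s, (r + 0.5) s). All distances between
relocations are centroid-to-centroid, so a within-cell move has distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Cell",
    "FruitCrop",
    "Landscape",
    "build_landscape",
    "fai_to_crop",
    "FAI_BOUNDS",
]

# FAI (Fruiting Abundance Index) class -> (low, high) inclusive fruit-count
# interval. Class 5 is open-ended; its high bound is a configurable cap.
FAI_BOUNDS = {
    0: (0, 0),
    1: (1, 10),
    2: (11, 100),
    3: (101, 1000),
    4: (1001, 10000),
    5: (10001, None),
}
DEFAULT_FAI5_CAP = 100_000


@dataclass
class FruitCrop:
    """One fruiting tree: an FAI class and (optionally) its realized crop."""

    tree_id: int
    species: str
    cell_id: int
    fai: int
    crop: int | None = None

    def __post_init__(self) -> None:
        if self.fai not in FAI_BOUNDS:
            raise ValueError(f"FAI class must be in 0..5, got {self.fai}")
        if self.crop is not None:
            lo, hi = FAI_BOUNDS[self.fai]
            if self.crop < lo or (hi is not None and self.crop > hi):
                raise ValueError(
                    f"crop {self.crop} outside FAI class {self.fai} interval"
                )


def fai_to_crop(fai: int, rng: np.random.Generator, cap: int = DEFAULT_FAI5_CAP) -> int:
    """Realize an integer fruit crop from an FAI class.

    Class 0 is exactly 0 and class 1 is uniform on [1, 10]. Classes 2-5 span
    orders of magnitude, so the draw is log-uniform within the class interval
    (class 5 between 10001 and ``cap``), keeping the class semantics of
    order-of-magnitude crop sizes without favouring the top of each interval.
    """
    if fai not in FAI_BOUNDS:
        raise ValueError(f"FAI class must be in 0..5, got {fai}")
    lo, hi = FAI_BOUNDS[fai]
    if fai == 0:
        return 0
    if fai == 1:
        return int(rng.integers(lo, hi + 1))
    if hi is None:
        hi = cap
    u = rng.uniform(np.log(lo), np.log(hi + 1))
    return int(min(hi, max(lo, int(np.exp(u)))))


@dataclass
class Cell:
    """Read-only view of one landscape cell."""

    id: int
    centroid: tuple[float, float]
    cover: float
    fruits: dict[str, int]


class Landscape:
    """The study plot: geometry, cover and mutable per-cell fruit counts.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions; the plot spans ``cols*cell_size`` m in x and
        ``rows*cell_size`` m in y.
    cell_size : float
        Side of the square cells, metres.
    cover_m2 : array of shape (n_cells,)
        Forest cover per cell in m^2, within [0, cell_size**2].
    plant_species : sequence of str
        Plant (fruit) species tracked per cell.
    fruits : int array of shape (n_cells, n_plants)
        Fruit counts per cell and plant species; mutated by :meth:`deplete`.
    """

    def __init__(self, rows, cols, cell_size, cover_m2, plant_species, fruits):
        self.rows = int(rows)
        self.cols = int(cols)
        self.cell_size = float(cell_size)
        self.n_cells = self.rows * self.cols
        cover_m2 = np.asarray(cover_m2, dtype=float)
        if cover_m2.shape != (self.n_cells,):
            raise ValueError(
                f"cover_m2 must have length {self.n_cells}, got {cover_m2.shape}"
            )
        area = self.cell_size**2
        if np.any(cover_m2 < 0) or np.any(cover_m2 > area + 1e-9):
            raise ValueError("cover must lie in [0, cell_area]")
        self.cover_m2 = cover_m2
        self.plant_species = list(plant_species)
        fruits = np.asarray(fruits, dtype=np.int64)
        if fruits.shape != (self.n_cells, len(self.plant_species)):
            raise ValueError("fruits must have shape (n_cells, n_plant_species)")
        if np.any(fruits < 0):
            raise ValueError("fruit counts must be non-negative")
        self.fruits = fruits.copy()
        self._initial_fruits = fruits.copy()

        s = self.cell_size
        r, c = np.divmod(np.arange(self.n_cells), self.cols)
        self.row_of = r
        self.col_of = c
        self.centroids = np.column_stack(((c + 0.5) * s, (r + 0.5) * s))
        self.bounds = (0.0, 0.0, self.cols * s, self.rows * s)
        d = self.centroids[:, None, :] - self.centroids[None, :, :]
        self.distance_matrix = np.sqrt((d**2).sum(-1))
        x, y = self.centroids[:, 0], self.centroids[:, 1]
        xmax, ymax = self.bounds[2], self.bounds[3]
        self.edge_distance = np.minimum.reduce([x, xmax - x, y, ymax - y])

    # -- geometry ----------------------------------------------------------
    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    @property
    def cover_fraction(self) -> np.ndarray:
        return self.cover_m2 / self.cell_area

    def cell_of_point(self, x: float, y: float) -> int:
        """Id of the cell containing (x, y); clips to the plot boundary."""
        c = min(self.cols - 1, max(0, int(x // self.cell_size)))
        r = min(self.rows - 1, max(0, int(y // self.cell_size)))
        return r * self.cols + c

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin <= y < ymax

    def cell(self, cell_id: int) -> Cell:
        return Cell(
            id=cell_id,
            centroid=tuple(self.centroids[cell_id]),
            cover=float(self.cover_m2[cell_id]),
            fruits={
                sp: int(self.fruits[cell_id, j])
                for j, sp in enumerate(self.plant_species)
            },
        )

    # -- fruits ------------------------------------------------------------
    def total_fruits(self, cell_id: int | None = None) -> int:
        """Total fruit count in one cell, or over the whole landscape."""
        if cell_id is None:
            return int(self.fruits.sum())
        return int(self.fruits[cell_id].sum())

    def fruit_totals(self) -> np.ndarray:
        """Per-cell totals across plant species (length n_cells)."""
        return self.fruits.sum(axis=1)

    def deplete(self, cell_id: int, species: str | int, n_eaten: int) -> "Landscape":
        """Remove ``n_eaten`` fruits of one species from one cell, in place.

        Depleting below zero indicates a simulator bug and raises.
        """
        j = species if isinstance(species, (int, np.integer)) else self.plant_species.index(species)
        if n_eaten < 0:
            raise ValueError("n_eaten must be >= 0")
        if n_eaten > self.fruits[cell_id, j]:
            raise RuntimeError(
                f"depletion below zero in cell {cell_id}: "
                f"{n_eaten} > {self.fruits[cell_id, j]}"
            )
        self.fruits[cell_id, j] -= n_eaten
        return self

    def reset_fruits(self) -> None:
        """Restore the fruit state present at construction."""
        self.fruits = self._initial_fruits.copy()

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "row": self.row_of,
                "col": self.col_of,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "cover_m2": self.cover_m2,
            }
        )
        for j, sp in enumerate(self.plant_species):
            df[f"fruits_{sp}"] = self.fruits[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, cell_size: float | None = None) -> "Landscape":
        df = pd.read_csv(path, float_precision="round_trip").sort_values(
            "cell_id"
        ).reset_index(drop=True)
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        if cell_size is None:
            # centroid of cell (0,0) is at (s/2, s/2)
            cell_size = 2.0 * float(df.loc[df["cell_id"] == 0, "x"].iloc[0])
        fruit_cols = [c for c in df.columns if c.startswith("fruits_")]
        species = [c[len("fruits_"):] for c in fruit_cols]
        return cls(
            rows,
            cols,
            cell_size,
            df["cover_m2"].to_numpy(),
            species,
            df[fruit_cols].to_numpy(dtype=np.int64),
        )


def build_landscape(
    rows: int,
    cols: int,
    cell_size: float,
    cover_m2,
    crops: list[FruitCrop] | None = None,
    plant_species: list[str] | None = None,
    rng: np.random.Generator | None = None,
    fai5_cap: int = DEFAULT_FAI5_CAP,
) -> Landscape:
    """Assemble a :class:`Landscape` from a grid spec, cover map and crops.

    Crops without a realized ``crop`` count are realized with
    :func:`fai_to_crop` (an ``rng`` is then required). Per-cell fruit counts
    are the sums of crop counts by species.
    """
    crops = crops or []
    if plant_species is None:
        plant_species = sorted({c.species for c in crops})
    n_cells = rows * cols
    fruits = np.zeros((n_cells, len(plant_species)), dtype=np.int64)
    sp_index = {sp: j for j, sp in enumerate(plant_species)}
    for crop in crops:
        if not (0 <= crop.cell_id < n_cells):
            raise ValueError(f"crop {crop.tree_id} references invalid cell {crop.cell_id}")
        count = crop.crop
        if count is None:
            if rng is None:
                raise ValueError("rng required to realize crops from FAI classes")
            count = fai_to_crop(crop.fai, rng, cap=fai5_cap)
            crop.crop = count
        fruits[crop.cell_id, sp_index[crop.species]] += count
    return Landscape(rows, cols, cell_size, cover_m2, plant_species, fruits)


def crops_to_frame(crops: list[FruitCrop]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tree_id": [c.tree_id for c in crops],
            "species": [c.species for c in crops],
            "cell_id": [c.cell_id for c in crops],
            "fai": [c.fai for c in crops],
            "crop": [c.crop for c in crops],
        }
    )


def crops_from_frame(df: pd.DataFrame) -> list[FruitCrop]:
    has_crop = "crop" in df.columns
    return [
        FruitCrop(
            tree_id=int(r.tree_id),
            species=str(r.species),
            cell_id=int(r.cell_id),
            fai=int(r.fai),
            crop=(int(r.crop) if has_crop and pd.notna(r.crop) else None),
        )
        for r in df.itertuples()
    ]
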