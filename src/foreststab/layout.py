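"""Plot and quadrat geometry, sampling-design generators, and census-table schemas.

Coordinates are plot-local metres with the origin at the southwest corner.
Quadrats are half-open boxes ``[x0, x0+s) x [y0, y0+s)`` so every interior
stem belongs to exactly one quadrat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column names for a stem-level census table.
CENSUS_COLUMNS = ["stem_id", "species_id", "x", "y", "census", "dbh", "height", "status"]

#: Radial offsets (m) of cluster soil samples from their parent point.
CLUSTER_DISTANCES = (0.16, 0.33, 0.61, 1.03, 2.66, 6.22, 7.67)

#: Adult/seedling size threshold: stems with DBH >= 1 cm are adults.
ADULT_DBH_CM = 1.0


@dataclass(frozen=True)
class QuadratLayout:
    """Regular quadrat grid over a rectangular plot.

    Parameters
    ----------
    plot_id : str
        Plot label.
    origin : tuple of float
        Southwest corner ``(x, y)`` in metres.
    width, height : float
        Plot extent in metres.
    quadrat_size : float
        Side length of the square quadrats.
    subplot_size : float, optional
        Side of an optional coarser subplot grid (e.g. 10 m subplots holding
        1 m seedling quadrats).
    """

    plot_id: str
    origin: tuple[float, float]
    width: float
    height: float
    quadrat_size: float
    subplot_size: float | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0 or self.quadrat_size <= 0:
            raise ValueError("plot dimensions and quadrat size must be positive")

    @property
    def ncol(self) -> int:
        return int(np.floor(self.width / self.quadrat_size))

    @property
    def nrow(self) -> int:
        return int(np.floor(self.height / self.quadrat_size))

    @property
    def n_quadrats(self) -> int:
        return self.nrow * self.ncol

    def quadrat_index(self, x, y) -> np.ndarray:
        """Map coordinates to quadrat indices (row-major); -1 outside the grid."""
        x = np.asarray(x, dtype=float) - self.origin[0]
        y = np.asarray(y, dtype=float) - self.origin[1]
        col = np.floor(x / self.quadrat_size).astype(int)
        row = np.floor(y / self.quadrat_size).astype(int)
        idx = row * self.ncol + col
        bad = (col < 0) | (col >= self.ncol) | (row < 0) | (row >= self.nrow)
        return np.where(bad, -1, idx)

    def quadrat_centers(self) -> np.ndarray:
        """(n_quadrats, 2) array of quadrat centre coordinates, row-major order."""
        s = self.quadrat_size
        cols = (np.arange(self.ncol) + 0.5) * s + self.origin[0]
        rows = (np.arange(self.nrow) + 0.5) * s + self.origin[1]
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def grid_shape(self) -> tuple[int, int]:
        return (self.nrow, self.ncol)

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        return (x >= x0) & (x < x0 + self.width) & (y >= y0) & (y < y0 + self.height)

    def to_dict(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "origin": list(self.origin),
            "width": self.width,
            "height": self.height,
            "quadrat_size": self.quadrat_size,
            "subplot_size": self.subplot_size,
            "nrow": self.nrow,
            "ncol": self.ncol,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadratLayout":
        return cls(
            plot_id=d["plot_id"],
            origin=tuple(d["origin"]),
            width=d["width"],
            height=d["height"],
            quadrat_size=d["quadrat_size"],
            subplot_size=d.get("subplot_size"),
        )


def adult_plot_layout(width: float = 500.0, height: float = 1000.0,
                      quadrat_size: float = 20.0) -> QuadratLayout:
    """Default 50-ha adult plot divided into non-overlapping 20 m quadrats."""
    return QuadratLayout("adult-50ha", (0.0, 0.0), width, height, quadrat_size)


def checkerboard_selected(nrow: int, ncol: int, phase: int = 0) -> np.ndarray:
    """Boolean (nrow, ncol) mask selecting alternating cells, (row+col) % 2 == phase."""
    r, c = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    return (r + c) % 2 == phase


def build_seedling_layout(n_plots: int = 6, subplot_grid: int = 10,
                          quadrats_per_selected_subplot: int = 4,
                          subplot_size: float = 10.0, quadrat_size: float = 1.0,
                          phase: int = 0, strict_alternation: bool = True) -> pd.DataFrame:
    """Generate seedling-quadrat geometries for ``n_plots`` 1-ha plots.

    Half the subplots of each plot are selected in a checkerboard pattern and
    each selected subplot receives ``quadrats_per_selected_subplot`` square
    quadrats of side ``quadrat_size`` (default four 1 m x 1 m quadrats placed
    at the subplot's inner corners).

    Returns
    -------
    DataFrame with columns plot_id, subplot_row, subplot_col, subplot_id,
    quadrat_id, x0, y0, size.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if strict_alternation and subplot_grid % 2 != 0:
        raise ValueError(
            "strict alternation is undefined on an odd subplot grid "
            f"({subplot_grid}x{subplot_grid}); pass strict_alternation=False"
        )
    offsets = _corner_offsets(quadrats_per_selected_subplot, subplot_size, quadrat_size)
    sel = checkerboard_selected(subplot_grid, subplot_grid, phase)
    rows = []
    for p in range(n_plots):
        plot_id = f"plot{p + 1}"
        for r in range(subplot_grid):
            for c in range(subplot_grid):
                if not sel[r, c]:
                    continue
                sx, sy = c * subplot_size, r * subplot_size
                sub_id = f"{plot_id}-s{r:02d}{c:02d}"
                for q, (ox, oy) in enumerate(offsets):
                    rows.append({
                        "plot_id": plot_id, "subplot_row": r, "subplot_col": c,
                        "subplot_id": sub_id, "quadrat_id": f"{sub_id}-q{q}",
                        "x0": sx + ox, "y0": sy + oy, "size": quadrat_size,
                    })
    return pd.DataFrame(rows)


def _corner_offsets(k: int, subplot_size: float, quadrat_size: float,
                    inset: float = 1.0) -> list[tuple[float, float]]:
    """Place k quadrats inside a subplot; default geometry is the four inner corners."""
    lo = inset
    hi = subplot_size - inset - quadrat_size
    corners = [(lo, lo), (hi, lo), (lo, hi), (hi, hi)]
    if k <= 4:
        return corners[:k]
    # beyond 4, fall back to a centred grid
    per_side = int(np.ceil(np.sqrt(k)))
    step = subplot_size / (per_side + 1)
    pts = [(step * (i + 1) - quadrat_size / 2, step * (j + 1) - quadrat_size / 2)
           for j in range(per_side) for i in range(per_side)]
    return pts[:k]


def build_soil_sampling_design(layout: QuadratLayout,
                               distances: tuple[float, ...] = CLUSTER_DISTANCES,
                               parents_per_block: int = 2,
                               block_size: float = 100.0,
                               regular_phase: int = 0,
                               seed: int = 0,
                               max_retries: int = 200) -> pd.DataFrame:
    """Regular + clustered soil sampling points for a plot.

    Regular points sit at the centres of alternate quadrats (checkerboard).
    Within each ``block_size`` x ``block_size`` block, ``parents_per_block``
    regular points are chosen at random; each spawns one sample per entry of
    ``distances`` along a randomly chosen diagonal ray.  Rays leaving the plot
    are re-drawn (seeded); an error is raised after ``max_retries`` failures.

    Returns a DataFrame with columns point_id, x, y, design_class, parent_id.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValueError("distance list must be strictly increasing and positive")
    rng = np.random.default_rng(seed)
    centers = layout.quadrat_centers()
    nrow, ncol = layout.grid_shape()
    sel = checkerboard_selected(nrow, ncol, regular_phase).ravel()
    reg = centers[sel]
    records = [
        {"point_id": f"R{i:04d}", "x": float(x), "y": float(y),
         "design_class": "regular", "parent_id": ""}
        for i, (x, y) in enumerate(reg)
    ]

    x0, y0 = layout.origin
    nbx = int(np.floor(layout.width / block_size))
    nby = int(np.floor(layout.height / block_size))
    diag = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float) / np.sqrt(2)
    k = 0
    for bi in range(nbx):
        for bj in range(nby):
            bx0, by0 = x0 + bi * block_size, y0 + bj * block_size
            in_block = ((reg[:, 0] >= bx0) & (reg[:, 0] < bx0 + block_size)
                        & (reg[:, 1] >= by0) & (reg[:, 1] < by0 + block_size))
            cand = np.flatnonzero(in_block)
            if len(cand) < parents_per_block:
                raise ValueError("not enough regular points in block for parents")
            chosen = rng.choice(cand, size=parents_per_block, replace=False)
            for pi in chosen:
                px, py = reg[pi]
                for attempt in range(max_retries):
                    u = diag[rng.integers(4)]
                    pts = np.array([px, py]) + d[:, None] * u[None, :]
                    if layout.contains(pts[:, 0], pts[:, 1]).all():
                        break
                else:
                    raise RuntimeError(
                        f"cluster ray at parent ({px:.1f},{py:.1f}) exits the plot "
                        f"after {max_retries} retries"
                    )
                for j, (cx, cy) in enumerate(pts):
                    records.append({
                        "point_id": f"C{k:04d}-{j}", "x": float(cx), "y": float(cy),
                        "design_class": "cluster", "parent_id": f"R{pi:04d}",
                    })
                k += 1
    return pd.DataFrame(records)


def filter_life_stage(records: pd.DataFrame, layout: QuadratLayout | None = None,
                      edge_buffer: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a mixed census table into adult and seedling tables.

    A stem is an adult from the first census at which its DBH reaches 1 cm.
    Stems that ever graduate to DBH >= 1 cm are excluded from the seedling
    table entirely (the seedling analyses drop them, they are not censored).
    Records with non-positive size are rejected and logged.

    When ``layout`` is given, adults receive a boolean ``focal`` column
    flagging stems at least ``edge_buffer`` metres from every plot boundary.
    """
    df = records.copy()
    size = df["dbh"].fillna(df.get("height")) if "height" in df else df["dbh"]
    alive = df["status"].ne("dead") if "status" in df else pd.Series(True, index=df.index)
    bad = alive & (size <= 0)
    if bad.any():
        logger.warning("rejected %d census records with non-positive size", int(bad.sum()))
        df = df[~bad]

    dbh = df["dbh"].fillna(-np.inf)
    is_adult_rec = dbh >= ADULT_DBH_CM
    graduated = df.loc[is_adult_rec, "stem_id"].unique()
    adults = df[is_adult_rec].copy()
    seedlings = df[~df["stem_id"].isin(graduated)].copy()
    if layout is not None and len(adults):
        x0, y0 = layout.origin
        adults["focal"] = (
            (adults["x"] >= x0 + edge_buffer)
            & (adults["x"] <= x0 + layout.width - edge_buffer)
            & (adults["y"] >= y0 + edge_buffer)
            & (adults["y"] <= y0 + layout.height - edge_buffer)
        )
    return adults, seedlings
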