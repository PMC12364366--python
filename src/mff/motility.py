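"""Cell movement (chemotaxis + excluded-volume random walk) and
recruitment of new cells.

Chemotaxis is a biased jump on the 3x3 neighbourhood: the probability
of moving to a neighbour is linear in the positive concentration
difference of the diffusible PIM over one pixel, ``p = k * max(0, dc)``
(the frozen biomaterial PIM exerts no chemotactic pull).  A cell first
attempts a chemotactic jump and, failing that, one unbiased step; both
succeed only onto an empty pixel (excluded volume).

Recruitment draws one candidate pixel per species per step (naive
macrophage M0, fibrocyte F0, fibroblast F1) and accepts it with a
probability composed of second-order Hill terms of the relevant
mediator amounts, combined as independent chances
``1 - prod(1 - h_i)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import NEIGHBOR_OFFSETS
from .kinetics import hill

__all__ = [
    "ChemotaxisParams",
    "OccupancyGrid",
    "chemotaxis_probabilities",
    "move_cell",
    "recruit_probability_macrophage",
    "recruit_probability_fibro",
    "place_recruit",
]


@dataclass
class ChemotaxisParams:
    """Chemotaxis proportionality constant k and pixel size."""

    k: float = 0.5
    dx: float = 10.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("chemotaxis k must be >= 0")


class OccupancyGrid:
    """grid_n x grid_n map from pixel to occupying cell id (-1 empty)."""

    def __init__(self, grid_n: int):
        self.grid = np.full((grid_n, grid_n), -1, dtype=np.int64)

    @property
    def grid_n(self) -> int:
        return self.grid.shape[0]

    def is_empty(self, pixel) -> bool:
        return self.grid[pixel] < 0

    def place(self, cell_id: int, pixel) -> None:
        if self.grid[pixel] >= 0:
            raise ValueError(f"pixel {pixel} already occupied")
        self.grid[pixel] = cell_id

    def move(self, cell_id: int, src, dst) -> None:
        if self.grid[src] != cell_id:
            raise ValueError("occupancy inconsistent with cell position")
        if self.grid[dst] >= 0:
            raise ValueError(f"target pixel {dst} occupied")
        self.grid[src] = -1
        self.grid[dst] = cell_id

    def remove(self, cell_id: int, pixel) -> None:
        if self.grid[pixel] != cell_id:
            raise ValueError("occupancy inconsistent with cell position")
        self.grid[pixel] = -1


def chemotaxis_probabilities(pim_grid: np.ndarray, pos: tuple,
                             cp: ChemotaxisParams) -> np.ndarray:
    """Probabilities of a chemotactic jump to each of the 8 neighbours.

    Only up-gradient moves have positive probability; if the raw sum
    exceeds 1 the vector is normalized to sum 1.  ``pim_grid`` must be
    the diffusible PIM only — the frozen mechanical field is excluded
    from the gradient.
    """
    n = pim_grid.shape[0]
    r, c = pos
    if not (0 <= r < n and 0 <= c < pim_grid.shape[1]):
        raise IndexError(f"position {pos} out of bounds")
    here = pim_grid[r, c]
    probs = np.zeros(8)
    for j, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nr, nc = r + dr, c + dc
        if 0 <= nr < n and 0 <= nc < pim_grid.shape[1]:
            probs[j] = cp.k * max(0.0, pim_grid[nr, nc] - here)
    s = probs.sum()
    if s > 1.0:
        probs /= s
    return probs


def move_cell(cell, pim_grid: np.ndarray, occ: OccupancyGrid,
              cp: ChemotaxisParams, rng: np.random.Generator):
    """Move one cell; returns (new_position, moved_by_chemotaxis).

    Scalar mirror of the engine's compiled movement loop: first a
    chemotactic attempt sampled from :func:`chemotaxis_probabilities`
    (succeeding only if the target pixel is empty), then — if no
    chemotactic move happened — one unbiased step to a uniformly chosen
    neighbour, again only if empty and in bounds.
    """
    r, c = cell.position
    if occ.grid[r, c] != cell.id:
        raise ValueError("occupancy inconsistent with cell position")
    n = occ.grid_n
    probs = chemotaxis_probabilities(pim_grid, (r, c), cp)
    u = rng.random()
    acc = 0.0
    for j in range(8):
        acc += probs[j]
        if u < acc:
            nr, nc = r + NEIGHBOR_OFFSETS[j][0], c + NEIGHBOR_OFFSETS[j][1]
            if occ.grid[nr, nc] < 0:
                occ.move(cell.id, (r, c), (nr, nc))
                cell.position = (int(nr), int(nc))
                return cell.position, True
            break
    j = min(int(rng.random() * 8.0), 7)
    nr, nc = r + NEIGHBOR_OFFSETS[j][0], c + NEIGHBOR_OFFSETS[j][1]
    if 0 <= nr < n and 0 <= nc < n and occ.grid[nr, nc] < 0:
        occ.move(cell.id, (r, c), (nr, nc))
        cell.position = (int(nr), int(nc))
    return cell.position, False


def _complement_combine(terms) -> float:
    p = 1.0
    for t in terms:
        p *= 1.0 - t
    return 1.0 - p


def recruit_probability_macrophage(total_pim: float, local_aim: float,
                                   params, mode: str = "pathological",
                                   total_fixed_pim: float = 0.0) -> float:
    """Acceptance probability for recruiting one naive macrophage.

    Macrophage recruitment is driven by the total PIM over the entire
    lattice and by the local AIM at the candidate pixel (second-order
    Hill terms combined as independent chances).  In biomaterial mode
    the frozen implant PIM enters as its own lattice-total term with
    cooperative parameter ``fix_pim_recruit_scale_m``.
    """
    if total_pim < 0 or local_aim < 0 or total_fixed_pim < 0:
        raise ValueError("mediator amounts must be >= 0")
    k = params.recruitment_mm_term
    terms = [
        hill(total_pim, a=params.mac.patho_pim_recruit_scale_m, n=2.0, k=k),
        hill(local_aim, a=params.aim_recruit_scale_m, n=2.0, k=k),
    ]
    if mode == "biomaterial":
        terms.append(
            hill(total_fixed_pim, a=params.fix_pim_recruit_scale_m,
                 n=2.0, k=k))
    elif mode != "pathological":
        raise ValueError(f"unknown recruitment mode {mode!r}")
    return _complement_combine(terms)


def recruit_probability_fibro(local_pim: float, local_aim: float,
                              params, mode: str = "pathological",
                              local_fixed_pim: float = 0.0) -> float:
    """Acceptance probability for recruiting one fibro cell (F0 or F1).

    Driven by the local diffusible PIM and local AIM at the candidate
    pixel; in biomaterial mode the local frozen PIM adds a third term
    with cooperative parameter ``fix_pim_recruit_scale_f``.
    """
    if local_pim < 0 or local_aim < 0 or local_fixed_pim < 0:
        raise ValueError("mediator amounts must be >= 0")
    k = params.recruitment_ff_term
    terms = [
        hill(local_pim, a=params.patho_pim_recruit_scale_f, n=2.0, k=k),
        hill(local_aim, a=params.aim_recruit_scale_f, n=2.0, k=k),
    ]
    if mode == "biomaterial":
        terms.append(
            hill(local_fixed_pim, a=params.fix_pim_recruit_scale_f,
                 n=2.0, k=k))
    elif mode != "pathological":
        raise ValueError(f"unknown recruitment mode {mode!r}")
    return _complement_combine(terms)


def crown_annulus(grid_n: int, stimulus_extent: int,
                  margin: float = 1.0, width: float = 2.0) -> np.ndarray:
    """Boolean mask of the circular-crown placement annulus.

    The crown sits just outside the central stimulus: inner Chebyshev
    radius = stimulus half-width + ``margin``, radial width ``width``
    pixels, measured from the grid centre ``(grid_n - 1) / 2``.
    """
    c = (grid_n - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(grid_n), np.arange(grid_n), indexing="ij")
    cheb = np.maximum(np.abs(rr - c), np.abs(cc - c))
    inner = stimulus_extent / 2.0 + margin
    return (cheb >= inner) & (cheb <= inner + width)


def border_mask(grid_n: int) -> np.ndarray:
    m = np.zeros((grid_n, grid_n), dtype=bool)
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = True
    return m


def place_recruit(mode: str, occ: OccupancyGrid, rng: np.random.Generator,
                  stimulus_extent: int = 13, margin: float = 1.0,
                  width: float = 2.0, region: np.ndarray | None = None):
    """Draw an empty pixel for a new recruit, or None if none is free.

    ``uniform`` mode draws uniformly among all empty pixels (the base
    model's recruitment: acceptance, not placement, concentrates cells
    near the stimulus); ``border`` mode draws among empty boundary
    pixels; ``crown`` mode among empty pixels of the annulus just
    outside the central stimulus (see :func:`crown_annulus`).
    """
    n = occ.grid_n
    if region is None:
        if mode == "uniform":
            region = np.ones((n, n), dtype=bool)
        elif mode == "border":
            region = border_mask(n)
        elif mode == "crown":
            region = crown_annulus(n, stimulus_extent, margin, width)
        else:
            raise ValueError(f"unknown placement mode {mode!r}")
    empty = np.flatnonzero(region.ravel() & (occ.grid.ravel() < 0))
    if empty.size == 0:
        return None
    flat = int(empty[int(rng.random() * empty.size)])
    return flat // n, flat % n
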