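"""Mediator concentration fields: stimuli, diffusion and decay.

PIM and AIM live on the simulation lattice as non-negative
concentration grids.  Each step they spread over the 3x3 neighbourhood
with a jump probability derived from the mediator's diffusion
coefficient, and decay exponentially with an intrinsic lifetime.  A
"mechanical" stimulus (an implanted biomaterial) is a frozen PIM
region: it neither diffuses nor decays and is excluded from the
chemotaxis gradient, but cells sense it when activating and it feeds
dedicated recruitment terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "MediatorField",
    "StimulusSpec",
    "DiffusionKernel",
    "make_stimulus",
    "diffusion_kernel",
    "step_field",
    "field_total",
    "field_local",
    "NEIGHBOR_OFFSETS",
]

#: the 8 nearest-neighbour lattice offsets, fixed order
NEIGHBOR_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@dataclass
class MediatorField:
    """One mediator concentration grid (kind: ``"PIM"`` or ``"AIM"``)."""

    grid: np.ndarray
    kind: str = "PIM"

    def copy(self) -> "MediatorField":
        return MediatorField(self.grid.copy(), self.kind)


@dataclass
class StimulusSpec:
    """Initial-stimulus geometry and amplitude.

    ``mode`` is ``"chemical"`` (a diffusing, decaying source),
    ``"mechanical"`` (a frozen biomaterial region) or ``"none"``.
    Chemical stimuli come in two shapes: a uniform ``"block"`` of side
    ``extent`` (optionally smoothed with ``smooth_sigma``), or a
    centre-peaked Gaussian ``"peak"`` whose maximum is ``amplitude``
    and spatial SD is ``sigma`` pixels.
    """

    mode: str = "chemical"
    amplitude: float = 0.0
    #: square side in pixels (footprint; also the crown-placement
    #: reference for peak-shaped stimuli)
    extent: int = 13
    #: Gaussian smoothing SD applied to block/mechanical stimuli
    #: (0 = none), pixels
    smooth_sigma: float = 0.0
    #: block or peak (chemical mode only)
    shape: str = "block"
    #: spatial SD of a peak-shaped stimulus, pixels
    sigma: float = 2.0
    #: centre pixel (row, col); None = grid centre
    center: Optional[tuple] = None


@dataclass
class DiffusionKernel:
    """3x3 jump probabilities for one mediator."""

    neighbor_p: float
    center_p: float
    D: float
    tau: float
    dx: float


def diffusion_kernel(D: float, tau: float, dx: float) -> DiffusionKernel:
    """Per-step jump probability to each of the 8 nearest pixels.

    The probability follows the 1-D Gaussian displacement kernel

        P = (dx / sqrt(4*pi*D*tau)) * exp(-dx^2 / (4*D*tau)),

    with the stay probability its complement ``1 - 8*P``.  For the
    default parameters (dx = 10 um, tau = 20 min) this gives
    P ~ 0.021 / stay ~ 0.832 for D = 900 um^2/min (PIM) and
    P ~ 0.0226 / stay ~ 0.820 for D = 780 um^2/min (AIM).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if tau <= 0 or dx <= 0:
        raise ValueError("tau and dx must be > 0")
    if D == 0:
        return DiffusionKernel(0.0, 1.0, D, tau, dx)
    p = dx / math.sqrt(4.0 * math.pi * D * tau) * math.exp(
        -dx * dx / (4.0 * D * tau)
    )
    if 8.0 * p > 1.0:
        raise ValueError(
            "8 * neighbor_p > 1 for D=%g, tau=%g, dx=%g; use a smaller "
            "time step or a larger pixel" % (D, tau, dx)
        )
    return DiffusionKernel(p, 1.0 - 8.0 * p, D, tau, dx)


def _center_block(grid_n: int, extent: int,
                  center: Optional[tuple]) -> tuple[slice, slice]:
    if center is None:
        lo = (grid_n - extent) // 2
        return slice(lo, lo + extent), slice(lo, lo + extent)
    r, c = center
    half = extent // 2
    r0, c0 = r - half, c - half
    return slice(r0, r0 + extent), slice(c0, c0 + extent)


def make_stimulus(spec: StimulusSpec, grid_n: int,
                  kind: str = "PIM"):
    """Build the initial field for a stimulus.

    Returns ``(MediatorField, mask)`` where ``mask`` is a boolean grid
    of biomaterial pixels for mechanical stimuli and ``None`` otherwise.
    Mechanical fields keep their nominal amplitude on the implant mask
    after boundary smoothing (the smoothed skirt represents adsorbed
    plasma proteins at the implant surface).
    """
    if spec.extent > grid_n:
        raise ValueError(
            f"stimulus extent {spec.extent} exceeds grid side {grid_n}"
        )
    if spec.amplitude < 0:
        raise ValueError("stimulus amplitude must be >= 0")
    grid = np.zeros((grid_n, grid_n), dtype=np.float64)
    if spec.mode == "none" or spec.amplitude == 0.0:
        return MediatorField(grid, kind), None
    if spec.mode == "chemical" and spec.shape == "peak":
        # default centre on a pixel so the printed maximum is attained
        c = (grid_n - 1) // 2
        cr, cc = (c, c) if spec.center is None else spec.center
        rr, cc_ = np.meshgrid(np.arange(grid_n), np.arange(grid_n),
                              indexing="ij")
        d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
        grid = spec.amplitude * np.exp(-d2 / (2.0 * spec.sigma ** 2))
        return MediatorField(grid, kind), None
    rs, cs = _center_block(grid_n, spec.extent, spec.center)
    grid[rs, cs] = spec.amplitude
    if spec.smooth_sigma > 0:
        grid = ndimage.gaussian_filter(grid, spec.smooth_sigma,
                                       mode="constant")
    if spec.mode == "mechanical":
        mask = np.zeros((grid_n, grid_n), dtype=bool)
        mask[rs, cs] = True
        grid[mask] = spec.amplitude  # re-impose the plateau
        return MediatorField(grid, kind), mask
    if spec.mode != "chemical":
        raise ValueError(f"unknown stimulus mode {spec.mode!r}")
    return MediatorField(grid, kind), None


def _blocked_counts(grid_n: int,
                    frozen_mask: Optional[np.ndarray]) -> np.ndarray:
    """Number of invalid (off-grid or frozen) neighbours per pixel."""
    valid = np.ones((grid_n, grid_n), dtype=np.float64)
    if frozen_mask is not None:
        valid[frozen_mask] = 0.0
    padded = np.pad(valid, 1, mode="constant")
    n_valid = np.zeros((grid_n, grid_n))
    for dr, dc in NEIGHBOR_OFFSETS:
        n_valid += padded[1 + dr: 1 + dr + grid_n, 1 + dc: 1 + dc + grid_n]
    return 8.0 - n_valid


def diffuse_array(grid: np.ndarray, kernel: DiffusionKernel,
                  decay_fraction: float,
                  frozen_mask: Optional[np.ndarray] = None,
                  blocked: Optional[np.ndarray] = None,
                  boundary: str = "reflecting") -> np.ndarray:
    """One diffusion + decay update on a raw array (engine hot path).

    Reflecting boundary: flux that would leave the grid (or enter a
    frozen pixel) stays at the source pixel, so with zero decay total
    mass is conserved exactly.  Frozen pixels are left untouched.
    """
    n = grid.shape[0]
    if grid.shape != (n, n):
        raise ValueError("field grid must be square")
    mobile = grid if frozen_mask is None else np.where(frozen_mask, 0.0, grid)
    flux = kernel.neighbor_p * mobile
    padded = np.pad(flux, 1, mode="constant")
    new = kernel.center_p * mobile
    for dr, dc in NEIGHBOR_OFFSETS:
        contrib = padded[1 - dr: 1 - dr + n, 1 - dc: 1 - dc + n]
        if frozen_mask is not None:
            contrib = np.where(frozen_mask, 0.0, contrib)
        new += contrib
    if boundary == "reflecting":
        if blocked is None:
            blocked = _blocked_counts(n, frozen_mask)
        new += flux * blocked
    elif boundary != "absorbing":
        raise ValueError(f"unknown boundary {boundary!r}")
    new *= 1.0 - decay_fraction
    if frozen_mask is not None:
        new[frozen_mask] = grid[frozen_mask]
    return new


def step_field(field: MediatorField, kernel: DiffusionKernel,
               decay_fraction: float,
               frozen_mask: Optional[np.ndarray] = None,
               boundary: str = "reflecting") -> MediatorField:
    """Diffuse and decay one mediator field for one time step."""
    if not 0.0 <= decay_fraction <= 1.0:
        raise ValueError("decay_fraction must be in [0, 1]")
    if frozen_mask is not None and frozen_mask.shape != field.grid.shape:
        raise ValueError("frozen mask shape does not match the field")
    new = diffuse_array(field.grid, kernel, decay_fraction,
                        frozen_mask=frozen_mask, boundary=boundary)
    return MediatorField(new, field.kind)


def field_total(field: MediatorField) -> float:
    """Total mediator content over the lattice."""
    return float(field.grid.sum())


def field_local(field: MediatorField, pixel: tuple) -> float:
    """Mediator concentration at one pixel (row, col)."""
    r, c = pixel
    n = field.grid.shape[0]
    if not (0 <= r < n and 0 <= c < field.grid.shape[1]):
        raise IndexError(f"pixel {pixel} out of bounds for {field.grid.shape}")
    return float(field.grid[r, c])
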