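"""Numba hot loops.

Cell movement is inherently sequential (excluded volume: each move
frees/claims a pixel immediately, affecting later cells in the same
step), so it runs as a compiled loop over a pre-shuffled cell order.
All randomness is consumed from uniforms pre-generated by the per-run
numpy Generator, keeping runs bit-reproducible.
"""

from __future__ import annotations

import numba
import numpy as np

#: 8-neighbour offsets, fixed order shared with fields.NEIGHBOR_OFFSETS
_OFF = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


@numba.njit(cache=True)
def move_all(order, xs, ys, occ, pim, k_chemo, u_chemo, u_dir):
    """Move every cell once, in the given order; returns (n_c, moved).

    Per cell: first a chemotactic attempt — neighbour probabilities
    proportional to the positive up-gradient of the diffusible PIM
    (p = k * max(0, c_nb - c_here), normalized if the sum exceeds 1),
    succeeding only onto an empty pixel; if no chemotactic move, one
    unbiased step to a uniformly drawn neighbour, again only if empty.
    ``occ``, ``xs``, ``ys`` are updated in place; n_c counts the
    chemotactic moves.
    """
    n = pim.shape[0]
    n_c = 0
    moved = np.zeros(order.shape[0], dtype=np.uint8)
    probs = np.empty(8, dtype=np.float64)
    for oi in range(order.shape[0]):
        i = order[oi]
        x = xs[i]
        y = ys[i]
        here = pim[x, y]
        s = 0.0
        for j in range(8):
            nx = x + _OFF[j, 0]
            ny = y + _OFF[j, 1]
            if 0 <= nx < n and 0 <= ny < n:
                d = pim[nx, ny] - here
                p = k_chemo * d if d > 0.0 else 0.0
            else:
                p = 0.0
            probs[j] = p
            s += p
        scale = 1.0 / s if s > 1.0 else 1.0
        u = u_chemo[oi]
        chemo_done = False
        acc = 0.0
        for j in range(8):
            acc += probs[j] * scale
            if u < acc:
                nx = x + _OFF[j, 0]
                ny = y + _OFF[j, 1]
                if occ[nx, ny] < 0:
                    occ[x, y] = -1
                    occ[nx, ny] = i
                    xs[i] = nx
                    ys[i] = ny
                    n_c += 1
                    moved[oi] = 1
                chemo_done = True
                break
        if chemo_done and moved[oi] == 1:
            continue
        j = int(u_dir[oi] * 8.0)
        if j > 7:
            j = 7
        nx = x + _OFF[j, 0]
        ny = y + _OFF[j, 1]
        if 0 <= nx < n and 0 <= ny < n and occ[nx, ny] < 0:
            occ[x, y] = -1
            occ[nx, ny] = i
            xs[i] = nx
            ys[i] = ny
            moved[oi] = 1
    return n_c, moved
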