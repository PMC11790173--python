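"""Numba inner loop for the reaction-diffusion stepper.

Semantically identical to :func:`turingrowth.engine.reaction_step` applied
``n_steps`` times (cross-checked in the test suite); exists because the
chunked pure-numpy path is an order of magnitude slower.
"""

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(a, b, n_steps, s, r, d, surface, g, dt, couple_diffusion,
              min_a, max_a, min_b, max_b):
    h, w = a.shape
    cur_a = a.copy()
    cur_b = b.copy()
    new_a = np.empty_like(cur_a)
    new_b = np.empty_like(cur_b)
    dil = 1.0 + g * dt
    dil2 = dil * dil
    for _ in range(n_steps):
        diff_a = d * r * s
        diff_b = d * s
        inv_dil = 1.0 / dil
        inv_dil2 = 1.0 / dil2
        sixth = 1.0 / 6.0
        for i in range(h):
            im = h - 1 if i == 0 else i - 1
            ip = 0 if i == h - 1 else i + 1
            # the two wrap columns first, then a branch-free interior loop
            for j in (0, w - 1):
                jm = w - 1 if j == 0 else j - 1
                jp = 0 if j == w - 1 else j + 1
                av = cur_a[i, j]
                bv = cur_b[i, j]
                lap_a = (
                    (cur_a[im, jm] - av) + 4.0 * (cur_a[im, j] - av) + (cur_a[im, jp] - av)
                    + 4.0 * (cur_a[i, jm] - av) + 4.0 * (cur_a[i, jp] - av)
                    + (cur_a[ip, jm] - av) + 4.0 * (cur_a[ip, j] - av) + (cur_a[ip, jp] - av)
                ) * sixth
                lap_b = (
                    (cur_b[im, jm] - bv) + 4.0 * (cur_b[im, j] - bv) + (cur_b[im, jp] - bv)
                    + 4.0 * (cur_b[i, jm] - bv) + 4.0 * (cur_b[i, jp] - bv)
                    + (cur_b[ip, jm] - bv) + 4.0 * (cur_b[ip, j] - bv) + (cur_b[ip, jp] - bv)
                ) * sixth
                ab = av * bv * inv_dil2
                na = av * inv_dil + (16.0 - ab + diff_a * lap_a) * dt
                nb = bv * inv_dil + (ab - bv * inv_dil - 12.0 + diff_b * lap_b) * dt
                new_a[i, j] = min(max(na, min_a), max_a)
                new_b[i, j] = min(max(nb, min_b), max_b)
            for j in range(1, w - 1):
                av = cur_a[i, j]
                bv = cur_b[i, j]
                lap_a = (
                    (cur_a[im, j - 1] - av) + 4.0 * (cur_a[im, j] - av) + (cur_a[im, j + 1] - av)
                    + 4.0 * (cur_a[i, j - 1] - av) + 4.0 * (cur_a[i, j + 1] - av)
                    + (cur_a[ip, j - 1] - av) + 4.0 * (cur_a[ip, j] - av) + (cur_a[ip, j + 1] - av)
                ) * sixth
                lap_b = (
                    (cur_b[im, j - 1] - bv) + 4.0 * (cur_b[im, j] - bv) + (cur_b[im, j + 1] - bv)
                    + 4.0 * (cur_b[i, j - 1] - bv) + 4.0 * (cur_b[i, j + 1] - bv)
                    + (cur_b[ip, j - 1] - bv) + 4.0 * (cur_b[ip, j] - bv) + (cur_b[ip, j + 1] - bv)
                ) * sixth
                ab = av * bv * inv_dil2
                na = av * inv_dil + (16.0 - ab + diff_a * lap_a) * dt
                nb = bv * inv_dil + (ab - bv * inv_dil - 12.0 + diff_b * lap_b) * dt
                new_a[i, j] = min(max(na, min_a), max_a)
                new_b[i, j] = min(max(nb, min_b), max_b)
        cur_a, new_a = new_a, cur_a
        cur_b, new_b = new_b, cur_b
        if g > 0.0:
            surface *= dil2
            if couple_diffusion:
                d /= dil2
    return cur_a, cur_b, d, surface
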