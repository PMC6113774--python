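"""Numba kernels for the Metropolis pixel-copy dynamics.

The lattice stores generalized-cell ids; per-id arrays give type, volume
and target volume.  Reserved ids: 0 medium, 1 lumen, 2 the shared immobile
matrix (ECM) domain, 3 the blood clot; real cells start at id 4.  A
pairwise permission matrix ``move_ok[a, b]`` states whether a domain of
type ``a`` may claim a pixel owned by type ``b``; frozen domains (lumen,
matrix) never appear as sources, and the wound protocol widens the matrix
at run time to unfreeze the epidermis.

Random numbers are drawn outside the kernel from the simulation's single
seeded generator and passed in as arrays, keeping runs reproducible and
independent of numba's internal RNG state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# cell-type codes (must match tissue.CELL_TYPES ordering)
T_MEDIUM = 0
T_LUMEN = 1
T_ECM = 2
T_CLOT = 3
T_EPIDERMIS = 4
T_PF = 5
T_QF = 6
T_ACTIVATED = 7
T_ADIPOCYTE = 8
T_IMMUNE = 9
N_TYPES = 10

# reserved lattice ids
ID_MEDIUM = 0
ID_LUMEN = 1
ID_ECM = 2
ID_CLOT = 3
FIRST_CELL_ID = 4

_NBR_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_NBR_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def metropolis_sweep(
    lattice,
    type_of,
    volume,
    target_volume,
    J,
    has_volume,
    move_ok,
    lambda_volume,
    temperature,
    ecm_stiffness,
    chemo_coeff,
    wound_field,
    sites,
    neigh_choice,
    accept_u,
):
    """One MCS worth of pixel-copy attempts; mutates lattice and volumes.

    ``sites`` are flattened pixel indices, ``neigh_choice`` in 0..3 picks
    the source neighbour, ``accept_u`` the Metropolis uniforms.
    ``move_ok[a, b]`` says whether a domain of type ``a`` may claim a pixel
    owned by type ``b``.
    ``chemo_coeff[t]`` is the chemotactic strength of type ``t`` up the
    wound-signal gradient.  Returns the number of accepted copies.
    """
    L = lattice.shape[0]
    accepted = 0
    for a in range(sites.shape[0]):
        s = sites[a]
        sx = s // L
        sy = s % L
        nx = sx + _NBR_DX[neigh_choice[a]]
        ny = sy + _NBR_DY[neigh_choice[a]]
        if nx < 0 or nx >= L or ny < 0 or ny >= L:
            continue  # wall boundary
        id_old = lattice[sx, sy]
        id_new = lattice[nx, ny]
        if id_old == id_new:
            continue
        t_old = type_of[id_old]
        t_new = type_of[id_new]
        if not move_ok[t_new, t_old]:
            continue
        # contact energy over the 4-neighbourhood of s
        dh = 0.0
        for k in range(4):
            ux = sx + _NBR_DX[k]
            uy = sy + _NBR_DY[k]
            if ux < 0 or ux >= L or uy < 0 or uy >= L:
                continue
            id_u = lattice[ux, uy]
            t_u = type_of[id_u]
            if id_u != id_old:
                dh -= J[t_old, t_u]
            if id_u != id_new:
                dh += J[t_new, t_u]
        # volume constraint
        if has_volume[t_new]:
            v = volume[id_new]
            dh += lambda_volume * (2.0 * (v - target_volume[id_new]) + 1.0)
        if has_volume[t_old]:
            v = volume[id_old]
            dh += lambda_volume * (-2.0 * (v - target_volume[id_old]) + 1.0)
        # displacing matrix costs extra work (matrix rigidity)
        if t_old == T_ECM:
            dh += ecm_stiffness
        # chemotaxis of the expanding cell up the wound signal
        c = chemo_coeff[t_new]
        if c != 0.0:
            dh -= c * (wound_field[sx, sy] - wound_field[nx, ny])
        if dh <= 0.0 or accept_u[a] < np.exp(-dh / temperature):
            lattice[sx, sy] = id_new
            volume[id_new] += 1.0
            volume[id_old] -= 1.0
            accepted += 1
    return accepted


@njit(cache=True)
def copy_attempt_delta_h(
    lattice,
    type_of,
    volume,
    target_volume,
    J,
    has_volume,
    lambda_volume,
    ecm_stiffness,
    chemo_coeff,
    wound_field,
    sx,
    sy,
    nx,
    ny,
):
    """Energy change of copying (nx,ny)'s id onto (sx,sy); test/diagnostic hook.

    Mirrors the arithmetic of :func:`metropolis_sweep` exactly so the
    acceptance rule can be cross-checked by enumeration on toy lattices.
    """
    L = lattice.shape[0]
    id_old = lattice[sx, sy]
    id_new = lattice[nx, ny]
    dh = 0.0
    for k in range(4):
        ux = sx + _NBR_DX[k]
        uy = sy + _NBR_DY[k]
        if ux < 0 or ux >= L or uy < 0 or uy >= L:
            continue
        id_u = lattice[ux, uy]
        t_u = type_of[id_u]
        if id_u != id_old:
            dh -= J[type_of[id_old], t_u]
        if id_u != id_new:
            dh += J[type_of[id_new], t_u]
    if has_volume[type_of[id_new]]:
        v = volume[id_new]
        dh += lambda_volume * (2.0 * (v - target_volume[id_new]) + 1.0)
    if has_volume[type_of[id_old]]:
        v = volume[id_old]
        dh += lambda_volume * (-2.0 * (v - target_volume[id_old]) + 1.0)
    if type_of[id_old] == T_ECM:
        dh += ecm_stiffness
    c = chemo_coeff[type_of[id_new]]
    if c != 0.0:
        dh -= c * (wound_field[sx, sy] - wound_field[nx, ny])
    return dh
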