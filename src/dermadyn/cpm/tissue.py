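"""Lattice state, update rules and drivers of the Cellular Potts tissue model.

Geometry: the lattice is a cross-section of the mouse trunk.  A frozen
central disc is the body cavity (lumen); a closed ring of epidermal cells
encloses the dermal annulus; everything outside the ring is exterior
medium.  Ten proliferating fibroblasts start just under the epidermis.
Matrix (ECM) is a single shared immobile domain excluded from Metropolis
source selection; it never expands by itself, and only cells (not free
medium) can displace -- remodel -- matrix pixels, so deposited matrix is
effectively permanent free-space filler that cells can still slowly
burrow through.

Normalised depth runs from 0 at the epidermis to 1 at the body wall, so
"upper dermis" means depth < 1/3 and "lower dermis" depth > 2/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from . import _kernels as K
from .config import CpmConfig

__all__ = [
    "CELL_TYPES",
    "TissueState",
    "TissueMetrics",
    "init_tissue",
    "update_fields",
    "mcs_step",
    "growth_update",
    "transition_update",
    "deposition_update",
    "adipocyte_update",
    "apply_wound_cpm",
    "run",
    "label_lineage",
    "lineage_trace",
    "epidermis_ring_closed",
]

CELL_TYPES = (
    "Medium",
    "Lumen",
    "ECM",
    "BloodClot",
    "Epidermis",
    "PF",
    "QF",
    "ActivatedFibroblast",
    "Adipocyte",
    "Immune",
)

_FIBROBLAST_TYPES = (K.T_PF, K.T_QF, K.T_ACTIVATED)

# lineage label codes
LABEL_NONE, LABEL_UPPER, LABEL_MIDDLE, LABEL_LOWER = 0, 1, 2, 3
_REGION_CODE = {"upper": LABEL_UPPER, "middle": LABEL_MIDDLE, "lower": LABEL_LOWER}


class TissueState:
    """Mutable simulation state: lattice, per-cell bookkeeping, fields, rng."""

    def __init__(self, config: CpmConfig):
        self.config = config
        L = config.size
        self.lattice = np.zeros((L, L), dtype=np.int32)
        cap = 1024
        self.type_of = np.zeros(cap, dtype=np.int8)
        self.volume = np.zeros(cap, dtype=np.float64)
        self.target_volume = np.zeros(cap, dtype=np.float64)
        self.lineage = np.zeros(cap, dtype=np.int8)
        self.birth_mcs = np.zeros(cap, dtype=np.int32)
        self.n_ids = K.FIRST_CELL_ID
        self.mcs = 0
        self.epi_field = np.zeros((L, L))
        self.wound_field = np.zeros((L, L))
        self.wounded = False
        self.wound_mask = np.zeros((L, L), dtype=bool)
        self.rng = np.random.default_rng(config.seed)
        # pairwise Metropolis permissions: move_ok[a, b] lets type a claim a
        # pixel of type b.  Matrix and lumen are frozen (never expand, never
        # overwritten); the epidermis is frozen until wounding.
        self.move_ok = np.zeros((K.N_TYPES, K.N_TYPES), dtype=np.bool_)
        mobile = (K.T_PF, K.T_QF, K.T_ACTIVATED, K.T_ADIPOCYTE)
        overwritable = (K.T_MEDIUM, K.T_CLOT, K.T_IMMUNE) + mobile
        for a in mobile:
            for b in overwritable:
                self.move_ok[a, b] = True
        for b in overwritable:
            self.move_ok[K.T_MEDIUM, b] = True
        self.has_volume = np.zeros(K.N_TYPES, dtype=np.bool_)
        for t in (K.T_EPIDERMIS, K.T_PF, K.T_QF, K.T_ACTIVATED, K.T_ADIPOCYTE):
            self.has_volume[t] = True
        self.J = _contact_matrix(config)
        self.chemo_coeff = np.zeros(K.N_TYPES)
        # geometry caches
        c = (L - 1) / 2.0
        yy, xx = np.indices((L, L))
        self.radius = np.hypot(xx - c, yy - c)
        self.angle = np.arctan2(yy - c, xx - c)
        self.center = c
        self.dermis_mask = (self.radius > config.lumen_radius) & (
            self.radius < config.epidermis_inner_radius
        )
        depth = (config.epidermis_inner_radius - self.radius) / (
            config.epidermis_inner_radius - config.lumen_radius
        )
        self.depth = np.clip(depth, 0.0, 1.0)

    # -- id bookkeeping ----------------------------------------------------
    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_ids + extra
        cap = self.type_of.size
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in ("type_of", "volume", "target_volume", "lineage", "birth_mcs"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[: arr.size] = arr
            setattr(self, name, grown)

    def new_cell(self, ctype: int, lineage: int = LABEL_NONE, target: Optional[float] = None) -> int:
        self._ensure_capacity(1)
        cid = self.n_ids
        self.n_ids += 1
        self.type_of[cid] = ctype
        self.volume[cid] = 0.0
        self.target_volume[cid] = self.config.target_volume if target is None else target
        self.lineage[cid] = lineage
        self.birth_mcs[cid] = self.mcs
        return cid

    def cell_ids(self, *types: int) -> np.ndarray:
        ids = np.arange(K.FIRST_CELL_ID, self.n_ids)
        mask = self.volume[ids] > 0
        if types:
            mask &= np.isin(self.type_of[ids], np.array(types, dtype=np.int8))
        return ids[mask]

    def type_lattice(self) -> np.ndarray:
        return self.type_of[self.lattice]

    def recount_volumes(self) -> np.ndarray:
        return np.bincount(self.lattice.ravel(), minlength=self.n_ids).astype(float)

    def check_volumes(self) -> None:
        counts = self.recount_volumes()
        if not np.array_equal(counts, self.volume[: self.n_ids]):
            bad = np.nonzero(counts != self.volume[: self.n_ids])[0]
            raise RuntimeError(f"volume bookkeeping mismatch for ids {bad[:5]}")


def _contact_matrix(config: CpmConfig) -> np.ndarray:
    J = np.full((K.N_TYPES, K.N_TYPES), config.j_default)
    cells = (K.T_PF, K.T_QF, K.T_ACTIVATED, K.T_ADIPOCYTE)

    def setj(a, b, v):
        J[a, b] = v
        J[b, a] = v

    for a in cells:
        setj(a, K.T_MEDIUM, config.j_cell_medium)
        setj(a, K.T_ECM, config.j_cell_ecm)
        setj(a, K.T_EPIDERMIS, config.j_cell_epidermis)
        setj(a, K.T_CLOT, config.j_cell_clot)
        for b in cells:
            setj(a, b, config.j_cell_cell)
    setj(K.T_EPIDERMIS, K.T_MEDIUM, config.j_epidermis_medium)
    setj(K.T_EPIDERMIS, K.T_EPIDERMIS, config.j_epidermis_epidermis)
    setj(K.T_EPIDERMIS, K.T_CLOT, config.j_epidermis_clot)
    J[K.T_MEDIUM, K.T_MEDIUM] = 0.0
    return J


def init_tissue(config: CpmConfig) -> TissueState:
    """Build the initial cross-section: lumen, closed epidermal ring, and
    ten proliferating fibroblasts disposed radially across the dermal
    annulus, touching both the epidermis and the body wall."""
    state = TissueState(config)
    L = config.size
    lat = state.lattice
    r, th = state.radius, state.angle

    lat[r <= config.lumen_radius] = K.ID_LUMEN
    state.type_of[K.ID_LUMEN] = K.T_LUMEN
    state.type_of[K.ID_ECM] = K.T_ECM
    state.type_of[K.ID_CLOT] = K.T_CLOT

    band = (r >= config.epidermis_inner_radius) & (
        r < config.epidermis_inner_radius + config.epidermis_thickness
    )
    seg = np.floor((th + math.pi) / (2 * math.pi) * config.n_epidermal_cells).astype(int)
    seg = np.clip(seg, 0, config.n_epidermal_cells - 1)
    epi_ids = []
    for s in range(config.n_epidermal_cells):
        cid = state.new_cell(K.T_EPIDERMIS)
        epi_ids.append(cid)
        m = band & (seg == s)
        lat[m] = cid
    # fibroblast spokes: radially oriented cells spanning the dermis from
    # the body wall to the epidermis, evenly spaced in angle
    ha = config.fibroblast_spoke_halfangle
    in_dermis = (r > config.lumen_radius) & (r < config.epidermis_inner_radius)
    for k in range(config.n_fibroblasts):
        ang = 2 * math.pi * k / config.n_fibroblasts - math.pi + math.pi / config.n_fibroblasts
        dth = np.arctan2(np.sin(th - ang), np.cos(th - ang))
        cid = state.new_cell(K.T_PF)
        m = in_dermis & (np.abs(dth) <= ha) & (state.type_of[lat] == K.T_MEDIUM)
        lat[m] = cid
    state.volume[: state.n_ids] = state.recount_volumes()
    # epidermal segments and fibroblast spokes start at their built size
    for cid in epi_ids:
        state.target_volume[cid] = state.volume[cid]
    for cid in state.cell_ids(K.T_PF):
        state.target_volume[cid] = state.volume[cid]
    n_fibro = state.cell_ids(K.T_PF).size
    if n_fibro != config.n_fibroblasts:
        raise ValueError("lattice too small to host all initial fibroblasts")
    update_fields(state)
    return state


def epidermis_ring_closed(state: TissueState) -> bool:
    """True if no 4-connected path of non-epidermis pixels links the
    exterior to the lumen."""
    not_epi = state.type_lattice() != K.T_EPIDERMIS
    lab, _ = ndimage.label(not_epi)
    outside = lab[0, 0]
    lumen = lab[state.lattice == K.ID_LUMEN]
    return not np.any(lumen == outside)


# ---------------------------------------------------------------------------
# fields


def _relax(field_arr, src_mask, amplitude, decay, sweeps):
    f = field_arr
    for _ in range(sweeps):
        p = np.pad(f, 1, mode="edge")
        avg = 0.25 * (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:])
        f = (1.0 - decay) * avg
        f[src_mask] = amplitude
    return f


def update_fields(state: TissueState) -> None:
    """Re-relax the signal fields from their current sources.

    The epidermal signal is sourced by epidermis pixels with an amplitude
    halving every ``epi_half_life_mcs``; per-sweep decay keeps it
    concentrated near the ring.  The wound signal (post-wounding only) is
    sourced by immune cells, with a stronger per-sweep decay so it cannot
    reach far from the wound bed, and its own amplitude clock.
    """
    cfg = state.config
    tl = state.type_lattice()
    amp_e = cfg.epi_amplitude * 0.5 ** (state.mcs / cfg.epi_half_life_mcs)
    state.epi_field = _relax(state.epi_field, tl == K.T_EPIDERMIS, amp_e, cfg.epi_decay, cfg.epi_sweeps)
    if state.wounded:
        age = state.mcs - cfg.wound_mcs
        amp_w = cfg.wound_amplitude * 0.5 ** (age / cfg.wound_half_life_mcs)
        src = tl == K.T_IMMUNE
        if np.any(src):
            state.wound_field = _relax(state.wound_field, src, amp_w, cfg.wound_decay, cfg.wound_sweeps)


# ---------------------------------------------------------------------------
# steppables


def _mean_field_per_cell(state: TissueState, field_arr: np.ndarray) -> np.ndarray:
    flat = state.lattice.ravel()
    sums = np.bincount(flat, weights=field_arr.ravel(), minlength=state.n_ids)
    counts = np.bincount(flat, minlength=state.n_ids)
    return sums / np.maximum(counts, 1)


def growth_update(state: TissueState) -> None:
    """Signal-driven target-volume growth followed by division.

    Proliferating fibroblasts grow in proportion to the local epidermal
    signal; activated fibroblasts additionally read the wound signal, and
    the epidermis reads the wound signal after wounding (re-epithelialisation).
    A cell whose actual volume reaches the division threshold splits along
    a random axis through its centroid; children inherit type and lineage
    and each receives half the parent's target volume.
    """
    cfg = state.config
    mean_epi = _mean_field_per_cell(state, state.epi_field)
    grow_types = [K.T_PF, K.T_ACTIVATED]
    pf_ids = state.cell_ids(K.T_PF)
    state.target_volume[pf_ids] += cfg.growth_rate * mean_epi[pf_ids]
    act_ids = state.cell_ids(K.T_ACTIVATED)
    grown = [pf_ids, act_ids]
    if act_ids.size or (state.wounded and cfg.epidermal_wound_growth > 0):
        mean_w = _mean_field_per_cell(state, state.wound_field)
        state.target_volume[act_ids] += (
            cfg.growth_rate * mean_epi[act_ids] + cfg.wound_growth_rate * mean_w[act_ids]
        )
        if state.wounded:
            epi_ids = state.cell_ids(K.T_EPIDERMIS)
            state.target_volume[epi_ids] += cfg.epidermal_wound_growth * mean_w[epi_ids]
            grow_types.append(K.T_EPIDERMIS)
            grown.append(epi_ids)
    # a cell that cannot realise its growth does not accumulate unbounded
    # drive: the target saturates until division relieves it, and decays
    # back toward the baseline size once the signal fades
    for ids in grown:
        tv = np.minimum(state.target_volume[ids], cfg.target_volume_cap)
        state.target_volume[ids] = tv - cfg.target_relax * (tv - cfg.target_volume)
    # quiescent fibroblasts condense gradually toward their resting size
    qf_ids = state.cell_ids(K.T_QF)
    state.target_volume[qf_ids] -= cfg.qf_condense_rate * (
        state.target_volume[qf_ids] - cfg.qf_target_volume
    )
    _divide_ready_cells(state, grow_types)


def _divide_ready_cells(state: TissueState, types) -> None:
    cfg = state.config
    ids = state.cell_ids(*types)
    ready = ids[state.volume[ids] >= cfg.division_volume]
    if ready.size == 0:
        return
    where = np.isin(state.lattice, ready)
    ys, xs = np.nonzero(where)
    owner = state.lattice[ys, xs]
    for cid in ready:
        sel = owner == cid
        py, px = ys[sel], xs[sel]
        if py.size < 2:
            continue
        cy, cx = py.mean(), px.mean()
        ang = state.rng.uniform(0, 2 * math.pi)
        side = (px - cx) * math.cos(ang) + (py - cy) * math.sin(ang) > 0
        if not side.any() or side.all():
            continue  # degenerate split; retry next MCS
        child = state.new_cell(
            int(state.type_of[cid]),
            lineage=int(state.lineage[cid]),
            target=state.target_volume[cid] / 2.0,
        )
        state.target_volume[cid] /= 2.0
        state.lattice[py[side], px[side]] = child
        moved = int(side.sum())
        state.volume[child] += moved
        state.volume[cid] -= moved


_SHIFTS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _boundary_counts(state: TissueState, cell_type: int, against_type: int):
    """Per-id (boundary pair count, pairs against ``against_type``) for
    cells of ``cell_type``, on the 4-neighbourhood."""
    lat = state.lattice
    tl = state.type_lattice()
    total = np.zeros(state.n_ids)
    hits = np.zeros(state.n_ids)
    for dy, dx in _SHIFTS:
        a = lat[max(dy, 0) or None : min(dy, 0) or None, max(dx, 0) or None : min(dx, 0) or None]
        b = lat[max(-dy, 0) or None : min(-dy, 0) or None, max(-dx, 0) or None : min(-dx, 0) or None]
        ta = tl[max(dy, 0) or None : min(dy, 0) or None, max(dx, 0) or None : min(dx, 0) or None]
        tb = tl[max(-dy, 0) or None : min(-dy, 0) or None, max(-dx, 0) or None : min(-dx, 0) or None]
        m = (a != b) & (ta == cell_type)
        if m.any():
            total += np.bincount(a[m], minlength=state.n_ids)
            mh = m & (tb == against_type)
            if mh.any():
                hits += np.bincount(a[mh], minlength=state.n_ids)
    return total, hits


def transition_update(state: TissueState) -> None:
    """Switch proliferating (and wound-activated) fibroblasts to quiescence
    when more than half of their boundary is in contact with matrix
    (strict inequality).

    Entering quiescence also condenses the cell toward its resting size,
    which frees space that the surrounding matrix then fills -- the lattice
    analogue of matrix progressively replacing cellular volume as the
    tissue matures."""
    for t in (K.T_PF, K.T_ACTIVATED):
        total, ecm = _boundary_counts(state, t, K.T_ECM)
        ids = state.cell_ids(t)
        switch = ids[(total[ids] > 0) & (ecm[ids] > 0.5 * total[ids])]
        state.type_of[switch] = K.T_QF


def _any_neighbor(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= mask[:, :-1]
    out[:, :-1] |= mask[:, 1:]
    return out


def deposition_update(state: TissueState) -> None:
    """Convert free pixels (medium or clot) bordering fibroblasts to matrix.

    Quiescent fibroblasts are the efficient depositors (``p_deposit_qf``);
    proliferating and activated fibroblasts deposit at the lower
    ``p_deposit_pf``.  A pixel with both kinds of neighbour uses the
    quiescent rate.  Free pixels bordering existing matrix but no
    fibroblast convert at ``p_ecm_spread``: deposited collagen matures
    into fibril bundles that extend through the tissue on their own.
    """
    cfg = state.config
    tl = state.type_lattice()
    free = (tl == K.T_MEDIUM) | (tl == K.T_CLOT)
    near_qf = _any_neighbor(tl == K.T_QF)
    near_pf = _any_neighbor((tl == K.T_PF) | (tl == K.T_ACTIVATED))
    near_ecm = _any_neighbor(tl == K.T_ECM)
    p = np.where(
        near_qf,
        cfg.p_deposit_qf,
        np.where(near_pf, cfg.p_deposit_pf, np.where(near_ecm, cfg.p_ecm_spread, 0.0)),
    )
    p = np.where(free, p, 0.0)
    if not np.any(p > 0):
        return
    conv = state.rng.random(p.shape) < p
    if not conv.any():
        return
    ys, xs = np.nonzero(conv)
    old = state.lattice[ys, xs]
    dec = np.bincount(old, minlength=state.n_ids)
    state.volume[: state.n_ids] -= dec
    state.lattice[ys, xs] = K.ID_ECM
    state.volume[K.ID_ECM] += ys.size
    _compaction(state)


def _compaction(state: TissueState) -> None:
    """Matrix squeezes fibroblasts that exceed their target volume.

    An ECM-bordering pixel of an over-sized fibroblast converts to matrix
    with probability ``p_ecm_compact`` until the cell is back at target.
    This lets condensing quiescent cells actually give up their volume in
    mature, fully matrix-embedded tissue where no free medium remains.
    """
    cfg = state.config
    if cfg.p_ecm_compact <= 0:
        return
    tl = state.type_lattice()
    fib = np.isin(tl, _FIBROBLAST_TYPES)
    cand = fib & _any_neighbor(tl == K.T_ECM)
    if not cand.any():
        return
    ids = state.lattice[cand]
    over = state.volume[: state.n_ids] > state.target_volume[: state.n_ids] + 0.5
    cand_over = cand.copy()
    cand_over[cand] = over[ids]
    if not cand_over.any():
        return
    take = cand_over & (state.rng.random(cand_over.shape) < cfg.p_ecm_compact)
    if not take.any():
        return
    ys, xs = np.nonzero(take)
    # honour per-cell budgets: never squeeze below target
    order = state.rng.permutation(ys.size)
    room = state.volume[: state.n_ids] - state.target_volume[: state.n_ids]
    for i in order:
        cid = state.lattice[ys[i], xs[i]]
        if room[cid] >= 1.0:
            state.lattice[ys[i], xs[i]] = K.ID_ECM
            state.volume[cid] -= 1.0
            state.volume[K.ID_ECM] += 1.0
            room[cid] -= 1.0


def adipocyte_update(state: TissueState) -> None:
    """After the onset MCS, fibroblasts touching the body wall (lumen)
    differentiate into adipocytes; the conversion is terminal."""
    if state.mcs <= state.config.adipocyte_onset_mcs:
        return
    tl = state.type_lattice()
    near_lumen = _any_neighbor(tl == K.T_LUMEN)
    touching = np.unique(state.lattice[near_lumen & np.isin(tl, _FIBROBLAST_TYPES)])
    touching = touching[touching >= K.FIRST_CELL_ID]
    state.type_of[touching] = K.T_ADIPOCYTE


def apply_wound_cpm(state: TissueState) -> None:
    """Cut a radial slice at the configured wound MCS.

    The slice (a wedge from the body wall through the epidermis) loses all
    cells, matrix and gradients; its dermal part is filled with a blood
    clot infiltrated by immune cells that source the wound signal.
    Quiescent fibroblasts within the activation radius become activated
    (proliferating-like rates, wound-field chemotaxis), and the epidermis
    is unfrozen so it can grow and chemotax to close the wound.
    """
    cfg = state.config
    if state.mcs != cfg.wound_mcs:
        raise ValueError(f"wound must be applied at MCS {cfg.wound_mcs}, not {state.mcs}")
    wedge = (np.abs(state.angle) <= cfg.wound_halfangle) & (
        state.radius > cfg.lumen_radius
    )
    dermal = wedge & (state.radius < cfg.epidermis_inner_radius)
    removed = state.lattice[wedge]
    dec = np.bincount(removed, minlength=state.n_ids)
    state.volume[: state.n_ids] -= dec
    state.lattice[wedge] = K.ID_MEDIUM
    state.volume[K.ID_MEDIUM] += int(wedge.sum())
    # clot fills the dermal part
    n_clot = int(dermal.sum())
    state.lattice[dermal] = K.ID_CLOT
    state.volume[K.ID_MEDIUM] -= n_clot
    state.volume[K.ID_CLOT] += n_clot
    # immune cells: small blocks inside the clot
    ys, xs = np.nonzero(dermal)
    order = state.rng.permutation(ys.size)
    placed = 0
    for i in order:
        if placed >= cfg.n_immune_cells:
            break
        y, x = ys[i], xs[i]
        sl = (slice(y, y + 2), slice(x, x + 2))
        if state.lattice[sl].shape != (2, 2) or not np.all(state.lattice[sl] == K.ID_CLOT):
            continue
        cid = state.new_cell(K.T_IMMUNE, target=4.0)
        state.lattice[sl] = cid
        state.volume[cid] += 4
        state.volume[K.ID_CLOT] -= 4
        placed += 1
    # activation of nearby quiescent fibroblasts
    dist = ndimage.distance_transform_edt(~wedge)
    qf_ids = state.cell_ids(K.T_QF, K.T_PF)
    if qf_ids.size:
        flat = state.lattice.ravel()
        ysum = np.bincount(flat, weights=np.indices(state.lattice.shape)[0].ravel(), minlength=state.n_ids)
        xsum = np.bincount(flat, weights=np.indices(state.lattice.shape)[1].ravel(), minlength=state.n_ids)
        cnt = np.bincount(flat, minlength=state.n_ids)
        for cid in qf_ids:
            if cnt[cid] == 0:
                continue
            cy = int(round(ysum[cid] / cnt[cid]))
            cx = int(round(xsum[cid] / cnt[cid]))
            if dist[cy, cx] <= cfg.activation_radius:
                state.type_of[cid] = K.T_ACTIVATED
    # unfreeze the epidermis; start the wound-signal clock
    for b in (K.T_MEDIUM, K.T_CLOT, K.T_IMMUNE, K.T_EPIDERMIS, K.T_PF, K.T_QF, K.T_ACTIVATED, K.T_ADIPOCYTE):
        state.move_ok[K.T_EPIDERMIS, b] = True
    for a in (K.T_MEDIUM, K.T_PF, K.T_QF, K.T_ACTIVATED, K.T_ADIPOCYTE):
        state.move_ok[a, K.T_EPIDERMIS] = True
    state.chemo_coeff[K.T_ACTIVATED] = cfg.chemotaxis_activated
    state.chemo_coeff[K.T_EPIDERMIS] = cfg.chemotaxis_epidermis
    state.wounded = True
    state.wound_mask = dermal
    state.wound_field = np.zeros_like(state.wound_field)
    update_fields(state)


def mcs_step(state: TissueState) -> None:
    """Advance one Monte Carlo step.

    Fixed update order: Metropolis sweep, growth/division, quiescence
    transition, matrix deposition, adipocyte differentiation, field
    relaxation.
    """
    cfg = state.config
    L = cfg.size
    n_attempts = L * L
    sites = state.rng.integers(0, L * L, size=n_attempts, dtype=np.int64)
    neigh = state.rng.integers(0, 4, size=n_attempts, dtype=np.int64)
    acc = state.rng.random(n_attempts)
    K.metropolis_sweep(
        state.lattice,
        state.type_of,
        state.volume,
        state.target_volume,
        state.J,
        state.has_volume,
        state.move_ok,
        cfg.lambda_volume,
        cfg.temperature,
        cfg.ecm_stiffness,
        state.chemo_coeff,
        state.wound_field,
        sites,
        neigh,
        acc,
    )
    state.mcs += 1
    growth_update(state)
    transition_update(state)
    deposition_update(state)
    adipocyte_update(state)
    update_fields(state)


# ---------------------------------------------------------------------------
# lineage labelling


def label_lineage(state: TissueState, region: str) -> int:
    """Label all fibroblasts whose centroid lies in the named dermal band
    (``upper`` / ``middle`` / ``lower`` third by normalised depth).
    Returns the number of labelled cells; raises if the region is empty."""
    code = _REGION_CODE[region]
    lo, hi = {LABEL_UPPER: (0, 1 / 3), LABEL_MIDDLE: (1 / 3, 2 / 3), LABEL_LOWER: (2 / 3, 1.0001)}[code]
    ids = state.cell_ids(*_FIBROBLAST_TYPES)
    if ids.size == 0:
        raise ValueError("no fibroblasts to label")
    flat = state.lattice.ravel()
    dsum = np.bincount(flat, weights=state.depth.ravel(), minlength=state.n_ids)
    cnt = np.bincount(flat, minlength=state.n_ids)
    mean_depth = dsum[ids] / np.maximum(cnt[ids], 1)
    chosen = ids[(mean_depth >= lo) & (mean_depth < hi)]
    if chosen.size == 0:
        raise ValueError(f"no fibroblasts in the {region} region")
    state.lineage[chosen] = code
    return int(chosen.size)


# ---------------------------------------------------------------------------
# metrics & drivers


@dataclass
class TissueMetrics:
    """Per-MCS observables of a simulation run."""

    records: dict = field(default_factory=dict)

    def append(self, **kv) -> None:
        for k, v in kv.items():
            self.records.setdefault(k, []).append(v)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def col(self, name: str) -> np.ndarray:
        return np.asarray(self.records[name])


def _record_metrics(state: TissueState, metrics: TissueMetrics) -> None:
    counts = {}
    ids = np.arange(K.FIRST_CELL_ID, state.n_ids)
    alive = ids[state.volume[ids] > 0]
    tt = state.type_of[alive]
    for t, name in ((K.T_EPIDERMIS, "n_epidermis"), (K.T_PF, "n_pf"), (K.T_QF, "n_qf"),
                    (K.T_ACTIVATED, "n_activated"), (K.T_ADIPOCYTE, "n_adipocyte"),
                    (K.T_IMMUNE, "n_immune")):
        counts[name] = int((tt == t).sum())
    n_fib = counts["n_pf"] + counts["n_qf"] + counts["n_activated"]
    pf_frac = 100.0 * (counts["n_pf"] + counts["n_activated"]) / n_fib if n_fib else 0.0
    tl = state.type_lattice()
    ecm_px = int((tl == K.T_ECM).sum())
    dermis_area = int(state.dermis_mask.sum())
    row = dict(
        mcs=state.mcs,
        **counts,
        n_fibroblasts=n_fib,
        pf_percent=pf_frac,
        ecm_pixels=ecm_px,
        ecm_fraction=ecm_px / dermis_area,
    )
    fib_px = np.isin(tl, _FIBROBLAST_TYPES + (K.T_ADIPOCYTE,))
    for code, name in ((LABEL_UPPER, "upper"), (LABEL_LOWER, "lower"), (LABEL_MIDDLE, "middle")):
        m = fib_px & (state.lineage[state.lattice] == code)
        n = int(m.sum())
        if n:
            d = state.depth[m]
            row[f"lin_{name}_pixels"] = n
            row[f"lin_{name}_mean_depth"] = float(d.mean())
            row[f"lin_{name}_frac_upper3"] = float((d < 1 / 3).mean())
            row[f"lin_{name}_frac_lower3"] = float((d > 2 / 3).mean())
            row[f"lin_{name}_frac_lower23"] = float((d > 1 / 3).mean())
        else:
            row[f"lin_{name}_pixels"] = 0
            row[f"lin_{name}_mean_depth"] = np.nan
            row[f"lin_{name}_frac_upper3"] = np.nan
            row[f"lin_{name}_frac_lower3"] = np.nan
            row[f"lin_{name}_frac_lower23"] = np.nan
    wm = state.wound_mask
    if wm.any():
        row["wound_fibroblast_pixels"] = int((np.isin(tl, _FIBROBLAST_TYPES) & wm).sum())
        row["wound_ecm_pixels"] = int(((tl == K.T_ECM) & wm).sum())
        row["wound_clot_pixels"] = int(((tl == K.T_CLOT) & wm).sum())
    else:
        row["wound_fibroblast_pixels"] = 0
        row["wound_ecm_pixels"] = 0
        row["wound_clot_pixels"] = 0
    metrics.append(**row)


def run(
    config: CpmConfig,
    label_region: Optional[str] = None,
    label_mcs: Optional[int] = None,
    with_wound: bool = True,
    check_every: int = 100,
) -> tuple[TissueMetrics, TissueState]:
    """Run maturation (and wounding, if the schedule reaches it) to
    ``end_mcs``, recording metrics each MCS."""
    state = init_tissue(config)
    metrics = TissueMetrics()
    _record_metrics(state, metrics)
    for m in range(1, config.end_mcs + 1):
        if label_region is not None and label_mcs == state.mcs and not state.lineage.any():
            label_lineage(state, label_region)
        if with_wound and state.mcs == config.wound_mcs and not state.wounded:
            apply_wound_cpm(state)
        mcs_step(state)
        _record_metrics(state, metrics)
        if check_every and m % check_every == 0:
            state.check_volumes()
    return metrics, state


def lineage_trace(
    config: CpmConfig,
    label_region: str,
    label_mcs: int,
    with_wound: bool = False,
) -> dict:
    """In-silico lineage tracing: run the model, label one dermal band at
    ``label_mcs``, and report the labelled clone's dispersal.

    Returns mean normalised depth and band occupancies at labelling time
    and at the end of the run.
    """
    if label_mcs >= config.end_mcs:
        raise ValueError("label_mcs must precede the end of the simulation")
    metrics, state = run(config, label_region=label_region, label_mcs=label_mcs, with_wound=with_wound)
    name = label_region
    mcs_col = metrics.col("mcs")
    i0 = int(np.searchsorted(mcs_col, label_mcs + 1))
    return {
        "region": name,
        "label_mcs": label_mcs,
        "n_labelled_pixels_start": int(metrics.col(f"lin_{name}_pixels")[i0]),
        "n_labelled_pixels_end": int(metrics.col(f"lin_{name}_pixels")[-1]),
        "mean_depth_start": float(metrics.col(f"lin_{name}_mean_depth")[i0]),
        "mean_depth_end": float(metrics.col(f"lin_{name}_mean_depth")[-1]),
        "frac_upper3_end": float(metrics.col(f"lin_{name}_frac_upper3")[-1]),
        "frac_lower3_end": float(metrics.col(f"lin_{name}_frac_lower3")[-1]),
        "frac_lower23_end": float(metrics.col(f"lin_{name}_frac_lower23")[-1]),
        "metrics": metrics,
    }
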