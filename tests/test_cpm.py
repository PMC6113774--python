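"""Cellular Potts tissue model: kernels, update rules, protocols, bookkeeping."""

import math

import numpy as np
import pytest

from dermadyn.cpm import CpmConfig, init_tissue, load_config, mcs_step, run, save_config
from dermadyn.cpm import _kernels as K
from dermadyn.cpm.tissue import (
    TissueState,
    adipocyte_update,
    apply_wound_cpm,
    deposition_update,
    epidermis_ring_closed,
    growth_update,
    label_lineage,
    transition_update,
    update_fields,
)


@pytest.fixture()
def small_config():
    return CpmConfig(
        size=64,
        lumen_radius=14.0,
        epidermis_inner_radius=24.0,
        epidermis_thickness=3.0,
        n_epidermal_cells=16,
        fibroblast_spoke_halfangle=0.09,
        end_mcs=60,
        wound_mcs=40,
        wound_halfangle=0.3,
        adipocyte_onset_mcs=20,
        seed=5,
    )


def blank_state(cfg):
    """A state with reserved domain types registered but an all-medium lattice."""
    st = TissueState(cfg)
    st.type_of[K.ID_LUMEN] = K.T_LUMEN
    st.type_of[K.ID_ECM] = K.T_ECM
    st.type_of[K.ID_CLOT] = K.T_CLOT
    return st


class TestInit:
    def test_ten_fibroblasts_and_closed_ring(self, small_config):
        st = init_tissue(small_config)
        assert st.cell_ids(K.T_PF).size == 10
        assert st.cell_ids(K.T_QF).size == 0
        assert epidermis_ring_closed(st)

    def test_pixel_conservation(self, small_config):
        st = init_tissue(small_config)
        assert st.recount_volumes().sum() == small_config.size**2
        st.check_volumes()

    def test_spokes_touch_wall_and_epidermis(self, small_config):
        st = init_tissue(small_config)
        tl = st.type_lattice()
        fib = np.isin(tl, (K.T_PF,))
        r = st.radius[fib]
        assert r.min() < small_config.lumen_radius + 2
        assert r.max() > small_config.epidermis_inner_radius - 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CpmConfig(size=32)
        with pytest.raises(ValueError):
            CpmConfig(p_deposit_qf=1.5)

    def test_config_roundtrip(self, small_config, tmp_path):
        path = tmp_path / "cfg.toml"
        save_config(small_config, path)
        assert load_config(path) == small_config


class TestMetropolis:
    def _two_cell_state(self, cfg):
        st = blank_state(cfg)
        a = st.new_cell(K.T_PF)
        b = st.new_cell(K.T_QF)
        st.lattice[10:14, 10:14] = a
        st.lattice[10:14, 14:18] = b
        st.volume[: st.n_ids] = st.recount_volumes()
        st.target_volume[a] = st.volume[a]
        st.target_volume[b] = st.volume[b]
        return st, a, b

    def test_zero_temperature_rejects_uphill(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, temperature=1e-9)
        st, a, b = self._two_cell_state(cfg)
        before = st.lattice.copy()
        e0 = _total_energy_proxy(st)
        for _ in range(20):
            mcs_args = _sweep_args(st, cfg)
            K.metropolis_sweep(*mcs_args)
        assert _total_energy_proxy(st) <= e0 + 1e-9

    def test_pixel_count_conserved_by_sweep(self, small_config):
        st, a, b = self._two_cell_state(small_config)
        for _ in range(5):
            K.metropolis_sweep(*_sweep_args(st, small_config))
        st.check_volumes()
        assert st.recount_volumes().sum() == small_config.size**2

    def test_acceptance_matches_boltzmann(self, small_config):
        # fixed single-copy attempt, many independent trials: empirical
        # acceptance must match exp(-dH/T) for an uphill move
        st, a, b = self._two_cell_state(small_config)
        sx, sy, nx, ny = 12, 13, 12, 14  # b's pixel (nx,ny) copying into a's (sx,sy)
        dh = K.copy_attempt_delta_h(
            st.lattice, st.type_of, st.volume, st.target_volume, st.J,
            st.has_volume, small_config.lambda_volume, small_config.ecm_stiffness,
            st.chemo_coeff, st.wound_field, sx, sy, nx, ny,
        )
        p_expect = min(1.0, math.exp(-dh / small_config.temperature))
        assert 0.02 < p_expect < 0.98, "toy configuration must be probabilistic"
        rng = np.random.default_rng(0)
        lattice0 = st.lattice.copy()
        vol0 = st.volume.copy()
        hits = 0
        trials = 4000
        site = np.array([sx * small_config.size + sy], dtype=np.int64)
        neigh = np.array([2], dtype=np.int64)  # (dx,dy)=(0,+1): neighbour (12,14)
        for _ in range(trials):
            st.lattice[:] = lattice0
            st.volume[:] = vol0
            acc = rng.random(1)
            n = K.metropolis_sweep(
                st.lattice, st.type_of, st.volume, st.target_volume, st.J,
                st.has_volume, st.move_ok, small_config.lambda_volume,
                small_config.temperature, small_config.ecm_stiffness,
                st.chemo_coeff, st.wound_field, site, neigh, acc,
            )
            hits += n
        se = math.sqrt(p_expect * (1 - p_expect) / trials)
        assert hits / trials == pytest.approx(p_expect, abs=5 * se)

    def test_frozen_domains_never_move(self, small_config):
        st = init_tissue(small_config)
        lumen0 = st.lattice == K.ID_LUMEN
        for _ in range(10):
            mcs_step(st)
        assert np.array_equal(st.lattice == K.ID_LUMEN, lumen0)
        assert np.all(st.type_of[st.lattice][lumen0] == K.T_LUMEN)


def _sweep_args(st, cfg):
    n = cfg.size * cfg.size
    return (
        st.lattice, st.type_of, st.volume, st.target_volume, st.J,
        st.has_volume, st.move_ok, cfg.lambda_volume, cfg.temperature,
        cfg.ecm_stiffness, st.chemo_coeff, st.wound_field,
        st.rng.integers(0, n, n), st.rng.integers(0, 4, n), st.rng.random(n),
    )


def _total_energy_proxy(st):
    # contact + volume energy of the whole lattice (chemotaxis-free states)
    tl = st.type_lattice()
    e = 0.0
    for sl_a, sl_b in (((slice(1, None), slice(None)), (slice(None, -1), slice(None))),
                       ((slice(None), slice(1, None)), (slice(None), slice(None, -1)))):
        ids_a, ids_b = st.lattice[sl_a], st.lattice[sl_b]
        m = ids_a != ids_b
        e += st.J[tl[sl_a][m], tl[sl_b][m]].sum()
    ids = np.arange(K.FIRST_CELL_ID, st.n_ids)
    hv = st.has_volume[st.type_of[ids]]
    e += (st.config.lambda_volume * (st.volume[ids][hv] - st.target_volume[ids][hv]) ** 2).sum()
    return e


class TestGrowth:
    def test_zero_field_no_growth(self, small_config):
        st = init_tissue(small_config)
        st.epi_field[:] = 0.0
        before = st.target_volume[: st.n_ids].copy()
        growth_update(st)
        ids = st.cell_ids(K.T_PF)
        # only the relaxation toward baseline may act; no signal-driven gain
        assert np.all(st.target_volume[ids] <= before[ids] + 1e-12)

    def test_increment_proportional_to_field(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, target_relax=0.0)
        gains = []
        for scale in (0.5, 1.0):
            st = init_tissue(cfg)
            st.epi_field[:] = scale
            ids = st.cell_ids(K.T_PF)
            before = st.target_volume[ids].copy()
            growth_update(st)
            gains.append((st.target_volume[ids] - before).mean())
        assert gains[1] == pytest.approx(2 * gains[0], rel=1e-9)

    def test_division_partitions_parent_pixels(self, small_config):
        st = blank_state(small_config)
        cid = st.new_cell(K.T_PF, lineage=2)
        st.lattice[20:28, 20:28] = cid
        st.volume[: st.n_ids] = st.recount_volumes()
        st.target_volume[cid] = 64.0
        parent_pixels = set(map(tuple, np.argwhere(st.lattice == cid)))
        st.epi_field[:] = 0.0
        growth_update(st)
        child = st.n_ids - 1
        assert child != cid and st.type_of[child] == K.T_PF
        assert st.lineage[child] == 2
        a = set(map(tuple, np.argwhere(st.lattice == cid)))
        b = set(map(tuple, np.argwhere(st.lattice == child)))
        assert a | b == parent_pixels and not (a & b)
        assert st.volume[cid] == len(a) and st.volume[child] == len(b)
        # both children receive half the parent's (capped, relaxed) drive
        assert st.target_volume[cid] == st.target_volume[child]
        assert st.target_volume[cid] <= 32.0


class TestTransition:
    def _pf_with_contacts(self, cfg, n_ecm):
        st = blank_state(cfg)
        cid = st.new_cell(K.T_PF)
        st.lattice[30, 30] = cid
        nbrs = [(29, 30), (31, 30), (30, 29), (30, 31)]
        for y, x in nbrs[:n_ecm]:
            st.lattice[y, x] = K.ID_ECM
        st.volume[: st.n_ids] = st.recount_volumes()
        return st, cid

    def test_above_half_switches(self, small_config):
        st, cid = self._pf_with_contacts(small_config, 3)
        transition_update(st)
        assert st.type_of[cid] == K.T_QF

    def test_exactly_half_stays(self, small_config):
        st, cid = self._pf_with_contacts(small_config, 2)
        transition_update(st)
        assert st.type_of[cid] == K.T_PF

    def test_no_contact_stays(self, small_config):
        st, cid = self._pf_with_contacts(small_config, 0)
        transition_update(st)
        assert st.type_of[cid] == K.T_PF

    def test_quiescence_never_reverts_in_homeostasis(self, small_config):
        st, cid = self._pf_with_contacts(small_config, 4)
        transition_update(st)
        assert st.type_of[cid] == K.T_QF
        for _ in range(3):
            transition_update(st)
            deposition_update(st)
        assert st.type_of[cid] == K.T_QF


class TestDeposition:
    def _qf_island(self, cfg, p_qf, p_pf=0.0):
        import dataclasses

        cfg = dataclasses.replace(cfg, p_deposit_qf=p_qf, p_deposit_pf=p_pf, p_ecm_spread=0.0, p_ecm_compact=0.0)
        st = blank_state(cfg)
        cid = st.new_cell(K.T_QF)
        st.lattice[30:32, 30:32] = cid
        st.volume[: st.n_ids] = st.recount_volumes()
        st.target_volume[cid] = st.volume[cid]
        return st, cid

    def test_zero_rates_no_matrix(self, small_config):
        st, _ = self._qf_island(small_config, 0.0)
        deposition_update(st)
        assert st.volume[K.ID_ECM] == 0

    def test_saturation_at_probability_one(self, small_config):
        st, cid = self._qf_island(small_config, 1.0)
        deposition_update(st)
        # every medium pixel 4-adjacent to the 2x2 island converts at once
        assert st.volume[K.ID_ECM] == 8
        st.check_volumes()

    def test_long_run_rate_matches_binomial(self, small_config):
        p = 0.3
        trials, converted = 400, 0
        for s in range(trials):
            st, _ = self._qf_island(small_config, p)
            st.rng = np.random.default_rng(s)
            deposition_update(st)
            converted += int(st.volume[K.ID_ECM])
        n_candidates = 8
        mean = converted / trials
        se = math.sqrt(n_candidates * p * (1 - p) / trials)
        assert mean == pytest.approx(n_candidates * p, abs=5 * se)


class TestAdipocyte:
    def _wall_toucher(self, cfg):
        st = blank_state(cfg)
        st.lattice[st.radius <= cfg.lumen_radius] = K.ID_LUMEN
        cid = st.new_cell(K.T_QF)
        ys, xs = np.nonzero(st.radius <= cfg.lumen_radius)
        y = ys.max()  # bottom of the lumen disc
        x = xs[ys == y][0]
        st.lattice[y + 1, x] = cid
        far = st.new_cell(K.T_QF)
        st.lattice[5, 5] = far
        st.volume[: st.n_ids] = st.recount_volumes()
        return st, cid, far

    def test_no_conversion_before_onset(self, small_config):
        st, cid, far = self._wall_toucher(small_config)
        st.mcs = small_config.adipocyte_onset_mcs  # rule requires mcs > onset
        adipocyte_update(st)
        assert st.type_of[cid] == K.T_QF

    def test_wall_contact_required_and_terminal(self, small_config):
        st, cid, far = self._wall_toucher(small_config)
        st.mcs = small_config.adipocyte_onset_mcs + 1
        adipocyte_update(st)
        assert st.type_of[cid] == K.T_ADIPOCYTE
        assert st.type_of[far] == K.T_QF
        adipocyte_update(st)
        assert st.type_of[cid] == K.T_ADIPOCYTE


class TestFields:
    def test_epidermal_field_peaks_at_source_and_decays_with_age(self, small_config):
        st = init_tissue(small_config)
        for _ in range(30):
            update_fields(st)
        tl = st.type_lattice()
        src = st.epi_field[tl == K.T_EPIDERMIS].mean()
        interior = st.epi_field[st.radius < small_config.lumen_radius].mean()
        assert src > interior
        amp0 = st.epi_field.max()
        st.mcs = 300
        for _ in range(30):
            update_fields(st)
        assert st.epi_field.max() < amp0

    def test_no_wound_field_before_wounding(self, small_config):
        st = init_tissue(small_config)
        for _ in range(10):
            mcs_step(st)
        assert np.all(st.wound_field == 0)


class TestWoundProtocol:
    def test_wrong_mcs_rejected(self, small_config):
        st = init_tissue(small_config)
        with pytest.raises(ValueError, match="MCS"):
            apply_wound_cpm(st)

    def test_slice_cleared_and_filled(self, small_config):
        st = init_tissue(small_config)
        while st.mcs < small_config.wound_mcs:
            mcs_step(st)
        tl_before = st.type_lattice()
        outside_cells = st.lattice.copy()
        apply_wound_cpm(st)
        tl = st.type_lattice()
        wedge = (np.abs(st.angle) <= small_config.wound_halfangle) & (
            st.radius > small_config.lumen_radius
        )
        dermal = wedge & (st.radius < small_config.epidermis_inner_radius)
        assert not np.any(tl[dermal] == K.T_ECM)
        assert np.any(tl[dermal] == K.T_CLOT)
        assert st.cell_ids(K.T_IMMUNE).size == small_config.n_immune_cells
        # pixels far from the wedge are untouched
        far = ~wedge
        assert np.array_equal(st.lattice[far], outside_cells[far])
        st.check_volumes()

    def test_activation_radius(self, small_config):
        st = init_tissue(small_config)
        while st.mcs < small_config.wound_mcs:
            mcs_step(st)
        qf_before = set(st.cell_ids(K.T_QF, K.T_PF))
        apply_wound_cpm(st)
        act = st.cell_ids(K.T_ACTIVATED)
        assert act.size > 0
        for cid in act:  # activation only converts pre-existing fibroblasts
            assert cid in qf_before
        # fibroblasts on the far side of the ring stay unactivated
        far_unactivated = [
            cid
            for cid in st.cell_ids(K.T_QF, K.T_PF)
            if np.mean(np.abs(st.angle[st.lattice == cid])) > math.pi / 2
        ]
        assert far_unactivated, "expected untouched fibroblasts far from the wound"


class TestRunAndLineage:
    def test_determinism(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, end_mcs=30, wound_mcs=10**9)
        m1, _ = run(cfg, with_wound=False)
        m2, _ = run(cfg, with_wound=False)
        assert m1.records == m2.records

    def test_metrics_schema_and_conservation(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, end_mcs=25, wound_mcs=10**9)
        metrics, st = run(cfg, with_wound=False, check_every=5)
        df = metrics.to_frame()
        assert len(df) == cfg.end_mcs + 1
        assert (df.n_pf + df.n_qf + df.n_activated == df.n_fibroblasts).all()
        assert df.pf_percent.between(0, 100).all()
        st.check_volumes()

    def test_labels_inherited(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, end_mcs=40, wound_mcs=10**9)
        st = init_tissue(cfg)
        # at initialisation the spokes span the dermis, so centroids sit mid-depth
        n = label_lineage(st, "middle")
        assert n > 0
        labelled_before = set(st.cell_ids()) & set(np.nonzero(st.lineage[: st.n_ids])[0])
        for _ in range(30):
            mcs_step(st)
        from dermadyn.cpm.tissue import LABEL_MIDDLE

        labelled_now = [cid for cid in st.cell_ids() if st.lineage[cid] == LABEL_MIDDLE]
        # every labelled cell is an original labelled cell or a descendant
        for cid in labelled_now:
            assert cid in labelled_before or st.birth_mcs[cid] > 0

    def test_empty_region_errors(self, small_config):
        st = blank_state(small_config)
        cid = st.new_cell(K.T_PF)
        st.lattice[5, 32] = cid  # near the top edge: depth 0 (upper)
        st.volume[: st.n_ids] = st.recount_volumes()
        with pytest.raises(ValueError):
            label_lineage(st, "lower")
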