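"""Assembly engine: initialization, stepping invariants, census math,
first-passage bookkeeping and trajectory outcomes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capsidyn.engine import (
    ClusterCensus,
    ConfigError,
    SimulationConfig,
    census,
    ensemble_yield,
    initialize_world,
    phase_of,
    run,
    step,
)
from capsidyn.geometry import build_blueprint
from capsidyn.reactions import STATE_LOCKED


def _cfg(bp, **kw):
    base = dict(N=20, L=20.0, k_a=5.0, k_d=1.35e-2, max_time=100.0,
                seed=1, record_interval=50.0, mode=bp.meta.get("mode", "direct"))
    base.update(kw)
    return SimulationConfig(blueprint=bp, **base)


def _min_image_distances(w):
    d = w.mon_wpos[:, None, :] - w.mon_wpos[None, :, :]
    d -= w.L * np.round(d / w.L)
    dist = np.sqrt((d * d).sum(-1))
    return dist[np.triu_indices(len(dist), 1)]


class TestInitialization:
    def test_standard_t1_box_is_4p5_millimolar(self, bp_t1_direct):
        cfg = _cfg(bp_t1_direct, N=60, L=28.0)
        assert cfg.concentration_molar * 1e3 == pytest.approx(4.5, abs=0.05)

    def test_nonoverlapping_random_placement(self, bp_t1_direct):
        w = initialize_world(_cfg(bp_t1_direct, N=60, L=28.0))
        assert _min_image_distances(w).min() >= 2 * bp_t1_direct.R

    def test_same_seed_identical_world(self, bp_t1_direct):
        w1 = initialize_world(_cfg(bp_t1_direct, N=30, seed=9))
        w2 = initialize_world(_cfg(bp_t1_direct, N=30, seed=9))
        assert np.array_equal(w1.mon_wpos, w2.mon_wpos)
        assert np.array_equal(w1.mon_wrot, w2.mon_wrot)

    def test_zero_monomers_rejected(self, bp_t1_direct):
        with pytest.raises(ConfigError):
            initialize_world(_cfg(bp_t1_direct, N=0))

    def test_rate_timestep_product_validated(self, bp_t1_direct):
        with pytest.raises(ConfigError, match="k_a"):
            initialize_world(_cfg(bp_t1_direct, k_a=11.0))

    def test_overpacked_box_rejected(self, bp_t1_direct):
        with pytest.raises(ConfigError, match="packing"):
            initialize_world(_cfg(bp_t1_direct, N=100, L=5.0,
                                  insertion_attempts=50))

    @pytest.mark.parametrize("N, per_type", [(180, 60), (198, 66), (216, 72)])
    def test_t3_type_stoichiometry_scales_proportionally(self, bp_t3, N, per_type):
        w = initialize_world(_cfg(bp_t3, N=N, L=60.0, mode="hierarchical"))
        counts = np.bincount(w.mon_type, minlength=3)
        assert (counts == per_type).all()

    def test_hierarchical_initial_state_two_active_patches(self, bp_t1):
        w = initialize_world(_cfg(bp_t1, mode="hierarchical", N=10))
        per_monomer = np.zeros(10, dtype=int)
        for p in range(len(w.patch_state)):
            if w.patch_state[p] == 1:
                per_monomer[w.patch_mon[p]] += 1
        assert (per_monomer == 2).all()


class TestStepping:
    def test_monomer_conservation(self, bp_t1_direct):
        w = initialize_world(_cfg(bp_t1_direct, N=40, L=22.0))
        for _ in range(300):
            step(w)
            assert w.monomer_count_check() == 40

    def test_zero_rates_leave_bonds_unchanged(self, bp_t1_direct):
        w = initialize_world(_cfg(bp_t1_direct, k_a=0.0, k_d=0.0, N=30, L=18.0))
        for _ in range(200):
            step(w)
        assert w.bond_list().size == 0
        assert w.n_clusters == 30

    def test_steric_invariant_after_steps(self, bp_t1_direct):
        w = initialize_world(_cfg(bp_t1_direct, N=40, L=20.0, seed=4))
        for _ in range(500):
            step(w)
        assert _min_image_distances(w).min() >= 2 * bp_t1_direct.R - 1e-6

    def test_identical_seeds_identical_trajectories(self, bp_t1_direct):
        states = []
        for _ in range(2):
            w = initialize_world(_cfg(bp_t1_direct, N=30, L=18.0, seed=17))
            for _ in range(250):
                step(w)
            states.append((w.mon_wpos.copy(), w.patch_bond.copy()))
        assert np.array_equal(states[0][0], states[1][0])
        assert np.array_equal(states[0][1], states[1][1])

    def test_hierarchical_safety_invariant(self, bp_t1):
        """No inter-capsomer bond may ever connect monomers that are not
        members of completed (locked) capsomers."""
        w = initialize_world(
            _cfg(bp_t1, mode="hierarchical", N=30, L=16.0, k_a=9.0, k_d=1.5e-3,
                 seed=8)
        )
        for i in range(3000):
            step(w)
            if i % 100 == 0 or w.ring_events:
                for p in np.nonzero(w.patch_bond >= 0)[0]:
                    if w.tables.class_kind[w.patch_class[p]] == 1:  # inter
                        m = int(w.patch_mon[p])
                        base = w.mon_patch_start[m]
                        t = w.mon_type[m]
                        intra_locked = [
                            w.patch_state[base + loc] == STATE_LOCKED
                            for loc in range(w.tables.type_patch_count[t])
                            if w.tables.class_kind[
                                w.patch_class[base + loc]] == 0
                        ]
                        assert all(intra_locked)


class TestCensus:
    def test_all_monomers(self, bp_t1_direct):
        w = initialize_world(_cfg(bp_t1_direct, N=20))
        c = census(w)
        assert c.nu[0] == 20 and c.nbar == 1.0

    def test_hand_evaluated_mixture(self):
        # one 30-mer plus thirty monomers, N = n_f = 60:
        # nbar = (30/60)*30 + (30/60)*1 = 15.5
        nu = np.zeros(60)
        nu[0] = 30
        nu[29] = 1
        c = ClusterCensus(t=0.0, nu=nu, N=60)
        assert c.p.sum() == pytest.approx(1.0)
        assert c.nbar == pytest.approx(15.5)

    def test_single_complete_cluster(self):
        nu = np.zeros(60)
        nu[59] = 1
        assert ClusterCensus(t=0.0, nu=nu, N=60).nbar == 60.0


class TestRunAndObservables:
    def test_zero_horizon_is_censored_monomeric(self, bp_t1_direct):
        series = run(_cfg(bp_t1_direct, N=25, max_time=0.0))
        assert series.outcome == "censored"
        assert series.nu[0][0] == 25
        assert series.fpt == {1: 0.0}

    def test_fpt_nondecreasing_and_recorded(self, bp_t1_direct):
        series = run(_cfg(bp_t1_direct, N=30, L=18.0, max_time=500.0, seed=2))
        sizes = sorted(series.fpt)
        fpts = [series.fpt[s] for s in sizes]
        assert sizes[0] == 1
        assert all(b >= a for a, b in zip(fpts, fpts[1:]))
        assert series.censored

    def test_forced_pentamer_closure_smoke(self, bp_t1):
        cfg = _cfg(bp_t1, mode="hierarchical", N=5, L=28.0, k_a=9.0, k_d=0.0,
                   max_time=100.0, record_interval=10.0)
        w = initialize_world(cfg)
        _, slots = bp_t1.capsomers[0]
        rng = np.random.default_rng(0)
        for m, s in enumerate(slots):
            w.place_monomer(
                m,
                bp_t1.ideal_positions[s] + 10.0 + rng.normal(scale=0.01, size=3),
                Rotation.from_quat(bp_t1.ideal_quats[s]).as_matrix(),
            )
        for _ in range(20000):
            step(w)
            if w.ring_events:
                break
        assert w.ring_events and w.ring_events[0][1] == 5
        (cid,) = w.alive_ids
        assert len(w.clus_members[cid]) == 5

    def test_ensemble_yield_counting(self, bp_t1_direct):
        runs = [run(_cfg(bp_t1_direct, N=8, L=14.0, max_time=60.0, seed=s))
                for s in range(4)]
        y2 = ensemble_yield(runs, 2)
        assert 0.0 <= y2 <= 1.0
        assert ensemble_yield(runs, 1) == 1.0
        assert ensemble_yield(runs, 60) == 0.0
        with pytest.raises(ValueError):
            ensemble_yield([], 2)


class TestPhases:
    @pytest.mark.parametrize(
        "size, expected",
        [(10, "early"), (19, "early"), (20, "intermediate"), (39, "intermediate"),
         (40, "final"), (60, "final")],
    )
    def test_phase_boundaries(self, size, expected):
        assert phase_of(size, 60) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            phase_of(0, 60)
        with pytest.raises(ValueError):
            phase_of(61, 60)
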