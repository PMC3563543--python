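"""Reaction kernel: encounter detection, stochastic binding with snap and
steric rejection, dissociation with cluster splitting, and hierarchical
patch switching."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capsidyn.engine import SimulationConfig, initialize_world, step
from capsidyn.reactions import (
    STATE_ACTIVE,
    STATE_LOCKED,
    ReactionError,
    attempt_association,
    attempt_dissociation,
    detect_encounters,
    update_patch_states,
)


class FixedRng:
    """Deterministic stand-in for the reaction RNG."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, *a):
        return self.values.pop(0)


def _pair_world(bp_t1_direct, gap, face_to_face=True, seed=0, mode="direct", n=2):
    """Two monomers on the x axis, patch-centre distance ``gap`` between
    monomer 0's inter patch (+x) and monomer 1's inter patch (-x)."""
    cfg = SimulationConfig(
        blueprint=bp_t1_direct, mode=mode, N=n, L=28.0,
        k_a=5.0, k_d=1.35e-2, max_time=10.0, seed=seed,
    )
    w = initialize_world(cfg)
    t = w.tables
    cls_inter = t.class_pid.index("T1.inter")
    d = t.class_dir[cls_inter]
    rot0, _ = Rotation.align_vectors([[1.0, 0, 0]], [d])
    w.place_monomer(0, np.array([5.0, 5.0, 5.0]), rot0.as_matrix())
    if face_to_face:
        rot1, _ = Rotation.align_vectors([[-1.0, 0, 0]], [d])
    else:
        rot1 = rot0  # inter patch points away from monomer 0
    sep = 2 * bp_t1_direct.R + gap
    w.place_monomer(1, np.array([5.0 + sep, 5.0, 5.0]), rot1.as_matrix())
    return w


class TestEncounterDetection:
    def test_patches_beyond_overlap_distance(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.9)
        assert detect_encounters(w) == []

    def test_overlapping_complementary_patches(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.5)
        events = detect_encounters(w)
        assert len(events) == 1
        assert events[0].separation == pytest.approx(0.5, abs=1e-9)

    def test_non_facing_patches_not_reported(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.5, face_to_face=False)
        assert detect_encounters(w) == []

    def test_inactive_patches_not_reported(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.5)
        w.patch_state[:] = 0
        assert detect_encounters(w) == []


class TestAssociation:
    def test_binding_probability_threshold(self, bp_t1_direct):
        # k_a dt = 0.5: a uniform draw just below binds, just above does not
        w = _pair_world(bp_t1_direct, gap=0.5)
        (ev,) = detect_encounters(w)
        assert attempt_association(w, ev, FixedRng([0.51])) == "rejected_rate"
        assert w.n_clusters == 2
        assert attempt_association(w, ev, FixedRng([0.49])) == "bound"
        assert w.n_clusters == 1

    def test_snap_places_partners_at_rest_distance(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.6)
        (ev,) = detect_encounters(w)
        attempt_association(w, ev, FixedRng([0.0]))
        d = np.linalg.norm(w.mon_wpos[0] - w.mon_wpos[1])
        assert d == pytest.approx(2 * bp_t1_direct.R, abs=1e-9)
        # equal monomers share the repositioning equally
        assert w.mon_wpos[0][0] == pytest.approx(5.0 + 0.3, abs=1e-9)

    def test_steric_clash_restores_poses_exactly(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.6, seed=1, n=3)
        # third monomer exactly where the snap would pull monomer 1
        w.place_monomer(2, np.array([5.0 + 2.0, 5.0 + 1.0, 5.0]), np.eye(3))
        pos = w.mon_wpos.copy()
        rot = w.mon_wrot.copy()
        events = [e for e in detect_encounters(w) if {0, 1} ==
                  {int(w.patch_mon[e.patch_a]), int(w.patch_mon[e.patch_b])}]
        result = attempt_association(w, events[0], FixedRng([0.0]))
        assert result == "rejected_steric"
        assert np.array_equal(w.mon_wpos, pos)
        assert np.array_equal(w.mon_wrot, rot)
        assert w.n_clusters == 3

    def _pair_world3(self, bp, seed):
        w = _pair_world(bp, gap=0.6, seed=seed)
        return w

    def test_merge_recomputes_diffusion_tensor(self, bp_t1_direct):
        w = _pair_world(bp_t1_direct, gap=0.5)
        ca = int(w.mon_cluster[0])
        trace_before = w.clus_dtrace[ca]
        (ev,) = detect_encounters(w)
        attempt_association(w, ev, FixedRng([0.0]))
        cid = int(w.mon_cluster[0])
        assert w.clus_dtrace[cid] < trace_before
        assert len(w.clus_members[cid]) == 2


class TestDissociation:
    def _bound_pair(self, bp):
        w = _pair_world(bp, gap=0.5)
        (ev,) = detect_encounters(w)
        attempt_association(w, ev, FixedRng([0.0]))
        return w

    def test_break_probability_threshold(self, bp_t1_direct):
        w = self._bound_pair(bp_t1_direct)
        (p,) = w.bond_list()
        # k_d dt = 1.35e-3
        assert attempt_dissociation(w, int(p), FixedRng([0.5])) == "intact"
        assert attempt_dissociation(w, int(p), FixedRng([1e-4])) == "split"

    def test_split_leaves_poses_unchanged(self, bp_t1_direct):
        w = self._bound_pair(bp_t1_direct)
        pos = w.mon_wpos.copy()
        (p,) = w.bond_list()
        attempt_dissociation(w, int(p), FixedRng([0.0]))
        assert w.n_clusters == 2
        assert np.array_equal(w.mon_wpos, pos)
        # freed patches remain in encounter range and may rebind
        assert len(detect_encounters(w)) == 1

    def test_locked_bond_rejected(self, bp_t1):
        cfg = SimulationConfig(
            blueprint=bp_t1, mode="hierarchical", N=5, L=20.0,
            k_a=9.0, k_d=0.0, max_time=1e4, seed=3,
        )
        w = initialize_world(cfg)
        _, slots = bp_t1.capsomers[0]
        for m, s in enumerate(slots):
            w.place_monomer(
                m,
                bp_t1.ideal_positions[s] + 8.0,
                Rotation.from_quat(bp_t1.ideal_quats[s]).as_matrix(),
            )
        for _ in range(200):
            step(w)
            if w.ring_events:
                break
        assert w.ring_events, "pentamer did not close"
        locked = np.nonzero((w.patch_bond >= 0) & (w.patch_state == STATE_LOCKED))[0]
        with pytest.raises(ReactionError, match="locked"):
            attempt_dissociation(w, int(locked[0]), FixedRng([0.0]))


class TestPatchSwitching:
    def _chain_world(self, bp, n, mode):
        """n monomers placed at consecutive slots of one pentamer ring."""
        cfg = SimulationConfig(
            blueprint=bp, mode=mode, N=n, L=20.0,
            k_a=9.0, k_d=0.0, max_time=1e3, seed=5,
        )
        w = initialize_world(cfg)
        _, slots = bp.capsomers[0]
        for m in range(n):
            s = slots[m]
            w.place_monomer(
                m,
                bp.ideal_positions[s] + 8.0,
                Rotation.from_quat(bp.ideal_quats[s]).as_matrix(),
            )
        # bind consecutive chain bonds deterministically
        for _ in range(n):
            for ev in detect_encounters(w, include_intracluster=True):
                attempt_association(w, ev, FixedRng([0.0, 0.0]))
        return w

    def test_open_chain_produces_no_transitions(self, bp_t1):
        w = self._chain_world(bp_t1, 4, "hierarchical")
        assert len(w.bond_list()) == 3
        assert not w.ring_events
        assert not (w.patch_state == STATE_LOCKED).any()

    def test_ring_closure_locks_and_activates(self, bp_t1):
        w = self._chain_world(bp_t1, 5, "hierarchical")
        assert w.ring_events and w.ring_events[0][1] == 5
        # all 10 intra patches locked, all 5 inter patches switched on
        assert int((w.patch_state == STATE_LOCKED).sum()) == 10
        inter = [p for p in range(len(w.patch_state))
                 if w.tables.class_kind[w.patch_class[p]] == 1]
        assert all(w.patch_state[p] == STATE_ACTIVE for p in inter)
        assert w.bond_list().size == 0  # every bond of the ring is locked

    def test_direct_mode_is_identity(self, bp_t1_direct):
        w = self._chain_world(bp_t1_direct, 5, "direct")
        # ring closes geometrically but nothing locks in direct mode
        assert len(w.bond_list()) == 5
        assert not (w.patch_state == STATE_LOCKED).any()
        new_bond = int(w.bond_list()[0])
        assert update_patch_states(w, new_bond) == []

    def test_ring_bond_break_keeps_cluster_intact(self, bp_t1_direct):
        w = self._chain_world(bp_t1_direct, 5, "direct")
        (cid,) = w.alive_ids
        w.tables.class_kd[:] = 1.0  # make the break certain
        p = int(w.bond_list()[0])
        assert attempt_dissociation(w, p, FixedRng([0.0])) == "removed"
        assert w.n_clusters == 1
        assert len(w.clus_members[int(w.alive_ids[0])]) == 5


class TestTwoStateEquilibrium:
    def test_bound_fraction_matches_markov_chain(self, bp_t1_direct):
        """A persistent encounter pair alternates bound/unbound as a
        two-state chain with p_bind = k_a dt and p_break = k_d dt; the
        occupancy converges to p_bind / (p_bind + p_break)."""
        cfg_rates = dict(k_a=5.0, k_d=1.0)  # p_b = 0.5, p_u = 0.1
        w = _pair_world(bp_t1_direct, gap=0.1)
        w.tables.class_ka[:] = cfg_rates["k_a"]
        w.tables.class_kd[:] = cfg_rates["k_d"]
        rng = np.random.default_rng(12345)
        bound_steps = 0
        n_steps = 20000
        for _ in range(n_steps):
            bonds = w.bond_list()
            if len(bonds):
                bound_steps += 1
                attempt_dissociation(w, int(bonds[0]), rng)
            else:
                events = detect_encounters(w)
                assert len(events) == 1
                attempt_association(w, events[0], rng)
        expected = 0.5 / 0.6
        # correlated-chain standard error ~ sqrt(p(1-p) * 2 tau / n)
        se = np.sqrt(expected * (1 - expected) * 2 * (1 / 0.6) / n_steps)
        assert bound_steps / n_steps == pytest.approx(expected, abs=4 * se)
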