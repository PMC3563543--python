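"""Stochastic association / dissociation kernel.

Binding follows the encounter-complex picture: when two complementary,
active, unbound patches overlap diffusively (patch-centre distance below
twice the patch radius), the encounter converts to a bond within one
timestep with probability ``p_bind = k_a * dt``.  An accepted bond snaps
the partners into the bond rule's relative transform — the repositioning
is shared according to the clusters' diffusive weights — and is rejected
wholesale if the snapped configuration would overlap any hard sphere with
any other, in which case all poses are restored exactly.  Existing bonds
break with ``p_break = k_d * dt``; a break that disconnects the bond
graph splits the cluster in two at unchanged poses, so the freed patches
remain in encounter and may rebind immediately.

Within one rigid cluster, complementary patch pairs that sit exactly in
their bound geometry (ring or shell closures, which the exact bond
transforms guarantee to be aligned) convert at the same ``p_bind`` but
involve no repositioning.

In hierarchical mode, completion of a capsomer ring (a closed cycle of 5
or 6 intra-capsomer bonds) permanently locks the ring's intra patches and
bonds and activates the members' inter-capsomer patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels as K
from .diffusion import diffusive_weights

STATE_INACTIVE = 0
STATE_ACTIVE = 1
STATE_LOCKED = 2

#: intra-cluster patch pairs closer than this are treated as aligned
#: closure contacts (exact closures land at ~1e-12 nm); nm
TOL_CLOSE = 1e-3

#: two centres count as overlapping below 2R - this slack; nm
STERIC_SLACK = 1e-7


class ReactionError(RuntimeError):
    pass


@dataclass(frozen=True)
class EncounterEvent:
    """A reactive patch overlap found by the encounter scan."""

    patch_a: int
    patch_b: int
    separation: float  # nm, min-image patch-centre distance
    same_cluster: bool = False


def detect_encounters(world, include_intracluster: bool = False):
    """All current encounter events.

    By default only patch pairs on distinct clusters are reported (the
    diffusional encounters of the two-step binding model); with
    ``include_intracluster`` the aligned in-cluster closure contacts are
    included as well, which is what the engine's step uses.
    """
    world.refresh_world_poses()
    world.ensure_verlet()
    n_ev = world.scan()
    events = []
    for k in range(n_ev):
        same = bool(world.ev_same[k])
        if same and not include_intracluster:
            continue
        events.append(
            EncounterEvent(
                int(world.ev_pa[k]), int(world.ev_pb[k]), float(world.ev_sep[k]), same
            )
        )
    return events


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _rotvec_to_matrix(phi: np.ndarray) -> np.ndarray:
    ang = float(np.linalg.norm(phi))
    vx = np.array(
        [[0.0, -phi[2], phi[1]], [phi[2], 0.0, -phi[0]], [-phi[1], phi[0], 0.0]]
    )
    if ang < 1e-12:
        return np.eye(3) + vx
    return (
        np.eye(3)
        + np.sin(ang) / ang * vx
        + (1.0 - np.cos(ang)) / ang**2 * (vx @ vx)
    )


def _matrix_to_rotvec(m: np.ndarray) -> np.ndarray:
    # scipy handles the angle ~ pi branch robustly; this path is not hot
    # enough to matter there, but the common small-angle case is inlined
    cos = 0.5 * (np.trace(m) - 1.0)
    if cos > 0.999999:
        return 0.5 * np.array(
            [m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]]
        )
    return Rotation.from_matrix(m).as_rotvec()


def _fractional_rotation(rotvec: np.ndarray, frac: float) -> np.ndarray:
    return _rotvec_to_matrix(frac * rotvec)


def attempt_association(world, event: EncounterEvent, rng=None):
    """Attempt to convert one encounter into a bond.

    Returns one of ``"bound"``, ``"rejected_rate"``, ``"rejected_steric"``,
    ``"invalid"``.  ``rng`` defaults to the world's reaction RNG.
    """
    rng = world.rng if rng is None else rng
    t = world.tables
    pa, pb = event.patch_a, event.patch_b
    if (
        world.patch_state[pa] != STATE_ACTIVE
        or world.patch_state[pb] != STATE_ACTIVE
        or world.patch_bond[pa] >= 0
        or world.patch_bond[pb] >= 0
    ):
        return "invalid"
    ma, mb = int(world.patch_mon[pa]), int(world.patch_mon[pb])
    ca, cb = int(world.mon_cluster[ma]), int(world.mon_cluster[mb])
    same = ca == cb
    # revalidate the encounter at the current poses (an earlier accepted
    # snap within this step may have moved either partner)
    d = world.patch_position(pa) - world.patch_position(pb)
    d -= world.L * np.round(d / world.L)
    sep = float(np.linalg.norm(d))
    if same:
        if not event.same_cluster or sep > TOL_CLOSE:
            return "invalid"
    elif sep >= 2.0 * world.blueprint.patch_radius:
        return "invalid"

    cls_a = int(world.patch_class[pa])
    p_bind = t.class_ka[cls_a] * world.dt
    if rng.random() >= p_bind:
        return "rejected_rate"

    if same:
        world.add_bond(pa, pb)
        return "bound"

    # --- snap-to-geometry, shared by diffusive weight -------------------
    L = world.L
    R = world.blueprint.R
    wa, wb = diffusive_weights(world.cluster_tensor(ca), world.cluster_tensor(cb))

    rot_a = world.mon_wrot[ma]
    rot_b = world.mon_wrot[mb]
    target_rot = rot_a @ t.class_Xrot[cls_a]

    g_vec = _matrix_to_rotvec(target_rot @ rot_b.T)
    dR_a = _fractional_rotation(g_vec, -wa)
    dR_b = _fractional_rotation(g_vec, wb)

    mem_a = world.clus_members[ca]
    mem_b = world.clus_members[cb]
    cen_a = world.clus_pos[ca]
    cen_b = world.clus_pos[cb]

    pos_a = cen_a + (world.mon_wpos[mem_a] - cen_a) @ dR_a.T
    rot_a_new = np.einsum("ij,mjk->mik", dR_a, world.mon_wrot[mem_a])
    pos_b = cen_b + (world.mon_wpos[mem_b] - cen_b) @ dR_b.T
    rot_b_new = np.einsum("ij,mjk->mik", dR_b, world.mon_wrot[mem_b])

    # residual translation after the rotations, split by weight; keep the
    # raw coordinates of group B contiguous with group A's periodic image
    ia = int(np.nonzero(mem_a == ma)[0][0])
    ib = int(np.nonzero(mem_b == mb)[0][0])
    target_pos = pos_a[ia] + rot_a_new[ia] @ t.class_Xtr[cls_a]
    delta_raw = target_pos - pos_b[ib]
    delta_mi = delta_raw - L * np.round(delta_raw / L)
    image_shift = delta_raw - delta_mi
    pos_a = pos_a - wa * delta_mi
    pos_b = pos_b + wb * delta_mi + image_shift

    # --- steric test ----------------------------------------------------
    limit2 = (2.0 * R - STERIC_SLACK) ** 2
    skip = np.zeros(world.M, dtype=np.bool_)
    skip[mem_a] = True
    skip[mem_b] = True
    cand = np.concatenate([pos_a, pos_b])
    cand_idx = np.concatenate([mem_a, mem_b])
    if K.steric_clash(cand_idx, cand, world.mon_wpos, skip, L, limit2):
        return "rejected_steric"
    if K.group_clash(pos_a, pos_b, L, limit2):
        return "rejected_steric"

    # --- commit ---------------------------------------------------------
    world.mon_wpos[mem_a] = pos_a
    world.mon_wrot[mem_a] = rot_a_new
    world.mon_wpos[mem_b] = pos_b
    world.mon_wrot[mem_b] = rot_b_new
    world.merge_clusters(ca, cb)
    world.add_bond(pa, pb)
    world.verlet_dirty = True
    return "bound"


# ---------------------------------------------------------------------------
# dissociation
# ---------------------------------------------------------------------------

def attempt_dissociation(world, patch: int, rng=None):
    """Attempt to break the bond attached to ``patch``.

    Returns ``"intact"``, ``"removed"`` or ``"split"``.  Calling this on a
    locked bond is a programming error.
    """
    rng = world.rng if rng is None else rng
    q = int(world.patch_bond[patch])
    if q < 0:
        raise ReactionError(f"patch {patch} carries no bond")
    if world.patch_state[patch] == STATE_LOCKED or world.patch_state[q] == STATE_LOCKED:
        raise ReactionError("attempted dissociation of a locked bond")
    p_break = world.tables.class_kd[world.patch_class[patch]] * world.dt
    if rng.random() >= p_break:
        return "intact"
    return remove_bond(world, patch)


def remove_bond(world, patch: int):
    """Unconditionally remove the bond at ``patch``; split the cluster if
    the bond graph disconnects.  Poses are unchanged, so freed patches
    remain in encounter range."""
    q = int(world.patch_bond[patch])
    ma, mb = int(world.patch_mon[patch]), int(world.patch_mon[q])
    world.patch_bond[patch] = -1
    world.patch_bond[q] = -1
    world.bonds_dirty = True
    cid = int(world.mon_cluster[ma])
    comp = world.bonded_component(ma)
    if mb in comp:
        return "removed"
    world.split_cluster(cid, comp)
    return "split"


# ---------------------------------------------------------------------------
# hierarchical patch switching
# ---------------------------------------------------------------------------

def update_patch_states(world, new_bond_patch: int):
    """Apply the hierarchical switching rule after a successful intra bond.

    If the bond completed a capsomer ring (closed cycle of ring-size intra
    bonds), lock every intra patch and bond of the ring's members and
    activate their inter-capsomer patches.  Identity in direct mode.
    Returns the list of (patch, old_state, new_state) transitions.
    """
    if world.mode != "hierarchical":
        return []
    t = world.tables
    cls = int(world.patch_class[new_bond_patch])
    if t.class_kind[cls] != 0:
        return []
    m0 = int(world.patch_mon[new_bond_patch])
    ring = _trace_ring(world, m0)
    if ring is None:
        return []
    transitions = []
    for m in ring:
        base = world.mon_patch_start[m]
        tp = world.mon_type[m]
        for loc in range(t.type_patch_count[tp]):
            p = base + loc
            kind = t.class_kind[world.patch_class[p]]
            old = int(world.patch_state[p])
            if kind == 0 and old != STATE_LOCKED:
                world.patch_state[p] = STATE_LOCKED
                transitions.append((p, old, STATE_LOCKED))
            elif kind == 1 and old == STATE_INACTIVE:
                world.patch_state[p] = STATE_ACTIVE
                transitions.append((p, old, STATE_ACTIVE))
    world.bonds_dirty = True
    world.ring_events.append((world.clock, len(ring)))
    return transitions


def _trace_ring(world, m0: int):
    """Walk intra_next bonds from monomer ``m0``; return the ring member
    list if the walk closes, else None."""
    t = world.tables
    ring = [m0]
    m = m0
    expected = t.type_ring[world.mon_type[m0]]
    for _ in range(expected):
        p_next = world.mon_patch_start[m] + t.type_intra_next[world.mon_type[m]]
        q = int(world.patch_bond[p_next])
        if q < 0:
            return None
        m = int(world.patch_mon[q])
        if m == m0:
            if len(ring) != expected:
                raise ReactionError(
                    f"ring of size {len(ring)} closed where {expected} expected"
                )
            return ring
        ring.append(m)
    return None
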