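"""Numba-compiled inner loops of the Brownian dynamics engine.

The world is laid out in flat arrays (see `capsidyn.engine.WorldState`);
these kernels implement the per-step hot path: correlated rigid-body
Brownian displacement, periodic minimum-image bookkeeping, Verlet
candidate-pair maintenance, and the reactive-patch encounter scan.
Orientations are carried as 3x3 rotation matrices in the hot path.

All randomness inside the kernels uses numba's internal np.random state,
seeded once per trajectory through `seed_kernel_rng`; reaction decisions
are drawn from a separate NumPy Generator on the Python side.  Both are
fully determined by the trajectory seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NOPYTHON = {"cache": True, "fastmath": False}


@njit(**_NOPYTHON)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(inline="always", **_NOPYTHON)
def _min_image(d, L):
    return d - L * np.round(d / L)


@njit(inline="always", **_NOPYTHON)
def _rotvec_to_matrix(phi, out):
    """Rodrigues formula; phi is a rotation vector (rad)."""
    ang = np.sqrt(phi[0] ** 2 + phi[1] ** 2 + phi[2] ** 2)
    if ang < 1e-12:
        out[:] = np.eye(3)
        out[0, 1] -= phi[2]
        out[1, 0] += phi[2]
        out[0, 2] += phi[1]
        out[2, 0] -= phi[1]
        out[1, 2] -= phi[0]
        out[2, 1] += phi[0]
        return
    c = np.cos(ang)
    s = np.sin(ang)
    x = phi[0] / ang
    y = phi[1] / ang
    z = phi[2] / ang
    omc = 1.0 - c
    out[0, 0] = c + x * x * omc
    out[0, 1] = x * y * omc - z * s
    out[0, 2] = x * z * omc + y * s
    out[1, 0] = y * x * omc + z * s
    out[1, 1] = c + y * y * omc
    out[1, 2] = y * z * omc - x * s
    out[2, 0] = z * x * omc - y * s
    out[2, 1] = z * y * omc + x * s
    out[2, 2] = c + z * z * omc


@njit(**_NOPYTHON)
def propagate(
    alive_ids,
    clus_pos,
    clus_rot,
    clus_chol,
    members_flat,
    members_start,
    members_count,
    mon_bpos,
    mon_brot,
    mon_wpos,
    mon_wrot,
    mon_cluster,
    verlet_ref,
    pairs,
    n_pairs,
    tmp_pos,
    R,
    L,
):
    """One diffusive step for every alive cluster, hard-sphere aware.

    Each cluster draws a correlated 6-vector (body frame) from its
    pre-factored covariance; translation is rotated to the world frame,
    rotation applied about the mobility centre (body axes).  A move that
    would bring any member within 2R of a monomer outside the cluster
    (candidates from the Verlet pair list) is rejected and the old pose
    kept, as for overlapping binding attempts.  Member world poses are
    refreshed for accepted moves; returns the maximum minimum-image
    displacement of any monomer from the Verlet reference positions.
    """
    drot = np.empty((3, 3))
    newrot = np.empty((3, 3))
    newpos = np.empty(3)
    xi = np.empty(6)
    dq = np.empty(6)
    limit2 = (2.0 * R - 1e-7) ** 2
    maxdisp2 = 0.0
    for a in range(alive_ids.shape[0]):
        c = alive_ids[a]
        for k in range(6):
            xi[k] = np.random.standard_normal()
        for k in range(6):
            s = 0.0
            for l in range(k + 1):
                s += clus_chol[c, k, l] * xi[l]
            dq[k] = s
        rot = clus_rot[c]
        # world-frame translation of the mobility centre
        for k in range(3):
            newpos[k] = clus_pos[c, k] + (
                rot[k, 0] * dq[0] + rot[k, 1] * dq[1] + rot[k, 2] * dq[2]
            )
            # keep the reference point inside the primary box
            newpos[k] -= L * np.floor(newpos[k] / L)
        _rotvec_to_matrix(dq[3:], drot)
        for i in range(3):
            for j in range(3):
                s = 0.0
                for k in range(3):
                    s += rot[i, k] * drot[k, j]
                newrot[i, j] = s
        # tentative member positions
        for mi in range(members_start[c], members_start[c] + members_count[c]):
            m = members_flat[mi]
            for i in range(3):
                tmp_pos[m, i] = (
                    newpos[i]
                    + newrot[i, 0] * mon_bpos[m, 0]
                    + newrot[i, 1] * mon_bpos[m, 1]
                    + newrot[i, 2] * mon_bpos[m, 2]
                )
        # hard-sphere check against monomers outside the cluster (earlier
        # clusters in this step are seen at their updated positions)
        clash = False
        for p in range(n_pairs):
            i = pairs[p, 0]
            j = pairs[p, 1]
            ic = mon_cluster[i] == c
            jc = mon_cluster[j] == c
            if ic == jc:  # both inside (rigid) or both outside: skip
                continue
            if jc:
                i, j = j, i  # i is the moving member, j the bystander
            d2 = 0.0
            for k in range(3):
                dd = _min_image(tmp_pos[i, k] - mon_wpos[j, k], L)
                d2 += dd * dd
            if d2 < limit2:
                clash = True
                break
        if clash:
            continue
        clus_pos[c] = newpos
        clus_rot[c] = newrot
        for mi in range(members_start[c], members_start[c] + members_count[c]):
            m = members_flat[mi]
            for i in range(3):
                mon_wpos[m, i] = tmp_pos[m, i]
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for k in range(3):
                        s += newrot[i, k] * mon_brot[m, k, j]
                    mon_wrot[m, i, j] = s
            d2 = 0.0
            for i in range(3):
                dd = _min_image(mon_wpos[m, i] - verlet_ref[m, i], L)
                d2 += dd * dd
            if d2 > maxdisp2:
                maxdisp2 = d2
    return np.sqrt(maxdisp2)


@njit(**_NOPYTHON)
def build_pairs(mon_wpos, L, cutoff, pairs, verlet_ref):
    """Brute-force O(M^2) candidate pair list under minimum image."""
    m = mon_wpos.shape[0]
    c2 = cutoff * cutoff
    n = 0
    for i in range(m):
        for k in range(3):
            verlet_ref[i, k] = mon_wpos[i, k]
    for i in range(m):
        for j in range(i + 1, m):
            d2 = 0.0
            for k in range(3):
                dd = _min_image(mon_wpos[i, k] - mon_wpos[j, k], L)
                d2 += dd * dd
            if d2 < c2:
                if n < pairs.shape[0]:
                    pairs[n, 0] = i
                    pairs[n, 1] = j
                n += 1
    return n


@njit(**_NOPYTHON)
def scan_encounters(
    pairs,
    n_pairs,
    mon_wpos,
    mon_wrot,
    mon_cluster,
    mon_type,
    mon_patch_start,
    compat_start,
    compat_count,
    compat_li,
    compat_lj,
    patch_class,
    patch_state,
    patch_bond,
    class_dir,
    n_types,
    R,
    patch_radius,
    tol_close,
    L,
    ev_pa,
    ev_pb,
    ev_sep,
    ev_same,
):
    """Find reactive patch encounters among candidate monomer pairs.

    An encounter is a complementary, active, unbound patch pair whose
    patch-centre minimum-image distance is below ``2*patch_radius`` when
    the patches sit on different clusters, or below ``tol_close`` (an
    already-aligned ring-closure contact) within one cluster.  Results are
    written to the ``ev_*`` output arrays; returns the event count.
    """
    reach = 2.0 * R + 2.0 * patch_radius
    reach2 = reach * reach
    enc2 = (2.0 * patch_radius) ** 2
    close2 = tol_close * tol_close
    n_ev = 0
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _min_image(mon_wpos[i, 0] - mon_wpos[j, 0], L)
        dy = _min_image(mon_wpos[i, 1] - mon_wpos[j, 1], L)
        dz = _min_image(mon_wpos[i, 2] - mon_wpos[j, 2], L)
        if dx * dx + dy * dy + dz * dz > reach2:
            continue
        same = mon_cluster[i] == mon_cluster[j]
        tp = mon_type[i] * n_types + mon_type[j]
        for cc in range(compat_start[tp], compat_start[tp] + compat_count[tp]):
            pa = mon_patch_start[i] + compat_li[cc]
            pb = mon_patch_start[j] + compat_lj[cc]
            if patch_state[pa] != 1 or patch_state[pb] != 1:
                continue
            if patch_bond[pa] >= 0 or patch_bond[pb] >= 0:
                continue
            d2 = 0.0
            for k in range(3):
                ca = class_dir[patch_class[pa]]
                cb = class_dir[patch_class[pb]]
                xa = mon_wpos[i, k] + R * (
                    mon_wrot[i, k, 0] * ca[0]
                    + mon_wrot[i, k, 1] * ca[1]
                    + mon_wrot[i, k, 2] * ca[2]
                )
                xb = mon_wpos[j, k] + R * (
                    mon_wrot[j, k, 0] * cb[0]
                    + mon_wrot[j, k, 1] * cb[1]
                    + mon_wrot[j, k, 2] * cb[2]
                )
                dd = _min_image(xa - xb, L)
                d2 += dd * dd
            lim2 = close2 if same else enc2
            if d2 < lim2:
                if n_ev < ev_pa.shape[0]:
                    ev_pa[n_ev] = pa
                    ev_pb[n_ev] = pb
                    ev_sep[n_ev] = np.sqrt(d2)
                    ev_same[n_ev] = same
                n_ev += 1
    return n_ev


@njit(**_NOPYTHON)
def steric_clash(cand_idx, cand_pos, mon_wpos, skip_mask, L, limit2):
    """True if any candidate position comes closer than sqrt(limit2) to a
    non-skipped monomer, or if two candidates from different groups do.

    ``cand_idx`` are the monomer ids being moved (their entries in
    ``skip_mask`` are True); ``cand_pos`` their tentative positions.
    """
    n = cand_idx.shape[0]
    m = mon_wpos.shape[0]
    for a in range(n):
        for b in range(m):
            if skip_mask[b]:
                continue
            d2 = 0.0
            for k in range(3):
                dd = _min_image(cand_pos[a, k] - mon_wpos[b, k], L)
                d2 += dd * dd
            if d2 < limit2:
                return True
    return False


@njit(**_NOPYTHON)
def group_clash(pos_a, pos_b, L, limit2):
    """True if any member of group A comes within sqrt(limit2) of group B."""
    for a in range(pos_a.shape[0]):
        for b in range(pos_b.shape[0]):
            d2 = 0.0
            for k in range(3):
                dd = _min_image(pos_a[a, k] - pos_b[b, k], L)
                d2 += dd * dd
            if d2 < limit2:
                return True
    return False
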