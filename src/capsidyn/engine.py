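"""Assembly engine: world state, main loop, and observables.

A simulation holds ``N`` hard-sphere monomers in a periodic cubic box of
side ``L``.  Each timestep ``dt`` (default 0.1 ns) performs, in order:
rigid-body Brownian propagation of every cluster, stochastic association
attempts for all patch encounters in uniformly random order, and
stochastic dissociation attempts for all unlocked bonds.  Observables
follow the cluster census: populations ``nu_n(t)`` of clusters of size
``n``, the monomer occupancy ``p(n) = nu_n n / N``, the mean cluster size
``nbar = sum_n p(n) n``, first-passage times of intermediate sizes, and
the success/censoring outcome of the trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels as K
from . import reactions
from .diffusion import (
    DiffusionTensor,
    cluster_diffusion_matrix,
    dimer_diffusion_tensor,
    stokes_einstein,
)
from .geometry import CapsidBlueprint, INTRA

AVOGADRO = 6.02214076e23


class ConfigError(ValueError):
    pass


def _rate_for(value, kind: str) -> float:
    if isinstance(value, dict):
        return float(value[kind])
    return float(value)


@dataclass
class SimulationConfig:
    """Parameters of one assembly simulation.

    Rates ``k_a`` and ``k_d`` (ns^-1) may be single floats (uniform over
    bond kinds) or dicts keyed ``{"intra": ..., "inter": ...}``.
    ``composition`` optionally fixes per-type monomer counts; otherwise N
    is split proportionally to the blueprint stoichiometry.
    """

    blueprint: CapsidBlueprint
    mode: str = "direct"
    N: int = 60
    L: float = 28.0             # nm
    dt: float = 0.1             # ns
    temperature: float = 293.0  # K
    viscosity: float = 2e-3     # Pa s
    k_a: float | dict = 5.0     # ns^-1
    k_d: float | dict = 1.35e-2 # ns^-1
    max_time: float = 9e6       # ns
    seed: int = 0
    record_interval: float = 1e3  # ns
    composition: dict[str, int] | None = None
    insertion_attempts: int = 2000  # placement attempts per monomer

    def validate(self) -> None:
        if self.mode not in ("direct", "hierarchical"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.N < 1:
            raise ConfigError("N must be >= 1")
        if self.L <= 4 * self.blueprint.R:
            raise ConfigError("box side must exceed 4R")
        if self.dt < 0:
            raise ConfigError("dt must be >= 0")
        for kind in ("intra", "inter"):
            if _rate_for(self.k_a, kind) * self.dt > 1.0:
                raise ConfigError(f"k_a*dt > 1 for {kind} bonds")
            if _rate_for(self.k_d, kind) * self.dt > 1.0:
                raise ConfigError(f"k_d*dt > 1 for {kind} bonds")
        if self.composition is not None:
            unknown = set(self.composition) - set(self.blueprint.particle_types)
            if unknown:
                raise ConfigError(f"composition names unknown types {unknown}")
            if sum(self.composition.values()) != self.N:
                raise ConfigError("composition must sum to N")

    @property
    def concentration_molar(self) -> float:
        """Initial monomer concentration, mol/L."""
        volume_l = (self.L * 1e-9) ** 3 * 1e3
        return self.N / AVOGADRO / volume_l


class ReactionTables:
    """Blueprint compiled to the flat arrays the kernels consume."""

    def __init__(self, bp: CapsidBlueprint, mode: str, k_a, k_d):
        self.type_ids = sorted(bp.particle_types)
        self.n_types = len(self.type_ids)
        tindex = {t: i for i, t in enumerate(self.type_ids)}

        counts, rings, nxt, prv = [], [], [], []
        cls_type, cls_dir, cls_kind, cls_pid = [], [], [], []
        for tid in self.type_ids:
            spec = bp.particle_types[tid]
            counts.append(len(spec.patches))
            rings.append(spec.ring_size)
            ni = pi = -1
            for li, p in enumerate(spec.patches):
                if p.patch_id.endswith("intra_next"):
                    ni = li
                if p.patch_id.endswith("intra_prev"):
                    pi = li
                cls_type.append(tindex[tid])
                cls_dir.append(p.direction)
                cls_kind.append(0 if p.kind == INTRA else 1)
                cls_pid.append(p.patch_id)
            nxt.append(ni)
            prv.append(pi)
        self.type_patch_count = np.array(counts, dtype=np.int64)
        self.type_ring = np.array(rings, dtype=np.int64)
        self.type_intra_next = np.array(nxt, dtype=np.int64)
        self.type_intra_prev = np.array(prv, dtype=np.int64)
        self.type_patch_offset = np.concatenate(
            [[0], np.cumsum(self.type_patch_count)]
        )

        C = len(cls_pid)
        self.class_pid = cls_pid
        self.class_type = np.array(cls_type, dtype=np.int64)
        self.class_dir = np.array(cls_dir, dtype=np.float64)
        self.class_kind = np.array(cls_kind, dtype=np.int64)
        pid_to_class = {pid: c for c, pid in enumerate(cls_pid)}
        self.class_partner = np.array(
            [pid_to_class[bp.partner_of(pid)] for pid in cls_pid], dtype=np.int64
        )
        self.class_ka = np.empty(C)
        self.class_kd = np.empty(C)
        self.class_init_state = np.empty(C, dtype=np.int8)
        self.class_Xrot = np.empty((C, 3, 3))
        self.class_Xtr = np.empty((C, 3))
        for c, pid in enumerate(cls_pid):
            tid = self.type_ids[self.class_type[c]]
            spec = bp.particle_types[tid]
            patch = spec.patches[c - self.type_patch_offset[self.class_type[c]]]
            kind = "intra" if patch.kind == INTRA else "inter"
            self.class_ka[c] = _rate_for(k_a, kind)
            self.class_kd[c] = _rate_for(k_d, kind)
            self.class_init_state[c] = (
                reactions.STATE_ACTIVE
                if patch.initial_state(mode) == "active"
                else reactions.STATE_INACTIVE
            )
            rule = bp.rule_for(pid, patch.partner_patch_id)
            q, t = rule.relative_transform
            rot = Rotation.from_quat(q)
            if rule.patch_pair[0] == pid:
                self.class_Xrot[c] = rot.as_matrix()
                self.class_Xtr[c] = t
            else:
                self.class_Xrot[c] = rot.as_matrix().T
                self.class_Xtr[c] = -rot.as_matrix().T @ t

        # compatibility lists per ordered type pair
        starts, ncomp, li_all, lj_all = [], [], [], []
        for ti in range(self.n_types):
            for tj in range(self.n_types):
                starts.append(len(li_all))
                cnt = 0
                for li in range(self.type_patch_count[ti]):
                    ci = self.type_patch_offset[ti] + li
                    for lj in range(self.type_patch_count[tj]):
                        cj = self.type_patch_offset[tj] + lj
                        if self.class_partner[ci] == cj:
                            li_all.append(li)
                            lj_all.append(lj)
                            cnt += 1
                ncomp.append(cnt)
        self.compat_start = np.array(starts, dtype=np.int64)
        self.compat_count = np.array(ncomp, dtype=np.int64)
        self.compat_li = np.array(li_all, dtype=np.int64)
        self.compat_lj = np.array(lj_all, dtype=np.int64)
        self.full_bond_count = len(bp.contacts)


class WorldState:
    """All clusters in the periodic box, plus RNG state and clock."""

    def __init__(self, config: SimulationConfig, tables: ReactionTables):
        self.config = config
        self.blueprint = config.blueprint
        self.tables = tables
        self.mode = config.mode
        self.L = float(config.L)
        self.dt = float(config.dt)
        self.M = int(config.N)
        self.rng = np.random.default_rng(config.seed)
        K.seed_kernel_rng(int((config.seed ^ 0x5DEECE66) % 2**31))
        self.clock = 0.0

        M = self.M
        self.mon_type = np.zeros(M, dtype=np.int64)
        self.mon_cluster = np.zeros(M, dtype=np.int64)
        self.mon_bpos = np.zeros((M, 3))
        self.mon_brot = np.zeros((M, 3, 3))
        self.mon_wpos = np.zeros((M, 3))
        self.mon_wrot = np.zeros((M, 3, 3))
        self.mon_patch_start = np.zeros(M, dtype=np.int64)

        self.clus_alive = np.zeros(M, dtype=np.bool_)
        self.clus_pos = np.zeros((M, 3))
        self.clus_rot = np.zeros((M, 3, 3))
        self.clus_chol = np.zeros((M, 6, 6))
        self.clus_dtrace = np.zeros(M)
        self.clus_members: list[np.ndarray | None] = [None] * M
        self._tensor_cache: list[DiffusionTensor | None] = [None] * M
        self._free: list[int] = list(range(M - 1, -1, -1))
        self._alive_ids: np.ndarray | None = None
        self.members_flat = np.zeros(M, dtype=np.int64)
        self.members_start = np.zeros(M, dtype=np.int64)
        self.members_count = np.zeros(M, dtype=np.int64)
        self._members_stale = True

        # verlet bookkeeping
        self.skin = 1.2
        self.cutoff = 2 * self.blueprint.R + 2 * self.blueprint.patch_radius + self.skin
        self.verlet_ref = np.zeros((M, 3))
        self.tmp_pos = np.zeros((M, 3))
        cap = max(64, 8 * M)
        self.pairs = np.zeros((cap, 2), dtype=np.int64)
        self.n_pairs = 0
        self.verlet_dirty = True

        evcap = 64
        self.ev_pa = np.zeros(evcap, dtype=np.int64)
        self.ev_pb = np.zeros(evcap, dtype=np.int64)
        self.ev_sep = np.zeros(evcap)
        self.ev_same = np.zeros(evcap, dtype=np.bool_)

        self.bonds_dirty = True
        self._bond_list = np.zeros(0, dtype=np.int64)
        self._mono_matrix: np.ndarray | None = None
        self._mono_chol: np.ndarray | None = None

        # observables
        self.fpt: dict[int, float] = {1: 0.0}
        self.max_size = 1
        self.ring_events: list[tuple[float, int]] = []
        self.completed = False
        self.completion_time = math.inf

        # patch layout filled by initialize_world
        self.patch_mon = np.zeros(0, dtype=np.int64)
        self.patch_class = np.zeros(0, dtype=np.int64)
        self.patch_state = np.zeros(0, dtype=np.int8)
        self.patch_bond = np.zeros(0, dtype=np.int64)

    # -- cluster bookkeeping -------------------------------------------
    @property
    def alive_ids(self) -> np.ndarray:
        if self._alive_ids is None:
            self._alive_ids = np.nonzero(self.clus_alive)[0]
        return self._alive_ids

    @property
    def n_clusters(self) -> int:
        return len(self.alive_ids)

    def cluster_tensor(self, cid: int) -> DiffusionTensor:
        t = self._tensor_cache[cid]
        if t is None:
            raise RuntimeError(f"stale tensor for cluster {cid}")
        return t

    def new_cluster(self, member_ids: np.ndarray) -> int:
        """Create a cluster from members at their current world poses."""
        cfg = self.config
        member_ids = np.asarray(member_ids, dtype=np.int64)
        coords = self.mon_wpos[member_ids]
        if len(member_ids) == 1:
            if self._mono_matrix is None:
                d_t, d_r = stokes_einstein(
                    self.blueprint.R, cfg.temperature, cfg.viscosity
                )
                self._mono_matrix = np.diag([d_t, d_t, d_t, d_r, d_r, d_r])
                self._mono_chol = (
                    np.sqrt(2.0 * self.dt) * np.sqrt(self._mono_matrix)
                    if self.dt > 0
                    else np.zeros((6, 6))
                )
            tensor = DiffusionTensor(
                matrix=self._mono_matrix, mobility_center=coords[0].copy()
            )
            cid = self._free.pop()
            self.clus_alive[cid] = True
            self.clus_pos[cid] = coords[0]
            self.clus_rot[cid] = np.eye(3)
            self.clus_chol[cid] = self._mono_chol
            self.clus_dtrace[cid] = float(np.trace(self._mono_matrix[:3, :3]))
            self.clus_members[cid] = member_ids
            self._tensor_cache[cid] = tensor
            self.mon_cluster[member_ids] = cid
            self.mon_bpos[member_ids] = 0.0
            self.mon_brot[member_ids] = self.mon_wrot[member_ids]
            self._alive_ids = None
            self._members_stale = True
            return cid
        if len(member_ids) == 2:
            tensor = dimer_diffusion_tensor(
                coords, self.blueprint.R, cfg.temperature, cfg.viscosity
            )
        else:
            tensor = cluster_diffusion_matrix(
                coords, self.blueprint.R, cfg.temperature, cfg.viscosity
            )
        cid = self._free.pop()
        self.clus_alive[cid] = True
        self.clus_pos[cid] = tensor.mobility_center
        self.clus_rot[cid] = np.eye(3)
        self.clus_chol[cid] = tensor.cholesky_step_factor(self.dt)
        self.clus_dtrace[cid] = tensor.translational_trace
        self.clus_members[cid] = member_ids
        self._tensor_cache[cid] = tensor
        self.mon_cluster[member_ids] = cid
        self.mon_bpos[member_ids] = coords - tensor.mobility_center
        self.mon_brot[member_ids] = self.mon_wrot[member_ids]
        self._alive_ids = None
        self._members_stale = True
        self._note_size(len(member_ids))
        return cid

    def kill_cluster(self, cid: int) -> None:
        self.clus_alive[cid] = False
        self.clus_members[cid] = None
        self._tensor_cache[cid] = None
        self._free.append(cid)
        self._alive_ids = None
        self._members_stale = True

    def merge_clusters(self, ca: int, cb: int) -> int:
        members = np.concatenate([self.clus_members[ca], self.clus_members[cb]])
        self.kill_cluster(ca)
        self.kill_cluster(cb)
        return self.new_cluster(members)

    def split_cluster(self, cid: int, component: set[int]) -> tuple[int, int]:
        members = self.clus_members[cid]
        in_comp = np.array([m in component for m in members])
        part_a = members[in_comp]
        part_b = members[~in_comp]
        self.kill_cluster(cid)
        return self.new_cluster(part_a), self.new_cluster(part_b)

    def _note_size(self, size: int) -> None:
        if size > self.max_size:
            for s in range(self.max_size + 1, size + 1):
                self.fpt[s] = self.clock
            self.max_size = size
        if (
            size == self.blueprint.n_f
            and self.blueprint.kind == "capsid"
            and not self.completed
        ):
            self._check_completion()

    def cluster_bond_count(self, cid: int) -> int:
        members = self.clus_members[cid]
        t = self.tables
        n = 0
        for m in members:
            base = self.mon_patch_start[m]
            for loc in range(t.type_patch_count[self.mon_type[m]]):
                if self.patch_bond[base + loc] >= 0:
                    n += 1
        return n // 2

    def _check_completion(self) -> None:
        for cid in self.alive_ids:
            members = self.clus_members[cid]
            if len(members) != self.blueprint.n_f:
                continue
            if self.cluster_bond_count(cid) == self.tables.full_bond_count:
                self.completed = True
                self.completion_time = self.clock
                return

    # -- geometry helpers ----------------------------------------------
    def place_monomer(self, m: int, pos: np.ndarray, rot: np.ndarray) -> None:
        """Reposition a still-unbonded monomer (fixture setup).  Only valid
        while the monomer is a singleton cluster."""
        cid = int(self.mon_cluster[m])
        if len(self.clus_members[cid]) != 1:
            raise RuntimeError("place_monomer requires a singleton cluster")
        self.mon_wpos[m] = pos
        self.mon_wrot[m] = rot
        self.mon_brot[m] = rot
        self.clus_pos[cid] = pos
        self.clus_rot[cid] = np.eye(3)
        tensor = self._tensor_cache[cid]
        tensor.mobility_center = np.asarray(pos, dtype=float).copy()
        self.verlet_dirty = True

    def refresh_world_poses(self) -> None:
        """Recompute member world poses from cluster poses (normally the
        propagation kernel keeps these current)."""
        for cid in self.alive_ids:
            members = self.clus_members[cid]
            rot = self.clus_rot[cid]
            self.mon_wpos[members] = self.clus_pos[cid] + self.mon_bpos[members] @ rot.T
            self.mon_wrot[members] = np.einsum("ij,mjk->mik", rot, self.mon_brot[members])

    def patch_position(self, p: int) -> np.ndarray:
        m = self.patch_mon[p]
        d = self.tables.class_dir[self.patch_class[p]]
        return self.mon_wpos[m] + self.blueprint.R * (self.mon_wrot[m] @ d)

    def _rebuild_members(self) -> None:
        pos = 0
        for cid in self.alive_ids:
            members = self.clus_members[cid]
            self.members_start[cid] = pos
            self.members_count[cid] = len(members)
            self.members_flat[pos : pos + len(members)] = members
            pos += len(members)
        self._members_stale = False

    # -- verlet / scanning ---------------------------------------------
    def ensure_verlet(self) -> None:
        if not self.verlet_dirty:
            return
        while True:
            n = K.build_pairs(
                self.mon_wpos, self.L, self.cutoff, self.pairs, self.verlet_ref
            )
            if n <= len(self.pairs):
                break
            self.pairs = np.zeros((2 * n, 2), dtype=np.int64)
        self.n_pairs = n
        self.verlet_dirty = False

    def scan(self) -> int:
        t = self.tables
        while True:
            n_ev = K.scan_encounters(
                self.pairs,
                self.n_pairs,
                self.mon_wpos,
                self.mon_wrot,
                self.mon_cluster,
                self.mon_type,
                self.mon_patch_start,
                t.compat_start,
                t.compat_count,
                t.compat_li,
                t.compat_lj,
                self.patch_class,
                self.patch_state,
                self.patch_bond,
                t.class_dir,
                t.n_types,
                self.blueprint.R,
                self.blueprint.patch_radius,
                reactions.TOL_CLOSE,
                self.L,
                self.ev_pa,
                self.ev_pb,
                self.ev_sep,
                self.ev_same,
            )
            if n_ev <= len(self.ev_pa):
                return n_ev
            cap = 2 * n_ev
            self.ev_pa = np.zeros(cap, dtype=np.int64)
            self.ev_pb = np.zeros(cap, dtype=np.int64)
            self.ev_sep = np.zeros(cap)
            self.ev_same = np.zeros(cap, dtype=np.bool_)

    # -- bonds -----------------------------------------------------------
    def add_bond(self, pa: int, pb: int) -> None:
        self.patch_bond[pa] = pb
        self.patch_bond[pb] = pa
        self.bonds_dirty = True
        reactions.update_patch_states(self, pa)
        if not self.completed and self.blueprint.kind == "capsid":
            cid = int(self.mon_cluster[self.patch_mon[pa]])
            if len(self.clus_members[cid]) == self.blueprint.n_f:
                self._check_completion()

    def bond_list(self) -> np.ndarray:
        """Patch indices p of unlocked bonds with p < partner(p)."""
        if self.bonds_dirty:
            p = np.nonzero(self.patch_bond >= 0)[0]
            p = p[self.patch_bond[p] > p]
            p = p[self.patch_state[p] != reactions.STATE_LOCKED]
            self._bond_list = p
            self.bonds_dirty = False
        return self._bond_list

    def bonded_component(self, m0: int) -> set[int]:
        t = self.tables
        seen = {int(m0)}
        stack = [int(m0)]
        while stack:
            m = stack.pop()
            base = self.mon_patch_start[m]
            for loc in range(t.type_patch_count[self.mon_type[m]]):
                q = self.patch_bond[base + loc]
                if q >= 0:
                    other = int(self.patch_mon[q])
                    if other not in seen:
                        seen.add(other)
                        stack.append(other)
        return seen

    def monomer_count_check(self) -> int:
        return int(sum(len(self.clus_members[c]) for c in self.alive_ids))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _type_counts(config: SimulationConfig, tables: ReactionTables) -> dict[str, int]:
    if config.composition is not None:
        return dict(config.composition)
    bp = config.blueprint
    slots = {t: 0 for t in tables.type_ids}
    for t in bp.slot_types:
        slots[t] += 1
    total = len(bp.slot_types)
    counts = {t: int(config.N * c // total) for t, c in slots.items()}
    # distribute the remainder deterministically, largest fraction first
    rem = config.N - sum(counts.values())
    order = sorted(
        tables.type_ids,
        key=lambda t: (config.N * slots[t] / total) - counts[t],
        reverse=True,
    )
    for t in order[:rem]:
        counts[t] += 1
    return counts


def initialize_world(config: SimulationConfig) -> WorldState:
    """Place N monomers at random non-overlapping positions with uniform
    random orientations; every monomer starts as its own cluster."""
    config.validate()
    tables = ReactionTables(
        config.blueprint, config.mode, config.k_a, config.k_d
    )
    world = WorldState(config, tables)
    rng = world.rng
    R = config.blueprint.R
    L = config.L
    M = config.N

    counts = _type_counts(config, tables)
    type_seq = []
    for tid in tables.type_ids:
        type_seq += [tables.type_ids.index(tid)] * counts.get(tid, 0)
    world.mon_type[:] = np.array(type_seq, dtype=np.int64)

    # patch layout
    starts, pmon, pclass = [], [], []
    for m in range(M):
        starts.append(len(pmon))
        t = world.mon_type[m]
        for loc in range(tables.type_patch_count[t]):
            pmon.append(m)
            pclass.append(tables.type_patch_offset[t] + loc)
    world.mon_patch_start[:] = np.array(starts, dtype=np.int64)
    world.patch_mon = np.array(pmon, dtype=np.int64)
    world.patch_class = np.array(pclass, dtype=np.int64)
    world.patch_state = tables.class_init_state[world.patch_class].copy()
    world.patch_bond = np.full(len(pmon), -1, dtype=np.int64)

    # rejection-sampled placement
    placed = np.empty((M, 3))
    min2 = (2.0 * R) ** 2
    for m in range(M):
        for attempt in range(config.insertion_attempts):
            x = rng.uniform(0.0, L, size=3)
            if m == 0:
                break
            d = placed[:m] - x
            d -= L * np.round(d / L)
            if (d * d).sum(axis=1).min() >= min2:
                break
        else:
            raise ConfigError(
                f"could not place monomer {m}: packing fraction too high "
                f"(N={M}, L={L})"
            )
        placed[m] = x
    world.mon_wpos[:] = placed

    # uniform random orientations
    quats = rng.standard_normal((M, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    world.mon_wrot[:] = Rotation.from_quat(quats).as_matrix()

    # one cluster per monomer; identical single-bead tensors
    d_t, d_r = stokes_einstein(R, config.temperature, config.viscosity)
    tensor_template = DiffusionTensor(
        matrix=np.diag([d_t, d_t, d_t, d_r, d_r, d_r]),
        mobility_center=np.zeros(3),
    )
    chol = tensor_template.cholesky_step_factor(config.dt) if config.dt > 0 else np.zeros((6, 6))
    for m in range(M):
        cid = world._free.pop()
        world.clus_alive[cid] = True
        world.clus_pos[cid] = placed[m]
        world.clus_rot[cid] = np.eye(3)
        world.clus_chol[cid] = chol
        world.clus_dtrace[cid] = 3 * d_t
        world.clus_members[cid] = np.array([m], dtype=np.int64)
        world._tensor_cache[cid] = DiffusionTensor(
            matrix=tensor_template.matrix.copy(), mobility_center=placed[m].copy()
        )
        world.mon_cluster[m] = cid
        world.mon_bpos[m] = 0.0
        world.mon_brot[m] = world.mon_wrot[m]
    world._alive_ids = None
    world._members_stale = True
    world.verlet_dirty = True
    return world


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def step(world: WorldState) -> None:
    """Advance the world by one timestep dt."""
    if world._members_stale:
        world._rebuild_members()
    world.ensure_verlet()  # propagation needs current clash candidates
    maxdisp = K.propagate(
        world.alive_ids,
        world.clus_pos,
        world.clus_rot,
        world.clus_chol,
        world.members_flat,
        world.members_start,
        world.members_count,
        world.mon_bpos,
        world.mon_brot,
        world.mon_wpos,
        world.mon_wrot,
        world.mon_cluster,
        world.verlet_ref,
        world.pairs,
        world.n_pairs,
        world.tmp_pos,
        world.blueprint.R,
        world.L,
    )
    if maxdisp > 0.5 * world.skin:
        world.verlet_dirty = True
    world.ensure_verlet()

    n_ev = world.scan()
    if n_ev:
        order = world.rng.permutation(n_ev)
        for k in order:
            ev = reactions.EncounterEvent(
                int(world.ev_pa[k]),
                int(world.ev_pb[k]),
                float(world.ev_sep[k]),
                bool(world.ev_same[k]),
            )
            reactions.attempt_association(world, ev)
        if world._members_stale:
            world._rebuild_members()

    bonds = world.bond_list()
    if len(bonds):
        p_break = world.tables.class_kd[world.patch_class[bonds]] * world.dt
        hits = bonds[world.rng.random(len(bonds)) < p_break]
        if len(hits):
            for p in world.rng.permutation(hits):
                if world.patch_bond[p] >= 0:  # may have been handled already
                    reactions.remove_bond(world, int(p))
            if world._members_stale:
                world._rebuild_members()

    world.clock += world.dt


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass
class ClusterCensus:
    """Snapshot of the cluster-size distribution at time t."""

    t: float
    nu: np.ndarray        # nu[n-1] = number of clusters of size n
    N: int                # monomers covered by the census

    @property
    def p(self) -> np.ndarray:
        """Occupancy p(n) = nu_n * n / N (sums to one)."""
        n = np.arange(1, len(self.nu) + 1)
        return self.nu * n / self.N

    @property
    def nbar(self) -> float:
        """Average cluster size, monomer-weighted: nbar = sum p(n) n."""
        n = np.arange(1, len(self.nu) + 1)
        return float((self.p * n).sum())


def census(world: WorldState, type_ids: list[str] | None = None) -> ClusterCensus:
    """Count clusters by size, optionally restricted to particle types."""
    bp = world.blueprint
    nu = np.zeros(bp.n_f, dtype=np.int64)
    tsel = None
    if type_ids is not None:
        tsel = {world.tables.type_ids.index(t) for t in type_ids}
    covered = 0
    for cid in world.alive_ids:
        members = world.clus_members[cid]
        if tsel is not None and int(world.mon_type[members[0]]) not in tsel:
            continue
        nu[len(members) - 1] += 1
        covered += len(members)
    return ClusterCensus(t=world.clock, nu=nu, N=covered if tsel is not None else world.M)


@dataclass
class ObservableSeries:
    """Time-resolved observables of one trajectory."""

    times: np.ndarray
    nu: np.ndarray                    # (n_records, n_f)
    fpt: dict[int, float]             # size -> first time size was reached
    outcome: str                      # "success" | "censored"
    max_time: float
    n_f: int
    N: int
    mode: str
    ring_events: list[tuple[float, int]] = field(default_factory=list)
    seed: int | None = None

    def reached(self, size: int) -> bool:
        return size in self.fpt

    def fpt_of(self, size: int) -> float:
        """First-passage time to cluster size >= size; the trajectory
        horizon if censored (check `reached` first)."""
        return self.fpt.get(size, self.max_time)

    @property
    def censored(self) -> bool:
        return self.outcome != "success"

    @property
    def assembly_speed(self) -> float:
        """v = 1 / FPT(n_f); zero for censored trajectories."""
        if self.censored:
            return 0.0
        return 1.0 / self.fpt[self.n_f]

    @property
    def max_size(self) -> int:
        return max(self.fpt)

    def nbar_series(self) -> np.ndarray:
        n = np.arange(1, self.n_f + 1)
        return (self.nu * n * n).sum(axis=1) / self.N

    def capsomer_completion_times(self) -> dict[int, list[float]]:
        """Ring-lock times grouped by ring size (hierarchical mode)."""
        out: dict[int, list[float]] = {}
        for t, size in self.ring_events:
            out.setdefault(size, []).append(t)
        return out


def run(config: SimulationConfig, census_types: list[str] | None = None) -> ObservableSeries:
    """Run one trajectory to completion or max_time.

    A trajectory is successful when a cluster with n_f members and the
    full bond complement of the blueprint exists within max_time.
    """
    world = initialize_world(config)
    times = [0.0]
    records = [census(world, census_types).nu.copy()]
    next_record = config.record_interval
    n_steps = 0
    max_steps = math.inf if config.dt == 0 else int(round(config.max_time / config.dt))
    while not world.completed and n_steps < max_steps:
        step(world)
        n_steps += 1
        if world.clock >= next_record - 1e-9:
            times.append(world.clock)
            records.append(census(world, census_types).nu.copy())
            next_record += config.record_interval
    if world.clock != times[-1]:
        times.append(world.clock)
        records.append(census(world, census_types).nu.copy())
    return ObservableSeries(
        times=np.array(times),
        nu=np.array(records),
        fpt=dict(world.fpt),
        outcome="success" if world.completed else "censored",
        max_time=config.max_time,
        n_f=config.blueprint.n_f,
        N=config.N,
        mode=config.mode,
        ring_events=list(world.ring_events),
        seed=config.seed,
    )


def ensemble_yield(results: list[ObservableSeries], target_size: int) -> float:
    """Fraction of trajectories that reached target_size within their
    simulation time."""
    if not results:
        raise ValueError("empty ensemble")
    return sum(r.reached(target_size) for r in results) / len(results)


def phase_of(cluster_size: int, n_f: int) -> str:
    """Assembly phase by cluster size: early (< n_f/3), intermediate
    (n_f/3 <= size < 2 n_f/3), final (>= 2 n_f/3)."""
    if not 1 <= cluster_size <= n_f:
        raise ValueError(f"cluster size {cluster_size} outside 1..{n_f}")
    if cluster_size < n_f / 3:
        return "early"
    if cluster_size < 2 * n_f / 3:
        return "intermediate"
    return "final"
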