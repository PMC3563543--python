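"""Caspar-Klug capsid blueprints for T1 and T3 shells.

A blueprint is the single source of geometric truth for the simulator: it
holds the ideal coordinates and orientations of every monomer slot in the
completed shell, the reactive-patch layout of every particle type, and the
bond rules (relative rigid transforms) extracted from those coordinates.

Construction
------------
Both supported geometries derive from the truncated icosahedron, whose 12
pentagonal and 20 hexagonal faces mirror the capsomer layout of an
icosahedral shell:

* **T1** (60 monomers): one monomer per truncated-icosahedron vertex.  The
  pentagonal faces are the 12 pentamer rings; the 30 edges shared by two
  hexagonal faces are the inter-capsomer contacts.  Every monomer carries
  two intra-capsomer patches and one (self-complementary) inter patch, and
  the complete shell has 90 bonds.  All bonded neighbours sit at centre
  distance exactly 2R because all edges of the solid are equal.
* **T3** (180 monomers): one monomer per (face, vertex) incidence.  Each
  face contributes a ring of monomers pulled from its corners towards the
  face centre — 12 pentamer rings of one protein type P and 20 hexamer
  rings alternating two types A and B.  At each of the 60 polyhedron
  vertices the three incident faces contribute one monomer each (one P,
  one A, one B), and these vertex triangles carry the inter-capsomer
  bonds.  The A/B colouring follows the globally consistent outward
  orientation of the icosahedron faces, which makes every vertex triangle
  identically typed.

Patch directions and bond transforms are *derived* from the ideal
coordinates, never prescribed: per particle type a reference slot defines
the body-frame patch directions, every other slot's orientation is the
unique rotation mapping the reference patch set onto its own bond
directions, and each bond rule's relative transform is read off a bonded
slot pair (and checked for consistency across all its instances).

Flat ring blueprints (isolated pentamers/hexamers, used for the capsomer
formation experiments) are built by the same machinery from ideal ring
coordinates in a plane.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from ._transforms import (
    pose_compose,
    pose_inverse,
    pose_relative,
    quat_identity,
    rotation_angle,
)

INTRA = "intra"
INTER = "inter"

#: default hard-sphere radius and patch radius, nm
DEFAULT_R = 1.0
DEFAULT_PATCH_RADIUS = 0.4

_GEOM_TOL = 1e-6  # nm / rad, declared tolerance for all blueprint invariants


class BlueprintError(ValueError):
    """Raised for invalid blueprint requests or inconsistent constructions."""


@dataclass(frozen=True)
class PatchSpec:
    """A reactive patch in a particle type's body frame."""

    patch_id: str          # globally unique, e.g. "P.intra_next"
    direction: np.ndarray  # unit vector, body frame
    kind: str              # INTRA or INTER
    partner_patch_id: str  # complementary patch (may equal patch_id)

    def initial_state(self, mode: str) -> str:
        """Initial reactivity: all patches active in direct mode, only the
        two intra-capsomer patches in hierarchical mode."""
        if mode == "direct":
            return "active"
        if mode == "hierarchical":
            return "active" if self.kind == INTRA else "inactive"
        raise BlueprintError(f"unknown mode {mode!r}; expected 'direct' or 'hierarchical'")


@dataclass(frozen=True)
class ParticleTypeSpec:
    type_id: str
    patches: tuple[PatchSpec, ...]
    ring_size: int  # size of the capsomer ring this type belongs to (5 or 6)

    def patch_index(self, patch_id: str) -> int:
        for i, p in enumerate(self.patches):
            if p.patch_id == patch_id:
                return i
        raise KeyError(patch_id)


@dataclass(frozen=True)
class BondRule:
    """Bond between two complementary patches.

    ``relative_transform = (quat, trans)`` places the partner monomer B
    relative to monomer A (body frame of A) when A's ``patch_pair[0]``
    binds B's ``patch_pair[1]``.  Rates are per-rule defaults that a
    simulation configuration may override uniformly or per bond kind.
    """

    patch_pair: tuple[str, str]
    relative_transform: tuple[np.ndarray, np.ndarray]
    kind: str                 # INTRA or INTER
    lockable: bool            # intra bonds become permanent on ring closure
    rest_distance: float      # centre-centre distance in the ideal shell, nm
    k_a: float | None = None  # ns^-1, per encounter
    k_d: float | None = None  # ns^-1, per bond


@dataclass
class CapsidBlueprint:
    """Target geometry: particle types, capsomers, bond rules, ideal poses."""

    T_number: int | None           # 1, 3, or None for ring-only blueprints
    n_f: int                       # monomers in the complete target
    particle_types: dict[str, ParticleTypeSpec]
    capsomers: list[tuple[str, list[int]]]      # (kind, cyclic slot list)
    bond_rules: dict[tuple[str, str], BondRule]
    slot_types: list[str]                       # per-slot particle type id
    ideal_positions: np.ndarray                 # (n_f, 3), nm
    ideal_quats: np.ndarray                     # (n_f, 4), scalar-last
    contacts: list[tuple[int, int, str, str]]   # (slot_i, slot_j, pid_i, pid_j)
    R: float = DEFAULT_R
    patch_radius: float = DEFAULT_PATCH_RADIUS
    kind: str = "capsid"          # "capsid" or "capsomers"
    shell_radius: float | None = None
    meta: dict = field(default_factory=dict)

    # -- convenience ---------------------------------------------------
    @property
    def n_pentamers(self) -> int:
        return sum(1 for k, _ in self.capsomers if k == "pentamer")

    @property
    def n_hexamers(self) -> int:
        return sum(1 for k, _ in self.capsomers if k == "hexamer")

    def rule_for(self, pid_a: str, pid_b: str) -> BondRule:
        key = (pid_a, pid_b) if (pid_a, pid_b) in self.bond_rules else (pid_b, pid_a)
        return self.bond_rules[key]

    def partner_of(self, patch_id: str) -> str:
        for t in self.particle_types.values():
            for p in t.patches:
                if p.patch_id == patch_id:
                    return p.partner_patch_id
        raise KeyError(patch_id)

    # -- I/O -----------------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "T_number": self.T_number,
            "n_f": self.n_f,
            "kind": self.kind,
            "R": self.R,
            "patch_radius": self.patch_radius,
            "shell_radius": self.shell_radius,
            "particle_types": {
                tid: {
                    "ring_size": t.ring_size,
                    "patches": [
                        {
                            "patch_id": p.patch_id,
                            "direction": p.direction.tolist(),
                            "kind": p.kind,
                            "partner_patch_id": p.partner_patch_id,
                        }
                        for p in t.patches
                    ],
                }
                for tid, t in self.particle_types.items()
            },
            "capsomers": [[k, list(s)] for k, s in self.capsomers],
            "bond_rules": [
                {
                    "patch_pair": list(r.patch_pair),
                    "quat": r.relative_transform[0].tolist(),
                    "trans": r.relative_transform[1].tolist(),
                    "kind": r.kind,
                    "lockable": r.lockable,
                    "rest_distance": r.rest_distance,
                }
                for r in self.bond_rules.values()
            ],
            "slot_types": self.slot_types,
            "ideal_positions": self.ideal_positions.tolist(),
            "ideal_quats": self.ideal_quats.tolist(),
            "contacts": [list(c) for c in self.contacts],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CapsidBlueprint":
        doc = json.loads(text)
        types = {}
        for tid, t in doc["particle_types"].items():
            patches = tuple(
                PatchSpec(
                    patch_id=p["patch_id"],
                    direction=np.asarray(p["direction"], dtype=float),
                    kind=p["kind"],
                    partner_patch_id=p["partner_patch_id"],
                )
                for p in t["patches"]
            )
            types[tid] = ParticleTypeSpec(tid, patches, t["ring_size"])
        rules = {}
        for r in doc["bond_rules"]:
            pair = tuple(r["patch_pair"])
            rules[pair] = BondRule(
                patch_pair=pair,
                relative_transform=(
                    np.asarray(r["quat"], dtype=float),
                    np.asarray(r["trans"], dtype=float),
                ),
                kind=r["kind"],
                lockable=r["lockable"],
                rest_distance=r["rest_distance"],
            )
        return cls(
            T_number=doc["T_number"],
            n_f=doc["n_f"],
            particle_types=types,
            capsomers=[(k, list(s)) for k, s in doc["capsomers"]],
            bond_rules=rules,
            slot_types=list(doc["slot_types"]),
            ideal_positions=np.asarray(doc["ideal_positions"], dtype=float),
            ideal_quats=np.asarray(doc["ideal_quats"], dtype=float),
            contacts=[tuple(c) for c in doc["contacts"]],
            R=doc["R"],
            patch_radius=doc["patch_radius"],
            kind=doc["kind"],
            shell_radius=doc["shell_radius"],
        )

    def to_xyz(self, comment: str = "") -> str:
        """Ideal shell as an XYZ frame, element label = particle type."""
        lines = [str(len(self.slot_types)), comment or f"capsidyn blueprint T={self.T_number}"]
        for t, p in zip(self.slot_types, self.ideal_positions):
            lines.append(f"{t.split('.')[0][:2]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# polyhedral scaffolding
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Vertices and outward-CCW faces of a regular icosahedron (edge 2)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for a, b in itertools.product((-1.0, 1.0), repeat=2):
        verts += [(0.0, a, b * phi), (a, b * phi, 0.0), (b * phi, 0.0, a)]
    v = np.array(verts)
    hull = ConvexHull(v)
    faces = []
    for simplex in hull.simplices:
        i, j, k = (int(x) for x in simplex)
        n = np.cross(v[j] - v[i], v[k] - v[i])
        if np.dot(n, v[[i, j, k]].mean(axis=0)) < 0:
            j, k = k, j  # enforce outward normal = CCW seen from outside
        faces.append((i, j, k))
    return v, faces


def _truncated_icosahedron():
    """Vertex coordinates and face rings of the truncated icosahedron.

    Returns (points, pentagons, hexagons) where points[(u, v)] is the
    vertex one third of the way along the directed icosahedron edge u->v,
    and the face rings are lists of directed-edge keys in CCW order seen
    from outside.
    """
    v, faces = _icosahedron()
    points: dict[tuple[int, int], np.ndarray] = {}
    for i, j, k in faces:
        for a, b in ((i, j), (j, i), (j, k), (k, j), (k, i), (i, k)):
            points[(a, b)] = v[a] + (v[b] - v[a]) / 3.0

    hexagons = [
        [(i, j), (j, i), (j, k), (k, j), (k, i), (i, k)] for (i, j, k) in faces
    ]

    pentagons = []
    for w in range(len(v)):
        keys = [k for k in points if k[0] == w]
        axis = v[w] / np.linalg.norm(v[w])
        e1 = np.cross(axis, [0.12, 0.34, 0.91])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        ang = {
            k: np.arctan2(np.dot(points[k], e2), np.dot(points[k], e1)) for k in keys
        }
        ring = sorted(keys, key=lambda k: ang[k])
        # ensure CCW seen from outside (axis points outward)
        p = [points[k] for k in ring]
        n = np.cross(p[1] - p[0], p[2] - p[1])
        if np.dot(n, axis) < 0:
            ring = ring[::-1]
        pentagons.append(ring)
    return points, pentagons, hexagons


# ---------------------------------------------------------------------------
# slot layout for T1 and T3
# ---------------------------------------------------------------------------

def _t1_layout(R: float):
    points, pentagons, hexagons = _truncated_icosahedron()
    keys = sorted(points)
    index = {k: i for i, k in enumerate(keys)}
    edge = np.linalg.norm(points[keys[0]] - points[(keys[0][1], keys[0][0])])
    # hexagon-hexagon edges are the middle thirds of the original edges and
    # have the same length as the pentagon edges; scale all edges to 2R
    scale = 2.0 * R / edge
    pos = np.array([points[k] for k in keys]) * scale

    rings = [("pentamer", [index[k] for k in ring]) for ring in pentagons]
    slot_types = ["T1"] * len(keys)

    contacts = []
    for _, ring in rings:
        m = len(ring)
        for a in range(m):
            i, j = ring[a], ring[(a + 1) % m]
            contacts.append((i, j, "T1.intra_next", "T1.intra_prev"))
    for (u, w) in {tuple(sorted(k)) for k in keys}:
        i, j = index[(u, w)], index[(w, u)]
        contacts.append((i, j, "T1.inter", "T1.inter"))

    type_patch_ids = {
        "T1": {
            "ring_size": 5,
            "partners": {
                "T1.intra_next": "T1.intra_prev",
                "T1.intra_prev": "T1.intra_next",
                "T1.inter": "T1.inter",
            },
            "kinds": {
                "T1.intra_next": INTRA,
                "T1.intra_prev": INTRA,
                "T1.inter": INTER,
            },
        }
    }
    return pos, slot_types, rings, contacts, type_patch_ids


def _t3_layout(R: float):
    points, pentagons, hexagons = _truncated_icosahedron()
    all_faces = [("pentamer", ring) for ring in pentagons] + [
        ("hexamer", ring) for ring in hexagons
    ]
    centers = {
        fi: np.mean([points[k] for k in ring], axis=0)
        for fi, (_, ring) in enumerate(all_faces)
    }

    # shrink factor s: slots sit at w + s*(face centre - w).  Intra-ring
    # neighbour distance is (1-s)*edge; vertex-triangle (inter) distances are
    # s*|c_f - c_g| for the two incident-face pairs.  Choose s so the closest
    # inter contact sits at exactly the intra contact distance (2R after
    # scaling); the other inter contact then rests slightly above 2R, which
    # the snap-to-transform bond model permits.
    k0 = next(iter(points))
    edge = np.linalg.norm(points[k0] - points[(k0[1], k0[0])])
    vertex_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (_, ring) in enumerate(all_faces):
        for k in ring:
            vertex_faces.setdefault(k, []).append(fi)
    dmin = np.inf
    for k, fis in vertex_faces.items():
        for fa, fb in itertools.combinations(fis, 2):
            dmin = min(dmin, np.linalg.norm(centers[fa] - centers[fb]))
    s = edge / (edge + dmin)
    scale = 2.0 * R / ((1.0 - s) * edge)

    slot_of: dict[tuple[int, tuple[int, int]], int] = {}
    pos_list, slot_types, rings = [], [], []
    for fi, (fkind, ring) in enumerate(all_faces):
        slots = []
        for pi, k in enumerate(ring):
            idx = len(pos_list)
            slot_of[(fi, k)] = idx
            pos_list.append((points[k] + s * (centers[fi] - points[k])) * scale)
            if fkind == "pentamer":
                slot_types.append("P")
            else:
                # A on even ring positions = slots whose truncated vertex is
                # the source of the directed face edge; consistent across
                # faces because all faces are oriented outward-CCW.
                slot_types.append("A" if pi % 2 == 0 else "B")
            slots.append(idx)
        rings.append((fkind, slots))
    pos = np.array(pos_list)

    contacts = []
    for _, slots in rings:
        m = len(slots)
        for a in range(m):
            i, j = slots[a], slots[(a + 1) % m]
            ti, tj = slot_types[i], slot_types[j]
            contacts.append((i, j, f"{ti}.intra_next", f"{tj}.intra_prev"))

    for k, fis in vertex_faces.items():
        if len(fis) != 3:
            raise BlueprintError("truncated icosahedron vertex without 3 faces")
        tri = [slot_of[(fi, k)] for fi in fis]
        tset = sorted(slot_types[i] for i in tri)
        if tset != ["A", "B", "P"]:
            raise BlueprintError(
                f"inconsistent vertex triangle typing {tset} at vertex {k}"
            )
        for i, j in itertools.combinations(tri, 2):
            ti, tj = slot_types[i], slot_types[j]
            contacts.append((i, j, f"{ti}.inter_{tj}", f"{tj}.inter_{ti}"))

    def _t3_partners(tid, others):
        a, b = others
        return {
            f"{tid}.intra_next": f"{a if tid != 'P' else 'P'}.intra_prev",
            f"{tid}.intra_prev": f"{a if tid != 'P' else 'P'}.intra_next",
            f"{tid}.inter_{a}": f"{a}.inter_{tid}",
            f"{tid}.inter_{b}": f"{b}.inter_{tid}",
        }

    type_patch_ids = {
        "P": {"ring_size": 5, "partners": _t3_partners("P", ("A", "B"))},
        "A": {"ring_size": 6, "partners": _t3_partners("A", ("B", "P"))},
        "B": {"ring_size": 6, "partners": _t3_partners("B", ("A", "P"))},
    }
    for tid, d in type_patch_ids.items():
        d["kinds"] = {
            pid: (INTRA if ".intra" in pid else INTER) for pid in d["partners"]
        }
    return pos, slot_types, rings, contacts, type_patch_ids


def _ring_layout(R: float, ring_size: int, type_cycle: list[str], prefix_ring=None):
    """Flat ring of ``ring_size`` monomers with neighbour distance 2R."""
    rho = R / np.sin(np.pi / ring_size)
    ang = 2.0 * np.pi * np.arange(ring_size) / ring_size
    pos = np.stack([rho * np.cos(ang), rho * np.sin(ang), np.zeros(ring_size)], axis=1)
    slot_types = [type_cycle[i % len(type_cycle)] for i in range(ring_size)]
    rings = [("pentamer" if ring_size == 5 else "hexamer", list(range(ring_size)))]
    contacts = []
    for a in range(ring_size):
        i, j = a, (a + 1) % ring_size
        contacts.append(
            (i, j, f"{slot_types[i]}.intra_next", f"{slot_types[j]}.intra_prev")
        )
    type_patch_ids = {}
    for i, tid in enumerate(slot_types):
        if tid in type_patch_ids:
            continue
        nxt = slot_types[(i + 1) % ring_size]
        prv = slot_types[(i - 1) % ring_size]
        type_patch_ids[tid] = {
            "ring_size": ring_size,
            "partners": {
                f"{tid}.intra_next": f"{nxt}.intra_prev",
                f"{tid}.intra_prev": f"{prv}.intra_next",
            },
            "kinds": {f"{tid}.intra_next": INTRA, f"{tid}.intra_prev": INTRA},
        }
    return pos, slot_types, rings, contacts, type_patch_ids


# ---------------------------------------------------------------------------
# orientation + rule extraction
# ---------------------------------------------------------------------------

def _derive_blueprint(
    pos, slot_types, rings, contacts, type_patch_ids, R, patch_radius, T_number, kind
) -> CapsidBlueprint:
    n = len(pos)
    # world-frame bond directions per slot, labelled by patch id
    slot_dirs: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    for i, j, pid_i, pid_j in contacts:
        d = pos[j] - pos[i]
        d = d / np.linalg.norm(d)
        for slot, pid, vec in ((i, pid_i, d), (j, pid_j, -d)):
            if pid in slot_dirs[slot]:
                raise BlueprintError(
                    f"slot {slot} would carry patch {pid} twice (ambiguous contact)"
                )
            slot_dirs[slot][pid] = vec

    # reference slot per type fixes the body-frame patch directions
    quats = np.zeros((n, 4))
    body_dirs: dict[str, dict[str, np.ndarray]] = {}
    for tid in type_patch_ids:
        ref = slot_types.index(tid)
        body_dirs[tid] = {pid: v.copy() for pid, v in slot_dirs[ref].items()}
        expected = set(type_patch_ids[tid]["partners"])
        if set(body_dirs[tid]) != expected:
            raise BlueprintError(
                f"type {tid}: reference slot patches {sorted(body_dirs[tid])} "
                f"!= declared {sorted(expected)}"
            )
    for i in range(n):
        tid = slot_types[i]
        pids = sorted(body_dirs[tid])
        ref_mat = np.array([body_dirs[tid][p] for p in pids])
        cur_mat = np.array([slot_dirs[i][p] for p in pids])
        rot, rssd = Rotation.align_vectors(cur_mat, ref_mat)
        if rssd > 1e-6:
            raise BlueprintError(
                f"slot {i} ({tid}) patch layout incongruent with reference "
                f"(rssd={rssd:.2e})"
            )
        quats[i] = rot.as_quat()

    # particle types
    types = {}
    for tid, d in type_patch_ids.items():
        patches = tuple(
            PatchSpec(
                patch_id=pid,
                direction=body_dirs[tid][pid],
                kind=d["kinds"][pid],
                partner_patch_id=d["partners"][pid],
            )
            for pid in sorted(d["partners"])
        )
        types[tid] = ParticleTypeSpec(tid, patches, d["ring_size"])

    # bond rules: relative transform from every instance, checked consistent
    rules: dict[tuple[str, str], BondRule] = {}
    for i, j, pid_i, pid_j in contacts:
        a, b, pa, pb = i, j, pid_i, pid_j
        if pa > pb:
            a, b, pa, pb = j, i, pid_j, pid_i
        q, t = pose_relative(quats[a], pos[a], quats[b], pos[b])
        rest = float(np.linalg.norm(pos[a] - pos[b]))
        kindab = INTRA if ".intra" in pa else INTER
        rule = BondRule(
            patch_pair=(pa, pb),
            relative_transform=(q, t),
            kind=kindab,
            lockable=kindab == INTRA,
            rest_distance=rest,
        )
        prev = rules.get((pa, pb))
        if prev is None:
            rules[(pa, pb)] = rule
        else:
            dq, dt = pose_relative(
                *prev.relative_transform, *rule.relative_transform
            )
            if rotation_angle(dq) > _GEOM_TOL or np.linalg.norm(dt) > _GEOM_TOL:
                raise BlueprintError(
                    f"bond rule {pa}~{pb} inconsistent across instances "
                    f"({i},{j}): d_angle={rotation_angle(dq):.2e}"
                )

    bp = CapsidBlueprint(
        T_number=T_number,
        n_f=n,
        particle_types=types,
        capsomers=rings,
        bond_rules=rules,
        slot_types=list(slot_types),
        ideal_positions=pos,
        ideal_quats=quats,
        contacts=list(contacts),
        R=R,
        patch_radius=patch_radius,
        kind=kind,
        shell_radius=float(np.linalg.norm(pos, axis=1).mean()) if kind == "capsid" else None,
    )
    return bp


def build_blueprint(
    T_number: int,
    mode: str = "direct",
    R: float = DEFAULT_R,
    patch_radius: float = DEFAULT_PATCH_RADIUS,
) -> CapsidBlueprint:
    """Construct the T1 or T3 capsid blueprint.

    ``mode`` only affects which patches start active (recorded in
    ``blueprint.meta['mode']``; `PatchSpec.initial_state` evaluates it) —
    the geometry is identical for direct and hierarchical assembly.
    """
    if mode not in ("direct", "hierarchical"):
        raise BlueprintError(f"unknown mode {mode!r}; expected 'direct' or 'hierarchical'")
    if T_number == 1:
        layout = _t1_layout(R)
    elif T_number == 3:
        layout = _t3_layout(R)
    else:
        raise BlueprintError(
            f"unsupported triangulation number T={T_number}; this package "
            "implements T in {1, 3}"
        )
    bp = _derive_blueprint(*layout, R, patch_radius, T_number, "capsid")
    bp.meta["mode"] = mode
    return bp


def build_ring_blueprint(
    ring_size: int,
    n_types: int = 1,
    R: float = DEFAULT_R,
    patch_radius: float = DEFAULT_PATCH_RADIUS,
    type_ids: list[str] | None = None,
) -> CapsidBlueprint:
    """Blueprint for an isolated flat capsomer ring (no inter patches)."""
    if ring_size not in (5, 6):
        raise BlueprintError("ring_size must be 5 or 6")
    if n_types == 2 and ring_size % 2:
        raise BlueprintError("two-type rings require even ring size")
    if type_ids is None:
        type_ids = ["H"] if n_types == 1 else ["A", "B"]
    layout = _ring_layout(R, ring_size, type_ids)
    bp = _derive_blueprint(*layout, R, patch_radius, None, "capsomers")
    bp.meta["mode"] = "hierarchical"
    return bp


def build_capsomer_mixture_blueprint(
    identical_hexamers: bool,
    R: float = DEFAULT_R,
    patch_radius: float = DEFAULT_PATCH_RADIUS,
) -> CapsidBlueprint:
    """Blueprint for the down-scaled capsomer-formation experiment: hexamer
    rings (one type or two alternating types) coexisting with
    pentamer-forming monomers.  Only intra patches exist; completed rings
    lock and are inert."""
    hx = build_ring_blueprint(6, 1 if identical_hexamers else 2, R, patch_radius)
    pent = build_ring_blueprint(5, 1, R, patch_radius, type_ids=["P5"])
    # keep the ideal frames of the two rings sterically disjoint
    pent.ideal_positions = pent.ideal_positions + np.array([0.0, 0.0, 4.0 * R])
    types = dict(hx.particle_types)
    types.update(pent.particle_types)
    rules = dict(hx.bond_rules)
    rules.update(pent.bond_rules)
    bp = CapsidBlueprint(
        T_number=None,
        n_f=6,
        particle_types=types,
        capsomers=hx.capsomers + [("pentamer", [i + 6 for i in range(5)])],
        bond_rules=rules,
        slot_types=list(hx.slot_types) + list(pent.slot_types),
        ideal_positions=np.vstack([hx.ideal_positions, pent.ideal_positions]),
        ideal_quats=np.vstack([hx.ideal_quats, pent.ideal_quats]),
        contacts=hx.contacts + [(i + 6, j + 6, a, b) for i, j, a, b in pent.contacts],
        R=R,
        patch_radius=patch_radius,
        kind="capsomers",
    )
    bp.meta["mode"] = "hierarchical"
    bp.meta["identical_hexamers"] = identical_hexamers
    return bp


def ideal_capsid_coordinates(blueprint: CapsidBlueprint):
    """Per-slot ideal poses ``(positions, quaternions)`` of the target."""
    return blueprint.ideal_positions, blueprint.ideal_quats


def bond_table(blueprint: CapsidBlueprint) -> list[BondRule]:
    return list(blueprint.bond_rules.values())


def reconstruct_from_rules(
    blueprint: CapsidBlueprint, seed_slot: int = 0, allow_disconnected: bool = False
):
    """Rebuild all slot poses from seed slots by composing bond-rule
    transforms along a BFS spanning forest of the contact graph.

    For ``capsid`` blueprints the graph must be connected from
    ``seed_slot``; ring-only blueprints may have several components, each
    reconstructed from its own lowest-index slot."""
    n = len(blueprint.slot_types)
    adj: dict[int, list[tuple[int, str, str]]] = {i: [] for i in range(n)}
    for i, j, pa, pb in blueprint.contacts:
        adj[i].append((j, pa, pb))
        adj[j].append((i, pb, pa))
    pos = np.full((n, 3), np.nan)
    quats = np.zeros((n, 4))
    seen: set[int] = set()
    seeds = [seed_slot]
    while seeds:
        seed = seeds.pop()
        pos[seed] = blueprint.ideal_positions[seed]
        quats[seed] = blueprint.ideal_quats[seed]
        seen.add(seed)
        queue = [seed]
        while queue:
            i = queue.pop(0)
            for j, pa, pb in adj[i]:
                if j in seen:
                    continue
                rule = blueprint.rule_for(pa, pb)
                q, t = rule.relative_transform
                if rule.patch_pair[0] != pa:
                    q, t = pose_inverse(q, t)
                quats[j], pos[j] = pose_compose(quats[i], pos[i], q, t)
                seen.add(j)
                queue.append(j)
        if len(seen) != n:
            if not allow_disconnected:
                raise BlueprintError("contact graph is not connected")
            seeds.append(min(set(range(n)) - seen))
    return pos, quats


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def record(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks[name] = (bool(ok), detail)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def __str__(self) -> str:
        lines = []
        for name, (ok, detail) in self.checks.items():
            lines.append(f"[{'PASS' if ok else 'FAIL'}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


def validate_blueprint(bp: CapsidBlueprint) -> ValidationReport:
    """Check every blueprint invariant; report-only (never raises)."""
    rep = ValidationReport()
    eps = _GEOM_TOL

    if bp.kind == "capsid":
        rep.record(
            "monomer_count",
            bp.n_f == 60 * bp.T_number,
            f"n_f={bp.n_f}, T={bp.T_number}",
        )
        rep.record("pentamer_count", bp.n_pentamers == 12, str(bp.n_pentamers))
        rep.record(
            "hexamer_count",
            bp.n_hexamers == 10 * (bp.T_number - 1),
            str(bp.n_hexamers),
        )
        rep.record(
            "particle_type_count",
            len(bp.particle_types) == bp.T_number,
            f"{len(bp.particle_types)} types",
        )

    # capsomer rings are simple cycles of length 5 or 6 with alternation
    ok_rings = True
    for kind, slots in bp.capsomers:
        want = 5 if kind == "pentamer" else 6
        if len(slots) != want or len(set(slots)) != want:
            ok_rings = False
        tids = [bp.slot_types[i] for i in slots]
        if kind == "hexamer" and len(set(tids)) == 2:
            if any(tids[a] == tids[(a + 1) % len(tids)] for a in range(len(tids))):
                ok_rings = False
        if kind == "pentamer" and len(set(tids)) != 1:
            ok_rings = False
    rep.record("capsomer_rings", ok_rings)

    # hard-sphere feasibility of the ideal shell
    dmin = pdist(bp.ideal_positions).min()
    rep.record(
        "steric_feasibility",
        dmin >= 2 * bp.R - eps,
        f"min pairwise distance {dmin:.6f} nm",
    )

    # bonded contacts at their recorded rest distances; intra exactly 2R
    ok_rest = True
    for i, j, pa, pb in bp.contacts:
        d = np.linalg.norm(bp.ideal_positions[i] - bp.ideal_positions[j])
        rule = bp.rule_for(pa, pb)
        if abs(d - rule.rest_distance) > eps:
            ok_rest = False
        if rule.kind == INTRA and abs(d - 2 * bp.R) > eps:
            ok_rest = False
    rep.record("bond_rest_distances", ok_rest)

    # patch complementarity is an involution; patch centres on the surface
    ok_inv, ok_surface = True, True
    for t in bp.particle_types.values():
        for p in t.patches:
            if bp.partner_of(p.partner_patch_id) != p.patch_id:
                ok_inv = False
            if abs(np.linalg.norm(p.direction) - 1.0) > eps:
                ok_surface = False
    rep.record("partner_involution", ok_inv)
    rep.record("patch_on_surface", ok_surface, "patch centre at R*direction")

    # ring-closure: composed intra transforms around every capsomer = identity
    worst_ang, worst_tr = 0.0, 0.0
    for kind, slots in bp.capsomers:
        q, t = quat_identity(), np.zeros(3)
        m = len(slots)
        for a in range(m):
            i, j = slots[a], slots[(a + 1) % m]
            pa = f"{bp.slot_types[i]}.intra_next"
            pb = f"{bp.slot_types[j]}.intra_prev"
            rule = bp.rule_for(pa, pb)
            rq, rt = rule.relative_transform
            if rule.patch_pair[0] != pa:
                rq, rt = pose_inverse(rq, rt)
            q, t = pose_compose(q, t, rq, rt)
        worst_ang = max(worst_ang, rotation_angle(q))
        worst_tr = max(worst_tr, float(np.linalg.norm(t)))
    rep.record(
        "ring_closure",
        worst_ang < eps and worst_tr < eps,
        f"max angle {worst_ang:.2e} rad, max translation {worst_tr:.2e} nm",
    )

    # transform round-trip: rules rebuild the ideal shell
    multi = bp.kind == "capsomers"
    try:
        pos, quats = reconstruct_from_rules(bp, allow_disconnected=multi)
        err = float(np.abs(pos - bp.ideal_positions).max())
        rep.record("reconstruction_roundtrip", err < 1e-5, f"max |dx|={err:.2e} nm")
    except BlueprintError as exc:
        rep.record("reconstruction_roundtrip", False, str(exc))

    # connectivity of the full bond graph (capsid blueprints only)
    if not multi:
        try:
            reconstruct_from_rules(bp)
            rep.record("bond_graph_connected", True)
        except BlueprintError:
            rep.record("bond_graph_connected", False)

    if bp.shell_radius is not None:
        rep.record("shell_radius", True, f"{bp.shell_radius:.4f} nm")
    return rep


def icosahedral_rotation_group() -> np.ndarray:
    """The 60 rotation matrices of the icosahedral group I, generated by
    closure from a five-fold vertex rotation and a three-fold face rotation."""
    v, faces = _icosahedron()
    axis5 = v[0] / np.linalg.norm(v[0])
    f = faces[0]
    c = v[list(f)].mean(axis=0)
    axis3 = c / np.linalg.norm(c)
    g1 = Rotation.from_rotvec(axis5 * (2 * np.pi / 5)).as_matrix()
    g2 = Rotation.from_rotvec(axis3 * (2 * np.pi / 3)).as_matrix()
    elems = [np.eye(3)]

    def _known(m):
        return any(np.abs(m - e).max() < 1e-9 for e in elems)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for e in frontier:
            for g in (g1, g2):
                m = g @ e
                if not _known(m):
                    elems.append(m)
                    nxt.append(m)
        frontier = nxt
    if len(elems) != 60:
        raise RuntimeError(f"group closure produced {len(elems)} elements")
    return np.array(elems)
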