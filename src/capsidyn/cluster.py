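"""Standalone rigid-cluster object with overdamped Brownian propagation.

The assembly engine keeps its clusters in flat arrays for speed; this
module provides the same physics on a self-contained object, convenient
for analysis, testing and single-cluster studies.  A cluster's pose is
its mobility centre position plus a unit quaternion; the Brownian step
draws a correlated 6-vector (translation + rotation, body frame) from
the full covariance ``2 D dt`` of its diffusion tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .diffusion import DiffusionTensor, cluster_diffusion_matrix


@dataclass
class RigidCluster:
    """A rigid assembly of one or more equal spheres.

    ``body_coords`` are bead centres relative to the mobility centre (the
    point the diffusion tensor is expressed about); ``position`` and
    ``orientation`` (scalar-last unit quaternion) give the world pose.
    """

    member_ids: np.ndarray
    body_coords: np.ndarray
    position: np.ndarray
    orientation: np.ndarray
    diffusion: DiffusionTensor
    bond_graph: list[tuple[int, int]] = field(default_factory=list)
    _chol: np.ndarray | None = None
    _chol_dt: float | None = None

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        R: float,
        temperature: float,
        viscosity: float,
        member_ids: np.ndarray | None = None,
    ) -> "RigidCluster":
        """Build a cluster from world bead coordinates; the diffusion
        tensor is computed on the fly and the body frame is centred at
        the cluster's centre of diffusion."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        tensor = cluster_diffusion_matrix(coords, R, temperature, viscosity)
        if member_ids is None:
            member_ids = np.arange(len(coords))
        return cls(
            member_ids=np.asarray(member_ids),
            body_coords=coords - tensor.mobility_center,
            position=tensor.mobility_center.copy(),
            orientation=np.array([0.0, 0.0, 0.0, 1.0]),
            diffusion=tensor,
        )

    @property
    def size(self) -> int:
        return len(self.body_coords)

    def world_coords(self) -> np.ndarray:
        return self.position + Rotation.from_quat(self.orientation).apply(
            self.body_coords
        )

    def propagate(self, dt: float, rng: np.random.Generator) -> None:
        """One Brownian step of length dt (ns), in place.

        The step vector is drawn from N(0, 2 D dt) in the body frame;
        translation is rotated to the world frame, rotation is applied
        about the mobility centre.  ``dt = 0`` leaves the pose unchanged;
        body coordinates are never modified (rigidity).
        """
        if dt < 0:
            raise ValueError("dt must be >= 0")
        if dt == 0.0:
            return
        if self._chol is None or self._chol_dt != dt:
            self._chol = self.diffusion.cholesky_step_factor(dt)
            self._chol_dt = dt
        delta = self._chol @ rng.standard_normal(6)
        rot = Rotation.from_quat(self.orientation)
        self.position = self.position + rot.apply(delta[:3])
        self.orientation = (rot * Rotation.from_rotvec(delta[3:])).as_quat()
        self.orientation /= np.linalg.norm(self.orientation)


def propagate_cluster(
    cluster: RigidCluster, dt: float, rng: np.random.Generator
) -> RigidCluster:
    """Advance ``cluster`` by one Brownian step and return it."""
    cluster.propagate(dt, rng)
    return cluster
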