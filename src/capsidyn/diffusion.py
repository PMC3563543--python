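"""Rigid-body diffusion tensors for clusters of equal hard spheres.

Model
-----
A cluster is a rigid array of beads of radius ``R``.  Translational
hydrodynamic coupling between beads uses the Rotne-Prager-Yamakawa tensor;
each bead additionally contributes its own rotational Stokes friction
``8*pi*eta*R^3`` (pair rotational coupling is neglected).  The bead-level
mobility is contracted onto rigid-body motion, giving a 6x6 resistance
matrix whose inverse times ``k_B T`` is the diffusion matrix.  The matrix
is reported about the cluster's centre of diffusion (the point where the
translation-rotation coupling block is symmetric), so a single bead
reduces exactly to the Stokes-Einstein values and the full 6x6 covariance
(including coupling) can drive the Brownian propagation.

Units: lengths nm, times ns, temperature K, viscosity accepted in Pa s.
With nm/ns units one Joule equals one kg nm^2/ns^2, so only the viscosity
needs rescaling (1 Pa s = 1e-18 kg/(nm ns)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform

KB = 1.380649e-23  # J/K == kg nm^2 / ns^2 / K in internal units
_PAS_TO_INTERNAL = 1e-18  # Pa s -> kg/(nm ns)


class DiffusionError(ValueError):
    pass


def stokes_einstein(R: float, temperature: float, viscosity: float):
    """Translational and rotational diffusion coefficients of a sphere.

    Parameters are the sphere radius (nm), temperature (K) and dynamic
    viscosity (Pa s).  Returns ``(D_t, D_r)`` in nm^2/ns and rad^2/ns:
    ``D_t = k_B T / (6 pi eta R)`` and ``D_r = k_B T / (8 pi eta R^3)``.
    """
    if R <= 0 or temperature <= 0 or viscosity <= 0:
        raise DiffusionError("R, temperature and viscosity must all be positive")
    eta = viscosity * _PAS_TO_INTERNAL
    kt = KB * temperature
    d_t = kt / (6.0 * np.pi * eta * R)
    d_r = kt / (8.0 * np.pi * eta * R**3)
    return d_t, d_r


@dataclass
class DiffusionTensor:
    """6x6 diffusion matrix about ``mobility_center``.

    Block layout: ``matrix[:3, :3]`` translational (nm^2/ns),
    ``matrix[3:, 3:]`` rotational (rad^2/ns), off-diagonal blocks the
    translation-rotation coupling (nm rad/ns).  ``mobility_center`` is
    expressed in the coordinate frame the bead positions were given in.
    """

    matrix: np.ndarray
    mobility_center: np.ndarray

    @property
    def translational_trace(self) -> float:
        return float(np.trace(self.matrix[:3, :3]))

    def cholesky_step_factor(self, dt: float) -> np.ndarray:
        """Lower factor L with L L^T = 2 D dt, used to draw Brownian steps."""
        return np.linalg.cholesky(2.0 * dt * self.matrix)


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def _rpy_mobility(coords: np.ndarray, R: float, eta: float) -> np.ndarray:
    """3n x 3n translational RPY mobility for equal beads (no overlap)."""
    n = len(coords)
    mu0 = 1.0 / (6.0 * np.pi * eta * R)
    rij = coords[None, :, :] - coords[:, None, :]          # (n, n, 3)
    r = np.linalg.norm(rij, axis=-1)
    np.fill_diagonal(r, np.inf)
    e = rij / r[..., None]
    ee = e[..., :, None] * e[..., None, :]                 # (n, n, 3, 3)
    eye = np.eye(3)
    pref = 1.0 / (8.0 * np.pi * eta * r)
    blk = pref[..., None, None] * (
        (eye + ee) + (2.0 * R**2 / r**2)[..., None, None] * (eye / 3.0 - ee)
    )
    blk[np.arange(n), np.arange(n)] = mu0 * eye
    return blk.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def _axial(w: np.ndarray) -> np.ndarray:
    return 0.5 * np.array([w[2, 1] - w[1, 2], w[0, 2] - w[2, 0], w[1, 0] - w[0, 1]])


def cluster_diffusion_matrix(
    body_coords: np.ndarray,
    R: float,
    temperature: float,
    viscosity: float,
) -> DiffusionTensor:
    """Rigid bead-model diffusion tensor of a cluster.

    ``body_coords`` is an (n, 3) array of bead centres (nm).  Beads must
    not overlap (pair distance >= 2R up to round-off).  The single-bead
    case reduces exactly to `stokes_einstein`.
    """
    coords = np.atleast_2d(np.asarray(body_coords, dtype=float))
    n = len(coords)
    if n == 0:
        raise DiffusionError("cluster needs at least one bead")
    if R <= 0 or temperature <= 0 or viscosity <= 0:
        raise DiffusionError("R, temperature and viscosity must all be positive")
    if n > 1 and pdist(coords).min() < 2.0 * R - 1e-7:
        raise DiffusionError("overlapping beads in cluster")

    eta = viscosity * _PAS_TO_INTERNAL
    kt = KB * temperature
    zeta_spin = 8.0 * np.pi * eta * R**3

    if n == 1:
        d_t, d_r = stokes_einstein(R, temperature, viscosity)
        return DiffusionTensor(
            matrix=np.diag([d_t, d_t, d_t, d_r, d_r, d_r]),
            mobility_center=coords[0].copy(),
        )

    mob = _rpy_mobility(coords, R, eta)
    mob_cf = cho_factor(mob)

    def resistance_about(center: np.ndarray) -> np.ndarray:
        d = coords - center
        k = np.zeros((n, 3, 6))
        k[:, 0, 0] = k[:, 1, 1] = k[:, 2, 2] = 1.0
        # rotational block is -cross(d): u_i = U + Omega x d_i
        k[:, 0, 4] = d[:, 2]
        k[:, 0, 5] = -d[:, 1]
        k[:, 1, 3] = -d[:, 2]
        k[:, 1, 5] = d[:, 0]
        k[:, 2, 3] = d[:, 1]
        k[:, 2, 4] = -d[:, 0]
        k = k.reshape(3 * n, 6)
        xi = k.T @ cho_solve(mob_cf, k)
        xi[3:, 3:] += n * zeta_spin * np.eye(3)
        return 0.5 * (xi + xi.T)

    centroid = coords.mean(axis=0)
    d0 = kt * np.linalg.inv(resistance_about(centroid))
    drr = d0[3:, 3:]
    dct = d0[3:, :3]  # angular velocity <- force coupling
    # centre of diffusion: asym(Dct + Drr A(a)) = 0, linear in the shift a
    shift = np.linalg.solve(
        np.trace(drr) * np.eye(3) - drr, -2.0 * _axial(dct - dct.T) / 2.0
    )
    center = centroid + shift
    d = kt * np.linalg.inv(resistance_about(center))
    d = 0.5 * (d + d.T)
    return DiffusionTensor(matrix=d, mobility_center=center)


_dimer_cache: dict[tuple[float, float, float, float], np.ndarray] = {}


def dimer_diffusion_tensor(
    coords: np.ndarray, R: float, temperature: float, viscosity: float
) -> DiffusionTensor:
    """Diffusion tensor of a two-bead cluster, via a cached canonical
    axis-aligned dimer rotated into the actual bond direction.

    Exactly equivalent to `cluster_diffusion_matrix` (the dimer's centre
    of diffusion is its midpoint by symmetry), but O(1) after the first
    call at a given separation — dimers are by far the most frequently
    formed and destroyed clusters during assembly.
    """
    axis = coords[1] - coords[0]
    d = float(np.linalg.norm(axis))
    axis = axis / d
    key = (round(d, 9), R, temperature, viscosity)
    canon = _dimer_cache.get(key)
    if canon is None:
        ref = cluster_diffusion_matrix(
            np.array([[0.0, 0.0, -d / 2], [0.0, 0.0, d / 2]]),
            R,
            temperature,
            viscosity,
        )
        canon = ref.matrix
        _dimer_cache[key] = canon
    # rotation taking ez onto the bond axis (Rodrigues, stable for all axes)
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(ez, axis)
    c = float(np.dot(ez, axis))
    if c < -1.0 + 1e-12:
        q = np.diag([1.0, -1.0, -1.0])
    else:
        vx = _cross_matrix(v)
        q = np.eye(3) + vx + vx @ vx / (1.0 + c)
    b = np.zeros((6, 6))
    b[:3, :3] = q
    b[3:, 3:] = q
    return DiffusionTensor(
        matrix=b @ canon @ b.T, mobility_center=0.5 * (coords[0] + coords[1])
    )


def diffusive_weights(tensor_a: DiffusionTensor, tensor_b: DiffusionTensor):
    """Fractions of a snap displacement carried by each partner.

    The more mobile cluster moves more: ``w_X`` is proportional to the
    trace of X's translational diffusion block, and ``w_a + w_b = 1``.
    """
    ta = tensor_a.translational_trace
    tb = tensor_b.translational_trace
    return ta / (ta + tb), tb / (ta + tb)
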