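"""Rigid-body diffusion: Stokes-Einstein limits, tensor structure, and an
independent bead-model oracle for multi-bead clusters."""

import numpy as np
import pytest

from capsidyn.cluster import RigidCluster, propagate_cluster
from capsidyn.diffusion import (
    KB,
    DiffusionError,
    cluster_diffusion_matrix,
    dimer_diffusion_tensor,
    diffusive_weights,
    stokes_einstein,
)

R, TEMP, VISC = 1.0, 293.0, 2e-3


def _oracle_tensor(coords, center):
    """Independent rigid bead-model resistance built element-by-element:
    RPY pair mobilities, bead spin friction, explicit 6x6 contraction."""
    coords = np.atleast_2d(coords)
    n = len(coords)
    eta = VISC * 1e-18
    mob = np.zeros((3 * n, 3 * n))
    for i in range(n):
        mob[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / (6 * np.pi * eta * R)
        for j in range(n):
            if i == j:
                continue
            rv = coords[j] - coords[i]
            r = np.linalg.norm(rv)
            e = rv / r
            blk = (np.eye(3) + np.outer(e, e)) + (2 * R**2 / r**2) * (
                np.eye(3) / 3 - np.outer(e, e)
            )
            mob[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk / (8 * np.pi * eta * r)
    kmat = np.zeros((3 * n, 6))
    for i in range(n):
        d = coords[i] - center
        kmat[3 * i : 3 * i + 3, :3] = np.eye(3)
        kmat[3 * i : 3 * i + 3, 3:] = -np.array(
            [[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]]
        )
    xi = kmat.T @ np.linalg.solve(mob, kmat)
    xi[3:, 3:] += n * 8 * np.pi * eta * R**3 * np.eye(3)
    return KB * TEMP * np.linalg.inv(xi)


def _random_chain(rng, n):
    pts = [np.zeros(3)]
    while len(pts) < n:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        cand = pts[-1] + 2.0 * R * d
        if all(np.linalg.norm(cand - p) >= 2.0 * R - 1e-12 for p in pts[:-1]):
            pts.append(cand)
    return np.array(pts)


def test_stokes_einstein_values():
    # hand evaluation: kT = 1.380649e-23 * 293 J; 1 J = 1 kg nm^2/ns^2
    d_t, d_r = stokes_einstein(R, TEMP, VISC)
    assert d_t == pytest.approx(0.107305, rel=1e-4)
    assert d_r == pytest.approx(0.080479, rel=1e-4)


def test_stokes_einstein_scaling():
    d_t1, d_r1 = stokes_einstein(R, TEMP, VISC)
    d_t2, d_r2 = stokes_einstein(2 * R, TEMP, VISC)
    assert d_t2 == pytest.approx(d_t1 / 2)
    assert d_r2 == pytest.approx(d_r1 / 8)


@pytest.mark.parametrize("bad", [(-1, TEMP, VISC), (R, 0, VISC), (R, TEMP, -2e-3)])
def test_nonpositive_arguments_rejected(bad):
    with pytest.raises(DiffusionError):
        stokes_einstein(*bad)
    with pytest.raises(DiffusionError):
        cluster_diffusion_matrix(np.zeros((1, 3)), *bad)


def test_single_bead_reduces_to_stokes_einstein():
    d_t, d_r = stokes_einstein(R, TEMP, VISC)
    tensor = cluster_diffusion_matrix(np.array([[5.0, -2.0, 1.0]]), R, TEMP, VISC)
    assert np.allclose(tensor.matrix, np.diag([d_t] * 3 + [d_r] * 3))
    assert np.allclose(tensor.mobility_center, [5.0, -2.0, 1.0])


def test_overlapping_beads_rejected():
    with pytest.raises(DiffusionError, match="overlap"):
        cluster_diffusion_matrix(np.array([[0, 0, 0], [1.0, 0, 0]]), R, TEMP, VISC)


def test_tensor_positive_definite_and_symmetric(rng):
    for n in (2, 4, 7):
        tensor = cluster_diffusion_matrix(_random_chain(rng, n), R, TEMP, VISC)
        assert np.allclose(tensor.matrix, tensor.matrix.T)
        assert np.linalg.eigvalsh(tensor.matrix).min() > 0


def test_coupling_symmetric_at_mobility_center(rng):
    tensor = cluster_diffusion_matrix(_random_chain(rng, 6), R, TEMP, VISC)
    ct = tensor.matrix[3:, :3]
    assert np.abs(ct - ct.T).max() < 1e-12 * np.abs(tensor.matrix).max()


def test_matches_independent_oracle(rng):
    for n in (2, 3, 5):
        coords = _random_chain(rng, n)
        tensor = cluster_diffusion_matrix(coords, R, TEMP, VISC)
        oracle = _oracle_tensor(coords, tensor.mobility_center)
        assert np.allclose(tensor.matrix, oracle, rtol=1e-9, atol=1e-12)


def test_growing_cluster_diffuses_slower(rng):
    """Adding a bead never increases the translational-block trace."""
    for _ in range(3):
        chain = _random_chain(rng, 6)
        traces = [
            cluster_diffusion_matrix(chain[:n], R, TEMP, VISC).translational_trace
            for n in range(1, 7)
        ]
        assert all(b < a for a, b in zip(traces, traces[1:]))


def test_dimer_cache_matches_direct_computation(rng):
    for _ in range(4):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        base = rng.normal(size=3) * 4
        coords = np.array([base, base + 2.0 * R * axis])
        direct = cluster_diffusion_matrix(coords, R, TEMP, VISC)
        cached = dimer_diffusion_tensor(coords, R, TEMP, VISC)
        assert np.allclose(direct.matrix, cached.matrix, atol=1e-13)
        assert np.allclose(direct.mobility_center, cached.mobility_center)


def test_diffusive_weights(rng):
    mono = cluster_diffusion_matrix(np.zeros((1, 3)), R, TEMP, VISC)
    w_a, w_b = diffusive_weights(mono, mono)
    assert w_a == pytest.approx(0.5) and w_b == pytest.approx(0.5)
    big = cluster_diffusion_matrix(_random_chain(rng, 10), R, TEMP, VISC)
    w_mono, w_big = diffusive_weights(mono, big)
    assert w_mono > 0.5 > w_big
    assert w_mono + w_big == pytest.approx(1.0)


def test_propagate_zero_dt_is_identity(rng):
    cluster = RigidCluster.from_coords(_random_chain(rng, 3), R, TEMP, VISC)
    pos, quat = cluster.position.copy(), cluster.orientation.copy()
    propagate_cluster(cluster, 0.0, rng)
    assert np.array_equal(cluster.position, pos)
    assert np.array_equal(cluster.orientation, quat)


def test_propagation_preserves_rigidity_and_unit_quaternion(rng):
    cluster = RigidCluster.from_coords(_random_chain(rng, 4), R, TEMP, VISC)
    ref = cluster.body_coords.copy()
    d0 = np.linalg.norm(
        cluster.world_coords()[:, None] - cluster.world_coords()[None], axis=-1
    )
    for _ in range(200):
        cluster.propagate(0.1, rng)
    d1 = np.linalg.norm(
        cluster.world_coords()[:, None] - cluster.world_coords()[None], axis=-1
    )
    assert np.array_equal(cluster.body_coords, ref)
    assert np.abs(d1 - d0).max() < 1e-9
    assert np.linalg.norm(cluster.orientation) == pytest.approx(1.0, abs=1e-12)
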