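"""Rigid-body geometry primitives.

Frame-fixed RMSD, Kabsch superposition, principal axes, and the
discretized rotation grid with solid-angle (sin θ) weights that the
uniform-sampling-efficiency computation averages over.

The rotation grid uses intrinsic z-y-z Euler angles (φ about the third
axis, θ about the second, ψ about the third again), φ and ψ uniform on
[0, 2π), θ uniform on [0, π].  Uniformity over rotations requires each
(φ, θ, ψ) triple to be weighted by sin θ — the circumference of the
circle θ draws on the sphere — with trapezoidal handling of the θ
endpoints (where sin θ = 0 anyway) so the grid is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "RigidTransform",
    "RotationGrid",
    "rmsd",
    "kabsch_superpose",
    "principal_axes",
    "build_rotation_grid",
    "translation_to_threshold",
    "random_rotations",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear/coincident points)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, applied as ``R x + t``."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords):
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls):
        return cls(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class RotationGrid:
    """M³ Euler triples with per-triple solid-angle weights summing to 1."""

    angles: np.ndarray    # (M³, 3) — (φ, θ, ψ)
    weights: np.ndarray   # (M³,)
    spacings: int         # M

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "weights", w)

    def __len__(self):
        return len(self.angles)

    def matrices(self):
        """(M³, 3, 3) rotation matrices (intrinsic z-y-z)."""
        return Rotation.from_euler("ZYZ", self.angles).as_matrix()


def _as_blocks(a, b, subset=None):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        a, b = a[subset], b[subset]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate blocks must share shape (n, 3); got {a.shape} vs {b.shape}")
    return a, b


def rmsd(a, b, subset=None):
    """Frame-fixed root-mean-square deviation between paired coordinates.

    No superposition is performed: pose RMSD in a fixed receptor frame is
    the evaluation metric throughout.
    """
    a, b = _as_blocks(a, b, subset)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile, target, subset=None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    The transform is fitted on ``subset`` (all atoms when None) and is a
    proper rotation; applying it minimizes the subset RMSD.  Fewer than
    three non-collinear points raise :class:`GeometryError`.
    """
    m, t = _as_blocks(mobile, target, subset)
    if len(m) < 3:
        raise GeometryError("superposition needs at least 3 points")
    mc, tc = m.mean(axis=0), t.mean(axis=0)
    m0, t0 = m - mc, t - tc
    sv = np.linalg.svd(m0, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GeometryError("superposition subset is collinear or coincident")
    rot, _ = Rotation.align_vectors(t0, m0)
    R = rot.as_matrix()
    return RigidTransform(R, tc - R @ mc)


def principal_axes(coords):
    """Orthonormal principal-axis frame of a coordinate block.

    Rows are eigenvectors of the centered gyration tensor ordered by
    descending eigenvalue.  Signs are fixed deterministically (largest-
    magnitude component positive for the first two axes) and the third
    axis completes a right-handed frame.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or len(X) < 2:
        raise GeometryError("need at least 2 points with shape (n, 3)")
    X0 = X - X.mean(axis=0)
    gyr = X0.T @ X0 / len(X0)
    if np.allclose(gyr, 0.0, atol=1e-12):
        raise GeometryError("all points coincident")
    evals, evecs = np.linalg.eigh(gyr)
    axes = evecs[:, ::-1].T            # rows, descending eigenvalue
    for i in range(2):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def build_rotation_grid(M):
    """Uniform rotation grid: M spacings per Euler axis, sin θ weights.

    φ and ψ run uniformly over [0, 2π) without endpoint duplication;
    θ runs over [0, π] inclusive.  Weights are sin θ with half-weight
    trapezoidal θ endpoints, normalized to sum to 1.  M = 1 degenerates
    to the single identity rotation with weight 1.
    """
    M = int(M)
    if M < 1:
        raise ValueError("M must be >= 1")
    phi = 2.0 * np.pi * np.arange(M) / M
    psi = phi.copy()
    if M == 1:
        theta = np.array([0.0])
        w_theta = np.array([1.0])
    else:
        theta = np.linspace(0.0, np.pi, M)
        w_theta = np.sin(theta)
        w_theta[0] *= 0.5
        w_theta[-1] *= 0.5
    ph, th, ps = np.meshgrid(phi, theta, psi, indexing="ij")
    angles = np.column_stack([ph.ravel(), th.ravel(), ps.ravel()])
    w = np.broadcast_to(w_theta[None, :, None], (M, M, M)).ravel().astype(float)
    w = w / w.sum()
    return RotationGrid(angles=angles, weights=w, spacings=M)


def translation_to_threshold(rmsd0, threshold):
    """Largest translation keeping a centroid-aligned pose under a threshold.

    For centroid-aligned blocks, translating by t gives
    RMSD² = rmsd0² + |t|² exactly, so the answer is
    √(threshold² − rmsd0²) when rmsd0 < threshold and 0 otherwise.
    Accepts scalars or arrays.
    """
    r0 = np.asarray(rmsd0, dtype=float)
    if np.any(r0 < 0) or threshold <= 0:
        raise ValueError("rmsd0 must be >= 0 and threshold > 0")
    d = np.sqrt(np.clip(threshold ** 2 - r0 ** 2, 0.0, None))
    return float(d) if np.isscalar(rmsd0) or r0.ndim == 0 else d


def random_rotations(n, rng):
    """n Haar-uniform rotation matrices (random unit quaternions)."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()
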