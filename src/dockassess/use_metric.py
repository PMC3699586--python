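"""Uniform sampling efficiency of a ligand conformer ensemble (USE2.0).

USE2.0 is the probability that placing a ligand conformer ensemble
uniformly at random — conformer chosen uniformly, orientation
Haar-uniform, centroid translated uniformly within the docking sphere of
radius R — yields a pose within a heavy-atom RMSD threshold (2.0 Å) of
the experimental binding mode, with no occluding protein.  It normalizes
docking sampling efficiencies so benchmark studies are comparable
across targets.

The deterministic computation aligns each conformer to the reference by
least squares, sweeps a discretized rotation grid about the conformer
centroid (M uniform spacings per Euler axis, sin θ solid-angle weights),
and for each rotation converts the residual centroid-aligned RMSD into
the radius d of the translation ball that stays under the threshold;
the rotation's contribution is (d/R)³, the fraction of the docking
sphere volume it occupies.  A Monte-Carlo estimator with the same
placement model serves as an independent check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rigidgeom import build_rotation_grid, kabsch_superpose, random_rotations
from .structio import ConformerSet

__all__ = ["UseParams", "UseResult", "compute_use", "compute_use_mc", "fold_decrease"]


@dataclass(frozen=True)
class UseParams:
    """Threshold (Å), docking-sphere radius R (Å), and Euler spacings M."""

    threshold: float = 2.0
    radius: float = 5.0
    spacings: int = 40

    def __post_init__(self):
        if not (0 < self.threshold <= self.radius):
            raise ValueError("require 0 < threshold <= radius")
        if self.spacings < 1:
            raise ValueError("spacings must be >= 1")


@dataclass(frozen=True)
class UseResult:
    use: float
    per_conformer: np.ndarray
    params: UseParams

    def __post_init__(self):
        object.__setattr__(self, "per_conformer",
                           np.asarray(self.per_conformer, dtype=float))

    @property
    def log10_use(self):
        return float(np.log10(self.use)) if self.use > 0 else -np.inf


def _conformer_blocks(conformers):
    if isinstance(conformers, ConformerSet):
        return conformers.coords
    arr = np.asarray(conformers, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("conformers must have shape (N, k, 3)")
    return arr


def _aligned_centered(conformers, reference):
    """Kabsch-align each conformer to the reference; return centered blocks."""
    ref = np.asarray(reference, dtype=float)
    blocks = _conformer_blocks(conformers)
    if blocks.shape[1] != ref.shape[0]:
        raise ValueError(
            f"conformer atom count {blocks.shape[1]} != reference {ref.shape[0]}"
        )
    ref0 = ref - ref.mean(axis=0)
    out = np.empty_like(blocks)
    for i, X in enumerate(blocks):
        if len(X) < 3:
            # too few atoms to orient; centroid alignment is exact for 1-2 atoms
            X0 = X - X.mean(axis=0)
            if len(X) == 2:
                # align the interatomic axis by least squares (planar Kabsch
                # is under-determined; any rotation mapping the axis works)
                v, w = X0[1] - X0[0], ref0[1] - ref0[0]
                nv, nw = np.linalg.norm(v), np.linalg.norm(w)
                if nv > 0 and nw > 0:
                    from scipy.spatial.transform import Rotation
                    rot, _ = Rotation.align_vectors(w[None] / nw, v[None] / nv)
                    X0 = X0 @ rot.as_matrix().T
            out[i] = X0
        else:
            tf = kabsch_superpose(X, ref)
            out[i] = tf.apply(X) - ref.mean(axis=0)
    return out, ref0


def compute_use(conformers, reference, params=UseParams()):
    """Deterministic grid computation of USE2.0.

    For each conformer: align to the reference, rotate about the centroid
    through every grid rotation, convert the residual RMSD into the
    surviving translation-ball volume fraction (d/R)³, and average with
    the solid-angle weights.  The ensemble value is the unweighted mean
    over conformers (each conformer is equally likely under random
    conformer selection).
    """
    aligned, ref0 = _aligned_centered(conformers, reference)
    k = ref0.shape[0]
    grid = build_rotation_grid(params.spacings)
    Rmats = grid.matrices()
    msq_ref = np.mean(np.sum(ref0 ** 2, axis=1))
    per = np.empty(len(aligned))
    for i, X0 in enumerate(aligned):
        msq_x = np.mean(np.sum(X0 ** 2, axis=1))
        # rmsd0²(R) = <|x|²> + <|r|²> − (2/k)·tr(R · Σ x rᵀ)
        C = X0.T @ ref0                       # (3,3): Σ_a x_a r_aᵀ
        cross = np.einsum("nij,ij->n", Rmats, C)
        rmsd0_sq = np.clip(msq_x + msq_ref - 2.0 * cross / k, 0.0, None)
        d = np.sqrt(np.clip(params.threshold ** 2 - rmsd0_sq, 0.0, None))
        per[i] = float(np.sum(grid.weights * (d / params.radius) ** 3))
    return UseResult(use=float(per.mean()), per_conformer=per, params=params)


def compute_use_mc(conformers, reference, params=UseParams(), n_samples=100_000,
                   seed=None, chunk=50_000):
    """Monte-Carlo estimate of USE2.0 with binomial standard error.

    Draws (conformer, Haar rotation, uniform translation in the R-ball)
    and counts placements whose heavy-atom RMSD to the reference is at
    or below the threshold.  The RMSD is computed directly from the
    placed coordinates, independently of the grid algorithm's
    translation-ball shortcut.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    aligned, ref0 = _aligned_centered(conformers, reference)
    n_conf, k, _ = aligned.shape
    successes = 0
    done = 0
    while done < n_samples:
        n = min(chunk, n_samples - done)
        idx = rng.integers(0, n_conf, size=n)
        Rm = random_rotations(n, rng)
        # uniform in ball: direction x radius with r ~ R * U^(1/3)
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = params.radius * rng.random(n) ** (1.0 / 3.0)
        t = u * r[:, None]
        placed = np.einsum("nij,nkj->nki", Rm, aligned[idx]) + t[:, None, :]
        msd = np.mean(np.sum((placed - ref0[None]) ** 2, axis=2), axis=1)
        successes += int(np.sum(msd <= params.threshold ** 2))
        done += n
    p = successes / n_samples
    se = float(np.sqrt(max(p * (1.0 - p), 1.0 / n_samples) / n_samples))
    return p, se


def fold_decrease(bioactive_use, ensemble_use):
    """Ratio USE2.0(bioactive conformation) / USE2.0(conformer ensemble).

    Quantifies how much an ensemble of conformers dilutes random
    sampling relative to using the bioactive conformation alone.
    """
    num = bioactive_use.use if isinstance(bioactive_use, UseResult) else float(bioactive_use)
    den = ensemble_use.use if isinstance(ensemble_use, UseResult) else float(ensemble_use)
    if den == 0.0:
        warnings.warn("ensemble USE2.0 is zero; fold decrease is infinite")
        return float("inf")
    return num / den
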