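"""Enrichment of near-native poses by constraints and score cutoffs.

Three ways of concentrating a docked ensemble on native-like binding
modes (heavy-atom RMSD to the native mode at or below 2.0 Å):

* resampled contact constraints — repeatedly draw n of the known native
  contacts and keep only poses whose own contact set contains all of
  them, averaging the near-native fraction of the retained poses over
  many iterations (10,000 by default), for n from 0 to all contacts;
* interaction-energy cutoffs — keep the best-scored fraction f of poses
  and measure the near-native fraction among them;
* explicit geometric constraints — keep poses satisfying a maximum
  distance between named receptor and ligand atoms (e.g. a salt bridge),
  reporting the fold improvement in sampling efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EnrichmentCurve",
    "GeometricConstraint",
    "ConstraintResult",
    "contact_enrichment",
    "contact_enrichment_exact",
    "energy_cutoff_sweep",
    "apply_geometric_constraint",
]

_NEAR_NATIVE_RMSD = 2.0


@dataclass(frozen=True)
class EnrichmentCurve:
    """Mean sampling efficiency vs number of imposed contacts."""

    n_constraints: np.ndarray    # 0..K
    mean_efficiency: np.ndarray  # NaN where every iteration retained nothing
    sd_efficiency: np.ndarray
    empty_fraction: np.ndarray   # fraction of iterations with no retained pose
    iterations: int
    seed: object = None

    def __post_init__(self):
        for name in ("n_constraints", "mean_efficiency", "sd_efficiency",
                     "empty_fraction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))


@dataclass(frozen=True)
class GeometricConstraint:
    """Maximum-distance constraint between receptor and ligand atoms.

    ``receptor_atoms`` selects via keyword arguments understood by
    ``ReceptorModel.select_atoms`` (res_ids / names / elements;
    hydrogens are permitted here).  ``ligand_atom_indices`` indexes the
    pose coordinate block.
    """

    receptor_atoms: dict
    ligand_atom_indices: tuple
    max_distance: float

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max distance must be positive")
        object.__setattr__(self, "ligand_atom_indices",
                           tuple(int(i) for i in self.ligand_atom_indices))


@dataclass(frozen=True)
class ConstraintResult:
    retained_indices: tuple
    efficiency_before: float
    efficiency_after: float
    fold_improvement: float


def _contact_matrix(pose_contacts, native_contacts):
    """Boolean (n_poses, K) membership of each native contact per pose."""
    native = list(native_contacts.contacts) if hasattr(native_contacts, "contacts") \
        else list(native_contacts)
    native = sorted(native, key=repr)
    sets = [c.contacts if hasattr(c, "contacts") else frozenset(c)
            for c in pose_contacts]
    M = np.array([[nc in s for nc in native] for s in sets], dtype=bool)
    return M, native


def _efficiency(mask, near):
    kept = int(mask.sum())
    if kept == 0:
        return math.nan
    return float(np.sum(mask & near) / kept)


def contact_enrichment(pose_contacts, rmsd_to_native, native_contacts,
                       iterations=10_000, seed=None, mode="all",
                       rmsd_threshold=_NEAR_NATIVE_RMSD):
    """Resampled enrichment curve over randomly drawn known contacts.

    For each n in 0..K (K = number of native contacts), ``iterations``
    random n-subsets of the native contacts are drawn without
    replacement; poses are retained when their contact set contains all
    drawn contacts (``mode="all"``; ``"any"`` requires at least one),
    and the fraction of retained poses within the RMSD threshold is
    averaged over iterations.  Iterations that retain no pose contribute
    no value and are reported via ``empty_fraction``.
    """
    if len(pose_contacts) == 0:
        raise ValueError("empty pose ensemble")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    M, native = _contact_matrix(pose_contacts, native_contacts)
    if not native:
        raise ValueError("native contact set is empty")
    K = len(native)
    if K > 63:
        raise ValueError("more than 63 native contacts not supported")
    near = np.asarray(rmsd_to_native, dtype=float) <= rmsd_threshold
    if len(near) != len(M):
        raise ValueError("one RMSD per pose required")
    rng = np.random.default_rng(seed)

    powers = np.uint64(1) << np.arange(K, dtype=np.uint64)
    pose_bits = (M.astype(np.uint64) * powers).sum(axis=1, dtype=np.uint64)

    base = _efficiency(np.ones(len(M), dtype=bool), near)
    means, sds, empties = [base], [0.0], [0.0]
    for n in range(1, K + 1):
        # iterations × n distinct contact indices via partial shuffles
        ranks = rng.random((iterations, K)).argsort(axis=1)[:, :n]
        subset_bits = np.zeros(iterations, dtype=np.uint64)
        for j in range(n):
            subset_bits |= powers[ranks[:, j]]
        effs = np.full(iterations, math.nan)
        chunk = max(1, 2_000_000 // max(len(M), 1))
        for s in range(0, iterations, chunk):
            sb = subset_bits[s:s + chunk, None]
            if mode == "all":
                kept = (sb & pose_bits[None, :]) == sb
            else:
                kept = (sb & pose_bits[None, :]) != 0
            kept_n = kept.sum(axis=1)
            hit_n = (kept & near[None, :]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                e = np.where(kept_n > 0, hit_n / np.maximum(kept_n, 1), math.nan)
            effs[s:s + chunk] = e
        ok = ~np.isnan(effs)
        means.append(float(np.mean(effs[ok])) if ok.any() else math.nan)
        sds.append(float(np.std(effs[ok])) if ok.any() else math.nan)
        empties.append(float(np.mean(~ok)))
    return EnrichmentCurve(
        n_constraints=np.arange(K + 1),
        mean_efficiency=np.array(means),
        sd_efficiency=np.array(sds),
        empty_fraction=np.array(empties),
        iterations=int(iterations),
        seed=seed,
    )


def contact_enrichment_exact(pose_contacts, rmsd_to_native, native_contacts,
                             mode="all", rmsd_threshold=_NEAR_NATIVE_RMSD):
    """Exhaustive-subset enrichment curve (average over all C(K, n) subsets).

    Enumerates every subset instead of resampling; the resampled curve
    converges to this as iterations grow.  Practical for small K only.
    """
    M, native = _contact_matrix(pose_contacts, native_contacts)
    K = len(native)
    near = np.asarray(rmsd_to_native, dtype=float) <= rmsd_threshold
    means, sds, empties = [], [], []
    for n in range(K + 1):
        vals, n_empty, total = [], 0, 0
        for subset in combinations(range(K), n):
            sel = M[:, subset]
            kept = sel.all(axis=1) if mode == "all" else (
                sel.any(axis=1) if n > 0 else np.ones(len(M), dtype=bool))
            total += 1
            e = _efficiency(kept, near)
            if math.isnan(e):
                n_empty += 1
            else:
                vals.append(e)
        means.append(float(np.mean(vals)) if vals else math.nan)
        sds.append(float(np.std(vals)) if vals else math.nan)
        empties.append(n_empty / total)
    return EnrichmentCurve(
        n_constraints=np.arange(K + 1),
        mean_efficiency=np.array(means),
        sd_efficiency=np.array(sds),
        empty_fraction=np.array(empties),
        iterations=0,
        seed=None,
    )


def energy_cutoff_sweep(energies, rmsd_to_native, fractions,
                        rmsd_threshold=_NEAR_NATIVE_RMSD):
    """Sampling efficiency after keeping the best-scored fraction of poses.

    For each fraction f the ⌈f·N⌉ lowest-energy poses are kept (ties
    broken by pose index) and the near-native fraction among them is
    returned, as a dict f -> efficiency.
    """
    energies = np.asarray(energies, dtype=float)
    near = np.asarray(rmsd_to_native, dtype=float) <= rmsd_threshold
    if len(energies) != len(near) or len(energies) == 0:
        raise ValueError("energies and RMSDs must be equal-length and non-empty")
    order = np.lexsort((np.arange(len(energies)), energies))
    out = {}
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fraction {f} outside (0, 1]")
        k = int(math.ceil(f * len(energies)))
        kept = order[:k]
        out[float(f)] = float(np.mean(near[kept]))
    return out


def apply_geometric_constraint(poses, receptor, constraint, rmsd_to_native,
                               rmsd_threshold=_NEAR_NATIVE_RMSD):
    """Retain poses satisfying a receptor–ligand distance constraint.

    A pose is retained when the minimum distance between any selected
    receptor atom (hydrogens permitted) and any selected ligand atom is
    strictly below ``constraint.max_distance``.  Returns retained pose
    indices plus sampling efficiency before/after and the fold
    improvement.
    """
    atoms = receptor.select_atoms(include_hydrogens=True,
                                  **constraint.receptor_atoms)
    if not atoms:
        raise LookupError(f"receptor selector matched nothing: {constraint.receptor_atoms}")
    rec_pos = np.array([a.position for a in atoms]).reshape(-1, 3)
    li = list(constraint.ligand_atom_indices)
    if not li:
        raise LookupError("ligand selector matched nothing")
    coords = poses.coords if hasattr(poses, "coords") else np.asarray(poses)
    near = np.asarray(rmsd_to_native, dtype=float) <= rmsd_threshold
    retained = []
    for i, block in enumerate(coords):
        lig = np.asarray(block)[li]
        if cdist(rec_pos, lig).min() < constraint.max_distance:
            retained.append(i)
    eff_before = float(np.mean(near))
    eff_after = float(np.mean(near[retained])) if retained else math.nan
    fold = eff_after / eff_before if eff_before > 0 else math.nan
    return ConstraintResult(
        retained_indices=tuple(retained),
        efficiency_before=eff_before,
        efficiency_after=eff_after,
        fold_improvement=fold,
    )
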