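"""Synthetic receptor families, model ensembles, conformers and poses.

Every input the assessment pipeline consumes can be generated here with
recorded ground truth, emulating the study conditions the toolkit is
meant for: a family of superposable receptor structures sharing an
alignment and a ligand-proximal pocket; comparative-model ensembles
whose pockets are distorted to a controlled degree; ligand conformer
ensembles with known RMSD to a reference (bioactive) conformation; and
docked-pose ensembles mixing near-native poses with decoys uniform in
the docking sphere, with scores correlated with pose RMSD to a chosen
degree and contacts derived purely from the generated geometry.

The receptor scaffold is an idealized ring of pseudo-helical strands —
a Cα/Cβ trace, not a physical model — because every downstream
operation consumes only coordinates, labels and an alignment.  Pocket
residues are placed 3.0 Å from a designated ligand atom (inside the
4.0 Å contact rule with margin comparable to the default 1.0 Å family
jitter); all other residues sit on a 12 Å cylinder, far outside contact
range.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rigidgeom import random_rotations, rmsd
from .structio import AlignmentMap, AtomRecord, ConformerSet, PoseEnsemble, ReceptorModel

__all__ = [
    "FamilyConfig",
    "PoseConfig",
    "SyntheticFamily",
    "ModelEnsembleTruth",
    "PoseTruth",
    "default_ligand",
    "gen_receptor_family",
    "gen_model_ensemble",
    "gen_conformers",
    "gen_pose_ensemble",
]

# 20 amino-acid cycle with glycines sprinkled in to exercise the
# Cβ -> Cα fallback; index 6, 13, ... are GLY
_RES_CYCLE = ("ALA", "LEU", "SER", "VAL", "THR", "PHE", "GLY",
              "ASP", "LYS", "ILE", "TYR", "ASN", "TRP", "GLY")

_ONE = {"ALA": "A", "LEU": "L", "SER": "S", "VAL": "V", "THR": "T",
        "PHE": "F", "GLY": "G", "ASP": "D", "LYS": "K", "ILE": "I",
        "TYR": "Y", "ASN": "N", "TRP": "W"}


@dataclass(frozen=True)
class FamilyConfig:
    """Geometry and spread of the synthetic receptor family."""

    n_structures: int = 5
    n_residues: int = 40
    pocket_size: int = 8
    sigma_family: float = 1.0     # Å, isotropic inter-structure jitter
    seed: int = 0
    with_indels: bool = False     # drop one non-pocket residue from the last member

    def __post_init__(self):
        if not (1 <= self.pocket_size <= self.n_residues):
            raise ValueError("pocket_size must be between 1 and n_residues")
        if self.sigma_family < 0:
            raise ValueError("sigma_family must be >= 0")
        if self.n_structures < 1:
            raise ValueError("need at least one structure")


@dataclass(frozen=True)
class PoseConfig:
    """Composition of a synthetic docked-pose ensemble."""

    n_poses: int = 1000
    near_native_fraction: float = 0.3
    sphere_radius: float = 5.0
    score_rmsd_correlation: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.near_native_fraction <= 1):
            raise ValueError("near_native_fraction must be in [0, 1]")
        if abs(self.score_rmsd_correlation) > 1:
            raise ValueError("|score_rmsd_correlation| must be <= 1")


@dataclass
class SyntheticFamily:
    """Generated family plus its ground truth."""

    members: list                 # ReceptorModel with het ligand each
    alignment: AlignmentMap
    pocket_residues: tuple        # designed residue numbers (scaffold row)
    pocket_columns: tuple         # designed alignment columns
    scaffold: ReceptorModel       # the unjittered consensus (with ligand)
    config: FamilyConfig


@dataclass
class ModelEnsembleTruth:
    labels: tuple                 # "good" | "bad" per model
    sigmas: tuple                 # jitter σ used per model
    displacements: tuple          # mean pocket-Cα displacement per model (Å)


@dataclass
class PoseTruth:
    rmsd_to_native: np.ndarray
    is_near_native: np.ndarray    # planted class (RMSD < 2.0 by construction)


def default_ligand():
    """Rigid 8-heavy-atom asymmetric ligand used by the synthetic world."""
    return np.array([
        [0.0, 0.0, 0.0],
        [1.4, 0.0, 0.0],
        [2.1, 1.2, 0.0],
        [0.7, -1.2, 0.5],
        [-1.2, 0.8, 0.3],
        [-0.4, 0.1, 1.4],
        [1.0, 1.0, 1.0],
        [2.3, -0.6, -0.8],
    ])


def _fibonacci_directions(n):
    """n well-spread unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _scaffold_coords(cfg, ligand):
    """Designed Cα and Cβ positions plus pocket residue indices (0-based)."""
    n, p = cfg.n_residues, cfg.pocket_size
    pocket_idx = np.unique(np.round(np.linspace(0, n - 1, p)).astype(int))
    center = ligand.mean(axis=0)
    dirs = _fibonacci_directions(p)
    ca = np.zeros((n, 3))
    cb = np.zeros((n, 3))
    non_pocket = [i for i in range(n) if i not in set(pocket_idx)]
    for rank, i in enumerate(non_pocket):
        ang = 2.0 * np.pi * rank / max(len(non_pocket), 1)
        z = -10.0 + 20.0 * rank / max(len(non_pocket) - 1, 1)
        ca[i] = center + np.array([12.0 * np.cos(ang), 12.0 * np.sin(ang), z])
    for rank, i in enumerate(pocket_idx):
        anchor = ligand[rank % len(ligand)]
        d = anchor - center
        nd = np.linalg.norm(d)
        u = d / nd if nd > 1e-9 else dirs[rank]
        # blend the radial direction with a spread direction so pocket
        # residues do not stack when several share an anchor atom
        u = u + 0.5 * dirs[rank]
        u /= np.linalg.norm(u)
        ca[i] = anchor + 3.0 * u
    away = ca - center
    away /= np.linalg.norm(away, axis=1, keepdims=True)
    cb[:] = ca + 1.5 * away
    return ca, cb, pocket_idx


def _residue_name(i):
    return _RES_CYCLE[i % len(_RES_CYCLE)]


def _build_model(ca, cb, ligand, tag, skip_residue=None, energy=math.nan):
    """Assemble a ReceptorModel from Cα/Cβ traces and ligand coordinates.

    ``skip_residue`` (0-based scaffold index) drops one residue and
    renumbers the rest sequentially, emulating a deletion relative to
    the family consensus.
    """
    atoms = []
    resnum = 0
    for i in range(len(ca)):
        if i == skip_residue:
            continue
        resnum += 1
        rname = _residue_name(i)
        atoms.append(AtomRecord("CA", "C", rname, str(resnum), "A", ca[i]))
        if rname != "GLY":
            atoms.append(AtomRecord("CB", "C", rname, str(resnum), "A", cb[i]))
    het = [
        AtomRecord(f"C{j + 1}", "C", "LIG", "1", "L", pos, record="HETATM")
        for j, pos in enumerate(ligand)
    ] if ligand is not None else []
    return ReceptorModel(atoms, het, energy=energy, tag=tag)


def gen_receptor_family(cfg=FamilyConfig()):
    """Generate a receptor family with a shared alignment and pocket.

    Members are the designed scaffold plus isotropic Gaussian jitter of
    ``sigma_family`` on every Cα/Cβ; each member carries its own rigid
    copy of the ligand, translated with a third of that jitter.  The
    alignment is gapless (identical sequences) unless ``with_indels``
    drops one non-pocket residue from the last member, producing a gap
    column in its row.
    """
    rng = np.random.default_rng(cfg.seed)
    ligand = default_ligand()
    ca, cb, pocket_idx = _scaffold_coords(cfg, ligand)
    scaffold = _build_model(ca, cb, ligand, tag="consensus")

    seq = "".join(_ONE[_residue_name(i)] for i in range(cfg.n_residues))
    members, sequences = [], {}
    skip_choice = None
    if cfg.with_indels:
        non_pocket = [i for i in range(cfg.n_residues) if i not in set(pocket_idx)]
        skip_choice = int(rng.choice(non_pocket))
    for m in range(cfg.n_structures):
        tag = f"S{m}"
        jca = ca + rng.normal(0.0, cfg.sigma_family, ca.shape)
        jcb = cb + rng.normal(0.0, cfg.sigma_family, cb.shape)
        lig = ligand + rng.normal(0.0, cfg.sigma_family / 3.0, (1, 3))
        skip = skip_choice if (cfg.with_indels and m == cfg.n_structures - 1) else None
        members.append(_build_model(jca, jcb, lig, tag=tag, skip_residue=skip))
        if skip is None:
            sequences[tag] = seq
        else:
            sequences[tag] = seq[:skip] + "-" + seq[skip + 1:]
    sequences["consensus"] = seq
    aln = AlignmentMap(sequences)
    pocket_residues = tuple(int(i) + 1 for i in pocket_idx)
    return SyntheticFamily(
        members=members,
        alignment=aln,
        pocket_residues=pocket_residues,
        pocket_columns=pocket_residues,  # gapless consensus row: column = residue
        scaffold=scaffold,
        config=cfg,
    )


def gen_model_ensemble(family, self_id, n_good=100, sigma_good=0.5,
                       n_bad=400, sigma_bad=4.0, energy_correlation=0.8,
                       seed=0):
    """Comparative-model ensemble around one family member.

    Good models jitter the pocket Cα/Cβ of the self structure by
    ``sigma_good``, bad models by ``sigma_bad`` (emulating native-like
    vs distorted pockets).  Energies are the mean pocket-Cα displacement
    plus Gaussian noise scaled so the energy/distortion correlation is
    approximately ``energy_correlation``.  Ground-truth labels, sigmas
    and realized displacements are returned alongside.
    """
    if sigma_good >= sigma_bad:
        raise ValueError("sigma_good must be < sigma_bad")
    rng = np.random.default_rng(seed)
    ref = next(m for m in family.members if m.tag == self_id)
    pocket_res = [
        family.alignment.residue_of[self_id].get(col)
        for col in family.pocket_columns
    ]
    pocket_res = [r for r in pocket_res if r is not None]

    models, labels, sigmas, displacements = [], [], [], []
    plan = [("good", sigma_good)] * n_good + [("bad", sigma_bad)] * n_bad
    for i, (label, sigma) in enumerate(plan):
        atoms = []
        disp_sum, disp_n = 0.0, 0
        pocket_set = {str(r) for r in pocket_res}
        for a in ref.atoms:
            if a.res_id in pocket_set:
                shift = rng.normal(0.0, sigma, 3)
                pos = a.position + shift
                if a.name == "CA":
                    disp_sum += float(np.linalg.norm(shift))
                    disp_n += 1
            else:
                pos = a.position
            atoms.append(AtomRecord(a.name, a.element, a.res_name, a.res_id,
                                    a.chain, pos))
        models.append(ReceptorModel(atoms, tag=f"M{i:04d}"))
        labels.append(label)
        sigmas.append(sigma)
        displacements.append(disp_sum / max(disp_n, 1))

    disp = np.array(displacements)
    rho = float(np.clip(energy_correlation, -1.0, 1.0))
    if abs(rho) < 1e-12:
        energies = rng.normal(0.0, max(disp.std(), 1.0), len(disp))
    else:
        noise_sd = disp.std() * math.sqrt(max(1.0 / rho ** 2 - 1.0, 0.0))
        energies = np.sign(rho) * disp + rng.normal(0.0, noise_sd, len(disp))
    for m, e in zip(models, energies):
        m.energy = float(e)
    truth = ModelEnsembleTruth(labels=tuple(labels), sigmas=tuple(sigmas),
                               displacements=tuple(displacements))
    return models, truth


def gen_conformers(reference_ligand, n=50, scale=0.3, seed=0):
    """Conformer ensemble: the reference plus internally perturbed copies.

    Perturbation rotates the second half of the atom list about a random
    axis through a pivot atom (a torsion-like rigid-subunit motion) by
    an angle ~N(0, scale rad), then adds small coordinate jitter
    (0.1·scale Å).  scale = 0 reproduces the reference exactly.  The
    per-conformer RMSD to the reference is returned alongside.
    """
    if n < 1:
        raise ValueError("need n >= 1 conformers")
    ref = np.asarray(reference_ligand, dtype=float)
    rng = np.random.default_rng(seed)
    k = len(ref)
    pivot = k // 2
    blocks = [ref.copy()]
    for _ in range(n - 1):
        X = ref.copy()
        if k > 2 and scale > 0:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, scale)
            Kx = np.array([[0, -axis[2], axis[1]],
                           [axis[2], 0, -axis[0]],
                           [-axis[1], axis[0], 0]])
            R = np.eye(3) + math.sin(angle) * Kx + (1 - math.cos(angle)) * Kx @ Kx
            X[pivot:] = (X[pivot:] - X[pivot]) @ R.T + X[pivot]
        if scale > 0:
            X = X + rng.normal(0.0, 0.1 * scale, X.shape)
        blocks.append(X)
    coords = np.stack(blocks)
    rmsds = np.array([rmsd(b, ref) for b in coords])
    return ConformerSet(coords, reference_index=0), rmsds


def gen_pose_ensemble(native_pose, receptor, cfg=PoseConfig()):
    """Docked-pose ensemble with a planted near-native fraction.

    Each pose is near-native with probability ``near_native_fraction``:
    a small rigid perturbation of the native pose (rotation up to ~0.25
    rad about the centroid plus a translation inside a 1.4 Å ball, which
    keeps heavy-atom RMSD below 2.0 Å; a rejection loop guards the
    bound).  Decoys get a Haar-uniform rotation and a uniform translation
    in the docking sphere.  Scores are RMSD plus Gaussian noise scaled so
    the score/RMSD correlation is approximately
    ``score_rmsd_correlation``.
    """
    native = np.asarray(native_pose, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    centroid = native.mean(axis=0)
    centered = native - centroid

    coords = np.empty((cfg.n_poses,) + native.shape)
    is_near = rng.random(cfg.n_poses) < cfg.near_native_fraction
    rmsds = np.empty(cfg.n_poses)
    for i in range(cfg.n_poses):
        if is_near[i]:
            for _ in range(100):
                ang = rng.uniform(0.0, 0.25)
                axis = rng.standard_normal(3)
                axis /= np.linalg.norm(axis)
                Kx = np.array([[0, -axis[2], axis[1]],
                               [axis[2], 0, -axis[0]],
                               [-axis[1], axis[0], 0]])
                R = (np.eye(3) + math.sin(ang) * Kx
                     + (1 - math.cos(ang)) * Kx @ Kx)
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                t = u * 1.4 * rng.random() ** (1.0 / 3.0)
                X = centered @ R.T + centroid + t
                r = rmsd(X, native)
                if r < 2.0:
                    break
        else:
            R = random_rotations(1, rng)[0]
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            t = u * cfg.sphere_radius * rng.random() ** (1.0 / 3.0)
            X = centered @ R.T + centroid + t
            r = rmsd(X, native)
        coords[i] = X
        rmsds[i] = r

    rho = cfg.score_rmsd_correlation
    if abs(rho) < 1e-12:
        energies = rng.normal(0.0, max(rmsds.std(), 1.0), cfg.n_poses)
    else:
        noise_sd = rmsds.std() * math.sqrt(max(1.0 / rho ** 2 - 1.0, 0.0))
        energies = np.sign(rho) * rmsds + rng.normal(0.0, noise_sd, cfg.n_poses)

    poses = PoseEnsemble(
        coords=coords,
        energies=energies,
        conformer_ids=np.zeros(cfg.n_poses, dtype=int),
        model_ids=tuple(f"pose{i:05d}" for i in range(cfg.n_poses)),
        atom_names=tuple(f"C{j + 1}" for j in range(native.shape[0])),
    )
    truth = PoseTruth(rmsd_to_native=rmsds, is_near_native=is_near)
    return poses, truth
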