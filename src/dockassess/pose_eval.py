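"""Ensemble evaluation: RMSD clustering, contacts, coverage/accuracy.

Docked poses are clustered on pairwise heavy-atom RMSD in the fixed
receptor frame (2.0 Å cutoff); receptor models are clustered on pairwise
Cα RMSD after per-pair superposition (3.0 Å cutoff), optionally after
reducing to the best-scoring energy quantile.  Complete linkage
approximates the "cluster radius" semantics: the cut at the cutoff
guarantees every intra-cluster pairwise distance is at or below it.
The representative of each cluster is its lowest-energy member, and the
top-ranked item is the representative of the largest cluster.

Contacts are residues with any heavy atom within a cutoff (4.0 Å) of any
ligand heavy atom.  Contact coverage is |model ∩ reference| / |reference|
and accuracy is |model ∩ reference| / |model|; across structures the
intersection is taken on alignment columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .rigidgeom import kabsch_superpose, rmsd

__all__ = [
    "ClusterResult",
    "ContactSet",
    "pairwise_rmsd_matrix",
    "cluster_items",
    "top_ranked",
    "contacts_of",
    "coverage_accuracy",
    "region_rmsd",
]


@dataclass(frozen=True)
class ContactSet:
    """Residue-level (or residue–atom pair) ligand contacts."""

    contacts: frozenset
    cutoff: float = 4.0
    granularity: str = "residue"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "contacts", frozenset(self.contacts))

    def __len__(self):
        return len(self.contacts)


@dataclass
class ClusterResult:
    """Flat clustering of an item ensemble.

    ``order`` lists cluster labels sorted by size (descending), ties by
    representative energy then representative id; ``representatives``
    maps each cluster label to the id of its lowest-energy member.
    """

    ids: tuple
    labels: np.ndarray
    energies: np.ndarray
    cutoff: float
    order: tuple
    sizes: dict
    representatives: dict

    def members(self, label):
        return [i for i, l in zip(self.ids, self.labels) if l == label]

    @property
    def n_clusters(self):
        return len(self.order)


def pairwise_rmsd_matrix(blocks, superpose=False):
    """Symmetric RMSD matrix over coordinate blocks.

    ``superpose=True`` performs a fresh Kabsch superposition for every
    pair (model clustering); otherwise RMSD is frame-fixed (pose
    clustering).
    """
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    n = len(blocks)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if superpose:
                tf = kabsch_superpose(blocks[i], blocks[j])
                D[i, j] = D[j, i] = rmsd(tf.apply(blocks[i]), blocks[j])
            else:
                D[i, j] = D[j, i] = rmsd(blocks[i], blocks[j])
    return D


def cluster_items(blocks, energies, cutoff, ids=None, superpose=False,
                  top_fraction=None, distance_matrix=None):
    """Complete-linkage agglomerative clustering cut at ``cutoff``.

    When ``top_fraction`` is given, items are first reduced to the
    best-scoring ⌈f·N⌉ by energy (ties broken by id order).  A
    pre-computed ``distance_matrix`` for the *full* item list may be
    passed to skip the pairwise RMSD computation.
    """
    n = len(blocks)
    energies = np.asarray(energies, dtype=float)
    if len(energies) != n:
        raise ValueError("one energy per item required")
    ids = tuple(ids) if ids is not None else tuple(range(n))

    keep = np.arange(n)
    if top_fraction is not None:
        if not (0 < top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        k = int(math.ceil(top_fraction * n))
        order = sorted(range(n), key=lambda i: (energies[i], ids[i]))
        keep = np.array(sorted(order[:k]))
    blocks = [blocks[i] for i in keep]
    energies = energies[keep]
    ids = tuple(ids[i] for i in keep)

    m = len(blocks)
    if m == 1:
        labels = np.array([1])
    else:
        if distance_matrix is not None:
            D = np.asarray(distance_matrix, dtype=float)[np.ix_(keep, keep)]
        else:
            D = pairwise_rmsd_matrix(blocks, superpose=superpose)
        Z = linkage(squareform(D, checks=False), method="complete")
        labels = fcluster(Z, t=cutoff, criterion="distance")

    sizes, reps = {}, {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sizes[int(lab)] = len(idx)
        best = min(idx, key=lambda i: (energies[i], ids[i]))
        reps[int(lab)] = ids[best]
    rep_energy = {lab: energies[ids.index(reps[lab])] for lab in reps}
    order = tuple(sorted(sizes, key=lambda l: (-sizes[l], rep_energy[l], reps[l])))
    return ClusterResult(ids=ids, labels=np.asarray(labels), energies=energies,
                         cutoff=float(cutoff), order=order, sizes=sizes,
                         representatives=reps)


def top_ranked(clusters, k=5):
    """Representatives of the k largest clusters, largest first.

    k = 1 gives the conventional "top-ranked" item: the lowest-energy
    member of the largest cluster.  If fewer clusters exist, all are
    returned with a warning.
    """
    if clusters.n_clusters == 0:
        raise ValueError("empty clustering")
    if k > clusters.n_clusters:
        warnings.warn(
            f"requested {k} clusters but only {clusters.n_clusters} exist"
        )
        k = clusters.n_clusters
    return [clusters.representatives[lab] for lab in clusters.order[:k]]


def contacts_of(pose_coords, receptor, cutoff=4.0, granularity="residue",
                column_map=None):
    """Ligand–receptor contacts of one pose.

    A residue is in contact when any of its heavy atoms is within
    ``cutoff`` of any ligand heavy atom.  ``granularity="atom-pair"``
    records (residue, receptor-atom-name, ligand-atom-index) triples.
    ``column_map`` (residue id -> alignment column) translates contacts
    to alignment columns for cross-structure comparison.
    """
    lig = np.asarray(pose_coords, dtype=float).reshape(-1, 3)
    contacts = set()
    if lig.size:
        rec_pos = np.array([a.position for a in receptor.atoms]).reshape(-1, 3)
        if rec_pos.size:
            close = cdist(rec_pos, lig) <= cutoff
            for ai in np.flatnonzero(close.any(axis=1)):
                atom = receptor.atoms[ai]
                key = atom.res_id if column_map is None else column_map.get(atom.res_id)
                if key is None:
                    continue
                if granularity == "residue":
                    contacts.add(key)
                elif granularity == "atom-pair":
                    for li in np.flatnonzero(close[ai]):
                        contacts.add((key, atom.name, int(li)))
                else:
                    raise ValueError(f"unknown granularity {granularity!r}")
    return ContactSet(contacts=frozenset(contacts), cutoff=cutoff,
                      granularity=granularity)


def coverage_accuracy(model_contacts, reference_contacts):
    """(coverage, accuracy) of model contacts against reference contacts.

    coverage = correct / |reference|, accuracy = correct / |model|, with
    correct = |model ∩ reference|.  An empty reference makes coverage
    undefined (NaN), not zero; an empty model likewise for accuracy.
    """
    mset = model_contacts.contacts if isinstance(model_contacts, ContactSet) else frozenset(model_contacts)
    rset = reference_contacts.contacts if isinstance(reference_contacts, ContactSet) else frozenset(reference_contacts)
    correct = len(mset & rset)
    coverage = correct / len(rset) if rset else math.nan
    accuracy = correct / len(mset) if mset else math.nan
    return coverage, accuracy


def region_rmsd(model, reference, region_res_ids, superpose_res_ids=None,
                chain="A"):
    """Cα RMSD over a residue region, after superposing on another subset.

    With ``superpose_res_ids=None`` the structures are assumed to share a
    frame already.  Used for full-receptor / transmembrane / loop-region
    RMSD reporting.
    """
    region = list(region_res_ids)
    if not region:
        raise ValueError("empty region")
    mob = model.ca_coords(region, chain)
    ref = reference.ca_coords(region, chain)
    if superpose_res_ids is not None:
        tf = kabsch_superpose(model.ca_coords(superpose_res_ids, chain),
                              reference.ca_coords(superpose_res_ids, chain))
        mob = tf.apply(mob)
    return rmsd(mob, ref)
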