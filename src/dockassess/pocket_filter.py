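"""Knowledge-based binding-pocket filter and pocket-collapse profiles.

The filter encodes the observed flexibility of a structure family at
the ligand-binding pocket.  Pocket positions are alignment columns whose
Cα lies within a contact cutoff (4.0 Å) of the bound ligand in at least
one family structure.  Each position gets a residue-specific cutoff: the
maximum Cα–Cα distance between any two family structures at that column
(in a common superposed frame), representing how much that position is
allowed to move.  A candidate model passes only if, at every pocket
column, its Cα sits within the cutoff of the equivalent Cα in at least
one family member other than the model's own target structure
(self-exclusion avoids circular bias).

Pocket collapse measures, per pocket residue, the change in distance
from the residue's Cβ (Cα for glycine) to the closest ligand heavy atom
between a model and the reference structure; positive values mean the
residue moved toward the ligand.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rigidgeom import kabsch_superpose

__all__ = [
    "PocketDefinition",
    "CollapseProfile",
    "derive_pocket_columns",
    "derive_cutoffs",
    "build_pocket",
    "apply_pocket_filter",
    "cap_by_energy",
    "pocket_collapse",
    "superpose_model",
]


@dataclass(frozen=True)
class PocketDefinition:
    """Pocket alignment columns, per-column cutoffs (Å), exclusions."""

    columns: frozenset
    cutoffs: dict          # column -> Å
    excluded_columns: frozenset = frozenset()

    def __post_init__(self):
        cols = frozenset(self.columns)
        excl = frozenset(self.excluded_columns)
        if cols & excl:
            raise ValueError("excluded columns must not overlap pocket columns")
        if any(v < 0 for v in self.cutoffs.values()):
            raise ValueError("cutoffs must be non-negative")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "excluded_columns", excl)


@dataclass(frozen=True)
class CollapseProfile:
    """Per-column pocket collapse (Å, positive = toward the ligand)."""

    values: dict           # column -> Å

    @property
    def mean(self):
        return float(np.mean(list(self.values.values()))) if self.values else math.nan

    @property
    def std(self):
        return float(np.std(list(self.values.values()))) if self.values else math.nan


def _ligand_or_raise(model):
    lig = model.ligand_coords()
    if lig.size == 0:
        raise ValueError(f"family member {model.tag!r} carries no ligand atoms")
    return lig


def derive_pocket_columns(family, aln, contact_cutoff=4.0, exclude=()):
    """Alignment columns whose Cα is < cutoff from the ligand in >= 1 member.

    The strict inequality mirrors the contact definition; a caller-supplied
    exclusion list (e.g. positions biased by the structural alignment) is
    subtracted afterwards.
    """
    columns = set()
    for model in family:
        lig = _ligand_or_raise(model)
        res_of = aln.residue_of[model.tag]
        for col, resnum in res_of.items():
            if col in columns or not model.has_residue(resnum):
                continue
            ca = model.ca(resnum)
            if np.min(np.linalg.norm(lig - ca, axis=1)) < contact_cutoff:
                columns.add(col)
    return columns - set(exclude)


def derive_cutoffs(family, aln, columns):
    """Per-column maximum Cα–Cα distance over ordered structure pairs.

    Family members must already share one superposed frame.  Columns
    occupied in fewer than two structures cannot be assigned a cutoff and
    are returned in the second element.
    """
    cutoffs = {}
    uncutoffable = set()
    for col in sorted(columns):
        cas = []
        for model in family:
            resnum = aln.residue_of[model.tag].get(col)
            if resnum is not None and model.has_residue(resnum):
                cas.append(model.ca(resnum))
        if len(cas) < 2:
            uncutoffable.add(col)
            continue
        cas = np.asarray(cas)
        diffs = cas[:, None, :] - cas[None, :, :]
        cutoffs[col] = float(np.max(np.linalg.norm(diffs, axis=2)))
    return cutoffs, uncutoffable


def build_pocket(family, aln, contact_cutoff=4.0, exclude=()):
    """Derive pocket columns and cutoffs from a superposed family."""
    cols = derive_pocket_columns(family, aln, contact_cutoff, exclude)
    cutoffs, skipped = derive_cutoffs(family, aln, cols)
    return PocketDefinition(
        columns=frozenset(cols - skipped),
        cutoffs=cutoffs,
        excluded_columns=frozenset(set(exclude) | skipped),
    )


def apply_pocket_filter(models, family, self_id, pocket, aln, model_row=None):
    """Pass/fail verdicts for candidate models against the family pocket.

    A model passes iff at every pocket column its Cα lies within the
    column cutoff (non-strict) of the equivalent Cα in at least one
    family member that is not the model's own target structure.  Models
    missing a pocket-column residue fail with the reason recorded.

    Returns a DataFrame with one row per model: ``model_id``, ``passed``,
    ``worst_column``, ``worst_margin`` (Å over the best available cutoff;
    negative when passing), ``reason``.
    """
    model_row = model_row if model_row is not None else self_id
    others = [m for m in family if m.tag != self_id]
    if not others:
        raise ValueError("family contains no non-self structures to compare against")

    # family Cα table per column
    fam_cas = {}
    for col in sorted(pocket.columns):
        entries = []
        for m in others:
            resnum = aln.residue_of[m.tag].get(col)
            if resnum is not None and m.has_residue(resnum):
                entries.append(m.ca(resnum))
        fam_cas[col] = np.asarray(entries).reshape(-1, 3)

    rows = []
    for model in models:
        passed, reason = True, ""
        worst_col, worst_margin = None, -math.inf
        for col in sorted(pocket.columns):
            cutoff = pocket.cutoffs.get(col)
            if cutoff is None:
                continue
            resnum = aln.residue_of[model_row].get(col)
            if resnum is None or not model.has_residue(resnum):
                passed = False
                reason = f"missing pocket residue at column {col}"
                worst_col, worst_margin = col, math.inf
                break
            ca = model.ca(resnum)
            refs = fam_cas[col]
            if len(refs) == 0:
                continue
            margin = float(np.min(np.linalg.norm(refs - ca, axis=1))) - cutoff
            if margin > worst_margin:
                worst_col, worst_margin = col, margin
            if margin > 0:
                passed = False
        if not passed and not reason:
            reason = f"column {worst_col} exceeds cutoff by {worst_margin:.2f} Å"
        rows.append({
            "model_id": model.tag,
            "passed": passed,
            "worst_column": worst_col,
            "worst_margin": worst_margin,
            "reason": reason,
        })
    return pd.DataFrame(rows)


def cap_by_energy(models, cap=100):
    """Lowest-energy ``cap`` models; ties broken by model id order."""
    order = sorted(range(len(models)),
                   key=lambda i: (models[i].energy, models[i].tag, i))
    return [models[i] for i in order[: int(cap)]]


def superpose_model(model, reference, res_ids, chain="A"):
    """Copy of ``model`` Kabsch-superposed onto ``reference`` over Cα of
    the given residues."""
    tf = kabsch_superpose(model.ca_coords(res_ids, chain),
                          reference.ca_coords(res_ids, chain))
    out = copy.deepcopy(model)
    for group in (out.atoms, out.het_atoms, out.hydrogens):
        for i, a in enumerate(group):
            group[i] = type(a)(
                name=a.name, element=a.element, res_name=a.res_name,
                res_id=a.res_id, chain=a.chain,
                position=tf.apply(a.position[None])[0],
                record=a.record, occupancy=a.occupancy,
            )
    out._res_index = None
    return out


def pocket_collapse(model, reference, pocket, aln, model_row=None,
                    reference_row=None, superpose_res_ids=None):
    """Pocket-collapse profile of a model against a ligand-bound reference.

    collapse(col) = d_reference(col) − d_model(col), with d the minimum
    distance from the residue's Cβ (Cα for glycine) to any reference-
    ligand heavy atom.  Columns without a residue in both structures are
    omitted.  When ``superpose_res_ids`` is given the model is first
    superposed onto the reference over those Cα's.
    """
    model_row = model_row or model.tag
    reference_row = reference_row or reference.tag
    lig = _ligand_or_raise(reference)
    if superpose_res_ids is not None:
        model = superpose_model(model, reference, superpose_res_ids)
    values = {}
    for col in sorted(pocket.columns):
        res_m = aln.residue_of[model_row].get(col)
        res_r = aln.residue_of[reference_row].get(col)
        if (res_m is None or res_r is None
                or not model.has_residue(res_m) or not reference.has_residue(res_r)):
            continue
        d_model = float(np.min(np.linalg.norm(lig - model.cb(res_m), axis=1)))
        d_ref = float(np.min(np.linalg.norm(lig - reference.cb(res_r), axis=1)))
        values[col] = d_ref - d_model
    return CollapseProfile(values=values)
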