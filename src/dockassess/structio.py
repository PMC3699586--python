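"""Coordinate, alignment and score-table I/O.

This module owns the on-disk formats every other part of the toolkit
consumes: a narrow PDB subset (ATOM/HETATM/MODEL/ENDMDL) for receptor
models, ligand conformers and docked poses; aligned FASTA / CLUSTAL for
the receptor-family alignment; and TSV score tables.  Parsing goes
through Biopython (Bio.PDB, Bio.AlignIO); writing of the PDB subset is
fixed-width formatting owned by this module so round trips are exact to
the format's 3-decimal precision.

Conventions
-----------
* Residue identifiers are author numbering from the file, kept as strings
  so insertion codes survive (``"84"``, ``"84A"``).
* Hydrogens are parsed and kept accessible (``ReceptorModel.hydrogens``)
  but excluded from all default coordinate sets; every distance/RMSD
  computation downstream runs on heavy atoms unless a caller explicitly
  asks for named hydrogens (geometric constraints do).
* Alternate locations: highest occupancy wins, first on tie (Bio.PDB's
  selection rule).
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

__all__ = [
    "AtomRecord",
    "ReceptorModel",
    "ConformerSet",
    "PoseEnsemble",
    "AlignmentMap",
    "PDBParseError",
    "AlignmentFormatError",
    "read_pdb_models",
    "write_pdb_models",
    "read_conformers",
    "write_conformers",
    "read_poses",
    "write_poses",
    "read_alignment",
    "write_alignment",
    "sequence_identity",
    "read_score_table",
    "write_score_table",
    "attach_scores",
]


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class AlignmentFormatError(ValueError):
    """Raised for malformed multiple-alignment input."""


# one-letter codes for sequence extraction from coordinates
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom (or, behind the hydrogen flag, one hydrogen)."""

    name: str
    element: str
    res_name: str
    res_id: str            # author numbering + insertion code
    chain: str
    position: np.ndarray   # (3,) Å
    record: str = "ATOM"   # "ATOM" | "HETATM"
    occupancy: float = 1.0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


class ReceptorModel:
    """Heavy-atom coordinates of one receptor model.

    Protein atoms (``atoms``) and bound-ligand/het atoms (``het_atoms``)
    are kept separately; hydrogens from either live in ``hydrogens`` and
    take no part in default analyses.  Per-residue Cα/Cβ access follows
    the convention that Cβ falls back to Cα for glycine (or when Cβ is
    missing).
    """

    def __init__(self, atoms, het_atoms=(), hydrogens=(), energy=math.nan, tag=""):
        self.atoms = list(atoms)
        self.het_atoms = list(het_atoms)
        self.hydrogens = list(hydrogens)
        self.energy = float(energy)
        self.tag = str(tag)
        self._res_index = None

    # -- residue access -------------------------------------------------
    def _index(self):
        if self._res_index is None:
            idx = {}
            for a in self.atoms:
                idx.setdefault((a.chain, a.res_id), []).append(a)
            self._res_index = idx
        return self._res_index

    @staticmethod
    def _key(res_id, chain):
        return (chain, str(res_id))

    def residue_ids(self):
        """Ordered (chain, res_id) keys of protein residues."""
        return list(self._index().keys())

    def residue_atoms(self, res_id, chain="A"):
        try:
            return self._index()[self._key(res_id, chain)]
        except KeyError:
            raise KeyError(f"residue {chain}/{res_id} not in model {self.tag!r}") from None

    def residue_name(self, res_id, chain="A"):
        return self.residue_atoms(res_id, chain)[0].res_name

    def ca(self, res_id, chain="A"):
        """Cα position of a residue (every residue must expose one)."""
        for a in self.residue_atoms(res_id, chain):
            if a.name == "CA":
                return a.position
        raise KeyError(f"residue {chain}/{res_id} has no CA atom")

    def cb(self, res_id, chain="A"):
        """Cβ position, falling back to Cα for glycine / missing Cβ."""
        atoms = self.residue_atoms(res_id, chain)
        if atoms[0].res_name != "GLY":
            for a in atoms:
                if a.name == "CB":
                    return a.position
        return self.ca(res_id, chain)

    def has_residue(self, res_id, chain="A"):
        return self._key(res_id, chain) in self._index()

    # -- coordinate blocks ----------------------------------------------
    def coords(self):
        """Protein heavy-atom coordinates, file order, (n, 3)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def ca_coords(self, res_ids=None, chain="A"):
        if res_ids is None:
            return np.array([self.ca(r, c) for c, r in self.residue_ids()])
        return np.array([self.ca(r, chain) for r in res_ids], dtype=float)

    def ligand_coords(self, res_name=None):
        """Heavy-atom coordinates of HETATM records (optionally one residue name)."""
        sel = [a for a in self.het_atoms if res_name is None or a.res_name == res_name]
        return np.array([a.position for a in sel], dtype=float).reshape(-1, 3)

    def all_heavy_coords(self):
        """All heavy atoms (protein + het), file order — used for ligand-only files."""
        return np.array(
            [a.position for a in self.atoms + self.het_atoms], dtype=float
        ).reshape(-1, 3)

    def all_heavy_atoms(self):
        return self.atoms + self.het_atoms

    def sequence(self, chain="A"):
        """One-letter sequence over protein residues of one chain, file order."""
        out = []
        for c, r in self.residue_ids():
            if c == chain:
                out.append(_THREE_TO_ONE.get(self.residue_name(r, c), "X"))
        return "".join(out)

    def select_atoms(self, res_ids=None, names=None, elements=None,
                     include_hydrogens=False, chain=None):
        """Atoms matching every given criterion; hydrogens only on request."""
        pool = self.atoms + self.het_atoms
        if include_hydrogens:
            pool = pool + self.hydrogens
        res_ids = None if res_ids is None else {str(r) for r in res_ids}
        names = None if names is None else set(names)
        elements = None if elements is None else set(elements)
        out = []
        for a in pool:
            if res_ids is not None and a.res_id not in res_ids:
                continue
            if names is not None and a.name not in names:
                continue
            if elements is not None and a.element not in elements:
                continue
            if chain is not None and a.chain != chain:
                continue
            out.append(a)
        return out

    def __repr__(self):
        return (f"<ReceptorModel {self.tag!r}: {len(self.atoms)} protein atoms, "
                f"{len(self.het_atoms)} het atoms, energy={self.energy:g}>")


@dataclass
class ConformerSet:
    """N ligand conformers sharing one atom ordering; one is the reference
    (bioactive) conformation."""

    coords: np.ndarray            # (N, k, 3)
    reference_index: int = 0
    atom_names: tuple = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("conformer coordinates must have shape (N, k, 3)")
        if not (0 <= self.reference_index < len(self.coords)):
            raise ValueError("reference_index out of range")

    def __len__(self):
        return len(self.coords)

    @property
    def n_atoms(self):
        return self.coords.shape[1]

    @property
    def reference(self):
        return self.coords[self.reference_index]


@dataclass
class PoseEnsemble:
    """Docked ligand poses in a fixed receptor frame."""

    coords: np.ndarray            # (N, k, 3)
    energies: np.ndarray          # (N,) interaction scores
    conformer_ids: np.ndarray = None
    model_ids: tuple = ()
    atom_names: tuple = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("pose coordinates must have shape (N, k, 3)")
        if len(self.energies) != len(self.coords):
            raise ValueError("one energy per pose required")
        if self.conformer_ids is None:
            self.conformer_ids = np.zeros(len(self.coords), dtype=int)
        self.conformer_ids = np.asarray(self.conformer_ids, dtype=int)
        if not self.model_ids:
            self.model_ids = tuple(f"pose{i}" for i in range(len(self.coords)))

    def __len__(self):
        return len(self.coords)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"^REMARK\s+220\s+ENERGY\s+(\S+)")


def _scan_model_energies(lines):
    """Per-MODEL energies from REMARK 220 ENERGY lines (NaN when absent)."""
    energies = {}
    model_idx = -1
    seen_model_card = False
    for ln in lines:
        if ln.startswith("MODEL"):
            model_idx += 1
            seen_model_card = True
        m = _ENERGY_RE.match(ln)
        if m:
            idx = model_idx if seen_model_card else 0
            try:
                energies[max(idx, 0)] = float(m.group(1))
            except ValueError:
                pass
    return energies


def read_pdb_models(path, keep_waters=False):
    """Read a (possibly multi-model) PDB file into ReceptorModel objects.

    Hydrogens are dropped from the default atom lists but retained in
    ``model.hydrogens``.  HETATM records are kept separate so a bound
    ligand is recoverable by residue name.  Malformed ATOM/HETATM lines
    raise :class:`PDBParseError` naming the offending line; a file with
    no coordinate records raises it too.
    """
    path = str(path)
    with open(path) as fh:
        text = fh.read()
    energies = _scan_model_energies(text.splitlines())

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("m", io.StringIO(text))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"{path}: malformed PDB record ({exc})") from exc

    models = []
    for mi, bm in enumerate(structure):
        atoms, het, hyd = [], [], []
        for chain in bm:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                if hetflag == "W" and not keep_waters:
                    continue
                res_id = f"{resseq}{icode.strip()}"
                is_het = hetflag.strip() != ""
                for atom in residue:
                    elem = (atom.element or "").strip().upper()
                    if not elem:
                        elem = re.sub(r"[^A-Z]", "", atom.get_name().upper())[:1]
                    rec = AtomRecord(
                        name=atom.get_name(),
                        element=elem,
                        res_name=residue.get_resname().strip(),
                        res_id=res_id,
                        chain=chain.id,
                        position=atom.get_coord().astype(float),
                        record="HETATM" if is_het else "ATOM",
                        occupancy=float(atom.get_occupancy() or 1.0),
                    )
                    if elem in ("H", "D"):
                        hyd.append(rec)
                    elif is_het:
                        het.append(rec)
                    else:
                        atoms.append(rec)
        models.append(
            ReceptorModel(atoms, het, hyd,
                          energy=energies.get(mi, math.nan),
                          tag=f"model{mi + 1}")
        )
    if not models or all(
        not (m.atoms or m.het_atoms or m.hydrogens) for m in models
    ):
        raise PDBParseError(f"{path}: no coordinate records found")
    return models


def _format_atom_line(rec, serial, resseq, icode):
    name = rec.name if len(rec.name) == 4 else f" {rec.name:<3}"
    return (
        f"{rec.record:<6}{serial:>5} {name}{'':1}{rec.res_name:>3} "
        f"{rec.chain:1}{resseq:>4}{icode:1}   "
        f"{rec.position[0]:8.3f}{rec.position[1]:8.3f}{rec.position[2]:8.3f}"
        f"{rec.occupancy:6.2f}{0.0:6.2f}          {rec.element:>2}\n"
    )


def _split_res_id(res_id):
    m = re.fullmatch(r"(-?\d+)([A-Za-z]?)", str(res_id))
    if not m:
        raise ValueError(f"unparseable residue id {res_id!r}")
    return int(m.group(1)), m.group(2) or " "


def write_pdb_models(models, path, include_hydrogens=True):
    """Write models as a (multi-)MODEL PDB file.

    Coordinates are written at the format's fixed 3-decimal precision;
    a finite ``model.energy`` is recorded as ``REMARK 220 ENERGY`` inside
    the MODEL block so round trips preserve it.
    """
    if isinstance(models, ReceptorModel):
        models = [models]
    multi = len(models) > 1
    with open(path, "w") as fh:
        for mi, m in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {mi:>4}\n")
            if math.isfinite(m.energy):
                fh.write(f"REMARK 220 ENERGY {m.energy:.6f}\n")
            serial = 1
            pool = m.atoms + m.het_atoms
            if include_hydrogens:
                pool = pool + m.hydrogens
            for rec in pool:
                resseq, icode = _split_res_id(rec.res_id)
                fh.write(_format_atom_line(rec, serial, resseq, icode))
                serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_conformers(path, reference_index=0):
    """Read a multi-model PDB of ligand conformers into a ConformerSet."""
    models = read_pdb_models(path)
    blocks = [m.all_heavy_coords() for m in models]
    counts = {b.shape[0] for b in blocks}
    if len(counts) != 1:
        raise PDBParseError(f"{path}: conformers differ in heavy-atom count {sorted(counts)}")
    names = tuple(a.name for a in models[0].all_heavy_atoms())
    return ConformerSet(np.stack(blocks), reference_index=reference_index,
                        atom_names=names)


def _coords_to_model(block, atom_names, energy=math.nan, res_name="LIG"):
    names = atom_names or tuple(f"C{i + 1}" for i in range(len(block)))
    atoms = [
        AtomRecord(name=n, element=re.sub(r"[^A-Za-z]", "", n)[:1].upper() or "C",
                   res_name=res_name, res_id="1", chain="X",
                   position=p, record="HETATM")
        for n, p in zip(names, block)
    ]
    return ReceptorModel([], atoms, energy=energy)


def write_conformers(conformers, path):
    models = [_coords_to_model(b, conformers.atom_names) for b in conformers.coords]
    write_pdb_models(models, path)


def write_poses(poses, path):
    models = [
        _coords_to_model(b, poses.atom_names, energy=e)
        for b, e in zip(poses.coords, poses.energies)
    ]
    write_pdb_models(models, path)


def read_poses(path):
    """Read a multi-model PDB of docked poses (energies from REMARK 220)."""
    models = read_pdb_models(path)
    blocks = [m.all_heavy_coords() for m in models]
    counts = {b.shape[0] for b in blocks}
    if len(counts) != 1:
        raise PDBParseError(f"{path}: poses differ in heavy-atom count {sorted(counts)}")
    return PoseEnsemble(
        coords=np.stack(blocks),
        energies=np.array([m.energy for m in models]),
        model_ids=tuple(m.tag for m in models),
        atom_names=tuple(a.name for a in models[0].all_heavy_atoms()),
    )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

class AlignmentMap:
    """Residue <-> column mapping across a receptor family.

    Columns are 1-based.  Residue numbers default to sequential from a
    per-sequence offset (1 unless a sidecar offset table says otherwise);
    gap columns map to no residue.
    """

    def __init__(self, sequences, offsets=None):
        self.sequences = dict(sequences)
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"aligned sequences differ in gapped length: {sorted(lengths)}"
            )
        self.offsets = {k: 1 for k in self.sequences}
        if offsets:
            self.offsets.update({k: int(v) for k, v in offsets.items()})
        self.column_of = {}
        self.residue_of = {}
        for sid, seq in self.sequences.items():
            col_of, res_of = {}, {}
            resnum = self.offsets[sid] - 1
            for col, ch in enumerate(seq, start=1):
                if ch not in "-.":
                    resnum += 1
                    col_of[resnum] = col
                    res_of[col] = resnum
            self.column_of[sid] = col_of
            self.residue_of[sid] = res_of

    @property
    def length(self):
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def ids(self):
        return list(self.sequences)

    def _seq(self, sid):
        try:
            return self.sequences[sid]
        except KeyError:
            raise LookupError(f"sequence id {sid!r} not in alignment") from None

    def residue_at(self, sid, column):
        """Residue number of `sid` at `column`, or None for a gap."""
        self._seq(sid)
        return self.residue_of[sid].get(column)

    def column_for(self, sid, resnum):
        self._seq(sid)
        try:
            return self.column_of[sid][int(resnum)]
        except KeyError:
            raise LookupError(f"residue {resnum} not mapped for {sid!r}") from None


def read_alignment(path, offsets=None, fmt=None):
    """Read a CLUSTAL or aligned-FASTA alignment into an AlignmentMap."""
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            head = fh.read(64)
        fmt = "clustal" if head.upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(path, fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    return AlignmentMap({rec.id: str(rec.seq) for rec in aln}, offsets=offsets)


def write_alignment(aln_map, path):
    with open(path, "w") as fh:
        for sid, seq in aln_map.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def sequence_identity(aln_map, a, b, denominator="coaligned"):
    """Percent identity between two rows of the alignment.

    By default the denominator is the number of columns where both rows
    are non-gap (``"coaligned"``); ``"alignment"`` divides by the full
    alignment length instead.
    """
    sa, sb = aln_map._seq(a), aln_map._seq(b)
    both = [(x, y) for x, y in zip(sa, sb) if x not in "-." and y not in "-."]
    ident = sum(1 for x, y in both if x.upper() == y.upper())
    if denominator == "coaligned":
        denom = len(both)
    elif denominator == "alignment":
        denom = aln_map.length
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return math.nan
    return 100.0 * ident / denom


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path):
    """TSV with header ``model_id<TAB>energy`` (+ optional extra columns)."""
    df = pd.read_csv(path, sep="\t")
    if "model_id" not in df.columns or "energy" not in df.columns:
        raise ValueError(f"{path}: score table needs model_id and energy columns")
    if df["model_id"].duplicated().any():
        dups = df.loc[df["model_id"].duplicated(), "model_id"].tolist()
        raise ValueError(f"{path}: duplicate model ids {dups}")
    return df


def write_score_table(df, path):
    pd.DataFrame(df).to_csv(path, sep="\t", index=False, float_format="%.6f")


def attach_scores(models, table):
    """Assign ``energy`` to each model from a score table, matching on tag."""
    lookup = dict(zip(table["model_id"].astype(str), table["energy"]))
    for m in models:
        if m.tag in lookup:
            m.energy = float(lookup[m.tag])
    return models
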