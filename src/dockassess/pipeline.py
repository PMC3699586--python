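"""End-to-end assessment pipeline.

Orchestrates the full workflow from one flat YAML config: derive the
family pocket, filter the comparative-model ensemble and cap it by
energy, cluster the models, compute USE2.0 for the conformer ensemble,
evaluate the docked-pose ensemble (clustering, top-ranked poses,
contact coverage/accuracy), and quantify enrichment from contact
constraints and energy cutoffs.  Every stage writes a TSV under the
output directory, and a manifest records seed, parameters and stage
outputs so a rerun with the same config is byte-identical.

Inputs are either generated synthetically (``synthetic:`` section) or
loaded from PDB/TSV paths (``inputs:`` section).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import contact_enrichment, energy_cutoff_sweep
from .pocket_filter import apply_pocket_filter, build_pocket, cap_by_energy
from .pose_eval import cluster_items, contacts_of, coverage_accuracy, top_ranked
from .rigidgeom import rmsd
from .structio import (
    attach_scores,
    read_alignment,
    read_conformers,
    read_pdb_models,
    read_poses,
    read_score_table,
)
from .synthetic import (
    FamilyConfig,
    PoseConfig,
    gen_conformers,
    gen_model_ensemble,
    gen_pose_ensemble,
    gen_receptor_family,
)
from .use_metric import UseParams, compute_use, fold_decrease

__all__ = ["RunConfig", "run_assessment", "PipelineError"]

_FLOAT_FMT = "%.6f"


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Flat run configuration with the protocol's default parameters."""

    seed: int = 0
    output_dir: str = "dockassess_out"
    # USE2.0
    use_threshold: float = 2.0          # Å, near-native RMSD threshold
    use_radius: float = 5.0             # Å, docking-sphere radius
    use_spacings: int = 40              # Euler spacings M
    # pocket filter
    contact_cutoff: float = 4.0         # Å, Cα–ligand pocket definition
    energy_cap: int = 100               # max filtered models kept by energy
    excluded_columns: tuple = ()
    # clustering
    model_cluster_cutoff: float = 3.0   # Å, model Cα cluster radius
    pose_cluster_cutoff: float = 2.0    # Å, pose heavy-atom cluster cutoff
    top_fraction: float = 0.1           # energy quantile before model clustering
    top_k: int = 5                      # clusters examined further
    # enrichment
    enrich_iterations: int = 10000
    energy_fractions: tuple = (1.0, 0.5, 0.2, 0.1, 0.05)
    # input source: exactly one of the two below
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(cfg):
    """Materialize family, models, conformers and poses for the run."""
    if cfg.inputs:
        paths = {k: Path(v) for k, v in cfg.inputs.items() if k != "self_id"}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        family_members = []
        for p in sorted(Path(paths["family_dir"]).glob("*.pdb")):
            m = read_pdb_models(p)[0]
            m.tag = p.stem
            family_members.append(m)
        aln = read_alignment(paths["alignment"])
        models = read_pdb_models(paths["models"])
        if "model_scores" in paths:
            attach_scores(models, read_score_table(paths["model_scores"]))
        conformers = read_conformers(paths["conformers"])
        poses = read_poses(paths["poses"])
        native = read_pdb_models(paths["native_pose"])[0].all_heavy_coords()
        self_id = cfg.inputs["self_id"]
        receptor = next(m for m in family_members if m.tag == self_id)
        return family_members, aln, self_id, models, conformers, poses, native, receptor

    syn = dict(cfg.synthetic)
    fam_kwargs = {k: syn[k] for k in
                  ("n_structures", "n_residues", "pocket_size", "sigma_family")
                  if k in syn}
    family = gen_receptor_family(FamilyConfig(seed=cfg.seed, **fam_kwargs))
    self_id = syn.get("self_id", "S0")
    mdl = dict(syn.get("models", {}))
    models, _ = gen_model_ensemble(family, self_id, seed=cfg.seed + 1, **mdl)
    receptor = next(m for m in family.members if m.tag == self_id)
    native = receptor.ligand_coords()
    conf = dict(syn.get("conformers", {}))
    conformers, _ = gen_conformers(native, seed=cfg.seed + 2, **conf)
    pose_kwargs = dict(syn.get("poses", {}))
    poses, _ = gen_pose_ensemble(
        native, receptor, PoseConfig(seed=cfg.seed + 3, **pose_kwargs))
    return family.members, family.alignment, self_id, models, conformers, \
        poses, native, receptor


def _neglog(x):
    return -math.log10(x) if x > 0 else math.inf


def run_assessment(cfg):
    """Run the full assessment; returns the manifest dict.

    Writes per-stage TSVs and ``manifest.json`` under ``cfg.output_dir``.
    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs of completed stages are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "dockassess",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items() if k not in ("synthetic", "inputs")
        },
        "stages": {},
    }
    state = {}

    def run_stage(name, fn):
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 — abort with stage name
            _write_manifest(out, manifest)
            raise PipelineError(name, exc) from exc

    def stage_load():
        (state["family"], state["aln"], state["self_id"], state["models"],
         state["conformers"], state["poses"], state["native"],
         state["receptor"]) = _load_inputs(cfg)
        return {
            "source": "inputs" if cfg.inputs else "synthetic",
            "n_family": len(state["family"]),
            "self_id": state["self_id"],
            "n_models": len(state["models"]),
            "n_conformers": len(state["conformers"]),
            "n_poses": len(state["poses"]),
        }

    def stage_filter():
        pocket = build_pocket(state["family"], state["aln"],
                              cfg.contact_cutoff, exclude=cfg.excluded_columns)
        pd.DataFrame(
            {"column": sorted(pocket.cutoffs),
             "cutoff_A": [pocket.cutoffs[c] for c in sorted(pocket.cutoffs)]}
        ).to_csv(out / "pocket.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
        report = apply_pocket_filter(state["models"], state["family"],
                                     state["self_id"], pocket, state["aln"])
        report.to_csv(out / "filter_report.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
        passing = [m for m, ok in zip(state["models"], report["passed"]) if ok]
        state["capped"] = cap_by_energy(passing, cfg.energy_cap)
        return {"n_pocket_columns": len(pocket.columns),
                "n_passing": len(passing), "n_capped": len(state["capped"])}

    def stage_model_clustering():
        models = state["models"]
        clusters = cluster_items([m.ca_coords() for m in models],
                                 [m.energy for m in models],
                                 cfg.model_cluster_cutoff,
                                 ids=[m.tag for m in models],
                                 superpose=True,
                                 top_fraction=cfg.top_fraction)
        rep_ids = top_ranked(clusters, min(cfg.top_k, clusters.n_clusters))
        reps = set(clusters.representatives.values())
        pd.DataFrame({
            "model_id": clusters.ids,
            "cluster": clusters.labels,
            "is_representative": [i in reps for i in clusters.ids],
        }).to_csv(out / "model_clusters.tsv", sep="\t", index=False)
        return {"n_clustered": len(clusters.ids),
                "n_clusters": clusters.n_clusters,
                "top_ranked": list(rep_ids)}

    def stage_use():
        conformers = state["conformers"]
        params = UseParams(cfg.use_threshold, cfg.use_radius, cfg.use_spacings)
        ens = compute_use(conformers, conformers.reference, params)
        bio = compute_use(conformers.reference[None], conformers.reference,
                          params)
        fold = fold_decrease(bio, ens)
        pd.DataFrame({
            "conformer": np.arange(len(ens.per_conformer)),
            "use": ens.per_conformer,
        }).to_csv(out / "use_per_conformer.tsv", sep="\t", index=False,
                  float_format="%.6e")
        state["use_ens"] = ens
        return {"use_ensemble": ens.use, "use_bioactive": bio.use,
                "neg_log10_use_ensemble": _neglog(ens.use),
                "fold_decrease_conformers": fold}

    def stage_pose():
        poses, native, receptor = state["poses"], state["native"], state["receptor"]
        pose_rmsd = np.array([rmsd(b, native) for b in poses.coords])
        clusters = cluster_items(list(poses.coords), poses.energies,
                                 cfg.pose_cluster_cutoff, ids=poses.model_ids)
        reps = top_ranked(clusters, min(cfg.top_k, clusters.n_clusters))
        native_contacts = contacts_of(native, receptor, cfg.contact_cutoff)
        rows = []
        for pid in reps:
            i = poses.model_ids.index(pid)
            c = contacts_of(poses.coords[i], receptor, cfg.contact_cutoff)
            cov, acc = coverage_accuracy(c, native_contacts)
            rows.append({"pose_id": pid, "rmsd": pose_rmsd[i],
                         "coverage": cov, "accuracy": acc})
        pd.DataFrame(rows).to_csv(out / "top_poses.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
        pd.DataFrame({"pose_id": poses.model_ids, "cluster": clusters.labels,
                      "rmsd": pose_rmsd}).to_csv(
            out / "pose_clusters.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        state["pose_rmsd"] = pose_rmsd
        state["native_contacts"] = native_contacts
        eff = float(np.mean(pose_rmsd <= cfg.use_threshold))
        state["efficiency"] = eff
        return {"sampling_efficiency": eff,
                "neg_log10_efficiency": _neglog(eff),
                "n_native_contacts": len(native_contacts),
                "n_pose_clusters": clusters.n_clusters,
                "top_ranked": list(reps)}

    def stage_enrichment():
        poses, receptor = state["poses"], state["receptor"]
        pose_contacts = [contacts_of(b, receptor, cfg.contact_cutoff)
                         for b in poses.coords]
        curve = contact_enrichment(pose_contacts, state["pose_rmsd"],
                                   state["native_contacts"],
                                   iterations=cfg.enrich_iterations,
                                   seed=cfg.seed + 4)
        pd.DataFrame({
            "n": curve.n_constraints,
            "mean_efficiency": curve.mean_efficiency,
            "sd": curve.sd_efficiency,
            "empty_fraction": curve.empty_fraction,
        }).to_csv(out / "enrichment.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
        sweep = energy_cutoff_sweep(poses.energies, state["pose_rmsd"],
                                    cfg.energy_fractions)
        pd.DataFrame({"fraction": list(sweep),
                      "efficiency": list(sweep.values())}).to_csv(
            out / "energy_sweep.tsv", sep="\t", index=False,
            float_format=_FLOAT_FMT)
        finite = [v for v in curve.mean_efficiency if not math.isnan(v)]
        return {"base_efficiency": float(curve.mean_efficiency[0]),
                "max_mean_efficiency": float(max(finite)),
                "efficiency_top10pct": sweep.get(0.1, math.nan)}

    def stage_summary():
        eff = state["efficiency"]
        use_ens = state["use_ens"].use
        fold_over_use = eff / use_ens if use_ens > 0 else math.inf
        rows = [
            ("sampling_efficiency", eff),
            ("neg_log10_sampling_efficiency", _neglog(eff)),
            ("fold_over_use2", fold_over_use),
            ("neg_log10_use2_ensemble", _neglog(use_ens)),
            ("fold_decrease_conformers",
             manifest["stages"]["use2"]["fold_decrease_conformers"]),
        ]
        pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
            out / "summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        return {"sampling_efficiency_vs_use2_fold": fold_over_use}

    run_stage("load_inputs", stage_load)
    run_stage("pocket_filter", stage_filter)
    run_stage("model_clustering", stage_model_clustering)
    run_stage("use2", stage_use)
    run_stage("pose_evaluation", stage_pose)
    run_stage("enrichment", stage_enrichment)
    run_stage("summary", stage_summary)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out, manifest):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
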