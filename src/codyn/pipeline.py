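"""Configuration-driven orchestration of the full comparative analysis.

A run configuration (YAML) names the systems to compare — either paths to
multi-model PDB trajectories or synthetic-generation blocks — plus the PC
report depth, distance specs and titration inputs.  ``run_pipeline``
executes simulate -> preprocess (C-alpha reduction, subunit splitting,
concatenation) -> alignment -> combined PCA -> per-system statistics ->
pseudo-trajectories -> contacts -> titration, writes every stage's tables
into the output directory and finishes with a manifest (inputs, seeds,
output hashes) so reruns are verifiably identical.

All randomness flows from one root seed through named substreams, so each
stage is reproducible independently of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as ct
from . import pca as cpca
from . import synthetic as syn
from . import titration as tit
from . import trajectory as tio
from .errors import ConfigError
from .superposition import align_to_mean

__all__ = ["RunConfig", "load_config", "run_pipeline", "substream"]

log = logging.getLogger(__name__)


def substream(root_seed: int, *names) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    tags = [zlib.crc32(str(n).encode()) for n in names]
    ss = np.random.SeedSequence([int(root_seed)] + tags)
    return int(ss.generate_state(1)[0] % (2**31))


class RunConfig:
    """Validated run configuration (see package docs for the YAML schema)."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.seed = raw.get("seed")
        self.out_dir = Path(raw.get("out_dir", "codyn_run"))
        self.systems = raw.get("systems", [])
        self.synthetic = raw.get("synthetic", {})
        self.n_pcs = int(raw.get("pca", {}).get("n_pcs", 10))
        self.distances = raw.get("distances", [])
        self.titration = raw.get("titration", {})
        self.validate()

    def validate(self):
        if self.systems and len(self.systems) < 2:
            raise ConfigError(
                "a comparison run needs at least 2 systems "
                f"(got {len(self.systems)})"
            )
        uses_synthetic = any("traj" not in s for s in self.systems) or (
            self.titration and "table" not in self.titration
        )
        if uses_synthetic and self.seed is None:
            raise ConfigError("a seed is mandatory for any stochastic step")
        for s in self.systems:
            if "name" not in s:
                raise ConfigError("every system block needs a name")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return RunConfig(raw)


def default_synthetic_config(seed: int = 0, out_dir: str = "codyn_run") -> RunConfig:
    """Desk-scale demonstration setup: 4 systems x 2 chains x 1000 frames,
    100 residues per chain, 3 planted modes, plus a synthetic titration."""
    raw = {
        "seed": seed,
        "out_dir": out_dir,
        "synthetic": {
            "n_residues_per_chain": 100,
            "n_chains": 2,
            "n_frames": 1000,
            "n_modes": 3,
            "sigma_noise": 0.2,
        },
        "systems": [
            {"name": "sysA", "mu": [2.0, 0.0, 0.0], "a": [3.0, 2.0, 1.0]},
            {"name": "sysB", "mu": [2.0, 0.0, 0.0], "a": [3.0, 2.0, 1.0]},
            {"name": "sysC", "mu": [-2.0, 0.0, 0.0], "a": [3.0, 2.0, 1.0]},
            {"name": "sysD", "mu": [-2.0, 0.0, 0.0], "a": [3.0, 4.0, 1.0]},
        ],
        "pca": {"n_pcs": 10},
        "titration": {
            "protein_mM": 0.5,
            "kd_mM": 0.6,
            "n_binders": 10,
            "n_silent": 5,
            "noise_sd_ppm": 0.005,
            "at_ligand_mM": 2.0,
            "threshold_ppm": 0.05,
        },
    }
    return RunConfig(raw)


def _simulate_systems(cfg: RunConfig):
    blk = cfg.synthetic
    structure = syn.make_toy_structure(
        blk.get("n_residues_per_chain", 100),
        blk.get("n_chains", 2),
        substream(cfg.seed, "structure"),
    )
    modes = syn.make_mode_set(
        structure,
        blk.get("n_modes", 3),
        substream(cfg.seed, "modes"),
        sigma_noise=blk.get("sigma_noise", 0.2),
    )
    trajs = {}
    for s in cfg.systems:
        modes.with_system(s["name"], s["mu"], s["a"])
        trajs[s["name"]] = syn.simulate_system_trajectory(
            structure,
            modes,
            s["name"],
            blk.get("n_frames", 1000),
            substream(cfg.seed, "traj", s["name"]),
        )
    return structure, modes, trajs


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
        "errors": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append({"name": name, "t": round(time.time() - t0, 3)})

    try:
        # --- obtain per-system trajectories -------------------------------
        if any("traj" not in s for s in cfg.systems):
            stage("simulate")
            _, modes, trajs = _simulate_systems(cfg)
        else:
            stage("load")
            trajs = {
                s["name"]: tio.read_trajectory(s["traj"], system=s["name"])
                for s in cfg.systems
            }

        # --- preprocess: Calpha, split subunits, concatenate --------------
        stage("preprocess")
        rmap = None
        if cfg.raw.get("residue_map"):
            rmap = tio.read_residue_map(cfg.raw["residue_map"])
        subunits = []
        for s in cfg.systems:
            ca = tio.select_calpha(trajs[s["name"]])
            for chain_traj in tio.split_chains(ca):
                subunits.append(chain_traj.with_system(s["name"]))
        combined = tio.concatenate(subunits, rmap)
        manifest["n_subunit_trajectories"] = len(subunits)
        manifest["n_combined_frames"] = combined.n_frames

        # --- align and fit the combined PCA -------------------------------
        stage("align")
        combined = align_to_mean(combined)
        stage("pca")
        model = cpca.fit_pca(combined)
        n_pcs = min(cfg.n_pcs, model.rank)
        series = cpca.project(combined, model, list(range(n_pcs)))
        stats = cpca.system_stats(series)
        stats_path = out / "projection_stats.tsv"
        stats.to_csv(stats_path, sep="\t", index=False, float_format="%.6f")
        manifest["outputs"]["projection_stats"] = str(stats_path)
        eig_path = out / "eigenvalues.tsv"
        pd.DataFrame(
            {
                "pc": np.arange(1, model.rank + 1),
                "eigenvalue_A2": model.eigenvalues,
                "fraction": model.eigenvalues / model.total_variance,
            }
        ).to_csv(eig_path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["eigenvalues"] = str(eig_path)
        manifest["n_pca_models"] = 1

        stage("pseudo-trajectories")
        for pc in range(min(3, model.rank)):
            ps = cpca.pseudo_trajectory(model, pc, n_frames=11)
            ptraj = tio.Trajectory(
                atoms=ps.atoms,
                coords=ps.frames,
                system=np.full(ps.frames.shape[0], f"PC{pc + 1}", dtype=object),
            )
            path = out / f"pseudo_pc{pc + 1}.pdb"
            tio.write_trajectory(ptraj, path, bfactor=ps.residue_rmsf)
            manifest["outputs"][f"pseudo_pc{pc + 1}"] = str(path)

        # --- contacts ------------------------------------------------------
        if cfg.distances:
            stage("contacts")
            rows = []
            for d in cfg.distances:
                spec = ct.DistanceSpec(
                    d["chain1"], d["resid1"], d["name1"],
                    d["chain2"], d["resid2"], d["name2"],
                    d.get("label", ""),
                )
                for name, traj in trajs.items():
                    s = ct.distance_series(traj, spec)
                    h = ct.histogram(s)
                    rows.append(
                        {
                            "label": spec.label,
                            "system": name,
                            "mean_A": h.mean,
                            "n_frames": h.n,
                        }
                    )
            dist_path = out / "distances.tsv"
            pd.DataFrame(rows).to_csv(
                dist_path, sep="\t", index=False, float_format="%.4f"
            )
            manifest["outputs"]["distances"] = str(dist_path)

        # --- titration -----------------------------------------------------
        if cfg.titration:
            stage("titrate")
            tcfg = cfg.titration
            if "table" in tcfg:
                tset = tit.read_titration_table(
                    tcfg["table"], protein=tcfg["protein_mM"]
                )
                truth = None
            else:
                truth = syn.make_titration_truth(
                    tcfg.get("n_binders", 10),
                    tcfg.get("kd_mM", 0.6),
                    substream(cfg.seed, "titration-truth"),
                    protein=tcfg.get("protein_mM", 0.5),
                    n_silent=tcfg.get("n_silent", 5),
                    noise_sd=tcfg.get("noise_sd_ppm", 0.0),
                )
                tset = syn.simulate_titration_set(
                    truth, substream(cfg.seed, "titration-noise")
                )
                table_path = out / "titration.tsv"
                tit.write_titration_table(tset, table_path)
                manifest["outputs"]["titration_table"] = str(table_path)
                sidecar = out / "titration_truth.tsv"
                syn.write_ground_truth_sidecar(truth, sidecar)
                manifest["outputs"]["titration_truth"] = str(sidecar)
            binders = tit.select_binders(
                tset,
                at_ligand=tcfg.get("at_ligand_mM", 2.0),
                threshold=tcfg.get("threshold_ppm", 0.05),
            )
            fit = tit.fit_global(tset, binders)
            fit_path = out / "binding_fit.tsv"
            pd.DataFrame(
                {
                    "residue": fit.d0.index,
                    "d0_ppm": fit.d0.to_numpy(),
                    "d0_stderr_ppm": fit.d0_stderr.to_numpy(),
                }
            ).to_csv(fit_path, sep="\t", index=False, float_format="%.6f")
            manifest["outputs"]["binding_fit"] = str(fit_path)
            manifest["kd_mM"] = fit.kd
            manifest["kd_stderr_mM"] = fit.kd_stderr
            manifest["n_binders"] = len(binders)
            if truth is not None:
                manifest["kd_true_mM"] = truth.kd

        manifest["output_hashes"] = {
            k: _file_hash(Path(v)) for k, v in manifest["outputs"].items()
        }
    except Exception as exc:
        current = manifest["stages"][-1]["name"] if manifest["stages"] else "setup"
        manifest["errors"].append({"stage": current, "error": str(exc)})
        _write_manifest(manifest, out)
        raise

    manifest["runtime_s"] = round(time.time() - t0, 3)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
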