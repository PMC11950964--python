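"""End-to-end orchestration with a reproducible run manifest.

Stages run in dependency order: ingest-or-simulate -> beta partition ->
occurrence correction -> MPD -> predictor assembly -> GLMs -> path model.
All randomness flows from one root seed through named per-stage
substreams.  A failure halts the run with a stage-named error; outputs
written up to that point are retained.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models, occurrence, phylo, predictors
from .decomposition import BetaDiversityPartition
from .simulate import ScenarioConfig, generate_landscape, read_landscape, write_landscape

__all__ = ["PipelineError", "run_pipeline", "stage_seed", "default_config"]


class PipelineError(RuntimeError):
    """Raised with the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def default_config(out_dir="pipeline_out", seed: int = 0, simulate: bool = True) -> dict:
    return {
        "seed": seed,
        "out_dir": str(out_dir),
        "simulate": simulate,
        "inputs": {},          # community/site_env/traits/tree paths when not simulating
        "scenario": {},        # ScenarioConfig overrides when simulating
        "orientation": "sites-rows",
        "mpd": {"weighted": False, "species_lift": "occupancy-mean"},
        "vif_threshold": 10.0,
        "glm": {"focals": ["aridity", "soil"]},
        "sem": {"eliminate": True, "standardize": True},
    }


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config) -> dict:
    """Run the full chain; returns the manifest dict (also written to disk).

    ``config`` is a dict or a path to a YAML file following
    :func:`default_config`.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config)
    cfg = default_config()
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
        "outputs": {},
        "input_checksums": {},
        "decisions": [],
    }

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 4)
                }
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
        return _Timer()

    # ---- stage: data ------------------------------------------------------
    with _stage("data"):
        if cfg["simulate"]:
            scenario = ScenarioConfig(seed=stage_seed(seed, "simulate"),
                                      **cfg["scenario"])
            land = generate_landscape(scenario)
            write_landscape(land, out / "landscape")
            manifest["outputs"]["landscape"] = str(out / "landscape")
        else:
            paths = cfg["inputs"]
            for key in ("community", "site_env", "traits", "tree"):
                if key not in paths:
                    raise FileNotFoundError(f"input {key!r} not configured")
                p = Path(paths[key])
                if not p.exists():
                    raise FileNotFoundError(f"input {key!r} missing: {p}")
                manifest["input_checksums"][key] = _file_checksum(p)
            community = pd.read_csv(paths["community"], index_col=0)
            if cfg["orientation"] == "species-rows":
                community = community.T
            site_env = pd.read_csv(paths["site_env"], index_col=0)
            traits = pd.read_csv(paths["traits"], index_col=0)
            tree = phylo.read_tree(paths["tree"])
            from .simulate import SyntheticLandscape
            land = SyntheticLandscape(community=community, site_env=site_env,
                                      traits=traits, tree=tree, truth={})
        bad_sites = sorted(set(map(str, land.community.index))
                           - set(map(str, land.site_env.index)))
        if bad_sites:
            raise ValueError(f"sites missing from site_env: {bad_sites}")
        bad_species = sorted(set(map(str, land.community.columns))
                             - set(map(str, land.traits.index)))
        if bad_species:
            raise ValueError(f"species missing from traits: {bad_species}")

    # ---- stage: beta partition --------------------------------------------
    with _stage("beta_partition"):
        part = BetaDiversityPartition().fit(land.community)
        dec = pd.DataFrame({"scbd": part.scbd_})
        dec.to_csv(out / "scbd.csv", index_label="species")
        part.lcbd_.to_frame().to_csv(out / "lcbd.csv", index_label="site")
        manifest["outputs"]["scbd"] = str(out / "scbd.csv")
        manifest["outputs"]["lcbd"] = str(out / "lcbd.csv")
        manifest["bd_total"] = part.bd_total_

    # ---- stage: occurrence correction --------------------------------------
    with _stage("occurrence_correction"):
        prof = occurrence.occurrence_profile(land.community)
        fit = occurrence.fit_quadratic_beta_regression(part.scbd_, prof)
        eff = occurrence.effective_scbd(part.scbd_, prof, fit)
        eff.to_csv(out / "scbdeff.csv", index_label="species")
        manifest["outputs"]["scbdeff"] = str(out / "scbdeff.csv")
        manifest["beta_regression"] = {
            "coefficients": [float(c) for c in fit.coefficients],
            "precision": fit.precision,
            "log_likelihood": fit.log_likelihood,
            "gradient_norm": fit.gradient_norm,
            "converged": fit.converged,
        }

    # ---- stage: phylogenetic diversity --------------------------------------
    with _stage("phylo_diversity"):
        if land.tree is None:
            raise FileNotFoundError("MPD requested but no tree available")
        D = phylo.patristic_distances(land.tree, prune_to=land.species)
        mpd_sites = phylo.mpd_per_site(land.community, D,
                                       weighted=cfg["mpd"]["weighted"])
        sp_mpd = phylo.species_level_mpd(land.community, mpd_sites,
                                         method=cfg["mpd"]["species_lift"], D=D)
        mpd_sites.to_frame().to_csv(out / "mpd_sites.csv", index_label="site")
        sp_mpd.to_frame().to_csv(out / "mpd_species.csv", index_label="species")
        manifest["outputs"]["mpd"] = str(out / "mpd_species.csv")

    # ---- stage: predictors ---------------------------------------------------
    with _stage("predictors"):
        table, report = predictors.assemble_predictor_table(
            land.community, land.site_env, land.traits, sp_mpd, eff["scbd_eff"],
        )
        numeric = ["aridity", "soil", "height_cm", "sla_cm2_per_g",
                   "leaf_production", "species_mpd", "c3_relative_abundance"]
        retained, vif_report = predictors.vif_screen(
            table[numeric].dropna(), threshold=cfg["vif_threshold"]
        )
        removed = [r for r in vif_report["removed"] if r]
        if removed:
            manifest["decisions"].append(f"VIF removed: {removed}")
        table.to_csv(out / "model_table.csv", index_label="species")
        manifest["outputs"]["model_table"] = str(out / "model_table.csv")
        manifest["soil_pca"] = report
        manifest["vif_retained"] = list(retained.columns)

    # ---- stage: GLMs ---------------------------------------------------------
    with _stage("glm"):
        modeled = table.dropna(subset=["scbd_eff"] + numeric)
        glms = {}
        for focal in cfg["glm"]["focals"]:
            g = models.fit_interaction_glm(modeled, focal=focal)
            glms[focal] = {
                "r_squared": g.r_squared_,
                "terms": g.terms_.reset_index().to_dict(orient="records"),
            }
        (out / "glm.json").write_text(json.dumps(glms, indent=2, default=float))
        manifest["outputs"]["glm"] = str(out / "glm.json")
        manifest["glm_r_squared"] = {k: v["r_squared"] for k, v in glms.items()}

    # ---- stage: path model ---------------------------------------------------
    with _stage("path_model"):
        sem = models.fit_path_model(modeled,
                                    standardize=cfg["sem"]["standardize"])
        result = {"full": _sem_dict(sem)}
        if cfg["sem"]["eliminate"]:
            reduced, trace = sem.backward_eliminate()
            eliminated = [t for t in trace["removed"] if t]
            if eliminated:
                manifest["decisions"].append(f"paths eliminated: {eliminated}")
            result["reduced"] = _sem_dict(reduced)
            result["aicc_trace"] = trace.to_dict(orient="records")
            final = reduced
        else:
            final = sem
        (out / "sem.json").write_text(json.dumps(result, indent=2, default=float))
        manifest["outputs"]["sem"] = str(out / "sem.json")
        manifest["sem_fit"] = final.fit_indices_.as_dict()
        manifest["sem_aicc"] = final.aicc_

    # ---- manifest (written atomically) ---------------------------------------
    tmp = out / "manifest.json.partial"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(out / "manifest.json")
    manifest["outputs"]["manifest"] = str(out / "manifest.json")
    return manifest


def _sem_dict(model) -> dict:
    return {
        "edges": model.edges_.to_dict(orient="records"),
        "fit": model.fit_indices_.as_dict(),
        "aicc": model.aicc_,
        "log_likelihood": model.log_likelihood_,
        "n": model.n_,
        "effects": model.effect_decomposition().to_dict(orient="records"),
        "mediator_coefficients": model.mediator_coefficients().to_dict(orient="records"),
    }
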