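"""One-command orchestration: simulate/ingest -> reconstruct -> metrics ->
decomposition -> covariate model.

Every stage writes tidy CSVs into the output directory and the run is
summarised in a JSON manifest holding the config hash, the seed, SHA-256
digests of inputs and outputs, and accumulated warnings (dropped cells,
fallback use).  Identical config + inputs + seed reproduce identical
digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from salmonsize import io as sio
from salmonsize import metrics
from salmonsize.allometry import fit_length_weight
from salmonsize.covariates import build_predictors, choose_competitor, screen_collinearity
from salmonsize.decompose import decompose, retrospective
from salmonsize.model_selection import partition_variance, select_model
from salmonsize.reconstruct import reconstruct
from salmonsize.simulate import TruthConfig, simulate_covariates, simulate_population

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, key: str, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    manifest.outputs[key] = {"path": str(path), "sha256": _sha256(path)}


def run_all(config: str | Path | dict, out_dir: str | Path = "out", seed: int | None = None) -> RunManifest:
    """Run the full analysis as configured; returns the run manifest.

    ``config`` may be a YAML path or a dict.  With an ``inputs`` section
    (paths to AL sample, brood and covariate CSVs) the pipeline analyses
    those files; otherwise it simulates a synthetic world from the
    ``simulate`` section (field overrides for the truth config).
    """
    cfg = sio.load_config(config) if not isinstance(config, dict) else {**sio.DEFAULT_CONFIG, **config}
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=seed)

    # -- stage 1: inputs ---------------------------------------------------
    try:
        if "inputs" in cfg:
            paths = cfg["inputs"]
            al = sio.read_al_samples(paths["al_samples"], cfg)
            brood = sio.read_brood_table(paths["brood_table"])
            covars = sio.read_covariates(paths["covariates"])
            for key in ("al_samples", "brood_table", "covariates"):
                manifest.inputs[key] = {"path": str(paths[key]), "sha256": _sha256(Path(paths[key]))}
        else:
            sim_cfg = dict(cfg.get("simulate", {}))
            sim_cfg.setdefault("seed", seed)
            truth = TruthConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim_cfg.items()})
            y0, y1 = truth.brood_years
            covars = simulate_covariates((y0, y1 + 8), seed=seed)
            world = simulate_population(truth, covars)
            al, brood = world["al_samples"], world["brood_table"]
            _write(al, out / "al_samples.csv", manifest, "al_samples")
            _write(brood, out / "brood_table.csv", manifest, "brood_table")
            _write(world["run_summary"], out / "run_summary.csv", manifest, "run_summary")
            _write(covars, out / "covariates.csv", manifest, "covariates")
            (out / "truth.json").write_text(json.dumps(world["truth"], indent=2, sort_keys=True))
            manifest.outputs["truth"] = {"path": str(out / "truth.json"), "sha256": _sha256(out / "truth.json")}
    except Exception as err:
        raise StageError("io_ingest", err) from err

    # -- stage 2: reconstruction ------------------------------------------
    try:
        recon = reconstruct(al, brood, cfg.get("river_districts"), seed=seed)
        _write(recon.data, out / "reconstruction.csv", manifest, "reconstruction")
        _write(recon.manifest, out / "coverage_manifest.csv", manifest, "coverage_manifest")
        dropped = recon.manifest[recon.manifest["status"] == "dropped"] if len(recon.manifest) else []
        if len(dropped):
            manifest.warnings.append(f"{len(dropped)} brood cells dropped for lack of AL samples")
    except Exception as err:
        raise StageError("reconstruction", err) from err

    # -- stage 3: size metrics --------------------------------------------
    try:
        mean_brood = metrics.mean_size(recon, "baywide", "brood")
        anom_brood = metrics.size_at_age_anomalies(recon, "baywide", "brood")
        anom_return = metrics.size_at_age_anomalies(recon, "baywide", "return")
        ages_tbl = metrics.mean_ages(recon, "baywide", "brood")
        seldiff = metrics.selection_differentials(recon, "baywide")
        _write(mean_brood.to_frame(), out / "mean_size.csv", manifest, "mean_size", index=True)
        _write(anom_brood, out / "anomalies_brood.csv", manifest, "anomalies_brood", index=True)
        _write(anom_return, out / "anomalies_return.csv", manifest, "anomalies_return", index=True)
        _write(ages_tbl, out / "mean_ages.csv", manifest, "mean_ages", index=True)
        _write(seldiff.to_frame(), out / "selection_differentials.csv", manifest, "selection", index=True)
        lw = None
        if al["mass_g"].notna().sum() >= 10:
            lw = fit_length_weight(al)
            manifest.outputs["length_weight"] = {"a": lw.a, "b": lw.b, "n": lw.n}
    except Exception as err:
        raise StageError("size_metrics", err) from err

    # -- stage 4: trend decomposition -------------------------------------
    try:
        w = int(cfg.get("window_years", 5))
        years = sorted(mean_brood.index)
        result = decompose(mean_brood, anom_brood["mean_anomaly_mm"], years[:w], years[-w:])
        dec = pd.DataFrame([{
            "scope": result.scope,
            "early": f"{result.early[0]}-{result.early[-1]}",
            "late": f"{result.late[0]}-{result.late[-1]}",
            "delta_mean_size_mm": result.delta_mean_size_mm,
            "delta_saa_mm": result.delta_saa_mm,
            "delta_age_structure_mm": result.delta_age_structure_mm,
        }])
        retro = retrospective(mean_brood, anom_brood["mean_anomaly_mm"], window=w)
        _write(dec, out / "decomposition.csv", manifest, "decomposition")
        _write(retro, out / "retrospective.csv", manifest, "retrospective", index=True)
    except Exception as err:
        raise StageError("trend_decomposition", err) from err

    # -- stage 5: covariate model ------------------------------------------
    try:
        pt = build_predictors(covars, anom_return["mean_anomaly_mm"], cfg, seldiff=seldiff)
        competitor = choose_competitor(pt)
        linear = [c for c in ["sockeye_run_z", competitor, "sst_winter_aleutians_z", "sst_summer_bering_lag1_z"] if c in pt.frame]
        exclusions = screen_collinearity(pt, threshold=float(cfg.get("collinearity_threshold", 0.5)), terms=linear)
        fit = select_model(pt, linear=linear, exclusions=exclusions)
        shares = partition_variance(fit)
        sel = pd.DataFrame({"term": ["(intercept)"] + list(fit.terms),
                            "coef": fit.params.to_numpy(), "se": fit.bse.to_numpy()})
        _write(sel, out / "model_selected.csv", manifest, "model_selected")
        _write(fit.candidates, out / "model_candidates.csv", manifest, "model_candidates")
        _write(shares.to_frame(), out / "variance_shares.csv", manifest, "variance_shares", index=True)
        manifest.outputs["model_summary"] = {"aic": fit.aic, "r2": fit.r2, "terms": list(fit.terms)}
    except Exception as err:
        raise StageError("covariate_model", err) from err

    manifest.to_json(out / "manifest.json")
    return manifest
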