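"""Pipeline orchestration: simulate, derive (fit), and test stages with
seeded, logged, file-based I/O.

Each stage reads/writes the standard CSV/TSV/JSON formats documented in
docs/schemas.md, validates input schemas up front (errors name the file and
column), and writes a manifest recording input hashes, seed and parameters
so identical manifests imply identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic, trajectory, survival as surv, proteomics
from .errors import ConfigurationError, EstimationError, SchemaError
from .harmonize import apply_recalibration, fit_recalibration

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_simulate", "run_derivation", "run_testing", "run_full"]

VISIT_COLUMNS = ["participant_id", "visit", "age_years", "lvef_pct", "ea_ratio"]
SURVIVAL_COLUMNS = ["participant_id", "time_years", "event"]
COVARIATE_COLUMNS = ["participant_id", "age_years", "male", "obesity",
                     "hypertension", "diabetes", "ckd", "chd", "af"]


def load_config(path) -> dict:
    """Read a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _require_columns(df: pd.DataFrame, columns, filename: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{filename}: missing column(s) {missing}")


def _read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise SchemaError(f"input file not found: {path}") from exc
    _require_columns(df, columns, str(path))
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list, seed, params: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1,
                                                              sort_keys=True))


def run_simulate(config: dict, outdir) -> dict:
    """Generate a synthetic cohort (+ proteome, GWAS pair) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    if seed is None:
        raise ConfigurationError("simulate requires a seed")
    style = config.get("style", "derivation")
    n = config.get("n_participants")
    maker = {"derivation": synthetic.derivation_config,
             "testing": synthetic.testing_config}.get(style)
    if maker is None:
        raise ConfigurationError(f"unknown simulate style {style!r}")
    kwargs = {"seed": int(seed)}
    if n is not None:
        kwargs["n_participants"] = int(n)
    cfg = maker(**kwargs)
    visits, covariates, survival, truth = synthetic.generate_cohort(cfg)
    visits.to_csv(outdir / "visits.csv", index=False)
    covariates.to_csv(outdir / "covariates.csv", index=False)
    survival.to_csv(outdir / "survival.csv", index=False)
    truth.to_json(outdir / "truth.json", orient="records", indent=1)

    outputs = {"visits": outdir / "visits.csv", "covariates": outdir / "covariates.csv",
               "survival": outdir / "survival.csv", "truth": outdir / "truth.json"}
    if config.get("proteome", False):
        pcfg = synthetic.ProteomeConfig(seed=int(seed) + 1,
                                        **config.get("proteome_params", {}))
        matrix, annotation, signal = synthetic.generate_proteome(truth, pcfg)
        matrix.to_csv(outdir / "proteins.tsv", sep="\t")
        annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        signal.to_json(outdir / "protein_truth.json", orient="records", indent=1)
        outputs["proteins"] = outdir / "proteins.tsv"
    if config.get("gwas", False):
        gcfg = synthetic.GwasSimConfig(seed=int(seed) + 2,
                                       **config.get("gwas_params", {}))
        exposure, outcome, effect = synthetic.generate_gwas_pair(gcfg)
        exposure.to_csv(outdir / "gwas_exposure.tsv", sep="\t", index=False)
        outcome.to_csv(outdir / "gwas_outcome.tsv", sep="\t", index=False)
        (outdir / "gwas_truth.json").write_text(json.dumps({"true_causal_effect": effect}))
    _write_manifest(outdir, "simulate", [], seed, {"style": style, "n": n})
    logger.info("simulate: wrote %d visit rows for %d participants",
                len(visits), len(truth))
    return {k: str(v) for k, v in outputs.items()}


def run_derivation(config: dict, outdir) -> trajectory.TrajectoryModel:
    """Recalibrate baseline measures, fit the trajectory mixture, report.

    Writes model.json, effective_groups.tsv, curves.tsv and (when a survival
    table is provided) composite HF-or-death Cox results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    visits = _read_csv(config["visits"], VISIT_COLUMNS)
    seed = int(config.get("seed", 0))
    params = config.get("fit", {})

    recal = config.get("recalibration")
    if recal:
        maps = {}
        baseline = visits["visit"] == visits["visit"].min()
        for measure, col in (("lvef", "lvef_pct"), ("ea", "ea_ratio")):
            ref = recal.get(measure)
            if not ref:
                continue
            m = fit_recalibration(visits.loc[baseline, col].to_numpy(),
                                  ref["mean"], ref["sd"], measure=measure)
            visits.loc[baseline, col] = apply_recalibration(
                m, visits.loc[baseline, col].to_numpy())
            maps[measure] = {"slope": m.slope, "intercept": m.intercept}
            logger.info("recalibration[%s]: slope %.4f intercept %.4f",
                        measure, m.slope, m.intercept)
        (outdir / "recalibration.json").write_text(json.dumps(maps, indent=1))

    basis = trajectory.AgeBasis(**params.get("basis", {}))
    model = trajectory.fit_trajectories(
        visits, basis=basis,
        k_max=int(params.get("k_max", 20)),
        restarts=int(params.get("restarts", 20)),
        seed=seed,
        concentration=float(params.get("concentration", 1.0)),
        max_iter=int(params.get("max_iter", 2000)),
    )
    trajectory.save_model(model, outdir / "model.json")

    order, mapping = trajectory.effective_groups(model,
                                                float(params.get("min_weight", 0.01)))
    eff = pd.DataFrame({
        "rank": [mapping[i] for i in order],
        "internal_index": order,
        "weight": [model.weights[i] for i in order],
    })
    eff.to_csv(outdir / "effective_groups.tsv", sep="\t", index=False)
    ages = np.arange(55.0, 90.1, 1.0)
    trajectory.trajectory_curves(model, ages).to_csv(outdir / "curves.tsv",
                                                     sep="\t", index=False)

    if config.get("survival"):
        survival_df = _read_csv(config["survival"], SURVIVAL_COLUMNS)
        covariates = _read_csv(config["covariates"], COVARIATE_COLUMNS) \
            if config.get("covariates") else None
        assignments = trajectory.assign_memberships(model, visits)
        merged = survival_df.merge(assignments[["participant_id", "map_group"]],
                                   on="participant_id")
        ds = surv.cause_specific_dataset(merged, "hf_or_death")
        if ds["event"].sum() == 0:
            logger.warning("derivation survival stage skipped: zero events")
        else:
            adj = None
            if covariates is not None:
                adj = covariates.set_index("participant_id").loc[
                    merged["participant_id"], ["age_years", "male"]].reset_index(drop=True)
            res = surv.fit_cox(ds, covariates=adj,
                               trajectory=merged["map_group"],
                               endpoint="hf_or_death", model_label="model1")
            res.table.to_csv(outdir / "cox_derivation.tsv", sep="\t")
    _write_manifest(outdir, "derivation", [config["visits"]], seed, params)
    logger.info("derivation: %d effective groups, best ELBO %.2f",
                len(order), model.fit_meta.get("elbo", np.nan))
    return model


def run_testing(config: dict, outdir) -> dict:
    """Assign single-visit participants, run survival and proteomic stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    model = trajectory.load_model(config["model"])
    visits = _read_csv(config["visits"], VISIT_COLUMNS)

    assignments = trajectory.assign_memberships(model, visits)
    order, mapping = trajectory.effective_groups(model)
    assignments["trajectory_rank"] = assignments["map_group"].map(
        lambda g: mapping.get(int(g), -1))
    assignments.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    results = {"assignments": str(outdir / "assignments.tsv")}
    reference = str(order[0]) if order else "0"

    if config.get("survival"):
        survival_df = _read_csv(config["survival"], SURVIVAL_COLUMNS)
        covariates = _read_csv(config["covariates"], COVARIATE_COLUMNS) \
            if config.get("covariates") else None
        merged = survival_df.merge(assignments[["participant_id", "map_group"]],
                                   on="participant_id")
        n_events = int((merged["event"] != "none").sum())
        if n_events == 0:
            logger.warning("survival stage skipped: zero events in %s",
                           config["survival"])
        else:
            tables = []
            for endpoint in ("any_hf", "hf_pef", "hf_ref"):
                ds = surv.cause_specific_dataset(merged, endpoint)
                if ds["event"].sum() == 0:
                    logger.warning("endpoint %s skipped: zero events", endpoint)
                    continue
                adj = None
                if covariates is not None:
                    cols = ["age_years", "male", "obesity", "hypertension",
                            "diabetes", "ckd", "chd", "af"]
                    adj = covariates.set_index("participant_id").loc[
                        merged["participant_id"], cols].reset_index(drop=True)
                try:
                    res = surv.fit_cox(ds, covariates=adj,
                                       trajectory=merged["map_group"],
                                       reference_group=reference, endpoint=endpoint,
                                       model_label="testing")
                except EstimationError as exc:
                    logger.warning("endpoint %s skipped: %s", endpoint, exc)
                    continue
                t = res.table.copy()
                t.insert(0, "endpoint", endpoint)
                t.insert(1, "n_events", res.n_events)
                tables.append(t)
                logger.info("survival[%s]: %d events", endpoint, res.n_events)
            if tables:
                pd.concat(tables).to_csv(outdir / "cox_testing.tsv", sep="\t")
                results["cox"] = str(outdir / "cox_testing.tsv")

    if config.get("proteins"):
        matrix = pd.read_csv(config["proteins"], sep="\t", index_col=0)
        covariates = _read_csv(config["covariates"], COVARIATE_COLUMNS)
        cov = covariates.set_index("participant_id").loc[
            matrix.index, ["age_years", "male"]].reset_index(drop=True)
        labels = assignments.set_index("participant_id").loc[
            matrix.index, "map_group"].astype(str)
        scan, significant = proteomics.scan_proteins(matrix, cov, labels, reference)
        scan.to_csv(outdir / "protein_scan.tsv", sep="\t", index=False)
        (outdir / "significant_proteins.json").write_text(json.dumps(
            {g: sorted(s) for g, s in significant.items()}, indent=1))
        results["protein_scan"] = str(outdir / "protein_scan.tsv")
        logger.info("proteomics: %d aptamers scanned", matrix.shape[1])

    inputs = [config[k] for k in ("model", "visits", "survival", "covariates", "proteins")
              if config.get(k)]
    _write_manifest(outdir, "testing", inputs, seed, {"reference": reference})
    return results


def run_full(config: dict, outdir) -> dict:
    """simulate -> fit -> simulate testing -> assign/survive in one call."""
    outdir = Path(outdir)
    seed = int(config.get("seed", 0))
    sim_dir = outdir / "derivation_data"
    sim = run_simulate({"seed": seed, "style": "derivation",
                        "n_participants": config.get("n_derivation", 747)}, sim_dir)
    model_dir = outdir / "model"
    run_derivation({"visits": sim["visits"], "survival": sim["survival"],
                    "covariates": sim["covariates"], "seed": seed,
                    "fit": config.get("fit", {})}, model_dir)
    test_dir = outdir / "testing_data"
    sim_t = run_simulate({"seed": seed + 1, "style": "testing",
                          "n_participants": config.get("n_testing", 4419)}, test_dir)
    out = run_testing({"model": str(model_dir / "model.json"),
                       "visits": sim_t["visits"], "survival": sim_t["survival"],
                       "covariates": sim_t["covariates"], "seed": seed + 2},
                      outdir / "testing_results")
    return out
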