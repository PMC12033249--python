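"""Configuration-driven orchestration of the full analysis.

Stage order mirrors the analysis narrative: simulate (or load) a cohort →
QC + imputation → clock → importance → acceleration GWAS (scan, signal
selection, conditional refinement, pQTL scan) → signal classification →
outcome/survival models → MR. Each enabled stage writes its TSV/JSON
artifact into the run directory; a manifest records the config hash, seed
and package version, and contains no timestamps so reruns with the same
config are byte-identical.

The single global seed fans out to per-stage seeds through a fixed named
sequence, so toggling one stage never shifts another stage's randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .assoc import burden_test, pqtl_scan, scan_variants, select_signals, conditional_refine
from .clock import (
    clock_metrics,
    cross_validated_predictions,
    fit_clock,
    fit_clock_sex_stratified,
    predict_and_accelerate,
)
from .importance import importance_table
from .mr import egger_estimate, harmonize, ivw_estimate
from .outcomes import fit_cox, km_estimate, outcome_regression, schoenfeld_ph_test, top_decile_groups
from .preprocess import impute_missing, qc_filter, qc_report
from .signalclass import classify_signals
from .synthgen import SimConfig, PlantedVariant, classification_scenario, simulate_cohort, simulate_mr_summary

__all__ = ["run_pipeline", "stage_seed", "default_config", "read_genotypes"]

logger = logging.getLogger(__name__)

read_genotypes = pio.read_genotypes  # re-exported: the pipeline owns external I/O

_STAGES = ("simulate", "preprocess", "clock", "importance", "assoc",
           "classify", "outcomes", "mr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage name."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def default_config(seed: int = 1) -> dict:
    """The bundled demo configuration: a synthetic cohort with two planted
    signals (one cis-pQTL, one widespread trans factor) among background
    variants, all stages enabled."""
    return {
        "seed": seed,
        "synth": {"scenario": "classification", "n_samples": 3000,
                  "n_proteins": 300, "n_variants": 500},
        "stages": {s: True for s in _STAGES},
        "clock": {"alpha": 0.5, "n_folds": 10},
        "thresholds": {"genome_wide_p": 5e-8, "min_maf": 0.001,
                       "max_missing": 0.10, "r2_max": 0.05},
        "mr": {"n_instruments": 50, "true_slope": 0.3,
               "pleiotropy_intercept": 0.02, "se_scale": 0.05},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build_sim_config(synth: dict, seed: int) -> SimConfig:
    synth = dict(synth)
    scenario = synth.pop("scenario", None)
    if scenario == "classification":
        return classification_scenario(
            seed,
            n_samples=synth.get("n_samples", 3000),
            n_proteins=synth.get("n_proteins", 300),
            n_variants=synth.get("n_variants", 20),
        )
    planted = tuple(
        PlantedVariant(**pv) for pv in synth.pop("planted_variants", [])
    )
    return SimConfig(**synth, planted_variants=planted, seed=seed)


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=pio.FLOAT_FMT, **kw)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the enabled stages and return the run directory.

    ``config`` is a dict or a YAML/JSON file path. Artifacts are TSV/JSON
    files named per stage; reruns with an identical config reproduce them
    byte for byte. A stage that needs an upstream artifact raises a
    dependency error when that stage was disabled.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    stages = {s: bool(cfg.get("stages", {}).get(s, True)) for s in _STAGES}
    thr = {"genome_wide_p": 5e-8, "min_maf": 0.001, "max_missing": 0.10,
           "r2_max": 0.05, **cfg.get("thresholds", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": [s for s, on in stages.items() if on],
        "artifacts": [],
    }

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return outdir / name

    cohort = genotypes = truth = None
    if stages["simulate"]:
        if "synth" not in cfg:
            raise ValueError("simulate stage enabled but no 'synth' config block")
        sim_cfg = _build_sim_config(cfg["synth"], stage_seed(seed, "simulate"))
        cohort, genotypes, truth = simulate_cohort(sim_cfg)
        pio.write_cohort(cohort, outdir)
        manifest["artifacts"] += ["cohort_proteins.tsv", "cohort_phenotypes.tsv"]
        pio.write_genotype_tsv(genotypes, emit("genotypes.tsv"))
        pio.write_truth_json(truth, emit("truth.json"))
    elif any(stages[s] for s in _STAGES[1:-1]):
        paths = cfg.get("inputs", {})
        needed = {"proteins", "phenotypes"}
        if not needed <= set(paths):
            raise FileNotFoundError(
                "downstream stages enabled without 'simulate'; provide "
                "inputs.proteins and inputs.phenotypes paths"
            )
        cohort = pio.read_cohort(paths["proteins"], paths["phenotypes"])
        if "genotypes" in paths:
            genotypes = pio.read_genotypes(paths["genotypes"])

    if stages["preprocess"]:
        if cohort is None:
            raise FileNotFoundError("preprocess needs a cohort (simulate stage or inputs)")
        cohort = impute_missing(
            qc_filter(cohort, thr["max_missing"], thr["max_missing"])
        )
        if genotypes is not None:
            genotypes = genotypes.subset_samples(cohort.sample_ids)
        (outdir / "qc_report.json").write_text(
            json.dumps(qc_report(cohort), indent=1, sort_keys=True)
        )
        manifest["artifacts"].append("qc_report.json")

    model = accel = prediction = None
    clock_kwargs = {}
    if stages["clock"]:
        if cohort is None:
            raise FileNotFoundError("clock stage needs a preprocessed cohort")
        ck = cfg.get("clock", {})
        clock_kwargs = {"alpha": ck.get("alpha", 0.5),
                        "n_folds": ck.get("n_folds", 10),
                        "seed": stage_seed(seed, "clock")}
        if ck.get("sex_stratified", False):
            # disjoint per-sex clocks; their predictions tile the cohort
            from .clock import AgePrediction

            models = fit_clock_sex_stratified(cohort, **clock_kwargs)
            pred = np.full(cohort.n_samples, np.nan)
            for stratum, m in models.items():
                rows = (cohort.phenotypes["sex"] == stratum).to_numpy()
                pred[rows] = m.predict(cohort.proteins.loc[rows])
                m.to_json(emit(f"clock_model_{stratum}.json"))
            chron = cohort.phenotypes["age"].to_numpy(dtype=float)
            prediction = AgePrediction(cohort.sample_ids, pred, chron, pred - chron)
            model = models["female"]  # representative for importance stage
        else:
            model = fit_clock(cohort, **clock_kwargs)
            prediction = predict_and_accelerate(model, cohort)
            model.to_json(emit("clock_model.json"))
        accel = prediction.acceleration
        _tsv(prediction.to_frame(), emit("predictions.tsv"))
        metrics = {"in_sample": clock_metrics(prediction)}
        if not ck.get("sex_stratified", False):
            cv_pred = cross_validated_predictions(cohort, model)
            metrics["cross_validated"] = clock_metrics(cv_pred)
        (emit("clock_metrics.json")).write_text(
            json.dumps(metrics, indent=1, sort_keys=True)
        )

    if stages["importance"]:
        if model is None:
            raise FileNotFoundError("importance stage needs a fitted clock")
        table = importance_table(
            model, cohort.proteins, seed=stage_seed(seed, "importance")
        )
        _tsv(table, emit("importance.tsv"), index=False)

    signals, pqtl_sets, covariates = [], {}, None
    if stages["assoc"]:
        if accel is None or genotypes is None:
            raise FileNotFoundError("assoc stage needs acceleration and genotypes")
        covariates = (cohort.phenotypes["sex"] == "male").astype(float).to_frame("sex_male")
        assoc = scan_variants(genotypes, accel, covariates, min_maf=thr["min_maf"])
        pio.write_sumstats_tsv(assoc, emit("gwas_sumstats.tsv"))
        signals = select_signals(assoc, threshold=thr["genome_wide_p"])
        signals = conditional_refine(
            genotypes, accel, covariates, signals, assoc=assoc,
            r2_max=thr["r2_max"], threshold=thr["genome_wide_p"],
        )
        sig_rows = [
            {"id": s.variant_id, "chrom": s.chrom, "pos": s.pos, "rank": s.rank,
             "beta": s.beta, "se": s.se, "p": s.p,
             "n_secondaries": len(s.secondaries)}
            for s in signals
        ]
        _tsv(pd.DataFrame(sig_rows,
                          columns=["id", "chrom", "pos", "rank", "beta", "se",
                                   "p", "n_secondaries"]),
             emit("signals.tsv"), index=False)
        pqtl_sets = pqtl_scan(
            genotypes, [s.variant_id for s in signals], cohort.proteins, covariates
        )
        pq_rows = [
            {"signal": vid, "protein_id": r.protein_id, "beta": r.beta,
             "se": r.se, "p": r.p}
            for vid, ps in pqtl_sets.items()
            for r in ps.table.itertuples(index=False)
        ]
        _tsv(pd.DataFrame(pq_rows,
                          columns=["signal", "protein_id", "beta", "se", "p"]),
             emit("pqtls.tsv"), index=False)
        carriers_path = cfg.get("inputs", {}).get("carriers")
        if carriers_path:
            carriers = pio.read_carrier_sets_tsv(carriers_path)
            accel_series = pd.Series(accel, index=cohort.sample_ids)
            _tsv(burden_test(carriers, accel_series, covariates),
                 emit("burden_tests.tsv"), index=False)

    if stages["classify"]:
        if not stages["assoc"]:
            raise FileNotFoundError("classify stage needs the assoc stage")
        report = classify_signals(
            signals, pqtl_sets, cohort, genotypes,
            covariates=covariates, clock_kwargs=clock_kwargs,
            threshold=thr["genome_wide_p"],
        )
        for row in report.to_dict("records"):
            (outdir / f"classification_{row['signal_id']}.json").write_text(
                json.dumps(row, indent=1, sort_keys=True, default=list)
            )
            manifest["artifacts"].append(f"classification_{row['signal_id']}.json")
        report["excluded_proteins"] = report["excluded_proteins"].map(
            lambda xs: ",".join(xs)
        )
        _tsv(report, emit("signal_classification.tsv"), index=False)

    if stages["outcomes"]:
        if prediction is None:
            raise FileNotFoundError("outcomes stage needs clock predictions")
        ph = cohort.phenotypes
        tables = []
        for name, fam in (("disease", "binary"), ("cont_outcome", "continuous")):
            tab = outcome_regression(
                ph[name], prediction.predicted_age, ph["age"], ph["sex"], family=fam
            )
            tab.insert(0, "outcome", name)
            tables.append(tab.reset_index(names="term"))
        _tsv(pd.concat(tables, ignore_index=True),
             emit("outcome_regressions.tsv"), index=False)

        cov = pd.DataFrame({
            "predicted_age": prediction.predicted_age,
            "age_at_recruitment": ph["age"].to_numpy(),
            "sex_male": (ph["sex"] == "male").astype(float).to_numpy(),
        })
        fit = fit_cox(ph["survival_time"], ph["event"], cov)
        _tsv(fit.table, emit("cox_mortality.tsv"))
        _tsv(schoenfeld_ph_test(fit), emit("cox_ph_test.tsv"))
        groups = top_decile_groups(prediction.predicted_age, ph["age"])
        km, logrank_p = km_estimate(ph["survival_time"], ph["event"], groups)
        _tsv(km, emit("km_curves.tsv"), index=False)
        manifest["km_logrank_p"] = logrank_p

    if stages["mr"]:
        mcfg = cfg.get("mr", {})
        if "input" in mcfg:
            mr_input = pio.read_mr_tsv(mcfg["input"])
        else:
            mr_input, _ = simulate_mr_summary(
                n_instruments=mcfg.get("n_instruments", 50),
                true_slope=mcfg.get("true_slope", 0.3),
                pleiotropy_intercept=mcfg.get("pleiotropy_intercept", 0.0),
                se_scale=mcfg.get("se_scale", 0.05),
                seed=stage_seed(seed, "mr"),
            )
        harmonised = harmonize(mr_input)
        results = pd.DataFrame(
            [ivw_estimate(harmonised).to_row(), egger_estimate(harmonised).to_row()]
        )
        _tsv(mr_input, emit("mr_instruments.tsv"), index=False)
        _tsv(results, emit("mr_results.tsv"), index=False)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    logger.info("pipeline complete: %s (%d artifacts)", outdir, len(manifest["artifacts"]))
    return outdir
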