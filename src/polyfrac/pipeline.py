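"""End-to-end study pipeline: generate -> cohort -> derive -> fit -> evaluate.

One :class:`~polyfrac.config.StudyConfig` and one master seed drive every
stage; stage seeds are derived from the master seed by fixed labels, so the
run is reproducible end to end and rerunning with the same config yields a
byte-identical report payload.  Intermediate artifacts are persisted as
CSV/JSON when an output directory is configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categories import default_maps
from .cohort import build_cohort
from .config import StudyConfig, stage_seed
from .evaluate import (
    external_validation,
    medcount_forest,
    nested_model_comparison,
    roc_auc,
    score_subjects,
    stepwise_logistic,
    youden_cutoff,
)
from .exposure import build_design, derive_covariates, descriptive_table
from .model import ConditionalLogisticLasso, pair_difference
from .synth import generate_study_data, write_claims

log = logging.getLogger("polyfrac")


def _jsonable(obj):
    """Recursively convert numpy/pandas payloads to plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.datetime64, pd.Timestamp)):
        return str(np.datetime64(obj, "D"))
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(config: StudyConfig) -> str:
    doc = repr(config).encode()
    return hashlib.sha256(doc).hexdigest()[:16]


@dataclass
class StudyReport:
    """All study outputs plus the provenance block."""

    provenance: dict
    counts: dict
    table1: pd.DataFrame
    fits: dict  # stratum -> {lambda, odds_ratios of selected variables, ...}
    nested: pd.DataFrame
    forest: pd.DataFrame
    stepwise: dict | None
    external: dict | None

    def to_payload(self) -> dict:
        return _jsonable(
            {
                "provenance": self.provenance,
                "counts": self.counts,
                "table1": self.table1,
                "fits": self.fits,
                "nested_comparison": self.nested,
                "forest": self.forest,
                "stepwise": self.stepwise,
                "external_validation": self.external,
            }
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_payload(), indent=2, sort_keys=True, **kwargs)


def _fit_stratum(dataset, stratum, config: StudyConfig):
    ds = dataset.filter(stratum)
    if ds.n_pairs < max(2, config.cv_folds):
        return None, None, f"too few pairs in stratum {stratum!r} ({ds.n_pairs})"
    Dm = pair_difference(ds)
    est = ConditionalLogisticLasso(
        lam="cv",
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        cv=config.cv_folds,
        rule=config.lambda_rule,
        tol=1e-6,
        random_state=stage_seed(config.seed, f"fit:{stratum}"),
    )
    est.fit(Dm)
    fit = est.result()
    scored = score_subjects(fit, ds)
    roc = roc_auc(scored["score"], scored["label"])
    mk = youden_cutoff(roc)
    summary = {
        "n_pairs": ds.n_pairs,
        "lambda": est.lambda_,
        "lambda_max": est.lambda_max_,
        "n_selected": len(fit.selected),
        "odds_ratios": {
            dataset.labels.get(n, n): float(np.exp(b))
            for n, b in zip(fit.names, fit.beta)
            if np.isfinite(b) and b != 0.0
        },
        "auc": roc.auc,
        "auc_ci": [roc.ci_low, roc.ci_high],
        "youden_cutoff": mk.cutoff,
        "sensitivity": mk.sensitivity,
        "specificity": mk.specificity,
        "ppv": mk.ppv,
        "npv": mk.npv,
    }
    return est, summary, None


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage in order and assemble the study report."""
    maps = default_maps()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: synthetic claims ---------------------------------------
    log.info("generate: %d patients", config.population.n_patients)
    data = generate_study_data(config.population)
    if out:
        write_claims(data, out)
    if data.patients.empty:
        raise ValueError("run_study failed at stage 'generate': empty population")

    # -- stage 2: cohort --------------------------------------------------
    cohort = build_cohort(
        data.patients,
        data.diagnoses,
        window=config.window,
        band_width=config.band_width,
        seed=config.seed,
        control_exclusion=config.control_exclusion,
    )
    cohort_frame = cohort.to_frame()
    log.info(
        "cohort: %d pairs, %d unmatched cases", cohort.n_pairs, len(cohort.selection_log)
    )
    if out:
        cohort_frame.to_csv(out / "cohort.csv", index=False)
    if cohort.n_pairs == 0:
        raise ValueError("run_study failed at stage 'cohort': no matched pairs")

    # -- stage 3: exposure derivation ------------------------------------
    covariates = derive_covariates(
        cohort_frame,
        data.diagnoses,
        data.prescriptions,
        maps,
        grace_days=config.grace_days,
        count_window=config.count_window,
    )
    dataset = build_design(cohort_frame, covariates, maps)
    table1 = descriptive_table(dataset)
    log.info("derive: %d subjects x %d covariates", len(dataset.data), len(dataset.variables))
    if out:
        dataset.data.to_csv(out / "design.csv", index=False)
        table1.to_csv(out / "table1.csv", index=False)

    # -- stage 4: penalized fits per stratum ------------------------------
    fits, estimators = {}, {}
    for st in config.strata:
        est, summary, err = _fit_stratum(dataset, st, config)
        if err:
            log.warning("fit[%s]: %s", st, err)
            fits[st] = {"error": err}
            continue
        fits[st] = summary
        estimators[st] = est
        log.info("fit[%s]: lambda=%.4g, %d selected", st, est.lambda_, summary["n_selected"])
    if out and "all" in estimators:
        path = estimators["all"].path_
        path_df = pd.DataFrame(path.coefficients, columns=path.names)
        path_df.insert(0, "lambda", path.lambdas)
        path_df.insert(1, "deviance", path.deviance)
        path_df.to_csv(out / "path.csv", index=False)
        with open(out / "fit.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(fits), fh, indent=2, sort_keys=True)

    # -- stage 5: evaluation ----------------------------------------------
    nested = nested_model_comparison(
        dataset,
        seed=stage_seed(config.seed, "nested"),
        strata=config.strata,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        cv=config.cv_folds,
        rule=config.lambda_rule,
    )
    forest = medcount_forest(dataset, strata=config.strata)
    if out:
        nested.to_csv(out / "metrics.csv", index=False)
        forest.to_csv(out / "forest.csv", index=False)

    stepwise = None
    if config.run_stepwise:
        sw = stepwise_logistic(dataset)
        stepwise = {
            "selected": [dataset.labels.get(v, v) for v in sw.selected],
            "n_selected": len(sw.selected),
            "aic": sw.aic,
            "auc": sw.auc,
        }

    external = None
    if config.validation_window is not None and "all" in estimators:
        vpop = replace(
            config.population,
            study_window=config.validation_window,
            n_patients=config.validation_n_patients or config.population.n_patients,
            seed=stage_seed(config.seed, "validation"),
        )
        vdata = generate_study_data(vpop)
        vcohort = build_cohort(
            vdata.patients,
            vdata.diagnoses,
            window=config.validation_window,
            band_width=config.band_width,
            seed=stage_seed(config.seed, "validation-cohort"),
            control_exclusion=config.control_exclusion,
        )
        vframe = vcohort.to_frame()
        if vcohort.n_pairs > 0:
            vcov = derive_covariates(
                vframe,
                vdata.diagnoses,
                vdata.prescriptions,
                maps,
                grace_days=config.grace_days,
                count_window=config.count_window,
            )
            vdataset = build_design(vframe, vcov, maps)
            roc = external_validation(estimators["all"].result(), vdataset)
            external = {
                "n_pairs": vcohort.n_pairs,
                "auc": roc.auc,
                "auc_ci": [roc.ci_low, roc.ci_high],
            }
        else:
            external = {"n_pairs": 0, "auc": None, "auc_ci": None}

    strata_counts = dataset.strata.value_counts().to_dict()
    report = StudyReport(
        provenance={
            "config_hash": config_hash(config),
            "seed": config.seed,
            "package_version": __version__,
        },
        counts={
            "patients": len(data.patients),
            "cases_selected": int(
                cohort.n_pairs + len(cohort.selection_log)
            ),
            "pairs": cohort.n_pairs,
            "unmatched_cases": len(cohort.selection_log),
            "subjects": 2 * cohort.n_pairs,
            "early_pairs": int(strata_counts.get("early", 0)),
            "late_pairs": int(strata_counts.get("late", 0)),
        },
        table1=table1,
        fits=fits,
        nested=nested,
        forest=forest,
        stepwise=stepwise,
        external=external,
    )
    if out:
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            fh.write(report.to_json())
    return report
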