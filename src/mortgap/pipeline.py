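"""End-to-end pipeline: simulate (optional) -> QC -> fit per cause -> float ->
mediate -> project, driven by a YAML run configuration."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._vocab import CAUSE_GROUPS, EDUCATION_REFERENCE
from .config import DEFAULT_EDUCATION_PROBS, config_digest, study_cohort_config
from .cox import StratifiedCoxModel
from .io import read_cohort, read_life_table, write_cohort, write_results
from .lexis import lexis_split, prepare_cause
from .mediation import DEFAULT_MEDIATORS, mediation_analysis
from .projection import EducationProjection, synthetic_national_life_table
from .qc import apply_exclusions, derive_categories
from .simulate import generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (see ``configs/demo.yaml``)."""

    seed: int = 0
    output_dir: str = "out"
    cohort_path: str | None = None           # read a cohort instead of simulating
    life_table_path: str | None = None       # default: synthetic stand-in table
    simulate_n: int = 20_000
    simulate_effects: str = "default"
    exposure: str = "education"
    reference: str | None = None
    causes: tuple[str, ...] = ("all",)
    age_min: float = 35.0
    age_max: float = 75.0
    sex_filter: str | None = None
    adjustment: tuple[str, ...] = ()
    mediators: tuple[str, ...] = DEFAULT_MEDIATORS
    contrast: tuple[str, str] = ("none", EDUCATION_REFERENCE)
    projection_start: float = 35.0
    projection_end: float = 70.0
    run_mediation: bool = True
    run_projection: bool = True

    def __post_init__(self) -> None:
        for cause in self.causes:
            if cause not in CAUSE_GROUPS:
                known = ", ".join(sorted(CAUSE_GROUPS))
                raise ValueError(f"unknown cause group {cause!r}; known: {known}")
        if not (35.0 <= self.age_min < self.age_max <= 85.0):
            raise ValueError("age range must satisfy 35 <= age_min < age_max <= 85")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        for key in ("causes", "adjustment", "mediators", "contrast"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, outdir: str | None = None) -> dict:
    """Execute every stage and write artifacts; returns them in memory too."""
    outdir = Path(outdir or config.output_dir)
    digest = config_digest(config)
    artifacts: dict[str, object] = {}

    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
        log.info("read cohort of %d from %s", len(cohort), config.cohort_path)
    else:
        cc = study_cohort_config(config.simulate_n, seed=config.seed,
                                 effects=config.simulate_effects)
        cohort = generate_cohort(cc)
        log.info("simulated cohort of %d (seed %d)", len(cohort), config.seed)

    kept, ledger = apply_exclusions(cohort)
    log.info("exclusions: %s -> %d retained", ledger.counts, ledger.total_out)
    derived = derive_categories(kept)
    artifacts["exclusion_ledger"] = ledger.to_frame()

    records = lexis_split(derived, age_min=config.age_min, age_max=config.age_max)
    if config.sex_filter:
        records = records[records["sex"] == config.sex_filter].reset_index(drop=True)

    rr_frames = []
    fit_summaries = {}
    results_by_cause = {}
    for cause in config.causes:
        cause_records = prepare_cause(records, cause)
        res = StratifiedCoxModel(
            cause_records, exposure=config.exposure, reference=config.reference,
            adjust=config.adjustment).fit()
        results_by_cause[cause] = res
        fv = res.floated_variances()
        tab = res.rr_table()
        tab.insert(0, "cause", cause)
        rr_frames.append(tab)
        fit_summaries[cause] = {
            "loglik": res.loglik, "lr_chi2": res.lr_chi2,
            "n_events": res.n_events, "n_records": res.n_records,
            "iterations": res.iterations, "converged": res.converged,
            "params": res.params.to_dict(),
            "cov": res.cov.to_numpy().tolist(),
            "floated": fv.to_dict(),
        }
        log.info("fit %s: %d events, %d iterations, floated distortion %.3g",
                 cause, res.n_events, res.iterations, fv.max_contrast_distortion)
    import pandas as pd
    artifacts["rate_ratios"] = pd.concat(rr_frames, ignore_index=True)
    artifacts["fits"] = fit_summaries

    if config.run_mediation:
        med = mediation_analysis(prepare_cause(records, config.causes[0]),
                                 exposure=config.exposure,
                                 mediators=config.mediators,
                                 contrast=tuple(config.contrast))
        artifacts["mediation"] = med.to_dict()
        log.info("mediation: %.1f%% of LR chi2 explained", med.prop_chi2_explained)

    if config.run_projection:
        lt = (read_life_table(config.life_table_path) if config.life_table_path
              else synthetic_national_life_table(config.projection_start,
                                                 config.projection_end))
        all_cause = results_by_cause.get("all")
        if all_cause is not None and config.exposure == "education":
            rr_vec = np.exp(all_cause.exposure_log_rr().to_numpy())
            rr_by_sex = {"male": rr_vec, "female": rr_vec}
        else:
            rr_by_sex = {"male": np.ones(5), "female": np.ones(5)}
        proj = EducationProjection(
            lt, rr_by_sex, prevalences_by_sex=DEFAULT_EDUCATION_PROBS,
            start=config.projection_start, end=config.projection_end).run()
        artifacts["projection_rates"] = proj.rates
        artifacts["projection_survival"] = proj.survival
        artifacts["projection_life_expectancy"] = proj.life_expectancy

    paths = write_results(outdir, artifacts,
                          manifest={"config_digest": digest, "seed": config.seed})
    if not config.cohort_path:
        write_cohort(cohort, outdir / "cohort.csv")
    return {"artifacts": artifacts, "paths": paths, "ledger": ledger,
            "results_by_cause": results_by_cause, "config_digest": digest}
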