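"""File formats and the end-to-end pipeline.

Trial data live in a long-format count CSV, one row per (subject, condition):

    subject_id,modality,pairing,auditory_snr,visual_snr,soa,n_B,n_D,n_G

Condition fields use the enumerated design vocabulary, with ``n/a`` marking
fields that do not apply (e.g. the SOA of a unimodal condition).  The count
format is what the multinomial likelihood needs; a converter from
trial-by-trial files (one row per presentation with a response column) is
provided for archive-style data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _params
from .design import Condition, Design, enumerate_design
from .evaluation import ComparisonTable, compare_models, extract_auditory_weights
from .fitting import FitConfig, cross_validate, fit_model
from .synthetic import CohortSpec, SubjectData, default_group_params, simulate_cohort

__all__ = [
    "TrialFormatError",
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "aggregate_trial_rows",
    "load_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = (
    "subject_id",
    "modality",
    "pairing",
    "auditory_snr",
    "visual_snr",
    "soa",
    "n_B",
    "n_D",
    "n_G",
)

_CONDITION_FIELDS = ("modality", "pairing", "auditory_snr", "visual_snr", "soa")


class TrialFormatError(ValueError):
    """The trial CSV violates the documented schema."""


def _condition_from_row(row: pd.Series, line: int) -> Condition:
    try:
        return Condition(**{f: str(row[f]) for f in _CONDITION_FIELDS})
    except ValueError as exc:
        raise TrialFormatError(f"row {line}: {exc}") from exc


def read_trials(path, expected_reps: int | None = 25) -> list[SubjectData]:
    """Read a long-format count CSV into per-subject data.

    Rows whose counts do not sum to ``expected_reps`` are accepted with a
    warning (real data sets may have dropped trials); duplicate
    (subject, condition) rows, negative counts and unknown condition labels
    are rejected with the offending row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty trial file, returning an empty cohort")
        return []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"missing columns: {missing}")

    cohort: dict[str, dict[Condition, tuple[int, int, int]]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after the header
        cond = _condition_from_row(row, line)
        try:
            counts = tuple(int(row[c]) for c in ("n_B", "n_D", "n_G"))
        except ValueError as exc:
            raise TrialFormatError(f"row {line}: counts must be integers") from exc
        if any(c < 0 for c in counts):
            raise TrialFormatError(f"row {line}: negative count in {counts}")
        per_subject = cohort.setdefault(str(row["subject_id"]), {})
        if cond in per_subject:
            raise TrialFormatError(f"row {line}: duplicate condition for subject {row['subject_id']}")
        if expected_reps is not None and sum(counts) != expected_reps:
            warnings.warn(
                f"{path} row {line}: counts sum to {sum(counts)}, expected {expected_reps} "
                "(dropped trials?)"
            )
        per_subject[cond] = counts
    if not cohort:
        warnings.warn(f"{path}: no data rows, returning an empty cohort")
    return [SubjectData(subject_id=sid, counts=conds) for sid, conds in cohort.items()]


def write_trials(cohort: Sequence[SubjectData], path, design: Design | None = None) -> None:
    """Write a cohort to the count CSV with deterministic row ordering
    (subjects in given order, conditions in canonical design order)."""
    if design is None:
        design = enumerate_design()
    rows = []
    for subject in cohort:
        for cond in design.conditions:
            if cond not in subject.counts:
                continue
            n_b, n_d, n_g = subject.counts[cond]
            rows.append((subject.subject_id, *cond.astuple(), n_b, n_d, n_g))
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def aggregate_trial_rows(
    df: pd.DataFrame,
    response_column: str = "response",
    subject_column: str = "subject_id",
    condition_columns: Mapping[str, str] | None = None,
) -> list[SubjectData]:
    """Convert trial-by-trial rows (one presentation per row) to count data.

    ``condition_columns`` maps the five canonical condition field names to
    the column names used in the input (identity by default), so archive
    files with different headers can be adapted without rewriting them.
    Responses must be 'B', 'D' or 'G'.
    """
    colmap = dict(condition_columns or {})
    cohort: dict[str, dict[Condition, list[int]]] = {}
    for idx, row in df.iterrows():
        cond = Condition(**{f: str(row[colmap.get(f, f)]) for f in _CONDITION_FIELDS})
        response = str(row[response_column])
        if response not in ("B", "D", "G"):
            raise TrialFormatError(f"row {idx}: unknown response {response!r}")
        counts = cohort.setdefault(str(row[subject_column]), {}).setdefault(cond, [0, 0, 0])
        counts["BDG".index(response)] += 1
    return [
        SubjectData(subject_id=sid, counts={c: tuple(v) for c, v in conds.items()})
        for sid, conds in cohort.items()
    ]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "input": None,  # path to a count CSV; None = simulate
    "simulate": {"n_subjects": 16, "n_reps": 25, "variant": "ReducedJP", "between_subject_sd": 0.25},
    "variants": ["MLE", "ReducedJP", "ReducedBCI"],
    "profile": "test",
    "lambda_reg": 7.0,
    "restarts": None,  # None = profile default
    "seed": 0,
    "outdir": "avbind_run",
}


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration, filling in defaults."""
    text = Path(path).read_text()
    loaded = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (loaded or {}).items():
        if key == "simulate" and isinstance(value, dict):
            config["simulate"].update(value)
        else:
            config[key] = value
    return config


def _fit_config(config: dict) -> FitConfig:
    overrides = {"lambda_reg": float(config["lambda_reg"]), "seed": int(config["seed"])}
    if config.get("restarts") is not None:
        overrides["n_restarts"] = int(config["restarts"])
    return FitConfig.profile(config.get("profile", "test"), **overrides)


def _params_record(params) -> dict:
    return {
        "variant": params.variant,
        "likelihood": {
            "mu_A_B": params.likelihood.mu_A_B,
            "mu_A_G": params.likelihood.mu_A_G,
            "mu_V_B": params.likelihood.mu_V_B,
            "mu_V_G": params.likelihood.mu_V_G,
            "sigma2_A": dict(params.likelihood.sigma2_A),
            "sigma2_V": dict(params.likelihood.sigma2_V),
        },
        "prior": dataclasses.asdict(params.prior),
        "response_map": dataclasses.asdict(params.response_map),
    }


def run_pipeline(config: dict) -> dict:
    """Run simulate/load -> fit -> cross-validate -> compare end to end.

    Outputs (resolved config, trial data, comparison and weight tables, JSON
    summary) are written under ``config['outdir']``.  Per-(subject, variant)
    failures are recorded and skipped rather than aborting the run; the
    comparison table is built from the subjects with complete results.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    fit_config = _fit_config(config)
    design = enumerate_design(int(config.get("simulate", {}).get("n_reps", 25)))
    logger.info(
        "run: seed=%s lambda=%s restarts=%s variants=%s",
        fit_config.seed, fit_config.lambda_reg, fit_config.n_restarts, config["variants"],
    )

    if config.get("input"):
        cohort = read_trials(config["input"], expected_reps=None)
        truths = None
    else:
        sim = config["simulate"]
        spec = CohortSpec(
            n_subjects=int(sim["n_subjects"]),
            group_params=default_group_params(sim.get("variant", "ReducedJP")),
            between_subject_sd=float(sim.get("between_subject_sd", 0.25)),
            seed=int(config["seed"]),
        )
        cohort, truths = simulate_cohort(spec, design)
        write_trials(cohort, outdir / "trials.csv", design)
        (outdir / "true_params.json").write_text(
            json.dumps([_params_record(p) for p in truths], indent=2)
        )

    cvs = {}
    fits = {}
    failures = []
    for subject in cohort:
        for variant in config["variants"]:
            try:
                fits[(subject.subject_id, variant)] = fit_model(subject, variant, design, fit_config)
                cvs[(subject.subject_id, variant)] = cross_validate(subject, variant, design, fit_config)
            except Exception as exc:  # noqa: BLE001 - partial failures are reported, not fatal
                logger.error("fit failed for %s/%s: %s", subject.subject_id, variant, exc)
                failures.append({"subject": subject.subject_id, "variant": variant, "error": str(exc)})

    complete_subjects = [
        s.subject_id
        for s in cohort
        if all((s.subject_id, v) in cvs for v in config["variants"])
    ]
    comparison: ComparisonTable | None = None
    if complete_subjects:
        comparison = compare_models(
            {(s, v): cvs[(s, v)] for s in complete_subjects for v in config["variants"]}
        )
        comparison.rmse.to_csv(outdir / "cv_rmse.csv")
        comparison.improvement.to_csv(outdir / "improvement.csv", index=False)
        comparison.tests.to_csv(outdir / "tests.csv", index=False)

    jp_variants = [v for v in config["variants"] if v in ("MLE", "ReducedJP", "FullJP")]
    if jp_variants:
        weight_variant = next((v for v in ("ReducedJP", "FullJP", "MLE") if v in jp_variants))
        weights = []
        for subject_id in complete_subjects:
            wt = extract_auditory_weights(fits[(subject_id, weight_variant)], design).table
            wt.insert(0, "subject_id", subject_id)
            weights.append(wt)
        if weights:
            pd.concat(weights, ignore_index=True).to_csv(outdir / "auditory_weights.csv", index=False)

    report = {
        "config": {**config, "resolved_fit_config": dataclasses.asdict(fit_config)},
        "n_subjects": len(cohort),
        "n_conditions": len(design.conditions),
        "failures": failures,
        "cv_rmse": {f"{s}/{v}": cvs[(s, v)].rmse for (s, v) in cvs},
        "fitted_params": {f"{s}/{v}": _params_record(fits[(s, v)].params) for (s, v) in fits},
    }
    (outdir / "summary.json").write_text(json.dumps(report, indent=2))
    return report
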