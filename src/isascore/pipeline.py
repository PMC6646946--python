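"""End-to-end orchestration: score -> analyze -> evaluate.

Runs one or more experiments (trial files or named synthetic fixtures)
through per-cell scoring, the within-subject multivariate ANOVA over all six
measures, and the signal-detection evaluation, writing delimited reports and
a JSON run manifest into an output directory:

``scores.csv``            one row per experiment x subject x cell
``effects.csv``           one row per experiment x effect x measure
``detection_labels.csv``  per-effect hit/miss/FA/CR labels per ISA measure
``detection_summary.csv`` per-experiment rows + Total: N effects, large,
                          small, and corrected H / FA / d' per ISA measure
``correlations.csv``      ISA-vs-component correlations (pooled effects)
``category_means.csv``    category-wise mean effect sizes (RCS and RCS-c)
``manifest.json``         versions, seed, parameter echo
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import (
    DEFAULT_MEASURES,
    DesignSpec,
    infer_design,
    load_design,
    run_design_anova,
)
from .detection import (
    ISA_MEASURES,
    category_effect_comparison,
    classify_effects,
    correlation_analysis,
    criterion_eta,
    detection_counts,
    dprime,
)
from .scoring import REQUIRED_COLUMNS, score_experiment
from .simulate import fixture_names, generate_experiment, make_fixture

log = logging.getLogger("isascore")

__all__ = ["RunConfig", "run_pipeline", "validate_trials", "load_trials"]


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run.

    ``experiments`` maps an experiment id either to a trial-file path or to
    a synthetic fixture name (resolved against :func:`fixture_names`).
    """

    experiments: dict[str, str]
    out_dir: str | Path = "isascore_out"
    design_path: str | Path | None = None
    alpha: float = 0.05
    correction: str = "loglinear"
    strict: bool = False
    seed: int = 0
    measures: tuple[str, ...] = DEFAULT_MEASURES
    isa_measures: tuple[str, ...] = ISA_MEASURES
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a delimited long-format trial file (comma or tab separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def validate_trials(source) -> list[dict]:
    """Structural validation of a trial table; returns a machine-readable
    issue list (empty when well-formed).

    Checks required columns, RT positivity/finiteness, the 0/1 accuracy
    domain, key uniqueness and subject x cell completeness. Row numbers are
    0-based positions in the file body.
    """
    if isinstance(source, (str, Path)):
        try:
            df = pd.read_csv(source, sep=None, engine="python")
        except OSError as exc:
            raise IOError(f"cannot read {source}: {exc}") from exc
    else:
        df = source
    issues: list[dict] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    for col in missing:
        issues.append({"issue": "missing_column", "column": col})
    if missing:
        return issues
    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad_rt = df.index[~np.isfinite(rt) | (rt <= 0)]
    for i in bad_rt:
        issues.append({"issue": "invalid_rt", "row": int(i), "value": df.at[i, "rt"]})
    acc = df["acc"]
    bad_acc = df.index[~acc.isin([0, 1])]
    for i in bad_acc:
        issues.append({"issue": "invalid_acc", "row": int(i), "value": df.at[i, "acc"]})
    dup = df.index[df.duplicated(["subject", "block", "trial"])]
    for i in dup:
        issues.append({"issue": "duplicate_trial_key", "row": int(i)})
    factors = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if factors and not len(bad_rt) and not len(bad_acc):
        counts = df.groupby(["subject", *factors], observed=True).size()
        full = pd.MultiIndex.from_product(
            [df["subject"].unique(), *[df[f].unique() for f in factors]],
            names=["subject", *factors],
        )
        absent = full.difference(counts.index)
        for key in absent:
            issues.append(
                {
                    "issue": "missing_cell",
                    "subject": key[0],
                    "cell": dict(zip(factors, key[1:])),
                }
            )
    return issues


def _resolve_experiment(
    name: str, source: str, config: RunConfig
) -> tuple[pd.DataFrame, DesignSpec]:
    if source in fixture_names():
        cfg = make_fixture(source, seed=int(config.seed) or make_fixture(source).seed)
        trials, _ = generate_experiment(cfg)
        design = cfg.design
        log.info("experiment %s: simulated fixture %s", name, source)
    else:
        trials = load_trials(source)
        factors = [c for c in trials.columns if c not in REQUIRED_COLUMNS]
        if config.design_path:
            design = load_design(config.design_path)
        else:
            design = infer_design(trials, factors)
        log.info("experiment %s: loaded %d trials from %s", name, len(trials), source)
    return trials, design


def _detection_summary_rows(
    labels: pd.DataFrame, isa_measures, correction: str
) -> pd.DataFrame:
    rows = []
    per_exp = list(labels.groupby("experiment_id", sort=False))
    scopes = per_exp + ([("Total", labels)] if len(per_exp) > 1 else [])
    for exp_id, sub in scopes:
        n_effects = sub[sub["measure"] == isa_measures[0]].shape[0]
        n_large = int(sub[sub["measure"] == isa_measures[0]]["large"].sum())
        row = {
            "experiment_id": exp_id,
            "n_effects": n_effects,
            "n_large": n_large,
            "n_small": n_effects - n_large,
        }
        for m in isa_measures:
            h, miss, fa, cr = detection_counts(sub, m)
            table = dprime(h, miss, fa, cr, correction=correction)
            row[f"{m}_h"] = round(table.h_rate_corrected, 6)
            row[f"{m}_fa"] = round(table.fa_rate_corrected, 6)
            row[f"{m}_dprime"] = round(table.d_prime, 6)
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run score -> analyze -> evaluate and write all reports.

    Returns the report frames keyed by file stem. Stage failures raise with
    the experiment id and stage named in the message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_scores, all_effects = [], []
    thresholds: dict[str, float] = {}
    for name, source in config.experiments.items():
        try:
            trials, design = _resolve_experiment(name, source, config)
        except Exception as exc:
            raise RuntimeError(f"[{name}] input stage failed: {exc}") from exc
        try:
            result = score_experiment(
                trials, factors=design.factor_names, strict=config.strict
            )
        except Exception as exc:
            raise RuntimeError(f"[{name}] scoring stage failed: {exc}") from exc
        scores = result.scores.copy()
        scores.insert(0, "experiment_id", name)
        all_scores.append(scores)
        try:
            effects = run_design_anova(
                result.scores, design, config.measures, experiment_id=name
            )
        except Exception as exc:
            raise RuntimeError(f"[{name}] analysis stage failed: {exc}") from exc
        all_effects.append(effects)
        n = int(effects["n_subjects"].min())
        thresholds[name] = criterion_eta(config.alpha, 1, n - 1)

    scores = pd.concat(all_scores, ignore_index=True)
    effects = pd.concat(all_effects, ignore_index=True)
    try:
        labels = classify_effects(effects, thresholds, config.isa_measures)
        summary = _detection_summary_rows(
            labels, config.isa_measures, config.correction
        )
    except Exception as exc:
        raise RuntimeError(f"[pooled] detection stage failed: {exc}") from exc

    n_effects = labels["effect_name"].nunique() * len(config.experiments)
    try:
        correlations = correlation_analysis(effects, config.isa_measures)
    except ValueError as exc:
        log.warning("correlation analysis skipped: %s", exc)
        correlations = pd.DataFrame(
            columns=[
                "measure", "component", "r", "ci_low", "ci_high",
                "partial_r", "partial_ci_low", "partial_ci_high", "n",
            ]
        )
    cat_frames = []
    for m in ("rcs", "rcs_c"):
        if m in config.isa_measures:
            comp = category_effect_comparison(effects, labels, measure=m)
            means = comp["means"].copy()
            means.insert(0, "target_measure", m)
            cat_frames.append(means)
    category_means = (
        pd.concat(cat_frames, ignore_index=True) if cat_frames else pd.DataFrame()
    )

    reports = {
        "scores": scores,
        "effects": effects,
        "detection_labels": labels,
        "detection_summary": summary,
        "correlations": correlations,
        "category_means": category_means,
    }
    for stem, frame in reports.items():
        frame.to_csv(out_dir / f"{stem}.csv", index=False)
    manifest = {
        "isascore_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "correction": config.correction,
        "experiments": dict(config.experiments),
        "thresholds": {k: round(v, 9) for k, v in thresholds.items()},
        "n_effects_per_measure": int(n_effects),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d experiments, reports in %s",
             len(config.experiments), out_dir)
    return reports
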