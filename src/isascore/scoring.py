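"""Per-cell aggregation and integrated speed-accuracy scores.

Choice-RT experiments yield two partially redundant performance measures per
subject and design cell: mean reaction time and the proportion of errors (PE).
This module aggregates a long-format trial table (one row per trial) into
per-subject-per-cell summaries and computes the composite scores that fold
speed and accuracy into a single number:

``IES``
    inverse efficiency score, ``RT_c / (1 - PE)`` — correct-response RT
    inflated by the error rate (ms).
``RCS``
    rate correct score, ``(1 - PE) / RT_a`` with RT in seconds — correct
    responses per second of response activity, based on all RTs.
``RCS_c``
    RCS computed from correct RTs only; algebraically ``1000 / IES`` when
    IES is expressed in ms.
``LISAS``
    linear integrated speed-accuracy score,
    ``RT_c + PE * S_RT / S_PE`` — PE rescaled so that one standard
    deviation of accuracy weighs as much as one standard deviation of RT.
``bin score``
    decile-weighted sum of correct switch-cost RT differences plus a fixed
    penalty per error.

Trial tables use the columns ``subject, block, trial, rt, acc``; every other
column is treated as a design factor. RTs are stored in milliseconds;
accuracy is coded 0 (error) / 1 (correct).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject", "block", "trial", "rt", "acc")

__all__ = [
    "REQUIRED_COLUMNS",
    "OrderingError",
    "CellSummary",
    "IntegratedScores",
    "BinResult",
    "ScoreResult",
    "filter_rt_stream",
    "summarize_cell",
    "ies",
    "rcs",
    "rcs_c",
    "lisas",
    "integrated_scores",
    "score_experiment",
    "bin_score",
    "switch_rt_differences",
]


class OrderingError(ValueError):
    """Raised when a trial table is not ordered by (subject, block, trial)."""


@dataclass(frozen=True)
class CellSummary:
    """Aggregates for one subject in one design cell.

    ``rt_c``/``s_rt`` come from the post-error-filtered correct-RT stream;
    ``rt_a`` is the mean over all trials; ``pe`` and ``s_pe`` are the mean
    error rate and the sample SD of the 0/1 accuracy indicator.
    """

    subject_id: Hashable
    cell: Mapping[str, Hashable]
    n_total: int
    n_correct: int
    n_rt_used: int
    rt_c: float
    rt_a: float
    pe: float
    s_rt: float
    s_pe: float


@dataclass(frozen=True)
class IntegratedScores:
    """The four composite scores for one cell; NaN marks a missing value."""

    lisas: float
    ies: float
    rcs: float
    rcs_c: float


@dataclass(frozen=True)
class BinResult:
    """Decile-weighted bin score for one subject."""

    subject_id: Hashable
    bin_score: float
    decile_counts: tuple[int, ...]
    n_e: int
    penalty: float


@dataclass
class ScoreResult:
    """Score table plus the missing-cell report from :func:`score_experiment`."""

    scores: pd.DataFrame
    missing: list[dict] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing


def _factor_columns(trials: pd.DataFrame) -> list[str]:
    return [c for c in trials.columns if c not in REQUIRED_COLUMNS]


def validate_trial_frame(trials: pd.DataFrame, *, require_sorted: bool = False) -> None:
    """Check structural invariants of a trial table; raise ``ValueError`` on failure."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table lacks required columns: {missing}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rt = trials["rt"].to_numpy(float)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt must be finite and > 0")
    acc = trials["acc"].to_numpy()
    if not np.isin(acc, (0, 1)).all():
        raise ValueError("acc must be 0 or 1")
    if trials.duplicated(["subject", "block", "trial"]).any():
        raise ValueError("(subject, block, trial) must be unique")
    if require_sorted:
        diffs = trials.groupby(["subject", "block"], sort=False)["trial"].diff()
        if (diffs.dropna() <= 0).any():
            raise OrderingError(
                "trials must be ordered by (subject, block, trial) with "
                "increasing trial index within each block"
            )


def filter_rt_stream(trials: pd.DataFrame) -> pd.DataFrame:
    """Return the correct-RT stream used for RT_c and S_RT.

    Keeps correct trials whose immediate predecessor within the same subject
    and block was also correct; the first trial of a block has no predecessor
    and is kept when correct. Incorrect trials and post-error trials are
    dropped — the standard latency filter for task-switching data.

    Raises :class:`OrderingError` if the input is not ordered by
    ``(subject, block, trial)``.
    """
    validate_trial_frame(trials, require_sorted=True)
    prev_acc = (
        trials.groupby(["subject", "block"], sort=False)["acc"].shift(1).fillna(1)
    )
    keep = (trials["acc"] == 1) & (prev_acc == 1)
    return trials.loc[keep]


def _sample_sd_binary(pe: np.ndarray, n: np.ndarray) -> np.ndarray:
    # sample SD (ddof=1) of a 0/1 indicator with mean error rate pe over n trials
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(pe * (1.0 - pe) * n / (n - 1.0))
    return np.where(n > 1, out, np.nan)


def summarize_cell(trials: pd.DataFrame, rt_stream: pd.DataFrame) -> CellSummary:
    """Aggregate one subject's trials in one cell into a :class:`CellSummary`.

    ``trials`` must all share subject and cell; ``rt_stream`` is the subset
    surviving :func:`filter_rt_stream`. An empty ``rt_stream`` flags
    ``rt_c``/``s_rt`` as missing (NaN) with a warning.
    """
    if len(trials) == 0:
        raise ValueError("summarize_cell requires at least one trial")
    subjects = trials["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("summarize_cell expects trials from a single subject")
    factors = _factor_columns(trials)
    for f in factors:
        if trials[f].nunique() != 1:
            raise ValueError(f"summarize_cell expects a single level of factor {f!r}")
    acc = trials["acc"].to_numpy(float)
    n_total = len(trials)
    n_correct = int(acc.sum())
    pe = 1.0 - n_correct / n_total
    s_pe = float(_sample_sd_binary(np.array(pe), np.array(n_total)))
    if n_total == 1:
        s_pe = 0.0
    if pe in (0.0, 1.0):
        s_pe = 0.0
    rt_a = float(trials["rt"].mean())
    n_used = len(rt_stream)
    if n_used == 0:
        warnings.warn(
            f"no correct post-filter RTs for subject {subjects[0]!r}; "
            "rt_c and s_rt flagged missing",
            stacklevel=2,
        )
        rt_c = np.nan
        s_rt = np.nan
    else:
        rt_c = float(rt_stream["rt"].mean())
        s_rt = float(rt_stream["rt"].std(ddof=1)) if n_used > 1 else np.nan
    return CellSummary(
        subject_id=subjects[0],
        cell={f: trials[f].iloc[0] for f in factors},
        n_total=n_total,
        n_correct=n_correct,
        n_rt_used=n_used,
        rt_c=rt_c,
        rt_a=rt_a,
        pe=pe,
        s_rt=s_rt,
        s_pe=s_pe,
    )


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    return arr


def ies(rt_c, pe):
    """Inverse efficiency score ``RT_c / (1 - PE)`` (ms).

    Undefined (NaN) when ``pe == 1``.
    """
    rt_c_a, pe_a = _as_float(rt_c), _as_float(pe)
    if np.any((pe_a < 0) | (pe_a > 1)):
        raise ValueError("pe must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pe_a < 1, rt_c_a / (1.0 - pe_a), np.nan)
    return out.item() if np.ndim(rt_c) == 0 and np.ndim(pe) == 0 else out


def rcs(rt_a_s, pe):
    """Rate correct score ``(1 - PE) / RT_a`` with RT_a in seconds."""
    rt_a_a, pe_a = _as_float(rt_a_s), _as_float(pe)
    if np.any(rt_a_a <= 0):
        raise ValueError("rt_a must be > 0")
    out = (1.0 - pe_a) / rt_a_a
    return out.item() if np.ndim(rt_a_s) == 0 and np.ndim(pe) == 0 else out


def rcs_c(rt_c_s, pe):
    """RCS computed from correct RTs: ``(1 - PE) / RT_c`` (RT_c in seconds).

    With IES in ms, ``rcs_c * ies == 1000`` on any valid cell.
    """
    rt_c_a, pe_a = _as_float(rt_c_s), _as_float(pe)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rt_c_a > 0, (1.0 - pe_a) / rt_c_a, np.nan)
    return out.item() if np.ndim(rt_c_s) == 0 and np.ndim(pe) == 0 else out


def lisas(rt_c, pe, s_rt, s_pe):
    """Linear integrated speed-accuracy score ``RT_c + PE * S_RT / S_PE`` (ms).

    When ``S_PE`` or ``PE`` is 0 the score is simply ``RT_c`` — the degenerate
    case is defined, not an error.
    """
    rt_c_a = _as_float(rt_c)
    pe_a = _as_float(pe)
    s_rt_a = _as_float(s_rt)
    s_pe_a = _as_float(s_pe)
    degenerate = (pe_a == 0) | (s_pe_a == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(degenerate, rt_c_a, rt_c_a + pe_a * s_rt_a / s_pe_a)
    scalar = all(np.ndim(v) == 0 for v in (rt_c, pe, s_rt, s_pe))
    return out.item() if scalar else out


def integrated_scores(summary: CellSummary) -> IntegratedScores:
    """Compute the four composite scores from one :class:`CellSummary`."""
    pe = summary.pe
    return IntegratedScores(
        lisas=lisas(summary.rt_c, pe, summary.s_rt, summary.s_pe),
        ies=ies(summary.rt_c, pe) if pe < 1 else np.nan,
        rcs=rcs(summary.rt_a / 1000.0, pe),
        rcs_c=rcs_c(summary.rt_c / 1000.0, pe),
    )


def score_experiment(
    trials: pd.DataFrame,
    factors: Sequence[str] | None = None,
    *,
    strict: bool = False,
) -> ScoreResult:
    """Score a whole experiment: one row per subject x design cell.

    The trial table is sorted by (subject, block, trial), the correct-RT
    stream is extracted with :func:`filter_rt_stream`, and every measure
    (``rt_c, rt_a, pe, s_rt, s_pe, lisas, ies, rcs, rcs_c``) is computed per
    subject x cell. Subject/cell combinations absent from the data are listed
    in the missing-cell report; with ``strict=True`` they raise instead.
    """
    if factors is None:
        factors = _factor_columns(trials)
    factors = list(factors)
    df = trials.sort_values(["subject", "block", "trial"], kind="mergesort")
    df = df.reset_index(drop=True)
    validate_trial_frame(df, require_sorted=True)
    stream = filter_rt_stream(df)

    keys = ["subject"] + factors
    g = df.groupby(keys, sort=True, observed=True)
    out = g.agg(
        n_total=("acc", "size"),
        n_correct=("acc", "sum"),
        rt_a=("rt", "mean"),
    )
    out["pe"] = 1.0 - out["n_correct"] / out["n_total"]
    out["s_pe"] = _sample_sd_binary(
        out["pe"].to_numpy(), out["n_total"].to_numpy(float)
    )
    out.loc[out["n_total"] == 1, "s_pe"] = 0.0
    out.loc[out["pe"].isin([0.0, 1.0]), "s_pe"] = 0.0

    gs = stream.groupby(keys, sort=True, observed=True)
    rtc = gs.agg(n_rt_used=("rt", "size"), rt_c=("rt", "mean"), s_rt=("rt", "std"))
    out = out.join(rtc)
    out["n_rt_used"] = out["n_rt_used"].fillna(0).astype(int)

    out["lisas"] = lisas(
        out["rt_c"].to_numpy(),
        out["pe"].to_numpy(),
        out["s_rt"].to_numpy(),
        out["s_pe"].to_numpy(),
    )
    out["ies"] = ies(out["rt_c"].to_numpy(), out["pe"].to_numpy())
    out["rcs"] = rcs(out["rt_a"].to_numpy() / 1000.0, out["pe"].to_numpy())
    out["rcs_c"] = rcs_c(out["rt_c"].to_numpy() / 1000.0, out["pe"].to_numpy())
    out = out.reset_index()

    # missing-cell report against the full crossing of observed levels
    missing: list[dict] = []
    if factors:
        subjects = df["subject"].unique()
        levels = [df[f].unique().tolist() for f in factors]
        seen = set(map(tuple, out[keys].itertuples(index=False, name=None)))
        for s in subjects:
            for combo in itertools.product(*levels):
                if (s, *combo) not in seen:
                    missing.append(
                        {"subject": s, **dict(zip(factors, combo))}
                    )
        if missing:
            if strict:
                raise ValueError(f"missing subject x cell combinations: {missing}")
            warnings.warn(
                f"{len(missing)} missing subject x cell combination(s); "
                "scoring proceeds without them",
                stacklevel=2,
            )
    if out["n_rt_used"].eq(0).any():
        warnings.warn(
            "some cells have no usable correct RTs; rt_c-based scores are NaN there",
            stacklevel=2,
        )
    return ScoreResult(scores=out, missing=missing)


def bin_score(
    switch_rt_diffs_by_subject: Mapping[Hashable, Sequence[float]],
    errors_by_subject: Mapping[Hashable, int],
    penalty: float = 20.0,
) -> dict[Hashable, BinResult]:
    """Decile-weighted bin score, one per subject.

    The correct-RT differences of *all* subjects are pooled to define decile
    edges (linear-interpolation quantiles at 0.1 ... 0.9); each subject's
    differences are counted per decile and scored as
    ``sum_i i * n_i + penalty * n_e``. A difference falling exactly on an
    edge counts toward the lower decile.
    """
    pooled = np.concatenate(
        [np.asarray(list(v), dtype=float) for v in switch_rt_diffs_by_subject.values()]
        or [np.empty(0)]
    )
    if pooled.size < 10:
        raise ValueError(
            f"need at least 10 pooled RT differences to form deciles, got {pooled.size}"
        )
    edges = np.quantile(pooled, np.arange(1, 10) / 10.0)
    results: dict[Hashable, BinResult] = {}
    for subj, diffs in switch_rt_diffs_by_subject.items():
        d = np.asarray(list(diffs), dtype=float)
        dec = np.searchsorted(edges, d, side="left") + 1  # deciles 1..10
        counts = np.bincount(dec, minlength=11)[1:11]
        n_e = int(errors_by_subject.get(subj, 0))
        score = float(np.dot(np.arange(1, 11), counts) + penalty * n_e)
        results[subj] = BinResult(
            subject_id=subj,
            bin_score=score,
            decile_counts=tuple(int(c) for c in counts),
            n_e=n_e,
            penalty=penalty,
        )
    return results


def switch_rt_differences(
    trials: pd.DataFrame,
    factor: str,
    switch_level: Hashable,
    repeat_level: Hashable,
) -> tuple[dict[Hashable, np.ndarray], dict[Hashable, int]]:
    """Per-subject correct switch-trial RTs minus the grand repetition mean.

    Convenience feeder for :func:`bin_score`: the reference is the mean
    correct RT of the repetition condition pooled over all subjects; error
    counts are the number of incorrect switch-condition trials per subject.
    No post-error filtering is applied here — the bin procedure predates it.
    """
    if factor not in trials.columns:
        raise ValueError(f"unknown factor {factor!r}")
    correct = trials[trials["acc"] == 1]
    rep = correct[correct[factor] == repeat_level]
    if len(rep) == 0:
        raise ValueError("no correct repetition trials")
    ref = rep["rt"].mean()
    sw = trials[trials[factor] == switch_level]
    diffs = {
        s: (grp.loc[grp["acc"] == 1, "rt"] - ref).to_numpy()
        for s, grp in sw.groupby("subject", sort=True)
    }
    errors = {
        s: int((grp["acc"] == 0).sum()) for s, grp in sw.groupby("subject", sort=True)
    }
    return diffs, errors
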