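"""Signal-detection evaluation of integrated speed-accuracy measures.

Each tested effect in an experiment carries a partial-eta-squared value for
reaction time (``rt_c``), error proportion (``pe``) and every integrated
measure. Against a per-experiment criterion — the eta_p^2 of a 1-df effect
exactly at alpha — effects are binned into *large* (RT or PE at/above the
criterion) and *small* sets; integrated measures are then scored as
hit / miss within the large set and false alarm / correct rejection within
the small set, and their sensitivity is summarized with

    d' = z(H) - z(FA)

using a log-linear correction (+0.5 to every cell of the 2x2 count matrix,
the default) or boundary replacement by 1/(2N) to avoid infinite values.

The module also provides the supporting analyses: Pearson and first-order
partial correlations between integrated and component effect sizes with
Fisher-z confidence intervals, Steiger's test for two dependent
correlations, decile-wise variability of integrated effect sizes along the
RT effect-size axis, category-wise effect-size comparisons (split-plot
Category x Measures ANOVA), and the Yates-corrected chi-square for 2x2
count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ISA_MEASURES = ("lisas", "ies", "rcs", "rcs_c")
COMPONENTS = ("rt_c", "pe")

__all__ = [
    "ISA_MEASURES",
    "COMPONENTS",
    "DetectionTable",
    "CorrelationResult",
    "criterion_eta",
    "classify_effects",
    "detection_counts",
    "dprime",
    "correlation_analysis",
    "compare_dependent_correlations",
    "decile_variability",
    "category_effect_comparison",
    "yates_chisq",
]


@dataclass(frozen=True)
class DetectionTable:
    """2x2 detection counts with corrected rates and sensitivity."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    h_rate_corrected: float
    fa_rate_corrected: float
    d_prime: float
    correction: str

    @property
    def n_large(self) -> int:
        return self.hits + self.misses

    @property
    def n_small(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r of an integrated measure with one component, with Fisher-z
    CI and the first-order partial holding the other component constant."""

    measure: str
    component: str
    r: float
    ci_low: float
    ci_high: float
    partial_r: float
    partial_ci_low: float
    partial_ci_high: float
    n: int


def criterion_eta(alpha: float = 0.05, df_num: int = 1, df_den: int = 19) -> float:
    """eta_p^2 of an effect exactly at significance level ``alpha``.

    ``F_crit = F^{-1}(1 - alpha; df_num, df_den)`` mapped through
    ``F_crit * df_num / (F_crit * df_num + df_den)``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    f_crit = stats.f.isf(alpha, df_num, df_den)
    return float(f_crit * df_num / (f_crit * df_num + df_den))


def _eta_wide(records: pd.DataFrame, measures: Sequence[str]) -> pd.DataFrame:
    """Accept either a wide per-effect table (eta_<measure> columns) or the
    tidy output of the design module and return the wide form."""
    if "eta_p_sq" in records.columns and "measure" in records.columns:
        idx = ["experiment_id", "effect_name"]
        extra = [c for c in ("df_num", "n_subjects") if c in records.columns]
        wide = records.pivot_table(
            index=idx, columns="measure", values="eta_p_sq", aggfunc="first",
            observed=True,
        )
        wide.columns = [f"eta_{c}" for c in wide.columns]
        if extra:
            meta = records.groupby(idx, sort=False)[extra].first()
            wide = wide.join(meta)
        return wide.reset_index()
    return records.copy()


def classify_effects(
    records: pd.DataFrame,
    thresholds: Mapping[str, float] | float,
    measures: Sequence[str] = ISA_MEASURES,
) -> pd.DataFrame:
    """Label every effect per integrated measure.

    An effect is *large* when its RT or PE eta_p^2 is at or above the
    experiment's criterion (ties count as detections); within the large set
    an integrated measure scores ``hit`` when its own eta reaches the
    criterion, else ``miss``; within the small set ``false_alarm`` /
    ``correct_rejection`` analogously.

    ``records`` is the tidy effect table from the design module or a wide
    per-effect frame with ``eta_rt_c``/``eta_pe``/``eta_<isa>`` columns;
    ``thresholds`` maps experiment_id -> criterion (or one global value).
    Returns a long frame: experiment_id, effect_name, measure, large,
    category.
    """
    wide = _eta_wide(records, measures)
    for comp in COMPONENTS:
        if f"eta_{comp}" not in wide.columns:
            raise ValueError(f"records lack the mandatory eta_{comp} entries")
        if wide[f"eta_{comp}"].isna().any():
            raise ValueError(f"missing eta_{comp} value(s)")
    if isinstance(thresholds, Mapping):
        crit = wide["experiment_id"].map(thresholds)
        if crit.isna().any():
            missing = wide.loc[crit.isna(), "experiment_id"].unique().tolist()
            raise ValueError(f"no threshold for experiment(s): {missing}")
    else:
        crit = pd.Series(float(thresholds), index=wide.index)
    large = (wide["eta_rt_c"] >= crit) | (wide["eta_pe"] >= crit)
    out = []
    for m in measures:
        col = f"eta_{m}"
        if col not in wide.columns:
            raise ValueError(f"records lack {col}")
        detected = wide[col] >= crit
        category = np.where(
            large,
            np.where(detected, "hit", "miss"),
            np.where(detected, "false_alarm", "correct_rejection"),
        )
        out.append(
            pd.DataFrame(
                {
                    "experiment_id": wide["experiment_id"],
                    "effect_name": wide["effect_name"],
                    "measure": m,
                    "large": large.to_numpy(),
                    "category": category,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def detection_counts(labels: pd.DataFrame, measure: str) -> tuple[int, int, int, int]:
    """(hits, misses, false_alarms, correct_rejections) for one measure."""
    sub = labels[labels["measure"] == measure]
    c = sub["category"].value_counts()
    return (
        int(c.get("hit", 0)),
        int(c.get("miss", 0)),
        int(c.get("false_alarm", 0)),
        int(c.get("correct_rejection", 0)),
    )


def dprime(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    correction: str = "loglinear",
) -> DetectionTable:
    """Sensitivity d' from raw 2x2 counts.

    ``loglinear`` (default) adds 0.5 to all four cells before forming rates;
    ``half_count`` keeps the raw proportions and only replaces boundary
    values 0 and 1 by 1/(2N) and 1 - 1/(2N), N being the relevant row total.
    """
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    n_large = hits + misses
    n_small = false_alarms + correct_rejections
    if n_large == 0 and n_small == 0:
        raise ValueError("at least one of the large/small sets must be non-empty")
    if correction == "loglinear":
        h = (hits + 0.5) / (n_large + 1)
        fa = (false_alarms + 0.5) / (n_small + 1)
    elif correction == "half_count":
        h = hits / n_large if n_large else 0.5
        fa = false_alarms / n_small if n_small else 0.5
        if h == 0.0:
            h = 1.0 / (2 * n_large)
        elif h == 1.0:
            h = 1.0 - 1.0 / (2 * n_large)
        if fa == 0.0:
            fa = 1.0 / (2 * n_small)
        elif fa == 1.0:
            fa = 1.0 - 1.0 / (2 * n_small)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    d = float(stats.norm.ppf(h) - stats.norm.ppf(fa))
    return DetectionTable(
        hits=hits,
        misses=misses,
        false_alarms=false_alarms,
        correct_rejections=correct_rejections,
        h_rate_corrected=float(h),
        fa_rate_corrected=float(fa),
        d_prime=d,
        correction=correction,
    )


def _fisher_ci(r: float, n_eff: int, conf: float = 0.95) -> tuple[float, float]:
    if n_eff <= 0:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n_eff)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _partial(r_xy: float, r_xz: float, r_yz: float) -> float:
    denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
    if denom_sq <= 0:
        # a conditioning correlation of +/-1: the partial degenerates to the
        # raw correlation's sign (exact collinearity)
        return float(np.sign(r_xy)) if abs(r_xy) == 1 else np.nan
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom_sq), -1.0, 1.0))


def correlation_analysis(
    records: pd.DataFrame,
    measures: Sequence[str] = ISA_MEASURES,
    components: Sequence[str] = COMPONENTS,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Correlations of integrated-measure effect sizes with RT and PE.

    Per (measure, component) pair: Pearson r with Fisher-z CI (n - 3 in the
    variance) and the first-order partial correlation holding the other
    component constant (n - 4). Raises on fewer than 4 records or
    zero-variance series.
    """
    wide = _eta_wide(records, measures)
    n = len(wide)
    if n < 4:
        raise ValueError("correlation_analysis requires at least 4 effect records")
    cols = {c: wide[f"eta_{c}"].to_numpy(float) for c in (*measures, *components)}
    for name, v in cols.items():
        if np.isnan(v).any():
            raise ValueError(f"missing eta values for {name}")
        if np.std(v) <= 1e-12 * max(1.0, float(np.abs(v).max())):
            raise ValueError(f"zero variance in eta series for {name}")
    rows = []
    for m in measures:
        for comp in components:
            other = [c for c in components if c != comp][0]
            r = float(np.corrcoef(cols[m], cols[comp])[0, 1])
            r_mo = float(np.corrcoef(cols[m], cols[other])[0, 1])
            r_co = float(np.corrcoef(cols[comp], cols[other])[0, 1])
            pr = float(_partial(r, r_mo, r_co))
            lo, hi = _fisher_ci(r, n - 3, conf)
            plo, phi = _fisher_ci(pr, n - 4, conf)
            rows.append(
                CorrelationResult(
                    measure=m, component=comp, r=r, ci_low=lo, ci_high=hi,
                    partial_r=pr, partial_ci_low=plo, partial_ci_high=phi, n=n,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_dependent_correlations(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable x.

    Tests r_xy = r_xz from one sample of size ``n`` where r_yz is the
    correlation of the two non-shared variables. Returns (z, two-sided p).
    """
    for r in (r_xy, r_xz, r_yz):
        if abs(r) >= 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    rbar = (r_xy + r_xz) / 2.0
    psi = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    s = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r_xy) - np.arctanh(r_xz)) * np.sqrt((n - 3) / (2 - 2 * s))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


EFFECT_LEVELS = {
    1: "1-3", 2: "1-3", 3: "1-3",
    4: "4-6", 5: "4-6", 6: "4-6",
    7: "7-10", 8: "7-10", 9: "7-10", 10: "7-10",
}


def decile_variability(
    records: pd.DataFrame,
    measures: Sequence[str] = ISA_MEASURES,
    *,
    dataset_col: str | None = None,
) -> pd.DataFrame:
    """Mean and SD of integrated effect sizes per decile of the RT effect size.

    Effects are ranked on eta_rt_c within each data set (``dataset_col``, or
    the prefix of ``experiment_id`` before the last underscore when absent);
    decile d of an effect with rank k among n is ``ceil(10 k / n)``. Deciles
    are grouped into effect levels 1-3, 4-6 and 7-10. The output (one row
    per dataset x decile x measure: mean_eta, sd_eta, n) is laid out to feed
    a Data Set x Effect Level x Measure ANOVA.
    """
    wide = _eta_wide(records, measures)
    if dataset_col and dataset_col in wide.columns:
        ds = wide[dataset_col].astype(str)
    else:
        ds = wide["experiment_id"].astype(str).str.rsplit("_", n=1).str[0]
    wide = wide.assign(_dataset=ds)
    rows = []
    for dname, grp in wide.groupby("_dataset", sort=True):
        n = len(grp)
        if n < 10:
            raise ValueError(
                f"data set {dname!r} has {n} effects; need >= 10 for deciles"
            )
        rank = grp["eta_rt_c"].rank(method="first")
        decile = np.ceil(10 * rank / n).astype(int)
        for d in range(1, 11):
            sel = grp[decile == d]
            for m in measures:
                v = sel[f"eta_{m}"].to_numpy(float)
                rows.append(
                    {
                        "dataset": dname,
                        "decile": d,
                        "effect_level": EFFECT_LEVELS[d],
                        "measure": m,
                        "mean_eta": float(np.mean(v)) if v.size else np.nan,
                        "sd_eta": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
                        "n": int(v.size),
                    }
                )
    return pd.DataFrame(rows)


def _splitplot_anova(
    y1: np.ndarray, y2: np.ndarray, group: np.ndarray
) -> pd.DataFrame:
    """Split-plot ANOVA: one between factor (group) x one 2-level within
    factor, via subject means (between part) and difference scores (within
    part). Also returns the interaction of each pairwise group contrast with
    the within factor, tested against the within-error MS."""
    groups = pd.unique(group)
    k = len(groups)
    n = len(y1)
    m = (y1 + y2) / 2.0  # between part
    d = y1 - y2  # within part
    df_err = n - k

    def one_way(v):
        gm = v.mean()
        ss_b = sum(
            len(v[group == g]) * (v[group == g].mean() - gm) ** 2 for g in groups
        )
        ss_w = sum(((v[group == g] - v[group == g].mean()) ** 2).sum() for g in groups)
        return ss_b, ss_w

    rows = []
    ss_bd, ss_wd = one_way(d)
    ms_err_w = (ss_wd / 2) / df_err
    if ms_err_w == 0:
        ms_err_w = np.nan  # identical series: within-error MS is zero
    if k > 1:
        # between factor main effect (on subject means; x2 for the two measures)
        ss_b, ss_w = one_way(m)
        f_cat = (2 * ss_b / (k - 1)) / (2 * ss_w / df_err)
        rows.append(("category", k - 1, df_err, f_cat))
    # within main + interaction from difference scores
    f_meas = (n * d.mean() ** 2 / 2) / ms_err_w
    rows.append(("measure", 1, df_err, f_meas))
    if k > 1:
        f_int = ((ss_bd / 2) / (k - 1)) / ms_err_w
        rows.append(("category:measure", k - 1, df_err, f_int))
    # pairwise group contrasts x measure
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            di, dj = d[group == gi], d[group == gj]
            num = (di.mean() - dj.mean()) ** 2 / (1 / len(di) + 1 / len(dj)) / 2
            rows.append((f"({gi} vs {gj}):measure", 1, df_err, num / ms_err_w))
    out = pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "f_value"])
    out["p_value"] = stats.f.sf(out["f_value"], out["df_num"], out["df_den"])
    out["eta_p_sq"] = (out["f_value"] * out["df_num"]) / (
        out["f_value"] * out["df_num"] + out["df_den"]
    )
    return out


def category_effect_comparison(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    measure: str = "rcs",
) -> dict[str, pd.DataFrame]:
    """Compare one integrated measure's effect sizes to max(eta_RT, eta_PE)
    within each detection category of that measure.

    Returns ``{"means": ..., "anova": ...}``: per-category means with
    standard errors for both series, and the Category x Measures split-plot
    ANOVA including the pairwise category-contrast x Measures tests. Empty
    categories are reported in the means table with NaN and excluded from
    the ANOVA with a warning.
    """
    wide = _eta_wide(records, (measure,))
    lab = labels[labels["measure"] == measure][
        ["experiment_id", "effect_name", "category"]
    ]
    merged = wide.merge(lab, on=["experiment_id", "effect_name"], how="inner")
    if len(merged) == 0:
        raise ValueError("no overlapping effects between records and labels")
    merged["eta_max_comp"] = merged[["eta_rt_c", "eta_pe"]].max(axis=1)
    order = ["hit", "miss", "false_alarm", "correct_rejection"]
    rows = []
    for cat in order:
        sel = merged[merged["category"] == cat]
        for series, col in (("max(rt,pe)", "eta_max_comp"), (measure, f"eta_{measure}")):
            v = sel[col].to_numpy(float)
            rows.append(
                {
                    "category": cat,
                    "series": series,
                    "mean_eta": float(v.mean()) if v.size else np.nan,
                    "se_eta": float(v.std(ddof=1) / np.sqrt(v.size))
                    if v.size > 1
                    else np.nan,
                    "n": int(v.size),
                }
            )
    means = pd.DataFrame(rows)
    present = [c for c in order if (merged["category"] == c).any()]
    empty = [c for c in order if c not in present]
    if empty:
        warnings.warn(
            f"empty detection categor{'y' if len(empty) == 1 else 'ies'} "
            f"{empty} excluded from the Category x Measures ANOVA",
            stacklevel=2,
        )
    sub = merged[merged["category"].isin(present)]
    anova = _splitplot_anova(
        sub["eta_max_comp"].to_numpy(float),
        sub[f"eta_{measure}"].to_numpy(float),
        sub["category"].to_numpy(),
    )
    return {"means": means, "anova": anova}


def yates_chisq(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table ``[[a, b], [c, d]]``.

    ``sum (|obs - exp| - 0.5)^2 / exp`` on 1 df; raises when a margin is 0.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all table margins must be > 0")
    exp = np.outer(rows, cols) / obs.sum()
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    chi2 = float((adj**2 / exp).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, p
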