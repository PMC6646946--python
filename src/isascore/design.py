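"""Within-subject effect sizes via the multivariate general linear model.

Fully within-subject factorial designs are tested without sphericity
assumptions by forming, per subject, orthonormal contrast scores over the
design cells and running a one-sample Hotelling T^2 on them:

    T^2 = N * zbar' S^{-1} zbar,      F = T^2 (N - p) / (p (N - 1))

with ``p`` contrast rows and ``N`` subjects, on (p, N - p) degrees of
freedom. The effect size is partial eta squared,

    eta_p^2 = T^2 / (T^2 + N - 1) = 1 - Wilks' Lambda,

which for a 1-df effect reduces to the familiar F / (F + df_error).

Contrast matrices are built from Kronecker products of orthonormal Helmert
blocks, so main-effect rows are constant over non-involved factors and
interaction rows are element-wise products of main-effect rows.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.linalg import helmert

P_FLOOR = 1e-300

__all__ = [
    "DesignSpec",
    "EffectResult",
    "load_design",
    "infer_design",
    "cells",
    "cell_frame",
    "contrast_matrix",
    "test_within_effect",
    "pivot_scores",
    "run_design_anova",
    "run_planned_contrasts",
    "enumerate_effects",
]


@dataclass(frozen=True)
class DesignSpec:
    """Ordered within-subject factors with levels, plus optional effect terms
    and named planned-contrast weight vectors."""

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    effects: tuple[tuple[str, ...], ...] | None = None
    contrasts: Mapping[str, Mapping] | None = None

    @property
    def factor_names(self) -> list[str]:
        return [name for name, _ in self.factors]

    def levels(self, factor: str) -> tuple[str, ...]:
        for name, lv in self.factors:
            if name == factor:
                return lv
        raise KeyError(factor)

    @property
    def n_cells(self) -> int:
        return int(np.prod([len(lv) for _, lv in self.factors]))


@dataclass(frozen=True)
class EffectResult:
    """One tested effect for one dependent measure."""

    experiment_id: str
    measure: str
    effect_name: str
    df_num: int
    df_den: int
    f_value: float
    p_value: float
    eta_p_sq: float
    n_subjects: int


def load_design(path) -> DesignSpec:
    """Read a design spec from YAML: ``factors`` (name -> level list),
    optional ``effects`` (lists of factor names) and ``contrasts``
    (name -> {factors: [...], weights: [...]})."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    factors = tuple(
        (str(name), tuple(str(l) for l in lv)) for name, lv in raw["factors"].items()
    )
    effects = raw.get("effects")
    if effects is not None:
        effects = tuple(tuple(e) for e in effects)
    return DesignSpec(factors=factors, effects=effects, contrasts=raw.get("contrasts"))


def infer_design(trials_or_scores: pd.DataFrame, factors: Sequence[str]) -> DesignSpec:
    """Build a :class:`DesignSpec` from the observed factor levels of a table
    (levels in order of first appearance)."""
    fac = tuple(
        (f, tuple(pd.unique(trials_or_scores[f]).tolist())) for f in factors
    )
    return DesignSpec(factors=fac)


def cells(design: DesignSpec) -> list[tuple]:
    """All design cells as level tuples, last factor varying fastest."""
    return list(itertools.product(*[lv for _, lv in design.factors]))


def cell_frame(design: DesignSpec) -> pd.DataFrame:
    """Cells as a DataFrame with one column per factor."""
    return pd.DataFrame(cells(design), columns=design.factor_names)


def _factor_block(design: DesignSpec, factor: str, involved: bool) -> np.ndarray:
    L = len(design.levels(factor))
    if involved:
        return helmert(L)  # (L-1, L), orthonormal rows
    return np.ones((1, L)) / np.sqrt(L)


def contrast_matrix(design: DesignSpec, effect: Sequence[str]) -> np.ndarray:
    """Orthonormal contrast rows over cells for a main effect or interaction.

    Rows are Kronecker products of per-factor blocks: an orthonormal Helmert
    basis for involved factors and the normalized constant vector for the
    rest. Returns shape ``(prod(L_f - 1), n_cells)``.
    """
    effect = list(effect)
    unknown = [f for f in effect if f not in design.factor_names]
    if unknown:
        raise ValueError(f"unknown factor(s) in effect: {unknown}")
    if not effect:
        raise ValueError("effect must involve at least one factor")
    mat = np.ones((1, 1))
    for name, _ in design.factors:
        mat = np.kron(mat, _factor_block(design, name, name in effect))
    return mat


def enumerate_effects(design: DesignSpec) -> list[tuple[str, ...]]:
    """All main effects and interactions (or the spec's explicit list)."""
    if design.effects is not None:
        return [tuple(e) for e in design.effects]
    names = design.factor_names
    out: list[tuple[str, ...]] = []
    for k in range(1, len(names) + 1):
        out.extend(itertools.combinations(names, k))
    return out


def effect_label(effect: Sequence[str]) -> str:
    return ":".join(effect)


def test_within_effect(
    cell_scores: np.ndarray,
    contrast: np.ndarray,
    *,
    experiment_id: str = "",
    measure: str = "",
    effect_name: str = "",
) -> EffectResult:
    """One-sample Hotelling T^2 of per-subject contrast scores against zero.

    ``cell_scores`` is an N x K subject-by-cell matrix (cells in design
    order); ``contrast`` a p x K orthonormal weight matrix. Requires
    ``N > p``. Degenerate zero-variance scores yield eta = 1 (nonzero mean,
    p-value floored) or eta = 0 (all-zero scores).
    """
    Y = np.asarray(cell_scores, dtype=float)
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    N, K = Y.shape
    p = C.shape[0]
    if C.shape[1] != K:
        raise ValueError("contrast width does not match number of cells")
    if N <= p:
        raise ValueError(f"need more subjects ({N}) than contrast rows ({p})")
    if np.isnan(Y).any():
        raise ValueError("cell_scores contains missing values")
    Z = Y @ C.T  # N x p contrast scores
    zbar = Z.mean(axis=0)
    resid = Z - zbar
    S = resid.T @ resid / (N - 1)
    df_num, df_den = p, N - p
    if np.allclose(Z, 0.0):
        t2 = 0.0
    else:
        try:
            sol = np.linalg.solve(S, zbar)
            t2 = float(N * zbar @ sol)
            if not np.isfinite(t2) or t2 < 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # singular covariance: zero variance with nonzero mean somewhere
            t2 = np.inf
    if np.isinf(t2):
        return EffectResult(
            experiment_id, measure, effect_name, df_num, df_den,
            f_value=np.inf, p_value=P_FLOOR, eta_p_sq=1.0, n_subjects=N,
        )
    f = t2 * (N - p) / (p * (N - 1))
    pval = max(float(stats.f.sf(f, df_num, df_den)), P_FLOOR)
    eta = t2 / (t2 + N - 1)
    return EffectResult(
        experiment_id, measure, effect_name, df_num, df_den,
        f_value=float(f), p_value=pval, eta_p_sq=float(eta), n_subjects=N,
    )


def pivot_scores(
    score_table: pd.DataFrame, design: DesignSpec, measure: str
) -> np.ndarray:
    """Subject-by-cell matrix of one measure, cells in design order.

    Subjects with any missing cell or NaN score are dropped (listwise) with
    a warning carrying the retained count.
    """
    wide = score_table.pivot_table(
        index="subject",
        columns=design.factor_names,
        values=measure,
        aggfunc="first",
        observed=True,
    )
    order = cells(design)
    cols = [c if len(design.factors) > 1 else c[0] for c in order]
    wide = wide.reindex(columns=cols)
    n_before = wide.shape[0]
    wide = wide.dropna(axis=0, how="any")
    if wide.shape[0] < n_before:
        warnings.warn(
            f"{measure}: dropped {n_before - wide.shape[0]} subject(s) with "
            f"missing cells; {wide.shape[0]} retained",
            stacklevel=2,
        )
    return wide.to_numpy(float)


DEFAULT_MEASURES = ("rt_c", "pe", "lisas", "ies", "rcs", "rcs_c")


def _results_frame(results: Iterable[EffectResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def run_design_anova(
    score_table: pd.DataFrame,
    design: DesignSpec,
    measures: Sequence[str] = DEFAULT_MEASURES,
    *,
    experiment_id: str = "",
) -> pd.DataFrame:
    """Full factorial ANOVA: every main effect and interaction, per measure.

    Returns a tidy frame with one row per effect x measure
    (columns ``experiment_id, measure, effect_name, df_num, df_den, f_value,
    p_value, eta_p_sq, n_subjects``).
    """
    results = []
    for measure in measures:
        Y = pivot_scores(score_table, design, measure)
        for effect in enumerate_effects(design):
            C = contrast_matrix(design, effect)
            results.append(
                test_within_effect(
                    Y, C,
                    experiment_id=experiment_id,
                    measure=measure,
                    effect_name=effect_label(effect),
                )
            )
    return _results_frame(results)


def _block_contrast_rows(
    design: DesignSpec,
    block: Sequence[str],
    weights: np.ndarray,
    others: Sequence[str],
) -> np.ndarray:
    """Spread a contrast over block cells to full-cell weight rows, interacted
    with the listed non-block factors (Helmert rows per involved factor)."""
    shape = [len(lv) for _, lv in design.factors]
    block = list(block)
    block_shape = [len(design.levels(f)) for f in block]
    w = np.asarray(weights, dtype=float).reshape(block_shape)
    # permute block axes into design order before embedding in the full grid
    block_in_order = [f for f in design.factor_names if f in block]
    w = np.transpose(w, [block.index(f) for f in block_in_order])
    block = block_in_order
    full_shape = [
        shape[i] if name in block else 1
        for i, (name, _) in enumerate(design.factors)
    ]
    base = w.reshape(full_shape)
    other_rows = []
    for name, _ in design.factors:
        if name in block:
            continue
        L = len(design.levels(name))
        if name in others:
            other_rows.append((name, helmert(L)))
        else:
            other_rows.append((name, np.ones((1, L)) / np.sqrt(L)))
    rows = []
    for combo in itertools.product(*[range(m.shape[0]) for _, m in other_rows]):
        t = base.copy()
        for (name, m), ridx in zip(other_rows, combo):
            axis = design.factor_names.index(name)
            vec_shape = [1] * len(shape)
            vec_shape[axis] = shape[axis]
            t = t * m[ridx].reshape(vec_shape)
        rows.append(t.reshape(-1))
    return np.vstack(rows)


def default_block_contrasts(
    design: DesignSpec, block: Sequence[str]
) -> dict[str, np.ndarray]:
    """Repetition-vs-switch style contrasts over a factorial building block:
    one set of orthonormal rows per block effect (mains and interactions)."""
    sub = DesignSpec(factors=tuple((f, design.levels(f)) for f in block))
    out = {}
    for effect in enumerate_effects(sub):
        out[effect_label(effect)] = contrast_matrix(sub, effect)
    return out


def _orthogonalize(named: list[tuple[str, np.ndarray]]) -> list[tuple[str, np.ndarray]]:
    """Check orthogonality of supplied single-row contrasts; Gram-Schmidt with
    a warning when they are not orthogonal."""
    flat = [(n, m) for n, m in named]
    vecs = [m for _, m in flat if m.shape[0] == 1]
    if len(vecs) > 1:
        V = np.vstack(vecs)
        G = V @ V.T
        off = G - np.diag(np.diag(G))
        if np.max(np.abs(off)) > 1e-8:
            warnings.warn(
                "supplied contrasts are not orthogonal; applying Gram-Schmidt",
                stacklevel=3,
            )
            Q = np.linalg.qr(V.T)[0].T
            # keep signs aligned with the originals
            for i in range(Q.shape[0]):
                if np.dot(Q[i], V[i]) < 0:
                    Q[i] = -Q[i]
            k = 0
            out = []
            for n, m in flat:
                if m.shape[0] == 1:
                    out.append((n, Q[k : k + 1]))
                    k += 1
                else:
                    out.append((n, m))
            return out
    return flat


def run_planned_contrasts(
    score_table: pd.DataFrame,
    design: DesignSpec,
    contrasts: Mapping[str, Mapping] | None = None,
    *,
    block: Sequence[str] | None = None,
    measures: Sequence[str] = DEFAULT_MEASURES,
    interact_with_others: bool = True,
    experiment_id: str = "",
) -> pd.DataFrame:
    """Planned contrasts over a factorial building block, plus (optionally)
    their interactions with the remaining design factors.

    ``contrasts`` maps a name to ``{"factors": [...], "weights": [...]}``
    where weights span the cells of the listed block factors (product order,
    last factor fastest) and must sum to zero. Without an explicit set, the
    repetition-vs-switch defaults over ``block`` are used (each block main
    effect and interaction). Non-orthogonal user sets are Gram-Schmidt
    orthogonalized with a warning.
    """
    if contrasts is None and design.contrasts:
        contrasts = design.contrasts
    named: list[tuple[str, Sequence[str], np.ndarray]] = []
    if contrasts:
        prepared = []
        for name, spec in contrasts.items():
            blk = list(spec["factors"])
            w = np.asarray(spec["weights"], dtype=float)
            if abs(w.sum()) > 1e-8 * max(1.0, np.abs(w).max()):
                raise ValueError(f"contrast {name!r} weights must sum to 0")
            w = w / np.linalg.norm(w)
            prepared.append((name, blk, w.reshape(1, -1)))
        same_block = len({tuple(b) for _, b, _ in prepared}) == 1
        if same_block:
            ortho = _orthogonalize([(n, m) for n, _, m in prepared])
            prepared = [
                (n, b, m) for ((n, b, _), (_, m)) in zip(prepared, ortho)
            ]
        named = prepared
    else:
        if block is None:
            raise ValueError("either contrasts or block must be given")
        for name, mat in default_block_contrasts(design, block).items():
            named.append((name, list(block), mat))

    results = []
    measure_mats: dict[str, np.ndarray] = {}
    for measure in measures:
        measure_mats[measure] = pivot_scores(score_table, design, measure)
    for name, blk, w in named:
        other_sets: list[tuple[str, ...]] = [()]
        remaining = [f for f in design.factor_names if f not in blk]
        if interact_with_others:
            for k in range(1, len(remaining) + 1):
                other_sets.extend(itertools.combinations(remaining, k))
        for others in other_sets:
            if w.shape[0] == 1:
                C = _block_contrast_rows(design, blk, w[0], others)
            else:
                C = np.vstack(
                    [_block_contrast_rows(design, blk, row, others) for row in w]
                )
            label = name if not others else f"{name}:{':'.join(others)}"
            for measure in measures:
                results.append(
                    test_within_effect(
                        measure_mats[measure], C,
                        experiment_id=experiment_id,
                        measure=measure,
                        effect_name=label,
                    )
                )
    return _results_frame(results)
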