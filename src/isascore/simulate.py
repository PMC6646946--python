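"""Synthetic task-switching experiments with controlled RT/PE effect structure.

The generator emulates the structure of multi-factorial within-subject
task-switching studies: each subject contributes `trials_per_cell` trials in
every cell of a factorial design, reaction times follow an ex-Gaussian
distribution (normal(mu, sigma) + exponential(tau)), accuracy is Bernoulli
with the error rate modelled on the logit scale, and subjects carry random
intercepts for both speed and error proneness (optionally coupled, to mimic
a between-subject speed-accuracy trade-off).

Experimental effects are injected as shifts: ``effect_rt`` moves the cell
mean RT (ms), ``effect_pe`` the cell error logit. Each factor's levels are
coded on a centered unit-range scale (two levels -> -1/2, +1/2), and an
effect's contribution to a cell is the shift times the product of the
involved factors' codes — so for a main effect the shift is the difference
between extreme levels, and for an interaction it is the double difference.

Fixture configurations mirror thirteen task-switching experiments from two
data sets: eight crossing Task transition x Dimension transition (with CSI
and CCI factors in the larger designs) and five crossing Cue type or
Response type with Transition type (and response Congruency).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import DesignSpec, cells, contrast_matrix, enumerate_effects, effect_label
from .scoring import score_experiment

DEFAULT_FIXTURE_SEED = 20180112
DEFAULT_ERROR_RATE = 0.07

__all__ = [
    "SimConfig",
    "generate_experiment",
    "make_fixture",
    "fixture_names",
    "run_recovery_study",
    "rt_shift_for_eta",
    "pe_logit_shift_for_eta",
    "balanced_opposite_shifts",
    "DEFAULT_FIXTURE_SEED",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic experiment.

    RT parameters are in ms; ``error_base`` is the logit of the base error
    rate; ``effect_rt``/``effect_pe`` map an effect term (tuple of factor
    names or colon-joined string) to a shift (ms / logit). ``sat_coupling``
    adds the subject's standardized speed deviation times this scalar to the
    subject's error logit (slow subjects -> more conservative when negative).
    """

    design: DesignSpec
    n_subjects: int = 24
    trials_per_cell: int = 60
    rt_mu: float = 500.0
    rt_sigma: float = 50.0
    rt_tau: float = 150.0
    effect_rt: Mapping = field(default_factory=dict)
    error_base: float = float(logit(DEFAULT_ERROR_RATE))
    effect_pe: Mapping = field(default_factory=dict)
    subject_sd_rt: float = 40.0
    subject_sd_pe: float = 0.3
    sat_coupling: float = 0.0
    error_rt_shift: float = 0.0
    seed: int = DEFAULT_FIXTURE_SEED

    def __post_init__(self):
        if self.rt_sigma <= 0 or self.rt_tau <= 0:
            raise ValueError("rt_sigma and rt_tau must be > 0")
        if self.trials_per_cell < 2:
            raise ValueError("trials_per_cell must be >= 2")
        p0 = float(expit(self.error_base))
        if not 0 < p0 < 0.5:
            raise ValueError("base error rate must lie in (0, 0.5)")


def _normalize_effect(key) -> tuple[str, ...]:
    if isinstance(key, str):
        return tuple(key.split(":"))
    return tuple(key)


def _factor_codes(n_levels: int) -> np.ndarray:
    # centered, unit range: 2 levels -> (-.5, +.5); 3 -> (-.5, 0, +.5)
    if n_levels == 1:
        return np.zeros(1)
    return (np.arange(n_levels) - (n_levels - 1) / 2) / (n_levels - 1)


def _cell_shifts(design: DesignSpec, effects: Mapping) -> np.ndarray:
    """Per-cell additive shift implied by an effect -> shift mapping."""
    cell_list = cells(design)
    level_index = {
        name: {lv: i for i, lv in enumerate(levels)}
        for name, levels in design.factors
    }
    codes = {
        name: _factor_codes(len(levels)) for name, levels in design.factors
    }
    shifts = np.zeros(len(cell_list))
    for key, delta in effects.items():
        term = _normalize_effect(key)
        for f in term:
            if f not in level_index:
                raise ValueError(f"effect {key!r} names unknown factor {f!r}")
        for ci, cell in enumerate(cell_list):
            prod = 1.0
            for f in term:
                ax = design.factor_names.index(f)
                prod *= codes[f][level_index[f][cell[ax]]]
            # unit-range codes: the (double-)difference along the term is delta
            shifts[ci] += delta * prod
    return shifts


def truth_table(config: SimConfig) -> pd.DataFrame:
    """Expected effect structure implied by a config: per design effect, the
    injected RT shift (ms), PE shift (logit) and a direction flag."""
    rt = {_normalize_effect(k): v for k, v in config.effect_rt.items()}
    pe = {_normalize_effect(k): v for k, v in config.effect_pe.items()}
    rows = []
    for effect in enumerate_effects(config.design):
        dr = float(rt.get(effect, 0.0))
        dp = float(pe.get(effect, 0.0))
        if dr == 0 and dp == 0:
            direction = "null"
        elif dp == 0:
            direction = "rt_only"
        elif dr == 0:
            direction = "pe_only"
        elif np.sign(dr) == np.sign(dp):
            direction = "same"
        else:
            direction = "opposite"
        rows.append(
            {
                "effect_name": effect_label(effect),
                "rt_shift_ms": dr,
                "pe_shift_logit": dp,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def generate_experiment(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic experiment.

    Returns ``(trials, truth)``: a long trial table (subject, block, trial,
    rt, acc + one column per factor; trials of each subject form one block
    with cells interleaved in random order) and the :func:`truth_table`.
    Deterministic for a given seed (``config.seed`` unless overridden).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = config.design
    cell_list = cells(design)
    K = len(cell_list)
    N = config.n_subjects
    t = config.trials_per_cell
    n_trials = K * t

    mu_cell = config.rt_mu + _cell_shifts(design, config.effect_rt)
    logit_cell = config.error_base + _cell_shifts(design, config.effect_pe)

    mu_dev = rng.normal(0.0, config.subject_sd_rt, size=N)
    pe_dev = rng.normal(0.0, config.subject_sd_pe, size=N)
    if config.subject_sd_rt > 0:
        pe_dev = pe_dev + config.sat_coupling * (mu_dev / config.subject_sd_rt)

    # interleaved cell order per subject
    base = np.repeat(np.arange(K), t)
    cell_idx = rng.permuted(np.tile(base, (N, 1)), axis=1)

    mu = mu_cell[cell_idx] + mu_dev[:, None]
    p_err = expit(logit_cell[cell_idx] + pe_dev[:, None])
    acc = (rng.random((N, n_trials)) >= p_err).astype(int)
    rt = (
        rng.normal(mu, config.rt_sigma)
        + rng.exponential(config.rt_tau, size=(N, n_trials))
        + (1 - acc) * config.error_rt_shift
    )
    rt = np.maximum(rt, 1.0)  # RTs must stay positive

    factor_names = design.factor_names
    cell_levels = np.array(cell_list, dtype=object)
    flat_idx = cell_idx.reshape(-1)
    trials = pd.DataFrame(
        {
            "subject": np.repeat([f"s{i + 1:02d}" for i in range(N)], n_trials),
            "block": 1,
            "trial": np.tile(np.arange(1, n_trials + 1), N),
            "rt": rt.reshape(-1),
            "acc": acc.reshape(-1),
        }
    )
    for j, f in enumerate(factor_names):
        trials[f] = cell_levels[flat_idx, j]
    return trials, truth_table(config)


def _design(*factors: tuple[str, tuple[str, ...]]) -> DesignSpec:
    return DesignSpec(factors=tuple(factors))

TD = ("task", ("repeat", "switch"))
DD = ("dimension", ("repeat", "switch"))
CSI = ("csi", ("300", "1000"))
CCI = ("cci", ("0", "300", "1000"))
CUE = ("cue", ("explicit", "transition"))
TT = ("transition", ("repeat", "switch"))
CONG = ("congruency", ("congruent", "incongruent"))
RESP = ("response", ("choice", "simple"))

# same-direction RT/PE effects typical of task-switching costs
_DS1_EFFECTS_RT = {"task": 60.0, "dimension": 25.0, "task:dimension": 20.0}
_DS1_EFFECTS_PE = {"task": 0.45, "dimension": 0.20, "task:dimension": 0.15}
_DS2_EFFECTS_RT = {"transition": 60.0, "cue": 30.0}
_DS2_EFFECTS_PE = {"transition": 0.45, "cue": 0.20}

_FIXTURES: dict[str, dict] = {
    "ds1_exp1": dict(n=20, factors=(TD, DD)),
    "ds1_exp2": dict(n=20, factors=(CSI, TD, DD)),
    "ds1_exp3": dict(n=22, factors=(CSI, TD, DD)),
    "ds1_exp4": dict(n=22, factors=(CSI, TD, DD)),
    "ds1_exp5": dict(n=48, factors=(CCI, CSI, TD, DD)),
    "ds1_exp6": dict(n=45, factors=(CCI, CSI, TD, DD)),
    "ds1_exp7": dict(n=48, factors=(CCI, CSI, TD, DD)),
    "ds1_exp8": dict(n=47, factors=(CCI, CSI, TD, DD)),
    "ds2_exp1": dict(n=24, factors=(CUE, TT, CONG), ds2=True),
    "ds2_exp2": dict(n=24, factors=(CUE, TT), ds2=True),
    "ds2_exp3": dict(n=20, factors=(CUE, TT), ds2=True),
    "ds2_exp4": dict(n=19, factors=(RESP, TT, CONG), ds2=True),
    "ds2_exp5": dict(n=18, factors=(RESP, TT, CONG), ds2=True),
}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def make_fixture(name: str, **overrides) -> SimConfig:
    """Named synthetic stand-ins for the thirteen study experiments.

    Subject counts and factor structure follow the study designs
    (``ds1_exp1``: 20 subjects, Task x Dimension; ``ds1_exp5``: 48 subjects,
    CCI x CSI x Task x Dimension; ``ds2_exp1``: 24 subjects, Cue x
    Transition x Congruency; ...). Defaults put same-direction task-switch
    costs on RT and PE and a base error rate of 0.07. Keyword overrides are
    forwarded to :class:`SimConfig`.
    """
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    spec = _FIXTURES[name]
    design = _design(*spec["factors"])
    if spec.get("ds2"):
        eff_rt, eff_pe = dict(_DS2_EFFECTS_RT), dict(_DS2_EFFECTS_PE)
    else:
        eff_rt, eff_pe = dict(_DS1_EFFECTS_RT), dict(_DS1_EFFECTS_PE)
    eff_rt = {k: v for k, v in eff_rt.items()
              if all(f in design.factor_names for f in _normalize_effect(k))}
    eff_pe = {k: v for k, v in eff_pe.items()
              if all(f in design.factor_names for f in _normalize_effect(k))}
    cfg = SimConfig(
        design=design,
        n_subjects=spec["n"],
        effect_rt=eff_rt,
        effect_pe=eff_pe,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _cellmean_sd_rt(config: SimConfig) -> float:
    return float(
        np.sqrt((config.rt_sigma**2 + config.rt_tau**2) / config.trials_per_cell)
    )


def _cellmean_sd_pe(config: SimConfig) -> float:
    p0 = float(expit(config.error_base))
    return float(np.sqrt(p0 * (1 - p0) / config.trials_per_cell))


def rt_shift_for_eta(config: SimConfig, eta_target: float) -> float:
    """Main-effect RT shift (ms, 2-level factor) whose expected eta_p^2
    is approximately ``eta_target``, by the closed-form power relation
    delta_z = sqrt(eta / (1 - eta)) on contrast scores."""
    if not 0 <= eta_target < 1:
        raise ValueError("eta_target must lie in [0, 1)")
    delta_z = np.sqrt(eta_target / (1 - eta_target))
    K = config.design.n_cells
    return float(2 * delta_z * _cellmean_sd_rt(config) / np.sqrt(K))


def pe_logit_shift_for_eta(config: SimConfig, eta_target: float) -> float:
    """Logit-scale PE shift analogue of :func:`rt_shift_for_eta`."""
    if not 0 <= eta_target < 1:
        raise ValueError("eta_target must lie in [0, 1)")
    delta_z = np.sqrt(eta_target / (1 - eta_target))
    K = config.design.n_cells
    p0 = float(expit(config.error_base))
    dp = 2 * delta_z * _cellmean_sd_pe(config) / np.sqrt(K)
    return float(dp / (p0 * (1 - p0)))


def balanced_opposite_shifts(
    config: SimConfig, delta_z: float, *, equal_sd: bool = False
) -> tuple[float, float]:
    """Opposite-direction RT and PE shifts that cancel inside LISAS.

    The RT shift has standardized size ``delta_z`` (cell-mean SD units). By
    default the PE shift solves the cancellation condition
    ``delta RT_c = -delta PE * S_RT / S_PE`` to first order *including* the
    dependence of the per-cell S_PE on the error rate: the LISAS penalty
    term is ``S_RT * sqrt(PE / (1 - PE)) * sqrt((t-1)/t)``, so the offsetting
    proportion shift is ``-rt_shift / g'(p0)`` with ``g`` that penalty as a
    function of the error rate.

    ``equal_sd=True`` instead returns a PE shift of standardized size
    ``delta_z`` (equal trial-level SD units, opposite sign) — the textbook
    statement of the balance property. Because the penalty is concave in the
    error rate, that variant under-compensates at small error rates and
    leaves a residual effect in LISAS.
    """
    K = config.design.n_cells
    rt_shift = 2 * delta_z * _cellmean_sd_rt(config) / np.sqrt(K)
    p0 = float(expit(config.error_base))
    if equal_sd:
        pe_prop = 2 * delta_z * _cellmean_sd_pe(config) / np.sqrt(K)
    else:
        t = config.trials_per_cell
        s_rt = float(np.sqrt(config.rt_sigma**2 + config.rt_tau**2))
        # g(p) = s_rt * sqrt((t-1)/t) * sqrt(p/(1-p));  g'(p0):
        g_prime = (
            s_rt
            * np.sqrt((t - 1) / t)
            / (2 * np.sqrt(p0 / (1 - p0)) * (1 - p0) ** 2)
        )
        pe_prop = rt_shift / g_prime
    pe_shift = -pe_prop / (p0 * (1 - p0))
    return float(rt_shift), float(pe_shift)


def run_recovery_study(
    configs: Mapping[str, SimConfig] | Sequence[SimConfig] | SimConfig,
    replicates: int,
    seed: int,
    *,
    alpha: float = 0.05,
    measures: Sequence[str] = ("rt_c", "pe", "lisas", "ies", "rcs", "rcs_c"),
) -> pd.DataFrame:
    """Detection rates of each measure against the generator's ground truth.

    Runs the full pipeline (generate -> score -> multivariate ANOVA ->
    criterion classification) on ``replicates`` fresh draws per config and
    tabulates, per measure, the hit rate over truly non-null effects and the
    false-alarm rate over truly null effects (detection: eta_p^2 at or above
    the alpha criterion for the experiment's subject count).
    """
    from .design import run_design_anova
    from .detection import criterion_eta

    if isinstance(configs, SimConfig):
        configs = {"config": configs}
    elif not isinstance(configs, Mapping):
        configs = {f"config{i + 1}": c for i, c in enumerate(configs)}
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {
        m: {"hits": 0, "n_true": 0, "false_alarms": 0, "n_null": 0} for m in measures
    }
    for name, cfg in configs.items():
        crit = criterion_eta(alpha, 1, cfg.n_subjects - 1)
        truth = truth_table(cfg).set_index("effect_name")["direction"]
        for _ in range(replicates):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            trials, _ = generate_experiment(cfg, seed=rep_seed)
            scores = score_experiment(trials).scores
            eff = run_design_anova(
                scores, cfg.design, measures, experiment_id=name
            )
            is_null = eff["effect_name"].map(truth).eq("null")
            detected = eff["eta_p_sq"] >= crit
            for m in measures:
                sel = eff["measure"] == m
                counts[m]["hits"] += int((detected & ~is_null & sel).sum())
                counts[m]["n_true"] += int((~is_null & sel).sum())
                counts[m]["false_alarms"] += int((detected & is_null & sel).sum())
                counts[m]["n_null"] += int((is_null & sel).sum())
    rows = []
    for m in measures:
        c = counts[m]
        rows.append(
            {
                "measure": m,
                "hit_rate": c["hits"] / c["n_true"] if c["n_true"] else np.nan,
                "fa_rate": c["false_alarms"] / c["n_null"] if c["n_null"] else np.nan,
                **c,
            }
        )
    return pd.DataFrame(rows)
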