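"""Model tuning: FC x RM grid search with AICc, plus variable importance.

Candidate models cross feature-class combinations {L, LQ, H, LQH, LQHP,
LQHPT} with regularization multipliers 0.5..4 in steps of 0.5 (48 models).
Each candidate is scored by bootstrap-replicated train/test AUC (75/25
splits) and by AICc computed on a fit to all occurrences, with the raw
density normalized over the full prediction domain. The selected model is
the delta-AICc = 0 row, ties broken by the larger auc_train - auc_diff_avg
metric, then simpler feature set, then smaller multiplier.

Variable importance comes three ways: percent contribution (objective gain
credited to variables during coordinate descent), permutation importance
(training-AUC drop after permuting one variable), and the leave-one-out /
only-one variable jackknife of training gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import EnvStack, OccurrenceSet, occurrence_cells
from .maxent import (Cell, MaxentModel, auc, build_features, feature_matrix,
                     fit_maxent, predict_scores, sample_background,
                     training_gain)

DEFAULT_RMS = tuple(np.arange(0.5, 4.01, 0.5))
DEFAULT_FCS = ("L", "LQ", "H", "LQH", "LQHP", "LQHPT")

#: Sentinel for AICc when the parameter count makes the correction undefined.
AICC_UNDEFINED = float("nan")


@dataclass
class EvalResult:
    fc: str
    rm: float
    auc_train: list[float]
    auc_test: list[float]
    aicc: float
    n_parameters: int
    delta_aicc: float = float("nan")

    @property
    def auc_train_mean(self) -> float:
        return float(np.mean(self.auc_train))

    @property
    def auc_test_mean(self) -> float:
        return float(np.mean(self.auc_test))

    @property
    def auc_diff_avg(self) -> float:
        return float(np.mean(np.array(self.auc_train) - np.array(self.auc_test)))

    @property
    def selection_metric(self) -> float:
        return self.auc_train_mean - self.auc_diff_avg


@dataclass
class ImportanceReport:
    percent_contribution: dict[str, float]
    permutation_importance: dict[str, float]
    jackknife: dict[str, tuple[float, float]]  # variable -> (gain_without, gain_only)
    full_gain: float = float("nan")


def evaluate_combo(occ: OccurrenceSet, stack: EnvStack, fc: str, rm: float,
                   n_replicates: int = 10, train_fraction: float = 0.75,
                   seed: int = 0, background_n: int = 10000,
                   n_knots: int = 10, max_iterations: int = 10000) -> EvalResult:
    """Bootstrap-replicated evaluation of one feature-class / RM combination.

    Each replicate resamples occurrence cells with replacement, splits the
    distinct resampled cells 75/25 into train/test, fits on train, and
    scores AUC on both partitions against a fixed background. AICc comes
    from a model fitted to all occurrences.
    """
    grid = stack.grid
    cells = occurrence_cells(occ, grid)
    if len(cells) < 8:
        raise ValueError(f"need at least 8 occurrence cells, got {len(cells)}")
    rng = np.random.default_rng(seed)
    background = sample_background(stack, n=background_n,
                                   seed=int(rng.integers(2**31)))
    spec = build_features(stack, classes=fc, n_knots=n_knots,
                          background_cells=background)
    auc_train: list[float] = []
    auc_test: list[float] = []
    for _ in range(n_replicates):
        boot_idx = rng.integers(0, len(cells), size=len(cells))
        boot = list(dict.fromkeys(cells[i] for i in boot_idx))
        if len(boot) < 4:
            boot = list(cells)
        perm = rng.permutation(len(boot))
        n_train = max(2, int(round(train_fraction * len(boot))))
        n_train = min(n_train, len(boot) - 1)
        train = [boot[i] for i in perm[:n_train]]
        test = [boot[i] for i in perm[n_train:]]
        model = fit_maxent(train, background, stack, spec, rm=rm,
                           max_iterations=max_iterations)
        bg_scores = predict_scores(model, stack, background)
        auc_train.append(auc(predict_scores(model, stack, train), bg_scores))
        auc_test.append(auc(predict_scores(model, stack, test), bg_scores))
    full = fit_maxent(cells, background, stack, spec, rm=rm,
                      max_iterations=max_iterations)
    return EvalResult(fc=fc, rm=float(rm), auc_train=auc_train,
                      auc_test=auc_test, aicc=aicc(full, occ, stack),
                      n_parameters=full.n_parameters)


def aicc(model: MaxentModel, occ: OccurrenceSet, stack: EnvStack) -> float:
    """Small-sample AIC of a fitted model on the occurrence data.

    The likelihood uses raw probabilities renormalized over the full
    prediction domain (all valid cells); k counts nonzero coefficients.
    Returns NaN when k >= n - 1 (correction undefined).
    """
    cells = occurrence_cells(occ, stack.grid)
    kept = []
    for c in cells:
        if np.isnan(stack.grid.values[c]):
            warnings.warn(f"occurrence on nodata cell {c} excluded from AICc")
        else:
            kept.append(c)
    n = len(kept)
    k = model.n_parameters
    if n == 0:
        raise ValueError("no occurrences on valid cells")
    if k >= n - 1:
        return AICC_UNDEFINED
    all_cells = stack.valid_cells()
    raw_all = predict_scores(model, stack, all_cells, output_kind="raw")
    index = {c: i for i, c in enumerate(all_cells)}
    z = raw_all.sum()
    p = np.array([raw_all[index[c]] for c in kept]) / z
    lnL = float(np.sum(np.log(np.maximum(p, 1e-300))))
    return float(2 * k - 2 * lnL + 2 * k * (k + 1) / (n - k - 1))


_FC_ORDER = {fc: i for i, fc in enumerate(DEFAULT_FCS)}


def tune_grid(occ: OccurrenceSet, stack: EnvStack,
              rms: tuple[float, ...] = DEFAULT_RMS,
              fcs: tuple[str, ...] = DEFAULT_FCS,
              seed: int = 0, **eval_kwargs) -> tuple[pd.DataFrame, EvalResult]:
    """Grid search over FC x RM; returns the results table and the best combo.

    delta_aicc = aicc - min(aicc) over defined rows; best = argmin
    delta_aicc with ties broken by larger auc_train - auc_diff_avg, then
    fewer feature classes, then smaller RM. If every AICc is undefined,
    selection falls back to the AUC metric with a warning.
    """
    if not rms or not fcs:
        raise ValueError("rms and fcs must be non-empty")
    results: list[EvalResult] = []
    for fc in fcs:
        for rm in rms:
            results.append(evaluate_combo(occ, stack, fc, rm, seed=seed,
                                          **eval_kwargs))
    finite = [r.aicc for r in results if np.isfinite(r.aicc)]
    if finite:
        amin = min(finite)
        for r in results:
            r.delta_aicc = r.aicc - amin if np.isfinite(r.aicc) else float("nan")
        candidates = [r for r in results if np.isfinite(r.delta_aicc)]
        best = min(candidates, key=lambda r: (
            r.delta_aicc, -r.selection_metric,
            _FC_ORDER.get(r.fc, len(r.fc)), r.rm))
    else:
        warnings.warn("AICc undefined for every combination; "
                      "selecting on auc_train - auc_diff_avg")
        best = max(results, key=lambda r: (
            r.selection_metric, -_FC_ORDER.get(r.fc, len(r.fc)), -r.rm))
    table = pd.DataFrame({
        "fc": [r.fc for r in results],
        "rm": [r.rm for r in results],
        "auc_train": [r.auc_train_mean for r in results],
        "auc_test": [r.auc_test_mean for r in results],
        "auc_diff_avg": [r.auc_diff_avg for r in results],
        "aicc": [r.aicc for r in results],
        "delta_aicc": [r.delta_aicc for r in results],
        "selection_metric": [r.selection_metric for r in results],
        "k": [r.n_parameters for r in results],
    })
    return table, best


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Share of the penalized-objective gain credited to each variable, %.

    Negative credits are floored at zero and the rest normalized to 100.
    An all-zero trace (no active feature) yields an all-zero map.
    """
    credit = {v: max(0.0, c) for v, c in model.gain_credit.items()}
    total = sum(credit.values())
    if total <= 0:
        warnings.warn("zero total training gain; contributions are all zero")
        return {v: 0.0 for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}


def permutation_importance(model: MaxentModel, occ: OccurrenceSet,
                           background: list[Cell], stack: EnvStack,
                           seed: int = 0) -> dict[str, float]:
    """AUC drop after permuting one variable across presence+background rows.

    importance_v = max(0, auc_original - auc_permuted), normalized to sum
    100 (when any drop is positive). Variables with no active feature
    score 0 without recomputation.
    """
    rng = np.random.default_rng(seed)
    pres = occurrence_cells(occ, stack.grid)
    rows = list(pres) + list(background)
    X = stack.values_at_cells(rows)
    X = X[:, [stack.names.index(v) for v in model.variable_names]]
    n_pres = len(pres)

    def auc_of(Xm: np.ndarray) -> float:
        F = feature_matrix(Xm, model.variable_names, model.spec, clamp=True)
        s = F @ model.lam
        return auc(s[:n_pres], s[n_pres:])

    base = auc_of(X)
    active = model.active_variables()
    raw_drop: dict[str, float] = {}
    for i, v in enumerate(model.variable_names):
        if v not in active:
            raw_drop[v] = 0.0
            continue
        Xp = X.copy()
        Xp[:, i] = Xp[rng.permutation(X.shape[0]), i]
        raw_drop[v] = max(0.0, base - auc_of(Xp))
    total = sum(raw_drop.values())
    if total <= 0:
        return {v: 0.0 for v in raw_drop}
    return {v: 100.0 * d / total for v, d in raw_drop.items()}


def jackknife_gains(occ: OccurrenceSet, stack: EnvStack, fc: str, rm: float,
                    background_n: int = 10000, n_knots: int = 10,
                    seed: int = 0,
                    max_iterations: int = 10000) -> tuple[dict[str, tuple[float, float]], float]:
    """Leave-one-variable-out / only-one-variable jackknife of training gain.

    For each variable v: gain of the model fitted without v and of the
    model fitted with only v, both relative to the uniform model. Returns
    (per-variable map, full-model gain).
    """
    if len(stack.names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    cells = occurrence_cells(occ, stack.grid)
    background = sample_background(stack, n=background_n, seed=seed)

    def gain_of(names: list[str]) -> float:
        sub = EnvStack({n: stack[n] for n in names})
        spec = build_features(sub, classes=fc, n_knots=n_knots,
                              background_cells=background)
        model = fit_maxent(cells, background, sub, spec, rm=rm,
                           max_iterations=max_iterations)
        return max(0.0, training_gain(model))

    full = gain_of(stack.names)
    out: dict[str, tuple[float, float]] = {}
    for v in stack.names:
        without = gain_of([n for n in stack.names if n != v])
        only = gain_of([v])
        out[v] = (without, only)
    return out, full
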