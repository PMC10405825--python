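"""Collinearity screening of candidate predictors.

Reduces a candidate environmental stack to a weakly collinear subset using
pairwise rank correlation (|r| < 0.7 by default) and variance-inflation
factors (VIF < 5 by default), both computed on the values extracted at the
occurrence cells. Which member of a correlated pair survives is decided by
a priority score — by default the univariate MaxEnt training gain of each
variable — with variable-name order as the deterministic tiebreak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import EnvStack, OccurrenceSet, occurrence_cells

#: Sentinel reported for the VIF of an exactly collinear column.
VIF_INF = np.inf


@dataclass
class ScreeningReport:
    correlation: pd.DataFrame
    vif: dict[str, float]
    kept: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)

    def summary(self) -> str:
        lines = [f"kept ({len(self.kept)}): {', '.join(self.kept)}"]
        for var, reason in self.dropped:
            lines.append(f"dropped {var}: {reason}")
        return "\n".join(lines)


def correlation_matrix(stack: EnvStack, occ: OccurrenceSet,
                       method: str = "spearman") -> pd.DataFrame:
    """Pairwise correlations between layers at the occurrence cells.

    A zero-variance column gets NaN correlations (flagged for dropping by
    the screening loop); the diagonal is always 1.
    """
    if method not in {"spearman", "pearson"}:
        raise ValueError("method must be 'spearman' or 'pearson'")
    cells = occurrence_cells(occ, stack.grid)
    if len(cells) < 3:
        raise ValueError("need at least 3 occurrence points on valid cells")
    X = stack.values_at_cells(cells)
    names = stack.names
    n = len(names)
    C = np.eye(n)
    const = X.std(axis=0) == 0
    for i in range(n):
        for j in range(i + 1, n):
            if const[i] or const[j]:
                r = np.nan
            elif method == "spearman":
                r = stats.spearmanr(X[:, i], X[:, j]).statistic
            else:
                r = stats.pearsonr(X[:, i], X[:, j]).statistic
            C[i, j] = C[j, i] = r
    return pd.DataFrame(C, index=names, columns=names)


def vif_scores(values: np.ndarray, names: list[str] | None = None) -> dict[str, float]:
    """Variance-inflation factor per column: VIF_j = 1/(1 - R^2_j).

    R^2_j is from OLS of (centered) column j on the other centered columns.
    Exact collinearity yields an infinity sentinel, never an exception.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be a 2-D points x variables matrix")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if n < p + 2:
        raise ValueError(f"need at least variables+2 = {p + 2} rows, got {n}")
    Xc = X - X.mean(axis=0)
    out: dict[str, float] = {}
    for j in range(p):
        y = Xc[:, j]
        ss_tot = float(y @ y)
        if ss_tot == 0:
            out[names[j]] = VIF_INF  # constant column: undefined, flag as collinear
            continue
        if p == 1:
            out[names[j]] = 1.0
            continue
        others = np.delete(Xc, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / ss_tot
        out[names[j]] = VIF_INF if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def screen_variables(stack: EnvStack, occ: OccurrenceSet,
                     r_max: float = 0.7, vif_max: float = 5.0,
                     priority: dict[str, float] | None = None,
                     method: str = "spearman") -> ScreeningReport:
    """Iteratively drop collinear variables until all survivors satisfy
    |r| < r_max and VIF < vif_max.

    Rule (a): for every pair at or above `r_max` (worst pair first), drop the
    lower-priority member. Rule (b): recompute VIF on the survivors and drop
    the largest-VIF variable while any VIF >= vif_max. Priority defaults to
    the univariate MaxEnt training gain; ties break by variable-name order.
    """
    corr = correlation_matrix(stack, occ, method=method)
    names = list(corr.index)
    if priority is None:
        priority = _training_gain_priority(stack, occ)
    cells = occurrence_cells(occ, stack.grid)
    X_all = stack.values_at_cells(cells)
    col_of = {n: i for i, n in enumerate(stack.names)}

    kept = list(names)
    dropped: list[tuple[str, str]] = []

    def prio_key(v: str) -> tuple[float, list[str]]:
        # higher priority wins; name order breaks ties (earlier name wins)
        return (priority.get(v, 0.0), [-ord(c) for c in v])

    # constant-at-points variables carry undefined correlations: drop first
    for v in list(kept):
        if corr.loc[v].drop(v).isna().all() and len(kept) > 1:
            kept.remove(v)
            dropped.append((v, "zero variance at occurrence cells"))

    # rule (a): pairwise correlation
    while len(kept) > 1:
        sub = corr.loc[kept, kept].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        sub = np.nan_to_num(sub, nan=1.0)  # undefined correlation treated as collinear
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < r_max:
            break
        a, b = kept[i], kept[j]
        loser = min(a, b, key=prio_key)
        kept.remove(loser)
        winner = a if loser == b else b
        dropped.append((loser, f"|r|={sub[i, j]:.3f} >= {r_max} with {winner}"))

    # rule (b): VIF elimination, one at a time
    while len(kept) > 1:
        X = X_all[:, [col_of[v] for v in kept]]
        vifs = vif_scores(X, names=kept)
        worst = max(kept, key=lambda v: (vifs[v], v))
        if vifs[worst] < vif_max:
            break
        kept.remove(worst)
        dropped.append((worst, f"VIF={vifs[worst]:.3f} >= {vif_max}"))

    if len(kept) < 2:
        warnings.warn("fewer than 2 variables survived screening")
    if len(kept) >= 1:
        X = X_all[:, [col_of[v] for v in kept]]
        final_vif = vif_scores(X, names=kept) if len(kept) > 1 else {kept[0]: 1.0}
    else:
        final_vif = {}
    return ScreeningReport(correlation=corr, vif=final_vif, kept=kept, dropped=dropped)


def _training_gain_priority(stack: EnvStack, occ: OccurrenceSet) -> dict[str, float]:
    """Univariate MaxEnt training gain of each variable (linear+quadratic)."""
    from .maxent import build_features, fit_maxent, sample_background, training_gain

    grid = stack.grid
    pres = occurrence_cells(occ, grid)
    bg = sample_background(stack, n=2000, seed=0)
    out: dict[str, float] = {}
    for name in stack.names:
        sub = EnvStack({name: stack[name]})
        spec = build_features(sub, classes="LQ")
        try:
            model = fit_maxent(pres, bg, sub, spec, rm=1.0)
            out[name] = training_gain(model)
        except Exception:
            out[name] = 0.0
    return out
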