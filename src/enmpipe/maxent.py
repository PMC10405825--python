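"""Regularized maximum-entropy species distribution model, from scratch.

The model estimates a Gibbs distribution over background cells,
``raw(x) = exp(lambda . f(x)) / Z``, whose feature expectations match the
presence sample, subject to an L1 penalty. Fitting maximizes the penalized
log-likelihood

    (1/m) sum_presences lambda . f(x_i)  -  ln Z_lambda
        -  sum_j beta_j |lambda_j|

by cyclic coordinate descent with soft-thresholding and backtracking, so
the objective is non-decreasing across updates. ``beta_j`` follows the
MaxEnt convention ``rm * beta_class(m) * sd_j(presences) / sqrt(m)`` where
``beta_class`` interpolates published default anchors in the presence count
m, and ``rm`` is the user's regularization multiplier.

Features are the five classic classes over min-max-scaled variables:
Linear, Quadratic, Product, Hinge (forward and reverse, at background
quantile knots), Threshold. Output is either the raw density or the
logistic transform ``e^H raw / (1 + e^H raw)`` with H the entropy of the
fitted background distribution (prevalence 0.5 convention).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .geodata import EnvStack, Grid

Cell = tuple[int, int]

FEATURE_CLASSES = "LQPHT"

# beta_class(m) anchor tables: piecewise-linear in presence count m,
# clamped outside the anchor range.
_BETA_ANCHORS = {
    "L": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "Q": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "P": ([10.0, 30.0, 100.0], [1.0, 0.2, 0.05]),
    "H": ([0.0, 100.0], [0.5, 0.5]),
    "T": ([0.0, 100.0], [2.0, 1.0]),
}


def beta_class(cls: str, m: int) -> float:
    """Default regularization level for a feature class at presence count m."""
    xs, ys = _BETA_ANCHORS[cls]
    return float(np.interp(float(m), xs, ys))


@dataclass(frozen=True)
class Feature:
    """One derived feature: its label, class, parent variable(s), knot."""

    label: str
    cls: str              # one of L Q P H T; H splits into hinge/reverse-hinge
    variables: tuple[str, ...]
    knot: float | None = None
    reverse: bool = False  # reverse hinge


@dataclass
class FeatureSpec:
    """Feature expansion recipe: classes, per-variable scaling bounds, knots."""

    classes: str
    variables: list[str]
    bounds: dict[str, tuple[float, float]]
    knots: dict[str, np.ndarray]
    features: list[Feature]

    def __post_init__(self) -> None:
        for v, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError(f"invalid scaling bounds for {v}: ({lo}, {hi})")
        for v, k in self.knots.items():
            if len(k) > 1 and not np.all(np.diff(k) > 0):
                raise ValueError(f"knots for {v} must be strictly increasing")
        labels = [f.label for f in self.features]
        if len(labels) != len(set(labels)):
            raise ValueError("feature labels must be unique")

    @property
    def n_features(self) -> int:
        return len(self.features)


def build_features(stack: EnvStack, classes: str, n_knots: int = 30,
                   background_cells: Sequence[Cell] | None = None) -> FeatureSpec:
    """Construct the feature expansion for `classes` (subset of "LQPHT").

    Scaling bounds are the background min/max of each variable; hinge and
    threshold knots sit at evenly spaced interior background quantiles.
    Constant variables get no nonlinear features (with a warning).
    """
    classes = "".join(c for c in FEATURE_CLASSES if c in classes.upper())
    if not classes:
        raise ValueError("classes must be a non-empty subset of 'LQPHT'")
    names = stack.names
    if background_cells is None:
        X = np.column_stack([stack[n].values[stack.mask] for n in names])
    else:
        X = stack.values_at_cells(background_cells)
    bounds: dict[str, tuple[float, float]] = {}
    knots: dict[str, np.ndarray] = {}
    constant: set[str] = set()
    for j, name in enumerate(names):
        lo, hi = float(np.nanmin(X[:, j])), float(np.nanmax(X[:, j]))
        if hi <= lo:
            constant.add(name)
            warnings.warn(f"variable {name} is constant on the background; "
                          "skipping its features")
            bounds[name] = (lo, lo + 1.0)  # placeholder, features skipped
            knots[name] = np.array([])
            continue
        bounds[name] = (lo, hi)
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        k = np.unique(np.quantile(X[:, j], qs))
        k = k[(k > lo) & (k < hi)]
        knots[name] = k
    feats: list[Feature] = []
    active = [n for n in names if n not in constant]
    if "L" in classes:
        feats += [Feature(f"L({v})", "L", (v,)) for v in active]
    if "Q" in classes:
        feats += [Feature(f"Q({v})", "Q", (v,)) for v in active]
    if "P" in classes:
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                feats.append(Feature(f"P({active[a]}*{active[b]})", "P",
                                     (active[a], active[b])))
    if "H" in classes:
        for v in active:
            for k in knots[v]:
                feats.append(Feature(f"H({v}>{k:.6g})", "H", (v,), knot=float(k)))
                feats.append(Feature(f"H'({v}<{k:.6g})", "H", (v,), knot=float(k),
                                     reverse=True))
    if "T" in classes:
        for v in active:
            for k in knots[v]:
                feats.append(Feature(f"T({v}>{k:.6g})", "T", (v,), knot=float(k)))
    return FeatureSpec(classes=classes, variables=list(names), bounds=bounds,
                       knots=knots, features=feats)


def feature_matrix(X: np.ndarray, names: Sequence[str], spec: FeatureSpec,
                   clamp: bool = True) -> np.ndarray:
    """Evaluate all features on raw variable values X (n_points x n_vars).

    With `clamp`, raw values are clipped to the training bounds first
    (MaxEnt's projection-time clamping). All features lie in [0, 1] on the
    training background by construction.
    """
    col = {n: i for i, n in enumerate(names)}
    n = X.shape[0]
    raw: dict[str, np.ndarray] = {}
    scaled: dict[str, np.ndarray] = {}
    for v in spec.variables:
        x = X[:, col[v]].astype(float)
        lo, hi = spec.bounds[v]
        if clamp:
            x = np.clip(x, lo, hi)
        raw[v] = x
        scaled[v] = (x - lo) / (hi - lo)
    F = np.empty((n, spec.n_features), order="F")
    for j, f in enumerate(spec.features):
        if f.cls == "L":
            F[:, j] = scaled[f.variables[0]]
        elif f.cls == "Q":
            F[:, j] = scaled[f.variables[0]] ** 2
        elif f.cls == "P":
            F[:, j] = scaled[f.variables[0]] * scaled[f.variables[1]]
        elif f.cls == "H":
            v = f.variables[0]
            lo, hi = spec.bounds[v]
            if f.reverse:
                F[:, j] = np.maximum(0.0, (f.knot - raw[v]) / (f.knot - lo)) \
                    if f.knot > lo else 0.0
            else:
                F[:, j] = np.maximum(0.0, (raw[v] - f.knot) / (hi - f.knot)) \
                    if f.knot < hi else 0.0
        elif f.cls == "T":
            F[:, j] = (raw[f.variables[0]] > f.knot).astype(float)
        else:  # pragma: no cover
            raise ValueError(f"unknown feature class {f.cls}")
    return F


def sample_background(stack: EnvStack, n: int = 10000, seed: int = 0) -> list[Cell]:
    """Uniform sample (without replacement) of valid cells; all if n exceeds them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cells = stack.valid_cells()
    if not cells:
        raise ValueError("stack has no valid cells")
    if n >= len(cells):
        return cells
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cells), size=n, replace=False)
    return [cells[i] for i in sorted(idx.tolist())]


@dataclass
class MaxentModel:
    spec: FeatureSpec
    variable_names: list[str]
    lam: np.ndarray                  # coefficients, one per feature
    log_partition: float             # lnZ over the estimation background
    entropy: float                   # H of the fitted background distribution
    rm: float
    beta: np.ndarray                 # per-feature L1 penalty weights
    background_cells: list[Cell]
    presence_feature_mean: np.ndarray
    n_presences: int
    iterations: int = 0
    objective: float = float("nan")
    gain_credit: dict[str, float] = field(default_factory=dict)

    @property
    def active_features(self) -> list[Feature]:
        return [f for f, l in zip(self.spec.features, self.lam) if l != 0.0]

    def active_variables(self) -> set[str]:
        out: set[str] = set()
        for f in self.active_features:
            out.update(f.variables)
        return out

    @property
    def n_parameters(self) -> int:
        return int(np.count_nonzero(self.lam))

    # -- serialization (structured text, exact round-trip via repr) ---------

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("enmpipe-maxent-model v1\n")
        buf.write(f"rm {self.rm!r}\n")
        buf.write(f"lnZ {self.log_partition!r}\n")
        buf.write(f"entropy {self.entropy!r}\n")
        buf.write(f"n_presences {self.n_presences}\n")
        buf.write(f"classes {self.spec.classes}\n")
        buf.write(f"variables {','.join(self.variable_names)}\n")
        for v in self.spec.variables:
            lo, hi = self.spec.bounds[v]
            ks = ",".join(repr(float(k)) for k in self.spec.knots[v])
            buf.write(f"var {v} {lo!r} {hi!r} [{ks}]\n")
        for f, l, b in zip(self.spec.features, self.lam, self.beta):
            knot = repr(f.knot) if f.knot is not None else "-"
            rev = "1" if f.reverse else "0"
            buf.write(f"feature\t{f.label}\t{f.cls}\t{'|'.join(f.variables)}"
                      f"\t{knot}\t{rev}\t{float(l)!r}\t{float(b)!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "MaxentModel":
        lines = text.strip().split("\n")
        if lines[0] != "enmpipe-maxent-model v1":
            raise ValueError("not an enmpipe model file")
        head: dict[str, str] = {}
        bounds: dict[str, tuple[float, float]] = {}
        knots: dict[str, np.ndarray] = {}
        feats: list[Feature] = []
        lam: list[float] = []
        beta: list[float] = []
        for line in lines[1:]:
            if line.startswith("feature\t"):
                _, label, fcls, vars_, knot, rev, l, b = line.split("\t")
                feats.append(Feature(label, fcls, tuple(vars_.split("|")),
                                     None if knot == "-" else float(knot),
                                     rev == "1"))
                lam.append(float(l))
                beta.append(float(b))
            elif line.startswith("var "):
                _, v, lo, hi, ks = line.split(" ", 4)
                bounds[v] = (float(lo), float(hi))
                inner = ks.strip()[1:-1]
                knots[v] = np.array([float(t) for t in inner.split(",") if t])
            else:
                k, _, v = line.partition(" ")
                head[k] = v
        variables = head["variables"].split(",")
        spec = FeatureSpec(classes=head["classes"], variables=variables,
                           bounds=bounds, knots=knots, features=feats)
        return cls(spec=spec, variable_names=variables,
                   lam=np.array(lam), log_partition=float(head["lnZ"]),
                   entropy=float(head["entropy"]), rm=float(head["rm"]),
                   beta=np.array(beta), background_cells=[],
                   presence_feature_mean=np.zeros(len(lam)),
                   n_presences=int(head["n_presences"]))


def penalized_objective(lam: np.ndarray, F_bg: np.ndarray, p_mean: np.ndarray,
                        beta: np.ndarray) -> float:
    """(1/m) sum lambda.f(presence) - lnZ - sum beta|lambda|, for any lambda."""
    eta = F_bg @ lam
    return float(p_mean @ lam - logsumexp(eta) - beta @ np.abs(lam))


def fit_maxent(presence_cells: Sequence[Cell], background_cells: Sequence[Cell],
               stack: EnvStack, spec: FeatureSpec, rm: float = 1.0,
               max_iterations: int = 10000, tolerance: float = 1e-5,
               track_gain: bool = True) -> MaxentModel:
    """Fit the L1-penalized maxent model by cyclic coordinate descent.

    Presence cells are added to the estimation background (standard
    practice). One iteration = one coordinate update; convergence when the
    relative objective change over a full sweep drops below `tolerance`.
    Each accepted update's objective gain is credited to the updated
    feature's parent variable(s) for the percent-contribution report.
    """
    presence_cells = list(presence_cells)
    if not presence_cells:
        raise ValueError("at least one presence cell is required")
    m = len(presence_cells)
    bg = list(dict.fromkeys(list(background_cells) + list(dict.fromkeys(presence_cells))))
    X_bg = stack.values_at_cells(bg)
    X_pres = stack.values_at_cells(presence_cells)
    F_bg = feature_matrix(X_bg, stack.names, spec, clamp=True)
    F_pres = feature_matrix(X_pres, stack.names, spec, clamp=True)
    p_mean = F_pres.mean(axis=0)
    p_sd = F_pres.std(axis=0)

    J = spec.n_features
    beta = np.empty(J)
    for j, f in enumerate(spec.features):
        beta[j] = rm * beta_class(f.cls, m) * max(p_sd[j], 1e-4) / np.sqrt(m)

    lam = np.zeros(J)
    N = F_bg.shape[0]
    eta = np.zeros(N)
    lnZ = np.log(N)
    obj = float(p_mean @ lam - lnZ)
    gain_credit: dict[str, float] = {v: 0.0 for v in stack.names}

    it = 0
    converged = False
    w = np.full(N, 1.0 / N)  # fitted background distribution, kept in sync
    while it < max_iterations and not converged:
        obj_sweep_start = obj
        for j in range(J):
            if it >= max_iterations:
                break
            it += 1
            fj = F_bg[:, j]
            Ew = float(w @ fj)
            g = p_mean[j] - Ew
            h = float(w @ (fj * fj)) - Ew * Ew
            h = max(h, 1e-8)
            z = lam[j] + g / h
            thr = beta[j] / h
            lam_new = np.sign(z) * max(abs(z) - thr, 0.0)
            delta = np.clip(lam_new - lam[j], -5.0, 5.0)
            if delta == 0.0:
                continue
            # backtracking to guarantee a non-decreasing objective
            pen_old = beta[j] * abs(lam[j])
            accepted = False
            for _ in range(30):
                cand = lam[j] + delta
                ratio = float(w @ np.exp(delta * fj))  # Z_new / Z_old
                lnZ_new = lnZ + np.log(ratio)
                obj_new = obj + p_mean[j] * delta - np.log(ratio) \
                    - beta[j] * abs(cand) + pen_old
                if obj_new >= obj - 1e-12:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-12:
                    break
            if not accepted:
                continue
            if not np.isfinite(obj_new):
                raise ArithmeticError(
                    f"maxent objective diverged at iteration {it} "
                    f"(feature {spec.features[j].label}, lambda={lam[j] + delta:.3g})")
            inc = obj_new - obj
            lam[j] += delta
            eta = eta + delta * fj
            lnZ = lnZ_new
            obj = obj_new
            w = w * np.exp(delta * fj) / ratio
            if track_gain and inc > 0:
                share = inc / len(spec.features[j].variables)
                for v in spec.features[j].variables:
                    gain_credit[v] += share
        # resync against incremental drift once per sweep
        lnZ = float(logsumexp(eta))
        w = np.exp(eta - lnZ)
        obj = float(p_mean @ lam - lnZ - beta @ np.abs(lam))
        denom = max(abs(obj), 1.0)
        if abs(obj - obj_sweep_start) / denom < tolerance:
            converged = True

    entropy = float(-np.sum(w * (eta - lnZ)))
    return MaxentModel(spec=spec, variable_names=list(stack.names), lam=lam,
                       log_partition=lnZ, entropy=entropy, rm=rm, beta=beta,
                       background_cells=bg, presence_feature_mean=p_mean,
                       n_presences=m, iterations=it, objective=obj,
                       gain_credit=gain_credit)


def training_gain(model: MaxentModel) -> float:
    """Unpenalized training gain relative to the uniform background model.

    gain = (1/m) sum lambda.f(presence) - lnZ + ln(N_background); 0 for the
    null model and increasing as presences concentrate where raw is high.
    """
    n_bg = len(model.background_cells)
    return float(model.presence_feature_mean @ model.lam
                 - model.log_partition + np.log(n_bg))


@dataclass
class SuitabilityMap:
    grid: Grid
    output_kind: str  # "raw" | "logistic"


def predict(model: MaxentModel, stack: EnvStack,
            output_kind: str = "logistic") -> SuitabilityMap:
    """Project the model over a stack; raw density or logistic suitability.

    Variables outside the training range are clamped. ``raw`` uses the
    training lnZ, so it sums to 1 when the prediction domain equals the
    estimation background. ``logistic`` is e^H raw/(1 + e^H raw).
    """
    if output_kind not in {"raw", "logistic"}:
        raise ValueError("output_kind must be 'raw' or 'logistic'")
    missing = set(model.spec.variables) - set(stack.names)
    if missing:
        raise KeyError(f"stack lacks model variable(s): {sorted(missing)}")
    ref = stack.grid
    mask = stack.mask
    rr, cc = np.nonzero(mask)
    X = np.column_stack([stack[v].values[rr, cc] for v in model.variable_names])
    F = feature_matrix(X, model.variable_names, model.spec, clamp=True)
    log_raw = F @ model.lam - model.log_partition
    out = np.full((ref.n_rows, ref.n_cols), np.nan)
    if output_kind == "raw":
        out[rr, cc] = np.exp(log_raw)
    else:
        s = model.entropy + log_raw
        out[rr, cc] = 1.0 / (1.0 + np.exp(-s))
    return SuitabilityMap(grid=ref.copy(values=out), output_kind=output_kind)


def predict_scores(model: MaxentModel, stack: EnvStack,
                   cells: Sequence[Cell], output_kind: str = "raw") -> np.ndarray:
    """Model scores at specific cells (vector), same conventions as predict."""
    X = stack.values_at_cells(cells)
    X = X[:, [stack.names.index(v) for v in model.variable_names]]
    F = feature_matrix(X, model.variable_names, model.spec, clamp=True)
    log_raw = F @ model.lam - model.log_partition
    if output_kind == "raw":
        return np.exp(log_raw)
    s = model.entropy + log_raw
    return 1.0 / (1.0 + np.exp(-s))


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank-based AUC: P(random presence outscores random background), ties 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def response_curve(model: MaxentModel, stack: EnvStack, variable: str,
                   n_points: int = 100) -> list[tuple[float, float]]:
    """Single-variable response: sweep `variable` over its background range
    holding all other variables at their background means; logistic output."""
    if variable not in model.spec.variables:
        raise KeyError(f"unknown variable {variable!r}")
    cells = model.background_cells or stack.valid_cells()
    X_bg = stack.values_at_cells(cells)
    X_bg = X_bg[:, [stack.names.index(v) for v in model.variable_names]]
    means = X_bg.mean(axis=0)
    lo, hi = model.spec.bounds[variable]
    sweep = np.linspace(lo, hi, n_points)
    X = np.tile(means, (n_points, 1))
    X[:, model.variable_names.index(variable)] = sweep
    F = feature_matrix(X, model.variable_names, model.spec, clamp=True)
    s = model.entropy + F @ model.lam - model.log_partition
    y = 1.0 / (1.0 + np.exp(-s))
    return list(zip(sweep.tolist(), y.tolist()))
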