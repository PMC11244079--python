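"""Stepwise linear discriminant analysis with Wilks'-lambda F criteria.

Implements the classical stepwise variable selection for LDA:
at each step the candidate with the largest F-to-enter is added if it exceeds
the entry criterion (default F > 3.84), after first removing any in-model
variable whose F-to-remove has dropped below the removal criterion (default
F < 2.71).  A tolerance floor (1 - R^2 of a candidate regressed within groups
on the in-model variables) guards against collinearity.  Classification uses
Fisher's linear classification functions

    C_j(x) = mu_j' W^{-1} x - 1/2 mu_j' W^{-1} mu_j + ln pi_j

with W the pooled within-class covariance, and leave-one-out cross-validation
re-estimates the group means and pooled covariance without each case while
holding the selected variable subset fixed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabelledFeatures",
    "StepEvent",
    "LDAModel",
    "ClassificationResult",
    "LOOCVResult",
    "wilks_lambda",
    "f_to_enter",
    "f_to_remove",
    "tolerance",
    "stepwise_select",
    "fit_lda",
    "classify",
    "loocv",
]

#: Stepwise thresholds: the conventional defaults of classical stepwise LDA.
F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71
TOLERANCE_MIN_DEFAULT = 0.001
#: Pooled covariance condition numbers above this are treated as singular.
CONDITION_LIMIT = 1e12


@dataclass
class LabelledFeatures:
    """Feature matrix with group labels.

    ``y`` may hold any hashable labels; groups are ordered by sorted unique
    label, and that order defines the deterministic tie-break in
    classification (lowest group index wins).
    """

    X: np.ndarray
    y: np.ndarray
    sample_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if self.sample_ids is None:
            self.sample_ids = np.arange(len(self.X))
        else:
            self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def groups(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _group_indices(data: LabelledFeatures) -> List[np.ndarray]:
    return [np.flatnonzero(data.y == g) for g in data.groups]


def _sscp(data: LabelledFeatures) -> Tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices on mean-centred data."""
    X = data.X
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for idx in _group_indices(data):
        G = X[idx] - X[idx].mean(axis=0)
        W += G.T @ G
    return W, T


def wilks_lambda(data: LabelledFeatures, subset: Sequence[int]) -> float:
    """Wilks' lambda det(W)/det(T) on a feature subset; 0 < lambda <= 1."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    W, T = _sscp(data)
    Ws = W[np.ix_(subset, subset)]
    Ts = T[np.ix_(subset, subset)]
    sign_t, logdet_t = np.linalg.slogdet(Ts)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise np.linalg.LinAlgError("singular total SSCP on subset")
    sign_w, logdet_w = np.linalg.slogdet(Ws)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def _wilks_from_sscp(W: np.ndarray, T: np.ndarray, subset: Sequence[int]) -> float:
    subset = list(subset)
    Ws = W[np.ix_(subset, subset)]
    Ts = T[np.ix_(subset, subset)]
    sign_t, logdet_t = np.linalg.slogdet(Ts)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise np.linalg.LinAlgError("singular total SSCP on subset")
    sign_w, logdet_w = np.linalg.slogdet(Ws)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def _partial_f(
    lam_small: float, lam_large: float, n: int, g: int, p_small: int
) -> float:
    """Partial F for growing a p_small-variable model by one variable."""
    df2 = n - g - p_small
    if df2 <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    if lam_large <= 0:
        return np.inf
    return (df2 / (g - 1)) * (lam_small / lam_large - 1.0)


def f_to_enter(
    data: LabelledFeatures, in_model: Sequence[int], candidate: int
) -> float:
    """Partial F for adding ``candidate`` to the current model.

    F = ((n - g - p) / (g - 1)) * (Lambda_p / Lambda_{p+1} - 1), with
    Lambda_0 = 1 for the empty model.
    """
    in_model = list(in_model)
    if candidate in in_model:
        raise ValueError("candidate already in model")
    W, T = _sscp(data)
    lam_p = _wilks_from_sscp(W, T, in_model) if in_model else 1.0
    lam_p1 = _wilks_from_sscp(W, T, in_model + [candidate])
    return _partial_f(lam_p, lam_p1, data.n, data.n_groups, len(in_model))


def f_to_remove(
    data: LabelledFeatures, in_model: Sequence[int], variable: int
) -> float:
    """Partial F for dropping ``variable`` from the current model."""
    in_model = list(in_model)
    if variable not in in_model:
        raise ValueError("variable not in model")
    rest = [v for v in in_model if v != variable]
    W, T = _sscp(data)
    lam_rest = _wilks_from_sscp(W, T, rest) if rest else 1.0
    lam_full = _wilks_from_sscp(W, T, in_model)
    return _partial_f(lam_rest, lam_full, data.n, data.n_groups, len(rest))


def tolerance(
    data: LabelledFeatures, in_model: Sequence[int], candidate: int
) -> float:
    """1 - R^2 of the candidate's within-group regression on the model."""
    in_model = list(in_model)
    if not in_model:
        return 1.0
    W, _ = _sscp(data)
    wcc = W[candidate, candidate]
    if wcc <= 0:
        return 0.0
    wxx = W[np.ix_(in_model, in_model)]
    wxc = W[in_model, candidate]
    try:
        r2 = float(wxc @ np.linalg.solve(wxx, wxc)) / wcc
    except np.linalg.LinAlgError:
        return 0.0
    return max(0.0, 1.0 - r2)


@dataclass
class StepEvent:
    step: int
    action: str  # "enter" | "remove" | "warning"
    variable: Optional[int]
    f_statistic: Optional[float]
    wilks: Optional[float]
    tolerance: Optional[float]
    message: str = ""


def trace_to_frame(trace: Sequence[StepEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in trace])


def stepwise_select(
    data: LabelledFeatures,
    f_enter: float = F_ENTER_DEFAULT,
    f_remove: float = F_REMOVE_DEFAULT,
    tolerance_min: float = TOLERANCE_MIN_DEFAULT,
    max_steps: Optional[int] = None,
) -> Tuple[List[int], List[StepEvent]]:
    """Stepwise variable selection by Wilks'-lambda partial F statistics.

    Each iteration first removes the in-model variable with the smallest
    F-to-remove if that F is strictly below ``f_remove``; otherwise it enters
    the candidate with the largest F-to-enter if that F is strictly above
    ``f_enter`` (candidates below the tolerance floor are ineligible).  The
    procedure stops when neither action applies, when residual degrees of
    freedom are exhausted, or if a model state repeats (cycling).
    """
    W, T = _sscp(data)
    n, g = data.n, data.n_groups
    if n <= g:
        raise ValueError("need more samples than groups")
    selected: List[int] = []
    trace: List[StepEvent] = []
    visited = {frozenset()}
    if max_steps is None:
        max_steps = 4 * data.p + 10
    step = 0

    def tol(candidate: int, model: List[int]) -> float:
        if not model:
            return 1.0
        wcc = W[candidate, candidate]
        if wcc <= 0:
            return 0.0
        wxx = W[np.ix_(model, model)]
        wxc = W[model, candidate]
        try:
            r2 = float(wxc @ np.linalg.solve(wxx, wxc)) / wcc
        except np.linalg.LinAlgError:
            return 0.0
        return max(0.0, 1.0 - r2)

    while step < max_steps:
        step += 1
        acted = False
        # (a) removal pass
        if selected:
            lam_full = _wilks_from_sscp(W, T, selected)
            worst_var, worst_f = None, np.inf
            for v in selected:
                rest = [u for u in selected if u != v]
                lam_rest = _wilks_from_sscp(W, T, rest) if rest else 1.0
                f = _partial_f(lam_rest, lam_full, n, g, len(rest))
                if f < worst_f:
                    worst_var, worst_f = v, f
            if worst_f < f_remove:
                selected.remove(worst_var)
                lam_after = (
                    _wilks_from_sscp(W, T, selected) if selected else 1.0
                )
                trace.append(
                    StepEvent(step, "remove", worst_var, worst_f, lam_after, None)
                )
                acted = True
        # (b) entry pass
        if not acted:
            p = len(selected)
            if n - g - p <= 0:
                trace.append(
                    StepEvent(
                        step, "warning", None, None, None, None,
                        "residual degrees of freedom exhausted",
                    )
                )
                break
            lam_p = _wilks_from_sscp(W, T, selected) if selected else 1.0
            best_var, best_f, best_lam, best_tol = None, -np.inf, None, None
            for j in range(data.p):
                if j in selected:
                    continue
                tj = tol(j, selected)
                if tj < tolerance_min:
                    continue
                try:
                    lam_j = _wilks_from_sscp(W, T, selected + [j])
                except np.linalg.LinAlgError:
                    continue
                f = _partial_f(lam_p, lam_j, n, g, p)
                if f > best_f:
                    best_var, best_f, best_lam, best_tol = j, f, lam_j, tj
            if best_var is not None and best_f > f_enter:
                selected.append(best_var)
                trace.append(
                    StepEvent(step, "enter", best_var, best_f, best_lam, best_tol)
                )
                acted = True
        if not acted:
            break
        state = frozenset(selected)
        if state in visited:
            trace.append(
                StepEvent(
                    step, "warning", None, None, None, None,
                    "cycling detected; selection stopped",
                )
            )
            logger.warning("stepwise selection cycling detected; stopping")
            break
        visited.add(state)
    return selected, trace


@dataclass
class LDAModel:
    """Fitted linear discriminant model on a selected feature subset."""

    selected: List[int]
    groups: np.ndarray
    group_means: np.ndarray  # (g, |selected|)
    pooled_cov: np.ndarray  # (|selected|, |selected|)
    priors: np.ndarray  # (g,)
    coef: np.ndarray  # (g, |selected|) classification-function slopes
    const: np.ndarray  # (g,) classification-function constants
    n_features_in: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected": list(map(int, self.selected)),
                "groups": [str(g) for g in self.groups],
                "group_means": self.group_means.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "priors": self.priors.tolist(),
                "coef": self.coef.tolist(),
                "const": self.const.tolist(),
                "n_features_in": int(self.n_features_in),
            },
            indent=1,
        )


def _resolve_priors(
    priors: Union[str, Sequence[float]], counts: np.ndarray
) -> np.ndarray:
    g = len(counts)
    if isinstance(priors, str):
        if priors == "equal":
            pr = np.full(g, 1.0 / g)
        elif priors == "proportional":
            pr = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors {priors!r}")
    else:
        pr = np.asarray(priors, dtype=float)
        if len(pr) != g or np.any(pr < 0):
            raise ValueError("priors must be g non-negative values")
        pr = pr / pr.sum()
    return pr


def fit_lda(
    data: LabelledFeatures,
    selected: Optional[Sequence[int]] = None,
    priors: Union[str, Sequence[float]] = "equal",
) -> LDAModel:
    """Fit classification functions on the selected feature subset.

    The pooled within-class covariance is W / (n - g) with W the within-group
    SSCP.  A condition number above ``CONDITION_LIMIT`` is reported as an
    error (use fewer features or more samples) rather than being silently
    regularised.
    """
    if selected is None:
        selected = list(range(data.p))
    selected = list(selected)
    groups = data.groups
    g = len(groups)
    idx_by_group = _group_indices(data)
    counts = np.array([len(i) for i in idx_by_group], dtype=float)
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members for fitting")
    pr = _resolve_priors(priors, counts)
    k = len(selected)
    Xs = data.X[:, selected]
    means = np.vstack([Xs[idx].mean(axis=0) for idx in idx_by_group])
    if k == 0:
        return LDAModel(
            selected=[],
            groups=groups,
            group_means=means.reshape(g, 0),
            pooled_cov=np.zeros((0, 0)),
            priors=pr,
            coef=np.zeros((g, 0)),
            const=np.log(pr),
            n_features_in=data.p,
        )
    W = np.zeros((k, k))
    for idx, mu in zip(idx_by_group, means):
        G = Xs[idx] - mu
        W += G.T @ G
    pooled = W / (data.n - g)
    if np.linalg.cond(pooled) > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular or ill-conditioned; "
            "select fewer features or provide more samples per group"
        )
    coef = np.linalg.solve(pooled, means.T).T  # (g, k)
    const = -0.5 * np.einsum("gk,gk->g", coef, means) + np.log(pr)
    return LDAModel(
        selected=selected,
        groups=groups,
        group_means=means,
        pooled_cov=pooled,
        priors=pr,
        coef=coef,
        const=const,
        n_features_in=data.p,
    )


@dataclass
class ClassificationResult:
    labels: np.ndarray  # object array; None for excluded samples
    scores: np.ndarray  # (m, g) classification-function values
    posteriors: np.ndarray  # (m, g) softmax of scores
    excluded: List[int] = field(default_factory=list)


def classify(model: LDAModel, X: np.ndarray) -> ClassificationResult:
    """Assign each row of ``X`` by the maximal classification function.

    Ties are broken deterministically toward the lowest group index.  Rows
    with missing or non-finite selected features are excluded from the
    assignment (label None, NaN scores) and logged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.n_features_in and X.shape[1] != model.n_features_in:
        raise ValueError(
            f"expected {model.n_features_in} features, got {X.shape[1]}"
        )
    Xs = X[:, model.selected] if model.selected else X[:, :0]
    m, g = len(Xs), len(model.groups)
    scores = np.full((m, g), np.nan)
    posteriors = np.full((m, g), np.nan)
    labels = np.empty(m, dtype=object)
    labels[:] = None
    ok = np.all(np.isfinite(Xs), axis=1)
    excluded = [int(i) for i in np.flatnonzero(~ok)]
    for i in excluded:
        logger.warning("sample %d has non-finite features; excluded", i)
    if ok.any():
        s = Xs[ok] @ model.coef.T + model.const
        scores[ok] = s
        e = np.exp(s - s.max(axis=1, keepdims=True))
        posteriors[ok] = e / e.sum(axis=1, keepdims=True)
        labels[ok] = model.groups[np.argmax(s, axis=1)]
    return ClassificationResult(labels, scores, posteriors, excluded)


@dataclass
class LOOCVResult:
    accuracy: float
    confusion: pd.DataFrame  # true (rows) x assigned (columns)
    assigned: np.ndarray


def loocv(
    data: LabelledFeatures,
    selected: Optional[Sequence[int]] = None,
    priors: Union[str, Sequence[float]] = "equal",
    reselect: bool = False,
    **stepwise_kwargs,
) -> LOOCVResult:
    """Leave-one-out cross-validation with the variable subset held fixed.

    For each case the group means and pooled within-class covariance are
    recomputed without that case (rank-one downdate of the within-group SSCP)
    and the case is classified by the classification functions of the reduced
    fit.  This matches refitting from scratch per case exactly, up to
    floating-point roundoff.

    With ``reselect=True`` the stepwise selection itself is repeated inside
    every fold (``stepwise_kwargs`` forwarded) — a much slower sensitivity
    analysis of selection stability; ``selected`` is then ignored.
    """
    if reselect:
        return _loocv_reselect(data, priors, **stepwise_kwargs)
    if selected is None:
        selected = list(range(data.p))
    selected = list(selected)
    groups = data.groups
    g = len(groups)
    Xs = data.X[:, selected]
    n, k = Xs.shape
    idx_by_group = _group_indices(data)
    counts = np.array([len(i) for i in idx_by_group])
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    pr = _resolve_priors(priors, counts.astype(float))
    log_pr = np.log(pr)
    group_of = np.empty(n, dtype=int)
    for j, idx in enumerate(idx_by_group):
        group_of[idx] = j
    means = np.vstack([Xs[idx].mean(axis=0) for idx in idx_by_group])
    W = np.zeros((k, k))
    for idx, mu in zip(idx_by_group, means):
        G = Xs[idx] - mu
        W += G.T @ G

    assigned = np.empty(n, dtype=object)
    if k == 0:
        assigned[:] = groups[int(np.argmax(log_pr))]
    else:
        for i in range(n):
            gi = group_of[i]
            ng = counts[gi]
            x = Xs[i]
            d = x - means[gi]
            mu_i = (ng * means[gi] - x) / (ng - 1)
            W_i = W - (ng / (ng - 1)) * np.outer(d, d)
            pooled = W_i / (n - 1 - g)
            means_i = means.copy()
            means_i[gi] = mu_i
            try:
                coef = np.linalg.solve(pooled, means_i.T).T
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"pooled covariance singular when case {i} is deleted"
                ) from exc
            if not np.all(np.isfinite(coef)):
                raise np.linalg.LinAlgError(
                    f"pooled covariance singular when case {i} is deleted"
                )
            s = coef @ x - 0.5 * np.einsum("gk,gk->g", coef, means_i) + log_pr
            assigned[i] = groups[int(np.argmax(s))]

    return _loocv_result(data, assigned)


def _loocv_reselect(
    data: LabelledFeatures, priors, **stepwise_kwargs
) -> LOOCVResult:
    assigned = np.empty(data.n, dtype=object)
    for i in range(data.n):
        keep = np.arange(data.n) != i
        sub = LabelledFeatures(
            data.X[keep], data.y[keep], data.sample_ids[keep]
        )
        sel_i, _ = stepwise_select(sub, **stepwise_kwargs)
        model = fit_lda(sub, sel_i, priors)
        assigned[i] = classify(model, data.X[i : i + 1]).labels[0]
    return _loocv_result(data, assigned)


def _loocv_result(data: LabelledFeatures, assigned: np.ndarray) -> LOOCVResult:
    n = data.n
    groups = data.groups
    correct = np.array([assigned[i] == data.y[i] for i in range(n)])
    confusion = pd.crosstab(
        pd.Series(data.y, name="true"),
        pd.Series(assigned, name="assigned"),
        dropna=False,
    ).reindex(index=groups, columns=groups, fill_value=0)
    return LOOCVResult(float(correct.mean()), confusion, assigned)
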