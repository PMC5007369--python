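"""Multivariate adaptive regression splines (MARS) for group classification.

MARS builds a piecewise-linear regression in two stages.  The forward
pass greedily grows an overly large model: at each step it scans every
(variable, knot) pair — knots are observed data values — and adds the
reflected hinge pair ``max(0, x - k)`` / ``max(0, k - x)`` that most
reduces the residual sum of squares of the least-squares fit.  The
backward pass then deletes basis functions one at a time, always removing
the weakest contributor, and returns the model in that nested sequence
minimising the generalized cross-validation score

    GCV(M) = (RSS / n) / (1 - C(M) / n)^2,
    C(M)   = #coefficients + penalty * #knots,

with ``penalty = 2`` for additive models.  Classification of a binary
0/1 outcome is done by least-squares regression on the labels with a 0.5
score threshold (classic MARS classification).

Per-variable importance is the increase in GCV caused by removing all of
a variable's basis functions from the fitted model, rescaled so the top
variable scores 100.

Validation supports stratified 10-fold cross-validation (out-of-fold
scores pooled into one test ROC) and a stratified 80/20 train/test
split; ROC curves and AUC come from scikit-learn and equal the
Mann–Whitney concordance probability with ties counted 1/2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ValidationError

__all__ = [
    "HingeBasis",
    "MARS",
    "MARSResults",
    "ValidationResult",
    "mars_forward",
    "mars_backward",
    "variable_importance",
    "validate",
    "roc_auc",
]

_EPS = 1e-10


@dataclass(frozen=True)
class HingeBasis:
    """Product of hinge factors; the empty product is the intercept.

    Each factor is ``(variable, knot, direction)`` with direction +1 for
    ``max(0, x - knot)`` and -1 for ``max(0, knot - x)``.
    """

    factors: tuple[tuple[int, float, int], ...] = ()

    @property
    def is_intercept(self) -> bool:
        return len(self.factors) == 0

    @property
    def variables(self) -> set[int]:
        return {v for v, _, _ in self.factors}

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for var, knot, direction in self.factors:
            out = out * np.maximum(0.0, direction * (X[:, var] - knot))
        return out

    def describe(self, names: list[str]) -> str:
        if self.is_intercept:
            return "(intercept)"
        parts = []
        for var, knot, direction in self.factors:
            x = names[var]
            parts.append(
                f"max(0, {x} - {knot:g})" if direction > 0 else f"max(0, {knot:g} - {x})"
            )
        return " * ".join(parts)


def _design(bases: list[HingeBasis], X: np.ndarray) -> np.ndarray:
    return np.column_stack([b.evaluate(X) for b in bases])


def _lstsq_rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _n_knots(bases: list[HingeBasis]) -> int:
    return len({(v, k) for b in bases for v, k, _ in b.factors})


def _gcv(rss: float, n: int, bases: list[HingeBasis], penalty: float) -> float:
    c = len(bases) + penalty * _n_knots(bases)
    if c >= n:
        return np.inf
    return (rss / n) / (1.0 - c / n) ** 2


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def mars_forward(
    X: np.ndarray,
    y: np.ndarray,
    max_bases: int,
    max_interaction: int = 1,
    rel_tol: float = 1e-8,
) -> tuple[list[HingeBasis], list[float]]:
    """Greedy hinge-pair construction.

    Returns the ordered basis list (intercept first) and the RSS trace
    after each accepted step.  ``max_bases`` bounds the number of hinge
    terms (the intercept is not counted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValidationError("X must be 2-D with one row per element of y")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValidationError("X and y must be finite (no missing values)")
    if max_bases < 1:
        raise ValidationError("max_bases must be >= 1")
    n, p = X.shape

    bases = [HingeBasis()]
    B = np.ones((n, 1))
    # orthonormal basis of the current column space
    Q, _ = np.linalg.qr(B)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    rss0 = max(rss, _EPS)
    trace = [rss]

    while len(bases) - 1 < max_bases:
        best = None  # (reduction, parent_idx, var, knot)
        for parent_idx, parent in enumerate(bases):
            if len(parent.factors) >= max_interaction:
                continue
            pvals = B[:, parent_idx]
            active = pvals > 0
            if not active.any():
                continue
            for var in range(p):
                if var in parent.variables:
                    continue
                knots = np.unique(X[active, var])
                if len(knots) < 2:
                    continue
                xv = X[:, var]
                # hinge columns for all candidate knots, times the parent
                H1 = np.maximum(0.0, xv[:, None] - knots[None, :]) * pvals[:, None]
                H2 = np.maximum(0.0, knots[None, :] - xv[:, None]) * pvals[:, None]
                # orthogonalize against the current column space
                H1p = H1 - Q @ (Q.T @ H1)
                H2p = H2 - Q @ (Q.T @ H2)
                g11 = np.einsum("ij,ij->j", H1p, H1p)
                g22 = np.einsum("ij,ij->j", H2p, H2p)
                g12 = np.einsum("ij,ij->j", H1p, H2p)
                b1 = H1p.T @ resid
                b2 = H2p.T @ resid
                det = g11 * g22 - g12 * g12
                scale = np.maximum(g11 * g22, _EPS)
                with np.errstate(divide="ignore", invalid="ignore"):
                    red_pair = (g22 * b1**2 - 2 * g12 * b1 * b2 + g11 * b2**2) / det
                    red_1 = np.where(g11 > _EPS * scale, b1**2 / g11, 0.0)
                    red_2 = np.where(g22 > _EPS * scale, b2**2 / g22, 0.0)
                reduction = np.where(
                    det > _EPS * scale, red_pair, np.maximum(red_1, red_2)
                )
                reduction = np.nan_to_num(reduction, nan=0.0, posinf=0.0)
                j = int(np.argmax(reduction))
                if best is None or reduction[j] > best[0] + _EPS * rss0:
                    best = (float(reduction[j]), parent_idx, var, float(knots[j]))
        if best is None:
            break
        reduction, parent_idx, var, knot = best
        if reduction < rel_tol * rss0:
            break
        parent = bases[parent_idx]
        new = [
            HingeBasis(parent.factors + ((var, knot, +1),)),
            HingeBasis(parent.factors + ((var, knot, -1),)),
        ]
        for basis in new:
            if len(bases) - 1 >= max_bases:
                break
            col = basis.evaluate(X)
            colp = col - Q @ (Q.T @ col)
            norm = np.linalg.norm(colp)
            if norm**2 <= _EPS * max(float(col @ col), _EPS):
                # linearly dependent on the current space: contributes nothing
                continue
            bases.append(basis)
            B = np.column_stack([B, col])
            q = colp / norm
            Q = np.column_stack([Q, q])
            resid = resid - q * (q @ resid)
        new_rss = float(resid @ resid)
        if new_rss >= trace[-1] - rel_tol * rss0:
            # accepted columns brought no real improvement; stop
            if len(bases) - 1 > 0 and new_rss < trace[-1]:
                trace.append(new_rss)
            break
        trace.append(new_rss)
        if new_rss <= _EPS * rss0:
            break
    return bases, trace


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def mars_backward(
    bases: list[HingeBasis],
    X: np.ndarray,
    y: np.ndarray,
    penalty: float = 2.0,
) -> tuple[list[HingeBasis], np.ndarray, float, list[tuple[int, float]]]:
    """GCV-guided pruning of a forward basis sequence.

    Iteratively removes the hinge basis whose deletion least increases
    RSS, then returns the subset (from the nested deletion sequence)
    minimising GCV.  Returns ``(bases, coefficients, gcv, trace)`` where
    ``trace`` lists ``(n_hinge_terms, gcv)`` down the sequence.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    current = list(bases)
    coef, rss = _lstsq_rss(_design(current, X), y)
    gcv = _gcv(rss, n, current, penalty)
    if not np.isfinite(gcv):
        warnings.warn("full model has C(M) >= n; skipped as a GCV candidate")
    trace = [(len(current) - 1, gcv)]
    best = (gcv, list(current), coef)

    while len(current) > 1:
        candidates = []
        for i in range(1, len(current)):  # never remove the intercept
            sub = current[:i] + current[i + 1:]
            c, r = _lstsq_rss(_design(sub, X), y)
            candidates.append((r, i, sub, c))
        r, i, sub, c = min(candidates, key=lambda t: t[0])
        current = sub
        g = _gcv(r, n, current, penalty)
        trace.append((len(current) - 1, g))
        if g < best[0] or (not np.isfinite(best[0]) and np.isfinite(g)):
            best = (g, list(current), c)
    gcv, final_bases, final_coef = best
    return final_bases, np.asarray(final_coef), float(gcv), trace


def variable_importance(
    bases: list[HingeBasis],
    coef: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    penalty: float = 2.0,
    n_features: int | None = None,
) -> np.ndarray:
    """Importance 0–100 per variable: GCV increase on removing its bases.

    Variables absent from the model score 0; the top variable scores 100.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_features is None:
        n_features = p
    _, rss = _lstsq_rss(_design(bases, X), y)
    gcv_full = _gcv(rss, n, bases, penalty)
    raw = np.zeros(n_features)
    used = sorted({v for b in bases for v in b.variables})
    for var in used:
        sub = [b for b in bases if var not in b.variables]
        _, r = _lstsq_rss(_design(sub, X), y)
        raw[var] = max(0.0, _gcv(r, n, sub, penalty) - gcv_full)
    top = raw.max()
    return raw / top * 100.0 if top > 0 else raw


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep over unique scores) and AUC.

    AUC equals the Mann–Whitney concordance probability with ties
    counted 1/2.  Raises on single-class label vectors.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("roc_auc requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return points, auc


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class MARS:
    """MARS model of a binary outcome on spot features.

    Parameters
    ----------
    X : DataFrame or ndarray
        Feature matrix (samples x features), typically log2-normalized
        spot volumes.
    y : array-like
        Response; binary 0/1 labels for classification (NH = 0, HF = 1)
        or a continuous outcome for plain regression.
    max_bases : int, optional
        Maximum number of hinge terms (intercept excluded).  Defaults to
        the number of features.
    max_interaction : int
        Maximum hinge factors per basis; 1 = additive (default).
    penalty : float
        GCV penalty per knot (default 2, standard for additive models).
    """

    def __init__(
        self,
        X,
        y,
        max_bases: int | None = None,
        max_interaction: int = 1,
        penalty: float = 2.0,
        rel_tol: float = 1e-8,
    ):
        if isinstance(X, pd.DataFrame):
            self.feature_names = [str(c) for c in X.columns]
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        self.y = np.asarray(y, dtype=float)
        self.max_bases = max_bases if max_bases is not None else self.X.shape[1]
        self.max_interaction = max_interaction
        self.penalty = penalty
        self.rel_tol = rel_tol

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, label_col: str, **kwargs) -> "MARS":
        y = data[label_col].to_numpy()
        X = data.drop(columns=[label_col])
        return cls(X, y, **kwargs)

    def fit(self) -> "MARSResults":
        forward_bases, rss_trace = mars_forward(
            self.X, self.y, self.max_bases, self.max_interaction, self.rel_tol
        )
        bases, coef, gcv, gcv_trace = mars_backward(
            forward_bases, self.X, self.y, self.penalty
        )
        importance = variable_importance(
            bases, coef, self.X, self.y, self.penalty, len(self.feature_names)
        )
        return MARSResults(
            model=self,
            bases=bases,
            params=coef,
            gcv=gcv,
            gcv_trace=gcv_trace,
            forward_rss_trace=rss_trace,
            importance=pd.Series(importance, index=self.feature_names),
        )


@dataclass
class MARSResults:
    """Fitted MARS model: bases, least-squares coefficients, GCV, importance."""

    model: MARS
    bases: list[HingeBasis]
    params: np.ndarray
    gcv: float
    gcv_trace: list[tuple[int, float]]
    forward_rss_trace: list[float] = field(repr=False, default_factory=list)
    importance: pd.Series | None = None

    def predict(self, X) -> np.ndarray:
        """Continuous score; >= 0.5 classifies as class 1."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        return _design(self.bases, np.asarray(X, dtype=float)) @ self.params

    def predict_class(self, X) -> np.ndarray:
        return (self.predict(X) >= 0.5).astype(int)

    @property
    def n_hinge_terms(self) -> int:
        return len(self.bases) - 1

    def selected_variables(self, min_importance: float = 20.0) -> list[str]:
        """Feature names with importance above the given score."""
        imp = self.importance
        return list(imp.index[imp > min_importance])

    def summary(self) -> str:
        names = self.model.feature_names
        lines = [
            "MARS regression results",
            "=======================",
            f"n = {len(self.model.y)}   features = {len(names)}   "
            f"hinge terms = {self.n_hinge_terms}   GCV = {self.gcv:.6g}",
            "",
            f"{'basis':<42} {'coef':>12}",
            "-" * 55,
        ]
        for basis, c in zip(self.bases, self.params):
            lines.append(f"{basis.describe(names):<42} {c:>12.5g}")
        imp = self.importance.sort_values(ascending=False)
        imp = imp[imp > 0]
        if len(imp):
            lines += ["", "variable importance (top = 100):"]
            for name, score in imp.items():
                lines.append(f"  {name:<20} {score:6.1f}")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.model.feature_names,
            "bases": [list(map(list, b.factors)) for b in self.bases],
            "coefficients": [float(c) for c in self.params],
            "gcv": self.gcv,
            "gcv_trace": [[int(m), float(g)] for m, g in self.gcv_trace],
            "importance": {k: float(v) for k, v in self.importance.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    """ROC validation of a MARS classifier under one scheme."""

    scheme: str  # "cv10" or "split80_20"
    seed: int
    scores_test: np.ndarray
    labels_test: np.ndarray
    roc_train: pd.DataFrame
    roc_test: pd.DataFrame
    auc_train: float
    auc_test: float
    selected_variables: list[str]

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "seed": self.seed,
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "selected_variables": self.selected_variables,
        }


def validate(X, y, scheme: str, seed: int = 0, **mars_kwargs) -> ValidationResult:
    """Validate a MARS classifier by cross-validation or a held-out split.

    ``cv10``: stratified 10-fold CV; out-of-fold scores are pooled into a
    single test ROC, and the train ROC comes from the full-data fit.
    ``split80_20``: stratified 80/20 split; train ROC on the 80% fit,
    test ROC on the held-out 20%.
    """
    if isinstance(X, pd.DataFrame):
        frame = X
    else:
        frame = pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("validate requires exactly two classes")

    if scheme == "cv10":
        if counts.min() < 5:
            raise ValidationError("cv10 requires >= 5 samples per class")
        full = MARS(frame, y, **mars_kwargs).fit()
        roc_tr, auc_tr = roc_auc(full.predict(frame), y)
        oof = np.empty(len(y))
        # stratification caps the fold count at the minority class size
        n_splits = int(min(10, counts.min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(frame, y):
            res = MARS(frame.iloc[train_idx], y[train_idx], **mars_kwargs).fit()
            oof[test_idx] = res.predict(frame.iloc[test_idx])
        roc_te, auc_te = roc_auc(oof, y)
        return ValidationResult(
            "cv10", seed, oof, y, roc_tr, roc_te, auc_tr, auc_te,
            full.selected_variables(),
        )

    if scheme == "split80_20":
        idx_train, idx_test = train_test_split(
            np.arange(len(y)), test_size=0.2, stratify=y, random_state=seed
        )
        res = MARS(frame.iloc[idx_train], y[idx_train], **mars_kwargs).fit()
        roc_tr, auc_tr = roc_auc(res.predict(frame.iloc[idx_train]), y[idx_train])
        scores = res.predict(frame.iloc[idx_test])
        roc_te, auc_te = roc_auc(scores, y[idx_test])
        return ValidationResult(
            "split80_20", seed, scores, y[idx_test], roc_tr, roc_te,
            auc_tr, auc_te, res.selected_variables(),
        )

    raise ValidationError(f"unknown validation scheme {scheme!r}")
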