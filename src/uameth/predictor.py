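"""Multivariate linear DAS28 predictor built from activity-correlated CpGs.

Recipe: genome-wide Spearman pre-filter (|rho| >= 0.7, p <= 1e-3) ->
OLS of DAS28 on all retained CpG betas, keeping significant coefficients ->
ranking by lmg relative importance (the average gain in R-squared a
predictor contributes over all orders of model entry, a Shapley-style exact
decomposition of the full-model R-squared) -> bidirectional AIC stepwise
selection over the ranked scope -> greedy collinearity pruning
(|Pearson r| < 0.5 between kept predictors) -> nested models of sizes
1..7 in importance order -> seeded 5-fold cross-validation to pick the
model size with the best mean out-of-fold R-squared.

Evaluation R-squared is the squared Pearson correlation between predicted
and observed DAS28 (with its p-value); 1 - RSS/TSS is reported alongside.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activity import correlate_activity
from .core import MethylationMatrix
from .stats import pearson

#: maximum predictor count for the exact subset-formula lmg
LMG_EXACT_MAX_P = 12


# ---------------------------------------------------------------------------
# lmg relative importance
# ---------------------------------------------------------------------------

def _r2_cache_factory(X: np.ndarray, y: np.ndarray):
    """Return an R^2(subset-bitmask) evaluator with memoization."""
    n = X.shape[0]
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("response has zero variance")
    Xc = X - X.mean(axis=0)
    cache: dict[int, float] = {0: 0.0}

    def r2(mask: int) -> float:
        if mask in cache:
            return cache[mask]
        cols = [j for j in range(X.shape[1]) if mask >> j & 1]
        coef, *_ = np.linalg.lstsq(Xc[:, cols], yc, rcond=None)
        rss = float(np.sum((yc - Xc[:, cols] @ coef) ** 2))
        val = 1.0 - rss / tss
        cache[mask] = val
        return val

    return r2


def lmg_importance(X, y, rng: np.random.Generator | None = None,
                   n_orderings: int = 5000) -> np.ndarray:
    """lmg relative-importance decomposition of the full-model R-squared.

    importance_j = average over all p! orderings of the predictors of the
    R-squared increase when j enters after its predecessors.  Exact via the
    subset formulation for p <= 12; seeded Monte-Carlo over orderings
    beyond that.  The importances sum to the full-model R-squared.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("lmg requires n > p")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"predictor matrix rank deficient (most collinear pair: {i}, {j})"
        )
    r2 = _r2_cache_factory(X, y)
    out = np.zeros(p)
    if p <= LMG_EXACT_MAX_P:
        # weight of a subset of size k preceding j: k! (p-k-1)! / p!
        weights = [math.factorial(k) * math.factorial(p - k - 1)
                   / math.factorial(p) for k in range(p)]
        for mask in range(1 << p):
            k = bin(mask).count("1")
            if k == p:
                continue
            base = r2(mask)
            for j in range(p):
                if not mask >> j & 1:
                    out[j] += weights[k] * (r2(mask | 1 << j) - base)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        for _ in range(n_orderings):
            order = rng.permutation(p)
            mask = 0
            prev = 0.0
            for j in order:
                cur = r2(mask | 1 << j)
                out[j] += cur - prev
                prev = cur
                mask |= 1 << j
        out /= n_orderings
    return out


# ---------------------------------------------------------------------------
# Stepwise selection and pruning
# ---------------------------------------------------------------------------

def _aic(X: np.ndarray, y: np.ndarray, cols: tuple) -> float:
    """AIC = n ln(RSS/n) + 2 (k + 1); the additive constant is dropped.

    k + 1 counts the regression coefficients including the intercept (the
    error-variance parameter adds a shared constant that cancels in
    comparisons).
    """
    n = X.shape[0]
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    if rss <= 0:
        return -np.inf
    return n * math.log(rss / n) + 2 * (len(cols) + 1)


def stepwise_select(X, y, scope=None) -> list[int]:
    """Bidirectional AIC stepwise selection starting from the full model.

    At every step each single addition (from ``scope``) and deletion is
    scored; the move with the lowest AIC is applied when it improves the
    current AIC, and the search stops at a local minimum.  Returns the
    selected column indices, in their scope order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if scope is None:
        scope = list(range(X.shape[1]))
    scope = list(scope)
    if not scope:
        return []
    if X.shape[0] <= len(scope) + 1:
        raise ValueError("stepwise requires n > |scope| + 1")
    current = tuple(scope)
    current_aic = _aic(X, y, current)
    if not math.isfinite(current_aic):
        warnings.warn("zero residual sum of squares; returning full model",
                      stacklevel=2)
        return list(current)
    while True:
        moves = []
        for j in scope:
            if j in current:
                moves.append(tuple(c for c in current if c != j))
            else:
                moves.append(tuple(sorted(current + (j,),
                                          key=scope.index)))
        scored = [(_aic(X, y, m), m) for m in moves]
        best_aic, best_move = min(scored, key=lambda t: t[0])
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_move, best_aic
        else:
            return list(current)


def prune_collinear(candidates: list, X: pd.DataFrame,
                    r_max: float = 0.5) -> list:
    """Greedy collinearity pruning in importance order.

    Scans ``candidates`` (already ordered by importance) and drops any whose
    |Pearson r| with an earlier kept candidate is >= ``r_max``.
    """
    kept: list = []
    for cand in candidates:
        x = X[cand].to_numpy(dtype=float)
        collides = False
        for other in kept:
            r = np.corrcoef(x, X[other].to_numpy(dtype=float))[0, 1]
            if abs(r) >= r_max:
                collides = True
                break
        if collides:
            warnings.warn(f"pruned collinear predictor {cand!r}", stacklevel=2)
        else:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class PredictorModel:
    """Fitted linear DAS28 model over an ordered CpG panel."""

    intercept: float
    cpgs: list[str]
    coefs: list[float]
    n_train: int
    r2_train: float

    @property
    def model_size(self) -> int:
        return len(self.cpgs)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "cpgs": list(self.cpgs),
            "coefs": list(self.coefs),
            "n_train": self.n_train,
            "r2_train": self.r2_train,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorModel":
        return cls(intercept=d["intercept"], cpgs=list(d["cpgs"]),
                   coefs=list(d["coefs"]), n_train=d["n_train"],
                   r2_train=d["r2_train"])

    @classmethod
    def from_json(cls, path) -> "PredictorModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CVReport:
    """Per-model-size cross-validation R-squared summary."""

    fold_r2: dict[int, list[float]]
    pooled_r2: dict[int, float]
    seed: int
    k: int = 5

    @property
    def mean_r2(self) -> dict[int, float]:
        return {size: float(np.nanmean(v)) for size, v in self.fold_r2.items()}

    @property
    def selected_size(self) -> int:
        """Size with the best mean fold R-squared; ties go to the smaller."""
        means = self.mean_r2
        best = max(means.values())
        return min(s for s, m in means.items() if m >= best - 1e-12)


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator,
                      stratify: bool = True) -> np.ndarray:
    """Fold labels in 0..k-1, stratified by response quartile."""
    n = y.size
    fold = np.empty(n, dtype=int)
    if stratify:
        quart = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y,
                                side="right")
    else:
        quart = np.zeros(n, dtype=int)
    offset = 0
    for q in np.unique(quart):
        idx = np.flatnonzero(quart == q)
        rng.shuffle(idx)
        fold[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size
    return fold


def _fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else float("nan")
    return float(coef[0]), coef[1:], r2


def build_predictor(train_matrix: MethylationMatrix,
                    sample_sheet: pd.DataFrame,
                    rho_min: float = 0.7,
                    p_max: float = 1e-3,
                    max_size: int = 7,
                    coef_alpha: float = 0.05,
                    cv_k: int = 5,
                    seed: int = 0,
                    stratify_cv: bool = True,
                    on_excess: str = "trim"):
    """Run the full predictor recipe; returns (models, cv_report).

    ``models`` maps model size -> :class:`PredictorModel` for the nested
    family of sizes 1..max_size (possibly truncated when fewer CpGs survive
    selection, with a warning).
    """
    sheet = sample_sheet.set_index("sample_id")
    train_samples = [s for s in train_matrix.sample_ids
                     if s in sheet.index and pd.notna(sheet.loc[s, "das28"])]
    if len(train_samples) < cv_k + 2:
        raise ValueError("too few DAS28-bearing training samples")
    y = sheet.loc[train_samples, "das28"].to_numpy(dtype=float)

    corr = correlate_activity(train_matrix, sample_sheet,
                              rho_min=rho_min, p_max=p_max)
    if corr.empty:
        raise ValueError("no CpGs pass the correlation pre-filter; "
                         "loosen rho_min/p_max")
    candidates = list(corr.index)
    if len(train_samples) <= len(candidates) + 1:
        if on_excess == "error":
            raise ValueError(
                f"{len(candidates)} candidate CpGs for {len(train_samples)} "
                "samples; tighten the correlation pre-filter (rho_min/p_max)"
            )
        # keep the strongest correlations so the full OLS stays identifiable
        keep_n = len(train_samples) - 2
        order = corr["rho"].abs().sort_values(ascending=False).index
        candidates = [c for c in order[:keep_n]]
        warnings.warn(
            f"correlation screen returned more CpGs than samples support; "
            f"trimmed to the {keep_n} strongest", stacklevel=2)
    X_all = train_matrix.beta.loc[candidates, train_samples].T  # samples x cpgs

    # full OLS; keep significant coefficients
    fit = sm.OLS(y, sm.add_constant(X_all.to_numpy())).fit()
    coef_p = fit.pvalues[1:]
    sig = [c for c, p in zip(candidates, coef_p) if p < coef_alpha]
    if not sig:
        warnings.warn("no individually significant coefficients; keeping the "
                      "full pre-filtered candidate set", stacklevel=2)
        sig = candidates

    # lmg ranking
    imp = lmg_importance(X_all[sig].to_numpy(), y,
                         rng=np.random.default_rng(seed))
    ranked = [c for _, c in sorted(zip(-imp, sig))]

    # bidirectional stepwise over the ranked scope
    sel_idx = stepwise_select(X_all[ranked].to_numpy(), y,
                              scope=list(range(len(ranked))))
    selected = [ranked[i] for i in sel_idx]

    # collinearity pruning, then cap at max_size
    pruned = prune_collinear(selected, X_all, r_max=0.5)
    panel = pruned[:max_size]
    if len(panel) < max_size:
        warnings.warn(f"model family truncated at size {len(panel)}",
                      stacklevel=2)
    if not panel:
        raise ValueError("selection removed every candidate CpG")

    # nested models on the first k CpGs in importance order
    models: dict[int, PredictorModel] = {}
    for size in range(1, len(panel) + 1):
        cpgs = panel[:size]
        icpt, coefs, r2 = _fit_ols(X_all[cpgs].to_numpy(), y)
        models[size] = PredictorModel(intercept=icpt, cpgs=cpgs,
                                      coefs=list(map(float, coefs)),
                                      n_train=len(train_samples),
                                      r2_train=r2)

    # seeded 5-fold CV per size
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, cv_k, rng, stratify=stratify_cv)
    fold_r2: dict[int, list[float]] = {}
    pooled_r2: dict[int, float] = {}
    for size, model in models.items():
        Xs = X_all[model.cpgs].to_numpy()
        per_fold = []
        yhat_all = np.empty_like(y)
        for f in range(cv_k):
            tr, te = folds != f, folds == f
            icpt, coefs, _ = _fit_ols(Xs[tr], y[tr])
            yhat = icpt + Xs[te] @ coefs
            yhat_all[te] = yhat
            if te.sum() >= 3 and np.ptp(yhat) > 0 and np.ptp(y[te]) > 0:
                per_fold.append(float(np.corrcoef(yhat, y[te])[0, 1] ** 2))
            else:
                per_fold.append(float("nan"))
        fold_r2[size] = per_fold
        pooled_r2[size] = float(np.corrcoef(yhat_all, y)[0, 1] ** 2) \
            if np.ptp(yhat_all) > 0 else float("nan")
    report = CVReport(fold_r2=fold_r2, pooled_r2=pooled_r2, seed=seed, k=cv_k)
    return models, report


def predict_das28(model: PredictorModel, matrix: MethylationMatrix,
                  y_true=None):
    """Apply a fitted model; optionally score against observed DAS28.

    Returns ``(predictions, metrics)``: a Series of predicted DAS28 per
    sample and, when ``y_true`` is given, a dict with the squared Pearson
    R-squared and its p-value plus the 1 - RSS/TSS variant.
    """
    missing = [c for c in model.cpgs if c not in matrix.probe_ids]
    if missing:
        raise ValueError(f"matrix lacks model CpGs: {missing}")
    X = matrix.beta.loc[model.cpgs].T.to_numpy()
    yhat = model.intercept + X @ np.asarray(model.coefs)
    preds = pd.Series(yhat, index=matrix.sample_ids, name="das28_pred")
    metrics = None
    if y_true is not None:
        y = np.asarray(pd.Series(y_true).reindex(matrix.sample_ids),
                       dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError("need >= 3 observed DAS28 values to score")
        if np.ptp(yhat[ok]) == 0:
            warnings.warn("constant predictions; R^2 undefined", stacklevel=2)
            metrics = {"r2": float("nan"), "p": float("nan"),
                       "r2_rss": float("nan"), "n": int(ok.sum())}
        else:
            res = pearson(yhat[ok], y[ok])
            tss = float(np.sum((y[ok] - y[ok].mean()) ** 2))
            rss = float(np.sum((y[ok] - yhat[ok]) ** 2))
            metrics = {"r2": res.statistic ** 2, "p": res.p,
                       "r2_rss": 1.0 - rss / tss if tss > 0 else float("nan"),
                       "n": res.n}
    return preds, metrics
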