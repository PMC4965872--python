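"""Additive multivariate adaptive regression splines (MARS).

The model is a sum of reflected hinge pairs, y ~ b0 + sum_m c_m * h_m(x)
with h_m(x) = max(0, x_v - t) or max(0, t - x_v); degree is fixed at 1 (no
interaction terms).  The forward pass greedily adds the hinge pair (knot
candidates at observed predictor values) that most reduces the residual sum
of squares, stopping when the relative improvement drops below ``thresh``
or the term budget is exhausted; the backward pass prunes terms to minimize
the generalized cross-validation score

    GCV = (RSS / n) / (1 - C / n)^2,   C = k + penalty * (k - 1) / 2,

with k the number of model terms including the intercept and penalty = 2
(the standard choice for additive models).  Variance decomposition fits
single-feature models for individual contributions and nested models in
descending order of individual contribution for cumulative/delta shares;
predictive performance is assessed by repeated 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class HingeTerm:
    predictor: int
    knot: float
    sign: int  # +1: max(0, x - t); -1: max(0, t - x)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        x = X[:, self.predictor]
        return np.maximum(0.0, self.sign * (x - self.knot))


@dataclass
class MarsModel:
    terms: list[HingeTerm]
    coef: np.ndarray            # intercept first, then one per term
    gcv: float
    gcv_unpruned: float
    rsq: float                  # training variance explained
    rss: float
    n_obs: int
    penalty: float
    columns: list[str] = field(default_factory=list)

    def basis(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = [np.ones(len(X))] + [t.evaluate(X) for t in self.terms]
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.basis(np.asarray(X, dtype=float)) @ self.coef


def _gcv(rss: float, n: int, k: int, penalty: float) -> float:
    c = k + penalty * (k - 1) / 2.0
    if c >= n:
        return float("inf")
    return (rss / n) / (1.0 - c / n) ** 2


def _fit_ls(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def mars_fit(
    X,
    y,
    degree: int = 1,
    penalty: float = 2.0,
    thresh: float = 0.001,
    max_terms: int | None = None,
) -> MarsModel:
    """Fit an additive MARS model with forward selection and GCV pruning.

    ``X`` may be a DataFrame (column names are kept for reporting) or a 2-D
    array; ``degree`` must be 1 (additive; interactions are out of scope).
    Candidate knots are the observed values of each predictor.
    """
    if degree != 1:
        raise ValueError("only additive models (degree=1) are supported")
    columns: list[str] = []
    if isinstance(X, pd.DataFrame):
        columns = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with one response per row")
    n, p = X.shape
    if n <= 10:
        raise ValueError("need more than 10 observations")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("predictors and response must be finite")
    if max_terms is None:
        max_terms = min(21, 2 * p + 1)

    sstot = float(np.sum((y - y.mean()) ** 2))
    terms: list[HingeTerm] = []
    B = np.ones((n, 1))
    coef, rss = _fit_ls(B, y)
    if sstot == 0:
        return MarsModel(terms=[], coef=coef, gcv=_gcv(rss, n, 1, penalty),
                         gcv_unpruned=_gcv(rss, n, 1, penalty), rsq=0.0,
                         rss=rss, n_obs=n, penalty=penalty, columns=columns)

    # forward pass
    while len(B[0]) < max_terms:
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        best = None  # (improvement, predictor, knot, which)
        for v in range(p):
            xv = X[:, v]
            knots = np.unique(xv)
            if len(knots) < 2:
                continue
            Hp = np.maximum(0.0, xv[:, None] - knots[None, :])
            Hm = np.maximum(0.0, knots[None, :] - xv[:, None])
            Hp -= Q @ (Q.T @ Hp)
            Hm -= Q @ (Q.T @ Hm)
            aa = np.einsum("ij,ij->j", Hp, Hp)
            bb = np.einsum("ij,ij->j", Hm, Hm)
            ab = np.einsum("ij,ij->j", Hp, Hm)
            c1 = Hp.T @ r
            c2 = Hm.T @ r
            det = aa * bb - ab**2
            tol = 1e-10 * np.maximum(aa * bb, 1e-30)
            with np.errstate(divide="ignore", invalid="ignore"):
                imp_pair = np.where(
                    det > tol,
                    (bb * c1**2 - 2 * ab * c1 * c2 + aa * c2**2) / det,
                    -np.inf,
                )
                imp_p = np.where(aa > 1e-12, c1**2 / aa, -np.inf)
                imp_m = np.where(bb > 1e-12, c2**2 / bb, -np.inf)
            for imp, which in ((imp_pair, "pair"), (imp_p, "plus"), (imp_m, "minus")):
                k = int(np.argmax(imp))
                if np.isfinite(imp[k]) and (best is None or imp[k] > best[0]):
                    best = (float(imp[k]), v, float(knots[k]), which)
        if best is None:
            break
        improvement, v, t, which = best
        if rss > 0 and improvement / rss < thresh:
            break
        new_terms = []
        if which in ("pair", "plus"):
            new_terms.append(HingeTerm(v, t, +1))
        if which in ("pair", "minus"):
            new_terms.append(HingeTerm(v, t, -1))
        if len(B[0]) + len(new_terms) > max_terms:
            new_terms = new_terms[:1]
        for term in new_terms:
            terms.append(term)
            B = np.column_stack([B, term.evaluate(X)])
        coef, new_rss = _fit_ls(B, y)
        if rss - new_rss <= thresh * max(rss, 1e-30):
            # adding the terms did not actually help; roll back and stop
            if new_rss >= rss:
                for _ in new_terms:
                    terms.pop()
                B = B[:, : len(terms) + 1]
                coef, rss = _fit_ls(B, y)
                break
            rss = new_rss
            break
        rss = new_rss

    gcv_unpruned = _gcv(rss, n, len(terms) + 1, penalty)

    # backward pass: greedy pruning, keep the GCV-best model visited
    current = list(range(len(terms)))
    best_subset, best_gcv = list(current), gcv_unpruned
    while current:
        options = []
        for drop in current:
            subset = [i for i in current if i != drop]
            Bs = np.column_stack(
                [np.ones(n)] + [terms[i].evaluate(X) for i in subset]
            )
            _, rss_s = _fit_ls(Bs, y)
            options.append((_gcv(rss_s, n, len(subset) + 1, penalty), drop))
        gcv_s, drop = min(options)
        current = [i for i in current if i != drop]
        if gcv_s <= best_gcv:
            best_gcv, best_subset = gcv_s, list(current)

    final_terms = [terms[i] for i in best_subset]
    Bf = np.column_stack([np.ones(n)] + [t.evaluate(X) for t in final_terms])
    coef, rss = _fit_ls(Bf, y)
    return MarsModel(
        terms=final_terms,
        coef=coef,
        gcv=_gcv(rss, n, len(final_terms) + 1, penalty),
        gcv_unpruned=gcv_unpruned,
        rsq=1.0 - rss / sstot,
        rss=rss,
        n_obs=n,
        penalty=penalty,
        columns=columns,
    )


def variance_decomposition(
    X: pd.DataFrame,
    y,
    groups: dict[str, list[str]] | None = None,
    **mars_kw,
) -> pd.DataFrame:
    """Individual / cumulative / delta variance explained per feature group.

    ``groups`` maps a feature name to the design columns it spans (e.g. all
    significant hexamer indicators as one feature); by default every column
    is its own group.  Individual contribution is the training variance
    explained by the model on that group alone; groups are then added in
    descending order of individual contribution, and the delta is the gain
    in cumulative variance explained at each step.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [str(c) for c in X.columns]
    if groups is None:
        groups = {str(c): [str(c)] for c in X.columns}
    if len(groups) < 2:
        raise ValueError("need at least two feature groups")
    y = np.asarray(y, dtype=float)
    individual = {
        name: mars_fit(X[cols], y, **mars_kw).rsq for name, cols in groups.items()
    }
    order = sorted(individual, key=lambda k: -individual[k])
    rows = []
    used: list[str] = []
    prev = 0.0
    for name in order:
        used.extend(groups[name])
        cum = mars_fit(X[used], y, **mars_kw).rsq
        rows.append(dict(feature=name, individual=individual[name],
                         cumulative=cum, delta=cum - prev))
        prev = cum
    return pd.DataFrame(rows)


def cross_validate(
    X,
    y,
    folds: int = 10,
    repeats: int = 100,
    rng: np.random.Generator | int | None = None,
    **mars_kw,
) -> dict:
    """Repeated k-fold cross-validation of the full MARS model.

    Each repeat randomly partitions the pairs into ``folds`` folds, fits on
    the training folds and predicts the held-out fold; the repeat's held-out
    variance explained is 1 - SS_res / SS_tot pooled over folds.  Returns
    ``{"values": per-repeat array, "mean": mean}``.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError("more folds than observations")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sstot = float(np.sum((y - y.mean()) ** 2))
    values = np.empty(repeats)
    for rep in range(repeats):
        assignment = rng.permutation(np.arange(n) % folds)
        pred = np.empty(n)
        for f in range(folds):
            test = assignment == f
            model = mars_fit(X[~test], y[~test], **mars_kw)
            pred[test] = model.predict(X[test])
        values[rep] = 1.0 - float(np.sum((y - pred) ** 2)) / sstot
    return {"values": values, "mean": float(values.mean())}
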