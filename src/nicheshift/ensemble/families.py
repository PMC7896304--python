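"""The four model families and their tuning procedures.

Each ``fit_*`` function runs the family's tuning rule under
leave-one-block-out cross-validation and returns up to ``n_blocks``
:class:`~nicheshift.ensemble.model.ModelFit` objects — one per viable
fold, each with its held-out AUC and max(sens+spec) threshold computed on
the left-out block.  Folds whose training data contain a single class, or
whose held-out block does, are skipped and logged; downstream weighting
renormalizes over the survivors.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import SplineTransformer

from .config import EnsembleConfig
from .metrics import evaluate_auc, select_threshold

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# basis expansions

class PolyBasis:
    """Per-variable orthogonal polynomial basis of a fixed max degree.

    Standardizes each variable on the fitting sample, builds the power
    basis up to ``max_degree`` and orthonormalizes it by QR; the stored
    (mean, sd, R) triple reproduces the same basis functions on new data.
    Orthogonalization decouples the degree terms numerically across the
    many refits of the formulation search.
    """

    def __init__(self, max_degree: int = 3):
        self.max_degree = max_degree

    def fit(self, X: np.ndarray) -> "PolyBasis":
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        self.r_inv_ = []
        Z = (X - self.mean_) / self.sd_
        for j in range(X.shape[1]):
            M = np.column_stack([Z[:, j] ** d for d in range(1, self.max_degree + 1)])
            M = M - M.mean(axis=0)
            _, R = np.linalg.qr(M)
            # guard degenerate columns (near-constant variable)
            diag = np.abs(np.diag(R))
            if np.any(diag < 1e-10):
                R = R + np.eye(len(R)) * 1e-10
            self.r_inv_.append(np.linalg.inv(R) * np.sqrt(len(X)))
        return self

    def transform(self, X: np.ndarray, degrees: tuple[int, ...]) -> np.ndarray:
        """Design matrix using ``degrees[j]`` polynomial terms of column j."""
        Z = (X - self.mean_) / self.sd_
        cols = []
        for j, deg in enumerate(degrees):
            M = np.column_stack([Z[:, j] ** d for d in range(1, self.max_degree + 1)])
            B = M @ self.r_inv_[j]
            cols.append(B[:, :deg])
        return np.column_stack(cols)


class SplineBasis:
    """Per-variable B-spline bases with a second-difference (P-spline)
    roughness penalty — the additive-model smooth terms.

    ``penalty()`` returns the block-diagonal penalty matrix S such that
    beta' S beta sums the squared second differences of each variable's
    spline coefficients; penalizing curvature rather than coefficient size
    keeps monotone trends monotone near the data boundary.
    """

    def __init__(self, n_knots: int = 5, degree: int = 3):
        self.n_knots = n_knots
        self.degree = degree

    def fit(self, X: np.ndarray) -> "SplineBasis":
        self.t = SplineTransformer(
            n_knots=self.n_knots, degree=self.degree, include_bias=False
        )
        self.t.fit(X)
        self.n_vars_ = X.shape[1]
        self.cols_per_var_ = self.t.transform(X[:1]).shape[1] // self.n_vars_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.t.transform(X)

    def penalty(self) -> np.ndarray:
        k = self.cols_per_var_
        d2 = np.diff(np.eye(k), n=2, axis=0)
        s_block = d2.T @ d2
        S = np.zeros((k * self.n_vars_, k * self.n_vars_))
        for j in range(self.n_vars_):
            S[j * k:(j + 1) * k, j * k:(j + 1) * k] = s_block
        return S


def fit_pirls(B: np.ndarray, y: np.ndarray, S: np.ndarray,
              lam: float = 1.0, ridge: float = 1e-6,
              max_iter: int = 50, tol: float = 1e-8):
    """Penalized IRLS for a logistic additive model.

    Minimizes the negative Bernoulli log-likelihood plus
    ``lam/2 * beta' S beta`` (plus a tiny ridge for rank safety); the
    intercept is unpenalized.  Returns ``(beta, edf)`` where edf is the
    trace of the influence matrix (X'WX + P)^-1 X'WX at convergence.
    """
    X = np.column_stack([np.ones(len(B)), B])
    p_dim = X.shape[1]
    P = np.zeros((p_dim, p_dim))
    P[1:, 1:] = lam * S + ridge * np.eye(S.shape[0])
    beta = np.zeros(p_dim)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-10
        XtWX = (X * w[:, None]).T @ X
        H = XtWX + P
        g = X.T @ (y - mu) - P @ beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta += step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu) + 1e-10
    XtWX = (X * w[:, None]).T @ X
    edf = float(np.trace(np.linalg.solve(XtWX + P, XtWX)))
    return beta, edf


def _logistic(c: float) -> LogisticRegression:
    return LogisticRegression(
        C=c, solver="newton-cholesky", max_iter=200
    )


def _irls_logistic(D: np.ndarray, y: np.ndarray, ridge: float,
                   max_iter: int = 30, tol: float = 1e-8) -> np.ndarray:
    """Ridge-penalized logistic regression by iteratively reweighted least
    squares; returns coefficients with the intercept first.  The intercept
    is unpenalized.  Used for the high-volume formulation search, where
    per-call overhead matters."""
    X = np.column_stack([np.ones(len(D)), D])
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    R = ridge * np.eye(p_dim)
    R[0, 0] = 0.0
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu) + 1e-10
        H = (X * w[:, None]).T @ X + R
        g = X.T @ (y - mu) - R @ beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def _irls_predict(beta: np.ndarray, D: np.ndarray) -> np.ndarray:
    eta = np.clip(beta[0] + D @ beta[1:], -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


def _quiet_proba(m, X) -> np.ndarray:
    """predict_proba with sklearn feature-name chatter suppressed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return m.predict_proba(X)[:, 1]


# --------------------------------------------------------------------------
# fold utilities

def _folds(blocks: np.ndarray, y: np.ndarray):
    """Yield (block_id, train_idx, test_idx) for viable leave-one-block-out
    folds: training and held-out parts must each contain both classes."""
    for b in np.unique(blocks):
        test = blocks == b
        train = ~test
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
            logger.info("fold %s skipped: single-class training or test data", b)
            continue
        yield int(b), np.nonzero(train)[0], np.nonzero(test)[0]


# --------------------------------------------------------------------------
# GLM with polynomial-degree search

def glm_formulations(n_vars: int, max_degree: int = 3):
    """All per-variable maximum-degree assignments (3^k formulations)."""
    return list(itertools.product(range(1, max_degree + 1), repeat=n_vars))


def fit_glm_poly(X, y, blocks, config: EnsembleConfig, seed: int = 0):
    """Polynomial-degree search: every assignment of degree 1-3 to each
    predictor (243 formulations for five) is scored by mean held-out AUC
    over the folds; the argmax is refit leave-one-block-out.

    Returns ``(fits, info)`` where fits is a list of
    ``(block, predict_fn, auc, threshold)`` and info records the winning
    degrees and the search table.
    """
    basis = PolyBasis(config.glm_max_degree).fit(X)
    folds = list(_folds(blocks, y))
    cands = glm_formulations(X.shape[1], config.glm_max_degree)
    n_folds = len(folds)
    mean_auc = np.full(len(cands), -np.inf)
    full = basis.transform(X, tuple([config.glm_max_degree] * X.shape[1]))
    # column slices per variable in the full design
    col_of = []
    start = 0
    for _ in range(X.shape[1]):
        col_of.append(np.arange(start, start + config.glm_max_degree))
        start += config.glm_max_degree
    ridge = 1.0 / config.glm_ridge_c
    for ci, degrees in enumerate(cands):
        keep = np.concatenate([col_of[j][:d] for j, d in enumerate(degrees)])
        aucs = []
        for b, tr, te in folds:
            try:
                beta = _irls_logistic(full[tr][:, keep], y[tr], ridge)
                p = _irls_predict(beta, full[te][:, keep])
                aucs.append(evaluate_auc(p, y[te]))
            except Exception:
                aucs.append(np.nan)
        aucs = np.asarray(aucs, dtype=float)
        ok = np.isfinite(aucs)
        if ok.sum() < max(1, n_folds / 2):  # > 50% failed folds: discard
            continue
        mean_auc[ci] = float(np.nanmean(aucs))
    best = int(np.argmax(mean_auc))
    degrees = cands[best]
    keep = np.concatenate([col_of[j][:d] for j, d in enumerate(degrees)])
    fits = []
    for b, tr, te in folds:
        try:
            beta = _irls_logistic(full[tr][:, keep], y[tr], ridge)
            p = _irls_predict(beta, full[te][:, keep])
            auc = evaluate_auc(p, y[te])
            thr = select_threshold(p, y[te])
        except Exception:
            logger.info("glm fold %s failed at refit; dropped", b)
            continue

        def predict(Xn, beta=beta, keep=keep):
            D = basis.transform(Xn, tuple([config.glm_max_degree] * Xn.shape[1]))
            return _irls_predict(beta, D[:, keep])

        fits.append((b, predict, auc, thr))
    info = {"degrees": degrees, "mean_auc": float(mean_auc[best])}
    return fits, info


# --------------------------------------------------------------------------
# additive spline model

def fit_gam_spline(X, y, blocks, config: EnsembleConfig, seed: int = 0):
    """Roughness-penalized spline additive logistic model (P-spline),
    one fit per fold."""
    fits = []
    for b, tr, te in _folds(blocks, y):
        try:
            sb = SplineBasis(config.gam_n_knots, config.gam_degree).fit(X[tr])
            S = sb.penalty()
            beta, _ = fit_pirls(sb.transform(X[tr]), y[tr], S,
                                lam=config.gam_smoothing)
            p = _irls_predict(beta, sb.transform(X[te]))
            auc = evaluate_auc(p, y[te])
            thr = select_threshold(p, y[te])
        except Exception:
            logger.info("gam fold %s failed; dropped", b)
            continue

        def predict(Xn, beta=beta, sb=sb):
            return _irls_predict(beta, sb.transform(Xn))

        fits.append((b, predict, auc, thr))
    return fits, {"n_knots": config.gam_n_knots, "degree": config.gam_degree,
                  "smoothing": config.gam_smoothing}


def gam_aic(X, y, config: EnsembleConfig | None = None) -> float:
    """AIC of the additive spline model on the full table.

    Used by the predictor-subset ranking: -2 log-likelihood at the
    penalized estimate plus twice the effective degrees of freedom (trace
    of the influence matrix), the standard penalized-regression AIC.
    """
    config = config or EnsembleConfig()
    sb = SplineBasis(config.gam_n_knots, config.gam_degree).fit(X)
    B = sb.transform(X)
    beta, edf = fit_pirls(B, y, sb.penalty(), lam=config.gam_smoothing)
    p = np.clip(_irls_predict(beta, B), 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return -2.0 * loglik + 2.0 * edf


# --------------------------------------------------------------------------
# random forest

def fit_random_forest(X, y, blocks, config: EnsembleConfig, seed: int = 0):
    """mtry in {1,..,3}; tree count grown from the initial size in fixed
    steps until the relative gain in mean held-out AUC drops below 1%,
    the final count being the last tested size.  The (mtry, n_trees) pair
    with the best mean AUC is kept, reusing its per-fold forests."""
    folds = list(_folds(blocks, y))
    best = None  # (mean_auc, mtry, n_trees, per-fold results)
    for mtry in config.rf_mtry_grid:
        mtry_eff = min(mtry, X.shape[1])
        forests, per_fold = {}, {}
        for b, tr, te in folds:
            forests[b] = RandomForestClassifier(
                n_estimators=config.rf_initial_trees,
                max_features=mtry_eff,
                warm_start=True,
                random_state=np.random.SeedSequence(
                    [seed, mtry, b]
                ).generate_state(1)[0] % (2**31),
                n_jobs=1,
            )
        n_trees = config.rf_initial_trees
        prev_mean = None
        history = []
        for step in range(config.rf_max_steps + 1):
            aucs = {}
            for b, tr, te in folds:
                f = forests[b]
                f.set_params(n_estimators=n_trees)
                f.fit(X[tr], y[tr])
                p = f.predict_proba(X[te])[:, 1]
                aucs[b] = (evaluate_auc(p, y[te]), select_threshold(p, y[te]))
            mean = float(np.mean([a for a, _ in aucs.values()]))
            history.append((n_trees, mean))
            if prev_mean is not None and (mean - prev_mean) / prev_mean < config.rf_gain_tol:
                break
            prev_mean = mean
            n_trees += config.rf_tree_step
        per_fold = {b: (forests[b], aucs[b][0], aucs[b][1]) for b, _, _ in folds}
        cand = (mean, mtry_eff, n_trees, per_fold)
        if best is None or cand[0] > best[0]:
            best = cand
    mean, mtry, n_trees, per_fold = best
    fits = []
    for b, (forest, auc, thr) in per_fold.items():
        def predict(Xn, forest=forest):
            return forest.predict_proba(Xn)[:, 1]

        fits.append((b, predict, auc, thr))
    return fits, {"mtry": mtry, "n_trees": n_trees, "mean_auc": mean}


# --------------------------------------------------------------------------
# boosted trees

def fit_boosted_trees(X, y, blocks, config: EnsembleConfig, seed: int = 0):
    """Fixed shrinkage and tree count; interaction depth (tree complexity)
    chosen from the grid to minimize summed held-out binomial deviance."""
    import lightgbm as lgb

    folds = list(_folds(blocks, y))
    best = None  # (summed deviance, complexity, per-fold results)
    for cx in config.brt_complexity_grid:
        per_fold = {}
        total_dev = 0.0
        for b, tr, te in folds:
            m = lgb.LGBMClassifier(
                n_estimators=config.brt_n_trees,
                learning_rate=config.brt_learning_rate,
                max_depth=cx,
                num_leaves=min(2**cx, 31),
                min_child_samples=config.brt_min_child,
                random_state=int(np.random.SeedSequence(
                    [seed, cx, b]
                ).generate_state(1)[0] % (2**31)),
                verbose=-1,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m.fit(X[tr], y[tr])
            p = np.clip(_quiet_proba(m, X[te]), 1e-12, 1 - 1e-12)
            dev = -2.0 * float(
                np.sum(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
            )
            total_dev += dev
            per_fold[b] = (m, evaluate_auc(p, y[te]), select_threshold(p, y[te]))
        if best is None or total_dev < best[0]:
            best = (total_dev, cx, per_fold)
    total_dev, cx, per_fold = best
    fits = []
    for b, (m, auc, thr) in per_fold.items():
        def predict(Xn, m=m):
            return _quiet_proba(m, Xn)

        fits.append((b, predict, auc, thr))
    info = {
        "complexity": cx,
        "learning_rate": config.brt_learning_rate,
        "n_trees": config.brt_n_trees,
        "summed_deviance": total_dev,
    }
    return fits, info


FAMILY_FITTERS = {
    "glm_poly": fit_glm_poly,
    "gam_spline": fit_gam_spline,
    "random_forest": fit_random_forest,
    "boosted_trees": fit_boosted_trees,
}
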