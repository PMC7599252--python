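"""Regression of organoid IC50 on pathway activity, coefficient-
magnitude biomarker ranking, out-of-sample evaluation, and the
correlation-based gene-selection baseline.

The biomarker statistic is simple: fit a (ridge, by default) regression
of IC50 on the z-standardized activities of the selected pathways, and
rank pathways by |beta|. The top-ranked pathway's coefficient later
translates patient pathway activity into a predicted resistance score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .core_io import DoseResponseTable, ExpressionMatrix

logger = logging.getLogger("netbiomark")

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
MODEL_KINDS = ("ridge", "linear", "svr_linear")


@dataclass
class CoefficientRanking:
    model_kind: str
    alpha: float | None
    intercept: float
    coefficients: dict[str, float]
    ranks: dict[str, int]

    def top_features(self, n: int) -> list[str]:
        order = sorted(self.ranks, key=self.ranks.get)
        if n > len(order):
            raise ValueError(f"n_top={n} exceeds {len(order)} features")
        return order[:n]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.ranks, key=self.ranks.get)
        return pd.DataFrame(
            {
                "beta": [self.coefficients[f] for f in rows],
                "abs_beta": [abs(self.coefficients[f]) for f in rows],
                "rank": [self.ranks[f] for f in rows],
                "alpha": self.alpha if self.alpha is not None else np.nan,
            },
            index=pd.Index(rows, name="feature"),
        )


@dataclass
class SplitEvaluation:
    fractions: tuple[float, float, float]
    chosen_alpha: float
    validation_rmse: float
    test_r2: float
    seed: int
    sizes: tuple[int, int, int]


def _design(X: ExpressionMatrix, y: DoseResponseTable, log10_ic50: bool = False):
    """Align samples: observations = samples of y, columns = features.

    ``log10_ic50`` regresses on log10(IC50) instead of the raw value;
    useful when responses span orders of magnitude.
    """
    samples = y.samples
    missing = set(samples) - set(X.samples)
    if missing:
        raise ValueError(f"response samples missing from activity matrix: {sorted(missing)}")
    mat = X.df[samples].T  # samples x features
    resp = y.ic50[samples].values.astype(float)
    if log10_ic50:
        resp = np.log10(resp)
    return mat.values.astype(float), resp, list(X.features)


def _ridge_solve(A: np.ndarray, b: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    """Closed-form ridge with intercept: center the design and response,
    solve (Xc'Xc + alpha*I) beta = Xc'y; the intercept absorbs the means.
    Equivalent to the standard penalized least-squares fit; the small
    (n_features x n_features) normal equations keep resampling loops
    cheap."""
    x_mean = A.mean(axis=0)
    y_mean = b.mean()
    Xc = A - x_mean
    yc = b - y_mean
    k = A.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(k), Xc.T @ yc)
    return beta, float(y_mean - x_mean @ beta)


def _ridge_predict(A: np.ndarray, beta: np.ndarray, intercept: float) -> np.ndarray:
    return A @ beta + intercept


def _rank_by_magnitude(features: list[str], beta: np.ndarray) -> dict[str, int]:
    order = sorted(range(len(features)), key=lambda i: (-abs(beta[i]), features[i]))
    return {features[i]: r + 1 for r, i in enumerate(order)}


def fit_model(
    X: ExpressionMatrix,
    y: DoseResponseTable,
    kind: str = "ridge",
    alphas=DEFAULT_ALPHA_GRID,
    folds: int = 3,
    seed: int = 0,
    log10_ic50: bool = False,
) -> CoefficientRanking:
    """Fit IC50 ~ activity and rank features by |coefficient|.

    ``ridge`` picks its penalty by ``folds``-fold cross-validated mean
    squared error over the alpha grid (0.1..1.0 step 0.1 by default),
    then refits on all samples. ``linear`` is OLS (singular designs are
    an error advising ridge); ``svr_linear`` is epsilon-insensitive
    linear SVR at default regularization (C=1).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    A, b, features = _design(X, y, log10_ic50)
    n = len(b)
    if n < folds:
        raise ValueError(f"n_samples={n} < folds={folds}")

    chosen_alpha: float | None = None
    if kind == "ridge":
        if len(alphas) > 1:
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
            splits = list(kf.split(A))
            cv_mse = []
            for a in alphas:
                errs = []
                for tr, te in splits:
                    bta, itc = _ridge_solve(A[tr], b[tr], a)
                    errs.append(np.mean((_ridge_predict(A[te], bta, itc) - b[te]) ** 2))
                cv_mse.append(np.mean(errs))
            chosen_alpha = float(alphas[int(np.argmin(cv_mse))])
        else:
            chosen_alpha = float(alphas[0])
        beta, intercept = _ridge_solve(A, b, chosen_alpha)
    elif kind == "linear":
        centered = A - A.mean(axis=0)
        if np.linalg.matrix_rank(centered) < A.shape[1]:
            raise ValueError("singular design for OLS; use kind='ridge'")
        model = LinearRegression().fit(A, b)
        beta, intercept = model.coef_, float(model.intercept_)
    else:  # svr_linear
        model = SVR(kernel="linear", C=1.0).fit(A, b)
        beta, intercept = model.coef_.ravel(), float(model.intercept_[0])

    coefficients = {f: float(beta[i]) for i, f in enumerate(features)}
    return CoefficientRanking(
        model_kind=kind,
        alpha=chosen_alpha,
        intercept=intercept,
        coefficients=coefficients,
        ranks=_rank_by_magnitude(features, np.asarray(beta, dtype=float)),
    )


def partition_sizes(n: int, fractions=(0.60, 0.10, 0.30)) -> tuple[int, int, int]:
    """Train/validation/test sizes: floor for train and validation, the
    remainder to test (n=20 at 60/10/30 -> 12/2/6)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"empty partition for n={n}: train/val/test = {n_train}/{n_val}/{n_test}"
        )
    return n_train, n_val, n_test


def evaluate_split(
    X: ExpressionMatrix,
    y: DoseResponseTable,
    fractions=(0.60, 0.10, 0.30),
    alphas=DEFAULT_ALPHA_GRID,
    seed: int = 0,
    log10_ic50: bool = False,
) -> SplitEvaluation:
    """Out-of-sample predictive ability of the selected features.

    The ridge penalty is tuned to minimize RMSE on the validation split
    (trained on the training split only); the tuned model is refit on
    the training split and scored on the test split as the squared
    Pearson correlation between observed and predicted IC50.
    """
    A, b, _ = _design(X, y, log10_ic50)
    n = len(b)
    n_train, n_val, n_test = partition_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr = perm[:n_train]
    va = perm[n_train:n_train + n_val]
    te = perm[n_train + n_val:]

    best = None
    for a in alphas:
        bta, itc = _ridge_solve(A[tr], b[tr], a)
        rmse = float(np.sqrt(np.mean((_ridge_predict(A[va], bta, itc) - b[va]) ** 2)))
        if best is None or rmse < best[1]:
            best = (float(a), rmse)
    chosen_alpha, val_rmse = best
    bta, itc = _ridge_solve(A[tr], b[tr], chosen_alpha)
    pred = _ridge_predict(A[te], bta, itc)
    if np.std(pred) == 0 or np.std(b[te]) == 0:
        r2 = 0.0
    else:
        r2 = float(pearsonr(b[te], pred)[0] ** 2)
    return SplitEvaluation(
        fractions=tuple(fractions), chosen_alpha=chosen_alpha,
        validation_rmse=val_rmse, test_r2=r2, seed=seed,
        sizes=(n_train, n_val, n_test),
    )


def bolis_select_genes(
    expr: ExpressionMatrix,
    y: DoseResponseTable,
    n_iter: int = 10,
    p_cut: float = 0.05,
    seed: int = 0,
) -> list[str]:
    """Leave-half-out correlation gene selection baseline.

    Over ``n_iter`` iterations, half the organoids are held out at
    random; Spearman rho/p of each gene's expression against IC50 is
    computed on the retained half. Genes whose mean p-value across
    iterations is below ``p_cut`` are selected. Genes constant in any
    retained half (Spearman undefined) are excluded with a warning.
    """
    A, b, genes = _design(expr, y)
    n = len(b)
    if n < 4:
        raise ValueError("need >= 4 organoids")
    n_keep = n - n // 2
    if n_keep < 4:
        raise ValueError("fewer than 4 retained samples per iteration")
    rng = np.random.default_rng(seed)
    pvals = np.zeros((n_iter, len(genes)))
    defined = np.ones(len(genes), dtype=bool)
    for it in range(n_iter):
        keep = rng.choice(n, size=n_keep, replace=False)
        for j in range(len(genes)):
            col = A[keep, j]
            if np.all(col == col[0]):
                defined[j] = False
                continue
            rho, p = spearmanr(col, b[keep])
            pvals[it, j] = p if np.isfinite(p) else 1.0
    if not defined.all():
        excluded = [genes[j] for j in np.flatnonzero(~defined)]
        logger.warning("excluding %d constant genes from selection: %s...",
                       len(excluded), excluded[:5])
    mean_p = pvals.mean(axis=0)
    return sorted(
        genes[j] for j in np.flatnonzero(defined & (mean_p < p_cut))
    )
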