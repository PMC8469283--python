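"""Ridge decoder of EMG from lagged cortical rates, evaluated by VAF.

The decoder is linear, y_hat = X beta, with beta the ridge estimator
beta = (X'X + lambda I)^-1 X'y.  The ridge parameter is not tuned by search:
lambda is the smallest value that caps the condition number of the penalised
Gram matrix at kappa_max (10^3 by default), computed in closed form from the
extreme eigenvalues of X'X.  Performance is the variance accounted for,

    VAF = 1 - sum (y_hat_i - y_i)^2 / sum (y_i - y_bar)^2,

estimated by 5-fold blocked cross-validation: each session is split into
five contiguous blocks, the decoder is trained on four and evaluated on the
held-out block, and the per-muscle VAF is reported as mean +/- s.e.m. over
folds.  Contiguous (not shuffled) blocks respect the autocorrelation of the
walking data and prevent train/test leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_KAPPA_MAX = 1.0e3


class SingularDesignError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ridge parameter from the condition-number cap
# ---------------------------------------------------------------------------

def select_lambda(X: np.ndarray,
                  kappa_max: float = DEFAULT_KAPPA_MAX) -> float:
    """Smallest lambda with cond(X'X + lambda I) <= kappa_max.

    With s_max, s_min the extreme eigenvalues of X'X, the penalised
    condition number is (s_max + lambda)/(s_min + lambda), so

        lambda = max(0, (s_max - kappa_max * s_min) / (kappa_max - 1)).
    """
    if kappa_max <= 1:
        raise ValueError("kappa_max must exceed 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eigs = np.linalg.eigvalsh(X.T @ X)
    return lambda_from_eigenvalues(float(eigs[-1]), float(max(eigs[0], 0.0)),
                                   kappa_max)


def lambda_from_eigenvalues(s_max: float, s_min: float,
                            kappa_max: float = DEFAULT_KAPPA_MAX) -> float:
    """Closed-form ridge parameter from the extreme Gram eigenvalues."""
    if kappa_max <= 1:
        raise ValueError("kappa_max must exceed 1")
    if s_max <= 0:
        raise SingularDesignError(
            "all-zero design: no ridge parameter can bound the condition "
            "number of a zero Gram matrix")
    return max(0.0, (s_max - kappa_max * s_min) / (kappa_max - 1.0))


def gram_condition(X: np.ndarray, lam: float) -> float:
    """Condition number of X'X + lambda I."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eigs = np.linalg.eigvalsh(X.T @ X)
    lo, hi = max(float(eigs[0]), 0.0) + lam, float(eigs[-1]) + lam
    return np.inf if lo <= 0 else hi / lo


# ---------------------------------------------------------------------------
# ridge fit
# ---------------------------------------------------------------------------

@dataclass
class RidgeModel:
    """Fitted ridge decoder: slopes per design column plus an intercept.

    The intercept is unpenalised (EMG envelopes have a nonzero baseline);
    fitting centres X and y, solves the penalised normal equations on the
    centred data, and recovers the intercept from the means.
    """

    beta: np.ndarray
    intercept: np.ndarray
    lam: float
    kappa_max: float
    condition_number: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.intercept


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float,
              kappa_max: float = DEFAULT_KAPPA_MAX,
              check_condition: bool = True) -> RidgeModel:
    """Solve beta = (X'X + lambda I)^-1 X'y with an unpenalised intercept.

    ``y`` may be a vector or an (n, n_targets) matrix.  After fitting, the
    condition number of the penalised Gram is verified against ``kappa_max``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    y2d = y[:, np.newaxis] if y.ndim == 1 else y
    if X.shape[0] != y2d.shape[0]:
        raise ValueError("X and y row counts differ")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    x_mean = X.mean(axis=0)
    y_mean = y2d.mean(axis=0)
    Xc = X - x_mean
    gram = Xc.T @ Xc + lam * np.eye(X.shape[1])
    try:
        beta = np.linalg.solve(gram, Xc.T @ (y2d - y_mean))
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            f"penalised Gram is singular at lambda={lam}: {exc}") from exc
    intercept = y_mean - x_mean @ beta

    eigs = np.linalg.eigvalsh(Xc.T @ Xc)
    lo = max(float(eigs[0]), 0.0) + lam
    cond = np.inf if lo <= 0 else (float(eigs[-1]) + lam) / lo
    if check_condition and cond > kappa_max * (1 + 1e-9):
        raise SingularDesignError(
            f"condition number {cond:.3g} exceeds the cap {kappa_max:.3g}; "
            "select lambda with select_lambda first")

    if y.ndim == 1:
        beta, intercept = beta[:, 0], intercept[0]
    return RidgeModel(beta=beta, intercept=np.atleast_1d(intercept),
                      lam=lam, kappa_max=kappa_max, condition_number=cond)


# ---------------------------------------------------------------------------
# variance accounted for
# ---------------------------------------------------------------------------

def vaf(measured: np.ndarray, predicted: np.ndarray) -> float:
    """VAF = 1 - SSE/SST; at most 1, negative when worse than the mean."""
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size:
        raise ValueError("length mismatch")
    if measured.size < 2:
        raise ValueError("need at least two samples")
    sst = float(np.sum((measured - measured.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("VAF undefined for a constant measured signal")
    sse = float(np.sum((predicted - measured) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# blocked cross-validation
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Per-muscle, per-fold VAF of one session's blocked CV."""

    muscles: list[str]
    fold_vaf: np.ndarray          # (k_folds, n_muscles)
    fold_bounds: list[tuple[int, int]]
    lambdas: np.ndarray
    kappa_max: float

    @property
    def mean_vaf(self) -> np.ndarray:
        return self.fold_vaf.mean(axis=0)

    @property
    def sem_vaf(self) -> np.ndarray:
        k = self.fold_vaf.shape[0]
        if k < 2:
            return np.zeros(self.fold_vaf.shape[1])
        return self.fold_vaf.std(axis=0, ddof=1) / np.sqrt(k)

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (float(mu), float(se)) for m, mu, se in
                zip(self.muscles, self.mean_vaf, self.sem_vaf)}


def blocked_cv(X: np.ndarray, Y: np.ndarray, muscles: list[str] | None = None,
               k_folds: int = 5,
               kappa_max: float = DEFAULT_KAPPA_MAX) -> DecodingResult:
    """k-fold blocked cross-validation of the ridge decoder.

    The rows (time order preserved) are split into ``k_folds`` contiguous
    blocks; for each fold the ridge parameter is re-selected on the training
    block only, the decoder fitted, and per-muscle VAF computed on the
    held-out block.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, np.newaxis]
    n = X.shape[0]
    if muscles is None:
        muscles = [f"m{j}" for j in range(Y.shape[1])]
    if n < 2 * k_folds:
        raise InsufficientDataError(
            f"{n} rows cannot form {k_folds} useful contiguous blocks")

    bounds = np.linspace(0, n, k_folds + 1).astype(int)
    fold_vaf = np.empty((k_folds, Y.shape[1]))
    lambdas = np.empty(k_folds)
    fold_bounds = []
    for f in range(k_folds):
        lo, hi = int(bounds[f]), int(bounds[f + 1])
        fold_bounds.append((lo, hi))
        test = np.zeros(n, dtype=bool)
        test[lo:hi] = True
        lam = select_lambda(X[~test] - X[~test].mean(axis=0), kappa_max)
        model = fit_ridge(X[~test], Y[~test], lam, kappa_max)
        pred = model.predict(X[test])
        for j in range(Y.shape[1]):
            fold_vaf[f, j] = vaf(Y[test][:, j], pred[:, j])
        lambdas[f] = lam
    return DecodingResult(muscles=list(muscles), fold_vaf=fold_vaf,
                          fold_bounds=fold_bounds, lambdas=lambdas,
                          kappa_max=kappa_max)


__all__ = [
    "DEFAULT_KAPPA_MAX",
    "DecodingResult",
    "InsufficientDataError",
    "RidgeModel",
    "SingularDesignError",
    "blocked_cv",
    "fit_ridge",
    "gram_condition",
    "lambda_from_eigenvalues",
    "select_lambda",
    "vaf",
]
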