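"""Adaboost.RT and its modified variant with penalized, soft-thresholded weak learners.

Standard Adaboost.RT boosts regressors by binarizing each round's outcome:
a training sample is "incorrect" when its absolute relative error exceeds
a fixed threshold psi in (0, 1). The round's error rate eps_z is the
distribution mass on incorrect samples, beta_z = eps_z ** c, and correctly
predicted samples are down-weighted by beta_z before renormalization. The
ensemble output is the log(1/beta_z)-weighted mean of weak outputs.

The modified variant replaces the manual psi with a data-driven robust
threshold: each round fits a ridge or lasso weak learner on the current
distribution and treats its residual signal as a noisy observation
l[n] = m[n] + v[n] of the genuine misfit m[n]; soft thresholding collapses
noise-level residuals to exactly zero, and the samples whose denoised
error deviates from the round's mean error by more than lambda_rel times
the error standard deviation are flagged as rejected. eps_z is the distribution mass on rejected
samples; the round is rolled back and boosting stops if eps_z > 1/2.
beta_z = eps_z / (1 - eps_z), the learner's vote is alpha_z = -log beta_z,
and rejected samples are down-weighted by beta_z (see
``classic_emphasis`` for the complementary update). Final votes are
normalized to sum to 1 and the ensemble output is their convex combination.

Both variants consume regression targets 0.0/1.0 and classify by
thresholding the continuous output at 0.45.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance_features import DEFAULT_THRESHOLD, decode_predictions, encode_targets

__all__ = [
    "WeakLearnerModel",
    "BoostEnsemble",
    "AdaboostRT",
    "ModifiedAdaboostRT",
    "absolute_relative_error",
    "soft_threshold",
    "ridge_fit",
    "lasso_fit",
    "fit_adaboost_rt",
    "predict_adaboost_rt",
    "fit_modified_adaboost_rt",
    "predict_modified",
    "universal_threshold",
]

_EPS_FLOOR = 1e-10
_ZERO_TRUTH_GUARD = 1e-12


@dataclass
class WeakLearnerModel:
    """A fitted linear weak learner: prediction = X @ coefficients + intercept."""

    kind: str  # "ridge" | "lasso" | "ols"
    coefficients: np.ndarray
    intercept: float
    penalty: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coefficients + self.intercept


@dataclass
class BoostEnsemble:
    """Ordered weak learners with their votes and variant hyperparameters.

    For the standard variant ``weights`` holds beta_z per round (votes are
    log(1/beta_z)); for the modified variant it holds the normalized
    alpha_z, which sum to 1.
    """

    variant: str  # "standard" | "modified"
    learners: list[WeakLearnerModel]
    weights: np.ndarray
    hyperparams: dict
    n_iters_used: int
    iteration_log: list[dict] = field(default_factory=list)


def absolute_relative_error(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """|pred - truth| / |truth|, falling back to |pred - truth| near zero truth."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same shape")
    abs_err = np.abs(pred - truth)
    small = np.abs(truth) < _ZERO_TRUTH_GUARD
    denom = np.where(small, 1.0, np.abs(truth))
    return np.where(small, abs_err, abs_err / denom)


def soft_threshold(l: np.ndarray | float, T: float) -> np.ndarray | float:
    """Shrinkage toward zero: l - sgn(l) T when |l| >= T, else 0 (elementwise)."""
    if T < 0:
        raise ValueError("threshold must be nonnegative")
    arr = np.asarray(l, dtype=np.float64)
    out = np.where(np.abs(arr) >= T, arr - np.sign(arr) * T, 0.0)
    return float(out) if np.isscalar(l) or arr.ndim == 0 else out


def universal_threshold(residuals: np.ndarray) -> float:
    """MAD-based universal threshold sigma_hat * sqrt(2 ln n) on the residuals."""
    r = np.asarray(residuals, dtype=np.float64).ravel()
    n = max(r.size, 2)
    sigma = np.median(np.abs(r - np.median(r))) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(n)))


def _weighted_design(A: np.ndarray, b: np.ndarray, weights: np.ndarray | None):
    A = np.asarray(A, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64).ravel()
    if A.ndim != 2 or A.shape[0] != b.size:
        raise ValueError("design matrix and targets are inconsistent")
    if weights is None:
        w = np.ones(b.size)
    else:
        w = np.asarray(weights, dtype=np.float64).ravel()
        if w.size != b.size or np.any(w < 0):
            raise ValueError("weights must be nonnegative and match the sample size")
    return A, b, w


def ridge_fit(
    A: np.ndarray,
    b: np.ndarray,
    lambda_pen: float,
    weights: np.ndarray | None = None,
) -> WeakLearnerModel:
    """Closed-form weighted ridge: min sum_j w_j (b_j - a_j beta - beta0)^2 + lambda ||beta||^2.

    The intercept is unpenalized. ``lambda_pen = 0`` reduces to weighted
    ordinary least squares and raises if the system is singular.
    """
    if lambda_pen < 0:
        raise ValueError("lambda_pen must be >= 0")
    A, b, w = _weighted_design(A, b, weights)
    n, p = A.shape
    Aug = np.hstack([np.ones((n, 1)), A])
    WA = Aug * w[:, None]
    gram = Aug.T @ WA
    reg = np.zeros(p + 1)
    reg[1:] = lambda_pen
    gram = gram + np.diag(reg)
    rhs = Aug.T @ (w * b)
    if lambda_pen == 0:
        if np.linalg.matrix_rank(np.sqrt(w)[:, None] * Aug) < p + 1:
            raise np.linalg.LinAlgError(
                "singular weighted system at lambda_pen=0; use lambda_pen > 0"
            )
    coef = np.linalg.solve(gram, rhs)
    return WeakLearnerModel(
        kind="ridge" if lambda_pen > 0 else "ols",
        coefficients=coef[1:],
        intercept=float(coef[0]),
        penalty=lambda_pen,
    )


def lasso_fit(
    A: np.ndarray,
    b: np.ndarray,
    lambda_pen: float,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
    beta_init: np.ndarray | None = None,
) -> WeakLearnerModel:
    """Coordinate-descent lasso: min sum_j w_j (b_j - a_j beta - beta0)^2 + lambda ||beta||_1.

    The intercept is unpenalized. Converges when the largest coefficient
    change in a full sweep drops below ``tol`` (or after ``max_sweeps``
    sweeps). With an orthonormal design and unit weights the solution is the
    soft-thresholding of the OLS coefficients at lambda_pen / 2.
    """
    if lambda_pen < 0:
        raise ValueError("lambda_pen must be >= 0")
    A, b, w = _weighted_design(A, b, weights)
    n, p = A.shape
    sw = w.sum()
    if sw <= 0:
        raise ValueError("weights sum to zero")
    # profile out the unpenalized intercept by weighted centering, then run
    # covariance-update coordinate descent on the p x p Gram system
    x_mean = (w[:, None] * A).sum(axis=0) / sw
    b_mean = float((w * b).sum() / sw)
    Ac = A - x_mean
    bc = b - b_mean
    G = (w[:, None] * Ac).T @ Ac
    c = Ac.T @ (w * bc)
    diag = np.diag(G).copy()
    if beta_init is not None and np.asarray(beta_init).shape == (p,):
        beta = np.asarray(beta_init, dtype=np.float64).copy()  # warm start
        Gbeta = G @ beta
    else:
        beta = np.zeros(p)
        Gbeta = np.zeros(p)
    half_lam = lambda_pen / 2.0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for i in range(p):
            if diag[i] <= 0:
                continue
            rho = c[i] - Gbeta[i] + diag[i] * beta[i]
            new = soft_threshold(rho, half_lam) / diag[i]
            delta = new - beta[i]
            if delta != 0.0:
                Gbeta += delta * G[:, i]
                beta[i] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    intercept = b_mean - float(x_mean @ beta)
    return WeakLearnerModel(
        kind="lasso", coefficients=beta, intercept=intercept, penalty=lambda_pen
    )


def _default_weak_factory():
    # near-OLS ridge: the tiny penalty only guards against exact singularity
    return lambda X, y, w: ridge_fit(X, y, 1e-6, w)


def fit_adaboost_rt(
    X: np.ndarray,
    y: np.ndarray,
    psi: float = 0.2,
    c: int = 1,
    Z: int = 50,
    weak_learner_factory=None,
) -> BoostEnsemble:
    """Standard Adaboost.RT (threshold psi, power coefficient c, Z rounds).

    ``weak_learner_factory`` is a callable ``(X, y, weights) -> model with
    .predict``; the default is near-OLS ridge. eps_z is floored at 1e-10
    (an exactly fit round would otherwise zero every vote) and clipped just
    below 1.
    """
    if not 0.0 < psi < 1.0:
        raise ValueError("psi must lie strictly in (0, 1)")
    if Z < 1:
        raise ValueError("Z must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    q = y.size
    fit_weak = weak_learner_factory or _default_weak_factory()

    D = np.full(q, 1.0 / q)
    learners: list[WeakLearnerModel] = []
    betas: list[float] = []
    log: list[dict] = []
    for z in range(Z):
        try:
            # weights rescaled to sum to q so the weak learner sees an
            # ordinary-sized loss (glmnet convention)
            model = fit_weak(X, y, D * q)
        except Exception as exc:  # noqa: BLE001 - re-raise with round context
            raise RuntimeError(f"weak learner failed at round {z}: {exc}") from exc
        pred = model.predict(X)
        are = absolute_relative_error(pred, y)
        incorrect = are > psi
        eps = float(D[incorrect].sum())
        eps = min(max(eps, _EPS_FLOOR), 1.0 - _EPS_FLOOR)
        beta = eps**c
        D_next = D.copy()
        D_next[~incorrect] *= beta
        Y = D_next.sum()
        D_next /= Y
        learners.append(model)
        betas.append(beta)
        log.append({"round": z, "eps": eps, "beta": beta, "norm": float(Y)})
        D = D_next
    return BoostEnsemble(
        variant="standard",
        learners=learners,
        weights=np.asarray(betas),
        hyperparams={"psi": psi, "c": c, "Z": Z},
        n_iters_used=len(learners),
        iteration_log=log,
    )


def predict_adaboost_rt(ensemble: BoostEnsemble, X: np.ndarray) -> np.ndarray:
    """log(1/beta_z)-weighted mean of the weak-learner outputs."""
    if ensemble.variant != "standard":
        raise ValueError("ensemble is not a standard Adaboost.RT model")
    X = np.asarray(X, dtype=np.float64)
    votes = np.log(1.0 / ensemble.weights)
    total = votes.sum()
    if total <= 0:
        # all rounds at the eps ceiling: fall back to a plain average
        votes = np.ones_like(votes)
        total = votes.sum()
    preds = np.stack([m.predict(X) for m in ensemble.learners], axis=0)
    return (votes[:, None] * preds).sum(axis=0) / total


def fit_modified_adaboost_rt(
    X: np.ndarray,
    y: np.ndarray,
    lambda_rel: float = 0.5,
    lambda_pen: float = 1.0,
    penalty: str = "ridge",
    Z: int = 50,
    threshold_rule="universal",
    classic_emphasis: bool = False,
) -> BoostEnsemble:
    """Modified Adaboost.RT with ridge/lasso weak learners and soft thresholding.

    Per round: fit the penalized learner on the current distribution p,
    form the residual signal prediction - target, and soft-threshold it
    with T from ``threshold_rule`` (``"universal"`` = MAD-based universal
    threshold on the current residuals, or ``("constant", T)``) so that
    noise-level residuals collapse to exactly zero; the surviving denoised
    errors e_z are the evidence of genuine misfit, and samples with
    |e_z - mean(e_z)| > lambda_rel * std(e_z) are rejected. eps_z is the rejected mass; a round with eps_z > 1/2 is
    rolled back and the loop terminates. beta_z = eps_z / (1 - eps_z),
    alpha_z = -log beta_z, and rejected samples are multiplied by beta_z
    (as printed; ``classic_emphasis=True`` instead down-weights accepted
    samples, the classic AdaBoost emphasis direction). The final alphas are
    normalized to sum to 1.
    """
    if not 0.0 < lambda_rel < 1.0:
        raise ValueError("lambda_rel must lie strictly in (0, 1)")
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if penalty not in ("ridge", "lasso"):
        raise ValueError("penalty must be 'ridge' or 'lasso'")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    q = y.size
    if penalty == "ridge":
        fit_weak = ridge_fit
    else:
        # warm-start each round's coordinate descent from the previous
        # round's coefficients; the distribution changes little per round
        _warm = {"beta": None}

        def fit_weak(Xf, yf, lam, wf):
            model = lasso_fit(Xf, yf, lam, wf, beta_init=_warm["beta"])
            _warm["beta"] = model.coefficients
            return model

    w = np.full(q, 1.0 / q)
    learners: list[WeakLearnerModel] = []
    alphas: list[float] = []
    log: list[dict] = []
    for z in range(Z):
        Yz = w.sum()
        p = w / Yz
        try:
            # as above: distribution rescaled to sum to q so lambda_pen is on
            # the familiar scale of an unweighted q-sample fit
            model = fit_weak(X, y, lambda_pen, p * q)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"weak learner failed at round {z}: {exc}") from exc
        raw = model.predict(X)
        resid = raw - y
        if threshold_rule == "universal":
            T = universal_threshold(resid)
        elif (
            isinstance(threshold_rule, tuple)
            and len(threshold_rule) == 2
            and threshold_rule[0] == "constant"
        ):
            T = float(threshold_rule[1])
        else:
            raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
        # denoise the error signal: noise-level residuals collapse to exactly
        # zero, genuine misfits survive (shrunk by T)
        e = soft_threshold(resid, T)
        e_bar = float(e.mean())
        sigma = float(e.std())
        rejected = np.abs(e - e_bar) > lambda_rel * sigma
        eps = float(p[rejected].sum())
        if eps > 0.5:
            if not learners:
                raise RuntimeError(
                    "no usable weak learner: first round error rate exceeds 1/2"
                )
            break  # roll back this round and terminate
        eps = max(eps, _EPS_FLOOR)
        beta = eps / (1.0 - eps)
        alpha = -np.log(beta)
        if classic_emphasis:
            w = np.where(rejected, w, w * beta)
        else:
            w = np.where(rejected, w * beta, w)
        learners.append(model)
        alphas.append(alpha)
        log.append(
            {
                "round": z,
                "eps": eps,
                "beta": beta,
                "alpha": float(alpha),
                "threshold": T,
                "n_rejected": int(rejected.sum()),
            }
        )
    alphas = np.asarray(alphas, dtype=np.float64)
    total = alphas.sum()
    if total <= 0:
        warnings.warn(
            "all rounds carried nonpositive votes; using equal weights",
            RuntimeWarning,
            stacklevel=2,
        )
        alphas = np.full(len(learners), 1.0 / len(learners))
    else:
        alphas = alphas / total
    return BoostEnsemble(
        variant="modified",
        learners=learners,
        weights=alphas,
        hyperparams={
            "lambda_rel": lambda_rel,
            "lambda_pen": lambda_pen,
            "penalty": penalty,
            "Z": Z,
            "threshold_rule": threshold_rule,
            "classic_emphasis": classic_emphasis,
        },
        n_iters_used=len(learners),
        iteration_log=log,
    )


def predict_modified(ensemble: BoostEnsemble, X: np.ndarray) -> np.ndarray:
    """Convex combination sum_z alpha_z h_z(a) of the weak-learner outputs."""
    if ensemble.variant != "modified":
        raise ValueError("ensemble is not a modified Adaboost.RT model")
    X = np.asarray(X, dtype=np.float64)
    preds = np.stack([m.predict(X) for m in ensemble.learners], axis=0)
    return (ensemble.weights[:, None] * preds).sum(axis=0)


class _BoostClassifierBase:
    """Common fit/predict surface: labels in, labels out, 0.45 decode."""

    threshold = DEFAULT_THRESHOLD
    ensemble_: BoostEnsemble | None = None

    def fit(self, X: np.ndarray, labels: np.ndarray):
        raise NotImplementedError

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        return decode_predictions(self.predict_value(X), self.threshold)


class AdaboostRT(_BoostClassifierBase):
    """Standard Adaboost.RT as a binary classifier (targets 0/1, decode at 0.45)."""

    def __init__(self, psi: float = 0.2, c: int = 1, Z: int = 50, weak_learner_factory=None):
        self.psi = psi
        self.c = c
        self.Z = Z
        self.weak_learner_factory = weak_learner_factory

    def fit(self, X: np.ndarray, labels: np.ndarray):
        y = encode_targets(labels)
        self.ensemble_ = fit_adaboost_rt(
            X, y, psi=self.psi, c=self.c, Z=self.Z,
            weak_learner_factory=self.weak_learner_factory,
        )
        return self

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        return predict_adaboost_rt(self.ensemble_, X)


class ModifiedAdaboostRT(_BoostClassifierBase):
    """Modified Adaboost.RT (ridge or lasso) as a binary classifier."""

    def __init__(
        self,
        penalty: str = "ridge",
        lambda_rel: float = 0.5,
        lambda_pen: float = 1.0,
        Z: int = 50,
        threshold_rule="universal",
        classic_emphasis: bool = False,
    ):
        self.penalty = penalty
        self.lambda_rel = lambda_rel
        self.lambda_pen = lambda_pen
        self.Z = Z
        self.threshold_rule = threshold_rule
        self.classic_emphasis = classic_emphasis

    def fit(self, X: np.ndarray, labels: np.ndarray):
        y = encode_targets(labels)
        self.ensemble_ = fit_modified_adaboost_rt(
            X,
            y,
            lambda_rel=self.lambda_rel,
            lambda_pen=self.lambda_pen,
            penalty=self.penalty,
            Z=self.Z,
            threshold_rule=self.threshold_rule,
            classic_emphasis=self.classic_emphasis,
        )
        return self

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        return predict_modified(self.ensemble_, X)
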