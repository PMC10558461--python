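"""L1-penalized conditional logistic regression for 1:1 matched pairs.

For a matched pair with case covariates x_case and control covariates
x_control, the conditional likelihood of the pair depends only on the
difference d = x_case - x_control:

    P(observed case is the case | pair)  =  sigmoid(d . beta)

so the negative conditional log-likelihood over n pairs is

    -log L(beta) = sum_i log(1 + exp(-d_i . beta)),

an intercept-free logistic loss on the difference rows with all responses
equal to one.  The penalized problem  min_beta  -log L + lambda * ||beta||_1
is solved by cyclic coordinate descent on the iteratively reweighted
quadratic approximation (soft-thresholding on the weighted Gram system),
with warm starts along a geometric lambda path and objective-based step
halving as a safeguard.  Columns are standardized by the standard
deviation of the pair differences before penalized fitting and reported
back on the original scale.

The estimators follow the scikit-learn protocol (get_params/set_params,
``fit`` / ``decision_function``, trailing-underscore fitted attributes);
``X`` passed to ``fit`` is the pair-difference matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .exposure import AnalysisDataset

_WMIN = 1e-6  # floor on IRLS weights, guards p(1-p) underflow


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------
@dataclass
class DiffMatrix:
    """Case-minus-control covariate differences, one row per pair."""

    D: np.ndarray
    names: list
    pair_ids: np.ndarray | None = None
    strata: np.ndarray | None = None
    scale: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("DiffMatrix: D must be 2-dimensional")
        if not np.isfinite(self.D).all():
            raise ValueError("DiffMatrix: non-finite difference entries")
        if self.scale is None:
            self.scale = (
                self.D.std(axis=0)
                if self.D.shape[0]
                else np.zeros(self.D.shape[1])
            )

    @property
    def n_pairs(self) -> int:
        return self.D.shape[0]

    @property
    def n_variables(self) -> int:
        return self.D.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Columns that are not identically zero (perfectly matched
        covariates are not estimable and are flagged out)."""
        return ~np.all(self.D == 0.0, axis=0)

    @property
    def dropped_names(self) -> list:
        return [n for n, a in zip(self.names, self.active) if not a]


def pair_difference(dataset: AnalysisDataset) -> DiffMatrix:
    """Build the difference matrix from a matched analysis dataset."""
    counts = dataset.data.groupby("pair_id")["role"].nunique()
    bad = counts.index[counts < 2].tolist()
    if bad:
        raise ValueError(f"incomplete pairs: {bad[:10]}")
    D = dataset.case_matrix() - dataset.control_matrix()
    return DiffMatrix(
        D,
        names=list(dataset.variables),
        pair_ids=dataset.pair_ids(),
        strata=dataset.strata.to_numpy(),
    )


def _as_matrix(D) -> tuple[np.ndarray, list]:
    if isinstance(D, DiffMatrix):
        return D.D, list(D.names)
    D = np.atleast_2d(np.asarray(D, dtype=float))
    return D, [f"x{j}" for j in range(D.shape[1])]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------
def neg_log_clik(beta, D) -> float:
    """Exact negative conditional log-likelihood, overflow-safe."""
    M, _ = _as_matrix(D)
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != M.shape[1]:
        raise ValueError(
            f"beta has length {beta.shape[0]}, expected {M.shape[1]}"
        )
    return float(np.logaddexp(0.0, -(M @ beta)).sum())


def _gradient(beta, M) -> np.ndarray:
    return -M.T @ (1.0 - expit(M @ beta))


def lambda_max(D) -> float:
    """Smallest penalty at which the all-zero fit is optimal.

    Equals the sup-norm of the gradient of -log L at beta = 0, i.e.
    max_j |0.5 * sum_i d_ij| (KKT condition for the L1 problem).
    """
    M, _ = _as_matrix(D)
    if M.size == 0:
        return 0.0
    return float(np.max(np.abs(0.5 * M.sum(axis=0))))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------
@dataclass
class FitResult:
    """Coefficients (original covariate scale) and bookkeeping for one fit.

    Non-estimable (zero-variance) columns carry NaN coefficients and are
    excluded from ``selected``.  Unpenalized fits additionally carry Wald
    standard errors and 95% confidence bounds.
    """

    beta: np.ndarray
    names: list
    lam: float
    converged: bool
    n_iter: int
    se: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def selected(self) -> list:
        return [
            n
            for n, b in zip(self.names, self.beta)
            if np.isfinite(b) and b != 0.0
        ]

    def coef_dict(self) -> dict:
        return dict(zip(self.names, self.beta))


@dataclass
class LassoPath:
    lambdas: np.ndarray
    coefficients: np.ndarray  # n_lambda x p, original scale
    deviance: np.ndarray
    nonzero: np.ndarray
    names: list


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    fold_assignments: np.ndarray
    lambda_min: float
    lambda_1se: float
    rule: str
    seed: int

    @property
    def lambda_selected(self) -> float:
        return self.lambda_1se if self.rule == "1se" else self.lambda_min


# ---------------------------------------------------------------------------
# solver internals (standardized coordinates)
# ---------------------------------------------------------------------------
def _cd_quadratic(G, b, lam, beta, tol, max_full_sweeps=50, max_active_sweeps=200):
    """Coordinate descent for 0.5 beta'G beta - b.beta + lam ||beta||_1.

    Active-set cycling: after each full sweep, iterate on the nonzero
    coordinates until stable, then verify with another full sweep.
    Columns with a zero diagonal (constant within this subsample) are
    skipped and keep coefficient zero.  Operates in place on ``beta``.
    """
    diag = G.diagonal()
    usable = np.nonzero(diag > 0)[0]
    Gbeta = G @ beta

    def sweep(indices) -> float:
        worst = 0.0
        for j in indices:
            gj = b[j] - Gbeta[j] + diag[j] * beta[j]
            new = np.sign(gj) * max(abs(gj) - lam, 0.0) / diag[j]
            step = new - beta[j]
            if step != 0.0:
                Gbeta[:] += G[:, j] * step
                beta[j] = new
                worst = max(worst, abs(step))
        return worst

    for _ in range(max_full_sweeps):
        if sweep(usable) < tol:
            break
        for _ in range(max_active_sweeps):
            act = np.nonzero(beta != 0.0)[0]
            if sweep(act) < tol:
                break
    return beta


def _fit_std(M, lam, beta0, tol, max_iter):
    """Proximal-Newton / IRLS loop on the standardized difference matrix.

    Converges on the max absolute coefficient change; an objective plateau
    (relative decrease below 1e-12) also terminates, which handles the
    quasi-separated small-sample regime where coefficients drift while the
    penalized objective is already flat.
    """
    beta = np.asarray(beta0, dtype=float).copy()
    obj = neg_log_clik(beta, M) + lam * np.abs(beta).sum()
    for it in range(1, max_iter + 1):
        eta = M @ beta
        prob = expit(eta)
        w = np.clip(prob * (1.0 - prob), _WMIN, None)
        z = eta + (1.0 - prob) / w
        G = (M * w[:, None]).T @ M
        b = M.T @ (w * z)
        proposal = _cd_quadratic(G, b, lam, beta.copy(), max(tol, 1e-10))
        # line search on the exact objective (the quadratic model can
        # overshoot for extreme linear predictors)
        step = 1.0
        while True:
            cand = beta + step * (proposal - beta)
            cobj = neg_log_clik(cand, M) + lam * np.abs(cand).sum()
            if cobj <= obj + 1e-12 or step < 1e-6:
                break
            step *= 0.5
        delta = float(np.max(np.abs(cand - beta))) if beta.size else 0.0
        plateau = obj - cobj < 1e-12 * (abs(obj) + 1.0)
        beta, obj = cand, cobj
        if delta < tol or plateau:
            return beta, it, True
    return beta, max_iter, False


def _standardize(D: DiffMatrix):
    act = D.active
    # constant non-zero difference columns carry information but have no
    # spread to scale by; they keep unit scale
    scale = np.where(D.scale[act] > 0, D.scale[act], 1.0)
    return D.D[:, act] / scale, act, scale


def _unpack(beta_std, act, scale, p):
    beta = np.full(p, np.nan)
    beta[act] = beta_std / scale
    return beta


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
class ConditionalLogisticLasso(BaseEstimator):
    """L1-penalized conditional logistic regression for 1:1 matched pairs.

    Parameters
    ----------
    lam : float or "cv"
        Penalty level on the standardized scale.  "cv" (default) selects it
        by cross-validated out-of-fold conditional deviance over the path.
    n_lambda, lambda_min_ratio : path grid (geometric from lambda_max down).
    cv : number of folds; folds partition pairs, never pair members.
    rule : "min" or "1se" CV selection rule.
    standardize : scale columns by the pair-difference SD before penalizing.
    tol, max_iter : convergence tolerance on the max coefficient change and
        outer iteration cap.

    Attributes (after ``fit``)
    --------------------------
    coef_ : coefficients on the original scale (NaN for non-estimable
        zero-variance columns).
    odds_ratios_, selected_, lambda_, path_, cv_, converged_, n_iter_.
    """

    def __init__(
        self,
        lam="cv",
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        cv: int = 10,
        rule: str = "min",
        standardize: bool = True,
        tol: float = 1e-7,
        max_iter: int = 10000,
        random_state: int = 0,
    ):
        self.lam = lam
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.rule = rule
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internals --------------------------------------------------------
    def _prepare(self, X) -> DiffMatrix:
        return X if isinstance(X, DiffMatrix) else DiffMatrix(*_as_matrix(X))

    def _std_matrix(self, D: DiffMatrix):
        if self.standardize:
            return _standardize(D)
        act = D.active
        return D.D[:, act], act, np.ones(int(act.sum()))

    def _grid(self, lmax: float) -> np.ndarray:
        if lmax <= 0:
            return np.array([0.0])
        return np.geomspace(lmax, lmax * self.lambda_min_ratio, self.n_lambda)

    def _path(self, M, lambdas, beta0=None):
        p = M.shape[1]
        betas = np.zeros((len(lambdas), p))
        dev = np.zeros(len(lambdas))
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        iters, all_ok = 0, True
        for i, lam in enumerate(lambdas):
            beta, it, ok = _fit_std(M, lam, beta, self.tol, self.max_iter)
            betas[i] = beta
            dev[i] = 2.0 * neg_log_clik(beta, M)
            iters += it
            all_ok &= ok
        return betas, dev, iters, all_ok

    # -- API --------------------------------------------------------------
    def fit(self, X, y=None):
        """Fit on a pair-difference matrix (DiffMatrix or n_pairs x p array).

        ``y`` is accepted for scikit-learn pipeline compatibility and
        ignored: the response is implicit in the sign convention of the
        difference rows.
        """
        D = self._prepare(X)
        M, act, scale = self._std_matrix(D)
        p = D.n_variables
        lmax = lambda_max(M)

        self.cv_ = None
        if self.lam == "cv":
            self.cv_ = cv_select_lambda(
                D,
                n_folds=self.cv,
                rule=self.rule,
                seed=self.random_state,
                n_lambda=self.n_lambda,
                lambda_min_ratio=self.lambda_min_ratio,
                standardize=self.standardize,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            lam = self.cv_.lambda_selected
        else:
            lam = float(self.lam)

        lambdas = self._grid(lmax)
        betas, dev, _, _ = self._path(M, lambdas)
        coefs = np.vstack([_unpack(b, act, scale, p) for b in betas])
        self.path_ = LassoPath(
            lambdas=lambdas,
            coefficients=coefs,
            deviance=dev,
            nonzero=(betas != 0).sum(axis=1),
            names=list(D.names),
        )
        # final fit at the requested lambda, warm-started from the nearest
        # path solution
        j = int(np.argmin(np.abs(lambdas - lam)))
        beta_std, n_iter, ok = _fit_std(M, lam, betas[j].copy(), self.tol, self.max_iter)
        if not ok:
            warnings.warn("ConditionalLogisticLasso: max_iter reached", stacklevel=2)
        self.coef_ = _unpack(beta_std, act, scale, p)
        self.lambda_ = lam
        self.lambda_max_ = lmax
        self.names_ = list(D.names)
        self.converged_ = ok
        self.n_iter_ = n_iter
        self.n_features_in_ = p
        return self

    @property
    def odds_ratios_(self) -> np.ndarray:
        return np.exp(self.coef_)

    @property
    def selected_(self) -> list:
        return [
            n
            for n, b in zip(self.names_, self.coef_)
            if np.isfinite(b) and b != 0.0
        ]

    def decision_function(self, X) -> np.ndarray:
        """Linear predictor x . beta (NaN coefficients contribute zero)."""
        X = np.asarray(X, dtype=float)
        beta = np.nan_to_num(self.coef_, nan=0.0)
        return X @ beta

    def result(self) -> FitResult:
        return FitResult(
            beta=self.coef_,
            names=self.names_,
            lam=self.lambda_,
            converged=self.converged_,
            n_iter=self.n_iter_,
        )


class ConditionalLogisticRegression(BaseEstimator):
    """Unpenalized conditional logistic regression (Newton-Raphson).

    Standard errors come from the inverse observed information at the
    maximum; Wald 95% confidence bounds are reported on the odds-ratio
    scale via exponentiation.  Quasi-separation is detected through a
    diverging coefficient norm and raised as an error suggesting
    penalization.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 200):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        D = X if isinstance(X, DiffMatrix) else DiffMatrix(*_as_matrix(X))
        M_all, act = D.D, D.active
        M = M_all[:, act]
        p_act = M.shape[1]
        beta = np.zeros(p_act)
        nll = neg_log_clik(beta, M)
        it, ok = 0, p_act == 0
        H = np.zeros((p_act, p_act))
        for it in range(1, self.max_iter + 1):
            prob = expit(M @ beta)
            w = np.clip(prob * (1 - prob), _WMIN, None)
            grad = _gradient(beta, M)
            H = (M * w[:, None]).T @ M
            try:
                direction = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as e:
                raise ValueError(
                    "conditional logistic MLE is not identifiable "
                    "(singular information); consider penalization"
                ) from e
            step = 1.0
            while True:
                cand = beta - step * direction
                cnll = neg_log_clik(cand, M)
                if cnll <= nll + 1e-12 or step < 1e-8:
                    break
                step *= 0.5
            delta = float(np.max(np.abs(cand - beta))) if p_act else 0.0
            plateau = nll - cnll < 1e-12 * (abs(nll) + 1.0)
            beta, nll = cand, cnll
            # |log-OR| beyond 15 on claims covariates means quasi-separation,
            # not a plausible effect size
            if np.max(np.abs(beta), initial=0.0) > 15.0:
                raise ValueError(
                    "separation detected (diverging coefficients); "
                    "use a penalized fit"
                )
            if delta < self.tol or plateau:
                ok = True
                break
        if p_act and not ok:
            warnings.warn("ConditionalLogisticRegression: max_iter reached", stacklevel=2)
        if p_act:
            prob = expit(M @ beta)
            w = np.clip(prob * (1 - prob), _WMIN, None)
            H = (M * w[:, None]).T @ M
            cov = np.linalg.inv(H)
            with np.errstate(invalid="ignore"):
                # ill-conditioned information can produce tiny negative
                # diagonal entries; their SEs come out NaN (not estimable)
                se = np.sqrt(np.diag(cov))
        else:
            se = np.zeros(0)
        if D.n_variables and not act.any():
            warnings.warn(
                "all difference columns are constant; likelihood is flat and "
                "coefficients are not estimable",
                stacklevel=2,
            )

        full = lambda v, fill: self._expand(v, act, D.n_variables, fill)
        self.coef_ = full(beta, np.nan)
        self.se_ = full(se, np.nan)
        z = 1.959963984540054  # Phi^{-1}(0.975)
        self.ci_low_ = full(beta - z * se, np.nan)
        self.ci_high_ = full(beta + z * se, np.nan)
        self.names_ = list(D.names)
        self.converged_ = ok
        self.n_iter_ = it
        self.n_features_in_ = D.n_variables
        self.neg_log_likelihood_ = nll
        return self

    @staticmethod
    def _expand(v, act, p, fill):
        out = np.full(p, fill, dtype=float)
        out[act] = v
        return out

    @property
    def odds_ratios_(self) -> np.ndarray:
        return np.exp(self.coef_)

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ np.nan_to_num(self.coef_, nan=0.0)

    def result(self) -> FitResult:
        return FitResult(
            beta=self.coef_,
            names=self.names_,
            lam=0.0,
            converged=self.converged_,
            n_iter=self.n_iter_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------
def fit_penalized(
    D,
    lam: float,
    beta_init=None,
    tol: float = 1e-7,
    max_iter: int = 10000,
    standardize: bool = True,
) -> FitResult:
    """Single penalized fit at a fixed lambda."""
    Dm = D if isinstance(D, DiffMatrix) else DiffMatrix(*_as_matrix(D))
    if lam < 0 or tol <= 0:
        raise ValueError("fit_penalized: need lam >= 0 and tol > 0")
    if standardize:
        M, act, scale = _standardize(Dm)
    else:
        act = Dm.active
        M, scale = Dm.D[:, act], np.ones(int(act.sum()))
    b0 = np.zeros(M.shape[1]) if beta_init is None else (
        np.asarray(beta_init, dtype=float)[act] * scale
    )
    beta_std, n_iter, ok = _fit_std(M, lam, b0, tol, max_iter)
    if not ok:
        warnings.warn("fit_penalized: max_iter reached", stacklevel=2)
    return FitResult(
        beta=_unpack(beta_std, act, scale, Dm.n_variables),
        names=list(Dm.names),
        lam=lam,
        converged=ok,
        n_iter=n_iter,
    )


def fit_path(
    D,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 10000,
) -> LassoPath:
    """Warm-started solution path on a geometric lambda grid."""
    if n_lambda < 2:
        raise ValueError("fit_path: n_lambda must be >= 2")
    Dm = D if isinstance(D, DiffMatrix) else DiffMatrix(*_as_matrix(D))
    if not Dm.active.any():
        raise ValueError("fit_path: all columns have zero variance")
    est = ConditionalLogisticLasso(
        lam=0.0,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        standardize=standardize,
        tol=tol,
        max_iter=max_iter,
    )
    M, act, scale = est._std_matrix(Dm)
    lambdas = est._grid(lambda_max(M))
    betas, dev, _, _ = est._path(M, lambdas)
    coefs = np.vstack([_unpack(b, act, scale, Dm.n_variables) for b in betas])
    return LassoPath(
        lambdas=lambdas,
        coefficients=coefs,
        deviance=dev,
        nonzero=(betas != 0).sum(axis=1),
        names=list(Dm.names),
    )


def cv_select_lambda(
    D,
    n_folds: int = 10,
    rule: str = "min",
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    standardize: bool = True,
    tol: float = 1e-7,
    max_iter: int = 10000,
    fold_assignments=None,
) -> CVResult:
    """Cross-validated lambda by out-of-fold conditional deviance.

    Folds partition *pairs* (a pair is never split).  Assignment is keyed
    to pair order after sorting by pair id when ids are available, so row
    permutations of the input do not change the folds under a fixed seed.
    """
    Dm = D if isinstance(D, DiffMatrix) else DiffMatrix(*_as_matrix(D))
    n = Dm.n_pairs
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"cv_select_lambda: need 2 <= n_folds <= {n}")
    est = ConditionalLogisticLasso(
        lam=0.0,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        standardize=standardize,
        tol=tol,
        max_iter=max_iter,
    )
    M, act, scale = est._std_matrix(Dm)
    lambdas = est._grid(lambda_max(M))

    if fold_assignments is not None:
        folds = np.asarray(fold_assignments)
    else:
        order = (
            np.argsort(Dm.pair_ids, kind="stable")
            if Dm.pair_ids is not None
            else np.arange(n)
        )
        rng = np.random.default_rng(seed)
        folds = np.empty(n, dtype=int)
        folds[order[rng.permutation(n)]] = np.arange(n) % n_folds

    fold_dev = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        train, test = folds != f, folds == f
        betas, _, _, _ = est._path(M[train], lambdas)
        # per-pair out-of-fold deviance, averaged within the fold
        eta = M[test] @ betas.T
        fold_dev[f] = 2.0 * np.logaddexp(0.0, -eta).mean(axis=0)
    mean_dev = fold_dev.mean(axis=0)
    se_dev = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    j = int(np.argmin(mean_dev))
    lambda_min_v = float(lambdas[j])
    within = mean_dev <= mean_dev[j] + se_dev[j]
    lambda_1se_v = float(lambdas[np.nonzero(within)[0][0]])
    return CVResult(
        lambdas=lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        fold_assignments=folds,
        lambda_min=lambda_min_v,
        lambda_1se=lambda_1se_v,
        rule=rule,
        seed=seed,
    )


def fit_unpenalized(D) -> FitResult:
    """Conditional logistic MLE with Wald standard errors."""
    est = ConditionalLogisticRegression()
    est.fit(D)
    return est.result()
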