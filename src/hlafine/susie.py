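"""Sum-of-single-effects (SuSiE) Bayesian variable selection.

The model is y = X b + e, e ~ N(0, sigma2 I), with b = sum_{l=1}^{L} b_l and
each *single effect* b_l having exactly one nonzero coordinate: a uniform
prior over which variable is selected and a N(0, sigma0_sq_l) prior on its
coefficient.  Fitting is by iterative Bayesian stepwise selection (IBSS):
each effect in turn is refit by exact single-effect regression (SER) on the
residual left by the other effects, which is coordinate-ascent variational
inference, so the evidence lower bound (ELBO) is non-decreasing.

The fit yields, per effect, posterior inclusion weights alpha_l (a
distribution over variables) from which come

* PIPs: pip_j = 1 - prod_l (1 - alpha_lj), and
* level-rho credible sets: the smallest set of variables per effect whose
  alpha mass reaches rho, filtered by *purity* (minimum absolute pairwise
  correlation of member genotype columns) so that sets spanning unlinked
  variants — the signature of a null effect — are discarded.

Binary case/control traits are handled as 0/1 responses to the same linear
model, the standard practice for fine-mapping large cohorts.

:class:`SuSiE` is a scikit-learn style estimator (``fit`` / ``predict`` /
``get_params``); :func:`susie_fit` is a thin functional wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

_NULL_PRIOR = 1e-9  # effects with prior variance below this count as switched off


@dataclass
class CredibleSet:
    """A level-``coverage`` credible set for one single effect."""

    effect_index: int
    variant_indices: list[int]
    variant_ids: list[str]
    alpha: list[float]
    coverage: float  # attained alpha mass, >= the requested level
    purity_min: float  # min |corr| over member column pairs (1 for singletons)
    purity_mean: float
    purity_median: float

    def __len__(self) -> int:
        return len(self.variant_indices)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.variant_ids


def single_effect_regression(
    X_std: np.ndarray,
    r: np.ndarray,
    sigma2: float,
    sigma0_sq: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Exact Bayesian single-effect regression on a residual vector.

    ``X_std`` must hold centered columns.  Returns (alpha, posterior mean mu,
    posterior second moment mu2, log Bayes factor of the whole SER model
    against the null).  Zero-variance columns get alpha = 0 (with a warning)
    and are excluded from the model average.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    if sigma0_sq < 0:
        raise ValueError(f"sigma0_sq must be >= 0, got {sigma0_sq}")
    d = np.einsum("ij,ij->j", X_std, X_std)
    live = d > 0
    if not live.all():
        warnings.warn("zero-variance columns excluded from single-effect regression")
    Xty = X_std.T @ r
    alpha, mu, mu2, lbf_model = _ser_from_sufficient(Xty, d, live, sigma2, sigma0_sq)
    return alpha, mu, mu2, lbf_model


def _ser_lbf(Xty: np.ndarray, d: np.ndarray, live: np.ndarray,
             sigma2: float, V: float) -> np.ndarray:
    """Per-variable log Bayes factors of the SER at prior variance V."""
    p = len(d)
    lbf = np.zeros(p)
    if V <= 0:
        lbf[~live] = -np.inf
        return lbf
    dd = np.where(live, d, 1.0)
    betahat = Xty / dd
    s2 = sigma2 / dd
    lbf = 0.5 * np.log(s2 / (V + s2)) + 0.5 * betahat**2 * V / (s2 * (V + s2))
    lbf[~live] = -np.inf
    return lbf


def _ser_from_sufficient(
    Xty: np.ndarray, d: np.ndarray, live: np.ndarray, sigma2: float, V: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    p = len(d)
    if not live.any():
        raise ValueError("all columns have zero variance")
    lbf = _ser_lbf(Xty, d, live, sigma2, V)
    with np.errstate(invalid="ignore"):
        finite = lbf[live]
        m = finite.max()
        w = np.where(live, np.exp(lbf - m, where=np.isfinite(lbf), out=np.zeros(p)), 0.0)
    alpha = w / w.sum()
    # uniform prior over the p live variables
    lbf_model = float(m + np.log(w.sum()) - np.log(live.sum()))
    dd = np.where(live, d, 1.0)
    s2 = sigma2 / dd
    if V <= 0:
        mu = np.zeros(p)
        mu2 = np.zeros(p)
    else:
        post_var = V * s2 / (V + s2)
        mu = np.where(live, (V / (V + s2)) * (Xty / dd), 0.0)
        mu2 = np.where(live, mu**2 + post_var, 0.0)
    return alpha, mu, mu2, lbf_model


def _optimize_prior_variance(
    Xty: np.ndarray, d: np.ndarray, live: np.ndarray, sigma2: float, V_init: float
) -> float:
    """Maximize the SER log marginal likelihood over the prior variance.

    The objective is lbf_model(V); if no positive V beats V = 0 (all Bayes
    factors <= 1), the effect is switched off by returning 0.
    """
    log_n_live = np.log(live.sum())

    def neg_loglik(log_v: float) -> float:
        lbf = _ser_lbf(Xty, d, live, sigma2, np.exp(log_v))
        return -(logsumexp(lbf[live]) - log_n_live)

    try:
        res = minimize_scalar(neg_loglik, bounds=(-30.0, 15.0), method="bounded")
        v_opt = float(np.exp(res.x))
        best = -res.fun
    except Exception:
        return V_init
    if V_init > 0:
        lbf_init = _ser_lbf(Xty, d, live, sigma2, V_init)
        if logsumexp(lbf_init[live]) - log_n_live > best:
            v_opt, best = V_init, logsumexp(lbf_init[live]) - log_n_live
    if best <= 0.0:  # the null (V = 0) is at least as good
        return 0.0
    return v_opt


class SuSiE(RegressorMixin, BaseEstimator):
    """Sum-of-single-effects regression with credible-set extraction.

    Parameters
    ----------
    L : int
        Maximum number of single effects (upper bound on causal signals).
    scaled_prior_variance : float
        Initial per-effect prior effect variance as a fraction of var(y)
        (on the column-standardized scale).
    prior_variance : float or None
        Absolute prior variance override; when set, ``scaled_prior_variance``
        is ignored.
    estimate_prior_variance : bool
        Re-estimate each effect's prior variance each sweep by maximizing
        the single-effect marginal likelihood (effects whose best prior
        variance is 0 are switched off).
    estimate_residual_variance : bool
        Update sigma2 from the expected residual sum of squares each sweep.
    coverage, min_purity : float
        Credible-set level and the minimum absolute pairwise correlation a
        set must attain to be reported.
    tol : float
        Convergence threshold on the ELBO change between sweeps.

    Attributes (after ``fit``)
    --------------------------
    alpha_ : (L, p) per-effect inclusion weights, rows summing to 1.
    mu_, mu2_ : (L, p) posterior first/second moments given inclusion
        (standardized-X scale).
    V_ : (L,) per-effect prior variances; 0 marks a switched-off effect.
    sigma2_ : residual variance estimate.
    pip_ : (p,) posterior inclusion probabilities.
    credible_sets_ : list of :class:`CredibleSet` (purity-filtered).
    elbo_trace_ : per-sweep ELBO values (non-decreasing up to slack).
    converged_, n_iter_ : convergence flag and sweep count.
    coef_, intercept_ : posterior-mean regression function on the raw scale.
    """

    def __init__(
        self,
        L: int = 10,
        scaled_prior_variance: float = 0.2,
        prior_variance: float | None = None,
        estimate_prior_variance: bool = True,
        estimate_residual_variance: bool = True,
        residual_variance: float | None = None,
        coverage: float = 0.95,
        min_purity: float = 0.5,
        tol: float = 1e-3,
        max_iter: int = 100,
    ) -> None:
        self.L = L
        self.scaled_prior_variance = scaled_prior_variance
        self.prior_variance = prior_variance
        self.estimate_prior_variance = estimate_prior_variance
        self.estimate_residual_variance = estimate_residual_variance
        self.residual_variance = residual_variance
        self.coverage = coverage
        self.min_purity = min_purity
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, variant_ids: list[str] | None = None,
            positions: np.ndarray | None = None) -> "SuSiE":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"X shape {X.shape} incompatible with y length {len(y)}")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite (mean-impute dosages upstream)")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage {self.coverage} outside (0, 1]")
        n, p = X.shape
        L = min(self.L, p)

        self._x_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        self._live = scale > 0
        self._x_scale = np.where(self._live, scale, 1.0)
        Xs = (X - self._x_mean) / self._x_scale
        Xs[:, ~self._live] = 0.0
        self._y_mean = float(y.mean())
        yc = y - self._y_mean
        d = np.einsum("ij,ij->j", Xs, Xs)

        var_y = float(yc @ yc / n) or 1.0
        sigma2 = (
            float(self.residual_variance)
            if self.residual_variance is not None
            else var_y
        )
        V = np.full(
            L,
            float(self.prior_variance)
            if self.prior_variance is not None
            else self.scaled_prior_variance * var_y,
        )

        alpha = np.full((L, p), 1.0 / max(self._live.sum(), 1))
        alpha[:, ~self._live] = 0.0
        alpha /= alpha.sum(axis=1, keepdims=True)
        mu = np.zeros((L, p))
        mu2 = np.zeros((L, p))
        b_bar = (alpha * mu).sum(axis=0)
        Xr = Xs @ b_bar

        elbo_trace: list[float] = []
        converged = False
        lbf_model = np.zeros(L)
        n_iter = 0
        for it in range(self.max_iter):
            n_iter = it + 1
            kl_sum = 0.0
            for l in range(L):
                b_l = alpha[l] * mu[l]
                Xr = Xr - Xs @ b_l
                r = yc - Xr
                Xty = Xs.T @ r
                if self.estimate_prior_variance:
                    V[l] = _optimize_prior_variance(Xty, d, self._live, sigma2, V[l])
                alpha[l], mu[l], mu2[l], lbf_model[l] = _ser_from_sufficient(
                    Xty, d, self._live, sigma2, V[l]
                )
                b_l = alpha[l] * mu[l]
                # KL of the exact SER posterior against its prior
                e_fit = 2.0 * float(r @ (Xs @ b_l)) - float(d @ (alpha[l] * mu2[l]))
                kl_sum += -lbf_model[l] + e_fit / (2.0 * sigma2)
                Xr = Xr + Xs @ b_l
            b_bar = (alpha * mu).sum(axis=0)
            resid = yc - Xr
            erss = float(resid @ resid)
            for l in range(L):
                b_l = alpha[l] * mu[l]
                erss += float(d @ (alpha[l] * mu2[l])) - float((Xs @ b_l) @ (Xs @ b_l))
            elbo = (
                -0.5 * n * np.log(2.0 * np.pi * sigma2)
                - erss / (2.0 * sigma2)
                - kl_sum
            )
            elbo_trace.append(float(elbo))
            if it > 0 and abs(elbo_trace[-1] - elbo_trace[-2]) < self.tol:
                converged = True
                break
            if self.estimate_residual_variance:
                sigma2 = max(erss / n, 1e-12)

        self.n_features_in_ = p
        self.alpha_ = alpha
        self.mu_ = mu
        self.mu2_ = mu2
        self.V_ = V
        self.sigma2_ = float(sigma2)
        self.lbf_model_ = lbf_model
        self.elbo_trace_ = elbo_trace
        self.converged_ = converged
        self.n_iter_ = n_iter
        self._Xs = Xs
        self._d = d
        self.variant_ids_ = (
            list(variant_ids) if variant_ids is not None else [f"v{j}" for j in range(p)]
        )
        self.positions_ = (
            np.asarray(positions) if positions is not None else np.arange(p)
        )
        self.coef_ = b_bar / self._x_scale
        self.intercept_ = self._y_mean - float(self._x_mean @ self.coef_)
        self.credible_sets_ = extract_credible_sets(
            self, coverage=self.coverage, min_purity=self.min_purity
        )
        self.pip_ = compute_pips(self)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def susie_fit(X: np.ndarray, y: np.ndarray, L: int = 10, coverage: float = 0.95,
              purity: float = 0.5, tol: float = 1e-3, max_iter: int = 100,
              estimate_prior_variance: bool = True, **kwargs) -> SuSiE:
    """Functional wrapper: fit a :class:`SuSiE` model and return it."""
    return SuSiE(
        L=L,
        coverage=coverage,
        min_purity=purity,
        tol=tol,
        max_iter=max_iter,
        estimate_prior_variance=estimate_prior_variance,
        **kwargs,
    ).fit(X, y)


def compute_pips(fit: SuSiE, effects: str = "nonnull") -> np.ndarray:
    """Posterior inclusion probabilities pip_j = 1 - prod_l (1 - alpha_lj).

    ``effects`` selects which single effects enter the product: "nonnull"
    (prior variance > 0; the default), "all", or "cs" (only effects whose
    credible set survived purity filtering).
    """
    if effects == "all":
        idx = np.arange(fit.alpha_.shape[0])
    elif effects == "nonnull":
        idx = np.flatnonzero(fit.V_ > _NULL_PRIOR)
    elif effects == "cs":
        idx = np.array([cs.effect_index for cs in fit.credible_sets_], dtype=int)
    else:
        raise ValueError(f"unknown effects selector {effects!r}")
    if idx.size == 0:
        return np.zeros(fit.alpha_.shape[1])
    return 1.0 - np.prod(1.0 - fit.alpha_[idx], axis=0)


def extract_credible_sets(
    fit: SuSiE, coverage: float = 0.95, min_purity: float = 0.5
) -> list[CredibleSet]:
    """Minimal level-``coverage`` credible sets per effect, purity-filtered.

    Per effect: sort alpha descending (ties broken by genomic position then
    id, so extraction is deterministic), take the smallest prefix whose mass
    reaches ``coverage``; compute purity as the min/mean/median absolute
    pairwise correlation of member genotype columns (singletons score 1);
    drop sets below ``min_purity`` and duplicate sets.  Effects switched off
    by prior-variance estimation report no set.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage {coverage} outside (0, 1]")
    L, p = fit.alpha_.shape
    n = fit._Xs.shape[0]
    ids = fit.variant_ids_
    pos = fit.positions_
    sets: list[CredibleSet] = []
    seen: set[tuple[int, ...]] = set()
    for l in range(L):
        if fit.V_[l] <= _NULL_PRIOR:
            continue
        order = sorted(range(p), key=lambda j: (-fit.alpha_[l, j], pos[j], ids[j]))
        cum = 0.0
        members: list[int] = []
        for j in order:
            members.append(j)
            cum += fit.alpha_[l, j]
            if cum >= coverage:
                break
        if cum < coverage:
            continue  # mass spread over dead columns; cannot attain coverage
        key = tuple(sorted(members))
        if key in seen:
            continue
        if len(members) == 1:
            pur_min = pur_mean = pur_med = 1.0
        else:
            cols = fit._Xs[:, members]
            norms = np.sqrt(np.einsum("ij,ij->j", cols, cols))
            norms[norms == 0] = 1.0
            corr = np.abs((cols.T @ cols) / np.outer(norms, norms))
            tri = corr[np.triu_indices(len(members), k=1)]
            pur_min = float(tri.min())
            pur_mean = float(tri.mean())
            pur_med = float(np.median(tri))
        if pur_min < min_purity:
            continue
        seen.add(key)
        sets.append(
            CredibleSet(
                effect_index=l,
                variant_indices=members,
                variant_ids=[ids[j] for j in members],
                alpha=[float(fit.alpha_[l, j]) for j in members],
                coverage=float(cum),
                purity_min=pur_min,
                purity_mean=pur_mean,
                purity_median=pur_med,
            )
        )
    return sets


def residualize_covariates(
    values: np.ndarray, covariates: np.ndarray | None, names: list[str] | None = None
) -> np.ndarray:
    """Project covariates (plus an intercept) out of a vector or matrix.

    The output is orthogonal to the covariate span.  Rank-deficient covariate
    matrices raise, naming the offending columns.
    """
    values = np.asarray(values, dtype=float)
    one_dim = values.ndim == 1
    Y = values[:, None] if one_dim else values
    n = Y.shape[0]
    C = (
        np.ones((n, 1))
        if covariates is None or np.size(covariates) == 0
        else np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))
                              .reshape(n, -1)])
    )
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        bad = []
        r = 1
        for j in range(1, C.shape[1]):
            if np.linalg.matrix_rank(C[:, : j + 1]) == r:
                bad.append(names[j - 1] if names else f"covariate_{j - 1}")
            else:
                r += 1
        raise ValueError(f"collinear covariate columns: {bad}")
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    resid = Y - C @ coef
    return resid.ravel() if one_dim else resid


def mean_impute(X: np.ndarray) -> np.ndarray:
    """Replace missing dosages by their column means (all-missing columns by 0)."""
    X = np.asarray(X, dtype=float).copy()
    means = np.nanmean(
        np.where(np.isnan(X).all(axis=0), 0.0, X), axis=0
    )
    means = np.nan_to_num(means)
    idx = np.where(np.isnan(X))
    X[idx] = means[idx[1]]
    return X
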