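"""Per-variant logistic association, heterogeneity and replication meta-analysis.

Case/control association is a covariate-adjusted logistic regression per
variant (Wald z test on the dosage term), with additive or dominant dosage
coding and optional conditioning on other variants' dosages (the classical
stepwise/conditional analysis).  Effect-sharing between two case groups
(e.g. childhood- vs adult-onset disease) is tested with Cochran's Q, and
replication uses an inverse-variance fixed-effect meta-analysis with a
one-sided p-value constrained to the discovery direction of effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .io_formats import GenotypeMatrix


class DegeneratePredictorError(ValueError):
    """The tested predictor is constant after listwise deletion."""


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    p_two_sided: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    n_cases: int
    n_controls: int
    model: str = "additive"
    conditioning_ids: list[str] = field(default_factory=list)
    converged: bool = True


@dataclass
class HetResult:
    variant_id: str
    q: float
    df: int
    p_het: float


@dataclass
class MetaResult:
    variant_id: str
    beta_meta: float
    se_meta: float
    p_one_sided: float
    directions: str  # per-cohort signs, METAL-style "+-+"
    scheme: str = "inverse_variance"


def _dominant(dosage: np.ndarray) -> np.ndarray:
    """Dominant coding: any copy of the alt allele counts once (0/1/2 -> 0/1/1)."""
    return np.minimum(dosage, 1.0)


def fit_logistic(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    model: str = "additive",
    variant_id: str = "",
    conditioning_ids: Sequence[str] = (),
) -> AssocResult:
    """Maximum-likelihood logistic fit of y on dosage + covariates.

    Samples with any missing value are dropped listwise.  Perfect separation
    is flagged (``converged=False`` with an infinite-beta sentinel), never
    silently reported as an estimate.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if model == "dominant":
        dosage = _dominant(dosage)
    elif model != "additive":
        raise ValueError(f"unknown model {model!r}")
    cov = (
        np.empty((len(y), 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != len(y):
        cov = cov.T
    ok = ~(np.isnan(y) | np.isnan(dosage) | np.isnan(cov).any(axis=1))
    y, dosage, cov = y[ok], dosage[ok], cov[ok]
    vals = np.unique(y)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if np.ptp(dosage) == 0.0:
        raise DegeneratePredictorError(
            f"variant {variant_id or '<dosage>'} is constant after listwise deletion"
        )
    X = sm.add_constant(np.column_stack([dosage, cov]), has_constant="add")
    if len(y) < X.shape[1] + 1:
        raise ValueError("fewer samples than parameters + 1")
    n_cases = int(np.sum(y == 1))
    n_controls = int(np.sum(y == 0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        converged = bool(fit.mle_retvals.get("converged", True)) and np.isfinite(se)
        if abs(beta) > 30 or se > 100:  # numerically separated
            converged = False
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        direction = np.sign(np.corrcoef(dosage, y)[0, 1]) or 1.0
        return AssocResult(
            variant_id=variant_id,
            beta=float(direction * np.inf),
            se=float("inf"),
            p_two_sided=1.0,
            odds_ratio=float("inf") if direction > 0 else 0.0,
            ci95_low=0.0,
            ci95_high=float("inf"),
            n_cases=n_cases,
            n_controls=n_controls,
            model=model,
            conditioning_ids=list(conditioning_ids),
            converged=False,
        )
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return AssocResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        p_two_sided=p,
        odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci95_high=float(np.exp(beta + 1.959963984540054 * se)),
        n_cases=n_cases,
        n_controls=n_controls,
        model=model,
        conditioning_ids=list(conditioning_ids),
        converged=converged,
    )


def association_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    model: str = "additive",
    conditioning_ids: Sequence[str] = (),
) -> list[AssocResult]:
    """Per-variant logistic scan; conditioning dosages join the covariates.

    Results are ordered by genomic position, then variant id.  Conditioning
    variants themselves are not re-tested.
    """
    known = set(G.variant_ids)
    for cid in conditioning_ids:
        if cid not in known:
            raise KeyError(f"unknown conditioning variant {cid!r}")
    cond_cols = (
        np.column_stack([np.nan_to_num(G.column(c)) for c in conditioning_ids])
        if conditioning_ids
        else np.empty((G.n_samples, 0))
    )
    base_cov = (
        np.empty((G.n_samples, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if base_cov.shape[0] != G.n_samples:
        base_cov = base_cov.T
    cov = np.hstack([base_cov, cond_cols])
    order = sorted(
        (j for j, v in enumerate(G.variants) if v.id not in set(conditioning_ids)),
        key=lambda j: (G.variants[j].pos, G.variants[j].id),
    )
    results = []
    for j in order:
        results.append(
            fit_logistic(
                y,
                G.dosages[:, j],
                cov,
                model=model,
                variant_id=G.variants[j].id,
                conditioning_ids=conditioning_ids,
            )
        )
    return results


def interaction_test(
    y: np.ndarray,
    dosage: np.ndarray,
    modifier: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Wald test of a dosage x modifier product term in the logistic model.

    Returns (beta_interaction, se, p).  Main effects of both the dosage and
    the modifier are always included.
    """
    modifier = np.asarray(modifier, dtype=float)
    m = modifier[~np.isnan(modifier)]
    if np.ptp(m) == 0.0:
        raise DegeneratePredictorError("modifier is constant")
    cov = (
        np.empty((len(y), 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, dtype=float))
    )
    if cov.shape[0] != len(y):
        cov = cov.T
    full_cov = np.column_stack([modifier, cov]) if cov.size else modifier[:, None]
    product = np.asarray(dosage, dtype=float) * modifier
    design_cov = np.column_stack([full_cov, np.asarray(dosage, dtype=float)])
    res = fit_logistic(y, product, design_cov, variant_id="<interaction>")
    return res.beta, res.se, res.p_two_sided


def heterogeneity_test(results: Sequence[AssocResult]) -> HetResult:
    """Cochran's Q heterogeneity test across per-study effect estimates.

    Q = sum_i w_i (beta_i - beta_w)^2 with w_i = 1/se_i^2 and beta_w the
    inverse-variance weighted mean; p from chi-square with k-1 df.
    """
    if len(results) < 2:
        raise ValueError("heterogeneity test needs >= 2 studies")
    betas = np.array([r.beta for r in results])
    ses = np.array([r.se for r in results])
    if not (np.isfinite(betas).all() and np.isfinite(ses).all()):
        raise ValueError("non-finite effect estimates")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta_w = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - beta_w) ** 2))
    df = len(results) - 1
    p = float(stats.chi2.sf(q, df))
    return HetResult(
        variant_id=results[0].variant_id,
        q=q,
        df=df,
        p_het=min(max(p, np.nextafter(0, 1)), 1.0),
    )


def meta_analyze(
    per_cohort: Sequence[AssocResult],
    expected_direction: int,
) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis with a direction constraint.

    The one-sided p requires the meta effect to share ``expected_direction``
    (+1 or -1, the discovery-sample sign): p_one = p_two/2 when the signs
    agree, 1 - p_two/2 otherwise.
    """
    if not per_cohort:
        raise ValueError("need >= 1 cohort")
    if expected_direction not in (-1, 1):
        raise ValueError("expected_direction must be +1 or -1")
    betas = np.array([r.beta for r in per_cohort])
    ses = np.array([r.se for r in per_cohort])
    if np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("cohort standard errors must be finite and positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(np.sqrt(1.0 / np.sum(w)))
    z = beta_meta / se_meta
    p_two = float(2.0 * stats.norm.sf(abs(z)))
    if np.sign(beta_meta) == expected_direction or beta_meta == 0.0:
        p_one = p_two / 2.0
    else:
        p_one = 1.0 - p_two / 2.0
    directions = "".join("+" if b > 0 else ("-" if b < 0 else "0") for b in betas)
    return MetaResult(
        variant_id=per_cohort[0].variant_id,
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_one_sided=min(max(p_one, np.nextafter(0, 1)), 1.0),
        directions=directions,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
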