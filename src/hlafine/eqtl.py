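"""cis-eQTL mapping: nominal OLS scans, kinship mixed-model scans, FDR,
and expression fine-mapping.

The nominal pass tests, for every gene, each variant within a +/-1 Mb
window of the transcription start site (inclusive boundary, strand-ignored)
by ordinary least squares of expression on dosage plus covariates.  For
related samples, a single-random-effect linear mixed model
``y = W g + x b + u + e`` with ``u ~ N(0, sg^2 K)`` is used instead: the
kinship matrix is eigendecomposed once, the variance ratio profiled per
gene under the covariate-only model (shared across that gene's variants,
the usual population-parameters-approximation), and each variant tested by
generalized least squares.  With K = I the LMM scan reduces exactly to the
OLS scan.

Genes with at least one test below the Benjamini-Hochberg FDR threshold
feed the fine-mapping step, which residualizes covariates out of
expression and runs the sum-of-single-effects engine over the cis window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, GenotypeMatrix
from .susie import CredibleSet, SuSiE, mean_impute, residualize_covariates


@dataclass
class EQTLResult:
    gene_id: str
    variant_id: str
    beta: float
    se: float
    p: float
    tss_distance: int  # variant_pos - tss, strand-independent
    cell_type: str = ""


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if K.shape != (n, n):
            raise ValueError(f"kinship shape {K.shape} != ({n}, {n})")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-6:
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {w.min():.3g})")
        self.values = K


def _window_variants(G: GenotypeMatrix, gene: GeneModel, window: float) -> list[int]:
    return [
        j
        for j, v in enumerate(G.variants)
        if v.chrom == gene.chrom and abs(v.pos - gene.tss) <= window
    ]


def _design(cov: np.ndarray | None, n: int) -> np.ndarray:
    if cov is None or np.size(cov) == 0:
        return np.ones((n, 1))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    return np.column_stack([np.ones(n), cov])


def _ols_variant_tests(
    y: np.ndarray, X_cov: np.ndarray, dosages: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS Wald tests of y on [X_cov, x_j], vectorized.

    Covariates are projected out of y and each dosage column (Frisch-Waugh);
    the slope, its standard error (dof = n - q - 1) and the two-sided t-test
    p-value are returned per column.
    """
    n, q = X_cov.shape
    Q, _ = np.linalg.qr(X_cov)
    y_r = y - Q @ (Q.T @ y)
    X_r = dosages - Q @ (Q.T @ dosages)
    xtx = np.einsum("ij,ij->j", X_r, X_r)
    # a column in the covariate span leaves only rounding noise behind
    tot = np.einsum("ij,ij->j", dosages, dosages)
    dead = xtx <= 1e-12 * np.maximum(tot, 1e-300)
    xtx_safe = np.where(dead, 1.0, xtx)
    beta = (X_r.T @ y_r) / xtx_safe
    dof = n - q - 1
    rss = y_r @ y_r - beta**2 * xtx_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / xtx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[dead] = np.nan
    se[dead] = np.nan
    p[dead] = np.nan
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


def cis_scan(
    G: GenotypeMatrix,
    expression: Mapping[str, np.ndarray],
    gene_models: Sequence[GeneModel],
    window: float = 1e6,
    covariates: np.ndarray | None = None,
    cell_type: str = "",
) -> list[EQTLResult]:
    """Nominal-pass OLS cis scan over all genes.

    Genes with no variant in the window contribute no rows; constant dosage
    columns yield NaN statistics rather than an error.
    """
    results: list[EQTLResult] = []
    X_cov = _design(covariates, G.n_samples)
    dosages = mean_impute(G.dosages)
    for gene in gene_models:
        if gene.gene_id not in expression:
            raise KeyError(f"gene {gene.gene_id!r} absent from expression matrix")
        idx = _window_variants(G, gene, window)
        if not idx:
            continue
        y = np.asarray(expression[gene.gene_id], dtype=float)
        beta, se, p = _ols_variant_tests(y, X_cov, dosages[:, idx])
        for k, j in enumerate(idx):
            results.append(
                EQTLResult(
                    gene_id=gene.gene_id,
                    variant_id=G.variants[j].id,
                    beta=float(beta[k]),
                    se=float(se[k]),
                    p=float(p[k]),
                    tss_distance=int(G.variants[j].pos - gene.tss),
                    cell_type=cell_type,
                )
            )
    return results


def _reml_loglik(delta_log: float, S: np.ndarray, Uty: np.ndarray, UtW: np.ndarray) -> float:
    """Restricted log-likelihood of the null model at log variance ratio.

    Parameterization: Var(y) = se^2 (lambda K + I), lambda = sg^2/se^2,
    rotated by the kinship eigenvectors U so the covariance is diagonal
    D = lambda S + 1.
    """
    lam = np.exp(delta_log)
    D = lam * S + 1.0
    n, q = UtW.shape
    Wd = UtW / D[:, None]
    A = UtW.T @ Wd
    try:
        Ainv_Wty = np.linalg.solve(A, Wd.T @ Uty)
    except np.linalg.LinAlgError:
        return -np.inf
    resid_quad = float(Uty @ (Uty / D)) - float((Wd.T @ Uty) @ Ainv_Wty)
    if resid_quad <= 0:
        return -np.inf
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - q) * np.log(resid_quad / (n - q))
        + np.sum(np.log(D))
        + logdet_A
    )


def _profile_variance_ratio(S: np.ndarray, Uty: np.ndarray, UtW: np.ndarray) -> float:
    """Grid search + golden-section refinement of the REML variance ratio."""
    grid = np.linspace(np.log(1e-5), np.log(1e5), 41)
    ll = np.array([_reml_loglik(g, S, Uty, UtW) for g in grid])
    k = int(np.nanargmax(ll))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = _reml_loglik(c, S, Uty, UtW), _reml_loglik(d, S, Uty, UtW)
    for _ in range(60):
        if b - a < 1e-6:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = _reml_loglik(c, S, Uty, UtW)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = _reml_loglik(d, S, Uty, UtW)
    return float(np.exp(0.5 * (a + b)))


def lmm_scan(
    G: GenotypeMatrix,
    expression: Mapping[str, np.ndarray],
    gene_models: Sequence[GeneModel],
    window: float = 1e6,
    covariates: np.ndarray | None = None,
    kinship: KinshipMatrix | np.ndarray | None = None,
    cell_type: str = "",
) -> list[EQTLResult]:
    """Kinship mixed-model cis scan.

    Per gene the variance ratio is profiled once under the covariate-only
    model and reused for every variant in the window; each variant is then
    a GLS Wald t-test in the rotated (whitened) coordinates.  ``kinship``
    may be a :class:`KinshipMatrix` or a raw symmetric PSD array.
    """
    if kinship is None:
        return cis_scan(G, expression, gene_models, window, covariates, cell_type)
    if not isinstance(kinship, KinshipMatrix):
        kinship = KinshipMatrix(list(G.sample_ids), np.asarray(kinship, dtype=float))
    if kinship.sample_ids != list(G.sample_ids):
        raise ValueError("kinship sample ids do not match the genotype matrix")
    S, U = np.linalg.eigh(kinship.values)
    S = np.clip(S, 0.0, None)
    W = _design(covariates, G.n_samples)
    UtW = U.T @ W
    dosages = mean_impute(G.dosages)
    UtX_all = U.T @ dosages
    results: list[EQTLResult] = []
    for gene in gene_models:
        if gene.gene_id not in expression:
            raise KeyError(f"gene {gene.gene_id!r} absent from expression matrix")
        idx = _window_variants(G, gene, window)
        if not idx:
            continue
        y = np.asarray(expression[gene.gene_id], dtype=float)
        Uty = U.T @ y
        lam = _profile_variance_ratio(S, Uty, UtW)
        D = np.sqrt(lam * S + 1.0)
        y_w = Uty / D
        W_w = UtW / D[:, None]
        X_w = UtX_all[:, idx] / D[:, None]
        beta, se, p = _ols_variant_tests(y_w, W_w, X_w)
        for k, j in enumerate(idx):
            results.append(
                EQTLResult(
                    gene_id=gene.gene_id,
                    variant_id=G.variants[j].id,
                    beta=float(beta[k]),
                    se=float(se[k]),
                    p=float(p[k]),
                    tss_distance=int(G.variants[j].pos - gene.tss),
                    cell_type=cell_type,
                )
            )
    return results


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def significant_genes(results: Sequence[EQTLResult], fdr: float = 0.05) -> list[str]:
    """Genes with >= 1 eQTL at BH q < ``fdr``, across all gene x variant tests."""
    usable = [r for r in results if np.isfinite(r.p)]
    if not usable:
        return []
    q = bh_fdr([r.p for r in usable])
    hits = sorted({r.gene_id for r, qv in zip(usable, q) if qv < fdr})
    return hits


def finemap_eqtls(
    G: GenotypeMatrix,
    expression: Mapping[str, np.ndarray],
    gene_models: Sequence[GeneModel],
    genes: Sequence[str],
    covariates: np.ndarray | None = None,
    window: float = 1e6,
    L: int = 10,
    coverage: float = 0.95,
    min_purity: float = 0.5,
) -> dict[str, list[CredibleSet]]:
    """Fine-map each selected gene's cis window with the SuSiE engine.

    Covariates are regressed out of expression first; dosages are
    mean-imputed.  Returns gene -> credible sets (possibly empty).
    """
    models = {g.gene_id: g for g in gene_models}
    out: dict[str, list[CredibleSet]] = {}
    for gene_id in genes:
        if gene_id not in models:
            raise KeyError(f"gene {gene_id!r} has no gene model")
        if gene_id not in expression:
            raise KeyError(f"gene {gene_id!r} absent from expression matrix")
        gene = models[gene_id]
        idx = _window_variants(G, gene, window)
        if not idx:
            out[gene_id] = []
            continue
        y = residualize_covariates(
            np.asarray(expression[gene_id], dtype=float), covariates
        )
        X = mean_impute(G.dosages[:, idx])
        fit = SuSiE(L=L, coverage=coverage, min_purity=min_purity).fit(
            X,
            y,
            variant_ids=[G.variants[j].id for j in idx],
            positions=np.array([G.variants[j].pos for j in idx]),
        )
        out[gene_id] = fit.credible_sets_
    return out
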