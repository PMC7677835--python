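"""SNP x gene association scan, plain (OLS) or intersample-correlation
corrected ("emended").

The emended test is an EMMAX-style mixed model. The sample correlation
matrix ``K`` is estimated from the expression matrix itself (genes
standardized, ``K = E E' / G``, rescaled to unit diagonal and clipped to
positive semidefinite). For each gene ``y`` the error covariance is
modeled as ``V = sigma2 * (K + delta * I)``: ``K`` carries the shared
(confounded) structure, ``delta`` the ratio of independent residual
variance to structured variance. ``delta`` is estimated once per gene by
restricted maximum likelihood on the intercept-projected spectrum of
``K`` and then held fixed while every SNP is tested by generalized least
squares; the per-SNP statistic is the t-ratio of the slope with n - 2
degrees of freedom. When the likelihood carries no information about the
K-vs-I split (e.g. ``K = I``) the gene is flagged "unstructured" and
tested by ordinary least squares.

The scan is chunked over contiguous SNP ranges and reassembled by chunk
index, so its output is bit-identical for any worker count.
"""

from __future__ import annotations

import logging
from contextlib import nullcontext
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy import optimize, stats

from .datatypes import ExpressionData, GenotypeData, PvalueMatrix, align_samples
from .exceptions import InputError

try:  # pin BLAS threads inside chunk workers so results never depend on them
    from threadpoolctl import threadpool_limits
except ImportError:  # pragma: no cover
    threadpool_limits = None

logger = logging.getLogger(__name__)

_DELTA_GRID = np.logspace(-5, 5, 81)
_FLAT_TOL = 1e-8


@dataclass
class SampleCorrelation:
    """Sample x sample correlation structure estimated from expression."""

    samples: list[str]
    K: np.ndarray  # (n, n) symmetric PSD, unit diagonal

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.samples)
        if self.K.shape != (n, n):
            raise InputError(f"K shape {self.K.shape} does not match {n} samples")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise InputError("K must be symmetric")


@dataclass
class VarianceComponents:
    """Per-gene nuisance parameters of the emended model."""

    gene_id: str
    delta: float  # residual-to-structured variance ratio
    sigma2: float  # total scale
    unstructured: bool = False  # True -> no K-vs-I information, use OLS


@dataclass
class ScanConfig:
    """Scan method and parallelism settings."""

    method: str = "emended"  # {"ols", "emended"}
    n_workers: int = 1
    chunk_size: int = 256  # SNPs per task
    covariates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in ("ols", "emended"):
            raise InputError(f"unknown scan method {self.method!r}")
        if self.n_workers < 1 or self.chunk_size < 1:
            raise InputError("n_workers and chunk_size must be >= 1")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def residualize_covariates(
    expr: ExpressionData, covariates: np.ndarray | None
) -> ExpressionData:
    """Replace each gene by its least-squares residual against
    ``[intercept | covariates]``.

    With ``covariates=None`` this reduces to per-gene mean centering.
    Residual columns have mean zero; genes rendered constant are dropped
    downstream by :meth:`ExpressionData.drop_constant_genes`.
    """
    n = expr.n_samples
    if covariates is None:
        X = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != n:
            raise InputError(
                f"covariate rows ({covariates.shape[0]}) != samples ({n})"
            )
        X = np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise InputError("covariate matrix is rank deficient (with intercept)")
    beta, *_ = np.linalg.lstsq(X, expr.values, rcond=None)
    resid = expr.values - X @ beta
    return ExpressionData(samples=list(expr.samples), genes=list(expr.genes), values=resid)


def compute_intersample_correlation(expr: ExpressionData) -> SampleCorrelation:
    """Estimate the sample correlation structure from expression.

    Genes are standardized to mean 0 / variance 1 across samples,
    ``K_raw = E E' / G`` is rescaled to unit diagonal, negative
    eigenvalues are clipped to zero, and the diagonal is re-normalized.
    """
    if expr.n_samples < 2:
        raise InputError("need >= 2 samples to estimate intersample correlation")
    if np.isnan(expr.values).any():
        raise InputError("expression contains missing values")
    sd = expr.values.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise InputError("need >= 2 non-constant genes to estimate correlation")
    E = (expr.values[:, keep] - expr.values[:, keep].mean(axis=0)) / sd[keep]
    K = E @ E.T / keep.sum()
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    w, U = np.linalg.eigh((K + K.T) / 2)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        K = (U * w) @ U.T
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
    K = (K + K.T) / 2
    np.fill_diagonal(K, 1.0)
    return SampleCorrelation(samples=list(expr.samples), K=K)


# ---------------------------------------------------------------------------
# variance components (REML)
# ---------------------------------------------------------------------------


class KEigen:
    """Eigendecompositions of ``K``, computed once and reused per gene.

    ``U, s``: spectrum of ``K`` itself (used for GLS whitening).
    ``Ur, xi``: non-null spectrum of ``S K S`` with ``S`` the centering
    projection (used for intercept-adjusted REML of ``delta``).
    """

    def __init__(self, K: np.ndarray):
        n = K.shape[0]
        self.n = n
        s, U = np.linalg.eigh(K)
        self.s = np.clip(s, 0.0, None)
        self.U = U
        S = np.eye(n) - np.ones((n, n)) / n
        xi, Ur = np.linalg.eigh(S @ K @ S)
        order = np.argsort(xi)[::-1]
        xi, Ur = xi[order], Ur[:, order]
        self.xi = np.clip(xi[: n - 1], 0.0, None)  # drop the forced null direction
        self.Ur = Ur[:, : n - 1]


def _reml_loglik(delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    q = len(xi)
    denom = xi + delta
    ss = float(np.sum(eta2 / denom))
    return 0.5 * (
        q * np.log(q / (2 * np.pi)) - q - q * np.log(ss) - float(np.sum(np.log(denom)))
    )


def fit_variance_components(
    y: np.ndarray, K: SampleCorrelation, eig: KEigen | None = None, gene_id: str = ""
) -> VarianceComponents:
    """REML estimate of ``delta`` for one gene under ``V = sigma2 (K + delta I)``.

    The restricted likelihood is profiled over ``sigma2`` and maximized in
    ``delta`` over a log-spaced grid on [1e-5, 1e5] refined by bounded
    scalar search; the procedure is deterministic for fixed inputs. A flat
    likelihood (no information on the K-vs-I split, e.g. ``K = I``) yields
    the "unstructured" flag and downstream OLS fallback.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise InputError("expression vector contains missing values")
    if y.std() == 0:
        raise InputError("expression vector is constant")
    if eig is None:
        eig = KEigen(K.K)
    eta2 = (eig.Ur.T @ y) ** 2
    lls = np.array([_reml_loglik(d, eig.xi, eta2) for d in _DELTA_GRID])
    if lls.max() - lls.min() < _FLAT_TOL * max(1.0, abs(lls.max())):
        q = eig.n - 1
        return VarianceComponents(
            gene_id=gene_id, delta=np.inf, sigma2=float(np.sum(eta2) / q), unstructured=True
        )
    i = int(np.argmax(lls))
    lo = _DELTA_GRID[max(i - 1, 0)]
    hi = _DELTA_GRID[min(i + 1, len(_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), eig.xi, eta2),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    q = eig.n - 1
    sigma2 = float(np.sum(eta2 / (eig.xi + delta)) / q)
    return VarianceComponents(gene_id=gene_id, delta=delta, sigma2=sigma2)


# ---------------------------------------------------------------------------
# per-gene GLS / OLS test
# ---------------------------------------------------------------------------


def _pvalues_weighted(
    Xt: np.ndarray, yt: np.ndarray, ot: np.ndarray, w: np.ndarray, n: int
) -> np.ndarray:
    """Two-sided p-values of the slope in ``y ~ a + b x`` under diagonal
    weights ``w`` (in the rotated basis), df = n - 2, vectorized over the
    SNP columns of ``Xt``. Degenerate (constant) regressors get p = 1."""
    wo = w * ot
    wy = w * yt
    S11 = float(ot @ wo)
    S1y = float(ot @ wy)
    Syy = float(yt @ wy)
    # einsum (not BLAS gemv) so per-column sums are identical for any
    # chunk width -- the determinism contract covers chunk_size too
    S1x = np.einsum("n,ns->s", wo, Xt)
    Sxy = np.einsum("n,ns->s", wy, Xt)
    Sxx = np.einsum("ns,ns->s", Xt, w[:, None] * Xt)
    det = S11 * Sxx - S1x**2
    scale = np.maximum(S11 * Sxx, np.finfo(float).tiny)
    degenerate = det <= 1e-12 * scale
    det_safe = np.where(degenerate, 1.0, det)
    b = (S11 * Sxy - S1x * S1y) / det_safe
    a = (Sxx * S1y - S1x * Sxy) / det_safe
    rss = np.maximum(Syy - a * S1y - b * Sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    var_b = sigma2 * S11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_b > 0, b / np.sqrt(np.where(var_b > 0, var_b, 1.0)), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return p


def gls_scan_gene(
    y: np.ndarray,
    genotypes: GenotypeData | np.ndarray,
    K: SampleCorrelation | None,
    vc: VarianceComponents,
    eig: KEigen | None = None,
) -> np.ndarray:
    """P-values of one gene against every SNP.

    Structured genes are tested by GLS under ``V = K + vc.delta * I``
    (rotated into K's eigenbasis, which is exact whitening); unstructured
    genes fall back to OLS. Genotype columns must be complete
    (mean-imputed beforehand); constant SNPs get p = 1.
    """
    X = genotypes.imputed_dosage() if isinstance(genotypes, GenotypeData) else np.asarray(genotypes, float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if y.shape[0] != n:
        raise InputError(f"gene vector length {y.shape[0]} != {n} samples")
    if vc.unstructured or not np.isfinite(vc.delta):
        return _pvalues_weighted(X, y, np.ones(n), np.ones(n), n)
    if eig is None:
        if K is None:
            raise InputError("structured test requires K")
        eig = KEigen(K.K)
    w = 1.0 / (eig.s + vc.delta)
    return _pvalues_weighted(eig.U.T @ X, eig.U.T @ y, eig.U.T @ np.ones(n), w, n)


# ---------------------------------------------------------------------------
# chunked scan
# ---------------------------------------------------------------------------


def _scan_chunk(
    Xc: np.ndarray,
    Xrc: np.ndarray | None,
    Y: np.ndarray,
    Yr: np.ndarray | None,
    orot: np.ndarray | None,
    s: np.ndarray | None,
    deltas: np.ndarray,
    unstructured: np.ndarray,
    n: int,
) -> np.ndarray:
    """P-values for one contiguous SNP chunk against all genes.

    Pure function of its arguments, and all basis rotations happen in the
    parent before chunking, so the result is bit-identical whatever the
    worker count or chunk layout."""
    ctx = threadpool_limits(limits=1) if threadpool_limits is not None else nullcontext()
    with ctx:
        G = Y.shape[1]
        out = np.empty((Xc.shape[1], G))
        ones = np.ones(n)
        for j in range(G):
            if unstructured[j] or Xrc is None:
                out[:, j] = _pvalues_weighted(Xc, Y[:, j], ones, ones, n)
            else:
                w = 1.0 / (s + deltas[j])
                out[:, j] = _pvalues_weighted(Xrc, Yr[:, j], orot, w, n)
        return out


def make_chunks(n_snps: int, chunk_size: int) -> list[tuple[int, int]]:
    """Contiguous [start, stop) SNP ranges of at most ``chunk_size``."""
    return [(i, min(i + chunk_size, n_snps)) for i in range(0, n_snps, chunk_size)]


def run_scan(
    geno: GenotypeData, expr: ExpressionData, cfg: ScanConfig
) -> PvalueMatrix:
    """Compute the full SNP x gene p-value matrix.

    Pipeline: sample alignment -> covariate residualization -> constant-gene
    drop -> missing-dosage mean imputation -> (emended only) K estimation
    and per-gene REML -> chunked per-SNP tests. Chunks are dispatched to
    ``cfg.n_workers`` joblib workers and reassembled in SNP order; output
    is bit-identical for any worker count.
    """
    if expr.n_genes == 0:
        raise InputError("empty gene set")
    if geno.n_snps == 0:
        raise InputError("empty SNP set")
    geno, expr = align_samples(geno, expr)
    expr = residualize_covariates(expr, cfg.covariates)
    expr = expr.drop_constant_genes()
    if expr.n_genes == 0:
        raise InputError("all genes constant after preprocessing")
    n = geno.n_samples
    if n < 4:
        raise InputError(f"need >= 4 samples for the t-test, got {n}")
    X = geno.imputed_dosage()
    Y = expr.values

    if cfg.method == "emended":
        K = compute_intersample_correlation(expr)
        eig = KEigen(K.K)
        vcs = [
            fit_variance_components(Y[:, j], K, eig=eig, gene_id=expr.genes[j].id)
            for j in range(expr.n_genes)
        ]
        deltas = np.array([vc.delta for vc in vcs])
        unstructured = np.array([vc.unstructured for vc in vcs])
        n_un = int(unstructured.sum())
        if n_un:
            logger.info("%d gene(s) flagged unstructured; OLS fallback", n_un)
        s = eig.s
        # rotate once, in the parent, so chunk boundaries cannot perturb
        # floating-point accumulation inside the workers
        ctx = threadpool_limits(limits=1) if threadpool_limits is not None else nullcontext()
        with ctx:
            Xr = eig.U.T @ X
            Yr = eig.U.T @ Y
            orot = eig.U.T @ np.ones(n)
    else:
        deltas = np.full(expr.n_genes, np.inf)
        unstructured = np.ones(expr.n_genes, dtype=bool)
        Xr = Yr = orot = s = None

    chunks = make_chunks(geno.n_snps, cfg.chunk_size)
    logger.info(
        "scanning %d SNPs x %d genes in %d chunk(s) on %d worker(s)",
        geno.n_snps, expr.n_genes, len(chunks), cfg.n_workers,
    )
    try:
        results = Parallel(n_jobs=cfg.n_workers, backend="loky")(
            delayed(_scan_chunk)(
                X[:, a:b],
                None if Xr is None else Xr[:, a:b],
                Y, Yr, orot, s, deltas, unstructured, n,
            )
            for a, b in chunks
        )
    except Exception as exc:
        raise InputError(f"scan worker failed (chunk plan {chunks}): {exc}") from exc
    pvalues = np.vstack(results)  # chunk index order == SNP order
    return PvalueMatrix(snps=list(geno.snps), genes=list(expr.genes), pvalues=pvalues)
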