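"""Linear mixed model machinery: GRM, REML variance components, and per-predictor tests.

The association model for the pre-adjusted trait y is

    y = 1 mu + x beta + u + e,    u ~ MVN(0, G Vg),   e ~ MVN(0, I Ve)

where G is the genomic relationship matrix built from standardized genotype
columns, G = W W' / m with column j of W centered by 2 p_j and scaled by
1 / sqrt(2 p_j (1 - p_j)).  A single eigendecomposition of G diagonalizes
the covariance, so REML reduces to a one-dimensional profile over
lambda = Vg / Ve, and every predictor test is a weighted least-squares fit
on the rotated data.  By default each predictor reuses the null-model
variance ratio (the EMMAX/P3D approximation); exact per-predictor REML is
available as an option.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from hapgwas.genotypes import PhasedGenotypes

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GRM:
    """Standardized-genotype genomic relationship matrix."""

    matrix: np.ndarray  # (n, n), symmetric PSD up to numerical tolerance
    samples: list[str]
    m: int  # number of markers used

    def eigendecompose(self) -> tuple[np.ndarray, np.ndarray]:
        d, U = np.linalg.eigh(self.matrix)
        d = np.clip(d, 0.0, None)  # clip small negative eigenvalues from roundoff
        return d, U


def compute_grm(geno: PhasedGenotypes) -> GRM:
    """G = W W' / m from standardized genotypes; errors on monomorphic markers."""
    X = geno.genotype_matrix()
    if np.isnan(X).any():
        raise ValueError("GRM requires complete genotypes (run QC / imputation first)")
    p = X.mean(axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        raise ValueError(f"{int(mono.sum())} monomorphic markers: cannot standardize")
    W = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / geno.n_variants
    return GRM(matrix=G, samples=list(geno.samples), m=geno.n_variants)


@dataclasses.dataclass
class NullModelFit:
    """REML fit of the covariance-only model on rotated data."""

    vg: float
    ve: float
    lam: float  # Vg / Ve
    loglik: float
    eigvals: np.ndarray  # eigenvalues d of G
    eigvecs: np.ndarray  # U, columns are eigenvectors
    y_rot: np.ndarray    # U' y
    boundary: bool = False  # lambda hit the search boundary (e.g. G = I)


def _reml_neg_loglik(log_lam: float, y_rot: np.ndarray, X_rot: np.ndarray,
                     d: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    n, p = X_rot.shape
    XtWX = X_rot.T @ (w[:, None] * X_rot)
    XtWy = X_rot.T @ (w * y_rot)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = y_rot - X_rot @ beta
    rss = float(r @ (w * r))
    if rss <= 0:
        return np.inf
    ve = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    ll = -0.5 * ((n - p) * np.log(2 * np.pi * ve) - np.log(w).sum()
                 + logdet_xwx + (n - p))
    return -ll


def _fit_reml(y: np.ndarray, X: np.ndarray, d: np.ndarray, U: np.ndarray,
              bounds: tuple[float, float] = (-12.0, 12.0)) -> tuple[float, float, float, bool]:
    """Profile REML over log(lambda); returns (vg, ve, lam, at_boundary)."""
    y_rot = U.T @ y
    X_rot = U.T @ X
    grid = np.linspace(bounds[0], bounds[1], 49)
    vals = np.array([_reml_neg_loglik(g, y_rot, X_rot, d) for g in grid])
    finite = vals[np.isfinite(vals)]
    # flat profile (e.g. G = I): Vg and Ve are not separately identifiable
    flat = finite.size > 1 and np.ptp(finite) < 1e-8 * max(1.0, abs(finite.min()))
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=(lo, hi), method="bounded",
                                   args=(y_rot, X_rot, d))
    log_lam = float(res.x)
    # boundary slack covers one grid step
    boundary = flat or log_lam <= bounds[0] + 0.6 or log_lam >= bounds[1] - 0.6
    lam = float(np.exp(log_lam))
    w = 1.0 / (lam * d + 1.0)
    XtWX = X_rot.T @ (w[:, None] * X_rot)
    beta = np.linalg.solve(XtWX, X_rot.T @ (w * y_rot))
    r = y_rot - X_rot @ beta
    ve = float(r @ (w * r)) / (len(y) - X.shape[1])
    vg = lam * ve
    return vg, ve, lam, boundary


def preadjust_phenotype(y: np.ndarray, cg_labels: np.ndarray, age: np.ndarray,
                        grm: GRM) -> tuple[np.ndarray, pd.DataFrame]:
    """Pre-adjust the trait for contemporary group and a linear age covariate.

    Fixed effects are estimated under the animal model (polygenic covariance
    from the GRM) by REML/GLS; the returned vector is y minus the fitted
    fixed part, so it retains the polygenic and residual components and is
    approximately centered.  Returns (adjusted y, fixed-effect estimates).
    """
    y = np.asarray(y, dtype=float)
    cg_labels = np.asarray(cg_labels)
    age = np.asarray(age, dtype=float)
    if not (len(y) == len(cg_labels) == len(age) == len(grm.samples)):
        raise ValueError("y, cg_labels, age and GRM must agree in length")
    levels, cg_idx = np.unique(cg_labels, return_inverse=True)
    counts = np.bincount(cg_idx)
    small = counts < 3
    if small.any():
        raise ValueError(
            f"contemporary groups with < 3 records: {', '.join(map(str, levels[small]))}"
        )
    n = len(y)
    k = len(levels)
    cols = [np.ones(n)]
    names = ["intercept"]
    for j in range(1, k):  # reference coding: first CG absorbed by intercept
        cols.append((cg_idx == j).astype(float))
        names.append(f"cg[{levels[j]}]")
    if np.ptp(age) > 0:  # constant age carries no information; model is mean-only
        cols.append(age - age.mean())
        names.append("age_slope")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "confounded fixed-effect design: age is collinear with contemporary groups"
        )
    d, U = grm.eigendecompose()
    vg, ve, lam, boundary = _fit_reml(y, X, d, U)
    w = 1.0 / (lam * d + 1.0)
    X_rot = U.T @ X
    y_rot = U.T @ y
    beta = np.linalg.solve(X_rot.T @ (w[:, None] * X_rot), X_rot.T @ (w * y_rot))
    y_adj = y - X @ beta
    est = pd.DataFrame({"term": names, "estimate": beta})
    est.attrs.update(vg=vg, ve=ve, lam=lam, boundary=boundary)
    return y_adj, est


def fit_null(y_adj: np.ndarray, grm: GRM) -> NullModelFit:
    """REML fit of the intercept-only animal model on the adjusted trait."""
    y_adj = np.asarray(y_adj, dtype=float)
    if not np.isfinite(y_adj).all():
        raise ValueError("non-finite values in adjusted phenotype")
    d, U = grm.eigendecompose()
    if d.min() < -1e-6:
        raise ValueError("GRM not positive semi-definite beyond jitter tolerance")
    X = np.ones((len(y_adj), 1))
    vg, ve, lam, boundary = _fit_reml(y_adj, X, d, U)
    if boundary:
        logger.warning("REML lambda at search boundary: variance components weakly identified")
    y_rot = U.T @ y_adj
    X_rot = U.T @ X
    ll = -_reml_neg_loglik(np.log(lam), y_rot, X_rot, d)
    return NullModelFit(vg=vg, ve=ve, lam=lam, loglik=ll, eigvals=d, eigvecs=U,
                        y_rot=y_rot, boundary=boundary)


@dataclasses.dataclass
class AssocResult:
    """Per-predictor association output."""

    predictor: str
    freq: float
    effect: float  # allele substitution effect, kg
    se: float
    pvalue: float
    sigma2: float = np.nan  # additive genetic variance, kg^2 (filled downstream)
    k: int = 2


def test_predictors(dosage: np.ndarray, null: NullModelFit,
                    exact: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS effect, SE and Wald p for each dosage column under Vg G + Ve I.

    Vectorized over columns; the model per column is y = 1 mu + x beta.
    Constant columns yield NaN (callers skip and log them).  With
    ``exact=True`` the variance ratio is re-estimated per predictor by REML
    instead of reusing the null-model lambda.
    """
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    if dosage.shape[0] != len(null.y_rot):
        dosage = dosage.T
    n, P = dosage.shape
    y_rot = null.y_rot
    U = null.eigvecs
    d = null.eigvals

    if exact:
        eff = np.full(P, np.nan)
        se = np.full(P, np.nan)
        pv = np.full(P, np.nan)
        ones = np.ones((n, 1))
        for j in range(P):
            x = dosage[:, j]
            if np.ptp(x) == 0:
                continue
            X = np.column_stack([ones, x])
            vg, ve, lam, _ = _fit_reml(U @ y_rot, X, d, U)
            w = 1.0 / (lam * d + 1.0)
            X_rot = U.T @ X
            XtWX = X_rot.T @ (w[:, None] * X_rot)
            beta = np.linalg.solve(XtWX, X_rot.T @ (w * y_rot))
            cov = ve * np.linalg.inv(XtWX)
            eff[j] = beta[1]
            se[j] = np.sqrt(cov[1, 1])
            pv[j] = stats.chi2.sf((eff[j] / se[j]) ** 2, df=1)
        return eff, se, pv

    w = 1.0 / (null.lam * d + 1.0)
    X_rot = U.T @ dosage  # (n, P)
    one_rot = U.T @ np.ones(n)
    sww = float(w @ np.square(one_rot))        # 1'W1
    swx = (w * one_rot) @ X_rot                # 1'Wx per column
    swxx = np.einsum("i,ij,ij->j", w, X_rot, X_rot)
    swy = float((w * one_rot) @ y_rot)
    swxy = (w * y_rot) @ X_rot
    det = sww * swxx - swx**2
    const = np.ptp(dosage, axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = (sww * swxy - swx * swy) / det
        se = np.sqrt(null.ve * sww / det)
    eff[const] = np.nan
    se[const] = np.nan
    with np.errstate(invalid="ignore"):
        pv = stats.chi2.sf((eff / se) ** 2, df=1)
    return eff, se, pv


def test_predictor(dosage_col: np.ndarray, null: NullModelFit, predictor: str = "x",
                   exact: bool = False) -> AssocResult:
    """Test a single 0/1/2 dosage column; errors on a constant column."""
    x = np.asarray(dosage_col, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError(f"constant dosage for predictor {predictor}: not testable")
    eff, se, pv = test_predictors(x[:, None], null, exact=exact)
    return AssocResult(predictor=predictor, freq=float(x.mean() / 2.0),
                       effect=float(eff[0]), se=float(se[0]), pvalue=float(pv[0]))
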