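"""Additive genetic variance per locus and gamma-distribution significance thresholds.

For a biallelic SNP with allele frequency p and substitution effect a (kg),
the additive genetic variance is

    sigma^2 = 2 p (1 - p) a^2            [kg^2]

For a multi-allelic haplotype locus with k alleles of frequencies p_i and
per-allele effects a_i, the variance is the sum over unordered allele pairs

    sigma^2 = sum_{i < l} (a_i - a_l)^2 p_i p_l

which equals the frequency-weighted variance Var_p(a) of the effect
distribution.  Note that at k = 2 this pairwise form equals HALF the
biallelic SNP formula applied to (p, a_1 - a_2); both conventions appear in
the literature and the ``scale`` flag selects between them (default keeps
the pairwise form as written).

Genome-wide, the per-locus variances of one analysis are modelled as a
Gamma(shape alpha, rate beta) sample.  Parameters come from the standard
moment (Newton-Raphson-derived) approximation

    s = ln(mean(v)) - mean(ln(v)),
    alpha = (3 - s + sqrt((3 - s)^2 + 24 s)) / (12 s),    beta = alpha / mean(v)

For haplotype analyses the per-allele-count (k) class parameters are
smoothed: a cubic polynomial predicts alpha(k) and the Brody asymptotic
growth curve beta(t) = A (1 - B exp(-kappa t)) predicts beta as a function
of the allele count t.  The significance cutoff for a locus with k alleles
is the gamma quantile at probability 1 - family_alpha / n_tests
(Bonferroni correction over all loci tested in that analysis).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


def snp_variance(p: float, a: float) -> float:
    """Additive genetic variance 2 p (1 - p) a^2 of a biallelic SNP (kg^2)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    return 2.0 * p * (1.0 - p) * float(a) ** 2


def haplotype_variance(freqs, effects, scale: str = "as_printed") -> float:
    """Additive variance of a multi-allelic locus from allele effects and frequencies.

    ``scale='as_printed'`` returns the plain pairwise sum
    sum_{i<l} (a_i - a_l)^2 p_i p_l; ``scale='snp_consistent'`` doubles it so
    that the k = 2 case coincides with :func:`snp_variance`.
    """
    p = np.asarray(freqs, dtype=float)
    a = np.asarray(effects, dtype=float)
    if p.shape != a.shape:
        raise ValueError("freqs and effects must have the same length")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies must sum to 1 (got {p.sum():.10f})")
    if scale not in ("as_printed", "snp_consistent"):
        raise ValueError(f"unknown scale {scale!r}")
    # sum_{i<l} (a_i - a_l)^2 p_i p_l == E_p[a^2] - (E_p[a])^2 (pairwise identity)
    mean = float(p @ a)
    v = float(p @ a**2) - mean**2
    v = max(v, 0.0)
    return 2.0 * v if scale == "snp_consistent" else v


@dataclasses.dataclass
class GammaClassFit:
    """Moment-approximation gamma fit for one allele-count class."""

    k: int | None
    n_loci: int
    s: float
    alpha: float
    beta: float
    mean: float


def fit_gamma_mom(variances, k: int | None = None) -> GammaClassFit:
    """Gamma shape/rate by the moment (Newton-Raphson) approximation.

    Requires at least two strictly positive, non-constant variances
    (the log statistic s is undefined at zero and degenerates for
    constant data).
    """
    v = np.asarray(variances, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 variances to fit a gamma distribution")
    if (v <= 0).any():
        raise ValueError("variances must be strictly positive for the log-moment fit")
    mu = float(v.mean())
    s = float(np.log(mu) - np.log(v).mean())
    if s <= 0 or not np.isfinite(s):
        raise ValueError("degenerate (constant) variances: moment statistic s <= 0")
    alpha = (3.0 - s + np.sqrt((3.0 - s) ** 2 + 24.0 * s)) / (12.0 * s)
    beta = alpha / mu
    return GammaClassFit(k=k, n_loci=int(v.size), s=s, alpha=float(alpha),
                         beta=float(beta), mean=mu)


def fit_gamma_classes(sigma2: np.ndarray, k: np.ndarray,
                      min_loci: int = 30) -> dict[int, GammaClassFit]:
    """Per-allele-count gamma fits for one haplotype analysis.

    Zero variances (effect exactly 0) are excluded with a logged count;
    classes with fewer than ``min_loci`` positive variances are dropped.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    k = np.asarray(k)
    pos = sigma2 > 0
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("excluding %d zero variances from gamma fitting", n_zero)
    fits: dict[int, GammaClassFit] = {}
    for kk in np.unique(k[pos]):
        vs = sigma2[pos & (k == kk)]
        if vs.size >= min_loci and np.ptp(vs) > 0:
            fits[int(kk)] = fit_gamma_mom(vs, k=int(kk))
    return fits


def _brody(t, A, B, kappa):
    return A * (1.0 - B * np.exp(-kappa * t))


@dataclasses.dataclass
class SmoothedParams:
    """Cubic alpha(k) and Brody beta(k) smoothing across allele-count classes."""

    cubic: np.ndarray       # c0..c3, alpha(k) = c0 + c1 k + c2 k^2 + c3 k^3
    brody: tuple[float, float, float]  # (A, B, kappa)
    k_range: tuple[int, int]
    alpha_residuals: np.ndarray
    beta_residuals: np.ndarray

    def alpha(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.cubic[0] + self.cubic[1] * k + self.cubic[2] * k**2 + self.cubic[3] * k**3

    def beta(self, k) -> np.ndarray:
        A, B, kappa = self.brody
        return _brody(np.asarray(k, dtype=float), A, B, kappa)


def smooth_params(fits: dict[int, GammaClassFit]) -> SmoothedParams:
    """Smooth class-wise gamma parameters over the allele count.

    Cubic OLS for alpha(k) (needs >= 5 distinct classes); Brody nonlinear
    least squares for beta(k) (needs >= 4), started at A = max observed beta,
    B = 1 - beta(k_min)/A, kappa = 0.1.
    """
    ks = np.array(sorted(fits))
    if len(ks) < 5:
        raise ValueError(f"need >= 5 distinct allele-count classes for the cubic fit, got {len(ks)}")
    alphas = np.array([fits[k].alpha for k in ks])
    betas = np.array([fits[k].beta for k in ks])

    cubic = np.polynomial.polynomial.polyfit(ks.astype(float), alphas, deg=3)
    alpha_hat = np.polynomial.polynomial.polyval(ks.astype(float), cubic)

    A0 = float(betas.max())
    B0 = float(1.0 - betas[0] / A0) if A0 > 0 else 0.5
    last_err: Exception | None = None
    popt = None
    for kappa0 in (0.1, 0.05, 0.5, 1.0):
        try:
            popt, _ = optimize.curve_fit(_brody, ks.astype(float), betas,
                                         p0=(A0, B0, kappa0), maxfev=20000)
            break
        except RuntimeError as err:  # nonconvergence; retry from another start
            last_err = err
    if popt is None:
        raise RuntimeError(f"Brody fit for beta(k) did not converge: {last_err}")
    beta_hat = _brody(ks.astype(float), *popt)

    sm = SmoothedParams(
        cubic=cubic,
        brody=(float(popt[0]), float(popt[1]), float(popt[2])),
        k_range=(int(ks[0]), int(ks[-1])),
        alpha_residuals=alphas - alpha_hat,
        beta_residuals=betas - beta_hat,
    )
    kk = np.arange(ks[0], ks[-1] + 1)
    if (sm.alpha(kk) <= 0).any() or (sm.beta(kk) <= 0).any():
        raise ValueError("smoothed gamma parameters non-positive inside the observed k range")
    return sm


def gamma_threshold(alpha: float, beta: float, n_tests: int,
                    family_alpha: float = 0.05) -> float:
    """Bonferroni-corrected gamma quantile: inverse CDF at 1 - family_alpha / n_tests."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("gamma parameters must be positive")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    q = family_alpha / n_tests
    if q <= 0 or 1.0 - q == 1.0:
        raise ValueError(f"tail probability {q} underflows at n_tests={n_tests}")
    return float(stats.gamma.isf(q, a=alpha, scale=1.0 / beta))


def threshold_table(fits: dict[int, GammaClassFit] | GammaClassFit,
                    n_tests: int, family_alpha: float = 0.05,
                    smoothed: SmoothedParams | None = None,
                    analysis: str = "") -> pd.DataFrame:
    """Variance cutoffs per allele-count class (or a single SNP cutoff).

    Haplotype analyses pass the class fits and optionally smoothed
    parameters (used when given); the SNP analysis passes its single fit.
    Bonferroni uses the genome-wide number of tested loci of that analysis.
    """
    if isinstance(fits, GammaClassFit):
        fits = {2 if fits.k is None else fits.k: fits}
    rows = []
    for k in sorted(fits):
        if smoothed is not None:
            a = float(smoothed.alpha(k))
            b = float(smoothed.beta(k))
        else:
            a, b = fits[k].alpha, fits[k].beta
        rows.append((analysis, k, a, b, gamma_threshold(a, b, n_tests, family_alpha)))
    return pd.DataFrame(rows, columns=["analysis", "k", "alpha", "beta", "cutoff"])


def call_significant(results: pd.DataFrame, thresholds: pd.DataFrame) -> pd.DataFrame:
    """Flag loci whose variance reaches the cutoff for their allele count.

    ``results`` needs columns ``sigma2`` and ``k``; a locus with an allele
    count absent from the threshold table raises.  Returns the input with a
    boolean ``flagged`` column (sigma2 >= cutoff).
    """
    cut = thresholds.set_index("k")["cutoff"]
    missing = sorted(set(results["k"]) - set(cut.index))
    if missing:
        raise ValueError(f"no threshold for allele counts: {missing}")
    out = results.copy()
    out["cutoff"] = results["k"].map(cut).to_numpy()
    out["flagged"] = out["sigma2"] >= out["cutoff"]
    return out
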