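"""Covariate-adjusted gene-based burden and SKAT tests.

Both tests are score tests under a Gaussian linear null model

    y = X beta + e,   e ~ N(0, sigma^2 I),

where y is an inverse-normal-transformed metabolite (or ratio) and X holds an
intercept plus covariates (age, sex, eGFR, UACR, genetic principal
components; optionally common index-SNP dosages for conditional analysis).
With residuals r = y - X beta_hat and residual projector
P = I - X (X'X)^-1 X':

* the burden test collapses a gene's qualifying-variant dosage matrix G into
  a weighted score s_i = sum_j w_j g_ij and tests its slope:
  beta_hat = s'r / s'Ps, SE = sigma_hat / sqrt(s'Ps), two-sided p from the
  standard-normal reference of beta_hat / SE.  With flat weights beta_hat is
  the average effect per copy of a rare qualifying allele, in SD units of the
  transformed phenotype.  Powerful when variant effects share a direction.

* SKAT is the variance-component score Q = || W G' r ||^2 whose null
  distribution is a mixture sum_k lambda_k chi2_1 with lambda_k the
  eigenvalues of sigma_hat^2 (W G' P G W); p-values come from numerical
  inversion of the characteristic function (Imhof/Davies-type).  Powerful
  when effects oppose in direction.  Default SKAT weights are
  w_j = Beta(maf_j; 1, 25), up-weighting the rarest variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "NullModel",
    "WeightScheme",
    "GeneTestResult",
    "fit_null_model",
    "burden_test",
    "skat_test",
    "quadform_pvalue",
    "single_variant_tests",
    "conditional_reanalysis",
    "effect_proportion",
    "beta_maf_weights",
]

_P_FLOOR = 5e-324  # smallest subnormal; p-values are clipped into (0, 1]


@dataclass
class NullModel:
    """Least-squares null fit y = X beta + e on complete cases."""

    y: np.ndarray
    X: np.ndarray
    beta: np.ndarray
    residuals: np.ndarray
    sigma2: float  # RSS / (n - p)
    xtx_inv: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Apply the residual projector P = I - X(X'X)^-1 X' to columns of v."""
        return v - self.X @ (self.xtx_inv @ (self.X.T @ v))


@dataclass
class WeightScheme:
    """Per-variant weights: flat (w=1) or Beta(MAF; a, b) density weights."""

    name: str = "flat"
    a: float = 1.0
    b: float = 25.0

    def weights(self, mafs: np.ndarray) -> np.ndarray:
        if self.name == "flat":
            return np.ones_like(np.asarray(mafs, dtype=float))
        if self.name == "beta":
            w = stats.beta.pdf(np.asarray(mafs, dtype=float), self.a, self.b)
            if not (w > 0).all():
                raise ValueError("beta weights must be positive; check MAFs in (0, 1)")
            return w
        raise ValueError(f"unknown weight scheme {self.name!r}")


FLAT = WeightScheme("flat")
BETA_1_25 = WeightScheme("beta", 1.0, 25.0)


def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    return WeightScheme("beta", a, b).weights(mafs)


@dataclass
class GeneTestResult:
    """One gene x phenotype record of both aggregation tests."""

    gene: str
    phenotype: str
    beta: float
    se: float
    p_burden: float
    q_skat: float
    p_skat: float
    n_variants: int
    total_mac: int
    cumulative_maf: float
    n_samples: int
    skat_fallback: bool = False


def fit_null_model(y: np.ndarray, X: np.ndarray) -> NullModel:
    """Fit the covariate-only null model by least squares.

    Rows with any missing value in y or X are dropped (complete-case
    analysis, recorded in ``n_dropped``).  Raises on singular designs and on
    n <= p.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X must align on samples")
    complete = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    n_dropped = int((~complete).sum())
    y, X = y[complete], X[complete]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is singular (aliased columns)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    r = y - X @ beta
    sigma2 = float(r @ r) / (n - p)
    return NullModel(y, X, beta, r, sigma2, xtx_inv, n_dropped)


def _score_stat(null: NullModel, s: np.ndarray) -> tuple[float, float]:
    """Slope and SE of a single score vector s added to the null design."""
    s_perp = null.residualize(s)
    sps = float(s_perp @ s_perp)
    if sps <= 1e-12 * max(1.0, float(s @ s)):
        raise ValueError("score is constant after projection on covariates")
    beta = float(s_perp @ null.residuals) / sps
    se = float(np.sqrt(null.sigma2 / sps))
    return beta, se


def _two_sided_normal_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(1.0, max(p, _P_FLOOR)))


def burden_test(
    null: NullModel, G: np.ndarray, weights: np.ndarray | WeightScheme | None = None,
    mafs: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Burden score test: returns (beta_hat, SE, two-sided p).

    ``G`` must be mean-imputed, minor-oriented, and row-aligned with the null
    model's complete cases.  ``weights`` may be a WeightScheme (needs
    ``mafs``), an explicit vector, or None for flat weights.
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != null.n:
        raise ValueError("G rows must match null-model samples")
    w = _resolve_weights(weights, mafs, G.shape[1])
    s = G @ w
    beta, se = _score_stat(null, s)
    return beta, se, _two_sided_normal_p(beta / se)


def _resolve_weights(weights, mafs, m) -> np.ndarray:
    if weights is None:
        return np.ones(m)
    if isinstance(weights, WeightScheme):
        if weights.name == "flat":
            return np.ones(m)
        if mafs is None:
            raise ValueError("beta weight scheme requires per-variant MAFs")
        return weights.weights(np.asarray(mafs, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError("weight vector length must match number of variants")
    if not (w > 0).all():
        raise ValueError("weights must be positive")
    return w


def skat_test(
    null: NullModel, G: np.ndarray, weights: np.ndarray | WeightScheme | None = None,
    mafs: np.ndarray | None = None,
) -> tuple[float, float, bool]:
    """SKAT variance-component test: returns (Q, p, used_fallback).

    Q = || W G' r ||^2; the null distribution is sum_k lambda_k chi2_1 with
    lambda_k eigenvalues of sigma_hat^2 (W G' P G W).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != null.n:
        raise ValueError("G rows must match null-model samples")
    m = G.shape[1]
    scheme = weights if weights is not None else BETA_1_25
    if isinstance(scheme, WeightScheme) and scheme.name == "beta" and mafs is None:
        mafs = G.mean(axis=0) / 2.0  # in-sample MAF of the imputed dosages
    w = _resolve_weights(scheme, mafs, m)
    GW = G * w
    q = float(np.sum((GW.T @ null.residuals) ** 2))
    lambdas = skat_lambdas(null, GW)
    return (q,) + quadform_pvalue(q, lambdas)


def skat_lambdas(null: NullModel, GW: np.ndarray) -> np.ndarray:
    """Eigenvalues of sigma_hat^2 * (GW' P GW), clipped at numerical zero."""
    GW_perp = null.residualize(GW)
    A = null.sigma2 * (GW.T @ GW_perp)
    A = (A + A.T) / 2.0
    lam = np.linalg.eigvalsh(A)
    lam = lam[lam > 1e-10 * max(lam.max(), 1.0)]
    if lam.size == 0:
        raise ValueError("kernel has no positive eigenvalue after projection")
    return lam[::-1]


def quadform_pvalue(
    q: float, lambdas: Sequence[float], *, abs_tol: float = 1e-9, limit: int = 10_000
) -> tuple[float, bool]:
    """Upper-tail probability of sum_k lambda_k chi2_1 at q.

    Computed by Imhof's characteristic-function inversion

        P(Q > q) = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u rho(u)) du,
        theta(u) = 1/2 sum_k arctan(lambda_k u) - q u / 2,
        rho(u)   = prod_k (1 + lambda_k^2 u^2)^(1/4),

    with absolute accuracy target ``abs_tol``.  If the integration fails to
    converge, a skewness/kurtosis moment-matched noncentral-free chi-square
    approximation is used instead and flagged via the returned boolean.
    Returns ``(p, used_fallback)`` with p clipped into (0, 1].
    """
    lam = np.asarray(lambdas, dtype=float)
    if not np.isfinite(q) or not np.isfinite(lam).all():
        raise ValueError("non-finite inputs to quadform_pvalue")
    if lam.size == 0 or (lam <= 0).all():
        raise ValueError("need at least one positive eigenvalue")
    lam = lam[lam > 0]
    if q <= 0:
        return 1.0, False

    try:
        p = _imhof_pvalue(q, lam, abs_tol, limit)
        if p >= 1e-11:  # within the absolute resolution of the inversion
            return float(min(1.0, p)), False
    except Exception:
        p = None
    # Far tail (or failed integration): characteristic-function inversion is
    # limited to absolute accuracy; switch to a flagged analytic fallback.
    try:
        return _saddlepoint_pvalue(q, lam), True
    except Exception:
        return _liu_moment_pvalue(q, lam), True


def _imhof_pvalue(q: float, lam: np.ndarray, abs_tol: float, limit: int) -> float:
    """Gil-Pelaez/Imhof inversion of the characteristic function.

    The integrand sin(theta(u)) / (u rho(u)) has a u^(-1 - m/2) envelope and
    oscillates at asymptotic frequency q/2, so the integral is split at U:
    adaptive quadrature on [0, U], then Fourier-weight quadrature (QAWF) on
    [U, inf) after factoring sin(theta) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2)
    with phi(u) = (1/2) sum_k arctan(lambda_k u) slowly varying.
    """

    def theta(u: float) -> float:
        return 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u

    def inv_urho(u: float) -> float:
        return np.exp(-0.25 * np.sum(np.log1p(lam * lam * u * u))) / u

    def phi(u: float) -> float:
        return 0.5 * np.sum(np.arctan(lam * u))

    U = 10.0 / lam.max()  # several arctan scales; tail phase is then ~linear
    head, _ = integrate.quad(
        lambda u: np.sin(theta(u)) * inv_urho(u),
        0.0, U, epsabs=abs_tol / (4 * np.pi), epsrel=0.0, limit=limit,
    )
    tail_cos, _ = integrate.quad(
        lambda u: np.sin(phi(u)) * inv_urho(u),
        U, np.inf, weight="cos", wvar=q / 2.0,
        epsabs=abs_tol / (4 * np.pi), limit=limit,
    )
    tail_sin, _ = integrate.quad(
        lambda u: np.cos(phi(u)) * inv_urho(u),
        U, np.inf, weight="sin", wvar=q / 2.0,
        epsabs=abs_tol / (4 * np.pi), limit=limit,
    )
    val = head + tail_cos - tail_sin
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or p < -1e-7 or p > 1 + 1e-7:
        raise RuntimeError("Imhof inversion out of range")
    return max(p, 0.0)


def _saddlepoint_pvalue(q: float, lam: np.ndarray) -> float:
    """Lugannani-Rice saddlepoint upper tail for sum_k lambda_k chi2_1.

    Cumulant generating function K(z) = -(1/2) sum_k log(1 - 2 z lambda_k),
    saddlepoint K'(z_hat) = q with z_hat < 1/(2 max lambda).  Accurate deep in
    the right tail where numerical inversion loses absolute precision.
    """
    from scipy.optimize import brentq

    lmax = lam.max()
    mean = lam.sum()
    if q <= mean:  # saddlepoint at/left of the mean: not a far right tail
        raise ValueError("saddlepoint fallback only applies right of the mean")

    def kprime(z: float) -> float:
        return float(np.sum(lam / (1.0 - 2.0 * z * lam)))

    hi = 1.0 / (2.0 * lmax)
    zhat = brentq(lambda z: kprime(z) - q, 0.0, hi * (1 - 1e-12), xtol=1e-16, rtol=1e-15)
    K = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    Kpp = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * zhat * lam) ** 2))
    w = np.sign(zhat) * np.sqrt(2.0 * (zhat * q - K))
    v = zhat * np.sqrt(Kpp)
    if w == 0:
        raise ValueError("degenerate saddlepoint")
    p = stats.norm.sf(w + np.log(v / w) / w)
    return float(min(1.0, max(p, _P_FLOOR)))


def _liu_moment_pvalue(q: float, lam: np.ndarray) -> float:
    """Skewness/kurtosis moment-matching fallback (Liu-type chi-square)."""
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = np.sqrt(df)
    t_star = (q - c1) / np.sqrt(2 * c2)
    x = t_star * np.sqrt(2) * np.sqrt(df + 2 * delta) + (df + delta)
    p = float(stats.ncx2.sf(x, df, delta) if delta > 0 else stats.chi2.sf(x, df))
    return float(min(1.0, max(p, _P_FLOOR)))


def single_variant_tests(null: NullModel, G: np.ndarray) -> pd.DataFrame:
    """Per-variant covariate-adjusted slope, SE and two-sided p."""
    G = np.atleast_2d(np.asarray(G, dtype=float))
    rows = []
    for j in range(G.shape[1]):
        beta, se = _score_stat(null, G[:, j])
        rows.append({"beta": beta, "se": se, "p": _two_sided_normal_p(beta / se)})
    return pd.DataFrame(rows)


def conditional_reanalysis(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    index_dosages: np.ndarray,
    weights: np.ndarray | WeightScheme | None = None,
    mafs: np.ndarray | None = None,
) -> dict:
    """Re-run burden and SKAT with common index-SNP dosage(s) in the design.

    ``index_dosages`` is one vector or a samples x k matrix of common-variant
    dosages (mean-imputed).  Returns both unconditional and conditional
    results and the conditional/unconditional burden effect proportion in
    percent.  Raises if an index SNP is collinear with existing covariates.
    """
    idx = np.atleast_2d(np.asarray(index_dosages, dtype=float))
    if idx.shape[0] != np.asarray(X).shape[0]:
        idx = idx.T
    X_cond = np.column_stack([X, idx])
    null_uncond = fit_null_model(y, X)
    null_cond = fit_null_model(y, X_cond)  # raises on collinearity
    complete = ~(np.isnan(np.asarray(y, float)) | np.isnan(np.asarray(X, float)).any(axis=1))
    complete_cond = complete & ~np.isnan(idx).any(axis=1)
    if complete_cond.sum() != complete.sum():
        raise ValueError("index dosages must be complete on the analysis samples")
    G = np.atleast_2d(np.asarray(G, dtype=float))[complete]
    b0, se0, p0 = burden_test(null_uncond, G, weights, mafs)
    q0, ps0, f0 = skat_test(null_uncond, G, mafs=mafs)
    absorbed = False
    try:
        b1, se1, p1 = burden_test(null_cond, G, weights, mafs)
        q1, ps1, f1 = skat_test(null_cond, G, mafs=mafs)
    except ValueError:
        # index dosages span the group's signal exactly: the conditional
        # effect is fully absorbed ("abolished" signal)
        absorbed = True
        b1, se1, p1 = 0.0, float("nan"), 1.0
        q1, ps1, f1 = 0.0, 1.0, False
    return {
        "unconditional": {"beta": b0, "se": se0, "p_burden": p0, "q_skat": q0, "p_skat": ps0},
        "conditional": {"beta": b1, "se": se1, "p_burden": p1, "q_skat": q1, "p_skat": ps1},
        "effect_proportion_pct": effect_proportion(b1, b0),
        "signal_absorbed": absorbed,
        "skat_fallback": bool(f0 or f1),
    }


def effect_proportion(beta_cond: float, beta_uncond: float) -> int:
    """Conditional / unconditional burden effect, as integer percent.

    Rounded half away from zero (0.98/0.92 -> 107, 0.75/0.76 -> 99).  A sign
    flip between the two estimates triggers a warning but is still reported.
    """
    if beta_uncond == 0:
        raise ValueError("unconditional effect is zero")
    if beta_cond * beta_uncond < 0:
        import warnings

        warnings.warn("conditional and unconditional effects have opposite signs")
    ratio = 100.0 * beta_cond / beta_uncond
    return int(np.floor(abs(ratio) + 0.5) * np.sign(ratio))
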