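"""Direct-effect FBAT and its conditional-mean screening statistic.

The scientific question: does a marker X affect the primary phenotype Y
*directly*, over and above its indirect effect mediated by a secondary
phenotype K?  Two linear models estimate the K→Y effect γ1:

    model (1):  E[Y | X, K, L] = γ0 + γ1·K + γ2·X + γ3·L
    model (2):  E[Y | K, L, S] = β0 + γ1*·K + β2·L + β3·E(X|S)

Model (2) replaces the offspring genotype with its Mendelian expectation
given the parental genotypes, so it never consumes X; under the null of no
direct effect (and no population substructure) γ1 coincides in the two
models.  Each model yields an adjusted phenotype
``Ỹ_i = Y_i − ȳ − γ̂1·(K_i − k̄)`` (deliberately not adjusted for L, which
may itself be genotype-dependent) and a score-type statistic:

* the confirmatory direct-effect test contrasts the observed transmission
  with its expectation, ``T_i = (X_i − E(X|S_i))·Ỹ_i``;
* the screening statistic uses the expected score only,
  ``T*_i = (E(X_i|S_i) − mean)·Ỹ*_i``, so ranking markers by it costs no
  multiple-testing adjustment for the confirmatory FBATs.

Both statistics correct their variance for the estimation of γ1 through a
nuisance regression of K on the covariates (and genotype terms), and are
referred to a chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trio_genetics import TrioMarker

__all__ = [
    "SingularDesignError",
    "Model1Fit",
    "Model2Fit",
    "NuisanceFit",
    "AdjustedPhenotype",
    "ScreenStatistic",
    "DirectTestResult",
    "fit_model1",
    "fit_model2",
    "center_adjust",
    "screen_statistic",
    "direct_test",
]

logger = logging.getLogger("trioscreen")


class SingularDesignError(ValueError):
    """An OLS design matrix is rank deficient."""


def _as_cov(L) -> np.ndarray:
    """Coerce covariates to an (n, p) array (possibly p = 0)."""
    if L is None:
        return np.empty((0, 0))
    L = np.asarray(L, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    return L


def _ols(columns: list[np.ndarray], names: list[str], y: np.ndarray):
    """Least-squares fit with an explicit rank check.

    Returns (beta, fitted, residuals). Raises SingularDesignError naming a
    zero-variance column when one exists, otherwise a generic message.
    """
    X = np.column_stack(columns)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        for j, name in enumerate(names):
            if name != "intercept" and np.ptp(X[:, j]) == 0.0:
                raise SingularDesignError(
                    f"design column {name!r} is constant; the model is not identifiable"
                )
        raise SingularDesignError(
            f"design matrix with columns {names} is rank deficient"
        )
    fitted = X @ beta
    return beta, fitted, y - fitted


@dataclass
class Model1Fit:
    """OLS fit of Y on (1, K, X, L): the model that uses the genotype."""

    gamma0: float
    gamma1: float
    gamma2: float
    gamma3: np.ndarray
    residuals: np.ndarray
    n: int


@dataclass
class Model2Fit:
    """OLS fit of Y on (1, K, L, E(X|S)): the conditional-mean model.

    ``exs_dropped`` marks a monomorphic expected-score column that was
    removed from the design instead of aborting the fit.
    """

    beta0: float
    gamma1_star: float
    beta2: np.ndarray
    beta3: float
    residuals: np.ndarray
    n: int
    exs_dropped: bool = False


@dataclass
class NuisanceFit:
    """Linear prediction of K used in the variance correction."""

    mu: np.ndarray
    sigma2: float
    covariates: str

    def __post_init__(self) -> None:
        if not self.sigma2 > 0.0:
            raise ValueError("nuisance residual variance must be positive")


@dataclass
class AdjustedPhenotype:
    """Ỹ_i = Y_i − ȳ − γ1·(K_i − k̄); mean-zero by construction."""

    values: np.ndarray
    y_mean: float
    k_mean: float
    gamma1_used: float


@dataclass
class ScreenStatistic:
    """Screening-step statistic for one marker (no offspring genotypes)."""

    value: float
    contributions: np.ndarray  # T*_i
    corrected: np.ndarray  # T̃*_i
    n_trios: int
    defined: bool = True
    message: str = ""


@dataclass
class DirectTestResult:
    """Variance-corrected direct-effect FBAT for one marker."""

    chi_square: float
    p_value: float
    gamma1_hat: float
    contributions: np.ndarray  # T_i
    corrected: np.ndarray  # T̃_i
    n_informative: int
    defined: bool = True
    message: str = ""


def fit_model1(Y, K, L, X) -> Model1Fit:
    """OLS of Y on intercept, K, X and covariates L (model (1))."""
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    X = np.asarray(X, dtype=float)
    L = _as_cov(L)
    n = Y.shape[0]
    cols = [np.ones(n), K, X]
    names = ["intercept", "K", "X"]
    for j in range(L.shape[1] if L.size else 0):
        cols.append(L[:, j])
        names.append(f"L{j + 1}")
    beta, _, resid = _ols(cols, names, Y)
    return Model1Fit(
        gamma0=float(beta[0]),
        gamma1=float(beta[1]),
        gamma2=float(beta[2]),
        gamma3=np.asarray(beta[3:], dtype=float),
        residuals=resid,
        n=n,
    )


def fit_model2(Y, K, L, exs) -> Model2Fit:
    """OLS of Y on intercept, K, covariates L and E(X|S) (model (2)).

    A constant expected-score column (all parental pairs identical) is
    dropped rather than raised, so panel-wide screening never aborts on a
    monomorphic marker; ``beta3`` is then 0 and ``exs_dropped`` is set.
    """
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    exs = np.asarray(exs, dtype=float)
    L = _as_cov(L)
    n = Y.shape[0]
    cols = [np.ones(n), K]
    names = ["intercept", "K"]
    for j in range(L.shape[1] if L.size else 0):
        cols.append(L[:, j])
        names.append(f"L{j + 1}")
    exs_dropped = bool(np.ptp(exs) == 0.0)
    if not exs_dropped:
        cols.append(exs)
        names.append("E(X|S)")
    beta, _, resid = _ols(cols, names, Y)
    return Model2Fit(
        beta0=float(beta[0]),
        gamma1_star=float(beta[1]),
        beta2=np.asarray(beta[2:-1] if not exs_dropped else beta[2:], dtype=float),
        beta3=float(beta[-1]) if not exs_dropped else 0.0,
        residuals=resid,
        n=n,
        exs_dropped=exs_dropped,
    )


def center_adjust(Y, K, gamma1: float) -> AdjustedPhenotype:
    """Adjusted phenotype Ỹ_i = Y_i − ȳ − γ1·(K_i − k̄).

    Removes the estimated mediated contribution of K; the measured
    covariates L are deliberately *not* subtracted, since L may itself be
    affected by the marker and adjusting for it would bias the test.
    """
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    if Y.size == 0:
        raise ValueError("cannot adjust an empty phenotype vector")
    ybar = float(Y.mean())
    kbar = float(K.mean())
    values = Y - ybar - gamma1 * (K - kbar)
    return AdjustedPhenotype(values=values, y_mean=ybar, k_mean=kbar, gamma1_used=gamma1)


def _nuisance_fit(K: np.ndarray, columns: list[np.ndarray], descriptor: str) -> NuisanceFit:
    """Predict K from the given columns (plus intercept); tolerant of rank
    deficiency (least-norm fit, dof from the achieved rank)."""
    n = K.shape[0]
    X = np.column_stack([np.ones(n)] + columns)
    beta, _, rank, _ = np.linalg.lstsq(X, K, rcond=None)
    mu = X @ beta
    dof = max(n - rank, 1)
    sigma2 = float(np.sum((K - mu) ** 2) / dof)
    return NuisanceFit(mu=mu, sigma2=sigma2, covariates=descriptor)


def _complete_case(marker: TrioMarker, arrays: list[np.ndarray]):
    """Mask trios with a missing genotype or phenotype; log exclusions."""
    mask = marker.complete
    for a in arrays:
        mask = mask & np.all(np.isfinite(np.atleast_2d(a).reshape(len(mask), -1)), axis=1)
    dropped = int(len(mask) - mask.sum())
    if dropped:
        logger.info("marker %s: dropped %d incomplete trios", marker.name, dropped)
    return mask


def _denominator(corrected: np.ndarray, variance: str) -> float:
    n = corrected.shape[0]
    if variance == "centered":
        return n * float(np.var(corrected, ddof=1))
    if variance == "uncentered":
        return float(np.sum(corrected**2))
    raise ValueError("variance must be 'centered' or 'uncentered'")


def screen_statistic(Y, K, L, marker: TrioMarker, variance: str = "centered") -> ScreenStatistic:
    """Screening statistic for one marker, using only parental genotypes.

    Steps: estimate γ1* from model (2); adjust Y; form per-subject
    contributions ``T*_i = (E(X_i|S_i) − mean)·Ỹ*_i``; correct them for the
    estimation of γ1* via the nuisance regression of K on (1, L, E(X|S));
    return ``(Σ T*_i)² / (n · var(T̃*))``.  The offspring genotype column is
    never read, so screening incurs no multiplicity cost for the
    confirmatory tests.
    """
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    L = _as_cov(L)
    mask = _complete_case(marker, [Y, K] + ([L] if L.size else []))
    y, k = Y[mask], K[mask]
    l = L[mask] if L.size else L
    exs = marker.exs[mask]
    n = int(mask.sum())
    if n == 0:
        return ScreenStatistic(np.nan, np.empty(0), np.empty(0), 0, False, "no complete trios")

    fit2 = fit_model2(y, k, l, exs)
    adj = center_adjust(y, k, fit2.gamma1_star)
    exs_centered = exs - exs.mean()
    t_star = exs_centered * adj.values
    if fit2.exs_dropped:
        # constant expected score: every contribution is 0, the statistic is
        # exactly 0 and the marker ranks behind any informative one
        return ScreenStatistic(
            value=0.0,
            contributions=t_star,
            corrected=t_star,
            n_trios=n,
            message="constant expected marker score",
        )

    cols = [l[:, j] for j in range(l.shape[1] if l.size else 0)]
    if not fit2.exs_dropped:
        cols = cols + [exs]
    nuis = _nuisance_fit(k, cols, "1 + L + E(X|S)")

    e_hat = float(np.mean(exs_centered * (k - adj.k_mean)))
    corrected = t_star - e_hat * (k - nuis.mu) / nuis.sigma2 * fit2.residuals

    denom = _denominator(corrected, variance)
    if not denom > 0.0 or not np.isfinite(denom):
        return ScreenStatistic(
            np.nan, t_star, corrected, n, False, "zero variance of corrected contributions"
        )
    value = float(t_star.sum() ** 2 / denom)
    return ScreenStatistic(value=value, contributions=t_star, corrected=corrected, n_trios=n)


def direct_test(Y, K, L, marker: TrioMarker, variance: str = "centered") -> DirectTestResult:
    """Variance-corrected FBAT for a direct X→Y effect at one marker.

    Steps: estimate γ̂1 from model (1); adjust Y; form
    ``T_i = (X_i − E(X_i|S_i))·Ỹ_i``; correct for the estimation of γ̂1 via
    the nuisance regression of K on (1, L, X, E(X|S)); refer
    ``(Σ T_i)² / (n · var(T̃))`` to chi-square with 1 df.  Only trios with a
    heterozygous parent contribute; a panel with none (or a degenerate
    variance) yields ``defined=False``.
    """
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    L = _as_cov(L)
    mask = _complete_case(marker, [Y, K] + ([L] if L.size else []))
    y, k = Y[mask], K[mask]
    l = L[mask] if L.size else L
    x = marker.offspring[mask].astype(float)
    exs = marker.exs[mask]
    n = int(mask.sum())
    n_informative = int(marker.informative[mask].sum())

    def undefined(msg: str) -> DirectTestResult:
        return DirectTestResult(
            chi_square=np.nan,
            p_value=np.nan,
            gamma1_hat=np.nan,
            contributions=np.empty(0),
            corrected=np.empty(0),
            n_informative=n_informative,
            defined=False,
            message=msg,
        )

    if n == 0:
        return undefined("no complete trios")
    if n_informative == 0:
        return undefined("no informative trios: every parent is homozygous, X ≡ E(X|S)")
    if np.ptp(x) == 0.0:
        return undefined("offspring genotype is monomorphic in the sample")

    fit1 = fit_model1(y, k, l, x)
    adj = center_adjust(y, k, fit1.gamma1)
    diff = x - exs
    t = diff * adj.values

    cols = [l[:, j] for j in range(l.shape[1] if l.size else 0)] + [x, exs]
    nuis = _nuisance_fit(k, cols, "1 + L + X + E(X|S)")

    # K is centered here so the statistic is exactly invariant to the scale
    # and location of K (the uncentered form differs by k̄·mean(X−E(X|S)),
    # an O(n^-1/2) term that breaks the invariance without changing the
    # asymptotics)
    e_hat = float(np.mean(diff * (k - adj.k_mean)))
    corrected = t - e_hat * (k - nuis.mu) / nuis.sigma2 * fit1.residuals

    denom = _denominator(corrected, variance)
    if not denom > 0.0 or not np.isfinite(denom):
        return undefined("zero variance of corrected contributions")
    chi = float(t.sum() ** 2 / denom)
    return DirectTestResult(
        chi_square=chi,
        p_value=float(stats.chi2.sf(chi, df=1)),
        gamma1_hat=fit1.gamma1,
        contributions=t,
        corrected=corrected,
        n_informative=n_informative,
    )
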