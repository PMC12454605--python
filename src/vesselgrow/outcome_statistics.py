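"""Outcome statistics: correlation maps and censored (Tobit) regression.

Lifespans of the cohort are right-censored: animals still alive at the
25-month cutoff were euthanized, so their recorded lifespan is a lower
bound.  Ordinary regression is biased under such censoring; the Tobit
model fits a latent linear model Y* = X beta + u, u ~ N(0, sigma^2),
observing Y = min(Y*, Y_max), by censored-normal maximum likelihood.
Goodness of fit uses the McKelvey-Zavoina pseudo-R^2, the share of latent
variance explained by the linear predictor.

Pairwise association across cohort variables is summarised by a Pearson
correlation map with Bonferroni-corrected significance flags.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

_COHORT_SHA256 = "47ddce286f4faab1f6b5125bfc2be01fe48f135f060409e2bccca1b21a5080ff"
CENSOR_CUTOFF_MONTHS = 25.0


@dataclass
class MouseRecord:
    """One cohort row: covariates, outcome and optional fitted quantities."""

    id: int
    sex: str
    lifespan: float           # months, censored at 25
    censored: bool
    E_asc: float              # kPa
    E_desc: float             # kPa
    ATI: float
    T_theta: float | None = None    # fitted, days
    T_s: float | None = None        # fitted, days
    sigma_theta_bar: float | None = None  # time-averaged mean stress, Pa

    def __post_init__(self):
        if self.lifespan > CENSOR_CUTOFF_MONTHS + 1e-9:
            raise ValueError("lifespan exceeds the censoring cutoff")
        if self.censored and abs(self.lifespan - CENSOR_CUTOFF_MONTHS) > 1e-9:
            raise ValueError("censored records must sit at the cutoff")


def load_cohort_table() -> list:
    """The packaged 10-mouse cohort fixture as a list of MouseRecord."""
    ref = resources.files("vesselgrow") / "data" / "cohort_table2.csv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _COHORT_SHA256:
        raise ValueError(
            f"cohort fixture checksum mismatch: {digest[:12]}..."
        )
    df = pd.read_csv(ref)
    return [
        MouseRecord(
            id=int(r.mouse), sex=str(r.sex),
            lifespan=float(r.lifespan_months), censored=bool(r.censored),
            E_asc=float(r.E_asc_kPa), E_desc=float(r.E_desc_kPa),
            ATI=float(r.ATI),
        )
        for r in df.itertuples()
    ]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(id=r.id, sex=r.sex, lifespan=r.lifespan,
                 censored=r.censored, E_asc=r.E_asc, E_desc=r.E_desc,
                 ATI=r.ATI, T_theta=r.T_theta, T_s=r.T_s,
                 sigma_theta_bar=r.sigma_theta_bar)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pearson correlation map with Bonferroni correction

@dataclass
class CorrelationMap:
    variables: list
    r: np.ndarray
    p: np.ndarray
    significant: np.ndarray   # Bonferroni-corrected at 95 % confidence
    n_tests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables,
                            columns=self.variables)


def pearson_map(data: pd.DataFrame, variables: list,
                alpha: float = 0.05) -> CorrelationMap:
    """Pairwise Pearson r with two-sided p and Bonferroni flags.

    p-values use the t-transform with n-2 degrees of freedom; the
    Bonferroni factor m is the number of distinct off-diagonal pairs.
    Zero-variance variables yield NaN r for their pairs.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 records for correlations")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            x = np.asarray(data[variables[i]], dtype=float)
            y = np.asarray(data[variables[j]], dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    p_adj = np.minimum(1.0, p * m)
    sig = (p_adj < alpha) & ~np.eye(k, dtype=bool) & ~np.isnan(p)
    return CorrelationMap(variables=list(variables), r=r, p=p,
                          significant=sig, n_tests=m)


# ---------------------------------------------------------------------------
# Tobit censored regression

@dataclass
class TobitResult:
    beta: np.ndarray
    sigma: float
    log_likelihood: float
    converged: bool
    n_censored: int
    standard_errors: np.ndarray | None = None

    def predict_latent(self, X) -> np.ndarray:
        return _design(X) @ self.beta


def _design(X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    return np.column_stack([np.ones(len(X)), X])


def _tobit_negloglik(params, Xd, y, censored, y_max):
    k = Xd.shape[1]
    beta, log_sigma = params[:k], params[k]
    sigma = np.exp(log_sigma)
    mu = Xd @ beta
    ll = 0.0
    unc = ~censored
    if unc.any():
        z = (y[unc] - mu[unc]) / sigma
        ll += np.sum(stats.norm.logpdf(z) - log_sigma)
    if censored.any():
        z = (y_max - mu[censored]) / sigma
        ll += np.sum(stats.norm.logsf(z))
    return -ll


def _tobit_neg_grad(params, Xd, y, censored, y_max):
    """Analytic gradient of the negative log-likelihood in (beta, log sigma)."""
    k = Xd.shape[1]
    beta, log_sigma = params[:k], params[k]
    sigma = np.exp(log_sigma)
    mu = Xd @ beta
    g_beta = np.zeros(k)
    g_logsig = 0.0
    unc = ~censored
    if unc.any():
        z = (y[unc] - mu[unc]) / sigma
        g_beta += Xd[unc].T @ (z / sigma)
        g_logsig += np.sum(z ** 2 - 1.0)
    if censored.any():
        zc = (y_max - mu[censored]) / sigma
        hazard = np.exp(stats.norm.logpdf(zc) - stats.norm.logsf(zc))
        g_beta += Xd[censored].T @ (hazard / sigma)
        g_logsig += np.sum(hazard * zc)
    return -np.r_[g_beta, g_logsig]


def tobit_fit(X, y, y_max: float = CENSOR_CUTOFF_MONTHS) -> TobitResult:
    """Right-censored Tobit regression by maximum likelihood.

    X excludes the intercept column (added internally).  Observations at
    or above ``y_max`` are treated as censored.  sigma is parameterized on
    the log scale; standard errors come from the inverse observed
    information (numeric Hessian).
    """
    Xd = _design(X)
    y = np.asarray(y, dtype=float)
    censored = y >= y_max - 1e-9
    if censored.all():
        raise ValueError(
            "all observations censored: likelihood uninformative"
        )
    # start from OLS on the observed values
    beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta0
    sigma0 = max(np.std(resid), 1e-3)
    x0 = np.r_[beta0, np.log(sigma0)]
    if np.isinf(y_max):
        censored = np.zeros(len(y), dtype=bool)
    res = optimize.minimize(
        _tobit_negloglik, x0, args=(Xd, y, censored, y_max),
        jac=_tobit_neg_grad,
        method="BFGS", options={"maxiter": 1000, "gtol": 1e-10},
    )
    k = Xd.shape[1]
    beta = res.x[:k]
    sigma = float(np.exp(res.x[k]))
    se = None
    H = _numeric_hessian(
        lambda p: _tobit_negloglik(p, Xd, y, censored, y_max), res.x
    )
    try:
        cov = np.linalg.inv(H)
        full_se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se = full_se[:k]
    except np.linalg.LinAlgError:
        pass
    return TobitResult(beta=beta, sigma=sigma,
                       log_likelihood=-float(res.fun),
                       converged=bool(res.success), n_censored=int(censored.sum()),
                       standard_errors=se)


def _numeric_hessian(f, x, h: float = 1e-5):
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


def mz_pseudo_r2(fit: TobitResult, X) -> float:
    """McKelvey-Zavoina pseudo-R^2 from latent predictions.

    r^2 = S / (S + N sigma^2) with S the sum of squared deviations of the
    latent predictions X beta-hat about their mean.
    """
    yhat = fit.predict_latent(X)
    s = float(np.sum((yhat - yhat.mean()) ** 2))
    n = len(yhat)
    return s / (s + n * fit.sigma ** 2)
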