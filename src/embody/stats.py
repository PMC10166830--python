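"""Association models linking embodiment metrics to schizotypy dimensions.

Four analysis families, chosen per outcome type:

* **Spearman + Holm** for the monotone associations (size, intensity,
  congruency vs each schizotypy z-score), with Fisher-z confidence
  intervals and step-down familywise adjustment within a declared family;
* **linear mixed model** for diffusion z-scores, with crossed random
  intercepts for subject, emotion and ROI and the three schizotypy
  dimensions as joint fixed effects;
* **zero-inflated negative binomial (ZINB)** for the mixed-pixel count — a
  logit-linked structural-zero part mixed with a log-linked NB2 count part,
  all three dimensions in both parts, exponentiated coefficients reported
  as odds/rate ratios;
* **correlation power** via the Fisher z approximation, and its inversion
  to the minimum detectable correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.stats.multitest import multipletests
from statsmodels.tools import add_constant

from .core import SCHIZOTYPY_FACTORS

__all__ = [
    "AssociationResult",
    "spearman_holm",
    "fit_diffusion_lmm",
    "fit_clarity_zinb",
    "simulate_zinb",
    "correlation_power",
    "detectable_r",
]

PREDICTORS = tuple(f"z_{f}" for f in SCHIZOTYPY_FACTORS)


@dataclass
class AssociationResult:
    """One outcome x predictor association, whatever the model family."""

    outcome: str
    predictor: str
    method: str  # spearman | lmm | zinb_count | zinb_zero
    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    family_size: int | None = None
    odds_ratio: float | None = None
    n: int | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["flags"] = ";".join(self.flags)
        return d


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# Spearman + Holm
# ---------------------------------------------------------------------------

def spearman_ci(rho: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z interval with the Spearman-specific variance 1.06/(n-3)."""
    if n <= 3 or abs(rho) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(rho)
    se = np.sqrt(1.06 / (n - 3))
    zc = stats.norm.ppf(0.5 + conf / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def spearman_holm(
    data: pd.DataFrame,
    outcomes: list[str],
    predictors: tuple[str, ...] = PREDICTORS,
    family: str = "block",
) -> list[AssociationResult]:
    """Spearman correlations of each outcome with each predictor, Holm-adjusted.

    Ranks use mid-rank ties.  The Holm family is the full outcome x
    predictor block by default (``family='block'``); ``family='outcome'``
    adjusts within each outcome's three predictor tests instead.  The
    family size used is recorded on every result.
    """
    if family not in ("block", "outcome"):
        raise ValueError("family must be 'block' or 'outcome'")
    results: list[AssociationResult] = []
    for outcome in outcomes:
        for pred in predictors:
            pair = data[[outcome, pred]].dropna()
            n = len(pair)
            if n < 4:
                raise ValueError(f"fewer than 4 complete pairs for {outcome} ~ {pred}")
            x, y = pair[outcome].to_numpy(), pair[pred].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"constant vector in {outcome} ~ {pred}")
            res = stats.spearmanr(x, y)
            rho, p = float(res.statistic), float(res.pvalue)
            lo, hi = spearman_ci(rho, n)
            results.append(AssociationResult(
                outcome=outcome, predictor=pred, method="spearman",
                estimate=rho, ci_low=lo, ci_high=hi,
                statistic=rho * np.sqrt((n - 2) / max(1 - rho**2, 1e-12)),
                p_raw=p, n=n,
            ))
    groups: dict[str, list[AssociationResult]] = {}
    for r in results:
        key = "all" if family == "block" else r.outcome
        groups.setdefault(key, []).append(r)
    for group in groups.values():
        adj = multipletests([r.p_raw for r in group], method="holm")[1]
        for r, pa in zip(group, adj):
            r.p_adjusted = float(pa)
            r.family_size = len(group)
    return results


# ---------------------------------------------------------------------------
# Linear mixed model for diffusion
# ---------------------------------------------------------------------------

@dataclass
class CrossedLMMResult:
    """Fit of a crossed random-intercept linear mixed model."""

    beta: np.ndarray
    se: np.ndarray
    fe_names: list[str]
    sigma2: float
    vc: dict[str, float]  # random-intercept variances by factor
    reml_loglik: float
    converged: bool
    n: int


def fit_crossed_intercepts(
    y: np.ndarray,
    X: np.ndarray,
    factors: dict[str, np.ndarray],
    fe_names: list[str] | None = None,
    theta_fix: dict[str, float] | None = None,
) -> CrossedLMMResult:
    """REML fit of ``y = X beta + sum_k u_k[factor_k] + e``.

    Crossed random intercepts (one per grouping factor, e.g. subject,
    emotion and ROI) with a profiled REML criterion: the variance ratios
    ``gamma_k = sigma_k^2 / sigma^2`` are optimized on the log scale while
    beta and sigma^2 are profiled out through the Woodbury identity, so one
    criterion evaluation costs a single q x q Cholesky (q = total number of
    random-effect levels).  ``theta_fix`` pins chosen ratios (0 removes a
    term: with all ratios fixed at 0 the fit is exactly OLS).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    # sparse-in-spirit dummy blocks: store index arrays, form Z'Z etc. by
    # bincount-style accumulation
    names = list(factors)
    codes = []
    sizes = []
    for name in names:
        _, code = np.unique(np.asarray(factors[name]), return_inverse=True)
        if code.max() < 1:
            raise ValueError(f"grouping factor {name!r} needs >=2 levels")
        codes.append(code)
        sizes.append(code.max() + 1)
    q = int(np.sum(sizes))
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
    col = np.concatenate([c + o for c, o in zip(codes, offsets)])
    row = np.tile(np.arange(n), len(names))
    from scipy import sparse

    Z = sparse.csr_matrix((np.ones_like(row, float), (row, col)), shape=(n, q))
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    block = np.repeat(np.arange(len(names)), sizes)

    def profile(gammas: np.ndarray):
        d = np.sqrt(gammas[block])
        A = (d[:, None] * ZtZ) * d[None, :]
        A[np.diag_indices_from(A)] += 1.0
        L = np.linalg.cholesky(A)
        # V0^{-1} = I - Z d A^{-1} d Z'
        dZtX = d[:, None] * ZtX
        dZty = d * Zty
        W_X = np.linalg.solve(L, dZtX)
        w_y = np.linalg.solve(L, dZty)
        XtVX = XtX - W_X.T @ W_X
        XtVy = Xty - W_X.T @ w_y
        ytVy = yty - w_y @ w_y
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta  # r' V0^{-1} r profiled
        sigma2 = max(rss / (n - p), 1e-12)
        logdetV0 = 2 * np.sum(np.log(np.diag(L)))
        s, logdetXtVX = np.linalg.slogdet(XtVX)
        m2ll = ((n - p) * (np.log(2 * np.pi * sigma2) + 1)
                + logdetV0 + logdetXtVX)
        return m2ll, beta, sigma2, XtVX

    fixed = dict(theta_fix or {})
    free = [i for i, name in enumerate(names) if name not in fixed]
    g0 = np.array([fixed.get(name, 0.1) for name in names], float)

    converged = True
    if free:
        def objective(log_g_free):
            g = g0.copy()
            g[free] = np.exp(np.clip(log_g_free, -30, 30))
            return profile(g)[0]

        opt = optimize.minimize(objective, np.log(np.full(len(free), 0.1)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        converged = bool(opt.success)
        g0[free] = np.exp(np.clip(opt.x, -30, 30))
    m2ll, beta, sigma2, XtVX = profile(g0)
    cov = sigma2 * np.linalg.inv(XtVX)
    return CrossedLMMResult(
        beta=beta, se=np.sqrt(np.diag(cov)),
        fe_names=fe_names or [f"x{i}" for i in range(p)],
        sigma2=float(sigma2),
        vc={name: float(g * sigma2) for name, g in zip(names, g0)},
        reml_loglik=-0.5 * float(m2ll), converged=converged, n=n,
    )


def fit_diffusion_lmm(
    long_table: pd.DataFrame,
    exclude_zeros: bool = False,
    theta_fix: dict[str, float] | None = None,
) -> list[AssociationResult]:
    """Mixed model of diffusion z on the three schizotypy dimensions.

    Crossed random intercepts for subject, emotion and ROI (REML, via
    :func:`fit_crossed_intercepts`); the three schizotypy dimensions enter
    jointly as fixed effects.  Fixed-effect tests use the normal
    approximation — results carry a ``df=normal`` flag in place of a
    small-sample Satterthwaite correction, which is immaterial at the
    designs used here (hundreds of subjects).  ``exclude_zeros`` refits on
    the nonzero-diffusion rows (the sensitivity analysis for unpainted
    ROIs).  Convergence problems and boundary (near-zero variance) fits
    are flagged on the results, never raised silently.
    """
    from .metrics import add_diffusion_z

    required = {"subject_id", "emotion", "roi", "diffusion_raw", *PREDICTORS}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    df = add_diffusion_z(long_table, exclude_zeros=exclude_zeros)
    for col in ("subject_id", "emotion", "roi"):
        if df[col].nunique() < 2:
            raise ValueError(f"grouping factor {col!r} needs >=2 levels")
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in PREDICTORS])
    fit = fit_crossed_intercepts(
        df["diffusion_z"].to_numpy(), X,
        factors={"subject": df["subject_id"].to_numpy(),
                 "emotion": df["emotion"].to_numpy(),
                 "roi": df["roi"].to_numpy()},
        fe_names=["const", *PREDICTORS],
        theta_fix=theta_fix,
    )
    flags = ["df=normal"]
    if not fit.converged:
        flags.append("nonconvergence")
    if any(v < 1e-8 * fit.sigma2 for v in fit.vc.values()):
        flags.append("singular")
    zc = stats.norm.ppf(0.975)
    out = []
    for i, pred in enumerate(["const", *PREDICTORS]):
        if pred == "const":
            continue
        beta, se = float(fit.beta[i]), float(fit.se[i])
        z = beta / se if se > 0 else float("nan")
        out.append(AssociationResult(
            outcome="diffusion_z" + ("_nonzero" if exclude_zeros else ""),
            predictor=pred, method="lmm", estimate=beta,
            ci_low=beta - zc * se, ci_high=beta + zc * se,
            statistic=z, p_raw=2 * stats.norm.sf(abs(z)),
            n=fit.n, flags=list(flags),
        ))
    return out


# ---------------------------------------------------------------------------
# Zero-inflated negative binomial for clarity (mixed pixels)
# ---------------------------------------------------------------------------

def fit_clarity_zinb(
    counts: np.ndarray | pd.Series,
    predictors: pd.DataFrame,
    outcome_label: str = "mixed_pixels",
    return_fit: bool = False,
):
    """ZINB regression of mixed-pixel counts on the schizotypy dimensions.

    NB2 parameterization (variance = mu + mu^2 / theta) with a log link on
    the count mean and a logit link on the structural-zero probability; all
    three predictors enter both parts.  Returns count-part results (method
    ``zinb_count``, exp(beta) as a rate ratio) and zero-part results
    (``zinb_zero``, exp(beta) as the multiplicative change in the odds of a
    structural zero per unit predictor).  Non-convergence is flagged, not
    raised.
    """
    y = np.asarray(counts)
    if y.ndim != 1 or np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be a 1-D non-negative integer array")
    if not np.any(y == 0):
        raise ValueError("zero-inflated model needs some zero counts")
    if np.all(y == 0):
        raise ValueError("all-zero outcome; nothing to model")
    X = add_constant(predictors[list(PREDICTORS)].astype(float), prepend=True)
    model = ZeroInflatedNegativeBinomialP(y.astype(float), X, exog_infl=X, p=2)
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # warm start: plain NB for the count part, empirical zero
            # fraction for the inflation intercept -- the default start
            # values diverge readily at small n
            from statsmodels.discrete.discrete_model import NegativeBinomialP

            nb = NegativeBinomialP(np.maximum(y, 1e-8), X, p=2).fit(disp=0, maxiter=200)
            frac0 = np.clip(np.mean(y == 0), 0.02, 0.98)
            start = np.concatenate([
                [np.log(frac0 / (1 - frac0))], np.zeros(X.shape[1] - 1),
                nb.params,
            ])
            fit = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            converged = bool(fit.mle_retvals.get("converged", False))
            if not converged or not np.all(np.abs(fit.params) < 50):
                refit = model.fit(start_params=start, method="nm",
                                  maxiter=5000, maxfun=5000, disp=0)
                refit = model.fit(start_params=refit.params, method="bfgs",
                                  maxiter=500, disp=0)
                if refit.llf >= fit.llf or not np.all(np.isfinite(fit.bse)):
                    fit = refit
                converged = bool(fit.mle_retvals.get("converged", False))
        except Exception as exc:  # pragma: no cover - pathological inputs
            raise RuntimeError(f"ZINB fit failed outright: {exc}") from exc
    if not converged:
        flags.append("nonconvergence")
    zc = stats.norm.ppf(0.975)
    out = []
    for pred in PREDICTORS:
        for method, name in (("zinb_count", pred), ("zinb_zero", f"inflate_{pred}")):
            beta = float(fit.params[name])
            se = float(fit.bse[name])
            z = beta / se if se > 0 else float("nan")
            out.append(AssociationResult(
                outcome=outcome_label, predictor=pred, method=method,
                estimate=beta, ci_low=beta - zc * se, ci_high=beta + zc * se,
                statistic=z, p_raw=2 * stats.norm.sf(abs(z)),
                odds_ratio=float(np.exp(beta)), n=len(y), flags=list(flags),
            ))
    if return_fit:
        return out, fit
    return out


def simulate_zinb(
    n: int,
    beta_count: dict[str, float],
    beta_zero: dict[str, float],
    intercept_count: float = 1.5,
    intercept_zero: float = -0.5,
    theta: float = 1.5,
    trait_correlation: float = 0.4,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw (predictors, counts) from a known ZINB model for recovery tests.

    Structural zeros occur with probability ``sigmoid(intercept_zero +
    X @ beta_zero)``; otherwise counts are NB2 with mean ``exp(
    intercept_count + X @ beta_count)`` and dispersion ``theta``.
    """
    rng = rng or np.random.default_rng()
    rho = trait_correlation
    corr = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
    X = rng.multivariate_normal(np.zeros(3), corr, size=n)
    Xdf = pd.DataFrame(X, columns=list(PREDICTORS))
    eta_zero = intercept_zero + X @ np.array([beta_zero.get(p, 0.0) for p in PREDICTORS])
    eta_count = intercept_count + X @ np.array([beta_count.get(p, 0.0) for p in PREDICTORS])
    p_struct = 1 / (1 + np.exp(-eta_zero))
    mu = np.exp(eta_count)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam)
    counts[rng.random(n) < p_struct] = 0
    return Xdf, counts


# ---------------------------------------------------------------------------
# Correlation power (Fisher z)
# ---------------------------------------------------------------------------

def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of zero Pearson correlation.

    Fisher z approximation: atanh(r_hat) ~ Normal(atanh(r), 1/(n-3)), so
    power = Phi(|atanh(r)| sqrt(n-3) - z_{1-alpha/2}) plus the (negligible)
    opposite-tail term Phi(-|atanh(r)| sqrt(n-3) - z_{1-alpha/2}).  At
    r = 0 this reduces to alpha, the size of the test.
    """
    if not abs(r) < 1:
        raise ValueError("r must lie in (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    d = abs(np.arctanh(r)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(d - za) + stats.norm.cdf(-d - za))


def detectable_r(power: float, n: int, alpha: float = 0.05) -> float:
    """Minimum |r| detectable with the given power: inverts correlation_power.

    Root-finding (Brent) to 1e-6; power must exceed the test's size alpha.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not alpha < power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    return float(optimize.brentq(
        lambda r: correlation_power(r, n, alpha) - power, 1e-9, 1 - 1e-9, xtol=1e-8,
    ))
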