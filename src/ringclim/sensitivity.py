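"""Climate-growth sensitivity: screening, mixed models, AIC stepwise.

Ring-width residuals are related to the standardised seasonal growth
factors in three stages: (1) a Pearson correlation screen of site-year
mean residuals against every legal (factor, season, lag) predictor;
(2) collinearity preselection keeping, per (season, lag), the water
factor with the largest |r| plus mean temperature; (3) a linear mixed
model with a random intercept per site, simplified by greedy backward
elimination on ML-based AIC, the surviving model refitted by REML for
reporting.

The random-intercept model is fitted by profiling the likelihood over
the variance ratio lambda = sigma_b^2 / sigma_e^2: given lambda the GLS
estimates and the profiled sigma_e^2 are closed-form in precomputed
cross-products, leaving a one-dimensional deterministic optimisation.
This makes a full 28-candidate stepwise run take milliseconds, which
the selection-recovery simulations rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .growth_factors import FACTORS
from .seasons import legal_season_keys

#: Water-category factors, in the canonical (tie-break) order.
WATER_FACTORS = ("transp_sum", "transp_deficit", "climatic_wb",
                 "mean_soil_moisture", "days_rew_lt_04", "days_rew_lt_07")
TEMPERATURE_FACTOR = "mean_temp"


# ---------------------------------------------------------------------------
# Profiled random-intercept linear mixed model
# ---------------------------------------------------------------------------

class _CrossProducts:
    """Sufficient statistics for profiled random-intercept fits.

    Holds X'X, X'y, y'y, per-group column sums and sizes for the full
    candidate design; any column subset can be fitted without touching
    the raw data again.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        codes, self.group_names = pd.factorize(groups)
        self.g = len(self.group_names)
        self.xtx = X.T @ X
        self.xty = X.T @ y
        self.yty = float(y @ y)
        self.sx = np.zeros((self.g, self.p))
        self.sy = np.zeros(self.g)
        np.add.at(self.sx, codes, X)
        np.add.at(self.sy, codes, y)
        self.ni = np.bincount(codes, minlength=self.g).astype(float)

    def subset(self, cols):
        cols = np.asarray(cols)
        sub = object.__new__(_CrossProducts)
        sub.n, sub.p = self.n, len(cols)
        sub.g, sub.group_names = self.g, self.group_names
        sub.xtx = self.xtx[np.ix_(cols, cols)]
        sub.xty = self.xty[cols]
        sub.yty = self.yty
        sub.sx = self.sx[:, cols]
        sub.sy = self.sy
        sub.ni = self.ni
        return sub


def _profile_pieces(cp: _CrossProducts, lam: float):
    """GLS pieces for V = sigma_e^2 (I + lam Z Z')."""
    c = lam / (1.0 + lam * cp.ni)          # per-group shrinkage weight
    a = cp.xtx - np.einsum("g,gi,gj->ij", c, cp.sx, cp.sx)
    b = cp.xty - (c * cp.sy) @ cp.sx
    q = cp.yty - float(c @ (cp.sy ** 2))
    beta = np.linalg.solve(a, b)
    wrss = q - float(beta @ b)
    logdet_ratio = float(np.sum(np.log1p(lam * cp.ni)))
    return a, beta, max(wrss, 1e-300), logdet_ratio


def _ml_loglik(cp: _CrossProducts, lam: float) -> float:
    _, _, wrss, logdet = _profile_pieces(cp, lam)
    n = cp.n
    sigma2 = wrss / n
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdet)


def _reml_loglik(cp: _CrossProducts, lam: float) -> float:
    a, _, wrss, logdet = _profile_pieces(cp, lam)
    n, p = cp.n, cp.p
    sigma2 = wrss / (n - p)
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return -np.inf
    return -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma2) + (n - p)
                   + logdet + logdet_a)


@dataclass
class RandomInterceptFit:
    """Result of a profiled random-intercept LMM fit."""

    params: np.ndarray          # fixed-effect estimates
    bse: np.ndarray             # standard errors
    sigma_b: float              # random-intercept sd
    sigma_e: float              # residual sd
    loglik: float
    method: str                 # "ml" or "reml"
    n: int
    p: int
    g: int

    @property
    def aic(self) -> float:
        # p fixed effects + residual variance + random-intercept variance
        return -2.0 * self.loglik + 2.0 * (self.p + 2)

    @property
    def df_containment(self) -> int:
        return max(self.n - self.g - self.p, 1)

    def pvalues(self) -> np.ndarray:
        t = self.params / self.bse
        return 2.0 * stats.t.sf(np.abs(t), self.df_containment)


def _fit_cp(cp: _CrossProducts, method: str = "ml") -> RandomInterceptFit:
    objective = _ml_loglik if method == "ml" else _reml_loglik

    def neg(u):
        return -objective(cp, 10.0 ** u)

    res = optimize.minimize_scalar(neg, bounds=(-10.0, 6.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    cand = [(objective(cp, 0.0), 0.0), (-res.fun, 10.0 ** res.x)]
    ll, lam = max(cand, key=lambda t: t[0])
    a, beta, wrss, _ = _profile_pieces(cp, lam)
    dof = cp.n if method == "ml" else cp.n - cp.p
    sigma2 = wrss / dof
    cov = sigma2 * np.linalg.inv(a)
    return RandomInterceptFit(
        params=beta, bse=np.sqrt(np.diag(cov)),
        sigma_b=float(np.sqrt(lam * sigma2)),
        sigma_e=float(np.sqrt(sigma2)),
        loglik=float(ll), method=method, n=cp.n, p=cp.p, g=cp.g,
    )


def fit_random_intercept(X: np.ndarray, y: np.ndarray, groups,
                         method: str = "ml") -> RandomInterceptFit:
    """Fit y = X beta + b_group + eps with b ~ N(0, sigma_b^2).

    A single group degenerates to OLS (lambda pinned to 0, confounded
    with the intercept).
    """
    cp = _CrossProducts(np.asarray(X, dtype=float),
                        np.asarray(y, dtype=float),
                        np.asarray(groups))
    if cp.g < 2:
        return _fit_ols_cp(cp, method)
    return _fit_cp(cp, method)


def _fit_ols_cp(cp: _CrossProducts, method: str = "ml") -> RandomInterceptFit:
    beta = np.linalg.solve(cp.xtx, cp.xty)
    wrss = cp.yty - float(beta @ cp.xty)
    dof = cp.n if method == "ml" else cp.n - cp.p
    sigma2 = max(wrss, 1e-300) / dof
    ll = -0.5 * (cp.n * np.log(2.0 * np.pi * wrss / cp.n) + cp.n)
    cov = sigma2 * np.linalg.inv(cp.xtx)
    return RandomInterceptFit(
        params=beta, bse=np.sqrt(np.diag(cov)), sigma_b=0.0,
        sigma_e=float(np.sqrt(sigma2)), loglik=float(ll), method=method,
        n=cp.n, p=cp.p, g=cp.g,
    )


# ---------------------------------------------------------------------------
# Screening and preselection
# ---------------------------------------------------------------------------

def correlation_screen(residuals: pd.DataFrame,
                       factors_std: pd.DataFrame,
                       min_obs: int = 10) -> pd.DataFrame:
    """Pearson r of site-year mean residuals vs each standardised factor.

    ``residuals`` has site_id, year (growth year), w_res at tree level;
    it is averaged per (site, year) before correlating, mirroring the
    site-wise screening display.  Returns a long table factor, season,
    lag, r, n; cells with a constant factor or too few overlapping
    observations have r = NaN.
    """
    resp = (residuals.groupby(["site_id", "year"], as_index=False)["w_res"]
            .mean().rename(columns={"year": "growth_year"}))
    merged = factors_std.merge(resp, on=["site_id", "growth_year"],
                               how="inner")
    rows = []
    for (factor, season, lag), sub in merged.groupby(
            ["factor", "season", "lag"], sort=False):
        x = sub["std_value"].to_numpy(dtype=float)
        y = sub["w_res"].to_numpy(dtype=float)
        if len(sub) < min_obs or np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"factor": factor, "season": season, "lag": lag,
                     "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def preselect(correlations: pd.DataFrame) -> list[tuple[str, str, str]]:
    """Candidate terms: per legal (season, lag) the water factor with
    maximal |r| plus mean temperature (at most 28 terms).

    Ties in |r| are broken by the canonical water-factor order; a
    (season, lag) whose water correlations are all missing contributes
    only the temperature term, and is dropped entirely if temperature
    is missing too.
    """
    corr = correlations.set_index(["factor", "season", "lag"])["r"]
    candidates: list[tuple[str, str, str]] = []
    for season, lag in legal_season_keys():
        best, best_abs = None, -1.0
        for f in WATER_FACTORS:
            r = corr.get((f, season, lag), np.nan)
            if np.isnan(r):
                continue
            if abs(r) > best_abs:
                best, best_abs = f, abs(r)
        if best is not None:
            candidates.append((best, season, lag))
        r_t = corr.get((TEMPERATURE_FACTOR, season, lag), np.nan)
        if not np.isnan(r_t):
            candidates.append((TEMPERATURE_FACTOR, season, lag))
    return candidates


# ---------------------------------------------------------------------------
# Model container, fitting and stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class SensitivityModel:
    """A fitted (and possibly reduced) climate-growth model."""

    species: str
    retained_terms: list = field(default_factory=list)  # (factor, season, lag)
    estimates: dict = field(default_factory=dict)       # term -> mm per SD
    pvalues: dict = field(default_factory=dict)
    intercept: float = 0.0
    intercept_p: float = np.nan
    site_intercept_sd: float = 0.0
    residual_sd: float = 0.0
    aic: float = np.nan
    marginal_r2: float = np.nan
    conditional_r2: float | None = None
    n_obs: int = 0
    n_sites: int = 0
    single_site_ols: bool = False
    standard_errors: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"growth_factor": f, "season": s, "lag": l,
                 "estimate": self.estimates[(f, s, l)],
                 "p": self.pvalues[(f, s, l)]}
                for f, s, l in self.retained_terms]
        rows.append({"growth_factor": "Intercept", "season": "", "lag": "",
                     "estimate": self.intercept, "p": self.intercept_p})
        return pd.DataFrame(rows)


def _design(residuals: pd.DataFrame, factors_wide: pd.DataFrame,
            candidates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tree-level response and candidate design matrix (intercept first)."""
    resp = residuals.rename(columns={"year": "growth_year"})
    keys = [f"{f}|{s}|{l}" for f, s, l in candidates]
    merged = resp.merge(factors_wide, on=["site_id", "growth_year"],
                        how="inner")
    missing = [k for k in keys if k not in merged.columns]
    if missing:
        raise KeyError(f"candidate columns missing from factors: {missing}")
    merged = merged.dropna(subset=keys + ["w_res"])
    X = np.column_stack([np.ones(len(merged))]
                        + [merged[k].to_numpy(dtype=float) for k in keys])
    y = merged["w_res"].to_numpy(dtype=float)
    groups = merged["site_id"].to_numpy()
    return X, y, groups


def fit_lme(residuals: pd.DataFrame, factors_wide: pd.DataFrame,
            candidates, species: str = "",
            method: str = "ml") -> tuple[SensitivityModel, _CrossProducts]:
    """Fit the full mixed model over all candidate terms.

    Response is the tree-level residual series; random intercept per
    site.  With a single site the model falls back to OLS (flagged).
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate term")
    X, y, groups = _design(residuals, factors_wide, candidates)
    cp = _CrossProducts(X, y, groups)
    fit = _fit_ols_cp(cp, method) if cp.g < 2 else _fit_cp(cp, method)
    model = _to_model(fit, cp, list(candidates), X, species)
    return model, cp


def _to_model(fit: RandomInterceptFit, cp: _CrossProducts, terms,
              X: np.ndarray, species: str,
              cols=None) -> SensitivityModel:
    pvals = fit.pvalues()
    model = SensitivityModel(species=species)
    model.retained_terms = list(terms)
    model.estimates = {t: float(b) for t, b in zip(terms, fit.params[1:])}
    model.pvalues = {t: float(p) for t, p in zip(terms, pvals[1:])}
    model.standard_errors = {t: float(s) for t, s in zip(terms, fit.bse[1:])}
    model.intercept = float(fit.params[0])
    model.intercept_p = float(pvals[0])
    model.site_intercept_sd = fit.sigma_b
    model.residual_sd = fit.sigma_e
    model.aic = fit.aic
    model.n_obs = fit.n
    model.n_sites = fit.g
    model.single_site_ols = fit.g < 2
    cols = cols if cols is not None else np.arange(X.shape[1])
    _attach_r2(model, fit, X[:, cols])
    return model


def _attach_r2(model: SensitivityModel, fit: RandomInterceptFit,
               X: np.ndarray) -> None:
    var_f = float(np.var(X @ fit.params))
    var_b = fit.sigma_b ** 2
    var_e = fit.sigma_e ** 2
    total = var_f + var_b + var_e
    model.marginal_r2 = var_f / total if total > 0 else 0.0
    if model.n_sites >= 2:
        model.conditional_r2 = (var_f + var_b) / total if total > 0 else 0.0
    else:
        model.conditional_r2 = None


def r2_decomposition(model: SensitivityModel) -> tuple[float, float | None]:
    """(marginal r2, conditional r2) of a fitted model; conditional is
    None for single-site fits."""
    return model.marginal_r2, model.conditional_r2


def stepwise_aic(residuals: pd.DataFrame, factors_wide: pd.DataFrame,
                 candidates, species: str = "") -> SensitivityModel:
    """Backward elimination on ML AIC, one term per iteration.

    Starting from the full candidate model, repeatedly remove the
    single term whose removal lowers AIC most (ties broken by candidate
    order); stop when no removal lowers AIC.  The intercept is never
    removed.  The surviving model is refitted by REML for the reported
    estimates; the AIC reported is the ML one used for selection.
    """
    candidates = list(candidates)
    X, y, groups = _design(residuals, factors_wide, candidates)
    cp_full = _CrossProducts(X, y, groups)
    single_site = cp_full.g < 2
    fitter = _fit_ols_cp if single_site else _fit_cp

    active = list(range(1, len(candidates) + 1))  # column indices, no icpt
    current = fitter(cp_full.subset([0] + active), "ml")
    while len(active) > 0:
        best_aic, best_j = current.aic, None
        for pos, j in enumerate(active):
            trial = [0] + [k for k in active if k != j]
            fit = fitter(cp_full.subset(trial), "ml")
            if fit.aic < best_aic - 1e-12:
                best_aic, best_j = fit.aic, j
        if best_j is None:
            break
        active = [k for k in active if k != best_j]
        current = fitter(cp_full.subset([0] + active), "ml")

    cols = [0] + active
    reml = fitter(cp_full.subset(cols), "reml")
    terms = [candidates[j - 1] for j in active]
    model = _to_model(reml, cp_full, terms, X, species, cols=np.array(cols))
    model.aic = current.aic
    return model


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def model_report_frame(model: SensitivityModel) -> pd.DataFrame:
    """Table mirroring the published predictor/performance layout."""
    df = model.to_frame()
    df["species"] = model.species
    df["marginal_r2"] = model.marginal_r2
    df["conditional_r2"] = model.conditional_r2
    return df
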