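"""Restricted-cubic-spline (RCS) regression for drought-legacy detection.

Daily GPP is regressed on hydro-meteorological drivers with natural cubic
spline bases,

``g(y) = b0 + b1 x + sum_{i=2}^{k-1} b_i C_i(x)``  (identity link),

where the spline components C_i are constrained to be linear beyond the
boundary knots. Model selection uses AIC = 2k - 2 ln L (k counting all
coefficients plus the error variance). A model with only concurrent drivers
(PPFD, SWC) is compared against one that adds drought history (SPEI at 90
and 365 days): a post-drought year whose productivity the concurrent-driver
model systematically overestimates — and the SPEI model does not — carries a
legacy effect.

Feature importance is the Wald statistic chi2 = beta_S' Sigma_S^-1 beta_S
over all basis coefficients of a predictor (equal to df times the nested
F statistic), reported as chi2 minus its degrees of freedom; the degree of
nonlinearity is the share of the predictor's partial sum of squares carried
by its spline columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}

MPE_FLOOR = 0.5        # gC m-2 d-1; days below are excluded from MPE
MIN_YEAR_DAYS = 30


def place_knots(x, k: int) -> np.ndarray:
    """Knot positions at the canonical default quantiles for k in 3..5.

    Quantile ties are nudged to the nearest distinct data values so the
    knots are strictly increasing.
    """
    if k not in KNOT_QUANTILES:
        raise ValueError(f"number of knots must be 3, 4 or 5, got {k}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    distinct = np.unique(x)
    if len(distinct) < 5 * k:
        raise ValueError(f"need >= {5 * k} distinct values for {k} knots, "
                         f"got {len(distinct)}")
    knots = np.quantile(x, KNOT_QUANTILES[k])
    for i in range(1, len(knots)):
        if knots[i] <= knots[i - 1]:
            higher = distinct[distinct > knots[i - 1]]
            knots[i] = higher[0]
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis: 1 linear + (k-2) nonlinear columns.

    Truncated-cubic construction with both tail-linearity constraints and
    the conventional (k_max - k_min)^2 normalization; the fitted function is
    exactly linear for x below the first and above the last knot.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3 or np.any(np.diff(knots) <= 0):
        raise ValueError("need >= 3 strictly increasing knots")
    tk, tk1 = knots[-1], knots[-2]
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        c = (np.clip(x - tj, 0, None) ** 3
             - np.clip(x - tk1, 0, None) ** 3 * (tk - tj) / (tk - tk1)
             + np.clip(x - tk, 0, None) ** 3 * (tk1 - tj) / (tk - tk1))
        cols.append(c / norm)
    return np.column_stack(cols)


@dataclass
class RcsModel:
    """Fitted RCS regression with its design bookkeeping."""

    response: str
    predictors: list
    k: int
    knots: dict                  # predictor -> knot array
    beta: np.ndarray
    cov: np.ndarray              # sigma^2 (X'X)^-1 with unbiased sigma^2
    llf: float
    aic: float
    adj_r2: float
    n_obs: int
    n_params: int                # coefficients + error variance
    columns: list                # design column labels
    col_index: dict              # predictor -> list of column positions
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    dates: pd.DatetimeIndex = field(repr=False)

    def design_for(self, data: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(data))]
        for p in self.predictors:
            cols.append(rcs_basis(data[p].to_numpy(dtype=float), self.knots[p]))
        return np.column_stack(cols)

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        X = self.X if data is None else self.design_for(data)
        return X @ self.beta

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    @property
    def ssr(self) -> float:
        return float(np.sum((self.y - self.fitted) ** 2))


@dataclass
class ImportanceResult:
    predictor: str
    chi2: float
    df: int
    importance: float            # chi2 - df
    nonlinearity: float          # spline share of the partial SS, in [0, 1]


@dataclass
class YearMetrics:
    year: int
    rmse: float                  # gC m-2 d-1
    mpe: float                   # %, negative = overestimation
    adj_r2: float
    n: int


def _ols_stats(X: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, X).fit()
    return res


def fit_model(daily: pd.DataFrame, predictors, k: int,
              response: str = "GPP") -> RcsModel:
    """Fit an RCS regression of daily GPP on the given predictors.

    ``daily`` must contain the response and predictor columns plus a
    ``date`` column; rows with any missing value are dropped. All
    predictors share the knot count ``k`` with knots at their own default
    quantiles. Gaussian OLS with identity link; AIC counts every
    coefficient plus the error variance.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    data = daily.dropna(subset=cols)
    y = data[response].to_numpy(dtype=float)
    knots = {p: place_knots(data[p].to_numpy(dtype=float), k) for p in predictors}
    design_cols = [np.ones(len(data))]
    labels = ["intercept"]
    col_index = {}
    pos = 1
    for p in predictors:
        basis = rcs_basis(data[p].to_numpy(dtype=float), knots[p])
        design_cols.append(basis)
        idx = list(range(pos, pos + basis.shape[1]))
        col_index[p] = idx
        labels += [p if j == 0 else f"{p}_s{j}" for j in range(basis.shape[1])]
        pos += basis.shape[1]
    X = np.column_stack(design_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix rank deficient ({rank} < {X.shape[1]}); "
                         f"check for collinear predictors among {predictors}")
    res = _ols_stats(X, y)
    n_params = X.shape[1] + 1          # + error variance
    aic = 2.0 * n_params - 2.0 * res.llf
    return RcsModel(response=response, predictors=predictors, k=k, knots=knots,
                    beta=np.asarray(res.params), cov=np.asarray(res.cov_params()),
                    llf=float(res.llf), aic=float(aic),
                    adj_r2=float(res.rsquared_adj), n_obs=len(y),
                    n_params=n_params, columns=labels, col_index=col_index,
                    X=X, y=y, dates=pd.DatetimeIndex(data["date"]))


def select_knots(daily: pd.DataFrame, predictors, response: str = "GPP"
                 ) -> tuple[int, RcsModel]:
    """Shared knot count in {3, 4, 5} minimizing AIC (ties -> smaller k)."""
    best = None
    for k in (3, 4, 5):
        model = fit_model(daily, predictors, k, response=response)
        if best is None or model.aic < best[1].aic - 1e-12:
            best = (k, model)
    return best


def feature_importance(model: RcsModel, predictor: str) -> ImportanceResult:
    """Wald chi2 importance and nonlinearity share of one predictor.

    chi2 = beta_S' Sigma_S^-1 beta_S over the predictor's basis columns
    (linear + splines); importance = chi2 - df. The nonlinearity fraction is
    (partial SS of the spline columns) / (partial SS of all the predictor's
    columns), each from a sequential sub-model refit.
    """
    if predictor not in model.col_index:
        raise ValueError(f"{predictor} not in model")
    idx = model.col_index[predictor]
    beta_s = model.beta[idx]
    cov_s = model.cov[np.ix_(idx, idx)]
    try:
        chi2 = float(beta_s @ np.linalg.solve(cov_s, beta_s))
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular coefficient covariance for {predictor}") from err
    df = len(idx)

    keep_wo_all = [j for j in range(model.X.shape[1]) if j not in idx]
    keep_wo_spline = [j for j in range(model.X.shape[1]) if j not in idx[1:]]
    ssr_full = model.ssr
    ssr_wo_all = float(_ols_stats(model.X[:, keep_wo_all], model.y).ssr)
    if len(idx) > 1:
        ssr_wo_spline = float(_ols_stats(model.X[:, keep_wo_spline], model.y).ssr)
        ss_spline = ssr_wo_spline - ssr_full
    else:
        ss_spline = 0.0
    ss_all = ssr_wo_all - ssr_full
    frac = float(np.clip(ss_spline / ss_all, 0.0, 1.0)) if ss_all > 0 else 0.0
    return ImportanceResult(predictor=predictor, chi2=chi2, df=df,
                            importance=chi2 - df, nonlinearity=frac)


def partial_dependence(model: RcsModel, predictors, grid_sizes=(25, 25)
                       ) -> pd.DataFrame:
    """Uni- or bivariate partial dependence of the fitted surface.

    For each grid point of the chosen predictor(s), the model prediction is
    averaged over the empirical distribution of the remaining columns. Grid
    points outside the data range are flagged (the spline tails are linear,
    so extrapolation is well defined but untested by data).
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    predictors = list(predictors)
    for p in predictors:
        if p not in model.col_index:
            raise ValueError(f"{p} not in model")
    grids = []
    for p, g in zip(predictors, grid_sizes):
        col = model.X[:, model.col_index[p][0]]   # linear column = raw values
        grids.append(np.linspace(col.min(), col.max(), g))
    base = model.fitted.copy()
    contrib = {}
    for p in predictors:
        idx = model.col_index[p]
        base = base - model.X[:, idx] @ model.beta[idx]
    rest_mean = float(base.mean())
    for p, grid in zip(predictors, grids):
        b = rcs_basis(grid, model.knots[p])
        contrib[p] = b @ model.beta[model.col_index[p]]
    if len(predictors) == 1:
        p = predictors[0]
        return pd.DataFrame({p: grids[0], "pd": rest_mean + contrib[p]})
    p1, p2 = predictors
    g1, g2 = np.meshgrid(grids[0], grids[1], indexing="ij")
    surface = rest_mean + contrib[p1][:, None] + contrib[p2][None, :]
    return pd.DataFrame({p1: g1.ravel(), p2: g2.ravel(), "pd": surface.ravel()})


def yearly_metrics(model: RcsModel, min_days: int = MIN_YEAR_DAYS) -> list:
    """Per-calendar-year RMSE, MPE and adjusted R2 of the fitted model.

    MPE = 100 * mean((obs - pred) / obs) over days with obs >= 0.5 gC m-2
    d-1 (avoids winter blow-ups); negative MPE means overestimation. The
    within-year R2 evaluates the *global* fit on that year's days. Years
    with fewer than 30 qualifying days are skipped.
    """
    pred = model.fitted
    obs = model.y
    years = model.dates.year
    out = []
    for year in sorted(set(years)):
        m = years == year
        if m.sum() < min_days:
            continue
        o, p = obs[m], pred[m]
        rmse = float(np.sqrt(np.mean((o - p) ** 2)))
        floor = o >= MPE_FLOOR
        mpe = float(100.0 * np.mean((o[floor] - p[floor]) / o[floor])) if floor.any() else float("nan")
        ss_res = float(np.sum((o - p) ** 2))
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        n, q = int(m.sum()), model.X.shape[1] - 1
        adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - q - 1, 1)
        out.append(YearMetrics(year=int(year), rmse=rmse, mpe=mpe,
                               adj_r2=float(adj), n=n))
    return out


@dataclass
class ModelComparison:
    delta_aic: float             # full - simple; negative favours the full model
    delta_adj_r2: float
    per_year: pd.DataFrame       # year, mpe_simple, mpe_full, delta_mpe
    legacy_mpe_reduction: dict   # year -> relative |MPE| reduction (fraction)


def compare_models(simple: RcsModel, full: RcsModel,
                   legacy_years=()) -> ModelComparison:
    """Compare the concurrent-driver model with the SPEI-augmented model."""
    if simple.n_obs != full.n_obs or not np.array_equal(simple.y, full.y):
        raise ValueError("models were fitted on different response rows")
    m_simple = {m.year: m for m in yearly_metrics(simple)}
    m_full = {m.year: m for m in yearly_metrics(full)}
    years = sorted(set(m_simple) & set(m_full))
    per_year = pd.DataFrame({
        "year": years,
        "mpe_simple": [m_simple[y].mpe for y in years],
        "mpe_full": [m_full[y].mpe for y in years],
    })
    per_year["delta_mpe"] = per_year["mpe_full"] - per_year["mpe_simple"]
    reductions = {}
    for y in legacy_years:
        if y in m_simple and y in m_full and abs(m_simple[y].mpe) > 0:
            reductions[y] = 1.0 - abs(m_full[y].mpe) / abs(m_simple[y].mpe)
    return ModelComparison(delta_aic=full.aic - simple.aic,
                           delta_adj_r2=full.adj_r2 - simple.adj_r2,
                           per_year=per_year,
                           legacy_mpe_reduction=reductions)
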