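"""Group-level inference: genotype + BMI regression on ROI PE estimates.

The dependent variable is a subject's ROI prediction-error parameter
estimate; predictors are BMI and ordinal genotype codes, entered
simultaneously (the "Enter" method — no stepwise selection).  Reported
coefficients are standardized betas; their p-values and confidence
intervals come from a case-resampling bootstrap (percentile intervals,
sign-count p-values with the +1 small-sample correction).  Collinearity
is screened with tolerance / variance-inflation factors (VIF > 5
flagged), non-normal continuous variables are rank-transformed after a
Shapiro-Wilk screen, and model-level p-values are Bonferroni-corrected
across the regions of interest tested per predictor grouping.

The public surface follows the statsmodels pattern: build a
:class:`PERegression` model from a DataFrame, call :meth:`fit`, read the
:class:`PERegressionResults`, print ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MODEL_SPECS",
    "DEFAULT_ROIS",
    "PERegression",
    "PERegressionResults",
    "enter_regression",
    "bootstrap_inference",
    "collinearity",
    "rank_transform_if_nonnormal",
    "bonferroni",
    "run_model_suite",
    "d1_reduced_posthoc",
]

#: Predictor groupings tested against each ROI's PE estimate.
MODEL_SPECS: dict[str, list[str]] = {
    "D2": ["bmi", "code_rs1799732", "code_rs1800497"],
    "D1": ["bmi", "code_rs686", "code_rs4532", "code_rs5326"],
    "OTHER": ["bmi", "code_rs4680", "code_DAT", "code_DRD4"],
    "SUMMARY": ["summary_score"],
}

#: A priori bilateral reward-circuitry regions of interest.
DEFAULT_ROIS: list[str] = [
    f"{region}_{hemi}"
    for region in ("caudate_head", "putamen", "substantia_nigra", "nucleus_accumbens")
    for hemi in ("left", "right")
]


def rank_transform_if_nonnormal(
    column: np.ndarray | pd.Series, alpha_sw: float = 0.05
) -> tuple[np.ndarray, bool]:
    """Rank-transform a column when Shapiro-Wilk rejects normality.

    Returns (possibly transformed column, flag).  Average ranks are used
    for ties, so the transform is idempotent.
    """
    x = np.asarray(column, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a normality screen")
    if np.ptp(x) == 0.0:
        return x, False  # constant: SW undefined, leave as is
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.shapiro(x).pvalue
    if p < alpha_sw:
        return stats.rankdata(x), True
    return x, False


def bonferroni(pvals, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment for a family of m tests: p_adj = min(1, m*p)."""
    p = np.atleast_1d(np.asarray(pvals, float))
    if m < len(p):
        raise ValueError("family size m smaller than the number of p-values")
    adj = np.minimum(1.0, m * p)
    return adj, adj < 0.05


def collinearity(X: pd.DataFrame, vif_threshold: float = 5.0) -> pd.DataFrame:
    """Tolerance and VIF per predictor; VIF above the threshold is flagged.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j (with intercept)
    on the remaining predictors.  A predictor perfectly explained by the
    others — including a constant column, which the intercept absorbs —
    reports an infinite VIF.
    """
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    rows = []
    cols = list(X.columns)
    Xv = X.to_numpy(float)
    for j, name in enumerate(cols):
        xj = Xv[:, j]
        others = np.delete(Xv, j, axis=1)
        Z = sm.add_constant(others) if others.size else np.ones((len(xj), 1))
        if np.ptp(xj) == 0.0:
            r2 = 1.0
        else:
            res = sm.OLS(xj, Z).fit()
            r2 = min(1.0, max(0.0, res.rsquared))
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append(
            {
                "predictor": name,
                "tolerance": 1.0 / vif if np.isfinite(vif) else 0.0,
                "vif": vif,
                "flagged": vif > vif_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def _standardized_betas(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Standardized coefficients of y on X (all z-scored, ddof=1)."""
    sd_x = X.std(axis=0, ddof=1)
    if np.any(sd_x == 0.0):
        bad = np.flatnonzero(sd_x == 0.0)
        raise ValueError(
            f"constant predictor column(s) at position {bad.tolist()}: "
            "standardized coefficients are undefined"
        )
    ys = (y - y.mean()) / y.std(ddof=1)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(ys)), Xs]), ys, rcond=None)
    return beta[1:]


def enter_regression(y, X: pd.DataFrame) -> "PERegressionResults":
    """All-predictors-at-once OLS with standardized betas (no bootstrap)."""
    return PERegression(y, X).fit(bootstrap=None)


def bootstrap_inference(
    y,
    X: pd.DataFrame,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Case-resampling bootstrap of the standardized coefficients.

    Resamples subjects with replacement B times, refits, and reports a
    percentile confidence interval and a sign-count p-value per
    predictor:  p = 2 * (min(#(b* <= 0), #(b* >= 0)) + 1) / (B + 1),
    capped at 1 (so p can never fall below 2/(B+1)).  Degenerate
    resamples (rank-deficient or zero-variance columns) are redrawn and
    counted.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yv = np.asarray(y, float)
    Xv = X.to_numpy(float)
    n, p = Xv.shape
    if np.ptp(yv) == 0.0:
        raise ValueError("dependent variable has zero variance")

    point = _standardized_betas(yv, Xv)
    boot = np.empty((B, p))
    pending = np.arange(B)
    n_redrawn = 0
    data = np.column_stack([yv, Xv])
    while len(pending):
        idx = rng.integers(0, n, size=(len(pending), n))
        samp = data[idx]  # (b, n, 1+p)
        ys, Xs = samp[:, :, 0], samp[:, :, 1:]
        sd_y = ys.std(axis=1, ddof=1)
        sd_x = Xs.std(axis=1, ddof=1)
        ok = (sd_y > 0) & (sd_x > 0).all(axis=1)
        zy = (ys - ys.mean(axis=1, keepdims=True)) / np.where(ok, sd_y, 1.0)[:, None]
        zx = (Xs - Xs.mean(axis=1, keepdims=True)) / np.where(
            ok[:, None], sd_x, 1.0
        )[:, None, :]
        G = np.einsum("bni,bnj->bij", zx, zx)
        h = np.einsum("bni,bn->bi", zx, zy)
        with np.errstate(all="ignore"):
            try:
                betas = np.linalg.solve(G, h[..., None])[..., 0]
            except np.linalg.LinAlgError:
                betas = np.full((len(pending), p), np.nan)
                for i in range(len(pending)):
                    try:
                        betas[i] = np.linalg.solve(G[i], h[i])
                    except np.linalg.LinAlgError:
                        pass
        ok &= np.isfinite(betas).all(axis=1)
        boot[pending[ok]] = betas[ok]
        n_redrawn += int((~ok).sum())
        pending = pending[~ok]

    lo = (1.0 - ci_level) / 2.0
    rows = []
    for j, name in enumerate(X.columns):
        b = boot[:, j]
        n_le = int((b <= 0).sum())
        n_ge = int((b >= 0).sum())
        pval = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (B + 1))
        rows.append(
            {
                "predictor": name,
                "beta_std": point[j],
                "p_boot": pval,
                "ci_low": float(np.quantile(b, lo)),
                "ci_high": float(np.quantile(b, 1.0 - lo)),
            }
        )
    out = pd.DataFrame(rows).set_index("predictor")
    out.attrs["n_redrawn"] = n_redrawn
    out.attrs["B"] = B
    return out


@dataclass
class PERegressionResults:
    """Fitted group-level model: coefficient table and model statistics.

    ``params`` has one row per predictor with standardized beta,
    bootstrap p / CI (when bootstrapped), tolerance and VIF.
    """

    params: pd.DataFrame
    f_statistic: float
    model_p: float
    r_squared: float
    n: int
    dependent: str
    rank_transformed: list[str] = field(default_factory=list)
    n_redrawn: int = 0
    B: int | None = None

    def summary(self) -> str:
        lines = [
            f"PE regression ({self.dependent}), Enter method, n = {self.n}",
            f"  F = {self.f_statistic:.3f}, model p = {self.model_p:.4g}, "
            f"R^2 = {self.r_squared:.3f}",
        ]
        if self.rank_transformed:
            lines.append(f"  rank-transformed: {', '.join(self.rank_transformed)}")
        if self.B:
            lines.append(f"  bootstrap: B = {self.B} ({self.n_redrawn} redrawn)")
        with pd.option_context("display.width", 120):
            lines.append(self.params.to_string(float_format=lambda v: f"{v: .3f}"))
        return "\n".join(lines)


class PERegression:
    """Enter-method multiple regression of an ROI PE estimate.

    Parameters
    ----------
    y : dependent variable (per-subject ROI PE parameter estimates).
    X : DataFrame of predictors, all entered simultaneously.
    screen_normality : Shapiro-Wilk screen (alpha 0.05) on the dependent
        variable and any predictors named in ``continuous``; columns that
        fail are rank-transformed before fitting.
    continuous : predictor columns treated as continuous for the screen
        (default: ``bmi``, ``age`` and ``summary_score`` when present;
        ordinal genotype codes are never transformed).
    """

    _CONTINUOUS_DEFAULT = ("bmi", "age", "summary_score")

    def __init__(
        self,
        y,
        X: pd.DataFrame,
        dependent: str = "y",
        screen_normality: bool = True,
        continuous: tuple[str, ...] | None = None,
    ) -> None:
        X = pd.DataFrame(X)
        yv = np.asarray(y, float)
        if len(yv) != len(X):
            raise ValueError("y and X lengths differ")
        if len(yv) <= X.shape[1] + 1:
            raise ValueError("need n > p + 1 observations")
        if np.isnan(yv).any() or X.isna().any().any():
            raise ValueError("missing values; apply complete-case filtering upstream")
        if X.columns.duplicated().any():
            raise ValueError("duplicate predictor names")
        self.dependent = dependent
        self.rank_transformed: list[str] = []
        if screen_normality:
            cont = continuous if continuous is not None else self._CONTINUOUS_DEFAULT
            yv, flag = rank_transform_if_nonnormal(yv)
            if flag:
                self.rank_transformed.append(dependent)
            X = X.copy()
            for c in X.columns:
                if c in cont:
                    X[c], flag = rank_transform_if_nonnormal(X[c])
                    if flag:
                        self.rank_transformed.append(c)
        self.y = yv
        self.X = X

    def fit(
        self,
        bootstrap: int | None = 1000,
        seed: int | np.random.Generator = 0,
    ) -> PERegressionResults:
        Xv = self.X.to_numpy(float)
        if np.linalg.matrix_rank(sm.add_constant(Xv)) < Xv.shape[1] + 1:
            bad = collinearity_rank_report(self.X)
            raise np.linalg.LinAlgError(
                f"rank-deficient design; collinear columns: {bad}"
            )
        ols = sm.OLS(self.y, sm.add_constant(Xv)).fit()
        beta_std = _standardized_betas(self.y, Xv)
        table = pd.DataFrame(
            {"beta_std": beta_std}, index=pd.Index(self.X.columns, name="predictor")
        )
        coll = collinearity(self.X)
        table["tolerance"] = coll["tolerance"]
        table["vif"] = coll["vif"]
        table["vif_flagged"] = coll["flagged"]
        n_redrawn, B = 0, None
        if bootstrap is not None:
            boot = bootstrap_inference(self.y, self.X, B=bootstrap, seed=seed)
            table["p_boot"] = boot["p_boot"]
            table["ci_low"] = boot["ci_low"]
            table["ci_high"] = boot["ci_high"]
            n_redrawn = boot.attrs["n_redrawn"]
            B = bootstrap
        return PERegressionResults(
            params=table,
            f_statistic=float(ols.fvalue),
            model_p=float(ols.f_pvalue),
            r_squared=float(ols.rsquared),
            n=len(self.y),
            dependent=self.dependent,
            rank_transformed=list(self.rank_transformed),
            n_redrawn=n_redrawn,
            B=B,
        )


def collinearity_rank_report(X: pd.DataFrame) -> str:
    """Name the columns that render a design rank deficient."""
    Xv = X.to_numpy(float)
    keep: list[int] = []
    bad: list[str] = []
    base = np.ones((len(Xv), 1))
    for j, name in enumerate(X.columns):
        trial = np.column_stack([base, Xv[:, keep + [j]]])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(name)
        else:
            keep.append(j)
    return ", ".join(bad) if bad else "(none)"


def run_model_suite(
    dataset: pd.DataFrame,
    specs: list[str] | None = None,
    rois: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    bonferroni_m: int | None = None,
    include_age: bool = False,
) -> pd.DataFrame:
    """Fit every (predictor grouping, ROI) model and collect a results table.

    For each grouping in ``specs`` (D2, D1, OTHER, ...) and each ROI
    column ``pe_<roi>`` of the dataset, fits a bootstrap Enter-method
    regression and records per-predictor standardized betas, bootstrap
    p-values, collinearity diagnostics and the model F-test.  Model
    p-values are Bonferroni-adjusted within each grouping across the
    ROIs tested (family size ``bonferroni_m``, default the number of
    ROIs).  Subjects with missing values for a grouping's columns are
    dropped from that grouping only (complete case), and the per-model
    ``n`` records it.
    """
    specs = specs or ["D2", "D1", "OTHER"]
    rois = rois or DEFAULT_ROIS
    m = bonferroni_m if bonferroni_m is not None else len(rois)
    rng = np.random.default_rng(seed)
    rows = []
    for spec_name in specs:
        predictors = MODEL_SPECS[spec_name]
        if include_age and "age" not in predictors:
            predictors = predictors + ["age"]
        model_ps = {}
        fits = {}
        for roi in rois:
            ycol = f"pe_{roi}"
            cols = [ycol] + predictors
            sub = dataset.dropna(subset=cols)
            model = PERegression(
                sub[ycol].to_numpy(), sub[predictors], dependent=ycol
            )
            res = model.fit(bootstrap=B, seed=rng)
            fits[roi] = (res, len(dataset) - len(sub))
            model_ps[roi] = res.model_p
        adj, _ = bonferroni(list(model_ps.values()), m)
        for (roi, (res, n_dropped)), p_adj in zip(fits.items(), adj):
            for pred, prow in res.params.iterrows():
                rows.append(
                    {
                        "spec": spec_name,
                        "roi": roi,
                        "predictor": pred,
                        "beta_std": prow["beta_std"],
                        "p_boot": prow["p_boot"],
                        "ci_low": prow["ci_low"],
                        "ci_high": prow["ci_high"],
                        "tolerance": prow["tolerance"],
                        "vif": prow["vif"],
                        "vif_flagged": prow["vif_flagged"],
                        "F": res.f_statistic,
                        "model_p": res.model_p,
                        "model_p_bonf": p_adj,
                        "r_squared": res.r_squared,
                        "n": res.n,
                        "n_dropped": n_dropped,
                        "rank_transformed": ";".join(res.rank_transformed),
                    }
                )
    return pd.DataFrame(rows)


def d1_reduced_posthoc(
    dataset: pd.DataFrame,
    roi: str = "nucleus_accumbens_left",
    B: int = 1000,
    seed: int = 0,
) -> PERegressionResults:
    """Exploratory post-hoc model: D1 rs686 + rs4532 only (no BMI).

    Clearly exploratory — fitted only after the full D1 grouping, for a
    single accumbens ROI, and never part of the corrected family.
    """
    cols = [f"pe_{roi}", "code_rs686", "code_rs4532"]
    sub = dataset.dropna(subset=cols)
    model = PERegression(
        sub[f"pe_{roi}"].to_numpy(),
        sub[["code_rs686", "code_rs4532"]],
        dependent=f"pe_{roi}",
    )
    return model.fit(bootstrap=B, seed=seed)
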