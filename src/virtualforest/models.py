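"""Area-based lidar prediction models for BA, Dg and BA_b.

The area-based approach calibrates, per stratum, a regression of each
stand variable on lidar metrics measured over field plots, then applies
the model wall-to-wall on a 25 m raster. Three model forms are supported
for BA and Dg:

``linear``   y-hat = a0 + sum_i a_i x_i
``log``      all variables log-transformed; back-transformed predictions
             P = exp(a0) * prod_i x_i**a_i carry the lognormal bias
             correction factor exp(v/2), v being the residual variance on
             the log scale.
``boxcox``   the response is Box-Cox transformed, Y = (y**lambda - 1)/lambda,
             with lambda chosen by profile maximum likelihood; predictions
             invert the transform with a second-order bias correction
             P = (lambda*Yhat + 1)**(1/lambda)
                 * (1 + v/2 * (1 - lambda) / (lambda*Yhat + 1)**2).

The broadleaf proportion BA_b is bounded to [0, 1] and is fitted with a
binomial GLM (logit link) weighted by plot basal area, with stepwise AIC
metric selection; predictions are therefore guaranteed inside (0, 1).

Subset selection for BA/Dg maximises adjusted R-squared over all subsets
of at most ``max_vars`` metrics (exhaustive up to 12 candidates, greedy
forward selection beyond).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import FittingError, InvalidInputError

__all__ = [
    "PredictionModel",
    "StratifiedModelSet",
    "fit_linear_best_subset",
    "predict",
    "predict_linear",
    "predict_log",
    "predict_boxcox",
    "boxcox_lambda",
    "boxcox_transform",
    "fit_bab_glm",
    "fit_stratified",
    "map_predict",
    "loocv_rmse",
    "select_form",
]

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_CANDIDATES = 12


@dataclass
class PredictionModel:
    """A fitted estimator for one stand variable in one stratum."""

    variable: str  # "BA" | "Dg" | "BA_b"
    form: str  # "linear" | "log" | "boxcox" | "binomial-logit"
    selected_metrics: list[str]
    coefficients: np.ndarray  # a0..an (a0 = intercept)
    lam: float | None = None  # Box-Cox lambda
    resid_variance: float = 0.0  # v, on the transformed scale
    n_obs: int = 0
    adj_r2: float | None = None
    search: str = "exhaustive"

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "form": self.form,
            "selected_metrics": list(self.selected_metrics),
            "coefficients": [float(c) for c in np.asarray(self.coefficients)],
            "lambda": None if self.lam is None else float(self.lam),
            "resid_variance": float(self.resid_variance),
            "n_obs": int(self.n_obs),
            "adj_r2": None if self.adj_r2 is None else float(self.adj_r2),
            "search": self.search,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionModel":
        return cls(
            variable=d["variable"],
            form=d["form"],
            selected_metrics=list(d["selected_metrics"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            lam=d.get("lambda"),
            resid_variance=float(d.get("resid_variance", 0.0)),
            n_obs=int(d.get("n_obs", 0)),
            adj_r2=d.get("adj_r2"),
            search=d.get("search", "exhaustive"),
        )


POOLED_STRATUM = "__pooled__"


@dataclass
class StratifiedModelSet:
    """Per-stratum models for one variable, with a pooled fallback."""

    variable: str
    models: dict[str, PredictionModel] = field(default_factory=dict)
    fallback: PredictionModel | None = None
    merged_strata: list[str] = field(default_factory=list)

    def model_for(self, stratum: str) -> PredictionModel:
        if stratum in self.models:
            return self.models[stratum]
        if self.fallback is None:
            raise InvalidInputError(
                f"no model for stratum {stratum!r} and no pooled fallback"
            )
        return self.fallback

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "fallback": None if self.fallback is None else self.fallback.to_dict(),
            "merged_strata": list(self.merged_strata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StratifiedModelSet":
        return cls(
            variable=d["variable"],
            models={
                k: PredictionModel.from_dict(m) for k, m in d["models"].items()
            },
            fallback=(
                None
                if d.get("fallback") is None
                else PredictionModel.from_dict(d["fallback"])
            ),
            merged_strata=list(d.get("merged_strata", [])),
        )


# ---------------------------------------------------------------------------
# transforms


def boxcox_transform(y: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox transform Y = (y**lam - 1)/lam, natural log at lam = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise InvalidInputError("Box-Cox requires strictly positive values")
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_lambda(y: np.ndarray, interval: tuple[float, float] = (-2.0, 2.0)) -> float:
    """Profile-ML estimate of the Box-Cox lambda on ``interval``.

    Returns NaN for a (near-)constant sample, where the likelihood is flat.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise InvalidInputError("Box-Cox requires strictly positive values")
    if y.size < 10:
        raise InvalidInputError("need n >= 10 observations to estimate lambda")
    if np.ptp(y) == 0 or np.std(y) / np.mean(y) < 1e-12:
        return float("nan")
    lam = stats.boxcox_normmax(y, brack=interval, method="mle")
    return float(np.clip(lam, interval[0], interval[1]))


# ---------------------------------------------------------------------------
# fitting


def _adjusted_r2(y, X_cols, n, p):
    X = sm.add_constant(X_cols, has_constant="add")
    fit = sm.OLS(y, X).fit()
    return fit, float(fit.rsquared_adj)


def fit_linear_best_subset(
    X: pd.DataFrame,
    y: np.ndarray,
    variable: str = "y",
    max_vars: int = 6,
    transform: str = "none",
    lam: float | None = None,
) -> PredictionModel:
    """Best-subset linear regression by adjusted R-squared.

    ``transform`` is one of ``none``, ``log`` (all variables logged) or
    ``boxcox`` (response transformed; ``lam`` estimated by profile ML when
    not supplied). Exhaustive search over subsets of size <= ``max_vars``
    when at most 12 candidate metrics are offered, greedy forward selection
    otherwise; ties between equal subsets break by column order.
    """
    if transform not in {"none", "log", "boxcox"}:
        raise InvalidInputError(f"unknown transform {transform!r}")
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(X) != n:
        raise InvalidInputError("X and y lengths differ")
    if n <= max_vars + 1:
        raise FittingError(
            f"insufficient observations: n={n} for up to {max_vars} metrics"
        )

    if transform == "log":
        for col in X.columns:
            if np.any(X[col].to_numpy() <= 0):
                raise InvalidInputError(
                    f"log transform requires positive values; column {col!r} fails"
                )
        if np.any(y <= 0):
            raise InvalidInputError("log transform requires positive response")
        Xw = np.log(X.to_numpy(dtype=float))
        yw = np.log(y)
    elif transform == "boxcox":
        if lam is None:
            lam = boxcox_lambda(y)
        if not np.isfinite(lam):
            raise FittingError("Box-Cox lambda undefined (constant response)")
        Xw = X.to_numpy(dtype=float)
        yw = boxcox_transform(y, lam)
    else:
        Xw = X.to_numpy(dtype=float)
        yw = y

    cols = list(X.columns)
    k = len(cols)
    max_vars = min(max_vars, k, n - 2)

    best: tuple[float, tuple[int, ...]] | None = None

    def consider(subset: tuple[int, ...]):
        nonlocal best
        _, r2 = _adjusted_r2(yw, Xw[:, list(subset)], n, len(subset))
        # strict improvement only => earlier (column-ordered) subsets win ties
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, subset)

    if k <= MAX_EXHAUSTIVE_CANDIDATES:
        search = "exhaustive"
        for size in range(1, max_vars + 1):
            for subset in itertools.combinations(range(k), size):
                consider(subset)
    else:
        search = "greedy-forward"
        chosen: list[int] = []
        current = -np.inf
        while len(chosen) < max_vars:
            step_best = None
            for j in range(k):
                if j in chosen:
                    continue
                _, r2 = _adjusted_r2(yw, Xw[:, chosen + [j]], n, len(chosen) + 1)
                if step_best is None or r2 > step_best[0] + 1e-12:
                    step_best = (r2, j)
            if step_best is None or step_best[0] <= current + 1e-12:
                break
            current = step_best[0]
            chosen.append(step_best[1])
            best = (current, tuple(chosen))
        if best is None:  # no metric helps: intercept only
            best = (-np.inf, ())

    r2_best, subset = best
    sel = [cols[i] for i in subset]
    Xfit = sm.add_constant(Xw[:, list(subset)], has_constant="add")
    fit = sm.OLS(yw, Xfit).fit()
    p = len(subset)
    resid = fit.resid
    dof = n - p - 1
    v = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    return PredictionModel(
        variable=variable,
        form=transform if transform != "none" else "linear",
        selected_metrics=sel,
        coefficients=np.asarray(fit.params, dtype=float),
        lam=lam if transform == "boxcox" else None,
        resid_variance=v,
        n_obs=n,
        adj_r2=float(fit.rsquared_adj),
        search=search,
    )


def _design(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in model.selected_metrics if c not in X.columns]
    if missing:
        raise InvalidInputError(f"missing metric columns: {missing}")
    return X[model.selected_metrics].to_numpy(dtype=float)


def predict_linear(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    """y-hat = a0 + sum a_i x_i."""
    M = _design(model, X)
    a = np.asarray(model.coefficients, dtype=float)
    return a[0] + M @ a[1:]


def predict_log(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    """Back-transformed log-model prediction with lognormal bias correction.

    P = exp(a0) * prod_i x_i**a_i * exp(v/2); without the exp(v/2) factor
    the back-transform estimates the conditional median, not the mean.
    """
    M = _design(model, X)
    if np.any(M <= 0):
        raise InvalidInputError("log-form prediction requires positive metrics")
    a = np.asarray(model.coefficients, dtype=float)
    yhat_log = a[0] + np.log(M) @ a[1:]
    return np.exp(yhat_log) * np.exp(model.resid_variance / 2.0)


def predict_boxcox(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    """Inverse Box-Cox prediction with second-order bias correction.

    P = (lam*Yhat + 1)**(1/lam) * (1 + v/2 * (1-lam)/(lam*Yhat + 1)**2).
    At lam = 0 the log limit exp(Yhat) * (1 + v/2) applies. Cells where
    lam*Yhat + 1 <= 0 fall outside the transform's domain and are clamped
    to zero with a warning.
    """
    M = _design(model, X)
    a = np.asarray(model.coefficients, dtype=float)
    yhat = a[0] + M @ a[1:]
    lam = model.lam
    v = model.resid_variance
    if lam is None:
        raise InvalidInputError("model has no Box-Cox lambda")
    if lam == 0.0:
        return np.exp(yhat) * (1.0 + v / 2.0)
    base = lam * yhat + 1.0
    bad = base <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} prediction(s) outside the Box-Cox domain "
            "(lam*Yhat + 1 <= 0); clamped to 0",
            stacklevel=2,
        )
    base_safe = np.where(bad, np.nan, base)
    out = np.power(base_safe, 1.0 / lam) * (
        1.0 + v / 2.0 * (1.0 - lam) / base_safe**2
    )
    return np.where(bad, 0.0, out)


def predict(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    """Dispatch prediction on the model form (bias-corrected scales)."""
    if model.form == "linear":
        return predict_linear(model, X)
    if model.form == "log":
        return predict_log(model, X)
    if model.form == "boxcox":
        return predict_boxcox(model, X)
    if model.form == "binomial-logit":
        return predict_bab(model, X)
    raise InvalidInputError(f"unknown model form {model.form!r}")


# ---------------------------------------------------------------------------
# broadleaf proportion GLM


def _glm_fit(y, Xd, weights):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(
            y, Xd, family=sm.families.Binomial(), freq_weights=weights
        ).fit(maxiter=200)


def fit_bab_glm(
    X: pd.DataFrame,
    bab: np.ndarray,
    weights: np.ndarray | None = None,
    variable: str = "BA_b",
) -> PredictionModel:
    """Binomial logit GLM for the broadleaf proportion, stepwise-AIC selected.

    ``weights`` carry the binomial totals (plot basal area); selection runs
    both directions from the full metric set with the classic AIC (k = 2).
    Complete separation is caught and refitted with a small L2 penalty.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    bab = np.asarray(bab, dtype=float)
    if np.any((bab < 0) | (bab > 1)):
        raise InvalidInputError("BA_b values must lie in [0, 1]")
    if weights is None:
        weights = np.ones(len(bab))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise InvalidInputError("binomial weights must be positive")

    cols = list(X.columns)
    Xa = X.to_numpy(dtype=float)

    def fit_subset(subset: list[int]):
        Xd = sm.add_constant(Xa[:, subset], has_constant="add")
        try:
            res = _glm_fit(bab, Xd, weights)
            if not np.all(np.isfinite(res.params)) or np.any(
                np.abs(res.params) > 1e6
            ):
                raise FittingError("separation")
            return res, float(res.aic)
        except (Exception,):
            # penalized fallback for separation / non-convergence
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    bab, Xd, family=sm.families.Binomial(), freq_weights=weights
                ).fit_regularized(alpha=1e-4, L1_wt=0.0)
            k = Xd.shape[1]
            mu = np.clip(res.predict(Xd), 1e-9, 1 - 1e-9)
            ll = np.sum(
                weights * (bab * np.log(mu) + (1 - bab) * np.log(1 - mu))
            )
            return res, float(2 * k - 2 * ll)

    current = list(range(len(cols)))
    res, aic = fit_subset(current)
    improved = True
    while improved:
        improved = False
        candidates: list[tuple[float, list[int]]] = []
        for j in current:  # backward steps
            candidates.append((0.0, [i for i in current if i != j]))
        for j in range(len(cols)):  # forward steps
            if j not in current:
                candidates.append((0.0, sorted(current + [j])))
        for _, subset in candidates:
            r, a = fit_subset(subset)
            if a < aic - 1e-9:
                res, aic, current = r, a, subset
                improved = True
    return PredictionModel(
        variable=variable,
        form="binomial-logit",
        selected_metrics=[cols[i] for i in current],
        coefficients=np.asarray(res.params, dtype=float),
        resid_variance=0.0,
        n_obs=len(bab),
        search="stepwise-aic",
    )


def predict_bab(model: PredictionModel, X: pd.DataFrame) -> np.ndarray:
    """Inverse-logit prediction, guaranteed inside (0, 1)."""
    M = _design(model, X)
    a = np.asarray(model.coefficients, dtype=float)
    eta = np.clip(a[0] + M @ a[1:], -500.0, 500.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, 1e-12, 1.0 - 1e-12)  # strictly inside (0, 1)


# ---------------------------------------------------------------------------
# stratification, mapping, cross-validation


def _fit_one(variable, X, y, weights, transform, max_vars):
    if variable == "BA_b":
        return fit_bab_glm(X, y, weights=weights, variable=variable)
    return fit_linear_best_subset(
        X, y, variable=variable, max_vars=max_vars, transform=transform
    )


def fit_stratified(
    plot_table: pd.DataFrame,
    metric_cols: list[str],
    variable: str,
    stratum_col: str = "stratum",
    transform: str = "none",
    max_vars: int = 6,
    min_plots: int = 30,
    weights_col: str | None = None,
) -> StratifiedModelSet:
    """Fit one model per stratum; small strata merge into a pooled fallback.

    ``plot_table`` holds one row per plot with the metric columns, the
    response column named ``variable`` and a stratum label. Strata with
    fewer than ``min_plots`` observations are pooled together (and the
    pooled model also backs unknown strata at prediction time).
    """
    if variable == "BA_b" and weights_col is None and "BA" in plot_table.columns:
        weights_col = "BA"  # binomial totals: broadleaf share is BA-weighted
    out = StratifiedModelSet(variable=variable)
    groups = dict(tuple(plot_table.groupby(stratum_col, sort=True)))
    small = [s for s, g in groups.items() if len(g) < min_plots]
    big = [s for s in groups if s not in small]
    weights = None

    for s in big:
        g = groups[s]
        w = g[weights_col].to_numpy() if weights_col else None
        out.models[s] = _fit_one(
            variable, g[metric_cols], g[variable].to_numpy(), w, transform, max_vars
        )
    pool_frames = [groups[s] for s in small]
    if not big:
        logger.warning(
            "no stratum reaches %d plots for %s; single pooled model", min_plots, variable
        )
    if pool_frames or not big:
        pool = pd.concat(pool_frames) if pool_frames else plot_table
        if len(pool) < 3:
            pool = plot_table  # degenerate: pool everything
        w = pool[weights_col].to_numpy() if weights_col else None
        out.fallback = _fit_one(
            variable, pool[metric_cols], pool[variable].to_numpy(), w, transform, max_vars
        )
        out.merged_strata = small
    elif big:
        # fallback for unseen strata: refit on everything
        w = plot_table[weights_col].to_numpy() if weights_col else None
        out.fallback = _fit_one(
            variable,
            plot_table[metric_cols],
            plot_table[variable].to_numpy(),
            w,
            transform,
            max_vars,
        )
    return out


def map_predict(
    model_sets: dict[str, StratifiedModelSet],
    cell_metrics: pd.DataFrame,
    stratum_col: str = "stratum",
    forest_col: str | None = "forest",
    dg_floor: float = 7.5,
) -> pd.DataFrame:
    """Predict BA, Dg and BA_b for every forest cell of a metric table.

    Returns a frame indexed like ``cell_metrics`` with columns ``BA``,
    ``Dg``, ``BA_b``; non-forest cells carry NaN. Negative BA predictions
    are floored at 0 and Dg at ``dg_floor`` (the smallest measurable dbh),
    since downstream matching divides by Dg.
    """
    out = pd.DataFrame(
        index=cell_metrics.index, columns=["BA", "Dg", "BA_b"], dtype=float
    )
    forest = (
        cell_metrics[forest_col].astype(bool)
        if forest_col and forest_col in cell_metrics.columns
        else pd.Series(True, index=cell_metrics.index)
    )
    cells = cell_metrics.loc[forest]
    unknown = 0
    strata_key = (
        cells[stratum_col]
        if stratum_col in cells.columns
        else pd.Series("all", index=cells.index)
    )
    for stratum, g in cells.groupby(strata_key):
        for var, ms in model_sets.items():
            if stratum not in ms.models:
                unknown += 1
            model = ms.model_for(str(stratum))
            out.loc[g.index, var] = predict(model, g)
    if unknown:
        logger.warning("%d stratum/variable lookups used the pooled fallback", unknown)
    out.loc[forest, "BA"] = out.loc[forest, "BA"].clip(lower=0.0)
    out.loc[forest, "Dg"] = out.loc[forest, "Dg"].clip(lower=dg_floor)
    out.loc[forest, "BA_b"] = out.loc[forest, "BA_b"].clip(0.0, 1.0)
    return out


def loocv_rmse(
    plot_table: pd.DataFrame,
    metric_cols: list[str],
    variable: str,
    stratum_col: str = "stratum",
    transform: str = "none",
    max_vars: int = 6,
    min_plots: int = 30,
    weights_col: str | None = None,
) -> float:
    """Leave-one-out RMSE of the stratified model for one variable.

    Each plot is dropped in turn, the full stratified fit (same selection
    settings) is rerun, and the held-out plot is predicted. Folds whose
    refit fails are skipped and logged.
    """
    errs = []
    skipped = 0
    for i in range(len(plot_table)):
        train = plot_table.drop(plot_table.index[i])
        test = plot_table.iloc[[i]]
        try:
            ms = fit_stratified(
                train,
                metric_cols,
                variable,
                stratum_col=stratum_col,
                transform=transform,
                max_vars=max_vars,
                min_plots=min_plots,
                weights_col=weights_col,
            )
            model = ms.model_for(str(test[stratum_col].iloc[0]))
            pred = predict(model, test)[0]
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("LOOCV fold %d skipped: %s", i, exc)
            skipped += 1
            continue
        errs.append(float(test[variable].iloc[0]) - float(pred))
    if not errs:
        raise FittingError("all LOOCV folds failed")
    if skipped:
        logger.warning("LOOCV skipped %d folds", skipped)
    return float(np.sqrt(np.mean(np.square(errs))))


def select_form(
    plot_table: pd.DataFrame,
    metric_cols: list[str],
    variable: str,
    forms: tuple[str, ...] = ("none", "log", "boxcox"),
    **kwargs,
) -> tuple[str, dict[str, float]]:
    """Choose the transform with the lowest LOOCV RMSE (ties: simpler form).

    ``forms`` are ordered simplest first, so the first minimum wins.
    """
    scores: dict[str, float] = {}
    for form in forms:
        try:
            scores[form] = loocv_rmse(
                plot_table, metric_cols, variable, transform=form, **kwargs
            )
        except (InvalidInputError, FittingError) as exc:
            logger.info("form %s not applicable for %s: %s", form, variable, exc)
    if not scores:
        raise FittingError(f"no usable model form for {variable}")
    best = min(scores, key=lambda f: (round(scores[f], 12), forms.index(f)))
    return best, scores
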