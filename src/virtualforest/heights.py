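"""Species-specific asymptotic diameter-height mixed-effects model.

Tree height is predicted from the tree's diameter relative to its stand's
quadratic mean diameter (social status) and from the stand Dg itself
(development stage):

    h = 1.3 + (1 + a_site) * alpha_sp
            * (1 - exp(-alpha1 * Dg**alpha2))
            * (1 - exp(-beta_sp * dbh / Dg))**gamma   [+ residual]

``alpha_sp`` is the species asymptotic height (m), ``beta_sp`` the
species-specific speed of approach to the asymptote, ``alpha1``/``alpha2``
shape the stand-level Dg response, ``gamma`` the within-stand curvature,
and ``a_site`` a plot/site-level Gaussian random effect. Residual errors
are heteroscedastic, with standard deviation proportional to a power of
the fitted value (a varPower error model).

Fitting maximises the marginal Gaussian likelihood: the random effect
enters multiplicatively, so within-plot covariance is a rank-one update
of the diagonal residual variance and is inverted analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigurationError, FittingError, InvalidInputError
from .heights_params import PUBLISHED

__all__ = [
    "HeightModelParams",
    "predict_height",
    "load_published_params",
    "fit_height_model",
    "assign_heights",
    "OTHER_SPECIES",
]

OTHER_SPECIES = "OtherSp"


@dataclass
class HeightModelParams:
    """Parameter set of the diameter-height model for one study area."""

    alpha_sp: dict[str, float]
    beta_sp: dict[str, float]
    alpha1: float
    alpha2: float
    gamma: float
    variance_power: float = 0.0
    random_sd: float = 0.0
    resid_sd: float = 0.0
    site: str = "custom"
    borrowed_from: str | None = None
    converged: bool = True
    loglik: float | None = None

    def species_key(self, species: str) -> str:
        if species in self.alpha_sp:
            return species
        if OTHER_SPECIES in self.alpha_sp:
            return OTHER_SPECIES
        raise ConfigurationError(
            f"species {species!r} has no height parameters and no "
            f"{OTHER_SPECIES!r} fallback row"
        )

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "alpha_sp": dict(self.alpha_sp),
            "beta_sp": dict(self.beta_sp),
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "gamma": self.gamma,
            "variance_power": self.variance_power,
            "random_sd": self.random_sd,
            "resid_sd": self.resid_sd,
            "borrowed_from": self.borrowed_from,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeightModelParams":
        return cls(
            alpha_sp={k: float(v) for k, v in d["alpha_sp"].items()},
            beta_sp={k: float(v) for k, v in d["beta_sp"].items()},
            alpha1=float(d["alpha1"]),
            alpha2=float(d["alpha2"]),
            gamma=float(d["gamma"]),
            variance_power=float(d.get("variance_power", 0.0)),
            random_sd=float(d.get("random_sd", 0.0)),
            resid_sd=float(d.get("resid_sd", 0.0)),
            site=d.get("site", "custom"),
            borrowed_from=d.get("borrowed_from"),
        )


def load_published_params(site: str) -> HeightModelParams:
    """Load one of the shipped parameter sets: bauges, milicz or sneznik."""
    key = site.lower()
    if key not in PUBLISHED:
        raise ConfigurationError(
            f"unknown site {site!r}; available: {sorted(PUBLISHED)}"
        )
    return HeightModelParams.from_dict(PUBLISHED[key])


def predict_height(
    dbh,
    dg: float,
    species: str,
    params: HeightModelParams,
    site_effect: float = 0.0,
):
    """Predicted total height (m) for trees of one species in one stand.

    Vectorised over ``dbh``. Strictly increasing in dbh at fixed Dg;
    tends to breast height 1.3 m as dbh -> 0 and to
    ``1.3 + alpha_sp*(1 - exp(-alpha1*Dg**alpha2))`` as dbh -> infinity.
    """
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0) or dg <= 0:
        raise InvalidInputError("dbh and Dg must be > 0")
    key = params.species_key(species)
    a_sp = params.alpha_sp[key]
    b_sp = params.beta_sp[key]
    stand = 1.0 - np.exp(-params.alpha1 * dg**params.alpha2)
    social = (1.0 - np.exp(-b_sp * d / dg)) ** params.gamma
    h = 1.3 + (1.0 + site_effect) * a_sp * stand * social
    return float(h) if np.isscalar(dbh) else h


# ---------------------------------------------------------------------------
# fitting
#
# Two-stage estimation: (1) the fixed effects by bounded, iteratively
# reweighted nonlinear least squares — consistent because the random
# effect has zero mean — with the variance power re-estimated from the
# log-|residual| vs log-fitted slope between passes; (2) the variance
# components (random-effect sd, residual sd, variance power) by marginal
# ML with the fixed effects held at stage-1 values. Bounds keep the
# optimizer off the degenerate ridge alpha1 -> 0, alpha_sp -> infinity
# along which only the product alpha_sp * alpha1 is identified.

_BOUNDS = {
    "alpha_sp": (2.0, 150.0),  # asymptote (m); no tree is 150 m
    "alpha1": (1e-4, 1.0),
    "alpha2": (0.3, 3.0),
    "beta_sp": (0.05, 10.0),
    "gamma": (0.3, 5.0),
}


def _pack_fixed(params, free_species, fix):
    names, x0, lo, hi = [], [], [], []

    def add(kind, sp, value):
        names.append((kind, sp))
        x0.append(value)
        b = _BOUNDS[kind]
        lo.append(b[0])
        hi.append(b[1])

    if "alpha_sp" not in fix:
        for sp in free_species:
            add("alpha_sp", sp, params.alpha_sp[sp])
    if "alpha1" not in fix:
        add("alpha1", None, params.alpha1)
    if "alpha2" not in fix:
        add("alpha2", None, params.alpha2)
    if "beta_sp" not in fix:
        for sp in free_species:
            add("beta_sp", sp, params.beta_sp[sp])
    if "gamma" not in fix:
        add("gamma", None, params.gamma)
    return names, np.asarray(x0, float), (np.asarray(lo), np.asarray(hi))


def _apply_fixed(x, names, base: HeightModelParams) -> HeightModelParams:
    p = replace(base, alpha_sp=dict(base.alpha_sp), beta_sp=dict(base.beta_sp))
    for val, (kind, sp) in zip(x, names):
        if kind == "alpha_sp":
            p.alpha_sp[sp] = float(val)
        elif kind == "beta_sp":
            p.beta_sp[sp] = float(val)
        else:
            setattr(p, kind, float(val))
    return p


def _neg_loglik(params: HeightModelParams, groups) -> float:
    """Negative marginal log-likelihood over plots.

    Within a plot, cov = sigma_b^2 f f' + diag(sigma^2 mu^(2*theta)) with
    f the fixed-effect mean minus breast height; the rank-one structure is
    handled with the Sherman-Morrison identity.
    """
    sb2 = params.random_sd**2
    s2 = params.resid_sd**2
    theta = params.variance_power
    nll = 0.0
    for dbh, dg, sp_keys, h in groups:
        stand = 1.0 - np.exp(-params.alpha1 * dg**params.alpha2)
        a = np.array([params.alpha_sp[k] for k in sp_keys])
        b = np.array([params.beta_sp[k] for k in sp_keys])
        inner = 1.0 - np.exp(-b * dbh / dg)
        if np.any(inner <= 0):
            return 1e12
        f = a * stand * inner**params.gamma
        mu = 1.3 + f
        var = s2 * np.maximum(mu, 1e-6) ** (2.0 * theta)
        if np.any(~np.isfinite(var)) or np.any(var <= 0):
            return 1e12
        r = h - mu
        dinv_r = r / var
        dinv_f = f / var
        c = 1.0 + sb2 * float(f @ dinv_f)
        quad = float(r @ dinv_r) - sb2 * float(f @ dinv_r) ** 2 / c
        logdet = float(np.sum(np.log(var))) + np.log(c)
        nll += 0.5 * (logdet + quad + len(r) * np.log(2.0 * np.pi))
        if not np.isfinite(nll):
            return 1e12
    return nll


def fit_height_model(
    trees: pd.DataFrame,
    fixed_params: HeightModelParams | None = None,
    fix: tuple[str, ...] = (),
    min_obs_per_species: int = 100,
    maxiter: int = 2000,
) -> HeightModelParams:
    """Fit the diameter-height model by marginal maximum likelihood.

    ``trees`` needs columns ``plot_id, species, dbh, height`` (heights
    > 1.3 m); stand Dg is computed per plot from the listed trees unless a
    ``dg`` column is supplied. Species with fewer than
    ``min_obs_per_species`` height observations are pooled into
    ``OtherSp``. ``fixed_params``/``fix`` implement borrowed-parameter
    fitting: e.g. ``fix=("beta_sp", "gamma")`` holds those at the values
    in ``fixed_params`` and estimates only the remaining parameters (the
    scheme used when only dominant heights are available).
    """
    req = {"plot_id", "species", "dbh", "height"}
    if not req <= set(trees.columns):
        raise InvalidInputError(f"need columns {sorted(req)}")
    df = trees.dropna(subset=["height"]).copy()
    if np.any(df["height"] <= 1.3):
        raise InvalidInputError("heights must exceed breast height (1.3 m)")
    counts = df["species"].value_counts()
    pooled = set(counts[counts < min_obs_per_species].index)
    df["sp_key"] = [
        OTHER_SPECIES if s in pooled else s for s in df["species"]
    ]
    species = sorted(df["sp_key"].unique())
    if "dg" not in df.columns:
        dg_by_plot = df.groupby("plot_id")["dbh"].apply(
            lambda d: float(np.sqrt(np.mean(np.square(d))))
        )
        df["dg"] = df["plot_id"].map(dg_by_plot)

    # starting values: asymptote from the tallest tree per species
    start_alpha = {
        sp: max(float(df.loc[df.sp_key == sp, "height"].max()) - 1.3, 5.0)
        for sp in species
    }
    base = HeightModelParams(
        alpha_sp=dict(start_alpha),
        beta_sp={sp: 1.0 for sp in species},
        alpha1=0.016,
        alpha2=1.2,
        gamma=1.4,
        variance_power=0.3,
        random_sd=0.05,
        resid_sd=max(float(df["height"].std() / 4.0), 0.1),
        site="fitted",
    )
    if fixed_params is not None:
        for kind in fix:
            if kind == "alpha_sp":
                base.alpha_sp = {
                    sp: fixed_params.alpha_sp[fixed_params.species_key(sp)]
                    for sp in species
                }
            elif kind == "beta_sp":
                base.beta_sp = {
                    sp: fixed_params.beta_sp[fixed_params.species_key(sp)]
                    for sp in species
                }
            else:
                setattr(base, kind, getattr(fixed_params, kind))

    groups = [
        (
            g["dbh"].to_numpy(float),
            float(g["dg"].iloc[0]),
            list(g["sp_key"]),
            g["height"].to_numpy(float),
        )
        for _, g in df.groupby("plot_id")
    ]

    dbh_all = df["dbh"].to_numpy(float)
    dg_all = df["dg"].to_numpy(float)
    h_all = df["height"].to_numpy(float)
    sp_idx = {sp: np.flatnonzero(df["sp_key"].to_numpy() == sp) for sp in species}

    def mean_height(p: HeightModelParams) -> np.ndarray:
        a = np.empty(len(df))
        b = np.empty(len(df))
        for sp, idx in sp_idx.items():
            a[idx] = p.alpha_sp[sp]
            b[idx] = p.beta_sp[sp]
        stand = 1.0 - np.exp(-p.alpha1 * dg_all**p.alpha2)
        return 1.3 + a * stand * (1.0 - np.exp(-b * dbh_all / dg_all)) ** p.gamma

    # --- stage 1: fixed effects by IRLS nonlinear least squares
    names, x0, bounds = _pack_fixed(base, species, set(fix))
    if len(names) == 0:
        stage1 = base
    else:
        weights = np.ones(len(df))
        theta = base.variance_power
        stage1 = base
        # multi-start over the stand-response rate: alpha1 trades off
        # against alpha_sp along a near-flat ridge, so several basins exist
        a1_starts = [0.008, 0.016, 0.04] if "alpha1" not in set(fix) else [None]
        for _ in range(3):
            def resid(x):
                return (h_all - mean_height(_apply_fixed(x, names, base))) * weights

            sol = None
            for a1 in a1_starts:
                x_start = x0.copy()
                if a1 is not None:
                    for j, (kind, _) in enumerate(names):
                        if kind == "alpha1":
                            x_start[j] = a1
                s = optimize.least_squares(
                    resid, x_start, bounds=bounds, method="trf",
                    xtol=1e-10, ftol=1e-10, max_nfev=maxiter,
                )
                if sol is None or s.cost < sol.cost:
                    sol = s
            a1_starts = [None]  # later IRLS passes continue from the best fit
            stage1 = _apply_fixed(sol.x, names, base)
            x0 = sol.x
            mu = np.maximum(mean_height(stage1), 1.4)
            r = h_all - mean_height(stage1)
            # varPower: sd(resid) ~ mu**theta, slope of log|r| on log(mu)
            mask = np.abs(r) > 1e-10
            if mask.sum() > 10 and np.ptp(np.log(mu[mask])) > 1e-8:
                theta = float(
                    np.polyfit(np.log(mu[mask]), np.log(np.abs(r[mask])), 1)[0]
                )
                theta = float(np.clip(theta, -2.0, 2.0))
            weights = 1.0 / mu**theta
        if not sol.success and sol.status <= 0:
            raise FittingError(f"fixed-effect least squares failed: {sol.message}")
        stage1.variance_power = theta

    # --- stage 2: variance components by marginal ML
    r = h_all - mean_height(stage1)
    s_start = float(np.std(r)) or 1e-2

    def vc_objective(z):
        p = replace(
            stage1,
            random_sd=float(np.exp(z[0])),
            resid_sd=float(np.exp(z[1])),
            variance_power=float(z[2]),
        )
        return _neg_loglik(p, groups)

    z0 = np.array([np.log(0.05), np.log(s_start), stage1.variance_power])
    vres = optimize.minimize(
        vc_objective, z0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
    )
    if not np.isfinite(vres.fun) or vres.fun >= 1e12:
        raise FittingError(f"variance-component ML failed: {vres.message}")
    fitted = replace(
        stage1,
        alpha_sp=dict(stage1.alpha_sp),
        beta_sp=dict(stage1.beta_sp),
        random_sd=float(np.exp(vres.x[0])),
        resid_sd=float(np.exp(vres.x[1])),
        variance_power=float(vres.x[2]),
    )
    fitted.converged = bool(vres.success)
    fitted.loglik = -float(vres.fun)
    fitted.site = "fitted"
    if fixed_params is not None and fix:
        fitted.borrowed_from = fixed_params.site
    return fitted


def assign_heights(
    tree_table: pd.DataFrame,
    params: HeightModelParams,
    site_effect: float = 0.0,
) -> pd.DataFrame:
    """Assign deterministic heights to a generated tree table.

    Stand Dg is recomputed per cell from the generated list itself
    (counting a row with n stems n times), then every tree receives the
    population-level model prediction. Returns a copy with an ``h``
    column; empty input passes through unchanged.
    """
    out = tree_table.copy()
    if out.empty:
        out["h"] = pd.Series(dtype=float)
        return out
    grp = out.groupby("cellID25")
    dg_cell = grp.apply(
        lambda g: float(np.sqrt(np.sum(g.n * g.dbh**2) / np.sum(g.n))),
        include_groups=False,
    )
    heights = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        heights[i] = predict_height(
            row.dbh, float(dg_cell.loc[row.cellID25]), row.sp, params, site_effect
        )
    out["h"] = heights
    return out
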