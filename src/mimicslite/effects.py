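"""Mixed-effects effect sizes of litter mass loss and their relativization.

The statistical model regresses percent litter mass loss (both collection
timepoints pooled) on three standardized predictors — log soil moisture,
litter lignin:N, and the copiotroph:oligotroph ratio — with random
intercepts for site and for plot nested within site, fitted by restricted
maximum likelihood.  Fixed-effect coefficients are then relativized to
signed percentages summing to 100 in absolute value, the scale on which
empirical and modelled drivers are compared and calibrated.

For model-output tables, "plot" is each litter type x moisture-variant
combination, the moisture predictor is the temporally averaged moisture
scalar, and the copiotroph:oligotroph predictor is the steady-state
biomass ratio MICr:MICk.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTORS",
    "EffectSizeResult",
    "prepare_predictors",
    "fit_mass_loss_model",
    "relative_effect_sizes",
    "variance_inflation",
]

PREDICTORS = ("moisture", "lignin_n", "co_ratio")
_ZCOLS = ("z_moisture", "z_lignin_n", "z_co_ratio")


@dataclasses.dataclass
class EffectSizeResult:
    """Fixed effects, their relativized percentages, and diagnostics."""

    coefficients: pd.Series  # standardized fixed effects (excl. intercept)
    relative: pd.Series  # signed percentages, sum |.| = 100
    cov: pd.DataFrame
    vif: pd.Series
    random_structure: str  # "site+plot" or "site"
    converged: bool
    n_obs: int

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy import stats

        se = np.sqrt(np.diag(self.cov))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.coefficients - zcrit * se,
                "upper": self.coefficients + zcrit * se,
            },
            index=self.coefficients.index,
        )


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"predictor {name!r} has zero variance")
    return (x - x.mean()) / sd


def prepare_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """Log-transform moisture and standardize all three predictors.

    Requires columns ``moisture`` (> 0), ``lignin_n``, ``co_ratio``; adds
    ``z_moisture``, ``z_lignin_n``, ``z_co_ratio`` with mean 0, SD 1.
    """
    out = table.copy()
    moisture = out["moisture"].to_numpy(dtype=float)
    if np.any(moisture <= 0):
        raise ValueError("moisture must be positive to log transform")
    out["z_moisture"] = _standardize(np.log(moisture), "moisture")
    out["z_lignin_n"] = _standardize(out["lignin_n"].to_numpy(dtype=float), "lignin_n")
    out["z_co_ratio"] = _standardize(out["co_ratio"].to_numpy(dtype=float), "co_ratio")
    return out


def relative_effect_sizes(coefficients: pd.Series | np.ndarray) -> pd.Series:
    """Relativize coefficients to signed percentages of the summed absolute
    coefficients; the absolute values total 100."""
    coefs = pd.Series(coefficients, dtype=float)
    denom = coefs.abs().sum()
    if denom == 0:
        raise ValueError("all coefficients are zero; relativization undefined")
    return 100.0 * coefs / denom


def variance_inflation(design: pd.DataFrame, columns=_ZCOLS) -> pd.Series:
    """VIF per predictor: 1/(1-R^2) from regressing it on the others."""
    X = design.loc[:, list(columns)].to_numpy(dtype=float)
    if X.shape[0] < len(columns) + 1:
        raise ValueError("need more rows than predictors for VIFs")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) <= len(columns):
        raise ValueError("rank-deficient design; a predictor is redundant")
    out = {}
    for i, col in enumerate(columns):
        others = np.column_stack([np.ones(len(X)), np.delete(X, i, axis=1)])
        fit = sm.OLS(X[:, i], others).fit()
        r2 = min(fit.rsquared, 1 - 1e-12)
        out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def _fe_covariance(result, table: pd.DataFrame, structure: str) -> np.ndarray:
    """Fixed-effect covariance (X' V^-1 X)^-1 from the fitted variance
    components.

    The numerical Hessian that statsmodels inverts can be indefinite when a
    variance component sits at the boundary; the GLS form is well defined
    whenever the fixed-effect design has full rank.
    """
    X = np.asarray(result.model.exog, dtype=float)
    groups = table["site"].to_numpy()
    var_site = float(np.asarray(result.cov_re)[0, 0])
    var_plot = float(result.vcomp[0]) if structure == "site+plot" and len(result.vcomp) else 0.0
    scale = float(result.scale)

    info = np.zeros((X.shape[1], X.shape[1]))
    for g in pd.unique(groups):
        mask = groups == g
        Xg = X[mask]
        n_g = Xg.shape[0]
        V = var_site * np.ones((n_g, n_g)) + scale * np.eye(n_g)
        if var_plot > 0:
            Z = pd.get_dummies(table.loc[mask, "plot"]).to_numpy(dtype=float)
            V += var_plot * Z @ Z.T
        info += Xg.T @ np.linalg.solve(V, Xg)
    return np.linalg.inv(info)


def fit_mass_loss_model(
    table: pd.DataFrame,
    *,
    response: str = "mass_loss_pct",
    include_temperature: bool = False,
) -> EffectSizeResult:
    """Fit the mixed model of mass loss on the standardized predictors.

    ``table`` needs columns ``site``, ``plot``, the response, and either
    the raw predictors (``moisture``, ``lignin_n``, ``co_ratio``; they are
    prepared here) or pre-standardized ``z_*`` columns.  Random intercepts:
    site and plot-within-site; on a singular/failed fit the model falls
    back to a site-only random intercept with a logged warning.

    ``include_temperature`` adds standardized site soil temperature as a
    fourth fixed effect (a sensitivity variant, off by default).
    """
    if not set(_ZCOLS) <= set(table.columns):
        table = prepare_predictors(table)
    if table["site"].nunique() < 2:
        raise ValueError("need at least 2 sites")

    zcols = list(_ZCOLS)
    if include_temperature:
        table = table.copy()
        table["z_soil_t"] = _standardize(table["soil_t"].to_numpy(dtype=float), "soil_t")
        zcols.append("z_soil_t")

    formula = f"{response} ~ " + " + ".join(zcols)

    def _fit(vc_formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                formula,
                data=table,
                groups="site",
                re_formula="1",
                vc_formula=vc_formula,
            )
            # gradient-free first: the plot variance component is weakly
            # identified with two observations per plot and derivative-based
            # optimizers routinely stall on it
            return model.fit(reml=True, method=["powell", "lbfgs"], maxiter=2000)

    structure = "site+plot"
    try:
        result = _fit({"plot": "0 + C(plot)"})
        ok = bool(result.converged) and np.all(np.isfinite(np.asarray(result.fe_params)))
    except Exception:
        ok = False
    if not ok:
        logger.warning("plot-within-site fit singular or failed; falling back to site-only")
        structure = "site"
        result = _fit(None)

    fe = pd.Series(result.fe_params).reindex(["Intercept"] + zcols).drop("Intercept")
    cov_full = _fe_covariance(result, table, structure)
    cov = pd.DataFrame(cov_full[1:, 1:], index=zcols, columns=zcols)
    return EffectSizeResult(
        coefficients=fe,
        relative=relative_effect_sizes(fe),
        cov=cov,
        vif=variance_inflation(table, columns=zcols),
        random_structure=structure,
        converged=bool(result.converged),
        n_obs=len(table),
    )
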