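"""Driver identification: PRCC, negative-binomial GLM, random forests.

Three complementary analyses of the simulated outcome tables:

* partial rank correlation (PRCC) between each varied parameter and the
  strategy lifespan, controlling for all other parameters on ranks —
  a global, monotone measure of how strongly each parameter drives the
  evolution of resistance;
* a count regression of lifespan on the parameters.  A Poisson GLM is fit
  first purely as an over-dispersion diagnostic (Pearson dispersion), then
  a negative-binomial GLM provides the coefficient estimates, with a
  regression-spline basis on the dispersal rate, whose effect is markedly
  nonlinear;
* random-forest classification of the *operational* outcome (which
  strategy, if any, wins by >= 10%) from the input parameters, with
  permutation importance (mean decrease in held-out accuracy) ranking the
  parameters by their decision-making value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .design import classify_pairs, classify_triples

__all__ = ["prcc", "nb_glm", "RFConfig", "RF_CONFIGURATIONS", "RFResult",
           "rf_importance"]


def prcc(outcome: np.ndarray, inputs: pd.DataFrame) -> pd.DataFrame:
    """Partial rank correlation of each input column with the outcome.

    Ranks every column and the outcome, then for each parameter correlates
    the residuals of (parameter ~ all other parameters) with the residuals
    of (outcome ~ all other parameters).  Two-sided p-values use the
    t-distribution with ``n - 2 - k`` degrees of freedom, ``k`` the number
    of controlled parameters.
    """
    y = stats.rankdata(np.asarray(outcome, dtype=float))
    n = len(y)
    if n != len(inputs):
        raise ValueError("outcome and inputs must be aligned")
    ranks = {}
    for c in inputs.columns:
        col = inputs[c].to_numpy(dtype=float)
        if np.all(col == col[0]):
            raise ValueError(f"constant input column: {c}")
        ranks[c] = stats.rankdata(col)

    rows = []
    cols = list(inputs.columns)
    for c in cols:
        others = [ranks[o] for o in cols if o != c]
        X = np.column_stack([np.ones(n)] + others)
        res_x = ranks[c] - X @ np.linalg.lstsq(X, ranks[c], rcond=None)[0]
        res_y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r = float(np.corrcoef(res_x, res_y)[0, 1])
        df = n - 2 - len(others)
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), df)
        rows.append((c, r, float(p)))
    return pd.DataFrame(rows, columns=["parameter", "prcc", "p_value"])


def nb_glm(
    outcomes: pd.DataFrame,
    cap: int = 500,
    spline_df: int = 6,
) -> dict:
    """Negative-binomial regression of strategy lifespan on the parameters.

    ``outcomes`` is a long table with one row per simulation and columns
    ``lifespan, h2, x, m, C, psi, theta, strategy, z0, d``.  Runs that hit
    the generation cap are excluded (artificially terminated).  The
    Poisson Pearson dispersion is reported first; coefficients come from a
    maximum-likelihood negative-binomial fit with a B-spline basis (cubic,
    ``spline_df`` degrees of freedom, i.e. three internal knots by
    default) on the dispersal rate.
    """
    data = outcomes[outcomes["lifespan"] < cap].copy()
    if len(data) == 0:
        raise ValueError("no uncensored simulations to fit")
    # patsy reserves C() for categorical coding; rename the coverage column
    data = data.rename(columns={"C": "coverage"})
    data["z0"] = pd.Categorical(data["z0"])
    data["d"] = pd.Categorical(data["d"])
    formula = (
        f"lifespan ~ h2 + x + m + coverage + psi + bs(theta, df={spline_df}) "
        "+ C(strategy) + C(z0) + C(d)"
    )
    pois = smf.glm(formula, data=data, family=sm.families.Poisson()).fit()
    dispersion = float(pois.pearson_chi2 / pois.df_resid)
    nb = smf.negativebinomial(formula, data=data).fit(disp=False, maxiter=200)
    coef = pd.DataFrame(
        {
            "coef": nb.params,
            "std_err": nb.bse,
            "p_value": nb.pvalues,
        }
    )
    return {
        "poisson_dispersion": dispersion,
        "coefficients": coef,
        "nb_alpha": float(nb.params.get("alpha", np.nan)),
        "n": len(data),
    }


@dataclass(frozen=True)
class RFConfig:
    """One of the eight forest configurations: design x comparison x
    coverage filter."""

    design: str            # "equal" | "unique"
    comparison: str        # "pair" | "triple"
    coverage_min: Optional[float] = None

    @property
    def solo_pair(self) -> tuple[str, str]:
        """The two solo strategies compared in this design."""
        return ("sequence", "rotation") if self.design == "equal" \
            else ("sequence", "adaptive_rotation")

    @property
    def features(self) -> list[str]:
        if self.design == "equal":
            return ["h2", "x", "m", "psi", "C", "theta", "alpha", "z0", "d"]
        return ["h2_1", "h2_2", "psi_1", "psi_2", "z0_1", "z0_2",
                "alpha", "x", "m", "C", "theta"]


RF_CONFIGURATIONS: tuple[RFConfig, ...] = tuple(
    RFConfig(design, comparison, cmin)
    for cmin in (None, 0.5)
    for design, comparison in (
        ("equal", "pair"), ("unique", "pair"),
        ("equal", "triple"), ("unique", "triple"),
    )
)


@dataclass
class RFResult:
    accuracy: float
    majority_share: float
    importances: pd.DataFrame = field(repr=False)


def rf_importance(
    outcomes: pd.DataFrame,
    config: RFConfig,
    seed: int = 0,
    n_estimators: int = 500,
    n_repeats: int = 10,
) -> RFResult:
    """Forest classification of the operational outcome + permutation
    importance.

    Trains on a random 70% of rows and reports held-out accuracy on the
    remaining 30%; importance is the mean decrease in held-out accuracy
    when each feature is permuted, sorted descending.
    """
    data = outcomes
    if config.coverage_min is not None:
        data = data[data["C"] >= config.coverage_min]
    a, b = config.solo_pair
    if config.comparison == "pair":
        cls = classify_pairs(
            data[f"lifespan_{a}"].to_numpy(), data[f"lifespan_{b}"].to_numpy()
        )
        label = cls["operational"].map(
            {"a": f"{a}-operational-win", "b": f"{b}-operational-win",
             "draw": "no-operational-win"}
        ).to_numpy()
    else:
        cls = classify_triples(
            data[f"lifespan_{a}"].to_numpy(),
            data[f"lifespan_{b}"].to_numpy(),
            data["lifespan_mixture"].to_numpy(),
        )
        label = cls["operational"].to_numpy()

    X = data[config.features].astype(float)
    classes, counts = np.unique(label, return_counts=True)
    if len(classes) < 2:
        raise ValueError("operational outcome has a single class; nothing to learn")
    majority = counts.max() / counts.sum()

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, label, test_size=0.3, random_state=seed
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(X_tr, y_tr)
    accuracy = float(forest.score(X_te, y_te))
    perm = permutation_importance(
        forest, X_te, y_te, n_repeats=n_repeats, random_state=seed,
        scoring="accuracy", n_jobs=1,
    )
    imp = (
        pd.DataFrame(
            {
                "parameter": config.features,
                "mean_decrease_accuracy": perm.importances_mean,
                "std": perm.importances_std,
            }
        )
        .sort_values("mean_decrease_accuracy", ascending=False)
        .reset_index(drop=True)
    )
    return RFResult(accuracy=accuracy, majority_share=float(majority),
                    importances=imp)
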