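"""Linear mixed-effects layer: heart-rate and pacing-location effects on
per-circle conduction velocity and voltage amplitude.

The model, for each response, is

    response ~ heart_rate + group,   random intercept per animal

where ``group`` is the interaction of mapped chamber (or chamber-wall) with
rhythm/pacing-site, fitted by REML with no heart-rate-by-group interaction
(heart rate is assumed to act equally on every chamber). Conduction velocity
enters on the natural-log scale, so the heart-rate coefficient
back-transforms to a per-bpm multiplicative effect and group contrasts
back-transform to ratios; voltage amplitude is modelled additively in mV.

Group means are reported as estimated marginal means at a reference heart
rate (90 or 145 bpm), at the population level (random intercept at its mean,
zero). Paced-vs-NSR contrasts carry multiplicity-adjusted p-values: Tukey's
HSD for all-pairwise families, Sidak for the targeted paced-vs-NSR family,
with one chamber (or one wall) as the family.

Inference uses residual-degree-of-freedom t statistics; with thousands of
circles per fit this is indistinguishable from small-sample df corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RateEffect",
    "RateLocationModel",
    "fit_mixed_model",
    "rate_effect",
    "marginal_means",
    "contrasts_vs_nsr",
    "predict_rate",
]

_HR = "heart_rate_bpm"


@dataclass
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    response: str  # "log_cv" | "va"
    level: str = "chamber"  # "chamber" | "wall"
    reference_hr_bpm: float = 145.0


@dataclass
class RateEffect:
    """Back-transformed per-bpm heart-rate effect."""

    cv_multiplier_per_bpm: float | None = None
    cv_multiplier_se: float | None = None
    va_slope_mv_per_bpm: float | None = None
    va_slope_se: float | None = None


class RateLocationModel(BaseEstimator):
    """Mixed-effects model of per-circle CV or VA versus heart rate and
    mapping/pacing location.

    Parameters
    ----------
    response : "log_cv" or "va"
        Natural-log conduction velocity or voltage amplitude.
    level : "chamber" or "wall"
        Whether groups are whole chambers or chamber walls.
    reference_hr_bpm : float
        Default heart rate for marginal means and contrasts.

    Fitted attributes (trailing underscore) expose the REML coefficient
    vector ``coef_``, its covariance ``cov_``, the heart-rate coefficient
    ``hr_coef_``/``hr_se_``, the group labels ``groups_`` and the underlying
    statsmodels result ``result_``.
    """

    def __init__(
        self,
        response: str = "log_cv",
        level: str = "chamber",
        reference_hr_bpm: float = 145.0,
    ):
        self.response = response
        self.level = level
        self.reference_hr_bpm = reference_hr_bpm

    # -- fitting ----------------------------------------------------------

    def _group_labels(self, table: pd.DataFrame) -> pd.Series:
        rhythm_part = np.where(
            table["rhythm"] == "NSR", "NSR", "p" + table["pacing_site"].astype(str)
        )
        if self.level == "chamber":
            prefix = table["chamber"].astype(str)
        elif self.level == "wall":
            prefix = table["chamber"].astype(str) + "." + table["wall"].astype(str)
        else:
            raise ValueError(f"level {self.level!r} must be 'chamber' or 'wall'")
        return prefix + ":" + rhythm_part

    def fit(self, metrics: pd.DataFrame, y=None) -> "RateLocationModel":
        """Fit on a per-circle metrics table (excluded rows are dropped)."""
        if self.response not in ("log_cv", "va"):
            raise ValueError(f"response {self.response!r} must be 'log_cv' or 'va'")
        tab = metrics.loc[~metrics["excluded"]].copy()
        value = tab["cv_mps"] if self.response == "log_cv" else tab["va_mv"]
        tab = tab.loc[np.isfinite(value)]
        if self.response == "log_cv":
            tab = tab.loc[tab["cv_mps"] > 0]
            endog = np.log(tab["cv_mps"].to_numpy())
        else:
            endog = tab["va_mv"].to_numpy()

        tab["_group"] = self._group_labels(tab)
        counts = tab["_group"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValueError(
                "groups with fewer than 2 observations: " + ", ".join(thin.index)
            )
        if tab["animal_id"].nunique() < 2:
            raise ValueError("need at least 2 animals for a random intercept")
        if counts.size < 2:
            raise ValueError("need at least 2 groups")

        groups = sorted(counts.index)
        dummies = pd.get_dummies(tab["_group"], dtype=float)[groups]
        exog = pd.concat([dummies, tab[_HR].astype(float)], axis=1)
        model = sm.MixedLM(endog, exog, groups=tab["animal_id"].to_numpy())
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = model.fit(reml=True)
        for w in caught:
            if "converge" in str(w.message).lower():
                warnings.warn(f"mixed-model fit: {w.message}", stacklevel=2)

        k = len(exog.columns)
        animal_var = float(np.asarray(result.cov_re).ravel()[0])
        if animal_var <= 1e-8 * float(np.var(endog)):
            # with the variance component on the boundary the mixed model
            # degenerates to GLS with an identity weight, i.e. plain least
            # squares; refit there, where the covariance is well defined
            warnings.warn(
                "animal random-intercept variance estimated at the boundary "
                "(0); fixed effects refitted by ordinary least squares",
                stacklevel=2,
            )
            result = sm.OLS(endog, exog).fit()
            animal_var = 0.0
            coef = pd.Series(np.asarray(result.params), index=list(exog.columns))
            cov = np.asarray(result.cov_params())
        else:
            coef = pd.Series(np.asarray(result.fe_params), index=list(exog.columns))
            cov = np.asarray(result.cov_params())[:k, :k]

        self.result_ = result
        self.groups_ = groups
        self.fe_names_ = list(exog.columns)
        self.coef_ = coef
        self.cov_ = pd.DataFrame(cov, index=self.fe_names_, columns=self.fe_names_)
        self.hr_coef_ = float(self.coef_[_HR])
        self.hr_se_ = float(np.sqrt(self.cov_.loc[_HR, _HR]))
        self.n_obs_ = len(tab)
        self.df_resid_ = self.n_obs_ - k
        self.hr_range_ = (float(tab[_HR].min()), float(tab[_HR].max()))
        self.animal_var_ = animal_var
        return self

    # -- derived quantities ----------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")

    def rate_effect(self) -> RateEffect:
        """Per-bpm heart-rate effect on the original scale."""
        self._check_fitted()
        if self.response == "log_cv":
            mult = float(np.exp(self.hr_coef_))
            return RateEffect(
                cv_multiplier_per_bpm=mult, cv_multiplier_se=mult * self.hr_se_
            )
        return RateEffect(
            va_slope_mv_per_bpm=self.hr_coef_, va_slope_se=self.hr_se_
        )

    def _linear_estimate(self, weights: np.ndarray) -> tuple[float, float]:
        est = float(weights @ self.coef_.to_numpy())
        se = float(np.sqrt(weights @ self.cov_.to_numpy() @ weights))
        return est, se

    def marginal_means(self, at_hr: float | None = None) -> pd.DataFrame:
        """Population-level estimated marginal mean per group at ``at_hr``.

        CV estimates are back-transformed to m/s (delta-method SE); the 95%
        interval is computed on the model scale and then transformed.
        """
        self._check_fitted()
        at_hr = self.reference_hr_bpm if at_hr is None else float(at_hr)
        lo, hi = self.hr_range_
        span = hi - lo
        if not (lo - 0.2 * span <= at_hr <= hi + 0.2 * span):
            warnings.warn(
                f"marginal means requested at {at_hr} bpm, outside the observed "
                f"heart-rate range [{lo:.0f}, {hi:.0f}] by more than 20%",
                stacklevel=2,
            )
        tcrit = stats.t.ppf(0.975, self.df_resid_)
        rows = []
        for g in self.groups_:
            w = np.array([1.0 if name == g else 0.0 for name in self.fe_names_])
            w[self.fe_names_.index(_HR)] = at_hr
            est, se = self._linear_estimate(w)
            ci = (est - tcrit * se, est + tcrit * se)
            if self.response == "log_cv":
                rows.append(
                    {
                        "group": g,
                        "estimate": np.exp(est),
                        "se": np.exp(est) * se,
                        "ci_lo": np.exp(ci[0]),
                        "ci_hi": np.exp(ci[1]),
                    }
                )
            else:
                rows.append(
                    {"group": g, "estimate": est, "se": se, "ci_lo": ci[0], "ci_hi": ci[1]}
                )
        out = pd.DataFrame(rows)
        out.insert(0, "at_hr_bpm", at_hr)
        return out

    def contrasts_vs_nsr(
        self, at_hr: float | None = None, adjustment: str = "sidak"
    ) -> pd.DataFrame:
        """Each paced group versus the NSR group of the same chamber (or
        wall): CV as a back-transformed ratio, VA as a difference in mV.

        ``adjustment`` is "sidak" (targeted paced-vs-NSR comparisons) or
        "tukey" (all-pairwise HSD reference); the family is one chamber or
        one wall.
        """
        self._check_fitted()
        if adjustment not in ("sidak", "tukey"):
            raise ValueError("adjustment must be 'sidak' or 'tukey'")
        at_hr = self.reference_hr_bpm if at_hr is None else float(at_hr)
        tcrit = stats.t.ppf(0.975, self.df_resid_)

        families: dict[str, list[str]] = {}
        for g in self.groups_:
            families.setdefault(g.split(":")[0], []).append(g)

        rows = []
        for prefix, members in sorted(families.items()):
            nsr = f"{prefix}:NSR"
            paced = [g for g in members if g != nsr]
            if not paced:
                continue
            if nsr not in members:
                raise ValueError(f"no NSR reference group for {prefix}")
            m = len(paced)  # Sidak family size
            k = len(members)  # Tukey number of group means
            for g in paced:
                w = np.zeros(len(self.fe_names_))
                w[self.fe_names_.index(g)] = 1.0
                w[self.fe_names_.index(nsr)] = -1.0
                diff, se = self._linear_estimate(w)
                t = diff / se
                p = 2.0 * stats.t.sf(abs(t), self.df_resid_)
                if adjustment == "sidak":
                    p_adj = 1.0 - (1.0 - p) ** m
                else:
                    p_adj = float(
                        stats.studentized_range.sf(
                            abs(t) * np.sqrt(2.0), k, self.df_resid_
                        )
                    )
                ci = (diff - tcrit * se, diff + tcrit * se)
                row = {
                    "family": prefix,
                    "group": g,
                    "vs": nsr,
                    "at_hr_bpm": at_hr,
                    "p": p,
                    "p_adjusted": min(1.0, p_adj),
                    "adjustment": adjustment,
                }
                if self.response == "log_cv":
                    ratio = float(np.exp(diff))
                    row.update(
                        effect=ratio,
                        effect_type="ratio",
                        se=ratio * se,
                        ci_lo=float(np.exp(ci[0])),
                        ci_hi=float(np.exp(ci[1])),
                    )
                else:
                    row.update(
                        effect=diff, effect_type="difference_mv",
                        se=se, ci_lo=ci[0], ci_hi=ci[1],
                    )
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def fit_mixed_model(metrics: pd.DataFrame, spec: ModelSpec) -> RateLocationModel:
    """Fit ``spec.response ~ heart rate + group`` with a random animal
    intercept on the exclusion-filtered metrics table."""
    return RateLocationModel(
        response=spec.response,
        level=spec.level,
        reference_hr_bpm=spec.reference_hr_bpm,
    ).fit(metrics)


def rate_effect(fit: RateLocationModel) -> RateEffect:
    return fit.rate_effect()


def marginal_means(fit: RateLocationModel, at_hr: float) -> pd.DataFrame:
    return fit.marginal_means(at_hr)


def contrasts_vs_nsr(
    fit: RateLocationModel, at_hr: float, adjustment: str = "sidak"
) -> pd.DataFrame:
    return fit.contrasts_vs_nsr(at_hr, adjustment)


def predict_rate(
    intercept: float, effect: RateEffect, hr: float, response: str
) -> float:
    """Predict CV or VA at a heart rate from an intercept and a rate effect.

    CV follows ``intercept * multiplier**hr`` (the multiplicative rate law in
    its original parameterisation, intercept at 0 bpm); VA follows
    ``intercept + slope * hr``.
    """
    if hr < 0:
        raise ValueError("heart rate must be non-negative")
    if response == "log_cv" or response == "cv":
        return intercept * effect.cv_multiplier_per_bpm ** hr
    if response == "va":
        return intercept + effect.va_slope_mv_per_bpm * hr
    raise ValueError(f"unknown response {response!r}")
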