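"""Mixed-effects layer: rate-law prediction arithmetic, null and recovery
simulations, marginal means, contrasts and an independent lme4 cross-check."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from circlemap.models import (
    ModelSpec,
    RateEffect,
    RateLocationModel,
    fit_mixed_model,
    predict_rate,
)
from circlemap.synthetic import GeneratorParams, StudyProtocol, generate_study
from circlemap.metrics import AnalysisConfig, compute_map_metrics
from circlemap.covering import build_circles, sample_centers

from conftest import reduced_protocol, small_chamber_specs


# -- predict_rate -----------------------------------------------------------

def test_cv_prediction_is_exponential_in_heart_rate():
    eff = RateEffect(cv_multiplier_per_bpm=1.004)
    assert predict_rate(0.5, eff, 0.0, "cv") == pytest.approx(0.5)
    assert predict_rate(0.5, eff, 100.0, "cv") == pytest.approx(0.7453, abs=5e-4)


def test_va_prediction_is_linear_in_heart_rate():
    eff = RateEffect(va_slope_mv_per_bpm=-0.012)
    assert predict_rate(6.0, eff, 100.0, "va") == pytest.approx(4.8)


def test_unit_multiplier_means_no_rate_effect():
    eff = RateEffect(cv_multiplier_per_bpm=1.0)
    assert predict_rate(0.8, eff, 250.0, "cv") == pytest.approx(0.8)


# -- fitting ----------------------------------------------------------------

def _metrics_for(params, seed):
    maps = generate_study(
        reduced_protocol(), params, seed=seed, chamber_specs=small_chamber_specs()
    )
    cfg = AnalysisConfig()
    frames = []
    for i, m in enumerate(maps):
        centers = sample_centers(m, cfg.radius_mm, cfg.spacing_mm, seed=i)
        frames.append(compute_map_metrics(m, build_circles(m, centers), cfg))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def null_metrics():
    """Study generated with no rate effect, no pacing effect."""
    params = GeneratorParams(
        cv_rate_base=1.0,
        va_rate_slope_mv_per_bpm=0.0,
        pacing_cv_multipliers={(c, "RA"): 1.0 for c in ("RA", "LA", "RV", "LV")},
        pacing_va_offsets_mv={(c, "RA"): 0.0 for c in ("RA", "LA", "RV", "LV")},
    )
    return _metrics_for(params, seed=13)


def test_null_simulation_recovers_zero_rate_effect(null_metrics):
    cv = RateLocationModel("log_cv").fit(null_metrics)
    va = RateLocationModel("va").fit(null_metrics)
    assert abs(cv.hr_coef_) < 2 * cv.hr_se_
    assert abs(va.hr_coef_) < 2 * va.hr_se_


def test_null_simulation_contrast_ratios_near_one(null_metrics):
    fit = RateLocationModel("log_cv").fit(null_metrics)
    for _, row in fit.contrasts_vs_nsr(145.0, "sidak").iterrows():
        assert abs(row["effect"] - 1.0) < 3 * row["se"]
        assert row["p_adjusted"] >= row["p"] - 1e-12


def test_rate_and_pacing_recovery_on_reduced_study(small_study_metrics):
    """Generating parameters (x1.004/bpm CV, -0.012 mV/bpm VA, x0.75 RA->RA
    CV) are recovered by the mixed model within simulation error."""
    truth = GeneratorParams()
    cv = RateLocationModel("log_cv").fit(small_study_metrics)
    eff = cv.rate_effect()
    assert abs(eff.cv_multiplier_per_bpm - truth.cv_rate_base) < 3 * eff.cv_multiplier_se
    va = RateLocationModel("va").fit(small_study_metrics)
    eff_va = va.rate_effect()
    assert (
        abs(eff_va.va_slope_mv_per_bpm - truth.va_rate_slope_mv_per_bpm)
        < 3 * eff_va.va_slope_se
    )
    cc = cv.contrasts_vs_nsr(145.0, "sidak").set_index("group")
    row = cc.loc["RA:pRA"]
    assert abs(row["effect"] - 0.75) < 3 * row["se"]


def test_marginal_means_back_transform_consistency(small_study_metrics):
    fit = RateLocationModel("log_cv").fit(small_study_metrics)
    mm = fit.marginal_means(145.0).set_index("group")
    for g in fit.groups_:
        log_scale = fit.coef_[g] + fit.hr_coef_ * 145.0
        assert mm.loc[g, "estimate"] == pytest.approx(np.exp(log_scale), rel=1e-12)
        assert mm.loc[g, "ci_lo"] < mm.loc[g, "estimate"] < mm.loc[g, "ci_hi"]
        assert mm.loc[g, "estimate"] > 0


def test_constant_response_gives_constant_group_estimates():
    rng = np.random.default_rng(4)
    n = 240
    tab = pd.DataFrame(
        {
            "animal_id": rng.choice(["pig1", "pig2", "pig3"], n),
            "chamber": rng.choice(["RA", "LV"], n),
            "rhythm": "NSR",
            "pacing_site": "none",
            "wall": "anterior",
            "heart_rate_bpm": rng.choice([100.0, 140.0], n),
            "cv_mps": 1.0,
            # tiny balanced jitter: exactly constant data degenerates REML
            "va_mv": 5.0 + rng.normal(0, 1e-3, n),
            "excluded": False,
        }
    )
    fit = RateLocationModel("va").fit(tab)
    for at_hr in (90.0, 145.0):
        mm = fit.marginal_means(at_hr)
        assert np.allclose(mm["estimate"], 5.0, atol=1e-2)


def test_contrasts_require_an_nsr_reference():
    rng = np.random.default_rng(5)
    n = 80
    tab = pd.DataFrame(
        {
            "animal_id": rng.choice(["pig1", "pig2"], n),
            "chamber": "RA",
            "rhythm": "paced",
            "pacing_site": rng.choice(["RA", "LA"], n),
            "wall": "anterior",
            "heart_rate_bpm": rng.uniform(100, 160, n),
            "cv_mps": rng.lognormal(0, 0.2, n),
            "va_mv": rng.uniform(1, 5, n),
            "excluded": False,
        }
    )
    fit = RateLocationModel("log_cv").fit(tab)
    with pytest.raises(ValueError, match="NSR"):
        fit.contrasts_vs_nsr(145.0)


def test_thin_groups_and_single_animal_rejected(small_study_metrics):
    thin = small_study_metrics.copy()
    extra = thin.iloc[[0]].copy()
    extra["chamber"] = "RA"
    extra["rhythm"] = "paced"
    extra["pacing_site"] = "LV"
    with pytest.raises(ValueError, match="RA:pLV"):
        RateLocationModel("log_cv").fit(pd.concat([thin, extra], ignore_index=True))
    solo = small_study_metrics[small_study_metrics["animal_id"] == "pig1"]
    with pytest.raises(ValueError, match="2 animals"):
        RateLocationModel("log_cv").fit(solo)


def test_extrapolated_marginal_means_warn(small_study_metrics):
    fit = RateLocationModel("va").fit(small_study_metrics)
    with pytest.warns(UserWarning, match="outside the observed"):
        fit.marginal_means(300.0)


def test_fit_mixed_model_wrapper_matches_estimator(small_study_metrics):
    a = fit_mixed_model(small_study_metrics, ModelSpec("log_cv"))
    b = RateLocationModel("log_cv").fit(small_study_metrics)
    assert a.hr_coef_ == pytest.approx(b.hr_coef_, rel=1e-12)


def test_excluding_outliers_never_produces_nonpositive_cv(small_study_metrics):
    fit = RateLocationModel("log_cv").fit(small_study_metrics)
    assert (fit.marginal_means(145.0)["estimate"] > 0).all()


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_heart_rate_coefficient_matches_lme4(small_study_metrics, tmp_path):
    """Independent oracle: the same REML model fitted with R's lme4 yields
    the same heart-rate coefficient."""
    tab = small_study_metrics.loc[~small_study_metrics["excluded"]].copy()
    tab = tab[np.isfinite(tab["cv_mps"]) & (tab["cv_mps"] > 0)]
    tab["log_cv"] = np.log(tab["cv_mps"])
    tab["group"] = tab["chamber"] + ":" + np.where(
        tab["rhythm"] == "NSR", "NSR", "p" + tab["pacing_site"]
    )
    csv = tmp_path / "metrics.csv"
    tab.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "m <- lmer(log_cv ~ heart_rate_bpm + group + (1|animal_id), data=d, REML=TRUE)\n"
        "cat(sprintf('%.10f', fixef(m)['heart_rate_bpm']))\n"
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    lme4_coef = float(out.stdout.strip().split()[-1])
    fit = RateLocationModel("log_cv").fit(small_study_metrics)
    assert fit.hr_coef_ == pytest.approx(lme4_coef, abs=1e-6)
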