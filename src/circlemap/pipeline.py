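"""End-to-end orchestration: simulate -> cover -> metrics -> model -> paired
differences -> report.

``run_pipeline`` executes the stages in order from a single configuration,
writing every table as CSV plus a run manifest (config hash, package version,
seed, per-stage counts, table hashes) that suffices to reproduce the bundle
bit-for-bit. When a directory of user-supplied maps is given, the simulation
stage is skipped and the same analysis runs on those files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covering import build_circles, circles_to_frame, coverage_summary, sample_centers
from .maps import MapSurface, load_map, write_map
from .metrics import AnalysisConfig, compute_map_metrics
from .models import RateLocationModel
from .paired import match_circles, paired_summary, paired_values
from .synthetic import GeneratorParams, StudyProtocol, generate_study

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` drives all stochastic stages."""

    out_dir: Path
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    protocol: StudyProtocol = field(default_factory=StudyProtocol.default)
    at_hr_bpm: float = 145.0
    adjustment: str = "sidak"
    make_figures: bool = True
    write_maps: bool = False
    maps_dir: Path | None = None  # bypass simulation with user maps
    chamber_specs: dict | None = None  # geometry override (e.g. scaled-down tests)

    def config_digest(self) -> str:
        payload = {
            "seed": self.seed,
            "analysis": vars(self.analysis),
            "generator": {
                k: (sorted((list(kk), vv) for kk, vv in v.items()) if isinstance(v, dict) else v)
                for k, v in vars(self.generator).items()
            },
            "protocol": [vars(e) for e in self.protocol.entries],
            "at_hr_bpm": self.at_hr_bpm,
            "adjustment": self.adjustment,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class ResultsBundle:
    out_dir: Path
    maps: list[MapSurface]
    coverage: pd.DataFrame
    metrics: pd.DataFrame
    cv_model: RateLocationModel | None
    va_model: RateLocationModel | None
    estimates: pd.DataFrame
    contrasts: pd.DataFrame
    paired: pd.DataFrame
    paired_changes: pd.DataFrame
    manifest: dict


def _cover_seed(base_seed: int, animal_id: str, chamber: str) -> int:
    # circles of the same (animal, chamber) must land on the same centers
    # across that chamber's maps so paced/intrinsic circles pair exactly
    key = [base_seed, 0xC0] + [ord(c) for c in animal_id + chamber]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _table_digest(frames: dict[str, pd.DataFrame]) -> str:
    h = hashlib.sha256()
    for name in sorted(frames):
        h.update(name.encode())
        h.update(frames[name].to_csv(index=False, float_format="%.12g").encode())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run every stage and persist the bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # -- stage 1: maps ---------------------------------------------------
    if config.maps_dir is not None:
        paths = sorted(Path(config.maps_dir).glob("*.ply"))
        maps = [load_map(p) for p in paths]
        log.info("loaded %d maps from %s", len(maps), config.maps_dir)
    else:
        maps = generate_study(
            config.protocol, config.generator, seed=config.seed,
            chamber_specs=config.chamber_specs,
        )
        log.info("simulated %d maps", len(maps))
        if config.write_maps:
            map_dir = out / "maps"
            map_dir.mkdir(exist_ok=True)
            for i, m in enumerate(maps):
                write_map(m, map_dir / f"map{i:03d}.ply")
    counts["maps"] = len(maps)

    # -- stage 2+3: circles and metrics ----------------------------------
    cfg = config.analysis
    all_circles, cov_rows, metric_frames = [], [], []
    for i, m in enumerate(maps):
        centers = sample_centers(
            m, cfg.radius_mm, cfg.spacing_mm,
            seed=_cover_seed(config.seed, m.meta.animal_id, m.meta.chamber),
        )
        circles = build_circles(m, centers, cfg.radius_mm, cfg.min_points)
        all_circles.append(circles)
        if circles:
            s = coverage_summary(circles)
            cov_rows.append(
                {
                    "map_index": i,
                    "animal_id": m.meta.animal_id,
                    "chamber": m.meta.chamber,
                    "group": m.meta.group,
                    "n_circles": s.n_circles,
                    "mean_area_mm2": s.mean_area_mm2,
                    "mean_points_per_circle": s.mean_points_per_circle,
                    "resolution_points_per_mm2": s.resolution_points_per_mm2,
                }
            )
        mt = compute_map_metrics(m, circles, cfg)
        mt.insert(0, "map_index", i)
        metric_frames.append(mt)
    coverage = pd.DataFrame(cov_rows)
    metrics = (
        pd.concat(metric_frames, ignore_index=True)
        if metric_frames
        else pd.DataFrame()
    )
    counts["circles"] = int(metrics.shape[0]) if len(metrics) else 0
    if len(metrics):
        counts["excluded_by_reason"] = (
            metrics.loc[metrics["excluded"], "exclusion_reason"]
            .value_counts().to_dict()
        )
        log.info("metrics: %d circles, %s excluded", len(metrics),
                 int(metrics["excluded"].sum()))

    # -- stage 4: mixed models -------------------------------------------
    cv_model = va_model = None
    estimates = pd.DataFrame()
    contrasts = pd.DataFrame()
    if len(metrics) and metrics["group"].nunique() >= 2:
        est_frames, con_frames = [], []
        for response in ("log_cv", "va"):
            model = RateLocationModel(
                response=response, reference_hr_bpm=config.at_hr_bpm
            ).fit(metrics)
            mm = model.marginal_means(config.at_hr_bpm)
            mm.insert(0, "response", response)
            est_frames.append(mm)
            cc = model.contrasts_vs_nsr(config.at_hr_bpm, config.adjustment)
            cc.insert(0, "response", response)
            con_frames.append(cc)
            if response == "log_cv":
                cv_model = model
            else:
                va_model = model
        estimates = pd.concat(est_frames, ignore_index=True)
        contrasts = pd.concat(con_frames, ignore_index=True)
    counts["contrasts"] = len(contrasts)

    # -- stage 5: paired differences -------------------------------------
    paired_rows, change_rows = [], []
    by_key: dict[tuple, list[int]] = {}
    for i, m in enumerate(maps):
        by_key.setdefault((m.meta.animal_id, m.meta.chamber), []).append(i)
    for (animal, chamber), idxs in sorted(by_key.items()):
        nsr = [i for i in idxs if maps[i].meta.rhythm == "NSR"]
        paced = [i for i in idxs if maps[i].meta.rhythm == "paced"]
        if not nsr:
            continue
        ref = nsr[0]
        for pi in paced:
            matches = match_circles(all_circles[pi], all_circles[ref])
            for column, unit in (("cv_mps", "m/s"), ("va_mv", "mV")):
                pairs = paired_values(
                    matches, all_circles[pi], all_circles[ref],
                    metrics[metrics["map_index"] == pi],
                    metrics[metrics["map_index"] == ref],
                    column,
                )
                if not pairs:
                    continue
                s = paired_summary(pairs)
                paired_rows.append(
                    {
                        "animal_id": animal,
                        "chamber": chamber,
                        "pacing_site": maps[pi].meta.pacing_site,
                        "quantity": column,
                        "unit": unit,
                        "n_pairs": s.n_pairs,
                        "mean_abs_diff": s.mean_abs_diff,
                        "iqr_abs_diff": s.iqr_abs_diff,
                        "abs_diff_ratio": s.abs_diff_ratio,
                        "iqr_relative_change_pct": s.iqr_relative_change_pct,
                    }
                )
                for p, rc in zip(pairs, s.relative_changes_pct):
                    change_rows.append(
                        {
                            "animal_id": animal,
                            "chamber": chamber,
                            "pacing_site": maps[pi].meta.pacing_site,
                            "quantity": column,
                            "pace_circle_id": p.pace_circle_id,
                            "relative_change_pct": rc,
                        }
                    )
    paired = pd.DataFrame(paired_rows)
    paired_changes = pd.DataFrame(change_rows)
    counts["map_pairs"] = int(paired["quantity"].eq("cv_mps").sum()) if len(paired) else 0

    # -- persist ----------------------------------------------------------
    frames = {
        "coverage": coverage,
        "metrics": metrics,
        "estimates": estimates,
        "contrasts": contrasts,
        "paired_summaries": paired,
        "paired_relative_changes": paired_changes,
    }
    for name, frame in frames.items():
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.12g")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": config.config_digest(),
        "tables_sha256": _table_digest(frames),
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle = ResultsBundle(
        out_dir=out, maps=maps, coverage=coverage, metrics=metrics,
        cv_model=cv_model, va_model=va_model, estimates=estimates,
        contrasts=contrasts, paired=paired, paired_changes=paired_changes,
        manifest=manifest,
    )
    if config.make_figures:
        render_report(bundle)
    return bundle


def render_report(bundle: ResultsBundle) -> list[Path]:
    """Figures (estimate-with-CI panels, rate scatter, relative-change
    boxplots), their backing data CSVs, and a plain-text summary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = bundle.out_dir
    written: list[Path] = []

    # estimate panels: one panel per chamber, CV and VA separately
    for response, unit in (("log_cv", "m/s"), ("va", "mV")):
        est = bundle.estimates
        if not len(est):
            break
        est = est[est["response"] == response]
        chambers = sorted({g.split(":")[0] for g in est["group"]})
        fig, axes = plt.subplots(1, len(chambers), figsize=(3 * len(chambers), 3.2),
                                 sharey=False, squeeze=False)
        sig = bundle.contrasts
        sig = sig[(sig["response"] == response) & (sig["p_adjusted"] < 0.05)] if len(sig) else sig
        for ax, ch in zip(axes[0], chambers):
            sub = est[est["group"].str.startswith(ch + ":")]
            labels = [g.split(":")[1] for g in sub["group"]]
            x = np.arange(len(sub))
            ax.errorbar(
                x, sub["estimate"],
                yerr=[sub["estimate"] - sub["ci_lo"], sub["ci_hi"] - sub["estimate"]],
                fmt="o", capsize=3,
            )
            marked = set(sig[sig["family"] == ch]["group"]) if len(sig) else set()
            for xi, (g, e) in enumerate(zip(sub["group"], sub["ci_hi"])):
                if g in marked:
                    ax.annotate("*", (xi, e), ha="center", va="bottom", fontsize=14)
            ax.set_xticks(x, labels, rotation=45)
            ax.set_title(ch)
            ax.set_ylabel(f"{'CV' if response == 'log_cv' else 'VA'} ({unit})")
        fig.suptitle(f"Estimated marginal means at {est['at_hr_bpm'].iloc[0]:.0f} bpm")
        fig.tight_layout()
        p = out / f"estimates_{'cv' if response == 'log_cv' else 'va'}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        est.to_csv(p.with_suffix(".csv"), index=False, float_format="%.12g")
        written += [p, p.with_suffix(".csv")]

    # relative-change boxplots
    ch = bundle.paired_changes
    if len(ch):
        for quantity, tag in (("cv_mps", "cv"), ("va_mv", "va")):
            sub = ch[ch["quantity"] == quantity]
            if not len(sub):
                continue
            keys = sorted(sub.groupby(["chamber", "pacing_site"]).groups)
            data = [
                sub[(sub["chamber"] == c) & (sub["pacing_site"] == s)][
                    "relative_change_pct"
                ].to_numpy()
                for c, s in keys
            ]
            fig, ax = plt.subplots(figsize=(1.0 + 0.8 * len(keys), 3.5))
            ax.boxplot(data, tick_labels=[f"{c}\np{s}" for c, s in keys])
            ax.axhline(0, color="grey", lw=0.8)
            ax.set_ylabel("relative change (%)")
            ax.set_title(f"Local {tag.upper()} change vs intrinsic rhythm")
            fig.tight_layout()
            p = out / f"relative_change_{tag}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            sub.to_csv(p.with_suffix(".csv"), index=False, float_format="%.12g")
            written += [p, p.with_suffix(".csv")]

    # text summary
    lines = ["circlemap run summary", "====================="]
    if bundle.cv_model is not None:
        re_cv = bundle.cv_model.rate_effect()
        re_va = bundle.va_model.rate_effect()
        lines.append(
            f"CV heart-rate effect: x{re_cv.cv_multiplier_per_bpm:.4f} per bpm "
            f"(SE {re_cv.cv_multiplier_se:.4f})"
        )
        lines.append(
            f"VA heart-rate effect: {re_va.va_slope_mv_per_bpm:+.4f} mV per bpm "
            f"(SE {re_va.va_slope_se:.4f})"
        )
    sig = bundle.contrasts
    if len(sig):
        lines.append("significant paced-vs-NSR contrasts (adjusted p < 0.05):")
        for _, r in sig[sig["p_adjusted"] < 0.05].iterrows():
            eff = (
                f"x{r['effect']:.2f}" if r["effect_type"] == "ratio"
                else f"{r['effect']:+.2f} mV"
            )
            lines.append(
                f"  {r['response']:6s} {r['group']:12s} vs {r['vs']:8s} {eff} "
                f"(p_adj={r['p_adjusted']:.2g})"
            )
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
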