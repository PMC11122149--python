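"""Per-circle conduction velocity and voltage amplitude.

CV is the theoretical circle diameter divided by the first-to-last activation
interval inside the circle (mm/ms = m/s); VA is the arithmetic mean unipolar
amplitude over the circle's points. Circles with a degenerate (zero) interval
or a CV strictly above the physiological outlier bound (default 6 m/s) are
flagged and excluded from modelling tables, but retained with their reason
for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covering import Circle
from .maps import MapSurface

__all__ = ["AnalysisConfig", "circle_cv", "circle_va", "compute_map_metrics"]


@dataclass
class AnalysisConfig:
    """Knobs of the circle analysis.

    ``cv_outlier_mps`` is read as a strict bound: exactly 6 m/s is kept,
    anything exceeding it is disregarded. ``reference_hr_bpm`` is the heart
    rate at which model estimates are reported (90 or 145 bpm).
    """

    radius_mm: float = 5.0
    cv_outlier_mps: float = 6.0
    reference_hr_bpm: float = 145.0
    min_points: int = 10
    spacing_mm: float = 7.0

    def __post_init__(self) -> None:
        if self.cv_outlier_mps <= 0:
            raise ValueError("cv_outlier_mps must be > 0")
        if self.reference_hr_bpm not in (90.0, 145.0):
            raise ValueError("reference_hr_bpm must be 90 or 145")

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


def circle_cv(lat_values, diameter_mm: float = 10.0) -> float | None:
    """CV (m/s) from the LATs inside one circle: diameter / (last − first).

    mm per ms is numerically identical to m/s. Returns None when all
    activations are simultaneous (undefined CV).
    """
    lat = np.asarray(lat_values, dtype=float)
    lat = lat[np.isfinite(lat)]
    if len(lat) < 2:
        raise ValueError("circle_cv needs at least 2 finite LAT values")
    dt = float(lat.max() - lat.min())
    if dt == 0.0:
        return None
    return diameter_mm / dt


def circle_va(amplitudes) -> float:
    """Mean unipolar amplitude (mV) over a circle's points."""
    amp = np.asarray(amplitudes, dtype=float)
    amp = amp[np.isfinite(amp)]
    if len(amp) == 0:
        raise ValueError("circle_va needs at least 1 finite amplitude")
    return float(amp.mean())


def compute_map_metrics(
    surface: MapSurface,
    circles: list[Circle],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """One metrics row per circle, with exclusion flags applied.

    Exclusion reasons: ``too_few_points`` (< config.min_points members),
    ``zero_dt`` (simultaneous activation), ``outlier_cv`` (CV strictly above
    the outlier bound). Excluded rows stay in the table for audit; modelling
    selects ``~excluded``.
    """
    config = config or AnalysisConfig()
    meta = surface.meta
    rows = []
    for c in circles:
        lat = surface.lat_ms[c.member_vertices]
        amp = surface.amplitude_mv[c.member_vertices]
        cv: float | None = None
        excluded, reason = False, "none"
        if c.n_points < config.min_points:
            excluded, reason = True, "too_few_points"
        else:
            cv = circle_cv(lat, config.diameter_mm)
            if cv is None:
                excluded, reason = True, "zero_dt"
            elif cv > config.cv_outlier_mps:
                excluded, reason = True, "outlier_cv"
        rows.append(
            {
                "circle_id": c.circle_id,
                "animal_id": meta.animal_id,
                "chamber": meta.chamber,
                "rhythm": meta.rhythm,
                "pacing_site": meta.pacing_site,
                "heart_rate_bpm": meta.heart_rate_bpm,
                "group": meta.group,
                "wall": c.wall,
                "n_points": c.n_points,
                "cv_mps": np.nan if cv is None else cv,
                "va_mv": circle_va(amp) if np.isfinite(amp).any() else np.nan,
                "excluded": excluded,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)
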