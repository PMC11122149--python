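"""Shared fixtures: flat planar-wave patches, a small chamber map, and a
reduced synthetic study sized for fast model tests."""

from __future__ import annotations

import numpy as np
import pytest

from circlemap.maps import MapMeta
from circlemap.metrics import AnalysisConfig, compute_map_metrics
from circlemap.covering import build_circles, sample_centers
from circlemap.synthetic import (
    ChamberSpec,
    GeneratorParams,
    ProtocolEntry,
    SourceSpec,
    StudyProtocol,
    generate_study,
    make_chamber_mesh,
    make_flat_patch,
    simulate_activation,
)


@pytest.fixture(scope="session")
def flat_planar_map():
    """40x40 mm flat patch at study density, planar wave at 1.2 m/s along x,
    constant 2 mV amplitude."""
    patch = make_flat_patch(40.0, 40.0, density=1.3)
    speed = np.full(patch.n_vertices, 1.2)
    lat = simulate_activation(patch, SourceSpec("planar", direction=(1, 0, 0)), speed)
    return patch.with_fields(lat_ms=lat, amplitude_mv=np.full(patch.n_vertices, 2.0))


@pytest.fixture(scope="session")
def dense_planar_map():
    """High-density jittered flat patch where per-circle CV should recover the
    planar speed to within the discretisation tolerance."""
    patch = make_flat_patch(40.0, 40.0, density=25.0, jitter=0.1, seed=3)
    speed = np.full(patch.n_vertices, 1.2)
    lat = simulate_activation(patch, SourceSpec("planar", direction=(1, 0, 0)), speed)
    return patch.with_fields(lat_ms=lat, amplitude_mv=np.full(patch.n_vertices, 2.0))


def interior_centers(patch, centers, margin=5.2):
    """Centers at least ``margin`` from the rectangular patch border, where
    circles are not truncated by the fixture's edge (an artifact closed
    chamber surfaces do not have)."""
    lo = patch.vertices[:, :2].min(axis=0) + margin
    hi = patch.vertices[:, :2].max(axis=0) - margin
    keep = np.all((centers[:, :2] >= lo) & (centers[:, :2] <= hi), axis=1)
    return centers[keep]


@pytest.fixture(scope="session")
def chamber_map():
    """One small closed chamber surface with cutouts and wall labels."""
    spec = ChamberSpec("LV", (12.0, 12.0, 15.0), cutout_fraction=0.08)
    return make_chamber_mesh(spec, seed=11)


def small_chamber_specs():
    return {
        ch: ChamberSpec(ch, (11.0, 11.0, 13.0), cutout_fraction=0.05)
        for ch in ("RA", "LA", "RV", "LV")
    }


def reduced_protocol() -> StudyProtocol:
    """Two NSR and two RA-paced maps per chamber over 4 animals."""
    entries = []
    for ch in ("RA", "LA", "RV", "LV"):
        for i, hr in enumerate((100.0, 150.0)):
            entries.append(ProtocolEntry(f"pig{i + 1}", ch, "NSR", "none", "none", hr))
        for i, hr in enumerate((145.0, 120.0)):
            entries.append(ProtocolEntry(f"pig{i + 1}", ch, "paced", "RA", "endo", hr))
    return StudyProtocol(entries)


@pytest.fixture(scope="session")
def small_study_metrics():
    """Metrics table from a reduced 16-map study on small chambers."""
    maps = generate_study(
        reduced_protocol(), GeneratorParams(), seed=5, chamber_specs=small_chamber_specs()
    )
    cfg = AnalysisConfig()
    import pandas as pd

    frames = []
    for i, m in enumerate(maps):
        centers = sample_centers(m, cfg.radius_mm, cfg.spacing_mm, seed=i)
        circles = build_circles(m, centers, cfg.radius_mm, cfg.min_points)
        t = compute_map_metrics(m, circles, cfg)
        t.insert(0, "map_index", i)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
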