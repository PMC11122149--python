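"""Synthetic electroanatomic study generator.

Real high-density porcine chamber maps are not publicly deposited, so every
downstream stage of this package is exercised on synthetic maps that carry the
same statistical structure the analysis assumes:

* ellipsoidal chamber surfaces sampled at ~1.3 measurement points/mm²,
  with contiguous cutout patches and angular-sector wall labels;
* local activation times from a planar or focal wavefront propagating at a
  per-vertex speed field (graph shortest paths for the focal case);
* a multiplicative per-bpm heart-rate effect on conduction velocity
  (speed = chamber intercept x base^(HR - reference)), a linear per-bpm
  effect on unipolar voltage amplitude, chamber-specific pacing
  multipliers/offsets, per-animal random intercepts shared across an
  animal's maps, and smooth spatial noise fields;
* a 44-map study protocol over four animals: NSR and pacing from RA/LA/RV/LV
  across all four chambers at 86-171 bpm.

Everything is deterministic given a seed: the same (protocol, params, seed)
produces byte-identical map files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import cdist

from .maps import CHAMBERS, MapMeta, MapSurface

__all__ = [
    "ChamberSpec",
    "SourceSpec",
    "GeneratorParams",
    "ProtocolEntry",
    "StudyProtocol",
    "ellipsoid_area",
    "make_chamber_mesh",
    "make_flat_patch",
    "simulate_activation",
    "simulate_voltage",
    "generate_study",
    "default_chamber_specs",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

#: default angular wall layout: four azimuthal quadrants, plus a superior cap
#: (top of the chamber) for the atria only.
_SECTOR_WALLS = ("anterior", "lateral", "posterior", "septal")


@dataclass
class ChamberSpec:
    """Geometry recipe for one synthetic chamber surface."""

    chamber: str
    semi_axes_mm: tuple[float, float, float]
    target_point_density: float = 1.3  # points / mm^2
    cutout_fraction: float = 0.08
    superior_cap: bool | None = None  # default: atria only
    superior_cap_z: float = 0.62  # cap where z / c exceeds this

    def __post_init__(self) -> None:
        if self.chamber not in CHAMBERS:
            raise ValueError(f"chamber {self.chamber!r} not in {CHAMBERS}")
        if self.target_point_density <= 0:
            raise ValueError("target_point_density must be > 0")
        if not (0.0 <= self.cutout_fraction <= 0.3):
            raise ValueError("cutout_fraction must lie in [0, 0.3]")
        if self.superior_cap is None:
            self.superior_cap = self.chamber in ("RA", "LA")

    def scaled(self, factor: float) -> "ChamberSpec":
        a, b, c = self.semi_axes_mm
        return replace(self, semi_axes_mm=(a * factor, b * factor, c * factor))


def default_chamber_specs() -> dict[str, ChamberSpec]:
    """Chamber geometries sized so a map holds roughly 5.6k points at the
    default density, matching the scale of in-vivo high-density maps."""
    return {
        "RA": ChamberSpec("RA", (17.0, 17.0, 21.0)),
        "LA": ChamberSpec("LA", (16.0, 16.0, 20.0)),
        "RV": ChamberSpec("RV", (17.0, 18.0, 22.0)),
        "LV": ChamberSpec("LV", (17.5, 17.5, 22.0)),
    }


@dataclass
class SourceSpec:
    """Wavefront source: a planar wave along ``direction`` or a focal source
    at ``focus`` (a 3-D location snapped to the nearest non-cutout vertex)."""

    kind: str  # "planar" | "focal"
    direction: tuple[float, float, float] | None = None
    focus: tuple[float, float, float] | None = None
    base_speed_mps: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "focal"):
            raise ValueError(f"source kind {self.kind!r} must be planar or focal")
        if not (0.05 < self.base_speed_mps < 6.0):
            raise ValueError("base_speed_mps must lie in (0.05, 6) m/s")
        if self.kind == "planar" and self.direction is None:
            raise ValueError("planar source needs a direction")
        if self.kind == "focal" and self.focus is None:
            raise ValueError("focal source needs a focus location")


def _default_pacing_cv_multipliers() -> dict[tuple[str, str], float]:
    # (mapped chamber, pacing site) -> multiplicative CV effect vs NSR;
    # combinations reported as non-significant default to 1.0
    return {
        ("RA", "RA"): 0.75,
        ("RA", "LA"): 1.44,
        ("LA", "RA"): 0.62,
        ("RV", "RA"): 0.75,
        ("RV", "LA"): 1.0,
        ("RV", "LV"): 1.0,
        ("LV", "RA"): 0.49,
        ("LV", "RV"): 1.4,
        ("LV", "LV"): 1.0,
    }


def _default_pacing_va_offsets() -> dict[tuple[str, str], float]:
    # (mapped chamber, pacing site) -> additive VA effect in mV vs NSR
    return {
        ("RA", "RA"): 0.0,
        ("RA", "LA"): 0.0,
        ("LA", "RA"): 0.0,
        ("RV", "RA"): 1.21,
        ("RV", "LA"): 1.236,
        ("RV", "LV"): 2.55,
        ("LV", "RA"): -1.83,
        ("LV", "RV"): 0.0,
        ("LV", "LV"): 0.0,
    }


@dataclass
class GeneratorParams:
    """Statistical parameters of the synthetic study.

    Conduction-velocity fields follow
    ``speed = intercept(chamber) * cv_rate_base**(HR - reference_hr_bpm)
    * pacing multiplier * exp(animal effect) * exp(spatial noise)``
    so the chamber intercepts are interpretable at the reference heart rate;
    amplitude fields are additive:
    ``VA = intercept(chamber) + slope*(HR - reference) + pacing offset
    + animal effect + spatial noise + point jitter``, truncated at 0 mV.

    Spatial noise is a smooth Gaussian-bump random field with correlation
    length ``noise_corr_length_mm``, normalised per map to exactly zero mean
    and the stated standard deviation over vertices.
    """

    cv_rate_base: float = 1.004  # multiplicative CV effect per bpm
    va_rate_slope_mv_per_bpm: float = -0.012
    chamber_cv_intercepts: dict[str, float] = field(
        default_factory=lambda: {"RA": 0.85, "LA": 1.05, "RV": 0.75, "LV": 0.90}
    )
    chamber_va_intercepts: dict[str, float] = field(
        default_factory=lambda: {"RA": 3.0, "LA": 4.3, "RV": 9.0, "LV": 14.0}
    )
    pacing_cv_multipliers: dict[tuple[str, str], float] = field(
        default_factory=_default_pacing_cv_multipliers
    )
    pacing_va_offsets_mv: dict[tuple[str, str], float] = field(
        default_factory=_default_pacing_va_offsets
    )
    animal_sd_log_cv: float = 0.1
    animal_sd_va_mv: float = 0.5
    cv_noise_sd: float = 0.3  # sd of the log-speed field
    va_noise_sd: float = 1.5  # sd of the amplitude field, mV
    va_point_jitter_sd: float = 0.3  # iid per-point amplitude jitter, mV
    noise_corr_length_mm: float = 3.5
    reference_hr_bpm: float = 145.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.pacing_cv_multipliers.values()):
            raise ValueError("pacing CV multipliers must be > 0")
        if self.cv_rate_base <= 0:
            raise ValueError("cv_rate_base must be > 0")
        for name in (
            "animal_sd_log_cv",
            "animal_sd_va_mv",
            "cv_noise_sd",
            "va_noise_sd",
            "va_point_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ProtocolEntry:
    animal_id: str
    chamber: str
    rhythm: str
    pacing_site: str
    pacing_access: str
    heart_rate_bpm: float


# Mapping protocol of the emulated study: mean heart rate of every mapping
# procedure, by mapped chamber (rows) and rhythm / pacing site (cells);
# "epi"/"endo" mark the pacing access route.
_PROTOCOL_TABLE: dict[str, dict[str, list[str]]] = {
    "RA": {
        "NSR": ["115", "115", "120", "134", "130", "95", "145"],
        "RA": ["145epi", "145epi", "145epi", "120endo", "146endo"],
        "LA": ["145epi", "145epi", "145epi"],
    },
    "LA": {
        "NSR": ["86", "90", "145", "171"],
        "RA": ["145endo", "171endo"],
    },
    "RV": {
        "NSR": ["104", "95", "135", "150", "110", "132"],
        "RA": ["145endo", "145epi", "146endo"],
        "LA": ["145epi"],
        "LV": ["145endo", "170endo", "146endo"],
    },
    "LV": {
        "NSR": ["122", "130", "120", "86"],
        "RA": ["145epi", "145epi", "145epi"],
        "RV": ["145epi"],
        "LV": ["145epi", "145"],
    },
}

_ANIMALS = ("pig1", "pig2", "pig3", "pig4")


@dataclass
class StudyProtocol:
    """Ordered list of mapping procedures (one entry per map)."""

    entries: list[ProtocolEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def default(cls) -> "StudyProtocol":
        """The emulated 44-map protocol.

        The source protocol does not publish a map-to-animal assignment, so
        animals rotate round-robin within each (chamber, pacing) cell, which
        keeps pacing conditions balanced over animals and guarantees each
        paced map has a same-animal NSR partner in its chamber.
        """
        entries = []
        for chamber, cells in _PROTOCOL_TABLE.items():
            for site, specs in cells.items():
                for i, txt in enumerate(specs):
                    access = "none"
                    hr = txt
                    for acc in ("endo", "epi"):
                        if txt.endswith(acc):
                            access, hr = acc, txt[: -len(acc)]
                    rhythm = "NSR" if site == "NSR" else "paced"
                    entries.append(
                        ProtocolEntry(
                            animal_id=_ANIMALS[i % len(_ANIMALS)],
                            chamber=chamber,
                            rhythm=rhythm,
                            pacing_site="none" if rhythm == "NSR" else site,
                            pacing_access=access,
                            heart_rate_bpm=float(hr),
                        )
                    )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyProtocol":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([ProtocolEntry(**e) for e in raw])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump([e.__dict__ for e in self.entries], fh, sort_keys=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def ellipsoid_area(a: float, b: float, c: float) -> float:
    """Approximate ellipsoid surface area (Thomsen's formula, <1.1% error)."""
    p = 1.6075
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _uniform_ellipsoid_points(n: int, axes: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly by surface area on an ellipsoid.

    Directions are drawn uniformly on the unit sphere and accepted with
    probability proportional to the local area-element Jacobian of the
    sphere-to-ellipsoid map.
    """
    a, b, c = axes
    w_max = max(a * b, a * c, b * c)
    out = np.empty((0, 3))
    while len(out) < n:
        m = max(2 * (n - len(out)), 256)
        u = rng.standard_normal((m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        w = np.linalg.norm(u * np.array([b * c, a * c, a * b]), axis=1)
        keep = rng.random(m) < w / w_max
        out = np.vstack([out, u[keep] * np.array([a, b, c])])
    return out[:n]


def _vertex_adjacency(n: int, triangles: np.ndarray) -> csr_matrix:
    i = np.concatenate([triangles[:, 0], triangles[:, 1], triangles[:, 2]])
    j = np.concatenate([triangles[:, 1], triangles[:, 2], triangles[:, 0]])
    a = coo_matrix((np.ones(len(i), dtype=bool), (i, j)), shape=(n, n)).tocsr()
    return ((a + a.T) > 0).tocsr()


def _grow_patches(adj: csr_matrix, seeds: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Grow contiguous vertex patches by breadth-first rings until ``target``
    vertices are collected; returns a boolean mask."""
    n = adj.shape[0]
    mask = np.zeros(n, dtype=bool)
    frontier = list(seeds)
    mask[seeds] = True
    count = int(mask.sum())
    while count < target and frontier:
        nxt = []
        for v in frontier:
            for u in adj.indices[adj.indptr[v]: adj.indptr[v + 1]]:
                if not mask[u]:
                    mask[u] = True
                    nxt.append(u)
                    count += 1
                    if count >= target:
                        return mask
        frontier = nxt
    return mask


def _wall_labels(spec: ChamberSpec, vertices: np.ndarray) -> np.ndarray:
    a, b, c = spec.semi_axes_mm
    wall = np.empty(len(vertices), dtype="U10")
    theta = np.degrees(np.arctan2(vertices[:, 1] / b, vertices[:, 0] / a))
    sector = ((theta + 45.0) % 360.0 / 90.0).astype(int) % 4
    wall[:] = np.array(_SECTOR_WALLS)[sector]
    if spec.superior_cap:
        wall[vertices[:, 2] / c > spec.superior_cap_z] = "superior"
    return wall


def make_chamber_mesh(spec: ChamberSpec, seed: int) -> MapSurface:
    """Build a closed triangulated ellipsoidal chamber surface.

    Vertex count equals ``round(density * analytic area)``; wall labels are
    assigned by angular sector and cutout patches are carved as contiguous
    regions. The returned surface has unset (NaN) LAT/amplitude fields and a
    placeholder metadata record.
    """
    rng = np.random.default_rng(seed)
    area = ellipsoid_area(*spec.semi_axes_mm)
    n = int(round(spec.target_point_density * area))
    if n < 100:
        raise ValueError(
            f"target density {spec.target_point_density}/mm^2 on area {area:.0f} mm^2 "
            f"gives only {n} vertices (<100); mesh would be degenerate"
        )
    pts = _uniform_ellipsoid_points(n, spec.semi_axes_mm, rng)
    tris = ConvexHull(pts).simplices.astype(np.int32)

    cutout = np.zeros(n, dtype=bool)
    if spec.cutout_fraction > 0:
        adj = _vertex_adjacency(n, tris)
        n_patches = 3
        seeds = rng.choice(n, size=n_patches, replace=False)
        cutout = _grow_patches(adj, seeds, int(round(spec.cutout_fraction * n)), rng)

    lat = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    meta = MapMeta(
        animal_id="synthetic", chamber=spec.chamber, rhythm="NSR", heart_rate_bpm=120.0
    )
    return MapSurface(
        vertices=pts,
        triangles=tris,
        lat_ms=lat,
        amplitude_mv=amp,
        cutout=cutout,
        wall=_wall_labels(spec, pts),
        meta=meta,
    )


def make_flat_patch(
    width_mm: float,
    height_mm: float,
    density: float = 1.3,
    chamber: str = "LV",
    heart_rate_bpm: float = 120.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> MapSurface:
    """Flat rectangular test patch at an exact point density (regular grid,
    optional positional jitter), triangulated into two triangles per cell."""
    rng = np.random.default_rng(seed)
    s = 1.0 / math.sqrt(density)
    nx = max(2, int(round(width_mm / s)) + 1)
    ny = max(2, int(round(height_mm / s)) + 1)
    xs = np.arange(nx) * s
    ys = np.arange(ny) * s
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
    if jitter > 0:
        pts[:, :2] += rng.uniform(-jitter, jitter, size=(len(pts), 2))
    idx = np.arange(nx * ny).reshape(nx, ny)
    quads = np.stack(
        [idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()],
        axis=1,
    )
    tris = np.vstack([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]]).astype(np.int32)
    n = len(pts)
    meta = MapMeta(
        animal_id="fixture", chamber=chamber, rhythm="NSR", heart_rate_bpm=heart_rate_bpm
    )
    return MapSurface(
        vertices=pts,
        triangles=tris,
        lat_ms=np.full(n, np.nan),
        amplitude_mv=np.full(n, np.nan),
        cutout=np.zeros(n, dtype=bool),
        wall=np.full(n, "unassigned", dtype="U10"),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# wavefront / voltage simulation
# ---------------------------------------------------------------------------

def _two_ring_graph(surface: MapSurface, speed: np.ndarray) -> csr_matrix:
    """Sparse traversal-time graph over 1-ring plus 2-ring mesh neighbours.

    Pure edge-graph distances on a triangular mesh overestimate geodesics by
    up to ~15% in the worst direction; including second-ring neighbours
    brings the metric dilation below ~4%, adequate for wavefront simulation
    at mapping resolution. Edge traversal time is Euclidean length divided by
    the mean endpoint speed (mm / (mm/ms) = ms). Cutout vertices are removed
    from the graph.
    """
    n = surface.n_vertices
    adj = _vertex_adjacency(n, surface.triangles)
    two = ((adj @ adj) > 0).tocsr()
    full = ((adj + two) > 0).tolil()
    full.setdiag(False)
    full = full.tocoo()
    i, j = full.row, full.col
    ok = ~(surface.cutout[i] | surface.cutout[j])
    i, j = i[ok], j[ok]
    length = np.linalg.norm(surface.vertices[i] - surface.vertices[j], axis=1)
    mean_speed = 0.5 * (speed[i] + speed[j])
    t = length / mean_speed
    return coo_matrix((t, (i, j)), shape=(n, n)).tocsr()


def simulate_activation(
    surface: MapSurface, source: SourceSpec, speed_field: np.ndarray
) -> np.ndarray:
    """Per-vertex local activation times (ms) for a wavefront on the mesh.

    Planar waves activate along the projection onto the propagation
    direction at the local speed; focal waves propagate from the focus along
    the mesh as graph shortest paths in traversal time. Cutout vertices get
    NaN; times are offset so the earliest non-cutout activation is 0.
    """
    speed = np.asarray(speed_field, dtype=float)
    live = ~surface.cutout
    if not live.any():
        raise ValueError("map has no non-cutout vertices to activate")
    if np.any(speed[live] <= 0):
        raise ValueError("speed_field must be positive on non-cutout vertices")
    lat = np.full(surface.n_vertices, np.nan)

    if source.kind == "planar":
        d = np.asarray(source.direction, dtype=float)
        d = d / np.linalg.norm(d)
        proj = surface.vertices @ d
        lat[live] = proj[live] / speed[live]
    else:
        focus = np.asarray(source.focus, dtype=float)
        dist2 = np.sum((surface.vertices - focus) ** 2, axis=1)
        nearest = int(np.argmin(dist2))
        if surface.cutout[nearest]:
            raise ValueError("focal source lies on a cutout vertex")
        graph = _two_ring_graph(surface, speed)
        t = dijkstra(graph, directed=False, indices=nearest)
        lat[live] = t[live]

    lat[live] -= np.nanmin(lat[live])
    return lat


def _smooth_field(
    vertices: np.ndarray,
    sd: float,
    corr_length_mm: float,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth Gaussian-bump random field over mesh vertices, normalised to
    exactly zero mean and standard deviation ``sd`` over the analysed
    (``mask``) vertices.

    Pinning the per-map mean to zero confines the noise to sub-map spatial
    scales, so between-map variation comes only from the modelled effects;
    normalisation is over the non-cutout vertices because those are the only
    ones the downstream analysis sees.
    """
    n = len(vertices)
    if sd == 0 or n < 2:
        return np.zeros(n)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    extent = float(np.prod(np.maximum(hi - lo, corr_length_mm)))
    n_bumps = int(np.clip(extent ** (2 / 3) / (math.pi * corr_length_mm**2) * 4, 40, 800))
    centers = vertices[rng.choice(n, size=n_bumps, replace=True)]
    weights = rng.standard_normal(n_bumps)
    d2 = cdist(vertices, centers, "sqeuclidean")
    f = np.exp(-d2 / (2.0 * corr_length_mm**2)) @ weights
    f -= f[mask].mean()
    s = f[mask].std()
    if s == 0:
        return np.zeros(n)
    return f * (sd / s)


def _animal_rng(seed: int, animal_id: str) -> np.random.Generator:
    key = [seed, 0xA11] + [ord(ch) for ch in animal_id]
    return np.random.default_rng(np.random.SeedSequence(key))


def animal_effects(params: GeneratorParams, animal_id: str, seed: int | None = None) -> tuple[float, float]:
    """Per-animal random intercepts (log-CV, VA in mV), drawn once per animal
    and shared across all of that animal's maps."""
    rng = _animal_rng(params.seed if seed is None else seed, animal_id)
    return (
        float(rng.normal(0.0, params.animal_sd_log_cv)),
        float(rng.normal(0.0, params.animal_sd_va_mv)),
    )


def simulate_voltage(
    surface: MapSurface,
    params: GeneratorParams,
    meta: MapMeta,
    seed: int,
    animal_effect_mv: float | None = None,
) -> np.ndarray:
    """Per-vertex unipolar amplitude field (mV), truncated at 0.

    amplitude = chamber intercept + slope*(HR - reference) + pacing offset
    + animal intercept + smooth spatial field + iid jitter.
    """
    rng = np.random.default_rng(seed)
    if animal_effect_mv is None:
        _, animal_effect_mv = animal_effects(params, meta.animal_id)
    base = params.chamber_va_intercepts[meta.chamber]
    base += params.va_rate_slope_mv_per_bpm * (meta.heart_rate_bpm - params.reference_hr_bpm)
    if meta.rhythm == "paced":
        key = (meta.chamber, meta.pacing_site)
        if key not in params.pacing_va_offsets_mv:
            raise KeyError(f"no pacing VA offset configured for {key}")
        base += params.pacing_va_offsets_mv[key]
    amp = np.full(surface.n_vertices, base + animal_effect_mv)
    amp += _smooth_field(
        surface.vertices, params.va_noise_sd, params.noise_corr_length_mm, rng,
        mask=~surface.cutout,
    )
    if params.va_point_jitter_sd > 0:
        amp += rng.normal(0.0, params.va_point_jitter_sd, surface.n_vertices)
    amp = np.maximum(amp, 0.0)
    amp[surface.cutout] = np.nan
    return amp


# fixed per-chamber "sinus" source directions and generic pacing-site entry
# directions, in normalised ellipsoid coordinates (arbitrary but configurable
# through SourceSpec overrides)
_SINUS_DIRECTIONS = {
    "RA": (-0.5, 0.1, 0.85),  # high posterior
    "LA": (-0.4, -0.4, 0.8),
    "RV": (0.2, -0.5, 0.84),
    "LV": (0.0, -0.5, 0.87),
}
_PACING_DIRECTIONS = {
    "RA": (0.6, -0.5, 0.62),
    "LA": (-0.6, -0.5, 0.62),
    "RV": (0.6, -0.5, -0.62),
    "LV": (-0.6, -0.5, -0.62),
}


def _focus_point(surface: MapSurface, spec: ChamberSpec, direction: tuple[float, float, float]) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    target = d * np.asarray(spec.semi_axes_mm)
    live = np.flatnonzero(~surface.cutout)
    nearest = live[np.argmin(np.sum((surface.vertices[live] - target) ** 2, axis=1))]
    return surface.vertices[nearest]


def _map_speed_field(
    surface: MapSurface,
    params: GeneratorParams,
    meta: MapMeta,
    animal_log_cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    base = params.chamber_cv_intercepts[meta.chamber]
    base *= params.cv_rate_base ** (meta.heart_rate_bpm - params.reference_hr_bpm)
    if meta.rhythm == "paced":
        key = (meta.chamber, meta.pacing_site)
        if key not in params.pacing_cv_multipliers:
            raise KeyError(f"no pacing CV multiplier configured for {key}")
        base *= params.pacing_cv_multipliers[key]
    log_noise = _smooth_field(
        surface.vertices, params.cv_noise_sd, params.noise_corr_length_mm, rng,
        mask=~surface.cutout,
    )
    return base * math.exp(animal_log_cv) * np.exp(log_noise)


def generate_study(
    protocol: StudyProtocol,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    chamber_specs: dict[str, ChamberSpec] | None = None,
) -> list[MapSurface]:
    """Generate one fully field-populated map per protocol entry.

    The same (animal, chamber) always reuses the same mesh — the anatomy of
    a chamber does not change between that animal's mapping procedures —
    which is what makes paced/intrinsic circle pairing geometrically exact on
    synthetic data. NSR maps use a focal source at the chamber's sinus
    location, paced maps at the pacing-site entry location. Deterministic
    given (protocol, params, seed).
    """
    params = params or GeneratorParams()
    master = params.seed if seed is None else seed
    chamber_specs = chamber_specs or default_chamber_specs()

    mesh_cache: dict[tuple[str, str], tuple[MapSurface, ChamberSpec]] = {}
    maps: list[MapSurface] = []
    for idx, entry in enumerate(protocol.entries):
        meta = MapMeta(
            animal_id=entry.animal_id,
            chamber=entry.chamber,
            rhythm=entry.rhythm,
            pacing_site=entry.pacing_site,
            pacing_access=entry.pacing_access,
            heart_rate_bpm=entry.heart_rate_bpm,
        )
        key = (entry.animal_id, entry.chamber)
        if key not in mesh_cache:
            arng = _animal_rng(master, entry.animal_id)
            size_factor = float(arng.uniform(0.93, 1.07))
            spec = chamber_specs[entry.chamber].scaled(size_factor)
            mesh_seed = int(
                np.random.SeedSequence(
                    [master, 0x3E5, CHAMBERS.index(entry.chamber)]
                    + [ord(ch) for ch in entry.animal_id]
                ).generate_state(1)[0] % (2**31)
            )
            mesh_cache[key] = (make_chamber_mesh(spec, mesh_seed), spec)
        skeleton, spec = mesh_cache[key]

        animal_log_cv, animal_va = animal_effects(params, entry.animal_id, master)
        map_ss = np.random.SeedSequence([master, 0x4D, idx])
        cv_rng = np.random.default_rng(map_ss.spawn(1)[0])
        va_seed = int(map_ss.generate_state(2)[1] % (2**31))

        speed = _map_speed_field(skeleton, params, meta, animal_log_cv, cv_rng)
        if entry.rhythm == "NSR":
            direction = _SINUS_DIRECTIONS[entry.chamber]
        else:
            direction = _PACING_DIRECTIONS[entry.pacing_site]
        source = SourceSpec(
            kind="focal",
            focus=tuple(_focus_point(skeleton, spec, direction)),
            base_speed_mps=min(params.chamber_cv_intercepts[entry.chamber], 5.9),
        )
        lat = simulate_activation(skeleton, source, speed)
        amp = simulate_voltage(skeleton, params, meta, va_seed, animal_effect_mv=animal_va)
        maps.append(
            skeleton.with_fields(
                lat_ms=lat, amplitude_mv=amp, meta=meta,
                cutout=skeleton.cutout.copy(), wall=skeleton.wall.copy(),
                vertices=skeleton.vertices.copy(), triangles=skeleton.triangles.copy(),
            )
        )
    return maps
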