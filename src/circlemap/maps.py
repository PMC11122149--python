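"""Core data model for electroanatomic maps: in-memory containers, validation
and file I/O.

A map is a triangulated chamber surface with four per-vertex scalar fields:

* ``lat_ms`` — local activation time (ms), the arrival time of the
  depolarisation wavefront at each mapped point;
* ``amplitude_mv`` — unipolar electrogram amplitude (mV);
* ``cutout`` — boolean flag marking transitions to vessels or neighbouring
  chambers, excluded from all analysis;
* ``wall`` — anatomical wall label (anterior / posterior / lateral / septal /
  superior / unassigned).

Units are fixed by contract: coordinates in mm, time in ms, amplitude in mV.
Missing scalar values are stored as NaN and are legal only on cutout vertices.

On disk a map is a binary little-endian PLY file with per-vertex properties
named exactly ``lat_ms``, ``amplitude_mv``, ``cutout`` and ``wall_id``
(integer wall codes), plus a YAML sidecar carrying the acquisition metadata
(animal, chamber, rhythm, pacing site and access, mean heart rate). Standard
mesh viewers open the geometry; the sidecar keeps metadata editable as text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CHAMBERS",
    "WALL_LABELS",
    "MapMeta",
    "MapSurface",
    "MapFormatError",
    "MapValidationError",
    "load_map",
    "write_map",
    "validate_map",
]

CHAMBERS = ("RA", "LA", "RV", "LV")
RHYTHMS = ("NSR", "paced")
PACING_SITES = ("none", "RA", "LA", "RV", "LV")
PACING_ACCESS = ("none", "endo", "epi")

#: wall label <-> integer code used in the PLY ``wall_id`` property
WALL_LABELS = ("unassigned", "anterior", "posterior", "lateral", "septal", "superior")
_WALL_TO_ID = {w: i for i, w in enumerate(WALL_LABELS)}

_SCALAR_ARRAYS = ("lat_ms", "amplitude_mv", "cutout", "wall_id")


class MapFormatError(ValueError):
    """A map file does not conform to the on-disk contract."""


class MapValidationError(ValueError):
    """A map object violates the data-model invariants."""


@dataclass(frozen=True)
class MapMeta:
    """Acquisition metadata for one electroanatomic map.

    ``heart_rate_bpm`` is the mean heart rate during the mapping procedure;
    ``rhythm`` is ``"NSR"`` for intrinsic sinus rhythm, ``"paced"`` otherwise,
    in which case ``pacing_site`` names the stimulated chamber and
    ``pacing_access`` whether pacing was endo- or epicardial.
    """

    animal_id: str
    chamber: str
    rhythm: str
    pacing_site: str = "none"
    pacing_access: str = "none"
    heart_rate_bpm: float = float("nan")

    def __post_init__(self) -> None:
        problems = self.problems()
        if problems:
            raise MapValidationError("; ".join(problems))

    def problems(self) -> list[str]:
        out = []
        if self.chamber not in CHAMBERS:
            out.append(f"chamber {self.chamber!r} not in {CHAMBERS}")
        if self.rhythm not in RHYTHMS:
            out.append(f"rhythm {self.rhythm!r} not in {RHYTHMS}")
        if self.pacing_site not in PACING_SITES:
            out.append(f"pacing_site {self.pacing_site!r} not in {PACING_SITES}")
        if self.pacing_access not in PACING_ACCESS:
            out.append(f"pacing_access {self.pacing_access!r} not in {PACING_ACCESS}")
        if (self.rhythm == "NSR") != (self.pacing_site == "none"):
            out.append("rhythm=NSR if and only if pacing_site=none")
        hr = float(self.heart_rate_bpm)
        if not (30.0 <= hr <= 400.0):
            out.append(f"heart_rate_bpm {hr} outside the plausible 30-400 range")
        return out

    @property
    def group(self) -> str:
        """Modelling group label: chamber x rhythm/pacing-site, e.g. ``LV:pRA``."""
        if self.rhythm == "NSR":
            return f"{self.chamber}:NSR"
        return f"{self.chamber}:p{self.pacing_site}"

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "chamber": self.chamber,
            "rhythm": self.rhythm,
            "pacing_site": self.pacing_site,
            "pacing_access": self.pacing_access,
            "heart_rate_bpm": float(self.heart_rate_bpm),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MapMeta":
        return cls(
            animal_id=str(d["animal_id"]),
            chamber=d["chamber"],
            rhythm=d["rhythm"],
            pacing_site=d.get("pacing_site", "none"),
            pacing_access=d.get("pacing_access", "none"),
            heart_rate_bpm=float(d["heart_rate_bpm"]),
        )


@dataclass
class MapSurface:
    """Triangulated chamber surface with per-vertex electrical fields."""

    vertices: np.ndarray  # (n, 3) float64, mm
    triangles: np.ndarray  # (m, 3) int32, 0-based
    lat_ms: np.ndarray  # (n,) float64, NaN = missing (cutout only)
    amplitude_mv: np.ndarray  # (n,) float64, NaN = missing (cutout only)
    cutout: np.ndarray  # (n,) bool
    wall: np.ndarray  # (n,) unicode labels from WALL_LABELS
    meta: MapMeta

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int32)
        self.lat_ms = np.asarray(self.lat_ms, dtype=np.float64)
        self.amplitude_mv = np.asarray(self.amplitude_mv, dtype=np.float64)
        self.cutout = np.asarray(self.cutout, dtype=bool)
        self.wall = np.asarray(self.wall, dtype="U10")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def with_fields(self, **kwargs) -> "MapSurface":
        """Return a copy with the given attributes replaced."""
        return replace(self, **kwargs)

    def triangle_areas(self) -> np.ndarray:
        """Area (mm^2) of each mesh triangle."""
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )


def validate_map(surface: MapSurface) -> list[str]:
    """Check a :class:`MapSurface` against the data-model invariants.

    Returns a list of human-readable violations; an empty list means the map
    is valid. Never raises.
    """
    report: list[str] = []
    n = surface.n_vertices
    if surface.vertices.ndim != 2 or surface.vertices.shape[1] != 3:
        report.append("vertices must be an (n, 3) array")
        return report
    for name in ("lat_ms", "amplitude_mv", "cutout", "wall"):
        arr = getattr(surface, name)
        if arr.shape != (n,):
            report.append(f"field {name} has length {arr.shape}, expected ({n},)")
    if report:  # per-element checks need consistent lengths
        return report
    if surface.triangles.ndim != 2 or surface.triangles.shape[1] != 3:
        report.append("triangles must be an (m, 3) array")
        return report
    if len(surface.triangles) < 1:
        report.append("mesh has no triangles")
    if len(surface.triangles) and (
        surface.triangles.min() < 0 or surface.triangles.max() >= n
    ):
        bad = int(
            np.sum((surface.triangles < 0) | (surface.triangles >= n))
        )
        report.append(f"{bad} triangle vertex indices out of range [0, {n})")
    unknown = set(np.unique(surface.wall)) - set(WALL_LABELS)
    if unknown:
        report.append(f"unknown wall labels {sorted(unknown)}")
    non_cut = ~surface.cutout
    for name in ("lat_ms", "amplitude_mv"):
        missing = np.isnan(getattr(surface, name)) & non_cut
        if missing.any():
            report.append(
                f"{int(missing.sum())} non-cutout vertices with missing {name}"
            )
    if np.any(surface.amplitude_mv < 0):
        report.append("negative amplitude_mv values")
    report.extend(surface.meta.problems())
    return report


# ---------------------------------------------------------------------------
# PLY dialect I/O
#
# Binary little-endian PLY, one vertex element with double x/y/z, double
# lat_ms, double amplitude_mv, uchar cutout, uchar wall_id, and one face
# element with "property list uchar int vertex_indices". The writer is fully
# deterministic: writing the same map twice yields byte-identical files.
# ---------------------------------------------------------------------------

_VERTEX_DTYPE = np.dtype(
    [
        ("x", "<f8"),
        ("y", "<f8"),
        ("z", "<f8"),
        ("lat_ms", "<f8"),
        ("amplitude_mv", "<f8"),
        ("cutout", "u1"),
        ("wall_id", "u1"),
    ]
)
_FACE_DTYPE = np.dtype([("n", "u1"), ("i0", "<i4"), ("i1", "<i4"), ("i2", "<i4")])

_PLY_HEADER = """ply
format binary_little_endian 1.0
comment circlemap electroanatomic map
element vertex {nv}
property double x
property double y
property double z
property double lat_ms
property double amplitude_mv
property uchar cutout
property uchar wall_id
element face {nf}
property list uchar int vertex_indices
end_header
"""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_map(surface: MapSurface, path: str | Path) -> None:
    """Write a map as binary PLY plus a ``<name>.ply.yaml`` metadata sidecar.

    Lossless for all fields; two writes of the same map are byte-identical.
    """
    path = Path(path)
    problems = validate_map(surface)
    if problems:
        raise MapValidationError("refusing to write invalid map: " + "; ".join(problems))
    n = surface.n_vertices
    vert = np.empty(n, dtype=_VERTEX_DTYPE)
    vert["x"], vert["y"], vert["z"] = surface.vertices.T
    vert["lat_ms"] = surface.lat_ms
    vert["amplitude_mv"] = surface.amplitude_mv
    vert["cutout"] = surface.cutout.astype("u1")
    vert["wall_id"] = np.array([_WALL_TO_ID[w] for w in surface.wall], dtype="u1")
    face = np.empty(len(surface.triangles), dtype=_FACE_DTYPE)
    face["n"] = 3
    face["i0"], face["i1"], face["i2"] = surface.triangles.T.astype("<i4")

    header = _PLY_HEADER.format(nv=n, nf=len(surface.triangles))
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vert.tobytes())
        fh.write(face.tobytes())
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(surface.meta.to_dict(), fh, sort_keys=True)


def load_map(path: str | Path) -> MapSurface:
    """Load a map written by :func:`write_map`.

    Raises :class:`MapFormatError` naming any missing per-vertex array, and
    :class:`MapValidationError` if the loaded map breaks the invariants
    (all-cutout maps load with a warning instead).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header_lines = []
        while True:
            line = fh.readline()
            if not line:
                raise MapFormatError(f"{path}: truncated PLY header")
            header_lines.append(line.decode("ascii", "replace").strip())
            if header_lines[-1] == "end_header":
                break
        if header_lines[0] != "ply":
            raise MapFormatError(f"{path}: not a PLY file")
        if "format binary_little_endian 1.0" not in header_lines:
            raise MapFormatError(f"{path}: expected binary little-endian PLY")

        nv = nf = None
        props: list[str] = []
        current = None
        for ln in header_lines:
            parts = ln.split()
            if parts[0] == "element":
                current = parts[1]
                if current == "vertex":
                    nv = int(parts[2])
                elif current == "face":
                    nf = int(parts[2])
            elif parts[0] == "property" and current == "vertex":
                props.append(parts[-1])
        if nv is None or nf is None:
            raise MapFormatError(f"{path}: missing vertex or face element")
        for name in _SCALAR_ARRAYS:
            if name not in props:
                raise MapFormatError(f"{path}: missing per-vertex array {name!r}")
        expected = [name for name, *_ in _VERTEX_DTYPE.descr]
        if props != expected:
            raise MapFormatError(
                f"{path}: vertex properties {props} do not match the contract {expected}"
            )

        vert = np.frombuffer(fh.read(nv * _VERTEX_DTYPE.itemsize), dtype=_VERTEX_DTYPE)
        if len(vert) != nv:
            raise MapFormatError(f"{path}: truncated vertex data")
        face = np.frombuffer(fh.read(nf * _FACE_DTYPE.itemsize), dtype=_FACE_DTYPE)
        if len(face) != nf:
            raise MapFormatError(f"{path}: truncated face data")

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MapFormatError(f"{path}: metadata sidecar {sidecar.name} not found")
    with open(sidecar) as fh:
        meta = MapMeta.from_dict(yaml.safe_load(fh))

    wall_id = vert["wall_id"]
    if wall_id.max(initial=0) >= len(WALL_LABELS):
        raise MapFormatError(f"{path}: wall_id codes outside {list(range(len(WALL_LABELS)))}")
    surface = MapSurface(
        vertices=np.column_stack([vert["x"], vert["y"], vert["z"]]),
        triangles=np.column_stack([face["i0"], face["i1"], face["i2"]]),
        lat_ms=vert["lat_ms"].copy(),
        amplitude_mv=vert["amplitude_mv"].copy(),
        cutout=vert["cutout"].astype(bool),
        wall=np.array(WALL_LABELS, dtype="U10")[wall_id],
        meta=meta,
    )
    if surface.cutout.all():
        warnings.warn(f"{path}: every vertex is marked cutout", stacklevel=2)
    problems = validate_map(surface)
    if problems:
        raise MapValidationError(f"{path}: " + "; ".join(problems))
    return surface
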