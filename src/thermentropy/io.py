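"""Interchange I/O for radiometric thermal frames and ROI polygons.

A radiometric frame is a matrix of calibrated surface temperatures in
degrees Celsius.  Two plain interchange formats are supported:

* ``csv`` — comma-separated decimal °C, one image row per line, no header.
* ``tiff16`` — single-channel 16-bit TIFF of raw counts plus a JSON sidecar
  ``{"scale": s, "offset": o, "time_s": t, "phase": p}`` mapping counts to
  temperature via ``temp = raw * scale + offset``.

Every frame file may carry a JSON sidecar (``<stem>.json``) holding capture
time and test phase; for csv the sidecar is optional.

Regions of interest (forehead, chest, abdomen) are stored as polygons in a
JSON sidecar and rasterized to boolean masks with a pixel-center even-odd
containment rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ThermalFrame",
    "ROIMask",
    "PolygonROI",
    "PLAUSIBILITY_WINDOW",
    "ROI_LABELS",
    "read_frame",
    "write_frame",
    "rasterize_polygon",
    "read_polygons",
    "write_polygons",
    "ThermalIOError",
]

#: Default window of physically plausible skin/room temperatures (°C).
PLAUSIBILITY_WINDOW = (15.0, 45.0)

ROI_LABELS = ("forehead", "chest", "abdomen")

PHASES = ("rest", "exercise", "recovery")


class ThermalIOError(ValueError):
    """Raised for malformed or implausible thermal interchange files."""


@dataclass(frozen=True)
class ThermalFrame:
    """One radiometric capture: temperatures in °C with a timestamp.

    Parameters
    ----------
    temperatures
        2-D float array of surface temperatures (°C), rows × cols.
    time_s
        Seconds since the start of the exercise test.
    phase
        Test phase, one of ``rest``, ``exercise``, ``recovery``.
    """

    temperatures: np.ndarray
    time_s: float = 0.0
    phase: str = "exercise"
    plausibility: tuple[float, float] = PLAUSIBILITY_WINDOW

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.ndim != 2 or temps.shape[0] < 1 or temps.shape[1] < 1:
            raise ThermalIOError(
                f"frame must be a 2-D matrix with >=1 row and column, got shape {temps.shape}"
            )
        object.__setattr__(self, "temperatures", temps)
        if not np.all(np.isfinite(temps)):
            idx = tuple(int(v) for v in np.argwhere(~np.isfinite(temps))[0])
            raise ThermalIOError(f"non-finite temperature at pixel {idx}")
        lo, hi = self.plausibility
        bad = (temps < lo) | (temps > hi)
        if bad.any():
            idx = tuple(int(v) for v in np.argwhere(bad)[0])
            raise ThermalIOError(
                f"temperature {temps[idx]:.2f} °C at pixel {idx} outside "
                f"plausibility window [{lo}, {hi}] °C"
            )
        if self.time_s < 0:
            raise ThermalIOError(f"time_s must be >= 0, got {self.time_s}")
        if self.phase not in PHASES:
            raise ThermalIOError(f"phase must be one of {PHASES}, got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass(frozen=True)
class ROIMask:
    """Boolean pixel membership for one labeled body region."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise ThermalIOError(f"mask must be 2-D, got shape {mask.shape}")
        if not mask.any():
            raise ThermalIOError(f"ROI mask {self.label!r} has no true pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PolygonROI:
    """Stored polygon standing in for a manually outlined region.

    Vertices are ordered ``(row, col)`` pixel coordinates (0-based).
    """

    vertices: tuple[tuple[float, float], ...]
    label: str

    def __post_init__(self) -> None:
        verts = tuple((float(r), float(c)) for r, c in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ThermalIOError(f"polygon {self.label!r} needs >=3 vertices")


# ---------------------------------------------------------------------------
# frame I/O


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_frame(
    path: str | Path,
    fmt: str = "csv",
    plausibility: tuple[float, float] = PLAUSIBILITY_WINDOW,
) -> ThermalFrame:
    """Read one thermal frame from disk.

    For ``tiff16`` the JSON sidecar must supply ``scale`` and ``offset``
    mapping raw counts to °C.  Raises :class:`ThermalIOError` for missing
    files, ragged rows, non-numeric cells and implausible temperatures.
    """
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such frame file: {path}")
    meta = _read_sidecar(path)
    if fmt == "csv":
        temps = _parse_csv_matrix(path)
    elif fmt == "tiff16":
        if "scale" not in meta or "offset" not in meta:
            raise ThermalIOError(
                f"tiff16 frame {path} requires a JSON sidecar with 'scale' and 'offset'"
            )
        raw = tifffile.imread(path).astype(float)
        temps = raw * float(meta["scale"]) + float(meta["offset"])
    else:
        raise ThermalIOError(f"unknown frame format {fmt!r}")
    return ThermalFrame(
        temperatures=temps,
        time_s=float(meta.get("time_s", 0.0)),
        phase=str(meta.get("phase", "exercise")),
        plausibility=plausibility,
    )


def _parse_csv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            row = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ThermalIOError(
                        f"non-numeric cell {cell!r} at row {i}, column {j} in {path}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ThermalIOError(f"empty frame file: {path}")
    ncols = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != ncols:
            raise ThermalIOError(
                f"ragged row {i} in {path}: {len(row)} cells, expected {ncols}"
            )
    return np.asarray(rows, dtype=float)


def write_frame(
    frame: ThermalFrame,
    path: str | Path,
    fmt: str = "csv",
    scale: float = 0.01,
    offset: float = 0.0,
) -> Path:
    """Write a frame plus its JSON sidecar; returns the frame path.

    The tiff16 encoding quantizes temperatures to ``scale`` °C per count,
    so a write→read round trip differs by at most ``scale / 2`` per pixel.
    """
    path = Path(path)
    meta: dict = {"time_s": frame.time_s, "phase": frame.phase}
    if fmt == "csv":
        with open(path, "w") as fh:
            for row in frame.temperatures:
                fh.write(",".join(format(v, ".4f") for v in row) + "\n")
    elif fmt == "tiff16":
        raw = np.rint((frame.temperatures - offset) / scale)
        if raw.min() < 0 or raw.max() > 65535:
            raise ThermalIOError(
                f"tiff16 scale={scale}, offset={offset} cannot encode range "
                f"[{frame.temperatures.min():.2f}, {frame.temperatures.max():.2f}] °C"
            )
        tifffile.imwrite(path, raw.astype(np.uint16))
        meta.update({"scale": scale, "offset": offset})
    else:
        raise ThermalIOError(f"unknown frame format {fmt!r}")
    path.with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# polygon rasterization

_EDGE_EPS = 1e-9


def _on_segment(pr: float, pc: float, a, b) -> bool:
    (ar, ac), (br, bc) = a, b
    cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
    seg_len2 = (br - ar) ** 2 + (bc - ac) ** 2
    if seg_len2 == 0.0:
        return abs(pr - ar) < _EDGE_EPS and abs(pc - ac) < _EDGE_EPS
    if cross * cross > _EDGE_EPS * seg_len2:
        return False
    dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
    return -_EDGE_EPS <= dot <= seg_len2 + _EDGE_EPS


def point_in_polygon(pr: float, pc: float, vertices) -> bool:
    """Even-odd containment of a point, with points on an edge counted inside."""
    n = len(vertices)
    for i in range(n):
        if _on_segment(pr, pc, vertices[i], vertices[(i + 1) % n]):
            return True
    inside = False
    for i in range(n):
        ar, ac = vertices[i]
        br, bc = vertices[(i + 1) % n]
        # half-open crossing rule on the row coordinate
        if (ar > pr) != (br > pr):
            c_at = ac + (pr - ar) * (bc - ac) / (br - ar)
            if pc < c_at:
                inside = not inside
    return inside


def rasterize_polygon(poly: PolygonROI, shape: tuple[int, int]) -> ROIMask:
    """Rasterize a polygon ROI: a pixel is set iff its center (row, col)
    lies inside the polygon under the even-odd rule (edge centers included).
    """
    rows, cols = shape
    verts = poly.vertices
    if all(v == verts[0] for v in verts[1:]):
        raise ThermalIOError(f"polygon {poly.label!r} is degenerate (all vertices coincide)")
    rs = [v[0] for v in verts]
    cs = [v[1] for v in verts]
    r0 = max(0, int(np.floor(min(rs))))
    r1 = min(rows - 1, int(np.ceil(max(rs))))
    c0 = max(0, int(np.floor(min(cs))))
    c1 = min(cols - 1, int(np.ceil(max(cs))))
    mask = np.zeros(shape, dtype=bool)
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            mask[r, c] = point_in_polygon(float(r), float(c), verts)
    if not mask.any():
        raise ThermalIOError(
            f"polygon {poly.label!r} rasterizes to an empty mask on shape {shape}"
        )
    return ROIMask(mask=mask, label=poly.label)


def write_polygons(polys: list[PolygonROI], path: str | Path) -> Path:
    path = Path(path)
    payload = [{"label": p.label, "vertices": [list(v) for v in p.vertices]} for p in polys]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_polygons(path: str | Path) -> list[PolygonROI]:
    path = Path(path)
    if not path.exists():
        raise ThermalIOError(f"no such ROI file: {path}")
    payload = json.loads(path.read_text())
    return [
        PolygonROI(vertices=tuple((v[0], v[1]) for v in item["vertices"]), label=item["label"])
        for item in payload
    ]
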