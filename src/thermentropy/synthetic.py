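"""Synthetic exercise-thermography sessions.

Generates multi-subject thermogram time series and pulmonary-ventilation
(VE) curves carrying the statistical signature observed on the torso
during graded cycling to exhaustion:

* the ROI *mean* temperature stays flat over the test,
* the *texture entropy* of the chest rises monotonically as a warm,
  tree-shaped (perforator-vessel-like) pattern grows on the skin,
* VE rises piecewise-linearly with two breakpoints (the aerobic threshold
  VT1 and the respiratory-compensation point VT2).

The mechanism is phenomenological, not a perfusion model: an additive
branching warm field is ramped up over the exercise and a spatially
uniform compensation offset is subtracted within each ROI so the ROI's
noise-free mean is time-invariant by construction.  Each ROI also carries
a static smooth baseline texture whose amplitude sets the resting entropy.

Frames are 160 × 120 (thermal-camera resolution), captured every 30 s
during exercise (~10 min to exhaustion) and every 60 s during a 5-min
recovery; noise of 0.05 °C sd reflects a 100 mK camera sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import (
    PolygonROI,
    ROIMask,
    ThermalFrame,
    rasterize_polygon,
    write_frame,
    write_polygons,
)

__all__ = [
    "SubjectConfig",
    "BranchSegment",
    "BranchingPattern",
    "SubjectSession",
    "default_roi_polygons",
    "generate_branching_pattern",
    "pattern_field",
    "render_frame",
    "generate_ve_curve",
    "generate_subject",
    "generate_cohort",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class SubjectConfig:
    """All knobs of one synthetic subject.

    Baseline texture sds are set so resting quantized entropy (0.1 °C
    bins) lands near typical resting values for each region: for a
    Gaussian temperature field, H ≈ log2(sd/0.1 °C) + 2.05 bits.
    """

    seed: int = 0
    frame_shape: tuple[int, int] = (120, 160)
    exercise_duration_s: float = 600.0
    capture_interval_exercise_s: float = 30.0
    capture_interval_recovery_s: float = 60.0
    recovery_duration_s: float = 300.0
    # regional baselines, °C
    baseline_temp: dict = field(
        default_factory=lambda: {"forehead": 34.0, "chest": 33.0, "abdomen": 32.5}
    )
    # static smooth heterogeneity per region, °C sd (renormalized per ROI)
    texture_sd: dict = field(
        default_factory=lambda: {"forehead": 0.333, "chest": 0.590, "abdomen": 0.369}
    )
    texture_smooth_px: float = 2.0
    pixel_noise_sd: float = 0.05
    # hyperthermal branching pattern (sized to the chest ROI at 160 × 120)
    delta_t_max: float = 1.5
    branch_depth: int = 6
    branch_count: int = 3
    trunk_length_px: float = 12.0
    trunk_width_px: float = 4.0
    branch_angle_deg: float = 50.0
    angle_jitter_deg: float = 18.0
    length_decay: float = 0.78
    width_decay: float = 0.92
    dt_decay: float = 0.97
    # ventilation curve
    ve_rest_lpm: float = 12.0
    ve_slopes_lpm_per_min: tuple[float, float, float] = (6.0, 12.0, 24.0)
    breakpoint_fractions: tuple[float, float] = (0.45, 0.80)
    ve_noise_sd: float = 2.0
    # between-subject spread of texture amplitude, in bits of resting
    # entropy (cohort-level; applied as 2**N(0, sd) multipliers)
    intersubject_sd_bits: dict = field(
        default_factory=lambda: {"forehead": 0.56, "chest": 0.35, "abdomen": 0.45}
    )

    def __post_init__(self) -> None:
        f1, f2 = self.breakpoint_fractions
        if not (0.0 < f1 < f2 < 1.0):
            raise ValueError(f"breakpoint fractions must satisfy 0 < f1 < f2 < 1, got {f1}, {f2}")
        s1, s2, s3 = self.ve_slopes_lpm_per_min
        if not (s1 <= s2 <= s3):
            raise ValueError(f"VE segment slopes must be non-decreasing, got {s1}, {s2}, {s3}")
        if self.delta_t_max < 0 or self.pixel_noise_sd < 0 or self.ve_noise_sd < 0:
            raise ValueError("noise sds and delta_t_max must be non-negative")
        if self.exercise_duration_s <= 0:
            raise ValueError("exercise_duration_s must be positive")


@dataclass(frozen=True)
class BranchSegment:
    origin: tuple[float, float]  # (row, col)
    angle_rad: float  # 0 = toward decreasing row, positive = clockwise
    length_px: float
    width_px: float
    delta_t: float

    @property
    def tip(self) -> tuple[float, float]:
        r, c = self.origin
        return (
            r - self.length_px * math.cos(self.angle_rad),
            c + self.length_px * math.sin(self.angle_rad),
        )


@dataclass(frozen=True)
class BranchingPattern:
    """A trunk plus recursively split child segments, rooted in the chest."""

    segments: tuple[BranchSegment, ...]


def default_roi_polygons(shape: tuple[int, int] = (120, 160)) -> list[PolygonROI]:
    """Rectangular stand-ins for manually outlined forehead/chest/abdomen."""
    rows, cols = shape
    r, c = rows / 120.0, cols / 160.0

    def rect(r0, c0, r1, c1, label):
        return PolygonROI(
            vertices=((r0 * r, c0 * c), (r0 * r, c1 * c), (r1 * r, c1 * c), (r1 * r, c0 * c)),
            label=label,
        )

    return [
        rect(6, 62, 24, 98, "forehead"),
        rect(40, 36, 76, 124, "chest"),
        rect(86, 46, 114, 114, "abdomen"),
    ]


def generate_branching_pattern(cfg: SubjectConfig, rng: np.random.Generator) -> BranchingPattern:
    """Recursive tree: each segment spawns ``branch_count`` children at its
    tip with decayed length/width/ΔT and jittered fan-out angles."""
    rows, cols = cfg.frame_shape
    # root near the bottom-center of the chest ROI, growing upward
    chest = next(p for p in default_roi_polygons(cfg.frame_shape) if p.label == "chest")
    rmax = max(v[0] for v in chest.vertices)
    cmid = sum(v[1] for v in chest.vertices) / len(chest.vertices)
    root = (rmax - 2.0, cmid + rng.uniform(-8.0, 8.0))
    trunk = BranchSegment(
        origin=root,
        angle_rad=math.radians(rng.uniform(-10.0, 10.0)),
        length_px=cfg.trunk_length_px,
        width_px=cfg.trunk_width_px,
        delta_t=cfg.delta_t_max,
    )
    segments = [trunk]
    frontier = [trunk]
    for _ in range(cfg.branch_depth):
        nxt = []
        for seg in frontier:
            fan = np.linspace(-cfg.branch_angle_deg, cfg.branch_angle_deg, cfg.branch_count)
            for base_angle in fan:
                child = BranchSegment(
                    origin=seg.tip,
                    angle_rad=seg.angle_rad
                    + math.radians(base_angle + rng.uniform(-cfg.angle_jitter_deg, cfg.angle_jitter_deg)),
                    length_px=seg.length_px * cfg.length_decay,
                    width_px=max(1.0, seg.width_px * cfg.width_decay),
                    delta_t=seg.delta_t * cfg.dt_decay,
                )
                nxt.append(child)
        segments.extend(nxt)
        frontier = nxt
    return BranchingPattern(segments=tuple(segments))


def pattern_field(pattern: BranchingPattern, shape: tuple[int, int]) -> np.ndarray:
    """Warm field (°C) of the pattern: per segment a Gaussian cross-profile
    of its ΔT around the segment axis; overlaps combine by maximum, so the
    field never exceeds the trunk ΔT."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    out = np.zeros(shape, dtype=float)
    for seg in pattern.segments:
        orow, ocol = seg.origin
        dr = -math.cos(seg.angle_rad)
        dc = math.sin(seg.angle_rad)
        vr, vc = rr - orow, cc - ocol
        t = np.clip(vr * dr + vc * dc, 0.0, seg.length_px)
        dist2 = (vr - t * dr) ** 2 + (vc - t * dc) ** 2
        sigma = seg.width_px / 2.0
        np.maximum(out, seg.delta_t * np.exp(-0.5 * dist2 / sigma**2), out=out)
    return out


def _baseline_and_texture(
    cfg: SubjectConfig, masks: dict[str, ROIMask], rng: np.random.Generator
) -> np.ndarray:
    """Static noise-free baseline: regional plateaus plus a smooth
    heterogeneity field scaled to each region's texture sd.

    The smooth field is renormalized *within* each ROI so its realized sd
    there equals the configured value exactly — a small ROI samples only a
    few correlation lengths of the field, which would otherwise depress
    its empirical sd and hence its resting entropy."""
    g = gaussian_filter(rng.standard_normal(cfg.frame_shape), cfg.texture_smooth_px)
    g = g / g.std()
    base = np.full(cfg.frame_shape, cfg.baseline_temp["chest"], dtype=float)
    tex = cfg.texture_sd["chest"] * g
    for label, mask in masks.items():
        m = mask.mask
        base[m] = cfg.baseline_temp[label]
        local = g[m]
        tex[m] = cfg.texture_sd[label] * (local - local.mean()) / local.std()
    return base + tex


def activation(cfg: SubjectConfig, t: float) -> float:
    """Pattern ramp a(t): 0 → 1 linearly over exercise, linear decay to 0
    over the recovery period."""
    T = cfg.exercise_duration_s
    if t <= T:
        return max(0.0, t / T)
    return max(0.0, 1.0 - (t - T) / cfg.recovery_duration_s)


def render_frame(
    cfg: SubjectConfig,
    static_base: np.ndarray,
    pat: np.ndarray,
    masks: dict[str, ROIMask],
    t: float,
    rng: np.random.Generator | None = None,
) -> ThermalFrame:
    """One frame at time ``t``: baseline + a(t)·pattern − per-ROI mean
    compensation + pixel noise.  The compensation offset is uniform within
    each ROI and equals a(t) times the pattern's ROI mean, so the ROI's
    noise-free mean temperature is exactly time-invariant."""
    a = activation(cfg, t)
    temps = static_base + a * pat
    for mask in masks.values():
        temps[mask.mask] -= a * pat[mask.mask].mean()
    if rng is not None and cfg.pixel_noise_sd > 0:
        temps = temps + rng.normal(0.0, cfg.pixel_noise_sd, size=temps.shape)
    phase = "exercise" if t <= cfg.exercise_duration_s else "recovery"
    return ThermalFrame(temperatures=temps, time_s=float(t), phase=phase)


def generate_ve_curve(
    cfg: SubjectConfig, times: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Continuous piecewise-linear VE (L/min) at the given times, with knots
    at the breakpoint fractions of exercise duration and Gaussian noise."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time list")
    T = cfg.exercise_duration_s
    f1, f2 = cfg.breakpoint_fractions
    t1, t2 = f1 * T, f2 * T
    s1, s2, s3 = (s / 60.0 for s in cfg.ve_slopes_lpm_per_min)  # L/min per second
    ve = (
        cfg.ve_rest_lpm
        + s1 * np.minimum(times, t1)
        + s2 * np.clip(times - t1, 0.0, t2 - t1)
        + s3 * np.clip(times - t2, 0.0, None)
    )
    if rng is not None and cfg.ve_noise_sd > 0:
        ve = ve + rng.normal(0.0, cfg.ve_noise_sd, size=ve.shape)
    return ve


@dataclass
class SubjectSession:
    """Frames, ROI masks, VE samples and exercise-end time for one subject."""

    subject_id: str
    frames: list[ThermalFrame]
    masks: dict[str, ROIMask]
    polygons: list[PolygonROI]
    ve_times_s: np.ndarray
    ve_lpm: np.ndarray
    exercise_end_s: float

    def exercise_frames(self) -> list[ThermalFrame]:
        return [f for f in self.frames if f.phase == "exercise"]


def capture_times(cfg: SubjectConfig) -> np.ndarray:
    """Capture schedule: every 30 s from 0 to exhaustion, then every 60 s
    through the 5-min recovery."""
    T = cfg.exercise_duration_s
    ex = np.arange(0.0, T + 1e-9, cfg.capture_interval_exercise_s)
    if ex[-1] < T:  # duration not a multiple of the cadence: capture at exhaustion too
        ex = np.append(ex, T)
    rec = T + np.arange(
        cfg.capture_interval_recovery_s,
        cfg.recovery_duration_s + 1e-9,
        cfg.capture_interval_recovery_s,
    )
    return np.concatenate([ex, rec])


def generate_subject(subject_id: str, cfg: SubjectConfig) -> SubjectSession:
    """One fully deterministic session from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    polys = default_roi_polygons(cfg.frame_shape)
    masks = {p.label: rasterize_polygon(p, cfg.frame_shape) for p in polys}
    static_base = _baseline_and_texture(cfg, masks, rng)
    pat = pattern_field(generate_branching_pattern(cfg, rng), cfg.frame_shape)
    times = capture_times(cfg)
    frames = [render_frame(cfg, static_base, pat, masks, t, rng) for t in times]
    ve_times = np.arange(0.0, cfg.exercise_duration_s + 1e-9, cfg.capture_interval_exercise_s)
    if ve_times[-1] < cfg.exercise_duration_s:
        ve_times = np.append(ve_times, cfg.exercise_duration_s)
    ve = generate_ve_curve(cfg, ve_times, rng)
    return SubjectSession(
        subject_id=subject_id,
        frames=frames,
        masks=masks,
        polygons=polys,
        ve_times_s=ve_times,
        ve_lpm=ve,
        exercise_end_s=cfg.exercise_duration_s,
    )


def generate_cohort(
    n_subjects: int = 18,
    master_seed: int = 0,
    template: SubjectConfig | None = None,
) -> list[SubjectSession]:
    """A cohort of healthy-young-adult sessions (default n = 18).

    Per-subject seeds derive deterministically from ``master_seed``;
    exercise durations are jittered around 10 min in whole capture
    intervals (9–11 min); texture amplitudes and VE parameters carry
    between-subject spread so the cohort's resting-entropy dispersion is
    realistic rather than degenerate."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    template = template or SubjectConfig()
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(n_subjects)]
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    sessions = []
    for i in range(n_subjects):
        dur = float(jitter_rng.integers(18, 23) * template.capture_interval_exercise_s)
        tex = {
            label: sd * 2.0 ** jitter_rng.normal(0.0, template.intersubject_sd_bits[label])
            for label, sd in template.texture_sd.items()
        }
        slope_factor = jitter_rng.uniform(0.85, 1.2)
        slopes = tuple(s * slope_factor for s in template.ve_slopes_lpm_per_min)
        f1, f2 = template.breakpoint_fractions
        f1 = float(np.clip(f1 + jitter_rng.normal(0.0, 0.02), 0.15, f2 - 0.1))
        f2 = float(np.clip(f2 + jitter_rng.normal(0.0, 0.02), f1 + 0.1, 0.95))
        cfg = replace(
            template,
            seed=child_seeds[i],
            exercise_duration_s=dur,
            texture_sd=tex,
            ve_rest_lpm=template.ve_rest_lpm + jitter_rng.uniform(-2.0, 2.0),
            ve_slopes_lpm_per_min=slopes,
            breakpoint_fractions=(f1, f2),
        )
        sessions.append(generate_subject(f"subject_{i + 1:02d}", cfg))
    return sessions


# ---------------------------------------------------------------------------
# session persistence (thermal interchange formats)


def save_session(session: SubjectSession, outdir: str | Path, fmt: str = "csv") -> Path:
    """Write a session as interchange files: per-frame matrix + sidecar,
    ROI polygons, VE table, and a small session manifest."""
    import json

    outdir = Path(outdir)
    frames_dir = outdir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if fmt == "csv" else "tif"
    for i, frame in enumerate(session.frames):
        write_frame(frame, frames_dir / f"frame_{i:04d}.{ext}", fmt=fmt)
    write_polygons(session.polygons, outdir / "rois.json")
    with open(outdir / "ve.csv", "w") as fh:
        fh.write("time_s,ve_lpm\n")
        for t, v in zip(session.ve_times_s, session.ve_lpm):
            fh.write(f"{t:.1f},{v:.4f}\n")
    (outdir / "session.json").write_text(
        json.dumps(
            {
                "subject_id": session.subject_id,
                "exercise_end_s": session.exercise_end_s,
                "format": fmt,
                "n_frames": len(session.frames),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return outdir


def load_session(indir: str | Path) -> SubjectSession:
    """Read a session previously written by :func:`save_session`."""
    import json

    from .io import read_frame, read_polygons

    indir = Path(indir)
    manifest = json.loads((indir / "session.json").read_text())
    fmt = manifest["format"]
    ext = "csv" if fmt == "csv" else "tif"
    frame_paths = sorted((indir / "frames").glob(f"frame_*.{ext}"))
    frames = [read_frame(p, fmt=fmt) for p in frame_paths]
    polys = read_polygons(indir / "rois.json")
    shape = frames[0].shape
    masks = {p.label: rasterize_polygon(p, shape) for p in polys}
    ve = np.loadtxt(indir / "ve.csv", delimiter=",", skiprows=1)
    ve = np.atleast_2d(ve)
    return SubjectSession(
        subject_id=manifest["subject_id"],
        frames=frames,
        masks=masks,
        polygons=polys,
        ve_times_s=ve[:, 0],
        ve_lpm=ve[:, 1],
        exercise_end_s=float(manifest["exercise_end_s"]),
    )
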