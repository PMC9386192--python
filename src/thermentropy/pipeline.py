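"""End-to-end orchestration: simulate → features → timeline → stats.

Each stage materializes a plain-text artifact in the run directory so it
can be inspected and re-run independently:

* ``features.csv``  — per subject / frame / ROI: mean temperature, entropy
* ``ve.csv``        — per subject pulmonary-ventilation samples
* ``group_series.csv`` — group mean ± sd trajectories on the percent grid
* ``stats_report.json`` — correlations, repeated-measures ANOVA, detected
  ventilatory thresholds
* ``run.log``       — frame-granularity structured log

All outputs are deterministic for a fixed configuration and seed and carry
the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import stats as st
from . import synthetic as syn
from . import timeline as tl

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "sessions_to_features",
           "features_to_groups", "groups_to_report"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and offending input."""


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"  # synthetic | directory
    n_subjects: int = 18
    master_seed: int = 0
    input_dir: str | None = None
    fmt: str = "csv"
    bin_width: float = feat.DEFAULT_BIN_WIDTH
    grid_step_pct: float = 5.0
    with_glcm: bool = False
    save_sessions: bool = False

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_step_pct, 100.0 + 1e-9, self.grid_step_pct)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_sessions(cfg: RunConfig) -> list[syn.SubjectSession]:
    if cfg.mode == "synthetic":
        return syn.generate_cohort(cfg.n_subjects, cfg.master_seed)
    if cfg.mode != "directory":
        raise PipelineError(f"[stage load] unknown mode {cfg.mode!r}")
    root = Path(cfg.input_dir or ".")
    subdirs = sorted(d for d in root.iterdir() if (d / "session.json").exists())
    if not subdirs:
        raise PipelineError(f"[stage load] no session directories under {root}")
    sessions = []
    for d in subdirs:
        try:
            sessions.append(syn.load_session(d))
        except Exception as exc:
            raise PipelineError(f"[stage load] session {d}: {exc}") from exc
    return sessions


def sessions_to_features(
    sessions: list[syn.SubjectSession],
    bin_width: float = feat.DEFAULT_BIN_WIDTH,
    with_glcm: bool = False,
    log: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature stage: per-frame, per-ROI feature table plus the VE table."""
    rows = []
    ve_rows = []
    for s in sessions:
        masks = list(s.masks.values())
        for frame in s.frames:
            try:
                recs = feat.frame_features(frame, masks, bin_width, with_glcm)
            except Exception as exc:
                raise PipelineError(
                    f"[stage features] subject {s.subject_id} frame t={frame.time_s}: {exc}"
                ) from exc
            for rec in recs:
                row = {
                    "subject_id": s.subject_id,
                    "time_s": frame.time_s,
                    "pct_time": 100.0 * frame.time_s / s.exercise_end_s,
                    "phase": frame.phase,
                    "roi_label": rec.label,
                    "mean_temp_C": rec.mean_temp,
                    "entropy_bits": rec.entropy,
                    "n_pixels": rec.n_pixels,
                    "n_levels": rec.n_levels,
                }
                if with_glcm:
                    row["contrast"] = rec.contrast
                    row["homogeneity"] = rec.homogeneity
                rows.append(row)
                if log is not None:
                    log.append(
                        f"feature subject={s.subject_id} t={frame.time_s:.0f} "
                        f"roi={rec.label} mean={rec.mean_temp:.4f} H={rec.entropy:.4f}"
                    )
        for t, v in zip(s.ve_times_s, s.ve_lpm):
            ve_rows.append(
                {
                    "subject_id": s.subject_id,
                    "time_s": t,
                    "pct_time": 100.0 * t / s.exercise_end_s,
                    "ve_lpm": v,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(ve_rows)


def _series_from_table(
    df: pd.DataFrame, value_col: str, feature_name: str, roi: str | None
) -> list[tl.FeatureSeries]:
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("time_s")
        end = 100.0 * g["time_s"].iloc[-1] / g["pct_time"].iloc[-1] if g["pct_time"].iloc[-1] else 1.0
        out.append(
            tl.normalize_time(
                tl.FeatureSeries(
                    subject_id=str(sid),
                    roi_label=roi or "all",
                    feature_name=feature_name,
                    times_s=g["time_s"].to_numpy(),
                    values=g[value_col].to_numpy(),
                    exercise_end_s=float(end),
                )
            )
        )
    return out


def features_to_groups(
    features_df: pd.DataFrame, ve_df: pd.DataFrame, grid: np.ndarray
) -> dict[tuple[str, str], tl.GroupSeries]:
    """Timeline stage: normalized, grid-resampled group trajectories.

    Keys are (roi_label, feature_name); VE appears as ("all", "ve").
    Recovery-phase rows are excluded — trajectories run to exhaustion only.
    """
    exercise = features_df[features_df["phase"] == "exercise"]
    groups: dict[tuple[str, str], tl.GroupSeries] = {}
    for roi, g in exercise.groupby("roi_label", sort=True):
        for value_col, name in (("mean_temp_C", "mean_temp"), ("entropy_bits", "entropy")):
            series = _series_from_table(g, value_col, name, str(roi))
            groups[(str(roi), name)] = tl.group_mean(series, grid)
    ve_series = _series_from_table(ve_df, "ve_lpm", "ve", None)
    groups[("all", "ve")] = tl.group_mean(ve_series, grid)
    return groups


def _corr_payload(fn, *args) -> dict:
    try:
        r = fn(*args)
        return {"rho": r.rho, "p_value": r.p_value, "n": r.n, "method": r.method}
    except ValueError as exc:  # e.g. constant vector: report, don't crash
        return {"error": str(exc)}


def groups_to_report(
    groups: dict[tuple[str, str], tl.GroupSeries],
    ve_df: pd.DataFrame,
    grid: np.ndarray,
    features_df: pd.DataFrame | None = None,
) -> dict:
    """Stats stage: correlations, RM-ANOVA over timepoints, VE thresholds."""
    report: dict = {"correlations": {}, "anova": {}, "thresholds": {}}
    ve_group = groups[("all", "ve")]
    for (roi, name), gs in groups.items():
        if name == "ve":
            continue
        report["correlations"][f"{roi}_{name}_vs_time"] = _corr_payload(
            st.correlate_feature_vs_time, gs
        )
        if name == "entropy":
            report["correlations"][f"{roi}_entropy_vs_ve"] = _corr_payload(
                st.correlate_entropy_ve, gs, ve_group
            )
    # repeated-measures ANOVA on the per-subject resampled entropy matrix
    if features_df is not None:
        exercise = features_df[features_df["phase"] == "exercise"]
        for roi in sorted(exercise["roi_label"].unique()):
            g = exercise[exercise["roi_label"] == roi]
            series = _series_from_table(g, "entropy_bits", "entropy", str(roi))
            try:
                mat = np.vstack([tl.resample_to_grid(s, grid) for s in series])
                a = st.repeated_anova(mat)
                report["anova"][f"{roi}_entropy"] = {
                    "F": a.F, "p_value": a.p_value, "df_time": a.df_time,
                    "df_error": a.df_error, "ss_time": a.ss_time,
                    "ss_subject": a.ss_subject, "ss_error": a.ss_error,
                    "degenerate": a.degenerate,
                }
            except ValueError as exc:
                report["anova"][f"{roi}_entropy"] = {"error": str(exc)}
    # group-level ventilatory thresholds + per-subject recovery
    try:
        thr = st.detect_ventilatory_thresholds(ve_group.grid, ve_group.mean)
        report["thresholds"]["group"] = {
            "vt1_pct": thr.vt1_pct, "vt2_pct": thr.vt2_pct, "sse": thr.sse,
            "slopes": list(thr.slopes), "low_confidence": thr.low_confidence,
        }
        for roi in ("chest", "abdomen", "forehead"):
            if (roi, "entropy") in groups:
                gs = groups[(roi, "entropy")]
                report["thresholds"][f"{roi}_entropy_at_vt"] = {
                    "at_vt1": float(np.interp(thr.vt1_pct, gs.grid, gs.mean)),
                    "at_vt2": float(np.interp(thr.vt2_pct, gs.grid, gs.mean)),
                }
    except ValueError as exc:
        report["thresholds"]["group"] = {"error": str(exc)}
    per_subject = {}
    for sid, g in ve_df.groupby("subject_id", sort=True):
        g = g.sort_values("pct_time")
        try:
            t = st.detect_ventilatory_thresholds(
                g["pct_time"].to_numpy(), g["ve_lpm"].to_numpy()
            )
            per_subject[str(sid)] = {"vt1_pct": t.vt1_pct, "vt2_pct": t.vt2_pct,
                                     "low_confidence": t.low_confidence}
        except ValueError as exc:
            per_subject[str(sid)] = {"error": str(exc)}
    report["thresholds"]["per_subject"] = per_subject
    return report


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> Path:
    """Run all stages, materializing every artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log: list[str] = [f"config_hash={chash}", f"config={json.dumps(asdict(cfg), sort_keys=True)}"]

    sessions = _load_sessions(cfg)
    log.append(f"loaded {len(sessions)} sessions (mode={cfg.mode})")
    if cfg.mode == "synthetic" and cfg.save_sessions:
        for s in sessions:
            syn.save_session(s, outdir / "sessions" / s.subject_id, fmt=cfg.fmt)

    features_df, ve_df = sessions_to_features(
        sessions, cfg.bin_width, cfg.with_glcm, log=log
    )
    grid = cfg.grid()
    groups = features_to_groups(features_df, ve_df, grid)
    report = groups_to_report(groups, ve_df, grid, features_df)
    report["config_hash"] = chash
    report["quantization"] = {"bin_width_C": cfg.bin_width,
                              "rounding": "half-away-from-zero", "log_base": 2}

    _write_csv(features_df, outdir / "features.csv", chash)
    _write_csv(ve_df, outdir / "ve.csv", chash)
    group_rows = []
    for (roi, name), gs in sorted(groups.items()):
        for i, p in enumerate(gs.grid):
            group_rows.append({"pct_time": p, "roi_label": roi, "feature": name,
                               "mean": gs.mean[i], "sd": gs.sd[i], "n": int(gs.n[i])})
    _write_csv(pd.DataFrame(group_rows), outdir / "group_series.csv", chash)
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_run_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV artifact, skipping the config-hash comment line."""
    return pd.read_csv(path, comment="#")
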