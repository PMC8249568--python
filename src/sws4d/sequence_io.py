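"""Plain-text sequence I/O, run configuration and reporting.

Vessel frames travel as CSV with one row per centerline point:

    frame_index, phase, x_mm, y_mm, z_mm, radius_mm

A cardiac sequence is one such file with multiple frame_index values, or a
directory of per-frame files. Units are fixed by the column names (mm);
pressures given in mmHg at the CLI boundary are converted once to kPa and
never converted again internally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SequenceValidationError
from .geometry import Centerline, VesselFrame
from .materials import MaterialModel, default_materials
from .synthetic import CardiacSequence

SCHEMA_VERSION = "1"
CSV_COLUMNS = ["frame_index", "phase", "x_mm", "y_mm", "z_mm", "radius_mm"]
VALID_PHASES = {
    "diastasis", "end_diastole", "early_systole", "end_systole", "early_diastole", "other"
}


def write_sequence(sequence: CardiacSequence, path) -> None:
    """Write a sequence as a single CSV (units in the header)."""
    rows = []
    for f in sequence.frames:
        for p, r in zip(f.centerline.points, f.ring_radius):
            rows.append((f.time_index, f.phase, p[0], p[1], p[2], r))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def _frames_from_df(df: pd.DataFrame, source: str) -> list[VesselFrame]:
    frames = []
    for idx in sorted(df["frame_index"].unique()):
        sub = df[df["frame_index"] == idx]
        phases = sub["phase"].unique()
        if len(phases) != 1:
            raise SequenceValidationError(
                f"{source}: frame {idx} carries multiple phase labels {sorted(phases)}"
            )
        phase = str(phases[0])
        if phase not in VALID_PHASES:
            raise SequenceValidationError(f"{source}: unknown phase label {phase!r} in frame {idx}")
        pts = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        radii = sub["radius_mm"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(pts)) and np.all(np.isfinite(radii))):
            bad = int(np.argmax(~(np.isfinite(radii) & np.isfinite(pts).all(axis=1))))
            raise SequenceValidationError(
                f"{source}: non-finite value in frame {idx}, row {bad}"
            )
        frames.append(
            VesselFrame(
                centerline=Centerline(points=pts),
                ring_radius=radii,
                phase=phase,  # type: ignore[arg-type]
                time_index=int(idx),
            )
        )
    return frames


def read_sequence(path) -> CardiacSequence:
    """Read a sequence from a CSV file or a directory of frame CSVs.

    Frames are sorted by time_index; the sequence invariants (exactly one
    diastasis frame, first in time order; consistent point counts; finite
    values) are validated with named errors.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise SequenceValidationError(f"{path}: no CSV files found")
        dfs = []
        for f in files:
            dfs.append(_read_csv(f))
        df = pd.concat(dfs, ignore_index=True)
        source = str(path)
    else:
        df = _read_csv(path)
        source = str(path)
    frames = _frames_from_df(df, source)
    frames.sort(key=lambda f: f.time_index)
    n_dia = sum(f.phase == "diastasis" for f in frames)
    if n_dia == 0:
        raise SequenceValidationError(f"{source}: no diastasis frame present")
    if n_dia > 1:
        raise SequenceValidationError(f"{source}: {n_dia} diastasis frames (exactly 1 allowed)")
    counts = {len(f.centerline) for f in frames}
    if len(counts) != 1:
        raise SequenceValidationError(f"{source}: inconsistent point counts across frames {counts}")
    if frames[0].phase != "diastasis":
        # re-anchor time so the cycle starts at diastasis
        dia = next(i for i, f in enumerate(frames) if f.phase == "diastasis")
        frames = frames[dia:] + frames[:dia]
    return CardiacSequence(frames=frames)


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, skip_blank_lines=True)
    except Exception as exc:
        raise SequenceValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceValidationError(f"{path}: missing columns {missing}")
    return df[CSV_COLUMNS]


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated run configuration with explicit units.

    Material constants are kPa; pressures may be declared in mmHg in the
    config file (``pressure_units: mmHg``) and are converted at load time.
    """

    mesh_rings: int = 101
    mesh_circumferential: int = 32
    alpha_deform: float = 1.0
    alpha_kinetic: float = 0.1
    stenosis_threshold_pct: float = 20.0
    seed: int = 0
    materials: dict = field(default_factory=default_materials)

    def __post_init__(self):
        if self.mesh_rings < 4 or self.mesh_circumferential < 8:
            raise ConfigurationError("mesh density too low (need rings >= 4, circumferential >= 8)")
        if not (0.0 < self.stenosis_threshold_pct < 100.0):
            raise ConfigurationError("stenosis threshold must lie in (0, 100) percent")
        if self.alpha_deform < 0.0 or self.alpha_kinetic < 0.0:
            raise ConfigurationError("energy weights must be >= 0")


_KNOWN_KEYS = {
    "mesh_rings", "mesh_circumferential", "alpha_deform", "alpha_kinetic",
    "stenosis_threshold_pct", "seed", "materials",
}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    materials = default_materials()
    for cls, consts in (raw.pop("materials", {}) or {}).items():
        materials[cls] = MaterialModel(
            c1=float(consts["c1_kpa"]), c2=float(consts["c2_kpa"]), tissue_class=cls
        )
    return RunConfig(materials=materials, **raw)


def config_hash(config: RunConfig) -> str:
    payload = {k: v for k, v in asdict(config).items() if k != "materials"}
    payload["materials"] = {
        k: (m.c1, m.c2) for k, m in config.materials.items()
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# reporting


def report(results: dict, path: Optional[Path] = None) -> str:
    """Render pipeline results as text and (optionally) schema-versioned JSON.

    ``results`` may contain any of: per-segment summaries, pulse-stress peak
    position, Procrustes cohort statistics. Missing entries appear as nulls
    in the JSON so partial runs stay machine-readable.
    """
    payload = {"schema_version": SCHEMA_VERSION, "units": {"length": "mm", "stress": "kPa"}}
    payload.update(_jsonify(results))
    lines = ["sws4d report", "============"]
    summary = results.get("summary")
    if summary is not None:
        for cls, v in summary.strain_by_class.items():
            lines.append(f"time-averaged max principal strain [{cls}]: {v * 100:.2f} %")
        for cls, v in summary.stress_by_class.items():
            lines.append(f"time-averaged von Mises stress   [{cls}]: {v:.2f} kPa")
        lines.append(
            f"cycle-peak stress: {summary.peak_von_mises_kpa:.2f} kPa at "
            f"{summary.peak_arclength_mm:.1f} mm from the ostial end "
            f"({summary.peak_location_class})"
        )
    pulse = results.get("pulse")
    if pulse is not None:
        lines.append(
            f"pulse stress peak: {pulse.values.max():.2f} kPa at "
            f"{pulse.argmax_arclength_mm:.1f} mm from the ostial end"
        )
    proc = results.get("procrustes")
    if proc is not None:
        lines.append(
            f"centerline prediction over {len(proc.scalings)} sequences: "
            f"scaling {proc.mean_scaling:.3f} ± {proc.sd_scaling:.3f}, "
            f"dissimilarity {proc.mean_dissimilarity:.4f} ± {proc.sd_dissimilarity:.4f}"
        )
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return text


def _jsonify(results: dict) -> dict:
    out: dict = {"summary": None, "pulse": None, "procrustes": None}
    summary = results.get("summary")
    if summary is not None:
        out["summary"] = {
            "strain_by_class": summary.strain_by_class,
            "stress_by_class_kpa": summary.stress_by_class,
            "peak_von_mises_kpa": summary.peak_von_mises_kpa,
            "peak_arclength_mm": summary.peak_arclength_mm,
            "peak_location_class": summary.peak_location_class,
        }
    pulse = results.get("pulse")
    if pulse is not None:
        out["pulse"] = {
            "max_kpa": float(pulse.values.max()),
            "argmax_arclength_mm": pulse.argmax_arclength_mm,
            "argmax_element": list(pulse.argmax_element),
        }
    proc = results.get("procrustes")
    if proc is not None:
        out["procrustes"] = {
            "mean_scaling": proc.mean_scaling,
            "sd_scaling": proc.sd_scaling,
            "mean_dissimilarity": proc.mean_dissimilarity,
            "sd_dissimilarity": proc.sd_dissimilarity,
            "n": int(len(proc.scalings)),
            "failures": proc.failures,
        }
    return out
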