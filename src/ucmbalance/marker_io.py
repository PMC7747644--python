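"""Reading, writing and validation of marker-trajectory trials.

A trial is one recording of the 19-marker full-body set sampled in a fixed
laboratory frame (x = anterior-posterior, positive forward in the pull
direction; y = medial-lateral, positive toward the subject's right;
z = vertical, positive up), in meters.

The native on-disk dialect is a plain CSV with one header row — a ``t``
column in seconds followed by ``<marker>_x``, ``<marker>_y``, ``<marker>_z``
triplets — plus a YAML sidecar with the same stem carrying subject metadata,
event sample indices and anthropometry.  C3D files are read through
``ezc3d`` when that package is installed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Canonical marker names, in canonical column order.
MARKER_NAMES: tuple[str, ...] = (
    "head_vertex",
    "L_acromion", "R_acromion",
    "L_elbow", "R_elbow",
    "L_wrist", "R_wrist",
    "L_finger3", "R_finger3",
    "L_greater_trochanter", "R_greater_trochanter",
    "L_knee", "R_knee",
    "L_malleolus", "R_malleolus",
    "L_heel", "R_heel",
    "L_toe", "R_toe",
)

#: Longest run of missing samples repaired by linear interpolation.
MAX_GAP_SAMPLES = 5


class TrialValidationError(ValueError):
    """Raised when a trial violates a structural invariant."""


@dataclass
class MarkerTrial:
    """One subject-trial of 3-D marker positions with events and anthropometry.

    Attributes
    ----------
    subject_id, group_label:
        Free-text identifiers (e.g. group ``"dancer"`` / ``"non-dancer"``).
    sampling_rate:
        Hz, strictly positive.
    positions:
        ``(T, 19, 3)`` array, meters, ordered as :data:`MARKER_NAMES`.
    events:
        Named sample indices.  ``perturbation_onset`` is required by the
        analysis; ``foot_contact`` is optional and overrides detection.
    anthropometry:
        ``body_mass`` (kg), ``body_height`` (m) and ``foot_length`` — either
        a scalar or a ``{"left": m, "right": m}`` mapping.
    stepping_side:
        Optional annotated side (``"left"``/``"right"``); overrides the
        kinematic stepping-side detector.
    """

    subject_id: str
    group_label: str
    sampling_rate: float
    positions: np.ndarray
    marker_names: tuple[str, ...] = MARKER_NAMES
    events: dict[str, int] = field(default_factory=dict)
    anthropometry: dict = field(default_factory=dict)
    stepping_side: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise TrialValidationError("sampling_rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (19, 3):
            raise TrialValidationError(
                f"positions must be (T, 19, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] == 0:
            raise TrialValidationError("empty trial (T=0)")
        missing = [m for m in MARKER_NAMES if m not in self.marker_names]
        if missing or len(self.marker_names) != 19:
            raise TrialValidationError(
                f"missing canonical marker(s): {', '.join(missing) or 'duplicate names'}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrialValidationError("non-finite samples remain after gap handling")
        T = self.positions.shape[0]
        for name, idx in self.events.items():
            if not (0 <= int(idx) <= T - 1):
                raise TrialValidationError(
                    f"event {name!r}={idx} outside [0, {T - 1}]"
                )
        if self.stepping_side not in (None, "left", "right"):
            raise TrialValidationError(f"bad stepping_side {self.stepping_side!r}")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """Return the ``(T, 3)`` trajectory of one canonical marker."""
        return self.positions[:, self.marker_names.index(name), :]

    def foot_length(self, side: str) -> float | None:
        fl = self.anthropometry.get("foot_length")
        if fl is None:
            return None
        if isinstance(fl, dict):
            return float(fl[side])
        return float(fl)


def fill_gaps(positions: np.ndarray, max_gap: int = MAX_GAP_SAMPLES) -> np.ndarray:
    """Linearly interpolate short NaN runs; longer gaps are fatal.

    Gaps at the start or end of a trajectory cannot be interpolated and are
    always fatal.
    """
    out = np.array(positions, dtype=float)
    T = out.shape[0]
    for m in range(out.shape[1]):
        for ax in range(out.shape[2]):
            col = out[:, m, ax]
            bad = ~np.isfinite(col)
            if not bad.any():
                continue
            # locate contiguous runs of missing samples
            idx = np.flatnonzero(bad)
            splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in splits:
                if run[0] == 0 or run[-1] == T - 1:
                    raise TrialValidationError(
                        f"marker {MARKER_NAMES[m]} axis {ax}: gap touches trial boundary"
                    )
                if len(run) > max_gap:
                    raise TrialValidationError(
                        f"marker {MARKER_NAMES[m]} axis {ax}: gap of {len(run)} "
                        f"samples exceeds {max_gap}"
                    )
            good = np.flatnonzero(~bad)
            col[bad] = np.interp(idx, good, col[good])
    return out


# ---------------------------------------------------------------------------
# CSV + YAML sidecar dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    for ext in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(ext)
        if cand.exists():
            return cand
    return path.with_suffix(".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        return {}
    with open(sc) as fh:
        return yaml.safe_load(fh) or {}


def read_trial(
    path: str | Path,
    format: str = "csv",
    alias: dict[str, str] | None = None,
    unit_scale: float | None = None,
) -> MarkerTrial:
    """Read one trial file into a validated :class:`MarkerTrial`.

    Parameters
    ----------
    path:
        Trial file.  For CSV a YAML/JSON sidecar with the same stem supplies
        metadata, events and anthropometry.
    format:
        ``"csv"`` (native dialect) or ``"c3d"`` (requires ``ezc3d``).
    alias:
        Optional mapping from source marker names to canonical names.
    unit_scale:
        Override the positions-to-meters factor (e.g. ``0.001`` for a
        millimeter CSV).  C3D units are taken from the file's own metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv_trial(path, alias=alias, unit_scale=unit_scale)
    if format == "c3d":
        return _read_c3d_trial(path, alias=alias)
    raise ValueError(f"unknown format {format!r}")


def _canonicalize(names: list[str], alias: dict[str, str] | None) -> dict[str, str]:
    alias = alias or {}
    mapping = {}
    for n in names:
        canon = alias.get(n, n)
        if canon in MARKER_NAMES:
            mapping[canon] = n
    missing = [m for m in MARKER_NAMES if m not in mapping]
    if missing:
        raise TrialValidationError(
            "missing canonical marker(s): " + ", ".join(missing)
        )
    return mapping


def _read_csv_trial(path: Path, alias=None, unit_scale=None) -> MarkerTrial:
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise TrialValidationError(f"{path}: no 't' column")
    if len(df) == 0:
        raise TrialValidationError(f"{path}: empty trial (no rows)")
    stems = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    mapping = _canonicalize(stems, alias)
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise TrialValidationError(f"{path}: non-increasing time column")
        rate = 1.0 / dt
    else:
        rate = 100.0
    scale = 1.0 if unit_scale is None else float(unit_scale)
    pos = np.empty((len(df), 19, 3))
    for i, canon in enumerate(MARKER_NAMES):
        src = mapping[canon]
        for j, ax in enumerate("xyz"):
            pos[:, i, j] = df[f"{src}_{ax}"].to_numpy(dtype=float) * scale
    pos = fill_gaps(pos)

    meta = _read_sidecar(path)
    return MarkerTrial(
        subject_id=str(meta.get("subject_id", path.stem)),
        group_label=str(meta.get("group_label", "")),
        sampling_rate=float(meta.get("sampling_rate", rate)),
        positions=pos,
        events={k: int(v) for k, v in (meta.get("events") or {}).items()},
        anthropometry=meta.get("anthropometry") or {},
        stepping_side=meta.get("stepping_side"),
    )


def _read_c3d_trial(path: Path, alias=None) -> MarkerTrial:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D requires the optional dependency 'ezc3d' "
            "(pip install ucmbalance[c3d]); alternatively export the trial "
            "to the CSV dialect"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    unit = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])[0]
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(unit.strip().lower())
    if scale is None:
        raise TrialValidationError(f"{path}: ambiguous POINT:UNITS {unit!r}")
    mapping = _canonicalize(labels, alias)
    pts = c3d["data"]["points"]  # 4 x nmarkers x T
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pos = np.empty((pts.shape[2], 19, 3))
    for i, canon in enumerate(MARKER_NAMES):
        j = labels.index(mapping[canon])
        pos[:, i, :] = pts[:3, j, :].T * scale
    pos = fill_gaps(pos)
    meta = _read_sidecar(path)
    return MarkerTrial(
        subject_id=str(meta.get("subject_id", path.stem)),
        group_label=str(meta.get("group_label", "")),
        sampling_rate=rate,
        positions=pos,
        events={k: int(v) for k, v in (meta.get("events") or {}).items()},
        anthropometry=meta.get("anthropometry") or {},
        stepping_side=meta.get("stepping_side"),
    )


def write_trial(trial: MarkerTrial, path: str | Path) -> None:
    """Write a trial to the CSV + YAML sidecar dialect.

    The round trip ``read_trial(write_trial(x))`` reproduces positions to
    better than 1e-9 m (full float precision is written) and events exactly.
    """
    path = Path(path)
    if trial.n_samples == 0:
        raise TrialValidationError("refusing to write empty trial")
    t = np.arange(trial.n_samples) / trial.sampling_rate
    cols: dict[str, np.ndarray] = {"t": t}
    for i, name in enumerate(MARKER_NAMES):
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = trial.positions[:, i, j]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "subject_id": trial.subject_id,
        "group_label": trial.group_label,
        "sampling_rate": float(trial.sampling_rate),
        "events": {k: int(v) for k, v in trial.events.items()},
        "anthropometry": _plain(trial.anthropometry),
    }
    if trial.stepping_side is not None:
        meta["stepping_side"] = trial.stepping_side
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _plain(obj):
    """Recursively convert numpy scalars so YAML stays human-readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        raise TrialValidationError("non-finite anthropometry value")
    return obj
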