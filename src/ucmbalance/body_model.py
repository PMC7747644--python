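"""Segmental center-of-mass model and extrapolated CoM kinematics.

Markers are mapped to 14 segmental CoMs with an anthropometric table
(mass fraction and proximal->distal CoM location per segment).  The
whole-body CoM is the mass-weighted sum of segmental CoMs,

    CoM[t] = sum_i (m_i / M) iCoM_i[t],

and the extrapolated CoM (xCoM) adds the velocity scaled by the
eigenfrequency of the equivalent pendulum,

    xCoM = CoM + dCoM/dt / w0,      w0 = sqrt(g / l),

with l the distance from the lateral malleolus to the whole-body CoM.
Because the map is linear, the whole-body xCoM equals the mass-weighted
sum of segmental xCoMs computed with the same w0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import butter, filtfilt

from .marker_io import MARKER_NAMES, MarkerTrial

#: Canonical segment order used by every array in the package.
SEGMENT_NAMES: tuple[str, ...] = (
    "trunk", "head",
    "L_upper_arm", "R_upper_arm",
    "L_forearm", "R_forearm",
    "L_hand", "R_hand",
    "L_thigh", "R_thigh",
    "L_shank", "R_shank",
    "L_foot", "R_foot",
)

GRAVITY = 9.81  # m/s^2, configurable through the eigenfrequency call


class BodyModelError(ValueError):
    """Raised for malformed anthropometric tables or topologies."""


@dataclass
class BodyModel:
    """Anthropometric segment table plus the kinematic chain topology.

    ``mass_fractions`` and ``com_fractions`` are aligned with ``segments``;
    ``proximal``/``distal`` list one or two canonical marker names per
    segment (two markers mean the midpoint).  ``parent`` maps each segment
    to its proximal neighbour; the trunk is the root.
    """

    segments: tuple[str, ...]
    mass_fractions: np.ndarray
    com_fractions: np.ndarray
    proximal: dict[str, tuple[str, ...]]
    distal: dict[str, tuple[str, ...]]
    parent: dict[str, str | None]

    def __post_init__(self) -> None:
        self.segments = tuple(self.segments)
        self.mass_fractions = np.asarray(self.mass_fractions, dtype=float)
        self.com_fractions = np.asarray(self.com_fractions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.segments) != 14:
            raise BodyModelError(f"expected 14 segments, got {len(self.segments)}")
        if set(self.segments) != set(SEGMENT_NAMES):
            raise BodyModelError("segment names do not match the canonical set")
        if abs(self.mass_fractions.sum() - 1.0) > 1e-9:
            raise BodyModelError(
                f"mass fractions sum to {self.mass_fractions.sum()!r}, not 1"
            )
        if np.any(self.com_fractions < 0) or np.any(self.com_fractions > 1):
            raise BodyModelError("com_fraction outside [0, 1]")
        # topology: a tree rooted at trunk, one parent per non-root segment
        roots = [s for s in self.segments if self.parent.get(s) is None]
        if roots != ["trunk"] and set(roots) != {"trunk"}:
            raise BodyModelError(f"tree must be rooted at trunk, roots={roots}")
        for s in self.segments:
            seen, cur = set(), s
            while cur is not None:
                if cur in seen:
                    raise BodyModelError(f"cycle in topology through {s!r}")
                seen.add(cur)
                p = self.parent.get(cur)
                if p is not None and p not in self.segments:
                    raise BodyModelError(f"unknown parent {p!r} of {cur!r}")
                cur = p
        for s in self.segments:
            for mk in (*self.proximal[s], *self.distal[s]):
                if mk not in MARKER_NAMES:
                    raise BodyModelError(f"unknown marker {mk!r} for segment {s!r}")

    # -- topology helpers -----------------------------------------------
    def index(self, segment: str) -> int:
        return self.segments.index(segment)

    def children(self, segment: str) -> list[str]:
        return [s for s in self.segments if self.parent.get(s) == segment]

    def descendants(self, segment: str) -> list[str]:
        """Segments strictly distal to ``segment`` in its chain(s)."""
        out, stack = [], [segment]
        while stack:
            for c in self.children(stack.pop()):
                out.append(c)
                stack.append(c)
        return out

    def topological_order(self) -> list[str]:
        """Parents before children, starting at the trunk."""
        order, stack = [], ["trunk"]
        while stack:
            s = stack.pop(0)
            order.append(s)
            stack.extend(self.children(s))
        return order

    def mass_fraction(self, segment: str) -> float:
        return float(self.mass_fractions[self.index(segment)])


def load_model(path: str | Path) -> BodyModel:
    """Load an anthropometric table from YAML.

    Mass fractions are renormalized to sum to exactly 1, so tables quoted
    to four decimals (summing to e.g. 0.9999) are accepted unchanged.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _model_from_dict(raw)


def load_default_model() -> BodyModel:
    """Load the bundled female 14-segment table."""
    ref = resources.files("ucmbalance") / "data" / "anthropometry_female.yaml"
    raw = yaml.safe_load(ref.read_text())
    return _model_from_dict(raw)


def _model_from_dict(raw: dict) -> BodyModel:
    try:
        seg_map = raw["segments"]
    except (TypeError, KeyError) as exc:
        raise BodyModelError("table must contain a 'segments' mapping") from exc
    names = tuple(s for s in SEGMENT_NAMES if s in seg_map)
    if set(seg_map) - set(SEGMENT_NAMES):
        raise BodyModelError(
            f"unknown segments {sorted(set(seg_map) - set(SEGMENT_NAMES))}"
        )
    mf = np.array([float(seg_map[s]["mass_fraction"]) for s in names])
    if mf.sum() <= 0:
        raise BodyModelError("non-positive total mass fraction")
    mf = mf / mf.sum()
    cf = np.array([float(seg_map[s]["com_fraction"]) for s in names])
    return BodyModel(
        segments=names,
        mass_fractions=mf,
        com_fractions=cf,
        proximal={s: tuple(seg_map[s]["proximal"]) for s in names},
        distal={s: tuple(seg_map[s]["distal"]) for s in names},
        parent={s: seg_map[s]["parent"] for s in names},
    )


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Zero-lag low-pass filtering applied before differentiation.

    A 2nd-order Butterworth run forward and backward (effective 4th order,
    zero phase).  Off by default: synthetic fixtures are noise-free and the
    tests rely on exact differentiation; turn it on for real recordings.
    """

    enabled: bool = False
    cutoff_hz: float = 6.0
    order: int = 2  # per pass; filtfilt doubles the effective order


@dataclass
class SegmentKinematics:
    """Per-trial segmental and whole-body (x)CoM kinematics in AP/ML.

    ``ixcom`` is onset-referenced (zero at the perturbation-onset sample);
    ``xcom`` is the absolute whole-body xCoM used for base-of-support
    comparisons, with ``xcom_ref`` the onset-referenced copy.
    """

    icom: np.ndarray        # (T, 14, 2) m
    icom_dot: np.ndarray    # (T, 14, 2) m/s
    com: np.ndarray         # (T, 2) m
    com_dot: np.ndarray     # (T, 2) m/s
    omega0: float           # rad/s
    pendulum_length: float  # m
    ixcom: np.ndarray       # (T, 14, 2) m, onset-referenced
    xcom: np.ndarray        # (T, 2) m, absolute
    xcom_ref: np.ndarray    # (T, 2) m, onset-referenced
    onset: int
    mass_fractions: np.ndarray = field(repr=False, default=None)


def segment_coms(trial: MarkerTrial, model: BodyModel) -> np.ndarray:
    """Estimate 3-D segmental CoM trajectories, shape ``(T, 14, 3)``.

    Each segment CoM is placed at ``proximal + f * (distal - proximal)``
    where endpoints given as marker pairs are midpoints.
    """
    if not np.all(np.isfinite(trial.positions)):
        raise BodyModelError("non-finite marker data")
    T = trial.n_samples
    out = np.empty((T, 14, 3))
    for i, seg in enumerate(model.segments):
        prox = _endpoint(trial, model.proximal[seg])
        dist = _endpoint(trial, model.distal[seg])
        f = model.com_fractions[i]
        out[:, i, :] = prox + f * (dist - prox)
    return out


def _endpoint(trial: MarkerTrial, markers: tuple[str, ...]) -> np.ndarray:
    pts = np.stack([trial.marker(m) for m in markers], axis=0)
    return pts.mean(axis=0)


def differentiate(
    series: np.ndarray, rate: float, filter_cfg: FilterConfig | None = None
) -> np.ndarray:
    """Differentiate a sampled series along axis 0.

    Optional zero-lag low-pass first, then central differences with
    one-sided differences at both ends.  Exact for linear trends.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if filter_cfg is not None and filter_cfg.enabled:
        b, a = butter(filter_cfg.order, filter_cfg.cutoff_hz, fs=rate)
        series = filtfilt(b, a, series, axis=0)
    return np.gradient(series, 1.0 / rate, axis=0)


def eigenfrequency(
    trial: MarkerTrial, model: BodyModel, g: float = GRAVITY
) -> tuple[float, float]:
    """Pendulum eigenfrequency ``w0 = sqrt(g/l)`` and length ``l``.

    ``l`` is the 3-D distance from the mean of the two lateral-malleolus
    markers to the whole-body CoM, both taken at the perturbation-onset
    sample, and is held constant for the trial.
    """
    onset = trial.events.get("perturbation_onset", 0)
    coms3 = segment_coms(trial, model)
    wb = np.einsum("i,ik->k", model.mass_fractions, coms3[onset])
    ankle = 0.5 * (trial.marker("L_malleolus")[onset] + trial.marker("R_malleolus")[onset])
    l = float(np.linalg.norm(wb - ankle))
    if l <= 0:
        raise BodyModelError("non-positive pendulum length")
    return float(np.sqrt(g / l)), l


def extrapolate(
    icom: np.ndarray,
    icom_dot: np.ndarray,
    omega0: float,
    onset: int,
    mass_fractions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segmental and whole-body extrapolated CoMs.

    Returns ``(ixcom, xcom, xcom_ref)`` where ``ixcom`` (T, 14, 2) is the
    onset-referenced segmental xCoM, ``xcom`` (T, 2) is the absolute
    whole-body xCoM (for base-of-support comparison) and ``xcom_ref`` its
    onset-referenced copy.
    """
    if omega0 <= 0:
        raise BodyModelError("omega0 must be positive")
    icom = np.asarray(icom, float)
    icom_dot = np.asarray(icom_dot, float)
    if icom.shape != icom_dot.shape:
        raise ValueError("icom and icom_dot shapes differ")
    ix_abs = icom + icom_dot / omega0
    ixcom = ix_abs - ix_abs[onset]
    xcom = np.einsum("i,tik->tk", np.asarray(mass_fractions, float), ix_abs)
    return ixcom, xcom, xcom - xcom[onset]


def compute_kinematics(
    trial: MarkerTrial,
    model: BodyModel,
    filter_cfg: FilterConfig | None = None,
    g: float = GRAVITY,
) -> SegmentKinematics:
    """Full kinematic pass: markers -> segmental CoMs -> xCoMs (AP/ML)."""
    onset = trial.events.get("perturbation_onset", 0)
    coms3 = segment_coms(trial, model)
    icom = coms3[:, :, :2]  # AP (x) and ML (y)
    icom_dot = differentiate(icom, trial.sampling_rate, filter_cfg)
    com = np.einsum("i,tik->tk", model.mass_fractions, icom)
    com_dot = np.einsum("i,tik->tk", model.mass_fractions, icom_dot)
    omega0, length = eigenfrequency(trial, model, g=g)
    ixcom, xcom, xcom_ref = extrapolate(
        icom, icom_dot, omega0, onset, model.mass_fractions
    )
    return SegmentKinematics(
        icom=icom,
        icom_dot=icom_dot,
        com=com,
        com_dot=com_dot,
        omega0=omega0,
        pendulum_length=length,
        ixcom=ixcom,
        xcom=xcom,
        xcom_ref=xcom_ref,
        onset=onset,
        mass_fractions=model.mass_fractions,
    )
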