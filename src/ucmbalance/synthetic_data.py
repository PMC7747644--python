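"""Synthetic inputs with known task-irrelevant / task-relevant structure.

Two generator levels:

* :func:`generate_deviations` emits raw chain-variable deviation series with
  exactly known null-space ("good") and range-space ("bad") content, for
  testing the variance decomposition in isolation.
* :func:`generate_step_trial` emits a full 19-marker trial of a kinematic
  puppet: quiet stance, an anterior waist-pull translating the upper body
  forward (minimum-jerk profile), and a single forward step of one leg,
  with configurable segment-level wobble injected *exactly* along the
  task-irrelevant / task-relevant subspaces of the xCoM task and additive
  marker noise.  The puppet is kinematic only — no forces or ground
  reaction are modelled.

All randomness flows through one ``numpy.random.Generator`` seeded from the
scenario, so identical scenarios are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .body_model import BodyModel, FilterConfig, compute_kinematics, load_default_model
from .chain_vars import RelativeXcom, reconstruct
from .marker_io import MARKER_NAMES, MarkerTrial
from .phase_events import segment_phases, toe_tip
from .ucm_synergy import null_space_basis


@dataclass
class SynthScenario:
    """Parameters of the synthetic generators.

    ``sigma_tir`` is the per-null-dimension deviation scale (m) and
    ``sigma_tr`` the range-direction scale (m).  ``temporal_model`` is
    ``"iid"`` or ``"ar1"`` (stationary, correlation ``rho`` per sample).
    Step parameters are in seconds / meters; ``marker_noise`` is the
    isotropic per-marker noise scale of the motion-capture emulation.
    """

    seed: int = 0
    n_samples: int = 10_000
    sigma_tir: float = 0.02
    sigma_tr: float = 0.01
    temporal_model: str = "iid"
    rho: float = 0.0
    sampling_rate: float = 100.0
    duration_s: float = 4.0
    onset_time: float = 1.0
    pull_displacement: float = 0.20
    pull_duration: float = 0.9
    step_delay: float = 0.45
    swing_duration: float = 0.5
    step_length: float = 0.30
    swing_lift: float = 0.08
    step_side: str = "right"
    marker_noise: float = 0.0004

    def __post_init__(self) -> None:
        if self.sigma_tir < 0 or self.sigma_tr < 0:
            raise ValueError("deviation scales must be non-negative")
        if self.temporal_model not in ("iid", "ar1"):
            raise ValueError(f"unknown temporal model {self.temporal_model!r}")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.step_side not in ("left", "right"):
            raise ValueError(f"step_side must be left/right, not {self.step_side!r}")
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate and duration_s must be positive")
        if self.swing_lift < 0:
            raise ValueError("swing_lift must be non-negative (floor at z=0)")

    @classmethod
    def step_default(cls, seed: int = 0, **overrides) -> "SynthScenario":
        """Default perturbation-step scenario: smooth postural wobble
        (AR(1), ~1 s time constant) at realistic motion-capture noise."""
        params = dict(
            seed=seed,
            sigma_tir=0.004,
            sigma_tr=0.001,
            temporal_model="ar1",
            rho=0.99,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthScenario":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class DeviationTruth:
    """Exact per-sample decomposition used to build the deviations."""

    tir: np.ndarray  # (N, 14)
    tr: np.ndarray   # (N, 14)


@dataclass
class StepTruth:
    """Scripted ground truth of one generated step trial."""

    onset: int
    bos_crossing: int
    foot_contact: int
    stepping_side: str


def _noise_series(
    rng: np.random.Generator, shape: tuple[int, ...], scenario: SynthScenario
) -> np.ndarray:
    """Unit-variance noise, iid or stationary AR(1) along axis 0."""
    e = rng.standard_normal(shape)
    if scenario.temporal_model == "iid" or scenario.rho == 0:
        return e
    rho = scenario.rho
    out = np.empty_like(e)
    out[0] = e[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + scale * e[t]
    return out


def generate_deviations(
    scenario: SynthScenario,
    jacobian: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, DeviationTruth]:
    """Chain-variable deviations with known subspace content (one direction).

    ``dev[t] = eps z[t] + (J^T/|J|) w[t]`` with ``z ~ N(0, sigma_tir^2 I)``
    in the 13-dimensional null space and ``w ~ N(0, sigma_tr^2)`` along the
    range direction, optionally AR(1)-correlated in time.  At large N the
    decomposition recovers ``MSD_TIR ~ 13 sigma_tir^2`` and
    ``MSD_TR ~ sigma_tr^2``.
    """
    if scenario.sigma_tir == 0 and scenario.sigma_tr == 0:
        raise ValueError("sigma_tir and sigma_tr cannot both be zero")
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    jac = np.asarray(jacobian, dtype=float)
    eps = null_space_basis(jac)
    n = jac.size
    N = scenario.n_samples
    z = scenario.sigma_tir * _noise_series(rng, (N, n - 1), scenario)
    w = scenario.sigma_tr * _noise_series(rng, (N, 1), scenario)
    tir = z @ eps.T
    tr = w * (jac / np.linalg.norm(jac))
    return tir + tr, DeviationTruth(tir=tir, tr=tr)


# ---------------------------------------------------------------------------
# Level (b): the kinematic puppet
# ---------------------------------------------------------------------------

#: Quiet-stance 19-marker template for a 1.62 m subject (x AP fwd, y right,
#: z up, floor at z = 0), meters.  Matches the cohorts' mean stature scale.
STANCE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "head_vertex": (0.00, 0.00, 1.62),
    "L_acromion": (0.00, -0.18, 1.33),
    "R_acromion": (0.00, 0.18, 1.33),
    "L_elbow": (0.01, -0.21, 1.05),
    "R_elbow": (0.01, 0.21, 1.05),
    "L_wrist": (0.02, -0.22, 0.82),
    "R_wrist": (0.02, 0.22, 0.82),
    "L_finger3": (0.02, -0.23, 0.64),
    "R_finger3": (0.02, 0.23, 0.64),
    "L_greater_trochanter": (0.00, -0.11, 0.84),
    "R_greater_trochanter": (0.00, 0.11, 0.84),
    "L_knee": (0.01, -0.11, 0.45),
    "R_knee": (0.01, 0.11, 0.45),
    "L_malleolus": (0.00, -0.11, 0.07),
    "L_heel": (-0.04, -0.11, 0.02),
    "R_malleolus": (0.00, 0.11, 0.07),
    "R_heel": (-0.04, 0.11, 0.02),
    "L_toe": (0.19, -0.11, 0.02),
    "R_toe": (0.19, 0.11, 0.02),
}

_ANTHROPOMETRY = {
    "body_mass": 50.0,          # kg, cohort-scale
    "body_height": 1.62,        # m
    "foot_length": {"left": 0.24, "right": 0.24},
}

#: Markers riding the waist-pull translation (upper body + pelvis).
_PULL_MARKERS = (
    "head_vertex", "L_acromion", "R_acromion", "L_elbow", "R_elbow",
    "L_wrist", "R_wrist", "L_finger3", "R_finger3",
    "L_greater_trochanter", "R_greater_trochanter",
)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1], clipped outside."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _scripted_positions(scenario: SynthScenario) -> tuple[np.ndarray, int, int]:
    """Noise-free puppet motion; returns (positions, onset, contact)."""
    rate = scenario.sampling_rate
    T = int(round(scenario.duration_s * rate))
    t = np.arange(T) / rate
    onset = int(round(scenario.onset_time * rate))
    t0 = scenario.onset_time

    pull = scenario.pull_displacement * _minimum_jerk(
        (t - t0) / scenario.pull_duration
    )
    t_swing = t0 + scenario.step_delay
    tau_sw = (t - t_swing) / scenario.swing_duration
    swing_ap = scenario.step_length * _minimum_jerk(tau_sw)
    swing_z = scenario.swing_lift * np.sin(np.pi * np.clip(tau_sw, 0, 1)) ** 2
    contact = int(round((t_swing + scenario.swing_duration) * rate))
    if contact >= T:
        raise ValueError("trial too short: foot contact beyond last sample")

    pos = np.empty((T, 19, 3))
    for i, name in enumerate(MARKER_NAMES):
        pos[:, i, :] = np.array(STANCE_TEMPLATE[name])

    for name in _PULL_MARKERS:
        pos[:, MARKER_NAMES.index(name), 0] += pull
    # legs lean forward with half the pelvis translation
    for name in ("L_knee", "R_knee"):
        pos[:, MARKER_NAMES.index(name), 0] += 0.5 * pull
    p = scenario.step_side[0].upper()
    for name in (f"{p}_malleolus", f"{p}_heel", f"{p}_toe"):
        idx = MARKER_NAMES.index(name)
        pos[:, idx, 0] += swing_ap
        pos[:, idx, 2] += swing_z
    # swing knee follows pelvis and foot halfway
    knee = MARKER_NAMES.index(f"{p}_knee")
    pos[:, knee, 0] += 0.5 * swing_ap

    foot_idx = [MARKER_NAMES.index(f"{s}_{m}") for s in "LR" for m in ("heel", "toe")]
    if np.min(pos[:, foot_idx, 2]) < -1e-9:
        raise ValueError("step parameters drive foot markers through the floor")
    return pos, onset, contact


def _wobble_marker_offsets(
    rel_wobble: np.ndarray, model: BodyModel
) -> np.ndarray:
    """Map chain-variable wobble (T, 14, 2) to marker AP/ML displacements.

    Solves, segment by segment from the trunk outward, for the distal
    marker displacement that shifts each segment's CoM by exactly the
    requested absolute offset; feet (marker-disconnected from the shank)
    are displaced rigidly.  The resulting segmental *position* CoM shifts
    equal the requested offsets, so position-plus-velocity xCoM wobble
    built from a null-space series stays exactly in the null space.
    """
    o = reconstruct(RelativeXcom(irxcom=rel_wobble, model=model))  # (T, 14, 2)
    T = o.shape[0]
    d = np.zeros((T, 19, 2))

    def seg(name: str) -> np.ndarray:
        return o[:, model.index(name), :]

    def set_marker(name: str, val: np.ndarray) -> None:
        d[:, MARKER_NAMES.index(name), :] = val

    def f(name: str) -> float:
        return float(model.com_fractions[model.index(name)])

    for mk in ("L_acromion", "R_acromion", "L_greater_trochanter",
               "R_greater_trochanter"):
        set_marker(mk, seg("trunk"))
    set_marker("head_vertex", (seg("head") - (1 - f("head")) * seg("trunk")) / f("head"))
    for s in "LR":
        ua, fa, ha = f(f"{s}_upper_arm"), f(f"{s}_forearm"), f(f"{s}_hand")
        d_elbow = (seg(f"{s}_upper_arm") - (1 - ua) * seg("trunk")) / ua
        set_marker(f"{s}_elbow", d_elbow)
        d_wrist = (seg(f"{s}_forearm") - (1 - fa) * d_elbow) / fa
        set_marker(f"{s}_wrist", d_wrist)
        set_marker(f"{s}_finger3", (seg(f"{s}_hand") - (1 - ha) * d_wrist) / ha)
        th, sh = f(f"{s}_thigh"), f(f"{s}_shank")
        d_knee = (seg(f"{s}_thigh") - (1 - th) * seg("trunk")) / th
        set_marker(f"{s}_knee", d_knee)
        set_marker(f"{s}_malleolus", (seg(f"{s}_shank") - (1 - sh) * d_knee) / sh)
        set_marker(f"{s}_heel", seg(f"{s}_foot"))
        set_marker(f"{s}_toe", seg(f"{s}_foot"))
    return d


def generate_step_trial(
    scenario: SynthScenario,
    model: BodyModel | None = None,
    subject_id: str = "synthetic",
    group_label: str = "synthetic",
) -> tuple[MarkerTrial, StepTruth]:
    """Generate one full 19-marker perturbation-step trial.

    Returns the trial (with ``perturbation_onset`` annotated) and the
    scripted ground truth.  The ground-truth base-of-support crossing is
    computed on the noise-free, wobble-free puppet with the same analysis
    geometry, so detector recovery can be scored against it.
    """
    if model is None:
        model = load_default_model()
    rng = np.random.default_rng(scenario.seed)
    pos, onset, contact = _scripted_positions(scenario)
    T = pos.shape[0]

    # ground truth from the clean puppet
    clean = MarkerTrial(
        subject_id=subject_id,
        group_label=group_label,
        sampling_rate=scenario.sampling_rate,
        positions=pos,
        events={"perturbation_onset": onset},
        anthropometry=dict(_ANTHROPOMETRY),
    )
    kin = compute_kinematics(clean, model, FilterConfig(enabled=False))
    contralateral = "left" if scenario.step_side == "right" else "right"
    tip = toe_tip(clean, contralateral, at_sample=onset)
    truth_seg = segment_phases(
        kin.xcom[:, 0], tip, onset, contact, stepping_side=scenario.step_side
    )
    truth = StepTruth(
        onset=onset,
        bos_crossing=truth_seg.bos_crossing,
        foot_contact=contact,
        stepping_side=scenario.step_side,
    )

    noisy = np.array(pos)
    if scenario.sigma_tir > 0 or scenario.sigma_tr > 0:
        from .ucm_synergy import build_jacobian

        jac = build_jacobian(model)
        eps = null_space_basis(jac)
        jhat = jac / np.linalg.norm(jac)
        rel = np.zeros((T, 14, 2))
        for k in range(2):  # AP, ML
            z = scenario.sigma_tir * _noise_series(rng, (T, 13), scenario)
            w = scenario.sigma_tr * _noise_series(rng, (T, 1), scenario)
            rel[:, :, k] = z @ eps.T + w * jhat
        noisy[:, :, :2] += _wobble_marker_offsets(rel, model)
    if scenario.marker_noise > 0:
        noisy += scenario.marker_noise * rng.standard_normal(noisy.shape)

    trial = MarkerTrial(
        subject_id=subject_id,
        group_label=group_label,
        sampling_rate=scenario.sampling_rate,
        positions=noisy,
        events={"perturbation_onset": onset},
        anthropometry=dict(_ANTHROPOMETRY),
    )
    return trial, truth
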