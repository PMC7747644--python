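"""Event detection and Phase I / Phase II segmentation.

Phase I runs from perturbation onset to the sample at which the whole-body
AP xCoM first exceeds the forward edge of the base of support — the toe
tip of the contralateral (non-stepping) foot, fixed at the onset sample.
Phase II runs from that crossing to foot-ground contact of the stepping
foot.  Annotated events in the trial sidecar always override the kinematic
detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import BodyModel, FilterConfig, differentiate, segment_coms
from .marker_io import MarkerTrial


class PhaseError(ValueError):
    pass


@dataclass
class PhaseSegmentation:
    """Sample-index segmentation of one stepping response.

    ``phase1``/``phase2`` are half-open ``(start, stop)`` windows:
    Phase I = [onset, bos_crossing), Phase II = [bos_crossing, contact].
    """

    onset: int
    bos_crossing: int
    foot_contact: int
    stepping_side: str
    toe_tip_ap: float

    def __post_init__(self) -> None:
        if not (self.onset < self.bos_crossing < self.foot_contact):
            raise PhaseError(
                f"need onset < crossing < contact, got "
                f"{self.onset}, {self.bos_crossing}, {self.foot_contact}"
            )
        if self.bos_crossing - self.onset < 2 or self.foot_contact - self.bos_crossing + 1 < 2:
            raise PhaseError("phase window shorter than 2 samples")

    @property
    def phase1(self) -> tuple[int, int]:
        return (self.onset, self.bos_crossing)

    @property
    def phase2(self) -> tuple[int, int]:
        return (self.bos_crossing, self.foot_contact + 1)


def toe_tip(
    trial: MarkerTrial, side: str, foot_length: float | None = None,
    at_sample: int | None = None,
) -> float:
    """AP coordinate of the anatomical toe tip of one foot.

    The heel-to-toe marker vector is rescaled to the measured foot length,
    so the tip lies beyond the toe marker (markers sit proximal of the
    anatomical tip).  Without a measured foot length the marker distance is
    used and a warning is emitted.  Evaluated at the perturbation-onset
    sample unless ``at_sample`` is given.
    """
    if at_sample is None:
        at_sample = trial.events.get("perturbation_onset", 0)
    heel = trial.marker(f"{side[0].upper()}_heel")[at_sample]
    toe = trial.marker(f"{side[0].upper()}_toe")[at_sample]
    vec = toe - heel
    norm = float(np.linalg.norm(vec))
    if norm < 1e-9:
        raise PhaseError(f"coincident heel/toe markers on {side} foot")
    if foot_length is None:
        foot_length = trial.foot_length(side)
    if foot_length is None:
        import warnings

        warnings.warn(
            f"no measured foot length for {side} side; using heel-toe marker "
            "distance", stacklevel=2,
        )
        foot_length = norm
    if foot_length <= 0:
        raise PhaseError("foot_length must be positive")
    tip = heel + vec * (foot_length / norm)
    return float(tip[0])


def detect_onset(
    trial: MarkerTrial,
    model: BodyModel,
    velocity_threshold: float = 0.05,
    sustain_s: float = 0.05,
) -> int:
    """Fallback perturbation-onset detector.

    First sample at which the trunk-CoM AP velocity exceeds
    ``velocity_threshold`` (m/s) and stays above it for ``sustain_s``
    seconds.  Used only when no ``perturbation_onset`` event is annotated.
    """
    coms3 = segment_coms(trial, model)
    trunk_ap = coms3[:, model.index("trunk"), 0]
    v = differentiate(trunk_ap[:, None], trial.sampling_rate, FilterConfig())[:, 0]
    n_sustain = max(1, int(round(sustain_s * trial.sampling_rate)))
    above = v > velocity_threshold
    for t in range(len(above) - n_sustain + 1):
        if above[t : t + n_sustain].all():
            return t
    raise PhaseError("no perturbation onset found (trunk never accelerates)")


def detect_stepping_side(trial: MarkerTrial, onset: int) -> str:
    """Side whose toe marker travels farther forward after onset.

    An annotated ``stepping_side`` on the trial overrides detection.  If
    neither foot displaces more than 1 cm the trial has no step.
    """
    if trial.stepping_side is not None:
        return trial.stepping_side
    disp = {}
    for side in ("left", "right"):
        toe_ap = trial.marker(f"{side[0].upper()}_toe")[:, 0]
        disp[side] = float(np.max(toe_ap[onset:]) - toe_ap[onset])
    if max(disp.values()) <= 0.01:
        raise PhaseError("no step detected: neither toe displaces > 1 cm")
    return max(disp, key=disp.get)


def detect_foot_contact(
    trial: MarkerTrial,
    side: str,
    after: int,
    height_tol: float = 0.01,
    velocity_tol: float = 0.05,
) -> int:
    """Kinematic landing detector for the stepping foot.

    First sample after the swing apex at which the heel or the toe marker
    has returned to within ``height_tol`` (m) of its pre-onset vertical
    baseline with vertical speed below ``velocity_tol`` (m/s).  An
    annotated ``foot_contact`` event is used verbatim.
    """
    if "foot_contact" in trial.events:
        return int(trial.events["foot_contact"])
    prefix = side[0].upper()
    T = trial.n_samples
    candidates = []
    for mk in (f"{prefix}_heel", f"{prefix}_toe"):
        z = trial.marker(mk)[:, 2]
        vz = differentiate(z[:, None], trial.sampling_rate, FilterConfig())[:, 0]
        baseline = float(np.mean(z[: max(after, 1)]))
        apex = after + int(np.argmax(z[after:]))
        ok = (np.abs(z - baseline) <= height_tol) & (np.abs(vz) < velocity_tol)
        hits = np.flatnonzero(ok[apex + 1 :])
        if hits.size:
            candidates.append(apex + 1 + int(hits[0]))
    if not candidates:
        raise PhaseError(f"no foot contact found for {side} foot before sample {T - 1}")
    return min(candidates)


def segment_phases(
    xcom_ap: np.ndarray,
    toe_tip_ap: float,
    onset: int,
    contact: int,
    stepping_side: str = "right",
) -> PhaseSegmentation:
    """Split a trial at the first strict exceedance of the BoS edge.

    ``xcom_ap`` must be the absolute (non-referenced) whole-body AP xCoM.
    """
    xcom_ap = np.asarray(xcom_ap, dtype=float)
    if not onset < contact <= len(xcom_ap) - 1:
        raise PhaseError(f"need onset < contact <= T-1, got {onset}, {contact}")
    beyond = np.flatnonzero(xcom_ap[onset + 1 : contact + 1] > toe_tip_ap)
    if beyond.size == 0:
        raise PhaseError("xCoM never left BoS before foot contact")
    crossing = onset + 1 + int(beyond[0])
    return PhaseSegmentation(
        onset=onset,
        bos_crossing=crossing,
        foot_contact=contact,
        stepping_side=stepping_side,
        toe_tip_ap=float(toe_tip_ap),
    )


def segment_trial(
    trial: MarkerTrial,
    model: BodyModel,
    xcom_ap: np.ndarray,
    height_tol: float = 0.01,
    velocity_tol: float = 0.05,
) -> PhaseSegmentation:
    """End-to-end segmentation of one trial (detectors + overrides)."""
    onset = trial.events.get("perturbation_onset")
    if onset is None:
        onset = detect_onset(trial, model)
    onset = int(onset)
    side = detect_stepping_side(trial, onset)
    contact = detect_foot_contact(
        trial, side, after=onset, height_tol=height_tol, velocity_tol=velocity_tol
    )
    contralateral = "left" if side == "right" else "right"
    tip = toe_tip(trial, contralateral, at_sample=onset)
    return segment_phases(xcom_ap, tip, onset, contact, stepping_side=side)
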