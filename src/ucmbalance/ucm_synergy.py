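"""Uncontrolled-manifold variance decomposition and synergy indices.

The whole-body xCoM is a linear function of the relative chain variables,
``xCoM = J . iRxCoM``, with a time-invariant 1 x 14 Jacobian whose entry
for a segment is the summed mass fraction of that segment and everything
distal to it (the trunk entry is therefore 1).  Deviations of the chain
variables are split by orthogonal projection onto the Jacobian's null
space (task-irrelevant: leaves the whole-body xCoM unchanged) and its
orthogonal complement (task-relevant).  Mean squared deviations in the
two subspaces give the synergy index

    SYN = (MSD_TIR / (n - d) - MSD_TR / d) / (MSD_TIR + MSD_TR),

bounded in [-1, 1/(n-d)] for n = 14 elemental variables and d = 1
performance variable, and the per-segment contribution

    iSYN_i = (iMSD_TIR_i - iMSD_TR_i) / (iMSD_TIR_i + iMSD_TR_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space as _null_space

from .body_model import BodyModel


class DegenerateTrialError(ValueError):
    """Raised when a phase window contains no deviation at all."""


@dataclass
class UcmResult:
    """UCM decomposition of one phase window in one direction."""

    jacobian: np.ndarray    # (14,)
    basis: np.ndarray       # (14, 13) orthonormal null-space basis
    tir: np.ndarray         # (N, 14) task-irrelevant component, m
    tr: np.ndarray          # (N, 14) task-relevant component, m
    imsd_tir: np.ndarray    # (14,) m^2
    imsd_tr: np.ndarray     # (14,) m^2
    msd_tir: float          # m^2
    msd_tr: float           # m^2
    syn: float              # dimensionless
    isyn: np.ndarray        # (14,), NaN where a segment has zero deviation
    n_elem: int = 14
    d_perf: int = 1

    @property
    def n_samples(self) -> int:
        return self.tir.shape[0]


def build_jacobian(model: BodyModel) -> np.ndarray:
    """Constant 1 x 14 Jacobian of whole-body xCoM w.r.t. chain variables.

    A unit change of segment j's relative variable translates j and every
    segment distal to j, so the entry is the sum of their mass fractions.
    The same row applies to AP and ML.
    """
    row = np.empty(14)
    for i, seg in enumerate(model.segments):
        members = [seg, *model.descendants(seg)]
        row[i] = sum(model.mass_fraction(s) for s in members)
    return row


def null_space_basis(jacobian: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the Jacobian's null space, shape ``(n, n-d)``.

    Computed by SVD; columns satisfy ``J @ eps = 0`` and ``eps.T @ eps = I``
    to machine precision.
    """
    j = np.atleast_2d(np.asarray(jacobian, dtype=float))
    if not np.any(j):
        raise ValueError("zero Jacobian has no meaningful null space")
    eps = _null_space(j)
    if eps.shape != (j.shape[1], j.shape[1] - j.shape[0]):
        raise ValueError(f"unexpected null-space dimension {eps.shape}")
    return eps


def project(deviations: np.ndarray, basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split reference-subtracted deviations into (task-irrelevant,
    task-relevant) components.

    ``tir[t] = eps eps^T dev[t]`` and ``tr[t] = dev[t] - tir[t]``; the pair
    is an exact, orthogonal decomposition of the input.
    """
    dev = np.asarray(deviations, dtype=float)
    if dev.ndim != 2 or dev.shape[1] != basis.shape[0]:
        raise ValueError(
            f"deviations {dev.shape} incompatible with basis {basis.shape}"
        )
    tir = (dev @ basis) @ basis.T
    return tir, dev - tir


def msd(components: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean squared deviation per segment and its total over segments."""
    comp = np.asarray(components, dtype=float)
    if comp.ndim != 2 or comp.shape[0] < 1:
        raise ValueError("need a non-empty (N, n) component array")
    per_segment = np.mean(comp**2, axis=0)
    return per_segment, float(per_segment.sum())


def synergy_index(msd_tir: float, msd_tr: float, n: int = 14, d: int = 1) -> float:
    """Whole-body synergy index; positive means variability is preferentially
    channelled into the task-irrelevant subspace."""
    total = msd_tir + msd_tr
    if total <= 0:
        raise DegenerateTrialError("degenerate trial: no deviation")
    return (msd_tir / (n - d) - msd_tr / d) / total


def segment_synergy(imsd_tir: np.ndarray, imsd_tr: np.ndarray) -> np.ndarray:
    """Per-segment synergy contribution in [-1, 1].

    Segments with zero deviation in both subspaces are undefined and
    returned as NaN; callers report them as missing.
    """
    a = np.asarray(imsd_tir, dtype=float)
    b = np.asarray(imsd_tr, dtype=float)
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (a - b) / denom
    out[denom <= 0] = np.nan
    return out


def analyze_deviations(
    deviations: np.ndarray,
    jacobian: np.ndarray,
    n: int = 14,
    d: int = 1,
    basis: np.ndarray | None = None,
) -> UcmResult:
    """Run the full decomposition on one window of reference-subtracted
    deviations (one direction)."""
    if basis is None:
        basis = null_space_basis(jacobian)
    tir, tr = project(deviations, basis)
    imsd_tir, msd_tir = msd(tir)
    imsd_tr, msd_tr = msd(tr)
    return UcmResult(
        jacobian=np.asarray(jacobian, float),
        basis=basis,
        tir=tir,
        tr=tr,
        imsd_tir=imsd_tir,
        imsd_tr=imsd_tr,
        msd_tir=msd_tir,
        msd_tr=msd_tr,
        syn=synergy_index(msd_tir, msd_tr, n=n, d=d),
        isyn=segment_synergy(imsd_tir, imsd_tr),
        n_elem=n,
        d_perf=d,
    )
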