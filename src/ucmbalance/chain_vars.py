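"""Relative (chain-differenced) segmental xCoM variables.

The 14 absolute segmental xCoMs are not mutually independent: moving the
trunk carries every limb with it.  Differencing each segment against its
proximal neighbour along the five chains (head; both arms; both legs)
rooted at the trunk yields independent elemental variables.  The trunk row
is kept absolute, so the map is a bijection — ``reconstruct`` is the
cumulative sum from the trunk out to each leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyModel


class TopologyError(ValueError):
    pass


@dataclass
class RelativeXcom:
    """Relative chain variables, shape ``(T, 14, 2)`` (AP, ML), meters.

    ``reference_vector`` records the ``(14, 2)`` snapshot subtracted by
    :func:`reference_subtract` (``None`` before any referencing).
    """

    irxcom: np.ndarray
    model: BodyModel
    reference_vector: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.irxcom = np.asarray(self.irxcom, dtype=float)
        if self.irxcom.ndim != 3 or self.irxcom.shape[1] != 14:
            raise ValueError(f"irxcom must be (T, 14, k), got {self.irxcom.shape}")


def decompose(ixcom: np.ndarray, model: BodyModel) -> RelativeXcom:
    """Absolute segmental xCoMs -> relative chain variables.

    ``irxcom_i = ixcom_i - ixcom_parent(i)``; the trunk keeps its absolute
    value.  Inverse of :func:`reconstruct`.
    """
    ixcom = np.asarray(ixcom, dtype=float)
    if ixcom.ndim != 3 or ixcom.shape[1] != 14:
        raise ValueError(f"ixcom must be (T, 14, k), got {ixcom.shape}")
    rel = np.array(ixcom)
    for i, seg in enumerate(model.segments):
        parent = model.parent.get(seg)
        if parent is not None:
            rel[:, i, :] = ixcom[:, i, :] - ixcom[:, model.index(parent), :]
    return RelativeXcom(irxcom=rel, model=model)


def reconstruct(rel: RelativeXcom) -> np.ndarray:
    """Relative chain variables -> absolute segmental xCoMs (cumulative sum
    along each chain from trunk to leaf)."""
    model = rel.model
    out = np.array(rel.irxcom)
    for seg in model.topological_order():
        parent = model.parent.get(seg)
        if parent is not None:
            out[:, model.index(seg), :] += out[:, model.index(parent), :]
    return out


def reference_subtract(rel: RelativeXcom, ref_sample: int) -> RelativeXcom:
    """Subtract the snapshot at ``ref_sample`` from every frame.

    Phase I uses the perturbation-onset sample as reference; Phase II uses
    the sample at which the whole-body xCoM crosses the base-of-support
    edge.
    """
    T = rel.irxcom.shape[0]
    if not (0 <= ref_sample < T):
        raise IndexError(f"reference sample {ref_sample} outside [0, {T - 1}]")
    ref = rel.irxcom[ref_sample].copy()
    return RelativeXcom(
        irxcom=rel.irxcom - ref, model=rel.model, reference_vector=ref
    )
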