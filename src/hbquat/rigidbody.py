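"""Rigid-body description of the quaternary transition.

The T->R transition is, to first order, a 12-15 degree rotation of one
alpha/beta dimer relative to the other.  This module quantifies that
motion directly: after anchoring the alpha1/beta1 dimer of a frame onto
the reference, the orientation of the alpha2/beta2 dimer is tracked
either through the axis connecting the alpha2 and beta2 centers of mass
(a cheap one-vector marker) or through the full optimal rotation that
maps the dimer onto its reference orientation (axis + angle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import (
    SelectionSpec,
    TetramerModel,
    center_of_mass,
    common_selection,
    kabsch_superpose,
)
from .subspace import ProjectionSeries

__all__ = [
    "DimerAxis",
    "RotationDescriptor",
    "dimer_axis",
    "axis_rotation_angle",
    "minimal_rotation_between_axes",
    "dimer_rotation_angle",
    "rotation_timeseries",
]

_ANCHOR = SelectionSpec(mode="backbone", subunits=("alpha1", "beta1"),
                        include_hemes=False)
_TARGET = SelectionSpec(mode="backbone", subunits=("alpha2", "beta2"),
                        include_hemes=False)


@dataclass(frozen=True)
class DimerAxis:
    """Line from the alpha2 center of mass to the beta2 center of mass."""

    origin: np.ndarray  # COM of alpha2, nm
    tip: np.ndarray  # COM of beta2, nm

    def __post_init__(self) -> None:
        if np.linalg.norm(self.tip - self.origin) < 1e-12:
            raise ValueError("degenerate dimer axis (zero length)")

    @property
    def direction(self) -> np.ndarray:
        d = self.tip - self.origin
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class RotationDescriptor:
    """Unit rotation axis and angle (degrees, in [0, 180]).

    ``axis`` is ``None`` when the rotation angle is (numerically) zero and
    the axis therefore undefined.
    """

    axis: np.ndarray | None
    angle: float

    @property
    def axis_defined(self) -> bool:
        return self.axis is not None


def dimer_axis(frame: TetramerModel,
               reference: TetramerModel | None = None) -> DimerAxis:
    """COM axis of the alpha2/beta2 dimer, in the reference's frame.

    If a reference is given, the frame's alpha1/beta1 backbone is first
    superposed onto the reference's alpha1/beta1 backbone, which makes the
    result invariant under global rigid transformations of the frame.
    """
    if reference is not None:
        ia, ir = common_selection(frame, reference, _ANCHOR)
        sup = kabsch_superpose(frame.coords[ia], reference.coords[ir])
        frame = frame.transformed(sup.rotation, sup.translation)
    return DimerAxis(origin=center_of_mass(frame, "alpha2"),
                     tip=center_of_mass(frame, "beta2"))


def axis_rotation_angle(frame_axis: DimerAxis,
                        reference_axis: DimerAxis) -> float:
    """Angle between two dimer axes, in degrees."""
    cosang = float(np.clip(np.dot(frame_axis.direction,
                                  reference_axis.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def minimal_rotation_between_axes(a: DimerAxis,
                                  b: DimerAxis) -> RotationDescriptor:
    """Smallest rotation mapping direction ``a`` onto direction ``b``.

    The axis is the normalized cross product of the two directions.  For
    parallel directions the angle is zero and the axis undefined (flagged
    by ``axis=None``); antiparallel directions leave the axis ambiguous
    and raise an error.
    """
    da, db = a.direction, b.direction
    angle = axis_rotation_angle(a, b)
    cross = np.cross(da, db)
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        if np.dot(da, db) < 0:
            raise ValueError(
                "antiparallel axes: minimal rotation axis is ambiguous")
        return RotationDescriptor(axis=None, angle=0.0)
    return RotationDescriptor(axis=cross / norm, angle=angle)


def dimer_rotation_angle(frame: TetramerModel,
                         reference: TetramerModel) -> RotationDescriptor:
    """Full rigid-body rotation of the alpha2/beta2 dimer.

    The frame's alpha1/beta1 backbone is superposed onto the reference's;
    the optimal rotation mapping the frame's (anchored) alpha2/beta2
    backbone onto the reference's alpha2/beta2 backbone is then extracted
    as axis + angle.  Between the R and T crystal structures this is the
    classic 12-15 degree quaternary rotation.
    """
    ia1, ir1 = common_selection(frame, reference, _ANCHOR)
    sup = kabsch_superpose(frame.coords[ia1], reference.coords[ir1])
    anchored = frame.transformed(sup.rotation, sup.translation)
    ia2, ir2 = common_selection(frame, reference, _TARGET)
    sup2 = kabsch_superpose(anchored.coords[ia2], reference.coords[ir2])
    rotvec = Rotation.from_matrix(sup2.rotation).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < 1e-9:
        return RotationDescriptor(axis=None, angle=angle)
    return RotationDescriptor(axis=rotvec / np.linalg.norm(rotvec),
                              angle=angle)


def rotation_timeseries(frames: Sequence[TetramerModel],
                        reference: TetramerModel) -> ProjectionSeries:
    """Per-frame COM-axis rotation angle versus the reference (degrees)."""
    ref_axis = dimer_axis(reference)
    times = np.array([f.frame_time for f in frames])
    values = np.array([
        axis_rotation_angle(dimer_axis(f, reference), ref_axis)
        for f in frames
    ])
    return ProjectionSeries(frame_times=times, values=values,
                            coordinate_id="axis_angle", kind="degrees")
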