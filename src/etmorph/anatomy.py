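"""Cranial landmark vocabulary, reference-plane definitions, and the
Eustachian-tube measurement itself.

The three reference planes are all anchored on the upper margins of both
external auditory canals (EAC) plus one anterior landmark:

====================  =====================================================
Reid's standard       right infraorbital margin + both EAC upper margins
Frankfort             left infraorbital margin + both EAC upper margins
Ku-Copson (KC)        right mandibular fossa + both EAC upper margins
====================  =====================================================

The Ku-Copson mandibular-fossa plane exists because limited-window cone-beam
CT temporal-bone scans usually exclude the orbits: the mandibular fossa sits
next to the middle ear and is almost always in frame, so it can replace the
infraorbital margin as the anterior anchor.

Per ear, the ET length is the Euclidean chord from the pharyngeal orifice
(at the torus tubarius) to the tympanic orifice, and the ET angle is the
3D line–plane angle of that chord against the chosen reference plane.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import GeometryError, MissingLandmarkError, ValidationError
from .geometry import (
    Point3,
    ReferencePlane,
    distance_mm,
    line_plane_angle_deg,
    plane_from_points,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkId",
    "PlaneType",
    "Side",
    "LandmarkSet",
    "ETMeasurement",
    "build_reference_plane",
    "measure_et",
    "measure_cohort",
]


class LandmarkId(str, enum.Enum):
    """The closed set of named cranial landmarks used by the pipeline."""

    IOM_R = "IOM_R"  #: right infraorbital margin
    IOM_L = "IOM_L"  #: left infraorbital margin
    MF_R = "MF_R"    #: right mandibular fossa
    MF_L = "MF_L"    #: left mandibular fossa
    EAC_R = "EAC_R"  #: upper margin of right external auditory canal
    EAC_L = "EAC_L"  #: upper margin of left external auditory canal
    PO_R = "PO_R"    #: pharyngeal orifice of right ET (torus tubarius)
    PO_L = "PO_L"    #: pharyngeal orifice of left ET
    TO_R = "TO_R"    #: tympanic orifice of right ET
    TO_L = "TO_L"    #: tympanic orifice of left ET

    @classmethod
    def parse(cls, name: str) -> "LandmarkId":
        try:
            return cls(name)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown landmark id {name!r}; valid ids: {valid}"
            ) from None


class PlaneType(str, enum.Enum):
    """Reference-plane definitions as ordered landmark triplets
    (right-sided anterior anchor first, then EAC_R, EAC_L)."""

    REIDS = "reids"
    FRANKFORT = "frankfort"
    KC_MFP = "kc"

    @property
    def landmarks(self) -> tuple[LandmarkId, LandmarkId, LandmarkId]:
        return _PLANE_LANDMARKS[self]

    @classmethod
    def parse(cls, name: str) -> "PlaneType":
        key = name.strip().lower()
        key = {"rsp": "reids", "mfp": "kc", "kc_mfp": "kc"}.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown plane type {name!r}; valid: reids (rsp), frankfort, kc (mfp)"
            ) from None


_PLANE_LANDMARKS = {
    PlaneType.REIDS: (LandmarkId.IOM_R, LandmarkId.EAC_R, LandmarkId.EAC_L),
    PlaneType.FRANKFORT: (LandmarkId.IOM_L, LandmarkId.EAC_R, LandmarkId.EAC_L),
    PlaneType.KC_MFP: (LandmarkId.MF_R, LandmarkId.EAC_R, LandmarkId.EAC_L),
}


class Side(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"

    @property
    def suffix(self) -> str:
        return "R" if self is Side.RIGHT else "L"

    @classmethod
    def parse(cls, name: str) -> "Side":
        key = name.strip().lower()
        key = {"r": "right", "l": "left"}.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(f"unknown side {name!r}; valid: right, left") from None


@dataclass(frozen=True)
class LandmarkSet:
    """Named landmark → coordinate map for one subject (mm, LPS frame)."""

    subject_id: str
    landmarks: Mapping[LandmarkId, Point3]

    def __post_init__(self) -> None:
        lm = {LandmarkId.parse(k) if not isinstance(k, LandmarkId) else k:
              (v if isinstance(v, Point3) else Point3.from_array(v))
              for k, v in dict(self.landmarks).items()}
        # LPS sanity check: +x is patient-left, so right-sided landmarks sit
        # at smaller x in canonical orientation. A warning, not an error: a
        # rigidly re-posed head is still measurable (all measurements are
        # rigid-motion invariant), but flipped sides usually mean mislabelled
        # input.
        for rid, lid in ((LandmarkId.EAC_R, LandmarkId.EAC_L),
                         (LandmarkId.IOM_R, LandmarkId.IOM_L),
                         (LandmarkId.MF_R, LandmarkId.MF_L)):
            if rid in lm and lid in lm and lm[rid].x >= lm[lid].x:
                warnings.warn(
                    f"subject {self.subject_id!r}: {rid.value} has x >= {lid.value}; "
                    "either the head is not in canonical LPS orientation or the "
                    "sides are mislabelled",
                    stacklevel=2,
                )
        object.__setattr__(self, "landmarks", lm)

    def __contains__(self, lid: LandmarkId) -> bool:
        return lid in self.landmarks

    def get(self, lid: LandmarkId, context: str = "") -> Point3:
        if lid not in self.landmarks:
            where = f" (required for {context})" if context else ""
            raise MissingLandmarkError(
                f"subject {self.subject_id!r} is missing landmark {lid.value}{where}"
            )
        return self.landmarks[lid]

    def has_ear(self, side: Side) -> bool:
        return (LandmarkId(f"PO_{side.suffix}") in self.landmarks
                and LandmarkId(f"TO_{side.suffix}") in self.landmarks)


@dataclass(frozen=True)
class ETMeasurement:
    """One ear's ET angle (degrees, in [0, 90]) and length (mm, > 0)."""

    subject_id: str
    side: Side
    plane: PlaneType
    angle_deg: float
    length_mm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg <= 90.0):
            raise ValidationError(f"ET angle {self.angle_deg} outside [0, 90] degrees")
        if not self.length_mm > 0.0:
            raise ValidationError(f"ET length {self.length_mm} must be positive")


def build_reference_plane(landmarks: LandmarkSet, plane: PlaneType) -> ReferencePlane:
    """Construct the requested reference plane from a subject's landmarks.

    Raises :class:`MissingLandmarkError` naming the absent landmark and the
    plane type, or :class:`GeometryError` if the triplet is degenerate.
    """
    ids = plane.landmarks
    pts = [landmarks.get(lid, context=f"{plane.name} plane") for lid in ids]
    return plane_from_points(*pts, labels=tuple(lid.value for lid in ids))


def measure_et(landmarks: LandmarkSet, side: Side | str, plane: PlaneType | str) -> ETMeasurement:
    """Measure one ear: chord length between the ET orifices and the chord's
    angle against the reference plane.

    Both ears are measured against the single (right-anchored) plane; no
    mirrored left-anchored plane is built.
    """
    side = Side.parse(side) if not isinstance(side, Side) else side
    plane = PlaneType.parse(plane) if not isinstance(plane, PlaneType) else plane
    po = landmarks.get(LandmarkId(f"PO_{side.suffix}"), context=f"{side.value} ET")
    to = landmarks.get(LandmarkId(f"TO_{side.suffix}"), context=f"{side.value} ET")
    ref = build_reference_plane(landmarks, plane)
    length = distance_mm(po, to)
    if length == 0.0:
        raise GeometryError(
            f"subject {landmarks.subject_id!r}: PO_{side.suffix} and TO_{side.suffix} "
            "coincide; ET segment has zero length"
        )
    angle = line_plane_angle_deg(po, to, ref)
    return ETMeasurement(landmarks.subject_id, side, plane, angle, length)


def measure_cohort(cohort: Iterable[LandmarkSet], plane: PlaneType | str) -> list[ETMeasurement]:
    """Measure every available ear of every subject.

    Complete subjects contribute two measurements (right before left);
    subjects missing an ear's orifice landmarks contribute the available ear
    only, with a warning. Ordering is stable (input subject order).
    """
    plane = PlaneType.parse(plane) if not isinstance(plane, PlaneType) else plane
    subjects = list(cohort)
    if not subjects:
        raise ValidationError("cannot measure an empty cohort")
    out: list[ETMeasurement] = []
    for lm in subjects:
        for side in (Side.RIGHT, Side.LEFT):
            if not lm.has_ear(side):
                msg = (f"subject {lm.subject_id!r}: skipping {side.value} ear "
                       "(missing orifice landmarks)")
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
                continue
            out.append(measure_et(lm, side, plane))
    return out
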