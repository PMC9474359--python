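"""Synthetic subject and cohort generation.

Each synthetic subject is a skull-landmark set constructed so that measuring
it with the anatomy module recovers a known ground truth exactly (when no
landmark jitter is added):

1. Per ear, a true angle θ* and true length L* are drawn from truncated
   normal distributions whose means/SDs are the cohort preset's parameters.
2. The tympanic orifice (TO) sits at its template position; the pharyngeal
   orifice (PO) is placed at distance L* from TO so that the chord makes
   angle θ* with the template's Ku-Copson (KC) mandibular-fossa plane, with
   the chord's in-plane azimuth drawn uniformly in the anatomically
   forward-medial quadrant (the ET runs antero-medially and inferiorly from
   the middle ear toward the nasopharynx).
3. Optional i.i.d. Gaussian jitter on every landmark coordinate emulates
   rater disagreement in landmark placement (raters disagree on where a
   landmark is, not on the arithmetic that follows).

Ground truth is defined relative to the KC plane of the noise-free template.
The template's ``mfp_tilt_deg`` rotates the mandibular fossae about the
interaural (EAC–EAC) axis, tilting the KC plane relative to Reid's plane by
that dihedral angle; because the chord azimuth is uniform on a quadrant, the
cohort-mean angle measured against Reid's plane then differs from the KC
truth by ≈ (2/π)·tilt (first order). Positive tilt tips the anterior edge of
the KC plane inferiorly, which raises Reid's-referenced angles.

Template coordinates are plausibility-only plumbing (EACs ±60 mm laterally,
mandibular fossae ~8 mm anterior, infraorbital margins ~55 mm anterior);
they carry no anthropometric claim and are overridable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .anatomy import LandmarkId, LandmarkSet, PlaneType, Side, build_reference_plane
from .errors import GenerationError, PresetError, ValidationError
from .geometry import Point3, plane_from_points
from .io import atomic_write

__all__ = [
    "SkullTemplate",
    "CohortPreset",
    "EarTruth",
    "SubjectRecord",
    "Cohort",
    "default_template",
    "get_preset",
    "list_presets",
    "generate_subject",
    "generate_cohort",
    "rasterize_to_volume",
]

#: rejection-sampling budget for truncated-normal draws
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class SkullTemplate:
    """Mean landmark coordinates (mm, LPS) plus the KC-plane tilt.

    ``mfp_tilt_deg`` is the dihedral angle from Reid's plane to the KC plane
    about the interaural axis, applied by rotating the mandibular fossae
    about that axis.
    """

    landmarks: Mapping[LandmarkId, Point3]
    mfp_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        lm = {LandmarkId.parse(k) if not isinstance(k, LandmarkId) else k:
              (v if isinstance(v, Point3) else Point3.from_array(v))
              for k, v in dict(self.landmarks).items()}
        object.__setattr__(self, "landmarks", lm)
        for plane in PlaneType:
            pts = [lm[i].to_array() for i in plane.landmarks if i in lm]
            if len(pts) == 3:
                plane_from_points(*pts)  # raises GeometryError if degenerate

    def kc_plane(self):
        """The template's KC mandibular-fossa reference plane."""
        ids = PlaneType.KC_MFP.landmarks
        return plane_from_points(*(self.landmarks[i].to_array() for i in ids),
                                 labels=tuple(i.value for i in ids))


# anchor layout (zero tilt): every plane-defining landmark in the z = 0 plane,
# so the three reference planes coincide exactly, as in a symmetric skull
_BASE_ANCHORS: dict[LandmarkId, tuple[float, float, float]] = {
    LandmarkId.EAC_R: (-60.0, 0.0, 0.0),
    LandmarkId.EAC_L: (60.0, 0.0, 0.0),
    LandmarkId.MF_R: (-58.0, -8.0, 0.0),
    LandmarkId.MF_L: (58.0, -8.0, 0.0),
    LandmarkId.IOM_R: (-30.0, -55.0, 0.0),
    LandmarkId.IOM_L: (30.0, -55.0, 0.0),
    LandmarkId.TO_R: (-50.0, -2.0, 2.0),
    LandmarkId.TO_L: (50.0, -2.0, 2.0),
}


def default_template(mfp_tilt_deg: float = 0.0) -> SkullTemplate:
    """Default symmetric skull template; tilt rotates the mandibular fossae
    about the interaural axis."""
    lm = {k: Point3(*v) for k, v in _BASE_ANCHORS.items()}
    if mfp_tilt_deg != 0.0:
        a = math.radians(mfp_tilt_deg)
        for lid in (LandmarkId.MF_R, LandmarkId.MF_L):
            p = lm[lid]
            lm[lid] = Point3(p.x, p.y * math.cos(a) - p.z * math.sin(a),
                             p.y * math.sin(a) + p.z * math.cos(a))
    return SkullTemplate(lm, mfp_tilt_deg)


@dataclass(frozen=True)
class CohortPreset:
    """Distributional parameters of a simulated cohort.

    Angles in degrees against the KC plane, lengths in millimetres, jitter is
    the per-coordinate SD of isotropic Gaussian landmark placement noise,
    ages in years. ``mfp_tilt_deg`` is forwarded to the skull template.
    """

    name: str
    angle_mean_deg: float
    angle_sd_deg: float
    length_mean_mm: float
    length_sd_mm: float
    age_mean_yr: float
    age_sd_yr: float
    female_fraction: float
    landmark_jitter_sd_mm: float = 0.0
    mfp_tilt_deg: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_mean_deg < 90.0):
            raise ValidationError("angle_mean_deg must lie in (0, 90)")
        if self.length_mean_mm <= 0:
            raise ValidationError("length_mean_mm must be positive")
        for f in ("angle_sd_deg", "length_sd_mm", "age_sd_yr", "landmark_jitter_sd_mm"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be non-negative")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValidationError("female_fraction must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortPreset":
        return cls(**{k: d[k] for k in d})


def _builtin_preset_names() -> list[str]:
    pkg = resources.files("etmorph") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def list_presets() -> list[str]:
    """Names of the shipped cohort presets."""
    return _builtin_preset_names()


def get_preset(name: str) -> CohortPreset:
    """Load a shipped preset by name, or any preset from a JSON file path."""
    p = Path(name)
    if p.suffix == ".json" and p.exists():
        return CohortPreset.from_dict(json.loads(p.read_text()))
    try:
        text = (resources.files("etmorph") / "presets" / f"{name}.json").read_text()
    except (FileNotFoundError, TypeError):
        raise PresetError(
            f"unknown preset {name!r}; registered presets: {', '.join(list_presets())}"
        ) from None
    return CohortPreset.from_dict(json.loads(text))


@dataclass(frozen=True)
class EarTruth:
    """Generated ground truth for one ear (angle against the template KC plane)."""

    angle_deg: float
    length_mm: float


@dataclass(frozen=True)
class SubjectRecord:
    """A simulated subject: demographics, landmark set, and per-ear truth."""

    subject_id: str
    age_yr: float
    sex: str  # 'F' or 'M'
    landmarks: LandmarkSet
    truth: Mapping[Side, EarTruth]


@dataclass(frozen=True)
class Cohort:
    """A reproducible simulated cohort: (preset, n, seed) fully determine it."""

    preset: CohortPreset
    seed: int
    subjects: tuple[SubjectRecord, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def landmark_sets(self) -> list[LandmarkSet]:
        return [s.landmarks for s in self.subjects]

    def to_dict(self) -> dict:
        return {
            "preset": asdict(self.preset),
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "age_yr": s.age_yr,
                    "sex": s.sex,
                    "landmarks": {k.value: [v.x, v.y, v.z]
                                  for k, v in s.landmarks.landmarks.items()},
                    "truth": {side.value: asdict(t) for side, t in s.truth.items()},
                }
                for s in self.subjects
            ],
        }

    def save(self, path) -> None:
        with atomic_write(path) as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "Cohort":
        preset = CohortPreset.from_dict(d["preset"])
        subs = tuple(
            SubjectRecord(
                subject_id=s["subject_id"],
                age_yr=s["age_yr"],
                sex=s["sex"],
                landmarks=LandmarkSet(s["subject_id"],
                                      {k: Point3(*v) for k, v in s["landmarks"].items()}),
                truth={Side(k): EarTruth(**t) for k, t in s["truth"].items()},
            )
            for s in d["subjects"]
        )
        return cls(preset, int(d["seed"]), subs)

    @classmethod
    def load(cls, path) -> "Cohort":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, what: str) -> float:
    """Truncated-normal draw by rejection (no point mass at the bounds)."""
    if sd == 0.0:
        if lo < mean < hi:
            return mean
        raise GenerationError(f"{what}: degenerate mean {mean} outside ({lo}, {hi})")
    for _ in range(_MAX_REDRAWS):
        x = mean + sd * rng.standard_normal()
        if lo < x < hi:
            return x
    raise GenerationError(
        f"{what}: no draw from N({mean}, {sd}²) fell in ({lo}, {hi}) "
        f"after {_MAX_REDRAWS} attempts"
    )


def _ear_direction(kc_normal: np.ndarray, side: Side, theta_deg: float,
                   azimuth_rad: float) -> np.ndarray:
    """Unit chord direction TO→PO making angle theta with the KC plane,
    pointing inferiorly, with in-plane azimuth between medial (0) and
    anterior (π/2)."""
    n = kc_normal  # superior unit normal
    e_med = np.array([1.0, 0.0, 0.0]) if side is Side.RIGHT else np.array([-1.0, 0.0, 0.0])
    e_med = e_med - (e_med @ n) * n
    e_med /= np.linalg.norm(e_med)
    ant = np.array([0.0, -1.0, 0.0])
    e_ant = ant - (ant @ n) * n
    e_ant /= np.linalg.norm(e_ant)
    th = math.radians(theta_deg)
    in_plane = math.cos(azimuth_rad) * e_med + math.sin(azimuth_rad) * e_ant
    return math.cos(th) * in_plane - math.sin(th) * n


def generate_subject(preset: CohortPreset, template: SkullTemplate | None,
                     rng: np.random.Generator, subject_id: str = "S000") -> SubjectRecord:
    """Draw one synthetic subject from a preset.

    Draw order is fixed (right ear, left ear, age, sex, jitter) so a given
    generator state always yields the same subject.
    """
    if template is None:
        template = default_template(preset.mfp_tilt_deg)
    kc = template.kc_plane()
    coords: dict[LandmarkId, np.ndarray] = {
        k: v.to_array().copy() for k, v in template.landmarks.items()
    }
    truth: dict[Side, EarTruth] = {}
    for side in (Side.RIGHT, Side.LEFT):
        theta = _trunc_normal(rng, preset.angle_mean_deg, preset.angle_sd_deg,
                              0.0, 90.0, f"{side.value} ET angle")
        length = _trunc_normal(rng, preset.length_mean_mm, preset.length_sd_mm,
                               5.0, math.inf, f"{side.value} ET length")
        azimuth = rng.uniform(0.0, math.pi / 2.0)
        to = coords[LandmarkId(f"TO_{side.suffix}")]
        d = _ear_direction(kc.normal, side, theta, azimuth)
        coords[LandmarkId(f"PO_{side.suffix}")] = to + length * d
        truth[side] = EarTruth(theta, length)
    age = _trunc_normal(rng, preset.age_mean_yr, preset.age_sd_yr, 18.0, 100.0, "age")
    sex = "F" if rng.uniform() < preset.female_fraction else "M"
    if preset.landmark_jitter_sd_mm > 0.0:
        for k in coords:
            coords[k] = coords[k] + rng.normal(0.0, preset.landmark_jitter_sd_mm, 3)
    lm = LandmarkSet(subject_id, {k: Point3.from_array(v) for k, v in coords.items()})
    return SubjectRecord(subject_id, age, sex, lm, truth)


def generate_cohort(preset: CohortPreset | str, n_subjects: int, seed: int,
                    template: SkullTemplate | None = None) -> Cohort:
    """Generate a reproducible cohort.

    Each subject gets its own child stream spawned from the master seed, so
    subject k is identical no matter how many subjects are generated.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    width = max(3, len(str(n_subjects)))
    subjects = tuple(
        generate_subject(preset, template, np.random.default_rng(streams[i]),
                         subject_id=f"{preset.name}-{i + 1:0{width}d}")
        for i in range(n_subjects)
    )
    return Cohort(preset, seed, subjects)


# stable LandmarkId -> voxel label map (declaration order, 1-based)
MARKER_LABELS: dict[LandmarkId, int] = {lid: i + 1 for i, lid in enumerate(LandmarkId)}


def rasterize_to_volume(landmarks: LandmarkSet, spacing: float = 0.3,
                        marker_radius: float = 0.9, padding: float = 5.0):
    """Render a landmark set as a voxel phantom: each landmark becomes a
    filled ball of a distinct integer label on zero background.

    The default 0.3 mm spacing matches a cone-beam sinus protocol's slice
    thickness. Returns an :class:`etmorph.mpr.VoxelVolume` whose affine maps
    voxel centers exactly onto world coordinates.
    """
    from .mpr import VoxelVolume  # local import: mpr depends on geometry only

    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    if marker_radius < spacing:
        raise ValidationError("marker_radius must be at least the voxel spacing")
    items = sorted(landmarks.landmarks.items(), key=lambda kv: MARKER_LABELS[kv[0]])
    pts = np.array([p.to_array() for _, p in items])
    ids = [k for k, _ in items]
    if len(pts) >= 2:
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] <= 2.0 * marker_radius:
            raise ValidationError(
                f"landmarks {ids[i].value} and {ids[j].value} are {d[i, j]:.2f} mm "
                f"apart; balls of radius {marker_radius} mm would touch — "
                "use a smaller marker_radius"
            )
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    data = np.zeros(shape, dtype=np.int16)
    origin = lo
    sp = np.full(3, float(spacing))
    for lid, p in items:
        c = p.to_array()
        i0 = np.maximum(np.floor((c - marker_radius - origin) / sp).astype(int), 0)
        i1 = np.minimum(np.ceil((c + marker_radius - origin) / sp).astype(int) + 1, shape)
        ax = [origin[k] + np.arange(i0[k], i1[k]) * sp[k] - c[k] for k in range(3)]
        mask = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2) <= marker_radius ** 2
        block = data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        block[mask] = MARKER_LABELS[lid]
    return VoxelVolume(data, sp, Point3.from_array(origin))
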