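"""Synthetic voxel head-and-eye phantom for periorbital stimulation modelling.

The phantom stands in for an MRI-derived anatomical model at desk scale: a
set of nested spheres (scalp, skull, CSF, gray matter, white matter) with two
layered eyes embedded anteriorly (cornea, aqueous, lens, vitreous and a
combined retina/choroid/sclera shell), optic-nerve cylinders running from the
posterior pole of each eye via the chiasm towards the occipital pole, a
designated V1 sub-region of posterior gray matter, four periorbital electrode
patches of 0.35 cm² (superior and inferior to each eye) and one posterior
9 cm² return patch.

Geometry is purely parametric and deterministic: the same parameters always
produce the same volume.  Electrode patches are sets of voxel faces on the
tissue–air boundary; current is injected through them by the volume-conductor
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import reference

__all__ = [
    "GeometryError",
    "PhantomParameters",
    "TissueLabelVolume",
    "SurfacePatch",
    "CurrentSourceSpec",
    "build_synthetic_head",
    "phantom_conductivities",
    "DEFAULT_REGIONS",
]


class GeometryError(ValueError):
    """Inconsistent phantom geometry."""


#: integer labels of the phantom tissue classes
LABELS: Dict[str, int] = {
    "air": 0,
    "scalp": 1,
    "skull": 2,
    "csf": 3,
    "gray_matter": 4,
    "white_matter": 5,
    "eye_cornea": 6,
    "eye_aqueous": 7,
    "eye_lens": 8,
    "eye_vitreous": 9,
    "eye_retina_choroid_sclera": 10,
    "optic_nerve": 11,
    "v1": 12,
}

#: analysis regions (Table-style rows) -> tissue names they comprise
DEFAULT_REGIONS: Dict[str, Tuple[str, ...]] = {
    "retina": ("eye_retina_choroid_sclera",),
    "optic nerve": ("optic_nerve",),
    "cortex": ("gray_matter", "v1"),
    "V1": ("v1",),
    "scalp": ("scalp",),
}


def phantom_conductivities() -> Dict[str, float]:
    """Isotropic conductivity (S/m) for every phantom tissue name."""
    table = {name: reference.CONDUCTIVITY_S_PER_M[name]
             for name in LABELS if name != "v1"}
    table["v1"] = reference.CONDUCTIVITY_S_PER_M["gray_matter"]
    return table


@dataclass(frozen=True)
class PhantomParameters:
    """Geometry of the synthetic head, in millimetres.

    Radii must be strictly nested (scalp > skull > CSF > gray > white); the
    eyes sit anteriorly (+y), partially protruding through the scalp sphere
    the way the cornea reaches the face surface.
    """

    voxel_mm: float = 2.0
    scalp_radius: float = 85.0
    skull_radius: float = 75.0
    csf_radius: float = 70.0
    gray_radius: float = 67.0
    white_radius: float = 55.0
    brain_offset_y: float = -9.0     # cranial cavity sits behind the orbits
    eye_radius: float = 12.0
    eye_center_x: float = 30.0       # lateral offset of each eye (±x)
    eye_center_y: float = 69.0       # anterior position
    eye_shell_mm: float = 2.0        # retina/choroid/sclera shell thickness
    cornea_half_angle_deg: float = 45.0
    lens_radius: float = 4.5
    lens_offset: float = 5.0         # lens center, anterior of eye center
    aqueous_depth: float = 6.0       # anterior chamber beyond this gaze depth
    nerve_radius: float = 2.5
    chiasm_y: float = 20.0           # optic chiasm on the midline
    occipital_y: float = -58.0       # posterior target of the optic tracts
    v1_depth: float = 12.0           # posterior gray-matter cap labelled V1
    electrode_area_cm2: float = 0.35
    electrode_offset_mm: float = 16.0  # patch centers above/below eye center
    return_area_cm2: float = 9.0
    pad_mm: float = 4.0

    def __post_init__(self) -> None:
        radii = (self.scalp_radius, self.skull_radius, self.csf_radius,
                 self.gray_radius, self.white_radius)
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise GeometryError("radii must be strictly nested "
                                "(scalp > skull > CSF > gray > white)")
        if self.skull_radius + abs(self.brain_offset_y) >= self.scalp_radius:
            raise GeometryError("offset cranial cavity must stay inside "
                                "the scalp sphere")
        if self.voxel_mm <= 0:
            raise GeometryError("voxel_mm must be > 0")
        if self.eye_radius <= self.eye_shell_mm:
            raise GeometryError("eye radius must exceed shell thickness")
        center = np.hypot(self.eye_center_x, self.eye_center_y)
        if center >= self.scalp_radius:
            raise GeometryError("eye centers must lie inside the scalp sphere")
        if not self.eye_center_y > 0:
            raise GeometryError("eyes must sit anteriorly (eye_center_y > 0)")


@dataclass
class TissueLabelVolume:
    """Voxel tissue-label grid with physical spacing.

    ``labels`` is a 3-D integer array; ``spacing`` the voxel edge lengths in
    mm; ``origin`` the physical coordinate (mm) of the center of voxel
    (0, 0, 0); ``names`` maps label value -> tissue name (label 0 is air /
    outside).
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float]
    names: Dict[int, str]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("voxel spacing must be > 0")
        if 0 not in self.names or self.names[0] != "air":
            raise GeometryError("label 0 must be the air/outside class")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != 0

    def label_counts(self) -> Dict[str, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {self.names[int(v)]: int(c) for v, c in zip(values, counts)}

    def voxel_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centers, as sparse axes."""
        ax = [self.origin[i] + self.spacing[i] * np.arange(self.labels.shape[i])
              for i in range(3)]
        return np.meshgrid(*ax, indexing="ij", sparse=True)


@dataclass(frozen=True)
class SurfacePatch:
    """A set of voxel faces on the tissue-air boundary.

    ``faces`` has one row per face: (ix, iy, iz, axis, side) where the voxel
    at (ix, iy, iz) is tissue and its neighbour ``side`` (+1/-1) along
    ``axis`` is air or outside the grid.
    """

    faces: np.ndarray
    current_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.faces.ndim != 2 or self.faces.shape[1] != 5 or len(self.faces) == 0:
            raise GeometryError("patch faces must be a non-empty (n, 5) array")

    def area_mm2(self, spacing: Sequence[float]) -> float:
        areas = _face_areas_mm2(spacing)
        return float(sum(areas[int(a)] for a in self.faces[:, 3]))


@dataclass(frozen=True)
class CurrentSourceSpec:
    """Electrode current boundary conditions.

    ``active_patches`` inject fractions of ``total_current`` (A, positive into
    the head); the ``return_patch`` is held at the reference potential.
    """

    active_patches: Tuple[SurfacePatch, ...]
    return_patch: SurfacePatch
    total_current: float = 350e-6

    def __post_init__(self) -> None:
        fractions = sum(p.current_fraction for p in self.active_patches)
        if abs(fractions - 1.0) > 1e-9:
            raise GeometryError("active patch current fractions must sum to 1")
        if self.total_current <= 0:
            raise GeometryError("total_current must be > 0")
        active = np.concatenate([p.faces for p in self.active_patches])
        both = np.concatenate([active, self.return_patch.faces])
        if len(np.unique(both, axis=0)) != len(both):
            raise GeometryError("electrode patches overlap")

    def scaled(self, total_current: float) -> "CurrentSourceSpec":
        return CurrentSourceSpec(self.active_patches, self.return_patch,
                                 total_current)

    def swapped(self) -> "CurrentSourceSpec":
        """Source/return exchanged (single merged active patch) — used for
        reciprocity checks."""
        merged = SurfacePatch(np.concatenate(
            [p.faces for p in self.active_patches]), 1.0)
        return CurrentSourceSpec((self.return_patch,), merged,
                                 self.total_current)


def _face_areas_mm2(spacing: Sequence[float]) -> Tuple[float, float, float]:
    sx, sy, sz = spacing
    return (sy * sz, sx * sz, sx * sy)


def boundary_faces(volume: TissueLabelVolume) -> np.ndarray:
    """All tissue-air faces of the volume as an (n, 5) index array."""
    tissue = volume.tissue_mask
    rows: List[np.ndarray] = []
    for axis in range(3):
        for side in (+1, -1):
            neighbour_air = np.ones_like(tissue)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if side == +1:
                dst[axis] = slice(0, -1)
                src[axis] = slice(1, None)
            else:
                dst[axis] = slice(1, None)
                src[axis] = slice(0, -1)
            neighbour_air[tuple(dst)] = ~tissue[tuple(src)]
            exposed = tissue & neighbour_air
            idx = np.argwhere(exposed)
            if len(idx):
                extra = np.column_stack([
                    np.full(len(idx), axis), np.full(len(idx), side)])
                rows.append(np.hstack([idx, extra]))
    return np.concatenate(rows) if rows else np.empty((0, 5), dtype=int)


def _face_centers_mm(faces: np.ndarray, volume: TissueLabelVolume) -> np.ndarray:
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    centers = origin + faces[:, :3] * spacing
    for axis in range(3):
        sel = faces[:, 3] == axis
        centers[sel, axis] += faces[sel, 4] * spacing[axis] / 2.0
    return centers


def _select_patch(faces: np.ndarray, centers: np.ndarray,
                  target_point: np.ndarray, target_area_mm2: float,
                  spacing: Sequence[float], tol_mm: float) -> np.ndarray:
    """Pick boundary faces nearest ``target_point`` totalling ~target area."""
    dist = np.linalg.norm(centers - target_point, axis=1)
    order = np.argsort(dist, kind="stable")
    if dist[order[0]] > tol_mm:
        raise GeometryError(
            f"electrode patch at {target_point} does not intersect the "
            f"outer surface (nearest face {dist[order[0]]:.1f} mm away)")
    areas = _face_areas_mm2(spacing)
    chosen: List[int] = []
    cum = 0.0
    for i in order:
        a = areas[int(faces[i, 3])]
        if chosen and abs(cum + a - target_area_mm2) >= abs(cum - target_area_mm2):
            break
        chosen.append(int(i))
        cum += a
    return faces[np.array(chosen)]


def build_synthetic_head(
    params: Optional[PhantomParameters] = None,
    seed: Optional[int] = None,
) -> Tuple[TissueLabelVolume, CurrentSourceSpec]:
    """Construct the layered head phantom and its electrode specification.

    The construction is fully deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic generators but unused.

    Returns the labelled volume and a :class:`CurrentSourceSpec` with four
    equal-fraction periorbital active patches (superior and inferior to each
    eye) and the posterior return patch.
    """
    p = params or PhantomParameters()
    h = p.voxel_mm

    # grid extent: everything plus padding
    reach = max(p.scalp_radius,
                np.hypot(p.eye_center_x, p.eye_center_y) + p.eye_radius)
    lo = -(reach + p.pad_mm)
    n = int(np.ceil(2 * (reach + p.pad_mm) / h))
    origin = (lo + h / 2.0, lo + h / 2.0, lo + h / 2.0)
    shape = (n, n, n)

    ax = [origin[i] + h * np.arange(shape[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    R = np.sqrt(X * X + Y * Y + Z * Z)
    # the cranial cavity sits posterior of the orbits: skull and brain shells
    # share a center displaced along -y, leaving anterior face soft tissue
    Yb = Y - p.brain_offset_y
    Rb = np.sqrt(X * X + Yb * Yb + Z * Z)

    labels = np.zeros(shape, dtype=np.int16)
    labels[R <= p.scalp_radius] = LABELS["scalp"]
    for name, radius in (("skull", p.skull_radius),
                         ("csf", p.csf_radius),
                         ("gray_matter", p.gray_radius),
                         ("white_matter", p.white_radius)):
        labels[Rb <= radius] = LABELS[name]

    eye_centers = [np.array([s * p.eye_center_x, p.eye_center_y, 0.0])
                   for s in (+1, -1)]
    for c in eye_centers:
        gaze = c / np.linalg.norm(c)  # anterior, radially outward
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        inside = d <= p.eye_radius
        shell = inside & (d > p.eye_radius - p.eye_shell_mm)
        # gaze-aligned depth of each voxel within the eye
        depth = dx * gaze[0] + dy * gaze[1] + dz * gaze[2]
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ang = np.where(d > 0, depth / d, 1.0)
        cornea = shell & (cos_ang >= np.cos(np.deg2rad(p.cornea_half_angle_deg)))
        interior = inside & ~shell
        lens_c = c + gaze * p.lens_offset
        ld = np.sqrt((X - lens_c[0]) ** 2 + (Y - lens_c[1]) ** 2
                     + (Z - lens_c[2]) ** 2)
        lens = interior & (ld <= p.lens_radius)
        aqueous = interior & ~lens & (depth > p.aqueous_depth)
        vitreous = interior & ~lens & ~aqueous
        labels[shell] = LABELS["eye_retina_choroid_sclera"]
        labels[cornea] = LABELS["eye_cornea"]
        labels[vitreous] = LABELS["eye_vitreous"]
        labels[aqueous] = LABELS["eye_aqueous"]
        labels[lens] = LABELS["eye_lens"]

    # optic nerves: eye posterior pole -> chiasm -> occipital target
    chiasm = np.array([0.0, p.chiasm_y, 0.0])
    occipital = np.array([0.0, p.occipital_y, 0.0])
    eye_labels = [LABELS[t] for t in ("eye_cornea", "eye_aqueous", "eye_lens",
                                      "eye_vitreous",
                                      "eye_retina_choroid_sclera")]
    protected = np.isin(labels, eye_labels) | (labels == LABELS["air"])
    nerve = np.zeros(shape, dtype=bool)
    segments = []
    for c in eye_centers:
        gaze = c / np.linalg.norm(c)
        pole = c - gaze * p.eye_radius
        segments.append((pole, chiasm))
    segments.append((chiasm, occipital))
    for a, b in segments:
        ab = b - a
        denom = float(ab @ ab)
        t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1] + (Z - a[2]) * ab[2]) / denom
        t = np.clip(t, 0.0, 1.0)
        px, py, pz = a[0] + t * ab[0], a[1] + t * ab[1], a[2] + t * ab[2]
        dist = np.sqrt((X - px) ** 2 + (Y - py) ** 2 + (Z - pz) ** 2)
        nerve |= dist <= p.nerve_radius
    labels[nerve & ~protected] = LABELS["optic_nerve"]

    # V1: posterior cap of gray matter
    v1 = (labels == LABELS["gray_matter"]) & (
        Yb <= -(p.gray_radius - p.v1_depth))
    labels[v1] = LABELS["v1"]

    volume = TissueLabelVolume(
        labels=labels, spacing=(h, h, h), origin=origin,
        names={v: k for k, v in LABELS.items()})

    # electrode patches on the outer surface
    all_faces = boundary_faces(volume)
    centers = _face_centers_mm(all_faces, volume)
    tol = 4.0 * h
    active = []
    for c in eye_centers:
        for sz in (+1, -1):
            target = c + np.array([0.0, 0.0, sz * p.electrode_offset_mm])
            target = target / np.linalg.norm(target) * p.scalp_radius
            faces = _select_patch(all_faces, centers, target,
                                  p.electrode_area_cm2 * 100.0,
                                  volume.spacing, tol)
            active.append(SurfacePatch(faces, 0.25))
    ret_target = np.array([0.0, -p.scalp_radius, 0.0])
    ret_faces = _select_patch(all_faces, centers, ret_target,
                              p.return_area_cm2 * 100.0, volume.spacing, tol)
    source = CurrentSourceSpec(tuple(active), SurfacePatch(ret_faces, 1.0))
    return volume, source
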