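"""Parametric collimator and camera geometry for 1-D prompt-gamma imaging.

Two collimator families are modelled, both machined from tungsten alloy:

* **KES** — a knife-edge slit: a single aperture whose walls are bevelled
  prisms, used pinhole-style at magnification d2/d1 < 1.  The image of the
  beam axis on the camera is spatially *inverted*.
* **MPS** — a multi-parallel slit: a stack of rectangular tungsten septa
  with open gaps in front of each crystal slab, used at 1:1 magnification
  with an upright image.

Coordinates
-----------
``z``  object coordinate along the beam axis (mm), increasing downstream,
       origin at the target entrance face.
``u``  detector coordinate along the beam axis (mm), origin at the camera
       centre.
``y``  perpendicular distance from the beam axis toward the camera (mm).

The camera (and, for the KES, the slit axis) is centred on the object
coordinate ``fov_center``, so a detector point ``u`` sits at lab position
``z = fov_center + u``.  Detector bins are half-open ``[left, right)`` with
centres at ``(k - (n - 1)/2) * pitch``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

__all__ = [
    "MaterialProps",
    "KESSpec",
    "MPSSpec",
    "CameraSpec",
    "SetupGeometry",
    "TUNGSTEN_ALLOY",
    "fill_factor",
    "equivalent_thickness",
    "kes_opening_angle",
    "magnification",
    "field_of_view",
    "detector_to_object",
    "object_to_detector",
    "tungsten_path_length",
    "default_kes_setup",
    "default_mps_setup",
    "geometry_summary",
]


@dataclass(frozen=True)
class MaterialProps:
    """Photon-attenuation properties of a collimator material.

    ``mu_linear`` is the linear attenuation coefficient (1/cm) at the
    reference photon energy; the default tungsten-alloy value corresponds
    to a mass attenuation coefficient of about 0.041 cm^2/g at 4.44 MeV
    times a density of 17.0 g/cm^3.
    """

    density: float = 17.0  # g/cm^3
    mu_linear: float = 0.70  # 1/cm at ref_energy
    ref_energy: float = 4.44  # MeV

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.mu_linear <= 0:
            raise ValueError("mu_linear must be positive")

    @property
    def mu_per_mm(self) -> float:
        return self.mu_linear / 10.0


TUNGSTEN_ALLOY = MaterialProps()


@dataclass(frozen=True)
class KESSpec:
    """Knife-edge slit collimator.

    The slit is a gap of ``slit_width`` between two mirrored tungsten
    prisms.  Each knife face is inclined at half the full ``opening_angle``
    so the gap widens linearly away from the slit centre plane.  The walls
    are ``thickness`` mm thick measured normal to the camera plane.
    """

    slit_width: float = 6.0  # mm, gap at the slit centre plane
    opening_angle: float = math.degrees(2 * math.atan(0.5))  # 2*acot(2) = 53.13 deg
    thickness: float = 40.0  # mm
    material: MaterialProps = TUNGSTEN_ALLOY

    def __post_init__(self) -> None:
        if self.slit_width <= 0:
            raise ValueError("slit_width must be positive")
        if not 0 < self.opening_angle < 180:
            raise ValueError("opening_angle must be in (0, 180) degrees")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def half_angle_tan(self) -> float:
        return math.tan(math.radians(self.opening_angle) / 2.0)


@dataclass(frozen=True)
class MPSSpec:
    """Multi-parallel slit collimator.

    ``n_slits`` open gaps of width ``gap`` alternate with tungsten sheets
    of thickness ``septum``; each sheet extends ``depth`` mm along the
    photon travel direction.  The pitch ``gap + septum`` matches the camera
    slab pitch so every gap faces one crystal slab, with septa on the slab
    boundaries (one extra septum closes each end).
    """

    gap: float = 2.4  # mm
    septum: float = 1.6  # mm
    depth: float = 100.0  # mm
    n_slits: int = 20
    material: MaterialProps = TUNGSTEN_ALLOY

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        if self.septum <= 0:
            raise ValueError("septum must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_slits < 1:
            raise ValueError("n_slits must be >= 1")

    @property
    def pitch(self) -> float:
        return self.gap + self.septum


CollimatorSpec = Union[KESSpec, MPSSpec]


@dataclass(frozen=True)
class CameraSpec:
    """Segmented 1-D gamma camera: a row (or two) of LYSO crystal slabs."""

    n_slabs: int = 20
    slab_pitch: float = 4.0  # mm along beam axis
    slab_height: float = 100.0  # mm
    slab_depth: float = 31.5  # mm along photon travel
    n_rows: int = 1
    intrinsic_efficiency: float = 0.60  # detection probability, 3-6 MeV photon

    def __post_init__(self) -> None:
        if self.n_slabs < 1:
            raise ValueError("n_slabs must be >= 1")
        if self.slab_pitch <= 0 or self.slab_height <= 0 or self.slab_depth <= 0:
            raise ValueError("slab dimensions must be positive")
        if self.n_rows not in (1, 2):
            raise ValueError("n_rows must be 1 or 2")
        if not 0 < self.intrinsic_efficiency <= 1:
            raise ValueError("intrinsic_efficiency must be in (0, 1]")

    @property
    def active_width(self) -> float:
        return self.n_slabs * self.slab_pitch

    @property
    def bin_centers_u(self) -> np.ndarray:
        k = np.arange(self.n_slabs)
        return (k - (self.n_slabs - 1) / 2.0) * self.slab_pitch


@dataclass(frozen=True)
class SetupGeometry:
    """A collimator + camera setup positioned relative to the beam axis.

    ``d1`` is the distance from the beam axis to the collimator reference
    plane (KES: slit centre plane; MPS: collimator mid-depth) and ``d2``
    the distance from that plane to the crystal centres.
    """

    collimator: CollimatorSpec
    camera: CameraSpec = field(default_factory=CameraSpec)
    d1: float = 220.0  # mm
    d2: float = 176.0  # mm
    fov_center: float = 0.0  # object coordinate (mm)

    def __post_init__(self) -> None:
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")
        if self.d2 < 0:
            raise ValueError("d2 must be >= 0")

    @property
    def is_kes(self) -> bool:
        return isinstance(self.collimator, KESSpec)

    @property
    def setup_id(self) -> str:
        return "kes" if self.is_kes else "mps"

    # --- y positions used by the ray tracer -------------------------------
    @property
    def collimator_y_span(self) -> tuple[float, float]:
        """(entrance, exit) distance of the tungsten from the beam axis."""
        half = (
            self.collimator.thickness / 2.0
            if self.is_kes
            else self.collimator.depth / 2.0
        )
        return (self.d1 - half, self.d1 + half)

    @property
    def crystal_center_y(self) -> float:
        return self.d1 + self.d2

    @property
    def crystal_face_y(self) -> float:
        return self.d1 + self.d2 - self.camera.slab_depth / 2.0

    def with_fov_center(self, fov_center: float) -> "SetupGeometry":
        return replace(self, fov_center=fov_center)


# ---------------------------------------------------------------------------
# scalar analytics


def fill_factor(mps: MPSSpec) -> float:
    """Fraction of the collimator pitch occupied by tungsten."""
    return mps.septum / (mps.septum + mps.gap)


def equivalent_thickness(mps: MPSSpec) -> float:
    """Tungsten thickness (mm) with the same attenuation as the full stack,
    i.e. fill factor times sheet depth."""
    return fill_factor(mps) * mps.depth


def kes_opening_angle(slope_ratio: float) -> float:
    """Full knife-edge opening angle (degrees) for faces of slope
    ``slope_ratio`` (rise along y per unit opening in z): 2*arccot(ratio)."""
    if slope_ratio <= 0:
        raise ValueError("slope_ratio must be positive")
    return math.degrees(2.0 * math.atan(1.0 / slope_ratio))


def magnification(setup: SetupGeometry) -> float:
    """Image/object scale on the detector: d2/d1 for the KES, 1 for the MPS."""
    return setup.d2 / setup.d1 if setup.is_kes else 1.0


def field_of_view(setup: SetupGeometry) -> float:
    """Span of object coordinates (mm) imaged onto the camera."""
    width = setup.camera.active_width
    if setup.is_kes:
        if setup.d2 == 0:
            raise ValueError("KES setup requires d2 > 0")
        return width * setup.d1 / setup.d2
    return width


def detector_to_object(setup: SetupGeometry, u):
    """Map a detector coordinate to the object coordinate it images.

    The KES projects through the slit centre, inverting the image; the MPS
    maps straight through.
    """
    u = np.asarray(u, dtype=float)
    if setup.is_kes:
        if setup.d2 == 0:
            raise ValueError("KES setup requires d2 > 0")
        out = setup.fov_center - (setup.d1 / setup.d2) * u
    else:
        out = setup.fov_center + u
    return float(out) if out.ndim == 0 else out


def object_to_detector(setup: SetupGeometry, z):
    """Inverse of :func:`detector_to_object`."""
    z = np.asarray(z, dtype=float)
    if setup.is_kes:
        if setup.d2 == 0:
            raise ValueError("KES setup requires d2 > 0")
        out = (setup.fov_center - z) * (setup.d2 / setup.d1)
    else:
        out = z - setup.fov_center
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# tungsten path lengths (closed-form segment intersections)


def _linear_nonneg_length(a, b, y0: float, y1: float):
    """Length of {y in [y0, y1] : a*y + b >= 0} for broadcastable a, b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    span = y1 - y0
    with np.errstate(divide="ignore", invalid="ignore"):
        root = np.where(a != 0.0, -b / np.where(a != 0.0, a, 1.0), 0.0)
    pos = np.clip(y1 - np.maximum(y0, root), 0.0, span)  # a > 0
    neg = np.clip(np.minimum(y1, root) - y0, 0.0, span)  # a < 0
    const = np.where(b >= 0.0, span, 0.0)  # a == 0
    return np.where(a > 0.0, pos, np.where(a < 0.0, neg, const))


def _kes_path_y_length(spec: KESSpec, d1: float, z_slit, slope_z, z_at0):
    """Total y-extent of tungsten crossed by rays z(y) = z_at0 + slope_z*y
    through a knife-edge slit centred at (z_slit, y=d1)."""
    y0 = d1 - spec.thickness / 2.0
    y1 = d1 + spec.thickness / 2.0
    s = spec.half_angle_tan
    w2 = spec.slit_width / 2.0
    f1 = slope_z
    f0 = z_at0 - z_slit  # f(y) = f1*y + f0 is the offset from the slit axis

    total = np.zeros(np.broadcast(f1, f0).shape)
    # lower half (entrance side): half-gap g(y) = w2 + s*(d1 - y)
    total = total + _linear_nonneg_length(f1 + s, f0 - w2 - s * d1, y0, d1)
    total = total + _linear_nonneg_length(-f1 + s, -f0 - w2 - s * d1, y0, d1)
    # upper half (camera side): half-gap g(y) = w2 + s*(y - d1)
    total = total + _linear_nonneg_length(f1 - s, f0 - w2 + s * d1, d1, y1)
    total = total + _linear_nonneg_length(-f1 - s, -f0 - w2 + s * d1, d1, y1)
    return total


def _mps_path_y_length(spec: MPSSpec, d1: float, z_cam, slope_z, z_at0):
    """Total y-extent of tungsten crossed by rays z(y) = z_at0 + slope_z*y.

    The collimator is a tungsten block of the full ``depth`` pierced by
    ``n_slits`` open gaps; outside the aperture region the block is treated
    as laterally unbounded (rays far outside any aperture see the full
    depth), mirroring the effectively infinite walls of the knife-edge
    design.  The tungsten extent is the block crossing minus the gap
    openings.
    """
    y0 = d1 - spec.depth / 2.0
    y1 = d1 + spec.depth / 2.0
    hw = spec.gap / 2.0
    za = z_at0 + slope_z * y0
    zb = z_at0 + slope_z * y1
    lo = np.minimum(za, zb)
    hi = np.maximum(za, zb)
    abs_slope = np.abs(slope_z)
    n = spec.n_slits
    open_y = np.zeros(np.broadcast(lo, hi).shape)
    for k in range(n):
        c = z_cam + (k - (n - 1) / 2.0) * spec.pitch
        overlap = np.clip(np.minimum(hi, c + hw) - np.maximum(lo, c - hw), 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            dy = np.where(abs_slope > 0.0, overlap / np.where(abs_slope > 0.0, abs_slope, 1.0), 0.0)
        parallel_inside = (abs_slope == 0.0) & (np.abs(za - c) <= hw)
        dy = np.where(parallel_inside, spec.depth, dy)
        open_y = open_y + dy
    return spec.depth - open_y


def tungsten_path_length(setup: SetupGeometry, src_z, det_u, det_h=0.0):
    """Length of tungsten (mm) crossed by the straight ray from a source on
    the beam axis at object depth ``src_z`` to the detector-face point
    ``(det_u, det_h)`` (``det_h`` along the slab height).

    All arguments broadcast; returns an array (or scalar) of path lengths.
    """
    src_z = np.asarray(src_z, dtype=float)
    det_u = np.asarray(det_u, dtype=float)
    det_h = np.asarray(det_h, dtype=float)
    y_f = setup.crystal_face_y
    if y_f <= 0:
        raise ValueError("detector face must be on the camera side of the beam axis")
    z_det = setup.fov_center + det_u
    slope_z = (z_det - src_z) / y_f
    z_at0 = src_z
    if setup.is_kes:
        dy = _kes_path_y_length(
            setup.collimator, setup.d1, setup.fov_center, slope_z, z_at0
        )
    else:
        dy = _mps_path_y_length(
            setup.collimator, setup.d1, setup.fov_center, slope_z, z_at0
        )
    oblique = np.sqrt((z_det - src_z) ** 2 + y_f**2 + det_h**2) / y_f
    out = dy * oblique
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# default setups (prototype dimensions)


def default_kes_setup(
    fov_center: float = 0.0,
    n_rows: int = 1,
    material: MaterialProps = TUNGSTEN_ALLOY,
    intrinsic_efficiency: float = 0.60,
) -> SetupGeometry:
    """KES prototype: slit centre 220 mm from the beam axis (entrance face
    at 200 mm), crystal centres 176 mm behind the slit (5:4 magnification,
    10 cm field of view)."""
    return SetupGeometry(
        collimator=KESSpec(material=material),
        camera=CameraSpec(n_rows=n_rows, intrinsic_efficiency=intrinsic_efficiency),
        d1=220.0,
        d2=176.0,
        fov_center=fov_center,
    )


def default_mps_setup(
    fov_center: float = 0.0,
    n_rows: int = 1,
    prototype: bool = False,
    material: MaterialProps = TUNGSTEN_ALLOY,
    intrinsic_efficiency: float = 0.60,
) -> SetupGeometry:
    """MPS prototype: collimator mid-depth 250 mm from the beam axis
    (entrance face at 200 mm), crystals right behind the exit face (1:1
    magnification, 8 cm field of view).

    ``prototype=True`` widens the gaps to 2.5 mm, as machined to preserve
    alignment with the 0.1 mm absorber sheets between the real crystal
    slabs.
    """
    gap = 2.5 if prototype else 2.4
    coll = MPSSpec(gap=gap, material=material)
    camera = CameraSpec(n_rows=n_rows, intrinsic_efficiency=intrinsic_efficiency)
    d2 = coll.depth / 2.0 + camera.slab_depth / 2.0
    return SetupGeometry(
        collimator=coll, camera=camera, d1=250.0, d2=d2, fov_center=fov_center
    )


def geometry_summary(setup: SetupGeometry) -> dict:
    """Headline geometry numbers (used by the CLI)."""
    out = {
        "collimator": setup.setup_id,
        "magnification": magnification(setup),
        "field_of_view_mm": field_of_view(setup),
        "d1_mm": setup.d1,
        "d2_mm": setup.d2,
        "camera_active_width_mm": setup.camera.active_width,
    }
    if not setup.is_kes:
        out["fill_factor"] = fill_factor(setup.collimator)
        out["equivalent_thickness_mm"] = equivalent_thickness(setup.collimator)
    else:
        out["slit_width_mm"] = setup.collimator.slit_width
        out["opening_angle_deg"] = setup.collimator.opening_angle
        out["thickness_mm"] = setup.collimator.thickness
    return out
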