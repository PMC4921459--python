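"""Synthetic prompt-gamma acquisitions.

This module generates the statistical stand-in for slit-camera beam tests:
a Bragg–Kleeman range model for protons in PMMA, a smooth prompt-gamma
depth-emission profile whose falloff sits a few mm before the proton range,
a sloped (forward-peaked) neutron-induced background, and expected /
Poisson-sampled 20-bin detection profiles obtained by deterministic,
attenuation-only projection through the collimator.

The transport model is intentionally simple: every emitted photon travels
in a straight line from the beam axis to a crystal face, weighted by the
subtended solid angle, attenuated exponentially by the tungsten it crosses,
and detected with a fixed intrinsic efficiency.  Photon scatter, neutron
transport and detector electronics are not simulated; their net effect —
an uncorrelated background — is modelled explicitly by
:class:`BackgroundModel`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .geometry import (
    SetupGeometry,
    detector_to_object,
    tungsten_path_length,
)

__all__ = [
    "BeamTargetModel",
    "BackgroundModel",
    "DetectionProfile",
    "QuadratureSpec",
    "ImpulseResponse",
    "range_pmma",
    "beam_target_model",
    "pg_emission_density",
    "background_rate",
    "expected_profile",
    "impulse_response",
    "profile_fwhm",
    "sample_profile",
    "DEFAULT_BACKGROUND",
    "BK_ALPHA_CM",
    "BK_EXPONENT",
    "RSP_PMMA",
]

# Bragg–Kleeman water-range fit R = alpha * E^p, constants fitted to
# CSDA proton ranges in liquid water from standard stopping-power tables
# (7.718 g/cm^2 at 100 MeV, 37.94 g/cm^2 at 250 MeV).
BK_ALPHA_CM = 2.5806e-3  # cm / MeV^p
BK_EXPONENT = 1.738
RSP_PMMA = 1.16  # PMMA stopping power relative to water


def range_pmma(
    energy: float,
    bk_alpha: float = BK_ALPHA_CM,
    bk_p: float = BK_EXPONENT,
    rsp_pmma: float = RSP_PMMA,
) -> float:
    """Mean maximum penetration depth (cm) of protons of ``energy`` MeV in
    PMMA: the Bragg–Kleeman water range ``alpha * E**p`` divided by the PMMA
    relative stopping power."""
    if not 50.0 <= energy <= 250.0:
        raise ValueError("energy outside the 50-250 MeV validity range")
    return bk_alpha * energy**bk_p / rsp_pmma


@dataclass(frozen=True)
class BeamTargetModel:
    """Proton pencil beam in a cylindrical PMMA target.

    The prompt-gamma linear emission density along the track is a smooth
    plateau: a Gaussian-CDF rise at the entrance face and a Gaussian-CDF
    falloff centred ``falloff_offset`` mm before the range ``range_pmma``.
    ``emission_yield`` is the number of 3-6 MeV prompt gammas escaping the
    target per proton per mm of plateau track.
    """

    energy: float  # MeV
    range_pmma: float  # mm
    falloff_offset: float = 3.0  # mm before the range
    falloff_width: float = 2.0  # mm (sigma)
    entrance_rise_width: float = 2.0  # mm (sigma)
    emission_yield: float = 4.0e-4  # 1 / proton / mm
    target_length: float = 200.0  # mm
    target_radius: float = 75.0  # mm

    def __post_init__(self) -> None:
        if not 0 < self.range_pmma <= self.target_length:
            raise ValueError("range_pmma must be in (0, target_length]")
        if self.falloff_width <= 0 or self.entrance_rise_width <= 0:
            raise ValueError("edge widths must be positive")
        if self.emission_yield < 0:
            raise ValueError("emission_yield must be >= 0")


# Plateau emission yield at the 160 MeV reference energy, chosen so the
# default KES setup detects prompt gammas at the clinically quoted order of
# one count per 1e5 protons (per crystal row); see docs/methods.md.
YIELD_AT_160 = 4.0e-4  # 1 / proton / mm
YIELD_ENERGY_EXPONENT = -0.5  # plateau emission density drops with energy


def beam_target_model(energy: float, emission_yield: Optional[float] = None) -> BeamTargetModel:
    """Default beam/target model for a nominal beam energy (MeV).

    The PMMA cylinder is 20 cm long up to 160 MeV and 40 cm at higher
    energies; the plateau emission yield scales as ``(E/160)**-0.5`` to
    reflect the lower prompt-gamma emission per mm of higher-energy protons.
    """
    r_mm = 10.0 * range_pmma(energy)
    length = 200.0 if energy <= 160.0 else 400.0
    if emission_yield is None:
        emission_yield = YIELD_AT_160 * (energy / 160.0) ** YIELD_ENERGY_EXPONENT
    return BeamTargetModel(
        energy=energy,
        range_pmma=r_mm,
        emission_yield=emission_yield,
        target_length=length,
    )


def pg_emission_density(z, beam: BeamTargetModel):
    """Prompt-gamma linear emission density (1/proton/mm) at depth ``z`` mm.

    Smooth plateau between the entrance rise at z = 0 and the falloff at
    z = range - falloff_offset; identically ~0 outside the target.
    """
    z = np.asarray(z, dtype=float)
    rise = ndtr(z / beam.entrance_rise_width)
    edge = beam.range_pmma - beam.falloff_offset
    fall = 1.0 - ndtr((z - edge) / beam.falloff_width)
    out = beam.emission_yield * rise * fall
    out = np.where((z < -6 * beam.entrance_rise_width) | (z > beam.target_length), 0.0, out)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BackgroundModel:
    """Uncollimated, neutron-induced background under the prompt-gamma signal.

    Per-slab rate per proton, in physical detector coordinates (identical
    slope direction for both collimators, since neither collimates the
    neutron-induced component):

        b0 * (E / ref_energy)**energy_exponent * (1 + beta_eff * u / halfwidth)

    with ``beta_eff = beta * (E / ref_energy)``.  ``beta`` is larger for
    entrance-aligned acquisitions (forward-peaked neutrons with no upstream
    compensation) than for Bragg-peak-aligned ones.  ``b0`` is quoted at a
    crystal-centre distance ``ref_distance`` from the beam axis and scales
    with the inverse square of the actual distance.
    """

    b0: float = 1.6e-6  # counts / slab / proton / row at ref conditions
    beta_entrance: float = 0.30
    beta_peak: float = 0.05
    energy_exponent: float = 1.7
    ref_energy: float = 230.0  # MeV
    ref_distance: float = 250.0  # mm

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError("b0 must be >= 0")
        if not (abs(self.beta_entrance) < 1 and abs(self.beta_peak) < 1):
            raise ValueError("background slope would drive rates negative")

    def beta_eff(self, alignment: str, energy: float) -> float:
        if alignment == "entrance":
            beta = self.beta_entrance
        elif alignment == "bragg_peak":
            beta = self.beta_peak
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
        return beta * energy / self.ref_energy

    def energy_scaling(self, energy: float) -> float:
        return (energy / self.ref_energy) ** self.energy_exponent


DEFAULT_BACKGROUND = BackgroundModel()


def background_rate(
    u,
    model: BackgroundModel,
    alignment: str,
    energy: float,
    halfwidth: float = 40.0,
    distance: Optional[float] = None,
):
    """Background count rate (1/proton/bin, per crystal row) at detector
    coordinate ``u`` mm.  ``distance`` is the beam-axis-to-crystal-centre
    distance; defaults to the model's reference distance."""
    u = np.asarray(u, dtype=float)
    beta = model.beta_eff(alignment, energy)
    geom = 1.0 if distance is None else (model.ref_distance / distance) ** 2
    rate = model.b0 * model.energy_scaling(energy) * geom * (1.0 + beta * u / halfwidth)
    if np.any(rate < 0):
        raise ValueError("background slope drives the rate negative")
    return float(rate) if rate.ndim == 0 else rate


@dataclass(frozen=True)
class QuadratureSpec:
    """Resolution of the deterministic projection quadrature."""

    dz: float = 0.5  # mm, emission-depth step
    n_u: int = 16  # sample points across each slab face, beam-axis direction
    n_h: int = 4  # sample points across each slab face, height direction

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.n_u < 1 or self.n_h < 1:
            raise ValueError("invalid quadrature spec")


DEFAULT_QUADRATURE = QuadratureSpec()


@dataclass
class DetectionProfile:
    """A binned 1-D detection profile.

    ``counts`` are expected (real-valued, ``seed is None``) or Poisson
    sampled (integer-valued).  ``bin_centers_u`` are detector coordinates,
    ``bin_centers_z`` the object coordinates they image.
    """

    counts: np.ndarray
    n_protons: float
    bin_centers_u: np.ndarray
    bin_centers_z: np.ndarray
    setup_id: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_centers_u = np.asarray(self.bin_centers_u, dtype=float)
        self.bin_centers_z = np.asarray(self.bin_centers_z, dtype=float)
        if self.counts.shape != self.bin_centers_u.shape:
            raise ValueError("counts and bin_centers_u must have the same length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    def with_counts(self, counts, seed: Optional[int] = None) -> "DetectionProfile":
        return DetectionProfile(
            counts=np.asarray(counts, dtype=float),
            n_protons=self.n_protons,
            bin_centers_u=self.bin_centers_u,
            bin_centers_z=self.bin_centers_z,
            setup_id=self.setup_id,
            seed=seed,
        )

    def scaled_to(self, n_protons: float) -> "DetectionProfile":
        """Expected profile rescaled to a different delivered proton count."""
        factor = n_protons / self.n_protons
        out = self.with_counts(self.counts * factor, seed=self.seed)
        out.n_protons = n_protons
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "u_mm": self.bin_centers_u,
                "z_mm": self.bin_centers_z,
                "counts": self.counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_protons: float, setup_id: str = "") -> "DetectionProfile":
        df = pd.read_csv(path)
        return cls(
            counts=df["counts"].to_numpy(),
            n_protons=n_protons,
            bin_centers_u=df["u_mm"].to_numpy(),
            bin_centers_z=df["z_mm"].to_numpy(),
            setup_id=setup_id,
        )


def _face_samples(setup: SetupGeometry, quad: QuadratureSpec):
    """Midpoint sample offsets (du, h) across one crystal face and the area
    weight each sample carries."""
    cam = setup.camera
    du = (np.arange(quad.n_u) + 0.5) / quad.n_u - 0.5
    dh = (np.arange(quad.n_h) + 0.5) / quad.n_h - 0.5
    du = du * cam.slab_pitch
    dh = dh * cam.slab_height
    area = cam.slab_pitch * cam.slab_height / (quad.n_u * quad.n_h)
    return du, dh, area


def _projected_rate(
    setup: SetupGeometry,
    src_z: np.ndarray,
    weights: np.ndarray,
    quad: QuadratureSpec,
) -> np.ndarray:
    """Per-bin detected rate for emission points ``src_z`` (mm, on the beam
    axis) carrying ``weights`` photons emitted isotropically.

    Each crystal face is sampled on an ``n_u x n_h`` midpoint grid; every
    sample contributes ``area * cos(theta) / (4 pi r^2)`` of solid angle,
    attenuated by the tungsten crossed, times the intrinsic efficiency and
    the number of crystal rows.
    """
    cam = setup.camera
    mu = setup.collimator.material.mu_per_mm
    du, dh, area = _face_samples(setup, quad)
    y_f = setup.crystal_face_y

    # broadcast: (n_src, n_bins, n_u, n_h)
    src = src_z[:, None, None, None]
    u_pts = (cam.bin_centers_u[None, :, None, None] + du[None, None, :, None])
    h_pts = dh[None, None, None, :]

    path = tungsten_path_length(setup, src, u_pts, h_pts)
    z_det = setup.fov_center + u_pts
    r2 = (z_det - src) ** 2 + y_f**2 + h_pts**2
    # cos(theta) = y_f / r  =>  area * cos / (4 pi r^2) = area * y_f / (4 pi r^3)
    geom = area * y_f / (4.0 * math.pi * r2 ** 1.5)
    rate = np.exp(-mu * path) * geom
    rate = rate.sum(axis=(2, 3))  # over face samples -> (n_src, n_bins)
    rate = (weights[:, None] * rate).sum(axis=0)
    return rate * cam.intrinsic_efficiency * cam.n_rows


def expected_profile(
    setup: SetupGeometry,
    beam: BeamTargetModel,
    bg: BackgroundModel = DEFAULT_BACKGROUND,
    alignment: str = "bragg_peak",
    n_protons: float = 1e11,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> DetectionProfile:
    """Deterministic expected detection profile (no counting noise).

    Integrates the emission density over the full target depth on a ``dz``
    grid, projects each emission element through the collimator, and adds
    the uncollimated background.  ``alignment`` only selects the background
    slope; the field-of-view placement is carried by ``setup.fov_center``.
    """
    cam = setup.camera
    z_grid = np.arange(0.0, beam.target_length, quad.dz) + quad.dz / 2.0
    density = pg_emission_density(z_grid, beam)
    keep = density > 0
    z_grid, density = z_grid[keep], density[keep]
    correlated = _projected_rate(setup, z_grid, density * quad.dz, quad)

    bg_rate = background_rate(
        cam.bin_centers_u,
        bg,
        alignment,
        beam.energy,
        halfwidth=cam.active_width / 2.0,
        distance=setup.crystal_center_y,
    ) * cam.n_rows

    counts = n_protons * (correlated + bg_rate)
    return DetectionProfile(
        counts=counts,
        n_protons=n_protons,
        bin_centers_u=cam.bin_centers_u.copy(),
        bin_centers_z=detector_to_object(setup, cam.bin_centers_u),
        setup_id=setup.setup_id,
        seed=None,
    )


@dataclass(frozen=True)
class ImpulseResponse:
    """Detector response to a monoenergetic point source on the beam axis."""

    response: np.ndarray  # per-bin detected fraction of emitted photons
    bin_centers_u: np.ndarray
    bin_centers_z: np.ndarray
    fwhm: float  # mm, in object coordinates
    source_z: float


def profile_fwhm(z: np.ndarray, values: np.ndarray) -> float:
    """FWHM (mm) of a binned peak: subtract the floor (minimum bin), find
    the half-maximum crossings by linear interpolation between bin centres."""
    order = np.argsort(z)
    z = np.asarray(z, float)[order]
    v = np.asarray(values, float)[order] - np.min(values)
    if np.all(v <= 0):
        raise ValueError("response has no maximum")
    half = v.max() / 2.0
    k = int(np.argmax(v))
    # walk outward from the peak to the first crossings below half-maximum
    left = None
    for i in range(k, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = z[i - 1] + (z[i] - z[i - 1]) * (half - v[i - 1]) / (v[i] - v[i - 1])
            break
    right = None
    for i in range(k, len(v) - 1):
        if v[i + 1] < half <= v[i]:
            right = z[i] + (z[i + 1] - z[i]) * (v[i] - half) / (v[i] - v[i + 1])
            break
    if left is None or right is None:
        raise ValueError("half-maximum crossing outside the profile support")
    return float(right - left)


def impulse_response(
    setup: SetupGeometry,
    source_z: Optional[float] = None,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> ImpulseResponse:
    """Response to a 4.44 MeV point source on the beam axis.

    ``source_z`` defaults to the centre of the field of view.  For the MPS
    collimator the response is not shift-invariant at the sub-pitch scale
    (the stack aliases with the slabs); the conventional resolution figure
    is the response with the source on an aperture axis, which is what the
    default delivers for the KES (slit axis) and what callers should pass
    explicitly for off-centre studies.
    """
    if source_z is None:
        source_z = setup.fov_center
    resp = _projected_rate(setup, np.array([source_z], float), np.array([1.0]), quad)
    z = detector_to_object(setup, setup.camera.bin_centers_u)
    fwhm = profile_fwhm(z, resp)
    return ImpulseResponse(
        response=resp,
        bin_centers_u=setup.camera.bin_centers_u.copy(),
        bin_centers_z=z,
        fwhm=fwhm,
        source_z=float(source_z),
    )


def sample_profile(
    expected: DetectionProfile, n_protons: float, seed
) -> DetectionProfile:
    """Poisson resample of an expected profile at ``n_protons`` delivered
    protons: independent per-bin draws with mean scaled by
    ``n_protons / expected.n_protons``."""
    if n_protons < 0:
        raise ValueError("n_protons must be >= 0")
    rng = np.random.default_rng(seed)
    lam = expected.counts * (n_protons / expected.n_protons)
    counts = rng.poisson(lam).astype(float)
    out = expected.with_counts(counts, seed=seed if isinstance(seed, int) else None)
    out.n_protons = n_protons
    return out
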