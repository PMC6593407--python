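"""Domain models shared across the simulator and the measurement pipeline.

Conventions
-----------
* All physical lengths are in nanometres and all times in minutes.
* 3D coordinates are ``(x, y, z)`` with ``z`` the optical axis; images are
  the projection onto the ``(x, y)`` plane.
* Image arrays are indexed ``[row, col]`` with ``row`` along ``y`` and
  ``col`` along ``x``; pixel centres sit at integer coordinates (0-based).
* The forespore "pole" (the DivIVA/RacA tether site) lies on the +x axis,
  i.e. in the image plane, so a tether offset survives 2D projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

SPHERE = "sphere"
HEMISPHERICAL_CAP = "hemispherical_cap"

TETHERED = "tethered"
FREE = "free"


class InvalidModelError(ValueError):
    """A model/configuration violates one of its invariants."""


class ResolutionError(ValueError):
    """The imaging configuration cannot resolve the requested scene."""


@dataclass(frozen=True)
class ForesporeModel:
    """Geometry of a single forespore compartment.

    The forespore is modelled as a sphere (default, diameter 600 nm — the
    scale assumed by the free-diffusion null model) or as a hemispherical
    cap abutting a flat septum at the plane ``x = center``.
    """

    center_3d: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter: float = 600.0
    geometry_variant: str = SPHERE
    membrane_thickness: float = 20.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidModelError("forespore diameter must be > 0")
        if self.membrane_thickness < 0:
            raise InvalidModelError("membrane_thickness must be >= 0")
        if self.membrane_thickness >= self.diameter:
            raise InvalidModelError("membrane_thickness must be << diameter")
        if self.geometry_variant not in (SPHERE, HEMISPHERICAL_CAP):
            raise InvalidModelError(
                f"unknown geometry_variant {self.geometry_variant!r}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def pole(self) -> Tuple[float, float, float]:
        """The tether anchor point: the pole on the +x axis, in-plane."""
        cx, cy, cz = self.center_3d
        return (cx + self.radius, cy, cz)


@dataclass(frozen=True)
class LocusPlacementModel:
    """How the chromosomal locus focus is positioned inside the forespore.

    ``tethered`` places the locus at ``tether_distance_mean`` (jittered by
    ``tether_distance_sd``) from the anchor along the inward normal;
    ``free`` draws it uniformly from the forespore volume and ignores the
    tether fields.
    """

    mode: str = TETHERED
    tether_anchor: Optional[Tuple[float, float, float]] = None  # None -> pole
    tether_distance_mean: float = 0.0
    tether_distance_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in (TETHERED, FREE):
            raise InvalidModelError(f"unknown placement mode {self.mode!r}")
        if self.tether_distance_mean < 0:
            raise InvalidModelError("tether_distance_mean must be >= 0")
        if self.tether_distance_sd < 0:
            raise InvalidModelError("tether_distance_sd must be >= 0")


SILHOUETTE_RING = "silhouette_ring"
PROJECTED_SHELL = "projected_shell"


@dataclass(frozen=True)
class ImagingConfig:
    """Camera/optics parameters for rendering synthetic frames.

    The PSF is an isotropic 2D Gaussian per channel (sigma ~ 0.21*lambda/NA:
    ~65 nm for the blue membrane stain, ~90 nm for mCherry at NA 1.4).
    Noise is Poisson shot noise on the expected counts plus additive
    Gaussian read noise; ``shot_noise=False`` disables the Poisson step for
    noiseless renders.

    ``membrane_render`` selects how the membrane channel is drawn:

    * ``silhouette_ring`` (default): the projected outline — a thin annulus
      at the true silhouette radius — convolved with the PSF.  This mimics
      the locally sheet-like membrane crossings of real forespore images
      (septum/cell envelope), where the line-scan intensity peak sits at
      the membrane.
    * ``projected_shell``: the full line-of-sight projection of the 3D
      shell.  Physically exact for an isolated stained vesicle, but a
      600-nm shell is below the diffraction limit and blurs into a blob
      whose peak is far inside the true membrane; kept as an option.
    """

    pixel_size: float = 65.0
    psf_sigma_membrane: float = 65.0
    psf_sigma_locus: float = 90.0
    photon_budget: float = 5000.0
    membrane_photon_budget: Optional[float] = None  # None -> 40x photon_budget
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    rng_seed: int = 0
    image_shape: Optional[Tuple[int, int]] = None  # None -> auto
    membrane_render: str = SILHOUETTE_RING
    oversample: int = 5

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidModelError("pixel_size must be > 0")
        if self.psf_sigma_membrane <= 0 or self.psf_sigma_locus <= 0:
            raise InvalidModelError("psf_sigma must be > 0")
        for name in ("photon_budget", "background_level", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidModelError(f"{name} must be >= 0")
        if self.membrane_photon_budget is not None and self.membrane_photon_budget < 0:
            raise InvalidModelError("membrane_photon_budget must be >= 0")
        if self.membrane_render not in (SILHOUETTE_RING, PROJECTED_SHELL):
            raise InvalidModelError(
                f"unknown membrane_render {self.membrane_render!r}"
            )
        if self.oversample < 1:
            raise InvalidModelError("oversample must be >= 1")

    @property
    def membrane_photons(self) -> float:
        if self.membrane_photon_budget is not None:
            return self.membrane_photon_budget
        return 40.0 * self.photon_budget


def _validate_distribution(spec: Sequence) -> None:
    if not spec or spec[0] not in ("fixed", "normal", "uniform"):
        raise InvalidModelError(f"unknown distribution spec {spec!r}")
    if spec[0] == "fixed" and len(spec) != 2:
        raise InvalidModelError("fixed distribution needs one value")
    if spec[0] == "normal" and len(spec) != 3:
        raise InvalidModelError("normal distribution needs (mean, sd)")
    if spec[0] == "uniform" and len(spec) != 3:
        raise InvalidModelError("uniform distribution needs (low, high)")


def draw_times(spec: Sequence, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` non-negative times from a parametric spec.

    Specs: ``("fixed", v)``, ``("normal", mean, sd)`` (truncated at 0 by
    resampling), ``("uniform", low, high)``.
    """
    _validate_distribution(spec)
    kind = spec[0]
    if kind == "fixed":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        low, high = float(spec[1]), float(spec[2])
        if low < 0 or high < low:
            raise InvalidModelError("uniform bounds must satisfy 0 <= low <= high")
        return rng.uniform(low, high, size=n)
    mean, sd = float(spec[1]), float(spec[2])
    if mean < 0:
        raise InvalidModelError("normal mean must be >= 0")
    out = rng.normal(mean, sd, size=n)
    # truncate at zero by redrawing; falls back to clipping in pathological cases
    for _ in range(100):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class KineticsConfig:
    """Dual-reporter time-lapse generator parameters.

    YFP turns on at septation (origin region captured in the forespore);
    CFP turns on once the reporter locus has been translocated across the
    septum, i.e. at septation + translocation time.  Frames are acquired
    every ``frame_interval`` minutes (2 min in the imaging regime emulated
    here).  ``yfp_miss_prob`` is the probability that a forespore never
    develops detectable YFP although CFP still appears (the CFP-only
    mis-capture class, ~10% in the population assays this emulates).
    """

    frame_interval: float = 2.0
    n_frames: int = 120
    septation_time: Sequence = ("normal", 60.0, 15.0)
    translocation_time: Sequence = ("normal", 11.0, 3.0)
    reporter_rise_rate: float = 50.0  # counts/min after onset
    detection_noise: float = 5.0  # additive Gaussian sd, counts
    background_level: float = 100.0
    yfp_miss_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidModelError("frame_interval must be > 0")
        if self.n_frames < 1:
            raise InvalidModelError("n_frames must be >= 1")
        if self.reporter_rise_rate < 0 or self.detection_noise < 0:
            raise InvalidModelError("rates and noise must be >= 0")
        if not 0.0 <= self.yfp_miss_prob <= 1.0:
            raise InvalidModelError("yfp_miss_prob must be in [0, 1]")
        _validate_distribution(self.septation_time)
        _validate_distribution(self.translocation_time)

    @property
    def duration(self) -> float:
        return self.frame_interval * (self.n_frames - 1)


@dataclass
class GroundTruthRecord:
    """Simulator truth for one cell, used by recovery tests."""

    cell_id: int
    locus_position_3d: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_membrane_distance_3d: float = 0.0
    true_projected_distance: float = 0.0
    mode: str = TETHERED
    true_onset_yfp: Optional[float] = None
    true_onset_cfp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.true_membrane_distance_3d < -1e-9 or self.true_projected_distance < -1e-9:
            raise InvalidModelError("ground-truth distances must be >= 0")
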