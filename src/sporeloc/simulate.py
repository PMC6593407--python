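"""Synthetic forespore image and dual-reporter time-lapse generator.

Every stochastic operation takes a :class:`numpy.random.Generator` (or a
seed) and is bit-reproducible under a fixed seed.  Multi-cell simulations
derive one independent substream per cell from the top-level seed via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .models import (
    FREE,
    HEMISPHERICAL_CAP,
    PROJECTED_SHELL,
    SILHOUETTE_RING,
    TETHERED,
    ForesporeModel,
    GroundTruthRecord,
    ImagingConfig,
    InvalidModelError,
    KineticsConfig,
    LocusPlacementModel,
    ResolutionError,
    draw_times,
)

__all__ = [
    "place_locus",
    "sample_locus_positions",
    "render_frame",
    "simulate_field",
    "simulate_timelapse",
    "FieldResult",
    "TimelapseResult",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_locus_positions(
    forespore: ForesporeModel,
    placement: LocusPlacementModel,
    rng,
    n: int,
) -> np.ndarray:
    """Vectorised draw of ``n`` locus positions (nm, shape ``(n, 3)``).

    ``free`` mode is uniform in the forespore volume (ball, or half-ball
    for the hemispherical cap).  ``tethered`` mode places the locus at a
    normal-jittered distance from the anchor along the inward normal,
    clipped to the volume.
    """
    rng = _as_rng(rng)
    R = forespore.radius
    c = np.asarray(forespore.center_3d, dtype=float)
    if placement.mode == FREE:
        # uniform direction x radius ~ R * U^(1/3)
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = R * rng.uniform(size=n) ** (1.0 / 3.0)
        pos = c + v * r[:, None]
        if forespore.geometry_variant == HEMISPHERICAL_CAP:
            # reflect into the half-ball x >= cx (uniform by symmetry)
            pos[:, 0] = c[0] + np.abs(pos[:, 0] - c[0])
        return pos

    if placement.tether_distance_mean > forespore.diameter:
        raise InvalidModelError(
            "tether_distance_mean exceeds the forespore diameter"
        )
    anchor = np.asarray(
        placement.tether_anchor if placement.tether_anchor is not None else forespore.pole,
        dtype=float,
    )
    inward = c - anchor
    norm = np.linalg.norm(inward)
    if norm == 0:
        raise InvalidModelError("tether_anchor must lie on the membrane, not the centre")
    inward /= norm
    dist = placement.tether_distance_mean + placement.tether_distance_sd * rng.normal(size=n)
    max_dist = R + norm  # stay inside the ball along the inward chord
    if forespore.geometry_variant == HEMISPHERICAL_CAP:
        max_dist = norm  # stop at the septum plane through the centre
    dist = np.clip(dist, 0.0, max_dist)
    return anchor[None, :] + inward[None, :] * dist[:, None]


def _truth_for_position(
    forespore: ForesporeModel, pos: np.ndarray, mode: str, cell_id: int
) -> GroundTruthRecord:
    c = np.asarray(forespore.center_3d, dtype=float)
    R = forespore.radius
    d = pos - c
    r3 = float(np.linalg.norm(d))
    r2 = float(np.hypot(d[0], d[1]))
    dist3 = R - r3
    proj = R - r2
    if forespore.geometry_variant == HEMISPHERICAL_CAP:
        dist3 = min(dist3, float(d[0]))  # distance to the septum plane
        proj = min(proj, float(d[0]))
    return GroundTruthRecord(
        cell_id=cell_id,
        locus_position_3d=tuple(float(v) for v in pos),
        true_membrane_distance_3d=max(dist3, 0.0),
        true_projected_distance=max(proj, 0.0),
        mode=mode,
    )


def place_locus(
    forespore: ForesporeModel,
    placement: LocusPlacementModel,
    rng,
    cell_id: int = 0,
) -> Tuple[np.ndarray, GroundTruthRecord]:
    """Draw one locus position and its ground-truth record."""
    pos = sample_locus_positions(forespore, placement, rng, 1)[0]
    return pos, _truth_for_position(forespore, pos, placement.mode, cell_id)


# --------------------------------------------------------------------------
# rendering


def default_image_shape(forespore: ForesporeModel, cfg: ImagingConfig) -> Tuple[int, int]:
    sigma = max(cfg.psf_sigma_membrane, cfg.psf_sigma_locus)
    half_nm = forespore.radius + 3.0 * sigma + 2.0 * cfg.pixel_size
    half_px = int(np.ceil(half_nm / cfg.pixel_size))
    side = 2 * half_px + 1
    return (side, side)


def _supersample_grid(shape: Tuple[int, int], os_: int) -> Tuple[np.ndarray, np.ndarray]:
    """Subpixel sample coordinates (px units) for each supersample point."""
    rows = (np.arange(shape[0] * os_) + 0.5) / os_ - 0.5
    cols = (np.arange(shape[1] * os_) + 0.5) / os_ - 0.5
    return np.meshgrid(rows, cols, indexing="ij")


def _membrane_column(
    forespore: ForesporeModel,
    cfg: ImagingConfig,
    X: np.ndarray,
    Y: np.ndarray,
) -> np.ndarray:
    """Un-normalised membrane emission density at image positions (nm)."""
    R = forespore.radius
    t = max(forespore.membrane_thickness, 1e-6)
    rho = np.hypot(X, Y)
    if cfg.membrane_render == SILHOUETTE_RING:
        col = (np.abs(rho - R) <= t / 2.0).astype(float)
        if forespore.geometry_variant == HEMISPHERICAL_CAP:
            col = np.where(X >= 0, col, 0.0)
            septum = (np.abs(X) <= t / 2.0) & (np.abs(Y) <= R)
            col = col + septum.astype(float)
        return col
    # projected shell: line-of-sight chord difference through the 3D shell
    Ro, Ri = R + t / 2.0, R - t / 2.0

    def chord(radius: float) -> np.ndarray:
        return 2.0 * np.sqrt(np.clip(radius * radius - rho * rho, 0.0, None))

    col = chord(Ro) - chord(Ri)
    if forespore.geometry_variant == HEMISPHERICAL_CAP:
        col = np.where(X >= 0, col, 0.0)
        septum = (np.abs(X) <= t / 2.0) & (np.abs(Y) < R)
        col = col + np.where(
            septum, 2.0 * np.sqrt(np.clip(R * R - Y * Y, 0.0, None)), 0.0
        )
    return col


def _apply_noise(expected: np.ndarray, cfg: ImagingConfig, rng: np.random.Generator) -> np.ndarray:
    img = expected + cfg.background_level
    if cfg.shot_noise:
        img = rng.poisson(img).astype(float)
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_frame(
    forespore: ForesporeModel,
    locus_position: Sequence[float],
    cfg: ImagingConfig,
    rng=None,
    center_px: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one (membrane, locus) channel pair as float count images.

    The forespore centre is placed at ``center_px`` (row, col; default the
    image centre).  The locus channel is a single PSF-shaped spot holding
    ``photon_budget`` expected photons at the projected locus position.
    """
    if cfg.pixel_size >= forespore.diameter:
        raise ResolutionError("pixel_size must be smaller than the forespore")
    rng = _as_rng(cfg.rng_seed if rng is None else rng)
    shape = cfg.image_shape or default_image_shape(forespore, cfg)
    sigma = max(cfg.psf_sigma_membrane, cfg.psf_sigma_locus)
    if min(shape) * cfg.pixel_size < forespore.diameter + 2 * 3 * sigma:
        raise ResolutionError(
            "image too small: forespore must fit with a margin >= 3 psf_sigma"
        )
    if center_px is None:
        center_px = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    cy, cx = center_px
    px = cfg.pixel_size
    os_ = cfg.oversample

    # membrane channel: emission density -> PSF blur -> pixel binning
    SY, SX = _supersample_grid(shape, os_)
    X = (SX - cx) * px
    Y = (SY - cy) * px
    col = _membrane_column(forespore, cfg, X, Y)
    total = col.sum()
    membrane_photons = cfg.membrane_photons
    if total > 0 and membrane_photons > 0:
        col = col * (membrane_photons / total)
        col = gaussian_filter(col, cfg.psf_sigma_membrane / px * os_, mode="constant")
        mem_expected = col.reshape(shape[0], os_, shape[1], os_).sum(axis=(1, 3))
    else:
        mem_expected = np.zeros(shape)

    # locus channel: normalised 2D Gaussian sampled at pixel centres
    c3 = np.asarray(forespore.center_3d, dtype=float)
    pos = np.asarray(locus_position, dtype=float)
    row0 = cy + (pos[1] - c3[1]) / px
    col0 = cx + (pos[0] - c3[0]) / px
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    s_px = cfg.psf_sigma_locus / px
    g = np.exp(-(((rr - row0) ** 2) + ((cc - col0) ** 2)) / (2.0 * s_px * s_px))
    loc_expected = cfg.photon_budget * g / (2.0 * np.pi * s_px * s_px)

    membrane = _apply_noise(mem_expected, cfg, rng)
    locus = _apply_noise(loc_expected, cfg, rng)
    return membrane, locus


# --------------------------------------------------------------------------
# multi-cell simulations


@dataclass
class FieldResult:
    """Images plus serialisable ground truth for a simulated field."""

    images: List[Tuple[np.ndarray, np.ndarray]]
    truth: pd.DataFrame
    forespore: ForesporeModel
    placement: LocusPlacementModel
    config: ImagingConfig


def _truth_frame(records: List[GroundTruthRecord]) -> pd.DataFrame:
    rows = []
    for t in records:
        x, y, z = t.locus_position_3d
        rows.append(
            {
                "cell_id": t.cell_id,
                "locus_x_nm": x,
                "locus_y_nm": y,
                "locus_z_nm": z,
                "true_membrane_distance_3d_nm": t.true_membrane_distance_3d,
                "true_projected_distance_nm": t.true_projected_distance,
                "mode": t.mode,
                "true_onset_yfp_min": t.true_onset_yfp,
                "true_onset_cfp_min": t.true_onset_cfp,
            }
        )
    return pd.DataFrame(rows)


def simulate_field(
    n_cells: int,
    forespore: ForesporeModel,
    placement: LocusPlacementModel,
    cfg: ImagingConfig,
) -> FieldResult:
    """Simulate ``n_cells`` independent forespores (one image pair each)."""
    if n_cells < 1:
        raise InvalidModelError("n_cells must be >= 1")
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(n_cells)
    images = []
    records = []
    for cell_id, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pos, truth = place_locus(forespore, placement, rng, cell_id=cell_id)
        mem, loc = render_frame(forespore, pos, cfg, rng=rng)
        images.append((mem, loc))
        records.append(truth)
    return FieldResult(images, _truth_frame(records), forespore, placement, cfg)


@dataclass
class TimelapseResult:
    """Per-cell reporter intensity traces on a common frame grid."""

    times: np.ndarray  # (n_frames,) minutes
    yfp: np.ndarray  # (n_cells, n_frames) counts
    cfp: np.ndarray
    truth: pd.DataFrame
    kinetics: KineticsConfig


def simulate_timelapse(
    n_cells: int,
    kinetics: KineticsConfig,
    seed: int = 0,
) -> TimelapseResult:
    """Simulate dual-reporter traces: YFP rises at septation, CFP after
    septation + translocation time.  Cells drawn ``yfp_miss_prob`` never
    develop YFP signal (CFP-only mis-capture class)."""
    if n_cells < 1:
        raise InvalidModelError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.arange(kinetics.n_frames) * kinetics.frame_interval
    t_sep = draw_times(kinetics.septation_time, n_cells, rng)
    t_trans = draw_times(kinetics.translocation_time, n_cells, rng)
    yfp_onset = t_sep
    cfp_onset = t_sep + t_trans
    yfp_missed = rng.uniform(size=n_cells) < kinetics.yfp_miss_prob

    rise_y = np.clip(times[None, :] - yfp_onset[:, None], 0.0, None)
    rise_c = np.clip(times[None, :] - cfp_onset[:, None], 0.0, None)
    rise_y[yfp_missed, :] = 0.0
    yfp = kinetics.background_level + kinetics.reporter_rise_rate * rise_y
    cfp = kinetics.background_level + kinetics.reporter_rise_rate * rise_c
    if kinetics.detection_noise > 0:
        yfp = yfp + rng.normal(0.0, kinetics.detection_noise, size=yfp.shape)
        cfp = cfp + rng.normal(0.0, kinetics.detection_noise, size=cfp.shape)

    records = []
    for i in range(n_cells):
        records.append(
            GroundTruthRecord(
                cell_id=i,
                mode="timelapse",
                true_onset_yfp=None if yfp_missed[i] else float(yfp_onset[i]),
                true_onset_cfp=float(cfp_onset[i]),
            )
        )
    truth = _truth_frame(records)
    truth["true_translocation_min"] = t_trans
    truth["yfp_missed"] = yfp_missed
    return TimelapseResult(times, yfp, cfp, truth, kinetics)
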