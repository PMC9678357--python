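"""Synthetic-data generators emulating the study's data structure.

Every analysis arm gets a generator that produces inputs with the
statistical structure the arm assumes, together with the ground truth
needed to phrase recovery tests:

* two-group six-session voxel panels with a region-localized
  group-by-time effect following one of the trajectory shapes, subject
  random intercept/slope, and Gaussian noise;
* confocal-like stacks of tubular fibers with known total centerline
  length and radius, a depth-dependent labeling decay emulating limited
  antibody penetration, PSF blur and Poisson noise;
* three-class fluorescence sections (background / autofluorescence /
  specific signal) with a stored class map;
* 30-trial reaching sessions with a saturating daily success probability.

All generators are deterministic given their config (seeded
``numpy.random.default_rng``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .behavior import TrialRecord
from .fiber import DEFAULT_SPACING_UM, FiberSkeleton, ProbeStack
from .timecourse import (
    SESSION_DAYS,
    DEFAULT_VOXEL_SIZE_MM,
    SubjectRecord,
    VolumeSeries,
    trajectory_basis,
)

__all__ = [
    "LongitudinalConfig",
    "FiberPhantomConfig",
    "SectionConfig",
    "BehaviorConfig",
    "gen_longitudinal_volumes",
    "gen_fiber_stack",
    "polyline_length_in_z_window",
    "gen_densitometry_section",
    "gen_behavior_sessions",
]


# ---------------------------------------------------------------------------
# Longitudinal voxel panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LongitudinalConfig:
    """Two-group longitudinal phantom.

    The trained group's voxels inside ``effect_region`` follow
    ``baseline * (1 + effect_amplitude * f(t))``; everything else is
    baseline plus subject random effects and Gaussian noise.  Amplitude
    is a fraction of baseline (negative = decrease, the gray-matter
    direction; positive = the white-matter direction).
    """

    seed: int = 0
    n_per_group: int = 20
    session_days: tuple[float, ...] = SESSION_DAYS
    grid: tuple[int, int, int] = (20, 20, 20)
    effect_shape: str = "asymptotic"
    effect_amplitude: float = -0.05
    effect_region: tuple[slice, slice, slice] | None = None
    baseline: float = 0.5
    baseline_spatial_sd: float = 0.02
    baseline_smooth_vox: float = 2.0
    noise_sd: float = 0.01
    random_intercept_sd: float = 0.02
    random_slope_sd: float = 0.01
    tiv_mean: float = 450.0
    tiv_sd: float = 25.0
    tiv_coef: float = 0.0
    voxel_size: float = DEFAULT_VOXEL_SIZE_MM
    dropout_per_session: tuple[int, ...] | None = None

    def region_slices(self) -> tuple[slice, slice, slice]:
        if self.effect_region is not None:
            return self.effect_region
        # default: centered 5x5x5 block
        out = []
        for dim in self.grid:
            lo = max(0, dim // 2 - 2)
            out.append(slice(lo, min(dim, lo + 5)))
        return tuple(out)


def gen_longitudinal_volumes(
    config: LongitudinalConfig,
) -> tuple[VolumeSeries, list[SubjectRecord], dict]:
    """Generate a voxel panel, its subject records, and the ground truth.

    Returns ``(series, subjects, truth)`` where ``truth`` holds the
    boolean ``effect_mask``, the per-session basis values ``f``, and the
    signal amplitude on the data scale (``baseline * effect_amplitude``).

    ``dropout_per_session`` optionally gives the number of trained
    subjects present at each session (nondecreasing, emulating the
    cross-sectional accrual of the study design); absent sessions are
    flagged missing and NaN-filled.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    days = np.asarray(cfg.session_days, dtype=float)
    n_sess = len(days)
    n = 2 * cfg.n_per_group
    gx, gy, gz = cfg.grid
    region = cfg.region_slices()
    effect_mask = np.zeros(cfg.grid, dtype=bool)
    try:
        effect_mask[region] = True
    except IndexError as err:
        raise ValueError(f"effect region outside grid {cfg.grid}") from err
    if not effect_mask.any():
        raise ValueError(f"effect region {region} outside grid {cfg.grid}")

    f = trajectory_basis(cfg.effect_shape, days, float(days.max()))

    # smooth spatial baseline field, strictly positive
    base_field = cfg.baseline + cfg.baseline_spatial_sd * ndimage.gaussian_filter(
        rng.standard_normal(cfg.grid), cfg.baseline_smooth_vox, mode="reflect"
    )
    base_field = np.clip(base_field, 1e-3, None)

    tiv = rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n)
    b0 = rng.normal(0.0, cfg.random_intercept_sd, size=n)
    b1 = rng.normal(0.0, cfg.random_slope_sd, size=n)
    trained = np.array([True] * cfg.n_per_group + [False] * cfg.n_per_group)

    data = np.empty((n, n_sess, gx, gy, gz))
    signal_scale = cfg.baseline * cfg.effect_amplitude
    for i in range(n):
        for j in range(n_sess):
            vol = base_field + b0[i] + b1[i] * f[j]
            vol = vol + cfg.tiv_coef * (tiv[i] - cfg.tiv_mean)
            if trained[i]:
                vol = vol + np.where(effect_mask, signal_scale * f[j], 0.0)
            if cfg.noise_sd > 0:
                vol = vol + rng.normal(0.0, cfg.noise_sd, size=cfg.grid)
            data[i, j] = vol

    missing = np.zeros((n, n_sess), dtype=bool)
    if cfg.dropout_per_session is not None:
        counts = cfg.dropout_per_session
        if len(counts) != n_sess:
            raise ValueError("dropout_per_session must give one count per session")
        for j, m in enumerate(counts):
            missing[m : cfg.n_per_group, j] = True  # later-accrued trained subjects
        data[missing] = np.nan

    subjects = []
    for i in range(n):
        present = tuple(days[~missing[i]])
        subjects.append(
            SubjectRecord(
                id=f"{'srt' if trained[i] else 'ntc'}{i:03d}",
                group="trained" if trained[i] else "control",
                tiv=float(tiv[i]),
                days_present=present,
            )
        )
    series = VolumeSeries(
        data=data,
        voxel_size=cfg.voxel_size,
        session_days=tuple(days),
        missing=missing,
    )
    truth = {
        "effect_mask": effect_mask,
        "f": f,
        "signal_scale": signal_scale,
        "baseline_field": base_field,
        "tiv": tiv,
        "random_intercepts": b0,
        "random_slopes": b1,
    }
    return series, subjects, truth


# ---------------------------------------------------------------------------
# Confocal fiber phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberPhantomConfig:
    """Tubular-fiber stack phantom.

    Fibers are smooth random 3D polylines rasterized as tubes of
    ``radius_um`` at the acquisition anisotropy; their intensity is
    modulated by a depth-decay profile (plateau to ``decay_depth_um``,
    then a smooth logistic fall-off of width ``decay_width_um``,
    emulating limited antibody penetration), blurred by a Gaussian PSF
    and corrupted by Poisson noise.
    """

    seed: int = 0
    shape: tuple[int, int, int] = (24, 112, 112)  # (z, y, x) voxels
    spacing: tuple[float, float, float] = DEFAULT_SPACING_UM
    n_fibers: int = 5
    radius_um: float = 0.45
    step_um: float = 0.25
    turn_sd: float = 0.08
    fiber_intensity: float = 180.0
    background: float = 15.0
    decay_depth_um: float = 8.0
    decay_width_um: float = 0.8
    z_amplitude_um: float = 0.8
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.1, 0.1)
    poisson_noise: bool = True


def _random_polyline(
    rng: np.random.Generator,
    extent_um: np.ndarray,
    step: float,
    turn_sd: float,
    z_center: float,
    z_amp: float,
    z_wavelength: float = 25.0,
) -> np.ndarray:
    """Smooth fiber path in (x, y, z) um.

    The fiber wanders in the section plane (heading jitter ``turn_sd``
    per step, reflecting at the lateral borders) while its depth follows
    a gentle undulation of amplitude ``z_amp`` around ``z_center`` --
    the way myelinated cortical axons dip through a tangential section.
    Undulating depths give every optical section some fiber coverage
    while keeping two fibers at the same depth only at isolated
    crossings (so their tubes rarely merge).
    """
    lo_xy = np.array([0.0, 0.0])
    hi_xy = np.array([extent_um[2], extent_um[1]])
    xy = lo_xy + rng.random(2) * (hi_xy - lo_xy)
    phi = rng.uniform(0, 2 * math.pi)
    phase = rng.uniform(0, 2 * math.pi)
    # long walks keep the (fixed, ~1 um) thinning end-erosion small
    # relative to each fiber's length
    n_steps = int(np.ceil(2.5 * max(extent_um) / step))
    z_max = extent_um[0]
    pts = []
    s = 0.0
    for k in range(n_steps + 1):
        z = z_center + z_amp * math.sin(2 * math.pi * s / z_wavelength + phase)
        z = float(np.clip(z, 0.05, z_max - 0.05))
        pts.append([xy[0], xy[1], z])
        phi += rng.normal(0.0, turn_sd)
        xy = xy + step * np.array([math.cos(phi), math.sin(phi)])
        for ax in range(2):
            if xy[ax] < lo_xy[ax]:
                xy[ax] = 2 * lo_xy[ax] - xy[ax]
                phi = math.pi - phi if ax == 0 else -phi
            elif xy[ax] > hi_xy[ax]:
                xy[ax] = 2 * hi_xy[ax] - xy[ax]
                phi = math.pi - phi if ax == 0 else -phi
        s += step
    return np.array(pts)


def polyline_length_in_z_window(
    polylines: Sequence[np.ndarray], z0: float, z1: float
) -> float:
    """Analytic arc length of ground-truth polylines with piece midpoint in [z0, z1]."""
    total = 0.0
    for pts in polylines:
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mid_z = 0.5 * (pts[:-1, 2] + pts[1:, 2])
        total += float(dl[(mid_z >= z0) & (mid_z <= z1)].sum())
    return total


def gen_fiber_stack(
    config: FiberPhantomConfig,
) -> tuple[ProbeStack, dict]:
    """Generate a fiber phantom and its ground truth.

    Returns ``(stack, truth)``; ``truth`` holds the exact polylines (um,
    (x, y, z) columns), their total arc length, the tube radius, the
    clean tube mask, and a ground-truth :class:`FiberSkeleton` built from
    the polylines.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nz, ny, nx = cfg.shape
    sz, sy, sx = cfg.spacing
    if cfg.radius_um < sx:
        import warnings

        warnings.warn("fiber radius below one in-plane voxel: sub-resolution tubes")
    extent = np.array([nz * sz, ny * sy, nx * sx])  # (z, y, x) um

    # undulating fibers stratified in depth from the cut surface (z ~ 0,
    # where the section was sliced through tissue) down to the labeled
    # depth, so every optical section in the stained range sees some
    z_lo = 0.4
    z_hi = max(z_lo + 0.1, min(cfg.decay_depth_um - 2.0, extent[0] - 2.0))
    centers = np.linspace(z_lo + 0.2, z_hi, cfg.n_fibers)
    polylines = [
        _random_polyline(
            rng, extent, cfg.step_um, cfg.turn_sd, zc, cfg.z_amplitude_um
        )
        for zc in centers
    ]
    total_length = float(
        sum(np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in polylines)
    )

    # rasterize centerlines, then grow tubes with the anisotropic EDT
    marks = np.zeros(cfg.shape, dtype=bool)
    for pts in polylines:
        # dense samples so no voxel along the path is skipped
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        n_sub = np.maximum(1, np.ceil(dl / (0.4 * min(sy, sx))).astype(int))
        dense = [pts[0]]
        for a, b, k in zip(pts[:-1], pts[1:], n_sub):
            for t in np.linspace(0, 1, k + 1)[1:]:
                dense.append(a + t * (b - a))
        dense = np.array(dense)
        iz = np.clip(np.round(dense[:, 2] / sz).astype(int), 0, nz - 1)
        iy = np.clip(np.round(dense[:, 1] / sy).astype(int), 0, ny - 1)
        ix = np.clip(np.round(dense[:, 0] / sx).astype(int), 0, nx - 1)
        marks[iz, iy, ix] = True
    dist = ndimage.distance_transform_edt(~marks, sampling=cfg.spacing)
    tube = dist <= cfg.radius_um

    # depth-dependent labeling: plateau then logistic fall-off
    z_um = np.arange(nz) * sz
    decay = expit((cfg.decay_depth_um - z_um) / cfg.decay_width_um)
    img = cfg.background + (cfg.fiber_intensity - cfg.background) * (
        tube * decay[:, None, None]
    )
    sigma_vox = tuple(s / v for s, v in zip(cfg.psf_sigma_um, cfg.spacing))
    img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="reflect")
    if cfg.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # polyline columns are (x, y, z) um, matching FiberSkeleton segments
    truth = {
        "polylines": polylines,
        "total_length_um": total_length,
        "radius_um": cfg.radius_um,
        "tube_mask": tube,
        "skeleton": FiberSkeleton(segments=[p.copy() for p in polylines]),
        "decay_profile": decay,
    }
    return ProbeStack(img, cfg.spacing), truth


# ---------------------------------------------------------------------------
# Densitometry sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectionConfig:
    """Three-class fluorescence-section phantom.

    Class means must be strictly increasing (background <
    autofluorescence < specific signal).  Spatial texture comes from
    smoothed Gaussian random fields thresholded to the target area
    fractions, so classes form contiguous blobs as real tissue does.
    """

    seed: int = 0
    shape: tuple[int, int] = (192, 192)
    class_means: tuple[float, float, float] = (20.0, 90.0, 200.0)
    class_sds: tuple[float, float, float] = (6.0, 10.0, 12.0)
    class_fractions: tuple[float, float, float] = (0.55, 0.35, 0.10)
    texture_smooth_px: float = 3.0


def gen_densitometry_section(
    config: SectionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a section image and its true class map (0, 1, 2).

    Returns ``(image, class_map)`` with ``image`` uint8.
    """
    cfg = config
    m = cfg.class_means
    if not (m[0] < m[1] < m[2]):
        raise ValueError(f"class means must be strictly increasing, got {m}")
    fr = np.asarray(cfg.class_fractions, dtype=float)
    if not math.isclose(fr.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("class fractions must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    field1 = ndimage.gaussian_filter(
        rng.standard_normal(cfg.shape), cfg.texture_smooth_px, mode="reflect"
    )
    # threshold the field at quantiles so area fractions hit their targets
    q_specific = np.quantile(field1, 1.0 - fr[2])
    q_auto = np.quantile(field1, fr[0])
    class_map = np.ones(cfg.shape, dtype=np.uint8)
    class_map[field1 <= q_auto] = 0
    class_map[field1 > q_specific] = 2
    image = np.empty(cfg.shape, dtype=float)
    for c in range(3):
        sel = class_map == c
        image[sel] = rng.normal(m[c], cfg.class_sds[c], size=int(sel.sum()))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return image, class_map


# ---------------------------------------------------------------------------
# Behavior sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorConfig:
    """Saturating-learner phantom for the reaching task.

    Daily success probability follows
    ``p(d) = p0 + (p_max - p0) * (1 - exp(-rate * d))`` over
    ``n_days`` training days with ``n_trials`` pellets per day.  Attempts
    on successful trials are geometric (support 1, 2, ...) with success
    parameter ``attempt_p``; a small fraction of trials is flagged
    invalid (abnormal behavior).
    """

    seed: int = 0
    n_animals: int = 12
    n_days: int = 12
    n_trials: int = 30
    p0: float = 0.08
    p_max: float = 0.5
    rate: float = 0.35
    attempt_p: float = 0.5
    invalid_rate: float = 0.02

    def success_probability(self, day: np.ndarray | float) -> np.ndarray | float:
        return self.p0 + (self.p_max - self.p0) * (1.0 - np.exp(-self.rate * np.asarray(day, dtype=float)))


def gen_behavior_sessions(
    config: BehaviorConfig,
) -> dict[str, dict[int, list[TrialRecord]]]:
    """Generate per-animal, per-day trial lists.

    Raises
    ------
    ValueError
        If the configured probabilities fall outside [0, 1].
    """
    cfg = config
    days = np.arange(1, cfg.n_days + 1)
    p = np.asarray(cfg.success_probability(days), dtype=float)
    if np.any((p < 0) | (p > 1)) or not (0 <= cfg.invalid_rate <= 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    if not (0 < cfg.attempt_p <= 1):
        raise ValueError("attempt_p must lie in (0, 1]")
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, dict[int, list[TrialRecord]]] = {}
    for a in range(cfg.n_animals):
        animal = f"m{a:03d}"
        out[animal] = {}
        for d, pd_ in zip(days, p):
            trials = []
            for _ in range(cfg.n_trials):
                invalid = bool(rng.random() < cfg.invalid_rate)
                success = bool(rng.random() < pd_) and not invalid
                attempts = int(rng.geometric(cfg.attempt_p))
                trials.append(TrialRecord(success=success, attempts=attempts, invalid=invalid))
            out[animal][int(d)] = trials
    return out
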