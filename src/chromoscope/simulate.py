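"""Ground-truth-known synthetic scene generator.

Every analysis stage in this package is validated against scenes produced
here: Brownian tracks inside (or outside) a compartment, Poisson arrival
processes of surface-captured emitters with photobleaching, ensemble
dissociation traces with an immobile fraction, nucleoid images built from a
diffuse body plus high-density sub-blobs decorated with condensin-like
spots, and stretch/relax kymographs. Each generator records its full ground
truth (positions, times, areas, labels) so downstream recovery can be
asserted without re-deriving it.

Image formation is a Gaussian PSF integrated over pixels, Poisson shot
noise on signal plus background, a gamma-distributed EM-gain stage and
additive Gaussian read noise. Optics beyond the Gaussian PSF and
photophysics beyond single-exponential bleaching are deliberately out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from ._seeds import rng_for
from .errors import ConfigurationError, DomainError
from .stack import CameraModel, ImageStack

__all__ = [
    "SceneTruth",
    "NucleoidScene",
    "Kymograph",
    "simulate_brownian_tracks",
    "simulate_arrivals",
    "simulate_decay_trace",
    "render_frames",
    "render_nucleoid_stack",
    "simulate_nucleoid_population",
    "simulate_stretch_kymograph",
    "plateau_photons_for_snr",
]


@dataclass
class SceneTruth:
    """Ground truth of one synthetic scene.

    Only the tables relevant to the generating process are populated;
    the seed and generator parameters are always recorded.
    """

    seed: int
    params: dict = field(default_factory=dict)
    tracks: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None
    blobs: pd.DataFrame | None = None
    spots: pd.DataFrame | None = None


@dataclass
class NucleoidScene:
    """One synthetic chromosome: diffuse body plus condensed sub-blobs.

    The DNA signal is a smooth-edged disk (radius ``body_radius_um``,
    plateau intensity 1) with Gaussian sub-blobs of width ``blob_sigma_um``
    and relative amplitude ``blob_amplitude`` at ``blob_xy_um``. The
    rendering threshold for the "true" mask is half the body plateau, so the
    true area is the half-plateau super-threshold area of the noiseless
    image. Condensin-like spots carry a colocalized flag: colocalized spots
    sit on sub-blob centres, non-colocalized ones at least 0.7 um away from
    every sub-blob.
    """

    center_um: tuple[float, float]
    body_radius_um: float
    blob_xy_um: np.ndarray
    blob_sigma_um: float
    blob_amplitude: float
    true_area_um2: float
    spots: pd.DataFrame

    @property
    def n_subblobs(self) -> int:
        return len(self.blob_xy_um)


@dataclass
class Kymograph:
    """Space-time intensity map of a 1D profile along the capillary."""

    profile: np.ndarray  # (n_frames, n_pixels)
    t_s: np.ndarray
    pixel_size_um: float
    extent_um: np.ndarray  # noiseless true extent per frame
    epochs: list[tuple[float, float, str]]  # (start_s, end_s, "on"|"off")
    seed: int


# ---------------------------------------------------------------------------
# diffusion


def simulate_brownian_tracks(
    diffusion_um2_per_s: float,
    n_particles: int,
    n_frames: int,
    frame_interval_s: float,
    seed: int,
    geometry=None,
) -> SceneTruth:
    """Brownian tracks with per-axis step variance 2*D*dt.

    With ``geometry`` set, particles start uniformly inside the chamber disk
    (centred at (R, R)) and reflect at the wall; escape through the
    capillaries is not modelled particle-by-particle — the analytic
    compartment lifetime covers it. Without geometry, particles perform free
    diffusion from the origin.
    """
    if diffusion_um2_per_s < 0:
        raise DomainError(f"diffusion_um2_per_s must be >= 0, got {diffusion_um2_per_s}")
    if n_frames < 2:
        raise DomainError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * diffusion_um2_per_s * frame_interval_s)
    steps = rng.normal(0.0, sigma, size=(n_particles, n_frames - 1, 2))

    if geometry is None:
        start = np.zeros((n_particles, 2))
        pos = np.concatenate(
            [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
        )
    else:
        radius = geometry.radius_um
        center = np.array([radius, radius])
        # uniform start inside the disk
        r = radius * np.sqrt(rng.uniform(size=n_particles))
        theta = rng.uniform(0, 2 * math.pi, size=n_particles)
        cur = center + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
        pos = np.empty((n_particles, n_frames, 2))
        pos[:, 0] = cur
        for i in range(1, n_frames):
            cur = cur + steps[:, i - 1]
            cur = _reflect_into_disk(cur, center, radius)
            pos[:, i] = cur

    particle = np.repeat(np.arange(n_particles), n_frames)
    frame = np.tile(np.arange(n_frames), n_particles)
    tracks = pd.DataFrame(
        {
            "particle": particle,
            "frame": frame,
            "t_s": frame * frame_interval_s,
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
        }
    )
    return SceneTruth(
        seed=seed,
        params={
            "diffusion_um2_per_s": diffusion_um2_per_s,
            "n_particles": n_particles,
            "n_frames": n_frames,
            "frame_interval_s": frame_interval_s,
            "confined": geometry is not None,
        },
        tracks=tracks,
    )


def _reflect_into_disk(xy: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect points that stepped outside the chamber wall."""
    out = xy - center
    for _ in range(16):  # a single step rarely needs more than one bounce
        r = np.hypot(out[:, 0], out[:, 1])
        outside = r > radius
        if not np.any(outside):
            break
        scale = (2 * radius - r[outside]) / r[outside]
        out[outside] *= scale[:, None]
    else:
        np.clip(out, -radius, radius, out=out)
    return center + out


# ---------------------------------------------------------------------------
# surface-capture arrivals


def simulate_arrivals(
    rate_per_min: float,
    duration_min: float,
    bleach_tau_s: float,
    capture_radius_um: float = 6.0,
    seed: int = 0,
) -> SceneTruth:
    """Homogeneous Poisson arrivals of surface-captured emitters.

    Event times are uniform on [0, duration] given the Poisson count;
    positions are uniform over a disk-shaped capture area centred at
    (r+1, r+1) um; each emitter is visible from its arrival until an
    exponential photobleaching time with mean ``bleach_tau_s``.
    """
    if rate_per_min < 0:
        raise DomainError(f"rate_per_min must be >= 0, got {rate_per_min}")
    if bleach_tau_s <= 0:
        raise DomainError(f"bleach_tau_s must be > 0, got {bleach_tau_s}")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_per_min * duration_min)
    t_s = np.sort(rng.uniform(0.0, duration_min * 60.0, size=n))
    r = capture_radius_um * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    cx = cy = capture_radius_um + 1.0
    events = pd.DataFrame(
        {
            "event": np.arange(n),
            "t_s": t_s,
            "x_um": cx + r * np.cos(theta),
            "y_um": cy + r * np.sin(theta),
            "bleach_s": rng.exponential(bleach_tau_s, size=n),
        }
    )
    return SceneTruth(
        seed=seed,
        params={
            "rate_per_min": rate_per_min,
            "duration_min": duration_min,
            "bleach_tau_s": bleach_tau_s,
            "capture_radius_um": capture_radius_um,
            "center_um": (cx, cy),
        },
        events=events,
    )


# ---------------------------------------------------------------------------
# dissociation traces


def simulate_decay_trace(
    tau_s: float,
    immobile_fraction: float,
    noise_sd: float,
    frame_interval_s: float,
    duration_s: float,
    seed: int,
) -> pd.DataFrame:
    """Normalized dissociation trace I(t) = (1-A) exp(-t/tau) + A plus noise.

    The noiseless value at t=0 is exactly 1; ``immobile_fraction`` A is the
    tightly bound plateau. Returns a DataFrame with columns t_s, intensity.
    """
    if tau_s <= 0:
        raise DomainError(f"tau_s must be > 0, got {tau_s}")
    if not 0.0 <= immobile_fraction <= 1.0:
        raise DomainError(
            f"immobile_fraction must be in [0, 1], got {immobile_fraction}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + 0.5 * frame_interval_s, frame_interval_s)
    clean = (1.0 - immobile_fraction) * np.exp(-t / tau_s) + immobile_fraction
    noisy = clean + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else clean
    return pd.DataFrame({"t_s": t, "intensity": noisy})


# ---------------------------------------------------------------------------
# image formation


def _camera_noise(
    expected_photons: np.ndarray, camera: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise -> gamma EM multiplication -> Gaussian read noise."""
    photons = rng.poisson(expected_photons).astype(float)
    counts = np.zeros_like(photons)
    lit = photons > 0
    counts[lit] = rng.gamma(shape=photons[lit], scale=camera.em_gain)
    if camera.read_noise_counts > 0:
        counts += rng.normal(0.0, camera.read_noise_counts, size=counts.shape)
    return np.clip(counts, 0.0, None)


def _add_integrated_gaussian(
    frame: np.ndarray,
    x_px: float,
    y_px: float,
    photons: float,
    sigma_px: float,
) -> None:
    """Add a pixel-integrated 2D Gaussian spot to one frame, in place."""
    h, w = frame.shape
    half = int(math.ceil(4 * sigma_px)) + 1
    c0 = max(int(round(x_px)) - half, 0)
    c1 = min(int(round(x_px)) + half + 1, w)
    r0 = max(int(round(y_px)) - half, 0)
    r1 = min(int(round(y_px)) + half + 1, h)
    if c0 >= c1 or r0 >= r1:
        return
    s = sigma_px * math.sqrt(2.0)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    fx = 0.5 * (erf((cols + 0.5 - x_px) / s) - erf((cols - 0.5 - x_px) / s))
    fy = 0.5 * (erf((rows + 0.5 - y_px) / s) - erf((rows - 0.5 - y_px) / s))
    frame[r0:r1, c0:c1] += photons * np.outer(fy, fx)


def _emitter_table(truth, camera: CameraModel, n_frames: int | None) -> pd.DataFrame:
    """Normalize the supported truth inputs to (frame, x_um, y_um) rows."""
    if isinstance(truth, pd.DataFrame):
        return truth
    if isinstance(truth, SceneTruth):
        if truth.tracks is not None:
            return truth.tracks
        if truth.events is not None:
            ev = truth.events
            dt = camera.frame_interval_s
            if n_frames is None:
                duration_s = truth.params.get("duration_min", 0.0) * 60.0
                n_frames = int(math.ceil(duration_s / dt))
            rows = []
            for t0, x, y, bleach in zip(ev.t_s, ev.x_um, ev.y_um, ev.bleach_s):
                f0 = int(math.ceil(t0 / dt))
                f1 = min(int(math.floor((t0 + bleach) / dt)), n_frames - 1)
                for f in range(f0, f1 + 1):
                    rows.append((f, x, y))
            return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])
    raise DomainError(f"cannot render truth of type {type(truth).__name__}")


def render_frames(
    truth,
    camera: CameraModel,
    seed: int,
    fov_um: tuple[float, float] | None = None,
    n_frames: int | None = None,
    photons_per_frame: float | None = None,
    channel_name: str = "ch0",
) -> ImageStack:
    """Render point emitters (tracks or arrival events) into a camera stack.

    ``truth`` may be a SceneTruth (tracks or events populated), a DataFrame
    with (frame, x_um, y_um) rows, or a list of NucleoidScene (delegated to
    :func:`render_nucleoid_stack`). The field of view defaults to the
    bounding box of all emitters plus a 2 um margin and must contain every
    emitter.
    """
    if isinstance(truth, NucleoidScene):
        truth = [truth]
    if isinstance(truth, (list, tuple)) and all(
        isinstance(s, NucleoidScene) for s in truth
    ):
        return render_nucleoid_stack(truth, camera, seed=seed, fov_um=fov_um)

    table = _emitter_table(truth, camera, n_frames)
    px = camera.pixel_size_um
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1 if len(table) else 1
    if fov_um is None:
        if len(table) == 0:
            raise ConfigurationError("empty truth requires an explicit fov_um")
        fov_um = (table["x_um"].max() + 2.0, table["y_um"].max() + 2.0)
    w = int(math.ceil(fov_um[0] / px))
    h = int(math.ceil(fov_um[1] / px))
    if len(table):
        if (
            table["x_um"].min() < -0.5 * px
            or table["y_um"].min() < -0.5 * px
            or table["x_um"].max() > (w - 0.5) * px
            or table["y_um"].max() > (h - 0.5) * px
        ):
            raise ConfigurationError(
                "field of view does not contain all emitters; enlarge fov_um"
            )
    flux = camera.photons_per_frame if photons_per_frame is None else photons_per_frame
    signal = np.zeros((n_frames, h, w))
    sigma_px = camera.psf_sigma_px
    for f, x, y in zip(
        table["frame"].to_numpy(), table["x_um"].to_numpy(), table["y_um"].to_numpy()
    ):
        fi = int(f)
        if 0 <= fi < n_frames:
            _add_integrated_gaussian(signal[fi], x / px, y / px, flux, sigma_px)
    rng = np.random.default_rng(seed)
    counts = _camera_noise(signal + camera.background_photons, camera, rng)
    return ImageStack(counts=counts, camera=camera, channel_names=(channel_name,))


# ---------------------------------------------------------------------------
# nucleoid scenes


def plateau_photons_for_snr(snr: float, background_photons: float) -> float:
    """Plateau photon level P with P / sqrt(P + B) equal to the requested SNR."""
    if snr <= 0:
        raise DomainError("snr must be > 0")
    return 0.5 * (snr**2 + snr * math.sqrt(snr**2 + 4.0 * background_photons))


def _nucleoid_field(
    scenes: list[NucleoidScene], shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Noiseless normalized DNA intensity field (plateau = 1 inside a body)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    xum = xx * pixel_size_um
    yum = yy * pixel_size_um
    field_img = np.zeros(shape)
    edge = 2 * pixel_size_um  # PSF-blurred body edge width
    for sc in scenes:
        r = np.hypot(xum - sc.center_um[0], yum - sc.center_um[1])
        field_img += 0.5 * (1.0 + erf((sc.body_radius_um - r) / (math.sqrt(2) * edge)))
        for bx, by in sc.blob_xy_um:
            d2 = (xum - bx) ** 2 + (yum - by) ** 2
            field_img += sc.blob_amplitude * np.exp(-d2 / (2 * sc.blob_sigma_um**2))
    return field_img


def render_nucleoid_stack(
    scenes: list[NucleoidScene],
    camera: CameraModel,
    seed: int,
    fov_um: tuple[float, float] | None = None,
    plateau_photons: float = 105.0,
    spot_photons: float | None = None,
    n_frames: int = 1,
) -> ImageStack:
    """Render a two-channel (dna, condensin) stack of nucleoid scenes.

    The DNA channel renders the body+blob field scaled to ``plateau_photons``
    at the body plateau (default ~105 photons, an SNR of 10 over a 5-photon
    background); the condensin channel renders each spot as a point emitter.
    """
    px = camera.pixel_size_um
    if fov_um is None:
        extent = max(
            sc.center_um[i] + sc.body_radius_um + 2.0 for sc in scenes for i in (0, 1)
        )
        fov_um = (extent, extent)
    w = int(math.ceil(fov_um[0] / px))
    h = int(math.ceil(fov_um[1] / px))
    for sc in scenes:
        if (
            sc.center_um[0] + sc.body_radius_um > fov_um[0]
            or sc.center_um[1] + sc.body_radius_um > fov_um[1]
        ):
            raise ConfigurationError("field of view smaller than the scene extent")
    dna_signal = plateau_photons * _nucleoid_field(scenes, (h, w), px)
    spot_signal = np.zeros((h, w))
    flux = camera.photons_per_frame if spot_photons is None else spot_photons
    for sc in scenes:
        for x, y in zip(sc.spots["x_um"], sc.spots["y_um"]):
            _add_integrated_gaussian(spot_signal, x / px, y / px, flux, camera.psf_sigma_px)
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        dna = _camera_noise(dna_signal + camera.background_photons, camera, rng)
        spot = _camera_noise(spot_signal + camera.background_photons, camera, rng)
        frames.append(np.stack([dna, spot]))
    return ImageStack(
        counts=np.stack(frames), camera=camera, channel_names=("dna", "condensin")
    )


def _scene_true_area_um2(scene: NucleoidScene, pixel_size_um: float) -> float:
    """Measured half-plateau mask area of one scene's noiseless field.

    Rendered on a local grid so that blob tails reaching past the body edge
    (relevant for compact chromosomes) are part of the recorded truth.
    """
    margin = scene.body_radius_um + 4.0 * scene.blob_sigma_um + 1.5
    n = int(math.ceil(2 * margin / pixel_size_um))
    local = NucleoidScene(
        center_um=(margin, margin),
        body_radius_um=scene.body_radius_um,
        blob_xy_um=scene.blob_xy_um
        - np.asarray(scene.center_um)
        + np.array([margin, margin]),
        blob_sigma_um=scene.blob_sigma_um,
        blob_amplitude=scene.blob_amplitude,
        true_area_um2=0.0,
        spots=scene.spots,
    )
    field_img = _nucleoid_field([local], (n, n), pixel_size_um)
    return float((field_img > 0.5).sum()) * pixel_size_um**2


def _place_blobs(
    rng: np.random.Generator,
    n: int,
    max_radius_um: float,
    min_sep_um: float,
) -> np.ndarray:
    """Sub-blob centres in a disk with pairwise separation, fallback to a ring."""
    if n == 0:
        return np.zeros((0, 2))
    for _ in range(300):
        pts = []
        for _ in range(n):
            for _ in range(60):
                r = max_radius_um * math.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * math.pi)
                p = (r * math.cos(a), r * math.sin(a))
                if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep_um for q in pts):
                    pts.append(p)
                    break
            else:
                break
        if len(pts) == n:
            return np.array(pts)
    # regular polygon fallback keeps determinism when rejection fails
    ring = min(min_sep_um / (2 * math.sin(math.pi / max(n, 2))), max_radius_um)
    a0 = rng.uniform(0, 2 * math.pi)
    ang = a0 + 2 * math.pi * np.arange(n) / max(n, 1)
    return np.stack([ring * np.cos(ang), ring * np.sin(ang)], axis=1)


def simulate_nucleoid_population(
    n_chromosomes: int,
    area_um2_mean: float,
    area_um2_cv: float,
    n_subblobs_range: tuple[int, int],
    mukb_spot_count_range: tuple[int, int],
    colocalized_fraction: float,
    seed: int,
    pixel_size_um: float = 0.16,
    blob_sigma_um: float = 0.45,
    blob_amplitude: float = 0.8,
    blob_min_sep_um: float = 2.0,
    spot_noise_um: float = 0.0,
    fov_um: float | None = None,
) -> tuple[list[NucleoidScene], SceneTruth]:
    """Population of synthetic chromosomes with known areas and colocalization.

    Each chromosome draws a target mask area (normal with the given mean and
    CV, truncated at 20% of the mean), renders as a smooth-edged disk whose
    half-plateau mask reproduces that area, and carries ``n_subblobs``
    condensed sub-blobs. Condensin-like spots (count drawn from
    ``mukb_spot_count_range``, inclusive) are placed on sub-blob centres for
    the colocalized share and >= 0.7 um away from every sub-blob otherwise;
    the population-level colocalized blob fraction equals the target up to
    rounding to whole blobs. ``spot_noise_um`` jitters colocalized spot
    placements (Gaussian per axis), emulating localization error.
    """
    if not 0.0 <= colocalized_fraction <= 1.0:
        raise DomainError("colocalized_fraction must be in [0, 1]")
    if n_subblobs_range[0] > n_subblobs_range[1] or n_subblobs_range[0] < 0:
        raise DomainError(f"invalid n_subblobs_range {n_subblobs_range}")
    if mukb_spot_count_range[0] > mukb_spot_count_range[1] or mukb_spot_count_range[0] < 0:
        raise DomainError(f"invalid mukb_spot_count_range {mukb_spot_count_range}")
    rng = np.random.default_rng(seed)

    areas = rng.normal(area_um2_mean, area_um2_cv * area_um2_mean, size=n_chromosomes)
    areas = np.clip(areas, 0.2 * area_um2_mean, None)
    radii = np.sqrt(areas / math.pi)

    pitch = 2.0 * (radii.max() + 2.0)
    n_cols = int(math.ceil(math.sqrt(n_chromosomes)))
    needed = n_cols * pitch + 2.0
    if fov_um is not None and fov_um < needed:
        raise ConfigurationError(
            f"cannot pack {n_chromosomes} chromosomes of these areas into "
            f"{fov_um} um (need >= {needed:.1f} um)"
        )
    fov = needed if fov_um is None else fov_um

    n_blob_draw = rng.integers(
        n_subblobs_range[0], n_subblobs_range[1] + 1, size=n_chromosomes
    )
    n_spot_draw = rng.integers(
        mukb_spot_count_range[0], mukb_spot_count_range[1] + 1, size=n_chromosomes
    )
    # apportion the exact population-level number of colocalized blobs:
    # floor(f * n_blobs) per chromosome, remainder handed out in order,
    # capped by both the blob and the spot count of each chromosome
    total_blobs = int(n_blob_draw.sum())
    budget = int(round(colocalized_fraction * total_blobs))
    cap = np.minimum(n_blob_draw, n_spot_draw).astype(int)
    n_coloc_per = np.minimum(
        np.floor(colocalized_fraction * n_blob_draw).astype(int), cap
    )
    short = budget - int(n_coloc_per.sum())
    for i in range(n_chromosomes):
        if short <= 0:
            break
        room = int(cap[i] - n_coloc_per[i])
        take = min(room, short)
        n_coloc_per[i] += take
        short -= take

    scenes: list[NucleoidScene] = []
    region_rows, blob_rows, spot_rows = [], [], []
    for i in range(n_chromosomes):
        cx = (i % n_cols + 0.5) * pitch + 1.0
        cy = (i // n_cols + 0.5) * pitch + 1.0
        r_body = radii[i]
        # compact chromosomes carry proportionally smaller sub-blobs so the
        # condensed structure stays inside the body
        sigma_eff = min(blob_sigma_um, 0.4 * r_body)
        blobs = _place_blobs(
            rng, int(n_blob_draw[i]), max(0.8 * r_body - sigma_eff, 0.3), blob_min_sep_um
        )
        blobs = blobs + np.array([cx, cy])

        n_here = len(blobs)
        n_coloc = int(n_coloc_per[i])
        coloc_idx = rng.choice(n_here, size=n_coloc, replace=False) if n_here else []

        srows = []
        for k in range(int(n_spot_draw[i])):
            jx, jy = (
                rng.normal(0.0, spot_noise_um, size=2) if spot_noise_um > 0 else (0.0, 0.0)
            )
            if k < n_coloc:
                bx, by = blobs[coloc_idx[k]]
                srows.append((i, bx + jx, by + jy, True, int(coloc_idx[k])))
            else:
                srows.append((i, *_far_point(rng, cx, cy, r_body, blobs), False, -1))
        for k, (bx, by) in enumerate(blobs):
            blob_rows.append((i, k, bx, by))
        spot_rows.extend(srows)
        spots_df = pd.DataFrame(
            srows, columns=["chromosome", "x_um", "y_um", "colocalized", "blob"]
        )
        scene = NucleoidScene(
            center_um=(cx, cy),
            body_radius_um=r_body,
            blob_xy_um=blobs,
            blob_sigma_um=sigma_eff,
            blob_amplitude=blob_amplitude,
            true_area_um2=0.0,
            spots=spots_df,
        )
        scene.true_area_um2 = _scene_true_area_um2(scene, pixel_size_um)
        scenes.append(scene)
        region_rows.append(
            (i, cx, cy, r_body, scene.true_area_um2, n_here, len(srows), n_coloc)
        )

    truth = SceneTruth(
        seed=seed,
        params={
            "n_chromosomes": n_chromosomes,
            "area_um2_mean": area_um2_mean,
            "area_um2_cv": area_um2_cv,
            "colocalized_fraction": colocalized_fraction,
            "fov_um": fov,
            "pixel_size_um": pixel_size_um,
            "blob_sigma_um": blob_sigma_um,
            "blob_amplitude": blob_amplitude,
        },
        regions=pd.DataFrame(
            region_rows,
            columns=[
                "chromosome",
                "center_x_um",
                "center_y_um",
                "body_radius_um",
                "true_area_um2",
                "n_subblobs",
                "n_spots",
                "n_colocalized",
            ],
        ),
        blobs=pd.DataFrame(blob_rows, columns=["chromosome", "blob", "x_um", "y_um"]),
        spots=pd.DataFrame(
            spot_rows, columns=["chromosome", "x_um", "y_um", "colocalized", "blob"]
        ),
    )
    return scenes, truth


def _far_point(
    rng: np.random.Generator,
    cx: float,
    cy: float,
    r_body: float,
    blobs: np.ndarray,
    min_dist_um: float = 0.7,
) -> tuple[float, float]:
    """A point inside the body at least ``min_dist_um`` from every sub-blob."""
    best, best_d = (cx + 0.9 * r_body, cy), -1.0
    for _ in range(500):
        r = 0.95 * r_body * math.sqrt(rng.uniform())
        a = rng.uniform(0, 2 * math.pi)
        p = (cx + r * math.cos(a), cy + r * math.sin(a))
        d = (
            float(np.min(np.hypot(blobs[:, 0] - p[0], blobs[:, 1] - p[1])))
            if len(blobs)
            else math.inf
        )
        if d >= min_dist_um:
            return p
        if d > best_d:
            best, best_d = p, d
    return best


# ---------------------------------------------------------------------------
# stretch/relax kymographs


def simulate_stretch_kymograph(
    extension_max_um: float,
    tau_on_s: float,
    tau_off_s: float,
    cycle_times: list[tuple[float, float]],
    frame_interval_s: float = 0.1,
    pixel_size_um: float = 0.16,
    profile_noise: float = 0.05,
    seed: int = 0,
) -> Kymograph:
    """Kymograph of a chromosome segment pulled into the capillary.

    ``cycle_times`` lists (field-on, field-off) second pairs; during ON
    epochs the super-threshold extent rises mono-exponentially toward
    ``extension_max_um`` with time constant ``tau_on_s`` and during OFF
    epochs it decays with ``tau_off_s``. Epochs must be ordered and
    non-overlapping.
    """
    if tau_on_s <= 0 or tau_off_s <= 0:
        raise DomainError("tau_on_s and tau_off_s must be > 0")
    last_end = -math.inf
    for t_on, t_off in cycle_times:
        if not t_on < t_off or t_on < last_end:
            raise ConfigurationError(f"overlapping or unordered epochs {cycle_times}")
        last_end = t_off
    duration = last_end + 4.0 * tau_off_s
    t = np.arange(0.0, duration, frame_interval_s)

    extent = np.zeros_like(t)
    x = 0.0
    epochs: list[tuple[float, float, str]] = []
    bounds = [0.0] + [b for pair in cycle_times for b in pair] + [duration]
    states = []
    for k in range(len(bounds) - 1):
        states.append("on" if k % 2 == 1 else "off")
    for (t0, t1), state in zip(zip(bounds[:-1], bounds[1:]), states):
        if t1 <= t0:
            continue
        sel = (t >= t0) & (t < t1)
        dt = t[sel] - t0
        if state == "on":
            extent[sel] = extension_max_um + (x - extension_max_um) * np.exp(
                -dt / tau_on_s
            )
        else:
            extent[sel] = x * np.exp(-dt / tau_off_s)
        if sel.any():
            x = float(extent[sel][-1])
        epochs.append((t0, t1, state))

    n_px = int(math.ceil(1.3 * extension_max_um / pixel_size_um)) + 4
    pos = np.arange(n_px) * pixel_size_um
    edge = pixel_size_um
    profile = 0.5 * (1.0 + erf((extent[:, None] - pos[None, :]) / (math.sqrt(2) * edge)))
    if profile_noise > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, profile_noise, size=profile.shape)
    return Kymograph(
        profile=profile,
        t_s=t,
        pixel_size_um=pixel_size_um,
        extent_um=extent,
        epochs=epochs,
        seed=seed,
    )
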