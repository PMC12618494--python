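"""End-to-end parameter-recovery pipelines on synthetic scenes.

Each routine generates scenes at known ground truth, runs the full analysis
chain (render -> detect -> link/cluster/segment -> fit) and returns the
recovered quantity next to the truth. They power the validation suite and
the reproduction script, and double as worked examples of how the library
modules compose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics, nucleoid, simulate, spots
from ._seeds import derive_seed
from .stack import CameraModel

__all__ = [
    "recover_diffusion",
    "recover_arrival_rate",
    "recover_decay",
    "recover_colocalization",
    "recover_cluster_counts",
    "recover_areas",
]


@dataclass(frozen=True)
class RecoveryResult:
    """Recovered value vs generator truth for one pipeline run."""

    value: float
    truth: float
    n: int
    extra: dict


def recover_diffusion(
    diffusion_um2_per_s: float = 1.7,
    n_tracks: int = 50,
    n_frames: int = 100,
    frame_interval_s: float = 2.0,
    seed: int = 0,
    render: bool = True,
    snr_min: float = 5.0,
) -> RecoveryResult:
    """Simulate free Brownian tracks, image and re-detect them, fit pooled MSD.

    Each track is rendered in its own field of view; detections are linked
    greedily (radius three standard deviations of a bridged-gap step) and
    per-track MSD curves are pooled with pair-count weights before the
    origin-constrained <r^2> = 4 D t fit.
    """
    camera = CameraModel(frame_interval_s=frame_interval_s)
    max_gap = 2
    link_radius = 3.0 * np.sqrt(
        4.0 * diffusion_um2_per_s * frame_interval_s * (max_gap + 1)
    )
    curves = []
    for i in range(n_tracks):
        truth = simulate.simulate_brownian_tracks(
            diffusion_um2_per_s, 1, n_frames, frame_interval_s,
            seed=derive_seed(seed, "diffusion-track", i),
        )
        table = truth.tracks
        if render:
            table = table.copy()
            table["x_um"] -= table["x_um"].min() - 3.0
            table["y_um"] -= table["y_um"].min() - 3.0
            stack = simulate.render_frames(
                table, camera, seed=derive_seed(seed, "diffusion-render", i)
            )
            det = spots.detect_spots(stack, snr_min=snr_min)
            linked = spots.link_tracks(det, link_radius, max_gap_frames=max_gap)
            sizes = linked.groupby("track_id").size()
            table = linked[linked["track_id"] == sizes.idxmax()]
        if len(table) >= 10:
            curves.append(spots.compute_msd(table, frame_interval_s=frame_interval_s))
    pooled = spots.pool_msd(curves)
    fit = spots.fit_diffusion(pooled)
    return RecoveryResult(
        value=fit.diffusion_um2_per_s,
        truth=diffusion_um2_per_s,
        n=len(curves),
        extra={"stderr": fit.stderr, "rendered": render},
    )


def recover_arrival_rate(
    rate_per_min: float,
    n_seeds: int = 10,
    duration_min: float = 60.0,
    bleach_tau_s: float = 60.0,
    seed: int = 0,
    capture_radius_um: float = 6.0,
    snr_min: float = 5.0,
    cluster_radius_um: float = 0.32,
    max_frame_gap: int = 5,
    min_detections: int = 2,
) -> RecoveryResult:
    """Full surface-capture chain: simulate movies, detect, cluster, fit CDF.

    Arrival events are recovered per movie by spot detection and
    spatiotemporal clustering; waiting times are pooled across movies and
    the mono-exponential waiting-time CDF is fitted by least squares.
    """
    camera = CameraModel(frame_interval_s=1.0)
    n_frames = int(duration_min * 60 / camera.frame_interval_s)
    fov = 2 * (capture_radius_um + 1.0) + 1.0
    waits, n_events_total, n_true_total = [], 0, 0
    for i in range(n_seeds):
        truth = simulate.simulate_arrivals(
            rate_per_min, duration_min, bleach_tau_s,
            capture_radius_um=capture_radius_um,
            seed=derive_seed(seed, "arrivals", i),
        )
        stack = simulate.render_frames(
            truth, camera, seed=derive_seed(seed, "arrivals-render", i),
            n_frames=n_frames, fov_um=(fov, fov),
        )
        det = spots.detect_spots(stack, snr_min=snr_min)
        events = spots.cluster_arrivals(
            det, cluster_radius_um, max_frame_gap, min_detections,
            frame_interval_s=camera.frame_interval_s,
        )
        n_events_total += len(events.events)
        n_true_total += len(truth.events)
        if len(events.events):
            waits.append(kinetics.waiting_times(events.arrival_times_s))
    pooled = np.concatenate(waits)
    fit = kinetics.fit_arrival_cdf(pooled, model="mono")
    return RecoveryResult(
        value=fit.rate_per_min,
        truth=rate_per_min,
        n=len(pooled),
        extra={"n_events": n_events_total, "n_true_events": n_true_total},
    )


def recover_decay(
    tau_s: float,
    immobile_fraction: float,
    n_seeds: int = 20,
    n_replicates: int = 4,
    noise_sd: float = 0.02,
    frame_interval_s: float = 5.0,
    duration_s: float = 1500.0,
    seed: int = 0,
) -> tuple[RecoveryResult, RecoveryResult]:
    """Average replicate dissociation traces per seed, fit, average fits.

    Mirrors the measurement protocol: traces are normalized, averaged over
    chromosomes, then fitted once (average-then-fit). Returns (tau result in
    minutes, immobile-fraction result).
    """
    taus, fracs = [], []
    for i in range(n_seeds):
        traces = []
        for r in range(n_replicates):
            df = simulate.simulate_decay_trace(
                tau_s, immobile_fraction, noise_sd, frame_interval_s, duration_s,
                seed=derive_seed(seed, "decay", i * 1000 + r),
            )
            traces.append(
                kinetics.DecayTrace(df["t_s"].to_numpy(), df["intensity"].to_numpy())
            )
        fit = kinetics.fit_decay(kinetics.average_traces(traces))
        taus.append(fit.tau_min)
        fracs.append(fit.immobile_fraction)
    return (
        RecoveryResult(float(np.mean(taus)), tau_s / 60.0, n_seeds,
                       {"sd": float(np.std(taus))}),
        RecoveryResult(float(np.mean(fracs)), immobile_fraction, n_seeds,
                       {"sd": float(np.std(fracs))}),
    )


def _nucleoid_scene_pipeline(
    seed: int,
    n_chromosomes: int,
    area_um2_mean: float,
    area_um2_cv: float,
    n_subblobs_range: tuple[int, int],
    mukb_spot_count_range: tuple[int, int],
    colocalized_fraction: float,
    spot_noise_um: float,
    snr_min: float = 5.0,
):
    """Generate, render, segment and detect one nucleoid scene."""
    camera = CameraModel()
    scenes, truth = simulate.simulate_nucleoid_population(
        n_chromosomes, area_um2_mean, area_um2_cv,
        n_subblobs_range, mukb_spot_count_range, colocalized_fraction,
        seed=derive_seed(seed, "nucleoid"),
        spot_noise_um=spot_noise_um,
    )
    fov = truth.params["fov_um"]
    stack = simulate.render_nucleoid_stack(
        scenes, camera, seed=derive_seed(seed, "nucleoid-render"),
        fov_um=(fov, fov),
    )
    px = camera.pixel_size_um
    dna = stack.channel("dna")[0]
    regions, labels = nucleoid.segment_chromosomes(dna, px)
    blobs = nucleoid.detect_blobs(dna, labels, px)
    det = spots.detect_spots(stack, channel="condensin", snr_min=snr_min)
    return truth, regions, labels, blobs, det, px


def recover_colocalization(
    colocalized_fraction: float = 0.9,
    n_seeds: int = 20,
    n_chromosomes: int = 6,
    spot_noise_um: float = 0.05,
    seed: int = 0,
    radius_um: float = 0.32,
) -> RecoveryResult:
    """Blob/condensin colocalized fraction via the strict <radius matching rule."""
    fractions = []
    total_blobs = 0
    for i in range(n_seeds):
        _, _, _, blobs, det, _ = _nucleoid_scene_pipeline(
            derive_seed(seed, "coloc", i), n_chromosomes,
            area_um2_mean=20.0, area_um2_cv=0.1,
            n_subblobs_range=(5, 5), mukb_spot_count_range=(5, 5),
            colocalized_fraction=colocalized_fraction,
            spot_noise_um=spot_noise_um,
        )
        res = nucleoid.colocalize(
            blobs[["x_um", "y_um"]].to_numpy(),
            det[["x_um", "y_um"]].to_numpy(),
            radius_um=radius_um,
        )
        fractions.append(res.fraction_colocalized)
        total_blobs += res.n_blobs
    return RecoveryResult(
        value=float(np.mean(fractions)),
        truth=colocalized_fraction,
        n=total_blobs,
        extra={"sd": float(np.std(fractions)), "n_seeds": n_seeds},
    )


def recover_cluster_counts(
    clusters_per_chromosome: int = 5,
    n_chromosomes: int = 5,
    seed: int = 0,
) -> RecoveryResult:
    """Median condensin clusters per chromosome from detection + containment."""
    _, _, labels, _, det, px = _nucleoid_scene_pipeline(
        derive_seed(seed, "counts"), n_chromosomes,
        area_um2_mean=20.0, area_um2_cv=0.1,
        n_subblobs_range=(clusters_per_chromosome, clusters_per_chromosome),
        mukb_spot_count_range=(clusters_per_chromosome, clusters_per_chromosome),
        colocalized_fraction=1.0, spot_noise_um=0.0,
    )
    counts = nucleoid.count_clusters(det[["x_um", "y_um"]].to_numpy(), labels, px)
    return RecoveryResult(
        value=float(counts.attrs["median"]),
        truth=float(clusters_per_chromosome),
        n=len(counts),
        extra={"counts": counts["n_clusters"].tolist()},
    )


def recover_areas(
    true_area_um2: float = 20.0,
    n_scenes: int = 20,
    chromosomes_per_scene: int = 4,
    seed: int = 0,
) -> RecoveryResult:
    """Mean segmented chromosome mask area on scenes of fixed true area."""
    areas = []
    for i in range(n_scenes):
        _, regions, _, _, _, _ = _nucleoid_scene_pipeline(
            derive_seed(seed, "areas", i), chromosomes_per_scene,
            area_um2_mean=true_area_um2, area_um2_cv=0.0,
            n_subblobs_range=(3, 6), mukb_spot_count_range=(0, 0),
            colocalized_fraction=0.0, spot_noise_um=0.0,
        )
        areas.extend(r.area_um2 for r in regions)
    return RecoveryResult(
        value=float(np.mean(areas)),
        truth=true_area_um2,
        n=len(areas),
        extra={"sd": float(np.std(areas))},
    )
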