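"""Camera model and in-memory image-stack container.

Coordinate convention used everywhere in the package: continuous positions in
micrometres, with the origin at the centre of the top-left pixel of frame 0;
``x_um`` runs along columns, ``y_um`` along rows; pixel indices are 0-based;
the time of frame ``i`` is ``i * frame_interval_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["CameraModel", "ImageStack"]


@dataclass(frozen=True)
class CameraModel:
    """EM-CCD imaging parameters for rendering and interpreting stacks.

    The pixel size of 0.16 um matches a back-projected EM-CCD pixel in the
    single-molecule setups this package emulates (two pixels = 0.32 um, the
    colocalization distance used downstream). Photon budget, background and
    read noise are generator defaults, not measured values, and are always
    recorded alongside rendered scenes.
    """

    pixel_size_um: float = 0.16
    frame_interval_s: float = 1.0
    exposure_s: float = 0.1
    photons_per_frame: float = 400.0
    background_photons: float = 5.0
    em_gain: float = 30.0
    read_noise_counts: float = 10.0
    psf_sigma_um: float = 0.16

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise DomainError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise DomainError(
                f"frame_interval_s must be > 0, got {self.frame_interval_s}"
            )
        # keep the PSF sampled at or above Nyquist; rendering narrower spots
        # than half a pixel would alias and is always a configuration mistake
        if self.psf_sigma_um < self.pixel_size_um / 2:
            raise DomainError(
                "psf_sigma_um must be >= pixel_size_um / 2 "
                f"({self.psf_sigma_um} < {self.pixel_size_um / 2})"
            )
        for name in ("photons_per_frame", "background_photons", "em_gain"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um


@dataclass
class ImageStack:
    """Frames x channels x rows x cols of camera counts with acquisition metadata."""

    counts: np.ndarray
    camera: CameraModel
    channel_names: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim == 2:
            counts = counts[None, None]
        elif counts.ndim == 3:
            counts = counts[:, None]
        if counts.ndim != 4:
            raise DomainError(
                f"counts must be (frame, channel, row, col), got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        if counts.shape[1] != len(self.channel_names):
            raise DomainError(
                f"{counts.shape[1]} channels but {len(self.channel_names)} channel names"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.counts.shape[2], self.counts.shape[3]

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise DomainError(
                f"unknown channel {channel!r}; stack has {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """All frames of one channel as (frame, row, col)."""
        return self.counts[:, self.channel_index(channel)]

    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.camera.frame_interval_s
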