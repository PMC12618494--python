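"""Curve fitting for dissociation, arrival and stretch/relax kinetics.

Dissociation of chromosome-bound proteins after exchanging to the active
cell-free system follows

    I(t) = (1 - A) * exp(-t / tau) + A

where ``tau`` is the decay constant and ``A`` the immobile (tightly bound)
fraction. Protein-synthesis arrivals are treated as a Poisson process: the
empirical CDF of waiting times between events is fitted to
``1 - exp(-t/tau)`` (mono) or ``1 - [A exp(-t/tau1) + (1-A) exp(-t/tau2)]``
(bi), by non-linear least squares on the ECDF — the field's standard route;
the maximum-likelihood rate (1 / mean wait) is reported alongside as an
alternative estimator. Fits use uniform weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientDataError, NormalizationError

__all__ = [
    "DecayTrace",
    "DecayFit",
    "ArrivalFit",
    "StretchFit",
    "normalize_trace",
    "average_traces",
    "fit_decay",
    "waiting_times",
    "fit_arrival_cdf",
    "select_arrival_model",
    "elongation_rate",
    "bound_fraction",
    "fit_stretch_cycles",
]


@dataclass
class DecayTrace:
    """Background-subtracted, initial-normalized intensity trace."""

    t_s: np.ndarray
    intensity_norm: np.ndarray
    n_chromosomes: int = 1


def normalize_trace(
    raw_intensity: np.ndarray,
    background: np.ndarray | float,
    t_s: np.ndarray,
) -> DecayTrace:
    """Subtract background and normalize by the initial value.

    Result is (raw - bg) / (raw(0) - bg(0)); the initial background-
    subtracted value must be positive.
    """
    raw = np.asarray(raw_intensity, dtype=float)
    bg = np.broadcast_to(np.asarray(background, dtype=float), raw.shape)
    net = raw - bg
    if net[0] <= 0:
        raise NormalizationError(
            f"initial background-subtracted intensity is {net[0]:.4g} <= 0"
        )
    return DecayTrace(t_s=np.asarray(t_s, dtype=float), intensity_norm=net / net[0])


def average_traces(traces: list[DecayTrace]) -> DecayTrace:
    """Pointwise average of already-normalized traces on a common time base."""
    if not traces:
        raise DomainError("no traces to average")
    t0 = traces[0].t_s
    for tr in traces[1:]:
        if len(tr.t_s) != len(t0) or not np.allclose(tr.t_s, t0):
            raise DomainError("traces must share a common time base")
    mean = np.mean([tr.intensity_norm for tr in traces], axis=0)
    return DecayTrace(t_s=t0, intensity_norm=mean, n_chromosomes=len(traces))


@dataclass(frozen=True)
class DecayFit:
    """Fitted dissociation parameters (tau, immobile fraction A)."""

    tau_s: float
    immobile_fraction: float
    tau_stderr: float
    immobile_stderr: float
    rss: float
    converged: bool
    unidentifiable: bool = False
    note: str = ""

    @property
    def tau_min(self) -> float:
        return self.tau_s / 60.0


def _decay_model(t: np.ndarray, tau: float, a: float) -> np.ndarray:
    return (1.0 - a) * np.exp(-t / tau) + a


def fit_decay(trace: DecayTrace) -> DecayFit:
    """Fit I(t) = (1-A) exp(-t/tau) + A by bounded non-linear least squares.

    Initialization: A0 is the mean of the last 10% of the trace; tau0 the
    time at which the trace first crosses (1 + A0) / 2. A trace that never
    leaves its plateau is flagged unidentifiable (tau is meaningless when
    A -> 1). Non-convergence is reported in the fit record, never silent.
    """
    t = trace.t_s
    y = trace.intensity_norm
    if len(t) < 10:
        raise InsufficientDataError(f"need >= 10 time points, got {len(t)}")
    n_tail = max(1, len(y) // 10)
    a0 = float(np.clip(np.mean(y[-n_tail:]), 0.0, 1.0))
    half_level = (1.0 + a0) / 2.0
    below = np.flatnonzero(y <= half_level)
    tau0 = float(t[below[0]]) if len(below) and t[below[0]] > 0 else float(t[-1]) / 3
    if a0 > 0.95:
        return DecayFit(
            tau_s=float(t[-1]),
            immobile_fraction=a0,
            tau_stderr=math.inf,
            immobile_stderr=0.0,
            rss=float(np.sum((y - a0) ** 2)),
            converged=True,
            unidentifiable=True,
            note="trace never decays; tau unidentifiable with A ~ 1",
        )
    try:
        popt, pcov = curve_fit(
            _decay_model,
            t,
            y,
            p0=[max(tau0, t[1] if len(t) > 1 else 1.0), a0],
            bounds=([1e-9, 0.0], [np.inf, 1.0]),
            maxfev=10000,
        )
        perr = np.sqrt(np.diag(pcov))
        resid = y - _decay_model(t, *popt)
        return DecayFit(
            tau_s=float(popt[0]),
            immobile_fraction=float(popt[1]),
            tau_stderr=float(perr[0]),
            immobile_stderr=float(perr[1]),
            rss=float(np.sum(resid**2)),
            converged=True,
            unidentifiable=popt[1] > 0.99,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger with bounds
        return DecayFit(
            tau_s=float("nan"),
            immobile_fraction=float("nan"),
            tau_stderr=math.inf,
            immobile_stderr=math.inf,
            rss=float("nan"),
            converged=False,
            note=f"non-convergence: {exc}",
        )


# ---------------------------------------------------------------------------
# arrival-time statistics


@dataclass(frozen=True)
class ArrivalFit:
    """Fitted arrival-time CDF (mono- or bi-exponential)."""

    model: str  # "mono" | "bi"
    tau_s: float  # mono: the single timescale; bi: tau1 (fast)
    tau2_s: float | None = None
    fraction_fast: float | None = None
    stderr: tuple = ()
    rss: float = math.nan
    n_events: int = 0
    collapsed: bool = False
    note: str = ""

    @property
    def rate_per_min(self) -> float:
        return 60.0 / self.tau_s


def waiting_times(arrival_times_s: np.ndarray, t_start_s: float = 0.0) -> np.ndarray:
    """Waiting times between consecutive events.

    The first wait is measured from the start of observation; for a Poisson
    process every entry is an independent Exp(rate) sample.
    """
    t = np.sort(np.asarray(arrival_times_s, dtype=float))
    return np.diff(np.concatenate([[t_start_s], t]))


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def fit_arrival_cdf(waits_s: np.ndarray, model: str = "mono") -> ArrivalFit:
    """Least-squares fit of the waiting-time ECDF to exponential models.

    ``waits_s`` are the (pooled) waiting times between protein arrival
    events, in seconds. The mono model is 1 - exp(-t/tau); the bi model
    1 - [A exp(-t/tau1) + (1-A) exp(-t/tau2)], reported in canonical
    tau1 <= tau2 order. A bi fit collapsing onto one component (tau2/tau1
    close to 1, or A at the boundary) is flagged as effectively mono.
    """
    w = np.asarray(waits_s, dtype=float)
    n = len(w)
    if model == "mono" and n < 10:
        raise InsufficientDataError(f"mono fit needs >= 10 events, got {n}")
    if model == "bi" and n < 30:
        raise InsufficientDataError(f"bi fit needs >= 30 events, got {n}")
    xs, ecdf = _ecdf(w)
    mean = float(np.mean(w))
    if model == "mono":
        popt, pcov = curve_fit(
            lambda t, tau: 1.0 - np.exp(-t / tau), xs, ecdf, p0=[mean],
            bounds=(1e-9, np.inf), maxfev=10000,
        )
        rss = float(np.sum((ecdf - (1 - np.exp(-xs / popt[0]))) ** 2))
        return ArrivalFit(
            model="mono",
            tau_s=float(popt[0]),
            stderr=(float(np.sqrt(pcov[0, 0])),),
            rss=rss,
            n_events=n,
        )
    if model != "bi":
        raise DomainError(f"unknown model {model!r}; use 'mono' or 'bi'")

    def bi(t, a, tau1, tau2):
        return 1.0 - (a * np.exp(-t / tau1) + (1 - a) * np.exp(-t / tau2))

    popt, pcov = curve_fit(
        bi, xs, ecdf,
        p0=[0.5, mean / 3.0, mean * 3.0],
        bounds=([0.0, 1e-9, 1e-9], [1.0, np.inf, np.inf]),
        maxfev=20000,
    )
    a, tau1, tau2 = popt
    perr = tuple(float(e) for e in np.sqrt(np.diag(pcov)))
    if tau1 > tau2:  # canonical order: tau1 is the fast component
        tau1, tau2 = tau2, tau1
        a = 1.0 - a
    collapsed = (tau2 / tau1 < 1.5) or a < 0.02 or a > 0.98
    rss = float(np.sum((ecdf - bi(xs, a, tau1, tau2)) ** 2))
    return ArrivalFit(
        model="bi",
        tau_s=float(tau1),
        tau2_s=float(tau2),
        fraction_fast=float(a),
        stderr=perr,
        rss=rss,
        n_events=n,
        collapsed=collapsed,
        note="components unresolved; effectively mono" if collapsed else "",
    )


@dataclass(frozen=True)
class ModelChoice:
    """Selected arrival model with the numbers behind the decision."""

    model: str
    rss_mono: float
    rss_bi: float
    improvement: float
    reason: str


def select_arrival_model(
    mono: ArrivalFit,
    bi: ArrivalFit,
    n_events: int,
    min_improvement: float = 0.25,
) -> ModelChoice:
    """Prefer the mono model unless the bi fit is clearly better and resolved.

    The bi model wins only when it reduces the residual sum by more than
    ``min_improvement`` (fractional) AND both components are resolved
    (tau2/tau1 > 3 with the fast fraction inside [0.1, 0.9]).
    """
    improvement = (mono.rss - bi.rss) / mono.rss if mono.rss > 0 else 0.0
    if bi.collapsed:
        return ModelChoice("mono", mono.rss, bi.rss, improvement, "bi fit collapsed")
    resolved = (
        bi.tau2_s is not None
        and bi.tau2_s / bi.tau_s > 3.0
        and bi.fraction_fast is not None
        and 0.1 <= bi.fraction_fast <= 0.9
    )
    if improvement > min_improvement and resolved:
        return ModelChoice(
            "bi", mono.rss, bi.rss, improvement,
            f"bi reduces RSS by {improvement:.0%} with resolved components",
        )
    return ModelChoice(
        "mono", mono.rss, bi.rss, improvement,
        "mono sufficient (Poissonian arrivals)",
    )


def elongation_rate(gene_length_nt: float, release_tau_s: float) -> float:
    """Transcription elongation rate in nt/s from gene length and release time.

    The exponential release timescale of chromosome-bound polymerases bounds
    the time to finish transcribing a typical gene, so rate = length / tau.
    """
    if gene_length_nt <= 0:
        raise DomainError(f"gene_length_nt must be > 0, got {gene_length_nt}")
    if release_tau_s <= 0:
        raise DomainError(f"release_tau_s must be > 0, got {release_tau_s}")
    return gene_length_nt / release_tau_s


@dataclass(frozen=True)
class BoundFractionResult:
    per_cell: np.ndarray
    median: float
    n_clipped: int


def bound_fraction(
    signal_before_lysis: np.ndarray,
    signal_after_lysis: np.ndarray,
    background: np.ndarray | float = 0.0,
) -> BoundFractionResult:
    """Chromosome-bound fraction of a protein from pre/post-lysis signals.

    fraction = (after - bg) / (before - bg), per cell; values pushed outside
    [0, 1] by noise are clipped and counted, and the ensemble median is
    reported alongside.
    """
    before = np.atleast_1d(np.asarray(signal_before_lysis, dtype=float))
    after = np.atleast_1d(np.asarray(signal_after_lysis, dtype=float))
    bg = np.broadcast_to(np.asarray(background, dtype=float), before.shape)
    denom = before - bg
    if np.any(denom <= 0):
        raise DomainError("background-subtracted before-lysis signal must be > 0")
    frac = (after - bg) / denom
    n_clipped = int(np.sum((frac < 0) | (frac > 1)))
    frac = np.clip(frac, 0.0, 1.0)
    return BoundFractionResult(per_cell=frac, median=float(np.median(frac)), n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# stretch/relax cycles


@dataclass(frozen=True)
class StretchFit:
    """Mono-exponential rise/decay constants of field-stretching cycles."""

    tau_rise_s: float
    tau_decay_s: float
    tau_rise_spread_s: float
    tau_decay_spread_s: float
    plateau_extension_um: float
    n_on_epochs: int
    n_off_epochs: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def _fit_epoch(t: np.ndarray, x: np.ndarray, rising: bool) -> tuple[float, float] | None:
    """Fit x(t) = plateau + (x0 - plateau) exp(-t/tau) on one epoch."""
    if len(t) < 3:
        return None
    t = t - t[0]
    x0 = x[0]
    plateau0 = x[-1]
    if abs(plateau0 - x0) < 1e-12:
        return None

    def model(tt, tau, plateau):
        return plateau + (x0 - plateau) * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, x, p0=[max(t[-1] / 3.0, 1e-6), plateau0],
            bounds=([1e-9, -np.inf], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError:
        return None
    return float(popt[0]), float(popt[1])


def fit_stretch_cycles(
    t_s: np.ndarray,
    extension_um: np.ndarray,
    epochs: list[tuple[float, float, str]],
) -> StretchFit:
    """Per-epoch mono-exponential fits of stretching (ON) and relaxation (OFF).

    Each ON epoch is fitted as a rise toward a plateau, each OFF epoch as a
    decay; time constants are averaged across epochs with their spread (sd).
    Epochs shorter than 3 frames are skipped with a warning flag; time
    constants below the frame interval are flagged as unresolved.
    """
    t = np.asarray(t_s, dtype=float)
    x = np.asarray(extension_um, dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    flags: list[str] = []
    rises, decays, plateaus = [], [], []
    has_on = any(s == "on" for _, _, s in epochs)
    has_off = any(s == "off" for _, _, s in epochs)
    if not (has_on and has_off):
        raise DomainError("need at least one complete ON and one OFF epoch")
    if np.ptp(x) < 1e-12:
        return StretchFit(
            math.nan, math.nan, math.nan, math.nan, float(x[0]), 0, 0,
            flags=("flat series: zero-amplitude fit",),
        )
    for t0, t1, state in epochs:
        sel = (t >= t0) & (t < t1)
        if sel.sum() < 3:
            flags.append(f"epoch ({t0:g}-{t1:g} s, {state}) shorter than 3 frames; skipped")
            continue
        res = _fit_epoch(t[sel], x[sel], rising=state == "on")
        if res is None:
            flags.append(f"epoch ({t0:g}-{t1:g} s, {state}) degenerate; skipped")
            continue
        tau, plateau = res
        if state == "on":
            rises.append(tau)
            plateaus.append(plateau)
        else:
            decays.append(tau)
    tau_rise = float(np.mean(rises)) if rises else math.nan
    tau_decay = float(np.mean(decays)) if decays else math.nan
    if rises and tau_rise < dt:
        flags.append("rise unresolved: tau below one frame interval")
    if decays and tau_decay < dt:
        flags.append("decay unresolved: tau below one frame interval")
    return StretchFit(
        tau_rise_s=tau_rise,
        tau_decay_s=tau_decay,
        tau_rise_spread_s=float(np.std(rises)) if len(rises) > 1 else 0.0,
        tau_decay_spread_s=float(np.std(decays)) if len(decays) > 1 else 0.0,
        plateau_extension_um=float(np.mean(plateaus)) if plateaus else math.nan,
        n_on_epochs=len(rises),
        n_off_epochs=len(decays),
        flags=tuple(flags),
    )
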