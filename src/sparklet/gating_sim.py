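"""Synthetic sparklet recordings with exported ground truth.

Sites carry ``n_channels`` independent, identical two-state (closed/open)
channels simulated in continuous time; the per-frame occupancy is sampled
at the frame's *start* time (``sample="start"``), matching threshold
idealization downstream.  Rendering adds a fixed per-open-channel
fluorescence increment (quantal amplitude, default 0.29 dF/F0), optional
multiplicative bleaching, and additive Gaussian acquisition noise in F/F0
units.  Movies place sites as 2-D Gaussian footprints in a flat field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import ParameterError
from .trace_ops import FluorescenceTrace, MovieStack

__all__ = [
    "GatingParams",
    "RenderParams",
    "GatingTruth",
    "simulate_open_counts",
    "render_trace",
    "render_movie",
]


@dataclass(frozen=True)
class GatingParams:
    """Two-state gating model for one sparklet site.

    ``n_channels`` is the channel count N; the stationary open probability
    is ``k_open / (k_open + k_close)``.
    """

    n_channels: int = 4
    k_open: float = 1.0  # 1/s
    k_close: float = 9.0  # 1/s
    duration: float = 120.0  # s
    frame_rate: float = 30.0  # frames/s
    seed: int = 0
    init: str = "stationary"  # "stationary" | "closed" | "open"
    sample: str = "start"  # per-frame level = occupancy at frame start

    def __post_init__(self) -> None:
        if self.n_channels < 0:
            raise ParameterError("n_channels must be >= 0")
        for name in ("k_open", "k_close"):
            rate = getattr(self, name)
            if not np.isfinite(rate) or rate < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {rate!r}")
        if not (self.duration > 0):
            raise ParameterError("duration must be > 0")
        if not (self.frame_rate > 0):
            raise ParameterError("frame_rate must be > 0")
        if self.init not in ("stationary", "closed", "open"):
            raise ParameterError("init must be 'stationary', 'closed' or 'open'")
        if self.sample != "start":
            raise ParameterError("only sample='start' is implemented")

    @property
    def stationary_po(self) -> float:
        total = self.k_open + self.k_close
        return self.k_open / total if total > 0 else 0.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass(frozen=True)
class RenderParams:
    """Measurement model mapping open-channel counts to fluorescence."""

    quantal_amplitude: float = 0.29  # dF/F0 per open channel
    baseline_f0: float = 1000.0  # arbitrary intensity units (movies)
    noise_sd: float = 0.05  # dF/F0 units; free parameter, not a paper value
    bleach_rate: float = 0.0  # fraction per second
    psf_sigma: float = 0.5  # um, movies only
    pixel_size: float = 0.26  # um/pixel, movies only
    cells_per_field: int = 15

    def __post_init__(self) -> None:
        if not (self.quantal_amplitude > 0):
            raise ParameterError("quantal_amplitude must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.bleach_rate < 0:
            raise ParameterError("bleach_rate must be >= 0")
        if self.cells_per_field < 0:
            raise ParameterError("cells_per_field must be >= 0")


@dataclass
class GatingTruth:
    """Per-frame open-channel counts plus the analytic stationary targets."""

    open_counts: np.ndarray  # int, per frame
    frame_rate: float
    n_channels: int
    stationary_po: float
    true_npo: float
    true_dwell_times: np.ndarray  # seconds at occupancy level 0..n_channels
    channel_transitions: list[tuple[int, np.ndarray]] = field(default_factory=list)
    # each entry: (state at t=0, sorted transition times within [0, duration))

    @property
    def duration(self) -> float:
        return self.open_counts.size / self.frame_rate

    def dwell_times_exact(self, which: str) -> np.ndarray:
        """Complete (uncensored) single-channel dwell times in seconds.

        ``which`` is 'open' or 'closed'.  Uses the continuous-time event
        record, so short events missed by frame sampling are included; the
        final censored interval of each channel is dropped.
        """
        if which not in ("open", "closed"):
            raise ParameterError("which must be 'open' or 'closed'")
        target = 1 if which == "open" else 0
        out: list[np.ndarray] = []
        for s0, times in self.channel_transitions:
            if times.size < 2:
                continue
            dwell = np.diff(times)
            # state during [times[i], times[i+1]) alternates from 1-s0 at i=0
            states = (1 - s0 + np.arange(dwell.size)) % 2
            out.append(dwell[states == target])
        return np.concatenate(out) if out else np.array([])


def _simulate_channel(
    rng: np.random.Generator, k_open: float, k_close: float, duration: float, start_open: bool
) -> tuple[int, np.ndarray]:
    """Event-driven trajectory of one channel; returns (s0, transition times)."""
    times: list[float] = []
    t = 0.0
    state = 1 if start_open else 0
    while True:
        rate = k_close if state else k_open
        if rate == 0.0:
            break  # absorbing state
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        times.append(t)
        state ^= 1
    return (1 if start_open else 0), np.asarray(times)


def simulate_open_counts(params: GatingParams) -> GatingTruth:
    """Continuous-time Markov simulation of independent two-state channels.

    Reproducible from ``params.seed``; identical params give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_frames
    frame_times = np.arange(n_frames) / params.frame_rate
    open_counts = np.zeros(n_frames, dtype=np.int64)
    transitions: list[tuple[int, np.ndarray]] = []
    po = params.stationary_po
    for _ in range(params.n_channels):
        if params.init == "stationary":
            start_open = bool(rng.random() < po)
        else:
            start_open = params.init == "open"
        s0, times = _simulate_channel(
            rng, params.k_open, params.k_close, params.duration, start_open
        )
        transitions.append((s0, times))
        n_switches = np.searchsorted(times, frame_times, side="right")
        open_counts += (s0 + n_switches) % 2
    dwell = np.bincount(open_counts, minlength=params.n_channels + 1) / params.frame_rate
    return GatingTruth(
        open_counts=open_counts,
        frame_rate=params.frame_rate,
        n_channels=params.n_channels,
        stationary_po=po,
        true_npo=params.n_channels * po,
        true_dwell_times=dwell,
        channel_transitions=transitions,
    )


def render_trace(truth: GatingTruth, render: RenderParams, seed: int = 0) -> FluorescenceTrace:
    """F/F0[t] = (1 + q * open[t]) * exp(-bleach_rate * t_s) + N(0, noise_sd)."""
    rng = np.random.default_rng(seed)
    t_s = np.arange(truth.open_counts.size) / truth.frame_rate
    clean = (1.0 + render.quantal_amplitude * truth.open_counts) * np.exp(
        -render.bleach_rate * t_s
    )
    noisy = clean + rng.normal(0.0, render.noise_sd, size=clean.shape) if render.noise_sd > 0 else clean
    trace = FluorescenceTrace(noisy, truth.frame_rate, None, ["render_trace"])
    return trace


def render_movie(
    sites: list[tuple[tuple[float, float], GatingTruth]],
    render: RenderParams,
    field_size: tuple[int, int] = (64, 64),
    seed: int = 0,
    frame_rate: float | None = None,
) -> MovieStack:
    """Render sparklet sites as 2-D Gaussian footprints over a flat field.

    ``sites`` holds ((row, col) pixel positions, GatingTruth) pairs; all
    truths must share frame count and rate.  Pixel intensity is
    ``baseline_f0 * (1 + sum_s q * open_s[t] * footprint_s)`` plus Gaussian
    noise of ``noise_sd * baseline_f0``.  Site and synthetic nucleus
    positions land in ``meta`` for sites-per-cell bookkeeping.
    """
    h, w = field_size
    rng = np.random.default_rng(seed)
    if sites:
        n_frames = sites[0][1].open_counts.size
        fr = sites[0][1].frame_rate
        for pos, truth in sites:
            r, c = pos
            if not (0 <= r < h and 0 <= c < w):
                raise ParameterError(f"site position {pos} outside field {field_size}")
            if truth.open_counts.size != n_frames or truth.frame_rate != fr:
                raise ParameterError("all site truths must share frame count and rate")
    else:
        n_frames, fr = 30, 30.0
    if frame_rate is not None:
        fr = frame_rate

    sigma_px = render.psf_sigma / render.pixel_size
    positions = [pos for pos, _ in sites]
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = np.hypot(
                positions[i][0] - positions[j][0], positions[i][1] - positions[j][1]
            )
            if d < 4.0 * sigma_px:
                warnings.warn(
                    f"sites {i} and {j} overlap (separation {d:.1f} px < 4 sigma)",
                    stacklevel=2,
                )

    rows, cols = np.mgrid[0:h, 0:w]
    dff = np.zeros((n_frames, h, w))
    for (r, c), truth in sites:
        footprint = np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * sigma_px**2))
        dff += render.quantal_amplitude * truth.open_counts[:, None, None] * footprint[None]
    data = render.baseline_f0 * (1.0 + dff)
    if render.noise_sd > 0:
        data = data + rng.normal(0.0, render.noise_sd * render.baseline_f0, size=data.shape)
    nuclei = rng.uniform(low=0.0, high=[h, w], size=(render.cells_per_field, 2))
    meta = {
        "site_positions": [list(map(float, pos)) for pos in positions],
        "nuclei_positions": nuclei.tolist(),
        "n_cells": render.cells_per_field,
        "quantal_amplitude": render.quantal_amplitude,
        "baseline_f0": render.baseline_f0,
        "noise_sd": render.noise_sd,
        "psf_sigma": render.psf_sigma,
    }
    return MovieStack(data, fr, render.pixel_size, meta)
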