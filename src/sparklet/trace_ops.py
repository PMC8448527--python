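"""Movie and trace preprocessing.

Kalman stack filtering of fluorescence movies, zero-phase Gaussian
low-pass smoothing for display, 5x5-pixel ROI F/F0 extraction, sparklet
event detection under steady-baseline / steady-peak inclusion criteria,
and trapezoidal area under the curve.

Conventions: pixel coordinates are 0-based row-major; frame ``t`` maps to
time ``t / frame_rate`` seconds with frame 0 at t = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._errors import DataError, ParameterError

__all__ = [
    "MovieStack",
    "FluorescenceTrace",
    "ROISpec",
    "KalmanParams",
    "SparkletEvent",
    "kalman_stack_filter",
    "gaussian_lowpass",
    "extract_ff0",
    "place_roi_at_peak",
    "detect_events",
    "event_auc",
    "robust_noise_sd",
]

ROI_SIZE = 5  # 5 x 5 pixel box (~1.7 um^2 at the acquisition pixel size)


@dataclass
class MovieStack:
    """A fluorescence movie: ``data`` has shape (frames, height, width)."""

    data: np.ndarray
    frame_rate: float = 30.0
    pixel_size: float | None = None  # um / pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ParameterError("movie data must be (frames, height, width) with >= 1 frame")
        if not np.all(np.isfinite(self.data)):
            raise DataError("movie contains non-finite values")
        if not (self.frame_rate > 0):
            raise ParameterError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class FluorescenceTrace:
    """An F/F0 time series at a fixed frame rate with provenance."""

    values: np.ndarray
    frame_rate: float = 30.0
    roi: "ROISpec | None" = None
    filters_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ParameterError("trace must contain at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace contains non-finite values")
        if not (self.frame_rate > 0):
            raise ParameterError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def with_values(self, values: np.ndarray, extra_filter: str | None = None) -> "FluorescenceTrace":
        filters = list(self.filters_applied)
        if extra_filter:
            filters.append(extra_filter)
        return FluorescenceTrace(values, self.frame_rate, self.roi, filters)


@dataclass(frozen=True)
class ROISpec:
    """A fixed 5x5-pixel box centered on (center_row, center_col), 0-based."""

    center_row: int
    center_col: int
    height: int = ROI_SIZE
    width: int = ROI_SIZE

    def validate(self, frame_shape: tuple[int, int]) -> None:
        h, w = frame_shape
        r0, r1 = self.row_slice.start, self.row_slice.stop
        c0, c1 = self.col_slice.start, self.col_slice.stop
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ParameterError(
                f"ROI box {self} does not fit inside frame of shape {frame_shape}"
            )

    @property
    def row_slice(self) -> slice:
        half = self.height // 2
        return slice(self.center_row - half, self.center_row - half + self.height)

    @property
    def col_slice(self) -> slice:
        half = self.width // 2
        return slice(self.center_col - half, self.center_col - half + self.width)


@dataclass(frozen=True)
class KalmanParams:
    """Stack-filter parameters: initial gain and acquisition noise variance."""

    gain: float = 0.8
    noise_variance: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain <= 1.0):
            raise ParameterError("gain must be in [0, 1]")
        if not (self.noise_variance > 0):
            raise ParameterError("noise_variance must be > 0")


@dataclass
class SparkletEvent:
    """A detected sparklet: frame indices plus amplitude and AUC."""

    start_frame: int
    peak_frame: int
    end_frame: int
    peak_amplitude: float
    auc: float = 0.0

    def __post_init__(self) -> None:
        if not (self.start_frame <= self.peak_frame <= self.end_frame):
            raise ParameterError("event must satisfy start <= peak <= end")
        if self.peak_amplitude < 0:
            raise ParameterError("peak_amplitude must be >= 0")


# ---------------------------------------------------------------------------
# filtering


def kalman_stack_filter(
    movie: MovieStack, params: KalmanParams | None = None, *, adaptive: bool = True
) -> MovieStack:
    """Per-pixel recursive predictive filter across frames.

    The estimate is ``E[t] = G[t] * E[t-1] + (1 - G[t]) * O[t]`` with
    ``E[0] = O[0]``.  In adaptive mode the per-pixel weight on the running
    estimate grows as the prediction variance shrinks against
    ``noise_variance``; the first update uses ``G[1] = gain``.  With
    ``adaptive=False`` the gain stays fixed at ``params.gain``, which gives
    the closed-form geometric step response ``1 - gain**k``.
    """
    params = params or KalmanParams()
    if movie.n_frames < 2:
        warnings.warn("single-frame movie returned unchanged", stacklevel=2)
        return MovieStack(movie.data.copy(), movie.frame_rate, movie.pixel_size, dict(movie.meta))

    data = movie.data.astype(float)
    out = np.empty_like(data)
    out[0] = data[0]
    g = params.gain
    if not adaptive or g == 0.0:
        for t in range(1, data.shape[0]):
            out[t] = g * out[t - 1] + (1.0 - g) * data[t]
    else:
        r = params.noise_variance
        # choose P so the first observation weight K = P/(P+R) equals 1-gain
        p = np.full(data.shape[1:], r * (1.0 - g) / g)
        for t in range(1, data.shape[0]):
            k = p / (p + r)
            out[t] = out[t - 1] + k * (data[t] - out[t - 1])
            p = (1.0 - k) * p
    meta = dict(movie.meta)
    meta.setdefault("filters", []).append(
        {"kalman": {"gain": params.gain, "noise_variance": params.noise_variance, "adaptive": adaptive}}
    )
    return MovieStack(out, movie.frame_rate, movie.pixel_size, meta)


def gaussian_lowpass(trace: FluorescenceTrace, cutoff_hz: float = 4.0) -> FluorescenceTrace:
    """Zero-phase Gaussian smoothing with its -3 dB point at ``cutoff_hz``.

    Display/provenance only: quantal analysis consumes unfiltered (or
    Kalman-filtered) data because smoothing biases dwell times.
    """
    nyquist = trace.frame_rate / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ParameterError(f"cutoff_hz must lie in (0, Nyquist={nyquist:g} Hz)")
    # |H(f)| = exp(-2 pi^2 sigma_t^2 f^2) = 2**-0.5 at f = cutoff
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    sigma_samples = sigma_t * trace.frame_rate
    smoothed = gaussian_filter1d(trace.values, sigma_samples, mode="nearest")
    return trace.with_values(smoothed, f"gaussian_lowpass(cutoff_hz={cutoff_hz:g})")


# ---------------------------------------------------------------------------
# extraction


def _box_means(movie: MovieStack, roi: ROISpec) -> np.ndarray:
    roi.validate(movie.data.shape[1:])
    box = movie.data[:, roi.row_slice, roi.col_slice]
    return box.mean(axis=(1, 2))


def extract_ff0(
    movie: MovieStack,
    roi: ROISpec,
    baseline: tuple[int, int] | None = None,
) -> FluorescenceTrace:
    """Mean ROI intensity per frame, normalized to the baseline F0.

    ``baseline`` is a (start, stop) frame window; when omitted, F0 is the
    mean of the lowest decile of per-frame box means.
    """
    box = _box_means(movie, roi)
    if baseline is not None:
        start, stop = baseline
        window = box[start:stop]
        if window.size == 0:
            raise ParameterError("baseline window is empty")
        f0 = float(window.mean())
    else:
        k = max(1, box.size // 10)
        f0 = float(np.sort(box)[:k].mean())
    if f0 <= 0:
        raise DataError(f"baseline F0 must be positive, got {f0!r}")
    return FluorescenceTrace(box / f0, movie.frame_rate, roi, ["extract_ff0"])


def place_roi_at_peak(
    movie: MovieStack,
    kalman: KalmanParams | None = None,
    *,
    apply_kalman: bool = True,
) -> ROISpec:
    """Center a 5x5 ROI on the pixel with maximum dF/F0 across all frames.

    Ties break by earliest frame, then smallest row, then smallest column
    (C-order argmax).  Per-pixel F0 is the lowest-decile temporal mean.
    The center is clamped so the box fits inside the frame.
    """
    src = movie
    if apply_kalman and movie.n_frames >= 2:
        src = kalman_stack_filter(movie, kalman or KalmanParams())
    data = src.data.astype(float)
    n = data.shape[0]
    k = max(1, n // 10)
    f0 = np.sort(data, axis=0)[:k].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(f0 > 0, data / f0 - 1.0, data - f0)
    flat = int(np.argmax(dff))
    _, row, col = np.unravel_index(flat, data.shape)
    half = ROI_SIZE // 2
    row = int(np.clip(row, half, data.shape[1] - 1 - half))
    col = int(np.clip(col, half, data.shape[2] - 1 - half))
    return ROISpec(row, col)


# ---------------------------------------------------------------------------
# event detection


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD from the scaled MAD of first differences divided by sqrt(2)."""
    d = np.diff(np.asarray(values, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop_inclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def _longest_run(mask: np.ndarray) -> int:
    best = 0
    for s, e in _runs(mask):
        best = max(best, e - s + 1)
    return best


def detect_events(
    trace: FluorescenceTrace,
    min_baseline_pts: int = 5,
    min_peak_pts: int = 5,
    baseline_tolerance: float | None = None,
) -> list[SparkletEvent]:
    """Detect sparklet events under steady-baseline / steady-peak criteria.

    A candidate is a contiguous run of frames above baseline + tolerance.
    It is kept only if the ``min_baseline_pts`` frames immediately before it
    stay within +/- tolerance of their own mean (stable baseline) and the
    run contains >= ``min_peak_pts`` consecutive frames within tolerance of
    the run maximum (steady peak).  ``baseline_tolerance`` defaults to twice
    the robust noise SD of the trace.
    """
    if trace.n_frames <= min_baseline_pts + min_peak_pts:
        raise ParameterError("trace too short for the requested criteria")
    v = trace.values
    tol = robust_noise_sd(v) * 2.0 if baseline_tolerance is None else float(baseline_tolerance)
    if tol < 0:
        raise ParameterError("baseline_tolerance must be >= 0")
    baseline = float(np.median(v))
    eps = 1e-12
    above = v > baseline + tol + eps
    events: list[SparkletEvent] = []
    for s, e in _runs(above):
        if s < min_baseline_pts:
            continue
        pre = v[s - min_baseline_pts : s]
        if np.max(np.abs(pre - pre.mean())) > tol + eps:
            continue
        seg = v[s : e + 1]
        peak_off = int(np.argmax(seg))
        peak_val = float(seg[peak_off])
        plateau = seg >= peak_val - tol - eps
        if _longest_run(plateau) < min_peak_pts:
            continue
        ev = SparkletEvent(s, s + peak_off, e, max(0.0, peak_val - baseline))
        ev.auc = event_auc(trace, ev)
        events.append(ev)
    return events


def event_auc(trace: FluorescenceTrace, event: SparkletEvent) -> float:
    """Trapezoidal integral of (F/F0 - 1) over the event, abscissa in seconds."""
    if event.start_frame < 0 or event.end_frame >= trace.n_frames:
        raise ParameterError("event lies outside the trace")
    if event.start_frame == event.end_frame:
        return 0.0
    sl = slice(event.start_frame, event.end_frame + 1)
    y = trace.values[sl] - 1.0
    x = trace.times[sl]
    return float(np.trapezoid(y, x))
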