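"""Quantal analysis of sparklet traces.

All-points amplitude histograms, multi-Gaussian mixture fitting with an
optional equal-spacing (quantal) constraint, nearest-level idealization
with half-amplitude hysteresis, dwell times, NP_O, and sites-per-cell.

The per-site statistic is

    NP_O = (T_level1 + 2 T_level2 + 3 T_level3 + 4 T_level4) / T_total

i.e. the time average of the open-channel count, estimated from the
idealized level sequence.  The mixture model fitted to the histogram is

    f(x) = sum_i a_i / (sqrt(2 pi) sigma_i) * exp(-(x - mu_i)^2 / (2 sigma_i^2))

with a shared baseline mean mu_0 and, under the quantal hypothesis,
mu_i = mu_0 + i * q for a single spacing q (the quantal amplitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from ._errors import FitError, ParameterError, StageError
from .trace_ops import FluorescenceTrace, SparkletEvent, detect_events

__all__ = [
    "MAX_QUANTAL_LEVELS",
    "AllPointsHistogram",
    "QuantalModel",
    "IdealizedTrace",
    "SparkletStats",
    "SiteConfig",
    "SiteResult",
    "build_histogram",
    "fit_multi_gaussian",
    "global_quantal_model",
    "idealize",
    "compute_npo",
    "sites_per_cell",
    "analyze_site",
]

MAX_QUANTAL_LEVELS = 4  # up to 4 simultaneously open channels per site

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class AllPointsHistogram:
    """Histogram of every frame's F/F0 value."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ParameterError("bin_edges must be strictly increasing")
        if self.counts.size != self.bin_edges.size - 1:
            raise ParameterError("counts/bin_edges size mismatch")
        if int(self.counts.sum()) != self.n_points:
            raise ParameterError("counts must sum to n_points")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(np.mean(np.diff(self.bin_edges)))


@dataclass
class QuantalModel:
    """Fitted mixture: areas a_i, means mu_i, SDs sigma_i, and spacing q.

    ``areas`` are probability fractions (they sum to ~1 for a good fit).
    ``quantal_amplitude`` is None for a baseline-only model (no events).
    """

    n_components: int
    areas: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    quantal_amplitude: float | None
    baseline_mean: float
    equal_spacing: bool = True
    converged: bool = True
    residual_norm: float = 0.0
    bic: float = float("nan")
    mode: str = "fit"  # "fit" | "global"

    def __post_init__(self) -> None:
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_1d(np.asarray(self.sds, dtype=float))
        if not (self.areas.size == self.means.size == self.sds.size == self.n_components):
            raise ParameterError("component arrays must match n_components")
        if np.any(self.areas <= 0) or np.any(self.sds <= 0):
            raise ParameterError("areas and sds must be > 0")
        if np.any(np.diff(self.means) <= 0):
            raise ParameterError("means must be strictly increasing")

    @property
    def n_levels(self) -> int:
        """Number of quantal levels above baseline."""
        return self.n_components - 1

    def level_means(self, max_level: int = MAX_QUANTAL_LEVELS) -> np.ndarray:
        """Ideal amplitudes mu_0 + i*q for levels 0..max_level."""
        if self.quantal_amplitude is None:
            return np.array([self.baseline_mean])
        return self.baseline_mean + self.quantal_amplitude * np.arange(max_level + 1)

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, m, s in zip(self.areas, self.means, self.sds):
            out += a / (_SQRT_2PI * s) * np.exp(-0.5 * ((x - m) / s) ** 2)
        return out


@dataclass
class IdealizedTrace:
    """Per-frame quantal levels and the dwell times they imply."""

    levels: np.ndarray  # int, values in 0..MAX_QUANTAL_LEVELS
    frame_rate: float
    dwell_times: np.ndarray  # seconds at levels 1..4
    t_total: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.dwell_times = np.asarray(self.dwell_times, dtype=float)
        if self.dwell_times.size != MAX_QUANTAL_LEVELS:
            raise ParameterError("dwell_times must cover levels 1..4")
        if np.any(self.dwell_times < 0) or self.t_total <= 0:
            raise ParameterError("dwell times must be >= 0 and t_total > 0")

    @property
    def t_level0(self) -> float:
        return self.t_total - float(self.dwell_times.sum())


@dataclass
class SparkletStats:
    """Per-field summary: NP_O per site and sparklet sites per cell."""

    per_site_table: dict[str, float]
    sites_per_cell: float

    @property
    def npo(self) -> float:
        """Mean NP_O across sites (0 if no sites)."""
        if not self.per_site_table:
            return 0.0
        return float(np.mean(list(self.per_site_table.values())))


# ---------------------------------------------------------------------------
# histogram


def build_histogram(
    trace: FluorescenceTrace,
    bin_width: float | None = None,
    n_bins: int | None = None,
) -> AllPointsHistogram:
    """All-points histogram over [min, max]; left-closed bins, last closed.

    Default binning is Freedman-Diaconis.
    """
    v = trace.values
    if v.size < 10:
        warnings.warn("histogram built from fewer than 10 frames", stacklevel=2)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        w = bin_width or 1e-3
        edges = np.array([lo - w / 2, lo + w / 2])
        return AllPointsHistogram(edges, np.array([v.size]), v.size)
    if bin_width is not None:
        if bin_width <= 0:
            raise ParameterError("bin_width must be > 0")
        edges = np.arange(lo, hi + bin_width, bin_width)
        if edges[-1] < hi:
            edges = np.append(edges, edges[-1] + bin_width)
    elif n_bins is not None:
        if n_bins < 1:
            raise ParameterError("n_bins must be >= 1")
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.histogram_bin_edges(v, bins="fd")
        if edges.size < 2:
            edges = np.histogram_bin_edges(v, bins="sturges")
    counts, edges = np.histogram(v, bins=edges)
    return AllPointsHistogram(edges, counts, v.size)


# ---------------------------------------------------------------------------
# mixture fitting


def _mixture_counts(x, areas, means, sds, scale):
    y = np.zeros_like(x)
    for a, m, s in zip(areas, means, sds):
        y += a / (_SQRT_2PI * s) * np.exp(-0.5 * ((x - m) / s) ** 2)
    return scale * y


def _init_means(hist: AllPointsHistogram, k: int, q_init: float) -> tuple[float, np.ndarray]:
    """Baseline mean and K level means, from histogram peaks when possible."""
    counts = hist.counts.astype(float)
    centers = hist.centers
    mu0 = float(centers[int(np.argmax(counts))])
    peaks, _ = find_peaks(counts, prominence=max(1.0, counts.max() * 0.02))
    above = np.sort(centers[peaks][centers[peaks] > mu0 + q_init / 2.0])
    means = [mu0 + (i + 1) * q_init for i in range(k)]
    for i in range(min(k, above.size)):
        means[i] = float(above[i])
    return mu0, np.asarray(means)


def fit_multi_gaussian(
    hist: AllPointsHistogram,
    max_levels: int = MAX_QUANTAL_LEVELS,
    equal_spacing: bool = True,
    n_levels: int | None = None,
    q_init: float = 0.29,
) -> QuantalModel:
    """Weighted least-squares mixture fit of an all-points histogram.

    Counts are fitted with Poisson weights (sigma_j = sqrt(max(count_j, 1))).
    The number of levels K above baseline is selected by BIC over
    0..max_levels unless ``n_levels`` pins it.  With ``equal_spacing`` the
    means are constrained to mu_i = mu_0 + i*q and q is the fitted spacing;
    otherwise q is reported as the mean spacing of the sorted means.
    """
    if max_levels < 1:
        raise ParameterError("max_levels must be >= 1")
    centers = hist.centers
    counts = hist.counts.astype(float)
    if centers.size == 1:
        return QuantalModel(
            1, np.array([1.0]), np.array([centers[0]]), np.array([hist.bin_width]),
            None, float(centers[0]), equal_spacing, True, 0.0, float("nan"),
        )
    err = np.sqrt(np.clip(counts, 1.0, None))
    scale = hist.n_points * hist.bin_width
    n_eff = int(np.count_nonzero(counts))
    span = float(centers[-1] - centers[0])
    sd_lo = max(hist.bin_width / 4.0, 1e-6)
    sd_hi = max(span, 2 * hist.bin_width)
    sd0 = max(hist.bin_width, q_init / 6.0)

    def n_params(k: int) -> int:
        return (2 + 2 * (k + 1)) if equal_spacing else (3 * (k + 1))

    ks = [n_levels] if n_levels is not None else list(range(0, max_levels + 1))
    ks = [k for k in ks if n_params(k) <= max(n_eff - 1, 3)] or [0]

    candidates: list[dict] = []
    diagnostics: dict[int, str] = {}
    for k in ks:
        mu0_init, level_means = _init_means(hist, k, q_init)
        if equal_spacing:
            q0 = (
                float(np.mean(np.diff(np.concatenate(([mu0_init], level_means)))))
                if k >= 1
                else q_init
            )
            q0 = min(max(q0, 2 * sd_lo), span if span > 0 else q_init)
            p0 = np.concatenate(([mu0_init, q0], np.full(k + 1, sd0), np.full(k + 1, 1.0 / (k + 1))))
            lo = np.concatenate(
                ([centers[0], 2 * sd_lo], np.full(k + 1, sd_lo), np.full(k + 1, 1e-8))
            )
            hi = np.concatenate(
                ([centers[-1], max(span, 4 * sd_lo)], np.full(k + 1, sd_hi), np.full(k + 1, 10.0))
            )

            def resid(theta, k=k):
                mu0, q = theta[0], theta[1]
                sds = theta[2 : 3 + k]
                areas = theta[3 + k :]
                means = mu0 + q * np.arange(k + 1)
                return (_mixture_counts(centers, areas, means, sds, scale) - counts) / err

        else:
            means0 = np.concatenate(([mu0_init], level_means))
            p0 = np.concatenate((means0, np.full(k + 1, sd0), np.full(k + 1, 1.0 / (k + 1))))
            lo = np.concatenate(
                (np.full(k + 1, centers[0] - span), np.full(k + 1, sd_lo), np.full(k + 1, 1e-8))
            )
            hi = np.concatenate(
                (np.full(k + 1, centers[-1] + span), np.full(k + 1, sd_hi), np.full(k + 1, 10.0))
            )

            def resid(theta, k=k):
                means = theta[: k + 1]
                sds = theta[k + 1 : 2 * (k + 1)]
                areas = theta[2 * (k + 1) :]
                return (_mixture_counts(centers, areas, means, sds, scale) - counts) / err

        p0 = np.clip(p0, lo, hi)
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=4000)
        except Exception as exc:  # numerical failure for this K only
            diagnostics[k] = repr(exc)
            continue
        chi2 = float(np.sum(res.fun**2))
        bic = chi2 + n_params(k) * np.log(max(n_eff, 2))
        candidates.append(
            {"k": k, "theta": res.x, "chi2": chi2, "bic": bic, "success": bool(res.success)}
        )

    converged = [c for c in candidates if c["success"]]
    if not converged:
        if candidates:  # all hit max_nfev; keep best iterate but flag it
            best = min(candidates, key=lambda c: c["bic"])
            raise FitError(
                "mixture fit did not converge",
                {"last_iterate": best["theta"], "per_k": diagnostics, "chi2": best["chi2"]},
            )
        raise FitError("mixture fit failed for every candidate K", {"per_k": diagnostics})

    best = min(converged, key=lambda c: c["bic"])
    k = best["k"]
    theta = best["theta"]
    if equal_spacing:
        mu0, q = float(theta[0]), float(theta[1])
        sds = theta[2 : 3 + k]
        areas = theta[3 + k :]
        means = mu0 + q * np.arange(k + 1)
    else:
        means = theta[: k + 1]
        order = np.argsort(means)
        means = means[order]
        sds = theta[k + 1 : 2 * (k + 1)][order]
        areas = theta[2 * (k + 1) :][order]
        mu0 = float(means[0])
        q = float(np.mean(np.diff(means))) if k >= 1 else None
    quantal = float(q) if (k >= 1 and q is not None) else None
    return QuantalModel(
        n_components=k + 1,
        areas=areas,
        means=means,
        sds=sds,
        quantal_amplitude=quantal,
        baseline_mean=mu0,
        equal_spacing=equal_spacing,
        converged=True,
        residual_norm=float(np.sqrt(best["chi2"])),
        bic=best["bic"],
    )


def global_quantal_model(trace: FluorescenceTrace, q: float = 0.29) -> QuantalModel:
    """Baseline-plus-fixed-q model: mu_0 estimated from the modal bin.

    Used when the quantal amplitude is taken as a global constant rather
    than fitted per trace.  The baseline mean is the mean of all frames
    within q/4 of the histogram's modal bin center (the baseline carries
    the highest count).
    """
    if q <= 0:
        raise ParameterError("q must be > 0")
    hist = build_histogram(trace)
    counts = hist.counts.astype(float)
    # baseline = lowest prominent histogram peak (not necessarily the global
    # mode: at high activity level 1 can carry more mass than level 0)
    peaks, _ = find_peaks(
        np.concatenate(([0.0], counts, [0.0])), prominence=max(1.0, counts.max() * 0.05)
    )
    candidates = hist.centers[peaks - 1] if peaks.size else hist.centers[[int(np.argmax(counts))]]
    mode = float(np.min(candidates))
    v = trace.values
    near = v[np.abs(v - mode) <= q / 4.0]
    if near.size == 0:
        near = v
    mu0 = float(near.mean())
    sd = float(near.std()) or hist.bin_width
    return QuantalModel(
        1, np.array([near.size / v.size]), np.array([mu0]), np.array([max(sd, 1e-9)]),
        float(q), mu0, equal_spacing=True, mode="global",
    )


# ---------------------------------------------------------------------------
# idealization and NP_O


def idealize(
    trace: FluorescenceTrace,
    model: QuantalModel,
    hysteresis: bool = True,
    min_dwell_frames: int = 0,
) -> IdealizedTrace:
    """Assign each frame the nearest quantal level mu_0 + i*q, i in 0..4.

    With ``hysteresis`` a transition requires strictly crossing the
    midpoint between adjacent level means: a frame exactly equidistant
    between two levels keeps the previous frame's level.  Without it, ties
    resolve to the lower level.  ``min_dwell_frames`` > 0 merges runs
    shorter than the minimum into the preceding level (off by default).
    """
    q = model.quantal_amplitude
    if q is None or q <= 0:
        raise ParameterError("model must define a positive quantal amplitude")
    means = model.level_means(MAX_QUANTAL_LEVELS)
    v = trace.values
    d = np.abs(v[:, None] - means[None, :])
    levels = np.argmin(d, axis=1).astype(np.int64)  # ties -> lower level
    if hysteresis:
        # a transition must strictly cross the midpoint between level means:
        # frames exactly equidistant between two levels keep the previous level
        dsort = np.sort(d, axis=1)
        tied = np.flatnonzero(dsort[:, 1] - dsort[:, 0] <= 1e-12)
        for t in tied:
            prev = levels[t - 1] if t > 0 else 0
            if d[t, prev] - dsort[t, 0] <= 1e-12:
                levels[t] = prev
    if min_dwell_frames > 0:
        levels = _enforce_min_dwell(levels, min_dwell_frames)
    counts = np.bincount(levels, minlength=MAX_QUANTAL_LEVELS + 1)
    dwell = counts[1:] / trace.frame_rate
    return IdealizedTrace(levels, trace.frame_rate, dwell, v.size / trace.frame_rate)


def _enforce_min_dwell(levels: np.ndarray, min_frames: int) -> np.ndarray:
    out = levels.copy()
    start = 0
    for t in range(1, out.size + 1):
        if t == out.size or out[t] != out[start]:
            if t - start < min_frames and start > 0:
                out[start:t] = out[start - 1]
                # re-scan from the merged run's start
            start = t
    return out


def compute_npo(ideal: IdealizedTrace) -> float:
    """NP_O = (T1 + 2 T2 + 3 T3 + 4 T4) / T_total."""
    if ideal.t_total <= 0:
        raise ParameterError("t_total must be > 0")
    weights = np.arange(1, MAX_QUANTAL_LEVELS + 1, dtype=float)
    return float(np.dot(weights, ideal.dwell_times) / ideal.t_total)


def sites_per_cell(n_sites: int, n_cells: int) -> float:
    """Sparklet sites in a field divided by cells in that field."""
    if n_cells <= 0:
        raise ParameterError("n_cells must be > 0")
    if n_sites < 0:
        raise ParameterError("n_sites must be >= 0")
    return n_sites / n_cells


# ---------------------------------------------------------------------------
# per-site pipeline


@dataclass(frozen=True)
class SiteConfig:
    """Configuration for the per-site quantal pipeline.

    ``quantal_mode`` 'global' uses a fixed quantal amplitude ``q`` for every
    trace (default 0.29 dF/F0); 'fit' estimates it per trace from the
    all-points histogram.
    """

    quantal_mode: str = "global"  # "global" | "fit"
    q: float = 0.29
    max_levels: int = MAX_QUANTAL_LEVELS
    equal_spacing: bool = True
    hysteresis: bool = True
    min_dwell_frames: int = 0
    bin_width: float | None = None
    detect: bool = True

    def __post_init__(self) -> None:
        if self.quantal_mode not in ("global", "fit"):
            raise ParameterError("quantal_mode must be 'global' or 'fit'")
        if self.q <= 0:
            raise ParameterError("q must be > 0")


@dataclass
class SiteResult:
    """All intermediates of one site's analysis, retained for audit."""

    trace: FluorescenceTrace
    histogram: AllPointsHistogram
    model: QuantalModel
    ideal: IdealizedTrace | None
    npo: float
    events: list[SparkletEvent]
    config: SiteConfig

    @property
    def q_hat(self) -> float | None:
        return self.model.quantal_amplitude

    @property
    def total_auc(self) -> float:
        return float(sum(ev.auc for ev in self.events))


def analyze_site(trace: FluorescenceTrace, config: SiteConfig | None = None) -> SiteResult:
    """Histogram -> mixture model -> idealization -> NP_O for one site."""
    config = config or SiteConfig()
    try:
        hist = build_histogram(trace, bin_width=config.bin_width)
    except Exception as exc:
        raise StageError("build_histogram", exc) from exc
    try:
        if config.quantal_mode == "global":
            model = global_quantal_model(trace, config.q)
        else:
            model = fit_multi_gaussian(
                hist, max_levels=config.max_levels, equal_spacing=config.equal_spacing
            )
    except Exception as exc:
        raise StageError("fit_model", exc) from exc
    if model.quantal_amplitude is None:
        # baseline-only model: no events detected, NP_O is zero by definition
        ideal = None
        npo = 0.0
    else:
        try:
            ideal = idealize(
                trace, model, hysteresis=config.hysteresis,
                min_dwell_frames=config.min_dwell_frames,
            )
        except Exception as exc:
            raise StageError("idealize", exc) from exc
        npo = compute_npo(ideal)
    events: list[SparkletEvent] = []
    if config.detect and trace.n_frames > 10:
        try:
            events = detect_events(trace)
        except Exception as exc:
            raise StageError("detect_events", exc) from exc
    return SiteResult(trace, hist, model, ideal, npo, events, config)
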