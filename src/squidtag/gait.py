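"""Swimming-gait classification from fin events and dynamic surge acceleration.

The record is first scanned in 1 s windows: a window is "active" when it
contains a fin event or its dynamic surge acceleration exceeds 0.10 g.
Inactive runs of at least 5 s are glides (passive descent with fins still);
shorter inactive runs are left unclassified. Active runs are tiled into 5 s
windows whose dominant frequency — from a Hann-tapered, zero-padded FFT of
the conditioned fin signal — separates high-frequency metachronal finning
from low-frequency movements; low-frequency windows with surge peaks above
0.10 g are jets, the rest "other". The frequency split point is the density
minimum between the two modes of the per-animal dominant-frequency
distribution, which is reliably bimodal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

from .fin_detection import ConditionedSignal, FinEventTrain
from .synthetic import FAST_HZ

SURGE_THRESHOLD_G = 0.10
MIN_GLIDE_S = 5
ACTIVE_WINDOW_S = 5
DEFAULT_SPLIT_FALLBACK_HZ = 0.75

STATES = ("finning", "jet", "other", "glide", "unclassified")


@dataclass(frozen=True)
class SpectralConfig:
    """FFT settings for dominant-frequency extraction.

    With the defaults (5 s of 100 Hz data plus 10,000 zeros) the frequency
    resolution is 100/10500 ~= 0.0095 Hz.
    """

    window_len: float = 5.0  # s
    zero_pad: int = 10_000  # samples
    sample_rate: float = float(FAST_HZ)

    @property
    def n_window(self) -> int:
        return int(round(self.window_len * self.sample_rate))

    @property
    def resolution(self) -> float:
        return self.sample_rate / (self.n_window + self.zero_pad)


@dataclass(frozen=True)
class ActivityWindow:
    start: float  # s
    has_fin_event: bool
    max_surge: float  # g, absolute dynamic surge
    label: str  # active | inactive

    duration: float = 1.0


@dataclass
class GaitSegment:
    start: float
    end: float
    state: str
    dominant_freq: float | None = None  # Hz, active states only
    max_surge: float = 0.0  # g
    jet_overlap_flag: bool = False  # finning window containing surge > threshold

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TimeBudget:
    fractions: dict[str, float]  # per state, sums to 1
    mean_fin_rate: float  # fins/s within finning time
    glide_durations: tuple[float, ...]  # s
    total_time: float  # s


def extract_dynamic_surge(
    accel_xyz: np.ndarray, axis: int = 0, window_s: float = 0.5
) -> np.ndarray:
    """Dynamic surge acceleration: the long-axis channel minus its postural
    (gravitational) component.

    The postural component is estimated as a centred running mean on a 0.5 s
    scale — slow orientation/gravity changes pass into it, movement-scale
    accelerations do not — and subtracted, so a stationary animal reads ~0.
    """
    accel_xyz = np.asarray(accel_xyz, dtype=float)
    if accel_xyz.size == 0:
        raise ValueError("empty acceleration input")
    surge = accel_xyz[:, axis] if accel_xyz.ndim == 2 else accel_xyz
    if not np.all(np.isfinite(surge)):
        raise ValueError("non-finite acceleration values")
    w = max(int(round(window_s * FAST_HZ)), 1)
    static = pd.Series(surge).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return surge - static


def label_windows(
    fin_train: FinEventTrain,
    surge: np.ndarray,
    threshold: float = SURGE_THRESHOLD_G,
    sample_rate: float = float(FAST_HZ),
) -> list[ActivityWindow]:
    """Label whole 1 s windows active/inactive.

    Active = at least one fin event in the window OR max |dynamic surge|
    above the threshold.
    """
    n_windows = int(len(surge) // sample_rate)
    events = np.asarray(fin_train.event_times)
    out = []
    for k in range(n_windows):
        lo, hi = int(k * sample_rate), int((k + 1) * sample_rate)
        max_surge = float(np.max(np.abs(surge[lo:hi])))
        has_fin = bool(np.any((events >= k) & (events < k + 1)))
        label = "active" if (has_fin or max_surge > threshold) else "inactive"
        out.append(ActivityWindow(float(k), has_fin, max_surge, label))
    return out


def segment_states(
    windows: list[ActivityWindow],
    min_glide: float = MIN_GLIDE_S,
    short_inactive: str = "merge",
) -> tuple[list[GaitSegment], list[tuple[float, float]]]:
    """Group 1 s windows into glide segments and active runs.

    An inactive *state* requires at least min_glide consecutive quiet seconds;
    such runs become glide segments. By default everything else — including
    quiet windows shorter than min_glide, which occur naturally between the
    crests of slow fin cycles — belongs to the surrounding active run and is
    passed on for spectral classification (short_inactive="merge"). With
    short_inactive="unclassified", sub-threshold inactive runs are instead
    split out as unclassified segments. Windows must be contiguous.
    """
    if short_inactive not in ("merge", "unclassified"):
        raise ValueError("short_inactive must be 'merge' or 'unclassified'")
    segments: list[GaitSegment] = []
    active_runs: list[tuple[float, float]] = []
    if not windows:
        return segments, active_runs
    starts = [w.start for w in windows]
    if not np.allclose(np.diff(starts), 1.0):
        raise ValueError("windows must be contiguous 1 s tiles")

    # maximal runs of identical labels
    runs: list[tuple[float, float, str]] = []
    i = 0
    while i < len(windows):
        j = i
        while j < len(windows) and windows[j].label == windows[i].label:
            j += 1
        runs.append((windows[i].start, windows[j - 1].start + 1.0, windows[i].label))
        i = j

    def run_surge(a: float, b: float) -> float:
        return max(w.max_surge for w in windows if a <= w.start < b)

    pending: tuple[float, float] | None = None
    for a, b, label in runs:
        is_glide = label == "inactive" and (b - a) >= min_glide
        if is_glide or (label == "inactive" and short_inactive == "unclassified"):
            if pending is not None:
                active_runs.append(pending)
                pending = None
            state = "glide" if is_glide else "unclassified"
            segments.append(GaitSegment(a, b, state, max_surge=run_surge(a, b)))
        else:
            # active windows, or short inactive runs absorbed into them
            pending = (pending[0], b) if pending is not None else (a, b)
    if pending is not None:
        active_runs.append(pending)
    return segments, active_runs


def dominant_frequency(values: np.ndarray, cfg: SpectralConfig = SpectralConfig()) -> float:
    """Dominant frequency of one active window via Hann-tapered, zero-padded FFT.

    The segment must be exactly cfg.window_len long; its mean is removed
    before tapering and the maximum-magnitude non-zero-frequency bin wins.
    """
    values = np.asarray(values, dtype=float)
    if values.size != cfg.n_window:
        raise ValueError(
            f"segment must be exactly {cfg.n_window} samples, got {values.size}"
        )
    centred = values - values.mean()
    if np.allclose(centred, 0.0, atol=1e-12):
        raise ValueError("constant segment has no dominant frequency")
    tapered = centred * np.hanning(values.size)
    n_fft = values.size + cfg.zero_pad
    spectrum = np.abs(np.fft.rfft(tapered, n=n_fft))
    k = int(np.argmax(spectrum[1:])) + 1  # skip the DC bin
    return k * cfg.sample_rate / n_fft


def find_split_frequency(
    dominant_freqs: np.ndarray,
    min_windows: int = 50,
    fallback: float = DEFAULT_SPLIT_FALLBACK_HZ,
    grid_points: int = 512,
) -> float:
    """Frequency splitting the bimodal dominant-frequency distribution.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a grid; the split is
    the density minimum between the two highest modes. If the distribution is
    not bimodal a warning is issued and the fallback is returned.
    """
    freqs = np.asarray(dominant_freqs, dtype=float)
    if freqs.size < min_windows:
        raise ValueError(
            f"need at least {min_windows} windows to locate the split, got {freqs.size}"
        )
    kde = gaussian_kde(freqs, bw_method="silverman")
    grid = np.linspace(freqs.min(), freqs.max(), grid_points)
    dens = kde(grid)
    peaks = argrelmax(dens)[0]
    if len(peaks) < 2:
        warnings.warn(
            "dominant-frequency distribution not bimodal; using fallback split",
            RuntimeWarning,
        )
        return fallback
    top2 = sorted(sorted(peaks, key=lambda i: dens[i])[-2:])
    lo, hi = top2
    k = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[k])


def classify_active_windows(
    active_runs: list[tuple[float, float]],
    fin_signal: ConditionedSignal,
    surge: np.ndarray,
    split: float,
    threshold: float = SURGE_THRESHOLD_G,
    cfg: SpectralConfig = SpectralConfig(),
) -> list[GaitSegment]:
    """Tile active runs into 5 s windows and assign finning / jet / other.

    dominant_freq >= split -> finning (jet_overlap_flag when the window's max
    surge exceeds the threshold); below the split, surge > threshold -> jet,
    otherwise other. Trailing active data shorter than one window is
    unclassified.
    """
    if split <= 0:
        raise ValueError("split frequency must be positive")
    fs = cfg.sample_rate
    out: list[GaitSegment] = []
    for start, end in active_runs:
        t0 = start
        while t0 + cfg.window_len <= end + 1e-9:
            t1 = t0 + cfg.window_len
            lo, hi = int(round(t0 * fs)), int(round(t1 * fs))
            max_surge = float(np.max(np.abs(surge[lo:hi])))
            try:
                f = dominant_frequency(fin_signal.value[lo:hi], cfg)
            except ValueError:
                out.append(GaitSegment(t0, t1, "unclassified", max_surge=max_surge))
                t0 = t1
                continue
            if f >= split:
                out.append(
                    GaitSegment(t0, t1, "finning", f, max_surge,
                                jet_overlap_flag=max_surge > threshold)
                )
            elif max_surge > threshold:
                out.append(GaitSegment(t0, t1, "jet", f, max_surge))
            else:
                out.append(GaitSegment(t0, t1, "other", f, max_surge))
            t0 = t1
        if t0 < end - 1e-9:
            lo, hi = int(round(t0 * fs)), int(round(end * fs))
            out.append(
                GaitSegment(t0, end, "unclassified",
                            max_surge=float(np.max(np.abs(surge[lo:hi]))))
            )
    return out


def compute_time_budget(
    segments: list[GaitSegment], fin_train: FinEventTrain
) -> TimeBudget:
    """Per-state time fractions, mean fin rate over finning time, and the
    glide-duration distribution. Segments must partition the record."""
    if not segments:
        raise ValueError("no segments")
    ordered = sorted(segments, key=lambda s: s.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end - 1e-9:
            raise ValueError("overlapping segments")
    total = sum(s.duration for s in ordered)
    fractions = {state: 0.0 for state in STATES}
    for s in ordered:
        fractions[s.state] += s.duration / total
    fin_time = sum(s.duration for s in ordered if s.state == "finning")
    events = np.asarray(fin_train.event_times)
    n_fins = sum(
        int(np.sum((events >= s.start) & (events < s.end)))
        for s in ordered if s.state == "finning"
    )
    rate = n_fins / fin_time if fin_time > 0 else float("nan")
    glides = tuple(s.duration for s in ordered if s.state == "glide")
    return TimeBudget(fractions, rate, glides, total)


def segments_to_frame(segments: list[GaitSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [s.start for s in segments],
            "end_s": [s.end for s in segments],
            "state": [s.state for s in segments],
            "dom_freq_hz": [s.dominant_freq for s in segments],
            "max_surge_g": [s.max_surge for s in segments],
            "jet_overlap": [s.jet_overlap_flag for s in segments],
        }
    )
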