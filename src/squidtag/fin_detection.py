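"""Fin-stroke detection from the fin-magnet magnetometer signal.

One fin event is one upstroke+downstroke cycle, visible as one crest in the
summed-magnitude magnetometer signal. The stages mirror how the detector was
trained against manually audited segments: condition (|x|+|y|+|z|, 30-sample
moving average), detect peaks by prominence and width, optimise the three
detector parameters over a grid against annotated crests (keep every
combination that marks 100 % of them, average the survivors), and finally
drop doubly isolated crests — peaks with more than 4 s to the nearest event
on BOTH sides — which are orientation-change artefacts, not fin strokes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .synthetic import FAST_HZ

DEFAULT_SMOOTH_WINDOW = 30  # samples at 100 Hz
DEFAULT_MAX_GAP = 4.0  # s, inter-fin-interval artefact threshold
DEFAULT_MATCH_TOL = 0.25  # s, annotation-to-detection matching tolerance


@dataclass(frozen=True)
class ConditionedSignal:
    time: np.ndarray  # s, 100 Hz
    value: np.ndarray  # >= 0, arbitrary field-strength units

    def segment(self, start: float, end: float) -> "ConditionedSignal":
        m = (self.time >= start) & (self.time < end)
        return ConditionedSignal(self.time[m], self.value[m])


@dataclass(frozen=True)
class PeakParams:
    min_prominence: float  # signal units
    min_width: float  # s
    max_width: float  # s

    def __post_init__(self) -> None:
        if not (0 < self.min_width < self.max_width):
            raise ValueError("need 0 < min_width < max_width")
        if self.min_prominence <= 0:
            raise ValueError("min_prominence must be positive")


@dataclass(frozen=True)
class ParamGrid:
    """Axes of the peak-detector search grid; size = product of axis lengths."""

    prominences: np.ndarray
    min_widths: np.ndarray
    max_widths: np.ndarray

    @classmethod
    def default(cls, n_prom: int = 59, n_wmin: int = 32, n_wmax: int = 32) -> "ParamGrid":
        # log-spaced prominences, linear widths; default shape gives
        # 59*32*32 = 60,416 combinations, the scale used to train the detector
        return cls(
            prominences=np.geomspace(0.05, 5.0, n_prom),
            min_widths=np.linspace(0.05, 0.67, n_wmin),
            max_widths=np.linspace(0.30, 3.0, n_wmax),
        )

    @property
    def size(self) -> int:
        return len(self.prominences) * len(self.min_widths) * len(self.max_widths)

    def combinations(self):
        for p, wmin, wmax in itertools.product(
            self.prominences, self.min_widths, self.max_widths
        ):
            if wmin < wmax:
                yield PeakParams(float(p), float(wmin), float(wmax))


@dataclass(frozen=True)
class FinEventTrain:
    event_times: np.ndarray  # s, strictly increasing (peak apex)
    prominences: np.ndarray
    widths: np.ndarray  # s
    params_used: PeakParams | None = None

    def __len__(self) -> int:
        return len(self.event_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.event_times, "prominence": self.prominences,
             "width_s": self.widths}
        )


def condition_signal(
    mag_xyz: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW,
    time: np.ndarray | None = None,
) -> ConditionedSignal:
    """Sum |x|+|y|+|z| of the magnetometer and smooth with a moving average.

    The average is centred, with shrinking windows at the edges, so event
    times carry no phase lag. Length is preserved.
    """
    mag_xyz = np.asarray(mag_xyz, dtype=float)
    if mag_xyz.size == 0:
        raise ValueError("empty magnetometer input")
    if mag_xyz.ndim != 2 or mag_xyz.shape[1] != 3:
        raise ValueError("mag_xyz must be (n, 3)")
    if not np.all(np.isfinite(mag_xyz)):
        raise ValueError("non-finite magnetometer values")
    if window < 1:
        raise ValueError("window must be >= 1")
    summed = np.abs(mag_xyz).sum(axis=1)
    smoothed = (
        pd.Series(summed).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    n = len(smoothed)
    t = np.arange(n) / FAST_HZ if time is None else np.asarray(time, dtype=float)
    return ConditionedSignal(t, smoothed)


def detect_peaks(signal: ConditionedSignal, params: PeakParams) -> FinEventTrain:
    """All local maxima with prominence >= min_prominence and half-prominence
    width in [min_width, max_width]; on a clean fin sinusoid this yields one
    event per upstroke-downstroke cycle."""
    fs = _sample_rate(signal)
    idx, props = find_peaks(
        signal.value,
        prominence=params.min_prominence,
        width=(params.min_width * fs, params.max_width * fs),
        rel_height=0.5,
    )
    return FinEventTrain(
        event_times=signal.time[idx],
        prominences=props["prominences"],
        widths=props["widths"] / fs,
        params_used=params,
    )


def _sample_rate(signal: ConditionedSignal) -> float:
    if len(signal.time) > 1:
        dt = np.median(np.diff(signal.time))
        if dt > 0:
            return 1.0 / dt
    return float(FAST_HZ)


@dataclass(frozen=True)
class CandidatePeaks:
    """Every local maximum of a segment with its prominence and width,
    computed once so grid combinations reduce to threshold masks."""

    times: np.ndarray
    prominences: np.ndarray
    widths_s: np.ndarray

    @classmethod
    def from_signal(cls, signal: ConditionedSignal) -> "CandidatePeaks":
        fs = _sample_rate(signal)
        idx, _ = find_peaks(signal.value)
        if idx.size == 0:
            z = np.empty(0)
            return cls(z, z, z)
        prom = peak_prominences(signal.value, idx)
        widths = peak_widths(signal.value, idx, rel_height=0.5,
                             prominence_data=prom)[0]
        return cls(signal.time[idx], prom[0], widths / fs)

    def select(self, p: PeakParams) -> np.ndarray:
        """Event times passing the thresholds; matches detect_peaks exactly
        because scipy's prominence/width filters are per-peak predicates."""
        m = (
            (self.prominences >= p.min_prominence)
            & (self.widths_s >= p.min_width)
            & (self.widths_s <= p.max_width)
        )
        return self.times[m]


def match_events(
    detected: np.ndarray, annotated: np.ndarray, tolerance: float = DEFAULT_MATCH_TOL
) -> tuple[int, int]:
    """Greedy one-to-one nearest-time matching.

    Returns (n_matched, n_detected). Each annotated peak may be claimed by at
    most one detection within the tolerance.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    annotated = np.sort(np.asarray(annotated, dtype=float))
    if annotated.size == 0 or detected.size == 0:
        return 0, int(detected.size)
    # candidate pairs via sorted windows: each annotation sees only the
    # detections inside [a - tol, a + tol]
    lo = np.searchsorted(detected, annotated - tolerance, side="left")
    hi = np.searchsorted(detected, annotated + tolerance, side="right")
    pairs = [
        (abs(detected[i] - a), i, j)
        for j, a in enumerate(annotated)
        for i in range(lo[j], hi[j])
    ]
    pairs.sort(key=lambda x: x[0])
    used_d: set[int] = set()
    used_a: set[int] = set()
    for _, i, j in pairs:
        if i not in used_d and j not in used_a:
            used_d.add(i)
            used_a.add(j)
    return len(used_a), int(detected.size)


@dataclass(frozen=True)
class OptimizationResult:
    params: PeakParams  # field-wise mean of the successful combinations
    n_successful: int
    per_segment_recall: tuple[float, ...]
    per_segment_precision: tuple[float, ...]
    successful: tuple[PeakParams, ...] = ()


class OptimizationFailure(RuntimeError):
    def __init__(self, best_recall: float):
        self.best_recall = best_recall
        super().__init__(
            f"no grid combination marked 100% of annotated crests on every "
            f"segment it was required to (best recall {best_recall:.3f})"
        )


def optimize_params(
    signal: ConditionedSignal,
    annotations: list[tuple[tuple[float, float], np.ndarray]],
    grid: ParamGrid,
    tolerance: float = DEFAULT_MATCH_TOL,
    require_no_false_positives: bool = False,
) -> OptimizationResult:
    """Grid-search the peak detector against manually annotated segments.

    annotations: [( (start, end), true_peak_times ), ...]. A combination is
    successful on a segment when every annotated crest is matched by exactly
    one detection within the tolerance (recall = 1); detections beyond the
    annotated crests do not disqualify unless require_no_false_positives is
    set. Successful combinations from all segments are pooled and averaged
    field-wise; recall and precision of the averaged setting are reported per
    segment so users can judge (and tighten) the grid.
    """
    if not annotations:
        raise ValueError("need at least one annotated segment")
    if grid.size == 0:
        raise ValueError("empty parameter grid")
    segs = [
        (CandidatePeaks.from_signal(signal.segment(a, b)), np.asarray(truth, float))
        for (a, b), truth in annotations
    ]
    successful: list[PeakParams] = []
    best_recall = 0.0
    # many combinations select identical peak subsets; memoise the matching
    caches: list[dict[bytes, tuple[int, int]]] = [{} for _ in segs]
    for p in grid.combinations():
        ok = True
        worst = 1.0
        for (cand, truth), cache in zip(segs, caches):
            m = (
                (cand.prominences >= p.min_prominence)
                & (cand.widths_s >= p.min_width)
                & (cand.widths_s <= p.max_width)
            )
            key = np.packbits(m).tobytes()
            if key in cache:
                matched, n_det = cache[key]
            else:
                matched, n_det = match_events(cand.times[m], truth, tolerance)
                cache[key] = (matched, n_det)
            recall = matched / len(truth) if len(truth) else 1.0
            worst = min(worst, recall)
            if recall < 1.0 or (require_no_false_positives and n_det > matched):
                ok = False
                break
        if ok:
            successful.append(p)
        best_recall = max(best_recall, worst)
    if not successful:
        raise OptimizationFailure(best_recall)
    mean = PeakParams(
        min_prominence=float(np.mean([p.min_prominence for p in successful])),
        min_width=float(np.mean([p.min_width for p in successful])),
        max_width=float(np.mean([p.max_width for p in successful])),
    )
    recalls, precisions = [], []
    for cand, truth in segs:
        det = cand.select(mean)
        matched, n_det = match_events(det, truth, tolerance)
        recalls.append(matched / len(truth) if len(truth) else 1.0)
        precisions.append(matched / n_det if n_det else 1.0)
    return OptimizationResult(mean, len(successful), tuple(recalls),
                              tuple(precisions), tuple(successful))


def filter_isolated_peaks(
    train: FinEventTrain, max_gap: float = DEFAULT_MAX_GAP
) -> FinEventTrain:
    """Remove doubly isolated events (gap > max_gap both before AND after).

    Recording edges count as infinite gaps on their open side, so a lone event
    in an otherwise quiet record is removed. Idempotent: the survivors are
    exactly the events within max_gap of another *original* event, and those
    neighbours survive too.
    """
    t = train.event_times
    if len(t) == 0:
        return train
    gap_prev = np.diff(t, prepend=-np.inf)
    gap_next = np.diff(t, append=np.inf)
    keep = ~((gap_prev > max_gap) & (gap_next > max_gap))
    return FinEventTrain(
        event_times=t[keep],
        prominences=train.prominences[keep],
        widths=train.widths[keep],
        params_used=train.params_used,
    )
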