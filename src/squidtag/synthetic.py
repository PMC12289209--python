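"""Ground-truth-labelled synthetic tag recordings.

Emulates the signal structure a fin-mounted magnet imposes on a squid-borne
tag: a magnet on one lateral fin modulates the magnetometer field at the
fin-beat frequency (dorsal = closer = stronger field), so metachronal finning
appears as a sinusoid riding on a slowly drifting orientation baseline.
Jets add discrete surge-acceleration pulses timed to the end of the fin
downstroke; glides leave the fin signal flat, the dynamic acceleration below
threshold and the animal sinking. Every recording carries its ground truth
(fin-event times and the state interval table) so the downstream detector,
classifier and budget stages can be tested without any field data.

Coupling is modelled as additive sinusoidal modulation of field magnitude
proportional to fin elevation; only relative fin position matters downstream,
so no dipole geometry is simulated. Gravity enters the accelerometer as a
1 g vector rotated by the orientation walk, which makes dynamic-acceleration
extraction non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

FAST_HZ = 100
SLOW_HZ = 1

#: default climb rates (m/s, negative = upward) applied while integrating depth
_VERTICAL_RATE = {"finning": -0.10, "jet": -0.20, "other": 0.0}

#: per-channel coupling weights of the fin magnet into the magnetometer axes
_COUPLING = np.array([0.6, 0.3, 0.1])

#: magnetometer baseline (arbitrary field-strength units); signs stay fixed
#: because the orientation walk is small relative to these offsets
_MAG_BASE = np.array([30.0, -12.0, 18.0])


@dataclass(frozen=True)
class GaitParams:
    """State-specific generator parameters.

    fin_freq is the metachronal fin-beat frequency (field mean 1.12 Hz,
    s.d. 0.19); jet_cycle_freq is the slower fin cycle accompanying jets and
    must stay below fin_freq so the two gaits are spectrally separable.
    jet_surge_peak must exceed the 0.10 g activity threshold; amplitudes are
    arbitrary magnetometer units (the magnet coupling is uncalibrated).
    """

    fin_freq: float = 1.12
    fin_amplitude: float = 1.0
    jet_cycle_freq: float = 0.45
    jet_surge_peak: float = 0.20
    glide_sink_rate: float = 0.15
    orientation_drift_scale: float = 0.02
    noise_sd: float = 0.05

    def validate(self) -> None:
        vals = [
            self.fin_freq, self.fin_amplitude, self.jet_cycle_freq,
            self.jet_surge_peak, self.glide_sink_rate,
            self.orientation_drift_scale, self.noise_sd,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite gait parameter")
        if self.fin_freq <= self.jet_cycle_freq:
            raise ValueError("fin_freq must exceed jet_cycle_freq")
        if self.jet_surge_peak <= 0.10:
            raise ValueError("jet_surge_peak must exceed the 0.10 g threshold")


@dataclass(frozen=True)
class ScriptEntry:
    state: str  # finning | jet | glide | other
    duration: float  # seconds
    params: GaitParams = field(default_factory=GaitParams)


@dataclass(frozen=True)
class BehaviourScript:
    """Ordered, contiguous behavioural states with a seed for all noise."""

    entries: tuple[ScriptEntry, ...]
    seed: int

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("behaviour script has no entries")
        for e in self.entries:
            if e.state not in {"finning", "jet", "glide", "other"}:
                raise ValueError(f"unknown state {e.state!r}")
            if not (math.isfinite(e.duration) and e.duration > 0):
                raise ValueError("entry durations must be strictly positive")
            e.params.validate()

    @property
    def duration(self) -> float:
        return float(sum(e.duration for e in self.entries))


@dataclass
class TagRecording:
    """Synchronized fast (100 Hz accel/mag) and slow (1 Hz depth/temp) streams."""

    fast_time: np.ndarray  # s
    accel_xyz: np.ndarray  # (n, 3) g
    mag_xyz: np.ndarray  # (n, 3) arbitrary units
    slow_time: np.ndarray  # s
    depth: np.ndarray  # m
    temperature: np.ndarray  # degC
    animal_mass: float  # kg
    mantle_length: float = 35.0  # cm

    def __post_init__(self) -> None:
        if self.animal_mass <= 0:
            raise ValueError("animal mass must be positive")

    def copy(self) -> "TagRecording":
        return TagRecording(
            self.fast_time.copy(), self.accel_xyz.copy(), self.mag_xyz.copy(),
            self.slow_time.copy(), self.depth.copy(), self.temperature.copy(),
            self.animal_mass, self.mantle_length,
        )


@dataclass(frozen=True)
class GroundTruth:
    fin_event_times: np.ndarray  # s, strictly increasing
    state_intervals: tuple[tuple[float, float, str], ...]  # (start, end, state)

    def intervals_of(self, state: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, s in self.state_intervals if s == state]


def _smooth_walk(rng: np.random.Generator, n_fast: int, scale: float,
                 corr_s: float = 8.0) -> np.ndarray:
    """Smooth stationary orientation wander: low-pass filtered 1 Hz noise
    interpolated to 100 Hz, with standard deviation `scale`.

    The ~8 s correlation scale keeps drift per 0.3 s far below the unit fin
    amplitude (so the smoothing window stays meaningful) and keeps its
    spectral power well under the fin line at any scripted fin frequency.
    """
    n_slow = max(n_fast // FAST_HZ + 2, 2)
    white = rng.normal(0.0, 1.0, n_slow + 8 * int(corr_s))
    k = np.exp(-0.5 * ((np.arange(-4 * corr_s, 4 * corr_s + 1)) / corr_s) ** 2)
    smooth = np.convolve(white, k / np.sqrt(np.sum(k**2)), mode="same")
    smooth = smooth[4 * int(corr_s): 4 * int(corr_s) + n_slow]
    t_slow = np.arange(n_slow, dtype=float)
    t_fast = np.arange(n_fast, dtype=float) / FAST_HZ
    return np.interp(t_fast, t_slow, smooth * scale)


def _temp_lookup(profile: Mapping[float, float] | Callable[[np.ndarray], np.ndarray] | None):
    if profile is None:
        profile = {0.0: 16.0, 50.0: 14.5, 200.0: 12.0}
    if callable(profile):
        return profile
    depths = np.array(sorted(profile))
    temps = np.array([profile[d] for d in depths])
    return lambda z: np.interp(z, depths, temps)


def simulate_recording(
    script: BehaviourScript,
    mass: float = 1.14,
    temp_profile: Mapping[float, float] | Callable | None = None,
    start_depth: float = 30.0,
) -> tuple[TagRecording, GroundTruth]:
    """Render a behaviour script into a tag recording plus its ground truth.

    Finning and jet segments emit one fin event per completed fin cycle, at
    the crest (maximum fin elevation) of each cycle; jet segments additionally
    emit one surge pulse per cycle whose acceleration maximum lies at the end
    of the fin downstroke. Glides keep the fin channel flat, dynamic surge
    below 0.10 g and depth increasing at the scripted sink rate.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    rng = np.random.default_rng(script.seed)
    total = script.duration
    n_fast = int(round(total * FAST_HZ))
    t = np.arange(n_fast) / FAST_HZ

    fin_mod = np.zeros(n_fast)
    surge_dyn = np.zeros(n_fast)
    vert_rate = np.zeros(n_fast)
    noise_sd = np.zeros(n_fast)
    drift_scale = np.zeros(n_fast)

    events: list[float] = []
    intervals: list[tuple[float, float, str]] = []
    t0 = 0.0
    for e in script.entries:
        t1 = t0 + e.duration
        sl = slice(int(round(t0 * FAST_HZ)), int(round(t1 * FAST_HZ)))
        tau = t[sl] - t0
        p = e.params
        noise_sd[sl] = p.noise_sd
        drift_scale[sl] = p.orientation_drift_scale
        if e.state == "finning":
            f = p.fin_freq
            fin_mod[sl] = p.fin_amplitude * np.sin(2 * np.pi * f * tau)
            # weak fin-correlated body acceleration, well under threshold
            surge_dyn[sl] = 0.02 * np.sin(2 * np.pi * f * tau)
            vert_rate[sl] = _VERTICAL_RATE["finning"]
            n_cyc = int(math.floor(e.duration * f + 1e-9))
            events.extend(t0 + (k + 0.25) / f for k in range(n_cyc))
        elif e.state in ("jet", "other"):
            f = p.jet_cycle_freq
            fin_mod[sl] = p.fin_amplitude * np.sin(2 * np.pi * f * tau)
            vert_rate[sl] = _VERTICAL_RATE[e.state]
            n_cyc = int(math.floor(e.duration * f + 1e-9))
            events.extend(t0 + (k + 0.25) / f for k in range(n_cyc))
            if e.state == "jet":
                # surge pulse at the end of each fin downstroke (cycle end)
                pulse = np.zeros_like(tau)
                for k in range(n_cyc):
                    pulse += np.exp(-0.5 * ((tau - (k + 1) / f) / 0.06) ** 2)
                surge_dyn[sl] = p.jet_surge_peak * pulse
            else:
                surge_dyn[sl] = 0.03 * np.sin(2 * np.pi * f * tau)
        elif e.state == "glide":
            vert_rate[sl] = p.glide_sink_rate
        intervals.append((t0, t1, e.state))
        t0 = t1

    # orientation walk -> small pitch/roll angles rotating the 1 g gravity vector
    pitch = _smooth_walk(rng, n_fast, 1.0) * drift_scale + 0.05
    roll = _smooth_walk(rng, n_fast, 1.0) * drift_scale

    accel = np.empty((n_fast, 3))
    accel[:, 0] = np.sin(pitch) + surge_dyn
    accel[:, 1] = -np.cos(pitch) * np.sin(roll)
    accel[:, 2] = np.cos(pitch) * np.cos(roll)
    accel += rng.normal(0.0, 1.0, (n_fast, 3)) * np.maximum(
        noise_sd[:, None] * 0.2, 1e-12
    )

    mag = np.empty((n_fast, 3))
    for ax in range(3):
        baseline = _MAG_BASE[ax] + _smooth_walk(rng, n_fast, 1.0) * drift_scale * 10.0
        mag[:, ax] = baseline + np.sign(_MAG_BASE[ax]) * _COUPLING[ax] * fin_mod
    mag += rng.normal(0.0, 1.0, (n_fast, 3)) * noise_sd[:, None]

    depth_fast = np.maximum(start_depth + np.cumsum(vert_rate) / FAST_HZ, 0.0)
    slow_idx = np.arange(0, n_fast, FAST_HZ)
    depth = depth_fast[slow_idx]
    temp = np.asarray(_temp_lookup(temp_profile)(depth), dtype=float)

    rec = TagRecording(
        fast_time=t, accel_xyz=accel, mag_xyz=mag,
        slow_time=t[slow_idx], depth=depth, temperature=temp,
        animal_mass=mass,
    )
    truth = GroundTruth(np.array(events), tuple(intervals))
    return rec, truth


def simulate_orientation_artefacts(
    recording: TagRecording,
    truth: GroundTruth,
    n_events: int,
    seed: int,
) -> tuple[TagRecording, GroundTruth]:
    """Inject slow, isolated magnetometer excursions during glide intervals.

    Each artefact mimics a gradual orientation change: a broad Gaussian bump
    in field magnitude, placed > 4 s from every true fin event and from every
    other artefact on both sides, so the inter-fin-interval filter should
    remove exactly these. Ground truth is returned unchanged.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events == 0:
        return recording, truth
    rng = np.random.default_rng(seed)
    clearance = 4.2  # strictly more than the 4 s filter gap
    spacing = 8.5  # artefact-to-artefact, keeps each doubly isolated
    slots: list[float] = []
    for a, b in truth.intervals_of("glide"):
        lo, hi = a + clearance, b - clearance
        pos = lo
        while pos <= hi:
            slots.append(pos)
            pos += spacing
    if len(slots) < n_events:
        raise ValueError(
            f"cannot place {n_events} artefacts: only {len(slots)} glide slots "
            "with 4 s clearance available"
        )
    chosen = np.sort(rng.choice(len(slots), size=n_events, replace=False))
    out = recording.copy()
    t = out.fast_time
    for i in chosen:
        c = slots[i]
        bump = 1.5 * np.exp(-0.5 * ((t - c) / 0.40) ** 2)
        out.mag_xyz[:, 0] += np.sign(_MAG_BASE[0]) * bump
    return out, truth


def simulate_do_trace(
    rate_mg_per_kg_h: float,
    mass_kg: float,
    volume_l: float,
    duration_s: float = 1800.0,
    do0_mg_l: float = 8.0,
    control_slope_mg_l_h: float = -0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate a 1 Hz dissolved-oxygen decline for a swim-tunnel trial.

    The animal removes rate*mass mg O2 per hour from volume_l litres, on top
    of a microbial background decline (control_slope, itself negative).
    Returns (time_s, do_mg_l). With noise_sd = 0 the trace is exactly linear,
    so re-estimating the rate after control subtraction is a strict round trip.
    """
    if volume_l <= 0 or mass_kg <= 0:
        raise ValueError("volume and mass must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s)) + 1, dtype=float)
    animal_slope = -rate_mg_per_kg_h * mass_kg / volume_l  # mg/l per hour
    do = do0_mg_l + (animal_slope + control_slope_mg_l_h) * t / 3600.0
    if noise_sd > 0:
        do = do + rng.normal(0.0, noise_sd, t.size)
    return t, do
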