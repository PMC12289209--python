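"""End-to-end pipeline: configuration, file I/O, stage orchestration, fixtures.

File formats are plain delimited text with one header line, times in seconds
from recording start:

    fast stream   time_s, ax_g, ay_g, az_g, mx, my, mz          (100 Hz)
    slow stream   time_s, depth_m, temp_c                       (1 Hz)
    event train   time_s, prominence, width_s
    segments      start_s, end_s, state, dom_freq_hz, max_surge_g, jet_overlap
    trials        time_s, do_mg_l (one file per trial) + metadata table

All random steps draw from one seeded generator; a run manifest records the
config snapshot, input checksums and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioenergetics as be
from . import fin_detection as fd
from . import gait
from . import respirometry as resp
from . import synthetic as syn

log = logging.getLogger("squidtag")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; seed is mandatory."""

    seed: int
    out_dir: str
    mass_kg: float = 1.14
    surge_threshold_g: float = gait.SURGE_THRESHOLD_G
    min_glide_s: float = gait.MIN_GLIDE_S
    smooth_window: int = fd.DEFAULT_SMOOTH_WINDOW
    max_gap_s: float = fd.DEFAULT_MAX_GAP
    match_tolerance_s: float = fd.DEFAULT_MATCH_TOL
    q10: float = 2.0
    lab_temp_c: float = resp.LAB_REFERENCE_TEMP_C
    o2_density_mg_ml: float = be.O2_DENSITY_MG_ML
    fish_mg_per_ml_o2: float = be.FISH_MG_PER_ML_O2
    glide_proxy_mg_kg_h: float = be.GLIDE_PROXY_MG_KG_H
    fast_file: str | None = None
    slow_file: str | None = None
    simulate_minutes: float = 20.0

    def validate(self) -> None:
        for name in ("mass_kg", "surge_threshold_g", "min_glide_s",
                     "q10", "o2_density_mg_ml", "fish_mg_per_ml_o2"):
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.seed is None:
            raise ValueError("config field 'seed' is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        missing = {"seed", "out_dir"} - set(raw)
        if missing:
            raise ValueError(f"config missing required fields: {sorted(missing)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------- file I/O


def write_fast(rec: syn.TagRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": rec.fast_time,
            "ax_g": rec.accel_xyz[:, 0], "ay_g": rec.accel_xyz[:, 1],
            "az_g": rec.accel_xyz[:, 2],
            "mx": rec.mag_xyz[:, 0], "my": rec.mag_xyz[:, 1],
            "mz": rec.mag_xyz[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def write_slow(rec: syn.TagRecording, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": rec.slow_time, "depth_m": rec.depth, "temp_c": rec.temperature}
    ).to_csv(path, index=False, float_format="%.4f")


def read_fast(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (time_s, accel_xyz, mag_xyz)."""
    d = pd.read_csv(path)
    return (
        d["time_s"].to_numpy(),
        d[["ax_g", "ay_g", "az_g"]].to_numpy(),
        d[["mx", "my", "mz"]].to_numpy(),
    )


def read_slow(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_events(train: fd.FinEventTrain, path: str | Path) -> None:
    train.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> fd.FinEventTrain:
    d = pd.read_csv(path)
    return fd.FinEventTrain(
        d["time_s"].to_numpy(), d["prominence"].to_numpy(), d["width_s"].to_numpy()
    )


def write_segments(segments: list[gait.GaitSegment], path: str | Path) -> None:
    gait.segments_to_frame(segments).to_csv(path, index=False)


def read_segments(path: str | Path) -> list[gait.GaitSegment]:
    d = pd.read_csv(path)
    return [
        gait.GaitSegment(
            float(r.start_s), float(r.end_s), str(r.state),
            None if pd.isna(r.dom_freq_hz) else float(r.dom_freq_hz),
            float(r.max_surge_g), bool(r.jet_overlap),
        )
        for r in d.itertuples()
    ]


def write_ground_truth(truth: syn.GroundTruth, events_path, intervals_path) -> None:
    pd.DataFrame({"time_s": truth.fin_event_times}).to_csv(
        events_path, index=False, float_format="%.6f"
    )
    pd.DataFrame(
        truth.state_intervals, columns=["start_s", "end_s", "state"]
    ).to_csv(intervals_path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------ orchestration


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, dict]  # file -> {stage, records, sha256}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "outputs": self.outputs}, fh, indent=2, default=str)


def default_demo_script(seed: int, minutes: float = 20.0) -> syn.BehaviourScript:
    """A deployment exercising all four gaits with the field time budget
    (66 % finning, 18 % glide, 4 % jet, 12 % other), interleaved in bouts."""
    total = minutes * 60.0
    unit = total / 100.0
    p = syn.GaitParams()
    entries = []
    # four repeats of a finning / glide / other / finning / jet rotation
    for _ in range(4):
        entries += [
            syn.ScriptEntry("finning", 8.25 * unit, p),
            syn.ScriptEntry("glide", 4.5 * unit, p),
            syn.ScriptEntry("other", 3.0 * unit, p),
            syn.ScriptEntry("finning", 8.25 * unit, p),
            syn.ScriptEntry("jet", 1.0 * unit, p),
        ]
    return syn.BehaviourScript(tuple(entries), seed=seed)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """simulate (when no input files are given) -> detect fins -> classify ->
    budget; deterministic for a fixed config + seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, dict] = {}

    if config.fast_file is None:
        log.info("simulating %s min deployment (seed %d)",
                 config.simulate_minutes, config.seed)
        script = default_demo_script(config.seed, config.simulate_minutes)
        rec, truth = syn.simulate_recording(script, mass=config.mass_kg)
        fast_path, slow_path = out / "fast.csv", out / "slow.csv"
        write_fast(rec, fast_path)
        write_slow(rec, slow_path)
        write_ground_truth(truth, out / "truth_events.csv", out / "truth_intervals.csv")
        accel, mag = rec.accel_xyz, rec.mag_xyz
        slow = pd.DataFrame({"time_s": rec.slow_time, "depth_m": rec.depth,
                             "temp_c": rec.temperature})
        for f in ("fast.csv", "slow.csv", "truth_events.csv", "truth_intervals.csv"):
            p = out / f
            outputs[f] = {"stage": "simulate",
                          "records": sum(1 for _ in open(p)) - 1,
                          "sha256": _sha256(p)}
    else:
        if not Path(config.fast_file).exists():
            raise FileNotFoundError(config.fast_file)
        _, accel, mag = read_fast(config.fast_file)
        slow = read_slow(config.slow_file)

    # fin detection with a permissive default setting
    signal = fd.condition_signal(mag, window=config.smooth_window)
    params = fd.PeakParams(min_prominence=0.4, min_width=0.1, max_width=2.5)
    train = fd.detect_peaks(signal, params)
    train = fd.filter_isolated_peaks(train, config.max_gap_s)
    write_events(train, out / "events.csv")
    outputs["events.csv"] = {"stage": "detect-fins", "records": len(train),
                             "sha256": _sha256(out / "events.csv")}
    log.info("detected %d fin events after artefact filtering", len(train))

    # gait classification
    surge = gait.extract_dynamic_surge(accel)
    windows = gait.label_windows(train, surge, config.surge_threshold_g)
    segments, active_runs = gait.segment_states(windows, config.min_glide_s)
    freqs = []
    for a, b in active_runs:
        t0 = a
        while t0 + gait.ACTIVE_WINDOW_S <= b + 1e-9:
            lo, hi = int(t0 * 100), int((t0 + gait.ACTIVE_WINDOW_S) * 100)
            try:
                freqs.append(gait.dominant_frequency(signal.value[lo:hi]))
            except ValueError:
                pass
            t0 += gait.ACTIVE_WINDOW_S
    try:
        split = gait.find_split_frequency(np.array(freqs))
    except ValueError:
        split = gait.DEFAULT_SPLIT_FALLBACK_HZ
    segments += gait.classify_active_windows(
        active_runs, signal, surge, split, config.surge_threshold_g
    )
    segments.sort(key=lambda s: s.start)
    write_segments(segments, out / "segments.csv")
    outputs["segments.csv"] = {"stage": "classify", "records": len(segments),
                               "sha256": _sha256(out / "segments.csv")}
    budget_t = gait.compute_time_budget(segments, train)
    log.info("time budget: %s", {k: round(v, 3) for k, v in budget_t.fractions.items()})

    # energy budget with a two-point fallback model when no trials are given
    model = resp.reference_allometric_model()
    q10 = be.Q10Params(q10=config.q10, T1=config.lab_temp_c)
    costs = be.assign_state_costs(
        segments, model, config.mass_kg,
        slow["time_s"].to_numpy(), slow["temp_c"].to_numpy(), q10,
        config.glide_proxy_mg_kg_h,
    )
    budget = be.daily_budget(costs, config.mass_kg)
    g_fish, pct_bw = be.fish_equivalent(
        budget.total_daily_mg, config.mass_kg,
        config.o2_density_mg_ml, config.fish_mg_per_ml_o2,
    )
    report = {
        "time_budget": budget_t.fractions,
        "mean_fin_rate_hz": budget_t.mean_fin_rate,
        "split_frequency_hz": split,
        "per_state_daily_mg_o2": budget.per_state_daily_mg,
        "per_state_daily_mg_o2_per_kg": budget.per_state_daily_mg_kg,
        "total_daily_mg_o2": budget.total_daily_mg,
        "uncosted_fraction": budget.uncosted_fraction,
        "fish_equivalent_g_per_day": g_fish,
        "pct_body_weight_per_day": pct_bw,
        "constants": {
            "q10": config.q10, "glide_proxy_mg_kg_h": config.glide_proxy_mg_kg_h,
            "o2_density_mg_ml": config.o2_density_mg_ml,
            "fish_mg_per_ml_o2": config.fish_mg_per_ml_o2,
        },
    }
    with open(out / "budget.json", "w") as fh:
        json.dump(report, fh, indent=2)
    outputs["budget.json"] = {"stage": "budget", "records": 1,
                              "sha256": _sha256(out / "budget.json")}

    manifest = RunManifest(asdict(config), __version__, outputs)
    manifest.write(out / "manifest.json")
    return manifest


def make_fixtures(seed: int, out_dir: str | Path, scale: str = "tiny") -> Path:
    """Deterministic synthetic fixtures for tests (tiny) and docs (demo)."""
    if scale not in ("tiny", "demo"):
        raise ValueError("scale must be 'tiny' or 'demo'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    minutes = 2.0 if scale == "tiny" else 20.0
    script = default_demo_script(seed, minutes)
    rec, truth = syn.simulate_recording(script)
    write_fast(rec, out / "fast.csv")
    write_slow(rec, out / "slow.csv")
    write_ground_truth(truth, out / "truth_events.csv", out / "truth_intervals.csv")
    rate = 292.0
    t, do = syn.simulate_do_trace(rate, mass_kg=1.14, volume_l=1485.0,
                                  duration_s=600 if scale == "tiny" else 1800,
                                  seed=seed)
    pd.DataFrame({"time_s": t, "do_mg_l": do}).to_csv(
        out / "trial_animal.csv", index=False, float_format="%.6f"
    )
    tc, doc = syn.simulate_do_trace(0.0, 1.0, 1485.0, control_slope_mg_l_h=-0.05,
                                    duration_s=600, seed=seed + 1)
    pd.DataFrame({"time_s": tc, "do_mg_l": doc}).to_csv(
        out / "trial_control.csv", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        [{"trial_id": "animal", "animal_id": "sq1", "mass_kg": 1.14,
          "motor_level": 2, "volume_l": 1485.0, "is_control": False,
          "temp_c": 18.8},
         {"trial_id": "control", "animal_id": "", "mass_kg": "",
          "motor_level": "", "volume_l": 1485.0, "is_control": True,
          "temp_c": 18.8}]
    ).to_csv(out / "trials_meta.csv", index=False)
    return out
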