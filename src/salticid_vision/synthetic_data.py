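"""Virtual-spider generator: treadmill traces with known ground truth.

Produces FicTrac-style rotation traces for whole trials, so that every
stage of the scoring pipeline can be exercised end to end without any
recordings.  Two behaviour sources are supported:

* :class:`VirtualSpiderParams` — a descriptive spider: each presentation
  whose stimulus produces a detectable event (appearing, disappearing, or
  crossing an eye-field edge) elicits a pivot with a configurable response
  probability, latency, amplitude and direction toward the event; the
  default response probabilities are the study's observed per-presentation
  response rates (20.4% with ALEs available, 11.1% with PLEs only);
* a :class:`~.neural_model.ModelConfig` — the integration model itself
  decides when and where to pivot, closing the loop between the circuit
  hypothesis and the analysis pipeline.

Pivots are injected as raised-cosine velocity pulses whose area is known
analytically, with the sphere-frame sign opposite to the spider's intended
rotation; baseline activity is white Gaussian velocity noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import EyeFieldMap, DEFAULT_EYE_FIELDS, in_field_array
from .neural_model import ModelConfig, run_model
from .stimuli import AzimuthTrack, TrialSchedule
from .treadmill_analysis import RotationTrace

__all__ = [
    "VirtualSpiderParams",
    "default_params",
    "StimulusEvent",
    "detectable_events",
    "raised_cosine_pulse",
    "simulate_trial",
    "generate_dataset",
    "RESPONSE_RATE_ALE",
    "RESPONSE_RATE_PLE",
]

# per-presentation response rates reported for the two eye treatments
RESPONSE_RATE_ALE = 0.204
RESPONSE_RATE_PLE = 0.111


@dataclass(frozen=True)
class VirtualSpiderParams:
    """Descriptive virtual spider.

    ``response_probability`` is the probability of responding to a
    presentation that produces at least one detectable event.  Latency
    (s, from the event) is lognormal; pivot amplitude (deg of rotation,
    i.e. the pulse's area) is normal truncated to ``amplitude_range`` so
    every injected pivot clears the 20-deg scoring criterion.
    """

    active_eyes: frozenset[str] = frozenset({"ALE"})
    eye_field_map: EyeFieldMap = field(default_factory=lambda: DEFAULT_EYE_FIELDS)
    response_probability: float = RESPONSE_RATE_ALE
    latency_median_s: float = 0.10
    latency_sigma: float = 0.35
    pivot_amplitude_deg: float = 40.0
    pivot_amplitude_sd: float = 5.0
    amplitude_range: tuple[float, float] = (25.0, 60.0)
    pivot_duration_s: float = 0.5
    noise_sd: float = 2.0
    min_event_azimuth_deg: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_probability <= 1.0):
            raise ValueError("response_probability must be in [0, 1]")
        if self.pivot_amplitude_deg <= 0 or self.pivot_duration_s <= 0:
            raise ValueError("pivot amplitude and duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_params(treatment: str, **overrides) -> VirtualSpiderParams:
    """Virtual spider for an eye treatment: 'ALE', 'PLE' or 'ALE+PLE'.

    Response probability defaults to the observed per-presentation rates:
    20.4% whenever the ALEs are available, 11.1% for PLE-only.
    """
    eyes = frozenset(treatment.split("+"))
    if not eyes <= {"ALE", "PLE"}:
        raise ValueError(f"unknown treatment {treatment!r}")
    p = RESPONSE_RATE_ALE if "ALE" in eyes else RESPONSE_RATE_PLE
    kw = dict(active_eyes=eyes, response_probability=p)
    kw.update(overrides)
    return VirtualSpiderParams(**kw)


# ---------------------------------------------------------------------------
# Detectable events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusEvent:
    """A moment at which a stimulus becomes salient to the secondary eyes."""

    time_s: float          # relative to presentation onset
    azimuth_deg: float
    kind: str              # appearance | disappearance | entry | exit


def detectable_events(track: AzimuthTrack, fmap: EyeFieldMap,
                      active_eyes, min_azimuth_deg: float = 5.0
                      ) -> list[StimulusEvent]:
    """Events produced by one stimulus track for a given eye treatment.

    The stimulus centroid is tracked; events are its appearance or
    disappearance while inside an active eye's field, and its crossings of
    field edges.  Events within ``min_azimuth_deg`` of straight ahead are
    dropped (no orienting pivot toward a target the animal already faces).
    """
    # raw (unnormalized) centroid keeps the sign of rear-field events
    # consistent with the track's side: a left-monitor stimulus reaching
    # the junction behind the animal stays at -180, not +180
    c = track.centroid()
    vis = np.zeros(track.n_frames, dtype=bool)
    for eye in active_eyes:
        vis |= in_field_array(fmap, eye, c)
    events: list[StimulusEvent] = []
    fr = track.frame_rate
    if vis[0]:
        events.append(StimulusEvent(0.0, float(c[0]), "appearance"))
    flips = np.flatnonzero(vis[1:] != vis[:-1]) + 1
    for f in flips:
        kind = "entry" if vis[f] else "exit"
        events.append(StimulusEvent(f / fr, float(c[f]), kind))
    if vis[-1]:
        events.append(StimulusEvent((track.n_frames - 1) / fr,
                                    float(c[-1]), "disappearance"))
    return [e for e in events if abs(e.azimuth_deg) >= min_azimuth_deg]


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

def raised_cosine_pulse(area_deg: float, duration_s: float,
                        frame_rate: float) -> np.ndarray:
    """Velocity pulse (deg/s) with exact analytic area ``area_deg``.

    v(t) = (area/duration) * (1 - cos(2*pi*t/duration)); the discrete
    samples are rescaled so the trapezoidal integral matches exactly.
    """
    n = max(int(round(duration_s * frame_rate)), 2)
    t = np.arange(n) / frame_rate
    v = (area_deg / duration_s) * (1.0 - np.cos(2.0 * np.pi * t / duration_s))
    integral = np.trapezoid(v) / frame_rate
    if integral != 0:
        v *= area_deg / integral
    return v


def _inject(velocity: np.ndarray, pulse: np.ndarray, start: int) -> None:
    end = min(start + pulse.size, velocity.size)
    if start < velocity.size:
        velocity[start:end] += pulse[:end - start]


def simulate_trial(schedule: TrialSchedule,
                   behavior_source: VirtualSpiderParams | ModelConfig,
                   seed: int = 0) -> tuple[RotationTrace, pd.DataFrame]:
    """Synthesize a full-trial rotation trace plus its ground truth.

    Returns a 120-Hz sphere-frame trace (positive increments = clockwise
    sphere = counterclockwise spider) and a per-pivot table with columns
    presentation, time_s, target_azimuth_deg, intended_direction,
    area_deg, plus one row per non-responded presentation.
    """
    rng = np.random.default_rng(seed)
    fr = schedule.frame_rate
    n_frames = int(np.ceil(schedule.duration_s * fr)) + 1
    if isinstance(behavior_source, VirtualSpiderParams):
        noise_sd = behavior_source.noise_sd
    else:
        noise_sd = 2.0
    velocity = rng.normal(0.0, noise_sd, n_frames) if noise_sd > 0 \
        else np.zeros(n_frames)

    records = []
    if isinstance(behavior_source, ModelConfig):
        cfg = replace(behavior_source, seed=int(rng.integers(2 ** 31)))
        decisions = run_model(schedule, cfg)
        for d in decisions:
            # the spider turns to face the target: amplitude = eccentricity
            area = abs(d.target_azimuth_deg)
            if area < 1.0:
                continue
            sgn = 1 if d.target_azimuth_deg > 0 else -1
            pulse = -sgn * raised_cosine_pulse(area, 0.5, fr)
            _inject(velocity, pulse, int(round(d.time_s * fr)))
            records.append({
                "presentation": d.presentation_index,
                "responded": True, "time_s": d.time_s,
                "target_azimuth_deg": d.target_azimuth_deg,
                "intended_direction": sgn, "area_deg": sgn * area,
                "trigger": d.trigger,
            })
    else:
        p = behavior_source
        for i, pres in enumerate(schedule.presentations):
            events: list[StimulusEvent] = []
            for tr in pres.tracks.values():
                events += detectable_events(tr, p.eye_field_map,
                                            p.active_eyes,
                                            p.min_event_azimuth_deg)
            if not events:
                records.append({"presentation": i, "responded": False,
                                "time_s": np.nan,
                                "target_azimuth_deg": np.nan,
                                "intended_direction": 0,
                                "area_deg": 0.0, "trigger": "none"})
                continue
            if rng.random() >= p.response_probability:
                records.append({"presentation": i, "responded": False,
                                "time_s": np.nan,
                                "target_azimuth_deg": np.nan,
                                "intended_direction": 0,
                                "area_deg": 0.0, "trigger": "none"})
                continue
            ev = events[rng.integers(len(events))]
            latency = float(rng.lognormal(np.log(p.latency_median_s),
                                          p.latency_sigma))
            t = pres.onset_s + ev.time_s + latency
            area = float(np.clip(
                rng.normal(p.pivot_amplitude_deg, p.pivot_amplitude_sd),
                *p.amplitude_range))
            sgn = 1 if ev.azimuth_deg > 0 else -1
            pulse = -sgn * raised_cosine_pulse(area, p.pivot_duration_s, fr)
            _inject(velocity, pulse, int(round(t * fr)))
            records.append({
                "presentation": i, "responded": True, "time_s": t,
                "target_azimuth_deg": ev.azimuth_deg,
                "intended_direction": sgn, "area_deg": sgn * area,
                "trigger": ev.kind,
            })

    trace = RotationTrace(fr, velocity / fr, source="synthetic")
    return trace, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(out_dir, n_spiders: int, treatments=("ALE",),
                     protocol: str = "exp1", seed: int = 0,
                     overwrite: bool = False,
                     schedule_kwargs: dict | None = None,
                     params_overrides: dict | None = None) -> dict:
    """Emit a file tree of per-spider traces with schedules & ground truth.

    Layout::

        out_dir/
          manifest.json          all seeds and parameters
          ground_truth.csv       per-presentation truth, all spiders
          <treatment>/spider_NNN/trace.csv
          <treatment>/spider_NNN/schedule.json

    Returns the manifest dict.  Replaying the manifest seeds reproduces
    byte-identical files.
    """
    from .stimuli import schedule_experiment

    if n_spiders < 1:
        raise ValueError("n_spiders must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    root_rng = np.random.default_rng(seed)
    schedule_kwargs = dict(schedule_kwargs or {})
    params_overrides = dict(params_overrides or {})
    manifest = {
        "seed": seed, "protocol": protocol, "n_spiders": n_spiders,
        "treatments": list(treatments),
        "schedule_kwargs": {k: v for k, v in schedule_kwargs.items()
                            if not hasattr(v, "__dict__")},
        "spiders": [],
    }
    truth_frames = []
    for treatment in treatments:
        tdir = out / treatment.replace("+", "_")
        tdir.mkdir(exist_ok=True)
        for s in range(n_spiders):
            sched_seed = int(root_rng.integers(2 ** 31))
            trial_seed = int(root_rng.integers(2 ** 31))
            sched = schedule_experiment(protocol, seed=sched_seed,
                                        **schedule_kwargs)
            params = default_params(treatment, **params_overrides)
            trace, truth = simulate_trial(sched, params, seed=trial_seed)
            sdir = tdir / f"spider_{s:03d}"
            sdir.mkdir(exist_ok=True)
            pd.DataFrame({
                "frame": np.arange(trace.n_frames),
                "z_increment_deg": trace.z_increments_deg,
            }).to_csv(sdir / "trace.csv", index=False)
            sched.to_json(sdir / "schedule.json")
            truth.insert(0, "spider", s)
            truth.insert(0, "treatment", treatment)
            truth_frames.append(truth)
            manifest["spiders"].append({
                "treatment": treatment, "spider": s,
                "schedule_seed": sched_seed, "trial_seed": trial_seed,
                "trace": str(sdir / "trace.csv"),
            })
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out / "ground_truth.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
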