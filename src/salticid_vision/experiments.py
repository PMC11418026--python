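"""Virtual replications of the two treadmill experiments.

These drivers wire the package together the way the study ran its animals:

* :func:`run_virtual_exp1` — behavioural visual-field mapping: virtual
  spiders of a given eye treatment watch single 4-deg dots sweep one
  monitor at 9 deg/s (30 presentations per trial, both arena angles, and
  both body orientations for the PLE treatment), their traces are scored
  with the first-detection criterion, and the detection angles are pooled
  into a 5-deg histogram whose modes estimate the eye-field edges.
* :func:`run_model_exp2` — the integration model plays experiment 2
  (mirrored biological/random display pairs) under a given eye
  configuration and geometry, returning first-pivot sides and
  amplitude-weighted signed scores.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import MonitorSetup
from .neural_model import ModelConfig, decision_scores, first_decisions, \
    run_model
from .stimuli import StimulusSpec, schedule_experiment
from .synthetic_data import default_params, simulate_trial
from .treadmill_analysis import DetectionHistogram, detection_histogram, \
    score_exp1

__all__ = [
    "Exp1Result",
    "run_virtual_exp1",
    "Exp2ModelResult",
    "run_model_exp2",
    "monitor_spans",
]

MONITOR_ANGLES = (120.0, 65.0)


def monitor_spans() -> dict[str, float]:
    """Azimuthal coverage of the two arena configurations (deg)."""
    from .geometry import angular_coverage

    spans = {
        "span_120": angular_coverage(MonitorSetup(537.0, 120.0, 200.0)),
        "span_65": angular_coverage(MonitorSetup(537.0, 65.0, 200.0)),
    }
    spans["back_remainder"] = 360.0 - spans["span_65"]
    return spans


@dataclass
class Exp1Result:
    """Pooled first-detection angles and their histogram."""

    treatment: str
    orientation: str
    detections: np.ndarray
    histogram: DetectionHistogram
    n_presentations: int

    @property
    def response_rate(self) -> float:
        return self.detections.size / self.n_presentations

    @property
    def modal_magnitude(self) -> float:
        return self.histogram.magnitude_mode

    @property
    def span(self) -> float | None:
        return self.histogram.span


def run_virtual_exp1(treatment: str = "ALE", orientation: str = "forward",
                     n_spiders: int = 50, seed: int = 0,
                     bin_width: float = 5.0,
                     response_probability: float | None = None,
                     angles=MONITOR_ANGLES) -> Exp1Result:
    """Virtual visual-field-mapping experiment for one eye treatment.

    Every spider runs one 30-presentation trial per arena angle (120 and
    65 deg), as in the study; detections are pooled over spiders and
    angles.  ``orientation`` "backward" seats the spider facing away from
    the monitor junction.
    """
    root = np.random.default_rng(seed)
    overrides = {}
    if response_probability is not None:
        overrides["response_probability"] = response_probability
    params = default_params(treatment, **overrides)
    detections: list[float] = []
    n_presentations = 0
    for _ in range(n_spiders):
        for angle in angles:
            setup = MonitorSetup(537.0, angle, 200.0,
                                 orientation=orientation)
            sched = schedule_experiment(
                "exp1", seed=int(root.integers(2 ** 31)), setup=setup)
            trace, _ = simulate_trial(sched, params,
                                      seed=int(root.integers(2 ** 31)))
            detections.extend(score_exp1(trace, sched))
            n_presentations += len(sched.presentations)
    det = np.asarray(detections, dtype=float)
    hist = detection_histogram(det, bin_width) if det.size else None
    return Exp1Result(treatment, orientation, det, hist, n_presentations)


@dataclass
class Exp2ModelResult:
    """Model-driven experiment 2 under one eye configuration."""

    treatment: str
    first_pivot_toward_target: np.ndarray   # bool per presentation
    scores: np.ndarray                      # signed, amplitude-weighted

    @property
    def first_pivot_fraction(self) -> float:
        return float(self.first_pivot_toward_target.mean())

    @property
    def mean_score(self) -> float:
        return float(self.scores.mean()) if self.scores.size else 0.0


def run_model_exp2(treatment: str = "ALE", n_runs: int = 100,
                   n_presentations: int = 2, seed: int = 0,
                   exp2_start: float = 90.0, exp2_end: float = 10.0,
                   exp2_dwell: float | None = 50.0) -> Exp2ModelResult:
    """Run the integration model over seeded experiment-2 schedules.

    Returns, pooled over ``n_runs`` independent runs: whether the first
    pivot of each presentation went toward the biological-display side,
    and the signed amplitude-weighted scores of all pivots (positive =
    toward the biological side).
    """
    eyes = frozenset(treatment.split("+"))
    root = np.random.default_rng(seed)
    firsts: list[bool] = []
    scores: list[float] = []
    for _ in range(n_runs):
        # independent streams for stimulus randomisation and tie-breaking
        sched_seed = int(root.integers(2 ** 31))
        model_seed = int(root.integers(2 ** 31))
        sched = schedule_experiment(
            "exp2", seed=sched_seed, n_presentations=n_presentations,
            spec=StimulusSpec(seed=sched_seed),
            exp2_start=exp2_start, exp2_end=exp2_end,
            exp2_dwell=exp2_dwell)
        cfg = ModelConfig(active_eyes=eyes, seed=model_seed)
        decisions = run_model(sched, cfg)
        for i, d in first_decisions(decisions).items():
            side = 1 if sched.presentations[i].target_side == "right" else -1
            firsts.append((d.target_azimuth_deg > 0) == (side > 0))
        scores.extend(decision_scores(decisions, sched))
    return Exp2ModelResult(treatment, np.asarray(firsts, dtype=bool),
                           np.asarray(scores, dtype=float))
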