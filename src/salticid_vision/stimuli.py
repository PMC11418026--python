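"""Point-light-display and single-dot stimulus tracks, plus trial schedules.

All stimuli are expressed as :class:`AzimuthTrack` objects: per-frame,
per-dot spider-centric azimuths at a fixed frame rate (elevation is 0
throughout — stimuli are presented vertically in line with the animal).

Two stimulus families matter:

* a *biological* point-light display — a cloud of dots organised into rigid
  pairs whose within-pair angular separation never changes, riding on a
  common translation, with seeded pendular oscillation of the pairs about
  the moving centroid (a minimal articulated "walker");
* its *random* counterpart — same centroid path and same per-frame
  displacement-magnitude multiset, but with the non-translational component
  of each frame's displacements shuffled across dots, destroying all local
  structure.

The two experimental protocols are provided as seeded
:class:`TrialSchedule` builders: a single dot sweeping one monitor
(experiment 1) and mirrored left/right display pairs that pause at
+/-50 deg (experiment 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .geometry import MonitorSetup, angular_coverage, normalize_azimuth

__all__ = [
    "StimulusSpec",
    "AzimuthTrack",
    "Presentation",
    "TrialSchedule",
    "constant_speed_path",
    "exp2_path",
    "make_biological_pld",
    "make_random_pld",
    "make_single_dot",
    "make_rigid_shape",
    "make_exp2_pair",
    "schedule_experiment",
]

Kind = Literal["biological", "random", "single_dot", "rigid_shape"]

FRAME_RATE = 120.0          # camera / model frame rate, Hz
DEFAULT_SPEED = 9.0         # deg/s, the translation speed used in the study


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one stimulus.

    ``limb_amplitude_deg``/``limb_frequency_hz`` set the pendular pair
    oscillation of the biological walker.  ``n_dots`` must be even for the
    paired walker (default 6 → 3 rigid pairs).
    """

    kind: Kind = "biological"
    n_dots: int = 6
    translation_speed: float = DEFAULT_SPEED
    dot_width_deg: float = 4.0
    limb_amplitude_deg: float = 3.0
    limb_frequency_hz: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")
        if self.translation_speed < 0:
            raise ValueError("translation_speed must be >= 0")


@dataclass
class AzimuthTrack:
    """Per-frame azimuths of every dot of one stimulus.

    ``dots`` has shape (n_dots, n_frames), degrees.  All consumers treat the
    dot cloud's centroid as the stimulus position.
    """

    frame_rate: float
    dots: np.ndarray
    label: Kind
    elevation_deg: float = 0.0

    def __post_init__(self) -> None:
        self.dots = np.atleast_2d(np.asarray(self.dots, dtype=float))
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_dots(self) -> int:
        return self.dots.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dots.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def centroid(self) -> np.ndarray:
        return self.dots.mean(axis=0)

    def azimuth_at(self, t: float, t0: float = 0.0) -> float:
        """Centroid azimuth at absolute time ``t`` (track starts at ``t0``)."""
        idx = int(round((t - t0) * self.frame_rate))
        idx = min(max(idx, 0), self.n_frames - 1)
        return float(normalize_azimuth(self.centroid()[idx]))

    def mirrored(self) -> "AzimuthTrack":
        return AzimuthTrack(self.frame_rate, -self.dots, self.label,
                            self.elevation_deg)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time_s, dot_id, azimuth_deg, elevation_deg."""
        n_d, n_f = self.dots.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, n_d),
                "dot_id": np.tile(np.arange(n_d), n_f),
                "azimuth_deg": self.dots.T.ravel(),
                "elevation_deg": self.elevation_deg,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: Kind = "single_dot") -> "AzimuthTrack":
        df = pd.read_csv(path)
        n_d = int(df["dot_id"].max()) + 1
        dots = df.pivot(index="dot_id", columns="time_s",
                        values="azimuth_deg").to_numpy()
        times = np.sort(df["time_s"].unique())
        fr = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else FRAME_RATE
        return cls(round(fr, 6), dots, label,
                   float(df["elevation_deg"].iloc[0]))


# ---------------------------------------------------------------------------
# Centroid paths
# ---------------------------------------------------------------------------

def constant_speed_path(start: float, end: float, speed: float,
                        frame_rate: float = FRAME_RATE) -> np.ndarray:
    """Azimuths moving from ``start`` to ``end`` at ``speed`` deg/s."""
    if start == end:
        raise ValueError("start and end azimuths are equal: empty trajectory")
    if speed <= 0:
        raise ValueError("speed must be > 0")
    duration = abs(end - start) / speed
    n = int(np.floor(duration * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    path = start + np.sign(end - start) * speed * t
    if abs(path[-1] - end) > 1e-9:      # close the sweep on the exact endpoint
        path = np.append(path, end)
    return path


def exp2_path(side: int, direction: str = "inward", start: float = 90.0,
              end: float = 10.0, dwell_azimuth: float | None = 50.0,
              dwell_s: float = 1.0, speed: float = DEFAULT_SPEED,
              frame_rate: float = FRAME_RATE) -> np.ndarray:
    """Centroid path for one side of an experiment-2 pair.

    ``side`` is +1 (right) or -1 (left).  The display travels between
    ``start`` and ``end`` deg (eccentricities) at ``speed``, pausing for
    ``dwell_s`` seconds at ``dwell_azimuth`` if given.  ``direction``
    "inward" goes start→end, "outward" end→start.
    """
    if direction not in ("inward", "outward"):
        raise ValueError("direction must be 'inward' or 'outward'")
    a0, a1 = (start, end) if direction == "inward" else (end, start)
    if dwell_azimuth is None or not (min(a0, a1) < dwell_azimuth < max(a0, a1)):
        path = constant_speed_path(a0, a1, speed, frame_rate)
        return side * path
    t_leg1 = abs(dwell_azimuth - a0) / speed
    t_leg2 = abs(a1 - dwell_azimuth) / speed
    total = t_leg1 + dwell_s + t_leg2
    n = int(np.floor(total * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    sgn = np.sign(a1 - a0)
    path = np.where(
        t <= t_leg1,
        a0 + sgn * speed * t,
        np.where(
            t <= t_leg1 + dwell_s,
            dwell_azimuth,
            dwell_azimuth + sgn * speed * (t - t_leg1 - dwell_s),
        ),
    )
    if abs(path[-1] - a1) > 1e-9:
        path = np.append(path, a1)
    return side * path


# ---------------------------------------------------------------------------
# Stimulus constructors
# ---------------------------------------------------------------------------

def make_biological_pld(spec: StimulusSpec, path: np.ndarray | None = None,
                        frame_rate: float = FRAME_RATE) -> AzimuthTrack:
    """Articulated-walker point-light display along a centroid ``path``.

    Dots are organised into rigid pairs: each pair's two dots keep an exactly
    constant angular separation for the whole track while the pair centre
    oscillates pendularly about the translating cloud centroid.  The
    oscillation is mean-corrected each frame so the cloud centroid equals
    ``path`` exactly.  Deterministic given ``spec.seed``.
    """
    if spec.n_dots < 2:
        raise ValueError("biological structure undefined for n_dots < 2")
    if spec.n_dots % 2:
        raise ValueError("paired walker requires an even n_dots")
    if path is None:
        path = constant_speed_path(90.0, 10.0, spec.translation_speed,
                                   frame_rate)
    path = np.asarray(path, dtype=float)
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_dots // 2
    t = np.arange(path.size) / frame_rate

    # static layout: pair centres spread around the centroid, seeded jitter
    offsets = np.linspace(-4.0, 4.0, n_pairs) + rng.uniform(-0.5, 0.5, n_pairs)
    offsets -= offsets.mean()
    separations = rng.uniform(2.0, 4.0, n_pairs)          # within-pair, deg
    phases = 2.0 * np.pi * np.arange(n_pairs) / n_pairs + rng.uniform(
        0.0, 2.0 * np.pi)

    osc = spec.limb_amplitude_deg * np.sin(
        2.0 * np.pi * spec.limb_frequency_hz * t[None, :] + phases[:, None])
    osc -= osc.mean(axis=0, keepdims=True)                # exact centroid
    centers = path[None, :] + offsets[:, None] + osc      # (n_pairs, T)

    dots = np.empty((spec.n_dots, path.size))
    dots[0::2] = centers - separations[:, None] / 2.0
    dots[1::2] = centers + separations[:, None] / 2.0
    return AzimuthTrack(frame_rate, dots, "biological")


def make_random_pld(template: AzimuthTrack, seed: int = 0) -> AzimuthTrack:
    """Scramble a biological display's local motion, keeping global motion.

    Per frame, the residual (non-translational) displacements are permuted
    across dots with a seeded RNG.  This preserves the centroid path exactly
    and the per-frame displacement-magnitude multiset exactly, while pairwise
    distances diffuse — fully incoherent local motion.
    """
    if template.label != "biological":
        raise ValueError("template must be a biological track")
    rng = np.random.default_rng(seed)
    disp = np.diff(template.dots, axis=1)                 # (n_dots, T-1)
    common = disp.mean(axis=0, keepdims=True)             # centroid steps
    resid = disp - common
    scrambled = np.empty_like(resid)
    n_d = template.n_dots
    for f in range(resid.shape[1]):
        scrambled[:, f] = resid[rng.permutation(n_d), f]
    new_disp = common + scrambled
    dots = np.concatenate(
        [template.dots[:, :1],
         template.dots[:, :1] + np.cumsum(new_disp, axis=1)], axis=1)
    return AzimuthTrack(template.frame_rate, dots, "random",
                        template.elevation_deg)


def make_single_dot(spec: StimulusSpec, start: float, end: float,
                    frame_rate: float = FRAME_RATE) -> AzimuthTrack:
    """Single dot sweeping from ``start`` to ``end`` at the spec's speed."""
    path = constant_speed_path(start, end, spec.translation_speed, frame_rate)
    return AzimuthTrack(frame_rate, path[None, :], "single_dot")


_SHAPE_LAYOUTS = {
    # rigid dot contours standing in for the silhouette and ellipse images;
    # identical in everything the 1-D azimuthal model can perceive
    "silhouette": np.array([-4.0, -2.5, -1.0, 0.5, 2.0, 3.5]),
    "ellipse": np.array([-4.0, -2.4, -0.8, 0.8, 2.4, 4.0]),
}


def make_rigid_shape(spec: StimulusSpec, path: np.ndarray | None = None,
                     shape: str = "silhouette",
                     frame_rate: float = FRAME_RATE) -> AzimuthTrack:
    """Rigid coherent dot contour translating along ``path``.

    Both shapes are, by construction, identical to the motion model: shape
    differences are a principal-eye (AME) matter, outside this model's scope.
    """
    if shape not in _SHAPE_LAYOUTS:
        raise ValueError(f"unknown shape {shape!r}")
    if path is None:
        path = constant_speed_path(90.0, 10.0, spec.translation_speed,
                                   frame_rate)
    path = np.asarray(path, dtype=float)
    dots = path[None, :] + _SHAPE_LAYOUTS[shape][:, None]
    return AzimuthTrack(frame_rate, dots, "rigid_shape")


def make_exp2_pair(spec: StimulusSpec, direction: str = "inward",
                   biological_side: str = "left", start: float = 90.0,
                   end: float = 10.0, dwell_azimuth: float | None = 50.0,
                   dwell_s: float = 1.0, condition: str = "dots",
                   frame_rate: float = FRAME_RATE,
                   ) -> tuple[AzimuthTrack, AzimuthTrack]:
    """Mirrored left/right stimulus pair for experiment 2.

    Returns ``(left_track, right_track)``.  In the "dots" condition one side
    carries the biological display and the other its scrambled counterpart;
    in the "shapes" condition the silhouette contour replaces the biological
    display and the ellipse contour the random one.  Centroid paths of the
    two sides are exact mirror images frame by frame.
    """
    if biological_side not in ("left", "right"):
        raise ValueError("biological_side must be 'left' or 'right'")
    sides = {"left": -1, "right": 1}
    paths = {
        s: exp2_path(sgn, direction, start, end, dwell_azimuth, dwell_s,
                     spec.translation_speed, frame_rate)
        for s, sgn in sides.items()
    }
    other = "right" if biological_side == "left" else "left"
    if condition == "dots":
        bio = make_biological_pld(spec, paths[biological_side], frame_rate)
        template = make_biological_pld(spec, paths[other], frame_rate)
        rnd = make_random_pld(template, seed=spec.seed + 1)
        tracks = {biological_side: bio, other: rnd}
    elif condition == "shapes":
        sil = make_rigid_shape(spec, paths[biological_side], "silhouette",
                               frame_rate)
        ell = make_rigid_shape(spec, paths[other], "ellipse", frame_rate)
        tracks = {biological_side: sil, other: ell}
    else:
        raise ValueError("condition must be 'dots' or 'shapes'")
    return tracks["left"], tracks["right"]


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Presentation:
    """One stimulus presentation within a trial.

    ``tracks`` maps side ("left"/"right") to the track shown there;
    experiment 1 uses a single side.  ``types`` records the stimulus kind per
    side, ``target_side`` the side of the biological/silhouette stimulus (or
    of the single dot).
    """

    onset_s: float
    tracks: dict[str, AzimuthTrack]
    types: dict[str, str]
    direction: str
    target_side: str

    @property
    def duration_s(self) -> float:
        return max(tr.duration_s for tr in self.tracks.values())

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class TrialSchedule:
    habituation_s: float
    presentations: list[Presentation]
    inter_stimulus_s: float
    frame_rate: float = FRAME_RATE
    protocol: str = "exp1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ends = [p.offset_s for p in self.presentations]
        starts = [p.onset_s for p in self.presentations]
        for e, s in zip(ends[:-1], starts[1:]):
            if s < e:
                raise ValueError("presentations overlap in time")

    @property
    def duration_s(self) -> float:
        if not self.presentations:
            return self.habituation_s
        return self.presentations[-1].offset_s + self.inter_stimulus_s

    def manifest(self) -> dict:
        return {
            "protocol": self.protocol,
            "habituation_s": self.habituation_s,
            "inter_stimulus_s": self.inter_stimulus_s,
            "frame_rate": self.frame_rate,
            "meta": self.meta,
            "presentations": [
                {
                    "onset_s": p.onset_s,
                    "duration_s": p.duration_s,
                    "direction": p.direction,
                    "target_side": p.target_side,
                    "types": p.types,
                    "sides": sorted(p.tracks),
                }
                for p in self.presentations
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def schedule_experiment(protocol: str, seed: int = 0,
                        setup: MonitorSetup | None = None,
                        spec: StimulusSpec | None = None,
                        n_presentations: int | None = None,
                        habituation_s: float = 210.0,
                        condition: str = "dots",
                        exp2_start: float = 90.0, exp2_end: float = 10.0,
                        exp2_dwell: float | None = 50.0,
                        frame_rate: float = FRAME_RATE) -> TrialSchedule:
    """Build a seeded trial schedule for either protocol.

    Experiment 1: ``n_presentations`` (default 30) single-dot sweeps across
    one monitor, 15-s inter-stimulus interval, side and direction randomised.
    Experiment 2: 20 mirrored display-pair repetitions, 25-s interval, the
    biological side and movement direction randomised per repetition.
    """
    rng = np.random.default_rng(seed)
    setup = setup or MonitorSetup()
    spec = spec or StimulusSpec(seed=seed)
    cov = angular_coverage(setup)
    presentations: list[Presentation] = []

    if protocol == "exp1":
        n = 30 if n_presentations is None else n_presentations
        isi = 15.0
        half = cov / 2.0
        lo, hi = (0.0, half) if setup.orientation == "forward" \
            else (180.0 - half, 180.0)
        t = habituation_s
        for _ in range(n):
            side = rng.choice(["left", "right"])
            direction = rng.choice(["outward", "inward"])
            # side names follow the spider frame: "right" = positive azimuths
            sgn = 1.0 if side == "right" else -1.0
            a_in, a_out = sgn * lo, sgn * hi
            start, end = (a_in, a_out) if direction == "outward" \
                else (a_out, a_in)
            track = make_single_dot(spec, start, end, frame_rate)
            presentations.append(
                Presentation(t, {side: track}, {side: "single_dot"},
                             direction, side))
            t += track.duration_s + isi
        sched = TrialSchedule(habituation_s, presentations, isi, frame_rate,
                              "exp1",
                              {"setup_angle": setup.inter_panel_angle_deg,
                               "orientation": setup.orientation, "seed": seed})
    elif protocol == "exp2":
        n = 20 if n_presentations is None else n_presentations
        isi = 25.0
        t = habituation_s
        for k in range(n):
            bio_side = rng.choice(["left", "right"])
            direction = rng.choice(["inward", "outward"])
            pair_spec = replace(spec, seed=int(rng.integers(2 ** 31)))
            left, right = make_exp2_pair(
                pair_spec, direction, bio_side, exp2_start, exp2_end,
                exp2_dwell, condition=condition, frame_rate=frame_rate)
            types = {"left": left.label, "right": right.label}
            presentations.append(
                Presentation(t, {"left": left, "right": right}, types,
                             direction, bio_side))
            t += left.duration_s + isi
        sched = TrialSchedule(habituation_s, presentations, isi, frame_rate,
                              "exp2",
                              {"setup_angle": setup.inter_panel_angle_deg,
                               "condition": condition, "seed": seed})
    else:
        raise ValueError("protocol must be 'exp1' or 'exp2'")

    half = cov / 2.0 + 1e-6
    for p in sched.presentations:
        for tr in p.tracks.values():
            rel = np.abs(normalize_azimuth(tr.dots)) if \
                setup.orientation == "forward" else \
                np.abs(normalize_azimuth(tr.dots + 180.0))
            if rel.max() > half + spec.limb_amplitude_deg + 5.0:
                raise ValueError("generated track exceeds monitor coverage")
    return sched
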