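"""Three-layer multi-eye integration model of pivot decisions.

The model formalises how a jumping spider's secondary eyes could jointly
decide where to pivot, using only early, eye-specific circuitry:

* **Layer 1** — photoreceptor occupancy: per active eye, per azimuth bin,
  the number of stimulus dots falling inside that eye's visual field.
* **Layer 2** — eye-specific motion detectors.  PL1 (the PLE stream) is a
  *global motion* detector: it fires at the receptive-field bin under a dot
  group whose centroid has displaced enough over a sliding window — it
  cannot tell biological from scrambled motion.  AL1 (the ALE stream) is
  additionally tuned to *local coherency*: it fires only when the dots in
  the group keep mutually fixed distances (each dot has a near-rigid
  partner), which biological displays do and scrambled ones do not.  A lone
  dot is vacuously coherent.
* **Layer 3** — per-bin comparator cells acting as XOR gates, receiving
  direct input from their own layer-2 bin and delayed (by τ) input from the
  neighbouring bins, in the manner of a Hassenstein–Reichardt detector one
  stage removed from the retina.  A stimulus tracked smoothly across
  neighbouring bins keeps each gate silent (direct and delayed inputs
  agree); appearances, disappearances, stops, starts and detector
  mismatches (a scrambled display crossing from the PLE field into the
  AL1-silent ALE field) fire the gates.

A pivot is made toward the azimuth bin with the highest summed XOR
activity; exact ties — e.g. mirrored stimuli seen only by the PLEs — are
broken uniformly at random, and targets already inside the frontal dead
zone (≈ the principal-eye field) trigger no pivot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .geometry import EyeFieldMap, in_field_array, normalize_azimuth
from .stimuli import AzimuthTrack, TrialSchedule

__all__ = [
    "ModelConfig",
    "MODEL_EYE_FIELDS",
    "LayerState",
    "PivotDecision",
    "project",
    "pl1_response",
    "al1_response",
    "xor_layer",
    "decide_pivot",
    "run_model",
    "decision_scores",
]

REFERENCE_SPEED = 9.0  # deg/s; stimulus speed the delay line is tuned to

# Contiguous model fields: the behavioural estimates put the ALE edge at
# ±50 and the PLE inner edge at ±60 deg; the integration mechanism requires
# the two detector sheets to tile the azimuth without a seam, so the model
# places the shared boundary at ±54 deg (a bin edge).
MODEL_EYE_FIELDS = EyeFieldMap(fields={
    "ALE": ((-54.0, 54.0),),
    "PLE": ((-180.0, -54.0), (54.0, 180.0)),
    "AME": (),
    "PME": (),
})


@dataclass(frozen=True)
class ModelConfig:
    """Tunable parameters of the integration model.

    ``bin_width_deg`` sets the layer-2/3 receptive-field spacing; ``tau_s``
    is the delay of the neighbour connections (default: the time the
    reference stimulus takes to traverse one bin, bin_width/9 s, making a
    smoothly tracked stimulus exactly cancel at the gates).  ``window_s``
    is the sliding window over which layer 2 evaluates motion and
    coherency.  ``dead_zone_deg`` is the frontal sector (≈ AME field)
    within which no orienting pivot is produced.
    """

    eye_field_map: EyeFieldMap = field(default_factory=lambda: MODEL_EYE_FIELDS)
    active_eyes: frozenset[str] = frozenset({"ALE", "PLE"})
    bin_width_deg: float = 6.0
    tau_s: float | None = None
    window_s: float = 1.0 / 3.0
    coherency_threshold_deg: float = 0.1
    motion_threshold_deg: float = 1.0
    activation_threshold: float = 0.5
    dead_zone_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width_deg <= 0:
            raise ValueError("bin_width_deg must be > 0")
        if 360.0 % self.bin_width_deg > 1e-9:
            raise ValueError("bin_width_deg must divide 360")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be > 0")
        for name in ("coherency_threshold_deg", "motion_threshold_deg",
                     "dead_zone_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.active_eyes) - set(self.eye_field_map.fields)
        if unknown:
            raise ValueError(f"active_eyes not in field map: {sorted(unknown)}")

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_width_deg))

    def tau_frames(self, frame_rate: float) -> int:
        tau = self.tau_s if self.tau_s is not None else \
            self.bin_width_deg / REFERENCE_SPEED
        return max(1, int(round(tau * frame_rate)))

    def window_frames(self, frame_rate: float) -> int:
        return max(2, int(round(self.window_s * frame_rate)))

    def bin_of(self, az) -> np.ndarray:
        """Bin index of azimuth(s); bins are edge-aligned to multiples of
        the bin width, circular over (-180, 180]."""
        a = normalize_azimuth(np.asarray(az, dtype=float))
        # nudge exact bin edges toward zero so binning is mirror-symmetric
        a = a - 1e-9 * np.sign(a)
        k = np.floor((a + 180.0) / self.bin_width_deg).astype(int)
        return np.mod(k, self.n_bins)

    def bin_centers(self) -> np.ndarray:
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width_deg

    def bin_eyes(self) -> dict[str, np.ndarray]:
        """Boolean mask per eye over bins (bin midpoint in the eye field)."""
        centers = self.bin_centers()
        return {
            eye: in_field_array(self.eye_field_map, eye, centers)
            for eye in self.active_eyes
        }


@dataclass
class LayerState:
    """Per-timestep activations of the three layers for one presentation.

    ``layer1`` maps eye → (T, n_bins) dot-occupancy counts; ``layer2`` is
    the combined binary detector sheet (T, n_bins); ``layer3`` the binary
    XOR-gate output (T, n_bins).
    """

    layer1: dict[str, np.ndarray]
    layer2: np.ndarray
    layer3: np.ndarray


@dataclass(frozen=True)
class PivotDecision:
    """A pivot command emitted by the model."""

    time_s: float
    direction: Literal["clockwise", "counterclockwise"]
    target_azimuth_deg: float
    trigger: Literal["appearance", "disappearance", "direction_change",
                     "tie_random"]
    presentation_index: int = 0


# ---------------------------------------------------------------------------
# Layer 1
# ---------------------------------------------------------------------------

def project(tracks: Sequence[AzimuthTrack],
            config: ModelConfig) -> dict[str, np.ndarray]:
    """Layer-1 occupancy: per active eye, (T, n_bins) dot counts.

    Dots outside an eye's field contribute nothing to that eye.
    """
    if not config.active_eyes:
        raise ValueError("no active eyes")
    if isinstance(tracks, AzimuthTrack):
        tracks = [tracks]
    T = max((tr.n_frames for tr in tracks), default=0)
    out = {eye: np.zeros((T, config.n_bins)) for eye in config.active_eyes}
    for tr in tracks:
        bins = config.bin_of(tr.dots)                        # (n_dots, T)
        tt = np.broadcast_to(np.arange(tr.n_frames), bins.shape)
        for eye in config.active_eyes:
            vis = in_field_array(config.eye_field_map, eye, tr.dots)
            np.add.at(out[eye], (tt[vis], bins[vis]), 1.0)
    return out


# ---------------------------------------------------------------------------
# Layer 2 — reference (windowed) operations
# ---------------------------------------------------------------------------

def _group_motion(dot_window: np.ndarray, threshold: float) -> bool:
    """Has the dot-group centroid displaced at least ``threshold`` deg?"""
    c = dot_window.mean(axis=0)
    return bool(abs(c[-1] - c[0]) >= threshold)


def _group_coherent(dot_window: np.ndarray, threshold: float) -> bool:
    """Local coherency: at least half the dots have a near-rigid partner.

    A partner is near-rigid when the std of the pairwise distance over the
    window is below ``threshold``.  A single dot is vacuously coherent.
    """
    n = dot_window.shape[0]
    if n == 1:
        return True
    rigid = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.std(dot_window[i] - dot_window[j]) < threshold:
                rigid[i] = rigid[j] = True
    return bool(rigid.sum() >= 0.5 * n)


def _l2_bin(dot_window: np.ndarray, config: ModelConfig,
            eye: str) -> int | None:
    """Receptive-field bin of the group (centroid), or None if outside."""
    c = float(dot_window.mean(axis=0)[-1])
    k = int(config.bin_of(c))
    return k if config.bin_eyes().get(eye, np.zeros(0, bool))[k] else None


def pl1_response(dot_window: np.ndarray, config: ModelConfig) -> np.ndarray:
    """PL1 (global-motion) activation for one dot group, (n_bins,) binary.

    Fires at the group-centroid bin iff the centroid displaced at least the
    motion threshold over the window and the bin lies in the PLE field.
    Blind to local structure: a biological display and its scrambled twin
    (which share the centroid path) produce identical PL1 activation.
    """
    dot_window = np.atleast_2d(np.asarray(dot_window, dtype=float))
    if dot_window.shape[1] < 2:
        raise ValueError("window must span at least 2 timesteps")
    out = np.zeros(config.n_bins, dtype=bool)
    if "PLE" not in config.active_eyes:
        return out
    if not _group_motion(dot_window, config.motion_threshold_deg):
        return out
    k = _l2_bin(dot_window, config, "PLE")
    if k is not None:
        out[k] = True
    return out


def al1_response(dot_window: np.ndarray, config: ModelConfig) -> np.ndarray:
    """AL1 (local-coherency) activation for one dot group, (n_bins,) binary.

    Fires like PL1 but only when the group is locally coherent; scrambled
    displays therefore never drive AL1.
    """
    dot_window = np.atleast_2d(np.asarray(dot_window, dtype=float))
    if dot_window.shape[1] < 2:
        raise ValueError("window must span at least 2 timesteps")
    out = np.zeros(config.n_bins, dtype=bool)
    if "ALE" not in config.active_eyes:
        return out
    if not _group_motion(dot_window, config.motion_threshold_deg):
        return out
    if not _group_coherent(dot_window, config.coherency_threshold_deg):
        return out
    k = _l2_bin(dot_window, config, "ALE")
    if k is not None:
        out[k] = True
    return out


# ---------------------------------------------------------------------------
# Layer 2 — vectorised track series (same definitions, full time axis)
# ---------------------------------------------------------------------------

def _sliding_std(x: np.ndarray, w: int) -> np.ndarray:
    """Rolling std over trailing windows of length ``w`` along axis -1."""
    c1 = np.cumsum(np.insert(x, 0, 0.0, axis=-1), axis=-1)
    c2 = np.cumsum(np.insert(x * x, 0, 0.0, axis=-1), axis=-1)
    s1 = c1[..., w:] - c1[..., :-w]
    s2 = c2[..., w:] - c2[..., :-w]
    var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
    return np.sqrt(var)


def layer2_series(track: AzimuthTrack, config: ModelConfig) -> np.ndarray:
    """Combined layer-2 sheet (T, n_bins) for one stimulus track.

    Vectorised application of :func:`pl1_response` / :func:`al1_response`
    over trailing windows; activation starts once a full window of history
    exists.
    """
    T = track.n_frames
    w = config.window_frames(track.frame_rate)
    out = np.zeros((T, config.n_bins), dtype=bool)
    if T < w:
        return out
    c = track.centroid()
    moving = np.zeros(T, dtype=bool)
    moving[w - 1:] = np.abs(c[w - 1:] - c[:T - w + 1]) >= \
        config.motion_threshold_deg

    n = track.n_dots
    if n == 1:
        coherent = np.ones(T, dtype=bool)
    else:
        pairs_i, pairs_j = np.triu_indices(n, k=1)
        dist = track.dots[pairs_i] - track.dots[pairs_j]   # (n_pairs, T)
        std = _sliding_std(dist, w)                        # (n_pairs, T-w+1)
        rigid_pair = std < config.coherency_threshold_deg
        rigid_dot = np.zeros((n, T - w + 1), dtype=bool)
        np.logical_or.at(rigid_dot, pairs_i, rigid_pair)
        np.logical_or.at(rigid_dot, pairs_j, rigid_pair)
        coherent = np.zeros(T, dtype=bool)
        coherent[w - 1:] = rigid_dot.sum(axis=0) >= 0.5 * n

    bins = config.bin_of(c)
    eye_masks = config.bin_eyes()
    active = np.zeros(T, dtype=bool)
    if "PLE" in eye_masks:
        active |= moving & eye_masks["PLE"][bins]
    if "ALE" in eye_masks:
        active |= moving & coherent & eye_masks["ALE"][bins]
    out[np.nonzero(active)[0], bins[active]] = True
    return out


# ---------------------------------------------------------------------------
# Layer 3
# ---------------------------------------------------------------------------

def _dilate(x: np.ndarray) -> np.ndarray:
    """OR over each bin and its two circular neighbours."""
    return x | np.roll(x, 1, axis=-1) | np.roll(x, -1, axis=-1)


def xor_layer(direct: np.ndarray, delayed: np.ndarray) -> np.ndarray:
    """Comparator gates: fire where exactly one of {direct input, delayed
    neighbouring input} is active.

    ``direct`` is the layer-2 sheet at time t, ``delayed`` the sheet at
    t - τ; both (..., n_bins) binary, circular in the bin axis.  A gate
    fires when its direct input is active with no delayed activity in its
    one-bin neighbourhood (an appearance), or when its delayed input is
    active with no direct activity in the neighbourhood (a disappearance).
    A stimulus tracked smoothly across neighbouring bins — at most one bin
    per τ — satisfies neither condition and keeps every gate silent.
    """
    direct = np.asarray(direct, dtype=bool)
    delayed = np.asarray(delayed, dtype=bool)
    appear = direct & ~_dilate(delayed)
    disappear = delayed & ~_dilate(direct)
    return appear | disappear


def xor_series(l2: np.ndarray, tau: int) -> np.ndarray:
    """Apply :func:`xor_layer` along time with delay ``tau`` frames.

    Before τ frames of history exist the delayed input is silent, so
    stimuli present at trial start register as appearances.
    """
    T = l2.shape[0]
    delayed = np.zeros_like(l2)
    if T > tau:
        delayed[tau:] = l2[:-tau]
    return xor_layer(l2, delayed)


# ---------------------------------------------------------------------------
# Decision
# ---------------------------------------------------------------------------

def decide_pivot(activity: np.ndarray, config: ModelConfig,
                 rng: np.random.Generator | None = None,
                 time_s: float = 0.0, presentation_index: int = 0,
                 trigger_hint: str | None = None) -> PivotDecision | None:
    """Pivot toward the bin with maximal summed XOR activity.

    ``activity`` is (n_bins,) or (T, n_bins).  Exact ties are broken
    uniformly at random (seeded).  Returns None when there is no activity
    or the winning bin lies inside the frontal dead zone.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    act = np.asarray(activity, dtype=float)
    if act.ndim == 2:
        act = act.sum(axis=0)
    act = act.copy()
    centers = config.bin_centers()
    act[np.abs(centers) <= config.dead_zone_deg] = 0.0
    if act.max() <= 0:
        return None
    best = np.nonzero(act == act.max())[0]
    tied = best.size > 1
    k = int(best[rng.integers(best.size)]) if tied else int(best[0])
    target = float(centers[k])
    direction = "clockwise" if target > 0 else "counterclockwise"
    if target == 0.0:
        direction = "clockwise" if rng.random() < 0.5 else "counterclockwise"
    trigger = "tie_random" if tied else (trigger_hint or "appearance")
    return PivotDecision(time_s, direction, target, trigger,
                         presentation_index)


def _burst_trigger(direct_only: float, delayed_only: float) -> str:
    if direct_only > 0 and delayed_only > 0:
        return "direction_change"
    return "appearance" if direct_only >= delayed_only else "disappearance"


def run_model(schedule: TrialSchedule, config: ModelConfig,
              return_states: bool = False):
    """Run the full model over a trial schedule.

    For each presentation: project the tracks, build the layer-2 detector
    sheet, apply the delayed XOR comparison, and emit one
    :class:`PivotDecision` per contiguous burst of gate activity (the first
    decision per presentation is the analysed orienting response).
    Deterministic given ``config.seed``.

    Returns the decision list, plus per-presentation :class:`LayerState`
    objects when ``return_states`` is set.
    """
    rng = np.random.default_rng(config.seed)
    decisions: list[PivotDecision] = []
    states: list[LayerState] = []
    for pi, pres in enumerate(schedule.presentations):
        tracks = list(pres.tracks.values())
        fr = tracks[0].frame_rate
        tau = config.tau_frames(fr)
        # pad beyond stimulus offset so end-of-presentation disappearances
        # reach the delayed comparison (the inter-stimulus gap is far longer)
        pad = tau + config.window_frames(fr)
        l2 = np.zeros((max(tr.n_frames for tr in tracks) + pad,
                       config.n_bins), dtype=bool)
        for tr in tracks:
            sheet = layer2_series(tr, config)
            l2[:sheet.shape[0]] |= sheet
        gates = xor_series(l2, tau)

        if return_states:
            states.append(LayerState(project(tracks, config), l2, gates))

        # classify gate causes for trigger labelling
        delayed = np.zeros_like(l2)
        if l2.shape[0] > tau:
            delayed[tau:] = l2[:-tau]
        direct_only = l2 & ~_dilate(delayed)
        delayed_only = delayed & ~_dilate(l2)

        any_on = gates.any(axis=1)
        if not any_on.any():
            continue
        starts = list(np.flatnonzero(any_on[1:] & ~any_on[:-1]) + 1)
        if any_on[0]:
            starts.insert(0, 0)
        ends = list(np.flatnonzero(any_on[:-1] & ~any_on[1:]) + 1)
        if any_on[-1]:
            ends.append(any_on.size)
        for t0, t1 in zip(starts, ends):
            act = gates[t0:t1].sum(axis=0)
            hint = _burst_trigger(
                float(direct_only[t0:t1].sum()),
                float(delayed_only[t0:t1].sum()))
            dec = decide_pivot(act, config, rng,
                               time_s=pres.onset_s + t0 / fr,
                               presentation_index=pi, trigger_hint=hint)
            if dec is not None:
                decisions.append(dec)
    if return_states:
        return decisions, states
    return decisions


def decision_scores(decisions: Sequence[PivotDecision],
                    schedule: TrialSchedule) -> np.ndarray:
    """Signed pivot values: +|target| toward the biological/silhouette side.

    The pivot magnitude is the target eccentricity (the spider turns to
    face the target), so decisions toward nearby targets weigh less —
    matching how the treadmill scoring weighs rotation speed.
    """
    vals = []
    for d in decisions:
        pres = schedule.presentations[d.presentation_index]
        side_sign = 1 if pres.target_side == "right" else -1
        dec_sign = 1 if d.target_azimuth_deg > 0 else -1
        vals.append(abs(d.target_azimuth_deg) *
                    (1 if dec_sign == side_sign else -1))
    return np.asarray(vals, dtype=float)


def first_decisions(decisions: Sequence[PivotDecision]
                    ) -> dict[int, PivotDecision]:
    """First decision per presentation index."""
    out: dict[int, PivotDecision] = {}
    for d in decisions:
        if d.presentation_index not in out:
            out[d.presentation_index] = d
    return out


def ablate(config: ModelConfig, *eyes: str) -> ModelConfig:
    """Config with ``eyes`` removed from the active set."""
    return replace(config, active_eyes=config.active_eyes - set(eyes))
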