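"""Spherical-treadmill rotation scoring.

A tethered spider walking on an air-suspended sphere expresses intended
body rotations as sphere rotations of the *opposite* sign.  The pipeline
mirrors the study's scoring: per-frame sphere rotations (FicTrac-style) →
z-axis angular-velocity series → velocity peaks with signed areas → either
the stimulus azimuth at first direction-consistent detection (experiment 1)
or a signed preference statistic over all peaks (experiment 2), with
seeded permutation/bootstrap inference in place of mixed-model fits.

Sign conventions, applied in exactly one place each:

* the z-velocity series is **sphere-frame**: positive = clockwise sphere
  rotation (seen from above);
* scoring operations convert to the spider's intended rotation by negating
  the sphere sign, so a positive-azimuth (right-side) stimulus should
  produce *negative* sphere peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

from .geometry import normalize_azimuth
from .stimuli import Presentation, TrialSchedule

__all__ = [
    "RotationTrace",
    "PivotPeak",
    "PeakParams",
    "PreferenceResult",
    "DetectionHistogram",
    "read_rotation_trace",
    "write_rotation_trace",
    "z_rotation_series",
    "detect_peaks",
    "first_detection",
    "assign_presentations",
    "signed_scores",
    "preference_statistic",
    "detection_histogram",
]


@dataclass
class RotationTrace:
    """Per-frame sphere rotation about the z axis.

    ``z_increments_deg`` holds the frame-to-frame rotation angle (deg/frame),
    positive = clockwise seen from above.
    """

    frame_rate: float = 120.0
    z_increments_deg: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    source: str = "recorded"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        self.z_increments_deg = np.asarray(self.z_increments_deg, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.z_increments_deg.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class PivotPeak:
    """One detected rotation event.

    ``signed_area`` is the area under the z-velocity curve between onset and
    offset (deg of sphere rotation); its sign is the rotation direction in
    the sphere frame.
    """

    onset_s: float
    offset_s: float
    signed_area_deg: float
    peak_velocity: float  # deg/s, signed, sphere frame

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")

    @property
    def spider_direction(self) -> int:
        """+1 = spider turned right (clockwise), -1 = left.

        The spider's intended rotation is opposite to the sphere's.
        """
        return -int(np.sign(self.signed_area_deg))


@dataclass(frozen=True)
class PeakParams:
    """Peak-finder settings (moving-average smoothing, velocity threshold)."""

    smooth_frames: int = 5
    height_deg_s: float = 10.0

    def __post_init__(self) -> None:
        if self.smooth_frames < 1:
            raise ValueError("smooth_frames must be >= 1")
        if self.height_deg_s <= 0:
            raise ValueError("height_deg_s must be > 0")


# ---------------------------------------------------------------------------
# FicTrac-style I/O
# ---------------------------------------------------------------------------

_MATRIX_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)]


def write_rotation_trace(trace: RotationTrace, path,
                         dialect: str = "z") -> None:
    """Write a trace as CSV in the ``z`` or ``matrix`` dialect."""
    if dialect == "z":
        df = pd.DataFrame({
            "frame": np.arange(trace.n_frames),
            "z_increment_deg": trace.z_increments_deg,
        })
    elif dialect == "matrix":
        rots = Rotation.from_euler(
            "z", -trace.z_increments_deg[:, None], degrees=True)
        mats = rots.as_matrix().reshape(-1, 9)
        df = pd.DataFrame(mats, columns=_MATRIX_COLS)
        df.insert(0, "frame", np.arange(trace.n_frames))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False)


def _z_from_matrices(mats: np.ndarray) -> np.ndarray:
    """Per-frame z rotation (deg) from frame-to-frame rotation matrices.

    Matrices map lab to sphere axes with z up; a positive mathematical
    rotation about +z is counterclockwise seen from above, so the clockwise
    -positive increment is the negated z Euler angle.
    """
    errs = np.abs(mats @ np.transpose(mats, (0, 2, 1)) -
                  np.eye(3)).max(axis=(1, 2))
    if (errs > 1e-6).any():
        warnings.warn(
            f"{int((errs > 1e-6).sum())} non-orthonormal rotation matrices; "
            "renormalizing via SVD", stacklevel=2)
        u, _, vt = np.linalg.svd(mats)
        mats = u @ vt
    ang = Rotation.from_matrix(mats).as_euler("zyx", degrees=True)[:, 0]
    return -ang


def read_rotation_trace(path, dialect: str = "auto",
                        frame_rate: float = 120.0) -> RotationTrace:
    """Read a FicTrac-style CSV trace.

    ``dialect`` is ``"z"`` (columns frame, z_increment_deg), ``"matrix"``
    (frame, r00..r22) or ``"auto"`` (sniff from the header).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"could not parse {path}: {exc}") from exc
    cols = set(df.columns)
    if dialect == "auto":
        dialect = "matrix" if set(_MATRIX_COLS) <= cols else "z"
    if dialect == "z":
        if "z_increment_deg" not in cols:
            raise ValueError(
                f"{path}: missing column z_increment_deg for dialect 'z'")
        bad = df.index[df["z_increment_deg"].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed row at line {int(bad[0]) + 2}")
        inc = df["z_increment_deg"].to_numpy(dtype=float)
    elif dialect == "matrix":
        missing = [c for c in _MATRIX_COLS if c not in cols]
        if missing:
            raise ValueError(f"{path}: missing matrix columns {missing}")
        arr = df[_MATRIX_COLS]
        bad = df.index[arr.isna().any(axis=1)]
        if len(bad):
            raise ValueError(
                f"{path}: malformed row at line {int(bad[0]) + 2}")
        mats = arr.to_numpy(dtype=float).reshape(-1, 3, 3)
        inc = _z_from_matrices(mats)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RotationTrace(frame_rate, inc, source="recorded")


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

def z_rotation_series(trace: RotationTrace,
                      smooth_frames: int = 0) -> np.ndarray:
    """Sphere-frame z angular velocity (deg/s), optionally box-smoothed."""
    v = trace.z_increments_deg * trace.frame_rate
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        v = np.convolve(v, kernel, mode="same")
    return v


def detect_peaks(series: np.ndarray, frame_rate: float = 120.0,
                 params: PeakParams = PeakParams(),
                 presmoothed: bool = False) -> list[PivotPeak]:
    """Detect rotation events of both polarities in a z-velocity series.

    The series is box-smoothed, candidate extrema above the velocity
    threshold are found per polarity, each is extended to the surrounding
    zero crossings, and the signed area is the trapezoidal integral of the
    smoothed velocity between onset and offset.  Overlapping candidates
    within one lobe are merged.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("series must have at least 2 samples")
    if params.smooth_frames > 1 and not presmoothed:
        kernel = np.ones(params.smooth_frames) / params.smooth_frames
        sm = np.convolve(series, kernel, mode="same")
    else:
        sm = series

    peaks: dict[tuple[int, int], PivotPeak] = {}
    for sign in (1.0, -1.0):
        s = sign * sm
        idx, _ = find_peaks(s, height=params.height_deg_s)
        for i in idx:
            # walk out to the zero crossings bounding this lobe
            lo = i
            while lo > 0 and s[lo - 1] > 0:
                lo -= 1
            hi = i
            while hi < s.size - 1 and s[hi + 1] > 0:
                hi += 1
            key = (int(sign), lo)
            if key in peaks:
                continue
            area = float(np.trapezoid(sm[lo:hi + 1]) / frame_rate)
            pk = float(sm[lo:hi + 1][np.argmax(s[lo:hi + 1])])
            peaks[key] = PivotPeak(lo / frame_rate, (hi + 1) / frame_rate,
                                   area, pk)
    return sorted(peaks.values(), key=lambda p: p.onset_s)


# ---------------------------------------------------------------------------
# Experiment-1 scoring: first detection angle
# ---------------------------------------------------------------------------

def first_detection(peaks: Sequence[PivotPeak], presentation: Presentation,
                    min_area_deg: float = 20.0,
                    window_end_s: float | None = None) -> float | None:
    """Stimulus azimuth at the first direction-consistent pivot, or None.

    A valid detection is the first peak inside the presentation window with
    at least ``min_area_deg`` of rotation whose spider-intended direction
    matches the stimulus side (clockwise for right-side stimuli).  Returns
    the stimulus centroid azimuth at peak onset.  The window runs from the
    presentation onset to ``window_end_s`` (default: the stimulus offset
    plus one second, so responses to the stimulus vanishing at the track
    end still count); pass the next presentation's onset to get strict
    half-open association.
    """
    track = next(iter(presentation.tracks.values()))
    side_sign = 1 if presentation.target_side == "right" else -1
    end = window_end_s if window_end_s is not None \
        else presentation.offset_s + 1.0
    for p in sorted(peaks, key=lambda q: q.onset_s):
        if not (presentation.onset_s <= p.onset_s < end):
            continue
        if abs(p.signed_area_deg) < min_area_deg:
            continue
        if p.spider_direction != side_sign:
            continue
        return track.azimuth_at(p.onset_s, presentation.onset_s)
    return None


# ---------------------------------------------------------------------------
# Experiment-2 scoring: signed preference
# ---------------------------------------------------------------------------

def assign_presentations(peaks: Sequence[PivotPeak],
                         schedule: TrialSchedule
                         ) -> list[tuple[PivotPeak, Presentation | None]]:
    """Associate peaks to presentations via half-open [onset, next-onset)."""
    out = []
    pres = schedule.presentations
    onsets = [p.onset_s for p in pres]
    for pk in peaks:
        w = None
        for i, p in enumerate(pres):
            nxt = onsets[i + 1] if i + 1 < len(pres) else np.inf
            if p.onset_s <= pk.onset_s < nxt:
                w = p
                break
        out.append((pk, w))
    return out


def signed_scores(peaks: Sequence[PivotPeak], schedule: TrialSchedule,
                  value: str = "peak_velocity") -> np.ndarray:
    """Sign every peak by the biological/silhouette stimulus position.

    Positive = spider-intended rotation toward the biological (or
    silhouette, or single-target) side; negative = toward the other side.
    All assignable peaks are included; peaks outside any presentation
    window are excluded.  ``value`` selects the scored magnitude
    ("peak_velocity" or "signed_area").
    """
    if value not in ("peak_velocity", "signed_area"):
        raise ValueError("value must be 'peak_velocity' or 'signed_area'")
    scores = []
    for pk, pres in assign_presentations(peaks, schedule):
        if pres is None:
            continue
        mag = abs(pk.peak_velocity if value == "peak_velocity"
                  else pk.signed_area_deg)
        side_sign = 1 if pres.target_side == "right" else -1
        scores.append(mag if pk.spider_direction == side_sign else -mag)
    return np.asarray(scores, dtype=float)


@dataclass(frozen=True)
class PreferenceResult:
    """Mean signed pivot value with resampling inference.

    Positive mean = preference for the biological/silhouette stimulus.
    """

    mean_signed_value: float
    n_peaks: int
    ci_low: float
    ci_high: float
    p_value: float
    exact: bool

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.mean_signed_value
                <= self.ci_high + 1e-12):
            raise ValueError("CI must contain the mean")


def preference_statistic(scores: np.ndarray, n_boot: int = 2000,
                         n_perm: int = 5000, seed: int = 0,
                         groups: np.ndarray | None = None,
                         exact_max_n: int = 15) -> PreferenceResult:
    """Mean signed score with bootstrap CI and sign-flip permutation p.

    The permutation null flips the sign of every score independently
    (two-sided p on the mean); for ``n <= exact_max_n`` all 2**n sign
    patterns are enumerated exactly.  The bootstrap resamples ``groups``
    (e.g. spiders) when given, otherwise individual scores.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValueError("scores must be non-empty")
    rng = np.random.default_rng(seed)
    mean_obs = float(scores.mean())

    # permutation (sign-flip) p-value
    if n <= exact_max_n:
        signs = np.array(
            [[1 if (m >> b) & 1 else -1 for b in range(n)]
             for m in range(2 ** n)], dtype=float)
        means = signs @ scores / n
        p = float(np.mean(np.abs(means) >= abs(mean_obs) - 1e-12))
        exact = True
    else:
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
        means = flips @ scores / n
        p = float((np.sum(np.abs(means) >= abs(mean_obs) - 1e-12) + 1)
                  / (n_perm + 1))
        exact = False

    # bootstrap CI for the mean (group-resampled when groups are given)
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        per_group = [scores[groups == g] for g in uniq]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(len(uniq), size=len(uniq))
            boots[b] = np.concatenate([per_group[i] for i in pick]).mean()
    else:
        idx = rng.integers(n, size=(n_boot, n))
        boots = scores[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, mean_obs), max(hi, mean_obs)
    return PreferenceResult(mean_obs, n, float(lo), float(hi), p, exact)


# ---------------------------------------------------------------------------
# Whole-trial conveniences
# ---------------------------------------------------------------------------

def score_exp1(trace: RotationTrace, schedule: TrialSchedule,
               min_area_deg: float = 20.0,
               params: PeakParams = PeakParams()) -> list[float]:
    """First-detection stimulus azimuths for every responded presentation."""
    series = z_rotation_series(trace)
    peaks = detect_peaks(series, trace.frame_rate, params)
    out = []
    pres = schedule.presentations
    for i, p in enumerate(pres):
        end = pres[i + 1].onset_s if i + 1 < len(pres) else np.inf
        a = first_detection(peaks, p, min_area_deg, window_end_s=end)
        if a is not None:
            out.append(a)
    return out


def score_exp2(trace: RotationTrace, schedule: TrialSchedule,
               params: PeakParams = PeakParams(), n_boot: int = 2000,
               n_perm: int = 5000, seed: int = 0,
               value: str = "peak_velocity") -> PreferenceResult:
    """Signed-preference statistic over all peaks of one trial."""
    series = z_rotation_series(trace)
    peaks = detect_peaks(series, trace.frame_rate, params)
    scores = signed_scores(peaks, schedule, value=value)
    return preference_statistic(scores, n_boot, n_perm, seed)


# ---------------------------------------------------------------------------
# Detection histogram / behavioural field mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionHistogram:
    """Relative-frequency histogram of first-detection azimuths.

    Bins are centred on multiples of ``bin_width``.  ``mode_left`` /
    ``mode_right`` are the per-side modal bin centres (None when that side
    has no detections); ``span`` is their angular distance, flagged None
    when undefined (a single side, or tied modes).
    """

    bin_width: float
    centers: np.ndarray
    counts: np.ndarray
    rel_freq: np.ndarray
    mode_left: float | None
    mode_right: float | None
    modes_left: tuple[float, ...]
    modes_right: tuple[float, ...]
    span: float | None

    @property
    def magnitude_mode(self) -> float:
        """Modal |azimuth| pooled over both sides."""
        mags = np.abs(self.centers)
        order = np.argsort(mags)
        uniq: dict[float, float] = {}
        for i in order:
            uniq[mags[i]] = uniq.get(mags[i], 0.0) + self.counts[i]
        best = max(uniq.items(), key=lambda kv: kv[1])
        return float(best[0])


def detection_histogram(detections: Sequence[float],
                        bin_width: float = 5.0) -> DetectionHistogram:
    """Bin detection azimuths and extract per-side modes and their span."""
    det = normalize_azimuth(np.asarray(list(detections), dtype=float))
    if det.size == 0:
        raise ValueError("need at least one detection")
    idx = np.round(det / bin_width).astype(int)
    # ±180 are the same bin
    nbins = int(round(360.0 / bin_width))
    idx = np.where(idx <= -nbins // 2, idx + nbins, idx)
    uniq, counts = np.unique(idx, return_counts=True)
    centers = uniq * bin_width
    rel = counts / counts.sum()

    def _modes(mask) -> tuple[tuple[float, ...], float | None]:
        if not mask.any():
            return (), None
        c = counts[mask]
        cent = centers[mask]
        best = c.max()
        tied = tuple(float(x) for x in cent[c == best])
        return tied, (tied[0] if len(tied) == 1 else None)

    modes_l, mode_l = _modes(centers < 0)
    modes_r, mode_r = _modes(centers > 0)
    span = None
    if mode_l is not None and mode_r is not None:
        span = float(mode_r - mode_l)
    return DetectionHistogram(bin_width, centers, counts, rel, mode_l,
                              mode_r, modes_l, modes_r, span)
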