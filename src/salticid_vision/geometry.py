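"""Spider-centric stimulus geometry.

The experimental arena consists of two flat monitors joined along a vertical
edge, angled towards each other, with the tethered spider placed on the
symmetry axis at a fixed distance from the junction.  Everything downstream of
this module works in a 1-D azimuthal coordinate system centred on the spider:
0 deg is directly ahead, positive azimuths are to the spider's right
(clockwise seen from above), and values are normalised into (-180, 180].

The module answers three questions: what azimuthal span the monitors subtend
(`angular_coverage`), where a given screen position lies in spider
coordinates (`screen_to_azimuth` / `azimuth_to_screen`), and which eye pair
can see a given azimuth (`EyeFieldMap` / `in_field`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "MonitorSetup",
    "EyeFieldMap",
    "DEFAULT_EYE_FIELDS",
    "normalize_azimuth",
    "angular_coverage",
    "screen_to_azimuth",
    "azimuth_to_screen",
    "in_field",
    "load_geometry_config",
]

Side = Literal["left", "right"]
Orientation = Literal["forward", "backward"]


def normalize_azimuth(a):
    """Normalise angles (deg) into (-180, 180].

    Works on scalars and arrays; -180 maps to +180 so that the junction seen
    from a backward-facing spider has a single well-defined coordinate.
    """
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class MonitorSetup:
    """Two monitors of width ``panel_width_mm`` joined at ``inter_panel_angle_deg``.

    ``viewer_distance_mm`` is the spider-to-junction distance along the
    bisector.  ``orientation`` says whether the spider faces the junction
    ("forward", junction at 0 deg) or away from it ("backward", junction at
    180 deg).
    """

    panel_width_mm: float = 537.0
    inter_panel_angle_deg: float = 65.0
    viewer_distance_mm: float = 200.0
    orientation: Orientation = "forward"
    pixels_across: int = 1920

    def __post_init__(self) -> None:
        if self.panel_width_mm <= 0:
            raise ValueError("panel_width_mm must be > 0")
        if not (0.0 < self.inter_panel_angle_deg <= 180.0):
            raise ValueError("inter_panel_angle_deg must be in (0, 180]")
        if self.viewer_distance_mm <= 0:
            raise ValueError(
                "viewer_distance_mm must be > 0: viewer on or beyond the "
                "panel junction is a degenerate geometry"
            )
        if self.orientation not in ("forward", "backward"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    # -- room-frame helpers -------------------------------------------------
    def _panel_point(self, side: Side, s_mm: float) -> tuple[float, float]:
        """Room-frame (x, y) of the point ``s_mm`` along ``side``'s panel.

        Room frame: spider at origin, junction at (0, d).  The panels open
        away from the viewer; at 180 deg they are coplanar and frontal.
        """
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        if not (0.0 <= s_mm <= self.panel_width_mm):
            raise ValueError(
                f"position {s_mm} mm outside panel extent "
                f"[0, {self.panel_width_mm}] mm"
            )
        alpha = math.radians(self.inter_panel_angle_deg / 2.0)
        sgn = 1.0 if side == "right" else -1.0
        x = sgn * s_mm * math.sin(alpha)
        y = self.viewer_distance_mm - s_mm * math.cos(alpha)
        return x, y


def angular_coverage(setup: MonitorSetup) -> float:
    """Total azimuthal span (deg) subtended by both panels, symmetric about 0.

    The azimuth of a point sliding along a straight panel is monotonic, so
    the span is twice the azimuth of the outer edge.
    """
    x, y = setup._panel_point("right", setup.panel_width_mm)
    edge = math.degrees(math.atan2(x, y))
    if edge <= 0:
        raise ValueError("degenerate geometry: panel edge azimuth not positive")
    return 2.0 * edge


def screen_to_azimuth(setup: MonitorSetup, side: Side, s_mm: float) -> float:
    """Azimuth (deg) of the screen point ``s_mm`` from the junction.

    ``side`` names the monitor in room coordinates.  For a backward-facing
    spider the junction maps to 180 deg and the room-left monitor appears on
    the spider's right.
    """
    x, y = setup._panel_point(side, s_mm)
    if setup.orientation == "forward":
        return normalize_azimuth(math.degrees(math.atan2(x, y)))
    return normalize_azimuth(math.degrees(math.atan2(-x, -y)))


def pixel_to_azimuth(setup: MonitorSetup, side: Side, px: float) -> float:
    """Azimuth of pixel column ``px`` (0 at the junction edge)."""
    s = px / setup.pixels_across * setup.panel_width_mm
    return screen_to_azimuth(setup, side, s)


def azimuth_to_screen(setup: MonitorSetup, a: float) -> tuple[Side, float]:
    """Invert :func:`screen_to_azimuth`; returns (side, position_mm).

    Raises ``ValueError`` naming the uncovered gap for azimuths the monitors
    do not cover.
    """
    a = normalize_azimuth(a)
    cov = angular_coverage(setup)
    if setup.orientation == "forward":
        rel = a
    else:
        # spider faces away from the junction: the forward-equivalent azimuth
        # of the same physical point is a rotated by 180 deg
        rel = normalize_azimuth(a + 180.0)
    if abs(rel) > cov / 2.0 + 1e-9:
        lo = cov / 2.0
        gap = (
            f"({lo:.1f}, 180.0] and [-180.0, -{lo:.1f})"
            if setup.orientation == "forward"
            else f"(-{180 - lo:.1f}, {180 - lo:.1f})"
        )
        raise ValueError(
            f"azimuth {a:.1f} deg outside monitor coverage; uncovered gap "
            f"is {gap} deg"
        )
    side: Side = "right" if rel >= 0 else "left"
    alpha = math.radians(setup.inter_panel_angle_deg / 2.0)
    th = math.radians(abs(rel))
    denom = math.sin(alpha + th)
    if denom <= 0:
        raise ValueError("degenerate geometry: ray parallel to panel")
    s = setup.viewer_distance_mm * math.sin(th) / denom
    s = min(max(s, 0.0), setup.panel_width_mm)
    return side, s


# ---------------------------------------------------------------------------
# Eye fields
# ---------------------------------------------------------------------------

EYES = ("ALE", "PLE", "AME", "PME")


@dataclass(frozen=True)
class EyeFieldMap:
    """Azimuth intervals (closed, deg) covered by each eye pair.

    Intervals live in (-180, 180]; wrap-around fields are given as two
    intervals.  The behavioural defaults place the ALE edges at +/-50 deg
    (the experiment-1 response peak) and the PLE inner edges at +/-60 deg,
    leaving the 50-60 deg annulus covered by neither pair.  AME and PME
    fields are present but empty: the principal eyes are occluded in all
    treatments here and the PMEs are considered vestigial.
    """

    fields: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: {
            "ALE": ((-50.0, 50.0),),
            "PLE": ((-180.0, -60.0), (60.0, 180.0)),
            "AME": (),
            "PME": (),
        }
    )

    def __post_init__(self) -> None:
        for eye, ivs in self.fields.items():
            if eye not in EYES:
                raise ValueError(f"unknown eye {eye!r}; expected one of {EYES}")
            for lo, hi in ivs:
                if lo >= hi:
                    raise ValueError(f"{eye}: empty interval ({lo}, {hi})")
                if lo < -180.0 or hi > 180.0:
                    raise ValueError(f"{eye}: interval ({lo}, {hi}) out of range")
            for (lo1, hi1) in ivs:
                for (lo2, hi2) in ivs:
                    if (lo1, hi1) < (lo2, hi2) and lo2 < hi1:
                        raise ValueError(f"{eye}: overlapping intervals")

    def eyes(self) -> tuple[str, ...]:
        return tuple(self.fields)


DEFAULT_EYE_FIELDS = EyeFieldMap()


def in_field(fmap: EyeFieldMap, eye: str, a: float) -> bool:
    """True iff azimuth ``a`` lies in any interval of ``eye``'s field."""
    if eye not in fmap.fields:
        raise KeyError(f"eye {eye!r} not present in map")
    a = normalize_azimuth(a)
    for lo, hi in fmap.fields[eye]:
        if lo <= a <= hi:
            return True
        # -180 and +180 are the same direction
        if a == 180.0 and lo <= -180.0 <= hi:
            return True
    return False


def in_field_array(fmap: EyeFieldMap, eye: str, a) -> np.ndarray:
    """Vectorised :func:`in_field` for an array of azimuths."""
    if eye not in fmap.fields:
        raise KeyError(f"eye {eye!r} not present in map")
    a = normalize_azimuth(np.asarray(a, dtype=float))
    out = np.zeros(np.shape(a), dtype=bool)
    for lo, hi in fmap.fields[eye]:
        out |= (a >= lo) & (a <= hi)
        if lo <= -180.0 <= hi:
            out |= a == 180.0
    return out


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def load_geometry_config(path) -> tuple[MonitorSetup, EyeFieldMap]:
    """Read a YAML config with ``monitor`` and ``eye_fields`` sections."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    mon = cfg.get("monitor", {})
    setup = MonitorSetup(
        panel_width_mm=float(mon.get("panel_width_mm", 537.0)),
        inter_panel_angle_deg=float(mon.get("inter_panel_angle_deg", 65.0)),
        viewer_distance_mm=float(mon.get("viewer_distance_mm", 200.0)),
        orientation=mon.get("orientation", "forward"),
        pixels_across=int(mon.get("pixels_across", 1920)),
    )
    ef = cfg.get("eye_fields")
    if ef is None:
        fmap = DEFAULT_EYE_FIELDS
    else:
        fields = {
            eye: tuple(tuple(float(v) for v in iv) for iv in ivs)
            for eye, ivs in ef.items()
        }
        for eye in EYES:
            fields.setdefault(eye, ())
        fmap = EyeFieldMap(fields=fields)
    return setup, fmap
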