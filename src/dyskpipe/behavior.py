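"""Dyskinesia (AIM) scoring aggregation and open-field locomotor metrics.

Abnormal involuntary movements (AIMs) are rated on the axial/limb/orofacial
(ALO) scale: each body segment scores 0-4 per timepoint, so the per-timepoint
total ranges 0-12.  Open-field behavior is summarized as quarter-turn
rotation rates (90 degree contralateral or ipsilateral turns), velocity and
distance traveled, computed from video-tracking coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AimTrace",
    "TrackingTrace",
    "OpenFieldMetrics",
    "total_aim",
    "bin_aim",
    "detect_rotations",
    "velocity_distance",
]

MAX_SUBSCORE = 4
N_SEGMENTS = 3
MAX_TOTAL = MAX_SUBSCORE * N_SEGMENTS  # 12


def total_aim(axial: int, limb: int, orofacial: int) -> int:
    """Total ALO AIM score for one timepoint.

    Each subscore must lie in {0..4}; the total is their sum, bounded by 12.

    Raises
    ------
    ValueError
        If any subscore is outside {0, 1, 2, 3, 4}.
    """
    for name, s in (("axial", axial), ("limb", limb), ("orofacial", orofacial)):
        if not (0 <= s <= MAX_SUBSCORE) or int(s) != s:
            raise ValueError(
                f"{name} subscore must be an integer in [0, {MAX_SUBSCORE}], got {s!r}"
            )
    return int(axial) + int(limb) + int(orofacial)


@dataclass
class AimTrace:
    """Per-timepoint ALO AIM subscores and totals.

    Attributes
    ----------
    t_min : array
        Minutes from levodopa injection, strictly increasing.
    axial, limb, orofacial : arrays
        Ordinal subscores, each in {0..4}.
    """

    t_min: np.ndarray
    axial: np.ndarray
    limb: np.ndarray
    orofacial: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        for name in ("axial", "limb", "orofacial"):
            arr = np.asarray(getattr(self, name))
            if arr.size and (arr.min() < 0 or arr.max() > MAX_SUBSCORE):
                raise ValueError(f"{name} subscores must lie in [0, {MAX_SUBSCORE}]")
            setattr(self, name, arr.astype(int))
        if self.t_min.size > 1 and not np.all(np.diff(self.t_min) > 0):
            raise ValueError("timepoints must be strictly increasing")
        n = self.t_min.size
        if not (self.axial.size == self.limb.size == self.orofacial.size == n):
            raise ValueError("subscore arrays must match timepoint length")

    @property
    def total(self) -> np.ndarray:
        return self.axial + self.limb + self.orofacial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.t_min,
                "axial": self.axial,
                "limb": self.limb,
                "orofacial": self.orofacial,
                "total": self.total,
            }
        )

    @classmethod
    def from_csv(cls, path) -> "AimTrace":
        df = pd.read_csv(path)
        return cls(
            t_min=df["t_min"].to_numpy(),
            axial=df["axial"].to_numpy(),
            limb=df["limb"].to_numpy(),
            orofacial=df["orofacial"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bin_aim(trace: AimTrace, bin_min: float = 1.0, t_start: float | None = None,
            t_end: float | None = None) -> pd.DataFrame:
    """Average the AIM total in fixed time bins.

    Bins containing no scored timepoint are reported as NaN, never
    interpolated: dyskinesia is commonly scored only every other minute, and
    downstream firing-rate correlations must use scored minutes only.

    Returns a frame with ``bin_start_min`` and ``aim_total`` columns.
    """
    if bin_min <= 0:
        raise ValueError("bin width must be positive")
    if t_start is None:
        t_start = float(np.floor(trace.t_min.min() / bin_min) * bin_min) if trace.t_min.size else 0.0
    if t_end is None:
        t_end = float(trace.t_min.max()) if trace.t_min.size else t_start + bin_min
    edges = np.arange(t_start, t_end + bin_min, bin_min)
    if edges[-1] < t_end:
        edges = np.append(edges, edges[-1] + bin_min)
    idx = np.digitize(trace.t_min, edges) - 1
    total = trace.total.astype(float)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    valid = (idx >= 0) & (idx < n_bins)
    np.add.at(sums, idx[valid], total[valid])
    np.add.at(counts, idx[valid], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame({"bin_start_min": edges[:-1], "aim_total": means})


@dataclass
class TrackingTrace:
    """Open-field tracking: time (s), position (cm), heading (rad, unwrapped).

    Heading may be supplied directly or derived from the direction of motion.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray | None = None
    arena_radius_cm: float = 12.5

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("tracking timestamps must be strictly increasing")
        if self.heading is not None:
            self.heading = np.asarray(self.heading, dtype=float)

    def heading_unwrapped(self) -> np.ndarray:
        """Unwrapped heading; derived from step direction when not supplied."""
        if self.heading is not None:
            return np.unwrap(self.heading)
        dx = np.diff(self.x)
        dy = np.diff(self.y)
        ang = np.arctan2(dy, dx)
        # stationary steps keep the previous heading
        moving = np.hypot(dx, dy) > 1e-9
        if not moving.any():
            return np.zeros_like(self.t)
        ang = pd.Series(np.where(moving, ang, np.nan)).ffill().bfill().to_numpy()
        ang = np.unwrap(ang)
        return np.concatenate([[ang[0]], ang])

    @classmethod
    def from_csv(cls, path, arena_radius_cm: float = 12.5) -> "TrackingTrace":
        df = pd.read_csv(path)
        heading = df["heading_rad"].to_numpy() if "heading_rad" in df else None
        return cls(
            t=df["t_s"].to_numpy(),
            x=df["x_cm"].to_numpy(),
            y=df["y_cm"].to_numpy(),
            heading=heading,
            arena_radius_cm=arena_radius_cm,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y})
        if self.heading is not None:
            df["heading_rad"] = self.heading
        df.to_csv(path, index=False)


@dataclass
class OpenFieldMetrics:
    """Rotation and locomotion summary for one session."""

    contra_quarter_turns: int
    ipsi_quarter_turns: int
    contra_rate_per_min: float
    ipsi_rate_per_min: float
    net_rotation_rate: float  # (contra - ipsi) quarter turns / min
    velocity_cm_s: float
    distance_cm: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


QUARTER = np.pi / 2


def _count_quarter_turns(heading: np.ndarray) -> tuple[int, int]:
    """Count completed 90-degree increments of cumulative heading change.

    The heading is decomposed into monotone runs; each run of angular extent
    L contributes floor(L / 90 deg) quarter turns in its direction.  Progress
    is therefore measured from the last turning point, the standard rotometer
    convention.  Positive heading change is counted as contralateral.
    """
    d = np.diff(heading)
    d = d[d != 0]
    if d.size == 0:
        return 0, 0
    contra = ipsi = 0
    run = 0.0
    sign = np.sign(d[0])
    for step in d:
        s = np.sign(step)
        if s != sign:
            sign = s
            run = 0.0
        run += abs(step)
        while run >= QUARTER:
            run -= QUARTER
            if sign > 0:
                contra += 1
            else:
                ipsi += 1
    return contra, ipsi


def _smooth_heading(heading: np.ndarray, t: np.ndarray, window_s: float) -> np.ndarray:
    if window_s <= 0 or t.size < 3:
        return heading
    dt = np.median(np.diff(t))
    w = max(1, int(round(window_s / dt)))
    if w <= 1:
        return heading
    kernel = np.ones(w) / w
    pad = w // 2
    # odd reflection preserves linear heading drift at the trace ends
    padded = np.pad(heading, (pad, w - 1 - pad), mode="reflect", reflect_type="odd")
    return np.convolve(padded, kernel, mode="valid")


def detect_rotations(track: TrackingTrace, smooth_window_s: float = 1.0) -> OpenFieldMetrics:
    """Quarter-turn rotation counts and rates from a tracking trace.

    The unwrapped heading is smoothed with a 1-s moving average to suppress
    jitter turns, then completed 90 degree increments of cumulative signed
    heading change are counted per direction.  Net rotation rate is
    (contralateral - ipsilateral) quarter turns per minute.
    """
    if track.t.size < 2:
        raise ValueError("need at least 2 tracking samples")
    heading = _smooth_heading(track.heading_unwrapped(), track.t, smooth_window_s)
    contra, ipsi = _count_quarter_turns(heading)
    minutes = (track.t[-1] - track.t[0]) / 60.0
    vel, dist = velocity_distance(track)
    return OpenFieldMetrics(
        contra_quarter_turns=contra,
        ipsi_quarter_turns=ipsi,
        contra_rate_per_min=contra / minutes,
        ipsi_rate_per_min=ipsi / minutes,
        net_rotation_rate=(contra - ipsi) / minutes,
        velocity_cm_s=vel,
        distance_cm=dist,
    )


def velocity_distance(track: TrackingTrace) -> tuple[float, float]:
    """Mean velocity (cm/s) and total path length (cm)."""
    if track.t.size < 2:
        raise ValueError("need at least 2 tracking samples")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    distance = float(steps.sum())
    elapsed = track.t[-1] - track.t[0]
    return distance / elapsed, distance
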