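"""Synthetic rest-bout samples, trajectories and rendered frame stacks.

The generator reproduces the statistical structure the analysis pipeline
assumes, so every downstream stage can be tested without recorded video:

* rest-bout durations follow the two-phase law — survival P(X > t) is an
  exact power law ``t^-beta`` on ``[xmin, K]`` joined continuously at ``K``
  to an exponential branch with mean excess ``lam`` (the density has a kink
  at ``K``; a density-continuous glue is available as ``tail_mode="density"``);
* trajectories alternate bounded move segments with stationary rest segments
  whose durations are drawn from that law, inside a 1D tube (5 x 78 mm) or a
  2D elliptic arena (50 x 30 mm) at 25 fps;
* frame stacks render the fly as a bright disk inside a dark chamber on a
  brighter surround, which is the contrast the tracker's background
  subtraction and chamber segmentation rely on.

Every generator takes a seed (or inherits one from its spec) and is exactly
reproducible; trajectories return their planted rest bouts as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import LightSchedule, Trajectory

__all__ = [
    "TwoPhaseSpec",
    "Chamber",
    "TrajectorySpec",
    "sample_two_phase",
    "two_phase_survival",
    "make_trajectory",
    "render_frames",
]


@dataclass
class TwoPhaseSpec:
    """Parameters of the two-phase rest-duration law.

    ``beta`` is the survival exponent of the power-law (latency) branch —
    the active index — so the density on the head goes as ``t^-(beta+1)``.
    ``K`` is the sleep latency (changepoint, s) and ``lam`` the mean of the
    exponential excess beyond ``K`` (sleep duration, s).
    """

    beta: float
    K: float
    lam: float
    xmin: float = 1.0
    n_bouts: int = 1000
    seed: int | None = None
    tail_mode: str = "survival"  # "survival": P(t) continuous, exact t^-beta head

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not self.K > self.xmin > 0:
            raise ValueError("K > xmin > 0 is required")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")
        if self.tail_mode not in ("survival", "density"):
            raise ValueError("tail_mode must be 'survival' or 'density'")

    @property
    def tail_weight(self) -> float:
        """Analytic P(X > K)."""
        b, K, lam, xmin = self.beta, self.K, self.lam, self.xmin
        if self.tail_mode == "survival":
            return (K / xmin) ** -b
        head = (xmin**-b - K**-b) / b
        tail = K ** -(b + 1) * lam
        return tail / (head + tail)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("beta", "K", "lam", "xmin", "n_bouts", "seed", "tail_mode")}

    @classmethod
    def from_json(cls, path) -> "TwoPhaseSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def two_phase_survival(t, spec: TwoPhaseSpec) -> np.ndarray:
    """Analytic survival function P(X > t) of the generating law."""
    t = np.asarray(t, dtype=float)
    b, K, lam, xmin = spec.beta, spec.K, spec.lam, spec.xmin
    w = spec.tail_weight
    if spec.tail_mode == "survival":
        head = (np.minimum(t, K) / xmin) ** -b
    else:
        C = w / (K ** -(b + 1) * lam)
        head = 1 - C * (xmin**-b - np.minimum(t, K) ** -b) / b
    tail = w * np.exp(-(np.maximum(t, K) - K) / lam)
    out = np.where(t <= K, head, tail)
    return np.where(t < xmin, 1.0, out)


def sample_two_phase(spec: TwoPhaseSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``spec.n_bouts`` i.i.d. rest durations by inverse-CDF sampling."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    b, K, lam, xmin = spec.beta, spec.K, spec.lam, spec.xmin
    w = spec.tail_weight
    u = rng.random(spec.n_bouts)
    tail = u < w
    out = np.empty(spec.n_bouts)
    # head: truncated Pareto by inverse CDF (identical conditional law in both modes)
    v = rng.random(spec.n_bouts)
    out[~tail] = (xmin**-b - v[~tail] * (xmin**-b - K**-b)) ** (-1.0 / b)
    out[tail] = K + rng.exponential(lam, size=int(tail.sum()))
    return out


@dataclass
class Chamber:
    """Observation chamber geometry.

    ``kind`` is "1D" (tube, 5 x 78 mm) or "2D" (ellipse, 50 x 30 mm); the
    long axis is the y axis. Pixel coordinates are (x, y) with y along rows
    of the rendered frame.
    """

    kind: str = "1D"
    long_mm: float = 78.0
    short_mm: float = 5.0
    px_per_mm: float = 2.0
    margin_px: int = 8

    def __post_init__(self) -> None:
        if self.kind not in ("1D", "2D"):
            raise ValueError("kind must be '1D' or '2D'")
        if self.long_mm <= 0 or self.short_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("chamber dimensions must be positive")

    @classmethod
    def tube(cls, px_per_mm: float = 2.0) -> "Chamber":
        return cls(kind="1D", long_mm=78.0, short_mm=5.0, px_per_mm=px_per_mm)

    @classmethod
    def ellipse(cls, px_per_mm: float = 2.0) -> "Chamber":
        return cls(kind="2D", long_mm=50.0, short_mm=30.0, px_per_mm=px_per_mm)

    @property
    def long_px(self) -> float:
        return self.long_mm * self.px_per_mm

    @property
    def short_px(self) -> float:
        return self.short_mm * self.px_per_mm

    @property
    def frame_shape(self) -> tuple[int, int]:
        h = int(np.ceil(self.long_px)) + 2 * self.margin_px
        w = int(np.ceil(self.short_px)) + 2 * self.margin_px
        return h, w

    @property
    def center(self) -> tuple[float, float]:
        h, w = self.frame_shape
        return (w - 1) / 2.0, (h - 1) / 2.0  # (x, y)

    def contains(self, x, y, pad_px: float = 0.0) -> np.ndarray:
        """True where (x, y) lies inside the interior, shrunk by ``pad_px``."""
        cx, cy = self.center
        if self.kind == "1D":
            return (np.abs(np.asarray(x) - cx) <= self.short_px / 2 - pad_px) & (
                np.abs(np.asarray(y) - cy) <= self.long_px / 2 - pad_px
            )
        rx = self.short_px / 2 - pad_px
        ry = self.long_px / 2 - pad_px
        return ((np.asarray(x) - cx) / rx) ** 2 + ((np.asarray(y) - cy) / ry) ** 2 <= 1.0

    def interior_mask(self) -> np.ndarray:
        h, w = self.frame_shape
        yy, xx = np.mgrid[0:h, 0:w]
        return self.contains(xx, yy)


@dataclass
class TrajectorySpec:
    """Recipe for a synthetic alternating move/rest trajectory."""

    chamber: Chamber = field(default_factory=Chamber.tube)
    fps: float = 25.0
    duration_s: float = 600.0
    move_speed_px_s: float = 30.0
    rest_spec: TwoPhaseSpec = field(
        default_factory=lambda: TwoPhaseSpec(beta=0.8, K=200.0, lam=1000.0, xmin=1.0)
    )
    # active-bout lengths: log-normal spacers (not modelled by the two-phase law)
    move_dur_mu_log: float = 1.0
    move_dur_sigma_log: float = 0.75
    jitter_px: float = 0.5
    schedule: LightSchedule = field(default_factory=LightSchedule)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.move_speed_px_s <= 0:
            raise ValueError("move_speed_px_s must be positive")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")


@dataclass
class SyntheticTrajectory:
    """A generated trajectory plus its planted rest bouts (ground truth)."""

    trajectory: Trajectory
    planted: pd.DataFrame  # onset_s, duration_s, x_px, y_px
    spec: TrajectorySpec


def make_trajectory(spec: TrajectorySpec, rng: np.random.Generator | None = None) -> SyntheticTrajectory:
    """Generate an alternating move/rest trajectory inside the chamber.

    Move segments head towards randomly chosen interior waypoints at constant
    speed; rest segments hold position up to ``jitter_px`` of stationary
    noise. Rest durations come from the two-phase sampler; planted bouts are
    quantized to the frame grid and reported with the extractor's duration
    convention (frame span / fps).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ch = spec.chamber
    fps = spec.fps
    n_frames = int(np.floor(spec.duration_s * fps))
    pad = 2.0
    min_rest_frames = 2  # a rest must occupy at least 2 frames to exist on the grid

    step = spec.move_speed_px_s / fps

    def random_point() -> np.ndarray:
        while True:
            h, w = ch.frame_shape
            p = rng.uniform([0, 0], [w - 1, h - 1])
            if ch.contains(p[0], p[1], pad_px=pad):
                return p

    def random_target(pos: np.ndarray) -> np.ndarray:
        # waypoints sit an integer number of steps away, so the walk covers
        # a full step every frame and corners fall on frame boundaries;
        # consecutive walking frames are then always a full step apart
        while True:
            p = random_point()
            d = float(np.hypot(*(p - pos)))
            m = int(d / step)
            if m >= 1:
                return pos + (p - pos) / d * (m * step)

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    planted: list[tuple[float, float, float, float]] = []

    pos = random_point()
    target = random_target(pos)
    i = 0
    resting = False
    while i < n_frames:
        if resting:
            dur = float(sample_two_phase(
                TwoPhaseSpec(**{**spec.rest_spec.to_dict(), "n_bouts": 1, "seed": None}), rng)[0])
            # the fly is already AT the rest location on the arrival frame
            # (the last move frame), so that frame opens the bout
            k = max(int(round(dur * fps)), min_rest_frames - 1)  # additional frames
            k = min(k, n_frames - i)
            if k >= min_rest_frames - 1 and k >= 1:
                jit = rng.normal(0.0, spec.jitter_px / 2.0, size=(k, 2)) if spec.jitter_px > 0 else np.zeros((k, 2))
                jit = np.clip(jit, -spec.jitter_px, spec.jitter_px)
                xs[i:i + k] = pos[0] + jit[:, 0]
                ys[i:i + k] = pos[1] + jit[:, 1]
                start = i - 1  # arrival frame; a move segment always precedes
                planted.append((start / fps, (i + k - 1 - start) / fps, pos[0], pos[1]))
                i += k
            resting = False
            target = random_target(pos)
        else:
            dur = float(rng.lognormal(spec.move_dur_mu_log, spec.move_dur_sigma_log))
            k = max(int(round(dur * fps)), 1)
            for _ in range(min(k, n_frames - i)):
                delta = target - pos
                dist = float(np.hypot(*delta))
                if dist <= step * (1 + 1e-9):
                    pos = target
                    target = random_target(pos)
                else:
                    pos = pos + delta / dist * step
                xs[i], ys[i] = pos
                i += 1
            resting = True

    planted_df = pd.DataFrame(planted, columns=["onset_s", "duration_s", "x_px", "y_px"])
    if planted_df.empty:
        raise ValueError("duration_s too short to contain a single rest bout")
    traj = Trajectory(times=np.arange(n_frames) / fps, x=xs, y=ys, fps=fps,
                      chamber_id=ch.kind)
    return SyntheticTrajectory(trajectory=traj, planted=planted_df, spec=spec)


def render_frames(
    traj: Trajectory,
    chamber: Chamber,
    fly_radius_px: float = 3.0,
    fly_intensity: int = 230,
    chamber_intensity: int = 50,
    surround_intensity: int = 150,
) -> np.ndarray:
    """Render a grayscale uint8 stack: bright fly disk, dark chamber, bright surround."""
    if fly_radius_px < 1:
        raise ValueError("fly_radius_px must be >= 1")
    if not fly_intensity > chamber_intensity:
        raise ValueError("fly must be brighter than the chamber background")
    h, w = chamber.frame_shape
    interior = chamber.interior_mask()
    bg = np.where(interior, chamber_intensity, surround_intensity).astype(np.uint8)
    if np.any(traj.x < 0) or np.any(traj.x > w - 1) or np.any(traj.y < 0) or np.any(traj.y > h - 1):
        raise ValueError("trajectory leaves the frame bounds")
    stack = np.empty((len(traj), h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for k in range(len(traj)):
        frame = bg.copy()
        d2 = (xx - traj.x[k]) ** 2 + (yy - traj.y[k]) ** 2
        frame[d2 <= fly_radius_px**2] = fly_intensity
        stack[k] = frame
    return stack
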