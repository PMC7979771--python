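"""Two-hemisphere brain-state random walk generating rest-bout durations.

Each hemisphere occupies one of L quietness states (1..L); the joint brain
state (i, j) performs a continuous-time random walk on the lattice. The
dwell time in state (i, j) is exponential with mean
``theta = (i^2 + j^2)^(a/2)`` — deeper (quieter) states are slower to leave
— and jumps go to a uniformly chosen admissible von Neumann neighbour,
reflecting at i or j = L. The rest bout ends when either hemisphere reaches
state 0 (the wake boundary): its duration is the first-passage time.

When the distance from the origin exceeds ``w_thresh`` the fly is asleep:
an independent wake clock with constant rate ``epsilon`` runs while the
walker is beyond the threshold and ends the bout when it fires. The walk
itself keeps moving (and may re-cross inward, pausing the clock); the
simpler absorb-at-threshold variant is available via
``sleep_dynamics="absorb"``. This competition is what turns the power-law
first-passage head into an exponential sleep tail, reproducing the observed
two-phase survival pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sleep_fit

__all__ = [
    "ModelParams",
    "SimResult",
    "dwell_time_scale",
    "simulate_rest_bout",
    "simulate_bouts",
    "mean_first_passage_oracle",
    "sweep_parameters",
]


@dataclass
class ModelParams:
    """Brain-state walk configuration.

    ``theta_scale`` multiplies every dwell mean and sets the time unit
    (seconds); ``epsilon`` is the wake rate (1/s) in the sleep region.
    """

    L: int = 50
    a: float = 1.0
    w_thresh: float = 10.0
    epsilon: float = 1e-3
    start_state: tuple[int, int] = (1, 1)
    n_bouts: int = 1000
    seed: int | None = None
    theta_scale: float = 1.0
    sleep_dynamics: str = "competing"  # or "absorb"
    threshold_metric: str = "euclidean"  # or "manhattan"

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.w_thresh <= 0:
            raise ValueError("w_thresh must be > 0")
        # w_thresh beyond the lattice diagonal is allowed: the sleep region
        # is then unreachable and no bout is ever flagged as slept.
        i, j = self.start_state
        if not (1 <= i <= self.L and 1 <= j <= self.L):
            raise ValueError("start_state coordinates must be in [1, L]")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")
        if self.sleep_dynamics not in ("competing", "absorb"):
            raise ValueError("sleep_dynamics must be 'competing' or 'absorb'")
        if self.threshold_metric not in ("euclidean", "manhattan"):
            raise ValueError("threshold_metric must be 'euclidean' or 'manhattan'")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "L", "a", "w_thresh", "epsilon", "start_state", "n_bouts", "seed",
            "theta_scale", "sleep_dynamics", "threshold_metric")}
        d["start_state"] = list(self.start_state)
        return d

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            d = json.load(fh)
        d["start_state"] = tuple(d.get("start_state", (1, 1)))
        return cls(**d)


@dataclass
class SimResult:
    """Simulated rest bouts: durations (s), slept flags, latency components."""

    durations: np.ndarray
    slept: np.ndarray
    latency: np.ndarray
    params: ModelParams


def dwell_time_scale(i: float, j: float, a: float) -> float:
    """Mean dwell time theta = (i^2 + j^2)^(a/2) of state (i, j)."""
    if i < 0 or j < 0:
        raise ValueError("state coordinates must be non-negative")
    return float((i * i + j * j) ** (a / 2.0))


def _beyond(i: int, j: int, params: ModelParams) -> bool:
    if params.threshold_metric == "euclidean":
        return i * i + j * j > params.w_thresh**2
    return i + j > params.w_thresh


def simulate_rest_bout(
    params: ModelParams, rng: np.random.Generator
) -> tuple[float, bool, float]:
    """One bout: (duration, slept, latency_component).

    ``latency_component`` is the time of the first threshold crossing for
    bouts that slept (0 for bouts that never crossed).
    """
    L, a, eps = params.L, params.a, params.epsilon
    i, j = params.start_state
    t = 0.0
    slept = False
    latency = 0.0
    while True:
        asleep = _beyond(i, j, params)
        if asleep and not slept:
            slept = True
            latency = t
            if params.sleep_dynamics == "absorb":
                return t + rng.exponential(1.0 / eps), True, latency
        theta = params.theta_scale * (i * i + j * j) ** (a / 2.0)
        jump_rate = 1.0 / theta
        total = jump_rate + (eps if asleep else 0.0)
        t += rng.exponential(1.0 / total)
        if asleep and rng.random() < eps / total:
            return t, True, latency
        moves = []
        if i > 0:
            moves.append((i - 1, j))
        if i < L:
            moves.append((i + 1, j))
        if j > 0:
            moves.append((i, j - 1))
        if j < L:
            moves.append((i, j + 1))
        i, j = moves[rng.integers(len(moves))]
        if i == 0 or j == 0:
            return t, slept, latency


def simulate_bouts(params: ModelParams, rng: np.random.Generator | None = None) -> SimResult:
    """Simulate ``params.n_bouts`` i.i.d. rest bouts."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dur = np.empty(params.n_bouts)
    slept = np.empty(params.n_bouts, dtype=bool)
    lat = np.empty(params.n_bouts)
    for k in range(params.n_bouts):
        dur[k], slept[k], lat[k] = simulate_rest_bout(params, rng)
    return SimResult(durations=dur, slept=slept, latency=lat, params=params)


def mean_first_passage_oracle(params: ModelParams, max_L: int = 12) -> float:
    """Exact expected first-passage time to the wake boundary (epsilon off).

    Solves the linear system E(s) = theta(s) + mean of E over admissible
    neighbours, with E = 0 on the boundary, by a dense solve over the
    interior lattice. Intended as an independent check of the simulator at
    small L.
    """
    L = params.L
    if L > max_L:
        raise ValueError(f"dense oracle limited to L <= {max_L}")
    idx = {(i, j): k for k, (i, j) in enumerate(
        (i, j) for i in range(1, L + 1) for j in range(1, L + 1))}
    n = len(idx)
    A = np.eye(n)
    b = np.empty(n)
    for (i, j), k in idx.items():
        b[k] = params.theta_scale * (i * i + j * j) ** (params.a / 2.0)
        moves = [(i - 1, j)] + ([(i + 1, j)] if i < L else []) \
            + [(i, j - 1)] + ([(i, j + 1)] if j < L else [])
        p = 1.0 / len(moves)
        for m in moves:
            if m in idx:  # boundary states contribute E = 0
                A[k, idx[m]] -= p
    E = np.linalg.solve(A, b)
    return float(E[idx[params.start_state]])


def sweep_parameters(
    a_grid,
    w_grid,
    epsilon: float = 1e-3,
    n_bouts: int = 4000,
    L: int = 50,
    seed: int | None = None,
    xmin: float = 3.0,
    scan_start: float = 50.0,
    alpha: float = 0.10,
    feasible_K: tuple[float, float] = (80.0, 300.0),
) -> pd.DataFrame:
    """Map the (a, w) plane to fitted sleep parameters.

    Each cell simulates ``n_bouts`` bouts and runs the standard fitting
    pipeline (KS latency scan, then the bounded head MLE); cells whose
    fitted latency lands in ``feasible_K`` are flagged feasible — these are
    the model configurations compatible with the latency range observed in
    flies. Per-cell fit failures are recorded in the ``error`` column and
    the sweep continues.
    """
    a_grid = np.asarray(list(a_grid), dtype=float)
    w_grid = np.asarray(list(w_grid), dtype=float)
    if a_grid.size == 0 or w_grid.size == 0:
        raise ValueError("grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(a_grid.size * w_grid.size)
    rows = []
    c = 0
    for a in a_grid:
        for w in w_grid:
            rng = np.random.default_rng(children[c])
            c += 1
            params = ModelParams(L=L, a=float(a), w_thresh=float(w),
                                 epsilon=epsilon, n_bouts=n_bouts)
            sim = simulate_bouts(params, rng)
            row = {"a": a, "w": w, "beta_hat": np.nan, "K_hat": np.nan,
                   "lambda_hat": np.nan, "n_tail": 0, "feasible": False,
                   "error": ""}
            try:
                lat = sleep_fit.find_sleep_latency(
                    sim.durations, scan_start=scan_start, alpha=alpha)
                head = sleep_fit.fit_active_index(sim.durations, xmin=xmin, K=lat.K)
                row.update(beta_hat=head.beta, K_hat=lat.K, lambda_hat=lat.lam,
                           n_tail=lat.n_tail,
                           feasible=feasible_K[0] <= lat.K <= feasible_K[1])
            except (ValueError, sleep_fit.LatencyScanError) as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
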