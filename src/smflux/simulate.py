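"""Synthetic single-molecule data generators.

Every downstream stage of the package assumes a specific statistical
structure in its input; this module generates data with exactly that
structure so the whole pipeline is testable without raw microscope
recordings:

* 2D multi-state Brownian trajectories with continuous-time Markov state
  switching, additive localization noise, and photobleaching truncation;
* single-molecule intensity-time traces with discrete downward bleach steps,
  background, noise, and an optional uneven illumination field;
* FCS auto/cross-correlation curves evaluated from the closed-form models of
  :mod:`smflux.fcs` (shared implementation) with optional noise;
* particle-brightness samples from Gaussian mixtures;
* rendered TIRF-like movies (Gaussian PSF, Poisson + read noise) with a
  ground-truth spot table, for end-to-end detection/linking tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.special import erf

from . import fcs
from .fcs import ACParams, CCParams, CorrelationCurve
from .photobleach import IntensityTrace
from .spotlink import DEFAULT_PIXEL_UM, Spot, Trajectory

__all__ = [
    "TrajectorySimConfig",
    "TraceSimConfig",
    "FCSSimConfig",
    "TraceSimResult",
    "simulate_trajectories",
    "simulate_traces",
    "simulate_correlation",
    "simulate_brightness",
    "render_movie",
    "trajectories_truth_frame",
]


@dataclass
class TrajectorySimConfig:
    """Multi-state Brownian trajectory generator settings.

    ``states`` lists (D in um^2/s, occupancy) pairs; occupancies must sum
    to 1. ``transition_rates`` is a continuous-time generator matrix Q in
    1/s (off-diagonals >= 0, rows sum to 0); state switching is simulated in
    continuous time and sampled at the frame interval ``dt``. None means no
    switching. ``bleach_rate`` truncates trajectories at geometrically
    distributed lengths (default mean trajectory duration 1.6 s at
    dt = 0.1 s); ``loc_sigma`` is the static localization precision added
    independently to every observed position.
    """

    n_traj: int = 100
    n_frames: int = 50
    dt: float = 0.1
    states: list[tuple[float, float]] = dc_field(
        default_factory=lambda: [(0.1, 1.0)]
    )
    transition_rates: np.ndarray | None = None
    loc_sigma: float = 0.02
    bleach_rate: float = 1.0 / 1.6
    fov: tuple[float, float] = (30.0, 30.0)
    brightness: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        occ = np.array([o for _, o in self.states], dtype=float)
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")
        if any(d < 0 for d, _ in self.states):
            raise ValueError("diffusion coefficients must be non-negative")
        if self.transition_rates is not None:
            Q = np.asarray(self.transition_rates, dtype=float)
            K = len(self.states)
            if Q.shape != (K, K):
                raise ValueError("transition_rates must be K x K")
            off = Q[~np.eye(K, dtype=bool)]
            if np.any(off < 0):
                raise ValueError("off-diagonal rates must be >= 0")
            if np.any(np.abs(Q.sum(axis=1)) > 1e-9):
                raise ValueError("generator rows must sum to 0")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be >= 0")


def simulate_trajectories(cfg: TrajectorySimConfig) -> list[Trajectory]:
    """Generate 2D Brownian trajectories with Markov state switching.

    Per-axis displacement variance in state k is ``2 D_k dt``; observed
    positions additionally carry independent N(0, loc_sigma^2) localization
    noise per coordinate, so observed step variance is ``2 D_k dt +
    2 loc_sigma^2``. State sequences follow the continuous-time generator
    discretized at dt; trajectory lengths are truncated at geometric bleach
    times (per-frame survival ``exp(-bleach_rate * dt)``).
    """
    rng = np.random.default_rng(cfg.seed)
    K = len(cfg.states)
    Ds = np.array([d for d, _ in cfg.states])
    occ = np.array([o for _, o in cfg.states])
    if cfg.transition_rates is not None:
        P = expm(np.asarray(cfg.transition_rates, dtype=float) * cfg.dt)
        P = np.clip(P, 0, None)
        P /= P.sum(axis=1, keepdims=True)
    else:
        P = np.eye(K)

    out: list[Trajectory] = []
    surv = np.exp(-cfg.bleach_rate * cfg.dt) if cfg.bleach_rate > 0 else 1.0
    for i in range(cfg.n_traj):
        if surv < 1.0:
            n_obs = min(int(rng.geometric(1.0 - surv)), cfg.n_frames)
        else:
            n_obs = cfg.n_frames
        n_obs = max(n_obs, 2)
        state = rng.choice(K, p=occ)
        states = np.empty(n_obs - 1, dtype=int)
        for t in range(n_obs - 1):
            states[t] = state
            state = rng.choice(K, p=P[state])
        steps = rng.normal(0.0, 1.0, size=(n_obs - 1, 2)) * np.sqrt(
            2.0 * Ds[states] * cfg.dt
        )[:, None]
        start = rng.uniform([0, 0], cfg.fov)
        true_xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
        obs_xy = true_xy + rng.normal(0.0, cfg.loc_sigma, size=true_xy.shape)
        spots = [
            Spot(frame=t, x=float(x), y=float(y), I=cfg.brightness)
            for t, (x, y) in enumerate(obs_xy)
        ]
        out.append(Trajectory(id=i, spots=spots))
    return out


def trajectories_truth_frame(trajectories: list[Trajectory], dt: float) -> pd.DataFrame:
    """Ground-truth table (frame, id, x_um, y_um, I) for rendered movies."""
    rows = [
        (s.frame, tr.id, s.x, s.y, s.I) for tr in trajectories for s in tr.spots
    ]
    return pd.DataFrame(rows, columns=["frame", "id", "x_um", "y_um", "I"])


@dataclass
class TraceSimConfig:
    """Photobleaching trace generator settings.

    Each trace carries ``n`` fluorophores (drawn from ``n_steps_dist``, a
    mapping subunit count -> probability) of common per-fluorophore
    brightness drawn from N(brightness_mean, brightness_sd). Fluorophores
    bleach independently at exponential times with mean ``bleach_tau``; the
    trace drops by one brightness unit at each bleach. Gaussian noise of sd
    ``noise_sd`` is added per frame on top of ``background``; an optional
    strictly positive ``illumination_field`` multiplies the signal (sampled
    at a random position per trace).
    """

    n_traces: int = 300
    n_frames: int = 200
    frame_dt: float = 0.5
    brightness_mean: float = 4.4
    brightness_sd: float = 0.88
    n_steps_dist: dict[int, float] = dc_field(default_factory=lambda: {1: 1.0})
    bleach_tau: float = 14.7
    noise_sd: float = 1.0
    background: float = 0.0
    illumination_field: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bleach_tau <= 0:
            raise ValueError("bleach_tau must be positive")
        if self.brightness_mean <= 0:
            raise ValueError("brightness_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")
        probs = np.array(list(self.n_steps_dist.values()), dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
            raise ValueError("n_steps_dist must be a probability distribution")
        if self.illumination_field is not None and np.any(
            np.asarray(self.illumination_field) <= 0
        ):
            raise ValueError("illumination field must be strictly positive")


class TraceSimResult(NamedTuple):
    traces: list[IntensityTrace]
    truth: pd.DataFrame  # trace_id, n_steps, I0, bleach_times (list), illum


def simulate_traces(cfg: TraceSimConfig) -> TraceSimResult:
    """Generate stepwise-bleaching intensity traces with ground truth.

    Returns the traces together with a truth table recording, per trace, the
    subunit count, the noise-free initial intensity I0 (signal only, above
    background), the fluorophore bleach times, and the illumination factor.
    """
    rng = np.random.default_rng(cfg.seed)
    ns = np.array(sorted(cfg.n_steps_dist), dtype=int)
    ps = np.array([cfg.n_steps_dist[int(n)] for n in ns], dtype=float)
    t = np.arange(cfg.n_frames) * cfg.frame_dt
    field = cfg.illumination_field

    traces, rows = [], []
    for i in range(cfg.n_traces):
        n = int(rng.choice(ns, p=ps))
        b = rng.normal(cfg.brightness_mean, cfg.brightness_sd)
        b = max(b, 0.1 * cfg.brightness_mean)
        if field is not None:
            fy = rng.integers(0, field.shape[0])
            fx = rng.integers(0, field.shape[1])
            illum = float(field[fy, fx])
        else:
            illum = 1.0
        bleach_times = np.sort(rng.exponential(cfg.bleach_tau, size=n))
        alive = (t[:, None] < bleach_times[None, :]).sum(axis=1)
        signal = alive * b * illum
        y = signal + cfg.background
        if cfg.noise_sd > 0:
            y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.n_frames)
        traces.append(IntensityTrace(intensity=y, frame_dt=cfg.frame_dt))
        rows.append((i, n, n * b * illum, list(bleach_times), illum))
    truth = pd.DataFrame(rows, columns=["trace_id", "n_steps", "I0", "bleach_times", "illum"])
    return TraceSimResult(traces=traces, truth=truth)


@dataclass
class FCSSimConfig:
    """Correlation-curve synthesis settings.

    ``ac_params`` may be a single :class:`~smflux.fcs.ACParams` or a mapping
    of channel name ('green'/'red') to parameters; an optional ``cc_params``
    adds a cross-correlation channel. ``noise_sd`` is relative (per lag bin,
    scaled by the local model value); with ``n_repeats > 1`` the returned
    curves carry the per-lag std across repeats.
    """

    ac_params: ACParams | dict[str, ACParams] | None = None
    cc_params: CCParams | None = None
    lag_grid: np.ndarray = dc_field(
        default_factory=lambda: np.logspace(-4, 1, 160)
    )
    noise_sd: float = 0.0
    n_repeats: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_grid, dtype=float)
        if np.any(lag <= 0) or np.any(np.diff(lag) <= 0):
            raise ValueError("lag grid must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def _synth_one(model_G, lag, noise_sd, n_repeats, rng, channel) -> CorrelationCurve:
    if noise_sd == 0:
        return CorrelationCurve(lag=lag, G=model_G.copy(), std=None, channel=channel)
    reps = model_G[None, :] + rng.normal(
        0.0, noise_sd, size=(n_repeats, len(lag))
    ) * np.abs(model_G)[None, :]
    G = reps.mean(axis=0)
    std = reps.std(axis=0, ddof=1) if n_repeats > 1 else None
    return CorrelationCurve(lag=lag, G=G, std=std, channel=channel)


def simulate_correlation(
    cfg: FCSSimConfig,
) -> CorrelationCurve | dict[str, CorrelationCurve]:
    """Synthesize correlation curves from the closed-form models.

    At zero noise the curves equal :func:`smflux.fcs.ac_model` /
    :func:`smflux.fcs.cc_model` on the lag grid to machine precision (the
    model implementation is shared). Returns a single curve when only one
    channel is configured, otherwise a dict keyed by channel name
    ('green'/'red'/'cross').
    """
    rng = np.random.default_rng(cfg.seed)
    lag = np.asarray(cfg.lag_grid, dtype=float)
    out: dict[str, CorrelationCurve] = {}
    ac = cfg.ac_params
    if isinstance(ac, ACParams):
        ac = {"green": ac}
    if ac:
        for channel, p in ac.items():
            out[channel] = _synth_one(
                fcs.ac_model(lag, p), lag, cfg.noise_sd, cfg.n_repeats, rng, channel
            )
    if cfg.cc_params is not None:
        out["cross"] = _synth_one(
            fcs.cc_model(lag, cfg.cc_params), lag, cfg.noise_sd, cfg.n_repeats, rng, "cross"
        )
    if not out:
        raise ValueError("configure at least one of ac_params / cc_params")
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def simulate_brightness(
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    n: int,
    seed: int | None = None,
) -> np.ndarray:
    """Draw particle-brightness samples (kHz) from a Gaussian mixture."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), size=n, p=weights)
    return rng.normal(means[comp], sds[comp])


def render_movie(
    spots_truth: pd.DataFrame,
    psf_sigma: float = 0.13,
    pixel: float = DEFAULT_PIXEL_UM,
    noise_model: dict | None = None,
    *,
    shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Render a TIRF-like movie from a ground-truth spot table.

    ``spots_truth`` must have columns frame, x_um, y_um, I (I is the
    integrated spot intensity in camera counts). Each spot is drawn as a
    pixel-integrated 2D Gaussian PSF of sd ``psf_sigma`` (um). The EMCCD
    noise model is Poisson shot noise on signal + background plus Gaussian
    read noise: ``noise_model = {"background": counts, "read_sd": counts}``;
    None renders noiselessly with zero background.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    req = {"frame", "x_um", "y_um", "I"}
    if not req.issubset(spots_truth.columns):
        raise ValueError(f"spots_truth needs columns {sorted(req)}")
    if n_frames is None:
        n_frames = int(spots_truth["frame"].max()) + 1 if len(spots_truth) else 1
    if shape is None:
        if len(spots_truth):
            nx = int(np.ceil(spots_truth["x_um"].max() / pixel)) + 8
            ny = int(np.ceil(spots_truth["y_um"].max() / pixel)) + 8
        else:
            ny = nx = 32
        shape = (ny, nx)
    ny, nx = shape
    stack = np.zeros((n_frames, ny, nx))
    s_px = psf_sigma / pixel
    half = max(int(np.ceil(4 * s_px)), 2)

    for row in spots_truth.itertuples():
        f = int(row.frame)
        if not 0 <= f < n_frames:
            continue
        cx = row.x_um / pixel
        cy = row.y_um / pixel
        if not (0 <= cx < nx and 0 <= cy < ny):
            raise ValueError("spot position outside the field of view")
        c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 2, nx)
        r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 2, ny)
        xs = np.arange(c0, c1)
        ys = np.arange(r0, r1)
        # exact pixel integration of the Gaussian via the error function
        fx = 0.5 * (
            erf((xs + 0.5 - cx) / (np.sqrt(2) * s_px))
            - erf((xs - 0.5 - cx) / (np.sqrt(2) * s_px))
        )
        fy = 0.5 * (
            erf((ys + 0.5 - cy) / (np.sqrt(2) * s_px))
            - erf((ys - 0.5 - cy) / (np.sqrt(2) * s_px))
        )
        stack[f, r0:r1, c0:c1] += row.I * np.outer(fy, fx)

    if noise_model:
        rng = np.random.default_rng(seed)
        bg = float(noise_model.get("background", 0.0))
        read_sd = float(noise_model.get("read_sd", 0.0))
        stack = rng.poisson(stack + bg).astype(float)
        if read_sd > 0:
            stack = stack + rng.normal(0.0, read_sd, size=stack.shape)
    return stack
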