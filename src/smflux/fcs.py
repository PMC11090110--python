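"""Fluorescence correlation spectroscopy (FCS) and dual-color FCS models.

Closed-form correlation models for 2D (membrane) diffusion with an optional
photophysical dark state, weighted nonlinear least-squares fitting, conversion
of the fitted residence time to a diffusion coefficient (``D = w^2 / 4 tau_D``),
surface-density estimation from the mean molecule number, and the
amplitude-ratio codiffusion fraction used in dual-color cross-correlation.

Model conventions
-----------------
The autocorrelation of a 2D (possibly anomalous) diffusing species with a
single dark state is taken in the standard multiplicative form

    G(tau) = (1/<N>) * [1 + (tau/tau_D)^alpha]^-1
             * [1 + f_ds/(1 - f_ds) * exp(-tau/tau_ds)]

and the cross-correlation of the codiffusing species, whose channel-specific
photophysics are uncorrelated, carries no dark-state term:

    G_x(tau) = N_x / (N_g * N_r) * [1 + (tau/tau_Dx)^alpha_x]^-1
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import lmfit

__all__ = [
    "CorrelationCurve",
    "ACParams",
    "CCParams",
    "DcFCSConfig",
    "FCSFitResult",
    "ac_model",
    "cc_model",
    "fit_curve",
    "compute_fcd",
    "density_from_fcs",
    "calibrate_w",
    "read_curve",
    "write_curve",
    "diffusion_coefficient",
]

#: Default fit window in seconds: focuses on membrane diffusion and excludes
#: sub-100-us photophysics as well as lags beyond the acquisition time.
FIT_WINDOW = (1e-4, 10.0)


@dataclass(frozen=True)
class ACParams:
    """Autocorrelation model parameters (single channel).

    Attributes
    ----------
    N_mean : mean number of molecules in the detection area, > 0.
    tau_D : mean residence (diffusion) time in seconds, > 0.
    alpha : anomalous-diffusion exponent, in (0, 1.5]; 1 is Brownian.
    tau_ds : dark-state lifetime in seconds (ignored when ``f_ds == 0``).
    f_ds : dark-state population fraction, in [0, 1).
    """

    N_mean: float
    tau_D: float
    alpha: float = 1.0
    tau_ds: float = 1e-3
    f_ds: float = 0.0

    def __post_init__(self) -> None:
        if self.N_mean <= 0:
            raise ValueError("N_mean must be positive")
        if self.tau_D <= 0:
            raise ValueError("tau_D must be positive")
        if not 0 < self.alpha <= 1.5:
            raise ValueError("alpha must lie in (0, 1.5]")
        if not 0 <= self.f_ds < 1:
            raise ValueError("f_ds must lie in [0, 1)")
        if self.f_ds > 0 and self.tau_ds <= 0:
            raise ValueError("tau_ds must be positive when f_ds > 0")


@dataclass(frozen=True)
class CCParams:
    """Cross-correlation model parameters for dual-color FCS.

    ``N_g`` and ``N_r`` are the mean numbers of green and red molecules in the
    common detection area and ``N_x`` the mean number of codiffusing species;
    ``0 <= N_x <= min(N_g, N_r)``.
    """

    N_g: float
    N_r: float
    N_x: float
    tau_Dx: float = 0.1
    alpha_x: float = 1.0

    def __post_init__(self) -> None:
        if self.N_g <= 0 or self.N_r <= 0:
            raise ValueError("N_g and N_r must be positive")
        if not 0 <= self.N_x <= min(self.N_g, self.N_r) + 1e-12:
            raise ValueError("N_x must lie in [0, min(N_g, N_r)]")
        if self.tau_Dx <= 0:
            raise ValueError("tau_Dx must be positive")


@dataclass(frozen=True)
class DcFCSConfig:
    """Dual-color geometry: overlap-volume correction factors and beam waists (um)."""

    OVCF_g: float = 1.0
    OVCF_r: float = 1.0
    w_g: float = 0.25
    w_r: float = 0.25

    def __post_init__(self) -> None:
        if self.OVCF_g <= 0 or self.OVCF_r <= 0:
            raise ValueError("OVCF factors must be positive")
        if self.w_g <= 0 or self.w_r <= 0:
            raise ValueError("beam waists must be positive")


@dataclass
class CorrelationCurve:
    """A lag-binned correlation curve G(tau), optionally with per-lag std."""

    lag: np.ndarray
    G: np.ndarray
    std: np.ndarray | None = None
    channel: Literal["green", "red", "cross"] = "green"

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lag.ndim != 1 or self.lag.shape != self.G.shape:
            raise ValueError("lag and G must be 1D arrays of equal length")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.lag <= 0):
            raise ValueError("lags must be positive")
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)
            if self.std.shape != self.lag.shape:
                raise ValueError("std must match lag shape")
            if np.any(self.std < 0):
                raise ValueError("std must be non-negative")


@dataclass
class FCSFitResult:
    """Outcome of a weighted correlation-curve fit."""

    params: ACParams | CCParams
    D: float | None
    density: float | None
    residuals: np.ndarray
    redchi: float
    success: bool
    message: str = ""
    stderr: dict = field(default_factory=dict)


def ac_model(lag: np.ndarray | float, p: ACParams) -> np.ndarray:
    """Evaluate the 2D anomalous-diffusion + dark-state autocorrelation."""
    lag = np.asarray(lag, dtype=float)
    diff = 1.0 / (1.0 + (lag / p.tau_D) ** p.alpha)
    if p.f_ds > 0:
        photo = 1.0 + p.f_ds / (1.0 - p.f_ds) * np.exp(-lag / p.tau_ds)
    else:
        photo = 1.0
    return diff * photo / p.N_mean


def cc_model(lag: np.ndarray | float, p: CCParams) -> np.ndarray:
    """Evaluate the dual-color cross-correlation (no photophysics term)."""
    lag = np.asarray(lag, dtype=float)
    amp = p.N_x / (p.N_g * p.N_r)
    return amp / (1.0 + (lag / p.tau_Dx) ** p.alpha_x)


def diffusion_coefficient(tau_D: float, w: float) -> float:
    """Convert a residence time to a diffusion coefficient, D = w^2 / (4 tau_D)."""
    if tau_D <= 0 or w <= 0:
        raise ValueError("tau_D and w must be positive")
    return w * w / (4.0 * tau_D)


def calibrate_w(tau_D_ref: float, D_ref: float) -> float:
    """Beam-waist calibration from a reference dye: w = sqrt(4 D_ref tau_D_ref)."""
    if tau_D_ref <= 0 or D_ref <= 0:
        raise ValueError("reference values must be positive")
    return math.sqrt(4.0 * D_ref * tau_D_ref)


def density_from_fcs(N_mean: float, w: float) -> float:
    """Surface density (molecules / um^2) = <N> / (pi w^2)."""
    if w <= 0:
        raise ValueError("w must be positive")
    if N_mean < 0:
        raise ValueError("N_mean must be non-negative")
    return N_mean / (math.pi * w * w)


def _window_mask(lag: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (lag >= lo) & (lag <= hi)


def _initial_grid_ac(lag: np.ndarray, G: np.ndarray) -> list[dict]:
    """Deterministic multi-start initial guesses for the AC fit."""
    G0 = max(float(G[0]), 1e-12)
    n0 = 1.0 / G0
    # half-decay lag as tau_D seed
    half = G0 / 2.0
    below = np.nonzero(G <= half)[0]
    tau_seed = float(lag[below[0]]) if below.size else float(lag[len(lag) // 2])
    grid = []
    for tau_fac in (1.0, 0.3, 3.0):
        for f_ds in (0.0, 0.2):
            grid.append(
                dict(N_mean=n0, tau_D=tau_seed * tau_fac, alpha=1.0, tau_ds=1e-3, f_ds=f_ds)
            )
    return grid


def fit_curve(
    curve: CorrelationCurve,
    model: Literal["ac", "cc"] = "ac",
    init: dict | None = None,
    bounds: dict | None = None,
    weights: np.ndarray | None = None,
    *,
    w: float | None = None,
    window: tuple[float, float] = FIT_WINDOW,
    fix: Sequence[str] = (),
) -> FCSFitResult:
    """Weighted least-squares fit of a correlation model to a measured curve.

    The fit is restricted to lags inside ``window``. Weights default to
    ``1/std`` where the curve carries per-lag standard deviations and to
    uniform weights otherwise. For the AC model a deterministic grid of
    starting points is tried and the lowest-chi-square solution returned, so
    the result is reproducible with no RNG in the optimizer path.

    Parameters named in ``fix`` are held at their initial values (e.g.
    ``fix=("alpha", "f_ds")`` for a pure Brownian fit).

    Passing the beam waist ``w`` (um) also reports ``D = w^2/(4 tau_D)`` and
    the surface density ``<N>/(pi w^2)``.
    """
    mask = _window_mask(curve.lag, window)
    if mask.sum() < 10:
        raise ValueError("need at least 10 lag points inside the fit window")
    lag = curve.lag[mask]
    g = curve.G[mask]
    if weights is not None:
        wts = np.asarray(weights, dtype=float)[mask]
    elif curve.std is not None and np.all(curve.std[mask] > 0):
        wts = 1.0 / curve.std[mask]
    else:
        wts = np.ones_like(lag)

    if model == "ac":
        return _fit_ac(lag, g, wts, init, bounds, w, fix)
    if model == "cc":
        return _fit_cc(lag, g, wts, init, bounds, w, fix)
    raise ValueError(f"unknown model {model!r}")


def _fit_ac(lag, g, wts, init, bounds, w, fix) -> FCSFitResult:
    bounds = bounds or {}

    def make_params(start: dict) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("N_mean", value=start["N_mean"], min=1e-6, max=1e9)
        p.add("tau_D", value=start["tau_D"], min=1e-6, max=1e3)
        p.add("alpha", value=start.get("alpha", 1.0), min=0.3, max=1.5)
        p.add("tau_ds", value=start.get("tau_ds", 1e-3), min=1e-6, max=1.0)
        p.add("f_ds", value=start.get("f_ds", 0.0), min=0.0, max=0.95)
        for name, (lo, hi) in bounds.items():
            p[name].min, p[name].max = lo, hi
        for name in fix:
            p[name].vary = False
        return p

    def resid(p):
        mp = ACParams(
            N_mean=p["N_mean"].value,
            tau_D=p["tau_D"].value,
            alpha=p["alpha"].value,
            tau_ds=max(p["tau_ds"].value, 1e-12),
            f_ds=p["f_ds"].value,
        )
        return (ac_model(lag, mp) - g) * wts

    starts = [init] if init is not None else _initial_grid_ac(lag, g)
    best = None
    for start in starts:
        try:
            out = lmfit.minimize(resid, make_params(start), method="leastsq", xtol=1e-12, ftol=1e-12)
        except Exception:  # singular starts are allowed to fail quietly
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("all AC fit starts failed")

    pv = best.params
    fitted = ACParams(
        N_mean=pv["N_mean"].value,
        tau_D=pv["tau_D"].value,
        alpha=pv["alpha"].value,
        tau_ds=max(pv["tau_ds"].value, 1e-12),
        f_ds=pv["f_ds"].value,
    )
    D = diffusion_coefficient(fitted.tau_D, w) if w else None
    dens = density_from_fcs(fitted.N_mean, w) if w else None
    return FCSFitResult(
        params=fitted,
        D=D,
        density=dens,
        residuals=np.asarray(best.residual),
        redchi=float(best.redchi),
        success=bool(best.success),
        message=best.message,
        stderr={k: (pv[k].stderr or float("nan")) for k in pv},
    )


def _fit_cc(lag, g, wts, init, bounds, w, fix) -> FCSFitResult:
    bounds = bounds or {}
    init = init or {}
    g0 = max(float(g[0]), 1e-12)
    half = np.nonzero(g <= g0 / 2)[0]
    tau_seed = float(lag[half[0]]) if half.size else float(lag[len(lag) // 2])

    p = lmfit.Parameters()
    # amplitude and decay are the identifiable quantities; channel populations
    # are fixed inputs from the AC fits
    p.add("N_g", value=init.get("N_g", 10.0), vary=False)
    p.add("N_r", value=init.get("N_r", 10.0), vary=False)
    p.add("N_x", value=init.get("N_x", g0 * init.get("N_g", 10.0) * init.get("N_r", 10.0)),
          min=0.0)
    p.add("tau_Dx", value=init.get("tau_Dx", tau_seed), min=1e-6, max=1e3)
    p.add("alpha_x", value=init.get("alpha_x", 1.0), min=0.3, max=1.5)
    for name, (lo, hi) in bounds.items():
        p[name].min, p[name].max = lo, hi
    for name in fix:
        p[name].vary = False

    def resid(pp):
        mp = CCParams(
            N_g=pp["N_g"].value,
            N_r=pp["N_r"].value,
            N_x=min(pp["N_x"].value, min(pp["N_g"].value, pp["N_r"].value)),
            tau_Dx=pp["tau_Dx"].value,
            alpha_x=pp["alpha_x"].value,
        )
        return (cc_model(lag, mp) - g) * wts

    out = lmfit.minimize(resid, p, method="leastsq", xtol=1e-12, ftol=1e-12)
    pv = out.params
    fitted = CCParams(
        N_g=pv["N_g"].value,
        N_r=pv["N_r"].value,
        N_x=min(pv["N_x"].value, min(pv["N_g"].value, pv["N_r"].value)),
        tau_Dx=pv["tau_Dx"].value,
        alpha_x=pv["alpha_x"].value,
    )
    D = diffusion_coefficient(fitted.tau_Dx, w) if w else None
    return FCSFitResult(
        params=fitted,
        D=D,
        density=None,
        residuals=np.asarray(out.residual),
        redchi=float(out.redchi),
        success=bool(out.success),
        message=out.message,
        stderr={k: (pv[k].stderr or float("nan")) for k in pv},
    )


def compute_fcd(
    Gx0: float, Gg0: float, Gr0: float, cfg: DcFCSConfig | None = None
) -> tuple[float, float, float]:
    """Codiffusion fractions from dual-color correlation amplitudes.

    With ideal amplitudes ``G_g(0) = 1/N_g``, ``G_r(0) = 1/N_r`` and
    ``G_x(0) = N_x/(N_g N_r)``, the amplitude ratios estimate the fraction of
    each species comoving with the other:

        fcd_g = G_x(0) / (G_r(0) * OVCF_g)   # = N_x / N_g
        fcd_r = G_x(0) / (G_g(0) * OVCF_r)   # = N_x / N_r

    Because dual labeling is stochastic, the smaller of the two is reported as
    the codiffusion (oligomer) fraction and should be read as a lower limit.

    Returns ``(fcd_g, fcd_r, fcd_min)``.
    """
    cfg = cfg or DcFCSConfig()
    if Gg0 <= 0 or Gr0 <= 0:
        raise ValueError("autocorrelation amplitudes must be positive")
    fcd_g = Gx0 / (Gr0 * cfg.OVCF_g)
    fcd_r = Gx0 / (Gg0 * cfg.OVCF_r)
    return fcd_g, fcd_r, min(fcd_g, fcd_r)


def write_curve(path, curve: CorrelationCurve) -> None:
    """Write a curve as whitespace-separated text: lag_s  G  [std]."""
    cols = [curve.lag, curve.G]
    if curve.std is not None:
        cols.append(curve.std)
    np.savetxt(path, np.column_stack(cols), header="lag_s G" + (" std" if curve.std is not None else ""))


def read_curve(path, channel: Literal["green", "red", "cross"] = "green") -> CorrelationCurve:
    """Read a two- or three-column whitespace text curve (lag_s, G, optional std)."""
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.shape[1] < 2:
        raise ValueError("curve file needs at least two columns (lag, G)")
    std = arr[:, 2] if arr.shape[1] >= 3 else None
    return CorrelationCurve(lag=arr[:, 0], G=arr[:, 1], std=std, channel=channel)
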