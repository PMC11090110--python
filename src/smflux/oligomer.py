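"""Oligomer fraction estimation from particle-brightness distributions.

Diffraction-limited particles containing n fluorophores are n times brighter
on average than monomers, so the distribution of initial particle intensities
in an SPT movie is a mixture of Gaussians at roughly integer multiples of the
monomer brightness I_m. A monomeric control protein imaged under identical
conditions provides I_m as a prior; a 1- vs 2-component Gaussian-mixture fit
then yields the monomer/oligomer area fractions. Because transient
colocalization of independently diffusing particles is not excluded, the
oligomer fraction is an upper limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spotlink import Trajectory

__all__ = ["MixtureFit", "initial_intensities", "fit_mixture"]


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture over particle brightnesses.

    ``fractions_by_area`` maps 'monomer'/'oligomer' to the mixture-weight
    (area) fractions; the oligomer number is an upper limit since transient
    colocalization events are not excluded.
    """

    n_comp: int
    means: np.ndarray              # kHz, ascending
    sds: np.ndarray                # kHz
    weights: np.ndarray            # sum to 1
    fractions_by_area: dict[str, float]
    criterion: float               # BIC
    loglik: float
    note: str = "oligomer fraction is an upper limit (transient colocalization not excluded)"
    converged: bool = True


def initial_intensities(
    trajectories: list[Trajectory],
    n_frames: int = 20,
) -> np.ndarray:
    """Per-particle mean brightness over its detections within the first frames.

    Only the movie's initial frames (default 20, i.e. 2 s at 10 fps) are used
    so that photobleaching within a trajectory does not dilute the intensity
    distribution. Particles with no detection in that window are excluded.
    """
    out = []
    for tr in trajectories:
        sel = tr.frames < n_frames
        if sel.any():
            out.append(float(tr.intensities[sel].mean()))
    return np.asarray(out)


def _gauss_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def _fit_two_component(
    x: np.ndarray,
    monomer_prior: tuple[float, float],
    dimer_mean_bounds: tuple[float, float],
    prior_weight: float,
    max_iter: int,
    tol: float,
    tie_cv: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """EM for a 2-component Gaussian mixture with a soft monomer anchor.

    The monomer mean carries a Gaussian penalty centred on the control-derived
    prior (strength ``prior_weight`` pseudo-observations); the second mean is
    projected into ``dimer_mean_bounds`` after each M step.

    With ``tie_cv`` the two components share a single coefficient of
    variation (sd proportional to mean), reflecting that particle-brightness
    spread scales with brightness; this strongly stabilizes the weight
    estimate when the components overlap. Without it each sd is free.
    """
    mu_p, sd_p = monomer_prior
    mu = np.array([mu_p, 2.0 * mu_p])
    cv = max(sd_p / mu_p, 1e-3)
    sd = np.array([max(sd_p, 1e-3)] * 2)
    w = np.array([0.7, 0.3])
    ll_prev = -np.inf
    for _ in range(max_iter):
        if tie_cv:
            sd = cv * mu
        logp = np.stack([
            _gauss_logpdf(x, mu[k], sd[k]) + np.log(max(w[k], 1e-300))
            for k in range(2)
        ])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        resp = np.exp(logp - lse)
        ll = float(lse.sum())
        nk = resp.sum(axis=1)
        w = nk / nk.sum()
        # monomer mean with conjugate-style soft anchor
        mu0 = (resp[0] @ x + prior_weight * mu_p) / (nk[0] + prior_weight)
        mu1 = (resp[1] @ x) / max(nk[1], 1e-12)
        mu1 = float(np.clip(mu1, *dimer_mean_bounds))
        mu = np.array([mu0, mu1])
        if tie_cv:
            cv2 = sum(resp[k] @ ((x - mu[k]) ** 2 / mu[k] ** 2) for k in range(2)) / len(x)
            cv = np.sqrt(max(cv2, 1e-8))
            sd = cv * mu
        else:
            for k in range(2):
                var = (resp[k] @ (x - mu[k]) ** 2) / max(nk[k], 1e-12)
                sd[k] = np.sqrt(max(var, 1e-8))
        if abs(ll - ll_prev) < tol * (abs(ll_prev) + 1e-12):
            break
        ll_prev = ll
    return mu, sd, w, ll


def fit_mixture(
    sample: np.ndarray,
    monomer_prior: tuple[float, float],
    max_comp: int = 2,
    *,
    prior_weight: float = 10.0,
    dimer_mean_range: tuple[float, float] = (1.5, 2.5),
    max_iter: int = 500,
    tol: float = 1e-10,
    min_samples: int = 200,
    tie_cv: bool = True,
) -> MixtureFit:
    """Fit 1- and 2-component brightness mixtures and report area fractions.

    ``monomer_prior`` is the (mean, sd) of the monomer brightness from the
    control protein; the monomer component is softly anchored to it and the
    second component's mean is constrained to ``dimer_mean_range`` times the
    monomer mean (dimer hypothesis). By default the two components share one
    coefficient of variation (``tie_cv``): brightness spread scales with
    brightness, and tying it keeps the weight estimate stable where the
    components overlap; set ``tie_cv=False`` for fully free sds. Model
    choice is by BIC with ties broken toward fewer components; the oligomer
    fraction is the mixture weight ("area under the Gaussian") of the
    higher-mean component.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if len(x) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(x)}")
    mu_p, sd_p = monomer_prior
    if mu_p <= 0:
        raise ValueError("monomer prior mean must be positive")

    n = len(x)
    if float(x.std()) <= 1e-12 * max(1.0, abs(float(x.mean()))):
        return MixtureFit(
            n_comp=1,
            means=np.array([x.mean()]),
            sds=np.array([0.0]),
            weights=np.array([1.0]),
            fractions_by_area={"monomer": 1.0, "oligomer": 0.0},
            criterion=float("-inf"),
            loglik=float("inf"),
        )

    # one component: closed-form MLE
    mu1, sd1 = float(x.mean()), float(x.std())
    ll1 = float(_gauss_logpdf(x, mu1, sd1).sum())
    bic1 = -2.0 * ll1 + 2 * np.log(n)

    results = {1: (np.array([mu1]), np.array([sd1]), np.array([1.0]), ll1, bic1)}

    if max_comp >= 2:
        bounds = (dimer_mean_range[0] * mu_p, dimer_mean_range[1] * mu_p)
        mu, sd, w, ll2 = _fit_two_component(
            x, monomer_prior, bounds, prior_weight, max_iter, tol, tie_cv
        )
        order = np.argsort(mu)
        mu, sd, w = mu[order], sd[order], w[order]
        n_params = 4 if tie_cv else 5   # means + weight + cv (or 2 sds)
        bic2 = -2.0 * ll2 + n_params * np.log(n)
        results[2] = (mu, sd, w, ll2, bic2)

    # parsimony tie-break: 2 components must beat 1 strictly
    best_k = 1
    if 2 in results and results[2][4] < results[1][4]:
        best_k = 2
    mu, sd, w, ll, bic = results[best_k]
    monomer_frac = float(w[0]) if best_k == 2 else 1.0
    return MixtureFit(
        n_comp=best_k,
        means=mu,
        sds=sd,
        weights=w,
        fractions_by_area={"monomer": monomer_frac, "oligomer": 1.0 - monomer_frac},
        criterion=float(bic),
        loglik=float(ll),
    )
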