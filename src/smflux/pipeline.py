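"""End-to-end pipeline orchestration and the synthetic demo suite.

`run_pipeline` executes the requested stages (simulate -> track -> hmm /
smpb / fcs / oligomer) in dependency order from a single structured config,
writing versioned outputs plus a JSON manifest (inputs, parameters, output
hashes, package version, seed). Runs are idempotent for a fixed config and
seed.

`demo_report` runs the package's parameter-recovery suite on synthetic data
generated at the study's printed conditions and returns the recovered
headline quantities; it backs the ``smflux demo`` CLI verb.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import diffusion_hmm, fcs, oligomer, photobleach, simulate, spotlink

__all__ = ["RunConfig", "run_pipeline", "demo_report"]

log = logging.getLogger("smflux")

_STAGE_ORDER = ["simulate", "track", "hmm", "smpb", "fcs", "oligomer"]


@dataclass
class RunConfig:
    """Pipeline run settings: stages, per-stage parameter blocks, seed, output dir."""

    stages: list[str]
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | Path = "smflux_run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    """Raised when a stage cannot run; the message names the stage."""


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, list[str]] = {}
    ordered = [s for s in _STAGE_ORDER if s in cfg.stages]
    artifacts: dict[str, Path] = {}

    for stage in ordered:
        p = dict(cfg.params.get(stage, {}))
        log.info("running stage %s", stage)
        if stage == "simulate":
            outputs[stage] = _stage_simulate(p, cfg.seed, outdir, artifacts)
        elif stage == "track":
            outputs[stage] = _stage_track(p, outdir, artifacts)
        elif stage == "hmm":
            outputs[stage] = _stage_hmm(p, cfg.seed, outdir, artifacts)
        elif stage == "smpb":
            outputs[stage] = _stage_smpb(p, cfg.seed, outdir, artifacts)
        elif stage == "fcs":
            outputs[stage] = _stage_fcs(p, cfg.seed, outdir, artifacts)
        elif stage == "oligomer":
            outputs[stage] = _stage_oligomer(p, cfg.seed, outdir, artifacts)

    manifest = {
        "package": "smflux",
        "version": __version__,
        "seed": cfg.seed,
        "stages": ordered,
        "params": cfg.params,
        "outputs": {
            k: {f: _sha256(outdir / f) for f in v} for k, v in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(p, seed, outdir, artifacts):
    sim_cfg = simulate.TrajectorySimConfig(seed=seed, **p.get("trajectories", {}))
    trajs = simulate.simulate_trajectories(sim_cfg)
    truth = simulate.trajectories_truth_frame(trajs, sim_cfg.dt)
    truth_csv = "truth_trajectories.csv"
    truth.to_csv(outdir / truth_csv, index=False)
    traj_csv = "simulated_trajectories.csv"
    spotlink.trajectories_to_frame(trajs, sim_cfg.dt).to_csv(outdir / traj_csv, index=False)
    artifacts["trajectories_csv"] = outdir / traj_csv
    written = [truth_csv, traj_csv]
    if p.get("render_movie", False):
        import tifffile

        stack = simulate.render_movie(
            truth, seed=seed, noise_model=p.get("noise_model"), **p.get("render", {})
        )
        tif = "simulated_movie.tif"
        tifffile.imwrite(outdir / tif, stack.astype(np.float32))
        artifacts["movie_tif"] = outdir / tif
        written.append(tif)
    return written


def _stage_track(p, outdir, artifacts):
    import tifffile

    tif = p.get("input") or artifacts.get("movie_tif")
    if tif is None or not Path(tif).exists():
        raise StageError("track: no input TIFF (provide params['track']['input'] "
                         "or run the simulate stage with render_movie)")
    stack = tifffile.imread(tif)
    pixel = p.get("pixel", spotlink.DEFAULT_PIXEL_UM)
    dt = p.get("dt", 0.1)
    by_frame = {
        f: spotlink.detect_spots(
            stack[f], p.get("est_diameter", 0.8), p.get("threshold"),
            pixel_um=pixel, frame=f,
        )
        for f in range(stack.shape[0])
    }
    trajs = spotlink.link_spots(
        by_frame, radius=p.get("radius", 0.5), max_gap=p.get("max_gap", 0.1), dt=dt
    )
    out = "tracked_trajectories.csv"
    spotlink.trajectories_to_frame(trajs, dt).to_csv(outdir / out, index=False)
    artifacts["trajectories_csv"] = outdir / out
    return [out]


def _stage_hmm(p, seed, outdir, artifacts):
    csv = p.get("input") or artifacts.get("trajectories_csv")
    if csv is None or not Path(csv).exists():
        raise StageError("hmm: no trajectory CSV (provide params['hmm']['input'] "
                         "or run simulate/track first)")
    trajs = spotlink.frame_to_trajectories(pd.read_csv(csv))
    trajs = [t for t in trajs if len(t) >= 4]  # >= 3 displacements
    dt = p.get("dt", 0.1)
    if "K" in p:
        model = diffusion_hmm.fit_hmm(trajs, p["K"], seed=seed, dt=dt)
    else:
        model = diffusion_hmm.select_model(trajs, p.get("K_max", 5), seed=seed, dt=dt)
    if p.get("bootstrap", 0) >= 2:
        model = diffusion_hmm.bootstrap_uncertainty(trajs, model, p["bootstrap"], seed=seed)
    out = "hmm_model.json"
    (outdir / out).write_text(json.dumps(model.to_dict(), indent=2))
    return [out]


def _stage_smpb(p, seed, outdir, artifacts):
    sim_cfg = simulate.TraceSimConfig(seed=seed, **p.get("traces", {}))
    traces, truth = simulate.simulate_traces(sim_cfg)
    results = [
        photobleach.find_changepoints(tr, p.get("confidence", 0.95)) for tr in traces
    ]
    rows = [
        (i, r.I0, r.T_pb, r.n_steps, r.bleached) for i, r in enumerate(results)
    ]
    per_trace = "smpb_traces.csv"
    pd.DataFrame(rows, columns=["spot_id", "I0_kHz", "Tpb_s", "n_steps", "bleached"]).to_csv(
        outdir / per_trace, index=False
    )
    ens = photobleach.fit_ensemble(results, t_min=2.5 * sim_cfg.frame_dt)
    out = "smpb_ensemble.json"
    (outdir / out).write_text(json.dumps({
        "I_m_kHz": ens.I_m, "I_sd_kHz": ens.I_sd, "tau_pb_s": ens.tau_pb,
        "n_traces": ens.n_traces,
    }, indent=2))
    return [per_trace, out]


def _stage_fcs(p, seed, outdir, artifacts):
    if "input" in p:
        curve = fcs.read_curve(p["input"])
    else:
        ac = p.get("ac_params")
        if ac is None:
            raise StageError("fcs: no curve input or ac_params block")
        sim_cfg = simulate.FCSSimConfig(
            ac_params=fcs.ACParams(**ac), noise_sd=p.get("noise_sd", 0.0),
            n_repeats=p.get("n_repeats", 1), seed=seed,
        )
        curve = simulate.simulate_correlation(sim_cfg)
    res = fcs.fit_curve(curve, w=p.get("w", 0.25), fix=tuple(p.get("fix", ())))
    out = "fcs_fit.json"
    (outdir / out).write_text(json.dumps({
        "N_mean": res.params.N_mean, "tau_D_s": res.params.tau_D,
        "alpha": res.params.alpha, "tau_ds_s": res.params.tau_ds,
        "f_ds": res.params.f_ds, "D_um2_s": res.D,
        "density_per_um2": res.density, "redchi": res.redchi,
    }, indent=2))
    return [out]


def _stage_oligomer(p, seed, outdir, artifacts):
    if "sample_file" in p:
        sample = np.loadtxt(p["sample_file"])
    elif "mixture" in p:
        m = p["mixture"]
        sample = simulate.simulate_brightness(
            m["means"], m["sds"], m["weights"], m.get("n", 2000), seed=seed
        )
    else:
        csv = p.get("input") or artifacts.get("trajectories_csv")
        if csv is None or not Path(csv).exists():
            raise StageError("oligomer: no brightness sample (sample_file, mixture "
                             "block, or trajectory CSV required)")
        trajs = spotlink.frame_to_trajectories(pd.read_csv(csv))
        sample = oligomer.initial_intensities(trajs, p.get("n_frames", 20))
    fit = oligomer.fit_mixture(
        sample,
        (p.get("monomer_mean", 4.3), p.get("monomer_sd", 0.86)),
    )
    out = "oligomer_fit.json"
    (outdir / out).write_text(json.dumps({
        "n_comp": fit.n_comp, "means_kHz": fit.means.tolist(),
        "sds_kHz": fit.sds.tolist(), "weights": fit.weights.tolist(),
        "fractions_by_area": fit.fractions_by_area, "bic": fit.criterion,
        "note": fit.note,
    }, indent=2))
    return [out]


# ---------------------------------------------------------------------------
# synthetic parameter-recovery demo
# ---------------------------------------------------------------------------

#: Three-state diffusion model of the receptor in the resting (Apo) state:
#: (D um^2/s, occupancy) for confined/immobile, slow and fast states.
APO_STATES = [(0.016, 0.05), (0.043, 0.22), (0.144, 0.73)]

#: Monomer photobleaching reference conditions: receptor (brightness kHz,
#: bleach lifetime s) and the monomeric control protein.
RECEPTOR_PB = (4.4, 14.7)
CONTROL_PB = (4.3, 18.0)

#: Brightness-mixture compositions (means kHz, oligomer weight): intermediate
#: expression and low expression.
MIX_INTERMEDIATE = ((4.6, 8.0), 0.27)
MIX_LOW = ((4.3, 7.5), 0.14)

#: FCS reference: beam waist (um), membrane diffusion coefficient (um^2/s),
#: red-fluorophore dark state (lifetime s, fraction), and the dual-color
#: codiffusion ground truth.
FCS_W = 0.25
FCS_D = 0.089
DARK_STATE = (2.7e-3, 0.37)
CODIFFUSION_FRACTION = 0.5


def _occupancy_generator(states, leave_rate):
    """CT generator with the given stationary occupancies and total leave rate."""
    occ = np.array([o for _, o in states])
    K = len(states)
    Q = leave_rate * np.tile(occ, (K, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def demo_report(seed: int = 0, *, n_traj: int = 1000, n_traces: int = 300,
                n_mix: int = 2000) -> dict:
    """Run the full synthetic parameter-recovery suite.

    Generates data at the study's printed conditions (three-state Apo
    diffusion; monomer photobleaching brightness/lifetime; brightness
    mixtures at low/intermediate expression; FCS/dcFCS model parameters),
    runs every analysis stage, and returns the recovered quantities in the
    units the study reports.
    """
    rng = np.random.default_rng(seed)
    s = lambda: int(rng.integers(0, 2**31 - 1))  # noqa: E731
    out: dict[str, float] = {}

    # --- diffusion-state recovery ------------------------------------------
    cfg = simulate.TrajectorySimConfig(
        n_traj=n_traj, n_frames=21, dt=0.1, states=APO_STATES,
        transition_rates=_occupancy_generator(APO_STATES, leave_rate=0.5),
        loc_sigma=0.02, bleach_rate=0.0, seed=s(),
    )
    trajs = simulate.simulate_trajectories(cfg)
    model = diffusion_hmm.fit_hmm(trajs, K=3, n_restarts=3, seed=s(), dt=cfg.dt)
    out["hmm_fast_D_um2_s"] = float(model.D[-1])
    out["hmm_fast_occupancy_pct"] = float(100.0 * model.occupancy[-1])

    # --- photobleaching recovery (receptor + monomeric control) -----------
    for label, (bright, tau) in (("receptor", RECEPTOR_PB), ("control", CONTROL_PB)):
        tcfg = simulate.TraceSimConfig(
            n_traces=n_traces, n_frames=200, frame_dt=0.5,
            brightness_mean=bright, brightness_sd=0.2 * bright,
            bleach_tau=tau, noise_sd=1.0, seed=s(),
        )
        traces, _ = simulate.simulate_traces(tcfg)
        results = [photobleach.find_changepoints(t, 0.95) for t in traces]
        ens = photobleach.fit_ensemble(results, t_min=2.5 * tcfg.frame_dt)
        if label == "receptor":
            out["smpb_I0_center_kHz"] = ens.I_m
            out["smpb_tau_pb_s"] = ens.tau_pb
        else:
            out["control_tau_pb_s"] = ens.tau_pb

    # --- brightness-mixture recovery ---------------------------------------
    (m1, m2), olig_w = MIX_INTERMEDIATE
    sample = simulate.simulate_brightness(
        [m1, m2], [0.2 * m1, 0.2 * m2], [1 - olig_w, olig_w], n_mix, seed=s()
    )
    fit = oligomer.fit_mixture(sample, monomer_prior=(CONTROL_PB[0], 0.2 * CONTROL_PB[0]))
    out["mixture_oligomer_pct"] = 100.0 * fit.fractions_by_area["oligomer"]
    out["mixture_dimer_mean_kHz"] = float(fit.means[-1])

    (m1, m2), olig_w = MIX_LOW
    sample = simulate.simulate_brightness(
        [m1, m2], [0.2 * m1, 0.2 * m2], [1 - olig_w, olig_w], n_mix, seed=s()
    )
    fit = oligomer.fit_mixture(sample, monomer_prior=(CONTROL_PB[0], 0.2 * CONTROL_PB[0]))
    out["mixture_low_monomer_pct"] = 100.0 * fit.fractions_by_area["monomer"]

    # --- FCS: diffusion and dark-state recovery ----------------------------
    tau_D = FCS_W**2 / (4.0 * FCS_D)
    curve = simulate.simulate_correlation(simulate.FCSSimConfig(
        ac_params=fcs.ACParams(N_mean=10.0, tau_D=tau_D, alpha=1.0, f_ds=0.0)
    ))
    res = fcs.fit_curve(curve, w=FCS_W)
    out["fcs_D_um2_s"] = float(res.D)

    curve = simulate.simulate_correlation(simulate.FCSSimConfig(
        ac_params=fcs.ACParams(N_mean=10.0, tau_D=0.15, alpha=1.0,
                               tau_ds=DARK_STATE[0], f_ds=DARK_STATE[1])
    ))
    res = fcs.fit_curve(curve, w=FCS_W)
    out["fcs_dark_fraction"] = float(res.params.f_ds)

    # --- dual-color codiffusion fraction -----------------------------------
    N = 20.0
    cc = fcs.CCParams(N_g=N, N_r=N, N_x=CODIFFUSION_FRACTION * N)
    Gg0 = fcs.ac_model(0.0, fcs.ACParams(N_mean=N, tau_D=tau_D))
    Gr0 = fcs.ac_model(0.0, fcs.ACParams(N_mean=N, tau_D=tau_D))
    Gx0 = fcs.cc_model(0.0, cc)
    _, _, fcd_min = fcs.compute_fcd(float(Gx0), float(Gg0), float(Gr0))
    out["dcfcs_fcd_min_pct"] = 100.0 * fcd_min

    return out
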