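"""Experiment drivers: unsupervised training, go/no-go pipeline, fixtures, I/O.

These functions wire the generative environment, the bulb/piriform circuits
and the metrics into reproducible, seedable runs.  Every driver takes a single
integer seed and derives independent sub-streams for weights, odors, sensory
noise and reward noise, so each randomness source can be reproduced in
isolation.  Ensemble runs (``n_sims > 1``) advance all simulations in lockstep
through the batched array support of the dynamics code.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import bulb as _bulb
from . import evaluation as ev
from . import piriform as _piri
from . import reward as _rew
from .bulb import BulbState, SimConfig, init_bulb, run_trial_dynamics, update_plasticity
from .environment import OdorWorld, glomeruli_response, make_world, sample_odors
from .piriform import init_piriform, run_circuit_trial, run_joint_dynamics
from .sparsecoding import init_sparse_coding, sc_trial

__all__ = [
    "train_unsupervised",
    "train_sparse_coding",
    "run_go_nogo_experiment",
    "concentration_sweep",
    "single_odor_responses",
    "make_fixture",
    "run_experiment",
    "save_run",
    "load_world",
]


def _ens_iter(*arrs):
    """Yield per-member views: treats a leading axis as the ensemble if 3-D."""
    if arrs[0].ndim == 2:
        yield arrs
    else:
        for k in range(arrs[0].shape[0]):
            yield tuple(a[k] for a in arrs)


def _batched_weight_error(wF, W_true):
    return np.array([
        ev.weight_error(w, W, ev.assign_selectivity(w, W))
        for w, W in _ens_iter(wF, W_true)])


def _batched_reconstruct(rates, wF, W_true):
    """Decode odor estimates per ensemble member via previous-trial selectivity."""
    out = []
    i = 0
    for w, W in _ens_iter(wF, W_true):
        sel = ev.assign_selectivity(w, W)
        r = rates if rates.ndim == 1 else rates[i]
        out.append(ev.reconstruct_odors(r, sel, M=W.shape[1]))
        i += 1
    return np.array(out) if rates.ndim > 1 else out[0]


def train_unsupervised(config: SimConfig, seed: int, n_trials: int,
                       n_sims: int | None = None, variant: str | None = None,
                       kappa_J: float = 1.0, world: OdorWorld | None = None,
                       eval_window: int = 0, metric_every: int = 0,
                       decode_pbar: bool = False):
    """Train the circuit on freshly sampled odor trials.

    variant : None trains the bulb alone; otherwise one of the piriform
        circuit variants, trained jointly.
    eval_window : record decoded estimates and truths for the last this-many
        trials (selectivity always taken from the pre-update weights).
    metric_every : record weight error d_w and pooled M/T rates every
        this-many trials (0 disables).

    Returns a dict with the world, final states, and the recorded logs.
    """
    rng = np.random.default_rng(seed)
    r_weights, r_odors, r_noise, _ = rng.spawn(4)
    if world is None:
        world = make_world(config.M, config.N, config.c_o, config.sigma_x,
                           r_weights, size=n_sims)
    bstate = init_bulb(config, r_weights, size=n_sims)
    pstate = init_piriform(bstate, r_weights, variant=variant,
                           kappa_J=kappa_J) if variant else None

    log = {"trial": [], "d_w": [], "mt_var": []}
    est_block, truth_block = [], []
    for t in range(n_trials):
        c = sample_odors(world.prior, r_odors, size=n_sims)
        x = glomeruli_response(world, c, r_noise)
        wF_pre = bstate.wF
        if pstate is None:
            m, cbar = run_trial_dynamics(bstate, x)
            pbar = None
            bstate = update_plasticity(bstate, m, cbar)
        else:
            bstate, pstate, m, cbar, pbar = run_circuit_trial(bstate, pstate, x)
        if eval_window and t >= n_trials - eval_window:
            rates = pbar if (decode_pbar and pbar is not None) else cbar
            wdec = pstate.wP if (decode_pbar and pstate is not None) else wF_pre
            est_block.append(_batched_reconstruct(rates, wdec, world.W))
            truth_block.append((c > 0).astype(float) if decode_pbar else c)
        if metric_every and (t % metric_every == 0 or t == n_trials - 1):
            log["trial"].append(t)
            log["d_w"].append(_batched_weight_error(bstate.wF, world.W))
            log["mt_var"].append(m)

    result = {"world": world, "bulb": bstate, "piriform": pstate,
              "metrics": {k: (np.array(v) if k != "mt_var" else v)
                          for k, v in log.items()}}
    if eval_window:
        result["estimates"] = np.array(est_block)
        result["truths"] = np.array(truth_block)
    return result


def pooled_correlation(estimates: np.ndarray, truths: np.ndarray):
    """Per-ensemble Pearson correlation pooled over the recorded eval block."""
    if estimates.ndim == 2:        # (trials, M) unbatched
        return ev.performance_correlation(estimates, truths)
    return np.array([
        ev.performance_correlation(estimates[:, k], truths[:, k])
        for k in range(estimates.shape[1])])


def train_sparse_coding(config: SimConfig, seed: int, n_trials: int,
                        n_sims: int | None = None, eta_w: float = 0.5,
                        world: OdorWorld | None = None,
                        max_steps: int = 100_000, grad_tol: float = 1e-10):
    """Train the sparse-coding baseline on the same kind of odor stream.

    Uses the identical seed-splitting scheme as ``train_unsupervised`` so a
    matched world and stimulus sequence can be shared via ``world=...`` plus
    the same seed.  Returns the world, the final state and d_w over time.
    """
    rng = np.random.default_rng(seed)
    r_weights, r_odors, r_noise, _ = rng.spawn(4)
    if world is None:
        world = make_world(config.M, config.N, config.c_o, config.sigma_x,
                           r_weights, size=n_sims)
    state = init_sparse_coding(config.M, config.N, config.c_o, config.sigma_x,
                               r_weights, size=n_sims, eta_w=eta_w)
    for t in range(n_trials):
        c = sample_odors(world.prior, r_odors, size=n_sims)
        x = glomeruli_response(world, c, r_noise)
        state, _ = sc_trial(state, x, max_steps=max_steps, grad_tol=grad_tol)
    # the dictionary is glomeruli-major; transpose to cell-major for metrics
    wT = np.swapaxes(state.w_hat, -1, -2)
    d_w = _batched_weight_error(wT, world.W)
    return {"world": world, "state": state, "d_w": d_w}


def run_go_nogo_experiment(seed: int, n_sims: int = 50, n_pretrain: int = 1500,
                           n_reward_trials: int = 20, M: int = 50, N: int = 200,
                           route: str = "piriform",
                           config: SimConfig | None = None,
                           pretrained: dict | None = None,
                           n_task_repeats: int = 1):
    """Full odor-reward association pipeline.

    Pretrains an ensemble of feedback-variant circuits without reward,
    freezes all unsupervised weights and precisions, then runs the go/no-go
    task.  ``n_task_repeats`` independent task sessions (fresh odor pair,
    fresh association weights, fresh reward sequence) are run on each
    pretrained circuit; since pretraining dominates the cost, this is the
    cheap way to grow the number of task simulations.  Returns per-trial
    classification performance and average error pooled over all
    ``n_sims * n_task_repeats`` sessions, plus the raw per-trial (e_hat, R).
    """
    if config is None:
        config = SimConfig(M=M, N=N)
    if pretrained is None:
        pretrained = train_unsupervised(config, seed, n_pretrain, n_sims=n_sims,
                                        variant="local_lateral_feedback")
    world, bstate, pstate = (pretrained["world"], pretrained["bulb"],
                             pretrained["piriform"])
    r_reward = np.random.default_rng(seed).spawn(4)[3]
    e_hats, rewards = [], []
    for rep in range(n_task_repeats):
        out = _rew.run_go_nogo(bstate, pstate, world, n_reward_trials,
                               r_reward.spawn(1)[0], route=route, size=n_sims)
        e_hats.append(out["e_hat"])
        rewards.append(out["R"])
    e_hat = np.concatenate(e_hats, axis=1)     # (n_trials, sims * repeats)
    R = np.concatenate(rewards, axis=1)
    perf = np.array([_rew.classification_performance(e_hat[k], R[k])
                     for k in range(n_reward_trials)])
    err = np.array([_rew.average_error(e_hat[k], R[k])
                    for k in range(n_reward_trials)])
    return {"performance": perf, "average_error": err, "e_hat": e_hat,
            "R": R, "pretrained": pretrained}


def ensemble_member(bstate: BulbState, pstate, world: OdorWorld, k: int):
    """Slice ensemble member ``k`` out of batched states (no copy of config)."""
    from dataclasses import replace as _rep
    b = _rep(bstate, wF=bstate.wF[k], wL=bstate.wL[k], rho=bstate.rho[k])
    p = None
    if pstate is not None:
        p = _rep(pstate, wP=pstate.wP[k], rhoP=pstate.rhoP[k], J=pstate.J[k])
    w = OdorWorld(W=world.W[k], sigma_x=world.sigma_x, prior=world.prior)
    return b, p, w


def single_odor_responses(bstate: BulbState, pstate, world: OdorWorld,
                          concentration: float = 1.0):
    """Steady-state cbar (and pbar) for each odor presented in isolation.

    The M single-odor stimuli run as one batched (noiseless) trial, so this
    is cheap even at M = 100.  States must be unbatched (use
    ``ensemble_member`` first).  Returns odor-major response matrices of
    shape (M_odors, M_cells), as the lifetime-sparseness metric expects.
    """
    X = concentration * world.W.T            # row j = response to odor j alone
    if pstate is None:
        _, cbar = run_trial_dynamics(bstate, X)
        return cbar, None
    _, cbar, pbar = run_joint_dynamics(bstate, pstate, X)
    return cbar, pbar


def concentration_sweep(bstate: BulbState, pstate, world: OdorWorld,
                        concentrations=None, n_members: int | None = None):
    """Matched-cell responses of each odor across presentation concentrations.

    For every odor, presents it alone at each concentration and records the
    mean granule and piriform rate of the cells selective for it (covariance
    bootstrap on the learned weights).  Returns (concentrations, g, p) with
    g and p of shape (n_conc, n_members, M) — NaN where no cell claims an
    odor.
    """
    if concentrations is None:
        concentrations = np.linspace(0.1, 2.0, 8)
    batched = bstate.wF.ndim == 3
    n = (bstate.wF.shape[0] if batched else 1)
    if n_members is not None:
        n = min(n, n_members)
    gr = np.full((len(concentrations), n, bstate.config.M), np.nan)
    pr = np.full_like(gr, np.nan)
    for k in range(n):
        if batched:
            b, p, w = ensemble_member(bstate, pstate, world, k)
        else:
            b, p, w = bstate, pstate, world
        sel_c = ev.assign_selectivity(b.wF, w.W)
        sel_p = ev.assign_selectivity(p.wP, w.W) if p is not None else sel_c
        for ic, conc in enumerate(concentrations):
            cbar_all, pbar_all = single_odor_responses(b, p, w, conc)
            for odor in range(w.M):
                cells_c = np.flatnonzero(sel_c == odor)
                cells_p = np.flatnonzero(sel_p == odor)
                if cells_c.size:
                    gr[ic, k, odor] = cbar_all[odor, cells_c].mean()
                if pbar_all is not None and cells_p.size:
                    pr[ic, k, odor] = pbar_all[odor, cells_p].mean()
    return np.asarray(concentrations), gr, pr


# ---------------------------------------------------------------------------
# Fixtures, serialization and the config-file entry point
# ---------------------------------------------------------------------------

FIXTURE_SIZES = {"tiny": dict(M=10, N=40, n_trials=200),
                 "small": dict(M=20, N=100, n_trials=1500)}


def make_fixture(size: str, seed: int, outdir=None):
    """Generate a reproducible world + trial stream for test suites.

    tiny = (M=10, N=40, 200 trials); small = (M=20, N=100, 1500 trials).
    If ``outdir`` is given, writes world and trials to HDF5 plus a JSON
    manifest; always returns the in-memory dict.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    spec = FIXTURE_SIZES[size]
    rng = np.random.default_rng(seed)
    r_weights, r_odors, r_noise, _ = rng.spawn(4)
    world = make_world(spec["M"], spec["N"], 3.0 / spec["M"], 1.0, r_weights)
    c = sample_odors(world.prior, r_odors, size=spec["n_trials"])
    x = (world.W @ c[..., None])[..., 0] + world.sigma_x * \
        r_noise.standard_normal((spec["n_trials"], spec["N"]))
    fixture = {"world": world, "c": c, "x": x,
               "manifest": {"size": size, "seed": seed, **spec}}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with h5py.File(outdir / f"fixture_{size}.h5", "w") as f:
            f.create_dataset("W", data=world.W)
            f.create_dataset("c", data=c)
            f.create_dataset("x", data=x)
            f.attrs.update({"sigma_x": world.sigma_x, "c_o": world.prior.c_o,
                            "gamma_shape": world.prior.gamma_shape,
                            "seed": seed, "size": size})
        (outdir / f"fixture_{size}.json").write_text(
            json.dumps(fixture["manifest"], indent=2))
    return fixture


def load_world(path) -> dict:
    """Round-trip loader for fixture files written by ``make_fixture``."""
    from .environment import OdorPrior
    with h5py.File(path, "r") as f:
        W = f["W"][...]
        prior = OdorPrior(c_o=float(f.attrs["c_o"]), M=W.shape[1],
                          gamma_shape=float(f.attrs["gamma_shape"]))
        return {"world": OdorWorld(W=W, sigma_x=float(f.attrs["sigma_x"]),
                                   prior=prior),
                "c": f["c"][...], "x": f["x"][...],
                "manifest": {"seed": int(f.attrs["seed"]),
                             "size": str(f.attrs["size"])}}


def save_run(path, bstate: BulbState, pstate=None, metrics: dict | None = None):
    """Checkpoint a run: weights/precisions to HDF5, metrics to CSV alongside."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        g = f.create_group("bulb")
        g.create_dataset("wF", data=bstate.wF)
        g.create_dataset("wL", data=bstate.wL)
        g.create_dataset("rho", data=bstate.rho)
        g.attrs["t"] = bstate.t
        g.attrs["config"] = json.dumps(asdict(bstate.config))
        if pstate is not None:
            gp = f.create_group("piriform")
            gp.create_dataset("wP", data=pstate.wP)
            gp.create_dataset("rhoP", data=pstate.rhoP)
            gp.create_dataset("J", data=pstate.J)
            gp.attrs["variant"] = pstate.variant
            gp.attrs["kappa_J"] = pstate.kappa_J
    if metrics:
        flat = {k: np.asarray(v).reshape(len(v), -1).mean(axis=1)
                for k, v in metrics.items() if len(v)}
        if flat:
            pd.DataFrame(flat).to_csv(path.with_suffix(".metrics.csv"), index=False)


def load_run(path):
    """Load a checkpoint written by ``save_run``."""
    with h5py.File(path, "r") as f:
        g = f["bulb"]
        config = SimConfig(**json.loads(g.attrs["config"]))
        bstate = BulbState(wF=g["wF"][...], wL=g["wL"][...], rho=g["rho"][...],
                           t=int(g.attrs["t"]), config=config)
        pstate = None
        if "piriform" in f:
            gp = f["piriform"]
            pstate = _piri.PiriformState(
                wP=gp["wP"][...], rhoP=gp["rhoP"][...], J=gp["J"][...],
                variant=str(gp.attrs["variant"]),
                kappa_J=float(gp.attrs["kappa_J"]))
    return bstate, pstate


#: desk-scale integration profile for the bundled long runs (see docs/methods.md)
DESK_PROFILE = {"dt": 4.0, "T_max": 3000.0, "steady_tol": 5e-5,
                "dyn_dtype": "float32"}

BUNDLED_SPECS = {
    "fig4_comparison": {
        "model": "comparison",
        "parameters": {"M": 20, "N": 100, "c_o": 0.15, **DESK_PROFILE},
        "n_trials": 1500, "n_sims": 5,
        "eta_w_values": [0.3, 0.5, 1.0],
        "sc_max_steps": 10000, "sc_grad_tol": 1e-4,
    },
    "fig7_gonogo": {
        "model": "gonogo",
        "parameters": {"M": 50, "N": 200, **DESK_PROFILE},
        "n_trials": 2000, "n_sims": 50, "n_reward_trials": 20,
    },
}


def run_experiment(spec, outdir=None, seed: int = 0):
    """Config-driven entry point: run a named or dict experiment spec.

    ``spec`` may be a bundled-spec name, a YAML path, or a dict with keys
    model (bayes | sparse_coding | comparison | gonogo), parameters (SimConfig
    overrides), n_trials, n_sims, seed, and model-specific options.  Results
    (metrics CSV, checkpoint HDF5, manifest JSON) land in ``outdir`` when
    given; the result dict is always returned.  Deterministic per (spec, seed).
    """
    if isinstance(spec, str) and spec in BUNDLED_SPECS:
        name, spec = spec, dict(BUNDLED_SPECS[spec])
    elif isinstance(spec, (str, Path)):
        name = Path(spec).stem
        spec = yaml.safe_load(Path(spec).read_text())
    else:
        spec = dict(spec)
        name = spec.get("name", "experiment")
    seed = int(spec.get("seed", seed))
    model = spec.get("model", "bayes")
    params = spec.get("parameters", {})
    config = SimConfig(**params)
    n_trials = int(spec.get("n_trials", 1000))
    n_sims = spec.get("n_sims")

    if model == "bayes":
        res = train_unsupervised(config, seed, n_trials, n_sims=n_sims,
                                 variant=spec.get("variant"),
                                 eval_window=spec.get("eval_window", 100),
                                 metric_every=spec.get("metric_every", 100))
        summary = {"d_w_final": np.mean(res["metrics"]["d_w"][-1]),
                   "correlation": float(np.mean(
                       pooled_correlation(res["estimates"], res["truths"])))}
    elif model == "sparse_coding":
        res = train_sparse_coding(config, seed, n_trials, n_sims=n_sims,
                                  eta_w=spec.get("eta_w", 0.5),
                                  max_steps=spec.get("sc_max_steps", 100_000),
                                  grad_tol=spec.get("sc_grad_tol", 1e-10))
        summary = {"d_w_final": float(np.mean(res["d_w"]))}
    elif model == "comparison":
        bayes = train_unsupervised(config, seed, n_trials, n_sims=n_sims,
                                   metric_every=n_trials)
        rows = {"bayes": float(np.mean(bayes["metrics"]["d_w"][-1]))}
        for eta_w in spec.get("eta_w_values", [0.5]):
            sc = train_sparse_coding(config, seed, n_trials, n_sims=n_sims,
                                     eta_w=eta_w,
                                     max_steps=spec.get("sc_max_steps", 100_000),
                                     grad_tol=spec.get("sc_grad_tol", 1e-10))
            rows[f"sparse_coding_eta_{eta_w}"] = float(np.mean(sc["d_w"]))
        res = {"d_w": rows, "bayes": bayes}
        summary = rows
    elif model == "gonogo":
        res = run_go_nogo_experiment(
            seed, n_sims=int(spec.get("n_sims", 50)),
            n_pretrain=n_trials,
            n_reward_trials=int(spec.get("n_reward_trials", 20)),
            config=config)
        summary = {"performance_trial6": float(res["performance"][5]),
                   "final_error": float(res["average_error"][-1])}
    else:
        raise ValueError(f"unknown model {model!r}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{name}_manifest.json").write_text(json.dumps(
            {"name": name, "seed": seed, "model": model, "summary": summary},
            indent=2, default=float))
        if model in ("bayes",):
            save_run(outdir / f"{name}.h5", res["bulb"], res.get("piriform"),
                     metrics=res["metrics"])
        if model == "gonogo":
            pd.DataFrame({"trial": np.arange(1, len(res["performance"]) + 1),
                          "performance": res["performance"],
                          "average_error": res["average_error"]}
                         ).to_csv(outdir / f"{name}_curves.csv", index=False)
    return {"name": name, "summary": summary, "result": res}
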