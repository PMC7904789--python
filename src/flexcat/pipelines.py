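"""Configured analysis pipelines and desk-scale reproduction drivers.

A pipeline run is described by a small YAML/dict configuration::

    name: my-run            # optional label
    seed: 1                 # master seed for every named stream
    outdir: results/my-run  # output directory
    task:
      kind: psychometric    # which analysis to run
      ...                   # keyword parameters of that analysis

Every run validates the configuration against the task's signature (unknown
keys are itemized errors), writes its artifacts as CSV/JSON into ``outdir``
beside the resolved configuration and a run log, and stamps each table with
the package version and a hash of the resolved configuration, so outputs are
traceable and byte-reproducible for a fixed seed.

``reproduce(figure)`` bundles the desk-scale experiment suites: canonical
and double-well kernel sweeps, the accuracy surface with its theory overlay,
the consistency dip, the synthetic brightness-kernel crossover, and the
synthetic two-pulse fit.
"""

from __future__ import annotations

import hashlib
import inspect
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, consistency, kernels, pulsefit, ratenet, spiking, stimuli, theory
from .models import IntegratorConfig, canonical_model, run_psychometric, simulate
from .potentials import double_well


class ConfigError(ValueError):
    """Configuration did not validate; message itemizes the offending keys."""


# ---------------------------------------------------------------------------
# tasks
# ---------------------------------------------------------------------------

def task_psychometric(
    seed: int,
    model: str = "dwm",
    mu_grid=(0.15,),
    sigma_s_grid=(0.1, 0.3, 0.5, 0.7, 1.0),
    T_grid=(2.0,),
    n_trials: int = 1000,
    sigma_i: float = 0.0,
    alpha: float = 1.0,
    tau: float = 0.2,
) -> dict:
    df = run_psychometric(
        model, mu_grid, sigma_s_grid, T_grid, n_trials, seed,
        sigma_i=sigma_i, alpha=alpha, tau=tau,
    )
    return {"psychometric.csv": df}


def task_theory(
    seed: int,
    alpha: float = 1.0,
    mu: float = 0.15,
    sigma: float = 0.5,
    T: float = 2.0,
    tau: float = 0.2,
) -> dict:
    pred = theory.predict(double_well(mu, alpha), sigma, T / tau)
    return {"prediction.json": pred.as_dict()}


def task_kernel_sweep(
    seed: int,
    model: str = "dwm",
    sigma_s_grid=(0.1, 0.3, 0.58, 1.0),
    T: float = 1.0,
    n_trials: int = 2000,
    sigma_i: float = 0.1,
    alpha: float = 1.0,
    tau: float = 0.2,
) -> dict:
    rows = []
    for i, sig in enumerate(sigma_s_grid):
        cfg = IntegratorConfig(tau=tau, sigma_i=sigma_i, seed=seed, stream_index=i)
        stim = stimuli.gaussian_frames(
            n_trials, int(round(T / cfg.dt)), 0.0, sig, seed,
            frame_duration=cfg.dt, stream_index=i,
        )
        pot, bnd = canonical_model(model, 0.0, alpha)
        ens = simulate(stim, pot, bnd, cfg)
        kr = kernels.compute_pk(stim, ens.choices)
        pot_pi, bnd_pi = canonical_model("pi")
        cfg0 = IntegratorConfig(tau=tau, sigma_i=0.0, seed=seed, stream_index=i)
        ref = kernels.compute_pk(stim, simulate(stim, pot_pi, bnd_pi, cfg0).choices)
        rows.append(
            {
                "sigma_s": sig,
                "slope": kr.slope,
                "npka": kernels.npka(kr, ref),
                "n_trials": n_trials,
            }
        )
    return {"kernel_sweep.csv": pd.DataFrame(rows)}


def task_consistency(
    seed: int,
    alpha: float = 1.0,
    sigma_i: float = 0.1,
    sigma_s_grid=(0.05, 0.15, 0.3, 0.5, 0.8, 1.2),
    n_stimuli: int = 150,
    n_passes: int = 20,
    duration_s: float = 0.5,
    tau: float = 0.2,
) -> dict:
    cfg = IntegratorConfig(tau=tau, sigma_i=sigma_i, seed=seed)
    res = consistency.double_pass(
        double_well(0.0, alpha), cfg, sigma_s_grid,
        n_stimuli=n_stimuli, n_passes=n_passes, duration_s=duration_s,
    )
    diag = consistency.transition_diag(
        double_well(0.0, alpha), sigma_s_grid, sigma_i,
        n_trials=max(500, n_stimuli * 4), seed=seed, duration_s=duration_s, tau=tau,
    )
    df = pd.DataFrame(
        {
            "sigma_s": res.sigma_s_grid,
            "consistency": res.consistency,
            "sem": res.sem,
            "delta_p_transition": diag["delta_p"],
        }
    )
    return {"consistency.csv": df}


def task_fit_pulses(
    seed: int,
    table: str | None = None,
    n_per_condition: int = 2000,
    n_restarts: int = 5,
) -> dict:
    if table is not None:
        df = pd.read_csv(table, comment="#")
    else:  # synthetic table at the reported parameters
        df = pulsefit.simulate_condition_table(
            pulsefit.PulseParams(**pulsefit.FITTED_PARAMS), n_per_condition, seed
        )
    res = pulsefit.fit(df, seed=seed, n_restarts=n_restarts)
    return {
        "fit.json": json.loads(res.to_json()),
        "fit_predictions.csv": res.predictions,
    }


def task_spiking(
    seed: int,
    config: str | None = None,
    sigma_s_grid=(0.5, 2.0, 5.0),
    T_grid=(1.0,),
    n_trials: int = 50,
    mu: float = 0.05,
) -> dict:
    params = spiking.NetworkParams() if config is None else spiking.NetworkParams.from_yaml(config)
    out = spiking.run_experiment(params, sigma_s_grid, T_grid, n_trials, seed, mu=mu)
    artifacts = {"spiking_accuracy.csv": out["accuracy"]}
    pk_rows = []
    for (sig, T), kr in out["kernels"].items():
        for t, v in zip(kr.times, kr.pk):
            pk_rows.append({"sigma_s": sig, "T": T, "time_s": t, "pk": v})
    if pk_rows:
        artifacts["spiking_pk.csv"] = pd.DataFrame(pk_rows)
    return artifacts


def task_rate_net(
    seed: int,
    n_choices: int = 3,
    sigma_grid=(0.02, 0.1, 0.18, 0.3, 0.5),
    n_trials: int = 400,
    duration_s: float = 2.0,
) -> dict:
    res = ratenet.accuracy_vs_noise(
        sigma_grid, ratenet.RateNetParams(n_choices=n_choices),
        duration_s=duration_s, n_trials=n_trials, seed=seed,
    )
    return {
        "ratenet_accuracy.csv": pd.DataFrame(
            {"sigma": res["sigma_grid"], "accuracy": res["accuracy"], "se": res["se"]}
        )
    }


def task_brightness_kernels(
    seed: int,
    durations=(1, 2, 3, 5),
    n_trials: int = 2000,
    alpha: float = 0.8,
    sigma_i: float = 0.3,
    tau: float = 0.2,
) -> dict:
    rows = []
    for T in durations:
        stim = stimuli.brightness_disc_frames(n_trials, float(T), seed=seed)
        cfg = IntegratorConfig(tau=tau, sigma_i=sigma_i, seed=seed, stream_index=int(T))
        ens = simulate(stim, double_well(0.0, alpha), None, cfg)
        kr = kernels.compute_pk(stim, ens.choices)
        rows.append({"T": T, "slope": kr.slope, "accuracy": ens.accuracy()})
    return {"brightness_kernels.csv": pd.DataFrame(rows)}


def task_accuracy_vs_fluctuations(
    seed: int,
    mu: float = 0.15,
    alpha: float = 1.0,
    sigma_s_grid=(0.15, 0.25, 0.35, 0.45, 0.55, 0.7, 0.9),
    T: float = 2.0,
    n_trials: int = 2000,
    tau: float = 0.2,
) -> dict:
    sim = run_psychometric("dwm", [mu], sigma_s_grid, [T], n_trials, seed, alpha=alpha, tau=tau)
    sim["p_theory"] = [
        theory.accuracy(double_well(mu, alpha), s, T / tau, p0_method="quadrature")
        for s in sigma_s_grid
    ]
    return {"accuracy_vs_sigma_s.csv": sim}


TASKS = {
    "psychometric": task_psychometric,
    "theory": task_theory,
    "kernel_sweep": task_kernel_sweep,
    "consistency": task_consistency,
    "fit_pulses": task_fit_pulses,
    "spiking": task_spiking,
    "rate_net": task_rate_net,
    "brightness_kernels": task_brightness_kernels,
    "accuracy_vs_fluctuations": task_accuracy_vs_fluctuations,
}

#: desk-scale reproduction bundles: figure tag -> (task kind, overrides)
REPRODUCE = {
    "fig1": ("kernel_sweep", {"model": "ddma", "sigma_s_grid": (0.03, 0.28, 0.69)}),
    "fig2": ("kernel_sweep", {"model": "dwm", "sigma_s_grid": (0.02, 0.1, 0.58, 1.0)}),
    "fig3": ("accuracy_vs_fluctuations", {}),
    "fig4": ("consistency", {}),
    "fig6-synthetic": ("brightness_kernels", {}),
    "fig7-synthetic": ("fit_pulses", {}),
}


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

TOP_KEYS = {"name", "seed", "outdir", "task"}


def validate_config(config: dict) -> dict:
    """Check the configuration schema; returns the resolved config."""
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(config) - TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    task = config.get("task")
    if not isinstance(task, dict) or "kind" not in task:
        raise ConfigError("configuration needs a 'task' mapping with a 'kind'")
    kind = task["kind"]
    if kind not in TASKS:
        raise ConfigError(f"unknown task kind {kind!r}; valid: {sorted(TASKS)}")
    fn = TASKS[kind]
    allowed = set(inspect.signature(fn).parameters) - {"seed"}
    extra = set(task) - allowed - {"kind"}
    if extra:
        raise ConfigError(f"unknown keys for task {kind!r}: {sorted(extra)}")
    resolved = {
        "name": config.get("name", kind),
        "seed": int(config.get("seed", 0)),
        "outdir": str(config.get("outdir", f"out/{kind}")),
        "task": dict(task),
    }
    return resolved


def _config_hash(resolved: dict) -> str:
    # hash the scientific content only (seed + task), not where it is written
    content = {"seed": resolved["seed"], "task": resolved["task"]}
    return hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_artifact(path: Path, obj, header: str) -> None:
    if isinstance(obj, pd.DataFrame):
        with open(path, "w") as fh:
            fh.write(header)
            obj.to_csv(fh, index=False)
    else:
        path.write_text(json.dumps({"_meta": header.strip("# \n"), **obj}, indent=1,
                                   default=float))


def run_pipeline(config: dict) -> Path:
    """Validate, run and persist one configured analysis.

    Returns the output directory; artifacts are CSV/JSON plus the resolved
    configuration (``config.resolved.yaml``) and a ``run.log``.
    """
    resolved = validate_config(config)
    outdir = Path(resolved["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(resolved)
    task = dict(resolved["task"])
    kind = task.pop("kind")
    t0 = time.time()
    artifacts = TASKS[kind](seed=resolved["seed"], **task)
    elapsed = time.time() - t0

    header = (
        f"# flexcat {__version__} task={kind} seed={resolved['seed']} "
        f"config_hash={chash}\n"
    )
    for fname, obj in artifacts.items():
        _write_artifact(outdir / fname, obj, header)
    with open(outdir / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{time.strftime('%Y-%m-%dT%H:%M:%S')} flexcat {__version__} "
            f"task={kind} seed={resolved['seed']} hash={chash} "
            f"elapsed={elapsed:.2f}s artifacts={sorted(artifacts)}\n"
        )
    return outdir


def reproduce(figure: str, seed: int = 1, outdir: str | None = None) -> Path:
    """Run one desk-scale reproduction bundle (see ``REPRODUCE`` for tags)."""
    if figure not in REPRODUCE:
        raise ConfigError(f"unknown reproduction tag {figure!r}; valid: {sorted(REPRODUCE)}")
    kind, overrides = REPRODUCE[figure]
    return run_pipeline(
        {
            "name": f"reproduce-{figure}",
            "seed": seed,
            "outdir": outdir or f"out/reproduce-{figure}",
            "task": {"kind": kind, **overrides},
        }
    )
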