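"""Scenario configuration, dispatch and provenance.

A scenario config is a mapping with a global ``seed`` and a list of
``scenarios``, each a mapping with a ``kind`` naming one of the module
operations plus its parameters.  Unknown top-level or scenario keys are
rejected.  Every run writes a ``provenance.json`` next to its outputs
recording the config hash, the root seed, the derived per-scenario
seeds and the toolkit version, so any table can be regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioenergetics import SigmoidResponse, sign_map
from .calcium import CalciumScenario, calcium_sweep
from .diffusion import WalkerConfig, diffusion_surface
from .fluctuations import FluctuationModel, fluctuation_scaling
from .lattice import cluster_timeseries, make_lattice
from .quality_control import QCParams, sweep_fusion
from .spins import SpinEnsemble, spin_failure_probability

__all__ = ["load_config", "run_scenario", "ReportBundle"]

log = logging.getLogger("mitonet")

_TOP_KEYS = {"seed", "scenarios", "output_dir", "verbosity"}

_SCENARIO_KEYS = {
    "lattice_timeseries": {"L", "d", "lambda_fus", "lambda_fis", "p", "tau", "dt", "n_steps", "boundary"},
    "diffusion_surface": {"p_grid", "tau_grid", "method", "lambda_dif", "d", "L", "n_walkers", "t_max"},
    "qc_sweep": {"lambda_fus_grid", "s", "lambda_fis", "mu", "delta", "damage", "biogenesis"},
    "atp_sign_map": {"psi_min", "psi_max", "n_psi", "psi_half", "slope", "r_max", "rule"},
    "calcium_sweep": {"c_high", "c_low", "c_half", "slope", "a_max", "n_max", "n_high"},
    "robustness_fluctuations": {"radii", "t_max", "n_reps", "invagination", "pore_rate_density", "pore_conductance", "pore_lifetime"},
    "robustness_spins": {"n_agents", "couplings", "bias", "beta_inv", "horizon", "topology", "dynamics", "definition", "method", "n_reps"},
}


class ReportBundle(dict):
    """Mapping scenario label -> written file path(s)."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    scenarios = cfg.get("scenarios", [])
    if not isinstance(scenarios, list):
        raise ValueError("'scenarios' must be a list")
    for i, sc in enumerate(scenarios):
        if "kind" not in sc:
            raise ValueError(f"scenario #{i} missing 'kind'")
        kind = sc["kind"]
        if kind not in _SCENARIO_KEYS:
            raise ValueError(f"scenario #{i}: unknown kind {kind!r}")
        unknown = set(sc) - _SCENARIO_KEYS[kind] - {"kind"}
        if unknown:
            raise ValueError(f"scenario #{i} ({kind}): unknown key(s) {sorted(unknown)}")


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _run_one(kind: str, sc: dict, seed: int) -> pd.DataFrame:
    if kind == "lattice_timeseries":
        lat = make_lattice(
            L=sc.get("L", 32),
            d=sc.get("d", 2),
            lambda_fus=sc.get("lambda_fus"),
            lambda_fis=sc.get("lambda_fis"),
            p=sc.get("p"),
            tau=sc.get("tau"),
            boundary=sc.get("boundary", "open"),
            seed=seed,
        )
        return cluster_timeseries(lat, dt=sc.get("dt", 0.25), n_steps=sc.get("n_steps", 40))
    if kind == "diffusion_surface":
        method = sc.get("method", "ema")
        cfg = WalkerConfig(
            lambda_dif=sc.get("lambda_dif", 1.0),
            n_walkers=sc.get("n_walkers", 400),
            t_max=sc.get("t_max", 200.0),
        )
        return diffusion_surface(
            sc["p_grid"],
            [np.inf if t in ("inf", None) else float(t) for t in sc["tau_grid"]],
            method=method,
            lambda_dif=sc.get("lambda_dif", 1.0),
            d=sc.get("d", 2),
            L=sc.get("L", 64),
            walker_config=cfg,
            seed=seed,
        )
    if kind == "qc_sweep":
        params = QCParams(
            s=sc.get("s", 0.2),
            lambda_fis=sc.get("lambda_fis", 0.5),
            mu=sc.get("mu", 0.3),
            delta=sc.get("delta", 0.05),
            damage=sc.get("damage", "fragmented"),
            biogenesis=sc.get("biogenesis", "healthy"),
        )
        return sweep_fusion(params, sc.get("lambda_fus_grid", [0.1, 0.3, 1.0, 3.0, 10.0]))
    if kind == "atp_sign_map":
        sig = SigmoidResponse(
            r_max=sc.get("r_max", 1.0),
            x_half=sc.get("psi_half", 150.0),
            slope=sc.get("slope", 10.0),
        )
        grid = np.linspace(sc.get("psi_min", 60.0), sc.get("psi_max", 240.0), sc.get("n_psi", 25))
        return sign_map(grid, sig, rule=sc.get("rule", "mean"))
    if kind == "calcium_sweep":
        scen = CalciumScenario(
            c_high=sc.get("c_high", 10.0),
            c_low=sc.get("c_low", 0.05),
            activation=SigmoidResponse(
                r_max=sc.get("a_max", 1.0),
                x_half=sc.get("c_half", 1.0),
                slope=sc.get("slope", 0.15),
            ),
            n_max=sc.get("n_max", 50),
            n_high=sc.get("n_high", 1),
        )
        return calcium_sweep(scen)
    if kind == "robustness_fluctuations":
        model = FluctuationModel(
            invagination=sc.get("invagination", 5.0),
            pore_rate_density=sc.get("pore_rate_density", 2.0),
            pore_conductance=sc.get("pore_conductance", 0.5),
            pore_lifetime=sc.get("pore_lifetime", 0.05),
        )
        df, exponent = fluctuation_scaling(
            model,
            sc.get("radii", [0.25, 0.5, 1.0, 2.0]),
            t_max=sc.get("t_max", 60.0),
            n_reps=sc.get("n_reps", 100),
            seed=seed,
        )
        df["fitted_exponent"] = exponent
        return df
    if kind == "robustness_spins":
        rows = []
        for J in sc.get("couplings", [0.0, 1.0, 2.0]):
            ens = SpinEnsemble(
                n_agents=sc.get("n_agents", 3),
                coupling=float(J),
                bias=sc.get("bias", 1.0),
                beta_inv=sc.get("beta_inv", 1.0),
                horizon=sc.get("horizon", 10.0),
                topology=sc.get("topology", "complete"),
                dynamics=sc.get("dynamics", "heat_bath"),
                definition=sc.get("definition", "first_hit"),
                seed=seed,
            )
            row = {"N": ens.n_agents, "J": J, "h": ens.bias}
            if ens.n_agents <= 12:
                row["P_exact"] = spin_failure_probability(ens, "exact").p_catastrophe
            mc = spin_failure_probability(ens, "monte_carlo", n_reps=sc.get("n_reps", 500))
            row["P_mc"] = mc.p_catastrophe
            row["se"] = mc.stderr
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown scenario kind {kind!r}")


def run_scenario(cfg: dict, outdir, seed: int | None = None) -> ReportBundle:
    """Run every scenario in the config; write CSVs and a provenance record.

    ``seed`` overrides the config's global seed.  Per-scenario seeds are
    spawned deterministically from the root seed in scenario order, so
    identical config + seed reproduces every table exactly.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = seed if seed is not None else cfg.get("seed", 0)
    ss = np.random.SeedSequence(root_seed)
    scenarios = cfg.get("scenarios", [])
    subs = ss.spawn(len(scenarios))
    bundle = ReportBundle()
    seeds_used = []
    for i, sc in enumerate(scenarios):
        kind = sc["kind"]
        sub_seed = int(subs[i].generate_state(1)[0])
        seeds_used.append({"scenario": i, "kind": kind, "seed": sub_seed})
        log.info("running scenario %d (%s) with seed %d", i, kind, sub_seed)
        df = _run_one(kind, sc, sub_seed)
        path = outdir / f"{i:02d}_{kind}.csv"
        df.to_csv(path, index=False)
        bundle[f"{i:02d}_{kind}"] = path
    prov = {
        "toolkit_version": __version__,
        "config_sha256": _config_hash(cfg),
        "root_seed": root_seed,
        "scenario_seeds": seeds_used,
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True))
    bundle["provenance"] = prov_path
    return bundle
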