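"""Seeded, self-describing scenario fixture files.

Each fixture is a small YAML scenario usable directly by
:func:`mitonet.scenario.run_scenario`, by the test suite and by the
documentation examples.  Regenerating a fixture with the same seed is
byte-identical (sorted keys, canonical dumping).
"""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["FIXTURE_KINDS", "generate_fixtures"]

FIXTURE_KINDS = ("lattice_demo", "qc_demo", "atp_grid", "calcium_demo", "robustness_demo")


def _fixture_config(kind: str, seed: int) -> dict:
    if kind == "lattice_demo":
        return {
            "seed": seed,
            "scenarios": [
                {
                    "kind": "lattice_timeseries",
                    "L": 32,
                    "d": 2,
                    "lambda_fus": 1.0,
                    "lambda_fis": 1.0,
                    "dt": 0.25,
                    "n_steps": 40,
                    "boundary": "open",
                },
            ],
        }
    if kind == "qc_demo":
        # regime with an interior healthy fraction 0 < h* < 1
        return {
            "seed": seed,
            "scenarios": [
                {
                    "kind": "qc_sweep",
                    "lambda_fus_grid": [0.1, 0.3, 1.0, 3.0, 10.0],
                    "s": 0.2,
                    "lambda_fis": 0.5,
                    "mu": 0.3,
                    "delta": 0.05,
                },
            ],
        }
    if kind == "atp_grid":
        # potentials straddling the half-maximum so all three fusion
        # outcomes (dr < 0, dr > 0, dr ~ 0) are populated
        return {
            "seed": seed,
            "scenarios": [
                {
                    "kind": "atp_sign_map",
                    "psi_min": 60.0,
                    "psi_max": 240.0,
                    "n_psi": 25,
                    "psi_half": 150.0,
                    "slope": 10.0,
                    "rule": "mean",
                },
            ],
        }
    if kind == "calcium_demo":
        return {
            "seed": seed,
            "scenarios": [
                {
                    "kind": "calcium_sweep",
                    "c_high": 10.0,
                    "c_low": 0.05,
                    "c_half": 1.0,
                    "slope": 0.15,
                    "n_max": 50,
                },
            ],
        }
    if kind == "robustness_demo":
        return {
            "seed": seed,
            "scenarios": [
                {
                    "kind": "robustness_fluctuations",
                    "radii": [0.25, 0.5, 1.0, 2.0],
                    "t_max": 60.0,
                    "n_reps": 100,
                },
                {
                    "kind": "robustness_spins",
                    "n_agents": 3,
                    "couplings": [0.0, 0.5, 1.0, 2.0],
                    "bias": 1.0,
                    "beta_inv": 1.0,
                    "horizon": 10.0,
                    "n_reps": 500,
                },
            ],
        }
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")


def generate_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write the fixture of the given kind; returns the written paths."""
    cfg = _fixture_config(kind, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{kind}.yaml"
    text = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)
    path.write_text(text)
    return [path]
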