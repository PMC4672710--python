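"""Figure-style summaries of the three headline model outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_diffusion_surface", "plot_sign_map", "plot_calcium_curve"]


def plot_diffusion_surface(df: pd.DataFrame, ax=None):
    """D(p) curves, one line per tau, from a diffusion_surface table."""
    if ax is None:
        _, ax = plt.subplots()
    for tau, sub in df.groupby("tau"):
        sub = sub.sort_values("p")
        label = "tau = inf" if np.isinf(tau) else f"tau = {tau:g}"
        ax.plot(sub["p"], sub["D"], marker="o", label=label)
    ax.set_xlabel("p (fraction of fused bonds)")
    ax.set_ylabel("apparent diffusion coefficient D")
    ax.legend()
    return ax


def plot_sign_map(df: pd.DataFrame, ax=None):
    """Heat map of the net ATP-rate change over the (psi1, psi2) plane."""
    if ax is None:
        _, ax = plt.subplots()
    piv = df.pivot(index="psi2", columns="psi1", values="delta_r")
    vmax = float(np.abs(piv.values).max()) or 1.0
    im = ax.pcolormesh(
        piv.columns, piv.index, piv.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.figure.colorbar(im, ax=ax, label="net change in ATP synthesis rate")
    ax.set_xlabel("psi_1 (mV)")
    ax.set_ylabel("psi_2 (mV)")
    return ax


def plot_calcium_curve(df: pd.DataFrame, ax=None):
    """Total enzyme output vs chain length from a calcium_sweep table."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(df["n"], df["total_output"], marker="o")
    i = int(df["total_output"].idxmax())
    ax.axvline(df["n"][i], ls="--", color="grey")
    ax.set_xlabel("number of fused mitochondria n")
    ax.set_ylabel("total enzyme output")
    return ax
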