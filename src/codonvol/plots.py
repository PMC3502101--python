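"""Scatterplot layouts for the three headline comparisons.

Thin wrappers over matplotlib producing (i) volatility P vs dN/dS, (ii) the
usage Axis 1/Axis 2 plane with a flagged subset overlaid, and (iii) Axis 1
vs GC3 with its regression line.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import fit_linear


def plot_volatility_vs_omega(gmt: pd.DataFrame, ax=None):
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    sub = gmt[["omega", "p_value"]].dropna()
    ax.scatter(sub["omega"], sub["p_value"], s=8, alpha=0.6, color="0.2")
    ax.set_xlabel("dN/dS")
    ax.set_ylabel("codon volatility P-value")
    return ax


def plot_usage_axes(gmt: pd.DataFrame, flag: str | None = None, ax=None):
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    ax.scatter(gmt["axis1"], gmt["axis2"], s=8, alpha=0.5, color="0.2", label="all genes")
    if flag and flag in gmt.columns and gmt[flag].any():
        sub = gmt[gmt[flag].astype(bool)]
        ax.scatter(sub["axis1"], sub["axis2"], s=10, alpha=0.8, color="0.7", label=flag)
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("Axis 1")
    ax.set_ylabel("Axis 2")
    return ax


def plot_axis1_vs_gc3(gmt: pd.DataFrame, ax=None):
    ax = ax or plt.subplots(figsize=(5, 4))[1]
    sub = gmt[["gc3", "axis1"]].dropna()
    ax.scatter(sub["gc3"], sub["axis1"], s=8, alpha=0.5, color="0.2")
    reg = fit_linear(sub["gc3"], sub["axis1"])
    xs = np.linspace(sub["gc3"].min(), sub["gc3"].max(), 50)
    ax.plot(xs, reg.slope * xs + reg.intercept, color="k",
            label=f"y = {reg.slope:.3f}x + {reg.intercept:.3f}  (R² = {reg.r_squared:.3f})")
    ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("GC3")
    ax.set_ylabel("Axis 1")
    return ax
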