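"""Plots mirroring the model's standard figures: population and damage
traces over time, and the final spatial damage map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import Snapshot, TimeSeries
from .io import PALETTE


def plot_populations(ts: TimeSeries, ax=None):
    """Active Teff (red), active Treg (blue) and virus (green) counts vs time."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ts.steps, ts.teff_active, color="red", lw=0.8, label="active Teff")
    ax.plot(ts.steps, ts.treg_active, color="blue", lw=0.8, label="active Treg")
    ax.plot(ts.steps, ts.virus, color="green", lw=0.8, label="virus")
    ax.set_xlabel("time step")
    ax.set_ylabel("agents")
    ax.legend(frameon=False)
    return ax


def plot_damage(ts: TimeSeries, ax=None):
    """Recoverable (blue), unrecoverable (red) and total (black) damage vs time."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(ts.steps, ts.recoverable, color="blue", lw=0.8, label="recoverable")
    ax.plot(ts.steps, ts.unrecoverable, color="red", lw=0.8, label="unrecoverable")
    ax.plot(ts.steps, ts.total, color="black", lw=0.8, label="total")
    ax.set_xlabel("time step")
    ax.set_ylabel("damage (myelin units)")
    ax.legend(frameon=False)
    return ax


def plot_snapshot(snap: Snapshot, ax=None):
    """Spatial damage map: one cell per patch, 3-level palette."""
    if ax is None:
        _, ax = plt.subplots()
    rgb = np.zeros((*snap.categories.shape, 3), dtype=np.uint8)
    for code, color in PALETTE.items():
        rgb[snap.categories == code] = color
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
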