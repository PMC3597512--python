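"""Minimal matplotlib figures for motif matrices, spacers, and metaprofiles."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from pirnakit.minicluster import SpacerProfile
from pirnakit.motif import MotifMatrix
from pirnakit.profiles import MetaProfile

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_motif_matrix(matrix: MotifMatrix, ax=None):
    """Stacked-letter-height logo: per-position information split by base
    frequency, corrected for genome composition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * len(matrix.freq) + 1, 2.5))
    for x, (pos, row) in enumerate(matrix.freq.iterrows()):
        bottom = 0.0
        total_bits = matrix.info.loc[pos]
        for base in sorted(row.index, key=lambda b: row[b]):
            h = row[base] * total_bits
            if h <= 0:
                continue
            ax.bar(x, h, bottom=bottom, color=_BASE_COLORS[base], width=0.8)
            bottom += h
    ax.set_xticks(range(len(matrix.freq)))
    ax.set_xticklabels(matrix.freq.index, fontsize=7)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    return ax


def plot_spacer_profile(profile: SpacerProfile, ax=None, canonical=(35, 42)):
    """Mean abundance vs spacer length for miniclustered and solitary loci,
    with the canonical spacer range marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for group, color in (("miniclustered", "#1f77b4"), ("solitary", "#7f7f7f")):
        mean = profile.profile[(group, "mean_rpm")]
        sem = profile.profile[(group, "sem")]
        ax.errorbar(profile.profile.index, mean, yerr=sem, label=group, color=color)
    for x in canonical:
        ax.axvline(x, linestyle=":", color="black", linewidth=0.8)
    ax.set_xlabel("spacer length (nt)")
    ax.set_ylabel("mean abundance (RPM)")
    ax.legend(frameon=False)
    return ax


def plot_metaprofile(profile: MetaProfile, ax=None, label=None, color="#1f77b4"):
    """Mean signal per offset with an SEM band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.offsets, profile.mean, color=color, label=label)
    sem = np.nan_to_num(profile.sem)
    ax.fill_between(
        profile.offsets, profile.mean - sem, profile.mean + sem,
        color=color, alpha=0.25, linewidth=0,
    )
    ax.set_xlabel("offset (nt)")
    ax.set_ylabel("mean signal")
    if label:
        ax.legend(frameon=False)
    return ax
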