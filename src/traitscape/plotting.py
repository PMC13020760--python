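"""Summary plots for ensemble runs (reference-pair and path-space panels)."""

from __future__ import annotations

import numpy as np

from .ensemble import EnsembleSummary, jumper_position_profile


def plot_reference_summary(summary: EnsembleSummary):
    """2x2 panel: M, EBref/ET, greedy-step count, selected-SME spectrum."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    t = summary.table

    ax = axes[0, 0]
    M = t["M"].to_numpy()
    ax.hist(M, bins=np.arange(1.5, M.max() + 1.5), density=True, color="steelblue")
    ax.set_xlabel("M (mutations between references)")
    ax.set_ylabel("probability")

    ax = axes[0, 1]
    ax.hist(t["EBref_over_ET"], bins=40, density=True, color="steelblue")
    ax.set_xlabel(r"$E_B^{ref}/E_T$")

    ax = axes[1, 0]
    ng = np.concatenate([t["n_greedy_blue"], t["n_greedy_red"]])
    ax.hist(ng, bins=np.arange(-0.5, ng.max() + 1.5), density=True, color="steelblue")
    ax.set_xlabel("greedy steps per reference")
    ax.set_ylabel("probability")

    ax = axes[1, 1]
    ax.hist(summary.selected_smes, bins=60, density=True, color="steelblue")
    ax.set_xlabel(r"selected SME $\tilde h$")
    ax.set_yscale("log")

    fig.tight_layout()
    return fig


def plot_pathspace_summary(summary: EnsembleSummary, M_values=(6, 8, 10)):
    """1x3 panel: EC/Emaxref by M, jumper position j/M, log #paths vs M."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    t = summary.table[summary.table["analyzed"]]

    ax = axes[0]
    bins = np.arange(0, 1.0001, 0.05)
    for M in M_values:
        x = t.loc[t["M"] == M, "EC_over_Emaxref"].dropna()
        if len(x):
            ax.hist(x, bins=bins, density=True, histtype="step", label=f"M={M}")
    ax.set_xlabel(r"$E_C/E_{max}^{ref}$")
    ax.set_ylabel("density")
    ax.legend()

    ax = axes[1]
    for M in M_values:
        try:
            probs, pos = jumper_position_profile(summary, M, min_count=50)
        except ValueError:
            continue
        ax.plot(pos / M, probs, "o-", label=f"M={M}")
    ax.set_xlabel("j / M")
    ax.set_ylabel("probability")
    if ax.get_legend_handles_labels()[0]:
        ax.legend()

    ax = axes[2]
    grp = t.groupby("M")["log_n_paths"].agg(["mean", "sem"])
    ax.errorbar(grp.index, grp["mean"], yerr=grp["sem"], fmt="o-")
    ax.set_xlabel("M")
    ax.set_ylabel(r"$\langle \ln(\#\,paths) \rangle$")

    fig.tight_layout()
    return fig
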