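"""Optional figure output mirroring the standard presentation of these
studies: PMF families per ionic strength, ΔF/ΔU/−TΔS versus temperature,
and ΔC_V/ΔS/ΔU versus ionic strength."""

from __future__ import annotations

import os
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import StudyReport
from .thermo import thermo_state

__all__ = ["plot_pmfs", "plot_thermo_vs_temperature", "plot_vs_ionic_strength", "save_all_plots"]


def plot_pmfs(report: StudyReport, IS: float, ax: Optional[plt.Axes] = None):
    """All-temperature PMF overlay at one ionic strength."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for (T, is_), pmf in sorted(report.pmfs.items()):
        if is_ != IS:
            continue
        ax.plot(pmf.bin_centers, pmf.F, lw=1, label=f"{T:g} K")
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.set_xlabel(r"$\xi$ (Å)")
    ax.set_ylabel(r"$F(\xi)$ (kcal/mol)")
    ax.set_title(f"IS = {IS:g} M")
    ax.legend(fontsize=6, ncol=2)
    return ax


def plot_thermo_vs_temperature(report: StudyReport, IS: float, ax=None):
    """ΔF, ΔU and −TΔS at the contact minimum versus temperature."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    fit = report.thermo_fits[IS]
    Ts = np.array(sorted({T for (T, is_) in report.features if is_ == IS}))
    dF = np.array([report.features[(T, IS)].cm_depth for T in Ts])
    states = [thermo_state(fit, T) for T in Ts]
    ax.plot(Ts, dF, "o", ms=4, label=r"$\Delta F$(CM)")
    ax.plot(Ts, fit.predict(Ts), "-", lw=1)
    ax.plot(Ts, [s.dU for s in states], "s-", ms=3, lw=1, label=r"$\Delta U$")
    ax.plot(Ts, [-s.T * s.dS for s in states], "^-", ms=3, lw=1, label=r"$-T\Delta S$")
    ax.set_xlabel("T (K)")
    ax.set_ylabel("kcal/mol")
    ax.set_title(f"IS = {IS:g} M")
    ax.legend(fontsize=7)
    return ax


def plot_vs_ionic_strength(report: StudyReport, ax=None):
    """ΔC_V, ΔS and ΔU at the evaluation temperature versus ionic strength."""
    if ax is None:
        _, axes = plt.subplots(3, 1, figsize=(4, 7), sharex=True)
    else:
        axes = ax
    ISs = np.array(sorted(report.thermo_states))
    states = [report.thermo_states[i] for i in ISs]
    axes[0].errorbar(ISs, [s.dCv for s in states], yerr=[s.dCv_err for s in states], fmt="o-")
    axes[0].set_ylabel(r"$\Delta C_V$ (cal mol$^{-1}$ K$^{-1}$)")
    axes[1].errorbar(ISs, [s.dS for s in states], yerr=[s.dS_err for s in states], fmt="o-")
    axes[1].set_ylabel(r"$\Delta S$ (kcal mol$^{-1}$ K$^{-1}$)")
    axes[2].errorbar(ISs, [s.dU for s in states], yerr=[s.dU_err for s in states], fmt="o-")
    axes[2].set_ylabel(r"$\Delta U$ (kcal/mol)")
    axes[2].set_xlabel(r"IS (mol/dm$^3$)")
    return axes


def save_all_plots(report: StudyReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for IS in sorted({is_ for (_, is_) in report.pmfs}):
        ax = plot_pmfs(report, IS)
        ax.figure.savefig(os.path.join(out_dir, f"pmf_IS{IS:g}.png"), dpi=150)
        plt.close(ax.figure)
    for IS in sorted(report.thermo_fits):
        ax = plot_thermo_vs_temperature(report, IS)
        ax.figure.savefig(os.path.join(out_dir, f"thermo_T_IS{IS:g}.png"), dpi=150)
        plt.close(ax.figure)
    if report.thermo_states:
        axes = plot_vs_ionic_strength(report)
        axes[0].figure.tight_layout()
        axes[0].figure.savefig(os.path.join(out_dir, "thermo_vs_IS.png"), dpi=150)
        plt.close(axes[0].figure)
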