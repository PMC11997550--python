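"""Figure conveniences for trajectories.

The standard four-panel layout mirrors the model-output figures the
simulator is judged against: areal reserves and biomass; normalised
reserves; pigments; reaction-centre state fractions.  A fifth panel shows
per-cell ROS and the expulsion rate with the bleaching threshold drawn in.
Daily tick marks fall at 0:00 h.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["PANELS", "plot_trajectory"]

PANELS = ("reserves", "normalised", "pigments", "reaction_centres", "ros")


def _day_ticks(ax, times) -> None:
    ax.set_xticks(np.arange(0, np.floor(times[-1]) + 1, 2))
    ax.set_xlabel("time (d)")


def plot_trajectory(traj, panels=PANELS, out_prefix: str | None = None):
    """Render the requested panels; returns the list of files written
    (empty panel list writes nothing)."""
    written: list[str] = []
    fr = traj.frame
    t = fr["time"].to_numpy()
    theta = traj.config.photophysiology.ros_threshold
    for panel in panels:
        if panel not in PANELS:
            raise ValueError(f"unknown panel {panel!r}; valid: {PANELS}")
        fig, ax = plt.subplots(figsize=(7, 3.2), constrained_layout=True)
        if panel == "reserves":
            ax.plot(t, fr["cs"], label="biomass CS (mg N m$^{-2}$)")
            ax.plot(t, fr["r_n"], label="R$_N$ (mg N m$^{-2}$)")
            ax.plot(t, fr["r_c"], label="R$_C$ (mg C m$^{-2}$)")
            ax.plot(t, fr["r_p"], label="R$_P$ (mg P m$^{-2}$)")
            ax.set_ylabel("areal mass")
        elif panel == "normalised":
            for col, lab in (("rn_norm", "R$_N^*$"), ("rc_norm", "R$_C^*$"),
                             ("rp_norm", "R$_P^*$")):
                ax.plot(t, fr[col], label=lab)
            ax.set_ylabel("normalised reserve (-)")
            ax.set_ylim(0, 1.05)
        elif panel == "pigments":
            ax.plot(t, fr["chl"], label="Chl a")
            ax.plot(t, fr["x_p"], label="diadinoxanthin X$_p$")
            ax.plot(t, fr["x_h"], label="diatoxanthin X$_h$")
            ax.set_ylabel("pigment (mg m$^{-2}$)")
        elif panel == "reaction_centres":
            for col, lab in (("f_ox", "oxidised"), ("f_red", "reduced"),
                             ("f_in", "inhibited")):
                ax.plot(t, fr[col], label=lab)
            ax.set_ylabel("RCII state fraction (-)")
            ax.set_ylim(0, 1.05)
        else:  # ros
            ax.plot(t, fr["ros_percell"], label="[ROS] (mg O cell$^{-1}$)")
            ax.axhline(theta, color="k", ls="--", lw=1,
                       label=f"threshold {theta:.2e}")
            ax2 = ax.twinx()
            ax2.plot(t, fr["expulsion"], color="C3", label="expulsion (d$^{-1}$)")
            ax2.set_ylabel("expulsion rate (d$^{-1}$)")
            ax.set_ylabel("[ROS] (mg O cell$^{-1}$)")
        _day_ticks(ax, t)
        ax.legend(loc="best", fontsize=8)
        if out_prefix is not None:
            path = f"{out_prefix}_{panel}.png"
            fig.savefig(path, dpi=120)
            written.append(path)
        plt.close(fig)
    return written
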