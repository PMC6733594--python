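"""Plot helpers for signalling profiles and timecourse morphometry."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .phresh_quant import IntensityProfile, SpatiotemporalMap  # noqa: E402

#: Intensity axes are drawn 0-50% of the unconverted green maximum.
INTENSITY_YLIM = (0.0, 50.0)


def plot_profile(profile: IntensityProfile, ax=None, label=None,
                 ylim=INTENSITY_YLIM):
    """One DV or ML profile; a dotted line marks the spinal canal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 2.4))
    ax.plot(profile.positions, profile.values, label=label)
    ax.axvline(profile.canal_frac, ls=":", color="0.5", lw=0.8)
    ax.set_xlabel(f"{profile.axis} position (fraction)")
    ax.set_ylabel("Kaede-green (% of unconverted max)")
    ax.set_ylim(*ylim)
    return ax


def plot_map(smap: SpatiotemporalMap, path=None, ylim=INTENSITY_YLIM):
    """DV and ML profile panels for every conversion time of a map."""
    t0s = smap.t0_grid
    fig, axes = plt.subplots(2, len(t0s), squeeze=False,
                             figsize=(2.2 * len(t0s), 4.2), sharey=True)
    for j, t0 in enumerate(t0s):
        entry = smap[t0]
        plot_profile(entry.dv, ax=axes[0][j], ylim=ylim)
        plot_profile(entry.ml, ax=axes[1][j], ylim=ylim)
        axes[0][j].set_title(f"t0 = {t0:g} hpf", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
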