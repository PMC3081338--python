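"""Matplotlib figures mirroring the standard views of this analysis:
density/noise profiles along x/L, the threshold scan, and the pixel
histogram triplet with its enrichment ratio."""

from __future__ import annotations

import numpy as np


def plot_profile(profile, ax=None):
    """rho(x/L) with bootstrap error bars when present."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = profile.table
    if {"rho_ci_lo", "rho_ci_hi"}.issubset(t.columns):
        yerr = np.vstack([t["rho"] - t["rho_ci_lo"],
                          t["rho_ci_hi"] - t["rho"]])
        ax.errorbar(t["bin_mid"], t["rho"], yerr=yerr, fmt="o-", ms=3)
    else:
        ax.plot(t["bin_mid"], t["rho"], "o-", ms=3)
    ax.set_xlabel("x/L")
    ax.set_ylabel(r"$\rho$ (dots/nucleus)")
    return ax


def plot_threshold_scan(scan_table, chosen=None, ax=None):
    """delta-rho between the two expression regions vs intensity threshold."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(scan_table["t_intensity"], scan_table["delta_rho"], "o-", ms=3)
    if chosen is not None:
        ax.axvline(chosen, ls="--", color="k")
    ax.set_xlabel("pixel intensity threshold")
    ax.set_ylabel(r"$\Delta\rho$")
    return ax


def plot_pixel_histograms(bin_hist, ax=None):
    """P(B_pix) for inactive/active nuclei and dot sites in one bin."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    colors = {"inactive": "tab:blue", "active": "tab:red",
              "dot_sites": "tab:green"}
    for name in ("inactive", "active", "dot_sites"):
        h = getattr(bin_hist, name)
        if h is None:
            continue
        ax.plot(np.arange(256), h.density, color=colors[name], label=name)
    ax.set_xlabel(r"$B_{pix}$")
    ax.set_ylabel(r"$P(B_{pix})$")
    ax.legend(frameon=False)
    return ax


def plot_enrichment_ratio(ratio, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.plot(np.arange(256), ratio, ".-", ms=2)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xlabel(r"$B_{pix}$")
    ax.set_ylabel("dot-site / active-nucleus density ratio")
    return ax
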