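"""Plot helpers for decompositions, matched pairs and allocation fits.

All functions take/return matplotlib Axes so they compose into figure
grids; none is required by the numerical pipeline.
"""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_explained_variance(decomp, ax=None):
    """Ranked bar plot of per-component explained variance."""
    ax = _get_ax(ax)
    ev = np.sort(decomp.component_ev)[::-1]
    ax.bar(range(1, len(ev) + 1), ev)
    ax.set_xlabel("component rank")
    ax.set_ylabel("explained variance")
    ax.set_title(f"cumulative EV = {decomp.cumulative_ev:.2f}")
    return ax


def plot_dima(dima_result, ax=None):
    """Activity-vs-activity scatter with the differential band."""
    ax = _get_ax(ax)
    df = dima_result.to_frame()
    base = df[~df["differential"]]
    diff = df[df["differential"]]
    ax.scatter(base["ti_activity"], base["pi_activity"], s=12, c="gray")
    ax.scatter(diff["ti_activity"], diff["pi_activity"], s=18, c="red")
    lo = min(df["ti_activity"].min(), df["pi_activity"].min())
    hi = max(df["ti_activity"].max(), df["pi_activity"].max())
    ax.plot([lo, hi], [lo, hi], ls="--", c="k", lw=0.8)
    ax.set_xlabel("tiModulon activity")
    ax.set_ylabel("piModulon activity")
    ax.set_title(f"r = {dima_result.correlation:.2f} ({dima_result.dominance})")
    return ax


def plot_dimm(dimm_df, threshold_t=None, threshold_p=None, ax=None):
    """Gene-weight scatter for a matched pair; members in both in red."""
    ax = _get_ax(ax)
    both = dimm_df["in_both"]
    ax.scatter(dimm_df.loc[~both, "ti_weight"], dimm_df.loc[~both, "pi_weight"],
               s=8, c="gray")
    ax.scatter(dimm_df.loc[both, "ti_weight"], dimm_df.loc[both, "pi_weight"],
               s=14, c="red")
    for thr, fn in ((threshold_t, ax.axvline), (threshold_p, ax.axhline)):
        if thr is not None:
            fn(thr, ls="--", c="gray", lw=0.8)
            fn(-thr, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("tiModulon gene weight")
    ax.set_ylabel("piModulon gene weight")
    return ax


def plot_allocation_fit(fit, x, y, ax=None):
    """Activity vs mass-fraction scatter with the selected regression."""
    ax = _get_ax(ax)
    x = np.asarray(x, float)
    ax.scatter(x, y, s=14)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, fit.predict(grid), c="C1")
    ax.set_xlabel("tiModulon activity")
    ax.set_ylabel("proteome mass fraction")
    ax.set_title(
        f"{fit.ti_index}: {fit.family}, adj R$^2$={fit.adjusted_r2:.2f} "
        f"({fit.strength})"
    )
    return ax
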