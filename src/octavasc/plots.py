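"""Report figures: split-violin depth distributions and class timelines."""

from __future__ import annotations

import numpy as np

from .phantom import TIMEPOINTS


def plot_depth_violins(results, ax=None, max_width_um=20.0):
    """Split-violin plot of pre (left) vs post (right) diameter distributions
    per 50-um depth bin; horizontal bars mark median and quartiles."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, r in enumerate(results):
        x0 = i
        for side, vals, color in ((-1, r.pre, "tab:green"), (1, r.post, "tab:pink")):
            if vals.size < 3 or np.ptp(vals) == 0:
                continue
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 80)
            dens = kde(grid)
            dens = 0.4 * dens / dens.max()
            ax.fill_betweenx(grid, x0, x0 + side * dens, color=color, alpha=0.6, lw=0)
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            ax.hlines(med, x0, x0 + side * 0.3, colors="black", lw=2)
            ax.hlines([q25, q75], x0, x0 + side * 0.2, colors="black", lw=0.8)
        label = f"{r.bin_lo_um:.0f}-{r.bin_hi_um:.0f}"
        if r.mannwhitney_p is not None and r.mannwhitney_p < 0.05:
            label += f"\np={r.mannwhitney_p:.3f}"
        ax.text(x0, -2.0, f"n={r.n_pre}|{r.n_post}", ha="center", fontsize=7)
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([f"{r.bin_lo_um:.0f}" for r in results])
    ax.set_xlabel("depth bin (um below surface)")
    ax.set_ylabel("branch diameter (um)")
    return ax


def plot_class_timeline(track_table, ax=None, timepoints=TIMEPOINTS):
    """Per-animal mean normalized diameters over the imaging timeline,
    one line per animal, one panel color per diameter class."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .longitudinal import per_animal_summary

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    colors = {"<15": "tab:red", "15-20": "tab:orange", ">20": "tab:blue"}
    xs = np.arange(len(timepoints))
    for cls, color in colors.items():
        s = per_animal_summary(track_table, cls, timepoints)
        if len(s) == 0:
            continue
        for _, row in s.iterrows():
            ax.plot(xs, [row[f"norm_{t}"] for t in timepoints],
                    color=color, alpha=0.35, lw=0.8)
        means = [s[f"norm_{t}"].mean() for t in timepoints]
        ax.plot(xs, means, color=color, lw=2.5, label=cls)
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xticks(xs)
    ax.set_xticklabels(timepoints, rotation=20)
    ax.set_ylabel("normalized diameter")
    ax.legend(title="baseline class")
    return ax
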