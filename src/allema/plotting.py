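"""Optional figures for the Monte Carlo and power studies.

Requires matplotlib (the ``plot`` extra); imports are deferred so the core
toolkit stays usable without it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cv_comparison_bars", "sampling_rate_boxplots",
           "detectability_plot"]


def cv_comparison_bars(results, level: str = "class", ax=None):
    """Bar chart of per-category CV (%) for each compared design.

    ``results`` is the mapping returned by
    :func:`allema.simulate.run_design_comparison`; categories are ordered
    by decreasing mean estimated share (frequent types first).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    first = next(iter(results.values()))
    order = first.estimates.mean(axis=0)
    if level == "class":
        cvs = {name: res.cv_class for name, res in results.items()}
        order = None
    else:
        cvs = {name: res.cv_habitat for name, res in results.items()}
        order = order.sort_values(ascending=False).index
    width = 0.8 / len(cvs)
    for k, (name, cv) in enumerate(cvs.items()):
        if order is not None:
            cv = cv.reindex(order)
        x = np.arange(len(cv))
        ax.bar(x + k * width, cv.to_numpy(), width=width, label=name)
    ax.set_ylabel("CV (%)")
    ax.set_xlabel("category (decreasing frequency)")
    ax.legend()
    return ax


def sampling_rate_boxplots(results, ax=None):
    """Boxplots of realized per-stratum sampling shares across draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, len(results), figsize=(4 * len(results), 3),
                             squeeze=False)
        ax = ax[0]
    for a, (name, res) in zip(ax, results.items()):
        res.sampling_rates.boxplot(ax=a)
        a.set_title(name)
        a.set_ylabel("share of sample")
    return ax


def detectability_plot(table: pd.DataFrame, m_available: int = 170, ax=None):
    """Minimum sample sizes per target with the available-m reference line.

    ``table`` comes from :func:`allema.power.detectability_table`; one
    marker per (target, delta) at fixed rho/power is drawn for each
    combination present.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    targets = list(dict.fromkeys(table["target"]))
    xpos = {t: i for i, t in enumerate(targets)}
    for delta, block in table.groupby("delta"):
        ax.scatter([xpos[t] for t in block["target"]], block["m_min"],
                   label=f"delta={delta:g}", alpha=0.7)
    ax.axhline(m_available, color="green", lw=1.5)
    ax.set_yscale("log")
    ax.set_xticks(range(len(targets)), targets, rotation=90)
    ax.set_ylabel("minimum number of squares")
    ax.legend()
    return ax
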