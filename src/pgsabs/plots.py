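"""Static plots of per-quantile absolute-scale estimates."""

from __future__ import annotations

import numpy as np

from pgsabs.binary import AbsoluteRiskTable
from pgsabs.continuous import AbsoluteTraitTable


def plot_risk_table(table: AbsoluteRiskTable, path: str, highlight: int | None = None):
    """Bar chart of case probability per score quantile; saves PNG to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = table.partition.n_quantiles
    fig, ax = plt.subplots(figsize=(8, 4.5))
    colors = ["#4878a8"] * n
    if highlight is not None:
        colors[highlight] = "#c44e52"
    ax.bar(np.arange(1, n + 1), 100.0 * table.case_probability, color=colors, width=0.9)
    ax.axhline(100.0 * table.model.prevalence, ls="--", c="grey", lw=1,
               label=f"prevalence {100 * table.model.prevalence:g}%")
    ax.set_xlabel(f"Polygenic score quantile (of {n})")
    ax.set_ylabel("Probability of being a case (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trait_table(
    table: AbsoluteTraitTable, path: str, level: float = 0.95, highlight: int | None = None
):
    """Per-quantile trait mean with prediction-interval whiskers; saves PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    n = table.partition.n_quantiles
    x = np.arange(1, n + 1)
    half = norm.ppf((1 + level) / 2) * table.trait_sd
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.errorbar(x, table.trait_mean, yerr=half, fmt="o", ms=4, capsize=2,
                color="#4878a8", ecolor="#a8c4d8")
    if highlight is not None:
        ax.plot(x[highlight], table.trait_mean[highlight], "o", ms=6, color="#c44e52")
    ax.axhline(table.model.trait_mean, ls="--", c="grey", lw=1,
               label=f"population mean {table.model.trait_mean:g}")
    ax.set_xlabel(f"Polygenic score quantile (of {n})")
    ax.set_ylabel(f"Trait value (mean with {100 * level:g}% prediction interval)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
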