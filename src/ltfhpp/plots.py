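"""Quick-look Manhattan and Q-Q plots for summary-statistics tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan_plot", "qq_plot"]


def manhattan_plot(results: pd.DataFrame, ax=None, alpha: float = 5e-8):
    """-log10 p per variant, with the significance threshold drawn."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    p = results["p"].to_numpy(dtype=float)
    logp = -np.log10(np.clip(p, 1e-320, 1.0))
    ax.scatter(np.arange(logp.size), logp, s=4, color="#3b5b92")
    ax.axhline(-np.log10(alpha), color="red", lw=0.8, ls="--")
    ax.set_xlabel("variant index")
    ax.set_ylabel(r"$-\log_{10} p$")
    label = results.get("phenotype")
    if label is not None and len(label):
        ax.set_title(str(label.iloc[0]))
    return ax


def qq_plot(results: pd.DataFrame, ax=None):
    """Observed vs expected -log10 p under the uniform null."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    p = np.sort(results["p"].to_numpy(dtype=float))
    n = p.size
    expected = -np.log10((np.arange(n) + 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-320, 1.0))
    ax.scatter(expected, observed, s=4, color="#3b5b92")
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], color="black", lw=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    return ax
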