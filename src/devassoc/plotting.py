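"""Figure-ready outputs: signed -log10(p) bar/point charts.

Bars (property results per stage) or points (decile scans) show
-log10(P) * sgn(beta), with dotted lines at the Bonferroni-adjusted
significance threshold for the number of tests in the tier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_signed_bars"]


def plot_signed_bars(
    df: pd.DataFrame,
    path,
    x: str = "stage",
    y: str = "signed_log10p",
    m: int | None = None,
    alpha: float = 0.05,
    title: str = "",
    points: bool = False,
) -> None:
    fig, ax = plt.subplots(figsize=(7, 3.2))
    xs = np.arange(len(df))
    if points:
        ax.plot(xs, df[y], "o", color="tab:blue")
    else:
        ax.bar(xs, df[y], color=np.where(df[y] >= 0, "tab:red", "tab:blue"))
    if m:
        thr = -np.log10(alpha / m)
        ax.axhline(thr, ls=":", c="k", lw=0.8)
        ax.axhline(-thr, ls=":", c="k", lw=0.8)
    ax.axhline(0, c="k", lw=0.5)
    ax.set_xticks(xs)
    ax.set_xticklabels(df[x], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(P)\,\mathrm{sgn}(\beta)$")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
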