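"""Bland-Altman and correlation scatter plots for comparison reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from ctrkit.stats import bland_altman, linear_fit_r2


def bland_altman_plot(a, b, path, title: str = "") -> None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = bland_altman(a, b, "percent_of_pair_mean")
    means = (a + b) / 2.0
    diffs = 100.0 * (a - b) / means
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=4, alpha=0.4)
    for y, style in ((res.bias, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean CTR")
    ax.set_ylabel("difference (% of pair mean)")
    ax.set_title(title or f"bias {res.bias:.2f}%, CV {res.cv:.2f}%")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def scatter_fit_plot(a, b, path, title: str = "") -> None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fit = linear_fit_r2(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(a, b, s=4, alpha=0.4)
    xs = np.linspace(a.min(), a.max(), 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, color="crimson", linewidth=1)
    ax.set_xlabel("method A CTR")
    ax.set_ylabel("method B CTR")
    ax.set_title(title or f"$R^2$ = {fit.r2:.3f} ({fit.category})")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
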