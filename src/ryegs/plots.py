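"""Plots of cross-validated prediction accuracy.

Box-and-whisker panels of r_p / r_g per scheme and the accuracy-vs-
environment-count curve, mirroring how such comparisons are usually
displayed in genomic-selection studies.
"""

from __future__ import annotations

import numpy as np

from .cv import CVResult


def _axes(ax=None):
    if ax is not None:
        return ax.figure, ax
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt.subplots(figsize=(6, 4))


def plot_cv_results(results: list[CVResult], metric: str = "r_p",
                    ax=None, path=None):
    """Box-whisker comparison of accuracy distributions across schemes."""
    fig, ax = _axes(ax)
    data, labels = [], []
    for res in results:
        vals = getattr(res, metric)
        vals = vals[~np.isnan(vals)]
        data.append(vals)
        labels.append(res.scheme.replace("cv-g:", "").replace("cv-", ""))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel({"r_p": "predictive ability $r_p$",
                   "r_g": "standardized accuracy $r_g$"}.get(metric, metric))
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return ax


def plot_env_curve(results_by_k: dict[int, CVResult], ax=None, path=None):
    """Mean accuracy against the number of environments in the data."""
    fig, ax = _axes(ax)
    ks = sorted(results_by_k)
    means = [np.nanmean(results_by_k[k].r_p) for k in ks]
    q1 = [np.nanquantile(results_by_k[k].r_p, 0.25) for k in ks]
    q3 = [np.nanquantile(results_by_k[k].r_p, 0.75) for k in ks]
    ax.fill_between(ks, q1, q3, alpha=0.25, label="interquartile range")
    ax.plot(ks, means, marker="s", label="mean $r_p$")
    ax.set_xlabel("number of environments")
    ax.set_ylabel("predictive ability $r_p$")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return ax
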