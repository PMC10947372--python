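"""Cohort-level reporting: feature comparison tables and metric figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, mann_whitney_u
from .synthetic import FEATURE_COLUMNS

__all__ = ["feature_summary_table", "plot_classifier_metrics"]


def feature_summary_table(
    features: pd.DataFrame,
    groups: pd.Series,
    positive_group: str = "iRBD",
    columns: tuple[str, ...] = FEATURE_COLUMNS,
    fdr_q: float | None = None,
) -> pd.DataFrame:
    """Median [IQR] of each movement feature per group with Mann–Whitney p.

    Rows are the per-region, per-duration-bin 3D rate / 3D ratio columns;
    the two groups are ``positive_group`` vs everyone else.  With ``fdr_q``
    set, a Benjamini–Hochberg-adjusted column is appended.
    """
    pos = groups == positive_group
    rows = []
    for col in columns:
        if col not in features.columns:
            continue
        a = features.loc[pos.values, col].to_numpy(dtype=float)
        b = features.loc[~pos.values, col].to_numpy(dtype=float)
        res = mann_whitney_u(a, b)

        def summ(x: np.ndarray) -> str:
            return f"{np.median(x):.2f} [{np.percentile(x, 25):.2f}, {np.percentile(x, 75):.2f}]"

        rows.append(
            {
                "feature": col,
                positive_group: summ(a),
                "no-RBD": summ(b),
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    if fdr_q is not None:
        reject, adj = benjamini_hochberg(out["p"].to_numpy(), q=fdr_q)
        out["adj_p"] = adj
        out["reject"] = reject
    return out


def plot_classifier_metrics(
    results: dict[str, "CVResult"],
    metrics: tuple[str, ...] = ("accuracy", "f1"),
    path: str | None = None,
):
    """Bar chart of mean +/- SD test metrics across configurations."""
    names = list(results)
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        means = []
        sds = []
        for name in names:
            agg = results[name].aggregate()
            means.append(agg.loc[metric, "mean"])
            sds.append(agg.loc[metric, "sd"])
        ax.bar(range(len(names)), means, yerr=sds, capsize=3, color="#4878d0")
        ax.set_xticks(range(len(names)))
        ax.set_xticklabels(names, rotation=45, ha="right", fontsize=8)
        ax.set_ylim(0, 1)
        ax.set_ylabel(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
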