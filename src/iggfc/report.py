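"""Association heatmap rendering and its tabular twin."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def heatmap_report(results: pd.DataFrame, alpha: float, out_prefix=None):
    """Render the trait x variable t-statistic heatmap and write its TSV twin.

    ``results`` needs columns feature, variable, t, p.  Cells are colored by
    t (red positive, blue negative); p < 0.05 gets a point marker, p < alpha
    an X.  Returns (figure, matrix frame); with ``out_prefix`` writes
    ``<prefix>.png`` and ``<prefix>.tsv``.
    """
    t_mat = results.pivot_table(index="feature", columns="variable", values="t")
    p_mat = results.pivot_table(index="feature", columns="variable", values="p")
    t_mat = t_mat.reindex(columns=pd.unique(results["variable"]))
    p_mat = p_mat.reindex(columns=t_mat.columns)

    vmax = np.nanmax(np.abs(t_mat.to_numpy())) or 1.0
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.55 * t_mat.shape[1], 1.2 + 0.5 * t_mat.shape[0]))
    mesh = ax.pcolormesh(np.nan_to_num(t_mat.to_numpy()), cmap="RdBu_r",
                         vmin=-vmax, vmax=vmax, edgecolors="white")
    for i, feature in enumerate(t_mat.index):
        for j, variable in enumerate(t_mat.columns):
            p = p_mat.iloc[i, j]
            if pd.isna(p):
                continue
            if p < alpha:
                ax.plot(j + 0.5, i + 0.5, marker="x", color="black", ms=8)
            elif p < 0.05:
                ax.plot(j + 0.5, i + 0.5, marker=".", color="black", ms=6)
    ax.set_xticks(np.arange(t_mat.shape[1]) + 0.5, t_mat.columns,
                  rotation=45, ha="right")
    ax.set_yticks(np.arange(t_mat.shape[0]) + 0.5, t_mat.index)
    fig.colorbar(mesh, ax=ax, label="t = β₁/SE(β₁)")
    fig.tight_layout()

    twin = results.copy()
    twin["marker"] = np.where(twin["p"] < alpha, "X",
                              np.where(twin["p"] < 0.05, "point", ""))
    missing = t_mat.isna().sum().sum()
    if missing:
        print(f"heatmap: {int(missing)} missing cell(s) rendered blank")
    if out_prefix is not None:
        fig.savefig(f"{out_prefix}.png", dpi=150)
        twin.to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
    return fig, twin
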