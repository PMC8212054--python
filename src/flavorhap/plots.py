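"""Figure helpers: haplotype heatmap, local-association plot, diversity bars
and a simple haplotype-network drawing.

The heatmap follows the usual genotype color semantics (reference blue,
alternate red, heterozygous yellow, missing white); the association plot marks
SNPs as blue dots, INDELs as yellow dots and SVs as purple triangles, with
horizontal lines at the two FDR tiers.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib.colors import BoundaryNorm, ListedColormap

from .haplotype_clusters import ClusterAssignment, HaplotypeMatrix
from .haplotype_network import HaplotypeNetwork

GENOTYPE_COLORS = ["white", "#2166ac", "#fddc4c", "#b2182b"]  # missing, ref, het, alt


def haplotype_heatmap(
    matrix: HaplotypeMatrix,
    assignment: ClusterAssignment | None = None,
    path: str | None = None,
    title: str = "",
):
    """Accessions x variants genotype heatmap, rows ordered by cluster."""
    df = matrix.data
    if assignment is not None:
        order = assignment.labels.sort_values(kind="stable").index
        df = df.loc[order]
    x = df.to_numpy(dtype=float)
    coded = np.where(np.isnan(x), -1.0, x)
    cmap = ListedColormap(GENOTYPE_COLORS)
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5, 2.5], cmap.N)
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(coded, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_xlabel("variants (position order)")
    ax.set_ylabel("accessions")
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


_CLASS_STYLE = {
    "SNP": {"color": "#2166ac", "marker": "o"},
    "INDEL": {"color": "#fddc4c", "marker": "o"},
    "SV": {"color": "#762a83", "marker": "^"},
}


def association_plot(assoc: pd.DataFrame, path: str | None = None, title: str = ""):
    """-log10(p) against variant rank with the q<=0.05 / q<=0.01 tier lines."""
    fig, ax = plt.subplots(figsize=(9, 4))
    assoc = assoc.reset_index(drop=True)
    classes = assoc["vclass"] if "vclass" in assoc else pd.Series("SNP", index=assoc.index)
    for vclass, style in _CLASS_STYLE.items():
        sub = assoc[classes == vclass]
        if len(sub):
            ax.scatter(sub.index, sub["neg_log10_p"], s=18, label=vclass, **style)
    for q_cut, ls in ((0.05, "--"), (0.01, ":")):
        passing = assoc[assoc["q"] <= q_cut]
        if len(passing):
            ax.axhline(passing["neg_log10_p"].min(), color="grey", linestyle=ls, lw=1)
    ax.set_xlabel("variant (position order)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def diversity_barplot(gene_summary: pd.DataFrame, path: str | None = None, title: str = ""):
    """Mean pi per subpopulation, one bar group per variant class."""
    pivot = gene_summary.pivot(index="subpopulation", columns="class", values="mean_pi")
    fig, ax = plt.subplots(figsize=(9, 4))
    pivot.plot.bar(ax=ax)
    ax.set_ylabel(r"$\pi$ (per site)")
    ax.set_title(title)
    fig.autofmt_xdate(rotation=45)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def network_plot(network: HaplotypeNetwork, path: str | None = None, title: str = ""):
    """Spring-layout drawing; node size scales with member count, edge labels
    show mutational steps."""
    g = network.graph()
    pos = nx.spring_layout(g, seed=0, weight=None)
    sizes = [60 + 40 * g.nodes[n]["n_members"] for n in g.nodes]
    colors = ["#b2182b" if g.nodes[n].get("is_outgroup") else "#2166ac" for n in g.nodes]
    fig, ax = plt.subplots(figsize=(7, 6))
    nx.draw_networkx(g, pos=pos, ax=ax, node_size=sizes, node_color=colors,
                     font_size=7, edge_color="grey")
    nx.draw_networkx_edge_labels(
        g, pos=pos, ax=ax, font_size=6,
        edge_labels={(a, b): d["steps"] for a, b, d in g.edges(data=True)},
    )
    ax.set_title(title)
    ax.axis("off")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
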