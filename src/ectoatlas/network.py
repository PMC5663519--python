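"""Seed-gene co-expression networks and per-gene report cards.

From the unsigned adjacency (|bicor|^power, which keeps negative
associations), each seed gene retrieves its 50 most adjacent transcripts;
edges are drawn only when the Pearson correlation between seed and neighbor
is significant at the configured p-value cutoff (1e-10 by default), with
the edge sign recording whether the correlation is positive or negative.
Nodes carry their co-expression group id.  Networks export to GraphML and
JSON and round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .coexpression import unsigned_adjacency  # noqa: F401  (re-export)


def pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Pearson r and two-sided p from the t-transform with n-2 df."""
    n = len(x)
    xz = x - x.mean()
    yz = y - y.mean()
    denom = np.linalg.norm(xz) * np.linalg.norm(yz)
    if denom == 0:
        return 0.0, 1.0
    r = float(np.clip(xz @ yz / denom, -1.0, 1.0))
    if n < 3 or abs(r) == 1.0:
        return r, 0.0 if abs(r) == 1.0 else 1.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * t_dist.sf(abs(tstat), n - 2))


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    seeds: tuple
    p_cutoff: float
    top_k: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def seed_network(seeds, adjacency, expr, groups=None,
                 p_cutoff: float = 1e-10, top_k: int = 50
                 ) -> CoexpressionNetwork:
    """Build the co-expression network around seed genes.

    Parameters
    ----------
    adjacency
        Unsigned adjacency as a DataFrame (transcripts x transcripts) or a
        plain array aligned with ``expr``'s genes.
    expr
        ExpressionMatrix (or DataFrame of log expression) used for the
        Pearson correlations.
    groups
        Optional CoexpressionGroups (or Series) supplying node group ids.
    """
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "genes") \
        else expr
    ids = values.index
    adj = adjacency if isinstance(adjacency, pd.DataFrame) \
        else pd.DataFrame(np.asarray(adjacency), index=ids, columns=ids)
    unknown = [s for s in seeds if s not in adj.index]
    if unknown:
        raise ValueError(f"unknown seed gene(s): {unknown}")
    labels = None
    if groups is not None:
        labels = groups.labels if hasattr(groups, "labels") else groups
    g = nx.Graph()

    def add_node(gene, is_seed):
        grp = int(labels.get(gene, 0)) if labels is not None else 0
        g.add_node(gene, is_seed=bool(is_seed), group=grp)

    for seed in seeds:
        add_node(seed, True)
        neigh = adj.loc[seed].drop(index=seed).nlargest(top_k)
        xs = values.loc[seed].to_numpy().astype(float)
        for other in neigh.index:
            r, p = pearson_with_p(xs, values.loc[other].to_numpy()
                                  .astype(float))
            if p <= p_cutoff:
                add_node(other, other in seeds)
                g.add_edge(seed, other, correlation=float(r), p_value=p,
                           sign=1 if r >= 0 else -1)
    return CoexpressionNetwork(g, tuple(seeds), p_cutoff, top_k)


def export_network(network: CoexpressionNetwork, out_dir) -> dict:
    """Write GraphML plus JSON node/edge tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gml = out / "network.graphml"
    nx.write_graphml(network.graph, gml)
    payload = {
        "seeds": list(network.seeds),
        "p_cutoff": network.p_cutoff,
        "top_k": network.top_k,
        "nodes": [{"id": n, **d} for n, d in network.graph.nodes(data=True)],
        "edges": [{"source": u, "target": v, **d}
                  for u, v, d in network.graph.edges(data=True)],
    }
    js = out / "network.json"
    js.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"graphml": gml, "json": js}


def load_network(out_dir) -> CoexpressionNetwork:
    """Round-trip loader for :func:`export_network` JSON output."""
    payload = json.loads((Path(out_dir) / "network.json").read_text())
    g = nx.Graph()
    for node in payload["nodes"]:
        node = dict(node)
        g.add_node(node.pop("id"), **node)
    for edge in payload["edges"]:
        edge = dict(edge)
        g.add_edge(edge.pop("source"), edge.pop("target"), **edge)
    return CoexpressionNetwork(g, tuple(payload["seeds"]),
                               payload["p_cutoff"], payload["top_k"])


def report_gene(gene: str, expr=None, W_full=None, enrichment_scores=None,
                groups=None, adjacency=None, top_coexpressed: int = 10
                ) -> dict:
    """Assemble one gene's report card from whatever layers are available.

    Layers the gene is absent from are omitted with a note.  Returns a dict
    with keys among ``nmf_pattern``, ``average_pattern``, ``region_means``,
    ``enrichment``, ``we_series``, ``group``, ``top_coexpressed`` and
    ``notes``.
    """
    from .nmf_spatial import average_pattern, nmf_pattern

    card: dict = {"gene": gene, "notes": []}
    if W_full is not None:
        if gene in W_full.index:
            card["nmf_pattern"] = nmf_pattern(W_full, gene)
        else:
            card["notes"].append("gene absent from extended component matrix")
    if expr is not None:
        if gene in expr.genes:
            ap = average_pattern(expr, gene)
            card["average_pattern"] = ap["percent_of_max"]
            card["region_means"] = ap["mean_expression"]
            meta = expr.sample_meta
            we = meta.index[meta["is_whole_embryo"]]
            if len(we):
                series = expr.values.loc[gene, we]
                series.index = meta.loc[we, "stage"]
                card["we_series"] = series
        else:
            card["notes"].append("gene absent from expression matrix")
    if enrichment_scores is not None and gene in getattr(
            enrichment_scores, "index", []):
        card["enrichment"] = enrichment_scores.loc[gene]
    if groups is not None:
        labels = groups.labels if hasattr(groups, "labels") else groups
        if gene in labels.index:
            card["group"] = int(labels[gene])
    if adjacency is not None and gene in getattr(adjacency, "index", []):
        card["top_coexpressed"] = adjacency.loc[gene].drop(index=gene) \
            .nlargest(top_coexpressed)
    return card


def plot_report(card: dict, path=None):
    """Render a report card (patterns, WE series) with matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [k for k in ("nmf_pattern", "average_pattern", "we_series")
              if k in card]
    fig, axes = plt.subplots(max(len(panels), 1), 1,
                             figsize=(6, 2.2 * max(len(panels), 1)))
    axes = np.atleast_1d(axes)
    for ax, key in zip(axes, panels):
        data = card[key]
        if key == "we_series":
            ax.plot(range(len(data)), data.to_numpy(), marker="o")
            ax.set_xticks(range(len(data)), data.index, rotation=45,
                          ha="right")
            ax.set_ylabel("log2-CPM")
        else:
            ax.bar(range(len(data)), data.to_numpy(), color="#08519c")
            ax.set_xticks(range(len(data)), data.index, rotation=45,
                          ha="right")
            ax.set_ylim(0, 105)
            ax.set_ylabel("% of max")
        ax.set_title(f"{card['gene']}: {key}", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
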