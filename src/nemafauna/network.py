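"""Genus co-occurrence networks from thresholded Spearman correlation.

Pairwise Spearman rank correlations are computed between genera across
samples (on relative abundances, the convention for compositional community
data); pairs with |r| above a threshold (default 0.6) and a two-sided p-value
below a threshold (default 0.05) become signed edges.  Metrics summarising
network complexity — average degree 2E/N, density 2E/(N(N-1)), connectivity,
positive/negative edge fractions — and per-trophic-group hub (controlling)
taxa are computed from the resulting graph.

"Connectivity" has no single convention; both a density-based percentage
(density x 100) and the average degree are reported side by side.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable
from .traits import TROPHIC_GROUPS, TraitTable

__all__ = [
    "correlation_matrix",
    "build_network",
    "network_metrics",
    "hub_taxa",
    "per_treatment_networks",
    "write_edge_list",
    "write_graphml",
]


def correlation_matrix(
    table: Union[CommunityTable, pd.DataFrame], method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genus x genus Spearman r and two-sided p matrices across samples.

    Accepts a :class:`CommunityTable` (converted to relative abundances) or a
    genera x samples frame used as-is.  Genera constant across samples have
    no defined rank correlation and are dropped with a warning.  Requires at
    least 3 samples.
    """
    if method != "spearman":
        raise ValueError(f"unsupported correlation method: {method}")
    df = table.relative_abundance() if isinstance(table, CommunityTable) else table
    n_samples = df.shape[1]
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, got {n_samples}")
    if n_samples < 6:
        warnings.warn(
            f"only {n_samples} samples: Spearman p-values have little power "
            "below 6 samples",
            stacklevel=2,
        )
    variable = df.std(axis=1) > 0
    dropped = df.index[~variable]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} zero-variance genera: {', '.join(dropped)}",
            stacklevel=2,
        )
    df = df.loc[variable]
    X = df.to_numpy(dtype=float)
    r, p = stats.spearmanr(X, axis=1)
    if df.shape[0] == 2:  # spearmanr collapses the 2-variable case to scalars
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
        pv = float(p)
        p = np.array([[0.0, pv], [pv, 0.0]])
    np.fill_diagonal(p, 0.0)
    idx = df.index
    return (
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    traits: TraitTable | None = None,
    keep_isolated: bool = False,
    signed_threshold: bool = False,
) -> nx.Graph:
    """Filter the correlation matrices into a signed co-occurrence graph.

    An edge joins genera a != b when ``|r| > r_threshold`` (or
    ``r > r_threshold`` with ``signed_threshold=True``) and
    ``p < p_threshold``.  Edge attributes: ``r``, ``p`` and ``sign``
    ('+'/'-').  Isolated nodes are dropped unless ``keep_isolated``; node
    attribute ``trophic_group`` is attached when *traits* is given.
    """
    if list(r.index) != list(r.columns) or r.shape != p.shape:
        raise ValueError("r and p must be square, conformable and equally labelled")
    G = nx.Graph()
    genera = list(r.index)
    G.add_nodes_from(genera)
    rv = r.to_numpy()
    pv = p.to_numpy()
    for i in range(len(genera)):
        for j in range(i + 1, len(genera)):
            rij = rv[i, j]
            if np.isnan(rij):
                continue
            strength = rij if signed_threshold else abs(rij)
            if strength > r_threshold and pv[i, j] < p_threshold:
                G.add_edge(
                    genera[i],
                    genera[j],
                    r=float(rij),
                    p=float(pv[i, j]),
                    sign="+" if rij > 0 else "-",
                )
    if not keep_isolated:
        G.remove_nodes_from([n for n in list(G) if G.degree(n) == 0])
    if traits is not None:
        for n in G:
            G.nodes[n]["trophic_group"] = traits.lookup(n).trophic_group
    return G


def network_metrics(G: nx.Graph) -> dict[str, float]:
    """Size, degree, density, connectivity and edge-sign summary of a network."""
    n = G.number_of_nodes()
    e = G.number_of_edges()
    pos = sum(1 for _, _, d in G.edges(data=True) if d.get("sign") == "+")
    neg = e - pos
    avg_degree = 2.0 * e / n if n else float("nan")
    density = 2.0 * e / (n * (n - 1)) if n > 1 else float("nan")
    return {
        "nodes": n,
        "edges": e,
        "average_degree": avg_degree,
        "density": density,
        "connectivity_density_pct": density * 100 if n > 1 else float("nan"),
        "connectivity_avg_degree": avg_degree,
        "positive_edges": pos,
        "negative_edges": neg,
        "positive_fraction": pos / e if e else float("nan"),
        "negative_fraction": neg / e if e else float("nan"),
    }


def hub_taxa(G: nx.Graph, top_n: int = 3) -> dict[str, list[str]]:
    """Top-degree ("controlling") genera per trophic group.

    Ranked by degree, then by total |r| of incident edges, then
    lexicographically.  Nodes lacking a ``trophic_group`` attribute are
    pooled under 'unknown'.
    """
    def sort_key(n):
        strength = sum(abs(d["r"]) for _, _, d in G.edges(n, data=True))
        return (-G.degree(n), -strength, n)

    groups: dict[str, list[str]] = {}
    for n in G:
        groups.setdefault(G.nodes[n].get("trophic_group", "unknown"), []).append(n)
    return {
        g: sorted(nodes, key=sort_key)[:top_n]
        for g, nodes in groups.items()
        if g in TROPHIC_GROUPS or g == "unknown"
    }


def per_treatment_networks(
    table: CommunityTable,
    traits: TraitTable | None = None,
    r_threshold: float = 0.6,
    p_threshold: float = 0.05,
    **kwargs,
) -> dict[str, nx.Graph]:
    """One co-occurrence network per treatment label (samples subset first)."""
    nets = {}
    for t in dict.fromkeys(table.treatments):
        sub = table.subset(t)
        r, p = correlation_matrix(sub)
        nets[t] = build_network(r, p, r_threshold, p_threshold, traits=traits, **kwargs)
    return nets


def write_edge_list(G: nx.Graph, path: str | Path, sep: str = ",") -> None:
    """Export edges as delimited text: genus_a, genus_b, r, p, sign."""
    rows = [
        {"genus_a": a, "genus_b": b, "r": d["r"], "p": d["p"], "sign": d["sign"]}
        for a, b, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["genus_a", "genus_b", "r", "p", "sign"]).to_csv(
        path, sep=sep, index=False
    )


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    """GraphML export for external viewers (Gephi, Cytoscape)."""
    nx.write_graphml(G, path)
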