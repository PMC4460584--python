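"""Per-class gene association networks.

Two kinds of undirected edges are inferred among each class's top-ranked
genes, over all samples of the dataset: co-expression edges from Pearson
correlation (kept when |r| >= 0.8 by default) and mutual-information edges
from an equal-frequency-binned plug-in estimator, normalized by the smaller
marginal entropy so the default 0.5 cutoff is scale-free. Nodes carry the
ranking annotations (posterior, expression difference, direction), whether
the gene is in the minimum classification subset, and its discriminant
power; a redundancy flag marks genes connected to any other gene of the
same list.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset, MarkernetError, write_table


def correlation_edges(
    dataset: ExpressionDataset,
    genes,
    threshold: float = 0.8,
    method: str = "pearson",
) -> list[tuple[str, str, float]]:
    """Gene pairs with |correlation| >= threshold over all samples.

    Returns (gene_a, gene_b, r) with a < b in input order. Zero-variance
    genes are excluded with a warning.
    """
    genes = list(genes)
    sub = dataset.matrix.loc[genes]
    sd = sub.to_numpy().std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(genes, sd) if s == 0]
        warnings.warn(f"excluding zero-variance genes: {bad[:10]}", stacklevel=2)
        genes = [g for g, s in zip(genes, sd) if s > 0]
        sub = dataset.matrix.loc[genes]
    if len(genes) < 2:
        return []
    if method == "spearman":
        R = sub.T.corr(method="spearman").to_numpy()
    else:
        R = np.corrcoef(sub.to_numpy())
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if abs(R[i, j]) >= threshold:
                edges.append((genes[i], genes[j], float(R[i, j])))
    return edges


def _discretize(x: np.ndarray, bins: int) -> np.ndarray | None:
    """Equal-frequency binning; None when fewer than 2 distinct bins."""
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    codes = np.searchsorted(edges, x, side="right")
    return codes if len(np.unique(codes)) >= 2 else None


def normalized_mutual_information(
    x: np.ndarray, y: np.ndarray, bins: int
) -> float:
    """Plug-in MI of equal-frequency-binned vectors, over min marginal entropy.

    MI = sum_ij p_ij log(p_ij / (p_i q_j)); the normalization maps a
    deterministic monotone relation to 1 and independence toward 0.
    """
    cx = _discretize(np.asarray(x, float), bins)
    cy = _discretize(np.asarray(y, float), bins)
    if cx is None or cy is None:
        raise MarkernetError("constant gene: mutual information undefined")
    return _nmi_from_codes(cx, cy)


def mutual_information_edges(
    dataset: ExpressionDataset,
    genes,
    threshold: float = 0.5,
    bins: int | None = None,
) -> list[tuple[str, str, float]]:
    """Gene pairs with normalized mutual information >= threshold.

    Bin count defaults to ceil(sqrt(n_samples)).
    """
    genes = list(genes)
    n = dataset.n_samples
    if bins is None:
        bins = max(2, math.ceil(math.sqrt(n)))
    if bins < 2:
        raise MarkernetError("bins must be >= 2")
    codes = {}
    for g in genes:
        c = _discretize(dataset.matrix.loc[g].to_numpy(dtype=float), bins)
        if c is None:
            warnings.warn(
                f"excluding constant gene from MI edges: {g!r}", stacklevel=2
            )
        else:
            codes[g] = c
    usable = [g for g in genes if g in codes]
    edges = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            nmi = _nmi_from_codes(codes[a], codes[b])
            if nmi >= threshold:
                edges.append((a, b, float(nmi)))
    return edges


def _nmi_from_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    joint = pd.crosstab(cx, cy).to_numpy().astype(float)
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / np.outer(px, py)[nz])).sum())
    hx = -float((px[px > 0] * np.log(px[px > 0])).sum())
    hy = -float((py[py > 0] * np.log(py[py > 0])).sum())
    denom = min(hx, hy)
    return mi / denom if denom > 0 else 0.0


def build_network(
    ranking: pd.DataFrame,
    dataset: ExpressionDataset,
    cls: str,
    selected_genes=None,
    dp: pd.DataFrame | None = None,
    top_n: int = 30,
    correlations_threshold: float = 0.8,
    interactions_threshold: float = 0.5,
) -> nx.Graph:
    """Build one class's annotated gene network.

    Nodes are the class's ``top_n`` top-ranked genes; edges of both types
    are computed among those genes only. When both an MI and a correlation
    edge exist for a pair both are kept, encoded as parallel attributes on
    one edge (``correlation`` and ``mutual_information`` weights plus a
    combined ``types`` field).
    """
    grp = ranking[ranking["class"] == cls].sort_values("rank")
    if grp.empty:
        raise MarkernetError(f"class {cls!r} absent from ranking")
    grp = grp.head(top_n)
    genes = list(grp["gene"])
    selected = set(selected_genes or [])
    dp_map = {}
    if dp is not None:
        dp_map = dict(zip(dp["gene"], dp["dp"]))

    G = nx.Graph(name=str(cls), klass=str(cls))
    for _, row in grp.iterrows():
        G.add_node(
            row["gene"],
            posterior_prob=float(row["posterior_prob"]),
            expr_diff=float(row["expr_diff"]),
            direction=str(row["direction"]),
            selected_for_classification=bool(row["gene"] in selected),
            dp=float(dp_map.get(row["gene"], 0.0)),
        )
    for a, b, r in correlation_edges(dataset, genes, correlations_threshold):
        G.add_edge(a, b, correlation=r, types="correlation")
    for a, b, m in mutual_information_edges(
        dataset, genes, interactions_threshold
    ):
        if G.has_edge(a, b):
            G[a][b]["mutual_information"] = m
            G[a][b]["types"] = "correlation+mutual_information"
        else:
            G.add_edge(a, b, mutual_information=m, types="mutual_information")
    return G


def flag_redundancy(G: nx.Graph) -> dict[str, bool]:
    """True for genes with at least one association edge in their class list."""
    return {n: G.degree(n) > 0 for n in G.nodes}


def write_sif(G: nx.Graph, path) -> None:
    """Cytoscape SIF export: one line per edge and type; isolated nodes last."""
    with open(path, "w") as fh:
        for a, b, data in G.edges(data=True):
            for t in ("correlation", "mutual_information"):
                if t in data:
                    fh.write(f"{a}\t{t}\t{b}\n")
        for n in nx.isolates(G):
            fh.write(f"{n}\n")


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def write_node_table(G: nx.Graph, path) -> None:
    redundancy = flag_redundancy(G)
    rows = []
    for n, data in G.nodes(data=True):
        rows.append(
            {
                "gene": n,
                "posterior_prob": data["posterior_prob"],
                "expr_diff": data["expr_diff"],
                "direction": data["direction"],
                "selected_for_classification": data[
                    "selected_for_classification"
                ],
                "dp": data["dp"],
                "redundancy": redundancy[n],
            }
        )
    write_table(pd.DataFrame(rows), path)
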