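"""Between-site community structure.

Bray-Curtis dissimilarities between sites, non-metric multidimensional
scaling (Kruskal stress-1, best of several seeded random starts), Ward
hierarchical clustering (Ward.D2 convention), shared-OTU fractions,
co-occurrence counts, and a force-directed layout of the bipartite
site-OTU presence network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .otucluster import DistanceMatrix

__all__ = [
    "Ordination",
    "Dendrogram",
    "NetworkLayout",
    "bray_curtis",
    "nmds",
    "ward_cluster",
    "shared_fraction",
    "cooccurrence",
    "layout_network",
]


@dataclass
class Ordination:
    """2D NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame  # sites x 2
    stress: float
    n_starts: int
    best_start: int

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be >= 0")


@dataclass
class Dendrogram:
    """Binary merge tree over sites (scipy linkage encoding)."""

    labels: list[str]
    linkage_matrix: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _cnt) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


@dataclass
class NetworkLayout:
    """Force-directed coordinates of the bipartite site-OTU network."""

    graph: nx.Graph
    positions: dict[str, np.ndarray]
    iterations: int
    seed: int


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all site pairs.

    d(a, b) = 1 - 2 * sum_i min(x_ai, x_bi) / (sum x_a + sum x_b).
    """
    if len(table.index) < 2:
        raise ValueError("need >= 2 sites")
    totals = table.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals[totals == 0].index)
        raise ValueError(f"all-zero site(s): {empty}")
    mat = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(labels=list(table.index), matrix=mat)


def nmds(dm: DistanceMatrix, dims: int = 2, n_starts: int = 20,
         max_iter: int = 300, seed: int = 0) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1; best of ``n_starts``.

    Each start is an independently seeded random initialization followed by
    SMACOF iterations with monotone (isotonic) regression of disparities on
    the input dissimilarities; the lowest-stress configuration is returned,
    centered at the origin.  Orientation is arbitrary (rotation/reflection
    indeterminacy).
    """
    if len(dm.labels) < 3:
        raise ValueError("NMDS needs >= 3 sites")
    best = None
    for start in range(n_starts):
        mds = MDS(n_components=dims, metric=False, dissimilarity="precomputed",
                  n_init=1, max_iter=max_iter, random_state=seed + start,
                  normalized_stress=True, eps=1e-9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(dm.matrix)
        if best is None or mds.stress_ < best[1]:
            best = (coords, float(mds.stress_), start)
    coords, stress, start = best
    coords = coords - coords.mean(axis=0)
    cols = [f"axis{i + 1}" for i in range(dims)]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=cols),
        stress=stress, n_starts=n_starts, best_start=start,
    )


def ward_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Ward hierarchical clustering of sites (Ward.D2 convention).

    Uses the Lance-Williams Ward update on the squared input
    dissimilarities, i.e. the variance-minimizing criterion applied to the
    dissimilarities as if they were Euclidean distances.
    """
    if len(dm.labels) < 2:
        raise ValueError("need >= 2 sites")
    condensed = squareform(dm.matrix, checks=False)
    lm = scipy_linkage(condensed, method="ward")
    return Dendrogram(labels=list(dm.labels), linkage_matrix=lm)


def shared_fraction(table: pd.DataFrame, site_a: str, site_b: str,
                    denominator: str = "union") -> float:
    """Percent of OTUs shared between two sites.

    Default denominator is the union of the two presence sets (Jaccard);
    ``denominator="min"`` divides by the smaller per-site richness
    instead.  Undefined (NaN) when both sites are empty.
    """
    if site_a == site_b:
        raise ValueError("sites must be distinct")
    a = table.loc[site_a] > 0
    b = table.loc[site_b] > 0
    inter = int((a & b).sum())
    if denominator == "union":
        denom = int((a | b).sum())
    elif denominator == "min":
        denom = min(int(a.sum()), int(b.sum()))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return float("nan")
    return 100.0 * inter / denom


def cooccurrence(table: pd.DataFrame) -> pd.DataFrame:
    """Site x site matrix of shared-OTU counts; diagonal = per-site richness."""
    if len(table.index) < 2:
        raise ValueError("need >= 2 sites")
    presence = (table.to_numpy() > 0).astype(int)
    shared = presence @ presence.T
    return pd.DataFrame(shared, index=table.index, columns=table.index)


def layout_network(table: pd.DataFrame, iterations: int = 50,
                   seed: int = 0) -> NetworkLayout:
    """Force-directed (Fruchterman-Reingold) layout of the presence network.

    Site nodes connect to the OTU nodes present at the site; sites sharing
    many OTUs are pulled together through their shared OTU neighbours.
    Node names are prefixed ``site:`` / ``otu:`` to keep the two partitions
    distinct.
    """
    if table.size == 0:
        raise ValueError("empty table")
    g = nx.Graph()
    for site in table.index:
        g.add_node(f"site:{site}", bipartite=0)
    for otu in table.columns:
        g.add_node(f"otu:{otu}", bipartite=1)
    for site in table.index:
        row = table.loc[site]
        for otu in table.columns[row.to_numpy() > 0]:
            g.add_edge(f"site:{site}", f"otu:{otu}")
    pos = nx.spring_layout(g, iterations=iterations, seed=seed)
    return NetworkLayout(graph=g, positions={k: np.asarray(v)
                                             for k, v in pos.items()},
                         iterations=iterations, seed=seed)
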