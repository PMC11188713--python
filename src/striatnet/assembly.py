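"""Cell-assembly structure of calcium rasters: embedding, clustering, transitions.

Descriptive analysis of which cells activate together and how the dominant
group hands over in time.  Each cell's binary activity vector is embedded
into 3D with UMAP and clustered by density (HDBSCAN); per time bin the
cluster with the largest active fraction (if at least half its cells are
active) is the dominant assembly, and successive changes of dominance are
accumulated into a directed transition graph.

This is a simplified, pinned reproduction of the visualization protocol
used for slice data (neighbors 15, min separation 0.1, 3 output
dimensions, minimum cluster size 5); it is descriptive output and feeds
nothing back into the inference path.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .features import CaRaster


@dataclass
class AssemblyConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 3
    min_cluster_size: int = 5
    seed: int = 0


@dataclass
class AssemblyClustering:
    labels: np.ndarray  # per active cell, contiguous from 0
    embedding: np.ndarray  # (n_active, 3)
    n_clusters: int


@dataclass
class TransitionGraph:
    graph: "nx.DiGraph"

    @property
    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def edge_weights(self) -> dict:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


class AssemblyConfigError(ValueError):
    pass


def embed_and_cluster(raster: CaRaster, cfg: AssemblyConfig = AssemblyConfig()) -> AssemblyClustering:
    """3D UMAP embedding of cell activity vectors + density clustering.

    Noise points from the density clustering are attached to the nearest
    labeled cluster so that every active cell carries a label; labels are
    re-indexed to be contiguous from 0.  Deterministic given the seed.
    """
    if raster.n_active < 10:
        raise AssemblyConfigError("need at least 10 active cells")
    if raster.n_active <= cfg.n_neighbors:
        raise AssemblyConfigError(
            f"{raster.n_active} cells <= n_neighbors = {cfg.n_neighbors}")
    x = raster.matrix.astype(float)
    if np.allclose(x, x[0]):  # identical rows: trivially one assembly
        return AssemblyClustering(
            labels=np.zeros(raster.n_active, dtype=int),
            embedding=np.zeros((raster.n_active, cfg.n_components)),
            n_clusters=1,
        )
    import umap  # deferred: heavy import

    from sklearn.cluster import HDBSCAN

    reducer = umap.UMAP(
        n_neighbors=cfg.n_neighbors,
        min_dist=cfg.min_dist,
        n_components=cfg.n_components,
        random_state=cfg.seed,
    )
    emb = reducer.fit_transform(x)
    labels = HDBSCAN(min_cluster_size=cfg.min_cluster_size).fit_predict(emb)
    if (labels >= 0).sum() == 0:
        labels = np.zeros_like(labels)
    elif (labels < 0).any():
        good = np.flatnonzero(labels >= 0)
        for i in np.flatnonzero(labels < 0):
            d = np.linalg.norm(emb[good] - emb[i], axis=1)
            labels[i] = labels[good[np.argmin(d)]]
    uniq = np.unique(labels)
    remap = {int(u): k for k, u in enumerate(uniq)}
    labels = np.array([remap[int(v)] for v in labels])
    return AssemblyClustering(labels=labels, embedding=emb, n_clusters=len(uniq))


def dominant_cluster_series(raster: CaRaster, labels: np.ndarray) -> np.ndarray:
    """Per-bin dominant cluster: the one with the largest fraction of its
    cells active, provided that fraction is at least 0.5; otherwise -1.
    Ties also yield -1."""
    labels = np.asarray(labels)
    n_clusters = labels.max() + 1
    fracs = np.zeros((n_clusters, raster.n_bins))
    for c in range(n_clusters):
        fracs[c] = raster.matrix[labels == c].mean(axis=0)
    out = np.full(raster.n_bins, -1, dtype=int)
    for b in range(raster.n_bins):
        col = fracs[:, b]
        best = col.max()
        if best >= 0.5 and (col == best).sum() == 1:
            out[b] = int(np.argmax(col))
    return out


def transition_graph(series: np.ndarray) -> TransitionGraph:
    """Count transitions between successive distinct dominant clusters.

    Bins without a dominant cluster are skipped; repeats of the same
    cluster are not edges.  The total edge weight therefore equals the
    number of dominance changes in the gap-skipped series.
    """
    g = nx.DiGraph()
    prev = None
    for v in series:
        if v < 0:
            continue
        if prev is not None and v != prev:
            if g.has_edge(prev, v):
                g[prev][v]["weight"] += 1
            else:
                g.add_edge(int(prev), int(v), weight=1)
        prev = v
    return TransitionGraph(graph=g)


def write_transition_graph(path, tg: TransitionGraph) -> None:
    with open(path, "w") as fh:
        fh.write("src\tdst\tweight\n")
        for (u, v), w in sorted(tg.edge_weights().items()):
            fh.write(f"{u}\t{v}\t{w}\n")
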