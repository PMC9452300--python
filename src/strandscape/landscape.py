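"""Conformational landscape: embedding, clustering, representatives.

The one-hot element matrix of all sampled structures is reduced to a
low-dimensional embedding (PCA by default, metric MDS behind a flag),
clustered with k-means, and summarised per cluster by

* its proportion of the population (computed over molecules: when
  several structures are sampled per bit vector each molecule
  contributes its per-cluster sample fractions, so proportions remain
  population fractions of molecules);
* its consensus element string (positionwise mode); and
* a representative member: the structure closest to the consensus by
  Hamming distance, ties broken by distance to the cluster centroid,
  then by read id.

Cluster ids are relabelled in decreasing proportion order, so cluster 1
is always the most abundant conformation regardless of k-means
initialisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .elements import ElementMatrix, consensus_elements, to_elements, to_matrix
from .structure import SecondaryStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ConformationLandscape",
    "embed",
    "cluster",
    "suggest_k",
    "representative",
    "build_landscape",
]


def embed(matrix: ElementMatrix, method: str = "pca", d: int = 2, seed: int = 0) -> np.ndarray:
    """Deterministic low-dimensional embedding of the element matrix.

    PCA fixes the sign convention (the largest-magnitude loading of each
    component is positive); MDS is seeded.
    """
    X = matrix.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 structures to embed")
    d_eff = min(d, n, X.shape[1])
    if d_eff < d:
        logger.warning("reducing embedding dimension to %d", d_eff)
    if method == "pca":
        pca = PCA(n_components=d_eff, svd_solver="full")
        Y = pca.fit_transform(X)
        for c in range(d_eff):
            j = np.argmax(np.abs(pca.components_[c]))
            if pca.components_[c][j] < 0:
                Y[:, c] = -Y[:, c]
        return Y
    if method == "mds":
        mds = MDS(
            n_components=d_eff,
            random_state=seed,
            normalized_stress="auto",
            n_init=2,
        )
        return mds.fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


def cluster(
    embedding: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """k-means clustering; returns (labels, proportions).

    Labels are relabelled so cluster 0 is the most populous; the
    proportions here are per structure row (see
    :func:`build_landscape` for per-molecule proportions).
    """
    n = embedding.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of structures n={n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
    raw = km.fit_predict(embedding)
    counts = np.bincount(raw, minlength=k)
    order = np.argsort(-counts, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    proportions = np.bincount(labels, minlength=k) / n
    return labels, proportions


def suggest_k(
    embedding: np.ndarray, k_range: Sequence[int], seed: int = 0
) -> pd.DataFrame:
    """Silhouette and inertia per candidate k; the caller decides.

    No automatic selection is made: the table makes a visual choice of
    k auditable.
    """
    rows = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
        labels = km.fit_predict(embedding)
        sil = (
            silhouette_score(embedding, labels)
            if 2 <= k <= embedding.shape[0] - 1
            else np.nan
        )
        rows.append({"k": k, "silhouette": sil, "inertia": km.inertia_})
    return pd.DataFrame(rows, columns=["k", "silhouette", "inertia"])


def representative(
    members: Sequence[tuple[str, SecondaryStructure, str]],
    coords: np.ndarray,
) -> tuple[str, SecondaryStructure, str]:
    """Pick a cluster's representative structure.

    ``members`` are (read_id, structure, element_string) triples and
    ``coords`` their embedding coordinates.  Returns
    (read_id, structure, consensus_element_string).  The member closest
    to the positionwise consensus (maximum-expected-accuracy object) by
    Hamming distance wins; centroid distance and read id break ties.
    """
    if not members:
        raise ValueError("empty cluster")
    consensus = consensus_elements([m[2] for m in members])
    centroid = coords.mean(axis=0)
    best = None
    for (read_id, structure, elems), xy in zip(members, coords):
        ham = sum(a != b for a, b in zip(elems, consensus))
        dist = float(np.linalg.norm(xy - centroid))
        key = (ham, dist, read_id)
        if best is None or key < best[0]:
            best = (key, read_id, structure)
    return best[1], best[2], consensus


@dataclass
class ConformationLandscape:
    """Embedded, clustered population of per-molecule structures."""

    embedding: np.ndarray
    method: str
    read_ids: tuple
    labels: np.ndarray
    k: int
    proportions: np.ndarray  # per molecule, most abundant first
    representatives: list  # (read_id, SecondaryStructure) per cluster
    consensus_elements: list  # element string per cluster
    molecule_labels: pd.Series  # modal cluster per molecule

    def to_frame(self) -> pd.DataFrame:
        d = self.embedding.shape[1]
        df = pd.DataFrame(
            self.embedding, columns=[f"PC{c + 1}" for c in range(d)]
        )
        df.insert(0, "read_id", list(self.read_ids))
        df["cluster"] = self.labels + 1  # 1-based cluster ids in reports
        return df


def build_landscape(
    tagged_structures: Sequence[tuple[str, SecondaryStructure]],
    k: int,
    method: str = "pca",
    d: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    encoding: str = "onehot",
    cluster_full_matrix: bool = False,
) -> ConformationLandscape:
    """Run the element -> embed -> cluster -> summarise pipeline.

    ``tagged_structures`` is the sampler output: (read_id, structure)
    with possibly several structures per molecule.  Clustering operates
    in the embedded space by default; ``cluster_full_matrix`` clusters
    the full one-hot matrix instead.
    """
    if not tagged_structures:
        raise ValueError("no structures supplied")
    read_ids = [rid for rid, _ in tagged_structures]
    structures = [s for _, s in tagged_structures]
    elems = [to_elements(s) for s in structures]
    matrix = to_matrix(elems, read_ids=read_ids, encoding=encoding)
    emb = embed(matrix, method=method, d=d, seed=seed)
    space = matrix.values if cluster_full_matrix else emb
    labels, _ = cluster(space, k=k, seed=seed, n_restarts=n_restarts)

    # per-molecule proportions: each molecule spreads unit mass over the
    # clusters of its samples
    df = pd.DataFrame({"read_id": read_ids, "label": labels})
    frac = (
        df.groupby("read_id")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(k), fill_value=0.0)
    )
    proportions = frac.mean(axis=0).to_numpy()
    # relabel again by per-molecule abundance (sample- and molecule-level
    # orderings can differ when samples_per_bitvector > 1)
    order = np.argsort(-proportions, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    proportions = proportions[order]
    molecule_labels = (
        pd.Series(labels, index=read_ids)
        .groupby(level=0)
        .agg(lambda s: s.mode().iloc[0])
    )

    reps, consensus = [], []
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            logger.warning("cluster %d is empty; skipped", c + 1)
            reps.append(None)
            consensus.append("")
            continue
        members = [(read_ids[i], structures[i], elems[i]) for i in idx]
        rid, rep, cons = representative(members, emb[idx])
        reps.append((rid, rep))
        consensus.append(cons)
    return ConformationLandscape(
        embedding=emb,
        method=method,
        read_ids=tuple(read_ids),
        labels=labels,
        k=k,
        proportions=proportions,
        representatives=reps,
        consensus_elements=consensus,
        molecule_labels=molecule_labels,
    )
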