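"""Between-class centrality, subgroup stratification and the PSN^2 summary.

A patient's centrality in a signature network combines how similar it is
to its own class and how dissimilar to the other:

    raw(i) = Median(s_ij, j in own class) * (1 - Median(s_ij, j in other)) / 2

(the area of the triangle with those two legs), min-max scaled within the
network so the most central patient scores 1.  The second-order
similarity Sim2 is the weighted Jaccard between two patients' adjacency
columns; clustering the Sim2 profiles per class and keeping the patient
nearest each centroid yields a small representative network for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .psn import SimilarityNetwork

logger = logging.getLogger(__name__)


@dataclass
class SummaryNetwork:
    """Representative-node reduction of one PSN for visualization."""

    pathway_id: str
    representatives: list[str]
    membership: dict[str, str]  # patient -> representative
    sim2: pd.DataFrame
    layout: dict[str, tuple[float, float]]


def patient_centrality(network: SimilarityNetwork) -> pd.DataFrame:
    """Raw and min-max-scaled between-class centrality per patient.

    Requires dense (pre-sparsification) weights and at least two patients
    per class; the self-similarity (diagonal) is excluded from the medians.
    If every raw value is equal all patients scale to 1.
    """
    idx = network.class_indices()
    for c, members in idx.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 patients")
    classes = list(idx)
    w = network.weights
    raw = np.zeros(network.n_patients)
    for i, pid in enumerate(network.patient_ids):
        own = idx[network.labels[pid]]
        other = idx[[c for c in classes if c != network.labels[pid]][0]]
        own_excl = own[own != i]
        raw[i] = (np.median(w[i, own_excl])
                  * (1.0 - np.median(w[i, other])) / 2.0)
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        scaled = (raw - lo) / (hi - lo)
    else:
        scaled = np.ones_like(raw)
    return pd.DataFrame({"raw": raw, "scaled": scaled},
                        index=network.patient_ids)


def centrality_table(networks: list[SimilarityNetwork]) -> pd.DataFrame:
    """Patients x pathways matrix of scaled centralities (NaN where a
    patient is absent from a network)."""
    cols = {}
    for net in networks:
        if net.centrality is None:
            net.centrality = patient_centrality(net)
        cols[net.pathway_id] = net.centrality["scaled"]
    return pd.DataFrame(cols)


def stratify_cohesive_class(networks: list[SimilarityNetwork], k: int,
                            seed: int = 0
                            ) -> tuple[dict[str, int], dict[str, int]]:
    """Split cohesive-class patients into k subgroups.

    Patients of each network's cohesive class are clustered (k-means on
    their scaled-centrality vectors across all signature networks); every
    network is then assigned to the subgroup of its most central cohesive
    patient.  Returns (patient -> subgroup, pathway_id -> subgroup).
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 signature networks to stratify")
    table = centrality_table(networks)
    cohesive_patients = sorted({
        p for net in networks
        for p in net.patient_ids
        if net.separability is not None
        and net.labels[p] == net.separability.cohesive_class})
    if k > len(cohesive_patients):
        raise ValueError(f"k={k} exceeds cohesive class size "
                         f"{len(cohesive_patients)}")
    x = table.loc[cohesive_patients].fillna(0.0).to_numpy()
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
    patient_group = {p: int(g) for p, g in zip(cohesive_patients, km.labels_)}
    network_group = {}
    for net in networks:
        cent = net.centrality if net.centrality is not None else patient_centrality(net)
        cohesive = net.separability.cohesive_class
        candidates = cent.loc[[p for p in net.patient_ids
                               if net.labels[p] == cohesive]]
        top = candidates["scaled"].idxmax()
        network_group[net.pathway_id] = patient_group[top]
    return patient_group, network_group


def second_order_similarity(network: SimilarityNetwork, i: str, j: str) -> float:
    """Weighted Jaccard of two patients' adjacency columns, in [0, 1]."""
    if i == j:
        return 1.0
    w = network.weights
    ci = w[:, network.index_of(i)]
    cj = w[:, network.index_of(j)]
    num = np.minimum(ci, cj).sum()
    den = np.maximum(ci, cj).sum()
    return 1.0 if den == 0 else float(num / den)


def second_order_matrix(network: SimilarityNetwork) -> pd.DataFrame:
    """All-pairs Sim2 (weighted Jaccard on adjacency columns)."""
    w = network.weights
    mins = np.minimum(w[:, :, None], w[:, None, :]).sum(axis=0)
    maxs = np.maximum(w[:, :, None], w[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim2 = np.where(maxs == 0, 1.0, mins / np.where(maxs == 0, 1.0, maxs))
    np.fill_diagonal(sim2, 1.0)
    return pd.DataFrame(sim2, index=network.patient_ids,
                        columns=network.patient_ids)


def summarize_network(network: SimilarityNetwork,
                      clusters_per_class: int = 20,
                      seed: int = 0) -> SummaryNetwork:
    """Pick representative patients per class from the PSN^2 and lay them out.

    The Sim2 adjacency is split by class; each class' columns are
    clustered with k-means (k = min(clusters_per_class, class size)) and
    the patient nearest each centroid represents its cluster.  Positions
    come from the Fruchterman-Reingold force-directed layout on the
    original weights restricted to the representatives.
    """
    if clusters_per_class < 1:
        raise ValueError("clusters_per_class must be >= 1")
    sim2 = second_order_matrix(network)
    idx = network.class_indices()
    representatives: list[str] = []
    membership: dict[str, str] = {}
    for c, members in idx.items():
        if len(members) == 0:
            raise ValueError(f"class {c!r} is empty")
        pids = [network.patient_ids[m] for m in members]
        x = sim2.loc[pids].to_numpy()  # Sim2 profile of each class member
        k = min(clusters_per_class, len(pids))
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
        for cluster in range(k):
            in_cluster = [p for p, g in zip(pids, km.labels_) if g == cluster]
            sub = sim2.loc[in_cluster].to_numpy()
            dists = np.linalg.norm(sub - km.cluster_centers_[cluster], axis=1)
            rep = in_cluster[int(np.argmin(dists))]
            representatives.append(rep)
            for p in in_cluster:
                membership[p] = rep
    rep_idx = [network.index_of(p) for p in representatives]
    sub_w = network.weights[np.ix_(rep_idx, rep_idx)]
    g = nx.Graph()
    for a, pa in enumerate(representatives):
        g.add_node(pa)
        for b in range(a + 1, len(representatives)):
            if sub_w[a, b] > 0:
                g.add_edge(pa, representatives[b], weight=float(sub_w[a, b]))
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    layout = {p: (float(xy[0]), float(xy[1])) for p, xy in pos.items()}
    return SummaryNetwork(pathway_id=network.pathway_id,
                          representatives=representatives,
                          membership=membership, sim2=sim2, layout=layout)


def plot_summary(summary: SummaryNetwork, network: SimilarityNetwork,
                 path: str, min_edge_weight: float = 0.0) -> None:
    """Static export of the representative network (node size ~ centrality,
    edge width ~ similarity)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cent = network.centrality
    fig, ax = plt.subplots(figsize=(7, 7))
    reps = summary.representatives
    colors = {c: col for c, col in zip(sorted(set(network.labels.values())),
                                       ("tab:green", "tab:blue"))}
    for a, pa in enumerate(reps):
        for b in range(a + 1, len(reps)):
            pb = reps[b]
            w = network.weights[network.index_of(pa), network.index_of(pb)]
            if w > min_edge_weight:
                xa, ya = summary.layout[pa]
                xb, yb = summary.layout[pb]
                ax.plot([xa, xb], [ya, yb], color="grey",
                        linewidth=0.5 + 6 * w, alpha=0.5, zorder=1)
    for p in reps:
        x, y = summary.layout[p]
        size = 100.0
        if cent is not None and p in cent.index:
            size = 60 + 400 * float(cent.loc[p, "scaled"])
        ax.scatter([x], [y], s=size, zorder=2,
                   color=colors.get(network.labels[p], "grey"),
                   edgecolors="black", linewidths=0.5)
        ax.annotate(p, (x, y), fontsize=6, ha="center", va="bottom")
    ax.set_title(f"{network.pathway_id} ({network.direction})")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
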