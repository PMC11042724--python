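"""Pathway-specific patient similarity networks.

The similarity between two patients on a pathway multiplies a *stability
component* (Comp1: how close the two patients' values are, molecule by
molecule) with an *intensity component* (Comp2: how high — or, for an
inhibited pathway, how low — the values are on average), halved:

    Comp1 = sum_i min(m_ij, m_ik) / sum_i max(m_ij, m_ik)
    Comp2 = mean_i (m_ij + m_ik) / 2          (activated pathways)
          = 1 - mean_i (m_ij + m_ik) / 2      (inhibited pathways)
    Sim   = Comp1 * Comp2 / 2

which is the area of the right triangle with legs Comp1 and Comp2.  With
unit-scaled inputs the similarity is bounded by [0, 0.5]; only patient
pairs whose molecules deregulate the pathway in the same direction with
the same intensity score highly.

Each network is then scored with a 0-10 *separability power*: level k
passes when a low percentile of one class' intra-similarities strictly
exceeds a high percentile of both the opposite class' intra-similarities
and the inter-class similarities, with the percentile pair tightening
from (0.35, 0.65) at level 1 to (0.10, 0.90) at level 10.  Networks with
power >= 1 are "signatures" of their cohesive class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import power_percentile_schedule
from .preprocess import OmicsMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("activated", "inhibited")


@dataclass
class SeparabilityResult:
    """Outcome of the 10-level percentile scoring of one network."""

    power: int
    cohesive_class: str | None
    level_detail: list[dict]
    mean_intra: dict[str, float]
    mean_inter: float


@dataclass
class SimilarityNetwork:
    """Weighted patient graph for one enriched pathway.

    ``weights`` is symmetric with zero diagonal; with unit-scaled inputs
    every weight lies in [0, 0.5].
    """

    pathway_id: str
    patient_ids: list[str]
    weights: np.ndarray
    direction: str
    labels: dict[str, str]
    molecule_ids: list[str] = field(default_factory=list)
    profile: pd.DataFrame | None = None  # unit-scaled molecule x patient block
    sparsified: bool = False
    separability: SeparabilityResult | None = None
    centrality: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match patients")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weight matrix must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def index_of(self, patient_id: str) -> int:
        return self.patient_ids.index(patient_id)

    def class_indices(self) -> dict[str, np.ndarray]:
        classes = sorted(set(self.labels.values()))
        return {c: np.array([i for i, p in enumerate(self.patient_ids)
                             if self.labels[p] == c], dtype=int)
                for c in classes}

    def copy(self) -> "SimilarityNetwork":
        return SimilarityNetwork(
            pathway_id=self.pathway_id,
            patient_ids=list(self.patient_ids),
            weights=self.weights.copy(),
            direction=self.direction,
            labels=dict(self.labels),
            molecule_ids=list(self.molecule_ids),
            profile=None if self.profile is None else self.profile.copy(),
            sparsified=self.sparsified,
            separability=self.separability,
            centrality=None if self.centrality is None else self.centrality.copy())


def pairwise_similarity(values_j: np.ndarray, values_k: np.ndarray,
                        direction: str = "activated") -> float:
    """Similarity of two unit-scaled pathway profiles, in [0, 0.5]."""
    vj = np.asarray(values_j, dtype=float)
    vk = np.asarray(values_k, dtype=float)
    if vj.shape != vk.shape:
        raise ValueError("profiles must cover the same molecules")
    if vj.size == 0:
        raise ValueError("empty profiles")
    for v in (vj, vk):
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("profile values must lie in [0, 1]")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    num = np.minimum(vj, vk).sum()
    den = np.maximum(vj, vk).sum()
    comp1 = 1.0 if den == 0 else num / den  # 0/0: values identical (all zero)
    comp2 = float(np.mean((vj + vk) / 2.0))
    if direction == "inhibited":
        comp2 = 1.0 - comp2
    return comp1 * comp2 / 2.0


def _similarity_matrix(values: np.ndarray, direction: str) -> np.ndarray:
    """All-pairs similarity for a molecule x patient block (vectorized)."""
    n = values.shape[1]
    mins = np.minimum(values[:, :, None], values[:, None, :]).sum(axis=0)
    maxs = np.maximum(values[:, :, None], values[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp1 = np.where(maxs == 0, 1.0, mins / np.where(maxs == 0, 1.0, maxs))
    means = values.mean(axis=0)
    comp2 = (means[:, None] + means[None, :]) / 2.0
    if direction == "inhibited":
        comp2 = 1.0 - comp2
    return comp1 * comp2 / 2.0


def build_psn(matrix: OmicsMatrix, pathway, patients: list[str],
              direction: str | None = None,
              labels: dict[str, str] | None = None) -> SimilarityNetwork | None:
    """Complete weighted patient graph for one enriched pathway.

    ``pathway`` may be an EnrichedPathway (direction taken from its
    category) or any object with ``pathway.id``-like fields plus an
    explicit ``direction`` argument.  Returns None (with a logged reason)
    when fewer than two of the pathway's significant molecules are present
    in the matrix.
    """
    members = getattr(pathway, "significant_members", None)
    if members is None:
        members = pathway.members if hasattr(pathway, "members") else set(pathway)
    pathway_id = getattr(pathway, "id", None)
    if pathway_id is None and hasattr(pathway, "pathway"):
        pathway_id = pathway.pathway.id
    if direction is None:
        direction = getattr(pathway, "direction", None)
    if direction is None:
        raise ValueError("direction not given and not derivable from pathway")
    rows = [m for m in members if m in matrix.values.index]
    if len(rows) < 2:
        logger.info("build_psn: skipping %s (only %d pathway molecules in "
                    "matrix)", pathway_id, len(rows))
        return None
    block = matrix.values.loc[rows, patients].to_numpy()
    if block.min() < -1e-12 or block.max() > 1 + 1e-12:
        raise ValueError("build_psn expects a unit-scaled matrix")
    w = _similarity_matrix(block, direction)
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0  # exact symmetry against float noise
    if labels is None:
        labels = {p: "?" for p in patients}
    return SimilarityNetwork(pathway_id=str(pathway_id),
                             patient_ids=list(patients), weights=w,
                             direction=direction,
                             labels={p: labels[p] for p in patients},
                             molecule_ids=rows,
                             profile=matrix.values.loc[rows, patients].copy())


def _intra_inter_similarities(network: SimilarityNetwork
                              ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    idx = network.class_indices()
    classes = list(idx)
    if len(classes) != 2:
        raise ValueError(f"expected two classes, found {classes}")
    for c, members in idx.items():
        if len(members) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 patients")
    w = network.weights
    intra = {}
    for c, members in idx.items():
        sub = w[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        intra[c] = sub[iu]
    inter = w[np.ix_(idx[classes[0]], idx[classes[1]])].ravel()
    return intra, inter


def score_separability(cohesive_intra: np.ndarray, other_intra: np.ndarray,
                       inter: np.ndarray,
                       schedule: list[tuple[float, float]] | None = None
                       ) -> tuple[int, list[dict]]:
    """Level-by-level percentile scoring of one cohesive-class orientation.

    Level k passes iff the low_k quantile of the cohesive class'
    intra-similarities strictly exceeds both the high_k quantile of the
    opposite class' intra-similarities and the high_k quantile of the
    inter-class similarities (linear-interpolation quantiles).  Returns
    the highest consecutive level passed plus the per-level detail.
    """
    if schedule is None:
        schedule = power_percentile_schedule()
    cohesive_intra = np.asarray(cohesive_intra, dtype=float)
    other_intra = np.asarray(other_intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    power = 0
    detail = []
    for level, (low_q, high_q) in enumerate(schedule, start=1):
        low = float(np.quantile(cohesive_intra, low_q))
        high_other = float(np.quantile(other_intra, high_q))
        high_inter = float(np.quantile(inter, high_q))
        passed = low > high_other and low > high_inter
        detail.append({"level": level, "low_q": low_q, "high_q": high_q,
                       "cohesive_low": low, "opposite_high": high_other,
                       "inter_high": high_inter, "passed": passed})
        if not passed:
            break
        power = level
    return power, detail


def separability_power(network: SimilarityNetwork,
                       schedule: list[tuple[float, float]] | None = None
                       ) -> SeparabilityResult:
    """Score 0-10 for how strongly one class' intra-similarities dominate.

    Both orientations are evaluated with :func:`score_separability`; at
    most one class can be cohesive (its level-1 low quantile would have to
    strictly exceed the other's high quantile and vice versa, which is
    impossible), and the power is the highest consecutive level passed.
    """
    if schedule is None:
        schedule = power_percentile_schedule()
    intra, inter = _intra_inter_similarities(network)
    classes = list(intra)
    best = SeparabilityResult(power=0, cohesive_class=None, level_detail=[],
                              mean_intra={c: float(v.mean()) for c, v in intra.items()},
                              mean_inter=float(inter.mean()))
    for cohesive in classes:
        other = classes[1] if cohesive == classes[0] else classes[0]
        power, detail = score_separability(intra[cohesive], intra[other],
                                           inter, schedule)
        if power > best.power:
            best = SeparabilityResult(power=power, cohesive_class=cohesive,
                                      level_detail=detail,
                                      mean_intra=best.mean_intra,
                                      mean_inter=best.mean_inter)
    return best


def filter_networks(networks: list[SimilarityNetwork],
                    schedule: list[tuple[float, float]] | None = None
                    ) -> list[SimilarityNetwork]:
    """Keep networks whose separability power is at least 1."""
    retained = []
    for net in networks:
        if net.separability is None:
            net.separability = separability_power(net, schedule)
        if net.separability.power >= 1:
            retained.append(net)
    if not retained:
        logger.info("filter_networks: no signature networks")
    return retained


def _top_edges_per_node(w: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Boolean mask marking each node's top-k edges (union over endpoints)."""
    n = w.shape[0]
    k = math.ceil(keep_fraction * (n - 1))
    mask = np.zeros_like(w, dtype=bool)
    for i in range(n):
        order = np.argsort(-w[i])
        order = order[order != i][:k]
        mask[i, order] = True
    return mask | mask.T


def sparsify_psn(network: SimilarityNetwork,
                 keep_fraction: float = 0.2) -> SimilarityNetwork:
    """Drop each patient's weakest edges, keeping the union of every
    patient's top ceil(keep_fraction * (n - 1)) edges."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must lie in (0, 1], got {keep_fraction}")
    out = network.copy()
    mask = _top_edges_per_node(network.weights, keep_fraction)
    out.weights = np.where(mask, network.weights, 0.0)
    np.fill_diagonal(out.weights, 0.0)
    out.sparsified = True
    return out


def attach_unknowns(network: SimilarityNetwork,
                    unknown_matrix: OmicsMatrix,
                    unknown_ids: list[str] | None = None,
                    keep_fraction: float | None = None) -> SimilarityNetwork:
    """Add unknown patients to a (possibly sparsified) training network.

    Unknown nodes connect only to training nodes, with weights from the
    pathway similarity; when the training network is sparsified each
    unknown keeps only its top ceil(keep_fraction * n_train) edges.
    Training-training edges are untouched.
    """
    if unknown_ids is None:
        unknown_ids = unknown_matrix.sample_ids
    overlap = set(unknown_ids) & set(network.patient_ids)
    if overlap:
        raise ValueError(f"unknown patients already in network: {sorted(overlap)}")
    if network.profile is None:
        raise ValueError("network carries no training profiles; build it with "
                         "build_psn before attaching unknowns")
    rows = list(network.molecule_ids)
    missing = [m for m in rows if m not in unknown_matrix.values.index]
    if missing:
        raise KeyError(f"unknown matrix lacks pathway molecules: {missing[:5]}")
    n_train = network.n_patients
    n_unk = len(unknown_ids)
    unk_block = unknown_matrix.values.loc[rows, unknown_ids].to_numpy()
    if unk_block.min() < -1e-12 or unk_block.max() > 1 + 1e-12:
        raise ValueError("attach_unknowns expects a unit-scaled matrix")
    train_block = network.profile.loc[rows, network.patient_ids].to_numpy()
    # cross similarities: unknown u vs training t
    mins = np.minimum(train_block[:, :, None], unk_block[:, None, :]).sum(axis=0)
    maxs = np.maximum(train_block[:, :, None], unk_block[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp1 = np.where(maxs == 0, 1.0, mins / np.where(maxs == 0, 1.0, maxs))
    comp2 = (train_block.mean(axis=0)[:, None] + unk_block.mean(axis=0)[None, :]) / 2.0
    if network.direction == "inhibited":
        comp2 = 1.0 - comp2
    cross = comp1 * comp2 / 2.0  # n_train x n_unk
    if network.sparsified and keep_fraction is not None:
        k = math.ceil(keep_fraction * n_train)
        sparse_cross = np.zeros_like(cross)
        for u in range(n_unk):
            top = np.argsort(-cross[:, u])[:k]
            sparse_cross[top, u] = cross[top, u]
        cross = sparse_cross
    w = np.zeros((n_train + n_unk, n_train + n_unk))
    w[:n_train, :n_train] = network.weights
    w[:n_train, n_train:] = cross
    w[n_train:, :n_train] = cross.T
    profile = pd.concat(
        [network.profile.loc[rows],
         unknown_matrix.values.loc[rows, unknown_ids]], axis=1)
    labels = dict(network.labels)
    for u in unknown_ids:
        labels[u] = "?"
    return SimilarityNetwork(pathway_id=network.pathway_id,
                             patient_ids=network.patient_ids + list(unknown_ids),
                             weights=w, direction=network.direction,
                             labels=labels, molecule_ids=rows,
                             profile=profile, sparsified=network.sparsified,
                             separability=network.separability)
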