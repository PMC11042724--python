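"""Synthetic two-class multi-omics cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline is built to
detect: RNA-seq-like counts drawn negative-binomially around log-normal
baseline means, with *planted* pathways whose member molecules differ
between the classes both in mean (a target expression log fold change)
and in coefficient of variation (a target CV ratio — the stability
signal).  The four pathway direction categories correspond to which class
deviates and in which direction:

    activated_case      cases higher and more stable
    activated_control   controls higher and more stable
    inhibited_case      cases lower and more stable
    inhibited_control   controls lower and more stable

Optionally the cohort carries a small ncRNA ome with a planted ncRNA
whose target genes are anti-correlated with it (targets are sampled with
per-sample means decreasing in the ncRNA's expression), and a binary
somatic-mutation matrix in which driver genes are mutated far more often
in one class, plus a random interaction network for propagation.

Identical design + seed reproduce the outputs bitwise; the ledger lists
every planted pathway with its intended category so recovery can be
scored downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import PathwayRecord
from .preprocess import OmicsMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("activated_case", "activated_control",
              "inhibited_case", "inhibited_control")


@dataclass(frozen=True)
class PlantedPathway:
    """One pathway to plant: its size, direction category and effect sizes."""

    id: str
    member_count: int
    category: str
    elfc: float = 2.0
    cv_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.elfc <= 0:
            raise ValueError("elfc magnitude must be > 0")
        if self.cv_ratio <= 1:
            raise ValueError("cv_ratio must be > 1")


@dataclass
class SimulationDesign:
    """Study conditions for one synthetic cohort."""

    n_case: int = 40
    n_control: int = 40
    n_genes: int = 300
    planted: tuple[PlantedPathway, ...] = (
        PlantedPathway("PLANTED_ACT_CASE", 15, "activated_case"),
        PlantedPathway("PLANTED_INH_CASE", 15, "inhibited_case"),
        PlantedPathway("PLANTED_ACT_CTRL", 15, "activated_control"),
    )
    n_background_pathways: int = 10
    background_pathway_size: int = 15
    baseline_log_mean: float = np.log(100.0)
    baseline_log_sd: float = 1.0
    base_cv: float = 0.4
    # ncRNA ome with planted anti-correlated target sets
    n_ncrna: int = 30
    n_planted_ncrna: int = 1
    n_targets_per_ncrna: int = 10
    target_anticorr_slope: float = 0.8
    # somatic mutations
    n_mutation_genes: int = 40
    n_drivers: int = 8
    driver_p_case: float = 0.6
    driver_p_control: float = 0.1
    background_mutation_p: float = 0.05
    require_disjoint: bool = True
    sample_prefix: str = ""
    seed: int = 0
    # gene-level structure (baseline means, gene-set membership, interaction
    # topology) is a property of the genes, not of the cohort: it comes from
    # its own seed so cohorts drawn with different `seed` share the biology
    baseline_seed: int = 20240101

    def __post_init__(self) -> None:
        total_planted = sum(p.member_count for p in self.planted)
        if total_planted > self.n_genes:
            raise ValueError("planted pathways need more molecules than n_genes")
        ids = [p.id for p in self.planted]
        if len(ids) != len(set(ids)):
            raise ValueError("planted pathway ids must be unique")


@dataclass
class SimulatedDataset:
    """Everything one run of the generator produces."""

    omics: dict[str, OmicsMatrix]
    labels: pd.Series
    pathways: list[PathwayRecord]
    relations: pd.DataFrame  # ncrna_id, target_id, relation
    mutation: OmicsMatrix | None
    interaction_network: nx.Graph | None
    ledger: dict


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               cv: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with the given per-entry mean and CV.

    Parametrized through the gamma-Poisson mixture: the overdispersion
    alpha satisfies CV^2 = 1/mean + alpha; entries where the requested CV
    is at or below the Poisson floor fall back to plain Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    cv = np.broadcast_to(np.asarray(cv, dtype=float), mean.shape)
    alpha = cv ** 2 - 1.0 / np.maximum(mean, 1e-9)
    counts = np.empty(mean.shape)
    over = alpha > 1e-9
    if over.any():
        shape = 1.0 / alpha[over]
        lam = rng.gamma(shape, alpha[over] * mean[over])
        counts[over] = rng.poisson(lam)
    if (~over).any():
        counts[~over] = rng.poisson(mean[~over])
    return counts


def _class_params(category: str, mu: np.ndarray, elfc: float, cv_ratio: float,
                  base_cv: float) -> tuple[np.ndarray, float, np.ndarray, float]:
    """(case mean, case cv, control mean, control cv) for planted molecules."""
    fold = 2.0 ** elfc
    if category == "activated_case":
        return mu * fold, base_cv / cv_ratio, mu, base_cv
    if category == "activated_control":
        return mu, base_cv, mu * fold, base_cv / cv_ratio
    if category == "inhibited_case":
        return mu / fold, base_cv / cv_ratio, mu, base_cv
    if category == "inhibited_control":
        return mu, base_cv, mu / fold, base_cv / cv_ratio
    raise ValueError(category)


def generate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Generate the cohort: omics, labels, gene sets, relations, mutations."""
    rng = np.random.default_rng(design.seed)
    rng_base = np.random.default_rng(design.baseline_seed)
    n_case, n_ctrl = design.n_case, design.n_control
    pre = design.sample_prefix
    samples = ([f"{pre}case_{i:03d}" for i in range(n_case)]
               + [f"{pre}ctrl_{i:03d}" for i in range(n_ctrl)])
    labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl,
                       index=samples, name="label")

    gene_ids = [f"G{i:04d}" for i in range(design.n_genes)]
    mu = rng_base.lognormal(design.baseline_log_mean, design.baseline_log_sd,
                            size=design.n_genes)
    case_mean = np.tile(mu[:, None], (1, n_case))
    ctrl_mean = np.tile(mu[:, None], (1, n_ctrl))
    case_cv = np.full((design.n_genes, 1), design.base_cv)
    ctrl_cv = np.full((design.n_genes, 1), design.base_cv)

    # assign planted members to disjoint gene blocks
    pathways: list[PathwayRecord] = []
    ledger_planted = []
    cursor = 0
    planted_members: dict[str, list[str]] = {}
    for planted in design.planted:
        members = gene_ids[cursor:cursor + planted.member_count]
        cursor += planted.member_count
        planted_members[planted.id] = members
        rows = [gene_ids.index(m) for m in members]
        cm, ccv, km, kcv = _class_params(planted.category, mu[rows],
                                         planted.elfc, planted.cv_ratio,
                                         design.base_cv)
        case_mean[rows] = cm[:, None]
        ctrl_mean[rows] = km[:, None]
        case_cv[rows] = ccv
        ctrl_cv[rows] = kcv
        pathways.append(PathwayRecord(id=planted.id, name=planted.id,
                                      source="planted",
                                      members=frozenset(members)))
        ledger_planted.append({"id": planted.id,
                               "category": planted.category,
                               "elfc": planted.elfc,
                               "cv_ratio": planted.cv_ratio,
                               "members": sorted(members)})
    if design.require_disjoint:
        seen: set[str] = set()
        for members in planted_members.values():
            if seen & set(members):
                raise ValueError("planted pathways overlap but disjointness "
                                 "was requested")
            seen |= set(members)

    case_counts = _nb_counts(rng, case_mean, case_cv)
    ctrl_counts = _nb_counts(rng, ctrl_mean, ctrl_cv)
    genes = pd.DataFrame(np.hstack([case_counts, ctrl_counts]),
                         index=gene_ids, columns=samples)

    # background pathways over non-planted genes
    free = gene_ids[cursor:]
    for b in range(design.n_background_pathways):
        size = min(design.background_pathway_size, len(free))
        members = rng_base.choice(free, size=size, replace=False)
        pathways.append(PathwayRecord(id=f"BG_{b:03d}", name=f"BG_{b:03d}",
                                      source="background",
                                      members=frozenset(members.tolist())))

    # ncRNA ome with planted anti-correlated targets
    omics: dict[str, OmicsMatrix] = {}
    relations_rows = []
    planted_ncrna = []
    if design.n_ncrna > 0:
        nc_ids = [f"MIR{i:03d}" for i in range(design.n_ncrna)]
        nc_mu = rng_base.lognormal(design.baseline_log_mean,
                                   design.baseline_log_sd,
                                   size=design.n_ncrna)
        nc_case_mean = np.tile(nc_mu[:, None], (1, n_case))
        nc_ctrl_mean = np.tile(nc_mu[:, None], (1, n_ctrl))
        nc_case_cv = np.full((design.n_ncrna, 1), design.base_cv)
        nc_ctrl_cv = np.full((design.n_ncrna, 1), design.base_cv)
        for j in range(design.n_planted_ncrna):
            # the planted ncRNA is itself deregulated (up and stable in cases)
            nc_case_mean[j] = nc_mu[j] * 4.0
            nc_case_cv[j] = design.base_cv / 2.0
        nc_counts = np.hstack([_nb_counts(rng, nc_case_mean, nc_case_cv),
                               _nb_counts(rng, nc_ctrl_mean, nc_ctrl_cv)])
        ncrna = pd.DataFrame(nc_counts, index=nc_ids, columns=samples)
        # targets: genes whose per-sample mean decreases with the ncRNA
        free_for_targets = list(free)
        for j in range(design.n_planted_ncrna):
            nc_id = nc_ids[j]
            targets = free_for_targets[
                j * design.n_targets_per_ncrna:(j + 1) * design.n_targets_per_ncrna]
            log_nc = np.log1p(ncrna.loc[nc_id].to_numpy())
            z = (log_nc - log_nc.mean()) / max(log_nc.std(), 1e-9)
            for t in targets:
                base = mu[gene_ids.index(t)]
                per_sample_mean = base * np.exp(-design.target_anticorr_slope * z)
                genes.loc[t] = _nb_counts(
                    rng, per_sample_mean, np.full_like(per_sample_mean, 0.15))
                relations_rows.append({"ncrna_id": nc_id, "target_id": t,
                                       "relation": "repress"})
            planted_ncrna.append({"id": nc_id, "targets": list(targets)})
        omics["mirna"] = OmicsMatrix(ncrna, "mirna")

    omics["genes"] = OmicsMatrix(genes, "expression")
    relations = pd.DataFrame(relations_rows,
                             columns=["ncrna_id", "target_id", "relation"])

    mutation = None
    graph = None
    if design.n_mutation_genes > 0:
        graph = _interaction_network(design, rng_base)
        mutation = generate_mutation_data(design, graph, labels, rng)

    ledger = {
        "seed": design.seed,
        "n_case": n_case,
        "n_control": n_ctrl,
        "planted_pathways": ledger_planted,
        "planted_ncrna": planted_ncrna,
        "drivers": [] if mutation is None else
                   [f"MUT{i:03d}" for i in range(design.n_drivers)],
    }
    return SimulatedDataset(omics=omics, labels=labels, pathways=pathways,
                            relations=relations, mutation=mutation,
                            interaction_network=graph, ledger=ledger)


def _interaction_network(design: SimulationDesign,
                         rng: np.random.Generator) -> nx.Graph:
    """Small random interaction network over the mutation genes."""
    ids = [f"MUT{i:03d}" for i in range(design.n_mutation_genes)]
    g = nx.watts_strogatz_graph(design.n_mutation_genes, k=4, p=0.2,
                                seed=int(rng.integers(2 ** 31)))
    g = nx.relabel_nodes(g, {i: ids[i] for i in range(len(ids))})
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def generate_mutation_data(design: SimulationDesign,
                           network: nx.Graph,
                           labels: pd.Series,
                           rng: np.random.Generator | None = None
                           ) -> OmicsMatrix:
    """Binary gene x sample mutation matrix with class-biased drivers."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    ids = [f"MUT{i:03d}" for i in range(design.n_mutation_genes)]
    missing = [g for g in ids[:design.n_drivers] if g not in network]
    if missing:
        logger.warning("driver genes absent from network: %s", missing[:3])
    values = np.zeros((design.n_mutation_genes, len(labels)), dtype=float)
    is_case = (labels == "case").to_numpy()
    for row in range(design.n_mutation_genes):
        if row < design.n_drivers:
            p = np.where(is_case, design.driver_p_case, design.driver_p_control)
        else:
            p = np.full(len(labels), design.background_mutation_p)
        values[row] = rng.random(len(labels)) < p
    return OmicsMatrix(pd.DataFrame(values, index=ids, columns=labels.index),
                       "mutation")


def null_design(seed: int = 0, **overrides) -> SimulationDesign:
    """A design with no planted effects anywhere (false-positive control)."""
    defaults = dict(planted=(), n_planted_ncrna=0,
                    driver_p_case=0.05, driver_p_control=0.05, seed=seed)
    defaults.update(overrides)
    return SimulationDesign(**defaults)
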