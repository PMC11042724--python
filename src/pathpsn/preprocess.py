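"""Omics containers, normalization, mutation propagation and unit scaling.

Matrices are molecule x sample everywhere; samples are addressed by id,
never by position.  Expression-like omes are library-size normalized
(counts per million) and log2 transformed; binary somatic-mutation
matrices are turned into continuous scores by random-walk-with-restart
propagation over a molecular interaction network; all omes are min-max
scaled per molecule to [0, 1] before similarity computation, with the
scaling parameters frozen at training time so later (test or external)
samples are mapped onto the training scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OME_KINDS = ("expression", "mirna", "lncrna", "mutation", "mutation_propagated")


@dataclass
class OmicsMatrix:
    """One ome: a molecule x sample table plus scaling state.

    Parameters
    ----------
    values
        DataFrame with molecule ids as the index and sample ids as columns.
    ome_kind
        One of ``expression``, ``mirna``, ``lncrna``, ``mutation``,
        ``mutation_propagated``.
    scaling_params
        Per-molecule ``(min, max)`` captured when :func:`scale_unit_interval`
        is run with ``fit=True``; reused verbatim for any later sample.
    """

    values: pd.DataFrame
    ome_kind: str = "expression"
    scaling_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ome_kind not in OME_KINDS:
            raise ValueError(f"unknown ome_kind {self.ome_kind!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate molecule ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("omics matrix must be numeric")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at molecule {idx[bad[0]]!r}, "
                f"sample {cols[bad[1]]!r}")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return OmicsMatrix(self.values[sample_ids].copy(), self.ome_kind,
                           self.scaling_params)

    def copy(self) -> "OmicsMatrix":
        params = None if self.scaling_params is None else self.scaling_params.copy()
        return OmicsMatrix(self.values.copy(), self.ome_kind, params)


def validate_binary(matrix: OmicsMatrix) -> None:
    """Raise unless every entry is exactly 0 or 1."""
    arr = matrix.values.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        bad = sorted(np.unique(arr[~np.isin(arr, (0, 1))]))[:5]
        raise ValueError(f"binary matrix contains values other than 0/1: {bad}")


def normalize_ome(raw: OmicsMatrix) -> OmicsMatrix:
    """Counts-per-million normalization followed by log2(x + 1).

    Molecules with zero total count across all samples are removed (and
    logged); a sample with zero total count is an error because its library
    size is undefined.
    """
    values = raw.values
    col_sums = values.sum(axis=0)
    zero_samples = col_sums.index[col_sums == 0].tolist()
    if zero_samples:
        raise ValueError(f"samples with zero total count: {zero_samples}")
    keep = values.sum(axis=1) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("normalize_ome: removed %d all-zero molecules", dropped)
    values = values.loc[keep]
    cpm = values.div(col_sums, axis=1) * 1e6
    logged = np.log2(cpm + 1.0)
    return OmicsMatrix(logged, raw.ome_kind)


def _degree_normalized_adjacency(graph: nx.Graph,
                                 nodes: list[str]) -> np.ndarray:
    """Symmetric D^(-1/2) A D^(-1/2) over the given node order."""
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


def propagate_mutations(binary: OmicsMatrix,
                        network: nx.Graph,
                        restart: float = 0.7,
                        tolerance: float = 1e-6,
                        max_iter: int = 1000) -> OmicsMatrix:
    """Random-walk-with-restart diffusion of binary mutation indicators.

    Iterates ``F <- (1 - restart) * F0 + restart * F @ S`` with ``S`` the
    symmetrically degree-normalized adjacency until the L1 change drops
    below ``tolerance``.  Genes absent from the interaction network keep
    their input score (self-only propagation).  Per-sample mass is restored
    to the input mass afterwards, so the scores remain comparable across
    samples.
    """
    if not 0.0 < restart < 1.0:
        raise ValueError(f"restart must lie in (0, 1), got {restart}")
    validate_binary(binary)
    genes = binary.molecule_ids
    missing = [g for g in genes if g not in network]
    if missing:
        logger.warning("propagate_mutations: %d genes not in network, kept "
                       "with self-only propagation (e.g. %s)",
                       len(missing), missing[:3])
    in_net = [g for g in genes if g in network]
    f0_all = binary.values.to_numpy(dtype=float).T  # sample x gene
    out = f0_all.copy()
    if in_net and network.number_of_edges() > 0:
        s = _degree_normalized_adjacency(network, in_net)
        col_idx = [genes.index(g) for g in in_net]
        f0 = f0_all[:, col_idx]
        f = f0.copy()
        for iteration in range(max_iter):
            f_next = (1.0 - restart) * f0 + restart * (f @ s)
            delta = np.abs(f_next - f).sum()
            f = f_next
            if delta < tolerance:
                break
        logger.info("propagate_mutations: converged in %d iterations",
                    iteration + 1)
        out[:, col_idx] = f
        # restore per-sample mass lost at degree-0 / boundary nodes
        in_mass = f0_all.sum(axis=1)
        out_mass = out.sum(axis=1)
        scale = np.where(out_mass > 0, in_mass / np.where(out_mass > 0, out_mass, 1.0), 1.0)
        out = out * scale[:, None]
    result = pd.DataFrame(out.T, index=genes, columns=binary.sample_ids)
    return OmicsMatrix(result, "mutation_propagated")


def scale_unit_interval(matrix: OmicsMatrix, fit: bool = True) -> OmicsMatrix:
    """Per-molecule min-max scaling to [0, 1].

    With ``fit=True`` the per-molecule minima and maxima are computed and
    stored on the returned matrix; with ``fit=False`` the stored parameters
    are applied and values are clipped to [0, 1] (external samples may fall
    outside the training range).  Constant molecules map to 0.5: a neutral
    intensity that avoids division by zero.
    """
    if fit:
        lo = matrix.values.min(axis=1)
        hi = matrix.values.max(axis=1)
        params = pd.DataFrame({"min": lo, "max": hi})
    else:
        if matrix.scaling_params is None:
            raise ValueError("scale_unit_interval(fit=False) requires stored "
                             "scaling parameters")
        params = matrix.scaling_params.reindex(matrix.values.index)
        if params["min"].isna().any():
            missing = params.index[params["min"].isna()].tolist()
            raise ValueError(f"no stored scaling params for molecules: {missing[:5]}")
        lo, hi = params["min"], params["max"]
    span = hi - lo
    constant = span == 0
    safe_span = span.mask(constant, 1.0)
    scaled = matrix.values.sub(lo, axis=0).div(safe_span, axis=0)
    scaled = scaled.clip(0.0, 1.0)
    scaled.loc[constant] = 0.5
    return OmicsMatrix(scaled, matrix.ome_kind, params)
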