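"""Run configuration shared by every stage of the pipeline.

A single :class:`RunConfig` travels through normalization, feature
selection, network construction and classifier training so that one seed
and one set of thresholds govern a whole run.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import numpy as np


def power_percentile_schedule(n_levels: int = 10,
                              low_start: float = 0.35,
                              low_end: float = 0.10,
                              high_start: float = 0.65,
                              high_end: float = 0.90) -> list[tuple[float, float]]:
    """Percentile pairs (low_k, high_k) for the separability-power levels.

    Level 1 compares the 0.35 quantile of the candidate cohesive class'
    intra-similarities against the 0.65 quantile of the two other similarity
    sets; each further level tightens both percentiles linearly until the
    0.10 / 0.90 pair at level 10.
    """
    lows = np.linspace(low_start, low_end, n_levels)
    highs = np.linspace(high_start, high_end, n_levels)
    return [(float(l), float(h)) for l, h in zip(lows, highs)]


@dataclass
class RunConfig:
    """Tunable parameters of a classification run.

    All fractions live in (0, 1]; the seed is consumed by every random
    operation downstream and recorded in every report.
    """

    seed: int = 0
    n_folds: int = 5
    validation_fraction: float = 0.2
    significance_alpha: float = 0.05
    min_pathway_size: int = 5
    max_pathway_size: int = 500
    min_overlap: int = 3
    top_n_molecules: int | None = None
    moderated_prior_df: float = 4.0
    log_ratio_epsilon: float = 1e-8
    restart_probability: float = 0.7
    propagation_tolerance: float = 1e-6
    sparsify_keep_fraction: float = 0.2
    power_levels: int = 10
    power_low_range: tuple[float, float] = (0.35, 0.10)
    power_high_range: tuple[float, float] = (0.65, 0.90)
    # GraphSAGE hyperparameters
    gcn_layers: int = 2
    gcn_hidden: int = 16
    gcn_dropout: float = 0.5
    gcn_learning_rate: float = 0.01
    gcn_max_epochs: int = 200
    gcn_patience: int = 20
    acceptance_mcc: float = 0.5
    representative_cluster_count: int = 20

    def __post_init__(self) -> None:
        for name in ("validation_fraction", "sparsify_keep_fraction",
                     "significance_alpha"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")
        if not 0.0 < self.restart_probability < 1.0:
            raise ValueError("restart_probability must lie in (0, 1), got "
                             f"{self.restart_probability}")

    @property
    def percentile_schedule(self) -> list[tuple[float, float]]:
        return power_percentile_schedule(
            self.power_levels,
            self.power_low_range[0], self.power_low_range[1],
            self.power_high_range[0], self.power_high_range[1])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["power_low_range"] = list(self.power_low_range)
        d["power_high_range"] = list(self.power_high_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("power_low_range", "power_high_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def derive_seed(self, tag: str) -> int:
        """Stable per-component seed below 2**31, derived from the run seed."""
        import zlib
        return (int(self.seed) ^ zlib.crc32(tag.encode())) % (2 ** 31)
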