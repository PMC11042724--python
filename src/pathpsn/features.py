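"""Feature selection: deregulated AND stable molecules, pathway enrichment.

For every molecule two log fold changes are computed between the classes:
the expression log fold change (elFC, log2 ratio of class means) and the
variance log fold change (vlFC, log2 ratio of class coefficients of
variation).  *Stability* is the negated vlFC: a molecule with positive
elFC and positive stability is higher and less dispersed in the cases.
Molecules are tested with a moderated t-statistic (empirical-Bayes
variance shrinkage towards the pooled prior), BH-adjusted, and the
significant ones are ranked by the product of their |elFC| and |vlFC|
ranks.  Selected molecules feed a hypergeometric over-representation
analysis, and each enriched pathway is assigned one of four direction
categories from the sign pattern (elFC, stability) of its significant
members:

    (+, +) activated by cases      (-, -) activated by controls
    (-, +) inhibited by cases      (+, -) inhibited by controls

Non-coding RNAs are integrated hierarchically: an ncRNA whose measured
targets are significantly anti-correlated with it (one-sided two-sample
Kolmogorov-Smirnov test on Spearman-correlation distributions against the
background) contributes its target set as a candidate pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayRecord
from .preprocess import OmicsMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("activated_case", "activated_control",
              "inhibited_case", "inhibited_control")


@dataclass
class EnrichedPathway:
    """A pathway over-represented among the selected molecules."""

    pathway: PathwayRecord
    significant_members: frozenset[str]
    ora_p: float
    ora_adjusted_p: float
    category: str | None = None
    contains_mutated_gene: bool = False

    @property
    def id(self) -> str:
        return self.pathway.id

    @property
    def overlap(self) -> int:
        return len(self.significant_members)

    @property
    def direction(self) -> str:
        if self.category is None:
            raise ValueError("pathway not categorized yet")
        return "activated" if self.category.startswith("activated") else "inhibited"


def compute_fold_changes(ome: OmicsMatrix, labels: pd.Series,
                         case_class: str | None = None,
                         epsilon: float = 1e-8) -> pd.DataFrame:
    """elFC / vlFC table, one row per molecule.

    ``case_class`` names which label is treated as the case (numerator);
    by default the lexicographically first class.  CV uses the sample
    standard deviation (ddof=1), hence at least two samples per class.
    """
    labels = labels.reindex(ome.sample_ids)
    classes = sorted(labels.dropna().unique())
    if case_class is None:
        case_class = classes[0]
    control_class = [c for c in classes if c != case_class][0]
    case_mask = (labels == case_class).to_numpy()
    ctrl_mask = (labels == control_class).to_numpy()
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValueError("each class needs at least 2 samples to compute a CV")
    x = ome.values.to_numpy()
    xc, xk = x[:, case_mask], x[:, ctrl_mask]
    adv_case, adv_ctrl = xc.mean(axis=1), xk.mean(axis=1)
    sd_case = xc.std(axis=1, ddof=1)
    sd_ctrl = xk.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_case = np.where(adv_case != 0, sd_case / np.where(adv_case != 0, adv_case, 1), 0.0)
        cv_ctrl = np.where(adv_ctrl != 0, sd_ctrl / np.where(adv_ctrl != 0, adv_ctrl, 1), 0.0)
    elfc = np.log2((adv_case + epsilon) / (adv_ctrl + epsilon))
    vlfc = np.log2((cv_case + epsilon) / (cv_ctrl + epsilon))
    return pd.DataFrame({
        "adv_case": adv_case, "adv_control": adv_ctrl,
        "cv_case": cv_case, "cv_control": cv_ctrl,
        "elfc": elfc, "vlfc": vlfc, "stability": -vlfc,
    }, index=ome.molecule_ids)


def moderated_t_test(ome: OmicsMatrix, labels: pd.Series,
                     case_class: str | None = None,
                     prior_df: float = 4.0) -> pd.DataFrame:
    """Two-sample moderated t with empirical-Bayes variance shrinkage.

    The per-molecule pooled variance is shrunk towards the grand mean of
    pooled variances with ``prior_df`` prior degrees of freedom; p-values
    come from a t distribution with residual + prior df.
    """
    labels = labels.reindex(ome.sample_ids)
    classes = sorted(labels.dropna().unique())
    if case_class is None:
        case_class = classes[0]
    control_class = [c for c in classes if c != case_class][0]
    case_mask = (labels == case_class).to_numpy()
    ctrl_mask = (labels == control_class).to_numpy()
    n1, n2 = int(case_mask.sum()), int(ctrl_mask.sum())
    x = ome.values.to_numpy()
    xc, xk = x[:, case_mask], x[:, ctrl_mask]
    diff = xc.mean(axis=1) - xk.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ((xc.var(axis=1, ddof=1) * (n1 - 1) + xk.var(axis=1, ddof=1) * (n2 - 1))
          / df_resid)
    s2_prior = float(s2.mean())
    s2_post = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_resid + prior_df)
    return pd.DataFrame({"mean_diff": diff, "t": t, "moderated_p": p},
                        index=ome.molecule_ids)


def select_molecules(stats_table: pd.DataFrame, ome: OmicsMatrix,
                     labels: pd.Series, alpha: float = 0.05,
                     top_n: int | None = None,
                     case_class: str | None = None,
                     prior_df: float = 4.0) -> pd.DataFrame:
    """Gate molecules at BH-adjusted moderated p <= alpha and rank them.

    The ranking is the product of the descending rank of |elFC| and the
    descending rank of |vlFC| (smaller product = more deregulated AND more
    differentially stable); ``top_n`` truncates the selection.
    Returns the stats table augmented with moderated_p, adjusted_p,
    rank_product and selected columns.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    tt = moderated_t_test(ome, labels, case_class=case_class, prior_df=prior_df)
    table = stats_table.join(tt[["moderated_p"]])
    _, adjusted, _, _ = multipletests(table["moderated_p"].to_numpy(),
                                      method="fdr_bh")
    table["adjusted_p"] = adjusted
    rank_e = table["elfc"].abs().rank(ascending=False, method="average")
    rank_v = table["vlfc"].abs().rank(ascending=False, method="average")
    table["rank_product"] = rank_e * rank_v
    selected = table["adjusted_p"] <= alpha
    if top_n is not None and selected.sum() > top_n:
        order = table.loc[selected].sort_values("rank_product").index[:top_n]
        selected = pd.Series(False, index=table.index)
        selected[order] = True
    table["selected"] = selected
    return table


def test_ncrna_target_link(ncrna_values: pd.Series, target_matrix: OmicsMatrix,
                           background_matrix: OmicsMatrix,
                           alpha: float = 0.05) -> tuple[bool, float, str]:
    """Does an ncRNA anti-correlate with its measured targets?

    Spearman correlations of the ncRNA with each target and with each
    background molecule are compared with a one-sided two-sample KS test
    (alternative: the target-correlation distribution is stochastically
    smaller).  Kept only when the KS p-value passes *and* the median
    target correlation is negative.  Returns (keep, p, reason).
    """
    targets = list(target_matrix.molecule_ids)
    if len(targets) < 5:
        return False, 1.0, "insufficient targets"
    samples = ncrna_values.index
    x = ncrna_values.to_numpy()
    t_corr = np.array([stats.spearmanr(x, target_matrix.values.loc[t, samples]).statistic
                       for t in targets])
    b_corr = np.array([stats.spearmanr(x, background_matrix.values.loc[b, samples]).statistic
                       for b in background_matrix.molecule_ids])
    t_corr = t_corr[np.isfinite(t_corr)]
    b_corr = b_corr[np.isfinite(b_corr)]
    if len(t_corr) < 5 or len(b_corr) < 5:
        return False, 1.0, "insufficient finite correlations"
    # alternative="greater": the eCDF of target correlations lies above the
    # background eCDF, i.e. target correlations are stochastically smaller
    ks = stats.ks_2samp(t_corr, b_corr, alternative="greater")
    keep = bool(ks.pvalue <= alpha and np.median(t_corr) < 0)
    reason = "ok" if keep else "not anti-correlated"
    return keep, float(ks.pvalue), reason


def enrich_pathways(selected: set[str], universe: set[str],
                    pathways: list[PathwayRecord], alpha: float = 0.05,
                    min_size: int = 5, max_size: int = 500,
                    min_overlap: int = 3) -> list[EnrichedPathway]:
    """Hypergeometric over-representation analysis with BH correction.

    Pathways are intersected with the universe and size-filtered before
    testing; kept when BH-adjusted p <= alpha and overlap >= min_overlap.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected molecules must be a subset of the universe")
    if not selected:
        logger.warning("enrich_pathways: empty selected set")
        return []
    n_universe, n_selected = len(universe), len(selected)
    tested: list[tuple[PathwayRecord, frozenset[str], float]] = []
    for rec in pathways:
        members = frozenset(rec.members & universe)
        if not min_size <= len(members) <= max_size:
            continue
        overlap = members & selected
        p = stats.hypergeom.sf(len(overlap) - 1, n_universe, len(members),
                               n_selected)
        tested.append((rec, frozenset(overlap), float(p)))
    if not tested:
        return []
    _, adjusted, _, _ = multipletests([t[2] for t in tested], method="fdr_bh")
    results = []
    for (rec, overlap, p), p_adj in zip(tested, adjusted):
        if p_adj <= alpha and len(overlap) >= min_overlap:
            results.append(EnrichedPathway(pathway=rec,
                                           significant_members=overlap,
                                           ora_p=p, ora_adjusted_p=float(p_adj)))
    return results


def categorize_pathway(enriched: EnrichedPathway,
                       stats_table: pd.DataFrame) -> str:
    """Assign one of the four direction categories by quadrant plurality.

    Members sit in the (elFC, stability) plane; the plurality quadrant
    wins, ties broken by the larger mean |elFC| within the tied quadrants.
    Members with both coordinates exactly zero abstain.
    """
    quadrant_of = {(1, 1): "activated_case", (-1, -1): "activated_control",
                   (-1, 1): "inhibited_case", (1, -1): "inhibited_control"}
    counts = {c: 0 for c in CATEGORIES}
    elfc_abs = {c: [] for c in CATEGORIES}
    for m in enriched.significant_members:
        if m not in stats_table.index:
            raise KeyError(f"no stats for pathway member {m!r}")
        e = float(stats_table.loc[m, "elfc"])
        s = float(stats_table.loc[m, "stability"])
        if e == 0 and s == 0:
            continue
        quad = (1 if e >= 0 else -1, 1 if s >= 0 else -1)
        cat = quadrant_of[quad]
        counts[cat] += 1
        elfc_abs[cat].append(abs(e))
    if all(v == 0 for v in counts.values()):
        raise ValueError(f"pathway {enriched.id}: no member votes")
    top = max(counts.values())
    tied = [c for c, v in counts.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    return max(tied, key=lambda c: float(np.mean(elfc_abs[c])))


def flag_mutated_pathways(enriched: list[EnrichedPathway],
                          mutated_significant: set[str]
                          ) -> list[EnrichedPathway]:
    """Mark pathways whose members intersect the significant mutated genes."""
    mutated_significant = set(mutated_significant)
    out = []
    for ep in enriched:
        flag = bool(ep.pathway.members & mutated_significant)
        out.append(replace(ep, contains_mutated_gene=flag))
    return out
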