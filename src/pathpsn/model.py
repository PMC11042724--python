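"""Model / Results interface tying the whole pipeline together.

:class:`PSNClassifier` is constructed from data (omics matrices, a
two-class label table, pathway collections and optional ncRNA-target
relations, mutation matrix and interaction network); ``fit()`` runs
feature selection, pathway enrichment, similarity-network construction,
separability filtering and per-network GraphSAGE training, and returns a
:class:`PSNClassifierResults` that carries the selected molecules,
enriched pathways, signature networks, trained models and diagnostics,
predicts unknown patients, and serializes to a model bundle for later
inference.  ``cross_validate()`` wraps the fit in a stratified k-fold
loop where test patients only ever enter a network through
``attach_unknowns``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import features as fs
from . import gcn, metrics, network_analysis
from . import psn as psn_mod
from .config import RunConfig
from .io import PathwayRecord
from .preprocess import (OmicsMatrix, normalize_ome, propagate_mutations,
                         scale_unit_interval)

logger = logging.getLogger(__name__)

CONTINUOUS_KINDS = ("expression", "mirna", "lncrna")
NCRNA_KINDS = ("mirna", "lncrna")


def _normalize_like(raw: OmicsMatrix, reference_index: pd.Index) -> OmicsMatrix:
    """CPM + log2 a new matrix and align its rows to the training molecules.

    Molecules measured at training but absent here are filled with zero
    (and logged); extra molecules are dropped.
    """
    norm = normalize_ome(raw)
    missing = reference_index.difference(norm.values.index)
    if len(missing):
        logger.warning("external ome lacks %d training molecules; filled "
                       "with 0 (e.g. %s)", len(missing), list(missing[:3]))
    aligned = norm.values.reindex(reference_index).fillna(0.0)
    return OmicsMatrix(aligned, raw.ome_kind)


@dataclass
class FoldReport:
    """Per-fold cross-validation outcome."""

    fold: int
    test_ids: list[str]
    ensemble: gcn.EnsemblePrediction | None
    metrics: metrics.MetricReport | None
    model_test_mcc: dict[str, float]
    n_signature_networks: int


class PSNClassifier:
    """Pathway-based patient-similarity-network classifier (the model).

    Parameters
    ----------
    omics
        Mapping of ome name to raw count :class:`OmicsMatrix`
        (kinds ``expression`` / ``mirna`` / ``lncrna``).
    labels
        Series mapping sample id to one of exactly two class labels.
    pathways
        Gene-set collection (e.g. from :func:`pathpsn.io.read_gmt`).
    relations
        Optional ncRNA-target table with columns
        ``ncrna_id, target_id, relation``.
    mutation
        Optional binary gene x sample mutation matrix.
    interaction_network
        Undirected weighted gene graph used to propagate mutations.
    config
        :class:`RunConfig`; defaults are used when omitted.
    """

    def __init__(self, omics: dict[str, OmicsMatrix], labels: pd.Series,
                 pathways: list[PathwayRecord],
                 relations: pd.DataFrame | None = None,
                 mutation: OmicsMatrix | None = None,
                 interaction_network=None,
                 config: RunConfig | None = None) -> None:
        self.omics = dict(omics)
        self.labels = labels.astype(str)
        self.classes = tuple(sorted(self.labels.unique()))
        if len(self.classes) != 2:
            raise ValueError(f"expected two classes, found {self.classes}")
        self.pathways = list(pathways)
        self.relations = relations
        self.mutation = mutation
        self.interaction_network = interaction_network
        self.config = config or RunConfig()
        for name, ome in self.omics.items():
            unlabeled = [s for s in ome.sample_ids if s not in self.labels.index]
            if unlabeled:
                raise KeyError(f"ome {name!r} has unlabeled samples: "
                               f"{unlabeled[:5]}")

    @classmethod
    def from_dataset(cls, dataset, config: RunConfig | None = None
                     ) -> "PSNClassifier":
        """Build a model from a :class:`pathpsn.simulate.SimulatedDataset`."""
        return cls(omics=dataset.omics, labels=dataset.labels,
                   pathways=dataset.pathways, relations=dataset.relations,
                   mutation=dataset.mutation,
                   interaction_network=dataset.interaction_network,
                   config=config)

    # ------------------------------------------------------------------ fit

    def _split_validation(self, sample_ids: list[str]) -> tuple[list[str], list[str]]:
        y = self.labels.loc[sample_ids]
        train, val = train_test_split(
            sample_ids, test_size=self.config.validation_fraction,
            stratify=y, random_state=self.config.derive_seed("valsplit"))
        return list(train), list(val)

    def fit(self, sample_ids: list[str] | None = None,
            validation_ids: list[str] | None = None) -> "PSNClassifierResults":
        """Run the training pipeline on the given samples.

        ``sample_ids`` defaults to every labeled sample present in the
        first ome; when ``validation_ids`` is not given a stratified
        ``validation_fraction`` of the samples is held out for gating.
        """
        cfg = self.config
        if sample_ids is None:
            first = next(iter(self.omics.values()))
            sample_ids = [s for s in first.sample_ids if s in self.labels.index]
        if validation_ids is None:
            train_ids, validation_ids = self._split_validation(list(sample_ids))
        else:
            train_ids = [s for s in sample_ids if s not in set(validation_ids)]
        fit_ids = train_ids + list(validation_ids)
        labels_fit = self.labels.loc[fit_ids]

        # 1. normalize each ome and restrict to the fitting samples
        normalized: dict[str, OmicsMatrix] = {}
        for name, ome in self.omics.items():
            if ome.ome_kind not in CONTINUOUS_KINDS:
                raise ValueError(f"ome {name!r} has kind {ome.ome_kind!r}; "
                                 "mutation data goes in the mutation slot")
            normalized[name] = normalize_ome(ome).subset_samples(
                [s for s in fit_ids])

        # 2. per-ome fold changes and moderated-t selection
        stats_tables: dict[str, pd.DataFrame] = {}
        for name, ome in normalized.items():
            table = fs.compute_fold_changes(ome, labels_fit,
                                            case_class=self.classes[0],
                                            epsilon=cfg.log_ratio_epsilon)
            table = fs.select_molecules(table, ome, labels_fit,
                                        alpha=cfg.significance_alpha,
                                        top_n=cfg.top_n_molecules,
                                        case_class=self.classes[0],
                                        prior_df=cfg.moderated_prior_df)
            stats_tables[name] = table

        # 3. hierarchical integration: ncRNA target sets as candidate pathways
        candidate_pathways = list(self.pathways)
        ncrna_sets: list[PathwayRecord] = []
        gene_omes = [n for n, o in normalized.items()
                     if o.ome_kind == "expression"]
        if self.relations is not None and len(self.relations) and gene_omes:
            gene_ome = normalized[gene_omes[0]]
            rng = np.random.default_rng(cfg.derive_seed("ncrna-bg"))
            for name, ome in normalized.items():
                if ome.ome_kind not in NCRNA_KINDS:
                    continue
                selected_nc = stats_tables[name].index[
                    stats_tables[name]["selected"]]
                for nc in selected_nc:
                    targets = self.relations.loc[
                        self.relations["ncrna_id"] == nc, "target_id"]
                    targets = [t for t in targets
                               if t in gene_ome.values.index]
                    if len(targets) < 5:
                        continue
                    background = [g for g in gene_ome.molecule_ids
                                  if g not in set(targets)]
                    if len(background) > 200:
                        background = list(rng.choice(background, size=200,
                                                     replace=False))
                    target_matrix = OmicsMatrix(
                        gene_ome.values.loc[targets], "expression")
                    background_matrix = OmicsMatrix(
                        gene_ome.values.loc[background], "expression")
                    keep, p, reason = fs.test_ncrna_target_link(
                        ome.values.loc[nc], target_matrix, background_matrix,
                        alpha=cfg.significance_alpha)
                    logger.info("ncRNA %s target link: keep=%s p=%.3g (%s)",
                                nc, keep, p, reason)
                    if keep:
                        ncrna_sets.append(PathwayRecord(
                            id=f"{nc}:targets", name=f"{nc} target set",
                            source="ncrna_target_set",
                            members=frozenset([nc, *targets])))
            candidate_pathways.extend(ncrna_sets)

        # 4. mutation propagation and significant mutated genes
        mutated_significant: set[str] = set()
        if self.mutation is not None and self.interaction_network is not None:
            binary = self.mutation.subset_samples(
                [s for s in fit_ids if s in self.mutation.values.columns])
            propagated = propagate_mutations(
                binary, self.interaction_network,
                restart=cfg.restart_probability,
                tolerance=cfg.propagation_tolerance)
            mut_stats = fs.compute_fold_changes(
                propagated, labels_fit.loc[propagated.sample_ids],
                case_class=self.classes[0], epsilon=cfg.log_ratio_epsilon)
            mut_stats = fs.select_molecules(
                mut_stats, propagated, labels_fit.loc[propagated.sample_ids],
                alpha=cfg.significance_alpha, case_class=self.classes[0],
                prior_df=cfg.moderated_prior_df)
            mutated_significant = set(mut_stats.index[mut_stats["selected"]])

        # 5. over-representation analysis on the combined molecule space
        combined_stats = pd.concat(stats_tables.values())
        universe = set(combined_stats.index)
        selected = set(combined_stats.index[combined_stats["selected"]])
        enriched = fs.enrich_pathways(selected, universe, candidate_pathways,
                                      alpha=cfg.significance_alpha,
                                      min_size=cfg.min_pathway_size,
                                      max_size=cfg.max_pathway_size,
                                      min_overlap=cfg.min_overlap)
        for ep in enriched:
            ep.category = fs.categorize_pathway(ep, combined_stats)
        enriched = fs.flag_mutated_pathways(enriched, mutated_significant)

        # 6. unit scaling (params frozen) and the combined scaled matrix
        scaled: dict[str, OmicsMatrix] = {}
        for name, ome in normalized.items():
            scaled[name] = scale_unit_interval(ome, fit=True)
        combined_scaled = pd.concat([m.values for m in scaled.values()])
        if combined_scaled.index.has_duplicates:
            dups = combined_scaled.index[
                combined_scaled.index.duplicated()].unique().tolist()
            raise ValueError(f"molecule ids collide across omes: {dups[:5]}")
        combined_matrix = OmicsMatrix(combined_scaled, "expression")

        # 7. similarity networks, separability filtering, sparsification
        networks: list[psn_mod.SimilarityNetwork] = []
        schedule = cfg.percentile_schedule
        for ep in enriched:
            net = psn_mod.build_psn(combined_matrix, ep, fit_ids,
                                    labels=labels_fit.to_dict())
            if net is None:
                continue
            net.separability = psn_mod.separability_power(net, schedule)
            networks.append(net)
        signature = psn_mod.filter_networks(networks, schedule)
        for net in signature:
            net.centrality = network_analysis.patient_centrality(net)
        sparsified = [psn_mod.sparsify_psn(net, cfg.sparsify_keep_fraction)
                      for net in signature]

        # 8. per-network GraphSAGE training with validation gating
        roles = {s: "train" for s in train_ids}
        roles.update({s: "validation" for s in validation_ids})
        models: dict[str, gcn.TrainedPSNModel] = {}
        for net in sparsified:
            feat = gcn.build_node_features(net, labels_fit, roles,
                                           class_order=self.classes)
            models[net.pathway_id] = gcn.train_model(net, feat, cfg)

        return PSNClassifierResults(
            model=self, config=cfg, train_ids=train_ids,
            validation_ids=list(validation_ids),
            stats_tables=stats_tables, combined_stats=combined_stats,
            mutated_significant=mutated_significant,
            ncrna_target_sets=ncrna_sets, enriched=enriched,
            scaled_omes=scaled, networks_dense=signature,
            networks=sparsified, trained_models=models)

    # ------------------------------------------------- cross-validation

    def cross_validate(self) -> "CrossValidationResults":
        """Stratified k-fold evaluation; test patients are attached as
        unknowns to networks fitted without them."""
        cfg = self.config
        first = next(iter(self.omics.values()))
        sample_ids = np.array([s for s in first.sample_ids
                               if s in self.labels.index])
        y = self.labels.loc[sample_ids].to_numpy()
        counts = pd.Series(y).value_counts()
        if counts.min() < cfg.n_folds:
            raise ValueError("a class is too small for stratified "
                             f"{cfg.n_folds}-fold CV: {counts.to_dict()}")
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=cfg.derive_seed("folds"))
        folds: list[FoldReport] = []
        all_true: list[str] = []
        all_pred: list[str] = []
        for fold_no, (fit_idx, test_idx) in enumerate(skf.split(sample_ids, y)):
            fit_samples = sample_ids[fit_idx].tolist()
            test_samples = sample_ids[test_idx].tolist()
            results = self.fit(sample_ids=fit_samples)
            if not any(m.accepted for m in results.trained_models.values()):
                logger.info("fold %d: no accepted models", fold_no)
                folds.append(FoldReport(fold=fold_no, test_ids=test_samples,
                                        ensemble=None, metrics=None,
                                        model_test_mcc={},
                                        n_signature_networks=len(results.networks)))
                continue
            ensemble = results.predict(
                {name: OmicsMatrix(
                    self.omics[name].values[test_samples],
                    self.omics[name].ome_kind)
                 for name in self.omics})
            true = self.labels.loc[ensemble.predictions.index]
            report = metrics.classification_metrics(true,
                                                    ensemble.predictions)
            per_model = {}
            for pathway_id, group in ensemble.votes.groupby("pathway_id"):
                per_model[pathway_id] = metrics.matthews_corrcoef(
                    self.labels.loc[group["patient"]].to_numpy(),
                    group["vote"].to_numpy())
            folds.append(FoldReport(fold=fold_no, test_ids=test_samples,
                                    ensemble=ensemble, metrics=report,
                                    model_test_mcc=per_model,
                                    n_signature_networks=len(results.networks)))
            all_true.extend(true.tolist())
            all_pred.extend(ensemble.predictions.tolist())
        pooled = (metrics.classification_metrics(all_true, all_pred)
                  if all_true else None)
        return CrossValidationResults(folds=folds, pooled=pooled,
                                      config=cfg)


@dataclass
class CrossValidationResults:
    """Fold-wise and pooled cross-validation reports."""

    folds: list[FoldReport]
    pooled: metrics.MetricReport | None
    config: RunConfig

    @property
    def model_test_mccs(self) -> pd.Series:
        rows = {}
        for fr in self.folds:
            for pid, mcc in fr.model_test_mcc.items():
                rows[f"fold{fr.fold}:{pid}"] = mcc
        return pd.Series(rows, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            m = fr.metrics.to_dict() if fr.metrics else {}
            rows.append({"fold": fr.fold,
                         "n_test": len(fr.test_ids),
                         "n_signature_networks": fr.n_signature_networks,
                         **{k: m.get(k) for k in
                            ("mcc", "accuracy", "sensitivity", "specificity")}})
        return pd.DataFrame(rows)


@dataclass
class PSNClassifierResults:
    """Everything ``fit()`` learned, plus prediction and reporting."""

    model: PSNClassifier
    config: RunConfig
    train_ids: list[str]
    validation_ids: list[str]
    stats_tables: dict[str, pd.DataFrame]
    combined_stats: pd.DataFrame
    mutated_significant: set[str]
    ncrna_target_sets: list[PathwayRecord]
    enriched: list[fs.EnrichedPathway]
    scaled_omes: dict[str, OmicsMatrix]
    networks_dense: list[psn_mod.SimilarityNetwork]
    networks: list[psn_mod.SimilarityNetwork]
    trained_models: dict[str, gcn.TrainedPSNModel]

    # -------------------------------------------------------- prediction

    @property
    def accepted_models(self) -> dict[str, gcn.TrainedPSNModel]:
        return {k: m for k, m in self.trained_models.items() if m.accepted}

    @property
    def fit_ids(self) -> list[str]:
        return self.train_ids + self.validation_ids

    def _scale_external(self, omics_new: dict[str, OmicsMatrix]
                        ) -> tuple[OmicsMatrix | None, list[str]]:
        """Normalize + frozen-scale external omes; returns the combined
        matrix and the list of omes that were available."""
        blocks = []
        available = []
        for name, scaled_ref in self.scaled_omes.items():
            if name not in omics_new:
                logger.warning("ome %r missing from external data; the "
                               "corresponding models are disabled", name)
                continue
            aligned = _normalize_like(omics_new[name],
                                      scaled_ref.values.index)
            aligned.scaling_params = scaled_ref.scaling_params
            blocks.append(scale_unit_interval(aligned, fit=False).values)
            available.append(name)
        if not blocks:
            return None, []
        return OmicsMatrix(pd.concat(blocks), "expression"), available

    def predict(self, omics_new: dict[str, OmicsMatrix],
                sample_ids: list[str] | None = None) -> gcn.EnsemblePrediction:
        """Ensemble prediction for unknown patients.

        ``omics_new`` holds raw count matrices over the unknown samples
        for (a subset of) the training omes; networks whose molecules are
        unavailable are skipped with a log message.
        """
        combined, available = self._scale_external(omics_new)
        if combined is None:
            raise ValueError("zero applicable models: external data shares "
                             f"no omes with training ({list(self.scaled_omes)})")
        if sample_ids is None:
            sample_ids = combined.sample_ids
        available_molecules = set(combined.values.index)
        roles = {s: "train" for s in self.train_ids}
        roles.update({s: "validation" for s in self.validation_ids})
        vote_frames = []
        for net in self.networks:
            trained = self.trained_models.get(net.pathway_id)
            if trained is None or not trained.accepted:
                continue
            if not set(net.molecule_ids) <= available_molecules:
                logger.info("predict: skipping %s (molecules missing from "
                            "external data)", net.pathway_id)
                continue
            extended = psn_mod.attach_unknowns(
                net, combined, sample_ids,
                keep_fraction=self.config.sparsify_keep_fraction)
            feat = gcn.build_node_features(
                extended, self.model.labels.reindex(self.fit_ids),
                roles, class_order=self.model.classes)
            vote_frames.append(gcn.predict_unknowns(trained, extended, feat,
                                                    sample_ids))
        if not vote_frames:
            raise ValueError("no usable signature networks: zero accepted "
                             "models could vote on the given data")
        return gcn.ensemble_vote(pd.concat(vote_frames, ignore_index=True))

    # ------------------------------------------------------- refit check

    def refit_with_predicted(self, predictions: pd.Series,
                             omics_new: dict[str, OmicsMatrix]
                             ) -> pd.DataFrame:
        """Re-run selection + enrichment + power with predicted labels
        merged in; reports each retained pathway as confirmed or dropped."""
        merged_omics = {}
        for name, ome in self.model.omics.items():
            if name in omics_new:
                joined = pd.concat(
                    [ome.values[self.fit_ids],
                     omics_new[name].values[list(predictions.index)]], axis=1)
                merged_omics[name] = OmicsMatrix(joined, ome.ome_kind)
            else:
                merged_omics[name] = ome.subset_samples(self.fit_ids)
        merged_labels = pd.concat(
            [self.model.labels.loc[self.fit_ids], predictions.astype(str)])
        refit_model = PSNClassifier(
            omics=merged_omics, labels=merged_labels,
            pathways=self.model.pathways, relations=self.model.relations,
            mutation=self.model.mutation,
            interaction_network=self.model.interaction_network,
            config=self.config)
        refit = refit_model.fit()
        confirmed_ids = {net.pathway_id for net in refit.networks}
        rows = []
        for net in self.networks:
            rows.append({"pathway_id": net.pathway_id,
                         "confirmed": net.pathway_id in confirmed_ids})
        return pd.DataFrame(rows)

    # --------------------------------------------------------- reporting

    def power_table(self) -> pd.DataFrame:
        rows = []
        for net in self.networks:
            sep = net.separability
            trained = self.trained_models.get(net.pathway_id)
            ep = next((e for e in self.enriched if e.id == net.pathway_id), None)
            rows.append({
                "pathway_id": net.pathway_id,
                "direction": net.direction,
                "category": ep.category if ep else None,
                "power": sep.power,
                "cohesive_class": sep.cohesive_class,
                "mean_intra_" + self.model.classes[0]:
                    sep.mean_intra.get(self.model.classes[0]),
                "mean_intra_" + self.model.classes[1]:
                    sep.mean_intra.get(self.model.classes[1]),
                "mean_inter": sep.mean_inter,
                "contains_mutated_gene":
                    ep.contains_mutated_gene if ep else False,
                "validation_mcc":
                    trained.validation_mcc if trained else None,
                "accepted": trained.accepted if trained else False,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a model fit report."""
        lines = ["Pathway PSN classifier fit",
                 "=" * 64,
                 f"classes:              {self.model.classes[0]} vs "
                 f"{self.model.classes[1]}",
                 f"training patients:    {len(self.train_ids)}",
                 f"validation patients:  {len(self.validation_ids)}",
                 f"seed:                 {self.config.seed}"]
        for name, table in self.stats_tables.items():
            lines.append(f"ome {name!r}: {int(table['selected'].sum())} of "
                         f"{len(table)} molecules selected")
        lines.append(f"ncRNA target sets kept: {len(self.ncrna_target_sets)}")
        lines.append(f"significant mutated genes: "
                     f"{len(self.mutated_significant)}")
        lines.append(f"enriched pathways: {len(self.enriched)}")
        lines.append(f"signature networks (power >= 1): {len(self.networks)}")
        lines.append(f"accepted models: {len(self.accepted_models)}")
        pt = self.power_table()
        if len(pt):
            lines.append("")
            lines.append(pt.to_string(index=False,
                                      float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-ready run report (seed and config always included)."""
        return {
            "config": self.config.to_dict(),
            "classes": list(self.model.classes),
            "train_ids": self.train_ids,
            "validation_ids": self.validation_ids,
            "selected_per_ome": {
                name: sorted(t.index[t["selected"]])
                for name, t in self.stats_tables.items()},
            "mutated_significant": sorted(self.mutated_significant),
            "ncrna_target_sets": [p.id for p in self.ncrna_target_sets],
            "power_table": self.power_table().to_dict(orient="records"),
        }

    # ------------------------------------------------------ model bundle

    def save(self, directory: str | Path) -> None:
        """Write a model bundle: manifest + networks + trained weights."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = self.to_report()
        manifest["scaling"] = {
            name: {"molecules": list(m.values.index),
                   "params": m.scaling_params.to_dict(orient="list"),
                   "ome_kind": m.ome_kind}
            for name, m in self.scaled_omes.items()}
        manifest["labels"] = self.model.labels.loc[self.fit_ids].to_dict()
        networks = []
        for net in self.networks:
            networks.append({
                "pathway_id": net.pathway_id,
                "patient_ids": net.patient_ids,
                "weights": net.weights.tolist(),
                "direction": net.direction,
                "labels": net.labels,
                "molecule_ids": net.molecule_ids,
                "profile": net.profile.to_dict(orient="split"),
                "sparsified": net.sparsified,
                "power": net.separability.power,
                "cohesive_class": net.separability.cohesive_class,
            })
        (directory / "manifest.json").write_text(json.dumps(manifest))
        (directory / "networks.json").write_text(json.dumps(networks))
        (directory / "models.json").write_text(json.dumps(
            {k: m.to_jsonable() for k, m in self.trained_models.items()}))


def load_bundle(directory: str | Path) -> "InferenceBundle":
    """Load a saved model bundle for inference on external cohorts."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    networks_raw = json.loads((directory / "networks.json").read_text())
    models_raw = json.loads((directory / "models.json").read_text())
    networks = []
    for d in networks_raw:
        profile = pd.DataFrame(**d["profile"]) if isinstance(
            d["profile"], dict) else None
        net = psn_mod.SimilarityNetwork(
            pathway_id=d["pathway_id"], patient_ids=d["patient_ids"],
            weights=np.asarray(d["weights"]), direction=d["direction"],
            labels=d["labels"], molecule_ids=d["molecule_ids"],
            profile=profile, sparsified=d["sparsified"])
        net.separability = psn_mod.SeparabilityResult(
            power=d["power"], cohesive_class=d["cohesive_class"],
            level_detail=[], mean_intra={}, mean_inter=float("nan"))
        networks.append(net)
    models = {k: gcn.TrainedPSNModel.from_jsonable(v)
              for k, v in models_raw.items()}
    return InferenceBundle(manifest=manifest, networks=networks,
                           models=models)


@dataclass
class InferenceBundle:
    """A reloaded model bundle: enough state to classify new cohorts."""

    manifest: dict
    networks: list[psn_mod.SimilarityNetwork]
    models: dict[str, gcn.TrainedPSNModel]

    def predict(self, omics_new: dict[str, OmicsMatrix],
                labels: pd.Series | None = None
                ) -> tuple[gcn.EnsemblePrediction, metrics.MetricReport | None]:
        """Classify external samples; metrics are computed when true
        labels are supplied."""
        config = RunConfig.from_dict(self.manifest["config"])
        classes = tuple(self.manifest["classes"])
        train_labels = pd.Series(self.manifest["labels"])
        blocks = []
        for name, scal in self.manifest["scaling"].items():
            if name not in omics_new:
                logger.warning("inference: ome %r missing, disabling its "
                               "models", name)
                continue
            ref_index = pd.Index(scal["molecules"])
            aligned = _normalize_like(omics_new[name], ref_index)
            aligned.scaling_params = pd.DataFrame(scal["params"],
                                                  index=ref_index)
            blocks.append(scale_unit_interval(aligned, fit=False).values)
        if not blocks:
            raise ValueError("zero applicable models: external data lacks "
                             f"all training omes {list(self.manifest['scaling'])}")
        combined = OmicsMatrix(pd.concat(blocks), "expression")
        sample_ids = combined.sample_ids
        available = set(combined.values.index)
        roles = {s: "train" for s in self.manifest["train_ids"]}
        roles.update({s: "validation"
                      for s in self.manifest["validation_ids"]})
        vote_frames = []
        for net in self.networks:
            model = self.models.get(net.pathway_id)
            if model is None or not model.accepted:
                continue
            if not set(net.molecule_ids) <= available:
                logger.info("inference: skipping %s (molecules missing)",
                            net.pathway_id)
                continue
            extended = psn_mod.attach_unknowns(
                net, combined, sample_ids,
                keep_fraction=config.sparsify_keep_fraction)
            feat = gcn.build_node_features(extended, train_labels, roles,
                                           class_order=classes)
            vote_frames.append(gcn.predict_unknowns(model, extended, feat,
                                                    sample_ids))
        if not vote_frames:
            raise ValueError("no usable signature networks for inference")
        ensemble = gcn.ensemble_vote(pd.concat(vote_frames,
                                               ignore_index=True))
        report = None
        if labels is not None:
            true = labels.reindex(ensemble.predictions.index)
            report = metrics.classification_metrics(true,
                                                    ensemble.predictions)
        return ensemble, report
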